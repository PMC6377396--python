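"""Figures: adversity-threshold scatter, defective CDFs, sweep histograms,
prior/posterior correlation densities."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .joint import JointPriorSpec
from .sampler import posterior_predictive_summary

QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def scatter_adversity_urgency(ela, urgency, ela_log, urg_log, path):
    """Raw and log-transformed adversity vs posterior-median threshold."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(ela, urgency, s=12, alpha=0.7)
    axes[0].set_xlabel("ELA")
    axes[0].set_ylabel("median threshold (b - A/2)")
    axes[1].scatter(ela_log, urg_log, s=12, alpha=0.7)
    axes[1].set_xlabel("ln(ELA + 1)")
    axes[1].set_ylabel("ln median threshold")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def defective_cdf(trials, draws, path, n_draws=50):
    """Observed vs posterior-predicted defective CDF (RT quantiles at the
    response proportions, correct and error separately)."""
    summ = posterior_predictive_summary(draws, trials, QUANTILES, n_draws=n_draws)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"correct": "tab:green", "error": "tab:red"}
    for resp in ("correct", "error"):
        for source, style in (("observed", "o"), ("predicted", "-x")):
            sub = summ[(summ.response == resp) & (summ.source == source)]
            y = sub["proportion"].to_numpy() * np.array(QUANTILES)
            ax.plot(sub["rt"], y, style, color=colors[resp], alpha=0.8,
                    label=f"{resp} {source}")
    ax.set_xlabel("RT (s)")
    ax.set_ylabel("defective cumulative proportion")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sweep_histograms(sweep_r, sweep_log_bf, path):
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].hist(sweep_r, bins=30, color="gray")
    axes[0].set_xlabel("correlation r (per posterior sample)")
    axes[1].hist(sweep_log_bf, bins=30, color="gray")
    axes[1].set_xlabel("ln BF10 (per posterior sample)")
    axes[1].axvline(0.0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rho_prior_posterior(rho_draws, prior: JointPriorSpec, path):
    """Posterior density of rho with its prior and the rho = 0 reference."""
    from scipy.stats import gaussian_kde

    lo, hi = prior.support
    grid = np.linspace(lo + 1e-3, hi - 1e-3, 400)
    kde = gaussian_kde(np.asarray(rho_draws).reshape(-1))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, kde(grid), "k", label="posterior")
    ax.plot(grid, np.exp(prior.log_prior_rho(grid)), color="dimgray", label="prior")
    ax.axvline(0.0, color="lightgray")
    ax.set_xlabel(r"correlation $\rho$")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pipeline_figures(outdir, config, indices, urgency, draws_by_p, trial_tables):
    """Best-effort figure bundle for a pipeline run."""
    import json

    import pandas as pd

    from .adversity import log_transform

    if indices is not None and urgency is not None:
        df = indices.copy()
        df["urgency"] = df["participant"].map(urgency)
        df = df.dropna(subset=["urgency"])
        scatter_adversity_urgency(
            df["ela"], df["urgency"],
            log_transform(df["ela"].to_numpy(dtype=float), config.count_offset),
            np.log(df["urgency"].to_numpy()),
            os.path.join(outdir, "fig_scatter.png"),
        )
    if draws_by_p:
        pid = sorted(draws_by_p)[0]
        defective_cdf(
            trial_tables[pid], draws_by_p[pid], os.path.join(outdir, "fig_cdf.png")
        )
    sweep_path = os.path.join(outdir, "sweep.csv")
    if os.path.exists(sweep_path):
        sw = pd.read_csv(sweep_path)
        sweep_histograms(sw["r"], sw["log_bf10"], os.path.join(outdir, "fig_sweep.png"))
    for name in sorted(os.listdir(outdir)):
        if name.startswith("joint_rho_") and name.endswith(".csv"):
            tag = name[len("joint_rho_"):-4]
            meta_path = os.path.join(outdir, f"joint_{tag}.json")
            if not os.path.exists(meta_path):
                continue
            with open(meta_path) as fh:
                meta = json.load(fh)
            rho = np.loadtxt(os.path.join(outdir, name), skiprows=1)
            rho_prior_posterior(
                rho,
                JointPriorSpec(kind=meta["prior"], partial=meta["partial"]),
                os.path.join(outdir, f"fig_rho_{tag}.png"),
            )
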