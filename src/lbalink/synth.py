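"""Synthetic study generator with known ground truth.

The study's raw human data are not deposited, so every pipeline stage is
validated against synthetic studies that emulate the real design: 126
participants, 5 blocks x 40 = 200 choice trials each, a distressing-life-
events survey yielding an ELA count (target moments M = 15, SD = 24, strong
positive skew), a SUDS-weighted Childhood Subjective Distress index (M = 52,
SD = 88), and a 28-item material-deprivation score (M = 1.8, SD = 0.586).

Generation order mirrors the assumed causal structure: a trivariate normal
draw of (ln urgency, ln(ELA+1), deprivation) with a configurable correlation
matrix defines each participant's latents; behaviour is realized by the LBA
simulator with the participant's urgency; the survey tables are realized so
that re-parsing them reproduces the latent adversity indices exactly.

Event-type and age weights for placing survey events come from a packaged
resource that mirrors the marginal frequencies of the published event-by-age
count table (stylized: only the marginals are used, and age 0 — absent from
the printed table — gets the same weight as age 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .adversity import AGES, EventReport, deprivation_score
from .lba import LbaParams, simulate_trials, write_trial_table

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "draw_latents",
    "realize_behavior",
    "realize_survey",
    "apply_exclusion",
    "generate_study",
    "default_reverse_flags",
]


def default_reverse_flags() -> np.ndarray:
    """Reverse-scoring pattern for the 28 deprivation items (every 4th)."""
    flags = np.zeros(28, dtype=bool)
    flags[3::4] = True
    return flags


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generating conditions.

    Defaults are the emulated study's conditions; correlations refer to the
    latent normal scale (ln urgency, ln(ELA+1), deprivation).
    """

    n_participants: int = 126
    trials_per_participant: int = 200  # 5 blocks x 40 trials
    true_rho: float = -0.2  # ln urgency vs ln(ELA+1)
    rho_md_urg: float = -0.1  # deprivation vs ln urgency
    rho_md_ela: float = 0.35  # deprivation vs ln(ELA+1)
    ela_mean: float = 15.0
    ela_sd: float = 24.0
    csd_mean: float = 52.0
    csd_sd: float = 88.0
    md_mean: float = 1.8
    md_sd: float = 0.586
    urg_log_mean: float = 0.2  # ln urgency marginal
    urg_log_sd: float = 0.25
    # population distributions of the non-threshold LBA parameters
    v_c_mean: float = 2.8
    v_c_sd: float = 0.8
    v_e_mean: float = 1.0
    v_e_sd: float = 0.5
    a_mean: float = 0.8
    a_sd: float = 0.25
    t0_mean: float = 0.25
    t0_sd: float = 0.05
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        R = np.array(
            [
                [1.0, self.true_rho, self.rho_md_urg],
                [self.true_rho, 1.0, self.rho_md_ela],
                [self.rho_md_urg, self.rho_md_ela, 1.0],
            ]
        )
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("implied correlation matrix is not positive-definite")
        return R

    def ela_log_params(self):
        """Lognormal moment matching for ELA + 1: mean, SD on the log scale."""
        m1 = self.ela_mean + 1.0
        s2 = np.log1p(self.ela_sd**2 / m1**2)
        return np.log(m1) - s2 / 2.0, np.sqrt(s2)


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    config: GeneratorConfig
    latents: pd.DataFrame  # participant, ln_urg, ln_ela1, md, ela_count, csd
    true_params: pd.DataFrame  # participant, v_c, v_e, A, k, t0, urgency
    trial_tables: dict  # participant -> DataFrame
    event_reports: list  # EventReport
    deprivation: pd.DataFrame  # participant, item_1..item_28
    reverse_flags: np.ndarray

    @property
    def participants(self):
        return list(self.latents["participant"])

    def to_dir(self, path):
        """Write the delimited-text files the pipeline consumes."""
        import os

        os.makedirs(path, exist_ok=True)
        trials = pd.concat(self.trial_tables.values(), ignore_index=True)
        write_trial_table(trials, os.path.join(path, "trials.csv"))
        pd.DataFrame(
            [
                {
                    "participant": r.participant,
                    "event_type": r.event_type,
                    "age_spec": r.age_spec,
                    "suds": r.suds,
                }
                for r in self.event_reports
            ],
            columns=["participant", "event_type", "age_spec", "suds"],
        ).to_csv(os.path.join(path, "events.csv"), index=False)
        self.deprivation.to_csv(os.path.join(path, "deprivation.csv"), index=False)
        truth = {
            "seed": self.config.seed,
            "true_rho": self.config.true_rho,
            "config": {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in vars(self.config).items()
            },
            "latents": self.latents.to_dict(orient="list"),
            "reverse_flags": self.reverse_flags.astype(int).tolist(),
        }
        with open(os.path.join(path, "ground_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)


def _load_weights():
    def read(name, key):
        text = resources.files("lbalink.data").joinpath(name).read_text()
        rows = [ln.split("\t") for ln in text.strip().split("\n")[1:]]
        return [r[0] for r in rows], np.array([float(r[1]) for r in rows])

    types, tw = read("event_weights.tsv", "event_type")
    ages, aw = read("age_weights.tsv", "age")
    return types, tw / tw.sum(), [int(a) for a in ages], aw / aw.sum()


def draw_latents(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Trivariate-normal participant latents and the implied ELA counts.

    Columns: ln_urg (ln urgency), ln_ela1 (latent ln(ELA+1)), md (target
    deprivation score, clipped to the 1-5 scale), ela_count (rounded,
    nonnegative realized count).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    R = config.corr_matrix()
    mu_e, sd_e = config.ela_log_params()
    means = np.array([config.urg_log_mean, mu_e, config.md_mean])
    sds = np.array([config.urg_log_sd, sd_e, config.md_sd])
    cov = R * np.outer(sds, sds)
    z = rng.multivariate_normal(means, cov, size=config.n_participants, method="cholesky")
    n_cells = len(_load_weights()[0]) * len(AGES)
    ela_count = np.clip(np.round(np.expm1(z[:, 1])), 0, n_cells).astype(int)
    ids = [f"P{i + 1:03d}" for i in range(config.n_participants)]
    return pd.DataFrame(
        {
            "participant": ids,
            "ln_urg": z[:, 0],
            "ln_ela1": z[:, 1],
            "md": np.clip(z[:, 2], 1.0, 5.0),
            "ela_count": ela_count,
        }
    )


def realize_behavior(latents: pd.DataFrame, config: GeneratorConfig, rng=None):
    """LBA trial tables per participant, honouring each latent urgency.

    Draws the non-threshold parameters from their population distributions,
    sets k = urgency - A/2 (re-drawing A when that would be nonpositive),
    and simulates balanced-stimulus trials.  Returns (trial_tables,
    true_params).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    tables = {}
    rows = []
    for _, row in latents.iterrows():
        urg = float(np.exp(row["ln_urg"]))
        for _ in range(200):
            A = rng.normal(config.a_mean, config.a_sd)
            if A > 0.05 and urg - A / 2.0 > 0.05:
                break
        else:
            A = min(0.1, urg)  # pathological urgency: minimal start-point range
        k = urg - A / 2.0
        v_c = max(rng.normal(config.v_c_mean, config.v_c_sd), 0.2)
        v_e = rng.normal(config.v_e_mean, config.v_e_sd)
        t0 = float(np.clip(rng.normal(config.t0_mean, config.t0_sd), 0.08, 0.5))
        p = LbaParams(v_c=v_c, v_e=v_e, A=A, k=k, t0=t0)
        tables[row["participant"]] = simulate_trials(
            p,
            config.trials_per_participant,
            seed=int(rng.integers(2**31 - 1)),
            participant=row["participant"],
        )
        rows.append(
            {
                "participant": row["participant"],
                "v_c": v_c,
                "v_e": v_e,
                "A": A,
                "k": k,
                "t0": t0,
                "urgency": urg,
            }
        )
    return tables, pd.DataFrame(rows)


def _runs(sorted_ages):
    """Split a sorted age list into contiguous runs."""
    runs = []
    for a in sorted_ages:
        if runs and a == runs[-1][-1] + 1:
            runs[-1].append(a)
        else:
            runs.append([a])
    return runs


def realize_survey(latents: pd.DataFrame, config: GeneratorConfig, rng=None):
    """Survey tables realizing the latent adversity exactly.

    Each participant's ela_count distinct (event type, age) cells are drawn
    without replacement with probabilities proportional to the packaged
    type x age marginal weights.  Contiguous ages of one event type merge
    into a span string; each run carries one SUDS rating from a scaled beta
    calibrated so the population CSD has approximately the configured
    moments.  Deprivation items are integers constructed so the reversed
    mean equals the latent md to within half an item step (1/56).

    Returns (event_reports, deprivation_frame, truth_frame) where
    truth_frame holds the realized ela/csd/md ground truth.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    types, tw, ages, aw = _load_weights()
    cellp = np.outer(tw, aw).reshape(-1)
    cellp /= cellp.sum()
    n_cells = cellp.size

    # scaled-beta SUDS calibration from the target CSD moments
    m_s = max(config.csd_mean / max(config.ela_mean, 1e-9), 1.0)
    var_s = max(
        (config.csd_sd**2 - (m_s**2) * config.ela_sd**2) / max(config.ela_mean, 1e-9),
        4.0,
    )
    mu01, var01 = m_s / 100.0, var_s / 100.0**2
    conc = max(mu01 * (1.0 - mu01) / var01 - 1.0, 0.1)
    a_beta, b_beta = mu01 * conc, (1.0 - mu01) * conc

    flags = default_reverse_flags()
    reports: list[EventReport] = []
    dep_rows = []
    truth_rows = []
    for _, row in latents.iterrows():
        pid = row["participant"]
        count = int(row["ela_count"])
        csd = 0.0
        if count > 0:
            cells = rng.choice(n_cells, size=count, replace=False, p=cellp)
            by_type: dict[int, list[int]] = {}
            for c in cells:
                by_type.setdefault(int(c) // len(ages), []).append(ages[int(c) % len(ages)])
            for ti, age_list in sorted(by_type.items()):
                for run in _runs(sorted(age_list)):
                    suds = int(np.clip(np.round(100.0 * rng.beta(a_beta, b_beta)), 0, 100))
                    spec = (
                        f"{run[0]}" if len(run) == 1 else f"{run[0]}-{run[-1]}"
                    )
                    reports.append(
                        EventReport(
                            participant=pid,
                            event_type=types[ti],
                            age_spec=spec,
                            suds=suds,
                        )
                    )
                    csd += suds * len(run)

        # deprivation items whose reversed mean hits the latent md exactly
        md = float(row["md"])
        target = int(np.clip(np.round(28 * md), 28, 140))
        items = np.clip(np.round(md + rng.normal(0.0, 0.8, size=28)), 1, 5).astype(int)
        diff = target - items.sum()
        while diff != 0:
            step = 1 if diff > 0 else -1
            adjustable = np.where((items < 5) if diff > 0 else (items > 1))[0]
            i = int(rng.choice(adjustable))
            items[i] += step
            diff -= step
        stored = np.where(flags, 6 - items, items)
        dep_rows.append({"participant": pid, **{f"item_{i+1}": int(v) for i, v in enumerate(stored)}})
        truth_rows.append(
            {
                "participant": pid,
                "ela": count,
                "csd": csd,
                "md": deprivation_score(stored, flags),
            }
        )
    return reports, pd.DataFrame(dep_rows), pd.DataFrame(truth_rows)


def draw_recovery_params(n: int, rng=None) -> pd.DataFrame:
    """Parameter sets for a recovery study, spanning the plausible range.

    Recovery simulations validate the estimator across the region where
    task parameters typically fall (rather than one study population):
    v_c ~ U(2, 4), v_e ~ U(0.5, 1.5), A ~ U(0.2, 1.2), k ~ U(0.2, 1.6),
    t0 ~ U(0.15, 0.35), giving urgencies between roughly 0.3 and 2.2.
    """
    rng = np.random.default_rng(rng)
    out = pd.DataFrame(
        {
            "v_c": rng.uniform(2.0, 4.0, n),
            "v_e": rng.uniform(0.5, 1.5, n),
            "A": rng.uniform(0.2, 1.2, n),
            "k": rng.uniform(0.2, 1.6, n),
            "t0": rng.uniform(0.15, 0.35, n),
        }
    )
    out["urgency"] = out["k"] + out["A"] / 2.0
    return out


def apply_exclusion(trial_tables: dict, threshold: float = 0.60):
    """Exclude participants with accuracy strictly below the threshold.

    Returns (retained_ids, log_frame); equality retains ("less than 60%"
    excludes).
    """
    rows = []
    retained = []
    for pid, table in trial_tables.items():
        acc = float(np.mean(table["correct"].to_numpy()))
        excluded = acc < threshold
        rows.append({"participant": pid, "accuracy": acc, "excluded": excluded})
        if not excluded:
            retained.append(pid)
    return retained, pd.DataFrame(rows)


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study: latents, behaviour, survey tables."""
    config = config or GeneratorConfig()
    latents = draw_latents(config)
    tables, true_params = realize_behavior(latents, config)
    reports, deprivation, truth = realize_survey(latents, config)
    latents = latents.merge(truth[["participant", "csd", "md"]].rename(columns={"md": "md_realized"}), on="participant")
    return SyntheticStudy(
        config=config,
        latents=latents,
        true_params=true_params,
        trial_tables=tables,
        event_reports=reports,
        deprivation=deprivation,
        reverse_flags=default_reverse_flags(),
    )
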