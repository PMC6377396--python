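"""End-to-end orchestration: generate/fit/indices/correlate/sweep/joint.

The pipeline mirrors the study's analysis plan: per-participant LBA fits
give posterior threshold distributions; survey tables give adversity
indices; point-estimate correlations (12 variants: {ela, csd, csd_early,
csd_late} x {raw Pearson, raw Kendall, log Pearson}, each also partialled
on material deprivation), a 500-draw posterior sweep, and the joint /
partial joint models under three rho priors ({ela, csd} x 3 priors x
{marginal, partial}).

Every stage writes delimited text or JSON into the run directory, records
the seeds used, and caches participant fits keyed by a hash of (trials,
priors, sampler config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import adversity as adv
from .adversity import log_transform, profiles_from_frame, read_event_reports
from .correlations import (
    kendall_one_tailed,
    pearson_one_tailed,
    posterior_sweep,
    residualize,
)
from .demcmc import SamplerConfig
from .joint import JointPriorSpec, fit_joint
from .lba import read_trial_table
from .priors import default_priors
from .sampler import fit_participant, load_draws, median_urgency, save_draws
from .synth import GeneratorConfig, apply_exclusion, default_reverse_flags, generate_study

log = logging.getLogger("lbalink")

STAGES = ("generate", "fit", "indices", "correlate", "sweep", "joint")
INDEX_VARIANTS = ("ela", "csd", "csd_early", "csd_late")
JOINT_INDICES = ("ela", "csd")
JOINT_PRIORS = ("uniform_onesided", "halfnormal_onesided", "estimation")


@dataclass
class RunConfig:
    """Structured pipeline configuration (YAML-loadable)."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    # inputs (ignored when the generate stage runs)
    trials_path: str | None = None
    events_path: str | None = None
    deprivation_path: str | None = None
    rt_in_ms: bool = False
    # stage settings
    generator: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    joint_sampler: dict = field(default_factory=lambda: {"n_chains": 9, "n_iter": 1500, "burn_in": 750})
    joint_variants: dict = field(
        default_factory=lambda: {
            "indices": list(JOINT_INDICES),
            "priors": list(JOINT_PRIORS),
            "partial": [False, True],
        }
    )
    sweep_draws: int = 500
    exclusion_threshold: float = 0.60
    count_offset: float = 1.0
    reverse_flags: list | None = None  # 28 booleans; default packaged pattern

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sampler_config(self, seed) -> SamplerConfig:
        return SamplerConfig(seed=seed, **self.sampler)

    def joint_config(self, seed) -> SamplerConfig:
        return SamplerConfig(seed=seed, **self.joint_sampler)


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def validate_inputs(trials_path=None, events_path=None, deprivation_path=None):
    """Schema checks on the delimited input files.

    Returns a dict with ``errors`` (schema violations), ``warnings``
    (participants missing from some table — the analysis uses completers
    only), and per-file row counts.
    """
    errors, warnings_, counts = [], [], {}
    trial_ids = event_ids = dep_ids = None
    if trials_path:
        try:
            trials = read_trial_table(trials_path)
            counts["trials"] = len(trials)
            trial_ids = set(trials["participant"].astype(str))
        except Exception as e:
            errors.append(f"trials: {e}")
    if events_path:
        try:
            reports = read_event_reports(events_path)
            counts["events"] = len(reports)
            event_ids = {r.participant for r in reports}
            vocab = set(adv.event_vocabulary())
            bad = {r.event_type for r in reports} - vocab
            if bad:
                errors.append(f"events: unknown event types {sorted(bad)}")
        except Exception as e:
            errors.append(f"events: {e}")
    if deprivation_path:
        try:
            dep = pd.read_csv(deprivation_path, dtype={"participant": str})
            counts["deprivation"] = len(dep)
            items = [f"item_{i}" for i in range(1, 29)]
            missing = [c for c in items if c not in dep.columns]
            if missing:
                errors.append(f"deprivation: missing columns {missing}")
            else:
                vals = dep[items].to_numpy()
                if np.any((vals < 1) | (vals > 5)):
                    errors.append("deprivation: responses outside 1-5")
            dep_ids = set(dep["participant"])
        except Exception as e:
            errors.append(f"deprivation: {e}")
    if trial_ids is not None:
        for other, name in ((event_ids, "events"), (dep_ids, "deprivation")):
            if other is not None:
                only_trials = trial_ids - other
                if only_trials:
                    warnings_.append(
                        f"participants with trials but no {name} entry "
                        f"(excluded from correlation stages): {sorted(only_trials)}"
                    )
    return {"errors": errors, "warnings": warnings_, "counts": counts}


def _fit_cache_key(trials: pd.DataFrame, config: SamplerConfig) -> str:
    h = hashlib.sha256()
    h.update(trials[["rt", "correct"]].to_csv(index=False).encode())
    h.update(repr(default_priors(float(trials["rt"].min()))).encode())
    h.update(
        f"{config.n_chains},{config.n_iter},{config.burn_in},{config.jitter},{config.seed}".encode()
    )
    return h.hexdigest()[:16]


def fit_all_participants(trial_tables: dict, config: RunConfig, fits_dir: str) -> dict:
    """Fit every participant (cached); returns participant -> PosteriorDraws."""
    os.makedirs(fits_dir, exist_ok=True)
    out = {}
    rng = np.random.default_rng(config.seed)
    for pid in sorted(trial_tables):
        trials = trial_tables[pid]
        pseed = int(rng.integers(2**31 - 1))
        scfg = config.sampler_config(pseed)
        key = _fit_cache_key(trials, scfg)
        csv_path = os.path.join(fits_dir, f"{pid}.csv")
        meta_path = os.path.join(fits_dir, f"{pid}.json")
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                if json.load(fh).get("cache_key") == key:
                    out[pid] = load_draws(csv_path, meta_path)
                    log.info("fit %s: cache hit", pid)
                    continue
        draws = fit_participant(trials, config=scfg)
        save_draws(draws, csv_path, meta_path, config=scfg)
        with open(meta_path) as fh:
            meta = json.load(fh)
        meta["cache_key"] = key
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)
        rh = max(draws.rhat().values())
        if rh > 1.05:
            log.warning("fit %s: max R-hat %.3f > 1.05", pid, rh)
        out[pid] = draws
    return out


def _index_table(profiles: dict, deprivation: pd.Series) -> pd.DataFrame:
    rows = []
    for pid, prof in profiles.items():
        rows.append(
            {
                "participant": pid,
                "ela": prof.ela,
                "csd": prof.csd,
                "csd_early": prof.csd_early,
                "csd_late": prof.csd_late,
                "ela_early": prof.ela_early,
                "ela_late": prof.ela_late,
                "deprivation": deprivation.get(pid, np.nan),
            }
        )
    return pd.DataFrame(rows).sort_values("participant").reset_index(drop=True)


def correlation_battery(indices: pd.DataFrame, urgency: pd.Series, count_offset=1.0) -> pd.DataFrame:
    """All point-estimate correlation variants as one tidy table.

    Variants: each adversity index x {raw Pearson, raw Kendall, log
    Pearson}, marginal and partialled on material deprivation (raw
    deprivation for raw variants, ln deprivation for log variants).
    """
    df = indices.copy()
    df["urgency"] = df["participant"].map(urgency)
    df = df.dropna(subset=["urgency", "deprivation"])
    rows = []
    urg = df["urgency"].to_numpy()
    log_urg = log_transform(urg, 0.0)
    md = df["deprivation"].to_numpy()
    log_md = log_transform(md, 0.0)
    for index_variant in INDEX_VARIANTS:
        x = df[index_variant].to_numpy(dtype=float)
        log_x = log_transform(x, count_offset)
        specs = [
            ("raw", "pearson", x, urg, md),
            ("raw", "kendall", x, urg, md),
            ("log", "pearson", log_x, log_urg, log_md),
        ]
        for transform, method, xv, yv, mv in specs:
            fn = pearson_one_tailed if method == "pearson" else kendall_one_tailed
            for partial in (False, True):
                if partial:
                    xv_, yv_ = residualize(xv, mv), residualize(yv, mv)
                else:
                    xv_, yv_ = xv, yv
                res = fn(xv_, yv_, transform=transform, partial=partial)
                rows.append(
                    {
                        "index_variant": index_variant,
                        "transform": transform,
                        "partial": partial,
                        "method": method,
                        "r": res.r,
                        "p": res.p_one_tailed,
                        "bf10": res.bf10,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> str:
    """Execute the configured stages; returns the run directory."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    stage = "setup"
    try:
        # ------------------------------------------------ generate / load
        if "generate" in config.stages:
            stage = "generate"
            gcfg = GeneratorConfig(seed=config.seed, **config.generator)
            study = generate_study(gcfg)
            study.to_dir(outdir)
            trial_tables = study.trial_tables
            reports = study.event_reports
            dep_frame = study.deprivation
            reverse_flags = study.reverse_flags
        else:
            stage = "load"
            trials = read_trial_table(config.trials_path, rt_in_ms=config.rt_in_ms)
            trial_tables = {
                str(p): g.reset_index(drop=True)
                for p, g in trials.groupby("participant")
            }
            reports = read_event_reports(config.events_path)
            dep_frame = pd.read_csv(config.deprivation_path, dtype={"participant": str})
            reverse_flags = (
                np.asarray(config.reverse_flags, dtype=bool)
                if config.reverse_flags is not None
                else default_reverse_flags()
            )

        stage = "exclusion"
        retained, excl_log = apply_exclusion(trial_tables, config.exclusion_threshold)
        excl_log.to_csv(os.path.join(outdir, "exclusions.csv"), index=False)
        summary["n_excluded"] = int(excl_log["excluded"].sum())
        trial_tables = {p: trial_tables[p] for p in retained}

        # completers only: participants present in all tables
        survey_ids = {r.participant for r in reports} | set()
        dep_ids = set(dep_frame["participant"].astype(str))
        complete = [p for p in retained if p in dep_ids]
        summary["n_analyzed"] = len(complete)

        # ------------------------------------------------ fits
        draws_by_p = {}
        if "fit" in config.stages:
            stage = "fit"
            draws_by_p = fit_all_participants(
                {p: trial_tables[p] for p in complete}, config, os.path.join(outdir, "fits")
            )
            urgency = pd.Series(
                {p: median_urgency(d) for p, d in draws_by_p.items()}, name="urgency"
            )
            urgency.rename_axis("participant").to_csv(
                os.path.join(outdir, "median_urgency.csv")
            )

        # ------------------------------------------------ indices
        if "indices" in config.stages:
            stage = "indices"
            profiles = profiles_from_frame(reports)
            for pid in complete:  # zero-event completers get empty profiles
                if pid not in profiles:
                    profiles[pid] = adv.build_profile([], participant=pid)
            items = [f"item_{i}" for i in range(1, 29)]
            dep_scores = pd.Series(
                {
                    str(row["participant"]): adv.deprivation_score(
                        row[items].to_numpy(dtype=float), reverse_flags
                    )
                    for _, row in dep_frame.iterrows()
                },
                name="deprivation",
            )
            indices = _index_table(
                {p: profiles[p] for p in complete if p in profiles}, dep_scores
            )
            indices.to_csv(os.path.join(outdir, "indices.csv"), index=False)

        # ------------------------------------------------ correlations
        if "correlate" in config.stages:
            stage = "correlate"
            corr = correlation_battery(indices, urgency, config.count_offset)
            corr.to_csv(os.path.join(outdir, "correlations.csv"), index=False)
            key = corr[
                (corr["index_variant"] == "ela")
                & (corr["transform"] == "log")
                & (~corr["partial"])
            ].iloc[0]
            summary["log_ela_pearson"] = {
                "r": float(key.r), "p": float(key.p), "bf10": float(key.bf10), "n": int(key.n)
            }

        # ------------------------------------------------ sweep
        if "sweep" in config.stages:
            stage = "sweep"
            order = list(indices["participant"])
            ela_log = log_transform(
                indices["ela"].to_numpy(dtype=float), config.count_offset
            )
            sweep = posterior_sweep(
                [draws_by_p[p] for p in order],
                ela_log,
                n_draws=config.sweep_draws,
                seed=config.seed + 7,
            )
            pd.DataFrame(
                {
                    "draw": np.arange(len(sweep.r)),
                    "r": sweep.r,
                    "log_bf10": np.log(sweep.bf10),
                }
            ).to_csv(os.path.join(outdir, "sweep.csv"), index=False)
            summary["sweep"] = {
                "r_range": sweep.r_range,
                "log_bf_range": [float(np.log(b)) for b in sweep.bf_range],
            }

        # ------------------------------------------------ joint models
        if "joint" in config.stages:
            stage = "joint"
            jv = config.joint_variants
            rngj = np.random.default_rng(config.seed + 13)
            joint_summaries = {}
            order = list(indices["participant"])
            tables = [trial_tables[p] for p in order]
            md = indices.set_index("participant").loc[order, "deprivation"].to_numpy()
            for index_variant in jv["indices"]:
                x = indices.set_index("participant").loc[order, index_variant].to_numpy(dtype=float)
                x_log = log_transform(x, config.count_offset)
                for kind in jv["priors"]:
                    for partial in jv["partial"]:
                        spec = JointPriorSpec(kind=kind, partial=partial)
                        jseed = int(rngj.integers(2**31 - 1))
                        res = fit_joint(
                            tables,
                            x_log,
                            prior=spec,
                            config=config.joint_config(jseed),
                            md=md if partial else None,
                        )
                        tag = f"{index_variant}_{kind}" + ("_partial" if partial else "")
                        np.savetxt(
                            os.path.join(outdir, f"joint_rho_{tag}.csv"),
                            res.rho_flat,
                            header="rho",
                            comments="",
                        )
                        joint_summaries[tag] = {
                            "bf10": res.bf10,
                            "ci95": list(res.ci95),
                            "rho_mean": float(res.rho_flat.mean()),
                            "rhat": res.rhat_rho,
                            "prior": kind,
                            "partial": partial,
                            "seed": jseed,
                            "diverged": res.diverged,
                        }
                        with open(os.path.join(outdir, f"joint_{tag}.json"), "w") as fh:
                            json.dump(joint_summaries[tag], fh, indent=1)
            summary["joint"] = joint_summaries

        # ------------------------------------------------ figures
        if "correlate" in config.stages or "joint" in config.stages:
            stage = "figures"
            try:
                from . import plots

                plots.pipeline_figures(outdir, config, indices if "indices" in config.stages else None,
                                       urgency if "fit" in config.stages else None,
                                       draws_by_p, trial_tables)
            except Exception as e:  # figures are best-effort
                log.warning("figure generation failed: %s", e)

        stage = "summary"
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return outdir
    except Exception as e:
        raise StageError(stage, e) from e
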