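"""Early-life-adversity indices from survey-style tables.

Two indices per participant, both built from an event-type x age (0-18)
matrix of self-reported distressing life events:

* **ELA** — the count of distinct (event type, age) cells experienced
  before age 19 (binary matrix sum).
* **CSD** (Childhood Subjective Distress) — the same matrix with each
  present cell weighted by the 0-100 SUDS distress rating, then summed.
  This distinguishes many mild events from few severe ones.

Both indices also come in early (ages 0-7) and late (ages 8-18) windows,
and a 28-item material-deprivation score (1-5 Likert, some items
reverse-scored) serves as the covariate for partial-correlation analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AGES",
    "EARLY_AGES",
    "LATE_AGES",
    "EventReport",
    "AdversityProfile",
    "event_vocabulary",
    "parse_age_spec",
    "build_profile",
    "windowed_indices",
    "deprivation_score",
    "log_transform",
    "read_event_reports",
    "read_deprivation_table",
    "profiles_from_frame",
]

AGES = tuple(range(0, 19))  # ages 0-18 inclusive, 19 columns
EARLY_AGES = tuple(range(0, 8))  # "ages 7 and under"
LATE_AGES = tuple(range(8, 19))  # "ages 8-18"

_TOKEN_RE = re.compile(r"^(\d+)(?:\s*[-–]\s*(\d+))?$")


def event_vocabulary() -> list[str]:
    """Controlled vocabulary of distressing-event types (packaged resource)."""
    text = resources.files("lbalink.data").joinpath("event_weights.tsv").read_text()
    return [ln.split("\t")[0] for ln in text.strip().split("\n")[1:]]


@dataclass(frozen=True)
class EventReport:
    """One survey row: an event type, the ages it spans, one SUDS rating."""

    participant: str
    event_type: str
    age_spec: str
    suds: int

    def __post_init__(self):
        if not 0 <= self.suds <= 100:
            raise ValueError(
                f"SUDS must be in [0, 100], got {self.suds} "
                f"(participant {self.participant})"
            )


@dataclass(frozen=True)
class AdversityProfile:
    """Event x age matrices and the scalar adversity indices they imply."""

    participant: str
    binary_matrix: pd.DataFrame  # event_type x age, bool
    suds_matrix: pd.DataFrame  # event_type x age, 0-100 where binary

    @property
    def ela(self) -> int:
        return int(self.binary_matrix.to_numpy().sum())

    @property
    def csd(self) -> float:
        return float(self.suds_matrix.to_numpy().sum())

    @property
    def ela_early(self) -> int:
        return int(self.binary_matrix[list(EARLY_AGES)].to_numpy().sum())

    @property
    def ela_late(self) -> int:
        return int(self.binary_matrix[list(LATE_AGES)].to_numpy().sum())

    @property
    def csd_early(self) -> float:
        return float(self.suds_matrix[list(EARLY_AGES)].to_numpy().sum())

    @property
    def csd_late(self) -> float:
        return float(self.suds_matrix[list(LATE_AGES)].to_numpy().sum())


def parse_age_spec(text: str, participant: str = "?") -> set[int]:
    """Expand an age-span string like ``"8, 12-14, 25-35"`` to integer ages.

    Ranges are inclusive; hyphen and en-dash both accepted; whitespace
    ignored; the empty string gives the empty set.
    """
    ages: set[int] = set()
    if text is None:
        return ages
    text = str(text).strip()
    if not text:
        return ages
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError(
                f"malformed age token {token!r} for participant {participant}"
            )
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise ValueError(
                f"decreasing age range {token!r} for participant {participant}"
            )
        ages.update(range(lo, hi + 1))
    return ages


def build_profile(
    reports, participant: str | None = None, vocabulary=None
) -> AdversityProfile:
    """Build one participant's event x age matrices from parsed reports.

    Ages outside 0-18 are dropped.  A binary cell is 1 if any report places
    that event type at that age; where two reports hit the same cell with
    different SUDS, the cell keeps the maximum (the most distressing
    experience of that event-year).
    """
    vocab = list(vocabulary) if vocabulary is not None else event_vocabulary()
    reports = list(reports)
    if participant is None:
        participant = reports[0].participant if reports else "?"
    binary = pd.DataFrame(False, index=vocab, columns=list(AGES))
    suds = pd.DataFrame(0.0, index=vocab, columns=list(AGES))
    for rep in reports:
        if rep.event_type not in binary.index:
            raise ValueError(
                f"unknown event type {rep.event_type!r} "
                f"(participant {rep.participant})"
            )
        for age in parse_age_spec(rep.age_spec, rep.participant):
            if age not in AGES:
                continue
            binary.loc[rep.event_type, age] = True
            suds.loc[rep.event_type, age] = max(
                suds.loc[rep.event_type, age], float(rep.suds)
            )
    return AdversityProfile(participant=participant, binary_matrix=binary, suds_matrix=suds)


def windowed_indices(profile: AdversityProfile) -> dict:
    """Early (0-7) and late (8-18) sub-indices; they partition the totals."""
    return {
        "ela_early": profile.ela_early,
        "ela_late": profile.ela_late,
        "csd_early": profile.csd_early,
        "csd_late": profile.csd_late,
    }


def deprivation_score(responses, reverse_flags) -> float:
    """Mean of 28 Likert items (1-5) after reverse-scoring flagged items.

    Reversal maps r -> 6 - r, so an 'Always' on a positively worded item
    counts as no deprivation.
    """
    r = np.asarray(responses, dtype=float)
    flags = np.asarray(reverse_flags, dtype=bool)
    if r.shape != flags.shape:
        raise ValueError("responses and reverse_flags must align")
    if np.any((r < 1) | (r > 5)) or np.any(r != np.round(r)):
        bad = np.where((r < 1) | (r > 5) | (r != np.round(r)))[0]
        raise ValueError(f"deprivation responses outside 1-5 at items {bad.tolist()}")
    adj = np.where(flags, 6.0 - r, r)
    return float(adj.mean())


def log_transform(values, offset: float = 0.0, labels=None):
    """Natural-log transform ln(value + offset).

    Count-like adversity indices use offset 1 (so zero-adversity
    participants stay defined); thresholds are strictly positive and use
    offset 0.  Raises, naming offenders, if any argument is nonpositive.
    """
    arr = np.asarray(values, dtype=float)
    shifted = arr + offset
    if np.any(shifted <= 0):
        bad = np.where(shifted <= 0)[0]
        who = [labels[i] for i in bad] if labels is not None else bad.tolist()
        raise ValueError(f"nonpositive values under log transform: {who}")
    return np.log(shifted)


def read_event_reports(path) -> list[EventReport]:
    """Read `participant,event_type,age_spec,suds` delimited text."""
    df = pd.read_csv(path, dtype={"participant": str, "age_spec": str}, keep_default_na=False)
    needed = {"participant", "event_type", "age_spec", "suds"}
    if not needed.issubset(df.columns):
        raise ValueError(f"events file missing columns: {sorted(needed - set(df.columns))}")
    return [
        EventReport(
            participant=row.participant,
            event_type=row.event_type,
            age_spec=row.age_spec,
            suds=int(row.suds),
        )
        for row in df.itertuples()
    ]


def profiles_from_frame(reports) -> dict[str, AdversityProfile]:
    """Group reports by participant and build each profile."""
    by_p: dict[str, list[EventReport]] = {}
    for rep in reports:
        by_p.setdefault(rep.participant, []).append(rep)
    vocab = event_vocabulary()
    return {
        p: build_profile(reps, participant=p, vocabulary=vocab)
        for p, reps in by_p.items()
    }


def read_deprivation_table(path, reverse_flags) -> pd.Series:
    """Read `participant,item_1..item_28` and score each participant."""
    df = pd.read_csv(path, dtype={"participant": str})
    items = [f"item_{i}" for i in range(1, 29)]
    missing = [c for c in items if c not in df.columns]
    if missing:
        raise ValueError(f"deprivation file missing columns: {missing}")
    flags = np.asarray(reverse_flags, dtype=bool)
    scores = {
        row["participant"]: deprivation_score(row[items].to_numpy(), flags)
        for _, row in df.iterrows()
    }
    return pd.Series(scores, name="deprivation")
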