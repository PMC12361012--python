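"""Respondent classification: T-score thresholds and the GCPS-R rubric.

Two independent routes to an impact level:

* ``classify_t`` — count how many panel thresholds the T-score reaches; a
  score equal to a threshold belongs to the HIGHER level (the threshold is
  the midpoint in front of the first vignette better described by the
  higher level).
* ``gcpsr_classify`` — the GCPS-R rubric: high-impact chronic pain (HICP)
  when both frequency items are "most days"/"every day"; otherwise a
  no-impact gate, then PEG >= 12 separates bothersome from mild.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .bookmarks import ThresholdSet

__all__ = [
    "Frequency",
    "GCPSRResponse",
    "ImpactLevel",
    "GCPSR_LABELS",
    "PEG_CUTOFF",
    "classify_t",
    "classify_sample",
    "peg_score",
    "gcpsr_classify",
    "load_gcpsr_responses",
    "classify_gcpsr_table",
]

GCPSR_LABELS = ("no impact", "mild", "bothersome", "high impact")
PEG_CUTOFF = 12
Gate = Literal["chronic_pain", "never_only"]


class Frequency(IntEnum):
    """Frequency of pain over the last 3 months."""

    NEVER = 0
    SOME_DAYS = 1
    MOST_DAYS = 2
    EVERY_DAY = 3

    @classmethod
    def parse(cls, value) -> "Frequency":
        """Accept verbatim strings ('most days') or 0-3 integer codes."""
        if isinstance(value, Frequency):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        text = str(value).strip().lower().replace("_", " ")
        mapping = {
            "never": cls.NEVER,
            "some days": cls.SOME_DAYS,
            "most days": cls.MOST_DAYS,
            "every day": cls.EVERY_DAY,
        }
        if text in mapping:
            return mapping[text]
        if text.isdigit():
            return cls(int(text))
        raise ValueError(f"unrecognized frequency value: {value!r}")


@dataclass(frozen=True)
class GCPSRResponse:
    """Two 3-month frequency items plus the three 0-10 PEG items."""

    freq_pain: Frequency
    freq_limit: Frequency
    peg_items: tuple[int, int, int]  # intensity, enjoyment-of-life, general activities

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_pain", Frequency.parse(self.freq_pain))
        object.__setattr__(self, "freq_limit", Frequency.parse(self.freq_limit))
        peg = tuple(int(x) for x in self.peg_items)
        if len(peg) != 3 or any(not 0 <= x <= 10 for x in peg):
            raise ValueError(f"PEG items must be three integers in 0..10, got {self.peg_items}")
        object.__setattr__(self, "peg_items", peg)


@dataclass(frozen=True)
class ImpactLevel:
    """Ordinal impact level: index 0..K with its rubric label."""

    index: int
    label: str

    def __int__(self) -> int:
        return self.index


def classify_t(t: float, thresholds: ThresholdSet) -> ImpactLevel:
    """Level of a T-score: the number of thresholds it reaches (ties go up)."""
    t = float(t)
    if not np.isfinite(t):
        raise ValueError(f"T-score must be finite, got {t}")
    idx = int(np.searchsorted(np.asarray(thresholds.thresholds), t, side="right"))
    return ImpactLevel(index=idx, label=thresholds.labels[idx])


def classify_sample(scores: Sequence[float], thresholds: ThresholdSet) -> pd.DataFrame:
    """Counts and proportions per level for a vector of T-scores."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("scores vector is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    idx = np.searchsorted(np.asarray(thresholds.thresholds), arr, side="right")
    counts = np.bincount(idx, minlength=len(thresholds.labels))
    return pd.DataFrame({
        "level": np.arange(len(thresholds.labels)),
        "label": thresholds.labels,
        "count": counts,
        "proportion": counts / arr.size,
    })


def peg_score(r: GCPSRResponse) -> int:
    """Sum of the three 0-10 PEG items (0..30)."""
    return int(sum(r.peg_items))


def gcpsr_classify(r: GCPSRResponse, gate: Gate = "chronic_pain") -> ImpactLevel:
    """GCPS-R rubric classification into the four impact levels.

    HICP requires *both* frequency items at most days/every day and is
    independent of PEG.  The no-impact gate is configurable because the
    source rubric's exact gate is published elsewhere:

    * ``"chronic_pain"`` (default): no impact when pain frequency is
      never/some days.
    * ``"never_only"``: no impact only when pain frequency is never.
    """
    if gate not in ("chronic_pain", "never_only"):
        raise ValueError(f"unknown gate {gate!r}")
    hicp = r.freq_pain >= Frequency.MOST_DAYS and r.freq_limit >= Frequency.MOST_DAYS
    if hicp:
        return ImpactLevel(index=3, label=GCPSR_LABELS[3])
    if gate == "chronic_pain":
        no_impact = r.freq_pain <= Frequency.SOME_DAYS
    else:
        no_impact = r.freq_pain == Frequency.NEVER
    if no_impact:
        return ImpactLevel(index=0, label=GCPSR_LABELS[0])
    if peg_score(r) >= PEG_CUTOFF:
        return ImpactLevel(index=2, label=GCPSR_LABELS[2])
    return ImpactLevel(index=1, label=GCPSR_LABELS[1])


# ---------------------------------------------------------------------------
# I/O

_GCPSR_COLS = ("freq_pain", "freq_limit", "peg_intensity", "peg_enjoyment", "peg_activity")


def load_gcpsr_responses(path: str | Path) -> pd.DataFrame:
    """Read a GCPS-R CSV; frequency columns may be verbatim strings or 0-3 codes."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    missing = [c for c in ("respondent_id",) + _GCPSR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def classify_gcpsr_table(df: pd.DataFrame, gate: Gate = "chronic_pain") -> pd.DataFrame:
    """Classify each record; incomplete records are refused with a reason code."""
    out = []
    for _, row in df.iterrows():
        rid = row["respondent_id"]
        if any(pd.isna(row[c]) for c in _GCPSR_COLS):
            bad = [c for c in _GCPSR_COLS if pd.isna(row[c])]
            out.append({"respondent_id": rid, "level": pd.NA, "label": pd.NA,
                        "reason": f"missing:{','.join(bad)}"})
            continue
        r = GCPSRResponse(
            freq_pain=Frequency.parse(row["freq_pain"]),
            freq_limit=Frequency.parse(row["freq_limit"]),
            peg_items=(int(row["peg_intensity"]), int(row["peg_enjoyment"]),
                       int(row["peg_activity"])),
        )
        lvl = gcpsr_classify(r, gate=gate)
        out.append({"respondent_id": rid, "level": lvl.index, "label": lvl.label, "reason": ""})
    return pd.DataFrame(out)
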