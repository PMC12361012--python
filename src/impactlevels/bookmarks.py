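"""Bookmark-panel thresholds.

Panelists order the vignettes by impact and drop a bookmark into the gap
where one level ends and the next begins.  An individual threshold is the
mean of the two adjacent vignettes' calibrated scores, rounded half-up to
integer T (63 and 66 -> 65).  Group thresholds are per-boundary modes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .vignettes import VignetteSet, round_half_up

__all__ = [
    "BookmarkPlacement",
    "ThresholdSet",
    "DEFAULT_LEVEL_LABELS",
    "PANELS",
    "individual_thresholds",
    "modal_thresholds",
    "threshold_distribution",
    "load_placements",
    "save_placements",
    "load_threshold_set",
    "save_threshold_set",
]

DEFAULT_LEVEL_LABELS = ("none", "mild", "moderate", "high")
PANELS = ("PLwCP", "clinician")


@dataclass(frozen=True)
class BookmarkPlacement:
    """One panelist's gap indices, one per level boundary.

    Gap ``g`` (1-based) means "between vignette g and g+1" in calibrated
    order.  Gaps must be nondecreasing; two boundaries may share a gap, but
    that yields equal thresholds, which group aggregation rejects.
    """

    panelist_id: str
    panel: str
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        gaps = tuple(int(g) for g in self.gaps)
        if not gaps:
            raise ValueError(f"panelist {self.panelist_id!r}: no gap placements")
        if any(g < 1 for g in gaps):
            raise ValueError(f"panelist {self.panelist_id!r}: gap indices are 1-based, got {gaps}")
        if any(b < a for a, b in zip(gaps, gaps[1:])):
            raise ValueError(f"panelist {self.panelist_id!r}: gaps must be nondecreasing: {gaps}")
        object.__setattr__(self, "gaps", gaps)

    def validate_against(self, vset: VignetteSet) -> None:
        max_gap = len(vset) - 1
        for k, g in enumerate(self.gaps, start=1):
            if g > max_gap:
                raise ValueError(
                    f"panelist {self.panelist_id!r}: boundary {k} gap {g} out of range "
                    f"1..{max_gap} for {len(vset)} vignettes"
                )


@dataclass(frozen=True)
class ThresholdSet:
    """K increasing threshold T-scores separating K+1 levels.

    Modal (group) threshold sets must be strictly increasing.  Individual
    sets may carry equal neighbors — a panelist may drop two bookmarks into
    one gap — which group aggregation then rejects as a data-quality error.
    """

    labels: tuple[str, ...]
    thresholds: tuple[float, ...]
    provenance: str = "individual"
    n_panelists: int = 1
    ties: tuple[int, ...] = ()  # boundary indices (1-based) where the mode was tied

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        thr = tuple(float(t) for t in self.thresholds)
        if len(labels) != len(thr) + 1:
            raise ValueError(f"need len(labels) == len(thresholds)+1, got {len(labels)} vs {len(thr)}")
        if any(b < a for a, b in zip(thr, thr[1:])):
            raise ValueError(f"thresholds must be nondecreasing: {thr}")
        if self.provenance == "modal" and any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError(f"modal thresholds must be strictly increasing: {thr}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "ties", tuple(int(i) for i in self.ties))

    def __len__(self) -> int:
        return len(self.thresholds)


def _gap_threshold(vset_scores: np.ndarray, gap: int) -> int:
    return int(round_half_up((vset_scores[gap - 1] + vset_scores[gap]) / 2.0))


def individual_thresholds(
    p: BookmarkPlacement,
    vset: VignetteSet | Sequence[float],
    labels: Sequence[str] = DEFAULT_LEVEL_LABELS,
) -> ThresholdSet:
    """One panelist's thresholds: rounded means of bookmark-adjacent vignette scores.

    ``vset`` may be a :class:`VignetteSet` or a plain ascending sequence of
    calibrated scores.
    """
    if isinstance(vset, VignetteSet):
        p.validate_against(vset)
        scores = vset.calibrated_scores
    else:
        scores = np.asarray(vset, dtype=float)
        if any(g > len(scores) - 1 for g in p.gaps):
            raise ValueError(f"panelist {p.panelist_id!r}: gap out of range for {len(scores)} scores")
    thr = tuple(_gap_threshold(scores, g) for g in p.gaps)
    return ThresholdSet(labels=tuple(labels), thresholds=thr, provenance="individual",
                        n_panelists=1)


def modal_thresholds(
    placements: Iterable[BookmarkPlacement],
    vset: VignetteSet | Sequence[float],
    panel_filter: str | None = None,
    labels: Sequence[str] = DEFAULT_LEVEL_LABELS,
) -> ThresholdSet:
    """Per-boundary mode of individual thresholds, as the group cut scores.

    Multimodal ties resolve toward the candidate nearest the boundary's
    panel median (remaining tie: lower value) and are flagged in ``ties``.
    A non-increasing modal sequence raises with per-boundary diagnostics.
    """
    placements = [p for p in placements if panel_filter is None or p.panel == panel_filter]
    if not placements:
        raise ValueError(f"no placements after filtering on panel={panel_filter!r}")
    per_panelist = [individual_thresholds(p, vset, labels) for p in placements]
    n_boundaries = {len(ts) for ts in per_panelist}
    if len(n_boundaries) != 1:
        raise ValueError(f"inconsistent boundary counts across panelists: {sorted(n_boundaries)}")
    k = n_boundaries.pop()
    modal, tied = [], []
    for b in range(k):
        values = [ts.thresholds[b] for ts in per_panelist]
        counts = Counter(values)
        top = max(counts.values())
        candidates = sorted(v for v, c in counts.items() if c == top)
        if len(candidates) > 1:
            tied.append(b + 1)
            med = float(np.median(values))
            candidates.sort(key=lambda v: (abs(v - med), v))
        modal.append(candidates[0])
    for lo, hi in zip(modal, modal[1:]):
        if hi <= lo:
            raise ValueError(
                "modal thresholds are not strictly increasing "
                f"(got {modal}); check panel data quality (boundaries sharing a gap "
                "collapse to equal thresholds)"
            )
    return ThresholdSet(labels=tuple(labels), thresholds=tuple(modal), provenance="modal",
                        n_panelists=len(placements), ties=tuple(tied))


def threshold_distribution(
    placements: Iterable[BookmarkPlacement],
    vset: VignetteSet | Sequence[float],
) -> pd.DataFrame:
    """Tidy per-boundary tally of individual thresholds: (boundary, threshold, count, panel)."""
    rows = []
    for p in placements:
        ts = individual_thresholds(p, vset)
        for b, value in enumerate(ts.thresholds, start=1):
            rows.append({"boundary": b, "threshold": value, "panel": p.panel})
    if not rows:
        raise ValueError("no placements supplied")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["panel", "boundary", "threshold"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out[["boundary", "threshold", "count", "panel"]]


# ---------------------------------------------------------------------------
# I/O


def load_placements(path: str | Path) -> list[BookmarkPlacement]:
    """Read a placements CSV: panelist_id, panel, gap_1..gap_K."""
    df = pd.read_csv(path, dtype={"panelist_id": str, "panel": str})
    gap_cols = sorted((c for c in df.columns if c.startswith("gap_")),
                      key=lambda c: int(c.split("_")[1]))
    if not gap_cols:
        raise ValueError(f"{path}: no gap_* columns found")
    return [
        BookmarkPlacement(
            panelist_id=str(row["panelist_id"]),
            panel=str(row["panel"]),
            gaps=tuple(int(row[c]) for c in gap_cols),
        )
        for _, row in df.iterrows()
    ]


def save_placements(placements: Sequence[BookmarkPlacement], path: str | Path) -> None:
    k = len(placements[0].gaps)
    rows = [
        {"panelist_id": p.panelist_id, "panel": p.panel,
         **{f"gap_{i + 1}": p.gaps[i] for i in range(k)}}
        for p in placements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_threshold_set(ts: ThresholdSet, path: str | Path) -> None:
    import json

    payload = {
        "labels": list(ts.labels),
        "thresholds": list(ts.thresholds),
        "provenance": ts.provenance,
        "n_panelists": ts.n_panelists,
        "ties": list(ts.ties),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_threshold_set(path: str | Path) -> ThresholdSet:
    import json

    d = json.loads(Path(path).read_text())
    return ThresholdSet(
        labels=tuple(d["labels"]),
        thresholds=tuple(d["thresholds"]),
        provenance=d.get("provenance", "modal"),
        n_panelists=int(d.get("n_panelists", 1)),
        ties=tuple(d.get("ties", ())),
    )
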