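"""Seed-deterministic generators for every input the pipeline consumes.

Generates item banks, respondent response matrices, clinic-like score
samples, panel bookmark placements, and GCPS-R records whose components
rise monotonically with the latent trait — so every stage of the pipeline
is testable end-to-end without external data.

All randomness is funneled through ``SimulationConfig.seed``; each
generator derives its own stream from ``(seed, stage_tag)`` so the same
config yields bit-identical artifacts regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .bookmarks import BookmarkPlacement, ThresholdSet
from .classify import Frequency, GCPSRResponse
from .irt import (
    DEFAULT_CATEGORY_LABELS,
    ItemBank,
    ItemParameters,
    ResponsePattern,
    category_probs,
    t_to_theta,
    theta_to_t,
)
from .vignettes import VignetteSet, round_half_up

__all__ = [
    "SimulationConfig",
    "SimulatedRespondents",
    "simulate_bank",
    "simulate_respondents",
    "simulate_panel",
    "simulate_gcpsr",
    "default_true_thresholds",
]

_SUBDOMAINS = ("chores", "social", "work", "cognition", "recreation", "sleep")

# Stage tags keep the per-generator streams independent of call order.
_STAGE_BANK, _STAGE_RESP, _STAGE_PANEL, _STAGE_GCPSR = 11, 13, 17, 19


@dataclass(frozen=True)
class SimulationConfig:
    """Hyperparameters for all generators; fixed seed => bit-identical output."""

    seed: int = 0
    # item bank
    n_items: int = 12
    a_log_mean: float = float(np.log(1.8))
    a_log_sd: float = 0.25
    b_first_low: float = -1.2
    b_first_high: float = 0.2
    b_gap_low: float = 0.4
    b_gap_high: float = 1.1
    # clinic-like respondent trait distribution, on the T metric
    t_mean: float = 62.5
    t_sd: float = 7.5
    n_respondents: int = 2000
    # bookmarking panel
    n_panelists: int = 10
    placement_noise_sd: float = 2.5  # T units, so noise interacts with vignette spacing
    panel_name: str = "PLwCP"
    # GCPS-R link: ordered-logit cuts on theta and a linear-in-theta PEG mean
    freq_slope: float = 1.5
    freq_pain_cuts: tuple[float, float, float] = (-0.5, 0.6, 1.4)
    freq_limit_cuts: tuple[float, float, float] = (0.0, 0.9, 1.7)
    peg_intercept: float = 2.0
    peg_slope: float = 2.2
    peg_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_respondents < 1 or self.n_panelists < 1:
            raise ValueError("all counts must be positive")
        if self.t_sd < 0 or self.placement_noise_sd < 0 or self.peg_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("freq_pain_cuts", "freq_limit_cuts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


class SimulatedRespondents(NamedTuple):
    theta: np.ndarray  # true latent traits (theta metric)
    t_true: np.ndarray  # same, on the T metric
    patterns: dict[str, ResponsePattern]


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def simulate_bank(cfg: SimulationConfig) -> ItemBank:
    """Generate a bank of 5-category GRM items with boundaries spanning ~[-1, 3].

    First boundaries are stratified over their range (shuffled grid plus
    jitter) so every part of the score continuum is covered by some item —
    banks built for trait measurement are targeted the same way.
    """
    rng = _rng(cfg, _STAGE_BANK)
    base = np.linspace(cfg.b_first_low, cfg.b_first_high, cfg.n_items)
    if cfg.n_items > 1:
        jitter = 0.25 * (cfg.b_first_high - cfg.b_first_low) / (cfg.n_items - 1)
    else:
        jitter = 0.0
    order = rng.permutation(cfg.n_items)
    items = []
    for i in range(cfg.n_items):
        a = float(np.exp(rng.normal(cfg.a_log_mean, cfg.a_log_sd)))
        b1 = base[order[i]] + rng.uniform(-jitter, jitter)
        gaps = rng.uniform(cfg.b_gap_low, cfg.b_gap_high, size=3)
        b = tuple(np.round(b1 + np.concatenate([[0.0], np.cumsum(gaps)]), 4))
        subdomain = _SUBDOMAINS[i % len(_SUBDOMAINS)]
        items.append(ItemParameters(
            item_id=f"PI{i + 1:03d}",
            text=f"How much did pain interfere with your {subdomain}?",
            subdomain=subdomain,
            a=round(a, 4),
            b=b,
            category_labels=DEFAULT_CATEGORY_LABELS,
        ))
    return ItemBank(items=tuple(items), name=f"synthetic-pi-seed{cfg.seed}")


def simulate_respondents(cfg: SimulationConfig, bank: ItemBank) -> SimulatedRespondents:
    """Draw true traits from the clinic distribution and GRM responses per item."""
    rng = _rng(cfg, _STAGE_RESP)
    theta = rng.normal(float(t_to_theta(cfg.t_mean)), cfg.t_sd / 10.0, size=cfg.n_respondents)
    patterns: dict[str, ResponsePattern] = {}
    # sample all items at once per respondent via inverse-CDF on category probs
    prob_by_item = {it.item_id: category_probs(theta, it) for it in bank}  # (n, 5)
    u = rng.uniform(size=(cfg.n_respondents, len(bank)))
    for r in range(cfg.n_respondents):
        resp = {}
        for j, it in enumerate(bank):
            cum = np.cumsum(prob_by_item[it.item_id][r])
            resp[it.item_id] = int(np.searchsorted(cum, u[r, j], side="right")) + 1
        patterns[f"r{r + 1:05d}"] = ResponsePattern(resp)
    return SimulatedRespondents(theta=theta, t_true=theta_to_t(theta), patterns=patterns)


def default_true_thresholds(vset: VignetteSet,
                            labels: Sequence[str] = ("none", "mild", "moderate", "high"),
                            ) -> ThresholdSet:
    """Generating cut scores for simulations: midpoints of evenly spread gaps."""
    scores = vset.calibrated_scores
    n_gaps = len(scores) - 1
    gaps = sorted({min(n_gaps, max(1, round(q * n_gaps))) for q in (0.25, 0.5, 0.75)})
    if len(gaps) != len(labels) - 1:
        raise ValueError("too few vignettes to place distinct generating thresholds")
    thr = tuple(round_half_up((scores[g - 1] + scores[g]) / 2.0) for g in gaps)
    return ThresholdSet(labels=tuple(labels), thresholds=thr, provenance="modal")


def simulate_panel(
    cfg: SimulationConfig,
    true_thresholds: ThresholdSet,
    vset: VignetteSet,
) -> list[BookmarkPlacement]:
    """Panelists perceive each cut with Gaussian noise (T units) and bookmark
    the gap whose midpoint is nearest; gaps are forced nondecreasing."""
    scores = vset.calibrated_scores
    lo, hi = scores[0], scores[-1]
    for t in true_thresholds.thresholds:
        if not lo <= t <= hi:
            raise ValueError(f"true threshold {t} outside vignette score range [{lo}, {hi}]")
    midpoints = (scores[:-1] + scores[1:]) / 2.0
    rng = _rng(cfg, _STAGE_PANEL)
    placements = []
    for p in range(cfg.n_panelists):
        gaps: list[int] = []
        for thr in true_thresholds.thresholds:
            perceived = thr + rng.normal(0.0, cfg.placement_noise_sd)
            g = int(np.argmin(np.abs(midpoints - perceived))) + 1
            if gaps:
                g = max(g, gaps[-1])
            gaps.append(g)
        placements.append(BookmarkPlacement(
            panelist_id=f"{cfg.panel_name.lower()}{p + 1:02d}",
            panel=cfg.panel_name,
            gaps=tuple(gaps),
        ))
    return placements


def simulate_gcpsr(cfg: SimulationConfig, thetas: Sequence[float]) -> list[GCPSRResponse]:
    """GCPS-R records monotonically linked to theta.

    Frequency items follow ordered-logit links (higher theta raises every
    cumulative probability); PEG items have a linear-in-theta mean with
    Gaussian noise, rounded and clipped to 0..10.
    """
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise ValueError("thetas must be finite")
    rng = _rng(cfg, _STAGE_GCPSR)

    def draw_freq(cuts: tuple[float, float, float]) -> np.ndarray:
        cum = 1.0 / (1.0 + np.exp(-cfg.freq_slope * (thetas[:, None] - np.asarray(cuts))))
        u = rng.uniform(size=(thetas.size, 1))
        return (u < cum).sum(axis=1)  # number of cuts passed = category 0..3

    f_pain = draw_freq(cfg.freq_pain_cuts)
    f_limit = draw_freq(cfg.freq_limit_cuts)
    peg_mean = cfg.peg_intercept + cfg.peg_slope * thetas
    peg = np.rint(peg_mean[:, None] + rng.normal(0.0, cfg.peg_noise_sd, size=(thetas.size, 3)))
    peg = np.clip(peg, 0, 10).astype(int)
    return [
        GCPSRResponse(
            freq_pain=Frequency(int(f_pain[i])),
            freq_limit=Frequency(int(f_limit[i])),
            peg_items=tuple(peg[i]),
        )
        for i in range(thetas.size)
    ]
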