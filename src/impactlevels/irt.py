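"""Graded response model (GRM) primitives and EAP pattern scoring.

Items are 5-category polytomous items with a single discrimination ``a``
and four strictly increasing boundary locations ``b`` on the latent (theta)
metric.  Boundary curves use the slope-location logistic form
``P*_k(theta) = 1 / (1 + exp(-a * (theta - b_k)))`` with no extra scaling
constant: any 1.7 is assumed to be absorbed into ``a``, so parameters
imported from other software must not be double-scaled.

Scores are reported on a T metric, ``t = 50 + 10 * theta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ItemBank",
    "ResponsePattern",
    "ScoredValue",
    "boundary_prob",
    "category_probs",
    "most_likely_response",
    "response_map",
    "eap_score",
    "score_range",
    "item_information",
    "theta_to_t",
    "t_to_theta",
    "load_bank",
    "save_bank",
    "load_responses",
    "save_responses",
]

N_CATEGORIES = 5
DEFAULT_CATEGORY_LABELS = (
    "not at all",
    "a little bit",
    "somewhat",
    "quite a bit",
    "very much",
)

#: EAP quadrature defaults: equally spaced nodes on theta in [-4, 4] with
#: rectangle weights times the prior density, renormalized.
EAP_NODES = 81
EAP_RANGE = (-4.0, 4.0)


def theta_to_t(theta, t_mean: float = 50.0, t_sd: float = 10.0):
    """Linear rescaling of the latent trait onto the T metric."""
    return t_mean + t_sd * np.asarray(theta, dtype=float)


def t_to_theta(t, t_mean: float = 50.0, t_sd: float = 10.0):
    """Inverse of :func:`theta_to_t`."""
    return (np.asarray(t, dtype=float) - t_mean) / t_sd


@dataclass(frozen=True)
class ItemParameters:
    """A single GRM item: discrimination and ordered boundary locations.

    Parameters
    ----------
    item_id : str
        Unique identifier within a bank.
    text : str
        Item prompt.
    subdomain : str
        Content tag used for balancing vignettes (e.g. ``"chores"``).
    a : float
        Discrimination, strictly positive.
    b : tuple of 4 floats
        Strictly increasing boundary locations on the theta metric.
    category_labels : tuple of 5 str
        Verbal descriptors, ordered least to most interference.
    """

    item_id: str
    text: str
    subdomain: str
    a: float
    b: tuple[float, float, float, float]
    category_labels: tuple[str, ...] = DEFAULT_CATEGORY_LABELS

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item {self.item_id!r}: discrimination must be > 0, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) != N_CATEGORIES - 1:
            raise ValueError(f"item {self.item_id!r}: expected 4 boundaries, got {len(b)}")
        if not all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: non-finite boundary location")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"item {self.item_id!r}: boundaries must be strictly increasing: {b}")
        object.__setattr__(self, "b", b)
        labels = tuple(self.category_labels)
        if len(labels) != N_CATEGORIES:
            raise ValueError(f"item {self.item_id!r}: exactly 5 category labels required")
        object.__setattr__(self, "category_labels", labels)

    @classmethod
    def from_slope_intercept(
        cls,
        item_id: str,
        a: float,
        c: Sequence[float],
        *,
        text: str = "",
        subdomain: str = "",
        category_labels: Sequence[str] = DEFAULT_CATEGORY_LABELS,
    ) -> "ItemParameters":
        """Build from slope-intercept form ``a*theta + c_k`` (b_k = -c_k / a)."""
        b = tuple(-float(ck) / float(a) for ck in c)
        return cls(item_id=item_id, text=text, subdomain=subdomain, a=float(a), b=b,
                   category_labels=tuple(category_labels))


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of :class:`ItemParameters` on a fixed T metric."""

    items: tuple[ItemParameters, ...]
    name: str = "bank"
    t_mean: float = 50.0
    t_sd: float = 10.0

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if not items:
            raise ValueError("item bank must contain at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in bank: {dupes}")
        if (float(self.t_mean), float(self.t_sd)) != (50.0, 10.0):
            raise ValueError("metric constants are fixed at t_mean=50, t_sd=10")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        try:
            return self._index[item_id]
        except AttributeError:
            object.__setattr__(self, "_index", {it.item_id: it for it in self.items})
            return self._index[item_id]

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def subdomains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.subdomain)
        return tuple(seen)


@dataclass(frozen=True)
class ResponsePattern:
    """Map item_id -> category in 1..5; unanswered items simply absent."""

    responses: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for item_id, cat in dict(self.responses).items():
            if cat is None or (isinstance(cat, float) and np.isnan(cat)):
                continue
            cat = int(cat)
            if not 1 <= cat <= N_CATEGORIES:
                raise ValueError(f"response to {item_id!r} outside 1..5: {cat}")
            clean[str(item_id)] = cat
        object.__setattr__(self, "responses", clean)

    def __len__(self) -> int:
        return len(self.responses)

    def items(self):
        return self.responses.items()

    def validate_against(self, bank: ItemBank) -> None:
        unknown = [i for i in self.responses if i not in bank]
        if unknown:
            raise KeyError(f"pattern references items not in bank {bank.name!r}: {unknown}")


@dataclass(frozen=True)
class ScoredValue:
    """EAP point estimate with its posterior SD, on both metrics."""

    theta_hat: float
    t_score: float
    se_theta: float

    def __post_init__(self) -> None:
        if self.se_theta <= 0:
            raise ValueError(f"posterior SD must be positive, got {self.se_theta}")

    @property
    def se_t(self) -> float:
        return 10.0 * self.se_theta


def boundary_prob(theta, item: ItemParameters, k: int):
    """Cumulative probability of responding in category > k at ``theta``.

    ``k`` is the 1-based boundary index (1..4).
    """
    if not 1 <= int(k) <= N_CATEGORIES - 1:
        raise IndexError(f"boundary index k must be in 1..4, got {k}")
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    z = item.a * (theta - item.b[int(k) - 1])
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def _cumulative_probs(theta, item: ItemParameters) -> np.ndarray:
    """P*_k for k = 0..5 with P*_0 = 1, P*_5 = 0; shape (..., 6)."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.b)
    z = item.a * (theta[..., None] - b)
    star = 1.0 / (1.0 + np.exp(-z))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    return np.concatenate([ones, star, zeros], axis=-1)


def category_probs(theta, item: ItemParameters) -> np.ndarray:
    """GRM category probabilities at ``theta``; shape (..., 5), sums to 1."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    star = _cumulative_probs(theta, item)
    p = star[..., :-1] - star[..., 1:]
    return np.clip(p, 0.0, 1.0)


def most_likely_response(theta: float, item: ItemParameters) -> int:
    """Modal category (1..5) at ``theta``; ties broken toward the lower category."""
    p = category_probs(float(theta), item)
    return int(np.argmax(p)) + 1  # argmax returns the first (lowest) maximizer


def response_map(item: ItemParameters, t_grid: Sequence[float]) -> np.ndarray:
    """Most likely response at every T in ``t_grid`` (ascending)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-d vector")
    if not np.all(np.isfinite(t_grid)):
        raise ValueError("t_grid must be finite")
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted ascending")
    theta = t_to_theta(t_grid)
    p = category_probs(theta, item)
    return np.argmax(p, axis=-1) + 1


def item_information(theta, item: ItemParameters):
    """Fisher information of a GRM item at ``theta``.

    I(theta) = a^2 * sum_k (Q_{k-1} - Q_k)^2 / P_k with Q_k = P*_k (1 - P*_k).
    """
    star = _cumulative_probs(np.asarray(theta, dtype=float), item)
    q = star * (1.0 - star)
    p = star[..., :-1] - star[..., 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, (q[..., :-1] - q[..., 1:]) ** 2 / np.where(p > 0, p, 1.0), 0.0)
    info = item.a**2 * terms.sum(axis=-1)
    return float(info) if np.ndim(info) == 0 else info


def _quadrature(n_nodes: int, theta_range: tuple[float, float],
                prior_mean: float, prior_sd: float) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.linspace(theta_range[0], theta_range[1], n_nodes)
    dens = np.exp(-0.5 * ((nodes - prior_mean) / prior_sd) ** 2)
    weights = dens / dens.sum()
    return nodes, weights


def _pattern_loglik(nodes: np.ndarray, pattern: ResponsePattern, bank: ItemBank) -> np.ndarray:
    logl = np.zeros_like(nodes)
    for item_id, cat in pattern.items():
        p = category_probs(nodes, bank[item_id])[:, cat - 1]
        logl += np.log(np.maximum(p, 1e-300))
    return logl


def eap_score(
    pattern: ResponsePattern | Mapping[str, int],
    bank: ItemBank,
    *,
    n_nodes: int = EAP_NODES,
    theta_range: tuple[float, float] = EAP_RANGE,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> ScoredValue:
    """EAP score of a response pattern under a normal prior on theta.

    Missing responses are dropped from the likelihood: only answered items
    contribute.  The posterior is evaluated on a fixed equally spaced grid
    with rectangle weights times the prior density, renormalized.
    """
    if not isinstance(pattern, ResponsePattern):
        pattern = ResponsePattern(pattern)
    if len(pattern) == 0:
        raise ValueError("cannot score an empty response pattern")
    pattern.validate_against(bank)
    nodes, weights = _quadrature(n_nodes, theta_range, prior_mean, prior_sd)
    logl = _pattern_loglik(nodes, pattern, bank)
    post = weights * np.exp(logl - logl.max())
    post /= post.sum()
    theta_hat = float(post @ nodes)
    var = float(post @ (nodes - theta_hat) ** 2)
    se = float(np.sqrt(max(var, 1e-12)))
    return ScoredValue(theta_hat=theta_hat, t_score=float(theta_to_t(theta_hat, bank.t_mean, bank.t_sd)),
                       se_theta=se)


def score_range(bank: ItemBank, item_subset: Iterable[str] | None = None) -> tuple[float, float]:
    """(min T, max T): EAP scores of the all-1s and all-5s patterns on the subset."""
    ids = tuple(item_subset) if item_subset is not None else bank.item_ids
    if not ids:
        raise ValueError("item subset must be non-empty")
    lo = eap_score(ResponsePattern({i: 1 for i in ids}), bank)
    hi = eap_score(ResponsePattern({i: N_CATEGORIES for i in ids}), bank)
    return lo.t_score, hi.t_score


# ---------------------------------------------------------------------------
# I/O: item bank JSON and response CSV


def _item_to_dict(item: ItemParameters) -> dict:
    return {
        "item_id": item.item_id,
        "text": item.text,
        "subdomain": item.subdomain,
        "a": item.a,
        "b": list(item.b),
        "category_labels": list(item.category_labels),
    }


def save_bank(bank: ItemBank, path: str | Path) -> None:
    payload = {
        "name": bank.name,
        "metric": {"t_mean": bank.t_mean, "t_sd": bank.t_sd},
        "items": [_item_to_dict(it) for it in bank.items],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_bank(path: str | Path) -> ItemBank:
    """Load an item bank JSON.

    Items may carry either ``"b"`` (slope-location boundaries) or ``"c"``
    (slope-intercept form ``a*theta + c_k``), which is converted on load.
    """
    payload = json.loads(Path(path).read_text())
    metric = payload.get("metric", {})
    items = []
    for raw in payload["items"]:
        labels = tuple(raw.get("category_labels", DEFAULT_CATEGORY_LABELS))
        if "b" in raw:
            items.append(ItemParameters(
                item_id=raw["item_id"], text=raw.get("text", ""),
                subdomain=raw.get("subdomain", ""), a=float(raw["a"]),
                b=tuple(float(x) for x in raw["b"]), category_labels=labels))
        elif "c" in raw:
            items.append(ItemParameters.from_slope_intercept(
                raw["item_id"], float(raw["a"]), raw["c"], text=raw.get("text", ""),
                subdomain=raw.get("subdomain", ""), category_labels=labels))
        else:
            raise ValueError(f"item {raw.get('item_id')!r} has neither 'b' nor 'c' parameters")
    return ItemBank(items=tuple(items), name=payload.get("name", "bank"),
                    t_mean=float(metric.get("t_mean", 50.0)), t_sd=float(metric.get("t_sd", 10.0)))


def load_responses(path: str | Path) -> dict[str, ResponsePattern]:
    """Read a response CSV (respondent_id then one column per item; blank = missing)."""
    df = pd.read_csv(path, dtype={0: str})
    rid_col = df.columns[0]
    out: dict[str, ResponsePattern] = {}
    for _, row in df.iterrows():
        resp = {c: int(row[c]) for c in df.columns[1:] if pd.notna(row[c])}
        out[str(row[rid_col])] = ResponsePattern(resp)
    return out


def save_responses(patterns: Mapping[str, ResponsePattern], bank: ItemBank, path: str | Path) -> None:
    rows = []
    for rid, pat in patterns.items():
        row: dict[str, object] = {"respondent_id": rid}
        for item_id in bank.item_ids:
            row[item_id] = pat.responses.get(item_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
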