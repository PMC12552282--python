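"""Gwet's AC2 chance-corrected agreement for multi-rater ordinal ratings.

AC2 = (Pa - Pe) / (1 - Pe), where Pa is the weighted observed agreement over
all rater pairs per item and Pe is Gwet's chance agreement built from overall
category propensities pi_k:

    Pe = T_w / (q (q - 1)) * sum_k pi_k (1 - pi_k),   T_w = sum_{k,l} w_kl.

With identity weights this reduces to Gwet's AC1.  Ordinal ("linear") weights
w_kl = 1 - |k - l| / (q - 1) are the default, quadratic weights are available.
The standard error follows Gwet's item-level linearization; the 95% interval
is the normal approximation truncated to [-1, 1].  Missing cells are handled
by pairwise deletion within an item (items rated by fewer than two raters
contribute to the propensities but not to Pa).

Fleiss-style benchmarks: < 0.40 poor, 0.40-0.75 good, > 0.75 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CtiqError, InputFormatError

__all__ = [
    "RatingsTable",
    "AgreementResult",
    "linear_weights",
    "quadratic_weights",
    "identity_weights",
    "gwet_ac2",
    "benchmark",
    "read_ratings_csv",
]


def linear_weights(q: int) -> np.ndarray:
    """Ordinal weights 1 - |i-j|/(q-1) on category ranks."""
    if q < 2:
        raise ValueError("need at least 2 categories")
    i = np.arange(q)
    return 1.0 - np.abs(i[:, None] - i[None, :]) / (q - 1)


def quadratic_weights(q: int) -> np.ndarray:
    if q < 2:
        raise ValueError("need at least 2 categories")
    i = np.arange(q)
    return 1.0 - ((i[:, None] - i[None, :]) / (q - 1)) ** 2


def identity_weights(q: int) -> np.ndarray:
    return np.eye(q)


_WEIGHT_FAMILIES = {
    "linear": linear_weights,
    "ordinal": linear_weights,
    "quadratic": quadratic_weights,
    "identity": identity_weights,
}


@dataclass
class RatingsTable:
    """Items x raters grid of ordinal scores; NaN marks a missing cell."""

    scores: np.ndarray
    categories: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise CtiqError("ratings must be an items x raters grid")
        n, r = self.scores.shape
        if n < 2 or r < 2:
            raise CtiqError("need at least 2 items and 2 raters")
        self.categories = np.unique(np.asarray(self.categories, dtype=float))
        if self.categories.size < 2:
            raise CtiqError("need at least 2 declared categories")
        observed = self.scores[np.isfinite(self.scores)]
        if observed.size == 0:
            raise CtiqError("ratings table is entirely missing")
        if not np.isin(observed, self.categories).all():
            bad = sorted(set(observed) - set(self.categories))
            raise CtiqError(f"scores outside declared categories: {bad}")

    @classmethod
    def from_scores(cls, scores, categories=None) -> "RatingsTable":
        scores = np.asarray(scores, dtype=float)
        if categories is None:
            categories = np.unique(scores[np.isfinite(scores)])
        return cls(scores, categories)

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    def category_counts(self) -> np.ndarray:
        """n_items x q matrix of raters per category (the r_ik of Gwet's notation)."""
        q = self.categories.size
        counts = np.zeros((self.n_items, q))
        for k, cat in enumerate(self.categories):
            counts[:, k] = (self.scores == cat).sum(axis=1)
        return counts


@dataclass
class AgreementResult:
    ac2: float
    se: float
    ci_low: float
    ci_high: float
    benchmark: str
    n_items: int
    n_raters: int
    weights: str
    note: str | None = None


def gwet_ac2(table: RatingsTable, weights: str | np.ndarray = "linear") -> AgreementResult:
    """Gwet's AC2 with standard error, 95% CI and Fleiss benchmark label.

    ``weights`` is a family name ('linear', 'quadratic', 'identity') or an
    explicit q x q matrix.
    """
    q = table.categories.size
    if isinstance(weights, str):
        try:
            W = _WEIGHT_FAMILIES[weights](q)
            wname = weights
        except KeyError:
            raise CtiqError(f"unknown weight family: {weights!r}") from None
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (q, q):
            raise CtiqError(f"weight matrix must be {q}x{q}")
        wname = "custom"

    counts = table.category_counts()
    ri = counts.sum(axis=1)
    rated = ri >= 1
    if not rated.all():
        counts = counts[rated]
        ri = ri[rated]
    n = counts.shape[0]
    if n < 2:
        raise CtiqError("need at least 2 items with ratings")
    multi = ri >= 2
    n2 = int(multi.sum())
    if n2 == 0:
        raise CtiqError("agreement requires at least one item rated by two raters")

    rstar = counts @ W
    num_i = (counts * (rstar - 1.0)).sum(axis=1)
    den_i = ri * (ri - 1.0)
    den_i = np.where(den_i == 0, 1.0, den_i)
    pa = float((num_i[multi] / den_i[multi]).sum() / n2)

    pi = (counts / ri[:, None]).mean(axis=0)
    tw = float(W.sum())
    pe = float(tw * (pi * (1.0 - pi)).sum() / (q * (q - 1)))

    note = None
    if pe == 0.0:
        # single category used throughout: perfect agreement by convention
        ac2 = 1.0 if pa == 1.0 else float(pa)
        note = "degenerate chance agreement (single category in use); variance is 0"
    else:
        ac2 = float((pa - pe) / (1.0 - pe))

    # Gwet's item-level linearized variance
    pa_i = (num_i / den_i) * (n / n2)
    pe_r2 = pe * multi.astype(float)
    denom = 1.0 - pe if pe != 1.0 else 1.0
    ac2_i = (n / n2) * (pa_i - pe_r2) / denom
    pe_i = (tw / (q * (q - 1))) * (counts @ (1.0 - pi)) / ri
    ac2_star = ac2_i - 2.0 * (1.0 - ac2) * (pe_i - pe) / denom
    var = float(((ac2_star - ac2) ** 2).sum() / (n * (n - 1)))
    se = float(np.sqrt(max(var, 0.0)))

    ci_low = float(np.clip(ac2 - 1.96 * se, -1.0, 1.0))
    ci_high = float(np.clip(ac2 + 1.96 * se, -1.0, 1.0))
    ci_low = min(ci_low, ac2)
    ci_high = max(ci_high, ac2)
    return AgreementResult(
        ac2=ac2,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        benchmark=benchmark(float(np.clip(ac2, -1.0, 1.0))),
        n_items=table.n_items,
        n_raters=table.n_raters,
        weights=wname,
        note=note,
    )


def benchmark(ac2: float) -> str:
    """Fleiss benchmark: poor < 0.40, good 0.40-0.75, excellent > 0.75."""
    if not -1.0 - 1e-12 <= ac2 <= 1.0 + 1e-12:
        raise CtiqError("agreement coefficient must lie in [-1, 1]")
    if ac2 < 0.40:
        return "poor"
    if ac2 <= 0.75:
        return "good"
    return "excellent"


def read_ratings_csv(path, categories=None) -> RatingsTable:
    """Read a ratings table from CSV.

    Long format (columns item_id, rater_id, score) is pivoted; anything else
    is treated as wide with the first column as item id and the remaining
    columns as raters.
    """
    df = pd.read_csv(path)
    long_cols = {"item_id", "rater_id", "score"}
    if long_cols.issubset(df.columns):
        wide = df.pivot_table(index="item_id", columns="rater_id", values="score",
                              aggfunc="first")
        scores = wide.to_numpy(dtype=float)
    elif df.shape[1] >= 3:
        scores = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        raise InputFormatError(
            "ratings CSV must be long (item_id, rater_id, score) or wide "
            "(item id + one column per rater)"
        )
    return RatingsTable.from_scores(scores, categories)
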