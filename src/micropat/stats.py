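"""Shared statistical primitives used by every pipeline stage.

Exact tests, FDR adjustment, the centered log-ratio transform, median-of-ratios
normalization, a Welch test on log-scale values, and resampling p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "bh_fdr",
    "clr_transform",
    "median_ratio_normalize",
    "welch_log_test",
    "empirical_pvalue",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts: rows = group, columns = outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x for x in cells):
            raise ValueError("contingency table entries must be integers")
        if any(x < 0 for x in cells):
            raise ValueError("contingency table entries must be non-negative")
        if all(x == 0 for x in cells):
            raise ValueError("contingency table must have at least one positive entry")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio a*d / (b*c); inf when b*c == 0 and a*d > 0."""
        num = self.a * self.d
        den = self.b * self.c
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den


def fisher_exact_two_sided(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass definition: the sum of hypergeometric
    probabilities, at fixed margins, of every table at most as probable as
    the observed one.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        table = ContingencyTable2x2(*(int(x) for x in arr.ravel()))
    return float(scipy.stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, clipped to 1.

    Order-preserving: q is monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def clr_transform(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of a composition (1-d) or of each row (2-d).

    The pseudocount is added to *every* entry, but only when the vector (row)
    contains zeros; zero-free input is transformed exactly.  Output rows sum
    to zero and are invariant to positive rescaling of the input.
    """
    x = np.asarray(counts, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    one_dim = x.ndim == 1
    if one_dim:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("composition must have length >= 2")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("all-zero composition cannot be clr-transformed")
    has_zero = (x == 0).any(axis=1)
    x = np.where(has_zero[:, None], x + pseudocount, x)
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return out[0] if one_dim else out


def median_ratio_normalize(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios normalization of a genes x samples count matrix.

    Size factors are the per-sample median ratio of each gene's count to that
    gene's geometric mean across samples; genes with a zero in any sample are
    excluded from the reference.  Factors are rescaled to geometric mean 1 so
    normalization is scale-neutral.  Returns ``(size_factors, normalized)``.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    usable = (m > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "add a pseudocount before normalizing"
        )
    ref = m[usable]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # center to geometric mean 1
    sf = np.exp(log_sf)
    return sf, m / sf[None, :]


def welch_log_test(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[Literal["up", "down", "none"], float]:
    """Welch two-sample t-test on log-normalized values.

    Returns ``(direction, p)`` where direction is the sign of
    ``mean(group_b) - mean(group_a)`` ("none" for an exact tie or a degenerate
    zero-variance tie).  Welch–Satterthwaite degrees of freedom; two-sided p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = b.mean() - a.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: identical-variance-free groups; t undefined or infinite
        if diff == 0:
            return "none", 1.0
        return ("up" if diff > 0 else "down"), 0.0
    t, p = scipy.stats.ttest_ind(b, a, equal_var=False)
    if diff == 0:
        return "none", float(p)
    return ("up" if diff > 0 else "down"), float(p)


def empirical_pvalue(observed: float, null_draws: np.ndarray) -> float:
    """Resampling p-value with the +1 correction: never 0, always in (0, 1].

    p = (1 + #{b : |null_b| >= |observed|}) / (B + 1).
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("null_draws must be non-empty")
    exceed = int(np.count_nonzero(np.abs(null) >= abs(observed)))
    return (1 + exceed) / (null.size + 1)
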