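"""Classical replicate diagnostics: variation fractions, correlation, slope.

A high Pearson correlation between two replicates can coexist with a large
systematic bias (slope far from 1) and with a large fraction of genes whose
values disagree by more than 50%.  These diagnostics expose that dissociation:
the correlation is invariant under scaling one replicate by a constant, the
regression slope and the variation fraction are not.  Log transformation
changes the slope again (y = 2x has slope 2 on the linear scale but slope 1
with intercept log 2 on the log scale), so log-scale slopes flatter the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReplicateQCResult",
    "IntervalNoiseSummary",
    "interreplicate_variation",
    "fraction_exceeding",
    "replicate_regression",
    "narrow_interval_summary",
]


@dataclass
class ReplicateQCResult:
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    n_genes_used: int
    fraction_exceeding: float
    log_base: int | None  # None => linear scale
    slope_deviation: float = field(init=False)
    variation_cutoff: float = 0.5
    n_excluded: int = 0
    slope_through_origin: float | None = None

    def __post_init__(self) -> None:
        self.slope_deviation = abs(self.slope - 1.0)


@dataclass
class IntervalNoiseSummary:
    interval: tuple[float, float]
    n_points: int
    max_fold_deviation: float | None
    quantile_fold_deviations: dict[float, float]


def _paired_positive(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must have the same length")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    return x[ok], y[ok], int((~ok).sum())


def interreplicate_variation(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Per-gene fold-ratio variation max(x, y)/min(x, y) - 1.

    Symmetric in the two replicates and invariant under a common positive
    rescaling of both.  Genes with a nonpositive or missing value in either
    replicate are excluded.  "Variation > 50%" means the larger replicate
    value exceeds 1.5x the smaller.
    """
    xs, ys, _ = _paired_positive(x, y)
    if xs.size == 0:
        raise ValueError("no genes with positive values in both replicates")
    return np.maximum(xs, ys) / np.minimum(xs, ys) - 1.0


def fraction_exceeding(
    variations: Sequence[float], cutoff: float = 0.5, inclusive: bool = False
) -> float:
    """Fraction of genes whose variation exceeds the cutoff.

    Strict ``>`` by default; ``inclusive=True`` counts genes exactly at the
    cutoff as well (">= 50%" reading).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    v = np.asarray(variations, dtype=float)
    if v.size == 0:
        raise ValueError("empty variation list")
    hits = (v >= cutoff) if inclusive else (v > cutoff)
    return float(hits.sum() / v.size)


def replicate_regression(
    x: Sequence[float],
    y: Sequence[float],
    log_base: int | None = None,
    variation_cutoff: float = 0.5,
    pseudocount: float = 0.0,
) -> ReplicateQCResult:
    """OLS regression of replicate y on replicate x, with Pearson r and p.

    With a log base, both replicates are transformed first; genes with a zero
    in either replicate are excluded (and counted) unless a pseudocount is
    given explicitly.  The Pearson p-value is two-tailed.  A slope through the
    origin is reported alongside the intercept fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must have the same length")
    if pseudocount:
        x = x + pseudocount
        y = y + pseudocount
    variations = interreplicate_variation(x, y)
    frac = fraction_exceeding(variations, cutoff=variation_cutoff)
    if log_base is not None:
        xs, ys, excluded = _paired_positive(x, y)
        xs = np.log(xs) / math.log(log_base)
        ys = np.log(ys) / math.log(log_base)
    else:
        ok = np.isfinite(x) & np.isfinite(y)
        xs, ys, excluded = x[ok], y[ok], int((~ok).sum())
    if xs.size < 3:
        raise ValueError(f"need at least 3 genes for regression, have {xs.size}")
    if np.ptp(xs) == 0:
        raise ValueError("zero variance in x: slope undefined")
    fit = stats.linregress(xs, ys)
    through_origin = float(np.dot(xs, ys) / np.dot(xs, xs)) if np.dot(xs, xs) else None
    return ReplicateQCResult(
        pearson_r=float(fit.rvalue),
        pearson_p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_genes_used=int(xs.size),
        fraction_exceeding=frac,
        log_base=log_base,
        variation_cutoff=variation_cutoff,
        n_excluded=excluded,
        slope_through_origin=through_origin,
    )


def narrow_interval_summary(
    x: Sequence[float],
    y: Sequence[float],
    interval: tuple[float, float],
    quantiles: Sequence[float] = (0.5, 0.9, 0.95),
) -> IntervalNoiseSummary:
    """Fold-level disagreement restricted to a narrow expression window.

    A gene belongs to the window when the mean of its two replicate values
    falls inside ``[low, high]``; the summary reports the maximum and selected
    quantiles of the per-gene fold deviation max/min, exposing noise the full
    dynamic range hides.
    """
    low, high = interval
    if not low < high:
        raise ValueError(f"interval low must be < high, got {interval}")
    xs, ys, _ = _paired_positive(x, y)
    mean = (xs + ys) / 2.0
    inside = (mean >= low) & (mean <= high)
    if not inside.any():
        return IntervalNoiseSummary(
            interval=(low, high), n_points=0, max_fold_deviation=None,
            quantile_fold_deviations={},
        )
    folds = np.maximum(xs[inside], ys[inside]) / np.minimum(xs[inside], ys[inside])
    qfd = {float(q): float(np.quantile(folds, q)) for q in quantiles}
    return IntervalNoiseSummary(
        interval=(low, high),
        n_points=int(inside.sum()),
        max_fold_deviation=float(folds.max()),
        quantile_fold_deviations=qfd,
    )
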