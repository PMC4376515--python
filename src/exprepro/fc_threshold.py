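"""Empirical inter-replicate fold-change thresholds for calling reliable changes.

Replicates of the same treatment should agree, so the distribution of
inter-replicate fold-changes (max/min, always >= 1) is an empirical null for
technical noise.  A significant inter-treatment fold-change is deemed reliable
only when changes of that size occur between replicates with frequency below a
chosen likelihood alpha (typically 5% or 1%).  The threshold is the smallest
observed inter-replicate fold-change t with P(FC >= t) < alpha; significant
genes whose fold-change is at or below the threshold are flagged as
sub-threshold (unreliable).  Thresholds can also be derived per gene group
(length or abundance bins) when noise is biased toward short or low-abundance
genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionDataset, GeneLengthTable

__all__ = [
    "FCThresholdResult",
    "interreplicate_fc_distribution",
    "fc_threshold",
    "apply_threshold",
    "grouped_thresholds",
]


@dataclass
class FCThresholdResult:
    alpha: float
    threshold: float
    n_genes: int
    source_pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    above_max: bool = False  # no observed value satisfied the condition
    group_key: str | None = None
    group_label: str | None = None
    low_n_warning: bool = False
    fold_changes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.fold_changes is not None and len(self.fold_changes) and not self.above_max:
            fc = np.asarray(self.fold_changes, dtype=float)
            frac = float((fc >= self.threshold).sum() / fc.size)
            assert frac < self.alpha, (
                f"threshold postcondition violated: P(FC >= {self.threshold}) = {frac}"
            )


def interreplicate_fc_distribution(
    dataset: ExpressionDataset,
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    return_genes: bool = False,
):
    """Pooled per-gene fold-changes max(x,y)/min(x,y) over replicate pairs.

    Every pair must name two replicates of the same treatment; genes with a
    nonpositive or missing value in either replicate are excluded per pair.
    """
    if not pairs:
        raise ValueError("no replicate pairs given")
    values: list[np.ndarray] = []
    genes: list[np.ndarray] = []
    for (ta, ra), (tb, rb) in pairs:
        if ta != tb:
            raise ValueError(
                f"pair ({ta},{ra})/({tb},{rb}) spans two treatments; "
                "inter-replicate pairs must be within one treatment"
            )
        x = dataset.column(ta, ra).to_numpy(dtype=float)
        y = dataset.column(tb, rb).to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        values.append(np.maximum(x[ok], y[ok]) / np.minimum(x[ok], y[ok]))
        genes.append(dataset.values.index.to_numpy()[ok])
    fc = np.concatenate(values)
    if fc.size == 0:
        raise ValueError("no genes with positive values in any requested pair")
    if return_genes:
        return fc, np.concatenate(genes)
    return fc


def fc_threshold(
    fold_changes: Sequence[float],
    alpha: float = 0.05,
    source_pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]] = (),
    group_key: str | None = None,
    group_label: str | None = None,
) -> FCThresholdResult:
    """Smallest observed fold-change whose occurrence likelihood is below alpha.

    Candidates are the observed values themselves (between them the empirical
    exceedance is flat).  If even the maximum observed value occurs with
    frequency >= alpha — only possible through ties at the maximum — the
    threshold is set just above the maximum and flagged ``above_max``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size == 0:
        raise ValueError("empty fold-change distribution")
    if np.any(fc < 1):
        raise ValueError("fold-changes must use the max/min convention (all >= 1)")
    if fc.size < 1 / alpha:
        warnings.warn(
            f"only {fc.size} fold-changes for alpha={alpha}; "
            "threshold estimate is unstable", stacklevel=2,
        )
    low_n = fc.size < 1 / alpha
    srt = np.sort(fc)
    n = srt.size
    # exceedance of candidate srt[i] is (n - first index of srt[i]) / n
    first_idx = np.searchsorted(srt, srt, side="left")
    exceedance = (n - first_idx) / n
    passing = np.nonzero(exceedance < alpha)[0]
    if passing.size:
        threshold = float(srt[passing[0]])
        above_max = False
    else:
        threshold = float(np.nextafter(srt[-1], np.inf))
        above_max = True
    return FCThresholdResult(
        alpha=alpha,
        threshold=threshold,
        n_genes=int(n),
        source_pairs=list(source_pairs),
        above_max=above_max,
        group_key=group_key,
        group_label=group_label,
        low_n_warning=low_n,
        fold_changes=fc,
    )


def apply_threshold(
    significant_table: pd.DataFrame,
    threshold: float,
    fc_column: str = "fc",
    significant_column: str = "significant",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Split externally-called significant genes at the reliability threshold.

    Among significant genes, fold-changes <= threshold ("same or lower") are
    sub-threshold and unreliable; strictly larger ones pass.  Returns the
    table with a ``passes_threshold`` column plus counts and fractions.
    """
    table = significant_table.copy()
    if len(table) and (table[fc_column] < 1).any():
        bad = table.loc[table[fc_column] < 1].index[0]
        raise ValueError(
            f"fold-change < 1 at {bad!r}: input must use the max/min convention"
        )
    if len(table):
        sig = table[table[significant_column].astype(bool)]
        passes = sig[fc_column] > threshold
        table["passes_threshold"] = False
        table.loc[sig.index[passes], "passes_threshold"] = True
        n_sig = int(len(sig))
        n_sub = int((~passes).sum())
    else:
        table["passes_threshold"] = pd.Series(dtype=bool)
        n_sig = n_sub = 0
    counts = {
        "n_significant": n_sig,
        "n_sub_threshold": n_sub,
        "n_passing": n_sig - n_sub,
        "fraction_sub_threshold": (n_sub / n_sig) if n_sig else math.nan,
    }
    return table, counts


def grouped_thresholds(
    dataset: ExpressionDataset,
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    alpha: float,
    group_key: str,
    bins: Sequence[float],
    lengths: GeneLengthTable | None = None,
    min_genes: int = 20,
) -> dict[str, FCThresholdResult | None]:
    """Gene-group-specific thresholds by length or abundance bins.

    ``bins`` are monotone edges [e0, e1, ..., ek]; gene g falls in bin j when
    e_j <= key(g) < e_{j+1} (the last bin is closed on the right).  The key is
    the ORF/exon length for ``length-bin`` and the mean expression over the
    samples of the requested pairs for ``abundance-bin``.  Bins with fewer
    than ``min_genes`` fold-changes are flagged; empty bins yield None.
    """
    if group_key not in {"length-bin", "abundance-bin"}:
        raise ValueError(f"group_key must be 'length-bin' or 'abundance-bin', got {group_key!r}")
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be at least two strictly increasing edges")
    fc, genes = interreplicate_fc_distribution(dataset, pairs, return_genes=True)
    if group_key == "length-bin":
        if lengths is None:
            raise ValueError("length-bin grouping requires a gene length table")
        keys = np.array([float(lengths[g]) if g in lengths else math.nan for g in genes])
    else:
        samples = sorted({dataset.sample_for(*p) for pair in pairs for p in pair})
        mean_expr = dataset.values[samples].mean(axis=1)
        keys = mean_expr.reindex(genes).to_numpy(dtype=float)
    idx = np.digitize(keys, edges, right=False) - 1
    idx[keys == edges[-1]] = edges.size - 2  # close the last bin on the right
    results: dict[str, FCThresholdResult | None] = {}
    for j in range(edges.size - 1):
        label = f"[{edges[j]:g}, {edges[j + 1]:g}{']' if j == edges.size - 2 else ')'}"
        in_bin = fc[idx == j]
        if in_bin.size == 0:
            results[label] = None
            continue
        if in_bin.size < min_genes:
            warnings.warn(
                f"bin {label} has only {in_bin.size} genes; threshold is unstable",
                stacklevel=2,
            )
        res = fc_threshold(
            in_bin, alpha=alpha, source_pairs=pairs,
            group_key=group_key, group_label=label,
        )
        res.low_n_warning = res.low_n_warning or in_bin.size < min_genes
        results[label] = res
    return results
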