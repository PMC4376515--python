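"""Expression-data corrections: RPKM, total-count, reference-gene, quantile.

These are the standard corrections applied before re-assessing replicate
agreement.  Per-sample scale factors (total-count, reference-gene) remove
systematic inter-replicate bias — they move the regression slope toward 1 and
shrink the fraction of genes with large inter-replicate variation — while
leaving the Pearson correlation untouched, since the correlation is invariant
under scaling a replicate by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionDataset, GeneLengthTable

__all__ = [
    "NormalizationRecord",
    "rpkm",
    "total_count_scaling",
    "reference_gene_scaling",
    "quantile_normalize",
]


@dataclass
class NormalizationRecord:
    method: str
    parameters: dict = field(default_factory=dict)
    scale_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.scale_factors is not None:
            bad = {s: f for s, f in self.scale_factors.items() if not f > 0}
            if bad:
                raise ValueError(f"scale factors must be positive: {bad}")


def rpkm(
    counts: ExpressionDataset,
    lengths: GeneLengthTable,
    totals: Mapping[str, float] | None = None,
) -> ExpressionDataset:
    """Reads per kilobase of exon model per million mapped reads.

    value = count * 1e9 / (total_mapped_reads * length_bp).  Totals default to
    the column sums; user-supplied totals (e.g. all mapped reads including
    intergenic) override them.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise KeyError(f"genes without a length entry: {missing[:5]}")
    if totals is None:
        totals = counts.values.sum(axis=0, skipna=True).to_dict()
    for sample in counts.values.columns:
        if not totals.get(sample, 0) > 0:
            raise ValueError(f"zero total reads in sample {sample!r}")
    length_bp = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    out = counts.values.copy()
    for sample in out.columns:
        out[sample] = out[sample].to_numpy() * 1e9 / (totals[sample] * length_bp)
    record = NormalizationRecord(method="rpkm", parameters={"totals": dict(totals)})
    return counts.with_values(out, normalization=record)


def total_count_scaling(
    dataset: ExpressionDataset,
    target: float | str = "mean-library",
) -> ExpressionDataset:
    """Scale every sample so its column sum hits a common target library size.

    ``target`` is either an explicit value or ``"mean-library"`` (the mean of
    the observed column sums).
    """
    sums = dataset.values.sum(axis=0, skipna=True)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"zero column sum in sample {bad!r}")
    target_value = float(sums.mean()) if target == "mean-library" else float(target)
    if target_value <= 0:
        raise ValueError(f"target library size must be positive, got {target_value}")
    factors = (target_value / sums).to_dict()
    out = dataset.values * pd.Series(factors)
    record = NormalizationRecord(
        method="total-count",
        parameters={"target": target_value},
        scale_factors={s: float(f) for s, f in factors.items()},
    )
    return dataset.with_values(out, normalization=record)


def reference_gene_scaling(
    dataset: ExpressionDataset,
    reference_genes: Sequence[str],
) -> ExpressionDataset:
    """Correct inter-replicate bias using reference (housekeeping) genes.

    Within each treatment the first replicate (sorted label order) is the
    anchor; every other replicate k is multiplied by the mean over reference
    genes of (value in anchor / value in replicate k).  After correction a
    single reference gene agrees exactly across the treatment's replicates.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    missing = [g for g in reference_genes if g not in dataset.values.index]
    if missing:
        raise KeyError(f"reference gene absent from dataset: {missing[0]!r}")
    out = dataset.values.copy()
    factors: dict[str, float] = {}
    for treatment in dataset.treatments:
        reps = dataset.replicates(treatment)
        anchor_sample = dataset.sample_for(treatment, reps[0])
        anchor = out.loc[reference_genes, anchor_sample]
        for rep in reps:
            sample = dataset.sample_for(treatment, rep)
            current = out.loc[reference_genes, sample]
            for g in reference_genes:
                if not current[g] > 0 or not anchor[g] > 0:
                    raise ValueError(
                        f"reference gene {g!r} is zero or missing in a sample of "
                        f"treatment {treatment!r}"
                    )
            if rep == reps[0]:
                factors[sample] = 1.0
                continue
            factor = float((anchor / current).mean())
            out[sample] = out[sample] * factor
            factors[sample] = factor
    record = NormalizationRecord(
        method="reference-gene",
        parameters={"reference_genes": reference_genes, "anchor": "first replicate (sorted)"},
        scale_factors=factors,
    )
    return dataset.with_values(out, normalization=record)


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Classical quantile normalization (rank-average tie handling).

    Each sample's values are replaced by the across-sample mean of the order
    statistics at their rank; tied values receive the mean of the order-stat
    means over the tied positions.  Afterwards every column holds the same
    multiset of values; the operation is idempotent.
    """
    if dataset.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = dataset.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile normalization requires a complete matrix (no missing cells)")
    sorted_mean = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(arr.shape[0])
        col[order] = sorted_mean
        # average over ties so equal inputs map to equal outputs
        s = pd.Series(col)
        out[:, j] = s.groupby(pd.Series(arr[:, j])).transform("mean").to_numpy()
    frame = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    record = NormalizationRecord(method="quantile", parameters={"ties": "rank-average"})
    return dataset.with_values(frame, normalization=record)
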