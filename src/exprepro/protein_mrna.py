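"""ORF-length correction of protein quantities before protein–mRNA correlation.

Even without any post-transcriptional regulation, two genes induced equally at
the transcript level need not show equal protein induction: a coding sequence
twice as long takes twice as long to translate, halving the apparent protein
response.  The correction factor CF_i = L_i / min_j L_j (ORF length over the
shortest ORF in the table, so min CF = 1 exactly) multiplies the observed
protein value PF to give the corrected value CPF = PF * CF.  Correlating
transcript quantities against CPF instead of PF removes this purely
length-driven decoupling; the residual shift in the correlation is then a
cleaner readout of post-transcriptional regulation.  The correction always
multiplies the protein side and never divides the transcript side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import GeneLengthTable

__all__ = [
    "CorrelationShift",
    "correction_factors",
    "correct_protein",
    "correlation_shift",
    "rank_correlations",
]


@dataclass
class CorrelationShift:
    """Pearson/Spearman correlations before and after ORF-length correction.

    An undefined coefficient (constant input vector) is reported as NaN,
    never as 0.
    """

    r_before: float
    r_after: float
    rho_before: float
    rho_after: float
    n_genes: int
    per_gene: pd.DataFrame | None = None


def _as_length_map(lengths: GeneLengthTable | Mapping[str, int]) -> Mapping[str, int]:
    return lengths.lengths if isinstance(lengths, GeneLengthTable) else lengths


def correction_factors(lengths: GeneLengthTable | Mapping[str, int] | Sequence[float]) -> pd.Series:
    """CF_i = ORF length of gene i divided by the shortest ORF in the table."""
    if isinstance(lengths, (GeneLengthTable, Mapping)):
        mapping = _as_length_map(lengths)
        ser = pd.Series(mapping, dtype=float)
    else:
        ser = pd.Series(np.asarray(lengths, dtype=float))
    if ser.empty:
        raise ValueError("empty length table")
    if (ser < 1).any():
        raise ValueError("ORF lengths must be >= 1 bp")
    return ser / ser.min()


def correct_protein(
    table: pd.DataFrame,
    lengths: GeneLengthTable | Mapping[str, int] | None = None,
    transcript_column: str = "TF",
    protein_column: str = "PF",
    length_column: str = "ORF",
) -> pd.DataFrame:
    """Append CF and CPF = PF * CF columns to a protein/transcript table.

    Lengths come from the table's length column or from a separate table; a
    gene without a length is a hard error naming the gene.
    """
    out = table.copy()
    if lengths is not None:
        mapping = _as_length_map(lengths)
        missing = [g for g in out.index if g not in mapping]
        if missing:
            raise KeyError(f"no ORF length for gene {missing[0]!r}")
        out[length_column] = [mapping[g] for g in out.index]
    if length_column not in out.columns:
        raise KeyError(f"table has no {length_column!r} column and no lengths were given")
    if out[length_column].isna().any():
        gene = out.index[out[length_column].isna()][0]
        raise KeyError(f"no ORF length for gene {gene!r}")
    cf = correction_factors(dict(zip(out.index, out[length_column])))
    out["CF"] = cf.reindex(out.index).to_numpy()
    out["CPF"] = out[protein_column] * out["CF"]
    return out


def rank_correlations(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Pearson r and Spearman rho with two-tailed p-values.

    Spearman uses average ranks on ties.  Constant inputs give NaN
    coefficients (undefined), not 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": np.nan, "pearson_p": np.nan,
                "spearman_rho": np.nan, "spearman_p": np.nan}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
    }


def correlation_shift(
    transcript: pd.Series | Sequence[float],
    protein: pd.Series | Sequence[float],
    lengths: GeneLengthTable | Mapping[str, int] | Sequence[float],
) -> CorrelationShift:
    """Correlations of transcript vs protein, uncorrected and length-corrected.

    Inputs are matched per gene (by index when Series are given).  Pearson and
    Spearman are computed on (transcript, protein) and on
    (transcript, protein * CF).
    """
    if isinstance(transcript, pd.Series) and isinstance(protein, pd.Series):
        genes = transcript.index
        if not genes.equals(protein.index):
            protein = protein.reindex(genes)
            if protein.isna().any():
                raise KeyError("transcript and protein tables do not share the same genes")
        t = transcript.to_numpy(dtype=float)
        p = protein.to_numpy(dtype=float)
        if isinstance(lengths, (GeneLengthTable, Mapping)):
            mapping = _as_length_map(lengths)
            missing = [g for g in genes if g not in mapping]
            if missing:
                raise KeyError(f"no ORF length for gene {missing[0]!r}")
            cf = correction_factors({g: mapping[g] for g in genes}).reindex(genes).to_numpy()
        else:
            cf = correction_factors(lengths).to_numpy()
    else:
        t = np.asarray(transcript, dtype=float)
        p = np.asarray(protein, dtype=float)
        genes = pd.RangeIndex(t.size)
        cf = correction_factors(lengths).to_numpy()
    if t.size < 3:
        raise ValueError(f"need at least 3 genes, have {t.size}")
    if not (t.size == p.size == cf.size):
        raise ValueError("transcript, protein and length inputs must match in size")
    corrected = p * cf
    before = rank_correlations(t, p)
    after = rank_correlations(t, corrected)
    per_gene = pd.DataFrame(
        {"transcript": t, "protein": p, "CF": cf, "corrected_protein": corrected},
        index=genes,
    )
    return CorrelationShift(
        r_before=before["pearson_r"],
        r_after=after["pearson_r"],
        rho_before=before["spearman_rho"],
        rho_after=after["spearman_rho"],
        n_genes=int(t.size),
        per_gene=per_gene,
    )
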