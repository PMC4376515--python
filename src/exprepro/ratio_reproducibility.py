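"""Reproducibility coefficients from ratios of inter-treatment ratio statistics.

For every ordered pair of treatments (a, b) and every replicate combination
(r of a, s of b) a *ratio population* holds the gene-wise expression ratios
x_{i,a,r} / x_{i,b,s}.  Its mean M and standard deviation S are the population
statistics.  Replicate substitution then compares populations that share the
same source replicate r and differ only in the target replicate: for every
unordered pair {s, s'} of b's replicates the statistic ratios M(r,s)/M(r,s')
and S(r,s)/S(r,s') are formed.  Each ratio v is folded into a deviation from 1,

    d = v - 1        if v >= 1
    d = 1/v - 1      otherwise,

so that v and 1/v deviate equally.  The mean of all deviations and their
standard deviation are the two reproducibility coefficients: both are 0 under
perfect replicate agreement and grow with inter-replicate noise.  Both
directions X/Y and Y/X are kept as separate populations, which symmetrizes the
asymmetry of raw ratios around 1 without a log transform.

The same idea applies within a treatment: the mean of the gene-wise ratio
population between two replicates of one treatment is expected to be 1 (and
its SD 0) under perfect reproducibility; its folded deviation from 1 averaged
over ordered replicate pairs is the between-replicates coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionDataset

__all__ = [
    "RatioPopulation",
    "ReproducibilityResult",
    "build_ratio_populations",
    "statistic_ratio_deviations",
    "reproducibility_coefficients",
    "within_treatment_deviation",
    "fold_deviation",
]


def fold_deviation(v: float) -> float:
    """Deviation of a positive ratio from 1, symmetric under inversion."""
    if v <= 0 or not math.isfinite(v):
        raise ValueError(f"ratio must be positive and finite, got {v}")
    return v - 1.0 if v >= 1.0 else 1.0 / v - 1.0


@dataclass
class RatioPopulation:
    """Gene-wise expression ratios for one ordered sample pair."""

    source: tuple[str, str]  # (treatment a, replicate r) — numerator
    target: tuple[str, str]  # (treatment b, replicate s) — denominator
    ratios: np.ndarray
    n_excluded: int = 0

    @property
    def M(self) -> float:
        return float(np.mean(self.ratios))

    def S(self, ddof: int = 1) -> float:
        if len(self.ratios) <= ddof:
            return 0.0
        return float(np.std(self.ratios, ddof=ddof))

    @property
    def n_genes(self) -> int:
        return len(self.ratios)


@dataclass
class ReproducibilityResult:
    """Deviations of statistic ratios and the two reproducibility coefficients."""

    mode: str  # "between-treatments" | "between-replicates"
    mean_deviations: list[float]
    sd_deviations: list[float]
    avg_deviation: float
    sd_of_deviations: float
    n_populations: int
    n_comparisons: int
    skipped: int
    pooling: str = "pooled"
    sd_convention: str = "sample"
    avg_mean_deviation: float | None = None
    avg_sd_deviation: float | None = None
    comparisons: pd.DataFrame | None = None

    @property
    def avg_deviation_percent(self) -> float:
        return 100.0 * self.avg_deviation

    @property
    def sd_of_deviations_percent(self) -> float:
        return 100.0 * self.sd_of_deviations


def _pair_ratios(
    dataset: ExpressionDataset,
    src: tuple[str, str],
    tgt: tuple[str, str],
    genes: Sequence[str] | None = None,
) -> RatioPopulation:
    x = dataset.column(*src).to_numpy(dtype=float)
    y = dataset.column(*tgt).to_numpy(dtype=float)
    if genes is not None:
        idx = dataset.values.index.get_indexer(list(genes))
        x, y = x[idx], y[idx]
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    return RatioPopulation(
        source=src, target=tgt, ratios=x[ok] / y[ok], n_excluded=int((~ok).sum())
    )


def _listwise_genes(dataset: ExpressionDataset) -> list[str]:
    arr = dataset.values.to_numpy(dtype=float)
    ok = np.all(np.isfinite(arr) & (arr > 0), axis=1)
    return [g for g, keep in zip(dataset.values.index, ok) if keep]


def build_ratio_populations(
    dataset: ExpressionDataset,
    gene_filter: str = "pairwise",
) -> list[RatioPopulation]:
    """One ratio population per ordered treatment pair per replicate combination.

    For n treatments with r_a replicates each, this yields
    sum over ordered pairs (a,b) of r_a * r_b populations — 48 for the
    four-treatment, two-replicate design.  Genes with a zero or missing value
    in either sample are excluded per population (``pairwise``, default) or
    from every population (``listwise``).
    """
    if gene_filter not in {"pairwise", "listwise"}:
        raise ValueError(f"gene_filter must be 'pairwise' or 'listwise', got {gene_filter!r}")
    treatments = dataset.treatments
    if len(treatments) < 2:
        raise ValueError("between-treatment analysis needs at least 2 treatments")
    for t in treatments:
        if len(dataset.replicates(t)) < 2:
            warnings.warn(
                f"treatment {t!r} has fewer than 2 replicates; its pairs are still built",
                stacklevel=2,
            )
    genes = _listwise_genes(dataset) if gene_filter == "listwise" else None
    populations: list[RatioPopulation] = []
    for a, b in permutations(treatments, 2):
        for r in dataset.replicates(a):
            for s in dataset.replicates(b):
                populations.append(_pair_ratios(dataset, (a, r), (b, s), genes))
    return populations


def statistic_ratio_deviations(
    populations: Iterable[RatioPopulation],
    sd_convention: str = "sample",
) -> tuple[list[float], list[float], int, pd.DataFrame]:
    """Deviations of mean- and SD-statistic ratios under replicate substitution.

    Populations sharing the same source sample (a, r) and target treatment b
    are compared across every unordered pair {s, s'} of target replicates:
    M(r,s)/M(r,s') and S(r,s)/S(r,s').  Returns the two deviation lists, the
    number of skipped SD comparisons (either SD zero), and a tidy comparison
    table.
    """
    ddof = {"sample": 1, "population": 0}[sd_convention]
    by_key: dict[tuple[tuple[str, str], str], dict[str, RatioPopulation]] = {}
    for pop in populations:
        by_key.setdefault((pop.source, pop.target[0]), {})[pop.target[1]] = pop
    mean_devs: list[float] = []
    sd_devs: list[float] = []
    skipped = 0
    records: list[dict] = []
    for (source, target_treatment), by_rep in sorted(by_key.items()):
        for s, s2 in combinations(sorted(by_rep), 2):
            p, q = by_rep[s], by_rep[s2]
            m_ratio = p.M / q.M
            d = fold_deviation(m_ratio)
            mean_devs.append(d)
            records.append({
                "statistic": "mean", "source": "/".join(source),
                "target_treatment": target_treatment, "target_rep_a": s,
                "target_rep_b": s2, "ratio": m_ratio, "deviation": d,
            })
            sp, sq = p.S(ddof), q.S(ddof)
            if sp == 0.0 and sq == 0.0:
                skipped += 1
                records.append({
                    "statistic": "sd", "source": "/".join(source),
                    "target_treatment": target_treatment, "target_rep_a": s,
                    "target_rep_b": s2, "ratio": math.nan, "deviation": math.nan,
                })
                continue
            if sp == 0.0 or sq == 0.0:
                skipped += 1
                warnings.warn(
                    f"SD ratio undefined (one SD is zero) for source {source}, "
                    f"target {target_treatment} replicates {s}/{s2}; skipped",
                    stacklevel=2,
                )
                records.append({
                    "statistic": "sd", "source": "/".join(source),
                    "target_treatment": target_treatment, "target_rep_a": s,
                    "target_rep_b": s2, "ratio": math.nan, "deviation": math.nan,
                })
                continue
            s_ratio = sp / sq
            ds = fold_deviation(s_ratio)
            sd_devs.append(ds)
            records.append({
                "statistic": "sd", "source": "/".join(source),
                "target_treatment": target_treatment, "target_rep_a": s,
                "target_rep_b": s2, "ratio": s_ratio, "deviation": ds,
            })
    table = pd.DataFrame.from_records(records) if records else pd.DataFrame()
    return mean_devs, sd_devs, skipped, table


def _sd(values: Sequence[float], convention: str) -> float:
    ddof = {"sample": 1, "population": 0}[convention]
    if len(values) <= ddof:
        return 0.0
    return float(np.std(values, ddof=ddof))


def reproducibility_coefficients(
    dataset_or_populations: ExpressionDataset | Sequence[RatioPopulation],
    pooling: str = "pooled",
    sd_convention: str = "sample",
    gene_filter: str = "pairwise",
) -> ReproducibilityResult:
    """The between-treatments reproducibility coefficients.

    ``avg_deviation`` is the arithmetic mean of the deviation list —
    mean-statistic and SD-statistic deviations pooled by default, or the
    per-statistic averages are also reported with ``pooling='per-statistic'``
    (then ``avg_deviation`` is the mean-statistic average, matching the
    expectation-of-ratios reading).  ``sd_of_deviations`` is the sample
    (default) or population standard deviation of the same list.
    """
    if pooling not in {"pooled", "per-statistic"}:
        raise ValueError(f"pooling must be 'pooled' or 'per-statistic', got {pooling!r}")
    if sd_convention not in {"sample", "population"}:
        raise ValueError(f"sd convention must be 'sample' or 'population', got {sd_convention!r}")
    if isinstance(dataset_or_populations, ExpressionDataset):
        populations = build_ratio_populations(dataset_or_populations, gene_filter=gene_filter)
    else:
        populations = list(dataset_or_populations)
    mean_devs, sd_devs, skipped, table = statistic_ratio_deviations(
        populations, sd_convention=sd_convention
    )
    pooled = mean_devs + sd_devs
    if not pooled:
        raise ValueError("all statistic-ratio comparisons were skipped; no deviations available")
    chosen = pooled if pooling == "pooled" else mean_devs
    if not chosen:
        raise ValueError("no mean-statistic deviations available")
    return ReproducibilityResult(
        mode="between-treatments",
        mean_deviations=mean_devs,
        sd_deviations=sd_devs,
        avg_deviation=float(np.mean(chosen)),
        sd_of_deviations=_sd(chosen, sd_convention),
        n_populations=len(populations),
        n_comparisons=len(mean_devs) + len(sd_devs) + skipped,
        skipped=skipped,
        pooling=pooling,
        sd_convention=sd_convention,
        avg_mean_deviation=float(np.mean(mean_devs)) if mean_devs else None,
        avg_sd_deviation=float(np.mean(sd_devs)) if sd_devs else None,
        comparisons=table,
    )


def within_treatment_deviation(
    dataset: ExpressionDataset,
    treatment: str,
    sd_convention: str = "sample",
) -> ReproducibilityResult:
    """Between-replicates variant: deviations of inter-replicate ratio means.

    For every ordered replicate pair (k, l) of the treatment, the gene-wise
    ratio population x_{i,k}/x_{i,l} is formed; the folded deviation of its
    mean from 1 enters the coefficient.  The population SDs (expected 0 under
    perfect reproducibility) are reported alongside as ``sd_deviations``.
    """
    reps = dataset.replicates(treatment)
    if len(reps) < 2:
        raise ValueError(f"treatment {treatment!r} needs at least 2 replicates")
    mean_devs: list[float] = []
    pop_sds: list[float] = []
    records: list[dict] = []
    populations = 0
    for k, l in permutations(reps, 2):
        pop = _pair_ratios(dataset, (treatment, k), (treatment, l))
        populations += 1
        d = fold_deviation(pop.M)
        s = pop.S({"sample": 1, "population": 0}[sd_convention])
        mean_devs.append(d)
        pop_sds.append(s)
        records.append({
            "statistic": "mean", "source": f"{treatment}/{k}",
            "target_treatment": treatment, "target_rep_a": l, "target_rep_b": l,
            "ratio": pop.M, "deviation": d,
        })
    return ReproducibilityResult(
        mode="between-replicates",
        mean_deviations=mean_devs,
        sd_deviations=pop_sds,
        avg_deviation=float(np.mean(mean_devs)),
        sd_of_deviations=_sd(mean_devs, sd_convention),
        n_populations=populations,
        n_comparisons=len(mean_devs),
        skipped=0,
        sd_convention=sd_convention,
        comparisons=pd.DataFrame.from_records(records),
    )
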