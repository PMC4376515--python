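"""Synthetic expression data with controlled inter-replicate noise.

The generator emulates the structure the reproducibility diagnostics assume:
each gene has a log-normal baseline abundance, each treatment multiplies it by
a fold-change effect, and each replicate observes the product under
multiplicative log-normal noise,

    x_{i,t,k} = baseline_i * effect_{t,i} * exp(sigma_rep * z_{i,t,k}),
    z iid standard normal.

Multiplicative noise is symmetric on the log scale, so ratio-based statistics
behave naturally and the inter-replicate "noise level" is directly tunable:
for a replicate pair, ln(max/min) = |z - z'| * sigma_rep with z - z' ~
N(0, 2 sigma_rep^2), hence

    P(max/min >= f) = 2 * Phi(-ln f / (sigma_rep * sqrt(2))).

``sigma_for_exceedance`` inverts this, e.g. the default noise level is chosen
so that about 65% of genes show more than 50% inter-replicate variation — the
level observed in uncorrected bulk RNA-Seq read counts.  With sigma_rep = 0
replicates within a treatment are exactly identical and every downstream
reproducibility deviation is exactly 0.

The paired transcript/protein generator implements the translation-time
mechanism: the observed protein fold-change is the transcript fold-change
divided by the ORF-length correction factor CF (longer ORFs translate more
slowly), times multiplicative noise.  With zero noise the downstream CPF
correction restores protein fold = transcript fold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionDataset, GeneLengthTable
from .protein_mrna import correction_factors

__all__ = [
    "SynthConfig",
    "sigma_for_exceedance",
    "exceedance_fraction",
    "generate_dataset",
    "generate_protein_transcript_pair",
]

#: default inter-replicate log-noise: ~65% of gene pairs differ by more than 1.5x
DEFAULT_EXCEEDANCE = 0.65


def exceedance_fraction(sigma_rep: float, fold: float = 1.5) -> float:
    """P(max/min >= fold) for a log-normal replicate pair with log-sd sigma_rep."""
    if sigma_rep < 0:
        raise ValueError("sigma_rep must be nonnegative")
    if sigma_rep == 0:
        return 0.0
    return float(2.0 * stats.norm.cdf(-math.log(fold) / (sigma_rep * math.sqrt(2.0))))


def sigma_for_exceedance(fraction: float = DEFAULT_EXCEEDANCE, fold: float = 1.5) -> float:
    """Log-noise sigma_rep such that P(max/min >= fold) equals ``fraction``."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    return float(math.log(fold) / (math.sqrt(2.0) * stats.norm.ppf(1.0 - fraction / 2.0)))


@dataclass
class SynthConfig:
    """Parameters of the synthetic expression generator.

    ``treatment_effects`` maps a treatment label (``T1`` .. ``Tn``) to a
    scalar fold-change or a per-gene fold-change vector; unlisted treatments
    have effect 1.  ``sigma_rep`` is the log-scale replicate noise SD; its
    default makes ~65% of replicate pairs differ by more than 1.5-fold.
    """

    n_genes: int = 10_000
    n_treatments: int = 4
    n_replicates: int = 2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    treatment_effects: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    sigma_rep: float = field(default_factory=sigma_for_exceedance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_treatments < 2:
            raise ValueError("need at least 2 treatments")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per treatment")
        if self.sigma_rep < 0:
            raise ValueError("sigma_rep must be nonnegative")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be nonnegative")
        labels = {f"T{t + 1}" for t in range(self.n_treatments)}
        unknown = set(self.treatment_effects) - labels
        if unknown:
            raise ValueError(f"treatment_effects for unknown treatments: {sorted(unknown)}")
        for t, eff in self.treatment_effects.items():
            arr = np.atleast_1d(np.asarray(eff, dtype=float))
            if arr.size not in (1, self.n_genes):
                raise ValueError(
                    f"effect vector for {t} has length {arr.size}, expected 1 or {self.n_genes}"
                )
            if np.any(arr <= 0):
                raise ValueError(f"treatment effects must be positive ({t})")


def generate_dataset(config: SynthConfig) -> ExpressionDataset:
    """Draw a synthetic gene × sample matrix under the multiplicative model.

    Deterministic for a fixed config (including the seed): the same config
    yields a bit-identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    g, n, r = config.n_genes, config.n_treatments, config.n_replicates
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=g))
    columns: dict[str, np.ndarray] = {}
    layout: dict[str, tuple[str, str]] = {}
    for t in range(n):
        label = f"T{t + 1}"
        eff = np.broadcast_to(
            np.atleast_1d(np.asarray(config.treatment_effects.get(label, 1.0), dtype=float)), (g,)
        )
        expected = baseline * eff
        for k in range(r):
            rep = f"R{k + 1}"
            noise = np.exp(rng.normal(0.0, config.sigma_rep, size=g)) if config.sigma_rep else 1.0
            sample = f"{label}_{rep}"
            columns[sample] = expected * noise
            layout[sample] = (label, rep)
    values = pd.DataFrame(
        columns, index=pd.Index([f"g{i + 1}" for i in range(g)], name="gene")
    )
    return ExpressionDataset(
        values=values,
        layout=layout,
        metadata={"generator": "synth_data", "seed": config.seed, "sigma_rep": config.sigma_rep},
    )


def generate_protein_transcript_pair(
    orf_lengths: GeneLengthTable | Mapping[str, int],
    transcript_folds: Mapping[str, float] | Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    protein_response: Mapping[str, float] | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Paired transcript/protein fold-changes under the length mechanism.

    The observed protein fold-change is

        PF_i = (transcript_fold_i / CF_i) * exp(noise_sd * z_i)

    where CF_i = L_i / min L.  ``protein_response`` overrides the
    length-derived response per gene: when given, PF_i = response_i * noise,
    letting intrinsic (regulated) protein responses be injected directly.
    A gene without an ORF length is a hard error naming the gene.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    lengths = orf_lengths.lengths if isinstance(orf_lengths, GeneLengthTable) else dict(orf_lengths)
    if isinstance(transcript_folds, Mapping):
        genes = list(transcript_folds)
        tf = np.array([transcript_folds[g] for g in genes], dtype=float)
    else:
        tf = np.asarray(transcript_folds, dtype=float)
        genes = [f"g{i + 1}" for i in range(tf.size)]
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise KeyError(f"no ORF length for gene {missing[0]!r}")
    if np.any(tf <= 0):
        raise ValueError("transcript folds must be positive")
    orf = np.array([lengths[g] for g in genes], dtype=float)
    cf = correction_factors(dict(zip(genes, orf))).reindex(genes).to_numpy()
    if protein_response is None:
        response = tf / cf
    elif isinstance(protein_response, Mapping):
        response = np.array([protein_response[g] for g in genes], dtype=float)
    else:
        response = np.asarray(protein_response, dtype=float)
        if response.size != tf.size:
            raise ValueError("protein_response length must match transcript_folds")
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, noise_sd, size=tf.size)) if noise_sd else 1.0
    pf = response * noise
    return pd.DataFrame(
        {"TF": tf, "ORF": orf.astype(int), "PF": pf},
        index=pd.Index(genes, name="gene"),
    )
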