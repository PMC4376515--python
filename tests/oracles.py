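"""Independent brute-force oracles used to cross-check the implementation.

Everything here is literal pure-Python enumeration over nested dictionaries —
no numpy, no pandas, no imports from the package's statistics code paths —
so a match with the implementation is evidence, not a tautology.
"""

from __future__ import annotations

import itertools
import math


def _mean(xs):
    return sum(xs) / len(xs)


def _stdev(xs, ddof=1):
    if len(xs) <= ddof:
        return 0.0
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - ddof))


def _fold(v):
    return v - 1.0 if v >= 1.0 else 1.0 / v - 1.0


def brute_force_between_treatments(data):
    """Literal enumeration of the ratio-statistics reproducibility procedure.

    ``data``: {treatment: {replicate: [gene values]}}.  Returns a dict with
    the pooled coefficients, the per-statistic deviation lists, population
    count and skipped-comparison count.
    """
    treatments = sorted(data)
    pops = {}
    for a, b in itertools.permutations(treatments, 2):
        for r in sorted(data[a]):
            for s in sorted(data[b]):
                ratios = [
                    x / y
                    for x, y in zip(data[a][r], data[b][s])
                    if x > 0 and y > 0
                ]
                pops[((a, r), (b, s))] = ratios
    mean_devs, sd_devs, skipped = [], [], 0
    for a, b in itertools.permutations(treatments, 2):
        for r in sorted(data[a]):
            for s, s2 in itertools.combinations(sorted(data[b]), 2):
                p = pops[((a, r), (b, s))]
                q = pops[((a, r), (b, s2))]
                mean_devs.append(_fold(_mean(p) / _mean(q)))
                sp, sq = _stdev(p), _stdev(q)
                if sp == 0.0 or sq == 0.0:
                    skipped += 1
                else:
                    sd_devs.append(_fold(sp / sq))
    pooled = mean_devs + sd_devs
    return {
        "avg_deviation": _mean(pooled),
        "sd_of_deviations": _stdev(pooled),
        "mean_deviations": mean_devs,
        "sd_deviations": sd_devs,
        "n_populations": len(pops),
        "skipped": skipped,
    }


def brute_force_within_treatment(reps):
    """Between-replicates variant: ``reps`` is {replicate: [gene values]}."""
    devs = []
    for k, l in itertools.permutations(sorted(reps), 2):
        ratios = [x / y for x, y in zip(reps[k], reps[l]) if x > 0 and y > 0]
        devs.append(_fold(_mean(ratios)))
    return {"avg_deviation": _mean(devs), "mean_deviations": devs}


def brute_force_fc_threshold(fold_changes, alpha):
    """Try every observed fold-change, smallest first, as candidate threshold."""
    n = len(fold_changes)
    for t in sorted(set(fold_changes)):
        if sum(1 for f in fold_changes if f >= t) / n < alpha:
            return t
    return None  # even the maximum occurs too often
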