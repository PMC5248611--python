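"""Coverage summaries, detection-probability model and performance metrics.

The detection-probability calculator answers the diagnostic question "given
n unique reads, what is the chance a variant at allele fraction p is
called?" under the calling rule (at least 3 unique variant reads and at
least 5% of reads).  Unique reads are independent draws of the allele, so
the answer is an exact binomial tail: with k* = max(min_var_reads,
ceil(min_vaf * n)),

    P(called) = P(X >= k*),  X ~ Binomial(n, p).

At 30 unique reads this gives a >= 95% chance of detecting a 20% VAF
variant, and at 20 reads a >= 95% chance at 30% VAF — the rationale for the
20x/30x minimal and expected depth gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CoverageSummary:
    n_bases: int
    mean_depth: float
    median_depth: float
    fraction_at_least: dict[int, float]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def coverage_summary(depths, thresholds=(20, 30)) -> CoverageSummary:
    """Fractions of the target at or above each unique-read depth threshold."""
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("empty target: no depth values")
    return CoverageSummary(
        n_bases=int(d.size),
        mean_depth=float(d.mean()),
        median_depth=float(np.median(d)),
        fraction_at_least={t: float((d >= t).mean()) for t in thresholds},
    )


def detection_probability(
    n: int, p: float, min_var_reads: int = 3, min_vaf: float = 0.05
) -> float:
    """Chance of calling a variant at allele fraction p from n unique reads.

    Exact binomial tail P(X >= k*) with the effective variant-read threshold
    k* = max(min_var_reads, ceil(min_vaf * n)).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele fraction must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError("depth must be >= 0")
    k_star = max(min_var_reads, math.ceil(min_vaf * n))
    if k_star > n:
        return 0.0
    return float(stats.binom.sf(k_star - 1, n, p))


def detection_probability_table(
    depths, vafs, min_var_reads: int = 3, min_vaf: float = 0.05
):
    """Grid of detection probabilities over (depth, VAF) pairs."""
    return {
        int(n): {float(p): detection_probability(n, p, min_var_reads, min_vaf) for p in vafs}
        for n in depths
    }


def confusion_metrics(c: ConfusionCounts, ci_method: str = "wald") -> dict:
    """Sensitivity, per-nucleotide accuracy and false-positive call rate.

    sensitivity = tp/(tp+fn); accuracy = (tp+tn)/total; fp rate of calls =
    fp/(tp+fp).  The 95% CI for sensitivity is Wald by default
    (p +/- 1.96*sqrt(p(1-p)/n)); ``ci_method="clopper-pearson"`` gives the
    exact interval instead.
    """
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: tp + fn == 0")
    if c.tp + c.fp == 0:
        raise ValueError("fp_rate_of_calls undefined: tp + fp == 0")
    n_pos = c.tp + c.fn
    sens = c.tp / n_pos
    total = c.tp + c.fp + c.tn + c.fn
    accuracy = (c.tp + c.tn) / total
    fp_rate = c.fp / (c.tp + c.fp)
    if ci_method == "wald":
        half = 1.96 * math.sqrt(sens * (1.0 - sens) / n_pos)
        ci = (max(0.0, sens - half), min(1.0, sens + half))
    elif ci_method == "clopper-pearson":
        lo = stats.beta.ppf(0.025, c.tp, c.fn + 1) if c.tp > 0 else 0.0
        hi = stats.beta.ppf(0.975, c.tp + 1, c.fn) if c.fn > 0 else 1.0
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "sensitivity": sens,
        "accuracy": accuracy,
        "fp_rate_of_calls": fp_rate,
        "sensitivity_ci_95": ci,
    }
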