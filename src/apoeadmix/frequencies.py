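"""APOE epsilon-allele counting, exact intervals and pairwise tests.

Counting rules (designed to maximize usable sample size at low coverage):

* epsilon4 is counted from its defining variant alone — C alleles at rs429358
  over all samples with that site called;
* epsilon2 likewise — T alleles at rs7412;
* epsilon3 requires the rs429358-T/rs7412-C haplotype and therefore only uses
  samples with BOTH sites called.  Because epsilon1 (rs429358-C with rs7412-T)
  is excluded from the alphabet, every non-double-heterozygous diplotype has a
  unique haplotype decomposition; double heterozygotes are resolved as
  epsilon2/epsilon4 (contributing zero epsilon3) and their count is reported
  so sensitivity to the alternative resolution can be assessed.

Frequencies carry exact 90% Clopper-Pearson intervals; population pairs are
compared per allele with Fisher's exact test, and all tests in a run are
pooled into one Benjamini-Hochberg family at FDR 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotyping import GenotypeCall

log = logging.getLogger(__name__)

ALLELES = ("e2", "e3", "e4")


@dataclass(frozen=True)
class EpsilonCounts:
    """Per-population allele counts with allele-specific denominators."""

    population: str
    x_e4: int
    n_e4: int
    x_e2: int
    n_e2: int
    x_e3: int
    n_e3: int
    n_ambiguous_dhet: int = 0

    def __post_init__(self) -> None:
        for allele in ALLELES:
            if not 0 <= self.x(allele) <= self.n(allele):
                raise ValueError(f"{self.population}: invalid {allele} counts")
        if self.n_e3 > min(self.n_e4, self.n_e2):
            raise ValueError(f"{self.population}: both-site denominator exceeds single-site")

    def x(self, allele: str) -> int:
        return {"e2": self.x_e2, "e3": self.x_e3, "e4": self.x_e4}[allele]

    def n(self, allele: str) -> int:
        return {"e2": self.n_e2, "e3": self.n_e3, "e4": self.n_e4}[allele]

    def freq(self, allele: str) -> float:
        n = self.n(allele)
        return self.x(allele) / n if n else float("nan")


@dataclass(frozen=True)
class FrequencyEstimate:
    population: str
    allele: str
    freq: float
    ci_low: float
    ci_high: float
    level: float = 0.90


@dataclass(frozen=True)
class PairwiseTestResult:
    population_a: str
    population_b: str
    allele: str
    p_raw: float
    p_adjusted: float
    significant: bool


def count_epsilon(samples: Sequence[tuple[GenotypeCall, GenotypeCall]], population: str = "") -> EpsilonCounts:
    """Tally epsilon alleles from per-sample (rs429358, rs7412) diploid calls.

    Every sample must already pass the focal-site filter (at least one site
    called).  Per individual with both sites called, the haplotype
    decomposition is forced by excluding epsilon1: each rs429358-C allele is
    an epsilon4, each rs7412-T allele an epsilon2, and the remainder epsilon3;
    double heterozygotes thus resolve to epsilon2/epsilon4.
    """
    x_e4 = n_e4 = x_e2 = n_e2 = x_e3 = n_e3 = n_dhet = 0
    for call_429358, call_7412 in samples:
        if call_429358.is_missing and call_7412.is_missing:
            raise ValueError("sample missing both sites; apply the focal-site filter first")
        if not call_429358.is_missing:
            n_e4 += 2
            x_e4 += sum(a == "C" for a in call_429358.alleles)
        if not call_7412.is_missing:
            n_e2 += 2
            x_e2 += sum(a == "T" for a in call_7412.alleles)
        if not call_429358.is_missing and not call_7412.is_missing:
            g1 = sum(a == "T" for a in call_429358.alleles)
            g2 = sum(a == "C" for a in call_7412.alleles)
            if g1 + g2 < 2:
                # would require an epsilon1 haplotype; cannot arise under the
                # three-allele alphabet — excluded from the both-site tally
                log.warning("%s: diplotype inconsistent with e2/e3/e4 alphabet; skipped", population)
                continue
            n_e3 += 2
            x_e3 += g1 + g2 - 2
            if g1 == 1 and g2 == 1:
                n_dhet += 1
    return EpsilonCounts(population, x_e4, n_e4, x_e2, n_e2, x_e3, n_e3, n_dhet)


def clopper_pearson(x: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval from beta quantiles.

    The lower bound is 0 when x = 0 and the upper bound 1 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1 for a confidence interval")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def frequency_estimates(counts: EpsilonCounts, level: float = 0.90) -> list[FrequencyEstimate]:
    """Point frequency plus Clopper-Pearson interval for each epsilon allele."""
    out = []
    for allele in ALLELES:
        n = counts.n(allele)
        if n == 0:
            continue
        x = counts.x(allele)
        low, high = clopper_pearson(x, n, level)
        out.append(FrequencyEstimate(counts.population, allele, x / n, low, high, level))
    return out


def fisher_pairwise(counts_a: EpsilonCounts, counts_b: EpsilonCounts, allele: str) -> float:
    """Two-sided Fisher's exact p for one allele between two populations.

    Uses the conventional probability-ordering two-sided definition (sum of
    hypergeometric probabilities of all tables at least as extreme).  A table
    with a zero margin carries no information and returns p = 1.
    """
    table = [
        [counts_a.x(allele), counts_a.n(allele) - counts_a.x(allele)],
        [counts_b.x(allele), counts_b.n(allele) - counts_b.x(allele)],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment over one pooled family.

    Returns (adjusted p-values, boolean rejection at level q).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return adjusted, adjusted <= q


def pairwise_frequency_tests(
    counts_by_pop: Sequence[EpsilonCounts], q: float = 0.05
) -> list[PairwiseTestResult]:
    """All pairwise population comparisons per allele, BH-corrected as one family."""
    jobs = [
        (a, b, allele)
        for a, b in itertools.combinations(counts_by_pop, 2)
        for allele in ALLELES
        if a.n(allele) > 0 and b.n(allele) > 0
    ]
    raw = [fisher_pairwise(a, b, allele) for a, b, allele in jobs]
    adjusted, reject = bh_adjust(raw, q)
    return [
        PairwiseTestResult(a.population, b.population, allele, p, float(padj), bool(rej))
        for (a, b, allele), p, padj, rej in zip(jobs, raw, adjusted, reject)
    ]
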