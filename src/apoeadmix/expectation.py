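"""Admixture-informed expected allele frequencies and deviation tests.

The core model: if an offspring population formed by mixing parents A and B
with ancestry components kA + kB = 1, its expected allele frequency is the
linear combination

    fexp = kA * fA + kB * fB.

Expectations can be chained over a multi-step demographic history (e.g.
hunter-gatherers and early farmers form late farmers; late farmers and
steppe herders form later Europeans), with each step consuming the parents'
OBSERVED frequencies — the test at each step asks whether the offspring's
observed frequency is explainable by admixture from what its parents
actually looked like, not from model output.

Deviation from fexp is assessed with an exact two-sided binomial test using
the minimum-likelihood ordering: p is the total Binomial(n, fexp) probability
of all outcomes whose point probability does not exceed that of the observed
count.  No drift variance is added and no uncertainty in k or f is
propagated; the test is exact for the stated null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

_K_TOL = 1e-9


@dataclass(frozen=True)
class DemographicStep:
    """One admixture event: parents A and B form the offspring population."""

    offspring: str
    parent_a: str
    parent_b: str
    k_a: float
    k_b: float

    def __post_init__(self) -> None:
        if abs(self.k_a + self.k_b - 1.0) > _K_TOL:
            raise ValueError(f"step {self.offspring}: components must sum to 1")
        if not (0 <= self.k_a <= 1):
            raise ValueError(f"step {self.offspring}: components must lie in [0,1]")


@dataclass(frozen=True)
class ExpectedFrequency:
    offspring: str
    allele: str
    fexp: float


@dataclass(frozen=True)
class DeviationTest:
    offspring: str
    allele: str
    x: int
    n: int
    fexp: float
    p_value: float

    @property
    def stars(self) -> str:
        for threshold, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value <= threshold:
                return mark
        return ""


def expected_frequency(k_a: float, f_a: float, k_b: float, f_b: float) -> float:
    """fexp = kA*fA + kB*fB, validating that the components sum to 1."""
    if abs(k_a + k_b - 1.0) > _K_TOL:
        raise ValueError("admixture components must sum to 1")
    if not (0 <= f_a <= 1 and 0 <= f_b <= 1):
        raise ValueError("parental frequencies must lie in [0,1]")
    return k_a * f_a + k_b * f_b


def chain_expectations(
    steps: Sequence[DemographicStep],
    observed: Mapping[str, Mapping[str, float]],
) -> list[ExpectedFrequency]:
    """Expected frequencies for every offspring over a demographic chain.

    ``observed[population][allele]`` holds observed frequencies; every step's
    parents must be present there (steps never feed their own expectations
    forward).  A missing parent raises an error naming the step.
    """
    out = []
    for step in steps:
        for parent in (step.parent_a, step.parent_b):
            if parent not in observed:
                raise ValueError(
                    f"step '{step.offspring}': no observed frequencies for parent '{parent}'"
                )
        alleles = sorted(set(observed[step.parent_a]) & set(observed[step.parent_b]))
        for allele in alleles:
            fexp = expected_frequency(
                step.k_a, observed[step.parent_a][allele],
                step.k_b, observed[step.parent_b][allele],
            )
            out.append(ExpectedFrequency(step.offspring, allele, fexp))
    return out


def binomial_deviation_test(x: int, n: int, fexp: float) -> float:
    """Exact two-sided binomial p for observing x of n at expected frequency fexp."""
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0 <= fexp <= 1:
        raise ValueError("fexp must lie in [0,1]")
    if n == 0:
        return 1.0
    return float(stats.binomtest(x, n, fexp, alternative="two-sided").pvalue)


def deviation_tests(
    expectations: Sequence[ExpectedFrequency],
    counts: Mapping[str, Mapping[str, tuple[int, int]]],
) -> list[DeviationTest]:
    """Run the deviation test for every expectation with observed counts.

    ``counts[population][allele]`` is (x, n) with the allele-specific
    denominator (single-site for epsilon2/4, both-site for epsilon3).
    """
    out = []
    for exp in expectations:
        if exp.offspring not in counts or exp.allele not in counts[exp.offspring]:
            continue
        x, n = counts[exp.offspring][exp.allele]
        p = binomial_deviation_test(x, n, exp.fexp)
        out.append(DeviationTest(exp.offspring, exp.allele, x, n, exp.fexp, p))
    return out
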