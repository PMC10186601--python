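"""Ancient-DNA-grade diploid genotype calling and sample QC.

Inputs are per-site pileup counts already filtered to base/mapping quality
> 20 (an input contract, not re-checked here).  The module implements:

* damage trimming — mask terminal read positions whose C->T deamination rate
  exceeds a threshold (default 0.05);
* an explicit binomial-likelihood diploid caller with a minimum-depth filter
  (default 3); pseudo-haploid calls are never produced — every emitted call
  is diploid or MISSING;
* the sample-level filters used downstream: keep a sample for allele counting
  if at least one focal site has a diploid call, and keep a sample for the
  selection scans only with chromosome coverage >= 70% and local mean depth
  > 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

MISSING = None  # sentinel genotype for sites without a confident diploid call


@dataclass(frozen=True)
class SitePileup:
    """Per-site base counts annotated by distance from the read end.

    ``counts[base]`` is an integer array of length ``terminal_bins + 1``:
    index ``d < terminal_bins`` holds reads whose site position sits ``d``
    bases from a read end; the final index holds interior reads.
    """

    site_id: str
    counts: dict[str, np.ndarray]
    terminal_bins: int

    def __post_init__(self) -> None:
        for base, arr in self.counts.items():
            if len(arr) != self.terminal_bins + 1 or (np.asarray(arr) < 0).any():
                raise ValueError(f"malformed counts for base {base}")

    @property
    def depth(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def base_totals(self) -> dict[str, int]:
        return {b: int(arr.sum()) for b, arr in self.counts.items() if arr.sum() > 0}

    def terminal_total(self, base: str) -> int:
        arr = self.counts.get(base)
        return 0 if arr is None else int(arr[: self.terminal_bins].sum())


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid call (ordered allele pair) or MISSING, with depth and quality."""

    site_id: str
    alleles: tuple[str, str] | None
    depth: int
    qual: float

    @property
    def is_missing(self) -> bool:
        return self.alleles is None


@dataclass(frozen=True)
class SampleScanQC:
    """Per-sample inputs to the selection-scan filter."""

    chrom_coverage: float  # fraction of chromosome site universe covered
    local_mean_depth: float  # mean depth in the window around the focal locus

    def __post_init__(self) -> None:
        if not 0 <= self.chrom_coverage <= 1:
            raise ValueError("chrom_coverage must lie in [0,1]")


def decide_trim(terminal_ct_rates: Sequence[float], threshold: float = 0.05) -> int:
    """Number of terminal read positions to mask, given per-position C->T rates.

    ``terminal_ct_rates[d]`` is the deamination rate at distance ``d`` from the
    read end.  Returns the smallest m such that every position at distance
    >= m has rate <= threshold, i.e. the contiguous damaged run is removed.
    An empty profile needs no trimming.
    """
    rates = np.asarray(terminal_ct_rates, dtype=float)
    if rates.size == 0:
        return 0
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rates must lie in [0,1]")
    over = np.nonzero(rates > threshold)[0]
    return 0 if over.size == 0 else int(over[-1]) + 1


def apply_trim(pileup: SitePileup, m: int) -> SitePileup:
    """Remove counts originating from the m outermost terminal positions.

    Distances are only tracked up to ``terminal_bins``; an m beyond that
    removes all terminal-origin counts but never touches interior reads.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return pileup
    cut = min(m, pileup.terminal_bins)
    new_counts = {}
    for base, arr in pileup.counts.items():
        trimmed = arr.copy()
        trimmed[:cut] = 0
        if trimmed.sum() > 0:
            new_counts[base] = trimmed
    return SitePileup(pileup.site_id, new_counts, pileup.terminal_bins)


def call_genotype(
    pileup: SitePileup, base_error: float, min_depth: int = 3
) -> GenotypeCall:
    """Maximum-likelihood diploid genotype from a pileup.

    Among the two most frequent observed bases A and B, picks the genotype in
    {AA, AB, BB} maximizing the binomial read-sampling likelihood with
    symmetric per-read error ``base_error``; genotypes supported by fewer
    than ``min_depth`` reads are MISSING.  ``qual`` is the phred-scaled
    complement of the genotype posterior under a uniform prior over the three
    genotypes, so it grows with depth and allele-balance evidence.
    """
    if not 0 < base_error < 0.5:
        raise ValueError("base_error must lie in (0, 0.5)")
    totals = pileup.base_totals()
    depth = pileup.depth
    if depth < min_depth or not totals:
        return GenotypeCall(pileup.site_id, MISSING, depth, 0.0)

    ranked = sorted(totals, key=lambda b: (-totals[b], b))
    if len(ranked) > 2:
        log.warning(
            "site %s: %d observed bases; using two most frequent", pileup.site_id, len(ranked)
        )
    a = ranked[0]
    b = ranked[1] if len(ranked) > 1 else None

    n_a = totals[a]
    n_b = totals.get(b, 0) if b is not None else 0
    n = n_a + n_b
    e = base_error
    # P(read shows B | genotype): AA -> e, AB -> 1/2, BB -> 1-e
    with np.errstate(divide="ignore"):
        loglik = np.array(
            [
                n_b * np.log(e) + n_a * np.log(1 - e),
                n * np.log(0.5),
                n_b * np.log(1 - e) + n_a * np.log(e),
            ]
        )
    post = np.exp(loglik - loglik.max())
    post /= post.sum()
    best = int(post.argmax())
    if b is None:
        b = a  # degenerate: only one base seen; AB/BB collapse onto AA
    genotype = [(a, a), (a, b), (b, b)][best]
    p_err = max(1.0 - float(post[best]), 1e-10)
    qual = -10.0 * np.log10(p_err)
    return GenotypeCall(pileup.site_id, tuple(sorted(genotype)), depth, float(qual))


def sample_passes_apoe_filter(calls: Sequence[GenotypeCall]) -> bool:
    """Keep a sample iff at least one focal site has a diploid call.

    Samples missing a diploid genotype at both polymorphic sites carry no
    epsilon information and are dropped.
    """
    if len(calls) != 2:
        raise ValueError("expected calls for exactly the two focal sites")
    return any(not c.is_missing for c in calls)


def sample_passes_scan_qc(
    qc: SampleScanQC, cov_min: float = 0.70, depth_min: float = 5.0
) -> bool:
    """Selection-scan sample filter: coverage >= cov_min and depth strictly > depth_min."""
    return qc.chrom_coverage >= cov_min and qc.local_mean_depth > depth_min
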