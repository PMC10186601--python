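"""Supervised two-way ancestry estimation.

With two parental panels and their per-site allele frequencies held fixed,
an individual's ancestry proportion q (of parent A) is estimated by
maximizing the binomial genotype likelihood

    L(q) = prod_l Binom(g_l | 2, q*fA_l + (1-q)*fB_l),  g_l in {0,1,2}.

The per-site success probability is linear in q, so the log-likelihood is
concave and the maximizer over [0,1] unique unless fA = fB at every used
site.  This is the supervised-admixture likelihood restricted to K = 2 with
known parental frequencies — exactly the quantity needed for the
admixture-informed frequency expectations downstream.  Uncertainty comes
from resampling sites with replacement (a site bootstrap, default 100
replicates).  The panel is assumed LD-pruned (unlinked sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

_XATOL = 1e-8


@dataclass(frozen=True)
class SnpPanel:
    """Fixed per-site parental allele frequencies for the supervised fit."""

    site_ids: np.ndarray
    freq_a: np.ndarray
    freq_b: np.ndarray

    def __post_init__(self) -> None:
        fa, fb = np.asarray(self.freq_a), np.asarray(self.freq_b)
        if fa.shape != fb.shape or fa.shape != np.asarray(self.site_ids).shape:
            raise ValueError("panel arrays must have identical shapes")
        if ((fa <= 0) | (fa >= 1) | ((fb <= 0) | (fb >= 1))).any():
            raise ValueError("panel frequencies must lie strictly inside (0,1)")

    @property
    def n_sites(self) -> int:
        return len(self.freq_a)


@dataclass(frozen=True)
class AncestryEstimate:
    individual: str
    q_hat: float
    bootstrap_se: float
    n_sites_used: int
    degenerate: bool = False


def estimate_parental_freqs(
    genotypes: np.ndarray, pseudocount: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt-allele frequencies from parental reference genotypes.

    ``genotypes`` is (n_individuals, n_sites) of alt dosages 0/1/2 with np.nan
    for missing.  The pseudocount keeps frequencies strictly inside (0,1):
    f = (alt + c) / (2*n_called + 2*c).  Sites with no called genotype are
    dropped; a boolean keep-mask is returned alongside the frequencies.
    """
    g = np.asarray(genotypes, dtype=float)
    called = ~np.isnan(g)
    n_called = called.sum(axis=0)
    keep = n_called > 0
    if not keep.all():
        log.warning("%d panel sites dropped: all genotypes missing", int((~keep).sum()))
    alt = np.nansum(g, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (alt + pseudocount) / (2 * n_called + 2 * pseudocount)
    return freq[keep], keep


def _neg_loglik(q: float, g: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> float:
    p = np.clip(q * fa + (1 - q) * fb, 1e-12, 1 - 1e-12)
    # binomial(2) kernel; the choose(2, g) term is constant in q
    return -float(np.sum(g * np.log(p) + (2 - g) * np.log1p(-p)))


def fit_q(genotypes: Sequence[float], panel: SnpPanel, individual: str = "") -> AncestryEstimate:
    """Maximum-likelihood ancestry proportion for one individual.

    Missing genotypes (np.nan) are ignored.  When fA = fB at every used site
    the likelihood is flat in q; the estimate defaults to 0.5 and is flagged
    degenerate.  Optimization is bounded scalar minimization to 1e-8.
    """
    g = np.asarray(genotypes, dtype=float)
    use = ~np.isnan(g)
    if not use.any():
        raise ValueError("need at least one non-missing genotype")
    g, fa, fb = g[use], np.asarray(panel.freq_a)[use], np.asarray(panel.freq_b)[use]
    if np.allclose(fa, fb):
        return AncestryEstimate(individual, 0.5, 0.0, int(use.sum()), degenerate=True)
    res = minimize_scalar(
        _neg_loglik, bounds=(0.0, 1.0), args=(g, fa, fb), method="bounded",
        options={"xatol": _XATOL},
    )
    return AncestryEstimate(individual, float(res.x), 0.0, int(use.sum()))


def bootstrap_q(
    genotypes: Sequence[float],
    panel: SnpPanel,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    individual: str = "",
) -> AncestryEstimate:
    """Point estimate plus site-bootstrap standard error of q.

    Sites are resampled with replacement B times; the SE is the standard
    deviation of the replicate estimates.  With a fixed seed the result is
    reproducible bit-for-bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = fit_q(genotypes, panel, individual)
    if base.degenerate:
        return base
    g = np.asarray(genotypes, dtype=float)
    use = ~np.isnan(g)
    g, fa, fb = g[use], np.asarray(panel.freq_a)[use], np.asarray(panel.freq_b)[use]
    L = len(g)
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, L, size=L)
        if np.allclose(fa[idx], fb[idx]):
            reps[b] = 0.5
            continue
        res = minimize_scalar(
            _neg_loglik, bounds=(0.0, 1.0), args=(g[idx], fa[idx], fb[idx]),
            method="bounded", options={"xatol": _XATOL},
        )
        reps[b] = res.x
    return AncestryEstimate(individual, base.q_hat, float(reps.std(ddof=1)), base.n_sites_used)


def population_components(estimates: Sequence[AncestryEstimate]) -> tuple[float, float]:
    """Population-level admixture components (kA, kB) = (mean q, 1 - mean q)."""
    if not estimates:
        raise ValueError("need at least one individual")
    k_a = float(np.mean([e.q_hat for e in estimates]))
    return k_a, 1.0 - k_a
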