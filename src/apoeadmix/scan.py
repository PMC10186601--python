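"""Selection scans: per-site Weir-Cockerham FST and windowed Tajima's D.

Both statistics are judged against empirical chromosome-wide backgrounds
rather than parametric nulls: a focal site's FST is compared with the 95th
and 97.5th percentiles of all defined per-site FST values on the chromosome,
and the mean Tajima's D of a focal locus (three consecutive windows) is
placed within the distribution of all window values (median, quartiles,
5th/95th percentiles — the box-plot summary).

FST uses the Weir & Cockerham (1984) variance-component estimator for two
populations from diploid genotype counts, including the within-individual
component: theta_hat = a / (a + b + c).  Negative estimates are retained as
computed (clamping would distort the percentile background; a config switch
downstream can clamp for display).  Tajima's D follows the 1989 definition,
D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)), with all constants derived from
the number of sampled chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PopSiteCounts:
    """One population's genotype summary at one site.

    n_alt   alternate-allele count over called chromosomes
    n_chrom called chromosomes (2 x called individuals)
    n_het   heterozygous called individuals
    """

    n_alt: int
    n_chrom: int
    n_het: int

    def __post_init__(self) -> None:
        if self.n_chrom % 2:
            raise ValueError("n_chrom must be even (diploid individuals)")
        if not 0 <= self.n_alt <= self.n_chrom:
            raise ValueError("alt count must lie in [0, n_chrom]")
        if not 0 <= self.n_het <= self.n_chrom // 2:
            raise ValueError("het count must lie in [0, individuals]")


@dataclass(frozen=True)
class FstSite:
    site_id: str
    a: float
    b: float
    c: float
    theta: float
    defined: bool


@dataclass(frozen=True)
class WindowD:
    index: int
    start: int
    end: int
    S: int
    pi: float
    D: float
    defined: bool


@dataclass(frozen=True)
class ScanSummary:
    """Chromosome background plus focal-locus placement."""

    d_percentiles: dict[float, float]
    locus_mean_d: float
    locus_defined: bool
    below_median: bool
    below_p5: bool
    above_p95: bool
    focal_windows: tuple[int, ...] = field(default_factory=tuple)


def wc_fst_site(pop1: PopSiteCounts, pop2: PopSiteCounts, site_id: str = "site") -> FstSite:
    """Weir & Cockerham (1984) two-population FST from diploid genotype counts.

    Returns the variance components a (among populations), b (among
    individuals within populations), c (within individuals) and
    theta = a/(a+b+c).  Undefined (flagged) when either population has fewer
    than two called chromosomes or the site is monomorphic across both
    populations (a + b + c = 0).
    """
    if pop1.n_chrom < 2 or pop2.n_chrom < 2:
        return FstSite(site_id, np.nan, np.nan, np.nan, np.nan, False)
    r = 2
    n = np.array([pop1.n_chrom / 2, pop2.n_chrom / 2], dtype=float)  # individuals
    p = np.array([pop1.n_alt / pop1.n_chrom, pop2.n_alt / pop2.n_chrom])
    h = np.array([pop1.n_het / n[0], pop2.n_het / n[1]])

    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)

    if n_bar > 1:
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
    else:
        # single individual per population: no within-population information
        a, b = s2 * (n_bar / n_c), 0.0
    c = h_bar / 2

    denom = a + b + c
    if denom == 0:
        return FstSite(site_id, a, b, c, np.nan, False)
    return FstSite(site_id, float(a), float(b), float(c), float(a / denom), True)


def fst_background(
    sites: Sequence[FstSite],
    focal_ids: Sequence[str] = (),
    levels: tuple[float, ...] = (95.0, 97.5),
    min_sites: int = 20,
) -> tuple[dict[float, float], dict[str, dict[float, bool]]]:
    """Empirical FST percentile thresholds and focal-site outlier flags.

    Thresholds are linear-interpolated percentiles over defined sites only;
    a focal site is flagged at a level iff its theta lies strictly above the
    threshold.  Undefined focal sites are never flagged.
    """
    defined = [s for s in sites if s.defined]
    if len(defined) < min_sites:
        raise ValueError(f"need >= {min_sites} defined FST values, got {len(defined)}")
    values = np.array([s.theta for s in defined])
    thresholds = {lv: float(np.percentile(values, lv)) for lv in levels}
    by_id = {s.site_id: s for s in sites}
    flags = {}
    for fid in focal_ids:
        site = by_id.get(fid)
        flags[fid] = {
            lv: bool(site is not None and site.defined and site.theta > thr)
            for lv, thr in thresholds.items()
        }
    return thresholds, flags


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    derived_counts: Sequence[int],
    n_chromosomes: int,
    index: int = 0,
    start: int = 0,
    window_len: int = 15_000,
) -> WindowD:
    """Tajima's D for one window from per-site minor/derived allele counts.

    pi is the mean pairwise difference, sum over sites of 2*x*(n-x)/(n*(n-1));
    S is the number of segregating sites.  D is undefined (flagged) for
    monomorphic windows.
    """
    x = np.asarray(derived_counts, dtype=float)
    x = x[(x > 0) & (x < n_chromosomes)]
    S = len(x)
    n = n_chromosomes
    pi = float(np.sum(2 * x * (n - x) / (n * (n - 1))))
    if S == 0:
        return WindowD(index, start, start + window_len, 0, pi, np.nan, False)
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return WindowD(index, start, start + window_len, S, pi, np.nan, False)
    d = (pi - S / k["a1"]) / np.sqrt(var)
    return WindowD(index, start, start + window_len, S, pi, float(d), True)


def windowed_scan(
    positions: Sequence[int],
    alt_counts: Sequence[int],
    n_chromosomes: int,
    window_len: int = 15_000,
    focal_windows: Sequence[int] = (),
    origin: int = 0,
    levels: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0),
) -> tuple[list[WindowD], ScanSummary]:
    """Tile the chromosome into half-open windows and summarize the focal locus.

    Windows are [origin + w*L, origin + (w+1)*L); a site at exactly a window
    boundary belongs to the right-hand window.  The locus summary is the mean
    of defined D values over the configured focal windows, compared with the
    chromosome-wide distribution of defined window values (median, quartiles,
    5th/95th percentiles) — flags mark a locus mean below the 5th or above
    the 95th percentile, plus the weaker below-median indicator.
    """
    pos = np.asarray(positions)
    alt = np.asarray(alt_counts)
    if len(pos) != len(alt):
        raise ValueError("positions and counts must align")
    order = np.argsort(pos)
    pos, alt = pos[order], alt[order]
    n_windows = 0 if len(pos) == 0 else int((pos.max() - origin) // window_len) + 1
    n_windows = max(n_windows, (max(focal_windows) + 1) if len(focal_windows) else 0)

    windows = []
    widx = (pos - origin) // window_len
    for w in range(n_windows):
        in_w = widx == w
        windows.append(
            tajimas_d(alt[in_w], n_chromosomes, index=w, start=origin + w * window_len,
                      window_len=window_len)
        )

    defined_d = np.array([w.D for w in windows if w.defined])
    if defined_d.size == 0:
        raise ValueError("no window has a defined Tajima's D")
    pcts = {lv: float(np.percentile(defined_d, lv)) for lv in levels}

    focal_d = [windows[w].D for w in focal_windows if w < len(windows) and windows[w].defined]
    if focal_d:
        locus = float(np.mean(focal_d))
        summary = ScanSummary(
            d_percentiles=pcts,
            locus_mean_d=locus,
            locus_defined=True,
            below_median=locus < pcts.get(50.0, np.median(defined_d)),
            below_p5=locus < pcts.get(5.0, np.percentile(defined_d, 5)),
            above_p95=locus > pcts.get(95.0, np.percentile(defined_d, 95)),
            focal_windows=tuple(focal_windows),
        )
    else:
        summary = ScanSummary(pcts, np.nan, False, False, False, False, tuple(focal_windows))
    return windows, summary
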