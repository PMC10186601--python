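"""Synthetic-data generation for every stage of the pipeline.

The generator emulates the statistical structure the analysis assumes:

* parental populations with fixed APOE epsilon-haplotype frequencies
  (including an epsilon2-free hunter-gatherer-like population),
* admixed offspring formed by drawing each haplotype from one of two parents,
* pileup-level ancient-DNA artifacts (Poisson depth, base error, terminal
  C->T deamination),
* an unlinked SNP panel with Balding-Nichols parental divergence for the
  supervised-admixture stage,
* neutral and sweep-like windows of segregating sites for the selection scans
  (neutral site-frequency spectrum proportional to 1/i; sweeps skew toward
  rare variants and lose diversity).

One top-level seed drives everything; each stage derives an independent child
stream via :func:`stage_rng`, so outputs are reproducible per stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

# Haplotype alphabet and the two defining SNPs.  epsilon1 (C at rs429358 with
# T at rs7412) is excluded: it is vanishingly rare in Europeans and the
# three-allele frame is standard.
EPS_HAPLOTYPES: tuple[str, ...] = ("e2", "e3", "e4")

RS429358 = "rs429358"  # T/C; C defines epsilon4
RS7412 = "rs7412"      # C/T; T defines epsilon2

SITE_ALLELES: dict[str, tuple[str, str]] = {RS429358: ("T", "C"), RS7412: ("C", "T")}

_HAP_TO_SITES: dict[str, tuple[str, str]] = {
    "e4": ("C", "C"),
    "e3": ("T", "C"),
    "e2": ("T", "T"),
}
_SITES_TO_HAP = {v: k for k, v in _HAP_TO_SITES.items()}


def haplotype_to_sites(hap: str) -> tuple[str, str]:
    """Map an epsilon haplotype to its (rs429358, rs7412) alleles."""
    return _HAP_TO_SITES[hap]


def sites_to_haplotype(rs429358_allele: str, rs7412_allele: str) -> str:
    """Inverse mapping; raises KeyError for the excluded epsilon1 combination."""
    return _SITES_TO_HAP[(rs429358_allele, rs7412_allele)]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator for a named pipeline stage.

    The child stream is seeded from (seed, crc32(stage)), so distinct stages
    are statistically independent while the whole run is reproducible from
    one integer.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass(frozen=True)
class PopulationSpec:
    """A named population with ground-truth epsilon-haplotype frequencies."""

    name: str
    f_e2: float
    f_e3: float
    f_e4: float
    n_individuals: int

    def __post_init__(self) -> None:
        freqs = (self.f_e2, self.f_e3, self.f_e4)
        if any(f < 0 or f > 1 for f in freqs):
            raise ValueError(f"{self.name}: haplotype frequencies must lie in [0,1]")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: haplotype frequencies must sum to 1")
        if self.n_individuals < 1:
            raise ValueError(f"{self.name}: n_individuals must be >= 1")

    @property
    def freq_vector(self) -> np.ndarray:
        return np.array([self.f_e2, self.f_e3, self.f_e4])


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two parents plus mixing proportions for an admixed offspring cohort."""

    parent_a: PopulationSpec
    parent_b: PopulationSpec
    k_a: float
    k_b: float
    n_offspring: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_a <= 1 and 0 <= self.k_b <= 1):
            raise ValueError("mixing proportions must lie in [0,1]")
        if abs(self.k_a + self.k_b - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")


@dataclass(frozen=True)
class SequencingModel:
    """Pileup-level sequencing/damage model.

    mean_depth
        Poisson mean of per-site read depth.
    base_error
        probability a read reports the other segregating allele.
    deamination_rate
        probability of a C->T flip at a terminal read position.
    damaged_terminal_len
        number of read-end positions subject to deamination.
    read_len
        read length used to convert damaged_terminal_len into the chance that
        a covered site sits in a terminal position.
    """

    mean_depth: float = 5.0
    base_error: float = 0.005
    deamination_rate: float = 0.15
    damaged_terminal_len: int = 2
    read_len: int = 60

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for p in (self.base_error, self.deamination_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if self.damaged_terminal_len < 0:
            raise ValueError("damaged_terminal_len must be non-negative")
        if self.read_len < 1:
            raise ValueError("read_len must be positive")

    @property
    def p_terminal(self) -> float:
        """Probability a covered site falls within the damaged terminal region."""
        return min(1.0, 2.0 * self.damaged_terminal_len / self.read_len)


@dataclass(frozen=True)
class WindowSimSpec:
    """Neutral/sweep window simulation for the Tajima's D scan."""

    n_chromosomes: int = 20
    theta_w: float = 10.0
    window_len_bp: int = 15_000
    n_windows: int = 50
    sweep_windows: frozenset[int] = field(default_factory=frozenset)
    sweep_rare_skew: float = 3.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be an even integer >= 2")
        if self.theta_w < 0:
            raise ValueError("theta_w must be non-negative")
        if self.window_len_bp < 1 or self.n_windows < 1:
            raise ValueError("window dimensions must be positive")
        if not set(self.sweep_windows) <= set(range(self.n_windows)):
            raise ValueError("sweep_windows must index existing windows")
        if self.sweep_rare_skew < 1:
            raise ValueError("sweep_rare_skew must be >= 1")


def draw_diploid_apoe(spec: PopulationSpec, seed: int | np.random.Generator) -> np.ndarray:
    """Draw phased two-haplotype APOE genotypes for every individual.

    Returns an (n_individuals, 2) array of haplotype labels from
    ``EPS_HAPLOTYPES``; each haplotype is i.i.d. from the spec frequencies.
    Phase (column order) is retained as ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, f"apoe:{spec.name}")
    idx = rng.choice(3, size=(spec.n_individuals, 2), p=spec.freq_vector)
    return np.array(EPS_HAPLOTYPES)[idx]


def draw_admixed_cohort(
    spec: AdmixtureSpec, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an admixed cohort: haplotypes plus per-individual realized ancestry.

    Each of the 2n haplotypes comes from parent A with probability ``k_a``,
    otherwise from parent B, so the expected population haplotype frequency is
    ``k_a*fA + k_b*fB``.  Returns ``(haplotypes, q_true)`` where ``q_true`` is
    each individual's realized fraction of parent-A haplotypes (0, 0.5 or 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "admixed-cohort")
    n = spec.n_offspring
    from_a = rng.random((n, 2)) < spec.k_a
    haps = np.empty((n, 2), dtype="<U2")
    for origin, parent in ((True, spec.parent_a), (False, spec.parent_b)):
        mask = from_a == origin
        idx = rng.choice(3, size=int(mask.sum()), p=parent.freq_vector)
        haps[mask] = np.array(EPS_HAPLOTYPES)[idx]
    return haps, from_a.mean(axis=1)


def cohort_site_genotypes(haplotypes: np.ndarray) -> dict[str, np.ndarray]:
    """Convert phased haplotypes to per-site allele pairs.

    Returns ``{site_id: (n, 2) array of allele characters}`` preserving phase.
    """
    out: dict[str, np.ndarray] = {}
    for col, site in enumerate((RS429358, RS7412)):
        alleles = np.vectorize(lambda h, c=col: _HAP_TO_SITES[h][c])(haplotypes)
        out[site] = alleles
    return out


def simulate_pileup(
    genotype: tuple[str, str],
    model: SequencingModel,
    seed: int | np.random.Generator,
    site_alleles: tuple[str, str] = ("T", "C"),
    site_id: str = "site",
):
    """Simulate a per-site pileup for one diploid genotype.

    Depth is Poisson(mean_depth).  Each read samples one of the two genotype
    alleles uniformly, is flipped to the other segregating allele with
    probability ``base_error``, and — if the read covers the site within the
    damaged terminal region — any C is flipped to T with ``deamination_rate``.
    Counts are annotated by distance-from-read-end (terminal bins) vs interior.
    """
    from .genotyping import SitePileup

    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, f"pileup:{site_id}")
    depth = int(rng.poisson(model.mean_depth))
    n_bins = max(model.damaged_terminal_len, 1)
    counts: dict[str, np.ndarray] = {}

    other = {site_alleles[0]: site_alleles[1], site_alleles[1]: site_alleles[0]}
    for _ in range(depth):
        base = genotype[int(rng.integers(2))]
        if rng.random() < model.base_error:
            base = other.get(base, base)
        if model.damaged_terminal_len > 0 and rng.random() < model.p_terminal:
            dist = int(rng.integers(model.damaged_terminal_len))
            if base == "C" and rng.random() < model.deamination_rate:
                base = "T"
        else:
            dist = n_bins  # interior bin
        arr = counts.setdefault(base, np.zeros(n_bins + 1, dtype=int))
        arr[dist] += 1
    return SitePileup(site_id=site_id, counts=counts, terminal_bins=n_bins)


@dataclass(frozen=True)
class SnpPanelSim:
    """Ground truth for a simulated unlinked SNP panel."""

    ancestral_freq: np.ndarray
    freq_a: np.ndarray
    freq_b: np.ndarray
    ref_genotypes_a: np.ndarray  # (n_ref, n_sites) alt-allele dosages 0/1/2
    ref_genotypes_b: np.ndarray


def simulate_snp_panel(
    n_sites: int,
    fst_divergence: float,
    seed: int | np.random.Generator,
    n_ref_per_parent: int = 20,
) -> SnpPanelSim:
    """Simulate parental allele frequencies and reference genotypes.

    Ancestral frequencies are uniform(0.05, 0.95); each parent's frequency is
    an independent Balding-Nichols draw, Beta(p(1-F)/F, (1-p)(1-F)/F), around
    the ancestral value with divergence parameter F, which makes the realized
    Hudson-style FST between the parents approximately F.  Sites are unlinked
    (the real pipeline expects an LD-pruned panel).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0 < fst_divergence < 1:
        raise ValueError("fst_divergence must lie in (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "snp-panel")
    p = rng.uniform(0.05, 0.95, size=n_sites)
    scale = (1 - fst_divergence) / fst_divergence
    freq_a = rng.beta(p * scale, (1 - p) * scale)
    freq_b = rng.beta(p * scale, (1 - p) * scale)
    # keep frequencies polymorphic enough for genotype likelihoods
    freq_a = np.clip(freq_a, 1e-6, 1 - 1e-6)
    freq_b = np.clip(freq_b, 1e-6, 1 - 1e-6)
    ga = rng.binomial(2, freq_a, size=(n_ref_per_parent, n_sites))
    gb = rng.binomial(2, freq_b, size=(n_ref_per_parent, n_sites))
    return SnpPanelSim(p, freq_a, freq_b, ga, gb)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class SimWindow:
    """One simulated window of segregating sites."""

    index: int
    start: int
    positions: np.ndarray      # bp positions within the chromosome
    derived_counts: np.ndarray  # derived-allele count per site, in 1..n-1
    is_sweep: bool


def simulate_windows(spec: WindowSimSpec, seed: int | np.random.Generator) -> list[SimWindow]:
    """Simulate per-window segregating sites for the Tajima's D scan.

    Neutral windows draw S ~ Poisson(theta_w * a1(n)) segregating sites with
    derived-allele counts i proportional to 1/i (the standard neutral
    frequency spectrum).  Sweep windows skew the spectrum toward rare variants
    (probability proportional to i**-sweep_rare_skew) and reduce the expected
    number of segregating sites by the same skew factor, mimicking the loss of
    diversity and rare-variant excess after a selective sweep.
    """
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "windows")
    n = spec.n_chromosomes
    a1 = _harmonic(n)
    i = np.arange(1, n)
    p_neutral = (1.0 / i) / np.sum(1.0 / i)
    p_sweep = i ** (-spec.sweep_rare_skew) / np.sum(i ** (-spec.sweep_rare_skew))

    windows = []
    for w in range(spec.n_windows):
        sweep = w in spec.sweep_windows
        mean_s = spec.theta_w * a1 / (spec.sweep_rare_skew if sweep else 1.0)
        s = int(rng.poisson(mean_s))
        start = w * spec.window_len_bp
        pos = np.sort(rng.integers(start, start + spec.window_len_bp, size=s))
        counts = rng.choice(i, size=s, p=p_sweep if sweep else p_neutral)
        windows.append(SimWindow(w, start, pos, counts, sweep))
    return windows
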