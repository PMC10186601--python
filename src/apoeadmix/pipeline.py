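"""End-to-end orchestration of the synthetic five-population analysis.

The default scenario mirrors the European demographic chain the method was
designed around: two deeply diverged parental populations (a hunter-gatherer
-like group that completely lacks epsilon2 but is epsilon4-rich, and an
early-farmer-like group that is epsilon3-rich), a first-step admixed
population (late farmers, 0.18/0.82 mixing), a steppe-like third parent and
a second-step admixed population.  Stages:

    simulate -> genotype -> freq -> admix -> expect -> scan

Each stage derives its own RNG stream from the run seed, writes standard
TSV/VCF outputs, and the run closes with a manifest of SHA-256 checksums so
identical (config, seed) pairs are verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .admixture import SnpPanel, bootstrap_q, estimate_parental_freqs, population_components
from .expectation import DemographicStep, chain_expectations, deviation_tests
from .frequencies import (
    ALLELES,
    count_epsilon,
    frequency_estimates,
    pairwise_frequency_tests,
)
from .genotyping import (
    SampleScanQC,
    apply_trim,
    call_genotype,
    decide_trim,
    sample_passes_apoe_filter,
    sample_passes_scan_qc,
)
from .scan import PopSiteCounts, fst_background, wc_fst_site, windowed_scan
from .synthetic import (
    RS7412,
    RS429358,
    SITE_ALLELES,
    AdmixtureSpec,
    PopulationSpec,
    SequencingModel,
    WindowSimSpec,
    cohort_site_genotypes,
    draw_admixed_cohort,
    draw_diploid_apoe,
    simulate_pileup,
    simulate_snp_panel,
    stage_rng,
)
from .vcfio import write_tsv, write_vcf

log = logging.getLogger(__name__)

STAGES = ("simulate", "genotype", "freq", "admix", "expect", "scan")

# VCF coordinates for the two focal sites (GRCh37 chr19, conventional).
FOCAL_SITES = ((45411941, RS429358), (45412079, RS7412))


@dataclass
class ScenarioStep:
    offspring: str
    parent_a: str
    parent_b: str
    k_a: float  # ground-truth mixing proportion of parent A


@dataclass
class RunConfig:
    """Declarative configuration collecting every pipeline constant."""

    seed: int = 0
    outdir: str = "apoeadmix_run"
    stages: tuple[str, ...] = STAGES

    # genotype filters
    min_depth: int = 3
    allow_low_depth: bool = False
    qual_min: float = 50.0
    cov_min: float = 0.70
    depth_min: float = 5.0
    deamination_threshold: float = 0.05

    # statistics
    ci_level: float = 0.90
    fdr_q: float = 0.05
    window_len: int = 15_000

    # sequencing model
    mean_depth: float = 8.0
    base_error: float = 0.005
    deamination_rate: float = 0.15
    damaged_terminal_len: int = 2

    # scenario: parental populations (name -> (f_e2, f_e3, f_e4, n))
    populations: dict[str, tuple[float, float, float, int]] = field(
        default_factory=lambda: {
            "WHG": (0.00, 0.60, 0.40, 40),
            "EF": (0.08, 0.87, 0.05, 60),
            "Steppe": (0.06, 0.72, 0.22, 50),
        }
    )
    chain: list[ScenarioStep] = field(
        default_factory=lambda: [
            ScenarioStep("LF", "WHG", "EF", 0.18),
            ScenarioStep("Modern", "Steppe", "LF", 0.45),
        ]
    )
    offspring_n: dict[str, int] = field(default_factory=lambda: {"LF": 60, "Modern": 80})

    # admixture panel
    panel_sites: int = 2_000
    panel_divergence: float = 0.10
    panel_ref_n: int = 100
    bootstrap_reps: int = 100

    # selection scan
    scan_n_chromosomes: int = 20
    scan_theta_w: float = 10.0
    scan_n_windows: int = 100
    scan_focal_windows: tuple[int, ...] = (45, 46, 47)
    sweep_at_locus: bool = True
    sweep_rare_skew: float = 3.0
    scan_background_sites: int = 1_000
    scan_pop_pair: tuple[str, str] = ("WHG", "EF")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "chain" in raw:
            raw["chain"] = [ScenarioStep(**s) for s in raw["chain"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["chain"] = [dataclasses.asdict(s) for s in self.chain]
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of invariant violations (empty iff the config is valid)."""
    v: list[str] = []
    if config.min_depth < 3 and not config.allow_low_depth:
        v.append("min_depth: below the default minimum of 3 requires allow_low_depth")
    if config.min_depth < 1:
        v.append("min_depth: must be >= 1")
    if not 0 < config.ci_level < 1:
        v.append("ci_level: must lie in (0,1)")
    if not 0 < config.fdr_q < 1:
        v.append("fdr_q: must lie in (0,1)")
    if config.window_len < 1:
        v.append("window_len: must be positive")
    if not 0 <= config.cov_min <= 1:
        v.append("cov_min: must lie in [0,1]")
    if config.depth_min < 0:
        v.append("depth_min: must be non-negative")
    if not 0 <= config.deamination_threshold <= 1:
        v.append("deamination_threshold: must lie in [0,1]")
    if config.qual_min < 0:
        v.append("qual_min: must be non-negative")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        v.append(f"stages: unknown stage(s) {sorted(unknown)}")
    defined = set(config.populations)
    for step in config.chain:
        if step.offspring in defined:
            v.append(f"chain: offspring '{step.offspring}' already defined (cycle)")
        for parent in (step.parent_a, step.parent_b):
            if parent not in defined:
                v.append(f"chain: parent '{parent}' of '{step.offspring}' not yet defined")
        if not 0 <= step.k_a <= 1:
            v.append(f"chain: k_a of '{step.offspring}' outside [0,1]")
        defined.add(step.offspring)
    return v


@dataclass
class RunResult:
    outputs: dict[str, Path]
    manifest: dict[str, Any]
    manifest_path: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_stage(config: RunConfig, state: dict) -> None:
    """Draw all cohorts, their pileups, and the ground-truth tables."""
    model = SequencingModel(
        mean_depth=config.mean_depth,
        base_error=config.base_error,
        deamination_rate=config.deamination_rate,
        damaged_terminal_len=config.damaged_terminal_len,
    )
    specs: dict[str, PopulationSpec] = {
        name: PopulationSpec(name, f2, f3, f4, n)
        for name, (f2, f3, f4, n) in config.populations.items()
    }
    haplotypes: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        haplotypes[name] = draw_diploid_apoe(spec, stage_rng(config.seed, f"simulate:{name}"))

    # admixed cohorts, in chain order; offspring haplotype frequencies feed
    # later steps through their realized draws
    realized: dict[str, PopulationSpec] = dict(specs)
    for step in config.chain:
        n_off = config.offspring_n.get(step.offspring, 50)
        spec = AdmixtureSpec(
            realized[step.parent_a], realized[step.parent_b], step.k_a, 1 - step.k_a, n_off
        )
        haps, _ = draw_admixed_cohort(spec, stage_rng(config.seed, f"simulate:{step.offspring}"))
        haplotypes[step.offspring] = haps
        f = np.array([(haps == h).mean() for h in ("e2", "e3", "e4")])
        f = f / f.sum()
        realized[step.offspring] = PopulationSpec(step.offspring, *f, n_off)

    pileups: dict[str, dict[str, Any]] = {}
    samples: list[tuple[str, str]] = []
    truth_rows = []
    for name, haps in haplotypes.items():
        site_geno = cohort_site_genotypes(haps)
        for i in range(len(haps)):
            sample = f"{name}_{i:03d}"
            samples.append((sample, name))
            rng = stage_rng(config.seed, f"pileup:{sample}")
            pileups[sample] = {
                site: simulate_pileup(
                    tuple(site_geno[site][i]), model, rng,
                    site_alleles=SITE_ALLELES[site], site_id=site,
                )
                for site in (RS429358, RS7412)
            }
            truth_rows.append((sample, name, haps[i, 0], haps[i, 1]))

    outdir = state["outdir"]
    pop_tsv = write_tsv(
        outdir / "populations.tsv",
        pd.DataFrame(samples, columns=["sample", "population"]),
    )
    truth_tsv = write_tsv(
        outdir / "truth.tsv",
        pd.DataFrame(truth_rows, columns=["sample", "population", "hap1", "hap2"]),
    )
    state.update(pileups=pileups, samples=samples, haplotypes=haplotypes, model=model)
    state["outputs"].update({"populations_tsv": pop_tsv, "truth_tsv": truth_tsv})


def _estimate_terminal_rates(pileups: dict, terminal_bins: int) -> np.ndarray:
    """Estimate per-distance terminal C->T rates pooled across all pileups.

    Deamination converts terminal C reads to T, so the per-distance rate is
    estimated as the excess T fraction at that distance over the interior,
    scaled by the interior C fraction.
    """
    t = np.zeros(terminal_bins + 1)
    c = np.zeros(terminal_bins + 1)
    for per_site in pileups.values():
        for pile in per_site.values():
            for base, arr in pile.counts.items():
                if base == "T":
                    t += arr
                elif base == "C":
                    c += arr
    tot = t + c
    with np.errstate(invalid="ignore", divide="ignore"):
        f_t = np.where(tot > 0, t / tot, 0.0)
    f_t_int, f_c_int = f_t[-1], np.where(tot[-1] > 0, c[-1] / tot[-1], 0.5)
    if f_c_int <= 0:
        return np.zeros(terminal_bins)
    return np.clip((f_t[:-1] - f_t_int) / f_c_int, 0.0, 1.0)


def _genotype_stage(config: RunConfig, state: dict) -> None:
    pileups = state["pileups"]
    model = state["model"]
    rates = _estimate_terminal_rates(pileups, model.damaged_terminal_len or 1)
    m = decide_trim(rates, config.deamination_threshold)
    log.info("trimming %d terminal position(s); estimated rates %s", m, np.round(rates, 3))

    calls: dict[str, dict[str, Any]] = {}
    kept, dropped = [], []
    for sample, _pop in state["samples"]:
        per_site = {}
        for site in (RS429358, RS7412):
            pile = apply_trim(pileups[sample][site], m)
            per_site[site] = call_genotype(pile, config.base_error, config.min_depth)
        if sample_passes_apoe_filter([per_site[RS429358], per_site[RS7412]]):
            calls[sample] = per_site
            kept.append(sample)
        else:
            dropped.append(sample)

    sites = [(pos, sid, *SITE_ALLELES[sid]) for pos, sid in FOCAL_SITES]
    genotypes = {
        sid: [
            (
                (calls[s][sid].alleles, calls[s][sid].depth, calls[s][sid].qual)
                if s in calls
                else (None, pileups[s][sid].depth, 0.0)
            )
            for s in [smp for smp, _ in state["samples"]]
        ]
        for _, sid in FOCAL_SITES
    }
    all_samples = [smp for smp, _ in state["samples"]]
    vcf_path = write_vcf(state["outdir"] / "apoe_calls.vcf", "19", sites, all_samples, genotypes)
    drop_path = write_tsv(
        state["outdir"] / "dropped_samples.tsv",
        pd.DataFrame({"sample": dropped, "reason": ["missing_both_sites"] * len(dropped)}),
    )
    state.update(calls=calls, trim_m=m)
    state["outputs"].update({"apoe_vcf": vcf_path, "drop_log": drop_path})


def _freq_stage(config: RunConfig, state: dict) -> None:
    pop_of = dict(state["samples"])
    by_pop: dict[str, list] = {}
    for sample, per_site in state["calls"].items():
        by_pop.setdefault(pop_of[sample], []).append((per_site[RS429358], per_site[RS7412]))

    counts = {pop: count_epsilon(pairs, pop) for pop, pairs in sorted(by_pop.items())}
    count_rows = [dataclasses.asdict(c) for c in counts.values()]
    est_rows = [
        dataclasses.asdict(e)
        for c in counts.values()
        for e in frequency_estimates(c, config.ci_level)
    ]
    tests = pairwise_frequency_tests(list(counts.values()), config.fdr_q)
    test_rows = [dataclasses.asdict(t) for t in tests]

    out = state["outputs"]
    out["epsilon_counts_tsv"] = write_tsv(
        state["outdir"] / "epsilon_counts.tsv", pd.DataFrame(count_rows)
    )
    out["frequencies_tsv"] = write_tsv(
        state["outdir"] / "frequencies.tsv", pd.DataFrame(est_rows)
    )
    out["pairwise_tests_tsv"] = write_tsv(
        state["outdir"] / "pairwise_tests.tsv", pd.DataFrame(test_rows)
    )
    state["counts"] = counts


def _admix_stage(config: RunConfig, state: dict) -> None:
    """Per-step supervised ancestry against simulated unlinked panels."""
    rows = []
    components: dict[str, tuple[float, float]] = {}
    for step in config.chain:
        rng = stage_rng(config.seed, f"admix:{step.offspring}")
        panel_sim = simulate_snp_panel(
            config.panel_sites, config.panel_divergence, rng,
            n_ref_per_parent=config.panel_ref_n,
        )
        fa, _ = estimate_parental_freqs(panel_sim.ref_genotypes_a)
        fb, _ = estimate_parental_freqs(panel_sim.ref_genotypes_b)
        panel = SnpPanel(np.arange(len(fa)), fa, fb)

        n_off = config.offspring_n.get(step.offspring, 50)
        origin = rng.random((n_off, 2, config.panel_sites)) < step.k_a
        p = np.where(origin, panel_sim.freq_a, panel_sim.freq_b)
        genotypes = (rng.random(p.shape) < p).sum(axis=1)  # (n_off, n_sites) dosages

        estimates = [
            bootstrap_q(
                genotypes[i], panel, B=config.bootstrap_reps,
                seed=stage_rng(config.seed, f"admix-boot:{step.offspring}:{i}"),
                individual=f"{step.offspring}_{i:03d}",
            )
            for i in range(n_off)
        ]
        k_a, k_b = population_components(estimates)
        components[step.offspring] = (k_a, k_b)
        rows += [
            {
                "population": step.offspring,
                "individual": e.individual,
                "q_hat": e.q_hat,
                "bootstrap_se": e.bootstrap_se,
                "n_sites": e.n_sites_used,
            }
            for e in estimates
        ]
    comp_rows = [
        {"population": pop, "parent_a": s.parent_a, "parent_b": s.parent_b,
         "k_a_hat": components[pop][0], "k_b_hat": components[pop][1], "k_a_true": s.k_a}
        for s, pop in ((s, s.offspring) for s in config.chain)
    ]
    out = state["outputs"]
    out["ancestry_tsv"] = write_tsv(state["outdir"] / "ancestry.tsv", pd.DataFrame(rows))
    out["components_tsv"] = write_tsv(
        state["outdir"] / "admixture_components.tsv", pd.DataFrame(comp_rows)
    )
    state["components"] = components


def _expect_stage(config: RunConfig, state: dict) -> None:
    counts = state["counts"]
    components = state.get("components", {})
    observed = {
        pop: {a: c.freq(a) for a in ALLELES if c.n(a) > 0} for pop, c in counts.items()
    }
    steps = []
    for s in config.chain:
        k_a = components.get(s.offspring, (s.k_a, 1 - s.k_a))[0]
        steps.append(DemographicStep(s.offspring, s.parent_a, s.parent_b, k_a, 1 - k_a))
    expectations = chain_expectations(steps, observed)
    count_map = {
        pop: {a: (c.x(a), c.n(a)) for a in ALLELES if c.n(a) > 0}
        for pop, c in counts.items()
    }
    tests = deviation_tests(expectations, count_map)
    rows = [dict(dataclasses.asdict(t), stars=t.stars) for t in tests]
    state["outputs"]["deviation_tests_tsv"] = write_tsv(
        state["outdir"] / "deviation_tests.tsv", pd.DataFrame(rows)
    )
    state["deviation_tests"] = tests


def _scan_stage(config: RunConfig, state: dict) -> None:
    rng = stage_rng(config.seed, "scan")

    # sample QC for the scan cohort (coverage fraction, local mean depth)
    qc_rows = []
    for sample, pop in state["samples"]:
        qc = SampleScanQC(
            chrom_coverage=float(np.clip(rng.beta(18, 2), 0, 1)),
            local_mean_depth=float(rng.gamma(4.0, 2.5)),
        )
        qc_rows.append(
            {"sample": sample, "population": pop, "chrom_coverage": qc.chrom_coverage,
             "local_mean_depth": qc.local_mean_depth,
             "pass": sample_passes_scan_qc(qc, config.cov_min, config.depth_min)}
        )
    qc_df = pd.DataFrame(qc_rows)

    # Tajima's D windows: neutral chromosome, optional sweep at the locus
    spec = WindowSimSpec(
        n_chromosomes=config.scan_n_chromosomes,
        theta_w=config.scan_theta_w,
        window_len_bp=config.window_len,
        n_windows=config.scan_n_windows,
        sweep_windows=frozenset(config.scan_focal_windows) if config.sweep_at_locus else frozenset(),
        sweep_rare_skew=config.sweep_rare_skew,
    )
    from .synthetic import simulate_windows

    sim = simulate_windows(spec, rng)
    positions = np.concatenate([w.positions for w in sim]) if sim else np.array([])
    alt = np.concatenate([w.derived_counts for w in sim]) if sim else np.array([])
    windows, summary = windowed_scan(
        positions, alt, config.scan_n_chromosomes, config.window_len,
        focal_windows=config.scan_focal_windows,
    )

    # per-site FST between the configured population pair: simulated neutral
    # background plus the two focal APOE sites from the called genotypes
    pop_a, pop_b = config.scan_pop_pair
    n_ind = {pop_a: 25, pop_b: 25}
    fst_sites = []
    for j in range(config.scan_background_sites):
        p = rng.uniform(0.05, 0.95)
        counts = {}
        for pop in (pop_a, pop_b):
            g = rng.binomial(2, p, size=n_ind[pop])
            counts[pop] = PopSiteCounts(int(g.sum()), 2 * n_ind[pop], int((g == 1).sum()))
        fst_sites.append(wc_fst_site(counts[pop_a], counts[pop_b], f"bg_{j:05d}"))

    pop_of = dict(state["samples"])
    for _pos, sid in FOCAL_SITES:
        counts = {}
        for pop in (pop_a, pop_b):
            alleles, het = [], 0
            for sample, per_site in state["calls"].items():
                if pop_of[sample] != pop or per_site[sid].is_missing:
                    continue
                pair = per_site[sid].alleles
                alleles += list(pair)
                het += pair[0] != pair[1]
            alt_allele = SITE_ALLELES[sid][1]
            counts[pop] = PopSiteCounts(
                sum(a == alt_allele for a in alleles), len(alleles), het
            )
        fst_sites.append(wc_fst_site(counts[pop_a], counts[pop_b], sid))

    thresholds, flags = fst_background(fst_sites, focal_ids=[sid for _, sid in FOCAL_SITES])

    out = state["outputs"]
    out["scan_qc_tsv"] = write_tsv(state["outdir"] / "scan_qc.tsv", qc_df)
    out["windows_tsv"] = write_tsv(
        state["outdir"] / "tajima_windows.tsv",
        pd.DataFrame([dataclasses.asdict(w) for w in windows]),
    )
    out["fst_tsv"] = write_tsv(
        state["outdir"] / "fst_sites.tsv",
        pd.DataFrame([dataclasses.asdict(s) for s in fst_sites]),
    )
    summary_rows = [
        {"metric": "locus_mean_D", "value": summary.locus_mean_d},
        {"metric": "locus_below_median", "value": summary.below_median},
        {"metric": "locus_below_p5", "value": summary.below_p5},
        {"metric": "locus_above_p95", "value": summary.above_p95},
    ]
    summary_rows += [
        {"metric": f"D_p{lv:g}", "value": val} for lv, val in summary.d_percentiles.items()
    ]
    summary_rows += [
        {"metric": f"FST_p{lv:g}", "value": val} for lv, val in thresholds.items()
    ]
    summary_rows += [
        {"metric": f"{sid}_above_p{lv:g}", "value": flag}
        for sid, by_level in flags.items()
        for lv, flag in by_level.items()
    ]
    out["scan_summary_tsv"] = write_tsv(
        state["outdir"] / "scan_summary.tsv", pd.DataFrame(summary_rows)
    )
    state["scan_summary"] = summary
    state["fst_flags"] = flags


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "genotype": _genotype_stage,
    "freq": _freq_stage,
    "admix": _admix_stage,
    "expect": _expect_stage,
    "scan": _scan_stage,
}


def run_all(config: RunConfig) -> RunResult:
    """Execute the configured stages and write a checksum manifest.

    Stage failures abort the run with the failing stage named; outputs
    produced so far are retained next to a FAILED marker file.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {"outdir": outdir, "outputs": {}}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    from . import __version__

    config_dict = config.to_dict()
    config_dict.pop("outdir")  # paths are not part of the scientific configuration
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in sorted(state["outputs"].items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(state["outputs"], manifest, manifest_path)
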