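"""Supervised ancestry estimation with bootstrap uncertainty.

With parental allele frequencies held fixed, each individual's ancestry
proportion q maximizes a concave binomial likelihood; a site bootstrap
(100 replicates) gives its standard error.
"""

import numpy as np

from apoeadmix import SnpPanel, bootstrap_q, population_components, simulate_snp_panel

rng = np.random.default_rng(7)
sim = simulate_snp_panel(n_sites=2000, fst_divergence=0.10, seed=rng)
panel = SnpPanel(np.arange(2000), sim.freq_a, sim.freq_b)

q_true = 0.18
estimates = []
for i in range(10):
    origin = rng.random((2, 2000)) < q_true
    p = np.where(origin, sim.freq_a, sim.freq_b)
    genotypes = (rng.random(p.shape) < p).sum(axis=0).astype(float)
    est = bootstrap_q(genotypes, panel, B=100, seed=rng, individual=f"ind{i}")
    estimates.append(est)
    print(f"{est.individual}: q_hat={est.q_hat:.3f} +/- {est.bootstrap_se:.3f}")

k_a, k_b = population_components(estimates)
print(f"population components: kA={k_a:.3f}, kB={k_b:.3f} (truth 0.18/0.82)")
# Individual estimates scatter around 0.18 with SEs near 0.02; the
# population mean recovers the simulated mixing proportions.
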