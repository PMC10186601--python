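"""Damage-aware diploid genotype calling from a simulated ancient pileup.

Terminal C->T deamination inflates T counts at read ends; the trim rule
masks terminal positions whose damage rate exceeds 5%, after which the
binomial-likelihood caller recovers the true genotype.
"""

from apoeadmix import (
    SequencingModel,
    apply_trim,
    call_genotype,
    decide_trim,
    simulate_pileup,
)

model = SequencingModel(mean_depth=15, base_error=0.002, deamination_rate=0.3,
                        damaged_terminal_len=2, read_len=20)
pileup = simulate_pileup(("C", "C"), model, seed=5, site_alleles=("C", "T"),
                         site_id="rs7412")
print("raw counts:", pileup.base_totals())

m = decide_trim([0.30, 0.30, 0.01], threshold=0.05)
trimmed = apply_trim(pileup, m)
print(f"trim {m} terminal positions -> counts: {trimmed.base_totals()}")

call = call_genotype(trimmed, base_error=0.002, min_depth=3)
print(f"call: {call.alleles}, depth={call.depth}, qual={call.qual:.1f}")
# The damage-derived T reads disappear after trimming and the C/C genotype is
# called with high confidence; depth < 3 would instead return MISSING.
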