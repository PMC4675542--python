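"""Single-variant carriage association on a simulated candidate-gene cohort.

Simulates a 325-case / 185-control cohort from the default study conditions,
tests dominant carriage of each allele and each recessive homozygote at every
locus, and prints the contrasts passing the reporting gates (Fisher p < 0.01
and a 95% OR confidence interval excluding 1).
"""

from epicombo import SignificanceGates, paper_like_config, simulate_cohort, single_variant_scan

dataset = simulate_cohort(paper_like_config(), seed=1)
print(f"cohort: {dataset.n_case} cases / {dataset.n_control} controls, "
      f"{len(dataset.loci)} loci\n")

gates = SignificanceGates()
print(f"{'element':<14} {'freq case':>9} {'freq ctrl':>9} {'OR':>6} {'95% CI':>14} {'p_f':>9}")
for rec in sorted(single_variant_scan(dataset, gates), key=lambda r: r.p_f):
    if not rec.significant(gates):
        continue
    o = rec.or_result
    print(f"{rec.pattern.label:<14} {rec.freq_case:>9.2f} {rec.freq_control:>9.2f} "
          f"{o.OR:>6.2f} {o.ci_low:>6.2f}-{o.ci_high:<6.2f} {rec.p_f:>9.2e}")

print("\nOR > 1 marks risk carriage, OR < 1 protective; the planted effects are"
      "\nthe recessive TGFB1 and CRP homozygotes, dominant FGB carriage, and the"
      "\ntwo weak-effect loci of the epistatic pair.")
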