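"""Phase a simulated block-structured population and score the result.

Simulates 200 diploid individuals over 100 SNP sites (blocks of 3-10 sites,
4 common haplotypes at 97% mass, 5% missing genotypes), runs the full
three-step pipeline, and compares its switch error rate with step 1 alone.
"""

from winhap import (
    BlockPoolSpec,
    evaluate,
    generate_population,
    phase_genotype_initial,
    run_winhap,
    switch_error_rate,
)

spec = BlockPoolSpec(missing_rate=0.05, seed=1)
G, truth = generate_population(spec, 200, total_sites=100)
print(f"simulated {G.n} individuals x {G.m} sites, "
      f"{(G.cells == -1).mean():.1%} missing cells")

step1 = phase_genotype_initial(G)
ser_step1, _, _ = switch_error_rate(step1, truth, include_missing=False, mask=G)

solution = run_winhap(G)
report = evaluate(solution, truth, G)

print(f"\nstep 1 only     SER1 = {ser_step1:.4f}")
print(f"full pipeline   SER1 = {report.ser1:.4f}   SER2 = {report.ser2:.4f}")
print(f"full pipeline   IER1 = {report.ier1:.4f}   IER2 = {report.ier2:.4f}")
# SER is switch errors per heterozygous locus (lower is better); IER is the
# fraction of individuals with any phasing mistake.  The window + parsimony
# stages typically cut the switch error rate several-fold relative to the
# adjacent-pair initialization.
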