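"""Single-recombination parsimony refinement, step by step.

Shows the suffix-exchange recombination operation on one haplotype pair and
the parsimony pass shrinking a small solution's distinct-haplotype set.
"""

from winhap import PhasingSolution, parsimony_refine, recombine_at

a, b = "11010010", "01100101"
na, nb = recombine_at(a, b, 3)  # switch at the 4th SNP site
print(f"({a}, {b}) switched at site 4 -> ({na}, {nb})")

sol = PhasingSolution.from_hap_strings(["01", "10", "00", "11"])
print(f"\nbefore refinement: {sol.distinct_haplotype_count()} distinct haplotypes")
moves = []
out = parsimony_refine(sol, record=moves)
for mv in moves:
    print(f"  accepted switch: individual {mv.individual}, "
          f"site {mv.site + 1}, distinct-count change {mv.delta}")
print(f"after refinement:  {out.distinct_haplotype_count()} distinct haplotypes")
print("rows:", out.to_strings())
# Exchanging the suffixes of individual 0's rows at site 2 turns {01,10}
# into {00,11}, which the other individual already carries: four distinct
# haplotypes collapse to two, the most parsimonious solution.
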