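"""Y-STR patriline consistency and the false-paternity exposure LR.

Five putative patrilinear relatives: four share a haplogroup and near-identical
STR haplotypes, one carries a different haplogroup — the signature of a
false-paternity event in its recorded line.  The remains' Y does not match the
patriline either; the evidence LR for that non-match is the probability that
at least one false paternity broke the 19 recorded father-son links.
"""

from kinlr.ystr import (
    FalsePaternityParams,
    StrPanel,
    YstrHaplotype,
    compare,
    false_paternity_prob,
    partition_patriline,
    y_lr,
)

panel = StrPanel(loci=("DYS19", "DYS390", "DYS391", "DYS385"),
                 multi_copy=frozenset({"DYS385"}))

core_alleles = {"DYS19": 14, "DYS390": 24, "DYS391": 11, "DYS385": (11, 14)}
relatives = [
    YstrHaplotype(panel, core_alleles, "R1b-U152", "relative_1"),
    YstrHaplotype(panel, core_alleles, "R1b-U152", "relative_2"),
    YstrHaplotype(panel, {**core_alleles, "DYS391": 12}, "R1b-U152", "relative_3"),
    YstrHaplotype(panel, core_alleles, "R1b-U152", "relative_4"),
    YstrHaplotype(panel, {"DYS19": 16, "DYS390": 22, "DYS391": 10, "DYS385": (13, 15)},
                  "I-M170", "relative_5"),
]

part = partition_patriline(relatives)
print(f"consistent patriline core: {sorted(part.core)}")
print(f"excluded (haplogroup discordant): {sorted(part.excluded)}")
# relative_5's clade I vs the modal R1b cannot arise by STR mutation: a
# false paternity occurred somewhere in its recorded descent.

result = compare(relatives[0], relatives[2])
print(f"relative_1 vs relative_3: {result.mismatch_count} mismatch at {result.mismatch_loci}"
      " (a single stepwise mutation, still consistent)")

params = FalsePaternityParams(r=0.009, m=19)
print(f"P(>=1 false paternity in {params.m} links at r={params.r}) = "
      f"{false_paternity_prob(params):.4f}")
print(f"evidence LR of the remains' Y non-match = {y_lr(params):.2f}")
# ~0.16: mild evidence against identification, because under H1 a
# false paternity MUST have occurred, and that is a priori unlikely.
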