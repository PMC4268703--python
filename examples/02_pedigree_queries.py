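"""Pedigree arithmetic: meioses, cousin terminology, matrilineal networks.

Builds a small genealogy by hand, then asks the questions the identification
framework needs: how many meioses separate two relatives on a uniparental
line (this exponent drives both the mtDNA no-mutation probability and the
false-paternity exposure), and who shares an inherited mtDNA type.
"""

from kinlr.pedigree import FEMALE, MALE, Individual, Pedigree, cousin_terms

# one ancestress, two daughter lines of depth 15 and 17
inds = [Individual("ancestress", FEMALE)]
for branch, depth in (("a", 15), ("b", 17)):
    prev = "ancestress"
    for i in range(1, depth + 1):
        inds.append(Individual(f"{branch}{i}", FEMALE, mother_id=prev))
        prev = f"{branch}{i}"
inds.append(Individual("son_of_b17", MALE, mother_id="b17"))
ped = Pedigree(inds)

m = ped.meioses_between("a15", "b17", "matrilineal")
terms = cousin_terms(15, 17)
print(f"a15 and b17 are {terms.degree}th cousins, {terms.removed}x removed")
print(f"meioses between them on the female line: {m}")
# 14th cousins twice removed correspond to 32 meioses: 15 transmissions up
# one branch plus 17 down the other.

network = ped.matrilineal_network("son_of_b17")
print(f"individuals sharing the ancestress's mtDNA type: {len(network)}")
# All 34 individuals descend from the same ancestress in the female line,
# so absent mutation they all carry her mtDNA; a male belongs to the network
# but does not pass the type on.
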