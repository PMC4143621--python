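"""Two-point LOD scores on a phase-known fully informative family.

Grandparents fix the phase of an affected father who is doubly heterozygous
under a fully penetrant dominant model, so every affected child carrying
the minor allele is an unambiguous nonrecombinant meiosis.  With n such
children the LOD at theta = 0 is exactly n * log10(2); one recombinant
child makes theta = 0 impossible (LOD -inf) and pushes the maximum
likelihood estimate of theta off zero.
"""

import math

from pedlod import TraitModel, maximize_theta, twopoint_lod
from pedlod.pedigree import Affection, Individual, Pedigree, Sex

A, U = Affection.AFFECTED, Affection.UNAFFECTED


def family(child_dosages):
    members = [
        Individual("GF", "P", sex=Sex.MALE, affection=A),
        Individual("GM", "P", sex=Sex.FEMALE, affection=U),
        Individual("FA", "P", "GF", "GM", sex=Sex.MALE, affection=A),
        Individual("MO", "P", sex=Sex.FEMALE, affection=U),
    ]
    dosages = {"GF": 2, "GM": 0, "FA": 1, "MO": 0}
    for k, d in enumerate(child_dosages):
        members.append(Individual(f"C{k}", "P", "FA", "MO", affection=A))
        dosages[f"C{k}"] = d
    return Pedigree("P", members), dosages


model = TraitModel.fully_penetrant_dominant(0.01)

ped, dosages = family([1, 1, 1, 1])
res = twopoint_lod(ped, dosages, 0.3, model, theta=0.0)
print(f"4 nonrecombinant children: LOD(0) = {res.total_lod:.4f} "
      f"(closed form 4*log10(2) = {4 * math.log10(2):.4f})")

ped, dosages = family([1, 1, 1, 0])
res = twopoint_lod(ped, dosages, 0.3, model, theta=0.0)
mx = maximize_theta(ped, dosages, 0.3, model)
print(f"1 obligate recombinant:   LOD(0) = {res.total_lod} "
      f"(impossible at theta=0)")
print(f"                          theta_hat = {mx.theta_hat:.3f}, "
      f"max LOD = {mx.max_lod:.4f}")

# A LOD of 3.3 is the classic genome-wide significance threshold; a single
# nuclear family needs ~11 nonrecombinant phase-known meioses to reach it.
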