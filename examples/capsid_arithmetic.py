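"""Icosahedral capsid stoichiometry, triangulation and tape-measure scaling.

All whole-virion counts follow from per-asymmetric-unit copy numbers
(x60), the triangulation number from the jelly-roll domain count
(two per major-capsid-protein chain, one per penton chain), and
tape-measure protein lengths for larger capsids from linear scaling of
the 473-residue reference span at 190 nm.
"""

from densitrace import (
    capsid_census,
    hk_candidates,
    symmetron_capsomer_count,
    t_number_from_chains,
    tape_measure_estimate,
    triangular_count,
)

totals = capsid_census()
print("whole-virion census (default per-AU table):")
print(f"  major capsid protein chains : {totals.mcp_chains}")
print(f"  penton chains               : {totals.penton_chains}")
print(f"  minor capsid protein chains : {totals.minor_total}")
print(f"  total polypeptides          : {totals.grand_total}")

T = t_number_from_chains(totals.mcp_chains, totals.penton_chains, 2, 1)
pairs = ", ".join(f"(h={p.h}, k={p.k})" + (" skew" if p.skew else "") for p in hk_candidates(T))
print(f"\ntriangulation number T = {T}; lattice vectors: {pairs}")

tri, penta = symmetron_capsomer_count()
print(f"capsomers per trisymmetron / pentasymmetron: {tri} / {penta}")
print(f"triangular array with 8 capsomers per edge: {triangular_count(8)} capsomers")

print("\ntape-measure protein length predictions (473 aa at 190 nm reference):")
for name, diam in (("~500 nm capsid", 500.0), ("~300 nm capsid", 300.0)):
    est = tape_measure_estimate(target_diameter_nm=diam, rounding=50)
    print(f"  {name}: ~{est.rounded} aa (unrounded {est.residues:.0f})")
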