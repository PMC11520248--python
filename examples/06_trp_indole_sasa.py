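"""Trp-indole solvent accessibility in three structural contexts.

Builds the synthetic Trp-pocket assembly (a Trp-bearing coiled-coil hairpin
flanked by neighbouring hairpin stacks) and compares the Shrake-Rupley SASA
of the nine indole-ring atoms in the full assembly, the isolated hairpin and
the lone Trp-bearing helix.  With a real structure, point
``AtomSet.from_pdb`` at the PDB file and select the chain/residue instead.
"""

import ureafold as uf
from ureafold.sasa import reference_indole_sasa

structure, sel = uf.build_synthetic_trp_pocket()
print(f"Synthetic assembly: {len(structure)} atoms, Trp at chain "
      f"{sel['chain']} residue {sel['residue']}")

kw = dict(coiled_coil_range=sel["coiled_coil_range"], helix_range=sel["helix_range"])
barrel = uf.trp_indole_sasa(structure, sel["chain"], sel["residue"], "full_assembly", **kw)
cc = uf.trp_indole_sasa(structure, sel["chain"], sel["residue"], "coiled_coil_chain", **kw)
helix = uf.trp_indole_sasa(structure, sel["chain"], sel["residue"], "single_helix", **kw)

print(f"  full assembly       : {barrel:6.1f} A^2")
print(f"  coiled-coil hairpin : {cc:6.1f} A^2  (+{100 * (cc / barrel - 1):.0f}%)")
print(f"  single helix        : {helix:6.1f} A^2  (+{100 * (helix / barrel - 1):.0f}%)")
print(f"  free indole ceiling : {reference_indole_sasa():6.1f} A^2")
# Disassembling the pocket while the coiled-coil stays intact exposes the
# indole only modestly; unwinding the hairpin more than doubles its surface.
# That asymmetry is why the Trp emission red-shift tracks coiled-coil
# unwinding rather than assembly disassembly.
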