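"""Global three-state fit of a simulated urea titration.

Generates a noisy (scattering, fluorescence, CD) triplet at the default
study conditions, fits the shared-parameter three-state model with the
native fraction pinned to the normalized scattering, and tabulates the
species-fraction curves.
"""

import numpy as np

import ureafold as uf
from ureafold.synth import generate_normalized_dataset

cfg = uf.default_config(seed=1, noise=True)
S, F, D, truth = generate_normalized_dataset(cfg)

result = uf.fit_three_state(F, D, S)
p = result.param_dict()
se = result.standard_errors

print("Global three-state fit (fluorescence + CD, fN from scattering)")
print(f"  c50 = {p['c50']:.3f} +/- {se['c50']:.3f} M   (truth {truth['c50']})")
print(f"  d   = {p['d']:.3f} +/- {se['d']:.3f} M   (truth {truth['d']})")
print(f"  a   = {p['a']:.3f} +/- {se['a']:.3f}     (truth {truth['a']})")
print(f"  b   = {p['b']:.3f} +/- {se['b']:.3f}     (truth {truth['b']})")

m, dg = uf.delta_g_water(uf.LEMParams(p["c50"], p["d"]))
print(f"  LEM slope m = {m/1000:.2f} kJ/mol/M; dG(H2O) = {dg/1000:.1f} kJ/mol")
# c50 is the urea concentration where intermediate and unfolded monomers are
# equally populated; a and b say how much of the fluorescence (CD) contrast
# the intermediate already shows.

table = uf.species_fraction_curves(result, S, np.arange(0, 7.01, 0.25))
peak = table.loc[table["fI"].idxmax()]
print(f"\nIntermediate fraction peaks at {peak['urea_M']:.2f} M urea "
      f"({100 * peak['fI']:.0f}% of all protein).")
print("Species fractions every 1 M urea:")
print(table[table["urea_M"] % 1 == 0].to_string(index=False,
      float_format=lambda x: f"{x:.3f}"))

# the nested model with b = 0 (intermediate spectroscopically identical to
# the ring-embedded monomer) fits systematically worse:
fixed = uf.fit_three_state(F, D, S, fix_b_zero=True)
print(f"\nResidual sum of squares: free b {result.residual_ss:.4f} "
      f"vs b = 0 {fixed.residual_ss:.4f} "
      f"({fixed.residual_ss / result.residual_ss:.1f}x worse)")
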