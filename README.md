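# ureafold

Analysis of urea-induced disassembly and unfolding of oligomeric, mainly
α-helical proteins — the experimental archetype being an ESCRT-III-family
protein that self-assembles into large barrel-shaped oligomers.  The package
covers the full chain from raw spectra to thermodynamic parameters:

* **Signal extraction** from fluorescence emission, far-UV CD and static
  light-scattering spectra: ±5 nm moving average, I₃₃₅, λ_max, θ₂₂₂/θ₂₀₈,
  the 222/208 coiled-coil ratio, Rayleigh scattering at 300 ± 5 nm,
  replicate averaging and plateau normalization.
* **A three-state equilibrium model** — native oligomer (N) ⇌ folded-core
  intermediate (I) ⇌ unfolded monomer (U) — with the I ⇌ U equilibrium
  parameterized by the linear extrapolation model (LEM) and the native
  fraction read directly from normalized scattering, so oligomer disassembly
  never has to be modelled thermodynamically.
* **Global shared-parameter fitting** (Levenberg–Marquardt) of the
  fluorescence and CD titrations simultaneously, two-state fits for
  non-assembling constructs, a nested b = 0 variant, and a brute-force
  grid-search reference path for validating the optimizer.
* **Dihedral helicity statistics** for coarse-grained trajectories (the
  φ ∈ (−160°, −20°), ψ ∈ (−120°, 50°) window with the triplet α-helix rule),
  the backbone H-bond 12-10 potential with the λ ≤ 1 denaturation prefactor,
  and a desk-scale cooperative helix–coil model (exact transfer matrix +
  Metropolis sampler) for trend-level melting studies.
* **Shrake–Rupley SASA** with the Trp-indole burial comparison across
  nested structural contexts (assembly / coiled-coil hairpin / lone helix).
* **A seeded synthetic-data generator** that emulates the statistical
  structure of the titration experiments, so the whole pipeline is testable
  without any instrument data.

## The model

The fraction of protein still in the native assembly is taken from the
normalized scattering signal, f_N = S_norm.  The remaining protein splits
between intermediate and unfolded according to

    K(U) = [U]/[I] = exp(−(c50 − U)/d),      d = RT/m,  c50 = ΔG°_H₂O / m,

where U is the urea concentration, c50 the midpoint (K = 1) and m the LEM
slope of ΔG° versus denaturant.  With f_I = (1 − f_N)/(1 + K) and
f_U = K·f_I, the normalized probe signals are

    F_norm = f_N + a·f_I          a = (F_I − F_U)/(F_N − F_U)
    D_norm = b·f_I + f_U          b = (D_I − D_N)/(D_U − D_N)

and (c50, d, a, b) are fitted to both curves simultaneously.  The contrast
ratios a and b measure how much of the total fluorescence (CD) change has
already happened in the intermediate; b = 0 is the testable null that the
intermediate's secondary structure is indistinguishable from the
ring-embedded monomer.

## Worked example

`python examples/01_global_three_state_fit.py` simulates a noisy titration
(0–7 M urea, 0.5 M steps, 3 replicates) and fits it globally:

```
Global three-state fit (fluorescence + CD, fN from scattering)
  c50 = 2.981 +/- 0.058 M   (truth 3.0)
  d   = 0.426 +/- 0.038 M   (truth 0.45)
  a   = 0.799 +/- 0.037     (truth 0.81)
  b   = 0.237 +/- 0.036     (truth 0.24)
  LEM slope m = 5.73 kJ/mol/M; dG(H2O) = 17.1 kJ/mol

Intermediate fraction peaks at 2.25 M urea (55% of all protein).
...
Residual sum of squares: free b 0.0164 vs b = 0 0.0326 (2.0x worse)
```

The fitted midpoint and contrasts recover the generating truth within their
standard errors; the intermediate — a monomer that has left the assembly but
kept its folded core — transiently holds more than half of the protein near
2.3 M urea; and forcing b = 0 visibly degrades the fit, showing that the
intermediate's secondary structure differs from the assembled state.  The
other examples demonstrate spectra preprocessing (`02`), two-state fits
(`03`), dihedral helicity statistics (`04`), helix–coil melting scans (`05`)
and the Trp-indole SASA comparison (`06`).

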