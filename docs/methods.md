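# Methods

## The three-state denaturation model

The system is an oligomeric protein whose denaturation proceeds in two
separable steps: disassembly of the large native oligomer (N) into a
folded-core monomeric intermediate (I), followed by unfolding of the
intermediate (U).  Because the oligomer population is heterogeneous (rings
of several sizes, stacks, tubes), disassembly is a cascade of overlapping
equilibria with no single well-defined transition; modelling it explicitly
would require assumptions the data cannot support.  The model therefore
*measures* the native fraction instead: large assemblies dominate static
light scattering, and the intermediate and unfolded monomers scatter
indistinguishably, so f_N equals the normalized scattering signal,
S_norm = (S − S_IU)/(S_N − S_IU).  Only the I ⇌ U step carries
thermodynamics:

    K = [U]/[I] = exp(−ΔG°/RT),   ΔG° = ΔG°_H₂O − m·[urea]   (LEM)

re-parameterized as K = exp(−(c50 − U)/d) with c50 = ΔG°_H₂O/m and
d = RT/m.  The (c50, d) form is preferred over (ΔG°_H₂O, m) because the two
parameters are nearly uncorrelated in a fit (midpoint and width of the
transition), while ΔG°_H₂O and m are strongly anti-correlated;
`delta_g_water` converts back.  Default temperature is 293.15 K, the
measurement temperature of the titrations.

Normalized fluorescence and CD signals are linear in the species
fractions (F_norm = f_N + a·f_I, D_norm = b·f_I + f_U).  Conventions:
F_norm is 1 for fully native and 0 for unfolded; D_norm is 0 for native and
1 for unfolded.  Raw CD titrations (θ₂₂₂ becoming less negative on
unfolding) therefore map onto D_norm as 1 − normalized θ₂₂₂.  The contrast
ratios a, b are constrained to [0, 1] during fitting: both compare the
intermediate's specific signal to the two states that bracket it, so values
outside the unit interval would mean a non-monotonic probe, which none of
the probes here is.

Numerics: K is evaluated in log space and the fraction splits
f_U/(f_I+f_U) = K/(1+K) through a stable logistic, so concentrations far
above the midpoint cannot overflow.  f_N values interpolated from noisy
scattering are clipped to [0, 1] before entering the model.

## Global fitting

`fit_three_state` concatenates the fluorescence and CD residuals into one
vector and minimizes it with Levenberg–Marquardt (lmfit), all four
parameters shared between the probes.  Design choices, each genuinely open:

* **Weighting** — equal weight per point by default; the replicate SDs of
  the two probes are similar after normalization, and SD-based weights from
  3 replicates are themselves noisy.  `weights="inverse_sd"` is available.
* **Initialization** — c50 from the urea at half-amplitude of the CD curve,
  d = 0.5 M, a = 0.8, b = 0.2; plus four additional log-normally jittered
  starts (seeded), keeping the best-residual solution.  The objective is
  nearly unimodal in practice; the multi-start is cheap insurance.
* **Uncertainties** — standard errors from the Jacobian-based covariance at
  the optimum scaled by reduced χ²; in the Monte Carlo study the implied
  1.96·SE intervals cover the true c50 at close to nominal rate (≈ 90–93%).
* **Scattering interpolation** — f_N at probe concentrations is linear
  interpolation of the normalized scattering; extrapolation outside the
  measured range is refused rather than guessed.
* **Degenerate inputs** — flat curves (span < 1e−8) and grids with fewer
  than 6 concentrations are rejected up front; a fitted midpoint outside
  the measured urea range sets a warning flag (the midpoint is then not
  identified by the data).

The nested variant `fix_b_zero=True` pins b = 0 and drops it from the free
set; by construction its residual sum can never undercut the free fit, and
on data generated with b > 0 it leaves one-sided CD residuals at low urea —
the signature used to argue that the intermediate's secondary structure
really differs from the assembled monomer.

`grid_search_three_state` is a deliberately brute-force reference: (c50, d)
scanned at 0.01-step resolution, and at each node the optimum over the
0.01-gridded (a, b) obtained exactly from the closed-form linear-least-squares
minimizer (the objective is quadratic in a and b separately, so rounding the
clipped continuous optimum to its two neighbouring grid values and keeping
the better one *is* the grid optimum).  This makes a full 4-D scan's answer
affordable and gives the optimizer an independent cross-check.

## Synthetic data

The generator defines the study conditions used throughout the tests:

* urea grid 0–7 M in 0.5 M steps; 3 replicates; additive Gaussian noise
  with per-probe SD of 5% (scattering), 3% (fluorescence) and 4% (CD) of
  the respective signal span — the scale of typical triplicate error bars;
* scattering decaying linearly from S_N at 0 M to S_IU = S_N/6 at 3.5 M and
  constant beyond: the continuous, non-sigmoidal disassembly of a
  heterogeneous oligomer population;
* three-state truth c50 = 3.0 M, a = 0.81, b = 0.24.  The transition width
  d is not constrained by any published number; d = 0.45 M is chosen once so
  that the visible I → U transition spans roughly 2.5–4.5 M urea, matching
  the reported qualitative window, and is not revisited;
* emission spectra as mixtures of Gaussian bands at 335 nm (folded) and
  344 nm (unfolded); CD spectra as mixtures of a helix-like basis (double
  minimum at 208/222 nm, positive lobe near 192 nm) and a coil-like basis
  (single negative band near 200 nm).  Each pure-state basis is scaled so
  that the *smoothed* probe extraction returns exactly the state's scalar
  signal level; since smoothing and extraction are linear, preprocessing
  the spectra reproduces the scalar titrations exactly at zero noise —
  a closure property the tests assert.

Two dataset flavours exist: `generate_denaturation_dataset` (raw units,
normalized downstream like real data) and `generate_normalized_dataset`
(noiseless means are exactly the model curves, for round-trip tests at
optimizer precision).  What the generator does *not* emulate: instrument
drift, photobleaching, wavelength-correlated noise, urea-background
subtraction errors, concentration errors in the titration series.  Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to systematic instrument artefacts.

## Spectra preprocessing

Moving average with a ±5 nm boxcar; at the spectrum edges the window
truncates (shrinks) rather than padding, preserving endpoints without
fabricating data.  Probe extraction uses nearest-grid-point lookup (the
instruments record 1 nm grids; interpolation would blur the reported
on-grid wavelengths).  λ_max ties break toward the lower wavelength, making
red-shift series deterministic.  Plateau normalization defaults to pooling
measured points in [0, 0.5] M (native) and [6.5, 7] M (unfolded); the
intervals are configurable, and single-endpoint normalization is obtained
by degenerate intervals such as (0, 0).  Normalized values escaping [0, 1]
are kept but flagged, as are 222/208 ratios above 4.5 M urea, where urea
absorbance buries the 208 nm signal.  Kinetic traces normalize to 1 at 6 ms
(after the mixing artifact) and 0 at 100 s (before photobleaching matters);
no rate law is fitted.

## Helicity statistics

A residue is in *helical form* when φ ∈ (−160°, −20°) and
ψ ∈ (−120°, 50°); it is part of an *α-helix* when it and both sequence
neighbours are in helical form; its *propensity* is the fraction of frames
in which that holds.  Boundary values are treated as outside (open
intervals) — a measure-zero convention fixed for reproducibility.  Missing
dihedrals (termini, incomplete backbones, degenerate geometry) count as
non-helical rather than being dropped, keeping the propensity denominator
equal to the total frame count.  Angles are handled in degrees end-to-end
and wrapped to (−180°, 180°].  Region aggregation is an unweighted mean
over configurable 1-based residue ranges; the defaults split at residue
156/157, the boundary of the coiled-coil-containing N-terminal region.

The backbone H-bond potential V = λ·ε·[5(σ/r)¹² − 6(σ/r)¹⁰]·cos²θ_N·cos²θ_C
(zero for |θ| ≥ 90°) has its well exactly at r = σ with depth −λ·ε at
aligned angles; λ ≤ 1 uniformly weakens hydrogen bonds, the coarse-grained
surrogate for urea.

## Helix–coil model

An intentionally simple stand-in for full coarse-grained denaturation
simulations, and labelled as such: binary helix/coil residues with
propagation weight s per helical residue and nucleation penalty σ_nuc per
coil→helix boundary on a linear chain.  `mean_helicity_exact` computes the
mean helical fraction by transfer-matrix forward–backward marginals with
per-step renormalization (no overflow on long chains); a 2ⁿ enumeration
oracle validates it for n ≤ 12, and a seeded single-flip Metropolis sampler
(batch-means standard errors) provides the stochastic route.  The H-bond
coupling s(λ) = exp(λ·ε/kT − c0) uses one global offset c0 = λ_mid·ε_ref/kT
so that a reference region sits at s = 1 (half-maximal helicity) at a
configurable λ_mid; regions with deeper wells then melt at lower λ
automatically.  Only trend-level claims are meaningful here — helicity
decreasing with λ, stronger-ε regions melting later; the model makes no
quantitative claim about any real force field's propensities.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set; defaults probe
radius 1.4 Å, 960 points/atom, Bondi-type heavy-atom radii, hydrogens
excluded (cryo-EM models carry none).  Doubling the point count changes the
indole areas by < 1%.  The Trp-indole comparison sums the nine ring atoms'
areas in three nested contexts: the full structure, one chain's coiled-coil
residue range, and the Trp-bearing helix alone.  The exact residue windows
of each helix are structure-specific and therefore configuration, not code.

Because no experimental structure is bundled, the worked example runs on a
synthetic stand-in assembly (`build_synthetic_trp_pocket`): an idealized
Trp-bearing helix paired into an antiparallel hairpin, flanked by two
identical poly-alanine hairpins at hexagonal-packing offsets that close a
pocket around the indole.  Helix placement was chosen for clash-free
packing (no interatomic contact below ≈ 3.5 Å) with the indole occluded
from three sides; the resulting context areas and relative increases are
outputs of the geometry, and only the ordering and the
modest-versus-large-increase pattern are asserted.  For a real assembly,
read the PDB file with `AtomSet.from_pdb` and supply the chain, residue and
helix ranges.

## Problem sizes

Defaults used by the test suite and the acceptance script: 15-concentration
titrations with 3 replicates; 200 datasets in the Monte Carlo recovery
study; 50 datasets in the nested-model comparison; 9-concentration curves
for the optimizer-versus-grid cross-check; chains of 10–40 residues and
10⁴ Metropolis sweeps in the helix–coil checks; 633-atom assemblies at 960
sphere points for SASA.  These sizes give every statistical check
comfortable resolution while the whole suite runs in well under a minute.

## Known limitations

* f_N is identified with normalized scattering; any scattering
  contribution that is nonlinear in oligomer mass (size-dependent form
  factors) biases the inferred fractions.
* The LEM linearity of ΔG° in urea is assumed, not tested, over 0–7 M.
* Replicate noise is modelled as a single additive Gaussian term; real
  replicate structure (preparation vs. instrument variance) is unknown.
* The helix–coil module and the synthetic pocket are stand-ins built for
  property-level validation, not quantitative reproduction of any specific
  simulation or structure.
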