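# Methods

## Membrane partitioning from tryptophan fluorescence

The partition model treats the toxin as equilibrating between an
aqueous phase and the accessible lipid phase of large unilamellar
vesicles. With a mole-fraction partition coefficient K, the fraction of
toxin in the membrane at available lipid molarity [L] is
K[L]/([W] + K[L]), and the observed relative fluorescence is

    F/F0(L) = 1 + (F/F0_max − 1) · K[L] / ([W] + K[L]).

Parameters and defaults:

* `water_molarity` [W] = 55.3 M — molarity of pure water; fixed by the
  model, overridable.
* `available_fraction` = 0.60 — only the outer leaflet of an extruded
  vesicle is accessible to an externally added peptide, so [L] is 60 %
  of total lipid. Overridable per series.
* Lipid is stored in mM and converted to M inside the model; unit
  suffixes in table headers are validated at I/O time because source
  experiments mix nM/µM/mM across assays.

The same equation, fit to the recovery of *maximal* emission intensity
when vesicles are titrated into an acrylamide-quenched toxin solution,
yields the dequenching coefficient K_dx; `model_kind` records which
readout a fit used. Stern–Volmer quenching is fit as F0/F = 1 + K_sv[Q]
with the intercept fixed at 1 (the model forces it; a free-intercept
diagnostic mode exists).

Fitting is Levenberg–Marquardt-style damped least squares
(`scipy.optimize.curve_fit`) with K initialised from the lipid
concentration at half-maximal response (at half-max, K[L] = [W]); a
small ladder of restarts guards against bad initialisation. Responses
are unweighted — no error model is imposed on the inputs. Standard
errors come from the fit covariance. Fits require ≥ 4 points spanning
at least a decade of lipid; a series whose response never rises 5 %
above baseline is returned as a flagged degenerate fit rather than a
spurious K.

Peak positions (for blue-shift metrics) are located by quadratic
interpolation through the three grid points around the argmax, so ~2 nm
shifts are resolvable on a 5 nm instrument grid; argmax ties break
toward the lower wavelength (arbitrary, documented). Brominated-lipid
quench profiles report, per bromination position (6,7 / 9,10 / 11,12),
the labeled/unlabeled intensity ratio at the unlabeled-condition peak;
no quantitative depth (parallax) analysis is attempted — the per-label
ratios are the deliverable.

## Occupancy model and alanine-scan energetics

The channel carries four voltage-sensing domains, each an independent
toxin site; one bound toxin is assumed sufficient to keep the channel
closed at weak depolarisations. Hence the unbound fraction measured
from steady-state current ratios is F_u = (K_d/(K_d+[T]))⁴, inverted
exactly for single-concentration estimates and fit by least squares for
multi-concentration curves (the single-point path and the fit agree
exactly by construction). `n_sites` defaults to 4 but is general.

F_u averaging uses only records in the weak-depolarisation window
(−20 to +10 mV default) and applies a plateau check: scanning voltages
in increasing order, a voltage whose F_u deviates more than 10 %
(relative, configurable) from the last accepted value is excluded —
rising F_u with voltage means toxin-bound channels have started to
open. Records with F_u > 1 + tolerance (current increased after toxin)
are flagged, never silently clipped.

ΔΔG = RT·ln(K_d^mut/K_d^wt) with R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K by default. Recordings of this kind are made near 22 °C,
but 298.15 K is the temperature that reproduces the published ΔΔG
values from their own printed K_d ratios to 2 decimal places, so it is
clearly the convention the reference table used; the temperature is a
parameter for users who prefer the thermodynamically literal choice.
One row of the packaged table (W28A, printed 3.14) recomputes to 3.13 —
consistent with the original authors rounding the ratio before taking
the log; the recomputation keeps both columns visible. SEM uses the
n−1 denominator; single-cell estimates report SEM 0 with a flag.

G–V curves normalise tail currents to their maximum; the optional
Boltzmann summary fits A/(1+exp(−(V−V½)/k)) with a free amplitude so
that incomplete saturation does not bias V½. This fit is a convenience
for activation-shift phenotypes, not part of the occupancy model.

## Structural surface mapping

* **Superposition** is the standard SVD (Kabsch) solution restricted to
  proper rotations; a degenerate case that would prefer a reflection is
  resolved to the nearest proper rotation. Intended use: cystine Cα of
  two ICK toxins, but any matched point sets work. Core-residue
  selections for toxin–toxin RMSD are user input — no default guess.
* **SASA** is Shrake–Rupley quadrature on a deterministic Fibonacci
  lattice (960 points default, no RNG, bit-for-bit reproducible), probe
  radius 1.4 Å, Bondi-type element radii (C 1.70, N 1.55, O 1.52,
  S 1.80 Å, 1.70 fallback), all configurable. Single-sphere agreement
  with 4π(r+probe)² is ~10⁻¹⁴ relative because the lattice weights are
  uniform. An atom exactly coincident with an identical earlier atom is
  fully occluded by it (lower index wins), so duplicates never double
  count. Convergence: doubling the point count moves toy-complex totals
  by < 1 %.
* **ΔSASA** uses the identical probe/quadrature for the free component
  and the complex, so non-interface residues cancel exactly and
  per-residue ΔSASA is non-negative up to quadrature noise. The sum of
  both components' ΔSASA equals the total area buried by the complex
  (checked as an invariant).
* **Hydrophobic patch area** clusters a user-supplied hydrophobic
  residue set by single-linkage on heavy-atom distances (4.5 Å cutoff)
  and sums per-residue SASA over the largest cluster. Which residues
  constitute "the" hydrophobic surface of a given toxin is a scientific
  choice left to the user.
* **Register grafting** places a toxin on a target helix by superposing
  the helix segment it is known to bind (equal-length windows, nine
  residues in the motivating application) onto the target segment, then
  advancing by whole-residue frames: each frame is a screw transform of
  100° about and 1.5 Å along the target helix axis. The published
  description of this construction quotes a 5.4 Å translation per
  one-residue register step, which is geometrically the per-*turn*
  pitch of an α-helix, not the per-residue rise; the rise is therefore
  an explicit parameter (canonical 1.5 Å/residue default) rather than a
  silently resolved constant. The helix axis is estimated algebraically:
  its direction is the common normal of the Cα second differences
  (which lie in planes perpendicular to the axis), and its position is
  a least-squares circle-fit centre of the projected trace — exact for
  ideal helices, stable for real ones; ≥ 4 residues required. Because
  frame k is defined as k elementary steps composed with the base
  placement, grafts form an exact one-parameter transform family.
* **Clash and interface screens** count inter-chain heavy-atom pairs
  below 2.5 Å (default; the qualitative "steric clash" criterion) and
  list residues with any heavy atom within 12 Å of the partner chain
  (the conventional interface-masking distance), both deterministic in
  ordering.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical and geometric structure* the
analyses assume: asymmetric-Gaussian Trp emission bands (red-tailed,
the published sources specify only peak behaviour, not line shape),
saturating partition titrations on a lipid grid spanning two decades
around half-saturation (0–2 mM total lipid), linear Stern–Volmer
series on a 0–0.3 M acrylamide grid (0.3 M is the working concentration
in the dequenching protocol; figure legends elsewhere cite 0.2 M, and
the generator takes the concentration as an explicit parameter rather
than resolving that discrepancy), four-site occupancy experiments at
the wild-type-like dose ladder (56–908 nM around K_d = 224 nM, four
weak-depolarisation voltages), and ideal α-helices (100°/residue,
1.5 Å rise, 2.3 Å Cα radius) with a rigid Fibonacci-ball toxin
placeholder.

Noise is multiplicative Gaussian with fixed relative SD — a shot-noise
approximation that keeps intensities positive at realistic SD; the
default recovery studies use 2 % (fluorescence) and 5 % (currents),
matching the scatter visible in the source data. The normalisation
point (zero lipid / zero quencher) is left noise-free, as it defines
the reference. Not emulated: vesicle scattering backgrounds (inputs are
assumed scatter-corrected), instrument drift, correlated noise between
voltages of one cell, toxin wash-in kinetics (only steady-state
endpoints are modelled), real side-chain packing and protonation in the
toy complexes. Passing the recovery tests therefore demonstrates
estimator correctness and calibration under the assumed error model,
not robustness to systematic instrument artefacts.

The 100-replicate recovery studies and the 525-point inversion grid in
the acceptance script were chosen as the smallest problem sizes at
which the mean-recovery and round-trip claims are statistically
meaningful; all complete in seconds.

## Known limitations

* The partition fits are unweighted; heteroscedastic real data would
  benefit from a variance model the sources do not provide.
* ΔSASA and patch areas depend on the vdW radius table; values differ
  by a few percent across published radius sets. The table is
  configurable but the default is fixed for reproducibility.
* Register grafting treats both helices as rigid and ideal for the
  offset step; real helices bend, so large |offset| placements drift
  from what re-superposing a shifted window would give.
* Reproducing published absolute patch areas (e.g. 380 vs 703 Å² for
  two specific toxins) requires the original residue selections, which
  are not enumerated in the sources; the package computes the areas for
  any user-supplied selection but claims no exact reproduction.
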