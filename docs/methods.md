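# Methods

## Pseudorotation analysis

A five-membered furanose ring has five endocyclic torsions
ν₀ = C4′-O4′-C1′-C2′, ν₁ = O4′-C1′-C2′-C3′, ν₂ = C1′-C2′-C3′-C4′,
ν₃ = C2′-C3′-C4′-O4′, ν₄ = C3′-C4′-O4′-C1′. Under the
Altona–Sundaralingam model they follow a single cosine wave,
ν_j = ν_max·cos(P + 144°·(j−2)), so the phase is

    tan P = (ν₄ + ν₁ − ν₃ − ν₀) / (2 ν₂ (sin 36° + sin 72°)).

We evaluate P with `atan2(numerator, denominator)` rather than the
textbook arctangent plus a conditional +180° when ν₂ < 0. The two forms
are identical wherever ν₂ ≠ 0 (the test suite proves agreement on 10,000
random torsion sets); the atan2 form additionally handles ν₂ = 0, where
it returns 90° or 270° by the numerator's sign. Dihedrals use the IUPAC
sign convention via the standard two-normal atan2 construction.

Numerical choices:

* **Reporting range.** P is reported on [0, 360); classification
  intervals written with signed angles (−10°) are interpreted
  circularly, so −10° ≡ 350°.
* **Planarity.** When max|ν_j| < 1°, the phase is undefined; the
  conformer is flagged degenerate (P = NaN) instead of raising, and
  ensemble statistics exclude it while reporting the count.
* **Amplitude.** ν_max = ν₂ / cos P when |cos P| > 0.1; near the wheel's
  east/west poles (P ≈ 90°, 270°) this is ill-conditioned and a
  least-squares projection of all five torsions onto the cosine wave at
  the computed phase is used instead. The amplitude is reported but never
  used for classification.
* **Classification endpoints.** Hemispheres are half-open arcs
  [lo, hi) that partition the circle exactly (northern [−90°, 90°),
  southern [90°, 270°)). The named bins C3′-endo [−10°, 40°] and
  C2′-endo [140°, 185°] are closed: they are isolated descriptive regions
  (no two touch), closing them creates no ambiguity, and it keeps the
  conventional boundary assignment that a phase of exactly 185° is still
  called C2′-endo. Schemes are validated: hemispheres must tile the
  circle and a named bin may not cross its hemisphere boundary.

## Structure input

Multi-model PDB files are read with gemmi; models keep file order and
1-based MODEL numbering. Both primed (C1′) and star (C1*) atom-name
dialects are normalised to primed, and HETATM records are accepted since
abasic-site analogs are het groups with inconsistent residue codes —
which is also why residues are selected by chain and number, never by
name. Alternate locations are resolved by highest summed occupancy
(alphabetical tie-break, with a warning naming discarded altlocs), by an
explicit altloc id, or returned exhaustively. Ring bonds outside
1.2–1.8 Å trigger a data-quality warning, not an error. mmCIF input and
symmetry handling are out of scope.

## Ensemble statistics

Phases are binned on the circle with uniform bins whose width must
divide 360° (default 5°, edges on multiples of the width), so no mass is
lost at the 0/360 wrap. Hemisphere and named-bin occupancies are direct
count fractions over the same conformers. The circular mean is the
direction of the vector resultant of unit vectors at each phase and the
resultant length |R|/n measures concentration; a vanishing resultant
(antipodal data) yields resultant length 0 with an undefined (NaN) mean.
Ensemble comparison reports per-bin probability differences and
occupancy differences only — the underlying claims are descriptive, so
no significance test is attached.

## Kinetic and binding models

Multiple-turnover (substrate-excess) time courses are fit to
`A(1 − e^(−k_obs t)) + v_ss t` with A (nM) the burst amplitude
(actively bound enzyme), k_obs (s⁻¹) the first-order chemistry rate and
v_ss (nM/s) the steady-state velocity; k_ss = v_ss/A is always derived
from the fitted pair, never a free parameter. Single-turnover
(enzyme-excess) courses drop the linear term. Titrations are fit to
fraction bound = scale · AB/B_T with AB the quadratic tight-binding
solution; the closed form is evaluated as 2·A_T·B_T/(s + √(s² − 4A_TB_T)),
s = A_T+B_T+K_D, which avoids catastrophic cancellation when K_D
dominates. The scale is fixed at 1 by default and optionally fitted
(bounded to [0.1, 1.5]) because gel quantification may not saturate at
exactly 1.

Fitting choices:

* Pooled replicate points by default (replicate means are recoverable by
  pre-averaging); with ≥ 3 replicates, parameter uncertainties come from
  per-replicate refits as the standard deviation of the mean, otherwise
  from the pooled-fit covariance. The derived k_ss gets a delta-method
  error in the pooled case and a replicate SEM otherwise.
* All rates and amplitudes are constrained positive by bounded
  trust-region least squares (`scipy.optimize.curve_fit`).
* Initialisation: v_ss and A from a straight line through the terminal
  half of the time range; k_obs from a log-linearised early phase;
  K_D from the titrant concentration at half of the maximal signal.
* Guard rails: ≥ 5 distinct timepoints (or titration points) are
  required; all-zero or flat product signals are rejected; timepoints
  spanning less than a decade, or titrations lying entirely below/above
  half-saturation, raise identifiability warnings.
* Units are fixed: seconds, nM, s⁻¹, nM·s⁻¹.

## Synthetic data

The generators define the conditions under which the package is
validated:

* **Torsion sets** are exact, ν_j = ν_max·cos(P + 144°(j−2)), so the
  analyse∘generate round trip is an identity to machine precision.
* **3D rings** place a regular pentagon (bond length 1.54 Å — idealised,
  since torsions are bond-length independent) and add out-of-plane
  displacements z_j = √(2/5)·q·cos(φ + 4πj/5). A one-time numeric
  calibration fixed the analyzed phase at φ + 126°; the residual wobble
  is within ±1° for q ≤ 0.5 Å and the embedder's contract is ±2°.
  q = 0.38 Å corresponds to ν_max ≈ 37°.
* **Ensembles** draw phases from von Mises mixtures (circular analogue
  of a Gaussian; the concentration κ is exposed, with κ = 50 ≈ ±8°
  spread used as the concentrated default). Northern-dominated
  (component at 19°, weight 0.8) vs southern-dominated (component at
  160°, weight 0.8) mixtures emulate RNA-like substrate vs B-DNA-like
  ensembles. Ground-truth per-conformer phases are always written to a
  sidecar.
* **Kinetics**: the default grid is 12 log-spaced timepoints over
  0.1–10 s with 3 replicates; defaults A = 25 nM, k_obs = 2.3 s⁻¹,
  v_ss = 7.5 nM·s⁻¹ (so k_ss = 0.30 s⁻¹) for multiple turnover and
  A = 45 nM, k_obs = 2.6 s⁻¹ for single turnover, consistent with 30 nM
  enzyme / 100 nM substrate and 500 nM enzyme / 50 nM substrate
  experiments. Noise is additive Gaussian on the observable (default
  2% of the amplitude, a typical gel-quantification error), truncated at
  physical bounds.
* **Titrations**: 2 nM probe, protein 0–20 nM on a 12-point grid
  concentrated around low-nM K_D, Gaussian noise (default 0.03 fraction
  units) clipped to [0, 1].

What the generators do **not** emulate: force-field physics (no solvent,
no sequence context, no correlated pucker interconversion dynamics),
systematic gel-quantification bias, or pipetting-series correlation in
titrations. Passing recovery tests therefore demonstrates estimator
correctness and statistical power at realistic noise, not robustness to
systematic experimental error.

Validation at these conditions (see `tests/test_acceptance.py` and
`scripts/acceptance.py`): the phase round trip is exact to 1e-9°; burst
and single-turnover rates are recovered within ±15% in ≥ 95% of 200
noisy repeats; K_D within ±20% likewise; ensemble hemisphere fractions
land within ±0.02 of the mixture weights at n = 10,000 (binomial bound);
the quadratic isotherm matches an independent bracketing root-finder to
1e-10 relative. Problem sizes (25–200 repeats, 10,000 conformers) were
chosen so the whole suite runs in seconds while keeping Monte Carlo
error well below the tolerances.

## Known limitations

* Six-membered-ring (Cremer–Pople) puckering, backbone/glycosidic
  torsions and repuckering free energies are out of scope.
* The PDB reader targets the fixed-width PDB dialect; mmCIF is not
  supported.
* Kinetic fitting covers the two-phase burst model only — no multi-step
  mechanism or global fitting across substrates.
* Circular statistics are reported without kernel density estimation or
  interconversion-rate analysis.
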