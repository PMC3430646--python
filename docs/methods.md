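# Methods

`nanobone` implements the computational chain of magnified X-ray phase
nanotomography of cortical bone: a cone-beam (projection microscope)
acquisition is simulated as magnified Fresnel diffraction patterns of a
synthetic bone phantom at several focus-to-sample distances; per-projection
phase maps are retrieved by linear contrast-transfer-function (CTF)
inversion followed by a non-linear conjugate-gradient refinement; the phase
maps are reconstructed by filtered backprojection into the refractive index
decrement δ, calibrated to mass density; and the lacuno-canalicular network
(LCN) is segmented with a Hessian-eigenvalue line filter and quantified.

## Physical model

**Geometry.** A point focus illuminates the sample at distance `D1` from
the focus with the detector fixed at `D1 + D2`. The geometric magnification
is `M = (D1 + D2)/D1`. Spherical-wave illumination at distance `D1` is
equivalent to plane-wave illumination of the object sampled at the
object-plane pixel `detector_pixel/M` and propagated over the equivalent
distance `D_eq = D1·D2/(D1 + D2)`; the forward model and the reconstruction
both work in this equivalent parallel geometry — no cone-beam ray tracing.
The default geometry is the nano-imaging configuration: 17 keV
(λ = hc/E = 12.398/17 = 0.729 Å), `D1 = {32.6, 33.6, 37.6, 47.6}` mm,
`D1 + D2 = 525` mm, a 1500-pixel detector, and a ~60 nm pixel in the plane
closest to the focus (90 µm field of view).

**Optical constants.** The complex refractive index is `n = 1 − δ + iβ`.
For light-element tissue with Z/A ≈ 1/2 and a negligible dispersion
correction far from absorption edges, δ is proportional to mass density:

    δ = C · ρ[g/cm³] · λ[Å]² ,   C = r_c λ_unit² N_A (Z/A) / 2π ≈ 1.342·10⁻⁶

with the classical electron radius r_c = 2.8 fm. The package computes C
from these constants (`constants.delta_density_coefficient`) rather than
hard-coding it, and β follows from the fixed δ/β ratio (202 for cortical
bone at 17 keV, from ICRU-44 composition). Inverting this relation converts
the reconstructed δ volume directly to mass density.

**Projection and propagation.** A thin object modulates the wave as
`ψ = A·exp(iφ)` with `φ = −(2π/λ)∫δ dl ≤ 0` and `A = exp(−(2π/λ)∫β dl)`.
Projections are computed by rotating the density volume about the vertical
tomographic axis (trilinear interpolation) and summing along rays. Free
propagation multiplies the spectrum by the Fresnel transfer function
`exp(−iπλD|f|²)`; the sign convention is fixed by the weak-object test
(contrast spectrum `+2 sin(πλD|f|²)·φ̃`). Compact objects are embedded in a
vacuum canvas large enough that the sampled kernel is alias-free
(`N ≥ λD/p²`) and the first fringes do not wrap; periodic propagation is
available for analytic tests and is the exact adjoint pair of its
conjugate-kernel inverse.

**Detector.** The simulated detector samples the propagated intensity at
each distance's object-plane pixel through anti-aliased (Gaussian ≈ pixel
integration) cubic resampling, then applies Poisson noise at a
configurable photon count per pixel (default 10⁴ in the recovery
experiments; the actual beamline flux is not modeled). Two points matter:

* *Order*: propagation happens at full resolution and *then* the
  intensity is sampled — resampling the wave before propagation is not
  physical and produces a structural data/model mismatch at the larger
  distances.
* *Field of view*: the exit wave is embedded in vacuum covering the
  largest detector field of view before propagating, so the Fresnel
  fringes that spread beyond the object (≈√(λD) ≈ 1.5 µm here) are
  recorded rather than truncated. A detector barely larger than the
  object loses that fringe energy and biases every retrieved contrast
  low by ~10%.

A related scale effect: for a compact object of size L, per-frequency CTF
reasoning assumes λD ≪ L·(feature size). At the full 90 µm field of view
this holds comfortably; at the 7.68 µm test phantom it fails for fine
features (their diffracted orders "walk off" the object), which is why
the non-linear refinement with the exact vacuum-embedded operator carries
more weight in the scaled experiments than it would on full-scale data.

## Phase retrieval

**Resampling and detector transfer.** The K radiographs per angle are
resampled onto the grid of the plane closest to the focus (separable
cubic interpolation; the exact magnification ratios come from the
geometry, no registration). A resampled image is attenuated towards —
and empty above — its native Nyquist frequency. Both retrieval stages
therefore model each distance's detector transfer explicitly: the net
frequency response of the anti-alias + cubic down/up chain is measured
once per pixel ratio by pushing white-noise probes through exactly that
chain (windowed cross-/auto-spectrum estimate, fixed seed) and enters the
CTF coefficients and the misfit residuals as a symmetric real multiplier,
so misfit and gradient remain an exact pair.

**Linear CTF stage.** For a weak object with the amplitude coupled to the
phase through the δ/β ratio (`B = −φ/ratio`), the intensity contrast at
distance k is `(2 sin χ_k + (2/ratio) cos χ_k)·T_k(f)·φ̃` with
`χ_k = πλD_k|f|²` and `T_k` the measured detector transfer. The phase is
the per-frequency least-squares solution over the K distances,

    φ̃ = Σ_k a_k·FT(I_k − 1) / (Σ_k a_k² + reg(f)) ,   a_k = (2 sin χ_k + (2/r) cos χ_k)·T_k ,

regularized by a Tikhonov floor that blends from `reg_hf = 10⁻³`
broadband down to `reg_lf = 10⁻⁵` in a Gaussian low-frequency band (width
5% of Nyquist). The low-frequency floor must stay well below the squared
absorption coefficient `(2/ratio)² ≈ 10⁻⁴`, or the absorption-borne
smooth-bulk information is destroyed. `prior_mode="low"` restricts the
δ/β coupling to the low band if desired. The regularization scalars are
implementation choices locked by the retrieval accuracy tests, not
physical constants.

**Non-linear refinement.** The linear estimate is refined by minimizing
the full Fresnel intensity misfit `Σ_k ‖T_k(|P_k ψ|²) − I_k‖²` with a
preconditioned Polak–Ribière conjugate gradient: the gradient (computed
by adjoint propagation and verified against central finite differences to
10⁻⁴ relative) is divided in Fourier space by the CTF normal operator
`2Σ_k a_k² + floor` (floor 0.1) — without this the misfit curvature spans
five orders of magnitude across frequency and the smooth components never
converge. Restarts occur only on a non-descent direction (scheduled
restarts were found to destroy the slowly accumulating conjugacy of the
smooth modes); the Armijo line search backtracks by quadratic
interpolation with an adaptive initial step, with a preconditioned
steepest-descent fallback on failure. Exactly `iterations` (default 10,
matching the reported procedure) outer steps are taken and the recorded
misfit history is non-increasing.

Two amplitude treatments are available:

* `amplitude_mode="coupled"` (default): the δ/β proportionality is kept
  through the refinement, leaving a single unknown φ. For a
  single-material object this is exact, and it removes a genuine
  rank-deficiency: the four equivalent distances are similar, so a free
  amplitude and the phase are nearly indistinguishable per frequency at
  low f, and a joint fit splits contrast wrongly between them.
* `amplitude_mode="free"`: the amplitude is an independent variable
  parameterized through a sharp Fourier low-pass (default 10% of
  Nyquist — its spectrum is identically zero above the cutoff after
  every update), and the phase spectrum below `phase_anchor_frac` is kept
  at the linear, absorption-complemented estimate. This is the
  formulation for objects that violate the δ/β assumption; it trades the
  low-frequency accuracy of the coupled mode for generality.

## Reconstruction and calibration

Phase maps are scaled to line integrals of δ (`∫δ dl = −φλ/2π`), full-turn
scans are folded to a half turn by averaging opposing rays, and slices are
reconstructed by ramp-filtered backprojection (linear interpolation). The
discrete Ram-Lak filter is built in real space — sampling |f| directly
underweights low frequencies and biases the reconstruction by several
percent. A raised-cosine apodization is available (default: pure ramp).

For region-of-interest (local) tomography the projections are extended by
symmetric edge-value padding of at least half the detector width before
filtering, which suppresses the truncation (cupping) bias; the remaining
scalar offset is removed using the prior that the density inside osteocyte
lacunae is zero (mean over an eroded lacuna mask is subtracted and
recorded in the calibration metadata). The recovery experiments use a
specimen that fits the field of view, so padding and offset correction are
exercised but truncation artifacts do not limit accuracy; the truncated
case is regression-tested separately (edge padding reduces the interior
error spread relative to zero padding).

## Synthetic phantom

The phantom emulates the imaged specimens: a cylindrical volume of
cortical bone split by a planar cement-line band (default 0.9 µm thick)
into an osteonal and an interstitial compartment. The cylinder is capped
with vacuum margins above and below (default 0.6 µm), so the specimen is
compactly supported in every direction: the wave model's vacuum
embedding is then exact, and no out-of-field structure biases the
reconstruction (a specimen filling the grid vertically produces a smooth
vertical bias bowl that the scalar offset cannot remove).

* **Densities.** Per-compartment means default to the measured values —
  osteonal 1.818, interstitial 1.845, cement line 1.909 g/cm³ — with
  per-voxel Gaussian fluctuation at the measured spreads (0.089 / 0.090 /
  0.097 g/cm³), clipped at zero. An optional sinusoidal lamellar
  modulation (amplitude, period, axis) is available but off by default;
  real lamellae are not parameterized quantitatively.
* **Lacunae** are flattened "lenticular drop" shapes: ellipsoids whose
  cross-section shrinks linearly with height by a taper coefficient
  (default 0.3). The analytic volume has the closed form
  `πabc·(4/3·(1−τ) + 2τ²/5)`; voxelization is an analytic inside-test at
  voxel centers (no anti-aliasing), reproducing the analytic volume to
  well under 1% for lacuna-sized bodies at 60 nm voxels. The default test
  grid is 128³ at 60 nm (7.68 µm side), so default lacunar volumes are
  scaled down (1.8 / 2.2 µm³, preserving the osteonal < interstitial size
  ordering); full-size lacunae (286.4 µm³ mean osteonal) are produced on
  demand for the volume-recovery experiment.
* **Canaliculi** are constant-radius tubes (radii drawn in 0.12–0.2 µm,
  within the observed 0.2–0.9 µm diameter range) along persistent random
  walks radiating from lacunar surfaces; each walk branches at most once
  into two or three children, to branch depth ≤ 3. Walks stop at the
  cement line — no canaliculus crosses it. Osteonal lacunae are connected
  by tubes into one pore component; interstitial lacunae stay isolated
  with a sparse short network. Default counts are chosen so the
  canalicular-to-lacunar volume ratio lands near the observed ~50%
  (osteonal) and a few percent (interstitial); the observed data do not
  fix canaliculi number densities, so these counts are configurable
  conventions, not measured values.

What the phantom does **not** emulate: collagen-fibril texture and true
lamellar structure, Haversian canals, curved osteon geometry, beamline
imperfections (partial coherence, detector PSF, flat-field residuals,
drift). Passing recovery tests therefore demonstrate correctness of the
computational chain under the stated noise model, not robustness to every
artifact of real beamline data.

## LCN segmentation and morphometry

Canaliculi are dark tubes in a bright matrix; the volume is negated so the
bright-structure conditions apply. The Hessian at scale σ is computed with
Gaussian-derivative convolutions (σ-normalized by σ²; σ must be at least
one voxel), eigen-decomposed per voxel and sorted by magnitude
|λ1| ≤ |λ2| ≤ |λ3|. The line similarity measure is Sato's:

    0                                    if λ2 ≥ 0 or λ3 ≥ 0
    |λ3|·(λ2/λ3)^γ23·(1 + λ1/|λ2|)^γ12       if λ1 ≤ 0
    |λ3|·(λ2/λ3)^γ23·(1 − α·λ1/|λ2|)^γ12     if 0 < λ1 < |λ2|/α

with defaults γ23 = 1, γ12 = 1, α = 0.25 (the study reports no values;
these are the filter's canonical defaults). Multi-scale enhancement takes
the voxelwise maximum over scales (defaults 0.12/0.2/0.3 µm, spanning the
canalicular radii at 60 nm resolution).

Segmentation unites a low-density pore mask (default threshold
0.9 g/cm³ — lacunae) with a threshold on the enhanced volume (canaliculi,
keeping their connectivity to the lacunae), labels 26-connected
components, and eliminates unconnected components smaller than ~2 µm³
(configurable; applied to components of the full network). Lacunar bodies
are separated from canaliculi by a morphological opening with a 0.5 µm
ball (implemented exactly via Euclidean distance transforms); opened-away
thin voxels are canalicular. The opening radius must stay below the
smallest lacunar semi-axis; at coarse test resolutions the boundary shell
it misclassifies bounds the achievable ratio accuracy (~10% at 120 nm
voxels with ~1 µm³ lacunae, ≪1% at full lacuna sizes). A component is
flagged cross-cement-line iff it holds voxels in both the osteonal and
interstitial compartments.

## Tissue statistics

Per-voxel densities from one ~8 µm³ subvolume per tissue (37,037 voxels
at 60 nm) are compared by one-way ANOVA with post-hoc Tukey HSD on all
pairs. Subvolume placement is deterministic: a cube centered on the most
interior voxel of the tissue mask; a thin compartment (the sub-µm cement
band at test scale) cannot contain such a cube, and an interior-voxel
fallback selects the same number of maximally interior, centrally located
voxels instead. Voxels are treated as independent observations, mirroring
the reported analysis; because of spatial correlation and within-tissue
biological variation the sample SD overestimates the statistical
uncertainty of the mean, so the significance calls here are anti-
conservative in principle — with n ≈ 37,000 per group the conclusion is
insensitive to this caveat on synthetic data.

## Recovery experiments and problem sizes

`nanobone.experiments` packages the headline checks (also driven by
`scripts/acceptance.py`):

* **Density recovery** — 128³ phantom at 60 nm, four distances, 180
  projection angles over a full turn, Poisson noise at 10⁴
  photons/pixel, recorded on a 192-pixel detector grid (the field of
  view must exceed the specimen plus its Fresnel fringes); full
  retrieval with 25 CG iterations (the reported 10 suit full-scale data;
  the scaled compact phantom sits partly in the walk-off regime and its
  smooth band converges around 25), FBP with edge padding and a
  cosine-apodized ramp (ringing inside the scaled-down lacunae would
  otherwise leak into the offset calibration), lacuna-based offset
  correction on lacuna interiors eroded by 0.18 µm (clear of boundary
  ringing). Compartment means are measured in interior regions
  (compartments eroded by 0.24 µm, pores excluded with a margin),
  emulating regions of interest well inside each tissue; the acceptance
  band is ±2% per compartment with the ordering cement line >
  interstitial > osteonal preserved. 180 angles (rather than the
  beamline's 2999) keeps the experiment desk-scale; means over interior
  regions are insensitive to the residual angular-undersampling streaks.
* **Lacunar volume** — one lenticular lacuna voxelized at 60 nm with
  analytic volume 286.4 µm³, segmented by density threshold + connected
  components + size filter; volume = voxel count × voxel volume, ±2%.
* **Significance** — Gaussian samples at the measured per-tissue
  means/SDs, n = 37,037 each; ANOVA and all Tukey pairs must fall below
  p = 0.01.

## Known limitations

* The refinement's low-frequency anchor means very-low-frequency phase
  information comes entirely from the linear, δ/β-prior stage; objects
  violating the δ/β assumption at large scales would be biased there.
* Parallel-beam equivalence ignores cone-beam effects beyond
  magnification (exact for the small fields of view used here).
* No phase unwrapping: projections with |φ| ≫ π would need it.
* No projection alignment/registration; simulated data are perfectly
  aligned by construction.
* Ring/rotation-axis artifacts, detector blur and partial coherence are
  out of scope.
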