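# Methods

`cztpet` models a four-panel small-animal PET prototype built from 3-D
position-sensitive CZT detectors, end to end: photon transport, detector
response, the analytic coincidence/sensitivity model, the near-field Compton
response used for event sequencing and random rejection, geometry
calibration, and list-mode OS-EM reconstruction. This note records the
models, their assumptions, the defaults, and the places where the design was
genuinely open.

## Geometry and units

Units are mm, keV, ns, Bq throughout. The global frame has its origin at the
centre of the field of view and z along the rotation axis. Four panels of
2 × 2 monolithic CZT modules (2.2 × 2.2 × 1.0 cm each) face the origin from
±x and ±y; opposite front faces are 80 mm apart. Each module carries 11 × 11
anode pixels of 1.9-mm pitch; the detector-voxel grid refines the pixelated
area to 100 × 100 lateral voxels of 209 µm and divides the 1-cm thickness
into D sublayers (D ∈ {1, 2, 4, 10}). Depth of interaction (DOI) is measured
from the cathode (front) face.

Poses are parametrised as a translation plus a rotation-*vector* delta
applied on top of a fixed base orientation. This matters: xyz Euler angles
are exactly gimbal-locked at the panels' nominal 90° pitch
(R_z(c)·R_y(90°)·R_x(a) depends only on c − a), which makes pose estimation
ill-posed in that parametrisation. The full parameter vector α has 130
entries: 4 × (6 panel-pose + 4 × 6 module-pose) + 7 rotation-stage + 3
vertical-stage parameters.

## Photon interaction physics

Attenuation coefficients for Cd₀.₉Zn₀.₁Te (5.9 g/cm³, molecular density
1.51 × 10²² cm⁻³) are shipped as a 50–1500 keV table
(`data/czt_attenuation.csv`, regenerable with
`scripts/make_attenuation_table.py`):

* **incoherent** — Klein–Nishina total cross section per electron × 98.2
  electrons per molecule, with a small effective incoherent-scattering-
  function correction below ~200 keV;
* **photoelectric** — a smooth power law (local exponent ≈ 2.9 near 100 keV
  flattening to ≈ 2.2 at 1.5 MeV; no K-edges lie in the range), anchored so
  that an interacting 511-keV photon Compton-scatters with probability 0.83,
  the established branching ratio for CZT;
* **coherent** — an E⁻² law anchored at ~2% of the total at 511 keV.

Transport excludes coherent scattering (no energy deposit, ~2% of µ);
`cross_sections` still reports it. The total at 511 keV is 0.52 cm⁻¹.

Compton scattering angles follow Klein–Nishina (Kahn's rejection sampling).
Doppler broadening uses the impulse approximation with hydrogenic per-shell
momentum profiles: shells are drawn proportional to occupancy; each shell's
projected-momentum profile is the hydrogenic J(p) ∝ (1 + (p/p_n)²)⁻³ with
scale p_n = Z_eff/n atomic units from Slater screening (realised as a scaled
Student-t with 5 degrees of freedom, so the heavy core-shell tails are
kept). The first-order energy shift at fixed angle is
δE′ = p_z·m_ec²·q/(E₀(1−cos θ) + m_ec²) with q the Compton-line momentum
transfer. The resulting line shape is a sharp valence core (FWHM ≈ 10–20 keV
at 511 keV/90°) over broad inner-shell wings; binding-energy thresholds per
shell are not enforced.

Transport samples free paths from the exponential law, picks interaction
types by cross-section ratio, follows Compton chains through the oriented
module boxes (gaps and neighbouring modules included), and absorbs photons
on the spot once they fall below the 50-keV table floor (mean free path
< 0.3 mm there). Energy is conserved exactly per absorbed history.

## Detector response

Interactions sharing an anode pixel of a module are merged before blurring
(energy-weighted centroid, summed energy). Merged deposits below a 50-keV
per-pixel trigger threshold are not read out (their energy is lost); this
threshold — typical for pixelated CZT readouts — is what brings the
multiplicity spectrum to the measured ~80% single-site / 18% double / ~2%
higher pattern; without it small forward-scatter deposits inflate the triple
fraction. Surviving sites get independent Gaussian energy blur (FWHM
interpolating 3 keV @ 200, 4.5 @ 450, 5.4 @ 511 keV) and isotropic 3-D
Gaussian position blur (0.5 mm FWHM).

Timing: each detected photon is stamped with the decay time plus 100-ns-FWHM
Gaussian jitter. Coincidences are formed by clustering: photons closer than
the pairing window (±250 ns default) chain into clusters; clusters of
exactly two become coincidences, larger ones are discarded as pile-up.
Photons from different annihilations paired this way are random
coincidences; ground-truth labels (random flag, emission point, true
first-site index) ride along in the simulated list-mode data and are absent
from experimental-style files.

## Coincidence-response model and sensitivity

For a source voxel i and detector-voxel pair (I₁, I₂) on opposite panels,
the coincidence probability sums over sublayer pairs (n, m) the product of

* the first-photon term S₁cos φ/(4πd²) · e^{−µl} · (1 − e^{−µl₀}), with l
  the CZT path to the sublayer's *entry* face and l₀ the in-sublayer path;
* the conditional second-photon term (S′/S₂) · e^{−µl′} · (1 − e^{−µl₀′}),
  where S′ is the overlap of the first slice back-projected through the
  source onto the second slice's plane (exact convex-polygon clipping; a
  numba kernel with a pure-numpy fallback).

Here µ is the total attenuation of CZT (coherent included), as the model
defines it. The sensitivity map sums the first-photon term over all detector
columns and sublayers of each panel times the opposite photon's interaction
probability along the mirrored ray. Two conventions are exposed: the model's
own sum over unordered voxel pairs with a designated first photon ("pair",
half the physical rate) and the physical per-decay coincidence probability
("physical" = 2 × pair). The quoted peak system sensitivity (~2.2% at the
FOV centre) corresponds to the pair convention with the lateral columns
covering the full 22-mm crystal — the monolithic crystal is active out to
its rim, with rim interactions recorded by edge pixels. The package computes
2.18% at D = 10; the transport Monte Carlo agrees with the physical-
convention value within 1σ when evaluated with the same (transport)
attenuation. An optional squared full-energy window factor (estimated once
per geometry by MC, ≈ 0.43² here) converts the map to in-window detected
sensitivity; it is off by default because the quoted peak corresponds to the
raw interaction model.

Sensitivity over reconstruction grids is evaluated on a ~2-mm lattice and
interpolated trilinearly (the map is smooth at the cm scale).

## Near-field Compton response F

F histograms (Ê₁, θ̂, d̂₂) over two-interaction, full-energy pencil-beam
histories in an idealised 4 × 4 × 1 cm slab: a Compton scatter followed by
photoelectric absorption, E₁ + E₂ = E₀. True positions/energies are blurred
by the detector model (no pixel merge, so small d̂₂ is covered; the 50-keV
site threshold applies); Ê₁ is the blurred energy of the *true* first site,
θ̂ the angle between the beam axis and the blurred inter-site vector, d̂₂
the blurred inter-site distance. Desk-default bins are 1 keV / 1° / 0.5 mm
(the reference setting is 1/3 keV / 1/3° / 0.25 mm; bins are configurable);
d̂₂ > 20 mm collects in an overflow bin that is included in the
normalisation and excluded from angular fits. The matrix is stored dense
(2.5 × 10⁶ cells at desk bins). Σ F = 1 over all retained events.

The builder can run to a fixed number of *retained* events
(`target_events`); the headline false-rejection figure uses 10⁷ retained
events. Occupancy matters for threshold-relative quantities: the mass below
0.2 × slice-max grows with occupancy (slice maxima are extreme statistics)
— 0.12 at 5 × 10⁵ events, 0.15 at 2 × 10⁶, ≈ 0.16 at 10⁷, approaching the
continuum value near the prototype's measured 0.18. The d̂₂-marginalised ("conventional")
variant gives ≈ 0.24 at desk scale versus the prototype's measured 0.26, and its angular
uncertainty is flat in d̂₂ by construction, reproducing the contrast between
the near-field and conventional angular-uncertainty maps.

## Sequencing, rejection, NECR

For a two-site photon, each candidate ordering fixes (Ê₁, d̂₂); the line
through the assumed first site and the opposite photon's centroid gives the
implied scattering angle under the back-to-back assumption, and
F(i, j, k)/max_j F(i, ·, k) is the ordering's relative probability. An event
is accepted when any (side, ordering) candidate reaches the threshold
(default 0.2); the argmax fixes the predicted first site. The false-
rejection probability of true Compton events follows from F alone (per-slice
below-threshold mass combined by the law of total probability), and equals
the empirical rate on events drawn from F (self-consistency, exact up to
binomial error). NECR′/NECR = (1 − false rejection)²/(1 − rejection rate),
scanned over thresholds with the empirical rejection rate of the
Compton-containing stream.

The NECR study stream mixes simulated trues from the hot-rod phantom with
explicit chance pairings of photons from different decays, dosed so that
*known* randoms (all candidate LORs miss the object cylinder) are ~53% of
the Compton stream, matching the prototype's accounting. Under these
conditions the package finds the near-field model's optimal gain ≈ 1.3–1.4,
above the marginalised model's, but below the prototype's measured 1.85: the prototype's
stream carried a much larger unlabelled junk fraction (object scatter,
out-of-FOV singles) than the in-FOV, scatter-free simulator produces — its
rejection rate at threshold 0.2 was 0.64 against our ≈ 0.38. The model
ordering and the gain-above-one conclusions are robust; the absolute gain is
a property of the stream composition.

## Geometry calibration

Point-source (250-µm sphere) coincidences at known rotation-stage poses are
voxel-free observations: the readout reports module-local coordinates. The
likelihood per event combines (i) a two-dimensional Gaussian on the
transverse offset of the source centre from the observed LOR — variance from
the 0.5-mm endpoint blur propagated to the source plane plus the sphere's
second moment r²/5 — and (ii) the smooth solid-angle and depth-attenuation
terms of the response model, normalised by the pose-dependent sensitivity at
the source positions (removing acceptance bias). A voxelised slice-overlap
likelihood was tried first and rejected: with 0.5-mm blur most events miss
the ~0.2-mm geometric overlap tube, leaving a floor-dominated objective
whose minimum sits ~0.5° from the truth. Optimisation is two-stage
Nelder–Mead over a free-parameter mask (default: one panel's six pose
parameters; the likelihood supports all 130). On the standard experiment
(24 stage poses, 2 × 10⁴ events, ≤1 mm/≤1° panel perturbation) recovery is
0.02 mm / 0.05°.

## Reconstruction

List-mode OS-EM with angle-grouped subsets. Event endpoints follow the
configured positioning rule (predicted first site, energy-weighted centroid,
or cathode-nearest), are quantised to detector voxels laterally and to the
configured DOI bin (1/2.5/5/10 mm) in depth, and the system-matrix row is
evaluated on the fly from the response model with a tube-of-response cutoff
(3 × voxel size) and 3-point Gauss quadrature of the sub-voxel overlap along
each lateral axis. Rows are cached sparse, so iterations are sparse
matrix-vector products. Per-event scale factors cancel in the update; the
sensitivity carries the absolute scale. Events that do not form an
opposite-panel LOR (same-panel or adjacent-panel chance pairings) are
skipped and counted. Voxels with zero sensitivity stay at zero;
per-subset sensitivities can be decay-adjusted by the subset count ratio
N_sub/N₁ (the rotation of the object between subsets is handled by rotating
event endpoints into the object frame and the sensitivity grid per subset).
A 0.40-mm-FWHM Gaussian post-filter (edge-renormalised) is available.
With one subset, one iteration, and the tube cutoff widened, the update
reproduces a dense MLEM step exactly (oracle test on an 8×8×8 grid).

## Study protocols and synthetic data

The phantom generators rasterise with exact z-overlap and 4 × 4 lateral
supersampling at circular boundaries: point (0.25 mm), two lines (0.65-mm
capillaries), the hot-rod resolution phantom (0.35/0.5/0.75/1-mm sectors at
0.7/1.0/1.5/1.6-mm pitches, with the continuous-solution uniform top
region), a 70%-scaled NU-4-style image-quality phantom, uniform cylinders,
and a composite line+uniform QC phantom (hot capillary at 20× the uniform
concentration) used by the dataset comparison so a line-spread measurement
and uniformity ROIs coexist at desk-scale counts.

The event-selection variants (single-site only; + accepted Compton with
predicted first site; + all Compton with cathode-nearest; count-matched
mixtures with predicted-first-site, centroid, and unrejected-centroid
Compton shares) are compared at matched event counts. The package provides
the matched-resolution protocol (iterate each variant until a common
line-spread FWHM, then compare the activity-weighted normalised SD over
uniform ROIs) — the mechanism that separates the variants at experiment
scale, where lower-quality mixes need more iterations and pay in noise.
At desk-scale counts (~3 × 10³ events per variant) the line-FWHM estimate
carries ±0.05 mm of statistical noise, which the iteration matching
amplifies into seed-dependent SD shifts, and the SD gaps between the three
mixed variants (a few percent) sit below the ROI sampling noise. The
asserted check is therefore the robust core of the ordering: at a fixed
mid-iteration and matched counts the single-site-only selection has strictly
the lowest normalised SD of all variants (stable across seeds); the full
four-way gradation would need roughly the experiment's event counts
(~10⁶ per variant, two orders of magnitude beyond the desk scale).

## Problem sizes and determinism

Desk-scale defaults used by the tests and the acceptance script: response
matrices of 10⁵–2×10⁶ retained events (10⁷ for the headline false-rejection
figure), 10⁶-photon module MC, coincidence streams of 10³–3×10⁴ events,
reconstruction grids of ~10⁵ voxels with 4–8 iterations, and 2×10⁴
calibration events. Every stochastic stage takes an explicit
`numpy.random.Generator`; identical seeds reproduce list-mode files
bit-for-bit. What passing these tests shows about real data is limited by
what the simulator emulates: no object attenuation/scatter (phantoms ≤1.4 cm
— flag available), no positron range or acollinearity, no charge-transport
physics or depth-dependent trigger delay (only the net 100-ns timing
resolution), no dead time, and chance coincidences only from in-FOV
activity. Quantities dominated by those mechanisms (absolute random rates,
NECR gain magnitudes, scatter fractions) are stream-composition properties
rather than detector-model properties here.

## Known limitations

* The Doppler model is hydrogenic-Slater, not Hartree–Fock; threshold-
  relative rejection quantities shift by a few points with the profile
  shape.
* F is built at normal incidence and reused for oblique source–detector
  geometries (an approximation; the event stream's incidence angles are
  ≤ ~20° in this geometry).
* The fast projector requires axis-aligned panels (the nominal geometry);
  calibrated/rotated-module reconstruction would need the general overlap
  path.
* Calibration optimises a masked parameter subset by local search; the full
  130-parameter estimation is experiment-scale and out of scope.
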