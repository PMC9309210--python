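# Methods

`tmsdose` models, at desk scale, how the choice of transcranial magnetic
stimulation (TMS) intensity translates into induced cortical electric
fields and into the activation of individual pyramidal cells, in two
cortical regions with different folding. This note documents the models,
their assumptions, the parameters that matter, and what the synthetic
data can and cannot show.

## Synthetic participants

A participant is a resting motor threshold (RMT, %MSO) plus a spherical
head geometry with two folded cortical patches. The only measured data
shipped with the package is the 16-row participant table
(`tmsdose/data/table1.tsv`: RMT and coil-to-cortex depth for both
targets); everything else is generated.

* RMTs are drawn uniformly on the integers 41–75 %MSO, the range observed
  in the participant table. Sixteen observed values are too few to
  justify a parametric fit, and four of them are capped at 75 %MSO for
  safety reasons; the generator does not model that censoring.
* Scalp radius 85 mm, cortex radius 78 mm (defaults), jittered
  log-normally with a 2% coefficient of variation; folding parameters
  with 10%. Radii are shared between the two regions of a participant,
  so scalp-to-cortex distance is matched by construction — the analysis
  is designed so that field differences between regions come from
  folding, not depth.

## Head and folding geometry

Each region is an open patch of the cortex sphere, corrugated radially
inward along a corrugation coordinate `u`:

    s(u) = sulcal_depth * ((1 - cos(2*pi*u / wavelength)) / 2) ** crown_exponent

Coordinates are head-centered and right-handed, +z through the M1-like
patch center, +x anterior, lengths in mm. Crowns stay on the cortex
sphere; folding only deepens tissue, so the coil-to-cortex distance of a
folded head is never below the unfolded value. Vertices are classified
into gyral crown / rim / wall / sulcal fundus by thresholds 0.15 / 0.35 /
0.8 on the normalized depth — conventions, not measured boundaries.

The two regions differ in three folding parameters:

| parameter | M1-like | DLPFC-like | role |
| --- | --- | --- | --- |
| wavelength (mm) | 12 | 16 | fold spacing |
| sulcal depth (mm) | 12 | 8 | fold amplitude |
| crown exponent | 2.0 | 0.7 | fold cross-section |

The crown exponent is the load-bearing choice. With a pure cosine
profile the two regions' ROI-mean fields come out statistically
indistinguishable: the deep region's fundi fall outside the 10 mm ROI
ball (they are too far from the ROI center in Euclidean distance) and
the two effects cancel. An exponent above 1 gives the M1-like region
broad, flat crowns with narrow deep sulci — the shape of the precentral
hand knob — so most of its ROI sits superficially; an exponent below 1
gives the DLPFC-like region rounded crowns with broad valleys, keeping
more of its cortex at depth. This reproduces the target contrast
(identical drive produces a 5–12% stronger ROI-mean field in the
M1-like region) robustly across the cohort jitter envelope.

Coil placement follows clinical practice: the coil center sits 4 mm
above the scalp point nearest the target, the handle is the anterior
tangent rotated by the coil angle about the coil normal, and the DLPFC
target is found by moving 50 mm anterior along the scalp *geodesic*
(the "5-cm rule" is a tape-measure rule, so arc length, not chord). The
corrugation axis is rotated 45 degrees from the anterior tangent so that
the field-vs-fold alignment, and hence the strongest ROI mean, lands at
the conventional ~45-degree coil angle.

## Induced electric field

The figure-of-eight coil is two mirrored clusters of magnetic dipoles.
Each wing tiles a disc with equal-area rings of dipoles (default 4 rings
of 8); a flat current loop is magnetically identical to a uniformly
magnetized disc, so this converges to the true loop field — 0.9%
relative error against a 720-segment line-current integral at cortex
depth with the defaults, where a single dipole ring saturates at ~13%.

The primary field is E_p = −∂A/∂t of the dipole sum. The conductor
response uses the classical spherically-symmetric-head result: the
secondary field is −∇φ with φ the interior harmonic function satisfying
∂φ/∂r = E_p·r̂ on the scalp sphere. φ is expanded in real spherical
harmonics; the boundary projection uses an FFT in azimuth plus
Gauss-Legendre nodes in colatitude, and the gradient is evaluated
spectrally with pole-safe ladder identities (cross-checked against
finite differences of φ in the tests). No conductivity value enters the
solution, and the interior field is purely tangential to the head
sphere. The folded cortical surface is an evaluation locus only, not a
conductivity boundary — that is what keeps the closed-form tangentiality
guarantee.

Expansion order defaults to L = 60, chosen so that the interior radial
leakage is below 1e-3 of the field maximum and doubling L changes the
result by less than 1e-4 in relative L2 norm with the default coil
standoff (the dipoles sit only ~4–16 mm outside the scalp sphere, so the
boundary data has a slowly decaying spectrum; L = 40 misses both bounds).

Units: 1 %MSO ≡ 1.49 A/µs of coil-current rate of change; fields in
mV/mm (≡ V/m). The field is exactly linear in the drive, so everything
is computed once at 1 %MSO and scaled. A single calibration constant
anchors the absolute scale: the reference head's M1 ROI mean (10 mm ROI,
45-degree placement) is set to 2.0 mV/mm per %MSO, which puts RMT-scaled
doses in the ~80–180 mV/mm range typical of modeled cortical fields. The
dipole model's raw output is a single-turn winding with no anatomy, so
its absolute scale is not meaningful; the constant is the documented
field-side calibration.

ROI statistics use a 10 mm Euclidean ball around the cortical vertex
nearest the coil center: mean of E_total, tangential and normal
components, plus a robust maximum defined as the nearest-rank 99.9th
percentile (unambiguous and testable as an order statistic).

## Reduced pyramidal cell

The cell is a surrogate layer-5 pyramidal neuron (~145 SWC nodes, ~250
compartments at 20 µm resolution): a soma, a 1 mm axon with initial
segment and two near-horizontal collaterals, an apical trunk with a
spread tuft (total apical extent ≤ 1.2 mm so a cell at 1.25 mm somatic
depth stays inside gray matter), and four oblique basal dendrites.
Channels are generic Hodgkin-Huxley-type: transient Na (m³h),
delayed-rectifier K (n⁴), a slow M-type K current, leak, and a
high-voltage-activated Ca current (m²h) on soma and apical dendrite
feeding a first-order Ca pool (rest 1e-4 mM, decay 80 ms). The leak
reversal is balanced per compartment so the configured resting potential
is an exact fixed point.

Three design choices deserve emphasis, because the default cell would
otherwise contradict the physiology it must reproduce:

* **Fast axonal membrane.** The early polarization of a cable terminal
  under a step field grows like E·sqrt(d·t / (4·Ra·Cm)) — independent of
  the membrane resistance. With the standard 1 µF/cm² everywhere, a
  ~0.3 ms biphasic pulse cannot bring any terminal near threshold at
  realistic field strengths. The axon therefore carries a reduced
  effective capacitance (0.01 µF/cm² in the calibrated default) and a
  high Na density, standing in for the fast
  spike-initiation physics of real axons without modeling explicit
  myelinated structure. This is the documented knob that places
  activation thresholds in the 30–90 %MSO band (M1-like median ≈ 63
  %MSO on the reference head, ~40% of cells censored above 100 %MSO).
  A side effect is that the cell is electrically far more compact than a
  full reconstruction, so absolute synaptic weights (the synaptic
  threshold is ~2.4 nS here) are not comparable to detailed models;
  only relative statements (e.g. "10% of the synaptic threshold") carry
  over.
* **Axon collaterals.** The induced field is tangential to the head and
  the cells stand perpendicular to the cortical surface, so a crown cell
  with a strictly radial arbor would integrate zero quasipotential and
  never fire — contradicting the observation that crown and rim cells
  are the easiest to activate. Near-horizontal collaterals (2 × 300 µm)
  give every cell terminals with tangential reach, with uniform-field
  thresholds of ~105 mV/mm parallel to the somato-dendritic axis and
  ~135 mV/mm perpendicular (parallel stays easier, as polarization
  physics requires).
* **Spike-frequency adaptation.** Without a slow K current the model
  enters tonic ~200 Hz firing after a single pulse (soma and dendrites
  stay depolarized and keep re-exciting the hair-trigger axon). The
  M-type current produces a post-spike hyperpolarization and makes
  threshold-level 10 Hz trains fire on only a subset of pulses, the
  qualitative rTMS behavior this model must show.

Extracellular coupling uses quasipotentials: ψ is the line integral of
−E along the tree (ψ = 0 at the soma/root), evaluated from the analytic
field at every compartment midpoint — no uniform-field shortcut — and
enters the cable equation through the axial differences of V + ψ·s·w(t).
For a two-compartment soma→terminal cable in a field pointing from soma
to terminal, ψ_terminal < ψ_soma and the terminal depolarizes during the
positive phase of w.

The solver is backward Euler with tree-ordered (Hines) elimination —
unconditionally stable for the stiff pulse drive — with staggered
exponential gate updates from tabulated rate functions (0.05 mV grid;
interpolation error far below solver tolerance). Time steps are 0.025 ms,
refined to 0.005 ms around each pulse. Validation: passive steady state
within 0.5% of I·R, membrane time constant within 2%, dt-halving moves
the somatic peak by < 1% at threshold-level drive. If any compartment
exceeds ±200 mV the solver raises a flagged divergence with the failure
time; the threshold search treats such drives as suprathreshold.

The biphasic pulse is one damped-cosine carrier period,
w(t) = cos(2π·3.4 kHz·t)·exp(−t/0.4 ms), peak-normalized; the synapse is
a two-exponential conductance (rise 0.2 ms, decay 2.5 ms, reversal 0 mV,
peak-normalized to its weight) attached to the apical dendrite ~20 µm
from the soma. Synaptic events are scheduled 2 ms before each pulse so
the weak input (10% of the synaptic threshold weight) is active at pulse
time; on its own it evokes no spike, and element-wise it never raises a
cell's TMS threshold.

## Thresholds, dosing, statistics

Cells are placed at surface vertices chosen by farthest-point
subsampling within a 15 mm ROI (desk default 150 cells per region per
participant; the full-scale analyses this emulates used ~1300), soma
1.25 mm beneath the vertex, azimuthal arbor orientation randomized per
placement. The activation threshold is the smallest integer %MSO whose
single pulse evokes an action potential within 5 ms of pulse onset
(0 mV upward crossing, 2 ms refractory), found by geometric bracketing
plus integer bisection with the returned bracket verified (a linear scan
is the fallback on non-monotonicity; on 50 test cells bisection and
exhaustive scanning agree exactly). Cells silent at 100 %MSO are
censored. Threshold analysis runs at the 45-degree coil angle only.

Four intensity-selection strategies are compared: a fraction of RMT
(default 120%), a fixed dose (60 %MSO), E-field-matched (the real-valued
intensity that makes the ROI mean hit 140 mV/mm — exact under the linear
field model, so the across-cohort SD of achieved means is numerically
zero), and the participant's median activation threshold (lower-median
convention, so the dose is an attained threshold). Outcomes are percent
activated among non-censored cells; censored cells are excluded from the
denominator. rTMS scenarios apply 20 biphasic pulses at 10 Hz plus a
200 ms tail to the cells whose thresholds sit nearest 95%, 100% and 105%
of the applied intensity (ties toward the lower threshold), without
synaptic input.

Paired comparisons use a two-sided paired t-test (depths) or the
Wilcoxon signed-rank test (activation percentages) with Bonferroni-Holm
adjustment. The Wilcoxon null distribution is enumerated exactly for
n ≤ 25 via a dynamic program over signed midranks (ties are common after
quantization to whole cells and scipy's exact path does not handle
them); zero differences are dropped before ranking.

## Numerical and degenerate-input conventions

* Nearest-rank percentile: the ⌈q/100·n⌉-th order statistic, with a
  1e-9 slack inside the ceiling so that binary floating point cannot
  bump the rank (0.999·1000 must give rank 999).
* The field solver computes at unit drive and scales once, so linearity
  in the drive is bit-exact for power-of-two factors and within 1 ulp
  otherwise.
* Zero sulcal depth degenerates cleanly: all vertices on the cortex
  sphere, all classified crown, rotationally symmetric sweeps.
* A variability summary of a single value reports its SD as absent
  (NaN), never 0.

## Determinism and problem sizes

Every stage is a pure function of (config, seed): cohorts, placements
and azimuths come from seeded generators, and pipeline re-runs are
byte-identical (fixed CSV float formatting, no timestamps in outputs).
The desk default — 4 participants × 2 regions × 150 cells × 2 synapse
variants, 45-degree analysis — completes in roughly 13 minutes on one
CPU; the test suite uses smaller cohorts and cell counts chosen to
exercise every contract at a fraction of that.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the modeled experiment —
matched scalp-to-cortex depth, region-specific folding, RMT ranges, the
direction of the M1-like vs DLPFC-like field and activation contrasts,
exact standardization under E-field matching, and the
every-other-pulse behavior of threshold-level trains. It does not
reproduce individual anatomy, FEM tissue-conductivity effects,
white-matter anisotropy, reconstructed-cell channel distributions, or
any published per-subject magnitude; passing tests therefore validate
the method's internal logic and directional findings, not subject-level
field or threshold predictions.

## Known limitations

* A single reduced morphology serves the whole population; only rigid
  placement and azimuth vary. No interneurons, no myelinated axon
  structure, no synaptic circuitry or plasticity rules.
* The spherical conductor ignores tissue boundaries; absolute field
  magnitudes are anchored by one calibration constant rather than
  predicted.
* The "Ca²⁺ event" criterion (crossing rest + 5× rest with 20 ms
  separation) and the 5 ms time-lock window are conventions; both are
  configurable.
* Integer-%MSO threshold quantization limits how exactly median-dose
  strategies can equalize activation; ties at the median set the floor.
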