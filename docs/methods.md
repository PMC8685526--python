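# Methods

`afpom` implements an in-silico safety-pharmacology pipeline for atrial
fibrillation (AF): a *population of models* of the chronic-AF human atrial
myocyte is generated and calibrated against action-potential biomarker
ranges, every accepted profile is challenged with a cross-field S1–S2
protocol on 2D monodomain tissue of two sizes and under three drugs, the
outcome (reentry induced / maintained or not) is read off phase-singularity
rotor tracks, and a Random Forest plus a depth-limited decision tree are
trained to predict and explain inducibility from the ionic profile.

## Membrane models

### Ionic model

The default membrane model is a compact Hodgkin–Huxley-type human atrial
myocyte authored for this package. It carries the currents the population
varies or chronic-AF remodeling touches — INa, IK1, Ito, IKur, IKr,
IKCa (SK), ICaL, INaK, INCX, background Na/Ca currents and a sarcolemmal Ca
pump — and a two-compartment Ca subsystem (cytosol + lumped SR) whose SERCA
uptake is modulated by expression scalars for SERCA itself, phospholamban
and sarcolipin (both regulators raise the pump's apparent Kd in proportion
to their abundance). INa kinetics use the classical Luo–Rudy rate
formulation; the K and Ca channel kinetics use standard Boltzmann/bell-shaped
rate forms adapted from the human atrial modeling literature. Intracellular
Na+ and K+ are clamped (11.2 / 139 mM), a common reduction that removes
slow ionic drift irrelevant on the seconds-to-minutes protocols used here.
It is deliberately *not* a transcription of any single published atrial
model: the pipeline's contracts only require a human-atrial-like AP with the
correct parameter sensitivities, and a compact model we fully control is
verifiable where a from-memory transcription of a ~40-state published model
would not be.

Baseline conductances were fixed once so that, *after* chronic-AF remodeling,
the model rests near −83 mV, fires an AP of ≈120 mV amplitude with a
spike-and-plateau morphology, and repolarizes with APD90 ≈ 260 ms at 1 Hz —
inside the chronic-AF stand-in biomarker box below. Two sensitivities are
structural and tested: halving gCaL shortens APD90; raising gK1 shortens
APD90 monotonically.

Chronic-AF electrical remodeling is applied as fixed rescalings of the
baseline: ICaL ×0.45, Ito ×0.38, IKur ×0.62, IK1 ×1.62, NCX ×1.50,
SERCA ×0.84, phospholamban ×1.18, sarcolipin ×0.60. Remodeling is applied
*before* the population multipliers; IKCa is not remodeled and varies only
through its population multiplier.

### Surrogate model

All tissue, phase-analysis and ML stages also run against a two-variable
Mitchell–Schaeffer excitable cell (`dv/dt = h·v²(1−v)/τ_in − v/τ_out + I`,
gate `h` relaxing toward 1 below `v_gate` with τ_open and toward 0 above it
with τ_close; normalized voltage mapped affinely to mV as −80 + 110·v).
Defaults: τ_in = 0.3 ms, τ_out = 2.0 ms, τ_open = 60 ms, τ_close = 265 ms,
v_gate = 0.13. These were chosen once so that (i) the propagated AP on the
calibration strip has APD90 ≈ 156 ms, inside the constraint box; (ii) the
short τ_open gives the abbreviated post-repolarization refractoriness and
steep APD restitution characteristic of AF-remodeled atrium, which is what
lets functional reentry fit on a 16 cm² sheet.

Population multipliers hook in as: m_gNa scales 1/τ_in; m_gK1·m_gKur scales
1/τ_out; m_gCaL scales τ_close; the other multipliers are inert in the
surrogate. Drug factors reach it through the same hooks (Nav1.5 block → τ_in,
Cav1.2 block/enhancement → τ_close; hERG has no surrogate correlate).

What the surrogate does *not* emulate: ionic-current-level pharmacology, Ca
handling, or rate adaptation beyond gate recovery. One visible consequence:
isoproterenol (ICaL up) *lengthens* the surrogate AP and therefore tends to
suppress reentry at desk scale, whereas β-adrenergic stimulation in real
atria is proarrhythmic through mechanisms (APD shortening via IKs/IKur
enhancement, Ca-driven triggers) the surrogate does not carry. Surrogate
results validate the pipeline's plumbing, PDE, phase analysis and ML stages —
not drug-specific biology.

## Population calibration

Candidates are Latin-hypercube samples of the nine multipliers
(gNa, INaK, gK1, gCaL, gKur, IKCa, [Na]o, [K]o, D) on [0.5, 2.0]
(−50 % … +100 %). Each candidate is paced on an 8×256-node strip for 15
beats at 1 Hz (3 ms stimuli at twice the diastolic threshold, found by 1 %
bisection per profile, delivered to a left-edge band), six biomarkers
(APD20/50/90, APA, RMP, V20) are measured at probe cells 500, 620 and 748
(linear index = row·256 + column) and averaged over the last five beats, and
the candidate is accepted only if **all three** probe cells satisfy **every**
bound. V20 is implemented as the voltage at time-offset APD20 after the
upstroke. Candidates whose simulation diverges are rejected with reason
`numerical`; candidates that cannot fire are rejected with reason `no AP`;
neither aborts the batch.

The experimental constraint ranges the original calibration used are not
available, so the package ships documented synthetic stand-ins
(`gen_constraint_box`): APD90 ∈ [150, 350] ms, APD50 ∈ [50, 250] ms,
APD20 ∈ [5, 120] ms, APA ∈ [80, 130] mV, RMP ∈ [−85, −65] mV,
V20 ∈ [−40, 30] mV — plausible chronic-AF atrial values at 1 Hz. A second
variant (`variant="surrogate"`, APD20 ≤ 280 ms, APD50 ≤ 320 ms) exists
because the spike-free surrogate AP repolarizes its first 20 % slowly
(APD20 ≈ 0.75·APD90 on tissue, structurally), which would otherwise make the
default box reject essentially every surrogate profile regardless of APD90.
Real constraint tables replace both through the CSV interface without code
changes.

## Tissue and protocol

The monodomain equation `∂V/∂t = D∇²V − (I_ion − I_stim)/Cm` is solved by
forward Euler with a 5-point Laplacian and mirrored (no-flux) boundaries on
fully insulated square planes: normal 400×400 nodes at 0.01 cm (16 cm²),
dilated 450×450 (20.25 cm²). Gating variables use the exact exponential
(Rush–Larsen) update. The explicit step must satisfy
dt ≤ 0.9·dx²/(4·D_eff); violating calls are refused with a suggested dt.
`D_eff = D_baseline · m_D`. The baseline diffusion coefficient is
calibrated once so a planar surrogate wave at the reference spacing runs at
≈ 40 cm/s (D_baseline = 0.0055 cm²/ms). We target the chronic-AF atrial
conduction-velocity range rather than healthy atrium (~65 cm/s) because with
APD90 ≥ 150 ms a 65 cm/s wave has a ≥ 10 cm wavelength that cannot reenter a
4 cm sheet at all — reentry on these plane sizes requires AF-like slowed
conduction, consistent with the remodeled substrate being modeled.

Induction is cross-field S1–S2: three planar S1 beats at 1 Hz from a
left-edge band (0.5 cm wide; a fixed physical width keeps ignition robust
across grid resolutions), then one S2 over the inferior-left quadrant
(rows ≥ ny/2, columns < nx/2). The S2 coupling defaults to the profile's
measured APD90 plus an offset that lands just past the recovery of
excitability; because gate reopening (τ_open) lags repolarization, an offset
of +10 ms after APD90 falls inside the absolute refractory period and never
captures, so the default offset is +60 ms, and inducibility is assessed like
clinical programmed stimulation: S2 is retried at APD90+100 ms if the first
coupling does not induce (`run_s1s2_induction`). Fixed couplings can be
forced through the protocol config. The observation window after S2 is
2000 ms by default (800 ms in the desk preset). Voltage movies are stored at
1 kHz regardless of the integration step.

Two numerical shortcuts keep desk runs tractable and are exact to numerical
noise: during fully quiescent diastole the surrogate state is relaxed in
closed form to just before the next stimulus (v and h both decay/recover
exponentially at rest), and a run whose plane extinguishes after S2 is
completed with resting frames.

## Reentry analysis

Per node, phase is the argument of the analytic signal (Hilbert transform)
of the mean-subtracted voltage over the post-S2 window; no band-pass is
applied. Constant nodes get an undefined marker and are excluded. A phase
singularity is declared where the winding number of wrapped phase
differences around a 2×2 plaquette is ±1; its sign is the chirality. SPs are
linked frame-to-frame by greedy nearest-neighbor association (matching
charge, link radius 10 nodes, gaps ≤ 2 frames). A track's rotation count is
the median unwrapped phase advance on a ring of radius 3 nodes around the
track centroid divided by 2π — robust to core meander — and tracks with
fewer than one full rotation are discarded. A simulation is *induced* when
at least one track survives that filter, and *maintained* when, in
addition, any node exceeds −60 mV in the final 200 ms of the observation
window. Table-1-style summaries count the maintained flag.

## Experiment grid and classifier

The design table is the full Cartesian product of accepted profiles, the
two sizes and the four conditions (basal, flecainide, verapamil,
isoproterenol); 127 profiles give exactly 1,016 rows. Drugs are encoded
through *effective* multipliers — the profile multipliers times the drug's
conductance factors on the mapped channels (Nav1.5-peak → gNa, hERG → gKr,
Cav1.2 → gCaL) — so all conditions share a single feature space. The
features are the nine effective multipliers plus the tissue area in cm²
(ten features; hERG block acts on the simulated cell but has no varied-axis
feature). Drug factors follow the pore-block law G = G₀/(1+[D]/IC50);
isoproterenol is a saturating Cav1.2 agonist G = G₀·(1+[D]/([D]+EC50)),
doubling at saturation (a linear law is config-selectable). Table
concentrations are interpreted in µM (0.2 µM flecainide, 0.5 µM verapamil,
80 µM isoproterenol) — the scale on which the published half-max values
produce physiologically sensible block fractions.

The predictor is a Random Forest (500 trees, √p features per split, fixed
seed) trained on a stratified 80 % split with 5-fold cross-validation on the
training portion and evaluated on the held-out 20 %. Interpretability comes
from a single CART tree (Gini, depth ≤ 7) fitted on all rows; its
root-to-leaf paths export as a nested sunburst structure (ring i = depth-i
split, leaves labeled induced / non-inducible). On fixtures whose labels
follow the rule m_gK1 > 1.09, the tree recovers the root split and threshold
— the analogue of inward-rectifier conductance being the first and most
important classification variable.

## Synthetic fixtures and what passing means

`synthetic_data` generates, seed-deterministically and with ground truth
attached: closed-form AP waveforms (linear or exponential repolarization)
for the biomarker oracle; rotating-spiral phase movies with known
singularity positions, chiralities and rotation counts for the
phase-analysis oracle; and rule-labeled outcome tables (uniform multipliers,
labels from an AND/OR threshold rule with optional label noise) for ML rule
recovery — including a two-cluster preset encoding the high-gK1/low-D/
high-[K]o/high-gNa/low-gKur and low-gK1/low-[K]o/high-INaK/high-gCaL/
high-IKCa/high-gNa induced-AF archetypes. These fixtures validate each
analysis stage against known answers; they do not validate the
electrophysiology of real atria, and conclusions about specific drugs at
desk scale inherit the surrogate's limitations above.

## Scales, runtimes, degenerate inputs

The full-scale configuration (`paper_config`) — ionic model, 500
candidates, full grids, 1 µs step — reproduces the study conditions and
needs substantial compute. The desk configuration (`desk_config`) — the
study's pipeline at reduced numerical scale — uses the surrogate membrane
model, 100×100 planes of the same physical areas, a 0.04 cm calibration
strip spacing, a 0.1 ms step cap (clamped per-profile to the diffusion
stability bound) and an 800 ms observation window; a complete
20-profile run (calibration, 160 tissue simulations, analysis, training)
takes minutes on one CPU. Desk-scale induction fractions are *qualitative*
analogues of the full-scale counts, not replications.

Degenerate inputs are handled explicitly: non-positive conductances,
out-of-range multipliers, min > max constraint bounds, unknown channel or
geometry labels, probe indices off the strip and single-class training
tables raise typed errors; NaN states name the offending variable and node;
tissue runs that blow up save the partial movie with a failure flag instead
of raising.
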