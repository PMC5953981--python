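# Methods

This note documents the models, numerical choices and limitations behind
`cardiorisk`, in the order of the pipeline.

## Pore-block pharmacodynamics

Drug–channel interaction is a conductance-scaling pore block: at free
concentration C (µM), each measured current's maximal conductance is
multiplied by `1/(1 + (C/IC50)^h)`. The Hill coefficient defaults to 1 and
is honored when a record supplies one. This is a steady-state,
state-independent model: no kinetics of binding/unbinding, no voltage or
use dependence, single chemical entity only (no metabolites or
combinations).

IC50 curation: literature patch-clamp data are heterogeneous, so when a
current carries several records the curation policy (a) restricts to
assays at 33–38 °C whenever any exist — the band is our operational
reading of "near-physiological temperature", the criterion itself being
qualitative — and (b) takes the lowest IC50 from the retained set
(conservative: stronger predicted block), ties broken by input order. An
explicit `selected` column in the input table overrides the policy.
Currents without a measurement are left unblocked rather than imputed.
Units are normalized to µM at ingestion.

## Myocyte model

The cellular substrate is the ten Tusscher 2004 (tT04) human
left-ventricular model — 17 state variables, Hodgkin–Huxley gating, with
the published endo/mid/epi differences in G_to, G_Ks and the s-gate. The
canonical published constants and initial state are used verbatim.
Integration is forward Euler at dt = 0.02 ms (the model's original
scheme), with an optional Rush–Larsen exponential gate update that agrees
with Euler to < 2 ms in APD90 and is available as an accuracy-preserving
acceleration. Halving dt changes APD90 by < 0.1 ms at default settings.
Kernels are numba-compiled; the first call in a session pays a one-time
compilation cost.

Sanity against the published model: at the canonical reference settings
(1 Hz pacing, K⁺ₒ 5.4, Na⁺ₒ 140, Ca²⁺ₒ 2.0 mM, reference morphometry) our
steady-state APD90 values are within ~3–5 % of the published steady-state
figures (epi ≈ 276, endo ≈ 282, mid ≈ 336 ms); residual differences come
from pre-pacing depth and protocol details.

**Virtual individual.** The default subject is a healthy adult
(age 34; K⁺ 5.49, Na⁺ 137.59, Ca²⁺ 2.25 mM; RR 808 ms; cardiomyocyte
volume 8183 µm³, area 2274 µm², capacitance 60.42 pF, SR volume
628.1 µm³; wall thickness 10.8 mm). Plasma ions and RR enter the model
directly. The morphometric covariates have no published mapping into the
tT04 equations, so we scale them proportionally against the model's
reference geometry (185 pF, 16404 µm³, 1094 µm³), which rescales the
Cm/(V·F) flux terms of the concentration ODEs. This is a documented
stand-in: it preserves the model exactly when the covariates equal the
reference values and perturbs only ion-accumulation rates otherwise.
Cell area is carried as metadata.

**Pacing.** Stimulus −52 pA/pF for 1 ms (conventional for tT04) at cycle
length RR; single cells are pre-paced 100 beats to a pseudo-steady state
by default and the final beat is analyzed. Diastolic potential is read
just before the stimulus; APD runs from the maximal-upstroke time to the
fractional repolarization crossing, linearly interpolated. The same
geometry on the Ca transient gives the calcium duration (CaD).

## Fiber and pseudoECG

The transmural wall is a 1D monodomain cable: n = round(length/dx) cells,
dx = 0.1 mm, diffusion D = 0.154 mm²/ms (literature-typical for human
ventricle; forward Euler on the cable is stable at dt = 0.02 ms for this
D/dx²). Composition defaults to 50/30/20 % endo/mid/epi, ordered
endocardium → epicardium with the stimulus at the endocardial end — the
physiological activation sequence; composition fractions are mapped to
integer cell counts by rounding with the remainder absorbed by the
largest fraction, deterministically. Boundaries are zero-flux. The
resulting conduction velocity (~0.7 mm/ms) matches the published tT04
cable value.

Because a 1 ms point stimulus cannot overcome the coupling load of the
cable, fiber pacing uses a 2 ms pulse at the same amplitude, delivered to
the first three endocardial cells.

**Steady state.** Cells are pre-paced to their single-cell limit cycle
(drug block applied) uncoupled, then coupled for 2 fiber beats, the last
of which is analyzed. Coupling perturbs the uncoupled limit cycle mainly
through electrotonic smoothing near interfaces; on the default fiber the
biomarker difference between 2 and 5 coupled beats is below the
biomarker-detector tolerance, while full coupled pre-pacing would
multiply the cost of a 10-concentration featurization by ~50.

**PseudoECG.** A unipolar electrode sits on the fiber axis 20 mm beyond
the epicardial end (standard pseudoECG practice; the absolute amplitude
is in arbitrary units, only intervals are meaningful). The far-field
potential is Φ(t) = −Σᵢ (∂V/∂x)ᵢ · ∂(1/rᵢ)/∂x · dx with central
differences. The sign convention makes the QRS main deflection positive
for endo→epi propagation.

**T-wave polarity.** With the published tT04 layer parameters the
epi−endo intrinsic APD difference (~6 ms) is smaller than the transmural
conduction delay (~16 ms), so repolarization propagates endo→epi and the
T wave at the epicardial electrode is *negative*, unlike the upright
clinical T wave (which reflects a larger epicardial APD shortening than
this parameter set produces). All interval detectors operate on the
rectified baseline-subtracted signal, so T polarity does not affect any
biomarker; transmural heterogeneity is still what generates the T wave
(a homogeneous fiber's T amplitude is an order of magnitude smaller,
which the tests assert).

## Biomarker detectors

* Baseline: median of the pre-QRS window (the recorded beat includes
  50 ms of preceding diastole).
* QRS: onset at the first crossing of 5 % of the QRS peak of
  |Φ − baseline|; J point at the first post-peak sub-threshold excursion
  sustained ≥ 10 ms. Relative thresholds make the detector amplitude-
  and polarity-invariant.
* T wave: peak as the post-J extremum of |Φ − baseline| (20 ms refractory
  gap); end by the tangent method — steepest tangent on the descending
  limb intersected with the baseline — with a 5 %-threshold fallback when
  the limb never descends. On a linear limb the tangent is exact; on a
  Gaussian limb it lands at center + 2σ, which the tests verify against a
  dense-grid oracle.
* QTc: Fridericia by default (the study RR of 808 ms makes the correction
  material; Bazett available and recorded in provenance).
* iCEB = QT/QRS, exact quotient.
* EMW = mechanical end − electrical end. Electrical end is the T-wave
  end. Mechanical end uses a calcium surrogate — the Ca-amplitude
  weighted mean over cells of (activation time + CaD90) — because the
  underlying contraction process is not modeled; the surrogate is
  isolated behind one function so a different operationalization (e.g. a
  fixed-offset contraction model) can be swapped in. Negative EMW
  (electrical systole outlasting mechanical) is the
  proarrhythmia-associated direction.
* Unmeasurable biomarkers (flat signal, no repolarization, conduction
  block) are NaN with explicit flags, never exceptions.

## Features and labels

Each drug is simulated at the fixed grid 0, 0.0001, 0.001, 0.01, 0.1, 1,
10, 30, 100, 500 µM; EMW and iCEB at grid index k (1-based, index 1 =
baseline) form the 20-vector EMW1-10/iCEB1-10. Features are raw values,
not baseline deltas (a delta encoding is available as a switch for
sensitivity analysis). Unmeasurable values at high concentrations are
imputed by last-measurable-concentration carry-forward so the feature
matrix stays complete; an unmeasurable baseline aborts instead, since it
signals an invalid setup rather than a drug effect. Concentrations are
nominal (no plasma-protein-binding correction).

Binary labels follow the CredibleMeds convention: "known risk of TdP" →
TdP(+); "possible", "conditional" and unlisted drugs → TdP(−). Applied to
the published 12-drug validation panel this yields exactly 6 positive and
6 negative compounds.

## ADTree classifier

Hand-built alternating decision tree: root prediction value
½ln((W₊+ε)/(W₋+ε)), then at each of n_iterations = 10 boosting steps
(default; the common default of the reference WEKA implementation) the
(precondition, feature, threshold) triple minimizing the Z criterion is
added, with candidate thresholds at midpoints of consecutive sorted
unique feature values, ε = 1 smoothing (the original formulation's
choice), all existing prediction nodes eligible as preconditions, and
deterministic tie-breaks (lowest Z, then feature index, threshold,
earliest precondition). Instance weights update as w ← w·exp(−y·r(x)).
The margin is the sum of prediction values along all satisfied paths;
probability = logistic(2·margin) — a conventional calibration, isolated
in one function since boosted margins are not inherently calibrated. By
the TdP convention the class mapped to margin > 0 is TdP(−), the reported
probability is that of lacking TdP association, and p ≥ 0.5 (the ≥ side
deliberately) classifies TdP(−). No class re-weighting is applied despite
the 28/68 learning-set imbalance.

Cross-validation is stratified 10-fold (sklearn `StratifiedKFold`,
seeded, seed recorded in outputs); ROC is a hand-rolled threshold sweep
with trapezoidal AUC, cross-checked in tests against the Mann–Whitney
pairwise statistic and sklearn.

## Synthetic data

The generators define the study conditions used by the tests and the
acceptance script.

* Drug level: log-uniform IC50 draws per current with archetype-specific
  bounds — `herg_selective` (IKr 0.01–1 µM, others ≥ 100 µM; labeled
  TdP(+)), `balanced_multichannel` (IKr and ICaL both 0.1–3 µM; TdP(−)),
  `inert` (all ≥ 10⁴ µM; TdP(−)).
* Feature level: 96 compounds with the learning set's 28/68 class split;
  TdP(+) compounds carry a linear EMW decline (40 ms total) and iCEB rise
  (1.5 total) across the ten concentrations, TdP(−) compounds are flat;
  Gaussian noise (5 ms EMW, 0.15 iCEB) approximates simulation- and
  assay-level variability. Effect magnitudes are of the order the
  simulator itself produces for a ~1 µM-IC50 hERG blocker over this grid
  (ΔEMW ≈ −45 ms, ΔiCEB ≈ +2.8 at 500 µM).

What the synthetic level does *not* emulate: correlated features from a
shared physiology, non-monotone dose-responses (e.g. multichannel
self-mitigation), mislabeled compounds, or the literature heterogeneity
of real IC50 panels. Passing the recovery tests therefore demonstrates
that the estimator recovers a monotone dose-response signal at realistic
n, noise and imbalance — not that real-panel accuracy would match.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests use a reduced fiber (6 mm, dx 0.2 mm → 30
cells) with short pre-pacing for dose-response sweeps, and the full
10.8 mm / 108-cell fiber with 100-beat pre-pacing for the baseline
biomarker computation; classifier results average 20 seeds at n = 96.
Reduced-fiber runs are recorded as such in result provenance so they are
never confused with full-scale runs.

## Known limitations

* tT04 only; the updated 2006 variant and the O'Hara–Rudy model are not
  implemented (the module structure accommodates them).
* 1D cable, no 2D/3D tissue, bidomain, anisotropy or torso geometry;
  pseudoECG amplitudes are arbitrary units.
* Pore block is state-independent; no metabolites, no drug combinations,
  no inter-individual or circadian variability (a single fixed virtual
  individual).
* The EMW mechanical end is a calcium surrogate, not a contraction model.
* The probability calibration is conventional, not matched to any
  external implementation; reported probabilities should be read
  comparatively, together with the binary call.
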