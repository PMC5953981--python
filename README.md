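# cardiorisk

In silico assessment of torsade-de-pointes (TdP) risk for single chemical
entities, intended for early drug-development triage (e.g. anti-infective
candidates with suspected hERG liability). From a compound's patch-clamp
ion-channel inhibition profile the package simulates drug effects on a
biophysically detailed human left-ventricular cardiomyocyte fiber, derives
pseudoECG biomarkers across a fixed concentration grid, and classifies the
compound with an alternating decision tree whose output is the probability
that it *lacks* a TdP association.

## What it computes

**Pharmacology.** Each blockable current (IKr/hERG, IKs, INa, ICaL) is
scaled by the simple pore-block factor

```
scale = 1 / (1 + (C / IC50)^h)
```

with the IC50 curated per current: assays near physiological temperature
(33–38 °C) are preferred, then the lowest IC50 wins (a conservative rule
for heterogeneous literature data).

**Electrophysiology.** The ten Tusscher 2004 (tT04) human ventricular
myocyte model — endocardial, midmyocardial and epicardial variants — is
integrated by forward Euler (optional Rush–Larsen gate update), either as
a paced single cell or as a heterogeneous 1D monodomain cable (default
50 % endo / 30 % mid / 20 % epi over a 10.8 mm wall). A unipolar electrode
beyond the epicardial end yields the pseudoECG

```
Φ(t) ∝ −∫ (∂V/∂x) · ∂(1/r)/∂x dx
```

**Biomarkers.** From the pseudoECG: QRS, QT, QTc (Fridericia or Bazett),
J-Tpeak, Tpeak−Tend, the index of cardiac electrophysiological balance
iCEB = QT/QRS, and the signed electromechanical window EMW (end of
mechanical systole − end of electrical systole, with a calcium-transient
surrogate for mechanical systole). From the cell: APD50/APD90 and
calcium-transient duration.

**Classification.** Each drug is simulated at the fixed grid
0, 0.0001, 0.001, 0.01, 0.1, 1, 10, 30, 100, 500 µM; the twenty features
EMW1-10 and iCEB1-10 feed an alternating decision tree (ADTree) trained by
minimizing the boosting criterion

```
Z = 2[√(W₊(c1∧c2)·W₋(c1∧c2)) + √(W₊(c1∧¬c2)·W₋(c1∧¬c2))] + W(¬c1)
```

The margin maps to a probability via `p = logistic(2·margin)`; p ≥ 0.5
classifies TdP(−). Risk labels follow the CredibleMeds convention: only
"known risk of TdP" counts as TdP(+). Stratified ten-fold cross-validation
and ROC analysis are built in.

## Worked example

```python
from cardiorisk import (VirtualIndividual, FiberConfig, simulate_fiber,
                        extract_biomarkers, DrugProfile, CurrentMeasurement,
                        block_state)

individual = VirtualIndividual()          # healthy adult, RR 808 ms
drug = DrugProfile("herg_blocker", [CurrentMeasurement("IKr", ic50=1.0)])

for conc in (0.0, 10.0):
    blk = block_state(drug, conc)         # 10 µM → IKr scale 1/11
    res = simulate_fiber(individual, FiberConfig(), blk,
                         n_beats=2, prepace_beats=100)
    bm = extract_biomarkers(res, rr=individual.rr)
    print(f"{conc:5.1f} µM  QRS {bm.qrs:5.1f}  QT {bm.qt:5.1f}  "
          f"iCEB {bm.iceb:5.2f}  EMW {bm.emw:6.1f}")
```

prints

```
  0.0 µM  QRS  28.6  QT 304.4  iCEB 10.64  EMW  -21.5
 10.0 µM  QRS  29.0  QT 349.1  iCEB 12.04  EMW  -57.2
```

i.e. a selective hERG blocker at 10 µM prolongs QT by ~45 ms while QRS is
untouched, so iCEB rises and the electromechanical window becomes markedly
more negative — the proarrhythmia-associated direction that the classifier
exploits. (The pseudoECG of a thin simulated fiber has a much shorter QRS
than a clinical ECG, so absolute iCEB values are not comparable to
clinical ones; their drug-induced changes are what matters.)

The same pipeline is scriptable from a shell:

```
cardiorisk synth features --out features.csv
cardiorisk crossval --features features.csv --seed 1 --out cv/
cardiorisk roc --predictions cv/predictions.csv --out cv/
```

Fully synthetic inputs at both levels — IC50 tables with known generative
risk class, and EMW/iCEB feature tables with a controllable dose-response
signal — come from `cardiorisk.synth`, so every stage is testable without
external data.

## File formats

* Drug table (CSV/XLSX): `drug, current, ic50, ic50_unit, hill,
  temperature_c, holding_mv, depolarization_mv, repolarization_mv,
  measurement_mv, source, selected`; IC50s are normalized to µM on read
  and the optional `selected` column overrides the curation policy.
* Labels (CSV): `drug, category` with CredibleMeds-style category strings.
* Features (CSV): `drug, label, emw_1..emw_10, iceb_1..iceb_10`.
* Models: JSON (root score, rules, conventions); every CLI run writes a
  `provenance.json` with configuration hash and seed.

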