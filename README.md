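# afpom — in-silico drug-effect prediction on atrial fibrillation

`afpom` is a population-of-models pipeline for safety pharmacology of
atrial fibrillation (AF). It is aimed at computational
electrophysiologists who want to ask: *given a patient-like spread of ionic
conductances, which electrophysiological profiles will sustain reentry, how
do tissue size and drugs shift that, and can an interpretable classifier
state the thresholds?*

The pipeline has four stages:

1. **Population.** Latin-hypercube sampling varies nine quantities of a
   chronic-AF human atrial myocyte model — g_Na, I_NaK, g_K1, g_CaL, g_Kur,
   I_KCa, [Na]ₒ, [K]ₒ and the tissue diffusion coefficient D — from −50 % to
   +100 % of baseline. Each candidate is paced 15 beats at 1 Hz on an 8×256
   strip and kept only if six AP biomarkers (APD20/50/90, APA, RMP, V20) at
   three probe cells fall inside experimental constraint ranges.
2. **Tissue simulation.** Every accepted profile is challenged with a
   cross-field S1–S2 protocol on 2D monodomain sheets
   (∂V/∂t = D∇²V − (I_ion − I_stim)/C_m, forward Euler + Rush–Larsen,
   no-flux borders) of a normal (16 cm²) and a dilated (20.25 cm²) atrium,
   at baseline and under flecainide, verapamil and isoproterenol, modeled by
   the pore-block law G = G₀ / (1 + [D]/IC₅₀) (isoproterenol: a saturating
   I_CaL agonist).
3. **Reentry analysis.** Phase maps from the Hilbert transform, phase
   singularities from the ±2π winding number, greedy rotor-track linking;
   a run is *induced* if a singularity persists ≥ 1 full rotation after S2
   and *maintained* if the tissue is still active at the end of the
   observation window.
4. **Learning.** A Random Forest (80/20 stratified split, 5-fold CV)
   predicts inducibility from the nine post-drug effective multipliers plus
   tissue area, and a depth-≤7 decision tree exports its root-to-leaf paths
   as a sunburst for interpretation.

Two membrane models ship: a compact Hodgkin–Huxley-type human atrial
ionic model with chronic-AF remodeling (I_CaL −55 %, I_to −62 %,
I_Kur −38 %, I_K1 +62 %, NCX +50 %, SERCA −16 %, PLB +18 %, SLN −40 %), and
a fast two-variable Mitchell–Schaeffer surrogate used for desk-scale runs
and stage-by-stage validation. See `docs/methods.md` for the science and
all numerical choices.

## Worked example

A complete desk-scale run (surrogate membrane model, 100×100 planes of the
full physical areas, 20-profile population):

```python
from afpom.config import desk_config
from afpom import pipeline
import pandas as pd, json

cfg = desk_config(n_profiles=20, seed=1234)
out = pipeline.run_pipeline(cfg, outdir="run")

labeled = pd.read_csv(out / "labeled_table.csv")
print(labeled.groupby(["tissue", "condition"])["label"]
      .apply(lambda s: (s == "induced").sum()))
print(json.loads((out / "model.json").read_text())["holdout_accuracy"])
```

Output of this exact run (seed 1234, ~6 minutes on one CPU):

```
tissue   condition
dilated  basal            3
         flecainide       4
         isoproterenol    3
         verapamil        1
normal   basal            2
         flecainide       4
         isoproterenol    2
         verapamil        0
Name: label, dtype: int64
0.9375
```

Reading: of 20 calibrated profiles, reentry was induced and maintained in 2
on the normal plane and 3 on the dilated plane at baseline — the dilated
tissue fibrillates more readily. Verapamil's strong I_CaL block (factor
1/6 at 0.5 µM) abbreviates the surrogate AP below the reentry regime for
almost every profile (antiarrhythmic), while flecainide's weak block at
0.2 µM barely moves the substrate and even unmasks reentry in two profiles —
the antagonistic-response phenomenon the population approach is built to
expose. The forest classifies held-out rows at 93.8 % accuracy.

The same stages run from the shell:

```bash
afpom run-all --desk --seed 1234 --out run
afpom fixtures --out fixtures      # synthetic constraint box + ML fixtures
```

The full-scale study configuration (`paper_config()`: ionic model, 500
candidates, 400×400/450×450 planes, 1 µs step, 1,016 simulations) is the
same code path and needs substantial compute.

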