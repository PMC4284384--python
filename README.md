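# endokin

Quantification of receptor-mediated internalization kinetics of
biopharmaceuticals from two-channel live-cell imaging, plus a mechanistic
target-mediated drug disposition (TMDD) simulator that puts the measured rate
constant into a translational PK-PD context.

## Who this is for

Scientists characterizing antibodies, ligands or other biologics that bind
cell-surface receptors and are carried into the cell with them.  The
internalization rate constant `k_int` drives receptor-mediated drug clearance,
target occupancy and the displacement of endogenous ligand, so measuring it
reliably matters for target evaluation, affinity goal setting and clinical
dose projection.

## What it computes

**Image analysis.**  Cells are imaged in two channels: a cytoplasmic
reference dye (e.g. CFSE) that defines cell bodies, and the fluorescently
tagged drug whose signal appears as compact spots.  The algorithm

1. thresholds the reference channel into an initial mask,
2. segments it into cell objects (watershed splitting of touching cells,
   round or irregular outlines, optional marker-channel gating for mixed
   populations),
3. builds a *membrane region* (a band extending a few pixels in and out of
   each object boundary) and a *cytoplasm region* (the remaining interior),
4. detects candidate fluorescent spots in the signal channel inside those
   regions, accepts or rejects each one on intensity, contrast and size, and
5. integrates accepted-spot intensity per unit region area, pooling all
   fields of a well.

**Kinetics.**  The cytoplasm signal is normalized by the total cell signal at
each time point, `f(t) = S_cyt / (S_cyt + S_mem)`, and fitted by nonlinear
least squares to

```
S_cyt(t) = S_0,cyt + (1 − e^(−k_int·t)) · S_max,cyt,        T½ = ln2 / k_int
```

per replicate well, reported as mean ± SD across wells.  An
acid-dissociation calculator (`1 − FL_acid/FL_PBS` per condition) covers the
orthogonal end-point assay.

**TMDD PK-PD.**  A six-state ODE model in which the antibody and an
endogenous ligand compete for the receptor, each complex internalizing at its
own rate: two-compartment antibody disposition (CL_RES 0.186 L/day, V_c
3.06 L, V_p 1.77 L, Q 0.294 L/day), ligand baseline 0.01 nM with a 2-h serum
half-life, steady-state initialization, and scenario grids over receptor
expression (R₀ = 0.1/0.6 nM), affinity (K_d = 0.1/0.3/1 nM) and
internalization T½ (30 min / 2 h) after a single 100 mg IV dose.

**Synthetic ground truth.**  No public image set exists for this assay, so
`endokin.synthetic` generates seeded two-channel time-lapse plates —
suspension, adherent (irregular outlines), low-expression (~5,000
receptors/cell signal scale), receptor-over-expressing and mixed
marker-positive populations — in which every cell's true membrane/cytoplasm
signal follows the exponential law exactly.  Every pipeline stage is
validated against this generator.

## Worked example

Simulate three replicate suspension wells with a ground-truth half-life of
34 min, run the full pipeline on the rendered images, and fit:

```python
from endokin.bench import recover_t_half

res = recover_t_half("suspension", t_half_min=34.0, n_wells=3, seed=7)
print(res.summary())
```

```
Internalization kinetics fit
  model: S_cyt(t) = S0 + (1 - exp(-k_int t)) Smax   [normalized fraction]
  replicates: 3

     replicate   k_int/min      S0    Smax  T1/2 min        RSS   flag
           W01     0.02000   0.095   0.800     34.66  1.109e-06     ok
           W02     0.01983   0.093   0.801     34.96  1.007e-06     ok
           W03     0.02017   0.095   0.800     34.37  1.341e-06     ok

  T1/2 = 34.7 +/- 0.3 min (mean +/- SD across wells)
```

Each row is one well fitted independently: `k_int` in 1/min, the initial and
maximal cytoplasmic fractions, and the half-life `ln2/k_int`.  The recovered
34.7 ± 0.3 min agrees with the 34-min truth; the generator's default Poisson +
read noise is on.

The same analysis is available from the shell over a directory of TIFFs —
`endokin generate`, `endokin run`, `endokin fit`, `endokin acid-calc`,
`endokin simulate-tmdd`; see `endokin --help`.

## Layout

```
src/endokin/
  synthetic.py     seeded two-channel generator with exact ground truth
  segmentation.py  mask -> cell objects -> membrane/cytoplasm regions
  spots.py         spot detection, accept/reject, per-area integration
  kinetics.py      normalization, InternalizationModel/Results, acid assay
  tmdd.py          six-state TMDD ODE model, steady state, scenario grids
  pipeline.py      TIFF I/O, run configuration, end-to-end orchestration
  bench.py         pipeline-level parameter-recovery experiments
  cli.py           click CLI
docs/methods.md    model, assumptions, parameter choices, limitations
```
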