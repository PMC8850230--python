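# octatex

Quantitative textural analysis of en-face OCT angiography (OCTA) images of
the choriocapillaris, for studies of central serous chorioretinopathy (CSC)
and related choroidal disease. The package is aimed at retinal-imaging
researchers who want an objective, operator-independent grading of
choriocapillaris texture from routine 3 × 3 mm OCTA exports, plus the
standard sector-wise capillary flow density (CFD) group statistics.

## The method

Healthy choriocapillaris appears on an en-face OCTA slab as a finely
homogeneous speckle; CSC produces dark flow voids that coarsen the texture.
The pipeline quantifies this as follows.

**Autocorrelation lag curves.** For an 8-bit slab *I* (512 × 512 px,
5 μm/px), the unbiased spatial autocorrelation at integer offset
Δ = (Δx, Δy) is

    ρ(Δ) = [ Σ over valid pairs (I(x) − μ)(I(x+Δ) − μ) / N_valid(Δ) ] / σ²

with the whole-image mean μ and variance σ², and
N_valid(Δ) = (H−|Δy|)(W−|Δx|) actually overlapping pairs (no periodic
wrap). Because μ and σ² are global, ρ is exactly invariant under
brightness/contrast changes a·I + b. The 2D map is pooled into radial
bins d = round(|Δ|), d = 0…30 px (0–150 μm), giving the lag curve ρ(d).
Two features summarise it: the **zero crossing** (first lag with
ρ ≤ 0 — about 90 μm = 18 px for fine control-like texture) and the
**plateau level** (mean ρ over 100–150 μm — near 0 for controls, roughly
0.05–0.2 for coarse flow-void texture).

**PCA grading index.** The cohort's curves (lags 1–30) form a matrix;
PCA on centred columns concentrates nearly all variance on PC1, and each
subject's PC1 score is its *textural grading index*, oriented so controls
sit at the low end.

**Six patterns A–F.** The index is binned by five ascending cuts (pooled
sextiles by default, persisted for reproducibility) into the six
choriocapillaris patterns, ordered by coarseness A, B, E, D, C, F
(A roughest, F finest).

**CFD statistics.** Per-sector case/control comparisons via two-sample
t-tests (pooled or Welch), computable either from raw per-subject values
or directly from printed (mean, SD, n) summaries, plus Pearson χ² tests
and Cohen's κ for intra-observer agreement.

Because no public image corpus exists for this analysis, the
`synthetic_data` module generates seeded cohorts with controlled texture
statistics: Gaussian random fields (normalized ACF exp(−d²/4σ²), σ = 2 px
for controls, 8 px for cases) with lognormal-radius dark spots for cases,
and CFD tables drawn from the published sector group parameters.

## Worked example

```
$ python -m octatex.cli simulate --out-dir cohort --seed 1 --n-control 5 --n-case 5
wrote 10 images + manifest to cohort
$ python -m octatex.cli all --manifest cohort/manifest.csv --out-dir cohort/results --cfd-csv cohort/cfd.csv
report written to cohort/results
```

`cohort/results/subjects.csv` then holds per-subject features, index and
pattern:

```
subject_id   group  zero_crossing_um  plateau_rho  grading_index pattern
      C000 control             115.0    -0.001533      -1.234177       F
      C002 control              90.0     0.001671      -1.230356       D
      P000    case             150.0     0.192553       1.242916       B
      P002    case             150.0     0.221548       1.401308       A
```

Controls decorrelate (zero crossing ≤ 115 μm, plateau ρ ≈ 0) and score
low; case curves never reach zero within 150 μm (censored), plateau at
ρ ≈ 0.07–0.24 and score high — the index separates the arms with no
overlap. `report.json` records the explained-variance vector (PC1 ≈ 99%
here), the pattern cuts and every exclusion.

The same steps run as a narrative analysis in `analysis/01…04`
(simulation → curves → grading/classification → CFD statistics), writing
tables under `results/`.

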