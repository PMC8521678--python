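# lrtme

Spatial and single-cell statistics for the tumor microenvironment of
**lymphocyte-rich classic Hodgkin lymphoma (LR-CHL)**.

In classic Hodgkin lymphoma the malignant CD30⁺ Hodgkin/Reed–Sternberg
(HRS) cells make up under 1% of the tumor; the disease biology lives in
the surrounding immune infiltrate. In the rare lymphocyte-rich subtype
that infiltrate is distinctive: a CD4⁺PD-1⁺CXCL13⁺CXCR5⁻ T-follicular-
helper-like population forms **rosettes** — rings of T cells immediately
surrounding HRS cells — and, being a CXCL13 source, draws CXCR5⁺ B cells
into the neighborhood. This package implements the quantitative workflow
for characterizing that architecture from two kinds of tabular data a
core facility typically produces:

- **segmented-cell tables** from multicolor immunofluorescence (one row
  per cell: coordinates in µm, per-marker mean intensities), and
- **cluster-labeled single-cell expression matrices** (cells × genes,
  sparse MTX with cell/gene annotation TSVs).

It is written for analysts who receive such exports and need defensible,
reproducible statistics rather than ad hoc notebook code. Patient data
from the motivating study are controlled-access, so the package ships a
fully parameterized synthetic generator that plants the same structure
(rosettes, subtype-dependent composition and coexpression, survival
differences) with ground-truth labels, which is also how the test suite
validates every estimator end to end.

## What it computes

| Module | Operations |
|---|---|
| `lrtme.phenotyping` | threshold gating (strict `intensity > cutoff`; parameter-free exact-Otsu default), priority-ordered phenotype assignment, exclusive coexpression-pattern counts (UpSet-style) |
| `lrtme.spatial` | neighborhood proportions within a radius (default 75 µm) around a reference population, mean nearest-neighbor distances, touching-cell pairs (center distance ≤ 10 µm), rosette calls (≥ 5 ring cells within the radius), Welch-t/ANOVA group comparison |
| `lrtme.sc` | per-sample cluster composition and cell-type ratios, Wilcoxon rank-sum differential expression with Benjamini–Hochberg q-values and the volcano rule (q < 0.05, \|log₂FC\| ≥ 1), diffusion-map embedding with gene–dimension correlations, ligand–receptor interaction scores (mean ligand in senders × mean receptor in receivers, per condition) |
| `lrtme.cohort` | integer percentages, 2×2 Fisher/odds-ratio crosstabs, point-biserial status–marker correlations, Kaplan–Meier curves, two-group log-rank tests, median-split biomarker stratification |
| `lrtme.synthetic` | generators for spatial maps with planted rosettes, negative-binomial expression matrices with subtype-dependent composition/coexpression, and exponential survival cohorts |
| `lrtme.io`, `lrtme.pipeline`, `lrtme.cli` | TSV/MTX readers and writers with provenance headers, a seeded `run-all` pipeline with a hash manifest, and the `lrtme` command-line tool |

The statistical core in the field's notation: the Kaplan–Meier estimator
S(t) = ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ); the log-rank statistic
χ² = (O − E)²/V with E and V the hypergeometric expectation and variance
of group-0 events accumulated over distinct event times; BH q-values
q₍ᵢ₎ = min_{j ≥ i} p₍ⱼ₎ m/j; and the diffusion map as the leading
nontrivial right eigenvectors (scaled by eigenvalue) of the
density-normalized transition operator P = D⁻¹K with
K = exp(−d²/2ε²)/(qᵢqⱼ).

## Worked example

```python
from lrtme import synthetic, phenotyping, spatial, sc, cohort

# 1. a synthetic 4-sample spatial cohort with planted rosettes
cells, truth = synthetic.generate_spatial(
    synthetic.default_spatial_spec(n_samples=4, seed=0))
gated = phenotyping.assign_phenotypes(
    phenotyping.gate_cells(cells), synthetic.default_phenotype_defs())
_, rosettes = spatial.call_rosettes(gated, "HRS", "TFH_CXCL13")
print(rosettes)
```

```
sample_id  n_hrs  n_rosette  rosette_fraction  case_positive  evaluable
     S000     10          5               0.5           True       True
     S001     10          5               0.5           True       True
     S002     10          5               0.5           True       True
     S003     10          5               0.5           True       True
```

Half of each sample's HRS cells were planted with a six-cell
CD4⁺PD-1⁺CXCL13⁺CXCR5⁻ ring at 20 µm; Otsu gating plus rosette calling
recovers the planted fraction of 0.5 exactly.

```python
# 2. differential expression in the TFH cluster, LR vs other subtypes
adata = synthetic.generate_expression(
    synthetic.default_expression_spec(seed=1))
tfh = (adata.obs["cluster"] == "TFH").to_numpy()
lr = (adata.obs["subtype"] == "LR").to_numpy()
de = sc.differential_expression(adata, tfh & lr, tfh & ~lr)
print(de.sort_values("log2_fold_change", ascending=False).head(3))
```

```
   gene  log2_fold_change  p_value  q_value  significant
 CXCL13             5.446      0.0      0.0         True
  PDCD1             1.230      0.0      0.0         True
HLA-DRA             0.978      0.0      0.0        False
```

CXCL13 tops the list (the planted LR-specific TFH signal); HLA-DRA is
upregulated but fails the |log₂FC| ≥ 1 volcano threshold.

```python
# 3. outcome: log-rank on the phenotype-high vs -low split
sv = synthetic.generate_survival(synthetic.default_survival_spec(seed=2))
res = cohort.logrank(sv["time_years"], sv["event"], sv["phenotype_high"])
print(f"chi2={res.chi_square:.3f} p={res.p_value:.4f}")
```

```
chi2=6.918 p=0.0085
```

The same chain is available from the shell:

```sh
lrtme run-all --out demo --seed 17      # simulate → gate → spatial → sc → survival
lrtme simulate --seed 2 --out demo2
lrtme gate demo2/cells.tsv --out demo2/gated.tsv
lrtme spatial demo2/gated.tsv --out-dir demo2/spatial
lrtme survival demo2/cohort.tsv --out-dir demo2/surv
```

`run-all` writes a `manifest.json` recording parameters, the seed, and a
SHA-256 per output; rerunning with the same seed reproduces identical
hashes.

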