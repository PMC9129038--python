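# nucleofish

Quantification of the subnuclear position of individual gene alleles from
3D DNA/RNA FISH image stacks, and the statistics that link that position
to parental origin, epigenotype and transcriptional state.

## The problem

In fixed nuclei, a DNA-FISH probe marks the two alleles of a locus and a
nascent-RNA probe reports whether each allele is transcribing.  The
nuclear periphery (lamina) is a broadly repressive environment, so a
recurring question in nuclear-organisation studies of imprinted loci —
here the mouse *Dlk1-Dio3* domain and its maternally expressed
*Gtl2/Meg3* gene — is whether an allele's distance from the periphery
tracks its parental origin, its epigenotype, or simply whether it is
being expressed.  Answering it requires, per nucleus:

1. a binary chromatin mask from the DNA counterstain (DAPI),
2. the signed 3D Euclidean distance *d* from each FISH-signal centre to
   the chromatin border on the anisotropic voxel grid (negative when a
   peripheral signal falls just outside the mask),
3. the local nuclear radius *r* (centroid-to-border ray through the
   signal) and the relative distance *d/r*,
4. equal-volume radial shells (outer/middle/inner thirds),
5. per-allele expression calls from the RNA channel,

and then, over thousands of alleles, the model battery

- OLS: `d ~ genotype + volume` (parental-origin contrast, volume-adjusted),
- linear mixed model: `d ~ n_expressed + volume + (1 | cell)` for the
  two correlated alleles of one nucleus,
- logistic: `expressed ~ d + volume`,
- Fisher exact test of near/far allele rank against expression,
- chi-squared tests of expression against radial shells or a 0.5 µm
  peripheral band.

Everything is testable without any microscope data: the
`simulate` module renders image stacks with known nucleus shape, spot
positions and true border distances, and draws allele tables with known
group means, cell-level random intercepts and logistic expression
structure, so each stage can be validated against ground truth.

## Worked example

```python
import nucleofish as nf

cfg = nf.SimulationConfig(seed=0, n_cells=300)
table = nf.simulate_allele_table(cfg, groups=["matrepKO", "patrepKO"])
print(nf.summarize_groups(table).to_string(index=False))
print(nf.fit_distance_model(table).summary())
```

```
genotype     mean       sd   n
matrepKO 1.602923 0.889000 300
patrepKO 1.796240 1.013194 300

linear model: distance_um ~ C(genotype, Treatment(reference='matrepKO')) + volume_um3
n_obs = 600
term                              estimate        SE       t      df         p
Intercept                           1.4248    0.1952   7.301     597 9.187e-13
genotype[patrepKO]                  0.1902    0.0779   2.442     597   0.01489
volume_um3                          0.0004    0.0004   0.951     597     0.342
```

`matrepKO` cells carry the probe-target deletion on the maternal
chromosome, so their single signal is the *paternal* allele;
`patrepKO` cells show the *maternal* allele.  The generator placed the
maternal population at 1.81 µm and the paternal at 1.58 µm from the
border; the volume-adjusted regression recovers a positive slope of
about 0.19 µm (maternal alleles deeper in the nucleus, *p* ≈ 0.01) —
the small parental-origin displacement the method is designed to detect.

The same battery runs on measured images:

```sh
nucleofish simulate --seed 3 --n-nuclei 20 --out data/        # or real TIFFs + ROI csv
nucleofish segment --stacks data/ --rois data/rois.csv --out results/
nucleofish analyze --table results/allele_table.csv \
    --analysis summary --analysis parental --analysis shells --out results/
```

`segment` writes the allele table (one row per allele: signed distance,
local radius, relative distance, shell, near/far rank, expression state,
nuclear volume), a QC report (fractions of negative distances and
ellipsoid-fallback nuclei, logged exclusions) and `analyze` the model
result tables plus a plain-text report.

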