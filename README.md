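# nucshift

Single-cell quantification of NF-κB nuclear translocation in multiplex
immunofluorescence images of liver tissue.

NF-κB (p65) signals inflammatory activation by relocating from the cytoplasm
to the nucleus. In liver sections stained for DAPI (nuclei), phalloidin
(F-actin cell boundaries), NF-κB and GFAP (hepatic stellate cells, HSCs),
this package segments hepatocyte nuclei and cytoplasm, measures per-cell
mean NF-κB intensities, normalizes them across images, and summarizes
activation per cell with a geometrically scaled **nuclear fraction**. It is
aimed at researchers quantifying transcription-factor localization in tissue
at single-cell resolution — particularly in models of chronic ethanol
adaptation and liver regeneration after 70% partial hepatectomy (PHx). A
synthetic tissue generator with known ground truth stands in for real
acquisitions, so the whole measurement chain can be validated end to end.

## The statistic

A hepatocyte nucleus occupies about 6% of the cell volume. For concentric
spheres sectioned at the nuclear equator the area fraction is
*a* = *v*^(2/3) ≈ 0.15, so per cell

```
NF = (0.15 · I_N) / (0.15 · I_N + 0.85 · I_C)
```

where *I_N* and *I_C* are the mean nuclear and cytoplasmic NF-κB
intensities. NF is invariant under common rescaling of both intensities, so
the per-image normalization factors (global mean ÷ image mean, observation-
weighted) cancel inside it. Group differences in mean NF are tested by
label-shuffling permutation (exact enumeration for small samples, 10,000
Monte-Carlo iterations by default) and by the unpaired Wilcoxon rank-sum
test; subpopulations appear as modes of the 2D kernel density in
(*I_N*, *I_C*) space; HSCs, whose footprint is mostly nucleus, are compared
by whole-cell intensity and the all-pairs exceedance probability
P(A > B) + ½·P(A = B).

## Worked example

Generate the four diet × surgery conditions at quarter scale, normalize,
compute nuclear fractions, and compare the two baseline groups:

```python
import pandas as pd
from nucshift import (study_conditions, generate_cell_table, IntensityNormalizer,
                      add_nuclear_fraction, permutation_test, kde2d, count_modes,
                      exceedance_probability)

specs = study_conditions(seed=0, scale=0.25)
tables = {g: generate_cell_table(s) for g, s in specs.items()}
df = pd.concat([tables["carbohydrate_baseline"], tables["ethanol_baseline"]])
df = add_nuclear_fraction(IntensityNormalizer().fit(df).transform(df))

hep = df[df.cell_type == "hepatocyte"]
nf = {g: s["nuclear_fraction"].to_numpy() for g, s in hep.groupby("group")}
res = permutation_test(nf["carbohydrate_baseline"], nf["ethanol_baseline"],
                       n_iterations=10000, seed=0)
```

Output of the full script (seed 0):

```
cells: carbohydrate=985, ethanol=734
carbohydrate_baseline: KDE modes = 1, mean nuclear fraction = 0.1132
ethanol_baseline: KDE modes = 2, mean nuclear fraction = 0.1230
permutation test: observed |d-mean| = 0.0098, p = 9.999e-05 (montecarlo)
rank-sum p = 9.72e-19
HSC exceedance P(ethanol > carbohydrate) = 0.887 (n = 33, 38)
```

Reading the numbers: the ethanol-adapted hepatocytes split into two
intensity subpopulations (2 KDE modes vs 1 in the pair-fed control), their
mean nuclear fraction is shifted upward by ~0.01, and no permuted labeling
out of 10,000 reproduced a difference that large (the reported p is the
add-one Monte-Carlo bound 1/(B+1)). Most ethanol-group HSCs exceed the
control HSCs in whole-cell NF-κB.

The same analysis runs from the shell:

```bash
nucshift simulate --outdir out --seed 0 --scale 0.25
nucshift run --config config.yaml --seed 0 --outdir out   # full pipeline
nucshift analyze --in out/measurements.csv --permutations 10000 --seed 0
```

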