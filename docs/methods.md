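# Methods

## Model and procedure

The analysis treats every segmented cell as a pair of compartments with mean
target-channel intensities: nuclear (*I_N*, over the DAPI-derived nucleus
object) and cytoplasmic (*I_C*, over the phalloidin-bounded cytoplasm
object). Activation per cell is the scaled nuclear fraction

NF = (a·I_N) / (a·I_N + (1−a)·I_C),

where the nuclear area weight *a* comes from a concentric-sphere model of
the cell: a nuclear volume fraction *v* gives an equatorial cross-sectional
area fraction *a* = *v*^(2/3). At the hepatocyte default *v* = 0.06 this is
0.1533; the statistic uses the conventional rounded weights 0.15/0.85 by
default (`GeometryParams(area_rounding=2)`), with `area_rounding=None`
giving the exact power law for sensitivity analyses. The assumptions are
explicit: spherical concentric compartments, optical section through the
nuclear equator, and intensity proportional to local protein amount. NF is
bounded in [0, 1], strictly increasing in *I_N*, strictly decreasing in
*I_C*, and invariant to any common rescaling of both intensities — the last
property is what makes it robust to per-image illumination differences.

Hepatic stellate cells are small and nucleus-dominated, so a
nuclear/cytoplasmic split is unreliable; they are measured whole-cell only
and compared between groups by the all-pairs exceedance probability
P(A > B) + ½·P(A = B), computed from the Mann-Whitney U statistic (tie mass
split in half, so exceedance(A,B) + exceedance(B,A) = 1 exactly).

## Segmentation

Nuclei: threshold the DAPI channel (Otsu by default; a fixed threshold mode
exists for reproducibility studies), label 4-connected components, filter by
area bounds, relabel consecutively. Blank images yield zero objects, not an
error. Touching-nuclei splitting (watershed) is deliberately not
implemented; the synthetic fixtures are generated disjoint and no splitting
rule is defined for them.

Cytoplasm: the phalloidin ridge (thresholded) is filled to recover cell
interiors; each interior pixel is assigned to its nearest nucleus (Euclidean
distance transform), subject to (i) exclusion of nucleus and ridge pixels,
(ii) a growth cap (`cyto_expansion`, default 8 px) and (iii) the
nearest-nucleus territory partition, which makes compartments of adjacent
cells pixel-disjoint by construction. One cytoplasm object per nucleus,
label-matched.

HSCs: rasterized manual polygon ROIs when provided (self-intersecting
polygons are rejected via a shapely validity check); otherwise GFAP
thresholding with area filtering. When HSCs are present their DAPI
footprints are removed from the hepatocyte nuclear mask by overlap with the
GFAP mask (`remove_objects_overlapping`).

Coordinates are 0-based (row, col); centroids are reported in the same
convention. Border-touching objects are kept by default
(`exclude_border=False`), as no exclusion rule is defined for the original
data; the flag exists for users who want it.

## Normalization

Each image's mean intensity is computed over all cellular-object
observations it contributes (nuclear and cytoplasmic means are two
observations of the same target channel, so a single factor per image per
channel results). The global reference is the observation-count-weighted
average of image means — identical to the grand per-cell mean, which is why
the two possible readings of "weighted global average" coincide. Factors are
global mean ÷ image mean; after application every image mean equals the
global mean (relative error < 1e−9 in tests) and the grand mean is conserved
exactly. Re-normalizing an already-normalized table is refused via the
`normalized` flag, since the operation is not idempotent. By default all
images of an analysis run form one pool; `pool_col` splits by batch. Cells
with *I_N* = *I_C* = 0 have no defined NF and are dropped with a logged
count rather than assigned 0.

## Statistics

Permutation test: statistic T = |mean(A) − mean(B)| of per-cell nuclear
fractions (a two-sample KS variant is available via `statistic="ks"`;
difference of means is the default as the minimal statistic for a location
shift). Labels are shuffled over the pooled sample preserving group sizes.
When C(n, n_A) ≤ 10⁵ every assignment is enumerated and p is the exact tail
proportion; otherwise 10,000 Monte-Carlo shuffles (default) give the add-one
estimate p = (1 + #{T_perm ≥ T_obs})/(B + 1), which can never report 0 and
is slightly conservative (null rejection rate 50/1001 ≈ 0.05 at α = 0.05,
B = 1000). Ties between permuted and observed statistics are counted with a
1e−9 relative tolerance so floating-point noise cannot flip them. Exact
empirical p-values are always reported; significance thresholds live in
caller configuration.

Rank test: the group comparison is computed as the *unpaired* two-sided
Wilcoxon rank-sum (Mann-Whitney) test — exact null distribution for untied
samples of ≤ 25 per group, normal approximation with tie correction above
that. A signed-rank test is sometimes named for this comparison in the
literature, but it is undefined for unpaired groups of unequal size; the
rank-sum form is the defined analogue and is what `wilcox.test` computes for
two unpaired samples. The discrepancy is documented here rather than
resolved.

2D KDE: Gaussian product kernel with per-axis Silverman bandwidths
h_i = σ_i·n^(−1/6) (the bivariate rule), evaluated on a 128×128 grid
spanning the data range ± 3 bandwidths. The product-kernel evaluation is
implemented directly because scipy's `gaussian_kde` only scales the full
data covariance by a scalar and cannot express a prescribed diagonal
bandwidth; for independent axes the two coincide and scipy serves as the
cross-check in the tests. Modes are grid local maxima whose density exceeds
`prominence` × global max (default 0.1); plateaus of equal density collapse
to a single mode (a flat surface counts once), and the mode count is
invariant under common positive rescaling of both axes with the bandwidth.
Densities integrate to 1 over the grid within 1% (Riemann sum).

qPCR: raw Ct matrices (genes × samples) are centered by subtracting each
sample's median, then each gene's median of the centred values, and negated
so higher output means higher expression (−ΔΔCt scale). Medians skip missing
entries, so undetectable genes are encoded as missing, never as a Ct
ceiling; medians are therefore taken over detected genes only. After the
transform every gene's median is exactly 0 and the output is invariant to a
constant offset in any single sample's column. The one-way ANOVA + Tukey HSD
on the normalized values is a thin pass-through to scipy/statsmodels.

Zonation: a cell is periportal when its centroid lies within the zone radius
of a portal landmark but outside its lumen, pericentral likewise for central
landmarks, midzonal otherwise; among overlapping zones the nearer landmark
wins and an exact tie goes to portal. No zonal radius is defined by the
source data, so the default zone radius is 6 hepatocyte diameters (120 px at
the default cell size), configurable per landmark. The classification is
translation- and rotation-equivariant with the landmark set.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
thousands of hepatocytes per condition with paired (I_N, I_C) values drawn
from one- or two-component Gaussian mixtures (the `study_conditions()`
presets fix per-condition cell counts at the scale of a typical confocal
study — 3941/2938 hepatocytes and 152/132 HSCs at baseline, 3639/3221 and
163/128 post-PHx — with a bimodal ethanol baseline and an HSC mixture placed so that roughly 80% of
ethanol-group HSCs exceed control HSCs); an optional linear zonal gradient
in nuclear intensity around vein landmarks (sign configurable per landmark
type); and a designed-shift mode (`FractionComponent`) that draws the
per-cell nuclear fraction directly and back-solves I_N, so a designed group
difference δ in mean NF is exact in expectation. Mixture means/sds for the
presets were chosen once as plausible values on the [0, 1] fluorescence
scale that reproduce the qualitative contrasts (unimodal vs bimodal, modest
NF shifts); they are conventions, not measurements.

Rendering: hepatocytes are concentric disks (nucleus radius ~5 px, cell
~10 px, jittered) with a 2-px phalloidin ring at the cell boundary; HSCs are
7×4 px ellipses with a dominant nuclear footprint; pixel values are floats
in [0, 1]; additive Gaussian noise (default sd 0.02) is clipped to [0, 1].
Disjoint placement uses rejection sampling with a per-cell retry cap —
exceeding it is an error, never a silent overlap. Images are written as
lossless 16-bit TIFF or 8-bit PNG; no lossy intermediates.

Deliberately absent: point-spread blur, chromatic aberration, uneven
illumination within an image, cell shape irregularity, touching cells,
autofluorescence texture. Passing tests therefore demonstrate correctness of
the measurement and inference chain on data satisfying the model's
assumptions, not robustness to real microscopy artifacts; per-image
intensity scale differences, the artifact normalization addresses, are
introduced only through sampling variation unless configured explicitly.

## Numerical and design choices

- Rasterization convention: a pixel belongs to a shape when its center
  satisfies the inequality (≤ on the boundary); renderer and tests share it.
- The weights 0.15/0.85 are derived from *v* (then rounded), not hard-coded.
- Noise-free measurement recovery is within 2% relative error per cell;
  count recovery is exact on disjoint high-contrast fixtures and within ±5%
  at noise sd 0.05.
- Designed-shift recovery: with δ = 0.05 at 1000 rendered cells/group
  (5 images of 512² per group, noise sd 0.02) the full pipeline estimates δ
  within ±0.01 and rejects the null at α = 0.01. These problem sizes are the
  package's standard validation configuration.
- Determinism: every random draw descends from one seed via
  `numpy.random.SeedSequence` spawning; identical config ⇒ byte-identical
  numeric outputs (CSV/JSON). Output files carry a 12-hex config hash
  (output paths excluded from the hash) in a header line or sidecar.
- Degenerate inputs: blank images → zero objects; empty masks → empty
  tables; zero-variance KDE axes → an error suggesting jitter; all-tied rank
  test → p = 1 with a warning; zero-mean image → a normalization error
  naming the image.
- The negative-control check passes when the upper quartile of all measured
  intensities is strictly below the threshold; a distribution exactly at the
  threshold fails.

## Known limitations

- The synthetic renderer is geometric, not photorealistic (see above); the
  segmentation has no splitting rule for touching nuclei and no
  machine-learned fallback for low-contrast boundaries.
- The zonal radii and the exact statistic behind the original permutation
  scheme are conventions chosen here (documented defaults), since no
  operational definitions exist for them.
- `PopulationSpec` permits zero component spread and zero noise so that
  exact, noise-free contracts can be tested; such configurations are
  validation fixtures, not models of real tissue.
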