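# Methods

`cortexmap` implements two quantitative engines for cytoarchitectonic
analysis of cell-body-stained cortical images — the grey-level-index (GLI)
profile approach to border detection, and a filter-activation
interpretability workflow for a dual-branch convolutional segmentation
network — together with a synthetic-phantom generator that provides ground
truth to exercise both end to end. This note describes the models, the
parameters that matter, the numerical choices, and what the phantom does
and does not emulate.

## Synthetic cortical phantoms (`synthio`)

A phantom is a 2D 8-bit image of a cortical ribbon of one or more
laterally adjacent areas, each specified as an ordered list of layers with
a thickness fraction, an expected cell density (cells/mm² of visible cell
bodies in a 20-µm-equivalent section), a cell radius distribution (µm), a
stain darkness, and an optional linear radius gradient across the layer's
depth. Cells are placed by an inhomogeneous Poisson process: the count of
each layer region is drawn by quantile inversion of a fixed uniform
variate and each cell's attributes come from a per-cell seeded substream.
This construction makes rendering monotone in density — raising one
layer's density only appends cells, leaving every other draw untouched —
which turns the mask/density rank-order properties into exact pathwise
statements rather than distributional ones.

Columnar arrangement is emulated by thinning the point process with a
vertical stripe pattern of ~50 µm period whose phase drifts smoothly along
the ribbon (a sum of seeded long-wavelength sinusoids per area). The
drift matters: cortical columns are locally but not globally coherent,
and a phase-locked cosine aliases against any regular traverse spacing
into a slow lateral beat that mimics spurious areal borders.

Two presets encode the qualitative laminar contrast between primary
("hOc1-like") and secondary ("hOc2-like") visual cortex: sublayers
IVa/IVb/IVc with IVc the densest layer of all and layer V the sparsest of
II–VI versus a single thinner layer IV; a pyramidal-cell size gradient in
layer III of the secondary area; and stronger columnarity there. The
quantitative densities are the package's own choices: granular visual
cortex is among the densest human cortex, the primary area carries roughly
twice the neuronal density of its neighbour, and the resulting GLI
amplitudes (~0.2–0.35) sit in the range typical of the GLI literature.

Geometry is a flat band or an annulus sector ("arc"); default resolution
2 µm/px (the desk studies use 4 µm/px). Gaussian pixel noise (default sd
4 grey levels) is added last. The phantom does **not** emulate staining
gradients, tissue tears, vasculature, glia/neuron distinction, realistic
Nissl texture, or 3D sectioning effects — so green tests demonstrate the
correctness and statistical behaviour of the algorithms under controlled
conditions, not performance on real histology.

## GLI images (`gli`)

Foreground is every pixel *strictly darker* than the threshold (cells
stain dark). When no threshold is given, Otsu's criterion picks one; on
integer images half a grey level is added so the strictly-darker rule
includes the dark class whose upper edge Otsu returns. The GLI value of a
field (default 20 × 20 µm; the field edge must be an integer number of
pixels) is its foreground fraction; trailing partial fields are discarded
so all fields have equal area, as the volume-fraction reading requires.

## Traverses (`traverses`)

The cortical depth field solves the Laplace equation with Dirichlet value
0 on the outer (layer I/II) contour and 1 on the inner (GM/WM) contour,
no-flux elsewhere. The discrete 5-point system is assembled sparse and
solved by conjugate gradients (the matrix is symmetric positive
definite); afterwards the per-pixel residual |Σ neighbours − deg·u|/deg is
verified against the tolerance (default 1e-4) and the call fails if it is
not met. Outside the valid set the field is extended by nearest-neighbour
fill so gradients can be interpolated right up to the boundary.

Traverses are streamlines of the normalised gradient, seeded at
equidistant arc-length positions along the outer contour (2% end margins)
and integrated by fixed-step RK4 (0.25 px) until the field reaches 0.995,
then snapped to the nearest inner-contour point; a step budget of
4·(H+W)/step aborts with the offending seed named. Profiles are read
from the GLI grid by bilinear interpolation at `n_points` (default 100)
equidistant arc-length positions, using the pixel-centre convention to map
image coordinates onto field centres.

Two discretization effects are worth knowing: rasterizing the boundary
contours onto the pixel grid shifts the effective Dirichlet boundary by up
to half a pixel (visible when comparing against closed-form solutions),
and where the ribbon is clipped by the image frame the no-flux sides are
not cortical-flow lines, so the field bends near the frame — traverses
within a few seeds of the ends inherit that bend.

## Profile features (`profile_features`)

A profile y over depths x ∈ [0,1] is treated as a frequency distribution
with weights w_i = y_i/Σy. The descriptor is: mean amplitude, centroid
Σw_i x_i, sd √m₂, skewness m₃/m₂^1.5 and kurtosis m₄/m₂² (raw, not
excess-corrected), plus the same five on the absolute differential
quotient |y_{i+1} − y_{i−1}|/(2Δx) (one-sided at the ends). The absolute
value makes the derivative trace a valid frequency distribution; the
signed alternative exists in the literature but is not used here.

## Border detection (`border_detect`)

At position i with window b, D²(i) is the Mahalanobis distance between
the mean feature vectors of the b profiles left and right of i, using the
pooled within-block covariance. Significance converts Hotelling's
T² = (b/2)·D² to F = T²·(2b−p−1)/(p(2b−2)) with (p, 2b−p−1) degrees of
freedom and Bonferroni-corrects over positions at α = 0.05. An optional
trace-scaled shrinkage S ← (1−γ)S + γ·tr(S)/p·I handles near-singular
short sequences (off by default).

Borders are confirmed across window sizes. Defaults: windows {15…24} and
confirmation when ≥ 80% of windows place their significant global maximum
within ±2 positions of a common candidate. Two defaults deserve their
rationale. The window floor of 15 keeps the Hotelling test powered: with
p = 10 features the second degree of freedom is 2b−p−1, which at b = 12 is
only 13, and after Bonferroni correction such windows systematically miss
genuinely strong borders. The ±2 vote tolerance reflects that consecutive
window positions share 2b−2 of their 2b profiles, so the argmax of D²
carries an intrinsic jitter of about two positions even across a strong
border; requiring exact ±1 agreement under-confirms structurally. The
confirmed position is the median of the supporting votes. Detection
iterates — each confirmed border masks ±max(window) positions and the
search repeats — so multiple well-separated borders are recovered.
Ties in a global maximum break toward the lower index and are flagged.

Under the desk study conditions (flat two-area phantoms, 4 µm/px,
1056 × 448 px, 1.4 mm cortical thickness, 100 traverses ≈ 41 µm spacing,
20 seeds), the confirmed border falls within ±2 traverse positions of
ground truth in ≥ 90% of seeds, and identical-area null phantoms yield
zero confirmed borders in ≥ 90% of seeds.

## Network architecture and training (`cnn_arch`, `nn`)

The segmentation architecture has three branches: a high-resolution
contracting branch (2025 px patches at 2 µm/px, a 4.05 mm field of view),
a low-resolution contracting branch (1123 px at 16 µm/px, 17.97 mm), and
one expanding branch. Contracting blocks are two 3×3 convolutions plus
2×2 max pooling; expanding blocks are a 2×2 up-convolution plus two
convolutions; every convolution is followed by batch normalization and a
ReLU, and skip connections concatenate high-resolution contracting
outputs into the expanding branch. Each branch holds exactly 864 units
(2592 per instance); the split of the 864 across layers is not uniquely
determined by the printed totals, so the package ships one documented
default — hr (48,48,96,96,144,144,144,144), lr (144,144,288,288),
expanding 4×(144/72/48/24 triples) over 10 blocks and 24 network layers —
with the branch totals enforced as hard validation. Network layers are
numbered hr 1–8, lr 9–12, expanding 13–24.

The trainable desk-scale realization divides unit counts by 8 (108 per
branch) and works on 64 px hr patches with co-centred lr patches covering
8× the extent at 8× coarser sampling. The lr bottom features are
2×-upsampled, centre-cropped to the hr bottom grid and concatenated (the
junction); four expanding blocks with skips restore full resolution and a
1×1 convolution yields 4-class per-pixel logits (background, white
matter, area of interest, other cortex). The layer stack (im2col
convolution, batch norm, ReLU, max pool, non-overlapping transposed
convolution, Adam) is implemented in numpy with manual backprop, float32
throughout, and every gradient path is covered by finite-difference
tests. Training draws class-balanced patch centres (exactly n per class)
and minimises per-pixel cross entropy with Adam (lr 2e-3, batch 8,
default 300 iterations) — small numbers chosen as the package's
desk-scale study size. Weights are randomly initialised (He) under a
documented seed; no pre-trained weights are used. Inference is fully
convolutional on images padded to a multiple of 32.

On an easy phantom pair (full density contrast, no noise) the held-out
within-cortex Dice for the area class is ≈ 0.95–0.97 after 300
iterations.

## Activation analysis (`activation_analysis`)

Per-unit post-ReLU maps from the hr-contracting and expanding branches
are normalized to [0,1] with the smallest strictly positive value as the
lower bound (values at or below it become 0; all-zero or constant maps
are flagged degenerate and excluded; a two-valued {0,c} map maps its
positives to 1 — the limit of the rule at its single positive level).

Similarity is mutual information in bits over 256-bin joint histograms
with edges i/256 (top bin closed); maps of different native resolutions
are first nearest-neighbour-resampled to the reference (input-image)
resolution. The 256 divisor of the histogram definition is used
throughout. MI identities (symmetry, non-negativity, MI(x,x) = H(x)) are
enforced by tests, and the whole matrix is computed once per unordered
pair from pre-digitized maps.

A unit is *characteristic* for its network layer when at least 3 of its
12 highest-MI partners (self excluded; ties at rank 12 break toward the
lower unit index, flagged) belong to the same layer. Characteristic maps
are then scored against phantom ground truth as a quantitative proxy for
an expert's visual categorization:

* `score_cell` — pixel-weighted mean over areas of the absolute Spearman
  correlation between map values and local cell density (cell mask
  box-averaged over 20 µm), computed *within* each area so a map that
  merely tells areas apart scores ~0;
* `score_layer` — best layer-vs-rest-of-cortex ranking separation,
  max(AUC, 1−AUC) since low-responding maps separate equally well;
* `score_area` — the same for area-vs-rest-of-tissue.

The level (first/second/third — cellular, laminar, areal) is the argmax
of the three scores when it clears its threshold (0.5 / 0.85 / 0.85),
otherwise unassigned. Scores are evaluated on a seeded subsample of up to
200k pixels. These thresholds and the proxy scores are design choices —
they make the categories reproducible on phantoms but are not a claim of
equivalence to expert judgement on real material. On a trained desk model
the qualitative ordering mirrors the superficial-to-deep hierarchy:
shallow fine-resolution layers score highest on `score_cell`, the coarse
post-bottleneck expanding layers carry the area-indicating (third-level)
maps and score near zero on `score_cell`. The very last expanding layers
operate again at fine resolution and may track cells too; the package
therefore phrases the depth comparison as fine-resolution contracting
(layers 1–6) versus coarsest expanding stages (13–18).

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_pipeline` chains synth → GLI → traverses → features → borders and
optionally train → activations → MI → characteristic filters → levels,
writing a versioned JSON report plus a human-readable summary; every
defaulted parameter (including the auto-picked threshold) is logged. A
single global seed fans out to per-stage seeds by fixed offsets, so each
stage reproduces independently; deterministic stages are byte-stable
under a re-run of a persisted config. The `cortexmap` CLI exposes the
stages as subcommands (`synth`, `gli`, `profiles`, `borders`, `train`,
`activations`, `mi`, `levels`, `run`, `report`).

## Known limitations

* The phantom's laminar contrast is an idealisation; border-recovery
  rates measured here do not transfer to real sections.
* The expert categorization step is replaced by mask-based scores with
  fixed thresholds; counts of first/second/third-level activations depend
  on training and are reported as computed, not compared to any external
  tally.
* The full-size architecture is constructed as a description only; all
  training happens at desk scale.
* Binarization has no shading correction or size-based particle
  filtering; phantoms do not need them.
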