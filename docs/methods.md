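# Methods

This note documents the models, defaults and numerical choices behind
`poldep`, and what its synthetic benchmarks do and do not demonstrate.

## Study design

The default design crosses 9 GFP-tagged markers (Bud6, For3, Mod5, Myo52,
Tea1, Tea2, Tea3, Tip1, Tea4) with 10 deletions (the 9 marker genes plus
*mal3*). A marker is never crossed with the deletion of its own gene — that
strain cannot carry the tag — so the full grid holds 81 combinations and
the serialized matrix is 9 rows × 10 columns with 9 structurally empty
cells. The full-scale preset (`full_scale_config`) plans 120 cells per
arm per combination (the screen's rule is *more than* 100 cells per
strain), i.e. 19,440 cells, imaged as 15 fields per combination with
8 wild-type + 8 deletion cells each.

## Synthetic forward model

Each cell is a spherocylinder (length ~ U(7, 14) μm, width 3.5 μm —
standard interphase dimensions) placed by rejection sampling with a
1.8 μm clearance between cell outlines (≤ 500 attempts per cell),
mimicking sparsely mounted cells. Clearance this large keeps the blurred
skirt of one cell's tip spot from bridging into a neighbour's mask at
segmentation time.

GFP signal per cell = a uniform cytosolic photon column density over the
rod mask plus an isotropic Gaussian spot at each pole; the red channel
of wild-type cells gets 1–2 punctate SPB spots (two with probability
0.3, the pre-mitotic fraction) placed in the central part of the cell.
Signal is spread over the 31 × 0.2 μm slices by a Gaussian axial
focus/thickness profile with peak 1 at the cell mid-plane, so the
noise-free maximum projection equals the in-focus column image — the
quantity the measurement procedure is designed to read. The lateral PSF
(Gaussian, σ 0.15 μm) is folded into each cell's contribution
analytically (blurred mask; variance-added spot widths), which by
linearity of convolution equals blurring the composed slice; a photon
conservation test holds this to <1%.

Noise, in order: Poisson shot noise on the expected photon image, then
additive Gaussian read noise (σ 2 counts), then a constant camera offset
(100 counts). Each term can be switched off independently for oracle
tests.

Default brightness priors (photon column densities, chosen once from the
forward-model arithmetic as typical of a bright endogenous GFP tip
marker): tip peak 250,000 /μm² (≈ 2,500 counts/px at 0.1 μm/px),
cytosol 3,000 /μm², SPB spot 150,000 /μm². Per-cell expression varies
log-normally with CV 0.15; the dim/bright tip ratio (bipolarity) is
N(0.30, 0.10) clipped to (0.02, 0.98) — a monopolar-leaning interphase
population. Deletion effects are purely phenomenological: multipliers on
the three compartment amplitudes and an additive shift of the
bipolarity parameter. Nothing mechanistic (microtubules, motors,
proteolysis) is simulated.

What the generator does *not* emulate: septating/mitotic cells, cell
overlap and clumping, autofluorescence gradients, photobleaching, stage
drift, chromatic offset between channels, and segmentation-hostile
debris. Passing tests therefore certify the statistical machinery and
the automated measurement under idealised-but-noisy imaging, not
robustness to every real-world artefact.

## Measurement

* **Projection**: per-pixel max over z.
* **Segmentation**: global robust threshold (median + 6 robust σ of the
  projection — scale-invariant), morphological closing and hole filling,
  minimum area 8 μm². QC gates: length in [5, 16] μm, aspect ≥ 1.5, no
  mid-cell transverse bright ridge (septum heuristic), not touching the
  image border. Excluded cells always carry a flag, so
  segmented = analysed + excluded holds per field.
* **Poles**: extremes of the mask along its principal axis, then snapped
  to the local smoothed-GFP maximum within 1.5 μm when a tip spot stands
  out above the cell's median signal (thresholded masks overshoot bright
  tips by ~1 μm; the spot centre is the pole). On default synthetic data
  this localises poles to <0.15 μm.
* **Genotype**: a cell is *control* iff its mask holds a punctate red
  local maximum with prominence ≥ 5 × the robust red background,
  *deletion* iff the brightest in-mask point stays below 2.5 ×, and
  *ambiguous* (excluded, flagged) in the hysteresis band.
* **ROIs**: three discs of 3 μm diameter (radius rounded to the nearest
  pixel) at the two poles and the mask centroid; pixels above the
  cytosol disc's 90th percentile are dropped before averaging (the
  "non-foci" rule); discs clipped by the image border are allowed down
  to 80% in-image area, else the cell is excluded. Background = mean of
  one 3 μm disc placed ≥ 1 μm clear of every cell at the position of
  minimum local variance (deterministic; avoids debris). All corrected
  values are raw − background mean; End1 is the end with the larger
  corrected mean. Measurements are computed in float64 so that a
  constant gain applied to a field cancels exactly in every normalised
  quantity.

## Statistics

Normalisation divides each cell's corrected compartment values by the
mean over the *same field's* control cells; fields without controls or
with a non-positive control mean are dropped with a logged warning.
Control cells are normalised by the same mean, making their per-field
normalised mean exactly 1 by construction. Because the denominator is
itself an ~8-cell estimate, the deletion arm's grand normalised mean
carries a field-level sampling error and the small positive
ratio-estimator (Jensen) bias of ~+0.006; both are second-order for the
matrix statistics, which compare the two arms through the same
denominators.

Per (marker, deletion, compartment): Welch's unequal-variance t-test on
log normalised values (intensity ratios are right-skewed; non-positive
values are dropped from the log), `rel_diff = mean(Δ̃)/mean(wt̃) − 1`,
and an *underpowered* flag (reported, never silently dropped) when an
arm has fewer than `min_cells` = 100 analysed cells. Benjamini–Hochberg
adjustment runs across all matrix entries jointly; a call requires
`q ≤ α = 0.05` **and** `|rel_diff| ≥ min_effect = 0.10`. The effect
floor absorbs the small biases introduced by End-brighter selection and
cytosol spillover into the pole discs. Calibration on null-truth
simulations run through the *full* image pipeline (including End
assignment): raw type-I rate 0.047 at α = 0.05; matrix-wide non-ns call
rate ≈ 0 after adjustment and effect gating.

NETO shifts: two-sided Mann–Whitney on the per-cell bipolarity index
(End2/End1 corrected means, clipped to [0, 1], 0 when End1 ≤ 0), BH
across combinations, `shifted ⇔ q ≤ α`; the bipolar/monopolar fraction
at the midpoint threshold 0.5 is reported alongside but does not drive
the call. With all-tied indices the p-value is defined as 1.

## Network

Edges are read off polar (end) calls only — a cytosolic change alone is
an abundance effect, not a recruitment dependency. Conflicting end1/end2
calls resolve by the larger |rel_diff| (both underlying calls stay in
the matrix). Combinations with a NETO shift but no intensity call get a
positive edge flagged `basis="neto"`; NETO flags otherwise ride on the
intensity edge. Loop sign is the product of edge signs (negative iff an
odd number of negative edges); because the reported multi-protein
"positive loops" are all-positive-edge cycles, an `all_positive` flag is
carried separately from the product sign. Cycle enumeration uses
`networkx.simple_cycles` with a length bound; canonical rotation starts
at the lexicographically smallest protein. Exports: TSV (lossless
round-trip), GraphML, and DOT with the green/red/blue (positive /
negative / NETO) colour convention.

`fixtures/reference_results_edges.tsv` holds the signed edges transcribable
from the reference study's results narrative, labelled by group
(pairwise loop examples, the nine positive-cycle edges, the five-protein
negative cycle, worked matrix examples). Two edges of the negative cycle
(Bud6→Tea3, Tea3→Tea2) are individually unstated — only their sign
product is constrained by the cycle's overall negative sign — and are
encoded +/+ with a provenance note. The fixture is deliberately partial:
the complete figure arrow set is not machine-readable and is not
reconstructed.

## Problem sizes and reproducibility

The full-scale preset samples at 0.2 μm/px over 320 × 320 px fields
(the package's compromise between sampling density and the ~100 M
voxels per combination a full 81-combination study implies); unit tests
and examples use the same geometry. All randomness flows from a single
seed through hierarchical per-(combination, field) generators, so any
field is reproducible in isolation and identical configs give
byte-identical CSV outputs. TIFF output is uint16, channel-major then z
(pages 0–30 GFP, 31–61 red).

## Known limitations

* Segmentation assumes non-touching rods; merged cells fail QC rather
  than being split by a watershed.
* The septum heuristic is conservative and untested against real
  septating cells (the generator does not render them).
* Genotype calling needs a positive red background level (camera
  offset); at zero offset it falls back to a MAD-based scale.
* The 3 μm pole discs unavoidably contain cytosol (~1/5 of a bright
  tip's disc signal), attenuating |rel_diff| slightly toward zero; the
  planted-recovery benchmark measures the pipeline's end-to-end
  sensitivity including this attenuation.
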