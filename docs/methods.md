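# Methods

## Screen model

The simulator is a generative model of a FACS-sorted pooled knockdown
screen read out with the tandem mCherry-EGFP-LC3B reporter.  Per
replicate it instantiates `n_cells_per_shrna` cells for every hairpin
(exact, even representation — the screen is planned that way and the
multinomial sequencing step supplies the dominant count noise).  Each
cell's flux-block state is Bernoulli with probability
`gene_effect × shrna_efficacy`, both in [0, 1]: `gene_effect` is the
biological requirement of the gene for flux, `shrna_efficacy` the
knockdown strength of that particular hairpin.  Basal GFP is
log-normal (`gfp_mean_log = ln 1000`, `gfp_sd_log = 0.4` — a ~40%
coefficient of variation typical of reporter MEF lines); flux-competent
cells have their starved GFP multiplied by `quench_factor` (default
0.2, i.e. 80% of the signal lost to lysosomal quenching, matching the
level of starvation-induced GFP loss seen in flux-competent reporter
lines).  Quenching is a single multiplicative factor because the
underlying biology (pH-dependent EGFP darkening) acts on every reporter
molecule that reaches the autolysosome.

Sort gates default to the outer deciles of the pooled starved GFP
distribution (bottom 10% = GFP-low, top 10% = GFP-high); real
instruments draw these windows graphically and no numeric boundaries
are published, so the deciles are a documented convention, not an
inferred value.  Sequencing draws `sequencing_depth` reads per sorted
sample multinomially from the pool's hairpin composition; an optional
Dirichlet-multinomial mode (concentration parameter `overdispersion`)
adds extra-multinomial noise.  The default is pure multinomial so that
column sums equal the depth exactly and the null fold change is
analytically centred at 1.

Defaults mirror the reference screen where stated: coverage 1,000
cells/hairpin, transduction efficiency 8.5%, two replicates, library
710 genes / 4,184 hairpins with the shRNA count split as evenly as
possible across genes (only totals are published; the remainder goes
one-per-gene in deterministic gene order).  Sequencing depth is not
published; the simulator default (500,000 reads/sample ≈ 120×/hairpin)
gives count noise well below the three-fold decision boundary.  The
planning arithmetic uses 6.5 pg per diploid mouse genome to convert
representation into PCR template mass.

## Readout and scoring

Reads are barcode + guide at fixed offsets (an artifact convention —
real amplicon layouts vary and are configuration here), matched
exactly.  No mismatch rescue is attempted: exactness keeps the
simulate → sequence → count round trip a strict identity, which the
tests rely on as an oracle.  Normalization is reads-per-million — the
minimal depth correction consistent with ratio scoring; the raw column
total stays in the denominator when a pseudocount is used, so a
pseudocount perturbs only numerators.  The pseudocount defaults to 0.5
when any zero is present (a dropout hairpin in the GFP-low gate should
register as strong enrichment, not a division error) and 0 otherwise.
Threshold comparisons are inclusive (geomean ≥ 3, ≥ 3 scoring
hairpins), reading "at least" literally; the geomean is computed in
log space and agrees with the product form to floating-point accuracy.
Hit-table ties are broken by gene name ascending — the published table
has no ties, but a deterministic rule is required for
permutation-invariance of the output.

## Cytometry quantification

Percent-of-control uses arithmetic means of linear fluorescence (the
convention for "mean relative fluorescence units"), control set to
100% per cell line and replicate, and an n−1 SD across replicates.
The event simulator draws each replicate's basal (mCherry, GFP) values
once and reuses them across conditions, applying the quench to
flux-competent cells only; this paired design makes a fully blocked
line's starved distribution *identical* to its control distribution at
the same seed, and makes the read-back of the quench factor exact
rather than merely unbiased.  Real cytometry adds acquisition noise,
day effects and compensation artifacts that this generator does not
model, so passing tests demonstrate correctness of the quantification
arithmetic, not robustness to instrument drift.  Gate derivation takes
the (1−α) quantile of the negative (flux-competent) control as the
GFP-low upper bound and the α quantile of the positive (blocked)
control as the GFP-high lower bound (α = 0.05 by default); overlapping
bounds raise an error rather than emitting inseparable gates.  Gate
membership is inclusive-lower / exclusive-upper.

## Imaging quantification

Spot detection: difference-of-Gaussians band-pass (defaults σ_low = 1,
σ_high = 5 voxels, bracketing vesicle-scale structure), Otsu threshold
on the filtered image (or a fixed value), morphological closing with a
radius-1 ball to reshape ragged masks, 26-connected labelling, then
filters on volume (≥ 5 voxels), mean intensity and CV.  The intensity
and CV filters exist because the original Definiens workflow names
them, but their numeric settings are unpublished; they default to off
(0 and ∞) and are expected to be calibrated per dataset.  All object
statistics are measured on the original intensities, never the
filtered image.

Overlap is computed on binary supports, making it invariant to
intensity rescaling.  "More than 40% overlap" leaves the denominator
ambiguous; the implementation computes both directional fractions for
the best-matching pair (|A∩B|/|A| and |A∩B|/|B|, with the A-side
fraction taken against the union of all B objects) and classifies a
spot double positive when either exceeds the threshold strictly — the
most permissive literal reading, with both values reported so stricter
conventions can be applied downstream.  Volume-weighted (not
intensity-weighted) overlap is used.  Containment counts a vesicle as
cargo-positive when at least one cargo centroid (voxel-rounded) falls
inside its voxel set.  Line profiles sample both channels by trilinear
interpolation at `round(length/spacing) + 1` equally spaced points.

The stack simulator renders solid spheres (optionally blurred by a
Gaussian PSF and degraded with Poisson/read noise).  Paired-spot
center distances are found by bisection *on the actual stack grid* so
that the voxelized support overlap hits the target within ±0.01;
a generic off-grid search is exposed separately
(`distance_for_overlap`) and is verified against brute-force voxel
counting in the tests.  Simulated spots are homogeneous spheres —
real vesicles are neither spherical nor uniform — so the closure tests
validate the measurement chain, not segmentation performance on real
microscopy.

## Benchmark problem sizes

The multi-seed benchmarks run reduced but well-powered screens chosen
so ten seeded repetitions complete in seconds: null calibration uses
50 genes × 4 hairpins at 200× coverage and 100 reads/hairpin (the
depth floor at which the <1% spurious-scoring guarantee is claimed);
parameter recovery uses 25 null + 5 regulator genes × 4 hairpins at
500× coverage, efficacy 0.85, quench 0.2 and 200 reads/hairpin.  At
these sizes the null log fold change has standard deviation ≈ 0.25
across replicates, putting the three-fold boundary more than 4 SDs
out — the analytic reason the null calibration criterion holds.  The
full-scale 4,184-hairpin screen is exercised by
`analysis/02_screen_simulation.py`.

## Known limitations

No FCS binary parsing (event tables are CSV); no compensation or
spillover modelling; no multi-copy transduction, selection kinetics or
integration-site effects (a single hairpin per cell is assumed); no
per-cell segmentation from images (an optional label mask stands in
for interactively drawn cell borders); exact-match-only read
assignment with no quality filtering.
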