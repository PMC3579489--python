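# Methods

## Data model and consolidation

A sample's hyperspectral image is a cube `(height, width, channels)` of
non-negative peak-integrated ion intensities; the channel axis is defined
by a peak list (ordered m/z centres with unique labels, one polarity per
list — peak lists of different polarities have different lengths and must
never be mixed). Consolidation unfolds each cube row-major (0-based,
origin top-left) and row-stacks the blocks in cube input order. No
scaling, centring, normalization or other pre-treatment is applied at any
point: the matrix entries are the cube intensities bit-exactly, and
negative inputs are rejected at load rather than clipped. Cubes may
differ in pixel grid across samples (the factorization is pixel-wise);
only the area-equivalence report, which assumes a single pixel pitch,
demands homogeneous fields. For n homogeneous fields it reports
`n · field area` in mm² and the most nearly square `a × b` tiling of the
n fields as an equivalent rectangle (eight 500 × 500 µm fields → 2 mm²,
reportable as 1 mm × 2 mm).

## PCA scree

The scree is the descending eigenvalue spectrum of the data
cross-product, `X'X / (n_pixels − 1)`, computed channels × channels since
channels ≪ pixels. Uncentred by default — consistent with the
no-pre-treatment policy; column mean-centring is an explicit flag. The
suggested component range is advisory and derives from an elbow
heuristic: walking down the eigenvalues, the plateau begins at the
smallest index `i` with `λ_i / λ_{i+1} < 1.5` (eigenvalues at the
numerical noise floor, ≤ 1e-12 of the largest, count as plateau; a real
eigenvalue dropping to the floor counts as a cliff); the range is
`(elbow − 2, elbow + 3)` clipped to `[1, channels]`. A range rather than
a point is deliberate — the spectrum of real multi-sample data rarely has
a single unambiguous elbow — and nothing downstream applies it
automatically.

## Constrained ALS

Each ALS half-step solves its non-negative least-squares problem exactly:
`min ‖D − C·S‖_F` over one factor, elementwise ≥ 0, the other factor
fixed. The solver works from the normal-equation cross-products and
groups right-hand sides sharing a passive set (fast combinatorial
active-set NNLS), with two engineering layers on top:

- a warm start from the previous iteration's active sets, screened by a
  single feasibility + gradient-optimality pass, so converged pixels cost
  one small linear solve per iteration;
- a per-column accuracy check on the *passive* gradient (which must
  vanish at a solved subsystem): near-singular Gram matrices — routine in
  over-fitted models, where loading rows duplicate — make the grouped
  linear solves untrustworthy, and such columns are routed onward rather
  than accepted;
- a guaranteed fallback for any column not settled within the active-set
  budget or failing the accuracy check: the quadratic is reduced through
  the eigendecomposition of the Gram matrix (rank-revealing, so exact
  singularity needs no regularization) and handed to scipy's
  single-column NNLS.

Exactness of the half-steps is what makes the lack-of-fit sequence
non-increasing across iterations (asserted to 1e-10 over every fit in the
test suite); clip-after-solve schemes lose that property. After every
loadings update the rows of `S` are renormalized to unit Euclidean norm
and the scales pushed into the matching score columns, fixing the
bilinear scale ambiguity and making loadings comparable across restarts.

Update order: every iteration solves scores from the current loadings
first, then loadings from those scores. With supplied initial loadings
(the consensus round) this is what lets them steer the fit. For random
starts it is equally deliberate: deriving loadings from i.i.d. random
scores first collapses all k loading estimates toward the global mean
spectrum (each is a random-weighted pixel average), which strands most
restarts in poor local minima — measured on the Poisson study phantom,
the good-basin rate drops from 7/10 (scores-first) to 3/10
(loadings-first). The loadings-first order remains available as a flag.

Initialization draws both factors uniform on (0.1, 1.1) — strictly
positive so no component is born degenerate — with loadings rows
unit-normalized; everything is reproducible from the integer seed.
Convergence is declared when the relative lack-of-fit change per
iteration falls below `tol` (default 1e-6), when the lack of fit reaches
the numerical floor of 1e-6 %, or at `max_iter` (default 500). On
noiseless data ALS approaches the exact factorization asymptotically, so
fits there typically run to the iteration cap with the lack of fit around
1e-3–1e-5 % — numerically exact for every practical purpose, but the cap
position means two such fits can differ by a few 1e-5 percentage points.

A component whose loading row or score column collapses to zero is
reseeded once from the dominant direction of the residual (absolute value
of the leading right-singular vector, computed by a few power
iterations); the reseed provably does not increase the residual. A second
collapse of the same component ends the run with the degenerate flag and
`converged=False`.

No regularization and no further constraint families (closure,
unimodality, equality) are applied.

## Consensus protocol

Ten (default) random-start fits run independently, repeat `i` seeded by
`SeedSequence([master_seed, i])` reduced below 2³¹ — so concurrent and
sequential execution produce bit-identical models and any repeat can be
reproduced in isolation. A repeat that raises is recorded as a warning
and dropped (the run fails only if fewer than two survive); unconverged
repeats still contribute. The pooled unit-norm loading vectors (minus
all-zero degenerate rows, which carry no spectral information) are
k-means clustered into k groups (Euclidean metric — monotonically related
to cosine on unit vectors; 10 seeded restarts). The renormalized cluster
means become the initial loadings of one final ALS round with fresh
random scores; that final model is the headline result.

Two stability diagnostics accompany it: per-cluster mean cosine of
members to their cluster mean, and per-cluster repeat coverage (distinct
repeats contributing at least one loading to the cluster). No constraint
forces one loading per repeat per cluster; coverage reports how close the
clustering comes to that ideal.

## Over-fit diagnostics and component-number scan

"Most significantly loaded ions" are the largest entries of a unit-norm
loading row, ties broken by ascending m/z; no statistical test is
implied. An over-fit pair is two components with score-column cosine
≥ 0.9 **and** loading cosine ≥ 0.9 (both thresholds configurable): the
operational form of "the same spatial feature with the same ions
appearing twice". The scan runs the full consensus pipeline for each k in
range and recommends the largest k with zero flagged pairs, every cluster
covered by ≥ 80 % of repeats, and minimum within-cluster mean cosine
≥ 0.95; the recommendation is advisory and always printed beside the full
table. In practice surplus components do not always duplicate in both
domains — they may die to zero during iteration (then refit residual dust
after the reseed) or split a source spatially while the spectra diverge —
which the cluster-stability gates catch even when the pair flags stay
silent.

## Synthetic phantoms

The generator emulates the structure of a polymer-microarray surface
study: eight samples imaged over identical fields; one substrate
chemistry (background) present everywhere; spot chemistries as
raised-cosine-edged discs (radius a fraction of the field, default 0.35,
edge band ±30 % of the radius) in stated sample subsets; optionally one
contamination overlay that adds its own spectrum over a smaller disc and
multiplicatively attenuates (by 80 %) the spot chemistry beneath it. The
substrate is fully suppressed where a spot's disc profile reaches 1 —
SIMS is top-monolayer sensitive, a covering layer hides what is below.
Pure spectra are unit-norm and sparse: each chemistry emits 3 dominant
ions (disjoint across chemistries) plus weak intensity on a random ~30 %
of channels, the rest exactly zero, as in real peak-integrated spectra
where most listed ions are absent from any one material. Pairwise cosine
< 0.95 is enforced at generation.

These two choices — spectral zeros and full substrate coverage at spot
cores — are what make the noiseless phantom *identifiable*: with them the
exact factorization is unique up to component order, so recovery can be
scored against the truth; without them non-negative factorizations admit
a band of rotated exact solutions and "recovery" is ill-posed regardless
of algorithm.

Default amplitudes (substrate 100, spots 60–90, contamination 80 mean
counts at a pixel's full concentration) put dominant-ion counts in the
50–100 range typical of static-SIMS imaging; Poisson noise treats each
noiseless intensity as a mean count. Gaussian noise is available and
truncated at zero. The master seed derives one spectrum stream and one
noise stream per sample, so cubes are byte-reproducible. What the phantom
does **not** emulate: fragmentation relationships between ions, m/z
dependent detector response, topography/charging artefacts, spatially
correlated contamination films, or intensity drift between acquisitions —
recovery results on phantoms bound what the pipeline can do on ideal
count data, not on instrument pathology.

The stock study layout is 8 samples of 64 × 64 pixels with 30 channels
and five chemistries; a full acquisition-scale preset (8 × 256 × 256,
461 channels, nine chemistries) exercises the same code at realistic
size. Tests and the acceptance script run the 64 × 64 scale (and a
16 × 16 three-sample variant for fast unit checks) — problem sizes chosen
so the full suite completes on one CPU in minutes while preserving every
structural feature of the large layout.

## Known limitations

- Unweighted least squares: Poisson counting noise is heteroscedastic,
  so high-intensity chemistries dominate the objective. One consequence,
  visible in the diagnostics, is a robust local minimum on the Poisson
  study phantom in which the small single-sample contamination (~2 % of
  pixels) merges into its host spot while the substrate splits; 30–50 %
  of random restarts land there, capping per-cluster repeat coverage at
  5–7 of 10 even though the consensus refit recovers all chemistries at
  cosine ≥ 0.999. Weighted ALS would likely soften this but is out of
  scope.
- The final consensus model is not guaranteed to edge out the single best
  repeat in lack of fit at a finite iteration cap (both are numerically
  exact on noiseless data; differences sit at the 1e-5 % level); it is
  asserted never to be worse than the median repeat.
- Rotational ambiguity is resolved only by non-negativity and data
  structure; on data without pure pixels or spectral zeros, recovered
  spectra are one member of the feasible band.
- k-means consensus assumes the repeats' solutions populate k coherent
  spectral families; when most repeats miss a chemistry, its cluster
  coverage drops and the stability report says so, but no reassignment
  is attempted.
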