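# Methods

## The VB index

A searchlight neighbourhood of m fMRI time series (length k) is modelled
as a complete weighted graph in which absent edges simply carry weight 0.
The similarity metric is the sample Pearson correlation mapped through

    w_ij = 1 − arccos(corr(s_i, s_j)) · (180/π) / 90 .

The arccos linearises the relation between angle and weight (a pair of
mean-centred series at 45° scores 0.5, where the raw cosine would score
0.71). Correlations are clipped to [−1, 1] before the arccos to absorb
floating-point overshoot. Negative correlations would produce negative
weights; they are clamped to 0, which preserves both the stated weight
interval [0, 1] and the disconnected-graph limit (VB = 0). A
zero-variance series has no defined correlation; it keeps its vertex but
all its weights are set to 0, with a warning, so flat voxels degrade a
neighbourhood gracefully instead of aborting a map. The metric is
pluggable in principle, but only this one ships.

From the affinity matrix A the degree matrix D and Laplacian L = D − A
follow, and the index is VB = λ₂(L)/n. Two normalisations are supported:

- **unnorm** — the standard problem L u = λ u. λ₂ of a complete
  unit-weight graph of order n is n, so the division by n calibrates the
  complete graph to exactly 1.
- **geig** — the generalised problem L u = λ D u (equivalently the
  random-walk Laplacian D⁻¹L), which damps high-degree vertices. On the
  same complete graph λ₂ equals n/(n−1) — the mean of the non-smallest
  eigenvalues — so geig values are divided by n/(n−1) to share the
  calibration point. This constant is derived here from the complete-graph
  spectrum rather than taken from any reference. geig requires strictly
  positive degrees; a zero-degree vertex raises a degenerate-graph error
  (the hybrid mapper converts it to NaN for that vertex). Because D⁻¹L is
  invariant to a uniform rescaling of the weights, geig scores of weakly
  but randomly correlated (noise) neighbourhoods run much higher and more
  variable than unnorm scores — the practical argument for preferring the
  standard problem.

Eigendecompositions use a full symmetric solver (`scipy.linalg.eigh`),
never an iterative one: neighbourhood graphs have at most 27 vertices and
determinism matters more than asymptotic speed. Eigenvalues with |λ| <
1e−8 are snapped to 0; this is the connectivity tolerance everywhere
(double-precision eigensolver noise on 27×27 matrices is orders of
magnitude below it). When λ₂ has multiplicity > 1 the Fiedler vector is an
arbitrary unit vector in the eigenspace and is documented as non-unique;
λ₂ itself — all the VB index needs — remains well defined. VB values that
exceed 1 by < 1e−8 from round-off are snapped to 1; a larger excess is
treated as a bug and raises.

One numerical wart is intrinsic to the weight formula: arccos has
unbounded slope at corr = 1, so the last ulp of a correlation near 1
inflates to ≈ 1e−8 in the weight. Identical series can therefore score
0.99999999 rather than 1.0 exactly; nothing downstream resolves
differences at that scale.

## The ratio-cut oracle

For a bipartition of the vertex set into non-empty B and C, the cut-set
weight is Σ w_ij over cross pairs and the ratio cut is (1/n_B + 1/n_C)
times that, penalising unbalanced splits. Substituting the indicator
vector (1/n_B on B, −1/n_C on C) into the Laplacian quadratic form shows
the minimum ratio cut is the combinatorial counterpart of λ₂, which the
spectral relaxation bounds from below. `min_ratio_cut_exhaustive`
enumerates all 2^(n−1) − 1 bipartitions exactly, encoding each as an
(n−1)-bit integer with vertex 0 pinned to B: deterministic, seedless, and
ties break reproducibly to the first-encountered bitmask. The search is
milliseconds up to n ≈ 10 (the default validation sizes), supported to the
searchlight order n = 27 (2²⁶ partitions) behind an explicit
`allow_large` flag, and refused above. The cut-based VB approximation
divides the minimising partition's cut weight by n_B·n_C, treating every
graph as complete with some zero-weight edges.

No heuristic min-cut (spectral rounding, Kernighan–Lin) is provided: the
module's purpose is exactness on small graphs.

## ReHo (Kendall's W)

Each series is ranked along time (average ranks for ties); R_i is the
column sum of ranks at time point i, and W = 12·Σ(R_i − R̄)²/(m²(k³−k)).
The formula is implemented without a tie-correction term: continuous
fMRI-like data make ties measure-zero, and when ties do occur the
midranks only lower W. This is a deliberate divergence from tie-corrected
W variants. k < 3 is refused (the denominator degenerates); constant
series are allowed with a warning, entering as all-tied midranks.

## Searchlight mapping

The hybrid algorithm maps each unmasked surface vertex to a voxel through
the inverse volume affine with nearest-voxel assignment, rounding halves
away from zero — deliberately no interpolation, which is the artefact the
volume-space approach exists to avoid. The 3×3×3 block around that voxel,
clipped to the grid and intersected with the volume mask, supplies the
time series; the VB index or W is written back to the originating vertex.
Vertices mapping outside the grid, or whose neighbourhood keeps fewer
than `min_neighbors` voxels (default 3 — below that λ₂ and W are
uninformative; no canonical floor exists), yield NaN, never a silent
zero. Scoring is per-vertex independent and deterministic, so chunked
parallel execution (joblib) reproduces the serial map bit for bit.

The surface searchlight uses the vertex plus its one-ring (vertices
sharing a triangle edge); ring depth 1 is a design choice, made because a
single ring already mirrors the 27-voxel volume neighbourhood's scale.
Voxel indices are 0-based; the affine convention is index → mm as stored
in the NIfTI header.

## Synthetic data

`orthogonal_graph_series` realises a target topology exactly: the Gram
matrix I + c·Adj (c the adjacency correlation floor, default 0.5) is
factorised and expressed in a seeded orthonormal basis of the zero-mean
subspace of R^k, so non-adjacent pairs have Pearson correlation 0 to
machine precision and adjacent pairs sit at c. Infeasible demands (Gram
matrix not positive semi-definite, e.g. a high floor on a path) raise a
construction error naming the most conflicted vertex pair. This requires
k ≥ n + 1.

`simulate_fmri` builds baseline + task signal + noise on a regular grid.
The signal is a boxcar (20 s blocks, starting off) confined to hard-edged
spheres; it is scaled so that the temporal SD of the signal in a
unit-amplitude sphere equals snr × the pooled noise SD (default SNR 3).
The noise is a weighted sum of six components, each normalised to unit SD
before weighting (weights are fractions of noise SD and must sum to 1;
defaults white 0.05, temporal 0.10, drift 0.01, physiological 0.09, task
0.05, spatial 0.70):

- *white*: Rician magnitude noise with zero non-centrality, i.e.
  Rayleigh, left uncentred so its distributional shape survives mixing;
- *temporal*: an AR(3) process, coefficients (0.2, 0.1, 0.05);
- *drift*: a cosine at period 128 s with a random phase per voxel;
- *physiological*: cardiac (1.17 Hz) plus respiratory (0.2 Hz) sinusoids
  with random per-voxel phases, aliased by the 2 s repetition time as in
  real acquisitions;
- *task*: Gaussian perturbation confined to the activation spheres,
  standing in for spontaneous activity at the activation sites;
- *spatial*: per-volume Gaussian random fields, white noise convolved
  with a kernel of FWHM 4 voxels (reflect boundaries).

The AR coefficients, physiological frequencies, TR (2 s), grid (40³ at
1 mm), series length (k = 100) and sphere geometry (five radius-4 spheres
in one plane) are desk-scale defaults chosen here — documented, seeded and
deliberately modest so a full simulate-and-map cycle takes seconds; they
are not canonical to any acquisition. `flat_grid_mesh` supplies a
triangulated plane through the sphere centres as a stand-in cortical
sheet for pipeline tests. All generators are pure functions of
(spec, seed).

### What the generator does and does not emulate

It reproduces the signal/noise structure needed to exercise the pipeline:
block activations with hard edges, realistic noise colour in time and
space, and exact SNR bookkeeping. It does **not** emulate cortical
geometry (the mesh is a plane, not a folded sheet), a brain-shaped mask,
scanner baselines/drift interactions, or motion. One consequence is
visible in the maps: with 70% of the noise SD in a spatially smooth field,
neighbouring background voxels correlate at ≈ 0.4, so the background VB
mode sits near 0.39 rather than near 0 — analyses on real data, where the
mask clips neighbourhoods and the smooth component is weaker relative to
thermal noise, show a lower noise mode. Passing pipeline tests therefore
demonstrate *contrast and separation* (interior activation vertices ≈ 0.82
vs background ≤ 0.61, and higher/greater-variance geig backgrounds), not
absolute background levels on real acquisitions.

## I/O conventions

Volumes are NIfTI-1; surfaces and vertex maps are GIFTI, with the map's
data array stored as float32 (the GIFTI standard type for functional
data). Every map also gets a TSV mirror — lossless at double precision
(`%.17g` written, round-trip parsing on read) — plus a histogram TSV and
a JSON sidecar (configuration, seed, package versions, NaN count) from
which a run can be reconstructed. Affinity matrices round-trip to TSV and
`.npy`. CLI exit codes: 0 success, 2 input error, 3 numerical failure.

## Validation problem sizes

The shipped validation uses brute-force-friendly sizes: ratio-cut bounds
on 200 random graphs of order 4–10, the slope experiment on 118 dense
order-10 graphs (least-squares slope of λ₂ on the minimum ratio cut lands
at ≈ 0.85, inside the expected [0.8, 1.0] band for this regime), and
pipeline checks on the 40³ default simulation. These sizes were chosen so
the entire suite runs in well under a minute of compute per experiment
while keeping every combinatorial check exact.

## Known limitations

- Negative correlations are clamped to zero weight; anti-correlated
  structure is invisible to the index by design.
- The exhaustive oracle is exponential; n = 27 runs take minutes and are
  gated, larger orders are refused outright.
- The surface searchlight assumes a reasonable-quality mesh (one-ring
  neighbourhoods; isolated unmasked vertices yield NaN with a warning).
- The simulator's spatial noise is stationary and isotropic; real fMRI
  spatial correlation is neither.
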