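# Methods

## Connectivity model

Each subject contributes a matrix `Y` of N component time courses
(timepoints × components). The FNC between components j and k is their
partial correlation controlling for the remaining N−2 components: with the
sample covariance of `[X, Z]` (X the pair, Z the rest) partitioned into
blocks `S11` (2×2), `S12` (2×(N−2)) and `S22`, the partial covariance of X
given Z is the Schur complement `S11 − S12 S22⁻¹ S21`, and its
off-diagonal, normalised by its own diagonal, is the partial correlation.
Production code computes the whole matrix at once from the precision
matrix, `r(j,k) = −P_jk / √(P_jj P_kk)` with `P = S⁻¹` — algebraically
identical (the tests assert agreement to 1e−10) and O(N³) instead of
O(N⁵). The covariance uses the unbiased T−1 denominator; partial
correlations are invariant to that choice. Values are Fisher r-to-z
transformed (`atanh`), the diagonal is stored as 0 by convention, and
connectivity strength is the mean |z| over the N(N−1)/2 pairs (a mean
rather than a sum; the two differ by a constant factor only).

An optional ridge (`ridge · mean(diag S) · I`) guards inversion when the
covariance is near-singular; it defaults to 0 and is not needed at
T ≈ 194 > N = 57 **unless the data are band-passed first** (next section).

## Band-pass filtering and a well-posedness caveat

`bandpass()` removes the column means and filters each component to
0.01–0.10 Hz. The default is an ideal rectangular filter in the rFFT
domain (zero-phase; exact passband/stopband behaviour, which the tests
exploit); a zero-phase 4th-order Butterworth is available.

Caveat discovered in implementation: at T = 194 samples and TR = 1.5 s the
0.01–0.10 Hz band contains only ~27 rFFT bins, i.e. ~54 real degrees of
freedom per time course. Ideal filtering therefore projects the data onto
a subspace of dimension smaller than N = 57, making the sample covariance
exactly singular, and even the Butterworth filter leaves the
partial-correlation step badly conditioned. The pipeline consequently
accepts `filter_method: none` (recommended for the broadband synthetic
cohorts, which carry information at all frequencies) alongside
`butterworth` (the default, appropriate for scanner data whose energy is
already concentrated in-band) and `fft`. For short recordings with many
components, band-passing before a full partial-correlation analysis
trades noise rejection against estimability; the ridge guard exists for
exactly this regime.

## Graphs at fixed cost

Binary undirected graphs keep the E pairs with largest |z|; the recorded
threshold is the smallest included |z|. Ties are broken by |z| descending
then node pair (i, j) ascending — deterministic and seed-free. The
analysis grid is defined in integer edge counts (for N = 57: 560 to 665
in steps of 7, costs 0.351–0.417 as 3-decimal labels; the rounding only
works edge-count-first, since 0.417 × 1596 rounds to 666). Equal edge
counts across subjects are a design guarantee asserted in tests, and
thresholds are nested: each graph is a subgraph of the next denser one.

Automatic regime selection (`find_regime`) scans multiples of the step:
the minimum cost is the first at which every subject's graph is connected
(per-subject by default; a group-mean mode exists), and the maximum is the
last contiguous cost at which the cohort's graphs keep lower global and
higher local efficiency than their degree-matched random references
(group-mean comparison by default). An empty regime raises with
per-criterion diagnostics.

## Topological metrics

For node i with neighbour subgraph G_i: degree `K_i = |G_i|`; clustering
`C_i` = fraction of neighbour pairs that are connected; `L_i` = mean BFS
shortest-path length to the other nodes; nodal global efficiency = mean
reciprocal distance; local efficiency `E_local(i)` = global efficiency of
G_i. Network values are nodal means; `K_cost = K_net/(N−1)`; `E_global`
is the mean reciprocal shortest-path length over distinct pairs.
Conventions: `C_i = E_local(i) = 0` for degree < 2 (the 0/0 case);
disconnected pairs have distance ∞, contributing 0 to efficiencies and
making `L` infinite (reported with a warning — the regime is chosen to
avoid it). Distances use per-node BFS via scipy's sparse graph routines;
Floyd–Warshall and networkx serve as independent oracles in the tests,
including over every connected graph of the atlas (all non-isomorphic
graphs up to 7 nodes) plus a seeded sample of 8-node graphs.

## Random references and small-worldness

Degree-preserving references are generated by Markov-chain double-edge
swaps: each attempt picks two edges (a,b), (c,d) (with a random
orientation flip) and replaces them with (a,d), (c,b) unless that creates
a self-loop or duplicate edge; failed attempts are skipped. The default
budget is 10 × E attempts — ample mixing at N ≈ 57, E ≈ 600. Swaps are
not forced to preserve connectedness (the classical scheme does not); a
rejection mode is available, and disconnected ensemble members are
counted and reported. γ, λ and σ compare the subject's C and L with
ensemble means over (by default) 100 rewired graphs per cost — the fair
comparison when degree sequences are non-Gaussian — while the closed
forms `C_random = K/N` and `L_random ≈ ln N / ln K` are exposed
separately. Ensembles are seeded via SeedSequence spawning and
bit-reproducible.

## Group statistics

Per cost, network metrics (C, L, E_global, E_local, γ, λ, σ) are compared
with pooled-variance two-sample two-tailed t-tests (Welch behind a flag),
significance flagged at α = 0.05 uncorrected; with a 16-point grid the
expected false-positive count is 16 × 0.05 = 0.80 < 1. Nodal metrics get
the same tests as post-hocs with BH-FDR q-values reported alongside raw
p-values (flags are columns, rows are never filtered). Pearson
correlations relate metrics to symptom scores within the patient group,
per cost. A calibration test confirms the per-cost test rejects at
0.05 ± 0.02 over 2000 null cohorts.

## Synthetic cohorts

Subjects are i.i.d. Gaussian draws with covariance `P⁻¹`, where the
precision matrix `P = I − s·B` has off-diagonal support on a generated
topology (ring lattice, Watts–Strogatz, or G(n,m)), so the ground-truth
partial correlations are exactly ±s on the support and 0 elsewhere.
`sign_pattern="negative"` makes all partial correlations +s;
`"alternating"` draws random edge signs, which halves the spectral norm
of the off-diagonal block (≈ 2√k instead of k for mean degree k) and
therefore admits roughly twice the strength while staying positive
definite — also closer to real FNC, where inter-network partial
correlations are mixed-sign. Positive definiteness is checked by
eigenvalue; if violated, the diagonal is inflated to 1.1 × row absolute
sums (diagonally dominant, hence SPD), and construction fails loudly if
that would shrink the realized strength below half the target. Temporal
AR(1) smoothing (default 0.3) is applied per component after the spatial
draw, with innovations scaled to preserve stationary variance and columns
re-standardised, so the cross-sectional partial-correlation target is
unchanged while the series gain realistic autocorrelation.

Default study conditions: two groups of 19 subjects, 57 components, 194
timepoints at TR = 1.5 s. Both groups are Watts–Strogatz with 6
neighbours and strength 0.19 (mixed signs); the designed clustering
effect is topological — the patient-like group uses 2% rewiring (near
lattice, high ground-truth clustering) and the control group 100%
rewiring (random topology at the same density). This choice followed a
design power analysis: with T = 194 the SPD constraint caps the per-edge
strength near the sampling noise of a partial correlation conditioned on
55 components (σ ≈ 0.09), so count-based effects (extra triangle-closing
edges, still available via `GroupEffect`) are both SPD-fragile (they grow
hubs) and statistically invisible, whereas the equal-density topology
contrast yields a group difference in the thresholded graphs' clustering
that is reliably signed across cohorts. Synthetic symptom scores are
integer-rounded Gaussians around a linear function of a chosen per-subject
network metric (standardised within the patient group), truncated to the
PANSS-like 7-item range 7–49; with slope a and noise σ the designed
correlation is a/√(a²+σ²). A subject whose reference-cost graph is
disconnected (infinite L) is scored as the most severe finite value.

What the generator does **not** emulate: voxel-level signals,
hemodynamics, ICA unmixing error, scanner artefacts, inter-subject
topology variability within a group (all subjects of a group share one
ground-truth network), or the empirical FNC strength distribution of real
data (whose |z| thresholds at these costs are several times larger than
any sparse SPD model at this T can produce). Passing tests therefore
demonstrate correctness of the estimation and statistics machinery under
a known truth, not clinical validity.

## Numerical and design notes

- Costs are exact rationals 2E/(N(N−1)); printed values are 3-decimal
  labels. `edges_for_cost` rounds half away from zero and is only used
  for user-supplied costs.
- Global seeds fan out through `numpy.random.SeedSequence` spawning keyed
  by stage name (CRC32) and subject/grid indices: independent streams,
  bit-identical reruns, all derived seeds < 2³¹.
- Problem sizes in the test suite are chosen for single-core runs: the
  designed-effect recovery uses 50 cohorts at full study size on a
  6-point subgrid of the 16-point cost grid (the subgrid mean carries the
  same information at a third of the cost); oracle sweeps use the 7-node
  atlas plus sampled 8-node graphs; the calibration study uses 2000 small
  cohorts (10 nodes, 50 timepoints, 5 vs 5).
- Known limitations: no weighted-graph variants, no lagged
  cross-correlation connectivity, no covariate adjustment or mixed
  models, no multiple-comparison correction of the network-level tests
  beyond the reported false-positive budget (by design), and `find_regime`
  can be slow for large n_random since it rewires every subject at every
  candidate cost.
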