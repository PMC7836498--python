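# Methods

## The criticality index

For each cortical vertex *i* with BOLD series *x_i(t_1) … x_i(t_N)*, the
vertexwise Index of Functional Criticality is

    vIFC(i) = STD(i) · ⟨r_ij : j ∈ I⟩ / ⟨r_ik : k ∉ I⟩

where *r* is the Pearson correlation across time and the angle brackets
average over vertices. The index rises when a vertex behaves like the
center manifold of an approaching critical transition: its own temporal
variation grows, its coupling to a dominant cluster *I* grows, and its
coupling to the rest of the network falls.

Conventions adopted here:

* **STD term.** `STD(i) = sqrt(Σ_n (x_i(t_n) − ⟨x_i⟩)²)` — the root sum
  of squared deviations, not divided by N. For a fixed scan length this
  differs from the sample standard deviation by the constant factor
  √N (or √(N−1)), which rescales every map identically and changes no
  downstream correlation, t-statistic or p-value.
* **Network membership.** Both *I* and *K* are drawn from the thresholded
  connectivity network `E(i) = {j ≠ i : r_ij ≥ p}` with signed (positive)
  correlations only. This guarantees `pcc_out > 0`, hence vIFC ≥ 0, and
  follows the convention of positive-FC thresholding that motivates the
  0.15–0.3 threshold grid. A config switch (`threshold_in_set=False`)
  preserves the alternative reading in which only the out-set is
  thresholded.
* **In-set.** D-vIFC: `I = E(i) ∩ {j : d(i,j) < D}` with strict
  inequality — a vertex at exactly the threshold distance belongs to the
  out-set. N-vIFC: `I = E(i) ∩ one-ring(i)`. Vertex *i* itself belongs to
  neither set (its self-correlation of 1 would bias the in-mean).
* **Degenerate vertices.** A masked vertex, a constant series, or an
  empty *I* or *K* yields NaN with a per-vertex reason code, and the map
  logs the counts. The index is simply undefined there; NaN is never
  silently replaced by 0.

The default parameter grid is the study grid: distance thresholds D ∈
{14, 28, 42, 56} mm, connectivity thresholds p ∈ {0.15, 0.2, 0.25, 0.3},
giving 16 maps per subject per smoothing level.

## Distances on the mesh

Geodesic distance (the default) is the graph shortest path with edge
weight equal to the Euclidean segment length, computed by Dijkstra over
the mesh edges **augmented with one shortcut per pair of adjacent
triangles** (joining the two vertices opposite the shared edge). The
plain edge graph overestimates surface geodesics by up to ~15–20% on a
triangular lattice (paths must zig-zag along lattice directions); the
across-face shortcuts cut the worst-case deviation on a subdivision-3
icosphere to ≈ 4% of the analytic great-circle arc, at unchanged
asymptotic cost. Exact polyhedral geodesics (MMP, heat method) were
deliberately not used: at ~4 mm vertex spacing against 14–56 mm
thresholds the residual error is immaterial, and graph Dijkstra is
trivially verifiable against an independent textbook implementation.
Euclidean (chord) distance is available as a configurable alternative;
it never exceeds the geodesic. Hemispheres are processed independently;
masked (medial-wall) vertices are removed from the graph before any
distance or correlation is computed.

`DistanceIndex` precomputes, for every unmasked vertex, all neighbors
within the largest configured radius; the per-radius balls are nested by
construction.

## Surface smoothing

Maps are smoothed by iterated graph diffusion `v ← v + λ L v` with the
unweighted graph Laplacian, step `λ = 1/(2·max degree)` (monotone and
stable), and an iteration count chosen so the accumulated kernel
variance matches a Gaussian of the requested FWHM given the mean edge
length (`n ≈ 2σ² / (λ·⟨deg⟩·⟨h²⟩)`, σ = FWHM/2.355). The mapping from
FWHM to iterations is approximate — iterated neighbor averaging
converges to a Gaussian only in the many-iteration limit — but the
update is exactly mean-preserving on an all-finite closed mesh
(symmetric edge flows cancel) and never increases variance. NaN vertices
are excluded from every average and remain NaN. FWHM is an independent
knob (default 10 mm), never inferred from the distance threshold: the
smoothing-kernel text in the source material lists three kernels against
four thresholds, so no mapping is assumed.

## Group inference

Vertexwise association maps follow the group-descriptor convention
"different offset, different slope" (DODS): with *g* group levels and
*m* regressors (age, sex, education, plus the behavioral scores of the
chosen model) the design holds one intercept per level and one slope per
regressor per level. Sex enters as a 0/1 column treated like a
continuous covariate; an all-zero column (a regressor vanishing within a
level) is dropped with a log note, and any remaining collinearity is a
hard error naming the columns. The behavioral contrast is the average of
the per-level slopes (the common slope); per-level contrasts are emitted
alongside. Fits are ordinary least squares vectorized across vertices;
vertices with NaN in any subject are skipped and counted.

Multiple-comparison control is Benjamini–Hochberg at α = 0.05/2 within
each hemisphere — the halving is a Bonferroni correction over the two
hemispheres. Significant vertices are split by contrast sign and grouped
into edge-connected components; components under 5 vertices are
discarded. Surviving clusters ("sigClusters") are summarized by the
partial correlation of cluster-mean criticality with the behavioral
score after residualizing both on age, sex and education (p-value from
the t-transform with n − covariates − 2 degrees of freedom).

## Connectivity distance

Each sigCluster seeds a functional-connectivity map: the cluster-mean
series is correlated with every unmasked non-cluster vertex and p-values
come from the t-transform `t = r·√((N−2)/(1−r²))`. The map is
Bonferroni-thresholded at α = 0.05 over the vertices actually tested.
A subject's connectivity distance for that cluster is the mean over
significant vertices of the cluster-to-vertex distance, where the
cluster-to-vertex distance is by default the mean over cluster members
(min-to-cluster and Euclidean-centroid variants are exposed because
"average distance between cluster and vertices" admits several
readings). Cluster members are excluded from the significant set — their
near-zero distances would mechanically deflate the statistic — and an
empty significant set yields an explicitly undefined (NaN) result, never
zero. Distances per behavior/configuration are averaged over a subject's
clusters and compared between groups with a two-sample t-test
(equal-variance by default, Welch optional).

## Synthetic data

The generator is a Gaussian latent-factor model:

    x_i(t) = Σ_c a_c·f_c(t)·[i ∈ cluster c] + b·g(t) + σ·ε_i(t)

with independent standard-normal factors, chosen over autoregressive
BOLD realism because every second moment is closed-form: two vertices
sharing a factor with weight *a* on noise σ correlate at
`a²/(a²+σ²)`, so expected vIFC components are analytically checkable.
Clusters are geodesic balls; clusters declaring the same factor id share
one latent series, which plants long-range functional connectivity
between separated patches (the substrate of the connectivity-distance
experiments).

Defaults are the package's study conditions, fixed once:

* sphere radius 75 mm — the 14–56 mm threshold grid then spans local to
  broad neighborhoods at roughly fsaverage5 scale (note the vertex
  *spacing* depends on the subdivision level: 162 vertices at 75 mm are
  ~20 mm apart, so the 14 mm ball is empty; fixtures that exercise
  D = 14 use either subdivision 3 at 75 mm or subdivision 2 at 40 mm,
  both ~10 mm spacing);
* global coupling b = 0.4 on unit noise (background r ≈ 0.14, at the
  scale of the lowest connectivity threshold) so the thresholded network
  is non-degenerate surface-wide, as on real cortex;
* cohorts of 30 per group, ages ~19.5–32.8 vs ~36.6–64.3 years,
  IQ-like scores at 100 ± 15, education 8–22 years, N = 200 timepoints
  (TR 2 s, ~7 min of scan);
* planted brain–behavior effect `a_subject = a₀ + γ·z(score)` linking
  cluster coherence linearly to the standardized score.

What the generator does **not** emulate: cortical folding (so geodesic ≈
Euclidean up to sphere curvature), distance-dependent background
connectivity decay, hemodynamic autocorrelation, motion artifacts, and
inter-subject anatomical variability. Passing tests therefore establish
the correctness and calibration of the algorithms under a controlled
generative model — not that real cortical criticality behaves this way.
In particular, the normal-quantile diagnostic on synthetic maps reflects
the planted patch/background mixture (heavy right tail), not the
distributional shape of criticality on real cortex.

## Numerical choices and limitations

* Correlations are computed on the series as given — preprocessing
  (nuisance regression, filtering, projection) is upstream and out of
  scope. Computed r values are clipped to [−1, 1] against rounding.
* Problem sizes in tests and the acceptance script (162–642-vertex
  spheres, 80–200 timepoints, 10–60-subject cohorts, 20–100 replicates)
  were chosen so the full verification chain — including brute-force
  O(V²) oracles — runs in seconds per experiment while leaving every
  statistical check well-powered.
* The per-vertex map computation builds the full V×V correlation matrix;
  at fsaverage5 scale (10,242 vertices) this is ~0.8 GB and remains
  practical, but substantially finer meshes would need a blocked
  implementation.
* BH-FDR is applied to the common-slope contrast per hemisphere;
  per-level contrasts are reported but not cluster-extracted by the CLI.
* Ties at the distance threshold are resolved by the strict d < D rule;
  ties in cluster ordering by (size desc, smallest vertex id).
* The CLI writes CSV with a fixed `%.10g` float format and sorted JSON
  keys, so repeated runs with one seed are byte-identical.
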