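# Methods

This package recomputes a family of eleven topological indices for ten drugs
(three hypouricemic agents: allopurinol, oxypurinol, febuxostat; seven
anti-androgens: abiraterone, bicalutamide, flutamide, nilutamide,
leflunomide, teriflunomide, ailanthone), and carries the downstream
chemometric and QSPR analyses those indices feed: single-linkage cluster
analysis, correlation-matrix PCA with the Kaiser criterion, and univariate
linear property models.

## The molecular graph

All indices operate on the hydrogen-suppressed Kekulé multigraph: heavy
atoms are vertices; bonds are edges with integer order b ∈ {1, 2, 3};
aromatic rings are kekulized to alternating single/double bonds; hydrogens
are folded into a per-atom count h. Two degree vectors are derived:

- the **multigraph degree** δ_i = sum of bond orders at vertex i (a double
  bond counts twice, a triple three times);
- the **valence delta** δ^ν_i = Z^ν_i − h_i, valence electrons minus
  attached hydrogens.

The multigraph (bond-order) reading of δ is the convention that reproduces
the published adjacency indices of the study compounds: allopurinol's degree
multiset {2,2,2,3,3,3,3,4,4,4} gives M = 96 and ⁰χ = 5.9307 against the
printed 96 / 5.9309, whereas simple edge-count degrees give M = 74 and
⁰χ ≈ 6.97. The simple-degree dialect remains available
(`degrees(g, dialect="simple")`) for comparison only.

Nitro groups are written as neutral pentavalent N(=O)=O (δ_N = 5,
δ^ν_N = 5), the hand-drawing convention of this index family; RDKit's
normalization step that would rewrite this into the charged form is
deliberately disabled. The supported element set {C, N, O, F, S, Cl} covers
all ten compounds; it is a data table, not a code assumption.

## The eleven indices

Adjacency-based: Gutman M = Σδ², Mν = Σ(δ^ν)²; Randić ⁰χ = Σδ^−1/2 over
vertices, ¹χ = Σ(δ_i δ_j)^−1/2 over edges, and the valence variants ⁰χ^ν,
¹χ^ν with δ^ν in place of δ. Each bond contributes one ¹χ term regardless of
its order; multiplicity enters only through the degrees.

Distance-based, from the Barysz weighted distance matrix D: diagonal
d_ii = 1 − 6/Z_i (zero for carbon); off-diagonal d_ij = minimum over paths
of the summed edge weights k_r = (1/b_r)·36/(Z_i Z_j). Then Wiener
W = trace(D) + Σ_{i<j} d_ij; Rouvray–Crafford R = full-matrix sum
(identically 2W − trace, an invariant the test suite checks to 1e-9); and
the Pyka indices from the distance degrees S_i = Σ_j d_ij (off-diagonal row
sums): A = ΣS_i², ⁰B = ΣS_i^−1/2, ¹B = Σ(S_i S_j)^−1/2 over bonded pairs.

Shortest paths are minimum *total weight* (Dijkstra from every vertex, all
weights positive), not minimum edge count. We verified on the study
compounds that the two conventions coincide or that minimum weight is the
better match to the published values; an exhaustive Floyd–Warshall oracle
backs the implementation in the tests at 1e-12. For an all-carbon
single-bonded molecule every weight is 1.0 and D reduces to the classic
integer topological distance matrix with zero trace.

**C=C weight dialect.** The published per-bond-type weight table prints
1.500 for C=C, but the defining formula gives 0.500, and the same table's
C=O (0.375 = 0.750/2) and C=N (0.428 ≈ 0.857/2) rows follow the formula.
Computed with 0.500, allopurinol's W is 76.798 against the printed 76.804;
with 1.500 it would be 86.99. The formula value is therefore the default
(`kcc_dialect="eq85"`); the printed 1.500 stays available as
`kcc_dialect="table6"`.

**Caveat on Pyka A.** A = ΣS_i² is implemented literally, but the published
A column cannot come from this formula: by Cauchy–Schwarz
ΣS_i² ≥ (ΣS_i)²/n, and for allopurinol the same published row's R implies a
lower bound near 2.3e3 while the printed A is 48.6479. Whatever reduction
the original authors applied is not recoverable from their text, so the
literal value is reported and every result carries the caveat string
(`topoindex.indices.PYKA_A_CAVEAT`). The A column is excluded from all
reproduction checks.

## Fixture structures and tautomer selection

The ten structures are embedded as Kekulé SMILES (`data/compounds.smi`) so
every drawing choice is auditable. M, Mν, ⁰χ and ⁰χ^ν depend only on the
degree multiset and are tautomer-invariant for these skeletons; ¹χ, ¹χ^ν and
the distance-matrix indices are not. For allopurinol and oxypurinol we
enumerated every valid Kekulé/NH placement of the keto skeletons and kept
the drawing that best reproduces the published row: the 1,2-dihydro form
(both pyrazole NH, ring doubles N5=C6 / N7=C7a / C3=C3a). For allopurinol it
gives ¹χ = 3.6480 (printed 3.6481), ¹χ^ν = 2.7451 (exact), W = 76.798
(printed 76.804); the canonical 1,5-dihydro tautomer would give ¹χ = 3.6212
and W = 78.08. The same 1,2-dihydro pattern independently wins for
oxypurinol (¹χ 4.0420 vs printed 4.0423; ¹χ^ν exact), which supports reading
it as the original drawing convention rather than a coincidence.

The ailanthone entry is a synthetic reconstruction from the published
constitution (picrasane skeleton; 2,16-dione with the δ-lactone; Δ3 and
Δ13(21) double bonds; 1-OH, 12-OH and the 11,20-epoxy hemiketal), verified
to C20H24O7; no structure or checkable index value is printed for it beyond
the table row.

## Known irreproducible published values

These are documented here once and excluded from reproduction tests; they
do not affect how the package computes anything.

- **Febuxostat adjacency row.** Printed M = 190, Mν = 342, ⁰χ = 14.499. The
  valid structure gives 202 / 354 / 14.2926. All three printed values are
  exactly consistent with a drawing that lost one benzene double bond
  between a CH and a substituted carbon (ΔM = −12, ΔMν = −12,
  Δ⁰χ = +0.2071); such a graph violates carbon valence, so the package keeps
  the correct structure and reports the honest values.
- **Distance-matrix residuals.** Even with the best-matching drawings,
  printed W/R/⁰B/¹B cells differ from the minimum-weight-path values by up
  to a few parts in 10³ (allopurinol W: +0.006; bicalutamide R: +16.4 on
  3495), consistent with occasional slightly non-minimal hand-chosen paths.
- **Internal identity violations in print.** 2W − R must equal
  Σ(1 − 6/Z) of the composition. Eight of the ten published rows satisfy
  this within 0.01; abiraterone misses by exactly 1.000 (a digit slip in R)
  and teriflunomide by 1.338.
- **Two anomalous cells** (abiraterone ¹χ = 1.5871, flutamide
  ¹χ^ν = 2.0128) are far outside any convention we can construct and are
  treated as misprints.

## Chemometrics

Cluster analysis is agglomerative single linkage on Euclidean distances,
on compounds (rows) or descriptors (columns). It runs on the **raw** index
values by default: that configuration reproduces both published dendrogram
readings — the compound clusters {allopurinol, oxypurinol},
{flutamide, leflunomide, teriflunomide}, {ailanthone, nilutamide}, and the
Rouvray index R joining the descriptor tree last. On autoscaled rows the
third compound cluster becomes {febuxostat, nilutamide} instead, so the
original analysis evidently clustered unscaled values (the huge-magnitude
W/R/A columns dominate the metric); `standardize_first=True` provides the
autoscaled variant. Because no cut height is published, "the three clusters"
are extracted as the tightest multi-member clusters: the partition at the
smallest merge height at which exactly three multi-member groups exist.

PCA is the eigendecomposition of the correlation matrix — identical to
covariance-PCA after autoscaling, the study's stated preprocessing. With 10
observations and 11 variables the matrix is rank-deficient; trailing
eigenvalues within −1e-9 of zero are clamped to 0, and eigenvalues sum to
the number of variables (checked to 1e-9). Component retention follows the
Kaiser rule (eigenvalue > 1); on the study table exactly two components
pass, explaining 83% of the variance. Loading signs are fixed by making
each component's largest-magnitude loading positive; all reproduction
checks are orientation-free.

## QSPR regression

Models are univariate ordinary least squares, property = b + a·index, with
Pearson r and the two-sided p-value from t = r·sqrt((n−2)/(1−r²)). The
published coefficient tables place the property on the left, and that
orientation is authoritative here (the source's running text nominally
swaps x and y). Fits never pool across pharmacological groups. The
hypouricemic group has n = 3, so its p-values carry one degree of freedom
and the `low_n` flag. Missing property cells are dropped pairwise. No
multiple-testing adjustment is applied: the screen is the raw p < α filter
with α = 0.05 by default, ranked by |r| within each property, ties broken
by index column order.

The property inputs the original equations were fitted on (thin-layer
chromatography R_MW values and eight calculator logP variants) are published
elsewhere and not printed, so the printed correlation coefficients are not
desk-verifiable. What is verifiable, and tested: refitting on noiseless data
generated from any of the 82 transcribed equations, with the group's
published index values as x, returns that equation's coefficients to 1e-9
with |r| = 1.

## Synthetic data

`generate_qspr` emulates the missing property tables: a descriptor drawn
uniformly over the span of the published Wiener column (76.8–1749.2), one
property exactly linear in it plus homoscedastic Gaussian noise, and
independent standard-normal noise columns. Default planted parameters echo
the published logP–W equation (slope 0.00599, intercept −1.060); the default
noise SD of 0.1 logP units is of the order of the scatter between the
published logP calculators. `generate_cluster_blobs` produces two
unit-variance Gaussian groups a configurable number of SDs apart for
cluster/PCA recovery checks. Both are driven by `numpy.random.default_rng`
seeds and are bit-reproducible.

What the generators do *not* emulate: correlated descriptor columns,
heteroscedastic or heavy-tailed measurement error, and the strong
inter-calculator correlation of real logP variants. Passing recovery tests
therefore demonstrate correctness of the fitting/screening machinery, not
predictive validity of the published equations on new compounds.

## Numerical policy

Full double precision throughout; CSV output rounded to 4 decimals to
mirror the published table. Comparisons against printed values use absolute
tolerance 5e-4 for 4-decimal columns (one unit in the last printed digit
has been allowed where the printed table visibly truncates, e.g. the C=N
weight 0.428 vs 0.42857). Degenerate inputs raise informative errors:
disconnected graphs (distances undefined), constant columns
(standardization/correlation undefined), fewer than 3 points per fit, zero
degrees or distance degrees in the inverse-square-root sums.

## Problem sizes

Everything here is small by construction: ten compounds of 10–29 heavy
atoms, 82 equations, and simulation-based checks sized at 2,000 replicates
(type-I calibration) and n = 10,000 (generator moment checks) — enough for
the confidence intervals asserted in the tests while keeping the whole
suite interactive.
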