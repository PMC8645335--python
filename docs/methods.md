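# Methods

`activemod` detects active modules — connected groups of genes on an
interaction network whose measured perturbation (per-gene p-values from a
differential-expression analysis) is jointly stronger than chance — without
requiring the user to choose a module count or size. This note records the
model, its parameters, the numerical choices, and the places where the
design was genuinely open, together with what our synthetic benchmarks do
and do not demonstrate.

## Model and pipeline

**Inputs.** An undirected interaction network with edge confidences in
[0, 1] (STRING `protein.links` scores divided by 1000, or a generic TSV
edge list), and a per-gene score table with a p-value per gene. Duplicate
edges keep the maximum confidence; duplicate genes keep the minimum
p-value; p-values are clipped to `[1e-16, 1 - 1e-16]` before any transform
(DESeq2 regularly reports exact zeros, whose normal quantile would be
infinite).

**Attribution.** Each network node receives
`z(v) = Φ⁻¹(1 − p(v))`, where `Φ` is the standard normal CDF. Genes
measured but absent from the network are logged and ignored; network nodes
without a measurement receive the neutral `p = 0.5` (`z = 0`) by default
(`missing_policy="neutral"`), because removing them would change the
topology that the embedding relies on. A `drop` policy is available.

**Embedding.** Second-order biased random walks (node2vec) over the
confidence-weighted network, followed by skip-gram training with negative
sampling. The walk's unnormalised transition weight from `cur` to a
neighbour `x` given the previous node `prev` is
`w(cur,x) · 1/p` if `x = prev`, `w(cur,x)` if `x` neighbours `prev`, and
`w(cur,x) · 1/q` otherwise. Cosine distance between trained vectors defines
`lov(v)`: all vertices sorted by distance from `v`, self first, ties broken
lexicographically by node id so the ranking is deterministic.

**Search.** For every vertex `v` the candidate module is the prefix of
`lov(v)` of length `k*+1`, where `k*` maximises the Stouffer aggregate
`z(v,k) = Σ_{j≤k} z(lov(v)[j]) / √(k+1)` over `k ∈ [0, k_max]`; ties go to
the smaller `k`. Adding an unperturbed (`z ≈ 0`) gene strictly lowers the
aggregate, which is the mechanism that bounds module growth. One candidate
per vertex; identical member sets are deduplicated keeping the smallest
seed id.

**Merge.** Candidates with a nonempty member intersection are spatially
cohesive. Starting from the highest-z unconsumed candidate, the union with
every subset of its cohesive pool is scored with the same Stouffer
aggregate and the best union is emitted; every candidate intersecting the
emitted module is consumed, so final modules are pairwise disjoint, and
because the empty subset is evaluated the emitted z never falls below the
best constituent. The pool is the 10 highest-z distinct overlapping
candidates and the subset search is always exhaustive (2^10 unions). The
bound exists for two reasons. First, an unbounded best-improvement loop
exhibits runaway accretion: once a module is large, the marginal z
threshold for absorbing another candidate falls roughly like
`z_agg / (2√n)`, and chains of moderately-scoring background genes get
absorbed indefinitely. Second — decisive — a bounded exhaustive rule can be
replayed exactly inside the permutation null below, so the significance
test compares the observed modules against the same maximisation that
produced them. In development this mattered: with an unbounded merge the
null was anti-conservative (2 of 10 null runs produced a "significant"
module; 0 of 10 after bounding).

**Significance and selection.** The method is advertised as parameter-free,
so module selection is automatic. Node p-values are shuffled across nodes
`n_perm` times (topology and embedding fixed); each permutation replays the
search — per-seed best prefix on the shuffled z, then the bounded cohesive
merge around the top candidate — and records the maximum module z. Each
observed module gets
`empirical_p = (1 + #{null_max ≥ z}) / (n_perm + 1)`; `finalize` keeps
modules with `empirical_p ≤ α` (default 0.05) and at least `min_size = 3`
genes (smaller modules are rarely informative) and renumbers them by
descending z. Comparing every module against the *maximum* null statistic
is a family-wise choice: it is exact for the top module and conservative
for the rest. When no embedding is supplied, a fallback null compares each
module against the maximum Stouffer z of `n` random same-size node sets
per permutation (set indices drawn with replacement; at these sizes the
collision probability is negligible).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_confidence` | 0.7 | STRING "high confidence" edge cut (score ≥ 700/1000) |
| `fold_threshold`, `padj_threshold` | 1.25, 0.05 | DE filter: keep `abs(log2FC) ≥ log2(1.25) ≈ 0.32` and adjusted p ≤ 0.05 |
| `dimensions` | 128 | embedding width (canonical node2vec) |
| `walks_per_node`, `walk_length` | 10, 80 | walk corpus size (canonical node2vec) |
| `p`, `q` | 1, 1 | return / in-out walk bias; 1,1 is a first-order weighted walk |
| `window`, `epochs` | 10, 5 | skip-gram context radius and passes |
| `negative` | 10 | negative samples per positive pair |
| `sample` | 1e-3 | word2vec frequency subsampling threshold |
| `k_max` | min(100, n−1) | prefix-search cap; real runs report modules well under 100 genes, and the cap keeps the search O(n²) |
| `n_perm` | 1000 | permutations; the smallest resolvable p is 1/1001 |
| `alpha`, `min_size` | 0.05, 3 | selection thresholds |

`negative = 10` (instead of word2vec's customary 5) and `sample = 1e-3`
were fixed during method development on the synthetic benchmark: with 5
negative samples the embedding was noticeably noisier and one of five
planted modules was missed outright. All values are overridable through
`EmbeddingConfig`, `ActiveModuleModel` arguments, the `RunConfig` file, or
CLI flags.

**Determinism.** One seed governs walk starts, transition sampling,
skip-gram initialisation and order, and the permutation test. Walks and
training run in single-threaded numba kernels seeded at entry, so a fixed
seed gives bitwise-identical embeddings and byte-identical output tables.
All set-to-list conversions that feed the RNG or float accumulation are
sorted first; results are therefore independent of Python's string-hash
randomisation.

## The score-biased walk option

`EmbeddingConfig(score_bias=True)` multiplies the transition weight toward
node `x` by `1 + max(z(x), 0)`, attracting walks to perturbed
neighbourhoods. On the planted benchmark this raises mean best-match F1
from ≈ 0.56 to ≈ 0.70, because on small-world networks topology alone
barely separates a 15-gene neighbourhood (two hops already reach a large
fraction of all genes). The flag nevertheless defaults to **off**: a
score-adapted embedding violates the exchangeability assumption of the
permutation test. The observed search then runs on an embedding aligned
with the observed scores, an advantage no fixed-embedding permutation can
reproduce, and on null data this measurably inflates significance (5 of 10
null runs reported a module with the naive null, 2 of 10 even with the
replay-matched null, versus 0 of 10 with the default). An honest null for
the biased mode would have to re-train the embedding for every
permutation, which is computationally out of reach at `n_perm = 1000`. Use
the flag for exploratory ranking, not for calibrated discovery.

## Synthetic benchmark

`generate_benchmark` builds a preferential-attachment (Barabási–Albert)
graph — matching the hub-dominated, small-world character of protein
interaction networks — plants `n_modules` connected subgraphs by seeded
random-walk induction, assigns planted p ~ U(0, `p_signal_max`) and
background p ~ U(`p_signal_max`, 1), and writes the same file formats the
pipeline reads. Edge confidences are drawn from U(0.7, 1), mirroring a
high-confidence STRING cut. Recovery is scored as best-match precision,
recall and F1 per planted module.

What this emulates: the size and sparsity regime of a high-confidence
interaction subnetwork, a coherent perturbed neighbourhood, and uniform
null p-values elsewhere. What it does not: correlated p-values between
interacting genes, measurement-platform artefacts, identifier mismatch
between network and score table, false and missing edges with structure,
and modules whose members are perturbed in opposite directions. Passing
the benchmark therefore demonstrates the machinery (embedding locality,
search correctness, calibration), not field performance on real tissue
data.

At the default settings (n = 500, attach m = 3, one planted module of 15,
signal p ≤ 1e-4, seeds 0–4) the pipeline reaches mean best-match F1 ≈ 0.56
with every planted module flagged significant, and reports zero modules on
fully null data. Two structural facts bound what is achievable here: an
oracle ranking built from exact hop distances, run through the identical
search and merge, reaches only F1 ≈ 0.72 (the information simply is not in
the topology at this density), and score-aware rankings that would lift
the candidates further make every vertex's candidate include the global
high-z backbone, after which Stouffer maximisation legitimately prefers
large diluted unions. The residual gap between 0.56 and the 0.72 oracle is
embedding noise.

## Numerical choices and degenerate inputs

* Inverse normal CDF via `scipy.stats.norm.isf`; validated against a
  bisection oracle on an erf-based CDF to 1e-9. The antisymmetry
  `z(p) = −z(1−p)` holds to 1e-9 only for p in roughly [1e-6, 1−1e-6]:
  beyond that, `1−p` itself rounds in double precision and no
  implementation can do better.
* Stouffer normaliser `√(k+1)` by default; a plain-mean normaliser is
  available (`normalizer="mean"`) for sensitivity analysis.
* Distance ties in `lov` break lexicographically; equal-z ties in the
  prefix search prefer the smaller module; candidate ties in sorting break
  by seed id.
* Degree-0 nodes emit singleton walks and receive near-random vectors
  rather than being dropped, preserving the all-nodes-embedded invariant.
* An embedding dimension at or above the node count is allowed but logged.
* Empty final module sets are legal everywhere: files are written with
  headers only, the CLI exits 0, and a warning is logged.

## Known limitations

* No identifier mapping: network and score table must share a namespace
  (a `--case-fold` option exists; nothing more).
* The permutation null assumes independent p-values under H0;
  co-expression-induced correlation between neighbouring genes will make
  it anti-conservative on real data, as for any method of this family.
* Modules are non-overlapping by construction; a gene belongs to at most
  one module per run.
* The cohesive merge explores subsets of the 10 strongest overlapping
  candidates; pathological inputs with hundreds of equally strong
  overlapping candidates are resolved greedily by that bound rather than
  globally.
* Benchmark recovery precision is intrinsically limited by Stouffer
  maximisation absorbing moderately perturbed neighbours of a true module;
  see the benchmark section.
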