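# Methods

## Model

`mdbirw` treats metabolite–disease association prediction as link prediction
on a heterogeneous network: a metabolite similarity graph, a disease
similarity graph, and the known bipartite association matrix `A` (rows =
metabolites, columns = diseases) connecting them. The working assumption is
guilt by association — functionally similar metabolites tend to associate
with the same or semantically similar diseases — so propagating the known
links a bounded number of steps through each similarity graph concentrates
probability mass on plausible unobserved pairs.

### Similarity construction

* **Disease semantic similarity** uses each disease's ancestor DAG. A term's
  contribution decays by `Δ` per level toward the disease (max over children,
  memoized depth-first evaluation with a cycle guard), the disease's semantic
  value is the sum of contributions, and pairwise similarity is the shared
  contribution mass normalised by the two semantic values. Self-similarity is
  algebraically 1; the diagonal is also forced to 1 to remove floating-point
  drift. Diseases with no DAG get a zero row/column (unit diagonal) so that
  integration falls back to the GIP kernel — the zero-substitution branch of
  the integration rule only makes sense under this convention.
* **Metabolite functional similarity** (MISIM-style) is group-max averaging of
  disease semantic similarities over the two metabolites' disease sets. If
  both sets are empty the value is defined as 0 (again deferring to GIP);
  the diagonal is 1 exactly when the metabolite has at least one association.
* **GIP kernels** use bandwidth `λ = λ′ / mean‖IP‖²` with `λ′ = 1` for both
  node types — each kernel normalised by its own side's mean squared profile
  norm. If every profile is zero the kernel degenerates (mean norm 0); it is
  then returned as the identity with a warning so downstream normalisation
  stays defined. An individual zero profile is kept as the kernel gives it:
  `exp(−λ‖IP_k‖²)` against node `k`. Note this value is *larger* for
  low-degree partners, which mildly distorts rankings for nodes blinded of
  all their associations; dense semantic similarity masks the effect, which
  is why the integration rule prefers the semantic value whenever it is
  nonzero.
* **Integration** substitutes the GIP value where the semantic/functional
  value is zero and otherwise averages the two, with the diagonal forced to 1.

### The walk

With Laplacian-normalised similarity networks `MS′ = D^{-1/2}·MS·D^{-1/2}`
(degree = row sums; zero-degree rows left zero) and the restart matrix
`A₀ = A / ΣA`, the two recursions

    RM_t = α·MS′·RM_{t−1} + (1−α)·A₀        (runs while t ≤ l)
    RD_t = α·RD_{t−1}·DS′ + (1−α)·A₀        (runs while t ≤ r)

start from `RM₀ = RD₀ = A₀` and run `max(l, r)` iterations. After each
iteration the score matrix is the average of whichever walks executed:
`R = (flagm·RM + flagd·RD) / (flagm + flagd)` with the flags raised only in
iterations where the corresponding bound is not yet exhausted. This gating is
the convention of the BiRW family and the only reading under which unequal
`l` and `r` change the result; a `strict_pseudocode=True` mode instead keeps
both flags raised permanently, so an exhausted walk's stale matrix keeps
averaging in — both behaviours are implemented because published pseudocode
for this family is ambiguous on the point, and neither is asserted to be the
variant behind any particular published number. The recursion is linear in
`A₀` and never feeds `R` back into `RM`/`RD`; with identity similarity
networks it telescopes exactly to `A₀`, which the tests verify in closed form.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.3 | decay: weight of the propagated term vs the restart term `(1−α)A₀` |
| `l`, `r` | 3, 3 | step bounds of the metabolite-side / disease-side walks |
| `delta` | 0.5 | semantic contribution decay per DAG level (dimensionless, in (0,1]) |
| `bandwidth_prime` | 1.0 | base GIP bandwidth before mean-norm normalisation |
| `normalization` | laplacian | `laplacian` (symmetric) or `row` (row-stochastic) |
| `strict_pseudocode` | False | average stale walk matrices past their bound |

The grid analysis behind the `alpha = 0.3, l = r = 3` default shows the best
AUC along the `l = r` diagonal and degradation for step counts above 4; the
`grid` CLI subcommand reproduces this analysis on any dataset.

## Evaluation protocol

Cross-validation folds partition the known associations (LOOCV or seeded
k-fold). Each fold's positives are zeroed in the training matrix, the model
is refit, and the held-out cells are read from the refit score matrix. An
equal number of negatives — cells that are zero in the *full* matrix, never a
held-out positive — is drawn once per evaluation with the scheme's seed and
partitioned across folds, so every fold contributes a balanced set of scored
pairs. ROC/AUC and PR/AUPR are computed on the pooled pairs by the trapezoid
rule (AUC therefore equals the Mann–Whitney probability with ties counted
half, which the tests check against a brute-force pairwise oracle); score
ties in rankings are broken by registry order for reproducibility.

`recompute_similarity` (default true) rebuilds the association-dependent
similarities (GIP kernels and the functional similarity) inside each fold so
the held-out association can never inform the similarity networks; disease
semantic similarity does not depend on `A` and is computed once. Setting it
to false reuses the full-data similarity networks — cheaper and the likelier
protocol behind published evaluations of this method family, but it leaks
the held-out link into the kernels. On the planted fixture the two protocols
differ by about 0.04 AUC (≈0.92 leak-free vs ≈0.96 with full-data
similarities; both recomputed at run time by `scripts/acceptance.py`, which
reports them side by side).

## Synthetic data

The fixture generator emulates the guilt-by-association premise as a planted
block model: aligned metabolite/disease blocks, within-block association
density 0.8 against a 0.02 background, and a disease DAG forest in which all
diseases share one global root while each block adds its own balanced
ancestor subtree (depth 3, branching 2 by default). Same-block diseases thus
share deep ancestor chains (semantic similarity 3/7 at the defaults) while
cross-block pairs share only the root (1/7) — low but nonzero, so
integration averages rather than substituting the GIP kernel across blocks.
Every metabolite is guaranteed at least one association. All generators are
deterministic given the seed.

What the fixtures do **not** emulate: the heavy-tailed degree distribution of
real metabolite–disease catalogues, multi-position MeSH descriptors (real
diseases occupy several tree positions; the loader supports this via
union-of-ancestor expansion, the generator does not exercise it), overlapping
or nested disease blocks, and annotation noise. Passing the recovery checks
therefore demonstrates that the pipeline recovers clean planted structure,
not that it attains any particular performance on curated real data.

Problem sizes used by the default test suite and the acceptance script —
40×20 fixtures for recovery, 6×5 instances for walk-oracle equivalence,
≤50-pair score sets for metric oracles — were chosen to keep the full suite
in the seconds-to-a-minute range while leaving every check statistically
meaningful at 10 seeds or 100 replicates.

## Numerical choices and degenerate inputs

* Matrix-equality tolerance in tests: 1e-12 absolute; similarity symmetry is
  validated at the same tolerance at construction.
* All-zero association matrix → error at walk initialisation (no mass to
  propagate). All-zero similarity degree → row left zero by both
  normalisations.
* Duplicate association rows are deduplicated with a logged count;
  identifiers are matched exactly after whitespace trimming.
* Score TSVs are written at 17 significant digits and parsed with
  round-trip float precision, so write → read is lossless.
* The semantic recursion treats a shared ancestor with no path to the
  disease inside that disease's DAG as contributing 0 (cannot occur in DAGs
  built by the provided loaders, which always connect ancestors downward).

## Known limitations

* Ranking for a fully blinded node (case-study style) relies on the semantic
  side: if a disease shares no DAG ancestors with any associated disease, its
  blinded ranking degrades to the zero-profile GIP artifact described above.
* The GIP kernels depend entirely on the known association matrix, so
  predictions for sparsely annotated nodes are dominated by the semantic
  similarity and the restart term.
* No convergence-based stopping: the walk is fixed-step by design, and `l`,
  `r` above ~4 over-smooth (visible in the grid analysis).
* The evaluation negatives are unverified zeros, as is standard for this
  problem; "negative" means unobserved, not experimentally excluded.
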