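# mdbirw

Bi-random-walks prediction of disease-related metabolites.

Changes in metabolite levels accompany many complex diseases, but experimentally
mapping which metabolites are involved in which disease is slow and expensive.
`mdbirw` predicts unobserved metabolite–disease associations from three
ingredients: a known bipartite association table (e.g. HMDB accessions against
disease terms), a disease ontology DAG (e.g. MeSH descriptor hierarchies), and
nothing else. It is aimed at computational biologists doing network-based
association inference and candidate prioritisation.

## Method

Let `A ∈ {0,1}^{m×n}` be the association matrix over `m` metabolites and `n`
diseases. The package builds two similarity networks and propagates `A`
through both:

1. **Disease semantic similarity** `S^d`. Each disease `d` has an ancestor DAG;
   a term `t` contributes `D_d(t) = 1` if `t = d` and otherwise
   `D_d(t) = max_{t' ∈ children(t)} Δ·D_d(t')` with decay `Δ = 0.5`. With
   `DV(d) = Σ_{t∈T(d)} D_d(t)`, two diseases are similar in proportion to the
   contribution mass of their shared ancestors:
   `S^d(i,j) = Σ_{t∈T(d_i)∩T(d_j)} (D_{d_i}(t) + D_{d_j}(t)) / (DV(d_i) + DV(d_j))`.
2. **Metabolite functional similarity** `S^m` (MISIM-style): metabolites are
   similar when each disease associated with one has a semantically similar
   disease associated with the other, via group-max averaging over the two
   disease sets.
3. **GIP kernel similarity** for both node types:
   `GS(i,j) = exp(−λ‖IP_i − IP_j‖²)` over binary interaction profiles
   (rows/columns of `A`), with bandwidth `λ = λ′ / mean‖IP‖²`, `λ′ = 1`.
4. **Integration**: `DS = GS_d` where `S^d = 0`, else `(S^d + GS_d)/2`;
   `MS` analogously from `S^m` and `GS_m`.
5. **Bi-random walks**: with Laplacian-normalised `MS′`, `DS′` and
   `A₀ = A / ΣA`, iterate
   `RM_t = α·MS′·RM_{t−1} + (1−α)·A₀` (metabolite side, up to `l` steps) and
   `RD_t = α·RD_{t−1}·DS′ + (1−α)·A₀` (disease side, up to `r` steps),
   averaging the walks that ran into the score matrix `R` each iteration.
   Defaults `α = 0.3`, `l = r = 3`.

High entries of `R` at zero cells of `A` are the predicted novel associations.
Evaluation uses LOOCV or k-fold CV over the known associations with balanced
negative sampling, reporting trapezoid ROC AUC and precision–recall AUPR.

## Worked example

```python
from mdbirw import (MDBIRW, FixtureSpec, make_association_matrix,
                    make_dag_forest, run_cv, WalkParams, CvScheme)
from mdbirw.evaluation import rank_metabolites

# planted-block synthetic data: 40 metabolites x 20 diseases in 4 blocks,
# within-block association density 0.8 against a 0.02 background
spec = FixtureSpec(n_metabolites=40, n_diseases=20, n_blocks=4, seed=0)
network = make_association_matrix(spec)
dags = make_dag_forest(spec)

model = MDBIRW(alpha=0.3, l=3, r=3).fit(network, dags=dags)
print("score matrix:", model.scores_.shape)

report = run_cv(network, dags, WalkParams(alpha=0.3, l=3, r=3),
                CvScheme(mode="kfold", k=5, seed=0))
print(f"5-fold CV: AUC = {report.auc:.3f}, AUPR = {report.aupr:.3f}")

top = rank_metabolites(network, dags, WalkParams(), "D000", top_k=5)
for rank, pair in enumerate(top, 1):
    print(f"{rank}. {pair.metabolite}  score={pair.score:.4f}  known={pair.label}")
```

prints

```
score matrix: (40, 20)
5-fold CV: AUC = 0.902, AUPR = 0.911
1. M0004  score=0.0003  known=1
2. M0009  score=0.0003  known=0
3. M0030  score=0.0002  known=1
4. M0001  score=0.0002  known=1
5. M0002  score=0.0002  known=1
```

The CV numbers say the planted block structure is recovered well above chance
(AUC 0.5). The ranking blinds disease `D000` (all its known associations are
removed before refitting) and still places its true associates at the top —
`known=1` marks metabolites that were associated with `D000` before blinding;
the `known=0` entry at rank 2 is a same-block metabolite, exactly the kind of
candidate the method is meant to surface. Scores are small because `R` is a
probability-like matrix with total mass 1.

The same operations are available from the shell:

```bash
mdbirw simulate --out-dir data/           # synthetic associations + DAG edges
mdbirw predict  -a data/associations.tsv -d data/dag_edges.tsv --out scores.tsv
mdbirw evaluate -a data/associations.tsv -d data/dag_edges.tsv \
                --mode kfold --k 5 --seed 0 --out report.json
mdbirw rank     -a data/associations.tsv -d data/dag_edges.tsv --disease D000 --top 10
mdbirw grid     -a data/associations.tsv -d data/dag_edges.tsv \
                --alphas 0.3,0.5 --ls 1,2,3 --rs 1,2,3 --out grid.json
```

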