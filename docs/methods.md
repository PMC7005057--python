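# Methods

## Model

`rwrknn` treats bipartite association prediction as supervised scoring of
entity pairs. The signal available is (i) the topology of the known binary
association matrix `A` (Nc circRNAs × Nd diseases) and (ii) per-disease
ontology ancestry. Both are converted into per-entity similarity profiles,
smoothed over similarity networks by random walk with restart, and fed to a
k-nearest-neighbour regressor whose inverse-distance-weighted vote over
binary labels yields a score in [0, 1] for every pair.

The underlying assumptions are the standard ones of this model family:
entities with similar interaction profiles have similar unobserved
associations (the Gaussian interaction-profile kernel makes this explicit),
diseases close in the ontology are functionally related (Wang's decayed
ancestor-contribution measure), and network proximity — not just direct
similarity — carries information (the RWR weighting step mixes every
entity's profile into its neighbours' features in proportion to steady-state
visit probability).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `delta` | semantic decay per DAG level (dimensionless, (0,1]) | 0.5 | halves an ancestor's contribution per generation |
| `sigma_star` | GIP bandwidth normaliser (dimensionless) | 1 | bandwidth is `sigma_star / mean(‖IP‖²)`; changing it is an ablation, not a default |
| `alpha` | disease-network similarity threshold | 0.6 | inclusive (≥); unit diagonals guarantee self-edges |
| `beta` | circRNA-network similarity threshold | 0.8 | inclusive |
| `restart_prob` (`c`) | RWR restart probability | 0.7 | contraction factor 1−c = 0.3 |
| `tol`, `max_iter` | RWR L1 stopping rule | 1e−10, 1000 | converges in < 100 iterations at these defaults |
| `k`, `p` | neighbour count, Minkowski exponent | 5, 1 | p = 1 is the Manhattan metric |
| `weighting` | `rwr` or `identity` | rwr | `identity` is the unweighted raw-KNN baseline |
| `normalization` | walk-matrix normalisation | column | row-stochastic variant available for sensitivity analysis |

The defaults are the method's chosen operating point; the `grid` subcommand
sweeps `alpha, beta ∈ {0.5..0.9}`, `k ∈ 1..5`, `p ∈ {1,2,3}` by CV AUC.

## Interpretation choices

Two places in the method's printed definition are internally inconsistent,
and the package fixes them the only way that is dimensionally coherent:

* **Similarity integration.** The mean branch of the integrated similarity
  is computed as `(DSS(i,j) + DGS(i,j))/2` (and likewise for CFS/CGS). The
  alternative self-index reading `DGS(i,i)` would add a constant 1 to every
  informative pair and destroy symmetry of interpretation.
* **Feature weighting.** Weighting is the matrix product `WSC = F^c · SC`
  (each row an affinity-weighted mixture of all similarity profiles). The
  per-entity column-vector × row-vector form would be an outer product —
  one matrix per entity — and contradicts both the stated feature
  dimensions (Nd + Nc per pair) and the description of weighting as
  multiplying the feature matrix by the affinity score matrix.

Other conventions: `SS(d, ∅) = 0`, so a circRNA with no known diseases has
zero functional similarity off-diagonal and 1 on the diagonal (absence of
evidence contributes nothing); "children of t" in the semantic recursion
means children within that disease's own DAG; thresholding is inclusive;
RWR convergence is a fixed-point tolerance in L1 (the informal "until all
nodes are traversed" description is not a stopping rule). All seeds —
negative sampling, fold shuffling, synthetic generation — are explicit
required inputs.

## Numerical choices

* RWR iterates from `p₀ = q`; with `c ∈ (0,1]` the update is a contraction,
  so the iterative solution matches the closed form
  `p = c (I − (1−c)W)⁻¹ q` to ~1e−13 at the default tolerance (asserted
  against the direct linear solve in tests). All seeds are iterated
  simultaneously as one matrix recursion; the update is linear, so the
  batched iterates equal the per-seed ones and results cannot depend on
  seed order.
* KNN ties at the k-th neighbour break by training-sample index (stable
  argsort), making scores exactly reproducible. Zero-distance neighbours
  take over with their mean label — the limit of inverse-distance weights —
  which matters under LOOCV where duplicate feature vectors occur.
* Column sums of the walk matrix are never zero because thresholded
  networks keep unit diagonals; the normaliser still guards the division.
* GIP kernels are symmetrised (`(K+Kᵀ)/2`) and their diagonals pinned to 1
  to remove floating-point asymmetry before validation at 1e−12.
* Matrices are written to TSV with `%.17g`, which round-trips IEEE doubles
  exactly; binary matrices are written as integers.

## Evaluation protocol

Only positive pairs are cross-validated; the balanced negative sample is by
default split into folds alongside them, so each fold's test set is
held-out positives versus an equally sized, training-disjoint negative set.
The `paper_faithful` protocol instead scores held-out positives against all
unknown pairs. The ACC/F1/MCC threshold defaults to 0.5 on the KNN score.

Features can be built once from the full matrix (default) or rebuilt per
fold with the held-out associations zeroed (`recompute_profiles=True`).
The default mirrors how methods of this family are usually evaluated, but
it leaks: a held-out association is visible in the GIP profiles and
functional similarity of its endpoints. The synthetic null experiment
quantifies this — with no planted signal at all, the default protocol still
yields mean AUC ≈ 0.73, entirely attributable to the leak, while the
leakage-free mode sits at ≈ 0.47–0.53 across seed batches. Consequently the
package's null-calibration check runs leakage-free, and any AUC from the
default mode should be read as an upper bound.

## Synthetic generator

The generator emulates the two real inputs with a planted block model:
diseases take blocks round-robin, circRNAs draw a block uniformly, and
links are Bernoulli(0.6) within block versus Bernoulli(0.02) across — the
package's reference study condition of 60 circRNAs, 20 diseases and 4
blocks, sized so a full 5-fold CV run takes well under a second and
multi-seed experiments stay cheap. Same-block diseases share a block-root
ancestor term (ancestor chains of random depth ≤ 3 through block-specific
intermediate terms, ordered so acyclicity holds by construction);
cross-block diseases share no terms, which exercises the zero-semantic
branches of the integration rules. Zero-degree entities are deliberately
retained to hit the degenerate-profile conventions. The null condition
lowers the within-block probability to the noise level (0.02 = 0.02).

What the generator does *not* emulate: real ontology topology (MeSH-like
breadth, multiple parents across subtrees), long-tailed degree
distributions, curation biases, or name variability. Passing the planted
recovery test therefore shows the pipeline detects block-structured signal
jointly expressed in profiles and ontology — not that any particular AUC
will be attained on a curated database.

## Known limitations

* Entities absent from training (a new disease with no associations, a new
  circRNA) receive only kernel-degenerate features; the method is not
  designed for cold-start prediction.
* `CFS` is quadratic in the number of circRNAs with a per-pair best-match
  reduction; at the 661-circRNA reference scale this is seconds, but very
  large problems would need a blocked implementation.
* Balanced negative sampling requires every circRNA to have at least as
  many unassociated as associated diseases; extremely dense rows are
  rejected with an explicit error rather than silently truncated.
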