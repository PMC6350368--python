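# Methods

## Model

The predictor treats miRNA–disease association as a link-prediction problem
on a miRNA similarity network, under the standard assumption that
functionally similar miRNAs tend to associate with phenotypically similar
diseases. It has four stages: (1) an interaction-profile kernel completes
the pairwise miRNA similarity where the curated functional similarity (FS)
has no value; (2) a restart random walk from every miRNA summarizes each
node's global network neighbourhood as a stationary probability vector;
(3) for a given disease, each miRNA's neighbourhood is condensed into two
numbers — how much stationary mass its strongest neighbours place on
miRNAs already known for that disease, and how much on the rest; (4) a
logistic regression on these two numbers (plus a constant) converts them
into posterior association probabilities used to rank the unlabelled
miRNAs.

## Parameters

| name | default | units / range | role |
|---|---|---|---|
| `gamma_prime` (γ'ₘ) | 1.0 | > 0 | raw kernel bandwidth, normalized by the mean squared profile norm |
| `restart` (r) | 0.7 | (0, 1) | per-step probability of jumping back to the seed distribution; larger r keeps the walk local |
| `cutoff` | 1e-6 | L1 norm | convergence threshold on successive walk iterates |
| `max_iter` | 10 000 | steps | safety bound, far beyond the contraction-rate prediction ≈ log(cutoff)/log(1−r) |
| `top_k` (K) | 50, or ⌈0.1·nₘ⌉ when nₘ < 51 | count | walk neighbours summed into each feature (~10 % of the miRNAs in the reference catalogue) |
| `tol` | 1e-8 | gradient ∞-norm | Newton convergence for the regression |
| `ridge` | 1e-8 | ≥ 0 | quadratic stabilizer; guards against complete separation, settable to 0 |

The restart probability deserves emphasis: the method's description fixes
every other constant but not r, so the 0.7 default is this package's
choice (a common RWR setting) and should be treated as unvalidated on any
new dataset; it is surfaced in the CLI and logged on every run.

## Numerical choices

* The similarity matrix is column-normalized into a transition matrix
  before iterating — the raw update with an unnormalized similarity matrix
  would not preserve probability mass, contradicting the walker semantics.
  Row vs. column vs. symmetric normalization is not otherwise constrained;
  column normalization keeps each update a proper Markov step.
* Power iteration is run in a batched engine (all seeds as columns of one
  matrix, each column frozen the moment its own L1 change passes the
  cutoff), which matches the per-seed loop up to floating-point
  associativity and makes per-fold recomputation affordable.
* The fixed point `p = r (I − (1−r)T)⁻¹ p0` is computed by a direct solve
  in the tests as an independent oracle; the iteration must agree within
  1e-5 in L1.
* Ties at the K-th walk rank, and ties in candidate scores, break by
  canonical identifier order (lexicographic over normalized ids), making
  every output deterministic and input-order invariant.
* The log-likelihood uses `logaddexp` (softplus) so extreme linear
  predictors neither overflow nor lose the sign of the objective.
* Newton steps are step-halved until the penalized objective does not
  decrease; with a concave log-likelihood this converges in a handful of
  iterations for the 3-parameter design.
* Degenerate inputs fail loudly: an all-zero adjacency (bandwidth
  undefined), a zero similarity row/column (walk undefined), a disease
  with no positive or no negative labels (regression untrainable).

## LOOCV protocol and the leakage caveat

Each known association (i, j) is removed in turn; the held-out miRNA is
ranked among disease j's label-0 candidates; folds are pooled by sweeping a
threshold on the *normalized* rank (the fraction of a fold's candidate
list called positive), so the FPR axis is exact even though candidate
counts differ across folds. The ROC curve is emitted as a right-continuous
staircase with explicit vertical segments, which makes its trapezoid area
identically equal to the mean per-fold tie-corrected Mann–Whitney
statistic.

Two recomputation scopes are offered:

* **default** — the kernel, integrated similarity and all walk profiles
  are computed once from the full adjacency and held fixed across folds;
  only labels, features and the regression are per-fold. This is the only
  tractable scope at catalogue scale (recomputing every walk for every
  fold is quadratic), but it leaks: the held-out association is still
  inside the interaction profile that shaped the kernel, which measurably
  inflates AUC (a label-permuted null scores ≈ 0.65 rather than 0.5 on the
  planted fixture).
* **strict** (`strict=True` / `--strict-loocv`) — kernel, integration and
  all walks are recomputed inside every fold. This is the faithful
  protocol and the one used for the package's validity checks; the batched
  walk engine keeps it at ~10 s for 150 miRNAs × ~1300 folds.

A disease that loses its last positive in its own fold is skipped (the
regression would have nothing to train on) and counted in the result.

## Synthetic fixture

The generator plants aligned bipartite communities: miRNAs and diseases
are partitioned into the same blocks; associations are Bernoulli
(within-block probability 0.6 by default vs. 0.05 across); functional
similarity is Gaussian around block-dependent means (0.8 within, 0.2
across, sd 0.05) clipped to [0, 1], with 70 % of pairs covered and the rest
masked undefined to exercise the kernel fallback. The default sizes for
end-to-end evaluation are 150 miRNAs, 30 diseases, 3 blocks — small enough
that a strict-mode LOOCV finishes in seconds; the "high-signal" condition
used in the end-to-end checks raises the within-block association
probability to 0.8, and the signal-monotonicity sweep uses 0.2 / 0.4 / 0.8.
The label-permutation null shuffles each disease's column independently,
preserving per-disease association counts while destroying all alignment
with the similarity structure.

What the fixture does *not* emulate: the heavy-tailed degree distribution
of curated catalogues (a few heavily studied miRNAs and diseases dominate
real data), literature bias correlated between FS and the association
list, and block overlap. Passing the planted-signal tests therefore shows
the machinery recovers the structural signal the model assumes, not that a
particular AUC will be attained on any real catalogue — on real data the
result also hinges on the unvalidated restart probability.

## Known limitations

* A disease with zero known miRNAs cannot be scored at all (the regression
  needs positive labels); one with a single known miRNA contributes no
  LOOCV fold.
* Feature extraction uses only miRNA-side similarity; no disease–disease
  similarity enters the model.
* The default LOOCV scope is optimistically biased (see above); strict
  mode is exact but impractical beyond a few hundred miRNAs.
* FS coverage is interpreted pairwise (a per-entry defined mask), which is
  one of two defensible readings of "has functional similarity".
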