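# Methods

## The problem

Bulk tumour transcriptomes are mixtures: tumour cells in one or several
states, stroma, immune infiltrate, and — crucially — signal that no available
reference captures. Given a reference atlas of single-cell-defined cell-type
expression profiles spanning developmental stages (early embryo,
gastrulation, foetal, adult), this package asks, for each bulk sample: *how
much of the expression profile does each reference cell state explain, how
much remains unexplained, and how good is the fit overall?* Group-level sums
of the fitted contributions give interpretable scores — foetalness,
embryoness, adultness — that expose, for example, the foetal-hepatocyte
character of childhood liver cancer against the adult-hepatocyte character of
most hepatocellular carcinoma.

## Cell signal model

For bulk counts `y_g` with gene lengths `l_g` we form length-normalized
intensities `z_g = y_g / l_g`, rescaled so that `sum(z) = sum(y)` (TPM-style
inputs use `l_g = 1` and pass through unchanged up to scale). Reference
profiles `f_gc` are per-cell-type relative expression vectors, each summing
to 1 over the genes entering the fit. The expected intensity is the additive
mixture

    mu_g = sum_c beta_c f_gc + beta_0 u_g,    beta >= 0,  u_g = 1/G,

and parameters maximize the gene-weighted Poisson log-likelihood
`sum_g w_g (z_g log mu_g - mu_g)`. The weights implement the gene rules:
`w_g = 0` for excluded genes (mitochondrial/ribosomal when the exclusion is
enabled, plus any user-dropped genes, e.g. refitting without *AFP*), 0.5 for
housekeeping genes, 1 otherwise. The likelihood is used as a
quasi-likelihood: `z` is generally non-integer after length normalization.

Reported contributions are `beta` normalized to sum 1. The normalized
intercept weight `w_0` is the **unexplained fraction**: mass not
attributable to any reference profile. The flat intercept shape is the
least-informative choice; see limitations below for what that implies.

**Optimizer.** Multiplicative (EM-style) updates
`beta_k <- beta_k * (sum_g w_g z_g f_gk / mu_g) / (sum_g w_g f_gk)` with
deterministic uniform initialization, `max_iter = 10000` and relative
log-likelihood tolerance `1e-8`. Because `mu` is linear in `beta` and the
Poisson log-likelihood is concave in `mu`, the objective is concave and the
monotone updates reach the global maximum; no seed enters the fit.
Convergence additionally requires the normalized weights to be stable
(`max |delta alpha| <= 1e-10` between checks): the likelihood flattens long
before boundary components settle, and stopping on the likelihood alone
breaks scale invariance at the promised `1e-6`. Exact-fit instances sit on a
likelihood plateau where boundary components decay sublinearly; a
machine-flat likelihood change (`<= 1e-14` relative) is accepted as
convergence there. Fits that exhaust `max_iter` are returned with
`converged=False` and a warning rather than raised.

**Goodness of fit.** `rho = 1 - D_fit / D_null`, clipped to [0, 1], where
`D` is the weighted Poisson deviance against the saturated model and the
null is the best constant (weighted-mean) intensity. A degenerate null
(`D_null ~ 0`, i.e. a flat sample) yields 1 when the fit is also perfect and
0 otherwise.

**Grid oracle.** `grid_search_fit` is an independent brute-force maximizer
used by the tests: it enumerates the simplex of normalized weights at a
fixed resolution, profiling the overall scale out analytically
(`s = sum(wz)/sum(wm)`). With three free dimensions a coarse `1e-2` pass
precedes a local `1e-3` pass, sound because the profiled objective is the
restriction of a concave problem and therefore has a single basin.

## Reference building

Profiles are **pseudobulk**: sum the counts of a type's cells, then
normalize to 1 over non-excluded genes. Sum-then-normalize (rather than the
mean of per-cell proportions) matches the count-scale additivity of the fit
and downweights near-empty cells. Full-length (Smart-Seq2-class) datasets
are TPM-transformed per cell before aggregation to cancel gene-length bias;
UMI data aggregate as raw counts. Cell types with fewer than 10 cells are
removed; sub-types can be merged through an explicit label map; multiple
datasets are intersected on version-stripped ENSEMBL identifiers.
Mitochondrial and ribosomal genes are identified by symbol prefix (`MT-`,
`RPL`/`RPS`), overridable by explicit lists; the shipped housekeeping list
is a default, also overridable — the classes matter, the exact membership is
a user decision. Group/tissue-level reference exclusions (e.g. dropping
foetal heart types when no adult counterpart exists) are predicates on the
per-type metadata.

## Summary scores

Each developmental group's score is the sum of contributions over its cell
types; `unexplained = w_0`; the scores sum to 1 by construction. Embryoness
includes gastrulation when that group is present in the reference (the
full-reference convention), controllable via `include_gastrulation`.

## Similarity scoring

A multinomial logistic regression is trained on the annotated reference
cells. Features: per-cell depth normalization to 10,000 counts followed by
`log1p` — the minimal standard featurization, making predictions invariant
to a cell's library size by construction. L2 regularization with inverse
strength `C = 0.1` and per-class balancing stabilize the p >> n,
imbalanced-class regime; training is capped at 1000 iterations with a fixed
seed. Scores are the predicted class probabilities renormalized to sum to 1
per cell. Target genes missing from the model are imputed as zero with the
coverage fraction logged; overlap below 20% of the model's genes is refused.

## QC and annotation

A cell is removed when its mitochondrial fraction **exceeds** the cutoff, or
it has **fewer than** the minimum detected genes or total UMIs — strict
inequalities, so a cell exactly at a threshold is retained. Typical presets:
(0.20, 200, 500) permissive and (0.10, 300, 1000) strict. Clustering is
Leiden community detection on a 15-nearest-neighbour graph of 30
log-normalized principal components at resolution 1.0, seeded. Marker
annotation scores each cluster per label by mean log-normalized marker
expression; a cluster is definitively annotated only when the top label
beats the runner-up by 0.5 on the log scale, otherwise it is `unassigned`
and excluded downstream.

## Synthetic data: what it emulates, what it does not

The generator draws per-cell counts Poisson (or gamma-Poisson with
`var = mu + dispersion * mu^2`) from type programs scaled to a uniformly
drawn library size; full-length chemistry multiplies gene rates by
length/1000 before sampling. Bulk samples are Poisson draws of a known
convex mixture of programs (length-biased), optionally with a planted
out-of-reference component. One global seed spawns per-type child streams,
so extending an atlas never perturbs existing types' draws.

Random atlases (`make_atlas_spec`) share a lognormal gene baseline across
types, with per-type lognormal variation and a private block of boosted
marker genes (~10% of genes split across types, 20-fold boost by default) —
enough structure to make types distinguishable without being orthogonal.

Deliberately absent: doublets, ambient RNA, batch effects, zero inflation,
and cross-dataset technical variation. Passing tests therefore demonstrate
correctness of the estimators under the generative model the method itself
assumes, not robustness to real-data artefacts.

**The planted novel component is diffuse.** For unexplained-fraction
recovery the scenario (`make_disjoint_novel_scenario`) confines reference
programs to a compact slice of the gene universe (7.5% by default) and
spreads the novel program uniformly over the disjoint complement. This is
the regime in which a flat intercept is a *calibrated* estimator of the
planted mass: analytically, the recovered `w_0` approaches
`nf / p` where `p` is the novel program's share of the gene universe, so a
concentrated novel program (small `p`) yields a conservative
*over*-estimate of the unexplained fraction. Real out-of-reference signal
that is highly concentrated in few genes will likewise inflate `w_0`; the
direction of the error is at least safe (unexplained signal is flagged, not
hidden).

## Problem sizes and numerical choices

Test and verification workloads use atlases of 300–2000 genes, 40–500 cells
per type, bulk depths of 1.5x10^5–10^7, and 10–200 replicates per property —
sizes at which every planted effect is comfortably resolvable and the whole
suite runs in minutes. Tie-breaking in the fit is inherited from the uniform
initialization; duplicated reference columns split mass evenly. Degenerate
inputs are defined behaviour: all-zero bulk errors, all-zero target cells
score at the model baseline with a log flag, empty gene overlap errors,
all-cells-removed QC errors with a threshold hint.

## Known limitations

- The unexplained fraction is calibrated for diffuse out-of-reference
  signal and biased upward for concentrated signal (see above).
- A present gene with zero bulk count and zero reference expression is not
  perfectly neutral: it still carries the intercept's flat cost `w_0/G`, so
  dropping it shifts contributions by O(`w_0`/G) — negligible in practice
  but not exactly zero.
- Poisson (quasi-)likelihood only; no negative-binomial bulk fit, no
  per-gene intercepts, no confidence intervals on contributions.
- The similarity model is a linear classifier; it reports resemblance under
  its feature map, not a rejection-calibrated label transfer.
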