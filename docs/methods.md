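# Methods

This note documents the models, parameter choices and numerical conventions
behind `orthopath`, and what the synthetic benchmark does and does not show
about real data.

## Orthology model

All cross-species reasoning runs through orthologous groups (OGs): sets of
genes, across organisms, descended from one ancestral gene. The package
assumes each gene belongs to at most one group (enforced at load time) and
that gene identifiers are namespaced by organism — the same string in two
organisms is two genes. Four coverage classes over a named organism subset
are supported (`any`/`each` × `at least one`/`exactly one`); comparisons
between organisms always restrict first to `each_at_least_one` over the
organisms being compared, and the pathway–tissue analysis restricts to
groups covering *all* organisms at once. Where within-organism paralogs
exist, a group is represented in expression space by the highest-scoring
member gene; this deliberately favours "some copy is expressed" over
averaging, because pathway function needs only one functional copy.

## Transferability

For a reference pathway, transferability to target organism *t* is the
fraction of the pathway's distinct member groups containing at least one
gene of *t*. Two conventions matter:

* The denominator is groups, not genes — paralogy cannot inflate the count.
* Reference genes not mapped to any group are excluded from the denominator
  and reported separately; the minimum-size filter (default 5) applies to
  mapped groups, in every compared organism, and a pathway failing anywhere
  is dropped everywhere so one pathway set underlies all comparisons.

Joint transferability to several targets credits only groups covered by
every target; it is provably ≤ each pairwise value, which the tests verify
by brute force.

## Percentile calibration

Confidence-score distributions differ between organisms by an order of
magnitude in scale, reflecting data volume rather than biology. Cutoffs are
therefore placed per organism × tissue at an empirical percentile of the
gene-level score distribution. The percentile is *lower nearest-rank*: the
smallest observed score *s* with #(scores ≤ *s*) ≥ *p*/100 · *n*. This
definition was fixed (over interpolating alternatives) because it is exact,
language-independent and always returns an observed score. A gene counts as
expressed only *strictly above* the cutoff; with heavy ties at the cutoff
this calls fewer than (100 − *p*)% of genes, which is accepted and
documented rather than corrected, and the generator's `tie_rate` knob
exists to probe that sensitivity. Cutoffs are computed before OG
collapsing; thresholding and max-collapse commute for a fixed cutoff, which
is tested.

Default *p* = 50: with roughly half of genes expressed in a typical tissue,
the median best approximates the expressed count. The pipeline reruns at
{25, 40, 60, 75} as a robustness sweep; because a stricter gene-level
cutoff warrants a laxer pathway-level rule, the sweep links the
expressed-pathway fraction to the percentile (0.85 at or below the median,
falling linearly to 0.75 at the 75th percentile) unless the fraction is set
explicitly.

## Pathway activity and agreement

The expression fraction divides expressed member OGs by member OGs *with
any information* in that tissue; uninformative OGs are missing data, not
evidence of silence. The expressed-pathway threshold (≥ 0.85, inclusive) is
a convention chosen so that canonical house-keeping pathways come out
expressed in most tissues; no tuning rule exists, so it is a plain config
constant. The Jaccard index compares expressed-OG sets per pathway × tissue
between the reference and each model; a 0/0 union is propagated as missing
and excluded from means and from the PCA input, because an empty union
carries no evidence of disagreement.

## PCA assignment

The PCA is an ordination, not a dimension reduction: all three components
are kept. Variables are centered but not scaled by default (the JIs already
share a scale; a config switch enables scaling). Loadings use the classic
convention ℓ = component · √eigenvalue; using the variance *ratio* instead
would rescale all loadings by one global factor and cannot change any
angular assignment. Component signs are fixed by making the
largest-magnitude loading entry of each component positive — signs are
otherwise arbitrary and determinism requires a rule.

Ranking uses the Euclidean distance from the PC2–PC3 origin (scores are
mean-centered by construction), with ties broken lexicographically by
(pathway, tissue). Assignment is by nearest *angle* to one of six reference
directions — the three model loadings and their antipodes, an antipode
labelled with the complementary organism pair. Angular distance was chosen
over Euclidean distance to loading endpoints because the latter would
conflate radius with direction, double-counting the separate
center-distance ranking step. The ≥ 5 expressed-members PCA gate counts the
union of expressed OGs over all organisms by default (config-switchable to
reference-only); the union reading keeps the gate symmetric in the
organisms being compared.

## Synthetic data

The generator emulates the statistical structure of the inputs, not their
biology:

* **Coverage.** Each of 5000 groups is 1-to-1 across all four organisms
  with probability 0.35; otherwise each organism is missing independently
  (human/mouse 0.08, rat 0.18, pig 0.15 — best coverage for human and
  mouse, worst for rat, as in real orthology resources) and present
  organisms gain a paralog with probability 0.2.
* **Pathways.** 200 reference gene sets of 40–120 genes drawn over the
  human-covered groups — the typical size range of curated human pathway
  maps. Pathways share OGs, as real pathways share genes.
* **Truth layer.** Expression truth lives on (OG, tissue): exactly
  round(*q*·*n*) groups are expressed per tissue (*q* = 0.5), with
  house-keeping pathways' groups elevated to 0.95 first and the balanced
  remainder drawn from the rest. Holding the realized expressed fraction at
  *q* is deliberate: it is the regime the median-percentile calibration
  presumes, and it makes the noiseless limit exact. The reference organism
  *is* the baseline; each model organism's truth is the baseline flipped
  independently at rate ε = 0.05 per (OG, tissue).
* **Planted divergences.** 20 pathway–tissue pairs per class (three single
  organisms, three pairs) have 40% of the pathway's groups flipped in the
  divergent organism(s) only, on the truth layer — so calibration,
  thresholding, JI and PCA are all exercised end to end. A divergence in
  organism X should surface as an assignment to the complementary pair
  group, and vice versa.
* **Scores.** Gene scores are normal around state-dependent locations
  (1.0 / 3.0, sd 0.35) times an organism-specific scale (human 1×, mouse
  2×, rat 0.5×, pig 4×), so absolute cutoffs would fail across organisms by
  construction and only the rank-based calibration works. Each gene–tissue
  score is missing with probability 0.05, roughly the per-tissue gap of
  transcriptomics coverage. A second, noisier "integrated" channel is
  emitted alongside the default "experimental" one.

What passing tests show: the pipeline recovers planted organism-specific
divergences (≈ 96% of 120 planted pairs into their implied group under the
defaults, ≥ 80% in ≥ 90% of seeds) and all primitives agree with
independent oracles. What they do not show: real pathways have correlated
co-expression, shared-gene structure with functional meaning, and
confidence scores whose noise is neither normal nor independent across
tissues; recovery rates on real data will be lower and cannot be validated
without organism-specific curated pathways.

## Numerical and degenerate-input conventions

* Every writer sorts rows, fixes column order and renders floats with
  `%.12g`; identical inputs + seed give byte-identical output directories
  (tested). Generated scores are rounded to 6 decimals so files round-trip
  losslessly.
* A constant JI matrix (e.g. the noiseless limit) raises a dedicated
  zero-variance error from the PCA stage; the pipeline's stage error
  carries all upstream results so the degenerate case remains inspectable.
* Fewer retained pairs than variables, a loading with zero PC2–PC3
  projection, a tissue with no scores, or a missing cutoff are hard errors
  with named stages, never silent defaults.
* Problem sizes in the test suite are scaled-down versions of the default
  study (hundreds to a few thousand groups) chosen so the full suite and
  the acceptance script each run in minutes on one CPU; the default
  5000-group study itself runs in a few seconds per seed.

## Known limitations

* Pathway *topology* is never transferred — membership only.
* Tissue labels are matched exactly; no ontology resolution.
* The annotation-overlap utilities count exact (term, OG) and OG-pair
  intersections; GO term ancestry is out of scope.
* With only three model organisms the PC2–PC3 plane is the entire
  between-model space; for more organisms the two-component visualisation
  would discard real structure.
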