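# orthopath

Cross-species pathway–tissue comparison through orthologous groups.

Animal models — mouse, rat, pig — stand in for human in most preclinical
work, but how faithfully a given biological pathway behaves in a given
tissue of a given model is rarely quantified. `orthopath` implements a
reusable pipeline that approximates pathway activity across species from
three kinds of public-style data: orthologous-group membership tables
(eggNOG-style mammalian-level groups), reference-organism pathway gene sets
(KEGG-style, GMT format) and per-organism gene–tissue confidence scores
(TISSUES-style). It is aimed at computational biologists who want to ask,
for each pathway and tissue, *which model organism agrees best with the
reference* — and at methodologists who want a seeded synthetic benchmark
with planted, recoverable cross-species divergences.

## Method

1. **Pathway transfer.** Each reference pathway gene is mapped to its
   orthologous group (OG), turning the pathway–gene association into a
   pathway–OG association. Transferability to a target organism is

   *T* = |{member OGs containing ≥ 1 target gene}| / |{member OGs}|,

   with reference paralogs in one group counted once and unmapped genes
   excluded from the denominator. Joint transfer to all models credits only
   OGs covered by every organism, so joint *T* ≤ every pairwise *T*.
   Pathways with fewer than 5 mapped OGs in any organism are dropped.

2. **Percentile-calibrated expression calls.** Score ranges differ wildly
   between organisms, so a fixed cutoff is meaningless. For each
   organism × tissue the cutoff is the lower nearest-rank *p*-th percentile
   of that score distribution (default *p* = 50, the median); a gene is
   expressed iff its score is strictly above it. Calls are therefore
   rank-based and invariant under monotone rescaling of any one
   organism × tissue. Gene scores collapse to OG level by the maximum over
   member genes. Tissues enter the panel only when covered by ≥ 2
   experimental datasets in every organism.

3. **Pathway activity.** Per (pathway, tissue, organism) the expression
   fraction is *f* = (expressed member OGs)/(member OGs with any
   information); the pathway is *expressed* there when *f* ≥ 0.85.

4. **Species agreement.** Per pathway × tissue, the Jaccard index
   *JI* = |A ∩ B| / |A ∪ B| between the reference's and each model's sets
   of expressed pathway OGs (an empty union is reported as missing, not 0).

5. **PCA assignment.** A centered PCA over the (JI_mouse, JI_rat, JI_pig)
   vectors of all pairs with ≥ 5 expressed members. PC1 captures overall
   agreement; the PC2–PC3 plane separates the models. Loadings are
   ℓ_vk = component_kv · √λ_k. Pairs are ranked by Euclidean distance from
   the PC2–PC3 center, and the top *N* (default 200) are assigned to the
   angularly nearest of six directions: each model's loading, or its
   antipode labelled with the other two models ("mouse & rat" opposite pig,
   etc.).

A seeded synthetic-data generator (`orthopath.simulate`) emulates all the
inputs — imperfect OG coverage with paralogs, organism-heterogeneous score
scales, conserved expression with a per-organism flip rate ε and planted
pathway–tissue divergences — together with ground truth, so the whole chain
is testable end to end.

## Worked example

```python
from orthopath import Config, SimulationConfig, generate, run_all, evaluate_recovery

sim = SimulationConfig(rng_seed=42, n_ogs=1500, n_pathways=50, n_planted_per_class=3)
data = generate(sim)
result = run_all(Config(rng_seed=42, top_n=60), data)

print("tissue panel:", ", ".join(result.tissues))
tm = result.transfer.groupby("organism")["transferability"].mean()
for org in ("mouse", "rat", "pig", "mouse+rat+pig"):
    print(f"mean transferability {org:14s} {tm[org]:.3f}")
print("mean JI:", {m: round(v, 3) for m, v in result.ji_overall.items()})
print("explained variance ratio:", result.pca.explained_variance_ratio.round(3))
print(result.summaries["groups"].to_string(index=False))
rec = evaluate_recovery(result.assignments, data.truth)
print(f"planted-divergence recovery: {rec['n_recovered'].sum()}/{rec['n_planted'].sum()}")
```

prints

```
tissue panel: heart, kidney, liver, lung, muscle, nervous system, spleen
mean transferability mouse          0.948
mean transferability rat            0.893
mean transferability pig            0.895
mean transferability mouse+rat+pig  0.764
mean JI: {'mouse': 0.772, 'rat': 0.762, 'pig': 0.776}
explained variance ratio: [0.562 0.232 0.205]
      group  n_pairs  n_pathways  mean_ji
      mouse        8           7 0.863516
mouse & pig       12          11 0.817901
mouse & rat       11          11 0.776471
        pig       10           9 0.826259
        rat        6           6 0.826237
  rat & pig       13          10 0.831220
planted-divergence recovery: 18/18
```

Mouse transfers best (~95% of pathway OGs on average) because its planted
OG coverage is highest; joint transfer to all three models is lower (~76%)
since it requires coverage in every organism. The six groups partition the
60 most center-distant pathway–tissue pairs; all 18 planted divergences are
recovered into their implied group (a divergence planted in pig lands in
"mouse & rat", and so on).

The same pipeline runs from the shell on TSV/GMT inputs:

```sh
orthopath simulate --seed 42 --out inputs/
orthopath run-all --input-dir inputs/ --out results/
orthopath sweep --input-dir inputs/ --out sweep/ --percentiles 25,40,50,60,75
```

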