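# gemcurate

Ensemble gap filling of genome-scale metabolic models (GEMs) and
machine-learning-guided prioritization of curation targets.

## The problem

Draft GEMs reconstructed from genome annotation are incomplete: gap-filling
algorithms add reactions from a universal biochemistry database so the model
can produce biomass on the media where the organism is known to grow. But
many alternative gap-fill solutions are usually consistent with the same
growth data, and the arbitrary choice among them silently shapes every
downstream simulation. `gemcurate` turns that ambiguity into a ranked
curation agenda: it enumerates many alternative gap-filled models, measures
how simulation outcomes (genome-wide gene essentiality) diverge across them,
and identifies the specific reactions whose uncertain presence drives that
divergence — the experiments or literature searches most worth doing next.

## The method

1. **Parsimonious gap filling.** For a draft model with stoichiometric matrix
   *S* and a universal reaction bag *U*, each growth condition is gap-filled
   by the LP

   ```
   min Σ_j |y_j|   s.t.   S·v + U·y = 0,   v_biomass ≥ 0.05 hr⁻¹,
                          lb ≤ v ≤ ub,  lb ≤ y ≤ ub
   ```

   Only fluxes through universal reactions (*y*) are penalized; a universal
   reaction is *activated* when |y_j| > 1e-11 at the optimum. |y| is
   linearized by splitting each universal flux into y⁺, y⁻ ≥ 0.

2. **Media-shuffled ensembles.** One ensemble member = one random ordering of
   the growth conditions, gap-filled sequentially with activated reactions
   losing their penalty for later conditions. Repeating with fresh shuffles
   and deduplicating identical reaction sets yields an ensemble of
   alternative models, represented as a base model plus a boolean
   member × variable-reaction matrix (a *variable* reaction is present in
   some members, absent in others).

3. **Ensemble simulation.** Single-gene knockouts are simulated per member on
   complete medium (1,000 mmol·gDW⁻¹·hr⁻¹ uptake for every exchange); a gene
   is essential when the biomass optimum falls below 1e-6 hr⁻¹.

4. **Clustering and classification.** Genes with perfectly correlated
   essentiality calls are collapsed; k-means (k = 2) clusters the members by
   simulation profile; a 500-tree random forest then predicts cluster
   membership from each member's variable-reaction presence vector.

5. **Curation metrics.** Each variable reaction gets a *fractional
   importance* (normalized Gini importance; sums to 1 over reactions) and a
   *cluster ratio* 1 − min(f₁,f₂)/max(f₁,f₂), where f_c is its presence
   frequency in cluster c (1 = cluster-exclusive, 0 = evenly spread).
   Reactions high on both metrics are the top curation targets.

Evaluation utilities compare per-member precision/recall against
experimental essentiality screens (Mann–Whitney between clusters with
Benjamini–Hochberg control), aggregate metrics across species, and test for
subsystem-level differences (Kruskal–Wallis with Dunn/Bonferroni post-hocs).

## Worked example

The package ships a synthetic fixture generator whose gap-fill ground truth
is verified by exhaustive enumeration, including an engineered "split"
carbon whose universal bypass reaction skips a gene-gated step — so members
that gap-filled the bypass call gene `gP` nonessential while the rest call
it essential.

```bash
gemcurate fixtures --out demo/suite --n-pathways 2 --n-decoys 1 \
    --n-media 2 --n-split 1 --seed 0
gemcurate gapfill-ensemble --model demo/suite/draft.json \
    --universal demo/suite/universal.json --media demo/suite/media.tsv \
    --out demo/ensemble --n-members 40 --seed 2
gemcurate simulate --ensemble demo/ensemble --out demo/essentiality.tsv
gemcurate analyze --ensemble demo/ensemble \
    --essentiality demo/essentiality.tsv --out demo/analysis --seed 0
```

which prints

```
fixture suite written to demo/suite
ensemble of 4 unique members (4 variable reactions) → demo/ensemble
4×4 essentiality matrix, 1 non-consensus genes → demo/essentiality.tsv
curation metrics (OOB accuracy 1.000) → demo/analysis
```

and ranks the curation targets (`demo/analysis/curation_targets.tsv`):

```
reaction_id  fractional_importance  cluster_ratio   f1   f2
U_SPLIT1     0.4808909136927359     1.0             1.0  0.0
U_SCONV1     0.43609212857504437    1.0             0.0  1.0
U_R2         0.047329789926600856   0.0             0.5  0.5
U_CONV2      0.03568716780561884    0.0             0.5  0.5
```

The engineered bypass `U_SPLIT1` ranks first with cluster ratio 1 — it is
present in every member of one simulation cluster and absent from every
member of the other — together with its perfectly anti-correlated converter
twin `U_SCONV1`; the two order-dependent but phenotype-neutral alternatives
(`U_R2`/`U_CONV2`) land at cluster ratio 0. Resolving whether the organism
truly carries `U_SPLIT1` would eliminate the essentiality disagreement for
`gP`. The same pipeline runs end to end from one config via
`gemcurate run-all --config config.yaml`.

As a library:

```python
from gemcurate import (FixtureSpec, make_toy_universe, generate_ensemble,
                       ensemble_essentiality)

draft, universal, media, truth = make_toy_universe(
    FixtureSpec(n_pathways=3, n_decoy_reactions=2, n_media=3))
ensemble = generate_ensemble(draft, universal, media, n=1000, seed=0)
matrix = ensemble_essentiality(ensemble)          # members × genes, boolean
print(matrix.non_consensus_genes())
```

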