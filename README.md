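# metahab

Metacommunity analysis of host-associated microbial communities across body
habitats.

Fish (and other hosts) carry distinct microbial communities on their skin,
gills, stomach and hindgut, embedded in the microbe-rich water around them.
Treating these habitat communities as a **metacommunity** — local communities
linked by dispersal — lets one ask *how much* diversity lives at each scale
and *which ecological processes* (selection, dispersal, drift) assemble it.
`metahab` implements that analysis as a reusable, seeded, fully tested
pipeline operating on an OTU count table, per-sample metadata (habitat, host
body weight, site, month) and a phylogeny over the OTUs. A synthetic
metacommunity generator with known ground truth provides a test bed for every
stage.

## What it computes

* **Diversity statistics** — Chao1 richness
  (`S_obs + F1(F1−1)/(2(F2+1))`), Bray–Curtis dissimilarity
  (`Σ|x−y| / Σ(x+y)`), PCoA ordination, PERMANOVA / ANOSIM habitat tests,
  simple and partial Mantel tests, and per-OTU Spearman correlations with
  body weight (BH-corrected).
* **Distance-based weight regression** — OLS of pairwise dissimilarity on
  pairwise body-weight difference `|w_i − w_j|`, with a permutation F-test
  that shuffles weights across *samples* (the exchangeable unit), per habitat
  and pooled.
* **Core taxa** — per-habitat core OTUs (relative abundance > 1% in > 80% of
  samples, thresholds configurable), their summed abundance, and the Venn
  partition of shared/unique cores across habitats.
* **Rao diversity partition** — hierarchical additive decomposition
  `γ_Ecosystem = β_InterHabitats + β̄_IntraHabitats + ᾱ_LocalCommunity`
  using Rao quadratic entropy `Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ`, with taxonomic or
  phylogenetic taxon distances and an optional Jost equivalent-number
  correction.
* **Assembly processes** — abundance-weighted βMNTD and its standardized
  effect size βNTI against a regional tip-shuffling null, Raup–Crick on
  Bray–Curtis (RC_Bray) against a richness- and abundance-preserving
  assembly null, and the five-way classification: βNTI > +2 heterogeneous
  selection, βNTI < −2 homogeneous selection, otherwise RC_Bray < −0.95
  homogenizing dispersal, RC_Bray > +0.95 dispersal limitation, else
  undominated.
* **Source tracking** — Bayesian estimation (collapsed Gibbs sampler) of the
  fraction of each sink community attributable to every other habitat plus
  an Unknown source, in a leave-one-habitat-out design.

## Worked example

Simulate a five-habitat metacommunity (four fish habitats plus water,
10 hosts each, 200-OTU regional pool, phylogenetically conserved habitat
filtering) and run the whole pipeline:

```bash
metahab simulate --n-habitats 5 --fish-per-habitat 10 --pool-size 200 \
    --selection-strength 10 --dispersal-rate 0.05 --weight-slope 0.001 \
    --reads-per-sample 5000 --output-dir demo --seed 42
metahab all --table demo/table.tsv --metadata demo/metadata.tsv \
    --tree demo/tree.nwk --output-dir demo/out --depth 2000 \
    --n-null 199 --permutations 499 --seed 1
```

Key numbers from `demo/out/report.json` for this run:

* PERMANOVA across habitats: pseudo-F = 218.0, R² = 0.951, p = 0.002 —
  habitats hold strongly distinct communities, as simulated.
* Weight regression: skin slope = 0.00102, gill slope = 0.00093 (both
  p = 0.002, 499 permutations) — per-habitat dissimilarity rises with
  body-weight difference near the generator's nominal 0.001 per gram.
* Rao partition (equivalent numbers): β_inter = 73.5% of γ,
  β̄_intra = 2.2%, ᾱ = 24.3% — between-habitat turnover dominates under
  strong habitat filtering.
* Within-habitat assembly: homogenizing dispersal is modal in every habitat
  (0.53–0.76 of pairs) — within a habitat all hosts draw from one filtered
  pool, so turnover sits below the metacommunity null.
* Source tracking, hindgut sinks: stomach 0.12, other habitats ≤ 0.03,
  Unknown 0.83 — habitat pools are nearly disjoint under this regime, so
  most reads trace to no other habitat.

The truth record (`demo/truth.json`) stores the generative regime, habitat
trait optima and per-fish weights for comparison against any estimate.

## Library layout

| module | contents |
| --- | --- |
| `metahab.model` | `OtuTable`, metadata/phylogeny validation, rarefaction |
| `metahab.io` | TSV and BIOM-JSON tables, metadata TSV, newick trees |
| `metahab.simulate` | coalescent phylogenies, ground-truth metacommunities |
| `metahab.diversity` | Chao1, Bray–Curtis, PCoA, PERMANOVA/ANOSIM, Mantel |
| `metahab.weightreg` | distance-based weight regression |
| `metahab.coretaxa` | core-OTU calling and Venn partition |
| `metahab.rao` | Rao quadratic entropy and the hierarchical partition |
| `metahab.assembly` | βMNTD, βNTI, RC_Bray, process classification |
| `metahab.sourcetrack` | Gibbs-sampling source tracking |
| `metahab.pipeline` / `metahab.cli` | orchestration, YAML config, CLI |

See `docs/methods.md` for the models, assumptions, parameter defaults and
numerical choices.
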