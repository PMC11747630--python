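# benthocouple

Pelagic-benthic coupling from environmental DNA count tables.

Deep-sea sediment communities are fed from above: organic particles
produced in the sunlit water column sink and export both carbon and
organisms to the seafloor. `benthocouple` quantifies that link from 18S
metabarcoding data of the two habitats — sediment-trap time series for
the water column (pelagic) and sediment cores for the seafloor
(benthic) — without requiring the raw reads: its input is the standard
trio of ASV count table (TSV), ranked taxonomy (TSV) and representative
sequences (FASTA), plus per-sample environmental metadata.

The pipeline chains five analyses:

1. **Filtering & CLR** — singleton removal, a 50-reads-in-3-samples
   abundance filter, closure to relative abundances and the centred
   log-ratio transform (zeros imputed at half the smallest positive
   relative abundance) so that correlation-based steps are valid on
   compositional data.
2. **Co-occurrence networks** — a sparse signed association graph from
   conditional-independence tests (partial correlations given up to 3
   covariates, Fisher z, Benjamini-Hochberg FDR 0.05), with
   environmental meta-variables as optional extra nodes; node degree
   centrality and betweenness.
3. **Subnetworks** — signed adjacency `((1 + r)/2)^6`, topological
   overlap (TOM), average-linkage clustering with a static cut;
   module eigengenes (first principal components) correlated against
   environmental drivers at p < 0.005. The modules positively
   correlated with POC flux (pelagic) and sediment organic carbon
   (benthic) are the *carbon subnetworks*.
4. **Keystone ASVs** — PLS1 regression of the carbon response on CLR
   profiles; variable importance in projection
   `VIP_j = sqrt(p * Σ_a SS_a (w_aj/||w_a||)² / Σ_a SS_a)` combined
   with degree centrality by rank product.
5. **Graph alignment** — an injective pelagic→benthic node mapping
   maximising `alpha·(Σ seqsim)/min(|V_A|,|V_B|) + (1−alpha)·S3` with
   `alpha = 0.4`; sequence identity from global nucleotide alignment,
   topology from graphlet-degree signatures, quality reported as edge
   correctness (EC) and the symmetric substructure score (S3), plus
   taxonomic concordance, flow tables and hiveplot layouts.

A seeded synthetic generator (`synthetic_data`) produces coupled
two-habitat studies — seasonal POC driver, module-structured
multinomial counts, taxonomy, near-identical sequences for exported
ASV pairs — with the planted truth, so every stage is verifiable by
parameter recovery. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Recover the carbon subnetwork of a synthetic pelagic community and
check which module tracks POC flux:

```python
from benthocouple import *

cfg = GeneratorConfig(seed=42)
pelagic, benthic, meta_p, meta_b, truth = generate_coupled_communities(cfg)

clr = clr_transform(to_relative_abundance(filter_asvs(pelagic)))
part = detect_modules(topological_overlap(signed_adjacency(clr)))
eig, _ = module_eigengene(clr, part)
tt = module_trait_correlation(eig, meta_p)
print(tt[tt.trait == "poc_flux"][["module", "r", "p_value", "significant"]])
```

```
module         r      p_value  significant
  Sn_1  0.717838 1.083140e-10         True
  Sn_2 -0.369273 3.689107e-03         True
  Sn_3 -0.276192 3.267007e-02        False
  Sn_4 -0.151075 2.492263e-01        False
```

`Sn_1` is the planted carbon module: its eigengene correlates at
r = 0.72 with POC flux, far past the p < 0.005 threshold. Aligning the
two habitats' carbon subnetworks then recovers the exported ASV pairs:

```python
carbon_p = [a for a, m in truth.module_labels["pelagic"].items() if m == 1]
carbon_b = [a for a, m in truth.module_labels["benthic"].items() if m == 1]
net_p = infer_network(clr_transform(to_relative_abundance(pelagic))[carbon_p])
net_b = infer_network(clr_transform(to_relative_abundance(benthic))[carbon_b])
ss = sequence_similarity({a: pelagic.sequences[a] for a in carbon_p},
                         {a: benthic.sequences[a] for a in carbon_b})
res = align_graphs(net_p, net_b, ss, alpha=0.4, seed=0)
```

```
aligned 30 of 30 possible nodes
EC = 1.00, S3 = 1.00, same-division fraction = 0.67
planted coupled pairs recovered: 15/15
```

Every edge of the pelagic carbon subnetwork is conserved in the benthic
one (EC = S3 = 1) and all 15 planted export pairs are re-identified;
the same-division fraction mixes the exported pairs (always concordant)
with habitat-specific nodes matched on topology alone.

The full pipeline, end to end, from the command line:

```sh
benthocouple -v run --out my_run --seed 1     # synthetic study, all stages
benthocouple synth --out data --seed 1        # or stage by stage
benthocouple filter data/pelagic_counts.tsv --out filtered
```

`run` writes each stage's TSV/JSON outputs and a `manifest.json` with
the parameter echo, seed and per-file checksums; re-running the same
config reproduces the checksums bit-for-bit.

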