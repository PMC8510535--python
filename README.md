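# ecoassembly

Community-ecology analysis of microbiome count tables: rare-biosphere
classification, phylogenetic and taxonomic null models of community
assembly, co-occurrence-network keystone detection, ecosystem
multifunctionality, and the permutation tests linking communities to their
environment — with a synthetic metacommunity generator so every stage can
be validated against planted ground truth.

## Who this is for

Microbial ecologists with an OTU/ASV table (samples × taxa), a rooted
phylogeny of the taxa, per-sample metadata (treatments and edaphic
variables), and optionally a per-sample table of measured ecosystem
functions, who want to answer:

* Which taxa are rare or abundant, and how do the two groups respond to
  treatments?
* Is each community pair shaped by deterministic selection or stochastic
  processes (dispersal, drift)?
* Who are the topological keystones of the co-occurrence network?
* How does community structure track environment and ecosystem
  multifunctionality?

## The statistics at the core

**βNTI** standardises the between-community mean nearest taxon distance
(βMNTD) against a null that shuffles taxon labels on the phylogeny:

βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null,  βMNTD(x,y) = ½[Σᵢ fᵢ min_{j∈y} d(i,j) + Σⱼ gⱼ min_{i∈x} d(j,i)]

**RC_bray** compares observed Bray–Curtis dissimilarity with a null that
reassembles each sample at fixed richness and depth from the regional pool
(occupancy-weighted membership, abundance-weighted filling), rescaled to
[−1, 1]. Together they partition every sample pair:

| rule | process |
|---|---|
| βNTI > 2 | variable selection |
| βNTI < −2 | homogeneous selection |
| \|βNTI\| < 2, RC > 0.95 | dispersal limitation |
| \|βNTI\| < 2, RC < −0.95 | homogenizing dispersal |
| \|βNTI\| < 2, \|RC\| < 0.95 | undominated |

**Zi–Pi** classifies network nodes by within-module degree z-score and
among-module participation; network hubs (Zi > 2.5, Pi > 0.62), module
hubs (Zi > 2.5, Pi < 0.62) and connectors (Zi < 2.5, Pi > 0.62) are the
keystone taxa. **EMF** is the mean of z-scored ecosystem functions per
sample. Rare/abundant classification uses the six-category scheme with
1% / 0.01% relative-abundance thresholds. See `docs/methods.md` for the
full definitions, null models, and design choices.

## Worked example

```python
from ecoassembly.synth import ScenarioConfig, simulate_dataset
from ecoassembly.phylo import beta_nti
from ecoassembly.assembly import raup_crick_bray, partition_processes

cfg = ScenarioConfig(scenario="selection", seed=11)   # 33 samples, 300 taxa
ds = simulate_dataset(cfg)
table = ds["table"].drop_empty_taxa()

nti = beta_nti(table, ds["tree"], n_null=199, seed=12)
rc = raup_crick_bray(table, n_null=199, seed=13)
print(partition_processes(nti.score, rc).proportions.round(3))
```

```
variable_selection        0.688
homogeneous_selection     0.000
dispersal_limitation      0.053
homogenizing_dispersal    0.110
undominated               0.150
Name: proportion, dtype: float64
```

The metacommunity was generated with environmental filtering along a
gradient, and the partition recovers it: variable selection is the modal
process (69% of sample pairs here; pairs at similar gradient positions
fall into the stochastic bins, as they should — filtering by the *same*
environment produces no phylogenetic turnover between them).

The numbered drivers under `analysis/` run the full study-shaped analysis
(simulate → classify → community/environment tests → assembly partition →
network keystones → multifunctionality → niche breadth), writing tables
under `results/`:

```bash
cd analysis
python 01_simulate_metacommunities.py
python 02_classify_rare_abundant.py
# ... through 07_niche_breadth.py
```

For example, step 02 prints the rare-biosphere shape of the synthetic
community (`rare group: 221/294 OTUs (75.2%) but only 9.9% of sequences`)
and step 04 the modal assembly process per scenario and group. A single
TOML-configured end-to-end run with a provenance manifest is available via
`ecoassembly.pipeline.run_all`.

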