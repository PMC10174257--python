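# tenonet

Comparative network analysis of literature-curated signaling interactions
for tendon development (tenogenesis).

Tendon differentiation is driven by a signaling program — TGFB-superfamily
ligands, tendon-specific transcription factors such as SCX and MKX, and
downstream extracellular-matrix effectors — that has been characterised
piecemeal across model organisms (mouse, rat, human, horse, cow, chicken,
zebrafish) and developmental stages (embryo/fetal vs prepubertal).  `tenonet`
takes a curated table of directed molecular interactions, one row per
literature-reported signaling event annotated with organism, stage and link
type (physical binding vs functional association), and turns it into
species- and stage-specific interaction networks that can be characterised,
clustered, enriched and compared — entirely offline and reproducibly.

## What it computes

* **Composition summaries** — per-organism / per-stage interaction counts
  and percentage shares of the corpus.
* **Network topology** — node/edge counts, average number of neighbors
  $\bar{k} = 2E/N$, diameter, radius, characteristic path length,
  mean local clustering coefficient, density and connected components
  (Network-Analyzer conventions: undirected simple-graph view, path
  statistics over connected pairs), plus a scale-free assessment by
  ordinary least squares on $\log_{10} P(k)$ vs $\log_{10} k$
  (Barabási–Albert sense; the fitted $\gamma$ is the slope magnitude).
* **Hubs** — hyperconnected nodes with degree $\ge \mu + k\sigma$ of the
  network's degree distribution ($k = 1$ by default, boundary inclusive),
  with a cross-network hub-conservation table.
* **MCL clustering** — a from-scratch Markov Cluster Algorithm: the
  column-stochastic flow matrix is alternately expanded (matrix power) and
  inflated (entrywise power $r$, default 3) until attractor systems emerge;
  per-cluster conductance quantifies flow containment.
* **Enrichment** — upper-tail hypergeometric over-representation of a node
  set against a local annotation collection (pathway terms grouped into
  BRITE-style macro-categories), with Benjamini–Hochberg FDR at
  $\alpha = 0.05$, and iterative network expansion from a STRING-style
  scored pair table (combined score cutoff 0.400, three cycles by default).
* **Comparison** — Venn overlap of node sets (Jaccard × 100), three-layer
  signaling stratification (upstream / TF / downstream) with the fraction
  of molecules newly contributed by enrichment, and stage-to-stage cluster
  cross-tabulation.

A seeded synthetic-data module generates interaction collections with the
exact composition of the curated corpus (286 interactions: 155 embryo, 131
prepubertal over 7 organisms), layer annotations, annotation collections
with planted enriched terms, and scored interaction sources — so the whole
pipeline is testable without any external service.

## Worked example

```python
from tenonet import (summarize_collection, build_network, compute_topology,
                     fit_power_law, identify_hubs, mcl_cluster)
from tenonet.synthetic_data import SyntheticConfig, generate_collection

records, layers = generate_collection(SyntheticConfig(seed=7))
summary = summarize_collection(records)
print(summary.total, summary.stage_totals, summary.species_share["m"])

mouse = build_network(records, {"m"}, label="mNET")
rep = compute_topology(mouse)
print(rep.n_nodes, rep.n_edges, rep.diameter, round(rep.density, 4))
fit = fit_power_law(rep.degree_distribution)
print(round(fit.gamma, 2), round(fit.r_squared, 2), fit.scale_free)
hubs = identify_hubs(mouse)
print(round(hubs.threshold, 2), hubs.hubs[:3])
print(mcl_cluster(mouse).n_clusters)
```

prints

```
286 {'embryo': 155, 'prepubertal': 131} 51.0
146 145 12 0.0137
1.82 0.95 True
4.08 [('CORE01', 15), ('CORE02', 13), ('CORE03', 10)]
47
```

The generated corpus reproduces the curated composition exactly (286
interactions, 51% from mouse).  The mouse network is sparse (density 0.014)
and scale-free (γ ≈ 1.8, r² = 0.95); its hub threshold is mean + 1 SD of
the degree list (≈ 4.1), and the conserved-core molecules planted by the
generator surface as the top hubs.  MCL at inflation 3 fragments the
146-node network into 47 tight flow clusters.

The same analysis runs from the shell:

```sh
tenonet make-fixtures --seed 7 -o fixtures
tenonet run --collection fixtures/collection.tsv --layers fixtures/layers.tsv \
            --annotations fixtures/annotations.tsv \
            --scored-source fixtures/scored_source.tsv -o out --seed 7
```

which writes one TSV per report (summary, topology, hubs, clusters per
network, enrichment, layer stratification, stage Venn/cross-tab) plus a
`manifest.json` with every constant, input checksum and seed; reruns with
the same inputs and seed are byte-identical.

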