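# polyvalent

Domain-architecture mining and network analysis of **polyvalent proteins** —
the large multidomain proteins that bacteriophages, plasmids and conjugative
transposons deliver into host cells together with their DNA during invasion.
These proteins combine 2–15 domains with highly disparate biochemical
activities (peptidases, ADP-ribosyltransferases, methylase–helicase dyads,
ssDNA-binding antirestriction domains, lysozymes, novel uncharacterized
"LPD" domains…) in a single polypeptide, and the way those domains combine
carries the signal: which element type a protein belongs to, which domains
act as architectural hubs, and which strategies phages and conjugative
elements share.

The package is aimed at comparative genomicists who have domain-architecture
annotations for mobile-element proteins and want the full statistical
treatment of that inventory:

* a packaged controlled vocabulary of the 131 polyvalent-protein domain
  types (including LPD1–LPD40) with functional categories and active-site
  motif links;
* readers/writers for architecture tables, gene-neighborhood annotations
  (GFF3 or TSV) and FASTA motif scanning (HEXXH, HEXXXH, NPP(Y/F), GXGU,
  DaN–, DD, NX+);
* genomic-context classification of each protein into
  conjugative / phage / host from flanking marker genes (relaxase and
  T4SS components vs. the portal–terminase packaging system);
* construction of the two domain networks: the undirected **co-occurrence
  network** (edge = both domains in one protein, adjacent or not, counted
  once per protein) and the directed **adjacency network** (edges between
  consecutive domains only, arrowheads pointing C-terminal);
* the network-parameter battery: discrete power-law fit of the degree
  distribution (maximum-likelihood exponent, KS-minimizing lower cutoff,
  semi-parametric bootstrap *p*), betweenness, HITS hub/authority scores,
  maximal cliques and their merged subnetwork, the largest biconnected
  subnetwork, and the exponential fit to the domains-per-protein histogram;
* prevalence / conditional co-occurrence / class-sharing percentage
  estimators; and
* a calibrated synthetic-corpus generator so the whole pipeline is testable
  without any external downloads.

## The statistics at the core

For a table of proteins with ordered domain hits, with `n_X` the number of
proteins containing domain X:

* prevalence(X) = 100 · n_X / n; conditional co-occurrence
  P(Y|X) = 100 · n_{X∧Y} / n_X (protein-level presence, copies ignored);
  class sharing = 100 · |D_phage ∩ D_conj| / |D_phage ∪ D_conj| over the
  sets of domains observed in each element class.
* The degree sequence of the co-occurrence network is fitted to a discrete
  power law P(k) ∝ k^(−α), k ≥ x_min: α is the discrete MLE for each
  candidate cutoff, x_min minimizes the Kolmogorov–Smirnov distance between
  empirical and fitted tail CDFs (the plfit convention), and *p* is the
  fraction of semi-parametric bootstrap replicates with KS at least the
  observed value.
* The domains-per-protein histogram n_k (k ≥ 2) is fitted by OLS of ln n_k
  on k; the slope is the per-domain log decrement and r² measures how
  exponential the decay is.

The synthetic generator emulates the study conditions: element-class
mixture 40/35/25 (conjugative/phage/host), truncated-geometric
domains-per-protein on 2–15 (success 0.55), Yule–Simon preferential
attachment over class domain pools with a configured 27% pool overlap, and
the calibrated pairwise rates between the named hub domains (MPTase in 36%
of proteins, ArdC-N in 26%, ArdC-N in 93% of conjugative-element proteins,
P(MPTase|ArdC-N)=70%, P(ArdC-N|MPTase)=52%, P(ArdC-N|MutS-I)=80%).

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end on the
default 10,000-protein corpus (seed 1) and write compact tables under
`results/` (full corpora and networks go to `scratch/`):

```
$ python analysis/01_simulate_corpus.py
generated 10000 proteins (seed 1)
class mixture: {'phage': '35.2%', 'host': '25.3%', 'conjugative': '39.5%'}
domains per protein: {2: 5452, 3: 2535, 4: 1114, 5: 516, 6: 208, 7: 96, 8: 45, 9: 17, 10: 8, 11: 7, 12: 2}

$ python analysis/02_classify_contexts.py
classified 10000 neighborhoods: 100.00% correct, 39.48% called conjugative

$ python analysis/04_network_stats.py
power-law fit: alpha=2.26 xmin=3 KS=0.054 p=0.32 (n_tail=88)
domains-per-protein exponential fit: r^2=0.995 slope=-0.784 p=8.64e-12
6 domains have >20 connections; top betweenness: ['SMS-RadA', 'ArdC-N', 'N6A-MTase', 'MPTase', 'MutS-I']
largest cliques have 8 nodes; merging cliques of size >= 7 gives a 25-node subnetwork
largest biconnected subnetwork: 113 nodes (86.3% of the network)
```

Reading: the corpus realizes the configured class mixture; the marker-tag
classifier recovers every planted context; the domains-per-protein counts
fall exponentially (r² = 0.995); the co-occurrence degree distribution is
power-law-like (KS = 0.054, bootstrap p = 0.32, so the power law is not
rejected); the largest cliques reach 8 domains and the biconnected core
spans 86% of the network — the architectural web is held together by many
redundant linkages, not by single bridge domains.

The same steps are available as a CLI (`polyvalent simulate | classify |
build-net | stats | cooccur | scan-motifs | report`).

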