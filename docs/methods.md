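# Methods

This note documents the models, numerical conventions and design choices
behind the package, and what the synthetic corpus does and does not show
about real data.

## Data model

A protein is an ordered N→C list of domain hits with 1-based inclusive
residue coordinates; its *architecture signature* is the domain ids joined
with `+`, and two proteins share an architectural type iff their signatures
are equal (order-sensitive). *Polyvalence* is defined purely as carrying at
least two catalog domains (`min_domains=2`); the large size typical of these
proteins is reported as a statistic, never used as a filter. Readers warn —
they do not fail — above 15 hits, since the 2–15 range is an empirical
observation about the inventory, not a rule.

The packaged catalog holds exactly 131 domain types in nine functional
categories. Forty are the novel uncharacterized LPD domains (LPD1–LPD40).
The named remainder covers every domain discussed in the survey literature
this package is built around; 44 entries are explicit `UNNAMED-k`
placeholders for inventory members whose identities are only recorded in
supplementary material that is no longer retrievable. Placeholders are
flagged as such (`is_novel=false`, category `other`) rather than guessed.

## Context classification

Each polyvalent-protein gene is classified from the product tags of up to
`k=10` genes on each side (the window size covers operon-scale contexts;
no published window exists to adopt). Conjugative markers are
{relaxase, t4ss, tra, vir, mob}; phage markers are
{portal, terminase, virion, capsid, tail, muf}. The call is conjugative if
any flanking gene carries a conjugative tag, else phage, else host — "host"
therefore means only "no markers found", not an inference of host capture
by homology. Mixed neighborhoods keep the three-way partition: they are
called conjugative (conjugative > phage precedence) with `ambiguous=true`
and the full evidence list, rather than introducing a fourth class. Tags
are controlled tokens; a packaged lookup maps common free-text products
("VirB4", "terminase large subunit", …) onto them.

## Networks

The co-occurrence network is undirected and per-protein deduplicated: a
protein contributes at most 1 to the {X,Y} edge count no matter how many
copies of X or Y it carries, matching the protein-level reading of
co-occurrence used by all percentage estimators. The adjacency network is
directed along the backbone (N-side → C-side) over consecutive distinct
domains only; tandem repeats contribute no edge, and antiparallel edges
(A→B and B→A) are kept distinct. Edge occurrence classes are ≤15 gray,
16–90 cadet blue, ≥91 maroon: the published wording ("<15 … 16 to 90")
leaves 15 unassigned, and 15 is resolved into gray so the classes are
exhaustive and contiguous. Networks are built from architectures only;
gene-neighborhood linkages never contribute edges.

## Network statistics

* **Power-law fit.** Discrete maximum likelihood: for each candidate lower
  cutoff x_min (every unique degree value whose tail retains at least two
  distinct values — the plfit convention, matching the igraph
  implementation this fit was verified against), α maximizes
  −n·ln ζ(α, x_min) − α·Σ ln k over α ∈ (1, 10] by bounded scalar
  minimization; the KS distance is the sup over integer support of
  |ECDF − fitted CDF| on the tail, and the cutoff minimizing it is kept.
  The bootstrap p value is semi-parametric: each replicate draws the tail
  from the fitted model (exact inverse-CDF sampling, with the rounded
  continuous approximation only beyond a 10^5 cap) and resamples the body
  empirically, is refitted from scratch including the cutoff scan, and p is
  the fraction of replicates with KS at least the observed. 250 replicates
  by default; `n_bootstrap=0` skips the bootstrap and reports the KS
  statistic alone. Zero degrees are excluded; fewer than 10 positive values
  or an all-equal sequence is an error, not a silent fit.
* **Degrees** are unweighted distinct-neighbor counts; directed networks
  are analyzed on their undirected view for total degree, cliques and
  biconnectivity (the published subnetworks ignore direction), while HITS
  uses direction.
* **HITS** is the mutually reinforcing power iteration from a uniform
  start with L2 normalization each step, stopping when the largest
  per-node change falls below `tol=1e-10` (convergence failure raises,
  reporting the residual). Reported report-level scores are additionally
  scaled so the maximum is 1 for readability.
* **Cliques** are enumerated exactly (Bron–Kerbosch via networkx), sorted
  (size desc, lexicographic); the clique subnetwork is the induced subgraph
  on the union of maximal cliques of size ≥ 7 by default. The largest
  biconnected component is taken with single edges admitted as size-2
  components and ties broken by the lexicographically smallest node set.
* **Exponential fit.** OLS of ln counts on domains-per-protein over bins
  ≥ 2 with count ≥ `min_count` (zero-count bins are dropped, never
  log-transformed); a flat histogram returns slope 0 and r² 0 by
  convention. At least 3 usable bins are required.

All graph algorithms are cross-checked in the test suite against
brute-force oracles (subset enumeration for cliques and biconnectivity,
explicit shortest-path enumeration for betweenness, grid-search likelihood
for α) on hundreds of random graphs.

## Synthetic corpus generator

The generator emulates the statistical structure reported for the real
inventory, so that every estimator can be validated against planted truth:

* **Class mixture** 40/35/25 conjugative/phage/host.
* **Domains per protein**: L = 2 + G with G truncated-geometric,
  success p = 0.55, capped at 15. This puts >75% of proteins at two or
  three domains and makes the expected histogram exactly log-linear, so the
  exponential fit recovers r² ≈ 0.99 at n = 10,000.
* **Anchor rules** encode the calibrated pairwise percentages: marginal
  rules (scope `any` or one element class) include a domain with fixed
  probability; conditional rules include Y with probability q when X was
  included. The printed percentages are mutually inconsistent as a joint
  distribution (e.g. 93% ArdC-N among 40% conjugative proteins already
  exceeds a 26% overall marginal), so no joint consistency is enforced:
  rules fire under a fixed priority (class marginal > any marginal >
  conditional; the first decision per domain wins) and skipped rules are
  counted in a reconciliation log. Calibration-recovery runs use dedicated
  configurations in which only the relevant rule is active, which is also
  how the acceptance targets are measured. Rule-referenced domains are
  excluded from the filler pools so each rule's probability is recovered
  exactly in expectation by its estimator.
* **Filler domains — Yule–Simon preferential attachment.** The rule-free
  catalog remainder is split deterministically into conjugative and phage
  pools whose intersection over union equals the configured overlap (0.27)
  exactly at pool level; host proteins mimic one element type (fair coin)
  and draw from its pool. Each filler slot either *activates* a
  not-yet-used pool domain — activation times are spread uniformly at
  random over the pool's total filler draws, so the whole pool enters
  play — or *copies* a used domain with probability proportional to its
  corpus-wide usage count plus the smoothing constant `hub_bias` (default
  1.0). Innovation plus preferential copying is the classic Yule–Simon
  route to Zipf-like usage and is what produces the hub-dominated,
  power-law-like degree distribution of the co-occurrence network (median
  KS ≈ 0.066 over seeds at defaults). A static-pool urn without innovation
  was evaluated and rejected: it converges to flat-Dirichlet usage with a
  humped degree distribution (median KS ≈ 0.12) and no usage range worth
  calling hub-dominated. Proteins are filled in a separately seeded random
  order so the attachment history is not tied to protein ids; everything
  is deterministic given the config and seed.
* **Placement.** ArdC-N is moved to rank 0 in conjugative proteins that
  carry it (its N-terminal "header" position); all other domains are
  shuffled. Hits receive synthetic non-overlapping coordinates (100-aa
  domains, 10-aa linkers).
* **Neighborhoods.** Each protein gets a 21-gene replicon with the anchor
  in the middle; conjugative proteins are flanked by a relaxase gene plus
  one further T4SS-pathway marker, phage proteins by a portal gene plus one
  further packaging/virion marker, host proteins by untagged genes only.
  `tag_noise` adds spurious marker tags per flanking gene with the given
  probability (default 0).

### What the generator does not emulate

Real domain-architecture grammar (position preferences beyond ArdC-N,
domain-order motifs, repeat expansions), multicopy anchor domains (the
calibrated hub domains are drawn at most once per protein, so the observed
multicopy rate concerns filler domains only), phylogenetic correlation
between proteins, any sequence-level realism, and annotation error other
than uniform tag noise. Passing tests therefore demonstrate that the
estimators and network statistics are correct and well-calibrated on data
with the reported marginal structure — not that the biological conclusions
of any particular survey are reproduced from primary data.

## Problem sizes

Default analysis scale is 10,000 proteins per corpus; the power-law
stability check uses the median KS over 25 corpora; bootstrap p values use
250 replicates (smaller corpora and replicate counts are used inside unit
tests). These sizes were chosen to keep every binomial standard error at
the sub-point level, matching the printed precision of the percentages
they are compared against.

## Known limitations

* The placeholder catalog entries make the 131-domain count honest but
  carry no biology; analyses that key on placeholder identities are
  meaningless.
* The power-law fit deliberately implements the plfit convention without a
  minimum tail size; on very small networks the KS-minimizing cutoff can
  select short tails, and its KS statistic should then be read together
  with `n_tail`.
* `class_shared_percent` uses the union of class-observed domains as the
  denominator; the catalog-wide variant is also reported because the
  published "fraction shared" wording admits both readings.
* Context classification is marker-tag-based only; it cannot recover
  host-captured elements the way homology-based synteny analysis would,
  and the "host" class absorbs every unmarked neighborhood.
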