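"""Synthetic polyvalent-protein corpora with the reported statistical structure.

The generator emulates the study conditions of the survey this package
analyses: a mixture of conjugative-element, phage and host-captured
proteins (40/35/25%), an exponentially decaying domains-per-protein
distribution on 2..15 (truncated geometric, success 0.55, putting over 75%
of proteins at two or three domains), hub-dominated power-law-like domain
usage, and the printed pairwise marginal/conditional co-occurrence rates
between named domains (e.g. MPTase in 36% of proteins; ArdC-N in 93% of
conjugative-element proteins; MPTase in ~70% of ArdC-N carriers).

Filler domains are drawn by a Yule-Simon preferential-attachment process
over class-specific domain pools: each filler slot either activates a
not-yet-used pool domain (innovation; activation times are spread uniformly
over the pool's filler draws so the whole pool enters play) or copies an
already-used domain with probability proportional to its corpus-wide usage
count plus the ``hub_bias`` smoothing constant.  Innovation plus
preferential copying is the classic mechanism behind Zipf-like usage
profiles and yields the hub-dominated degree structure such domain
networks show; a static-pool urn without innovation does not.

The printed percentages are not mutually consistent as one joint
distribution, so the generator does not force joint consistency: rules are
applied per protein under a fixed priority (class-scoped marginal, then
any-scoped marginal, then conditionals; the first decision for a domain
wins and later rules touching it are skipped and counted in a
reconciliation log).  Estimator-calibration runs use dedicated
single-rule configurations (the ``config_for_*`` constructors).

Domains referenced by active rules are excluded from the preferential-
attachment filler pools, so each rule's probability is recovered exactly in
expectation by the corresponding estimator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np

from ._errors import ConfigError, UsageError
from .architectures import ArchitectureTable, DomainHit, ProteinArchitecture
from .catalog import DomainCatalog, load_catalog
from .motifs import MotifPattern, default_motifs, AA20, CLASS_TOKENS
from .neighborhoods import (
    CONJUGATIVE_TAGS,
    PHAGE_TAGS,
    GeneNeighborhood,
    GeneRecord,
)

_DOMAIN_LEN = 100
_LINKER = 10
_GENE_LEN = 900
_GENE_GAP = 100


@dataclass(frozen=True)
class MarginalRule:
    """Include ``domain`` with probability ``prob`` in proteins of ``scope``
    ("any" or an element class)."""

    scope: str
    domain: str
    prob: float


@dataclass(frozen=True)
class ConditionalRule:
    """When ``given`` is already present, include ``then`` with ``prob``."""

    scope: str
    given: str
    then: str
    prob: float


DEFAULT_MIXTURE: Mapping[str, float] = {"conjugative": 0.40, "phage": 0.35, "host": 0.25}

#: the printed pairwise statistics, encoded as default rules
DEFAULT_MARGINALS: tuple[MarginalRule, ...] = (
    MarginalRule("conjugative", "ArdC-N", 0.93),
    MarginalRule("any", "MPTase", 0.36),
    MarginalRule("any", "ArdC-N", 0.26),
    MarginalRule("any", "MutS-I", 0.10),
)
DEFAULT_CONDITIONALS: tuple[ConditionalRule, ...] = (
    ConditionalRule("any", "ArdC-N", "MPTase", 0.70),
    ConditionalRule("any", "MPTase", "ArdC-N", 0.52),
    ConditionalRule("any", "MutS-I", "ArdC-N", 0.80),
)

_SCOPES = ("any", "conjugative", "phage", "host")


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 10_000
    seed: int = 1
    class_mixture: tuple[tuple[str, float], ...] = tuple(DEFAULT_MIXTURE.items())
    length_p: float = 0.55          # truncated-geometric success probability
    max_domains: int = 15
    hub_bias: float = 1.0           # preferential-attachment smoothing constant
    marginals: tuple[MarginalRule, ...] = DEFAULT_MARGINALS
    conditionals: tuple[ConditionalRule, ...] = DEFAULT_CONDITIONALS
    class_domain_overlap: float = 0.27
    neighborhood_k: int = 10
    tag_noise: float = 0.0
    with_neighborhoods: bool = True

    def mixture(self) -> dict[str, float]:
        return dict(self.class_mixture)

    def validate(self) -> None:
        mix = self.mixture()
        if set(mix) != {"conjugative", "phage", "host"}:
            raise ConfigError(f"class mixture must cover the three classes, got {set(mix)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class mixture must sum to 1")
        if not (0.0 < self.length_p < 1.0):
            raise ConfigError("length_p must be in (0, 1)")
        if not (2 <= self.max_domains):
            raise ConfigError("max_domains must be >= 2")
        if not (0.0 <= self.class_domain_overlap <= 1.0):
            raise ConfigError("class_domain_overlap must be in [0, 1]")
        if not (0.0 <= self.tag_noise <= 1.0):
            raise ConfigError("tag_noise must be in [0, 1]")
        bad = [r for r in self.marginals if not (0.0 <= r.prob <= 1.0)] + [
            r for r in self.conditionals if not (0.0 <= r.prob <= 1.0)
        ]
        if bad:
            raise ConfigError(f"rule probabilities outside [0, 1]: {bad}")
        for r in tuple(self.marginals) + tuple(self.conditionals):
            if r.scope not in _SCOPES:
                raise ConfigError(f"unknown rule scope {r.scope!r} in {r}")
        seen = set()
        for r in self.marginals:
            key = (r.scope, r.domain)
            if key in seen:
                raise ConfigError(f"duplicate marginal rule for {key}")
            seen.add(key)
        seen = set()
        for r in self.conditionals:
            key = (r.scope, r.given, r.then)
            if key in seen:
                raise ConfigError(f"duplicate conditional rule for {key}")
            seen.add(key)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticCorpus:
    table: ArchitectureTable
    neighborhoods: list[GeneNeighborhood]
    truth: GeneratorConfig
    reconciliation: dict[str, int] = field(default_factory=dict)
    pools: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# class domain pools

def build_class_pools(
    catalog: DomainCatalog, config: GeneratorConfig
) -> dict[str, list[str]]:
    """Deterministically split the rule-free catalog remainder into
    conjugative/phage filler pools with the configured shared fraction.

    With union size U and shared count S = round(overlap * U), the pool-level
    intersection-over-union equals S/U exactly; the observed class-sharing
    statistic converges to it as the corpus grows.  Host proteins mimic one
    of the two element types and draw from that type's pool.
    """
    rule_domains = {r.domain for r in config.marginals} | {
        d for r in config.conditionals for d in (r.given, r.then)
    }
    eligible = [d for d in catalog.ids() if d not in rule_domains]
    u = len(eligible)
    s = int(round(config.class_domain_overlap * u))
    shared = eligible[:s]
    rest = eligible[s:]
    half = (len(rest) + 1) // 2
    conj_pool = shared + rest[:half]
    phage_pool = shared + rest[half:]
    return {"conjugative": conj_pool, "phage": phage_pool, "shared": shared}


# ---------------------------------------------------------------------------
# corpus generation

def _apply_rules(
    cls: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    reconciliation: dict[str, int],
) -> list[str]:
    """Anchor domains for one protein under the priority order."""
    decided: dict[str, bool] = {}

    def decide(domain: str, prob: float, label: str) -> None:
        if domain in decided:
            reconciliation[label] = reconciliation.get(label, 0) + 1
            return
        decided[domain] = bool(rng.random() < prob)

    for r in config.marginals:            # class-scoped marginals first
        if r.scope == cls:
            decide(r.domain, r.prob, f"skip:marginal:{r.scope}:{r.domain}")
    for r in config.marginals:            # then any-scoped marginals
        if r.scope == "any":
            decide(r.domain, r.prob, f"skip:marginal:any:{r.domain}")
    for r in config.conditionals:         # conditionals last, class scope first
        if r.scope in (cls, "any"):
            if decided.get(r.given, False):
                decide(r.then, r.prob, f"skip:conditional:{r.given}->{r.then}")
    return [d for d, present in decided.items() if present]


def _coords(n_hits: int) -> tuple[list[tuple[int, int]], int]:
    spans = []
    pos = 1
    for _ in range(n_hits):
        spans.append((pos, pos + _DOMAIN_LEN - 1))
        pos += _DOMAIN_LEN + _LINKER
    return spans, pos - _LINKER - 1


def generate_corpus(config: GeneratorConfig, catalog: DomainCatalog | None = None) -> SyntheticCorpus:
    """Generate a corpus; fully deterministic given the config (incl. seed)."""
    config.validate()
    if catalog is None:
        catalog = load_catalog()
    pools = build_class_pools(catalog, config)
    rng = np.random.default_rng(config.seed)
    # separate stream for the fill order so the preferential-attachment
    # history does not depend on protein ids
    fill_rng = np.random.default_rng((config.seed * 2_654_435_761 + 1) % (2**31))
    # activation order within each pool is itself randomized per seed
    pool_rng = np.random.default_rng((config.seed * 40_503 + 7) % (2**31))
    activation_order = {
        c: [pools[c][j] for j in pool_rng.permutation(len(pools[c]))]
        for c in ("conjugative", "phage")
    }

    n = config.n_proteins
    classes = list(config.mixture().keys())
    probs = np.array([config.mixture()[c] for c in classes])
    cls_draw = rng.choice(len(classes), size=n, p=probs)
    # truncated geometric: L = 2 + k, P(k) ∝ p (1-p)^k, k = 0..max-2
    kmax = config.max_domains - 2
    pk = config.length_p * (1.0 - config.length_p) ** np.arange(kmax + 1)
    pk /= pk.sum()
    lengths = 2 + rng.choice(kmax + 1, size=n, p=pk)

    reconciliation: dict[str, int] = {}
    anchors_per_protein: list[list[str]] = []
    eff_class: list[str] = []
    for i in range(n):
        cls = classes[cls_draw[i]]
        eff_class.append(cls)
        anchors_per_protein.append(_apply_rules(cls, config, rng, reconciliation))

    # Yule-Simon filler: innovation (activate an unused pool domain, with
    # activation times spread uniformly over the pool's remaining draws) or
    # preferential copy proportional to corpus-wide usage count + hub_bias
    host_mimic = rng.random(n) < 0.5  # which pool a host protein mimics
    pool_of = [
        ("conjugative" if host_mimic[i] else "phage") if c == "host" else c
        for i, c in enumerate(eff_class)
    ]
    n_fill = [max(int(lengths[i]) - len(anchors_per_protein[i]), 0) for i in range(n)]
    total_draws = {c: 0 for c in ("conjugative", "phage")}
    for i in range(n):
        total_draws[pool_of[i]] += n_fill[i]

    counts: dict[str, float] = {}
    active: dict[str, list[str]] = {"conjugative": [], "phage": []}
    n_active = {"conjugative": 0, "phage": 0}
    t_pool = {"conjugative": 0, "phage": 0}
    order = fill_rng.permutation(n)
    fillers: list[list[str]] = [[] for _ in range(n)]
    for i in order:
        pc = pool_of[i]
        pool_order = activation_order[pc]
        for _ in range(n_fill[i]):
            remaining_draws = total_draws[pc] - t_pool[pc]
            remaining_dom = len(pool_order) - n_active[pc]
            t_pool[pc] += 1
            innovate = remaining_dom > 0 and (
                not active[pc]
                or fill_rng.random() < remaining_dom / max(remaining_draws, 1)
            )
            if innovate:
                d = pool_order[n_active[pc]]
                active[pc].append(d)
                n_active[pc] += 1
            else:
                sub = active[pc]
                w = np.array([counts.get(x, 0.0) for x in sub]) + config.hub_bias
                cum = np.cumsum(w)
                d = sub[int(np.searchsorted(cum, fill_rng.random() * cum[-1], side="right"))]
            counts[d] = counts.get(d, 0.0) + 1.0
            fillers[i].append(d)

    proteins: list[ProteinArchitecture] = []
    neighborhoods: list[GeneNeighborhood] = []
    conj_tag_extra = sorted(CONJUGATIVE_TAGS - {"relaxase"})
    phage_tag_extra = sorted(PHAGE_TAGS - {"portal"})
    all_tags = sorted(CONJUGATIVE_TAGS | PHAGE_TAGS)
    for i in range(n):
        cls = eff_class[i]
        anchors = list(anchors_per_protein[i])
        domains = anchors + fillers[i]
        perm = rng.permutation(len(domains))
        domains = [domains[j] for j in perm]
        if cls == "conjugative" and "ArdC-N" in domains:
            # ArdC-N of conjugative-element proteins sits at the N terminus
            domains.remove("ArdC-N")
            domains.insert(0, "ArdC-N")
        spans, length_aa = _coords(len(domains))
        pid = f"SYN{i:06d}"
        proteins.append(
            ProteinArchitecture(
                protein_id=pid,
                accession="",
                organism="synthetic",
                length_aa=length_aa,
                hits=[DomainHit(d, s, e, r) for r, (d, (s, e)) in enumerate(zip(domains, spans))],
                element_class=cls,
            )
        )
        if config.with_neighborhoods:
            neighborhoods.append(
                _make_neighborhood(pid, cls, config, rng, conj_tag_extra,
                                   phage_tag_extra, all_tags)
            )

    table = ArchitectureTable(proteins, source=f"synthetic:{config.digest()}")
    return SyntheticCorpus(
        table=table,
        neighborhoods=neighborhoods,
        truth=config,
        reconciliation=reconciliation,
        pools=pools,
    )


def _make_neighborhood(
    pid: str,
    cls: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    conj_tag_extra: list[str],
    phage_tag_extra: list[str],
    all_tags: list[str],
) -> GeneNeighborhood:
    k = config.neighborhood_k
    n_genes = 2 * k + 1
    anchor_pos = k
    tags_by_gene: list[set[str]] = [set() for _ in range(n_genes)]
    flank = [j for j in range(n_genes) if j != anchor_pos]
    if flank and cls == "conjugative":
        # plant a relaxase plus one further T4SS-pathway marker
        picks = rng.choice(len(flank), size=min(2, len(flank)), replace=False)
        tags_by_gene[flank[picks[0]]].add("relaxase")
        if len(picks) > 1:
            tags_by_gene[flank[picks[1]]].add(
                conj_tag_extra[int(rng.integers(len(conj_tag_extra)))]
            )
    elif flank and cls == "phage":
        # plant a portal plus one further packaging/virion marker
        picks = rng.choice(len(flank), size=min(2, len(flank)), replace=False)
        tags_by_gene[flank[picks[0]]].add("portal")
        if len(picks) > 1:
            tags_by_gene[flank[picks[1]]].add(
                phage_tag_extra[int(rng.integers(len(phage_tag_extra)))]
            )
    if config.tag_noise > 0:
        for j in flank:
            if rng.random() < config.tag_noise:
                tags_by_gene[j].add(all_tags[int(rng.integers(len(all_tags)))])
    genes = []
    pos = 1
    for j in range(n_genes):
        gid = f"{pid}_g{j}" if j != anchor_pos else f"{pid}_anchor"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(gid, pos, pos + _GENE_LEN - 1, strand, frozenset(tags_by_gene[j]))
        )
        pos += _GENE_LEN + _GENE_GAP
    return GeneNeighborhood(replicon_id=f"repl_{pid}", anchor_gene_id=f"{pid}_anchor",
                            genes=genes)


def neighborhoods_as_annotation(corpus: SyntheticCorpus) -> dict[str, list[GeneRecord]]:
    return {nb.replicon_id: nb.genes for nb in corpus.neighborhoods}


# ---------------------------------------------------------------------------
# motif fixtures

def generate_motif_sequence(motif_id: str, length: int, plant_at: int, seed: int) -> str:
    """Random background sequence with one motif instance planted at
    ``plant_at`` (1-based); deterministic given ``seed``."""
    pats = {m.motif_id: m for m in default_motifs()}
    if motif_id not in pats:
        raise KeyError(f"unknown motif {motif_id!r}")
    pat = pats[motif_id]
    if plant_at < 1 or plant_at + pat.length - 1 > length:
        raise UsageError(
            f"cannot plant {motif_id} (length {pat.length}) at {plant_at} in {length} residues"
        )
    rng = np.random.default_rng(seed)
    seq = [AA20[j] for j in rng.integers(len(AA20), size=length)]
    instance = _realize_motif(pat, rng)
    seq[plant_at - 1 : plant_at - 1 + pat.length] = instance
    return "".join(seq)


def _realize_motif(pat: MotifPattern, rng: np.random.Generator) -> list[str]:
    out = []
    expr, i = pat.pattern, 0
    while i < len(expr):
        c = expr[i]
        if c == "[":
            j = expr.index("]", i)
            members = expr[i + 1 : j]
            out.append(members[int(rng.integers(len(members)))])
            i = j + 1
        elif c == "X":
            out.append(AA20[int(rng.integers(len(AA20)))])
            i += 1
        elif c in CLASS_TOKENS:
            members = CLASS_TOKENS[c]
            out.append(members[int(rng.integers(len(members)))])
            i += 1
        else:
            out.append(c)
            i += 1
    return out


# ---------------------------------------------------------------------------
# dedicated single-rule configurations for estimator calibration
#
# Defaults encode the printed statistics this generator is calibrated to:
# P(MPTase | ArdC-N) = 0.70, P(ArdC-N | MPTase) = 0.52,
# P(ArdC-N | MutS-I) = 0.80, P(ArdC-N | conjugative) = 0.93,
# P(MPTase) = 0.36, P(ArdC-N) = 0.26, shared domain fraction 0.27,
# conjugative mixture share 0.40.

def _base(n: int, seed: int, **kw) -> GeneratorConfig:
    return GeneratorConfig(
        n_proteins=n, seed=seed, marginals=(), conditionals=(),
        with_neighborhoods=False, **kw,
    )


def config_for_conditional(
    given: str, then: str, prob: float, given_marginal: float,
    n: int = 10_000, seed: int = 1,
) -> GeneratorConfig:
    return replace(
        _base(n, seed),
        marginals=(MarginalRule("any", given, given_marginal),),
        conditionals=(ConditionalRule("any", given, then, prob),),
    )


def config_for_marginal(domain: str, prob: float, n: int = 10_000, seed: int = 1) -> GeneratorConfig:
    return replace(_base(n, seed), marginals=(MarginalRule("any", domain, prob),))


def config_for_class_marginal(
    cls: str, domain: str, prob: float, n: int = 10_000, seed: int = 1
) -> GeneratorConfig:
    return replace(_base(n, seed), marginals=(MarginalRule(cls, domain, prob),))


def config_for_overlap(overlap: float = 0.27, n: int = 10_000, seed: int = 1) -> GeneratorConfig:
    return replace(_base(n, seed), class_domain_overlap=overlap)
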