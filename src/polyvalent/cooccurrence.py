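"""Prevalence, copy-number, conditional co-occurrence and class-sharing
statistics over architecture tables.

Co-occurrence throughout is protein-level presence — copy numbers are
ignored — consistent with the per-protein deduplication used when building
the co-occurrence network.  Percentages are kept at full precision and
rounded only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._errors import SizeError, UsageError
from .architectures import ArchitectureTable, architecture_signature


def domain_prevalence(table: ArchitectureTable, d: str) -> float:
    """Percent of proteins in the table containing >= 1 hit of ``d``."""
    if len(table) == 0:
        raise SizeError("prevalence is undefined on an empty table")
    n_with = sum(1 for p in table if d in p.domain_ids)
    return 100.0 * n_with / len(table)


def multicopy_fraction(table: ArchitectureTable, d: str) -> float:
    """Among proteins containing ``d``, percent with >= 2 copies."""
    carriers = [p for p in table if d in p.domain_ids]
    if not carriers:
        raise SizeError(f"no protein contains {d!r}; multicopy fraction undefined")
    multi = sum(1 for p in carriers if p.domain_ids.count(d) >= 2)
    return 100.0 * multi / len(carriers)


def conditional_cooccurrence(table: ArchitectureTable, x: str, y: str) -> float:
    """Percent of X-containing proteins that also contain Y."""
    if x == y:
        raise UsageError("conditional co-occurrence of a domain with itself")
    carriers = [p for p in table if x in p.domain_ids]
    if not carriers:
        raise SizeError(f"no protein contains {x!r}; conditional undefined")
    both = sum(1 for p in carriers if y in p.domain_ids)
    return 100.0 * both / len(carriers)


def count_distinct_architectures(table: ArchitectureTable, containing: str | None = None) -> int:
    """Number of distinct architecture signatures, optionally restricted to
    signatures containing the given domain."""
    sigs = set()
    for p in table:
        if containing is not None and containing not in p.domain_ids:
            continue
        sigs.add(architecture_signature(p))
    return len(sigs)


def _class_domains(table: ArchitectureTable, cls: str) -> set[str]:
    out: set[str] = set()
    for p in table:
        if p.element_class == cls:
            out.update(p.domain_ids)
    return out


def class_shared_percent(table: ArchitectureTable, class_a: str, class_b: str) -> float:
    """Shared fraction of class-observed domain sets: 100 * |A∩B| / |A∪B|."""
    a = _class_domains(table, class_a)
    b = _class_domains(table, class_b)
    if not a or not b:
        raise SizeError(f"class {class_a if not a else class_b!r} has no observed domains")
    return 100.0 * len(a & b) / len(a | b)


def prevalence_by_class(table: ArchitectureTable, d: str, cls: str) -> float:
    """Percent of class-``cls`` proteins containing ``d``."""
    members = [p for p in table if p.element_class == cls]
    if not members:
        raise SizeError(f"class {cls!r} is empty")
    n_with = sum(1 for p in members if d in p.domain_ids)
    return 100.0 * n_with / len(members)


def domain_frequency_table(table: ArchitectureTable, top_n: int = 100) -> list[tuple[str, int]]:
    """Domains ranked by distinct-protein count desc, ties lexicographic."""
    if top_n < 1:
        raise UsageError("top_n must be >= 1")
    counts: dict[str, int] = {}
    for p in table:
        for d in set(p.domain_ids):
            counts[d] = counts.get(d, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


@dataclass
class CooccurrenceReport:
    prevalence: dict
    multicopy: dict
    conditional: dict
    distinct_architectures: dict
    class_domain_sets: dict
    shared_percent: float | None
    shared_percent_of_catalog: float | None
    frequency_table: list
    notes: str = ""

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        # conditional[(X, Y)] is P(Y present | X present), rendered as "Y|X"
        d["conditional"] = {f"{y}|{x}": v for (x, y), v in self.conditional.items()}
        d["class_domain_sets"] = {c: sorted(s) for c, s in self.class_domain_sets.items()}
        return d


def compute_cooccurrence_report(
    table: ArchitectureTable,
    top_n: int = 100,
    conditional_pairs: list[tuple[str, str]] | None = None,
    catalog_size: int | None = None,
) -> CooccurrenceReport:
    """Assemble the full report.

    ``conditional_pairs`` defaults to all ordered pairs among the ten most
    frequent domains.  ``shared_percent`` (phage vs conjugative) is reported
    against the union of class-observed domains (primary) and, when
    ``catalog_size`` is given, also against the whole catalog.
    """
    freq = domain_frequency_table(table, top_n=top_n)
    observed = [d for d, _ in freq]
    if conditional_pairs is None:
        top = observed[:10]
        conditional_pairs = [(x, y) for x in top for y in top if x != y]
    prevalence = {d: domain_prevalence(table, d) for d in observed}
    multicopy = {d: multicopy_fraction(table, d) for d in observed}
    conditional = {
        (x, y): conditional_cooccurrence(table, x, y) for x, y in conditional_pairs
    }
    distinct = {d: count_distinct_architectures(table, containing=d) for d in observed}
    class_sets = {
        c: _class_domains(table, c) for c in ("conjugative", "phage", "host")
    }
    shared = shared_catalog = None
    if class_sets["phage"] and class_sets["conjugative"]:
        shared = class_shared_percent(table, "phage", "conjugative")
        if catalog_size:
            inter = class_sets["phage"] & class_sets["conjugative"]
            shared_catalog = 100.0 * len(inter) / catalog_size
    return CooccurrenceReport(
        prevalence=prevalence,
        multicopy=multicopy,
        conditional=conditional,
        distinct_architectures=distinct,
        class_domain_sets=class_sets,
        shared_percent=shared,
        shared_percent_of_catalog=shared_catalog,
        frequency_table=freq,
        notes="shared_percent uses the union of class-observed domains as denominator; "
              "shared_percent_of_catalog divides by the full catalog size instead",
    )


def write_frequency_tsv(freq: list[tuple[str, int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdomain_id\tdistinct_proteins\n")
        for i, (d, c) in enumerate(freq, start=1):
            fh.write(f"{i}\t{d}\t{c}\n")
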