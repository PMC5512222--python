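"""Domain-architecture tables: reading, validation, normalization, selection.

A protein's architecture is its ordered N-to-C sequence of domain hits.
Coordinates are 1-based inclusive residue positions.  The polyvalent subset
is defined purely as proteins with at least two catalog domains; the
informal large-size property of these proteins is reported as a statistic,
never used as a filter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from ._errors import ParseError, ValidationError

log = logging.getLogger(__name__)

ELEMENT_CLASSES = ("conjugative", "phage", "host", "unknown")

#: synthetic coordinates for bare (coordinate-free) architecture strings
_UNIT_DOMAIN_LEN = 100
_UNIT_LINKER = 10

_TABLE_COLUMNS = ("protein_id", "accession", "organism", "length_aa",
                  "architecture", "element_class")

#: hit counts above the empirically observed ceiling draw a warning, not an error
DOMAINS_PER_PROTEIN_WARN = 15


@dataclass(frozen=True)
class DomainHit:
    domain_id: str
    start: int
    end: int
    rank: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"bad hit coordinates {self.domain_id}:{self.start}-{self.end}"
            )


@dataclass
class ProteinArchitecture:
    protein_id: str
    accession: str
    organism: str
    length_aa: int
    hits: list[DomainHit]
    element_class: str = "unknown"

    def __post_init__(self):
        if self.element_class not in ELEMENT_CLASSES:
            raise ValidationError(
                f"{self.protein_id}: unknown element_class {self.element_class!r}"
            )
        if self.length_aa <= 0:
            raise ValidationError(f"{self.protein_id}: non-positive length")
        prev_end = 0
        for i, h in enumerate(self.hits):
            if h.rank != i:
                raise ValidationError(f"{self.protein_id}: hit ranks out of order")
            if h.start <= prev_end:
                raise ValidationError(
                    f"{self.protein_id}: overlapping or unsorted hits at rank {i}"
                )
            if h.end > self.length_aa:
                raise ValidationError(
                    f"{self.protein_id}: hit {h.domain_id} exceeds protein length"
                )
            prev_end = h.end
        if len(self.hits) > DOMAINS_PER_PROTEIN_WARN:
            log.warning(
                "%s has %d domain hits (above the empirical 2-15 range)",
                self.protein_id, len(self.hits),
            )

    @property
    def domain_ids(self) -> list[str]:
        return [h.domain_id for h in self.hits]


@dataclass
class ArchitectureTable:
    proteins: list[ProteinArchitecture]
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        seen = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise ValidationError(f"duplicate protein_id {p.protein_id!r}")
            seen.add(p.protein_id)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)


def parse_architecture_string(s: str) -> list[DomainHit]:
    """Parse ``ID:start-end,...`` or bare ``ID,ID,...`` into ordered hits.

    The two forms may not be mixed.  The bare form assigns synthetic
    non-overlapping unit coordinates that preserve the given order; the
    coordinate form sorts hits by start.  An empty string is an empty
    architecture, not an error.
    """
    s = s.strip()
    if not s:
        return []
    items = [t.strip() for t in s.split(",")]
    has_coords = [":" in t for t in items]
    if any(has_coords) and not all(has_coords):
        raise ParseError(f"mixed bare and coordinate forms in {s!r}")
    hits: list[DomainHit] = []
    if all(has_coords):
        parsed = []
        for t in items:
            dom, _, coords = t.partition(":")
            try:
                a, b = coords.split("-")
                start, end = int(a), int(b)
            except ValueError as exc:
                raise ParseError(f"bad coordinate item {t!r}") from exc
            if not dom:
                raise ParseError(f"missing domain id in item {t!r}")
            parsed.append((dom, start, end))
        parsed.sort(key=lambda x: x[1])
        for rank, (dom, start, end) in enumerate(parsed):
            hits.append(DomainHit(dom, start, end, rank))
    else:
        pos = 1
        for rank, dom in enumerate(items):
            if not dom:
                raise ParseError(f"empty domain id in {s!r}")
            hits.append(DomainHit(dom, pos, pos + _UNIT_DOMAIN_LEN - 1, rank))
            pos += _UNIT_DOMAIN_LEN + _UNIT_LINKER
    return hits


def format_architecture_string(hits: Iterable[DomainHit]) -> str:
    return ",".join(f"{h.domain_id}:{h.start}-{h.end}" for h in hits)


def read_architecture_table(path, catalog=None, strict: bool = True) -> ArchitectureTable:
    """Read the architecture TSV dialect into a validated table.

    With a catalog and ``strict=True``, any domain token absent from the
    catalog aborts the read; with ``strict=False`` such rows are dropped,
    counted in ``n_dropped`` and logged.
    """
    p = Path(path)
    proteins: list[ProteinArchitecture] = []
    dropped = 0
    with open(p, encoding="utf-8", newline="") as fh:
        reader = csv.reader(
            (ln for ln in fh if not ln.startswith("#")),
            delimiter="\t", quoting=csv.QUOTE_NONE,
        )
        header = next(reader, None)
        if header is None or tuple(header[:5]) != _TABLE_COLUMNS[:5]:
            raise ParseError(f"bad architecture table header in {p}: {header}")
        for row in reader:
            if len(row) == 5:
                row = row + ["unknown"]
            if len(row) != 6:
                raise ParseError(f"bad row in {p}: {row}")
            pid, acc, org, length_aa, arch, eclass = row
            hits = parse_architecture_string(arch)
            if catalog is not None:
                unknown = [h.domain_id for h in hits if h.domain_id not in catalog]
                if unknown:
                    if strict:
                        raise ValidationError(
                            f"{pid}: unknown domain token(s) {unknown}"
                        )
                    dropped += 1
                    log.info("dropping %s: unknown domain token(s) %s", pid, unknown)
                    continue
            proteins.append(
                ProteinArchitecture(pid, acc, org, int(length_aa), hits, eclass)
            )
    if dropped:
        log.warning("read_architecture_table: dropped %d row(s) with unknown tokens", dropped)
    return ArchitectureTable(proteins, source=str(p), n_dropped=dropped)


def write_architecture_table(table: ArchitectureTable, path) -> None:
    """Write the normalized TSV form (coordinates 1-based inclusive)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive residue positions\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for pr in table.proteins:
            fh.write(
                "\t".join(
                    (
                        pr.protein_id,
                        pr.accession,
                        pr.organism,
                        str(pr.length_aa),
                        format_architecture_string(pr.hits),
                        pr.element_class,
                    )
                )
                + "\n"
            )


def filter_polyvalent(table: ArchitectureTable, min_domains: int = 2) -> ArchitectureTable:
    """Retain exactly the proteins with at least ``min_domains`` hits."""
    if min_domains < 1:
        raise ValidationError("min_domains must be >= 1")
    kept = [p for p in table.proteins if len(p.hits) >= min_domains]
    return ArchitectureTable(kept, source=table.source, n_dropped=table.n_dropped)


def architecture_signature(p: ProteinArchitecture) -> str:
    """Canonical architecture-type string: domain ids joined N-to-C with '+'.

    Two proteins share a signature iff their ordered domain sequences are
    identical; this defines the "architectural type" used for redundancy
    counts.
    """
    return "+".join(p.domain_ids)
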