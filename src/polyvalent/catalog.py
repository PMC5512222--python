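"""Controlled vocabulary of the domain types found in polyvalent proteins.

Polyvalent proteins — large multidomain proteins of phages, plasmids and
conjugative transposons that are co-delivered with the element's DNA — draw
on an inventory of 131 domain types.  The packaged catalog carries every
domain named in the source survey's running text and figures, the forty
novel uncharacterized LPD domains (LPD1..LPD40, "large polyvalent-protein-
associated domain"), and numbered ``UNNAMED-k`` placeholders standing in for
inventory members whose identity is only recorded in unavailable
supplementary material.  Placeholders are flagged as such and carry
``is_novel = False``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from ._errors import ValidationError
from .motifs import default_motifs

CATEGORIES = (
    "peptidase",
    "protein-modifying-enzyme",
    "nucleic-acid-enzyme",
    "nucleotide-metabolism",
    "peptidoglycan-cytoskeleton",
    "nucleic-acid-binding",
    "virion-structural",
    "uncharacterized-LPD",
    "other",
)

_CATALOG_COLUMNS = ("domain_id", "display_name", "category", "is_novel", "motif_ids", "notes")


@dataclass(frozen=True)
class DomainType:
    domain_id: str
    display_name: str
    category: str
    is_novel: bool = False
    motif_ids: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for domain {self.domain_id!r}"
            )


@dataclass
class DomainCatalog:
    entries: list[DomainType]
    version: str = "0"
    _by_id: dict[str, DomainType] = field(init=False, repr=False)

    def __post_init__(self):
        by_id: dict[str, DomainType] = {}
        for e in self.entries:
            if e.domain_id in by_id:
                raise ValidationError(f"duplicate domain_id {e.domain_id!r} in catalog")
            by_id[e.domain_id] = e
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._by_id

    def __getitem__(self, domain_id: str) -> DomainType:
        return self._by_id[domain_id]

    def ids(self) -> list[str]:
        return [e.domain_id for e in self.entries]

    def validate_motif_links(self) -> None:
        """Every motif_id referenced by a catalog entry must be a packaged motif."""
        known = {m.motif_id for m in default_motifs()}
        for e in self.entries:
            for mid in e.motif_ids:
                if mid not in known:
                    raise ValidationError(
                        f"domain {e.domain_id!r} links unknown motif {mid!r}"
                    )


def _default_catalog_path() -> Path:
    return Path(resources.files("polyvalent").joinpath("data/domain_catalog.tsv"))


def load_catalog(path=None) -> DomainCatalog:
    """Load a catalog TSV; ``path=None`` loads the packaged default.

    The dialect is one header line with columns domain_id, display_name,
    category, is_novel, motif_ids (comma-separated, may be empty), notes;
    UTF-8, tab-delimited, no quoting.
    """
    p = _default_catalog_path() if path is None else Path(path)
    if not p.exists():
        raise FileNotFoundError(f"catalog file not found: {p}")
    entries: list[DomainType] = []
    with open(p, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        header = next(reader, None)
        if header is None or tuple(header) != _CATALOG_COLUMNS:
            raise ValidationError(f"bad catalog header in {p}: {header}")
        for row in reader:
            if len(row) != len(_CATALOG_COLUMNS):
                raise ValidationError(f"bad catalog row in {p}: {row}")
            domain_id, display_name, category, is_novel, motif_ids, notes = row
            entries.append(
                DomainType(
                    domain_id=domain_id,
                    display_name=display_name,
                    category=category,
                    is_novel={"true": True, "false": False}[is_novel],
                    motif_ids=tuple(m for m in motif_ids.split(",") if m),
                    notes=notes,
                )
            )
    cat = DomainCatalog(entries, version="1")
    cat.validate_motif_links()
    return cat


def write_catalog(catalog: DomainCatalog, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for e in catalog.entries:
            fh.write(
                "\t".join(
                    (
                        e.domain_id,
                        e.display_name,
                        e.category,
                        "true" if e.is_novel else "false",
                        ",".join(e.motif_ids),
                        e.notes,
                    )
                )
                + "\n"
            )


def domains_by_category(catalog: DomainCatalog, category: str) -> list[DomainType]:
    """All and only the entries with the given category, in catalog order."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category token {category!r}")
    return [e for e in catalog.entries if e.category == category]
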