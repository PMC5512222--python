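"""Gene-neighborhood extraction and genomic-context classification.

Polyvalent-protein genes occur in three broad genomic contexts: alongside
the conjugation machinery of plasmids and integrative conjugative elements
(relaxase, Tra/Vir T4SS components), inside (pro)phages marked by the
portal-terminase packaging system, or with no distinguishing flanking
markers at all (interpreted as host-captured copies).  Classification here
is marker-tag based: each flanking gene carries controlled product tags, and
the call is conjugative if any non-anchor gene carries a conjugative tag,
else phage if any carries a phage tag, else host.  Mixed neighborhoods are
called conjugative with an ambiguity flag rather than a fourth class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from ._errors import UsageError, ValidationError

#: controlled product-tag vocabulary
CONJUGATIVE_TAGS = frozenset({"relaxase", "t4ss", "tra", "vir", "mob"})
PHAGE_TAGS = frozenset({"portal", "terminase", "virion", "capsid", "tail", "muf"})
ALL_TAGS = CONJUGATIVE_TAGS | PHAGE_TAGS | {"none"}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    start: int
    end: int
    strand: str
    product_tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        bad = set(self.product_tags) - ALL_TAGS
        if bad:
            raise ValidationError(f"{self.gene_id}: unknown tags {sorted(bad)}")


@dataclass
class GeneNeighborhood:
    replicon_id: str
    anchor_gene_id: str
    genes: list[GeneRecord]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if self.anchor_gene_id not in ids:
            raise ValidationError(
                f"anchor {self.anchor_gene_id!r} absent from neighborhood genes"
            )
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValidationError("neighborhood genes not sorted by start")


@dataclass(frozen=True)
class MarkerSet:
    conjugative_tags: frozenset[str] = CONJUGATIVE_TAGS
    phage_tags: frozenset[str] = PHAGE_TAGS

    def __post_init__(self):
        if self.conjugative_tags & self.phage_tags:
            raise ValidationError("marker tag sets must be disjoint")


@dataclass
class ContextCall:
    element_class: str
    ambiguous: bool
    evidence: list[tuple[str, str]]


#: annotation container: replicon_id -> genes sorted by start
GeneAnnotation = Mapping[str, list[GeneRecord]]


def extract_neighborhood(annotation: GeneAnnotation, anchor: str, k: int) -> GeneNeighborhood:
    """Anchor plus up to ``k`` genes on each side of it on its replicon."""
    if k < 0:
        raise UsageError("k must be >= 0")
    found = [
        (rep, i)
        for rep, genes in annotation.items()
        for i, g in enumerate(genes)
        if g.gene_id == anchor
    ]
    if not found:
        raise KeyError(f"anchor gene {anchor!r} not found in annotation")
    if len({rep for rep, _ in found}) > 1 or len(found) > 1:
        raise UsageError(f"anchor gene {anchor!r} occurs on multiple replicons")
    rep, i = found[0]
    genes = annotation[rep]
    window = list(genes[max(0, i - k) : i + k + 1])
    return GeneNeighborhood(rep, anchor, window)


def classify_context(nb: GeneNeighborhood, markers: MarkerSet = MarkerSet()) -> ContextCall:
    """Three-way context call from flanking marker tags.

    Precedence on mixed evidence is conjugative over phage, with
    ``ambiguous=True`` and the full evidence list retained.
    """
    conj_ev: list[tuple[str, str]] = []
    phage_ev: list[tuple[str, str]] = []
    for g in nb.genes:
        if g.gene_id == nb.anchor_gene_id:
            continue
        for t in sorted(g.product_tags):
            if t in markers.conjugative_tags:
                conj_ev.append((g.gene_id, t))
            elif t in markers.phage_tags:
                phage_ev.append((g.gene_id, t))
    if conj_ev:
        return ContextCall("conjugative", bool(phage_ev), conj_ev + phage_ev)
    if phage_ev:
        return ContextCall("phage", False, phage_ev)
    return ContextCall("host", False, [])


# ---------------------------------------------------------------------------
# product-string -> tag mapping

def _load_product_map() -> list[tuple[str, str]]:
    path = resources.files("polyvalent").joinpath("data/product_tags.tsv")
    out = []
    with path.open(encoding="utf-8") as fh:
        next(fh)
        for ln in fh:
            needle, tag = ln.rstrip("\n").split("\t")
            out.append((needle.lower(), tag))
    return out


def product_to_tags(product: str) -> frozenset[str]:
    """Map a free-text product description to controlled marker tags."""
    low = product.lower()
    return frozenset(tag for needle, tag in _load_product_map() if needle in low)


# ---------------------------------------------------------------------------
# I/O: TSV fallback and GFF3

def read_gene_table(path) -> dict[str, list[GeneRecord]]:
    """TSV dialect: replicon_id, gene_id, start, end, strand, tags (comma-sep)."""
    ann: dict[str, list[GeneRecord]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        header = next(reader)
        if tuple(header) != ("replicon_id", "gene_id", "start", "end", "strand", "tags"):
            raise ValidationError(f"bad gene table header: {header}")
        for rep, gid, start, end, strand, tags in reader:
            rec = GeneRecord(
                gid, int(start), int(end), strand,
                frozenset(t for t in tags.split(",") if t and t != "none"),
            )
            ann.setdefault(rep, []).append(rec)
    for genes in ann.values():
        genes.sort(key=lambda g: g.start)
    return ann


def write_gene_table(ann: GeneAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("replicon_id\tgene_id\tstart\tend\tstrand\ttags\n")
        for rep in ann:
            for g in ann[rep]:
                tags = ",".join(sorted(g.product_tags)) or "none"
                fh.write(f"{rep}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{tags}\n")


def read_gff3(path) -> dict[str, list[GeneRecord]]:
    """Read gene features from GFF3; marker tags come from the product_tag
    attribute when present, otherwise mapped from the product attribute."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    ann: dict[str, list[GeneRecord]] = {}
    for feat in db.features_of_type("gene", order_by="start"):
        if "product_tag" in feat.attributes:
            tags = frozenset(
                t for v in feat.attributes["product_tag"] for t in v.split(",")
                if t and t != "none"
            )
        elif "product" in feat.attributes:
            tags = product_to_tags(" ".join(feat.attributes["product"]))
        else:
            tags = frozenset()
        rec = GeneRecord(feat.id, feat.start, feat.end, feat.strand, tags)
        ann.setdefault(feat.seqid, []).append(rec)
    for genes in ann.values():
        genes.sort(key=lambda g: g.start)
    return ann


def write_gff3(ann: GeneAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for rep in ann:
            for g in ann[rep]:
                tags = ",".join(sorted(g.product_tags)) or "none"
                fh.write(
                    f"{rep}\tpolyvalent\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};product_tag={tags}\n"
                )


def write_calls_tsv(calls: Mapping[str, ContextCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("anchor_gene_id\telement_class\tambiguous\tevidence\n")
        for gid in calls:
            c = calls[gid]
            ev = ";".join(f"{g}:{t}" for g, t in c.evidence)
            fh.write(f"{gid}\t{c.element_class}\t{str(c.ambiguous).lower()}\t{ev}\n")
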