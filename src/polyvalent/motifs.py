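"""Short active-site motif scanning over protein sequences.

Motif expressions use the alignment-consensus conventions common in the
comparative-genomics literature: uppercase letters are literal residues,
``X`` matches any residue, ``[YF]`` is an explicit residue class, and the
lowercase/symbol classes are ``a`` (aromatic: F, W, Y), ``+`` (basic: K, R)
and ``-`` (acidic: D, E).  All matches, including overlapping ones, are
reported: motifs are diagnostic hints for domain families, not tilings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._errors import ParseError, ValidationError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)

#: residue classes for the lowercase/symbol tokens of motif expressions
CLASS_TOKENS = {
    "a": "FWY",  # aromatic
    "+": "KR",   # basic (positively charged)
    "-": "DE",   # acidic (negatively charged)
}


@dataclass(frozen=True)
class MotifPattern:
    """A compiled short-sequence motif tied to a catalog domain."""

    motif_id: str
    pattern: str
    associated_domain: str
    notes: str = ""
    _regex: re.Pattern = field(init=False, repr=False, compare=False)
    _length: int = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        regex, length = compile_motif(self.pattern)
        object.__setattr__(self, "_regex", regex)
        object.__setattr__(self, "_length", length)

    @property
    def length(self) -> int:
        return self._length

    def matches_window(self, window: str) -> bool:
        return len(window) == self._length and bool(self._regex.match(window))


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif: 1-based start and the literal substring."""

    motif_id: str
    start: int
    matched: str


def compile_motif(expr: str) -> tuple[re.Pattern, int]:
    """Compile a motif expression into an anchored regex and its width.

    Raises ParseError for empty expressions, unbalanced brackets, or tokens
    outside the motif grammar.
    """
    if not expr:
        raise ParseError("empty motif expression")
    parts: list[str] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c == "[":
            j = expr.find("]", i)
            if j < 0:
                raise ParseError(f"unbalanced '[' in motif expression {expr!r}")
            members = expr[i + 1 : j]
            if not members or any(m not in _AA_SET for m in members):
                raise ParseError(f"bad residue class '[{members}]' in {expr!r}")
            parts.append(f"[{members}]")
            i = j + 1
        elif c == "X":
            parts.append(f"[{AA20}]")
            i += 1
        elif c in CLASS_TOKENS:
            parts.append(f"[{CLASS_TOKENS[c]}]")
            i += 1
        elif c in _AA_SET:
            parts.append(c)
            i += 1
        else:
            raise ParseError(f"illegal token {c!r} in motif expression {expr!r}")
    return re.compile("".join(parts)), len(parts)


def scan_sequence(seq: str, patterns: Iterable[MotifPattern]) -> list[MotifMatch]:
    """Report every (possibly overlapping) motif match in ``seq``.

    Matches are sorted by (start, motif_id); starts are 1-based.  Characters
    outside the 20 standard amino-acid letters are rejected.
    """
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            raise ValidationError(
                f"illegal character {ch!r} at position {pos} (not a standard amino acid)"
            )
    out: list[MotifMatch] = []
    for pat in patterns:
        # lookahead so that overlapping occurrences are all reported
        rx = re.compile(f"(?=({pat._regex.pattern}))")
        for m in rx.finditer(seq):
            out.append(MotifMatch(pat.motif_id, m.start() + 1, m.group(1)))
    out.sort(key=lambda mm: (mm.start, mm.motif_id))
    return out


def default_motifs() -> list[MotifPattern]:
    """The packaged motif set diagnostic for polyvalent-protein domain families."""
    return [
        MotifPattern("HEXXH", "HEXXH", "MPTase",
                     "zincin-like metallopeptidase catalytic motif"),
        MotifPattern("HEXXXH", "HEXXXH", "MPTase",
                     "metallopeptidase variant with one extra inter-histidine residue"),
        MotifPattern("NPPYF", "NPP[YF]", "N6A-MTase",
                     "active-site asparagine motif of adenine N6-methyltransferases"),
        MotifPattern("GXGU", "GXG[GAS]", "LPD36",
                     "nucleotide-binding-like motif; U stands for G, A or S"),
        MotifPattern("DAN", "DaN-", "Toprim-primase",
                     "D-aromatic-N-acidic motif of mobile-element DnaG-like primases; "
                     "the four symbols are taken as consecutive residues"),
        MotifPattern("DD", "DD", "PRTase",
                     "catalytic double-aspartate motif of invasive-element PRTases"),
        MotifPattern("NXB", "NX+", "DarA-N",
                     "asparagine followed by a basic residue after a spacer"),
    ]


def scan_fasta(path, patterns: Sequence[MotifPattern]) -> dict[str, list[MotifMatch]]:
    """Scan every record of a FASTA file; returns {seq_id: matches}."""
    from Bio import SeqIO

    return {
        rec.id: scan_sequence(str(rec.seq).upper(), patterns)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_matches_tsv(matches: dict[str, list[MotifMatch]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id\tmotif_id\tstart\tmatched\n")
        for seq_id in sorted(matches):
            for mm in matches[seq_id]:
                fh.write(f"{seq_id}\t{mm.motif_id}\t{mm.start}\t{mm.matched}\n")
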