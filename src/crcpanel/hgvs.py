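"""Parsing and normalisation of cDNA HGVS descriptions.

The parser deliberately covers the subset of HGVS that germline panel
reports actually emit for small variants: substitutions, deletions,
insertions, deletion-insertions, duplications, and intronic offsets on
either end of the span (``c.117-1G>A``, ``c.1476+2C>T``).  Full HGVS
grammar (alleles, repeats, mosaicism, uncertain positions) is out of
scope; anything unparseable is preserved verbatim with kind ``unknown``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "VariantKind",
    "HgvsVariant",
    "VariantKey",
    "HgvsFormatError",
    "parse_cdna",
    "classify_consequence",
    "normalize_cdna",
    "variant_key",
]


class HgvsFormatError(ValueError):
    """Raised when a string is not a recognisable ``c.`` description."""


class VariantKind(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC_OTHER = "intronic_other"
    UNKNOWN = "unknown"


# one coding position with optional intronic offset, e.g. 117-1, 1476+2
_POS = re.compile(r"(?P<pos>\d+)(?P<off>[+-]\d+)?")
_BASES = "ACGTacgt"


def normalize_cdna(text: str) -> str:
    """Whitespace-stripped canonical form used for identity everywhere."""
    return "".join(text.split())


@dataclass(frozen=True)
class VariantKey:
    """Identity of a unique variant: gene symbol + normalised cDNA string.

    Keys are the sole basis of "unique variant" counting; two calls of the
    same cDNA change in the same gene in different samples share one key.
    """

    gene: str
    cdna: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "cdna", normalize_cdna(self.cdna))


@dataclass
class HgvsVariant:
    """A parsed small-variant cDNA description.

    ``cdna_position``/``cdna_end`` are 1-based coding coordinates of the
    affected span (equal for single-base changes); ``intron_offset`` is the
    signed offset of the start position when the variant lies in an intron
    (``-1`` for ``c.117-1G>A``), or ``None`` for exonic positions.
    """

    gene: str
    cdna: str
    protein: str = ""
    kind: VariantKind = VariantKind.UNKNOWN
    cdna_position: int = 0
    cdna_end: int = 0
    intron_offset: int | None = None
    end_offset: int | None = None
    op: str = "sub"  # sub | del | ins | delins | dup | unknown
    ref: str = ""
    alt: str = ""
    seq: str = ""  # trailing sequence for del/ins/dup/delins
    splice_candidate: bool = field(default=False, compare=False)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.gene, self.cdna)

    @property
    def is_indel(self) -> bool:
        return self.op in ("del", "ins", "delins", "dup")

    @property
    def length_change(self) -> int:
        """Net change in coding length (0 for substitutions/inframe events)."""
        span = self.cdna_end - self.cdna_position + 1
        if self.op == "del":
            return -(len(self.seq) or span)
        if self.op == "ins":
            return len(self.seq) or 1
        if self.op == "dup":
            return len(self.seq) or span
        if self.op == "delins":
            return len(self.seq) - span
        return 0

    def format(self) -> str:
        """Render the normalised cDNA string (round-trips through parse)."""
        return self.cdna


def _fmt_pos(pos: int, off: int | None) -> str:
    return f"{pos}{off:+d}" if off is not None else str(pos)


def parse_cdna(hgvs_string: str, gene: str = "", protein: str = "",
               splice_candidate: bool = False) -> HgvsVariant:
    """Parse a cDNA HGVS string such as ``c.2192_2196delTAACT``.

    The optional protein description refines the consequence call (``fs``
    designations, stop gains, synonymous ``p.X=``).  Unparseable suffixes
    yield ``kind=unknown`` with the raw (normalised) string preserved.
    """
    raw = normalize_cdna(hgvs_string)
    if not raw.startswith("c."):
        raise HgvsFormatError(f"not a cDNA (c.) description: {hgvs_string!r}")
    body = raw[2:]

    m = _POS.match(body)
    if m is None:
        v = HgvsVariant(gene=gene, cdna=raw, protein=protein, op="unknown")
        v.kind = VariantKind.UNKNOWN
        return v
    pos = int(m.group("pos"))
    off = int(m.group("off")) if m.group("off") else None
    rest = body[m.end():]

    end, end_off = pos, off
    if rest.startswith("_"):
        m2 = _POS.match(rest[1:])
        if m2 is None:
            v = HgvsVariant(gene=gene, cdna=raw, protein=protein,
                            cdna_position=pos, intron_offset=off, op="unknown")
            return v
        end = int(m2.group("pos"))
        end_off = int(m2.group("off")) if m2.group("off") else None
        rest = rest[1 + m2.end():]

    v = HgvsVariant(gene=gene, cdna=raw, protein=protein,
                    cdna_position=pos, cdna_end=end,
                    intron_offset=off, end_offset=end_off,
                    splice_candidate=splice_candidate)

    sub = re.fullmatch(rf"(?P<ref>[{_BASES}])>(?P<alt>[{_BASES}])", rest)
    if sub:
        v.op = "sub"
        v.ref = sub.group("ref").upper()
        v.alt = sub.group("alt").upper()
    elif rest.startswith("delins"):
        v.op, v.seq = "delins", rest[6:].upper()
    elif rest.startswith("del"):
        v.op, v.seq = "del", rest[3:].upper()
    elif rest.startswith("dup"):
        v.op, v.seq = "dup", rest[3:].upper()
    elif rest.startswith("ins"):
        v.op, v.seq = "ins", rest[3:].upper()
    else:
        v.op = "unknown"
    if v.op in ("del", "ins", "dup", "delins") and v.seq and not re.fullmatch(
            rf"[{_BASES}]*", v.seq):
        v.op, v.seq = "unknown", ""

    v.kind = classify_consequence(v, protein, splice_candidate=splice_candidate)
    return v


def classify_consequence(v: HgvsVariant, protein: str = "",
                         splice_candidate: bool = False) -> VariantKind:
    """Derive the functional consequence of a parsed variant.

    Priority: canonical-splice intronic positions, then frame effects of
    indels, then what the protein description says about a substitution.
    A synonymous change (``p.X=``) flagged as a splice candidate (an exonic
    base adjacent to an annotated exon boundary) is promoted to splice_site
    rather than being written off as silent.
    """
    protein = (protein or v.protein or "").strip()
    splice_candidate = splice_candidate or v.splice_candidate

    if v.op == "unknown":
        return VariantKind.UNKNOWN

    if v.intron_offset is not None or v.end_offset is not None:
        offs = [o for o in (v.intron_offset, v.end_offset) if o is not None]
        if any(abs(o) <= 2 for o in offs):
            return VariantKind.SPLICE_SITE
        return VariantKind.INTRONIC_OTHER

    if v.is_indel:
        if "fs" in protein:
            return VariantKind.FRAMESHIFT
        if v.length_change % 3 != 0:
            return VariantKind.FRAMESHIFT
        return VariantKind.INFRAME_INDEL

    # substitutions: read the protein annotation
    if protein.endswith("="):
        if splice_candidate:
            return VariantKind.SPLICE_SITE
        return VariantKind.SYNONYMOUS
    if "fs" in protein:
        return VariantKind.FRAMESHIFT
    if re.search(r"(Ter|\*)\d*$", protein):
        return VariantKind.NONSENSE
    if re.fullmatch(r"p\.\(?[A-Z][a-z]{2}\d+[A-Z][a-z]{2}\)?", protein):
        return VariantKind.MISSENSE
    if splice_candidate:
        return VariantKind.SPLICE_SITE
    return VariantKind.UNKNOWN


def variant_key(gene: str, cdna: str, panel=None) -> VariantKey:
    """Deterministic, whitespace/case-normalised identity for dedup.

    When a panel is supplied the gene symbol is validated against it.
    """
    key = VariantKey(gene, cdna)
    if panel is not None and key.gene not in panel:
        raise KeyError(f"gene {key.gene!r} is not in the panel")
    return key
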