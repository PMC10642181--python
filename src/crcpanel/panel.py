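"""The 14-gene hereditary colorectal cancer panel definition.

The default panel covers the Lynch-syndrome mismatch-repair genes
(MLH1, MSH2, MSH6, PMS2) plus EPCAM, the polyposis genes (APC, BMPR1A,
MUTYH, SMAD4, PTEN, STK11), the polymerase proofreading genes
(POLD1, POLE) and TP53.  Exon boundaries, where provided, are 1-based
coding coordinates of exon edges and drive splice-candidate detection for
exonic variants; they are configuration, not hard-coded biology.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .hgvs import HgvsVariant

__all__ = ["RiskLevel", "PanelGene", "Panel", "load_panel", "default_panel",
           "MMR_GENES"]

#: Mismatch-repair genes counted for Lynch syndrome (EPCAM excluded).
MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})


class RiskLevel(str, enum.Enum):
    HIGH = "high"
    RISK = "risk"
    LOWER = "lower"


@dataclass(frozen=True)
class PanelGene:
    """One gene on the panel.

    ``lof_mechanism`` marks genes for which null (truncating / canonical
    splice) variants are an accepted disease mechanism — a precondition for
    the very-strong loss-of-function evidence code.  The proofreading
    polymerases act through missense changes in the exonuclease domain, so
    they default to False.
    """

    symbol: str
    refseq: str
    locus: str
    risk_level: RiskLevel
    phenotype: str = ""
    lof_mechanism: bool = True
    exon_boundaries: tuple[int, ...] = field(default=())


class Panel:
    """A mapping-like container of :class:`PanelGene` keyed by symbol."""

    def __init__(self, genes: list[PanelGene]):
        self._genes: dict[str, PanelGene] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene symbol {g.symbol}")
            if not g.refseq.startswith("NM_"):
                raise ValueError(
                    f"{g.symbol}: transcript {g.refseq!r} is not an NM_ accession")
            self._genes[g.symbol] = g

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> PanelGene:
        return self._genes[symbol]

    def __iter__(self):
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def symbols(self) -> list[str]:
        return list(self._genes)

    def get(self, symbol: str, default=None):
        return self._genes.get(symbol, default)

    def is_splice_candidate(self, v: HgvsVariant, flank_bp: int = 2) -> bool:
        """True if ``v`` sits at/next to a splice junction.

        Canonical +/-1,2 intronic positions always qualify; exonic
        positions qualify when within ``flank_bp`` coding bases of an
        annotated exon boundary of the gene.
        """
        offs = [o for o in (v.intron_offset, v.end_offset) if o is not None]
        if any(abs(o) <= 2 for o in offs):
            return True
        gene = self.get(v.gene)
        if gene is None or not gene.exon_boundaries or offs:
            return False
        for b in gene.exon_boundaries:
            if (abs(v.cdna_position - b) < flank_bp
                    or abs(v.cdna_end - b) < flank_bp):
                return True
        return False


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes", "y")


def load_panel(path: str | Path) -> Panel:
    """Read a panel definition TSV.

    Columns: symbol, refseq, locus, risk_level, phenotype, lof_mechanism,
    optional exon_boundaries (semicolon-separated 1-based coding coords).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"symbol", "refseq", "locus", "risk_level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns {sorted(missing)}")
    genes = []
    for _, row in df.iterrows():
        boundaries = ()
        if row.get("exon_boundaries", ""):
            boundaries = tuple(
                int(x) for x in str(row["exon_boundaries"]).split(";") if x)
        genes.append(PanelGene(
            symbol=row["symbol"].strip(),
            refseq=row["refseq"].strip(),
            locus=row["locus"].strip(),
            risk_level=RiskLevel(row["risk_level"].strip().lower()),
            phenotype=row.get("phenotype", ""),
            lof_mechanism=_parse_bool(row.get("lof_mechanism", "true")),
            exon_boundaries=boundaries,
        ))
    return Panel(genes)


def default_panel() -> Panel:
    """The packaged 14-gene panel."""
    with resources.as_file(
            resources.files("crcpanel").joinpath("data/panel_genes.tsv")) as p:
        return load_panel(p)
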