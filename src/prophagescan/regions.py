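"""The ProphageRegion container: a candidate region with its member genes,
evidence flags and conservation call."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .conservation import ConservationCall
from .evidence import GcEvidence, TrnaEvidence
from .genome_io import GeneFeature


@dataclass
class ProphageRegion:
    """A candidate prophage region spanning its member genes.

    ``start``/``end`` are 1-based inclusive and equal the extent of the
    member genes (min start .. max end).  Evidence and conservation are
    annotative: a region failing every test is still reported, with its
    flags false.
    """

    region_id: str
    start: int
    end: int
    genes: List[GeneFeature] = field(default_factory=list)
    genome_id: str = ""
    gc_evidence: Optional[GcEvidence] = None
    trna_evidence: Optional[TrnaEvidence] = None
    conservation: Optional[ConservationCall] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"region {self.region_id}: end {self.end} < start {self.start}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "genome_id": self.genome_id,
            "start": self.start,
            "end": self.end,
            "genes": [g.to_dict() for g in self.genes],
            "gc_evidence": None
            if self.gc_evidence is None
            else self.gc_evidence.to_dict(),
            "trna_evidence": None
            if self.trna_evidence is None
            else self.trna_evidence.to_dict(),
            "conservation": None
            if self.conservation is None
            else self.conservation.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProphageRegion":
        return cls(
            region_id=d["region_id"],
            genome_id=d.get("genome_id", ""),
            start=d["start"],
            end=d["end"],
            genes=[GeneFeature.from_dict(g) for g in d["genes"]],
            gc_evidence=None
            if d.get("gc_evidence") is None
            else GcEvidence.from_dict(d["gc_evidence"]),
            trna_evidence=None
            if d.get("trna_evidence") is None
            else TrnaEvidence.from_dict(d["trna_evidence"]),
            conservation=None
            if d.get("conservation") is None
            else ConservationCall.from_dict(d["conservation"]),
        )
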