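"""Reading annotated genomes and writing region calls in standard formats.

Input is a GenBank or EMBL flat file with CDS and tRNA features; the parser
extracts both feature kinds, normalises coordinates to 1-based inclusive on
the forward strand, and computes missing CDS translations with the bacterial
genetic code (translation table 11).

Output formats for candidate prophage regions: TSV (one row per region),
GFF3 (1-based inclusive), BED (0-based half-open) and JSON (full detail;
lossless round-trip via :func:`read_regions_json`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import GenomeParseError, NoCodingFeaturesError

logger = logging.getLogger(__name__)

#: feature kinds extracted from annotation files
FEATURE_KINDS = ("CDS", "tRNA")


@dataclass
class GeneFeature:
    """One CDS or tRNA feature with 1-based inclusive genomic coordinates.

    Compound (join/complement-join) locations are collapsed to their
    outermost start..end span: downstream clustering and evidence scoring
    only use the gene's genomic extent.
    """

    feature_id: str
    kind: str  # "CDS" or "tRNA"
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, start <= end
    strand: int = 1  # +1 or -1
    product: str = ""
    translation: Optional[str] = None  # CDS only

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid feature interval {self.start}..{self.end} "
                f"for {self.feature_id}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def midpoint(self) -> int:
        """Genomic midpoint, (start+end)//2; the 1-D clustering feature."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "kind": self.kind,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "product": self.product,
            "translation": self.translation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneFeature":
        return cls(**d)


@dataclass
class GenomeRecord:
    """A genome sequence plus its ordered CDS/tRNA features."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    features: List[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds(self) -> List[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def trnas(self) -> List[GeneFeature]:
        return [f for f in self.features if f.kind == "tRNA"]

    def subsequence(self, start: int, end: int) -> str:
        """Forward-strand sequence of the 1-based inclusive span start..end."""
        return self.sequence[start - 1 : end]

    def validate(self) -> None:
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.feature_id} ({f.start}..{f.end}) exceeds "
                    f"genome length {self.length}"
                )


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith("LOCUS"):
                    return "genbank"
                if line.startswith("ID "):
                    return "embl"
                raise GenomeParseError(
                    f"{path}: cannot determine format from first line: "
                    f"{line.rstrip()!r}"
                )
    raise GenomeParseError(f"{path}: file is empty")


def _translate_span(record_seq: str, f: GeneFeature) -> str:
    """Translate a CDS span with table 11, tolerating sloppy annotations.

    Lengths not divisible by 3 are truncated to the longest in-frame prefix
    (with a warning) rather than aborting.
    """
    nt = record_seq[f.start - 1 : f.end]
    if f.strand == -1:
        nt = str(Seq(nt).reverse_complement())
    if len(nt) % 3 != 0:
        logger.warning(
            "CDS %s length %d not divisible by 3; translating longest "
            "in-frame prefix",
            f.feature_id,
            len(nt),
        )
        nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate(table=11)).rstrip("*")


def _extract_features(rec, sequence: str) -> List[GeneFeature]:
    feats: List[GeneFeature] = []
    ordinal = 0
    for sf in rec.features:
        if sf.type not in FEATURE_KINDS:
            continue
        ordinal += 1
        start = int(sf.location.start) + 1  # Biopython is 0-based half-open
        end = int(sf.location.end)
        strand = sf.location.strand if sf.location.strand in (1, -1) else 1
        quals = sf.qualifiers
        feature_id = quals.get("locus_tag", [f"feat_{ordinal:05d}"])[0]
        product = quals.get("product", [""])[0]
        translation = None
        if sf.type == "CDS":
            translation = quals.get("translation", [None])[0]
        gf = GeneFeature(
            feature_id=feature_id,
            kind=sf.type,
            start=start,
            end=end,
            strand=strand,
            product=product,
            translation=translation,
        )
        if sf.type == "CDS" and gf.translation is None:
            gf.translation = _translate_span(sequence, gf)
        feats.append(gf)
    feats.sort(key=lambda f: (f.start, f.end, f.feature_id))
    return feats


def read_annotated_genomes(path, format: str = "auto") -> List[GenomeRecord]:
    """Read every record of a GenBank/EMBL file (multi-contig files are
    processed record by record)."""
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("genbank", "embl"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        seq_records = list(SeqIO.parse(str(path), fmt))
    except ValueError as exc:
        raise GenomeParseError(f"{path}: {exc}") from exc
    if not seq_records:
        raise GenomeParseError(f"{path}: no records parsed as {fmt}")
    out = []
    for rec in seq_records:
        sequence = str(rec.seq).upper()
        topology = rec.annotations.get("topology", "linear")
        features = _extract_features(rec, sequence)
        gr = GenomeRecord(
            id=rec.id, sequence=sequence, topology=topology, features=features
        )
        gr.validate()
        out.append(gr)
    if not any(f.kind == "CDS" for r in out for f in r.features):
        raise NoCodingFeaturesError(
            f"{path}: no coding features (CDS) found; pipeline cannot run"
        )
    return out


def read_annotated_genome(path, format: str = "auto") -> GenomeRecord:
    """Read a single-record annotation file.

    Multi-record files: the first record is returned with a warning; use
    :func:`read_annotated_genomes` to process each record independently.
    """
    records = read_annotated_genomes(path, format=format)
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path,
            len(records),
            records[0].id,
        )
    return records[0]


# ---------------------------------------------------------------------------
# Region output
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "region_id",
    "start",
    "end",
    "n_genes",
    "gc_evidence",
    "trna_evidence",
    "conserved",
    "best_phage",
    "phage_fraction",
)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def _region_row(region) -> List[str]:
    gc = region.gc_evidence
    trna = region.trna_evidence
    cons = region.conservation
    return [
        _fmt(region.region_id),
        _fmt(region.start),
        _fmt(region.end),
        _fmt(region.n_genes),
        _fmt(None if gc is None else gc.supported),
        _fmt(None if trna is None else trna.supported),
        _fmt(None if cons is None else cons.conserved),
        _fmt(None if cons is None else cons.best_phage),
        _fmt(None if cons is None else cons.phage_fraction),
    ]


def write_regions(regions: Iterable, path, format: str = "tsv") -> None:
    """Write candidate prophage regions to ``path``.

    Formats: ``tsv`` (summary table), ``gff3`` (type prophage_region,
    1-based inclusive), ``bed`` (0-based half-open) and ``json`` (full
    evidence detail; read back with :func:`read_regions_json`).
    """
    regions = list(regions)
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        lines += ["\t".join(_region_row(r)) for r in regions]
        path.write_text("\n".join(lines) + "\n")
    elif format == "gff3":
        lines = ["##gff-version 3"]
        for r in regions:
            attrs = [f"ID={r.region_id}", f"n_genes={r.n_genes}"]
            if r.gc_evidence is not None:
                attrs.append(f"gc_evidence={_fmt(r.gc_evidence.supported)}")
            if r.trna_evidence is not None:
                attrs.append(f"trna_evidence={_fmt(r.trna_evidence.supported)}")
            if r.conservation is not None:
                attrs.append(f"conserved={_fmt(r.conservation.conserved)}")
                attrs.append(f"best_phage={_fmt(r.conservation.best_phage)}")
            lines.append(
                "\t".join(
                    [
                        r.genome_id or ".",
                        "prophagescan",
                        "prophage_region",
                        str(r.start),
                        str(r.end),
                        ".",
                        ".",
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "bed":
        lines = []
        for r in regions:
            lines.append(
                "\t".join(
                    [
                        r.genome_id or ".",
                        str(r.start - 1),  # 0-based half-open
                        str(r.end),
                        r.region_id,
                        "0",
                        ".",
                    ]
                )
            )
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "json":
        payload = {"regions": [r.to_dict() for r in regions]}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported region output format {format!r}")


def read_regions_json(path) -> list:
    """Inverse of ``write_regions(..., format='json')``."""
    from .regions import ProphageRegion  # local import avoids a cycle

    payload = json.loads(Path(path).read_text())
    return [ProphageRegion.from_dict(d) for d in payload["regions"]]
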