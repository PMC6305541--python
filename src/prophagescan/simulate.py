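"""Seeded synthetic genomes with implanted prophage cassettes.

The generator emits the three inputs the pipeline consumes — an annotated
GenBank genome, a 12-column homology-hits table, and reference prophage
coordinates — plus a machine-readable truth set, all mutually consistent
and byte-reproducible for a fixed seed.

What is emulated: a bacterial chromosome of i.i.d. nucleotides at a
background G+C, with non-overlapping prophage cassettes whose composition
is shifted by a configurable amount; genes tiled densely inside cassettes
and at a typical bacterial density outside; tRNA genes placed near cassette
boundaries with a configurable probability (the insertion-site signal); and
a hits table in which cassette genes hit their source phage at high
identity (minus dropouts) while background genes occasionally draw a
spurious hit.

What is *not* emulated: codon structure, real phage gene content, sequence-
level homology (hits are declared, not aligned), and repeat-driven
integration sites.  The generator tests the pipeline's signal processing,
not database realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import PlacementError
from .genome_io import GeneFeature, GenomeRecord
from .homology import HomologyHit, write_hits_table

TRNA_LENGTH = 75
#: minimum background spacer between cassettes and to the genome ends
MIN_IMPLANT_GAP = 10_000


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults describe the study conditions used throughout the test suite:
    a 200 kb chromosome at 45% G+C with three cassettes of 15-45 kb shifted
    +0.10 in G+C, 10-30 genes per cassette, ~0.9 genes/kb background
    density, a flanking tRNA for half the cassettes, 1% spurious hits on
    background genes and 5% dropout of cassette-gene hits.
    """

    genome_length: int = 200_000
    background_gc: float = 0.45
    n_prophages: int = 3
    prophage_length: Tuple[int, int] = (15_000, 45_000)
    prophage_gc_shift: float = 0.10
    genes_per_prophage: Tuple[int, int] = (10, 30)
    background_gene_density: float = 0.9  # genes per kb
    trna_flank_probability: float = 0.5
    false_hit_rate: float = 0.01  # spurious hit per background gene
    miss_rate: float = 0.05  # dropped hit per cassette gene
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_gc", "trna_flank_probability",
                     "false_hit_rate", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.background_gc + self.prophage_gc_shift <= 1.0:
            raise ValueError("background_gc + prophage_gc_shift outside [0,1]")


@dataclass
class TruthRegion:
    start: int  # 1-based inclusive cassette span
    end: int
    phage_id: str
    trna_flank: bool
    gene_ids: List[str] = field(default_factory=list)


@dataclass
class TruthSet:
    """Ground truth matching the emitted annotation and hits files."""

    regions: List[TruthRegion] = field(default_factory=list)
    trna_positions: List[Tuple[str, int, int]] = field(default_factory=list)
    gene_assignments: Dict[str, str] = field(default_factory=dict)

    def intervals(self) -> List[Tuple[int, int]]:
        return [(r.start, r.end) for r in self.regions]

    def to_dict(self) -> dict:
        return {
            "regions": [
                {
                    "start": r.start,
                    "end": r.end,
                    "phage_id": r.phage_id,
                    "trna_flank": r.trna_flank,
                    "gene_ids": list(r.gene_ids),
                }
                for r in self.regions
            ],
            "trna_positions": [list(t) for t in self.trna_positions],
            "gene_assignments": dict(self.gene_assignments),
        }


@dataclass
class SyntheticDataset:
    genome: GenomeRecord
    truth: TruthSet
    hits: List[HomologyHit]
    genome_path: Optional[Path] = None
    hits_path: Optional[Path] = None
    truth_bed_path: Optional[Path] = None
    truth_json_path: Optional[Path] = None


# ---------------------------------------------------------------------------


def _draw_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)

def _place_implants(
    rng: np.random.Generator, spec: SyntheticSpec
) -> List[Tuple[int, int]]:
    """Non-overlapping cassette spans (1-based inclusive), separated from
    each other and the genome ends by at least MIN_IMPLANT_GAP."""
    n = spec.n_prophages
    if n == 0:
        return []
    lo, hi = spec.prophage_length
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    free = spec.genome_length - sum(lengths) - (n + 1) * MIN_IMPLANT_GAP
    if free < 0:
        raise PlacementError(
            f"cannot place {n} cassettes totalling {sum(lengths)} bp in a "
            f"{spec.genome_length} bp genome with {MIN_IMPLANT_GAP} bp "
            f"spacers; reduce n_prophages or prophage_length"
        )
    slack = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1))
    spans = []
    pos = 1
    for i in range(n):
        pos += MIN_IMPLANT_GAP + int(slack[i])
        spans.append((pos, pos + lengths[i] - 1))
        pos += lengths[i]
    return spans


@dataclass
class _Gene:
    start: int
    end: int
    strand: int
    kind: str  # CDS | tRNA
    origin: str  # phage id | "background"
    feature_id: str = ""


def _tile_genes(
    rng: np.random.Generator,
    span: Tuple[int, int],
    max_genes: Optional[int],
    gap_range: Tuple[int, int],
    reserved: List[Tuple[int, int]],
) -> List[Tuple[int, int, int]]:
    """Tile non-overlapping genes left to right inside span, skipping
    reserved intervals.  Returns (start, end, strand) triples."""
    out = []
    cur = span[0] + int(rng.integers(20, 150))
    while cur + 600 - 1 <= span[1]:
        if max_genes is not None and len(out) >= max_genes:
            break
        length = int(rng.integers(600, 1201))
        length -= length % 3
        end = cur + length - 1
        if end > span[1]:
            break
        hit_reserved = next(
            (r for r in reserved if end >= r[0] and cur <= r[1]), None
        )
        if hit_reserved is not None:
            cur = hit_reserved[1] + 1 + int(rng.integers(20, 150))
            continue
        strand = 1 if rng.random() < 0.5 else -1
        out.append((cur, end, strand))
        cur = end + 1 + int(rng.integers(*gap_range))
    return out


def _translate(seq_bytes: np.ndarray, start: int, end: int, strand: int) -> str:
    nt = seq_bytes[start - 1 : end].tobytes().decode("ascii")
    if strand == -1:
        nt = str(Seq(nt).reverse_complement())
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate(table=11)).rstrip("*")


def simulate(spec: SyntheticSpec) -> SyntheticDataset:
    """Build one synthetic dataset in memory.  Deterministic given
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    implants = _place_implants(rng, spec)

    # 1. sequence: background draw, cassette spans overwritten at shifted GC
    seq = _draw_sequence(rng, spec.genome_length, spec.background_gc)
    for start, end in implants:
        seq[start - 1 : end] = _draw_sequence(
            rng, end - start + 1, spec.background_gc + spec.prophage_gc_shift
        )

    genes: List[_Gene] = []

    # 2. cassette genes, tiled densely
    lo_g, hi_g = spec.genes_per_prophage
    implant_gene_lists: List[List[_Gene]] = []
    for k, (start, end) in enumerate(implants):
        phage_id = f"PHAGE_{k + 1:02d}"
        n_target = int(rng.integers(lo_g, hi_g + 1))
        tiles = _tile_genes(rng, (start, end), n_target, (20, 151), [])
        glist = [_Gene(s, e, st, "CDS", phage_id) for s, e, st in tiles]
        genes.extend(glist)
        implant_gene_lists.append(glist)

    # 3. flanking tRNAs (the insertion-site signal), one per cassette with
    #    probability trna_flank_probability, within 2 kb of a boundary
    trna_flank: List[bool] = []
    trnas: List[_Gene] = []
    for k, (start, end) in enumerate(implants):
        placed = False
        if rng.random() < spec.trna_flank_probability:
            side = "left" if rng.random() < 0.5 else "right"
            offset = int(rng.integers(40, 2000 - TRNA_LENGTH))
            if side == "left":
                t_end = start - offset
                t_start = t_end - TRNA_LENGTH + 1
            else:
                t_start = end + offset
                t_end = t_start + TRNA_LENGTH - 1
            inside_genome = 1 <= t_start and t_end <= spec.genome_length
            in_other = any(
                t_end >= s and t_start <= e
                for i, (s, e) in enumerate(implants)
                if i != k
            )
            if inside_genome and not in_other:
                trnas.append(_Gene(t_start, t_end, 1, "tRNA", "background"))
                placed = True
        trna_flank.append(placed)

    # 4. background spans between cassettes
    bounds = [0] + [b for s, e in implants for b in (s - 1, e)] + [
        spec.genome_length + 1
    ]
    background_spans = [
        (bounds[i] + 1, bounds[i + 1])
        for i in range(0, len(bounds), 2)
        if bounds[i + 1] - bounds[i] >= 1
    ]

    # background tRNAs, kept well clear (>5 kb) of cassette boundaries so
    # flank evidence stays unambiguous
    for span in background_spans:
        safe = (span[0] + 5000, span[1] - 5000)
        if span[0] == 1:
            safe = (span[0], safe[1])
        if span[1] == spec.genome_length:
            safe = (safe[0], span[1])
        n_extra = max(0, (safe[1] - safe[0] + 1) // 50_000)
        for _ in range(n_extra):
            t_start = int(rng.integers(safe[0], safe[1] - TRNA_LENGTH))
            cand = _Gene(t_start, t_start + TRNA_LENGTH - 1, 1, "tRNA",
                         "background")
            if not any(
                cand.end >= t.start and cand.start <= t.end for t in trnas
            ):
                trnas.append(cand)
    genes.extend(trnas)

    # 5. background CDS at ~background_gene_density genes/kb
    #    (mean gene 900 bp; the gap range sets the achieved density)
    period = 1000.0 / max(spec.background_gene_density, 1e-9)
    mean_gap = max(period - 900.0, 25.0)
    gap_range = (20, int(2 * mean_gap - 20) + 1)
    reserved = [(t.start, t.end) for t in trnas]
    for span in background_spans:
        if span[1] - span[0] + 1 < 700:
            continue
        tiles = _tile_genes(rng, span, None, gap_range, reserved)
        genes.extend(_Gene(s, e, st, "CDS", "background") for s, e, st in tiles)

    # 6. stable feature ids in genome order
    genes.sort(key=lambda g: (g.start, g.end))
    for i, g in enumerate(genes):
        g.feature_id = f"PSCAN_{i + 1:05d}"

    # 7. homology hits: cassette genes hit their phage (minus dropouts),
    #    background genes draw spurious hits at false_hit_rate
    hits: List[HomologyHit] = []
    for k, glist in enumerate(implant_gene_lists):
        phage_id = f"PHAGE_{k + 1:02d}"
        for j, g in enumerate(glist):
            dropped = rng.random() < spec.miss_rate
            pident = round(float(rng.uniform(85.0, 100.0)), 1)
            evalue = 10.0 ** -float(rng.uniform(20.0, 120.0))
            if dropped:
                continue
            aa_len = (g.end - g.start + 1) // 3
            hits.append(
                HomologyHit(
                    query_id=g.feature_id,
                    subject_id=f"{phage_id}|gp{j + 1:03d}",
                    percent_identity=pident,
                    align_length=aa_len,
                    mismatches=int(round(aa_len * (100.0 - pident) / 100.0)),
                    gap_opens=0,
                    qstart=1,
                    qend=aa_len,
                    sstart=1,
                    send=aa_len,
                    evalue=evalue,
                    bitscore=round(2.0 * aa_len * pident / 100.0, 1),
                )
            )
    for g in genes:
        if g.kind != "CDS" or g.origin != "background":
            continue
        spurious = rng.random() < spec.false_hit_rate
        decoy = int(rng.integers(1, 10))
        pident = round(float(rng.uniform(82.0, 98.0)), 1)
        evalue = 10.0 ** -float(rng.uniform(6.0, 40.0))
        if not spurious:
            continue
        aa_len = (g.end - g.start + 1) // 3
        hits.append(
            HomologyHit(
                query_id=g.feature_id,
                subject_id=f"PHAGE_BG{decoy:02d}|gp001",
                percent_identity=pident,
                align_length=aa_len,
                mismatches=int(round(aa_len * (100.0 - pident) / 100.0)),
                gap_opens=0,
                qstart=1,
                qend=aa_len,
                sstart=1,
                send=aa_len,
                evalue=evalue,
                bitscore=round(2.0 * aa_len * pident / 100.0, 1),
            )
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))

    # 8. assemble genome record + truth
    sequence = seq.tobytes().decode("ascii")
    features = []
    for g in genes:
        if g.kind == "CDS":
            product = (
                f"phage protein ({g.origin})"
                if g.origin != "background"
                else "hypothetical protein"
            )
            features.append(
                GeneFeature(
                    feature_id=g.feature_id,
                    kind="CDS",
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    product=product,
                    translation=_translate(seq, g.start, g.end, g.strand),
                )
            )
        else:
            features.append(
                GeneFeature(
                    feature_id=g.feature_id,
                    kind="tRNA",
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    product="tRNA-Xxx",
                )
            )
    genome = GenomeRecord(
        id=f"SYNTH_{spec.seed}",
        sequence=sequence,
        topology="linear",
        features=features,
    )

    truth = TruthSet()
    gene_by_pos = {(g.start, g.end): g for g in genes}
    for k, (start, end) in enumerate(implants):
        glist = implant_gene_lists[k]
        truth.regions.append(
            TruthRegion(
                start=start,
                end=end,
                phage_id=f"PHAGE_{k + 1:02d}",
                trna_flank=trna_flank[k],
                gene_ids=[gene_by_pos[(g.start, g.end)].feature_id for g in glist],
            )
        )
    for t in trnas:
        truth.trna_positions.append((t.feature_id, t.start, t.end))
    for g in genes:
        if g.kind == "CDS":
            truth.gene_assignments[g.feature_id] = g.origin
    return SyntheticDataset(genome=genome, truth=truth, hits=hits)


def _to_seqrecord(genome: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="synthetic bacterial genome with implanted prophages",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-reproducibility
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, genome.length),
            type="source",
            qualifiers={"organism": ["synthetic construct"]},
        )
    )
    for f in genome.features:
        quals = {"locus_tag": [f.feature_id], "product": [f.product]}
        if f.kind == "CDS" and f.translation is not None:
            quals["transl_table"] = ["11"]
            quals["translation"] = [f.translation]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=f.strand),
                type=f.kind,
                qualifiers=quals,
            )
        )
    return rec


def generate_genome(
    spec: SyntheticSpec, out_dir
) -> SyntheticDataset:
    """Generate a dataset and write genome.gbk, hits.tsv, truth_regions.bed
    and truth.json under ``out_dir``.  Byte-identical across runs for a
    fixed spec."""
    ds = simulate(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.genome_path = out / "genome.gbk"
    ds.hits_path = out / "hits.tsv"
    ds.truth_bed_path = out / "truth_regions.bed"
    ds.truth_json_path = out / "truth.json"
    SeqIO.write([_to_seqrecord(ds.genome)], str(ds.genome_path), "genbank")
    write_hits_table(ds.hits, ds.hits_path)
    bed_lines = [
        "\t".join(
            [ds.genome.id, str(r.start - 1), str(r.end), r.phage_id, "0", "."]
        )
        for r in ds.truth.regions
    ]
    ds.truth_bed_path.write_text(
        "\n".join(bed_lines) + ("\n" if bed_lines else "")
    )
    ds.truth_json_path.write_text(
        json.dumps(ds.truth.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return ds
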