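"""Compositional and positional evidence for candidate prophage regions.

Two reinforcing signals are scored, neither of which removes a region:

* **G+C deviation** — a 1 kb sliding window (100 bp step) over the whole
  genome gives the background G+C distribution; a region is supported when
  at least 80% of its genes have G+C strictly above mean + 1 SD or strictly
  below mean - 1 SD of the window values.  Horizontally transferred DNA,
  prophages included, frequently deviates from the host's base composition.
* **tRNA flank** — phages preferentially integrate at tRNA genes, so a tRNA
  inside the region or within a configurable flank distance (default 2 kb)
  of either boundary is evidence of an insertion site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Optional, Tuple

import numpy as np

from .errors import UndefinedGcError

if TYPE_CHECKING:  # pragma: no cover
    from .genome_io import GenomeRecord
    from .regions import ProphageRegion

logger = logging.getLogger(__name__)

DEFAULT_GC_WINDOW = 1000
DEFAULT_GC_STEP = 100
DEFAULT_GENE_FRACTION = 0.80
DEFAULT_FLANK_DISTANCE = 2000


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T), case-insensitive; N and ambiguity codes excluded
    from numerator and denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedGcError(
            "G+C content undefined: no countable A/C/G/T bases"
        )
    return gc / (gc + at)


@dataclass
class GcStats:
    """Sliding-window G+C statistics over a whole genome."""

    window_size: int
    step: int
    window_values: np.ndarray  # fractions in [0,1]
    mean: float
    sd: float  # population SD


def windowed_gc_stats(
    genome: "GenomeRecord",
    window_size: int = DEFAULT_GC_WINDOW,
    step: int = DEFAULT_GC_STEP,
) -> GcStats:
    """Slide a window over the genome and collect per-window G+C fractions.

    Windows start at 1, 1+step, ... while start+window_size-1 <= length.
    If the genome is shorter than one window, a single window covering the
    whole sequence is used (with a warning).  Mean and *population* SD are
    taken over the window values: the windows enumerate the genome rather
    than sample it.
    """
    s = genome.sequence.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_acgt = is_gc | ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])

    if n < window_size:
        logger.warning(
            "genome length %d < window size %d; using one whole-genome window",
            n,
            window_size,
        )
        starts = np.array([0])
        window_size = n
    else:
        starts = np.arange(0, n - window_size + 1, step)
    gc_counts = cum_gc[starts + window_size] - cum_gc[starts]
    ok_counts = cum_ok[starts + window_size] - cum_ok[starts]
    with np.errstate(invalid="ignore"):
        values = np.where(ok_counts > 0, gc_counts / ok_counts, np.nan)
    if np.isnan(values).any():
        logger.warning("dropping %d windows without countable bases",
                       int(np.isnan(values).sum()))
        values = values[~np.isnan(values)]
    if values.size == 0:
        raise UndefinedGcError("no window has countable A/C/G/T bases")
    return GcStats(
        window_size=window_size,
        step=step,
        window_values=values,
        mean=float(values.mean()),
        sd=float(values.std()),  # population SD
    )


@dataclass
class GcEvidence:
    """Per-region outcome of the G+C deviation rule."""

    supported: bool
    gene_gc_values: List[float] = field(default_factory=list)
    deviant_fraction: float = 0.0
    gene_fraction_threshold: float = DEFAULT_GENE_FRACTION
    genome_mean: float = 0.0
    genome_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "supported": self.supported,
            "gene_gc_values": list(self.gene_gc_values),
            "deviant_fraction": self.deviant_fraction,
            "gene_fraction_threshold": self.gene_fraction_threshold,
            "genome_mean": self.genome_mean,
            "genome_sd": self.genome_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GcEvidence":
        return cls(**d)


@dataclass
class TrnaEvidence:
    """Per-region outcome of the tRNA insertion-site rule.

    ``flanking_trnas`` lists (feature_id, signed distance): 0 for a tRNA
    overlapping the region, negative upstream of the start, positive
    downstream of the end.
    """

    supported: bool
    flanking_trnas: List[Tuple[str, int]] = field(default_factory=list)
    flank_distance: int = DEFAULT_FLANK_DISTANCE

    def to_dict(self) -> dict:
        return {
            "supported": self.supported,
            "flanking_trnas": [list(t) for t in self.flanking_trnas],
            "flank_distance": self.flank_distance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrnaEvidence":
        return cls(
            supported=d["supported"],
            flanking_trnas=[tuple(t) for t in d["flanking_trnas"]],
            flank_distance=d["flank_distance"],
        )


def gc_evidence(
    region: "ProphageRegion",
    genome: "GenomeRecord",
    stats: Optional[GcStats] = None,
    gene_fraction_threshold: float = DEFAULT_GENE_FRACTION,
) -> GcEvidence:
    """Apply the G+C deviation rule to one region.

    A member gene is *deviant* iff its G+C is strictly above mean + SD or
    strictly below mean - SD of the genome's window values.  The region is
    supported iff the deviant fraction is >= the gene-fraction threshold
    (boundary inclusive: "at least 80% of the genes").  Per-gene G+C is
    computed on the gene's genomic span, which is strand-independent.
    """
    if not region.genes:
        raise ValueError(f"region {region.region_id} has no member genes")
    if stats is None:
        stats = windowed_gc_stats(genome)
    lo = stats.mean - stats.sd
    hi = stats.mean + stats.sd
    values = [
        gc_fraction(genome.subsequence(g.start, g.end)) for g in region.genes
    ]
    n_deviant = sum(1 for v in values if v > hi or v < lo)
    frac = n_deviant / len(values)
    return GcEvidence(
        supported=frac >= gene_fraction_threshold,
        gene_gc_values=values,
        deviant_fraction=frac,
        gene_fraction_threshold=gene_fraction_threshold,
        genome_mean=stats.mean,
        genome_sd=stats.sd,
    )


def trna_evidence(
    region: "ProphageRegion",
    genome: "GenomeRecord",
    flank_distance: int = DEFAULT_FLANK_DISTANCE,
) -> TrnaEvidence:
    """Report tRNA genes inside the region or within ``flank_distance`` bp
    of either boundary."""
    found: List[Tuple[str, int]] = []
    for t in genome.trnas():
        if t.end >= region.start and t.start <= region.end:
            found.append((t.feature_id, 0))
        elif t.end < region.start and region.start - t.end <= flank_distance:
            found.append((t.feature_id, -(region.start - t.end)))
        elif t.start > region.end and t.start - region.end <= flank_distance:
            found.append((t.feature_id, t.start - region.end))
    found.sort(key=lambda x: (abs(x[1]), x[0]))
    return TrnaEvidence(
        supported=bool(found),
        flanking_trnas=found,
        flank_distance=flank_distance,
    )
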