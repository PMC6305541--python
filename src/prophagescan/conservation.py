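"""Conservation call: is a candidate region dominated by a single phage?

Each member gene votes for the source phage of its best homology hit.  If a
fraction >= threshold (default 0.80) of the region's genes best-hit one
phage, the region is called *potentially conserved* — suggestive of an
intact prophage rather than a decayed mosaic.  Genes without a surviving
hit stay in the denominator; excluding them would inflate conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .homology import HomologyHit
    from .regions import ProphageRegion

DEFAULT_CONSERVATION_THRESHOLD = 0.80


@dataclass
class ConservationCall:
    best_phage: Optional[str]
    phage_fraction: float
    threshold: float
    conserved: bool
    per_phage_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_phage": self.best_phage,
            "phage_fraction": self.phage_fraction,
            "threshold": self.threshold,
            "conserved": self.conserved,
            "per_phage_counts": dict(self.per_phage_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConservationCall":
        return cls(
            best_phage=d["best_phage"],
            phage_fraction=d["phage_fraction"],
            threshold=d["threshold"],
            conserved=d["conserved"],
            per_phage_counts=dict(d["per_phage_counts"]),
        )


def _best_hit_per_query(hits: Iterable["HomologyHit"]) -> Dict[str, "HomologyHit"]:
    best: Dict[str, "HomologyHit"] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def conservation_call(
    region: "ProphageRegion",
    hits: Iterable["HomologyHit"],
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> ConservationCall:
    """Call a region conserved iff >= ``threshold`` of its genes best-hit a
    single phage.

    ``hits`` should already be filtered to one best hit per CDS; if not,
    the reduction is applied here (highest bitscore, ties by lower e-value
    then lexicographically smallest subject).  Ties for the top phage are
    broken by lexicographically smallest phage_id; all counts are reported.
    """
    if not region.genes:
        raise ValueError(f"region {region.region_id} has no member genes")
    best = _best_hit_per_query(hits)
    counts: Dict[str, int] = {}
    for g in region.genes:
        h = best.get(g.feature_id)
        if h is not None:
            counts[h.phage_id] = counts.get(h.phage_id, 0) + 1
    n = len(region.genes)
    if counts:
        best_phage = min(counts, key=lambda p: (-counts[p], p))
        fraction = counts[best_phage] / n
    else:
        best_phage, fraction = None, 0.0
    return ConservationCall(
        best_phage=best_phage,
        phage_fraction=fraction,
        threshold=threshold,
        conserved=fraction >= threshold,
        per_phage_counts=counts,
    )
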