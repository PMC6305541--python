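"""End-to-end prophage scan: read genome -> filter hits -> cluster ->
regions -> G+C / tRNA evidence -> conservation -> write outputs."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from . import __version__
from .clustering import ClusterParams, cluster_phage_genes, labeling_to_regions
from .conservation import conservation_call
from .errors import ConfigError
from .evidence import gc_evidence, trna_evidence, windowed_gc_stats
from .genome_io import GenomeRecord, read_annotated_genome, write_regions
from .homology import HomologyHit, SearchParams, filter_hits, parse_hits_table
from .regions import ProphageRegion

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the scan, with their documented defaults.

    Precedence when assembled by the CLI: command-line flag > config file >
    built-in default.
    """

    min_identity: float = 80.0
    max_evalue: float = 1e-5
    best_hit_per_query: bool = True
    method: str = "hdbscan"
    min_pts: int = 4
    eps: float = 10_000.0
    gc_window: int = 1000
    gc_step: int = 100
    gc_gene_fraction: float = 0.80
    flank_distance: int = 2000
    conservation_threshold: float = 0.80
    skip_evidence: bool = False
    phage_id_regex: str = r"^([^|]+)"

    _BOOL = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}

    def validate(self) -> None:
        try:
            SearchParams(
                min_identity=self.min_identity,
                max_evalue=self.max_evalue,
                best_hit_per_query=self.best_hit_per_query,
            )
            ClusterParams(method=self.method, min_pts=self.min_pts, eps=self.eps)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.gc_window < 1 or self.gc_step < 1:
            raise ConfigError("gc_window and gc_step must be >= 1")
        if not 0.0 <= self.gc_gene_fraction <= 1.0:
            raise ConfigError(
                f"gc_gene_fraction {self.gc_gene_fraction} outside [0,1]"
            )
        if self.flank_distance < 0:
            raise ConfigError("flank_distance must be >= 0")
        if not 0.0 <= self.conservation_threshold <= 1.0:
            raise ConfigError(
                f"conservation_threshold {self.conservation_threshold} "
                "outside [0,1]"
            )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat key=value config file (# comments allowed)."""
        values: Dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown parameter {key!r}")
            ftype = fields[key].type
            try:
                if ftype == "bool":
                    values[key] = cls._BOOL[raw.lower()]
                elif ftype == "int":
                    values[key] = int(raw)
                elif ftype == "float":
                    values[key] = float(raw)
                else:
                    values[key] = raw
            except (KeyError, ValueError) as exc:
                raise ConfigError(
                    f"{path}:{lineno}: cannot parse {raw!r} for {key}"
                ) from exc
        cfg = cls(**values)  # type: ignore[arg-type]
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    regions: List[ProphageRegion]
    counts: Dict[str, int] = field(default_factory=dict)
    config: Optional[PipelineConfig] = None

    def to_dict(self) -> dict:
        return {
            "regions": [r.to_dict() for r in self.regions],
            "counts": dict(self.counts),
            "config": None
            if self.config is None
            else dataclasses.asdict(self.config),
            "version": __version__,
        }


def run_pipeline(
    genome: Union[GenomeRecord, str, Path],
    hits: Union[List[HomologyHit], str, Path],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full scan and return annotated regions plus stage counts.

    ``genome`` may be a parsed :class:`GenomeRecord` or a GenBank/EMBL
    path; ``hits`` a parsed hit list or a tabular-alignment path.
    Deterministic: identical inputs and config give identical results.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    logger.info("pipeline config: %s", dataclasses.asdict(config))

    if not isinstance(genome, GenomeRecord):
        genome = read_annotated_genome(genome)
    if not isinstance(hits, list):
        hits = parse_hits_table(hits, phage_id_regex=config.phage_id_regex)

    cds = genome.cds()
    counts: Dict[str, int] = {
        "n_cds": len(cds),
        "n_trna": len(genome.trnas()),
        "n_hits_raw": len(hits),
    }
    logger.info("genome %s: %d bp, %d CDS, %d tRNA",
                genome.id, genome.length, counts["n_cds"], counts["n_trna"])

    params = SearchParams(
        min_identity=config.min_identity,
        max_evalue=config.max_evalue,
        best_hit_per_query=config.best_hit_per_query,
    )
    kept = filter_hits(hits, params)
    counts["n_hits_kept"] = len(kept)

    cds_by_id = {g.feature_id: g for g in cds}
    unknown = [h for h in kept if h.query_id not in cds_by_id]
    if unknown:
        logger.warning(
            "%d hits reference query ids absent from the genome; skipped",
            len(unknown),
        )
        kept = [h for h in kept if h.query_id in cds_by_id]
    phage_genes = sorted(
        {h.query_id for h in kept}, key=lambda fid: cds_by_id[fid].start
    )
    genes_with_hits = [cds_by_id[fid] for fid in phage_genes]
    counts["n_genes_with_hits"] = len(genes_with_hits)

    labeling = cluster_phage_genes(
        genes_with_hits,
        ClusterParams(method=config.method, min_pts=config.min_pts,
                      eps=config.eps),
    )
    counts["n_clusters"] = labeling.n_clusters
    regions = labeling_to_regions(labeling, genes_with_hits, genome)
    counts["n_regions"] = len(regions)
    logger.info("%d candidate regions", len(regions))

    if regions and not config.skip_evidence:
        stats = windowed_gc_stats(genome, config.gc_window, config.gc_step)
        for r in regions:
            r.gc_evidence = gc_evidence(
                r, genome, stats, config.gc_gene_fraction
            )
            r.trna_evidence = trna_evidence(r, genome, config.flank_distance)
    for r in regions:
        r.conservation = conservation_call(
            r, kept, config.conservation_threshold
        )
    return PipelineResult(regions=regions, counts=counts, config=config)


def write_result(
    result: PipelineResult, out_prefix, formats=("tsv", "json")
) -> List[Path]:
    """Write the region list under ``out_prefix`` in each requested format."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ext = {"tsv": ".tsv", "gff3": ".gff3", "bed": ".bed", "json": ".json"}
    written = []
    for fmt in formats:
        path = out_prefix.with_suffix(ext[fmt])
        write_regions(result.regions, path, format=fmt)
        written.append(path)
    return written
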