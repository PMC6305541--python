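"""Homology hits against a phage protein collection: parsing, filtering and
(optionally) producing them with an external aligner.

The on-disk format is the de-facto 12-column tabular alignment dialect
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore).  The source-phage identifier is parsed from the subject
id — by default the text before the first ``|`` (the ``PHAGEID|protein``
convention), overridable with a regex whose first capture group is the
phage id.

The pipeline is fully usable without any aligner binary: supply a
precomputed hits table instead.  When an aligner is wanted,
:func:`run_external_search` discovers ``diamond`` or NCBI ``blastp`` on
PATH and logs the exact command line it ran.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

from .errors import AlignerNotFoundError, HitsParseError

logger = logging.getLogger(__name__)

HITS_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore"
).split()

DEFAULT_PHAGE_ID_REGEX = r"^([^|]+)"


@dataclass
class HomologyHit:
    """One CDS-vs-phage-protein alignment row."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    phage_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0,100]"
            )
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not self.phage_id:
            self.phage_id = parse_phage_id(self.subject_id)

    def to_row(self) -> List[str]:
        return [
            self.query_id,
            self.subject_id,
            f"{self.percent_identity:.1f}",
            str(self.align_length),
            str(self.mismatches),
            str(self.gap_opens),
            str(self.qstart),
            str(self.qend),
            str(self.sstart),
            str(self.send),
            f"{self.evalue:.2e}" if self.evalue != 0 else "0.0",
            f"{self.bitscore:.1f}",
        ]


@dataclass
class SearchParams:
    """Filtering parameters for homology hits.

    ``min_identity`` defaults to 80% — the identity cutoff the detection
    method is benchmarked at.  The e-value cutoff is a conventional 1e-5.
    ``best_hit_per_query`` keeps the single highest-bitscore hit per CDS,
    which the conservation call requires (one source phage per gene).
    """

    min_identity: float = 80.0
    max_evalue: float = 1e-5
    best_hit_per_query: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError(
                f"min_identity {self.min_identity} outside [0,100]"
            )
        if self.max_evalue <= 0:
            raise ValueError(f"max_evalue must be positive: {self.max_evalue}")


def parse_phage_id(
    subject_id: str, regex: str = DEFAULT_PHAGE_ID_REGEX
) -> str:
    """Extract the source-phage identifier from a subject id.

    Default rule: text before the first ``|``; if the pattern does not
    match, the whole subject id is used.
    """
    m = re.search(regex, subject_id)
    if m and m.groups() and m.group(1):
        return m.group(1)
    return subject_id


def parse_hits_table(
    source, phage_id_regex: str = DEFAULT_PHAGE_ID_REGEX
) -> List[HomologyHit]:
    """Parse a 12-column tabular alignment file (path) or its text content.

    Lines starting with ``#`` and blank lines are skipped.  Extra trailing
    columns are tolerated (some aligners append them); fewer than 12
    columns or untypeable fields raise :class:`HitsParseError` with the
    offending line number.  An empty file yields an empty list.
    """
    text_like = isinstance(source, str) and ("\n" in source or "\t" in source)
    if isinstance(source, (str, Path)) and not text_like:
        text = Path(source).read_text()
        origin = str(source)
    else:
        text = str(source)
        origin = "<text>"
    hits: List[HomologyHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise HitsParseError(
                f"{origin}:{lineno}: expected >= 12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            hit = HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                align_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                qstart=int(fields[6]),
                qend=int(fields[7]),
                sstart=int(fields[8]),
                send=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                phage_id=parse_phage_id(fields[1], phage_id_regex),
            )
        except (ValueError, IndexError) as exc:
            raise HitsParseError(f"{origin}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits_table(hits: Iterable[HomologyHit], path) -> None:
    """Write hits in the 12-column tabular dialect (parseable back by
    :func:`parse_hits_table`)."""
    lines = ["#" + "\t".join(HITS_COLUMNS)]
    lines += ["\t".join(h.to_row()) for h in hits]
    Path(path).write_text("\n".join(lines) + "\n")


def filter_hits(
    hits: Iterable[HomologyHit], params: Optional[SearchParams] = None
) -> List[HomologyHit]:
    """Apply identity/e-value cutoffs and (optionally) best-hit-per-query.

    Thresholds are boundary-inclusive: identity >= min_identity, evalue <=
    max_evalue.  Best hit per query = highest bitscore, ties broken by
    lower e-value then lexicographically smallest subject id.  Output is
    sorted by query id (then subject id); the operation is idempotent.
    """
    if params is None:
        params = SearchParams()
    kept = [
        h
        for h in hits
        if h.percent_identity >= params.min_identity
        and h.evalue <= params.max_evalue
    ]
    if params.best_hit_per_query:
        best = {}
        for h in kept:
            cur = best.get(h.query_id)
            if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
                -cur.bitscore,
                cur.evalue,
                cur.subject_id,
            ):
                best[h.query_id] = h
        kept = list(best.values())
    kept.sort(key=lambda h: (h.query_id, h.subject_id))
    return kept


def _count_fasta_records(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                n += 1
    return n


def run_external_search(
    proteins, db, params: Optional[SearchParams] = None, out_path=None
) -> Path:
    """Run a protein-vs-protein homology search with an external aligner.

    Tries ``diamond blastp`` first, then NCBI ``blastp`` (building a
    temporary database with ``makeblastdb``).  Writes a 12-column tabular
    file readable by :func:`parse_hits_table` and returns its path.  The
    exact command line is logged.

    Raises :class:`AlignerNotFoundError` when neither executable is on
    PATH — supply a precomputed hits table in that case.
    """
    if params is None:
        params = SearchParams()
    proteins = Path(proteins)
    db = Path(db)
    if _count_fasta_records(db) == 0:
        raise ValueError(f"{db}: phage protein database is empty")
    out_path = (
        Path(out_path)
        if out_path is not None
        else proteins.with_suffix(".hits.tsv")
    )
    if _count_fasta_records(proteins) == 0:
        logger.warning("%s: empty query FASTA; writing empty hits table",
                       proteins)
        out_path.write_text("#" + "\t".join(HITS_COLUMNS) + "\n")
        return out_path

    if shutil.which("diamond"):
        cmd = [
            "diamond", "blastp",
            "--query", str(proteins),
            "--db", str(db),
            "--out", str(out_path),
            "--outfmt", "6",
            "--evalue", str(params.max_evalue),
            "--id", str(params.min_identity),
        ]
        logger.info("running: %s", " ".join(cmd))
        subprocess.run(cmd, check=True, capture_output=True)
        return out_path
    if shutil.which("blastp") and shutil.which("makeblastdb"):
        with tempfile.TemporaryDirectory() as tmp:
            dbdir = Path(tmp) / "phagedb"
            cmd1 = [
                "makeblastdb", "-in", str(db), "-dbtype", "prot",
                "-out", str(dbdir),
            ]
            logger.info("running: %s", " ".join(cmd1))
            subprocess.run(cmd1, check=True, capture_output=True)
            cmd2 = [
                "blastp",
                "-query", str(proteins),
                "-db", str(dbdir),
                "-out", str(out_path),
                "-outfmt", "6",
                "-evalue", str(params.max_evalue),
            ]
            logger.info("running: %s", " ".join(cmd2))
            subprocess.run(cmd2, check=True, capture_output=True)
        return out_path
    raise AlignerNotFoundError(
        "no protein aligner found on PATH (tried diamond, blastp); "
        "supply a precomputed hits table instead (--hits)"
    )
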