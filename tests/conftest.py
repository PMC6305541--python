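"""Shared fixtures: hand-written flat-file snippets and small synthetic
datasets (generated programmatically, never stored)."""

from __future__ import annotations

import pytest

from prophagescan import SyntheticSpec, simulate


def format_genbank(name: str, seq: str, feature_lines: list[str]) -> str:
    """Assemble a minimal but valid GenBank flat file."""
    lines = [
        f"LOCUS       {name:<17}{len(seq):>11} bp    DNA     linear   UNK 01-JAN-2000",
        f"DEFINITION  test record {name}.",
        f"ACCESSION   {name}",
        "FEATURES             Location/Qualifiers",
    ]
    lines += feature_lines
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def minimal_genbank(tmp_path):
    """One CDS (1..30, +) and one tRNA (100..175) on a 200 bp record."""
    seq = ("ATGGCCAAATTTGGGCCCAAATTTGGGTAA" + "ACGT" * 43)[:200]
    text = format_genbank(
        "TEST01",
        seq,
        [
            "     CDS             1..30",
            '                     /locus_tag="cds_0001"',
            '                     /product="test protein"',
            "     tRNA            100..175",
            '                     /locus_tag="trna_0001"',
            '                     /product="tRNA-Met"',
        ],
    )
    path = tmp_path / "mini.gbk"
    path.write_text(text)
    return path, seq


@pytest.fixture
def minimal_genbank_complement(tmp_path):
    """Same record with the CDS on the reverse strand."""
    seq = ("ATGGCCAAATTTGGGCCCAAATTTGGGTAA" + "ACGT" * 43)[:200]
    text = format_genbank(
        "TEST02",
        seq,
        [
            "     CDS             complement(1..30)",
            '                     /locus_tag="cds_0001"',
            "     tRNA            100..175",
            '                     /locus_tag="trna_0001"',
        ],
    )
    path = tmp_path / "mini_rc.gbk"
    path.write_text(text)
    return path, seq


@pytest.fixture(scope="session")
def small_spec():
    """A 60 kb genome with two well-separated cassettes; fast to simulate."""
    return SyntheticSpec(
        genome_length=60_000,
        n_prophages=2,
        prophage_length=(8_000, 12_000),
        genes_per_prophage=(6, 10),
        trna_flank_probability=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate(small_spec)
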