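"""Shared fixtures: programmatically generated GenBank text and small
synthetic objects. No stored data files; everything is built at test time."""

from __future__ import annotations

import textwrap

import pytest

from ptmbgc.genome_io import Gene, Genome


def _genbank_record(
    locus: str,
    seq: str,
    features: list[tuple[int, int, str, dict]],
) -> str:
    """Minimal GenBank flat-file text for one contig.

    ``features``: (start_1based, end_1based, strand, qualifiers) per CDS.
    """
    lines = [
        f"LOCUS       {locus:<16} {len(seq):>11} bp    DNA     linear   BCT 01-JAN-2017",
        f"DEFINITION  synthetic test contig {locus}.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    for start, end, strand, quals in features:
        loc = f"{start}..{end}" if strand == "+" else f"complement({start}..{end})"
        lines.append(f"     CDS             {loc}")
        for key, value in quals.items():
            wrapped = textwrap.wrap(
                f'/{key}="{value}"', width=58, break_long_words=True
            )
            for w in wrapped:
                lines.append(" " * 21 + w)
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i+1:>9} {groups}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def make_genbank(tmp_path):
    """Factory writing GenBank text to a temp file; returns the path."""

    def _make(locus, seq, features, filename=None):
        path = tmp_path / (filename or f"{locus}.gbk")
        path.write_text(_genbank_record(locus, seq, features))
        return path

    return _make


@pytest.fixture
def three_cds_genbank(make_genbank):
    """One contig, three plus-strand CDS with translation qualifiers."""
    seq = "ATG" + "A" * 297
    return make_genbank(
        "ctg1",
        seq,
        [
            (1, 30, "+", {"locus_tag": "g1", "translation": "MKVLWAALLV", "product": "alpha"}),
            (61, 90, "+", {"locus_tag": "g2", "translation": "MNPQRSTVWY", "product": "beta"}),
            (121, 150, "+", {"locus_tag": "g3", "translation": "MACDEFGHIK", "product": "gamma"}),
        ],
    )


def make_gene(gene_id: str, protein: str, index: int = 0, contig: str = "c1") -> Gene:
    """A gene with synthetic non-overlapping coordinates."""
    start = 1000 * index + 10
    return Gene(
        gene_id=gene_id,
        contig_id=contig,
        start=start,
        end=start + 3 * (len(protein) + 1),
        strand="+",
        protein=protein,
        product="",
    )


def make_genome(proteins: dict[str, str], genome_id: str = "g") -> Genome:
    """A one-contig genome from {gene_id: protein}."""
    genes = [
        make_gene(gid, prot, i, f"{genome_id}_c1")
        for i, (gid, prot) in enumerate(proteins.items())
    ]
    total = max(g.end for g in genes) + 100 if genes else 0
    return Genome(
        genome_id=genome_id,
        contigs={f"{genome_id}_c1": genes},
        total_length_bp=total,
    )
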