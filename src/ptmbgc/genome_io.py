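"""Reading and writing annotated bacterial genomes.

The pipeline treats a genome as an ordered, stranded list of protein-coding
genes per contig: neighborhood extraction around an anchor gene works in units
of gene index, so gene order (not nucleotide coordinates) is the primary
structure. GenBank flat files are the input format; protein FASTA and a flat
gene table are the outputs consumed by downstream stages.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
positions are converted on read. CDS features lacking a ``translation``
qualifier are translated from the nucleotide span with the bacterial genetic
code (NCBI table 11); internal stops are kept as ``X`` so pseudogenes still
occupy a neighborhood slot.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, FeatureLocation
from Bio.SeqRecord import SeqRecord


class GenomeParseError(ValueError):
    """Raised when a GenBank record or CDS feature cannot be interpreted."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    contig; ``protein`` is the amino-acid sequence without a trailing stop.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class Genome:
    """Ordered gene lists per contig, plus the total assembly length in bp."""

    genome_id: str
    taxon_label: str = ""
    contigs: Dict[str, List[Gene]] = field(default_factory=dict)
    total_length_bp: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig_id, genes in self.contigs.items():
            starts = [g.start for g in genes]
            if starts != sorted(starts):
                raise ValueError(
                    f"genome {self.genome_id}: contig {contig_id} genes not "
                    "sorted by start"
                )
            for g in genes:
                if g.gene_id in seen:
                    raise ValueError(
                        f"genome {self.genome_id}: duplicate gene_id {g.gene_id}"
                    )
                seen.add(g.gene_id)

    def genes(self) -> Iterator[Gene]:
        """All genes in genomic order (contig insertion order, then start)."""
        for contig_genes in self.contigs.values():
            yield from contig_genes

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())

    @property
    def length_mbp(self) -> float:
        return self.total_length_bp / 1e6

    def gene_index(self, gene: Gene) -> int:
        """Index of ``gene`` within its contig's ordered gene list."""
        try:
            return self.contigs[gene.contig_id].index(gene)
        except (KeyError, ValueError) as exc:
            raise KeyError(
                f"gene {gene.gene_id} not found in genome {self.genome_id}"
            ) from exc


def _translate_cds(feature: SeqFeature, record: SeqRecord, contig_id: str) -> str:
    """Translate a CDS from its (possibly compound) nucleotide span.

    Uses the bacterial code (table 11); trailing stop removed, internal stops
    become 'X'.
    """
    try:
        nt = feature.extract(record.seq)
    except Exception as exc:  # pragma: no cover - biopython internals
        raise GenomeParseError(
            f"contig {contig_id}: cannot extract CDS at {feature.location}: {exc}"
        ) from exc
    if len(nt) == 0 or str(nt).upper().strip("N") == "":
        raise GenomeParseError(
            f"contig {contig_id}: CDS at {feature.location} has no translation "
            "qualifier and no usable nucleotide sequence"
        )
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X")


def parse_genbank(path: str | Path, genome_id: str | None = None) -> Genome:
    """Parse a GenBank flat file into a :class:`Genome`.

    One :class:`Gene` is produced per CDS feature, ordered by start within
    each contig. ``total_length_bp`` is the sum of contig sequence lengths.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    contigs: Dict[str, List[Gene]] = {}
    total = 0
    taxon = ""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise GenomeParseError(f"{path}: malformed GenBank record: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no GenBank records found")
    for record in records:
        contig_id = record.id or record.name
        total += len(record.seq)
        if not taxon:
            taxon = record.annotations.get("organism", "") or ""
        genes: List[Gene] = []
        counter = 0
        seen_ids = set()
        for feature in record.features:
            if feature.type != "CDS":
                continue
            counter += 1
            quals = feature.qualifiers
            gid = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{contig_id}_cds{counter}"
            )
            if gid in seen_ids:
                gid = f"{gid}.{counter}"
            seen_ids.add(gid)
            translation = quals.get("translation", [None])[0]
            if translation:
                protein = translation.replace("*", "X")
            else:
                protein = _translate_cds(feature, record, contig_id)
            if not protein:
                raise GenomeParseError(
                    f"contig {contig_id}: CDS {gid} yields an empty protein"
                )
            loc = feature.location
            genes.append(
                Gene(
                    gene_id=gid,
                    contig_id=contig_id,
                    start=int(loc.start),
                    end=int(loc.end),
                    strand="-" if loc.strand == -1 else "+",
                    protein=protein,
                    product=quals.get("product", [""])[0],
                )
            )
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        contigs[contig_id] = genes
    return Genome(
        genome_id=genome_id,
        taxon_label=taxon,
        contigs=contigs,
        total_length_bp=total,
    )


def write_protein_fasta(genome: Genome, path: str | Path) -> int:
    """Write one FASTA record per gene; returns the record count.

    Headers are ``genome_id|contig_id|gene_id``.
    """
    count = 0
    with open(path, "w") as fh:
        for gene in genome.genes():
            fh.write(f">{genome.genome_id}|{gene.contig_id}|{gene.gene_id}\n")
            seq = gene.protein
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            count += 1
    return count


GENE_TABLE_COLUMNS = (
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
)


def write_gene_table(genome: Genome, path: str | Path) -> int:
    """Write the per-gene TSV; returns the number of data rows.

    Tab characters inside the free-text product field are replaced by spaces
    so the table stays a valid TSV.
    """
    rows = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for gene in genome.genes():
            writer.writerow(
                [
                    genome.genome_id,
                    gene.contig_id,
                    gene.gene_id,
                    gene.start,
                    gene.end,
                    gene.strand,
                    gene.product.replace("\t", " "),
                ]
            )
            rows += 1
    return rows


def write_genbank(genome: Genome, path: str | Path, contig_seqs: Dict[str, str] | None = None) -> None:
    """Write a genome back to GenBank (1-based inclusive on disk).

    ``contig_seqs`` supplies nucleotide sequences per contig; absent contigs
    get an undefined 'N' placeholder of the right span so coordinates and
    translations survive a round trip.
    """
    records = []
    for contig_id, genes in genome.contigs.items():
        span = max((g.end for g in genes), default=0)
        if contig_seqs and contig_id in contig_seqs:
            seq = Seq(contig_seqs[contig_id])
        else:
            seq = Seq("N" * span)
        record = SeqRecord(seq, id=contig_id, name=contig_id[:16], description="")
        record.annotations["molecule_type"] = "DNA"
        if genome.taxon_label:
            record.annotations["organism"] = genome.taxon_label
        for gene in genes:
            feature = SeqFeature(
                FeatureLocation(gene.start, gene.end, strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [gene.gene_id],
                    "product": [gene.product],
                    "translation": [gene.protein],
                    "transl_table": ["11"],
                },
            )
            record.features.append(feature)
        records.append(record)
    SeqIO.write(records, str(path), "genbank")
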