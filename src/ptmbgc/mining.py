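"""Anchored-synteny mining of orthologous PTM BGCs.

The procedure mirrors CORASON-style core analysis around a reference
cluster: (1) find anchor genes — homologs of the reference cluster's
ikaB-like anchor — by local-alignment search with an E-value and bit-score
cutoff; (2) extract the gene neighborhood of a fixed radius (15 genes
upstream and downstream by default) around each anchor; (3) map synteny as
bidirectional best hits between the reference cluster and the neighborhood;
(4) call the neighborhood an orthologous BGC when it shares at least
``min_syntenic`` homologs with E-values below the synteny cutoff.

"Syntenic homolog" here means a BBH between a reference gene and a window
gene; gene order and strand are not required (the most permissive reading —
an optional colinearity column is reported but never filters). The anchor's
own hit counts toward the threshold; exclude it by raising ``min_syntenic``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_io import Gene, Genome
from .homology import (
    HomologyHit,
    ScoringScheme,
    bidirectional_best_hits,
    bits_and_evalue,
    local_score,
)


@dataclass(frozen=True)
class MiningConfig:
    """All mining thresholds; defaults follow the original CORASON-style mining protocol."""

    anchor_max_e: float = 1e-6
    anchor_min_bits: float = 1000.0
    window_radius: int = 15
    synteny_max_e: float = 1e-6
    min_syntenic: int = 3
    marker_max_e: float = 1e-8
    ikaA_min_bits: float = 4000.0
    rpoB_min_bits: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "anchor_max_e",
            "anchor_min_bits",
            "synteny_max_e",
            "marker_max_e",
            "ikaA_min_bits",
            "rpoB_min_bits",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")
        if self.min_syntenic < 1:
            raise ValueError("min_syntenic must be >= 1")


@dataclass(frozen=True)
class ReferenceGene:
    gene_id: str
    role: str  # 'anchor', 'pks_nrps', or an enzyme-family label
    protein: str

    def as_gene(self) -> Gene:
        return Gene(
            gene_id=self.gene_id,
            contig_id="ref",
            start=0,
            end=3 * len(self.protein),
            strand="+",
            protein=self.protein,
            product=self.role,
        )


@dataclass
class ReferenceBGC:
    """The ordered reference cluster (ikarugamycin-BGC-like query)."""

    bgc_id: str
    genes: List[ReferenceGene]

    def __post_init__(self) -> None:
        anchors = [g for g in self.genes if g.role == "anchor"]
        if len(anchors) != 1:
            raise ValueError("reference BGC must have exactly one anchor gene")
        if len(self.genes) < 3:
            raise ValueError("reference BGC must have >= 3 genes")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("reference gene ids must be unique")

    @property
    def anchor(self) -> ReferenceGene:
        return next(g for g in self.genes if g.role == "anchor")

    def as_genes(self) -> List[Gene]:
        # dummy non-overlapping coordinates; only order and protein matter
        out = []
        pos = 0
        for g in self.genes:
            span = 3 * len(g.protein)
            out.append(
                Gene(
                    gene_id=g.gene_id,
                    contig_id="ref",
                    start=pos,
                    end=pos + span,
                    strand="+",
                    protein=g.protein,
                    product=g.role,
                )
            )
            pos += span + 1
        return out


@dataclass
class Neighborhood:
    genome_id: str
    contig_id: str
    anchor: Gene
    members: List[Gene]
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.anchor.gene_id not in {g.gene_id for g in self.members}:
            raise ValueError("anchor must be among neighborhood members")


@dataclass(frozen=True)
class SyntenyPair:
    ref_gene_id: str
    member_gene_id: str
    hit: HomologyHit
    qualifying: bool
    colinear: Optional[bool] = None  # reported, never used as a filter


@dataclass
class BgcCall:
    neighborhood: Neighborhood
    pairs: List[SyntenyPair] = field(default_factory=list)

    @property
    def qualifying_count(self) -> int:
        return sum(1 for p in self.pairs if p.qualifying)

    @property
    def status(self) -> str:
        return "orthologous" if self._orthologous else "rejected"

    @property
    def call_id(self) -> str:
        nb = self.neighborhood
        return f"{nb.genome_id}:{nb.contig_id}:{nb.anchor.gene_id}"

    def __post_init__(self) -> None:
        self._min_syntenic = MiningConfig().min_syntenic

    @property
    def _orthologous(self) -> bool:
        return self.qualifying_count >= self._min_syntenic


def find_anchor_genes(
    genome: Genome,
    ref: ReferenceBGC,
    cfg: MiningConfig = MiningConfig(),
    scheme: ScoringScheme = ScoringScheme(),
) -> List[Gene]:
    """Genes whose hit to the reference anchor passes both anchor cutoffs.

    Returned in genomic order; each seeds its own neighborhood.
    """
    query = ref.anchor.protein
    m = len(query)
    n = sum(len(g.protein) for g in genome.genes())
    if n == 0:
        return []
    anchors = []
    for gene in genome.genes():
        raw = local_score(query, gene.protein, scheme)
        bits, e_value = bits_and_evalue(raw, scheme, m, n)
        if e_value <= cfg.anchor_max_e and bits >= cfg.anchor_min_bits:
            anchors.append(gene)
    return anchors


def extract_neighborhood(genome: Genome, anchor: Gene, radius: int) -> Neighborhood:
    """The ``radius`` genes on each side of the anchor by gene index.

    Truncated at contig ends (flagged); strand is ignored for membership.
    """
    idx = genome.gene_index(anchor)  # raises if anchor not in genome
    contig_genes = genome.contigs[anchor.contig_id]
    lo = max(0, idx - radius)
    hi = min(len(contig_genes), idx + radius + 1)
    truncated = (idx - radius < 0) or (idx + radius + 1 > len(contig_genes))
    return Neighborhood(
        genome_id=genome.genome_id,
        contig_id=anchor.contig_id,
        anchor=anchor,
        members=list(contig_genes[lo:hi]),
        truncated=truncated,
    )


#: loose E-value ceiling for listing BBH pairs; the strict synteny cutoff
#: only decides which pairs qualify.
_BBH_LIST_MAX_E = 10.0


def map_synteny(
    nb: Neighborhood,
    ref: ReferenceBGC,
    scheme: ScoringScheme = ScoringScheme(),
    cfg: MiningConfig = MiningConfig(),
) -> List[SyntenyPair]:
    """BBH pairs between reference genes and neighborhood genes.

    Every mutual best hit is listed; a pair qualifies when its E-value is
    strictly below ``cfg.synteny_max_e``. The colinearity column records
    whether the pair order along the window matches the reference order.
    """
    if not nb.members:
        raise ValueError("neighborhood has no members")
    ref_genes = ref.as_genes()
    pairs = bidirectional_best_hits(ref_genes, nb.members, scheme, max_e=_BBH_LIST_MAX_E)
    ref_order = {g.gene_id: i for i, g in enumerate(ref_genes)}
    member_order = {g.gene_id: i for i, g in enumerate(nb.members)}
    raw_pairs = sorted(pairs, key=lambda p: ref_order[p[0]])
    member_ranks = [member_order[b] for _, b, _ in raw_pairs]
    colinear_all = member_ranks == sorted(member_ranks) or member_ranks == sorted(
        member_ranks, reverse=True
    )
    out = []
    for a_id, b_id, hit in raw_pairs:
        out.append(
            SyntenyPair(
                ref_gene_id=a_id,
                member_gene_id=b_id,
                hit=hit,
                qualifying=hit.e_value < cfg.synteny_max_e,
                colinear=colinear_all,
            )
        )
    return out


def call_orthologous_bgc(
    nb: Neighborhood,
    pairs: Sequence[SyntenyPair],
    cfg: MiningConfig = MiningConfig(),
) -> BgcCall:
    """Orthologous iff at least ``cfg.min_syntenic`` qualifying pairs.

    All pairs are retained on the call either way.
    """
    call = BgcCall(neighborhood=nb, pairs=list(pairs))
    call._min_syntenic = cfg.min_syntenic
    return call


def mine_genomes(
    genomes: Sequence[Genome],
    ref: ReferenceBGC,
    scheme: ScoringScheme = ScoringScheme(),
    cfg: MiningConfig = MiningConfig(),
) -> List[BgcCall]:
    """Run the full anchored-synteny procedure over a set of genomes.

    Every anchor in every genome seeds one independently evaluated
    neighborhood; output order is deterministic (genome, contig, anchor
    index).
    """
    if not genomes:
        raise ValueError("at least one genome required")
    calls: List[BgcCall] = []
    for genome in genomes:
        for anchor in find_anchor_genes(genome, ref, cfg, scheme):
            nb = extract_neighborhood(genome, anchor, cfg.window_radius)
            pairs = map_synteny(nb, ref, scheme, cfg)
            calls.append(call_orthologous_bgc(nb, pairs, cfg))
    return calls


def group_overlapping_calls(calls: Sequence[BgcCall]) -> List[List[BgcCall]]:
    """Group calls that share at least one neighborhood gene (for reporting).

    Calls from duplicated anchors on one contig may cover overlapping
    windows; each is still called independently.
    """
    groups: List[List[BgcCall]] = []
    gene_sets: List[set] = []
    for call in calls:
        ids = {
            (call.neighborhood.genome_id, g.gene_id)
            for g in call.neighborhood.members
        }
        for i, seen in enumerate(gene_sets):
            if seen & ids:
                groups[i].append(call)
                gene_sets[i] |= ids
                break
        else:
            groups.append([call])
            gene_sets.append(ids)
    return groups


def write_call_table(calls: Sequence[BgcCall], path) -> int:
    """BGC-call TSV: one row per evaluated neighborhood."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcontig_id\tanchor_gene\twindow_start\twindow_end\t"
            "n_members\ttruncated\tqualifying_count\tstatus\tcolinear\n"
        )
        for call in calls:
            nb = call.neighborhood
            colinear = all(p.colinear for p in call.pairs) if call.pairs else False
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        nb.genome_id,
                        nb.contig_id,
                        nb.anchor.gene_id,
                        nb.members[0].start,
                        nb.members[-1].end,
                        len(nb.members),
                        int(nb.truncated),
                        call.qualifying_count,
                        call.status,
                        int(colinear),
                    )
                )
                + "\n"
            )
            n += 1
    return n


def call_to_json(call: BgcCall) -> dict:
    """Full synteny map of one call as a JSON-serializable dict."""
    nb = call.neighborhood
    return {
        "call_id": call.call_id,
        "genome_id": nb.genome_id,
        "contig_id": nb.contig_id,
        "anchor": nb.anchor.gene_id,
        "members": [g.gene_id for g in nb.members],
        "truncated": nb.truncated,
        "status": call.status,
        "qualifying_count": call.qualifying_count,
        "pairs": [
            {
                "ref_gene": p.ref_gene_id,
                "member_gene": p.member_gene_id,
                "e_value": p.hit.e_value,
                "bit_score": p.hit.bit_score,
                "percent_identity": p.hit.percent_identity,
                "qualifying": p.qualifying,
                "colinear": p.colinear,
            }
            for p in call.pairs
        ],
    }


def write_call_json(calls: Sequence[BgcCall], path) -> None:
    with open(path, "w") as fh:
        json.dump([call_to_json(c) for c in calls], fh, indent=2)
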