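"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the study system: a clade of host-associated
*Streptomyces*-like taxa diverging along a Yule tree, each carrying a PTM
BGC embedded in a decoy proteome, with scripted per-branch gain/loss/
duplication of the 7 enzyme families, an rpoB-like housekeeping marker
evolving along the same tree, and noisy negative-mode [M-H]- ion lists for
the bundled PTM compounds.

Family exemplars are synthetic proteins drawn once from a fixed internal
seed, so the bundled reference set is stable across runs; user-facing
randomness (trees, divergence, decoys, ion noise) flows from the single
``SimConfig.seed``. Decoys are uniform-random proteins, which makes their
chance of passing E <= 1e-6 against any reference negligible and
false-positive accounting clean.

Exemplar dimensions are chosen so the protocol's bit-score thresholds are exercisable:
the ikaA-like PKS/NRPS is ~3000 aa (reachable bit score 4000), the
ikaB-like anchor ~800 aa (reachable bit score 1000), the rpoB-like marker
~1200 aa. The three dehydrogenase exemplars descend from a common ancestor
(DH3 from a recent duplication on the DH2 side), mirroring the
super-family's history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .chemotype import CompoundRecord, bundled_compounds
from .families import EnzymeFamily, FamilyReferenceSet, ReferenceProtein
from .genome_io import Gene, Genome, write_genbank
from .homology import AA_ALPHABET
from .mining import ReferenceBGC, ReferenceGene

#: internal seed for the bundled exemplar proteins (not a user knob)
_EXEMPLAR_SEED = 20170424

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_protein(rng: RngLike, length: int) -> str:
    rng = _rng(rng)
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


@lru_cache(maxsize=1)
def _blosum_conditional() -> Dict[str, Tuple[str, np.ndarray]]:
    """P(replacement | original) proportional to 2**(S/2), identity excluded."""
    from .homology import _matrix

    mat = _matrix("BLOSUM62")
    table = {}
    for a in AA_ALPHABET:
        others = [b for b in AA_ALPHABET if b != a]
        weights = np.array([2.0 ** (mat[a, b] / 2.0) for b in others])
        table[a] = ("".join(others), weights / weights.sum())
    return table


def evolve_protein(
    seq: str, branch_length: float, rate: float, seed: RngLike
) -> str:
    """Evolve a protein along a branch by point substitution.

    The substitution count is Poisson(len * rate * branch_length);
    positions are uniform (with replacement, so a site can be hit twice);
    replacements are drawn from the BLOSUM62-conditional distribution
    excluding the identity.
    """
    if not seq:
        raise ValueError("cannot evolve an empty sequence")
    if rate < 0 or branch_length < 0:
        raise ValueError("rate and branch length must be >= 0")
    rng = _rng(seed)
    n_sub = rng.poisson(len(seq) * rate * branch_length)
    if n_sub == 0:
        return seq
    table = _blosum_conditional()
    chars = list(seq)
    positions = rng.integers(0, len(seq), size=n_sub)
    for pos in positions:
        current = chars[pos]
        if current not in table:  # X etc.: leave untouched
            continue
        others, probs = table[current]
        chars[pos] = others[rng.choice(len(others), p=probs)]
    return "".join(chars)


def diverge(seq: str, divergence: float, seed: RngLike) -> str:
    """Evolve with expected ``divergence`` substitutions per site."""
    return evolve_protein(seq, 1.0, divergence, seed)


# --- bundled exemplars -----------------------------------------------------


@lru_cache(maxsize=1)
def _exemplar_proteins() -> Dict[str, str]:
    rng = np.random.default_rng(_EXEMPLAR_SEED)
    ikaA = random_protein(rng, 3000)
    sd = random_protein(rng, 300)
    cyp = random_protein(rng, 400)
    oxr = random_protein(rng, 350)
    # 0.45 per side keeps DH1-DH2 similarity well below the anchor bit-score
    # threshold while leaving homologs of either subfamily easily detectable
    dh_ancestor = random_protein(rng, 800)
    dh1 = diverge(dh_ancestor, 0.45, rng)
    dh2 = diverge(dh_ancestor, 0.45, rng)
    dh3 = diverge(dh2, 0.18, rng)  # recent duplication on the DH2 side
    rpoB = random_protein(rng, 1200)
    return {
        "PKS_NRPS": ikaA,
        "SD": sd,
        "CYP450": cyp,
        "OXR": oxr,
        "DH1": dh1,
        "DH2": dh2,
        "DH3": dh3,
        "rpoB": rpoB,
    }


def make_family_references() -> FamilyReferenceSet:
    """The bundled synthetic exemplar per enzyme family."""
    ex = _exemplar_proteins()
    return FamilyReferenceSet(
        [
            ReferenceProtein(f"ref_{fam.value}", fam, ex[fam.value])
            for fam in EnzymeFamily
        ]
    )


def marker_reference(marker: str) -> str:
    """Reference protein for marker extraction (rpoB-like or ikaA-like)."""
    ex = _exemplar_proteins()
    if marker == "rpoB":
        return ex["rpoB"]
    if marker == "ikaA":
        return ex["PKS_NRPS"]
    raise ValueError(f"unknown marker: {marker!r}")


def make_reference_bgc() -> ReferenceBGC:
    """The template/query cluster (ikarugamycin-BGC-like).

    The ikaB-like anchor is the DH1 exemplar (the universally conserved
    dehydrogenase); the template content matches the cone-snail-type BGC:
    PKS/NRPS, SD, CYP450, OxR, DH1, DH2 (no DH3).
    """
    ex = _exemplar_proteins()
    return ReferenceBGC(
        bgc_id="ptm_template",
        genes=[
            ReferenceGene("ref_sd", "SD", ex["SD"]),
            ReferenceGene("ref_cyp450", "CYP450", ex["CYP450"]),
            ReferenceGene("ref_ikaA", "PKS_NRPS", ex["PKS_NRPS"]),
            ReferenceGene("ref_ikaB", "anchor", ex["DH1"]),
            ReferenceGene("ref_dh2", "DH2", ex["DH2"]),
            ReferenceGene("ref_oxr", "OXR", ex["OXR"]),
        ],
    )


#: enzyme family of each template gene (the anchor is DH1-like)
TEMPLATE_FAMILIES: Dict[str, EnzymeFamily] = {
    "ref_sd": EnzymeFamily.SD,
    "ref_cyp450": EnzymeFamily.CYP450,
    "ref_ikaA": EnzymeFamily.PKS_NRPS,
    "ref_ikaB": EnzymeFamily.DH1,
    "ref_dh2": EnzymeFamily.DH2,
    "ref_oxr": EnzymeFamily.OXR,
}


# --- trees -----------------------------------------------------------------


def simulate_tree(n_taxa: int, seed: RngLike) -> dendropy.Tree:
    """A rooted binary Yule tree with n_taxa leaves, labels t1..tn.

    Internal nodes are labeled n1..n(n-1) in preorder; branch lengths are
    in expected-substitution time units (unit birth rate). Deterministic
    per seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = _rng(seed)
    # each entry: [birth_time, left, right] ; leaves have children None
    nodes: List[List] = [[0.0, 1, 2], [0.0, None, None], [0.0, None, None]]
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active[idx]
        left, right = len(nodes), len(nodes) + 1
        nodes.append([t, None, None])
        nodes.append([t, None, None])
        nodes[parent][1] = left
        nodes[parent][2] = right
        active[idx] = left
        active.append(right)
    t_end = t + rng.exponential(1.0 / n_taxa)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaf_counter = [0]
    internal_counter = [0]

    def build(i: int) -> dendropy.Node:
        node = dendropy.Node()
        birth, left, right = nodes[i]
        if left is None:
            leaf_counter[0] += 1
            node.taxon = taxa.new_taxon(f"t{leaf_counter[0]}")
            node.edge.length = t_end - birth
        else:
            internal_counter[0] += 1
            node.label = f"n{internal_counter[0]}"
            child_birth = nodes[left][0]
            node.edge.length = child_birth - birth
            node.add_child(build(left))
            node.add_child(build(right))
        return node

    tree.seed_node = build(0)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def branch_ids(tree: dendropy.Tree) -> List[str]:
    """Valid EventScript branch ids: every non-root node's id."""
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        out.append(node.taxon.label if node.is_leaf() else node.label)
    return out


# --- scripted BGC evolution ------------------------------------------------


@dataclass(frozen=True)
class ScriptEvent:
    branch_id: str
    family: EnzymeFamily
    kind: str  # gain | loss | duplicate

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss", "duplicate"):
            raise ValueError(f"unknown event kind: {self.kind!r}")


@dataclass
class EventScript:
    events: List[ScriptEvent] = field(default_factory=list)


@dataclass(frozen=True)
class SimGene:
    label: str
    family: EnzymeFamily
    protein: str


@dataclass
class BgcSimResult:
    """Per-leaf simulated BGC gene sets plus the generating truth."""

    leaf_genes: Dict[str, List[SimGene]]
    leaf_content: Dict[str, List[str]]  # family labels present per leaf
    applied_events: List[Dict[str, str]]  # branch, family, kind(R/L), via
    tree_newick: str


def synthesize_bgc_variants(
    tree: dendropy.Tree,
    template: ReferenceBGC,
    script: EventScript,
    rate: float,
    seed: RngLike,
) -> BgcSimResult:
    """Evolve the template BGC down the tree under a scripted event series.

    Gains insert a fresh (lightly diverged) family exemplar; losses remove
    every gene of the family (error if the family is absent on that
    lineage); a duplication of DH2 models the documented DH2 -> DH3
    expansion (the copy classifies as DH3); duplications of other families
    add a paralog of the same family. Events apply at the top of the
    named branch, before divergence along it.
    """
    from .phylogeny import write_newick

    rng = _rng(seed)
    valid_branches = set(branch_ids(tree))
    for ev in script.events:
        if ev.branch_id not in valid_branches:
            raise ValueError(f"script references unknown branch: {ev.branch_id!r}")
    by_branch: Dict[str, List[ScriptEvent]] = {}
    for ev in script.events:
        by_branch.setdefault(ev.branch_id, []).append(ev)

    refs = {r.family: r.protein for r in make_family_references().references}
    root_genes = [
        SimGene(g.gene_id, TEMPLATE_FAMILIES[g.gene_id], g.protein)
        for g in template.genes
    ]
    leaf_genes: Dict[str, List[SimGene]] = {}
    applied: List[Dict[str, str]] = []

    def node_id(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def walk(node: dendropy.Node, genes: List[SimGene]) -> None:
        nid = node_id(node)
        if node.parent_node is not None:
            for ev in by_branch.get(nid, []):
                fams_here = {g.family for g in genes}
                if ev.kind == "gain":
                    new = SimGene(
                        f"gain_{ev.family.value}_{nid}",
                        ev.family,
                        diverge(refs[ev.family], 0.05, rng),
                    )
                    genes = genes + [new]
                    applied.append(
                        {"branch": nid, "family": ev.family.value, "kind": "R",
                         "via": "gain"}
                    )
                elif ev.kind == "loss":
                    if ev.family not in fams_here:
                        raise ValueError(
                            f"scripted loss of absent family {ev.family.value} "
                            f"on branch {nid}"
                        )
                    genes = [g for g in genes if g.family is not ev.family]
                    applied.append(
                        {"branch": nid, "family": ev.family.value, "kind": "L",
                         "via": "loss"}
                    )
                else:  # duplicate
                    if ev.family not in fams_here:
                        raise ValueError(
                            f"scripted duplication of absent family "
                            f"{ev.family.value} on branch {nid}"
                        )
                    if ev.family is EnzymeFamily.DH2:
                        new_family = EnzymeFamily.DH3
                        source = refs[EnzymeFamily.DH3]
                    else:
                        new_family = ev.family
                        source = next(
                            g.protein for g in genes if g.family is ev.family
                        )
                    new = SimGene(
                        f"dup_{new_family.value}_{nid}",
                        new_family,
                        diverge(source, 0.05, rng),
                    )
                    genes = genes + [new]
                    if new_family is not ev.family:
                        applied.append(
                            {"branch": nid, "family": new_family.value,
                             "kind": "R", "via": "duplicate"}
                        )
            bl = node.edge.length or 0.0
            genes = [
                SimGene(g.label, g.family, evolve_protein(g.protein, bl, rate, rng))
                for g in genes
            ]
        if node.is_leaf():
            leaf_genes[nid] = genes
        for child in node.child_nodes():
            walk(child, genes)

    walk(tree.seed_node, root_genes)
    content = {
        leaf: sorted({g.family.value for g in genes})
        for leaf, genes in leaf_genes.items()
    }
    return BgcSimResult(
        leaf_genes=leaf_genes,
        leaf_content=content,
        applied_events=applied,
        tree_newick=write_newick(tree),
    )


# --- genome assembly -------------------------------------------------------


def assemble_genome(
    bgc_genes: Sequence[SimGene],
    n_decoys: int,
    insertion_index: int,
    seed: RngLike,
    genome_id: str = "sim",
    extra_genes: Sequence[Tuple[str, str, str]] = (),
    genome_length_bp: Optional[int] = None,
    path=None,
) -> Genome:
    """A one-contig genome: random decoys with the BGC inserted contiguously.

    Decoy proteins are uniform-random, 150-450 aa, on random strands with
    non-overlapping coordinates. ``extra_genes`` are (gene_id, protein,
    product) tuples appended after the last decoy (used for housekeeping
    markers). When ``path`` is given a GenBank file with translations is
    written there.
    """
    if not (0 <= insertion_index <= n_decoys):
        raise ValueError(
            f"insertion_index must be in [0, {n_decoys}], got {insertion_index}"
        )
    rng = _rng(seed)
    entries: List[Tuple[str, str, str, str]] = []  # id, protein, product, strand
    for i in range(n_decoys):
        length = int(rng.integers(150, 451))
        strand = "+" if rng.integers(2) else "-"
        entries.append(
            (f"{genome_id}_decoy{i+1:03d}", random_protein(rng, length),
             "hypothetical protein", strand)
        )
    bgc_entries = [
        (f"{genome_id}_{g.label}", g.protein, f"PTM BGC {g.family.value}", "+")
        for g in bgc_genes
    ]
    entries[insertion_index:insertion_index] = bgc_entries
    for gene_id, protein, product in extra_genes:
        entries.append((f"{genome_id}_{gene_id}", protein, product, "+"))

    contig_id = f"{genome_id}_c1"
    genes: List[Gene] = []
    pos = int(rng.integers(50, 200))
    for gene_id, protein, product, strand in entries:
        span = 3 * (len(protein) + 1)
        genes.append(
            Gene(
                gene_id=gene_id,
                contig_id=contig_id,
                start=pos,
                end=pos + span,
                strand=strand,
                protein=protein,
                product=product,
            )
        )
        pos += span + int(rng.integers(50, 200))
    total = pos + int(rng.integers(50, 200))
    if genome_length_bp is not None:
        if genome_length_bp < total:
            raise ValueError("genome_length_bp smaller than the gene span")
        total = genome_length_bp
    genome = Genome(
        genome_id=genome_id,
        taxon_label=genome_id,
        contigs={contig_id: genes},
        total_length_bp=total,
    )
    if path is not None:
        write_genbank(genome, path)
    return genome


# --- ion lists -------------------------------------------------------------


def simulate_ion_list(
    compounds: Sequence[CompoundRecord],
    noise_sd: float,
    seed: RngLike,
) -> List[float]:
    """One Gaussian-jittered [M-H]- ion per compound; deterministic per seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    return [
        float(c.expected_mz + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        for c in compounds
    ]


# --- whole-dataset simulation ----------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic dataset.

    Defaults emulate a small host-associated clade: 8 taxa, 0.1 expected
    substitutions per site per unit branch length, 40 decoy genes around
    each implanted BGC, Gaussian ion noise of 0.1 Da.
    """

    n_taxa: int = 8
    seed: int = 0
    rate: float = 0.1
    n_decoys: int = 40
    insertion_index: int = 20
    ion_noise_sd: float = 0.1
    genome_length_mbp: Optional[Tuple[float, float]] = (6.5, 9.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.rate < 0 or self.ion_noise_sd < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimulatedDataset:
    tree: dendropy.Tree
    genomes: List[Genome]
    bgc: BgcSimResult
    script: EventScript
    ion_lists: Dict[str, List[float]]
    genome_files: Dict[str, str] = field(default_factory=dict)


def default_event_script(tree: dendropy.Tree) -> EventScript:
    """The default per-branch scenario: a tailoring loss, a DH2->DH3
    duplication, and an OxR loss on three pendant branches (when present)."""
    leaves = [
        n.taxon.label for n in tree.leaf_node_iter() if n.taxon is not None
    ]
    events = []
    if len(leaves) >= 2:
        events.append(ScriptEvent(leaves[1], EnzymeFamily.CYP450, "loss"))
    if len(leaves) >= 3:
        events.append(ScriptEvent(leaves[2], EnzymeFamily.DH2, "duplicate"))
    if len(leaves) >= 4:
        events.append(ScriptEvent(leaves[3], EnzymeFamily.OXR, "loss"))
    return EventScript(events)


def simulate_dataset(
    cfg: SimConfig,
    script: Optional[EventScript] = None,
    out_dir=None,
) -> SimulatedDataset:
    """Generate a complete ground-truthed dataset from one seed.

    Produces the species tree, per-leaf BGC variants under the event
    script, one genome per leaf (decoys + implanted BGC + an rpoB-like
    marker evolved along the same tree), and a noisy ion list per leaf.
    GenBank files and the truth JSON are written when ``out_dir`` is given.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    tree = simulate_tree(cfg.n_taxa, np.random.default_rng(seeds[0]))
    if script is None:
        script = default_event_script(tree)
    bgc = synthesize_bgc_variants(
        tree, make_reference_bgc(), script, cfg.rate, np.random.default_rng(seeds[1])
    )
    # rpoB evolves along the same tree
    rpo_rng = np.random.default_rng(seeds[2])
    rpo: Dict[str, str] = {}

    def walk(node, seq):
        if node.parent_node is not None:
            seq = evolve_protein(seq, node.edge.length or 0.0, cfg.rate, rpo_rng)
        if node.is_leaf():
            rpo[node.taxon.label] = seq
        for child in node.child_nodes():
            walk(child, seq)

    walk(tree.seed_node, marker_reference("rpoB"))

    genome_rng = np.random.default_rng(seeds[3])
    ion_rng = np.random.default_rng(seeds[4])
    genomes: List[Genome] = []
    genome_files: Dict[str, str] = {}
    ion_lists: Dict[str, List[float]] = {}
    compounds = bundled_compounds()
    leaves = sorted(bgc.leaf_genes)
    for leaf in leaves:
        length_bp = None
        if cfg.genome_length_mbp is not None:
            lo, hi = cfg.genome_length_mbp
            length_bp = int(genome_rng.uniform(lo, hi) * 1e6)
        path = None
        if out_dir is not None:
            path = str(Path(out_dir) / f"{leaf}.gbk")
        genome = assemble_genome(
            bgc.leaf_genes[leaf],
            cfg.n_decoys,
            cfg.insertion_index,
            genome_rng,
            genome_id=leaf,
            extra_genes=[("rpoB", rpo[leaf], "RNA polymerase beta subunit")],
            genome_length_bp=length_bp,
            path=path,
        )
        genomes.append(genome)
        if path is not None:
            genome_files[leaf] = path
        ion_lists[leaf] = simulate_ion_list(compounds, cfg.ion_noise_sd, ion_rng)
    dataset = SimulatedDataset(
        tree=tree,
        genomes=genomes,
        bgc=bgc,
        script=script,
        ion_lists=ion_lists,
        genome_files=genome_files,
    )
    if out_dir is not None:
        with open(Path(out_dir) / "truth.json", "w") as fh:
            json.dump(emit_ground_truth(dataset), fh, indent=2)
    return dataset


def emit_ground_truth(dataset: SimulatedDataset) -> dict:
    """Truth JSON sufficient to score every pipeline stage."""
    from .phylogeny import write_newick

    bgc_loci = {}
    for genome in dataset.genomes:
        leaf = genome.genome_id
        bgc_ids = {f"{leaf}_{g.label}" for g in dataset.bgc.leaf_genes[leaf]}
        indices = [
            i for i, g in enumerate(genome.genes()) if g.gene_id in bgc_ids
        ]
        bgc_loci[leaf] = {"first_index": min(indices), "last_index": max(indices)}
    return {
        "tree": write_newick(dataset.tree),
        "leaf_content": dataset.bgc.leaf_content,
        "events": dataset.bgc.applied_events,
        "bgc_loci": bgc_loci,
        "ion_lists": dataset.ion_lists,
        "compounds": {
            c.label: {"name": c.name, "formula": c.formula.hill(),
                      "nominal_mz": c.expected_mz}
            for c in bundled_compounds()
        },
        "genome_lengths_mbp": {
            g.genome_id: g.length_mbp for g in dataset.genomes
        },
    }
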