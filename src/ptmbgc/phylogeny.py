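"""Marker extraction, alignment, and distance-based tree building.

Species and gene trees are built from single-copy markers: an rpoB-like RNA
polymerase beta-subunit homolog (species marker, finer resolution than 16S
within *Streptomyces*) and the ikaA-like PKS/NRPS megasynthase (BGC marker).
Markers are pulled from each genome by local-alignment search with
marker-specific bit-score floors, aligned progressively (guide tree from
pairwise distances, then profile-profile global alignment with affine
gaps), trimmed, and turned into neighbor-joining trees with nonparametric
bootstrap supports. The method is deliberately deterministic and
desk-scale; supports are bootstrap percentages, reported as such, not
posterior probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from numba import njit

from .genome_io import Gene, Genome
from .homology import AA_ALPHABET, ScoringScheme, _matrix, find_homologs
from .mining import MiningConfig

logger = logging.getLogger(__name__)

GAP = "-"
_CHAR_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_CHAR_INDEX["X"] = 20
_CHAR_INDEX[GAP] = 21
_N_STATES = 22  # 20 aa + X + gap


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows, unique labels."""

    labels: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        arr = np.empty((self.n_seqs, self.n_cols), dtype=np.int8)
        for i, row in enumerate(self.rows):
            arr[i] = [_CHAR_INDEX[c] for c in row]
        return arr

    def trim(self, max_gap_frac: float = 0.5) -> "Msa":
        """Drop columns with a gap fraction above ``max_gap_frac``."""
        arr = self.to_array()
        keep = (arr == _CHAR_INDEX[GAP]).mean(axis=0) <= max_gap_frac
        rows = ["".join(np.array(list(r))[keep]) for r in self.rows]
        return Msa(list(self.labels), rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.rows):
                fh.write(f">{label}\n{row}\n")


def extract_marker(
    genome: Genome,
    marker_ref: str,
    cfg: MiningConfig = MiningConfig(),
    marker: str = "rpoB",
    scheme: ScoringScheme = ScoringScheme(),
) -> Optional[Gene]:
    """Best marker homolog in a genome, or None (with a logged warning).

    ``marker`` selects the bit-score floor: 4000 for ikaA, 200 for rpoB.
    """
    if marker == "ikaA":
        min_bits = cfg.ikaA_min_bits
    elif marker == "rpoB":
        min_bits = cfg.rpoB_min_bits
    else:
        raise ValueError(f"unknown marker: {marker!r}")
    proteome = list(genome.genes())
    if not proteome:
        logger.warning("genome %s has no genes; %s marker absent", genome.genome_id, marker)
        return None
    hits = find_homologs(
        marker_ref, proteome, scheme, max_e=cfg.marker_max_e, min_bits=min_bits,
        query_id=marker,
    )
    if not hits:
        logger.warning("no %s marker found in genome %s", marker, genome.genome_id)
        return None
    by_id = {g.gene_id: g for g in proteome}
    return by_id[hits[0].subject_id]


# --- progressive alignment -------------------------------------------------


@njit(cache=False)
def _gotoh_profile(C: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a column-score matrix; returns pointers.

    State 0 = match, 1 = gap in columns (consume row profile), 2 = gap in
    rows (consume column profile).
    """
    n1, n2 = C.shape
    neg = -1e30
    prev_m = np.full(n2 + 1, neg)
    prev_x = np.full(n2 + 1, neg)
    prev_y = np.full(n2 + 1, neg)
    ptr_m = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_x = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_y = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    prev_m[0] = 0.0
    for j in range(1, n2 + 1):
        prev_y[j] = -gap_open - (j - 1) * gap_extend
        ptr_y[0, j] = 2 if j > 1 else 0
    cur_m = np.empty(n2 + 1)
    cur_x = np.empty(n2 + 1)
    cur_y = np.empty(n2 + 1)
    for i in range(1, n1 + 1):
        cur_m[0] = neg
        cur_y[0] = neg
        cur_x[0] = -gap_open - (i - 1) * gap_extend
        ptr_x[i, 0] = 1 if i > 1 else 0
        for j in range(1, n2 + 1):
            # match state
            best, arg = prev_m[j - 1], 0
            if prev_x[j - 1] > best:
                best, arg = prev_x[j - 1], 1
            if prev_y[j - 1] > best:
                best, arg = prev_y[j - 1], 2
            cur_m[j] = best + C[i - 1, j - 1]
            ptr_m[i, j] = arg
            # gap consuming row profile (vertical)
            open_x = prev_m[j] - gap_open
            ext_x = prev_x[j] - gap_extend
            if open_x >= ext_x:
                cur_x[j] = open_x
                ptr_x[i, j] = 0
            else:
                cur_x[j] = ext_x
                ptr_x[i, j] = 1
            # gap consuming column profile (horizontal)
            open_y = cur_m[j - 1] - gap_open
            ext_y = cur_y[j - 1] - gap_extend
            if open_y >= ext_y:
                cur_y[j] = open_y
                ptr_y[i, j] = 0
            else:
                cur_y[j] = ext_y
                ptr_y[i, j] = 2
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    end_state = 0
    best = prev_m[n2]
    if prev_x[n2] > best:
        best, end_state = prev_x[n2], 1
    if prev_y[n2] > best:
        best, end_state = prev_y[n2], 2
    return ptr_m, ptr_x, ptr_y, end_state


def _traceback(ptr_m, ptr_x, ptr_y, end_state, n1, n2) -> List[int]:
    """Recover the alignment path as a list of ops (0=M, 1=X, 2=Y)."""
    i, j, state = n1, n2, end_state
    ops: List[int] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == 0:
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptr_x[i, j])
            i -= 1
        else:
            state = int(ptr_y[i, j])
            j -= 1
    ops.reverse()
    return ops


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    arr = np.empty((len(rows), len(rows[0])), dtype=np.intp)
    for i, row in enumerate(rows):
        arr[i] = [_CHAR_INDEX[c] for c in row]
    freqs = np.zeros((len(rows[0]), _N_STATES))
    for i in range(arr.shape[0]):
        freqs[np.arange(arr.shape[1]), arr[i]] += 1.0
    return freqs / arr.shape[0]


def _score_table(scheme: ScoringScheme) -> np.ndarray:
    """22x22 column-score table: BLOSUM entries; X and gap score 0."""
    mat = _matrix(scheme.matrix_name)
    table = np.zeros((_N_STATES, _N_STATES))
    for a, ca in enumerate(AA_ALPHABET):
        for b, cb in enumerate(AA_ALPHABET):
            table[a, b] = mat[ca, cb]
    return table


def _align_profiles(
    rows_a: List[str], rows_b: List[str], scheme: ScoringScheme
) -> Tuple[List[str], List[str]]:
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    table = _score_table(scheme)
    C = fa @ table @ fb.T
    ptr_m, ptr_x, ptr_y, end_state = _gotoh_profile(
        C, float(scheme.gap_open), float(scheme.gap_extend)
    )
    ops = _traceback(ptr_m, ptr_x, ptr_y, end_state, C.shape[0], C.shape[1])
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in (0, 1):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in (0, 2):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            j += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _pairwise_p_distance(a: str, b: str, scheme: ScoringScheme) -> float:
    ra, rb = _align_profiles([a], [b], scheme)
    same = comparable = 0
    for x, y in zip(ra[0], rb[0]):
        if x != GAP and y != GAP:
            comparable += 1
            if x == y:
                same += 1
    if comparable == 0:
        return 1.0
    return 1.0 - same / comparable


def progressive_align(
    seqs: Sequence[Tuple[str, str]], scheme: ScoringScheme = ScoringScheme()
) -> Msa:
    """Progressive MSA: UPGMA guide from pairwise distances, then
    profile-profile global alignment. Deterministic; ties in the guide
    clustering join the lowest-index pair first.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    labels = [s[0] for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _pairwise_p_distance(
                seqs[i][1], seqs[j][1], scheme
            )
    # UPGMA-style merge order
    clusters: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([labels[i]], [seqs[i][1]]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        la, ra = clusters.pop(i)
        lb, rb = clusters.pop(j)
        aligned_a, aligned_b = _align_profiles(ra, rb, scheme)
        merged = (la + lb, aligned_a + aligned_b)
        for k in list(clusters):
            key_i = (min(i, k), max(i, k))
            key_j = (min(j, k), max(j, k))
            new_d = (d[key_i] * sizes[i] + d[key_j] * sizes[j]) / (
                sizes[i] + sizes[j]
            )
            d[(min(next_id, k), max(next_id, k))] = new_d
            del d[key_i], d[key_j]
        del d[(i, j)]
        clusters[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        next_id += 1
    final_labels, final_rows = next(iter(clusters.values()))
    order = {lab: i for i, lab in enumerate(labels)}
    paired = sorted(zip(final_labels, final_rows), key=lambda t: order[t[0]])
    return Msa([p[0] for p in paired], [p[1] for p in paired])


# --- distances and trees ---------------------------------------------------


def distance_matrix(msa: Msa, model: str = "p_distance") -> pd.DataFrame:
    """Pairwise distances with pairwise deletion of gapped columns.

    ``p_distance`` is the mismatch proportion; ``poisson`` is -ln(1 - p).
    A pair with zero comparable columns is an error.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model: {model!r}")
    arr = msa.to_array()
    gap = _CHAR_INDEX[GAP]
    n = msa.n_seqs
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (arr[i] != gap) & (arr[j] != gap)
            comparable = int(mask.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {msa.labels[i]} and "
                    f"{msa.labels[j]}"
                )
            p = float(((arr[i] != arr[j]) & mask).sum()) / comparable
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {msa.labels[i]}/{msa.labels[j]} "
                        "(p = 1) under the Poisson model"
                    )
                p = -np.log(1.0 - p)
            out[i, j] = out[j, i] = p
    return pd.DataFrame(out, index=msa.labels, columns=msa.labels)


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbor joining; returns an unrooted dendropy tree.

    Equal minimal Q values are resolved by joining the lowest-index pair
    first; negative branch lengths are clamped to zero.
    """
    labels = list(dist.index)
    mat = dist.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: Dict[int, dendropy.Node] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[i] = node
    active = list(range(len(labels)))
    d = {(i, j): mat[i, j] for i in active for j in active if i < j}

    def get(i: int, j: int) -> float:
        return d[(min(i, j), max(i, j))]

    next_id = len(labels)
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best_pair, best_q = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (i, j)
        i, j = best_pair
        li = 0.5 * get(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = get(i, j) - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = max(0.0, length)
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            d[(min(next_id, k), max(next_id, k))] = 0.5 * (
                get(i, k) + get(j, k) - get(i, j)
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    # final three-way join
    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    center = dendropy.Node()
    for child, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        center.add_child(child)
        child.edge.length = max(0.0, length)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_tree(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge (split at its midpoint).

    Re-rooting an already-rooted tree on the same outgroup is a no-op, so
    the operation is idempotent. Ingroup splits are unchanged.
    """
    rooted = tree.clone(depth=1)
    leaf = None
    for node in rooted.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == outgroup:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not found among leaves")
    root = rooted.seed_node
    if len(root.child_nodes()) == 2 and leaf in root.child_nodes():
        rooted.is_rooted = True
        return rooted
    half = (leaf.edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    new_root = rooted.seed_node
    children = new_root.child_nodes()
    if leaf in children and len(children) == 2:
        for child in children:
            child.edge.length = half
    rooted.is_rooted = True
    return rooted


def _splits(tree: dendropy.Tree) -> Dict[frozenset, dendropy.Node]:
    """Non-trivial unrooted splits keyed by the frozenset pair of leaf sets."""
    all_leaves = frozenset(
        n.taxon.label for n in tree.leaf_node_iter() if n.taxon is not None
    )
    out: Dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(
            n.taxon.label for n in node.leaf_iter() if n.taxon is not None
        )
        if 1 < len(side) < len(all_leaves) - 1:
            out[frozenset((side, all_leaves - side))] = node
    return out


def bootstrap_support(
    msa: Msa,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "p_distance",
) -> dendropy.Tree:
    """NJ tree with bootstrap percentages on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; each internal
    split's support is the percentage of replicate trees containing it.
    Supports are stored as ``node.label`` (and ``bootstrap_pct`` attribute)
    on internal nodes. Deterministic per seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    main = nj_tree(distance_matrix(msa, model))
    counts: Dict[frozenset, int] = {s: 0 for s in _splits(main)}
    rng = np.random.default_rng(seed)
    cols = np.arange(msa.n_cols)
    arr_rows = [list(r) for r in msa.rows]
    for _ in range(n_reps):
        idx = rng.choice(cols, size=msa.n_cols, replace=True)
        rep_rows = ["".join(row[c] for c in idx) for row in arr_rows]
        rep = Msa(list(msa.labels), rep_rows)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:  # a replicate with no comparable columns
            continue
        rep_splits = _splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for split, node in _splits(main).items():
        pct = 100.0 * counts[split] / n_reps
        node.label = f"{pct:g}"
        node.bootstrap_pct = pct
    return main


def write_newick(tree: dendropy.Tree) -> str:
    """Canonical newick string (supports as internal labels, %g lengths).

    The writer is its own parser's fixed point: write -> read -> write is
    byte-stable.
    """

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else (node.label or "")
            label = label.replace(" ", "_")
        else:
            inner = ",".join(render(c) for c in node.child_nodes())
            label = f"({inner})" + (node.label or "")
        if node.edge.length is not None and node.parent_node is not None:
            label += f":{node.edge.length:g}"
        return label

    return render(tree.seed_node) + ";"


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
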