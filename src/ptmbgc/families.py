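"""The 7-member PTM enzyme repertoire and gene classification.

The PTM biosynthetic gene cluster family draws on a small enzymatic
repertoire: a hybrid PKS/NRPS megasynthase, a sterol desaturase (SD), a
cytochrome P450 (CYP450), an oxidoreductase (OxR), and three dehydrogenases
(DH1, DH2, DH3 — one super-family, with DH3 arising from a recent
duplication). BGC member genes are assigned to families by nearest labeled
reference (best bit score passing an E-value cutoff); dehydrogenase hits are
refined into subfamilies. The per-cluster presence/absence of families forms
the binary gene-content matrix consumed by the chemotype and evolution
stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .homology import ScoringScheme, bits_and_evalue, local_align, local_score


class EnzymeFamily(Enum):
    PKS_NRPS = "PKS_NRPS"
    SD = "SD"
    CYP450 = "CYP450"
    OXR = "OXR"
    DH1 = "DH1"
    DH2 = "DH2"
    DH3 = "DH3"


#: fixed column order of the gene-content matrix
FAMILY_ORDER: Tuple[EnzymeFamily, ...] = (
    EnzymeFamily.PKS_NRPS,
    EnzymeFamily.SD,
    EnzymeFamily.CYP450,
    EnzymeFamily.OXR,
    EnzymeFamily.DH1,
    EnzymeFamily.DH2,
    EnzymeFamily.DH3,
)

#: the dehydrogenase super-family
DH_FAMILIES: Tuple[EnzymeFamily, ...] = (
    EnzymeFamily.DH1,
    EnzymeFamily.DH2,
    EnzymeFamily.DH3,
)


@dataclass(frozen=True)
class ReferenceProtein:
    ref_id: str
    family: EnzymeFamily
    protein: str


@dataclass
class FamilyReferenceSet:
    """Labeled reference proteins, at least one per family.

    The bundled set is synthetic exemplars (see :mod:`ptmbgc.simulate`);
    real-data use expects user-supplied curated references.
    """

    references: List[ReferenceProtein]

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.references]
        if len(ids) != len(set(ids)):
            raise ValueError("reference ids must be unique")
        covered = {r.family for r in self.references}
        missing = [f.value for f in FAMILY_ORDER if f not in covered]
        if missing:
            raise ValueError(f"families without references: {missing}")

    def by_family(self, family: EnzymeFamily) -> List[ReferenceProtein]:
        return [r for r in self.references if r.family is family]

    @property
    def total_residues(self) -> int:
        return sum(len(r.protein) for r in self.references)


def _score_refs(
    protein: str, refs: Sequence[ReferenceProtein], scheme: ScoringScheme
) -> List[Tuple[ReferenceProtein, int]]:
    return [(r, local_score(protein, r.protein, scheme)) for r in refs]


def assign_dh_subfamily(
    protein: str,
    dh_refs: Sequence[ReferenceProtein],
    scheme: ScoringScheme = ScoringScheme(),
) -> EnzymeFamily:
    """Subfamily of a dehydrogenase: nearest DH reference by bit score.

    Ties are broken by higher percent identity, then by the fixed order
    DH1 < DH2 < DH3.
    """
    if not dh_refs:
        raise ValueError("no dehydrogenase references supplied")
    order = {f: i for i, f in enumerate(DH_FAMILIES)}
    best: Optional[Tuple[float, float, int, EnzymeFamily]] = None
    for ref, raw in _score_refs(protein, dh_refs, scheme):
        identity = local_align(protein, ref.protein, scheme).percent_identity
        key = (-float(raw), -identity, order[ref.family], ref.family)
        if best is None or key[:3] < best[:3]:
            best = key
    return best[3]


def classify_enzyme(
    protein: str,
    refs: FamilyReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
    max_e: float = 1e-6,
) -> Optional[EnzymeFamily]:
    """Family of the best-scoring reference passing ``max_e``, or None.

    A hit landing in the dehydrogenase super-family is refined with
    :func:`assign_dh_subfamily`. A gene receives at most one label.
    """
    m = len(protein)
    n = refs.total_residues
    scored = _score_refs(protein, refs.references, scheme)
    scored.sort(key=lambda t: (-t[1], t[0].ref_id))
    best_ref, best_raw = scored[0]
    _, e_value = bits_and_evalue(best_raw, scheme, m, n)
    if e_value > max_e:
        return None
    if best_ref.family in DH_FAMILIES:
        return assign_dh_subfamily(
            protein, [r for r in refs.references if r.family in DH_FAMILIES], scheme
        )
    return best_ref.family


def classify_call_members(
    call,
    refs: FamilyReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
    max_e: float = 1e-6,
) -> Dict[str, Optional[EnzymeFamily]]:
    """Per-gene family labels for one BGC call's neighborhood members."""
    return {
        g.gene_id: classify_enzyme(g.protein, refs, scheme, max_e)
        for g in call.neighborhood.members
    }


def build_content_matrix(
    calls,
    refs: FamilyReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
    max_e: float = 1e-6,
) -> pd.DataFrame:
    """Binary presence/absence matrix: one row per orthologous call.

    A cell is 1 iff at least one member gene of that call classifies to the
    family; paralogs do not increment it. Column order is fixed.
    """
    rows = {}
    for call in calls:
        if call.status != "orthologous":
            continue
        labels = classify_call_members(call, refs, scheme, max_e)
        present = {fam for fam in labels.values() if fam is not None}
        rows[call.call_id] = [1 if f in present else 0 for f in FAMILY_ORDER]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f.value for f in FAMILY_ORDER], dtype=int
    )


def write_content_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="call_id")


def read_content_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="call_id")
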