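"""The core crosstalk procedure: classify each tissue's differentially
expressed genes into database ligands and receptors, then assemble the
directed blood/synovium communication map.

An edge (A, L) -> (B, R) exists exactly when (L, R) is a curated database
pair, L is a differential ligand in tissue A and R a differential receptor in
tissue B, over all four ordered tissue combinations BL->BL, BL->SY, SY->BL,
SY->SY (within-tissue pairs are first-class outputs, not a by-product). The
procedure is presence/absence on DEG status: up/down directions are carried
as annotations, never used as filters, and no expression-level weighting is
applied. A gene curated as both ligand and receptor participates in both
roles.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import pandas as pd

from .containers import (
    DIRECTION_CLASSES,
    CommunicationMap,
    DEGSet,
    Edge,
    LRClassification,
    LRPairTable,
)
from .errors import ConsistencyError

__all__ = ["classify_lr", "build_communication_map", "summarize_map", "ligand_hubs"]


def classify_lr(degs: DEGSet, pairs: LRPairTable, tissue: str = "BL") -> LRClassification:
    """Intersect a tissue's DEGs with the database ligand and receptor sets.

    Each classified gene keeps its OA-vs-HC direction. Empty intersections
    are valid results.
    """
    lig = {g: d for g, d in degs.directions.items() if g in pairs.ligand_set}
    rec = {g: d for g, d in degs.directions.items() if g in pairs.receptor_set}
    return LRClassification(tissue=tissue, ligands=lig, receptors=rec)


def build_communication_map(
    class_bl: LRClassification, class_sy: LRClassification, pairs: LRPairTable
) -> CommunicationMap:
    """Assemble the four-class directed communication map.

    For every ordered tissue pair (A, B) and every database pair (L, R) with
    L a differential ligand of A and R a differential receptor of B, emit the
    edge (A, L) -> (B, R) tagged with both genes' directions and the
    direction class ``A->B``.
    """
    by_tissue = {class_bl.tissue: class_bl, class_sy.tissue: class_sy}
    if set(by_tissue) != {"BL", "SY"}:
        raise ConsistencyError("need exactly one BL and one SY classification")
    for cls in (class_bl, class_sy):
        stray_l = set(cls.ligands) - set(pairs.ligand_set)
        stray_r = set(cls.receptors) - set(pairs.receptor_set)
        if stray_l or stray_r:
            raise ConsistencyError(
                f"classification for {cls.tissue} references symbols absent from the "
                f"pair table: {sorted(stray_l | stray_r)[:5]}"
            )
    edges: list[Edge] = []
    for src in ("BL", "SY"):
        for dst in ("BL", "SY"):
            lig = by_tissue[src].ligands
            rec = by_tissue[dst].receptors
            for L, R in pairs.pairs:
                if L in lig and R in rec:
                    edges.append(
                        Edge(
                            source_tissue=src,
                            ligand=L,
                            ligand_direction=lig[L],
                            target_tissue=dst,
                            receptor=R,
                            receptor_direction=rec[R],
                            direction_class=f"{src}->{dst}",
                        )
                    )
    return CommunicationMap(edges=edges)


def summarize_map(cmap: CommunicationMap) -> dict:
    """Count edges per direction class and per-node ligand/receptor degrees.

    Returns ``{"class_counts": {...}, "total_edges": int, "out_degree":
    {(tissue, ligand): n}, "in_degree": {(tissue, receptor): n}}``; the four
    class counts always sum to the total.
    """
    class_counts = {c: 0 for c in DIRECTION_CLASSES}
    out_deg: Counter = Counter()
    in_deg: Counter = Counter()
    for e in cmap.edges:
        class_counts[e.direction_class] += 1
        out_deg[(e.source_tissue, e.ligand)] += 1
        in_deg[(e.target_tissue, e.receptor)] += 1
    return {
        "class_counts": class_counts,
        "total_edges": len(cmap),
        "out_degree": dict(out_deg),
        "in_degree": dict(in_deg),
    }


def ligand_hubs(ligands: set[str], interaction_edges: list[tuple[str, str]]) -> pd.DataFrame:
    """Rank ligands by connectivity in a protein-interaction network.

    The undirected interaction graph is induced on the ligand set (edges with
    both endpoints in it); ligands absent from the edge list get degree 0 and
    their own singleton component. Returns a DataFrame sorted by degree
    descending, ties alphabetical, with columns ligand, degree, component.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(ligands))
    for a, b in interaction_edges:
        if a in ligands and b in ligands and a != b:
            graph.add_edge(a, b)
    component_of: dict[str, int] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    for i, comp in enumerate(comps):
        for node in comp:
            component_of[node] = i
    rows = [
        {"ligand": n, "degree": graph.degree(n), "component": component_of[n]}
        for n in graph.nodes
    ]
    df = pd.DataFrame(rows, columns=["ligand", "degree", "component"])
    if not df.empty:
        df = df.sort_values("ligand", kind="mergesort").sort_values(
            "degree", ascending=False, kind="mergesort"
        )
    return df.reset_index(drop=True)
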