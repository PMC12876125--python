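"""Core in-memory containers shared by every pipeline stage.

The pipeline transforms an :class:`ExpressionMatrix` (genes x samples, log2
scale, with HC/OA group labels and a tissue tag) into a per-gene differential
table, intersects the significant genes with a curated ligand-receptor pair
table (:class:`LRPairTable`), and assembles a directed
:class:`CommunicationMap` whose edges run from a ligand in a source tissue to
a receptor in a target tissue.

Tabular results (differential tables, enrichment tables) are plain pandas
DataFrames with documented column contracts rather than bespoke classes; the
classes here exist where invariants need enforcing at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError

GROUPS = ("HC", "OA")
TISSUES = ("BL", "SY")
#: direction classes of communication edges, in canonical order
DIRECTION_CLASSES = ("BL->BL", "BL->SY", "SY->BL", "SY->SY")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for one tissue cohort.

    Parameters
    ----------
    values
        genes x samples DataFrame; index = unique gene symbols,
        columns = unique sample identifiers, all entries finite.
    sample_group
        Series indexed by sample id with values in ``{"HC", "OA"}``.
    tissue
        ``"BL"`` (blood / PBMC) or ``"SY"`` (synovium / synovial fibroblast).
    """

    values: pd.DataFrame
    sample_group: pd.Series
    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ParameterError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ConsistencyError("expression values must all be finite")
        if list(self.sample_group.index) != list(self.values.columns):
            raise ConsistencyError("sample_group index must match value columns in order")
        bad = set(self.sample_group) - set(GROUPS)
        if bad:
            raise ConsistencyError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to one group (``HC`` or ``OA``)."""
        if group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        return list(self.sample_group.index[self.sample_group == group])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same labels, new value matrix (used by transforms)."""
        return ExpressionMatrix(values=values, sample_group=self.sample_group, tissue=self.tissue)


@dataclass
class LRPairTable:
    """Curated directed ligand -> receptor gene-symbol pairs.

    ``pairs`` keeps the curated order; ``ligand_set`` / ``receptor_set`` are
    exactly the two projections. Duplicate pairs are rejected here (readers
    deduplicate before construction).
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(l), str(r)) for l, r in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ConsistencyError("pair table contains duplicate (ligand, receptor) pairs")

    @property
    def ligand_set(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptor_set(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    term_name: str
    category: str  # BP / MF / CC
    genes: frozenset[str]


@dataclass
class GeneSetAnnotation:
    """A GO-style collection of gene sets with BP/MF/CC category labels."""

    terms: list[GeneSetTerm]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(f"duplicate term ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: str) -> GeneSetTerm:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass
class DEGSet:
    """Differentially expressed genes with their OA-vs-HC direction.

    ``directions`` maps gene symbol -> ``"up"`` (higher in OA) or ``"down"``.
    """

    directions: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in ("up", "down")}
        if bad:
            raise ConsistencyError(f"invalid directions: {bad}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class LRClassification:
    """A tissue's DEGs split into database ligands and receptors.

    A gene annotated with both roles in the database appears in both maps.
    """

    tissue: str
    ligands: dict[str, str]  # symbol -> direction
    receptors: dict[str, str]

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ParameterError(f"tissue must be one of {TISSUES}")


class Edge(NamedTuple):
    """One directed communication edge: ligand in source tissue binds its
    receptor in the target tissue."""

    source_tissue: str
    ligand: str
    ligand_direction: str
    target_tissue: str
    receptor: str
    receptor_direction: str
    direction_class: str


def _edge_sort_key(e: Edge) -> tuple:
    return (e.direction_class, e.ligand, e.receptor)


@dataclass
class CommunicationMap:
    """The directed blood/synovium communication network.

    Edges are stored in canonical order (direction class, ligand, receptor)
    so that all serialisations are byte-deterministic.
    """

    edges: list[Edge]

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ConsistencyError("duplicate edges in communication map")
        for e in self.edges:
            if e.direction_class != f"{e.source_tissue}->{e.target_tissue}":
                raise ConsistencyError(f"direction class mismatch on edge {e}")
        self.edges = sorted(self.edges, key=_edge_sort_key)

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=Edge._fields)


@dataclass
class TruthTable:
    """Ground truth of a synthetic two-tissue study (what was planted where)."""

    de: dict[str, dict[str, str]]  # tissue -> {gene: direction}
    ligand_set: frozenset[str]
    receptor_set: frozenset[str]
    pair_list: list[tuple[str, str]]
    planted_term_id: str | None = None

    def de_genes(self, tissue: str) -> frozenset[str]:
        return frozenset(self.de[tissue])

    def to_json_dict(self) -> dict:
        return {
            "de": {t: dict(sorted(d.items())) for t, d in sorted(self.de.items())},
            "ligand_set": sorted(self.ligand_set),
            "receptor_set": sorted(self.receptor_set),
            "pair_list": [list(p) for p in self.pair_list],
            "planted_term_id": self.planted_term_id,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthTable":
        return cls(
            de={t: dict(v) for t, v in d["de"].items()},
            ligand_set=frozenset(d["ligand_set"]),
            receptor_set=frozenset(d["receptor_set"]),
            pair_list=[tuple(p) for p in d["pair_list"]],
            planted_term_id=d.get("planted_term_id"),
        )


@dataclass
class PCAResult:
    """Sample-space principal components of an expression matrix."""

    scores: pd.DataFrame  # samples x k
    explained_variance_ratio: np.ndarray  # k
    component_loadings: pd.DataFrame  # genes x k
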