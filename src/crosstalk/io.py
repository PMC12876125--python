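"""Readers and writers for every external format the pipeline touches.

Formats: expression TSV (first column gene symbol, header = sample ids) with
a sample-metadata TSV (sample_id, group in {HC, OA}, tissue in {BL, SY});
ligand-receptor pair TSV (columns ``ligand``, ``receptor``); GMT gene sets;
and the serialised communication-map outputs (edge TSV, GraphML, chord JSON)
that replace interactive circos/network rendering.

Conventions enforced at every ingestion point:

* gene symbols are uppercased and whitespace-stripped (case mismatch between
  platform annotation and pair databases is a classic silent-failure mode);
* readers reject malformed input with coordinates rather than coercing;
* writers emit UTF-8, LF line endings, tab delimiters, fully sorted content,
  so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    CommunicationMap,
    ExpressionMatrix,
    GeneSetAnnotation,
    GeneSetTerm,
    LRPairTable,
)
from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

_GMT_CATEGORIES = ("BP", "MF", "CC")


def _norm_symbol(s: str) -> str:
    return str(s).strip().upper()


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV plus its sample metadata.

    The first column holds gene symbols; remaining columns are samples in
    file order. Metadata must cover every sample column and carry a single
    tissue label.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids in header: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = [_norm_symbol(g) for g in raw.index]
    if raw.shape[0] < 1:
        raise FormatError(f"{path}: no gene rows")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            row = raw.index[(bad | raw[col].isna()).to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        values[col] = converted
    if pd.Index(values.index).duplicated().any():
        dups = pd.Index(values.index)
        raise FormatError(
            f"{path}: duplicate gene ids: {sorted(dups[dups.duplicated()].unique())[:5]}"
        )

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "tissue"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path}: missing column {col!r}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise FormatError(f"{metadata_path}: duplicate sample ids")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise FormatError(f"{metadata_path}: samples missing from metadata: {missing[:5]}")
    tissues = set(meta.loc[sample_ids, "tissue"])
    if len(tissues) != 1:
        raise FormatError(f"{metadata_path}: expected a single tissue label, got {sorted(tissues)}")
    group = meta.loc[sample_ids, "group"]
    group.name = "group"
    return ExpressionMatrix(values=values, sample_group=group, tissue=tissues.pop())


def write_expression_tsv(
    mat: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a matrix (and optionally its metadata) in the format
    :func:`read_expression_tsv` accepts; the pair round-trips losslessly."""
    df = mat.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "sample_id": mat.sample_ids,
                "group": list(mat.sample_group),
                "tissue": mat.tissue,
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene symbols by per-sample arithmetic mean.

    ``probe_map`` maps probe id -> gene symbol; probes absent from the map are
    dropped and counted in the log. Output rows are sorted lexicographically
    by gene symbol.
    """
    probe_map = {str(p): _norm_symbol(g) for p, g in probe_map.items()}
    mapped = [p for p in probe_matrix.gene_ids if p in probe_map]
    dropped = probe_matrix.n_genes - len(mapped)
    if not mapped:
        raise FormatError("no probe in the matrix has a probe-map entry")
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = probe_matrix.values.loc[mapped]
    collapsed = sub.groupby([probe_map[p] for p in mapped]).mean()
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(
        values=collapsed, sample_group=probe_matrix.sample_group, tissue=probe_matrix.tissue
    )


# ---------------------------------------------------------------------------
# ligand-receptor pair tables


def read_lr_pairs(path: str | Path) -> LRPairTable:
    """Read a curated pair table (TSV with ``ligand`` and ``receptor``
    columns). Symbols are case-normalised; exact duplicate pairs after
    normalisation are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lig, rec in zip(df["ligand"], df["receptor"]):
        pair = (_norm_symbol(lig), _norm_symbol(rec))
        if pair in seen:
            n_dup += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    if n_dup:
        logger.info("read_lr_pairs: dropped %d duplicate pairs", n_dup)
    return LRPairTable(pairs=pairs)


def write_lr_pairs(table: LRPairTable, path: str | Path) -> None:
    df = pd.DataFrame(table.pairs, columns=["ligand", "receptor"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetAnnotation:
    """Read gene sets from GMT (term, description, members...).

    The description field doubles as the GO category when it is one of
    BP/MF/CC; anything else falls back to BP with a warning.
    """
    terms: list[GeneSetTerm] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc = fields[0], fields[1]
            if term_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen_ids.add(term_id)
            if desc in _GMT_CATEGORIES:
                category = desc
            else:
                logger.warning(
                    "read_gmt: term %s has unrecognised category %r, defaulting to BP",
                    term_id,
                    desc,
                )
                category = "BP"
            members = frozenset(_norm_symbol(g) for g in fields[2:] if g.strip())
            terms.append(
                GeneSetTerm(term_id=term_id, term_name=term_id, category=category, genes=members)
            )
    return GeneSetAnnotation(terms=terms)


def write_gmt(annotation: GeneSetAnnotation, path: str | Path) -> None:
    """Write gene sets as GMT with the category in the description field;
    members sorted so output is byte-deterministic."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in annotation.terms:
            fields = [term.term_id, term.category] + sorted(term.genes)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# protein-interaction edge tables (STRING-style stand-in)


def read_interaction_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected protein-interaction edge table (two tab-separated
    symbol columns, header ``node_a``/``node_b`` or any two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: interaction table needs two columns")
    a, b = df.columns[:2]
    return [(_norm_symbol(x), _norm_symbol(y)) for x, y in zip(df[a], df[b])]


# ---------------------------------------------------------------------------
# communication-map serialisation


def _chord_payload(cmap: CommunicationMap) -> dict:
    # segments: per tissue, ligand nodes then receptor nodes, each sorted
    roles: dict[tuple[str, str, str], None] = {}
    for e in cmap.edges:
        roles[(e.source_tissue, "ligand", e.ligand)] = None
        roles[(e.target_tissue, "receptor", e.receptor)] = None
    order = {"ligand": 0, "receptor": 1}
    segs = sorted(roles, key=lambda k: (k[0], order[k[1]], k[2]))
    index = {seg: i for i, seg in enumerate(segs)}
    segments = [
        {"index": i, "tissue": t, "role": role, "symbol": sym}
        for i, (t, role, sym) in enumerate(segs)
    ]
    ribbons = [
        {
            "source": index[(e.source_tissue, "ligand", e.ligand)],
            "target": index[(e.target_tissue, "receptor", e.receptor)],
            "direction_class": e.direction_class,
        }
        for e in cmap.edges
    ]
    return {"segments": segments, "ribbons": ribbons}


def write_communication_outputs(cmap: CommunicationMap, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a communication map as edge TSV + GraphML + chord JSON.

    Files (all deterministically ordered):

    ``edges.tsv``
        one row per edge, sorted by (direction_class, ligand, receptor).
    ``communication.graphml``
        directed graph; nodes keyed ``<tissue>:<symbol>`` with tissue, symbol,
        role (ligand/receptor/ligand;receptor) and direction attributes.
    ``chord.json``
        per-tissue ordered ligand-then-receptor segments and the ribbon list
        indexed by segment, ready for circos-style rendering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.tsv"
    graphml_path = out_dir / "communication.graphml"
    chord_path = out_dir / "chord.json"

    cmap.to_frame().to_csv(edges_path, sep="\t", index=False, lineterminator="\n")

    graph = nx.DiGraph()
    node_attrs: dict[str, dict[str, str]] = {}
    for e in cmap.edges:
        src = f"{e.source_tissue}:{e.ligand}"
        dst = f"{e.target_tissue}:{e.receptor}"
        for key, tissue, symbol, role, direction in (
            (src, e.source_tissue, e.ligand, "ligand", e.ligand_direction),
            (dst, e.target_tissue, e.receptor, "receptor", e.receptor_direction),
        ):
            attrs = node_attrs.setdefault(
                key, {"tissue": tissue, "symbol": symbol, "role": role, "direction": direction}
            )
            if role not in attrs["role"].split(";"):
                attrs["role"] = ";".join(sorted(attrs["role"].split(";") + [role]))
    for key in sorted(node_attrs):
        graph.add_node(key, **node_attrs[key])
    for e in cmap.edges:
        graph.add_edge(
            f"{e.source_tissue}:{e.ligand}",
            f"{e.target_tissue}:{e.receptor}",
            direction_class=e.direction_class,
        )
    nx.write_graphml_xml(graph, graphml_path)

    with open(chord_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_chord_payload(cmap), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"edges": edges_path, "graphml": graphml_path, "chord": chord_path}


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, LF, trailing newline)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
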