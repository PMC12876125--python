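"""End-to-end orchestration: QC/normalisation -> per-tissue differential
screening -> ligand/receptor classification -> communication map ->
over-representation of differential ligands, with a machine-readable run
summary.

Every stage's output is written to disk so any later stage can be re-run in
isolation; all outputs are deterministically ordered, making repeated runs on
the same inputs byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .containers import ExpressionMatrix
from .differential import DEGConfig, differential_expression, filter_degs, volcano_annotations
from .enrichment import enrich
from .errors import CrosstalkError, ParameterError
from .lrmap import build_communication_map, classify_lr, ligand_hubs, summarize_map
from .preprocess import column_summaries, log2_transform, pca, quantile_normalize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_crosstalk_pipeline"]


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    blood_expr: str
    blood_meta: str
    syn_expr: str
    syn_meta: str
    pairs: str
    out_dir: str
    gmt: str | None = None
    ppi: str | None = None
    deg: DEGConfig = field(default_factory=DEGConfig)
    log2_offset: float | None = None  # None: input already on the log2 scale
    quantile: bool = True
    pca_components: int = 2
    pca_scale: bool = False
    volcano_top_n: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        deg = DEGConfig(**raw.pop("deg", {}))
        return cls(deg=deg, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "deg"}
        d["deg"] = {
            "alpha": self.deg.alpha,
            "use_adjusted": self.deg.use_adjusted,
            "method": self.deg.method,
        }
        return d


def _preprocess_tissue(mat: ExpressionMatrix, config: RunConfig, out: Path) -> ExpressionMatrix:
    tag = mat.tissue.lower()
    column_summaries(mat).to_csv(out / f"box_raw_{tag}.tsv", sep="\t", lineterminator="\n")
    if config.log2_offset is not None:
        mat = log2_transform(mat, offset=config.log2_offset)
    if config.quantile:
        mat = quantile_normalize(mat)
    column_summaries(mat).to_csv(out / f"box_normalized_{tag}.tsv", sep="\t", lineterminator="\n")
    k = min(config.pca_components, mat.n_samples, mat.n_genes)
    res = pca(mat, k=k, scale=config.pca_scale)
    scores = res.scores.copy()
    scores.insert(0, "group", list(mat.sample_group))
    scores.index.name = "sample_id"
    scores.to_csv(out / f"pca_scores_{tag}.tsv", sep="\t", lineterminator="\n")
    cio.write_expression_tsv(
        mat, out / f"normalized_{tag}.tsv", out / f"normalized_{tag}_meta.tsv"
    )
    return mat


def run_crosstalk_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes all
    intermediate tables plus ``summary.json`` under ``config.out_dir``.

    Stages: read -> (log2) -> quantile normalisation + box/PCA QC ->
    differential screening per tissue -> DEG filter -> ligand/receptor
    classification -> communication map -> ligand enrichment (if an
    annotation is configured) -> optional ligand hub ranking (if a
    protein-interaction table is configured).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read")
        blood = cio.read_expression_tsv(config.blood_expr, config.blood_meta)
        synovium = cio.read_expression_tsv(config.syn_expr, config.syn_meta)
        if {blood.tissue, synovium.tissue} != {"BL", "SY"}:
            raise ParameterError("expected one BL and one SY cohort")
        if blood.tissue != "BL":
            blood, synovium = synovium, blood
        pairs = cio.read_lr_pairs(config.pairs)

        stage("preprocess")
        blood = _preprocess_tissue(blood, config, out)
        synovium = _preprocess_tissue(synovium, config, out)

        stage("differential")
        tables, degs, classes = {}, {}, {}
        for mat in (blood, synovium):
            table = differential_expression(mat, config.deg)
            table.to_csv(out / f"de_{mat.tissue.lower()}.tsv", sep="\t", lineterminator="\n")
            volcano = volcano_annotations(table, top_n=config.volcano_top_n)
            volcano.to_csv(
                out / f"volcano_{mat.tissue.lower()}.tsv", sep="\t", lineterminator="\n"
            )
            deg_set = filter_degs(table, config.deg)
            logger.info("%s: %d genes, %d DEGs", mat.tissue, len(table), len(deg_set))
            tables[mat.tissue] = table
            degs[mat.tissue] = deg_set
            classes[mat.tissue] = classify_lr(deg_set, pairs, tissue=mat.tissue)

        stage("communication map")
        cmap = build_communication_map(classes["BL"], classes["SY"], pairs)
        cio.write_communication_outputs(cmap, out)
        summary_map = summarize_map(cmap)

        stage("enrichment")
        enrichments = {}
        if config.gmt is not None:
            annotation = cio.read_gmt(config.gmt)
            for mat in (blood, synovium):
                query = set(classes[mat.tissue].ligands)
                if not query:
                    logger.info("%s: no differential ligands, skipping enrichment", mat.tissue)
                    continue
                res = enrich(query, annotation, background=set(mat.gene_ids))
                res.to_csv(
                    out / f"enrich_ligands_{mat.tissue.lower()}.tsv",
                    sep="\t",
                    index=False,
                    lineterminator="\n",
                )
                enrichments[mat.tissue] = res

        hubs = {}
        if config.ppi is not None:
            ppi_edges = cio.read_interaction_edges(config.ppi)
            for tissue in ("BL", "SY"):
                table = ligand_hubs(set(classes[tissue].ligands), ppi_edges)
                table.to_csv(
                    out / f"ligand_hubs_{tissue.lower()}.tsv",
                    sep="\t",
                    index=False,
                    lineterminator="\n",
                )
                hubs[tissue] = table

        stage("summary")
        summary = {
            "seed": config.seed,
            "genes": {"BL": blood.n_genes, "SY": synovium.n_genes},
            "samples": {"BL": blood.n_samples, "SY": synovium.n_samples},
            "deg_counts": {t: len(degs[t]) for t in ("BL", "SY")},
            "ligand_counts": {t: len(classes[t].ligands) for t in ("BL", "SY")},
            "receptor_counts": {t: len(classes[t].receptors) for t in ("BL", "SY")},
            "edge_class_counts": summary_map["class_counts"],
            "total_edges": summary_map["total_edges"],
            "top_enriched_terms": {
                t: res.head(5)[["term_id", "category", "p_value", "adj_p"]].to_dict("records")
                for t, res in enrichments.items()
            },
        }
        cio.write_json(summary, out / "summary.json")
        with open(out / "resolved_config.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    except CrosstalkError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise CrosstalkError(f"pipeline failed: {exc}") from exc

    return {
        "blood": blood,
        "synovium": synovium,
        "de_tables": tables,
        "deg_sets": degs,
        "classifications": classes,
        "communication_map": cmap,
        "map_summary": summary_map,
        "enrichments": enrichments,
        "ligand_hubs": hubs,
        "summary": summary,
    }
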