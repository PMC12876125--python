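"""Synthetic two-tissue case/control study generator with known ground truth.

Emulates the shape of the study this pipeline targets: two independent bulk
transcriptome cohorts — blood (PBMC, 33 healthy controls vs 108
osteoarthritis patients) and synovium (synovial fibroblasts, 11 vs 11) — on
the log2 scale, together with a FANTOM5/Ramilowski-style curated
ligand-receptor pair table and GO-style gene-set annotations.

Generative model per tissue: gene g in sample s has value

    x_gs = baseline_g + effect_log2 * d_g * 1[s in OA] + N(0, sigma^2)

where d_g is +1 for genes planted up in OA, -1 for planted down, 0 otherwise.
Baselines are drawn uniformly from ``baseline_range`` (independently per
tissue, mimicking platform differences). Noise is i.i.d. Gaussian on the log2
scale, the standard emulation of RMA-normalised microarray intensities. The
planted differential genes are drawn from the ligand, receptor and background
strata at configurable fractions, independently in each tissue, and recorded
in a :class:`~crosstalk.containers.TruthTable` so that every downstream stage
(differential screening, ligand/receptor classification, communication-map
construction, enrichment) can be scored against ground truth.

All operations are deterministic for a fixed seed; each draws from its own
`numpy` Generator with no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetAnnotation,
    GeneSetTerm,
    LRPairTable,
    TruthTable,
)
from .errors import ParameterError

#: term id of the planted (truly enriched) gene set in generated annotations
PLANTED_TERM_ID = "PLANTED"

_GO_CATEGORIES = ("BP", "MF", "CC")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic two-tissue study.

    Sample-size defaults follow the study cohorts (blood 33 HC / 108 OA,
    synovium 11 HC / 11 OA). The gene universe defaults to 2,000 genes — much
    smaller than real array platforms (~20-25k) but large enough to preserve
    the multiple-testing structure — with a ligand-receptor database of
    Ramilowski-like density scaled to that universe.
    """

    n_genes: int = 2000
    n_ligands: int = 120
    n_receptors: int = 120
    n_pairs: int = 250
    blood_hc_n: int = 33
    blood_oa_n: int = 108
    syn_hc_n: int = 11
    syn_oa_n: int = 11
    frac_de_ligands: float = 0.10
    frac_de_receptors: float = 0.10
    frac_de_background: float = 0.05
    effect_log2: float = 1.0
    sigma: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands + self.n_receptors > self.n_genes:
            raise ParameterError("n_ligands + n_receptors must not exceed n_genes")
        if self.n_pairs > self.n_ligands * self.n_receptors:
            raise ParameterError("n_pairs exceeds the ligand x receptor grid")
        for name in ("blood_hc_n", "blood_oa_n", "syn_hc_n", "syn_oa_n"):
            if getattr(self, name) < 2:
                raise ParameterError(f"{name} must be >= 2")
        for name in ("frac_de_ligands", "frac_de_receptors", "frac_de_background"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {f}")
        if self.effect_log2 < 0:
            raise ParameterError("effect_log2 must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ParameterError("baseline_range must satisfy low < high")


def _symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_lr_database(
    n_ligands: int, n_receptors: int, n_pairs: int, seed: int
) -> LRPairTable:
    """Draw ``n_pairs`` distinct ligand->receptor pairs over synthetic symbols.

    Ligands are named ``LIG0001..``, receptors ``REC0001..`` (disjoint
    universes by construction, which keeps truth-table recovery unambiguous).
    Pairs are sampled without replacement from the full cross grid, so a
    symbol may participate in zero or many pairs, as in curated databases.
    """
    if n_ligands < 1 or n_receptors < 1:
        raise ParameterError("need at least one ligand and one receptor")
    if n_pairs < 0 or n_pairs > n_ligands * n_receptors:
        raise ParameterError(
            f"n_pairs={n_pairs} infeasible for a {n_ligands} x {n_receptors} grid"
        )
    ligands = _symbols("LIG", n_ligands)
    receptors = _symbols("REC", n_receptors)
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_ligands * n_receptors, size=n_pairs, replace=False)
    flat.sort()
    pairs = [(ligands[i // n_receptors], receptors[i % n_receptors]) for i in flat]
    return LRPairTable(pairs=pairs)


def _plant(
    rng: np.random.Generator,
    ligands: list[str],
    receptors: list[str],
    background: list[str],
    cfg: SyntheticConfig,
) -> dict[str, str]:
    """Select DE genes per stratum and assign up/down directions."""
    chosen: list[str] = []
    for pool, frac in (
        (ligands, cfg.frac_de_ligands),
        (receptors, cfg.frac_de_receptors),
        (background, cfg.frac_de_background),
    ):
        k = int(round(frac * len(pool)))
        if k > 0:
            chosen.extend(str(g) for g in rng.choice(pool, size=k, replace=False))
    directions = rng.choice(["up", "down"], size=len(chosen))
    return {g: str(d) for g, d in zip(chosen, directions)}


def _tissue_matrix(
    rng: np.random.Generator,
    tissue: str,
    genes: list[str],
    hc_n: int,
    oa_n: int,
    planted: dict[str, str],
    cfg: SyntheticConfig,
) -> ExpressionMatrix:
    n_genes = len(genes)
    lo, hi = cfg.baseline_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    n_samples = hc_n + oa_n
    values = baseline[:, None] + rng.normal(0.0, cfg.sigma, size=(n_genes, n_samples))
    sign = {"up": 1.0, "down": -1.0}
    for i, g in enumerate(genes):
        if g in planted:
            values[i, hc_n:] += cfg.effect_log2 * sign[planted[g]]
    sample_ids = [f"{tissue}_HC_{i + 1:03d}" for i in range(hc_n)] + [
        f"{tissue}_OA_{i + 1:03d}" for i in range(oa_n)
    ]
    groups = ["HC"] * hc_n + ["OA"] * oa_n
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    return ExpressionMatrix(
        values=df,
        sample_group=pd.Series(groups, index=sample_ids, name="group"),
        tissue=tissue,
    )


def generate_two_tissue_study(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Generate blood and synovium cohorts plus the ground-truth table.

    The gene universe is the ligand symbols, the receptor symbols, then
    background genes ``GENE0001..`` up to ``n_genes``. Differential genes are
    planted independently per tissue (the two cohorts are independent
    studies); the shared pair database ties them together downstream.
    """
    cfg = config
    pairs = generate_lr_database(cfg.n_ligands, cfg.n_receptors, cfg.n_pairs, seed=cfg.seed)
    ligands = _symbols("LIG", cfg.n_ligands)
    receptors = _symbols("REC", cfg.n_receptors)
    background = _symbols("GENE", cfg.n_genes - cfg.n_ligands - cfg.n_receptors)
    genes = ligands + receptors + background

    ss = np.random.SeedSequence(cfg.seed)
    s_plant_bl, s_plant_sy, s_bl, s_sy = ss.spawn(4)
    planted_bl = _plant(np.random.default_rng(s_plant_bl), ligands, receptors, background, cfg)
    planted_sy = _plant(np.random.default_rng(s_plant_sy), ligands, receptors, background, cfg)
    if cfg.effect_log2 == 0.0:
        planted_bl, planted_sy = {}, {}

    blood = _tissue_matrix(
        np.random.default_rng(s_bl), "BL", genes, cfg.blood_hc_n, cfg.blood_oa_n, planted_bl, cfg
    )
    synovium = _tissue_matrix(
        np.random.default_rng(s_sy), "SY", genes, cfg.syn_hc_n, cfg.syn_oa_n, planted_sy, cfg
    )
    truth = TruthTable(
        de={"BL": planted_bl, "SY": planted_sy},
        ligand_set=frozenset(ligands),
        receptor_set=frozenset(receptors),
        pair_list=list(pairs.pairs),
    )
    return blood, synovium, truth


def generate_gene_sets(
    genes: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    planted_term_genes: set[str],
    seed: int,
) -> GeneSetAnnotation:
    """Random GO-style annotation plus one planted term.

    Returns ``n_terms`` random sets with sizes uniform in ``size_range`` and
    categories cycling over BP/MF/CC at random, plus one term with id
    :data:`PLANTED_TERM_ID` whose members are exactly ``planted_term_genes``
    (the set a truly enriched query should recover).
    """
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ParameterError("size_range must satisfy 1 <= min <= max")
    if hi > len(genes):
        raise ParameterError("size_range max exceeds the gene universe")
    missing = set(planted_term_genes) - set(genes)
    if missing:
        raise ParameterError(f"planted_term_genes not in universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: list[GeneSetTerm] = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        cat = str(rng.choice(_GO_CATEGORIES))
        terms.append(
            GeneSetTerm(
                term_id=f"TERM{i + 1:04d}",
                term_name=f"random term {i + 1}",
                category=cat,
                genes=frozenset(map(str, members)),
            )
        )
    terms.append(
        GeneSetTerm(
            term_id=PLANTED_TERM_ID,
            term_name="planted enriched term",
            category="BP",
            genes=frozenset(planted_term_genes),
        )
    )
    return GeneSetAnnotation(terms=terms)
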