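"""Generate the synthetic two-tissue study used by the rest of the analysis.

Emulates the study design: a blood cohort (PBMC, 33 healthy controls vs 108
osteoarthritis patients) and a synovium cohort (synovial fibroblasts, 11 vs
11) over 2,000 genes, with a 250-pair ligand-receptor database, planted
differential genes, GO-style gene sets (one truly enriched among the planted
blood ligands), and the full ground-truth table.

Writes expression/metadata TSVs, the pair table, the GMT and truth.json
under results/analysis/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from crosstalk import io as cio
from crosstalk.containers import LRPairTable
from crosstalk.synthetic import SyntheticConfig, generate_gene_sets, generate_two_tissue_study

SEED = 20240501
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis" / "data"


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    blood, synovium, truth = generate_two_tissue_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    cio.write_expression_tsv(blood, OUT / "expr_bl.tsv", OUT / "meta_bl.tsv")
    cio.write_expression_tsv(synovium, OUT / "expr_sy.tsv", OUT / "meta_sy.tsv")
    cio.write_lr_pairs(LRPairTable(pairs=truth.pair_list), OUT / "lr_pairs.tsv")
    planted_ligands = sorted(truth.de_genes("BL") & truth.ligand_set)
    ann = generate_gene_sets(blood.gene_ids, 50, (10, 50), set(planted_ligands), seed=SEED)
    cio.write_gmt(ann, OUT / "gene_sets.gmt")
    cio.write_json(truth.to_json_dict(), OUT / "truth.json")
    print(f"blood: {blood.values.shape[0]} genes x {blood.values.shape[1]} samples")
    print(f"synovium: {synovium.values.shape[0]} genes x {synovium.values.shape[1]} samples")
    print(f"pair database: {len(truth.pair_list)} pairs")
    print(
        f"planted DE: blood {len(truth.de['BL'])} genes "
        f"({len(planted_ligands)} ligands), synovium {len(truth.de['SY'])} genes"
    )
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
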