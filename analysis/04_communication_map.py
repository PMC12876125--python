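"""Ligand-receptor classification and the blood/synovium communication map.

Intersects each tissue's DEGs with the pair database, builds the directed
four-class map (BL->BL, BL->SY, SY->BL, SY->SY), serialises it (edge TSV,
GraphML, chord JSON) and verifies against ground truth that every planted
(blood ligand, synovium receptor) database pair surfaced as a BL->SY edge.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from crosstalk import io as cio
from crosstalk.containers import TruthTable
from crosstalk.differential import DEGConfig, filter_degs
from crosstalk.lrmap import build_communication_map, classify_lr, summarize_map

ROOT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    out = ROOT / "map"
    out.mkdir(parents=True, exist_ok=True)
    truth = TruthTable.from_json_dict(json.loads((ROOT / "data" / "truth.json").read_text()))
    pairs = cio.read_lr_pairs(ROOT / "data" / "lr_pairs.tsv")
    cfg = DEGConfig()
    classes = {}
    for tag, tissue in (("bl", "BL"), ("sy", "SY")):
        table = pd.read_csv(ROOT / "de" / f"de_{tag}.tsv", sep="\t", index_col=0)
        classes[tissue] = classify_lr(filter_degs(table, cfg), pairs, tissue=tissue)
        print(
            f"{tissue}: {len(classes[tissue].ligands)} differential ligands, "
            f"{len(classes[tissue].receptors)} differential receptors"
        )
    cmap = build_communication_map(classes["BL"], classes["SY"], pairs)
    cio.write_communication_outputs(cmap, out)
    summary = summarize_map(cmap)
    cio.write_json(
        {"class_counts": summary["class_counts"], "total_edges": summary["total_edges"]},
        out / "map_summary.json",
    )
    print(f"communication map: {summary['total_edges']} edges, {summary['class_counts']}")

    planted_lig = truth.de_genes("BL") & truth.ligand_set
    planted_rec = truth.de_genes("SY") & truth.receptor_set
    expected = {(l, r) for l, r in truth.pair_list if l in planted_lig and r in planted_rec}
    got = {(e.ligand, e.receptor) for e in cmap.edges if e.direction_class == "BL->SY"}
    print(
        f"planted blood-ligand -> synovium-receptor pairs recovered: "
        f"{len(expected & got)}/{len(expected)}"
    )


if __name__ == "__main__":
    main()
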