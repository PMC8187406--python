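#!/usr/bin/env python
"""Run the full pipeline on the simulated study and report the funnel.

Detection filtering (4 of 5 samples) -> gene conversion -> placenta
expression verification -> ortholog consensus (one-to-many excluded) ->
secretion classification -> integration into the secretome map with
tissue-enrichment, complication overlays and over-representation
statistics. Outputs land in results/pipeline/.
"""

import json
from pathlib import Path

from secretomap.pipeline import PipelineConfig, run_all
from secretomap.syndata import GroundTruth, SimConfig, Study

ROOT = Path(__file__).resolve().parents[1]


def load_study() -> Study:
    out_dir = ROOT / "results" / "study"
    cfg = SimConfig.from_json(out_dir / "sim_config.json")
    names = {
        "detection_cells": "detection_cells.tsv",
        "detection_media": "detection_media.tsv",
        "detection_sorted": "detection_sorted.tsv",
        "idmap": "idmap.tsv", "orthologs": "ortholog_assertions.tsv",
        "secretion": "secretion_annotations.tsv",
        "mouse_expression": "mouse_expression.tsv",
        "human_expression": "human_expression.tsv",
        "complications": "complication_sets.tsv",
        "organoid_secretome": "organoid_secretome.txt",
        "stb_expressed": "stb_expressed.txt", "damp": "damp.txt",
        "plasma": "plasma_quant.tsv", "plasma_groups": "plasma_groups.tsv",
        "biomarkers": "biomarkers.tsv", "promoters": "promoters.fasta",
        "motifs": "motifs.meme", "regulators": "regulator_predictions.tsv",
        "complication_tfs": "complication_tfs.tsv",
    }
    paths = {k: out_dir / v for k, v in names.items()}
    gt = GroundTruth.from_json(out_dir / "ground_truth.json")
    return Study(out_dir=out_dir, paths=paths, ground_truth=gt, config=cfg)


def main() -> None:
    study = load_study()
    res = run_all(PipelineConfig.from_study(study), ROOT / "results" / "pipeline")

    print("per-stream secreted gene counts (cells / media / sorted):")
    sizes = {s: len(g) for s, g in res["stream_secreted"].items()}
    print(f"  {sizes}")
    common = res["venn"][("cells", "media", "sorted")]
    print(f"  common to all three streams: {common}")
    shared = [e for e in res["entries"] if e.shared_with_human]
    print(f"secretome map: {len(res['entries'])} genes, "
          f"{len(shared)} shared mouse+human, "
          f"{len(res['entries']) - len(shared)} mouse-only")
    print(f"placenta-enriched (>10-fold vs other tissues): "
          f"{len(res['enriched'])}")
    summary = res["overlay_summary"]
    print(f"complication-flagged genes: {summary['n_flagged']}; shared by >= "
          f"{summary['shared_min_k']['k']} complications: "
          f"{len(summary['shared_min_k']['genes'])}")
    top = res["ora"].head(3)[["category", "overlap", "p_value", "q_value"]]
    print("top over-represented complication sets:")
    print(top.to_string(index=False))

    funnel = json.loads((ROOT / "results/pipeline/funnel.json").read_text())
    print(f"funnel report: {len(funnel)} stages -> results/pipeline/funnel.json")
    print(f"manifest: {res['manifest_path']}")


if __name__ == "__main__":
    main()
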