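#!/usr/bin/env python
"""TF funnel: motif enrichment, two-route consensus, STB filter, network.

Promoters (TSS -1000..+100) of the shared secretome genes are scanned for
PWM hits against non-secretome promoters (Fisher enrichment, BH), enriched
motifs are intersected with the upstream-regulator predictions, surviving
TFs are filtered for syncytiotrophoblast expression and secretome targets,
and the complication-linked subset forms the regulatory network.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pipe = ROOT / "results" / "pipeline"
    enr = pd.read_csv(pipe / "motif_enrichment.tsv", sep="\t")
    print("motif enrichment (foreground = shared-secretome promoters):")
    cols = ["motif", "fg_hits", "fg_total", "bg_hits", "bg_total", "q_value"]
    print(enr[cols].head(8).to_string(index=False))

    edges = pd.read_csv(pipe / "tf_network_edges.tsv", sep="\t")
    n_tfs = edges["tf"].nunique() if len(edges) else 0
    n_targets = edges["target"].nunique() if len(edges) else 0
    funnel = [e for e in json.loads((pipe / "funnel.json").read_text())]
    print(f"network: {n_tfs} complication-linked TFs -> {n_targets} secretome "
          f"targets ({len(edges)} edges); GraphML at "
          f"{pipe / 'tf_network.graphml'}")
    print(f"full stage funnel: {len(funnel)} entries in "
          f"{pipe / 'funnel.json'}")


if __name__ == "__main__":
    main()
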