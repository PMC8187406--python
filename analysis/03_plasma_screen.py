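#!/usr/bin/env python
"""Summarize the mouse plasma screen: normalization, folds, clustering.

Peak areas are expressed relative to the spiked bovine-insulin internal
standard, per-protein pregnancy fold changes (pregnant vs non-pregnant
means) are classified at the 1.5-fold threshold, and the row-Z-scored
matrix is clustered by average linkage under Spearman distance.
"""

from pathlib import Path

import pandas as pd

from secretomap.plasma import (
    hcluster, normalize_to_standard, pregnancy_fold_change, row_zscore,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    out = ROOT / "results" / "plasma"
    out.mkdir(parents=True, exist_ok=True)
    quant = pd.read_csv(study / "plasma_quant.tsv", sep="\t", index_col=0)
    gdf = pd.read_csv(study / "plasma_groups.tsv", sep="\t")
    groups = dict(zip(gdf["animal"], gdf["group"]))
    n_np = sum(v == "NP" for v in groups.values())
    n_p = sum(v == "P" for v in groups.values())

    normalized = normalize_to_standard(quant)
    folds = pregnancy_fold_change(normalized, groups, threshold=1.5)
    folds.to_csv(out / "folds.tsv", sep="\t")
    higher = folds[folds["higher_in_pregnancy"]].sort_values(
        "fold_p_vs_np", ascending=False)
    print(f"plasma screen: {len(normalized)} proteins in {n_np} non-pregnant "
          f"and {n_p} pregnant animals")
    print(f"{len(higher)} proteins higher in pregnancy (>= 1.5-fold); "
          f"range {higher['fold_p_vs_np'].min():.2f}- "
          f"{higher['fold_p_vs_np'].max():.2f}-fold")

    zs = row_zscore(normalized)
    zs.to_csv(out / "zscore.tsv", sep="\t")
    variable = zs.loc[zs.std(axis=1) > 0]
    rows = hcluster(variable, axis="rows")
    cols = hcluster(variable, axis="columns")
    (out / "rows.nwk").write_text(rows.to_newick() + "\n")
    (out / "columns.nwk").write_text(cols.to_newick() + "\n")
    print(f"clustered {len(variable)} proteins x {zs.shape[1]} animals; "
          f"column leaf order: {' '.join(cols.leaf_order)}")


if __name__ == "__main__":
    main()
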