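#!/usr/bin/env python
"""Generate the synthetic study that stands in for the raw MS datasets.

Emits every pipeline input (three detection streams, ID map, ortholog
assertions, secretion annotations, expression tables, complication sets,
plasma screen, serum cohort, promoters + motifs, regulator predictions)
under results/study/, with the planted ground truth saved alongside in
ground_truth.json (read by nothing downstream).
"""

from pathlib import Path

from secretomap.syndata import SimConfig, generate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimConfig(seed=1)
    study = generate_study(cfg, ROOT / "results" / "study")
    gt = study.ground_truth
    print(f"study written to {study.out_dir} ({len(study.paths)} files)")
    print(f"  genes: {cfg.n_genes}, samples/stream: {cfg.n_samples_per_stream},"
          f" dropout: {cfg.detection_dropout}")
    print(f"  planted secreted genes:          {len(gt.true_secreted)}")
    print(f"  one-to-one orthologs:            {len(gt.true_ortholog_pairs)}")
    print(f"  one-to-many (to be excluded):    {len(gt.true_one_to_many)}")
    print(f"  planted shared secretome:        {len(gt.true_shared_secretome)}")
    print(f"  plasma proteins screened:        {len(gt.true_pregnancy_fold)}")
    print(f"  planted TF-target edges:         {len(gt.true_tf_edges)}")


if __name__ == "__main__":
    main()
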