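"""End-to-end orchestration: evidence -> ortho -> secrete -> map -> plasma ->
biomarker -> tfnet, with a funnel report and a reproducibility manifest.

Every stage reads and writes plain text tables, so composing the stages
here is equivalent to running them individually on the intermediate files;
the manifest records the configuration hash, the seed and a checksum of
every output, making reruns byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from secretomap import biomarker as bm
from secretomap import evidence, mapbuild, ortho, plasma, secrete, tfnet
from secretomap.logs import StageLog, write_funnel

logger = logging.getLogger("secretomap")

STREAMS = ("cells", "media", "sorted")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All input paths and analysis constants for one pipeline run.

    The defaults are the pipeline's canonical constants: detection in 4 of
    5 samples, extracellular GO evidence terms, 10-fold tissue enrichment,
    1.5-fold pregnancy classification, healthy-reference MoM, pooled
    t-test, PWM threshold at 60% of the maximal log-odds score.
    """

    # input paths
    detection: dict[str, str] = field(default_factory=dict)  # stream -> path
    idmap: str = ""
    orthologs: str = ""
    secretion: str = ""
    mouse_expression: str = ""
    human_expression: str = ""
    complications: str = ""
    overlays: dict[str, str] = field(default_factory=dict)  # name -> path
    plasma_quant: str = ""
    plasma_groups: str = ""
    biomarkers: str = ""
    promoters: str = ""
    motifs: str = ""
    regulators: str = ""
    complication_tfs: str = ""
    # analysis constants
    k_of_n: tuple[int, int] = (4, 5)
    min_expression: float = 1.0
    human_min_expression: float = 1.0
    secretion_go_terms: tuple[str, ...] = tuple(
        sorted(secrete.DEFAULT_SECRETION_GO_TERMS))
    tissue_fold: float = 10.0
    pregnancy_fold_threshold: float = 1.5
    mom_reference: str = "healthy"
    test_variant: str = "student"
    pwm_threshold_fraction: float = 0.6
    alpha: float = 0.05
    min_shared_complications: int = 2
    seed: int = 0

    def validate(self) -> None:
        k, n = self.k_of_n
        if not 1 <= k <= n:
            raise ValueError(f"k_of_n requires 1 <= k <= n, got ({k}, {n})")
        for name in ("tissue_fold", "pregnancy_fold_threshold", "alpha",
                     "pwm_threshold_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.secretion_go_terms:
            raise ValueError("secretion_go_terms must be non-empty")
        if self.test_variant not in ("student", "welch"):
            raise ValueError(f"unknown test_variant {self.test_variant!r}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["k_of_n"] = list(self.k_of_n)
        d["secretion_go_terms"] = list(self.secretion_go_terms)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["k_of_n"] = tuple(d["k_of_n"])
        d["secretion_go_terms"] = tuple(d["secretion_go_terms"])
        return cls(**d)

    @classmethod
    def from_study(cls, study, **overrides) -> "PipelineConfig":
        """Build a config pointing at a generated study's files."""
        p = {k: str(v) for k, v in study.paths.items()}
        cfg = cls(
            detection={s: p[f"detection_{s}"] for s in STREAMS},
            idmap=p["idmap"],
            orthologs=p["orthologs"],
            secretion=p["secretion"],
            mouse_expression=p["mouse_expression"],
            human_expression=p["human_expression"],
            complications=p["complications"],
            overlays={
                "organoid_secretome": p["organoid_secretome"],
                "stb_expressed": p["stb_expressed"],
                "damp": p["damp"],
            },
            plasma_quant=p["plasma"],
            plasma_groups=p["plasma_groups"],
            biomarkers=p["biomarkers"],
            promoters=p["promoters"],
            motifs=p["motifs"],
            regulators=p["regulators"],
            complication_tfs=p["complication_tfs"],
            k_of_n=(4, study.config.n_samples_per_stream),
            seed=study.config.seed,
        )
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _read_gene_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages in order; returns the result bundle.

    On any stage failure, partial outputs are retained, a FAILED marker
    naming the stage is written, and a :class:`StageError` is raised.
    The result dict keys: stream_secreted, entries, venn, enriched,
    overlay_summary, ora, plasma (normalized/folds/zscore/trees),
    biomarker (mom/ratios/tests), tfnet (enrichment/funnel/network),
    funnel, manifest_path.
    """
    config.validate()  # reject before any stage runs
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs: list[StageLog] = []
    results: dict = {}
    stage = "setup"
    try:
        # ---- evidence -------------------------------------------------------
        stage = "evidence"
        k, n = config.k_of_n
        idmap = evidence.read_idmap(config.idmap)
        mouse_expr = pd.read_csv(config.mouse_expression, sep="\t", index_col=0)
        stream_verified: dict[str, set[str]] = {}
        for s in STREAMS:
            mat = evidence.read_detection(config.detection[s], s)
            kept, lg = evidence.filter_k_of_n(mat, k=k, n=n)
            logs.append(lg)
            genes, _unmapped, lg = evidence.map_to_genes(kept, idmap)
            logs.append(lg)
            verified, lg = evidence.verify_expression(
                genes, mouse_expr, "placenta", config.min_expression)
            logs.append(lg)
            stream_verified[s] = verified

        # ---- ortho ----------------------------------------------------------
        stage = "ortho"
        assertions = ortho.read_assertions(config.orthologs)
        universe = set().union(*stream_verified.values())
        omap = ortho.build_consensus(assertions, universe)
        omap.to_frame().to_csv(out / "ortholog_map.tsv", sep="\t", index=False)

        # ---- secrete --------------------------------------------------------
        stage = "secrete"
        annotations = secrete.read_annotations(config.secretion)
        go_terms = frozenset(config.secretion_go_terms)
        stream_secreted: dict[str, set[str]] = {}
        for s in STREAMS:
            part, lg = secrete.classify_set(
                annotations, stream_verified[s], go_terms)
            logs.append(lg)
            stream_secreted[s] = part.secreted
        results["stream_secreted"] = stream_secreted

        # ---- mapbuild -------------------------------------------------------
        stage = "map"
        secreted_union = set().union(*stream_secreted.values())
        pairs, lg = ortho.apply_exclusion(omap, secreted_union)
        logs.append(lg)
        human_expr = pd.read_csv(config.human_expression, sep="\t", index_col=0)
        human_expressed = set(
            human_expr.index[human_expr["placenta"] >= config.human_min_expression])
        entries, lg = mapbuild.integrate_streams(
            stream_secreted, pairs, human_expressed)
        logs.append(lg)
        results["venn"] = mapbuild.venn_counts(stream_secreted)
        shared_mouse = {e.mouse_gene for e in entries if e.shared_with_human}
        shared_human = {e.human_gene for e in entries if e.shared_with_human}
        results["enriched"] = mapbuild.tissue_enrichment(
            mouse_expr, shared_mouse, "placenta", config.tissue_fold)
        comp_df = pd.read_csv(config.complications, sep="\t", dtype=str)
        comp_sets = {c: set(g["gene"]) for c, g in comp_df.groupby("complication")}
        entries, summary = mapbuild.complication_overlay(
            entries, comp_sets, config.min_shared_complications)
        results["overlay_summary"] = summary
        results["ora"] = mapbuild.overrepresentation(
            shared_human, set(human_expr.index) | shared_human, comp_sets)
        results["ora"].to_csv(out / "overrepresentation.tsv", sep="\t",
                              index=False)

        # ---- plasma ---------------------------------------------------------
        stage = "plasma"
        quant = pd.read_csv(config.plasma_quant, sep="\t", index_col=0)
        groups_df = pd.read_csv(config.plasma_groups, sep="\t")
        groups = dict(zip(groups_df["animal"], groups_df["group"]))
        normalized = plasma.normalize_to_standard(quant)
        folds = plasma.pregnancy_fold_change(
            normalized, groups, threshold=config.pregnancy_fold_threshold)
        folds.to_csv(out / "plasma_folds.tsv", sep="\t")
        zs = plasma.row_zscore(normalized)
        zs.to_csv(out / "plasma_zscore.tsv", sep="\t")
        # constant vectors carry no ordering information for a rank-based
        # distance; drop them from the clustered heat-map matrix
        variable = zs.loc[zs.std(axis=1) > 0]
        trees = {}
        if len(variable) >= 2:
            trees["rows"] = plasma.hcluster(variable, axis="rows")
            (out / "plasma_rows.nwk").write_text(trees["rows"].to_newick() + "\n")
        col_ok = variable.loc[:, variable.std(axis=0) > 0]
        if col_ok.shape[1] >= 2 and len(variable) >= 3:
            trees["columns"] = plasma.hcluster(col_ok, axis="columns")
            (out / "plasma_columns.nwk").write_text(
                trees["columns"].to_newick() + "\n")
        plasma_detected = set(normalized.index)
        results["plasma"] = {"normalized": normalized, "folds": folds,
                             "zscore": zs, "trees": trees}
        n_higher = int(folds["higher_in_pregnancy"].sum())
        logs.append(StageLog("plasma:pregnancy_fold", len(folds), n_higher,
                             len(folds) - n_higher))

        # overlays need the plasma screen result
        overlay_sets = {name: _read_gene_set(path)
                        for name, path in config.overlays.items()}
        overlay_sets["plasma_detected"] = plasma_detected
        entries = mapbuild.apply_overlays(entries, overlay_sets)
        results["entries"] = entries
        mapbuild.entries_to_frame(entries).to_csv(
            out / "secretome_map.tsv", sep="\t", index=False)

        # ---- biomarker ------------------------------------------------------
        stage = "biomarker"
        cohort = pd.read_csv(config.biomarkers, sep="\t")
        moms = bm.compute_mom(cohort, reference=config.mom_reference)
        moms.to_csv(out / "biomarker_mom.tsv", sep="\t", index=False)
        ratios = {}
        for num, den in (("sFLT1", "MIF"), ("ANGPT2", "MIF")):
            r = bm.mom_ratio(moms, num, den)
            wk12 = r[r["week"] == 12]
            case = wk12.loc[wk12["group"] == "GDM", "ratio"]
            ref = wk12.loc[wk12["group"] == "healthy", "ratio"]
            t, df, p = bm.two_sample_ttest(case, ref, config.test_variant)
            ratios[f"{num}/{den}"] = {
                "percent_increase": bm.percent_increase(case, ref),
                "t": t, "df": df, "p": p,
            }
        anova = {}
        for analyte in sorted(moms["analyte"].unique()):
            sub = moms[moms["analyte"] == analyte]
            anova[analyte] = bm.two_way_anova(
                sub["mom"], sub["group"], sub["week"])
        results["biomarker"] = {"mom": moms, "ratios": ratios, "anova": anova}
        with open(out / "biomarker_tests.json", "w") as fh:
            json.dump({"ratios": ratios,
                       "anova": {a: {f: dict(v) for f, v in r.items()}
                                 for a, r in anova.items()}}, fh, indent=2)

        # ---- tfnet ----------------------------------------------------------
        stage = "tfnet"
        promoters = tfnet.read_promoters(config.promoters)
        pwms = tfnet.read_meme(config.motifs)
        fg = {g: s for g, s in promoters.items() if g in shared_human}
        bg = {g: s for g, s in promoters.items() if g not in shared_human}
        enr = tfnet.motif_enrichment(
            fg, bg, pwms, threshold_fraction=config.pwm_threshold_fraction)
        enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        sig = enr[enr["q_value"] < config.alpha]
        motif_preds = [
            tfnet.TFPrediction(row.motif, t, "motif_enrichment")
            for row in sig.itertuples(index=False)
            for t in (row.targets.split(";") if row.targets else [])
        ]
        reg_preds = tfnet.read_predictions(config.regulators)
        both = tfnet.consensus_tfs(motif_preds, reg_preds)
        stb = _read_gene_set(config.overlays["stb_expressed"])
        filtered = tfnet.filter_by_expression(both, stb, shared_human)
        ctf_df = pd.read_csv(config.complication_tfs, sep="\t", dtype=str)
        comp_tfs = {r.tf: set(r.complications.split(";"))
                    for r in ctf_df.itertuples(index=False)}
        linked = {tf: tg for tf, tg in filtered.items() if tf in comp_tfs}
        network = tfnet.build_network(linked, comp_tfs, comp_sets)
        tfnet.export_network(network, out / "tf_network_edges.tsv",
                             out / "tf_network.graphml")
        funnel_tf = {
            "motif_enriched": int(len(sig)),
            "regulator_predicted": len({p.tf for p in reg_preds}),
            "both_tools": len(both),
            "stb_filtered": len(filtered),
            "complication_linked": len(linked),
        }
        results["tfnet"] = {"enrichment": enr, "both": both,
                            "filtered": filtered, "network": network,
                            "funnel": funnel_tf}
        for name, cnt in funnel_tf.items():
            logger.info("tf funnel %s: %d", name, cnt)

        # ---- reports --------------------------------------------------------
        stage = "report"
        results["funnel"] = logs
        write_funnel(logs, out / "funnel.json")
        config.to_json(out / "pipeline_config.json")
        outputs = sorted(p for p in out.iterdir()
                         if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest_path"] = manifest_path
        results["manifest"] = manifest
    except Exception as exc:  # halt with the stage name; keep partial output
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc
    return results
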