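"""Synthetic study generator with retained ground truth.

Emulates every input the secretome pipeline consumes — per-sample detection
tables for three sample streams, accession-to-gene maps, ortholog assertions
from three sources, secretion annotations, tissue/cell-type expression
tables, complication gene sets, a plasma screen with a spiked internal
standard, a serum biomarker cohort, promoter sequences with planted motif
occurrences, and upstream-regulator predictions — while recording the
planted truth (secreted set, orthology, pregnancy folds, GDM effects,
TF-target edges) in a separate machine-readable file that the pipeline
itself never reads.

The default configuration mirrors the study design the pipeline was built
around: five biological replicates per MS stream with a 4-of-5 detection
rule downstream, a cohort of 10 healthy and 6 GDM pregnancies sampled at
gestational weeks 12 and 28, a plasma screen of 3 non-pregnant versus 8
pregnant animals over 45 detectable proteins, and promoter windows of
1100 bp (TSS -1000..+100).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from secretomap.tfnet import PWM, write_meme

STREAMS = ("cells", "media", "sorted")
ANALYTES = ("sFLT1", "MIF", "ANGPT2", "IGF2")
WEEKS = (12, 28)
TISSUES = ("placenta", "brain", "liver", "kidney", "lung", "heart",
           "spleen", "muscle")
COMPLICATIONS = ("PE", "GDM", "IUGR", "SGA", "LGA")

#: Healthy-group median serum concentrations by analyte and week (assay
#: units): sFLT1 rises with gestation, ANGPT2 and MIF decline, IGF2 is flat.
HEALTHY_MEDIANS = {
    "sFLT1": {12: 1500.0, 28: 3200.0},
    "MIF": {12: 20.0, 28: 12.0},
    "ANGPT2": {12: 18.0, 28: 9.0},
    "IGF2": {12: 550.0, 28: 540.0},
}

#: Default multiplicative GDM effects by analyte and week: the week-12
#: sFLT1 and ANGPT2 effects (x3.1 and x1.97 against an unchanged MIF)
#: produce ~+210% and ~+97% increases of the sFLT1/MIF and ANGPT2/MIF
#: MoM ratios; the week-28 MIF effect encodes the failure of MIF to
#: decline with gestation under GDM.
DEFAULT_GDM_EFFECTS = {
    "sFLT1": {12: 3.1, 28: 1.3},
    "MIF": {12: 1.0, 28: 1.4},
    "ANGPT2": {12: 1.97, 28: 1.0},
    "IGF2": {12: 1.0, 28: 1.0},
}

NON_SECRETION_GO = ("GO:0005739", "GO:0005634", "GO:0005737", "GO:0016020")
SECRETION_GO = ("GO:0005576", "GO:0005615", "GO:0070062", "GO:0044421")


@dataclass
class SimConfig:
    """Study-generation parameters; ``validate`` names the offending field."""

    n_genes: int = 500
    n_samples_per_stream: int = 5
    detection_dropout: float = 0.10
    lognormal_sigma: float = 0.5
    n_healthy: int = 10
    n_gdm: int = 6
    biomarker_sigma: float = 0.3
    seed: int = 0
    # orthology
    frac_one_to_many: float = 0.10
    frac_unmapped: float = 0.08
    ortholog_conflict_rate: float = 0.4
    # secretion / expression
    frac_secreted: float = 0.35
    frac_mouse_expressed: float = 0.90
    frac_human_expressed: float = 0.90
    n_enriched: int = 20
    enriched_fold: float = 12.0
    background_fold: float = 2.0
    # plasma screen
    n_plasma_proteins: int = 45
    n_np: int = 3
    n_p: int = 8
    plasma_sigma: float = 0.2
    # promoters / motifs
    motif_length: int = 10
    n_promoters: int = 60
    promoter_length: int = 1100
    planted_occurrence_rate: float = 0.6
    background_occurrence_rate: float = 0.05
    n_tfs: int = 12

    def validate(self) -> None:
        counts = ("n_genes", "n_samples_per_stream", "n_healthy", "n_gdm",
                  "n_enriched", "n_plasma_proteins", "n_np", "n_p",
                  "motif_length", "n_promoters", "promoter_length", "n_tfs")
        for name in counts:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        probs = ("detection_dropout", "frac_one_to_many", "frac_unmapped",
                 "ortholog_conflict_rate", "frac_secreted",
                 "frac_mouse_expressed", "frac_human_expressed",
                 "planted_occurrence_rate", "background_occurrence_rate")
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("lognormal_sigma", "biomarker_sigma", "plasma_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("enriched_fold", "background_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.motif_length < 4:
            raise ValueError("motif_length must be >= 4")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """Planted truth saved beside the generated study; never read by the pipeline."""

    true_secreted: set[str]
    true_ortholog_pairs: dict[str, str]
    true_one_to_many: set[str]
    true_unmapped: set[str]
    true_placenta_expressed_mouse: set[str]
    true_placenta_expressed_human: set[str]
    true_pregnancy_fold: dict[str, float]
    true_gdm_effects: dict[str, dict[int, float]]
    true_tf_edges: set[tuple[str, str]]
    true_complication_sets: dict[str, set[str]]
    stream_membership: dict[str, set[str]] = field(default_factory=dict)
    true_enriched_mouse: set[str] = field(default_factory=set)
    true_plasma_detected: set[str] = field(default_factory=set)
    true_motif_tfs: set[str] = field(default_factory=set)
    true_regulator_tfs: set[str] = field(default_factory=set)
    true_stb_expressed: set[str] = field(default_factory=set)
    true_complication_tfs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_one_to_many & set(self.true_ortholog_pairs):
            raise ValueError("one-to-many genes must be disjoint from pair domain")
        if any(f <= 0 for f in self.true_pregnancy_fold.values()):
            raise ValueError("pregnancy folds must be positive")
        for eff in self.true_gdm_effects.values():
            if any(m <= 0 for m in eff.values()):
                raise ValueError("GDM effect multipliers must be positive")

    @property
    def true_shared_secretome(self) -> set[str]:
        """Mouse genes that the noise-free pipeline must recover as shared:
        secreted, placenta-expressed, one-to-one ortholog with a
        placenta-expressed human partner."""
        return {
            g for g in self.true_secreted & self.true_placenta_expressed_mouse
            if g in self.true_ortholog_pairs
            and self.true_ortholog_pairs[g] in self.true_placenta_expressed_human
        }

    def to_json(self, path: str | Path) -> None:
        enc = {
            "true_secreted": sorted(self.true_secreted),
            "true_ortholog_pairs": dict(sorted(self.true_ortholog_pairs.items())),
            "true_one_to_many": sorted(self.true_one_to_many),
            "true_unmapped": sorted(self.true_unmapped),
            "true_placenta_expressed_mouse":
                sorted(self.true_placenta_expressed_mouse),
            "true_placenta_expressed_human":
                sorted(self.true_placenta_expressed_human),
            "true_pregnancy_fold": dict(sorted(self.true_pregnancy_fold.items())),
            "true_gdm_effects": {
                a: {str(w): m for w, m in sorted(e.items())}
                for a, e in sorted(self.true_gdm_effects.items())},
            "true_tf_edges": sorted(map(list, self.true_tf_edges)),
            "true_complication_sets": {
                c: sorted(g) for c, g in sorted(self.true_complication_sets.items())},
            "stream_membership": {
                s: sorted(g) for s, g in sorted(self.stream_membership.items())},
            "true_enriched_mouse": sorted(self.true_enriched_mouse),
            "true_plasma_detected": sorted(self.true_plasma_detected),
            "true_motif_tfs": sorted(self.true_motif_tfs),
            "true_regulator_tfs": sorted(self.true_regulator_tfs),
            "true_stb_expressed": sorted(self.true_stb_expressed),
            "true_complication_tfs": {
                t: sorted(c) for t, c in sorted(self.true_complication_tfs.items())},
        }
        with open(path, "w") as fh:
            json.dump(enc, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_secreted=set(d["true_secreted"]),
            true_ortholog_pairs=d["true_ortholog_pairs"],
            true_one_to_many=set(d["true_one_to_many"]),
            true_unmapped=set(d["true_unmapped"]),
            true_placenta_expressed_mouse=set(d["true_placenta_expressed_mouse"]),
            true_placenta_expressed_human=set(d["true_placenta_expressed_human"]),
            true_pregnancy_fold=d["true_pregnancy_fold"],
            true_gdm_effects={a: {int(w): m for w, m in e.items()}
                              for a, e in d["true_gdm_effects"].items()},
            true_tf_edges={tuple(e) for e in d["true_tf_edges"]},
            true_complication_sets={c: set(g)
                                    for c, g in d["true_complication_sets"].items()},
            stream_membership={s: set(g)
                               for s, g in d["stream_membership"].items()},
            true_enriched_mouse=set(d["true_enriched_mouse"]),
            true_plasma_detected=set(d["true_plasma_detected"]),
            true_motif_tfs=set(d["true_motif_tfs"]),
            true_regulator_tfs=set(d["true_regulator_tfs"]),
            true_stb_expressed=set(d["true_stb_expressed"]),
            true_complication_tfs={t: set(c)
                                   for t, c in d["true_complication_tfs"].items()},
        )


@dataclass
class Study:
    """Paths of every emitted table plus the retained ground truth."""

    out_dir: Path
    paths: dict[str, Path]
    ground_truth: GroundTruth
    config: SimConfig


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def generate_biomarker_cohort(
    config: SimConfig,
    effects: dict[str, float | dict[int, float]] | None = None,
) -> pd.DataFrame:
    """Serum biomarker cohort: subject x week x analyte concentrations.

    Concentrations are log-normal around week- and analyte-specific healthy
    medians; GDM subjects receive multiplicative effects (scalar per analyte
    or per (analyte, week)).  Returns a long-format table with columns
    subject, group, week, analyte, concentration.
    """
    config.validate()
    if config.n_healthy < 2 or config.n_gdm < 2:
        raise ValueError("n_healthy and n_gdm must be >= 2")
    eff: dict[str, dict[int, float]] = {}
    source = effects if effects is not None else DEFAULT_GDM_EFFECTS
    for a in ANALYTES:
        e = source.get(a, 1.0)
        eff[a] = dict(e) if isinstance(e, dict) else {w: float(e) for w in WEEKS}
        for w in WEEKS:
            eff[a].setdefault(w, 1.0)
            if eff[a][w] <= 0:
                raise ValueError(f"non-positive effect for {a} at week {w}")
    rng = np.random.default_rng(config.seed)
    subjects = [f"H{i:04d}" for i in range(config.n_healthy)] + \
               [f"G{i:04d}" for i in range(config.n_gdm)]
    groups = ["healthy"] * config.n_healthy + ["GDM"] * config.n_gdm
    frame = pd.DataFrame([
        (s, g, w, a)
        for s, g in zip(subjects, groups)
        for w in WEEKS
        for a in ANALYTES
    ], columns=["subject", "group", "week", "analyte"])
    median = np.array([HEALTHY_MEDIANS[a][w]
                       for a, w in zip(frame["analyte"], frame["week"])])
    mult = np.array([
        eff[a][w] if g == "GDM" else 1.0
        for a, w, g in zip(frame["analyte"], frame["week"], frame["group"])
    ])
    noise = np.exp(config.biomarker_sigma * rng.standard_normal(len(frame)))
    frame["concentration"] = median * mult * noise
    return frame


def _mouse_gene(i: int) -> str:
    return f"Gm{i:04d}"


def _human_gene(i: int) -> str:
    return f"HS{i:04d}"


def generate_study(config: SimConfig, out_dir: str | Path) -> Study:
    """Generate every pipeline input under ``out_dir`` with retained truth.

    Identical (config, seed) produce byte-identical files.  With
    ``detection_dropout=0`` every stream member is detected in all samples;
    with all sigmas at 0 every downstream stage recovers its planted set
    exactly.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    paths: dict[str, Path] = {}

    genes = [_mouse_gene(i) for i in range(config.n_genes)]

    # --- orthology partition -------------------------------------------------
    order = rng.permutation(config.n_genes)
    n_many = int(round(config.frac_one_to_many * config.n_genes))
    n_unmapped = int(round(config.frac_unmapped * config.n_genes))
    many = {genes[i] for i in order[:n_many]}
    unmapped = {genes[i] for i in order[n_many:n_many + n_unmapped]}
    one_to_one = [genes[i] for i in order[n_many + n_unmapped:]]
    pairs = {g: _human_gene(int(g[2:])) for g in one_to_one}
    # a couple of many-to-one cases (two mouse genes, one human partner)
    if len(one_to_one) >= 4:
        pairs[one_to_one[1]] = pairs[one_to_one[0]]
        pairs[one_to_one[3]] = pairs[one_to_one[2]]

    assertion_rows = []
    sources = ("MGI", "NCBI", "Ensembl")
    for g in sorted(pairs):
        k = int(rng.integers(1, 4))
        for src in rng.choice(sources, size=k, replace=False):
            h = pairs[g]
            if rng.random() < 0.05:  # dialect: versioned id, normalized away
                h = f"{h}.{int(rng.integers(1, 4))}"
            assertion_rows.append((g, h, src))
    for j, g in enumerate(sorted(many)):
        h1, h2 = f"HX{j:04d}a", f"HX{j:04d}b"
        if rng.random() < config.ortholog_conflict_rate:
            # cross-source conflict: two sources, two different partners
            s1, s2 = rng.choice(sources, size=2, replace=False)
            assertion_rows.append((g, h1, s1))
            assertion_rows.append((g, h2, s2))
        else:  # one source asserting two partners
            src = str(rng.choice(sources))
            assertion_rows.append((g, h1, src))
            assertion_rows.append((g, h2, src))
    assertions = pd.DataFrame(
        assertion_rows, columns=["mouse_gene", "human_gene", "source"])
    paths["orthologs"] = out_dir / "ortholog_assertions.tsv"
    _tsv(assertions, paths["orthologs"])

    # --- planted gene sets ---------------------------------------------------
    secreted = set(rng.choice(genes, size=int(round(
        config.frac_secreted * config.n_genes)), replace=False))
    mouse_expressed = set(rng.choice(genes, size=int(round(
        config.frac_mouse_expressed * config.n_genes)), replace=False))
    human_genes = sorted(set(pairs.values()))
    human_expressed = set(
        h for h in human_genes if rng.random() < config.frac_human_expressed)

    # --- stream membership and detection tables ------------------------------
    membership: dict[str, set[str]] = {s: set() for s in STREAMS}
    for g in genes:
        mask = rng.random(3) < 0.6
        if not mask.any():
            mask[int(rng.integers(0, 3))] = True
        for s, m in zip(STREAMS, mask):
            if m:
                membership[s].add(g)

    # accession map: one accession per gene, ~2% of genes get a second
    # accession, plus decoy accessions absent from the map
    idmap_rows = []
    acc_of: dict[str, list[str]] = {}
    for i, g in enumerate(genes):
        acc = f"ACC{i:05d}"
        acc_of[g] = [acc]
        idmap_rows.append((acc, g))
        if rng.random() < 0.02:
            acc2 = f"ACC{i:05d}B"
            acc_of[g].append(acc2)
            idmap_rows.append((acc2, g))
    paths["idmap"] = out_dir / "idmap.tsv"
    _tsv(pd.DataFrame(idmap_rows, columns=["accession", "gene"]), paths["idmap"])

    n_s = config.n_samples_per_stream
    for stream in STREAMS:
        members = sorted(membership[stream])
        accs, vals = [], []
        for g in members:
            base = float(np.exp(rng.normal(np.log(1e6), 1.0)))
            for acc in acc_of[g]:
                noise = np.exp(config.lognormal_sigma * rng.standard_normal(n_s))
                detected = rng.random(n_s) >= config.detection_dropout
                accs.append(acc)
                vals.append(base * noise * detected)
        # decoy accessions with no gene mapping (reported as unmapped)
        for j in range(3):
            accs.append(f"DECOY_{stream.upper()}{j}")
            vals.append(np.exp(rng.normal(np.log(1e5), 1.0, n_s)))
        df = pd.DataFrame(np.array(vals), index=accs,
                          columns=[f"{stream}_s{i+1}" for i in range(n_s)])
        df.index.name = "accession"
        paths[f"detection_{stream}"] = out_dir / f"detection_{stream}.tsv"
        _tsv(df, paths[f"detection_{stream}"], index=True)

    # --- secretion annotations ------------------------------------------------
    ann_rows = []
    for g in genes:
        if g in secreted:
            route = rng.random()
            if route < 0.45:  # conventional only
                sp, er, terms = True, False, ()
            elif route < 0.75:  # unconventional only (may be an ER resident)
                sp = bool(rng.random() < 0.2)
                er = sp  # signal captured for an ER-lumen protein: GO rescues it
                terms = (str(rng.choice(SECRETION_GO)),)
            else:  # both evidence routes
                sp, er = True, False
                terms = (str(rng.choice(SECRETION_GO)),)
        else:
            route = rng.random()
            if route < 0.15:  # ER-lumen trap: signal peptide but not secreted
                sp, er, terms = True, True, ()
            elif route < 0.5:
                sp, er = False, False
                terms = (str(rng.choice(NON_SECRETION_GO)),)
            else:
                sp, er, terms = False, False, ()
        ann_rows.append((g, str(sp).lower(), str(er).lower(), ";".join(terms)))
    paths["secretion"] = out_dir / "secretion_annotations.tsv"
    _tsv(pd.DataFrame(
        ann_rows, columns=["gene", "signal_peptide", "er_lumen", "go_terms"]),
        paths["secretion"])

    # --- mouse tissue expression ----------------------------------------------
    enriched_pool = sorted(secreted & mouse_expressed)
    n_enr = min(config.n_enriched, len(enriched_pool))
    enriched = set(
        rng.choice(enriched_pool, size=n_enr, replace=False)) if n_enr else set()
    expr_rows = []
    for g in genes:
        others = rng.uniform(1.0, 5.0, len(TISSUES) - 1)
        if g not in mouse_expressed:
            placenta = 0.0
        elif g in enriched:
            placenta = config.enriched_fold * float(others.max())
        else:
            # expressed but bounded at background_fold x the strongest other
            placenta = config.background_fold * float(others.max())
            placenta = max(placenta, 5.0)
            others[int(rng.integers(0, len(others)))] = max(
                others.max(), placenta / config.background_fold)
        expr_rows.append([g, placenta, *others])
    mouse_expr = pd.DataFrame(expr_rows, columns=["gene", *TISSUES])
    paths["mouse_expression"] = out_dir / "mouse_expression.tsv"
    _tsv(mouse_expr, paths["mouse_expression"])

    # --- human tissue expression ----------------------------------------------
    hexpr_rows = []
    for h in human_genes:
        others = rng.uniform(0.0, 10.0, len(TISSUES) - 1)
        placenta = float(rng.uniform(5.0, 100.0)) if h in human_expressed else 0.0
        hexpr_rows.append([h, placenta, *others])
    human_expr = pd.DataFrame(hexpr_rows, columns=["gene", *TISSUES])
    paths["human_expression"] = out_dir / "human_expression.tsv"
    _tsv(human_expr, paths["human_expression"])

    # --- ground-truth shared secretome (for overlay construction only) -------
    shared = {
        g for g in secreted & mouse_expressed
        if g in pairs and pairs[g] in human_expressed
    }
    shared_human = sorted(pairs[g] for g in shared)

    # --- complication differential sets ---------------------------------------
    comp_sets: dict[str, set[str]] = {}
    pool = sorted(human_expressed)
    core = shared_human[:4] if len(shared_human) >= 4 else shared_human
    for c in COMPLICATIONS:
        size = int(rng.integers(15, 40))
        members = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
        comp_sets[c] = members
    for h in core:  # a 4-complication core, as complication overlays show
        for c in COMPLICATIONS[:4]:
            comp_sets[c].add(h)
    comp_rows = [(c, h) for c in COMPLICATIONS for h in sorted(comp_sets[c])]
    paths["complications"] = out_dir / "complication_sets.tsv"
    _tsv(pd.DataFrame(comp_rows, columns=["complication", "gene"]),
         paths["complications"])

    # --- overlay gene sets -----------------------------------------------------
    stb_expressed_genes = set(
        h for h in shared_human if rng.random() < 0.9)
    organoid = set(h for h in shared_human if rng.random() < 0.2)
    damp = set(h for h in shared_human if rng.random() < 0.08)
    for name, gs in (("stb_expressed", stb_expressed_genes),
                     ("organoid_secretome", organoid), ("damp", damp)):
        paths[name] = out_dir / f"{name}.txt"
        paths[name].write_text("".join(f"{g}\n" for g in sorted(gs)))

    # --- plasma screen ---------------------------------------------------------
    plasma_pool = sorted(shared) if len(shared) >= config.n_plasma_proteins \
        else sorted(set().union(*membership.values()))
    n_plasma = min(config.n_plasma_proteins, len(plasma_pool))
    plasma_genes = sorted(rng.choice(plasma_pool, size=n_plasma, replace=False))
    folds = {}
    boundary = [0.8, 1.0, 1.5, 2.0, 10.0, 52.0]
    for i, g in enumerate(plasma_genes):
        if i < len(boundary):
            folds[g] = boundary[i]
        elif rng.random() < 0.5:  # higher in pregnancy, log-uniform 1.5..52
            folds[g] = float(np.exp(rng.uniform(np.log(1.5), np.log(52.0))))
        else:
            folds[g] = float(rng.uniform(0.5, 1.2))
    np_cols = [f"NP{i+1}" for i in range(config.n_np)]
    p_cols = [f"P{i+1}" for i in range(config.n_p)]
    col_scale = rng.uniform(0.5, 2.0, config.n_np + config.n_p)  # run drift
    quant_rows, quant_idx = [], []
    for g in plasma_genes:
        base = float(np.exp(rng.normal(np.log(1e4), 1.0)))
        vals = []
        for j, col in enumerate(np_cols + p_cols):
            fold = folds[g] if col.startswith("P") else 1.0
            noise = float(np.exp(config.plasma_sigma * rng.standard_normal()))
            vals.append(base * fold * noise * col_scale[j])
        quant_idx.append(g)
        quant_rows.append(vals)
    quant_idx.append("__STANDARD__")
    quant_rows.append(list(1e5 * col_scale))
    quant = pd.DataFrame(quant_rows, index=quant_idx, columns=np_cols + p_cols)
    quant.index.name = "protein"
    paths["plasma"] = out_dir / "plasma_quant.tsv"
    _tsv(quant, paths["plasma"], index=True)
    groups = pd.DataFrame(
        {"animal": np_cols + p_cols,
         "group": ["NP"] * config.n_np + ["P"] * config.n_p})
    paths["plasma_groups"] = out_dir / "plasma_groups.tsv"
    _tsv(groups, paths["plasma_groups"])

    # --- serum biomarker cohort ------------------------------------------------
    cohort = generate_biomarker_cohort(config)
    paths["biomarkers"] = out_dir / "biomarkers.tsv"
    _tsv(cohort, paths["biomarkers"])

    # --- promoters, motifs, regulator predictions ------------------------------
    tfs = [f"TF{i+1:02d}" for i in range(config.n_tfs)]
    n_active = max(1, (2 * config.n_tfs) // 3)
    motif_tfs = set(tfs[:n_active])            # detectable by motif scanning
    regulator_tfs = set(tfs[config.n_tfs // 3:])  # predicted by the second route
    pwms = []
    consensus: dict[str, str] = {}
    for tf in tfs:
        cons_idx = rng.integers(0, 4, config.motif_length)
        mat = np.full((config.motif_length, 4), 0.01)
        mat[np.arange(config.motif_length), cons_idx] = 0.97
        pwm = PWM(motif_id=tf, matrix=mat, pseudocount=1e-6)
        pwms.append(pwm)
        consensus[tf] = "".join("ACGT"[i] for i in cons_idx)
    paths["motifs"] = out_dir / "motifs.meme"
    write_meme(pwms, paths["motifs"])

    n_fg = min(config.n_promoters, len(shared_human))
    fg_genes = sorted(rng.choice(shared_human, size=n_fg, replace=False)) \
        if n_fg else []
    bg_pool = sorted(set(human_genes) - set(shared_human))
    bg_genes = sorted(rng.choice(
        bg_pool, size=min(config.n_promoters, len(bg_pool)), replace=False))
    tf_edges: set[tuple[str, str]] = set()
    fasta_lines = []
    for h in fg_genes + bg_genes:
        seq = list("ACGT"[i] for i in rng.integers(0, 4, config.promoter_length))
        in_fg = h in set(fg_genes)
        for tf in sorted(motif_tfs):
            rate = (config.planted_occurrence_rate if in_fg
                    else config.background_occurrence_rate)
            if rng.random() < rate:
                pos = int(rng.integers(
                    0, config.promoter_length - config.motif_length + 1))
                seq[pos:pos + config.motif_length] = consensus[tf]
                if in_fg:
                    tf_edges.add((tf, h))
        fasta_lines.append(f">{h}\n{''.join(seq)}\n")
    paths["promoters"] = out_dir / "promoters.fasta"
    (out_dir / "promoters.fasta").write_text("".join(fasta_lines))

    # upstream-regulator predictions (second, independent route)
    reg_rows = []
    for tf in sorted(regulator_tfs):
        targets = sorted(h for t, h in tf_edges if t == tf)
        if not targets and fg_genes:
            targets = [str(rng.choice(fg_genes))]
        extra = [str(rng.choice(human_genes))
                 for _ in range(int(rng.integers(0, 3)))]
        for t in sorted(set(targets) | set(extra)):
            reg_rows.append((tf, t, "upstream_regulator"))
    paths["regulators"] = out_dir / "regulator_predictions.tsv"
    _tsv(pd.DataFrame(reg_rows, columns=["tf", "target", "source"]),
         paths["regulators"])

    # STB expression covers most both-route TFs and the STB gene overlay
    both_tfs = sorted(motif_tfs & regulator_tfs)
    stb_tfs = set(both_tfs[:max(1, int(0.75 * len(both_tfs)))])
    stb_all = stb_expressed_genes | stb_tfs
    paths["stb_expressed"].write_text("".join(f"{g}\n" for g in sorted(stb_all)))

    comp_tfs = {tf: {str(rng.choice(COMPLICATIONS))}
                for tf in sorted(stb_tfs)[:max(1, len(stb_tfs) * 2 // 3)]}
    paths["complication_tfs"] = out_dir / "complication_tfs.tsv"
    _tsv(pd.DataFrame(
        [(tf, ";".join(sorted(cs))) for tf, cs in sorted(comp_tfs.items())],
        columns=["tf", "complications"]), paths["complication_tfs"])

    truth = GroundTruth(
        true_secreted=secreted,
        true_ortholog_pairs=pairs,
        true_one_to_many=many,
        true_unmapped=unmapped,
        true_placenta_expressed_mouse=mouse_expressed,
        true_placenta_expressed_human=human_expressed,
        true_pregnancy_fold=folds,
        true_gdm_effects={a: dict(e) for a, e in DEFAULT_GDM_EFFECTS.items()},
        true_tf_edges=tf_edges,
        true_complication_sets=comp_sets,
        stream_membership=membership,
        true_enriched_mouse=enriched,
        true_plasma_detected=set(plasma_genes),
        true_motif_tfs=motif_tfs,
        true_regulator_tfs=regulator_tfs,
        true_stb_expressed=stb_all,
        true_complication_tfs=comp_tfs,
    )
    paths["ground_truth"] = out_dir / "ground_truth.json"
    truth.to_json(paths["ground_truth"])
    paths["config"] = out_dir / "sim_config.json"
    config.to_json(paths["config"])
    return Study(out_dir=out_dir, paths=paths, ground_truth=truth, config=config)
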