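"""Promoter motif scanning, enrichment and TF-target network filtering.

Transcription-factor binding motifs (position weight matrices, MEME format)
are scanned over promoter windows (default 1000 bp upstream to 100 bp
downstream of the TSS, strand-resolved) by additive log2-odds scoring
against a background composition, on both strands.  Motif enrichment in a
foreground promoter set versus background uses a Fisher exact test on
has-a-hit counts with BH correction across motifs — a threshold-based
approximation to rank-based enrichment scanners.  TFs supported by two
independent prediction routes (motif enrichment and upstream-regulator
inference) are intersected, filtered for syncytiotrophoblast expression and
for having at least one secretome target, and assembled into a directed
TF->target network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("secretomap")

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix over {A, C, G, T} with pseudocount smoothing.

    ``matrix`` is length x 4 (columns in A, C, G, T order); each row sums
    to 1 after pseudocount normalization.  Log-odds are log2(p/background).
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 1e-3
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be length x 4")
        if len(self.matrix) < 4:
            raise ValueError("motif length must be >= 4")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence: column-wise max log-odds sum."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


def read_meme(path: str | Path) -> list[PWM]:
    """Read PWMs from a minimal-MEME motif file (Biopython parser)."""
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in ALPHABET]
                        for i in range(m.length)])
        bg = np.array([m.background[b] for b in ALPHABET])
        # MEME letter probabilities are already smoothed; keep them intact
        out.append(PWM(motif_id=m.name, matrix=mat, pseudocount=1e-9,
                       background=bg / bg.sum()))
    return out


def write_meme(pwms: list[PWM], path: str | Path) -> None:
    """Write PWMs in minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites keeps count-based readers from quantizing probabilities
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} "
                     f"nsites= 1000000 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_promoters(path: str | Path) -> dict[str, str]:
    """Read promoter FASTA (sequences already strand-resolved, 5'->3')."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    gene: str
    position: int  # 0-based start on the given (forward) sequence
    strand: str    # '+' or '-'
    score: float


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i


def _scan_strand(seq: str, log_odds: np.ndarray, threshold: float):
    """(pos, score) pairs for windows scoring >= threshold; N scores -inf.

    Vectorized over all windows of the sequence; a window containing any N
    has score -inf and can never pass a finite threshold.
    """
    L = len(log_odds)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.where(
        valid,
        log_odds[np.arange(L), np.where(windows >= 0, windows, 0)].sum(axis=1),
        -np.inf,
    )
    hits = np.flatnonzero(scores >= threshold)
    return [(int(p), float(scores[p])) for p in hits]


def scan_pwm(
    promoters: dict[str, str],
    pwm: PWM,
    score_threshold: float,
) -> list[MotifHit]:
    """Scan both strands of every promoter for log-odds hits >= threshold.

    Positions are 0-based starts on the given sequence; minus-strand hits
    report the start of the matching window in forward coordinates.
    Sequences shorter than the motif yield no hits, with a warning.
    """
    if not np.isfinite(score_threshold):
        raise ValueError("score threshold must be finite")
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    for gene in sorted(promoters):
        seq = promoters[gene].upper()
        if len(seq) < pwm.length:
            logger.warning("promoter %s shorter than motif %s", gene, pwm.motif_id)
            continue
        for pos, score in _scan_strand(seq, lo, score_threshold):
            hits.append(MotifHit(gene, pos, "+", score))
        rc = reverse_complement(seq)
        for pos, score in _scan_strand(rc, lo, score_threshold):
            # window start in forward coordinates
            fwd = len(seq) - pos - pwm.length
            hits.append(MotifHit(gene, fwd, "-", score))
    return hits


def default_threshold(pwm: PWM, fraction: float = 0.6) -> float:
    """Default scan threshold: a fraction of the maximal log-odds score."""
    return fraction * pwm.max_score


def occurrence_fisher(
    fg_hits: int, fg_total: int, bg_hits: int, bg_total: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the has-hit x promoter-set 2x2 table."""
    table = [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]]
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def motif_enrichment(
    foreground: dict[str, str],
    background: dict[str, str],
    pwms: list[PWM],
    threshold: float | None = None,
    threshold_fraction: float = 0.6,
) -> pd.DataFrame:
    """Fisher-exact enrichment of motif occurrence in foreground promoters.

    Per motif, promoters are classified has-a-hit / no-hit (either strand,
    score >= threshold; per-motif default = ``threshold_fraction`` of the
    maximal score); the 2x2 table (hit x set) is tested two-sided and BH
    corrected across motifs.  Foreground and background must be disjoint
    and non-empty.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    overlap = set(foreground) & set(background)
    if overlap:
        raise ValueError(f"foreground and background overlap: {sorted(overlap)[:5]}")
    rows = []
    for pwm in pwms:
        thr = threshold if threshold is not None else default_threshold(
            pwm, threshold_fraction)
        fg_hit = {h.gene for h in scan_pwm(foreground, pwm, thr)}
        bg_hit = {h.gene for h in scan_pwm(background, pwm, thr)}
        odds, p = occurrence_fisher(len(fg_hit), len(foreground),
                                    len(bg_hit), len(background))
        rows.append({"motif": pwm.motif_id, "fg_hits": len(fg_hit),
                     "fg_total": len(foreground), "bg_hits": len(bg_hit),
                     "bg_total": len(background),
                     "odds_ratio": odds, "p_value": p,
                     "targets": ";".join(sorted(fg_hit))})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


@dataclass(frozen=True)
class TFPrediction:
    tf: str
    target: str
    source: str


def read_predictions(path: str | Path) -> list[TFPrediction]:
    """Read a TSV of (tf, target, source) prediction rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TFPrediction(r.tf, r.target, r.source)
            for r in df.itertuples(index=False)]


def consensus_tfs(
    preds_a: list[TFPrediction], preds_b: list[TFPrediction]
) -> dict[str, set[str]]:
    """TFs predicted by both sources; target sets pooled across sources."""
    tfs_a = {p.tf for p in preds_a}
    tfs_b = {p.tf for p in preds_b}
    keep = tfs_a & tfs_b
    targets: dict[str, set[str]] = {tf: set() for tf in keep}
    for p in list(preds_a) + list(preds_b):
        if p.tf in keep:
            targets[p.tf].add(p.target)
    return targets


def filter_by_expression(
    tf_targets: dict[str, set[str]],
    stb_expression: set[str],
    secretome: set[str],
) -> dict[str, set[str]]:
    """Keep STB-expressed TFs with >= 1 STB-expressed secretome target.

    Surviving targets are restricted to the secretome-and-STB intersection,
    which makes the filter idempotent.
    """
    allowed = secretome & stb_expression
    out = {}
    for tf, targets in tf_targets.items():
        if tf not in stb_expression:
            continue
        kept = targets & allowed
        if kept:
            out[tf] = kept
    return out


def build_network(
    tf_targets: dict[str, set[str]],
    complication_tfs: dict[str, set[str]],
    complication_gene_sets: dict[str, set[str]],
) -> nx.DiGraph:
    """Directed TF->target network with complication-dysregulation flags.

    ``complication_tfs`` maps TF -> complications it is linked to (TFs not
    present are unflagged); targets are flagged when any complication
    differential set contains them.  Every edge endpoint must exist as a
    node (guarded during construction).
    """
    g = nx.DiGraph()
    for tf in sorted(tf_targets):
        comps = sorted(complication_tfs.get(tf, set()))
        g.add_node(tf, kind="tf", dysregulated=bool(comps),
                   complications=";".join(comps))
    for tf, targets in sorted(tf_targets.items()):
        for t in sorted(targets):
            if t not in g:
                comps = sorted(c for c, gs in complication_gene_sets.items()
                               if t in gs)
                g.add_node(t, kind="target", differential=bool(comps),
                           complications=";".join(comps))
            g.add_edge(tf, t)
    for u, v in g.edges:
        if u not in g.nodes or v not in g.nodes:  # construction bug guard
            raise RuntimeError(f"dangling edge {u}->{v}")
    n_flagged = sum(1 for _, d in g.nodes(data=True)
                    if d["kind"] == "target" and d.get("differential"))
    logger.info("network: %d TFs, %d targets (%d flagged), %d edges",
                sum(1 for _, d in g.nodes(data=True) if d["kind"] == "tf"),
                sum(1 for _, d in g.nodes(data=True) if d["kind"] == "target"),
                n_flagged, g.number_of_edges())
    return g


def export_network(g: nx.DiGraph, edge_tsv: str | Path,
                   graphml: str | Path | None = None) -> None:
    rows = [{"tf": u, "target": v} for u, v in sorted(g.edges)]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(
        edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(g, graphml)
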