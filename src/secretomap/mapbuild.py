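"""Secretome-map integration, Venn partitions, enrichment and overlays.

Per-stream secreted gene lists are merged into one entry per gene recording
which evidence streams contributed, whether the gene is shared with the
human placenta (one-to-one ortholog with verified human expression), overlay
membership (organoid secretome, syncytiotrophoblast expression, DAMP list,
plasma detection) and pregnancy-complication flags.  Over-representation of
gene categories is tested with the exact hypergeometric upper tail and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from secretomap.logs import StageLog, log_stage

COMPLICATIONS = ("PE", "GDM", "IUGR", "SGA", "LGA")
OVERLAY_KEYS = ("organoid_secretome", "stb_expressed", "damp", "plasma_detected")


@dataclass
class SecretomeEntry:
    mouse_gene: str
    human_gene: str | None
    evidence_streams: frozenset[str]
    shared_with_human: bool
    overlays: dict[str, bool] = field(default_factory=dict)
    complication_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.evidence_streams:
            raise ValueError(f"{self.mouse_gene}: entry with no evidence stream")
        if self.shared_with_human and self.human_gene is None:
            raise ValueError(f"{self.mouse_gene}: shared entry lacks human ortholog")


def integrate_streams(
    stream_sets: dict[str, set[str]],
    ortholog_pairs: dict[str, str],
    human_expressed: set[str],
) -> tuple[list[SecretomeEntry], StageLog]:
    """One entry per gene in the union of the per-stream secreted sets.

    ``shared_with_human`` holds when the gene has a one-to-one human
    ortholog whose expression in the human placenta was verified.
    """
    if not stream_sets:
        raise ValueError("need at least one stream set")
    union = sorted(set().union(*stream_sets.values()))
    entries = []
    n_shared = 0
    for g in union:
        streams = frozenset(s for s, gs in stream_sets.items() if g in gs)
        human = ortholog_pairs.get(g)
        shared = human is not None and human in human_expressed
        n_shared += shared
        entries.append(SecretomeEntry(
            mouse_gene=g,
            human_gene=human,
            evidence_streams=streams,
            shared_with_human=shared,
        ))
    lg = log_stage(StageLog(
        stage="integrate_streams",
        n_in=len(union),
        n_retained=n_shared,
        n_dropped=len(union) - n_shared,
        detail={"per_stream": {s: len(gs) for s, gs in stream_sets.items()},
                "mouse_only": len(union) - n_shared},
    ))
    return entries, lg


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts over every non-empty membership pattern of 2-5 sets.

    Keys are sorted tuples of the labels an element belongs to; the counts
    over patterns containing a label sum to that set's cardinality.
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError(f"venn_counts supports 2-5 sets, got {len(sets)}")
    labels = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(*(sets[l] for l in labels if l not in combo)) \
                if len(combo) < len(labels) else set()
            counts[combo] = len(inside - outside)
    return counts


def tissue_enrichment(
    expression: pd.DataFrame,
    genes: set[str],
    target: str,
    fold: float = 10.0,
    comparator: str = "max",
) -> dict[str, float]:
    """Genes whose target-tissue expression exceeds ``fold`` x the other tissues.

    The comparator over non-target tissues is the max (strictest) by
    default; "mean" is available. Returns gene -> achieved fold ratio for
    the enriched genes only. A gene with zero target expression is never
    enriched; zero expression everywhere else counts as infinitely enriched
    provided the target is positive.
    """
    if target not in expression.columns:
        raise ValueError(f"target tissue {target!r} not in expression table")
    if expression.shape[1] < 2:
        raise ValueError("need at least two tissues")
    if fold <= 0:
        raise ValueError("fold threshold must be positive")
    if comparator not in ("max", "mean"):
        raise ValueError(f"unknown comparator {comparator!r}")
    others = expression.drop(columns=[target])
    ref = others.max(axis=1) if comparator == "max" else others.mean(axis=1)
    out: dict[str, float] = {}
    for g in sorted(genes & set(expression.index)):
        tgt = float(expression.at[g, target])
        r = float(ref.loc[g])
        if tgt <= 0:
            continue
        if tgt > fold * r:
            out[g] = tgt / r if r > 0 else float("inf")
    return out


def complication_overlay(
    entries: list[SecretomeEntry],
    differential_sets: dict[str, set[str]],
    min_shared: int = 2,
) -> tuple[list[SecretomeEntry], dict]:
    """Flag entries by membership of their human ortholog in complication sets.

    Mouse-only entries (no human ortholog) cannot be matched and are counted
    as unmatchable. The summary lists genes unique to each complication and
    genes shared by >= ``min_shared`` complications.
    """
    unknown = set(differential_sets) - set(COMPLICATIONS)
    if unknown:
        raise ValueError(f"unknown complication labels: {sorted(unknown)}")
    unmatchable = 0
    for e in entries:
        if e.human_gene is None:
            unmatchable += 1
            e.complication_flags = frozenset()
        else:
            e.complication_flags = frozenset(
                c for c, gs in differential_sets.items() if e.human_gene in gs
            )
    flagged = [e for e in entries if e.complication_flags]
    unique = {
        c: sorted(e.human_gene for e in entries
                  if e.complication_flags == frozenset({c}))
        for c in differential_sets
    }
    shared = sorted(
        (e.human_gene, sorted(e.complication_flags))
        for e in entries if len(e.complication_flags) >= min_shared
    )
    summary = {
        "n_flagged": len(flagged),
        "n_unmatchable": unmatchable,
        "unique_per_complication": unique,
        "shared_min_k": {"k": min_shared, "genes": shared},
    }
    return entries, summary


def overrepresentation(
    hits: set[str],
    universe: set[str],
    categories: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation with BH correction.

    For a category of size K in a universe of size N, with n hits of which
    k fall in the category, p = P[X >= k], X ~ Hypergeom(N, K, n). Returns a
    DataFrame sorted by p with columns category, overlap, category_size,
    p_value, q_value.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    N, n = len(universe), len(hits)
    for name, members in categories.items():
        members = members & universe
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, N, len(members), n))
        rows.append({"category": name, "overlap": k,
                     "category_size": len(members), "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def entries_to_frame(entries: list[SecretomeEntry]) -> pd.DataFrame:
    """Flatten secretome entries to a TSV-ready table (one row per gene)."""
    rows = []
    for e in entries:
        row = {
            "mouse_gene": e.mouse_gene,
            "human_gene": e.human_gene or "",
            "shared_with_human": e.shared_with_human,
            "evidence_streams": ";".join(sorted(e.evidence_streams)),
            "complications": ";".join(sorted(e.complication_flags)),
        }
        for key in OVERLAY_KEYS:
            row[key] = bool(e.overlays.get(key, False))
        rows.append(row)
    return pd.DataFrame(rows)


def apply_overlays(
    entries: list[SecretomeEntry], overlay_sets: dict[str, set[str]]
) -> list[SecretomeEntry]:
    """Mark overlay membership.

    Human-derived overlays (organoid secretome, STB expression, DAMP list)
    are matched on the human ortholog; plasma detection comes from the mouse
    plasma screen and is matched on the mouse gene.
    """
    for e in entries:
        for key, gs in overlay_sets.items():
            if key == "plasma_detected":
                e.overlays[key] = e.mouse_gene in gs
            else:
                e.overlays[key] = e.human_gene is not None and e.human_gene in gs
    return entries
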