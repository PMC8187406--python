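"""Secretion classification: conventional signal-peptide route + GO evidence.

A protein is called secreted when it carries an N-terminal signal peptide
and is not an ER-lumen resident (conventional, ER/Golgi route), or when it
is annotated to an extracellular GO term (unconventional route, e.g.
exosomal release of leaderless proteins).  Signal-peptide prediction is
consumed as a boolean annotation (SignalP output), never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from secretomap.logs import StageLog, log_stage

#: Extracellular GO terms defining the unconventional-secretion evidence:
#: extracellular region, extracellular space, extracellular exosome,
#: extracellular region part. Configurable in every classifier call.
DEFAULT_SECRETION_GO_TERMS = frozenset(
    {"GO:0005576", "GO:0005615", "GO:0070062", "GO:0044421"}
)

CONVENTIONAL = "conventional"
UNCONVENTIONAL = "unconventional"


@dataclass(frozen=True)
class SecretionAnnotation:
    """Per-gene secretion evidence; flags are explicit booleans, never missing."""

    gene: str
    signal_peptide: bool
    er_lumen: bool
    go_terms: frozenset[str] = frozenset()


@dataclass
class SecretionPartition:
    secreted: set[str]
    not_secreted: set[str]
    unannotated: set[str]
    evidence: dict[str, frozenset[str]]  # gene -> evidence labels


def read_annotations(path: str | Path) -> dict[str, SecretionAnnotation]:
    """Read annotation TSV: gene, signal_peptide, er_lumen, go_terms (';'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, SecretionAnnotation] = {}
    for row in df.itertuples(index=False):
        terms = frozenset(t for t in row.go_terms.split(";") if t)
        out[row.gene] = SecretionAnnotation(
            gene=row.gene,
            signal_peptide=row.signal_peptide.lower() in ("1", "true", "yes"),
            er_lumen=row.er_lumen.lower() in ("1", "true", "yes"),
            go_terms=terms,
        )
    return out


def classify_secreted(
    ann: SecretionAnnotation,
    secretion_go_terms: frozenset[str] = DEFAULT_SECRETION_GO_TERMS,
) -> tuple[bool, frozenset[str]]:
    """Classify one gene; returns (secreted, satisfied evidence labels).

    secreted <=> (signal_peptide and not er_lumen)
                 or (go_terms intersects secretion_go_terms)
    """
    if not secretion_go_terms:
        raise ValueError("secretion_go_terms must be non-empty")
    labels = set()
    if ann.signal_peptide and not ann.er_lumen:
        labels.add(CONVENTIONAL)
    if ann.go_terms & secretion_go_terms:
        labels.add(UNCONVENTIONAL)
    return bool(labels), frozenset(labels)


def classify_set(
    annotations: dict[str, SecretionAnnotation],
    genes: set[str],
    secretion_go_terms: frozenset[str] = DEFAULT_SECRETION_GO_TERMS,
) -> tuple[SecretionPartition, StageLog]:
    """Partition genes into secreted / not secreted / unannotated.

    A gene missing from the annotation table goes to the unannotated bucket;
    it is never silently called secreted.
    """
    part = SecretionPartition(set(), set(), set(), {})
    counts = {CONVENTIONAL: 0, UNCONVENTIONAL: 0}
    for g in genes:
        ann = annotations.get(g)
        if ann is None:
            part.unannotated.add(g)
            continue
        ok, labels = classify_secreted(ann, secretion_go_terms)
        if ok:
            part.secreted.add(g)
            part.evidence[g] = labels
            for lab in labels:
                counts[lab] += 1
        else:
            part.not_secreted.add(g)
    lg = log_stage(StageLog(
        stage="secretion_classification",
        n_in=len(genes),
        n_retained=len(part.secreted),
        n_dropped=len(genes) - len(part.secreted),
        detail={"not_secreted": len(part.not_secreted),
                "unannotated": len(part.unannotated),
                "evidence_counts": counts},
    ))
    return part, lg
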