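"""Detection filtering, protein-to-gene conversion, expression verification.

A detection matrix is a proteins x samples table of MS peak areas for one
sample stream (cultured cells, conditioned medium, sorted cells, or plasma).
Proteins are kept when detected in at least k of the n samples of the stream
(default 4 of 5), converted to gene identifiers through an accession map,
and retained only when the tissue-expression table confirms expression in
the target tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from secretomap.logs import StageLog, log_stage

logger = logging.getLogger("secretomap")

VALID_STREAMS = ("cells", "media", "sorted", "plasma")


@dataclass
class DetectionMatrix:
    """Proteins x samples peak-area table for one sample stream.

    ``values`` holds finite, non-negative intensities; a value above the
    detection floor counts as "present" in that sample.
    """

    stream: str
    data: pd.DataFrame  # index: protein accession, columns: sample ids

    def __post_init__(self) -> None:
        if self.stream not in VALID_STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein row {dup!r} in stream {self.stream}")
        if self.data.shape[1] < 1:
            raise ValueError("detection matrix needs at least one sample column")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("peak areas must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_detection(path: str | Path, stream: str) -> DetectionMatrix:
    """Read a TSV detection table (first column = protein accession)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DetectionMatrix(stream=stream, data=df)


@dataclass
class IdMap:
    """Protein accession -> gene id(s). One accession may map to several genes."""

    mapping: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for acc, genes in self.mapping.items():
            if any(not g for g in genes):
                raise ValueError(f"empty gene id mapped from accession {acc!r}")

    def genes_for(self, accession: str) -> tuple[str, ...]:
        return self.mapping.get(accession, ())


def read_idmap(path: str | Path) -> IdMap:
    """Read a two-column TSV (accession, gene); repeated accessions accumulate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, list[str]] = {}
    for acc, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(acc, [])
        if gene not in mapping[acc]:
            mapping[acc].append(gene)
    return IdMap({a: tuple(gs) for a, gs in mapping.items()})


def filter_k_of_n(
    matrix: DetectionMatrix,
    k: int = 4,
    n: int = 5,
    floor: float = 0.0,
) -> tuple[set[str], StageLog]:
    """Keep proteins detected (value > floor) in at least k of the n samples.

    ``n`` must equal the matrix's sample count — it is passed explicitly so a
    misconfigured stream fails loudly rather than silently changing the rule.
    """
    if n != matrix.n_samples:
        raise ValueError(
            f"n={n} does not match sample count {matrix.n_samples} "
            f"of stream {matrix.stream!r}"
        )
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    present = (matrix.data.to_numpy(dtype=float) > floor).sum(axis=1)
    retained = set(matrix.data.index[present >= k])
    lg = log_stage(StageLog(
        stage=f"{matrix.stream}:k_of_n",
        n_in=len(matrix.data),
        n_retained=len(retained),
        n_dropped=len(matrix.data) - len(retained),
        detail={"k": k, "n": n, "floor": floor},
    ))
    return retained, lg


def map_to_genes(
    proteins: set[str], idmap: IdMap
) -> tuple[set[str], list[str], StageLog]:
    """Convert accessions to a de-duplicated gene set.

    Accessions without a mapping are reported in the unmapped list, never
    silently dropped. An accession mapping to several genes contributes all
    of them (lossless; ambiguity is logged).
    """
    if not proteins:
        logger.warning("map_to_genes called with an empty accession set")
    genes: set[str] = set()
    unmapped: list[str] = []
    ambiguous = 0
    for acc in sorted(proteins):
        targets = idmap.genes_for(acc)
        if not targets:
            unmapped.append(acc)
        else:
            if len(targets) > 1:
                ambiguous += 1
                logger.info("accession %s maps to %d genes", acc, len(targets))
            genes.update(targets)
    lg = log_stage(StageLog(
        stage="map_to_genes",
        n_in=len(proteins),
        n_retained=len(proteins) - len(unmapped),
        n_dropped=len(unmapped),
        detail={"n_genes": len(genes), "n_ambiguous": ambiguous,
                "unmapped": unmapped},
    ))
    return genes, unmapped, lg


def verify_expression(
    genes: set[str],
    expression: pd.DataFrame,
    tissue: str,
    min_value: float = 0.0,
) -> tuple[set[str], StageLog]:
    """Keep genes whose expression in ``tissue`` is >= ``min_value``.

    Genes absent from the expression table are excluded and logged; a
    missing tissue column is an error.
    """
    if tissue not in expression.columns:
        raise ValueError(f"tissue {tissue!r} not in expression table")
    col = expression[tissue]
    in_table = genes & set(expression.index)
    missing = sorted(genes - in_table)
    if missing:
        logger.info("%d genes absent from expression table", len(missing))
    kept = {g for g in in_table if col.loc[g] >= min_value}
    lg = log_stage(StageLog(
        stage=f"verify_expression:{tissue}",
        n_in=len(genes),
        n_retained=len(kept),
        n_dropped=len(genes) - len(kept),
        detail={"min_value": min_value, "n_absent_from_table": len(missing)},
    ))
    return kept, lg
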