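"""Mouse-human ortholog consensus across multiple assertion sources.

Assertions from several curated sources (MGI, NCBI HomoloGene, Ensembl) are
combined per mouse gene: a gene with exactly one distinct human partner
across all sources is one-to-one; more than one distinct partner (within or
between sources) is one-to-many and excluded downstream; no partner is
unmapped.  Classification is per mouse gene, so two mouse genes sharing one
human gene (many-to-one) both remain one-to-one; this is logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from secretomap.logs import StageLog, log_stage

logger = logging.getLogger("secretomap")

ONE_TO_ONE = "one_to_one"
ONE_TO_MANY = "one_to_many"
UNMAPPED = "unmapped"

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene: str) -> str:
    """Trim whitespace and strip a trailing version suffix (``Abc.2`` -> ``Abc``)."""
    return _VERSION_SUFFIX.sub("", gene.strip())


@dataclass(frozen=True)
class OrthologAssertion:
    mouse_gene: str
    human_gene: str
    source: str

    def __post_init__(self) -> None:
        if not self.mouse_gene or not self.human_gene or not self.source:
            raise ValueError("assertion fields must be non-empty")


@dataclass(frozen=True)
class OrthologRecord:
    classification: str
    human_gene: str | None  # present iff one_to_one
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if (self.human_gene is not None) != (self.classification == ONE_TO_ONE):
            raise ValueError("human gene present iff classification is one_to_one")


@dataclass
class OrthologMap:
    """Per-mouse-gene classification; the three classes partition the universe."""

    records: dict[str, OrthologRecord]

    def classification_counts(self) -> dict[str, int]:
        counts = {ONE_TO_ONE: 0, ONE_TO_MANY: 0, UNMAPPED: 0}
        for rec in self.records.values():
            counts[rec.classification] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mouse_gene": g,
                "classification": rec.classification,
                "human_gene": rec.human_gene or "",
                "sources": ";".join(sorted(rec.sources)),
            }
            for g, rec in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=["mouse_gene", "classification",
                                           "human_gene", "sources"])


def read_assertions(path: str | Path) -> list[OrthologAssertion]:
    """Read a TSV with columns mouse_gene, human_gene, source.

    Malformed rows (missing fields) are rejected with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mouse_gene", "human_gene", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"assertion table must have columns {sorted(required)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if not row.mouse_gene or not row.human_gene or not row.source:
            raise ValueError(f"malformed assertion at row {i}: {row}")
        out.append(OrthologAssertion(row.mouse_gene, row.human_gene, row.source))
    return out


def build_consensus(
    assertions: list[OrthologAssertion], universe: set[str]
) -> OrthologMap:
    """Classify every mouse gene in the universe from the pooled assertions.

    The set of distinct (normalized) human partners over all sources decides:
    size 1 -> one_to_one, size > 1 -> one_to_many, size 0 -> unmapped.
    Input order is irrelevant by construction (set semantics).
    """
    partners: dict[str, set[str]] = {}
    sources: dict[str, set[str]] = {}
    for a in assertions:
        m = normalize_gene_id(a.mouse_gene)
        h = normalize_gene_id(a.human_gene)
        partners.setdefault(m, set()).add(h)
        sources.setdefault(m, set()).add(a.source)

    records: dict[str, OrthologRecord] = {}
    for gene in universe:
        g = normalize_gene_id(gene)
        hs = partners.get(g, set())
        src = frozenset(sources.get(g, set()))
        if len(hs) == 1:
            rec = OrthologRecord(ONE_TO_ONE, next(iter(hs)), src)
        elif len(hs) > 1:
            rec = OrthologRecord(ONE_TO_MANY, None, src)
        else:
            rec = OrthologRecord(UNMAPPED, None, frozenset())
        records[gene] = rec

    # many-to-one transparency: several mouse genes sharing a human partner
    seen: dict[str, list[str]] = {}
    for g, rec in records.items():
        if rec.classification == ONE_TO_ONE:
            seen.setdefault(rec.human_gene, []).append(g)
    many_to_one = {h: gs for h, gs in seen.items() if len(gs) > 1}
    if many_to_one:
        logger.info("many-to-one human partners allowed: %d cases", len(many_to_one))
    return OrthologMap(records)


def apply_exclusion(
    omap: OrthologMap, genes: set[str]
) -> tuple[dict[str, str], StageLog]:
    """Keep only one-to-one genes, paired with their human ortholog.

    One-to-many genes are excluded (ambiguous identity); unmapped genes have
    nothing to pair with. Excluded counts are logged by class.
    """
    pairs: dict[str, str] = {}
    dropped = {ONE_TO_MANY: 0, UNMAPPED: 0}
    for g in genes:
        rec = omap.records.get(g)
        if rec is None:
            dropped[UNMAPPED] += 1
        elif rec.classification == ONE_TO_ONE:
            pairs[g] = rec.human_gene
        else:
            dropped[rec.classification] += 1
    lg = log_stage(StageLog(
        stage="ortholog_exclusion",
        n_in=len(genes),
        n_retained=len(pairs),
        n_dropped=len(genes) - len(pairs),
        detail={"excluded_one_to_many": dropped[ONE_TO_MANY],
                "excluded_unmapped": dropped[UNMAPPED]},
    ))
    return pairs, lg
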