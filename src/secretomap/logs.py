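"""Per-stage count logging: every filter reports |input| = |retained| + |dropped|.

The pipeline's figures are funnels of counts; each filtering operation
therefore returns a :class:`StageLog` alongside its result so that the
composed run can emit a machine-readable funnel report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("secretomap")


@dataclass(frozen=True)
class StageLog:
    """Counts for one filtering stage.

    Invariant: ``n_in == n_retained + n_dropped``.
    """

    stage: str
    n_in: int
    n_retained: int
    n_dropped: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_retained + self.n_dropped:
            raise ValueError(
                f"stage {self.stage!r}: {self.n_in} != "
                f"{self.n_retained} + {self.n_dropped}"
            )

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_retained": self.n_retained,
            "n_dropped": self.n_dropped,
        }
        if self.detail:
            d["detail"] = self.detail
        return d


def write_funnel(logs: list[StageLog], path) -> None:
    """Write an ordered funnel report (one entry per stage) as JSON."""
    with open(path, "w") as fh:
        json.dump([lg.to_dict() for lg in logs], fh, indent=2)


def log_stage(lg: StageLog) -> StageLog:
    logger.info(
        "%s: in=%d retained=%d dropped=%d",
        lg.stage, lg.n_in, lg.n_retained, lg.n_dropped,
    )
    return lg
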