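"""Target-decoy false-discovery-rate control for PSM lists.

The FDR at a score threshold t is estimated as D/T, the number of decoy
matches at or above t over the number of target matches at or above t
(the 2D/(T+D) variant is switchable). The filtering threshold is the
lowest score whose estimate stays at or below the configured target,
which maximizes the number of targets kept.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .search_engine import PSM

logger = logging.getLogger(__name__)


@dataclass
class FDRResult:
    score_threshold: float
    n_targets_kept: int
    n_decoys_kept: int
    estimated_fdr: float
    target_fdr: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "score_threshold": self.score_threshold,
                    "n_targets_kept": self.n_targets_kept,
                    "n_decoys_kept": self.n_decoys_kept,
                    "estimated_fdr": self.estimated_fdr,
                    "target_fdr": self.target_fdr,
                },
                fh,
                indent=2,
            )


def compute_threshold(
    psms: Sequence[PSM],
    target_fdr: float = 0.01,
    estimator: str = "d/t",
) -> FDRResult:
    """Score threshold achieving the target FDR while keeping the most
    targets.

    Scans all candidate thresholds (the observed scores, descending);
    at each, FDR = decoys-above / max(1, targets-above). Returns +inf
    and zero counts when no threshold qualifies.
    """
    if not 0 < target_fdr < 1:
        raise ValueError(f"target FDR must be in (0, 1), got {target_fdr}")
    if estimator not in ("d/t", "2d/(t+d)"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if not psms:
        return FDRResult(math.inf, 0, 0, 0.0, target_fdr)
    if not any(p.is_decoy for p in psms):
        logger.warning("no decoy PSMs present; FDR estimate is degenerate")

    scores = np.array([p.score for p in psms])
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, decoy = scores[order], decoy[order]
    # counts at thresholds equal to each distinct score, scanning down
    cum_decoys = np.cumsum(decoy)
    cum_targets = np.cumsum(~decoy)
    # only evaluate at the last index of each tied score block
    last_of_block = np.r_[scores[1:] != scores[:-1], True]
    best: tuple[float, int, int, float] | None = None
    for i in np.flatnonzero(last_of_block):
        t, d = int(cum_targets[i]), int(cum_decoys[i])
        if estimator == "d/t":
            fdr = d / max(1, t)
        else:
            fdr = 2 * d / max(1, t + d)
        if fdr <= target_fdr:
            best = (float(scores[i]), t, d, fdr)
    if best is None:
        return FDRResult(math.inf, 0, 0, 0.0, target_fdr)
    return FDRResult(best[0], best[1], best[2], best[3], target_fdr)


def filter_psms(psms: Sequence[PSM], result: FDRResult) -> list[PSM]:
    """Target PSMs with score >= threshold; decoys are never reported."""
    return [
        p for p in psms if not p.is_decoy and p.score >= result.score_threshold
    ]


def control_fdr(
    psms: Sequence[PSM], target_fdr: float = 0.01, estimator: str = "d/t"
) -> tuple[list[PSM], FDRResult]:
    """Convenience: threshold computation plus filtering in one call."""
    result = compute_threshold(psms, target_fdr=target_fdr, estimator=estimator)
    return filter_psms(psms, result), result
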