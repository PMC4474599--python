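"""Candidate-substrate calling, enrichment scoring and NSAF normalization.

The calling rule is the ligase-trap screen's: a protein is a candidate
substrate iff it was identified (TSC at or above a presence threshold)
in at least ``min_bait_runs`` of the bait purifications and in none of
the negative-control purifications, and is not excluded by a shared-
family rule (e.g. HLA alleles are excluded as a group when any family
member shows up in controls).

The enrichment score is mean bait counts over mean control counts, with
a pseudocount guarding the zero-background case.  NSAF for protein *i*
in one run is (SpC_i / L_i) / Σ_j (SpC_j / L_j), scaled by 1e5.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SpectralCountTable

__all__ = [
    "CallingConfig",
    "CandidateCall",
    "call_candidates",
    "enrichment_score",
    "nsaf",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

NSAF_SCALE = 1e5


@dataclass(frozen=True)
class CallingConfig:
    """Tunable parameters of the candidate-calling rule.

    ``min_bait_runs``: minimum number of bait runs a protein must be
    identified in (default 2, the screen's two-of-three rule).
    ``presence_threshold``: TSC at which a protein counts as identified
    in a run (default 1; the two-unique-peptide / <5% FDR identification
    filter is assumed applied upstream of the count matrix).
    ``control_presence_threshold``: TSC at which a control detection
    disqualifies (default 1 — any control evidence).
    ``exclusion_groups``: protein-id sets with shared-family semantics;
    if any member is control-detected, every member is excluded.
    ``pseudocount``: floor for the mean control count in the enrichment
    score; 0 requests a flagged-infinite score for zero background.
    """

    min_bait_runs: int = 2
    presence_threshold: int = 1
    control_presence_threshold: int = 1
    exclusion_groups: tuple[frozenset[str], ...] = ()
    pseudocount: float = 0.5
    condition: str | None = None  # restrict bait runs to one condition label

    def __post_init__(self) -> None:
        if self.min_bait_runs < 1:
            raise ValueError("min_bait_runs must be >= 1")
        if self.presence_threshold < 1 or self.control_presence_threshold < 1:
            raise ValueError("presence thresholds must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        object.__setattr__(
            self,
            "exclusion_groups",
            tuple(frozenset(g) for g in self.exclusion_groups),
        )


@dataclass
class CandidateCall:
    """Per-protein calling decision with detection tallies and scores."""

    protein: str
    n_bait_detected: int
    n_control_detected: int
    is_candidate: bool
    excluded_reason: str | None = None
    enrichment_score: float = 0.0  # math.inf when flagged-infinite
    total_bait_tsc: int = 0
    nsaf: dict[str, float] = field(default_factory=dict)


def enrichment_score(
    bait_counts: Sequence[int],
    control_counts: Sequence[int],
    pseudocount: float = 0.5,
) -> float:
    """Mean bait counts over mean control counts.

    The control mean is floored at ``pseudocount``; with pseudocount 0
    and an all-zero background the score is ``math.inf`` (flagged
    "unique to bait") rather than an error.  An empty control list is
    treated as zero background.
    """
    bait = np.asarray(bait_counts, dtype=float)
    if bait.size == 0:
        raise ValueError("bait_counts must be non-empty")
    ctrl = np.asarray(control_counts, dtype=float)
    if (bait < 0).any() or (ctrl.size and (ctrl < 0).any()):
        raise ValueError("spectral counts must be non-negative")
    bait_mean = float(bait.mean())
    ctrl_mean = float(ctrl.mean()) if ctrl.size else 0.0
    if bait_mean == 0.0:
        return 0.0
    denom = max(ctrl_mean, pseudocount)
    if denom == 0.0:
        return math.inf
    return bait_mean / denom


def call_candidates(
    table: SpectralCountTable,
    bait: str,
    config: CallingConfig | None = None,
) -> list[CandidateCall]:
    """Apply the candidate-substrate rule to every protein in the table.

    Returns one :class:`CandidateCall` per protein, in table order.
    Control runs are all runs with bait ``"control"``; with zero control
    runs the control-absence requirement is vacuously true (a degraded
    mode, logged as a warning).
    """
    config = config or CallingConfig()
    bait_idx = table.bait_run_indices(bait)
    if config.condition is not None:
        bait_idx = [i for i in bait_idx if table.runs[i].condition == config.condition]
    if not bait_idx:
        raise KeyError(
            f"no runs found for bait {bait!r}"
            + (f" in condition {config.condition!r}" if config.condition else "")
        )
    ctrl_idx = table.control_run_indices()
    if not ctrl_idx:
        warnings.warn(
            "no control runs in table: control absence is vacuously true",
            stacklevel=2,
        )
    if config.min_bait_runs > len(bait_idx):
        raise ValueError(
            f"min_bait_runs={config.min_bait_runs} exceeds the "
            f"{len(bait_idx)} available bait run(s)"
        )

    bait_counts = table.counts[:, bait_idx]
    ctrl_counts = table.counts[:, ctrl_idx] if ctrl_idx else np.zeros(
        (len(table.proteins), 0), dtype=int
    )
    n_bait = (bait_counts >= config.presence_threshold).sum(axis=1)
    n_ctrl = (ctrl_counts >= config.control_presence_threshold).sum(axis=1)

    # family exclusion: any control-detected member poisons the whole group
    control_detected = {p for p, n in zip(table.proteins, n_ctrl) if n > 0}
    excluded: dict[str, str] = {}
    for group in config.exclusion_groups:
        hits = sorted(group & control_detected)
        if hits:
            for member in group:
                excluded[member] = (
                    f"family exclusion: {', '.join(hits)} detected in controls"
                )

    calls = []
    for i, protein in enumerate(table.proteins):
        reason = excluded.get(protein)
        is_candidate = (
            n_bait[i] >= config.min_bait_runs and n_ctrl[i] == 0 and reason is None
        )
        score = enrichment_score(
            bait_counts[i], ctrl_counts[i] if ctrl_idx else [], config.pseudocount
        )
        calls.append(
            CandidateCall(
                protein=protein,
                n_bait_detected=int(n_bait[i]),
                n_control_detected=int(n_ctrl[i]),
                is_candidate=bool(is_candidate),
                excluded_reason=reason,
                enrichment_score=score,
                total_bait_tsc=int(bait_counts[i].sum()),
            )
        )
    logger.info(
        "called %d candidate(s) among %d proteins (%d bait, %d control runs)",
        sum(c.is_candidate for c in calls),
        len(calls),
        len(bait_idx),
        len(ctrl_idx),
    )
    return calls


def nsaf(table: SpectralCountTable, run_id: str) -> dict[str, float]:
    """Normalized spectral abundance factors (×1e5) for one run.

    Only proteins with nonzero counts in the run appear in the result;
    their values sum to 1e5.  Lengths are required for every counted
    protein.  An all-zero run yields an empty map with a warning.
    """
    j = table.run_index(run_id)
    col = table.counts[:, j]
    nonzero = [i for i, c in enumerate(col) if c > 0]
    if not nonzero:
        warnings.warn(f"run {run_id!r} has no nonzero counts", stacklevel=2)
        return {}
    if table.lengths is None:
        raise ValueError("protein lengths are required for NSAF")
    saf = np.array(
        [col[i] / table.lengths[table.proteins[i]] for i in nonzero], dtype=float
    )
    saf /= saf.sum()
    return {table.proteins[i]: float(v * NSAF_SCALE) for i, v in zip(nonzero, saf)}


def rank_candidates(calls: Sequence[CandidateCall]) -> list[CandidateCall]:
    """Order calls by abundance: descending total bait TSC, then
    descending enrichment score, then lexical protein id (stable)."""
    return sorted(
        calls,
        key=lambda c: (-c.total_bait_tsc, -c.enrichment_score, c.protein),
    )
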