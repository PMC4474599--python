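"""Discovery/validation tallies and simple IP arithmetic.

Confirmation bookkeeping follows the ligase-trap screen's criterion: a
novel candidate counts as confirmed when polyubiquitinated forms of it
were precipitated by the bait trap (regardless of whether its bulk
stability responded to ligase inhibition), a false positive when that
experiment was negative, and untested when it was not performed.  The
confirmation rate is (known + confirmed novel) over candidates actually
examined; the known fraction is known over all candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import enrichment_score
from .io import SpectralCountTable, Table1Fixture

__all__ = [
    "ValidationSummary",
    "tally_validation",
    "compare_conditions",
    "ip_background_fraction",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ValidationSummary:
    """Candidate tallies and derived percentages.

    Invariants: known + novel = candidates; confirmed + false positive
    + untested = novel.  Percentages are reported rounded (half away
    from zero) with the unrounded values retained.
    """

    n_candidates: int
    n_known: int
    n_novel: int
    n_novel_confirmed: int
    n_false_positive: int
    n_untested: int
    confirmation_rate_pct: float  # unrounded; nan when nothing was tested
    known_fraction_pct: float  # unrounded; nan for empty input

    def __post_init__(self) -> None:
        if self.n_known + self.n_novel != self.n_candidates:
            raise ValueError("known + novel must equal candidates")
        if self.n_novel_confirmed + self.n_false_positive + self.n_untested != self.n_novel:
            raise ValueError("confirmed + false_positive + untested must equal novel")

    @property
    def confirmation_rate_pct_rounded(self) -> int | None:
        if math.isnan(self.confirmation_rate_pct):
            return None
        return _round_half_away(self.confirmation_rate_pct)

    @property
    def known_fraction_pct_rounded(self) -> int | None:
        if math.isnan(self.known_fraction_pct):
            return None
        return _round_half_away(self.known_fraction_pct)


def tally_validation(annotations: Table1Fixture | pd.DataFrame) -> ValidationSummary:
    """Tally validation outcomes over annotated candidates.

    Accepts the packaged fixture or a DataFrame with columns ``status``
    (``known``/``novel``; ``below_bar`` rows are ignored) and
    ``ubiquitinated_forms`` (``yes``/``no``/``untested``/'' for novel
    rows).  A ``confirmed`` column, if present, must agree with
    ``ubiquitinated_forms`` (a false positive marked confirmed is a
    validation error).
    """
    if isinstance(annotations, Table1Fixture):
        df = annotations.candidates
    else:
        df = annotations[annotations["status"].isin(("known", "novel"))]

    bad_status = set(annotations["status"] if isinstance(annotations, pd.DataFrame) else []) - {
        "known",
        "novel",
        "below_bar",
    }
    if bad_status:
        raise ValueError(f"unknown status value(s): {sorted(bad_status)}")

    n_known = int((df["status"] == "known").sum())
    novel = df[df["status"] == "novel"]
    n_novel = len(novel)
    ub = novel["ubiquitinated_forms"].fillna("").replace("", "untested")
    bad = set(ub) - {"yes", "no", "untested"}
    if bad:
        raise ValueError(f"unknown ubiquitinated_forms value(s): {sorted(bad)}")
    if "confirmed" in novel.columns:
        conflict = novel[(novel["confirmed"].astype(bool)) & (ub == "no")]
        if len(conflict):
            raise ValueError(
                f"false positives marked confirmed: {conflict['protein'].tolist()}"
            )
    n_confirmed = int((ub == "yes").sum())
    n_false = int((ub == "no").sum())
    n_untested = int((ub == "untested").sum())
    n_candidates = n_known + n_novel
    n_tested = n_candidates - n_untested
    conf_pct = (
        100.0 * (n_known + n_confirmed) / n_tested if n_tested else float("nan")
    )
    known_pct = 100.0 * n_known / n_candidates if n_candidates else float("nan")
    return ValidationSummary(
        n_candidates=n_candidates,
        n_known=n_known,
        n_novel=n_novel,
        n_novel_confirmed=n_confirmed,
        n_false_positive=n_false,
        n_untested=n_untested,
        confirmation_rate_pct=conf_pct,
        known_fraction_pct=known_pct,
    )


def compare_conditions(
    table: SpectralCountTable,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-protein mean TSC in two drug conditions (e.g. MG132 ±).

    Returns a DataFrame indexed by protein with mean counts per
    condition, their difference (a − b) and the a/b ratio computed with
    the same pseudocount floor as the enrichment score.
    """
    idx_a = table.condition_run_indices(cond_a)
    idx_b = table.condition_run_indices(cond_b)
    if not idx_a:
        raise KeyError(f"no runs with condition {cond_a!r}")
    if not idx_b:
        raise KeyError(f"no runs with condition {cond_b!r}")
    mean_a = table.counts[:, idx_a].mean(axis=1)
    mean_b = table.counts[:, idx_b].mean(axis=1)
    ratio = [
        enrichment_score(table.counts[i, idx_a], table.counts[i, idx_b], pseudocount)
        for i in range(len(table.proteins))
    ]
    return pd.DataFrame(
        {
            f"mean_{cond_a}": mean_a,
            f"mean_{cond_b}": mean_b,
            "difference": mean_a - mean_b,
            "ratio": ratio,
        },
        index=pd.Index(table.proteins, name="protein"),
    )


def ip_background_fraction(loading_ratio: float) -> float:
    """Percent of input an IP band of equal intensity represents at a
    given IP:input loading ratio (e.g. 5000:1 loading → 0.02%)."""
    if loading_ratio <= 0:
        raise ValueError("loading_ratio must be positive")
    return 100.0 / loading_ratio
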