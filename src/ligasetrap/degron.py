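"""Scanning protein sequences for relaxed βTRCP phosphodegrons.

The βTRCP phosphodegron consensus is DpSG-X(1-4)-pS: an acidic/phospho
position, a phospho-acceptor, a glycine, a 1-4 residue spacer and a
final phospho-acceptor.  Acidic residues can substitute for the
phosphorylated serines (phosphomimetics), so positions 1, 2 and last
are scored over the class {D, E, S, T} with per-residue weights rather
than matched literally; phospho-status itself is not modeled — the scan
runs on unmodified sequence.

A window's score is the sum of the three class weights plus a small
bonus for additional acidic/phospho-acceptor residues inside the
spacer, bounded by 3.2.  The canonical DSG...S arrangement therefore
outranks acidic variants such as DDG or SDG, which in turn outrank
degenerate windows.  Degenerate ("relaxed") windows lacking the glycine
entirely are admitted at a flat score penalty, since validated
substrates occasionally present degrons with no glycine at all; they
can never outscore a glycine-anchored window in the same neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import ProteinRecord

__all__ = [
    "DegronModel",
    "DegronMatch",
    "scan",
    "best_degron",
    "compare_orthologs",
]

CANONICAL = "canonical_DSG"
ACIDIC_VARIANT = "acidic_variant"
RELAXED = "relaxed"


def _freeze(d: Mapping[str, float]) -> tuple[tuple[str, float], ...]:
    return tuple(sorted(d.items()))


@dataclass(frozen=True)
class DegronModel:
    """Weighted class model of the relaxed βTRCP degron.

    Position classes and default weights:

    * p1 (acidic or phospho-acceptor): D=1.0, E=0.8, S=0.6, T=0.6
    * p2 (phospho-acceptor or acidic): S=1.0, T=0.9, D=0.8, E=0.8
    * p3: glycine (anchor; required for canonical/acidic windows)
    * spacer: 1-4 residues, any identity; +0.05 per acidic or
      phospho-acceptor residue inside it, capped at +0.2
    * p_last: as p2

    ``allow_gless`` additionally admits windows with no glycine (class
    ``relaxed``), scored with ``gless_penalty`` subtracted — needed to
    recover the weakest printed degrons (e.g. DTTFLLD).
    ``allow_transposed_g`` admits a glycine swapped into position 2
    (D-G-D-type windows, also class ``relaxed``); off by default.
    """

    p1_weights: tuple[tuple[str, float], ...] = _freeze(
        {"D": 1.0, "E": 0.8, "S": 0.6, "T": 0.6}
    )
    p2_weights: tuple[tuple[str, float], ...] = _freeze(
        {"S": 1.0, "T": 0.9, "D": 0.8, "E": 0.8}
    )
    last_weights: tuple[tuple[str, float], ...] = _freeze(
        {"S": 1.0, "T": 0.9, "D": 0.8, "E": 0.8}
    )
    spacer_min: int = 1
    spacer_max: int = 4
    acidity_bonus: float = 0.05
    acidity_bonus_cap: float = 0.2
    allow_gless: bool = True
    gless_penalty: float = 1.0
    allow_transposed_g: bool = False

    def __post_init__(self) -> None:
        for name in ("p1_weights", "p2_weights", "last_weights"):
            for res, w in getattr(self, name):
                if not 0 < w <= 1:
                    raise ValueError(f"{name}[{res}] = {w} outside (0, 1]")
        if self.spacer_min < 1 or self.spacer_max < self.spacer_min:
            raise ValueError("spacer range must be non-empty with min >= 1")

    @property
    def p1(self) -> dict[str, float]:
        return dict(self.p1_weights)

    @property
    def p2(self) -> dict[str, float]:
        return dict(self.p2_weights)

    @property
    def last(self) -> dict[str, float]:
        return dict(self.last_weights)

    @property
    def max_score(self) -> float:
        return (
            max(w for _, w in self.p1_weights)
            + max(w for _, w in self.p2_weights)
            + max(w for _, w in self.last_weights)
            + self.acidity_bonus_cap
        )

    def spacer_bonus(self, spacer: str) -> float:
        n = sum(1 for r in spacer if r in "DEST")
        return min(n * self.acidity_bonus, self.acidity_bonus_cap)


@dataclass(frozen=True)
class DegronMatch:
    """A scored degron window (1-based inclusive coordinates).

    For glycine-anchored windows the span is 3 + spacer_len + 1
    residues; ``relaxed`` glycine-less windows span 2 + spacer_len + 1.
    """

    protein: str
    start: int
    end: int
    matched_string: str
    spacer_len: int
    score: float
    variant_class: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_string):
            raise ValueError("coordinates do not match the matched string length")


def _windows(model: DegronModel, sequence: str, protein: str) -> Iterable[DegronMatch]:
    p1, p2, last = model.p1, model.p2, model.last
    n = len(sequence)
    for i in range(n):  # 0-based p1 position
        r1 = sequence[i]
        if r1 not in p1:
            continue
        for s in range(model.spacer_min, model.spacer_max + 1):
            # glycine-anchored: p1 p2 G spacer p_last
            j_last = i + 3 + s
            if j_last < n:
                r2, r3, rl = sequence[i + 1], sequence[i + 2], sequence[j_last]
                if r2 in p2 and r3 == "G" and rl in last:
                    spacer = sequence[i + 3 : j_last]
                    score = p1[r1] + p2[r2] + last[rl] + model.spacer_bonus(spacer)
                    cls = CANONICAL if (r1 == "D" and r2 == "S") else ACIDIC_VARIANT
                    yield DegronMatch(
                        protein=protein,
                        start=i + 1,
                        end=j_last + 1,
                        matched_string=sequence[i : j_last + 1],
                        spacer_len=s,
                        score=score,
                        variant_class=cls,
                    )
                # transposed glycine: p1 G p2 spacer p_last
                if (
                    model.allow_transposed_g
                    and r2 == "G"
                    and r3 in p2
                    and rl in last
                ):
                    spacer = sequence[i + 3 : j_last]
                    score = (
                        p1[r1]
                        + p2[r3]
                        + last[rl]
                        + model.spacer_bonus(spacer)
                        - model.gless_penalty
                    )
                    yield DegronMatch(
                        protein=protein,
                        start=i + 1,
                        end=j_last + 1,
                        matched_string=sequence[i : j_last + 1],
                        spacer_len=s,
                        score=score,
                        variant_class=RELAXED,
                    )
            # glycine-less relaxed: p1 p2 spacer p_last
            if model.allow_gless:
                j_last = i + 2 + s
                if j_last < n:
                    r2, rl = sequence[i + 1], sequence[j_last]
                    if r2 in p2 and rl in last:
                        spacer = sequence[i + 2 : j_last]
                        score = (
                            p1[r1]
                            + p2[r2]
                            + last[rl]
                            + model.spacer_bonus(spacer)
                            - model.gless_penalty
                        )
                        yield DegronMatch(
                            protein=protein,
                            start=i + 1,
                            end=j_last + 1,
                            matched_string=sequence[i : j_last + 1],
                            spacer_len=s,
                            score=score,
                            variant_class=RELAXED,
                        )


def scan(
    record: ProteinRecord,
    model: DegronModel | None = None,
    min_score: float = 0.0,
) -> list[DegronMatch]:
    """All degron windows scoring at least ``min_score``.

    Overlapping matches are all reported, sorted by descending score,
    then ascending start, then ascending spacer length.  Sequences
    shorter than the minimal window yield an empty list.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    model = model or DegronModel()
    # a span readable both as glycine-anchored and as relaxed is reported
    # once, under its best-scoring interpretation
    by_span: dict[tuple[int, int], DegronMatch] = {}
    for m in _windows(model, record.sequence, record.id):
        prev = by_span.get((m.start, m.end))
        if prev is None or m.score > prev.score:
            by_span[(m.start, m.end)] = m
    hits = [m for m in by_span.values() if m.score >= min_score and m.score > 0]
    return sorted(hits, key=lambda m: (-m.score, m.start, m.spacer_len))


def best_degron(
    record: ProteinRecord,
    model: DegronModel | None = None,
    min_score: float = 0.0,
) -> DegronMatch | None:
    """The closest-to-consensus degron in a sequence, or ``None``.

    Highest score wins; ties go to the smaller spacer, then the
    earlier start.
    """
    hits = scan(record, model, min_score)
    if not hits:
        return None
    return min(hits, key=lambda m: (-m.score, m.spacer_len, m.start))


def _best_window_identity(window: str, sequence: str) -> tuple[int, list[bool]]:
    """Slide ``window`` along ``sequence``; return (best 0-based offset,
    per-position identity flags).  Ties go to the leftmost offset."""
    L = len(window)
    if len(sequence) < L:
        flags = [a == b for a, b in zip(window, sequence)]
        flags += [False] * (L - len(flags))
        return 0, flags
    best_off, best_flags, best_n = 0, [False] * L, -1
    for off in range(len(sequence) - L + 1):
        flags = [window[k] == sequence[off + k] for k in range(L)]
        n = sum(flags)
        if n > best_n:
            best_off, best_flags, best_n = off, flags, n
    return best_off, best_flags


def compare_orthologs(
    sequences: Mapping[str, Mapping[str, ProteinRecord]],
    reference_species: str = "human",
    model: DegronModel | None = None,
    min_score: float = 0.0,
    flank: int = 10,
) -> pd.DataFrame:
    """Alignment-free degron conservation across species.

    ``sequences`` maps protein → species → record (the reference
    species must be present for every protein).  For each protein the
    reference's best degron window, extended by ``flank`` residues on
    each side, is located in every ortholog by best local (Hamming)
    match; the identity fraction over the degron window proper is
    reported per species, along with each species' own best-degron
    string ("absent" when no window scores).  Per-position identity
    fractions across non-reference species are returned in the
    ``positional_identity`` column of the reference rows.
    """
    model = model or DegronModel()
    rows = []
    for protein, by_species in sequences.items():
        if reference_species not in by_species:
            raise KeyError(f"no {reference_species!r} sequence for {protein!r}")
        if len(by_species) < 2:
            raise ValueError(f"need >=2 species for {protein!r}")
        ref_rec = by_species[reference_species]
        ref_best = best_degron(ref_rec, model, min_score)
        per_pos: list[list[bool]] = []
        ref_row = {
            "protein": protein,
            "species": reference_species,
            "best_degron": ref_best.matched_string if ref_best else "absent",
            "identity": 1.0 if ref_best else float("nan"),
            "positional_identity": None,
        }
        species_rows = []
        for species, rec in by_species.items():
            if species == reference_species:
                continue
            own_best = best_degron(rec, model, min_score)
            identity = float("nan")
            if ref_best is not None:
                w0, w1 = ref_best.start - 1, ref_best.end  # 0-based half-open
                f0 = max(0, w0 - flank)
                neighborhood = ref_rec.sequence[f0 : min(len(ref_rec.sequence), w1 + flank)]
                off, _ = _best_window_identity(neighborhood, rec.sequence)
                # identity over the degron window proper within the located neighborhood
                win_off = off + (w0 - f0)
                aligned = rec.sequence[win_off : win_off + (w1 - w0)]
                flags = [
                    k < len(aligned) and ref_rec.sequence[w0 + k] == aligned[k]
                    for k in range(w1 - w0)
                ]
                per_pos.append(flags)
                identity = sum(flags) / len(flags)
            species_rows.append(
                {
                    "protein": protein,
                    "species": species,
                    "best_degron": own_best.matched_string if own_best else "absent",
                    "identity": identity,
                    "positional_identity": None,
                }
            )
        if per_pos:
            L = len(per_pos[0])
            ref_row["positional_identity"] = [
                sum(f[k] for f in per_pos) / len(per_pos) for k in range(L)
            ]
        rows.append(ref_row)
        rows.extend(species_rows)
    return pd.DataFrame(rows)
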