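"""Synthetic IP-MS tables, degron-bearing sequences and decay curves.

Every generator is seeded and bit-reproducible, and returns ground
truth alongside the data so calling, scanning and fitting can be
benchmarked without external downloads.

The count simulator emulates the ligase-trap experimental design: a few
bait purifications in which true substrates yield Poisson spectral
counts (with per-run dropout, mimicking low-abundance substrates that
miss a run), a sticky background of nonspecific proteins that shed
counts into every run, bait and control alike, and a silent remainder.
True substrates yield exactly zero control counts by construction,
matching the regime in which the unique-to-bait calling rule is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DecayTimecourse
from .io import AMINO_ACIDS, ProteinRecord, RunMetadata, SpectralCountTable

__all__ = [
    "IpmsSimConfig",
    "TruthLabels",
    "simulate_ipms",
    "generate_sequences",
    "simulate_decay",
]

SUBSTRATE = "substrate"
STICKY = "sticky_background"
ABSENT = "absent"


@dataclass(frozen=True)
class IpmsSimConfig:
    """Parameters of the IP-MS count simulation.

    Defaults mirror the screen's design: 3 bait and 2 control
    purifications; modest substrate abundance (mean 8 TSC) against a
    sticky background (mean 3 TSC) covering 20% of proteins; 10%
    per-run dropout motivated by candidates detected in only two of
    three runs.
    """

    n_proteins: int = 500
    substrate_fraction: float = 0.05
    n_bait_runs: int = 3
    n_control_runs: int = 2
    lambda_substrate: float = 8.0
    lambda_background: float = 3.0
    sticky_fraction: float = 0.2
    dropout: float = 0.1
    length_range: tuple[int, int] = (100, 1000)
    bait: str = "bait"
    condition: str = "MG132"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.substrate_fraction < 1:
            raise ValueError("substrate_fraction must be in (0, 1)")
        if not 0 < self.sticky_fraction < 1:
            raise ValueError("sticky_fraction must be in (0, 1)")
        if self.substrate_fraction + self.sticky_fraction >= 1:
            raise ValueError("substrate and sticky fractions must sum below 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lambda_substrate <= 0 or self.lambda_background < 0:
            raise ValueError("rates must be positive (background may be 0)")
        if self.n_bait_runs < 1 or self.n_control_runs < 0:
            raise ValueError("need >=1 bait run and >=0 control runs")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must be a non-empty positive range")


@dataclass
class TruthLabels:
    """Ground truth for simulated data: per-protein class and, for
    generated sequences, planted-degron positions (1-based starts)."""

    classes: dict[str, str] = field(default_factory=dict)
    planted_degrons: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def of_class(self, cls: str) -> list[str]:
        return [p for p, c in self.classes.items() if c == cls]


def simulate_ipms(config: IpmsSimConfig) -> tuple[SpectralCountTable, TruthLabels]:
    """Simulate a spectral-count table with known substrate labels.

    Substrates draw Poisson(``lambda_substrate``) counts in bait runs,
    each zeroed independently with probability ``dropout``, and 0 in
    controls.  Sticky proteins draw Poisson(``lambda_background``) in
    every run.  The rest are silent.  Lengths are uniform over
    ``length_range``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_sub = round(n * config.substrate_fraction)
    n_sticky = round(n * config.sticky_fraction)
    width = len(str(n))
    proteins = [f"P{i:0{width}d}" for i in range(n)]

    order = rng.permutation(n)
    substrates = sorted(order[:n_sub])
    sticky = sorted(order[n_sub : n_sub + n_sticky])

    n_runs = config.n_bait_runs + config.n_control_runs
    counts = np.zeros((n, n_runs), dtype=np.int64)
    bait_cols = np.arange(config.n_bait_runs)
    ctrl_cols = np.arange(config.n_bait_runs, n_runs)

    sub_counts = rng.poisson(config.lambda_substrate, size=(n_sub, len(bait_cols)))
    kept = rng.random(size=sub_counts.shape) >= config.dropout
    counts[np.ix_(substrates, bait_cols)] = sub_counts * kept
    if config.lambda_background > 0 and n_sticky:
        counts[np.ix_(sticky, np.arange(n_runs))] = rng.poisson(
            config.lambda_background, size=(n_sticky, n_runs)
        )

    lo, hi = config.length_range
    lengths = {p: int(L) for p, L in zip(proteins, rng.integers(lo, hi + 1, size=n))}

    runs = [
        RunMetadata(
            run_id=f"{config.bait}_{i + 1}",
            bait=config.bait,
            replicate=i + 1,
            condition=config.condition,
        )
        for i in range(config.n_bait_runs)
    ] + [
        RunMetadata(
            run_id=f"control_{i + 1}",
            bait="control",
            replicate=i + 1,
            condition=config.condition,
        )
        for i in range(config.n_control_runs)
    ]
    table = SpectralCountTable(proteins=proteins, runs=runs, counts=counts, lengths=lengths)

    classes = {p: ABSENT for p in proteins}
    for i in substrates:
        classes[proteins[i]] = SUBSTRATE
    for i in sticky:
        classes[proteins[i]] = STICKY
    return table, TruthLabels(classes=classes)


# background frequencies: uniform, with D/E/S/T (and G) down-weighted so
# spurious degron-class windows are rare outside planted motifs
_BG_DOWNWEIGHTED = frozenset("DESTG")
_BG_WEIGHT = 0.1


def _background_probs() -> np.ndarray:
    w = np.array([_BG_WEIGHT if aa in _BG_DOWNWEIGHTED else 1.0 for aa in AMINO_ACIDS])
    return w / w.sum()


def generate_sequences(
    n: int,
    length: int,
    planted: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], TruthLabels]:
    """Random protein sequences with motifs planted verbatim.

    ``planted`` lists (motif, 1-based start) pairs written into *every*
    sequence; windows must fit inside ``length`` and must not overlap.
    Background residues are drawn with acidic/phospho-acceptor letters
    down-weighted, keeping chance degron hits rare.
    """
    planted = planted or []
    spans = []
    for motif, start in planted:
        if start < 1 or start + len(motif) - 1 > length:
            raise ValueError(f"motif {motif!r} at {start} does not fit in length {length}")
        spans.append((start - 1, start - 1 + len(motif)))
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("planted windows overlap")

    rng = np.random.default_rng(seed)
    probs = _background_probs()
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    truth = TruthLabels()
    for i in range(n):
        residues = rng.choice(alphabet, size=length, p=probs)
        for motif, start in planted:
            residues[start - 1 : start - 1 + len(motif)] = list(motif)
        rec = ProteinRecord(id=f"synth{i:03d}", sequence="".join(residues))
        records.append(rec)
        truth.planted_degrons[rec.id] = list(planted)
        truth.classes[rec.id] = SUBSTRATE if planted else ABSENT
    return records, truth


def simulate_decay(
    k: float,
    times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    noise_sigma: float = 0.05,
    seed: int = 0,
    protein: str = "synthetic",
    condition: str = "chase",
) -> DecayTimecourse:
    """Exponential decay exp(-k t) with multiplicative lognormal noise.

    ``noise_sigma`` is the standard deviation of the log-intensity
    noise; 0 gives an exact exponential.  Loading is identically 1.
    """
    if k < 0:
        raise ValueError("decay rate k must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = np.exp(-k * t)
    if noise_sigma > 0:
        y = y * rng.lognormal(mean=0.0, sigma=noise_sigma, size=t.size)
    return DecayTimecourse(
        protein=protein,
        condition=condition,
        times=tuple(t),
        intensity=tuple(y),
        loading=tuple(np.ones_like(t)),
    )
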