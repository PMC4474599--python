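"""Readers, writers and packaged data for ligase-trap IP-MS analyses.

The central container is :class:`SpectralCountTable`, a dense proteins ×
purification-runs matrix of total spectral counts (TSC) with per-run
metadata (bait identity, replicate, drug condition) and optional protein
lengths for NSAF normalization.  Delimited-text round-tripping is exact:
``write_counts_table`` followed by :func:`read_counts_table` is the
identity on any valid table.

A packaged fixture reproduces the discovery/validation summary table of
the βTRCP ligase-trap screen (28 candidate substrates plus four known
substrates that fell below the calling bar), including spectral counts
for the three bait purifications, novelty status, validation outcomes
and the printed near-consensus degron strings.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "RunMetadata",
    "SpectralCountTable",
    "ProteinRecord",
    "Table1Fixture",
    "read_counts_table",
    "write_counts_table",
    "read_fasta",
    "write_fasta",
    "read_densitometry",
    "load_table1_fixture",
]

CONTROL_BAIT = "control"

# 20 canonical amino acids, upper case
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the expected format."""


@dataclass(frozen=True)
class RunMetadata:
    """One purification run: bait ligase trap (or ``"control"``), replicate, condition."""

    run_id: str
    bait: str
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValueError("run_id must be non-empty")
        if not self.bait:
            raise ValueError("bait must be non-empty")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")

    @property
    def is_control(self) -> bool:
        return self.bait == CONTROL_BAIT


@dataclass
class SpectralCountTable:
    """Dense matrix of total spectral counts per (protein, purification run).

    Parameters
    ----------
    proteins
        Ordered protein identifiers (opaque strings, unique).
    runs
        Ordered :class:`RunMetadata`, one per column; ``run_id`` unique.
    counts
        Integer array of shape ``(len(proteins), len(runs))``, all ≥ 0.
    lengths
        Optional protein lengths in residues (for NSAF), one per protein.
    """

    proteins: list[str]
    runs: list[RunMetadata]
    counts: np.ndarray
    lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.proteins), len(self.runs)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.runs)} runs"
            )
        if len(set(self.proteins)) != len(self.proteins):
            dupes = {p for p in self.proteins if self.proteins.count(p) > 1}
            raise ValueError(f"duplicated protein identifiers: {sorted(dupes)}")
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise ValueError("run_id values must be unique within a table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths is not None:
            missing = set(self.proteins) - set(self.lengths)
            if missing:
                raise ValueError(f"lengths missing for proteins: {sorted(missing)}")
            bad = {p: L for p, L in self.lengths.items() if L <= 0}
            if bad:
                raise ValueError(f"lengths must be positive, got {bad}")

    # -- indexing helpers -------------------------------------------------

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    def run_index(self, run_id: str) -> int:
        try:
            return self.run_ids.index(run_id)
        except ValueError:
            raise KeyError(f"unknown run_id {run_id!r}") from None

    def protein_index(self, protein: str) -> int:
        try:
            return self.proteins.index(protein)
        except ValueError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def bait_run_indices(self, bait: str) -> list[int]:
        return [i for i, r in enumerate(self.runs) if r.bait == bait]

    def control_run_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.runs) if r.is_control]

    def condition_run_indices(self, condition: str) -> list[int]:
        return [i for i, r in enumerate(self.runs) if r.condition == condition]

    def counts_for(self, protein: str) -> np.ndarray:
        return self.counts[self.protein_index(protein)]

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (proteins × run_ids)."""
        return pd.DataFrame(self.counts, index=self.proteins, columns=self.run_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        return (
            self.proteins == other.proteins
            and self.runs == other.runs
            and np.array_equal(self.counts, other.counts)
            and self.lengths == other.lengths
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an opaque identifier (canonical residues, upper case)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"non-canonical residues {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Table1Fixture:
    """Packaged discovery/validation table of the βTRCP ligase-trap screen.

    ``table`` holds the three bait-purification TSC columns for all 32
    printed rows (28 candidates above the bar, 4 known substrates below
    it).  ``annotations`` carries per-protein status (``known`` /
    ``novel`` / ``below_bar``), validation flags and the printed degron
    string ('' where the table leaves the cell blank; slash-separated
    when several motifs are listed).  HIVEP1/2 is stored as the single
    row the table prints, though it aggregates two loci.
    """

    table: SpectralCountTable
    annotations: pd.DataFrame

    CANDIDATE_STATUSES = ("known", "novel")

    def __post_init__(self) -> None:
        status = self.annotations["status"]
        n_known = int((status == "known").sum())
        n_novel = int((status == "novel").sum())
        n_below = int((status == "below_bar").sum())
        if n_known + n_novel != 28:
            raise ValueError(f"expected 28 candidate rows, got {n_known + n_novel}")
        if n_known != 12 or n_novel != 16:
            raise ValueError(
                f"expected 12 known + 16 novel rows, got {n_known} + {n_novel}"
            )
        if n_below != 4:
            raise ValueError(f"expected 4 below-bar rows, got {n_below}")

    @property
    def candidates(self) -> pd.DataFrame:
        return self.annotations[self.annotations["status"].isin(self.CANDIDATE_STATUSES)]

    @property
    def below_bar(self) -> pd.DataFrame:
        return self.annotations[self.annotations["status"] == "below_bar"]

    def degron_strings(self, protein: str) -> list[str]:
        """The printed motif string(s) for one protein ([] when blank)."""
        cell = self.annotations.loc[
            self.annotations["protein"] == protein, "degron"
        ].squeeze()
        if not isinstance(cell, str) or not cell:
            return []
        return cell.split("/")


# ---------------------------------------------------------------------------
# delimited-text I/O


def _parse_metadata(
    metadata: str | Path | Mapping[str, Mapping[str, object]],
    run_ids: Sequence[str],
    sep: str,
) -> list[RunMetadata]:
    if isinstance(metadata, (str, Path)):
        meta_df = pd.read_csv(metadata, sep=sep, dtype=str).fillna("")
        required = {"run_id", "bait"}
        if not required.issubset(meta_df.columns):
            raise FormatError(
                f"run metadata must have columns {sorted(required)}, "
                f"got {list(meta_df.columns)}"
            )
        mapping: dict[str, dict[str, object]] = {}
        for _, row in meta_df.iterrows():
            mapping[row["run_id"]] = {
                "bait": row["bait"],
                "replicate": int(row["replicate"]) if row.get("replicate", "") else 1,
                "condition": row.get("condition", ""),
            }
    else:
        mapping = {k: dict(v) for k, v in metadata.items()}

    runs = []
    for rid in run_ids:
        if rid not in mapping:
            raise FormatError(f"no metadata declared for run column {rid!r}")
        m = mapping[rid]
        runs.append(
            RunMetadata(
                run_id=rid,
                bait=str(m["bait"]),
                replicate=int(m.get("replicate", 1)),
                condition=str(m.get("condition", "")),
            )
        )
    return runs


def read_counts_table(
    path: str | Path,
    metadata: str | Path | Mapping[str, Mapping[str, object]],
    *,
    sep: str = "\t",
    lengths: Mapping[str, int] | None = None,
    missing_as_zero: bool = False,
) -> SpectralCountTable:
    """Read a delimited spectral-count matrix plus run metadata.

    The first column holds protein identifiers; every remaining column
    is a purification run that must be declared in ``metadata`` (a
    TSV/CSV with columns ``run_id``, ``bait`` and optionally
    ``replicate``, ``condition`` — or an equivalent inline mapping).
    Counts must be non-negative integers; empty cells are rejected
    unless ``missing_as_zero`` is set, in which case they become 0 with
    a warning.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("counts table needs a protein column plus >=1 run column")
    first = df.columns[0]
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"duplicated header column(s): {dupes}")
    proteins = df[first].tolist()
    if any(pd.isna(p) or p == "" for p in proteins):
        raise FormatError("empty protein identifier in first column")
    if len(set(proteins)) != len(proteins):
        dupes = sorted({p for p in proteins if proteins.count(p) > 1})
        raise ValueError(f"duplicated protein id(s): {dupes}")

    run_ids = list(df.columns[1:])
    raw = df[run_ids]
    if raw.isna().any().any():
        if not missing_as_zero:
            raise ValueError(
                "missing count cells (set missing_as_zero=True to treat as 0)"
            )
        n_missing = int(raw.isna().sum().sum())
        warnings.warn(f"{n_missing} missing count cell(s) treated as 0", stacklevel=2)
        raw = raw.fillna("0")
    try:
        numeric = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count value: {exc}") from None
    if (numeric.to_numpy() % 1 != 0).any():
        raise ValueError("fractional spectral counts are not allowed")
    if (numeric.to_numpy() < 0).any():
        raise ValueError("negative spectral counts are not allowed")
    counts = numeric.to_numpy().astype(np.int64)

    runs = _parse_metadata(metadata, run_ids, sep)
    return SpectralCountTable(
        proteins=proteins,
        runs=runs,
        counts=counts,
        lengths=dict(lengths) if lengths is not None else None,
    )


def write_counts_table(
    table: SpectralCountTable,
    counts_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    sep: str = "\t",
) -> None:
    """Write a table (and optionally its run metadata) as delimited text."""
    df = table.to_frame()
    df.index.name = "protein"
    df.to_csv(counts_path, sep=sep)
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "run_id": [r.run_id for r in table.runs],
                "bait": [r.bait for r in table.runs],
                "replicate": [r.replicate for r in table.runs],
                "condition": [r.condition for r in table.runs],
            }
        )
        meta.to_csv(metadata_path, sep=sep, index=False)


def read_fasta(
    path: str | Path, *, on_stop: str = "reject"
) -> list[ProteinRecord]:
    """Read protein FASTA; ids are the first whitespace token of each header.

    Sequences are upper-cased.  ``on_stop`` controls '*' handling:
    ``"reject"`` (default) raises, ``"strip"`` removes them.
    """
    if on_stop not in ("reject", "strip"):
        raise ValueError(f"on_stop must be 'reject' or 'strip', got {on_stop!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            if on_stop == "reject":
                raise FormatError(f"record {rec.id!r} contains stop character '*'")
            seq = seq.replace("*", "")
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_densitometry(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a band-densitometry table.

    Expected columns: ``protein``, ``condition``, ``time_h``,
    ``intensity`` and optionally ``loading`` (loading-control band).
    """
    df = pd.read_csv(path, sep=sep)
    required = {"protein", "condition", "time_h", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"densitometry table missing column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# packaged fixture

_FIXTURE_RUNS = [
    RunMetadata(run_id=f"btrcp_mg132_{i}", bait="bTRCP", replicate=i, condition="MG132")
    for i in (1, 2, 3)
]


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged βTRCP discovery/validation table.

    Spectral counts are stored verbatim as printed; the three count
    columns map to the three bait (MG132-treated) purifications.  The
    negative-control purifications are not part of the printed table —
    by construction every candidate row had zero control detections,
    and the below-bar rows had at least one.
    """
    resource = importlib.resources.files("ligasetrap.data").joinpath("table1.tsv")
    with importlib.resources.as_file(resource) as p:
        ann = pd.read_csv(p, sep="\t", dtype=str)
    for col in ("ubiquitinated_forms", "shrna_stabilized", "mln4924"):
        ann[col] = ann[col].fillna("")
    ann["degron"] = ann["degron"].fillna("")
    ann["note"] = ann["note"].fillna("")
    counts = ann[["tsc1", "tsc2", "tsc3"]].astype(int).to_numpy()
    table = SpectralCountTable(
        proteins=ann["protein"].tolist(),
        runs=list(_FIXTURE_RUNS),
        counts=counts,
    )
    ann = ann.drop(columns=["tsc1", "tsc2", "tsc3"]).reset_index(drop=True)
    return Table1Fixture(table=table, annotations=ann)
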