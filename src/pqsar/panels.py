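"""Domain-peptide affinity panels: reading, validation, transforms, splits.

A panel is one peptide-recognition domain's SPOT-array screen: a list of
fixed-length peptide sequences with their measured binding intensities in
Boehringer light units (BLU).  Modeling happens on the log10 scale
(LogBLU), so records carry both the raw intensity and its log transform.

The package also ships a registry of the 18 reference SH3/PDZ/14-3-3
panels (domain metadata and valid-record counts) used for bookkeeping.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aad import PARENT_RESIDUE, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

DOMAIN_CLASSES = ("SH3", "PDZ", "14-3-3", "other")


class PanelFormatError(ValueError):
    """Raised for unreadable or malformed panel files."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide and its measured binding intensity.

    ``blu`` may be NaN for records with no reported affinity;
    ``log_affinity`` is log10(blu), set by :func:`log_transform`.
    """

    sequence: str
    blu: float
    log_affinity: float | None = None


@dataclass(frozen=True)
class PeptidePanel:
    panel_id: str
    records: tuple
    domain_class: str = "other"
    domain_name: str = ""
    domain_index: str = ""
    species: str = ""

    def __post_init__(self):
        if self.domain_class not in DOMAIN_CLASSES:
            raise PanelFormatError(
                f"unknown domain class {self.domain_class!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def length(self) -> int:
        """Common peptide length; raises if lengths are mixed."""
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise PanelFormatError(
                f"panel {self.panel_id!r} has mixed peptide lengths {sorted(lengths)}"
            )
        return lengths.pop()

    def log_affinities(self) -> np.ndarray:
        vals = [r.log_affinity for r in self.records]
        if any(v is None for v in vals):
            raise PanelFormatError(
                f"panel {self.panel_id!r} has untransformed records; "
                "call log_transform first"
            )
        return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_META_KEYS = ("panel_id", "domain_class", "domain_name", "domain_index", "species")


def read_metadata(path) -> dict:
    """Read a key=value sidecar file of panel metadata."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key in _META_KEYS:
                meta[key] = val.strip()
    return meta


def _normalize_sequence(seq: str) -> str:
    # uppercase standard letters, preserve declared phospho codes
    return "".join(c if c in PARENT_RESIDUE else c.upper() for c in seq.strip())


def _records_from_frame(df: pd.DataFrame) -> tuple:
    records = []
    for seq, blu in zip(df["sequence"], df["blu"]):
        blu = float(blu) if pd.notna(blu) else math.nan
        records.append(PeptideRecord(sequence=_normalize_sequence(str(seq)), blu=blu))
    return tuple(records)


def read_panel(path, meta: dict | None = None, affinity_table=None) -> PeptidePanel:
    """Read a panel from a TSV/CSV table or a FASTA + affinity table pair.

    Tabular input needs ``sequence`` and ``blu`` columns.  FASTA input
    (``.fasta``/``.fa``) needs ``affinity_table``, a two-column TSV mapping
    record id to BLU.  ``meta`` supplies panel metadata; a sidecar file
    ``<path>.meta`` is read automatically when present.
    """
    path = Path(path)
    meta = dict(meta) if meta else {}
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        meta = {**read_metadata(sidecar), **meta}

    if path.suffix.lower() in (".fasta", ".fa"):
        if affinity_table is None:
            raise PanelFormatError(
                "FASTA panels require an id->blu affinity table"
            )
        aff = pd.read_csv(affinity_table, sep="\t", dtype={0: str})
        if aff.shape[1] < 2:
            raise PanelFormatError(
                "affinity table must have columns 'id' and 'blu'"
            )
        aff.columns = ["id", "blu", *aff.columns[2:]]
        blu_by_id = dict(zip(aff["id"], aff["blu"]))
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in blu_by_id:
                raise PanelFormatError(
                    f"FASTA record {rec.id!r} missing from the affinity table"
                )
            rows.append({"sequence": str(rec.seq), "blu": blu_by_id[rec.id]})
        if not rows:
            raise PanelFormatError(f"empty FASTA panel: {path}")
        df = pd.DataFrame(rows)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            raise PanelFormatError(f"empty panel file: {path}") from None
        missing = {"sequence", "blu"} - set(df.columns)
        if missing:
            raise PanelFormatError(
                f"panel file {path} lacks required column(s): "
                f"{', '.join(sorted(missing))}"
            )
        if df.empty:
            raise PanelFormatError(f"panel file {path} has no records")

    return PeptidePanel(
        panel_id=meta.get("panel_id", path.stem),
        domain_class=meta.get("domain_class", "other"),
        domain_name=meta.get("domain_name", ""),
        domain_index=meta.get("domain_index", ""),
        species=meta.get("species", ""),
        records=_records_from_frame(df),
    )


def write_panel(panel: PeptidePanel, path, float_format: str = "%.6f") -> None:
    """Write a panel as a TSV with a key=value metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sequence\tblu\n")
        for rec in panel.records:
            fh.write(f"{rec.sequence}\t{float_format % rec.blu}\n")
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        for key in _META_KEYS:
            fh.write(f"{key}={getattr(panel, key)}\n")


# ---------------------------------------------------------------------------
# validation, transform, split
# ---------------------------------------------------------------------------

def default_alphabet() -> frozenset:
    """Standard residues plus the declared phospho codes."""
    return frozenset(STANDARD_RESIDUES) | frozenset(PARENT_RESIDUE)


def filter_valid(panel: PeptidePanel, alphabet=None):
    """Drop invalid records; return the cleaned panel and an exclusion report.

    Exclusion reasons, in the order applied: ``missing_affinity`` (NaN BLU),
    ``nonpositive_affinity`` (BLU <= 0, covering non-binders), ``invalid_residue``
    (codes outside the alphabet policy), ``length_mismatch`` (length differs
    from the panel's modal length, since positionwise encoding needs fixed L).
    """
    alphabet = frozenset(alphabet) if alphabet is not None else default_alphabet()
    report = Counter()
    survivors = []
    for rec in panel.records:
        if rec.blu is None or math.isnan(rec.blu):
            report["missing_affinity"] += 1
        elif rec.blu <= 0:
            report["nonpositive_affinity"] += 1
        elif not set(rec.sequence) <= alphabet or not rec.sequence:
            report["invalid_residue"] += 1
        else:
            survivors.append(rec)
    if survivors:
        modal_len = Counter(len(r.sequence) for r in survivors).most_common(1)[0][0]
        kept = [r for r in survivors if len(r.sequence) == modal_len]
        if len(kept) < len(survivors):
            report["length_mismatch"] += len(survivors) - len(kept)
        survivors = kept
    if not survivors:
        raise PanelFormatError(
            f"empty panel after validation: {panel.panel_id!r} "
            f"(exclusions: {dict(report)})"
        )
    return replace(panel, records=tuple(survivors)), dict(report)


def write_exclusion_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason, count in report.items():
            fh.write(f"{reason}\t{count}\n")


def log_transform(panel: PeptidePanel) -> PeptidePanel:
    """Set log_affinity = log10(blu) on every record (all BLU must be > 0)."""
    records = []
    for i, rec in enumerate(panel.records):
        if not (rec.blu > 0):
            raise ValueError(
                f"record {i} ({rec.sequence!r}) in panel {panel.panel_id!r} "
                f"has non-positive BLU {rec.blu!r}; filter the panel first"
            )
        records.append(replace(rec, log_affinity=math.log10(rec.blu)))
    return replace(panel, records=tuple(records))


@dataclass(frozen=True)
class SplitSpec:
    """A seeded train/test partition of panel record indices."""

    seed: int
    train_fraction: float
    train_indices: tuple
    test_indices: tuple

    def __post_init__(self):
        if set(self.train_indices) & set(self.test_indices):
            raise ValueError("train and test indices overlap")


def split_panel(panel: PeptidePanel, seed: int, train_fraction: float = 2 / 3) -> SplitSpec:
    """Random train/test split: a seeded permutation, first floor(f*n) to train."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = len(panel)
    if n < 3:
        raise ValueError(f"panel {panel.panel_id!r} has {n} records; need >= 3")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(train_fraction * n)
    return SplitSpec(
        seed=seed,
        train_fraction=train_fraction,
        train_indices=tuple(int(i) for i in perm[:n_train]),
        test_indices=tuple(int(i) for i in perm[n_train:]),
    )


def subset_panel(panel: PeptidePanel, indices) -> PeptidePanel:
    """Panel restricted to the given record indices, in the given order."""
    return replace(panel, records=tuple(panel.records[i] for i in indices))


# ---------------------------------------------------------------------------
# reference panel registry
# ---------------------------------------------------------------------------

def reference_panels() -> pd.DataFrame:
    """The 18 reference SH3/PDZ/14-3-3 panels: metadata and valid counts."""
    with resources.as_file(
        resources.files("pqsar").joinpath("data", "reference_panels.tsv")
    ) as path:
        return pd.read_csv(path, sep="\t")
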