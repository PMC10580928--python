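"""Typed readers/writers for the external formats the pipeline consumes.

Formats: FASTA (isolates, ASVs, reference sets), tab-separated tables with a
header row (counts, metadata, copy numbers, plate counts, DAPI counts) and
Newick trees.  All readers validate and reject malformed input instead of
coercing; every writer produces files its paired reader parses back to an
equal value.  Sequences are stored uppercase with U converted to T.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import skbio

from ._alignment import IUPAC_DNA

SEASONS = ("winter", "spring", "summer", "fall")
TREATMENTS = ("t0", "CL", "CD", "PL", "PD", "DL", "VL")
TIMES = ("t0", "tf")
MEDIA = ("MA", "mR2A")

_IUPAC_SET = frozenset(IUPAC_DNA)
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_TREATMENT_CANON = {t.lower(): t for t in TREATMENTS}
_SEASON_CANON = {s.lower(): s for s in SEASONS}
_TIME_CANON = {t.lower(): t for t in TIMES}
_MEDIUM_CANON = {m.lower(): m for m in MEDIA}


class FormatError(ValueError):
    """Malformed external input (names the offending record/cell)."""


def _canon(label: str, table: Mapping[str, str], what: str) -> str:
    try:
        return table[str(label).strip().lower()]
    except KeyError:
        raise FormatError(f"unknown {what} label: {label!r}") from None


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, U->T, and validate against the IUPAC DNA alphabet."""
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise FormatError(f"{context}: empty sequence")
    bad = set(s) - _IUPAC_SET
    if bad:
        raise FormatError(f"{context}: non-IUPAC characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity mapping (R<->Y, B<->V, ...)."""
    s = normalize_sequence(seq, context="reverse_complement input")
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Sequences are uppercased (U converted to T) and validated; duplicate ids
    and empty sequences are rejected.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = normalize_sequence(str(rec.seq), context=f"{path}:{rec.id}")
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    """Write an id -> sequence mapping as FASTA wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(normalize_sequence(s, context=i)), id=i, description="")
        for i, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Isolates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IsolateRecord:
    """One isolate: its near-full-length 16S sequence plus experiment labels."""

    isolate_id: str
    sequence: str
    season: str
    treatment: str
    time: str
    medium: str
    replicate: str = "1"
    genus: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, context=self.isolate_id)
        self.season = _canon(self.season, _SEASON_CANON, "season")
        self.treatment = _canon(self.treatment, _TREATMENT_CANON, "treatment")
        self.time = _canon(self.time, _TIME_CANON, "time")
        self.medium = _canon(self.medium, _MEDIUM_CANON, "medium")
        if (self.treatment == "t0") != (self.time == "t0"):
            raise FormatError(
                f"{self.isolate_id}: treatment 't0' and time 't0' must coincide "
                f"(got treatment={self.treatment!r}, time={self.time!r})"
            )

    @property
    def group(self) -> tuple[str, str, str]:
        return (self.season, self.treatment, self.time)


def read_isolates(fasta_path: str | Path, meta_path: str | Path) -> list[IsolateRecord]:
    """Join an isolate FASTA with its metadata TSV into IsolateRecords.

    The join is strict in both directions: an isolate missing from either
    file aborts the run (silent drops would bias downstream denominators).
    """
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"isolate_id", "season", "treatment", "time", "medium", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{meta_path}: missing metadata columns {sorted(missing)}")
    if meta["isolate_id"].duplicated().any():
        dup = meta.loc[meta["isolate_id"].duplicated(), "isolate_id"].iloc[0]
        raise FormatError(f"{meta_path}: duplicate isolate_id {dup!r}")
    meta_ids = set(meta["isolate_id"])
    if meta_ids != set(seqs):
        only_fa = sorted(set(seqs) - meta_ids)[:5]
        only_meta = sorted(meta_ids - set(seqs))[:5]
        raise FormatError(
            f"isolate FASTA/metadata mismatch (fasta-only: {only_fa}, "
            f"meta-only: {only_meta})"
        )
    records = []
    for row in meta.itertuples(index=False):
        records.append(
            IsolateRecord(
                isolate_id=row.isolate_id,
                sequence=seqs[row.isolate_id],
                season=row.season,
                treatment=row.treatment,
                time=row.time,
                medium=row.medium,
                replicate=str(row.replicate),
                genus=getattr(row, "genus", None),
                class_label=getattr(row, "class_label", None),
            )
        )
    return records


def write_isolates(
    fasta_path: str | Path, meta_path: str | Path, isolates: Iterable[IsolateRecord]
) -> None:
    isolates = list(isolates)
    write_fasta(fasta_path, {r.isolate_id: r.sequence for r in isolates})
    pd.DataFrame(
        {
            "isolate_id": [r.isolate_id for r in isolates],
            "season": [r.season for r in isolates],
            "treatment": [r.treatment for r in isolates],
            "time": [r.time for r in isolates],
            "medium": [r.medium for r in isolates],
            "replicate": [r.replicate for r in isolates],
            "genus": [r.genus or "" for r in isolates],
            "class_label": [r.class_label or "" for r in isolates],
        }
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Amplicon table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AmpliconTable:
    """Samples x ASVs integer read counts plus ASV sequences and metadata."""

    counts: pd.DataFrame  # index = sample ids, columns = ASV ids, int
    asv_sequences: dict[str, str]
    sample_meta: pd.DataFrame  # index = sample ids; season/treatment/time/replicate
    asv_class: dict[str, str] = dataclasses.field(default_factory=dict)
    asv_genus: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing_seq = [a for a in self.counts.columns if a not in self.asv_sequences]
        if missing_seq:
            raise FormatError(f"ASVs without a sequence: {missing_seq[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("amplicon read counts must be integers")
        if (vals < 0).any():
            raise FormatError("amplicon read counts must be non-negative")
        totals = vals.sum(axis=1)
        if (totals <= 0).any():
            bad = self.counts.index[np.asarray(totals) <= 0][0]
            raise FormatError(f"sample {bad!r} has zero total reads")
        missing_meta = [s for s in self.counts.index if s not in self.sample_meta.index]
        if missing_meta:
            raise FormatError(f"samples without metadata: {missing_meta[:5]}")
        for col in ("season", "treatment", "time", "replicate"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_of(self, sample_id: str) -> tuple[str, str, str]:
        row = self.sample_meta.loc[sample_id]
        return (row["season"], row["treatment"], row["time"])

    def groups(self) -> dict[tuple[str, str, str], list[str]]:
        """Sample ids per (season, treatment, time) group, in table order."""
        out: dict[tuple[str, str, str], list[str]] = {}
        for s in self.counts.index:
            out.setdefault(self.group_of(s), []).append(s)
        return out

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        vals = self.counts.to_numpy(dtype=float)
        return pd.DataFrame(
            vals / vals.sum(axis=1, keepdims=True),
            index=self.counts.index,
            columns=self.counts.columns,
        )


def _read_counts_tsv(counts_path: str | Path) -> pd.DataFrame:
    """Read a counts TSV, auto-detecting orientation from the header flag.

    The first header cell must be ``asv_id`` (rows are ASVs) or ``sample_id``
    (rows are samples).
    """
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    flag = df.columns[0].strip().lower()
    if flag not in ("asv_id", "sample_id"):
        raise FormatError(
            f"{counts_path}: first header cell must be 'asv_id' or 'sample_id', "
            f"got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    for col in df.columns:
        for row_label, raw in df[col].items():
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{counts_path}: non-integer read value {raw!r} at "
                    f"row {row_label!r}, column {col!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{counts_path}: negative read value at row {row_label!r}, "
                    f"column {col!r}"
                )
    df = df.astype(np.int64)
    if flag == "asv_id":
        df = df.T  # -> samples x ASVs
    df.index.name = "sample_id"
    return df


def read_amplicon_table(
    counts_path: str | Path,
    fasta_path: str | Path,
    meta_path: str | Path,
) -> AmpliconTable:
    """Assemble an :class:`AmpliconTable` from counts + FASTA + metadata TSV."""
    counts = _read_counts_tsv(counts_path)
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{meta_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    missing = [s for s in counts.index if s not in meta.index]
    if missing:
        raise FormatError(f"{meta_path}: samples without metadata: {missing[:5]}")
    # per-ASV taxonomy is an optional separate TSV (read_asv_taxonomy); the
    # caller attaches it after construction when available
    return AmpliconTable(
        counts=counts,
        asv_sequences={a: seqs[a] for a in counts.columns if a in seqs},
        sample_meta=meta,
    )


def write_amplicon_table(
    table: AmpliconTable,
    counts_path: str | Path,
    fasta_path: str | Path,
    meta_path: str | Path,
    *,
    orientation: str = "asv_id",
) -> None:
    """Write the three files :func:`read_amplicon_table` consumes."""
    if orientation == "asv_id":
        df = table.counts.T
        df.index.name = "asv_id"
    elif orientation == "sample_id":
        df = table.counts.copy()
        df.index.name = "sample_id"
    else:
        raise ValueError(f"orientation must be 'asv_id' or 'sample_id': {orientation!r}")
    df.to_csv(counts_path, sep="\t")
    write_fasta(fasta_path, table.asv_sequences)
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_asv_taxonomy(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read an ASV taxonomy TSV (asv_id, class[, genus]) into two mappings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in df.columns or "class" not in df.columns:
        raise FormatError(f"{path}: taxonomy TSV needs 'asv_id' and 'class' columns")
    classes = dict(zip(df["asv_id"], df["class"]))
    genera = dict(zip(df["asv_id"], df["genus"])) if "genus" in df.columns else {}
    return classes, genera


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CopyNumberTable:
    """Mean 16S rRNA gene copy number per taxonomic class.

    SAR11 is carried as its own key (the study treats it separately from the
    Alphaproteobacteria class mean); ``default_copies`` is the fallback for
    classes absent from the table.
    """

    copies: dict[str, float]
    default_copies: float = 1.0

    def __post_init__(self) -> None:
        if self.default_copies <= 0:
            raise FormatError("default copy number must be > 0")
        for k, v in self.copies.items():
            if v <= 0:
                raise FormatError(f"copy number for {k!r} must be > 0, got {v}")
        if "SAR11" not in self.copies:
            raise FormatError("copy-number table must contain the special key 'SAR11'")

    def lookup(self, label: str | None) -> float:
        if label is None:
            return self.default_copies
        return self.copies.get(label, self.default_copies)


def read_copy_numbers(path: str | Path) -> CopyNumberTable:
    """Read a copy-number TSV with columns (label, mean_copies).

    A row labelled ``default`` sets the fallback for unmapped classes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    if "label" not in df.columns or "mean_copies" not in df.columns:
        raise FormatError(f"{path}: need columns 'label' and 'mean_copies'")
    copies = {}
    default = 1.0
    for row in df.itertuples(index=False):
        value = float(row.mean_copies)
        if row.label == "default":
            default = value
        else:
            copies[row.label] = value
    return CopyNumberTable(copies=copies, default_copies=default)


def write_copy_numbers(path: str | Path, table: CopyNumberTable) -> None:
    rows = [{"label": k, "mean_copies": v} for k, v in table.copies.items()]
    rows.append({"label": "default", "mean_copies": table.default_copies})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plate counts / DAPI
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlateCountTable:
    """Colony counts from the dilution-plating series plus DAPI totals.

    ``rows`` columns: sample_group, medium, replicate, colonies,
    dilution_factor, plated_volume_mL.  ``dapi`` maps sample_group to total
    cells per mL from DAPI epifluorescence counts.
    """

    rows: pd.DataFrame
    dapi: dict[str, float]

    def __post_init__(self) -> None:
        required = {
            "sample_group",
            "medium",
            "replicate",
            "colonies",
            "dilution_factor",
            "plated_volume_mL",
        }
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"plate-count table missing columns {sorted(missing)}")
        if (self.rows["colonies"].astype(int) < 0).any():
            raise FormatError("colony counts must be >= 0")
        if (self.rows["dilution_factor"].astype(int) < 1).any():
            raise FormatError("dilution factors must be >= 1")
        if (self.rows["plated_volume_mL"].astype(float) <= 0).any():
            raise FormatError("plated volumes must be > 0")
        for g, v in self.dapi.items():
            if v <= 0:
                raise FormatError(f"DAPI count for group {g!r} must be > 0")


def read_plate_counts(plates_path: str | Path, dapi_path: str | Path) -> PlateCountTable:
    rows = pd.read_csv(plates_path, sep="\t")
    dapi_df = pd.read_csv(dapi_path, sep="\t")
    if "sample_group" not in dapi_df.columns or "cells_per_mL" not in dapi_df.columns:
        raise FormatError(f"{dapi_path}: need columns 'sample_group' and 'cells_per_mL'")
    dapi = dict(zip(dapi_df["sample_group"].astype(str), dapi_df["cells_per_mL"].astype(float)))
    return PlateCountTable(rows=rows, dapi=dapi)


def write_plate_counts(
    table: PlateCountTable, plates_path: str | Path, dapi_path: str | Path
) -> None:
    table.rows.to_csv(plates_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_group": list(table.dapi), "cells_per_mL": list(table.dapi.values())}
    ).to_csv(dapi_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a Newick tree; validates unique tip names and branch lengths >= 0."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError(f"{path}: duplicate tip names in tree")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError(f"{path}: negative branch length at {node.name!r}")
    return tree
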