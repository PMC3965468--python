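"""Reading, validation and quality control of barcode reference libraries.

A reference library couples one aligned COI barcode sequence per specimen
with specimen-level metadata (taxonomy, geography, origin and larval
host-plant category).  Sequences are expected to be pre-aligned to the
barcode region, i.e. to share a coordinate frame; no aligner is provided.

Quality control mirrors standard barcode-compliance screening: records
shorter than a minimum ungapped length are dropped, as are records whose
three forward reading frames all contain internal stop codons under the
invertebrate mitochondrial genetic code (a pseudogene/frameshift signal).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import JoinError, ParseError, SchemaError, ValidationError

ORIGIN_LEVELS = ("native", "introduced", "unknown")
HOST_LEVELS = (
    "grass_herb",
    "tree_shrub",
    "detritus_fungi_lichen",
    "generalist",
    "unknown",
)

REQUIRED_COLUMNS = ("specimen_id", "species", "genus", "family")
OPTIONAL_COLUMNS = ("region", "country", "origin", "host_category")

#: Invertebrate mitochondrial genetic code (NCBI translation table 5).
INVERTEBRATE_MITO_TABLE = 5

GAP_CHARS = "-."


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen: aligned barcode sequence plus metadata labels."""

    specimen_id: str
    sequence: str
    species: str
    genus: str
    family: str
    region: str = "unknown"
    country: str = "unknown"
    origin: str = "unknown"
    host_category: str = "unknown"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"empty sequence for specimen {self.specimen_id!r}")
        if self.origin not in ORIGIN_LEVELS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: origin {self.origin!r} "
                f"not in {ORIGIN_LEVELS}"
            )
        if self.host_category not in HOST_LEVELS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: host_category "
                f"{self.host_category!r} not in {HOST_LEVELS}"
            )
        # species implies genus implies family: no orphan ranks
        if self.species and not self.genus:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: species without genus"
            )
        if self.genus and not self.family:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: genus without family"
            )

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in GAP_CHARS)


@dataclass
class ReferenceLibrary:
    """All retained specimens in a shared alignment coordinate frame."""

    records: list[SequenceRecord]
    alignment_length: int

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        for r in self.records:
            if len(r.sequence) != self.alignment_length:
                raise ValidationError(
                    f"specimen {r.specimen_id!r} has length {len(r.sequence)}, "
                    f"expected alignment_length={self.alignment_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_map(self) -> dict[str, str]:
        return {r.specimen_id: r.species for r in self.records}

    @property
    def genus_map(self) -> dict[str, str]:
        """Species → genus (consistent by the no-orphan-ranks invariant)."""
        return {r.species: r.genus for r in self.records}

    @property
    def family_map(self) -> dict[str, str]:
        return {r.species: r.family for r in self.records}

    def metadata_frame(self) -> pd.DataFrame:
        cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self.records], columns=list(cols)
        )


@dataclass
class QCReport:
    """Accounting of every record removed by quality control."""

    n_input: int
    n_retained: int
    removed_short: list[str] = field(default_factory=list)
    removed_stop_or_frameshift: list[str] = field(default_factory=list)
    min_length_threshold: int = 500

    def __post_init__(self) -> None:
        removed = set(self.removed_short) | set(self.removed_stop_or_frameshift)
        if self.n_retained != self.n_input - len(removed):
            raise ValidationError(
                "QC accounting violated: "
                f"{self.n_input} input != {self.n_retained} retained + "
                f"{len(removed)} removed"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("removed_short", i) for i in self.removed_short]
        rows += [("removed_stop_or_frameshift", i) for i in self.removed_stop_or_frameshift]
        return pd.DataFrame(rows, columns=["reason", "specimen_id"])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, uppercase sequence)`` tuples, in file order."""
    path = Path(path)
    try:
        with open(path) as fh:
            records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    except ValueError as exc:  # Biopython's malformed-FASTA signal
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found (empty or malformed file)")
    for rec_id, seq in records:
        if not seq:
            raise ParseError(f"{path}: record {rec_id!r} has an empty sequence")
    return records


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read tab-separated specimen metadata.

    Requires columns ``specimen_id, species, genus, family``; the optional
    columns ``region, country, origin, host_category`` default to
    ``"unknown"`` where absent or blank.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
        else:
            df[col] = df[col].replace("", "unknown")
    dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate specimen_id values: {sorted(set(dupes))}")
    return df[list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)]


def _has_open_forward_frame(sequence: str, genetic_code: int) -> bool:
    """True if at least one of the three forward frames is free of internal stops."""
    ungapped = "".join(c for c in sequence if c not in GAP_CHARS)
    for frame in range(3):
        sub = ungapped[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate(table=genetic_code))
        if "*" not in aa:
            return True
    return False


def qc_filter(
    records: Iterable[SequenceRecord],
    min_length: int = 500,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> tuple[ReferenceLibrary, QCReport]:
    """Apply length and reading-frame quality filters.

    A record is dropped if its ungapped length is below ``min_length``
    (inclusive retention at exactly ``min_length``) or if every forward
    frame contains an internal stop codon.  Both reasons are recorded
    independently, so a record may appear in both removal lists.
    """
    records = list(records)
    removed_short: list[str] = []
    removed_stop: list[str] = []
    kept: list[SequenceRecord] = []
    for rec in records:
        short = rec.ungapped_length < min_length
        stop = not _has_open_forward_frame(rec.sequence, genetic_code)
        if short:
            removed_short.append(rec.specimen_id)
        if stop:
            removed_stop.append(rec.specimen_id)
        if not short and not stop:
            kept.append(rec)
    library = _pad_to_common_frame(kept)
    report = QCReport(
        n_input=len(records),
        n_retained=len(kept),
        removed_short=removed_short,
        removed_stop_or_frameshift=removed_stop,
        min_length_threshold=min_length,
    )
    return library, report


def _pad_to_common_frame(records: Sequence[SequenceRecord]) -> ReferenceLibrary:
    length = max((len(r.sequence) for r in records), default=0)
    padded = [
        r if len(r.sequence) == length
        else SequenceRecord(**{**r.__dict__, "sequence": r.sequence.ljust(length, "-")})
        for r in records
    ]
    return ReferenceLibrary(records=list(padded), alignment_length=length)


def assemble_library(
    sequences: Sequence[tuple[str, str]],
    metadata: pd.DataFrame,
) -> ReferenceLibrary:
    """Join sequences with metadata rows and pad to a common alignment length.

    Every sequence id must appear in the metadata; sequences are right-padded
    with the gap symbol so all records share ``alignment_length`` (treated as
    missing data downstream, under pairwise deletion).
    """
    meta = metadata.set_index("specimen_id")
    missing = [sid for sid, _ in sequences if sid not in meta.index]
    if missing:
        raise JoinError(f"sequence id(s) absent from metadata: {missing}")
    records = []
    for sid, seq in sequences:
        row = meta.loc[sid]
        records.append(
            SequenceRecord(
                specimen_id=sid,
                sequence=seq,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                region=row.get("region", "unknown"),
                country=row.get("country", "unknown"),
                origin=row.get("origin", "unknown"),
                host_category=row.get("host_category", "unknown"),
            )
        )
    return _pad_to_common_frame(records)


def write_library(
    library: ReferenceLibrary, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Serialize a library as the FASTA + metadata TSV dialect this module reads."""
    with open(fasta_path, "w") as fh:
        for rec in library.records:
            fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")
    library.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_library(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceLibrary:
    """Convenience: read sequences and metadata and assemble the library."""
    return assemble_library(read_fasta(fasta_path), read_metadata(metadata_path))
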