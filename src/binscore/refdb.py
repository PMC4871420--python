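"""Custom CO1 reference database: specimen records joined to BINs and taxonomy.

The database is the local stand-in for a BOLD export: one record per specimen
(keyed by its unique process ID), each carrying the Barcode Index Number (BIN)
of its species cluster, its Linnean taxonomy and its CO1 nucleotide sequence.
A BIN typically owns several specimen records.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .seq import normalize

HEADER_DELIM = "|"

#: BOLD-style default column names for TSV ingest; override via ``column_map``.
DEFAULT_COLUMNS = {
    "process_id": "processid",
    "bin_id": "bin_uri",
    "order_name": "order_name",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "sequence": "nucleotides",
}

_MANDATORY = ("process_id", "bin_id", "sequence")
_TAXONOMY = ("order_name", "family", "genus", "species")


class ReferenceDBError(ValueError):
    """Raised for malformed reference tables or FASTA files."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One identified specimen: process ID, BIN, taxonomy and CO1 sequence."""

    process_id: str
    bin_id: str
    sequence: str
    order_name: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""


@dataclass
class ReferenceDB:
    """Collection of reference records, unique per process_id."""

    records: list[ReferenceRecord] = field(default_factory=list)
    load_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.process_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dups = set(), []
            for pid in ids:
                if pid in seen:
                    dups.append(pid)
                seen.add(pid)
            raise ReferenceDBError(f"duplicate process_id(s): {sorted(set(dups))}")
        self._by_pid = {r.process_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceDB):
            return NotImplemented
        return sorted(self.records, key=lambda r: r.process_id) == sorted(
            other.records, key=lambda r: r.process_id
        )

    def get(self, process_id: str) -> ReferenceRecord | None:
        return self._by_pid.get(process_id)

    def bins(self) -> set[str]:
        return {r.bin_id for r in self.records}

    def bin_taxonomy(self) -> dict[str, dict[str, str]]:
        """Map each BIN to the taxonomy of its first record (BINs are the
        reporting unit; records within a BIN share taxonomy by construction)."""
        out: dict[str, dict[str, str]] = {}
        for r in self.records:
            out.setdefault(
                r.bin_id,
                {
                    "order_name": r.order_name,
                    "family": r.family,
                    "genus": r.genus,
                    "species": r.species,
                },
            )
        return out


def load_reference_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    min_length: int = 0,
) -> ReferenceDB:
    """Load a BOLD-style TSV of specimen records into a ReferenceDB.

    Rows with an empty BIN or empty sequence are dropped and counted, as are
    rows whose gap-stripped sequence is shorter than ``min_length``. Sequences
    are uppercased, alignment gaps removed and IUPAC ambiguity codes other
    than N converted to N (counted in the load summary).

    Parameters
    ----------
    column_map
        Maps the logical fields (process_id, bin_id, sequence, order_name,
        family, genus, species) to column names in the file; defaults to
        BOLD export names.
    min_length
        Minimum sequence length after gap stripping; 100 is a sensible value
        for real CO1 exports, 0 keeps everything.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise ReferenceDBError(
                f"mandatory column {cols[key]!r} (for {key}) missing from {path}"
            )

    records: list[ReferenceRecord] = []
    dropped_empty_bin = dropped_empty_seq = dropped_short = ambig_converted = 0
    for _, row in df.iterrows():
        bin_id = row[cols["bin_id"]].strip()
        raw_seq = row[cols["sequence"]].strip()
        if not bin_id:
            dropped_empty_bin += 1
            continue
        if not raw_seq:
            dropped_empty_seq += 1
            continue
        seq, n_ambig = normalize(raw_seq)
        if len(seq) < min_length:
            dropped_short += 1
            continue
        ambig_converted += n_ambig
        tax = {
            k: row[cols[k]].strip() if cols[k] in df.columns else ""
            for k in _TAXONOMY
        }
        records.append(
            ReferenceRecord(
                process_id=row[cols["process_id"]].strip(),
                bin_id=bin_id,
                sequence=seq,
                **tax,
            )
        )

    db = ReferenceDB(records)
    db.load_summary = {
        "records_in": len(df),
        "records_kept": len(records),
        "dropped_empty_bin": dropped_empty_bin,
        "dropped_empty_sequence": dropped_empty_seq,
        "dropped_short": dropped_short,
        "ambiguity_codes_converted": ambig_converted,
    }
    assert db.load_summary["records_in"] == len(records) + (
        dropped_empty_bin + dropped_empty_seq + dropped_short
    )
    return db


def _header(rec: ReferenceRecord) -> str:
    fields = (
        rec.process_id,
        rec.bin_id,
        rec.order_name,
        rec.family,
        rec.genus,
        rec.species,
    )
    for f in fields:
        if HEADER_DELIM in f:
            raise ReferenceDBError(
                f"field {f!r} of record {rec.process_id!r} contains the "
                f"reserved delimiter {HEADER_DELIM!r}"
            )
    return HEADER_DELIM.join(fields)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write the database as FASTA, one record per specimen.

    The header encodes ``process_id|bin_id|order|family|genus|species`` so
    that :func:`load_reference_fasta` round-trips losslessly.
    """
    if len(db) == 0:
        raise ReferenceDBError("refusing to write an empty reference database")
    with open(path, "w") as fh:
        for rec in db:
            fh.write(f">{_header(rec)}\n")
            fh.write(textwrap.fill(rec.sequence, width=80) + "\n")


def load_reference_fasta(path: str | Path) -> ReferenceDB:
    """Inverse of :func:`write_reference_fasta`."""
    records = []
    for i, sr in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = sr.description or sr.id
        parts = header.split(HEADER_DELIM)
        if len(parts) != 6:
            raise ReferenceDBError(
                f"malformed header (record {i}, {header!r}): expected 6 "
                f"{HEADER_DELIM!r}-separated fields, got {len(parts)}"
            )
        seq, _ = normalize(str(sr.seq))
        records.append(
            ReferenceRecord(
                process_id=parts[0],
                bin_id=parts[1],
                order_name=parts[2],
                family=parts[3],
                genus=parts[4],
                species=parts[5],
                sequence=seq,
            )
        )
    return ReferenceDB(records)
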