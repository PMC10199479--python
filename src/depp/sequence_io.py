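"""Protein FASTA input and delimited-table output.

All downstream modules consume :class:`ProteinRecord` objects produced here.
Sequences are sanitized on read (upper-cased, stop symbols removed) and
validated against the 20-letter standard amino-acid alphabet; ambiguity codes
(B, J, O, U, X, Z) are handled according to an explicit policy so that a
curated training file and a noisy proteome scan can be treated differently.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)

#: Ambiguity / non-standard codes that may appear in translated ORFs.
AMBIGUOUS_AMINO_ACIDS = frozenset("BJOUXZ")

#: Shortest sequence for which every feature family (incl. tripeptides) is defined.
MIN_SEQUENCE_LENGTH = 3

#: Policies for records containing ambiguity codes.
AMBIGUOUS_POLICIES = ("reject", "drop-residue", "skip-record")


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with its FASTA identity.

    Parameters
    ----------
    id : str
        First whitespace-delimited token of the FASTA header; unique within
        one file.
    sequence : str
        Upper-case string over the 20 standard one-letter codes, length >= 3.
    description : str
        Free-text remainder of the header (may be empty).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record has an empty identifier")
        if len(self.sequence) < MIN_SEQUENCE_LENGTH:
            raise ValidationError(
                f"record '{self.id}': sequence shorter than {MIN_SEQUENCE_LENGTH} "
                f"residues after sanitization (length {len(self.sequence)})"
            )
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValidationError(
                f"record '{self.id}': non-standard residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _sanitize(raw: str, record_id: str, on_ambiguous: str) -> str | None:
    """Upper-case, strip '*', apply the ambiguity policy.

    Returns the clean sequence, or None if the record is to be skipped.
    """
    seq = raw.upper().replace("*", "").replace("-", "").replace(".", "")
    ambiguous = [c for c in set(seq) if c not in _STANDARD_SET]
    if ambiguous:
        if on_ambiguous == "reject":
            raise ValidationError(
                f"record '{record_id}': ambiguous/non-standard residue(s) "
                f"{sorted(ambiguous)} (policy 'reject')"
            )
        if on_ambiguous == "drop-residue":
            seq = "".join(c for c in seq if c in _STANDARD_SET)
        elif on_ambiguous == "skip-record":
            logger.warning(
                "skipping record '%s': ambiguous residue(s) %s",
                record_id,
                sorted(ambiguous),
            )
            return None
    return seq


def read_protein_fasta(
    path: str | Path, on_ambiguous: str = "reject"
) -> list[ProteinRecord]:
    """Read a protein FASTA file into an ordered list of :class:`ProteinRecord`.

    Parameters
    ----------
    path : path-like
        FASTA file of amino-acid sequences.
    on_ambiguous : {"reject", "drop-residue", "skip-record"}
        What to do with records containing letters outside the 20-letter
        alphabet after sanitization. ``reject`` raises (appropriate for curated
        training input); ``drop-residue`` deletes the offending letters;
        ``skip-record`` drops the whole record with a warning (appropriate for
        whole-proteome scans, where one bad ORF should not abort the run).

    Returns
    -------
    list of ProteinRecord
        Records in file order. Duplicate ids get a deterministic numeric
        suffix (``_2``, ``_3``, ...) and a logged warning. Sequences are
        upper-cased with ``*`` translation stops removed.

    Raises
    ------
    EmptyInputError
        If the file contains no records, or no record survives the policy.
    ValidationError
        Under ``reject``/``drop-residue`` for ambiguous or too-short records.
    OSError
        If the file cannot be read.
    """
    if on_ambiguous not in AMBIGUOUS_POLICIES:
        raise ValidationError(
            f"unknown ambiguity policy '{on_ambiguous}'; "
            f"expected one of {AMBIGUOUS_POLICIES}"
        )
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rec_id = rec.id
            if not rec_id:
                raise ValidationError(f"{path}: record with empty header")
            seq = _sanitize(str(rec.seq), rec_id, on_ambiguous)
            if seq is None:
                continue
            if len(seq) < MIN_SEQUENCE_LENGTH:
                if on_ambiguous == "skip-record":
                    logger.warning(
                        "skipping record '%s': shorter than %d residues "
                        "after sanitization",
                        rec_id,
                        MIN_SEQUENCE_LENGTH,
                    )
                    continue
                raise ValidationError(
                    f"record '{rec_id}': sequence shorter than "
                    f"{MIN_SEQUENCE_LENGTH} residues after sanitization"
                )
            seen[rec_id] = seen.get(rec_id, 0) + 1
            if seen[rec_id] > 1:
                new_id = f"{rec_id}_{seen[rec_id]}"
                logger.warning(
                    "duplicate id '%s' renamed to '%s'", rec_id, new_id
                )
                rec_id = new_id
            description = rec.description.split(maxsplit=1)
            desc = description[1] if len(description) > 1 else ""
            records.append(ProteinRecord(id=rec_id, sequence=seq, description=desc))
    if not records:
        raise EmptyInputError(f"{path}: no protein records survived parsing")
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as a plain protein FASTA file (60-column wrap)."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i : i + 60] + "\n")


def write_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    delimiter: str = "\t",
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows to a delimited text file with a mandatory header line.

    Floats are rendered with ``repr`` (shortest round-trip form) so that
    reading the file back reproduces the values exactly.

    Raises
    ------
    SchemaError
        If the rows do not all share one column schema (same keys, same order).
    """
    if isinstance(rows, pd.DataFrame):
        columns = list(rows.columns)
        iter_rows: list[Sequence[object]] = [list(r) for r in rows.itertuples(index=False)]
    else:
        rows = list(rows)
        if rows:
            if columns is None:
                columns = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != list(columns):
                    raise SchemaError(
                        f"row {i} columns {list(row.keys())} differ from "
                        f"header columns {list(columns)}"
                    )
            iter_rows = [[row[c] for c in columns] for row in rows]
        elif columns is not None:
            iter_rows = []
        else:
            raise SchemaError(
                "cannot infer a header from an empty row collection; "
                "pass `columns` or a DataFrame"
            )
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter=delimiter, lineterminator="\n")
        writer.writerow(columns)
        for row in iter_rows:
            writer.writerow([repr(v) if isinstance(v, float) else v for v in row])


def read_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a delimited table written by :func:`write_table` (header required)."""
    return pd.read_csv(path, sep=delimiter)
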