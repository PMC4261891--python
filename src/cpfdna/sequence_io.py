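"""FASTA, truth-table, feature-table and assignment input/output.

All tabular interfaces are UTF-8, tab-delimited, ``'.'`` decimal.  DNA input
is normalised to uppercase A/C/G/T (RNA ``U`` becomes ``T``); any other
residue is rejected by default, or kept as ``N`` under ambiguity masking so
that downstream window extraction can skip windows overlapping it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("cpfdna")

VALID_BASES = frozenset("ACGT")

__all__ = [
    "DnaRecord",
    "FastaError",
    "TruthError",
    "read_fasta",
    "read_truth",
    "write_truth",
    "write_fasta",
    "write_vectors",
    "read_vectors",
    "write_assignments",
    "read_assignments",
]


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class TruthError(ValueError):
    """Malformed family-truth table."""


@dataclass(frozen=True)
class DnaRecord:
    """An identified DNA sequence.

    ``residues`` is uppercase over {A, C, G, T} after normalisation, except
    when ambiguity masking kept ``N`` placeholders.
    """

    id: str
    residues: str


def _normalise(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(
    path,
    min_length: int = 2,
    *,
    ambiguous: str = "reject",
) -> list[DnaRecord]:
    """Read and validate a multi-record FASTA file.

    Parameters
    ----------
    path
        FASTA file (wrapped or unwrapped records).
    min_length
        Records shorter than this are dropped with a logged warning.
        Defaults to 2, the CPF window size.
    ambiguous
        ``"reject"`` (default) raises on any residue outside {A, C, G, T}
        after normalisation; ``"mask"`` replaces such residues with ``N``
        so featurisers skip the windows overlapping them.

    Returns
    -------
    list of DnaRecord
        In file order, residues normalised.

    Raises
    ------
    FastaError
        On an empty file, text before the first header (named by line
        number), a duplicate id, an invalid residue under ``"reject"``, or
        when no record survives the length filter.
    """
    if ambiguous not in ("reject", "mask"):
        raise ValueError(f"ambiguous must be 'reject' or 'mask', got {ambiguous!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path.name}: line {lineno}: expected a '>' header, "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaError(f"{path.name}: empty FASTA file")

    records: list[DnaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path.name}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _normalise(str(rec.seq))
        invalid = set(residues) - VALID_BASES
        if invalid:
            if ambiguous == "reject":
                pos = next(
                    i for i, ch in enumerate(residues) if ch not in VALID_BASES
                )
                raise FastaError(
                    f"{path.name}: record {rec.id!r}: invalid residue "
                    f"{residues[pos]!r} at position {pos + 1}"
                )
            residues = "".join(
                ch if ch in VALID_BASES else "N" for ch in residues
            )
        if len(residues) < min_length:
            logger.warning(
                "skipping record %r: length %d < min_length %d",
                rec.id, len(residues), min_length,
            )
            continue
        records.append(DnaRecord(rec.id, residues))
    if not records:
        raise FastaError(f"{path.name}: no usable records")
    return records


def write_fasta(records: Iterable[DnaRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start : start + width] + "\n")


def read_truth(path) -> dict[str, str]:
    """Read a two-column (id, family) tab-separated truth table.

    A first row of ``id<TAB>family`` (case-insensitive) is treated as an
    optional header.  Raises :class:`TruthError` on an empty file, a row
    without exactly two columns, a duplicate id, or an empty label.
    """
    path = Path(path)
    truth: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TruthError(
                    f"{path.name}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            seq_id, family = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (seq_id.lower(), family.lower()) == ("id", "family"):
                continue
            if not seq_id or not family:
                raise TruthError(f"{path.name}: line {lineno}: empty id or label")
            if seq_id in truth:
                raise TruthError(f"{path.name}: duplicate id {seq_id!r}")
            truth[seq_id] = family
    if not truth:
        raise TruthError(f"{path.name}: empty truth file")
    return truth


def write_truth(truth: Mapping[str, str], path) -> None:
    """Write an id -> family mapping as a two-column TSV with header."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\tfamily\n")
        for seq_id, family in truth.items():
            handle.write(f"{seq_id}\t{family}\n")


def write_vectors(vectors: Sequence, path) -> None:
    """Write feature vectors as a TSV table: id column, then one column per
    feature dimension headed by its word label.

    Values round-trip bit-identically (written with 17 significant digits).
    All vectors must share length, model and labels.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no vectors to write")
    first = vectors[0]
    for vec in vectors:
        if len(vec.values) != len(first.values):
            raise ValueError(
                f"mixed vector lengths: {len(first.values)} and {len(vec.values)}"
            )
        if vec.model != first.model or vec.labels != first.labels:
            raise ValueError("all vectors must share one model and label set")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\t" + "\t".join(first.labels) + "\n")
        for vec in vectors:
            row = "\t".join(format(v, ".17g") for v in vec.values)
            handle.write(f"{vec.source_id}\t{row}\n")


def read_vectors(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a vector TSV back as ``(ids, values matrix, column labels)``."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "id":
            raise ValueError(f"{path.name}: not a vector table (bad header)")
        labels = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}: line {lineno}: expected {len(header)} "
                    f"columns, got {len(fields)}"
                )
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    return ids, np.asarray(rows, dtype=float), labels


def write_assignments(run, path) -> None:
    """Write per-repeat cluster assignments as TSV (id, repeat, cluster)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\trepeat\tcluster\n")
        for repeat, assignment in enumerate(run.assignments):
            for seq_id, cluster in assignment.items():
                handle.write(f"{seq_id}\t{repeat}\t{cluster}\n")


def read_assignments(path) -> list[dict[str, int]]:
    """Read an assignment TSV back as one id -> cluster dict per repeat."""
    path = Path(path)
    by_repeat: dict[int, dict[str, int]] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["id", "repeat", "cluster"]:
            raise ValueError(f"{path.name}: not an assignment table (bad header)")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path.name}: line {lineno}: expected 3 columns")
            seq_id, repeat, cluster = fields
            by_repeat.setdefault(int(repeat), {})[seq_id] = int(cluster)
    if not by_repeat:
        raise ValueError(f"{path.name}: empty assignment table")
    return [by_repeat[r] for r in sorted(by_repeat)]
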