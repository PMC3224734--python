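"""Sequence, alignment and result I/O.

Readers normalise records into the two in-memory types the rest of the
package works with: :class:`ProteinSequence` (a degapped query protein) and
:class:`AlignedRow` (one gapped row of a seed alignment).  Parsing of the
standard formats (FASTA, aligned FASTA, Stockholm) is delegated to
Biopython; this layer only enforces the package's residue alphabet and
normalisation contract.

Conventions
-----------
* Residues are the 20 standard one-letter amino-acid codes plus ``X``
  (unknown, scored at background odds downstream).  The ambiguity codes
  B/Z/J and the rare letters U/O are rejected per record with an explicit
  report, because they would make emission probabilities ill-defined.
* The only gap character is ``-``; ``.`` on input is normalised to ``-``.
* All residue positions are 1-based and intervals are inclusive, matching
  crystal-structure residue numbering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_REJECTED_RESIDUES = frozenset("BZJUO")
GAP = "-"

CLASS_LABELS = ("classI", "classII", "other", "unknown")

#: Fixed column order of the results table.
RESULT_COLUMNS_FIXED = (
    "id",
    "gate",
    "score",
)
RESULT_COLUMNS_TAIL = (
    "f87_pos",
    "f87_res",
    "ris1_len",
    "ris2_len",
    "redox_class",
)
MISSING = "."


class SeqIOError(ValueError):
    """Raised on malformed sequence or alignment input."""


class EmptyInputError(SeqIOError):
    """Raised when a sequence file contains no records."""


class AlignmentShapeError(SeqIOError):
    """Raised when alignment rows are not all the same length."""


@dataclass(frozen=True)
class ProteinSequence:
    """A degapped protein sequence.

    ``residues`` is an uppercase string over the 20 amino acids plus 'X';
    it is non-empty and contains no gap characters.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise SeqIOError(
                f"sequence {self.id!r} contains invalid residues: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRow:
    """One gapped row of a multiple alignment.

    Removing the gaps yields a valid :class:`ProteinSequence`.  The class
    label defaults to ``unknown`` and is filled in from the annotation
    sidecar by the seed-model layer.
    """

    id: str
    gapped: str
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise SeqIOError(
                f"row {self.id!r}: unknown class label {self.class_label!r}"
            )
        # validates residue alphabet of the degapped sequence
        self.to_sequence()

    @property
    def degapped(self) -> str:
        return self.gapped.replace(GAP, "")

    def to_sequence(self) -> ProteinSequence:
        return ProteinSequence(id=self.id, residues=self.degapped)

    def __len__(self) -> int:
        return len(self.gapped)


def _normalise(raw: str) -> str:
    return raw.upper().replace(".", GAP).replace("*", "")


def _dedupe_ids(records: Iterable[SeqRecord]) -> list[SeqRecord]:
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        n = seen.get(rec.id, 0)
        seen[rec.id] = n + 1
        if n:
            rec.id = f"{rec.id}.{n + 1}"
        out.append(rec)
    return out


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Order is preserved; duplicate ids are suffixed deterministically
    (``id.2``, ``id.3`` ...); lowercase residues are uppercased and ``*``
    stop characters stripped.  Records containing residues outside the
    accepted alphabet are rejected with a report naming every offender.
    """
    records = _dedupe_ids(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    seqs: list[ProteinSequence] = []
    rejected: list[str] = []
    for rec in records:
        residues = _normalise(str(rec.seq)).replace(GAP, "")
        try:
            seqs.append(
                ProteinSequence(
                    id=rec.id, residues=residues, description=rec.description
                )
            )
        except SeqIOError as exc:
            rejected.append(str(exc))
    if rejected:
        raise SeqIOError(
            "rejected {} record(s):\n  {}".format(
                len(rejected), "\n  ".join(rejected)
            )
        )
    return seqs


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA with 60-column line wrapping."""
    if not seqs:
        raise SeqIOError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id if not s.description else s.description
            if not header.startswith(s.id):
                header = f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def _looks_like_stockholm(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("# STOCKHOLM")


def read_alignment(path: str | Path) -> list[AlignedRow]:
    """Read an aligned FASTA or Stockholm alignment into gapped rows.

    Stockholm ``#=GC``/``#=GR`` annotation lines are ignored at this layer;
    class labels default to ``unknown``.  Rows of differing length raise
    :class:`AlignmentShapeError` naming the offending row.
    """
    fmt = "stockholm" if _looks_like_stockholm(path) else "fasta"
    if fmt == "stockholm":
        records = list(AlignIO.read(str(path), "stockholm"))
    else:
        # AlignIO.read enforces equal lengths itself but with a less
        # helpful message; parse records and check shape explicitly.
        records = _dedupe_ids(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no alignment rows in {path}")
    width = len(_normalise(str(records[0].seq)))
    rows = []
    for rec in records:
        gapped = _normalise(str(rec.seq))
        if len(gapped) != width:
            raise AlignmentShapeError(
                f"row {rec.id!r} has length {len(gapped)}, expected {width}"
            )
        rows.append(AlignedRow(id=rec.id, gapped=gapped))
    return rows


def write_alignment(rows: Sequence[AlignedRow], path: str | Path) -> None:
    """Write gapped rows as aligned FASTA."""
    if not rows:
        raise SeqIOError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.gapped), 60):
                fh.write(r.gapped[i : i + 60] + "\n")


def _fmt(value) -> str:
    return MISSING if value is None else str(value)


def write_results_tsv(results: Sequence, path: str | Path) -> None:
    """Write annotation results as a TSV table, one row per query.

    Column order: id, gate, score, per-SCR start/stop pairs (union of SCR
    names across results, in sorted order), then f87_pos, f87_res,
    ris1_len, ris2_len, redox_class.  Missing values are ``.``; a gap call
    at the F87-equivalent position is written as pos ``.`` and residue
    ``-``.
    """
    if not results:
        raise SeqIOError("no results to write")
    scr_names = sorted(
        {name for r in results for name in r.scr_intervals},
        key=_scr_sort_key,
    )
    header = list(RESULT_COLUMNS_FIXED)
    for name in scr_names:
        header += [f"{name}_start", f"{name}_stop"]
    header += list(RESULT_COLUMNS_TAIL)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for r in results:
            row = [r.query_id, "pass" if r.gate_pass else "fail",
                   f"{r.gate_score_bits:.2f}"]
            for name in scr_names:
                iv = r.scr_intervals.get(name)
                if iv is None:
                    row += [MISSING, MISSING]
                else:
                    row += [str(iv[0]), str(iv[1])]
            if r.f87_call is None:  # gap at the hotspot position
                row += [MISSING, GAP]
            else:
                row += [str(r.f87_call[0]), r.f87_call[1]]
            row += [_fmt(r.ris1_len), _fmt(r.ris2_len), r.redox_class]
            w.writerow(row)


def _scr_sort_key(name: str):
    digits = "".join(c for c in name if c.isdigit())
    return (int(digits) if digits else 0, name)


def write_results_gff3(results: Sequence, path: str | Path) -> None:
    """Write transferred structural regions as GFF3 in protein coordinates.

    One ``structural_region`` feature per present SCR, source ``cypmod``.
    """
    if not results:
        raise SeqIOError("no results to write")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in results:
            for name in sorted(r.scr_intervals, key=_scr_sort_key):
                iv = r.scr_intervals[name]
                if iv is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            r.query_id,
                            "cypmod",
                            "structural_region",
                            str(iv[0]),
                            str(iv[1]),
                            ".",
                            ".",
                            ".",
                            f"ID={r.query_id}.{name};Name={name}",
                        ]
                    )
                    + "\n"
                )
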