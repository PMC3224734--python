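"""The annotated structure-based seed alignment.

A seed is a multiple alignment of CYP sequences whose rows are anchored to
crystal structures, together with a JSON sidecar that records everything the
structural analysis contributed: the column spans of the structurally
conserved regions (SCRs), the anchor columns (the F87-equivalent hotspot,
the ExxR glutamate/arginine pair and the heme-ligating cysteine), the
column pairs flanking the two reductase interaction sites (RIS1 = the
αJ/J' region, RIS2 = the meander-to-Cys-pocket insertion), and a redox
class label per row.  One row — CYP102A1 (P450 BM-3) in the real seed — is
the reference: all annotation transfer is expressed through its coordinate
system.

SCR boundaries are data, not code: they arrive through the sidecar, and
every downstream computation is boundary-agnostic.

Sidecar schema (all columns 1-based inclusive)::

    {
      "reference_id": str,
      "scrs": [{"name": str, "start_col": int, "end_col": int,
                "content": str}, ...],
      "anchors": {"f87_col": int, "glu_col": int, "arg_col": int,
                  "cys_col": int},
      "ris1": {"left_col": int, "right_col": int},
      "ris2": {"left_col": int, "right_col": int},
      "class_labels": {row_id: label, ...}
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .seqio import GAP, AlignedRow, read_alignment


class SeedError(ValueError):
    """Raised when a seed alignment or its annotation is malformed."""


@dataclass(frozen=True)
class SeedAlignment:
    rows: tuple[AlignedRow, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SeedError("seed alignment needs at least 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise SeedError(f"ragged seed alignment: row lengths {sorted(widths)}")
        if self.reference_id not in {r.id for r in self.rows}:
            raise SeedError(f"reference row {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> AlignedRow:
        return next(r for r in self.rows if r.id == self.reference_id)

    def row(self, row_id: str) -> AlignedRow:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(row_id)

    def drop_row(self, row_id: str) -> "SeedAlignment":
        """Return a copy without ``row_id`` (used by leave-one-out)."""
        if row_id == self.reference_id:
            raise SeedError("cannot drop the reference row")
        kept = tuple(r for r in self.rows if r.id != row_id)
        if len(kept) == len(self.rows):
            raise KeyError(row_id)
        return SeedAlignment(rows=kept, reference_id=self.reference_id)

    def with_class_labels(self, labels: dict[str, str]) -> "SeedAlignment":
        rows = tuple(
            replace(r, class_label=labels.get(r.id, r.class_label))
            for r in self.rows
        )
        return SeedAlignment(rows=rows, reference_id=self.reference_id)


@dataclass(frozen=True)
class ScrInterval:
    """One structurally conserved region as a 1-based inclusive column span."""

    name: str
    start_col: int
    end_col: int
    content: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start_col <= self.end_col):
            raise SeedError(
                f"{self.name}: bad span [{self.start_col}, {self.end_col}]"
            )

    def columns(self) -> range:
        return range(self.start_col, self.end_col + 1)


@dataclass(frozen=True)
class SeedAnnotation:
    scrs: tuple[ScrInterval, ...]
    f87_col: int
    glu_col: int
    arg_col: int
    cys_col: int
    ris1: tuple[int, int]
    ris2: tuple[int, int]
    class_labels: dict[str, str] = field(default_factory=dict)

    @property
    def anchor_columns(self) -> dict[str, int]:
        return {
            "f87": self.f87_col,
            "glu": self.glu_col,
            "arg": self.arg_col,
            "cys": self.cys_col,
            "ris1_left": self.ris1[0],
            "ris1_right": self.ris1[1],
            "ris2_left": self.ris2[0],
            "ris2_right": self.ris2[1],
        }

    def scr_by_name(self, name: str) -> ScrInterval:
        for scr in self.scrs:
            if scr.name == name:
                return scr
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loading and validation


def _check_scrs(scrs: Sequence[ScrInterval], n_columns: int) -> list[str]:
    problems = []
    for scr in scrs:
        if scr.end_col > n_columns:
            problems.append(
                f"{scr.name} ends at column {scr.end_col} beyond alignment "
                f"width {n_columns}"
            )
    ordered = sorted(scrs, key=lambda s: s.start_col)
    if [s.name for s in ordered] != [s.name for s in scrs]:
        problems.append("SCRs are not sorted by start column")
    for a, b in zip(ordered, ordered[1:]):
        if b.start_col <= a.end_col:
            problems.append(f"SCRs {a.name} and {b.name} overlap")
    return problems


def load_seed(
    aln_path: str | Path, sidecar_path: str | Path
) -> tuple[SeedAlignment, SeedAnnotation]:
    """Load a seed alignment and its JSON annotation sidecar.

    All structural invariants are checked; violations are aggregated into a
    single :class:`SeedError` report rather than failing one at a time.
    """
    rows = read_alignment(aln_path)
    with open(sidecar_path) as fh:
        side = json.load(fh)

    labels = dict(side.get("class_labels", {}))
    seed = SeedAlignment(
        rows=tuple(rows), reference_id=side["reference_id"]
    ).with_class_labels(labels)

    scrs = tuple(
        ScrInterval(
            name=s["name"],
            start_col=int(s["start_col"]),
            end_col=int(s["end_col"]),
            content=s.get("content", ""),
        )
        for s in side["scrs"]
    )
    anchors = side["anchors"]
    ann = SeedAnnotation(
        scrs=scrs,
        f87_col=int(anchors["f87_col"]),
        glu_col=int(anchors["glu_col"]),
        arg_col=int(anchors["arg_col"]),
        cys_col=int(anchors["cys_col"]),
        ris1=(int(side["ris1"]["left_col"]), int(side["ris1"]["right_col"])),
        ris2=(int(side["ris2"]["left_col"]), int(side["ris2"]["right_col"])),
        class_labels=labels,
    )

    problems = _check_scrs(ann.scrs, seed.n_columns)
    ref = seed.reference.gapped
    for name, col in ann.anchor_columns.items():
        if not (1 <= col <= seed.n_columns):
            problems.append(f"anchor {name} column {col} out of bounds")
    if 1 <= ann.f87_col <= seed.n_columns and ref[ann.f87_col - 1] == GAP:
        problems.append(
            f"reference row has a gap at the F87 anchor column {ann.f87_col}"
        )
    for which, (left, right) in (("ris1", ann.ris1), ("ris2", ann.ris2)):
        if left >= right:
            problems.append(
                f"{which} anchors not ordered: left {left} >= right {right}"
            )
    # ExxR spacing in degapped reference coordinates
    if all(1 <= c <= seed.n_columns for c in (ann.glu_col, ann.arg_col)):
        if ann.glu_col >= ann.arg_col:
            problems.append("glu anchor column not left of arg anchor column")
        elif GAP not in (ref[ann.glu_col - 1], ref[ann.arg_col - 1]):
            glu_pos = column_to_ref_pos(seed, ann.glu_col)
            arg_pos = column_to_ref_pos(seed, ann.arg_col)
            if arg_pos - glu_pos != 3:
                problems.append(
                    "ExxR spacing violated in reference: glu at residue "
                    f"{glu_pos}, arg at residue {arg_pos} (expected +3)"
                )
    if 1 <= ann.cys_col <= seed.n_columns and ref[ann.cys_col - 1] != "C":
        problems.append(
            f"reference residue at cys anchor column {ann.cys_col} is "
            f"{ref[ann.cys_col - 1]!r}, expected 'C'"
        )
    if problems:
        raise SeedError(
            "invalid seed annotation:\n  " + "\n  ".join(problems)
        )
    return seed, ann


@dataclass(frozen=True)
class Violation:
    row_id: str
    column: int
    expected: str
    observed: str
    fatal: bool

    def __str__(self) -> str:
        level = "FATAL" if self.fatal else "warning"
        return (
            f"{level}: row {self.row_id} column {self.column}: expected "
            f"{self.expected!r}, observed {self.observed!r}"
        )


def validate_seed(
    seed: SeedAlignment, ann: SeedAnnotation
) -> list[Violation]:
    """Check every row for the universally conserved CYP anchors.

    Each row must carry E at the glutamate column, R at the arginine column
    and C at the cysteine column of the ExxR motif / Cys-pocket.  Rows
    violating this are listed as warnings; violations on the reference row
    are fatal (the reference defines the coordinate system and must be a
    canonical CYP).
    """
    checks = (
        (ann.glu_col, "E"),
        (ann.arg_col, "R"),
        (ann.cys_col, "C"),
    )
    report = []
    for row in seed.rows:
        for col, expected in checks:
            observed = row.gapped[col - 1]
            if observed != expected:
                report.append(
                    Violation(
                        row_id=row.id,
                        column=col,
                        expected=expected,
                        observed=observed,
                        fatal=(row.id == seed.reference_id),
                    )
                )
    return report


# ---------------------------------------------------------------------------
# coordinate bookkeeping


def ref_pos_to_column(seed: SeedAlignment, ref_pos: int) -> int:
    """Map a 1-based residue position of the reference row to its column."""
    return row_pos_to_column(seed.reference, ref_pos)


def column_to_ref_pos(seed: SeedAlignment, column: int) -> int:
    """Map an alignment column to the 1-based reference residue position.

    The reference must not have a gap in that column.
    """
    return column_to_row_pos(seed.reference, column)


def row_pos_to_column(row: AlignedRow, pos: int) -> int:
    """Column index of the ``pos``-th non-gap character of a gapped row."""
    if pos < 1:
        raise SeedError(f"residue position {pos} out of range")
    seen = 0
    for i, c in enumerate(row.gapped, start=1):
        if c != GAP:
            seen += 1
            if seen == pos:
                return i
    raise SeedError(
        f"residue position {pos} out of range for row {row.id!r} "
        f"(degapped length {seen})"
    )


def column_to_row_pos(row: AlignedRow, column: int) -> int:
    """1-based degapped position of a non-gap character at ``column``."""
    if not (1 <= column <= len(row.gapped)):
        raise SeedError(f"column {column} out of range")
    if row.gapped[column - 1] == GAP:
        raise SeedError(f"row {row.id!r} has a gap at column {column}")
    return column - row.gapped[: column - 1].count(GAP)


def column_to_row_pos_or_none(row: AlignedRow, column: int) -> int | None:
    """Like :func:`column_to_row_pos` but returns None on a gap."""
    if row.gapped[column - 1] == GAP:
        return None
    return column_to_row_pos(row, column)


def seed_to_json(ann: SeedAnnotation, reference_id: str) -> dict:
    """Serialise an annotation back to the sidecar schema."""
    return {
        "reference_id": reference_id,
        "scrs": [
            {
                "name": s.name,
                "start_col": s.start_col,
                "end_col": s.end_col,
                "content": s.content,
            }
            for s in ann.scrs
        ],
        "anchors": {
            "f87_col": ann.f87_col,
            "glu_col": ann.glu_col,
            "arg_col": ann.arg_col,
            "cys_col": ann.cys_col,
        },
        "ris1": {"left_col": ann.ris1[0], "right_col": ann.ris1[1]},
        "ris2": {"left_col": ann.ris2[0], "right_col": ann.ris2[1]},
        "class_labels": dict(ann.class_labels),
    }
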