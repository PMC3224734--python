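"""Synthetic annotated seed alignments and query sets with known truth.

The generator emulates the shape of a structure-based CYP seed alignment:

* a run of structurally conserved regions (SCR blocks) present in every
  row, with a configurable per-column conservation level;
* universally conserved anchors — the ExxR glutamate/arginine pair in a
  mid-model SCR, the heme cysteine in the Cys-pocket SCR, and the
  F87-equivalent hotspot column whose residue is drawn per row from a
  configurable composition (defaulting to the hotspot composition observed
  across the CYP family: F 22%, L 22%, V 12%, I 10%, A 9%, remainder
  spread thinly);
* variable linkers between SCRs, sampled from background frequencies, with
  two designated linkers acting as the reductase interaction sites whose
  per-row lengths are drawn from class-conditional bands (class I short,
  class II long, and the reductase-independent very-long-RIS2 subgroup).

Rows with shorter interaction-site insertions are padded with gaps, so the
alignment reproduces the low-occupancy insert columns a real seed shows
between its conserved flanks.  Every generated artifact carries a truth
record (class, anchor position/residue, RIS lengths, SCR intervals in its
own coordinates), making each downstream stage testable without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import AMINO_ACIDS, GAP, AlignedRow, ProteinSequence
from .seedmodel import ScrInterval, SeedAlignment, SeedAnnotation

_AA = np.array(list(AMINO_ACIDS))

#: Hotspot residue composition used for the F87-equivalent column.
DEFAULT_ANCHOR_DISTRIBUTION: dict[str, float] = {
    "F": 0.22,
    "L": 0.22,
    "V": 0.12,
    "I": 0.10,
    "A": 0.09,
}
# remaining mass spread uniformly over the other residues
_rest = [a for a in AMINO_ACIDS if a not in DEFAULT_ANCHOR_DISTRIBUTION]
DEFAULT_ANCHOR_DISTRIBUTION.update(
    {a: (1.0 - 0.75) / len(_rest) for a in _rest}
)

DEFAULT_RIS_BANDS: dict[str, dict[str, tuple[int, int]]] = {
    "classI": {"RIS1": (3, 5), "RIS2": (3, 5)},
    "classII": {"RIS1": (21, 22), "RIS2": (11, 17)},
    "classII_verylongRIS2": {"RIS1": (21, 22), "RIS2": (18, 23)},
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    "classI": 0.16,
    "classII": 0.73,
    "classII_verylongRIS2": 0.11,
}

#: Map generator class names onto seed-row class labels.
_SEED_LABEL = {
    "classI": "classI",
    "classII": "classII",
    "classII_verylongRIS2": "other",
}

REFERENCE_ID = "CYPREF"


class GeneratorError(ValueError):
    """Raised on infeasible generator parameters."""


@dataclass(frozen=True)
class GeneratorParams:
    n_rows: int = 20
    n_scrs: int = 19
    scr_len_range: tuple[int, int] = (6, 10)
    linker_len_range: tuple[int, int] = (2, 6)
    flank_len_range: tuple[int, int] = (0, 8)
    scr_conservation: float = 1.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    ris_length_bands: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {
            c: dict(b) for c, b in DEFAULT_RIS_BANDS.items()
        }
    )
    anchor_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_DISTRIBUTION)
    )
    rng_seed: int = 42

    # fixed topology: which SCR houses which anchor (1-based SCR index)
    f87_scr: int = 4
    exxr_scr: int = 11
    meander_scr: int = 15
    cys_pocket_scr: int = 16

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise GeneratorError("need at least 2 rows")
        if self.n_scrs < self.cys_pocket_scr:
            raise GeneratorError(
                f"need at least {self.cys_pocket_scr} SCRs to place the "
                "Cys-pocket"
            )
        for name, rng_ in (
            ("scr_len_range", self.scr_len_range),
            ("linker_len_range", self.linker_len_range),
            ("flank_len_range", self.flank_len_range),
        ):
            if rng_[0] > rng_[1] or rng_[0] < 0:
                raise GeneratorError(f"{name} is empty: {rng_}")
        if self.scr_len_range[0] < 6:
            raise GeneratorError(
                "SCR blocks need at least 6 columns to house the anchors"
            )
        if not (0.0 < self.scr_conservation <= 1.0):
            raise GeneratorError("scr_conservation must be in (0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise GeneratorError("class_mix fractions must sum to 1")
        for c in self.class_mix:
            if c not in self.ris_length_bands:
                raise GeneratorError(f"no RIS bands configured for {c!r}")
            for which in ("RIS1", "RIS2"):
                lo, hi = self.ris_length_bands[c][which]
                if lo > hi or lo < 0:
                    raise GeneratorError(f"empty {which} band for {c!r}")
        if abs(sum(self.anchor_distribution.values()) - 1.0) > 1e-9:
            raise GeneratorError("anchor_distribution must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Generating truth for one sequence, in its own 1-based coordinates."""

    seq_id: str
    class_label: str
    anchor_pos: int
    anchor_res: str
    ris1_len: int
    ris2_len: int
    scr_intervals: dict[str, tuple[int, int]]
    indel_regions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# blueprint: the shared column plan


@dataclass(frozen=True)
class _Blueprint:
    params: GeneratorParams
    scr_lengths: tuple[int, ...]
    scr_consensus: tuple[str, ...]  # concatenated consensus per SCR
    f87_offset: int  # 0-based offset of the hotspot inside its SCR
    exxr_offset: int  # 0-based offset of the glutamate inside its SCR
    cys_offset: int

    def regions(self) -> list[tuple[str, str]]:
        """Ordered (kind, name) region plan: kinds are flank | scr | linker
        | ris1 | ris2."""
        p = self.params
        plan: list[tuple[str, str]] = [("flank", "nterm")]
        for i in range(1, p.n_scrs + 1):
            plan.append(("scr", f"SCR{i}"))
            if i == p.n_scrs:
                break
            if i == p.exxr_scr:
                plan.append(("ris1", "RIS1"))
            elif i == p.meander_scr:
                plan.append(("ris2", "RIS2"))
            else:
                plan.append(("linker", f"linker{i}"))
        plan.append(("flank", "cterm"))
        return plan

    def excluded_for_region(self, region_index: int) -> set[str]:
        """Residues a variable region must avoid: the consensus of the
        conserved columns flanking it.  Variable residues equal to a
        flanking consensus would make the region boundary ambiguous under
        alignment (the flank could absorb them at no cost), so the
        generator keeps ground truth identifiable by excluding them."""
        plan = self.regions()
        out: set[str] = set()
        if region_index > 0 and plan[region_index - 1][0] == "scr":
            i = int(plan[region_index - 1][1][3:])
            out.add(self.scr_consensus[i - 1][-1])
        if region_index + 1 < len(plan) and plan[region_index + 1][0] == "scr":
            i = int(plan[region_index + 1][1][3:])
            out.add(self.scr_consensus[i - 1][0])
        return out


def _make_blueprint(params: GeneratorParams, rng: np.random.Generator) -> _Blueprint:
    lengths = tuple(
        int(rng.integers(params.scr_len_range[0], params.scr_len_range[1] + 1))
        for _ in range(params.n_scrs)
    )
    consensus = []
    for i, L in enumerate(lengths, start=1):
        block = list(rng.choice(_AA, size=L))
        consensus.append("".join(block))
    consensus = list(consensus)

    f87_offset = lengths[params.f87_scr - 1] // 2
    exxr_offset = max(0, lengths[params.exxr_scr - 1] // 2 - 2)
    cys_offset = lengths[params.cys_pocket_scr - 1] // 2

    # stamp the invariant anchors into the consensus
    def stamp(scr_1based: int, offset: int, text: str) -> None:
        s = list(consensus[scr_1based - 1])
        s[offset : offset + len(text)] = list(text)
        consensus[scr_1based - 1] = "".join(s)

    exxr_mid = "".join(rng.choice(_AA, size=2))
    stamp(params.exxr_scr, exxr_offset, "E" + exxr_mid + "R")
    stamp(params.cys_pocket_scr, cys_offset, "C")

    return _Blueprint(
        params=params,
        scr_lengths=lengths,
        scr_consensus=tuple(consensus),
        f87_offset=f87_offset,
        exxr_offset=exxr_offset,
        cys_offset=cys_offset,
    )


def _anchor_cols_in_scr(bp: _Blueprint, scr_1based: int) -> set[int]:
    """0-based offsets within the SCR that carry invariant anchors."""
    p = bp.params
    out: set[int] = set()
    if scr_1based == p.exxr_scr:
        out |= {bp.exxr_offset, bp.exxr_offset + 3}
    if scr_1based == p.cys_pocket_scr:
        out.add(bp.cys_offset)
    return out


def _sample_scr_block(
    bp: _Blueprint, scr_1based: int, rng: np.random.Generator
) -> list[str]:
    """One row's residues for an SCR block."""
    p = bp.params
    consensus = bp.scr_consensus[scr_1based - 1]
    fixed = _anchor_cols_in_scr(bp, scr_1based)
    hotspot = bp.f87_offset if scr_1based == p.f87_scr else None
    out = []
    anchor_res, anchor_p = zip(*sorted(p.anchor_distribution.items()))
    for j, c in enumerate(consensus):
        if j == hotspot:
            out.append(str(rng.choice(anchor_res, p=anchor_p)))
        elif j in fixed:
            out.append(c)
        elif rng.random() < p.scr_conservation:
            out.append(c)
        else:
            alternatives = [a for a in AMINO_ACIDS if a != c]
            out.append(str(rng.choice(alternatives)))
    return out


def _draw_class(params: GeneratorParams, rng: np.random.Generator) -> str:
    names, probs = zip(*sorted(params.class_mix.items()))
    return str(rng.choice(names, p=probs))


def _sample_row_pieces(
    bp: _Blueprint,
    class_label: str,
    rng: np.random.Generator,
    *,
    with_flanks: bool,
) -> list[tuple[str, str, list[str]]]:
    """(kind, name, residues) pieces of one generated sequence, in order."""
    p = bp.params
    bands = p.ris_length_bands[class_label]
    pieces: list[tuple[str, str, list[str]]] = []
    scr_i = 0
    for idx, (kind, name) in enumerate(bp.regions()):
        if kind == "scr":
            scr_i += 1
            pieces.append((kind, name, _sample_scr_block(bp, scr_i, rng)))
            continue
        allowed = [a for a in AMINO_ACIDS if a not in bp.excluded_for_region(idx)]
        if kind == "flank":
            lo, hi = p.flank_len_range if with_flanks else (0, 0)
            n = int(rng.integers(lo, hi + 1)) if hi else 0
        elif kind == "linker":
            n = int(
                rng.integers(p.linker_len_range[0], p.linker_len_range[1] + 1)
            )
        else:  # ris1 / ris2
            lo, hi = bands["RIS1" if kind == "ris1" else "RIS2"]
            n = int(rng.integers(lo, hi + 1))
        pieces.append((kind, name, [str(a) for a in rng.choice(allowed, size=n)]))
    return pieces


def _truth_from_pieces(
    seq_id: str,
    class_label: str,
    bp: _Blueprint,
    pieces: Sequence[tuple[str, str, list[str]]],
    indel_regions: tuple[str, ...] = (),
) -> tuple[ProteinSequence, TruthRecord]:
    pos = 0
    scr_intervals: dict[str, tuple[int, int]] = {}
    ris = {"RIS1": 0, "RIS2": 0}
    anchor_pos = anchor_res = None
    for kind, name, residues in pieces:
        start = pos + 1
        pos += len(residues)
        if kind == "scr":
            scr_intervals[name] = (start, pos)
            if name == f"SCR{bp.params.f87_scr}":
                # valid because indels never touch the anchor-bearing SCRs
                anchor_pos = start + bp.f87_offset
                anchor_res = residues[bp.f87_offset]
        elif kind in ("ris1", "ris2"):
            ris[name] = len(residues)
    seq = ProteinSequence(
        id=seq_id, residues="".join("".join(r) for _, _, r in pieces)
    )
    truth = TruthRecord(
        seq_id=seq_id,
        class_label=class_label,
        anchor_pos=anchor_pos,
        anchor_res=anchor_res,
        ris1_len=ris["RIS1"],
        ris2_len=ris["RIS2"],
        scr_intervals=scr_intervals,
        indel_regions=indel_regions,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# public generators


def generate_seed(
    params: GeneratorParams | None = None,
) -> tuple[SeedAlignment, SeedAnnotation, list[TruthRecord]]:
    """Generate a schema-complete annotated seed alignment with truth.

    The first row is the reference (id ``CYPREF``, class II, like the
    CYP102A1 row of the real seed).  Reproducible per ``params.rng_seed``.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    bp = _make_blueprint(params, rng)

    row_specs = []
    for r in range(params.n_rows):
        row_id = REFERENCE_ID if r == 0 else f"SYN{r:03d}"
        cls = "classII" if r == 0 else _draw_class(params, rng)
        pieces = _sample_row_pieces(bp, cls, rng, with_flanks=False)
        row_specs.append((row_id, cls, pieces))

    # column budget per region: the widest row
    plan = bp.regions()
    widths = []
    for idx in range(len(plan)):
        widths.append(max(len(spec[2][idx][2]) for spec in row_specs))

    rows: list[AlignedRow] = []
    truths: list[TruthRecord] = []
    for row_id, cls, pieces in row_specs:
        gapped = []
        for idx, (kind, name, residues) in enumerate(pieces):
            gapped.append(
                "".join(residues) + GAP * (widths[idx] - len(residues))
            )
        rows.append(
            AlignedRow(
                id=row_id, gapped="".join(gapped), class_label=_SEED_LABEL[cls]
            )
        )
        seq, truth = _truth_from_pieces(row_id, cls, bp, pieces)
        truths.append(truth)

    seed = SeedAlignment(rows=tuple(rows), reference_id=REFERENCE_ID)

    # column spans of each region
    col = 0
    region_cols: dict[str, tuple[int, int]] = {}
    for idx, (kind, name) in enumerate(plan):
        if widths[idx]:
            region_cols[name] = (col + 1, col + widths[idx])
        col += widths[idx]

    scrs = tuple(
        ScrInterval(
            name=f"SCR{i}",
            start_col=region_cols[f"SCR{i}"][0],
            end_col=region_cols[f"SCR{i}"][1],
            content="",
        )
        for i in range(1, params.n_scrs + 1)
    )
    f87_col = region_cols[f"SCR{params.f87_scr}"][0] + bp.f87_offset
    glu_col = region_cols[f"SCR{params.exxr_scr}"][0] + bp.exxr_offset
    cys_col = region_cols[f"SCR{params.cys_pocket_scr}"][0] + bp.cys_offset
    ann = SeedAnnotation(
        scrs=scrs,
        f87_col=f87_col,
        glu_col=glu_col,
        arg_col=glu_col + 3,
        cys_col=cys_col,
        ris1=(
            region_cols[f"SCR{params.exxr_scr}"][1],
            region_cols[f"SCR{params.exxr_scr + 1}"][0],
        ),
        ris2=(
            region_cols[f"SCR{params.meander_scr}"][1],
            region_cols[f"SCR{params.cys_pocket_scr}"][0],
        ),
        class_labels={r.id: r.class_label for r in rows},
    )
    return seed, ann, truths


def generate_queries(
    params: GeneratorParams | None = None,
    n: int = 100,
    class_mix: dict[str, float] | None = None,
    indel_rate: float = 0.0,
    rng_seed: int | None = None,
) -> tuple[list[ProteinSequence], list[TruthRecord]]:
    """Generate full-length query sequences with ground-truth annotation.

    Queries follow the same column plan as the seed from ``params`` (so a
    profile built from :func:`generate_seed` with the same params is the
    matching model), carry N-/C-terminal flanks, class-conditional RIS
    insert lengths, and optional point indels at per-residue rate
    ``indel_rate`` in non-anchor positions.  Truth records describe the
    emitted sequence (post-indel coordinates) and name the regions that
    received indels so recovery checks can condition on them.
    """
    params = params or GeneratorParams()
    if not (0.0 <= indel_rate <= 0.2):
        raise GeneratorError("indel_rate must be in [0, 0.2]")
    mix = class_mix or params.class_mix
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise GeneratorError("class_mix fractions must sum to 1")
    # the blueprint must match generate_seed's: consume the seed stream
    # identically before drawing queries
    rng = np.random.default_rng(params.rng_seed)
    bp = _make_blueprint(params, rng)
    qrng = np.random.default_rng(
        params.rng_seed + 1 if rng_seed is None else rng_seed
    )

    names, probs = zip(*sorted(mix.items()))
    seqs: list[ProteinSequence] = []
    truths: list[TruthRecord] = []
    for qi in range(n):
        cls = str(qrng.choice(names, p=probs))
        pieces = _sample_row_pieces(bp, cls, qrng, with_flanks=True)
        pieces, hit = _apply_indels(bp, pieces, indel_rate, qrng)
        seq, truth = _truth_from_pieces(
            f"Q{qi:04d}", cls, bp, pieces, indel_regions=hit
        )
        seqs.append(seq)
        truths.append(truth)
    return seqs, truths


def _apply_indels(
    bp: _Blueprint,
    pieces: list[tuple[str, str, list[str]]],
    rate: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, list[str]]], tuple[str, ...]]:
    if rate == 0.0:
        return pieces, ()
    # the anchor-bearing SCRs are exempt so truth anchor offsets stay valid
    protected = {
        f"SCR{bp.params.f87_scr}",
        f"SCR{bp.params.exxr_scr}",
        f"SCR{bp.params.cys_pocket_scr}",
    }
    hit: list[str] = []
    out = []
    for kind, name, residues in pieces:
        if name in protected:
            out.append((kind, name, residues))
            continue
        new: list[str] = []
        changed = False
        for res in residues:
            u = rng.random()
            if u >= rate:
                new.append(res)
                continue
            changed = True
            if u < rate / 2:
                continue  # deletion
            new.append(res)
            new.append(str(rng.choice(_AA)))  # insertion after the residue
        if changed:
            hit.append(name)
        out.append((kind, name, new))
    return out, tuple(hit)


def sample_ris_cohort(
    params: GeneratorParams | None = None,
    n: int = 1000,
    class_mix: dict[str, float] | None = None,
    rng_seed: int | None = None,
) -> list[tuple[str, int, int]]:
    """Draw (class, RIS1, RIS2) truth triples without building sequences.

    The cheap path for database-scale cohort statistics: the class is drawn
    from the mix and the lengths uniformly from that class's bands.
    """
    params = params or GeneratorParams()
    mix = class_mix or params.class_mix
    rng = np.random.default_rng(
        params.rng_seed if rng_seed is None else rng_seed
    )
    names, probs = zip(*sorted(mix.items()))
    out = []
    for _ in range(n):
        cls = str(rng.choice(names, p=probs))
        b = params.ris_length_bands[cls]
        r1 = int(rng.integers(b["RIS1"][0], b["RIS1"][1] + 1))
        r2 = int(rng.integers(b["RIS2"][0], b["RIS2"][1] + 1))
        out.append((cls, r1, r2))
    return out


def sample_anchor_residues(
    params: GeneratorParams | None = None,
    n: int = 5000,
    rng_seed: int | None = None,
) -> list[str]:
    """Draw hotspot residues from the configured anchor composition."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(
        params.rng_seed if rng_seed is None else rng_seed
    )
    names, probs = zip(*sorted(params.anchor_distribution.items()))
    return [str(r) for r in rng.choice(names, p=probs, size=n)]


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "seq_id",
                "class_label",
                "anchor_pos",
                "anchor_res",
                "ris1_len",
                "ris2_len",
                "indel_regions",
            ]
        )
        for t in truths:
            w.writerow(
                [
                    t.seq_id,
                    t.class_label,
                    t.anchor_pos,
                    t.anchor_res,
                    t.ris1_len,
                    t.ris2_len,
                    ",".join(t.indel_regions),
                ]
            )
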