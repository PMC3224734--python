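"""Optional reproduction layer for the crystal-structure seed set.

The seed set is the 31 CYP crystal structures (12 class II CPR-type, 16
class I, 3 others, reference CYP102A1 / PDB 1BU7).  This module assembles
that set from the PDB when network or a warm cache is available, and
reconstructs a seed alignment from sequence alone by pinning every chain at
its two universal motifs — the ExxR glutamate and the heme-ligating
cysteine — followed by iterative profile re-alignment.

The reconstruction is an approximation of a structure-derived alignment:
motif pinning guarantees the anchors share columns, but boundaries of the
structurally conserved regions are inferred from column occupancy rather
than from superposed coordinates, so comparisons against structure-derived
annotations are tolerance-framed by design.
"""

from __future__ import annotations

import hashlib
import re
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .profilehmm import BuildParams, ProfileHMM, QueryMapping, align_query, build_profile
from .seedmodel import (
    ScrInterval,
    SeedAlignment,
    SeedAnnotation,
    SeedError,
    ref_pos_to_column,
    row_pos_to_column,
)
from .seqio import GAP, AlignedRow, ProteinSequence, read_fasta, write_fasta

REFERENCE_PDB = "1BU7"
REFERENCE_CYP = "102A1"

#: The crystal-structure seed set: (CYP name, PDB id, class block).
TABLE1_ENTRIES: tuple[tuple[str, str, str], ...] = (
    # class II (CPR-type)
    ("1A2", "2HI4", "classII"),
    ("2A6", "1Z10", "classII"),
    ("2A13", "2P85", "classII"),
    ("2B4", "1SUO", "classII"),
    ("2C5", "1N6B", "classII"),
    ("2C8", "1PQ2", "classII"),
    ("2C9", "1OG2", "classII"),
    ("2D6", "2F9Q", "classII"),
    ("2R1", "2OJD", "classII"),
    ("3A4", "1TQN", "classII"),
    ("102A1", "1BU7", "classII"),
    ("175A1", "1N97", "classII"),
    # class I
    ("51B1", "1E9X", "classI"),
    ("101D", "2CPP", "classI"),
    ("107A1", "1OXA", "classI"),
    ("107L1", "2BVJ", "classI"),
    ("108A", "1CPT", "classI"),
    ("119", "1IO7", "classI"),
    ("154A1", "1ODO", "classI"),
    ("154C1", "1GWI", "classI"),
    ("158A1", "2DKK", "classI"),
    ("158A2", "1S1F", "classI"),
    ("165B3", "1LFK", "classI"),
    ("165C4", "1UED", "classI"),
    ("167A1", "1Q5D", "classI"),
    ("176A1", "1T2B", "classI"),
    ("199A2", "2FR7", "classI"),
    ("245A1", "2Z3T", "classI"),
    # others (no redox partner / peroxide-driven)
    ("8A", "2IAG", "other"),
    ("55A2", "1CL6", "other"),
    ("152A1", "1IZO", "other"),
)

#: Eleven later-published structures used to validate the prediction
#: (not part of the seed alignment).
VALIDATION11_ENTRIES: tuple[tuple[str, str, str], ...] = (
    ("2E1", "3E4E", "unknown"),
    ("3A43", "2V0M", "unknown"),
    ("7A1", "2DAX", "unknown"),
    ("19A1", "3EQM", "unknown"),
    ("46A1", "2Q9F", "unknown"),
    ("74A1", "2RCH", "unknown"),
    ("105A1", "2ZBX", "unknown"),
    ("105K1", "2Z36", "unknown"),
    ("120A1", "2VE3", "unknown"),
    ("231A2", "2RFB", "unknown"),
    ("248A", "3BUJ", "unknown"),
)

_FASTA_URL = "https://www.rcsb.org/fasta/entry/{pdb}"

#: ExxR and heme-cysteine motif patterns, tried in order; the first match
#: of the cysteine motif fixes the Cys column, and the last ExxR match
#: upstream of it fixes the glutamate.
DEFAULT_CYS_PATTERNS = (
    r"F[A-Z]{2}G[A-Z]{3}(C)[A-Z]G",  # FxxGxxxCxG Cys-pocket consensus
    r"G[A-Z]{3}(C)[A-Z]G",
    r"G[A-Z]{2,4}(C)[A-Z]G",
)
DEFAULT_EXXR_PATTERN = r"E[A-Z]{2}R"


class RealDataError(RuntimeError):
    """Raised when the crystal-structure set cannot be assembled."""


@dataclass(frozen=True)
class ManifestEntry:
    cyp: str
    pdb: str
    class_label: str


@dataclass(frozen=True)
class SeedManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        if len({e.pdb for e in self.entries}) != len(self.entries):
            raise RealDataError("duplicate PDB ids in manifest")

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.class_label] = out.get(e.class_label, 0) + 1
        return out


def default_manifest() -> SeedManifest:
    return SeedManifest(
        entries=tuple(ManifestEntry(*row) for row in TABLE1_ENTRIES)
    )


def validation_manifest() -> SeedManifest:
    return SeedManifest(
        entries=tuple(ManifestEntry(*row) for row in VALIDATION11_ENTRIES)
    )


def checksum(seq: ProteinSequence) -> str:
    return hashlib.sha256(seq.residues.encode()).hexdigest()


def _first_chain_from_fasta_text(text: str, pdb: str) -> ProteinSequence:
    blocks = [b for b in text.split(">") if b.strip()]
    if not blocks:
        raise RealDataError(f"no FASTA records returned for {pdb}")
    lines = blocks[0].splitlines()
    residues = "".join(lines[1:]).strip().upper()
    return ProteinSequence(id=pdb, residues=residues, description=lines[0])


def fetch_seed_sequences(
    manifest: SeedManifest | None = None,
    cache_dir: str | Path = ".cypmod-cache",
    *,
    allow_network: bool = True,
    timeout: float = 30.0,
) -> list[ProteinSequence]:
    """One sequence per PDB id (first protein chain), cache-first.

    A warm cache makes this fully offline and deterministic; a cold cache
    without network raises an actionable error naming the missing entries.
    """
    manifest = manifest or default_manifest()
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    out: list[ProteinSequence] = []
    missing: list[str] = []
    for entry in manifest.entries:
        path = cache / f"{entry.pdb}.fasta"
        if path.exists():
            out.append(read_fasta(path)[0])
            continue
        if not allow_network:
            missing.append(entry.pdb)
            continue
        try:
            with urllib.request.urlopen(
                _FASTA_URL.format(pdb=entry.pdb), timeout=timeout
            ) as resp:
                text = resp.read().decode()
        except Exception as exc:
            raise RealDataError(
                f"could not fetch PDB entry {entry.pdb}: {exc}; populate "
                f"the cache directory {cache} with {entry.pdb}.fasta to run "
                "offline"
            ) from exc
        seq = _first_chain_from_fasta_text(text, entry.pdb)
        write_fasta([seq], path)
        out.append(read_fasta(path)[0])
    if missing:
        raise RealDataError(
            "cache misses with network disabled: "
            + ", ".join(missing)
            + f"; populate {cache} with <PDBID>.fasta files"
        )
    return out


def find_motif_anchors(
    residues: str,
    cys_patterns: Sequence[str] = DEFAULT_CYS_PATTERNS,
    exxr_pattern: str = DEFAULT_EXXR_PATTERN,
) -> tuple[int, int] | None:
    """1-based (glutamate, cysteine) positions, or None when not locatable.

    The cysteine is the first Cys-pocket motif hit; the glutamate is the
    last ExxR hit upstream of it.
    """
    cys_pos = None
    for pat in cys_patterns:
        m = re.search(pat, residues)
        if m:
            cys_pos = m.start(1) + 1
            break
    if cys_pos is None:
        return None
    glu_pos = None
    for m in re.finditer(exxr_pattern, residues[: cys_pos - 1]):
        glu_pos = m.start() + 1
    if glu_pos is None:
        return None
    return glu_pos, cys_pos


def mappings_to_alignment(
    profile: ProfileHMM,
    pairs: Sequence[tuple[ProteinSequence, QueryMapping]],
    reference_id: str,
) -> SeedAlignment:
    """Assemble a multiple alignment from per-query profile mappings.

    Match states become columns; each inter-match insert slot (and each
    flank) is widened to the longest run observed, with insert residues
    left-justified (N-flank right-justified so it abuts the model).
    """
    L = profile.n_match
    ins_width = [0] * (L + 1)
    for seq, m in pairs:
        ins_width[0] = max(ins_width[0], m.n_flank)
        ins_width[L] = max(ins_width[L], m.c_flank)
        for k, run in m.insertions:
            ins_width[k + 1] = max(ins_width[k + 1], len(run))
    rows = []
    for seq, m in pairs:
        runs = dict(m.insertions)
        parts: list[str] = []
        nf = seq.residues[: m.n_flank]
        parts.append(GAP * (ins_width[0] - len(nf)) + nf)
        for k in range(L):
            pos = m.assignments[k]
            parts.append(GAP if pos is None else seq.residues[pos - 1])
            if k < L:
                width = ins_width[k + 1]
                run = runs.get(k, ())
                text = "".join(seq.residues[p - 1] for p in run)
                if k == L - 1:
                    text = seq.residues[len(seq) - m.c_flank :]
                parts.append(text + GAP * (width - len(text)))
        rows.append(AlignedRow(id=seq.id, gapped="".join(parts)))
    return SeedAlignment(rows=tuple(rows), reference_id=reference_id)


def derive_annotation(
    seed: SeedAlignment,
    f87_ref_pos: int = 87,
    class_labels: dict[str, str] | None = None,
    min_occupancy: float = 0.8,
    min_run: int = 3,
) -> SeedAnnotation:
    """Best-effort annotation of a reconstructed seed alignment.

    SCRs are maximal runs of columns with occupancy >= ``min_occupancy``
    (length >= ``min_run``); anchors come from the reference row (hotspot at
    its residue ``f87_ref_pos``, ExxR/Cys by motif scan); RIS anchors
    default to the flanking-SCR convention: RIS1 spans from the SCR holding
    the ExxR motif to the next SCR, RIS2 from the SCR preceding the
    Cys-pocket SCR to the Cys-pocket SCR.  This stands in for a
    structure-derived annotation and is approximate by construction.
    """
    ref = seed.reference
    anchors = find_motif_anchors(ref.degapped)
    if anchors is None:
        raise SeedError(
            f"reference row {seed.reference_id!r} lacks the ExxR/Cys motifs"
        )
    glu_pos, cys_pos = anchors
    glu_col = row_pos_to_column(ref, glu_pos)
    arg_col = row_pos_to_column(ref, glu_pos + 3)
    cys_col = row_pos_to_column(ref, cys_pos)
    f87_col = row_pos_to_column(ref, f87_ref_pos)

    n_rows = len(seed.rows)
    occ = [
        sum(r.gapped[c] != GAP for r in seed.rows) / n_rows
        for c in range(seed.n_columns)
    ]
    runs: list[tuple[int, int]] = []
    start = None
    for c, o in enumerate(occ, start=1):
        if o >= min_occupancy and start is None:
            start = c
        elif o < min_occupancy and start is not None:
            if c - start >= min_run:
                runs.append((start, c - 1))
            start = None
    if start is not None and seed.n_columns - start + 1 >= min_run:
        runs.append((start, seed.n_columns))
    if not runs:
        raise SeedError("no conserved column runs found")
    scrs = tuple(
        ScrInterval(name=f"SCR{i}", start_col=a, end_col=b)
        for i, (a, b) in enumerate(runs, start=1)
    )

    def scr_index_containing(col: int) -> int:
        for i, s in enumerate(scrs):
            if s.start_col <= col <= s.end_col:
                return i
        # fall back to the nearest SCR left of the column
        best = 0
        for i, s in enumerate(scrs):
            if s.end_col < col:
                best = i
        return best

    i_exxr = scr_index_containing(glu_col)
    i_cys = scr_index_containing(cys_col)
    ris1_right = scrs[min(i_exxr + 1, len(scrs) - 1)].start_col
    ris2_left = scrs[max(i_cys - 1, 0)].end_col
    return SeedAnnotation(
        scrs=scrs,
        f87_col=f87_col,
        glu_col=glu_col,
        arg_col=arg_col,
        cys_col=cys_col,
        ris1=(scrs[i_exxr].end_col, ris1_right),
        ris2=(ris2_left, scrs[i_cys].start_col),
        class_labels=dict(class_labels or {}),
    )


def bootstrap_seed_alignment(
    seqs: Sequence[ProteinSequence],
    reference_id: str = REFERENCE_PDB,
    f87_ref_pos: int = 87,
    refine_rounds: int | None = 2,
    build_params: BuildParams | None = None,
    max_rounds: int = 25,
) -> tuple[SeedAlignment, list[str]]:
    """Motif-pinned progressive alignment of the seed sequences.

    Sequences are pinned at their ExxR glutamate and heme-cysteine motifs
    (all rows share the glutamate and cysteine columns by construction),
    then re-aligned against the profile of the current alignment for
    ``refine_rounds`` rounds (None: iterate until the alignment stops
    changing, up to ``max_rounds``).  Sequences lacking the motifs are
    excluded; the report names them.
    """
    report: list[str] = []
    pinned: list[tuple[ProteinSequence, int, int]] = []
    for seq in seqs:
        anchors = find_motif_anchors(seq.residues)
        if anchors is None:
            report.append(f"excluded {seq.id}: ExxR/Cys motifs not locatable")
            continue
        pinned.append((seq, *anchors))
    if not any(s.id == reference_id for s, _, _ in pinned):
        raise RealDataError(
            f"reference {reference_id!r} missing or motif-less; cannot anchor"
        )
    if len(pinned) < 2:
        raise RealDataError("fewer than 2 sequences carry both motifs")

    # initial block alignment: [prefix][glu..cys-1][cys..end], each block
    # padded to its widest member; prefix right-justified so the glutamate
    # columns coincide, the others left-justified.
    pre_w = max(glu - 1 for _, glu, _ in pinned)
    mid_w = max(cys - glu for _, glu, cys in pinned)
    post_w = max(len(s) - cys + 1 for s, _, cys in pinned)
    rows = []
    for seq, glu, cys in pinned:
        pre = seq.residues[: glu - 1]
        mid = seq.residues[glu - 1 : cys - 1]
        post = seq.residues[cys - 1 :]
        rows.append(
            AlignedRow(
                id=seq.id,
                gapped=(
                    GAP * (pre_w - len(pre))
                    + pre
                    + mid
                    + GAP * (mid_w - len(mid))
                    + post
                    + GAP * (post_w - len(post))
                ),
            )
        )
    seed = SeedAlignment(rows=tuple(rows), reference_id=reference_id)

    params = build_params or BuildParams()
    n_rounds = max_rounds if refine_rounds is None else refine_rounds
    for _ in range(n_rounds):
        ann = derive_annotation(seed, f87_ref_pos=f87_ref_pos)
        profile = build_profile(seed, ann, params)
        pairs = [
            (s, align_query(profile, s, allow_fragment=True))
            for s, _, _ in pinned
        ]
        refined = mappings_to_alignment(profile, pairs, reference_id)
        if refine_rounds is None and [r.gapped for r in refined.rows] == [
            r.gapped for r in seed.rows
        ]:
            seed = refined
            break
        seed = refined
    return seed, report
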