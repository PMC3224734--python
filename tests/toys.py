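"""Tiny hand-traceable seed alignments for unit tests."""

from cypmod.seedmodel import ScrInterval, SeedAlignment, SeedAnnotation
from cypmod.seqio import AlignedRow


def make_toy_seed(rows, *, f87_col, glu_col, arg_col, cys_col,
                  scrs=None, ris1=None, ris2=None, reference_id=None):
    """Build a seed + annotation from (id, gapped) pairs.

    Defaults: one SCR spanning all columns; RIS anchors at the alignment
    edges (unused unless the test measures them).
    """
    aligned = tuple(AlignedRow(id=i, gapped=g) for i, g in rows)
    n_cols = len(aligned[0].gapped)
    seed = SeedAlignment(
        rows=aligned, reference_id=reference_id or aligned[0].id
    )
    ann = SeedAnnotation(
        scrs=tuple(scrs) if scrs else (
            ScrInterval(name="SCR1", start_col=1, end_col=n_cols),
        ),
        f87_col=f87_col,
        glu_col=glu_col,
        arg_col=arg_col,
        cys_col=cys_col,
        ris1=ris1 or (1, n_cols),
        ris2=ris2 or (1, n_cols),
        class_labels={},
    )
    return seed, ann


def gapfree_toy():
    """3 rows x 4 gap-free columns; anchors E(1) f87(2) C(3) R(4)."""
    return make_toy_seed(
        [("REF", "EFCR"), ("S1", "EYCR"), ("S2", "ELCR")],
        f87_col=2, glu_col=1, arg_col=4, cys_col=3,
    )


def insert_column_toy():
    """5 columns; column 3 occupied by 1 of 3 rows (below 0.5 occupancy)."""
    return make_toy_seed(
        [("REF", "EF-CR"), ("S1", "EY-CR"), ("S2", "ELACR")],
        f87_col=2, glu_col=1, arg_col=5, cys_col=4,
    )


def pseudocount_toy():
    """Column 2 carries residues {A, A, V} for the emission formula check."""
    return make_toy_seed(
        [("REF", "EAARCFAA"), ("S1", "EALRCFAA"), ("S2", "EVIRCFAA")],
        f87_col=6, glu_col=1, arg_col=4, cys_col=5,
    )
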