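"""Annotation transfer from the profile onto query sequences.

Given the Viterbi mapping of a query through the seed-derived profile, this
module reads off everything the structural analysis annotated on the seed:

* the query-coordinate span of each structurally conserved region (SCR);
* the F87-equivalent substrate-specificity position in the BC-loop (the
  residue homologous to phenylalanine 87 of CYP102A1 / P450 BM-3), or a gap
  call when the BC-loop houses no residue at the hotspot;
* the lengths of the two reductase interaction sites — RIS1 (the αJ/J'
  region) and RIS2 (the insertion between the meander loop and the
  Cys-pocket) — counted as query residues strictly between the flanking
  anchor states;
* a redox-class call from the two RIS lengths;
* an applicability gate replacing a database homology search: a query is
  in-scope when its forward score clears a bit threshold and the heme
  cysteine anchor aligns to a cysteine.

All positions are 1-based; intervals are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .profilehmm import (
    FragmentError,
    ProfileHMM,
    QueryMapping,
    align_query,
    forward_score,
)
from .seedmodel import SeedAnnotation
from .seqio import ProteinSequence

#: Sentinel for an SCR whose match states are all deleted in the query.
ABSENT = None
#: Sentinel for a RIS length that cannot be measured (flanking SCR deleted).
UNDEFINED = None

REDOX_CLASSES = (
    "classI",
    "classII",
    "classII_verylongRIS2",
    "ambiguous",
    "discordant",
    "unusual_flagged",
)


@dataclass(frozen=True)
class ClassThresholds:
    """Length bands separating the redox classes.

    RIS1 (αJ/J' region): short is fewer than 10 residues (class I), long is
    more than 15 (class II); 10-15 is the ambiguity window.  RIS2 (meander
    insertion): short is fewer than 7 (class I), long is 11-17 (class II),
    very long is 18 and above (the reductase-independent subgroup of class
    II); 7-10 is the ambiguity window.  Lengths above 35 are formally
    class II but flagged as unusual.
    """

    ris1_short_max: int = 9
    ris1_long_min: int = 16
    ris2_short_max: int = 6
    ris2_long_lo: int = 11
    ris2_long_hi: int = 17
    ris2_verylong_min: int = 18
    unusual_min: int = 36

    def __post_init__(self) -> None:
        if not (self.ris1_short_max < self.ris1_long_min):
            raise ValueError("RIS1 short band must end below the long band")
        if not (
            self.ris2_short_max
            < self.ris2_long_lo
            <= self.ris2_long_hi
            < self.ris2_verylong_min
        ):
            raise ValueError("RIS2 bands must be ordered and non-overlapping")

    def ris1_band(self, length: int) -> str:
        if length <= self.ris1_short_max:
            return "short"
        if length >= self.unusual_min:
            return "unusual"
        if length >= self.ris1_long_min:
            return "long"
        return "ambiguous"

    def ris2_band(self, length: int) -> str:
        if length <= self.ris2_short_max:
            return "short"
        if length >= self.unusual_min:
            return "unusual"
        if length >= self.ris2_verylong_min:
            return "verylong"
        if length >= self.ris2_long_lo:
            return "long"
        return "ambiguous"


@dataclass(frozen=True)
class GateParams:
    """Applicability gate: forward-score floor plus heme-cysteine check."""

    min_bits: float = 100.0
    require_cys: bool = True


@dataclass(frozen=True)
class AnnotationResult:
    query_id: str
    gate_pass: bool
    gate_score_bits: float
    scr_intervals: dict[str, tuple[int, int] | None]
    f87_call: tuple[int, str] | None  # None encodes a gap call
    ris1_len: int | None
    ris2_len: int | None
    redox_class: str


def transfer_scrs(
    mapping: QueryMapping, ann: SeedAnnotation, profile: ProfileHMM
) -> dict[str, tuple[int, int] | None]:
    """Transfer each SCR's span onto the query.

    The interval starts at the query position of the first non-deleted
    match state whose source column lies in the SCR and ends at the last;
    an SCR with every match state deleted maps to ABSENT.
    """
    out: dict[str, tuple[int, int] | None] = {}
    for scr in ann.scrs:
        states = profile.match_states_in_span(scr.start_col, scr.end_col)
        if not states:
            raise ValueError(
                f"{scr.name} spans no match states; the profile was not "
                "built from this annotation"
            )
        emitted = [
            mapping.assignments[k]
            for k in states
            if mapping.assignments[k] is not None
        ]
        out[scr.name] = (emitted[0], emitted[-1]) if emitted else ABSENT
    return out


def predict_f87(
    mapping: QueryMapping, profile: ProfileHMM, seq: ProteinSequence
) -> tuple[int, str] | None:
    """Query position and residue at the F87-equivalent anchor state.

    Returns None (a gap call) when the anchor state is deleted: the
    query's BC-loop then houses no residue at the heme-facing hotspot.
    """
    k = profile.anchor_states["f87"]
    pos = mapping.assignments[k]
    if pos is None:
        return None
    return (pos, seq.residues[pos - 1])


def _anchor_position(
    mapping: QueryMapping,
    profile: ProfileHMM,
    ann: SeedAnnotation,
    anchor: str,
    scan_inward: int,
) -> int | None:
    """Emitted query position of an anchor state, substituting the nearest
    emitting match state inward within the flanking SCR when deleted."""
    k = profile.anchor_states[anchor]
    col = profile.match_states[k].source_column
    scr = next(
        (s for s in ann.scrs if s.start_col <= col <= s.end_col), None
    )
    if scr is None:
        return mapping.assignments[k]
    states = profile.match_states_in_span(scr.start_col, scr.end_col)
    idx = states.index(k)
    while 0 <= idx < len(states):
        pos = mapping.assignments[states[idx]]
        if pos is not None:
            return pos
        idx += scan_inward
    return None


def measure_ris(
    mapping: QueryMapping,
    ann: SeedAnnotation,
    profile: ProfileHMM,
    which: str,
) -> int | None:
    """Residue count of a reductase interaction site in the query.

    The length is the number of query residues strictly between the left
    and right anchor states' emitted positions — matched residues of
    low-occupancy columns and insertions alike.  A deleted anchor is
    replaced by the nearest emitting match state inward within its flanking
    SCR; if that SCR is entirely deleted the length is UNDEFINED.
    """
    if which not in ("RIS1", "RIS2"):
        raise ValueError(f"unknown interaction site {which!r}")
    tag = which.lower()
    # left anchor sits at the right edge of the upstream SCR: scan leftward
    # (into the SCR) when deleted; mirrored for the right anchor.
    left = _anchor_position(mapping, profile, ann, f"{tag}_left", -1)
    right = _anchor_position(mapping, profile, ann, f"{tag}_right", +1)
    if left is None or right is None:
        return UNDEFINED
    return right - left - 1


def classify_redox(
    ris1_len: int | None,
    ris2_len: int | None,
    thresholds: ClassThresholds | None = None,
) -> str:
    """Redox-class call from the two reductase-interaction-site lengths.

    Total over (non-negative int | UNDEFINED)^2: both short -> classI; long
    RIS1 with long RIS2 -> classII; long RIS1 with very long RIS2 ->
    classII_verylongRIS2; any length in an ambiguity window -> ambiguous;
    short/long mixtures -> discordant; any length at or above the unusual
    floor -> unusual_flagged (formally class II); any UNDEFINED ->
    discordant.
    """
    t = thresholds or ClassThresholds()
    if ris1_len is UNDEFINED or ris2_len is UNDEFINED:
        return "discordant"
    if ris1_len < 0 or ris2_len < 0:
        raise ValueError("RIS lengths must be non-negative")
    if ris1_len >= t.unusual_min or ris2_len >= t.unusual_min:
        return "unusual_flagged"
    b1 = t.ris1_band(ris1_len)
    b2 = t.ris2_band(ris2_len)
    if "ambiguous" in (b1, b2):
        return "ambiguous"
    if b1 == "short" and b2 == "short":
        return "classI"
    if b1 == "long" and b2 == "long":
        return "classII"
    if b1 == "long" and b2 == "verylong":
        return "classII_verylongRIS2"
    return "discordant"


def applicability_gate(
    profile: ProfileHMM,
    seq: ProteinSequence,
    min_bits: float = 100.0,
    require_cys: bool = True,
    *,
    mapping: QueryMapping | None = None,
) -> tuple[bool, float]:
    """Database-free check that a query plausibly has the CYP fold.

    Passes iff the glocal forward score reaches ``min_bits`` and (when
    ``require_cys``) the heme-cysteine anchor state aligns to a cysteine.
    """
    bits = forward_score(profile, seq, allow_fragment=True)
    ok = bits >= min_bits
    if ok and require_cys:
        m = mapping or align_query(profile, seq, allow_fragment=True)
        k = profile.anchor_states["cys"]
        pos = m.assignments[k]
        ok = pos is not None and seq.residues[pos - 1] == "C"
    return ok, float(bits)


def annotate_sequence(
    profile: ProfileHMM,
    ann: SeedAnnotation,
    seq: ProteinSequence,
    thresholds: ClassThresholds | None = None,
    gate_params: GateParams | None = None,
) -> AnnotationResult:
    """Full annotation of one query sequence.

    A query failing the applicability gate still gets all structural fields
    computed — ``gate_pass`` records the verdict and the caller decides.
    Queries below the fragment guard raise :class:`FragmentError`.
    """
    gate_params = gate_params or GateParams()
    mapping = align_query(profile, seq)  # raises FragmentError when too short
    gate_pass, bits = applicability_gate(
        profile,
        seq,
        min_bits=gate_params.min_bits,
        require_cys=gate_params.require_cys,
        mapping=mapping,
    )
    scrs = transfer_scrs(mapping, ann, profile)
    f87 = predict_f87(mapping, profile, seq)
    ris1 = measure_ris(mapping, ann, profile, "RIS1")
    ris2 = measure_ris(mapping, ann, profile, "RIS2")
    return AnnotationResult(
        query_id=seq.id,
        gate_pass=gate_pass,
        gate_score_bits=bits,
        scr_intervals=scrs,
        f87_call=f87,
        ris1_len=ris1,
        ris2_len=ris2,
        redox_class=classify_redox(ris1, ris2, thresholds),
    )
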