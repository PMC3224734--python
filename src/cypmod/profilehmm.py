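"""Profile hidden Markov model over a structure-anchored seed alignment.

The model follows the classic match/insert/delete column architecture.
Columns of the seed alignment whose non-gap fraction reaches the occupancy
threshold become match states; anchor columns (F87-equivalent, ExxR
glutamate/arginine, heme cysteine, RIS flanks) and SCR boundary columns are
force-included as match states regardless of occupancy, so every annotation
the model must transfer is representable on the match-state backbone.

Alignment is *glocal*: the model is traversed from begin to end (deletions
may eat into either end through the delete chain), while query residues
before the first and after the last model-emitted residue are free flanks
scored at background odds 1.  This fits full-length CYP queries whose
variable termini (and, for fusion proteins such as P450 BM-3, a whole
reductase domain) fall outside the structurally conserved core.

Scores are log-odds in bits against a background residue model: a match
emission contributes ``log2(e_k(a)/q(a))``, insert emissions are tied to the
background (0 bits), transitions contribute their log2 probabilities, and
flank residues contribute nothing.  All arithmetic is in log space and the
Viterbi tie-break is fixed (Match > Delete > Insert), so outputs are
bit-reproducible.

The state graph has no I->D or D->I edges (the standard simplification);
insert runs in the seed that border a deletion are attributed to the direct
match/delete transition during estimation.  The unknown residue ``X`` is
emitted at background odds (0 bits) and excluded from emission counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import AMINO_ACIDS, GAP, ProteinSequence
from .seedmodel import SeedAlignment, SeedAnnotation

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG_INF = float("-inf")

PROFILE_FORMAT_VERSION = 1

#: Sentinel for a match state that emitted nothing (delete state used).
DELETED = None


class ProfileError(ValueError):
    """Raised on invalid model construction or scoring input."""


class FragmentError(ProfileError):
    """Raised when a query is shorter than the fragment guard."""


@dataclass(frozen=True)
class BuildParams:
    """Estimation parameters for profile construction.

    occupancy_threshold
        Minimum non-gap column fraction for a column to become a match
        state (anchors and SCR boundaries are forced regardless).
    pseudocount_alpha
        Weight of the background-proportional pseudocount added to both
        emission and transition counts.
    background
        Length-20 residue frequency table in ``ACDEFGHIKLMNPQRSTVWY``
        order; uniform when omitted.
    min_query_length
        Fragment guard: queries shorter than this are refused.
    """

    occupancy_threshold: float = 0.5
    pseudocount_alpha: float = 1.0
    background: tuple[float, ...] | None = None
    min_query_length: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ProfileError("occupancy_threshold must be in (0, 1]")
        if self.pseudocount_alpha < 0:
            raise ProfileError("pseudocount_alpha must be >= 0")
        if self.background is not None:
            if len(self.background) != 20:
                raise ProfileError("background must have 20 entries")
            if abs(sum(self.background) - 1.0) > 1e-9:
                raise ProfileError("background must sum to 1")


@dataclass(frozen=True)
class MatchState:
    source_column: int  # 1-based seed alignment column
    emissions: tuple[float, ...]  # probability over the 20 residues
    # outgoing transitions; the last match state exits to End with prob 1.
    m_to_m: float = 0.0
    m_to_i: float = 0.0
    m_to_d: float = 0.0


@dataclass(frozen=True)
class ProfileHMM:
    match_states: tuple[MatchState, ...]
    # insert state k sits between match k and k+1 (len = n_match - 1)
    i_to_m: tuple[float, ...]
    i_to_i: tuple[float, ...]
    # delete state k (len = n_match - 1); the last delete exits to End.
    d_to_m: tuple[float, ...]
    d_to_d: tuple[float, ...]
    begin_to_m: float
    begin_to_d: float
    background: tuple[float, ...]
    anchor_states: dict[str, int]  # anchor name -> 0-based match index
    min_query_length: int = 50

    def __post_init__(self) -> None:
        L = len(self.match_states)
        if L == 0:
            raise ProfileError("profile needs at least one match state")
        cols = [m.source_column for m in self.match_states]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ProfileError("match source columns must be strictly increasing")
        for m in self.match_states:
            if abs(sum(m.emissions) - 1.0) > 1e-9:
                raise ProfileError("match emissions must sum to 1")
        for k, m in enumerate(self.match_states[:-1]):
            if abs(m.m_to_m + m.m_to_i + m.m_to_d - 1.0) > 1e-9:
                raise ProfileError(f"match state {k} transitions do not sum to 1")
        for k in range(L - 1):
            if abs(self.i_to_m[k] + self.i_to_i[k] - 1.0) > 1e-9:
                raise ProfileError(f"insert state {k} transitions do not sum to 1")
            if abs(self.d_to_m[k] + self.d_to_d[k] - 1.0) > 1e-9:
                raise ProfileError(f"delete state {k} transitions do not sum to 1")
        if abs(self.begin_to_m + self.begin_to_d - 1.0) > 1e-9:
            raise ProfileError("begin transitions do not sum to 1")
        for name, idx in self.anchor_states.items():
            if not (0 <= idx < L):
                raise ProfileError(f"anchor {name!r} points outside the model")

    @property
    def n_match(self) -> int:
        return len(self.match_states)

    def state_for_column(self, column: int) -> int | None:
        """0-based match state index whose source is ``column``, if any."""
        for k, m in enumerate(self.match_states):
            if m.source_column == column:
                return k
        return None

    def match_states_in_span(self, start_col: int, end_col: int) -> list[int]:
        return [
            k
            for k, m in enumerate(self.match_states)
            if start_col <= m.source_column <= end_col
        ]


@dataclass(frozen=True)
class QueryMapping:
    """The alignment path of one query through the profile.

    ``assignments[k]`` is the 1-based query position emitted by match state
    k, or None when the state was deleted.  ``insertions`` lists runs of
    query positions emitted by the insert state after match state k.
    Flank counts record query residues consumed before/after the model.
    """

    query_id: str
    assignments: tuple[int | None, ...]
    insertions: tuple[tuple[int, tuple[int, ...]], ...]
    n_flank: int
    c_flank: int
    score_bits: float

    def __post_init__(self) -> None:
        emitted = [p for p in self.assignments if p is not None]
        if any(b <= a for a, b in zip(emitted, emitted[1:])):
            raise ProfileError("match positions must be strictly increasing")

    def position_of(self, state_index: int) -> int | None:
        return self.assignments[state_index]

    def all_positions_partition(self, query_length: int) -> bool:
        """True iff flanks + matches + insertions tile 1..query_length."""
        used = list(range(1, self.n_flank + 1))
        used += [p for p in self.assignments if p is not None]
        for _, run in self.insertions:
            used += list(run)
        used += list(range(query_length - self.c_flank + 1, query_length + 1))
        return sorted(used) == list(range(1, query_length + 1))


def uniform_background() -> tuple[float, ...]:
    return tuple([1.0 / 20] * 20)


# ---------------------------------------------------------------------------
# construction


def _column_chars(seed: SeedAlignment, col: int) -> list[str]:
    return [r.gapped[col - 1] for r in seed.rows]


def _row_events(
    gapped: str, match_cols: Sequence[int]
) -> tuple[list[str], list[int]]:
    """Per-row path summary: M/D at each match column and the insert-run
    length between consecutive match columns (index k = run after match k)."""
    states = ["D" if gapped[c - 1] == GAP else "M" for c in match_cols]
    gaps_between = []
    for a, b in zip(match_cols, match_cols[1:]):
        gaps_between.append(
            sum(gapped[c - 1] != GAP for c in range(a + 1, b))
        )
    return states, gaps_between


def build_profile(
    seed: SeedAlignment,
    ann: SeedAnnotation,
    params: BuildParams | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an annotated seed alignment.

    Match columns are those with non-gap fraction >= the occupancy
    threshold, plus all anchor columns and SCR boundary columns (forced).
    Emissions use background-weighted pseudocounts,
    ``e(a) = (count(a) + alpha * q(a)) / (n_obs + alpha)``; transitions are
    estimated from the observed state paths of the seed rows with the same
    pseudocount scheme (prior uniform over each state's outgoing set).
    """
    params = params or BuildParams()
    alpha = params.pseudocount_alpha
    q = np.asarray(params.background or uniform_background())
    n_rows = len(seed.rows)
    n_cols = seed.n_columns

    forced = set(ann.anchor_columns.values())
    for scr in ann.scrs:
        forced.add(scr.start_col)
        forced.add(scr.end_col)

    match_cols: list[int] = []
    for col in range(1, n_cols + 1):
        chars = _column_chars(seed, col)
        occupancy = sum(c != GAP for c in chars) / n_rows
        if occupancy >= params.occupancy_threshold or col in forced:
            match_cols.append(col)

    for name, col in ann.anchor_columns.items():
        if all(c == GAP for c in _column_chars(seed, col)):
            raise ProfileError(
                f"anchor {name!r} column {col} has no observed residues"
            )

    L = len(match_cols)
    col_to_state = {c: k for k, c in enumerate(match_cols)}

    # emissions
    emissions = []
    for col in match_cols:
        counts = np.zeros(20)
        for c in _column_chars(seed, col):
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        n_obs = counts.sum()
        if n_obs + alpha > 0:
            e = (counts + alpha * q) / (n_obs + alpha)
        else:
            e = q.copy()
        emissions.append(tuple(e.tolist()))

    # transition counts from observed row paths
    mm = np.zeros(L); mi = np.zeros(L); md = np.zeros(L)
    im = np.zeros(L); ii = np.zeros(L)
    dm = np.zeros(L); dd = np.zeros(L)
    bm = 0.0; bd = 0.0
    for row in seed.rows:
        states, inserts = _row_events(row.gapped, match_cols)
        if states[0] == "M":
            bm += 1
        else:
            bd += 1
        for k in range(L - 1):
            a, b, c = states[k], states[k + 1], inserts[k]
            if c > 0 and a == "M" and b == "M":
                mi[k] += 1
                ii[k] += c - 1
                im[k] += 1
            else:
                # insert residues bordering a deletion are not
                # representable (no I->D / D->I edges); attribute the step
                # to the direct transition.
                if a == "M" and b == "M":
                    mm[k] += 1
                elif a == "M":
                    md[k] += 1
                elif b == "M":
                    dm[k] += 1
                else:
                    dd[k] += 1

    def _norm(counts: Sequence[float], n_out: int) -> list[float]:
        total = float(sum(counts))
        if total + alpha <= 0:
            return [1.0 / n_out] * n_out
        prior = alpha / n_out
        return [(c + prior) / (total + alpha) for c in counts]

    m_trans = [_norm((mm[k], mi[k], md[k]), 3) for k in range(L - 1)]
    i_trans = [_norm((im[k], ii[k]), 2) for k in range(L - 1)]
    d_trans = [_norm((dm[k], dd[k]), 2) for k in range(L - 1)]
    b_trans = _norm((bm, bd), 2)

    match_states = []
    for k in range(L):
        if k == L - 1:
            match_states.append(
                MatchState(source_column=match_cols[k], emissions=emissions[k])
            )
        else:
            t = m_trans[k]
            match_states.append(
                MatchState(
                    source_column=match_cols[k],
                    emissions=emissions[k],
                    m_to_m=t[0],
                    m_to_i=t[1],
                    m_to_d=t[2],
                )
            )

    anchor_states = {
        name: col_to_state[col] for name, col in ann.anchor_columns.items()
    }

    return ProfileHMM(
        match_states=tuple(match_states),
        i_to_m=tuple(t[0] for t in i_trans),
        i_to_i=tuple(t[1] for t in i_trans),
        d_to_m=tuple(t[0] for t in d_trans),
        d_to_d=tuple(t[1] for t in d_trans),
        begin_to_m=b_trans[0],
        begin_to_d=b_trans[1],
        background=tuple(q.tolist()),
        anchor_states=anchor_states,
        min_query_length=params.min_query_length,
    )


# ---------------------------------------------------------------------------
# scoring


def _log2(p: float) -> float:
    return math.log2(p) if p > 0 else _NEG_INF


def _emission_bits(profile: ProfileHMM, seq: str) -> np.ndarray:
    """(L, n) match log-odds emission matrix; X scores 0 everywhere."""
    q = np.asarray(profile.background)
    e = np.asarray([m.emissions for m in profile.match_states])
    with np.errstate(divide="ignore"):
        lo = np.log2(e) - np.log2(q)[None, :]
    idx = np.array([_AA_INDEX.get(a, -1) for a in seq])
    em = lo[:, np.where(idx < 0, 0, idx)]
    em[:, idx < 0] = 0.0
    return em


def _transition_bits(profile: ProfileHMM):
    L = profile.n_match
    tmm = np.array([_log2(m.m_to_m) for m in profile.match_states[:-1]])
    tmi = np.array([_log2(m.m_to_i) for m in profile.match_states[:-1]])
    tmd = np.array([_log2(m.m_to_d) for m in profile.match_states[:-1]])
    tim = np.array([_log2(p) for p in profile.i_to_m])
    tii = np.array([_log2(p) for p in profile.i_to_i])
    tdm = np.array([_log2(p) for p in profile.d_to_m])
    tdd = np.array([_log2(p) for p in profile.d_to_d])
    for arr in (tmm, tmi, tmd, tim, tii, tdm, tdd):
        arr.resize(max(L - 1, 0), refcheck=False)
    return tmm, tmi, tmd, tim, tii, tdm, tdd


def _check_query(profile: ProfileHMM, seq: ProteinSequence) -> None:
    if len(seq) < profile.min_query_length:
        raise FragmentError(
            f"query {seq.id!r} has {len(seq)} residues, below the fragment "
            f"guard of {profile.min_query_length}; pass a full-length "
            "sequence or lower min_query_length"
        )


def align_query(
    profile: ProfileHMM, seq: ProteinSequence, *, allow_fragment: bool = False
) -> QueryMapping:
    """Glocal Viterbi alignment of a query to the profile.

    Returns the optimal path as a :class:`QueryMapping` with its log-odds
    score in bits.  Ties are broken deterministically: at each cell the
    Match predecessor wins over Delete, which wins over Insert.
    """
    if not allow_fragment:
        _check_query(profile, seq)
    s = seq.residues
    L, n = profile.n_match, len(s)
    em = _emission_bits(profile, s)
    tmm, tmi, tmd, tim, tii, tdm, tdd = _transition_bits(profile)
    lbm, lbd = _log2(profile.begin_to_m), _log2(profile.begin_to_d)

    # V*[k][i]: best score of a path ending at that state having consumed i
    # query residues (for M/I, i is the position of the last emission).
    # Pointer codes: 0 = from Match, 1 = from Delete, 2 = from Insert,
    # 3 = from Begin.
    VM = np.full((L, n + 1), _NEG_INF)
    VD = np.full((L, n + 1), _NEG_INF)
    VI = np.full((L, n + 1), _NEG_INF)
    PM = np.zeros((L, n + 1), dtype=np.int8)
    PD = np.zeros((L, n + 1), dtype=np.int8)
    PI = np.full((L, n + 1), 2, dtype=np.int8)

    VM[0, 1:] = lbm + em[0, :]
    PM[0, 1:] = 3
    VD[0, :] = lbd
    PD[0, :] = 3

    codes_mdi = np.array([0, 1, 2], dtype=np.int8)
    for k in range(L):
        if k > 0:
            stacked = np.stack(
                (
                    VM[k - 1, :-1] + tmm[k - 1],
                    VD[k - 1, :-1] + tdm[k - 1],
                    VI[k - 1, :-1] + tim[k - 1],
                )
            )
            choice = stacked.argmax(axis=0)  # first max wins: M > D > I
            VM[k, 1:] = stacked.max(axis=0) + em[k, :]
            PM[k, 1:] = codes_mdi[choice]
            stacked_d = np.stack(
                (VM[k - 1, :] + tmd[k - 1], VD[k - 1, :] + tdd[k - 1])
            )
            choice_d = stacked_d.argmax(axis=0)
            VD[k, :] = stacked_d.max(axis=0)
            PD[k, :] = codes_mdi[choice_d]
        if k < L - 1 and n > 0:
            enter = VM[k, :-1] + tmi[k]  # entry from M at consumed j
            if tii[k] == _NEG_INF:
                VI[k, 1:] = enter
                PI[k, 1:] = 0
            else:
                j = np.arange(n)
                g = enter - j * tii[k]
                run = np.maximum.accumulate(g)
                VI[k, 1:] = run + j * tii[k]
                # direct entry preferred on ties (Match > Insert)
                PI[k, 1:] = np.where(g >= run, 0, 2)

    # end: last match or last delete, any consumed count (rest is C flank)
    end_m = int(VM[L - 1, :].argmax())
    end_d = int(VD[L - 1, :].argmax())
    if VM[L - 1, end_m] >= VD[L - 1, end_d]:
        best_state, best_i, best_score = "M", end_m, float(VM[L - 1, end_m])
    else:
        best_state, best_i, best_score = "D", end_d, float(VD[L - 1, end_d])
    if best_score == _NEG_INF:
        raise ProfileError(f"no admissible alignment for query {seq.id!r}")

    # traceback
    assignments: list[int | None] = [None] * L
    insert_runs: dict[int, list[int]] = {}
    state, k, i = best_state, L - 1, best_i
    c_flank = n - best_i
    n_flank = 0
    while True:
        if state == "M":
            assignments[k] = i
            code = int(PM[k, i])
            i -= 1
            if code == 3:
                n_flank = i
                break
            k -= 1
        elif state == "D":
            code = int(PD[k, i])
            if code == 3:
                n_flank = i
                break
            k -= 1
        else:  # insert after match k
            insert_runs.setdefault(k, []).append(i)
            code = int(PI[k, i])
            i -= 1
        state = {0: "M", 1: "D", 2: "I"}[code]

    insertions = tuple(
        (k, tuple(sorted(pos))) for k, pos in sorted(insert_runs.items())
    )
    return QueryMapping(
        query_id=seq.id,
        assignments=tuple(assignments),
        insertions=insertions,
        n_flank=n_flank,
        c_flank=c_flank,
        score_bits=best_score,
    )


def forward_score(
    profile: ProfileHMM, seq: ProteinSequence, *, allow_fragment: bool = False
) -> float:
    """Glocal forward log-odds score in bits (sum over all paths).

    Always >= the Viterbi ``score_bits`` of :func:`align_query`.
    """
    if not allow_fragment:
        _check_query(profile, seq)
    s = seq.residues
    L, n = profile.n_match, len(s)
    em = _emission_bits(profile, s)
    tmm, tmi, tmd, tim, tii, tdm, tdd = _transition_bits(profile)
    lbm, lbd = _log2(profile.begin_to_m), _log2(profile.begin_to_d)

    FM = np.full((L, n + 1), _NEG_INF)
    FD = np.full((L, n + 1), _NEG_INF)
    FI = np.full((L, n + 1), _NEG_INF)
    FM[0, 1:] = lbm + em[0, :]
    FD[0, :] = lbd
    with np.errstate(invalid="ignore"):
        for k in range(L):
            if k > 0:
                prev = np.logaddexp2(
                    np.logaddexp2(
                        FM[k - 1, :-1] + tmm[k - 1],
                        FD[k - 1, :-1] + tdm[k - 1],
                    ),
                    FI[k - 1, :-1] + tim[k - 1],
                )
                FM[k, 1:] = prev + em[k, :]
                FD[k, :] = np.logaddexp2(
                    FM[k - 1, :] + tmd[k - 1], FD[k - 1, :] + tdd[k - 1]
                )
            if k < L - 1:
                for i in range(1, n + 1):
                    FI[k, i] = np.logaddexp2(
                        FM[k, i - 1] + tmi[k], FI[k, i - 1] + tii[k]
                    )
    ends = np.concatenate([FM[L - 1, :], FD[L - 1, :]])
    finite = ends[np.isfinite(ends)]
    if finite.size == 0:
        raise ProfileError(f"no admissible alignment for query {seq.id!r}")
    m = finite.max()
    return float(m + math.log2(np.exp2(finite - m).sum()))


# ---------------------------------------------------------------------------
# sampling


def score_mapping(
    profile: ProfileHMM, seq: ProteinSequence, mapping: QueryMapping
) -> float:
    """Log-odds (bits) of one explicit path; used to score sampled truths."""
    tmm, tmi, tmd, tim, tii, tdm, tdd = _transition_bits(profile)
    em = _emission_bits(profile, seq.residues)
    L = profile.n_match
    inserts = dict(mapping.insertions)
    score = 0.0
    prev = "B"
    for k in range(L):
        state = "D" if mapping.assignments[k] is None else "M"
        if prev == "B":
            score += _log2(
                profile.begin_to_m if state == "M" else profile.begin_to_d
            )
        elif prev == "M":
            score += (tmm if state == "M" else tmd)[k - 1]
        elif prev == "D":
            score += (tdm if state == "M" else tdd)[k - 1]
        else:  # prev == "I"
            if state != "M":
                return _NEG_INF  # no I->D edge
            score += tim[k - 1]
        if state == "M":
            score += em[k, mapping.assignments[k] - 1]
        run = inserts.get(k, ())
        if run:
            if state != "M" or k >= L - 1:
                raise ProfileError("insert run must follow an emitting match")
            score += tmi[k] + tii[k] * (len(run) - 1)
            prev = "I"
        else:
            prev = state
    return float(score)


def sample_path(
    profile: ProfileHMM,
    rng_seed: int | np.random.Generator,
    mode: str = "faithful",
    query_id: str = "sampled",
) -> tuple[ProteinSequence, QueryMapping]:
    """Sample a sequence and its generating path from the model.

    ``faithful`` samples states and emissions according to the model
    probabilities; ``mainline`` forces the all-match path (emissions still
    sampled from the match emission tables).  The returned mapping is the
    generating truth, including its path log-odds; the same seed yields an
    identical draw.  An all-delete draw emits nothing and is redrawn.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if mode not in ("faithful", "mainline"):
        raise ProfileError(f"unknown sampling mode {mode!r}")
    L = profile.n_match
    q = np.asarray(profile.background)

    while True:
        residues: list[str] = []
        assignments: list[int | None] = [None] * L
        insert_runs: list[tuple[int, tuple[int, ...]]] = []
        if mode == "mainline":
            for k in range(L):
                residues.append(
                    _sample_residue(rng, profile.match_states[k].emissions)
                )
                assignments[k] = len(residues)
        else:
            state = "M" if rng.random() < profile.begin_to_m else "D"
            k = 0
            while True:
                if state == "M":
                    residues.append(
                        _sample_residue(rng, profile.match_states[k].emissions)
                    )
                    assignments[k] = len(residues)
                if k == L - 1:
                    break
                if state == "M":
                    m = profile.match_states[k]
                    u = rng.random()
                    if u < m.m_to_m:
                        state = "M"
                    elif u < m.m_to_m + m.m_to_i:
                        run = []
                        while True:
                            residues.append(_sample_residue(rng, q))
                            run.append(len(residues))
                            if rng.random() < profile.i_to_m[k]:
                                break
                        insert_runs.append((k, tuple(run)))
                        state = "M"
                    else:
                        state = "D"
                else:
                    state = "M" if rng.random() < profile.d_to_m[k] else "D"
                k += 1
        if residues:
            break

    seq = ProteinSequence(id=query_id, residues="".join(residues))
    mapping = QueryMapping(
        query_id=query_id,
        assignments=tuple(assignments),
        insertions=tuple(insert_runs),
        n_flank=0,
        c_flank=0,
        score_bits=0.0,
    )
    mapping = QueryMapping(
        query_id=query_id,
        assignments=mapping.assignments,
        insertions=mapping.insertions,
        n_flank=0,
        c_flank=0,
        score_bits=score_mapping(profile, seq, mapping),
    )
    return seq, mapping


def _sample_residue(rng: np.random.Generator, probs: Sequence[float]) -> str:
    p = np.asarray(probs, dtype=float)
    return AMINO_ACIDS[int(rng.choice(20, p=p / p.sum()))]


# ---------------------------------------------------------------------------
# serialization


def profile_to_json(profile: ProfileHMM) -> dict:
    """Versioned JSON form; probabilities as decimal strings for an exact
    round-trip (``float(repr(x)) == x``)."""

    def fmt(x: float) -> str:
        return repr(float(x))

    return {
        "format": "cypmod-profile",
        "version": PROFILE_FORMAT_VERSION,
        "alphabet": AMINO_ACIDS,
        "background": [fmt(p) for p in profile.background],
        "begin": {"to_m": fmt(profile.begin_to_m), "to_d": fmt(profile.begin_to_d)},
        "match_states": [
            {
                "source_column": m.source_column,
                "emissions": [fmt(p) for p in m.emissions],
                "to_m": fmt(m.m_to_m),
                "to_i": fmt(m.m_to_i),
                "to_d": fmt(m.m_to_d),
            }
            for m in profile.match_states
        ],
        "insert": {
            "to_m": [fmt(p) for p in profile.i_to_m],
            "to_i": [fmt(p) for p in profile.i_to_i],
        },
        "delete": {
            "to_m": [fmt(p) for p in profile.d_to_m],
            "to_d": [fmt(p) for p in profile.d_to_d],
        },
        "anchor_states": dict(profile.anchor_states),
        "min_query_length": profile.min_query_length,
    }


def profile_from_json(data: dict) -> ProfileHMM:
    if data.get("format") != "cypmod-profile":
        raise ProfileError("not a cypmod profile file")
    if data.get("version") != PROFILE_FORMAT_VERSION:
        raise ProfileError(f"unsupported profile version {data.get('version')}")
    match_states = tuple(
        MatchState(
            source_column=m["source_column"],
            emissions=tuple(float(p) for p in m["emissions"]),
            m_to_m=float(m["to_m"]),
            m_to_i=float(m["to_i"]),
            m_to_d=float(m["to_d"]),
        )
        for m in data["match_states"]
    )
    return ProfileHMM(
        match_states=match_states,
        i_to_m=tuple(float(p) for p in data["insert"]["to_m"]),
        i_to_i=tuple(float(p) for p in data["insert"]["to_i"]),
        d_to_m=tuple(float(p) for p in data["delete"]["to_m"]),
        d_to_d=tuple(float(p) for p in data["delete"]["to_d"]),
        begin_to_m=float(data["begin"]["to_m"]),
        begin_to_d=float(data["begin"]["to_d"]),
        background=tuple(float(p) for p in data["background"]),
        anchor_states={k: int(v) for k, v in data["anchor_states"].items()},
        min_query_length=int(data.get("min_query_length", 50)),
    )


def save_profile(profile: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_json(profile), fh, indent=1)


def load_profile(path: str | Path) -> ProfileHMM:
    with open(path) as fh:
        return profile_from_json(json.load(fh))
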