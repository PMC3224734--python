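"""Independent brute-force oracle for glocal profile-HMM scoring.

Enumerates every legal glocal path explicitly: a free N-flank of f
residues, entry at match/delete 1, interior match/insert/delete moves (no
I<->D edges), exit from the last match/delete state, and a free C-flank.
Scores are accumulated exactly as log-odds in bits, independently of the
dynamic-programming implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

from cypmod.profilehmm import MatchState, ProfileHMM
from cypmod.seqio import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _lo(p: float) -> float:
    return math.log2(p) if p > 0 else float("-inf")


def enumerate_path_scores(profile: ProfileHMM, residues: str) -> list[float]:
    """Log-odds score (bits) of every legal glocal path, one per path."""
    L = profile.n_match
    n = len(residues)
    q = profile.background
    em = [
        [
            _lo(m.emissions[_AA_INDEX[a]]) - _lo(q[_AA_INDEX[a]])
            if a in _AA_INDEX
            else 0.0
            for a in residues
        ]
        for m in profile.match_states
    ]
    tm = [( _lo(m.m_to_m), _lo(m.m_to_i), _lo(m.m_to_d)) for m in profile.match_states[:-1]]
    tim = [_lo(p) for p in profile.i_to_m]
    tii = [_lo(p) for p in profile.i_to_i]
    tdm = [_lo(p) for p in profile.d_to_m]
    tdd = [_lo(p) for p in profile.d_to_d]

    scores: list[float] = []

    def walk(k: int, state: str, i: int, score: float) -> None:
        # i = number of query residues consumed so far (absolute)
        if score == float("-inf"):
            return
        if k == L - 1:
            scores.append(score)  # exit to End with probability 1
            return
        if state == "M":
            tmm, tmi, tmd = tm[k]
            if i < n:
                walk(k + 1, "M", i + 1, score + tmm + em[k + 1][i])
            walk(k + 1, "D", i, score + tmd)
            # insert run of m >= 1 residues, then I->M into match k+1
            run_score = score + tmi
            j = i
            while j < n - 1:  # need one residue left for M_{k+1}
                run_score += 0.0  # insert emissions are background-tied
                extra = tii[k] * (j - i)  # m-1 self-loops for m = j-i+1
                walk(
                    k + 1,
                    "M",
                    j + 2,
                    run_score + extra + tim[k] + em[k + 1][j + 1],
                )
                j += 1
        else:  # state == "D"
            if i < n:
                walk(k + 1, "M", i + 1, score + tdm[k] + em[k + 1][i])
            walk(k + 1, "D", i, score + tdd[k])

    bm, bd = _lo(profile.begin_to_m), _lo(profile.begin_to_d)
    for f in range(n + 1):
        if f < n:
            walk(0, "M", f + 1, bm + em[0][f])
        walk(0, "D", f, bd)
    return scores


def brute_viterbi(profile: ProfileHMM, residues: str) -> float:
    return max(enumerate_path_scores(profile, residues))


def brute_forward(profile: ProfileHMM, residues: str) -> float:
    scores = np.array(enumerate_path_scores(profile, residues))
    finite = scores[np.isfinite(scores)]
    m = finite.max()
    return float(m + math.log2(np.exp2(finite - m).sum()))


def random_profile(rng: np.random.Generator, n_match: int) -> ProfileHMM:
    """A random, fully normalised profile for oracle sweeps."""
    L = n_match
    states = []
    for k in range(L):
        e = rng.dirichlet(np.full(20, 0.5))
        if k == L - 1:
            states.append(
                MatchState(source_column=k + 1, emissions=tuple(e.tolist()))
            )
        else:
            t = rng.dirichlet(np.ones(3))
            states.append(
                MatchState(
                    source_column=k + 1,
                    emissions=tuple(e.tolist()),
                    m_to_m=float(t[0]),
                    m_to_i=float(t[1]),
                    m_to_d=float(t[2]),
                )
            )
    ti = rng.dirichlet(np.ones(2), size=max(L - 1, 1))
    td = rng.dirichlet(np.ones(2), size=max(L - 1, 1))
    tb = rng.dirichlet(np.ones(2))
    return ProfileHMM(
        match_states=tuple(states),
        i_to_m=tuple(float(x) for x in ti[: L - 1, 0]),
        i_to_i=tuple(float(x) for x in ti[: L - 1, 1]),
        d_to_m=tuple(float(x) for x in td[: L - 1, 0]),
        d_to_d=tuple(float(x) for x in td[: L - 1, 1]),
        begin_to_m=float(tb[0]),
        begin_to_d=float(tb[1]),
        background=tuple([1.0 / 20] * 20),
        anchor_states={},
        min_query_length=1,
    )


def random_query(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
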