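"""Batch statistics over annotation results.

Two cohort-level views mirror the database-wide analyses the annotation
pipeline enables: the residue composition observed at the F87-equivalent
hotspot (with configurable physicochemical grouping), and the length
distribution of each reductase interaction site with the fraction of the
cohort falling into each class band.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate import AnnotationResult, ClassThresholds
from .seqio import AMINO_ACIDS, GAP

#: Default residue grouping for the hotspot composition.  The bulky
#: aliphatics plus phenylalanine dominate heme-facing hotspots; the split of
#: the remaining residues into small/polar and charged is one consistent
#: interpretation and is fully configurable.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "aliphatic+F": tuple("GAVLIPMF"),
    "small_polar": tuple("STCNQYWH"),
    "charged": tuple("DEKR"),
}


@dataclass(frozen=True)
class CompositionTable:
    """Residue fractions at an anchor position; gaps count under '-'."""

    freq: dict[str, float]
    groups: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if self.freq and abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")


@dataclass(frozen=True)
class RisDistribution:
    """Per-length histogram and class-band fractions for one RIS.

    Band fractions are over *measurable* entries; UNDEFINED lengths are
    excluded from the histogram and reported separately.
    """

    which: str
    histogram: dict[int, int]
    fractions: dict[str, float]
    n: int
    n_undefined: int


def _check_groups(groups: Mapping[str, Sequence[str]]) -> None:
    seen: set[str] = set()
    for name, members in groups.items():
        dup = seen & set(members)
        if dup:
            raise ValueError(
                f"residues {sorted(dup)} assigned to more than one group "
                f"(group {name!r})"
            )
        seen |= set(members)


def composition_at_anchor(
    results: Sequence[AnnotationResult],
    groups_config: Mapping[str, Sequence[str]] | None = None,
) -> CompositionTable:
    """Residue composition at the F87-equivalent position across a cohort.

    Gap calls are tallied under ``-``.  Group sums cover only the grouped
    residues (gaps belong to no group).
    """
    if not results:
        raise ValueError("no results to analyze")
    groups = dict(groups_config) if groups_config is not None else DEFAULT_GROUPS
    _check_groups(groups)
    counts: Counter[str] = Counter()
    for r in results:
        counts[GAP if r.f87_call is None else r.f87_call[1]] += 1
    n = sum(counts.values())
    freq = {res: c / n for res, c in sorted(counts.items())}
    group_sums = {
        name: sum(freq.get(res, 0.0) for res in members)
        for name, members in groups.items()
    }
    return CompositionTable(freq=freq, groups=group_sums, n=n)


def merge_compositions(parts: Iterable[CompositionTable]) -> CompositionTable:
    """Weighted merge of compositions of a partition of a cohort."""
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to merge")
    n = sum(p.n for p in parts)
    freq: Counter[str] = Counter()
    for p in parts:
        for res, f in p.freq.items():
            freq[res] += f * p.n / n
    groups: Counter[str] = Counter()
    for p in parts:
        for name, f in p.groups.items():
            groups[name] += f * p.n / n
    return CompositionTable(freq=dict(freq), groups=dict(groups), n=n)


def ris_distribution(
    results: Sequence[AnnotationResult],
    thresholds: ClassThresholds | None = None,
    which: str = "RIS1",
) -> RisDistribution:
    """Length histogram and class-band fractions for RIS1 or RIS2.

    Bands for RIS1: short / ambiguous / long / unusual; for RIS2: short /
    ambiguous / long / verylong / unusual.  Fractions are over measurable
    entries and sum to 1 when every entry is measurable.
    """
    if not results:
        raise ValueError("no results to analyze")
    if which not in ("RIS1", "RIS2"):
        raise ValueError(f"unknown interaction site {which!r}")
    t = thresholds or ClassThresholds()
    lengths = [
        (r.ris1_len if which == "RIS1" else r.ris2_len) for r in results
    ]
    defined = [x for x in lengths if x is not None]
    n_undefined = len(lengths) - len(defined)
    histogram = dict(sorted(Counter(defined).items()))
    band_of = t.ris1_band if which == "RIS1" else t.ris2_band
    band_counts: Counter[str] = Counter(band_of(x) for x in defined)
    n = len(defined)
    fractions = {
        band: band_counts.get(band, 0) / n if n else 0.0
        for band in (
            ("short", "ambiguous", "long", "unusual")
            if which == "RIS1"
            else ("short", "ambiguous", "long", "verylong", "unusual")
        )
    }
    return RisDistribution(
        which=which,
        histogram=histogram,
        fractions=fractions,
        n=n,
        n_undefined=n_undefined,
    )


def stats_to_json(
    composition: CompositionTable,
    ris1: RisDistribution,
    ris2: RisDistribution,
) -> dict:
    """Bundle the cohort tables for the `cypmod stats` output file."""
    return {
        "composition": {
            "n": composition.n,
            "freq": composition.freq,
            "groups": composition.groups,
        },
        "ris1": {
            "n": ris1.n,
            "n_undefined": ris1.n_undefined,
            "histogram": {str(k): v for k, v in ris1.histogram.items()},
            "fractions": ris1.fractions,
        },
        "ris2": {
            "n": ris2.n,
            "n_undefined": ris2.n_undefined,
            "histogram": {str(k): v for k, v in ris2.histogram.items()},
            "fractions": ris2.fractions,
        },
    }
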