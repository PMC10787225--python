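"""Detection of candidate amyloidogenic β-hairpins in a propensity profile.

The filter nominates a β-hairpin candidate wherever two β-stretches —
maximal runs of residues whose β-aggregation propensity exceeds a
threshold — are connected by a short turn and the two strands have an
amino-acid composition like the β-hairpins of Aβ, α-synuclein and IAPP:

1.  residues with propensity > 1.06 are "in β-stretch";
2.  only stretches of 5–23 residues are considered;
3.  consecutive stretches must be separated by at most 9 residues
    (the potential turn);
4.  the N-terminal strand must contain at least one aromatic residue
    (4.1) and an Ile+Leu+Val fraction between 0.32 and 0.50 (4.2);
5.  the C-terminal strand must contain 1–3 glycines (5.1) and an
    Ile+Leu+Val fraction between 0.32 and 0.61 (5.2).

All "between" bounds are inclusive, and fraction bounds are compared with
exact rational arithmetic so that e.g. an ILV count of 8 in a 25-residue
strand (8/25 = 0.32) passes deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence, Union

import yaml

from .sequence_io import AlignmentError, PropensityProfile, ProteinRecord

__all__ = [
    "FilterConfig",
    "Stretch",
    "CompositionMetrics",
    "HairpinCandidate",
    "find_stretches",
    "length_filter",
    "enumerate_pairs",
    "ilv_fraction",
    "composition_check",
    "scan",
]

#: Fixed order in which failure codes are reported.
FAILURE_CODES = ("C2_N", "C2_C", "C3", "C4_1", "C4_2", "C5_1", "C5_2")


def _as_fraction(x: Union[float, int, str, Fraction]) -> Fraction:
    # str() round-trips the shortest decimal of a float, so 0.32 -> 8/25.
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


@dataclass(frozen=True)
class FilterConfig:
    """All numeric thresholds of the hairpin filter plus policy switches.

    The defaults reproduce the published criteria. ``strict_greater``
    selects ``> threshold`` (default) versus ``>= threshold`` for stretch
    membership; ``turn_requires_zero`` additionally demands that every
    turn residue have a propensity of exactly zero.
    """

    propensity_threshold: float = 1.06
    strict_greater: bool = True
    min_stretch_len: int = 5
    max_stretch_len: int = 23
    max_turn_len: int = 9
    turn_requires_zero: bool = False
    n_aromatic_min: int = 1
    n_ilv_lo: float = 0.32
    n_ilv_hi: float = 0.50
    c_gly_lo: int = 1
    c_gly_hi: int = 3
    c_ilv_lo: float = 0.32
    c_ilv_hi: float = 0.61
    aromatic_set: frozenset = frozenset("FWY")
    ilv_set: frozenset = frozenset("ILV")
    gly_set: frozenset = frozenset("G")

    def __post_init__(self) -> None:
        if not (0 < self.min_stretch_len <= self.max_stretch_len):
            raise ValueError("need 0 < min_stretch_len <= max_stretch_len")
        if self.max_turn_len < 1:
            raise ValueError("max_turn_len must be >= 1")
        if self.propensity_threshold < 0:
            raise ValueError("propensity_threshold must be >= 0")
        for lo, hi, name in (
            (self.n_ilv_lo, self.n_ilv_hi, "n_ilv"),
            (self.c_ilv_lo, self.c_ilv_hi, "c_ilv"),
        ):
            if not (0 <= _as_fraction(lo) <= _as_fraction(hi) <= 1):
                raise ValueError(f"need 0 <= {name}_lo <= {name}_hi <= 1")
        if self.c_gly_lo > self.c_gly_hi:
            raise ValueError("need c_gly_lo <= c_gly_hi")
        object.__setattr__(self, "aromatic_set", frozenset(self.aromatic_set))
        object.__setattr__(self, "ilv_set", frozenset(self.ilv_set))
        object.__setattr__(self, "gly_set", frozenset(self.gly_set))

    def passes_threshold(self, score: float) -> bool:
        if self.strict_greater:
            return score > self.propensity_threshold
        return score >= self.propensity_threshold

    # -- flat config-file (de)serialization -------------------------------

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, frozenset):
                value = "".join(sorted(value))
            d[name] = value
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        kwargs = dict(d)
        for key in ("aromatic_set", "ilv_set", "gly_set"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class Stretch:
    """A maximal run of residues above the propensity threshold.

    ``start``/``end`` are 1-based inclusive positions.
    """

    start: int
    end: int
    subsequence: str
    mean_score: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.subsequence) != self.length:
            raise ValueError("subsequence length disagrees with coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CompositionMetrics:
    """Strand-composition descriptors entering criteria 4.1–5.2."""

    n_aromatic: int
    n_ilv_fraction: Fraction
    c_gly: int
    c_ilv_fraction: Fraction


@dataclass(frozen=True)
class HairpinCandidate:
    """An N-strand/turn/C-strand triple with pass/fail provenance.

    ``turn_len == c_strand.start - n_strand.end - 1`` and
    ``passed == (failure_reasons == ())``.
    """

    protein_id: str
    n_strand: Stretch
    c_strand: Stretch
    metrics: CompositionMetrics
    failure_reasons: tuple = ()

    def __post_init__(self) -> None:
        if self.c_strand.start <= self.n_strand.end:
            raise ValueError("C-strand must start after the N-strand ends")
        unknown = set(self.failure_reasons) - set(FAILURE_CODES)
        if unknown:
            raise ValueError(f"unknown failure codes: {sorted(unknown)}")

    @property
    def turn_start(self) -> int:
        return self.n_strand.end + 1

    @property
    def turn_end(self) -> int:
        return self.c_strand.start - 1

    @property
    def turn_len(self) -> int:
        return self.c_strand.start - self.n_strand.end - 1

    @property
    def passed(self) -> bool:
        return not self.failure_reasons


def find_stretches(
    profile: PropensityProfile,
    config: FilterConfig = FilterConfig(),
    sequence: Union[str, None] = None,
) -> list[Stretch]:
    """Return the maximal runs of positions passing the threshold test.

    No length filtering is applied here. ``sequence`` supplies the residue
    letters for the ``subsequence`` field; when omitted, ``"X"`` is used
    (composition checks on such stretches are meaningless).
    """
    seq = sequence if sequence is not None else "X" * len(profile)
    if len(seq) != len(profile):
        raise AlignmentError(
            f"sequence length {len(seq)} != profile length {len(profile)} "
            f"for {profile.protein_id!r}"
        )
    stretches: list[Stretch] = []
    run_start = None
    scores = profile.scores
    for i, score in enumerate(scores):
        if config.passes_threshold(score):
            if run_start is None:
                run_start = i
        elif run_start is not None:
            stretches.append(_make_stretch(run_start, i - 1, seq, scores))
            run_start = None
    if run_start is not None:
        stretches.append(_make_stretch(run_start, len(scores) - 1, seq, scores))
    return stretches


def _make_stretch(i0: int, i1: int, seq: str, scores: Sequence[float]) -> Stretch:
    window = scores[i0 : i1 + 1]
    return Stretch(
        start=i0 + 1,
        end=i1 + 1,
        subsequence=seq[i0 : i1 + 1],
        mean_score=float(sum(window)) / len(window),
    )


def length_filter(
    stretches: Iterable[Stretch], config: FilterConfig = FilterConfig()
) -> list[Stretch]:
    """Keep stretches with length in [min_stretch_len, max_stretch_len]."""
    return [
        s
        for s in stretches
        if config.min_stretch_len <= s.length <= config.max_stretch_len
    ]


def enumerate_pairs(
    stretches: Sequence[Stretch],
    profile: PropensityProfile,
    config: FilterConfig = FilterConfig(),
) -> list[tuple]:
    """Pair consecutive stretches separated by a turn of 1..max_turn_len.

    ``stretches`` must be sorted by start and non-overlapping (as produced
    by :func:`find_stretches`, optionally length-filtered). Returns
    ``(n_strand, c_strand, turn_len)`` triples. With
    ``config.turn_requires_zero``, every turn-position score must equal
    zero for the pair to be emitted.
    """
    pairs = []
    for prev, nxt in zip(stretches, stretches[1:]):
        gap = nxt.start - prev.end - 1
        if gap < 1:
            raise ValueError("stretches overlap or abut; expected maximal runs")
        if gap > config.max_turn_len:
            continue
        if config.turn_requires_zero:
            turn_scores = profile.scores[prev.end : nxt.start - 1]
            if any(s != 0 for s in turn_scores):
                continue
        pairs.append((prev, nxt, gap))
    return pairs


def ilv_fraction(segment: str, config: FilterConfig = FilterConfig()) -> Fraction:
    """Exact fraction of Ile/Leu/Val residues in ``segment``."""
    if not segment:
        raise ValueError("empty segment")
    count = sum(1 for ch in segment if ch in config.ilv_set)
    return Fraction(count, len(segment))


def composition_check(
    n_strand: Stretch,
    c_strand: Stretch,
    config: FilterConfig = FilterConfig(),
) -> tuple[CompositionMetrics, list[str]]:
    """Apply criteria 4.1–5.2 to the two strand subsequences.

    Turn residues are excluded: metrics are computed on the strands only.
    Returns the metrics and the failure codes in fixed order.
    """
    n_seq, c_seq = n_strand.subsequence, c_strand.subsequence
    metrics = CompositionMetrics(
        n_aromatic=sum(1 for ch in n_seq if ch in config.aromatic_set),
        n_ilv_fraction=ilv_fraction(n_seq, config),
        c_gly=sum(1 for ch in c_seq if ch in config.gly_set),
        c_ilv_fraction=ilv_fraction(c_seq, config),
    )
    reasons = []
    if metrics.n_aromatic < config.n_aromatic_min:
        reasons.append("C4_1")
    if not (
        _as_fraction(config.n_ilv_lo)
        <= metrics.n_ilv_fraction
        <= _as_fraction(config.n_ilv_hi)
    ):
        reasons.append("C4_2")
    if not (config.c_gly_lo <= metrics.c_gly <= config.c_gly_hi):
        reasons.append("C5_1")
    if not (
        _as_fraction(config.c_ilv_lo)
        <= metrics.c_ilv_fraction
        <= _as_fraction(config.c_ilv_hi)
    ):
        reasons.append("C5_2")
    return metrics, reasons


def _length_reasons(n_strand: Stretch, c_strand: Stretch, config: FilterConfig) -> list[str]:
    reasons = []
    if not (config.min_stretch_len <= n_strand.length <= config.max_stretch_len):
        reasons.append("C2_N")
    if not (config.min_stretch_len <= c_strand.length <= config.max_stretch_len):
        reasons.append("C2_C")
    return reasons


def scan(
    record: ProteinRecord,
    profile: PropensityProfile,
    config: FilterConfig = FilterConfig(),
    include_failed: bool = False,
    apply_composition: bool = True,
) -> list[HairpinCandidate]:
    """Run the full filter cascade on one (sequence, profile) pair.

    By default only passing candidates are returned, ordered by N-strand
    start. With ``include_failed``, rejected strand pairs are returned as
    well, annotated with their failure codes: length violations of either
    strand (``C2_N``/``C2_C``, evaluated on pairs of consecutive maximal
    runs), over-long turns (``C3``, evaluated on pairs of consecutive
    length-filtered stretches), and composition violations
    (``C4_1``/``C4_2``/``C5_1``/``C5_2``).

    With ``apply_composition=False`` the cascade stops after the turn
    criterion: the relaxed screen counting all stretch/turn/stretch
    topologies regardless of composition.
    """
    profile.check_alignment(record)
    all_stretches = find_stretches(profile, config, sequence=record.sequence)
    kept = length_filter(all_stretches, config)

    candidates: list[HairpinCandidate] = []
    seen_pairs: set[tuple] = set()

    def emit(n_strand: Stretch, c_strand: Stretch, pre_reasons: list[str]) -> None:
        key = (n_strand.start, c_strand.start)
        if key in seen_pairs:
            return
        seen_pairs.add(key)
        metrics, comp_reasons = composition_check(n_strand, c_strand, config)
        reasons = list(pre_reasons)
        if apply_composition:
            reasons += comp_reasons
        reasons.sort(key=FAILURE_CODES.index)
        cand = HairpinCandidate(
            protein_id=record.id,
            n_strand=n_strand,
            c_strand=c_strand,
            metrics=metrics,
            failure_reasons=tuple(reasons),
        )
        if cand.passed or include_failed:
            candidates.append(cand)

    # Canonical pairing: consecutive length-filtered stretches; a stretch
    # discarded by the length filter does not block pairing of its
    # neighbours, but its residues count toward the positional gap.
    for n_strand, c_strand, gap in enumerate_pairs(kept, profile, config):
        emit(n_strand, c_strand, [])
    if include_failed:
        # Annotate near-misses for diagnostics: consecutive filtered pairs
        # with an over-long turn, and consecutive maximal-run pairs where a
        # strand fails the length bounds.
        for prev, nxt in zip(kept, kept[1:]):
            gap = nxt.start - prev.end - 1
            if gap > config.max_turn_len:
                emit(prev, nxt, ["C3"])
        for prev, nxt in zip(all_stretches, all_stretches[1:]):
            gap = nxt.start - prev.end - 1
            pre = _length_reasons(prev, nxt, config)
            if not pre:
                continue
            if gap > config.max_turn_len:
                pre.append("C3")
            emit(prev, nxt, pre)

    candidates.sort(key=lambda c: (c.n_strand.start, c.c_strand.start))
    return candidates
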