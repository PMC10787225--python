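"""Synthetic (sequence, profile) fixtures with planted β-hairpin motifs.

Generates proteins whose propensity profiles and strand compositions are
constructed to satisfy the filter criteria exactly — or to break exactly
one named criterion — together with a ground-truth table of the planted
coordinates. Also provides a surrogate propensity backend (a windowed
combination of β-sheet preference and hydropathy scales) so the whole
pipeline can run without the external predictor; surrogate output is
always tagged ``backend=surrogate`` and makes no attempt to reproduce the
external predictor's numerical scores.

All randomness flows from explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from math import ceil, floor
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .hairpin_filter import FilterConfig
from .sequence_io import PropensityProfile, ProteinRecord, write_propensity_table

__all__ = [
    "PlantSpec",
    "PlantedPair",
    "PlantedTruth",
    "VIOLATION_LABELS",
    "make_planted",
    "make_corpus",
    "surrogate_propensity",
]

VIOLATION_LABELS = (
    "none",
    "C1",
    "C2_N",
    "C2_C",
    "C3",
    "C4_1",
    "C4_2",
    "C5_1",
    "C5_2",
)

#: Disorder-promoting background residues; under the surrogate scales and
#: under planted (hand-assigned) profiles they never form a stretch.
FLANK_RESIDUES = "PGSEK"
#: Strand filler: neither aromatic, nor ILV, nor glycine, so planted
#: composition counts stay exact.
FILLER_RESIDUES = "ATNQSEKD"


class InfeasibleSpec(ValueError):
    """The requested strand lengths cannot satisfy the composition window."""


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic protein with a single planted strand pair.

    ``violation="none"`` plants a motif passing all criteria under the
    default :class:`FilterConfig`; any other label minimally breaks
    exactly that criterion while keeping the rest satisfied.
    """

    n_len: int = 7
    c_len: int = 7
    turn_len: int = 4
    flank_len: int = 10
    seed: int = 0
    violation: str = "none"
    protein_id: Union[str, None] = None

    def __post_init__(self) -> None:
        if self.violation not in VIOLATION_LABELS:
            raise ValueError(f"violation must be one of {VIOLATION_LABELS}")
        if not (5 <= self.n_len <= 23 and 5 <= self.c_len <= 23):
            raise ValueError("strand lengths must lie in [5, 23]")
        if not (1 <= self.turn_len <= 9):
            raise ValueError("turn_len must lie in [1, 9]")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth coordinates (1-based inclusive) of one planted pair."""

    n_start: int
    n_end: int
    turn_len: int
    c_start: int
    c_end: int
    violation: str


@dataclass(frozen=True)
class PlantedTruth:
    protein_id: str
    pairs: tuple = ()


def _ilv_window(length: int, lo: Fraction, hi: Fraction) -> tuple[int, int]:
    k_lo = ceil(lo * length)
    k_hi = floor(hi * length)
    return k_lo, k_hi


def _sample_strand(
    rng: np.random.Generator,
    length: int,
    role: str,
    violation: str,
    config: FilterConfig,
) -> str:
    """Draw a strand whose composition satisfies (or minimally breaks) the bounds."""
    ilv = sorted(config.ilv_set)
    aromatic = sorted(config.aromatic_set)
    if role == "N":
        k_lo, k_hi = _ilv_window(length, Fraction("0.32"), Fraction("0.50"))
        n_arom = 0 if violation == "C4_1" else 1
        if violation == "C4_2":
            n_ilv = k_hi + 1
        else:
            if k_lo > k_hi:
                raise InfeasibleSpec(f"empty N-strand ILV window for length {length}")
            n_ilv = int(rng.integers(k_lo, k_hi + 1))
        n_gly = 0
        specials = [str(rng.choice(aromatic)) for _ in range(n_arom)]
    else:
        k_lo, k_hi = _ilv_window(length, Fraction("0.32"), Fraction("0.61"))
        if violation == "C5_1":
            n_gly = 0
        elif violation == "C5_2":
            n_gly = 1
        else:
            gly_max = min(3, length - k_lo)
            if gly_max < 1:
                raise InfeasibleSpec(f"C-strand of length {length} cannot host any glycine")
            n_gly = int(rng.integers(1, gly_max + 1))
        if violation == "C5_2":
            n_ilv = k_hi + 1
        else:
            if k_lo > k_hi:
                raise InfeasibleSpec(f"empty C-strand ILV window for length {length}")
            n_ilv = int(rng.integers(k_lo, min(k_hi, length - n_gly) + 1))
        specials = ["G"] * n_gly
    if n_ilv + len(specials) > length:
        raise InfeasibleSpec(
            f"{role}-strand of length {length} cannot host {n_ilv} ILV residues "
            f"plus {len(specials)} marker residues"
        )
    residues = (
        specials
        + [str(rng.choice(ilv)) for _ in range(n_ilv)]
        + [str(rng.choice(list(FILLER_RESIDUES))) for _ in range(length - n_ilv - len(specials))]
    )
    rng.shuffle(residues)
    return "".join(residues)


def make_planted(
    spec: PlantSpec, config: FilterConfig = FilterConfig()
) -> tuple[ProteinRecord, PropensityProfile, PlantedTruth]:
    """Build one synthetic protein with a planted strand/turn/strand motif.

    Deterministic given ``spec.seed``. The propensity profile is assigned
    directly: strand positions get scores drawn uniformly in [2, 80], turn
    and flank positions get 0, so the planted strands are exactly the
    maximal stretches of the profile. For ``violation="C1"`` the N-strand
    scores are set to the threshold value itself, which fails the strict
    ``>`` comparison, leaving a single stretch and hence no pair.
    """
    rng = np.random.default_rng(spec.seed)
    n_len, c_len, turn_len = spec.n_len, spec.c_len, spec.turn_len
    if spec.violation == "C2_N":
        n_len = config.min_stretch_len - 1
    elif spec.violation == "C2_C":
        c_len = config.min_stretch_len - 1
    elif spec.violation == "C3":
        turn_len = config.max_turn_len + 1

    n_strand = _sample_strand(rng, n_len, "N", spec.violation, config)
    c_strand = _sample_strand(rng, c_len, "C", spec.violation, config)
    turn = "".join(str(rng.choice(list(FLANK_RESIDUES))) for _ in range(turn_len))
    left = "".join(str(rng.choice(list(FLANK_RESIDUES))) for _ in range(spec.flank_len))
    right = "".join(str(rng.choice(list(FLANK_RESIDUES))) for _ in range(spec.flank_len))
    sequence = left + n_strand + turn + c_strand + right

    n_start = len(left) + 1
    n_end = n_start + n_len - 1
    c_start = n_end + turn_len + 1
    c_end = c_start + c_len - 1

    scores = np.zeros(len(sequence))
    if spec.violation == "C1":
        scores[n_start - 1 : n_end] = config.propensity_threshold
    else:
        scores[n_start - 1 : n_end] = rng.uniform(2.0, 80.0, n_len)
    scores[c_start - 1 : c_end] = rng.uniform(2.0, 80.0, c_len)

    pid = spec.protein_id or f"PLANT_{spec.violation}_{spec.seed}"
    record = ProteinRecord(id=pid, sequence=sequence, description=f"planted {spec.violation}")
    profile = PropensityProfile(protein_id=pid, scores=tuple(scores))
    truth = PlantedTruth(
        protein_id=pid,
        pairs=(
            PlantedPair(
                n_start=n_start,
                n_end=n_end,
                turn_len=turn_len,
                c_start=c_start,
                c_end=c_end,
                violation=spec.violation,
            ),
        ),
    )
    return record, profile, truth


_DECOY_CYCLE = ("C1", "C2_N", "C2_C", "C3", "C4_1", "C4_2", "C5_1", "C5_2", "background")

TRUTH_COLUMNS = ("protein_id", "violation", "n_start", "n_end", "turn_len", "c_start", "c_end")


def make_corpus(
    n_records: int,
    hit_fraction: float,
    seed: int,
    out_dir: Union[str, Path],
    backend: str = "truth",
    config: FilterConfig = FilterConfig(),
) -> tuple[Path, Path, Path]:
    """Write a synthetic proteome: FASTA + per-sequence profiles + truth TSV.

    ``round(n_records * hit_fraction)`` records carry one planted passing
    motif; the remainder cycle through single-criterion decoys and
    motif-free background sequences. With ``backend="truth"`` profiles are
    the hand-assigned planted scores and screening the corpus recovers
    exactly the truth table's ``violation == "none"`` rows. With
    ``backend="surrogate"`` profiles are computed from the sequences by
    :func:`surrogate_propensity`; coordinates are then not guaranteed and
    the truth table is written for reference only.

    Returns ``(fasta_path, profiles_dir, truth_path)``.
    """
    if not (0 <= hit_fraction <= 1):
        raise ValueError("hit_fraction must lie in [0, 1]")
    if backend not in {"truth", "surrogate"}:
        raise ValueError("backend must be 'truth' or 'surrogate'")
    out_dir = Path(out_dir)
    profiles_dir = out_dir / "profiles"
    profiles_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "corpus.fasta"
    truth_path = out_dir / "truth.tsv"

    rng = np.random.default_rng(seed)
    n_hits = round(n_records * hit_fraction)
    hit_idx = set(rng.choice(n_records, size=n_hits, replace=False).tolist()) if n_hits else set()

    with open(fasta_path, "w") as fa, open(truth_path, "w") as tr:
        tr.write("\t".join(TRUTH_COLUMNS) + "\n")
        decoy_i = 0
        for i in range(n_records):
            pid = f"SYN{i:05d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if i in hit_idx:
                violation = "none"
            else:
                violation = _DECOY_CYCLE[decoy_i % len(_DECOY_CYCLE)]
                decoy_i += 1
            if violation == "background":
                sub_rng = np.random.default_rng(sub_seed)
                length = int(sub_rng.integers(30, 80))
                seq = "".join(
                    str(sub_rng.choice(list(FLANK_RESIDUES))) for _ in range(length)
                )
                record = ProteinRecord(id=pid, sequence=seq, description="background")
                profile = PropensityProfile(protein_id=pid, scores=(0.0,) * length)
                truth_rows = []
            else:
                spec = PlantSpec(
                    n_len=int(rng.integers(5, 13)),
                    c_len=int(rng.integers(5, 13)),
                    turn_len=int(rng.integers(1, 10)),
                    flank_len=int(rng.integers(6, 16)),
                    seed=sub_seed,
                    violation=violation,
                    protein_id=pid,
                )
                record, profile, truth = make_planted(spec, config)
                truth_rows = list(truth.pairs)
            if backend == "surrogate":
                profile = surrogate_propensity(record.sequence, protein_id=pid)
                tag = "surrogate"
            else:
                tag = "synthetic-truth"
            fa.write(f">{record.id} {record.description}\n{record.sequence}\n")
            write_propensity_table(profile, record, profiles_dir / f"{pid}.txt", backend=tag)
            for pair in truth_rows:
                tr.write(
                    "\t".join(
                        (
                            pid,
                            pair.violation,
                            str(pair.n_start),
                            str(pair.n_end),
                            str(pair.turn_len),
                            str(pair.c_start),
                            str(pair.c_end),
                        )
                    )
                    + "\n"
                )
    return fasta_path, profiles_dir, truth_path


@functools.cache
def _load_scales() -> dict:
    text = resources.files("hairpinscan.data").joinpath("residue_scales.yaml").read_text()
    return yaml.safe_load(text)


#: Default surrogate weights: score = clip(a*(P_beta - 1) + b*KD - c, 0, 100)
#: on centred window means. Chosen so that disorder-promoting residues
#: (G, P, S, E, K) score 0 while aliphatic/aromatic runs score well above
#: the 1.06 stretch threshold.
DEFAULT_SURROGATE_PARAMS = {"weight_beta": 30.0, "weight_hydro": 5.0, "offset": 10.0}


def surrogate_propensity(
    sequence: str,
    window: int = 5,
    params: Union[dict, None] = None,
    protein_id: str = "peptide",
) -> PropensityProfile:
    """Per-residue surrogate β-aggregation scores on a 0–100 scale.

    ``score_i = max(0, a*<P_beta>_w + b*<hydropathy>_w - c)`` with centred
    window means (truncated at the chain ends), clipped at 100. This is a
    deliberately simple stand-in for the external predictor, adequate for
    exercising the pipeline but not for reproducing its numbers.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    p = dict(DEFAULT_SURROGATE_PARAMS)
    if params:
        p.update(params)
    scales = _load_scales()
    beta = np.array([scales["beta_sheet"].get(ch, 0.5) for ch in sequence])
    hydro = np.array([scales["hydrophobicity"].get(ch, -3.0) for ch in sequence])

    # centred window mean, truncated at the chain ends
    half = window // 2
    n = len(sequence)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)

    def window_mean(values: np.ndarray) -> np.ndarray:
        csum = np.concatenate(([0.0], np.cumsum(values)))
        return (csum[hi] - csum[lo]) / (hi - lo)

    beta_w = window_mean(beta)
    hydro_w = window_mean(hydro)

    raw = (
        p["weight_beta"] * (beta_w - 1.0)
        + p["weight_hydro"] * hydro_w
        - p["offset"]
    )
    scores = np.clip(raw, 0.0, 100.0)
    return PropensityProfile(protein_id=protein_id, scores=tuple(scores))
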