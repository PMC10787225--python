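"""Brute-force reference enumerator for the hairpin criteria.

Deliberately independent of the package's scan implementation: positions
are classified one by one, runs are grouped with itertools, and every
pair of length-valid runs is tested literally against the written
criteria. Used as the oracle in equivalence tests.
"""

from fractions import Fraction
from itertools import groupby

import numpy as np

AROMATIC = set("FWY")
ILV = set("ILV")


def maximal_runs(scores, threshold=1.06, strict=True):
    """0-based [start, end] inclusive runs of positions above threshold."""
    flags = [(s > threshold if strict else s >= threshold) for s in scores]
    runs = []
    i = 0
    for val, group in groupby(flags):
        n = len(list(group))
        if val:
            runs.append((i, i + n - 1))
        i += n
    return runs


def brute_scan(
    sequence,
    scores,
    threshold=1.06,
    strict=True,
    min_len=5,
    max_len=23,
    max_turn=9,
    turn_requires_zero=False,
):
    """Return 1-based (n_start, n_end, c_start, c_end) of passing pairs."""
    runs = maximal_runs(scores, threshold, strict)
    valid = [(a, b) for a, b in runs if min_len <= b - a + 1 <= max_len]
    hits = []
    for i, (a1, b1) in enumerate(valid):
        for a2, b2 in valid[i + 1 :]:
            # only consecutive length-valid runs may pair
            if any(a1 < x < a2 for x, _ in valid):
                continue
            gap = a2 - b1 - 1
            if not (1 <= gap <= max_turn):
                continue
            if turn_requires_zero and any(s != 0 for s in scores[b1 + 1 : a2]):
                continue
            n_seq = sequence[a1 : b1 + 1]
            c_seq = sequence[a2 : b2 + 1]
            if sum(ch in AROMATIC for ch in n_seq) < 1:
                continue
            n_ilv = Fraction(sum(ch in ILV for ch in n_seq), len(n_seq))
            if not Fraction("0.32") <= n_ilv <= Fraction("0.5"):
                continue
            if not 1 <= c_seq.count("G") <= 3:
                continue
            c_ilv = Fraction(sum(ch in ILV for ch in c_seq), len(c_seq))
            if not Fraction("0.32") <= c_ilv <= Fraction("0.61"):
                continue
            hits.append((a1 + 1, b1 + 1, a2 + 1, b2 + 1))
    return hits


#: Alphabet biased toward aromatic/ILV/G so composition boundaries are hit.
_ALPHABET = list("ILVILVFWYGGASTNEKQD")
#: Score atoms including the exact threshold and near-threshold values.
_SCORE_ATOMS = (0.0, 0.0, 0.0, 1.06, 1.05, 1.07, 2.0, 50.0, 99.0)


def random_instance(rng, max_len=60):
    """One random (sequence, scores) pair stressing boundary behaviour."""
    n = int(rng.integers(1, max_len + 1))
    seq = "".join(rng.choice(_ALPHABET, size=n))
    kind = rng.random(n)
    scores = np.where(
        kind < 0.45,
        rng.choice(_SCORE_ATOMS, size=n),
        np.round(rng.uniform(0, 100, size=n), 2),
    )
    # bias toward long runs: occasionally smear a block above threshold
    if rng.random() < 0.5 and n >= 8:
        a = int(rng.integers(0, n - 6))
        b = int(rng.integers(a + 4, min(n, a + 26)))
        scores[a:b] = rng.uniform(1.2, 60, size=b - a)
    return seq, scores.tolist()
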