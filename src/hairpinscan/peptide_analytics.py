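"""Peptide descriptors for candidate hairpin segments.

Composition summaries (aromatic, glycine, ILV content) reuse the residue
sets of the filter; the isoelectric point is the unique root of the
Henderson-Hasselbalch net-charge function, found by bisection.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml

from .hairpin_filter import FilterConfig, ilv_fraction

__all__ = [
    "PeptideReport",
    "available_pka_sets",
    "get_pka_set",
    "net_charge",
    "isoelectric_point",
    "peptide_report",
]

_POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
_NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


@functools.cache
def _load_pka_sets() -> dict:
    text = resources.files("hairpinscan.data").joinpath("pka_sets.yaml").read_text()
    return yaml.safe_load(text)


def available_pka_sets() -> list[str]:
    return sorted(_load_pka_sets())


def get_pka_set(name: str = "emboss") -> dict:
    """Return a named pKa table (ionizable side chains plus both termini)."""
    sets = _load_pka_sets()
    if name not in sets:
        raise KeyError(f"unknown pKa set {name!r}; available: {sorted(sets)}")
    return dict(sets[name])


def _group_counts(sequence: str, termini_free: bool) -> dict:
    counts = {g: 0 for g in _POSITIVE_GROUPS + _NEGATIVE_GROUPS}
    if termini_free:
        counts["Nterm"] = 1
        counts["Cterm"] = 1
    for ch in sequence:
        if ch in counts:
            counts[ch] += 1
    return counts


def net_charge(
    sequence: str,
    ph: float,
    pka_set: dict | str = "emboss",
    termini_free: bool = True,
) -> float:
    """Net charge (elementary charges) at a given pH.

    Each basic group contributes ``+1/(1+10^(pH-pKa))``, each acidic group
    ``-1/(1+10^(pKa-pH))``. Nonstandard residues contribute zero charge.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = get_pka_set(pka_set) if isinstance(pka_set, str) else pka_set
    counts = _group_counts(sequence, termini_free)
    charge = 0.0
    for g in _POSITIVE_GROUPS:
        if counts[g]:
            charge += counts[g] / (1.0 + 10.0 ** (ph - pka[g]))
    for g in _NEGATIVE_GROUPS:
        if counts[g]:
            charge -= counts[g] / (1.0 + 10.0 ** (pka[g] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_set: dict | str = "emboss",
    termini_free: bool = True,
    tol: float = 1e-6,
) -> float:
    """pH at which the peptide's net charge vanishes.

    The charge function is strictly decreasing in pH, so bisection on
    [0, 14] converges to the unique root; iteration stops when
    ``|charge| < tol``. A sequence with no ionizable groups (possible only
    with suppressed termini) has no root and raises ``ValueError``.
    """
    pka = get_pka_set(pka_set) if isinstance(pka_set, str) else pka_set
    counts = _group_counts(sequence, termini_free)
    if not any(counts.values()):
        raise ValueError("sequence has no ionizable groups; pI undefined")
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo, pka, termini_free) < 0 or net_charge(
        sequence, hi, pka, termini_free
    ) > 0:
        raise ValueError("net charge does not change sign on [0, 14]; pI undefined")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka, termini_free)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PeptideReport:
    """Computable descriptors of one peptide."""

    sequence: str
    length: int
    pI: float
    aromatic_count: int
    gly_count: int
    ilv_fraction: float
    net_charge_at_pH7: float


def peptide_report(
    sequence: str,
    config: FilterConfig = FilterConfig(),
    pka_set: dict | str = "emboss",
    termini_free: bool = True,
) -> PeptideReport:
    """Aggregate composition, pI and net charge for one peptide sequence."""
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    return PeptideReport(
        sequence=sequence,
        length=len(sequence),
        pI=isoelectric_point(sequence, pka_set, termini_free),
        aromatic_count=sum(1 for ch in sequence if ch in config.aromatic_set),
        gly_count=sum(1 for ch in sequence if ch in config.gly_set),
        ilv_fraction=float(ilv_fraction(sequence, config)),
        net_charge_at_pH7=net_charge(sequence, 7.0, pka_set, termini_free),
    )
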