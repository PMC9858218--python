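"""Physicochemical characterization of protein sequences.

Molecular weight is the sum of average (isotope-abundance-weighted) residue
masses plus one water; the theoretical isoelectric point is the pH at which
the Henderson-Hasselbalch net charge of the ionizable groups is zero, found
by bisection (the net charge is strictly decreasing in pH, so the root is
unique).

The pKa set defaults to the EMBOSS values.  Different programs ship
different pKa tables, so computed pI values agree with other tools only to
a few tenths of a pH unit; the molecular-weight table is essentially
universal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

# Average residue (amino acid minus water) masses, daltons.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
# Unknown residue (X) contributes the mean residue mass and no charge.
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# EMBOSS pKa set. Positive groups: N-terminus, H, K, R; negative: C-terminus,
# D, E, C, Y.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass
class PhyschemStats:
    """Sequence length, molecular weight (kDa) and theoretical pI."""

    aa: int
    mw_kda: float
    pi: float


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(RESIDUE_MASS) - {"X"}
    if bad:
        raise ValueError(f"illegal residue characters: {sorted(bad)}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight of a protein in daltons."""
    _check_sequence(seq)
    return sum(RESIDUE_MASS.get(c, MEAN_RESIDUE_MASS) for c in seq) + WATER_MASS


def net_charge(seq: str, ph: float,
               pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of the sequence at a given pH."""
    _check_sequence(seq)
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE:
        charge += counts[group] / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE:
        charge -= counts[group] / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(seq: str, pka: Mapping[str, float] = EMBOSS_PKA,
                      tol: float = 1e-3) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    _check_sequence(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def characterize(seq: str) -> PhyschemStats:
    """Length, MW (kDa) and pI for one sequence."""
    return PhyschemStats(
        aa=len(seq),
        mw_kda=molecular_weight(seq) / 1000.0,
        pi=isoelectric_point(seq),
    )
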