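"""Peptide physicochemical properties: average mass and isoelectric point.

The mass of a peptide is the sum of standard average residue masses plus
one water (18.015 Da).  The isoelectric point is found by bisection on the
Henderson-Hasselbalch net-charge function over the ionizable groups
(Asp, Glu, Cys, Tyr, His, Lys, Arg and the two termini) using the
Bjellqvist pKa set; because the charge model depends only on composition,
the pI is invariant under any permutation of the sequence.

Convenience constructors build the arginine-rich dipeptide-repeat
constructs studied in the C9ORF72 context, e.g. (PR)20 or (GR)20 with a
C-terminal influenza HA epitope tag (YPYDVPDYA).
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "HA_TAG",
    "average_mass",
    "net_charge",
    "isoelectric_point",
    "dipeptide_repeat",
    "PeptideRecord",
]

# Standard average residue masses (Da), i.e. amino acid minus water.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

HA_TAG = "YPYDVPDYA"  # influenza hemagglutinin epitope

# Bjellqvist pKa set.  Side chains; C-terminal carboxyl (with residue-specific
# variants); N-terminal amine (residue-specific variants, 7.5 otherwise).
PKA_SETS = {
    "bjellqvist": {
        "side": {"D": 4.05, "E": 4.45, "H": 5.98, "C": 9.0,
                 "Y": 10.0, "K": 10.0, "R": 12.0},
        "cterm_default": 3.55,
        "cterm": {"D": 4.55, "E": 4.75},
        "nterm_default": 7.5,
        "nterm": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                  "T": 6.82, "V": 7.44, "E": 7.7, "G": 7.5},
    },
}

_POSITIVE = frozenset("HKR")
_NEGATIVE = frozenset("DECY")


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("sequence must be nonempty")
    sequence = sequence.upper()
    bad = set(sequence) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    return sequence


def dipeptide_repeat(unit: str, n: int, tag: str = HA_TAG) -> str:
    """Build an n-fold dipeptide repeat with an optional C-terminal tag."""
    if len(unit) != 2:
        raise ValueError("unit must be two residues, e.g. 'PR'")
    return _validate(unit * n + tag)


def average_mass(sequence: str) -> float:
    """Average molecular mass in daltons (residues + one water)."""
    sequence = _validate(sequence)
    return sum(AVERAGE_RESIDUE_MASS[c] for c in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Net charge at a given pH under the Henderson-Hasselbalch model.

    Strictly decreasing in pH for every sequence, so it has a unique root.
    """
    sequence = _validate(sequence)
    pka = PKA_SETS[pka_set]

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka["nterm"].get(sequence[0], pka["nterm_default"]))
    charge -= neg(pka["cterm"].get(sequence[-1], pka["cterm_default"]))
    for c in sequence:
        if c in _POSITIVE:
            charge += pos(pka["side"][c])
        elif c in _NEGATIVE:
            charge -= neg(pka["side"][c])
    return charge


def isoelectric_point(
    sequence: str, pka_set: str = "bjellqvist", tol: float = 1e-3
) -> float:
    """pH of zero net charge, by bisection on [0, 14] to ``tol``."""
    sequence = _validate(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@dataclass(frozen=True)
class PeptideRecord:
    """Sequence with its computed average mass and isoelectric point."""

    sequence: str
    avg_mass_da: float
    pI: float

    def __post_init__(self) -> None:
        _validate(self.sequence)
        if self.avg_mass_da <= 0:
            raise ValueError("mass must be positive")
        if not 0 < self.pI < 14:
            raise ValueError("pI must lie in (0, 14)")

    @classmethod
    def from_sequence(cls, sequence: str, pka_set: str = "bjellqvist") -> "PeptideRecord":
        sequence = _validate(sequence)
        return cls(
            sequence=sequence,
            avg_mass_da=average_mass(sequence),
            pI=isoelectric_point(sequence, pka_set=pka_set),
        )

    @property
    def avg_mass_kda_truncated(self) -> float:
        """Mass in kDa truncated (not rounded) to one decimal."""
        import math

        return math.floor(self.avg_mass_da / 100.0) / 10.0
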