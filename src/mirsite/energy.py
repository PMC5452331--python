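"""Hybridization free-energy model for a miRNA:site duplex.

The duplex is scored by counting hydrogen bonds over the antiparallel
pairing (miRNA position i against site position L-i+1): a G:C pair
contributes 3 bonds, A:U 2, the G:U wobble a configurable weight
(default 1), the noncanonical A:C pair a configurable weight (default 0),
and anything else 0. The free energy is dG = -e_bond * bonds, with e_bond
a positive per-bond constant in kJ/mole. The site-acceptance statistic is
the percentage ratio dG/dGm, where dGm is the energy of the miRNA bound to
its perfect complement; the ratio cancels e_bond, so the 100% complete-
complementarity criterion is independent of the energy scale.

The default e_bond = 121/57 kJ/mole is calibrated so the perfect duplex of
the 22-nt query miR-619-5p (13 G:C + 9 A:U pairs = 57 bonds) scores
-121 kJ/mole.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .seqcore import MatureMiRNA, normalize, reverse_complement

PAIR_GC = "GC"
PAIR_AU = "AU"
PAIR_GU = "GU"
PAIR_AC = "AC"
MISMATCH = "MISMATCH"

_PAIR_CLASSES = {
    frozenset("GC"): PAIR_GC,
    frozenset("AU"): PAIR_AU,
    frozenset("GU"): PAIR_GU,
    frozenset("AC"): PAIR_AC,
}

#: Bonds of the perfect miR-619-5p duplex under the default scheme.
PERFECT_MIR619_BONDS = 57
#: Printed hybridization energy of that duplex, kJ/mole.
MIR619_DELTA_G = -121.0


def classify_pair(mirna_base: str, site_base: str) -> str:
    """Classify one antiparallel base pair; symmetric; N always mismatches."""
    return _PAIR_CLASSES.get(frozenset((mirna_base, site_base)), MISMATCH)


@dataclasses.dataclass(frozen=True)
class EnergyScheme:
    """Per-pair hydrogen-bond counts plus the per-bond energy constant."""

    gc: int = 3
    au: int = 2
    gu: int = 1
    ac: int = 0
    e_bond: float = 121.0 / PERFECT_MIR619_BONDS

    def __post_init__(self) -> None:
        for name in ("gc", "au", "gu", "ac"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"bond count {name} must be a non-negative integer, got {v!r}")
        if self.gu > 2:
            raise ValueError("G:U wobble cannot outscore a Watson-Crick A:U pair (gu <= 2)")
        if self.e_bond <= 0:
            raise ValueError("e_bond must be positive")

    def bonds(self, mirna_base: str, site_base: str) -> int:
        pair = classify_pair(mirna_base, site_base)
        if pair == PAIR_GC:
            return self.gc
        if pair == PAIR_AU:
            return self.au
        if pair == PAIR_GU:
            return self.gu
        if pair == PAIR_AC:
            return self.ac
        return 0

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyScheme":
        known = {k: d[k] for k in ("gc", "au", "gu", "ac", "e_bond") if k in d}
        unknown = set(d) - {"gc", "au", "gu", "ac", "e_bond"}
        if unknown:
            raise ValueError(f"unknown energy-scheme keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


DEFAULT_SCHEME = EnergyScheme()


@dataclasses.dataclass(frozen=True)
class DuplexScore:
    """Energetics of one miRNA:site pairing.

    dg and dg_max are non-positive energies in kJ/mole; ratio is the
    percentage 100*dg/dg_max in [0, 100], equal to 100 exactly when the
    site is the complete complement (given gu < au and ac < gc defaults).
    """

    bonds: int
    max_bonds: int
    dg: float
    dg_max: float
    ratio: float


def hydrogen_bonds(mirna: MatureMiRNA, site: str, scheme: EnergyScheme = DEFAULT_SCHEME) -> int:
    """Total hydrogen bonds of the antiparallel duplex (site given 5'->3')."""
    site = normalize(site, "rna")
    if len(site) != mirna.length:
        raise ValueError(f"site length {len(site)} != miRNA length {mirna.length}")
    m = mirna.sequence
    L = mirna.length
    return sum(scheme.bonds(m[i], site[L - 1 - i]) for i in range(L))


def max_hydrogen_bonds(mirna: MatureMiRNA, scheme: EnergyScheme = DEFAULT_SCHEME) -> int:
    """Bonds of the miRNA against its perfect complementary site."""
    return hydrogen_bonds(mirna, reverse_complement(mirna.sequence), scheme)


def delta_g(mirna: MatureMiRNA, site: str, scheme: EnergyScheme = DEFAULT_SCHEME) -> DuplexScore:
    """Score one site: dG, dGm against the perfect complement, and their ratio."""
    bonds = hydrogen_bonds(mirna, site, scheme)
    max_bonds = max_hydrogen_bonds(mirna, scheme)
    dg = -scheme.e_bond * bonds
    dg_max = -scheme.e_bond * max_bonds
    return DuplexScore(
        bonds=bonds,
        max_bonds=max_bonds,
        dg=dg,
        dg_max=dg_max,
        ratio=100.0 * bonds / max_bonds,
    )


# index map shared with the scanner's vectorized window scoring
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


_ENCODE_LUT = np.full(128, 4, dtype=np.uint8)
for _c, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a normalized RNA string as uint8 indices (A,C,G,U,N -> 0..4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def bond_profile(mirna: MatureMiRNA, scheme: EnergyScheme = DEFAULT_SCHEME) -> np.ndarray:
    """(L, 5) matrix: bonds contributed by site base b at site position j.

    Site position j (0-based, 5'->3' on the mRNA) pairs miRNA position
    L-1-j, so row j is the scheme's bond count of that miRNA base against
    each of A, C, G, U, N.
    """
    letters = "ACGUN"
    L = mirna.length
    prof = np.zeros((L, 5), dtype=np.int64)
    for j in range(L):
        mb = mirna.sequence[L - 1 - j]
        for k, sb in enumerate(letters):
            prof[j, k] = scheme.bonds(mb, sb)
    return prof
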