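"""Monoisotopic mass bookkeeping for peptides, modifications and fragment ions.

All masses are monoisotopic daltons. Residue masses are the standard
monoisotopic residue (amino-acid minus water) masses; a peptide's neutral
mass is the sum of its residue masses plus one water plus any modification
delta masses. Branched isopeptide remnants (e.g. the diglycyl stub left on a
modified lysine) are ordinary delta-mass modifications here: the remnant's
residue chain contributes its residue masses only, because the isopeptide
bond condenses out one water exactly like a backbone peptide bond.

Fragment ion conventions (singly protonated, charge ``z`` handled by
``(M + z*proton) / z``):

* ``b``  = prefix residue masses + proton
* ``y``  = suffix residue masses + water + proton
* ``c``  = b + NH3
* ``z``  = y - NH3 + H  (the ETD z-dot radical ion)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "WATER",
    "PROTON",
    "ResidueMassTable",
    "Modification",
    "Peptide",
    "ModificationRegistry",
    "default_registry",
    "mod_mass",
    "peptide_mass",
    "fragment_ions",
]

WATER: float = _pmass.calculate_mass(formula="H2O")      # 18.0105646...
PROTON: float = _pmass.calculate_mass(formula="H+")      # 1.0072764...
_NH3: float = _pmass.calculate_mass(formula="NH3")
_H: float = _pmass.calculate_mass(formula="H")

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ResidueMassTable:
    """Monoisotopic residue masses for the 20 standard amino acids."""

    def __init__(self, masses: Mapping[str, float] | None = None):
        if masses is None:
            masses = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}
        missing = STANDARD_RESIDUES - set(masses)
        if missing:
            raise ValueError(f"residue mass table missing {sorted(missing)}")
        if any(m <= 0 for m in masses.values()):
            raise ValueError("residue masses must be positive")
        self._masses = dict(masses)
        self.water = WATER
        self.proton = PROTON

    def __getitem__(self, residue: str) -> float:
        try:
            return self._masses[residue]
        except KeyError:
            raise KeyError(f"non-standard residue {residue!r}") from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._masses

    def chain_mass(self, sequence: str) -> float:
        """Sum of residue masses (no water) for a residue string."""
        return sum(self[r] for r in sequence)


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A named delta-mass modification with residue and position constraints.

    ``position`` is one of ``"anywhere"``, ``"nterm"``, ``"cterm"``.
    """

    name: str
    delta_mass: float
    targets: frozenset = frozenset()
    position: str = "anywhere"

    def __post_init__(self):
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) != float("inf")):
            raise ValueError("delta mass must be finite")
        if self.position not in ("anywhere", "nterm", "cterm"):
            raise ValueError(f"bad positional constraint {self.position!r}")
        object.__setattr__(self, "targets", frozenset(self.targets))


class ModificationRegistry:
    """Registry of named modifications; names are unique."""

    def __init__(self):
        self._mods: dict[str, Modification] = {}

    def register(self, mod: Modification) -> Modification:
        if mod.name in self._mods:
            raise ValueError(f"modification {mod.name!r} already registered")
        self._mods[mod.name] = mod
        return mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def names(self) -> list[str]:
        return sorted(self._mods)


def _build_default_registry() -> ModificationRegistry:
    reg = ModificationRegistry()
    # Diglycyl remnant on lysine: two glycine residues on the epsilon-amine.
    reg.register(Modification("GlyGly", 2 * _pmass.std_aa_mass["G"], frozenset("K")))
    # SILAC heavy lysine, 13C6 15N2.
    heavy = 6 * (_pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]) + 2 * (
        _pmass.nist_mass["N"][15][0] - _pmass.nist_mass["N"][14][0]
    )
    reg.register(Modification("HeavyK(13C6 15N2)", heavy, frozenset("K")))
    reg.register(
        Modification("Carbamidomethyl", _pmass.calculate_mass(formula="C2H3NO"), frozenset("C"))
    )
    reg.register(Modification("Oxidation", _pmass.calculate_mass(formula="O"), frozenset("M")))
    return reg


default_registry = _build_default_registry()


def mod_mass(name: str, registry: ModificationRegistry = default_registry) -> float:
    """Monoisotopic delta mass of a registered modification."""
    return registry[name].delta_mass


@dataclass(frozen=True)
class Peptide:
    """A peptide with 1-based positioned modifications and optional charge."""

    sequence: str
    modifications: tuple = ()
    charge: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)} in {self.sequence!r}")
        mods = tuple(self.modifications)
        for pos, mod in mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside [1, {len(self.sequence)}]"
                )
            if mod.targets and self.sequence[pos - 1] not in mod.targets:
                raise ValueError(
                    f"{mod.name} does not target residue "
                    f"{self.sequence[pos - 1]!r} at position {pos}"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1")
        object.__setattr__(self, "modifications", mods)

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_mass_at(self, pos: int) -> float:
        """Total modification delta mass sitting on 1-based position ``pos``."""
        return sum(m.delta_mass for p, m in self.modifications if p == pos)


def peptide_mass(p: Peptide, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    return table.chain_mass(p.sequence) + table.water + sum(
        m.delta_mass for _, m in p.modifications
    )


def precursor_mz(p: Peptide, charge: int | None = None,
                 table: ResidueMassTable = DEFAULT_TABLE) -> float:
    z = charge if charge is not None else (p.charge or 1)
    return (peptide_mass(p, table) + z * table.proton) / z


_SERIES = frozenset("bycz")


def fragment_ions(
    p: Peptide,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[str, float]]:
    """All prefix/suffix fragment ions for the requested series.

    Returns ``(label, m/z)`` pairs, e.g. ``("b3+2", 217.1)``. Modification
    masses are carried by whichever fragment contains the modified residue.
    """
    if len(p) < 2:
        raise ValueError("fragmentation requires peptide length >= 2")
    series = list(series)
    unknown = set(series) - _SERIES
    if unknown:
        raise ValueError(f"unknown ion series {sorted(unknown)}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    n = len(p)
    # Neutral prefix chain masses including modifications.
    prefix = [0.0]
    for i in range(1, n + 1):
        prefix.append(prefix[-1] + table[p.sequence[i - 1]] + p.mod_mass_at(i))
    total = prefix[n]

    out: list[tuple[str, float]] = []
    for i in range(1, n):  # fragment length along the prefix
        neutral_b = prefix[i]
        neutral_y = total - prefix[n - i] + table.water
        neutrals = {"b": neutral_b, "c": neutral_b + _NH3,
                    "y": neutral_y, "z": neutral_y - _NH3 + _H}
        for s in series:
            m0 = neutrals[s]
            for z in range(1, max_charge + 1):
                label = f"{s}{i}" if z == 1 else f"{s}{i}+{z}"
                out.append((label, (m0 + z * table.proton) / z))
    return out
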