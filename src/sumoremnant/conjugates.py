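"""Ubiquitin-like modifier attachment and remnant prediction.

A ubiquitin-like modifier (SUMO, ubiquitin, NEDD8, ...) conjugates to a
substrate lysine through an isopeptide bond between the modifier's
C-terminal glycine carboxyl and the lysine epsilon-amine. Proteolysis of the
conjugate digests the modifier like any other protein; whatever suffix of
the modifier lies downstream of the modifier's C-terminal-most cleavage site
stays attached to the substrate lysine. For ubiquitin under trypsin that
suffix is the classic diglycine (KGG remnant, +114.0429 Da); for SUMO
paralogs trypsin leaves a long, antibody-invisible tail, but a protease
that cuts after the threonine of the C-terminal ...TGG (WaLP) leaves the
same diglycine stub — which is what makes one KGG enrichment workflow serve
both modifier families.

Because different modifiers can leave identical remnants, a remnant-based
experiment cannot always tell them apart: ubiquitin and NEDD8 both end
...LRGG (indistinguishable under trypsin), and any modifier ending ...TGG /
...LGG collapses to "GG" under WaLP. ``distinguishability`` computes exactly
these equivalence classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .chem import (
    DEFAULT_TABLE,
    Modification,
    Peptide,
    ResidueMassTable,
    STANDARD_RESIDUES,
)
from .digestion import DigestParams, DigestPeptide, ProteaseSpec, cleavage_sites, digest

__all__ = [
    "ModifierProtein",
    "ConjugateTopology",
    "RemnantPeptide",
    "builtin_modifiers",
    "remnant",
    "remnant_modification",
    "remnant_peptides",
    "distinguishability",
    "remnant_report",
]


@dataclass(frozen=True)
class ModifierProtein:
    """A mature ubiquitin-like modifier ending in the attachment diglycine."""

    name: str
    sequence: str
    strict: bool = True  # require the canonical ...GG C-terminus

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("modifier sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)}")
        if not self.sequence.endswith("GG"):
            msg = f"modifier {self.name!r} does not end in the attachment 'GG'"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ConjugateTopology:
    """Attachment map of modifiers onto a substrate, with optional chains.

    ``attachments`` lists (substrate 1-based K position, modifier);
    ``chain_links`` lists (carrier index into an implicit modifier list,
    carrier K position, modifier) for modifier-on-modifier attachments.
    Positions must be lysines and distinct per carrier; the attachment graph
    is acyclic by construction (links only point from later modifiers onto
    earlier carriers is not required — we check acyclicity explicitly).
    """

    substrate_id: str
    substrate_sequence: str
    attachments: tuple = ()
    chain_links: tuple = ()

    def __post_init__(self):
        atts = tuple(self.attachments)
        seen = set()
        for pos, mod in atts:
            if not 1 <= pos <= len(self.substrate_sequence):
                raise ValueError(f"attachment position {pos} out of range")
            if self.substrate_sequence[pos - 1] != "K":
                raise ValueError(f"attachment position {pos} is not a lysine")
            if pos in seen:
                raise ValueError(f"duplicate attachment at position {pos}")
            seen.add(pos)
        links = tuple(self.chain_links)
        per_carrier: dict[int, set[int]] = {}
        for carrier, pos, mod in links:
            if not 0 <= carrier < len(atts) + len(links):
                raise ValueError(f"chain link carrier index {carrier} out of range")
            if pos in per_carrier.setdefault(carrier, set()):
                raise ValueError(f"duplicate chain link at carrier {carrier} pos {pos}")
            per_carrier[carrier].add(pos)
        # Acyclicity: a link's carrier must be an earlier-listed modifier.
        for k, (carrier, pos, mod) in enumerate(links):
            if carrier >= len(atts) + k:
                raise ValueError("chain links must attach to already-placed modifiers")
        object.__setattr__(self, "attachments", atts)
        object.__setattr__(self, "chain_links", links)


@dataclass(frozen=True)
class RemnantPeptide:
    """A substrate peptide carrying a modifier remnant on one of its lysines."""

    peptide: Peptide
    modified_position: int  # 1-based within the peptide
    remnant_sequence: str
    remnant_mass: float
    span: tuple = ()  # (start, end) in the parent protein, when known

    def __post_init__(self):
        if self.peptide.sequence[self.modified_position - 1] != "K":
            raise ValueError("remnant must sit on a lysine")
        expected = DEFAULT_TABLE.chain_mass(self.remnant_sequence)
        if abs(expected - self.remnant_mass) > 1e-4:
            raise ValueError(
                f"remnant mass {self.remnant_mass} inconsistent with sequence "
                f"{self.remnant_sequence!r} ({expected})"
            )


def builtin_modifiers() -> dict[str, ModifierProtein]:
    """The packaged mature-modifier snapshot (SUMO1-4, Ub, Nedd8).

    Fat10 and Fub1 are not shipped; supply them as custom modifiers from a
    FASTA of mature sequences if needed.
    """
    from Bio import SeqIO

    path = resources.files("sumoremnant.data") / "modifiers.fasta"
    mods = {}
    with resources.as_file(path) as p:
        for rec in SeqIO.parse(str(p), "fasta"):
            mods[rec.id] = ModifierProtein(rec.id, str(rec.seq).upper())
    return mods


def remnant(
    modifier: ModifierProtein,
    spec: ProteaseSpec,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> tuple[str, float]:
    """Remnant left on the substrate lysine after digesting the conjugate.

    The remnant is the modifier suffix downstream of its C-terminal-most
    cleavage site; if the modifier has no cleavage site at all the whole
    modifier stays attached. The returned mass is the residue-chain mass
    (the isopeptide bond condenses one water, like a backbone bond).
    """
    sites = [s for s in cleavage_sites(modifier.sequence, spec) if s < len(modifier)]
    start = sites[-1] if sites else 0
    seq = modifier.sequence[start:]
    return seq, table.chain_mass(seq)


def remnant_modification(
    modifier: ModifierProtein, spec: ProteaseSpec
) -> Modification:
    """The remnant as a lysine-targeted delta-mass modification."""
    seq, m = remnant(modifier, spec)
    return Modification(f"remnant:{modifier.name}:{seq}", m, frozenset("K"))


def remnant_peptides(
    substrate: str,
    site: int,
    modifier: ModifierProtein,
    spec: ProteaseSpec,
    params: DigestParams = DigestParams(),
) -> list[RemnantPeptide]:
    """Digest a substrate with the modified site cleavage-blocked and attach
    the predicted remnant to the site within every covering peptide."""
    if not 1 <= site <= len(substrate):
        raise ValueError(f"site {site} out of range")
    if substrate[site - 1] != "K":
        raise ValueError(f"residue at site {site} is not a lysine")
    rem_seq, rem_mass = remnant(modifier, spec)
    mod = Modification(f"remnant:{modifier.name}:{rem_seq}", rem_mass, frozenset("K"))
    out = []
    for pep in digest(substrate, spec, params, blocked_positions={site}):
        if pep.start <= site <= pep.end:
            local = site - pep.start + 1
            out.append(
                RemnantPeptide(
                    Peptide(pep.sequence, ((local, mod),)),
                    local,
                    rem_seq,
                    rem_mass,
                    span=(pep.start, pep.end),
                )
            )
    return out


def topology_remnant_peptides(
    topology: ConjugateTopology,
    spec: ProteaseSpec,
    params: DigestParams = DigestParams(),
) -> list[RemnantPeptide]:
    """Remnant peptides from a whole conjugate, chains included.

    Each modifier in a chain is digested independently: substrate
    attachments yield remnant peptides on the substrate, and every chain
    link yields remnant peptides on its carrier modifier — which is how a
    poly-SUMO chain shows up as SUMO-derived peptides that themselves carry
    a remnant.
    """
    out = []
    carriers: list[tuple[str, ModifierProtein | None]] = []
    for pos, mod in topology.attachments:
        out.extend(remnant_peptides(topology.substrate_sequence, pos, mod, spec, params))
        carriers.append((mod.sequence, mod))
    for carrier_idx, pos, mod in topology.chain_links:
        carrier_seq, _ = carriers[carrier_idx]
        out.extend(remnant_peptides(carrier_seq, pos, mod, spec, params))
        carriers.append((mod.sequence, mod))
    return out


def distinguishability(
    modifiers: Sequence[ModifierProtein],
    spec: ProteaseSpec,
    by: str = "sequence",
) -> list[list[ModifierProtein]]:
    """Partition modifiers into groups leaving identical remnants.

    ``by="sequence"`` compares remnant residue strings exactly (keeps the
    Leu/Ile isobars apart); ``by="mass"`` groups within 1e-4 Da for an
    MS-realistic view.
    """
    if not modifiers:
        raise ValueError("need at least one modifier")
    if by not in ("sequence", "mass"):
        raise ValueError("by must be 'sequence' or 'mass'")
    groups: list[tuple[object, list[ModifierProtein]]] = []
    for m in modifiers:
        seq, mass = remnant(m, spec)
        key = seq if by == "sequence" else mass
        for gkey, members in groups:
            same = key == gkey if by == "sequence" else abs(key - gkey) <= 1e-4
            if same:
                members.append(m)
                break
        else:
            groups.append((key, [m]))
    return [members for _, members in groups]


def remnant_report(
    modifiers: Sequence[ModifierProtein], specs: Sequence[ProteaseSpec]
):
    """Tabulate remnant sequence and mass per (modifier, protease)."""
    import pandas as pd

    rows = []
    for spec in specs:
        for m in modifiers:
            seq, mass = remnant(m, spec)
            rows.append(
                {
                    "modifier": m.name,
                    "protease": spec.name,
                    "remnant_sequence": seq,
                    "remnant_mass": round(mass, 5),
                }
            )
    return pd.DataFrame(rows)
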