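"""In-silico proteolysis under configurable cleavage-specificity rules.

Coordinates are 1-based throughout; a peptide span ``(start, end)`` is
inclusive, and cleavage "after position i" cuts between residues i and i+1.

Built-in specificities:

* ``trypsin`` — cleaves after K/R, suppressed before P, and a modified K in
  the cleave-after set does not cleave (an isopeptide-linked lysine is not a
  tryptic substrate). That blocking rule is what makes "which tryptic peptide
  would have covered this modified site" a well-posed question.
* ``walp`` — wild-type alpha-lytic protease. The enzyme prefers threonine in
  P1 and also cuts after A/S/V and L (with some I); it rarely cuts after
  arginine, so R is excluded. The set is user-configurable because the full
  preference distribution of the enzyme is broader than any hard rule.
* ``nonspecific`` — permissive spec (cleaves after every residue), used to
  emulate "no enzyme specificity" searches without enumerating substrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .chem import STANDARD_RESIDUES

__all__ = [
    "ProteaseSpec",
    "DigestParams",
    "TRYPSIN",
    "WALP",
    "NONSPECIFIC",
    "get_protease",
    "load_protease_spec",
    "cleavage_sites",
    "digest",
    "peptide_covering_site",
    "excise_nterm_met",
]


@dataclass(frozen=True)
class ProteaseSpec:
    """A named cleavage rule: cut after ``cleave_after`` unless suppressed.

    ``not_before`` suppresses cleavage when the *next* residue is in the set
    (the classic "K/R but not before P" rule). ``blocked_by_modification``
    means a modified residue in the cleave-after set does not cleave.
    """

    name: str
    cleave_after: frozenset
    not_before: frozenset = frozenset()
    blocked_by_modification: bool = True

    def __post_init__(self):
        ca = frozenset(self.cleave_after)
        nb = frozenset(self.not_before)
        if not ca:
            raise ValueError("cleave-after set must be non-empty")
        bad = (ca | nb) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"invalid residue code(s) {sorted(bad)}")
        object.__setattr__(self, "cleave_after", ca)
        object.__setattr__(self, "not_before", nb)


@dataclass(frozen=True)
class DigestParams:
    """Missed-cleavage allowance, length bounds and terminal specificity."""

    max_missed_cleavages: int = 0
    min_length: int = 1
    max_length: int = 10**9
    specificity: str = "full"  # full | semi

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.specificity not in ("full", "semi"):
            raise ValueError("specificity must be 'full' or 'semi'")


TRYPSIN = ProteaseSpec("trypsin", frozenset("KR"), frozenset("P"))
WALP = ProteaseSpec("walp", frozenset("ASTVLI"))
NONSPECIFIC = ProteaseSpec("nonspecific", STANDARD_RESIDUES,
                           blocked_by_modification=False)

_BUILTIN = {s.name: s for s in (TRYPSIN, WALP, NONSPECIFIC)}


def get_protease(name: str) -> ProteaseSpec:
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protease {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


def load_protease_spec(path: str | Path) -> ProteaseSpec:
    """Read a spec from a plain-text key-value file.

    Recognised keys: ``name``, ``cleave_after`` (residue string),
    ``not_before`` (residue string), ``blocked_by_modification`` (true/false).
    Lines starting with '#' are comments.
    """
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line {line!r}")
        k, v = line.split("=", 1)
        kv[k.strip().lower()] = v.strip()
    if "name" not in kv or "cleave_after" not in kv:
        raise ValueError("protease config requires 'name' and 'cleave_after'")
    return ProteaseSpec(
        name=kv["name"],
        cleave_after=frozenset(kv["cleave_after"].upper()),
        not_before=frozenset(kv.get("not_before", "").upper()),
        blocked_by_modification=kv.get("blocked_by_modification", "true").lower()
        in ("1", "true", "yes"),
    )


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)}")


def cleavage_sites(
    sequence: str,
    spec: ProteaseSpec,
    blocked_positions: Iterable[int] = (),
) -> list[int]:
    """1-based positions i such that the protease cuts between i and i+1.

    A position is returned iff its residue is in the cleave-after set, no
    suppression rule fires on the following residue, and (when the spec is
    modification-blocked) the position is not in ``blocked_positions``.
    The final residue counts as a (vacuous) site when it matches the
    cleave-after set: no residue follows, so no suppression can fire.
    """
    _check_sequence(sequence)
    blocked = set(blocked_positions) if spec.blocked_by_modification else set()
    sites = []
    for i in range(1, len(sequence) + 1):
        if sequence[i - 1] not in spec.cleave_after:
            continue
        if i < len(sequence) and sequence[i] in spec.not_before:
            continue
        if i in blocked:
            continue
        sites.append(i)
    return sites


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its 1-based inclusive span in the parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


def digest(
    sequence: str,
    spec: ProteaseSpec,
    params: DigestParams = DigestParams(),
    blocked_positions: Iterable[int] = (),
) -> list[DigestPeptide]:
    """Enumerate digestion products.

    With 0 missed cleavages and full specificity the spans partition the
    sequence (before length filtering); with k allowed missed cleavages every
    concatenation of up to k+1 adjacent fully-cleaved fragments is produced.
    Semi-specific mode additionally yields sub-peptides keeping at least one
    specific terminus.
    """
    _check_sequence(sequence)
    if not sequence:
        return []
    sites = cleavage_sites(sequence, spec, blocked_positions)
    bounds = [0] + sites  # fragment i spans bounds[i]+1..bounds[i+1]
    if bounds[-1] != len(sequence):
        bounds.append(len(sequence))
    nfrag = len(bounds) - 1

    spans: list[tuple[int, int, int]] = []  # (start, end, missed)
    for i in range(nfrag):
        for j in range(i, min(i + params.max_missed_cleavages + 1, nfrag)):
            spans.append((bounds[i] + 1, bounds[j + 1], j - i))

    if params.specificity == "semi":
        semi: set[tuple[int, int, int]] = set(spans)
        for start, end, mc in spans:
            for s2 in range(start + 1, end + 1):  # keep C-terminal specificity
                semi.add((s2, end, mc))
            for e2 in range(start, end):  # keep N-terminal specificity
                semi.add((start, e2, mc))
        spans = sorted(semi)

    out = []
    for start, end, mc in spans:
        length = end - start + 1
        if params.min_length <= length <= params.max_length:
            out.append(DigestPeptide(sequence[start - 1 : end], start, end, mc))
    return out


def peptide_covering_site(
    sequence: str,
    spec: ProteaseSpec,
    site: int,
    params: DigestParams = DigestParams(),
) -> DigestPeptide:
    """The fully-specific peptide containing a cleavage-blocked modified site.

    The site's own residue is treated as modification-blocked (a
    remnant-carrying lysine does not cleave); the peptide's boundaries are
    the nearest unblocked cleavage sites, or the protein termini. This is the
    operation behind "this site would have sat in a tryptic peptide of length
    57": a long stretch without accessible K/R means a peptide too long (or
    too short) to observe in a standard tryptic run.
    """
    _check_sequence(sequence)
    if not 1 <= site <= len(sequence):
        raise ValueError(f"site {site} outside sequence of length {len(sequence)}")
    if sequence[site - 1] != "K":
        import warnings

        warnings.warn(f"residue at site {site} is {sequence[site - 1]!r}, not K")
    sites = cleavage_sites(sequence, spec, blocked_positions={site})
    start = 1
    end = len(sequence)
    for s in sites:
        if s < site:
            start = s + 1
        if s >= site:
            end = s
            break
    return DigestPeptide(sequence[start - 1 : end], start, end)


def excise_nterm_met(sequence: str) -> str:
    """Optional preprocessing: drop an initiator methionine."""
    return sequence[1:] if sequence.startswith("M") else sequence
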