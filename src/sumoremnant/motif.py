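"""Sequence windows around modified lysines and SUMO consensus classification.

The canonical ("forward") SUMOylation consensus is psi-K-x-[E/D]: a
hydrophobic residue immediately N-terminal of the acceptor lysine and an
acidic residue two positions C-terminal. The "inverted" consensus places the
acidic residue two positions N-terminal ([E/D]-x-K). Windows that satisfy
both are counted as forward (the better-characterized motif). Everything
else is "none".

The hydrophobic set psi defaults to {A, I, L, M, P, F, V}, the usual SUMO
consensus convention; it is configurable. Terminal padding uses '-' and a
padded position never matches psi or the acidic set.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PSI_DEFAULT",
    "ACIDIC",
    "SequenceWindow",
    "extract_window",
    "classify_motif",
    "motif_summary",
]

PSI_DEFAULT = frozenset("AILMPFV")
ACIDIC = frozenset("ED")
PAD = "-"

MOTIF_CLASSES = ("forward", "inverted", "none")


@dataclass(frozen=True)
class SequenceWindow:
    """A residue window of length 2*flank+1 centered on a site."""

    residues: str
    flank: int

    def __post_init__(self):
        if len(self.residues) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.residues)} != 2*{self.flank}+1"
            )

    def at(self, offset: int) -> str:
        """Residue at signed offset from the center (0 = the site itself)."""
        if abs(offset) > self.flank:
            raise IndexError(f"offset {offset} outside flank {self.flank}")
        return self.residues[self.flank + offset]

    @property
    def center(self) -> str:
        return self.at(0)


def extract_window(sequence: str, site: int, flank: int = 5) -> SequenceWindow:
    """Window of ``2*flank+1`` residues centered on 1-based ``site``,
    '-'-padded past the protein termini."""
    if not 1 <= site <= len(sequence):
        raise ValueError(f"site {site} outside sequence of length {len(sequence)}")
    i = site - 1
    left = sequence[max(0, i - flank) : i]
    right = sequence[i + 1 : i + 1 + flank]
    return SequenceWindow(
        PAD * (flank - len(left)) + left + sequence[i] + right + PAD * (flank - len(right)),
        flank,
    )


def classify_motif(
    window: SequenceWindow, psi: frozenset = PSI_DEFAULT
) -> str:
    """Classify a K-centered window as forward, inverted, or none.

    forward: position -1 in psi and position +2 acidic;
    inverted: position -2 acidic (checked only if forward fails).
    """
    if window.flank < 2:
        raise ValueError("classification requires flank >= 2")
    if window.center != "K":
        raise ValueError(f"window center is {window.center!r}, not K")
    if window.at(-1) in psi and window.at(+2) in ACIDIC:
        return "forward"
    if window.at(-2) in ACIDIC:
        return "inverted"
    return "none"


def motif_summary(
    windows: Sequence[SequenceWindow], psi: frozenset = PSI_DEFAULT
) -> dict:
    """Class fractions (exact rationals summing to 1) and per-position
    residue-composition counts for logo/enrichment display."""
    if not windows:
        raise ValueError("no windows to summarize")
    counts = dict.fromkeys(MOTIF_CLASSES, 0)
    for w in windows:
        counts[classify_motif(w, psi)] += 1
    n = len(windows)
    fractions = {c: Fraction(k, n) for c, k in counts.items()}
    assert sum(fractions.values()) == 1

    flank = max(w.flank for w in windows)
    composition: dict[int, dict[str, int]] = {
        off: {} for off in range(-flank, flank + 1)
    }
    for w in windows:
        for off in range(-w.flank, w.flank + 1):
            r = w.at(off)
            if r != PAD:
                composition[off][r] = composition[off].get(r, 0) + 1
    return {"counts": counts, "fractions": fractions, "composition": composition}
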