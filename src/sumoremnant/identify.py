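"""Post-search processing of remnant peptide-spectrum matches.

Four stages turn raw search-engine output into localized modification sites:

1. ``merge_heavy_light`` — SILAC heavy and light searches report the
   remnant-bearing lysine differently (the heavy search folds the heavy-K
   label and the diglycyl remnant into one composite delta mass); merging
   decomposes composites so both channels speak the same modification
   language.
2. ``fdr_filter`` — classic target-decoy false-discovery-rate control with
   q-values; decoys are reversed protein sequences.
3. ``localize`` — an Ascore-style binomial localization probability over
   candidate lysines, from site-determining fragment ions.
4. ``collapse_to_sites`` — aggregate localized PSMs to unique
   (protein, residue) sites, dropping placements below a probability cut
   (0.9 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .chem import (
    DEFAULT_TABLE,
    Modification,
    Peptide,
    default_registry,
    fragment_ions,
)

__all__ = [
    "PSMRecord",
    "SpectrumPeaks",
    "SiteIdentification",
    "merge_heavy_light",
    "fdr_filter",
    "localize",
    "collapse_to_sites",
    "compare_known",
]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``accession`` may hold several ';'-separated accessions for shared
    peptides. ``start`` is the peptide's 1-based start in the protein (needed
    to map peptide-local modification positions to absolute residues).
    ``site_probs`` maps peptide-local candidate positions to localization
    probabilities once ``localize`` has run.
    """

    spectrum_id: str
    accession: str
    peptide: Peptide
    score: float
    decoy: bool = False
    label: str | None = None  # "H" | "L" | None
    charge: int | None = None
    start: int | None = None
    site_probs: tuple = ()  # ((position, probability), ...)
    flags: tuple = ()

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError("PSM score must be finite")
        if self.label not in (None, "H", "L"):
            raise ValueError(f"bad label state {self.label!r}")


@dataclass(frozen=True)
class SpectrumPeaks:
    """A centroided MS/MS peak list."""

    mz: tuple
    intensity: tuple
    precursor_mz: float | None = None
    precursor_charge: int | None = None

    def __post_init__(self):
        mz = tuple(float(x) for x in self.mz)
        it = tuple(float(x) for x in self.intensity)
        if len(mz) != len(it):
            raise ValueError("m/z and intensity lengths differ")
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("m/z values must be strictly ascending")
        if any(x < 0 for x in it):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)

    def top_peaks(self, depth: int, window: float = 100.0) -> "SpectrumPeaks":
        """Keep the ``depth`` most intense peaks per ``window`` m/z."""
        keep: list[int] = []
        idx = np.arange(len(self.mz))
        mz = np.asarray(self.mz)
        it = np.asarray(self.intensity)
        if len(mz) == 0:
            return self
        for lo in np.arange(0.0, mz.max() + window, window):
            sel = idx[(mz >= lo) & (mz < lo + window)]
            if len(sel):
                order = sel[np.argsort(it[sel])[::-1][:depth]]
                keep.extend(order.tolist())
        keep = sorted(set(keep))
        return SpectrumPeaks(
            tuple(mz[keep]), tuple(it[keep]), self.precursor_mz, self.precursor_charge
        )


@dataclass(frozen=True)
class SiteIdentification:
    """A localized, FDR-filtered modification site on one protein."""

    accession: str
    position: int  # 1-based residue in the protein
    modification: str
    probability: float
    psm_count: int
    best_score: float
    ambiguous: bool = False

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.psm_count < 1:
            raise ValueError("psm_count must be >= 1")

    @property
    def site_key(self) -> tuple:
        return (self.accession, self.position, self.modification)


# ---------------------------------------------------------------------------
# heavy/light merging


def merge_heavy_light(
    psms: Iterable[PSMRecord],
    label_delta: float | None = None,
    remnant_delta: float | None = None,
    tolerance: float = 1e-3,
) -> list[PSMRecord]:
    """Normalize heavy-search composite lysine modifications.

    Heavy searches report a remnant-bearing heavy lysine as one composite
    delta of (label + remnant). Records whose K modifications match the
    composite within ``tolerance`` are decomposed into explicit label +
    remnant annotations; plain-label K mods are normalized to the canonical
    label modification; light records pass through. A heavy K modification
    matching neither is flagged ``unresolved_k_mod`` rather than silently
    merged.
    """
    label_mod = default_registry["HeavyK(13C6 15N2)"]
    remnant_mod = default_registry["GlyGly"]
    if label_delta is None:
        label_delta = label_mod.delta_mass
    if remnant_delta is None:
        remnant_delta = remnant_mod.delta_mass
    composite = label_delta + remnant_delta

    out = []
    for psm in psms:
        if psm.label != "H":
            out.append(replace(psm, label=psm.label or "L"))
            continue
        new_mods: list[tuple[int, Modification]] = []
        flags = list(psm.flags)
        for pos, mod in psm.peptide.modifications:
            residue = psm.peptide.sequence[pos - 1]
            if residue == "K":
                if abs(mod.delta_mass - composite) <= tolerance:
                    new_mods.append((pos, label_mod))
                    new_mods.append((pos, remnant_mod))
                    continue
                if abs(mod.delta_mass - label_delta) <= tolerance:
                    new_mods.append((pos, label_mod))
                    continue
                if abs(mod.delta_mass - remnant_delta) <= tolerance:
                    # remnant without label on a heavy record: keep, but the
                    # lysine itself should also carry the label — flag it.
                    new_mods.append((pos, remnant_mod))
                    flags.append(f"unlabeled_k_remnant@{pos}")
                    continue
                new_mods.append((pos, mod))
                flags.append(f"unresolved_k_mod@{pos}")
            else:
                new_mods.append((pos, mod))
        out.append(
            replace(
                psm,
                peptide=Peptide(psm.peptide.sequence, tuple(new_mods), psm.peptide.charge),
                flags=tuple(flags),
                label="H",
            )
        )
    return out


# ---------------------------------------------------------------------------
# target-decoy FDR


def fdr_filter(
    psms: Sequence[PSMRecord], threshold: float = 0.01
) -> tuple[list[PSMRecord], np.ndarray]:
    """Target-decoy FDR filtering with q-values.

    FDR at score s = (#decoys with score >= s) / max(1, #targets >= s);
    q-values are the running minimum of FDR over decreasing score. Returns
    the retained target PSMs (q <= threshold; decoys never returned) and the
    q-value of every input PSM, aligned with input order. At tied scores
    decoys are counted before targets (conservative).
    """
    psms = list(psms)
    if not psms:
        return [], np.empty(0)
    if all(p.decoy for p in psms):
        warnings.warn("all input PSMs are decoys; nothing retained")
        return [], np.ones(len(psms))

    # Sort descending by score; at ties, decoys first (conservative).
    order = sorted(range(len(psms)), key=lambda i: (-psms[i].score, not psms[i].decoy))
    n = len(psms)
    fdr = np.empty(n)
    n_decoy = n_target = 0
    for rank, i in enumerate(order):
        if psms[i].decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdr[rank] = n_decoy / max(1, n_target)
    # q-value: minimum FDR over this-or-any-lower score cut.
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    qvals = np.empty(n)
    for rank, i in enumerate(order):
        qvals[i] = q_sorted[rank]
    retained = [p for p, q in zip(psms, qvals) if not p.decoy and q <= threshold]
    return retained, qvals


# ---------------------------------------------------------------------------
# localization


def _ion_key(mz: float, tolerance: float) -> int:
    return round(mz / max(tolerance, 1e-9))


def localize(
    spectrum: SpectrumPeaks,
    peptide: Peptide,
    remnant: Modification | None = None,
    tolerance: float = 0.5,
    peak_depth: int = 10,
    series: Sequence[str] = ("b", "y"),
) -> dict[int, float]:
    """Binomial localization probabilities over candidate lysine placements.

    For each candidate K the remnant is placed there and the theoretical
    fragment ions computed; site-determining ions are those not shared by
    every placement. Matches are counted against the ``peak_depth`` most
    intense peaks per 100 m/z. With per-ion chance
    p = (peak_depth/100) * 2*tolerance of a random match, a placement with
    k of n site-determining ions matched gets weight
    1 / P(Binomial(n, p) >= k) — the less explicable by chance a placement's
    matches are, the more probable the placement. Weights are normalized to
    probabilities summing to 1 (the usual inverse-chance-probability scheme
    of binomial PTM localizers).
    """
    if remnant is None:
        remnant = default_registry["GlyGly"]
    candidates = [i + 1 for i, r in enumerate(peptide.sequence) if r == "K"]
    if not candidates:
        raise ValueError("peptide contains no lysine")
    if len(spectrum.mz) == 0:
        raise ValueError("empty spectrum")
    if len(candidates) == 1:
        return {candidates[0]: 1.0}

    base_mods = tuple(
        (pos, mod) for pos, mod in peptide.modifications if mod.name != remnant.name
    )
    placements = {
        c: Peptide(peptide.sequence, base_mods + ((c, remnant),), peptide.charge)
        for c in candidates
    }
    max_charge = max(1, (peptide.charge or 2) - 1)
    theo = {
        c: {_ion_key(mz, tolerance) for _, mz in fragment_ions(p, series, max_charge)}
        for c, p in placements.items()
    }
    common = set.intersection(*theo.values())
    determining = {c: ions - common for c, ions in theo.items()}

    filtered = spectrum.top_peaks(peak_depth)
    peak_keys = set()
    for mz in filtered.mz:
        peak_keys.add(_ion_key(mz, tolerance))

    p_match = min(1.0, (peak_depth / 100.0) * 2.0 * tolerance)
    loglik = {}
    for c, ions in determining.items():
        n = len(ions)
        k = sum(1 for ion in ions if ion in peak_keys)
        # log weight = -log P(X >= k), X ~ Binomial(n, p_match)
        loglik[c] = -float(stats.binom.logsf(k - 1, n, p_match)) if n else 0.0
    m = max(loglik.values())
    lik = {c: math.exp(v - m) for c, v in loglik.items()}
    total = sum(lik.values())
    return {c: lik[c] / total for c in candidates}


# ---------------------------------------------------------------------------
# collapsing to unique sites


def collapse_to_sites(
    psms: Iterable[PSMRecord],
    localization_threshold: float = 0.9,
    modification: str = "GlyGly",
) -> list[SiteIdentification]:
    """Collapse localized PSMs to unique (accession, position) sites.

    Each PSM contributes every candidate placement whose localization
    probability meets the threshold (a peptide with two confident remnants
    contributes two sites). PSMs without a protein-start mapping are skipped
    with a warning. Shared peptides (';'-joined accessions) yield one site
    per accession, flagged ambiguous.
    """
    best: dict[tuple, dict] = {}
    for psm in psms:
        if psm.start is None:
            warnings.warn(f"PSM {psm.spectrum_id}: no peptide-to-protein mapping; skipped")
            continue
        accessions = [a.strip() for a in psm.accession.split(";") if a.strip()]
        ambiguous = len(accessions) > 1
        for pos, prob in psm.site_probs:
            if prob < localization_threshold:
                continue
            for acc in accessions:
                key = (acc, psm.start + pos - 1, modification)
                entry = best.setdefault(
                    key,
                    {"probability": prob, "psm_count": 0, "best_score": psm.score,
                     "ambiguous": ambiguous},
                )
                entry["psm_count"] += 1
                entry["probability"] = max(entry["probability"], prob)
                entry["best_score"] = max(entry["best_score"], psm.score)
                entry["ambiguous"] = entry["ambiguous"] or ambiguous
    return [
        SiteIdentification(acc, pos, mod, e["probability"], e["psm_count"],
                           e["best_score"], e["ambiguous"])
        for (acc, pos, mod), e in sorted(best.items())
    ]


def compare_known(
    sites: Iterable[SiteIdentification],
    known: Mapping[str, Iterable[tuple]],
) -> dict:
    """Overlap/novelty of identified sites against known-site tables.

    ``known`` maps a source name to an iterable of (accession, position)
    pairs. Returns per-source overlap counts, the union overlap, and the
    count of sites novel to every source.
    """
    ours = {(s.accession, s.position) for s in sites}
    per_source = {}
    union: set = set()
    for name, table in known.items():
        kset = {(a, int(p)) for a, p in table}
        union |= kset
        per_source[name] = {
            "known_sites": len(kset),
            "overlap": len(ours & kset),
        }
    return {
        "identified": len(ours),
        "per_source": per_source,
        "union_known": len(union),
        "union_overlap": len(ours & union),
        "novel": len(ours - union),
    }
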