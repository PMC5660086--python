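"""SILAC heavy/light quantitation at the modification-site level.

Peptide-level heavy/light intensity pairs are aggregated per site as an
intensity-weighted average of log2(H/L); site ratios are median-centered
across the experiment, then flagged "changing" when they fall outside
``sd_mult`` standard deviations from the median, and "twofold" when the
normalized log2 ratio clears ``fold_cut`` (log2(2) = 1). With lysine-only
heavy labeling every remnant-bearing peptide contains a labeled residue, so
every confidently identified site is in principle quantifiable.

Averaging happens in log2 space by default (symmetric treatment of up- and
down-regulation); a linear-space mode is available. Weights are the summed
heavy+light intensity of each peptide measurement, a proxy for measurement
precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SilacMeasurement",
    "SiteQuant",
    "DualModRecord",
    "site_ratio",
    "normalize_ratios",
    "flag_changing",
    "compare_conditions",
    "quantify_sites",
    "dual_modification_table",
]


@dataclass(frozen=True)
class SilacMeasurement:
    """One peptide-level heavy/light intensity pair linked to a site."""

    peptide: str
    accession: str
    position: int
    heavy: float
    light: float

    def __post_init__(self):
        if self.heavy < 0 or self.light < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def log2_ratio(self) -> float | None:
        """log2(H/L); undefined unless both channels are positive."""
        if self.light > 0 and self.heavy > 0:
            return math.log2(self.heavy / self.light)
        return None

    @property
    def weight(self) -> float:
        return self.heavy + self.light


@dataclass(frozen=True)
class SiteQuant:
    """Site-level weighted SILAC log2 ratio with change flags."""

    accession: str
    position: int
    modification: str
    log2_ratio: float
    n_peptides: int
    changing: str | None = None  # up | down | unchanged | None (n too small)
    twofold: str = "neither"  # up | down | neither

    def __post_init__(self):
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")

    @property
    def site_key(self) -> tuple:
        return (self.accession, self.position)


@dataclass(frozen=True)
class DualModRecord:
    """Per-lysine record joining SUMO and ubiquitin quantitation."""

    accession: str
    position: int
    sumo_log2_ratio: float | None = None
    ub_log2_ratio: float | None = None

    def __post_init__(self):
        if self.sumo_log2_ratio is None and self.ub_log2_ratio is None:
            raise ValueError("at least one ratio must be present")


def site_ratio(
    measurements: Sequence[SilacMeasurement], mode: str = "log2"
) -> float | None:
    """Intensity-weighted average ratio for one site.

    ``mode="log2"`` (default) averages per-peptide log2(H/L); ``"linear"``
    averages H/L and returns log2 of that mean. Measurements with a zero
    channel carry no ratio and are excluded; if none remain the site is not
    quantifiable and ``None`` is returned with a warning.
    """
    if mode not in ("log2", "linear"):
        raise ValueError("mode must be 'log2' or 'linear'")
    usable = [m for m in measurements if m.log2_ratio is not None]
    if not usable:
        warnings.warn("no measurement with both channels > 0; site skipped")
        return None
    w = np.array([m.weight for m in usable])
    w = w / w.sum()
    if mode == "log2":
        vals = np.array([m.log2_ratio for m in usable])
        return float(np.dot(w, vals))
    vals = np.array([m.heavy / m.light for m in usable])
    return float(math.log2(np.dot(w, vals)))


def normalize_ratios(ratios: Mapping[tuple, float]) -> dict:
    """Median-center site log2 ratios; the output median is 0."""
    if not ratios:
        raise ValueError("no ratios to normalize")
    med = float(np.median(list(ratios.values())))
    return {k: v - med for k, v in ratios.items()}


def flag_changing(
    normalized: Mapping[tuple, float],
    sd_mult: float = 1.0,
    fold_cut: float = 1.0,
) -> dict:
    """Flag sites as changing (outside sd_mult s.d. of the median) and as
    at-least-twofold up/down (|log2 ratio| >= fold_cut).

    Returns ``{site: (changing, twofold)}``. With fewer than two sites the
    s.d. is undefined and the changing flag is ``None``; twofold flags are
    still computed.
    """
    vals = np.array(list(normalized.values()), dtype=float)
    out = {}
    if len(vals) >= 2:
        med = float(np.median(vals))
        sd = float(np.std(vals, ddof=1))
    else:
        med = sd = None
    for site, r in normalized.items():
        if sd is None:
            changing = None
        elif sd == 0.0:
            changing = "unchanged"
        elif r - med > sd_mult * sd:
            changing = "up"
        elif med - r > sd_mult * sd:
            changing = "down"
        else:
            changing = "unchanged"
        if r >= fold_cut:
            twofold = "up"
        elif r <= -fold_cut:
            twofold = "down"
        else:
            twofold = "neither"
        out[site] = (changing, twofold)
    return out


def compare_conditions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float] | None:
    """Two-tailed Welch t-test between two groups of site log2 ratios.

    Returns (t, p); ``None`` when either group has fewer than two values.
    Identical groups give p = 1.0 (including the zero-variance case, where
    the t statistic is taken as 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a[0] == b[0] else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def quantify_sites(
    measurements: Iterable[SilacMeasurement],
    modification: str = "GlyGly",
    sd_mult: float = 1.0,
    fold_cut: float = 1.0,
    mode: str = "log2",
) -> list[SiteQuant]:
    """Full site-level pipeline: group by site, weighted-average, median-
    center, flag. Sites with no usable ratio are dropped (heavy-only or
    light-only sites are qualitative, not ratio statistics)."""
    by_site: dict[tuple, list[SilacMeasurement]] = {}
    for m in measurements:
        by_site.setdefault((m.accession, m.position), []).append(m)
    raw: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for site, ms in by_site.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = site_ratio(ms, mode=mode)
        if r is not None:
            raw[site] = r
            counts[site] = sum(1 for m in ms if m.log2_ratio is not None)
    if not raw:
        return []
    normalized = normalize_ratios(raw)
    flags = flag_changing(normalized, sd_mult=sd_mult, fold_cut=fold_cut)
    return [
        SiteQuant(acc, pos, modification, normalized[(acc, pos)],
                  counts[(acc, pos)], *flags[(acc, pos)])
        for acc, pos in sorted(normalized)
    ]


def dual_modification_table(
    sumo_sites: Sequence[SiteQuant], ub_sites: Sequence[SiteQuant]
) -> tuple[list[DualModRecord], dict]:
    """Join SUMO and Ub site quantitation on lysine identity.

    Returns the per-lysine records plus summary counts: lysines modified by
    both, and proteins that are SUMO-only / Ub-only / dually quantified.
    """
    sumo = {s.site_key: s for s in sumo_sites}
    ub = {s.site_key: s for s in ub_sites}
    records = []
    for key in sorted(set(sumo) | set(ub)):
        records.append(
            DualModRecord(
                key[0], key[1],
                sumo_log2_ratio=sumo[key].log2_ratio if key in sumo else None,
                ub_log2_ratio=ub[key].log2_ratio if key in ub else None,
            )
        )
    sumo_prot = {k[0] for k in sumo}
    ub_prot = {k[0] for k in ub}
    summary = {
        "lysines_both": len(set(sumo) & set(ub)),
        "lysines_sumo_only": len(set(sumo) - set(ub)),
        "lysines_ub_only": len(set(ub) - set(sumo)),
        "proteins_both": len(sumo_prot & ub_prot),
        "proteins_sumo_only": len(sumo_prot - ub_prot),
        "proteins_ub_only": len(ub_prot - sumo_prot),
    }
    return records, summary
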