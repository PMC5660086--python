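"""Synthetic proteomes, planted remnant sites, PSM tables and spectra.

The generator is the package's ground-truth factory: it emits the exact
table and peak-list dialects the other modules read, with every planted
quantity (site positions, motif classes, SILAC log2 ratios, decoy fraction,
score distributions) known, so identification, localization, FDR and
quantitation can be validated end to end without any raw MS data.

What it emulates: uniform-composition protein sequences; modification sites
planted on lysines with window edits enforcing an assigned consensus class
(forward / inverted / none, largest-remainder rounding of the configured
fractions); remnant peptides produced by the configured protease with the
site cleavage-blocked; Gaussian search-score distributions for true and
decoy PSMs (decoys drawn from reversed sequences); log-normal heavy/light
intensity pairs around planted log2 ratios; and peak lists containing the
theoretical fragments of the true placement, with site-determining ions
observed at a configurable fraction.

What it does not emulate: real amino-acid composition, chromatography,
charge-state or isotope envelopes, chimeric spectra, or search-engine score
correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import Peptide, default_registry, fragment_ions
from .conjugates import ModifierProtein, remnant_peptides
from .digestion import DigestParams, ProteaseSpec, digest, get_protease
from .identify import PSMRecord, SpectrumPeaks
from .quant import SilacMeasurement

__all__ = ["SimConfig", "simulate_proteome", "plant_sites", "simulate_psms", "SimOutput"]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# toy SUMO-like modifier: WaLP cuts after the T of ...TGG leaving "GG"
_DEFAULT_MODIFIER = ModifierProtein("simSUMO", "MQKARTGG")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the seed fixes every downstream draw."""

    seed: int = 0
    n_proteins: int = 60
    protein_length: tuple = (80, 240)  # uniform inclusive bounds
    n_sites: int = 100
    motif_fractions: tuple = (0.31, 0.09, 0.60)  # forward, inverted, none
    decoy_fraction: float = 0.1
    protease: str = "walp"
    max_missed_cleavages: int = 1
    peptide_length_bounds: tuple = (4, 60)
    psms_per_site: tuple = (1, 3)  # uniform inclusive bounds
    changed_fraction: float = 0.1  # fraction of sites with a planted change
    change_log2: float = 1.5  # |log2 H/L| of planted changes (>= twofold)
    intensity_sigma: float = 0.2  # per-channel log2 intensity noise (s.d.)
    base_log2_intensity: float = 20.0
    true_score: tuple = (3.0, 1.0)  # Gaussian mean, s.d.
    decoy_score: tuple = (0.0, 1.0)
    false_target_fraction: float = 0.0  # entrapment: fraction of target PSMs
    # that are wrong matches (null-scored, from shuffled sequences)
    ion_observed_fraction: float = 0.9
    flank: int = 5

    def __post_init__(self):
        f = self.motif_fractions
        if len(f) != 3 or any(not 0 <= x <= 1 for x in f) or abs(sum(f) - 1) > 1e-9:
            raise ValueError("motif fractions must be three values summing to 1")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy fraction must be in [0, 1)")
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")


def simulate_proteome(cfg: SimConfig) -> list[tuple[str, str]]:
    """Random proteins (uniform residue background), each with >= 1 lysine."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.protein_length
    out = []
    for i in range(cfg.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(_RESIDUES[j] for j in rng.integers(0, 20, size=n))
        if "K" not in seq:
            k = int(rng.integers(0, n))
            seq = seq[:k] + "K" + seq[k + 1 :]
        out.append((f"SIMP{i:04d}", seq))
    return out


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [math.floor(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _edit_window(seq: list, i: int, cls: str, rng: np.random.Generator) -> None:
    """Edit residues around 0-based center i so the window classifies as cls."""
    psi_choices = "VLIA"
    non_psi = "G"
    if cls == "forward":
        seq[i - 1] = psi_choices[int(rng.integers(0, len(psi_choices)))]
        seq[i + 2] = "ED"[int(rng.integers(0, 2))]
    elif cls == "inverted":
        seq[i - 2] = "ED"[int(rng.integers(0, 2))]
        seq[i - 1] = non_psi  # forward must fail
    else:  # none
        seq[i - 2] = non_psi
        seq[i - 1] = non_psi
        seq[i + 2] = non_psi


def plant_sites(
    proteome: Sequence[tuple], cfg: SimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Plant modification sites and return (edited proteome, truth table).

    Sites are spaced at least 2*flank+1 apart so window edits never collide;
    the truth table carries accession, position, motif class and the planted
    SILAC log2 ratio. Raises if the proteome cannot host ``n_sites``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    spacing = 2 * cfg.flank + 1
    # candidate slots: (protein index, position), leaving room for edits
    slots: list[tuple[int, int]] = []
    for pi, (_, seq) in enumerate(proteome):
        pos = cfg.flank + 1
        while pos <= len(seq) - cfg.flank:
            slots.append((pi, pos))
            pos += spacing
    if len(slots) < cfg.n_sites:
        raise ValueError(
            f"proteome offers {len(slots)} plantable slots < {cfg.n_sites} sites"
        )
    chosen_idx = rng.choice(len(slots), size=cfg.n_sites, replace=False)
    chosen = [slots[i] for i in sorted(chosen_idx)]

    counts = _largest_remainder(cfg.n_sites, cfg.motif_fractions)
    classes = (
        ["forward"] * counts[0] + ["inverted"] * counts[1] + ["none"] * counts[2]
    )
    perm = rng.permutation(cfg.n_sites)
    classes = [classes[i] for i in perm]

    n_changed = round(cfg.changed_fraction * cfg.n_sites)
    ratios = np.zeros(cfg.n_sites)
    if n_changed:
        which = rng.choice(cfg.n_sites, size=n_changed, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_changed)
        ratios[which] = signs * cfg.change_log2

    seqs = {pi: list(seq) for pi, (_, seq) in enumerate(proteome)}
    rows = []
    for k, (pi, pos) in enumerate(chosen):
        s = seqs[pi]
        i = pos - 1
        s[i] = "K"
        _edit_window(s, i, classes[k], rng)
        rows.append(
            {
                "accession": proteome[pi][0],
                "position": pos,
                "motif_class": classes[k],
                "true_log2_ratio": float(ratios[k]),
            }
        )
    edited = [
        (acc, "".join(seqs[pi])) for pi, (acc, _) in enumerate(proteome)
    ]
    return edited, pd.DataFrame(rows)


@dataclass
class SimOutput:
    """Everything the generator knows about one simulated experiment."""

    proteome: list
    sites: pd.DataFrame
    psms: list
    measurements: list
    spectra: dict  # spectrum_id -> (SpectrumPeaks, true peptide, true local position)
    false_target_ids: set = field(default_factory=set)  # entrapment PSMs


def _spectrum_for(
    peptide: Peptide,
    true_pos: int,
    remnant,
    frac_observed: float,
    rng: np.random.Generator,
) -> SpectrumPeaks:
    """Peak list containing the true placement's fragments; ions that are
    site-determining (differ between candidate K placements) are kept with
    probability ``frac_observed`` each."""
    candidates = [i + 1 for i, r in enumerate(peptide.sequence) if r == "K"]
    base_mods = tuple((p, m) for p, m in peptide.modifications if m.name != remnant.name)
    theo = {}
    for c in candidates:
        pep_c = Peptide(peptide.sequence, base_mods + ((c, remnant),))
        theo[c] = {label: mz for label, mz in fragment_ions(pep_c, ("b", "y"), 1)}
    true_ions = theo[true_pos]
    if len(candidates) > 1:
        others = [set(v.values()) for c, v in theo.items() if c != true_pos]
        common = set(true_ions.values()).intersection(*others)
    else:
        common = set(true_ions.values())
    mzs = []
    for label, mz in true_ions.items():
        determining = mz not in common
        if determining and rng.random() > frac_observed:
            continue
        mzs.append((mz, 200.0 if determining else 100.0))
    mzs.sort()
    # collapse numerically identical m/z
    out_mz, out_int = [], []
    for mz, inten in mzs:
        if out_mz and mz - out_mz[-1] < 1e-6:
            out_int[-1] += inten
        else:
            out_mz.append(mz)
            out_int.append(inten)
    return SpectrumPeaks(tuple(out_mz), tuple(out_int))


def simulate_psms(
    proteome: Sequence[tuple],
    sites: pd.DataFrame,
    cfg: SimConfig,
    modifier: ModifierProtein = _DEFAULT_MODIFIER,
) -> SimOutput:
    """True and decoy PSMs, SILAC measurements and spectra for planted sites.

    Every true PSM's peptide comes from digesting its source protein with the
    configured protease (site cleavage-blocked, remnant attached); decoys are
    drawn from reversed sequences so that decoys make up
    ``cfg.decoy_fraction`` of all PSM records. Heavy/light intensities are
    log-normal around each site's planted log2 ratio.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    spec = get_protease(cfg.protease)
    params = DigestParams(
        max_missed_cleavages=cfg.max_missed_cleavages,
        min_length=cfg.peptide_length_bounds[0],
        max_length=cfg.peptide_length_bounds[1],
    )
    remnant_mod = default_registry["GlyGly"]
    seq_by_acc = dict(proteome)

    psms: list[PSMRecord] = []
    measurements: list[SilacMeasurement] = []
    spectra: dict[str, tuple] = {}
    counter = 0
    mu_t, sd_t = cfg.true_score
    for row in sites.itertuples(index=False):
        substrate = seq_by_acc[row.accession]
        candidates = remnant_peptides(substrate, row.position, modifier, spec, params)
        if not candidates:
            continue
        n_psm = int(rng.integers(cfg.psms_per_site[0], cfg.psms_per_site[1] + 1))
        used_seqs = set()
        for _ in range(n_psm):
            rp = candidates[int(rng.integers(0, len(candidates)))]
            local = rp.modified_position
            # normalize the remnant onto the registry GlyGly modification
            pep = Peptide(rp.peptide.sequence, ((local, remnant_mod),), 2)
            sid = f"sim{counter:06d}"
            counter += 1
            label = "H" if rng.random() < 0.5 else "L"
            psms.append(
                PSMRecord(
                    spectrum_id=sid,
                    accession=row.accession,
                    peptide=pep,
                    score=float(rng.normal(mu_t, sd_t)),
                    decoy=False,
                    label=label,
                    charge=2,
                    start=rp.span[0],
                )
            )
            spectra[sid] = (
                _spectrum_for(pep, local, remnant_mod, cfg.ion_observed_fraction, rng),
                pep,
                local,
            )
            # one measurement per distinct peptide sequence per site
            if pep.sequence not in used_seqs:
                used_seqs.add(pep.sequence)
                eps_l = rng.normal(0.0, cfg.intensity_sigma)
                eps_h = rng.normal(0.0, cfg.intensity_sigma)
                light = 2.0 ** (cfg.base_log2_intensity + eps_l)
                heavy = 2.0 ** (
                    cfg.base_log2_intensity + row.true_log2_ratio + eps_h
                )
                measurements.append(
                    SilacMeasurement(
                        pep.sequence, row.accession, int(row.position), heavy, light
                    )
                )

    mu_d, sd_d = cfg.decoy_score

    def _null_psm(sequence: str, accession: str, decoy: bool) -> PSMRecord | None:
        """A null-scored PSM from a K-containing peptide of ``sequence``."""
        nonlocal counter
        peps = [p for p in digest(sequence, spec, params) if "K" in p.sequence]
        if not peps:
            return None
        dp = peps[int(rng.integers(0, len(peps)))]
        ks = [i + 1 for i, r in enumerate(dp.sequence) if r == "K"]
        local = ks[int(rng.integers(0, len(ks)))]
        sid = f"sim{counter:06d}"
        counter += 1
        return PSMRecord(
            spectrum_id=sid,
            accession=accession,
            peptide=Peptide(dp.sequence, ((local, remnant_mod),), 2),
            score=float(rng.normal(mu_d, sd_d)),
            decoy=decoy,
            label="H" if rng.random() < 0.5 else "L",
            charge=2,
            start=dp.start,
        )

    # entrapment: wrong target matches from shuffled sequences, null-scored
    ft = cfg.false_target_fraction
    n_false = round(len(psms) * ft / (1.0 - ft)) if ft > 0 else 0
    false_ids: set[str] = set()
    made = guard = 0
    while made < n_false and guard < 50 * max(1, n_false):
        guard += 1
        acc, seq = proteome[int(rng.integers(0, len(proteome)))]
        shuffled = "".join(
            seq[i] for i in rng.permutation(len(seq))
        )
        psm = _null_psm(shuffled, acc, decoy=False)
        if psm is not None:
            psms.append(psm)
            false_ids.add(psm.spectrum_id)
            made += 1

    # decoys from reversed sequences, decoy_fraction of all records
    f = cfg.decoy_fraction
    n_decoy = round(len(psms) * f / (1.0 - f)) if f > 0 else 0
    made = guard = 0
    while made < n_decoy and guard < 50 * max(1, n_decoy):
        guard += 1
        acc, seq = proteome[int(rng.integers(0, len(proteome)))]
        psm = _null_psm(seq[::-1], f"decoy_{acc}", decoy=True)
        if psm is not None:
            psms.append(psm)
            made += 1

    return SimOutput(list(proteome), sites, psms, measurements, spectra, false_ids)
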