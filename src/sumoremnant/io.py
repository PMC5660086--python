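"""Readers and writers for the package's external formats.

Formats: FASTA (Biopython), MGF peak lists (pyteomics), and tab-separated
tables (pandas). The TSV dialect is tab-separated UTF-8 with a required
header row; lines starting with '#' are comments.

PSM table columns: ``spectrum_id, accession, peptide, mod_string, score,
decoy, label, charge, start``. ``mod_string`` is ';'-joined
``position:modification`` items, where modification is either a registered
name (``8:GlyGly``) or a numeric delta mass (``8:+122.0571``); ``start`` is
the peptide's 1-based start position in the protein (optional, '.' if
unknown). ``label`` is H, L or '.'.

Measurement table: ``peptide, accession, position, heavy_intensity,
light_intensity``. Site table: ``accession, position, modification,
probability, psm_count, best_score, ambiguous``. Known-site table:
``accession, position, source``.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .chem import Modification, Peptide, default_registry
from .identify import PSMRecord, SiteIdentification, SpectrumPeaks
from .quant import SilacMeasurement, SiteQuant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_measurement_table",
    "write_measurement_table",
    "read_known_sites",
    "write_site_table",
    "read_mgf",
    "write_mgf",
    "read_config",
]

PSM_COLUMNS = [
    "spectrum_id", "accession", "peptide", "mod_string",
    "score", "decoy", "label", "charge", "start",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Ordered (id, description, sequence) triples.

    Sequences are upper-cased with trailing '*' stripped. Duplicate record
    identifiers or an empty file are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA identifier(s): {dups}")
    return [
        (r.id, r.description, str(r.seq).upper().rstrip("*")) for r in records
    ]


def write_fasta(records: Iterable[tuple], path: str | Path) -> None:
    """Write (id, sequence) or (id, description, sequence) tuples."""
    out = []
    for rec in records:
        if len(rec) == 2:
            rid, seq = rec
            desc = ""
        else:
            rid, desc, seq = rec
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSM tables


def format_mod_string(peptide: Peptide) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in peptide.modifications) or "."


def parse_mod_string(mod_string: str, sequence: str) -> tuple:
    """Parse ';'-joined position:name-or-delta items into Modification pairs."""
    if not mod_string or mod_string == ".":
        return ()
    mods = []
    for item in mod_string.split(";"):
        pos_s, name = item.split(":", 1)
        pos = int(pos_s)
        if name in default_registry:
            mod = default_registry[name]
        else:
            try:
                delta = float(name)
            except ValueError:
                raise KeyError(f"unknown modification {name!r}") from None
            mod = Modification(f"mass:{name}", delta)
        mods.append((pos, mod))
    return tuple(mods)


def read_psm_table(path: str | Path) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Read a PSM TSV; malformed rows go to a rejects report, not the floor.

    Returns (records, rejects) where rejects carries the offending row plus
    a ``reason`` column.
    """
    df = _read_tsv(path, PSM_COLUMNS[:8])
    records: list[PSMRecord] = []
    rejects = []
    if df.empty:
        warnings.warn(f"{path}: empty PSM table")
    for _, row in df.iterrows():
        try:
            mods = parse_mod_string(row["mod_string"], row["peptide"])
            charge = None if row["charge"] in (".", "", None) else int(row["charge"])
            start_val = row.get("start", ".")
            start = None if start_val in (".", "", None) or pd.isna(start_val) else int(start_val)
            label = None if row["label"] in (".", "", None) else str(row["label"])
            records.append(
                PSMRecord(
                    spectrum_id=str(row["spectrum_id"]),
                    accession=str(row["accession"]),
                    peptide=Peptide(str(row["peptide"]), mods, charge),
                    score=float(row["score"]),
                    decoy=str(row["decoy"]).strip() in ("1", "True", "true"),
                    label=label,
                    charge=charge,
                    start=start,
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append({**row.to_dict(), "reason": str(exc)})
    return records, pd.DataFrame(rejects)


def write_psm_table(psms: Iterable[PSMRecord], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "accession": p.accession,
                "peptide": p.peptide.sequence,
                "mod_string": format_mod_string(p.peptide),
                "score": repr(p.score),
                "decoy": int(p.decoy),
                "label": p.label or ".",
                "charge": p.charge if p.charge is not None else ".",
                "start": p.start if p.start is not None else ".",
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=PSM_COLUMNS), path)


# ---------------------------------------------------------------------------
# measurements / sites / known sites


def read_measurement_table(path: str | Path) -> list[SilacMeasurement]:
    df = _read_tsv(
        path, ["peptide", "accession", "position", "heavy_intensity", "light_intensity"]
    )
    return [
        SilacMeasurement(
            str(r["peptide"]), str(r["accession"]), int(r["position"]),
            float(r["heavy_intensity"]), float(r["light_intensity"]),
        )
        for _, r in df.iterrows()
    ]


def write_measurement_table(ms: Iterable[SilacMeasurement], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "peptide": m.peptide,
                    "accession": m.accession,
                    "position": m.position,
                    "heavy_intensity": repr(m.heavy),
                    "light_intensity": repr(m.light),
                }
                for m in ms
            ],
            columns=["peptide", "accession", "position", "heavy_intensity", "light_intensity"],
        ),
        path,
    )


def write_site_table(sites: Iterable[SiteIdentification], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "accession": s.accession,
                    "position": s.position,
                    "modification": s.modification,
                    "probability": s.probability,
                    "psm_count": s.psm_count,
                    "best_score": s.best_score,
                    "ambiguous": int(s.ambiguous),
                }
                for s in sites
            ]
        ),
        path,
    )


def write_quant_table(quants: Iterable[SiteQuant], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "accession": q.accession,
                    "position": q.position,
                    "modification": q.modification,
                    "log2_ratio": q.log2_ratio,
                    "n_peptides": q.n_peptides,
                    "changing": q.changing or ".",
                    "twofold": q.twofold,
                }
                for q in quants
            ]
        ),
        path,
    )


def read_known_sites(path: str | Path) -> dict[str, set]:
    """Known-site TSV (accession, position, source) -> {source: {(acc, pos)}}.

    Malformed rows are skipped; their count is reported via a warning.
    """
    df = _read_tsv(path, ["accession", "position", "source"])
    out: dict[str, set] = {}
    bad = 0
    for _, r in df.iterrows():
        try:
            out.setdefault(str(r["source"]), set()).add(
                (str(r["accession"]), int(r["position"]))
            )
        except (TypeError, ValueError):
            bad += 1
    if bad:
        warnings.warn(f"{path}: skipped {bad} malformed known-site row(s)")
    return out


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> dict[str, SpectrumPeaks]:
    """MGF peak lists keyed by spectrum TITLE."""
    out = {}
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pep = params.get("pepmass")
            charge = params.get("charge")
            out[str(params["title"])] = SpectrumPeaks(
                tuple(spec["m/z array"]),
                tuple(spec["intensity array"]),
                precursor_mz=float(pep[0]) if pep else None,
                precursor_charge=int(charge[0]) if charge else None,
            )
    return out


def write_mgf(spectra: dict, path: str | Path) -> None:
    """Write {title: SpectrumPeaks} to MGF."""
    entries = []
    for title, sp in spectra.items():
        params = {"title": title}
        if sp.precursor_mz is not None:
            params["pepmass"] = sp.precursor_mz
        if sp.precursor_charge is not None:
            params["charge"] = sp.precursor_charge
        entries.append(
            {
                "params": params,
                "m/z array": list(sp.mz),
                "intensity array": list(sp.intensity),
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# plain-text key-value config


def read_config(path: str | Path) -> dict[str, str]:
    """key = value lines, '#' comments; values kept as strings."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
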