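"""Readers and writers for the plain-text interchange formats.

Identification tables and peak lists are tab-separated; protein databases
are standard FASTA whose headers carry MAG and genus tags as
``>proteinID MAG=<magID> genus=<genus>``; Raman spectra are two-column
wavenumber/intensity text files listed in a manifest TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import MAGTrajectory, OrdinationResult, RIAProfile
from .extraction import PeakList, PeptideIdentification

__all__ = [
    "read_identifications",
    "write_identifications",
    "read_peak_list",
    "write_peak_list",
    "read_mag_map",
    "write_fasta",
    "read_raman_spectrum",
    "write_profiles",
    "write_trajectories",
    "ordination_to_json",
]

ID_COLUMNS = [
    "sequence", "mods", "charge", "mz", "rt_min", "sample",
    "replicate", "timepoint", "proteins", "mags", "genus",
]


def _parse_mods(cell: str) -> tuple[tuple[int, str], ...]:
    if not cell or cell in ("-", "nan"):
        return ()
    out = []
    for token in cell.split(";"):
        pos, name = token.split(":")
        out.append((int(pos), name))
    return tuple(out)


def _format_mods(mods: Iterable[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods) or "-"


def read_identifications(path: str | Path) -> list[PeptideIdentification]:
    """Read a peptide identification table (TSV with the documented columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"identification table missing columns: {missing}")
    idents = []
    for row in df.itertuples(index=False):
        idents.append(
            PeptideIdentification(
                sequence=row.sequence,
                modifications=_parse_mods(row.mods),
                charge=int(row.charge),
                mz=float(row.mz),
                rt_min=float(row.rt_min),
                sample=row.sample,
                replicate=row.replicate,
                timepoint=row.timepoint,
                proteins=tuple(row.proteins.split(";")),
                mags=tuple(row.mags.split(";")) if row.mags else (),
                genus=tuple(row.genus.split(";")) if row.genus else (),
            )
        )
    return idents


def write_identifications(
    idents: Iterable[PeptideIdentification], path: str | Path
) -> None:
    rows = [
        {
            "sequence": i.sequence,
            "mods": _format_mods(i.modifications),
            "charge": i.charge,
            "mz": f"{i.mz:.6f}",
            "rt_min": f"{i.rt_min:.3f}",
            "sample": i.sample,
            "replicate": i.replicate,
            "timepoint": i.timepoint,
            "proteins": ";".join(i.proteins),
            "mags": ";".join(i.mags),
            "genus": ";".join(i.genus),
        }
        for i in idents
    ]
    pd.DataFrame(rows, columns=ID_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peak_list(path: str | Path, sample: str | None = None) -> PeakList:
    """Read a centroid peak list (TSV: mz, intensity, rt_min)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mz", "intensity", "rt_min"):
        if col not in df.columns:
            raise ValueError(f"peak list missing column {col!r}")
    return PeakList(
        sample=sample or Path(path).stem,
        mz=df["mz"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        rt_min=df["rt_min"].to_numpy(float),
    )


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    pd.DataFrame(
        {"mz": peaks.mz, "intensity": peaks.intensity, "rt_min": peaks.rt_min}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_mag_map(fasta_path: str | Path) -> dict[str, tuple[str, str]]:
    """Protein accession -> (MAG, genus) from tagged FASTA headers."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(fasta_path) as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            tokens = line[1:].split()
            accession = tokens[0]
            tags = dict(
                token.split("=", 1) for token in tokens[1:] if "=" in token
            )
            mapping[accession] = (tags.get("MAG", ""), tags.get("genus", ""))
    return mapping


def write_fasta(
    records: Iterable[tuple[str, str, str, str]], path: str | Path
) -> None:
    """Write (accession, mag, genus, sequence) records with tagged headers."""
    with open(path, "w") as fh:
        for accession, mag, genus, seq in records:
            fh.write(f">{accession} MAG={mag} genus={genus}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_raman_spectrum(path: str | Path):
    """Read a two-column (wavenumber, intensity) text spectrum."""
    from .raman import RamanSpectrum

    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return RamanSpectrum(
        wavenumbers=data[:, 0], intensities=data[:, 1],
        metadata={"path": str(path)},
    )


def write_profiles(profiles: Iterable[RIAProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"owner": p.owner, "timepoint": p.timepoint}
        row.update(
            {f"r2_ria_{v:.2f}": r for v, r in zip(p.grid.values, p.r2)}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trajectories(
    trajectories: Iterable[MAGTrajectory], path: str | Path
) -> None:
    rows = []
    for t in trajectories:
        for i, tp in enumerate(t.timepoints):
            rows.append(
                {
                    "mag": t.mag_id,
                    "timepoint": tp,
                    "ria": t.ria[i] if t.ria else np.nan,
                    "labeled_fraction": (
                        t.labeled_fraction[i] if t.labeled_fraction else np.nan
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ordination_to_json(result: OrdinationResult, path: str | Path | None = None):
    """Serialize ordination scores and ellipse parameters to JSON."""
    payload = {
        "layout": result.layout,
        "mag_ids": list(result.mag_ids),
        "scores": result.scores.tolist(),
        "explained_variance_ratio": result.explained_variance_ratio.tolist(),
        "cluster_labels": result.cluster_labels,
        "ellipses": {
            name: {
                "center": e.center.tolist(),
                "covariance": e.covariance.tolist(),
                "scale": e.scale,
            }
            for name, e in result.ellipses.items()
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload
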