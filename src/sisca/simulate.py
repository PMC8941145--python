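"""Ground-truth simulator for SIP-metaproteomics and single-cell Raman data.

Emulates the inputs of a ¹³C labeling experiment: a community of genome bins
(MAGs), each following a carbon-utilization archetype that fixes its ¹³C RIA
trajectory over the incubation time points; tryptic peptides per MAG; and
per-sample centroid peak lists in which every peptide's isotopologue pattern
is a mixture of an unlabeled (natural-abundance) envelope and a labeled
envelope at the MAG's RIA, with configurable labeled fraction, multiplicative
per-peak noise and m/z jitter.  A truth table records the RIA, labeled
fraction and implied doublings/generation time per peptide and time point, so
every downstream stage can be scored against known ground truth.

The four built-in archetypes encode the canonical trajectory shapes of a
chemolithoautotrophic labeling experiment: a strict autotroph sits at high
stable RIA from the start; a switching mixotroph starts moderate and jumps
high once it switches to CO₂ fixation; a cross-feeding incorporator ramps up
gradually as the organic-carbon pool becomes labeled; a heterotroph living on
unlabeled groundwater carbon stays near natural abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as pt_parser

from .chem import (
    ElementalComposition,
    IsotopologuePattern,
    composition_from_peptide,
    predict_pattern,
)
from .constants import NATURAL_13C
from .extraction import PeakList, PeptideIdentification

__all__ = [
    "ARCHETYPE_RIA",
    "DEFAULT_TIMEPOINTS",
    "NoiseModel",
    "MAGSpec",
    "CommunitySpec",
    "SimulatedDataset",
    "simulate_peptides",
    "simulate_spectrum",
    "simulate_community",
    "simulate_raman",
    "tryptic_digest",
]

#: RIA trajectories of the four trophic archetypes over three time points.
ARCHETYPE_RIA: dict[str, tuple[float, ...]] = {
    "strict_autotroph": (0.95, 0.95, 0.95),
    "switching_mixotroph": (0.65, 0.91, 0.91),
    "crossfeeding_incorporator": (0.18, 0.53, 0.76),
    "unlabeled_heterotroph": (0.06, 0.06, 0.06),
}

#: Default sampling schedule: (label, days since label addition).
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("T1", 21.0),
    ("T2", 43.0),
    ("T3", 70.0),
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class NoiseModel:
    """Spectral noise: per-peak multiplicative lognormal at coefficient of
    variation `cv`, peaks below `floor` (absolute intensity) dropped, and
    uniform m/z jitter within ±`mz_jitter_ppm`."""

    cv: float = 0.05
    floor: float = 0.0
    mz_jitter_ppm: float = 3.0

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(cv=0.0, floor=0.0, mz_jitter_ppm=0.0)


@dataclass(frozen=True)
class MAGSpec:
    """One simulated genome bin."""

    mag_id: str
    genus: str
    archetype: str = "strict_autotroph"
    ria: tuple[float, ...] | None = None  # overrides the archetype trajectory
    labeled_fraction: tuple[float, ...] | None = None  # default: fully labeled
    doublings: tuple[float, ...] | None = None  # alternative to labeled_fraction
    n_peptides: int = 20
    peptide_length: tuple[int, int] = (7, 30)

    def ria_trajectory(self, n_timepoints: int) -> tuple[float, ...]:
        if self.ria is not None:
            traj = self.ria
        elif self.archetype in ARCHETYPE_RIA:
            traj = ARCHETYPE_RIA[self.archetype]
        else:
            raise ValueError(f"unknown archetype {self.archetype!r} and no ria given")
        if len(traj) != n_timepoints:
            raise ValueError(
                f"{self.mag_id}: {len(traj)} RIA values for {n_timepoints} time points"
            )
        if any(not 0.0 <= r <= 1.0 for r in traj):
            raise ValueError("RIA values must lie in [0, 1]")
        return tuple(traj)

    def labeled_trajectory(self, n_timepoints: int) -> tuple[float, ...]:
        if self.labeled_fraction is not None and self.doublings is not None:
            raise ValueError("give labeled_fraction or doublings, not both")
        if self.doublings is not None:
            # invert n = log2(total/labeled): f = 2^-n
            traj = tuple(2.0 ** (-n) for n in self.doublings)
        elif self.labeled_fraction is not None:
            traj = tuple(self.labeled_fraction)
        else:
            traj = (1.0,) * n_timepoints
        if len(traj) != n_timepoints:
            raise ValueError(
                f"{self.mag_id}: {len(traj)} labeled fractions for "
                f"{n_timepoints} time points"
            )
        if any(not 0.0 <= f <= 1.0 for f in traj):
            raise ValueError("labeled fractions must lie in [0, 1]")
        return traj


@dataclass(frozen=True)
class CommunitySpec:
    """Full description of a simulated labeling experiment."""

    mags: tuple[MAGSpec, ...]
    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINTS
    replicates: int = 2
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @classmethod
    def archetype_panel(
        cls,
        mags_per_archetype: int = 1,
        n_peptides: int = 20,
        noise: NoiseModel | None = None,
        seed: int = 0,
        replicates: int = 2,
    ) -> "CommunitySpec":
        """One or more MAGs per built-in archetype — the standard test bed."""
        mags = []
        for arch in ARCHETYPE_RIA:
            for i in range(mags_per_archetype):
                mags.append(
                    MAGSpec(
                        mag_id=f"{arch}_{i + 1}",
                        genus=f"Genus_{arch[:5]}{i + 1}",
                        archetype=arch,
                        n_peptides=n_peptides,
                    )
                )
        return cls(
            mags=tuple(mags),
            noise=noise or NoiseModel(),
            seed=seed,
            replicates=replicates,
        )


def tryptic_digest(sequence: str, missed_cleavages: int = 2) -> set[str]:
    """In-silico trypsin digest: cleave after K/R except before P."""
    return pt_parser.cleave(
        sequence, pt_parser.expasy_rules["trypsin"], missed_cleavages
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def simulate_peptides(
    spec: CommunitySpec,
) -> tuple[list[tuple[str, str, str, str]], list[PeptideIdentification]]:
    """Random proteins per MAG plus their identification records.

    Proteins are random sequences (uniform residue frequencies); peptides are
    drawn from the tryptic digest (≤ 2 missed cleavages) within the length
    window, each unique to its MAG by construction.  Charges are 2–3, m/z is
    computed from the composition, retention times are uniform draws shared
    across samples (co-chromatography).  Identification rows are emitted once
    per replicate and time point, mirroring a ¹²C identification table.
    """
    rng = np.random.default_rng(spec.seed)
    fasta: list[tuple[str, str, str, str]] = []
    idents: list[PeptideIdentification] = []
    seen_peptides: set[str] = set()
    for mag in spec.mags:
        lo, hi = mag.peptide_length
        chosen: list[tuple[str, str]] = []  # (peptide, source accession)
        for attempt in range(60):
            accession = f"{mag.mag_id}_p{attempt + 1}"
            protein = _random_protein(rng, max(400, mag.n_peptides * 30))
            fasta.append((accession, mag.mag_id, mag.genus, protein))
            candidates = sorted(
                pep
                for pep in tryptic_digest(protein)
                if lo <= len(pep) <= hi and pep not in seen_peptides
            )
            rng.shuffle(candidates)
            for pep in candidates:
                if len(chosen) >= mag.n_peptides:
                    break
                chosen.append((pep, accession))
                seen_peptides.add(pep)
            if len(chosen) >= mag.n_peptides:
                break
        if len(chosen) < mag.n_peptides:
            raise ValueError(
                f"{mag.mag_id}: could not draw {mag.n_peptides} unique tryptic "
                f"peptides of length {lo}-{hi}"
            )
        for pep, accession in chosen:
            charge = int(rng.integers(2, 4))
            rt = float(rng.uniform(10.0, 120.0))
            mz = composition_from_peptide(pep).mz(charge)
            for tp_label, _ in spec.timepoints:
                for rep in range(spec.replicates):
                    idents.append(
                        PeptideIdentification(
                            sequence=pep,
                            modifications=(),
                            charge=charge,
                            mz=mz,
                            rt_min=rt,
                            sample=f"{tp_label}_rep{rep + 1}",
                            replicate=f"rep{rep + 1}",
                            timepoint=tp_label,
                            proteins=(accession,),
                            mags=(mag.mag_id,),
                            genus=(mag.genus,),
                            label=mag.mag_id,
                        )
                    )
    return fasta, idents


def simulate_spectrum(
    composition: ElementalComposition,
    charge: int,
    ria: float,
    labeled_fraction: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    total_intensity: float = 1e6,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak positions and intensities of one peptide's mixed pattern.

    The intensity series is ``(1−f)·natural + f·labeled`` scaled to
    `total_intensity`, with lognormal per-peak noise at the configured CV
    (unit mean), peaks below the floor dropped, and uniform m/z jitter.
    Returns ``(mz_array, intensity_array)`` of the surviving peaks.
    """
    natural = predict_pattern(composition, NATURAL_13C, charge)
    mixture = (1.0 - labeled_fraction) * np.pad(
        natural.intensities, (0, 0)
    )
    if labeled_fraction > 0.0:
        labeled = predict_pattern(composition, ria, charge)
        size = max(len(natural), len(labeled))
        mixture = (1.0 - labeled_fraction) * np.pad(
            natural.intensities, (0, size - len(natural))
        ) + labeled_fraction * np.pad(
            labeled.intensities, (0, size - len(labeled))
        )
    intensities = mixture * total_intensity
    if noise.cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma,
                                size=len(intensities))
        intensities = intensities * factors
    mz = natural.mz_positions()
    if len(mz) < len(intensities):
        mz = natural.base_mz + np.arange(len(intensities)) * natural.spacing
    if noise.mz_jitter_ppm > 0:
        mz = mz * (
            1.0
            + rng.uniform(-noise.mz_jitter_ppm, noise.mz_jitter_ppm, size=len(mz))
            * 1e-6
        )
    keep = intensities > noise.floor
    return mz[keep], intensities[keep]


@dataclass
class SimulatedDataset:
    """Everything one simulated experiment produced."""

    spec: CommunitySpec
    fasta: list[tuple[str, str, str, str]]
    identifications: list[PeptideIdentification]
    peak_lists: dict[str, PeakList]
    truth: pd.DataFrame

    def mag_map(self) -> dict[str, tuple[str, str]]:
        return {acc: (mag, genus) for acc, mag, genus, _ in self.fasta}

    def write(self, out_dir: str | Path) -> None:
        from .io import write_fasta, write_identifications, write_peak_list

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.fasta, out / "proteins.fasta")
        write_identifications(self.identifications, out / "identifications.tsv")
        peaks_dir = out / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for sample in sorted(self.peak_lists):
            write_peak_list(self.peak_lists[sample], peaks_dir / f"{sample}.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def simulate_community(spec: CommunitySpec) -> SimulatedDataset:
    """Run the full simulator: FASTA, identifications, peak lists, truth."""
    fasta, idents = simulate_peptides(spec)
    rng = np.random.default_rng(spec.seed + 1)
    mag_specs = {m.mag_id: m for m in spec.mags}
    n_tp = len(spec.timepoints)
    tp_index = {label: i for i, (label, _) in enumerate(spec.timepoints)}
    tp_days = dict(spec.timepoints)

    sample_peaks: dict[str, dict[str, list[np.ndarray]]] = {}
    truth_rows = []
    seen_truth: set[tuple[str, str]] = set()
    for ident in idents:
        mag = mag_specs[ident.mags[0]]
        i_tp = tp_index[ident.timepoint]
        ria = mag.ria_trajectory(n_tp)[i_tp]
        f = mag.labeled_trajectory(n_tp)[i_tp]
        composition = composition_from_peptide(ident.sequence)
        total = float(rng.lognormal(mean=math.log(1e6), sigma=0.3))
        mz, inten = simulate_spectrum(
            composition, ident.charge, ria, f, spec.noise, rng, total
        )
        store = sample_peaks.setdefault(ident.sample, {"mz": [], "i": [], "rt": []})
        store["mz"].append(mz)
        store["i"].append(inten)
        store["rt"].append(np.full(len(mz), ident.rt_min))
        key = (ident.sequence, ident.timepoint)
        if key not in seen_truth:
            seen_truth.add(key)
            n_printed = math.log2(1.0 / f) if f > 0 else math.inf
            n_conv = math.log2(1.0 / (1.0 - f)) if f < 1 else math.inf
            dt = tp_days[ident.timepoint]
            truth_rows.append(
                {
                    "peptide": ident.sequence,
                    "mag": mag.mag_id,
                    "genus": mag.genus,
                    "timepoint": ident.timepoint,
                    "dt_days": dt,
                    "ria": ria,
                    "labeled_fraction": f,
                    "n_as_printed": n_printed,
                    "n_unlabeled_denominator": n_conv,
                    "t_d_as_printed": dt / n_printed if n_printed > 0 else math.nan,
                    "carbon_fraction_13c": f * ria + (1.0 - f) * NATURAL_13C,
                }
            )
    peak_lists = {
        sample: PeakList(
            sample=sample,
            mz=np.concatenate(store["mz"]),
            intensity=np.concatenate(store["i"]),
            rt_min=np.concatenate(store["rt"]),
        )
        for sample, store in sorted(sample_peaks.items())
    }
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        spec=spec,
        fasta=fasta,
        identifications=idents,
        peak_lists=peak_lists,
        truth=truth,
    )


def simulate_raman(
    n_cells: int,
    true_cd_ratio: float,
    seed: int,
    axis: np.ndarray | None = None,
    band_amplitude: float = 200.0,
    cd_center: float = 2170.0,
    cd_sigma: float = 45.0,
    ch_center: float = 2930.0,
    ch_sigma: float = 55.0,
    baseline_coeffs: Sequence[float] = (50.0, 30.0, -15.0),
    noise_sd: float = 0.01,
    spike_probability: float = 0.0,
    cell_variability: float = 0.0,
):
    """Synthetic single-cell Raman spectra with a known C-D ratio.

    Each cell gets a Gaussian C-D band (in 2040–2300 cm⁻¹) and C-H band
    (2800–3100 cm⁻¹) whose areas satisfy A_CD/(A_CD+A_CH) = `true_cd_ratio`
    (optionally jittered per cell by `cell_variability`, a relative SD), a
    smooth polynomial baseline, Gaussian noise at `noise_sd` × band
    amplitude, and optional cosmic spikes.
    """
    from .raman import RamanSpectrum

    if not 0.0 <= true_cd_ratio < 1.0:
        raise ValueError("true_cd_ratio must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = np.arange(1800.0, 3203.0, 2.0)
    x = np.asarray(axis, dtype=float)
    u = (x - x[0]) / (x[-1] - x[0])
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs))
    spectra = []
    for cell in range(n_cells):
        r = true_cd_ratio
        if cell_variability > 0:
            r = float(
                np.clip(rng.normal(true_cd_ratio, cell_variability * true_cd_ratio),
                        0.0, 0.999)
            )
        # unit-area Gaussians scaled so band areas give the requested ratio
        cd = (
            r
            / (cd_sigma * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((x - cd_center) / cd_sigma) ** 2)
        )
        ch = (
            (1.0 - r)
            / (ch_sigma * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((x - ch_center) / ch_sigma) ** 2)
        )
        # scale so the C-H band height is ~band_amplitude·(1−r)
        amp = band_amplitude * ch_sigma * math.sqrt(2 * math.pi)
        y = baseline + amp * (cd + ch)
        y = y + rng.normal(0.0, noise_sd * band_amplitude, size=len(x))
        if spike_probability > 0:
            n_spikes = rng.binomial(3, spike_probability)
            for _ in range(n_spikes):
                pos = int(rng.integers(0, len(x)))
                y[pos] += band_amplitude * rng.uniform(20.0, 60.0)
        spectra.append(
            RamanSpectrum(
                wavenumbers=x,
                intensities=y,
                metadata={"cell": f"cell_{cell + 1}", "true_cd_ratio": r},
            )
        )
    return spectra
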