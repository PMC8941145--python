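"""Locating and vetting measured isotopologue patterns in ¹³C-sample peak
lists, guided by peptide identifications from parallel ¹²C samples.

Identifications come from the unlabeled runs (a labeled peptide's precursor
mass shifts, so it is rarely re-identified directly); the labeled runs are
assumed co-chromatographed, so each identification's m/z and retention time
define where that peptide's isotopologue series must lie in the labeled
sample.  Candidate positions are the monoisotopic m/z plus k·(1.003355/z)
for k = 0…max_index; matches must fall within a ppm mass tolerance and a
retention-time window.  Patterns showing signal before the monoisotopic peak
(M−1) or overlapping another peptide's expected positions are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    ElementalComposition,
    IsotopologuePattern,
    composition_from_peptide,
)
from .constants import C13_C12_SPACING

__all__ = [
    "PeptideIdentification",
    "PeakList",
    "MeasuredPattern",
    "Rejection",
    "filter_peptides",
    "locate_pattern",
    "validate_pattern",
    "require_replicates",
    "DEFAULT_PPM_TOL",
    "DEFAULT_RT_TOL_MIN",
    "DEFAULT_M1_REL_THRESHOLD",
]

DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_TOL_MIN = 3.0
DEFAULT_M1_REL_THRESHOLD = 0.05


@dataclass(frozen=True)
class PeptideIdentification:
    """One peptide-spectrum identification from a ¹²C sample."""

    sequence: str
    modifications: tuple[tuple[int, str], ...]
    charge: int
    mz: float
    rt_min: float
    sample: str
    replicate: str
    timepoint: str
    proteins: tuple[str, ...]
    mags: tuple[str, ...] = ()
    genus: tuple[str, ...] = ()
    label: str = ""  # resolved MAG-or-genus group, set by filter_peptides

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        if not self.proteins:
            raise ValueError("identification needs at least one protein accession")

    def composition(self) -> ElementalComposition:
        return composition_from_peptide(self.sequence, self.modifications)


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks of one sample: parallel m/z, intensity, RT arrays."""

    sample: str
    mz: np.ndarray
    intensity: np.ndarray
    rt_min: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        rt = np.asarray(self.rt_min, dtype=float)
        if not (len(mz) == len(inten) == len(rt)):
            raise ValueError("peak columns must have equal length")
        if np.any(mz <= 0) or np.any(inten < 0):
            raise ValueError("m/z must be positive, intensities non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        object.__setattr__(self, "rt_min", rt[order])

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class MeasuredPattern:
    """A located isotopologue intensity series with quality flags."""

    identification: PeptideIdentification
    pattern: IsotopologuePattern
    flags: frozenset[str] = frozenset()
    m1_intensity: float = 0.0


@dataclass(frozen=True)
class Rejection:
    identification: PeptideIdentification
    reason: str  # machine-readable: "m1-signal" | "overlap"
    detail: str = ""


def filter_peptides(
    identifications: Iterable[PeptideIdentification],
    mag_map: Mapping[str, tuple[str, str]],
) -> list[PeptideIdentification]:
    """Keep peptides attributable to a single MAG or a single genus.

    `mag_map` maps protein accession -> (MAG id, genus).  A peptide is kept
    iff all its proteins lie in one MAG (labeled with that MAG), or its MAGs
    all share one genus (labeled ``genus:<name>``).  Peptides spanning
    several genera are dropped — their label incorporation cannot be
    attributed to one organism group.
    """
    kept = []
    for ident in identifications:
        mags, genera = set(), set()
        for acc in ident.proteins:
            if acc not in mag_map:
                raise ValueError(f"protein accession {acc!r} missing from MAG map")
            mag, genus = mag_map[acc]
            mags.add(mag)
            genera.add(genus)
        if len(mags) == 1:
            label = next(iter(mags))
        elif len(genera) == 1:
            label = f"genus:{next(iter(genera))}"
        else:
            continue
        kept.append(
            replace(
                ident,
                mags=tuple(sorted(mags)),
                genus=tuple(sorted(genera)),
                label=label,
            )
        )
    return kept


def _best_peak(
    peaks: PeakList,
    target_mz: float,
    rt_ref: float,
    ppm_tol: float,
    rt_tol: float,
) -> tuple[float, float] | None:
    """(intensity, ppm deviation) of the best in-tolerance peak, or None.

    Among in-tolerance candidates the smallest |ppm| wins; ties go to the
    higher intensity.
    """
    half = target_mz * ppm_tol * 1e-6
    lo = int(np.searchsorted(peaks.mz, target_mz - half, side="left"))
    hi = int(np.searchsorted(peaks.mz, target_mz + half, side="right"))
    best: tuple[float, float] | None = None
    for i in range(lo, hi):
        if abs(peaks.rt_min[i] - rt_ref) >= rt_tol:
            continue
        ppm = (peaks.mz[i] - target_mz) / target_mz * 1e6
        if abs(ppm) >= ppm_tol:
            continue
        if (
            best is None
            or abs(ppm) < abs(best[1]) - 1e-12
            or (abs(abs(ppm) - abs(best[1])) <= 1e-12 and peaks.intensity[i] > best[0])
        ):
            best = (float(peaks.intensity[i]), ppm)
    return best


def locate_pattern(
    ident: PeptideIdentification,
    peaks: PeakList,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL_MIN,
    max_index: int | None = None,
) -> MeasuredPattern | None:
    """Extract the isotopologue intensity series of one peptide.

    Candidate positions are ``mz + k·spacing`` for ``k = 0…max_index``
    (default: the peptide's carbon count, the largest possible ¹³C shift).
    Positions without an in-tolerance peak are recorded as zero intensity —
    labeled patterns legitimately have near-empty valleys between the
    unlabeled and labeled envelopes.  Returns ``None`` when no position
    matches at all.  The M−1 position is probed too and stored for
    validation.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if max_index is None:
        max_index = ident.composition().carbon
    spacing = C13_C12_SPACING / ident.charge
    intensities = np.zeros(max_index + 1)
    any_hit = False
    for k in range(max_index + 1):
        hit = _best_peak(peaks, ident.mz + k * spacing, ident.rt_min, ppm_tol, rt_tol)
        if hit is not None:
            intensities[k] = hit[0]
            any_hit = True
    if not any_hit:
        return None
    m1 = _best_peak(peaks, ident.mz - spacing, ident.rt_min, ppm_tol, rt_tol)
    # trim trailing zeros beyond the last observed peak
    last = int(np.max(np.nonzero(intensities)[0]))
    pattern = IsotopologuePattern(
        base_mz=ident.mz,
        charge=ident.charge,
        intensities=intensities[: last + 1],
    )
    return MeasuredPattern(
        identification=ident,
        pattern=pattern,
        m1_intensity=m1[0] if m1 else 0.0,
    )


def validate_pattern(
    measured: MeasuredPattern,
    neighbors: Sequence[MeasuredPattern] = (),
    m1_rel_threshold: float = DEFAULT_M1_REL_THRESHOLD,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL_MIN,
) -> MeasuredPattern | Rejection:
    """Reject patterns with M−1 signal or overlap with other peptides.

    A peak at ``base_mz − spacing`` above ``m1_rel_threshold`` × the
    pattern's maximum intensity indicates the window caught a different
    (lighter) species.  A neighbor pattern (different peptide) whose expected
    isotopologue positions fall within the ppm tolerance of this pattern's
    positions, with overlapping retention-time windows, contaminates the
    series.  Clean patterns are returned flagged ``validated``.
    """
    peak_max = float(measured.pattern.intensities.max())
    if peak_max > 0 and measured.m1_intensity > m1_rel_threshold * peak_max:
        return Rejection(measured.identification, "m1-signal",
                         f"M-1 at {measured.m1_intensity / peak_max:.1%} of max")
    own = measured.pattern.mz_positions()
    for other in neighbors:
        ident = other.identification
        if (
            ident.sequence == measured.identification.sequence
            and ident.charge == measured.identification.charge
        ):
            continue
        if abs(ident.rt_min - measured.identification.rt_min) >= rt_tol:
            continue
        theirs = other.pattern.mz_positions()
        tol = own * ppm_tol * 1e-6
        if np.any(np.abs(own[:, None] - theirs[None, :]) < tol[:, None]):
            return Rejection(
                measured.identification,
                "overlap",
                f"shares positions with {ident.sequence}/{ident.charge}+",
            )
    flags = set(measured.flags)
    flags.add("validated")
    return MeasuredPattern(
        identification=measured.identification,
        pattern=measured.pattern,
        flags=frozenset(flags),
        m1_intensity=measured.m1_intensity,
    )


def require_replicates(
    patterns: Iterable[MeasuredPattern],
    min_replicates: int = 2,
) -> list[MeasuredPattern]:
    """Drop MAG/time-point groups supported by too few replicates.

    A group counts distinct replicate IDs among its accepted patterns; groups
    below `min_replicates` are excluded from downstream aggregation.  Output
    order is deterministic (sorted by label, timepoint, replicate, sequence)
    regardless of input order.
    """
    items = list(patterns)
    support: dict[tuple[str, str], set[str]] = {}
    for p in items:
        key = (p.identification.label or "", p.identification.timepoint)
        support.setdefault(key, set()).add(p.identification.replicate)
    kept = [
        p
        for p in items
        if len(support[(p.identification.label or "", p.identification.timepoint)])
        >= min_replicates
    ]
    kept.sort(
        key=lambda p: (
            p.identification.label,
            p.identification.timepoint,
            p.identification.replicate,
            p.identification.sequence,
            p.identification.charge,
        )
    )
    return kept


def replicate_agreement(
    patterns: Sequence[MeasuredPattern],
    min_cosine: float = 0.0,
) -> list[MeasuredPattern]:
    """Optional replicate-consistency check (disabled at min_cosine=0).

    Keeps patterns whose cosine similarity to the element-wise mean pattern
    of their (peptide, timepoint) group reaches `min_cosine`.  The manual
    workflow this mechanizes compared replicates by eye; no quantitative
    criterion is canonical, so the default accepts everything.
    """
    if min_cosine <= 0:
        return list(patterns)
    groups: dict[tuple[str, int, str], list[MeasuredPattern]] = {}
    for p in patterns:
        key = (p.identification.sequence, p.identification.charge,
               p.identification.timepoint)
        groups.setdefault(key, []).append(p)
    kept = []
    for members in groups.values():
        size = max(len(p.pattern.intensities) for p in members)
        mat = np.stack(
            [np.pad(p.pattern.intensities, (0, size - len(p.pattern.intensities)))
             for p in members]
        )
        mean = mat.mean(axis=0)
        for p, row in zip(members, mat):
            denom = np.linalg.norm(row) * np.linalg.norm(mean)
            if denom > 0 and float(row @ mean) / denom >= min_cosine:
                kept.append(p)
    return kept
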