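"""Peptide elemental composition and isotopologue pattern prediction.

The model is the aggregated (nominal-mass / neutron-count) isotopologue
distribution: for each element the per-atom isotope distribution is raised to
the atom count by discrete self-convolution, and the per-element distributions
are combined by convolution.  Carbon is special — its heavy-isotope
probability is the free parameter, the ¹³C relative isotope abundance (RIA),
swept over a grid (default 0–100 % in 5 % steps, 21 patterns) to produce the
reference patterns each measured pattern is scored against.  All other
elements stay at natural abundance.

Fine isotopic structure (e.g. ¹³C vs ¹⁵N mass splits within one nominal
isotopologue) is deliberately not modeled: Orbitrap peptide data are matched
at unit-isotopologue resolution and peak positions use the ¹³C−¹²C spacing
of 1.003355 u divided by charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import (
    C13_C12_SPACING,
    ELEMENTS,
    PROTON_MASS,
    WATER,
    monoisotopic_mass_of_element,
    natural_abundance_vector,
    residue_compositions,
)

__all__ = [
    "ElementalComposition",
    "IsotopologuePattern",
    "RIAGrid",
    "composition_from_peptide",
    "predict_pattern",
    "reference_pattern_set",
    "MODIFICATION_DELTAS",
]

#: Elemental deltas of the two search modifications: carbamidomethylation of
#: cysteine (iodoacetamide adduct C2H3NO) and oxidation of methionine (+O).
MODIFICATION_DELTAS: dict[str, dict[str, int]] = {
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation": {"O": 1},
}

#: Residues each modification may sit on.
_MODIFICATION_TARGETS = {"carbamidomethyl": {"C"}, "oxidation": {"M"}}


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> atom-count map of a (modified) peptide.

    The carbon count drives isotope labeling; every other element contributes
    its natural-abundance envelope.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative atom count for {el}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        els = set(self.counts) | set(other.counts)
        return all(self[el] == other[el] for el in els)

    def __hash__(self) -> int:
        return hash(tuple(sorted((el, n) for el, n in self.counts.items() if n)))

    @property
    def carbon(self) -> int:
        return self["C"]

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in u (all atoms at the lightest isotope)."""
        return sum(
            n * monoisotopic_mass_of_element(el) for el, n in self.counts.items()
        )

    def mz(self, charge: int) -> float:
        """Monoisotopic m/z assuming protonation with `charge` protons."""
        if charge < 1:
            raise ValueError("charge must be a positive integer")
        return (self.monoisotopic_mass() + charge * PROTON_MASS) / charge

    def formula(self) -> str:
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] > 1 else ''}"
            for el in ELEMENTS
            if self.counts.get(el)
        )


def composition_from_peptide(
    sequence: str,
    modifications: Iterable[tuple[int, str]] = (),
) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum plus one water.

    Parameters
    ----------
    sequence
        Amino-acid sequence in one-letter codes (20 standard residues).
    modifications
        ``(position, name)`` pairs, 1-based positions; names are
        ``"carbamidomethyl"`` (Cys) or ``"oxidation"`` (Met).

    Raises
    ------
    ValueError
        On unknown residue letters, unknown modification names, or a
        modification placed on an incompatible residue.
    """
    residues = residue_compositions()
    counts: dict[str, int] = dict(WATER)
    for letter in sequence:
        try:
            residue = residues[letter]
        except KeyError:
            raise ValueError(f"unknown residue {letter!r} in {sequence!r}") from None
        for el, n in residue.items():
            counts[el] = counts.get(el, 0) + n
    for pos, name in modifications:
        key = name.lower()
        if key not in MODIFICATION_DELTAS:
            raise ValueError(f"unknown modification {name!r}")
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        if sequence[pos - 1] not in _MODIFICATION_TARGETS[key]:
            raise ValueError(
                f"{name} not applicable to residue {sequence[pos - 1]!r} at {pos}"
            )
        for el, n in MODIFICATION_DELTAS[key].items():
            counts[el] = counts.get(el, 0) + n
    return ElementalComposition(counts)


@dataclass(frozen=True)
class IsotopologuePattern:
    """Relative intensities at successive isotopologue positions.

    ``intensities[k]`` is the relative abundance of the isotopologue k nominal
    mass units above the monoisotopic peak; adjacent peaks are separated by
    ``spacing`` = 1.003355/charge in m/z.
    """

    base_mz: float
    charge: int
    intensities: np.ndarray
    spacing: float = field(default=0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)
        if self.spacing == 0.0:
            object.__setattr__(self, "spacing", C13_C12_SPACING / self.charge)

    def __len__(self) -> int:
        return len(self.intensities)

    def mz_positions(self) -> np.ndarray:
        return self.base_mz + np.arange(len(self)) * self.spacing

    def normalized(self) -> "IsotopologuePattern":
        total = float(self.intensities.sum())
        if total <= 0:
            raise ValueError("cannot normalize a zero-intensity pattern")
        return IsotopologuePattern(
            self.base_mz, self.charge, self.intensities / total, self.spacing
        )

    def mean_index(self) -> float:
        """Intensity-weighted mean isotopologue index (mass-shift centroid)."""
        w = self.intensities / self.intensities.sum()
        return float(np.arange(len(w)) @ w)


@dataclass(frozen=True)
class RIAGrid:
    """Uniform grid of ¹³C RIA fractions spanning [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError("grid needs at least the endpoints 0 and 1")
        if not (arr[0] == 0.0 and arr[-1] == 1.0):
            raise ValueError("grid must start at 0 and end at 1")
        steps = np.diff(arr)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-12):
            raise ValueError("grid must be strictly increasing with uniform step")
        object.__setattr__(self, "values", arr)

    @classmethod
    def default(cls, step: float = 0.05) -> "RIAGrid":
        n = round(1.0 / step)
        return cls(np.linspace(0.0, 1.0, n + 1))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])


def _element_distribution(element: str, count: int) -> np.ndarray:
    """Neutron-count distribution of `count` atoms at natural abundance."""
    base = np.asarray(natural_abundance_vector(element), dtype=float)
    # binary exponentiation of the single-atom polynomial
    result = np.array([1.0])
    power = base
    n = count
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def aggregated_distribution(
    composition: ElementalComposition,
    ria: float,
    abundance_overrides: Mapping[str, Sequence[float]] | None = None,
) -> np.ndarray:
    """Full neutron-count distribution before truncation.

    Carbon atoms are ¹³C with probability `ria` (independent draws, hence a
    binomial across the carbon count); other elements convolve in at natural
    abundance, unless overridden via `abundance_overrides` (mainly for tests).
    """
    if not 0.0 <= ria <= 1.0:
        raise ValueError(f"ria must lie in [0, 1], got {ria}")
    overrides = abundance_overrides or {}
    dist = np.array([1.0])
    for el, n in composition.counts.items():
        if n == 0:
            continue
        if el == "C" and el not in overrides:
            part = stats.binom.pmf(np.arange(n + 1), n, ria)
        elif el in overrides:
            base = np.asarray(overrides[el], dtype=float)
            part = _pow_distribution(base, n)
        else:
            part = _element_distribution(el, n)
        dist = np.convolve(dist, part)
    return dist


def _pow_distribution(base: np.ndarray, count: int) -> np.ndarray:
    result = np.array([1.0])
    power = base
    n = count
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def _truncate(dist: np.ndarray, coverage: float) -> np.ndarray:
    """Shortest prefix with cumulative abundance >= coverage, renormalized."""
    cum = np.cumsum(dist)
    stop = int(np.searchsorted(cum, coverage * cum[-1] - 1e-15)) + 1
    kept = dist[:stop]
    return kept / kept.sum()


def predict_pattern(
    composition: ElementalComposition,
    ria: float,
    charge: int = 1,
    coverage: float = 0.999,
    abundance_overrides: Mapping[str, Sequence[float]] | None = None,
) -> IsotopologuePattern:
    """Theoretical isotopologue pattern of a peptide at a given ¹³C RIA.

    Parameters
    ----------
    composition
        Elemental composition of the (modified, neutral) peptide.
    ria
        ¹³C relative isotope abundance in [0, 1]; natural abundance ≈ 0.0107.
    charge
        Protonation state; sets base m/z and peak spacing.
    coverage
        Cumulative-abundance cutoff; the pattern is truncated at the shortest
        prefix reaching it, then renormalized to sum 1.
    """
    if not 0.9 <= coverage < 1.0:
        raise ValueError("coverage must lie in [0.9, 1)")
    dist = aggregated_distribution(composition, ria, abundance_overrides)
    intensities = _truncate(dist, coverage)
    return IsotopologuePattern(
        base_mz=composition.mz(charge), charge=charge, intensities=intensities
    )


def reference_pattern_set(
    composition: ElementalComposition,
    charge: int = 1,
    grid: RIAGrid | None = None,
    coverage: float = 0.999,
) -> list[IsotopologuePattern]:
    """One predicted pattern per grid RIA, in grid order (default: 21).

    The non-carbon envelope does not depend on RIA, so it is convolved once
    and reused across the grid.
    """
    grid = grid or RIAGrid.default()
    noncarbon = np.array([1.0])
    for el, n in composition.counts.items():
        if el == "C" or n == 0:
            continue
        noncarbon = np.convolve(noncarbon, _element_distribution(el, n))
    n_c = composition.carbon
    base_mz = composition.mz(charge)
    patterns = []
    k = np.arange(n_c + 1)
    for ria in grid.values:
        carbon = stats.binom.pmf(k, n_c, ria)
        dist = np.convolve(carbon, noncarbon)
        patterns.append(
            IsotopologuePattern(base_mz, charge, _truncate(dist, coverage))
        )
    return patterns
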