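"""Physical constants: isotope masses/abundances and residue compositions.

Both tables ship as plain-text data files next to this module so that the
numbers are inspectable and versioned independently of the code.  Everything
downstream (pattern prediction, m/z computation, the natural-abundance
anchor used in intensity decomposition) reads from here.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = [
    "isotope_table",
    "natural_abundance_vector",
    "monoisotopic_mass_of_element",
    "residue_compositions",
    "NATURAL_13C",
    "C13_C12_SPACING",
    "PROTON_MASS",
    "WATER",
    "ELEMENTS",
]

#: Mass difference between 13C and 12C in u; divides by charge to give the
#: m/z spacing of adjacent isotopologue peaks.
C13_C12_SPACING = 1.00335483507

#: Mass of a proton (u), used to convert neutral mass to m/z.
PROTON_MASS = 1.007276466879

#: Elements a peptide can contain in this model.
ELEMENTS = ("C", "H", "N", "O", "S")

#: Composition of one water molecule, added once per peptide chain.
WATER = {"H": 2, "O": 1}


def _read_data(name: str) -> list[list[str]]:
    text = resources.files("sisca.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def isotope_table() -> dict[str, list[tuple[str, float, float, int]]]:
    """element -> list of (isotope label, mass, abundance, neutron offset)."""
    table: dict[str, list[tuple[str, float, float, int]]] = {}
    for el, iso, mass, ab, off in _read_data("isotopes.tsv"):
        table.setdefault(el, []).append((iso, float(mass), float(ab), int(off)))
    return table


@lru_cache(maxsize=None)
def natural_abundance_vector(element: str) -> tuple[float, ...]:
    """Natural-abundance distribution of `element` indexed by neutron offset."""
    isotopes = isotope_table()[element]
    size = max(off for *_, off in isotopes) + 1
    vec = [0.0] * size
    for _, _, ab, off in isotopes:
        vec[off] = ab
    return tuple(vec)


@lru_cache(maxsize=None)
def monoisotopic_mass_of_element(element: str) -> float:
    isotopes = isotope_table()[element]
    return min(isotopes, key=lambda row: row[3])[1]


@lru_cache(maxsize=None)
def residue_compositions() -> dict[str, dict[str, int]]:
    """One-letter residue code -> element counts of the chain monomer."""
    table: dict[str, dict[str, int]] = {}
    for row in _read_data("residues.tsv"):
        code, *counts = row
        table[code] = {
            el: int(n) for el, n in zip(("C", "H", "N", "O", "S"), counts) if int(n)
        }
    return table


#: Natural abundance of 13C; the RIA floor of an unlabeled peptide.
NATURAL_13C = dict(
    (iso, ab) for iso, _, ab, _ in isotope_table()["C"]
)["13C"]
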