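"""Peptide composition arithmetic and isotopologue pattern prediction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sisca.chem import (
    ElementalComposition,
    RIAGrid,
    aggregated_distribution,
    composition_from_peptide,
    predict_pattern,
    reference_pattern_set,
)
from sisca.constants import NATURAL_13C, natural_abundance_vector

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def enumerated_distribution(composition, ria):
    """Independent oracle: exhaustive enumeration over every per-atom isotope
    choice, aggregated by total neutron count.  Feasible for <= 15 atoms."""
    atom_options = []
    for el, n in composition.counts.items():
        if el == "C":
            options = [(0, 1.0 - ria), (1, ria)]
        else:
            options = [
                (off, ab)
                for off, ab in enumerate(natural_abundance_vector(el))
                if ab > 0
            ]
        atom_options.extend([options] * n)
    max_shift = sum(max(off for off, _ in opts) for opts in atom_options)
    dist = np.zeros(max_shift + 1)
    for combo in itertools.product(*atom_options):
        shift = sum(off for off, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        dist[shift] += prob
    return dist


class TestComposition:
    @pytest.mark.parametrize(
        "sequence, mods, formula",
        [
            ("G", (), "C2H5NO2"),
            ("GG", (), "C4H8N2O3"),
            ("C", ((1, "carbamidomethyl"),), "C5H10N2O3S"),
            ("M", ((1, "oxidation"),), "C5H11NO3S"),
        ],
    )
    def test_known_formulas(self, sequence, mods, formula):
        assert composition_from_peptide(sequence, mods).formula() == formula

    def test_matches_pyteomics_masses(self):
        """Residue table and water agree with an independent reference."""
        from pyteomics import mass as pmass

        for seq in ["PEPTIDE", "GLSDGEWQQVLNVWGK", AMINO_ACIDS]:
            ours = composition_from_peptide(seq).monoisotopic_mass()
            theirs = pmass.calculate_mass(sequence=seq)
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_concatenation_additivity(self):
        """Composition of AB equals sum of A and B minus one water."""
        water = ElementalComposition({"H": 2, "O": 1})
        a = composition_from_peptide("PEPTIDE")
        b = composition_from_peptide("KR")
        ab = composition_from_peptide("PEPTIDEKR")
        assert ab + water == a + b

    @pytest.mark.parametrize(
        "sequence, mods",
        [
            ("PXPTIDE", ()),
            ("PEPTIDE", ((1, "carbamidomethyl"),)),  # P cannot carry cam
            ("PEPTIDE", ((1, "phospho"),)),
            ("PEPTIDE", ((99, "oxidation"),)),
        ],
    )
    def test_rejected_inputs(self, sequence, mods):
        with pytest.raises(ValueError):
            composition_from_peptide(sequence, mods)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})


class TestPrediction:
    def test_single_carbon_half_ria(self):
        pattern = predict_pattern(ElementalComposition({"C": 1}), 0.5)
        assert np.allclose(pattern.intensities, [0.5, 0.5])

    def test_monoisotopic_override_collapses_pattern(self):
        mono = {"C": [1.0], "H": [1.0], "N": [1.0], "O": [1.0]}
        pattern = predict_pattern(
            ElementalComposition({"C": 3}), 0.0, abundance_overrides=mono
        )
        assert np.allclose(pattern.intensities, [1.0])

    def test_enumeration_oracle_glycine(self):
        comp = composition_from_peptide("G")  # C2H5NO2, 10 atoms
        expected = enumerated_distribution(comp, NATURAL_13C)
        actual = aggregated_distribution(comp, NATURAL_13C)
        size = max(len(expected), len(actual))
        assert np.allclose(
            np.pad(actual, (0, size - len(actual))),
            np.pad(expected, (0, size - len(expected))),
            atol=1e-10,
        )

    def test_enumeration_oracle_random_compositions(self, rng):
        """Aggregated convolution equals per-atom enumeration, <=15 atoms."""
        for _ in range(8):
            counts = {
                "C": int(rng.integers(1, 5)),
                "H": int(rng.integers(0, 6)),
                "N": int(rng.integers(0, 3)),
                "O": int(rng.integers(0, 3)),
                "S": int(rng.integers(0, 2)),
            }
            comp = ElementalComposition(counts)
            assert comp.total_atoms() <= 15
            ria = float(rng.uniform(0, 1))
            expected = enumerated_distribution(comp, ria)
            actual = aggregated_distribution(comp, ria)
            size = max(len(expected), len(actual))
            assert np.allclose(
                np.pad(actual, (0, size - len(actual))),
                np.pad(expected, (0, size - len(expected))),
                atol=1e-10,
            )

    def test_patterns_normalized(self):
        for ria in (0.0, 0.3, 1.0):
            p = predict_pattern(composition_from_peptide("PEPTIDEK"), ria)
            assert p.intensities.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p.intensities >= 0)

    def test_mean_shift_monotone_in_ria(self):
        """The centroid of the pattern moves strictly right as RIA grows."""
        comp = composition_from_peptide("AVLYHEK")
        means = [
            predict_pattern(comp, ria).mean_index()
            for ria in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(means) > 0)

    def test_additivity_under_convolution(self):
        a = ElementalComposition({"C": 3, "H": 5, "N": 1, "O": 1})
        b = ElementalComposition({"C": 2, "H": 4, "O": 2, "S": 1})
        ria = 0.35
        combined = aggregated_distribution(a + b, ria)
        convolved = np.convolve(
            aggregated_distribution(a, ria), aggregated_distribution(b, ria)
        )
        assert np.allclose(combined, convolved, atol=1e-9)

    def test_spacing_scales_with_charge(self):
        comp = composition_from_peptide("PEPTIDEK")
        p1 = predict_pattern(comp, 0.2, charge=1)
        p2 = predict_pattern(comp, 0.2, charge=2)
        assert p2.spacing == pytest.approx(p1.spacing / 2)

    def test_invalid_ria_rejected(self):
        with pytest.raises(ValueError):
            predict_pattern(composition_from_peptide("G"), 1.2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ria=st.floats(0.0, 1.0),
        seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12),
    )
    def test_pattern_is_probability_vector(self, ria, seq):
        p = predict_pattern(composition_from_peptide(seq), ria)
        assert p.intensities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p.intensities >= 0)


class TestReferenceSet:
    def test_default_grid_has_21_patterns(self):
        refs = reference_pattern_set(composition_from_peptide("PEPTIDEK"))
        assert len(refs) == 21

    def test_coarse_grid(self):
        grid = RIAGrid.default(step=0.5)
        refs = reference_pattern_set(composition_from_peptide("GG"), grid=grid)
        assert len(refs) == 3
        assert list(grid.values) == [0.0, 0.5, 1.0]

    def test_extreme_grid_endpoints(self):
        """RIA 0 peaks near index 0; RIA 1 peaks near the carbon count."""
        comp = composition_from_peptide("PEPTIDEK")
        refs = reference_pattern_set(comp)
        assert int(np.argmax(refs[0].intensities)) == 0
        assert int(np.argmax(refs[-1].intensities)) == comp.carbon

    def test_matches_individual_predictions(self):
        comp = composition_from_peptide("AVLYHEK")
        grid = RIAGrid.default()
        refs = reference_pattern_set(comp, 2, grid)
        for ria, ref in zip(grid.values[::5], refs[::5]):
            direct = predict_pattern(comp, float(ria), 2)
            assert np.allclose(ref.intensities, direct.intensities, atol=1e-12)

    @pytest.mark.parametrize(
        "values",
        [[0.0, 0.5], [0.1, 0.5, 1.0], [0.0, 0.4, 1.0], [1.0, 0.0]],
    )
    def test_bad_grids_rejected(self, values):
        with pytest.raises(ValueError):
            RIAGrid(np.array(values))
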