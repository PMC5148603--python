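"""Composition arithmetic and isotope-envelope operations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxpulse.constants import DEUTERIUM_MASS_SHIFT, ISOTOPES
from hdxpulse.isotopes import (
    ElementalComposition,
    IsotopeEnvelope,
    PeptideSpec,
    apply_deuteration,
    averagine_composition,
    centroid_mass,
    composition_from_sequence,
    envelope_variance,
    from_mz,
    mix_envelopes,
    n_exchangeable_amides,
    natural_envelope,
    read_envelope,
    to_mz,
    write_envelope,
)


class TestComposition:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("G", {"C": 2, "H": 5, "N": 1, "O": 2}),
            ("GG", {"C": 4, "H": 8, "N": 2, "O": 3}),
        ],
    )
    def test_known_compositions(self, sequence, expected):
        assert dict(composition_from_sequence(sequence)) == expected

    def test_composition_is_order_invariant(self):
        assert composition_from_sequence("AGP") == composition_from_sequence("APG")

    def test_unknown_letter_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            composition_from_sequence("GGXG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_from_sequence("")

    def test_monoisotopic_mass_matches_pyteomics(self):
        """Independent cross-check of the residue table and water terminus."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for sequence in ("G", "PEPTIDE", "ACDEFGHIKLMNPQRSTVWY"):
            ours = composition_from_sequence(sequence).monoisotopic_mass
            theirs = pyteomics_mass.calculate_mass(sequence=sequence)
            assert ours == pytest.approx(theirs, abs=1e-3)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})


class TestAveragine:
    def test_single_unit_rounds_to_integers(self):
        assert dict(averagine_composition(111.1254)) == {"C": 5, "H": 8, "N": 1, "O": 1}

    def test_scaled_mass_within_one_unit(self):
        composition = averagine_composition(3800.0)
        assert abs(composition.average_mass - 3800.0) < 111.1254

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            averagine_composition(0.0)


class TestNaturalEnvelope:
    def test_single_carbon(self):
        envelope = natural_envelope({"C": 1})
        assert envelope.masses == pytest.approx([12.0, 13.003355])
        assert envelope.abundances == pytest.approx([0.9893, 0.0107])

    def test_water_monoisotopic_abundance(self):
        envelope = natural_envelope({"H": 2, "O": 1})
        expected = 0.999885**2 * 0.99757  # product of per-atom abundances
        assert envelope.abundances[0] == pytest.approx(expected, abs=1e-6)

    def test_empty_composition_is_degenerate(self):
        envelope = natural_envelope({})
        assert envelope.degenerate
        assert envelope.masses == pytest.approx([0.0])

    @pytest.mark.parametrize(
        "composition",
        [{"C": 2, "H": 3, "N": 1, "O": 1}, {"H": 2, "O": 1}, {"C": 3, "S": 2},
         {"C": 5, "N": 3, "O": 2}],
    )
    def test_matches_brute_force_enumeration(self, composition):
        """Convolution agrees with explicit isotopologue enumeration to 1e-9."""
        expected = _enumerate_envelope(composition)
        envelope = natural_envelope(composition, truncation=1e-12)
        by_offset = dict(zip(np.round(envelope.masses - envelope.masses[0]).astype(int),
                             envelope.abundances))
        for offset, abundance in expected.items():
            assert by_offset.get(offset, 0.0) == pytest.approx(abundance, abs=1e-9)

    def test_abundances_sum_to_one(self):
        envelope = natural_envelope(averagine_composition(3800.0))
        assert envelope.abundances.sum() == pytest.approx(1.0, abs=1e-9)


def _enumerate_envelope(composition):
    """Brute-force oracle: enumerate every isotopologue of a small composition."""
    atoms = []
    for element, count in composition.items():
        atoms.extend([ISOTOPES[element]] * count)
    mono = sum(isos[0][0] for isos in atoms)
    totals: dict[int, float] = {}
    for choice in itertools.product(*atoms):
        mass = sum(m for m, _ in choice)
        abundance = 1.0
        for _, p in choice:
            abundance *= p
        offset = round(mass - mono)
        totals[offset] = totals.get(offset, 0.0) + abundance
    return totals


class TestExchangeableAmides:
    @pytest.mark.parametrize("sequence, expected", [("AGPM", 2), ("AA", 1), ("AP", 0)])
    def test_proline_and_terminus_rules(self, sequence, expected):
        assert n_exchangeable_amides(sequence) == expected


class TestDeuteration:
    def test_binomial_weights_on_single_peak(self):
        envelope = IsotopeEnvelope([1000.0], [1.0])
        deuterated = apply_deuteration(envelope, 2, 0.5)
        assert deuterated.abundances == pytest.approx([0.25, 0.5, 0.25])
        assert np.diff(deuterated.masses) == pytest.approx(
            [DEUTERIUM_MASS_SHIFT] * 2
        )

    def test_centroid_shift_is_mean_uptake(self, state_envelopes):
        base = natural_envelope(averagine_composition(3800.0))
        deuterated = apply_deuteration(base, 31, 0.7)
        shift = centroid_mass(deuterated) - centroid_mass(base)
        assert shift == pytest.approx(31 * 0.7 * DEUTERIUM_MASS_SHIFT, abs=1e-6)

    def test_identity_cases(self):
        base = natural_envelope({"C": 3, "H": 5, "N": 1, "O": 1})
        assert apply_deuteration(base, 0, 0.5) is base
        assert apply_deuteration(base, 5, 0.0) is base

    def test_invalid_probability_rejected(self):
        base = natural_envelope({"C": 1})
        with pytest.raises(ValueError):
            apply_deuteration(base, 3, 1.2)

    @given(n=st.integers(0, 40), p=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_normalization_preserved(self, n, p):
        base = natural_envelope({"C": 4, "H": 8, "N": 2, "O": 2})
        deuterated = apply_deuteration(base, n, p)
        assert deuterated.abundances.sum() == pytest.approx(1.0, abs=1e-9)


class TestMixtures:
    def test_pure_endpoints(self, state_envelopes):
        folded, unfolded = state_envelopes
        assert mix_envelopes(folded, unfolded, 0.0) is folded
        assert mix_envelopes(folded, unfolded, 1.0) is unfolded

    @given(w=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_centroid_is_linear_in_weight(self, w, state_envelopes):
        folded, unfolded = state_envelopes
        mixture = mix_envelopes(folded, unfolded, w)
        expected = (1 - w) * centroid_mass(folded) + w * centroid_mass(unfolded)
        assert centroid_mass(mixture) == pytest.approx(expected, abs=1e-9)
        assert mixture.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mixture_variance_identity(self, state_envelopes):
        """var(mix) = (1-w) var_f + w var_u + w(1-w) (dc)^2 exactly."""
        folded, unfolded = state_envelopes
        w = 0.37
        mixture = mix_envelopes(folded, unfolded, w)
        separation = centroid_mass(unfolded) - centroid_mass(folded)
        expected = (
            (1 - w) * envelope_variance(folded)
            + w * envelope_variance(unfolded)
            + w * (1 - w) * separation**2
        )
        assert envelope_variance(mixture) == pytest.approx(expected, rel=1e-6)


class TestCentroidAndMz:
    def test_centroid_examples(self):
        assert centroid_mass(IsotopeEnvelope([1000.0], [1.0])) == 1000.0
        env = IsotopeEnvelope([10.0, 20.0], [0.5, 0.5])
        assert centroid_mass(env) == pytest.approx(15.0)

    def test_empty_envelope_rejected(self):
        empty = IsotopeEnvelope(np.array([]), np.array([]), normalized=False)
        with pytest.raises(ValueError):
            centroid_mass(empty)

    @pytest.mark.parametrize("charge, expected", [(1, 1001.00728), (2, 501.00728)])
    def test_mz_conversion(self, charge, expected):
        envelope = IsotopeEnvelope([1000.0], [1.0])
        assert to_mz(envelope, charge).masses[0] == pytest.approx(expected)

    def test_mz_round_trip(self, state_envelopes):
        folded, _ = state_envelopes
        recovered = from_mz(to_mz(folded, 3), 3)
        assert recovered.masses == pytest.approx(folded.masses, abs=1e-6)

    def test_invalid_charge_rejected(self, state_envelopes):
        with pytest.raises(ValueError):
            to_mz(state_envelopes[0], 0)


class TestPeptideSpec:
    def test_coordinate_validation(self):
        with pytest.raises(ValueError):
            PeptideSpec("P", 10, 5)
        with pytest.raises(ValueError):
            PeptideSpec("P", 1, 3, sequence="AAAA")
        with pytest.raises(ValueError):
            PeptideSpec("P", 1, 3, n_exchangeable=3)

    def test_exchangeable_resolution_order(self):
        assert PeptideSpec("P", 1, 4, n_exchangeable=1).exchangeable == 1
        assert PeptideSpec("P", 1, 4, sequence="AGPM").exchangeable == 2
        assert PeptideSpec("P", 1, 4).exchangeable == 3


class TestEnvelopeSerialization:
    def test_round_trip(self, tmp_path, state_envelopes):
        folded, _ = state_envelopes
        path = tmp_path / "envelope.csv"
        write_envelope(folded, path)
        recovered = read_envelope(path)
        assert recovered.masses == pytest.approx(folded.masses)
        assert recovered.abundances == pytest.approx(folded.abundances)
        assert recovered.normalized
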