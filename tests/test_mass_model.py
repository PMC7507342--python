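import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanthiseek.constants import AMINO_ACIDS, NISIN_Z_CORE, PROTON_MASS, WATER_MONO
from lanthiseek.mass_model import (
    PeptideSpecies,
    assign_peaks,
    count_dehydratable,
    dehydration_series,
    format_modification,
    monoisotopic_mass,
    mz,
    ring_topology,
    species_mass,
)

from ._oracles import residue_sum_mass

RL6 = "ITSVSLCTPGCKTGALMGCNMKTASCGCHVHVSK"
RL1 = "ITVRSKSLCTPGCITGPLRTCYLCFPTHVNC"

peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40)


class TestMonoisotopicMass:
    def test_glycine_is_residue_plus_water(self):
        assert monoisotopic_mass("G") == pytest.approx(75.032028, abs=1e-5)

    def test_nisin_z_core_mass(self):
        # frozen from the independent residue-sum oracle
        assert monoisotopic_mass(NISIN_Z_CORE) == pytest.approx(3472.613737, abs=1e-5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("")

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            monoisotopic_mass("GGZG")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(peptides)
    def test_agrees_with_residue_sum_oracle(self, seq):
        assert monoisotopic_mass(seq) == pytest.approx(residue_sum_mass(seq), abs=1e-6)


class TestSpeciesMass:
    def test_unmodified_equals_monoisotopic(self):
        assert species_mass(RL6, 0, 0) == monoisotopic_mass(RL6)

    def test_eightfold_dehydrated_nisin_z(self):
        expected = monoisotopic_mass(NISIN_Z_CORE) - 8 * WATER_MONO
        assert species_mass(NISIN_Z_CORE, 8, 0) == pytest.approx(expected, abs=1e-9)
        assert species_mass(NISIN_Z_CORE, 8, 0) == pytest.approx(3328.529, abs=1e-3)

    def test_dehydration_bounded_by_ser_thr(self):
        assert species_mass(NISIN_Z_CORE, 9, 0) > 0  # capacity is 9
        with pytest.raises(ValueError):
            species_mass(NISIN_Z_CORE, 10, 0)

    def test_nem_bounded_by_cysteines(self):
        with pytest.raises(ValueError):
            species_mass(NISIN_Z_CORE, 0, 6)  # only 5 Cys

    def test_nem_shift_is_nominal_125(self):
        shift = species_mass(RL6, 0, 1) - species_mass(RL6, 0, 0)
        assert round(shift) == 125
        assert shift == pytest.approx(125.047678, abs=1e-5)


class TestMz:
    def test_printed_five_plus_anchor(self):
        observed = mz(species_mass(NISIN_Z_CORE, 8, 0), 5)
        assert observed == pytest.approx(666.71312, abs=1e-3)

    def test_singly_charged_adds_one_proton(self):
        assert mz(1000.0, 1) == pytest.approx(1000.0 + PROTON_MASS)

    def test_zero_mass_gives_proton(self):
        assert mz(0.0, 3) == pytest.approx(PROTON_MASS)

    def test_nonpositive_charge_rejected(self):
        with pytest.raises(ValueError):
            mz(1000.0, 0)


@pytest.mark.parametrize(
    "seq,expected",
    [(RL6, 8), (RL1, 7), (NISIN_Z_CORE, 9), ("AAAA", 0), ("STst", 4)],
)
def test_count_dehydratable(seq, expected):
    assert count_dehydratable(seq) == expected


class TestDehydrationSeries:
    def test_series_size(self):
        assert len(dehydration_series(RL6, charges=(3,))) == 9  # n = 0..8
        assert len(dehydration_series(RL6, charges=(3,), nem_range=(0, 1))) == 18

    def test_adjacent_species_spacing(self):
        series = dehydration_series(RL6, charges=(3,))
        mzs = sorted(sp.mz for sp in series)
        for lo, hi in zip(mzs, mzs[1:]):
            assert hi - lo == pytest.approx(WATER_MONO / 3, abs=1e-9)

    def test_empty_charges_rejected(self):
        with pytest.raises(ValueError):
            dehydration_series(RL6, charges=())

    def test_mass_monotone_in_modifications(self):
        for z in (1, 3):
            for m in (0, 1):
                masses = [PeptideSpecies(RL6, n, m, z).mz for n in range(9)]
                assert all(a > b for a, b in zip(masses, masses[1:]))
            nem = [PeptideSpecies(RL6, 0, m, z).mz for m in range(6)]  # 5 Cys
            assert all(a < b for a, b in zip(nem, nem[1:]))


class TestAssignPeaks:
    def test_zero_noise_roundtrip_recovers_exact_species(self):
        species = dehydration_series(RL6, charges=(3, 4, 5), nem_range=(0, 1))
        peaks = [(sp.mz, 1.0) for sp in species]
        result = assign_peaks(peaks, species, tol_ppm=10)
        assert not result.unassigned
        recovered = {(a.species.n_dehyd, a.species.n_nem, a.species.charge) for a in result.assignments}
        assert recovered == {(sp.n_dehyd, sp.n_nem, sp.charge) for sp in species}
        assert all(a.ppm_error == 0.0 for a in result.assignments)

    def test_observed_range_report(self):
        species = dehydration_series(RL6, charges=(3,))
        peaks = [(sp.mz, 1.0) for sp in species if sp.n_dehyd in (6, 7, 8)]
        assert assign_peaks(peaks, species).report == "6-8 (8)"

    def test_empty_peaklist_reports_capacity_only(self):
        species = dehydration_series(RL6, charges=(3,))
        assert assign_peaks([], species).report == "(8)"

    def test_noncontiguous_report_uses_commas(self):
        species = dehydration_series(RL6, charges=(3,))
        peaks = [(sp.mz, 1.0) for sp in species if sp.n_dehyd in (5, 6, 8)]
        assert assign_peaks(peaks, species).report == "5-6,8 (8)"

    def test_peak_outside_tolerance_unassigned(self):
        species = dehydration_series(RL6, charges=(3,))
        off = species[0].mz * (1 + 25e-6)  # 25 ppm away
        result = assign_peaks([(off, 1.0)], species, tol_ppm=10)
        assert result.unassigned == [(off, 1.0)]
        assert result.report == "(8)"


def test_format_modification_rendering():
    assert format_modification([6, 7, 8], 8) == "6-8 (8)"
    assert format_modification([6, 7], 9) == "6-7 (9)"
    assert format_modification([6, 8], 9) == "6,8 (9)"
    assert format_modification([], 10) == "(10)"
    assert format_modification([4], 8) == "4 (8)"


class TestRingTopology:
    def test_fully_cyclized_nisin_has_five_rings(self):
        topo = ring_topology(NISIN_Z_CORE, observed_nem_adducts=0)
        assert (topo.n_cys, topo.n_free_cys, topo.n_rings) == (5, 0, 5)

    def test_partial_cyclization(self):
        assert ring_topology(NISIN_Z_CORE, 2).n_rings == 3

    def test_adducts_exceeding_cysteines_rejected(self):
        with pytest.raises(ValueError):
            ring_topology(NISIN_Z_CORE, 6)
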