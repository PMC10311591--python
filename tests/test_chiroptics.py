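"""Boltzmann weighting, Lorentzian broadening, ensemble averaging, label
decomposition and the Hausdorff chirality measure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from edchiro.chiroptics import (
    EPSILON_DEFAULT,
    StickSpectrum,
    boltzmann_weights,
    broaden,
    decompose_by_labels,
    ensemble_average,
    hausdorff_chirality_measure,
    read_sticks,
    renormalize_subset,
    write_sticks,
)
from edchiro.constants import R_KJ
from edchiro.reference import reference_conformers
from edchiro.synthetic import make_stick_spectra, solvent_free_variant
from edchiro.trajectory import DegeneracyError

REF = reference_conformers()


class TestBoltzmannWeights:
    def test_reference_13_conformer_table(self):
        """The published 13-conformer probability column reproduces at
        2 significant figures from the ΔG°TOT values at 300 K."""
        labels = list(REF.labels)
        table = boltzmann_weights([REF.delta_g_tot[l] for l in labels],
                                  temperature=300.0, labels=labels)
        for l in labels:
            printed = REF.p_norm[l]
            # one unit in the last printed digit (2 significant figures)
            ulp = 10.0 ** np.floor(np.log10(abs(printed)) - 1)
            assert table[l] == pytest.approx(printed, abs=ulp), l
        assert table.probabilities.sum() == pytest.approx(1.0)

    def test_equal_dG_equal_weights(self):
        table = boltzmann_weights([1.3] * 4)
        np.testing.assert_allclose(table.probabilities, 0.25)

    def test_rt_ln2_closed_form(self):
        rt = R_KJ * 300.0
        table = boltzmann_weights([0.0, rt * np.log(2.0)], temperature=300.0)
        np.testing.assert_allclose(table.probabilities, [2 / 3, 1 / 3],
                                   rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights([])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=-50.0, max_value=50.0))
    def test_shift_invariance_and_ordering(self, seed, shift):
        r = np.random.default_rng(seed)
        dg = r.uniform(0.0, 10.0, 6)
        a = boltzmann_weights(dg).probabilities
        b = boltzmann_weights(dg + shift).probabilities
        np.testing.assert_allclose(a, b, rtol=1e-9)
        assert a.sum() == pytest.approx(1.0)
        order = np.argsort(dg)
        assert np.all(np.diff(a[order]) <= 1e-15)  # lower dG -> weight >=


class TestRenormalizeSubset:
    def test_subset_c_published_values(self):
        labels = list(REF.labels)
        table = boltzmann_weights([REF.delta_g_tot[l] for l in labels],
                                  temperature=300.0, labels=labels)
        sub = renormalize_subset(table, list(REF.subsets["c"]))
        assert round(sub["B3-1"], 2) == pytest.approx(0.44)
        assert round(sub["B4-1"], 2) == pytest.approx(0.18)
        assert round(sub["B5-2"], 2) == pytest.approx(0.38)

    def test_subset_b_published_values(self):
        labels = list(REF.labels)
        table = boltzmann_weights([REF.delta_g_tot[l] for l in labels],
                                  temperature=300.0, labels=labels)
        sub = renormalize_subset(table, list(REF.subsets["b"]))
        for l, printed in REF.subset_p["b"].items():
            assert round(sub[l], 2) == pytest.approx(printed), l

    def test_subset_a_with_rounding_edge(self):
        """Subset a reproduces within ±0.01; B1-2 is the known edge where
        the computed 0.155 was published as 0.16."""
        labels = list(REF.labels)
        table = boltzmann_weights([REF.delta_g_tot[l] for l in labels],
                                  temperature=300.0, labels=labels)
        sub = renormalize_subset(table, list(REF.subsets["a"]))
        for l, printed in REF.subset_p["a"].items():
            assert sub[l] == pytest.approx(printed, abs=0.01), l
        assert sub["B1-2"] == pytest.approx(0.155, abs=0.001)

    def test_keep_all_is_identity(self):
        table = boltzmann_weights([0.0, 1.0, 2.0], labels=["a", "b", "c"])
        sub = renormalize_subset(table, ["a", "b", "c"])
        np.testing.assert_allclose(sub.probabilities, table.probabilities)

    def test_unknown_label_rejected(self):
        table = boltzmann_weights([0.0], labels=["a"])
        with pytest.raises(KeyError):
            renormalize_subset(table, ["nope"])


class TestBroaden:
    grid = np.linspace(0.5, 8.0, 2001)

    def test_single_line_peak_height(self):
        """Unit rotatory strength: Lorentzian maximum 1/(pi eps) at the line."""
        sticks = StickSpectrum(energies=np.array([3.0]),
                               strengths=np.array([1.0]))
        spec = broaden(sticks, self.grid, epsilon=0.15)
        i = np.argmin(np.abs(self.grid - 3.0))
        assert spec.intensity[i] == pytest.approx(1.0 / (np.pi * 0.15),
                                                  rel=1e-4)

    def test_unit_area(self):
        sticks = StickSpectrum(energies=np.array([4.0]),
                               strengths=np.array([1.0]))
        wide = np.linspace(-200.0, 200.0, 400_001)
        spec = broaden(sticks, wide, epsilon=0.15)
        assert spec.integral() == pytest.approx(1.0, rel=0.01)

    def test_linearity(self):
        e = np.array([2.0, 5.0])
        r = np.array([1.5, -0.7])
        both = broaden(StickSpectrum(energies=e, strengths=r), self.grid)
        parts = sum(
            broaden(StickSpectrum(energies=e[[i]], strengths=r[[i]]),
                    self.grid).intensity
            for i in range(2))
        np.testing.assert_allclose(both.intensity, parts, atol=1e-15)

    def test_integrated_intensity_matches_summed_strengths(self, rng):
        e = rng.uniform(2.0, 4.0, 15)
        r = rng.standard_normal(15)
        wide = np.linspace(-300.0, 300.0, 600_001)
        spec = broaden(StickSpectrum(energies=e, strengths=r), wide)
        assert spec.integral() == pytest.approx(r.sum(), rel=0.01, abs=0.01)

    def test_invalid_inputs(self):
        sticks = StickSpectrum(energies=np.array([1.0]),
                               strengths=np.array([1.0]))
        with pytest.raises(ValueError):
            broaden(sticks, self.grid, epsilon=0.0)
        with pytest.raises(ValueError):
            broaden(sticks, np.array([1.0]))


class TestEnsembleAverage:
    grid = np.linspace(1.0, 6.0, 501)

    def test_single_spectrum_identity(self):
        s = broaden(StickSpectrum(energies=np.array([3.0]),
                                  strengths=np.array([2.0])), self.grid)
        avg = ensemble_average([s], [1.0])
        np.testing.assert_array_equal(avg.intensity, s.intensity)

    def test_identical_spectra_any_weights(self):
        s = broaden(StickSpectrum(energies=np.array([3.0]),
                                  strengths=np.array([2.0])), self.grid)
        avg = ensemble_average([s, s], [0.3, 0.7])
        np.testing.assert_allclose(avg.intensity, s.intensity, rtol=1e-12)

    def test_single_conformer_scaled_by_its_weight(self):
        """Weight-0.13 construction: every grid value is 0.13 x unweighted."""
        s = broaden(StickSpectrum(energies=np.array([2.7, 4.9]),
                                  strengths=np.array([1.0, -0.5])), self.grid)
        scaled = ensemble_average([s], [0.13])
        np.testing.assert_array_equal(scaled.intensity, 0.13 * s.intensity)

    def test_broadening_commutes_with_averaging(self, rng):
        """Averaging sticks then broadening equals broadening then averaging."""
        spectra = make_stick_spectra(3, n_lines=20, seed=5)
        w = np.array([0.5, 0.3, 0.2])
        route1 = ensemble_average(
            [broaden(s, self.grid) for s in spectra], w)
        merged = StickSpectrum(
            energies=np.concatenate([s.energies for s in spectra]),
            strengths=np.concatenate([wi * s.strengths
                                      for wi, s in zip(w, spectra)]))
        route2 = broaden(merged, self.grid)
        np.testing.assert_allclose(route1.intensity, route2.intensity,
                                   atol=1e-12)

    def test_grid_mismatch_rejected(self):
        s1 = broaden(StickSpectrum(energies=np.array([3.0]),
                                   strengths=np.array([1.0])), self.grid)
        s2 = broaden(StickSpectrum(energies=np.array([3.0]),
                                   strengths=np.array([1.0])),
                     self.grid + 0.01)
        with pytest.raises(ValueError):
            ensemble_average([s1, s2], [0.5, 0.5])

    def test_solvent_difference_equals_broadened_stick_difference(self):
        """With-shell minus without-shell spectra equals the broadened
        difference of the stick sets (solvent-effect differencing)."""
        wet = make_stick_spectra(1, n_lines=30, seed=9)[0]
        dry = solvent_free_variant(wet)
        diff_spec = (broaden(wet, self.grid).intensity
                     - broaden(dry, self.grid).intensity)
        dropped = [i for i, (a, b) in enumerate(zip(wet.initial_labels,
                                                    wet.final_labels))
                   if a == "H2O" or b == "H2O"]
        sticks_diff = StickSpectrum(energies=wet.energies[dropped],
                                    strengths=wet.strengths[dropped])
        np.testing.assert_allclose(diff_spec,
                                   broaden(sticks_diff, self.grid).intensity,
                                   atol=1e-12)


class TestDecomposeByLabels:
    grid = np.linspace(1.0, 6.0, 301)

    def test_uniform_labels_single_component(self):
        s = StickSpectrum(energies=np.array([2.0, 3.0]),
                          strengths=np.array([1.0, -1.0]),
                          initial_labels=["AuNC", "AuNC"],
                          final_labels=["AuNC", "AuNC"])
        parts = decompose_by_labels(s, self.grid)
        assert list(parts) == [("AuNC", "AuNC")]
        np.testing.assert_allclose(parts[("AuNC", "AuNC")].intensity,
                                   broaden(s, self.grid).intensity)

    def test_fifty_fifty_split_peak_ratio(self):
        s = StickSpectrum(energies=np.array([3.0, 3.0]),
                          strengths=np.array([0.5, 0.5]),
                          initial_labels=["AuNC", "H2O"],
                          final_labels=["AuNC", "AuNC"])
        parts = decompose_by_labels(s, self.grid)
        i = np.argmin(np.abs(self.grid - 3.0))
        ratio = (parts[("H2O", "AuNC")].intensity[i]
                 / parts[("AuNC", "AuNC")].intensity[i])
        assert ratio == pytest.approx(1.0, rel=1e-12)

    def test_components_sum_to_total(self):
        s = make_stick_spectra(1, n_lines=50, seed=3)[0]
        parts = decompose_by_labels(s, self.grid)
        total = sum(p.intensity for p in parts.values())
        np.testing.assert_allclose(total, broaden(s, self.grid).intensity,
                                   atol=1e-12)

    def test_unlabelled_rejected(self):
        s = StickSpectrum(energies=np.array([2.0]), strengths=np.array([1.0]))
        with pytest.raises(ValueError):
            decompose_by_labels(s, self.grid)


class TestStickIO:
    def test_labelled_round_trip(self, tmp_path):
        s = make_stick_spectra(1, n_lines=12, seed=2)[0]
        path = tmp_path / "sticks.txt"
        write_sticks(s, path)
        back = read_sticks(path)
        np.testing.assert_allclose(back.energies, s.energies, atol=1e-6)
        np.testing.assert_allclose(back.strengths, s.strengths, rtol=1e-6)
        assert back.initial_labels == s.initial_labels
        assert back.final_labels == s.final_labels


CHIRAL_4PT = np.array([
    [0.0, 0.0, 0.0],
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [0.2, 0.3, 0.9],
])


class TestHCM:
    def test_planar_sets_achiral(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.3, 1.2, 0],
                        [-0.5, 0.7, 0]])
        assert hausdorff_chirality_measure(pts) < 1e-6

    def test_enantiomers_have_equal_hcm(self):
        mirror = CHIRAL_4PT * np.array([1.0, 1.0, -1.0])
        a = hausdorff_chirality_measure(CHIRAL_4PT)
        b = hausdorff_chirality_measure(mirror)
        assert a == pytest.approx(b, abs=1e-6)
        assert a > 0.01

    def test_rigid_motion_and_scale_invariance(self, rng):
        rot = Rotation.random(random_state=4).as_matrix()
        moved = 3.7 * CHIRAL_4PT @ rot.T + rng.standard_normal(3)
        a = hausdorff_chirality_measure(CHIRAL_4PT)
        b = hausdorff_chirality_measure(moved)
        assert a == pytest.approx(b, abs=1e-5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegeneracyError):
            hausdorff_chirality_measure(np.zeros((3, 3)))
        with pytest.raises(DegeneracyError):
            hausdorff_chirality_measure(np.zeros((1, 3)))

    def test_bounded_below_one(self, rng):
        pts = rng.standard_normal((12, 3))
        v = hausdorff_chirality_measure(pts)
        assert 0.0 <= v < 1.0
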