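"""Spectra, conditional cell probabilities and expectation ranges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairkin import (KCoefficients, RELATIONSHIPS, SpectrumModel,
                     demography_spectrum, expectation_range, expected_cells,
                     expected_stats, ibd_conditional_cells, king_kinship,
                     r0, r1)
from pairkin.expectations import default_grid
from .conftest import oracle_ibd_cells


class TestSpectrumModel:
    def test_point_mass_and_sampling(self, rng):
        sp = SpectrumModel.point_mass(0.3)
        assert (sp.sample(rng, 50) == 0.3).all()

    def test_weights_normalized(self):
        sp = SpectrumModel([0.1, 0.4], [2.0, 6.0])
        assert sp.w.sum() == pytest.approx(1.0)
        assert sp.w[1] == pytest.approx(0.75)

    def test_invalid_frequencies_rejected(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                SpectrumModel.point_mass(bad)

    def test_folded_unfolds_symmetrically(self):
        sp = SpectrumModel.folded([0.1, 0.5], [0.5, 0.5])
        assert set(np.round(sp.p, 6)) == {0.1, 0.5, 0.9}
        w = dict(zip(np.round(sp.p, 6), sp.w))
        assert w[0.1] == pytest.approx(w[0.9])
        with pytest.raises(ValueError, match="p <= 0.5"):
            SpectrumModel.folded([0.7], [1.0])

    def test_neutral_constant_weights_follow_one_over_j(self):
        sp = SpectrumModel.neutral_constant(10)
        assert sp.p[0] == pytest.approx(0.1)
        assert sp.w[0] / sp.w[4] == pytest.approx(5.0)

    def test_demography_names(self):
        for name in ("constant", "expansion", "decline"):
            assert demography_spectrum(name).p.size == 39
        with pytest.raises(ValueError, match="unknown demography"):
            demography_spectrum("boom")

    def test_empirical_spectrum_counts_duplicates(self):
        sp = SpectrumModel.empirical([0.2, 0.2, 0.4])
        assert dict(zip(sp.p, sp.w))[0.2] == pytest.approx(2 / 3)


class TestIbdConditionalCells:
    def test_ibd2_is_hardy_weinberg_diagonal(self):
        _, _, m2 = ibd_conditional_cells(0.5)
        assert np.allclose(np.diag(m2), [0.25, 0.5, 0.25])
        assert np.allclose(m2 - np.diag(np.diag(m2)), 0)

    def test_ibd1_half_frequency_cells(self):
        _, m1, _ = ibd_conditional_cells(0.5)
        assert m1[1, 1] == pytest.approx(0.25)
        assert m1[0, 2] == 0 and m1[2, 0] == 0

    def test_ibd0_is_outer_product_of_margins(self):
        m0, _, _ = ibd_conditional_cells(0.3)
        q = 0.7
        hw = np.array([q * q, 2 * 0.3 * q, 0.09])
        assert np.allclose(m0, np.outer(hw, hw))

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=60)
    def test_matches_enumeration_oracle_and_normalizes(self, p):
        got = ibd_conditional_cells(p)
        want = oracle_ibd_cells(p)
        for g, w in zip(got, want):
            assert np.allclose(g, w, atol=1e-12)
            assert g.sum() == pytest.approx(1.0)

    def test_out_of_range_frequency_raises(self):
        with pytest.raises(ValueError):
            ibd_conditional_cells(1.0)

    def test_vectorized_matches_scalar(self):
        ps = np.array([0.2, 0.4])
        m0v, m1v, m2v = ibd_conditional_cells(ps)
        for j, p in enumerate(ps):
            m0, m1, m2 = ibd_conditional_cells(p)
            assert np.allclose(m0v[j], m0)
            assert np.allclose(m1v[j], m1)
            assert np.allclose(m2v[j], m2)


class TestExpectedCells:
    def test_po_point_mass_anchors(self):
        cells = expected_cells(RELATIONSHIPS["PO"], SpectrumModel.point_mass(0.5))
        assert cells.e == pytest.approx(0.25)
        assert cells.opposing_homozygotes == 0
        assert (r1(cells), r0(cells)) == (pytest.approx(0.5), 0.0)

    def test_fs_point_mass_triple(self):
        cells = expected_cells(RELATIONSHIPS["FS"], SpectrumModel.point_mass(0.5))
        assert r0(cells) == pytest.approx(0.1)
        assert r1(cells) == pytest.approx(10 / 13)
        assert king_kinship(cells) == pytest.approx(0.25)

    def test_ur_null_for_arbitrary_spectrum(self, constant_spectrum):
        cells = expected_cells(RELATIONSHIPS["UR"], constant_spectrum)
        assert king_kinship(cells) == pytest.approx(0.0, abs=1e-12)
        assert r0(cells) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(0.05, 0.95), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=60)
    def test_cells_sum_to_one(self, p, a, b):
        tot = a + b + 1.0
        k = KCoefficients(a / tot, b / tot, 1.0 / tot)
        cells = expected_cells(k, SpectrumModel.point_mass(p))
        assert cells.n_sites == pytest.approx(1.0)


class TestExpectationRange:
    @pytest.fixture(scope="class")
    def ranges(self):
        return {lab: expectation_range(RELATIONSHIPS[lab])
                for lab in ("PO", "FS", "HS", "C1", "UR")}

    def test_po_range_is_a_single_point(self, ranges):
        po = ranges["PO"]
        assert po.r0_min == po.r0_max == 0.0
        assert po.r1_min == pytest.approx(0.5, abs=1e-12)
        assert po.r1_max == pytest.approx(0.5, abs=1e-12)
        assert po.kinship_min == pytest.approx(0.25)

    def test_ur_ranges_degenerate(self, ranges):
        ur = ranges["UR"]
        assert ur.r0_min == pytest.approx(0.5, abs=1e-9)
        assert ur.r0_max == pytest.approx(0.5, abs=1e-9)
        assert abs(ur.kinship_min) < 1e-9 and abs(ur.kinship_max) < 1e-9

    def test_expected_kinship_equals_theta_for_every_spectrum(self, ranges):
        for lab, er in ranges.items():
            theta = RELATIONSHIPS[lab].theta
            assert er.kinship_min == pytest.approx(theta, abs=1e-9)
            assert er.kinship_max == pytest.approx(theta, abs=1e-9)

    def test_fs_r0_extremes_bracketed_by_point_masses(self):
        """The FS R0 range endpoints are attained at the grid's end point
        masses (p -> 0 gives R0 -> 0, p = 0.5 gives the maximum 0.1)."""
        er = expectation_range(RELATIONSHIPS["FS"])
        grid = default_grid()
        lo = expected_stats(RELATIONSHIPS["FS"], SpectrumModel.point_mass(grid[0]))
        hi = expected_stats(RELATIONSHIPS["FS"], SpectrumModel.point_mass(0.5))
        assert er.r0_min == pytest.approx(lo[1], abs=1e-12)
        assert er.r0_max == pytest.approx(hi[1], abs=1e-12)
        assert er.r0_max == pytest.approx(0.1)

    def test_close_relationship_regions_do_not_overlap(self, ranges, rng):
        """FS/HS/C1/UR joint (R1, R0) regions are pairwise disjoint over all
        spectra, which is what makes spectrum-free classification possible."""
        labs = ["FS", "HS", "C1", "UR"]
        clouds = {}
        for lab in labs:
            pts = ranges[lab].joint_r1r0
            clouds[lab] = pts[rng.choice(len(pts), 4000, replace=False)]
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                d2 = ((clouds[a][:, None, :] - clouds[b][None, :, :]) ** 2
                      ).sum(-1)
                assert np.sqrt(d2.min()) > 0.05, (a, b)

    def test_po_point_touches_only_fs(self, ranges):
        po = np.array([0.5, 0.0])
        dist = {lab: np.sqrt(((ranges[lab].joint_r1r0 - po) ** 2).sum(1)).min()
                for lab in ("FS", "HS", "C1", "UR")}
        assert dist["FS"] < 0.01
        assert all(dist[lab] > 0.1 for lab in ("HS", "C1", "UR"))

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="at least 100"):
            expectation_range(RELATIONSHIPS["FS"], np.linspace(0.01, 0.5, 10))
        with pytest.raises(ValueError, match="empty"):
            expectation_range(RELATIONSHIPS["FS"], np.array([]))
        with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
            expectation_range(RELATIONSHIPS["FS"], np.linspace(0.1, 0.9, 200))
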