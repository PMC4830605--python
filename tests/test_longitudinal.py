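import numpy as np
import pandas as pd
import pytest

import blastmap as bm
from blastmap.io import PanelMismatchError, ParameterError
from blastmap.longitudinal import SubpopulationProfile
from blastmap.populations import UNASSIGNED, BlastArea

from conftest import make_coords_embedding


def _area_from_blobs(seed=0):
    rng = np.random.default_rng(seed)
    coords = np.vstack([rng.normal((-15, 0), 1, (400, 2)),
                        rng.normal((15, 0), 1, (400, 2))])
    part = bm.density_islands(make_coords_embedding(coords))
    labels = bm.imported_labels(["blast"] * 400 + ["other"] * 400)
    area = bm.define_blast_area(part, labels)
    return area, coords, part


class TestBlastAreaOccupancy:
    def test_events_on_mask_cells_are_fully_inside(self):
        area, coords, part = _area_from_blobs()
        blast_island = next(iter(area.member_islands))
        inside_pts = coords[:400][part.island_id[:400] == blast_island]
        occ = bm.blast_area_occupancy([("s", inside_pts)], area)
        assert occ.loc[0, "fraction_inside"] == 1.0
        assert occ.loc[0, "fraction_outside"] == 0.0

    def test_matches_bruteforce_point_in_mask(self):
        area, _, _ = _area_from_blobs()
        rng = np.random.default_rng(1)
        pts = rng.uniform(-25, 25, size=(2000, 2))
        occ = bm.blast_area_occupancy([("r", pts)], area)
        xmin, xmax, ymin, ymax = area.grid_extent
        nx, ny = area.grid_mask.shape
        inside = 0
        for x, y in pts:
            ix = min(max(int((x - xmin) / (xmax - xmin) * nx), 0), nx - 1)
            iy = min(max(int((y - ymin) / (ymax - ymin) * ny), 0), ny - 1)
            inside += bool(area.grid_mask[ix, iy])
        assert occ.loc[0, "fraction_inside"] == pytest.approx(inside / 2000)

    def test_fractions_sum_to_one(self):
        area, coords, _ = _area_from_blobs()
        occ = bm.blast_area_occupancy(
            [("a", coords[:100]), ("b", coords[500:])], area)
        assert np.allclose(occ["fraction_inside"] + occ["fraction_outside"], 1.0)

    def test_empty_mask_warns_and_reports_zero(self, caplog):
        area, coords, _ = _area_from_blobs()
        empty = BlastArea(member_islands=frozenset(),
                          grid_mask=np.zeros_like(area.grid_mask),
                          grid_extent=area.grid_extent)
        with caplog.at_level("WARNING"):
            occ = bm.blast_area_occupancy([("s", coords)], empty)
        assert occ.loc[0, "fraction_inside"] == 0.0
        assert any("empty" in r.message for r in caplog.records)


class TestAbundanceTable:
    def test_counting(self):
        labels = bm.imported_labels(["1"] * 40 + ["2"] * 60)
        tp = ["day0"] * 100
        abund = bm.abundance_table(labels, tp)
        assert abund.loc["1", "day0"] == pytest.approx(0.40)

    def test_columns_sum_to_one_with_unassigned_row(self):
        labels = bm.imported_labels(["1"] * 50 + [UNASSIGNED] * 30 + ["2"] * 20)
        tp = ["day0"] * 60 + ["day14"] * 40
        abund = bm.abundance_table(labels, tp)
        assert UNASSIGNED in abund.index
        assert np.allclose(abund.sum(axis=0), 1.0)

    def test_zero_blast_timepoint_errors(self):
        labels = bm.imported_labels(["1", "1"])
        with pytest.raises(ParameterError, match="day14"):
            bm.abundance_table(labels, ["day0", "day0"],
                               timepoints=["day0", "day14"])


class TestMedianProfiles:
    def _matrix(self, panel, vals, labels):
        return (bm.EventMatrix(vals, panel, scale="arcsinh", cofactor=15.0),
                bm.imported_labels(labels))

    def test_odd_count_median(self, panel):
        vals = np.full((3, 27), 1.0)
        vals[:, panel.index("CD34")] = [0.1, 0.9, 2.0]
        m, lab = self._matrix(panel, vals, ["a"] * 3)
        (prof,) = bm.median_profiles(m, lab)
        assert prof.median_expression[panel.index("CD34")] == 0.9

    def test_single_event_subpop_is_itself(self, panel):
        vals = np.arange(27, dtype=float).reshape(1, 27)
        m, lab = self._matrix(panel, vals, ["solo"])
        (prof,) = bm.median_profiles(m, lab)
        assert np.array_equal(prof.median_expression, vals[0])

    def test_matches_sort_and_pick_oracle(self, panel):
        rng = np.random.default_rng(2)
        vals = np.abs(rng.normal(1, 1, size=(13 * 40, 27)))
        labels = [f"s{i:02d}" for i in range(13) for _ in range(40)]
        m, lab = self._matrix(panel, vals, labels)
        profs = {p.subpop_id: p.median_expression
                 for p in bm.median_profiles(m, lab)}
        for i in range(13):
            block = vals[i * 40:(i + 1) * 40]
            expect = [sorted(block[:, j])[(40 - 1) // 2] for j in range(27)]
            assert np.array_equal(profs[f"s{i:02d}"], expect)


class TestMarkerShift:
    def _single_marker_matrices(self, panel, pre_val, post_val, n=51):
        pre = np.full((n, 27), 0.5)
        post = np.full((n, 27), 0.5)
        pre[:, panel.index("CD34")] = pre_val
        post[:, panel.index("CD34")] = post_val
        mk = lambda v: bm.EventMatrix(v, panel, scale="arcsinh", cofactor=15.0)
        return mk(pre), mk(post)

    def test_additive_arcsinh_change(self, panel):
        pre, post = self._single_marker_matrices(panel, 1.0, 1.7)
        shifts = {s.marker: s.delta_median for s in bm.marker_shift(pre, post)}
        assert shifts["CD34"] == pytest.approx(0.7)

    def test_null_case_all_zero(self, panel):
        pre, post = self._single_marker_matrices(panel, 1.0, 1.0)
        assert all(s.delta_median == 0 for s in bm.marker_shift(pre, post))

    def test_antisymmetry_exact(self, healthy_spec):
        a, _ = bm.generate_sample(healthy_spec, "marrow", 400, seed=3)
        b, _ = bm.generate_sample(healthy_spec, "marrow", 400, seed=4)
        fwd = bm.marker_shift(a, b)
        rev = bm.marker_shift(b, a)
        for f, r in zip(fwd, rev):
            assert f.delta_median == -r.delta_median

    def test_weighted_profile_variant(self):
        mk = lambda v: np.asarray(v, dtype=float)
        pre = [SubpopulationProfile("1", mk([1.0, 2.0]), {}),
               SubpopulationProfile("2", mk([3.0, 2.0]), {})]
        post = [SubpopulationProfile("1", mk([2.0, 2.0]), {})]
        out = bm.marker_shift(pre, post, pre_weights={"1": 0.75, "2": 0.25},
                              post_weights={"1": 1.0},
                              marker_names=["m1", "m2"])
        # pre weighted: 0.75*1 + 0.25*3 = 1.5 -> delta m1 = 0.5
        assert out[0].marker == "m1"
        assert out[0].delta_median == pytest.approx(0.5)
        assert out[1].delta_median == pytest.approx(0.0)

    def test_null_scenario_small_deltas_across_seeds(self):
        """Two draws from the same spec give |delta| < 0.1 for every marker
        at n=5000 in at least 9 of 10 seeds."""
        spec = bm.refractory_spec()
        good = 0
        for seed in range(10):
            a, _ = bm.generate_sample(spec, "day0", 5000, seed=2 * seed)
            b, _ = bm.generate_sample(spec, "day0", 5000, seed=2 * seed + 1)
            deltas = [abs(s.delta_median) for s in bm.marker_shift(a, b)]
            if max(deltas) < 0.1:
                good += 1
        assert good >= 9

    def test_panel_mismatch_rejected(self, panel, healthy_spec):
        a, _ = bm.generate_sample(healthy_spec, "marrow", 50, seed=5)
        small = bm.MarkerPanel(panel.markers[:5])
        b = bm.EventMatrix(a.values[:, :5], small, scale="arcsinh")
        with pytest.raises(PanelMismatchError):
            bm.marker_shift(a, b)


class TestMarkerSdRanking:
    @staticmethod
    def _profiles(mat):
        return [SubpopulationProfile(str(i), np.asarray(row, dtype=float), {})
                for i, row in enumerate(mat)]

    def test_constant_marker_ranked_last_with_zero_sd(self):
        mat = [[0.0, 1.0], [0.0, 3.0], [0.0, 5.0]]
        out = bm.marker_sd_ranking(self._profiles(mat), ["flat", "vary"])
        assert out[-1] == ("flat", 0.0)
        assert out[0][0] == "vary"

    def test_two_value_sd_uses_n_minus_one(self):
        out = bm.marker_sd_ranking(self._profiles([[0.0], [2.0]]), ["m"])
        assert out[0][1] == pytest.approx(np.sqrt(2.0))

    def test_single_subpopulation_errors(self):
        with pytest.raises(ParameterError):
            bm.marker_sd_ranking(self._profiles([[1.0]]), ["m"])

    def test_tie_break_on_marker_name(self):
        mat = [[0.0, 0.0], [1.0, 1.0]]
        out = bm.marker_sd_ranking(self._profiles(mat), ["b", "a"])
        assert [m for m, _ in out] == ["a", "b"]


class TestPersistence:
    def test_summed_occupancy(self):
        abund = pd.DataFrame(
            {"day0": [0.93 / 6] * 6 + [0.01] * 7,
             "day14": [0.118 / 6] * 6 + [0.126] * 7},
            index=pd.Index([f"{i}" for i in range(1, 14)], name="subpopulation"))
        dom = {f"{i}" for i in range(1, 7)}
        per = {f"{i}" for i in range(7, 14)}
        pre, post = bm.persistence_report(abund, dom, per, "day0", "day14")
        assert pre == pytest.approx(0.07)
        assert post == pytest.approx(0.882)

    def test_empty_persister_set(self):
        abund = pd.DataFrame({"day0": [1.0], "day14": [1.0]},
                             index=pd.Index(["1"], name="subpopulation"))
        assert bm.persistence_report(abund, {"1"}, set(), "day0", "day14") == \
            (0.0, 0.0)

    def test_overlapping_sets_rejected(self):
        abund = pd.DataFrame({"day0": [0.5, 0.5], "day14": [0.5, 0.5]},
                             index=pd.Index(["1", "2"], name="subpopulation"))
        with pytest.raises(ParameterError):
            bm.persistence_report(abund, {"1", "2"}, {"2"}, "day0", "day14")

    def test_designation_splits_by_gaining_share(self):
        abund = pd.DataFrame({"day0": [0.6, 0.3, 0.1],
                              "day14": [0.1, 0.5, 0.4]},
                             index=pd.Index(["1", "2", UNASSIGNED],
                                            name="subpopulation"))
        dom, per = bm.designate_persisters(abund, "day0", "day14")
        assert dom == {"1"} and per == {"2"}
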