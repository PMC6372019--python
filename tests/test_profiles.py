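"""Profile extraction, region assignment, QC filtering, regional averaging."""

import numpy as np
import pytest
from oracles import pearson_formula

from cytoconn.profiles import (
    EKLayerTable,
    LabelIndex,
    PointPair,
    Profile,
    assign_region,
    compare_profiles,
    ek_profile,
    extract_profile,
    nearest_neighbor_pairs,
    qc_filter,
    regional_profiles,
)


def vpair(pid, x, y0=0.0, y1=2.0, section="0"):
    """Vertical pair at abscissa x: pial on top, wm below."""
    return PointPair(pair_id=pid, pial=(x, y0), wm=(x, y1), section_id=section)


class TestNearestNeighborPairs:
    def test_collinear_matches_exhaustive_oracle(self):
        pairs = [vpair(0, 0.0), vpair(1, 1.0), vpair(2, 5.0)]
        nn = nearest_neighbor_pairs(pairs)
        mids = {p.pair_id: p.midpoint for p in pairs}
        for p in pairs:
            d = {
                q.pair_id: np.linalg.norm(mids[p.pair_id] - mids[q.pair_id])
                for q in pairs
                if q.pair_id != p.pair_id
            }
            best = min(sorted(d), key=lambda k: d[k])
            assert nn[p.pair_id] == (best, pytest.approx(d[best]))
        assert nn[0][0] == 1 and nn[2][0] == 1

    def test_two_pairs_are_mutual(self):
        nn = nearest_neighbor_pairs([vpair(0, 0.0), vpair(1, 3.0)])
        assert nn[0][0] == 1 and nn[1][0] == 0

    def test_duplicate_midpoints_break_ties_by_lowest_id(self):
        pairs = [vpair(5, 0.0), vpair(3, 1.0), vpair(4, 1.0)]
        nn = nearest_neighbor_pairs(pairs)
        assert nn[5][0] == 3  # pairs 3 and 4 are equidistant

    def test_single_pair_section_flagged_unpaired(self):
        nn = nearest_neighbor_pairs([vpair(0, 0.0, section="a"),
                                     vpair(1, 0.0, section="b"),
                                     vpair(2, 3.0, section="b")])
        assert nn[0] == (None, np.inf)
        assert nn[1][0] == 2

    def test_search_restricted_within_section(self):
        pairs = [vpair(0, 0.0, section="a"), vpair(1, 0.1, section="b"),
                 vpair(2, 9.0, section="a"), vpair(3, 9.1, section="b")]
        nn = nearest_neighbor_pairs(pairs)
        assert nn[0][0] == 2 and nn[1][0] == 3


def rect_quad(x0=10.0, x1=20.0, y0=10.0, y1=50.0):
    """Axis-aligned rectangular quadrilateral: pial edge at y0, wm at y1."""
    pair = PointPair(pair_id=0, pial=(x0, y0), wm=(x0, y1))
    nb = PointPair(pair_id=1, pial=(x1, y0), wm=(x1, y1))
    return pair, nb


class TestExtractProfile:
    def test_constant_image(self):
        img = np.full((64, 64), 0.4)
        prof = extract_profile(img, *rect_quad())
        assert prof.values.shape == (1000,)
        assert np.allclose(prof.values, 0.4)

    def test_profile_length_is_1000(self):
        img = np.random.default_rng(0).random((64, 64))
        assert len(extract_profile(img, *rect_quad()).values) == 1000

    def test_two_band_image_plateaus_and_monotone_transition(self):
        """Top half 1.0, bottom half 0.0: exact plateaus away from the band
        boundary; the transition is monotone and confined to the strata
        within the one-pixel bilinear ramp around the boundary."""
        img = np.zeros((64, 64))
        img[:30, :] = 1.0  # boundary between pixel rows 29 and 30
        prof = extract_profile(img, *rect_quad(y0=10.0, y1=50.0))
        v = prof.values
        # depth of the ramp window y in [29, 30] -> v in [0.475, 0.5]
        assert np.all(v[:470] == 1.0)
        assert np.all(v[505:] == 0.0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_linear_gradient_matches_closed_form(self):
        """Bilinear interpolation is exact on a linear intensity field, so
        stratum k must equal the gradient at depth (k + 0.5)/1000."""
        img = np.tile(np.arange(64, dtype=float)[:, None], (1, 64))
        prof = extract_profile(img, *rect_quad(y0=10.0, y1=50.0))
        k = np.arange(1000)
        expected = 10.0 + 40.0 * (k + 0.5) / 1000.0
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_intensity_scaling_is_linear(self):
        rng = np.random.default_rng(1)
        img = rng.random((64, 64))
        a = extract_profile(img, *rect_quad()).values
        b = extract_profile(3.5 * img, *rect_quad()).values
        assert np.allclose(b, 3.5 * a, atol=1e-12)

    def test_depth_orientation(self):
        """On an image whose intensity increases with depth, profiles are
        non-decreasing."""
        img = np.tile(np.arange(64, dtype=float)[:, None], (1, 64))
        prof = extract_profile(img, *rect_quad())
        assert np.all(np.diff(prof.values) >= -1e-12)

    def test_degenerate_quadrilateral_rejected(self):
        img = np.zeros((32, 32))
        pair = PointPair(pair_id=0, pial=(5.0, 5.0), wm=(5.0, 15.0))
        nb = PointPair(pair_id=1, pial=(5.0, 5.0 + 1e-12), wm=(5.0, 15.0))
        with pytest.raises(ValueError, match="degenerate"):
            extract_profile(img, pair, nb)

    def test_missing_neighbor_rejected(self):
        with pytest.raises(ValueError, match="neighbor"):
            extract_profile(np.zeros((8, 8)), vpair(0, 1.0), None)


class TestAssignRegion:
    def test_midpoint_on_labeled_pixel(self):
        labels = np.zeros((9, 9), dtype=int)
        labels[4, 4] = 3
        pair = PointPair(pair_id=0, pial=(4.0, 3.0), wm=(4.0, 5.0))
        assert assign_region(pair, labels) == (3, 0.0)

    def test_equidistant_tie_goes_to_lower_region_id(self):
        labels = np.zeros((5, 9), dtype=int)
        labels[0, 0] = 5
        labels[0, 2] = 3
        pair = PointPair(pair_id=0, pial=(1.0, 0.0), wm=(1.0, 0.5))
        # midpoint (1, 0.25) equidistant from pixels (0,0) and (2,0)
        region, d = assign_region(pair, labels)
        assert region == 3
        assert d == pytest.approx(np.hypot(1.0, 0.25))

    def test_matches_exhaustive_scan_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            labels = np.zeros((15, 15), dtype=int)
            n_lab = rng.integers(3, 15)
            ys = rng.integers(0, 15, n_lab)
            xs = rng.integers(0, 15, n_lab)
            labels[ys, xs] = rng.integers(1, 6, n_lab)
            mid = rng.uniform(0, 14, 2)
            pair = PointPair(pair_id=0, pial=mid - (0.0, 0.5), wm=mid + (0.0, 0.5))
            # brute force with the same deterministic tie rule
            yy, xx = np.nonzero(labels)
            d = np.hypot(xx - mid[0], yy - mid[1])
            dmin = d.min()
            ties = np.nonzero(d <= dmin + 1e-9)[0]
            expected = min(labels[yy[t], xx[t]] for t in ties)
            region, dist = assign_region(pair, labels)
            assert region == expected
            assert dist == pytest.approx(dmin)

    def test_empty_label_map_rejected(self):
        with pytest.raises(ValueError, match="no labeled"):
            LabelIndex(np.zeros((4, 4), dtype=int))


def make_profile(pid, region, dist, nn_id, seglen=10.0):
    return Profile(
        values=np.zeros(10),
        pair_id=pid,
        region=region,
        nn_pair_id=nn_id,
        voxel_distance=dist,
        segment_length=seglen,
    )


class TestQcFilter:
    def test_far_outlier_excluded_by_iqr_rule(self):
        dists = [1.0, 1.0, 1.0, 1.0, 100.0]
        profs = [make_profile(i, 1, d, (i + 1) % 5) for i, d in enumerate(dists)]
        kept = qc_filter(profs)
        # quantile oracle (linear interpolation convention)
        q1, q3 = np.quantile(dists, [0.25, 0.75])
        assert 100.0 > q3 + 1.5 * (q3 - q1)
        assert {p.pair_id for p in kept} == {0, 1, 2, 3}
        assert profs[4].excluded_reason == "iqr_outlier"

    def test_identical_distances_keep_everything(self):
        profs = [make_profile(i, 1, 2.0, (i + 1) % 4) for i in range(4)]
        assert len(qc_filter(profs)) == 4

    def test_boundary_crossing_pairs_both_excluded(self):
        profs = [
            make_profile(0, 3, 1.0, 1),
            make_profile(1, 5, 1.0, 0),
            make_profile(2, 5, 1.0, 1),
            make_profile(3, 5, 1.0, 2),
        ]
        kept = qc_filter(profs)
        assert {p.pair_id for p in kept} == {2, 3}
        assert profs[0].excluded_reason == "boundary_crossing"
        assert profs[1].excluded_reason == "boundary_crossing"

    def test_iqr_rule_applies_before_boundary_rule(self):
        profs = [make_profile(i, 1, 1.0, (i + 1) % 6) for i in range(6)]
        profs.append(make_profile(6, 2, 50.0, 0))  # outlier AND boundary-crosser
        qc_filter(profs)
        assert profs[6].excluded_reason == "iqr_outlier"

    def test_empty_input_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cytoconn.profiles"):
            assert qc_filter([]) == []
        assert "no profiles" in caplog.text


class TestRegionalProfiles:
    def test_min_count_threshold_excludes_small_regions(self):
        profs = [make_profile(i, 1, 0.0, 0) for i in range(19)]
        (rp,) = regional_profiles(profs, min_count=20)
        assert rp.n_profiles == 19 and not rp.included
        (rp,) = regional_profiles(profs, min_count=19)
        assert rp.included

    def test_mean_of_identical_profiles(self):
        v = np.linspace(0, 1, 10)
        profs = [
            Profile(values=v, pair_id=i, region=2, segment_length=5.0)
            for i in range(2)
        ]
        (rp,) = regional_profiles(profs, min_count=0)
        assert np.array_equal(rp.mean_profile, v)
        assert rp.mean_thickness == 5.0

    def test_zero_min_count_includes_all_regions(self):
        profs = [make_profile(i, r, 0.0, 0) for i, r in enumerate([1, 2, 2])]
        out = regional_profiles(profs, min_count=0)
        assert all(rp.included for rp in out)
        assert [rp.region for rp in out] == [1, 2]


class TestEkProfile:
    def test_single_layer_constant(self):
        t = EKLayerTable([1.0], [2.0], [3.0])
        assert np.all(ek_profile(t) == 6.0)

    def test_layer_boundary_step_count(self):
        t = EKLayerTable([0.3, 0.7], [1.0, 2.0], [1.0, 1.0])
        prof = ek_profile(t)
        assert (prof == 1.0).sum() == 300
        assert (prof == 2.0).sum() == 700

    def test_increasing_layer_values_give_nondecreasing_profile(self):
        t = EKLayerTable([0.2, 0.3, 0.5], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert np.all(np.diff(ek_profile(t)) >= 0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EKLayerTable([0.3, 0.6], [1.0, 1.0], [1.0, 1.0])


class TestCompareProfiles:
    def test_self_correlation_is_one(self):
        a = np.sin(np.linspace(0, 3, 1000))
        assert compare_profiles(a, a) == pytest.approx(1.0)

    def test_sign_flip(self):
        a = np.sin(np.linspace(0, 3, 1000))
        assert compare_profiles(a, -a) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.arange(1000, dtype=float)
        b = a**2
        assert compare_profiles(a, b) == pytest.approx(
            pearson_formula(a, b), abs=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_profiles(np.ones(10), np.arange(10.0))


class TestRecovery:
    def test_noise_free_recovery_of_truth_profiles(self, recovered_regional):
        """Extraction round-trip: on a noise-free section the regional mean
        profiles must track the planted truth curves almost perfectly."""
        regional, truth = recovered_regional
        included = [r for r in regional if r.included]
        assert len(included) >= 5
        for rp in included:
            assert compare_profiles(rp.mean_profile, truth[rp.region]) > 0.99
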