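"""Viability pipeline: projection, Otsu, watershed, registration, death area."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from chondroview.stack import ChannelError, MicrographStack
from chondroview.synth import (
    FieldSpec,
    ImpactSpec,
    generate_impact_pair,
    render_discs,
)
from chondroview.viability import (
    ViabilityParams,
    analyze_pair,
    classify_viability,
    max_intensity_projection,
    otsu_threshold,
    quantify_viability,
    register_roi,
    segment_cells,
)
from conftest import disc_mask


def brute_force_otsu(values: np.ndarray) -> int:
    """Independent oracle: exhaustive scan of all 256 integer thresholds.

    For each candidate t, class statistics are recomputed from the raw
    pixels partitioned at <= t, and the best between-class variance wins
    (lowest t on ties).
    """
    values = values.ravel().astype(float)
    best_t, best_s = None, -np.inf
    for t in range(256):
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_t, best_s = t, s
    return best_t


class TestProjection:
    def test_single_plane_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        stack = MicrographStack(img[None, None], ("live",), 1.0)
        np.testing.assert_array_equal(max_intensity_projection(stack, "live"), img)

    def test_two_planes_take_elementwise_max(self):
        a = np.array([[1.0, 5.0], [3.0, 0.0]])
        b = np.array([[2.0, 4.0], [1.0, 7.0]])
        stack = MicrographStack(np.stack([a, b])[:, None], ("live",), 1.0)
        np.testing.assert_array_equal(
            max_intensity_projection(stack, "live"), np.maximum(a, b)
        )

    def test_matches_plane_loop_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        planes = rng.random((5, 1, 16, 16))
        stack = MicrographStack(planes, ("live",), 1.0)
        mip = max_intensity_projection(stack, "live")
        oracle = planes[0, 0].copy()
        for k in range(1, 5):
            oracle = np.maximum(oracle, planes[k, 0])
        np.testing.assert_array_equal(mip, oracle)
        again = max_intensity_projection(
            MicrographStack(mip[None, None], ("live",), 1.0), "live"
        )
        np.testing.assert_array_equal(again, mip)

    def test_unknown_channel_names_available_ones(self):
        stack = MicrographStack(np.zeros((1, 2, 4, 4)), ("live", "dead"), 1.0)
        with pytest.raises(ChannelError, match="live"):
            max_intensity_projection(stack, "expression")


class TestOtsu:
    def test_two_point_histogram_separates_halves(self):
        img = np.array([0] * 50 + [100] * 50, dtype=np.uint8)
        t = otsu_threshold(img)
        assert 0 <= t < 100
        assert ((img > t) == (img == 100)).all()

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_integer_scan(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish mixture over the 8-bit range
        img = np.concatenate(
            [rng.normal(60, 25, 600), rng.normal(180, 20, 400)]
        ).clip(0, 255).astype(np.uint8)
        assert otsu_threshold(img) == brute_force_otsu(img)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, st.integers(32, 256)))
    def test_equals_exhaustive_scan_on_arbitrary_uint8(self, img):
        if img.min() == img.max():
            return
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_bimodal_threshold_minimizes_misclassification(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(30, 10, 5000).clip(0, 255)
        hi = rng.normal(180, 10, 5000).clip(0, 255)
        img = np.concatenate([lo, hi]).astype(np.uint8)
        t = otsu_threshold(img)
        err_t = (lo > t).sum() + (hi <= t).sum()
        errs = [(lo > c).sum() + (hi <= c).sum() for c in range(256)]
        assert err_t <= min(errs) + 0.001 * img.size  # near-optimal split

    def test_float_image_uses_256_bin_histogram(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(0.2, 0.05, 500), rng.normal(0.8, 0.05, 500)])
        t = otsu_threshold(img)
        assert 0.3 < t < 0.7


class TestSegmentation:
    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_recovers_k_nontouching_discs(self, k):
        side = int(np.ceil(np.sqrt(k)))
        centers = np.array(
            [[40 + 60 * (i // side), 40 + 60 * (i % side)] for i in range(k)],
            dtype=float,
        )
        r = 12.0
        shape = (60 * side + 20, 60 * side + 20)
        img = render_discs(shape, centers, np.full(k, r), 200.0, 10.0)
        seg = segment_cells(img > 100, {"img": img}, pixel_size=1.0)
        assert seg.n_cells == k
        got = seg.cells.sort_values(["centroid_row", "centroid_col"])
        want = centers[np.lexsort((centers[:, 1], centers[:, 0]))]
        np.testing.assert_allclose(
            got[["centroid_row", "centroid_col"]].to_numpy(), want, atol=1.0
        )
        np.testing.assert_allclose(
            got["area_um2"].to_numpy(), np.pi * r**2, rtol=0.05
        )

    def test_watershed_splits_two_overlapping_discs(self):
        img = np.zeros((64, 64), dtype=bool)
        img |= disc_mask((64, 64), (32, 24), 10)
        img |= disc_mask((64, 64), (32, 39), 10)  # centers 15 px apart, r=10
        seg = segment_cells(img, pixel_size=1.0, min_separation_um=8.0)
        assert seg.n_cells == 2

    def test_all_background_yields_empty_segmentation(self):
        seg = segment_cells(np.zeros((32, 32), dtype=bool), pixel_size=1.0)
        assert seg.n_cells == 0
        assert seg.total_area_um2() == 0.0

    def test_area_filter_only_removes_labels_and_conserves_pixels(self):
        img = np.zeros((64, 64), dtype=bool)
        img |= disc_mask((64, 64), (20, 20), 10)
        img |= disc_mask((64, 64), (50, 50), 2)   # below the area cutoff
        coarse = segment_cells(img, pixel_size=1.0, min_cell_area=50.0)
        fine = segment_cells(img, pixel_size=1.0, min_cell_area=0.0)
        assert coarse.n_cells <= fine.n_cells
        assert coarse.n_cells == 1
        # no label maps to zero pixels; per-cell areas sum to the labeled area
        for seg in (coarse, fine):
            assert (seg.cells["area_px"] > 0).all()
            assert seg.cells["area_px"].sum() == (seg.labels > 0).sum()

    def test_labels_are_contiguous_from_one(self):
        img = disc_mask((64, 64), (32, 32), 10)
        seg = segment_cells(img, pixel_size=1.0)
        assert sorted(np.unique(seg.labels)) == [0, 1]
        assert list(seg.cells["label"]) == [1]


class TestClassification:
    def _one_cell_seg(self):
        fg = disc_mask((40, 40), (20, 20), 8)
        return segment_cells(fg, pixel_size=1.0)

    def test_bright_dead_channel_classes_dead(self):
        seg = self._one_cell_seg()
        live = np.random.default_rng(0).normal(10, 2, (40, 40)).clip(0)
        dead = np.where(seg.labels > 0, 200.0, 10.0)
        out = classify_viability(seg, live, dead)
        assert list(out.cells["viability"]) == ["dead"]

    def test_bright_live_channel_classes_live(self):
        seg = self._one_cell_seg()
        dead = np.random.default_rng(0).normal(10, 2, (40, 40)).clip(0)
        live = np.where(seg.labels > 0, 200.0, 10.0)
        out = classify_viability(seg, live, dead)
        assert list(out.cells["viability"]) == ["live"]

    def test_exact_tie_is_classed_dead_by_default(self):
        seg = self._one_cell_seg()
        img = np.where(seg.labels > 0, 100.0, 0.0)
        img[0, 0] = 50.0  # avoid constant-channel degeneracy
        out = classify_viability(seg, img, img.copy())
        assert list(out.cells["viability"]) == ["dead"]
        out_live = classify_viability(seg, img, img.copy(), tie_class="live")
        assert list(out_live.cells["viability"]) == ["live"]

    def test_generator_mixture_accuracy_at_default_snr(self):
        spec = ImpactSpec(field=FieldSpec(seed=31), impact_radius=80.0,
                          death_probability_inside=0.7,
                          death_probability_outside=0.1)
        pre, post, truth = generate_impact_pair(spec)
        _, _, post_seg, _ = analyze_pair(pre, post, ViabilityParams(max_shift=10))
        truth_states = {
            (round(c.row), round(c.col)): c.post_state for c in truth.cells
        }
        hits = total = 0
        for _, row in post_seg.cells.iterrows():
            # match each segmented cell to the nearest truth center
            best = min(
                truth_states,
                key=lambda rc: (rc[0] - row["centroid_row"]) ** 2
                + (rc[1] - row["centroid_col"]) ** 2,
            )
            total += 1
            hits += row["viability"] == truth_states[best]
        assert total >= 0.9 * len(truth.cells)
        assert hits / total >= 0.98


class TestRegistration:
    def naive_ncc(self, pre, post, max_shift):
        """Loop oracle: Pearson correlation on the overlap for every shift."""
        h, w = pre.shape
        best = (None, -np.inf)
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                r0, r1 = max(0, -dy), h - max(0, dy)
                c0, c1 = max(0, -dx), w - max(0, dx)
                a = pre[r0:r1, c0:c1]
                b = post[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
                if a.std() == 0 or b.std() == 0:
                    continue
                s = np.corrcoef(a.ravel(), b.ravel())[0, 1]
                if s > best[1] + 1e-12:
                    best = ((dy, dx), s)
        return best

    def test_identical_images_give_zero_offset_unit_score(self):
        img = np.random.default_rng(3).random((64, 64))
        al = register_roi(img, img, max_shift=10)
        assert al.offset == (0, 0)
        assert al.score == pytest.approx(1.0)
        assert al.roi == (0, 64, 0, 64)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(4)
        img = rng.random((96, 96))
        shifted = np.zeros_like(img)
        shifted[3:, :-2] = img[:-3, 2:]  # content moves by (+3, -2)
        al = register_roi(img, shifted, max_shift=8)
        assert al.offset == (3, -2)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.random((48, 48))
        noisy = np.roll(img, (2, 5), axis=(0, 1)) + rng.normal(0, 0.05, img.shape)
        al = register_roi(img, noisy, max_shift=7)
        (dy, dx), score = self.naive_ncc(img, noisy, 7)
        assert al.offset == (dy, dx)
        assert al.score == pytest.approx(score, abs=1e-9)

    def test_inverse_symmetry_on_noise_free_pair(self, small_field):
        fs = dataclasses.replace(small_field, noise_sd=0.0)
        pre, post, _ = generate_impact_pair(
            ImpactSpec(field=fs, post_shift=(6, -4))
        )
        a = np.maximum(pre.data[2, 0], pre.data[2, 1])
        b = np.maximum(post.data[2, 0], post.data[2, 1])
        fwd = register_roi(a, b, max_shift=12)
        rev = register_roi(b, a, max_shift=12)
        assert fwd.offset == (6, -4)
        assert rev.offset == (-6, 4)

    def test_low_score_sets_flag_but_returns_offset(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="below floor"):
            al = register_roi(rng.random((64, 64)), rng.random((64, 64)),
                              max_shift=4, score_floor=0.9)
        assert al.low_confidence
        assert al.offset is not None


class TestQuantification:
    def test_identical_frames_give_zero_death_area(self, impact_spec):
        spec = dataclasses.replace(
            impact_spec, death_probability_inside=0.0,
            death_probability_outside=0.0, post_shift=(0, 0)
        )
        pre, post, _ = generate_impact_pair(spec)
        result, *_ = analyze_pair(pre, post, ViabilityParams(max_shift=5))
        assert result.death_area_um2 == 0.0

    def test_single_flipped_disc_yields_its_area(self):
        """One cell dying contributes its segmented area, close to pi r^2."""
        fs = FieldSpec(width=256, height=256, n_cells=8, noise_sd=0.0, seed=41,
                       cell_radius_range=(6.0, 6.0))
        spec = ImpactSpec(field=fs, impact_radius=1e6,
                          death_probability_inside=0.5)
        pre, post, truth = generate_impact_pair(spec)
        n_dead = truth.n_dead_post()
        assert n_dead >= 1
        result, *_ = analyze_pair(pre, post, ViabilityParams(max_shift=5))
        np.testing.assert_allclose(
            result.death_area_um2, n_dead * np.pi * 6.0**2, rtol=0.05
        )

    def test_death_area_matches_generator_truth(self):
        spec = ImpactSpec(field=FieldSpec(seed=51), impact_radius=70.0,
                          death_probability_inside=1.0,
                          death_probability_outside=0.0, post_shift=(4, 3))
        pre, post, truth = generate_impact_pair(spec)
        result, *_ = analyze_pair(pre, post, ViabilityParams(max_shift=10))
        assert result.death_area_um2 == pytest.approx(
            truth.true_death_area_um2(), rel=0.10
        )

    def test_unclassified_segmentation_rejected(self):
        fg = disc_mask((40, 40), (20, 20), 8)
        seg = segment_cells(fg, pixel_size=1.0)
        from chondroview.viability import RoiAlignment

        al = RoiAlignment(offset=(0, 0), roi=(0, 40, 0, 40), score=1.0)
        with pytest.raises(ValueError, match="classif"):
            quantify_viability(seg, seg, al)

    def test_death_monotonic_in_inside_probability(self):
        """More lethal impacts do not produce less mean death area
        (checked over 20 simulated pairs)."""
        means = []
        for p in (0.2, 0.8):
            areas = []
            for seed in range(10):
                fs = FieldSpec(width=256, height=256, n_cells=25, seed=100 + seed)
                spec = ImpactSpec(field=fs, impact_radius=50.0,
                                  death_probability_inside=p,
                                  death_probability_outside=0.0)
                pre, post, _ = generate_impact_pair(spec)
                result, *_ = analyze_pair(pre, post, ViabilityParams(max_shift=5))
                areas.append(result.death_area_um2)
            means.append(np.mean(areas))
        assert means[1] >= means[0]
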