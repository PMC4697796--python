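"""Localization, width-filter artifact mechanism, shape, filament."""

import math

import numpy as np
import pytest

from focipair.model import FrameStack, LocalizationSet, ValidationError
from focipair.dstorm import (
    artifact_decay_curve,
    cluster_localizations,
    detect_image_foci,
    estimate_filament,
    fit_ellipse,
    localize_frames,
    reconstruct,
    tag_multi_emitter,
)
from focipair.synthetic import EmitterModel, _render_points, simulate_blink_stack


def noiseless_frame(points, photons, shape=(20, 20), sigma=70.0, px=100.0):
    pts = np.atleast_2d(np.asarray(points, float))
    w = np.full(len(pts), float(photons))
    return FrameStack(_render_points(pts, w, shape, px, sigma)[None], pixel_size_nm=px)


def locset(pts, fwhm=150.0):
    import pandas as pd

    pts = np.atleast_2d(np.asarray(pts, float))
    return LocalizationSet(
        pd.DataFrame(
            {
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "frame": np.arange(len(pts)),
                "photons": 500.0,
                "fwhm_nm": fwhm,
            }
        )
    )


class TestLocalizeFrames:
    def test_noiseless_single_emitter(self):
        stack = noiseless_frame([(955.0, 1042.0)], 10_000)
        locs = localize_frames(stack)
        assert len(locs) == 1
        row = locs.df.iloc[0]
        assert math.hypot(row.x_nm - 955.0, row.y_nm - 1042.0) < 10.0
        # measured width near the 165 nm PSF FWHM, inside the 2 px cutoff
        assert 140.0 < row.fwhm_nm <= 200.0

    def test_merged_event_at_midpoint_with_inflated_width(self):
        stack = noiseless_frame([(800.0, 1000.0), (1200.0, 1000.0)], 2000)
        merged = localize_frames(stack, fwhm_cutoff_px=math.inf)
        assert len(merged) == 1
        row = merged.df.iloc[0]
        assert math.hypot(row.x_nm - 1000.0, row.y_nm - 1000.0) < 50.0
        single = localize_frames(noiseless_frame([(1000.0, 1000.0)], 2000)).df.iloc[0]
        assert row.fwhm_nm > single.fwhm_nm
        # the 2 px width cutoff rejects the merged event
        assert len(localize_frames(stack, fwhm_cutoff_px=2.0)) == 0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            localize_frames(FrameStack(np.zeros((1, 0, 0))))

    def test_precision_bound_and_scaling(self):
        rms = {}
        for photons in (500, 8000):
            model = EmitterModel(
                positions=[[1000.0, 1000.0]], p_on=1.0, photons_mean=photons,
                psf_sigma_nm=70.0, background_rate=5.0, shape_px=(20, 20),
            )
            stack, _ = simulate_blink_stack(model, 250, seed=8)
            locs = localize_frames(stack)
            err = np.hypot(locs.df.x_nm - 1000.0, locs.df.y_nm - 1000.0)
            rms[photons] = math.sqrt((err**2).mean())
        # within a factor of 2 of the sigma/sqrt(N) bound at high photons
        assert rms[8000] < 2 * 70.0 / math.sqrt(8000)
        # and the error scales like 1/sqrt(photons) (factor 4 expected)
        ratio = rms[500] / rms[8000]
        assert 2.0 < ratio < 8.0

    def test_multi_emitter_events_suppressed_by_width_filter(self):
        sep = 400.0
        ca, cb = (800.0, 1000.0), (1200.0, 1000.0)
        model = EmitterModel(
            positions=np.array([ca, cb]), p_on=0.25, photons_mean=3000,
            psf_sigma_nm=70.0, background_rate=5.0, shape_px=(20, 20),
        )
        stack, truth = simulate_blink_stack(model, 3000, seed=9)
        locs = localize_frames(stack, fwhm_cutoff_px=math.inf)
        multi = tag_multi_emitter(locs, truth, radius_nm=sep + 50.0)
        assert multi.sum() > 50
        widths_px = locs.df["fwhm_nm"].to_numpy() / 100.0
        surviving = (widths_px[multi] <= 2.0).sum()
        assert surviving < 0.1 * multi.sum()


class TestReconstruct:
    def test_empty_gives_zero_image(self):
        assert reconstruct(locset(np.empty((0, 2)))).sum() == 0.0

    def test_single_localization_single_pixel(self):
        img = reconstruct(locset([(105.0, 205.0)]), blur_px=0.0)
        assert img.sum() == 1.0
        assert img[10, 5] == 1.0  # bin (y // 20, x // 20)

    def test_blur_conserves_total_intensity(self, rng):
        pts = rng.uniform(200, 1800, size=(500, 2))
        img = reconstruct(locset(pts), blur_px=0.75)
        assert img.sum() == pytest.approx(500.0, rel=1e-3)


@pytest.fixture(scope="module")
def two_cluster_curve():
    ca, cb = (800.0, 1000.0), (1200.0, 1000.0)
    model = EmitterModel(
        positions=np.array([ca, cb]), p_on=0.25, photons_mean=3000,
        psf_sigma_nm=70.0, background_rate=5.0, shape_px=(20, 20),
    )
    stack, _ = simulate_blink_stack(model, 4000, seed=10)
    return artifact_decay_curve(stack, ca, cb, cutoff_grid_px=[2.0, 3.0, 4.0, math.inf])


class TestArtifactCurve:
    def test_midpoint_fraction_decays_with_cutoff(self, two_cluster_curve):
        mf = two_cluster_curve.midpoint_fraction
        assert all(mf[i] <= mf[i + 1] + 1e-12 for i in range(len(mf) - 1))
        assert mf[-1] > 0.05  # artifact present without the filter
        assert mf[0] < 0.1 * mf[-1]  # and suppressed at 2 px

    def test_cluster_ratio_stable(self, two_cluster_curve):
        ratios = np.asarray(two_cluster_curve.cluster_intensity_ratio)
        assert np.nanmax(ratios) / np.nanmin(ratios) < 1.2

    def test_single_cluster_has_no_midpoint_signal(self):
        model = EmitterModel(
            positions=[[800.0, 1000.0]], p_on=0.3, photons_mean=3000,
            psf_sigma_nm=70.0, background_rate=5.0, shape_px=(20, 20),
        )
        stack, _ = simulate_blink_stack(model, 1000, seed=11)
        curve = artifact_decay_curve(
            stack, (800.0, 1000.0), (1200.0, 1000.0), cutoff_grid_px=[2.0, math.inf]
        )
        assert max(curve.midpoint_fraction) < 0.01

    def test_overlapping_regions_rejected(self):
        stack = noiseless_frame([(1000.0, 1000.0)], 1000)
        with pytest.raises(ValidationError, match="overlap"):
            artifact_decay_curve(
                stack, (900.0, 1000.0), (1100.0, 1000.0), cluster_radius_nm=75.0
            )


class TestClustering:
    def test_two_tight_clusters(self, rng):
        pts = np.vstack(
            [
                rng.normal((500.0, 500.0), 10.0, size=(30, 2)),
                rng.normal((900.0, 500.0), 10.0, size=(30, 2)),
            ]
        )
        foci, n_noise = cluster_localizations(locset(pts))
        assert len(foci) == 2 and n_noise == 0

    def test_sparse_noise_yields_no_clusters(self, rng):
        pts = rng.uniform(0, 10_000, size=(20, 2))
        foci, n_noise = cluster_localizations(locset(pts))
        assert foci == [] and n_noise == 20

    def test_centroids_near_truth(self, rng):
        centers = rng.uniform(1000, 9000, size=(12, 2))
        pts = np.vstack([rng.normal(c, 12.0, size=(40, 2)) for c in centers])
        foci, _ = cluster_localizations(locset(pts))
        assert len(foci) == 12
        hits = 0
        for f in foci:
            d = min(math.hypot(*(np.asarray(f.centroid) - c)) for c in centers)
            hits += d < 20.0
        assert hits >= 0.95 * len(foci)


class TestFitEllipse:
    def test_isotropic_cluster_aspect_near_one(self, rng):
        pts = rng.normal((0.0, 0.0), 25.0, size=(500, 2))
        fit = fit_ellipse(pts)
        assert 1.0 <= fit.aspect_ratio <= 1.15

    def test_matches_brute_force_covariance(self, rng):
        t = rng.uniform(-100, 100, size=200)
        pts = np.column_stack([t, rng.normal(0, 10.0, size=200)])
        fit = fit_ellipse(pts)
        cov = np.cov(pts.T, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert fit.l_major_nm == pytest.approx(4 * math.sqrt(evals[0]), abs=1e-9)
        assert fit.l_minor_nm == pytest.approx(4 * math.sqrt(evals[1]), abs=1e-9)

    def test_rotation_invariance(self, rng):
        pts = np.column_stack(
            [rng.uniform(-100, 100, size=100), rng.normal(0, 8.0, size=100)]
        )
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        a, b = fit_ellipse(pts), fit_ellipse(pts @ rot.T)
        assert b.l_major_nm == pytest.approx(a.l_major_nm, rel=1e-9)
        assert b.l_minor_nm == pytest.approx(a.l_minor_nm, rel=1e-9)
        delta = (b.orientation_rad - a.orientation_rad - theta) % math.pi
        assert min(delta, math.pi - delta) < 1e-6

    def test_collinear_flagged_degenerate(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        fit = fit_ellipse(pts)
        assert fit.degenerate and fit.aspect_ratio is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_ellipse(np.zeros((2, 2)))


class TestEstimateFilament:
    def test_width_floor_recovers_core_width(self):
        # a 10 nm-wide structure images at 70 nm after ~60 nm broadening
        assert estimate_filament(70.0).core_length_nm == pytest.approx(10.0)

    def test_100nt_gives_33_protomers_and_5_turns(self):
        est = estimate_filament(110.0)  # 50 nm core -> 100 nt
        assert est.nt == pytest.approx(100.0)
        assert est.protomers == 33
        assert est.turns == pytest.approx(5.0)

    def test_observed_length_stays_below_tract_bound(self):
        est = estimate_filament(114.0)
        assert est.core_length_nm == pytest.approx(54.0)
        assert est.nt == pytest.approx(108.0)
        assert est.tract_fraction_pct == pytest.approx(13.5)
        assert est.tract_fraction_pct < 15.0

    def test_below_broadening_floor_rejected(self):
        with pytest.raises(ValidationError, match="broadening"):
            estimate_filament(60.0)

    def test_tract_fraction_monotone_in_length(self):
        lengths = np.linspace(70.0, 300.0, 24)
        fracs = [estimate_filament(L).tract_fraction_pct for L in lengths]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))


class TestDetectImageFoci:
    def test_single_localization_detected_within_pixel(self):
        locs = locset([(500.0, 700.0)])
        img = reconstruct(locs, pixel_nm=20.0, blur_px=6.0, shape_px=(60, 60))
        pts = detect_image_foci(img, 20.0)
        assert len(pts) == 1
        assert math.hypot(pts[0][0] - 500.0, pts[0][1] - 700.0) <= 20.0 + 1e-9
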