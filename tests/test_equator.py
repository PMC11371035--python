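"""Equatorial lattice analysis: offsets, widths, bilateral fits, refits."""

import itertools
import math

import numpy as np
import pytest

from fiberfold.equator import (
    EquatorSettings,
    HexLatticeFit,
    analyze_equator,
    evaluate_model,
    hex_offsets,
    paracrystal_width,
    refit_with_overrides,
)
from fiberfold.geometry import Calibration, PatternFrame, pixel_to_d
from fiberfold.synthgen import SyntheticSpec, generate_pattern
from fiberfold.trace1d import Box, project_box


def brute_force_hex_distances(n_max=4):
    """All distinct lattice-vector lengths of a unit hexagonal lattice,
    enumerated directly from integer combinations of the basis vectors."""
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, math.sqrt(3) / 2])
    lengths = set()
    for n1, n2 in itertools.product(range(-n_max, n_max + 1), repeat=2):
        if (n1, n2) != (0, 0):
            lengths.add(round(np.linalg.norm(n1 * a1 + n2 * a2), 9))
    return sorted(lengths)


class TestHexOffsets:
    def test_defining_reflection(self):
        assert hex_offsets(80.0, [(1, 0)])[0] == 80.0

    def test_against_lattice_enumeration_oracle(self):
        # offsets for the standard index set must be the shortest distinct
        # distances of the hexagonal lattice, in order
        offs = hex_offsets(1.0, [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0)])
        oracle = brute_force_hex_distances()[:5]
        np.testing.assert_allclose(sorted(offs), oracle, rtol=1e-9)

    def test_known_ratios(self):
        offs = hex_offsets(1.0, [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0)])
        np.testing.assert_allclose(
            offs, [1.0, math.sqrt(3), 2.0, math.sqrt(7), 3.0], rtol=1e-12
        )

    def test_rejects_origin_and_bad_s10(self):
        with pytest.raises(ValueError):
            hex_offsets(80.0, [(0, 0)])
        with pytest.raises(ValueError):
            hex_offsets(-1.0, [(1, 0)])


class TestParacrystalWidth:
    def test_disorder_free_limit(self):
        for hk in [(1, 0), (2, 1), (3, 0)]:
            assert paracrystal_width(1.7, 0.0, hk) == 1.7

    def test_direct_evaluation(self):
        assert paracrystal_width(1.0, 0.5, (1, 0)) == pytest.approx(1.5)
        assert paracrystal_width(1.0, 0.5, (1, 1)) == pytest.approx(2.5)
        assert paracrystal_width(1.0, 0.5, (2, 0)) == pytest.approx(3.0)

    def test_monotone_in_order(self):
        hks = [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0)]
        widths = [paracrystal_width(1.0, 0.2, hk) for hk in hks]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            paracrystal_width(-1.0, 0.0, (1, 0))


SPEC_PEAKS = (((1, 0), 10000.0, 0.0), ((1, 1), 6000.0, 0.0), ((2, 0), 1500.0, 0.0))


class TestAnalyzeEquator:
    def test_noise_free_recovery(self):
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             sigma_s=2.0, sigma_d=0.3, background=())
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        fit = analyze_equator(img, None, es, frame=PatternFrame(truth["center"], 0.0))
        assert not fit.flagged
        assert fit.S10 == pytest.approx(80.0, rel=0.002)
        assert fit.I11_over_I10 == pytest.approx(0.600, rel=0.01)

    def test_poisson_noise_recovery(self):
        # peak counts ~1e4: area chosen so the (1,0) amplitude is ~1e4
        a10 = 1.0e4 * 2 * math.pi * 2.3 * 4.0
        peaks = (((1, 0), a10, 0.0), ((1, 1), 0.6 * a10, 0.0), ((2, 0), 0.15 * a10, 0.0))
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=peaks,
                             sigma_s=2.0, sigma_d=0.3, noise="poisson", seed=11)
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        fit = analyze_equator(img, None, es, frame=PatternFrame(truth["center"], 0.0))
        assert fit.S10 == pytest.approx(80.0, rel=0.005)
        assert fit.I11_over_I10 == pytest.approx(0.600, rel=0.05)

    def test_mirror_symmetry(self):
        spec = SyntheticSpec(shape=(220, 512), S10=70.0, eq_peaks=SPEC_PEAKS,
                             background=())
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        frame = PatternFrame(truth["center"], 0.0)
        fit = analyze_equator(img, None, es, frame=frame)
        fit_m = analyze_equator(np.fliplr(img), None, es, frame=frame)
        assert fit_m.S10 == pytest.approx(fit.S10, rel=1e-4)
        assert fit_m.I11_over_I10 == pytest.approx(fit.I11_over_I10, rel=1e-3)

    def test_d10_reported_when_calibrated(self):
        cal = Calibration(0.1033, 3000.0, 0.172, calibrated=True)
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             background=())
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        fit = analyze_equator(img, cal, es, frame=PatternFrame(truth["center"], 0.0))
        assert fit.d10 == pytest.approx(pixel_to_d(fit.S10, cal), rel=1e-9)

    def test_d10_s10_geometry_self_consistency(self):
        # d10 depends on the geometry only through r * pixel / distance, so
        # rescaling detector distance and S10 together leaves d10 unchanged
        cal1 = Calibration(0.1033, 2000.0, 0.172)
        cal2 = Calibration(0.1033, 4000.0, 0.172)
        assert float(pixel_to_d(80.0, cal1)) == pytest.approx(
            float(pixel_to_d(160.0, cal2)), rel=1e-12
        )

    def test_no_peaks_flagged_not_raised(self):
        img = np.full((128, 128), 10.0)
        img[60:68, 60:68] = 2000.0  # only a central blob, no reflections
        fit = analyze_equator(img, None, EquatorSettings(),
                              frame=PatternFrame((63.5, 63.5), 0.0))
        assert fit.flagged

    def test_forward_model_matches_generator_projection(self):
        spec = SyntheticSpec(shape=(256, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             sigma_s=2.0, sigma_d=0.3, background=())
        img, truth = generate_pattern(spec)
        cx, cy = truth["center"]
        box = Box("equator_axial", anchor=(cx, cy), length=512, width=255)
        trace = project_box(img, box)
        hand = HexLatticeFit(
            S10=80.0, d10=None, centerline=0.0,
            areas={(1, 0): 10000.0, (1, 1): 6000.0, (2, 0): 1500.0},
            widths={}, extra_peaks=[], I11_over_I10=0.6,
            sigma_s=2.0, sigma_d=0.3, model="gaussian",
            fit_error=0.0, flagged=False,
            settings=EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0))),
        )
        yhat = evaluate_model(hand, trace.coordinate)
        scale = trace.intensity.max()
        assert np.max(np.abs(yhat - trace.intensity)) < 5e-3 * scale


class TestRefitWithOverrides:
    def _fit(self):
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             background=())
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        return analyze_equator(img, None, es, frame=PatternFrame(truth["center"], 0.0))

    def test_empty_overrides_identity(self):
        fit = self._fit()
        refit = refit_with_overrides(fit, {})
        assert refit.S10 == pytest.approx(fit.S10, rel=1e-6)
        assert refit.I11_over_I10 == pytest.approx(fit.I11_over_I10, rel=1e-5)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            refit_with_overrides(self._fit(), {"S99": 1.0})

    def test_s10_override_rescues_flagged_fit(self):
        # a wildly wrong initial lattice spacing produces a rejected fit;
        # overriding S10 with the true value rescues it
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             background=())
        img, truth = generate_pattern(spec)
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        fit = analyze_equator(img, None, es, frame=PatternFrame(truth["center"], 0.0))
        bad = refit_with_overrides(fit, {"S10": 80.0})
        assert not bad.flagged
        assert bad.S10 == pytest.approx(80.0, rel=0.002)

    def test_extra_peak_recovers_indexed_areas(self):
        # a non-indexing contaminant at 2.3 * S10 biases the plain fit;
        # declaring it as an extra peak restores the lattice areas
        contaminant = 2.3 * 80.0
        spec = SyntheticSpec(shape=(220, 512), S10=80.0, eq_peaks=SPEC_PEAKS,
                             mer_peaks=(), background=())
        img, truth = generate_pattern(spec)
        yy, xx = np.indices(img.shape, dtype=float)
        cx, cy = truth["center"]
        for sign in (+1, -1):
            img = img + 3000.0 / (2 * math.pi * 3.0 * 4.0) * np.exp(
                -0.5 * (((xx - cx - sign * contaminant) / 3.0) ** 2 + ((yy - cy) / 4.0) ** 2)
            )
        es = EquatorSettings(hk_list=((1, 0), (1, 1), (2, 0)))
        first = analyze_equator(img, None, es, frame=PatternFrame((cx, cy), 0.0))
        refit = refit_with_overrides(first, {"extra_peaks": [(contaminant, 3000.0, 3.0)]})
        assert refit.areas[(1, 0)] == pytest.approx(10000.0, rel=0.02)
        assert refit.areas[(1, 1)] == pytest.approx(6000.0, rel=0.02)

    def test_recovery_grid(self):
        # 20 synthetic conditions spanning lattice spacing, intensity ratio
        # and both peak models, with Poisson noise at >= 1e3 peak counts
        errs_s10, errs_ratio = [], []
        i = 0
        for s10 in (40.0, 60.0, 80.0, 100.0, 120.0):
            for ratio in (0.5, 2.0):
                for model in ("gaussian", "voigt"):
                    a10 = 2.0e5
                    spec = SyntheticSpec(
                        shape=(192, 1024), S10=s10,
                        eq_peaks=(((1, 0), a10, 0.0), ((1, 1), ratio * a10, 0.0),
                                  ((2, 0), 0.15 * a10, 0.0), ((2, 1), 0.08 * a10, 0.0),
                                  ((3, 0), 0.05 * a10, 0.0)),
                        sigma_s=2.0, sigma_d=0.3,
                        background=(("exp", 200.0, 80.0),),
                        noise="poisson", seed=100 + i,
                    )
                    i += 1
                    img, truth = generate_pattern(spec)
                    fit = analyze_equator(img, None, EquatorSettings(model=model))
                    errs_s10.append(abs(fit.S10 - s10) / s10)
                    errs_ratio.append(abs(fit.I11_over_I10 - ratio) / ratio)
        assert np.median(errs_s10) < 0.005
        assert np.median(errs_ratio) < 0.05
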