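"""Decision criteria: preselection, SSIM/SDIFF, structural verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strikefinder.decision import (
    DecisionError,
    PreselectionThresholds,
    StructuralThresholds,
    Verdict,
    evaluate_candidate,
    preselect,
    sdiff_series,
    ssim,
    structural_decision,
)
from strikefinder.frames import Channel
from strikefinder.regions import generate_regions
from strikefinder.scoring import ScoreMap

from conftest import stack_from_arrays


def ssim_loop_oracle(x, y, c1, c2):
    """Reference SSIM from explicit loops over the pixel lists."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )


# ---------------------------------------------------------------------- SSIM
def test_ssim_identical_inputs_total_similarity(rng):
    x = rng.uniform(0, 1, 30)
    assert ssim(x, x) == 1.0
    const = np.full(10, 0.4)
    assert ssim(const, const) == 1.0  # stabilizers dominate zero variance


def test_ssim_input_validation():
    with pytest.raises(DecisionError):
        ssim([0.1], [0.2])
    with pytest.raises(DecisionError):
        ssim([0.1, 0.2, 0.3], [0.1, 0.2])


def test_ssim_matches_oracle_and_monotone_in_c2(rng):
    x = rng.uniform(0, 1, 30)
    y = rng.uniform(0, 1, 30)
    values = []
    for c2 in (1e-6, 0.01, 0.03):
        s = ssim(x, y, 1e-4, c2)
        assert s == pytest.approx(ssim_loop_oracle(list(x), list(y), 1e-4, c2), abs=1e-12)
        values.append(s)
    # noise-dominated pairs gain similarity as the stabilizer grows
    mx, my = x.mean(), y.mean()
    if ((x - mx) ** 2).mean() + ((y - my) ** 2).mean() > 2 * ((x - mx) * (y - my)).mean():
        assert values[0] < values[1] < values[2]


@settings(max_examples=100, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 50))
def test_ssim_symmetry_property(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    y = rng.uniform(0, 1, n)
    assert ssim(x, y) == ssim(y, x)


def test_c2_rescues_near_constant_patches(rng):
    """Low-variance patches are noise-dominated at c2=0, similar at c2=0.03."""
    base = np.full(40, 0.45)
    x = base + rng.normal(0, 0.004, 40)
    y = base + rng.normal(0, 0.004, 40)
    assert ssim(x, y, 1e-4, 1e-9) < 0.5
    assert ssim(x, y, 1e-4, 0.03) > 0.9


# -------------------------------------------------------------- preselection
def _phantom_fixture(inner_value=127.0, outer_value=91.0, background=100.0):
    """Stack + region reproducing a field-calibrated thermal candidate:
    area 10 px, temporal discernibility 27, spatial discernibility 36."""
    shape = (40, 40)
    binary = np.zeros(shape, bool)
    binary[18:20, 15:20] = True  # 10-px inner blob
    region = generate_regions(binary, dilate_iters=2, gap_iters=1)[0]

    old = [np.full(shape, background) for _ in range(5)]
    new_img = np.full(shape, background)
    new_img[region.outer[:, 0], region.outer[:, 1]] = outer_value
    new_img[18:20, 15:20] = inner_value
    new = [new_img.copy() for _ in range(5)]
    stack = stack_from_arrays(old + new, channel=Channel.LWIR)
    score = ScoreMap(values=np.zeros(shape), mask=np.ones(shape, bool), channel=Channel.LWIR)
    return region, stack, score


def test_preselection_passes_field_calibrated_candidate():
    region, stack, score = _phantom_fixture()
    ev = preselect(region, stack, score, PreselectionThresholds())
    assert ev.verdict is None  # all four criteria pass
    assert ev.criterion_values["area"] == 10
    assert ev.criterion_values["temporal_discernibility"] == 27.0
    assert ev.criterion_values["spatial_discernibility"] == 36.0
    assert ev.criterion_values["surround_score"] < 2.9


def test_preselection_rejects_oversized_area():
    region, stack, score = _phantom_fixture()
    thr = PreselectionThresholds(area_min=1, area_max=9)
    ev = preselect(region, stack, score, thr)
    assert ev.verdict == Verdict.REJECTED_PRESELECTION
    assert "area" in ev.rejection_reason


def test_preselection_rejects_weak_discernibility():
    region, stack, score = _phantom_fixture(inner_value=108.0)  # temporal 8 < 11
    ev = preselect(region, stack, score, PreselectionThresholds())
    assert ev.verdict == Verdict.REJECTED_PRESELECTION
    assert "temporal" in ev.rejection_reason


def test_preselection_rejects_wind_elevated_surround():
    """High scores spread over the surround (wind gust) veto the candidate."""
    region, stack, score = _phantom_fixture()
    windy = score.values.copy()
    windy[:, :] = 6.0  # elevated everywhere around the candidate
    score_windy = ScoreMap(values=windy, mask=score.mask, channel=Channel.LWIR)
    ev = preselect(region, stack, score_windy, PreselectionThresholds())
    assert ev.verdict == Verdict.REJECTED_PRESELECTION
    assert "surround" in ev.rejection_reason


def test_preselection_vis_sign_flip():
    """On the VIS channel a darkening object passes the same criteria."""
    region, stack, score = _phantom_fixture(inner_value=73.0, outer_value=109.0)
    frames = [f.with_pixels(f.pixels) for f in stack.frames]
    for f in frames:
        f.channel = Channel.VIS
    vis_stack = stack.replace_frames(frames)
    ev = preselect(region, vis_stack, score, PreselectionThresholds())
    assert ev.verdict is None
    assert ev.criterion_values["temporal_discernibility"] == 27.0
    assert ev.criterion_values["spatial_discernibility"] == 36.0


# --------------------------------------------------------------------- SDIFF
def test_sdiff_identical_frames_all_zero():
    region, stack, _ = _phantom_fixture()
    flat = stack_from_arrays([np.full((40, 40), 90.0)] * 10, channel=Channel.LWIR)
    sdiffs = sdiff_series(region, flat, StructuralThresholds())
    assert len(sdiffs) == 9
    assert np.allclose(sdiffs, 0.0, atol=1e-12)


def test_sdiff_is_one_minus_ssim(rng):
    region, stack, _ = _phantom_fixture()
    arrays = [rng.uniform(0, 255, (40, 40)) for _ in range(10)]
    noisy = stack_from_arrays(arrays, channel=Channel.LWIR)
    thr = StructuralThresholds()
    sdiffs = sdiff_series(region, noisy, thr)
    rows, cols = region.full[:, 0], region.full[:, 1]
    for i in range(9):
        a = arrays[i][rows, cols] / 255.0
        b = arrays[i + 1][rows, cols] / 255.0
        assert sdiffs[i] == pytest.approx(1.0 - ssim(a, b, thr.c1, thr.c2), abs=1e-15)


def test_sdiff_rejects_heavily_masked_region():
    region, stack, _ = _phantom_fixture()
    frames = list(stack.frames)
    frames[0].mask[:] = False
    with pytest.raises(DecisionError, match="masked"):
        sdiff_series(region, stack.replace_frames(frames), StructuralThresholds())


# ---------------------------------------------------------------- structural
def test_structural_accepts_clear_middle_peak():
    sdiffs = [0.007, 0.004, 0.004, 0.003, 0.443, 0.003, 0.005, 0.003, 0.004]
    detected, reason, values = structural_decision(np.array(sdiffs), StructuralThresholds())
    assert detected and reason is None
    assert values["middle_sdiff"] == 0.443
    assert values["sdiff_quotient"] == pytest.approx(0.443 / 0.007)


def test_structural_rejects_uniform_low_series():
    """Illumination-change pattern: content unchanged at the middle pair."""
    detected, reason, _ = structural_decision(np.full(9, 0.01), StructuralThresholds())
    assert not detected
    assert "middle" in reason


def test_structural_rejects_restless_sitter():
    """Sitting-bird pattern: large SDIFF at side pairs vetoes the candidate."""
    sdiffs = np.array([0.01, 0.30, 0.01, 0.01, 0.40, 0.01, 0.25, 0.01, 0.01])
    detected, reason, _ = structural_decision(sdiffs, StructuralThresholds())
    assert not detected
    assert "side" in reason


def test_structural_rejects_insufficient_quotient():
    sdiffs = np.array([0.04, 0.01, 0.01, 0.01, 0.05, 0.01, 0.01, 0.01, 0.01])
    detected, reason, _ = structural_decision(sdiffs, StructuralThresholds())
    assert not detected
    assert "quotient" in reason


def test_structural_zero_sides_quotient_is_infinite():
    sdiffs = np.zeros(9)
    sdiffs[4] = 0.2
    detected, _, values = structural_decision(sdiffs, StructuralThresholds())
    assert detected
    assert values["sdiff_quotient"] == float("inf")


def test_structural_requires_odd_series():
    with pytest.raises(DecisionError):
        structural_decision(np.zeros(8), StructuralThresholds())


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 5000), bump=st.floats(0.0, 0.5))
def test_structural_monotone_in_middle_sdiff(seed, bump):
    """Raising the middle SDIFF never flips detected -> rejected."""
    rng = np.random.default_rng(seed)
    sdiffs = rng.uniform(0, 0.1, 9)
    thr = StructuralThresholds()
    before, _, _ = structural_decision(sdiffs, thr)
    raised = sdiffs.copy()
    raised[4] = min(1.0, raised[4] + bump)
    after, _, _ = structural_decision(raised, thr)
    assert after or not before


def test_evaluate_candidate_full_path():
    """A constructed strike passes preselection and the structural check."""
    region, stack, score = _phantom_fixture()
    ev = evaluate_candidate(
        region, stack, score, PreselectionThresholds(), StructuralThresholds()
    )
    assert ev.verdict == Verdict.DETECTED
    assert ev.sdiff_series is not None and len(ev.sdiff_series) == 9
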