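"""Synthetic scene generator: determinism, event rendering, cooling."""

import math

import numpy as np
import pytest

from strikefinder.frames import Channel
from strikefinder.synth import (
    DropEvent,
    IlluminationEvent,
    SceneSpec,
    SitterEvent,
    SynthError,
    WalkerEvent,
    WindEvent,
    benchmark_lwir_scene,
    cooling_curve,
    footprint_offsets,
    generate_sequence,
    scene_from_dict,
)


# ------------------------------------------------------------- cooling curve
@pytest.mark.parametrize(
    "delta0,tau,t,expected",
    [
        (30.0, 300.0, 0.0, 30.0),
        (30.0, 300.0, 300.0, 30.0 / math.e),  # ~11.04
        (12.0, 100.0, 250.0, 12.0 * math.exp(-2.5)),
    ],
)
def test_cooling_curve_closed_form(delta0, tau, t, expected):
    assert cooling_curve(delta0, tau, t) == pytest.approx(expected, rel=1e-12)


def test_cooling_curve_validation():
    with pytest.raises(SynthError):
        cooling_curve(30.0, 0.0, 10.0)
    with pytest.raises(SynthError):
        cooling_curve(30.0, 300.0, -1.0)


def test_footprint_offsets_compact_growth():
    assert footprint_offsets(1).tolist() == [[0, 0]]
    assert len(footprint_offsets(2)) == 2
    np.testing.assert_array_equal(np.abs(footprint_offsets(2)).sum(axis=1), [0, 1])
    assert len(np.unique(footprint_offsets(9), axis=0)) == 9


# ----------------------------------------------------------------- rendering
def test_same_spec_and_seed_bit_identical():
    spec = benchmark_lwir_scene(3)
    f1, t1 = generate_sequence(spec)
    f2, t2 = generate_sequence(benchmark_lwir_scene(3))
    for a, b in zip(f1, f2):
        assert np.array_equal(a.pixels, b.pixels)
    assert t1.records == t2.records


def test_zero_noise_no_events_static_frames():
    spec = SceneSpec(n_frames=6, noise_sigma=0.0, seed=1)
    frames, _ = generate_sequence(spec)
    for f in frames[1:]:
        assert np.array_equal(f.pixels, frames[0].pixels)


def test_drop_appears_persists_and_cools():
    spec = SceneSpec(
        n_frames=12,
        noise_sigma=0.0,
        texture_sigma=0.0,
        base_gray=100.0,
        channel=Channel.LWIR,
        drops=[DropEvent(frame=4, position=(30, 30), footprint_px=2, contrast=30.0, tau=300.0)],
        seed=0,
    )
    frames, truth = generate_sequence(spec)
    assert frames[3].pixels[30, 30] == 100
    assert frames[4].pixels[30, 30] == 130
    for k in range(4, 12):
        age = (k - 4) * spec.frame_interval
        expected = 100.0 + cooling_curve(30.0, 300.0, age)
        assert abs(frames[k].pixels[30, 30] - expected) <= 0.5  # quantization
    assert truth.drops()[0]["row"] == 30


def test_vis_drop_darkens():
    spec = SceneSpec(
        n_frames=6, noise_sigma=0.0, texture_sigma=0.0, base_gray=100.0,
        channel=Channel.VIS,
        drops=[DropEvent(frame=2, position=(10, 10), footprint_px=1, contrast=30.0)],
        seed=0,
    )
    frames, _ = generate_sequence(spec)
    assert frames[1].pixels[10, 10] == 100
    assert np.all([f.pixels[10, 10] == 70 for f in frames[2:]])


def test_walker_is_transient():
    spec = SceneSpec(
        n_frames=10, noise_sigma=0.0, texture_sigma=0.0, base_gray=100.0,
        walkers=[WalkerEvent(start_frame=2, start=(20, 4), velocity=(0, 5),
                             size_px=1, contrast=40.0)],
        seed=0,
    )
    frames, _ = generate_sequence(spec)
    assert frames[2].pixels[20, 4] == 140
    assert frames[3].pixels[20, 4] == 100  # moved on
    assert frames[3].pixels[20, 9] == 140


def test_illumination_step_is_global_and_persistent():
    spec = SceneSpec(
        n_frames=6, noise_sigma=0.0, channel=Channel.VIS,
        illumination=[IlluminationEvent(frame=3, offset=25.0)], seed=2,
    )
    frames, _ = generate_sequence(spec)
    delta = frames[3].pixels - frames[2].pixels
    assert np.all(np.abs(delta - 25.0) <= 1.0)
    assert np.array_equal(frames[3].pixels, frames[5].pixels)


def test_wind_confined_to_box_and_zero_mean():
    spec = SceneSpec(
        n_frames=8, noise_sigma=0.0, seed=4,
        wind=[WindEvent(start=2, stop=6, center=(16, 16), area_fraction=0.1,
                        amplitude=10.0)],
    )
    frames, _ = generate_sequence(spec)
    inside = frames[3].pixels[10:22, 10:22] - frames[0].pixels[10:22, 10:22]
    outside = frames[3].pixels[40:, 40:] - frames[0].pixels[40:, 40:]
    assert np.abs(inside).max() > 3.0
    assert np.abs(outside).max() <= 1.0
    assert abs(inside.mean()) < 5.0  # fluctuation, not a step


def test_overlapping_drops_rejected():
    with pytest.raises(SynthError, match="overlap"):
        SceneSpec(
            drops=[
                DropEvent(frame=5, position=(20, 20), footprint_px=4),
                DropEvent(frame=8, position=(20, 21), footprint_px=4),
            ]
        )


def test_event_outside_sequence_rejected():
    with pytest.raises(SynthError):
        SceneSpec(n_frames=10, drops=[DropEvent(frame=10, position=(5, 5))])


def test_nacelle_jitter_recorded_and_recoverable():
    """Estimated frame-pair alignment matches the injected transforms."""
    from strikefinder.register import AffineTransform2D, estimate_alignment

    spec = SceneSpec(
        shape=(96, 96), n_frames=5, texture_sigma=20.0, texture_scale=2.0,
        jitter_translation=3.0, jitter_rotation=0.5, seed=6,
    )
    frames, truth = generate_sequence(spec)
    corners = np.array([[0, 0], [95, 0], [0, 95], [95, 95]], float)
    for i in range(4):
        est = estimate_alignment(frames[i], frames[i + 1], rng=i)
        true_rel = AffineTransform2D(
            matrix=truth.frame_transforms[i + 1]
            @ np.linalg.inv(truth.frame_transforms[i])
        )
        err = np.abs(est.apply(corners) - true_rel.apply(corners)).max()
        assert err <= 1.0


def test_scene_from_dict_round_trip():
    spec = scene_from_dict(
        {
            "shape": [32, 32],
            "n_frames": 8,
            "channel": "vis",
            "seed": 5,
            "drops": [{"frame": 3, "position": [10, 12], "footprint_px": 2}],
            "wind": [{"start": 1, "stop": 4, "center": [20, 20]}],
        }
    )
    assert spec.channel == Channel.VIS
    assert spec.drops[0].position == (10, 12)
    frames, truth = generate_sequence(spec)
    assert len(frames) == 8 and len(truth.drops()) == 1
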