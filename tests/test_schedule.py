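"""Warmup schedule and augmentation pipeline behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strawdet.augment import apply_augmentations, fliplr
from strawdet.schedule import (AugmentationPlan, ScheduleState, effective_plan,
                               warmup_probability)


@pytest.mark.parametrize("epoch,total,expected", [
    (0, 100, 0.0),      # no augmentation in the first epoch
    (10, 100, 0.5),     # halfway through the ramp
    (20, 100, 1.0),     # exactly one fifth of training: full pipeline
    (90, 100, 1.0),     # clamped afterwards
])
def test_warmup_probability_values(epoch, total, expected):
    assert warmup_probability(ScheduleState(epoch, total)) == pytest.approx(expected)


def test_invalid_schedule_state_rejected():
    with pytest.raises(ValueError):
        ScheduleState(0, 0)
    with pytest.raises(ValueError):
        ScheduleState(-1, 10)


@given(total=st.integers(1, 500))
@settings(max_examples=50, deadline=None)
def test_warmup_monotone_and_saturates_at_one_fifth(total):
    vals = [warmup_probability(ScheduleState(e, total)) for e in range(total + 1)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    e_full = math.ceil(total / 5)
    assert vals[e_full] == 1.0
    if e_full >= 1:
        assert vals[e_full - 1] <= 1.0


@pytest.mark.parametrize("epoch,total,base,expected", [
    (0, 100, {"fliplr": 0.5, "mosaic": 1.0}, {"fliplr": 0.0, "mosaic": 0.0}),
    (20, 100, {"fliplr": 0.5}, {"fliplr": 0.5}),
    (8, 100, {"mosaic": 1.0, "fliplr": 0.5}, {"mosaic": 0.4, "fliplr": 0.2}),
])
def test_effective_plan_scales_elementwise(epoch, total, base, expected):
    plan = effective_plan(ScheduleState(epoch, total), base)
    for k, v in expected.items():
        assert plan.effective_probabilities[k] == pytest.approx(v)


def test_plan_rejects_probability_outside_unit_interval():
    with pytest.raises(ValueError):
        AugmentationPlan(warmup_factor=0.5, base_probabilities={"fliplr": 1.5})


def _sample(rng):
    img = rng.random((16, 16, 3)).astype(np.float32)
    lab = np.array([[1, 0.2, 0.5, 0.1, 0.1]], dtype=np.float32)
    return img, lab


def test_zero_warmup_leaves_sample_untouched(rng):
    img, lab = _sample(rng)
    plan = effective_plan(ScheduleState(0, 100), {"fliplr": 1.0, "hsv": 1.0})
    out_img, out_lab = apply_augmentations(img, lab, plan, rng_seed=0)
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_lab, lab)


def test_horizontal_flip_mirrors_box(rng):
    img, lab = _sample(rng)
    out_img, out_lab = fliplr(img, lab)
    assert out_lab[0, 1] == pytest.approx(0.8)
    assert out_lab[0, 2:].tolist() == lab[0, 2:].tolist()
    assert np.array_equal(out_img[:, 0], img[:, -1])


def test_augmentation_determinism(rng):
    img, lab = _sample(rng)
    plan = effective_plan(ScheduleState(50, 100),
                          {"fliplr": 0.5, "hsv": 0.7, "translate_scale": 0.5})
    a = apply_augmentations(img, lab, plan, rng_seed=42)
    b = apply_augmentations(img, lab, plan, rng_seed=42)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_full_warmup_matches_base_firing_frequency(rng):
    """At P=1 the gated pipeline fires at the base rates (3 SE over 1500 trials)."""
    img, lab = _sample(rng)
    base = {"fliplr": 0.5, "hsv": 0.25}
    plan_full = effective_plan(ScheduleState(100, 100), base)
    assert plan_full.effective_probabilities == base
    n = 1500
    counts = {k: 0 for k in base}
    for seed in range(n):
        fired: list = []
        apply_augmentations(img, lab, plan_full, rng_seed=seed, fired=fired)
        for k in fired:
            counts[k] += 1
    for k, p in base.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(counts[k] / n - p) < 3 * se


def test_boxes_stay_normalized_under_geometry(rng):
    img, lab = _sample(rng)
    plan = effective_plan(ScheduleState(100, 100),
                          {"translate_scale": 1.0, "fliplr": 1.0})
    for seed in range(25):
        _, out = apply_augmentations(img, lab, plan, rng_seed=seed)
        if out.size:
            assert (out[:, 1:] >= 0).all() and (out[:, 1:] <= 1).all()
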