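"""Feature-extraction correctness against independent brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosedx import (
    FeatureConfig,
    SampleMeta,
    SensorRecording,
    extract_features,
    response_intensity,
    simulate_recording,
)
from enosedx.features import (
    feature_A,
    feature_B,
    feature_C,
    feature_D,
    feature_E,
    feature_F,
    feature_G,
    feature_H,
)

import _oracles as oracle
from conftest import HAND_CURVES, HAND_PHASES, make_hand_recording, noiseless_config

RAW = dict(use_snv=False, halfwidth_s=0.0)

#: small configuration matching the hand recording's phase windows
HAND_CFG = FeatureConfig(
    during_points=(1, 2, 4),
    after_points=(0, 1),
    triples=((0, 2, 4),),
    pairs=((0, 4),),
    alphas=(0.3,),
    use_snv=False,
    halfwidth_s=0.0,
)


@pytest.mark.parametrize("sensor", [0, 1])
def test_hand_series_oracle_equivalence(hand_recording, sensor):
    """Every descriptor matches its naive pure-Python evaluation to 1e-10."""
    curve = HAND_CURVES[sensor]
    checks = [
        (feature_A(hand_recording, sensor, 2, **RAW), oracle.feat_A(curve, HAND_PHASES, 2)),
        (feature_B(hand_recording, sensor, 2, **RAW), oracle.feat_B(curve, HAND_PHASES, 2)),
        (feature_C(hand_recording, sensor, 1, **RAW), oracle.feat_C(curve, HAND_PHASES, 1)),
        (feature_D(hand_recording, sensor, use_snv=False), oracle.feat_D(curve, HAND_PHASES)),
        (
            feature_E(hand_recording, sensor, 0, 2, 4, **RAW),
            oracle.feat_E(curve, HAND_PHASES, 0, 2, 4),
        ),
        (
            feature_F(hand_recording, sensor, 0, 4, **RAW),
            oracle.feat_F(curve, HAND_PHASES, 0, 4),
        ),
        (
            feature_G(hand_recording, sensor, 0.3, use_snv=False),
            oracle.feat_G_unrolled(curve, HAND_PHASES, 0.3),
        ),
        (feature_H(hand_recording, sensor), oracle.feat_H(curve, HAND_PHASES)),
    ]
    for got, want in checks:
        assert got == pytest.approx(want, abs=1e-10)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(alpha=st.floats(0.05, 0.95), seed=st.integers(0, 500))
def test_feature_G_recursion_matches_unrolled_sum(alpha, seed):
    curve = np.random.default_rng(seed).uniform(10.0, 30.0, size=12).tolist()
    rec = SensorRecording(
        time_s=np.arange(12.0),
        resistance=np.array([curve]),
        sampling_hz=1.0,
        phases={"baseline": (0, 3), "during": (3, 9), "after": (9, 12)},
        meta=SampleMeta("g", "g"),
    )
    got = feature_G(rec, 0, alpha, use_snv=False)
    want = oracle.feat_G_unrolled(curve, rec.phases, alpha)
    assert got == pytest.approx(want, abs=1e-10)


def test_feature_G_alpha_near_one_approaches_min_first_difference():
    curve = [10.0, 9.0, 8.5, 7.0, 6.8, 6.5, 6.4, 6.4, 6.5, 7.0]
    rec = SensorRecording(
        time_s=np.arange(10.0),
        resistance=np.array([curve]),
        sampling_hz=1.0,
        phases=HAND_PHASES,
        meta=SampleMeta("g", "g"),
    )
    got = feature_G(rec, 0, 1.0 - 1e-9, use_snv=False)
    dx = np.diff(curve[: HAND_PHASES["during"][1]])
    assert got == pytest.approx(min(0.0, dx.min()), abs=1e-6)


def test_feature_E_linear_curve_is_interval_length_ratio():
    curve = np.linspace(100.0, 50.0, 10)
    rec = SensorRecording(
        time_s=np.arange(10.0),
        resistance=np.array([curve]),
        sampling_hz=1.0,
        phases=HAND_PHASES,
        meta=SampleMeta("lin", "lin"),
    )
    got = feature_E(rec, 0, 0, 1, 4, **RAW)
    assert got == pytest.approx((4 - 1) / (1 - 0), abs=1e-10)


def test_feature_E_degenerate_denominator_returns_zero(caplog):
    curve = [100.0] * 3 + [90.0, 90.0, 90.0, 80.0, 70.0] + [100.0, 100.0]
    rec = SensorRecording(
        time_s=np.arange(10.0),
        resistance=np.array([curve]),
        sampling_hz=1.0,
        phases=HAND_PHASES,
        meta=SampleMeta("deg", "deg"),
    )
    with caplog.at_level("WARNING"):
        got = feature_E(rec, 0, 0, 1, 4, **RAW)
    assert got == 0.0
    assert "degenerate" in caplog.text


def test_flat_curve_trivial_values():
    curve = np.full((1, 10), 42.0)
    rec = SensorRecording(
        time_s=np.arange(10.0),
        resistance=curve,
        sampling_hz=1.0,
        phases=HAND_PHASES,
        meta=SampleMeta("flat", "flat"),
    )
    assert feature_A(rec, 0, 2, **RAW) == pytest.approx(1.0)
    assert feature_B(rec, 0, 2, **RAW) == pytest.approx(0.0)
    assert feature_C(rec, 0, 1, **RAW) == pytest.approx(0.0)
    assert feature_D(rec, 0, use_snv=False) == pytest.approx(42.0)
    assert feature_F(rec, 0, 0, 4, **RAW) == pytest.approx(0.0)
    assert feature_G(rec, 0, 0.5, use_snv=False) == 0.0
    assert feature_H(rec, 0) == pytest.approx(1.0)


def test_feature_B_negative_for_responding_sensor(noiseless_recording):
    assert feature_B(noiseless_recording, 0, 1500, use_snv=False) < 0


def test_feature_C_magnitude_decreases_during_recovery(noiseless_recording):
    c1 = feature_C(noiseless_recording, 0, 300, use_snv=False)
    c2 = feature_C(noiseless_recording, 0, 1200, use_snv=False)
    assert abs(c2) < abs(c1)


def test_feature_D_closed_form_and_exhaustive_min(noiseless_recording):
    cfg = noiseless_config()
    lo, hi = noiseless_recording.phases["during"]
    for s in range(6):
        got = feature_D(noiseless_recording, s, use_snv=False)
        brute = min(noiseless_recording.resistance[s, lo:hi])
        assert got == brute
        a = cfg.amplitude_control[s]
        sat = 1.0 - np.exp(-cfg.exposure_s / cfg.tau_on_s)
        expected = cfg.baseline_resistance_ohm[s] * (1.0 - a * sat)
        assert got == pytest.approx(expected, rel=1e-9)


def test_feature_H_consistent_with_response_intensity(default_recording):
    for s in range(6):
        assert feature_H(default_recording, s) == pytest.approx(
            response_intensity(default_recording, s), abs=1e-12
        )


def test_out_of_window_timepoints_rejected(hand_recording):
    with pytest.raises(ValueError, match="outside"):
        feature_A(hand_recording, 0, 99, **RAW)
    with pytest.raises(ValueError, match="outside"):
        feature_C(hand_recording, 0, 99, **RAW)
    with pytest.raises(ValueError):
        feature_E(hand_recording, 0, 3, 2, 1, **RAW)
    with pytest.raises(ValueError):
        feature_G(hand_recording, 0, 1.5)


def test_default_extraction_dimensionality(default_recording):
    fv = extract_features(default_recording)
    assert len(fv) == 150
    assert fv.values.index.is_unique
    assert np.all(np.isfinite(fv.values.to_numpy()))


def test_extraction_deterministic(default_recording):
    v1 = extract_features(default_recording).values
    v2 = extract_features(default_recording).values
    assert (v1 == v2).all()


def test_extraction_matches_individual_features(default_recording):
    """Compositional oracle: the vector equals per-feature evaluation."""
    cfg = FeatureConfig()
    fv = extract_features(default_recording, cfg).values
    rec = default_recording
    kw = dict(use_snv=cfg.use_snv, halfwidth_s=cfg.halfwidth_s)
    for s in (0, 3, 5):
        tag = f"s{s + 1}"
        for t in cfg.during_points:
            assert fv[f"{tag}_A_t{t:g}"] == feature_A(rec, s, t, **kw)
            assert fv[f"{tag}_B_t{t:g}"] == feature_B(rec, s, t, **kw)
        for t in cfg.after_points:
            assert fv[f"{tag}_C_t{t:g}"] == feature_C(rec, s, t, **kw)
        assert fv[f"{tag}_D"] == feature_D(rec, s, use_snv=cfg.use_snv)
        for t1, t2, t3 in cfg.triples:
            assert fv[f"{tag}_E_{t1:g}_{t2:g}_{t3:g}"] == feature_E(
                rec, s, t1, t2, t3, **kw
            )
        for t1, t2 in cfg.pairs:
            assert fv[f"{tag}_F_{t1:g}_{t2:g}"] == feature_F(rec, s, t1, t2, **kw)
        for a in cfg.alphas:
            assert fv[f"{tag}_G_a{a:g}"] == feature_G(rec, s, a, use_snv=cfg.use_snv)
        assert fv[f"{tag}_H"] == feature_H(rec, s)


def test_scale_free_features_on_raw_curves(default_recording):
    scaled = SensorRecording(
        time_s=default_recording.time_s,
        resistance=default_recording.resistance * 3.7,
        sampling_hz=default_recording.sampling_hz,
        phases=default_recording.phases,
        meta=default_recording.meta,
    )
    for s in range(6):
        assert feature_A(scaled, s, 1500, use_snv=False) == pytest.approx(
            feature_A(default_recording, s, 1500, use_snv=False), rel=1e-12
        )
        assert feature_H(scaled, s) == pytest.approx(
            feature_H(default_recording, s), rel=1e-12
        )


def test_day_multiplier_invariance_with_snv_only():
    cfg = noiseless_config()
    meta = SampleMeta("dm", "dm", class_label="PCa")
    r1 = simulate_recording(cfg, meta, day_multiplier=1.0)
    r2 = simulate_recording(cfg, meta, day_multiplier=3.3)
    snv_cfg = FeatureConfig(use_snv=True)
    raw_cfg = FeatureConfig(use_snv=False)
    v1 = extract_features(r1, snv_cfg).values
    v2 = extract_features(r2, snv_cfg).values
    np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), rtol=1e-9, atol=1e-12)
    w1 = extract_features(r1, raw_cfg).values
    w2 = extract_features(r2, raw_cfg).values
    assert np.max(np.abs(w1.to_numpy() - w2.to_numpy())) > 1.0  # raw is NOT invariant


def test_hand_config_counts():
    assert HAND_CFG.n_per_sensor == 13
    fv = extract_features(make_hand_recording(), HAND_CFG)
    assert len(fv) == 2 * 13
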