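"""VSD measurement operations against independent brute-force oracles."""

import numpy as np
import pytest

from vsdcortex.errors import (ConfigurationError, DegenerateInputError,
                              InvalidParameterError)
from vsdcortex.geometry import INFRA, SUPRA, assign_layer_bands, build_hex_geometry
from vsdcortex.recordings import StimulusSpec, VSDRecording
from vsdcortex.vsd import (FractionalSignal, activity_map, amplitude_latency,
                           average_trials, fractional_fluorescence,
                           layer_signal, layer_time_heatmap,
                           normalize_to_reference, select_layer_diodes)


def _recording(mat, onset=45, dt=1.274):
    return VSDRecording(intensities=mat, stimulus_onset=onset,
                        stimulation=StimulusSpec(50, "short"),
                        slice_id="s0", condition="control",
                        sampling_interval=dt)


def _signal(values, onset=45, dt=1.274):
    return FractionalSignal(values=values, stimulus_onset=onset,
                            sampling_interval=dt, slice_id="s0",
                            condition="control")


# ---------------------------------------------------------------------------
# fractional fluorescence

def test_constant_intensity_gives_zero_dii():
    sig = fractional_fluorescence(_recording(np.full((3, 100), 250.0)))
    assert np.allclose(sig.values, 0.0)


def test_dii_formula_arithmetic():
    mat = np.full((1, 100), 100.0)
    mat[0, 60] = 99.66
    sig = fractional_fluorescence(_recording(mat))
    assert sig.values[0, 60] * 100 == pytest.approx(0.34)


def test_dii_matches_elementwise_oracle(rng):
    for _ in range(50):
        mat = rng.uniform(50.0, 150.0, size=(5, 100))
        rec = _recording(mat)
        sig = fractional_fluorescence(rec)
        nb = int(round(50.0 / 1.274))
        for i in range(5):
            i_rest = mat[i, 45 - nb:45].mean()
            for t in range(100):
                assert sig.values[i, t] == pytest.approx(
                    (i_rest - mat[i, t]) / i_rest, abs=1e-14)


def test_nonpositive_rest_light_rejected():
    rec = _recording(np.full((2, 100), 100.0))
    rec.intensities = np.zeros((2, 100))     # corrupt after construction
    with pytest.raises(DegenerateInputError):
        fractional_fluorescence(rec)


# ---------------------------------------------------------------------------
# trial averaging

def test_average_of_identical_trials_is_identity(rng):
    v = rng.normal(size=(4, 80))
    out = average_trials([_signal(v)] * 3)
    np.testing.assert_allclose(out.values, v)
    assert out.n_trials_averaged == 3


def test_opposite_trials_cancel(rng):
    v = rng.normal(size=(4, 80))
    out = average_trials([_signal(np.zeros_like(v)), _signal(v), _signal(-v)])
    np.testing.assert_allclose(out.values, 0.0, atol=1e-15)


def test_average_matches_bruteforce_mean(rng):
    trials = [rng.normal(size=(3, 60)) for _ in range(3)]
    out = average_trials([_signal(t) for t in trials])
    expect = (trials[0] + trials[1] + trials[2]) / 3.0
    np.testing.assert_allclose(out.values, expect)


def test_dii_then_average_equals_average_then_dii_for_common_baseline(rng):
    """Linearity: with identical resting light across trials the two
    orderings of averaging and dI/I agree."""
    base = np.full((4, 100), 200.0)
    trials = []
    for _ in range(3):
        m = base.copy()
        m[:, 45:] += rng.uniform(-5, 5, size=(4, 55))
        trials.append(m)
    per_trial = average_trials([fractional_fluorescence(_recording(m))
                                for m in trials])
    pooled = fractional_fluorescence(_recording(np.mean(trials, axis=0)))
    np.testing.assert_allclose(per_trial.values, pooled.values, atol=1e-12)


# ---------------------------------------------------------------------------
# six-diode layer selection

@pytest.fixture(scope="module")
def small_geom():
    return assign_layer_bands(build_hex_geometry(4, 0.05))


def test_uniform_field_layer_signal_equals_single_site(small_geom, rng):
    ts = rng.normal(size=60)
    values = np.tile(ts, (small_geom.n_active, 1))
    out = layer_signal(_signal(values), small_geom, SUPRA, (0.0, 0.1))
    np.testing.assert_allclose(out, ts)


def test_electrode_on_a_site_includes_that_site(small_geom):
    rows = small_geom.band_rows(INFRA)
    target = small_geom.position[rows[3]]
    chosen = select_layer_diodes(small_geom, INFRA, target)
    active_rows = small_geom.active_rows
    assert rows[3] in active_rows[chosen]


def test_layer_signal_matches_exhaustive_nearest6_oracle(small_geom, rng):
    for trial in range(30):
        values = rng.normal(size=(small_geom.n_active, 40))
        electrode = rng.uniform(-0.2, 0.2, size=2)
        layer = SUPRA if trial % 2 == 0 else INFRA
        out = layer_signal(_signal(values), small_geom, layer, electrode)
        # oracle: full distance sort among in-band sites
        act = small_geom.active_rows
        in_band = [k for k in range(act.size)
                   if small_geom.layer_band[act[k]] == layer]
        pos = small_geom.position[act]
        seed = min(in_band, key=lambda k: (np.linalg.norm(pos[k] - electrode),
                                           small_geom.site_id[act[k]]))
        six = sorted(in_band, key=lambda k: (np.linalg.norm(pos[k] - pos[seed]),
                                             small_geom.site_id[act[k]]))[:6]
        np.testing.assert_allclose(out, values[six].mean(axis=0))


def test_too_few_in_band_sites_is_configuration_error():
    g = assign_layer_bands(build_hex_geometry(1, 0.05), supra_fraction=0.2)
    with pytest.raises(ConfigurationError):
        select_layer_diodes(g, SUPRA, (0.0, 0.0))


# ---------------------------------------------------------------------------
# amplitude / latency

def test_flat_trace_flagged_zero_amplitude():
    m = amplitude_latency(np.ones(200), 45, 1.274)
    assert m.amplitude == 0.0 and m.flagged


def test_amplitude_latency_matches_argmax_oracle(rng):
    for _ in range(200):
        tr = rng.normal(size=150)
        m = amplitude_latency(tr, 45, 1.274, search_ms=100.0)
        nb = int(round(50 / 1.274))
        ns = int(round(100 / 1.274))
        base = tr[45 - nb:45].mean()
        seg = tr[46:46 + ns] - base
        k = int(np.argmax(seg))
        assert m.amplitude == pytest.approx(seg[k])
        assert m.latency_ms == pytest.approx((k + 1) * 1.274)
        assert m.peak_sample == 46 + k


def test_amplitude_invariant_to_constant_offset_and_latency_to_scaling(rng):
    tr = rng.normal(size=150)
    m0 = amplitude_latency(tr, 45, 1.274)
    m_off = amplitude_latency(tr + 7.3, 45, 1.274)
    assert m_off.amplitude == pytest.approx(m0.amplitude, abs=1e-10)
    assert m_off.latency_ms == m0.latency_ms
    shifted = tr - tr[0:45].mean()    # keep the peak positive under scaling
    m1 = amplitude_latency(shifted, 45, 1.274)
    m_scaled = amplitude_latency(shifted * 3.7, 45, 1.274)
    assert m_scaled.latency_ms == m1.latency_ms


# ---------------------------------------------------------------------------
# display transforms

def test_normalize_to_reference():
    assert normalize_to_reference(np.array([0.17]), 0.34)[0] == pytest.approx(0.5)
    v = np.array([0.1, 0.34])
    assert normalize_to_reference(v, v.max())[1] == pytest.approx(1.0)
    with pytest.raises(InvalidParameterError):
        normalize_to_reference(v, 0.0)


def test_normalize_matches_elementwise_oracle(rng):
    v = rng.normal(size=(4, 9))
    out = normalize_to_reference(v, 0.34)
    np.testing.assert_allclose(out, v / 0.34)


def test_activity_map_scales_to_session_max(small_geom, rng):
    values = rng.normal(size=(small_geom.n_active, 30))
    frames, pos = activity_map(_signal(values), small_geom, [0, 10, 29])
    assert frames.shape == (3, small_geom.n_active)
    assert np.abs(frames).max() <= 1.0 + 1e-12
    assert pos.shape == (small_geom.n_active, 2)


# ---------------------------------------------------------------------------
# laminar heatmap

def test_uniform_signal_gives_equal_heatmap_bins(small_geom):
    values = np.full((small_geom.n_active, 20), 0.25)
    hm = layer_time_heatmap([_signal(values)], small_geom, n_depth_bins=4)
    assert np.allclose(hm[~np.isnan(hm)], 0.25)


def test_two_band_input_separates_into_two_plateaus(small_geom):
    values = np.zeros((small_geom.n_active, 10))
    supra_mask = small_geom.band_mask_active(SUPRA)
    values[supra_mask] = 0.40
    values[~supra_mask] = 0.10
    hm = layer_time_heatmap([_signal(values)], small_geom, n_depth_bins=6)
    # oracle: per-bin mean from site depths
    depth = small_geom.depth[small_geom.active_rows]
    edges = np.linspace(depth.min(), depth.max(), 7)
    which = np.clip(np.digitize(depth, edges) - 1, 0, 5)
    for b in range(6):
        rows = which == b
        if rows.any():
            assert hm[b, 0] == pytest.approx(values[rows, 0].mean())
    assert hm[0, 0] == pytest.approx(0.40)      # shallowest bin: supragranular
    assert hm[5, 0] == pytest.approx(0.10)      # deepest bin: infragranular


def test_empty_cohort_rejected(small_geom):
    with pytest.raises(InvalidParameterError):
        layer_time_heatmap([], small_geom)
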