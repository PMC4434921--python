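"""Filtering, epoching, rejection, difference waves and peak extraction."""

import numpy as np
import pandas as pd
import pytest

from affectrl import erp
from affectrl.erp import (
    EpochSet,
    EvokedWave,
    average_epochs,
    bandpass,
    baseline_correct,
    classify_outcome,
    classify_outcomes,
    difference_wave,
    epoch,
    frn_analysis,
    mean_rejection_rate,
    peak_component,
    reject_artifacts,
)
from affectrl.rl import AgentParams, simulate_agent
from affectrl.task import TaskConfig, generate_schedule, realize_rewards


def _epochs(data, channels=("Fz",), tmin=-100.0, labels=None):
    return EpochSet(data=np.asarray(data, float), channels=list(channels),
                    sfreq=1000.0, tmin_ms=tmin,
                    labels=labels if labels is not None else pd.DataFrame())


# ---------------------------------------------------------------- filtering

def test_bandpass_preserves_passband_tone():
    t = np.arange(0, 20, 1e-3)
    x = np.sin(2 * np.pi * 10 * t)
    y = bandpass(x, 0.1, 40.0, 1000.0)
    mid = slice(5000, 15000)
    assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)


def test_bandpass_removes_dc():
    x = np.full(30_000, 7.0)
    y = bandpass(x, 0.1, 40.0, 250.0)
    trim = y[7500:-7500]
    assert np.abs(trim).max() < 0.07


def test_bandpass_attenuates_stopband():
    t = np.arange(0, 30, 1e-3)
    x = np.sin(2 * np.pi * 80 * t)
    y = bandpass(x, 0.1, 40.0, 1000.0)
    assert np.abs(y[10_000:-10_000]).max() < 0.1


def test_bandpass_rejects_bad_edges():
    with pytest.raises(ValueError):
        bandpass(np.zeros(100), 40.0, 0.1, 1000.0)
    with pytest.raises(ValueError):
        bandpass(np.zeros(100), 0.1, 600.0, 1000.0)


# ----------------------------------------------------------------- epoching

def test_epoch_counts_and_alignment():
    cont = np.zeros((2, 10_000))
    events = [2000, 5000, 8000]
    cont[:, 5000] = 9.0  # impulse at the second event
    eps = epoch(cont, events, (-100, 700), 1000.0, ["Fz", "Cz"])
    assert eps.data.shape == (3, 2, 801)
    zero_idx = int(np.argmin(np.abs(eps.times_ms)))
    assert eps.data[1, 0, zero_idx] == 9.0


def test_epoch_drops_edge_events_with_warning():
    cont = np.zeros((1, 10_000))
    with pytest.warns(UserWarning, match="dropped"):
        eps = epoch(cont, [50, 5000], (-100, 700), 1000.0, ["Fz"],
                    labels=pd.DataFrame({"outcome": ["reward", "nonreward"]}))
    assert eps.n_epochs == 1
    assert eps.labels["outcome"].tolist() == ["nonreward"]


# ----------------------------------------------------------------- baseline

def test_baseline_constant_epoch_zeroed():
    eps = _epochs(np.full((1, 1, 801), 7.0))
    out = baseline_correct(eps)
    assert np.allclose(out.data, 0.0, atol=1e-9)


def test_baseline_idempotent_and_preserves_bump():
    data = np.zeros((1, 1, 801))
    data[0, 0, 400:450] = 3.0
    with_offset = _epochs(data + 5.0)
    out = baseline_correct(with_offset)
    assert np.abs(out.data[0, 0, :100].mean()) < 1e-9
    assert out.data[0, 0, 420] == pytest.approx(3.0)
    again = baseline_correct(out)
    np.testing.assert_allclose(again.data, out.data, atol=1e-12)


def test_baseline_requires_prestimulus_samples():
    eps = _epochs(np.zeros((1, 1, 100)))
    eps.tmin_ms = 10.0  # post-stimulus-only window
    with pytest.raises(ValueError):
        baseline_correct(eps)


# ---------------------------------------------------------------- rejection

def test_rejection_threshold_rule():
    data = np.zeros((3, 1, 801))
    data[0, 0, 100] = 60.0        # exceeds +-50: rejected
    data[1, 0, :] = 49.0          # bounded by +-49: kept
    eps = _epochs(data, labels=pd.DataFrame({"outcome": ["a", "b", "b"]}))
    kept, report = reject_artifacts(eps, 50.0)
    assert kept.n_epochs == 2 and report.n_rejected == 1
    assert report.percent == pytest.approx(100 / 3)
    kept_all, rep_all = reject_artifacts(eps, 1e9)
    assert kept_all.n_epochs == 3 and rep_all.n_rejected == 0


def test_rejection_monotone_in_threshold():
    rng = np.random.default_rng(0)
    eps = _epochs(rng.normal(0, 30, (50, 1, 100)))
    kept = [reject_artifacts(eps, thr)[0].n_epochs for thr in (20, 40, 60, 120)]
    assert kept == sorted(kept)


def test_rejection_all_rejected_flag_blocks_averaging():
    eps = _epochs(np.full((4, 1, 100), 99.0))
    kept, report = reject_artifacts(eps, 50.0)
    assert report.all_rejected and kept.n_epochs == 0
    with pytest.raises(ValueError):
        average_epochs(kept)


def test_mean_rejection_rate_across_groups():
    reports = [erp.RejectionReport(n_total=100, n_rejected=k, threshold=50)
               for k in (10, 20, 30)]
    assert mean_rejection_rate(reports) == pytest.approx(20.0)


# ----------------------------------------------------------- classification

@pytest.mark.parametrize("chose_rich,reward,expected", [
    (True, 1, "expected-delivery"),
    (False, 0, "expected-omission"),
    (False, 1, "unexpected-delivery"),
    (True, 0, "unexpected-omission"),
])
def test_classify_outcome_mapping(chose_rich, reward, expected):
    assert classify_outcome(chose_rich, reward) == expected


def test_classify_outcomes_vectorized_and_tie_propagation():
    cfg = TaskConfig(n_blocks_per_condition=2, trials_per_condition=80,
                     block_length_range=(30, 50))
    sch = generate_schedule(cfg, seed=0)
    log = simulate_agent(AgentParams(0.3, 3.0), sch, realize_rewards(sch, 1), 2)
    classes = classify_outcomes(log, sch)
    rich = sch.trials.set_index("trial")["rich_deck"]
    i = log.index[5]
    manual = classify_outcome(log.loc[i, "choice"] == rich.loc[log.loc[i, "trial"]],
                              log.loc[i, "reward"])
    assert classes.loc[i] == manual
    sch.trials.loc[:, "p2"] = sch.trials["p1"]
    from affectrl.task import InvalidScheduleError
    with pytest.raises(InvalidScheduleError):
        classify_outcomes(log, sch)


# ----------------------------------------------------- differences and peaks

def test_difference_wave_algebra():
    a = EvokedWave(np.ones((1, 100)), ["Fz"], 1000.0, -100.0, 10)
    b = EvokedWave(np.ones((1, 100)), ["Fz"], 1000.0, -100.0, 10)
    assert np.all(difference_wave(a, b).data == 0.0)
    c = EvokedWave(np.ones((1, 100)) - 5.0, ["Fz"], 1000.0, -100.0, 10)
    assert np.all(difference_wave(c, b).data == -5.0)
    np.testing.assert_array_equal(difference_wave(a, c).data,
                                  -difference_wave(c, a).data)
    bad = EvokedWave(np.ones((1, 100)), ["Cz"], 1000.0, -100.0, 10)
    with pytest.raises(ValueError):
        difference_wave(a, bad)


def test_peak_component_constructed_extrema():
    times = -100.0 + np.arange(801)
    dip = -7.0 * np.exp(-0.5 * ((times - 280) / 30) ** 2)
    wave = EvokedWave(dip[None, :], ["FCz"], 1000.0, -100.0, 1)
    res = peak_component(wave, (200, 400), "negative")
    assert res.loc["FCz", "amplitude"] == pytest.approx(-7.0)
    assert res.loc["FCz", "latency_ms"] == 280.0

    flat = EvokedWave(np.zeros((1, 801)), ["Fz"], 1000.0, -100.0, 1)
    res = peak_component(flat, (200, 400), "negative")
    assert res.loc["Fz", "amplitude"] == 0.0
    assert res.loc["Fz", "latency_ms"] == 200.0  # tie -> earliest

    eep = 4.0 * np.exp(-0.5 * ((times - 150) / 20) ** 2)
    wave = EvokedWave(eep[None, :], ["Cz"], 1000.0, -100.0, 1)
    res = peak_component(wave, (120, 180), "positive")
    assert res.loc["Cz", "amplitude"] == pytest.approx(4.0)
    assert res.loc["Cz", "latency_ms"] == 150.0

    with pytest.raises(ValueError):
        peak_component(wave, (1000, 2000), "negative")


def test_peak_component_matches_exhaustive_scan():
    rng = np.random.default_rng(3)
    wave = EvokedWave(rng.normal(0, 2, (3, 801)), ["Fz", "FCz", "Cz"],
                      1000.0, -100.0, 1)
    res = peak_component(wave, (200, 400), "negative")
    times = wave.times_ms
    for k, ch in enumerate(wave.channels):
        best_amp, best_lat = np.inf, None
        for j, t in enumerate(times):
            if 200 <= t <= 400 and wave.data[k, j] < best_amp:
                best_amp, best_lat = wave.data[k, j], t
        assert res.loc[ch, "amplitude"] == best_amp
        assert res.loc[ch, "latency_ms"] == best_lat


# ------------------------------------------------------------- frn_analysis

def _labeled_epochs(n_per_class, amp_map, noise_sd=0.0, seed=0, channels=("Fz", "FCz", "Cz")):
    rng = np.random.default_rng(seed)
    times = -100.0 + np.arange(801)
    bump = np.exp(-0.5 * ((times - 280) / 40) ** 2)
    rows, data = [], []
    for cls, amp in amp_map.items():
        for _ in range(n_per_class):
            e = rng.normal(0, noise_sd, (len(channels), 801)) if noise_sd else \
                np.zeros((len(channels), 801))
            e += amp * bump
            data.append(e)
            rows.append({"outcome_class": cls,
                         "outcome": "reward" if cls.endswith("delivery") else "nonreward"})
    return _epochs(np.stack(data), channels=channels, labels=pd.DataFrame(rows))


def test_frn_general_recovers_embedded_negativity():
    eps = _labeled_epochs(20, {"expected-delivery": 0.0, "expected-omission": -8.0,
                               "unexpected-delivery": 0.0, "unexpected-omission": -8.0},
                          noise_sd=1.0, seed=1)
    res = frn_analysis(eps, "general")
    assert res.peaks.loc["FCz", "amplitude"] == pytest.approx(-8.0, abs=0.8)
    assert 200 <= res.peaks.loc["FCz", "latency_ms"] <= 400


def test_frn_expected_variant_bookkeeping():
    eps = _labeled_epochs(15, {"expected-delivery": 0.0, "expected-omission": -5.0,
                               "unexpected-delivery": 0.0, "unexpected-omission": -9.0})
    res = frn_analysis(eps, "expected")
    assert (res.n_minuend, res.n_subtrahend) == (15, 15)
    assert res.peaks.loc["Cz", "amplitude"] == pytest.approx(-5.0, abs=1e-9)


def test_frn_missing_cell_not_fabricated():
    eps = _labeled_epochs(4, {"expected-delivery": 0.0, "expected-omission": -5.0})
    res = frn_analysis(eps, "expected", min_epochs=10)
    assert res.missing and res.peaks.empty


def test_pipeline_linearity():
    eps = _labeled_epochs(10, {"expected-delivery": 0.0, "expected-omission": -4.0},
                          noise_sd=0.5, seed=2)
    scaled = EpochSet(eps.data * 3.0, eps.channels, eps.sfreq, eps.tmin_ms, eps.labels)
    r1 = frn_analysis(baseline_correct(eps), "general")
    r3 = frn_analysis(baseline_correct(scaled), "general")
    np.testing.assert_allclose(r3.wave.data, 3.0 * r1.wave.data, atol=1e-10)
    assert r3.peaks["amplitude"].loc["FCz"] == pytest.approx(
        3.0 * r1.peaks["amplitude"].loc["FCz"])


def test_epoch_bundle_round_trip(tmp_path):
    eps = _labeled_epochs(3, {"expected-delivery": 1.0, "expected-omission": -1.0},
                          noise_sd=0.2, seed=5)
    erp.write_epoch_bundle(eps, tmp_path / "bundle")
    back = erp.read_epoch_bundle(tmp_path / "bundle")
    assert back.channels == eps.channels and back.sfreq == eps.sfreq
    np.testing.assert_allclose(back.data, eps.data, atol=1e-4)  # float32 storage
    assert back.labels["outcome_class"].tolist() == eps.labels["outcome_class"].tolist()


def test_epoching_matches_mne():
    """Independent cross-check of epoch extraction and averaging against MNE."""
    mne = pytest.importorskip("mne")
    rng = np.random.default_rng(7)
    cont = rng.normal(0, 1, (2, 20_000))
    events = np.array([3000, 8000, 15_000])
    ours = epoch(cont, events, (-100, 700), 1000.0, ["Fz", "Cz"])
    info = mne.create_info(["Fz", "Cz"], 1000.0, "eeg")
    raw = mne.io.RawArray(cont * 1e-6, info, verbose="error")
    ev = np.column_stack([events, np.zeros_like(events), np.ones_like(events)])
    m_eps = mne.Epochs(raw, ev, tmin=-0.1, tmax=0.7, baseline=None,
                       preload=True, verbose="error")
    np.testing.assert_allclose(ours.data, m_eps.get_data(copy=True) * 1e6,
                               atol=1e-9)
    np.testing.assert_allclose(average_epochs(ours).data,
                               m_eps.average().data * 1e6, atol=1e-9)


def test_frn_peak_mode_sides():
    """Peaks measured per side then subtracted: with a clean embedded
    negativity on the omission side only, both modes agree."""
    eps = _labeled_epochs(12, {"expected-delivery": 0.0, "expected-omission": -6.0})
    diff = frn_analysis(eps, "expected")
    sides = frn_analysis(eps, "expected", peak_mode="sides")
    assert sides.peaks.loc["FCz", "amplitude"] == pytest.approx(
        diff.peaks.loc["FCz", "amplitude"], abs=1e-9)
    with pytest.raises(ValueError):
        frn_analysis(eps, "expected", peak_mode="bogus")
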