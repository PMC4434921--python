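"""Feedback- and prime-locked ERP processing.

Implements the standard event-related-potential chain on epoched EEG in
microvolts: zero-phase Butterworth bandpass filtering, epoch extraction,
pre-stimulus baseline correction, amplitude-threshold artifact rejection,
condition averaging, difference waves and windowed peak extraction.

Feedback outcomes are crossed with the learned expectation to form four
classes: choosing the rich deck and being rewarded (expected delivery),
poor deck unrewarded (expected omission), poor deck rewarded (unexpected
delivery), and rich deck unrewarded (unexpected omission).  Three FRN
difference waves follow: General (all non-reward minus all reward),
Expected (expected omission minus expected delivery) and Unexpected
(unexpected omission minus unexpected delivery); each is quantified as the
negative peak in 200-400 ms at fronto-central channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EpochSet",
    "EvokedWave",
    "FRNResult",
    "RejectionReport",
    "OUTCOME_CLASSES",
    "bandpass",
    "rereference",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "classify_outcome",
    "classify_outcomes",
    "average_epochs",
    "difference_wave",
    "peak_component",
    "frn_analysis",
    "mean_rejection_rate",
    "write_epoch_bundle",
    "read_epoch_bundle",
]

OUTCOME_CLASSES = (
    "expected-delivery",
    "expected-omission",
    "unexpected-delivery",
    "unexpected-omission",
)

FRN_VARIANTS = ("general", "expected", "unexpected")


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is (n_epochs, n_channels, n_samples) in uV.

    ``tmin_ms`` is the time of the first sample relative to the event;
    ``labels`` is a per-epoch table (outcome/outcome_class/condition/state/
    subject columns as available) aligned with the first axis.
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float = 1000.0
    tmin_ms: float = -100.0
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel-name count does not match data")
        if len(self.labels) not in (0, self.data.shape[0]):
            raise ValueError("labels must have one row per epoch")
        self.labels = self.labels.reset_index(drop=True)
        if self.tmin_ms >= 0:
            raise ValueError("epoch window must start before the event (tmin < 0)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage {self.channels}") from None

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        labels = self.labels.iloc[mask].reset_index(drop=True) if len(self.labels) else self.labels
        return replace(self, data=self.data[mask], labels=labels)


@dataclass
class EvokedWave:
    """An averaged (or difference) waveform: (n_channels, n_samples) in uV."""

    data: np.ndarray
    channels: list[str]
    sfreq: float
    tmin_ms: float
    n_epochs: int = 0

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[1]) * 1000.0 / self.sfreq


@dataclass
class RejectionReport:
    """Outcome of amplitude-threshold artifact rejection."""

    n_total: int
    n_rejected: int
    threshold: float
    by_label: pd.DataFrame | None = None
    all_rejected: bool = False

    @property
    def rate(self) -> float:
        """Rejected fraction of all epochs."""
        return self.n_rejected / self.n_total if self.n_total else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def mean_rejection_rate(reports) -> float:
    """Mean rejection percentage across a collection of reports (one per
    group/condition), as conventionally summarized over an experiment."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports given")
    return float(np.mean([r.percent for r in reports]))


@dataclass
class FRNResult:
    """A difference wave plus its windowed negative peak per channel."""

    variant: str
    wave: EvokedWave
    peaks: pd.DataFrame            # index channel; columns amplitude, latency_ms
    n_minuend: int                 # omission / non-reward side
    n_subtrahend: int              # delivery / reward side
    window_ms: tuple[float, float] = (200.0, 400.0)
    missing: bool = False


def bandpass(data, low: float, high: float, sfreq: float | None = None,
             order: int = 4):
    """Zero-phase (forward-backward) Butterworth bandpass along time.

    Accepts an :class:`EpochSet` (returns a filtered copy) or a plain array
    whose last axis is time (then ``sfreq`` is required).  The 0.1-40 Hz
    default band of the pipeline removes DC and slow drift while keeping
    ERP components intact.
    """
    if isinstance(data, EpochSet):
        filtered = bandpass(data.data, low, high, data.sfreq, order)
        return replace(data, data=filtered)
    if sfreq is None:
        raise ValueError("sfreq is required for array input")
    if not (0 < low < high < sfreq / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({sfreq / 2} Hz), "
            f"got {low}-{high}")
    sos = butter(order, (low, high), btype="bandpass", fs=sfreq, output="sos")
    arr = np.asarray(data, dtype=float)
    # pad past the slow high-pass pole's settling time (~3/low seconds),
    # else the reflection transient leaks drift into the output
    padlen = int(min(arr.shape[-1] - 1, max(3 * sfreq / low, 100)))
    return sosfiltfilt(sos, arr, axis=-1, padlen=padlen)


def rereference(continuous: np.ndarray, channels: list[str],
                ref_channels: tuple[str, str]) -> np.ndarray:
    """Subtract the mean of two reference channels (e.g. mastoids) from all
    channels of a continuous recording.  A no-op when the recording was
    generated reference-free with zero-mean references."""
    idx = [channels.index(r) for r in ref_channels]
    ref = np.asarray(continuous, dtype=float)[idx].mean(axis=0, keepdims=True)
    return continuous - ref


def epoch(continuous: np.ndarray, events, window_ms: tuple[float, float],
          sfreq: float, channels: list[str],
          labels: pd.DataFrame | None = None) -> EpochSet:
    """Cut one epoch per event from a continuous (n_channels, n_samples)
    recording.  ``events`` are event times in samples; the window is in ms
    relative to the event and inclusive of both endpoints.  Events whose
    window would leave the recording are dropped with a warning."""
    continuous = np.asarray(continuous, dtype=float)
    lo_ms, hi_ms = window_ms
    lo = int(round(lo_ms * sfreq / 1000.0))
    hi = int(round(hi_ms * sfreq / 1000.0))
    n_samp = hi - lo + 1
    events = np.asarray(events, dtype=int)
    good = (events + lo >= 0) & (events + hi < continuous.shape[1])
    n_dropped = int((~good).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) too close to the recording edge; dropped")
    kept = events[good]
    data = np.stack([continuous[:, e + lo:e + lo + n_samp] for e in kept]) \
        if len(kept) else np.empty((0, continuous.shape[0], n_samp))
    if labels is not None:
        labels = labels.iloc[good].reset_index(drop=True)
    return EpochSet(data=data, channels=list(channels), sfreq=sfreq,
                    tmin_ms=float(lo_ms), labels=labels if labels is not None else pd.DataFrame())


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean over the pre-stimulus window
    [tmin, 0) ms."""
    pre = epochs.times_ms < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples to baseline on")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_artifacts(epochs: EpochSet, threshold: float = 50.0
                     ) -> tuple[EpochSet, RejectionReport]:
    """Drop every epoch in which any channel at any sample exceeds
    +-threshold uV.  Returns the kept epochs and a report with per-label
    rejection rates (computed over ``outcome`` / ``outcome_class`` columns
    when present)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = (np.abs(epochs.data) > threshold).any(axis=(1, 2))
    by_label = None
    if len(epochs.labels):
        cols = [c for c in ("outcome", "outcome_class") if c in epochs.labels.columns]
        if cols:
            tab = epochs.labels[cols].copy()
            tab["rejected"] = bad
            by_label = tab.groupby(cols, observed=True)["rejected"].agg(["mean", "sum", "count"])
    report = RejectionReport(n_total=epochs.n_epochs, n_rejected=int(bad.sum()),
                             threshold=threshold, by_label=by_label,
                             all_rejected=bool(bad.all()) and epochs.n_epochs > 0)
    return epochs.select(~bad), report


def classify_outcome(chose_rich: bool, reward: int) -> str:
    """Map (chose rich deck?, rewarded?) to one of the four outcome classes."""
    if chose_rich:
        return "expected-delivery" if reward else "unexpected-omission"
    return "unexpected-delivery" if reward else "expected-omission"


def classify_outcomes(trials: pd.DataFrame, schedule) -> pd.Series:
    """Vectorized outcome classification of a trial log against its schedule.

    Raises the schedule's tie error if any trial's rich deck is undefined.
    """
    sched = schedule.trials
    if (sched["p1"].to_numpy() == sched["p2"].to_numpy()).any():
        from .task import InvalidScheduleError
        raise InvalidScheduleError("tied deck probabilities: rich deck undefined")
    rich = sched.set_index("trial")["rich_deck"]
    chose_rich = trials["choice"].to_numpy() == rich.loc[trials["trial"]].to_numpy()
    reward = trials["reward"].to_numpy().astype(bool)
    out = np.where(chose_rich,
                   np.where(reward, "expected-delivery", "unexpected-omission"),
                   np.where(reward, "unexpected-delivery", "expected-omission"))
    return pd.Series(out, index=trials.index, name="outcome_class")


def average_epochs(epochs: EpochSet, mask=None) -> EvokedWave:
    """Average epochs (optionally a subset) into an evoked waveform."""
    data = epochs.data if mask is None else epochs.data[np.asarray(mask)]
    if data.shape[0] == 0:
        raise ValueError("refusing to average an empty epoch set")
    return EvokedWave(data=data.mean(axis=0), channels=list(epochs.channels),
                      sfreq=epochs.sfreq, tmin_ms=epochs.tmin_ms,
                      n_epochs=data.shape[0])


def difference_wave(minuend: EvokedWave, subtrahend: EvokedWave) -> EvokedWave:
    """Pointwise subtraction of two evoked waveforms (omission minus
    delivery for FRN variants)."""
    if minuend.channels != subtrahend.channels:
        raise ValueError("channel sets differ")
    if minuend.data.shape != subtrahend.data.shape or \
            minuend.sfreq != subtrahend.sfreq or minuend.tmin_ms != subtrahend.tmin_ms:
        raise ValueError("window/rate mismatch between operands")
    return EvokedWave(data=minuend.data - subtrahend.data,
                      channels=list(minuend.channels), sfreq=minuend.sfreq,
                      tmin_ms=minuend.tmin_ms,
                      n_epochs=min(minuend.n_epochs, subtrahend.n_epochs))


def peak_component(wave: EvokedWave, window_ms: tuple[float, float],
                   polarity: str, channels=None) -> pd.DataFrame:
    """Windowed peak amplitude and latency per channel.

    Negative polarity takes the minimum sample in the window, positive the
    maximum; ties are broken by the earliest latency.  Returns a frame
    indexed by channel with ``amplitude`` (uV) and ``latency_ms`` columns.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    times = wave.times_ms
    in_win = (times >= window_ms[0]) & (times <= window_ms[1])
    if not in_win.any():
        raise ValueError(f"window {window_ms} contains no samples")
    sel = channels if channels is not None else wave.channels
    rows = []
    for ch in sel:
        i = wave.channels.index(ch)
        seg = wave.data[i, in_win]
        j = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
        rows.append((ch, float(seg[j]), float(times[in_win][j])))
    return pd.DataFrame(rows, columns=["channel", "amplitude", "latency_ms"]
                        ).set_index("channel")


def _variant_masks(labels: pd.DataFrame, variant: str):
    cls = labels["outcome_class"]
    if variant == "general":
        minu = cls.isin(["expected-omission", "unexpected-omission"])
        subt = cls.isin(["expected-delivery", "unexpected-delivery"])
    elif variant == "expected":
        minu = cls == "expected-omission"
        subt = cls == "expected-delivery"
    elif variant == "unexpected":
        minu = cls == "unexpected-omission"
        subt = cls == "unexpected-delivery"
    else:
        raise ValueError(f"variant must be one of {FRN_VARIANTS}, got {variant!r}")
    return minu.to_numpy(), subt.to_numpy()


def frn_analysis(epochs: EpochSet, variant: str = "general",
                 split_by: str | list[str] | None = None,
                 channels: tuple[str, ...] = ("Fz", "FCz", "Cz"),
                 window_ms: tuple[float, float] = (200.0, 400.0),
                 min_epochs: int = 10, peak_mode: str = "difference"):
    """Average each side of an FRN variant, subtract, and extract the
    windowed negative peak at the requested channels.

    With ``split_by`` (e.g. ``"state"`` or ``["condition", "state"]``) a
    dict of cell -> :class:`FRNResult` is returned; cells where either side
    has fewer than ``min_epochs`` epochs are marked ``missing`` rather than
    fabricated.

    ``peak_mode="difference"`` (default) measures the peak on the
    difference wave; ``peak_mode="sides"`` measures the windowed negative
    peak on each side's raw average and reports their difference (the peak
    latency is then taken from the omission side).
    """
    if peak_mode not in ("difference", "sides"):
        raise ValueError("peak_mode must be 'difference' or 'sides'")
    if "outcome_class" not in epochs.labels.columns:
        raise ValueError("epochs need an 'outcome_class' label column")
    for ch in channels:
        epochs.channel_index(ch)

    if split_by is not None:
        keys = split_by if isinstance(split_by, str) else list(split_by)
        results = {}
        for cell, sub in epochs.labels.groupby(keys, observed=True):
            mask = np.zeros(epochs.n_epochs, dtype=bool)
            mask[sub.index.to_numpy()] = True
            results[cell] = frn_analysis(epochs.select(mask), variant=variant,
                                         channels=channels, window_ms=window_ms,
                                         min_epochs=min_epochs, peak_mode=peak_mode)
        return results

    minu, subt = _variant_masks(epochs.labels, variant)
    n_minu, n_subt = int(minu.sum()), int(subt.sum())
    if min(n_minu, n_subt) < min_epochs:
        empty = EvokedWave(np.zeros((len(channels), epochs.data.shape[2])),
                           list(channels), epochs.sfreq, epochs.tmin_ms, 0)
        return FRNResult(variant=variant, wave=empty,
                         peaks=pd.DataFrame(columns=["amplitude", "latency_ms"]),
                         n_minuend=n_minu, n_subtrahend=n_subt,
                         window_ms=window_ms, missing=True)
    ave_minu = average_epochs(epochs, minu)
    ave_subt = average_epochs(epochs, subt)
    wave = difference_wave(ave_minu, ave_subt)
    if peak_mode == "difference":
        peaks = peak_component(wave, window_ms, "negative", channels=channels)
    else:
        p_minu = peak_component(ave_minu, window_ms, "negative", channels=channels)
        p_subt = peak_component(ave_subt, window_ms, "negative", channels=channels)
        peaks = p_minu.copy()
        peaks["amplitude"] = p_minu["amplitude"] - p_subt["amplitude"]
    ch_idx = [epochs.channel_index(c) for c in channels]
    wave = EvokedWave(wave.data[ch_idx], list(channels), wave.sfreq,
                      wave.tmin_ms, wave.n_epochs)
    return FRNResult(variant=variant, wave=wave, peaks=peaks,
                     n_minuend=n_minu, n_subtrahend=n_subt, window_ms=window_ms)


def write_epoch_bundle(epochs: EpochSet, directory) -> None:
    """Documented bundle: ``meta.json`` (channels, rate, window, labels) +
    ``epochs.bin`` (little-endian float32, epoch-major then channel then
    time)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "channels": list(epochs.channels),
        "sfreq": epochs.sfreq,
        "tmin_ms": epochs.tmin_ms,
        "shape": list(epochs.data.shape),
        "labels": epochs.labels.to_dict(orient="list"),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    epochs.data.astype("<f4").tofile(directory / "epochs.bin")


def read_epoch_bundle(directory) -> EpochSet:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(directory / "epochs.bin", dtype="<f4").reshape(shape)
    return EpochSet(data=data.astype(float), channels=meta["channels"],
                    sfreq=meta["sfreq"], tmin_ms=meta["tmin_ms"],
                    labels=pd.DataFrame(meta["labels"]))
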