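"""Deterministic signal conditioning of epoched EEG.

The canonical order mirrors standard ERP practice for stimulation-artifact
data: broad band-pass → (interpolation) → trial rejection → baseline
correction → final low-pass → common-average reference.  Every operation
is pure (returns a new :class:`EpochSet`), appends itself to the
provenance log, and warns if applied out of canonical order.

Filters are 4th-order Butterworth sections applied forward–backward
(zero phase), the standard choice when ERP latencies must be preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet
from .montage import neighbours, template_positions

CANONICAL_ORDER = ("bandpass", "interpolate_channels", "reject_trials",
                   "baseline_correct", "lowpass", "rereference_average")


@dataclass
class PreprocConfig:
    """Defaults of the conditioning chain (µV / Hz / ms)."""

    hp_hz: float = 0.5
    lp_hz: float = 80.0
    final_lp_hz: float = 40.0
    baseline_window: tuple[float, float] = (-500.0, -260.0)
    reject_uv: float = 100.0
    notch_50hz: bool = False
    interpolate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.hp_hz >= self.lp_hz:
            raise ValueError("high-pass cutoff must lie below low-pass")
        if self.reject_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if not (self.baseline_window[0] < self.baseline_window[1] <= 0):
            raise ValueError("baseline window must precede stimulus onset")


def _check_order(epochs: EpochSet, op: str) -> None:
    done = [e["op"] for e in epochs.log if e.get("op") in CANONICAL_ORDER]
    pos = CANONICAL_ORDER.index(op)
    late = [d for d in done if CANONICAL_ORDER.index(d) > pos]
    if late:
        warnings.warn(
            f"{op} applied after {late} — outside the canonical "
            f"preprocessing order {CANONICAL_ORDER}", stacklevel=3)


def bandpass(epochs: EpochSet, hp_hz: float | None, lp_hz: float | None,
             order: int = 4, _opname: str = "bandpass") -> EpochSet:
    """Zero-phase Butterworth band-pass (either edge may be ``None``)."""
    nyq = epochs.srate / 2.0
    for cut in (hp_hz, lp_hz):
        if cut is not None and not (0 < cut < nyq):
            raise ValueError(f"cutoff {cut} Hz outside (0, Nyquist)")
    if hp_hz is not None and lp_hz is not None:
        sos = signal.butter(order, [hp_hz, lp_hz], btype="bandpass",
                            fs=epochs.srate, output="sos")
    elif hp_hz is not None:
        sos = signal.butter(order, hp_hz, btype="highpass", fs=epochs.srate,
                            output="sos")
    elif lp_hz is not None:
        sos = signal.butter(order, lp_hz, btype="lowpass", fs=epochs.srate,
                            output="sos")
    else:
        raise ValueError("at least one cutoff required")
    _check_order(epochs, _opname)
    out = signal.sosfiltfilt(sos, epochs.data.astype(np.float64),
                             axis=-1).astype(epochs.data.dtype)
    entry = {"op": _opname, "hp_hz": hp_hz, "lp_hz": lp_hz, "order": order,
             "design": "butterworth-sos-filtfilt"}
    return epochs.with_data(out, entry)


def lowpass(epochs: EpochSet, lp_hz: float, order: int = 4) -> EpochSet:
    """Final zero-phase low-pass (e.g. 40 Hz before ERP statistics)."""
    return bandpass(epochs, None, lp_hz, order=order, _opname="lowpass")


def notch(epochs: EpochSet, freq_hz: float = 50.0, q: float = 30.0) -> EpochSet:
    """Optional mains notch (off by default; synthetic data has no mains)."""
    b, a = signal.iirnotch(freq_hz, q, fs=epochs.srate)
    out = signal.filtfilt(b, a, epochs.data.astype(np.float64),
                          axis=-1).astype(epochs.data.dtype)
    return epochs.with_data(out, {"op": "notch", "freq_hz": freq_hz, "q": q})


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-500.0, -260.0)
                     ) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window_ms``.

    The window is half-open; afterwards the data mean over the window is
    zero, making the operation idempotent.
    """
    _check_order(epochs, "baseline_correct")
    sl = epochs.window_slice(window_ms)
    base = epochs.data[:, :, sl].mean(axis=-1, keepdims=True)
    entry = {"op": "baseline_correct", "window_ms": list(window_ms),
             "n_samples": sl.stop - sl.start}
    return epochs.with_data(epochs.data - base, entry)


def reject_trials(epochs: EpochSet, threshold_uv: float = 100.0
                  ) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials whose absolute voltage exceeds the threshold anywhere.

    The rule is strict: a trial is rejected iff ``|v| > threshold`` at any
    channel × sample; a sample at exactly the threshold is retained.
    Returns the reduced set plus a per-trial report.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    _check_order(epochs, "reject_trials")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    report = epochs.design.copy()
    report["peak_uv"] = peak
    report["rejected"] = ~keep
    entry = {"op": "reject_trials", "threshold_uv": threshold_uv,
             "n_rejected": int((~keep).sum()), "n_kept": int(keep.sum())}
    reduced = epochs.with_data(epochs.data[keep], entry,
                               design=epochs.design[keep])
    return reduced, report


def retained_counts(report: pd.DataFrame,
                    by=("fnmes",)) -> pd.DataFrame:
    """Retained/rejected trial counts per condition cell."""
    g = report.groupby(list(by))["rejected"]
    return pd.DataFrame({"n_total": g.size(), "n_rejected": g.sum(),
                         "n_retained": g.size() - g.sum()}).reset_index()


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Common-average reference: at every sample the channel mean is zero."""
    if len(epochs.channels) < 2:
        raise ValueError("average reference needs >= 2 channels")
    _check_order(epochs, "rereference_average")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(out, {"op": "rereference_average"})


def interpolation_weights(bad: str, good: list[str],
                          radius: float = 0.045) -> dict[str, float]:
    """Inverse-distance weights of ``bad``'s good neighbours (sum to 1)."""
    pos = template_positions()
    nbrs = [c for c in neighbours(bad, radius) if c in good]
    if len(nbrs) < 3:
        raise ValueError(
            f"channel {bad!r} has only {len(nbrs)} good neighbours (< 3)")
    d = np.array([np.linalg.norm(pos[c] - pos[bad]) for c in nbrs])
    w = 1.0 / d
    w /= w.sum()
    return dict(zip(nbrs, w))


def interpolate_channels(epochs: EpochSet, bad: list[str],
                         radius: float = 0.045) -> EpochSet:
    """Replace each bad channel by the inverse-distance-weighted mean of
    its good neighbours on the template head; good channels are untouched.
    """
    if not bad:
        return epochs.with_data(epochs.data.copy(),
                                {"op": "interpolate_channels", "bad": []})
    unknown = [c for c in bad if c not in epochs.channels]
    if unknown:
        raise KeyError(f"channels not in montage: {unknown}")
    _check_order(epochs, "interpolate_channels")
    good = [c for c in epochs.channels if c not in bad]
    data = epochs.data.copy()
    lut = {c: i for i, c in enumerate(epochs.channels)}
    for ch in bad:
        weights = interpolation_weights(ch, good, radius)
        acc = np.zeros_like(data[:, 0, :], dtype=np.float64)
        for nb, w in weights.items():
            acc += w * data[:, lut[nb], :]
        data[:, lut[ch], :] = acc.astype(data.dtype)
    entry = {"op": "interpolate_channels", "bad": list(bad), "radius": radius}
    return epochs.with_data(data, entry)


def run_pipeline(epochs: EpochSet, config: PreprocConfig | None = None
                 ) -> tuple[EpochSet, pd.DataFrame]:
    """Full conditioning chain in canonical order; returns the cleaned
    epochs and the rejection report."""
    cfg = config or PreprocConfig()
    out = bandpass(epochs, cfg.hp_hz, cfg.lp_hz)
    if cfg.notch_50hz:
        out = notch(out, 50.0)
    if cfg.interpolate:
        out = interpolate_channels(out, list(cfg.interpolate))
    out, report = reject_trials(out, cfg.reject_uv)
    out = baseline_correct(out, cfg.baseline_window)
    out = lowpass(out, cfg.final_lp_hz)
    out = rereference_average(out)
    return out, report
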