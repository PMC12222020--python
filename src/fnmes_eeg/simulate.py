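"""Synthetic EEG epochs, stimulation artifacts, choices and AU traces.

The generator plants, on top of 1/f + white background noise, the three
signal components the downstream analyses target:

* an N170 — a Gaussian-windowed negative occipito-temporal deflection
  centred in the 150–200 ms window, whose amplitude depends on emotion and
  on the stimulation condition;
* a beta-band (13–22 Hz) oscillation shared between central and
  left-occipital channels from 650 ms onward.  The shared fraction is the
  per-condition coupling strength ``c``: every involved channel receives
  ``sqrt(c) * shared + sqrt(1 - c) * private`` so that, absent background
  noise, across-trial magnitude coherence between any central–occipital
  pair converges to ``c`` (the analytic common-source limit);
* optionally (separate operation) a biphasic 70 Hz pulse-train artifact
  with a frontal-dominant spatial footprint, identical for every trial of
  a stimulation condition so that happy−sad differencing removes it
  exactly.

Binary choices follow a subject-level random-intercept logistic model, and
AU time series mimic OpenFace intensity output with a stimulation-locked
lift of AU12 (the lip-corner puller driven by zygomaticus major).

All randomness derives from one integer seed through
``numpy.random.SeedSequence`` spawning (one child stream per component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (EpochSet, SRATE_DEFAULT, TMIN_MS_DEFAULT,
                         TMAX_MS_DEFAULT, n_samples_for, window_slice)
from .montage import (CHANNELS_64, N170_CHANNELS, ROI_CENTRAL,
                      ROI_OCCIPITAL_LEFT, channel_index,
                      posterior_gain_profile)

# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class NoiseSpec:
    """Background-noise model: 1/f^alpha ("pink") plus white noise, µV."""

    pink_rms_uv: float = 8.0
    white_sd_uv: float = 2.0
    alpha: float = 1.0


def _default_emotion_deltas() -> dict[str, float]:
    # emotional faces elicit a larger (more negative) N170 than neutral
    return {"neutral": 0.0, "happy": -1.5, "sad": -1.0}


def _default_beta_coupling() -> dict[tuple[str, str], float]:
    # coupling strength by (fnmes, eventual choice); without stimulation
    # coherence is higher for faces judged happy, the pattern reversing
    # under late (and, as a trend, early) stimulation
    return {
        ("off", "happy"): 0.340, ("off", "sad"): 0.316,
        ("early", "happy"): 0.320, ("early", "sad"): 0.332,
        ("late", "happy"): 0.318, ("late", "sad"): 0.332,
    }


@dataclass
class EffectParams:
    """Ground-truth effect sizes for the epoch and choice generators.

    ``n170_base_amp`` is the (negative) deflection on neutral faces without
    stimulation; emotion deltas add to it.  ``n170_early_fnmes_delta`` is a
    main-effect amplitude reduction (positive shift) applied to every face
    under early stimulation, and ``n170_happy_early_delta`` an additional
    reduction specific to happy faces under early stimulation — it is this
    interaction term that survives the happy−sad double subtraction.
    Choice coefficients are log-odds of answering "happy" relative to a
    neutral face without stimulation.
    """

    n170_base_amp: float = -5.0
    n170_emotion_delta: dict[str, float] = field(
        default_factory=_default_emotion_deltas)
    n170_early_fnmes_delta: float = 1.0
    n170_happy_early_delta: float = 2.0
    n170_window: tuple[float, float] = (150.0, 200.0)
    n170_channels: tuple[str, ...] = N170_CHANNELS
    beta_band: tuple[float, float] = (13.0, 22.0)
    beta_coupling: dict[tuple[str, str], float] = field(
        default_factory=_default_beta_coupling)
    beta_onset_ms: float = 650.0
    beta_amp_uv: float = 10.0
    beta_channels_central: tuple[str, ...] = ROI_CENTRAL
    beta_channels_occipital: tuple[str, ...] = ROI_OCCIPITAL_LEFT
    choice_b_early: float = 0.17
    choice_b_late: float = 0.133
    choice_b_happy: float = 5.50
    choice_b_sad: float = -4.23
    subject_sd: float = 1.36

    def validate(self, channels=CHANNELS_64) -> None:
        for key, c in self.beta_coupling.items():
            if not (0.0 <= c < 1.0):
                raise ValueError(f"coupling {key} = {c} outside [0, 1)")
        for ch in (*self.n170_channels, *self.beta_channels_central,
                   *self.beta_channels_occipital):
            if ch not in channels:
                raise ValueError(f"unknown channel {ch!r}")
        for v in (self.n170_base_amp, self.n170_early_fnmes_delta,
                  self.beta_amp_uv, self.subject_sd):
            if not np.isfinite(v):
                raise ValueError("non-finite effect parameter")


@dataclass
class ArtifactSpec:
    """Biphasic pulse-train stimulation artifact.

    A 500 ms train at 70 Hz carries exactly 35 biphasic pulses (100 µs per
    phase — far shorter than one EEG sample, so each pulse is represented
    as a signed two-sample transient).  ``window_ms`` is (−250, 250) for
    early and (500, 1000) for late stimulation.
    """

    rate_hz: float = 70.0
    train_ms: float = 500.0
    pulse_width_us: float = 100.0
    window_ms: tuple[float, float] = (-250.0, 250.0)
    amplitude_uv: float = 60.0
    spatial_profile: np.ndarray | None = None
    target: str | None = None  # fnmes level; inferred from window if None

    def __post_init__(self) -> None:
        w0, w1 = self.window_ms
        if not np.isclose(w1 - w0, self.train_ms):
            raise ValueError("window length must equal train duration")
        n_pulses = self.rate_hz * self.train_ms / 1000.0
        if not np.isclose(n_pulses, round(n_pulses)):
            raise ValueError("rate x duration must give an integer pulse count")
        if self.target is None:
            self.target = "early" if w0 < 0 else "late"

    @property
    def n_pulses(self) -> int:
        return int(round(self.rate_hz * self.train_ms / 1000.0))


# ---------------------------------------------------------------------------
# noise / component builders


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise along the last axis."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)
    spec *= gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # normalise by the analytic output variance of the shaping filter
    norm = np.sqrt(2.0 * np.sum(gain[1:] ** 2) / n_samples)
    return x / norm


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, srate: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    keep = (f >= band[0]) & (f <= band[1])
    spec[..., ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    norm = np.sqrt(keep.sum() * 2.0 / n_samples)
    return x / norm


def _n170_profile(times_ms: np.ndarray, window: tuple[float, float],
                  win_slice: slice) -> np.ndarray:
    """Gaussian bump centred mid-window, normalised so its mean over the
    extraction window is exactly 1 (hence noise-free extraction returns the
    planted amplitude to machine precision)."""
    centre = 0.5 * (window[0] + window[1])
    sigma = (window[1] - window[0]) / 4.0
    g = np.exp(-0.5 * ((times_ms - centre) / sigma) ** 2)
    return g / g[win_slice].mean()


# ---------------------------------------------------------------------------
# operations


def simulate_choices(design: pd.DataFrame, params: EffectParams,
                     seed: int) -> pd.DataFrame:
    """Bernoulli choices from a random-intercept logistic model.

    ``logit P(happy) = b0_subject + emotion term + fnmes term``; rows
    without a face (stimulation-only trials) are excluded.  Returns the
    face rows of the design with added ``choice`` ("happy"/"sad") and the
    true ``p_happy``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    face = design[design["emotion"] != "none"].copy()
    subjects = np.sort(design["subject"].unique())
    intercepts = dict(zip(
        subjects, params.subject_sd * rng.standard_normal(len(subjects))))
    eta = face["subject"].map(intercepts).to_numpy(dtype=float)
    eta += np.where(face["emotion"] == "happy", params.choice_b_happy, 0.0)
    eta += np.where(face["emotion"] == "sad", params.choice_b_sad, 0.0)
    eta += np.where(face["fnmes"] == "early", params.choice_b_early, 0.0)
    eta += np.where(face["fnmes"] == "late", params.choice_b_late, 0.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    face["p_happy"] = p
    face["choice"] = np.where(rng.random(len(face)) < p, "happy", "sad")
    return face.reset_index(drop=True)


def simulate_epochs(design: pd.DataFrame, params: EffectParams,
                    noise: NoiseSpec | None = None, seed: int = 0,
                    srate: float = SRATE_DEFAULT,
                    tmin_ms: float = TMIN_MS_DEFAULT,
                    tmax_ms: float = TMAX_MS_DEFAULT,
                    dtype=np.float32) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate epoched EEG for every row of ``design``.

    If ``design`` lacks a ``choice`` column, choices are first drawn with
    :func:`simulate_choices` (stimulation-only rows keep no choice) so the
    beta coupling can depend on the eventual categorisation.

    Returns the :class:`EpochSet` and a ground-truth table with the planted
    per-trial N170 amplitude and beta coupling strength.
    """
    params.validate()
    noise = noise if noise is not None else NoiseSpec()
    ss = np.random.SeedSequence(seed)
    s_choice, s_bg, s_white, s_beta = ss.spawn(4)

    if "choice" not in design.columns:
        choices = simulate_choices(design, params,
                                   seed=s_choice.generate_state(1)[0] % 2**31)
        design = design.merge(
            choices[["subject", "trial_index", "choice", "p_happy"]],
            on=["subject", "trial_index"], how="left")
    design = design.reset_index(drop=True)

    n_trials = len(design)
    n_samples = n_samples_for(tmin_ms, tmax_ms, srate)
    times = tmin_ms + np.arange(n_samples) * 1000.0 / srate
    n_ch = len(CHANNELS_64)

    data = np.zeros((n_trials, n_ch, n_samples), dtype=dtype)
    if noise.pink_rms_uv > 0:
        data += (noise.pink_rms_uv * _pink_noise(
            np.random.default_rng(s_bg), (n_trials, n_ch), n_samples,
            noise.alpha)).astype(dtype)
    if noise.white_sd_uv > 0:
        data += noise.white_sd_uv * np.random.default_rng(
            s_white).standard_normal((n_trials, n_ch, n_samples)).astype(dtype)

    # ---- N170 component ------------------------------------------------
    win = window_slice(params.n170_window, tmin_ms, srate, n_samples)
    profile = _n170_profile(times, params.n170_window, win)
    n170_idx = channel_index(CHANNELS_64, params.n170_channels)

    emotion = design["emotion"].to_numpy()
    fnmes = design["fnmes"].to_numpy()
    amp = np.zeros(n_trials)
    is_face = emotion != "none"
    amp[is_face] = params.n170_base_amp
    for emo, d in params.n170_emotion_delta.items():
        amp[emotion == emo] += d
    amp[is_face & (fnmes == "early")] += params.n170_early_fnmes_delta
    amp[(emotion == "happy") & (fnmes == "early")] += params.n170_happy_early_delta
    data[:, n170_idx, :] += (amp[:, None, None] * profile).astype(dtype)

    # ---- beta-band coupled oscillation ---------------------------------
    choice = design.get("choice")
    choice = (np.array([None] * n_trials) if choice is None
              else choice.to_numpy(dtype=object))
    coupling = np.array([
        params.beta_coupling.get((f, c), np.nan)
        for f, c in zip(fnmes, choice)])
    active = np.isfinite(coupling)
    if active.any() and params.beta_amp_uv > 0:
        rng_b = np.random.default_rng(s_beta)
        beta_ch = tuple(params.beta_channels_central) + tuple(
            params.beta_channels_occipital)
        beta_idx = channel_index(CHANNELS_64, beta_ch)
        n_act = int(active.sum())
        shared = _band_noise(rng_b, (n_act,), n_samples, srate,
                             params.beta_band)
        private = _band_noise(rng_b, (n_act, len(beta_idx)), n_samples,
                              srate, params.beta_band)
        env = np.zeros(n_samples)
        on = times >= params.beta_onset_ms
        env[on] = 1.0
        ramp = (times >= params.beta_onset_ms) & (times < params.beta_onset_ms + 20.0)
        env[ramp] = 0.5 * (1 - np.cos(
            np.pi * (times[ramp] - params.beta_onset_ms) / 20.0))
        c = coupling[active][:, None, None]
        comp = params.beta_amp_uv * env * (
            np.sqrt(c) * shared[:, None, :] + np.sqrt(1.0 - c) * private)
        data[np.ix_(np.flatnonzero(active), beta_idx)] += comp.astype(dtype)

    truth = design[["subject", "trial_index", "emotion", "fnmes"]].copy()
    if "choice" in design.columns:
        truth["choice"] = design["choice"]
    truth["n170_uv"] = amp
    truth["beta_coupling"] = coupling

    epochs = EpochSet(
        data=data, design=design, srate=srate, tmin_ms=tmin_ms,
        log=[{"op": "simulate_epochs", "seed": int(seed),
              "noise": vars(noise).copy()}])
    return epochs, truth


def artifact_waveform(spec: ArtifactSpec, tmin_ms: float, srate: float,
                      n_samples: int) -> np.ndarray:
    """Sampled biphasic pulse train (single channel, unit spatial gain)."""
    w = np.zeros(n_samples)
    w0 = spec.window_ms[0]
    for i in range(spec.n_pulses):
        t_ms = w0 + i * 1000.0 / spec.rate_hz
        idx = int(np.floor((t_ms - tmin_ms) / 1000.0 * srate))
        if idx < 0 or idx + 1 >= n_samples:
            raise ValueError("artifact window outside epoch bounds")
        w[idx] += spec.amplitude_uv
        w[idx + 1] -= spec.amplitude_uv
    return w


def inject_fnmes_artifact(epochs: EpochSet, spec: ArtifactSpec) -> EpochSet:
    """Add the stimulation artifact to every trial of the targeted
    condition.

    The waveform is identical across trials (and thus across emotions)
    within the condition, so any contrast that differences two emotions at
    the same condition cancels it to machine precision.
    """
    wave = artifact_waveform(spec, epochs.tmin_ms, epochs.srate,
                             epochs.n_samples)
    profile = (spec.spatial_profile if spec.spatial_profile is not None
               else posterior_gain_profile())
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(epochs.channels),):
        raise ValueError("spatial profile length must match channel count")
    target = epochs.design["fnmes"].to_numpy() == spec.target
    data = epochs.data.copy()
    data[target] += (profile[:, None] * wave).astype(data.dtype)
    entry = {"op": "inject_fnmes_artifact", "target": spec.target,
             "n_pulses": spec.n_pulses, "amplitude_uv": spec.amplitude_uv}
    return epochs.with_data(data, entry)


def simulate_au_timeseries(design: pd.DataFrame,
                           gain: dict[str, float] | None = None,
                           seed: int = 0, fps: float = 30.0,
                           baseline_s: float = 1.0, stim_s: float = 0.5,
                           au_base: float = 0.5,
                           noise_sd: float = 0.05) -> pd.DataFrame:
    """OpenFace-style AU intensity traces, one frame per row.

    Each trial spans 2 s before to 2 s after stimulation onset (time 0).
    AU12 is lifted multiplicatively by ``gain[fnmes]`` during the
    stimulation window [0, ``stim_s``); AU4/6/15 carry baseline + noise
    only.  The first ``baseline_s`` seconds serve as the per-trial
    baseline for percent-of-baseline statistics.
    """
    gain = gain if gain is not None else {"off": 0.0, "early": 0.137,
                                          "late": 0.156}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    face = design[design["emotion"] != "none"]
    t = np.arange(-2.0, 2.0, 1.0 / fps)
    stim = (t >= 0.0) & (t < stim_s)
    frames = []
    for row in face.itertuples(index=False):
        g = gain.get(row.fnmes, 0.0)
        tr = pd.DataFrame({
            "subject": row.subject, "trial_index": row.trial_index,
            "emotion": row.emotion, "fnmes": row.fnmes,
            "frame": np.arange(len(t)), "timestamp": t})
        for au in ("AU04_r", "AU06_r", "AU12_r", "AU15_r"):
            trace = np.full(len(t), au_base)
            if au == "AU12_r":
                trace = trace * (1.0 + g * stim)
            trace = trace + noise_sd * rng.standard_normal(len(t))
            tr[au] = trace
        frames.append(tr)
    return pd.concat(frames, ignore_index=True)
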