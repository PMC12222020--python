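"""Time–frequency cross-spectra and across-trial magnitude coherence.

The spectral estimator is a short-time Fourier coefficient on a grid of
5–40 Hz (0.5 Hz steps) × 0–1000 ms (10 ms steps): at each frequency *f*
the signal is windowed by a Hanning taper whose length spans 5 cycles
(5/f seconds) centred on the requested time point, drawing on samples
before 0 ms / after 1000 ms where the epoch provides them.  Grid cells
whose window would leave the epoch are marked missing (NaN), never
zero-filled, and missingness propagates through ROI averages.

Coherence is the *magnitude* coherence across trials,

    coh(f, t) = |Σ_k X_k conj(Y_k)| / sqrt(Σ_k |X_k|² · Σ_k |Y_k|²),

bounded in [0, 1] and invariant to per-channel rescaling.  For a
common-source pair x = s + n₁, y = s + n₂ it converges to the variance
ratio σ_s²/(σ_s² + σ_n²); for independent signals E[coh²] ≈ 1/n_trials.
A squared variant is available via ``squared=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EpochSet
from .montage import OCCIPITAL_ROIS, ROI_CENTRAL


@dataclass
class TFGrid:
    """Analysis grid: frequency × time resolution and taper length."""

    f_lo: float = 5.0
    f_hi: float = 40.0
    df: float = 0.5
    t_lo_ms: float = 0.0
    t_hi_ms: float = 1000.0
    dt_ms: float = 10.0
    cycles: float = 5.0

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.f_lo, self.f_hi + self.df / 2, self.df)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.t_lo_ms, self.t_hi_ms + self.dt_ms / 2,
                         self.dt_ms)

    def window_samples(self, freq: float, srate: float) -> int:
        return int(round(self.cycles / freq * srate))


@dataclass
class TFSpectra:
    """Complex STFT coefficients, trials × channels × freqs × times."""

    X: np.ndarray
    channels: list
    freqs: np.ndarray
    times_ms: np.ndarray


def stft_kernel(freq: float, n_win: int, srate: float) -> np.ndarray:
    """Hanning-tapered complex exponential; coefficients equal the DFT of
    the tapered segment at ``freq`` (segment-local phase origin)."""
    m = np.arange(n_win)
    return np.hanning(n_win) * np.exp(-2j * np.pi * freq * m / srate)


def tf_transform(epochs: EpochSet, grid: TFGrid | None = None,
                 channels=None) -> TFSpectra:
    """STFT coefficients on the analysis grid for the selected channels."""
    grid = grid or TFGrid()
    channels = list(channels) if channels is not None else list(epochs.channels)
    idx = epochs.channel_index(channels)
    x = epochs.data[:, idx, :].astype(np.float64)
    n_trials, n_ch, n_samp = x.shape
    flat = x.reshape(n_trials * n_ch, n_samp)

    freqs, times = grid.freqs, grid.times_ms
    # epoch sample index of each requested time point
    t_idx = np.floor((times - epochs.tmin_ms) / 1000.0 * epochs.srate
                     ).astype(int)
    out = np.full((n_trials, n_ch, len(freqs), len(times)), np.nan,
                  dtype=np.complex64)
    for fi, f in enumerate(freqs):
        L = grid.window_samples(f, epochs.srate)
        if L > n_samp:
            continue  # window longer than the epoch: whole row missing
        kern = stft_kernel(f, L, epochs.srate)
        # correlation with the kernel via FFT convolution; entry j of the
        # aligned result is the DFT of the segment starting at sample j
        full = sps.fftconvolve(flat, kern[::-1][None, :], mode="full",
                               axes=-1)
        start_aligned = full[:, L - 1:L - 1 + n_samp - L + 1]
        starts = t_idx - L // 2
        valid = (starts >= 0) & (starts + L <= n_samp)
        if valid.any():
            coefs = start_aligned[:, starts[valid]]
            out[:, :, fi, valid] = coefs.reshape(
                n_trials, n_ch, -1).astype(np.complex64)
    return TFSpectra(out, channels, freqs, times)


def pairwise_coherence(spectra: TFSpectra,
                       pairs: list[tuple[str, str]],
                       squared: bool = False) -> np.ndarray:
    """Across-trial magnitude coherence for each channel pair.

    Returns ``(n_pairs, n_freqs, n_times)`` in [0, 1]; cells with missing
    spectra or zero power are NaN.
    """
    if spectra.X.shape[0] < 2:
        raise ValueError("coherence needs >= 2 trials")
    lut = {c: i for i, c in enumerate(spectra.channels)}
    out = np.empty((len(pairs),) + spectra.X.shape[2:])
    for pi, (a, b) in enumerate(pairs):
        Xa = spectra.X[:, lut[a]]
        Xb = spectra.X[:, lut[b]]
        cross = np.abs((Xa * np.conj(Xb)).sum(axis=0))
        pa = (np.abs(Xa) ** 2).sum(axis=0).real
        pb = (np.abs(Xb) ** 2).sum(axis=0).real
        with np.errstate(divide="ignore", invalid="ignore"):
            c = cross / np.sqrt(pa * pb)
        out[pi] = c ** 2 if squared else c
    return out


def roi_pairs(central=ROI_CENTRAL, occipital=None) -> dict[str, list]:
    """Central × occipital electrode pairs per region (5×7, 5×3, 5×7)."""
    occipital = occipital or OCCIPITAL_ROIS
    return {name: [(c, o) for c in central for o in chans]
            for name, chans in occipital.items()}


def roi_average(pair_coh: np.ndarray, pairs: list,
                rois: dict[str, list]) -> dict[str, np.ndarray]:
    """Arithmetic mean of pair coherences within each central × region
    set; NaN cells propagate (missing support is not averaged away)."""
    lut = {tuple(p): i for i, p in enumerate(pairs)}
    out = {}
    for name, plist in rois.items():
        missing = [p for p in plist if tuple(p) not in lut]
        if missing:
            raise KeyError(f"pairs missing from coherence array: {missing}")
        out[name] = pair_coh[[lut[tuple(p)] for p in plist]].mean(axis=0)
    return out


@dataclass
class TFCoherenceMap:
    """ROI-pair coherence map for one subject × condition × choice cell."""

    subject: int
    fnmes: str
    choice: str
    roi: str
    coh: np.ndarray
    n_trials: int
    freqs: np.ndarray
    times_ms: np.ndarray


def subject_coherence_maps(epochs: EpochSet, grid: TFGrid | None = None,
                           emotion: str | None = "neutral",
                           min_trials: int = 10,
                           rois: dict[str, tuple] | None = None,
                           squared: bool = False) -> list[TFCoherenceMap]:
    """Central↔occipital ROI coherence per subject × fNMES × choice.

    Coherence is pooled across trials within each cell (it is not a
    single-trial quantity); cells with fewer than ``min_trials`` trials
    are skipped.  By default only neutral-face trials enter, grouped by
    the subject's eventual categorisation.
    """
    grid = grid or TFGrid()
    rois = {k: tuple(v) for k, v in (rois or OCCIPITAL_ROIS).items()}
    pairs_by_roi = roi_pairs(occipital=rois)
    all_pairs = [p for ps in pairs_by_roi.values() for p in ps]
    channels = sorted({c for p in all_pairs for c in p})

    design = epochs.design
    sel = design["emotion"].notna() & (design["emotion"] != "none")
    if emotion is not None:
        sel &= design["emotion"] == emotion
    sel &= design["choice"].notna() if "choice" in design else False

    maps: list[TFCoherenceMap] = []
    for subj in sorted(design.loc[sel, "subject"].unique()):
        s_mask = (sel & (design["subject"] == subj)).to_numpy()
        sub = EpochSet(epochs.data[s_mask], design[s_mask],
                       srate=epochs.srate, tmin_ms=epochs.tmin_ms,
                       channels=list(epochs.channels))
        spectra = tf_transform(sub, grid, channels)
        for (fn, ch), grp in sub.design.groupby(["fnmes", "choice"],
                                                sort=True):
            rows = sub.design.index.get_indexer(grp.index)
            if len(rows) < min_trials:
                continue
            cell = TFSpectra(spectra.X[rows], channels, spectra.freqs,
                             spectra.times_ms)
            pc = pairwise_coherence(cell, all_pairs, squared=squared)
            for roi, cohmap in roi_average(pc, all_pairs,
                                           pairs_by_roi).items():
                maps.append(TFCoherenceMap(
                    subject=int(subj), fnmes=str(fn), choice=str(ch),
                    roi=roi, coh=cohmap, n_trials=len(rows),
                    freqs=spectra.freqs, times_ms=spectra.times_ms))
    return maps
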