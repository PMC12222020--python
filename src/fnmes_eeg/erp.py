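"""Difference waves, mass-univariate channel × time statistics and N170
extraction.

The analysis contrast is a *double subtraction*: sad trials are subtracted
from happy trials within each stimulation condition, and those difference
waves are then compared between conditions.  Any signal that is additive
and identical across emotions within a condition — notably the
stimulation artifact — cancels in the first subtraction, so trials with
and without stimulation are never compared directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EpochSet
from .montage import N170_CHANNELS

N170_WINDOW_MS = (150.0, 200.0)


@dataclass
class SubjectMaps:
    """Per-subject channel × time maps sharing one axis set."""

    maps: np.ndarray  # (n_subjects, n_channels, n_samples)
    subjects: list
    channels: list
    times_ms: np.ndarray


@dataclass
class StatMap:
    """Mass-univariate t/p maps with a BH-FDR significance mask."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    df: int
    alpha: float = 0.05
    correction: str = "BH-FDR"
    channels: list | None = None
    times_ms: np.ndarray | None = None


def difference_waves(epochs: EpochSet, level1: str = "happy",
                     level2: str = "sad", by: str = "fnmes"
                     ) -> dict[str, SubjectMaps]:
    """Per-subject (mean ``level1``) − (mean ``level2``) maps, grouped by
    the levels of ``by`` (excluding stimulation-only rows)."""
    design = epochs.design
    face = design["emotion"] != "none"
    conds = [c for c in pd.unique(design.loc[face, by])]
    subjects = sorted(design.loc[face, "subject"].unique())
    out: dict[str, SubjectMaps] = {}
    for cond in conds:
        maps = np.empty((len(subjects), len(epochs.channels),
                         epochs.n_samples))
        for i, subj in enumerate(subjects):
            sel = (design["subject"] == subj) & (design[by] == cond)
            m1 = sel & (design["emotion"] == level1)
            m2 = sel & (design["emotion"] == level2)
            if not m1.any() or not m2.any():
                raise ValueError(
                    f"subject {subj}, {by}={cond}: empty {level1!r} or "
                    f"{level2!r} cell")
            maps[i] = (epochs.data[m1.to_numpy()].mean(axis=0, dtype=np.float64)
                       - epochs.data[m2.to_numpy()].mean(axis=0, dtype=np.float64))
        out[cond] = SubjectMaps(maps, subjects, list(epochs.channels),
                                epochs.times_ms)
    return out


def second_difference(diffs: dict[str, SubjectMaps], cond1: str,
                      cond2: str = "off") -> SubjectMaps:
    """Per-subject (happy−sad)@cond1 − (happy−sad)@cond2 maps."""
    for c in (cond1, cond2):
        if c not in diffs:
            raise KeyError(f"condition {c!r} missing from difference maps")
    a, b = diffs[cond1], diffs[cond2]
    if a.subjects != b.subjects:
        raise ValueError("subject sets differ between conditions")
    return SubjectMaps(a.maps - b.maps, a.subjects, a.channels, a.times_ms)


def mass_univariate(maps: SubjectMaps, alpha: float = 0.05) -> StatMap:
    """One-sample t-test against zero at every channel × time cell, with
    Benjamini–Hochberg correction applied jointly across all cells.

    With per-subject paired difference maps as input this is exactly the
    paired t-test between the two underlying conditions at each cell.
    """
    data = np.asarray(maps.maps, dtype=np.float64)
    n = data.shape[0]
    if n < 3:
        raise ValueError("mass-univariate testing needs >= 3 subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance cells set to p=1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 1.0
    reject, _, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return StatMap(t=t, p=p, mask=reject.reshape(p.shape), df=n - 1,
                   alpha=alpha, channels=maps.channels, times_ms=maps.times_ms)


def extract_n170(epochs: EpochSet,
                 window_ms: tuple[float, float] = N170_WINDOW_MS,
                 channels: tuple[str, ...] = N170_CHANNELS) -> pd.DataFrame:
    """Trial-level N170: mean voltage over the posterior electrode set and
    the 150–200 ms window (half-open), one record per face trial."""
    idx = epochs.channel_index(channels)  # raises on a missing channel
    sl = epochs.window_slice(window_ms)
    vals = epochs.data[:, idx, sl].mean(axis=(1, 2), dtype=np.float64)
    out = epochs.design.copy()
    out["n170_uv"] = vals
    out = out[out["emotion"] != "none"].reset_index(drop=True)
    keep = [c for c in ("subject", "trial_index", "identity", "emotion",
                        "fnmes", "choice", "n170_uv") if c in out.columns]
    return out[keep]


def choice_by_n170_model(records: pd.DataFrame,
                         fnmes_levels: tuple[str, str] = ("off", "early"),
                         emotions: tuple[str, ...] | None = ("neutral",)):
    """Logistic mixed model of choice on fNMES × N170 amplitude.

    Defaults to the planned contrast: neutral faces, off vs early
    stimulation.  Estimation is the random-intercept Laplace fit of
    :mod:`fnmes_eeg.behavior`.
    """
    from .behavior import fit_choice_model

    df = records[records["fnmes"].isin(fnmes_levels)]
    if emotions is not None:
        df = df[df["emotion"].isin(emotions)]
    return fit_choice_model(df, "choice ~ fnmes * n170_uv",
                            fnmes_levels=fnmes_levels)


def mask_to_runs(mask: np.ndarray, channels: list, times_ms: np.ndarray
                 ) -> list[dict]:
    """Compact (channel, t_start, t_end) run-length encoding of a mask."""
    runs = []
    for ci, ch in enumerate(channels):
        row = mask[ci]
        edges = np.flatnonzero(np.diff(np.r_[0, row.astype(int), 0]))
        for lo, hi in zip(edges[::2], edges[1::2]):
            runs.append({"channel": str(ch),
                         "t_start_ms": float(times_ms[lo]),
                         "t_end_ms": float(times_ms[hi - 1])})
    return runs
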