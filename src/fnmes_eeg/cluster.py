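"""Monte-Carlo cluster-based permutation testing on time–frequency maps.

The test follows the standard nonparametric recipe for dependent samples:
a paired t-statistic against zero at every frequency × time cell, a
two-tailed threshold at the cluster-forming alpha, 4-connected clustering
of suprathreshold cells (positive and negative separately), cluster mass
as the sum of member t-values, and a null distribution of the maximum
absolute mass over random whole-map sign flips of the per-subject
difference maps (exact under exchangeability of the paired conditions).
Positive and negative clusters are pooled into one max-|mass| null and
tested at the final alpha.  Monte-Carlo p-values use the plus-one rule,
so they are never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class PermParams:
    n_perm: int = 2000
    cluster_alpha: float = 0.01
    alpha: float = 0.05
    tails: int = 2
    seed: int = 0


@dataclass
class Cluster:
    cells: np.ndarray  # (k, 2) array of (freq_idx, time_idx)
    mass: float
    p_mc: float

    @property
    def significant(self) -> bool:
        return self.p_mc <= 0.05  # overridden by ClusterResult.alpha in use


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tmap: np.ndarray
    threshold: float
    params: PermParams
    null_max_mass: np.ndarray

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_mc <= self.params.alpha]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.tmap.shape, dtype=bool)
        for c in self.significant_clusters():
            m[c.cells[:, 0], c.cells[:, 1]] = True
        return m


@dataclass
class CoherenceMask:
    mask: np.ndarray
    provenance: list[str] = field(default_factory=list)


def paired_difference_maps(cell_maps: dict, condition: str,
                           reference: str = "off",
                           choices: tuple[str, str] = ("happy", "sad")
                           ) -> tuple[np.ndarray, list, list]:
    """Per-subject (happy−sad)@condition − (happy−sad)@reference maps.

    ``cell_maps`` maps ``(subject, fnmes, choice)`` to a 2-D array.
    Subjects missing any of the four cells (e.g. those who labelled every
    neutral face the same way) are excluded and reported, not imputed.
    """
    subjects = sorted({k[0] for k in cell_maps})
    hi, lo = choices
    maps, kept, excluded = [], [], []
    for s in subjects:
        need = [(s, condition, hi), (s, condition, lo),
                (s, reference, hi), (s, reference, lo)]
        if any(k not in cell_maps for k in need):
            excluded.append(s)
            continue
        maps.append((cell_maps[need[0]] - cell_maps[need[1]])
                    - (cell_maps[need[2]] - cell_maps[need[3]]))
        kept.append(s)
    if excluded:
        warnings.warn(f"excluded subjects missing a 2x2 cell: {excluded}")
    return np.asarray(maps), kept, excluded


def _t_from_mean(mean: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    var = (ssq - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _clusters_and_masses(t: np.ndarray, thresh: np.ndarray | float,
                         finite: np.ndarray) -> tuple[list, list]:
    comps, masses = [], []
    for sign in (1, -1):
        supra = finite & (sign * t > thresh)
        labels, n = ndimage.label(supra, structure=FOUR_CONN)
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            comps.append(cells)
            masses.append(float(t[labels == lab].sum()))
    return comps, masses


def cluster_test(subject_maps: np.ndarray,
                 params: PermParams | None = None) -> ClusterResult:
    """Sign-flip cluster permutation test of subject difference maps
    against zero.  Cells that are non-finite for any subject (missing
    window support) never enter a cluster."""
    params = params or PermParams()
    data = np.asarray(subject_maps, dtype=np.float64)
    n = data.shape[0]
    if n < 5:
        raise ValueError("cluster test needs >= 5 subjects")
    if params.n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    grid_shape = data.shape[1:]
    finite = np.isfinite(data).all(axis=0)
    flat = np.where(finite, data, 0.0).reshape(n, -1)

    tcrit = stats.t.ppf(1.0 - params.cluster_alpha / params.tails, df=n - 1)
    ssq = (flat ** 2).sum(axis=0)
    t_obs = _t_from_mean(flat.mean(axis=0), ssq, n).reshape(grid_shape)

    comps, masses = _clusters_and_masses(t_obs, tcrit, finite)

    rng = np.random.default_rng(params.seed)
    signs = rng.choice([-1.0, 1.0], size=(params.n_perm, n))
    null = np.zeros(params.n_perm)
    means = signs @ flat / n  # sum of squares is sign-invariant
    for i in range(params.n_perm):
        t_p = _t_from_mean(means[i], ssq, n).reshape(grid_shape)
        _, m = _clusters_and_masses(t_p, tcrit, finite)
        null[i] = max((abs(x) for x in m), default=0.0)

    clusters = []
    for cells, mass in zip(comps, masses):
        p = (1.0 + np.sum(null >= abs(mass))) / (params.n_perm + 1.0)
        clusters.append(Cluster(cells=cells, mass=mass, p_mc=float(p)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, tmap=t_obs, threshold=tcrit,
                         params=params, null_max_mass=null)


def integrate_masks(results: list[ClusterResult],
                    labels: list[str] | None = None) -> CoherenceMask:
    """Union of significant-cluster cells across contrasts (cell-wise OR)."""
    if not results:
        raise ValueError("no cluster results to integrate")
    shape = results[0].tmap.shape
    mask = np.zeros(shape, dtype=bool)
    for r in results:
        if r.tmap.shape != shape:
            raise ValueError("cluster results are on different grids")
        mask |= r.mask()
    return CoherenceMask(mask=mask,
                         provenance=list(labels or []))


def extract_masked_mean(tfmap: np.ndarray, mask: np.ndarray | CoherenceMask
                        ) -> float:
    """Mean of a map over the masked cells (insensitive to anything
    outside the mask)."""
    m = mask.mask if isinstance(mask, CoherenceMask) else mask
    if not m.any():
        raise ValueError("empty mask")
    return float(np.asarray(tfmap)[m].mean())


def masked_means(cell_maps: dict, mask) -> pd.DataFrame:
    """Masked mean per (subject, fnmes, choice) cell as a tidy table."""
    rows = [{"subject": s, "fnmes": f, "choice": c,
             "coherence": extract_masked_mean(v, mask)}
            for (s, f, c), v in cell_maps.items()]
    return pd.DataFrame(rows)


def masked_anova(means: pd.DataFrame, dv: str = "coherence",
                 subject: str = "subject",
                 within: tuple[str, str] = ("fnmes", "choice")
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-measures ANOVA (Greenhouse–Geisser corrected) on masked
    coherence means, plus Bonferroni-corrected paired t post-hocs of the
    choice effect within each stimulation condition.

    Returns ``(anova_table, posthoc_table)``; the ANOVA table carries
    GG-corrected degrees of freedom and p-values alongside partial eta
    squared.
    """
    import pingouin as pg

    wide_check = means.groupby([subject] + list(within)).size()
    if (wide_check != 1).any():
        raise ValueError("means table must hold exactly one value per cell")
    n_cells = means.groupby(list(within)).size()
    if n_cells.nunique() != 1:
        raise ValueError("unbalanced design: missing subject cells")

    aov = pg.rm_anova(data=means, dv=dv, within=list(within),
                      subject=subject, correction=True, detailed=True,
                      effsize="np2")

    conds = sorted(means[within[0]].unique())
    choices = sorted(means[within[1]].unique())
    if len(choices) != 2:
        raise ValueError("post-hocs expect exactly two choice levels")
    rows = []
    m_correct = len(conds)
    for cond in conds:
        cell = means[means[within[0]] == cond]
        piv = cell.pivot(index=subject, columns=within[1], values=dv)
        t, p = stats.ttest_rel(piv[choices[0]], piv[choices[1]])
        rows.append({within[0]: cond,
                     "contrast": f"{choices[0]} - {choices[1]}",
                     "mean_diff": float((piv[choices[0]]
                                         - piv[choices[1]]).mean()),
                     "t": float(t), "df": len(piv) - 1, "p_raw": float(p),
                     "p_bonf": float(min(1.0, m_correct * p))})
    return aov, pd.DataFrame(rows)
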