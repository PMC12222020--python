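"""Trial-design construction for the fNMES face-categorisation task.

Each subject sees 722 trials: 16 face identities × 3 emotions, with every
neutral expression repeated six times and every happy/sad expression four
times in each of the three stimulation conditions (off / early / late),
plus 50 stimulation-only trials without a face.  Presentation order is
pseudo-random under the constraint that no more than four consecutive
trials share a stimulation condition and no more than four share an
emotion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EMOTIONS = ("neutral", "happy", "sad")
FNMES_LEVELS = ("off", "early", "late")
N_IDENTITIES = 16
REPS_NEUTRAL = 6
REPS_EMOTIONAL = 4
N_STIM_ONLY = 50
MAX_RUN = 4  # longest permitted run of equal fnmes or emotion levels

N_TRIALS_PER_SUBJECT = (
    N_IDENTITIES * len(FNMES_LEVELS) * (REPS_NEUTRAL + 2 * REPS_EMOTIONAL)
    + N_STIM_ONLY
)  # 722

DESIGN_COLUMNS = ["subject", "trial_index", "identity", "emotion", "fnmes",
                  "repetition"]


class DesignConstraintError(RuntimeError):
    """Raised when the pseudo-random ordering constraints cannot be met
    within the allotted number of repair moves."""


def _subject_rows(subject: int) -> pd.DataFrame:
    rows = []
    for fnmes in FNMES_LEVELS:
        for identity in range(1, N_IDENTITIES + 1):
            for emotion in EMOTIONS:
                reps = REPS_NEUTRAL if emotion == "neutral" else REPS_EMOTIONAL
                for rep in range(1, reps + 1):
                    rows.append((subject, identity, emotion, fnmes, rep))
    for rep in range(1, N_STIM_ONLY + 1):
        rows.append((subject, 0, "none", "stim_only", rep))
    return pd.DataFrame(
        rows, columns=["subject", "identity", "emotion", "fnmes", "repetition"])


def _run_violations(values: np.ndarray) -> list[int]:
    """Start indices of length-(MAX_RUN+1) windows whose values are all equal."""
    w = MAX_RUN + 1
    return [i for i in range(len(values) - w + 1)
            if len(set(values[i:i + w])) == 1]


def check_design_constraints(design: pd.DataFrame) -> list[dict]:
    """Scan every length-5 window of each subject's sequence.

    Returns one violation record per offending window, empty if the design
    satisfies both run-length constraints.
    """
    violations = []
    for subject, grp in design.groupby("subject", sort=True):
        grp = grp.sort_values("trial_index") if "trial_index" in grp else grp
        for col in ("fnmes", "emotion"):
            vals = grp[col].to_numpy()
            for i in _run_violations(vals):
                violations.append(
                    {"subject": int(subject), "kind": col, "start": int(i),
                     "level": str(vals[i])})
    return violations


def _order_one_subject(frame: pd.DataFrame, rng: np.random.Generator,
                       max_moves: int = 50_000) -> pd.DataFrame:
    perm = rng.permutation(len(frame))
    fn = frame["fnmes"].to_numpy()[perm]
    em = frame["emotion"].to_numpy()[perm]
    for _ in range(max_moves):
        bad = _run_violations(fn) + _run_violations(em)
        if not bad:
            return frame.iloc[perm].reset_index(drop=True)
        # break the first offending window by swapping its last member with
        # a random position; accepted unconditionally, convergence is
        # stochastic but fast because violations are sparse
        i = bad[0] + MAX_RUN
        j = int(rng.integers(len(perm)))
        perm[i], perm[j] = perm[j], perm[i]
        fn[i], fn[j] = fn[j], fn[i]
        em[i], em[j] = em[j], em[i]
    raise DesignConstraintError(
        f"could not satisfy run-length constraints after {max_moves} moves")


def build_trial_design(n_subjects: int, seed: int) -> pd.DataFrame:
    """Pseudo-random 722-trial design for ``n_subjects`` subjects.

    Deterministic given ``seed``; raises :class:`DesignConstraintError`
    rather than silently relaxing the ordering constraints.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for s in range(1, n_subjects + 1):
        ordered = _order_one_subject(_subject_rows(s),
                                     np.random.default_rng(streams[s - 1]))
        ordered.insert(1, "trial_index", np.arange(len(ordered)))
        out.append(ordered)
    design = pd.concat(out, ignore_index=True)[DESIGN_COLUMNS]
    return design


def subsample_design(design: pd.DataFrame, n_per_cell: int,
                     seed: int = 0, face_only: bool = False) -> pd.DataFrame:
    """Reduced design keeping ``n_per_cell`` trials per subject ×
    emotion × fnmes cell — used to run the pipeline at small scale.

    Presentation order (and therefore run-length structure) is not
    preserved; the result is meant for effect-recovery simulations, not
    for order-constraint checks.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in design.groupby(["subject", "emotion", "fnmes"], sort=True):
        if face_only and grp["emotion"].iloc[0] == "none":
            continue
        take = min(n_per_cell, len(grp))
        idx = rng.choice(len(grp), size=take, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return (pd.concat(parts)
            .sort_values(["subject", "trial_index"])
            .reset_index(drop=True))
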