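"""Per-subject reduction of finger-level features, and a clustered rank-sum test.

Eight rewarming curves per subject yield eight feature sets; modelling uses
one row per subject. The reduction keeps the clinically conservative value of
each characteristic: mean baseline and post-cooling temperatures, the *lowest*
end temperature, and the *longest* time to end temperature. The derived
quantities ``t_50*`` and ``R%`` are recomputed from the selected values rather
than averaged, and a subject counts as S-shaped only if every finger is.

Whether hands may be pooled at all is checked with a rank-sum test that
respects the clustering of fingers within subjects: the test statistic sums
within-subject rank differences between left and right hands, and its null
distribution flips the left/right labels subject by subject (exactly for small
cohorts, by normal approximation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .features import HORIZONTAL, S_SHAPED, CurveFeatures


class ReductionError(ValueError):
    """Cannot reduce a subject's finger features."""


SUBJECT_COLUMNS = [
    "subject_id",
    "diagnosis",
    "age",
    "t_base",
    "t_0",
    "t_end",
    "time_to_t_end",
    "t_50_star",
    "R_pct",
    "curve_type",
    "n_fingers",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One-row-per-subject predictor set with the diagnosis label."""

    subject_id: str
    diagnosis: int
    age: float
    t_base: float
    t_0: float
    t_end: float
    time_to_t_end: float
    t_50_star: float
    R_pct: float
    curve_type: str
    n_fingers: int


def reduce_subject(
    features: Sequence[CurveFeatures],
    *,
    subject_id: str,
    diagnosis: int,
    age: float,
    expected_fingers: int = 8,
) -> SubjectRecord:
    """Collapse per-finger features into a single subject record.

    Selection rules: ``t_base`` and ``t_0`` by mean over fingers, ``t_end`` by
    minimum, ``time_to_t_end`` by maximum; ``t_50*`` and ``R%`` recomputed from
    the selected values; curve type S-shaped only when all fingers are
    S-shaped. Fewer than the expected number of fingers is tolerated with a
    warning; zero fingers is an error.
    """
    features = list(features)
    if not features:
        raise ReductionError(f"subject {subject_id}: no finger features to reduce")
    if len(features) != expected_fingers:
        warnings.warn(
            f"subject {subject_id}: reducing over {len(features)} fingers "
            f"(expected {expected_fingers})",
            stacklevel=2,
        )
    t_base = float(np.mean([f.t_base for f in features]))
    t_0 = float(np.mean([f.t_0 for f in features]))
    t_end = float(np.min([f.t_end for f in features]))
    time_to_t_end = float(np.max([f.time_to_t_end for f in features]))
    t_50_star = (t_end - t_0) / 2.0 + t_0
    if t_base <= t_0:
        raise ReductionError(f"subject {subject_id}: reduced t_base <= t_0")
    r_pct = 100.0 * (t_end - t_0) / (t_base - t_0)
    curve_type = (
        S_SHAPED if all(f.curve_type == S_SHAPED for f in features) else HORIZONTAL
    )
    return SubjectRecord(
        subject_id=subject_id,
        diagnosis=int(diagnosis),
        age=float(age),
        t_base=t_base,
        t_0=t_0,
        t_end=t_end,
        time_to_t_end=time_to_t_end,
        t_50_star=t_50_star,
        R_pct=r_pct,
        curve_type=curve_type,
        n_fingers=len(features),
    )


def reduce_cohort(
    features: pd.DataFrame, metadata: pd.DataFrame, expected_fingers: int = 8
) -> pd.DataFrame:
    """Reduce a per-finger features table to a one-row-per-subject table.

    ``features`` follows the per-finger CSV layout; ``metadata`` has columns
    subject_id, diagnosis, age.
    """
    meta = metadata.set_index("subject_id")
    rows = []
    for sid, grp in features.groupby("subject_id", sort=False):
        feats = [
            CurveFeatures(
                t_base=r.t_base,
                t_0=r.t_0,
                t_end=r.t_end,
                time_to_t_end=r.time_to_t_end,
                duration=r.duration,
                R_pct=r.R_pct,
                t_50_star=r.t_50_star,
                curve_type=r.curve_type,
            )
            for r in grp.itertuples()
        ]
        rec = reduce_subject(
            feats,
            subject_id=str(sid),
            diagnosis=int(meta.loc[sid, "diagnosis"]),
            age=float(meta.loc[sid, "age"]),
            expected_fingers=expected_fingers,
        )
        rows.append({c: getattr(rec, c) for c in SUBJECT_COLUMNS})
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


# ---------------------------------------------------------------------------
# Clustered rank-sum test (left vs right hand)
# ---------------------------------------------------------------------------


def clustered_rank_sum(
    left: Sequence[np.ndarray],
    right: Sequence[np.ndarray],
    *,
    exact_limit: int = 12,
) -> tuple[float, float]:
    """Rank-sum test for a left/right difference with subject clustering.

    ``left[i]`` and ``right[i]`` hold subject *i*'s per-finger values for each
    hand (equal counts within a subject). Within each subject the combined
    values are ranked (average ranks for ties) and the statistic is the sum
    over subjects of the centered left-hand rank sum; exchanging a subject's
    hands flips the sign of their contribution. The two-sided p-value comes
    from exhaustive enumeration of all sign assignments when there are at most
    ``exact_limit`` subjects, and from a normal approximation otherwise.

    Returns ``(statistic, p_value)``.
    """
    if len(left) != len(right):
        raise ReductionError("left and right must list the same subjects")
    n = len(left)
    if n < 2:
        raise ReductionError("need at least 2 subjects")
    w = np.empty(n)
    for i, (l, r) in enumerate(zip(left, right)):
        l = np.asarray(l, dtype=float)
        r = np.asarray(r, dtype=float)
        if l.size != r.size or l.size == 0:
            raise ReductionError(
                f"subject {i}: fingers must be paired across hands (got {l.size} vs {r.size})"
            )
        m = l.size
        ranks = rankdata(np.concatenate([l, r]))
        w[i] = ranks[:m].sum() - m * (2 * m + 1) / 2.0
    t = float(w.sum())

    if n <= exact_limit:
        signs = np.array([1.0, -1.0])
        # all 2^n sign assignments, vectorized over subjects
        grid = np.stack(
            np.meshgrid(*([signs] * n), indexing="ij"), axis=-1
        ).reshape(-1, n)
        null = grid @ w
        p = float(np.mean(np.abs(null) >= abs(t) - 1e-12))
        return t, p

    var = float((w**2).sum())
    if var == 0.0:
        return t, 1.0
    z = t / np.sqrt(var)
    return t, float(2.0 * norm.sf(abs(z)))


def hands_frame(features: pd.DataFrame, column: str) -> tuple[list, list]:
    """Split a per-finger features table into per-subject left/right arrays."""
    left, right = [], []
    for _, grp in features.groupby("subject_id", sort=False):
        l = grp.loc[grp["hand"] == "L", column].to_numpy(dtype=float)
        r = grp.loc[grp["hand"] == "R", column].to_numpy(dtype=float)
        left.append(l)
        right.append(r)
    return left, right
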