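"""Threshold-indicator change points and group-level environmental breadth.

For one taxon and one environmental gradient, the change point is the
split of the gradient that maximises the one-sided indicator value
IndVal = (side mean relative abundance / sum of the two side means) x
(side occurrence frequency): a taxon concentrated above the split scores
high on the right side (direction "z+"), below it on the left ("z-").
Candidate splits are midpoints between consecutive sorted unique gradient
values, keeping at least ``min_side`` samples on each side.  A bootstrap
over samples gives a 5th-95th percentile interval for the change point.

This is the core indicator-threshold computation only; the full TITAN
machinery (permutation-standardised z-scores, purity and reliability
filters, community-level sum(z) curves) is deliberately not reproduced.

Group-level environmental breadth summarises the dispersion of a taxon
group's change points along a variable: the interquartile range of the
change points divided by the variable's observed range, in [0, 1].  A
narrower value means the group's thresholds are concentrated - a narrow
environmental breadth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChangePoint", "indval_changepoint", "environmental_breadth"]


@dataclass
class ChangePoint:
    taxon_id: str
    variable: str
    change_point: float
    direction: str  # "z+" or "z-"
    score: float
    interval: tuple[float, float]
    n_boot: int
    seed: int
    uninformative: bool


def _candidate_points(env: np.ndarray, min_side: int) -> np.ndarray:
    order = np.sort(np.unique(env))
    if len(order) < 2:
        raise ValueError("constant environmental variable")
    mids = (order[:-1] + order[1:]) / 2.0
    keep = []
    for c in mids:
        left = np.count_nonzero(env < c)
        if left >= min_side and len(env) - left >= min_side:
            keep.append(c)
    return np.asarray(keep)


def _best_split(abund: np.ndarray, env: np.ndarray, candidates: np.ndarray):
    """(change point, direction, score, all-tied flag) by exhaustive scan."""
    best_score = -np.inf
    best_c = None
    best_dir = None
    scores = []
    for c in candidates:
        left = env < c
        right = ~left
        mean_l = abund[left].mean()
        mean_r = abund[right].mean()
        denom = mean_l + mean_r
        if denom == 0:
            scores.append(0.0)
            continue
        occ_l = np.count_nonzero(abund[left] > 0) / left.sum()
        occ_r = np.count_nonzero(abund[right] > 0) / right.sum()
        iv_l = (mean_l / denom) * occ_l
        iv_r = (mean_r / denom) * occ_r
        score = max(iv_l, iv_r)
        scores.append(score)
        # strict > keeps the lowest candidate on ties
        if score > best_score + 1e-12:
            best_score = score
            best_c = c
            best_dir = "z+" if iv_r > iv_l else "z-"
    if best_c is None:
        return None
    all_tied = bool(np.ptp(np.asarray(scores)) <= 1e-12)
    return float(best_c), best_dir, float(best_score), all_tied


def indval_changepoint(
    abund,
    env,
    n_boot: int = 500,
    seed: int = 0,
    min_side: int = 3,
    taxon_id: str = "",
    variable: str = "",
) -> ChangePoint:
    """Indicator-value change point of one taxon along one gradient."""
    abund = np.asarray(abund, dtype=float)
    env = np.asarray(env, dtype=float)
    if len(abund) != len(env):
        raise ValueError("abundance and env must be the same length")
    if np.count_nonzero(abund > 0) < 3:
        raise ValueError("taxon present in fewer than 3 samples")
    candidates = _candidate_points(env, min_side)
    if len(candidates) == 0:
        raise ValueError("no valid split with the requested minimum side size")
    best = _best_split(abund, env, candidates)
    if best is None:
        raise ValueError("degenerate abundance vector")
    cp, direction, score, all_tied = best

    rng = np.random.default_rng(seed)
    boot_points = []
    n = len(env)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a, e = abund[idx], env[idx]
        if np.count_nonzero(a > 0) < 3 or np.ptp(e) == 0:
            continue
        cand = _candidate_points(e, min_side)
        if len(cand) == 0:
            continue
        res = _best_split(a, e, cand)
        if res is not None:
            boot_points.append(res[0])
    if boot_points:
        lo, hi = np.percentile(boot_points, [5, 95])
        lo, hi = min(lo, cp), max(hi, cp)
    else:
        lo = hi = cp
    return ChangePoint(
        taxon_id=taxon_id,
        variable=variable,
        change_point=cp,
        direction=direction,
        score=score,
        interval=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        uninformative=all_tied,
    )


def environmental_breadth(points, env_range) -> float:
    """Normalised IQR of a taxon group's change points along one variable.

    ``points`` are the (informative) change points of the group's taxa;
    ``env_range`` is (min, max) of the observed variable.  Returns a value
    in [0, 1]; 0 means every taxon switches at the same threshold.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 informative taxa in the group")
    lo, hi = float(env_range[0]), float(env_range[1])
    if hi <= lo:
        raise ValueError("invalid environmental range")
    q1, q3 = np.percentile(pts, [25, 75])
    return float((q3 - q1) / (hi - lo))
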