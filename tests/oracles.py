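"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from its definition by direct
enumeration, independently of the library's implementation path.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_score_panel(row: dict) -> dict[str, int]:
    """Point-sum oracle for all five scores from a flat feature dict.

    Walks the published component lists literally, one condition at a
    time, without any of the library's grading helpers.
    """
    bend = row["max_bend_deg"] > 45.0
    severe = bool(row["calc_area_frac_ge_50"])
    central = bool(row["calc_area_frac_100"]) and row["calc_arc_max_deg"] == "360"
    severe_peripheral = (
        not central
        and severe
        and row["calc_arc_max_deg"] in (">=180", "360")
    )
    ct_rector = (
        int(row["multiple_occlusions"])
        + int(row["blunt_cap_entry_or_exit"])
        + int(severe)
        + int(bend)
        + int(row["duration_gt_12mo_or_unknown"])
        + int(row["reattempt"])
    )
    kcct = (
        int(row["blunt_cap_proximal"])
        + int(row["proximal_side_branch"])
        + int(row["occlusion_length_mm"] >= 15.0)
        + int(bend)
        + int(row["duration_gt_12mo_or_unknown"])
        + int(row["reattempt"])
        + (2 if central else (1 if severe_peripheral else 0))
    )
    jcto_ccta = (
        int(row["blunt_cap_proximal"])
        + int(row["occlusion_length_mm"] >= 20.0)
        + int(severe)
        + int(bend)
        + int(row["reattempt"])
    )
    recharge = (
        int(row["blunt_cap_proximal"])
        + int(row["occlusion_length_mm"] >= 20.0)
        + int(severe)
        + int(bend)
        + int(row["diseased_distal_landing_zone"])
        + int(row["prior_cabg_to_cto_vessel"])
    )
    jcto_ca = (
        int(row["angio_blunt_stump"])
        + int(row["angio_any_calcification"])
        + int(row["angio_max_bend_deg"] > 45.0)
        + int(row["angio_occlusion_length_mm"] >= 20.0)
        + int(row["reattempt"])
    )
    return {
        "ct_rector": ct_rector,
        "kcct": kcct,
        "jcto_ccta": jcto_ccta,
        "recharge_ccta": recharge,
        "jcto_ca": jcto_ca,
    }


def oracle_auc_pairs(values, labels, direction) -> float:
    """AUC by enumerating all positive-negative pairs (ties half)."""
    x = np.asarray(values, float)
    y = np.asarray(labels, bool)
    pos, neg = x[y], x[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                total += 0.5
            elif (p < q) == (direction == "low"):
                total += 1.0
    return total / (len(pos) * len(neg))


def oracle_fisher_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by exhausting tables with the same margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[k] = math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)), 1.0)


def oracle_youden_sweep(values, labels, direction):
    """Best (J, sens, spec) by brute-force over every candidate rule."""
    x = np.asarray(values, float)
    y = np.asarray(labels, bool)
    pos, neg = x[y], x[~y]
    candidates = np.concatenate([[-np.inf], np.unique(x)])
    best = (-np.inf, -np.inf)
    for t in candidates:
        if direction == "low":
            sens = np.mean(pos <= t)
            spec = np.mean(neg > t)
        else:
            sens = np.mean(pos > t)
            spec = np.mean(neg <= t)
        best = max(best, (sens + spec - 1.0, sens))
    return best


def oracle_jackknife_auc_variance(values, labels, direction, auc_fn) -> float:
    """Leave-one-subject-out jackknife variance of the AUC."""
    x = np.asarray(values, float)
    y = np.asarray(labels, bool)
    n = len(x)
    thetas = np.array(
        [auc_fn(np.delete(x, i), np.delete(y, i), direction) for i in range(n)]
    )
    return (n - 1) / n * float(np.sum((thetas - thetas.mean()) ** 2))


def oracle_jackknife_auc_diff_variance(xa, xb, labels, direction, auc_fn) -> float:
    """Jackknife variance of an AUC difference on paired predictors."""
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    y = np.asarray(labels, bool)
    n = len(y)
    thetas = np.array(
        [
            auc_fn(np.delete(xa, i), np.delete(y, i), direction)
            - auc_fn(np.delete(xb, i), np.delete(y, i), direction)
            for i in range(n)
        ]
    )
    return (n - 1) / n * float(np.sum((thetas - thetas.mean()) ** 2))
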