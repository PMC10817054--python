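"""Synthetic CTO cohort generation.

Generates lesion-feature and procedure tables with the statistical
structure of a hybrid CTO-PCI cohort: realistic marginal prevalences
of the CCTA/angiographic risk factors, a single latent per-lesion
*difficulty* factor inducing all feature-outcome correlation, and an
escalation process in which antegrade wiring is attempted first and a
non-AW strategy is deployed once a drawn switch time is exceeded.

Generative model
----------------
* ``d ~ N(0, 1)`` is the latent difficulty of each lesion.
* Each binary feature ``f`` is Bernoulli with
  ``P(f | d) = logistic(alpha_f + beta_f * d)``; the intercept
  ``alpha_f`` is solved numerically so the *marginal* prevalence hits
  its configured target regardless of the loading ``beta_f``.
* Calcification is an ordinal ladder (none < non-severe < severe
  peripheral < central) cut from a latent normal ``c = kappa*d + eps``
  at thresholds matched to the configured nested prevalences, so
  "area >= 50% CSA" always contains "area = 100% CSA".
* Occlusion length and maximal bend are lognormal with the configured
  median and a difficulty loading added on the log scale (the median
  is invariant to the loading).
* Angiographic features are the CCTA features seen through reader
  noise: symmetric misclassification for the blunt stump, a noisier
  threshold on the same calcium latent, and multiplicative lognormal
  noise (with a calibrated median ratio) for length and bend.
* Crossing time is lognormal, ``log T = mu + gamma*d + sigma*eps``;
  a never-cross event has probability ``logistic(nu0 + nu1*d)``.
  Escalation to a non-AW strategy occurs when the lesion never
  crosses, when ``T`` exceeds an independently drawn switch time, or
  (rarely) when the operator goes retrograde primarily; the escalated
  strategy set is sampled from a configured mix of ADR/RW/RDR
  combinations.

All randomness comes from one ``numpy`` generator seeded with
``config.seed``; every base draw is made up front in a fixed,
documented order, and parameters are applied analytically afterwards.
Two consequences: regeneration is bit-identical for a given config and
seed, and changing only the strength parameters (loadings, ``gamma``)
reuses the same underlying random numbers — the common-random-numbers
property that :func:`calibrate_discrimination` and the monotonicity
properties rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .endpoints import endpoint_table
from .scores import SCORE_COLUMNS, score_table
from .diagnostics import auc_value

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "calibrate_discrimination",
    "fixture_table2_cohort",
    "ENDPOINT_DIRECTIONS",
]

#: direction convention per endpoint: 'low' = low scores predict the
#: positive class (success endpoints), 'high' = high scores predict it
#: (needing a non-AW strategy).
ENDPOINT_DIRECTIONS = {
    "time_efficient_crossing": "low",
    "final_procedural_success": "low",
    "any_non_aw": "high",
}


def _default_feature_prevalences():
    # marginal prevalences of the CCTA lesion features
    return {
        "blunt_cap_proximal": 0.364,
        "proximal_side_branch": 0.518,
        "multiple_occlusions": 0.145,
        "diseased_distal_landing_zone": 0.50,
    }


def _default_feature_loadings():
    # effect of latent difficulty on each feature's log-odds
    return {
        "blunt_cap_proximal": 0.9,
        "proximal_side_branch": 0.4,
        "multiple_occlusions": 0.8,
        "diseased_distal_landing_zone": 0.2,
    }


def _default_clinical_prevalences():
    return {
        "duration_gt_12mo_or_unknown": 0.891,
        "reattempt": 0.218,
        "prior_cabg_to_cto_vessel": 0.173,
    }


def _default_clinical_loadings():
    # clinical context barely separates the outcome groups
    return {
        "duration_gt_12mo_or_unknown": 0.3,
        "reattempt": 0.2,
        "prior_cabg_to_cto_vessel": 0.2,
    }


def _default_calc_prevalences():
    # nested: any calcium > area >= 50% CSA > area = 100% CSA
    return {"any": 0.809, "ge50": 0.409, "full": 0.164}


def _default_strategy_mix():
    # conditional distribution of the non-AW strategy set once escalated
    return {
        ("ADR",): 0.15,
        ("RW",): 0.275,
        ("ADR", "RW"): 0.35,
        ("ADR", "RDR"): 0.05,
        ("RW", "RDR"): 0.075,
        ("ADR", "RW", "RDR"): 0.10,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the synthetic population.

    Defaults target the marginal summaries of a hybrid CTO-PCI cohort
    (occlusion length median 15.6 mm, bend median 27 degrees, blunt cap
    36.4%, time-to-switch median 27 min, never-cross rate 9.1%, ...).
    Spreads are log-scale standard deviations; loadings act on the
    latent-difficulty scale and can be rescaled jointly without moving
    any marginal (see :func:`calibrate_discrimination`).
    """

    n_lesions: int = 110
    seed: int = 0
    feature_prevalences: dict = field(default_factory=_default_feature_prevalences)
    feature_loadings: dict = field(default_factory=_default_feature_loadings)
    clinical_prevalences: dict = field(default_factory=_default_clinical_prevalences)
    clinical_loadings: dict = field(default_factory=_default_clinical_loadings)
    calc_prevalences: dict = field(default_factory=_default_calc_prevalences)
    calc_loading: float = 0.8
    length_median_mm: float = 15.6
    length_log_sd: float = 0.536  # residual, on top of the loading
    length_loading: float = 0.45
    bend_median_deg: float = 27.0
    bend_log_sd: float = 0.50
    bend_loading: float = 0.35
    blunt_exit_extra_prob: float = 0.10
    angio_flip_prob: float = 0.10
    angio_calc_prevalence: float = 0.155
    angio_calc_noise_sd: float = 0.5
    angio_length_median_ratio: float = 11.3 / 15.6
    angio_length_log_sd: float = 0.25
    angio_bend_median_ratio: float = 25.0 / 27.0
    angio_bend_log_sd: float = 0.25
    crossing_median_min: float = 20.0
    crossing_log_sd: float = 1.0
    gamma: float = 1.2  # difficulty effect on log crossing time
    never_cross_prob: float = 0.091
    never_cross_loading: float = 1.0
    #: marginal median of the switch-time draw; escalation selects small
    #: draws, so the *recorded* switch times have median near 27 min
    switch_median_min: float = 36.0
    switch_log_sd: float = 0.75
    primary_retro_prob: float = 0.036
    timi3_prob: float = 0.98
    strategy_mix: dict = field(default_factory=_default_strategy_mix)
    escalated_final_aw_prob: float = 0.03

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        probs = {
            **self.feature_prevalences,
            **self.clinical_prevalences,
            **self.calc_prevalences,
            "angio_calc": self.angio_calc_prevalence,
            "never_cross": self.never_cross_prob,
            "primary_retro": self.primary_retro_prob,
            "timi3": self.timi3_prob,
            "blunt_exit_extra": self.blunt_exit_extra_prob,
            "angio_flip": self.angio_flip_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        c = self.calc_prevalences
        if not c["any"] >= c["ge50"] >= c["full"]:
            raise ValueError("calc prevalences must be nested: any >= ge50 >= full")
        for name in ("length_log_sd", "bend_log_sd", "crossing_log_sd", "switch_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        total = sum(self.strategy_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"strategy_mix must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: feature table, procedure table, and truth."""

    lesions: pd.DataFrame
    procedures: pd.DataFrame
    difficulty: np.ndarray
    config: CohortConfig | None = None
    seed: int | None = None


# Gauss-Hermite nodes for E over d ~ N(0,1)
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(64)
_GH_D = _GH_X * np.sqrt(2.0)
_GH_W = _GH_W / np.sqrt(np.pi)


def _solve_intercept(target: float, loading: float, feature: str) -> float:
    """Intercept alpha with E_d[logistic(alpha + loading*d)] = target."""
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"marginal prevalence for {feature} must be in (0, 1), got {target}"
        )

    def marginal(alpha):
        return float(np.sum(_GH_W * expit(alpha + loading * _GH_D))) - target

    lo, hi = -40.0, 40.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError(
            f"marginal prevalence {target} unreachable for feature {feature} "
            f"under loading {loading}"
        )
    return float(brentq(marginal, lo, hi, xtol=1e-12))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config``.

    Deterministic given ``config`` (including ``config.seed``).
    """
    n = config.n_lesions
    rng = np.random.default_rng(config.seed)

    # --- base draws, fixed order (do not reorder) ----------------------
    d = rng.standard_normal(n)
    u_feat = {k: rng.random(n) for k in sorted(config.feature_prevalences)}
    eps_calc = rng.standard_normal(n)
    eps_len = rng.standard_normal(n)
    eps_bend = rng.standard_normal(n)
    u_blunt_exit = rng.random(n)
    u_clin = {k: rng.random(n) for k in sorted(config.clinical_prevalences)}
    u_flip_blunt = rng.random(n)
    eps_angio_calc = rng.standard_normal(n)
    eps_angio_len = rng.standard_normal(n)
    eps_angio_bend = rng.standard_normal(n)
    eps_t = rng.standard_normal(n)
    u_never = rng.random(n)
    eps_switch = rng.standard_normal(n)
    u_retro = rng.random(n)
    u_combo = rng.random(n)
    u_final_aw = rng.random(n)
    u_final_pick = rng.random(n)
    u_timi = rng.random(n)

    # --- lesion features -----------------------------------------------
    features = {}
    for name in config.feature_prevalences:
        beta = config.feature_loadings.get(name, 0.0)
        alpha = _solve_intercept(config.feature_prevalences[name], beta, name)
        features[name] = u_feat[name] < expit(alpha + beta * d)
    clinical = {}
    for name in config.clinical_prevalences:
        beta = config.clinical_loadings.get(name, 0.0)
        alpha = _solve_intercept(config.clinical_prevalences[name], beta, name)
        clinical[name] = u_clin[name] < expit(alpha + beta * d)

    kappa = config.calc_loading
    c = kappa * d + eps_calc
    sd_c = np.sqrt(1.0 + kappa**2)
    thr = {k: sd_c * ndtri(1.0 - p) for k, p in config.calc_prevalences.items()}
    calc_full = c > thr["full"]
    calc_ge50 = c > thr["ge50"]
    calc_any = c > thr["any"]
    arc = np.where(calc_full, "360", np.where(calc_ge50, ">=180", "<180"))

    length = config.length_median_mm * np.exp(
        config.length_loading * d + config.length_log_sd * eps_len
    )
    bend = np.minimum(
        config.bend_median_deg
        * np.exp(config.bend_loading * d + config.bend_log_sd * eps_bend),
        180.0,
    )
    blunt_entry_exit = features["blunt_cap_proximal"] | (
        u_blunt_exit < config.blunt_exit_extra_prob
    )

    # --- angiographic view (reader noise on the CCTA truth) ------------
    angio_blunt = features["blunt_cap_proximal"] ^ (
        u_flip_blunt < config.angio_flip_prob
    )
    c_angio = c + config.angio_calc_noise_sd * eps_angio_calc
    sd_ca = np.sqrt(1.0 + kappa**2 + config.angio_calc_noise_sd**2)
    angio_calc = c_angio > sd_ca * ndtri(1.0 - config.angio_calc_prevalence)
    angio_length = length * config.angio_length_median_ratio * np.exp(
        config.angio_length_log_sd * eps_angio_len
    )
    angio_bend = np.minimum(
        bend
        * config.angio_bend_median_ratio
        * np.exp(config.angio_bend_log_sd * eps_angio_bend),
        180.0,
    )

    # --- procedure ------------------------------------------------------
    nu1 = config.never_cross_loading
    nu0 = _solve_intercept(config.never_cross_prob, nu1, "never_cross")
    never_cross = u_never < expit(nu0 + nu1 * d)
    crossed = ~never_cross
    t_cross = config.crossing_median_min * np.exp(
        config.gamma * d + config.crossing_log_sd * eps_t
    )
    switch = config.switch_median_min * np.exp(config.switch_log_sd * eps_switch)
    primary_retro = u_retro < config.primary_retro_prob
    escalated = primary_retro | never_cross | (t_cross > switch)
    used_aw = ~primary_retro

    combos = list(config.strategy_mix)
    cum = np.cumsum([config.strategy_mix[k] for k in combos])
    combo_idx = np.searchsorted(cum, u_combo, side="right").clip(0, len(combos) - 1)
    used = {s: np.zeros(n, dtype=bool) for s in ("ADR", "RW", "RDR")}
    for i, combo in enumerate(combos):
        mask = escalated & (combo_idx == i)
        for s in combo:
            used[s][mask] = True

    final = np.full(n, "none", dtype=object)
    final[crossed & ~escalated] = "AW"
    esc_crossed = crossed & escalated
    final_aw = esc_crossed & used_aw & (u_final_aw < config.escalated_final_aw_prob)
    final[final_aw] = "AW"
    for i in np.flatnonzero(esc_crossed & ~final_aw):
        opts = combos[combo_idx[i]]
        final[i] = opts[int(u_final_pick[i] * len(opts))]

    timi = np.where(crossed, np.where(u_timi < config.timi3_prob, 3, 2), 0)
    resid = np.where(crossed, np.where(timi == 3, 10.0, 60.0), np.nan)
    switch_rec = np.where(escalated & used_aw, switch, np.nan)

    ids = [f"L{i + 1:04d}" for i in range(n)]
    lesions = pd.DataFrame(
        {
            "lesion_id": ids,
            "blunt_cap_proximal": features["blunt_cap_proximal"].astype(int),
            "blunt_cap_entry_or_exit": blunt_entry_exit.astype(int),
            "proximal_side_branch": features["proximal_side_branch"].astype(int),
            "occlusion_length_mm": length,
            "max_bend_deg": bend,
            "any_calcification": calc_any.astype(int),
            "calc_arc_max_deg": arc,
            "calc_area_frac_ge_50": calc_ge50.astype(int),
            "calc_area_frac_100": calc_full.astype(int),
            "multiple_occlusions": features["multiple_occlusions"].astype(int),
            "diseased_distal_landing_zone": features[
                "diseased_distal_landing_zone"
            ].astype(int),
            "angio_blunt_stump": angio_blunt.astype(int),
            "angio_any_calcification": angio_calc.astype(int),
            "angio_max_bend_deg": angio_bend,
            "angio_occlusion_length_mm": angio_length,
            "duration_gt_12mo_or_unknown": clinical[
                "duration_gt_12mo_or_unknown"
            ].astype(int),
            "reattempt": clinical["reattempt"].astype(int),
            "prior_cabg_to_cto_vessel": clinical["prior_cabg_to_cto_vessel"].astype(
                int
            ),
        }
    )
    procedures = pd.DataFrame(
        {
            "lesion_id": ids,
            "gw_crossing_time_min": np.where(crossed, t_cross, np.nan),
            "used_aw": used_aw.astype(int),
            "used_adr": used["ADR"].astype(int),
            "used_rw": used["RW"].astype(int),
            "used_rdr": used["RDR"].astype(int),
            "final_strategy": final,
            "residual_stenosis_pct": resid,
            "timi_flow": timi,
            "switch_time_min": switch_rec,
        }
    )
    return SyntheticCohort(lesions, procedures, d, config, config.seed)


_SCALED_FIELDS = (
    "calc_loading",
    "length_loading",
    "bend_loading",
    "gamma",
    "never_cross_loading",
)


def scaled_config(config: CohortConfig, scale: float) -> CohortConfig:
    """Config with every difficulty loading multiplied by ``scale``.

    Marginal prevalences and medians are untouched (intercepts are
    re-solved at generation time), so only the feature-outcome
    association strength changes.
    """
    changes = {f: getattr(config, f) * scale for f in _SCALED_FIELDS}
    changes["feature_loadings"] = {
        k: v * scale for k, v in config.feature_loadings.items()
    }
    changes["clinical_loadings"] = {
        k: v * scale for k, v in config.clinical_loadings.items()
    }
    return dataclasses.replace(config, **changes)


def _population_auc(
    config: CohortConfig, score_system: str, endpoint: str, n_sim: int, inner_seed: int
) -> float:
    cfg = dataclasses.replace(config, n_lesions=n_sim, seed=inner_seed)
    cohort = generate_cohort(cfg)
    scores = score_table(cohort.lesions)
    eps = endpoint_table(cohort.procedures)
    col = SCORE_COLUMNS[score_system]
    direction = ENDPOINT_DIRECTIONS[endpoint]
    return auc_value(scores[col].to_numpy(float), eps[endpoint].to_numpy(), direction)


def calibrate_discrimination(
    config: CohortConfig,
    score_system: str,
    endpoint: str,
    target_auc: float,
    tol: float = 0.01,
    n_sim: int = 20000,
    inner_seed: int = 987654321,
    max_scale: float = 8.0,
    max_iter: int = 60,
) -> CohortConfig:
    """Rescale the difficulty loadings to hit a target population AUC.

    Finds a common factor for all loadings (including ``gamma``) by
    bisection on a deterministic Monte-Carlo AUC estimate (one fixed
    inner seed, ``n_sim`` lesions, common random numbers across
    factors), stopping when the estimate is within ``tol`` of
    ``target_auc``.  Raises if the target is unreachable below
    ``max_scale``.
    """
    if score_system not in SCORE_COLUMNS:
        raise ValueError(f"unknown score system {score_system!r}")
    if endpoint not in ENDPOINT_DIRECTIONS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must be in [0.5, 1)")
    if target_auc == 0.5:
        return scaled_config(config, 0.0)

    def estimate(s):
        return _population_auc(
            scaled_config(config, s), score_system, endpoint, n_sim, inner_seed
        )

    lo, hi = 0.0, 1.0
    a_hi = estimate(hi)
    while a_hi < target_auc:
        hi *= 2.0
        if hi > max_scale:
            raise ValueError(
                f"target AUC {target_auc} unreachable below scale {max_scale} "
                f"(best {a_hi:.3f})"
            )
        a_hi = estimate(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a_mid = estimate(mid)
        if abs(a_mid - target_auc) <= tol:
            return scaled_config(config, mid)
        if a_mid < target_auc:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration did not converge; widen tol or raise n_sim")


# ---------------------------------------------------------------------------
# deterministic 110-lesion reference fixture
# ---------------------------------------------------------------------------


def _first_k(n: int, k: int) -> np.ndarray:
    return np.arange(n) < k


def _group_flags(k_success: int, k_failure: int) -> np.ndarray:
    return np.concatenate([_first_k(59, k_success), _first_k(51, k_failure)])


def fixture_table2_cohort() -> SyntheticCohort:
    """Deterministic 110-lesion cohort encoding the reference counts.

    The cohort has 59 lesions with time-efficient guidewire crossing
    (crossing time 9 min) and 51 without (110 min or never crossed);
    strategy-usage flags, final strategies, crossing indicators and
    TIMI-3 counts reproduce the reference per-group counts exactly, as
    do the per-group feature prevalences.  Within each group features
    are assigned to the first k lesions, so per-feature counts are
    exact but the *joint* feature structure carries no information —
    use :func:`generate_cohort` for correlated cohorts.
    """
    n = 110

    # -- lesion features: (success count of 59, failure count of 51) ----
    blunt = _group_flags(11, 29)
    side_branch = _group_flags(25, 32)
    tort45 = _group_flags(3, 20)
    calc_any = _group_flags(46, 43)
    calc_ge50 = _group_flags(16, 29)
    calc_full = _group_flags(3, 15)
    multiple = _group_flags(3, 13)
    landing = _group_flags(27, 28)
    duration = _group_flags(50, 48)
    reattempt = _group_flags(11, 13)
    grafted = _group_flags(8, 11)
    len_ge20 = _group_flags(9, 30)
    len_ge15 = _group_flags(16, 40)
    length = np.where(len_ge20, 25.0, np.where(len_ge15, 16.0, 9.0))
    bend = np.where(tort45, 50.0, 25.0)
    arc = np.where(calc_full, "360", np.where(calc_ge50, ">=180", "<180"))

    angio_blunt = _group_flags(10, 29)
    angio_calc = _group_flags(4, 13)
    angio_tort45 = _group_flags(6, 17)
    angio_len20 = _group_flags(7, 34)
    angio_length = np.where(angio_len20, 25.0, 10.0)
    angio_bend = np.where(angio_tort45, 50.0, 25.0)

    ids = [f"T{i + 1:03d}" for i in range(n)]
    lesions = pd.DataFrame(
        {
            "lesion_id": ids,
            "blunt_cap_proximal": blunt.astype(int),
            "blunt_cap_entry_or_exit": blunt.astype(int),
            "proximal_side_branch": side_branch.astype(int),
            "occlusion_length_mm": length,
            "max_bend_deg": bend,
            "any_calcification": calc_any.astype(int),
            "calc_arc_max_deg": arc,
            "calc_area_frac_ge_50": calc_ge50.astype(int),
            "calc_area_frac_100": calc_full.astype(int),
            "multiple_occlusions": multiple.astype(int),
            "diseased_distal_landing_zone": landing.astype(int),
            "angio_blunt_stump": angio_blunt.astype(int),
            "angio_any_calcification": angio_calc.astype(int),
            "angio_max_bend_deg": angio_bend,
            "angio_occlusion_length_mm": angio_length,
            "duration_gt_12mo_or_unknown": duration.astype(int),
            "reattempt": reattempt.astype(int),
            "prior_cabg_to_cto_vessel": grafted.astype(int),
        }
    )

    # -- procedures ------------------------------------------------------
    # success group: 57 pure AW, one AW+ADR (final ADR), one AW+RW
    # (final RW); failure group built block-wise so that every strategy
    # marginal (any/final AW, ADR, RW, RDR), the crossed count (41) and
    # the TIMI-3 count (39) land exactly on the reference values.
    rows = []

    def add(m, aw, adr, rw, rdr, final_s, t, timi, resid, sw):
        for _ in range(m):
            rows.append((aw, adr, rw, rdr, final_s, t, timi, resid, sw))

    # success group (59), crossing at 9 min, all TIMI 3
    add(1, 1, 1, 0, 0, "ADR", 9.0, 3, 10.0, 14.5)
    add(1, 1, 0, 1, 0, "RW", 9.0, 3, 10.0, 14.5)
    add(57, 1, 0, 0, 0, "AW", 9.0, 3, 10.0, np.nan)
    # failure group (51), crossings at 110 min
    add(11, 1, 0, 0, 0, "AW", 110.0, 3, 10.0, np.nan)
    add(2, 1, 0, 0, 0, "AW", 110.0, 2, 60.0, np.nan)  # flow not restored
    add(1, 1, 1, 1, 0, "AW", 110.0, 3, 10.0, 30.0)
    add(5, 1, 1, 0, 0, "ADR", 110.0, 3, 10.0, 30.0)
    add(2, 1, 1, 1, 0, "ADR", 110.0, 3, 10.0, 30.0)
    add(6, 1, 0, 1, 0, "RW", 110.0, 3, 10.0, 30.0)
    add(4, 0, 0, 1, 0, "RW", 110.0, 3, 10.0, np.nan)  # primary retrograde
    add(1, 1, 1, 1, 0, "RW", 110.0, 3, 10.0, 30.0)
    add(2, 1, 1, 0, 1, "RDR", 110.0, 3, 10.0, 30.0)
    add(3, 1, 0, 1, 1, "RDR", 110.0, 3, 10.0, 30.0)
    add(4, 1, 1, 1, 1, "RDR", 110.0, 3, 10.0, 30.0)
    add(10, 1, 1, 1, 0, "none", np.nan, 0, np.nan, 30.0)  # never crossed

    proc = pd.DataFrame(
        rows,
        columns=[
            "used_aw",
            "used_adr",
            "used_rw",
            "used_rdr",
            "final_strategy",
            "gw_crossing_time_min",
            "timi_flow",
            "residual_stenosis_pct",
            "switch_time_min",
        ],
    )
    proc.insert(0, "lesion_id", ids)
    procedures = proc[
        [
            "lesion_id",
            "gw_crossing_time_min",
            "used_aw",
            "used_adr",
            "used_rw",
            "used_rdr",
            "final_strategy",
            "residual_stenosis_pct",
            "timi_flow",
            "switch_time_min",
        ]
    ]
    return SyntheticCohort(
        lesions, procedures, np.full(n, np.nan), config=None, seed=None
    )
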