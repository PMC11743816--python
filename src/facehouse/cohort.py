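"""Synthetic behavioral cohort: questionnaire subscales and emotion labeling.

Emulates a population-based pre-adolescent cohort (ages 8-11): four
social-competence subscale scores, per-emotion labeling accuracy (correct out
of 8 items) and the median reaction time over correct trials.  Every score is
drawn from a bounded two-moment family calibrated so that, with no planted
effects, the sample moments converge to the cohort's published descriptive
statistics.  Age and sex effects are planted on the per-child *mean* of the
family (centered at the design midpoints), so an OLS regression of the
generated score on age and sex recovers the planted slope without
discretization bias, and the grand mean stays on calibration.

Families
--------
* SDQ subscales (0-10): beta-binomial - bounded, skewed, overdispersed.
* IRI subscales (0-28) and accuracy (0-8): rounded-and-clipped normal with
  latent moments solved numerically; this family also represents mild
  underdispersion and the ceiling effect on happy-face accuracy.
* Reaction times: lognormal per trial with a child-level speed factor; the
  recorded value is the median over the child's correct trials, missing when
  the child has no correct trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import EMOTIONS, GroundTruth

# Published cohort moments: outcome -> (mean, sd, lo, hi).
SCORE_MOMENTS = {
    "sdq_prosocial": (8.49, 1.69, 0, 10),
    "sdq_peer_problems": (1.07, 1.56, 0, 10),
    "iri_pt": (14.37, 4.96, 0, 28),
    "iri_ec": (18.44, 4.40, 0, 28),
    "acc_happy": (7.64, 0.62, 0, 8),
    "acc_sad": (4.89, 1.56, 0, 8),
    "acc_angry": (4.28, 1.40, 0, 8),
    "acc_fearful": (6.53, 1.59, 0, 8),
    "acc_neutral": (6.92, 1.62, 0, 8),
}

SUBSCALES = ("sdq_prosocial", "sdq_peer_problems", "iri_pt", "iri_ec")

# Child-level median RT scale (ms): happy faces are labeled fastest; the
# other emotions share a common scale (group mean ~2.5 s, between-child SD
# ~0.7 s as in the cohort's fearful-face distribution).
RT_BASE_MS = {
    "happy": 1900.0,
    "sad": 2500.0,
    "angry": 2500.0,
    "fearful": 2500.0,
    "neutral": 2500.0,
}
RT_CHILD_SDLOG = 0.27  # between-child spread of the median, log scale
RT_TRIAL_SDLOG = 0.25  # within-child trial-to-trial spread, log scale

N_ITEMS = 8  # emotion-labeling items per emotion (40 items / 5 emotions)


@dataclass(frozen=True)
class PlannedEffect:
    """Planted age slope and girl-boy difference for one outcome.

    ``age_reliable`` / ``sex_reliable`` mark effects large enough (relative
    to cohort-scale sampling noise) that their sign is recoverable; weak
    effects are planted too but excluded from sign-recovery checks.
    """

    age: float = 0.0
    sex: float = 0.0
    age_reliable: bool = False
    sex_reliable: bool = False


#: Default planted-effect scenario: the cohort-scale age/sex coefficients
#: (outcome units per year; girl minus boy) reported for each behavioral
#: outcome, with reliability flags for the effects that survived Bonferroni
#: correction at cohort scale.
DEFAULT_EFFECT_PLAN = {
    "sdq_prosocial": PlannedEffect(0.175, 0.557, True, True),
    "sdq_peer_problems": PlannedEffect(0.0, -0.443, False, True),
    "iri_pt": PlannedEffect(0.751, 1.488, True, True),
    "iri_ec": PlannedEffect(0.0, 1.211, False, True),
    "acc_happy": PlannedEffect(0.05, 0.12, False, True),
    "acc_sad": PlannedEffect(0.18, 0.37, True, True),
    "acc_angry": PlannedEffect(0.28, 0.15, True, False),
    "acc_fearful": PlannedEffect(0.29, 0.32, True, True),
    "acc_neutral": PlannedEffect(0.23, -0.10, True, False),
    "rt_happy": PlannedEffect(-150.0, -96.0, True, True),
    "rt_sad": PlannedEffect(-145.0, -97.0, True, False),
    "rt_angry": PlannedEffect(-181.0, -156.0, True, True),
    "rt_fearful": PlannedEffect(-213.0, -67.0, True, False),
    "rt_neutral": PlannedEffect(-253.0, 18.0, True, False),
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_children : int
        Cohort size (>= 2).
    age_range : (float, float)
        Uniform age range in years, increasing.
    sex_proportion_girls : float
        Probability that a child is a girl (sex coded 0=boy, 1=girl).
    effect_age, effect_sex : dict or None
        Outcome -> planted slope (units/year) and girl-boy difference.
        ``None`` means no planted effects.
    rt_missing_rule : bool
        If True (default), a child with zero correct trials for an emotion
        has a missing median RT; if False, such children are regenerated
        with at least one correct trial (rarely needed; kept for tests).
    seed : int
        RNG seed; identical config + seed gives bit-identical output.
    """

    n_children: int
    age_range: tuple = (8.0, 11.0)
    sex_proportion_girls: float = 0.5
    effect_age: dict | None = None
    effect_sex: dict | None = None
    rt_missing_rule: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 2:
            raise ValueError("n_children must be >= 2")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range must be increasing")
        if not 0.0 <= self.sex_proportion_girls <= 1.0:
            raise ValueError("sex_proportion_girls must be in [0, 1]")
        for d in (self.effect_age, self.effect_sex):
            if d is not None:
                unknown = set(d) - set(SCORE_MOMENTS) - {f"rt_{e}" for e in EMOTIONS}
                if unknown:
                    raise ValueError(f"unknown outcome(s) in effect dict: {sorted(unknown)}")


def effect_plan_to_dicts(plan: dict) -> tuple:
    """Split an outcome -> :class:`PlannedEffect` plan into effect dicts."""
    age = {k: v.age for k, v in plan.items() if v.age}
    sex = {k: v.sex for k, v in plan.items() if v.sex}
    return age, sex


# ---------------------------------------------------------------------------
# Two-moment bounded families


@lru_cache(maxsize=None)
def betabinom_params(mean: float, sd: float, n: int) -> tuple:
    """Beta-binomial (n, a, b) with the requested mean and SD.

    Closed form: with mu = mean/n and intraclass correlation rho,
    var = n mu (1-mu) (1 + (n-1) rho).  Requires overdispersion relative to
    the binomial (rho > 0).
    """
    mu = mean / n
    base = n * mu * (1.0 - mu)
    rho = (sd**2 / base - 1.0) / (n - 1)
    if rho <= 0:
        raise ValueError("beta-binomial requires SD above the binomial level")
    s = (1.0 - rho) / rho
    return mu * s, (1.0 - mu) * s


def _clipped_normal_moments(mu, sigma, hi):
    """Mean/SD of clip(round(Normal(mu, sigma)), 0, hi)."""
    k = np.arange(hi + 1)
    edges_lo = np.where(k == 0, -np.inf, k - 0.5)
    edges_hi = np.where(k == hi, np.inf, k + 0.5)
    p = stats.norm.cdf((edges_hi - mu) / sigma) - stats.norm.cdf((edges_lo - mu) / sigma)
    m = float(np.sum(k * p))
    v = float(np.sum((k - m) ** 2 * p))
    return m, np.sqrt(v)


@lru_cache(maxsize=None)
def clipped_normal_params(mean: float, sd: float, hi: int) -> tuple:
    """Latent (mu, sigma) so the rounded-clipped normal has the target moments."""

    def eqs(x):
        m, s = _clipped_normal_moments(x[0], np.exp(x[1]), hi)
        return [m - mean, s - sd]

    sol = optimize.root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - calibration targets are fixed
        raise RuntimeError(f"moment calibration failed for ({mean}, {sd}, 0-{hi})")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    return mu, sigma


@lru_cache(maxsize=None)
def _clipped_normal_mean_inverse(sigma: float, hi: int) -> tuple:
    """Monotone grid mapping observed mean -> latent mean at fixed sigma."""
    mu_grid = np.linspace(-4.0 * sigma, hi + 4.0 * sigma, 2001)
    mean_grid = np.array([_clipped_normal_moments(m, sigma, hi)[0] for m in mu_grid])
    return mean_grid, mu_grid


def _draw_scores(rng, outcome, target_means):
    """Draw integer scores for one outcome with per-child planted means."""
    mean0, sd0, lo, hi = SCORE_MOMENTS[outcome]
    if np.any(target_means <= lo) or np.any(target_means >= hi):
        raise ValueError(
            f"planted effects push the {outcome} mean outside ({lo}, {hi})"
        )
    if outcome.startswith("sdq_"):
        a0, b0 = betabinom_params(mean0, sd0, hi)
        s = a0 + b0  # concentration held fixed; per-child mean moves
        mu_i = target_means / hi
        p = rng.beta(mu_i * s, (1.0 - mu_i) * s)
        return rng.binomial(hi, p).astype(np.int64)
    mu0, sigma = clipped_normal_params(mean0, sd0, hi)
    if np.allclose(target_means, mean0):
        mu_i = np.full(len(target_means), mu0)
    else:
        mean_grid, mu_grid = _clipped_normal_mean_inverse(sigma, hi)
        mu_i = np.interp(target_means, mean_grid, mu_grid)
    z = rng.normal(mu_i, sigma)
    return np.clip(np.rint(z), lo, hi).astype(np.int64)


# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple:
    """Generate a cohort table and the ground truth planted in it.

    Returns
    -------
    (DataFrame, GroundTruth)
        One row per child: ``child_id``, ``age`` (years), ``sex`` (0=boy,
        1=girl), the four subscales, per-emotion ``acc_*`` (0-8), ``rt_*``
        (median correct-trial RT, ms; NaN when accuracy is 0) and
        ``n_correct_basis_*`` (trial count behind each median).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    lo_age, hi_age = config.age_range
    age = rng.uniform(lo_age, hi_age, n)
    sex = (rng.random(n) < config.sex_proportion_girls).astype(np.int64)
    # effects are centered at the design expectations so the grand mean
    # stays on the calibrated target
    age_c = age - 0.5 * (lo_age + hi_age)
    sex_c = sex - config.sex_proportion_girls

    eff_age = config.effect_age or {}
    eff_sex = config.effect_sex or {}
    effects = {
        k: (eff_age.get(k, 0.0), eff_sex.get(k, 0.0))
        for k in set(eff_age) | set(eff_sex)
    }

    table = {"child_id": [f"sub-{i + 1:06d}" for i in range(n)], "age": age, "sex": sex}

    for outcome in SCORE_MOMENTS:
        ea, es = effects.get(outcome, (0.0, 0.0))
        target = SCORE_MOMENTS[outcome][0] + ea * age_c + es * sex_c
        table[outcome] = _draw_scores(rng, outcome, target)

    for emo in EMOTIONS:
        acc = table[f"acc_{emo}"]
        ea, es = effects.get(f"rt_{emo}", (0.0, 0.0))
        med_target = RT_BASE_MS[emo] + ea * age_c + es * sex_c
        if np.any(med_target <= 0):
            raise ValueError(f"planted effects push rt_{emo} medians below 0 ms")
        if not config.rt_missing_rule:
            acc = np.maximum(acc, 1)
            table[f"acc_{emo}"] = acc
        eta = rng.normal(0.0, RT_CHILD_SDLOG, n)
        meanlog = np.log(med_target) + eta
        trials = rng.lognormal(
            meanlog[:, None], RT_TRIAL_SDLOG, size=(n, N_ITEMS)
        )
        # pad all-incorrect children with a dummy trial so nanmedian never
        # sees an all-NaN row; the result is overwritten with NaN below
        keep = np.arange(N_ITEMS)[None, :] < np.maximum(acc, 1)[:, None]
        trials[~keep] = np.nan
        rt = np.nanmedian(trials, axis=1)
        rt[acc == 0] = np.nan
        table[f"rt_{emo}"] = rt
        table[f"n_correct_basis_{emo}"] = acc

    truth = GroundTruth(
        behavioral_effects={k: v for k, v in effects.items() if any(v)}
    )
    return pd.DataFrame(table), truth
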