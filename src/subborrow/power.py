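"""Monte-Carlo operating characteristics of the planned borrowing analysis.

Simulates two-arm binomial trials under planning assumptions (1:1 arms,
common failure rate, independent loss to follow-up with complete-case
analysis), applies the commensurate-prior posterior with the elicitation-
fixed ``sigma_delta`` to each simulated trial, and counts declarations of
non-inferiority.  A closed-form normal approximation for the standalone
analysis serves as a cross-check on the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import (
    InteractionPrior,
    ModelConfig,
    PlanningDesign,
    PosteriorResult,
    SubgroupSummary,
    Z_95,
    planning_se,
    posterior_combine,
)

__all__ = [
    "TruthScenario",
    "PowerResult",
    "declare_noninferior",
    "simulate_trial",
    "predictive_power",
    "standalone_power",
    "analytic_standalone_power",
    "analytic_predictive_power",
]


@dataclass(frozen=True)
class TruthScenario:
    """True failure probabilities generating the simulated data.

    ``p_fail_soc`` / ``p_fail_dtg`` apply to both subgroups; ``delta_true``
    is an optional true interaction added to the target subgroup's DTG-arm
    failure probability (a true difference in risk differences).
    """

    p_fail_soc: float = 0.18
    p_fail_dtg: float = 0.18
    delta_true: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_fail_soc, self.p_fail_dtg):
            if not 0 < p < 1:
                raise ValueError(f"failure probability must be in (0, 1), got {p}")
        if not 0 < self.p_fail_dtg + self.delta_true < 1:
            raise ValueError("target-subgroup DTG failure probability outside (0, 1)")

    def arm_probs(self, subgroup: str) -> tuple[float, float]:
        """(p_dtg, p_soc) for 'target' or 'source'."""
        extra = self.delta_true if subgroup == "target" else 0.0
        return self.p_fail_dtg + extra, self.p_fail_soc


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    mc_se: float
    n_reps: int
    seed: int


def declare_noninferior(result: PosteriorResult, margin: float) -> bool:
    """Non-inferiority is declared iff the 95% upper bound is strictly below
    the margin."""
    if not margin > 0:
        raise ValueError("margin must be > 0")
    return result.cri_upper < margin


def _simulate_subgroup(n: int, p_dtg: float, p_soc: float, ltfu: float,
                       rng: np.random.Generator, n_reps: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-arm simulation: (estimates, Wald SEs) over reps.

    1:1 randomisation (fixed split, DTG gets the floor), Bernoulli dropout
    with complete-case analysis, Wald SE with a 0.5 continuity correction to
    both cells of any arm with a zero cell.  Trials with an empty analysed
    arm are redrawn.
    """
    n_dtg, n_soc = n // 2, n - n // 2
    est = np.empty(n_reps)
    se = np.empty(n_reps)
    pending = np.arange(n_reps)
    while pending.size:
        m = pending.size
        a_dtg = n_dtg - rng.binomial(n_dtg, ltfu, m)
        a_soc = n_soc - rng.binomial(n_soc, ltfu, m)
        ok = (a_dtg > 0) & (a_soc > 0)
        idx = pending[ok]
        x_dtg = rng.binomial(a_dtg[ok], p_dtg)
        x_soc = rng.binomial(a_soc[ok], p_soc)
        ad, asoc = a_dtg[ok], a_soc[ok]
        p1, p0 = x_dtg / ad, x_soc / asoc
        est[idx] = p1 - p0
        # continuity fix only where an arm has a zero cell
        z1 = (x_dtg == 0) | (x_dtg == ad)
        z0 = (x_soc == 0) | (x_soc == asoc)
        p1c = np.where(z1, (x_dtg + 0.5) / (ad + 1.0), p1)
        n1c = np.where(z1, ad + 1.0, ad)
        p0c = np.where(z0, (x_soc + 0.5) / (asoc + 1.0), p0)
        n0c = np.where(z0, asoc + 1.0, asoc)
        se[idx] = np.sqrt(p1c * (1 - p1c) / n1c + p0c * (1 - p0c) / n0c)
        pending = pending[~ok]
    return est, se


def simulate_trial(design: PlanningDesign, truth: TruthScenario,
                   rng: np.random.Generator
                   ) -> tuple[SubgroupSummary, SubgroupSummary]:
    """Simulate one trial; returns (target, source) subgroup summaries."""
    out = []
    for name, n in (("target", design.n_target), ("source", design.n_source)):
        p_dtg, p_soc = truth.arm_probs(name)
        est, se = _simulate_subgroup(int(n), p_dtg, p_soc, design.ltfu, rng, 1)
        out.append(SubgroupSummary(float(est[0]), float(se[0]), name))
    return out[0], out[1]


def predictive_power(design: PlanningDesign, prior: InteractionPrior,
                     truth: TruthScenario, n_reps: int = 20_000,
                     seed: int = 0) -> PowerResult:
    """Probability that the borrowing analysis declares non-inferiority.

    ``sigma_delta`` is held fixed (its elicitation-derived value) across
    replicates; the realised source weight varies with each trial's
    simulated standard errors.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    p_dtg_t, p_soc_t = truth.arm_probs("target")
    p_dtg_s, p_soc_s = truth.arm_probs("source")
    est_t, se_t = _simulate_subgroup(int(design.n_target), p_dtg_t, p_soc_t,
                                     design.ltfu, rng, n_reps)
    est_s, se_s = _simulate_subgroup(int(design.n_source), p_dtg_s, p_soc_s,
                                     design.ltfu, rng, n_reps)
    prec_t = 1.0 / se_t**2
    prec_s = 1.0 / (se_s**2 + prior.variance)
    prec = prec_t + prec_s
    mean = (est_t * prec_t + est_s * prec_s) / prec
    upper = mean + Z_95 * np.sqrt(1.0 / prec)
    hits = int(np.count_nonzero(upper < design.margin))
    power = hits / n_reps
    return PowerResult(power=power,
                       mc_se=float(np.sqrt(power * (1 - power) / n_reps)),
                       n_reps=n_reps, seed=seed)


def standalone_power(design: PlanningDesign, truth: TruthScenario,
                     n_reps: int = 20_000, seed: int = 0) -> PowerResult:
    """Power of the frequentist analysis of the target subgroup alone:
    non-inferiority iff estimate + z * SE < margin."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    p_dtg, p_soc = truth.arm_probs("target")
    est, se = _simulate_subgroup(int(design.n_target), p_dtg, p_soc,
                                 design.ltfu, rng, n_reps)
    hits = int(np.count_nonzero(est + Z_95 * se < design.margin))
    power = hits / n_reps
    return PowerResult(power=power,
                       mc_se=float(np.sqrt(power * (1 - power) / n_reps)),
                       n_reps=n_reps, seed=seed)


def analytic_standalone_power(design: PlanningDesign,
                              truth: TruthScenario | None = None) -> float:
    """Normal-approximation power of the standalone target analysis.

    ``Phi((margin - d) / se_plan - z)`` with the planning SE evaluated at the
    LTFU-deflated target size and ``d`` the true risk difference in the
    target subgroup (0 under the default planning truth).
    """
    truth = truth or TruthScenario(p_fail_soc=design.p_fail,
                                   p_fail_dtg=design.p_fail)
    p_dtg, p_soc = truth.arm_probs("target")
    d = p_dtg - p_soc
    n_eff = design.n_target * (1 - design.ltfu)
    se_plan = planning_se(n_eff, design.p_fail, design.alloc)
    return float(norm.cdf((design.margin - d) / se_plan - Z_95))


def analytic_predictive_power(design: PlanningDesign, prior: InteractionPrior,
                              truth: TruthScenario | None = None) -> float:
    """Normal-approximation (delta-method) predictive power of the borrowing
    analysis, a cross-check on the simulator.

    Treats both subgroup estimates as normal with their LTFU-deflated
    planning variances: the posterior mean is then normal, and non-
    inferiority is declared when it falls below ``margin - z * sd_post``.
    """
    truth = truth or TruthScenario(p_fail_soc=design.p_fail,
                                   p_fail_dtg=design.p_fail)
    shrink = 1 - design.ltfu
    var_t = planning_se(design.n_target * shrink, design.p_fail, design.alloc) ** 2
    var_s = planning_se(design.n_source * shrink, design.p_fail, design.alloc) ** 2
    prec_t = 1.0 / var_t
    prec_s = 1.0 / (var_s + prior.variance)
    prec = prec_t + prec_s
    sd_post = (1.0 / prec) ** 0.5
    w_t, w_s = prec_t / prec, prec_s / prec
    p_dtg_t, p_soc_t = truth.arm_probs("target")
    p_dtg_s, p_soc_s = truth.arm_probs("source")
    mean_m = w_t * (p_dtg_t - p_soc_t) + w_s * (p_dtg_s - p_soc_s)
    sd_m = (w_t**2 * var_t + w_s**2 * var_s) ** 0.5
    threshold = design.margin - Z_95 * sd_post
    return float(norm.cdf((threshold - mean_m) / sd_m))
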