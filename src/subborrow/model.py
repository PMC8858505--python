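"""Closed-form commensurate-prior borrowing between two trial subgroups.

The model: a small *target* subgroup provides an estimate ``y1`` of its
treatment effect (a risk difference) with standard error ``sigma1``; a larger
*source* subgroup in the same trial provides ``y0`` with standard error
``sigma0``.  The two true effects are linked through an interaction parameter
``delta = theta1 - theta0`` given a zero-mean normal prior with standard
deviation ``sigma_delta`` (the commensurability parameter).  With a flat prior
on ``theta0`` the posterior for the target-subgroup effect is conjugate
normal: a precision-weighted average of the two subgroup estimates in which
the source subgroup's variance is inflated by ``sigma_delta**2``.

``sigma_delta`` has a one-to-one correspondence with the *relative weight*
the source data receive in that average, which is how the amount of borrowing
is communicated to, and elicited from, clinical experts.  All quantities are
on the proportion scale internally; percent conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "SubgroupSummary",
    "InteractionPrior",
    "ModelConfig",
    "PosteriorResult",
    "PlanningDesign",
    "se_from_ci",
    "planning_se",
    "relative_weight",
    "max_weight",
    "sigma_delta_from_weight",
    "posterior_combine",
    "pooled_estimate",
    "effective_sample_size",
    "implied_prior_range",
    "round_half_away",
]

#: exact two-sided 95% standard-normal quantile, used everywhere a "1.96"
#: would appear.
Z_95 = float(norm.ppf(0.975))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of clinical reports,
    unlike banker's rounding used by built-in :func:`round`)."""
    scale = 10.0**ndigits
    # the trailing +0.0 normalises negative zero
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x) + 0.0


@dataclass(frozen=True)
class SubgroupSummary:
    """A risk-difference estimate and its standard error for one subgroup.

    Both are on the proportion scale: ``estimate`` in [-1, 1], ``se`` > 0.
    The standard error is treated as fixed and known.
    """

    estimate: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if abs(self.estimate) > 1:
            raise ValueError(
                f"risk difference must lie in [-1, 1], got {self.estimate}"
            )

    @property
    def variance(self) -> float:
        return self.se**2

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Symmetric normal confidence interval at the given coverage."""
        z = float(norm.ppf((1 + level) / 2))
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass(frozen=True)
class InteractionPrior:
    """Zero-mean normal prior on the treatment-by-subgroup interaction.

    ``sigma_delta`` is the prior standard deviation of the difference between
    the target- and source-subgroup treatment effects; 0 encodes the belief
    that the effects are identical (full pooling).
    """

    sigma_delta: float

    def __post_init__(self) -> None:
        if self.sigma_delta < 0:
            raise ValueError(f"sigma_delta must be >= 0, got {self.sigma_delta}")

    @property
    def variance(self) -> float:
        return self.sigma_delta**2


@dataclass(frozen=True)
class ModelConfig:
    """Analysis conventions: flat-prior variance for the source effect, the
    normal quantile for 95% intervals, and the reporting scale."""

    flat_prior_variance: float = 1e6
    z: float = Z_95
    report_scale: str = "proportion"

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.report_scale not in ("proportion", "percent"):
            raise ValueError("report_scale must be 'proportion' or 'percent'")


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior summary for the target-subgroup treatment effect."""

    mean: float
    sd: float
    cri_lower: float
    cri_upper: float
    weight_source: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "cri_lower": self.cri_lower,
            "cri_upper": self.cri_upper,
            "weight_source": self.weight_source,
        }


@dataclass(frozen=True)
class PlanningDesign:
    """Planning assumptions for the trial design.

    ``n_target`` / ``n_source`` are planned subgroup sizes, ``p_fail`` the
    assumed common failure probability in both arms, ``ltfu`` the expected
    loss-to-follow-up fraction, ``margin`` the non-inferiority margin on the
    risk-difference scale, ``alloc`` the allocation fraction per arm.
    """

    n_target: float
    n_source: float
    p_fail: float
    ltfu: float = 0.0
    margin: float = 0.10
    alloc: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p_fail < 1:
            raise ValueError(f"p_fail must be in (0, 1), got {self.p_fail}")
        if self.n_target < 2 or self.n_source < 2:
            raise ValueError("subgroup sizes must be >= 2")
        if not 0 <= self.ltfu < 1:
            raise ValueError(f"ltfu must be in [0, 1), got {self.ltfu}")
        if not self.margin > 0:
            raise ValueError("margin must be > 0")
        if not 0 < self.alloc < 1:
            raise ValueError("alloc must be in (0, 1)")

    def se_target(self) -> float:
        """Planning standard error of the target-subgroup risk difference."""
        return planning_se(self.n_target, self.p_fail, self.alloc)

    def se_source(self) -> float:
        return planning_se(self.n_source, self.p_fail, self.alloc)

    def summaries(self, y_target: float = 0.0, y_source: float = 0.0
                  ) -> tuple[SubgroupSummary, SubgroupSummary]:
        """Subgroup summaries with planning SEs and the given estimates."""
        return (
            SubgroupSummary(y_target, self.se_target(), "target"),
            SubgroupSummary(y_source, self.se_source(), "source"),
        )


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Back out a standard error from a symmetric normal confidence interval.

    ``se = (upper - lower) / (2 * z)`` with ``z`` the two-sided quantile for
    ``level``.  Raises on a degenerate (non-positive width) interval.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not upper > lower:
        raise ValueError(f"degenerate interval: ({lower}, {upper})")
    z = float(norm.ppf((1 + level) / 2))
    return (upper - lower) / (2 * z)


def planning_se(n_total: float, p_fail: float, alloc: float = 0.5) -> float:
    """Planning standard error of a risk difference for a two-arm comparison.

    Assumes failure probability ``p_fail`` in both arms of a subgroup of
    ``n_total`` participants split ``alloc : 1 - alloc``.  Fractional arm
    sizes are allowed (no rounding): this is a design-stage approximation.
    For 1:1 allocation it reduces to ``sqrt(4 p (1-p) / n)``.
    """
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    if not 0 < p_fail < 1:
        raise ValueError(f"p_fail must be in (0, 1), got {p_fail}")
    if not 0 < alloc < 1:
        raise ValueError(f"alloc must be in (0, 1), got {alloc}")
    v = p_fail * (1 - p_fail) * (1 / (alloc * n_total) + 1 / ((1 - alloc) * n_total))
    return math.sqrt(v)


def relative_weight(prior: InteractionPrior, target: SubgroupSummary,
                    source: SubgroupSummary) -> float:
    """Relative weight of the source subgroup in the combined analysis.

    The fraction of posterior precision contributed by the source data,
    ``[1/(s0^2+sd^2)] / [1/s1^2 + 1/(s0^2+sd^2)]``.  Strictly decreasing in
    ``sigma_delta``; equals ``s1^2/(s0^2+s1^2)`` at ``sigma_delta = 0``.
    """
    prec_source = 1.0 / (source.variance + prior.variance)
    prec_target = 1.0 / target.variance
    return prec_source / (prec_target + prec_source)


def max_weight(target: SubgroupSummary, source: SubgroupSummary) -> float:
    """Largest attainable source weight (full pooling, ``sigma_delta = 0``)."""
    return target.variance / (source.variance + target.variance)


def sigma_delta_from_weight(weight: float, target: SubgroupSummary,
                            source: SubgroupSummary) -> InteractionPrior:
    """Invert the weight formula: the interaction-prior sd that realises a
    requested source weight.

    Solves ``sigma_delta = sqrt(s1^2 (1-w)/w - s0^2)``.  Only weights in
    ``(0, w_max]`` are attainable, where ``w_max`` is the full-pooling weight.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    w_max = max_weight(target, source)
    var = target.variance * (1 - weight) / weight - source.variance
    if abs(var) < 1e-14 * target.variance:
        # float round-off at or within an ulp of w_max
        var = 0.0
    if var < 0:
        if math.isclose(weight, w_max, rel_tol=1e-12):
            var = 0.0
        else:
            raise ValueError(
                f"weight {weight} exceeds the full-pooling bound {w_max:.6f}; "
                "no nonnegative sigma_delta can borrow that much"
            )
    return InteractionPrior(math.sqrt(var))


def posterior_combine(target: SubgroupSummary, source: SubgroupSummary,
                      prior: InteractionPrior,
                      config: ModelConfig = ModelConfig()) -> PosteriorResult:
    """Posterior for the target-subgroup effect, borrowing from the source.

    Precision-weighted average of the target estimate (precision ``1/s1^2``)
    and the source estimate (precision ``1/(s0^2 + sigma_delta^2)``), the flat
    -prior limit of the full conjugate model.  Standard errors are treated as
    fixed and known; the credible interval is equal-tailed normal.
    """
    prec_target = 1.0 / target.variance
    prec_source = 1.0 / (source.variance + prior.variance)
    prec = prec_target + prec_source
    mean = (target.estimate * prec_target + source.estimate * prec_source) / prec
    sd = math.sqrt(1.0 / prec)
    z = config.z
    return PosteriorResult(
        mean=mean,
        sd=sd,
        cri_lower=mean - z * sd,
        cri_upper=mean + z * sd,
        weight_source=prec_source / prec,
    )


def pooled_estimate(target: SubgroupSummary, source: SubgroupSummary,
                    config: ModelConfig = ModelConfig()) -> PosteriorResult:
    """Conventional inverse-variance pooling of the two subgroups.

    Identical to :func:`posterior_combine` with ``sigma_delta = 0`` — the
    analysis appropriate when the treatment effects are believed identical.
    """
    return posterior_combine(target, source, InteractionPrior(0.0), config)


def effective_sample_size(prior: InteractionPrior, design: PlanningDesign
                          ) -> tuple[int, int]:
    """Effective sample size of the borrowed source information.

    The number of target-population children whose planning variance equals
    the down-weighted source variance ``s0^2 + sigma_delta^2``; for the
    design's allocation this is ``p(1-p)(1/alloc + 1/(1-alloc)) / (s0^2 +
    sd^2)``, rounded to the nearest integer.  Returns ``(ess_borrowed,
    ess_borrowed + n_target)``.
    """
    var = design.se_source() ** 2 + prior.variance
    if var <= 0:
        raise ValueError("nonpositive effective variance")
    p = design.p_fail
    unit_var = p * (1 - p) * (1 / design.alloc + 1 / (1 - design.alloc))
    ess_borrowed = int(round_half_away(unit_var / var))
    return ess_borrowed, ess_borrowed + int(round_half_away(design.n_target))


def implied_prior_range(theta0_assumed: float, prior: InteractionPrior,
                        level: float = 0.95) -> tuple[float, float]:
    """Uncertainty range for the target effect implied by a borrowing choice.

    Conditional on the source effect being known exactly (the "very large
    trial" framing used during elicitation), the target effect is
    ``theta0 + delta`` and its central ``level`` range is ``theta0 ±
    z * sigma_delta``.  This is the feedback quantity shown to experts when
    they choose a weight.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = float(norm.ppf((1 + level) / 2))
    half = z * prior.sigma_delta
    return theta0_assumed - half, theta0_assumed + half
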