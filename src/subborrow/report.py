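"""Configuration loading and the three-way analysis report.

A run config (YAML) carries a planning block, an analysis block (the two
subgroup summaries plus either a weight or a sigma_delta) and reporting
options.  ``run_report`` computes the standalone, pooled and borrowing
analyses side by side — the recommended transparent presentation — and
checks their ordering invariants before returning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import yaml

from . import __version__
from .model import (
    InteractionPrior,
    ModelConfig,
    PlanningDesign,
    PosteriorResult,
    SubgroupSummary,
    pooled_estimate,
    posterior_combine,
    se_from_ci,
    sigma_delta_from_weight,
)
from .power import declare_noninferior

__all__ = ["RunConfig", "Report", "load_config", "run_report"]

_PLANNING_KEYS = {"n_target", "n_source", "p_fail", "ltfu", "margin", "alloc"}
_SUBGROUP_KEYS = {"estimate", "se", "ci_lower", "ci_upper"}
_ANALYSIS_KEYS = {"target", "source", "weight", "sigma_delta"}
_REPORTING_KEYS = {"scale", "round_digits"}
_TOP_KEYS = {"planning", "analysis", "reporting", "seed", "n_reps"}


class ConfigError(ValueError):
    """A config file failed validation; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    design: PlanningDesign
    target: SubgroupSummary
    source: SubgroupSummary
    prior: InteractionPrior
    scale: str = "percent"
    round_digits: int = 0
    seed: int = 0
    n_reps: int = 20_000
    raw: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class Report:
    """Standalone, pooled and borrowing analyses with decision flags."""

    inputs: dict
    standalone: PosteriorResult
    pooled: PosteriorResult
    borrowing: PosteriorResult
    noninferior: dict[str, bool]
    meta: dict

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "analyses": {
                "standalone": self.standalone.to_dict(),
                "pooled": self.pooled.to_dict(),
                "borrowing": self.borrowing.to_dict(),
            },
            "noninferior": self.noninferior,
            "meta": self.meta,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Human-readable side-by-side table, percent scale."""
        lines = [
            f"{'analysis':<12}{'estimate':>10}{'95% interval':>20}"
            f"{'weight':>9}{'non-inf':>9}",
        ]
        for name, res in (("standalone", self.standalone),
                          ("pooled", self.pooled),
                          ("borrowing", self.borrowing)):
            ci = f"({res.cri_lower * 100:+.1f}, {res.cri_upper * 100:+.1f})"
            lines.append(
                f"{name:<12}{res.mean * 100:>+9.1f}%{ci:>20}"
                f"{res.weight_source * 100:>8.0f}%"
                f"{'yes' if self.noninferior[name] else 'no':>9}"
            )
        return "\n".join(lines)


def _require_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{name}: unknown key(s) {sorted(unknown)}")


def _parse_subgroup(block: dict, label: str, factor: float) -> SubgroupSummary:
    if not isinstance(block, dict):
        raise ConfigError(f"analysis.{label}: expected a mapping")
    _require_keys(block, _SUBGROUP_KEYS, f"analysis.{label}")
    if "estimate" not in block:
        raise ConfigError(f"analysis.{label}.estimate is required")
    est = float(block["estimate"]) * factor
    has_se = "se" in block
    has_ci = "ci_lower" in block or "ci_upper" in block
    if has_se and has_ci:
        raise ConfigError(f"analysis.{label}: give se OR a CI, not both")
    if has_se:
        se = float(block["se"]) * factor
    elif "ci_lower" in block and "ci_upper" in block:
        se = se_from_ci(float(block["ci_lower"]) * factor,
                        float(block["ci_upper"]) * factor)
    else:
        raise ConfigError(f"analysis.{label}: needs se or both CI bounds")
    try:
        return SubgroupSummary(est, se, label)
    except ValueError as e:
        raise ConfigError(f"analysis.{label}: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config (percent or proportion scale)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(raw, _TOP_KEYS, "config")
    for key in ("planning", "analysis"):
        if key not in raw:
            raise ConfigError(f"missing required block '{key}'")

    reporting = raw.get("reporting", {}) or {}
    _require_keys(reporting, _REPORTING_KEYS, "reporting")
    scale = reporting.get("scale", "percent")
    if scale not in ("percent", "proportion"):
        raise ConfigError(f"reporting.scale: expected percent|proportion, got {scale!r}")
    factor = 0.01 if scale == "percent" else 1.0

    planning = raw["planning"]
    _require_keys(planning, _PLANNING_KEYS, "planning")
    try:
        design = PlanningDesign(
            n_target=float(planning["n_target"]),
            n_source=float(planning["n_source"]),
            p_fail=float(planning["p_fail"]) * factor,
            ltfu=float(planning.get("ltfu", 0.0)),
            margin=float(planning.get("margin", 0.10)) * factor,
            alloc=float(planning.get("alloc", 0.5)),
        )
    except KeyError as e:
        raise ConfigError(f"planning.{e.args[0]} is required") from e
    except ValueError as e:
        raise ConfigError(f"planning: {e}") from e

    analysis = raw["analysis"]
    _require_keys(analysis, _ANALYSIS_KEYS, "analysis")
    target = _parse_subgroup(analysis.get("target", {}), "target", factor)
    source = _parse_subgroup(analysis.get("source", {}), "source", factor)

    has_w = "weight" in analysis
    has_sd = "sigma_delta" in analysis
    if has_w and has_sd:
        raise ConfigError("analysis: weight and sigma_delta are mutually exclusive")
    if not has_w and not has_sd:
        raise ConfigError("analysis: one of weight or sigma_delta is required")
    if has_sd:
        prior = InteractionPrior(float(analysis["sigma_delta"]) * factor)
    else:
        # the weight is dimensionless; derive sigma_delta under PLANNING SEs,
        # which is how an elicited weight is carried into the analysis
        t_plan, s_plan = design.summaries()
        prior = sigma_delta_from_weight(float(analysis["weight"]), t_plan, s_plan)

    return RunConfig(
        design=design, target=target, source=source, prior=prior,
        scale=scale, round_digits=int(reporting.get("round_digits", 0)),
        seed=int(raw.get("seed", 0)), n_reps=int(raw.get("n_reps", 20_000)),
        raw=raw,
    )


def run_report(config: RunConfig) -> Report:
    """Compute the three analyses and assemble a provenance-stamped report."""
    mc = ModelConfig()
    target, source = config.target, config.source
    standalone = PosteriorResult(
        mean=target.estimate, sd=target.se,
        cri_lower=target.estimate - mc.z * target.se,
        cri_upper=target.estimate + mc.z * target.se,
        weight_source=0.0,
    )
    pooled = pooled_estimate(target, source, mc)
    borrowing = posterior_combine(target, source, config.prior, mc)

    # ordering sanity: borrowing lies between standalone and pooled
    lo = min(standalone.mean, pooled.mean) - 1e-12
    hi = max(standalone.mean, pooled.mean) + 1e-12
    if not lo <= borrowing.mean <= hi:
        raise RuntimeError("internal error: borrowing estimate not between "
                           "standalone and pooled estimates")

    margin = config.design.margin
    noninferior = {
        "standalone": declare_noninferior(standalone, margin),
        "pooled": declare_noninferior(pooled, margin),
        "borrowing": declare_noninferior(borrowing, margin),
    }
    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "sigma_delta": config.prior.sigma_delta,
        "margin": margin,
    }
    inputs = {
        "target": {"estimate": target.estimate, "se": target.se},
        "source": {"estimate": source.estimate, "se": source.se},
        "design": {
            "n_target": config.design.n_target,
            "n_source": config.design.n_source,
            "p_fail": config.design.p_fail,
            "ltfu": config.design.ltfu,
            "margin": margin,
            "alloc": config.design.alloc,
        },
    }
    return Report(inputs=inputs, standalone=standalone, pooled=pooled,
                  borrowing=borrowing, noninferior=noninferior, meta=meta)
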