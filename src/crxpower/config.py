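"""Run configuration: validated parameter sets for a power simulation.

A :class:`RunConfig` collects everything needed for one simulation run —
design geometry, data-generating parameters, the analysis label, alpha and
the master seed — under snake_case keys.  The dotted R-style spellings
(``btw.clust.var``, ``n.clusters`` …) are accepted as aliases for
familiarity with existing cluster-trial tooling.

Parameter applicability by outcome family:

=================  ==========  ========  =======
key                continuous  binary    count
=================  ==========  ========  =======
btw_clust_var      two of      yes       yes
indiv_var          these       --        --
icc                three       --        --
at_risk_params     --          --        yes
=================  ==========  ========  =======

Unknown keys and family/parameter mismatches are rejected outright rather
than ignored, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .datagen import BinomialParams, GaussianParams, PoissonParams
from .design import TrialDesign, complete_variances, make_design

__all__ = ["RunConfig", "ConfigError", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_FIELDS = {
    "family",
    "n_sim",
    "effect_size",
    "alpha",
    "n_clusters",
    "n_periods",
    "cluster_size",
    "btw_clust_var",
    "icc",
    "indiv_var",
    "at_risk_params",
    "period_effect",
    "period_var",
    "estimation_function",
    "master_seed",
}
_EXTRA_ALIASES = {
    "at_risk": "at_risk_params",
    "seed": "master_seed",
    "clust_size": "cluster_size",
}
_REQUIRED = (
    "family",
    "effect_size",
    "n_clusters",
    "n_periods",
    "cluster_size",
    "period_effect",
)
_DEFAULTS = {"alpha": 0.05, "period_var": 0.0, "n_sim": 1000, "master_seed": 0}
_FAMILIES = ("gaussian", "binomial", "poisson")

# family -> (required keys, forbidden keys); gaussian variance keys are
# checked separately (two of three must be present)
_FAMILY_KEYS = {
    "gaussian": ((), ("at_risk_params",)),
    "binomial": (("btw_clust_var",), ("icc", "indiv_var", "at_risk_params")),
    "poisson": (("btw_clust_var", "at_risk_params"), ("icc", "indiv_var")),
}


def _canonical(key: str) -> str:
    k = str(key).strip().lower().replace("-", "_").replace(".", "_")
    return _EXTRA_ALIASES.get(k, k)


@dataclass(frozen=True)
class RunConfig:
    """One fully resolved power-simulation configuration."""

    family: str
    effect_size: float
    n_clusters: int
    n_periods: int
    cluster_size: Any
    period_effect: Any
    n_sim: int = 1000
    alpha: float = 0.05
    period_var: float = 0.0
    btw_clust_var: float | None = None
    icc: float | None = None
    indiv_var: float | None = None
    at_risk_params: Any = None
    estimation_function: str | None = None
    master_seed: int = 0
    defaulted: tuple[str, ...] = field(default=(), repr=False, compare=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        data: dict[str, Any] = {}
        unknown = []
        for key, value in mapping.items():
            canon = _canonical(key)
            if canon == "defaulted":
                continue
            if canon not in _FIELDS:
                unknown.append(str(key))
                continue
            if canon in data:
                raise ConfigError(f"duplicate key {key!r} (alias collision)")
            data[canon] = value
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

        missing = [k for k in _REQUIRED if data.get(k) is None]
        if missing:
            raise ConfigError(f"missing required keys: {missing}")

        family = str(data["family"]).lower()
        if family not in _FAMILIES:
            raise ConfigError(f"family must be one of {_FAMILIES}, got {family!r}")
        data["family"] = family

        defaulted = []
        for key, default in _DEFAULTS.items():
            if data.get(key) is None:
                data[key] = default
                defaulted.append(key)
        if defaulted:
            logger.info("config defaults applied: %s",
                        {k: _DEFAULTS[k] for k in defaulted})

        required, forbidden = _FAMILY_KEYS[family]
        for key in required:
            if data.get(key) is None:
                raise ConfigError(f"family {family!r} requires {key!r}")
        present_forbidden = [k for k in forbidden if data.get(k) is not None]
        if present_forbidden:
            raise ConfigError(
                f"keys {present_forbidden} are not applicable to family {family!r}"
            )
        if family == "gaussian":
            var_keys = ("btw_clust_var", "indiv_var", "icc")
            n_var = sum(data.get(k) is not None for k in var_keys)
            if n_var < 2:
                raise ConfigError(
                    "gaussian family needs two of btw_clust_var, indiv_var, icc"
                )
            try:  # validates consistency when all three are given
                complete_variances(
                    data.get("btw_clust_var"), data.get("indiv_var"), data.get("icc")
                )
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

        cfg = cls(**data, defaulted=tuple(defaulted))
        cfg._basic_checks()
        return cfg

    def _basic_checks(self) -> None:
        if self.n_sim < 1:
            raise ConfigError("n_sim must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        if self.n_periods < 1:
            raise ConfigError("n_periods must be >= 1")
        if self.period_var < 0:
            raise ConfigError("period_var must be >= 0")
        if self.master_seed < 0:
            raise ConfigError("master_seed must be a non-negative integer")
        if self.estimation_function is not None:
            from .estimators import available_estimators

            if self.estimation_function not in available_estimators():
                raise ConfigError(
                    f"unknown estimation_function {self.estimation_function!r}; "
                    f"available: {available_estimators()}"
                )

    def to_dict(self) -> dict[str, Any]:
        """Plain-dict form (resolved defaults included, JSON/YAML friendly)."""
        def _plain(v):
            if isinstance(v, (list, tuple)):
                return [_plain(x) for x in v]
            if hasattr(v, "item"):
                return v.item()
            return v

        out = {
            k: _plain(getattr(self, k))
            for k in sorted(_FIELDS)
            if getattr(self, k) is not None
        }
        return out

    def replace(self, **overrides) -> "RunConfig":
        """Return a re-validated copy with the given keys overridden."""
        merged = self.to_dict()
        merged.update(overrides)
        return RunConfig.from_mapping(merged)

    def resolved_estimator(self) -> str:
        """Estimator label, defaulting by design: cluster fixed effects for
        crossover designs, the single-period analysis otherwise."""
        if self.estimation_function is not None:
            return self.estimation_function
        return "cluster_fixed" if self.n_periods >= 2 else "single_period"

    def build(self) -> tuple[TrialDesign, Any]:
        """Materialize the trial design and data-generating parameters."""
        try:
            design = make_design(self.n_clusters, self.n_periods, self.cluster_size)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        pe = self.period_effect
        if isinstance(pe, (list, tuple)):
            pe = [float(v) for v in pe]
        if self.family == "gaussian":
            spec = complete_variances(self.btw_clust_var, self.indiv_var, self.icc)
            params = GaussianParams(pe, float(self.effect_size), spec, self.period_var)
        elif self.family == "binomial":
            params = BinomialParams(
                pe, float(self.effect_size), float(self.btw_clust_var), self.period_var
            )
        else:
            params = PoissonParams(
                pe,
                float(self.effect_size),
                float(self.btw_clust_var),
                self.at_risk_params,
                self.period_var,
            )
        return design, params


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Load and validate a configuration from YAML/JSON or a mapping.

    File format is chosen by suffix: ``.json`` is parsed as JSON, anything
    else through the YAML loader (which also accepts JSON documents).
    """
    if isinstance(source, Mapping):
        return RunConfig.from_mapping(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    return RunConfig.from_mapping(doc)
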