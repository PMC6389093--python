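"""Config-driven logistic classifier for TIA/minor stroke vs mimic.

The triage system's diagnostic component is a logistic regression model
over form checkboxes: ``lp = intercept + Σ βᵢ·xᵢ + Σ γⱼ·xₐ·x_b`` and
``p = 1 / (1 + exp(-lp))``.  The production model this mirrors has 50
main effects and 12 pairwise interaction terms (31 and 8 with positive
coefficients); its fitted coefficients are not public, so the model here
is entirely configuration-driven and the package bundles a synthetic
example with the same structure, suitable only for simulation and tests,
never for clinical use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from scipy.special import expit

from . import features as _features
from .referrals import Referral

EXPECTED_MAIN_EFFECTS = 50
EXPECTED_INTERACTIONS = 12


class ModelError(ValueError):
    """Invalid classifier configuration."""


class EncodingError(ValueError):
    """A referral carries a value a codebook rule cannot encode."""


class StructureWarning(UserWarning):
    """Model term counts differ from the expected 50/12 structure."""


@dataclass(frozen=True)
class TiaProbability:
    p: float
    linear_predictor: float


@dataclass(frozen=True)
class ClassifierModel:
    """Intercept plus ordered main-effect and interaction coefficients.

    ``feature_codebook`` maps each feature to its encoding rule:
    ``"binary"`` (checkbox; absent = 0) or ``"real"`` (numeric referral
    attribute such as ``age_years``).
    """

    intercept: float
    main_effects: dict[str, float]
    interactions: dict[tuple[str, str], float]
    feature_codebook: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.main_effects) | set(self.feature_codebook)
        for pair in self.interactions:
            for name in pair:
                if name not in known:
                    raise ModelError(
                        f"interaction term references undeclared feature {name!r}"
                    )
        for name, coef in list(self.main_effects.items()) + [
            (f"{a}:{b}", c) for (a, b), c in self.interactions.items()
        ]:
            if not isinstance(coef, (int, float)) or not math.isfinite(coef):
                raise ModelError(f"non-numeric coefficient for {name!r}: {coef!r}")
        if len(self.main_effects) != EXPECTED_MAIN_EFFECTS or (
            len(self.interactions) != EXPECTED_INTERACTIONS
        ):
            warnings.warn(
                f"model has {len(self.main_effects)} main effects and "
                f"{len(self.interactions)} interactions (expected "
                f"{EXPECTED_MAIN_EFFECTS}/{EXPECTED_INTERACTIONS})",
                StructureWarning,
                stacklevel=3,
            )

    def audit(self) -> dict[str, int]:
        """Structural counts for checking a loaded model's shape."""
        return {
            "main_effects": len(self.main_effects),
            "interactions": len(self.interactions),
            "positive_main_effects": sum(1 for c in self.main_effects.values() if c > 0),
            "positive_interactions": sum(1 for c in self.interactions.values() if c > 0),
        }


def load_model(source: str | Path | dict) -> ClassifierModel:
    """Load a classifier from a YAML file (or an equivalent dict).

    Schema::

        intercept: <float>
        main_effects: {feature: coefficient, ...}
        interactions:
          - {features: [a, b], coefficient: <float>}
        codebook: {feature: binary|real, ...}   # optional; default binary
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            config = yaml.safe_load(fh)
    else:
        config = source
    try:
        intercept = float(config["intercept"])
        mains = {str(k): float(v) for k, v in config["main_effects"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelError(f"invalid classifier config: {exc}") from exc
    interactions: dict[tuple[str, str], float] = {}
    for term in config.get("interactions") or []:
        a, b = term["features"]
        interactions[(str(a), str(b))] = float(term["coefficient"])
    codebook = {str(k): str(v) for k, v in (config.get("codebook") or {}).items()}
    if not codebook:
        codebook = {name: "binary" for name in mains}
    for name, rule in codebook.items():
        if rule not in ("binary", "real"):
            raise ModelError(f"unknown codebook rule {rule!r} for feature {name!r}")
    return ClassifierModel(
        intercept=intercept,
        main_effects=mains,
        interactions=interactions,
        feature_codebook=codebook,
    )


def _encode(model: ClassifierModel, referral: Referral, name: str) -> float:
    rule = model.feature_codebook.get(name, "binary")
    if rule == "binary":
        value = referral.symptoms.get(name, 0)
        if value not in (0, 1):
            raise EncodingError(f"feature {name!r}: non-binary value {value!r}")
        return float(value)
    value = getattr(referral, name, None)
    if value is None or not isinstance(value, (int, float)):
        raise EncodingError(f"feature {name!r}: non-encodable value {value!r}")
    return float(value)


def predict_probability(model: ClassifierModel, referral: Referral) -> TiaProbability:
    """Probability that the referral is a true TIA/minor stroke.

    Absent checkboxes encode as 0 (fax semantics: unchecked means not
    reported).  The logistic link is evaluated with a numerically stable
    sigmoid, so extreme linear predictors saturate instead of overflowing.
    """
    x = {name: _encode(model, referral, name) for name in model.feature_codebook}
    for name in model.main_effects:
        if name not in x:
            x[name] = _encode(model, referral, name)
    lp = model.intercept
    lp += sum(coef * x[name] for name, coef in model.main_effects.items())
    lp += sum(coef * x[a] * x[b] for (a, b), coef in model.interactions.items())
    return TiaProbability(p=float(expit(lp)), linear_predictor=lp)


def example_model(prevalence: float = 0.58) -> ClassifierModel:
    """The bundled synthetic example classifier (non-clinical).

    Coefficients are naive-Bayes log odds ratios derived from the
    synthetic symptom rates in :mod:`tiatriage.features`, with the
    intercept calibrated to the given TIA prevalence; by construction the
    model has 50 main effects (31 positive) and 12 interactions
    (8 positive).
    """
    mains: dict[str, float] = {}
    intercept = math.log(prevalence / (1.0 - prevalence))
    for name, (p_tia, p_mimic) in _features.SYMPTOM_RATES.items():
        mains[name] = math.log(p_tia * (1 - p_mimic) / (p_mimic * (1 - p_tia)))
        intercept += math.log((1 - p_tia) / (1 - p_mimic))
    return ClassifierModel(
        intercept=intercept,
        main_effects=mains,
        interactions=dict(_features.INTERACTION_COEFFICIENTS),
        feature_codebook={name: "binary" for name in mains},
    )


def write_example_model(path: str | Path, prevalence: float = 0.58) -> None:
    """Write the synthetic example classifier as a YAML config file."""
    model = example_model(prevalence)
    config = {
        "description": (
            "Synthetic example TIA/mimic classifier for simulation and "
            "testing only; not fitted to clinical data."
        ),
        "intercept": model.intercept,
        "main_effects": dict(model.main_effects),
        "interactions": [
            {"features": list(pair), "coefficient": coef}
            for pair, coef in model.interactions.items()
        ],
        "codebook": dict(model.feature_codebook),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
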