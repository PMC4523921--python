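"""Linear binding-affinity models and ΔG ↔ K_d conversion.

Every predictor here is a linear combination of structural properties of
a complex,

    ΔG_calc = Σ_N w_N · P_N + Q,

where the P_N are interfacial contact counts per pair-class (``ICs_*``),
buried-surface areas (``BSA_*``) and non-interacting-surface composition
percentages (``%NIS_*``). The published weights produce a *positive*
number, the magnitude of the binding free energy in kcal/mol; the
physical (favourable) ΔG is its negation. Six fixed models are shipped:

* model1 — total contacts only
* model2 — total BSA only
* model3 — contacts split by polarity pair-class (AIC-selected terms)
* model4 — contacts split by hydropathy pair-class
* model5 — BSA split into polar/apolar (Horton–Lewis style, re-trained)
* model6 — polarity contacts + NIS composition; the final predictor

Dissociation constants follow ΔG = RT ln K_d with
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ (default T = 298.15 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PROPERTY_NAMES", "GAS_CONSTANT", "DEFAULT_TEMPERATURE",
    "LinearAffinityModel", "AffinityPrediction", "builtin_model",
    "BUILTIN_MODELS", "predict_affinity", "dg_to_kd", "kd_to_dg",
]

GAS_CONSTANT = 1.987e-3       # kcal · mol⁻¹ · K⁻¹
DEFAULT_TEMPERATURE = 298.15  # K

#: The property vocabulary models may draw terms from.
PROPERTY_NAMES: tuple[str, ...] = (
    "ICs_total",
    "ICs_charged/charged", "ICs_charged/polar", "ICs_charged/apolar",
    "ICs_polar/polar", "ICs_polar/apolar", "ICs_apolar/apolar",
    "ICs_hydrophilic/hydrophilic", "ICs_hydrophilic/hydrophobic",
    "ICs_hydrophobic/hydrophilic", "ICs_hydrophobic/hydrophobic",
    "BSA_total", "BSA_polar", "BSA_apolar",
    "%NIS_polar", "%NIS_apolar", "%NIS_charged",
)


class LinearAffinityModel(RegressorMixin, BaseEstimator):
    """A linear affinity predictor with explicit named terms.

    This estimator is "pre-fitted" at construction: ``terms`` maps
    property names to weights and ``intercept`` is the shift Q in
    kcal/mol. ``fit`` only validates and freezes the coefficients into
    the sklearn-conventional fitted attributes, so instances compose
    with sklearn tooling; the training module produces instances of
    this class from data.

    ``predict`` returns |ΔG| (the positive model output); use
    :meth:`predict_dg` for the signed free energy.
    """

    def __init__(self, terms: Mapping[str, float] | None = None,
                 intercept: float = 0.0, name: str = "custom"):
        self.terms = terms
        self.intercept = intercept
        self.name = name

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, X=None, y=None):  # noqa: N803 - sklearn signature
        terms = dict(self.terms or {})
        unknown = [t for t in terms if t not in PROPERTY_NAMES]
        if unknown:
            raise ValueError(f"unknown property name(s): {unknown}")
        self.terms_ = terms
        self.feature_names_in_ = np.asarray(list(terms), dtype=object)
        self.coef_ = np.asarray(list(terms.values()), dtype=float)
        self.intercept_ = float(self.intercept)
        self.n_features_in_ = len(terms)
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "terms_"):
            self.fit()

    # -- evaluation -------------------------------------------------------
    def evaluate(self, properties: Mapping[str, float]) -> float:
        """|ΔG| in kcal/mol for one property mapping."""
        self._ensure_fitted()
        total = self.intercept_
        for term, weight in self.terms_.items():
            if term not in properties:
                raise KeyError(
                    f"model {self.name!r} requires property {term!r}")
            total += weight * float(properties[term])
        return total

    def predict(self, X) -> np.ndarray:  # noqa: N803
        """|ΔG| for a DataFrame / list of property mappings."""
        self._ensure_fitted()
        if hasattr(X, "iterrows"):  # DataFrame
            rows = [row for _, row in X.iterrows()]
        else:
            rows = list(X)
        return np.asarray([self.evaluate(r) for r in rows], dtype=float)

    def predict_dg(self, X) -> np.ndarray:  # noqa: N803
        """Signed (negative = favourable) ΔG in kcal/mol."""
        return -self.predict(X)

    def to_dict(self) -> dict:
        self._ensure_fitted()
        return {"name": self.name, "terms": dict(self.terms_),
                "intercept": self.intercept_}


def _model(name: str, terms: dict[str, float], intercept: float
           ) -> LinearAffinityModel:
    return LinearAffinityModel(terms=terms, intercept=intercept,
                               name=name).fit()


#: The six published fixed-coefficient models. Terms dropped by the AIC
#: stepwise selection during the original training simply do not appear.
BUILTIN_MODELS: dict[str, LinearAffinityModel] = {
    "model1": _model("model1", {"ICs_total": 0.07782}, 4.78839),
    "model2": _model("model2", {"BSA_total": 0.00278}, 5.66032),
    "model3": _model("model3", {
        "ICs_charged/apolar": 0.11627,
        "ICs_polar/polar": -0.12655,
        "ICs_polar/apolar": 0.23595,
    }, 5.13766),
    "model4": _model("model4", {
        "ICs_hydrophilic/hydrophilic": 0.09055,
        "ICs_hydrophilic/hydrophobic": 0.05726,
        "ICs_hydrophobic/hydrophilic": 0.06037,
    }, 4.90452),
    "model5": _model("model5", {
        "BSA_polar": 0.00131,
        "BSA_apolar": 0.00400,
    }, 5.44809),
    "model6": _model("model6", {
        "ICs_charged/charged": 0.09459,
        "ICs_charged/apolar": 0.10007,
        "ICs_polar/polar": -0.19577,
        "ICs_polar/apolar": 0.22671,
        "%NIS_apolar": -0.18681,
        "%NIS_charged": -0.13810,
    }, 15.9433),
}


def builtin_model(name: str) -> LinearAffinityModel:
    """Return one of the six published models by name (``model1``…``model6``)."""
    key = name.lower().replace(" ", "").replace("_", "")
    if key not in BUILTIN_MODELS:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(BUILTIN_MODELS)}")
    return BUILTIN_MODELS[key]


def dg_to_kd(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (mol/L) from ΔG (kcal/mol): K_d = exp(ΔG/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg / (GAS_CONSTANT * temperature))


def kd_to_dg(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔG (kcal/mol) from a dissociation constant: ΔG = RT ln K_d."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * temperature * math.log(kd)


@dataclass
class AffinityPrediction:
    """One complex's predicted affinity with its inputs."""

    dg: float                 # kcal/mol, negative = favourable
    kd: float                 # mol/L
    temperature: float
    model_name: str
    properties: dict[str, float] = dc_field(default_factory=dict)

    @property
    def dg_abs(self) -> float:
        return abs(self.dg)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "dg_kcal_mol": self.dg,
            "dg_abs_kcal_mol": self.dg_abs,
            "kd_M": self.kd,
            "temperature_K": self.temperature,
            "properties": dict(self.properties),
        }


def predict_affinity(
    model: LinearAffinityModel | str,
    properties: Mapping[str, float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> AffinityPrediction:
    """Evaluate a model on a property mapping and convert to K_d."""
    if isinstance(model, str):
        model = builtin_model(model)
    dg_abs = model.evaluate(properties)
    dg = -dg_abs
    return AffinityPrediction(
        dg=dg,
        kd=dg_to_kd(dg, temperature),
        temperature=temperature,
        model_name=model.name,
        properties={t: float(properties[t]) for t in model.terms_},
    )
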