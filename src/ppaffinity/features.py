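"""Structure → model-property featurisation.

`compute_properties` runs the full structural pipeline on one complex
(contacts at a cutoff, BSA, NIS composition) and returns the flat
property mapping the affinity models consume. `InterfaceFeaturizer`
wraps it as a sklearn transformer so structures can feed pipelines and
model selection directly.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .contacts import DEFAULT_CUTOFF, compute_contacts, profile_contacts
from .models import PROPERTY_NAMES
from .structure import Structure
from .surface import (
    DEFAULT_N_POINTS,
    DEFAULT_NIS_THRESHOLD,
    DEFAULT_PROBE_RADIUS,
    compute_surface,
)

__all__ = ["compute_properties", "InterfaceFeaturizer"]


def compute_properties(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    nis_threshold: float = DEFAULT_NIS_THRESHOLD,
) -> dict[str, float]:
    """All model properties (ICs_*, BSA_*, %NIS_*) of one complex."""
    contact_set = compute_contacts(structure, cutoff)
    profile = profile_contacts(contact_set, structure)
    surface = compute_surface(structure, contact_set, probe_radius,
                              n_points, nis_threshold)
    props = profile.as_properties()
    props.update(surface.as_properties())
    return {name: props[name] for name in PROPERTY_NAMES}


class InterfaceFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a sequence of :class:`Structure` into a property DataFrame.

    Stateless (fit is a no-op); parameters mirror `compute_properties`.
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_N_POINTS,
                 nis_threshold: float = DEFAULT_NIS_THRESHOLD):
        self.cutoff = cutoff
        self.probe_radius = probe_radius
        self.n_points = n_points
        self.nis_threshold = nis_threshold

    def fit(self, X: Iterable[Structure], y=None):  # noqa: N803
        self.n_features_in_ = len(PROPERTY_NAMES)
        return self

    def transform(self, X: Iterable[Structure]) -> pd.DataFrame:  # noqa: N803
        rows = []
        index = []
        for structure in X:
            rows.append(compute_properties(
                structure, self.cutoff, self.probe_radius,
                self.n_points, self.nis_threshold))
            index.append(structure.name or len(index))
        return pd.DataFrame(rows, index=index, columns=list(PROPERTY_NAMES))

    def get_feature_names_out(self, input_features=None):
        import numpy as np
        return np.asarray(PROPERTY_NAMES, dtype=object)
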