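"""Declarative variable specifications and cohort configuration.

A study variable is described by a :class:`VariableSpec`: its role in the
dataset (demographic, anthropometric, MRI-derived, glycaemic, plasma
biomarker, or categorical), the distribution family it is drawn from, and
per-group parameters *on the modelled scale*.  Plasma biomarkers are
modelled as log10-normal, so their (location, scale) are the mean and SD of
the log10-transformed concentration; the generator emits values on the
natural (back-transformed) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

ROLES = ("demographic", "anthropometric", "mri", "glycaemic", "biomarker", "categorical")
FAMILIES = ("normal", "log10normal", "bernoulli")


class SchemaError(ValueError):
    """A variable spec does not cover a requested group or is malformed."""


@dataclass(frozen=True)
class VariableSpec:
    """One study variable: role, distribution family and per-group parameters.

    ``params_by_group`` maps a group label to ``(location, scale)`` for the
    continuous families (log10 scale for ``log10normal``) or to a single
    success probability for ``bernoulli``.
    """

    name: str
    role: str
    family: str
    params_by_group: Mapping[str, tuple]
    unit: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.family not in FAMILIES:
            raise SchemaError(f"{self.name}: unknown family {self.family!r}")
        for group, params in self.params_by_group.items():
            if self.family == "bernoulli":
                p = float(params if np.isscalar(params) else params[0])
                if not 0.0 <= p <= 1.0:
                    raise SchemaError(
                        f"{self.name}: bernoulli probability {p} for group "
                        f"{group!r} outside [0, 1]"
                    )
            else:
                loc, scale = params
                if not np.isfinite(loc) or not np.isfinite(scale):
                    raise SchemaError(f"{self.name}: non-finite parameters for {group!r}")
                if scale < 0:
                    raise SchemaError(
                        f"{self.name}: negative scale {scale} for group {group!r}"
                    )

    def params_for(self, group: str) -> tuple:
        try:
            return self.params_by_group[group]
        except KeyError:
            raise SchemaError(
                f"variable {self.name!r} has no parameters for group {group!r}"
            ) from None

    @property
    def is_continuous(self) -> bool:
        return self.family in ("normal", "log10normal")


@dataclass
class CohortConfig:
    """Sizes, dependence structure and perturbations for cohort generation.

    ``arm_effects`` maps ``(arm, variable)`` to an additive shift applied at
    follow-up on the modelled scale (log10 scale for log10-normal
    variables).  ``within_subject_corr`` is the pre/post correlation of each
    continuous variable on the modelled scale.  ``cross_corr`` optionally
    imposes a correlation matrix across a subset of continuous variables
    (Gaussian copula on the modelled scale); by default variables are
    mutually independent.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 36, "t2d": 83}
    )
    arm_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"standard_care": 30, "mrp": 24, "exercise": 22}
    )
    within_subject_corr: float = 0.7
    arm_effects: Mapping[tuple, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0
    cross_corr: Optional[tuple] = None  # (list of variable names, corr matrix)

    def __post_init__(self):
        for label, n in {**self.group_sizes, **self.arm_sizes}.items():
            if n < 0:
                raise ValueError(f"negative count {n} for {label!r}")
        if abs(self.within_subject_corr) > 1:
            raise ValueError(f"|within_subject_corr| > 1: {self.within_subject_corr}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1): {self.missing_rate}")
        if self.cross_corr is not None:
            names, mat = self.cross_corr
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(names), len(names)):
                raise ValueError("cross_corr matrix shape does not match names")
            if not np.allclose(mat, mat.T):
                raise ValueError("cross_corr matrix must be symmetric")


def validate_specs(specs: Sequence[VariableSpec], groups: Sequence[str]) -> None:
    """Check every spec covers every group label; raise SchemaError if not."""
    seen = set()
    for spec in specs:
        if spec.name in seen:
            raise SchemaError(f"duplicate variable name {spec.name!r}")
        seen.add(spec.name)
        for g in groups:
            spec.params_for(g)
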