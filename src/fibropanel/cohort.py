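"""Synthetic cohort generation.

Generates subject-level case–control and three-arm pre/post RCT tables with
the distributional structure the downstream analysis assumes: independent
normal / log10-normal / bernoulli variables with per-group parameters,
bivariate-Gaussian within-subject dependence for pre/post pairs, additive
arm effects at follow-up, and MCAR missingness injected cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .variables import CohortConfig, SchemaError, VariableSpec, validate_specs

LABEL_COLUMNS = ("subject_id", "group", "arm", "timepoint")
BASELINE = "baseline"
FOLLOW_UP = "follow_up"


@dataclass
class CohortTable:
    """Tidy subject-level table plus a per-column schema.

    One row per subject (case–control) or per subject × timepoint (RCT).
    Missing values are NaN, distinguishable from zero.  ``schema`` maps each
    variable name to its role, family and unit.
    """

    data: pd.DataFrame
    schema: Dict[str, dict] = field(default_factory=dict)

    @property
    def variables(self) -> List[str]:
        return list(self.schema.keys())

    def continuous_variables(self) -> List[str]:
        return [n for n, m in self.schema.items() if m["family"] != "bernoulli"]

    def variables_by_role(self, *roles: str) -> List[str]:
        return [n for n, m in self.schema.items() if m["role"] in roles]

    def validate(self) -> None:
        cols = set(self.data.columns)
        expected = set(LABEL_COLUMNS) | set(self.schema)
        if cols != expected:
            missing = expected - cols
            extra = cols - expected
            raise SchemaError(
                f"column set mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        if self.data[["subject_id", "timepoint"]].duplicated().any():
            raise SchemaError("duplicate (subject, timepoint) rows")
        for col in LABEL_COLUMNS:
            if self.data[col].isna().any() and col != "arm":
                raise SchemaError(f"label column {col!r} contains missing values")

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), {k: dict(v) for k, v in self.schema.items()})


def _schema_from_specs(specs: Sequence[VariableSpec]) -> Dict[str, dict]:
    return {
        s.name: {"role": s.role, "family": s.family, "unit": s.unit} for s in specs
    }


def _draw_standard_normals(
    rng: np.random.Generator,
    specs: Sequence[VariableSpec],
    n: int,
    cross_corr: Optional[tuple],
) -> Dict[str, np.ndarray]:
    """Standard-normal draws per continuous variable, optionally correlated.

    Variables named in ``cross_corr`` are drawn jointly via the Cholesky
    factor of the requested correlation matrix; all others independently.
    """
    cont = [s.name for s in specs if s.is_continuous]
    z: Dict[str, np.ndarray] = {}
    corr_names: List[str] = []
    if cross_corr is not None:
        corr_names, mat = cross_corr
        unknown = [c for c in corr_names if c not in cont]
        if unknown:
            raise SchemaError(f"cross_corr names not continuous variables: {unknown}")
        chol = np.linalg.cholesky(np.asarray(mat, dtype=float))
        joint = rng.standard_normal((n, len(corr_names))) @ chol.T
        for j, name in enumerate(corr_names):
            z[name] = joint[:, j]
    for name in cont:
        if name not in z:
            z[name] = rng.standard_normal(n)
    return z


def _emit(spec: VariableSpec, group: str, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map standard-normal draws (or fresh uniforms for bernoulli) to values."""
    params = spec.params_for(group)
    if spec.family == "bernoulli":
        p = float(params if np.isscalar(params) else params[0])
        return (rng.random(z.shape[0]) < p).astype(float)
    loc, scale = params
    modelled = loc + scale * z
    if spec.family == "log10normal":
        return np.power(10.0, modelled)
    return modelled


def generate_case_control(
    specs: Sequence[VariableSpec], config: CohortConfig
) -> CohortTable:
    """Draw one row per subject for each group in ``config.group_sizes``.

    Continuous variables are sampled from the declared family with the
    declared per-group parameters; log10-normal variables are emitted on the
    natural (back-transformed) scale.  Identical (specs, config, seed) give
    bit-identical tables.
    """
    groups = list(config.group_sizes.keys())
    validate_specs(specs, groups)
    rng = np.random.default_rng(config.seed)

    frames = []
    offset = 0
    for group in groups:
        n = int(config.group_sizes[group])
        z = _draw_standard_normals(rng, specs, n, config.cross_corr)
        cols = {
            "subject_id": [f"S{offset + i:04d}" for i in range(n)],
            "group": [group] * n,
            "arm": [np.nan] * n,
            "timepoint": [BASELINE] * n,
        }
        for spec in specs:
            zv = z[spec.name] if spec.is_continuous else np.empty(n)
            cols[spec.name] = _emit(spec, group, zv, rng)
        frames.append(pd.DataFrame(cols))
        offset += n

    table = CohortTable(pd.concat(frames, ignore_index=True), _schema_from_specs(specs))
    table.validate()
    return table


def generate_rct(
    specs: Sequence[VariableSpec],
    config: CohortConfig,
    baseline_group: str = "t2d",
) -> CohortTable:
    """Three-arm pre/post cohort: two rows (baseline, follow-up) per subject.

    Baseline values are drawn from the ``baseline_group`` parameters.  Each
    continuous variable's follow-up is a correlated Gaussian draw on the
    modelled scale (correlation ``within_subject_corr`` with baseline) plus
    the configured additive arm effect.  Categorical variables are carried
    forward unchanged.
    """
    validate_specs(specs, [baseline_group])
    names = {s.name for s in specs}
    for (arm, var) in config.arm_effects:
        if arm not in config.arm_sizes:
            raise ValueError(f"arm_effects references unknown arm {arm!r}")
        if var not in names:
            raise SchemaError(f"arm_effects references unknown variable {var!r}")

    rho = float(config.within_subject_corr)
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for arm, n in config.arm_sizes.items():
        n = int(n)
        z1 = _draw_standard_normals(rng, specs, n, config.cross_corr)
        eps = _draw_standard_normals(rng, specs, n, config.cross_corr)
        ids = [f"R{offset + i:04d}" for i in range(n)]
        base_cols = {
            "subject_id": ids,
            "group": [baseline_group] * n,
            "arm": [arm] * n,
            "timepoint": [BASELINE] * n,
        }
        post_cols = {
            "subject_id": ids,
            "group": [baseline_group] * n,
            "arm": [arm] * n,
            "timepoint": [FOLLOW_UP] * n,
        }
        for spec in specs:
            if spec.family == "bernoulli":
                values = _emit(spec, baseline_group, np.empty(n), rng)
                base_cols[spec.name] = values
                post_cols[spec.name] = values.copy()
                continue
            loc, scale = spec.params_for(baseline_group)
            zb = z1[spec.name]
            zf = rho * zb + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps[spec.name]
            shift = config.arm_effects.get((arm, spec.name), 0.0)
            base_mod = loc + scale * zb
            post_mod = loc + scale * zf + shift
            if spec.family == "log10normal":
                base_cols[spec.name] = np.power(10.0, base_mod)
                post_cols[spec.name] = np.power(10.0, post_mod)
            else:
                base_cols[spec.name] = base_mod
                post_cols[spec.name] = post_mod
        frames.append(pd.DataFrame(base_cols))
        frames.append(pd.DataFrame(post_cols))
        offset += n

    table = CohortTable(pd.concat(frames, ignore_index=True), _schema_from_specs(specs))
    table.validate()
    return table


@dataclass
class MissingnessMask:
    """Boolean mask of injected missing cells plus the masked-out values."""

    mask: pd.DataFrame  # bool, same index as the table, eligible columns
    original: pd.DataFrame  # original values at masked positions (NaN elsewhere)

    @property
    def n_masked(self) -> int:
        return int(self.mask.to_numpy().sum())


def inject_missingness(
    table: CohortTable,
    rate: float,
    seed: int,
    columns: Optional[Sequence[str]] = None,
) -> tuple:
    """Mask each eligible cell independently with probability ``rate`` (MCAR).

    Label columns are never masked.  Returns ``(masked_table, mask)`` where
    the mask records positions and original values so imputation error can
    be scored and the original table restored exactly.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1): {rate}")
    if columns is None:
        columns = table.continuous_variables()
    else:
        bad = [c for c in columns if c in LABEL_COLUMNS or c not in table.schema]
        if bad:
            raise ValueError(f"columns not maskable: {bad}")
        noncont = [c for c in columns if table.schema[c]["family"] == "bernoulli"]
        if noncont:
            raise ValueError(f"only continuous variables may be masked: {noncont}")

    out = table.copy()
    rng = np.random.default_rng(seed)
    block = out.data[list(columns)]
    mask = pd.DataFrame(
        rng.random(block.shape) < rate, index=block.index, columns=block.columns
    )
    original = block.where(mask)
    out.data[list(columns)] = block.mask(mask)
    return out, MissingnessMask(mask=mask, original=original)


def restore_masked(table: CohortTable, mask: MissingnessMask) -> CohortTable:
    """Undo :func:`inject_missingness`: put masked-out values back."""
    out = table.copy()
    cols = list(mask.mask.columns)
    block = out.data[cols]
    out.data[cols] = block.where(~mask.mask, mask.original)
    return out
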