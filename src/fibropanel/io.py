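"""Cohort file round-tripping, run configuration and the end-to-end report.

Cohorts are exchanged as UTF-8 comma-separated CSV (empty field = missing)
with a JSON sidecar schema naming role, family and unit per column.  The
``run_report`` orchestrator runs the whole pipeline in order — simulate (or
load), log10-transform biomarkers, standardize, impute, compare groups,
embed — and writes every artifact with the seed and a config hash in its
metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import catalog
from .cohort import (
    BASELINE,
    FOLLOW_UP,
    LABEL_COLUMNS,
    CohortTable,
    generate_case_control,
    generate_rct,
    inject_missingness,
)
from .prep import apply_standardizer, fit_standardizer, knn_impute, log10_transform
from .stats import (
    classify_remission,
    compare_case_control,
    convert_hba1c,
    prepost_change_model,
    results_to_frame,
)
from .variables import CohortConfig, SchemaError
from .views import best_fit_plane, fisher_plane, pca_svd

logger = logging.getLogger("fibropanel")


def write_cohort(table: CohortTable, csv_path, schema_path) -> None:
    table.data.to_csv(csv_path, index=False, na_rep="")
    with open(schema_path, "w") as fh:
        json.dump(table.schema, fh, indent=1)


def read_cohort(csv_path, schema_path) -> CohortTable:
    """Load a cohort CSV against its JSON schema; validate the column set."""
    with open(schema_path) as fh:
        schema = json.load(fh)
    df = pd.read_csv(csv_path, dtype={"subject_id": str})
    expected = list(LABEL_COLUMNS) + list(schema)
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"header/schema mismatch: missing columns {missing}, unexpected {extra}"
        )
    for name in schema:
        if not pd.api.types.is_numeric_dtype(df[name]):
            bad = df[name][pd.to_numeric(df[name], errors="coerce").isna() & df[name].notna()]
            loc = bad.index[0] if len(bad) else "?"
            raise SchemaError(f"non-numeric cell in numeric column {name!r} at row {loc}")
    table = CohortTable(df, schema)
    table.validate()
    logger.info("read %d rows × %d variables from %s", len(df), len(schema), csv_path)
    return table


@dataclass
class RunConfig:
    """Everything a report run needs, serializable for the run log."""

    seed: int = 0
    out_dir: str = "results/report"
    cohort_csv: Optional[str] = None  # load instead of simulating when set
    cohort_schema: Optional[str] = None
    variable_set: str = "full"  # or "biomarkers_demographics"
    normality_flags: Dict[str, str] = field(default_factory=dict)
    knn_k: int = 5
    ridge: Optional[float] = None  # None -> 1e-3 * trace(S_w)/p
    within_subject_corr: float = 0.7
    missing_rate: float = 0.05
    make_figures: bool = True

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def select_variables(table: CohortTable, variable_set: str) -> List[str]:
    """Variable subsets used by the visualizations.

    ``full``: every schema variable.  ``biomarkers_demographics``: the
    sensitivity set — plasma biomarkers plus key demographics only.
    """
    if variable_set == "full":
        return table.variables
    if variable_set == "biomarkers_demographics":
        return table.variables_by_role("biomarker", "demographic", "categorical")
    raise ValueError(f"unknown variable set {variable_set!r}")


def analysis_matrix(
    table: CohortTable,
    variables: Optional[Sequence[str]] = None,
    k: int = 5,
    standardizer=None,
) -> Tuple[pd.DataFrame, object, object]:
    """Numeric analysis matrix: log10 biomarkers → z-standardize → kNN-impute.

    Returns (complete standardized matrix, standardizer, imputation report).
    A pre-fitted standardizer can be supplied to place new rows in an
    existing standardized space.
    """
    variables = list(variables) if variables is not None else table.variables
    X = table.data[variables].astype(float).copy()
    for name in variables:
        if table.schema[name]["family"] == "log10normal":
            X[name] = log10_transform(X[name])
    if standardizer is None:
        standardizer = fit_standardizer(X)
    Z = apply_standardizer(standardizer, X)
    report = None
    if Z.isna().any().any():
        Z, report = knn_impute(Z, k=k)
    return Z, standardizer, report


def _json_dump(obj, path, meta):
    with open(path, "w") as fh:
        json.dump({"meta": meta, **obj}, fh, indent=1)


def _pca_figure(emb, labels, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    lab = np.asarray(labels)
    for g, color in zip(pd.unique(lab), ("tab:blue", "tab:red", "tab:green")):
        pts = emb.scores[lab == g]
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=12, alpha=0.7, label=str(g), color=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fisher_figure(res, arm, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(res.coords_pre[:, 0], res.coords_pre[:, 1], s=16, label="pre", color="tab:red")
    ax.scatter(res.coords_post[:, 0], res.coords_post[:, 1], s=16, label="post", color="tab:green")
    for c, name, col in (
        (res.center_pre, "pre center", "darkred"),
        (res.center_post, "post center", "darkgreen"),
        (res.center_healthy, "healthy center", "navy"),
    ):
        ax.scatter([c[0]], [c[1]], marker="*", s=160, color=col, label=name)
    ax.axvline(res.threshold, ls="--", lw=1, color="gray")
    ax.set_xlabel("Fisher axis u")
    ax.set_ylabel("healthy-anchor axis v")
    ax.set_title(f"{arm}: accuracy {res.accuracy:.2f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def simulate_default_cohorts(seed: int, missing_rate: float = 0.0, rho: float = 0.7):
    """Default case–control and RCT cohorts from the published parameters."""
    specs = catalog.default_specs()
    cc_cfg = CohortConfig(seed=seed, within_subject_corr=rho)
    cc = generate_case_control(specs, cc_cfg)
    rct_cfg = CohortConfig(
        seed=seed + 1,
        within_subject_corr=rho,
        arm_effects=catalog.default_arm_effects(),
    )
    rct = generate_rct(specs, rct_cfg)
    masks = {}
    if missing_rate > 0:
        biom = [s.name for s in specs if s.role == "biomarker"]
        cc, masks["case_control"] = inject_missingness(cc, missing_rate, seed + 2, biom)
        rct, masks["rct"] = inject_missingness(rct, missing_rate, seed + 3, biom)
    return cc, rct, masks


def arm_fisher_view(
    cc: CohortTable,
    rct: CohortTable,
    arm: str,
    variables: Optional[Sequence[str]] = None,
    k: int = 5,
    ridge: Optional[float] = None,
):
    """Fisher plane for one arm: healthy controls anchor, pre vs post rows.

    Healthy-control rows and the arm's baseline/follow-up rows are placed in
    one jointly standardized space (fit over all three row blocks), imputed
    if needed, then projected.
    """
    healthy = cc.data[cc.data["group"] == catalog.CONTROL]
    pre = rct.data[(rct.data["arm"] == arm) & (rct.data["timepoint"] == BASELINE)]
    post = rct.data[(rct.data["arm"] == arm) & (rct.data["timepoint"] == FOLLOW_UP)]
    if len(pre) == 0:
        raise ValueError(f"no rows for arm {arm!r}")
    combined = CohortTable(
        pd.concat([healthy, pre, post], ignore_index=True), rct.schema
    )
    Z, _, _ = analysis_matrix(combined, variables, k=k)
    nh, npre = len(healthy), len(pre)
    Zh = Z.iloc[:nh].to_numpy()
    Zpre = Z.iloc[nh : nh + npre].to_numpy()
    Zpost = Z.iloc[nh + npre :].to_numpy()
    return fisher_plane(Zpre, Zpost, Zh.mean(axis=0), ridge=ridge)


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle under ``out_dir``.

    Deterministic given the config seed; every artifact records the seed and
    config hash.  Returns a manifest of written paths and headline numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "knn_k": config.knn_k,
        "ridge": config.ridge if config.ridge is not None else "1e-3*trace(Sw)/p",
        "variable_set": config.variable_set,
    }

    if config.cohort_csv:
        cc = read_cohort(config.cohort_csv, config.cohort_schema)
        _, rct, _ = simulate_default_cohorts(config.seed, config.missing_rate,
                                             config.within_subject_corr)
    else:
        cc, rct, _ = simulate_default_cohorts(
            config.seed, config.missing_rate, config.within_subject_corr
        )
    write_cohort(cc, out / "case_control.csv", out / "case_control.schema.json")
    write_cohort(rct, out / "rct.csv", out / "rct.schema.json")

    variables = select_variables(cc, config.variable_set)

    # --- case-control comparisons (biomarkers on the log10 scale) ---
    biomarkers = cc.variables_by_role("biomarker")
    cc_log = cc.copy()
    for b in biomarkers:
        cc_log.data[b] = log10_transform(cc_log.data[b])
    flags = {b: "parametric" for b in biomarkers}  # log10 scale is the modelled scale
    flags.update(config.normality_flags)
    comparisons = compare_case_control(cc_log, flags=flags)
    results_to_frame(comparisons).to_csv(out / "case_control_comparisons.csv", index=False)

    # --- PCA view ---
    Z, standardizer, imp_report = analysis_matrix(cc, variables, k=config.knn_k)
    emb = pca_svd(Z, n_components=3, labels=cc.data["group"])
    plane = best_fit_plane(emb.scores)
    _json_dump(
        {
            **emb.to_dict(),
            "best_fit_plane": {
                "point": plane.point.tolist(),
                "normal": plane.normal.tolist(),
            },
            "dropped_columns": standardizer.dropped,
        },
        out / "pca_embedding.json",
        meta,
    )
    if imp_report is not None:
        _json_dump(imp_report.to_dict(), out / "imputation_report.json", meta)

    # --- change models per arm × biomarker × model ---
    rows = []
    m = len(biomarkers)
    for arm in rct.data["arm"].dropna().unique():
        arm_n = (rct.data["arm"] == arm).sum() // 2
        for model_id in (1, 2, 3):
            for b in biomarkers:
                try:
                    res = prepost_change_model(rct, b, model_id, arm=arm, m=m)
                except ValueError:
                    continue
                row = res.to_row()
                row["arm"] = arm
                row["n_pairs"] = int(arm_n)
                rows.append(row)
    pd.DataFrame(rows).to_csv(out / "change_models.csv", index=False)

    # --- Fisher plane per arm ---
    fisher = {}
    for arm in rct.data["arm"].dropna().unique():
        res = arm_fisher_view(cc, rct, arm, variables, k=config.knn_k, ridge=config.ridge)
        fisher[str(arm)] = res
        _json_dump(res.to_dict(), out / f"fisher_{arm}.json", meta)
        if config.make_figures:
            _fisher_figure(res, arm, out / f"fisher_{arm}.png")
    if config.make_figures:
        _pca_figure(emb, cc.data["group"], out / "pca_view.png")

    # --- remission at follow-up (meal-replacement arm headline) ---
    follow = rct.data[rct.data["timepoint"] == FOLLOW_UP]
    remission = {}
    for arm in follow["arm"].unique():
        sub = follow[follow["arm"] == arm]
        flags_r = classify_remission(
            sub["fasting_glucose"].to_numpy(),
            convert_hba1c(sub["hba1c_mmol_mol"].to_numpy()),
            np.zeros(len(sub), dtype=bool),
        )
        remission[str(arm)] = float(np.mean([bool(f) for f in flags_r]))
    _json_dump({"remission_fraction": remission}, out / "remission.json", meta)

    manifest = {
        "meta": meta,
        "out_dir": str(out),
        "n_case_control_rows": int(len(cc.data)),
        "n_rct_rows": int(len(rct.data)),
        "pc_variance_explained": emb.variance_explained.tolist(),
        "fisher_accuracy": {a: r.accuracy for a, r in fisher.items()},
        "remission_fraction": remission,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("report written to %s", out)
    return manifest
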