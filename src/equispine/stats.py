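"""Mixed-model comparison of straight-line versus circle kinematics.

Two model categories are fitted on stride-by-stride data:

1. *path comparison*: ``value ~ path * speed`` with random intercepts for
   horse and measurement-within-horse (REML).  Least-squares means per path
   are evaluated at the speed grand mean; the three pairwise path differences
   are tested with Benjamini-Hochberg FDR adjustment within each model.
2. *association models*: whole-back FE / LB (mean or ROM) regressed on the
   pelvic rotations, speed, head swivel and body tracking, separately per
   path, with the same random structure.  Mean predictors accompany mean
   responses and ROM predictors ROM responses; speed and the stride-mean head
   swivel / body tracking enter every model; for FE responses, head swivel
   and body tracking enter as absolute values.  All fixed effects are kept
   (no model reduction).

p-values use the large-sample normal approximation of the fixed-effect
estimates; alpha = 0.05 is the reporting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
PATH_ORDER = ("straight", "left", "right")
CONTRASTS = (("straight", "left"), ("straight", "right"), ("left", "right"))


class ModelDataError(ValueError):
    pass


@dataclass
class PathComparison:
    """LS means per path, pairwise differences and FDR-adjusted p-values."""

    response: str
    statistic: str  # mean | rom
    ls_means: pd.DataFrame  # path, est, se
    differences: pd.DataFrame  # contrast, est, se, z, p_raw, p_fdr
    n_obs: int
    converged: bool
    speed_grand_mean: float

    def __post_init__(self) -> None:
        d = self.differences.set_index("contrast")["est"]
        if {"straight-left", "straight-right", "left-right"} <= set(d.index):
            resid = (d["straight-left"] - d["straight-right"]) + d["left-right"]
            assert abs(resid) < 1e-6, "pairwise contrasts are inconsistent"
        dd = self.differences
        assert (dd["p_fdr"] >= dd["p_raw"] - 1e-12).all(), "FDR must not lower p"


@dataclass
class AssociationModel:
    """Fixed-effect estimates of one per-path association model."""

    response: str
    statistic: str
    path: str
    coefficients: pd.DataFrame  # term, est, se, z, p
    n_obs: int
    converged: bool
    absolute_value_terms: tuple[str, ...] = ()


def _require_paths(data: pd.DataFrame, paths) -> None:
    for p in paths:
        if (data["path"] == p).sum() == 0:
            raise ModelDataError(f"path {p!r} has zero observations; cannot fit model")


def _fit_mixedlm(formula: str, data: pd.DataFrame, random_structure: str):
    """REML mixed model with the requested random structure.

    ``nested`` (default reading of "measurement within horse"): random
    intercept per horse plus a variance component for measurement within
    horse.  ``measurement``: random intercept per measurement only.
    """
    if random_structure == "nested":
        model = smf.mixedlm(
            formula,
            data,
            groups=data["horse"],
            re_formula="1",
            vc_formula={"measurement": "0 + C(measurement)"},
        )
    elif random_structure == "measurement":
        model = smf.mixedlm(formula, data, groups=data["measurement"], re_formula="1")
    else:
        raise ValueError(f"unknown random_structure {random_structure!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    return model, result


def _fixed_effect_cov(result) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(result.model.exog_names)
    params = np.asarray(result.params)[: len(names)]
    cov = np.asarray(result.cov_params())[: len(names), : len(names)]
    return params, cov, names


def _stride_values(table: pd.DataFrame, response: str, statistic: str) -> pd.DataFrame:
    if statistic not in ("mean", "rom"):
        raise ValueError("statistic must be 'mean' or 'rom'")
    col = "stride_mean" if statistic == "mean" else "stride_rom"
    if response == "speed":
        data = (
            table.drop_duplicates(["measurement", "stride"])
            .loc[:, ["horse", "day", "trial", "path", "measurement", "stride", "speed"]]
            .assign(value=lambda d: d["speed"])
        )
    else:
        sub = table[table["variable"] == response]
        if sub.empty:
            raise ModelDataError(f"no rows for response variable {response!r}")
        data = sub.rename(columns={col: "value"})[
            ["horse", "day", "trial", "path", "measurement", "stride", "speed", "value"]
        ]
    return data.dropna(subset=["value", "speed"]).reset_index(drop=True)


def fit_path_model(
    table: pd.DataFrame,
    response: str,
    statistic: str = "mean",
    random_structure: str = "nested",
) -> PathComparison:
    """Fit the path-comparison mixed model for one response variable.

    Fixed effects are path, speed and their interaction; LS means are
    evaluated at the grand-mean speed across all observations; the pairwise
    differences are FDR-adjusted within the model.
    """
    data = _stride_values(table, response, statistic)
    if data["horse"].nunique() < 2:
        raise ModelDataError("need at least 2 horses")
    paths = [p for p in PATH_ORDER if p in set(data["path"])]
    if len(paths) < 2:
        raise ModelDataError("need at least 2 paths")
    _require_paths(data, paths)
    grand = float(data["speed"].mean())
    data = data.assign(speed_c=data["speed"] - grand)
    # ordered categorical fixes the reference level (straight first)
    data["path"] = pd.Categorical(data["path"], categories=paths)

    formula = "value ~ path * speed_c"
    model, result = _fit_mixedlm(formula, data, random_structure)
    params, cov, names = _fixed_effect_cov(result)
    design_info = model.data.design_info

    new = pd.DataFrame(
        {"path": pd.Categorical(paths, categories=paths), "speed_c": 0.0}
    )
    (X,) = patsy.build_design_matrices([design_info], new)
    X = np.asarray(X)
    ls_est = X @ params
    ls_se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    ls_means = pd.DataFrame({"path": paths, "est": ls_est, "se": ls_se})

    rows = []
    pvals = []
    for a, b in CONTRASTS:
        if a not in paths or b not in paths:
            continue
        L = X[paths.index(a)] - X[paths.index(b)]
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append([f"{a}-{b}", est, se, z, p])
        pvals.append(p)
    _, p_fdr, _, _ = multipletests(pvals, alpha=ALPHA, method="fdr_bh")
    differences = pd.DataFrame(rows, columns=["contrast", "est", "se", "z", "p_raw"])
    differences["p_fdr"] = p_fdr
    return PathComparison(
        response=response,
        statistic=statistic,
        ls_means=ls_means,
        differences=differences,
        n_obs=len(data),
        converged=bool(result.converged),
        speed_grand_mean=grand,
    )


# predictors of the association models; pelvic rotations follow the response
# statistic, swivel / tracking / speed are always stride-level means
ASSOCIATION_RESPONSES = ("fe_whole_back", "lb_whole_back")
PELVIC_PREDICTORS = ("pelvis_roll", "pelvis_pitch", "pelvis_yaw")


def _wide_stride_table(table: pd.DataFrame, statistic: str) -> pd.DataFrame:
    keys = ["horse", "day", "trial", "path", "measurement", "stride"]
    col = "stride_mean" if statistic == "mean" else "stride_rom"
    stat_wide = table.pivot_table(index=keys, columns="variable", values=col).add_suffix(
        f"_{statistic}"
    )
    mean_wide = table.pivot_table(
        index=keys, columns="variable", values="stride_mean"
    ).add_suffix("_mean")
    speed = table.groupby(keys)["speed"].first()
    wide = stat_wide.join(mean_wide, how="left", lsuffix="", rsuffix="_dup")
    wide = wide.loc[:, ~wide.columns.str.endswith("_dup")]
    wide["speed"] = speed
    return wide.reset_index()


def fit_association_model(
    table: pd.DataFrame,
    response: str,
    statistic: str = "mean",
    path: str = "straight",
    random_structure: str = "nested",
) -> AssociationModel:
    """Fit one single-path association model for a whole-back response."""
    if response not in ASSOCIATION_RESPONSES:
        raise ValueError(f"response must be one of {ASSOCIATION_RESPONSES}")
    if statistic not in ("mean", "rom"):
        raise ValueError("statistic must be 'mean' or 'rom'")
    sub = table[table["path"] == path]
    if sub.empty:
        raise ModelDataError(f"path {path!r} has zero observations; cannot fit model")
    wide = _wide_stride_table(sub, statistic)

    resp_col = f"{response}_{statistic}"
    use_abs = response.startswith("fe_")
    terms: list[str] = [f"{v}_{statistic}" for v in PELVIC_PREDICTORS]
    abs_terms: tuple[str, ...] = ()
    if use_abs:
        terms += ["np.abs(head_swivel_mean)", "np.abs(body_tracking_mean)"]
        abs_terms = ("head_swivel_mean", "body_tracking_mean")
    else:
        terms += ["head_swivel_mean", "body_tracking_mean"]
    terms.append("speed_c")
    needed = [resp_col] + [f"{v}_{statistic}" for v in PELVIC_PREDICTORS] + [
        "head_swivel_mean",
        "body_tracking_mean",
        "speed",
    ]
    wide = wide.dropna(subset=needed).reset_index(drop=True)
    if wide.empty:
        raise ModelDataError("no complete stride records for the association model")
    wide["speed_c"] = wide["speed"] - wide["speed"].mean()

    formula = f"{resp_col} ~ " + " + ".join(terms)
    _, result = _fit_mixedlm(formula, wide, random_structure)
    params, cov, names = _fixed_effect_cov(result)
    se = np.sqrt(np.diag(cov))
    z = params / se
    p = 2 * sps.norm.sf(np.abs(z))
    coef = pd.DataFrame({"term": names, "est": params, "se": se, "z": z, "p": p})
    return AssociationModel(
        response=response,
        statistic=statistic,
        path=path,
        coefficients=coef,
        n_obs=len(wide),
        converged=bool(result.converged),
        absolute_value_terms=abs_terms,
    )
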