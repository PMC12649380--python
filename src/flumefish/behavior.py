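"""Use-availability resource selection: dataset construction and RSF-GAMM.

For every non-stationary trajectory step from reference point P0 to realised
point P1, a circular utilisation space of radius r = |P1 - P0| is drawn
around P0 and three available alternatives are placed on it by rotating the
step vector through pi/2, pi and 3pi/2.  Each of the four candidate points
carries signed hydraulic-difference covariates

    d_q = q(candidate) - q(P0)     for q in {u, v, TKE, tau_uv, tau_uw, tau_vw}

so a row describes the hydraulic contrast a move to that point would have
encountered.  Candidates falling outside the gridded field domain are
discarded (the flume walls make some rotations physically impossible), with
counts reconciled.

Selection is modelled as a binomial GAMM on the used/available indicator:
per-mode penalized smooths of each retained covariate, tensor-product
interaction smooths with the endurance state E, and random intercepts for
movement mode and fish identity (see :mod:`flumefish.gam`).  Model quality
is assessed by fish-grouped 10-fold cross-validation (AUC, recall, balanced
accuracy) and effects are summarised with partial-dependence curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, recall_score, roc_auc_score
from sklearn.model_selection import GroupKFold

from .errors import ConfigError, StructuralError
from .gam import BinomialGAM, GAMSpec, effect_summary
from .hydraulics import HydraulicField
from .kinematics import MODE_STATIONARY

#: Hydraulic-difference covariates, in reporting order.
DELTA_COVARIATES = ("du", "dv", "dtke", "dtau_uv", "dtau_uw", "dtau_vw")

_QUANTITY_FOR = {"du": "u_bar", "dv": "v_bar", "dtke": "tke",
                 "dtau_uv": "tau_uv", "dtau_uw": "tau_uw",
                 "dtau_vw": "tau_vw"}

#: Classification threshold for recall / balanced accuracy: the base rate of
#: used rows in the 1-used : 3-available design.
DEFAULT_PROB_THRESHOLD = 0.25


def default_rsf_spec(covariates=DELTA_COVARIATES, k: int = 5) -> GAMSpec:
    """Standard model structure: all covariates in per-mode smooths, all but
    dtau_uv in E-interaction tensors."""
    tensors = tuple(c for c in covariates if c != "dtau_uv")
    return GAMSpec(mode_smooths=tuple(covariates), tensor_smooths=tensors, k=k)


# ---------------------------------------------------------------------------
# Dataset construction


def build_use_availability(steps: pd.DataFrame, field: HydraulicField,
                           E: np.ndarray) -> pd.DataFrame:
    """Use-availability rows for one fish's step table.

    ``steps`` is a kinematics step table (needs fish_id, mode, x_m, y_m,
    x1_m, y1_m); ``E`` is the endurance state at each step (aligned with
    ``steps``).  Stationary steps are skipped; rows whose candidate point
    leaves the field domain are discarded with counts recorded in
    ``df.attrs``:``n_steps_retained``, ``n_candidates_discarded``.
    """
    if len(E) != len(steps):
        raise StructuralError("E must align with the step table")
    moving = (steps["mode"] != MODE_STATIONARY).to_numpy()
    p0 = steps[["x_m", "y_m"]].to_numpy(dtype=float)[moving]
    p1 = steps[["x1_m", "y1_m"]].to_numpy(dtype=float)[moving]
    d = p1 - p0
    nonzero = np.linalg.norm(d, axis=1) > 0
    p0, p1, d = p0[nonzero], p1[nonzero], d[nonzero]
    sub = steps.loc[moving].loc[nonzero]
    e_step = np.asarray(E, dtype=float)[moving][nonzero]
    n_steps = len(sub)
    if n_steps == 0:
        empty = pd.DataFrame()
        empty.attrs.update(n_steps_retained=0, n_candidates_discarded=0)
        return empty

    # candidate offsets: rotations of the step vector by pi/2, pi, 3pi/2
    rotations = [np.column_stack([-d[:, 1], d[:, 0]]),
                 -d,
                 np.column_stack([d[:, 1], -d[:, 0]])]
    candidates = [p1] + [p0 + r for r in rotations]

    ref_q = field.interpolate(p0)
    rows = []
    n_discarded = 0
    for cand_idx, pts in enumerate(candidates):
        inside = field.contains(pts)
        n_discarded += int((~inside).sum()) if cand_idx > 0 else 0
        if cand_idx == 0 and not inside.all():
            # realised positions should be in-domain; drop the whole step
            raise StructuralError("realised step end point outside field domain")
        q = field.interpolate(pts[inside])
        keep = np.flatnonzero(inside)
        block = pd.DataFrame({
            "fish_id": sub["fish_id"].to_numpy()[keep],
            "step": sub["step"].to_numpy()[keep],
            "candidate": cand_idx,
            "used": 1 if cand_idx == 0 else 0,
            "x_m": pts[keep, 0],
            "y_m": pts[keep, 1],
            "mode": sub["mode"].to_numpy()[keep],
            "E": e_step[keep],
        })
        for dcov, qname in _QUANTITY_FOR.items():
            block[dcov] = (np.atleast_1d(q[qname])
                           - np.atleast_1d(ref_q[qname])[keep])
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["step", "candidate"], ignore_index=True)
    out.attrs["n_steps_retained"] = n_steps
    out.attrs["n_candidates_discarded"] = n_discarded
    return out


# ---------------------------------------------------------------------------
# Collinearity screen


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors via R^2 of each column on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def collinearity_screen(rows: pd.DataFrame,
                        covariates=DELTA_COVARIATES,
                        r_max: float = 0.6, vif_max: float = 3.0
                        ) -> tuple[list[str], pd.DataFrame]:
    """Drop collinear covariates by pairwise correlation then VIF.

    While any pair has |r| > ``r_max``, the member with the larger mean
    absolute correlation to the remaining covariates is dropped; then the
    max-VIF covariate is dropped until all VIF <= ``vif_max``.  Returns the
    retained covariate list and a report of the drops.
    """
    retained = [c for c in covariates]
    if len(retained) < 2:
        raise ConfigError("need at least 2 covariates to screen")
    report = []
    while len(retained) > 1:
        M = rows[retained].to_numpy(dtype=float)
        R = np.corrcoef(M, rowvar=False)
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        if abs(R[i, j]) <= r_max:
            break
        mean_abs = np.abs(R).sum(axis=0) / (len(retained) - 1)
        drop = retained[i] if mean_abs[i] >= mean_abs[j] else retained[j]
        report.append({"dropped": drop, "rule": "pearson",
                       "value": float(abs(R[i, j]))})
        retained.remove(drop)
    while len(retained) > 1:
        vifs = _vif(rows[retained].to_numpy(dtype=float))
        if np.nanmax(vifs) <= vif_max:
            break
        drop = retained[int(np.nanargmax(vifs))]
        report.append({"dropped": drop, "rule": "vif",
                       "value": float(np.nanmax(vifs))})
        retained.remove(drop)
    if not retained:
        raise ConfigError("collinearity screen removed every covariate")
    return retained, pd.DataFrame(report, columns=["dropped", "rule", "value"])


# ---------------------------------------------------------------------------
# Model fitting and evaluation


def fit_rsf_gamm(rows: pd.DataFrame, spec: GAMSpec | None = None,
                 **fit_kwargs) -> BinomialGAM:
    """Fit the binomial RSF-GAMM on a use-availability table."""
    if rows["fish_id"].nunique() < 2:
        warnings.warn("fewer than 2 fish: the fish random effect is "
                      "unidentifiable", stacklevel=2)
    if spec is None:
        spec = default_rsf_spec()
    model = BinomialGAM(spec)
    model.fit(rows, rows["used"].to_numpy(dtype=float), **fit_kwargs)
    return model


def cross_validate(rows: pd.DataFrame, spec: GAMSpec | None = None,
                   k: int = 10, threshold: float = DEFAULT_PROB_THRESHOLD,
                   **fit_kwargs) -> dict:
    """Fish-grouped k-fold cross-validation of the RSF-GAMM.

    Folds are grouped by fish so no fish contributes to both training and
    validation.  Reports per-fold and mean AUC, recall of used rows, and
    balanced accuracy at the given probability threshold.
    """
    if spec is None:
        spec = default_rsf_spec()
    groups = rows["fish_id"].to_numpy()
    n_groups = len(np.unique(groups))
    k_eff = min(k, n_groups)
    if k_eff < 2:
        raise ConfigError("grouped CV needs at least 2 fish")
    folds = []
    splitter = GroupKFold(n_splits=k_eff)
    for train_idx, test_idx in splitter.split(rows, groups=groups):
        train, test = rows.iloc[train_idx], rows.iloc[test_idx]
        y_test = test["used"].to_numpy(dtype=float)
        if y_test.min() == y_test.max():
            warnings.warn("single-class CV fold skipped", stacklevel=2)
            continue
        model = BinomialGAM(spec)
        model.fit(train, train["used"].to_numpy(dtype=float), **fit_kwargs)
        p = model.predict_proba(test)
        yhat = (p >= threshold).astype(float)
        folds.append({
            "auc": roc_auc_score(y_test, p),
            "recall": recall_score(y_test, yhat),
            "balanced_accuracy": balanced_accuracy_score(y_test, yhat),
            "n_test": len(test),
        })
    fold_df = pd.DataFrame(folds)
    return {
        "auc": float(fold_df["auc"].mean()),
        "recall": float(fold_df["recall"].mean()),
        "balanced_accuracy": float(fold_df["balanced_accuracy"].mean()),
        "folds": fold_df,
    }


def partial_dependence(model: BinomialGAM, covariate: str,
                       mode: str | None = None,
                       grid: np.ndarray | None = None,
                       surface: bool = False,
                       n_grid: int = 200) -> tuple[pd.DataFrame, dict | None]:
    """PDP curve (or (covariate, E) surface) plus univariate summary.

    For curves, the summary carries the optimal effect point (argmax) and
    positive-effect ranges; surfaces return ``None`` as summary.
    """
    if surface:
        return model.partial_dependence_surface(covariate), None
    curve = model.partial_dependence(covariate, mode=mode, grid=grid,
                                     n_grid=n_grid)
    return curve, effect_summary(curve)


def effect_report(model: BinomialGAM, covariates=None) -> pd.DataFrame:
    """Optimal points and positive ranges for every per-mode smooth."""
    if covariates is None:
        covariates = model.spec.mode_smooths
    rows = []
    for cov in covariates:
        for mode in model.spec.modes:
            _, summ = partial_dependence(model, cov, mode=mode)
            rows.append({
                "covariate": cov, "mode": mode,
                "optimal_point": summ["optimal_point"],
                "optimal_effect": summ["optimal_effect"],
                "positive_ranges": "; ".join(
                    f"[{a:.3g}, {b:.3g}]" for a, b in summ["positive_ranges"]),
            })
    return pd.DataFrame(rows)
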