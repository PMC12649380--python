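"""Fatigue-time extraction and the breakpoint Weibull AFT endurance model.

Fatigue time ``T`` is the total duration a fish swims faster than the
sustained-swimming threshold (3.83 BL/s for the study species); fish that
traverse the full test area without fatiguing are right-censored.  Endurance
is modelled with an accelerated failure time (AFT) regression,

    ln(T) = b0 + b1*C_ps + sum_k (b_2k + b_{2k+1}*C_ps) * x_k + eps,

where ``eps`` follows a Weibull (extreme-value on the log scale) error with
scale ``sigma`` and ``C_ps`` indicates the prolonged (0) vs sprint (1)
regime, split at a breakpoint swim speed.  Because every covariate carries a
regime interaction and the Weibull scale is regime-specific, the model is
fitted as two independent Weibull AFT regressions, one per regime; their
log-likelihoods and parameter counts add.  The breakpoint itself is found by
a moving-point search over observed mean swim speeds, scored by AIC with
Harrell's concordance index (C-index) reported alongside.

The dynamic endurance state

    E(t) = 1 - integral_0^t dt' / T(Vs(t'))

tracks the remaining fraction of the fatigue budget: swimming at a speed the
model predicts to be sustainable for ``T`` seconds depletes ``1/T`` of the
budget per second; sub-threshold swimming costs nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _ll_concordance
from scipy import optimize, stats

from .errors import FitError, StructuralError, UndefinedStatisticError

#: Sustained-swimming threshold, BL/s: speeds below it are treated as fully
#: aerobic and excluded from fatigue accounting.
SUSTAINED_THRESHOLD_BLS = 3.83

#: Length of the test area, m; traversing it without fatigue censors T.
TEST_AREA_LENGTH = 6.0

#: Covariate label -> fatigue-record column.
COVARIATE_COLUMNS = {
    "Vs": "mean_Vs_bls",
    "BL": "BL_m",
    "Temp": "Temp_C",
    "DO": "DO_mgL",
}


# ---------------------------------------------------------------------------
# Fatigue-time extraction


def fatigue_time(vs_bls: np.ndarray, frame_rate: float,
                 threshold: float = SUSTAINED_THRESHOLD_BLS,
                 traversed: bool = False) -> dict[str, float | bool]:
    """Fatigue time and mean supra-threshold speed from per-step swim speeds.

    ``T`` counts only steps with ``|Vs| > threshold``; ``mean_Vs`` is the
    arithmetic mean over those steps.  ``traversed`` marks the record as
    right-censored (the fish crossed the whole test area still swimming).
    """
    vs = np.asarray(vs_bls, dtype=float)
    above = vs > threshold
    if not above.any():
        raise StructuralError("no steps above the sustained threshold")
    return {
        "T_s": float(above.sum() / frame_rate),
        "mean_Vs_bls": float(vs[above].mean()),
        "censored": bool(traversed),
    }


def fatigue_records_from_steps(steps: pd.DataFrame, body_length: float,
                               frame_rate: float,
                               threshold: float = SUSTAINED_THRESHOLD_BLS,
                               per: str = "excursion",
                               test_area_length: float = TEST_AREA_LENGTH,
                               temp: float = np.nan, do: float = np.nan
                               ) -> pd.DataFrame:
    """Fatigue records for one fish's step table.

    ``per='excursion'`` yields one record per continuous supra-threshold
    excursion; ``per='fish'`` pools all supra-threshold steps into a single
    record.  A record is censored when the fish's cumulative upstream
    displacement over the excursion reaches the full test-area length.
    """
    vs = steps["vs_bls"].to_numpy()
    above = vs > threshold
    if not above.any():
        return pd.DataFrame()
    if per == "fish":
        groups = [np.flatnonzero(above)]
    elif per == "excursion":
        idx = np.flatnonzero(above)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        groups = np.split(idx, splits)
    else:
        raise ValueError(f"per must be 'excursion' or 'fish', got {per!r}")

    dx = steps["x1_m"].to_numpy() - steps["x_m"].to_numpy()
    fish_id = steps["fish_id"].iloc[0]
    records = []
    for g, idx in enumerate(groups):
        distance = float(np.maximum(dx[idx], 0.0).sum())
        rec = fatigue_time(vs[idx], frame_rate, threshold,
                           traversed=distance >= test_area_length)
        records.append({
            "fish_id": fish_id,
            "excursion": g,
            **rec,
            "BL_m": body_length,
            "Temp_C": temp,
            "DO_mgL": do,
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Weibull AFT maximum likelihood


@dataclass
class WeibullAFTFit:
    """One Weibull AFT regression: ln(T) = X beta + sigma * eps_gumbel."""

    covariates: tuple[str, ...]      # labels, in design order after intercept
    beta: np.ndarray                 # (p,) incl. leading intercept
    log_scale: float                 # ln(sigma) ("Log(scale)")
    cov: np.ndarray                  # (p+1, p+1) for (beta, log_scale)
    loglik: float
    n: int
    n_censored: int

    @property
    def n_params(self) -> int:
        return self.beta.size + 1

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def p_values(self) -> np.ndarray:
        z = np.concatenate([self.beta, [self.log_scale]]) / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([np.ones(len(X)), X]) @ self.beta

    def summary(self) -> pd.DataFrame:
        names = ["Intercept", *self.covariates, "Log(scale)"]
        est = np.concatenate([self.beta, [self.log_scale]])
        return pd.DataFrame({"variable": names, "coefficient": est,
                             "se": self.se, "p": self.p_values})


def _weibull_aft_nll_grad(theta, X1, logt, uncens):
    beta, log_sigma = theta[:-1], theta[-1]
    # keep sigma representable; the gradient still pushes back into range
    sigma = np.exp(np.clip(log_sigma, -15.0, 15.0))
    z = (logt - X1 @ beta) / sigma
    ez = np.exp(np.clip(z, -700, 700))
    ll = np.sum(np.where(uncens, -log_sigma + z - ez, -ez))
    g = np.where(uncens, 1.0 - ez, -ez)           # dll/dz
    grad_beta = -(X1 * (g / sigma)[:, None]).sum(axis=0)
    grad_ls = np.sum(np.where(uncens, -1.0, 0.0) - g * z)
    return -ll, -np.concatenate([grad_beta, [grad_ls]])


def fit_weibull_aft(X: np.ndarray, t: np.ndarray, censored: np.ndarray,
                    covariate_names: tuple[str, ...] = ()) -> WeibullAFTFit:
    """Maximum-likelihood Weibull AFT fit with right-censoring.

    ``X`` is (n, k) without intercept; ``t`` the observed (or censoring)
    times; ``censored`` flags right-censored rows.  The covariance is the
    inverse observed information (finite differences of the analytic score).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if np.any(t <= 0):
        raise StructuralError("fatigue times must be positive")
    if not np.all(np.isfinite(X)):
        raise StructuralError("covariates must be finite")
    uncens = ~censored
    if uncens.sum() < X.shape[1] + 2:
        raise FitError(
            f"only {int(uncens.sum())} uncensored records for "
            f"{X.shape[1] + 2} parameters"
        )
    X1 = np.column_stack([np.ones(len(t)), X])
    logt = np.log(t)

    beta0, *_ = np.linalg.lstsq(X1[uncens], logt[uncens], rcond=None)
    resid = logt[uncens] - X1[uncens] @ beta0
    sd = max(float(resid.std()), 1e-2)
    theta0 = np.concatenate([beta0, [np.log(sd)]])

    # line searches may briefly overflow exp(z); harmless, silenced
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            _weibull_aft_nll_grad, theta0, args=(X1, logt, uncens),
            jac=True, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-7})
        if not np.isfinite(res.fun):
            raise FitError("Weibull AFT likelihood diverged")
        if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1, len(t)):
            res2 = optimize.minimize(
                lambda th: _weibull_aft_nll_grad(th, X1, logt, uncens)[0],
                res.x, method="Nelder-Mead", options={"maxiter": 2000})
            if np.isfinite(res2.fun) and res2.fun <= res.fun:
                res = res2

    theta = res.x
    # observed information via central differences of the analytic score
    p = theta.size
    H = np.empty((p, p))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _weibull_aft_nll_grad(tp, X1, logt, uncens)
        _, gm = _weibull_aft_nll_grad(tm, X1, logt, uncens)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular observed information") from exc
    if np.any(np.diag(cov) <= 0):
        raise FitError("non-positive-definite observed information")

    # the optimisation works on the log-time density; report the likelihood
    # on the time scale (standard survival convention) via the Jacobian
    loglik = float(-res.fun - logt[uncens].sum())
    return WeibullAFTFit(
        covariates=tuple(covariate_names),
        beta=theta[:-1],
        log_scale=float(theta[-1]),
        cov=cov,
        loglik=loglik,
        n=len(t),
        n_censored=int(censored.sum()),
    )


# ---------------------------------------------------------------------------
# Breakpoint endurance model


@dataclass
class AFTModel:
    """Two-regime breakpoint Weibull AFT endurance model.

    ``C_ps = 1`` iff ``mean_Vs > breakpoint``.  Separate regressions per
    regime realise the full main-effect + interaction parametrisation of the
    log-time model with regime-specific Weibull scales.
    """

    breakpoint: float
    covariates: tuple[str, ...]
    prolonged: WeibullAFTFit
    sprint: WeibullAFTFit
    c_index_: float | None = None
    candidates: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_coefficients(cls, breakpoint: float, covariates,
                          prolonged: dict, sprint: dict) -> "AFTModel":
        """Build a model from published coefficient tables.

        Each regime dict maps ``"Intercept"``, each covariate label, and
        ``"Log(scale)"`` to its coefficient.  Standard errors are unknown
        (identity covariance placeholder); intended for prediction, e.g.
        endurance-state integration from reported coefficients.
        """
        covariates = tuple(covariates)

        def build(d: dict) -> WeibullAFTFit:
            beta = np.array([d["Intercept"], *[d[c] for c in covariates]],
                            dtype=float)
            return WeibullAFTFit(
                covariates=covariates, beta=beta,
                log_scale=float(d.get("Log(scale)", 0.0)),
                cov=np.eye(beta.size + 1), loglik=np.nan,
                n=int(d.get("n", 0)), n_censored=0)

        return cls(breakpoint=float(breakpoint), covariates=covariates,
                   prolonged=build(prolonged), sprint=build(sprint))

    @property
    def aic(self) -> float:
        return self.prolonged.aic + self.sprint.aic

    @property
    def loglik(self) -> float:
        return self.prolonged.loglik + self.sprint.loglik

    @property
    def n_prolonged(self) -> int:
        return self.prolonged.n

    @property
    def n_sprint(self) -> int:
        return self.sprint.n

    def summary(self) -> pd.DataFrame:
        frames = []
        for name, fit_ in (("Prolonged", self.prolonged), ("Sprint", self.sprint)):
            df = fit_.summary()
            df.insert(0, "model", name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _design(records: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        col = COVARIATE_COLUMNS.get(c, c)
        if col not in records.columns:
            raise StructuralError(f"records lack covariate column {col!r}")
        cols.append(records[col].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(records), 0))


def fit_aft(records: pd.DataFrame, covariates=("Vs", "BL"),
            breakpoint: float | None = None) -> AFTModel | WeibullAFTFit:
    """Fit the endurance AFT model.

    With a ``breakpoint``, records are split into prolonged
    (``mean_Vs <= breakpoint``) and sprint (``mean_Vs > breakpoint``) regimes
    and one Weibull AFT is fitted per regime.  Without one, a single-regime
    fit over all records is returned.
    """
    covariates = tuple(covariates)
    X = _design(records, covariates)
    t = records["T_s"].to_numpy(dtype=float)
    cens = records["censored"].to_numpy(dtype=bool)
    if breakpoint is None:
        return fit_weibull_aft(X, t, cens, covariates)
    sprint_mask = records["mean_Vs_bls"].to_numpy(dtype=float) > breakpoint
    pro = fit_weibull_aft(X[~sprint_mask], t[~sprint_mask], cens[~sprint_mask],
                          covariates)
    spr = fit_weibull_aft(X[sprint_mask], t[sprint_mask], cens[sprint_mask],
                          covariates)
    model = AFTModel(breakpoint=float(breakpoint), covariates=covariates,
                     prolonged=pro, sprint=spr)
    model.c_index_ = c_index(model, records)
    return model


def predict_log_T(model: AFTModel, records: pd.DataFrame) -> np.ndarray:
    """Regime-aware linear predictor of ln(T) for a record table."""
    X = _design(records, model.covariates)
    sprint_mask = records["mean_Vs_bls"].to_numpy(dtype=float) > model.breakpoint
    out = np.empty(len(records))
    if (~sprint_mask).any():
        out[~sprint_mask] = model.prolonged.linear_predictor(X[~sprint_mask])
    if sprint_mask.any():
        out[sprint_mask] = model.sprint.linear_predictor(X[sprint_mask])
    return out


def predict_T(model: AFTModel, vs_bls, bl_m, temp=np.nan, do=np.nan,
              threshold: float = SUSTAINED_THRESHOLD_BLS) -> np.ndarray | float:
    """Predicted fatigue time (s) at swim speed ``vs_bls`` and length ``bl_m``.

    Uses ``T = exp(linear predictor)`` with the regime chosen by the swim
    speed relative to the model's breakpoint.  Speeds at or below the
    sustained threshold are outside the model's support.
    """
    vs = np.atleast_1d(np.asarray(vs_bls, dtype=float))
    if np.any(vs <= threshold):
        raise StructuralError(
            f"swim speed below sustained threshold {threshold} BL/s: "
            "fatigue time undefined"
        )
    rec = pd.DataFrame({
        "mean_Vs_bls": vs,
        "BL_m": np.broadcast_to(np.asarray(bl_m, dtype=float), vs.shape),
        "Temp_C": np.broadcast_to(np.asarray(temp, dtype=float), vs.shape),
        "DO_mgL": np.broadcast_to(np.asarray(do, dtype=float), vs.shape),
    })
    T = np.exp(predict_log_T(model, rec))
    return float(T[0]) if np.isscalar(vs_bls) else T


def c_index(model: AFTModel, records: pd.DataFrame) -> float:
    """Harrell's concordance for right-censored fatigue times.

    Admissible pairs are those whose ordering is observable (the shorter
    observed time is uncensored); concordant pairs are ordered the same way
    by predicted ln(T); ties in prediction count one half.
    """
    pred = predict_log_T(model, records)
    event = ~records["censored"].to_numpy(dtype=bool)
    if not event.any():
        raise UndefinedStatisticError("all records censored: C-index undefined")
    try:
        return float(_ll_concordance(records["T_s"].to_numpy(dtype=float),
                                     pred, event_observed=event))
    except ZeroDivisionError as exc:
        raise UndefinedStatisticError("no admissible pairs") from exc


def breakpoint_search(records: pd.DataFrame, covariates=("Vs", "BL"),
                      min_group: int | None = None) -> AFTModel:
    """Moving-point breakpoint search over observed mean swim speeds.

    Every distinct observed ``mean_Vs`` is a candidate breakpoint, excluding
    enough order statistics at either end to leave both regimes at least
    ``min_group`` records (default: parameters-per-regime + 2, and never
    fewer than the spec'd 2-record trim).  The candidate minimising the
    summed two-regime AIC wins; AIC ties within 1e-6 go to the higher
    C-index.  The per-candidate (breakpoint, AIC, C-index) table is attached
    as ``model.candidates``.
    """
    covariates = tuple(covariates)
    speeds = np.sort(records["mean_Vs_bls"].unique())
    if speeds.size < 3:
        raise FitError("need at least 3 distinct candidate speeds")
    if min_group is None:
        min_group = max(len(covariates) + 3, 3)
    vs_all = records["mean_Vs_bls"].to_numpy(dtype=float)
    rows = []
    best: AFTModel | None = None
    for bp in speeds:
        n_pro = int((vs_all <= bp).sum())
        n_spr = int((vs_all > bp).sum())
        if n_pro < min_group or n_spr < min_group:
            continue
        try:
            model = fit_aft(records, covariates, breakpoint=bp)
        except FitError:
            continue
        rows.append({"breakpoint": bp, "aic": model.aic,
                     "c_index": model.c_index_,
                     "n_prolonged": n_pro, "n_sprint": n_spr})
        if best is None or model.aic < best.aic - 1e-6 or (
                abs(model.aic - best.aic) <= 1e-6
                and model.c_index_ > best.c_index_):
            best = model
    if best is None:
        raise FitError("no candidate breakpoint yielded a convergent fit")
    best.candidates = pd.DataFrame(rows)
    return best


# ---------------------------------------------------------------------------
# Model selection


def akaike_weights(aic_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    aic = np.asarray(aic_values, dtype=float)
    if aic.size == 0 or not np.all(np.isfinite(aic)):
        raise StructuralError("need at least one finite AIC")
    delta = aic - aic.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


def model_selection(records: pd.DataFrame, breakpoint: float,
                    candidate_sets=None) -> pd.DataFrame:
    """Rank covariate subsets by AIC at a fixed breakpoint.

    Default candidates are all 15 non-empty subsets of {Vs, BL, Temp, DO}.
    Subsets whose fit fails are ranked last with missing AIC.
    """
    if candidate_sets is None:
        pool = ("Vs", "BL", "Temp", "DO")
        candidate_sets = [c for r in range(1, len(pool) + 1)
                          for c in itertools.combinations(pool, r)]
    rows = []
    for covs in candidate_sets:
        try:
            model = fit_aft(records, covs, breakpoint=breakpoint)
            rows.append({"covariates": " + ".join(covs), "aic": model.aic,
                         "c_index": model.c_index_})
        except (FitError, StructuralError):
            rows.append({"covariates": " + ".join(covs), "aic": np.nan,
                         "c_index": np.nan})
    df = pd.DataFrame(rows).sort_values("aic", na_position="last",
                                        ignore_index=True)
    ok = df["aic"].notna()
    df["delta_aic"] = df["aic"] - df.loc[ok, "aic"].min()
    df.loc[ok, "w"] = akaike_weights(df.loc[ok, "aic"].to_numpy())
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Endurance state


def endurance_state(vs_bls: np.ndarray, frame_rate: float, model: AFTModel,
                    bl_m: float,
                    threshold: float = SUSTAINED_THRESHOLD_BLS) -> np.ndarray:
    """Endurance state E after each step, starting from E = 1.

    Returns an array of length ``len(vs_bls) + 1``; entry k is the state
    before step k (entry 0 is 1).  Each supra-threshold step depletes
    ``(1/frame_rate) / T_pred(Vs)`` with the regime chosen per step from the
    instantaneous speed; the state is clamped at 0 and never increases.
    """
    vs = np.asarray(vs_bls, dtype=float)
    depletion = np.zeros(vs.size)
    above = vs > threshold
    if above.any():
        T = predict_T(model, vs[above], bl_m, threshold=threshold)
        depletion[above] = (1.0 / frame_rate) / np.atleast_1d(T)
    E = 1.0 - np.concatenate([[0.0], np.cumsum(depletion)])
    return np.clip(E, 0.0, 1.0)
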