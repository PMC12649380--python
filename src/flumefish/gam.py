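"""Penalized-spline binomial additive model with REML smoothing selection.

This is the engine behind the resource-selection GAMM: a logistic additive
model whose terms are

* per-mode P-spline smooths of each hydraulic-difference covariate
  (a by-factor smooth: one independently penalized curve per movement mode),
* tensor-product P-spline interaction surfaces of a covariate with the
  endurance state E,
* i.i.d. Gaussian random intercepts (movement mode, fish identity) realised
  as ridge-penalized dummy blocks — the standard mixed-model-as-smooth
  equivalence.

Smooths use cubic B-spline bases with second-order difference penalties
(P-splines).  Each smooth block is reparametrized to absorb a sum-to-zero
constraint (its contribution averages to zero over the training rows), and
carries a double penalty: the usual wiggliness penalty plus a projector onto
the penalty null space, so that every direction — including the linear
margins that tensor products share with the per-mode smooths — is shrunk by
a REML-chosen amount and the model stays identifiable.  This mirrors the
null-space-selection device used for term selection in modern GAM software.

Coefficients are estimated by penalized IRLS; every smoothing parameter is
updated between IRLS solves with the Fellner-Schall REML step

    lambda_j  <-  (rank(S_j) - lambda_j * tr(V S_j)) / (beta_j' S_j beta_j),

where ``V = (X'WX + S)^-1`` is the Bayesian posterior covariance of the
coefficients, which also supplies the credible intervals reported for
partial-dependence curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space

from .errors import FitError, StructuralError


# ---------------------------------------------------------------------------
# B-spline basis


@dataclass
class PSplineBasis:
    """Cubic B-spline basis on a fixed range with a difference penalty."""

    lo: float
    hi: float
    k: int = 5          # number of basis functions
    degree: int = 3

    def __post_init__(self) -> None:
        if self.k < self.degree + 1:
            raise StructuralError(f"k={self.k} too small for degree {self.degree}")
        if self.hi <= self.lo:
            self.hi = self.lo + 1.0     # degenerate covariate: flat basis range
        n_interior = self.k - self.degree - 1
        interior = np.linspace(self.lo, self.hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate([
            np.full(self.degree + 1, self.lo), interior,
            np.full(self.degree + 1, self.hi)])

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        D = np.diff(np.eye(self.k), n=order, axis=0)
        return D.T @ D


# ---------------------------------------------------------------------------
# Model specification and terms


@dataclass
class GAMTerm:
    """Metadata for one column block of the design matrix."""

    name: str
    kind: str                       # intercept | mode_smooth | tensor | random
    sl: slice                       # column slice in the full design
    penalties: list                 # penalty components (constrained space)
    ranks: list                     # rank of each component
    lams: list                      # smoothing parameter per component
    covariate: str | None = None
    mode: str | None = None
    basis: PSplineBasis | None = None
    basis2: PSplineBasis | None = None     # E margin for tensors
    Z: np.ndarray | None = None            # sum-to-zero constraint basis
    levels: tuple | None = None            # random-effect levels
    edf: float = np.nan
    p_value: float = np.nan


@dataclass
class GAMSpec:
    """Structure of the additive model.

    ``mode_smooths``: covariates given one smooth per movement mode.
    ``tensor_smooths``: covariates given a (covariate x E) interaction
    surface.  ``k`` is the marginal basis dimension (3-5 band; default 5).
    """

    mode_smooths: tuple[str, ...]
    tensor_smooths: tuple[str, ...] = ()
    k: int = 5
    modes: tuple[str, ...] = ("upstream", "cross", "downstream")
    e_column: str = "E"
    random_effects: tuple[str, ...] = ("mode", "fish_id")


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(len(A), -1)


class BinomialGAM:
    """Penalized binomial logit additive model (see module docstring)."""

    def __init__(self, spec: GAMSpec):
        self.spec = spec
        self.terms: list[GAMTerm] = []
        self.coef_: np.ndarray | None = None
        self.Vp_: np.ndarray | None = None       # Bayesian posterior cov
        self.converged_: bool = False
        self.n_obs_: int = 0

    # -- design construction ----------------------------------------------

    def _init_terms(self, df: pd.DataFrame) -> None:
        spec = self.spec
        terms = [GAMTerm("intercept", "intercept", slice(0, 1), [], [], [])]
        col = 1

        def basis_for(covariate: str) -> PSplineBasis:
            x = df[covariate].to_numpy(dtype=float)
            return PSplineBasis(float(x.min()), float(x.max()), k=spec.k)

        # smooth blocks lose one column to the sum-to-zero constraint
        for cov in spec.mode_smooths:
            for mode in spec.modes:
                b = basis_for(cov)
                terms.append(GAMTerm(
                    name=f"s({cov}):{mode}", kind="mode_smooth",
                    sl=slice(col, col + spec.k - 1),
                    penalties=[b.penalty()], ranks=[], lams=[],
                    covariate=cov, mode=mode, basis=b))
                col += spec.k - 1
        for cov in spec.tensor_smooths:
            bx = basis_for(cov)
            be = PSplineBasis(float(df[spec.e_column].min()),
                              float(df[spec.e_column].max()), k=spec.k)
            S = (np.kron(bx.penalty(), np.eye(spec.k))
                 + np.kron(np.eye(spec.k), be.penalty()))
            terms.append(GAMTerm(
                name=f"te({cov},{spec.e_column})", kind="tensor",
                sl=slice(col, col + spec.k ** 2 - 1),
                penalties=[S], ranks=[], lams=[],
                covariate=cov, basis=bx, basis2=be))
            col += spec.k ** 2 - 1
        for factor in spec.random_effects:
            levels = tuple(sorted(df[factor].astype(str).unique()))
            m = len(levels)
            terms.append(GAMTerm(
                name=f"s({factor})", kind="random",
                sl=slice(col, col + m),
                penalties=[np.eye(m)], ranks=[m], lams=[1.0],
                covariate=factor, levels=levels))
            col += m
        self.terms = terms
        self.n_cols_ = col

    @staticmethod
    def _constrain(term: GAMTerm, B: np.ndarray) -> None:
        """Absorb the sum-to-zero constraint and split the penalty.

        Finds Z with mean(B) @ Z = 0, reparametrizes the block as B @ Z, and
        replaces the penalty with two components in the constrained space:
        the wiggliness penalty and the projector onto its null space (the
        double-penalty device), so no direction of the smooth is left
        unpenalized.
        """
        c = B.mean(axis=0)
        k = B.shape[1]
        if np.linalg.norm(c) < 1e-12:
            Z = np.eye(k)[:, :k - 1]
        else:
            Z = null_space(c[None, :])
        term.Z = Z
        S = Z.T @ term.penalties[0] @ Z
        eig, U = np.linalg.eigh(S)
        tol = 1e-10 * max(eig.max(), 1.0)
        null_dim = int(np.sum(eig <= tol))
        term.penalties = [S]
        term.ranks = [S.shape[0] - null_dim]
        term.lams = [1.0]
        if null_dim:
            U0 = U[:, eig <= tol]
            term.penalties.append(U0 @ U0.T)
            term.ranks.append(null_dim)
            term.lams.append(1.0)

    def _build_design(self, df: pd.DataFrame, training: bool) -> np.ndarray:
        X = np.zeros((len(df), self.n_cols_))
        X[:, 0] = 1.0
        mode_arr = df["mode"].astype(str).to_numpy() if "mode" in df else None
        for term in self.terms:
            if term.kind == "intercept":
                continue
            if term.kind == "mode_smooth":
                active = mode_arr == term.mode
                if training and not active.any():
                    B = term.basis.design(df[term.covariate].to_numpy())
                    self._constrain(term, B)     # keep shapes consistent
                    continue
                if not active.any():
                    continue
                B = term.basis.design(df[term.covariate].to_numpy()[active])
                if training:
                    self._constrain(term, B)
                X[np.ix_(active, range(term.sl.start, term.sl.stop))] = \
                    B @ term.Z
            elif term.kind == "tensor":
                Bx = term.basis.design(df[term.covariate].to_numpy())
                Be = term.basis2.design(df[self.spec.e_column].to_numpy())
                B = _row_kron(Bx, Be)
                if training:
                    self._constrain(term, B)
                X[:, term.sl] = B @ term.Z
            elif term.kind == "random":
                vals = df[term.covariate].astype(str).to_numpy()
                index = {lv: i for i, lv in enumerate(term.levels)}
                for r, v in enumerate(vals):
                    j = index.get(v)       # unseen level -> zero effect
                    if j is not None:
                        X[r, term.sl.start + j] = 1.0
        return X

    def _penalty_matrix(self) -> np.ndarray:
        S = np.zeros((self.n_cols_, self.n_cols_))
        for term in self.terms:
            for lam, Sj in zip(term.lams, term.penalties):
                S[term.sl, term.sl] += lam * Sj
        return S

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _solve_pd(A, b):
        """Cholesky solve with ridge escalation for near-singular systems."""
        scale = max(float(np.mean(np.diag(A))), 1.0)
        for bump in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
            try:
                c, low = cho_factor(A + bump * scale * np.eye(A.shape[0]))
                return cho_solve((c, low), b)
            except np.linalg.LinAlgError:
                continue
        raise FitError("penalized IRLS system not positive definite")

    def _pirls(self, X, y, S, beta, max_iter, tol):
        p = X.shape[1]
        ridge = 1e-8 * np.eye(p)
        for _ in range(max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            XtW = X.T * w
            A = XtW @ X + S + ridge
            beta_new = self._solve_pd(A, XtW @ z)
            step = np.max(np.abs(beta_new - beta)) / max(
                1.0, np.max(np.abs(beta_new)))
            beta = beta_new
            if step < tol:
                break
        return beta

    def fit(self, df: pd.DataFrame, y: np.ndarray,
            max_outer: int = 25, max_pirls: int = 30,
            tol: float = 1e-6, lam_tol: float = 0.02) -> "BinomialGAM":
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise StructuralError("response must be binary 0/1")
        self._init_terms(df)
        X = self._build_design(df, training=True)
        n, p = X.shape
        self.n_obs_ = n
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        penalized = [t for t in self.terms if t.penalties]

        for outer in range(max_outer):
            S = self._penalty_matrix()
            beta = self._pirls(X, y, S, beta, max_pirls, tol)
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = np.maximum(mu * (1 - mu), 1e-10)
            A = (X.T * w) @ X + S + 1e-8 * np.eye(p)
            V = np.linalg.inv(A)
            # Fellner-Schall REML update per penalty component
            max_step = 0.0
            for term in penalized:
                Vjj = V[term.sl, term.sl]
                bj = beta[term.sl]
                for i, Sj in enumerate(term.penalties):
                    lam = term.lams[i]
                    num = term.ranks[i] - lam * np.trace(Vjj @ Sj)
                    den = float(bj @ Sj @ bj)
                    lam_new = float(np.clip(max(num, 1e-10) / max(den, 1e-12),
                                            1e-7, 1e9))
                    max_step = max(max_step, abs(np.log(lam_new)
                                                 - np.log(lam)))
                    term.lams[i] = lam_new
            if max_step < lam_tol:
                self.converged_ = True
                break

        # final solve at converged smoothing parameters
        S = self._penalty_matrix()
        beta = self._pirls(X, y, S, beta, max_pirls, tol)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1 - mu), 1e-10)
        XtWX = (X.T * w) @ X
        self.Vp_ = np.linalg.inv(XtWX + S + 1e-8 * np.eye(p))
        self.coef_ = beta
        self._finalize_terms(XtWX)
        return self

    def _finalize_terms(self, XtWX: np.ndarray) -> None:
        F = self.Vp_ @ XtWX          # edf matrix
        for term in self.terms:
            if term.kind == "intercept":
                term.edf = float(F[0, 0])
                continue
            term.edf = float(np.trace(F[term.sl, term.sl]))
            bj = self.coef_[term.sl]
            Vjj = self.Vp_[term.sl, term.sl]
            # Wald-type test on the term block (approximate reference df)
            Vinv = np.linalg.pinv(Vjj, rcond=1e-8)
            T = float(bj @ Vinv @ bj)
            df_ref = max(1.0, min(term.edf, term.sl.stop - term.sl.start))
            term.p_value = float(stats.chi2.sf(T, df_ref))

    # -- prediction --------------------------------------------------------

    def predict_link(self, df: pd.DataFrame) -> np.ndarray:
        if self.coef_ is None:
            raise FitError("model not fitted")
        X = self._build_design(df, training=False)
        return X @ self.coef_

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.predict_link(df), -30, 30)))

    def term_summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"term": t.name, "kind": t.kind, "edf": t.edf,
             "lambda": t.lams[0] if t.lams else np.nan,
             "p_value": t.p_value}
            for t in self.terms if t.kind != "intercept"])

    # -- partial dependence -------------------------------------------------

    def _find_term(self, covariate: str, mode: str | None, kind: str) -> GAMTerm:
        for t in self.terms:
            if t.kind == kind and t.covariate == covariate and (
                    kind != "mode_smooth" or t.mode == mode):
                return t
        raise KeyError(f"no {kind} term for {covariate!r} (mode={mode!r})")

    def partial_dependence(self, covariate: str, mode: str | None = None,
                           grid: np.ndarray | None = None,
                           n_grid: int = 200) -> pd.DataFrame:
        """Centered link-scale contribution of one per-mode smooth.

        Returns a frame with ``grid, effect, lo, hi`` (95% credible band).
        Values outside the training range trigger an extrapolation warning
        and are evaluated at the clipped boundary.
        """
        term = self._find_term(covariate, mode, "mode_smooth")
        if grid is None:
            grid = np.linspace(term.basis.lo, term.basis.hi, n_grid)
        else:
            grid = np.asarray(grid, dtype=float)
            if grid.min() < term.basis.lo or grid.max() > term.basis.hi:
                warnings.warn("partial-dependence grid outside observed "
                              "covariate range; extrapolating at boundary",
                              stacklevel=2)
        B = term.basis.design(grid) @ term.Z
        effect = B @ self.coef_[term.sl]
        se = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", B, self.Vp_[term.sl, term.sl], B), 0))
        return pd.DataFrame({"grid": grid, "effect": effect,
                             "lo": effect - 1.96 * se,
                             "hi": effect + 1.96 * se})

    def partial_dependence_surface(self, covariate: str,
                                   grid_x: np.ndarray | None = None,
                                   grid_e: np.ndarray | None = None,
                                   n_grid: int = 40) -> pd.DataFrame:
        """Centered contribution of a (covariate, E) tensor interaction."""
        term = self._find_term(covariate, None, "tensor")
        if grid_x is None:
            grid_x = np.linspace(term.basis.lo, term.basis.hi, n_grid)
        if grid_e is None:
            grid_e = np.linspace(term.basis2.lo, term.basis2.hi, n_grid)
        GX, GE = np.meshgrid(grid_x, grid_e, indexing="ij")
        B = _row_kron(term.basis.design(GX.ravel()),
                      term.basis2.design(GE.ravel())) @ term.Z
        effect = B @ self.coef_[term.sl]
        se = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", B, self.Vp_[term.sl, term.sl], B), 0))
        return pd.DataFrame({"grid_x": GX.ravel(), "grid_e": GE.ravel(),
                             "effect": effect, "lo": effect - 1.96 * se,
                             "hi": effect + 1.96 * se})


def effect_summary(pd_frame: pd.DataFrame) -> dict:
    """Optimal effect point and positive-effect range(s) of a PDP curve.

    The optimal point is the grid argmax of the effect; positive ranges are
    the maximal intervals where the effect exceeds zero, with end points
    linearly interpolated at the sign changes.
    """
    g = pd_frame["grid"].to_numpy()
    e = pd_frame["effect"].to_numpy()
    i_max = int(np.argmax(e))
    ranges: list[tuple[float, float]] = []
    pos = e > 0
    if pos.any():
        start = None
        for i in range(len(g)):
            if pos[i] and start is None:
                if i == 0:
                    start = g[0]
                else:   # interpolate crossing between i-1 and i
                    f = e[i - 1] / (e[i - 1] - e[i])
                    start = g[i - 1] + f * (g[i] - g[i - 1])
            if start is not None and (not pos[i] or i == len(g) - 1):
                if not pos[i]:
                    f = e[i - 1] / (e[i - 1] - e[i])
                    end = g[i - 1] + f * (g[i] - g[i - 1])
                else:
                    end = g[-1]
                ranges.append((float(start), float(end)))
                start = None
    return {"optimal_point": float(g[i_max]),
            "optimal_effect": float(e[i_max]),
            "positive_ranges": ranges}
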