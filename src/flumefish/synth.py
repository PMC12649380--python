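"""Synthetic flume, velocimeter, fish and trajectory generators.

Every stage of the analysis pipeline has a generator here that emulates the
statistical structure the analysis assumes, so the whole pipeline can be
exercised and validated without field data:

* :func:`gen_adv_series` — Gaussian 3-component velocity series with a
  prescribed mean, turbulent kinetic energy and Reynolds-stress targets
  (the exact inverse of the point-statistics estimator).
* :func:`gen_flow_field` — a smooth gridded flow field over the 6.0 m x
  0.5 m test area whose central-section mean speed equals the nominal
  velocity exactly, with faster water near one wall, TKE peaking where the
  velocity contrast is largest, and wall-hugging shear-stress bands.
* :func:`gen_fatigue` — fatigue times drawn from the two-regime Weibull AFT
  truth (default coefficients follow the fitted endurance model of the
  study species) with right-censoring.
* :func:`gen_trajectory` — a preference-driven walk: at each 1/18 s step
  four candidate headings are scored by a configurable selection function
  of the hydraulic-difference covariates, movement mode and endurance
  state, and the next position is drawn from the implied multinomial logit.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .endurance import SUSTAINED_THRESHOLD_BLS, TEST_AREA_LENGTH
from .errors import ConfigError
from .hydraulics import (FIELD_QUANTITIES, RHO_WATER, HydraulicField,
                         VelocityTimeSeries)
from .kinematics import Trajectory, classify_mode


@dataclass(frozen=True)
class FlumeGeometry:
    """Test-area grid layout: 25 sections x 5 points over 6.0 m x 0.5 m."""

    length: float = TEST_AREA_LENGTH
    width: float = 0.5
    n_sections: int = 25
    n_points: int = 5
    point_margin: float = 0.05    # lateral offset of the first point, m

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_sections)

    @property
    def y(self) -> np.ndarray:
        return self.point_margin + 0.10 * np.arange(self.n_points)

    @property
    def monitored_section(self) -> int:
        """Central monitoring cross-section (1-based): 12 for the 25-section
        layout, counted from the downstream end."""
        return (self.n_sections + 1) // 2 - 1


@dataclass(frozen=True)
class AFTTruth:
    """Generating truth for the two-regime Weibull AFT endurance model."""

    breakpoint: float = 6.13                  # BL/s
    prolonged_intercept: float = 6.29
    prolonged_vs: float = -0.94
    prolonged_bl: float = 6.98
    prolonged_log_scale: float = -0.86
    sprint_intercept: float = 9.87
    sprint_vs: float = -0.48
    sprint_bl: float = -7.81
    sprint_log_scale: float = -0.50

    def linear_predictor(self, vs_bls, bl_m) -> np.ndarray:
        vs = np.asarray(vs_bls, dtype=float)
        bl = np.broadcast_to(np.asarray(bl_m, dtype=float), vs.shape)
        sprint = vs > self.breakpoint
        return np.where(
            sprint,
            self.sprint_intercept + self.sprint_vs * vs + self.sprint_bl * bl,
            self.prolonged_intercept + self.prolonged_vs * vs
            + self.prolonged_bl * bl)

    def predict_T(self, vs_bls, bl_m) -> np.ndarray:
        return np.exp(self.linear_predictor(vs_bls, bl_m))

    def sigma(self, vs_bls) -> np.ndarray:
        sprint = np.asarray(vs_bls, dtype=float) > self.breakpoint
        return np.where(sprint, np.exp(self.sprint_log_scale),
                        np.exp(self.prolonged_log_scale))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror the flume study the pipeline targets: a 25 x 5 grid of
    25 Hz x 60 s velocimeter series, nominal velocities 1.80-2.50 m/s, 18 Hz
    trajectories of ~0.39 m fish, and the fitted endurance coefficients as
    the fatigue-time generating truth.
    """

    seed: int = 0
    geometry: FlumeGeometry = field(default_factory=FlumeGeometry)
    v_nom_levels: tuple[float, ...] = (1.80, 2.00, 2.20, 2.40, 2.50)
    n_fish_per_trial: int = 40
    bl_mean: float = 0.3916        # m
    bl_sd: float = 0.045           # m
    bl_min: float = 0.25           # truncation, m
    frame_rate: float = 18.0       # Hz
    adv_n: int = 1500              # 25 Hz x 60 s
    adv_rate: float = 25.0
    temp_mean: float = 12.84       # deg C
    temp_sd: float = 0.30
    do_mean: float = 6.18          # mg/L
    do_sd: float = 0.06
    aft_truth: AFTTruth = field(default_factory=AFTTruth)


# ---------------------------------------------------------------------------
# ADV series


def gen_adv_series(mean, tke_target: float, tau_targets=(0.0, 0.0, 0.0),
                   n: int = 1500, rng=None, sample_rate: float = 25.0,
                   location=(0.0, 0.0), rho: float = RHO_WATER,
                   variances=None) -> VelocityTimeSeries:
    """Gaussian velocity series with prescribed moments.

    The fluctuation covariance is built so the population estimators recover
    the targets in expectation: component variances sum to ``2 * tke_target``
    (split equally unless ``variances`` gives the (var_u, var_v, var_w)
    split) and ``cov(a, b) = -tau_ab / rho``.  Raises if the implied
    covariance is not positive semi-definite.
    """
    rng = np.random.default_rng(rng)
    mean = np.asarray(mean, dtype=float)
    if variances is None:
        variances = np.full(3, 2.0 * tke_target / 3.0)
    else:
        variances = np.asarray(variances, dtype=float)
    tau_uv, tau_uw, tau_vw = tau_targets
    cov = np.array([
        [variances[0], -tau_uv / rho, -tau_uw / rho],
        [-tau_uv / rho, variances[1], -tau_vw / rho],
        [-tau_uw / rho, -tau_vw / rho, variances[2]],
    ])
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-12 * max(1.0, eig.max()):
        raise ConfigError(
            f"TKE/stress targets imply a non-PSD covariance (min eig {eig.min():.3g})"
        )
    if np.allclose(cov, 0):
        samples = np.tile(mean, (n, 1))
    else:
        samples = rng.multivariate_normal(mean, cov, size=n,
                                          method="eigh")
    return VelocityTimeSeries(u=samples[:, 0], v=samples[:, 1],
                              w=samples[:, 2], sample_rate=sample_rate,
                              location=tuple(location))


# ---------------------------------------------------------------------------
# Flow field


def _tke_max(v_nom: float) -> float:
    # observed endpoints: 0.05 m^2/s^2 at 1.80 m/s, 0.30 at 2.50 m/s
    return float(np.interp(v_nom, [1.80, 2.50], [0.05, 0.30]))


def gen_flow_field(v_nom: float, geometry: FlumeGeometry | None = None,
                   seed: int = 0, monitored_section: int = 12
                   ) -> HydraulicField:
    """Smooth synthetic hydraulic field for one nominal-velocity level.

    The mean-speed surface increases upstream and toward the right bank
    (high y), and is rescaled so the mean point speed across the monitored
    cross-section equals ``v_nom`` exactly.  TKE peaks where the speed
    contrast is largest (upstream right bank) with a maximum interpolated
    from the study's observed range; shear-stress bands hug the walls.
    Deterministic given the seed.
    """
    if v_nom <= 0:
        raise ConfigError("v_nom must be positive")
    geom = geometry or FlumeGeometry()
    rng = np.random.default_rng(seed)
    x, y = geom.x, geom.y
    X, Y = np.meshgrid(x, y, indexing="ij")
    xn = X / geom.length                       # 0 downstream -> 1 upstream
    yn = (Y - y.mean()) / geom.width           # centred lateral coordinate

    # smooth unit-scale speed shape plus a small seeded harmonic perturbation
    shape = 1.0 + 0.18 * (xn - 0.5) + 0.22 * yn + 0.06 * xn * yn
    phase = rng.uniform(0, 2 * np.pi, size=2)
    shape *= 1.0 + 0.015 * np.sin(2 * np.pi * xn + phase[0]) \
        * np.cos(np.pi * yn * 2 + phase[1])
    angle = 0.06 * yn * np.sin(np.pi * xn)     # small lateral flow component

    speed = v_nom * shape
    sec = speed[monitored_section - 1, :]
    speed *= v_nom / sec.mean()                # exact nominal-velocity anchor
    # flow runs downstream (negative x in this frame)
    u_bar = -speed * np.cos(angle)
    v_bar = speed * np.sin(angle)
    speed = np.hypot(u_bar, v_bar)

    tke_shape = np.exp(-((xn - 0.85) ** 2) / 0.18
                       - ((yn - 0.35) ** 2) / 0.08)
    tke = _tke_max(v_nom) * (0.12 + 0.88 * tke_shape)

    wall = 2.0 * yn                            # -1 at left wall, +1 at right
    tau_scale = v_nom / 2.50
    tau_uv = 7.55 * tau_scale * np.sign(wall) * np.abs(wall) ** 3
    tau_uw = 5.0 * tau_scale * np.sin(3 * np.pi * xn + phase[0]) * wall ** 2
    tau_vw = 2.9 * tau_scale * np.cos(2 * np.pi * xn + phase[1]) * wall ** 2

    data = {"u_bar": u_bar, "v_bar": v_bar,
            "w_bar": np.zeros_like(u_bar), "speed": speed,
            "tke": tke, "tau_uv": tau_uv, "tau_uw": tau_uw,
            "tau_vw": tau_vw}
    return HydraulicField(x=x, y=y, data=data)


# ---------------------------------------------------------------------------
# Fish and fatigue times


def gen_fish(n: int, rng=None, config: SimulationConfig | None = None
             ) -> pd.DataFrame:
    """Fish metadata table: body length (truncated normal), Temp, DO."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(rng)
    bl = rng.normal(cfg.bl_mean, cfg.bl_sd, size=4 * n)
    bl = bl[bl > cfg.bl_min][:n]
    while bl.size < n:
        extra = rng.normal(cfg.bl_mean, cfg.bl_sd, size=n)
        bl = np.concatenate([bl, extra[extra > cfg.bl_min]])[:n]
    return pd.DataFrame({
        "fish_id": [f"fish{i:03d}" for i in range(n)],
        "BL_m": bl,
        "Temp_C": rng.normal(cfg.temp_mean, cfg.temp_sd, size=n),
        "DO_mgL": rng.normal(cfg.do_mean, cfg.do_sd, size=n),
    })


def gen_fatigue(fish: pd.DataFrame, truth: AFTTruth | None = None,
                rng=None, censor_fraction: float | None = 0.10
                ) -> pd.DataFrame:
    """Fatigue records drawn from the two-regime Weibull AFT truth.

    ``fish`` must carry ``mean_Vs_bls`` and ``BL_m`` (plus any extra
    covariates to pass through).  ``ln T`` is the regime linear predictor
    plus ``sigma * log(Exp(1))`` (a standard minimum-extreme-value error,
    i.e. Weibull time).  With ``censor_fraction`` set, each record is
    right-censored at its own conditional ``1 - f`` survival quantile, so
    every fish independently has probability ``f`` of traversing the test
    area before fatiguing — independent censoring, as the estimator assumes.
    """
    truth = truth or AFTTruth()
    rng = np.random.default_rng(rng)
    vs = fish["mean_Vs_bls"].to_numpy(dtype=float)
    bl = fish["BL_m"].to_numpy(dtype=float)
    lp = truth.linear_predictor(vs, bl)
    sigma = truth.sigma(vs)
    log_t = lp + sigma * np.log(rng.exponential(size=vs.size))
    t = np.exp(log_t)
    censored = np.zeros(vs.size, dtype=bool)
    if censor_fraction and censor_fraction > 0:
        # S(c | x) = f  =>  ln c = lp + sigma * ln(-ln f)
        c = np.exp(lp + sigma * np.log(-np.log(censor_fraction)))
        censored = t > c
        t = np.minimum(t, c)
    out = fish.copy()
    out["T_s"] = t
    out["censored"] = censored
    return out


# ---------------------------------------------------------------------------
# Preference-driven trajectories


class SelectionTruth:
    """Additive link-scale selection function over candidate points.

    Terms are additive contributions matching the RSF-GAMM structure:
    per-mode (or mode-independent) functions of one hydraulic-difference
    covariate, plus optional (covariate, E) interaction surfaces.  A null
    truth scores every candidate equally (uniform choice).
    """

    def __init__(self):
        self._terms: list[tuple[str, str | None, callable]] = []
        self._interactions: list[tuple[str, callable]] = []

    @classmethod
    def null(cls) -> "SelectionTruth":
        return cls()

    def add_smooth(self, covariate: str, func, mode: str | None = None
                   ) -> "SelectionTruth":
        self._terms.append((covariate, mode, func))
        return self

    def add_interaction(self, covariate: str, func) -> "SelectionTruth":
        """``func(x, E)`` contribution."""
        self._interactions.append((covariate, func))
        return self

    @classmethod
    def inverted_u(cls, covariate: str, center: float, width: float,
                   amplitude: float, mode: str | None = None
                   ) -> "SelectionTruth":
        """Single-peak preference: amplitude * (1 - ((x - center)/width)^2)."""
        truth = cls()
        truth.add_smooth(
            covariate,
            lambda x: amplitude * (1.0 - ((x - center) / width) ** 2),
            mode=mode)
        return truth

    def score(self, covs: dict[str, np.ndarray], modes: np.ndarray,
              e_state: float) -> np.ndarray:
        n = len(modes)
        s = np.zeros(n)
        for cov, mode, func in self._terms:
            vals = func(np.asarray(covs[cov], dtype=float))
            if mode is None:
                s += vals
            else:
                s += np.where(modes == mode, vals, 0.0)
        for cov, func in self._interactions:
            s += func(np.asarray(covs[cov], dtype=float), e_state)
        return s

    def describe(self) -> dict:
        return {"n_smooths": len(self._terms),
                "n_interactions": len(self._interactions)}


_COV_FOR_QUANTITY = {"u_bar": "du", "v_bar": "dv", "tke": "dtke",
                     "tau_uv": "dtau_uv", "tau_uw": "dtau_uw",
                     "tau_vw": "dtau_vw"}


def gen_trajectory(field: HydraulicField, fish_id: str, body_length: float,
                   selection_truth: SelectionTruth | None = None,
                   aft_truth: AFTTruth | None = None,
                   rng=None, n_steps: int = 500,
                   frame_rate: float = 18.0,
                   vg_mean_bls: float = 2.0, vg_cv: float = 0.4,
                   start: tuple[float, float] | None = None,
                   threshold: float = SUSTAINED_THRESHOLD_BLS) -> Trajectory:
    """Preference-driven 18 Hz walk through the hydraulic field.

    Per step, a ground speed is drawn log-normal (mean ``vg_mean_bls`` BL/s,
    coefficient of variation ``vg_cv``), the four candidate headings
    (forward plus three rotations of the current heading) are scored by the
    selection truth on their hydraulic-difference covariates, candidate
    movement mode and current endurance state, and the next position is a
    multinomial-logit draw among in-domain candidates.  Endurance depletes
    according to the AFT truth at supra-threshold swim speeds.  The walk
    terminates early (flagged in ``frames.attrs['terminated_trapped']``) if
    no candidate stays in the domain.
    """
    truth = selection_truth or SelectionTruth.null()
    aft = aft_truth or AFTTruth()
    rng = np.random.default_rng(rng)
    xmin, xmax, ymin, ymax = field.bounds
    if start is None:
        start = (xmin + 0.05 * (xmax - xmin), 0.5 * (ymin + ymax))
    pos = np.array(start, dtype=float)
    if not field.contains(pos[None, :])[0]:
        raise ConfigError("start position outside the field domain")
    heading = np.array([1.0, 0.0])      # upstream (+x) initially
    e_state = 1.0
    log_sd = np.sqrt(np.log(1 + vg_cv ** 2))
    log_mu = np.log(vg_mean_bls * body_length) - log_sd ** 2 / 2

    xs, ys = [pos[0]], [pos[1]]
    trapped = False
    for _ in range(n_steps):
        speed = rng.lognormal(log_mu, log_sd)
        r = speed / frame_rate
        h = heading / np.linalg.norm(heading)
        dirs = np.array([h, [-h[1], h[0]], -h, [h[1], -h[0]]])
        cands = pos + r * dirs
        inside = field.contains(cands)
        if not inside.any():
            trapped = True
            break
        cands, dirs = cands[inside], dirs[inside]
        ref = field.interpolate(pos)
        q = field.interpolate(cands)
        covs = {_COV_FOR_QUANTITY[k]: np.atleast_1d(q[k]) - ref[k]
                for k in _COV_FOR_QUANTITY}
        vf = np.array([ref["u_bar"], ref["v_bar"]])
        vg_vecs = dirs * speed
        modes = classify_mode(vg_vecs, np.tile(vf, (len(dirs), 1)),
                              stationary_speed=0.0)
        scores = truth.score(covs, modes, e_state)
        p = np.exp(scores - scores.max())
        choice = rng.choice(len(cands), p=p / p.sum())
        vs_vec = vg_vecs[choice] - vf
        vs_bls = np.linalg.norm(vs_vec) / body_length
        if vs_bls > threshold:
            e_state = max(0.0, e_state - (1.0 / frame_rate)
                          / float(aft.predict_T(vs_bls, body_length)))
        heading = dirs[choice]
        pos = cands[choice]
        xs.append(pos[0])
        ys.append(pos[1])

    frames = pd.DataFrame({
        "t_s": np.arange(len(xs)) / frame_rate,
        "x_m": xs, "y_m": ys,
    })
    frames.attrs["terminated_trapped"] = trapped
    traj = Trajectory(fish_id=fish_id, body_length=body_length,
                      frames=frames, frame_rate=frame_rate)
    return traj


# ---------------------------------------------------------------------------
# Full dataset emission


def write_dataset(outdir: str | Path, config: SimulationConfig | None = None,
                  n_fish: int = 5, n_steps: int = 300,
                  v_nom: float | None = None,
                  selection_truth: SelectionTruth | None = None,
                  adv_n: int | None = None) -> dict:
    """Emit a complete synthetic dataset in the CSV formats the readers consume.

    Writes the ADV manifest + per-point series, the trajectory table, the
    fish metadata table, and a truth JSON with all generating parameters.
    Returns the path map.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    v = v_nom if v_nom is not None else cfg.v_nom_levels[-1]
    field_true = gen_flow_field(v, cfg.geometry, seed=cfg.seed)
    n = adv_n if adv_n is not None else cfg.adv_n

    adv_dir = outdir / "adv"
    adv_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for i, xv in enumerate(field_true.x):
        for j, yv in enumerate(field_true.y):
            point = {q: field_true.data[q][i, j] for q in FIELD_QUANTITIES}
            series = gen_adv_series(
                mean=(point["u_bar"], point["v_bar"], point["w_bar"]),
                tke_target=point["tke"],
                tau_targets=(point["tau_uv"], point["tau_uw"],
                             point["tau_vw"]),
                n=n, rng=rng, sample_rate=cfg.adv_rate, location=(xv, yv))
            fname = f"adv_s{i + 1:02d}_p{j + 1}.csv"
            pd.DataFrame({
                "time_s": np.arange(n) / cfg.adv_rate,
                "u_ms": series.u, "v_ms": series.v, "w_ms": series.w,
            }).to_csv(adv_dir / fname, index=False, float_format="%.5f")
            manifest_rows.append({"file": fname, "section": i + 1,
                                  "point": j + 1, "x_m": xv, "y_m": yv})
    manifest_path = adv_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)

    fish = gen_fish(n_fish, rng=rng, config=cfg)
    fish["trial"] = 1
    fish["V_nom"] = v
    fish_path = outdir / "fish.csv"
    fish.to_csv(fish_path, index=False)

    frames = []
    for _, row in fish.iterrows():
        traj = gen_trajectory(field_true, row["fish_id"], row["BL_m"],
                              selection_truth=selection_truth,
                              aft_truth=cfg.aft_truth, rng=rng,
                              n_steps=n_steps, frame_rate=cfg.frame_rate)
        f = traj.frames.copy()
        f.insert(0, "fish_id", row["fish_id"])
        frames.append(f)
    traj_path = outdir / "trajectories.csv"
    pd.concat(frames, ignore_index=True).to_csv(traj_path, index=False,
                                                float_format="%.6f")

    truth_path = outdir / "truth.json"
    truth = {
        "seed": cfg.seed,
        "v_nom": v,
        "n_fish": n_fish,
        "n_steps": n_steps,
        "aft_truth": asdict(cfg.aft_truth),
        "selection_truth": (selection_truth or SelectionTruth.null()
                            ).describe(),
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"manifest": manifest_path, "fish": fish_path,
            "trajectories": traj_path, "truth": truth_path}
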