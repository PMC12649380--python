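"""Trajectory kinematics: velocity vectors, movement-mode classification, profiles.

From frame-wise fish positions sampled at a fixed rate (18 Hz video tracking)
we derive, per step,

* the ground velocity ``Vg = displacement * frame_rate`` (fixed frame),
* the local flow velocity ``Vf`` interpolated from a hydraulic field at the
  step's starting position,
* the swim velocity ``Vs = Vg - Vf`` — the fish's effort through the water,

and classify the movement mode from the angle theta between ``Vg`` and ``Vf``:
downstream for theta in [0, pi/3), cross-stream for [pi/3, 2pi/3], upstream
for (2pi/3, pi].  Steps slower than a configurable stationary threshold are
labelled ``stationary`` and excluded from selection analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StructuralError, UndefinedAngleError, UndefinedStatisticError
from .hydraulics import HydraulicField

#: Video tracking frame rate, Hz.
DEFAULT_FRAME_RATE = 18.0

#: Stationary-step threshold as a fraction of body length per second.
DEFAULT_STATIONARY_BLS = 0.05

MODE_STATIONARY = "stationary"
MODE_DOWNSTREAM = "downstream"
MODE_CROSS = "cross"
MODE_UPSTREAM = "upstream"
MOVEMENT_MODES = (MODE_UPSTREAM, MODE_CROSS, MODE_DOWNSTREAM)


@dataclass
class Trajectory:
    """One fish's tracked positions plus metadata.

    ``frames`` is a DataFrame with columns ``t_s, x_m, y_m`` (strictly
    increasing timestamps).
    """

    fish_id: str
    body_length: float           # m
    frames: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    v_nom: float | None = None   # trial nominal velocity, m/s

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise StructuralError("body_length must be positive")
        t = self.frames["t_s"].to_numpy()
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise StructuralError(
                f"{self.fish_id}: timestamps must be strictly increasing"
            )


def ground_velocity(positions: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-step ground-velocity vectors from an (n, 2) position array.

    Returns an (n-1, 2) array; step k spans frames k -> k+1.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise StructuralError("need an (n>=2, 2) position array")
    return np.diff(pos, axis=0) * frame_rate


def swim_velocity(vg: np.ndarray, vf: np.ndarray) -> np.ndarray:
    """Swim velocity ``Vs = Vg - Vf`` (componentwise, same frame)."""
    return np.asarray(vg, dtype=float) - np.asarray(vf, dtype=float)


def classify_mode(vg: np.ndarray, vf: np.ndarray,
                  stationary_speed: float) -> np.ndarray:
    """Movement mode per step from the angle between Vg and Vf.

    ``vg``/``vf`` are (n, 2) (or single (2,)) vectors; ``stationary_speed``
    is in m/s (typically 0.05 BL/s * body length).  Depends only on the
    angle, so rescaling either vector's magnitude leaves the label unchanged.
    """
    vg = np.atleast_2d(np.asarray(vg, dtype=float))
    vf = np.atleast_2d(np.asarray(vf, dtype=float))
    speed_g = np.linalg.norm(vg, axis=1)
    speed_f = np.linalg.norm(vf, axis=1)
    moving = speed_g > stationary_speed
    if np.any(moving & (speed_f == 0)):
        raise UndefinedAngleError("zero flow vector: mode angle undefined")
    modes = np.full(vg.shape[0], MODE_STATIONARY, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", vg, vf) / (speed_g * speed_f)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    # half-open bins with cross-stream closed on both ends
    modes[moving & (theta < np.pi / 3)] = MODE_DOWNSTREAM
    modes[moving & (theta >= np.pi / 3) & (theta <= 2 * np.pi / 3)] = MODE_CROSS
    modes[moving & (theta > 2 * np.pi / 3)] = MODE_UPSTREAM
    return modes if modes.size > 1 else modes[:1]


def step_table(trajectory: Trajectory, field: HydraulicField,
               stationary_bls: float = DEFAULT_STATIONARY_BLS) -> pd.DataFrame:
    """Per-step kinematics table for one trajectory.

    Flow velocity is attached at each step's starting position; steps that
    start outside the field domain are dropped (their count is recorded in
    ``df.attrs['n_dropped_out_of_domain']``).  Speeds are reported both in
    m/s and body lengths per second (columns suffixed ``_bls``).
    """
    pos = trajectory.frames[["x_m", "y_m"]].to_numpy()
    t = trajectory.frames["t_s"].to_numpy()
    vg = ground_velocity(pos, trajectory.frame_rate)
    starts = pos[:-1]
    inside = field.contains(starts)
    n_dropped = int((~inside).sum())

    idx = np.flatnonzero(inside)
    q = field.interpolate(starts[idx]) if idx.size else {
        "u_bar": np.empty(0), "v_bar": np.empty(0)}
    vf = np.column_stack([np.atleast_1d(q["u_bar"]), np.atleast_1d(q["v_bar"])])
    vg_in = vg[idx]
    vs = swim_velocity(vg_in, vf)
    stationary_speed = stationary_bls * trajectory.body_length
    modes = classify_mode(vg_in, vf, stationary_speed)

    bl = trajectory.body_length
    df = pd.DataFrame({
        "fish_id": trajectory.fish_id,
        "step": idx,
        "t_s": t[idx],
        "x_m": starts[idx, 0],
        "y_m": starts[idx, 1],
        "x1_m": pos[idx + 1, 0],
        "y1_m": pos[idx + 1, 1],
        "vg_x": vg_in[:, 0], "vg_y": vg_in[:, 1],
        "vf_x": vf[:, 0], "vf_y": vf[:, 1],
        "vs_x": vs[:, 0], "vs_y": vs[:, 1],
        "vg": np.linalg.norm(vg_in, axis=1),
        "vf": np.linalg.norm(vf, axis=1),
        "vs": np.linalg.norm(vs, axis=1),
        "mode": modes,
    })
    df["vg_bls"] = df["vg"] / bl
    df["vf_bls"] = df["vf"] / bl
    df["vs_bls"] = df["vs"] / bl
    df.attrs["n_dropped_out_of_domain"] = n_dropped
    df.attrs["body_length"] = bl
    df.attrs["frame_rate"] = trajectory.frame_rate
    return df


def bin_speed_profile(steps: pd.DataFrame, bin_width: float = 0.1,
                      mode: str | None = None,
                      speed_cols: tuple[str, ...] = ("vs_bls", "vf_bls", "vg_bls"),
                      x_col: str = "x_m") -> pd.DataFrame:
    """Binned speed profile along movement distance x.

    Pools all steps (optionally filtered to one movement mode) into bins of
    ``bin_width`` metres and reports, per bin and speed column, the mean and
    normal-approximation 95% CI (mean +/- 1.96 * SE).  Bins with a single
    observation report the mean with missing CI; empty bins are omitted.
    """
    df = steps if mode is None else steps[steps["mode"] == mode]
    if df.empty:
        return pd.DataFrame(columns=["x_bin", "n"])
    bins = np.floor(df[x_col].to_numpy() / bin_width).astype(int)
    out = []
    for b in np.unique(bins):
        sel = df[bins == b]
        row: dict[str, float] = {"x_bin": (b + 0.5) * bin_width, "n": len(sel)}
        for col in speed_cols:
            vals = sel[col].to_numpy()
            m = float(vals.mean())
            row[f"{col}_mean"] = m
            if vals.size > 1:
                se = vals.std(ddof=1) / np.sqrt(vals.size)
                row[f"{col}_lo"] = m - 1.96 * se
                row[f"{col}_hi"] = m + 1.96 * se
            else:
                row[f"{col}_lo"] = np.nan
                row[f"{col}_hi"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def profile_stats(series_a: np.ndarray, series_b: np.ndarray
                  ) -> dict[str, float]:
    """Pearson correlation between two profiles plus per-series CV (%).

    CV = SD/mean * 100 (sample SD).  Raises if either series has zero
    variance (correlation undefined).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise StructuralError("profiles must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero-variance series: r undefined")
    r, p = stats.pearsonr(a, b)
    return {
        "r": float(r),
        "p_value": float(p),
        "cv_a_pct": float(a.std(ddof=1) / a.mean() * 100),
        "cv_b_pct": float(b.std(ddof=1) / b.mean() * 100),
    }


# ---------------------------------------------------------------------------
# CSV ingestion


def read_trajectories(traj_path, meta_path,
                      frame_rate: float = DEFAULT_FRAME_RATE
                      ) -> list[Trajectory]:
    """Load trajectories from a frames CSV plus a fish-metadata CSV.

    Frames CSV: ``fish_id, t_s, x_m, y_m``.  Metadata CSV: ``fish_id, BL_m``
    and optionally ``trial, V_nom``.
    """
    frames = pd.read_csv(traj_path)
    meta = pd.read_csv(meta_path).set_index("fish_id")
    out = []
    for fish_id, grp in frames.groupby("fish_id", sort=False):
        if fish_id not in meta.index:
            raise StructuralError(f"no metadata for fish {fish_id!r}")
        row = meta.loc[fish_id]
        out.append(Trajectory(
            fish_id=str(fish_id),
            body_length=float(row["BL_m"]),
            frames=grp[["t_s", "x_m", "y_m"]].reset_index(drop=True),
            frame_rate=frame_rate,
            v_nom=float(row["V_nom"]) if "V_nom" in row else None,
        ))
    return out
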