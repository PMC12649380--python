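"""Hydraulic statistics from velocimeter time series and gridded field interpolation.

An acoustic Doppler velocimeter (ADV) records instantaneous 3-component
velocities ``(u, v, w)`` — longitudinal, lateral, vertical — at a fixed point.
From each series we derive time-averaged velocities, turbulent kinetic energy

    TKE = 1/2 * (var(u) + var(v) + var(w))            [m^2/s^2]

and the three Reynolds shear stress components

    tau_ab = -rho * cov(a, b)                          [N/m^2]

with population (1/n) variances and covariances and water density
``rho = 1000 kg/m^3``.  Statistics computed on a rectangular grid of
measurement points form a :class:`HydraulicField`, which supports bilinear
interpolation of every quantity at arbitrary in-domain positions, so that
hydraulic covariates can be attached to fish positions.

Coordinate convention: ``x`` increases upstream along the test area from its
downstream end, ``y`` across the channel width; all positions in metres.  The
time-averaged longitudinal velocity ``u_bar`` is signed in this frame (flow
moves downstream, i.e. toward negative ``x``); ``speed`` is the magnitude of
the mean horizontal velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    DegenerateSeriesError,
    IncompleteSectionError,
    OutOfDomainError,
    StructuralError,
)

#: Water density, kg/m^3.
RHO_WATER = 1000.0

#: Quantities stored per grid node and available from interpolation.
FIELD_QUANTITIES = ("u_bar", "v_bar", "w_bar", "speed", "tke",
                    "tau_uv", "tau_uw", "tau_vw")


@dataclass(frozen=True)
class VelocityTimeSeries:
    """Raw 3-component instantaneous velocities at one measurement point."""

    u: np.ndarray            # longitudinal, m/s
    v: np.ndarray            # lateral, m/s
    w: np.ndarray            # vertical, m/s
    sample_rate: float       # Hz
    location: tuple[float, float] = (0.0, 0.0)   # (x, y), m

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if not (u.shape == v.shape == w.shape) or u.ndim != 1:
            raise StructuralError(
                "u, v, w must be one-dimensional arrays of equal length"
            )
        if self.sample_rate <= 0:
            raise StructuralError("sample_rate must be positive")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", w)

    @property
    def n(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class HydraulicPoint:
    """Time-averaged hydraulic statistics at one grid node."""

    location: tuple[float, float]
    u_bar: float
    v_bar: float
    w_bar: float
    speed: float      # |mean horizontal velocity|, m/s
    tke: float        # m^2/s^2
    tau_uv: float     # N/m^2
    tau_uw: float
    tau_vw: float


def compute_point_stats(series: VelocityTimeSeries,
                        rho: float = RHO_WATER) -> HydraulicPoint:
    """Reduce one velocity series to its hydraulic point statistics.

    Variances and covariances use the 1/n (population) divisor.  The
    Reynolds stresses are ``-rho`` times the fluctuation covariances, so a
    positive correlation between ``u`` and ``v`` fluctuations yields a
    negative ``tau_uv``.
    """
    if series.n < 2:
        raise DegenerateSeriesError(
            f"need at least 2 samples to estimate fluctuations, got {series.n}"
        )
    u, v, w = series.u, series.v, series.w
    du, dv, dw = u - u.mean(), v - v.mean(), w - w.mean()
    tke = 0.5 * (np.mean(du ** 2) + np.mean(dv ** 2) + np.mean(dw ** 2))
    return HydraulicPoint(
        location=series.location,
        u_bar=float(u.mean()),
        v_bar=float(v.mean()),
        w_bar=float(w.mean()),
        speed=float(np.hypot(u.mean(), v.mean())),
        tke=float(tke),
        tau_uv=float(-rho * np.mean(du * dv)),
        tau_uw=float(-rho * np.mean(du * dw)),
        tau_vw=float(-rho * np.mean(dv * dw)),
    )


@dataclass
class HydraulicField:
    """Gridded hydraulic statistics over the rectangular test area.

    ``x`` holds the section coordinates (sections run downstream to
    upstream), ``y`` the cross-channel point coordinates.  Each quantity is a
    ``(len(x), len(y))`` array.  Interpolation is bilinear, exact at nodes.
    """

    x: np.ndarray                      # section coordinates, m, ascending
    y: np.ndarray                      # lateral coordinates, m, ascending
    data: dict[str, np.ndarray]        # quantity -> (nx, ny) array
    rho: float = RHO_WATER
    _interp: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise StructuralError("grid coordinates must be strictly ascending")
        for name in FIELD_QUANTITIES:
            if name not in self.data:
                raise StructuralError(f"field quantity {name!r} missing")
            arr = np.asarray(self.data[name], dtype=float)
            if arr.shape != (self.x.size, self.y.size):
                raise StructuralError(
                    f"{name}: expected shape {(self.x.size, self.y.size)}, "
                    f"got {arr.shape}"
                )
            self.data[name] = arr
        self._interp = {
            name: RegularGridInterpolator(
                (self.x, self.y), self.data[name],
                method="linear", bounds_error=True)
            for name in FIELD_QUANTITIES
        }

    # -- geometry ----------------------------------------------------------

    @property
    def n_sections(self) -> int:
        return self.x.size

    @property
    def n_points(self) -> int:
        return self.y.size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the interpolable domain."""
        return float(self.x[0]), float(self.x[-1]), float(self.y[0]), float(self.y[-1])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized in-domain test for an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xmin, xmax, ymin, ymax = self.bounds
        return ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
                & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))

    # -- interpolation -----------------------------------------------------

    def interpolate(self, point: Sequence[float] | np.ndarray,
                    quantities: Iterable[str] = FIELD_QUANTITIES
                    ) -> dict[str, np.ndarray | float]:
        """Bilinear interpolation of the requested quantities.

        ``point`` is a single (x, y) pair or an (n, 2) array.  Raises
        :class:`OutOfDomainError` if any query point lies outside the grid's
        bounding rectangle; callers decide whether to clip or discard.
        """
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        if not np.all(self.contains(pts)):
            raise OutOfDomainError(
                f"query point(s) outside grid domain {self.bounds}"
            )
        scalar = np.asarray(point).ndim == 1
        out: dict[str, np.ndarray | float] = {}
        for name in quantities:
            vals = self._interp[name](pts)
            out[name] = float(vals[0]) if scalar else vals
        return out

    def flow_vector(self, point) -> np.ndarray:
        """Mean horizontal flow velocity (u_bar, v_bar) at point(s)."""
        q = self.interpolate(point, quantities=("u_bar", "v_bar"))
        return np.stack([np.atleast_1d(q["u_bar"]),
                         np.atleast_1d(q["v_bar"])], axis=-1).squeeze()

    # -- summaries ---------------------------------------------------------

    def compute_vnom(self, section_index: int) -> float:
        """Nominal velocity: mean point speed across one monitoring section.

        ``section_index`` is 1-based, numbered downstream to upstream; the
        central monitoring cross-section of a 25-section layout is 12.
        """
        if not 1 <= section_index <= self.n_sections:
            raise IncompleteSectionError(
                f"section {section_index} outside 1..{self.n_sections}"
            )
        speeds = self.data["speed"][section_index - 1, :]
        if not np.all(np.isfinite(speeds)):
            raise IncompleteSectionError(
                f"section {section_index} has non-finite point speeds"
            )
        return float(speeds.mean())

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per grid node with all stored quantities."""
        xi, yi = np.meshgrid(np.arange(self.x.size), np.arange(self.y.size),
                             indexing="ij")
        rows = {
            "section": xi.ravel() + 1,
            "point": yi.ravel() + 1,
            "x_m": self.x[xi.ravel()],
            "y_m": self.y[yi.ravel()],
        }
        for name in FIELD_QUANTITIES:
            rows[name] = self.data[name].ravel()
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rho: float = RHO_WATER) -> "HydraulicField":
        """Rebuild a field from :meth:`to_frame` output."""
        x = np.sort(df["x_m"].unique())
        y = np.sort(df["y_m"].unique())
        if len(df) != x.size * y.size:
            raise StructuralError("field table is not a complete grid")
        pivot = {name: df.pivot_table(index="x_m", columns="y_m",
                                      values=name).to_numpy()
                 for name in FIELD_QUANTITIES}
        return cls(x=x, y=y, data=pivot, rho=rho)


def field_from_point_stats(points: Iterable[HydraulicPoint],
                           rho: float = RHO_WATER) -> HydraulicField:
    """Assemble a :class:`HydraulicField` from per-node statistics.

    Node locations must form a complete rectangular grid.
    """
    pts = list(points)
    xs = np.sort(np.unique([p.location[0] for p in pts]))
    ys = np.sort(np.unique([p.location[1] for p in pts]))
    if len(pts) != xs.size * ys.size:
        raise StructuralError(
            f"{len(pts)} points do not fill a {xs.size} x {ys.size} grid"
        )
    data = {name: np.full((xs.size, ys.size), np.nan) for name in FIELD_QUANTITIES}
    for p in pts:
        i = int(np.searchsorted(xs, p.location[0]))
        j = int(np.searchsorted(ys, p.location[1]))
        for name in FIELD_QUANTITIES:
            data[name][i, j] = getattr(p, name)
    if any(np.isnan(data[name]).any() for name in FIELD_QUANTITIES):
        raise StructuralError("grid has duplicate or missing node locations")
    return HydraulicField(x=xs, y=ys, data=data, rho=rho)


# ---------------------------------------------------------------------------
# ADV CSV ingestion


def read_adv_field(manifest_path: str | Path, rho: float = RHO_WATER
                   ) -> HydraulicField:
    """Build a field from an ADV manifest plus per-point series CSVs.

    The manifest CSV has columns ``file, section, point, x_m, y_m``; each
    referenced file has columns ``time_s, u_ms, v_ms, w_ms``.  Paths in the
    manifest are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"file", "section", "point", "x_m", "y_m"}
    if not required.issubset(manifest.columns):
        raise StructuralError(f"manifest needs columns {sorted(required)}")
    points = []
    for _, row in manifest.iterrows():
        series_df = pd.read_csv(manifest_path.parent / row["file"])
        t = series_df["time_s"].to_numpy()
        if t.size < 2:
            raise DegenerateSeriesError(f"{row['file']}: fewer than 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        ts = VelocityTimeSeries(
            u=series_df["u_ms"].to_numpy(),
            v=series_df["v_ms"].to_numpy(),
            w=series_df["w_ms"].to_numpy(),
            sample_rate=rate,
            location=(float(row["x_m"]), float(row["y_m"])),
        )
        points.append(compute_point_stats(ts, rho=rho))
    return field_from_point_stats(points, rho=rho)
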