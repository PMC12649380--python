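"""End-to-end orchestration: hydraulics -> kinematics -> endurance -> behavior.

Reads the CSV inputs (ADV manifest + series, trajectories, fish metadata)
under a YAML-configurable set of constants, runs the four analysis stages in
order, and writes the report bundle: field table, per-step table, binned
speed profiles, endurance model reports (covariate-subset ranking and
per-regime coefficient tables), the use-availability table, cross-validation
metrics and partial-dependence summaries.  Every output CSV gets a JSON
provenance sidecar (config hash, seed, package version) and every stage logs
its dropped-row counts so the multiple filters (stationary steps,
sustained-only fish, out-of-domain candidates) stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, endurance, kinematics
from .errors import ConfigError, FitError
from .gam import GAMSpec
from .hydraulics import read_adv_field

log = logging.getLogger("flumefish")


@dataclass
class RunConfig:
    """Paths and constants for one pipeline run."""

    adv_manifest: str = ""
    trajectories: str = ""
    fish_metadata: str = ""
    output_dir: str = "flumefish_out"
    seed: int = 0
    frame_rate: float = 18.0
    rho: float = 1000.0
    sustained_threshold_bls: float = endurance.SUSTAINED_THRESHOLD_BLS
    stationary_threshold_bls: float = kinematics.DEFAULT_STATIONARY_BLS
    bin_width_m: float = 0.1
    test_area_length_m: float = endurance.TEST_AREA_LENGTH
    cv_folds: int = 10
    basis_dimension: int = 5
    aft_covariates: tuple[str, ...] = ("Vs", "BL")
    records_per: str = "excursion"
    run_behavior: bool = True
    run_cv: bool = True

    def __post_init__(self) -> None:
        for name in ("frame_rate", "rho", "sustained_threshold_bls",
                     "bin_width_m", "test_area_length_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 3 <= self.basis_dimension <= 5:
            raise ConfigError("basis_dimension must be within 3..5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for name in ("adv_manifest", "trajectories", "fish_metadata"):
            p = getattr(cfg, name)
            if p and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    df.to_csv(path, index=False)
    sidecar = {"config_hash": config.digest(), "seed": config.seed,
               "version": __version__, "rows": len(df)}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every enabled stage; returns the output-path manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        _write(df, path, config)
        written[name] = path

    try:
        # -- hydraulics ---------------------------------------------------
        field_obj = read_adv_field(config.adv_manifest, rho=config.rho)
        emit("field", field_obj.to_frame())
        central = (field_obj.n_sections + 1) // 2 - 1
        log.info("hydraulics: %d x %d grid, V_nom(section %d) = %.3f m/s",
                 field_obj.n_sections, field_obj.n_points, central,
                 field_obj.compute_vnom(central))

        # -- kinematics ---------------------------------------------------
        trajectories = kinematics.read_trajectories(
            config.trajectories, config.fish_metadata,
            frame_rate=config.frame_rate)
        steps_by_fish = {}
        dropped = 0
        for traj in trajectories:
            st = kinematics.step_table(
                traj, field_obj,
                stationary_bls=config.stationary_threshold_bls)
            dropped += st.attrs["n_dropped_out_of_domain"]
            steps_by_fish[traj.fish_id] = (traj, st)
        all_steps = pd.concat([s for _, s in steps_by_fish.values()],
                              ignore_index=True)
        emit("steps", all_steps)
        log.info("kinematics: %d steps from %d fish (%d dropped out of domain)",
                 len(all_steps), len(trajectories), dropped)
        profiles = []
        for mode in kinematics.MOVEMENT_MODES:
            prof = kinematics.bin_speed_profile(
                all_steps, bin_width=config.bin_width_m, mode=mode)
            prof.insert(0, "mode", mode)
            profiles.append(prof)
        emit("speed_profiles", pd.concat(profiles, ignore_index=True))

        # -- endurance ----------------------------------------------------
        meta = pd.read_csv(config.fish_metadata).set_index("fish_id")
        record_frames = []
        for traj, st in steps_by_fish.values():
            env = meta.loc[traj.fish_id] if traj.fish_id in meta.index else {}
            rec = endurance.fatigue_records_from_steps(
                st, traj.body_length, config.frame_rate,
                threshold=config.sustained_threshold_bls,
                per=config.records_per,
                test_area_length=config.test_area_length_m,
                temp=float(env.get("Temp_C", np.nan)),
                do=float(env.get("DO_mgL", np.nan)))
            if not rec.empty:
                record_frames.append(rec)
        if not record_frames:
            raise FitError("no fish produced supra-threshold fatigue records")
        records = pd.concat(record_frames, ignore_index=True)
        emit("fatigue_records", records)
        log.info("endurance: %d fatigue records (%d censored) from %d fish",
                 len(records), int(records["censored"].sum()),
                 records["fish_id"].nunique())
        model = endurance.breakpoint_search(records, config.aft_covariates)
        emit("endurance_candidates", model.candidates)
        emit("endurance_coefficients", model.summary())
        selection = endurance.model_selection(records, model.breakpoint)
        emit("endurance_model_selection", selection)
        log.info("endurance: breakpoint %.3f BL/s, AIC %.2f, C-index %.3f",
                 model.breakpoint, model.aic, model.c_index_)

        # -- behavior -----------------------------------------------------
        if config.run_behavior:
            ua_frames = []
            for traj, st in steps_by_fish.values():
                E = endurance.endurance_state(
                    st["vs_bls"].to_numpy(), config.frame_rate, model,
                    traj.body_length,
                    threshold=config.sustained_threshold_bls)[:-1]
                ua = behavior.build_use_availability(st, field_obj, E)
                if not ua.empty:
                    ua_frames.append(ua)
                    log.info("behavior: fish %s -> %d steps retained, "
                             "%d candidates discarded", traj.fish_id,
                             ua.attrs["n_steps_retained"],
                             ua.attrs["n_candidates_discarded"])
            rows = pd.concat(ua_frames, ignore_index=True)
            emit("use_availability", rows)
            retained, screen_report = behavior.collinearity_screen(rows)
            emit("collinearity_screen", screen_report)
            spec = GAMSpec(
                mode_smooths=tuple(retained),
                tensor_smooths=tuple(c for c in retained if c != "dtau_uv"),
                k=config.basis_dimension)
            rsf = behavior.fit_rsf_gamm(rows, spec)
            emit("rsf_terms", rsf.term_summary())
            emit("rsf_effects", behavior.effect_report(rsf))
            if config.run_cv:
                cv = behavior.cross_validate(rows, spec, k=config.cv_folds)
                emit("cv_metrics", pd.DataFrame([{
                    "auc": cv["auc"], "recall": cv["recall"],
                    "balanced_accuracy": cv["balanced_accuracy"],
                    "n_folds": len(cv["folds"])}]))
                log.info("behavior: CV AUC %.3f recall %.3f bal-acc %.3f",
                         cv["auc"], cv["recall"], cv["balanced_accuracy"])
    except Exception:
        manifest = {k: str(v) for k, v in written.items()}
        (out / "partial_outputs.json").write_text(json.dumps(manifest,
                                                             indent=2))
        raise

    (out / "outputs.json").write_text(json.dumps(
        {k: str(v) for k, v in written.items()}, indent=2))
    return written
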