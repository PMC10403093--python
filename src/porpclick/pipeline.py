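"""End-to-end orchestration: simulate -> detect -> localize -> screen ->
metrics -> context -> models, as one reproducible run.

A run is declared by a :class:`RunConfig` (YAML-serializable, validated
with pydantic).  Stage outputs are flat CSV files in the run directory
so the audit trail stays diffable; a manifest records the config hash
and per-stage row counts.  The same seed reproduces byte-identical
tabular outputs.

The stage chain itself is an sklearn :class:`~sklearn.pipeline.Pipeline`
of the run-state transformers, so the stages compose and their
parameters are reachable through ``set_params``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from sklearn.pipeline import Pipeline

from . import __version__
from .detect import ClickTrainDetector, classify_buzz, summarize_rates
from .localize import TrainLocalizer
from .metrics import ClickParameterExtractor
from .models import DredgeSelector
from .screen import OnAxisScreener
from .simulate import SceneConfig, render_scene

__all__ = ["RunConfig", "run", "summarize", "build_stage_pipeline"]


class StageToggles(BaseModel):
    simulate: bool = True
    detect: bool = True
    localize: bool = True
    screen: bool = True
    metrics: bool = True
    context: bool = True
    models: bool = True


_DEFAULT_VARIANTS = [
    {"day_night_label": "day", "vessel": False},
    {"day_night_label": "day", "vessel": True},
    {"day_night_label": "night", "vessel": False},
    {"day_night_label": "night", "vessel": True},
]


class RunConfig(BaseModel):
    """Validated, serializable description of one pipeline run.

    A run renders one scene per *variant* (by default the four
    day/night x vessel-absence/presence strata, ``n_trains`` trains
    each) so the model-selection stage sees factor variation.
    """

    seed: int = 0
    n_trains: int = 12
    source_level: float = 175.0
    center_frequency: float = 134.0
    stages: StageToggles = Field(default_factory=StageToggles)
    scene_overrides: dict = Field(default_factory=dict)
    variants: list[dict] = Field(
        default_factory=lambda: [dict(v) for v in _DEFAULT_VARIANTS]
    )
    model_responses: list[str] = Field(default_factory=lambda: ["asl"])
    log_level: str = "INFO"

    def scene_config(self, variant_index: int = 0) -> SceneConfig:
        from .simulate import VesselNoise

        var = dict(self.variants[variant_index]) if self.variants else {}
        vessel = var.pop("vessel", False)
        kw = dict(self.scene_overrides)
        kw.update(var)
        kw.setdefault("vessel_noise", VesselNoise(present=bool(vessel)))
        return SceneConfig(
            seed=self.seed + 1000 * variant_index,
            n_trains=self.n_trains,
            source_level=self.source_level,
            center_frequency=self.center_frequency,
            **kw,
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_stage_pipeline(use_true_range: bool = False) -> Pipeline:
    """The detect->localize->screen->metrics chain as an sklearn Pipeline."""
    return Pipeline(
        [
            ("localize", TrainLocalizer()),
            ("screen", OnAxisScreener()),
            ("metrics", ClickParameterExtractor(use_true_range=use_true_range)),
        ]
    )


def run(
    config: RunConfig | str | Path,
    out_dir: str | Path,
    resume: bool = False,
) -> Path:
    """Execute the enabled stages and write stage outputs + manifest.

    With ``resume=True`` and an existing run directory whose manifest
    matches this config, the simulation/measurement stages are loaded
    from their CSV outputs and only the summary/model stages re-run.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(**yaml.safe_load(Path(config).read_text()))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    st = config.stages

    if resume and (out / "manifest.json").exists():
        prev = json.loads((out / "manifest.json").read_text())
        if (
            prev.get("config_hash") == config.config_hash()
            and (out / "metrics.csv").exists()
            and (out / "env.csv").exists()
        ):
            metrics_df = pd.read_csv(out / "metrics.csv")
            env_df = pd.read_csv(out / "env.csv")
            counts = dict(prev.get("row_counts", {}))
            _model_and_summary(config, out, metrics_df, env_df, st)
            manifest = {
                "config_hash": config.config_hash(),
                "porpclick_version": __version__,
                "seed": config.seed,
                "row_counts": counts,
                "resumed": True,
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return out

    n_var = len(config.variants) if st.simulate else 0
    all_events, all_truth, all_trains_frames = [], [], []
    all_audits, all_metrics, all_env = [], [], []
    rate_labels: list[str] = []
    rate_trains = []

    for vi in range(n_var):
        scene = render_scene(config.scene_config(vi))
        ev = scene.events.assign(variant=vi)
        all_events.append(ev)
        all_truth.append(scene.truth.assign(variant=vi))
        if not st.detect:
            continue
        state = {
            "events": scene.events,
            "scene": scene,
            "sound_speed": scene.sound_speed,
            "alpha": scene.alpha_db_per_m,
            "water": scene.config.water,
        }
        trains = ClickTrainDetector().transform(scene.events)
        all_trains_frames.append(
            ClickTrainDetector.summary_frame(trains).assign(variant=vi)
        )
        rate_trains.extend(trains)
        rate_labels.extend([scene.config.day_night_label] * len(trains))
        if not (st.localize and trains):
            continue
        state["trains"] = trains
        state = TrainLocalizer().fit().transform(state)
        if not st.screen:
            continue
        state = OnAxisScreener().fit().transform(state)
        audit = state["screen_audit"].assign(variant=vi)
        all_audits.append(audit)
        for _, row in audit.iterrows():
            if not row["accepted"]:
                failed = [
                    c for c in row.index
                    if c not in ("train_index", "accepted", "snr_db", "variant")
                    and not row[c]
                ]
                warnings.warn(
                    f"variant {vi} train {int(row['train_index'])} rejected: "
                    + ",".join(failed),
                    stacklevel=2,
                )
        if not st.metrics:
            continue
        state = ClickParameterExtractor().fit().transform(state)
        m = state["metrics"].assign(variant=vi)
        all_metrics.append(m)
        if st.context:
            all_env.append(
                pd.DataFrame(
                    {
                        "train_index": m["train_index"],
                        "variant": vi,
                        "day_night": scene.config.day_night_label,
                        "vessel": "presence"
                        if scene.config.vessel_noise.present
                        else "absence",
                        "temperature": scene.config.water.temperature,
                        "noise_level": scene.config.ambient_noise_level,
                    }
                )
            )

    def _cat(frames):
        return pd.concat(frames, ignore_index=True) if frames else None

    events_df, truth_df = _cat(all_events), _cat(all_truth)
    if events_df is not None:
        events_df.to_csv(out / "events.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False)
        counts["events"] = len(events_df)
        counts["truth"] = len(truth_df)
    trains_df = _cat(all_trains_frames)
    if trains_df is not None:
        trains_df.to_csv(out / "trains.csv", index=False)
        counts["trains"] = len(trains_df)
        (out / "rates.json").write_text(
            json.dumps(summarize_rates(rate_trains, rate_labels), indent=2)
        )
    audit_df = _cat(all_audits)
    if audit_df is not None:
        audit_df.to_csv(out / "screen_audit.csv", index=False)
        counts["accepted"] = int(audit_df["accepted"].sum())
    metrics_df = _cat(all_metrics)
    if metrics_df is not None:
        metrics_df.to_csv(out / "metrics.csv", index=False)
        counts["metrics"] = len(metrics_df)
    env_df = _cat(all_env)
    if env_df is not None:
        env_df.to_csv(out / "env.csv", index=False)
        counts["env"] = len(env_df)

    _model_and_summary(config, out, metrics_df, env_df, st)

    manifest = {
        "config_hash": config.config_hash(),
        "porpclick_version": __version__,
        "seed": config.seed,
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _model_and_summary(config, out, metrics_df, env_df, st) -> None:
    if metrics_df is None or env_df is None:
        return
    table = metrics_df.merge(env_df, on=["train_index", "variant"])
    if st.models:
        for resp in config.model_responses:
            usable = [
                t for t in ("day_night", "vessel", "temperature", "noise_level")
                if t in table and table[t].nunique() > 1
            ]
            if resp not in table or len(table) < len(usable) + 3 or not usable:
                warnings.warn(
                    f"too few rows/levels to fit models for {resp!r}",
                    stacklevel=2,
                )
                continue
            sel = DredgeSelector(
                response=resp,
                family="gaussian" if resp == "asl" else "gamma",
                terms=tuple(usable),
            ).fit(table)
            sel.table_.to_csv(out / f"model_selection_{resp}.csv", index=False)
    summarize(table).to_csv(out / "summary.csv")


_SUMMARY_PARAMS = (
    "range_m", "asl", "peak_frequency", "center_frequency", "bw3",
    "duration", "ici", "n_clicks", "temperature", "noise_level",
)


def summarize(table: pd.DataFrame, site_col: str = "site") -> pd.DataFrame:
    """Per-site and pooled mean +/- SD and range for each parameter.

    Mirrors a field-summary table: one row per parameter, columns for
    the pooled sample and each site; a single-row input reports its
    value as the mean and a missing SD.  When day/night and vessel
    columns are present a count per stratum is appended to ``.attrs``.
    """
    params = [p for p in _SUMMARY_PARAMS if p in table]
    groups = {"total": table}
    if site_col in table:
        for s, g in table.groupby(site_col):
            groups[f"site_{s}"] = g
    rows = []
    for p in params:
        row: dict = {"parameter": p}
        for gname, g in groups.items():
            v = g[p].dropna().to_numpy(float)
            row[f"{gname}_mean"] = np.mean(v) if len(v) else np.nan
            row[f"{gname}_sd"] = np.std(v, ddof=1) if len(v) > 1 else np.nan
            row[f"{gname}_min"] = np.min(v) if len(v) else np.nan
            row[f"{gname}_max"] = np.max(v) if len(v) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("parameter")
    if {"day_night", "vessel"} <= set(table.columns):
        out.attrs["strata_counts"] = (
            table.groupby(["day_night", "vessel"]).size().to_dict()
        )
    return out
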