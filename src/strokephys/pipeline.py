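"""Cohort-level orchestration: generate -> analyze -> summarize.

Runs the full synthetic study for a set of groups (condition, n, seed),
scores every subject with the ephys / kinematics / behavior stages, and
writes tidy per-subject CSV tables plus group mean +/- SEM summaries and a
JSON manifest that suffices to reproduce every number.  Inferential
statistics (ANOVA, post-hoc tests) are deliberately out of scope: the tidy
tables are meant to be consumed by any statistics environment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import platform_metrics, foot_fault_percentage, asymmetry_index, \
    reach_error_percentage
from .ephys import (epoch_and_average, measure_fp_components, paired_pulse_ratio,
                    pool_layers, default_layer_map)
from .kinematics import kinematic_metrics
from .synth import (BEHAVIOR_PRESETS, CohortConfig, PlatformConfig, ReachConfig,
                    gen_behavior_counts, gen_evoked_lfp, gen_platform_trial,
                    gen_reach_trajectory)

__all__ = ["GroupSpec", "StudyConfig", "PipelineError", "run_pipeline",
           "summarize_groups", "summarize_table"]

logger = logging.getLogger("strokephys")


class PipelineError(RuntimeError):
    """One or more pipeline stages failed (partial results were preserved)."""


@dataclass
class GroupSpec:
    name: str
    condition: str
    n_subjects: int
    seed: int


@dataclass
class StudyConfig:
    """Study layout plus per-stage parameter overrides.

    ``ephys``/``reach``/``platform``/``behavior`` are keyword overrides
    forwarded to the corresponding generator configs; analysis defaults are
    the module defaults.
    """

    groups: list[GroupSpec]
    out_dir: str | Path | None = None
    isi_list: tuple[int | None, ...] = (None, 50)
    ephys: dict = field(default_factory=dict)
    reach: dict = field(default_factory=dict)
    platform: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        groups = [GroupSpec(**g) for g in d["groups"]]
        isi_list = tuple(d.get("isi_list", (None, 50)))
        return cls(groups=groups, out_dir=d.get("out_dir"), isi_list=isi_list,
                   ephys=dict(d.get("ephys", {})), reach=dict(d.get("reach", {})),
                   platform=dict(d.get("platform", {})),
                   behavior=dict(d.get("behavior", {})))

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


def _derived_seed(*keys: int) -> int:
    """Deterministic sub-seed below 2^31 from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_groups(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean, SEM (SD/sqrt(n)) and n per group; NaNs excluded and counted.

    A single-value group gets SEM 0 by convention and is flagged in the
    ``single_subject`` column so tables stay rectangular.
    """
    rows = []
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        valid = arr[np.isfinite(arr)]
        n = valid.size
        if n == 0:
            raise ValueError(f"group {name!r} has no usable values")
        sem = float(valid.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(dict(group=name, mean=float(valid.mean()), sem=sem, n=n,
                         n_missing=int(arr.size - n), single_subject=n == 1))
    return pd.DataFrame(rows)


def summarize_table(df: pd.DataFrame, value_cols: Sequence[str],
                    by: Sequence[str] = ("group",)) -> pd.DataFrame:
    """Tidy mean/SEM/n summary of ``value_cols`` per combination of ``by``."""
    out = []
    for keys, sub in df.groupby(list(by), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_cols:
            vals = sub[col].to_numpy(dtype=float)
            valid = vals[np.isfinite(vals)]
            n = valid.size
            row = dict(zip(by, keys))
            row.update(
                variable=col,
                mean=float(valid.mean()) if n else float("nan"),
                sem=float(valid.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                n=n,
                n_missing=int(vals.size - n),
                single_subject=n == 1,
            )
            out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_ephys_stage(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    fp_rows, pool_rows, ppr_rows = [], [], []
    for g in config.groups:
        cohort = CohortConfig(condition=g.condition, n_subjects=g.n_subjects,
                              seed=g.seed, **config.ephys)
        for sub in gen_evoked_lfp(cohort, config.isi_list):
            if None in sub.recordings:
                avg = epoch_and_average(sub.recordings[None], (-50.0, 250.0))
                comp = measure_fp_components(avg)
                for ch in range(avg.n_channels):
                    fp_rows.append(dict(
                        group=g.name, condition=g.condition, subject=sub.subject,
                        channel=ch, depth_um=float(avg.channel_depths[ch]),
                        neg_amp_mV=comp.neg_amplitude[ch], neg_lat_ms=comp.neg_latency[ch],
                        pos_amp_mV=comp.pos_amplitude[ch], pos_lat_ms=comp.pos_latency[ch],
                    ))
                gmap = default_layer_map(avg.n_channels)
                neg_pool = pool_layers(comp.neg_amplitude, gmap)
                pos_pool = pool_layers(comp.pos_amplitude, gmap)
                for layer in gmap:
                    pool_rows.append(dict(
                        group=g.name, condition=g.condition, subject=sub.subject,
                        layer=layer, neg_amp_mV=neg_pool.mean[layer],
                        pos_amp_mV=pos_pool.mean[layer],
                    ))
            for isi in config.isi_list:
                if isi is None:
                    continue
                avg = epoch_and_average(sub.recordings[isi], (-50.0, isi + 100.0))
                res = paired_pulse_ratio(avg, isi)
                deep = default_layer_map(avg.n_channels)["Deep"]
                ppr_rows.append(dict(
                    group=g.name, condition=g.condition, subject=sub.subject,
                    isi_ms=isi, ppr_deep=float(np.nanmean(res.ppr[deep])),
                ))
    return pd.DataFrame(fp_rows), pd.DataFrame(pool_rows), pd.DataFrame(ppr_rows)


def _run_kinematics_stage(config: StudyConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        preset = BEHAVIOR_PRESETS[g.condition]
        for subj in range(g.n_subjects):
            kwargs = dict(n_submovements=int(preset["n_submovements"]),
                          seed=_derived_seed(g.seed, subj, 1))
            kwargs.update(config.reach)
            traj, truth = gen_reach_trajectory(ReachConfig(**kwargs))
            m = kinematic_metrics(traj)
            rows.append(dict(group=g.name, condition=g.condition, subject=subj,
                             arc_len_mm=m.arc_len, auc_mm2=m.auc,
                             mean_speed_mm_s=m.mean_speed, smoothness=m.smoothness,
                             true_submovements=truth.n_submovements))
    return pd.DataFrame(rows)


def _run_behavior_stage(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    plat_rows, beh_rows = [], []
    for g in config.groups:
        preset = BEHAVIOR_PRESETS[g.condition]
        for subj in range(g.n_subjects):
            rng = np.random.default_rng(_derived_seed(g.seed, subj, 2))
            n_attempts = int(rng.poisson(preset["platform_attempts"]))
            kwargs = dict(n_attempts=n_attempts, seed=_derived_seed(g.seed, subj, 3))
            kwargs.update(config.platform)
            trial, truth = gen_platform_trial(PlatformConfig(**kwargs))
            pm = platform_metrics(trial)
            plat_rows.append(dict(group=g.name, condition=g.condition, subject=subj,
                                  t_target_s=pm.t_target, n_attempts=pm.n_attempts,
                                  true_t_target_s=truth.t_target,
                                  true_n_attempts=truth.n_attempts))

            beh_kwargs = dict(n_events=50)
            beh_kwargs.update(config.behavior)
            counts, _ = gen_behavior_counts(
                {"impaired": preset["p_fault"], "unimpaired": 0.05},
                p_impaired_use=preset["p_impaired_use"],
                p_incorrect_reach=preset["p_incorrect"],
                seed=_derived_seed(g.seed, subj, 4),
                **beh_kwargs,
            )
            beh_rows.append(dict(
                group=g.name, condition=g.condition, subject=subj,
                foot_fault_pct=foot_fault_percentage(counts, "impaired"),
                asymmetry_index=asymmetry_index(counts),
                reach_error_pct=reach_error_percentage(counts),
            ))
    return pd.DataFrame(plat_rows), pd.DataFrame(beh_rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_SUMMARY_SPECS = {
    "layer_pools": (["neg_amp_mV", "pos_amp_mV"], ("group", "layer")),
    "ppr": (["ppr_deep"], ("group", "isi_ms")),
    "kinematics": (["arc_len_mm", "auc_mm2", "mean_speed_mm_s", "smoothness"], ("group",)),
    "platform": (["t_target_s", "n_attempts"], ("group",)),
    "behavior": (["foot_fault_pct", "asymmetry_index", "reach_error_pct"], ("group",)),
}


def run_pipeline(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run generation + all analysis stages; return (and optionally write) tables.

    Deterministic given the config: repeated runs produce byte-identical
    CSVs (no timestamps enter the outputs).  A failing stage is logged and
    skipped so partial results are preserved; a :class:`PipelineError` is
    raised at the end if anything failed.
    """
    tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []

    stages = [
        ("ephys", lambda: dict(zip(["fp_components", "layer_pools", "ppr"],
                                   _run_ephys_stage(config)))),
        ("kinematics", lambda: {"kinematics": _run_kinematics_stage(config)}),
        ("behavior", lambda: dict(zip(["platform", "behavior"],
                                      _run_behavior_stage(config)))),
    ]
    for name, stage in stages:
        try:
            tables.update(stage())
        except Exception:
            logger.exception("stage %s failed", name)
            failures.append(name)

    for key, (cols, by) in _SUMMARY_SPECS.items():
        if key in tables and not tables[key].empty:
            tables[f"summary_{key}"] = summarize_table(tables[key], cols, by)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = dict(
            package="strokephys",
            version=__version__,
            config=_config_dict(config),
            tables=sorted(f"{name}.csv" for name in tables),
            failures=failures,
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if failures:
        raise PipelineError(f"stages failed: {', '.join(failures)}")
    return tables


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = None if config.out_dir is None else str(config.out_dir)
    d["isi_list"] = [i for i in config.isi_list]
    return d
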