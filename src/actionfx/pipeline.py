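"""Configuration-driven orchestration: simulate -> clean -> ERP/behavior ->
ANOVA -> decode -> cluster -> report.

A :class:`PipelineConfig` (YAML-loadable) fixes one master seed and the
per-stage settings; :func:`run_pipeline` executes every stage in order,
writes all tables as CSV under a run directory and returns a
:class:`RunReport` with SHA-256 digests of every artifact, so a rerun with
an identical config is verifiably byte-identical.

The analysis surface mirrors the study: validity decoding in each
congruency x action cell (4 analyses) and orientation decoding in each
congruency x action x validity cell (8 analyses), each followed by a
vs-chance cluster test, plus action vs no-action decoding comparisons
within congruency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior_stats, cluster_inference, erp_components
from .decoding import DecodingConfig, decode_group
from .design import CELLS, ConfigurationError, FACTORS, iter_condition_splits
from .epochs_core import baseline_correct, reject_by_threshold, save_epochs
from .synthetic_data import SimConfig, default_config, generate_dataset
from .within_stats import FactorialDataset, rm_anova_table

log = logging.getLogger("actionfx")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = None                        # type: ignore[assignment]
    out_dir: str = "actionfx_run"
    rejection_threshold_uv: float = 80.0
    baseline_window_ms: Tuple[float, float] = (-200.0, 0.0)
    components: Tuple[str, ...] = ("n2pc", "p300b", "latelpc")
    decode_iterations: int = 100
    decode_bins: int = 8
    decode_target_rate: float = 100.0
    cluster_n_permutations: int = 10000
    cluster_alpha: float = 0.05
    validity_decoding_cells: Tuple[Mapping[str, str], ...] = tuple(
        iter_condition_splits(["congruency", "action"]))
    orientation_decoding_cells: Tuple[Mapping[str, str], ...] = tuple(
        iter_condition_splits(["congruency", "action", "validity"]))
    write_epochs: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.sim is None:
            object.__setattr__(self, "sim", default_config(seed=self.seed))
        for filt in (*self.validity_decoding_cells, *self.orientation_decoding_cells):
            for factor, level in filt.items():
                if factor not in FACTORS:
                    raise ConfigurationError(f"unknown factor {factor!r} in decoding cells")
                if level not in FACTORS[factor]:
                    raise ConfigurationError(
                        f"unknown level {level!r} of factor {factor!r} in decoding cells")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        sim_raw = raw.pop("sim", {})
        seed = int(raw.get("seed", 0))
        sim = default_config(seed=int(sim_raw.pop("seed", seed)), **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in sim_raw.items()})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("validity_decoding_cells", "orientation_decoding_cells"):
            if key in raw:
                raw[key] = tuple(dict(d) for d in raw[key])
        if "baseline_window_ms" in raw:
            raw["baseline_window_ms"] = tuple(raw["baseline_window_ms"])
        if "components" in raw:
            raw["components"] = tuple(raw["components"])
        return cls(sim=sim, **raw)


@dataclass
class RunReport:
    out_dir: str
    seed: int
    version: str
    digests: Dict[str, str] = field(default_factory=dict)
    trial_counts: Dict[str, Dict[str, float]] = field(default_factory=dict)
    stages: List[Dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    report.digests[path.name] = _digest(path)


def trial_count_report(tables: List[pd.DataFrame]) -> pd.DataFrame:
    """Kept-trial counts per subject x cell, plus mean ± sd across subjects."""
    rows = []
    for tab in tables:
        for subject, sub in tab.groupby("subject", sort=True):
            kept = sub["kept"].to_numpy(dtype=bool) if "kept" in sub.columns \
                else np.ones(len(sub), dtype=bool)
            for cell in CELLS:
                m = kept & (sub["congruency"] == cell[0]).to_numpy() \
                    & (sub["action"] == cell[1]).to_numpy() \
                    & (sub["validity"] == cell[2]).to_numpy()
                rows.append((subject, *cell, int(m.sum())))
    counts = pd.DataFrame(rows, columns=["subject", "congruency", "action",
                                         "validity", "n_kept"])
    return counts


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    g = counts.groupby(["congruency", "action", "validity"])["n_kept"]
    return g.agg(["mean", "std", "min"]).reset_index()


def _cell_name(filt: Mapping[str, str]) -> str:
    return "_".join(f"{v}" for v in filt.values()) or "all"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; artifacts under ``config.out_dir``; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=str(out), seed=config.seed, version=__version__)

    def stage(name):
        log.info("stage %s", name)
        report.stages.append({"stage": name, "t_start": time.time()})

        def done():
            report.stages[-1]["duration_s"] = time.time() - report.stages[-1].pop("t_start")
        return done

    # -- simulate ----------------------------------------------------------
    done = stage("simulate")
    epochs_list, tables, truth = generate_dataset(config.sim)
    (out / "ground_truth.json").write_text(truth.to_json())
    report.digests["ground_truth.json"] = _digest(out / "ground_truth.json")
    done()

    # -- clean -------------------------------------------------------------
    done = stage("clean")
    cleaned, kept_tables = [], []
    for ep, tab in zip(epochs_list, tables):
        ep2, tab2, n_rej = reject_by_threshold(ep, tab, config.rejection_threshold_uv)
        ep2 = baseline_correct(ep2, config.baseline_window_ms)
        cleaned.append(ep2)
        kept_tables.append(tab2)
        if config.write_epochs:
            save_epochs(out / f"epochs_{ep2.subject_id}.h5", ep2, tab2)
    counts = trial_count_report(kept_tables)
    _write_csv(counts, out / "trial_counts.csv", report)
    summary = summarize_counts(counts)
    _write_csv(summary, out / "trial_counts_summary.csv", report)
    report.trial_counts = {
        "_".join(r[:3]): {"mean": float(r[3]), "std": float(r[4] if r[4] == r[4] else 0.0)}
        for r in summary.itertuples(index=False)}
    done()

    # -- behavior ----------------------------------------------------------
    done = stage("behavior")
    all_trials = pd.concat(kept_tables, ignore_index=True)
    trimmed = behavior_stats.trim_rts(all_trials)
    cell_stats = behavior_stats.behavior_cell_stats(trimmed)
    _write_csv(cell_stats, out / "behavior_cells.csv", report)
    rt_eff = behavior_stats.rt_validity_effect(cell_stats)
    _write_csv(rt_eff, out / "rt_validity_effects.csv", report)
    anova_frames = []
    for dv in ("mean_rt", "accuracy"):
        ds = FactorialDataset.from_table(cell_stats, dv)
        at = rm_anova_table(ds)
        at.insert(0, "dv", dv)
        anova_frames.append(at)
    done()

    # -- ERP components ----------------------------------------------------
    done = stage("erp")
    erp_cells_frames, erp_eff_frames = [], []
    for name in config.components:
        spec = erp_components.COMPONENTS[name.lower()]
        per_subject = [erp_components.component_cell_means(ep, tab, spec)
                       for ep, tab in zip(cleaned, kept_tables)]
        cells = pd.concat(per_subject, ignore_index=True)
        erp_cells_frames.append(cells)
        eff = erp_components.validity_effect(cells, spec)
        erp_eff_frames.append(eff)
        ds = FactorialDataset.from_table(cells, "amplitude")
        at = rm_anova_table(ds)
        at.insert(0, "dv", spec.name)
        anova_frames.append(at)
    _write_csv(pd.concat(erp_cells_frames, ignore_index=True),
               out / "erp_cells.csv", report)
    _write_csv(pd.concat(erp_eff_frames, ignore_index=True),
               out / "erp_validity_effects.csv", report)
    _write_csv(pd.concat(anova_frames, ignore_index=True),
               out / "anova.csv", report)
    done()

    # -- decoding ----------------------------------------------------------
    done = stage("decode")
    decode_results = {}   # analysis name -> (matrix, times)
    analyses = [("validity", filt) for filt in config.validity_decoding_cells] \
        + [("orientation", filt) for filt in config.orientation_decoding_cells]
    frames = []
    for label, filt in analyses:
        dcfg = DecodingConfig(label_name=label, cells=(filt,),
                              n_bins=config.decode_bins,
                              n_folds=config.decode_bins,
                              n_iterations=config.decode_iterations,
                              target_rate=config.decode_target_rate,
                              seed=config.seed)
        mat, times, subjects = decode_group(cleaned, kept_tables, dcfg)
        name = f"{label}_{_cell_name(filt)}"
        decode_results[name] = (mat, times)
        df = pd.DataFrame(mat, columns=[f"{t:g}" for t in times])
        df.insert(0, "subject", subjects)
        df.insert(0, "analysis", name)
        frames.append(df)
    _write_csv(pd.concat(frames, ignore_index=True),
               out / "decoding_accuracy.csv", report)
    done()

    # -- cluster inference -------------------------------------------------
    done = stage("cluster")
    cluster_rows = []
    for name, (mat, times) in decode_results.items():
        res = cluster_inference.cluster_test(
            mat, mu0=0.5, n_permutations=config.cluster_n_permutations,
            tail="greater", times=times, seed=config.seed)
        for c in res.clusters:
            cluster_rows.append((name, "vs_chance", c.start_ms, c.end_ms,
                                 c.summed_t, c.p))
    # action vs no-action comparison within congruency (validity decoding)
    for congruency in FACTORS["congruency"]:
        a = decode_results.get(f"validity_{congruency}_action")
        b = decode_results.get(f"validity_{congruency}_no_action")
        if a is None or b is None:
            continue
        res = cluster_inference.compare_conditions(
            a[0], b[0], n_permutations=config.cluster_n_permutations,
            tail="two-sided", times=a[1], seed=config.seed)
        for c in res.clusters:
            cluster_rows.append((f"validity_{congruency}", "action_vs_no_action",
                                 c.start_ms, c.end_ms, c.summed_t, c.p))
    clusters_df = pd.DataFrame(cluster_rows, columns=[
        "analysis", "contrast", "start_ms", "end_ms", "summed_t", "p"])
    _write_csv(clusters_df, out / "clusters.csv", report)
    done()

    (out / "run_report.json").write_text(report.to_json())
    return report
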