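"""End-to-end orchestration: simulate -> detect -> features -> kinetics ->
NSFA -> cluster, with per-cell aggregation and group statistics.

Group comparisons operate on per-cell summaries only (per-cell medians for
interevent intervals), never on pooled event-level values, to avoid
pseudo-replication.  Two groups are compared with a two-tailed Student
t-test; more with one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import events as ev
from . import nsfa as nsfa_mod
from . import skewt
from .core import Trace, write_events
from .kinetics import average_waveform
from .synth import ChannelEnsemble, EventClass, TrainConfig, simulate_train

log = logging.getLogger("synaptoscope")


@dataclass
class ConditionConfig:
    """Simulation settings for one experimental condition."""

    name: str
    n_cells: int = 5
    sweep_duration: float = 120.0  # s per cell
    rate: float = 10_000.0         # Hz
    event_rate: float = 0.8        # Hz
    ensemble: ChannelEnsemble | None = None
    noise_sd: float = 2.0          # pA


@dataclass
class RunConfig:
    conditions: list[ConditionConfig]
    seed: int = 0
    out_dir: str | Path = "results/run"
    detect_threshold: float = 5.0
    detect_fit_window_ms: float | None = 10.0
    template_rise_ms: float = 0.5
    template_decay_ms: float = 20.0
    nsfa_min_events: int = 25
    nsfa_bins: int = 50
    cluster_g_range: tuple[int, ...] = (1, 2, 3)
    cluster_max_events: int = 1500
    run_cluster: bool = True

    def digest(self) -> str:
        payload = json.dumps({
            "seed": self.seed,
            "conditions": [(c.name, c.n_cells, c.sweep_duration, c.rate,
                            c.event_rate, c.noise_sd,
                            None if c.ensemble is None else
                            (c.ensemble.N, c.ensemble.i, c.ensemble.rise_tau_ms,
                             c.ensemble.decay, c.ensemble.p_peak))
                           for c in self.conditions],
            "detect_threshold": self.detect_threshold,
            "template": (self.template_rise_ms, self.template_decay_ms),
            "nsfa": (self.nsfa_min_events, self.nsfa_bins),
            "cluster_g_range": list(self.cluster_g_range),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyse_cell(trace: Trace, template: ev.Template, threshold: float,
                 nsfa_min_events: int, nsfa_bins: int,
                 fit_window_ms: float | None = 10.0) -> dict:
    """Detect, flag and featurize one sweep; per-cell summaries + NSFA."""
    detected = ev.detect_events(trace, template, threshold,
                                fit_window_ms=fit_window_ms)
    detected = ev.flag_selection(detected, trace)
    table = ev.extract_features(detected, trace)
    clean_rise = table[table["clean_rise"]]
    clean_decay = table[table["clean_rise"] & table["clean_decay"]]
    summary = {
        "n_events": len(table),
        "n_clean_rise": len(clean_rise),
        "n_clean_decay": len(clean_decay),
        "mean_amplitude": float(clean_rise["amplitude"].mean())
        if len(clean_rise) else np.nan,
        "median_iei": float(table["iei"].median()),
        "mean_rise_20_80": float(table["rise_20_80"].mean()),
    }
    nsfa_res = None
    if len(clean_decay) >= nsfa_min_events:
        try:
            _, mat, peak_idx = average_waveform(trace, clean_decay, align="peak")
            nsfa_res = nsfa_mod.nsfa_from_matrix(mat, peak_idx, n_bins=nsfa_bins,
                                                 min_events=nsfa_min_events)
        except (nsfa_mod.NSFAError, Exception) as exc:  # noqa: BLE001
            log.warning("NSFA failed for a cell: %s", exc)
    if nsfa_res is not None:
        summary["nsfa_i"] = nsfa_res.i
        summary["nsfa_N"] = nsfa_res.N
        summary["nsfa_var"] = nsfa_res.var_baseline
    else:
        summary["nsfa_i"] = summary["nsfa_N"] = summary["nsfa_var"] = np.nan
    return {"table": table, "summary": summary}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-condition emulation; writes TSVs plus a JSON manifest.

    Deterministic given ``config.seed``.  Returns a dict with the per-cell
    summary table, the pooled event table, the cluster summary (if run) and
    the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    template = ev.Template(config.template_rise_ms, config.template_decay_ms)
    cell_rows = []
    event_tables = []
    for cond in config.conditions:
        ensemble = cond.ensemble or ChannelEnsemble(N=26, i=-3.33)
        for cell in range(cond.n_cells):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cfg = TrainConfig(
                duration=cond.sweep_duration,
                classes=(EventClass(rate=cond.event_rate, ensemble=ensemble,
                                    name=cond.name),),
                noise_sd=cond.noise_sd, rate=cond.rate, seed=cell_seed)
            trace, _truth = simulate_train(cfg)
            res = analyse_cell(trace, template, config.detect_threshold,
                               config.nsfa_min_events, config.nsfa_bins,
                               config.detect_fit_window_ms)
            res["summary"].update({"condition": cond.name, "cell": cell,
                                   "seed": cell_seed})
            cell_rows.append(res["summary"])
            tab = res["table"].copy()
            tab["condition"] = cond.name
            tab["cell"] = cell
            event_tables.append(tab)
            log.info("%s cell %d: %d events (%d clean rise, %d clean decay)",
                     cond.name, cell, res["summary"]["n_events"],
                     res["summary"]["n_clean_rise"],
                     res["summary"]["n_clean_decay"])
    cells = pd.DataFrame(cell_rows)
    all_events = pd.concat(event_tables, ignore_index=True)
    write_events(cells, out / "cells.tsv")
    write_events(all_events, out / "events.tsv")

    cluster_summary = None
    bic_table = None
    if config.run_cluster:
        X, keep = ev.feature_matrix(all_events)
        conds = all_events["condition"].to_numpy()[keep]
        amps = all_events["amplitude"].to_numpy()[keep]
        if X.shape[0] > config.cluster_max_events:
            sub = np.sort(np.random.default_rng(config.seed).choice(
                X.shape[0], config.cluster_max_events, replace=False))
            X, conds, amps = X[sub], conds[sub], amps[sub]
        Z, _ = skewt.standardize(X, ev.CLUSTER_FEATURES)
        fit, bic_table = skewt.select_components(
            X=Z, G_range=config.cluster_g_range,
            seed=int(np.random.default_rng(config.seed ^ 0x5eed).integers(0, 2**31 - 1)),
            n_init=2, max_iter=200, tol=1e-5)
        cluster_summary = skewt.cluster_condition_summary(
            fit.labels, conds, table=pd.DataFrame({"amplitude": amps}),
            report_columns=["amplitude"])
        write_events(cluster_summary, out / "cluster_summary.tsv")
        write_events(bic_table, out / "bic_table.tsv")

    manifest = {"seed": config.seed, "config_hash": config.digest(),
                "n_cells": len(cells), "n_events": len(all_events)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"cells": cells, "events": all_events,
            "cluster_summary": cluster_summary, "bic_table": bic_table,
            "out_dir": out}


@dataclass
class GroupResult:
    test: str
    statistic: float
    df: float | tuple
    p_value: float
    pairwise: pd.DataFrame | None = None


def group_compare(groups: dict[str, np.ndarray],
                  equal_var: bool = True) -> GroupResult:
    """Compare per-cell summary values across treatment groups.

    Two groups: two-tailed Student t-test (Welch via ``equal_var=False``).
    More than two: one-way ANOVA followed by Tukey's HSD.  Reports the
    statistic, degrees of freedom and p value; significance judgements are
    left to the caller.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
    if len(arrays) == 2:
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        df = (arrays[0].size + arrays[1].size - 2) if equal_var else float(res.df)
        return GroupResult(test="t-test" if equal_var else "welch",
                           statistic=float(res.statistic), df=df,
                           p_value=float(res.pvalue))
    f_res = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    rows = []
    for a in range(len(arrays)):
        for b in range(a + 1, len(arrays)):
            rows.append({"group_a": names[a], "group_b": names[b],
                         "diff": float(np.mean(arrays[a]) - np.mean(arrays[b])),
                         "p_value": float(tk.pvalue[a, b])})
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    return GroupResult(test="anova+tukey", statistic=float(f_res.statistic),
                       df=(df_between, df_within), p_value=float(f_res.pvalue),
                       pairwise=pd.DataFrame(rows))


def mean_cumulative_probability(per_cell_values: list[np.ndarray],
                                grid: np.ndarray) -> np.ndarray:
    """Mean of per-cell empirical CDFs evaluated on a common grid."""
    cdfs = []
    for vals in per_cell_values:
        vals = np.sort(np.asarray(vals, dtype=float))
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        cdfs.append(np.searchsorted(vals, grid, side="right") / vals.size)
    if not cdfs:
        raise ValueError("no finite values in any cell")
    return np.mean(cdfs, axis=0)
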