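"""End-to-end run: curation → segmentation → metrics → statistics → figures.

Inputs are either a simulated cohort or user-supplied trace + attribute CSVs.
Curation applies the quality rules (pre-test inactivity above the threshold,
incomplete attributes, procedure-error flag); each fly is curated
independently — excluding one triplet member does not drop its partners, so
group sizes may end up unequal.  All downstream statistics see only retained
flies.  Every run emits a manifest (config snapshot, seeds, input digests,
software version) that fully determines the numeric outputs of a rerun on
simulated inputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import (AnalysisConfig, ProtocolSpec, SimConfig, GROUPS,
                     TRAIN_SESSIONS, SESSION_ORDER, to_flat_dict)
from .cohort import simulate_cohort
from .metrics import metrics_table, per_fly_summary, activity_level, cad_curve
from .segmentation import segment_trace
from .stats import (kruskal_wallis, pairwise_wilcoxon, correlation_with_slope,
                    rank_sum_test, significance_stars)
from .trace import FlyRecord, PositionTrace

EXCLUSION_REASONS = ("pretest-inactivity", "attribute-missing",
                     "procedure-error-flag")


@dataclass
class CurationReport:
    retained: List[str]
    excluded: Dict[str, str]  # fly_id -> primary reason
    inactivity_threshold: float

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded)

    def to_dict(self) -> dict:
        return {"retained": sorted(self.retained),
                "excluded": dict(sorted(self.excluded.items())),
                "inactivity_threshold": self.inactivity_threshold,
                "n_input": self.n_input}


def curate(records: Sequence[FlyRecord], traces: Sequence[PositionTrace],
           segs: Dict[str, "object"],
           inactivity_threshold: float = 0.90) -> CurationReport:
    """Apply the exclusion rules; flies are curated independently.

    A fly is excluded iff it was inactive *more than* the threshold fraction
    of the Pre-test session (strict inequality — exactly 90% inactive is
    retained), or its attribute record is incomplete, or it carries the
    procedure-error flag.  One primary reason per exclusion, in that
    priority order.
    """
    by_id = {r.fly_id: r for r in records}
    retained, excluded = [], {}
    for trace in traces:
        rec = by_id.get(trace.fly_id)
        if rec is None:
            raise ValueError(f"no attribute record for fly {trace.fly_id}")
        try:
            window = trace.window("Pre-test")
        except KeyError as exc:
            raise ValueError(
                f"fly {trace.fly_id} has no Pre-test session") from exc
        inactive = 1.0 - activity_level(segs[trace.fly_id], window)
        if inactive > inactivity_threshold:
            excluded[trace.fly_id] = "pretest-inactivity"
        elif not rec.attribute_complete:
            excluded[trace.fly_id] = "attribute-missing"
        elif rec.procedure_error:
            excluded[trace.fly_id] = "procedure-error-flag"
        else:
            retained.append(trace.fly_id)
    return CurationReport(retained=retained, excluded=excluded,
                          inactivity_threshold=inactivity_threshold)


@dataclass
class RunManifest:
    config: dict
    seed: Optional[int]
    software_version: str
    input_digests: Dict[str, str]
    timestamp: str
    common_cut: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trace_digest(trace: PositionTrace) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(trace.position).tobytes())
    h.update(np.ascontiguousarray(trace.laser_on).tobytes())
    h.update(",".join(f"{w.label}:{w.start}:{w.stop}"
                      for w in trace.sessions).encode())
    return h.hexdigest()


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    per_fly: pd.DataFrame
    curation: CurationReport
    stats_report: dict
    manifest: RunManifest
    episode_table: Optional[pd.DataFrame] = None
    figures: List[str] = field(default_factory=list)


def _group_values(frame: pd.DataFrame, column: str) -> tuple:
    labels = [g for g in GROUPS if (frame["group"] == g).any()]
    values = [frame.loc[frame["group"] == g, column].dropna().to_numpy()
              for g in labels]
    return labels, values


def _comparison_block(frame: pd.DataFrame, column: str, n_resamples: int,
                      seed: Optional[int]) -> dict:
    labels, values = _group_values(frame, column)
    block = {"groups": labels, "n": [len(v) for v in values]}
    if any(len(v) < 2 for v in values) or len(values) < 2:
        block["error"] = "a group has fewer than 2 values"
        return block
    kw = kruskal_wallis(values)
    block["kruskal_wallis"] = {
        "H": kw["H"], "p": kw["p"], "df": kw["df"],
        "stars": significance_stars(kw["p"]),
    }
    block["pairwise"] = [c.to_dict() for c in pairwise_wilcoxon(
        values, labels=labels, n_resamples=n_resamples, seed=seed)]
    return block


def build_stats_report(metrics: pd.DataFrame, per_fly: pd.DataFrame,
                       analysis: AnalysisConfig,
                       seed: Optional[int] = None) -> dict:
    """The full inference layer over the metric tables (retained flies)."""
    nres = analysis.n_resamples
    report: dict = {"n_resamples": nres, "seed": seed}

    # heat contingency within each Train session, per heated group
    contingency = {}
    for session in TRAIN_SESSIONS:
        sub = metrics[metrics["session"] == session]
        per_group = {}
        for g in ("train", "yoked"):
            gsub = sub[sub["group"] == g]
            walk = gsub["p_heat_walk"].dropna().to_numpy()
            pause = gsub["p_heat_pause"].dropna().to_numpy()
            if len(walk) < 2 or len(pause) < 2:
                continue
            stat, p = rank_sum_test(walk, pause)
            per_group[g] = {
                "median_p_heat_walk": float(np.median(walk)),
                "median_p_heat_pause": float(np.median(pause)),
                "p": p, "stars": significance_stars(p),
                "n": [len(walk), len(pause)],
            }
        contingency[session] = per_group
    report["heat_contingency"] = contingency

    # CAD at the common cut, across groups, per Train session
    report["cad_at_cut"] = {
        session: _comparison_block(
            metrics[metrics["session"] == session], "cad_at_cut", nres, seed)
        for session in TRAIN_SESSIONS}

    # activity levels per test session, AD per test session
    report["activity_level"] = {
        session: _comparison_block(
            metrics[metrics["session"] == session], "activity_level",
            nres, seed)
        for session in SESSION_ORDER if session not in TRAIN_SESSIONS}
    report["activity_difference"] = {
        "Test1": _comparison_block(per_fly, "ad_test1", nres, seed),
        "Test2": _comparison_block(per_fly, "ad_test2", nres, seed),
    }

    # yoked-only correlation analyses
    yoked = per_fly[per_fly["group"] == "yoked"]
    correlations = {}
    if len(yoked) >= 3:
        correlations["ad2_vs_total_exposure"] = correlation_with_slope(
            yoked["heat_exposure_total"], yoked["ad_test2"]).to_dict()
        ed1 = metrics[(metrics["session"] == "Train1")
                      & (metrics["group"] == "yoked")][
            ["fly_id", "exposure_differential"]]
        merged = yoked.merge(ed1, on="fly_id").dropna(
            subset=["exposure_differential", "ad_test1"])
        if len(merged) >= 3:
            correlations["ad1_vs_ed_train1"] = correlation_with_slope(
                merged["exposure_differential"], merged["ad_test1"]).to_dict()
        pooled = yoked.dropna(subset=["ed_overall", "ad_test2"])
        if len(pooled) >= 3:
            correlations["ad2_vs_ed_overall"] = correlation_with_slope(
                pooled["ed_overall"], pooled["ad_test2"]).to_dict()
    report["yoked_correlations"] = correlations
    return report


def _make_figures(metrics, per_fly, traces, segs, cut, out_dir) -> List[str]:
    """Best-effort cosmetic figures; numeric tables are the contract."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    colors = {"train": "tab:red", "yoked": "tab:blue", "blank": "0.4"}
    by_id = {t.fly_id: t for t in traces}
    groups_of = per_fly.set_index("fly_id")["group"].to_dict()

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, session in zip(axes, TRAIN_SESSIONS):
        tgrid = np.arange(0.0, cut, 1.0)
        for g in GROUPS:
            curves = []
            for fly_id, fg in groups_of.items():
                if fg != g:
                    continue
                t = by_id[fly_id]
                w = t.window(session)
                c = cad_curve(segs[fly_id], w)
                idx = np.minimum((tgrid / t.dt).astype(int), len(c) - 1)
                curves.append(c[idx])
            if not curves:
                continue
            curves = np.vstack(curves)
            med = np.median(curves, axis=0)
            lo, hi = np.quantile(curves, [0.25, 0.75], axis=0)
            ax.plot(tgrid, med, color=colors[g], label=g)
            ax.fill_between(tgrid, lo, hi, color=colors[g], alpha=0.2, lw=0)
        ax.set_title(session)
        ax.set_xlabel("time in session (s)")
    axes[0].set_ylabel("cumulative active duration (s)")
    axes[0].legend(frameon=False)
    path = out_dir / "cad_curves.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    sessions = [s for s in SESSION_ORDER if s not in TRAIN_SESSIONS]
    width = 0.25
    for gi, g in enumerate(GROUPS):
        data = [metrics[(metrics["session"] == s) & (metrics["group"] == g)]
                ["activity_level"].to_numpy() for s in sessions]
        pos = np.arange(len(sessions)) + (gi - 1) * width
        bp = axes[0].boxplot(data, positions=pos, widths=width * 0.9,
                             patch_artist=True, showfliers=False)
        for box in bp["boxes"]:
            box.set_facecolor(colors[g])
            box.set_alpha(0.5)
    axes[0].set_xticks(np.arange(len(sessions)))
    axes[0].set_xticklabels(sessions)
    axes[0].set_ylabel("activity level")
    for gi, g in enumerate(GROUPS):
        data = [per_fly[per_fly["group"] == g][c].dropna().to_numpy()
                for c in ("ad_test1", "ad_test2")]
        pos = np.arange(2) + (gi - 1) * width
        bp = axes[1].boxplot(data, positions=pos, widths=width * 0.9,
                             patch_artist=True, showfliers=False)
        for box in bp["boxes"]:
            box.set_facecolor(colors[g])
            box.set_alpha(0.5)
    axes[1].set_xticks([0, 1])
    axes[1].set_xticklabels(["AD Test1", "AD Test2"])
    axes[1].axhline(0, color="k", lw=0.5)
    path = out_dir / "activity_and_ad.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    yoked = per_fly[per_fly["group"] == "yoked"]
    if len(yoked) >= 3:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, (xcol, xlabel) in zip(axes, [
                ("heat_exposure_total", "total heat exposure (s)"),
                ("ed_overall", "exposure differential (all Train)")]):
            sub = yoked.dropna(subset=[xcol, "ad_test2"])
            ax.scatter(sub[xcol], sub["ad_test2"], s=12,
                       color="tab:blue", alpha=0.7)
            if len(sub) >= 3 and np.ptp(sub[xcol].to_numpy()) > 0:
                res = correlation_with_slope(sub[xcol], sub["ad_test2"])
                xs = np.linspace(sub[xcol].min(), sub[xcol].max(), 50)
                ax.plot(xs, res.intercept + res.slope * xs, "k-", lw=1)
                ax.set_title(f"r={res.r:.2f}, p={res.p:.3g}")
            ax.set_xlabel(xlabel)
        axes[0].set_ylabel("AD (Test2 − Pre-test)")
        path = out_dir / "yoked_correlations.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written


def run_pipeline(protocol: Optional[ProtocolSpec] = None,
                 sim: Optional[SimConfig] = None,
                 analysis: Optional[AnalysisConfig] = None,
                 traces: Optional[Sequence[PositionTrace]] = None,
                 records: Optional[Sequence[FlyRecord]] = None,
                 out_dir: Optional[str] = None,
                 make_figures: bool = False) -> PipelineResult:
    """Run the full analysis over simulated or supplied traces.

    With ``traces=None`` a cohort is simulated from ``sim``.  Writes tables,
    reports and (optionally) figures under ``out_dir`` when given; always
    returns the in-memory result.
    """
    protocol = protocol or ProtocolSpec()
    sim = sim or SimConfig()
    analysis = analysis or AnalysisConfig()

    episode_table = None
    if traces is None:
        traces, records, episode_table = simulate_cohort(sim, protocol)
    elif records is None:
        raise ValueError("records must accompany user-supplied traces")

    segs = {t.fly_id: segment_trace(t, analysis.speed_threshold,
                                    analysis.min_bout) for t in traces}
    curation = curate(records, traces, segs,
                      inactivity_threshold=analysis.inactivity_threshold)
    kept = set(curation.retained)
    kept_traces = [t for t in traces if t.fly_id in kept]
    kept_records = [r for r in records if r.fly_id in kept]
    labels, values = np.unique([r.group for r in kept_records],
                               return_counts=True)
    sizes = dict(zip(labels, values))
    for g in GROUPS:
        if sizes.get(g, 0) < 2:
            raise ValueError(
                f"group {g!r} has fewer than 2 retained flies; aborting")

    metrics = metrics_table(kept_traces, kept_records, analysis, segs=segs)
    per_fly = per_fly_summary(metrics)
    cut = float(metrics["common_cut"].iloc[0])
    stats_report = build_stats_report(metrics, per_fly, analysis,
                                      seed=sim.seed)

    manifest = RunManifest(
        config=to_flat_dict(protocol, sim, analysis),
        seed=sim.seed,
        software_version=__version__,
        input_digests={t.fly_id: _trace_digest(t) for t in traces},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        common_cut=cut,
    )

    figures: List[str] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        per_fly.to_csv(out / "per_fly.csv", index=False)
        if episode_table is not None:
            episode_table.to_csv(out / "episodes.csv", index=False)
        (out / "curation.json").write_text(
            json.dumps(curation.to_dict(), indent=2))
        (out / "stats_report.json").write_text(
            json.dumps(stats_report, indent=2))
        (out / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2))
        if make_figures:
            figures = _make_figures(metrics, per_fly, kept_traces, segs,
                                    cut, out / "figures")
    elif make_figures:
        raise ValueError("make_figures requires out_dir")

    return PipelineResult(metrics=metrics, per_fly=per_fly, curation=curation,
                          stats_report=stats_report, manifest=manifest,
                          episode_table=episode_table, figures=figures)
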