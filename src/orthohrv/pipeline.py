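"""End-to-end orchestration: read -> clean -> segment -> panels ->
deltas -> summaries -> tests -> (optional) permutation specificity.

The results bundle holds tidy DataFrames only; rendered tables are pure
formatting of those frames ("median (Q1–Q3)" cells with star/letter
annotations), with no additional arithmetic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (ComparisonResult, comparison_frame, omnibus_test,
                           pairwise_tests, summarize)
from .hrv_metrics import METRIC_NAMES, compute_panel, panel_frame
from .io_protocol import (ProtocolDefinition, RRSeries, clean_rr, read_metadata,
                          read_rr, segment_phases)
from .permutation_null import specificity_test
from .response_stats import delta_panels, delta_wide

log = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    panels: pd.DataFrame
    deltas: pd.DataFrame
    phase_summary: pd.DataFrame
    delta1_summary: pd.DataFrame
    delta2_summary: pd.DataFrame
    phase_tests: pd.DataFrame
    group_tests: pd.DataFrame
    run_log: dict = field(default_factory=dict)
    specificity: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.panels.to_csv(out / "panels.csv", index=False)
        self.deltas.to_csv(out / "deltas.csv", index=False)
        self.phase_summary.to_csv(out / "summary_phases.csv", index=False)
        self.delta1_summary.to_csv(out / "summary_delta1.csv", index=False)
        self.delta2_summary.to_csv(out / "summary_delta2.csv", index=False)
        self.phase_tests.to_csv(out / "tests_phases.csv", index=False)
        self.group_tests.to_csv(out / "tests_groups.csv", index=False)
        if self.specificity is not None:
            self.specificity.to_csv(out / "specificity.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=1))


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def analyze_cohort(series: Mapping[str, RRSeries], metadata: pd.DataFrame,
                   protocol: ProtocolDefinition | None = None, *,
                   clean_policy: str = "interpolate", min_beats: int = 60,
                   metrics: Sequence[str] | None = None,
                   paired_phase_tests: bool = True) -> ResultsBundle:
    """Run the full analysis on in-memory RR series plus metadata.

    Subjects failing validation, or missing an analyzable phase, are
    excluded with a logged reason; the pipeline errors only when no
    subject survives.
    """
    protocol = protocol or ProtocolDefinition.default()
    metric_cols = list(metrics) if metrics is not None else list(METRIC_NAMES)
    meta = metadata.set_index("subject_id")

    panels = []
    dropped: dict[str, str] = {}
    for sid in meta.index:
        if sid not in series:
            dropped[sid] = "no RR recording"
            continue
        try:
            cleaned, report = clean_rr(series[sid], policy=clean_policy)
            segs = segment_phases(cleaned, protocol, min_beats=min_beats)
        except ValueError as exc:
            dropped[sid] = f"validation: {exc}"
            continue
        subj_panels = [compute_panel(seg, metrics=metric_cols) for seg in segs]
        bad = [p for p in subj_panels if p.insufficient_reason]
        if bad:
            dropped[sid] = f"insufficient segment(s): {bad[0].insufficient_reason}"
            continue
        panels.extend(subj_panels)
    if not panels:
        raise ValueError("no subjects survived validation")
    if dropped:
        for sid, why in dropped.items():
            log.warning("subject %s excluded: %s", sid, why)

    panel_df = panel_frame(panels)
    panel_df = panel_df.merge(metadata[["subject_id", "group_label"]],
                              on="subject_id", how="left")
    phase_names = [p[0] for p in protocol.phases]
    delta_df = delta_panels(panel_df, phases=phase_names, metrics=metric_cols)
    delta_df = delta_df.merge(metadata[["subject_id", "group_label"]],
                              on="subject_id", how="left")

    phase_summary = summarize(panel_df, metric_cols, by=["group_label", "phase_name"])
    d1w = delta_wide(delta_df, "delta1_pct").join(meta["group_label"])
    d2w = delta_wide(delta_df, "delta2_pct").join(meta["group_label"])
    present = [m for m in metric_cols if m in d1w.columns]
    delta1_summary = summarize(d1w, present, by=["group_label"])
    delta2_summary = summarize(d2w, present, by=["group_label"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phase_tests = _phase_tests(panel_df, phase_names, metric_cols) \
            if paired_phase_tests else pd.DataFrame()
        group_tests = _group_tests(d1w, d2w, present)

    run_log = {
        "version": __version__,
        "n_subjects": int(panel_df["subject_id"].nunique()),
        "n_dropped": len(dropped),
        "dropped": dropped,
        "config_hash": _config_hash({
            "clean_policy": clean_policy, "min_beats": min_beats,
            "metrics": metric_cols,
            "protocol": [list(p) for p in protocol.phases]}),
    }
    return ResultsBundle(panels=panel_df, deltas=delta_df,
                         phase_summary=phase_summary,
                         delta1_summary=delta1_summary,
                         delta2_summary=delta2_summary,
                         phase_tests=phase_tests, group_tests=group_tests,
                         run_log=run_log)


def _phase_tests(panel_df: pd.DataFrame, phases: Sequence[str],
                 metrics: Sequence[str]) -> pd.DataFrame:
    """Paired phase contrasts (pooled across groups) per metric."""
    results: list[ComparisonResult] = []
    wide = {p: panel_df[panel_df.phase_name == p].set_index("subject_id")
            for p in phases}
    common = sorted(set.intersection(*(set(w.index) for w in wide.values())))
    for metric in metrics:
        data = {p: wide[p].loc[common, metric].to_numpy(float) for p in phases}
        results.extend(pairwise_tests(data, paired=True, metric_name=metric))
    return comparison_frame(results)


def _group_tests(d1w: pd.DataFrame, d2w: pd.DataFrame,
                 metrics: Sequence[str]) -> pd.DataFrame:
    """Omnibus + pairwise group contrasts on %Δ1 and %Δ2 per metric."""
    results: list[ComparisonResult] = []
    for tag, wide in (("delta1", d1w), ("delta2", d2w)):
        labels = wide["group_label"].to_numpy()
        if len(pd.unique(labels)) < 2:
            continue
        for metric in metrics:
            v = wide[metric].to_numpy(float)
            try:
                res = omnibus_test(v, labels, metric_name=f"{tag}:{metric}")
            except ValueError:
                continue
            results.append(res)
            results.extend(pairwise_tests(v, labels,
                                          metric_name=f"{tag}:{metric}"))
    return comparison_frame(results)


def run_pipeline(data_dir: str | Path,
                 protocol: ProtocolDefinition | None = None, *,
                 dialect: str = "plain_ms", clean_policy: str = "interpolate",
                 min_beats: int = 60, metrics: Sequence[str] | None = None,
                 out_dir: str | Path | None = None) -> ResultsBundle:
    """File-based entry point: reads ``metadata.csv`` plus one RR file per
    subject from ``data_dir`` and runs :func:`analyze_cohort`."""
    data_dir = Path(data_dir)
    meta_path = data_dir / "metadata.csv"
    if not meta_path.exists():
        raise ValueError(f"no subjects: {meta_path} not found")
    metadata = read_metadata(meta_path)
    ext = "txt" if dialect == "plain_ms" else "csv"
    series = {}
    for sid in metadata["subject_id"]:
        path = data_dir / f"{sid}.{ext}"
        if path.exists():
            series[sid] = read_rr(path, dialect=dialect, subject_id=sid)
    if not series:
        raise ValueError(f"no subjects: no RR files found in {data_dir}")
    bundle = analyze_cohort(series, metadata, protocol,
                            clean_policy=clean_policy, min_beats=min_beats,
                            metrics=metrics)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def run_specificity(bundle: ResultsBundle, which: str = "delta1_pct",
                    metrics: Sequence[str] | None = None,
                    n_perm: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Label-permutation specificity on the bundle's delta table."""
    wide = delta_wide(bundle.deltas, which)
    labels = (bundle.deltas.drop_duplicates("subject_id")
              .set_index("subject_id")["group_label"].reindex(wide.index))
    result = specificity_test(wide, labels.to_numpy(), metric_set=metrics,
                              n_perm=n_perm, seed=seed)
    bundle.specificity = result
    return result


# ---------------------------------------------------------------------------
# rendering


def format_cell(median: float, q1: float, q3: float) -> str:
    if not np.isfinite(median):
        return "-"
    return f"{median:.4g} ({q1:.4g}–{q3:.4g})"


def _annotation(pairwise: pd.DataFrame) -> str:
    """Letter codes for significant pairwise contrasts: the contrast letter
    repeated once per significance star (e.g. 'aaa' = contrast a, p<.001)."""
    codes = []
    for _, row in pairwise.iterrows():
        stars = len(row["significance_code"])
        if stars and row["contrast_letter"]:
            codes.append(row["contrast_letter"] * stars)
    return ",".join(codes)


def render_summary_table(summary: pd.DataFrame, tests: pd.DataFrame | None,
                         group_col: str = "group_label",
                         metric_prefix: str = "") -> str:
    """Plain-text table: one row per metric, 'median (Q1–Q3)' per group,
    omnibus p and significant-contrast codes."""
    groups = list(pd.unique(summary[group_col]))
    lines = ["\t".join(["metric"] + groups + ["p_value", "contrasts"])]
    for metric in pd.unique(summary["metric"]):
        row = [metric]
        for g in groups:
            cell = summary[(summary["metric"] == metric) & (summary[group_col] == g)]
            if len(cell) == 0 or cell.iloc[0]["n"] == 0:
                row.append("-")
            else:
                c = cell.iloc[0]
                row.append(format_cell(c["median"], c["q1"], c["q3"]))
        p_txt, ann = "", ""
        if tests is not None and len(tests):
            mt = tests[tests["metric_name"] == f"{metric_prefix}{metric}"]
            omni = mt[mt["contrast"] == "omnibus"]
            if len(omni):
                p_txt = f"{omni.iloc[0]['p_raw']:.3g}"
            ann = _annotation(mt[mt["contrast"] != "omnibus"])
        row += [p_txt, ann]
        lines.append("\t".join(row))
    return "\n".join(lines)


def render_tables(bundle: ResultsBundle) -> dict[str, str]:
    """Render the per-phase and delta summary tables as text."""
    out = {}
    phase_sum = bundle.phase_summary.copy()
    phase_sum["stratum"] = phase_sum["group_label"] + "/" + phase_sum["phase_name"]
    out["phases"] = render_summary_table(phase_sum, None, group_col="stratum")
    out["delta1"] = render_summary_table(bundle.delta1_summary, bundle.group_tests,
                                         metric_prefix="delta1:")
    out["delta2"] = render_summary_table(bundle.delta2_summary, bundle.group_tests,
                                         metric_prefix="delta2:")
    return out
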