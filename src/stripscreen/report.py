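"""Figures, cohort summary tables and end-to-end orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .colorimetry import COMBINED_RGB_COLUMN, FEATURE_SCHEMA, extract_cohort_features
from .longitudinal import GROUPINGS, compliance_table, trajectory_table, weekly_changes
from .screen import TIME_POINTS, ColorVariableScreen
from .simulate import SimulationConfig, generate_cohort, write_cohort

logger = logging.getLogger("stripscreen")

__all__ = ["RunConfig", "make_heatmap", "plot_trajectories", "cohort_summary", "run_all"]

#: Heat-map column order: grouping-major, then time point.
HEATMAP_COLUMNS = [(g, tp) for g in GROUPINGS for tp in TIME_POINTS]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    outdir: str = "run"
    simulate: SimulationConfig | None = None
    images_dir: str | None = None  # used instead of simulation when set
    participants_path: str | None = None
    testlog_path: str | None = None
    landmark_week: int = 25
    groupings: tuple = tuple(GROUPINGS)
    ci_method: str = "delong"
    significance_rule: str = "ci_bound"
    trajectory_subset: int = 10
    trajectory_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        cfg.groupings = tuple(cfg.groupings)
        return cfg


def make_heatmap(results: pd.DataFrame, path=None, ax=None):
    """AUC heat map: 72 variable rows (schema order, grouped by color
    model) × grouping-major time-point columns. The diverging scale is
    anchored at the no-information AUC of 50 — green toward 100, red
    toward 0 — and missing cells are rendered neutral grey."""
    if results is None or len(results) == 0:
        raise ValueError("no screen results to plot")
    variables = list(FEATURE_SCHEMA)
    mat = np.full((len(variables), len(HEATMAP_COLUMNS)), np.nan)
    col_index = {c: j for j, c in enumerate(HEATMAP_COLUMNS)}
    var_index = {v: i for i, v in enumerate(variables)}
    for r in results.itertuples(index=False):
        key = (r.grouping, r.time_point)
        if r.variable in var_index and key in col_index:
            mat[var_index[r.variable], col_index[key]] = r.auc
    masked = np.ma.masked_invalid(mat)
    cmap = plt.get_cmap("RdYlGn").copy()
    cmap.set_bad("0.85")
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(9, 14))
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=100, aspect="auto")
    ax.set_yticks(range(len(variables)))
    ax.set_yticklabels(variables, fontsize=5)
    ax.set_xticks(range(len(HEATMAP_COLUMNS)))
    ax.set_xticklabels([f"{g}\n{tp}" for g, tp in HEATMAP_COLUMNS], fontsize=5, rotation=90)
    ax.figure.colorbar(im, ax=ax, label="AUC (0-100; 50 = no discrimination)")
    ax.set_title("Discriminatory ability of the 72 color variables")
    if path is not None and own_fig:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


_STRATUM_COLORS = {"normotensive": "tab:blue", "pih": "tab:green",
                   "pe": "tab:orange", "iugr": "tab:red"}


def plot_trajectories(trajectories: pd.DataFrame, path=None, ax=None):
    """Weekly combined-minimum-RGB trajectories by outcome stratum, with
    the 110 reference level that separated growth-restricted pregnancies."""
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(8, 5))
    for pid, grp in trajectories.groupby("participant_id"):
        stratum = grp["stratum"].iloc[0]
        ax.plot(grp["week"], grp["value"], color=_STRATUM_COLORS.get(stratum, "gray"),
                alpha=0.9 if stratum == "iugr" else 0.35, lw=1.5 if stratum == "iugr" else 0.8)
    ax.axhline(110, color="k", ls="--", lw=0.8)
    ax.set_xlabel("gestational week")
    ax.set_ylabel("combined minimum RGB value")
    ax.set_ylim(0, 255)
    handles = [plt.Line2D([], [], color=c, label=s) for s, c in _STRATUM_COLORS.items()]
    ax.legend(handles=handles, fontsize=8)
    if path is not None and own_fig:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def _median_iqr(x: pd.Series) -> str:
    if len(x) == 0:
        return "-"
    q1, q2, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{q2:.1f} ({q3 - q1:.1f})"


def cohort_summary(participants: pd.DataFrame, compliance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Outcome-group summary of a participant table.

    Handles an optional boolean ``excluded`` column (e.g. a bad strip
    batch): excluded rows are counted but dropped from the group rows.
    Returns one row per group — normotensive non-IUGR, PE, PIH, PE∪PIH,
    IUGR, any outcome — with n, % of eligible, and (when compliance is
    given) median (IQR) samples submitted and compliance rate, plus
    enrolled/excluded/eligible accounting rows.
    """
    enrolled = len(participants)
    if "excluded" in participants.columns:
        excluded = int(participants["excluded"].astype(bool).sum())
        eligible = participants[~participants["excluded"].astype(bool)]
    else:
        excluded = 0
        eligible = participants
    n_el = len(eligible)

    pe = eligible["pe"].astype(bool)
    pih = eligible["pih"].astype(bool)
    iugr = eligible["iugr"].astype(bool)
    groups = {
        "normotensive_non_iugr": ~(pe | pih | iugr),
        "pe": pe,
        "pih": pih,
        "pe_pih": pe | pih,
        "iugr": iugr,
        "any_outcome": pe | pih | iugr,
    }
    comp = None
    if compliance is not None:
        comp = compliance.set_index("id")
    rows = []
    for name, mask in groups.items():
        row = {"group": name, "n": int(mask.sum()),
               "pct": 100.0 * mask.sum() / n_el if n_el else 0.0}
        if comp is not None:
            ids = eligible.loc[mask, "id"]
            sub = comp.loc[comp.index.intersection(ids)]
            row["samples_submitted_median_iqr"] = _median_iqr(sub["n_submitted"])
            row["compliance_median_iqr"] = _median_iqr(sub["rate"])
            row["compliance_mean"] = float(sub["rate"].mean()) if len(sub) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_enrolled"] = enrolled
    out.attrs["n_excluded"] = excluded
    out.attrs["n_eligible"] = n_el
    return out


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Full pipeline: (simulate) → extract → longitudinal → screen → report.

    Writes under ``config.outdir``: participants.csv, testlog.csv,
    features.csv, landmark/changes/trajectories/exclusions CSVs,
    screen_results.csv, screen_skipped.csv, summary tables, the heat map
    and trajectory figures, and a run manifest. Idempotent given a fixed
    seed. Any stage failure raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            logger.info("simulating cohort (n=%d, seed=%d)",
                        config.simulate.n_participants, config.simulate.seed)
            cohort = generate_cohort(config.simulate)
            write_cohort(cohort, outdir)
            participants = cohort.participants_frame()
            testlog = cohort.testlog
            images_dir = outdir / "images"
        else:
            stage = "load"
            participants = pd.read_csv(config.participants_path)
            testlog = pd.read_csv(config.testlog_path)
            images_dir = Path(config.images_dir)
            if not images_dir.is_dir():
                raise FileNotFoundError(f"images directory not found: {images_dir}")

        stage = "extract"
        logger.info("extracting features from %s", images_dir)
        if not Path(images_dir).is_dir():
            raise FileNotFoundError(f"images directory not found: {images_dir}")
        features = extract_cohort_features(images_dir, testlog)
        features.to_csv(outdir / "features.csv", index=False)

        stage = "longitudinal"
        comp = compliance_table(participants, testlog)
        comp.to_csv(outdir / "compliance.csv", index=False)
        changes = weekly_changes(features)
        changes.to_csv(outdir / "changes.csv", index=False)
        traj = trajectory_table(participants, features,
                                subset_size=config.trajectory_subset,
                                seed=config.trajectory_seed)
        traj.to_csv(outdir / "trajectories.csv", index=False)

        stage = "screen"
        model = ColorVariableScreen(
            features, participants,
            landmark_week=config.landmark_week,
            groupings=config.groupings,
            ci_method=config.ci_method,
            significance_rule=config.significance_rule,
        )
        res = model.fit()
        res.to_csv(outdir / "screen_results.csv")
        res.skipped.to_csv(outdir / "screen_skipped.csv", index=False)
        res.exclusion_log().to_csv(outdir / "exclusions.csv", index=False)
        for g, ds in res.landmark_datasets.items():
            ds.data.to_csv(outdir / f"landmark_{g}.csv", index=False)

        stage = "report"
        summary = cohort_summary(participants, comp)
        summary.to_csv(outdir / "cohort_summary.csv", index=False)
        (outdir / "screen_summary.txt").write_text(res.summary() + "\n")
        if len(res.results):
            make_heatmap(res.results, path=outdir / "heatmap.png")
        if len(traj):
            plot_trajectories(traj, path=outdir / "trajectories.png")
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.simulate.seed if config.simulate else None,
            "n_participants": int(len(participants)),
            "n_tests": int(len(features)),
            "n_analyses": int(len(res.results)),
            "stages": ["simulate" if config.simulate else "load", "extract",
                       "longitudinal", "screen", "report"],
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    except Exception as e:
        logger.error("pipeline failed at stage %r: %s", stage, e)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    return outdir
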