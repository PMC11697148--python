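"""AUC discrimination screen over the 72 color variables.

For every (variable, outcome grouping, time point) cell the screen computes
the area under the ROC curve as the Mann–Whitney concordance probability
(ties count one half), reported on a 0–100 scale with a 95% confidence
interval, by default from DeLong's method. A cell shows *significant
discriminatory ability* when its CI lower bound exceeds the no-information
benchmark of 50 (a point-estimate rule is available as an option but would
flag about half of all null analyses). No multiple-testing correction is
applied to the significance flag; Benjamini–Hochberg adjusted p-values are
emitted as a supplementary column only.

The screen is exposed in two layers:

* functional: :func:`auc_with_ci`, :func:`run_screen`,
  :func:`summarize_screen`;
* model-style: :class:`ColorVariableScreen` (built from the feature and
  participant tables) whose :meth:`~ColorVariableScreen.fit` returns a
  :class:`ScreenResults` carrying the estimates, CIs, diagnostics, a
  ``summary()`` table and the heat-map plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .colorimetry import FEATURE_SCHEMA
from .longitudinal import (
    GROUPINGS,
    LandmarkDataset,
    build_change_dataset,
    build_landmark_dataset,
    weekly_changes,
)

__all__ = [
    "AUCResult",
    "ScreenSummary",
    "auc_with_ci",
    "run_screen",
    "summarize_screen",
    "ColorVariableScreen",
    "ScreenResults",
]

#: Screen time points in report order: the week-25 level then the five
#: adjacent weekly changes.
TIME_POINTS = ("week25", "d20_21", "d21_22", "d22_23", "d23_24", "d24_25")

_Z975 = float(_stats.norm.ppf(0.975))


@dataclass
class AUCResult:
    """One cell of the screen, on the 0–100 scale."""

    variable: str
    grouping: str
    time_point: str
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    se: float = np.nan
    p_value: float = np.nan
    low_n: bool = False
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.ci_low > 50.0)


def _midranks(x: np.ndarray) -> np.ndarray:
    return _stats.rankdata(x, method="average", axis=0)


def _auc_core(cases: np.ndarray, controls: np.ndarray):
    """Vectorised Mann–Whitney AUC + DeLong variance.

    ``cases`` is (m, k), ``controls`` (n, k); returns (auc, var, degenerate,
    low_n) each of length k, AUC on the probability scale.
    """
    m, n = cases.shape[0], controls.shape[0]
    allv = np.concatenate([cases, controls], axis=0)
    r_all = _midranks(allv)
    r_x = _midranks(cases)
    r_y = _midranks(controls)
    auc = (r_all[:m].sum(axis=0) - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    s10 = v10.var(axis=0, ddof=1) if m > 1 else np.zeros(cases.shape[1])
    s01 = v01.var(axis=0, ddof=1) if n > 1 else np.zeros(controls.shape[1])
    var = s10 / m + s01 / n
    degenerate = allv.max(axis=0) == allv.min(axis=0)
    low_n = (m < 2) or (n < 2)
    return auc, var, degenerate, low_n


def _hanley_mcneil_var(auc: np.ndarray, m: int, n: int) -> np.ndarray:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (auc * (1.0 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)


def auc_with_ci(
    case_values,
    control_values,
    variable: str = "",
    grouping: str = "",
    time_point: str = "",
    ci_method: str = "delong",
) -> AUCResult:
    """AUC (0–100 scale) with a 95% CI for one case/control comparison.

    The AUC is the Mann–Whitney probability that a random case scores above
    a random control, ties counting one half. The CI is DeLong's (default)
    or Hanley–McNeil's, truncated to [0, 100]. Orientation is never
    flipped: values below 50 are reported as-is. A pooled sample with no
    variation yields AUC 50 with a degenerate (zero-width) CI, flagged.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one case and one control")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("AUC inputs must be finite")
    auc, var, degenerate, low_n = _auc_core(x[:, None], y[:, None])
    auc, var, degenerate = float(auc[0]), float(var[0]), bool(degenerate[0])
    if ci_method == "hanley-mcneil":
        var = float(_hanley_mcneil_var(np.array([auc]), x.size, y.size)[0])
    elif ci_method != "delong":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - _Z975 * se)
    hi = min(1.0, auc + _Z975 * se)
    p = 2.0 * _stats.norm.sf(abs(auc - 0.5) / se) if se > 0 else (1.0 if auc == 0.5 else 0.0)
    return AUCResult(
        variable=variable,
        grouping=grouping,
        time_point=time_point,
        auc=100.0 * auc,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        n_cases=int(x.size),
        n_controls=int(y.size),
        se=100.0 * se,
        p_value=float(p),
        low_n=low_n,
        degenerate=degenerate,
    )


def _screen_cell(dataset: LandmarkDataset, time_point: str, ci_method: str,
                 variables) -> tuple[list[dict], list[dict]]:
    """All variables of one (grouping, time point) cell, vectorised."""
    results, skipped = [], []
    cases = dataset.data[dataset.data["case"]]
    controls = dataset.data[~dataset.data["case"]]
    if len(cases) == 0 or len(controls) == 0:
        skipped.append(
            {
                "grouping": dataset.grouping,
                "time_point": time_point,
                "reason": "no cases" if len(cases) == 0 else "no controls",
            }
        )
        return results, skipped
    x = cases[list(variables)].to_numpy(dtype=float)
    y = controls[list(variables)].to_numpy(dtype=float)
    auc, var, degenerate, low_n = _auc_core(x, y)
    if ci_method == "hanley-mcneil":
        var = _hanley_mcneil_var(auc, x.shape[0], y.shape[0])
    se = np.sqrt(np.maximum(var, 0.0))
    lo = np.maximum(0.0, auc - _Z975 * se)
    hi = np.minimum(1.0, auc + _Z975 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(auc - 0.5) / se
    p = np.where(se > 0, 2.0 * _stats.norm.sf(z), np.where(auc == 0.5, 1.0, 0.0))
    for j, v in enumerate(variables):
        results.append(
            {
                "variable": v,
                "grouping": dataset.grouping,
                "time_point": time_point,
                "auc": 100.0 * auc[j],
                "ci_low": 100.0 * lo[j],
                "ci_high": 100.0 * hi[j],
                "se": 100.0 * se[j],
                "p_value": p[j],
                "n_cases": x.shape[0],
                "n_controls": y.shape[0],
                "low_n": bool(low_n),
                "degenerate": bool(degenerate[j]),
            }
        )
    return results, skipped


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (supplementary output only)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def run_screen(
    landmark_datasets: dict[str, LandmarkDataset],
    change_datasets: dict[tuple[str, str], LandmarkDataset],
    ci_method: str = "delong",
    significance_rule: str = "ci_bound",
    variables=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full screen: variables × groupings × time points.

    Parameters
    ----------
    landmark_datasets : mapping grouping → LandmarkDataset (week-25 level).
    change_datasets : mapping (grouping, week_pair) → LandmarkDataset.
    significance_rule : ``"ci_bound"`` (CI lower bound > 50, default) or
        ``"point"`` (point estimate > 50).

    Returns
    -------
    (results, skipped) : results has one row per computed cell with columns
        variable, grouping, time_point, auc, ci_low, ci_high, se, p_value,
        p_bh, n_cases, n_controls, significant, low_n, degenerate; skipped
        logs (grouping, time_point, reason) for combinations that could not
        be computed.
    """
    if variables is None:
        variables = list(FEATURE_SCHEMA)  # the 72 schema variables
    rows, skipped = [], []
    for grouping in landmark_datasets:
        res, skip = _screen_cell(landmark_datasets[grouping], "week25", ci_method, variables)
        rows.extend(res)
        skipped.extend(skip)
    for (grouping, pair), ds in change_datasets.items():
        res, skip = _screen_cell(ds, pair, ci_method, variables)
        rows.extend(res)
        skipped.extend(skip)
    _dtypes = {
        "variable": str, "grouping": str, "time_point": str, "auc": float,
        "ci_low": float, "ci_high": float, "se": float, "p_value": float,
        "n_cases": int, "n_controls": int, "low_n": bool, "degenerate": bool,
    }
    results = pd.DataFrame(rows, columns=list(_dtypes))
    if len(results) == 0:
        results = results.astype(_dtypes)
    if len(results):
        if significance_rule == "ci_bound":
            sig = results["ci_low"] > 50.0
        elif significance_rule == "point":
            sig = results["auc"] > 50.0
        else:
            raise ValueError(f"unknown significance_rule {significance_rule!r}")
        results["significant"] = sig & ~results["degenerate"]
        results["p_bh"] = _bh_adjust(results["p_value"].to_numpy())
    else:
        results["significant"] = pd.Series(dtype=bool)
        results["p_bh"] = pd.Series(dtype=float)
    skipped = pd.DataFrame(skipped, columns=["grouping", "time_point", "reason"])
    return results, skipped


@dataclass
class ScreenSummary:
    n_analyses: int
    n_significant: int
    family_counts: dict[str, int]
    top: pd.DataFrame

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_analyses if self.n_analyses else 0.0

    def family_share(self, family: str) -> float:
        """Share (%) of significant results whose variable belongs to a
        channel family (the channel prefix of the variable name)."""
        if self.n_significant == 0:
            return 0.0
        return 100.0 * self.family_counts.get(family, 0) / self.n_significant


def summarize_screen(results: pd.DataFrame, top_k: int = 5) -> ScreenSummary:
    """Aggregate a screen: significant fraction, per-channel-family counts
    among significant results, and the top-k cells by AUC with CIs."""
    if len(results) == 0:
        return ScreenSummary(0, 0, {}, results)
    sig = results[results["significant"]]
    family = sig["variable"].str.split("_").str[0]
    fam_counts = family.value_counts().to_dict()
    top = results.sort_values("auc", ascending=False).head(top_k)
    top = top[["variable", "grouping", "time_point", "auc", "ci_low", "ci_high"]]
    return ScreenSummary(
        n_analyses=int(len(results)),
        n_significant=int(len(sig)),
        family_counts=fam_counts,
        top=top.reset_index(drop=True),
    )


class ColorVariableScreen:
    """Discrimination screen as a fitted-model object.

    Built from the per-test feature table and the participant table;
    ``fit()`` assembles the landmark and weekly-change datasets for every
    outcome grouping and computes the AUC screen.

    Parameters
    ----------
    features : DataFrame
        One row per submitted test: participant_id, week, the 72 schema
        variables and combined_rgb_min.
    participants : DataFrame
        One row per woman: id, enrollment_week, delivery_week, pe, pih,
        iugr, event_week_* (optionally an ``excluded`` flag column, whose
        True rows are dropped before analysis).
    landmark_week : int, default 25
    groupings : sequence of grouping names, default all three.
    change_weeks : (start, end) window of the weekly-change analysis.
    ci_method : "delong" (default) or "hanley-mcneil".
    significance_rule : "ci_bound" (default) or "point".
    """

    def __init__(
        self,
        features: pd.DataFrame,
        participants: pd.DataFrame,
        landmark_week: int = 25,
        groupings=tuple(GROUPINGS),
        change_weeks: tuple[int, int] = (20, 25),
        ci_method: str = "delong",
        significance_rule: str = "ci_bound",
        variables=None,
    ):
        if "excluded" in participants.columns:
            participants = participants[~participants["excluded"].astype(bool)]
        unknown = [g for g in groupings if g not in GROUPINGS]
        if unknown:
            raise ValueError(f"unknown groupings: {unknown}")
        self.features = features
        self.participants = participants.reset_index(drop=True)
        self.landmark_week = int(landmark_week)
        self.groupings = tuple(groupings)
        self.change_weeks = tuple(change_weeks)
        self.ci_method = ci_method
        self.significance_rule = significance_rule
        self.variables = variables

    @classmethod
    def from_csv(cls, features_path, participants_path, **kwargs):
        return cls(pd.read_csv(features_path), pd.read_csv(participants_path), **kwargs)

    def build_datasets(self):
        landmark = {
            g: build_landmark_dataset(
                self.participants, self.features, self.landmark_week, g
            )
            for g in self.groupings
        }
        changes = weekly_changes(self.features, *self.change_weeks)
        change_ds = {}
        for g in self.groupings:
            for w in range(self.change_weeks[0], self.change_weeks[1]):
                pair = f"d{w}_{w + 1}"
                change_ds[(g, pair)] = build_change_dataset(
                    self.participants, changes, pair, g
                )
        return landmark, change_ds

    def fit(self) -> "ScreenResults":
        landmark, change_ds = self.build_datasets()
        results, skipped = run_screen(
            landmark,
            change_ds,
            ci_method=self.ci_method,
            significance_rule=self.significance_rule,
            variables=self.variables,
        )
        return ScreenResults(self, results, skipped, landmark, change_ds)


class ScreenResults:
    """Results of a fitted :class:`ColorVariableScreen`.

    Attributes
    ----------
    results : DataFrame — one row per computed (variable, grouping, time
        point) cell with AUC, CI, p-values and flags.
    skipped : DataFrame — combinations that produced no result, with reason.
    landmark_datasets, change_datasets : the assembled input datasets
        (each with its exclusion log).
    """

    def __init__(self, model, results, skipped, landmark_datasets, change_datasets):
        self.model = model
        self.results = results
        self.skipped = skipped
        self.landmark_datasets = landmark_datasets
        self.change_datasets = change_datasets

    @property
    def screen_summary(self) -> ScreenSummary:
        return summarize_screen(self.results)

    def exclusion_log(self) -> pd.DataFrame:
        frames = []
        for g, ds in self.landmark_datasets.items():
            f = ds.exclusions.copy()
            f["grouping"], f["time_point"] = g, "week25"
            frames.append(f)
        for (g, pair), ds in self.change_datasets.items():
            f = ds.exclusions.copy()
            f["grouping"], f["time_point"] = g, pair
            frames.append(f)
        cols = ["participant_id", "reason", "grouping", "time_point"]
        return pd.concat(frames, ignore_index=True)[cols] if frames else pd.DataFrame(columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        """Results with AUC and CI rounded to one decimal, report-style."""
        out = self.results.copy()
        for c in ("auc", "ci_low", "ci_high"):
            out[c] = out[c].round(1)
        return out

    def summary(self) -> str:
        s = self.screen_summary
        lines = [
            "Color-variable discrimination screen",
            "=" * 52,
            f"analyses computed:    {s.n_analyses}",
            f"skipped cells:        {len(self.skipped)}",
            f"significant (CI>50):  {s.n_significant} ({s.pct_significant:.1f}%)",
        ]
        if s.family_counts:
            fams = ", ".join(f"{k}: {v}" for k, v in sorted(s.family_counts.items()))
            lines.append(f"families among significant: {fams}")
        lines.append("")
        lines.append("Top cells by AUC (0-100 scale, 95% CI):")
        for r in s.top.itertuples(index=False):
            lines.append(
                f"  {r.variable:<18} {r.grouping:<12} {r.time_point:<7} "
                f"{r.auc:5.1f} ({r.ci_low:.1f}-{r.ci_high:.1f})"
            )
        return "\n".join(lines)

    def plot_heatmap(self, path=None, ax=None):
        from .report import make_heatmap

        return make_heatmap(self.results, path=path, ax=ax)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)
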