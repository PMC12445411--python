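"""Cohort-level normative statistics for transmural perfusion metrics.

The entry point is the :class:`TransmuralNormals` model: built from a tidy
cohort table (one row per subject, columns for demographics, hemodynamics
and every perfusion metric), its :meth:`~TransmuralNormals.fit` derives the
normative report — per-metric descriptive summaries, 95% cohort ranges
(2.5th–97.5th percentiles), bootstrap confidence intervals of the median,
sex comparisons, age correlations and slice contrasts — and returns a
:class:`TransmuralNormalsResults` object with the seven report tables and a
``summary()`` rendering.

Statistical conventions
-----------------------
A Shapiro–Wilk gate at alpha = 0.05 decides, per metric and stratum, both
the presentation (mean ± SD when normal, median ± IQR otherwise) and the
test family (t-tests / ANOVA / Pearson when normal; Mann–Whitney, Wilcoxon,
Friedman, Spearman otherwise).  Percentiles use linear interpolation; the
IQR is Q3 − Q1.  The CI of the median is a seeded percentile bootstrap
(2,000 resamples by default).  Raw p-values are reported except for the
three-way slice contrasts, which are Bonferroni-adjusted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_NORMALITY = 0.05
_SHAPIRO_MAX_N = 5000


class CohortError(ValueError):
    """Raised when cohort statistics are requested on invalid input."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return np.sort(v[np.isfinite(v)])


def normality_gate(values) -> tuple[bool, float]:
    """Shapiro–Wilk decision: (is_normal, p).

    Degenerate samples (n < 3 or zero spread) are routed to the
    non-parametric branch with an undefined p.  For n > 5000 the test runs
    on 5000 evenly spaced order statistics, which keeps the gate
    deterministic and order-invariant.
    """
    v = _clean(values)
    if v.size < 3 or v.std() == 0:
        return False, float("nan")
    if v.size > _SHAPIRO_MAX_N:
        idx = np.linspace(0, v.size - 1, _SHAPIRO_MAX_N).round().astype(int)
        v = v[idx]
    p = float(stats.shapiro(v).pvalue)
    return p >= ALPHA_NORMALITY, p


def _task_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def summarize(values, n_boot: int = 2000, seed: int = 0,
              label: str = "") -> dict[str, float]:
    """Descriptive summary of one metric sample.

    Returns n, mean, sd, median, iqr (Q3 − Q1), the 95% cohort range
    (2.5th–97.5th percentiles, linear interpolation), a bootstrap 95% CI of
    the median, the Shapiro–Wilk p and the chosen presentation.
    """
    v = _clean(values)
    if v.size < 2:
        raise CohortError("summary statistics need at least 2 values")
    is_normal, p_norm = normality_gate(v)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    lo, hi = np.percentile(v, [2.5, 97.5])
    rng = _task_rng(seed, f"median-ci|{label}")
    # chunked so large samples never materialise an n_boot x n matrix
    chunk = max(int(2e7 // v.size), 1)
    boots = np.concatenate([
        np.median(rng.choice(v, size=(min(chunk, n_boot - i), v.size),
                             replace=True), axis=1)
        for i in range(0, n_boot, chunk)])
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(med),
        "iqr": float(q3 - q1),
        "q1": float(q1),
        "q3": float(q3),
        "normal_range_low": float(lo),
        "normal_range_high": float(hi),
        "ci_low": float(ci_lo),
        "ci_high": float(ci_hi),
        "normality_p": p_norm,
        "normal": bool(is_normal),
        "presentation": "mean±sd" if is_normal else "median±iqr",
    }


@dataclass
class ComparisonResult:
    metric: str
    groups: str
    test: str
    statistic: float
    p_value: float
    direction: float  # sign of (first − second) central tendency

    def as_dict(self) -> dict:
        return {"metric": self.metric, "groups": self.groups,
                "test": self.test, "statistic": self.statistic,
                "p_value": self.p_value, "direction": self.direction}


def compare_groups(values_a, values_b, paired: bool = False,
                   metric: str = "", groups: str = "") -> ComparisonResult:
    """Two-group comparison with the normality-gated test choice.

    Normal on both sides: independent or paired t-test; otherwise
    Mann–Whitney U or Wilcoxon signed-rank.  Paired samples of identical
    length are required when ``paired``; zero-variance paired differences
    short-circuit (all-zero -> p = 1, constant shift -> p = 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and a.shape != b.shape:
        raise CohortError("paired comparison needs equal-length samples")
    if not paired:
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    else:
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
    if min(a.size, b.size) < 3:
        raise CohortError("need at least 3 values per group")
    direction = float(np.sign(np.median(a) - np.median(b)))
    gate = normality_gate(a)[0] and normality_gate(b)[0]

    if paired:
        d = a - b
        if np.ptp(d) == 0:  # degenerate: exactly constant difference
            if d[0] == 0:
                return ComparisonResult(metric, groups, "paired (degenerate)",
                                        0.0, 1.0, 0.0)
            return ComparisonResult(metric, groups, "paired (degenerate)",
                                    float("inf"), 0.0, float(np.sign(d[0])))
        if gate:
            res = stats.ttest_rel(a, b)
            test = "paired t-test"
        else:
            res = stats.wilcoxon(a, b)
            test = "Wilcoxon signed-rank"
    else:
        if gate:
            res = stats.ttest_ind(a, b)
            test = "independent t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
    return ComparisonResult(metric, groups, test,
                            float(res.statistic), float(res.pvalue), direction)


def _rm_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (subject-blocked F test)."""
    data = np.column_stack(groups)  # subjects x conditions
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    return float(f), float(stats.f.sf(f, df_cond, df_err))


def compare_multi(groups: Sequence, paired: bool = True,
                  metric: str = "") -> ComparisonResult:
    """Three-or-more-condition analogue of :func:`compare_groups`.

    Normal: one-way (repeated-measures if paired) ANOVA; otherwise Friedman
    (paired) or Kruskal–Wallis.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise CohortError("compare_multi needs at least 3 conditions")
    if paired:
        keep = np.all(np.isfinite(np.column_stack(arrays)), axis=1)
        arrays = [a[keep] for a in arrays]
    else:
        arrays = [a[np.isfinite(a)] for a in arrays]
    gate = all(normality_gate(a)[0] for a in arrays)
    if paired:
        if gate:
            f, p = _rm_anova(arrays)
            return ComparisonResult(metric, "slices", "RM-ANOVA", f, p, 0.0)
        res = stats.friedmanchisquare(*arrays)
        return ComparisonResult(metric, "slices", "Friedman",
                                float(res.statistic), float(res.pvalue), 0.0)
    if gate:
        res = stats.f_oneway(*arrays)
        return ComparisonResult(metric, "groups", "one-way ANOVA",
                                float(res.statistic), float(res.pvalue), 0.0)
    res = stats.kruskal(*arrays)
    return ComparisonResult(metric, "groups", "Kruskal-Wallis",
                            float(res.statistic), float(res.pvalue), 0.0)


def correlate_age(values, ages, metric: str = "") -> dict[str, float]:
    """Age correlation, Pearson when both variables pass the normality gate,
    Spearman otherwise.  Returns coefficient, p and the method used."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    keep = np.isfinite(v) & np.isfinite(a)
    v, a = v[keep], a[keep]
    if v.size < 10:
        raise CohortError("age correlation needs at least 10 pairs")
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        raise CohortError("correlation undefined for a constant variable")
    if normality_gate(v)[0] and normality_gate(a)[0]:
        r, p = stats.pearsonr(v, a)
        method = "pearson"
    else:
        r, p = stats.spearmanr(v, a)
        method = "spearman"
    return {"metric": metric, "r": float(r), "p": float(p), "method": method}


# ---------------------------------------------------------------------------
# the normative-values model
# ---------------------------------------------------------------------------

_TABLE_LAYOUT: dict[str, list[str]] = {
    "demographics": ["age", "hr_rest", "sbp_rest", "RPP_rest", "hr_stress",
                     "sbp_stress", "RPP_stress", "hr_change", "sbp_change",
                     "RPP_change"],
    "global_regional_mbf": ["rMBF", "rMBF_c", "sMBF", "MPR",
                            "rMBF_LAD", "rMBF_LCX", "rMBF_RCA",
                            "sMBF_LAD", "sMBF_LCX", "sMBF_RCA",
                            "MPR_LAD", "MPR_LCX", "MPR_RCA"],
    "global_layer_mbf": ["rMBF_ENDO", "rMBF_EPI", "sMBF_ENDO", "sMBF_EPI",
                         "MPR_ENDO", "MPR_EPI"],
    "slice_mpr": ["MPR_ENDO_basal", "MPR_ENDO_mid", "MPR_ENDO_apical",
                  "MPR_EPI_basal", "MPR_EPI_mid", "MPR_EPI_apical"],
    "global_regional_gradients": ["sGRAD", "rGRAD",
                                  "sGRAD_LAD", "sGRAD_LCX", "sGRAD_RCA",
                                  "rGRAD_LAD", "rGRAD_LCX", "rGRAD_RCA"],
    "slice_gradients": ["sGRAD_basal", "sGRAD_mid", "sGRAD_apical",
                        "rGRAD_basal", "rGRAD_mid", "rGRAD_apical"],
}

_NORMAL_VALUE_METRICS = ("MPR_ENDO", "MPR_EPI", "sGRAD", "rGRAD")

_AGE_METRICS = ("MPR_ENDO", "MPR_EPI", "sMBF_ENDO", "sMBF_EPI",
                "rMBF_ENDO", "rMBF_EPI", "sGRAD", "rGRAD")

_SLICE_CONTRAST_METRICS = ("MPR_ENDO", "MPR_EPI", "sGRAD", "rGRAD")


class TransmuralNormals:
    """Normative-value model for a cohort of transmural perfusion metrics.

    Parameters
    ----------
    data
        Tidy cohort table, one row per subject.  Expected columns: ``sex``
        (``female``/``male``), ``age``, the hemodynamic columns and any
        subset of the metric columns produced by ``subject_pipeline`` or
        ``make_cohort``.  An optional boolean ``qc_excluded`` column flags
        subjects to drop.
    """

    def __init__(self, data: pd.DataFrame, exclude_qc: bool = True):
        if len(data) < 2:
            raise CohortError("cohort model needs at least 2 subjects")
        self.data_all = data.reset_index(drop=True)
        if exclude_qc and "qc_excluded" in data.columns:
            kept = self.data_all[~self.data_all["qc_excluded"].astype(bool)]
        else:
            kept = self.data_all
        if len(kept) < 2:
            raise CohortError("fewer than 2 subjects remain after QC exclusion")
        self.data = kept.reset_index(drop=True)
        self.n_excluded = len(self.data_all) - len(self.data)

    @classmethod
    def from_records(cls, records, **kwargs) -> "TransmuralNormals":
        from .synthetic import cohort_to_frame
        return cls(cohort_to_frame(records), **kwargs)

    def _frame(self) -> pd.DataFrame:
        df = self.data.copy()
        for delta, hi, lo in (("hr_change", "hr_stress", "hr_rest"),
                              ("sbp_change", "sbp_stress", "sbp_rest"),
                              ("RPP_change", "RPP_stress", "RPP_rest")):
            if delta not in df.columns and {hi, lo} <= set(df.columns):
                df[delta] = df[hi] - df[lo]
        return df

    def fit(self, seed: int = 0, n_boot: int = 2000,
            bonferroni_slices: bool = True) -> "TransmuralNormalsResults":
        """Derive the full normative report; deterministic for a fixed seed."""
        df = self._frame()
        metric_cols = [c for c in df.columns
                       if c not in ("subject_id", "sex", "qc_excluded")
                       and pd.api.types.is_numeric_dtype(df[c])]
        sexes = [s for s in ("female", "male") if (df["sex"] == s).any()] \
            if "sex" in df.columns else []

        rows, comps = [], []
        for col in metric_cols:
            strata = {"all": df[col]}
            for s in sexes:
                strata[s] = df.loc[df["sex"] == s, col]
            for name, vals in strata.items():
                v = _clean(vals)
                if v.size < 2:
                    continue
                summ = summarize(v, n_boot=n_boot, seed=seed,
                                 label=f"{col}|{name}")
                rows.append({"metric": col, "stratum": name, **summ})
            if len(sexes) == 2:
                f = _clean(strata["female"])
                mvals = _clean(strata["male"])
                if min(f.size, mvals.size) >= 3 and (np.ptp(f) or np.ptp(mvals)):
                    comps.append(compare_groups(
                        f, mvals, paired=False, metric=col,
                        groups="female vs male").as_dict())

        summaries = pd.DataFrame(rows).set_index(["metric", "stratum"])
        sex_comparisons = pd.DataFrame(
            comps, columns=["metric", "groups", "test", "statistic",
                            "p_value", "direction"])

        age_rows = []
        if "age" in df.columns and len(df) >= 10:
            for col in _AGE_METRICS:
                if col in df.columns and np.ptp(_clean(df[col])) > 0:
                    age_rows.append(correlate_age(df[col], df["age"], col))
        age_correlations = pd.DataFrame(
            age_rows, columns=["metric", "r", "p", "method"])

        contrast_rows = []
        for col in _SLICE_CONTRAST_METRICS if len(df) >= 3 else []:
            cols = [f"{col}_{sl}" for sl in ("basal", "mid", "apical")]
            if not all(c in df.columns for c in cols):
                continue
            omni = compare_multi([df[c] for c in cols], paired=True, metric=col)
            contrast_rows.append({**omni.as_dict(), "contrast": "omnibus"})
            pairs = [("basal", "mid"), ("basal", "apical"), ("mid", "apical")]
            for a, b in pairs:
                res = compare_groups(df[f"{col}_{a}"], df[f"{col}_{b}"],
                                     paired=True, metric=col,
                                     groups=f"{a} vs {b}")
                d = res.as_dict()
                if bonferroni_slices:
                    d["p_value"] = min(d["p_value"] * len(pairs), 1.0)
                contrast_rows.append({**d, "contrast": f"{a} vs {b}"})
        slice_contrasts = pd.DataFrame(
            contrast_rows, columns=["metric", "groups", "test", "statistic",
                                    "p_value", "direction", "contrast"])

        return TransmuralNormalsResults(
            model=self, summaries=summaries, sex_comparisons=sex_comparisons,
            age_correlations=age_correlations, slice_contrasts=slice_contrasts,
            seed=seed)


class TransmuralNormalsResults:
    """Fitted normative report; exposes the seven tables and ``summary()``."""

    def __init__(self, model: TransmuralNormals, summaries: pd.DataFrame,
                 sex_comparisons: pd.DataFrame, age_correlations: pd.DataFrame,
                 slice_contrasts: pd.DataFrame, seed: int):
        self.model = model
        self.summaries = summaries
        self.sex_comparisons = sex_comparisons
        self.age_correlations = age_correlations
        self.slice_contrasts = slice_contrasts
        self.seed = seed
        self.n_subjects = len(model.data)
        self.n_excluded = model.n_excluded

    # -- lookups ----------------------------------------------------------
    def stat(self, metric: str, field: str, stratum: str = "all") -> float:
        return float(self.summaries.loc[(metric, stratum), field])

    def normal_range(self, metric: str, stratum: str = "all"
                     ) -> tuple[float, float]:
        """95% cohort range (2.5th–97.5th percentile) of a metric."""
        row = self.summaries.loc[(metric, stratum)]
        return float(row["normal_range_low"]), float(row["normal_range_high"])

    def sex_p(self, metric: str) -> float:
        sel = self.sex_comparisons[self.sex_comparisons["metric"] == metric]
        return float(sel["p_value"].iloc[0]) if len(sel) else float("nan")

    # -- report tables ----------------------------------------------------
    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        out = {name: self._stratified_table(cols)
               for name, cols in _TABLE_LAYOUT.items()
               if any(self._has(c) for c in cols)}
        out["slice_normal_values"] = self._normal_values_table()
        return out

    def _has(self, metric: str) -> bool:
        return (metric, "all") in self.summaries.index

    def _stratified_table(self, metrics: list[str]) -> pd.DataFrame:
        rows = []
        for mcol in metrics:
            if not self._has(mcol):
                continue
            row: dict = {"metric": mcol}
            for stratum in ("all", "female", "male"):
                if (mcol, stratum) not in self.summaries.index:
                    continue
                s = self.summaries.loc[(mcol, stratum)]
                center, spread = ((s["mean"], s["sd"]) if s["normal"]
                                  else (s["median"], s["iqr"]))
                row[f"n_{stratum}"] = int(s["n"])
                row[f"center_{stratum}"] = float(center)
                row[f"spread_{stratum}"] = float(spread)
            row["presentation"] = self.summaries.loc[(mcol, "all"), "presentation"]
            row["p_sex"] = self.sex_p(mcol)
            rows.append(row)
        return pd.DataFrame(rows)

    def _normal_values_table(self) -> pd.DataFrame:
        rows = []
        for mcol in _NORMAL_VALUE_METRICS:
            for sl in ("basal", "mid", "apical"):
                key = f"{mcol}_{sl}"
                if not self._has(key):
                    continue
                s = self.summaries.loc[(key, "all")]
                rows.append({
                    "metric": mcol, "slice": sl,
                    "median": float(s["median"]), "iqr": float(s["iqr"]),
                    "ci_low": float(s["ci_low"]), "ci_high": float(s["ci_high"]),
                    "normal_range_low": float(s["normal_range_low"]),
                    "normal_range_high": float(s["normal_range_high"]),
                })
        return pd.DataFrame(rows)

    # -- rendering --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Transmural perfusion normative report",
            "=" * 53,
            f"subjects analysed: {self.n_subjects}"
            + (f"  (excluded by QC: {self.n_excluded})" if self.n_excluded else ""),
            "",
        ]
        key = ["rMBF", "sMBF", "MPR", "rMBF_c", "MPR_c",
               "rMBF_ENDO", "rMBF_EPI", "sMBF_ENDO", "sMBF_EPI",
               "MPR_ENDO", "MPR_EPI", "sGRAD", "rGRAD"]
        lines.append(f"{'metric':<12}{'value':>16}{'95% cohort range':>22}")
        lines.append("-" * 53)
        for mcol in key:
            if not self._has(mcol):
                continue
            s = self.summaries.loc[(mcol, "all")]
            if s["normal"]:
                val = f"{s['mean']:.2f} ± {s['sd']:.2f}"
            else:
                val = f"{s['median']:.2f} ± {s['iqr']:.2f}*"
            rng = f"[{s['normal_range_low']:.2f}, {s['normal_range_high']:.2f}]"
            lines.append(f"{mcol:<12}{val:>16}{rng:>22}")
        lines.append("-" * 53)
        lines.append("* median ± IQR (Shapiro–Wilk p < 0.05); MBF in mL/min/g")
        if len(self.age_correlations):
            lines.append("")
            lines.append("age correlations:")
            for _, r in self.age_correlations.iterrows():
                lines.append(f"  {r['metric']:<12} r = {r['r']:+.2f}  "
                             f"p = {r['p']:.3g}  ({r['method']})")
        return "\n".join(lines)

    def plot_age_correlation(self, metric: str, ax=None):
        """Scatter of a metric against age with a least-squares fit line."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        df = self.model.data
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        x = df["age"].to_numpy(float)
        y = df[metric].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        ax.scatter(x, y, s=12, alpha=0.6)
        coef = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, np.polyval(coef, xs), "r-")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(metric)
        return ax


def build_report(records, seed: int = 0, n_boot: int = 2000
                 ) -> dict[str, pd.DataFrame]:
    """One-call normative report from SubjectRecords or a cohort DataFrame."""
    if isinstance(records, pd.DataFrame):
        model = TransmuralNormals(records)
    else:
        model = TransmuralNormals.from_records(records)
    return model.fit(seed=seed, n_boot=n_boot).tables
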