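"""Group-stratified hypothesis testing and summary tables.

Test selection follows a Shapiro–Wilk normality gate (p > 0.05 in every
group -> parametric): one-way ANOVA vs Kruskal–Wallis for omnibus
comparisons; paired t vs Wilcoxon signed-rank for matched contrasts;
Welch's t vs Wilcoxon rank-sum for independent contrasts.  Pairwise
families are Bonferroni-corrected within one metric.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NORMAL = "normal"
NON_NORMAL = "non_normal"

#: conventional contrast letters for the four constitution groups
DEFAULT_GROUP_LETTERS = {
    frozenset(("Vata", "Kapha")): "a",
    frozenset(("Kapha", "Pitta")): "b",
    frozenset(("Vata", "Pitta")): "c",
    frozenset(("Kapha", "Mixed")): "d",
    frozenset(("Vata", "Mixed")): "e",
    frozenset(("Pitta", "Mixed")): "f",
}

#: letters for the three phase contrasts
DEFAULT_PHASE_LETTERS = {
    frozenset(("supine", "tilt")): "a",
    frozenset(("tilt", "resupine")): "b",
    frozenset(("supine", "resupine")): "c",
}


@dataclass
class ComparisonResult:
    metric_name: str
    contrast: str
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_per_group: dict = field(default_factory=dict)
    significance_code: str = ""
    contrast_letter: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.significance_code:
            self.significance_code = significance_code(self.p_adjusted)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["n_per_group"] = ";".join(f"{k}={v}" for k, v in self.n_per_group.items())
        return d


@dataclass
class SummaryCell:
    metric_name: str
    group: str
    phase: str
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    n: int


def significance_code(p: float) -> str:
    """Star annotation: * p<.05, ** p<.01, *** p<.001, **** p<.0001."""
    if not np.isfinite(p):
        return ""
    for stars, thr in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < thr:
            return stars
    return ""


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    return min(1.0, p_raw * n_comparisons) if np.isfinite(p_raw) else np.nan


def _as_groups(values, labels=None) -> dict[str, np.ndarray]:
    if labels is None:
        if not isinstance(values, Mapping):
            raise TypeError("pass either {label: array} or (values, labels)")
        return {str(k): np.asarray(v, float) for k, v in values.items()}
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    return {str(g): values[labels == g] for g in pd.unique(labels)}


def _dropna(a: np.ndarray) -> np.ndarray:
    return a[np.isfinite(a)]


def normality_gate(values, labels=None, alpha: float = 0.05) -> str:
    """``normal`` iff Shapiro–Wilk p > alpha in every group.

    Groups with n < 3 or zero variance force the non-parametric path
    (with a warning for undersized groups).
    """
    groups = _as_groups(values, labels)
    for name, g in groups.items():
        g = _dropna(g)
        if len(g) < 3:
            warnings.warn(f"group {name!r}: n={len(g)} < 3; using "
                          f"non-parametric path", stacklevel=2)
            return NON_NORMAL
        if np.ptp(g) == 0:
            return NON_NORMAL
        if stats.shapiro(g).pvalue <= alpha:
            return NON_NORMAL
    return NORMAL


def omnibus_test(values, labels=None, metric_name: str = "",
                 gate: str | None = None) -> ComparisonResult:
    """Gate-selected one-way ANOVA or Kruskal–Wallis across k groups.

    Kruskal–Wallis uses the tie-corrected H statistic with a chi-square
    reference distribution on k−1 degrees of freedom.  A zero-variance
    group on the ANOVA path falls back to Kruskal–Wallis with a warning.
    """
    groups = {k: _dropna(v) for k, v in _as_groups(values, labels).items()}
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("omnibus test needs >= 2 groups with n >= 2")
    arrays = list(groups.values())
    gate = gate or normality_gate(groups)

    note = ""
    if gate == NORMAL and any(np.ptp(a) == 0 for a in arrays):
        warnings.warn("zero-variance group under ANOVA; falling back to "
                      "Kruskal-Wallis", stacklevel=2)
        gate, note = NON_NORMAL, "anova_fallback"

    if gate == NORMAL:
        res = stats.f_oneway(*arrays)
        test, statistic, p = "one-way ANOVA", float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(np.concatenate(arrays)) == 0:
            test, statistic, p = "Kruskal-Wallis", 0.0, 1.0
        else:
            res = stats.kruskal(*arrays)
            test, statistic, p = "Kruskal-Wallis", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        metric_name=metric_name, contrast="omnibus", test_name=test,
        statistic=statistic, p_raw=p, p_adjusted=p,
        n_per_group={k: len(v) for k, v in groups.items()}, note=note)


def signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Wilcoxon signed-rank p for paired samples.

    Zeros are discarded (Wilcoxon's method); the exact distribution is
    used for n <= 25 without tied magnitudes, otherwise the normal
    approximation with continuity correction.  All-zero differences give
    p = 1 with a note.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) == 0:
        return np.nan, 1.0, "all differences zero"
    ad = np.abs(d)
    exact = len(d) <= 25 and len(np.unique(ad)) == len(ad)
    res = stats.wilcoxon(d, zero_method="wilcox",
                         correction=not exact,
                         method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue), ""


def pairwise_tests(values, labels=None, *, paired: bool = False,
                   metric_name: str = "", gate: str | None = None,
                   letter_map: Mapping[frozenset, str] | None = None,
                   n_comparisons: int | None = None) -> list[ComparisonResult]:
    """All pairwise contrasts between groups, Bonferroni-corrected.

    ``paired=True`` requires equal-length matched vectors per group (e.g.
    phases of the same subjects) and uses paired t / signed-rank;
    otherwise Welch's t / rank-sum.  The Bonferroni family defaults to the
    number of pairwise contrasts for this metric.
    """
    groups = _as_groups(values, labels)
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    if letter_map is None:
        letter_map = {**DEFAULT_GROUP_LETTERS, **DEFAULT_PHASE_LETTERS}
    gate = gate or normality_gate({k: _dropna(v) for k, v in groups.items()})

    results = []
    for ga, gb in pairs:
        a, b = groups[ga], groups[gb]
        note = ""
        if paired:
            if len(a) != len(b):
                raise ValueError(f"paired contrast {ga} vs {gb}: unequal lengths")
            ok = np.isfinite(a) & np.isfinite(b)
            a, b = a[ok], b[ok]
            if gate == NORMAL:
                res = stats.ttest_rel(a, b)
                test, statistic, p = "paired t-test", float(res.statistic), float(res.pvalue)
            else:
                statistic, p, note = signed_rank(a, b)
                test = "Wilcoxon signed-rank"
        else:
            a, b = _dropna(a), _dropna(b)
            if gate == NORMAL:
                res = stats.ttest_ind(a, b, equal_var=False)
                test, statistic, p = "Welch t-test", float(res.statistic), float(res.pvalue)
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                test, statistic, p = "Wilcoxon rank-sum", float(res.statistic), float(res.pvalue)
        letter = letter_map.get(frozenset((ga, gb)), "")
        results.append(ComparisonResult(
            metric_name=metric_name, contrast=f"{ga}-vs-{gb}", test_name=test,
            statistic=statistic, p_raw=p, p_adjusted=bonferroni(p, m),
            n_per_group={ga: len(a), gb: len(b)},
            contrast_letter=letter, note=note))
    return results


def summarize(df: pd.DataFrame, value_cols: Sequence[str],
              by: Sequence[str]) -> pd.DataFrame:
    """Median / Q1 / Q3 (linear-interpolation quantiles), mean, SD, n
    per metric per stratum.  Empty strata appear with n = 0."""
    rows = []
    grouped = df.groupby(list(by), dropna=False, observed=True)
    for keys, sub in grouped:
        keys = keys if isinstance(keys, tuple) else (keys,)
        for col in value_cols:
            v = _dropna(sub[col].to_numpy(float))
            base = dict(zip(by, keys))
            base["metric"] = col
            if len(v) == 0:
                base.update(median=np.nan, q1=np.nan, q3=np.nan,
                            mean=np.nan, sd=np.nan, n=0)
            else:
                q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
                base.update(median=med, q1=q1, q3=q3, mean=v.mean(),
                            sd=v.std(ddof=1) if len(v) > 1 else np.nan, n=len(v))
            rows.append(base)
    return pd.DataFrame(rows)


def age_band_compare(values_df: pd.DataFrame, metadata: pd.DataFrame,
                     metrics: Sequence[str],
                     bands: tuple[tuple[float, float], tuple[float, float]] = ((18, 20), (35, 40)),
                     by_group: bool = True) -> list[ComparisonResult]:
    """Compare each metric between two age bands, overall and per group.

    ``values_df`` must be indexed or keyed by subject_id with metric
    columns; ``metadata`` supplies age and group_label.  Bands are closed
    intervals and must not overlap.  Empty strata are skipped.
    """
    (lo1, hi1), (lo2, hi2) = bands
    if not (hi1 < lo2 or hi2 < lo1):
        raise ValueError("age bands must be disjoint")
    df = values_df.merge(metadata[["subject_id", "group_label", "age"]],
                         on="subject_id", how="inner")
    lower = df[(df.age >= lo1) & (df.age <= hi1)]
    upper = df[(df.age >= lo2) & (df.age <= hi2)]
    band_names = (f"{lo1:g}-{hi1:g}y", f"{lo2:g}-{hi2:g}y")

    strata = [("all", lower, upper)]
    if by_group:
        for g in sorted(df.group_label.unique()):
            strata.append((g, lower[lower.group_label == g],
                           upper[upper.group_label == g]))

    results = []
    for stratum, lo_df, up_df in strata:
        if len(lo_df) < 2 or len(up_df) < 2:
            continue
        for metric in metrics:
            data = {band_names[0]: lo_df[metric].to_numpy(float),
                    band_names[1]: up_df[metric].to_numpy(float)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = pairwise_tests(data, metric_name=metric, n_comparisons=1)
            for r in res:
                r.contrast = f"{r.contrast} ({stratum})"
            results.extend(res)
    return results


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
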