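"""Cohort statistics for per-subject HFA rates.

Implements the analysis plan used to compare HFA rates between clinical
groups: two-sided permutation tests on the difference of means (10 000
resamples, add-one p-value estimator), Hedges g effect sizes,
Youden-index threshold selection with sensitivity/specificity/AUC and
Wilson score confidence intervals, Welch's ANOVA with Games-Howell post
hoc comparisons for the etiology groups, and the Kruskal-Wallis H test
for the (non-normal) EEG-background groups.

All formulas are the classical closed forms; scipy supplies the
reference distributions (F, chi-square, studentized range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class GroupComparisonResult:
    n1: int
    n2: int
    mean1: float
    mean2: float
    observed_diff: float
    p_value: float
    n_resamples: int
    effect_size_g: float | None
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "n1": self.n1, "n2": self.n2,
            "mean1": self.mean1, "mean2": self.mean2,
            "observed_diff": self.observed_diff, "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "effect_size_g": self.effect_size_g, "seed": self.seed,
        }


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    youden_j: float
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    ci_auc: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "auc": self.auc, "youden_j": self.youden_j,
            "ci_sens": list(self.ci_sens), "ci_spec": list(self.ci_spec),
            "ci_auc": list(self.ci_auc),
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


@dataclass
class MultiGroupResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    posthoc: list = field(default_factory=list)  # (a, b, p)

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "df": list(self.df), "p_value": self.p_value,
            "posthoc": [list(p) for p in self.posthoc],
        }


def _as_arrays(*groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.ndim != 1:
            raise StatsError("each group must be a 1-D sequence of rates")
        out.append(a)
    return out


def permutation_test(
    x, y, n_resamples: int = 10_000, seed: int | None = 0,
    compute_effect_size: bool = True,
) -> GroupComparisonResult:
    """Two-sided permutation test on the absolute difference of means.

    Group labels are permuted uniformly; the p-value uses the add-one
    estimator (1 + #{|perm diff| >= |observed|}) / (n_resamples + 1),
    which is never zero and keeps the test valid at any resample count.
    """
    x, y = _as_arrays(x, y)
    if len(x) < 2 or len(y) < 2:
        raise StatsError(f"need >= 2 observations per group, got {len(x)}/{len(y)}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    observed = abs(x.mean() - y.mean())
    # vectorized label permutation: argsort of uniforms is a uniform permutation
    total = pooled.sum()
    u = rng.random((n_resamples, len(pooled)))
    order = np.argsort(u, axis=1)[:, :n1]
    sum1 = pooled[order].sum(axis=1)
    perm_diff = np.abs(sum1 / n1 - (total - sum1) / len(y))
    count = int((perm_diff >= observed - 1e-12).sum())
    p = (1 + count) / (n_resamples + 1)
    g = hedges_g(x, y) if compute_effect_size and _pooled_sd(x, y) > 0 else None
    return GroupComparisonResult(
        n1=n1, n2=len(y), mean1=float(x.mean()), mean2=float(y.mean()),
        observed_diff=float(x.mean() - y.mean()), p_value=float(p),
        n_resamples=n_resamples, effect_size_g=g, seed=seed,
    )


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    return float(
        np.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
    )


def hedges_g(x, y, correction: str = "classic") -> float:
    """Hedges g: pooled-SD standardized mean difference, bias-corrected.

    ``correction='classic'`` uses J = 1 - 3/(4N - 9); ``'exact'`` uses
    the gamma-function form J = Gamma(m/2) / (sqrt(m/2) Gamma((m-1)/2))
    with m = N - 2. The two differ only in the third decimal for the
    sample sizes involved here.
    """
    x, y = _as_arrays(x, y)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("need >= 2 observations per group")
    sp = _pooled_sd(x, y)
    if sp == 0:
        raise StatsError("zero pooled variance: effect size undefined")
    n = len(x) + len(y)
    d = (x.mean() - y.mean()) / sp
    if correction == "classic":
        j = 1.0 - 3.0 / (4.0 * n - 9.0)
    elif correction == "exact":
        from scipy.special import gammaln

        m = n - 2
        j = np.exp(gammaln(m / 2) - np.log(np.sqrt(m / 2)) - gammaln((m - 1) / 2))
    else:
        raise StatsError(f"unknown correction {correction!r}")
    return float(j * d)


def wilson_interval(
    successes: int, n: int, conf: float = 0.95, z: float | None = None
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    Uses z = 1.96 for 95% intervals (the conventional rounded value);
    pass ``z`` explicitly for other choices.
    """
    if n < 1:
        raise StatsError("n must be >= 1")
    if not 0 <= successes <= n:
        raise StatsError(f"successes {successes} outside [0, {n}]")
    if z is None:
        z = 1.96 if abs(conf - 0.95) < 1e-12 else float(sps.norm.ppf((1 + conf) / 2))
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    lo = 0.0 if successes == 0 else max(center - half, 0.0)
    hi = 1.0 if successes == n else min(center + half, 1.0)
    return (lo, hi)


def roc_youden(rates, binary_labels) -> ThresholdResult:
    """Youden-optimal rate threshold with Wilson CIs and trapezoidal AUC.

    A subject is called positive when rate >= threshold (higher HFA =
    disease). Candidate thresholds are midpoints between consecutive
    sorted unique rates plus sentinels beyond the data range; ties in
    the Youden index are broken toward the lowest threshold (maximal
    sensitivity). The AUC equals the Mann-Whitney U statistic divided
    by n_pos * n_neg. The AUC interval applies the Wilson formula with
    the total sample size (a proportion-scale heuristic, since the AUC
    is not a binomial proportion).
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(binary_labels).astype(bool)
    if rates.shape != labels.shape:
        raise StatsError("rates and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError("both classes must be present")
    uniq = np.unique(rates)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for thr in candidates:  # ascending, so ties keep the lowest threshold
        calls = rates >= thr
        sens = (calls & labels).sum() / n_pos
        spec = (~calls & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    # AUC via the Mann-Whitney relation (ties counted half)
    u = sps.mannwhitneyu(rates[labels], rates[~labels]).statistic
    auc = float(u / (n_pos * n_neg))
    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    n_tot = n_pos + n_neg
    return ThresholdResult(
        threshold=float(thr), sensitivity=float(sens), specificity=float(spec),
        auc=auc, youden_j=float(j),
        ci_sens=wilson_interval(tp, n_pos),
        ci_spec=wilson_interval(tn, n_neg),
        ci_auc=wilson_interval(int(round(auc * n_tot)), n_tot),
        n_pos=n_pos, n_neg=n_neg,
    )


def welch_anova(groups) -> MultiGroupResult:
    """Welch's heteroscedastic one-way ANOVA (Satterthwaite-type df)."""
    groups = _as_arrays(*groups)
    k = len(groups)
    if k < 2:
        raise StatsError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise StatsError("each group needs >= 2 observations")
        if g.var(ddof=1) == 0:
            raise StatsError("zero-variance group: Welch ANOVA undefined")
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = k - 1
    df2 = 1.0 / lam
    p = float(sps.f.sf(f, df1, df2))
    return MultiGroupResult(
        test="welch_anova", statistic=float(f), df=(float(df1), float(df2)), p_value=p
    )


def _welch_df(v1, n1, v2, n2) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def games_howell(groups, names: list[str] | None = None) -> list[tuple]:
    """Games-Howell pairwise comparisons (unequal variances and sizes).

    For each pair: t = dm / sqrt(s1^2/n1 + s2^2/n2) with Welch df, and
    p from the studentized-range distribution with q = t * sqrt(2) and
    k = number of groups.
    """
    groups = _as_arrays(*groups)
    k = len(groups)
    if k < 2:
        raise StatsError("need >= 2 groups")
    for g in groups:
        if len(g) < 2 or g.var(ddof=1) == 0:
            raise StatsError("each group needs >= 2 observations and variance > 0")
    names = names or [f"group{i}" for i in range(k)]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            t = abs(a.mean() - b.mean()) / se
            df = _welch_df(a.var(ddof=1), len(a), b.var(ddof=1), len(b))
            p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
            out.append((names[i], names[j], p))
    return out


def kruskal_wallis(groups) -> MultiGroupResult:
    """Kruskal-Wallis H test with tie correction (chi-square approximation)."""
    groups = _as_arrays(*groups)
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    if sum(len(g) for g in groups) < 5:
        raise StatsError("need total n >= 5 for the chi-square approximation")
    if np.ptp(np.concatenate(groups)) == 0:
        raise StatsError("all observations identical: H undefined")
    h, p = sps.kruskal(*groups)
    return MultiGroupResult(
        test="kruskal_wallis", statistic=float(h),
        df=(float(len(groups) - 1),), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# study plan
# ---------------------------------------------------------------------------

DEFAULT_PLAN = (
    "seizure_vs_healthy",
    "etiology",
    "hypothermia_within_hie",
    "background_grade",
    "pne_vs_normal_dev",
    "term_vs_preterm",
)


def _comparison_block(x, y, seed, with_threshold: bool, labels) -> dict:
    res = permutation_test(x, y, seed=seed)
    block = res.to_dict()
    block["sd1"] = float(np.std(x, ddof=1))
    block["sd2"] = float(np.std(y, ddof=1))
    block["groups"] = labels
    if with_threshold and res.p_value < 0.05:
        rates = np.concatenate([x, y])
        lab = np.concatenate([np.ones(len(x), bool), np.zeros(len(y), bool)])
        try:
            block["threshold"] = roc_youden(rates, lab).to_dict()
        except StatsError as exc:
            block["threshold_error"] = str(exc)
    return block


def run_study(
    cohort: pd.DataFrame, plan=DEFAULT_PLAN, seed: int = 0
) -> dict:
    """Execute the cohort comparison plan on a subject rate table.

    ``cohort`` needs columns ``rate`` and whichever label columns the
    planned comparisons use (``group``, ``etiology``, ``hypothermia``,
    ``background_grade``, ``outcome``, ``term``). Comparisons whose
    labels are missing are skipped with a note. Returns a JSON-ready
    dict, one entry per executed comparison.
    """
    report: dict = {}
    rng = np.random.default_rng(seed)

    def rates(mask) -> np.ndarray:
        return cohort.loc[mask, "rate"].to_numpy(dtype=float)

    def sub_seed() -> int:
        return int(rng.integers(2**31 - 1))

    for comparison in plan:
        try:
            if comparison == "seizure_vs_healthy":
                x, y = rates(cohort["group"] == "seizure"), rates(cohort["group"] == "healthy")
                report[comparison] = _comparison_block(
                    x, y, sub_seed(), True, ["seizure", "healthy"]
                )
            elif comparison == "etiology":
                groups, names = [], []
                for etio in ("HIE", "SVL", "genetic"):
                    g = rates(cohort["etiology"] == etio)
                    if len(g) >= 2:
                        groups.append(g)
                        names.append(etio)
                if len(groups) < 2:
                    raise StatsError("fewer than two etiology groups present")
                res = welch_anova(groups)
                res.posthoc = games_howell(groups, names)
                block = res.to_dict()
                block["groups"] = names
                block["means"] = [float(g.mean()) for g in groups]
                report[comparison] = block
            elif comparison == "hypothermia_within_hie":
                hie = cohort[cohort["etiology"] == "HIE"]
                x = hie.loc[hie["hypothermia"].astype(bool), "rate"].to_numpy(float)
                y = hie.loc[~hie["hypothermia"].astype(bool), "rate"].to_numpy(float)
                report[comparison] = _comparison_block(
                    x, y, sub_seed(), False, ["hypothermia", "no_hypothermia"]
                )
            elif comparison == "background_grade":
                groups, names = [], []
                seizure = cohort[cohort["group"] == "seizure"]
                for grade in ("normal", "mild_moderate", "severe"):
                    g = seizure.loc[seizure["background_grade"] == grade, "rate"].to_numpy(float)
                    if len(g) >= 2:
                        groups.append(g)
                        names.append(grade)
                if len(groups) < 2:
                    raise StatsError("fewer than two background-grade groups")
                res = kruskal_wallis(groups)
                block = res.to_dict()
                block["groups"] = names
                report[comparison] = block
            elif comparison == "pne_vs_normal_dev":
                x = rates(cohort["outcome"] == "PNE")
                y = rates(cohort["outcome"] == "normal")
                report[comparison] = _comparison_block(
                    x, y, sub_seed(), True, ["PNE", "normal_development"]
                )
            elif comparison == "term_vs_preterm":
                seizure = cohort[cohort["group"] == "seizure"]
                x = seizure.loc[seizure["term"].astype(bool), "rate"].to_numpy(float)
                y = seizure.loc[~seizure["term"].astype(bool), "rate"].to_numpy(float)
                report[comparison] = _comparison_block(
                    x, y, sub_seed(), False, ["term", "preterm"]
                )
            else:
                report[comparison] = {"skipped": f"unknown comparison {comparison!r}"}
        except (KeyError, StatsError) as exc:
            report[comparison] = {"skipped": str(exc)}
    return report


def report_markdown(report: dict) -> str:
    """Human-readable summary of a run_study report."""
    lines = ["# HFA cohort statistics", ""]
    for name, block in report.items():
        lines.append(f"## {name}")
        if "skipped" in block:
            lines.append(f"skipped: {block['skipped']}")
            lines.append("")
            continue
        if "p_value" in block and "mean1" in block:
            lines.append(
                f"n = {block['n1']} vs {block['n2']}; "
                f"means {block['mean1']:.3f} vs {block['mean2']:.3f} "
                f"HFA/min/ch; permutation p = {block['p_value']:.4g}"
            )
            if block.get("effect_size_g") is not None:
                lines.append(f"Hedges g = {block['effect_size_g']:.2f}")
            thr = block.get("threshold")
            if thr:
                lines.append(
                    f"Youden threshold {thr['threshold']:.3f} HFA/min/ch: "
                    f"sensitivity {100 * thr['sensitivity']:.0f}% "
                    f"(CI {100 * thr['ci_sens'][0]:.0f}-{100 * thr['ci_sens'][1]:.0f}%), "
                    f"specificity {100 * thr['specificity']:.0f}% "
                    f"(CI {100 * thr['ci_spec'][0]:.0f}-{100 * thr['ci_spec'][1]:.0f}%), "
                    f"AUC {100 * thr['auc']:.0f}% "
                    f"(CI {100 * thr['ci_auc'][0]:.0f}-{100 * thr['ci_auc'][1]:.0f}%)"
                )
        elif "statistic" in block:
            lines.append(
                f"{block['test']}: statistic = {block['statistic']:.3f}, "
                f"p = {block['p_value']:.4g}"
            )
            for a, b, p in block.get("posthoc", []):
                lines.append(f"  {a} vs {b}: p = {p:.4g}")
        lines.append("")
    return "\n".join(lines)
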