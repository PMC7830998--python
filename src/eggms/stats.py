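"""Statistical harness for trial comparisons.

Implements the screening rule for sickness-prone participants, the adaptive
test-selection tree used to compare indicator values across trials
(Shapiro-Wilk normality -> paired t / Wilcoxon for two levels, RMANOVA with
Mauchly/Greenhouse-Geisser or Friedman for three, Bonferroni-corrected
post-hocs), Spearman rank correlations, and analytic sensitivity (minimal
detectable effect size) computations for the repeated-measures designs, each
cross-checkable by Monte-Carlo power simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerQuery",
    "ScreeningForm",
    "ScreeningResult",
    "StatReport",
    "TestOutcome",
    "TestPlan",
    "choose_test",
    "compare_levels",
    "compare_trials",
    "gtsssp_screen",
    "paired_t_power",
    "rmanova_power",
    "sensitivity_paired_t",
    "sensitivity_rmanova",
    "simulate_paired_t_power",
    "simulate_rmanova_power",
    "spearman",
]

SHAPIRO_ALPHA = 0.05
DEFAULT_ALPHAS = (0.05, 0.1)


def _shapiro_p(x) -> float:
    """Shapiro-Wilk p-value; constant input cannot reject normality (p=1)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


# ---------------------------------------------------------------- screening

@dataclass(frozen=True)
class ScreeningForm:
    """Pre/post ratings (0-10) of the 17 discomfort symptoms."""

    pre: tuple[float, ...]
    post: tuple[float, ...]
    n_symptoms: int = 17

    def __post_init__(self) -> None:
        for name, vals in (("pre", self.pre), ("post", self.post)):
            if len(vals) != self.n_symptoms:
                raise ValueError(f"{name} must have {self.n_symptoms} ratings, got {len(vals)}")
            if any(not 0 <= v <= 10 for v in vals):
                raise ValueError(f"{name} ratings must lie in [0, 10]")


@dataclass(frozen=True)
class ScreeningResult:
    passed: bool
    reasons: tuple[str, ...] = ()
    diffs: tuple[float, ...] = ()


def gtsssp_screen(form: ScreeningForm) -> ScreeningResult:
    """Simulator-sickness screening on pre/post symptom differences.

    A participant fails (is excluded as sickness-prone) iff any post-pre
    difference exceeds 5, or at least three differences simultaneously
    exceed 3.  Boundary values (a difference of exactly 5 or exactly 3) do
    not trigger.
    """
    diffs = tuple(po - pr for pr, po in zip(form.pre, form.post))
    reasons: list[str] = []
    big = [i for i, d in enumerate(diffs) if d > 5]
    for i in big:
        reasons.append(f"symptom {i + 1}: difference {diffs[i]:g} > 5")
    over3 = [i for i, d in enumerate(diffs) if d > 3]
    if len(over3) >= 3:
        syms = ", ".join(str(i + 1) for i in over3)
        reasons.append(f"{len(over3)} symptoms ({syms}) with difference > 3")
    return ScreeningResult(passed=not reasons, reasons=tuple(reasons), diffs=diffs)


# ------------------------------------------------------- test selection tree

@dataclass(frozen=True)
class TestPlan:
    """Which omnibus test to run and why."""

    levels: int
    normal: bool
    shapiro_ps: tuple[float, ...]
    test: str                       # 'paired_t' | 'wilcoxon' | 'rm_anova' | 'friedman'
    posthoc: str | None             # 'bonferroni_t' | 'bonferroni_wilcoxon' | None
    mauchly_p: float | None = None
    use_gg: bool = False


def _as_wide(samples) -> pd.DataFrame:
    wide = pd.DataFrame(samples)
    if wide.isna().any().any():
        raise ValueError("unequal subject sets across levels (missing values)")
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 paired samples per level")
    return wide.astype(float)


def choose_test(samples, design: int | None = None) -> TestPlan:
    """Select the trial-comparison test for paired per-subject values.

    ``samples``: subjects x levels (wide) array or DataFrame.  Two levels:
    Shapiro-Wilk on the paired differences decides paired t versus Wilcoxon.
    Three or more: Shapiro-Wilk on each level's residuals decides RMANOVA
    (with Mauchly's sphericity test arming the Greenhouse-Geisser correction)
    versus Friedman; post-hocs are Bonferroni-corrected paired t or Wilcoxon.
    """
    wide = _as_wide(samples)
    k = wide.shape[1]
    if design is not None and design != k:
        raise ValueError(f"design={design} but data has {k} levels")
    if k < 2:
        raise ValueError("need at least 2 levels")

    if k == 2:
        diffs = wide.iloc[:, 1] - wide.iloc[:, 0]
        p = _shapiro_p(diffs)
        normal = p >= SHAPIRO_ALPHA
        return TestPlan(
            levels=2, normal=normal, shapiro_ps=(p,),
            test="paired_t" if normal else "wilcoxon", posthoc=None,
        )

    ps = tuple(_shapiro_p(wide.iloc[:, j] - wide.iloc[:, j].mean()) for j in range(k))
    normal = all(p >= SHAPIRO_ALPHA for p in ps)
    if not normal:
        return TestPlan(levels=k, normal=False, shapiro_ps=ps,
                        test="friedman", posthoc="bonferroni_wilcoxon")
    import pingouin as pg

    diffs = wide.values - wide.values.mean(axis=1, keepdims=True)
    if np.allclose(diffs, diffs[:1], atol=1e-12) or np.ptp(wide.values) == 0:
        # no within-subject variation at all: sphericity trivially holds
        mauchly_p = 1.0
    else:
        spher = pg.sphericity(wide)
        mauchly_p = float(spher.pval)
    return TestPlan(
        levels=k, normal=True, shapiro_ps=ps, test="rm_anova",
        posthoc="bonferroni_t", mauchly_p=mauchly_p,
        use_gg=mauchly_p < SHAPIRO_ALPHA,
    )


@dataclass(frozen=True)
class TestOutcome:
    """One omnibus comparison plus optional corrected post-hocs."""

    plan: TestPlan
    statistic: float
    df: tuple[float, ...]
    p: float
    significant: dict[float, bool]
    posthoc: tuple[dict, ...] = ()

    def as_dict(self) -> dict:
        return {
            "test": self.plan.test,
            "normal": self.plan.normal,
            "shapiro_ps": list(self.plan.shapiro_ps),
            "mauchly_p": self.plan.mauchly_p,
            "use_gg": self.plan.use_gg,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "significant": {str(a): bool(s) for a, s in self.significant.items()},
            "posthoc": list(self.posthoc),
        }


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def _pairwise_posthoc(wide: pd.DataFrame, kind: str) -> tuple[dict, ...]:
    k = wide.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        a, b = wide.iloc[:, i], wide.iloc[:, j]
        if kind == "bonferroni_t":
            d = b - a
            if np.ptp(d) == 0 and d.iloc[0] == 0:
                stat, p = 0.0, 1.0
            else:
                res = stats.ttest_rel(b, a)
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            d = b - a
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(b, a, method="auto")
                stat, p = float(res.statistic), float(res.pvalue)
        direction = "increase" if b.mean() > a.mean() else (
            "decrease" if b.mean() < a.mean() else "none")
        out.append({
            "pair": (str(wide.columns[i]), str(wide.columns[j])),
            "statistic": stat, "p_raw": p, "p_corrected": _bonferroni(p, m),
            "direction": direction,
        })
    return tuple(out)


def compare_levels(samples, alphas: tuple[float, ...] = DEFAULT_ALPHAS) -> TestOutcome:
    """Run the selected test on subjects x levels data.

    Post-hocs are computed only when the omnibus null is rejected at the
    loosest reported alpha; the Bonferroni correction multiplies each
    pairwise p by the number of comparisons (capped at 1).
    """
    wide = _as_wide(samples)
    plan = choose_test(wide)
    k = wide.shape[1]
    n = wide.shape[0]

    if plan.test == "paired_t":
        d = wide.iloc[:, 1] - wide.iloc[:, 0]
        if np.ptp(d) == 0 and d.iloc[0] == 0:
            stat, p, df = 0.0, 1.0, (float(n - 1),)
        else:
            res = stats.ttest_rel(wide.iloc[:, 1], wide.iloc[:, 0])
            stat, p, df = float(res.statistic), float(res.pvalue), (float(n - 1),)
    elif plan.test == "wilcoxon":
        d = wide.iloc[:, 1] - wide.iloc[:, 0]
        if np.all(d == 0):
            stat, p, df = 0.0, 1.0, (float(n),)
        else:
            res = stats.wilcoxon(wide.iloc[:, 1], wide.iloc[:, 0], method="auto")
            stat, p, df = float(res.statistic), float(res.pvalue), (float(n),)
    elif plan.test == "friedman":
        res = stats.friedmanchisquare(*[wide.iloc[:, j] for j in range(k)])
        stat, p, df = float(res.statistic), float(res.pvalue), (float(k - 1),)
    else:  # rm_anova
        lev_dev = wide.values - wide.values.mean(axis=1, keepdims=True)
        if np.allclose(lev_dev, 0.0, atol=1e-12):
            # identical values across levels: nothing to test
            stat, p, df = 0.0, 1.0, (float(k - 1), float((n - 1) * (k - 1)))
        else:
            import pingouin as pg

            long = wide.reset_index(names="subject").melt(
                id_vars="subject", var_name="level", value_name="y")
            aov = pg.rm_anova(data=long, dv="y", within="level", subject="subject",
                              correction=plan.use_gg, detailed=False)
            row = aov.iloc[0]
            stat = float(row["F"])
            df = (float(row["ddof1"]), float(row["ddof2"]))
            p = float(row["p_GG_corr"]) if plan.use_gg and "p_GG_corr" in aov.columns \
                else float(row["p_unc"])

    significant = {a: p < a for a in alphas}
    posthoc: tuple[dict, ...] = ()
    if plan.posthoc and p < max(alphas):
        posthoc = _pairwise_posthoc(wide, plan.posthoc)
    return TestOutcome(plan=plan, statistic=stat, df=df, p=p,
                       significant=significant, posthoc=posthoc)


# --------------------------------------------------------- trial comparison

#: Comparisons run for every indicator: the three trials (before/during/
#: after) and the calm-vs-dynamic halves of the driving trial.
COMPARISONS = {
    "trials": ("trial1", "trial2", "trial3"),
    "parts": ("trial2A", "trial2B"),
}


@dataclass(frozen=True)
class StatReport:
    """Per-parameter test outcomes plus rank correlations and exclusions."""

    outcomes: dict[str, dict[str, TestOutcome]]
    correlations: tuple[dict, ...] = ()
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    dropped: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "dropped": list(self.dropped),
            "outcomes": {
                param: {cmp: oc.as_dict() for cmp, oc in per.items()}
                for param, per in self.outcomes.items()
            },
            "correlations": list(self.correlations),
        }


def compare_trials(
    features: pd.DataFrame,
    parameters: tuple[str, ...] | None = None,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    comparisons: dict[str, tuple[str, ...]] = COMPARISONS,
) -> StatReport:
    """Adaptive trial comparison over a tidy per-subject feature table.

    ``features`` must be long-format with columns ``subject``, ``segment``
    and one column per indicator.  Subjects missing any segment used by a
    comparison are dropped from that comparison and listed in the report.
    Requires at least 3 complete subjects per comparison.
    """
    if parameters is None:
        parameters = tuple(c for c in features.columns if c not in ("subject", "segment"))
    outcomes: dict[str, dict[str, TestOutcome]] = {}
    dropped: set[str] = set()
    for param in parameters:
        per: dict[str, TestOutcome] = {}
        for cname, segs in comparisons.items():
            wide = features.pivot_table(index="subject", columns="segment",
                                        values=param, aggfunc="first")
            missing_cols = [s for s in segs if s not in wide.columns]
            if missing_cols:
                raise ValueError(f"feature table lacks segments {missing_cols}")
            wide = wide[list(segs)]
            incomplete = wide.index[wide.isna().any(axis=1)]
            dropped.update(f"{s} ({cname}: missing segment)" for s in incomplete)
            wide = wide.dropna()
            if wide.shape[0] < 3:
                raise ValueError(
                    f"comparison '{cname}' for '{param}': fewer than 3 complete subjects")
            per[cname] = compare_levels(wide, alphas=alphas)
        outcomes[param] = per
    return StatReport(outcomes=outcomes, alphas=alphas, dropped=tuple(sorted(dropped)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    Raises on constant input (ranks undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be paired with length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------- sensitivity / power

@dataclass(frozen=True)
class PowerQuery:
    """Design parameters for a minimal-detectable-effect computation.

    ``rho`` is the assumed correlation among repeated measures and ``eps``
    the nonsphericity correction, both entering the noncentrality in the
    G*Power 'as in Cohen' convention.
    """

    n: int
    k: int = 2
    alpha: float = 0.05
    power: float = 0.80
    rho: float = 0.5
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


def rmanova_power(f: float, query: PowerQuery) -> float:
    """Power of the one-way RMANOVA F-test at Cohen's f.

    Noncentral-F with df1=(k-1)eps, df2=(n-1)(k-1)eps and noncentrality
    lambda = f^2 * n * k / (1 - rho) * eps.
    """
    n, k, eps = query.n, query.k, query.eps
    df1 = (k - 1) * eps
    df2 = (n - 1) * (k - 1) * eps
    lam = f**2 * n * k / (1.0 - query.rho) * eps
    fcrit = stats.f.ppf(1.0 - query.alpha, df1, df2)
    return float(1.0 - stats.ncf.cdf(fcrit, df1, df2, lam))


def paired_t_power(d: float, query: PowerQuery) -> float:
    """Power of the two-sided paired t-test at standardized difference dz."""
    df = query.n - 1
    ncp = d * np.sqrt(query.n)
    tcrit = stats.t.ppf(1.0 - query.alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def _bisect_effect(power_fn, target: float, hi: float = 3.0) -> float:
    def pf(e: float) -> float:
        p = power_fn(e)
        # extreme noncentrality can underflow the cdf; power is 1 there
        return 1.0 if not np.isfinite(p) else p

    if pf(hi) < target:
        raise ValueError(f"target power {target} unreachable for this design")
    return float(optimize.brentq(lambda e: pf(e) - target, 1e-9, hi, xtol=1e-10))


def sensitivity_rmanova(query: PowerQuery) -> float:
    """Minimal detectable partial eta-squared for the RMANOVA design.

    Bisects Cohen's f until :func:`rmanova_power` reaches the target power,
    then converts via eta_p^2 = f^2 / (1 + f^2).
    """
    if query.k < 2:
        raise ValueError("k must be >= 2")
    f = _bisect_effect(lambda f: rmanova_power(f, query), query.power)
    return f**2 / (1.0 + f**2)


def sensitivity_paired_t(query: PowerQuery) -> float:
    """Minimal detectable eta-squared for the paired t design.

    Bisects dz until :func:`paired_t_power` reaches the target power, then
    converts via f = dz/2 and eta^2 = f^2 / (1 + f^2).
    """
    d = _bisect_effect(lambda d: paired_t_power(d, query), query.power)
    f = d / 2.0
    return f**2 / (1.0 + f**2)


def simulate_rmanova_power(f: float, query: PowerQuery, reps: int = 5000,
                           seed: int = 0) -> float:
    """Monte-Carlo power of the RMANOVA F-test at Cohen's f.

    Simulates y_ij = mu_j + b_i + e_ij with subject variance rho, error
    variance (1 - rho) and sum(mu_j^2)/k = f^2, then applies the
    within-subject F-test; independent of the analytic noncentral-F route.
    """
    rng = np.random.default_rng(seed)
    n, k = query.n, query.k
    # level means with the prescribed effect size (contrast on first/last level)
    mu = np.zeros(k)
    mu[0], mu[-1] = -1.0, 1.0
    mu *= f / np.sqrt(np.sum(mu**2) / k)
    b = rng.normal(0.0, np.sqrt(query.rho), size=(reps, n, 1))
    e = rng.normal(0.0, np.sqrt(1.0 - query.rho), size=(reps, n, k))
    y = mu + b + e
    grand = y.mean(axis=(1, 2), keepdims=True)
    lev = y.mean(axis=1, keepdims=True)
    sub = y.mean(axis=2, keepdims=True)
    ss_lev = n * ((lev - grand) ** 2).sum(axis=(1, 2))
    ss_err = ((y - lev - sub + grand) ** 2).sum(axis=(1, 2))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_lev / df1) / (ss_err / df2)
    fcrit = stats.f.ppf(1.0 - query.alpha, df1, df2)
    return float(np.mean(F > fcrit))


def simulate_paired_t_power(d: float, query: PowerQuery, reps: int = 5000,
                            seed: int = 0) -> float:
    """Monte-Carlo power of the two-sided paired t-test at effect dz."""
    rng = np.random.default_rng(seed)
    n = query.n
    diffs = rng.normal(d, 1.0, size=(reps, n))
    t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(1.0 - query.alpha / 2.0, n - 1)
    return float(np.mean(np.abs(t) > tcrit))
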