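"""Statistical analysis of larval development outcomes.

Implements the experiment's analysis chain on per-larva records: development
rates (1/duration), Kaplan-Meier survival with emergence-censoring, pairwise
log-rank comparisons of development timing with a Schoenfeld
proportional-hazards check, the bootstrap slope-resampling comparison of
development rate versus water temperature, a Gaussian linear mixed model for
wing length (random intercept per replicate run, Satterthwaite degrees of
freedom), and Kruskal-Wallis tests for wing asymmetry and per-run mortality.

Cohorts carry four experimental conditions — low/high temperature controls
(LC, HC) and low/high RF-EMF exposures (LE, HE) — crossed with two diets,
milk powder (M) and Tetramin (T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CONDITIONS",
    "DIETS",
    "CohortTable",
    "SurvivalCurve",
    "TwoGroupTestResult",
    "SlopeSample",
    "WingLengthModelFit",
    "development_rate",
    "mortality_rate",
    "kaplan_meier",
    "logrank_test",
    "ph_check",
    "slope_resampling",
    "compare_slopes",
    "wing_lmm",
    "diet_percent_difference",
    "asymmetry_test",
    "mortality_test",
]

CONDITIONS = ("LC", "LE", "HC", "HE")
DIETS = ("M", "T")

RECORD_COLUMNS = [
    "id", "run", "generation", "condition", "diet",
    "pupation_day", "emergence_day", "death_day",
    "sex", "wing_left", "wing_right",
]


@dataclass
class CohortTable:
    """Per-larva records plus per-condition water-temperature measurements."""

    records: pd.DataFrame
    temperatures: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        df = self.records
        both = df["emergence_day"].notna() & df["death_day"].notna()
        if both.any():
            raise ValueError("a larva cannot both emerge and die (terminal events)")
        ok = df["pupation_day"].notna() & df["emergence_day"].notna()
        if (df.loc[ok, "pupation_day"] > df.loc[ok, "emergence_day"]).any():
            raise ValueError("pupation must not come after emergence")
        for day in ("pupation_day", "emergence_day", "death_day"):
            vals = df[day].dropna()
            if (vals < 1).any():
                raise ValueError(f"{day} must be >= 1")
        self.temperatures = {
            k: np.asarray(v, dtype=float) for k, v in self.temperatures.items()
        }
        for k, v in self.temperatures.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite temperature for condition {k}")

    def subset(self, condition: str | None = None, diet: str | None = None) -> pd.DataFrame:
        df = self.records
        if condition is not None:
            df = df[df["condition"] == condition]
        if diet is not None:
            df = df[df["diet"] == diet]
        return df


@dataclass
class SurvivalCurve:
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray


@dataclass
class TwoGroupTestResult:
    statistic: float
    df: float
    p_value: float
    test: str
    ph_ok: bool | None = None  # proportional-hazards reliability flag

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class SlopeSample:
    """Bootstrap slope distribution for one condition pair."""

    slopes: np.ndarray
    B: int
    n_redrawn: int
    seed: int | None = None


@dataclass
class WingLengthModelFit:
    """Fitted Gaussian random-intercept mixed model for wing length."""

    terms: pd.DataFrame  # estimate, se, t, df (Satterthwaite), p per term
    run_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    loglik_reml: float
    lrt_interaction: TwoGroupTestResult | None = None

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])


# ----------------------------------------------------------------------
# elementary rates

def development_rate(duration_days) -> np.ndarray | float:
    """Development rate as 1/duration [per day]."""
    d = np.asarray(duration_days, dtype=float)
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    out = 1.0 / d
    return float(out) if np.ndim(duration_days) == 0 else out


def mortality_rate(deaths: int, emergences: int) -> float:
    """Deaths over deaths + adult emergences."""
    if deaths < 0 or emergences < 0:
        raise ValueError("counts must be nonnegative")
    total = deaths + emergences
    if total == 0:
        raise ValueError("empty cohort: no deaths or emergences")
    return deaths / total


# ----------------------------------------------------------------------
# survival

def _death_durations(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(duration, observed) for death as event, emergence as censoring."""
    last = np.nanmax(df[["pupation_day", "emergence_day", "death_day"]].values)
    dur = np.where(
        df["death_day"].notna(), df["death_day"],
        np.where(df["emergence_day"].notna(), df["emergence_day"], last),
    ).astype(float)
    obs = df["death_day"].notna().to_numpy()
    return dur, obs


def _event_durations(df: pd.DataFrame, event: str) -> tuple[np.ndarray, np.ndarray]:
    """(duration, observed) for a development event; deaths censored at death day."""
    col = {"pupation": "pupation_day", "emergence": "emergence_day"}[event]
    last = np.nanmax(df[[col, "death_day"]].values)
    dur = np.where(
        df[col].notna(), df[col],
        np.where(df["death_day"].notna(), df["death_day"], last),
    ).astype(float)
    obs = df[col].notna().to_numpy()
    return dur, obs


def kaplan_meier(records: pd.DataFrame) -> SurvivalCurve:
    """Product-limit survival with deaths as events and emergence censored."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    from lifelines import KaplanMeierFitter

    dur, obs = _death_durations(records)
    kmf = KaplanMeierFitter()
    kmf.fit(dur, event_observed=obs)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        survival=kmf.survival_function_at_times(times).to_numpy(dtype=float),
        n_events=table["observed"].to_numpy(dtype=float),
        n_censored=table["censored"].to_numpy(dtype=float),
    )


def logrank_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    event: str = "pupation",
) -> TwoGroupTestResult:
    """Mantel-Cox log-rank comparison of a development event between groups.

    Deaths are treated as right-censoring for development events; day
    resolution ties are handled by the standard log-rank correction.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    from lifelines.statistics import logrank_test as _lr

    da, oa = _event_durations(group_a, event)
    db, ob = _event_durations(group_b, event)
    if oa.sum() + ob.sum() == 0:
        raise ValueError("no observed events in either group")
    res = _lr(da, db, event_observed_A=oa, event_observed_B=ob)
    return TwoGroupTestResult(
        statistic=float(res.test_statistic), df=1.0,
        p_value=float(res.p_value), test="log-rank",
    )


def ph_check(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    event: str = "pupation",
    flag_level: float = 0.001,
) -> tuple[float, bool]:
    """Schoenfeld-residual check of proportional hazards between two groups.

    Returns ``(p_value, reliable)`` where comparisons with p below
    *flag_level* are flagged unreliable (non-proportional hazards).
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    da, oa = _event_durations(group_a, event)
    db, ob = _event_durations(group_b, event)
    if oa.sum() < 2 or ob.sum() < 2:
        raise ValueError("too few observed events for a proportional-hazards fit")
    df = pd.DataFrame({
        "duration": np.concatenate([da, db]),
        "observed": np.concatenate([oa, ob]).astype(int),
        "group": np.r_[np.zeros(len(da)), np.ones(len(db))],
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="observed")
    res = proportional_hazard_test(cph, df, time_transform="rank")
    p = float(np.atleast_1d(res.p_value)[0])
    return p, p >= flag_level


# ----------------------------------------------------------------------
# slope resampling

def slope_resampling(
    rates_1, temps_1, rates_2, temps_2,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> SlopeSample:
    """Bootstrap distribution of development-rate-vs-temperature slopes.

    Each of the B draws picks, independently and uniformly, a measured
    development rate and a measured water temperature from condition 1 and
    likewise from condition 2, and forms ``(r2 - r1) / (T2 - T1)``.  Draws
    with identical temperatures are rejected and redrawn (counted).
    """
    r1 = np.asarray(rates_1, float)
    t1 = np.asarray(temps_1, float)
    r2 = np.asarray(rates_2, float)
    t2 = np.asarray(temps_2, float)
    for arr, name in ((r1, "rates_1"), (t1, "temps_1"), (r2, "rates_2"), (t2, "temps_2")):
        if arr.size == 0:
            raise ValueError(f"{name} is empty")
    if set(t1.tolist()) == set(t2.tolist()) and len(set(t1.tolist())) == 1:
        raise ValueError("temperature supports coincide in a single point")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rr1 = rng.choice(r1, size=B)
    rr2 = rng.choice(r2, size=B)
    tt1 = rng.choice(t1, size=B)
    tt2 = rng.choice(t2, size=B)
    n_redrawn = 0
    bad = tt1 == tt2
    while bad.any():
        n_redrawn += int(bad.sum())
        tt1[bad] = rng.choice(t1, size=int(bad.sum()))
        tt2[bad] = rng.choice(t2, size=int(bad.sum()))
        bad = tt1 == tt2
    slopes = (rr2 - rr1) / (tt2 - tt1)
    return SlopeSample(slopes=slopes, B=B, n_redrawn=n_redrawn,
                       seed=None if isinstance(seed, np.random.Generator) else seed)


def compare_slopes(control: SlopeSample, exposed: SlopeSample) -> TwoGroupTestResult:
    """Welch unequal-variance t-test between two bootstrap slope distributions."""
    if control.B != exposed.B:
        raise ValueError("slope samples must use the same replicate count B")
    a, b = control.slopes, exposed.slopes
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both slope samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TwoGroupTestResult(
        statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), test="welch",
    )


# ----------------------------------------------------------------------
# wing-length linear mixed model (random intercept, REML, Satterthwaite df)

def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    bounds = np.r_[starts, len(y)]
    return [(X[a:b], y[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def _gls_pieces(blocks, lam: float):
    """A = X'V^-1 X * sigma^2, b likewise, RSS in sigma^2 units, logdet of I + lam J."""
    p = blocks[0][0].shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    logdet = 0.0
    for Xi, yi in blocks:
        ni = len(yi)
        ci = lam / (1.0 + ni * lam)
        Xs, ys = Xi.sum(axis=0), yi.sum()
        A += Xi.T @ Xi - ci * np.outer(Xs, Xs)
        bvec += Xi.T @ yi - ci * Xs * ys
        logdet += np.log1p(ni * lam)
    beta = np.linalg.solve(A, bvec)
    rss = 0.0
    for Xi, yi in blocks:
        ri = yi - Xi @ beta
        ci = lam / (1.0 + len(yi) * lam)
        rss += ri @ ri - ci * ri.sum() ** 2
    return A, beta, rss, logdet


def _reml_criterion(blocks, n: int, p: int, lam: float) -> float:
    A, _, rss, logdet = _gls_pieces(blocks, lam)
    sign, logdetA = np.linalg.slogdet(A)
    return (n - p) * np.log(rss) + logdet + logdetA


def _neg2_reml(blocks, n: int, p: int, sigma2: float, tau2: float) -> float:
    """-2 restricted log-likelihood at explicit variance components."""
    lam = tau2 / sigma2
    A, _, rss, logdet = _gls_pieces(blocks, lam)
    _, logdetA = np.linalg.slogdet(A)
    # log|V| = n log sigma2 + logdet ; log|X'V^-1 X| = logdetA - p log sigma2
    return (n - p) * np.log(sigma2) + logdet + logdetA + rss / sigma2


def _fit_random_intercept(X, y, groups, reml: bool = True):
    n, p = X.shape
    blocks = _group_blocks(np.asarray(X, float), np.asarray(y, float), np.asarray(groups))
    dof = (n - p) if reml else n

    def crit(loglam: float) -> float:
        lam = np.exp(loglam)
        A, _, rss, logdet = _gls_pieces(blocks, lam)
        out = dof * np.log(rss) + logdet
        if reml:
            out += np.linalg.slogdet(A)[1]
        return out

    res = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    # also consider the boundary lam -> 0
    if crit(np.log(1e-12)) < res.fun:
        lam = 0.0
    A, beta, rss, _logdet = _gls_pieces(blocks, lam)
    sigma2 = rss / dof
    tau2 = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)
    return blocks, beta, cov_beta, sigma2, tau2


def _satterthwaite_df(blocks, n, p, sigma2, tau2, cov_beta_fn, contrasts):
    """Satterthwaite df per contrast via the delta method on (sigma2, tau2)."""
    theta = np.array([sigma2, tau2])
    h = np.maximum(1e-6 * theta, 1e-10)

    def nu(th, c):
        return c @ cov_beta_fn(th[0], th[1]) @ c

    # observed information of -2 reml loglik / 2 => information of loglik
    def f(th):
        return 0.5 * _neg2_reml(blocks, n, p, th[0], th[1])

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        Vtheta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Vtheta = np.linalg.pinv(H)

    dfs = []
    for c in contrasts:
        g = np.zeros(2)
        for i in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            g[i] = (nu(theta + ei, c) - nu(theta - ei, c)) / (2 * h[i])
        var_nu = float(g @ Vtheta @ g)
        v = float(nu(theta, c))
        dfs.append(2 * v**2 / var_nu if var_nu > 0 else np.inf)
    return dfs


def _wing_design(records: pd.DataFrame, sex: str) -> pd.DataFrame:
    df = records[records["sex"] == sex]
    long = df.melt(
        id_vars=["id", "run", "condition", "diet"],
        value_vars=["wing_left", "wing_right"],
        var_name="side", value_name="wing",
    ).dropna(subset=["wing"])
    return long


def wing_lmm(
    cohort: CohortTable | pd.DataFrame,
    sex: str = "F",
    baseline_condition: str = "LC",
    baseline_diet: str = "T",
    include_interaction: bool = True,
) -> WingLengthModelFit:
    """Gaussian linear mixed model for wing length.

    Fixed effects: condition + diet (+ condition x diet interaction) against
    the LC/Tetramin baseline; random intercept per replicate run; REML fit
    with Satterthwaite-style degrees of freedom, plus a likelihood-ratio test
    (ML fits) for the interaction block.  Observations are individual wing
    measurements of one sex.
    """
    records = cohort.records if isinstance(cohort, CohortTable) else cohort
    long = _wing_design(records, sex)
    if long.empty:
        raise ValueError(f"no measured wings for sex {sex!r}")
    runs = long["run"].unique()
    if len(runs) < 2:
        raise ValueError("need >= 2 runs to identify the run random effect")
    conds = [c for c in CONDITIONS if c in set(long["condition"])]
    if len(conds) < 2 or len(set(long["diet"])) < 2:
        raise ValueError("need >= 2 conditions and both diets")

    other_conds = [c for c in conds if c != baseline_condition]
    other_diets = [d for d in sorted(set(long["diet"])) if d != baseline_diet]

    def design(include_ix: bool) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(long))]
        names = ["(Intercept)"]
        for c in other_conds:
            cols.append((long["condition"] == c).to_numpy(float))
            names.append(f"type {c}")
        for d in other_diets:
            cols.append((long["diet"] == d).to_numpy(float))
            names.append(f"Food {d}")
        if include_ix:
            for c in other_conds:
                for d in other_diets:
                    cols.append(
                        ((long["condition"] == c) & (long["diet"] == d)).to_numpy(float)
                    )
                    names.append(f"type {c}:Food {d}")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        return X, names

    y = long["wing"].to_numpy(float)
    groups = long["run"].to_numpy()

    X, names = design(include_interaction)
    n, p = X.shape
    blocks, beta, cov_beta, sigma2, tau2 = _fit_random_intercept(X, y, groups, reml=True)

    def cov_beta_fn(s2, t2):
        lam = t2 / s2
        A, _, _, _ = _gls_pieces(blocks, lam)
        return s2 * np.linalg.inv(A)

    contrasts = list(np.eye(p))
    dfs = _satterthwaite_df(blocks, n, p, sigma2, tau2, cov_beta_fn, contrasts)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)
    terms = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "df": dfs, "p": pvals}, index=names
    )

    lrt = None
    if include_interaction:
        ll_full = _ml_loglik(X, y, groups)
        X0, _ = design(False)
        ll_red = _ml_loglik(X0, y, groups)
        chi2 = max(0.0, 2.0 * (ll_full - ll_red))
        k = X.shape[1] - X0.shape[1]
        lrt = TwoGroupTestResult(
            statistic=chi2, df=float(k),
            p_value=float(stats.chi2.sf(chi2, k)), test="lrt-interaction",
        )

    ll_reml = _reml_loglik_value(blocks, n, p, sigma2, tau2)
    return WingLengthModelFit(
        terms=terms,
        run_sd=float(np.sqrt(tau2)),
        residual_sd=float(np.sqrt(sigma2)),
        n_obs=n,
        n_groups=len(runs),
        loglik_reml=ll_reml,
        lrt_interaction=lrt,
    )


def _ml_loglik(X, y, groups) -> float:
    n, p = X.shape
    blocks = _group_blocks(np.asarray(X, float), np.asarray(y, float), np.asarray(groups))

    def crit(loglam):
        lam = np.exp(loglam)
        _, _, rss, logdet = _gls_pieces(blocks, lam)
        return n * np.log(rss) + logdet

    res = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    if crit(np.log(1e-12)) < res.fun:
        lam = 0.0
    _, _, rss, logdet = _gls_pieces(blocks, lam)
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + rss / sigma2)


def _reml_loglik_value(blocks, n, p, sigma2, tau2) -> float:
    return -0.5 * (_neg2_reml(blocks, n, p, sigma2, tau2) + (n - p) * np.log(2 * np.pi))


def diet_percent_difference(fit: WingLengthModelFit, diet_term: str = "Food M") -> int:
    """Diet main effect as a whole-percent of the baseline wing length."""
    intercept = fit.estimate("(Intercept)")
    if intercept == 0:
        raise ValueError("zero intercept")
    return round(abs(fit.estimate(diet_term)) / intercept * 100)


# ----------------------------------------------------------------------
# group tests

def _kruskal(samples) -> tuple[float, float]:
    """Kruskal-Wallis H with the degenerate all-tied case defined as H = 0."""
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p)


def asymmetry_test(
    records: pd.DataFrame,
    group_cols: tuple[str, ...] = ("condition", "diet"),
) -> TwoGroupTestResult:
    """Kruskal-Wallis test of |left - right| wing asymmetry across groups."""
    df = records.dropna(subset=["wing_left", "wing_right"]).copy()
    df["asym"] = (df["wing_left"] - df["wing_right"]).abs()
    samples = [g["asym"].to_numpy() for _, g in df.groupby(list(group_cols))]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 groups with complete wing pairs")
    stat, p = _kruskal(samples)
    return TwoGroupTestResult(
        statistic=float(stat), df=float(len(samples) - 1),
        p_value=float(p), test="kruskal-wallis",
    )


def mortality_test(records: pd.DataFrame) -> TwoGroupTestResult:
    """Kruskal-Wallis comparison of per-run mortality rates across the
    condition x diet groups."""
    rates: dict[tuple, list[float]] = {}
    for (cond, diet, _run), g in records.groupby(["condition", "diet", "run"]):
        deaths = int(g["death_day"].notna().sum())
        emerg = int(g["emergence_day"].notna().sum())
        if deaths + emerg == 0:
            continue
        rates.setdefault((cond, diet), []).append(mortality_rate(deaths, emerg))
    samples = [np.asarray(v) for v in rates.values()]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need per-run mortality rates in >= 2 groups")
    stat, p = _kruskal(samples)
    return TwoGroupTestResult(
        statistic=float(stat), df=float(len(samples) - 1),
        p_value=float(p), test="kruskal-wallis",
    )
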