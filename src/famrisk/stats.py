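"""Statistical procedures for the interface usability study.

Covers the full analysis pipeline applied to a two-group (diagram vs.
questionnaire interface) usability dataset: recoding of negatively worded
satisfaction items, Little's MCAR test over missingness patterns, a single
deterministic EM conditional-mean imputation, Cronbach's alpha for the
17-item satisfaction instrument, and the two-group comparisons (pooled
t-test with a Shapiro–Wilk normality gate falling back to Mann–Whitney).

Satisfaction items follow the IBM Computer System Usability Questionnaire
(CSUQ): 17 items on a 7-point Likert scale.  After recoding, higher totals
mean higher satisfaction; totals range 17..119.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, StatsError

__all__ = [
    "InstrumentSpec",
    "StudyDataset",
    "TestResult",
    "MCARResult",
    "GroupStats",
    "ComparisonBlock",
    "SatisfactionBlock",
    "AnalysisConfig",
    "AnalysisReport",
    "recode",
    "total_score",
    "cronbach_alpha",
    "little_mcar",
    "impute_single",
    "t_test_ind",
    "normality_check",
    "mann_whitney",
    "analyze_study",
    "read_study",
    "write_study",
    "ITEM_COLUMNS",
    "GROUPS",
    "AGE_BANDS",
    "WEB_USE_LEVELS",
]

N_ITEMS = 17
LIKERT_MIN, LIKERT_MAX = 1, 7
ITEM_COLUMNS = tuple(f"i{j:02d}" for j in range(1, N_ITEMS + 1))
GROUPS = ("diagram", "questionnaire")
AGE_BANDS = ("<18", "18-24", "25-34", "35-44", "45-54", "55-64", ">64")
WEB_USE_LEVELS = ("lt_monthly", "monthly", "several_monthly", "weekly_plus")

STUDY_COLUMNS = (
    ("participant_id", "group", "gender", "age_band", "web_use", "task_time_s")
    + ITEM_COLUMNS
)


@dataclass(frozen=True)
class InstrumentSpec:
    """The 17-item satisfaction instrument and per-item wording polarity.

    ``negative`` lists item ids that are negatively worded and must be
    recoded (x -> 8 - x) so that higher always means more satisfied.
    """

    items: tuple[str, ...] = ITEM_COLUMNS
    negative: frozenset = frozenset()

    def __post_init__(self):
        if len(self.items) != N_ITEMS:
            raise DataError(f"instrument must have exactly {N_ITEMS} items, got {len(self.items)}")
        unknown = set(self.negative) - set(self.items)
        if unknown:
            raise DataError(f"negative item(s) not in instrument: {sorted(unknown)}")


@dataclass(frozen=True)
class StudyDataset:
    """One usability-study dataset: one row per participant.

    Columns: participant_id, group (diagram/questionnaire), gender,
    age_band, web_use, task_time_s, i01..i17 (Likert 1..7, NaN = missing).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in STUDY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"study dataset missing column(s): {missing}")
        bad_group = set(self.frame["group"].unique()) - set(GROUPS)
        if bad_group:
            raise DataError(f"unknown group label(s): {sorted(bad_group)}")

    def items(self) -> pd.DataFrame:
        return self.frame.loc[:, list(ITEM_COLUMNS)].astype(float)

    def __len__(self) -> int:
        return len(self.frame)


def read_study(path) -> StudyDataset:
    """Read a study CSV (missing Likert cells as empty)."""
    frame = pd.read_csv(path)
    return StudyDataset(frame)


def write_study(dataset: StudyDataset, path) -> None:
    """Write a study CSV; missing cells become empty, responses stay integers."""
    out = dataset.frame.copy()
    for col in ITEM_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scoring


def recode(items: pd.DataFrame, spec: InstrumentSpec | None = None) -> pd.DataFrame:
    """Recode negatively worded items (x -> 8 - x); missing stays missing.

    Raises :class:`DataError` naming the item id on out-of-range responses.
    """
    if spec is None:
        spec = InstrumentSpec()
    out = items.loc[:, list(spec.items)].astype(float).copy()
    for item in spec.items:
        col = out[item]
        bad = col.dropna()
        bad = bad[(bad < LIKERT_MIN) | (bad > LIKERT_MAX)]
        if len(bad):
            raise DataError(
                f"item {item!r} has response(s) outside {LIKERT_MIN}..{LIKERT_MAX}: "
                f"{sorted(bad.unique().tolist())}"
            )
    for item in spec.negative:
        out[item] = (LIKERT_MIN + LIKERT_MAX) - out[item]
    return out


def total_score(recoded: pd.DataFrame) -> pd.Series:
    """Sum the 17 recoded items per participant; NaN if any item is missing."""
    return recoded.sum(axis=1, min_count=len(recoded.columns))


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of totals).

    Sample variances use the n-1 denominator.  Requires a complete matrix
    with at least two items and two respondents and nonzero total variance.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise StatsError("cronbach_alpha needs at least 2 respondents and 2 items")
    if np.isnan(X).any():
        raise StatsError("cronbach_alpha requires a complete (imputed) matrix")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise StatsError("reliability undefined: total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# Missing data: EM for the multivariate normal, Little's MCAR test, imputation


def _patterns(mask: np.ndarray):
    """Group row indices by observed-variable pattern (mask True = observed)."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(tuple(row.tolist()), []).append(i)
    return groups


def _em_mvnorm(X: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """ML mean/covariance of an incomplete data matrix via pattern-grouped EM.

    Returns (mu, sigma) with the maximum-likelihood (1/n) covariance, as
    used by Little's test.  Rows with no observed values are ignored by the
    caller; every column must be observed at least once.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if n < 2:
        raise StatsError("EM needs at least 2 rows")
    never = np.where(~obs.any(axis=0))[0]
    if len(never):
        raise StatsError(f"column(s) never observed: {never.tolist()}")

    mu = np.nanmean(X, axis=0)
    filled = np.where(obs, X, mu)
    sigma = np.cov(filled, rowvar=False, ddof=0)
    sigma = sigma + 1e-6 * np.eye(p)

    groups = _patterns(obs)
    for _ in range(max_iter):
        M = np.zeros(p)
        S = np.zeros((p, p))
        for pattern, rows in groups.items():
            o = np.array(pattern)
            m = ~o
            rows = np.asarray(rows)
            Xo = X[np.ix_(rows, np.where(o)[0])]
            k = len(rows)
            Xhat = np.empty((k, p))
            Xhat[:, o] = Xo
            if m.any():
                Soo = sigma[np.ix_(o, o)]
                Som = sigma[np.ix_(o, m)]
                try:
                    beta = np.linalg.solve(Soo, Som)  # |o| x |m|
                except np.linalg.LinAlgError:
                    raise StatsError(
                        f"singular observed-covariance block for pattern {pattern}"
                    ) from None
                Xhat[:, m] = mu[m] + (Xo - mu[o]) @ beta
                C = sigma[np.ix_(m, m)] - sigma[np.ix_(m, o)] @ beta
                S[np.ix_(m, m)] += k * C
            M += Xhat.sum(axis=0)
            S += Xhat.T @ Xhat
        mu_new = M / n
        sigma_new = S / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        shift = max(
            np.abs(mu_new - mu).max(),
            np.abs(sigma_new - sigma).max(),
        )
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma


@dataclass(frozen=True)
class MCARResult:
    """Little's MCAR chi-square test over missingness patterns.

    ``applicable`` is False when the data are complete (a single fully
    observed pattern), in which case no test is performed.
    """

    d2: float
    df: int
    p_value: float | None
    n_patterns: int
    applicable: bool
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None


def little_mcar(data) -> MCARResult:
    """Little's test that values are missing completely at random (MCAR).

    Estimates the grand mean and covariance by EM, then sums over
    missingness patterns j the quadratic form
    n_j (ybar_obs,j - mu_j)' Sigma_j^{-1} (ybar_obs,j - mu_j);
    under MCAR the statistic is chi-square with
    df = sum_j (#variables observed in pattern j) - p.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise StatsError("little_mcar needs a 2-D matrix with at least 2 variables")
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    obs = ~np.isnan(X)
    n, p = X.shape
    groups = _patterns(obs)
    if not np.isnan(X).any():
        return MCARResult(
            d2=0.0, df=0, p_value=None, n_patterns=len(groups), applicable=False,
            mu=X.mean(axis=0), sigma=np.cov(X, rowvar=False, ddof=0),
        )
    mu, sigma = _em_mvnorm(X)
    d2 = 0.0
    df = 0
    for pattern, rows in groups.items():
        o = np.where(np.array(pattern))[0]
        ybar = X[np.ix_(rows, o)].mean(axis=0)
        diff = ybar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        try:
            sol = np.linalg.solve(Soo, diff)
        except np.linalg.LinAlgError:
            raise StatsError(f"singular covariance block for pattern {pattern}") from None
        d2 += len(rows) * float(diff @ sol)
        df += len(o)
    df -= p
    p_value = float(sps.chi2.sf(d2, df)) if df > 0 else None
    return MCARResult(
        d2=float(d2), df=df, p_value=p_value, n_patterns=len(groups),
        applicable=True, mu=mu, sigma=sigma,
    )


def impute_single(data) -> pd.DataFrame | np.ndarray:
    """Deterministic single imputation by EM conditional means.

    Missing cells are replaced with their conditional expectation given the
    row's observed values under the EM-estimated normal model; observed
    cells are returned bit-identical.  Complete data are returned unchanged.
    """
    is_frame = isinstance(data, pd.DataFrame)
    X = np.asarray(data, dtype=float)
    if not np.isnan(X).any():
        return data.copy() if is_frame else X.copy()
    if np.isnan(X).all(axis=1).any():
        raise StatsError("cannot impute rows with no observed values")
    mu, sigma = _em_mvnorm(X)
    out = X.copy()
    for pattern, rows in _patterns(~np.isnan(X)).items():
        o = np.array(pattern)
        m = ~o
        if not m.any():
            continue
        Xo = X[np.ix_(rows, np.where(o)[0])]
        beta = np.linalg.solve(sigma[np.ix_(o, o)], sigma[np.ix_(o, m)])
        out[np.ix_(rows, np.where(m)[0])] = mu[m] + (Xo - mu[o]) @ beta
    if is_frame:
        return pd.DataFrame(out, index=data.index, columns=data.columns)
    return out


# ---------------------------------------------------------------------------
# Two-group tests


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    summaries: Mapping[str, tuple[int, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value out of [0, 1]: {self.p_value}")


def _summaries(a: np.ndarray, b: np.ndarray, names=("a", "b")):
    return {
        name: (len(x), float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        for name, x in zip(names, (a, b))
    }


def t_test_ind(a, b, welch: bool = False, names=("a", "b")) -> TestResult:
    """Two-sided independent-groups t-test, pooled-variance by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("t-test needs at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of a difference
            return TestResult("t", 0.0, 1.0, df=float(len(a) + len(b) - 2),
                              summaries=_summaries(a, b, names))
        raise StatsError("t-test undefined: both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TestResult(
        method="welch_t" if welch else "t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        summaries=_summaries(a, b, names),
    )


def normality_check(sample, name: str = "sample") -> TestResult:
    """Shapiro–Wilk normality test (appropriate for n below 50)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise StatsError("normality check needs at least 3 observations")
    if np.ptp(x) == 0:
        raise StatsError("normality check undefined on a constant sample")
    stat, p = sps.shapiro(x)
    return TestResult(
        method="shapiro_wilk", statistic=float(stat), p_value=float(p),
        summaries={name: (len(x), float(np.mean(x)), float(np.std(x, ddof=1)))},
    )


_EXACT_MAX_N = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x vs y with 1/2 credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumerating every group assignment.

    Handles ties correctly: the null distribution of U is built over all
    C(n1+n2, n1) relabellings of the pooled sample, under which U is
    symmetric about n1*n2/2.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)
    u_obs = _u_statistic(a, b)
    centre = n1 * (n - n1) / 2.0
    dev = abs(u_obs - centre)
    count = 0
    total = 0
    idx_all = frozenset(range(n))
    for combo in itertools.combinations(range(n), n1):
        xs = pooled[list(combo)]
        ys = pooled[list(idx_all - set(combo))]
        u = _u_statistic(xs, ys)
        if abs(u - centre) >= dev - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def mann_whitney(a, b, names=("a", "b")) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration over group assignments when both groups have at
    most 8 observations, and the tie-corrected normal approximation for
    larger groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise StatsError("mann_whitney needs non-empty groups")
    if len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N:
        u, p = _mann_whitney_exact(a, b)
        method = "mann_whitney_exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "mann_whitney_asymptotic"
    return TestResult(
        method=method, statistic=u, p_value=min(p, 1.0),
        summaries=_summaries(a, b, names),
    )


# ---------------------------------------------------------------------------
# The full study analysis pipeline


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    welch: bool = False
    shapiro_max_n: int = 50  # the small-sample regime where Shapiro-Wilk applies


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class ComparisonBlock:
    """Descriptives plus the gated two-group comparison for one outcome."""

    groups: Mapping[str, GroupStats]
    normality: Mapping[str, TestResult]
    t_test: TestResult
    mann_whitney_test: TestResult
    selected: str  # "t" or "mann_whitney"

    @property
    def selected_p(self) -> float:
        return (self.t_test if self.selected == "t" else self.mann_whitney_test).p_value


@dataclass(frozen=True)
class SatisfactionBlock(ComparisonBlock):
    n_participants_missing: int = 0
    mcar: MCARResult | None = None
    imputed: bool = False
    imputation_justified: bool = True
    alpha: float = float("nan")


@dataclass(frozen=True)
class AnalysisReport:
    efficiency: ComparisonBlock
    satisfaction: SatisfactionBlock

    def to_dict(self) -> dict:
        def test_d(t: TestResult | None):
            if t is None:
                return None
            return {"method": t.method, "statistic": t.statistic, "df": t.df, "p_value": t.p_value}

        def block_d(b: ComparisonBlock) -> dict:
            return {
                "groups": {g: {"n": s.n, "mean": s.mean, "sd": s.sd} for g, s in b.groups.items()},
                "normality": {g: test_d(t) for g, t in b.normality.items()},
                "t_test": test_d(b.t_test),
                "mann_whitney": test_d(b.mann_whitney_test),
                "selected": b.selected,
                "selected_p": b.selected_p,
            }

        sat = block_d(self.satisfaction)
        sat.update(
            {
                "n_participants_missing": self.satisfaction.n_participants_missing,
                "mcar": None
                if self.satisfaction.mcar is None
                else {
                    "d2": self.satisfaction.mcar.d2,
                    "df": self.satisfaction.mcar.df,
                    "p_value": self.satisfaction.mcar.p_value,
                    "n_patterns": self.satisfaction.mcar.n_patterns,
                    "applicable": self.satisfaction.mcar.applicable,
                },
                "imputed": self.satisfaction.imputed,
                "imputation_justified": self.satisfaction.imputation_justified,
                "cronbach_alpha": self.satisfaction.alpha,
            }
        )
        return {"efficiency": block_d(self.efficiency), "satisfaction": sat}


def _compare_groups(values_by_group: Mapping[str, np.ndarray], config: AnalysisConfig) -> tuple:
    names = tuple(values_by_group)
    a, b = (values_by_group[g] for g in names)
    groups = {
        g: GroupStats(len(x), float(np.mean(x)), float(np.std(x, ddof=1)))
        for g, x in values_by_group.items()
    }
    normality = {
        g: normality_check(x, name=g)
        for g, x in values_by_group.items()
        if len(x) < config.shapiro_max_n
    }
    t_res = t_test_ind(a, b, welch=config.welch, names=names)
    mw_res = mann_whitney(a, b, names=names)
    non_normal = any(t.p_value < config.alpha for t in normality.values())
    selected = "mann_whitney" if non_normal else "t"
    return groups, normality, t_res, mw_res, selected


def analyze_study(dataset: StudyDataset, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the complete usability analysis.

    Efficiency: per-group mean/SD of task time, per-group Shapiro–Wilk
    normality check (for groups below 50), pooled t-test, and Mann–Whitney;
    the nonparametric test is selected exactly when any group's normality
    check rejects at the configured alpha.

    Satisfaction: recode negatively worded items, test missingness with
    Little's MCAR test, impute a single completed dataset by EM conditional
    means, sum the 17 items into totals, compute Cronbach's alpha, and
    compare the groups with the same normality-gated procedure.
    """
    if config is None:
        config = AnalysisConfig()
    frame = dataset.frame

    # ---- efficiency -------------------------------------------------------
    times = {
        g: frame.loc[frame["group"] == g, "task_time_s"].to_numpy(dtype=float)
        for g in GROUPS
    }
    eff = ComparisonBlock(*_compare_groups(times, config))

    # ---- satisfaction -----------------------------------------------------
    recoded = recode(dataset.items(), config.instrument)
    n_missing = int(recoded.isna().any(axis=1).sum())
    mcar = little_mcar(recoded.to_numpy())
    if mcar.applicable:
        completed = impute_single(recoded)
        imputed = True
        justified = mcar.p_value is None or mcar.p_value >= config.alpha
    else:
        completed = recoded
        imputed = False
        justified = True
    alpha_val = cronbach_alpha(completed.to_numpy())
    totals = total_score(completed)
    totals_by_group = {
        g: totals[frame["group"] == g].to_numpy(dtype=float) for g in GROUPS
    }
    groups, normality, t_res, mw_res, selected = _compare_groups(totals_by_group, config)
    sat = SatisfactionBlock(
        groups=groups,
        normality=normality,
        t_test=t_res,
        mann_whitney_test=mw_res,
        selected=selected,
        n_participants_missing=n_missing,
        mcar=mcar,
        imputed=imputed,
        imputation_justified=justified,
        alpha=alpha_val,
    )
    return AnalysisReport(efficiency=eff, satisfaction=sat)
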