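"""Two-group inference for small diet-group cohorts.

The central statistic is the probability index PI = P(X > Y) + 0.5 P(X = Y),
the probability that a randomly drawn member of group A exceeds a randomly
drawn member of group B (ties split evenly). PI = 0.5 means stochastic
equality; PI equals the Mann-Whitney U statistic divided by n1*n2 under the
midrank tie convention. Inference is by permutation of group labels, either
exhaustive (all C(n, n1) splits) or Monte Carlo, with optional age- and
sex-adjustment by null-model OLS residualization or by sex x age-tertile
restricted permutation. Welch tests, Behrens-Fisher (Welch-Satterthwaite)
confidence intervals, and Benjamini-Hochberg correction round out the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError, FeasibilityError, InputError

#: permuting more splits than this exhaustively is refused
EXHAUSTIVE_LIMIT = 200_000

#: Monte Carlo permutation count used throughout unless overridden
DEFAULT_N_PERM = 47_500

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group probability-index permutation test."""

    statistic: float  # probability index, in [0, 1]
    effect: float  # |PI - 0.5|
    p_raw: float
    q: float | None
    n_perm: int
    mode: str  # "exhaustive" or "monte_carlo"
    n1: int
    n2: int
    adjusted: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise InputError(f"probability index {self.statistic} outside [0, 1]")


def probability_index(x, y) -> float:
    """PI = [#(x_i > y_j) + 0.5 #(x_i = y_j)] / (n1 n2).

    Computed through pooled midranks: with R1 the midrank sum of group A,
    U = R1 - n1(n1+1)/2 and PI = U / (n1 n2), which is algebraically equal
    to the pairwise count with ties weighted one half.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("probability_index requires both groups nonempty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def residualize(values, age, sex):
    """OLS residuals of values on intercept + age + sex, pooled over groups.

    The fit ignores group labels entirely, so the residuals are exchangeable
    under the null hypothesis and may be permuted directly.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_ind = _sex_indicator(sex)
    n = values.size
    if n < 4:
        raise InputError("residualize requires at least 4 observations")
    if age.size != n or sex_ind.size != n:
        raise InputError("values, age, and sex must have equal length")
    design = np.column_stack([np.ones(n), age, sex_ind])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError(
            "design matrix (intercept, age, sex) is rank deficient; "
            "age or sex carries no variation"
        )
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _sex_indicator(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "fiub":
        return arr.astype(float)
    codes = {"F": 1.0, "M": 0.0}
    try:
        return np.array([codes[str(s)] for s in arr])
    except KeyError as exc:  # pragma: no cover - defensive
        raise InputError(f"unknown sex code {exc.args[0]!r}; expected F or M") from exc


def _strata(age, sex) -> np.ndarray:
    """Sex x age-tertile stratum index per observation."""
    age = np.asarray(age, dtype=float)
    cuts = np.quantile(age, [1 / 3, 2 / 3])
    tert = np.digitize(age, cuts, right=True)
    return _sex_indicator(sex).astype(int) * 3 + tert


def _permutation_indices(n, n_perm, rng, strata=None) -> np.ndarray:
    """n_perm independent uniform shuffles of 0..n-1 (within strata if given)."""
    if strata is None:
        return np.argsort(rng.random((n_perm, n)), axis=1, kind="stable")
    idx = np.broadcast_to(np.arange(n), (n_perm, n)).copy()
    for s in np.unique(strata):
        pos = np.flatnonzero(strata == s)
        order = np.argsort(rng.random((n_perm, pos.size)), axis=1, kind="stable")
        idx[:, pos] = pos[order]
    return idx


def _annihilator(age, sex) -> np.ndarray:
    """I - H for the label-free design (intercept, age, sex)."""
    n = len(age)
    design = np.column_stack(
        [np.ones(n), np.asarray(age, dtype=float), _sex_indicator(sex)]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError(
            "design matrix (intercept, age, sex) is rank deficient"
        )
    hat = design @ np.linalg.pinv(design)
    return np.eye(n) - hat


def perm_test(
    values,
    groups,
    age=None,
    sex=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    mode: str = "monte_carlo",
    adjust: bool = False,
    scheme: str = "residualize",
) -> TestResult:
    """Two-sided permutation test with |PI - 0.5| as test statistic.

    Parameters
    ----------
    values, groups
        Observations and their two group labels; group A is the label that
        appears first, so PI estimates P(A > B) + 0.5 P(A = B).
    age, sex
        Covariates, required when ``adjust`` is true.
    mode
        ``"exhaustive"`` enumerates all C(n, n1) label splits (p has no
        Monte Carlo error); ``"monte_carlo"`` draws ``n_perm`` independent
        uniform shuffles and applies the +1 correction so p >= 1/(n_perm+1).
    adjust, scheme
        With ``scheme="residualize"`` the observed statistic is computed on
        pooled OLS residuals of values on intercept + age + sex (a label-free
        fit), and the null follows the Freedman-Lane construction: permuted
        residuals are re-residualized on the same design before ranking,
        which restores orthogonality to the covariates and keeps the test
        level exact even when group membership is correlated with age or sex.
        With ``scheme="stratified"`` raw values are used but labels are
        permuted only within sex x age-tertile strata.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise InputError(f"exactly two group labels required, got {uniq}")
    if mode not in ("exhaustive", "monte_carlo"):
        raise InputError(f"unknown mode {mode!r}")
    if scheme not in ("residualize", "stratified"):
        raise InputError(f"unknown scheme {scheme!r}")
    if mode == "monte_carlo" and n_perm < 1:
        raise InputError("n_perm must be >= 1 for monte_carlo mode")

    mask_a = labels == uniq[0]
    pos_a = np.flatnonzero(mask_a)
    n1, n = int(mask_a.sum()), values.size
    n2 = n - n1

    strata = None
    annihilate = None
    if adjust:
        if age is None or sex is None:
            raise InputError("adjust=True requires age and sex")
        if scheme == "residualize":
            if n < 4:
                raise InputError("residualize requires at least 4 observations")
            annihilate = _annihilator(age, sex)
            values = annihilate @ values
        else:
            strata = _strata(age, sex)

    ranks = sps.rankdata(values)
    offset = n1 * (n1 + 1) / 2.0
    scale = n1 * n2
    pi_obs = (ranks[pos_a].sum() - offset) / scale
    t_obs = abs(pi_obs - 0.5)

    if mode == "exhaustive":
        if adjust:
            raise InputError(
                "the adjusted null is defined over full permutations "
                "(Freedman-Lane) or stratified shuffles; use mode='monte_carlo'"
            )
        n_splits = math.comb(n, n1)
        if n_splits > EXHAUSTIVE_LIMIT:
            raise FeasibilityError(
                f"C({n},{n1}) = {n_splits} splits exceed the exhaustive limit "
                f"{EXHAUSTIVE_LIMIT}; use mode='monte_carlo'"
            )
        sums = np.fromiter(
            (ranks[list(c)].sum() for c in combinations(range(n), n1)),
            dtype=float,
            count=n_splits,
        )
        t_null = np.abs((sums - offset) / scale - 0.5)
        p = float((t_null >= t_obs - _TIE_EPS).sum() / n_splits)
        n_used = n_splits
    else:
        rng = np.random.default_rng(seed)
        idx = _permutation_indices(n, n_perm, rng, strata=strata)
        if annihilate is not None:
            # Freedman-Lane: re-residualize each permuted residual vector
            permuted = values[idx] @ annihilate.T
            rank_rows = sps.rankdata(permuted, axis=1)
            sums = rank_rows[:, pos_a].sum(axis=1)
        else:
            sums = ranks[idx[:, pos_a]].sum(axis=1)
        t_null = np.abs((sums - offset) / scale - 0.5)
        p = float(((t_null >= t_obs - _TIE_EPS).sum() + 1) / (n_perm + 1))
        n_used = n_perm

    return TestResult(
        statistic=float(pi_obs),
        effect=float(t_obs),
        p_raw=p,
        q=None,
        n_perm=n_used,
        mode=mode,
        n1=n1,
        n2=n2,
        adjusted=adjust,
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("welch_t requires at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise InputError("welch_t undefined: both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def behrens_fisher_ci(x, y, level: float = 0.95) -> tuple[float, float]:
    """Welch-Satterthwaite CI for mean(x) - mean(y) under unequal variances."""
    if not 0.0 < level < 1.0:
        raise InputError(f"confidence level {level} outside (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("behrens_fisher_ci requires >= 2 observations per group")
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    diff = x.mean() - y.mean()
    se = math.sqrt(vx + vy)
    if se == 0.0:
        return float(diff), float(diff)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    t = sps.t.ppf((1 + level) / 2, df)
    return float(diff - t * se), float(diff + t * se)
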