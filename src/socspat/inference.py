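"""Hypothesis-level statistics with permutation-based significance.

All p-values come from permutation rather than parametric distributions:
the study group is the whole population of interest, not a sample from a
larger one, so permutation of observations (or of matrix rows/columns for
dyadic data) gives exact conditional inference.  Every p-value counts the
observed arrangement once, so p lies in [1/(n_perm + 1), 1].

Dyadic (matrix) predictors are handled with QAP machinery: simultaneous
row/column permutation of one matrix preserves the dependence structure
within rows that makes naive dyad-level permutation invalid.  Multiple
matrix regression uses Dekker's double-semi-partialing (DSP): for each
predictor, the residual of that predictor on the remaining ones is QAP-
permuted and the model refit, which is robust to predictor collinearity
and network autocorrelation.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.stats.api as sms

_ALTERNATIVES = ("two-sided", "greater", "less")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _perm_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    """Monte-Carlo p with the observed arrangement counted once."""
    if alternative == "greater":
        hits = np.sum(null >= observed)
    elif alternative == "less":
        hits = np.sum(null <= observed)
    else:
        hits = np.sum(np.abs(null) >= abs(observed))
    return float((hits + 1) / (len(null) + 1))


# ---------------------------------------------------------------------------
# Vector permutation tests
# ---------------------------------------------------------------------------


def perm_pearson(
    x,
    y,
    alternative: str = "two-sided",
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson correlation with a permutation p-value (shuffling y)."""
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    norm = np.linalg.norm(xc) * np.linalg.norm(yc)
    r = float(xc @ yc / norm)

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(yc, (n_perm, len(yc))), axis=1)
    null = perm @ xc / norm
    return r, _perm_pvalue(r, null, alternative)


def perm_ttest(
    values,
    group_labels,
    alternative: str = "two-sided",
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Welch t statistic with a permutation p-value (shuffling labels).

    ``alternative="greater"`` tests that the first group (in sorted label
    order) has the larger mean.
    """
    _check_alternative(alternative)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    mask = labels == groups[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")

    def welch_t(mask1: np.ndarray) -> float:
        a, b = values[mask1], values[~mask1]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        if se == 0:
            return 0.0
        return (a.mean() - b.mean()) / se

    t_obs = welch_t(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = welch_t(rng.permutation(mask))
    return float(t_obs), _perm_pvalue(t_obs, null, alternative)


# ---------------------------------------------------------------------------
# Attribute distance matrices
# ---------------------------------------------------------------------------


def attribute_matrices(individuals: pd.DataFrame, mds: pd.Series) -> dict:
    """Dyadic attribute matrices for the included individuals.

    Returns ``{"age_dist", "mds_dist", "sex_same", "kinship"}`` as labelled
    DataFrames: absolute differences for age and dominance score, binary
    same-sex (1 = same) and same-matriline (1 = kin).  Individuals with a
    missing matriline are treated as singleton matrilines (no kin) and
    reported in the returned dict under ``"singleton_matrilines"``.
    """
    ids = list(individuals["id"])
    age = individuals["age"].to_numpy(dtype=float)
    sex = individuals["sex"].to_numpy()
    mat = individuals["matriline"].astype("object").to_numpy()
    scores = mds.reindex(ids).to_numpy(dtype=float)

    def frame(m):
        return pd.DataFrame(m, index=ids, columns=ids)

    age_dist = np.abs(age[:, None] - age[None, :])
    mds_dist = np.abs(scores[:, None] - scores[None, :])
    sex_same = (sex[:, None] == sex[None, :]).astype(float)
    singletons = [i for i, m in zip(ids, mat) if pd.isna(m)]
    mat_filled = np.array(
        [f"_singleton_{i}" if pd.isna(m) else m for i, m in zip(ids, mat)], dtype=object
    )
    kinship = (mat_filled[:, None] == mat_filled[None, :]).astype(float)
    for m in (sex_same, kinship):
        np.fill_diagonal(m, 0.0)
    np.fill_diagonal(age_dist, 0.0)
    return {
        "age_dist": frame(age_dist),
        "mds_dist": frame(mds_dist),
        "sex_same": frame(sex_same),
        "kinship": frame(kinship),
        "singleton_matrilines": singletons,
    }


# ---------------------------------------------------------------------------
# QAP core: Mantel and MRQAP-DSP
# ---------------------------------------------------------------------------


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m.to_numpy() if hasattr(m, "to_numpy") else m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    return a


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _qap_permutations(n: int, n_perm: int, rng, exact: bool):
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def mantel(
    a,
    b,
    alternative: str = "two-sided",
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation over off-diagonal dyads with a null
    from simultaneous row/column permutation of the second matrix.

    With ``exact=True`` all n! permutations are enumerated (n <= 8) and the
    p-value is the exact permutation fraction.
    """
    _check_alternative(alternative)
    am, bm = _as_matrix(a), _as_matrix(b)
    if am.shape != bm.shape:
        raise ValueError("matrices must share shape")
    n = am.shape[0]
    mask = _offdiag_mask(n)
    av = am[mask]
    if np.std(av) == 0 or np.std(bm[mask]) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    avc = av - av.mean()
    anorm = np.linalg.norm(avc)

    def corr(mat: np.ndarray) -> float:
        v = mat[mask]
        vc = v - v.mean()
        return float(avc @ vc / (anorm * np.linalg.norm(vc)))

    r = corr(bm)
    rng = np.random.default_rng(seed)
    perms = _qap_permutations(n, n_perm, rng, exact)
    null = np.array([corr(bm[np.ix_(p, p)]) for p in perms])
    if exact:
        if alternative == "greater":
            p = float(np.mean(null >= r - 1e-12))
        elif alternative == "less":
            p = float(np.mean(null <= r + 1e-12))
        else:
            p = float(np.mean(np.abs(null) >= abs(r) - 1e-12))
        return r, p
    return r, _perm_pvalue(r, null, alternative)


@dataclasses.dataclass
class MatrixModelResult:
    """Coefficients and permutation p-values for matrix/vector regressions."""

    terms: pd.DataFrame  # per-term statistics
    r_squared: float
    adj_r_squared: float
    model_p: float | None
    n_perm: int
    seed: int | None


def mrqap_dsp(
    y,
    predictors: dict,
    alternative: str = "two-sided",
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> MatrixModelResult:
    """MRQAP with Dekker's double-semi-partialing.

    OLS on the vectorised off-diagonal dyads gives observed coefficients;
    for each predictor X_k, its matrix residual on the remaining predictors
    is row/column permuted and the partial statistic recomputed, giving a
    per-predictor null that respects network autocorrelation.  Reported per
    term: raw and standardized coefficients, partial correlation, and the
    permutation p (two-sided by default on the partial r).

    With one predictor DSP reduces to plain QAP regression.
    """
    _check_alternative(alternative)
    ym = _as_matrix(y)
    n = ym.shape[0]
    mask = _offdiag_mask(n)
    names = list(predictors)
    xms = {k: _as_matrix(predictors[k]) for k in names}
    for k, xm in xms.items():
        if xm.shape != ym.shape:
            raise ValueError(f"predictor {k!r} not conformable with response")

    yv = ym[mask]
    xcols = np.column_stack([xms[k][mask] for k in names])
    design = np.column_stack([np.ones(len(yv)), xcols])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Name a predictor whose removal restores full rank.
        for j, k in enumerate(names):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"collinear predictor set: {k!r} is redundant")
        raise ValueError("rank-deficient design")

    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant response matrix: regression undefined")
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((yv - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    d = len(yv)
    adj_r2 = 1.0 - (1.0 - r2) * (d - 1) / (d - design.shape[1])
    sd_y = yv.std(ddof=1)

    rng = np.random.default_rng(seed)
    rows = []
    for j, k in enumerate(names):
        others = np.column_stack(
            [np.ones(len(yv))] + [xcols[:, i] for i in range(len(names)) if i != j]
        )
        q_others, _ = np.linalg.qr(others)

        def resid(v: np.ndarray) -> np.ndarray:
            return v - q_others @ (q_others.T @ v)

        ry = resid(yv)
        e_vec = resid(xcols[:, j])
        e_mat = np.zeros((n, n))
        e_mat[mask] = e_vec
        ry_norm = np.linalg.norm(ry)

        def partial_stats(ev: np.ndarray) -> tuple[float, float]:
            er = resid(ev)
            denom = float(er @ er)
            if denom == 0:
                return 0.0, 0.0
            b = float(er @ ry) / denom
            pr = float(er @ ry) / (np.linalg.norm(er) * ry_norm)
            return b, pr

        b_obs, pr_obs = partial_stats(xcols[:, j])
        perms = _qap_permutations(n, n_perm, rng, exact)
        null = np.array(
            [partial_stats(e_mat[np.ix_(p, p)][mask])[1] for p in perms]
        )
        if exact:
            if alternative == "greater":
                p = float(np.mean(null >= pr_obs - 1e-12))
            elif alternative == "less":
                p = float(np.mean(null <= pr_obs + 1e-12))
            else:
                p = float(np.mean(np.abs(null) >= abs(pr_obs) - 1e-12))
        else:
            p = _perm_pvalue(pr_obs, null, alternative)
        rows.append(
            {
                "term": k,
                "beta": beta[j + 1],
                "beta_std": beta[j + 1] * xcols[:, j].std(ddof=1) / sd_y,
                "partial_r": pr_obs,
                "p": p,
            }
        )
    terms = pd.DataFrame(rows).set_index("term")
    return MatrixModelResult(terms, r2, adj_r2, None, n_perm, seed)


# ---------------------------------------------------------------------------
# Variance partitioning (partial regression with semipartial r^2)
# ---------------------------------------------------------------------------


def _dummies(labels) -> tuple[np.ndarray, int]:
    labels = pd.Series(list(labels))
    levels = sorted(labels.unique(), key=str)
    cols = [np.asarray(labels == lv, dtype=float) for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(labels), 0))), len(levels)


def variance_partition(
    y,
    block_continuous,
    block_categorical,
    n_perm: int = 10000,
    seed: int | None = None,
    permute: str = "response",
    block_names: tuple = ("continuous", "categorical"),
) -> MatrixModelResult:
    """Partial regression of y on a continuous block and a categorical block.

    Semipartial r² of a block is R²(full) − R²(without the block): the
    variance uniquely attributable to that block.  Significance per block
    (and for the full model R²) comes from permuting the response vector;
    ``permute="residuals"`` instead permutes reduced-model residuals
    (Freedman–Lane) as a sensitivity mode.
    """
    y = np.asarray(y, dtype=float)
    xc = np.asarray(block_continuous, dtype=float).reshape(len(y), -1)
    dummies, n_levels = _dummies(block_categorical)
    if len(dummies) != len(y):
        raise ValueError("blocks and response lengths differ")
    counts = pd.Series(list(block_categorical)).value_counts()
    flagged = sorted(map(str, counts[counts == 1].index))
    df_cont, df_cat = xc.shape[1], n_levels - 1
    n = len(y)
    if n <= 1 + df_cont + df_cat:
        raise ValueError("more parameters than observations")
    if permute not in ("response", "residuals"):
        raise ValueError("permute must be 'response' or 'residuals'")

    ones = np.ones((n, 1))
    q_full, _ = np.linalg.qr(np.column_stack([ones, xc, dummies]))
    q_no_cont, _ = np.linalg.qr(np.column_stack([ones, dummies]))
    q_no_cat, _ = np.linalg.qr(np.column_stack([ones, xc]))

    def r2(qmat: np.ndarray, yy: np.ndarray) -> np.ndarray:
        yc = yy - yy.mean(axis=0)
        proj = qmat.T @ yc
        return (proj**2).sum(axis=0) / (yc**2).sum(axis=0)

    def r2_stats(yy: np.ndarray):
        full = r2(q_full, yy)
        sp_cont = full - r2(q_no_cont, yy)
        sp_cat = full - r2(q_no_cat, yy)
        return full, sp_cont, sp_cat

    ymat = y.reshape(-1, 1)
    r2_full, sp_cont, sp_cat = (v[0] for v in r2_stats(ymat))
    adj_r2 = 1.0 - (1.0 - r2_full) * (n - 1) / (n - 1 - df_cont - df_cat)

    rng = np.random.default_rng(seed)
    if permute == "response":
        base = y
    else:  # ter Braak style: permute full-model residuals around the fit
        fitted_full = y.mean() + q_full @ (q_full.T @ (y - y.mean()))
        base = y - fitted_full
    perm = rng.permuted(np.broadcast_to(base, (n_perm, n)), axis=1).T
    if permute == "residuals":
        perm = perm + fitted_full.reshape(-1, 1)
    null_full, null_cont, null_cat = r2_stats(perm)

    terms = pd.DataFrame(
        {
            "df": [df_cont, df_cat],
            "semipartial_r2": [sp_cont, sp_cat],
            "p": [
                (np.sum(null_cont >= sp_cont) + 1) / (n_perm + 1),
                (np.sum(null_cat >= sp_cat) + 1) / (n_perm + 1),
            ],
        },
        index=pd.Index(list(block_names), name="term"),
    )
    terms.attrs["singleton_levels"] = flagged
    model_p = float((np.sum(null_full >= r2_full) + 1) / (n_perm + 1))
    return MatrixModelResult(terms, float(r2_full), float(adj_r2), model_p, n_perm, seed)


# ---------------------------------------------------------------------------
# Homoscedasticity diagnostics (pre-flight report, not a gate)
# ---------------------------------------------------------------------------


def homoscedasticity_report(y, x_continuous, group_labels) -> dict:
    """Breusch–Pagan (residuals vs continuous predictor) and Bartlett
    (variance across groups) statistics for a response."""
    y = np.asarray(y, dtype=float)
    x = sm.add_constant(np.asarray(x_continuous, dtype=float))
    fit = sm.OLS(y, x).fit()
    bp_stat, bp_p, _, _ = sms.het_breuschpagan(fit.resid, x)
    groups = pd.Series(list(group_labels))
    samples = [y[(groups == g).to_numpy()] for g in groups.unique()]
    samples = [s for s in samples if len(s) > 1]
    if len(samples) > 1:
        bart = scipy.stats.bartlett(*samples)
        bartlett_stat, bartlett_p = float(bart.statistic), float(bart.pvalue)
    else:
        bartlett_stat, bartlett_p = float("nan"), float("nan")
    return {
        "breusch_pagan_stat": float(bp_stat),
        "breusch_pagan_p": float(bp_p),
        "bartlett_stat": bartlett_stat,
        "bartlett_p": bartlett_p,
    }
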