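"""Within-subject group statistics implemented from the textbook formulas.

One-way repeated-measures ANOVA with the two-way (subject x condition)
sums-of-squares decomposition, partial eta squared, Mauchly's sphericity
test on orthonormal within-subject contrasts, and Bonferroni-corrected
pairwise paired-t post hocs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "RmAnovaResult",
    "MauchlyResult",
    "PairwiseComparison",
    "rm_anova",
    "mauchly_test",
    "bonferroni_posthoc",
]


@dataclass
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    mauchly_W: float
    mauchly_p: float
    sphericity_ok: bool
    ss_condition: float
    ss_subject: float
    ss_error: float


@dataclass
class MauchlyResult:
    W: float
    chi_sq: float
    df: int
    p: float


@dataclass
class PairwiseComparison:
    condition_a: str
    condition_b: str
    mean_difference: float
    t: float
    p_corrected: float
    significant: bool


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("measures must be a subjects x conditions matrix")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    return X


def rm_anova(measures: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions
    matrix.

    F = MS_condition / MS_error with (k-1, (k-1)(n-1)) degrees of freedom;
    partial eta squared = SS_condition / (SS_condition + SS_error).
    Mauchly's sphericity test is run alongside; a violation (p <= 0.05) is
    reported via ``sphericity_ok`` and a warning, without correction.
    """
    X = _check_matrix(measures)
    n, k = X.shape
    grand = X.mean()
    cond_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    F = ms_cond / ms_err if ms_err > 0 else (np.inf if ms_cond > 0 else 0.0)
    p = float(sstats.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    denom = ss_cond + ss_err
    eta = ss_cond / denom if denom > 0 else 0.0
    try:
        mau = mauchly_test(X)
        ok = mau.p > 0.05
        if not ok:
            warnings.warn(
                f"sphericity violated (Mauchly W={mau.W:.4f}, p={mau.p:.4g}); "
                "F test reported uncorrected", RuntimeWarning,
            )
    except ValueError as err:
        warnings.warn(f"Mauchly's test unavailable: {err}", RuntimeWarning)
        mau = MauchlyResult(W=np.nan, chi_sq=np.nan, df=0, p=np.nan)
        ok = True
    return RmAnovaResult(F=float(F), df_effect=df_effect, df_error=df_error,
                         p=p, partial_eta_sq=float(eta), mauchly_W=mau.W,
                         mauchly_p=mau.p, sphericity_ok=ok,
                         ss_condition=ss_cond, ss_subject=ss_subj,
                         ss_error=ss_err)


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal (k x k-1) matrix with columns orthogonal to the constant."""
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -j
        C[:, j - 1] /= np.sqrt(j * (j + 1))
    return C


def mauchly_test(measures: np.ndarray) -> MauchlyResult:
    """Mauchly's W on the covariance of orthonormal within-subject contrasts.

    W = det(S_c) / (tr(S_c)/(k-1))^(k-1); the chi-square approximation uses
    df = k(k-1)/2 - 1 with the standard small-sample correction factor.
    For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    X = _check_matrix(measures)
    n, k = X.shape
    d = k - 1
    if d == 1:
        return MauchlyResult(W=1.0, chi_sq=0.0, df=0, p=1.0)
    if n <= d:
        raise ValueError(
            f"need more subjects ({n}) than contrasts ({d}) for a "
            "nonsingular contrast covariance"
        )
    C = _helmert_contrasts(k)
    Y = X @ C
    S = np.cov(Y, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    if eig.min() <= 0:
        raise ValueError(
            "singular contrast covariance (condition number "
            f"{eig.max() / max(eig.min(), 1e-300):.3g})"
        )
    W = float(np.prod(eig) / (eig.mean() ** d))
    df = k * (k - 1) // 2 - 1
    # chi-square approximation with the standard first- and second-order
    # correction terms (as in R's ezANOVA)
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    chi2 = -(n - 1) * f * np.log(W)
    p1 = sstats.chi2.sf(chi2, df)
    p2 = sstats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return MauchlyResult(W=W, chi_sq=float(chi2), df=df, p=p)


def bonferroni_posthoc(measures: np.ndarray,
                       condition_names: list[str] | None = None,
                       alpha: float = 0.05,
                       error_term: str = "pairwise") -> list[PairwiseComparison]:
    """Paired t test per condition pair, Bonferroni-corrected.

    Raw p values are multiplied by k(k-1)/2 and capped at 1.  The default
    uses the pairwise error term; ``error_term="pooled"`` uses the rmANOVA
    MS_error with (k-1)(n-1) df instead.
    """
    X = _check_matrix(measures)
    n, k = X.shape
    if condition_names is None:
        condition_names = [f"C{j + 1}" for j in range(k)]
    if len(condition_names) != k:
        raise ValueError("condition_names length must match columns")
    n_pairs = k * (k - 1) // 2
    if error_term == "pooled":
        res = rm_anova(X)
        ms_err = res.ss_error / res.df_error
        df = res.df_error
    elif error_term != "pairwise":
        raise ValueError(f"unknown error_term {error_term!r}")
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            d = X[:, a] - X[:, b]
            md = float(d.mean())
            if error_term == "pairwise":
                sd = d.std(ddof=1)
                df = n - 1
                se = sd / np.sqrt(n)
            else:
                se = np.sqrt(2.0 * ms_err / n)
            if se == 0:
                t = 0.0 if md == 0 else np.inf * np.sign(md)
            else:
                t = md / se
            praw = 2.0 * float(sstats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            pc = min(1.0, praw * n_pairs)
            out.append(PairwiseComparison(
                condition_a=condition_names[a], condition_b=condition_names[b],
                mean_difference=md, t=float(t), p_corrected=pc,
                significant=pc < alpha,
            ))
    return out
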