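"""Bin-wise nonparametric statistics with TFCE permutation FWE correction,
whole-tract comparisons, Barnard's unconditional exact test, the cognitive
crowding rule, and the logistic crowding models.

TFCE for a 1-D profile of z-scores z_1..z_M:

    TFCE_j = sum_{i >= 1, i*dh <= max(z)} e(i*dh, j)^E * (i*dh)^H * dh

where e(h, j) is the length (in bins) of the maximal contiguous run of bins
with z >= h that contains bin j (0 if z_j < h).  Scores are computed
separately on +z and -z so both directions share one family-wise error
budget; the permutation null is the distribution of the maximum TFCE score
over bins and signs, and corrected p-values are the plain exceedance
fraction (which can be exactly 0; optional add-one smoothing available).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats as sps

from tractcrowd.io_formats import SubjectRecord

__all__ = [
    "TFCEParams",
    "TFCEResult",
    "CrowdingLabel",
    "mannwhitney_z",
    "mannwhitney_p",
    "tfce_1d",
    "permutation_fwe",
    "whole_tract_compare",
    "barnard_exact",
    "classify_crowding",
    "fit_crowding_models",
    "LogisticModelSummary",
]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE and permutation settings (defaults E=0.5, H=2, dh=0.01)."""

    E: float = 0.5
    H: float = 2.0
    dh: float = 0.01
    n_permutations: int = 10000
    seed: int = 0
    smoothing: bool = False  # (1 + count) / (1 + N) instead of count / N
    #: "two": TFCE on +z and -z with one max-statistic budget over both
    #: signs; "positive"/"negative": the literal one-directional form where
    #: thresholds run over positive heights of the (signed) z array only.
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.sided not in ("two", "positive", "negative"):
            raise ValueError("sided must be two/positive/negative")


@dataclass
class TFCEResult:
    """Observed TFCE scores, permutation null maxima and corrected p-values."""

    z_obs: np.ndarray
    tfce_obs: np.ndarray
    null_maxima: np.ndarray
    p_corrected: np.ndarray
    alpha: float = 0.05
    n_permutations: int = 0
    exhaustive: bool = False

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha


@dataclass(frozen=True)
class CrowdingLabel:
    """VIQ - PIQ discrepancy and the crowding classification (delta >= 10)."""

    delta: float
    crowding: bool


# ---------------------------------------------------------------------------
# Mann-Whitney


def _rank_stats(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks and the tie-correction term sum(t^3 - t)."""
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return ranks, float(np.sum(counts**3 - counts))


def mannwhitney_z(bin_values_a, bin_values_b) -> float:
    """Tie-corrected normal z-score of the Mann-Whitney U statistic.

    Positive when group a is stochastically larger.  Missing values are
    dropped; each group needs at least 2 remaining values.  Returns 0 when
    all pooled values are tied.
    """
    a = np.asarray(bin_values_a, dtype=np.float64)
    b = np.asarray(bin_values_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    m, n = len(a), len(b)
    if m < 2 or n < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    ranks, tie = _rank_stats(np.concatenate([a, b]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    big_n = m + n
    var = m * n / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        return 0.0
    return float((u - m * n / 2.0) / math.sqrt(var))


def mannwhitney_p(bin_values_a, bin_values_b, method: str = "normal") -> float:
    """Two-sided Mann-Whitney p-value.

    ``method="normal"`` uses the tie-corrected normal approximation with
    continuity correction; ``method="exact"`` enumerates all label
    assignments of the pooled sample (feasible for small groups) and is the
    reference the approximation is validated against.
    """
    a = np.asarray(bin_values_a, dtype=np.float64)
    b = np.asarray(bin_values_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    m, n = len(a), len(b)
    if m < 2 or n < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    pooled = np.concatenate([a, b])
    ranks, tie = _rank_stats(pooled)
    mu = m * n / 2.0
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    if method == "normal":
        big_n = m + n
        var = m * n / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
        if var <= 0:
            return 1.0
        z = max(abs(u_obs - mu) - 0.5, 0.0) / math.sqrt(var)
        return float(2.0 * sps.norm.sf(z))
    if method == "exact":
        if special.comb(m + n, m) > 5e6:
            raise ValueError("groups too large for exact enumeration")
        devs = []
        head = m * (m + 1) / 2.0
        for combo in itertools.combinations(range(m + n), m):
            devs.append(abs(ranks[list(combo)].sum() - head - mu))
        devs = np.array(devs)
        return float(np.mean(devs >= abs(u_obs - mu) - 1e-12))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# TFCE


def _tfce_batch_one_sign(z: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """TFCE scores for non-negative z, rows = profiles, columns = bins.

    Vectorized over rows: iterates threshold heights h = dh, 2*dh, ...,
    labels contiguous supra-threshold runs per row and accumulates
    extent^E * h^H * dh at every supra-threshold bin.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    p, m = z.shape
    out = np.zeros_like(z)
    zmax = z.max()
    if zmax <= 0:
        return out
    n_steps = int(math.floor(zmax / dh + 1e-12))
    row_offsets = (np.arange(p) * (m + 1))[:, None]
    for i in range(1, n_steps + 1):
        h = i * dh
        mask = z >= h
        if not mask.any():
            break
        starts = mask.copy()
        starts[:, 1:] &= ~mask[:, :-1]
        run_id = np.cumsum(starts, axis=1)
        flat = (row_offsets + run_id)[mask]
        counts = np.bincount(flat)
        out[mask] += counts[flat].astype(np.float64) ** E * h**H * dh
    return out


def tfce_scores(z: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Two-sided per-bin TFCE: computed on +z and -z and summed.

    The two sign contributions are disjoint (a bin contributes only on the
    sign of its own z), so the sum equals the score on the bin's own sign.
    """
    z = np.asarray(z, dtype=np.float64)
    pos = _tfce_batch_one_sign(np.maximum(z, 0.0)[None], params.E, params.H, params.dh)[0]
    neg = _tfce_batch_one_sign(np.maximum(-z, 0.0)[None], params.E, params.H, params.dh)[0]
    return pos + neg


def tfce_1d(z: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Alias of :func:`tfce_scores` matching the operation name."""
    return tfce_scores(z, params)


# ---------------------------------------------------------------------------
# Permutation FWE


def _permutation_labels(
    labels: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """(N, S) boolean matrix of permuted group-a masks.

    Falls back to complete enumeration when the number of distinct
    assignments does not exceed ``n_permutations``.
    """
    s = len(labels)
    m = int(labels.sum())
    n_distinct = special.comb(s, m, exact=True)
    if n_distinct <= n_permutations:
        perms = np.zeros((n_distinct, s), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(s), m)):
            perms[i, list(combo)] = True
        return perms, True
    perms = np.zeros((n_permutations, s), dtype=bool)
    for i in range(n_permutations):
        perms[i, rng.choice(s, size=m, replace=False)] = True
    return perms, False


def _zscores_for_masks(profiles: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-bin tie-corrected Mann-Whitney z for many group-a masks at once.

    ``profiles`` is (S, M) with NaN marking missing bin values (dropped
    pairwise per bin); ``masks`` is (N, S).  Degenerate bins (all tied, or
    fewer than 2 values in a group) get z = 0.
    """
    s, m = profiles.shape
    finite = np.isfinite(profiles)
    ranks = np.zeros_like(profiles)
    ties = np.zeros(m)
    for j in range(m):
        col = profiles[finite[:, j], j]
        if len(col):
            ranks[finite[:, j], j] = sps.rankdata(col)
            _, counts = np.unique(col, return_counts=True)
            ties[j] = np.sum(counts**3 - counts)
    n_j = finite.sum(axis=0).astype(np.float64)  # (M,)

    masks = masks.astype(np.float64)
    ma = masks @ finite  # (N, M) group-a sizes per bin
    sum_ranks = masks @ ranks
    mb = n_j[None, :] - ma
    u = sum_ranks - ma * (ma + 1) / 2.0
    mu = ma * mb / 2.0
    denom = np.where(n_j > 1, n_j * (n_j - 1), 1.0)
    var = ma * mb / 12.0 * ((n_j + 1) - ties[None, :] / denom[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu) / np.sqrt(var)
    z[~np.isfinite(z)] = 0.0
    z[(ma < 2) | (mb < 2)] = 0.0
    return z


def permutation_fwe(
    profiles: np.ndarray,
    labels: np.ndarray,
    params: TFCEParams = TFCEParams(),
    alpha: float = 0.05,
) -> TFCEResult:
    """Max-statistic TFCE permutation test over bins.

    ``profiles`` is the (subjects, bins) matrix (NaN = missing, dropped
    pairwise per bin); ``labels`` flags group a.  For every permuted
    labeling the per-bin z-profile is recomputed, TFCE applied to both
    signs, and the maximum score over bins and signs collected into the
    null distribution; corrected p-values are exceedance fractions against
    the observed per-bin TFCE.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if profiles.ndim != 2 or len(labels) != profiles.shape[0]:
        raise ValueError("profiles must be (subjects, bins) aligned with labels")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    rng = np.random.default_rng(params.seed)
    masks, exhaustive = _permutation_labels(labels, params.n_permutations, rng)
    n_eff = len(masks)

    z_obs = _zscores_for_masks(profiles, labels[None])[0]
    z_null = _zscores_for_masks(profiles, masks)
    sign = -1.0 if params.sided == "negative" else 1.0
    if params.sided == "two":
        tfce_obs = tfce_scores(z_obs, params)
        pos = _tfce_batch_one_sign(np.maximum(z_null, 0.0), params.E, params.H, params.dh)
        neg = _tfce_batch_one_sign(np.maximum(-z_null, 0.0), params.E, params.H, params.dh)
        null_maxima = np.maximum(pos.max(axis=1), neg.max(axis=1))
    else:
        tfce_obs = _tfce_batch_one_sign(
            np.maximum(sign * z_obs, 0.0)[None], params.E, params.H, params.dh
        )[0]
        null_maxima = _tfce_batch_one_sign(
            np.maximum(sign * z_null, 0.0), params.E, params.H, params.dh
        ).max(axis=1)

    exceed = (null_maxima[:, None] >= tfce_obs[None, :]).sum(axis=0)
    if params.smoothing:
        p = (1.0 + exceed) / (1.0 + n_eff)
    else:
        p = exceed / n_eff
    return TFCEResult(
        z_obs=z_obs,
        tfce_obs=tfce_obs,
        null_maxima=null_maxima,
        p_corrected=p,
        alpha=alpha,
        n_permutations=n_eff,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# Whole-tract comparison


def whole_tract_compare(values_a, values_b) -> tuple[float, float]:
    """Welch two-sided t-test p-value and Cohen's d (pooled SD, n-1).

    d is positive when group a's mean is larger; raises on zero pooled SD.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 <= 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    d = (a.mean() - b.mean()) / math.sqrt(sp2)
    p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return p, float(d)


# ---------------------------------------------------------------------------
# Barnard's exact test


def _wald_stat(x1: np.ndarray, x2: np.ndarray, c1: int, c2: int) -> np.ndarray:
    """Pooled Wald statistic for two binomial proportions; 0 when degenerate."""
    p1, p2 = x1 / c1, x2 / c2
    pool = (x1 + x2) / (c1 + c2)
    var = pool * (1.0 - pool) * (1.0 / c1 + 1.0 / c2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (p1 - p2) / np.sqrt(var)
    return np.where(var > 0, t, 0.0)


def barnard_exact(table, grid_step: float = 0.001) -> float:
    """Two-sided unconditional exact test for a 2x2 table.

    Columns are the two groups (fixed sizes), rows success/failure.  The
    Wald statistic orders outcomes; the p-value maximizes the two-sided
    tail probability over the nuisance success probability on a grid of
    step ``grid_step``.  An empty column margin yields p = 1.
    """
    arr = np.asarray(table, dtype=np.float64)
    if arr.shape != (2, 2) or np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("table must be a non-negative integer 2x2 count table")
    tbl = arr.astype(np.int64)
    c1, c2 = int(tbl[:, 0].sum()), int(tbl[:, 1].sum())
    if c1 == 0 or c2 == 0:
        return 1.0
    t_obs = float(_wald_stat(np.array([tbl[0, 0]]), np.array([tbl[0, 1]]), c1, c2)[0])

    x1 = np.arange(c1 + 1)
    x2 = np.arange(c2 + 1)
    t_all = _wald_stat(x1[:, None].astype(float), x2[None, :].astype(float), c1, c2)
    reject = np.abs(t_all) >= abs(t_obs) - 1e-12

    grid = np.arange(grid_step, 1.0, grid_step)
    pmf1 = sps.binom.pmf(x1[None, :], c1, grid[:, None])  # (G, c1+1)
    pmf2 = sps.binom.pmf(x2[None, :], c2, grid[:, None])
    tail = np.einsum("gi,ij,gj->g", pmf1, reject.astype(float), pmf2)
    return float(min(1.0, tail.max()))


# ---------------------------------------------------------------------------
# Crowding classification and logistic models


def classify_crowding(record: SubjectRecord, threshold: float = 10.0) -> CrowdingLabel | None:
    """Crowding iff VIQ exceeds PIQ by at least ``threshold`` points.

    Returns None (unlabeled, excluded downstream) when a score is missing.
    """
    if not (np.isfinite(record.viq) and np.isfinite(record.piq)):
        return None
    delta = float(record.viq - record.piq)
    return CrowdingLabel(delta=delta, crowding=delta >= threshold)


@dataclass
class LogisticModelSummary:
    """One fitted crowding model, mirroring a model-comparison table row."""

    name: str
    terms: list[str]
    coef: np.ndarray
    stderr: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    aic: float
    bic: float
    llr_pvalue: float
    pseudo_r2: float
    cond_number: float
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "stderr": self.stderr.tolist(),
            "z": self.zvalues.tolist(),
            "p": self.pvalues.tolist(),
            "aic": self.aic,
            "bic": self.bic,
            "llr_p": self.llr_pvalue,
            "pseudo_r2": self.pseudo_r2,
            "cond_number": self.cond_number,
            "separation": self.separation,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def fit_logistic(
    y: np.ndarray, x: np.ndarray, terms: list[str], name: str = "model"
) -> LogisticModelSummary:
    """Fit one logistic model (constant added here); ridge fallback on
    perfect separation."""
    exog = sm.add_constant(np.asarray(x, dtype=np.float64), has_constant="add")
    cond = float(np.linalg.cond(exog))
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
            raise sm.tools.sm_exceptions.PerfectSeparationError("degenerate fit")
        return LogisticModelSummary(
            name=name,
            terms=["const", *terms],
            coef=np.asarray(fit.params),
            stderr=np.asarray(fit.bse),
            zvalues=np.asarray(fit.tvalues),
            pvalues=np.asarray(fit.pvalues),
            aic=float(fit.aic),
            bic=float(fit.bic),
            llr_pvalue=float(fit.llr_pvalue),
            pseudo_r2=float(fit.prsquared),
            cond_number=cond,
        )
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ):
        separation = True
    warnings.warn(f"{name}: perfect separation; reporting ridge-stabilized fit", stacklevel=2)
    beta, cov = _ridge_logit(y, exog, alpha=1.0)
    se = np.sqrt(np.diag(cov))
    zv = beta / se
    pv = 2.0 * sps.norm.sf(np.abs(zv))
    ll = _logit_loglike(beta, y, exog)
    ll0 = _logit_loglike(_ridge_logit(y, exog[:, :1], alpha=1.0)[0], y, exog[:, :1])
    k = exog.shape[1]
    llr = 2.0 * (ll - ll0)
    return LogisticModelSummary(
        name=name,
        terms=["const", *terms],
        coef=beta,
        stderr=se,
        zvalues=zv,
        pvalues=pv,
        aic=float(2 * k - 2 * ll),
        bic=float(k * math.log(len(y)) - 2 * ll),
        llr_pvalue=float(sps.chi2.sf(max(llr, 0.0), k - 1)) if k > 1 else 1.0,
        pseudo_r2=float(1.0 - ll / ll0) if ll0 != 0 else float("nan"),
        cond_number=cond,
        separation=separation,
    )


def _logit_loglike(beta: np.ndarray, y: np.ndarray, exog: np.ndarray) -> float:
    eta = exog @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _ridge_logit(y: np.ndarray, exog: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic fit; covariance from the penalized Hessian."""

    def neg(beta):
        return -_logit_loglike(beta, y, exog) + 0.5 * alpha * beta @ beta

    def grad(beta):
        mu = special.expit(exog @ beta)
        return -exog.T @ (y - mu) + alpha * beta

    res = optimize.minimize(neg, np.zeros(exog.shape[1]), jac=grad, method="BFGS")
    beta = res.x
    mu = special.expit(exog @ beta)
    hess = exog.T @ (exog * (mu * (1 - mu))[:, None]) + alpha * np.eye(exog.shape[1])
    return beta, np.linalg.inv(hess)


def fit_crowding_models(
    subjects: list[SubjectRecord],
    whole_tract_norm_fa: dict[str, float],
    crowding_threshold: float = 10.0,
) -> list[LogisticModelSummary]:
    """The three crowding models: one age covariate each, plus normalized FA
    and affected hemisphere.

    ``whole_tract_norm_fa`` maps subject_id to the whole-tract normalized
    scalar.  Continuous covariates are z-scored; affected hemisphere is
    coded 1 for a right-sided lesion (left contralesional hemisphere).
    Only patient records with complete covariates enter; at least 10 are
    required.
    """
    rows = []
    for rec in subjects:
        if rec.group != "patient" or rec.subject_id not in whole_tract_norm_fa:
            continue
        label = classify_crowding(rec, threshold=crowding_threshold)
        if label is None:
            continue
        fa = whole_tract_norm_fa[rec.subject_id]
        if not np.isfinite(fa):
            continue
        rows.append(
            {
                "crowding": float(label.crowding),
                "age_at_surgery": rec.age_at_surgery,
                "age_at_onset": rec.age_at_onset,
                "age_at_scan": rec.age_at_scan,
                "norm_fa": fa,
                "affected_right": 1.0 if rec.contralesional_hemisphere == "left" else 0.0,
            }
        )
    df = pd.DataFrame(rows).dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 fully labeled subjects, have {len(df)}")
    y = df["crowding"].to_numpy()
    fa = _zscore(df["norm_fa"].to_numpy())
    hemi = df["affected_right"].to_numpy()
    summaries = []
    for i, age_col in enumerate(("age_at_surgery", "age_at_onset", "age_at_scan"), start=1):
        age = _zscore(df[age_col].to_numpy())
        x = np.column_stack([age, fa, hemi])
        summaries.append(
            fit_logistic(y, x, terms=[age_col, "norm_fa", "affected_hemisphere"], name=f"model_{i}")
        )
    return summaries
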