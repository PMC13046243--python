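"""Parcel-wise developmental linear models and inference.

Per parcel, a central moment (mu1 or mu2) is regressed on developmental
covariates:

* cumulative maturation: ``moment ~ PMA + sex``
* pre/postnatal dissection: ``moment ~ GA + PNA + sex`` — because
  PMA = GA + PNA exactly, a spec containing all three is perfectly
  collinear and rejected;
* the birth-timing interaction: ``moment ~ GA + PNA + GA:PNA + sex``
  with GA and PNA mean-centred before forming the product.

The t statistic of the term of interest is extracted per parcel and the
family of parcel p-values is corrected with the Benjamini-Hochberg
step-up procedure (default alpha 0.025, i.e. two moments tested at an
overall 0.05).

Fits are ordinary least squares on the closed-form normal equations,
vectorized across parcels sharing one design matrix so that the
calibration and recovery simulations (hundreds of cohort replicates)
stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, CollinearityError, ContractError

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "bh_significant",
    "fit_ols",
    "parcelwise_effects",
    "interaction_effects",
    "compare_models",
    "depthwise_age_correlation",
]

_PREDICTORS = ("pma", "ga", "pna", "sex", "thickness", "ga_x_pna")

_COHORT_COLUMNS = {
    "pma": "pma_weeks",
    "ga": "ga_weeks",
    "pna": "pna_weeks",
    "sex": "sex",
    "thickness": "thickness_mm",
}


@dataclass(frozen=True)
class ModelSpec:
    """A parcel-wise regression model.

    ``predictors`` is an ordered subset of
    {pma, ga, pna, sex, thickness, ga_x_pna}; an intercept is always
    included implicitly.  ``term_of_interest`` selects which coefficient
    is mapped across parcels.
    """

    response: str
    predictors: tuple
    term_of_interest: str

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        unknown = set(self.predictors) - set(_PREDICTORS)
        if unknown:
            raise ContractError(f"unknown predictors: {sorted(unknown)}")
        if len(set(self.predictors)) != len(self.predictors):
            raise ContractError("duplicate predictors")
        if "pma" in self.predictors and {"ga", "pna"} <= set(self.predictors):
            raise CollinearityError(
                "PMA = GA + PNA exactly; a model may not contain all three",
                columns=["pma", "ga", "pna"],
            )
        if self.term_of_interest not in self.predictors:
            raise ContractError(
                f"term_of_interest {self.term_of_interest!r} not among predictors"
            )


@dataclass
class FitResult:
    """OLS fit summary; arrays are aligned with ``names``."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    k: int
    r2: float
    aic: float
    rss: float = field(default=np.nan)

    def term(self, name: str):
        """(coef, se, t, p) for one named term."""
        i = self.names.index(name)
        return self.coef[i], self.se[i], self.t[i], self.p[i]


def bh_significant(pvalues, alpha: float = 0.025):
    """Benjamini-Hochberg step-up decisions and adjusted p-values.

    Rejects the hypotheses with the ``k`` smallest p-values, where ``k``
    is the largest rank with ``p_(k) <= alpha * k / m``.  Returns
    (reject, q) with ``q >= p`` elementwise.
    """
    reject, q, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                    alpha=alpha, method="fdr_bh")
    return reject, q


def build_design(cohort: pd.DataFrame, predictors) -> tuple[np.ndarray, list]:
    """Design matrix (intercept first) for the given predictor names.

    ``ga_x_pna`` is the product of mean-centred GA and PNA, so its
    coefficient is invariant to shifting either age by a constant.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for pred in predictors:
        if pred == "ga_x_pna":
            ga = cohort["ga_weeks"].to_numpy(dtype=float)
            pna = cohort["pna_weeks"].to_numpy(dtype=float)
            cols.append((ga - ga.mean()) * (pna - pna.mean()))
        else:
            col = _COHORT_COLUMNS[pred]
            if col not in cohort.columns:
                raise ContractError(f"cohort table lacks column {col!r}")
            vals = cohort[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ContractError(f"non-finite values in cohort column {col!r}")
            cols.append(vals)
        names.append(pred)
    return np.column_stack(cols), names


def _check_rank(design: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify dependent columns via the QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise CollinearityError(
            f"design matrix rank deficient (rank {rank} < {design.shape[1]}); "
            f"offending columns: {bad}",
            columns=bad,
        )


def fit_ols(design: np.ndarray, response: np.ndarray, names=None) -> FitResult:
    """Ordinary least squares with t-based inference.

    ``design`` must include its intercept column.  Standard errors use
    the unbiased residual variance with n - k degrees of freedom; p is
    two-sided from the t distribution.  AIC follows the Gaussian
    log-likelihood convention (sigma^2 profiled out, 2k penalty).
    """
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(response, dtype=np.float64)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k:
        raise ContractError(f"need n > k (n={n}, k={k})")
    _check_rank(X, names)

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, float(y @ y), 1.0)
    if rss < 1e-24 * scale:  # numerically perfect fit
        rss = 0.0
    dof = n - k
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    coef_tol = 1e-10 * np.sqrt(scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            se > 0, coef / se,
            np.where(np.abs(coef) <= coef_tol, 0.0, np.sign(coef) * np.inf),
        )
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    with np.errstate(divide="ignore"):  # perfect fit: llf diverges, aic -inf
        llf = -0.5 * n * (np.log(2.0 * np.pi) + np.log(rss / n) + 1.0)
    aic = 2.0 * k - 2.0 * llf
    return FitResult(
        names=list(names), coef=coef, se=se, t=t, p=p,
        n=n, k=k, r2=r2, aic=aic, rss=rss,
    )


def _fit_many(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many responses (columns of Y) on one design.

    Returns (coef, se, t, p), each of shape (k, m).
    """
    n, k = X.shape
    dof = n - k
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss = np.einsum("nm,nm->m", resid, resid)
    sigma2 = rss / dof
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, t, p


def _align_moments(moments, cohort):
    """Moments as (parcels x subjects) DataFrame aligned to cohort order."""
    if isinstance(moments, pd.DataFrame):
        subj = cohort["subject_id"].astype(str)
        cols = moments.columns.astype(str)
        if set(cols) != set(subj):
            raise AlignmentError(
                "subject ids of the moment table and cohort table differ"
            )
        return moments.loc[:, subj].to_numpy(dtype=float), moments.index.to_numpy()
    arr = np.asarray(moments, dtype=float)
    if arr.shape[1] != len(cohort):
        raise AlignmentError(
            f"moment matrix has {arr.shape[1]} subjects, cohort {len(cohort)}"
        )
    return arr, np.arange(arr.shape[0])


def parcelwise_effects(
    moments, cohort: pd.DataFrame, spec: ModelSpec, alpha: float = 0.025
) -> pd.DataFrame:
    """Fit the model in every parcel and FDR-correct the term of interest.

    Parameters
    ----------
    moments : (parcels x subjects) array or DataFrame
        One moment value per parcel and subject.  A DataFrame must carry
        subject ids as columns (matched to ``cohort.subject_id``) and
        parcel ids as index.
    cohort : CohortTable DataFrame
    spec : ModelSpec
    alpha : BH-FDR level (default 0.025).

    Returns
    -------
    DataFrame indexed by parcel id with columns
    ``term, coef, se, t, p, q, significant``.
    """
    Y, parcel_ids = _align_moments(moments, cohort)
    X, names = build_design(cohort, spec.predictors)
    _check_rank(X, names)
    coef, se, t, p = _fit_many(X, Y.T)
    i = names.index(spec.term_of_interest)
    reject, q = bh_significant(p[i], alpha=alpha)
    out = pd.DataFrame(
        {
            "term": spec.term_of_interest,
            "coef": coef[i],
            "se": se[i],
            "t": t[i],
            "p": p[i],
            "q": q,
            "significant": reject,
        },
        index=pd.Index(parcel_ids, name="parcel_id"),
    )
    return out


def interaction_effects(
    moments, cohort: pd.DataFrame, alpha: float = 0.025, response: str = "mu1"
) -> pd.DataFrame:
    """Parcel-wise map for the GA x PNA product term.

    GA and PNA are mean-centred before the product is formed, so the
    interaction t value is unchanged by shifting either age axis.
    """
    spec = ModelSpec(
        response=response,
        predictors=("ga", "pna", "ga_x_pna", "sex"),
        term_of_interest="ga_x_pna",
    )
    return parcelwise_effects(moments, cohort, spec, alpha=alpha)


def compare_models(
    global_moments: np.ndarray, cohort: pd.DataFrame, candidate_specs
):
    """Compare candidate covariate sets for the global (parcel-mean) moment.

    Returns
    -------
    fits : DataFrame
        One row per candidate (model, k, r2, adj_r2, aic), ranked by AIC.
    ftests : DataFrame
        Nested F-tests for every strictly nested candidate pair.
    """
    if len(candidate_specs) < 2:
        raise ContractError("need at least two candidate models")
    y = np.asarray(global_moments, dtype=float)
    fits = []
    results = []
    for spec in candidate_specs:
        preds = tuple(spec.predictors) if isinstance(spec, ModelSpec) else tuple(spec)
        X, names = build_design(cohort, preds)
        res = fit_ols(X, y, names)
        adj = 1.0 - (1.0 - res.r2) * (res.n - 1) / (res.n - res.k)
        fits.append(
            {
                "model": "+".join(preds) if preds else "intercept",
                "k": res.k,
                "r2": res.r2,
                "adj_r2": adj,
                "aic": res.aic,
            }
        )
        results.append((preds, res))
    fit_table = pd.DataFrame(fits).sort_values("aic").reset_index(drop=True)

    ftests = []
    for i, (pi, ri) in enumerate(results):
        for j, (pj, rj) in enumerate(results):
            if i == j or not (set(pi) < set(pj)):
                continue
            df1 = rj.k - ri.k
            df2 = rj.n - rj.k
            f = ((ri.rss - rj.rss) / df1) / (rj.rss / df2)
            pval = stats.f.sf(f, df1, df2)
            ftests.append(
                {
                    "restricted": "+".join(pi) if pi else "intercept",
                    "full": "+".join(pj),
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": pval,
                }
            )
    return fit_table, pd.DataFrame(ftests)


def depthwise_age_correlation(profiles: np.ndarray, age: np.ndarray):
    """Pearson correlation of intensity with age at each depth.

    Returns (r, p), each of length n_depths; depths with zero intensity
    variance get NaN rather than raising.
    """
    profiles = np.asarray(profiles, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(profiles) < 3:
        raise ContractError("need at least 3 subjects")
    n_depths = profiles.shape[1]
    r = np.full(n_depths, np.nan)
    p = np.full(n_depths, np.nan)
    for d in range(n_depths):
        col = profiles[:, d]
        if np.std(col) == 0 or np.std(age) == 0:
            continue
        r[d], p[d] = stats.pearsonr(col, age)
    return r, p
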