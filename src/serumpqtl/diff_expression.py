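"""Per-probe aging/sex differential expression with empirical permutation FDR.

For cohorts with one serum sample per subject (UC, NC) each probe's log2
intensity is regressed by ordinary least squares on age, sex and array
plate; for the CD cohort, which contributes baseline and week-22 visits
per subject, a random-intercept mixed model adds a time-point fixed
effect and a per-subject random intercept and is fitted by maximum
likelihood.  Significance of the tested coefficient is a two-sided Wald
test (t reference with residual degrees of freedom for OLS, standard
normal for the ML mixed model).

The false-discovery rate is estimated empirically: the exposure (age or
sex) is permuted across subjects N times (default 1000) — both visits of
a subject receive the subject's permuted value — the scan is re-run on
each permuted dataset, and for each observed p-value threshold t

    FDR(t) = min(1, avg over iterations of #(permuted p <= t)
                    / #(observed p <= t)).

The literal FDR(t) is not monotone in t; a monotonized q-value (running
minimum over decreasing t) is reported alongside it.

An aging signature is the set of gene symbols whose probes pass a nominal
p cutoff with the requested direction of association; heterogeneity of a
probe's effect across cohorts is assessed with Cochran's Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import AssocResult, GeneSet, ProteinMatrix, SampleTable, logger
from .lmm import fit_random_intercept

DEFAULT_N_PERMUTATIONS = 1000

_TERM_COLUMN = {"age": "Age", "sex": "SexM"}


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def build_design(
    samples: SampleTable,
    include_plate: bool = True,
    include_time: bool = False,
    age: np.ndarray | None = None,
    sex_m: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate matrix: intercept, Age, SexM, plate indicators, TimePoint.

    Plate indicators use the first (lexicographic) plate as reference;
    indicator columns constant in this sample subset are dropped.  A
    rank-deficient matrix after that pruning is a hard error.  ``age`` /
    ``sex_m`` override the table's columns (used by permutation scans).
    """
    df = samples.df
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["Age"] = df["age"].to_numpy() if age is None else np.asarray(age, dtype=float)
    X["SexM"] = (
        (df["sex"] == "M").to_numpy(dtype=float) if sex_m is None
        else np.asarray(sex_m, dtype=float)
    )
    if include_plate:
        plates = sorted(df["plate_id"].unique())
        for p in plates[1:]:
            col = (df["plate_id"] == p).to_numpy(dtype=float)
            X[f"Plate[{p}]"] = col
    if include_time:
        X["TimePoint"] = (df["time_point"] == "week22").to_numpy(dtype=float)
    keep = ["Intercept"] + [c for c in X.columns if c != "Intercept" and X[c].nunique() > 1]
    X = X[keep]
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(f"collinear design matrix (columns {list(X.columns)})")
    return X


def _resolve_term(term: str) -> str:
    key = term.lower()
    if key in _TERM_COLUMN:
        return _TERM_COLUMN[key]
    return term


# ---------------------------------------------------------------------------
# Single-probe fits
# ---------------------------------------------------------------------------


def fit_probe_ols(y: np.ndarray, samples: SampleTable, term: str = "Age") -> AssocResult:
    """OLS fit of one probe: y ~ Age + Sex + PlateID; Wald t test on ``term``.

    Requires one sample per subject (no repeated measures).
    """
    df = samples.df
    if df["subject_id"].duplicated().any():
        raise ValueError("fit_probe_ols requires one sample per subject; use fit_probe_mixed")
    X = build_design(samples, include_plate=True, include_time=False)
    if len(df) < X.shape[1] + 2:
        raise ValueError(f"too few observations ({len(df)}) for {X.shape[1]} covariates")
    col = _resolve_term(term)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return AssocResult(
        unit_id=None, term=term,
        estimate=float(res.params[col]), se=float(res.bse[col]),
        wald=float(res.tvalues[col]), p=float(res.pvalues[col]),
        n_obs=int(res.nobs),
    )


def fit_probe_mixed(y: np.ndarray, samples: SampleTable, term: str = "Age") -> AssocResult:
    """Random-intercept ML fit: y ~ Age + Sex + PlateID + TimePoint + (1|Subject).

    Wald test on ``term`` against a standard-normal reference (ML
    asymptotics).  Non-convergence yields a flagged result with p absent.
    """
    X = build_design(samples, include_plate=True, include_time=True)
    col = _resolve_term(term)
    fit = fit_random_intercept(
        np.asarray(y, dtype=float), X.to_numpy(),
        samples.df["subject_id"].to_numpy(), names=list(X.columns),
    )
    if not fit.converged:
        return AssocResult(None, term, np.nan, np.nan, np.nan, np.nan,
                           n_obs=len(samples.df), flag="non-convergence")
    c = fit.coef(col)
    return AssocResult(unit_id=None, term=term, n_obs=fit.n_obs, **c)


# ---------------------------------------------------------------------------
# Vectorized scans (all probes at once)
# ---------------------------------------------------------------------------


def _ols_scan(Y: np.ndarray, X: np.ndarray, col: int):
    """OLS over every column of Y against a shared design; t-based p."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)                      # (k, n_probes)
    resid = Y - X @ B
    dof = n - k
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(XtX_inv[col, col] * s2)
    est = B[col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    return est, se, tval, p


def _mixed_scan(Y: np.ndarray, X: np.ndarray, groups: np.ndarray, col: int, names: list):
    est = np.empty(Y.shape[1])
    se = np.empty(Y.shape[1])
    wald = np.empty(Y.shape[1])
    p = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        fit = fit_random_intercept(Y[:, j], X, groups, names=names)
        est[j], se[j] = fit.beta[col] if fit.converged else np.nan, fit.se[col] if fit.converged else np.nan
        wald[j] = fit.wald[col] if fit.converged else np.nan
        p[j] = fit.p[col] if fit.converged else np.nan
    return est, se, wald, p


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------


@dataclass
class PermutationStore:
    """Observed and permuted per-probe p-values for empirical FDR."""

    observed_p: pd.Series
    permuted_p: np.ndarray  # (n_iterations, n_probes)
    permuted_variable: str

    def __post_init__(self) -> None:
        obs = self.observed_p.to_numpy(dtype=float)
        if ((obs <= 0) | (obs > 1)).any():
            raise ValueError("observed p-values must be in (0, 1]")
        perm = np.asarray(self.permuted_p, dtype=float)
        if perm.ndim != 2 or perm.shape[1] != len(obs):
            raise ValueError("permuted_p must be (n_iterations, n_probes)")
        if ((perm <= 0) | (perm > 1)).any():
            raise ValueError("permuted p-values must be in (0, 1]")
        self.permuted_p = perm

    @property
    def n_iterations(self) -> int:
        return self.permuted_p.shape[0]


def empirical_fdr_counts(observed_p: np.ndarray, permuted_p: np.ndarray) -> np.ndarray:
    """FDR(t) = min(1, avg #(permuted <= t) / #(observed <= t)) at each
    observed p as threshold t; counting is over all units pooled."""
    obs = np.asarray(observed_p, dtype=float)
    perm = np.asarray(permuted_p, dtype=float)
    n_iter = perm.shape[0]
    perm_sorted = np.sort(perm.ravel())
    obs_sorted = np.sort(obs)
    null_count = np.searchsorted(perm_sorted, obs, side="right") / n_iter
    obs_count = np.searchsorted(obs_sorted, obs, side="right")
    return np.minimum(1.0, null_count / obs_count)


def monotonize(observed_p: np.ndarray, fdr: np.ndarray) -> np.ndarray:
    """q(t) = min over thresholds t' >= t of FDR(t'): running minimum over
    decreasing t, so q is non-decreasing in p."""
    order = np.argsort(observed_p)[::-1]  # decreasing t
    q = np.empty_like(np.asarray(fdr, dtype=float))
    q[order] = np.minimum.accumulate(np.asarray(fdr, dtype=float)[order])
    return q


def permutation_fdr(store: PermutationStore) -> pd.DataFrame:
    """Per-probe literal FDR and monotonized q-value."""
    obs = store.observed_p.to_numpy(dtype=float)
    fdr = empirical_fdr_counts(obs, store.permuted_p)
    q = monotonize(obs, fdr)
    return pd.DataFrame(
        {"fdr_literal": fdr, "q_monotone": q}, index=store.observed_p.index
    )


def permute_exposure(samples: SampleTable, term: str, rng: np.random.Generator) -> np.ndarray:
    """Permute the exposure across subjects; every sample of a subject
    receives its subject's permuted value.  Returns the per-sample vector."""
    df = samples.df
    col = "age" if term.lower() == "age" else "sex"
    subj_vals = df.drop_duplicates("subject_id").set_index("subject_id")[col]
    permuted = pd.Series(
        subj_vals.to_numpy()[rng.permutation(len(subj_vals))], index=subj_vals.index
    )
    vals = permuted.reindex(df["subject_id"]).to_numpy()
    if col == "sex":
        return (vals == "M").astype(float)
    return vals.astype(float)


# ---------------------------------------------------------------------------
# Full per-cohort scan
# ---------------------------------------------------------------------------


def diffexpr_scan(
    proteins: ProteinMatrix,
    samples: SampleTable,
    cohort: str,
    term: str = "Age",
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe association scan within one cohort, with permutation FDR.

    OLS for single-visit cohorts (UC, NC); random-intercept ML mixed model
    (with a TimePoint fixed effect) whenever repeated measures are present
    (CD).  Returns one row per probe: gene, estimate, se, wald, p,
    fdr_literal, q_monotone, n_obs.
    """
    sub = samples.subset(cohort)
    Y_df = proteins.values.loc[sub.df["sample_id"]]
    Y = Y_df.to_numpy()
    repeated = sub.df["subject_id"].duplicated().any()
    col_name = _resolve_term(term)
    groups = sub.df["subject_id"].to_numpy()

    def scan(age=None, sex_m=None):
        X = build_design(sub, include_plate=True, include_time=repeated,
                         age=age, sex_m=sex_m)
        if col_name not in X.columns:
            raise ValueError(f"term {term!r} not identifiable in this cohort design")
        c = list(X.columns).index(col_name)
        if repeated:
            return _mixed_scan(Y, X.to_numpy(), groups, c, list(X.columns))
        return _ols_scan(Y, X.to_numpy(), c)

    est, se, wald, p = scan()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    perm_p = np.empty((n_perm, Y.shape[1]))
    for it in range(n_perm):
        vec = permute_exposure(sub, term, rng)
        if term.lower() == "age":
            perm_p[it] = scan(age=vec)[3]
        else:
            perm_p[it] = scan(sex_m=vec)[3]

    out = pd.DataFrame(
        {
            "probe_id": proteins.probe_ids,
            "gene": proteins.probes["gene"].to_numpy(),
            "estimate": est, "se": se, "wald": wald, "p": p,
            "n_obs": len(sub.df),
        }
    )
    ok = np.isfinite(p)
    if not ok.all():
        logger.warning("%d probes failed to converge; excluded from FDR", (~ok).sum())
    fdr = np.full(len(out), np.nan)
    q = np.full(len(out), np.nan)
    if n_perm > 0 and ok.any():
        fdr[ok] = empirical_fdr_counts(p[ok], perm_p[:, ok])
        q[ok] = monotonize(p[ok], fdr[ok])
    out["fdr_literal"] = fdr
    out["q_monotone"] = q
    return out


# ---------------------------------------------------------------------------
# Signature extraction and heterogeneity
# ---------------------------------------------------------------------------


def extract_signature(
    results: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "positive",
    label: str = "signature",
) -> GeneSet:
    """Gene symbols of probes with nominal p <= alpha and the requested
    direction of the estimate; multiple probes per gene collapse."""
    if len(results) == 0:
        raise ValueError("empty results table")
    if direction not in ("positive", "negative", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    mask = results["p"] <= alpha
    if direction == "positive":
        mask &= results["estimate"] > 0
    elif direction == "negative":
        mask &= results["estimate"] < 0
    return GeneSet.from_symbols(label, results.loc[mask, "gene"])


def cochran_q(estimates, ses) -> tuple[float, float]:
    """Cochran's Q heterogeneity test across independent effect estimates.

    Inverse-variance weights w_i = 1/se_i^2; Q = sum w_i (b_i - b_w)^2 with
    b_w the weighted mean; p from chi-square with k-1 degrees of freedom.
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("Cochran's Q needs at least two estimates")
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    bw = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - bw) ** 2))
    p = float(stats.chi2.sf(q, df=len(b) - 1))
    return q, p
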