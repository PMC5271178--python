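"""Cis proteomic-QTL mapping with repeated measures and a permuted-genotype null.

Each protein trait is inverse-normal transformed (rank-based Blom scores)
and regressed, pair by (probe, variant) pair, on the variant's imputed
effective-allele dosage plus age, sex and time point with a per-subject
random intercept, fitted by maximum likelihood:

    INT(y) ~ EffectiveAlleleCopyNumber + Age + Sex + TimePoint + (1|Subject)

Candidate pairs are all variants within a configurable cis window
(default +/- 1 Mb) of the probe's gene anchor.  The empirical null is
obtained by permuting genotype subject identifiers — each subject's whole
dosage vector moves as a unit, so both visits of a subject keep sharing
one (permuted) genotype and per-variant allele frequencies are conserved
— and re-running the scan; FDR uses the same pooled counting estimator as
the differential-expression stage, with thresholds at the observed
p-values.  A conditional scan re-tests a region's variants with a chosen
variant's dosage added as a fixed covariate, asking whether one signal
explains another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, ProteinMatrix, SampleTable, logger
from .diff_expression import empirical_fdr_counts, monotonize
from .lmm import fit_random_intercept

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_N_PERMUTATIONS = 10


def inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Maps value of rank r (average ranks on ties) among n to
    ``Phi^-1((r - 3/8) / (n + 1/4))``; output is mean-zero and symmetric
    for tie-free input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("inverse_normal needs a 1-d vector of length >= 3")
    if not np.isfinite(x).all():
        raise ValueError("inverse_normal requires finite values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks carry no information")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (len(x) + 0.25))


def enumerate_cis_pairs(
    probes: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    """All (probe, variant) pairs on the same chromosome with
    |variant_pos - gene_anchor| <= window (closed interval).

    ``probes`` is a probe-annotation frame indexed by probe_id with chrom /
    pos anchor columns; probes lacking an anchor are skipped with a logged
    warning.  Returns columns probe_id, variant_id, distance (signed,
    variant minus anchor).
    """
    if window <= 0:
        raise ValueError("cis window must be positive")
    unanchored = probes.index[probes["pos"].isna() | probes["chrom"].isna()]
    if len(unanchored):
        logger.warning("skipping %d probes without genomic anchor: %s",
                       len(unanchored), list(unanchored[:5]))
    anchored = probes.dropna(subset=["chrom", "pos"])
    rows = []
    vby = {c: g for c, g in variants.groupby("chrom")}
    for probe_id, prow in anchored.iterrows():
        cand = vby.get(str(prow["chrom"]))
        if cand is None:
            continue
        dist = cand["pos"].to_numpy(dtype=np.int64) - int(prow["pos"])
        keep = np.abs(dist) <= window
        for vid, d in zip(cand.index[keep], dist[keep]):
            rows.append((probe_id, vid, int(d)))
    return pd.DataFrame(rows, columns=["probe_id", "variant_id", "distance"])


def _base_design(samples: SampleTable) -> tuple[np.ndarray, list, np.ndarray]:
    """Covariates shared by every pair: intercept, Age, SexM, TimePoint.

    TimePoint is always part of the model; if it is constant in this
    sample set (single-visit data) the column is dropped by rank rules
    with a log message.
    """
    df = samples.df
    cols = {"Intercept": np.ones(len(df)),
            "Age": df["age"].to_numpy(dtype=float),
            "SexM": (df["sex"] == "M").to_numpy(dtype=float),
            "TimePoint": (df["time_point"] == "week22").to_numpy(dtype=float)}
    for name in ("Age", "SexM", "TimePoint"):
        if len(np.unique(cols[name])) < 2:
            logger.info("covariate %s constant in this sample set; dropped", name)
            del cols[name]
    X = np.column_stack(list(cols.values()))
    groups = df["subject_id"].to_numpy()
    return X, list(cols.keys()), groups


def scan_pqtl(
    pairs: pd.DataFrame,
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    apply_inverse_normal: bool = True,
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Mixed-model association for every cis pair.

    Returns one row per pair with estimate (per effective-allele copy, in
    inverse-normal trait units), se, wald, p, n_obs and a ``flag`` column
    (monomorphic / collinear / non-convergence; flagged rows carry no p).
    """
    df = samples.df
    missing = set(df["subject_id"]) - set(genotypes.dosages.index)
    if missing:
        raise ValueError(f"subjects without genotypes: {sorted(missing)[:5]}")
    X0, names0, groups = _base_design(samples)
    if extra_covariates:
        extras = np.column_stack([np.asarray(v, dtype=float) for v in extra_covariates.values()])
        X0 = np.hstack([X0, extras])
        names0 = names0 + list(extra_covariates.keys())
    names = names0 + ["EffectiveAlleleCopyNumber"]
    g_col = len(names0)

    dosage_by_subject = genotypes.dosages.reindex(df["subject_id"])
    records = []
    for probe_id, grp in pairs.groupby("probe_id", sort=False):
        y = proteins.values.loc[df["sample_id"], probe_id].to_numpy(dtype=float)
        if apply_inverse_normal:
            y = inverse_normal(y)
        for _, pair in grp.iterrows():
            vid = pair["variant_id"]
            g = dosage_by_subject[vid].to_numpy(dtype=float)
            rec = {"probe_id": probe_id, "variant_id": vid,
                   "distance": pair.get("distance", np.nan),
                   "estimate": np.nan, "se": np.nan, "wald": np.nan,
                   "p": np.nan, "n_obs": len(df), "flag": ""}
            if np.ptp(g) == 0:
                rec["flag"] = "monomorphic"
                records.append(rec)
                continue
            X = np.column_stack([X0, g])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                rec["flag"] = "collinear"
                records.append(rec)
                continue
            fit = fit_random_intercept(y, X, groups, names=names)
            if not fit.converged:
                rec["flag"] = "non-convergence"
            else:
                rec.update(estimate=float(fit.beta[g_col]), se=float(fit.se[g_col]),
                           wald=float(fit.wald[g_col]), p=float(fit.p[g_col]))
            records.append(rec)
    return pd.DataFrame(records,
                        columns=["probe_id", "variant_id", "distance", "estimate",
                                 "se", "wald", "p", "n_obs", "flag"])


def permute_genotype_subjects(genotypes: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Permute genotype subject identifiers: one random permutation
    reassigns whole dosage rows, conserving each variant's dosage multiset."""
    n = len(genotypes.dosages)
    if n < 2:
        raise ValueError("need at least two subjects to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    permuted = pd.DataFrame(
        genotypes.dosages.to_numpy()[perm],
        index=genotypes.dosages.index,
        columns=genotypes.dosages.columns,
    )
    return GenotypeMatrix(permuted, genotypes.variants.copy())


def empirical_fdr_scan(observed: pd.DataFrame, permuted_runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Pooled empirical FDR over all cis pairs, thresholds at observed p's.

    Permuted runs must test exactly the observed pair list.  Returns the
    observed table with fdr_literal / q_monotone columns added (flagged
    pairs get NaN).
    """
    key = observed[["probe_id", "variant_id"]]
    for run in permuted_runs:
        if len(run) != len(observed) or not key.equals(run[["probe_id", "variant_id"]].set_axis(key.index)):
            raise ValueError("permuted run tests a different pair list")
    ok = observed["p"].notna().to_numpy()
    obs_p = observed["p"].to_numpy(dtype=float)[ok]
    perm_p = np.vstack([run["p"].to_numpy(dtype=float)[ok] for run in permuted_runs])
    if np.isnan(perm_p).any():
        # a pair may be degenerate only under permutation; drop those columns
        # from the null pool but keep thresholds
        perm_p = np.where(np.isnan(perm_p), np.inf, perm_p)
    fdr = empirical_fdr_counts(obs_p, perm_p)
    q = monotonize(obs_p, fdr)
    out = observed.copy()
    out["fdr_literal"] = np.nan
    out["q_monotone"] = np.nan
    out.loc[ok, "fdr_literal"] = fdr
    out.loc[ok, "q_monotone"] = q
    return out


def run_pqtl_scan(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    window: int = DEFAULT_CIS_WINDOW,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cis scan: enumerate pairs, fit, permuted-genotype empirical FDR."""
    pairs = enumerate_cis_pairs(proteins.probes, genotypes.variants, window)
    if len(pairs) == 0:
        raise ValueError("no cis pairs within the window")
    observed = scan_pqtl(pairs, proteins, genotypes, samples)
    seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31)
    runs = [
        scan_pqtl(pairs, proteins, permute_genotype_subjects(genotypes, int(s)), samples)
        for s in seeds
    ]
    if n_perm == 0:
        observed = observed.assign(fdr_literal=np.nan, q_monotone=np.nan)
        return observed
    return empirical_fdr_scan(observed, runs)


def lead_snp(result: pd.DataFrame) -> pd.DataFrame:
    """Per-probe lead variant: minimum p, ties broken by smaller
    |distance| then lexicographic variant_id.  Probes whose every pair is
    flagged are dropped with a warning."""
    ok = result[result["p"].notna()].copy()
    dropped = set(result["probe_id"]) - set(ok["probe_id"])
    if dropped:
        logger.warning("probes with no testable pair: %s", sorted(dropped))
    if len(ok) == 0:
        raise ValueError("no probe has a non-flagged pair")
    ok["_absd"] = ok["distance"].abs()
    ok = ok.sort_values(["probe_id", "p", "_absd", "variant_id"], kind="mergesort")
    lead = ok.groupby("probe_id", sort=False).head(1).drop(columns="_absd")
    return lead.reset_index(drop=True)


def conditional_scan(
    probe_id: str,
    region: tuple[str, int, int],
    conditioning_variant: str,
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    samples: SampleTable,
) -> pd.DataFrame:
    """Re-test a region's variants for one probe, conditioning on a variant.

    All variants in ``region = (chrom, start, end)`` are tested regardless
    of the cis window; the conditioning variant's dosage enters as a fixed
    covariate and the variant itself is excluded from testing.  Variants
    perfectly collinear with the conditioning dosage are flagged.
    """
    chrom, start, end = region
    if conditioning_variant not in genotypes.variant_ids:
        raise ValueError(f"conditioning variant {conditioning_variant!r} not genotyped")
    v = genotypes.variants
    in_region = v[(v["chrom"].astype(str) == str(chrom)) & (v["pos"] >= start) & (v["pos"] <= end)]
    tested = [vid for vid in in_region.index if vid != conditioning_variant]
    if not tested:
        raise ValueError("no variants to test in the region")
    pairs = pd.DataFrame({"probe_id": probe_id, "variant_id": tested,
                          "distance": np.nan})
    cond = genotypes.dosages[conditioning_variant].reindex(samples.df["subject_id"]).to_numpy()
    return scan_pqtl(pairs, proteins, genotypes, samples,
                     extra_covariates={"Conditioned[" + conditioning_variant + "]": cond})
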