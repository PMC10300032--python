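"""Association models for heteroplasmy-QTL, disease association and cis-eQTL.

All model fitting is implemented here directly: logistic regression by
iteratively reweighted least squares with Wald z-tests, ordinary least
squares with t-tests, Benjamini-Hochberg step-up FDR, a Wigginton-style
exact Hardy-Weinberg test for QC, and an exact binomial tail for the
eQTL replication-enrichment test.

Conventions shared by the fitting routines:

* binary outcomes are modelled on the logit scale, so hetQTL effect
  estimates are per-allele log-odds increments;
* categorical covariates are one-hot encoded dropping a reference level;
* samples with any missing value in the model frame are dropped
  (complete-case analysis);
* perfect separation is detected by coefficient divergence during IRLS
  (|coef| > 15 on the logit scale) and flagged rather than reported as a
  finite estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heteroplasmy import HetPresenceMatrix
from .mt_io import CovariateTable, ExpressionMatrix, GenotypeTable

SEPARATION_COEF_BOUND = 15.0

OK = "ok"
DEGENERATE = "degenerate"
SEPARATED = "separated"
NOT_CONVERGED = "not_converged"
SKIPPED = "skipped"


@dataclass
class AssociationResult:
    predictor_id: str
    outcome_id: str
    estimate: float
    se: float
    p: float
    q: float = float("nan")
    flag: str = OK
    n: int = 0

    @property
    def significant(self) -> bool:
        return self.flag == OK and self.q < 0.05


@dataclass
class GlmFit:
    """Per-column coefficients of one generalized linear model fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    flag: str
    n: int
    n_iter: int = 0

    def term(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i]), float(self.p[i])


# ---------------------------------------------------------------------------
# core fitters
# ---------------------------------------------------------------------------


def fit_glm_binomial(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> GlmFit:
    """Maximum-likelihood logistic regression via IRLS with Wald z-tests.

    ``X`` must include an intercept column if one is wanted.  Constant
    non-intercept columns make the design rank deficient and raise; a
    constant outcome or separated fit is returned flagged rather than
    raising, because genome-wide scans must tolerate degenerate sites.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and X are misaligned")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    nan_fit = GlmFit(names, np.full(k, np.nan), np.full(k, np.nan),
                     np.full(k, np.nan), DEGENERATE, n)
    if y.min() == y.max():
        return nan_fit
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns for the caller
        bad = _collinear_columns(X, names)
        raise np.linalg.LinAlgError(f"design matrix is rank deficient: {bad}")

    beta = np.zeros(k)
    flag = NOT_CONVERGED
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.abs(beta_new).max() > SEPARATION_COEF_BOUND:
            beta = beta_new
            flag = SEPARATED
            break
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            flag = OK
            break
        beta = beta_new
    if flag == SEPARATED:
        coef = np.where(np.abs(beta) > SEPARATION_COEF_BOUND,
                        np.sign(beta) * np.inf, beta)
        return GlmFit(names, coef, np.full(k, np.nan), np.full(k, np.nan),
                      SEPARATED, n, it)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    return GlmFit(names, beta, se, p, flag, n, it)


def fit_ols(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> GlmFit:
    """Ordinary least squares with classical t-tests on each coefficient."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"n={n} samples cannot identify {k} parameters")
    if y.min() == y.max():
        return GlmFit(names, np.full(k, np.nan), np.full(k, np.nan),
                      np.full(k, np.nan), DEGENERATE, n)
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        bad = _collinear_columns(X, names)
        raise np.linalg.LinAlgError(f"design matrix is rank deficient: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return GlmFit(names, beta, se, p, OK, n)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedily identify columns that add no rank."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; NaN inputs are
    passed through and excluded from m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


def apply_bh(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach BH q-values in place, over results with a defined p only."""
    p = np.array([r.p if r.flag == OK else np.nan for r in results])
    q = bh_fdr(p)
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("diagnosis", "study", "sex", "age_death", "education", "pmi")


def build_design(
    cov: pd.DataFrame,
    columns: list[str],
    n_pcs: int = 10,
    drop_constant: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """One-hot encode categoricals (dropping a reference level) and append
    ancestry PCs; returns the numeric design block and its column names."""
    blocks = []
    for c in columns:
        if c not in cov.columns:
            continue
        s = cov[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(s.astype(float).to_frame(c))
    pc_cols = [c for c in cov.columns if c.startswith("pc") and c[2:].isdigit()]
    pc_cols = sorted(pc_cols, key=lambda c: int(c[2:]))[:n_pcs]
    if pc_cols:
        blocks.append(cov[pc_cols].astype(float))
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=cov.index)
    if drop_constant:
        keep = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
        X = X[keep]
    return X, list(X.columns)


def _aligned_samples(*tables: list[str]) -> list[str]:
    common = set(tables[0])
    for t in tables[1:]:
        common &= set(t)
    if not common:
        raise ValueError("no samples shared across tables")
    return [s for s in tables[0] if s in common]


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def het_qtl(
    presence: HetPresenceMatrix,
    geno: GenotypeTable,
    cov: CovariateTable,
    maf_min: float = 0.05,
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES,
    n_pcs: int = 10,
) -> list[AssociationResult]:
    """Heteroplasmy-QTL scan: logistic presence ~ genotype + covariates.

    One result per (variant, site) pair over variants with MAF >= maf_min;
    BH-FDR is applied jointly across all pairs.
    """
    samples = _aligned_samples(presence.samples, geno.samples, cov.samples)
    if len(samples) < len(presence.samples):
        missing = sorted(set(presence.samples) - set(samples))
        raise ValueError(f"samples missing from genotype/covariate tables: {missing}")
    geno_idx = [geno.samples.index(s) for s in samples]
    maf = geno.maf()
    keep_variants = [j for j in range(len(geno.variants)) if maf[j] >= maf_min]

    cov_df = cov.data.loc[samples]
    Xc, cov_names = build_design(cov_df, list(covariate_columns), n_pcs=n_pcs)
    pres = presence.presence.loc[samples]

    results: list[AssociationResult] = []
    for j in keep_variants:
        vid = geno.variant_ids[j]
        g = geno.calls[geno_idx, j]
        for site in presence.sites:
            y = pres[site].to_numpy(dtype=float)
            frame = pd.DataFrame({"genotype": g}, index=samples).join(Xc)
            frame["__y"] = y
            frame = frame.dropna()
            names = ["intercept", "genotype"] + [c for c in frame.columns if c not in ("genotype", "__y")]
            X = np.column_stack(
                [np.ones(len(frame)), frame["genotype"].to_numpy()]
                + [frame[c].to_numpy(dtype=float) for c in names[2:]]
            )
            fit = fit_glm_binomial(frame["__y"].to_numpy(), X, names)
            if fit.flag == OK:
                est, se, p = fit.term("genotype")
            else:
                est, se, p = float("nan"), float("nan"), float("nan")
            results.append(
                AssociationResult(vid, str(site), est, se, p, flag=fit.flag, n=fit.n)
            )
    return apply_bh(results)


def ad_association(
    presence: HetPresenceMatrix,
    cov: CovariateTable,
    covariate_columns: tuple[str, ...] = ("study", "sex", "age_death", "education", "pmi"),
    n_pcs: int = 10,
) -> tuple[list[AssociationResult], AssociationResult]:
    """Association of AD diagnosis with heteroplasmy.

    Returns per-site logistic results (presence ~ diagnosis + covariates,
    BH-FDR across sites) and a single linear model of the per-sample
    heteroplasmic-site count on diagnosis.
    """
    samples = _aligned_samples(presence.samples, cov.samples)
    cov_df = cov.data.loc[samples]
    if "diagnosis" not in cov_df.columns:
        raise ValueError("covariate table lacks a 'diagnosis' column")
    Xc, _ = build_design(cov_df, list(covariate_columns), n_pcs=n_pcs)
    pres = presence.presence.loc[samples]
    diag = cov_df["diagnosis"].astype(float)

    per_site: list[AssociationResult] = []
    for site in presence.sites:
        frame = pd.DataFrame({"diagnosis": diag}, index=samples).join(Xc)
        frame["__y"] = pres[site].to_numpy(dtype=float)
        frame = frame.dropna()
        names = ["intercept", "diagnosis"] + [
            c for c in frame.columns if c not in ("diagnosis", "__y")
        ]
        X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in names[1:]])
        if diag.nunique() < 2:
            fit = GlmFit(names, np.full(len(names), np.nan), np.full(len(names), np.nan),
                         np.full(len(names), np.nan), DEGENERATE, len(frame))
        else:
            fit = fit_glm_binomial(frame["__y"].to_numpy(), X, names)
        if fit.flag == OK:
            est, se, p = fit.term("diagnosis")
        else:
            est, se, p = float("nan"), float("nan"), float("nan")
        per_site.append(
            AssociationResult("diagnosis", str(site), est, se, p, flag=fit.flag, n=fit.n)
        )
    apply_bh(per_site)

    totals = presence.total_het_sites.loc[samples].to_numpy(dtype=float)
    frame = pd.DataFrame({"diagnosis": diag}, index=samples).join(Xc)
    frame["__y"] = totals
    frame = frame.dropna()
    names = ["intercept", "diagnosis"] + [
        c for c in frame.columns if c not in ("diagnosis", "__y")
    ]
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in names[1:]])
    if diag.nunique() < 2:
        total_res = AssociationResult("diagnosis", "total_het_sites", float("nan"),
                                      float("nan"), float("nan"), flag=DEGENERATE,
                                      n=len(frame))
    else:
        fit = fit_ols(frame["__y"].to_numpy(), X, names)
        if fit.flag == OK:
            est, se, p = fit.term("diagnosis")
            total_res = AssociationResult("diagnosis", "total_het_sites", est, se, p,
                                          q=p, flag=OK, n=fit.n)
        else:
            total_res = AssociationResult("diagnosis", "total_het_sites", float("nan"),
                                          float("nan"), float("nan"), flag=fit.flag,
                                          n=fit.n)
    return per_site, total_res


def cis_eqtl(
    expr: ExpressionMatrix,
    geno: GenotypeTable,
    cov: CovariateTable,
    min_expressed: int = 5,
    cis_window: float = 1e6,
    maf_min: float = 0.05,
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES + ("rin", "batch"),
    n_pcs: int = 10,
    gene_positions: dict[str, int] | None = None,
) -> list[AssociationResult]:
    """cis-eQTL scan: OLS of log2(count+1) on genotype plus covariates.

    Genes expressed (count > 0) in fewer than ``min_expressed`` samples are
    dropped.  On the 16.6 kb MT genome every variant-gene pair is within
    any megabase cis window; when gene positions are supplied the window is
    enforced explicitly.  BH-FDR is applied across all tested pairs.
    """
    samples = _aligned_samples(expr.samples, geno.samples, cov.samples)
    geno_idx = [geno.samples.index(s) for s in samples]
    counts = expr.counts[samples]
    expressed = (counts > 0).sum(axis=1)
    genes = [g for g in expr.genes if expressed[g] >= min_expressed]
    log_expr = np.log2(counts.loc[genes] + 1.0)

    maf = geno.maf()
    keep_variants = [j for j in range(len(geno.variants)) if maf[j] >= maf_min]
    cov_df = cov.data.loc[samples]
    Xc, _ = build_design(cov_df, list(covariate_columns), n_pcs=n_pcs)

    Xc_np = Xc.to_numpy(dtype=float)
    Y = log_expr.to_numpy(dtype=float)  # retained genes x samples
    results: list[AssociationResult] = []
    for j in keep_variants:
        vid = geno.variant_ids[j]
        vpos = int(geno.variants.iloc[j]["position"])
        g = geno.calls[geno_idx, j]
        mask = ~np.isnan(g)
        if Xc_np.size:
            mask &= ~np.isnan(Xc_np).any(axis=1)
        gm = g[mask]
        if gm.size == 0 or gm.min() == gm.max():
            continue  # constant genotype carries no information
        X = np.column_stack([np.ones(int(mask.sum())), gm, Xc_np[mask]])
        n, k = X.shape
        if n <= k:
            raise ValueError(f"n={n} samples cannot identify {k} parameters")
        XtX_inv = np.linalg.inv(X.T @ X)
        # the design is shared across genes: one normal-equations pass
        Ym = Y[:, mask]
        B = XtX_inv @ (X.T @ Ym.T)  # k x genes
        resid = Ym.T - X @ B
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        se_g = np.sqrt(sigma2 * XtX_inv[1, 1])
        for gi, gene in enumerate(genes):
            if gene_positions is not None and gene in gene_positions:
                if abs(gene_positions[gene] - vpos) > cis_window:
                    continue
            yv = Ym[gi]
            if yv.min() == yv.max():
                results.append(
                    AssociationResult(vid, gene, float("nan"), float("nan"),
                                      float("nan"), flag=SKIPPED, n=n)
                )
                continue
            est = float(B[1, gi])
            se = float(se_g[gi])
            p = float(2.0 * stats.t.sf(abs(est / se), dof))
            results.append(AssociationResult(vid, gene, est, se, p, n=n))
    return apply_bh(results)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    n_samples_in: int = 0
    n_variants_in: int = 0

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_in - len(self.removed_samples)

    @property
    def n_variants_retained(self) -> int:
        return self.n_variants_in - len(self.removed_variants)


def hwe_exact_test(n_ref: int, n_het: int, n_alt: int) -> float:
    """Exact Hardy-Weinberg test on diploid genotype counts.

    Conditional-on-allele-counts exact test: the p-value sums the
    probabilities of all heterozygote counts no more likely than the one
    observed.  MT genotypes are haploid, so applying this test to them
    (coding 0 -> ref-homozygote, 1 -> alt-homozygote) follows the diploid
    convention of standard GWAS tooling and is flagged by the caller.
    """
    n = n_ref + n_het + n_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_ref, n_alt) + n_het
    # enumerate heterozygote counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros(len(hets))
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logprob[i] = (
            math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            + h * math.log(2)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError(f"heterozygote count {n_het} inconsistent with allele counts")
    return float(min(1.0, prob[prob <= prob[obs] * (1 + 1e-12)].sum()))


def qc_filter(
    geno: GenotypeTable,
    cov: CovariateTable | None = None,
    call_rate_min: float = 0.80,
    maf_max_removed: float = 0.09,
    hwe_p_min: float = 1e-6,
    apply_hwe: bool = False,
) -> tuple[GenotypeTable, QcReport]:
    """Sample and variant QC mirroring standard GWAS practice.

    Samples below ``call_rate_min`` genotyping rate are removed, as are
    duplicated genotype rows and (when the covariate table carries both
    ``sex`` and ``genetic_sex``) sex-discordant samples.  Variants with
    MAF <= ``maf_max_removed`` are removed.  The Hardy-Weinberg filter
    follows the diploid convention and is OFF by default because it is not
    meaningful for haploid MT calls; enable ``apply_hwe`` to reproduce
    diploid-tooling behaviour.
    """
    report = QcReport(n_samples_in=len(geno.samples), n_variants_in=len(geno.variants))

    keep_samples = []
    call_rates = geno.call_rate()
    seen: dict[bytes, str] = {}
    for i, s in enumerate(geno.samples):
        if call_rates[i] < call_rate_min:
            report.removed_samples.append((s, f"call_rate<{call_rate_min}"))
            continue
        key = np.nan_to_num(geno.calls[i], nan=-1.0).tobytes()
        if key in seen and len(geno.variants) >= 5:
            report.removed_samples.append((s, f"duplicate_of:{seen[key]}"))
            continue
        seen[key] = s
        if cov is not None and {"sex", "genetic_sex"} <= set(cov.data.columns):
            if s in cov.data.index:
                row = cov.data.loc[s]
                if pd.notna(row["sex"]) and pd.notna(row["genetic_sex"]) and row["sex"] != row["genetic_sex"]:
                    report.removed_samples.append((s, "sex_discordance"))
                    continue
        keep_samples.append(i)

    sub_calls = geno.calls[keep_samples]
    keep_variants = []
    for j in range(len(geno.variants)):
        vid = geno.variant_ids[j]
        col = sub_calls[:, j]
        valid = col[~np.isnan(col)]
        if valid.size == 0:
            report.removed_variants.append((vid, "no_calls"))
            continue
        af = valid.mean()
        maf = min(af, 1 - af)
        if maf <= maf_max_removed:
            report.removed_variants.append((vid, f"maf<={maf_max_removed}"))
            continue
        if apply_hwe:
            n_alt = int(valid.sum())
            n_ref = int(valid.size - n_alt)
            p_hwe = hwe_exact_test(n_ref, 0, n_alt)
            if p_hwe < hwe_p_min:
                report.removed_variants.append((vid, f"hwe_p<{hwe_p_min}"))
                continue
        keep_variants.append(j)

    filtered = GenotypeTable(
        [geno.samples[i] for i in keep_samples],
        geno.variants.iloc[keep_variants].reset_index(drop=True),
        geno.calls[np.ix_(keep_samples, keep_variants)],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# heteroplasmy-score association with genotype PCs
# ---------------------------------------------------------------------------


def genotype_pca(geno: GenotypeTable, k: int = 2) -> np.ndarray:
    """Principal components of the genotype matrix.

    Columns are mean-centred and scaled to unit variance (constant columns
    dropped); missing calls are mean-imputed before the SVD.  Returns the
    first k sample scores.
    """
    M = geno.calls.copy()
    col_mean = np.nanmean(M, axis=0)
    idx = np.where(np.isnan(M))
    M[idx] = np.take(col_mean, idx[1])
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    M = (M[:, keep] - col_mean[keep]) / sd[keep]
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    k = min(k, len(S))
    return U[:, :k] * S[:k]


def het_score_assoc(
    scores: pd.DataFrame,
    geno: GenotypeTable,
    n_pcs: int = 2,
    score_column: str = "het_total",
) -> list[AssociationResult]:
    """Linear model of the total heteroplasmy score on each SNP.

    The first ``n_pcs`` genotype principal components enter as ancestry
    covariates, mirroring standard GWAS stratification control.
    """
    samples = _aligned_samples(list(scores.index), geno.samples)
    geno_idx = [geno.samples.index(s) for s in samples]
    y_all = scores.loc[samples, score_column].to_numpy(dtype=float)
    pcs = genotype_pca(geno, k=n_pcs)[geno_idx]
    if len(samples) < n_pcs + 3:
        raise ValueError(f"n={len(samples)} too small for {n_pcs} PCs + SNP + intercept")
    results = []
    for j in range(len(geno.variants)):
        vid = geno.variant_ids[j]
        g = geno.calls[geno_idx, j]
        mask = ~np.isnan(g) & ~np.isnan(y_all)
        yv, gv = y_all[mask], g[mask]
        if yv.size == 0 or yv.min() == yv.max() or gv.min() == gv.max():
            results.append(
                AssociationResult(vid, score_column, float("nan"), float("nan"),
                                  float("nan"), flag=DEGENERATE, n=int(mask.sum()))
            )
            continue
        X = np.column_stack([np.ones(mask.sum()), gv, pcs[mask]])
        names = ["intercept", "genotype"] + [f"pc{i+1}" for i in range(pcs.shape[1])]
        fit = fit_ols(yv, X, names)
        est, se, p = fit.term("genotype")
        results.append(AssociationResult(vid, score_column, est, se, p, flag=fit.flag, n=fit.n))
    return apply_bh(results)


# ---------------------------------------------------------------------------
# replication enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    n_tested: int
    n_nominal: int
    alpha: float
    expected_null: float
    p_enrichment: float
    sign_concordance: float

    def __post_init__(self) -> None:
        assert 0 <= self.n_nominal <= self.n_tested


def replication_enrichment(
    results: list[AssociationResult],
    reference: pd.DataFrame,
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Test whether previously reported QTLs replicate in ``results``.

    ``reference`` needs columns (predictor_id, outcome_id, direction) with
    direction in {-1, +1}.  Pairs present in both tables define n_tested;
    the expected null count is n_tested * alpha exactly, and enrichment is
    the exact binomial upper tail P(X >= n_nominal | n_tested, alpha).
    Sign concordance is the fraction of nominal hits whose effect sign
    matches the reference direction.
    """
    res_index = {(r.predictor_id, r.outcome_id): r for r in results if r.flag == OK}
    tested = []
    for row in reference.itertuples():
        key = (row.predictor_id, row.outcome_id)
        if key in res_index:
            tested.append((res_index[key], int(row.direction)))
    if not tested:
        raise ValueError("no overlap between results and reference table")
    n_tested = len(tested)
    nominal = [(r, d) for r, d in tested if r.p < alpha]
    n_nominal = len(nominal)
    expected = n_tested * alpha
    p_enr = float(stats.binom.sf(n_nominal - 1, n_tested, alpha))
    if nominal:
        concord = sum(1 for r, d in nominal if np.sign(r.estimate) == d) / n_nominal
    else:
        concord = float("nan")
    return EnrichmentResult(n_tested, n_nominal, alpha, expected, p_enr, concord)


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "predictor": [r.predictor_id for r in results],
            "outcome": [r.outcome_id for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "flag": [r.flag for r in results],
            "n": [r.n for r in results],
        }
    )
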