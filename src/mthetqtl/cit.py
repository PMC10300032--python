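"""Causal inference testing (CIT) for genotype -> mediator -> trait trios.

For a trio of a DNA locus L, a candidate mediator G (e.g. MT-ND3
expression) and a quantitative trait T (e.g. expression of another gene),
G is called a causal mediator of the L-T association when four conditions
hold simultaneously:

1. L and G are associated,
2. L and T are associated,
3. L is associated with G given T,
4. L is independent of T given G.

Conditions 1-3 are ordinary F-tests on nested linear models.  Condition 4
asserts a null effect, so it is tested in the equivalence direction: the
observed statistic is the partial F for L in T ~ G + L, and its reference
distribution is built by a semi-parametric permutation that preserves the
L-G association while severing any G-T information -- the mediator is
reconstructed as G* = fitted(G ~ L) + permuted residuals.  If G truly
transmits the L-T association, conditioning on the real G absorbs it
(small observed F) while conditioning on G* cannot (large permuted F), so
p4 = P(F* <= F_obs) is small exactly when mediation is supported.

The omnibus p-value is the maximum of the four component p-values; it is
calibrated under the least-favourable partial null (three conditions hold
exactly, one sits at its boundary).  Permutation FDR over a collection of
trios uses trait-label permutations, which preserve the shared locus ->
anchor structure while voiding each candidate trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CAUSAL = "causal"
NOT_CAUSAL = "not_causal"
UNDEFINED = "undefined"


@dataclass
class Trio:
    """Complete-case vectors for one (locus, mediator, trait) test."""

    L: np.ndarray
    G: np.ndarray
    T: np.ndarray
    trait_id: str = ""

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if not (len(self.L) == len(self.G) == len(self.T)):
            raise ValueError("trio vectors have unequal lengths")
        mask = np.isnan(self.L) | np.isnan(self.G) | np.isnan(self.T)
        if mask.any():
            self.L, self.G, self.T = self.L[~mask], self.G[~mask], self.T[~mask]

    @property
    def n(self) -> int:
        return len(self.L)


@dataclass
class CitResult:
    trait_id: str
    p1: float  # L-G association
    p2: float  # L-T association
    p3: float  # L-G association given T
    p4: float  # equivalence test of L independent of T given G
    q_perm: float
    n: int
    n_perm: int
    flag: str = "ok"
    warnings: list[str] = field(default_factory=list)

    @property
    def p_omnibus(self) -> float:
        return max(self.p1, self.p2, self.p3, self.p4)

    @property
    def call(self) -> str:
        if self.flag != "ok":
            return UNDEFINED
        return CAUSAL if self.q_perm < 0.05 else NOT_CAUSAL


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd


def _f_sf(F, df2):
    return stats.f.sf(F, 1, df2)


def _partial_f(r_xy, r_xz, r_yz, n):
    """Partial F for x predicting y given z, from pairwise correlations."""
    denom = np.sqrt(np.clip((1 - r_xz**2) * (1 - r_yz**2), 1e-300, None))
    pr = (r_xy - r_xz * r_yz) / denom
    pr = np.clip(pr, -1 + 1e-15, 1 - 1e-15)
    return pr**2 / (1 - pr**2) * (n - 3)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y on an intercept plus covariate columns."""
    if covariates is None:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def cit_test(
    trio: Trio,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    covariates: np.ndarray | None = None,
) -> CitResult:
    """Run the four-condition causal inference test on one trio.

    ``covariates`` (n x k) are residualized out of G and T before testing.
    The returned ``q_perm`` equals the omnibus p-value floored FDR estimate
    for the single trio; within :func:`build_network` trios share a pooled
    permutation FDR instead.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    warnings: list[str] = []
    if trio.n < 20:
        raise ValueError(f"need >= 20 complete cases, got {trio.n}")
    if trio.L.min() == trio.L.max():
        raise ValueError("locus vector is constant")
    if trio.G.std() == 0 or trio.T.std() == 0:
        return CitResult(trio.trait_id, *(float("nan"),) * 5, trio.n, n_perm,
                         flag="degenerate_constant_vector")
    if n_perm < 100:
        warnings.append(f"n_perm={n_perm} < 100: permutation p resolution is coarse")

    l = _z(trio.L)
    g = _z(residualize(trio.G, covariates))
    t = _z(residualize(trio.T, covariates))
    n = trio.n

    obs = _component_pvalues(l, g, t, n)
    p4, f_obs = _equivalence_p4(l, g, t, n, n_perm, rng)
    p_omni = max(*obs, p4)

    # single-trio permutation FDR: plug-in estimate from trait permutations,
    # floored at the omnibus p (an FDR estimate cannot undercut its own p)
    perm_omni = _permuted_omnibus(l, g, t, n, n_perm, rng)
    plug_in = float(np.mean(perm_omni <= p_omni))
    q = float(min(1.0, max(p_omni, plug_in)))

    return CitResult(trio.trait_id, obs[0], obs[1], obs[2], p4, q, n, n_perm,
                     warnings=warnings)


def _component_pvalues(l, g, t, n) -> tuple[float, float, float]:
    r_lg = l @ g / n
    r_lt = l @ t / n
    r_gt = g @ t / n
    f1 = r_lg**2 / max(1 - r_lg**2, 1e-300) * (n - 2)
    f2 = r_lt**2 / max(1 - r_lt**2, 1e-300) * (n - 2)
    f3 = _partial_f(r_lg, r_lt, r_gt, n)  # L on G given T
    return (
        float(_f_sf(f1, n - 2)),
        float(_f_sf(f2, n - 2)),
        float(_f_sf(f3, n - 3)),
    )


def _cond4_f(l, t, gstar_cov_l, gstar_cov_t, gstar_var, r_lt, n):
    """Partial F for L in T ~ G* + L from covariance pieces of G*."""
    sd = np.sqrt(gstar_var)
    r_lg = gstar_cov_l / sd
    r_tg = gstar_cov_t / sd
    return _partial_f(r_lt, r_lg, r_tg, n)


def _equivalence_p4(l, g, t, n, n_perm, rng) -> tuple[float, float]:
    """Permutation equivalence test for 'L independent of T given G'."""
    r_lg = l @ g / n
    r_lt = l @ t / n
    r_gt = g @ t / n
    f_obs = _partial_f(r_lt, r_lg, r_gt, n)

    e = g - r_lg * l  # exact residual of G on L for z-scored vectors
    # permuted mediators G* = r_lg * L + perm(e): keep the L-G association,
    # break any G-T information
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    E = e[perm_idx]  # (n_perm, n)
    cov_l = r_lg + E @ l / n
    cov_t = r_lg * r_lt + E @ t / n
    var_gstar = r_lg**2 + e @ e / n + 2 * r_lg * (E @ l) / n
    f_star = _cond4_f(l, t, cov_l, cov_t, var_gstar, r_lt, n)
    p4 = (1.0 + np.sum(f_star <= f_obs)) / (n_perm + 1.0)
    return float(p4), float(f_obs)


def _permuted_omnibus(l, g, t, n, n_perm, rng) -> np.ndarray:
    """Omnibus p-values under trait-label permutations.

    Permuting T preserves the L-G leg while voiding every T-dependent
    condition; for these fully void replicates the condition-4 statistic
    and its reference distribution share the same central-F limit, so p4*
    is taken as the analytic lower tail instead of a nested permutation.
    """
    r_lg = l @ g / n
    p1 = float(_f_sf(r_lg**2 / max(1 - r_lg**2, 1e-300) * (n - 2), n - 2))
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    P = t[perm_idx]  # (n_perm, n)
    r_lt = P @ l / n
    r_gt = P @ g / n
    f2 = r_lt**2 / np.clip(1 - r_lt**2, 1e-300, None) * (n - 2)
    p2 = _f_sf(f2, n - 2)
    f3 = _partial_f(r_lg, r_lt, r_gt, n)
    p3 = _f_sf(f3, n - 3)
    f4 = _partial_f(r_lt, r_lg, r_gt, n)
    p4 = stats.f.cdf(f4, 1, n - 3)  # lower tail: equivalence direction
    return np.maximum.reduce([np.full(n_perm, p1), p2, p3, p4])


# ---------------------------------------------------------------------------
# network construction around an anchor mediator
# ---------------------------------------------------------------------------


@dataclass
class NetworkResult:
    results: list[CitResult]
    edges: "object"  # pandas DataFrame, avoided at import for typing only
    screened_out: list[str]
    warnings: list[str] = field(default_factory=list)


def build_network(
    anchor_gene: str,
    candidate_genes: list[str],
    expr,  # ExpressionMatrix
    geno_locus: np.ndarray,
    cov=None,  # CovariateTable or None
    n_perm: int = 1000,
    seed: int | None = None,
    screen_p: float = 0.05,
    q_threshold: float = 0.05,
    top_k: int = 45,
) -> NetworkResult:
    """Orient candidate genes downstream of an anchor mediator.

    Candidates are screened to genes whose expression correlates with the
    anchor (Pearson p < ``screen_p``); each survivor forms a trio with the
    locus and the anchor, and trios with pooled permutation FDR below
    ``q_threshold`` become edges anchored at ``anchor_gene``.  Expression
    is log2(count+1)-transformed and covariate-residualized before testing.
    """
    import pandas as pd

    from .association import build_design

    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    samples = list(expr.samples)
    geno_locus = np.asarray(geno_locus, dtype=float)
    if len(geno_locus) != len(samples):
        raise ValueError("locus vector does not match expression samples")
    if anchor_gene not in expr.genes:
        raise ValueError(f"anchor gene {anchor_gene!r} not in expression matrix")

    mask = ~np.isnan(geno_locus)
    log_expr = np.log2(expr.counts[samples] + 1.0)
    cov_block = None
    if cov is not None:
        Xc, _ = build_design(cov.data.loc[samples], list(cov.data.columns))
        cov_block = Xc.to_numpy(dtype=float)[mask]
    anchor = log_expr.loc[anchor_gene].to_numpy()[mask]
    L = geno_locus[mask]
    n = int(mask.sum())

    g = _z(residualize(anchor, cov_block))

    # correlation screen against the anchor
    screened: list[str] = []
    kept: list[tuple[str, np.ndarray]] = []
    for gene in candidate_genes:
        if gene == anchor_gene:
            screened.append(gene)
            continue
        y = log_expr.loc[gene].to_numpy()[mask]
        if y.std() == 0 or np.allclose(y, anchor):
            screened.append(gene)
            continue
        tvec = _z(residualize(y, cov_block))
        r = g @ tvec / n
        fstat = r**2 / max(1 - r**2, 1e-300) * (n - 2)
        if _f_sf(fstat, n - 2) < screen_p:
            kept.append((gene, tvec))
        else:
            screened.append(gene)
    if not kept:
        warnings.append("no candidate passed the anchor-correlation screen")
        return NetworkResult([], pd.DataFrame(), screened, warnings)

    l = _z(L)
    results: list[CitResult] = []
    perm_pool: list[np.ndarray] = []
    strengths: list[float] = []
    # one generator per trio derived from the master seed keeps results
    # independent of candidate ordering subsets
    for gene, tvec in kept:
        sub_rng = np.random.default_rng(rng.integers(2**31))
        obs = _component_pvalues(l, g, tvec, n)
        p4, _ = _equivalence_p4(l, g, tvec, n, n_perm, sub_rng)
        res = CitResult(gene, obs[0], obs[1], obs[2], p4, float("nan"), n, n_perm)
        results.append(res)
        perm_pool.append(_permuted_omnibus(l, g, tvec, n, n_perm, sub_rng))
        strengths.append(abs(g @ tvec / n))

    obs_omni = np.array([r.p_omnibus for r in results])
    perm_matrix = np.stack(perm_pool)  # (n_trios, n_perm)
    q = _pooled_fdr(obs_omni, perm_matrix)
    for r, qi in zip(results, q):
        r.q_perm = float(qi)

    edges = pd.DataFrame(
        {
            "source": anchor_gene,
            "target": [r.trait_id for r in results],
            "p1": [r.p1 for r in results],
            "p2": [r.p2 for r in results],
            "p3": [r.p3 for r in results],
            "p4": [r.p4 for r in results],
            "p_omnibus": obs_omni,
            "q_perm": q,
            "weight": strengths,
        }
    )
    edges = edges[edges["q_perm"] < q_threshold]
    edges = edges.sort_values("weight", ascending=False).head(top_k).reset_index(drop=True)
    return NetworkResult(results, edges, screened, warnings)


def _pooled_fdr(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Plug-in permutation FDR pooled across trios.

    For each observed omnibus p, the expected null count is the mean over
    permutation replicates of trios at or below that p; q is the ratio to
    the observed count, floored at the trio's own omnibus p, clipped to
    [0, 1] and made monotone in p.
    """
    n_trios, n_perm = perm.shape
    order = np.argsort(obs, kind="stable")
    q = np.empty(len(obs))
    flat = np.sort(perm.ravel())
    for rank, i in enumerate(order, start=1):
        null_count = np.searchsorted(flat, obs[i], side="right") / n_perm
        q[i] = null_count / rank
    q = np.maximum(q, obs)
    q = np.minimum(q, 1.0)
    # enforce monotonicity: larger p never gets smaller q
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = q_sorted
    return q
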