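"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume: a
haplogroup-structured haploid MT genotype table whose causal variant tags
a haplogroup (mimicking 10398A>G tagging haplogroups I/J/K), control-
region-restricted heteroplasmy whose per-site presence follows a logistic
model in the causal genotype, amplicon pileups built by binomial read
sampling with sequencing error, negative-binomial expression counts with
a planted genotype effect on one gene, covariates matching a brain-bank
cohort, and fragment quantifications for the copy-number assay.  All
randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mt_io
from .heteroplasmy import WINDOW_16043, WINDOW_16469
from .mt_io import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeTable,
    MT_LENGTH_HG19,
    PileupTable,
)
from .copy_number import FragmentQuant

#: the 37 mitochondrially encoded genes (13 protein-coding, 2 rRNA, 22 tRNA)
MT_GENES = (
    "MT-ND1 MT-ND2 MT-ND3 MT-ND4 MT-ND4L MT-ND5 MT-ND6 MT-CYB MT-CO1 MT-CO2 "
    "MT-CO3 MT-ATP6 MT-ATP8 MT-RNR1 MT-RNR2 MT-TA MT-TC MT-TD MT-TE MT-TF "
    "MT-TG MT-TH MT-TI MT-TK MT-TL1 MT-TL2 MT-TM MT-TN MT-TP MT-TQ MT-TR "
    "MT-TS1 MT-TS2 MT-TT MT-TV MT-TW MT-TY"
).split()

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_samples: int = 400
    mt_length: int = MT_LENGTH_HG19
    seed: int = 0

    # haplogroup-structured genotypes
    haplogroup_freqs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    causal_position: int = 10398
    causal_ref: str = "A"
    causal_alt: str = "G"
    causal_haplogroups: tuple[int, ...] = (0,)  # haplogroups carrying the alt
    tag_positions: tuple[int, ...] = (11467, 12308, 12372)
    tag_concordance: float = 0.95  # P(tag allele matches causal allele)
    background_positions: tuple[int, ...] = (73, 146, 152, 195, 2706, 7028, 14766, 16519)
    background_freq_range: tuple[float, float] = (0.10, 0.45)

    # heteroplasmy model: presence ~ Bernoulli(logistic(b0 + b1 * g))
    het_sites: tuple[int, ...] = (65, 150, 185, 189, 204, 16093, 16129, 16188, 16223)
    causal_het_sites: tuple[int, ...] = (65, 185, 189, 16093, 16129)
    baseline_het_prob: float = 0.10
    het_effect: float = 1.0  # log-odds increment per alt allele
    het_fraction_range: tuple[float, float] = (0.06, 0.5)

    # amplicon pileups
    depth_mean: float = 500.0
    seq_error: float = 0.005
    with_pileups: bool = True

    # expression: negative binomial counts, log2-scale genotype shift
    genes: tuple[str, ...] = tuple(MT_GENES)
    target_gene: str = "MT-ND3"
    expr_effect: float = -0.5  # log2 fold change per alt allele
    nb_dispersion: float = 0.2
    expr_mean_range: tuple[float, float] = (50.0, 5000.0)

    # covariates
    ad_prevalence: float = 0.5
    n_ancestry_outliers: int = 0

    # copy-number assay
    x_female_factor: float = 2.0
    quant_cv: float = 0.10
    m_genotype_effect: float = 0.0  # multiplicative M-fragment shift per alt allele
    n_batches: int = 2

    def validate(self) -> None:
        if not 0 < self.baseline_het_prob < 1:
            raise ValueError("baseline_het_prob must lie in (0, 1)")
        lo, hi = self.het_fraction_range
        if not 0 < lo < hi < 1:
            raise ValueError("het_fraction_range must be inside (0, 1)")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if abs(sum(self.haplogroup_freqs) - 1.0) > 1e-9:
            raise ValueError("haplogroup frequencies must sum to 1")
        if self.target_gene not in self.genes:
            raise ValueError(f"target gene {self.target_gene!r} not among genes")


@dataclass
class SimTruth:
    causal_variant_id: str
    het_effect: float
    baseline_het_prob: float
    causal_het_sites: list[int]
    het_presence: pd.DataFrame  # samples x het sites, planted truth
    het_fractions: pd.DataFrame  # samples x het sites, 0 where absent
    eqtl_gene: str
    eqtl_slope: float
    haplogroups: np.ndarray


@dataclass
class SimCohort:
    config: SimConfig
    genotypes: GenotypeTable
    covariates: CovariateTable
    expression: ExpressionMatrix
    pileups: list[PileupTable]
    fragments: list[FragmentQuant]
    truth: SimTruth


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i+1:04d}" for i in range(n)]

    # --- genotypes -------------------------------------------------------
    hap = rng.choice(len(cfg.haplogroup_freqs), size=n, p=cfg.haplogroup_freqs)
    causal = np.isin(hap, cfg.causal_haplogroups).astype(float)
    positions = [cfg.causal_position]
    refs = [cfg.causal_ref]
    alts = [cfg.causal_alt]
    cols = [causal]
    for pos in cfg.tag_positions:
        match = rng.random(n) < cfg.tag_concordance
        cols.append(np.where(match, causal, 1 - causal))
        positions.append(pos)
        ref, alt = rng.choice(BASES, size=2, replace=False)
        refs.append(str(ref))
        alts.append(str(alt))
    for pos in cfg.background_positions:
        f = rng.uniform(*cfg.background_freq_range)
        cols.append((rng.random(n) < f).astype(float))
        positions.append(pos)
        ref, alt = rng.choice(BASES, size=2, replace=False)
        refs.append(str(ref))
        alts.append(str(alt))
    calls = np.column_stack(cols)
    if cfg.n_ancestry_outliers:
        # a divergent mtDNA lineage differs across the whole panel: flip every
        # non-causal variant for the outlier block
        out_idx = np.arange(n - cfg.n_ancestry_outliers, n)
        other_cols = np.arange(1, calls.shape[1])
        calls[np.ix_(out_idx, other_cols)] = 1.0 - calls[np.ix_(out_idx, other_cols)]
    variants = pd.DataFrame(
        {"position": positions, "ref": refs, "alt": alts,
         "rsid": [""] * len(positions)}
    )
    geno = GenotypeTable(samples, variants, calls)

    # --- heteroplasmy truth ---------------------------------------------
    b0 = np.log(cfg.baseline_het_prob / (1 - cfg.baseline_het_prob))
    presence = pd.DataFrame(0, index=samples, columns=list(cfg.het_sites), dtype=int)
    fractions = pd.DataFrame(0.0, index=samples, columns=list(cfg.het_sites))
    for site in cfg.het_sites:
        eta = b0 + (cfg.het_effect * causal if site in cfg.causal_het_sites else 0.0)
        prob = 1.0 / (1.0 + np.exp(-eta))
        pres = rng.random(n) < prob
        frac = np.where(pres, rng.uniform(*cfg.het_fraction_range, size=n), 0.0)
        presence[site] = pres.astype(int)
        fractions[site] = frac

    # --- covariates ------------------------------------------------------
    cov = pd.DataFrame(
        {
            "diagnosis": (rng.random(n) < cfg.ad_prevalence).astype(int),
            "study": rng.choice(["ROS", "MAP"], size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "age_death": rng.normal(85, 5, size=n).round(1),
            "education": rng.normal(16, 3, size=n).round(1),
            "pmi": np.abs(rng.normal(7, 3, size=n)).round(2),
            "rin": np.clip(rng.normal(7, 1, size=n), 2, 10).round(2),
            "batch": rng.choice(["B1", "B2"], size=n),
        },
        index=samples,
    )
    for k in range(1, 11):
        cov[f"pc{k}"] = rng.normal(0, 1, size=n).round(4)
    covariates = CovariateTable(cov)

    # --- expression ------------------------------------------------------
    base_mean = np.exp(
        rng.uniform(np.log(cfg.expr_mean_range[0]), np.log(cfg.expr_mean_range[1]),
                    size=len(cfg.genes))
    )
    counts = np.empty((len(cfg.genes), n))
    r = 1.0 / cfg.nb_dispersion  # NB shape: var = mu + dispersion * mu^2
    for i, gene in enumerate(cfg.genes):
        mu = np.full(n, base_mean[i])
        if gene == cfg.target_gene:
            mu = mu * np.power(2.0, cfg.expr_effect * causal)
        lam = rng.gamma(shape=r, scale=mu / r)
        counts[i] = rng.poisson(lam)
    expression = ExpressionMatrix(
        pd.DataFrame(counts, index=list(cfg.genes), columns=samples)
    )

    # --- amplicon pileups -------------------------------------------------
    pileups: list[PileupTable] = []
    if cfg.with_pileups:
        window_pos = _amplicon_positions(cfg.mt_length)
        ref_seq = {p: str(rng.choice(BASES)) for p in window_pos}
        alt_base = {p: str(rng.choice([b for b in BASES if b != ref_seq[p]]))
                    for p in window_pos}
        for i, s in enumerate(samples):
            rows = []
            for p in window_pos:
                depth = max(int(rng.poisson(cfg.depth_mean)), 1)
                f_true = fractions.at[s, p] if p in fractions.columns else 0.0
                if f_true > 0:
                    n_alt = rng.binomial(depth, f_true)
                else:
                    n_alt = rng.binomial(depth, cfg.seq_error)
                counts_d = {ref_seq[p]: depth - n_alt}
                if n_alt:
                    counts_d[alt_base[p]] = n_alt
                rows.append((p, ref_seq[p], counts_d))
            pileups.append(
                PileupTable(s, pd.DataFrame(rows, columns=["position", "ref", "counts"]),
                            mt_length=cfg.mt_length)
            )

    # --- fragment quantifications ----------------------------------------
    fragments: list[FragmentQuant] = []
    batches = [f"batch{(i % cfg.n_batches) + 1}" for i in range(n)]
    batch_scale = {f"batch{b+1}": rng.uniform(0.5, 2.0) for b in range(cfg.n_batches)}
    for i, s in enumerate(samples):
        scale = batch_scale[batches[i]]
        q22 = scale * 100.0 * np.exp(rng.normal(0, cfg.quant_cv))
        x_factor = cfg.x_female_factor if cov.at[s, "sex"] == "F" else 1.0
        qx = scale * 100.0 * x_factor * np.exp(rng.normal(0, cfg.quant_cv))
        m_factor = (1.0 + cfg.m_genotype_effect) ** causal[i]
        qm = scale * 500.0 * m_factor * np.exp(rng.normal(0, cfg.quant_cv))
        fragments.append(
            FragmentQuant(s, batches[i], qm, qx, q22, sex=cov.at[s, "sex"],
                          genotype=causal[i])
        )

    truth = SimTruth(
        causal_variant_id=f"{cfg.causal_position}_{cfg.causal_ref}/{cfg.causal_alt}",
        het_effect=cfg.het_effect,
        baseline_het_prob=cfg.baseline_het_prob,
        causal_het_sites=list(cfg.causal_het_sites),
        het_presence=presence,
        het_fractions=fractions,
        eqtl_gene=cfg.target_gene,
        eqtl_slope=cfg.expr_effect,
        haplogroups=hap,
    )
    return SimCohort(cfg, geno, covariates, expression, pileups, fragments, truth)


def _amplicon_positions(mt_length: int) -> list[int]:
    w1 = range(WINDOW_16043[0], WINDOW_16043[1] + 1)
    w2a = range(WINDOW_16469[0], mt_length + 1)
    w2b = range(1, WINDOW_16469[1] + 1)
    return sorted(set(w1) | set(w2a) | set(w2b))


def simulate_trio(
    n: int,
    regime: str,
    effect: float = 0.8,
    maf: float = 0.5,
    seed: int | np.random.Generator | None = None,
):
    """Generate one (L, G, T) trio under a known causal regime.

    Regimes: ``causal`` L -> G -> T; ``reactive`` L -> T -> G;
    ``independent`` L -> G and L -> T with G and T conditionally
    independent given L; ``null`` no associations at all.
    """
    from .cit import Trio

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = (rng.random(n) < maf).astype(float)
    if L.min() == L.max():  # tiny-n edge: force both alleles present
        L[: n // 2] = 1.0 - L[0]
    eps_g = rng.normal(0, 1, n)
    eps_t = rng.normal(0, 1, n)
    if regime == "causal":
        G = effect * L + eps_g
        T = effect * G + eps_t
    elif regime == "reactive":
        T = effect * L + eps_t
        G = effect * T + eps_g
    elif regime == "independent":
        G = effect * L + eps_g
        T = effect * L + eps_t
    elif regime == "null":
        G, T = eps_g, eps_t
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return Trio(L, G, T, trait_id=regime)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def emit_fixtures(cohort: SimCohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort to disk in every supported dialect.

    Produces a minimal VCF, a genotype TSV, per-sample pileups in both the
    mpileup-text and counts-TSV dialects, expression and covariate TSVs, a
    fragment-quantification TSV and a JSON truth manifest.  Byte-stable
    for a fixed config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    vcf_path = out / "genotypes.vcf"
    mt_io.write_genotypes(cohort.genotypes, vcf_path, dialect="vcf_min",
                          mt_length=cohort.config.mt_length)
    paths["genotypes_vcf"] = str(vcf_path)
    tsv_path = out / "genotypes.tsv"
    mt_io.write_genotypes(cohort.genotypes, tsv_path, dialect="tsv")
    paths["genotypes_tsv"] = str(tsv_path)

    expr_path = out / "expression.tsv"
    mt_io.write_expression(cohort.expression, expr_path)
    paths["expression"] = str(expr_path)
    cov_path = out / "covariates.tsv"
    mt_io.write_covariates(cohort.covariates, cov_path)
    paths["covariates"] = str(cov_path)

    if cohort.pileups:
        pdir = out / "pileups"
        pdir.mkdir(exist_ok=True)
        for pt in cohort.pileups:
            mt_io.write_pileup(pt, pdir / f"{pt.sample_id}.counts.tsv", "counts_tsv")
            mt_io.write_pileup(pt, pdir / f"{pt.sample_id}.mpileup", "mpileup_text")
        paths["pileup_dir"] = str(pdir)

    frag_path = out / "fragments.tsv"
    from .copy_number import quant_table

    quant_table(cohort.fragments).to_csv(frag_path, sep="\t", float_format="%.6f")
    paths["fragments"] = str(frag_path)

    manifest = {
        "n_samples": cohort.config.n_samples,
        "seed": cohort.config.seed,
        "causal_variant": cohort.truth.causal_variant_id,
        "het_effect": cohort.truth.het_effect,
        "baseline_het_prob": cohort.truth.baseline_het_prob,
        "causal_het_sites": cohort.truth.causal_het_sites,
        "eqtl_gene": cohort.truth.eqtl_gene,
        "eqtl_slope": cohort.truth.eqtl_slope,
        "samples": cohort.genotypes.samples,
        "het_presence": {
            s: cohort.truth.het_presence.loc[s].tolist()
            for s in cohort.genotypes.samples
        },
    }
    manifest_path = out / "truth.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["truth"] = str(manifest_path)
    return paths
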