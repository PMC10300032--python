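"""End-to-end orchestration: simulate or load inputs, call heteroplasmy,
score, associate, and write stage tables with provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import heteroplasmy as het
from . import mt_io
from .association import (
    ad_association,
    cis_eqtl,
    het_qtl,
    het_score_assoc,
    qc_filter,
    results_table,
)
from .copy_number import group_test, ratio_z
from .synthetic_data import SimConfig, simulate_cohort

log = logging.getLogger("mthetqtl")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    n_samples: int = 400
    # ... or load from disk
    pileup_dir: str | None = None
    genotypes: str | None = None
    expression: str | None = None
    covariates: str | None = None
    fragments: str | None = None
    # thresholds
    lower: float = 0.05
    upper: float = 0.95
    min_carriers: int = 5
    maf_min: float = 0.05
    fdr: float = 0.05
    n_perm: int = 1000

    def validate(self) -> None:
        if not 0 <= self.lower < self.upper <= 1:
            raise ValueError(f"need 0 <= lower < upper <= 1, got ({self.lower}, {self.upper})")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not self.simulate:
            for name in ("pileup_dir", "genotypes", "covariates"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"input path for {name!r} missing: {path}")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    status: str = "ok"
    stages: list[dict] = field(default_factory=list)
    error: dict | None = None

    def record(self, stage: str, **counts) -> None:
        log.info("stage %s: %s", stage, counts)
        self.stages.append({"stage": stage, **counts})


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in dependency order, writing TSVs under out_dir.

    A stage failure halts the run; tables already written stay on disk and
    the report carries a machine-readable error summary.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=cfg.digest(), seed=cfg.seed)
    try:
        _run_stages(cfg, out, report)
    except Exception as exc:  # pragma: no cover - exercised via error tests
        report.status = "failed"
        report.error = {
            "stage": report.stages[-1]["stage"] if report.stages else "setup",
            "type": type(exc).__name__,
            "message": str(exc),
            "traceback": traceback.format_exc(),
        }
    with open(out / "run_report.json", "w") as fh:
        json.dump({"config_hash": report.config_hash, "seed": report.seed,
                   "status": report.status, "stages": report.stages,
                   "error": report.error}, fh, indent=1)
    return report


def _run_stages(cfg: RunConfig, out: Path, report: RunReport) -> None:
    if cfg.simulate:
        sim_cfg = SimConfig(n_samples=cfg.n_samples, seed=cfg.seed)
        cohort = simulate_cohort(sim_cfg)
        pileups = cohort.pileups
        geno = cohort.genotypes
        cov = cohort.covariates
        expr = cohort.expression
        fragments = cohort.fragments
        report.record("simulate", n_samples=len(geno.samples),
                      n_variants=len(geno.variants))
    else:
        pdir = Path(cfg.pileup_dir)
        pileups = [
            mt_io.read_pileup(p, "counts_tsv", sample_id=p.name.split(".")[0])
            for p in sorted(pdir.glob("*.counts.tsv"))
        ]
        geno = mt_io.read_genotypes(cfg.genotypes, "vcf_min")
        cov = mt_io.read_covariates(cfg.covariates)
        expr = mt_io.read_expression(cfg.expression) if cfg.expression else None
        fragments = None
        report.record("load", n_samples=len(geno.samples), n_pileups=len(pileups))

    all_calls = []
    scores = []
    for pt in pileups:
        calls = het.call_heteroplasmy(pt, cfg.lower, cfg.upper)
        all_calls.extend(calls)
        scores.append(het.het_score(calls, mt_length=pt.mt_length))
    het.calls_table(all_calls).to_csv(out / "het_calls.tsv", sep="\t", index=False)
    score_df = het.score_table(scores)
    score_df.to_csv(out / "het_scores.tsv", sep="\t")
    report.record("het_call", n_calls=len(all_calls), n_samples=len(scores))

    presence = het.presence_matrix(all_calls, min_carriers=cfg.min_carriers)
    presence.presence.to_csv(out / "het_presence.tsv", sep="\t")
    n_sites_all = int((presence.total_het_sites > 0).sum())
    report.record("presence", n_sites_retained=len(presence.sites),
                  n_samples_with_het=n_sites_all)

    geno_f, qc = qc_filter(geno, cov)
    pd.DataFrame(qc.removed_variants, columns=["variant", "reason"]).to_csv(
        out / "qc_removed_variants.tsv", sep="\t", index=False)
    report.record("qc", n_variants_in=qc.n_variants_in,
                  n_variants_retained=qc.n_variants_retained,
                  n_samples_in=qc.n_samples_in,
                  n_samples_retained=qc.n_samples_retained)

    hq = het_qtl(presence, geno, cov, maf_min=cfg.maf_min)
    results_table(hq).to_csv(out / "hetqtl.tsv", sep="\t", index=False)
    report.record("het_qtl", n_tests=len(hq),
                  n_significant=sum(r.significant for r in hq))

    per_site, total_res = ad_association(presence, cov)
    results_table(per_site + [total_res]).to_csv(out / "ad_assoc.tsv", sep="\t",
                                                 index=False)
    report.record("ad_association", n_tests=len(per_site) + 1,
                  n_significant=sum(r.significant for r in per_site))

    if expr is not None:
        eq = cis_eqtl(expr, geno, cov, maf_min=cfg.maf_min)
        results_table(eq).to_csv(out / "eqtl.tsv", sep="\t", index=False)
        report.record("cis_eqtl", n_tests=len(eq),
                      n_significant=sum(r.significant for r in eq))

    sa = het_score_assoc(score_df, geno_f)
    results_table(sa).to_csv(out / "het_score_assoc.tsv", sep="\t", index=False)
    report.record("het_score_assoc", n_tests=len(sa))

    if fragments:
        rz = ratio_z(fragments)
        rz.to_csv(out / "copy_number.tsv", sep="\t")
        tests = [group_test(rz, "sex", "x22_z")]
        if rz["genotype"].nunique() == 2:
            tests.append(group_test(rz, "genotype", "m22_z"))
        results_table(tests).to_csv(out / "copy_number_tests.tsv", sep="\t",
                                    index=False)
        report.record("copy_number", n_samples=len(rz), n_tests=len(tests))
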