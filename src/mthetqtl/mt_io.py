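"""Readers and writers for the file formats the pipeline touches.

The mitochondrial genome is circular; all coordinates here are 1-based
inclusive positions on the circle ``1..L_MT``.  ``L_MT`` defaults to the
hg19 chrM length (16571 bp) and may be set to 16569 for rCRS-aligned data.

Supported external formats:

* samtools ``mpileup`` 6-column text output (one line per covered site),
* a simple ``counts_tsv`` dialect (``position  ref  allele:count,...``),
* a minimal VCF 4.x subset with haploid (or homozygous diploid) GT calls,
* TSV expression matrices (genes x samples) and covariate tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: hg19 chrM length; the rCRS length is 16569.
MT_LENGTH_HG19 = 16571
MT_LENGTH_RCRS = 16569



class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


class CoordinateError(ValueError):
    """Raised for positions outside the circular MT coordinate range."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class PileupTable:
    """Per-position read evidence for one sample.

    ``rows`` has columns ``position`` (int), ``ref`` (str) and ``counts``
    (dict allele -> read count).  The reference allele is always present as
    a key, possibly with count 0.
    """

    sample_id: str
    rows: pd.DataFrame
    mt_length: int = MT_LENGTH_HG19

    def __post_init__(self) -> None:
        pos = self.rows["position"].to_numpy()
        bad = (pos < 1) | (pos > self.mt_length)
        if bad.any():
            raise CoordinateError(
                f"positions outside 1..{self.mt_length}: {sorted(pos[bad])[:5]}"
            )

    def depth(self) -> pd.Series:
        return self.rows["counts"].map(lambda c: sum(c.values()))


@dataclass
class GenotypeTable:
    """Haploid genotype calls, samples x variants.

    ``calls`` is a float matrix with entries 0 (ref), 1 (alt) or NaN
    (missing).  Multiallelic records are split into biallelic columns, so
    every column has a single alt allele.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: position, ref, alt, rsid
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls matrix {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1 or missing (haploid MT)")

    @property
    def variant_ids(self) -> list[str]:
        return [
            f"{int(r.position)}_{r.ref}/{r.alt}" for r in self.variants.itertuples()
        ]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.calls, axis=0)
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.isnan(self.calls).mean(axis=1)


@dataclass
class ExpressionMatrix:
    """Gene-level abundance, genes x samples (raw or normalised counts)."""

    counts: pd.DataFrame  # index genes, columns samples

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class CovariateTable:
    """Per-sample covariates, indexed by sample id.

    Typical columns: diagnosis (0/1 AD status), study, sex, age_death,
    education, pmi, rin, batch and ancestry PCs named ``pc1..pc10``.
    """

    data: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def pcs(self, k: int) -> pd.DataFrame:
        cols = [c for c in self.data.columns if re.fullmatch(r"pc\d+", c)]
        cols = sorted(cols, key=lambda c: int(c[2:]))[:k]
        return self.data[cols]


# ---------------------------------------------------------------------------
# pileup parsing
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _parse_base_string(bases: str, ref: str, line_no: int) -> dict[str, int]:
    """Resolve an mpileup read-base string into allele counts.

    Handles '.'/',' (ref match), ACGTacgt (substitution), '+n<seq>'/'-n<seq>'
    (indel attached to the preceding read), '^q' read-start markers (the
    following character is a mapping quality, not a base), '$' read ends and
    '*' deletion placeholders.
    """
    counts: dict[str, int] = {ref: 0}
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # skip caret and the mapping-quality char
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases, i)
            if m is None:
                raise ParseError(f"line {line_no}: malformed indel in {bases!r}")
            length = int(m.group(1))
            seq = bases[m.end() : m.end() + length].upper()
            if len(seq) != length:
                raise ParseError(f"line {line_no}: truncated indel in {bases!r}")
            allele = f"{ref}+{seq}" if ch == "+" else f"{ref}-{seq}"
            # the indel replaces the preceding match/mismatch call
            prev = bases[i - 1]
            if prev in ".,":
                counts[ref] -= 1
            elif prev.upper() in "ACGTN":
                counts[prev.upper()] -= 1
                if counts[prev.upper()] == 0:
                    del counts[prev.upper()]
            counts[allele] = counts.get(allele, 0) + 1
            i = m.end() + length
            continue
        if ch in ".,":
            counts[ref] += 1
        elif ch.upper() in "ACGTN":
            counts[ch.upper()] = counts.get(ch.upper(), 0) + 1
        elif ch == "*":
            counts["*"] = counts.get("*", 0) + 1
        else:
            raise ParseError(f"line {line_no}: unexpected character {ch!r} in {bases!r}")
        i += 1
    return counts


def read_pileup(
    path: str | Path,
    dialect: str = "mpileup_text",
    sample_id: str | None = None,
    mt_length: int = MT_LENGTH_HG19,
) -> PileupTable:
    """Read per-site allele counts for one sample.

    ``mpileup_text`` expects the 6-column samtools output
    (chrom, pos, ref, depth, bases, quals); base qualities are ignored.
    ``counts_tsv`` expects a header line ``position  ref  counts`` with
    counts encoded as ``allele:count`` pairs joined by commas.
    """
    path = Path(path)
    if dialect not in ("mpileup_text", "counts_tsv"):
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    if sample_id is None:
        sample_id = path.stem

    records: list[tuple[int, str, dict[str, int]]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "counts_tsv" and lines and lines[0].startswith("position"):
        lines = lines[1:]
    if not lines:
        raise ParseError(f"{path}: no records")

    for line_no, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if dialect == "mpileup_text":
            if len(fields) < 5:
                raise ParseError(f"line {line_no}: expected >=5 mpileup columns")
            _, pos_s, ref, depth_s, bases = fields[:5]
            ref = ref.upper()
            if int(depth_s) == 0:
                # samtools prints "*\t*" placeholders at uncovered sites
                counts = {ref: 0}
            else:
                counts = _parse_base_string(bases, ref, line_no)
            total = sum(counts.values())
            if total != int(depth_s):
                raise ParseError(
                    f"line {line_no}: parsed depth {total} != stated depth {depth_s}"
                )
        else:
            if len(fields) != 3:
                raise ParseError(f"line {line_no}: expected 3 counts_tsv columns")
            pos_s, ref, counts_s = fields
            ref = ref.upper()
            counts = {}
            for pair in counts_s.split(","):
                allele, _, cnt = pair.partition(":")
                if not cnt:
                    raise ParseError(f"line {line_no}: malformed counts {counts_s!r}")
                counts[allele] = counts.get(allele, 0) + int(cnt)
        counts.setdefault(ref, 0)
        records.append((int(pos_s), ref, counts))

    rows = pd.DataFrame(records, columns=["position", "ref", "counts"])
    return PileupTable(sample_id=sample_id, rows=rows, mt_length=mt_length)


def write_pileup(table: PileupTable, path: str | Path, dialect: str = "counts_tsv") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "counts_tsv":
            fh.write("position\tref\tcounts\n")
            for r in table.rows.itertuples():
                pairs = ",".join(f"{a}:{c}" for a, c in sorted(r.counts.items()))
                fh.write(f"{r.position}\t{r.ref}\t{pairs}\n")
        elif dialect == "mpileup_text":
            for r in table.rows.itertuples():
                bases = []
                for allele, cnt in sorted(r.counts.items()):
                    if allele == r.ref:
                        bases.append("." * cnt)
                    elif allele.startswith(f"{r.ref}+"):
                        ins = allele.split("+", 1)[1]
                        bases.append(f".+{len(ins)}{ins}" * cnt)
                    elif allele.startswith(f"{r.ref}-"):
                        dele = allele.split("-", 1)[1]
                        bases.append(f".-{len(dele)}{dele}" * cnt)
                    else:
                        bases.append(allele * cnt)
                depth = sum(r.counts.values())
                base_s = "".join(bases) if depth else "*"
                qual = "I" * max(depth, 1)
                fh.write(f"chrM\t{r.position}\t{r.ref}\t{depth}\t{base_s}\t{qual}\n")
        else:
            raise ValueError(f"unknown pileup dialect {dialect!r}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    dialect: str = "vcf_min",
    on_heterozygote: str = "error",
) -> GenotypeTable:
    """Read haploid MT genotype calls.

    VCF genotypes are mapped ``0``/``0/0`` -> 0, ``1``/``1/1`` -> 1,
    ``.``/``./.`` -> missing.  A true heterozygote (e.g. ``0/1``) has no
    haploid interpretation; by default it raises, with
    ``on_heterozygote='missing'`` it is recoded as missing.  Multiallelic
    records are split into one biallelic column per alt allele.
    """
    if on_heterozygote not in ("error", "missing"):
        raise ValueError("on_heterozygote must be 'error' or 'missing'")
    path = Path(path)
    if dialect == "vcf_min":
        return _read_vcf(path, on_heterozygote)
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path: Path, on_heterozygote: str) -> GenotypeTable:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants = []
    columns = []
    for rec in vcf:
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            col = np.full(len(samples), np.nan)
            for i, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:-1] if a != -1]
                if not alleles:
                    continue
                if len(set(alleles)) > 1:
                    if on_heterozygote == "error":
                        raise ParseError(
                            f"{path}: heterozygous MT call for sample "
                            f"{samples[i]} at position {rec.POS}"
                        )
                    continue
                col[i] = 1.0 if alleles[0] == alt_idx else 0.0
            variants.append(
                {"position": rec.POS, "ref": rec.REF, "alt": alt, "rsid": rec.ID or ""}
            )
            columns.append(col)
    if not variants:
        raise ParseError(f"{path}: no records")
    calls = np.column_stack(columns)
    return GenotypeTable(samples, pd.DataFrame(variants), calls)


def _read_genotype_tsv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    required = {"position", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: genotype TSV needs columns {sorted(required)}")
    meta_cols = [c for c in ("position", "ref", "alt", "rsid") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")
    variants = df[meta_cols].copy()
    if "rsid" not in variants:
        variants["rsid"] = ""
    calls = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeTable(sample_cols, variants.reset_index(drop=True), calls)


def write_genotypes(table: GenotypeTable, path: str | Path, dialect: str = "vcf_min",
                    mt_length: int = MT_LENGTH_HG19) -> None:
    path = Path(path)
    if dialect == "tsv":
        df = table.variants.copy()
        for i, s in enumerate(table.samples):
            col = table.calls[i]
            df[s] = col
        df.to_csv(path, sep="\t", index=False, float_format="%g")
        return
    if dialect != "vcf_min":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chrM,length={mt_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        for j, v in enumerate(table.variants.itertuples()):
            gts = []
            for i in range(len(table.samples)):
                g = table.calls[i, j]
                gts.append("." if np.isnan(g) else str(int(g)))
            rsid = v.rsid or "."
            fh.write(
                f"chrM\t{int(v.position)}\t{rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression and covariates
# ---------------------------------------------------------------------------


def _check_duplicate_header(path: Path) -> None:
    # pandas mangles duplicate column names on read; inspect the raw header
    with open(path) as fh:
        for line in fh:
            if line.strip():
                cols = line.rstrip("\n").split("\t")[1:]
                dup = sorted({c for c in cols if cols.count(c) > 1})
                if dup:
                    raise ParseError(f"{path}: duplicate sample ids {dup}")
                return
    raise ParseError(f"{path}: no records")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: no records")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dup}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id", float_format="%g")


def read_covariates(path: str | Path) -> CovariateTable:
    path = Path(path)
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: no records")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%g")


def reconcile_samples(*tables: Iterable[str]) -> dict[str, list[str]]:
    """Report sample ids missing from at least one table.

    Returns a mapping ``table_index -> ids absent from that table`` for ids
    present anywhere; an empty dict means all tables agree.
    """
    sets = [set(t) for t in tables]
    universe = set().union(*sets)
    report = {}
    for i, s in enumerate(sets):
        missing = sorted(universe - s)
        if missing:
            report[f"table_{i}"] = missing
    return report
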