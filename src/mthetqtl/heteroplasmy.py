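"""Per-site heteroplasmy calling and weighted heteroplasmy scores.

A site is heteroplasmic when the alternate-allele read fraction f lies
strictly inside the open band (0.05, 0.95); sites with f <= 0.05 are
called absent and sites with f >= 0.95 are stably inherited variants.
Heteroplasmy scores weight each heteroplasmic site by its fraction and sum
over two amplicon windows of the control region:

    het16043 = sum over 16043..16238 of 1{0.05 < f < 0.95} * f
    het16469 = sum over 1..262 and 16469..L_MT of 1{0.05 < f < 0.95} * f
    het_total = het16043 + het16469

The second window wraps across the origin of the circular MT genome; on
hg19 chrM (L_MT = 16571) its two arcs are 16469..16571 and 1..262.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mt_io import MT_LENGTH_HG19, PileupTable

ABSENT = "absent"
HETEROPLASMIC = "heteroplasmic"
STABLE = "stable_variant"
NO_COVERAGE = "no_coverage"

#: default score windows, 1-based inclusive on the circle (hg19 chrM)
WINDOW_16043 = (16043, 16238)
WINDOW_16469 = (16469, 262)  # wraps through the origin


@dataclass
class HeteroplasmyCall:
    sample_id: str
    position: int
    ref: str
    alt: str | None
    alt_fraction: float  # NaN when no coverage
    status: str

    @property
    def measure(self) -> float:
        """Score contribution: the fraction for heteroplasmic sites, else 0."""
        return self.alt_fraction if self.status == HETEROPLASMIC else 0.0


@dataclass
class HetScore:
    sample_id: str
    het16043: float
    het16469: float

    @property
    def het_total(self) -> float:
        return self.het16043 + self.het16469


@dataclass
class HetPresenceMatrix:
    """Binary heteroplasmy presence, samples x sites.

    ``presence`` holds the sites retained for QTL analysis (detected in at
    least ``min_carriers`` samples); ``total_het_sites`` counts every
    heteroplasmic call per sample, including sites dropped by the carrier
    filter.
    """

    presence: pd.DataFrame  # index samples, columns site positions, values 0/1
    total_het_sites: pd.Series
    min_carriers: int

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def sites(self) -> list[int]:
        return list(self.presence.columns)


def call_heteroplasmy(
    pileup: PileupTable, lower: float = 0.05, upper: float = 0.95
) -> list[HeteroplasmyCall]:
    """Call heteroplasmy status at every covered position of one sample.

    The alternate fraction is the count of the single most frequent
    non-reference allele divided by total depth; additional minor alleles
    contribute to the denominator only.  Zero-depth rows yield
    ``no_coverage`` with an undefined (NaN) fraction.
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError(f"need 0 <= lower < upper <= 1, got ({lower}, {upper})")
    calls = []
    for row in pileup.rows.itertuples():
        counts: dict[str, int] = row.counts
        depth = sum(counts.values())
        if depth == 0:
            calls.append(
                HeteroplasmyCall(pileup.sample_id, row.position, row.ref, None,
                                 float("nan"), NO_COVERAGE)
            )
            continue
        alts = {a: c for a, c in counts.items() if a != row.ref}
        if alts:
            # deterministic tie-break: larger count, then allele string
            alt, alt_count = max(alts.items(), key=lambda kv: (kv[1], kv[0]))
        else:
            alt, alt_count = None, 0
        frac = alt_count / depth
        if frac <= lower:
            status = ABSENT
        elif frac >= upper:
            status = STABLE
        else:
            status = HETEROPLASMIC
        calls.append(
            HeteroplasmyCall(pileup.sample_id, row.position, row.ref, alt, frac, status)
        )
    return calls


def _window_positions(window: tuple[int, int], mt_length: int) -> set[int]:
    lo, hi = window
    if not (1 <= lo <= mt_length and 1 <= hi <= mt_length):
        raise ValueError(f"window {window} outside 1..{mt_length}")
    if lo <= hi:
        return set(range(lo, hi + 1))
    # wrap across the origin: two arcs lo..L_MT and 1..hi
    return set(range(lo, mt_length + 1)) | set(range(1, hi + 1))


def het_score(
    calls: list[HeteroplasmyCall],
    w1: tuple[int, int] = WINDOW_16043,
    w2: tuple[int, int] = WINDOW_16469,
    mt_length: int = MT_LENGTH_HG19,
) -> HetScore:
    """Compute the weighted heteroplasmy score triplet for one sample."""
    if not calls:
        raise ValueError("no calls given")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    set1 = _window_positions(w1, mt_length)
    set2 = _window_positions(w2, mt_length)
    if set1 & set2:
        raise ValueError(f"score windows {w1} and {w2} overlap")
    s1 = sum(c.measure for c in calls if c.position in set1 and c.status == HETEROPLASMIC)
    s2 = sum(c.measure for c in calls if c.position in set2 and c.status == HETEROPLASMIC)
    return HetScore(sample_id=sample_ids.pop(), het16043=s1, het16469=s2)


def score_table(scores: list[HetScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "het16043": [s.het16043 for s in scores],
            "het16469": [s.het16469 for s in scores],
            "het_total": [s.het_total for s in scores],
        }
    ).set_index("sample_id")


def calls_table(all_calls: list[HeteroplasmyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in all_calls],
            "position": [c.position for c in all_calls],
            "ref": [c.ref for c in all_calls],
            "alt": [c.alt or "" for c in all_calls],
            "alt_fraction": [c.alt_fraction for c in all_calls],
            "status": [c.status for c in all_calls],
        }
    )


def presence_matrix(
    all_calls: list[HeteroplasmyCall], min_carriers: int = 5
) -> HetPresenceMatrix:
    """Build the samples x sites presence matrix used by QTL models.

    Sites carried by fewer than ``min_carriers`` samples are dropped from
    the QTL-ready matrix; per-sample totals keep every heteroplasmic call.
    """
    if not all_calls:
        raise ValueError("no calls given")
    df = calls_table(all_calls)
    samples = list(dict.fromkeys(df["sample_id"]))
    het = df[df["status"] == HETEROPLASMIC]
    sites = sorted(het["position"].unique())
    presence = pd.DataFrame(0, index=samples, columns=sites, dtype=int)
    for r in het.itertuples():
        presence.at[r.sample_id, r.position] = 1
    totals = presence.sum(axis=1)
    carriers = presence.sum(axis=0)
    keep = [s for s in sites if carriers[s] >= min_carriers]
    return HetPresenceMatrix(
        presence=presence[keep], total_het_sites=totals, min_carriers=min_carriers
    )
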