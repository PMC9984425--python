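"""GWAS summary-statistic standardization and harmonization.

Summary statistics arrive in heterogeneous shapes: effect sizes as beta or
odds ratios, standard errors sometimes missing, non-effect alleles sometimes
absent, and alleles reported on either strand.  This module standardizes
records to a single convention — beta per copy of the reference panel's alt
allele, with SE recovered from the P value where necessary — and reports
exactly what happened to every input record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMSTAT_COLUMNS = ["chrom", "pos", "rsid", "ea", "nea", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start ({self.start}) exceeds end ({self.end})"
            )
        if self.start < 1:
            raise ValueError("1-based interval start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return iv.length


@dataclass
class AssociationRecord:
    """One variant's summary statistics for one trait.

    ``beta`` is on the trait scale per effect-allele copy (log-OR if the
    source reported an odds ratio); ``nea`` may be empty when the source
    omitted the non-effect allele.
    """

    chrom: str
    pos: int
    rsid: str
    ea: str
    nea: str
    beta: float
    se: float
    p: float
    n: int

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class HarmonizationReport:
    """Counts of what harmonization did to each input record."""

    n_input: int = 0
    kept: int = 0
    sign_flipped: int = 0
    strand_flipped: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


def estimate_se_from_p(beta: float, p: float) -> float:
    """Recover the standard error from an effect size and a two-sided P value.

    Under a two-sided normal test, |z| = Q(1 - p/2) with Q the standard
    normal quantile, so se = |beta| / Q(1 - p/2).

    Raises ``ValueError`` for p outside (0, 1) or beta == 0, where the
    quantity is undefined.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1); got {p}")
    if beta == 0:
        raise ValueError("se cannot be recovered when beta is 0")
    q = stats.norm.isf(p / 2.0)
    if q <= 0:
        raise ValueError(f"degenerate quantile for p={p}")
    return abs(beta) / q


def or_to_beta(
    odds_ratio: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    p: float | None = None,
) -> tuple[float, float]:
    """Convert an odds ratio to (beta, se) on the log scale.

    SE comes from the log-scale 95% confidence bounds when present,
    otherwise it is recovered from the P value.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    beta = math.log(odds_ratio)
    if ci_low is not None and ci_high is not None:
        if not (0 < ci_low <= odds_ratio <= ci_high):
            raise ValueError("confidence bounds must bracket the odds ratio")
        se = (math.log(ci_high) - math.log(ci_low)) / (2 * stats.norm.isf(0.025))
    elif p is not None:
        se = estimate_se_from_p(beta, p)
    else:
        raise ValueError("need either confidence bounds or a P value")
    return beta, se


def _panel_site_index(panel) -> dict[tuple[str, int], tuple[str, str]]:
    tbl = panel.variants
    return {
        (str(c), int(q)): (str(r), str(a))
        for c, q, r, a in zip(tbl["chrom"], tbl["pos"], tbl["ref"], tbl["alt"])
    }


def infer_noneffect_allele(
    record: AssociationRecord, panel
) -> AssociationRecord | None:
    """Fill in a missing non-effect allele from the panel's biallelic site.

    Returns the completed record, or ``None`` when the site is absent from
    the panel or its alleles do not contain the effect allele.
    """
    site = _panel_site_index(panel).get((record.chrom, record.pos))
    if site is None:
        return None
    ref, alt = site
    if record.ea == ref:
        nea = alt
    elif record.ea == alt:
        nea = ref
    else:
        return None
    return AssociationRecord(
        record.chrom, record.pos, record.rsid, record.ea, nea,
        record.beta, record.se, record.p, record.n,
    )


def harmonize_to_panel(
    records: pd.DataFrame, panel
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align summary statistics to the panel's ref/alt orientation.

    After harmonization every beta is expressed per copy of the panel's
    *alt* allele.  Records are matched by (chrom, pos); allele handling:

    * ea==alt, nea==ref: kept as-is.
    * ea==ref, nea==alt: beta sign flipped (allele swap).
    * complementary-strand matches of either orientation: bases
      complemented first (strand flip), then as above.
    * palindromic variants (A/T, C/G): dropped unconditionally.
    * missing nea: inferred from the panel when the effect allele is one
      of the site's two alleles, else dropped.
    * unresolvable alleles or sites absent from the panel: dropped.

    Duplicate records at one (chrom, pos) are an error.
    """
    report = HarmonizationReport(n_input=len(records))
    sites = _panel_site_index(panel)

    dup = records.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        where = records.loc[dup, ["chrom", "pos"]].drop_duplicates()
        locs = ", ".join(f"{c}:{q}" for c, q in where.itertuples(index=False))
        raise ValueError(f"duplicate summary records at: {locs}")

    rows = []
    for rec in records.itertuples(index=False):
        chrom, pos = str(rec.chrom), int(rec.pos)
        rsid = getattr(rec, "rsid", "") or ""
        if (pd.isna(rec.chrom) or pd.isna(rec.pos)) and not rsid:
            report.drop("missing_coords_and_id")
            continue
        site = sites.get((chrom, pos))
        if site is None:
            report.drop("not_in_panel")
            continue
        ref, alt = site
        ea = str(rec.ea).upper()
        nea = "" if pd.isna(rec.nea) or rec.nea == "" else str(rec.nea).upper()
        if not nea:
            if ea == ref:
                nea = alt
            elif ea == alt:
                nea = ref
            else:
                report.drop("undetermined_noneffect_allele")
                continue
        if (ea, nea) in _PALINDROMIC:
            report.drop("ambiguous_palindromic")
            continue
        beta = float(rec.beta)
        strand_flipped = False
        if {ea, nea} != {ref, alt}:
            cea = _COMPLEMENT.get(ea)
            cnea = _COMPLEMENT.get(nea)
            if cea is not None and {cea, cnea} == {ref, alt}:
                ea, nea = cea, cnea
                strand_flipped = True
            else:
                report.drop("allele_mismatch")
                continue
        if ea == ref:  # effect reported for panel ref: orient to alt
            beta = -beta
            ea, nea = alt, ref
            report.sign_flipped += 1
        if strand_flipped:
            report.strand_flipped += 1
        report.kept += 1
        rows.append(
            dict(chrom=chrom, pos=pos, rsid=rsid, ea=ea, nea=nea,
                 beta=beta, se=float(rec.se), p=float(rec.p), n=int(rec.n))
        )

    out = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    assert report.kept + report.n_dropped == report.n_input
    return out, report


def zscores(table: pd.DataFrame) -> np.ndarray:
    """beta/se for each row of a standardized summary table."""
    return np.asarray(table["beta"], float) / np.asarray(table["se"], float)
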