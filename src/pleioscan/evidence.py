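"""Evidence aggregation and candidate causal-regulatory-variant ranking.

A variant is a candidate causal regulatory variant iff all four evidence
conditions hold:

  1. reproduced pleiotropy: shared-model posterior pp3 >= 0.9 for at
     least one trait pair;
  2. fine-mapped: member of a 95% credible set for at least one trait;
  3. colocalized: RTC >= 0.9 against at least one eQTL dataset;
  4. regulatory: regBase PHRED >= 15 and cepip combined >= 0.6 and
     RegulomeDB category at least as strong as 2c.

All comparisons are inclusive, matching the thresholds as printed.
Candidates are ranked by the number of autoimmune diseases they are
estimated to share, ties broken by genomic position.  Target genes are
assigned from chromatin-interaction (PCHi-C-style) regions with score
strictly above 5, colocalized eGenes, and direct protein/splice
consequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .sumstats import GenomicInterval

REGULOMEDB_ORDER = [
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6", "7",
]

PP3_THRESHOLD = 0.9
RTC_THRESHOLD = 0.9
REGBASE_PHRED_THRESHOLD = 15.0
CEPIP_THRESHOLD = 0.6
REGULOMEDB_THRESHOLD = "2c"
PCHIC_SCORE_THRESHOLD = 5.0  # strict


@dataclass
class AnnotationScores:
    """External regulatory-potential scores for one variant."""

    regbase_phred: float
    cepip_combined: float
    regulomedb_category: str

    def __post_init__(self) -> None:
        if self.regulomedb_category not in REGULOMEDB_ORDER:
            raise ValueError(
                f"unknown RegulomeDB category {self.regulomedb_category!r}"
            )


@dataclass
class EvidenceProfile:
    """The four evidence flags plus ranking inputs for one variant."""

    variant_id: str
    chrom: str
    pos: int
    reproduced_pleiotropy: bool
    fine_mapped: bool
    colocalized: bool
    regulatory: bool
    shared_disease_count: int = 0

    @property
    def candidate(self) -> bool:
        return (
            self.reproduced_pleiotropy
            and self.fine_mapped
            and self.colocalized
            and self.regulatory
        )


@dataclass
class InteractionRegion:
    """A chromatin-interaction region linking an interval to a bait gene."""

    interval: GenomicInterval
    bait_gene: str
    score: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.score):
            raise ValueError("interaction score must be finite")


def regulomedb_at_least(category: str, threshold: str = REGULOMEDB_THRESHOLD) -> bool:
    """True iff ``category`` is at least as strong as ``threshold`` in the
    RegulomeDB 1a..7 ladder (lower index = stronger evidence)."""
    try:
        ci = REGULOMEDB_ORDER.index(category)
    except ValueError:
        raise ValueError(f"unknown RegulomeDB category {category!r}") from None
    try:
        ti = REGULOMEDB_ORDER.index(threshold)
    except ValueError:
        raise ValueError(f"unknown RegulomeDB category {threshold!r}") from None
    return ci <= ti


def evidence_flags(
    variant_id: str,
    chrom: str,
    pos: int,
    pleiotropy: Mapping[str, tuple[float, int]],
    finemap: Mapping[str, bool],
    rtc: Mapping[str, float],
    scores: AnnotationScores | None,
) -> EvidenceProfile:
    """Compute the four evidence flags for one variant.

    ``pleiotropy`` maps variant -> (max pp3 over trait pairs, shared
    disease count); ``finemap`` maps variant -> credible-set membership;
    ``rtc`` maps variant -> max RTC over eQTL datasets.  A variant absent
    from a table gets that flag False (a declared evidence gap), and a
    missing annotation row fails the regulatory flag.
    """
    pp3, n_shared = pleiotropy.get(variant_id, (0.0, 0))
    regulatory = False
    if scores is not None:
        regulatory = (
            scores.regbase_phred >= REGBASE_PHRED_THRESHOLD
            and scores.cepip_combined >= CEPIP_THRESHOLD
            and regulomedb_at_least(scores.regulomedb_category)
        )
    return EvidenceProfile(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        reproduced_pleiotropy=pp3 >= PP3_THRESHOLD,
        fine_mapped=bool(finemap.get(variant_id, False)),
        colocalized=rtc.get(variant_id, 0.0) >= RTC_THRESHOLD,
        regulatory=regulatory,
        shared_disease_count=n_shared,
    )


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = str(chrom).removeprefix("chr")
    return (0, f"{int(c):09d}") if c.isdigit() else (1, c)


def rank_candidates(profiles: Iterable[EvidenceProfile]) -> list[EvidenceProfile]:
    """Candidates ordered by descending shared-disease count, ties broken
    by (chrom, pos) ascending; non-candidates are excluded."""
    cands = [p for p in profiles if p.candidate]
    return sorted(
        cands,
        key=lambda p: (-p.shared_disease_count, _chrom_key(p.chrom), p.pos),
    )


def assign_target_genes(
    chrom: str,
    pos: int,
    regions: Iterable[InteractionRegion] = (),
    egenes: Iterable[str] = (),
    consequence_genes: Iterable[str] = (),
) -> dict[str, set[str]]:
    """Target genes of one variant, each tagged by evidence source.

    Sources: 'PCHi-C' for bait genes of overlapping interaction regions
    with score strictly > 5, 'eQTL' for colocalized eGenes, and
    'consequence' for genes whose protein product or splicing the variant
    alters directly.
    """
    out: dict[str, set[str]] = {}
    for region in regions:
        if region.score > PCHIC_SCORE_THRESHOLD and region.interval.contains(
            chrom, pos
        ):
            out.setdefault(region.bait_gene, set()).add("PCHi-C")
    for gene in egenes:
        out.setdefault(gene, set()).add("eQTL")
    for gene in consequence_genes:
        out.setdefault(gene, set()).add("consequence")
    return out
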