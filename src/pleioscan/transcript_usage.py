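"""Promoter-usage transcript groups and genotype association.

Genes with alternative promoters (the IRF5 long/short pattern) partition
their transcripts by whether the transcription start site lies upstream
of a breakpoint — typically the chromatin-contact locus with the highest
interaction frequency — in the gene's strand sense.  Group-level TPM
sums are then tested for association with a variant's dosage by ordinary
least squares; a promoter-switch variant shows opposite-signed slopes
for the two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

LONG = "long"
SHORT = "short"


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    gene: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-'; got {self.strand!r}")
        if self.tss < 1:
            raise ValueError("TSS must be a positive 1-based coordinate")


@dataclass
class UsageQTLResult:
    group: str
    beta: float
    se: float
    p: float
    n: int


def classify_transcripts(
    annotations: Iterable[TranscriptAnnotation], breakpoint: int
) -> dict[str, str]:
    """Map each transcript to 'long' or 'short' relative to a breakpoint.

    A transcript is long iff its TSS is upstream of the breakpoint in the
    gene's strand sense (+ strand: TSS < breakpoint; - strand:
    TSS > breakpoint); a TSS exactly at the breakpoint is classified
    short (the downstream-promoter side) with a warning.
    """
    mapping: dict[str, str] = {}
    for a in annotations:
        if a.tss == breakpoint:
            warnings.warn(
                f"TSS of {a.transcript_id} coincides with the breakpoint; "
                "classified short"
            )
            mapping[a.transcript_id] = SHORT
        elif (a.strand == "+" and a.tss < breakpoint) or (
            a.strand == "-" and a.tss > breakpoint
        ):
            mapping[a.transcript_id] = LONG
        else:
            mapping[a.transcript_id] = SHORT
    return mapping


def group_tpm(
    tpm: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample long/short TPM sums from a samples x transcripts matrix.

    Every transcript column must be mapped; long + short equals the total
    gene TPM by construction.
    """
    unmapped = [t for t in tpm.columns if t not in mapping]
    if unmapped:
        raise KeyError(f"unmapped transcripts: {unmapped}")
    long_cols = [t for t in tpm.columns if mapping[t] == LONG]
    short_cols = [t for t in tpm.columns if mapping[t] == SHORT]
    return pd.DataFrame(
        {
            LONG: tpm[long_cols].sum(axis=1) if long_cols else 0.0,
            SHORT: tpm[short_cols].sum(axis=1) if short_cols else 0.0,
        },
        index=tpm.index,
    )


def usage_qtl(dosage, expression, group: str = LONG) -> UsageQTLResult:
    """OLS association of group-level TPM with alt-allele dosage."""
    x = np.asarray(dosage, float)
    y = np.asarray(expression, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0:
        raise ValueError("constant dosage")
    if y.std() == 0:
        raise ValueError("constant expression")
    fit = stats.linregress(x, y)
    return UsageQTLResult(
        group=group, beta=fit.slope, se=fit.stderr, p=fit.pvalue, n=n
    )
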