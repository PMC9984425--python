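"""Regulatory trait concordance (RTC) colocalization scoring.

RTC asks whether a GWAS sentinel variant and an eQTL share a causal
variant within one recombination-hotspot interval.  For every variant s
in the interval, gene expression is residualized on the covariates plus
s's dosage, and the eQTL lead variant is re-tested against the residuals;
if the sentinel tags the eQTL's causal variant, conditioning on it
extinguishes the eQTL signal better than conditioning on most other
variants.  Variants are ranked by how well they extinguish the signal
(ascending residual association); with Rank the sentinel's 0-based
position among N_int interval variants,

    RTC = (N_int - Rank) / N_int,

so RTC = 1 means the sentinel is the best extinguisher, and RTC >= 0.9
is called colocalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import GenomicInterval

RTC_THRESHOLD = 0.9


@dataclass
class RTCInput:
    """One sentinel/eQTL pair with its interval's genotypes."""

    interval: GenomicInterval
    variant_ids: list[str]
    positions: list[int]
    dosages: np.ndarray  # samples x interval variants
    expression: np.ndarray
    covariates: np.ndarray | None
    sentinel_id: str
    lead_id: str

    def __post_init__(self) -> None:
        n, v = self.dosages.shape
        if v != len(self.variant_ids) or v != len(self.positions):
            raise ValueError("dosage columns must match variant ids/positions")
        if len(self.expression) != n:
            raise ValueError("expression length must match sample count")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows must match sample count")
        for vid, what in ((self.sentinel_id, "sentinel"), (self.lead_id, "lead")):
            if vid not in self.variant_ids:
                raise KeyError(f"{what} variant {vid!r} absent from interval")


@dataclass
class RTCResult:
    n_int: int
    rank: int
    rtc: float
    sentinel_id: str
    lead_id: str

    @property
    def colocalized(self) -> bool:
        return colocalized(self, RTC_THRESHOLD)


def colocalized(result: RTCResult, threshold: float = RTC_THRESHOLD) -> bool:
    """Colocalization call: RTC at or above the threshold (inclusive)."""
    return result.rtc >= threshold


def genotype_pcs(dosages: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal-component scores of the centered dosage matrix.

    Deterministic up to sign; the sign of each component is fixed by
    making its largest-magnitude variant loading positive.
    """
    X = np.asarray(dosages, float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if rank < k:
        warnings.warn(f"rank {rank} < k={k}; returning {rank} component(s)")
        k = rank
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def residualize(y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on X (an intercept is always added).

    Collinear columns are handled by the pseudoinverse solution; residuals
    are orthogonal to every column of X.
    """
    y = np.asarray(y, float)
    if X is None or X.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def rank_inverse_normal(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset 3/8)."""
    y = np.asarray(y, float)
    n = len(y)
    ranks = stats.rankdata(y)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _lead_stat(expr_resid: np.ndarray, g_lead: np.ndarray) -> float:
    """Squared t statistic of the lead dosage against residual expression."""
    x = g_lead - g_lead.mean()
    y = expr_resid - expr_resid.mean()
    sxx = float(x @ x)
    if sxx == 0:
        return 0.0
    beta = float(x @ y) / sxx
    n = len(y)
    rss = float(y @ y) - beta * float(x @ y)
    df = n - 2
    sigma2 = max(rss, 0.0) / df
    if sigma2 == 0:
        return np.inf
    return beta * beta / (sigma2 / sxx)


def rtc_score(inp: RTCInput, transform: bool = True) -> RTCResult:
    """RTC score of one sentinel/eQTL-lead pair.

    For each interval variant s, expression is residualized on the
    covariates plus dosage(s) and the lead's squared t statistic is
    computed against the residuals; variants are ranked ascending by that
    statistic (ties broken by genomic position), and the sentinel's rank
    yields RTC = (N_int - Rank) / N_int.
    """
    expr = np.asarray(inp.expression, float)
    if transform:
        expr = rank_inverse_normal(expr)
    g_lead = inp.dosages[:, inp.variant_ids.index(inp.lead_id)].astype(float)
    n_int = len(inp.variant_ids)

    stats_per_variant = np.empty(n_int)
    for j in range(n_int):
        covs = inp.dosages[:, [j]].astype(float)
        if inp.covariates is not None:
            covs = np.column_stack([inp.covariates, covs])
        resid = residualize(expr, covs)
        stats_per_variant[j] = _lead_stat(resid, g_lead)

    order = sorted(range(n_int), key=lambda j: (stats_per_variant[j], inp.positions[j]))
    rank = order.index(inp.variant_ids.index(inp.sentinel_id))
    rtc = (n_int - rank) / n_int
    return RTCResult(
        n_int=n_int, rank=rank, rtc=rtc,
        sentinel_id=inp.sentinel_id, lead_id=inp.lead_id,
    )
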