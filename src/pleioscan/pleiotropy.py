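"""Block-wise pairwise pleiotropy posteriors with MeSH-derived overlap.

For a pair of traits and one LD block, five models compete: no
association (0), trait-1-only (1), trait-2-only (2), one shared causal
variant (3), and two distinct causal variants (4).  Per-variant Bayes
factors are combined into block-level model scores and normalized to
posteriors; a posterior of the shared model (pp3) at or above 0.9 flags a
reproduced pleiotropic signal.

When the two GWAS come from one cohort, their test statistics are
correlated under the null.  The expected null correlation C is set from
how related the two diseases are in the MeSH tree: relationship level L
(longest common prefix of the dotted tree numbers, capped at 5) maps to
C = 0.09 * L, the ladder 0.09, 0.18, 0.27, 0.36, 0.45; distinct-cohort
pairs use C = 0.  C enters the shared-model Bayes factor through the
bivariate normal density of the two Z scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

MAX_MESH_LEVEL = 5
CORRELATION_STEP = 0.09
SHARED_PP_THRESHOLD = 0.9


@dataclass(frozen=True)
class MeshTreeNumber:
    """A dotted MeSH tree number, e.g. C06.405.469.432.249."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components or any(not c for c in self.components):
            raise ValueError("MeSH tree number needs non-empty components")

    def __str__(self) -> str:
        return ".".join(self.components)


def parse_mesh(tree_number: str) -> MeshTreeNumber:
    parts = tuple(p.strip() for p in str(tree_number).split("."))
    if not parts or any(not p for p in parts):
        raise ValueError(f"unparseable MeSH tree number: {tree_number!r}")
    return MeshTreeNumber(parts)


def mesh_relationship_level(a: MeshTreeNumber | str, b: MeshTreeNumber | str) -> int:
    """Relationship level: longest common component prefix, capped at 5."""
    if isinstance(a, str):
        a = parse_mesh(a)
    if isinstance(b, str):
        b = parse_mesh(b)
    level = 0
    for x, y in zip(a.components, b.components):
        if x != y:
            break
        level += 1
    return min(level, MAX_MESH_LEVEL)


def expected_correlation(level: int, same_cohort: bool) -> float:
    """Expected null correlation of two traits' summary statistics.

    Distinct cohorts: 0.  Same cohort: 0.09 per MeSH relationship level,
    the ladder 0.09 ... 0.45.
    """
    if level < 0:
        raise ValueError("relationship level must be >= 0")
    if not same_cohort:
        return 0.0
    return round(CORRELATION_STEP * min(level, MAX_MESH_LEVEL), 10)


@dataclass
class OverlapSpec:
    """Cohort relation and the null correlation it implies."""

    level: int
    same_cohort: bool

    @property
    def correlation(self) -> float:
        return expected_correlation(self.level, self.same_cohort)


@dataclass
class PleiotropyPriors:
    """Per-variant prior probabilities for the four non-null models.

    These play the role the genome-wide empirical-Bayes priors play in a
    full-scale scan; at desk scale they are fixed and configurable.
    """

    pi1: float = 1e-4
    pi2: float = 1e-4
    pi3: float = 1e-5
    pi4: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("pi1", "pi2", "pi3", "pi4"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"prior {name} must lie in (0, 1); got {v}")


@dataclass
class ModelPosteriors:
    """Posterior probabilities of the five block models."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.as_array()))


def log_joint_abf_shared(z1, z2, V1, V2, C: float, W1: float, W2: float):
    """Log Bayes factor for one variant being causal for both traits.

    The Z-score pair is N(0, Sigma) under the null with
    Sigma = [[1, C], [C, 1]], and N(0, Sigma + Lambda) under the shared
    alternative with Lambda = diag(W1/V1, W2/V2); the BF is the density
    ratio, evaluated in log space.  With C = 0 it factorizes into the two
    marginal Wakefield ABFs.
    """
    if not abs(C) < 1.0:
        raise ValueError("|C| must be < 1")
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    V1 = np.asarray(V1, float)
    V2 = np.asarray(V2, float)
    if np.any(V1 <= 0) or np.any(V2 <= 0):
        raise ValueError("sampling variances must be positive")

    a1 = 1.0 + W1 / V1  # alt marginal variances of the Z scores
    a2 = 1.0 + W2 / V2

    det0 = 1.0 - C * C
    det1 = a1 * a2 - C * C
    # quadratic forms z' Sigma^{-1} z for 2x2 covariances
    q0 = (z1 * z1 - 2.0 * C * z1 * z2 + z2 * z2) / det0
    q1 = (a2 * z1 * z1 - 2.0 * C * z1 * z2 + a1 * z2 * z2) / det1
    return 0.5 * (np.log(det0) - np.log(det1)) + 0.5 * (q0 - q1)


def _log1mexp(x: np.ndarray | float) -> float:
    """log(1 - exp(x)) for x <= 0, stable near both ends."""
    x = float(x)
    if x >= 0.0:
        return -np.inf
    if x > -0.693:
        return float(np.log(-np.expm1(x)))
    return float(np.log1p(-np.exp(x)))


def block_model_posteriors(
    log_bf1, log_bf2, log_bf_joint, priors: PleiotropyPriors | None = None
) -> ModelPosteriors:
    """Combine per-variant Bayes factors into five-model posteriors.

    Unnormalized block scores (k variants):
        S0 = 1
        S1 = pi1 * sum_i bf1_i
        S2 = pi2 * sum_i bf2_i
        S3 = pi3 * sum_i bf_joint_i
        S4 = pi4 * sum_{i != j} bf1_i * bf2_j
    normalized to pp0..pp4, all in log space.
    """
    priors = priors or PleiotropyPriors()
    lb1 = np.asarray(log_bf1, float)
    lb2 = np.asarray(log_bf2, float)
    lbj = np.asarray(log_bf_joint, float)
    k = lb1.size
    if k == 0 or lb2.size != k or lbj.size != k:
        raise ValueError("Bayes-factor vectors must be non-empty and equal length")

    ls1 = logsumexp(lb1)
    ls2 = logsumexp(lb2)
    ls12 = logsumexp(lb1 + lb2)  # diagonal of the product sum
    logS = np.empty(5)
    logS[0] = 0.0
    logS[1] = np.log(priors.pi1) + ls1
    logS[2] = np.log(priors.pi2) + ls2
    logS[3] = np.log(priors.pi3) + logsumexp(lbj)
    if k == 1:
        logS[4] = -np.inf
    else:
        total = ls1 + ls2
        logS[4] = np.log(priors.pi4) + total + _log1mexp(ls12 - total)
    pp = np.exp(logS - logsumexp(logS))
    return ModelPosteriors(*pp)


def is_shared_effect(
    posteriors: ModelPosteriors, threshold: float = SHARED_PP_THRESHOLD
) -> bool:
    """Shared-effect call: pp3 at or above the threshold (inclusive)."""
    return posteriors.pp3 >= threshold


def analyze_block_pair(
    summary1,
    summary2,
    C: float = 0.0,
    W1: float = 0.04,
    W2: float = 0.04,
    priors: PleiotropyPriors | None = None,
) -> ModelPosteriors:
    """Five-model posteriors for one block from two standardized summary
    tables (rows aligned on the same variants in the same order)."""
    from .finemap import log_abf

    if list(summary1["rsid"]) != list(summary2["rsid"]):
        raise ValueError("summary tables must cover identical variants in order")
    b1, s1 = np.asarray(summary1["beta"], float), np.asarray(summary1["se"], float)
    b2, s2 = np.asarray(summary2["beta"], float), np.asarray(summary2["se"], float)
    lb1 = log_abf(b1, s1, W1)
    lb2 = log_abf(b2, s2, W2)
    lbj = log_joint_abf_shared(b1 / s1, b2 / s2, s1**2, s2**2, C, W1, W2)
    return block_model_posteriors(lb1, lb2, lbj, priors)
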