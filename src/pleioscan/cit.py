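"""Causal inference test (CIT) for variant/cis-gene/trans-gene triplets.

For a triplet (L = genotype dosage, G = cis-gene expression, T =
trans-gene expression) the causal model L -> G -> T is supported when
four conditions hold simultaneously (an intersection-union test):

  1. L is associated with T                      (F-test, T ~ L)
  2. L is associated with G given T              (F-test, G ~ L + T)
  3. G is associated with T given L              (F-test, T ~ G + L)
  4. L is independent of T given G               (permutation equivalence
                                                  test)

Condition 4 is an equivalence test whose *null* is conditional
dependence: surrogate outcomes are generated under a direct (unmediated)
effect of L on T whose size equals the observed marginal slope, with L
permuted within tertile bins of G to preserve the L-G association, and
p4 is the proportion of dependence-null F statistics at or below the
observed F for L in T ~ G + L.  A small p4 therefore supports
conditional independence — the same orientation as p1..p3, so the
omnibus causal P value is simply max(p1, p2, p3, p4) and all four must
be small for a causal call.  The reactive model (L -> T -> G) swaps the
roles of G and T.  A triplet is classified causal/reactive/independent
by comparing both omnibus P values to a Bonferroni level
alpha = 0.05 / number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seeds import child_seed

ALPHA = 0.05
MIN_SAMPLES = 10


@dataclass
class Triplet:
    """Aligned sample vectors for one (variant, cis, trans) triplet."""

    L: np.ndarray
    G: np.ndarray
    T: np.ndarray
    variant_id: str = "variant"
    cis_id: str = "cis"
    trans_id: str = "trans"

    def __post_init__(self) -> None:
        n = len(self.L)
        if len(self.G) != n or len(self.T) != n:
            raise ValueError("triplet vectors must have equal length")
        if n < MIN_SAMPLES:
            raise ValueError(f"triplet needs >= {MIN_SAMPLES} samples")


@dataclass
class CITResult:
    variant_id: str
    cis_id: str
    trans_id: str
    causal_components: tuple[float, float, float, float]
    reactive_components: tuple[float, float, float, float]
    p_causal: float
    p_reactive: float
    classification: str | None = None


def prefilter_triplet(G, T, alpha: float = ALPHA) -> bool:
    """Keep a triplet iff its cis and trans expression are correlated
    (Pearson test P <= alpha); constant vectors are dropped."""
    G = np.asarray(G, float)
    T = np.asarray(T, float)
    if G.std() == 0 or T.std() == 0:
        return False
    return stats.pearsonr(G, T).pvalue <= alpha


def _partial_f_p(y, x, covars) -> tuple[float, float]:
    """1-df F test (and P) of x in the regression y ~ x + covars."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    if covars is None:
        X0 = np.ones((n, 1))
    else:
        X0 = np.column_stack([np.ones(n), np.asarray(covars, float)])
    Q, _ = np.linalg.qr(X0)
    yr = y - Q @ (Q.T @ y)
    xr = x - Q @ (Q.T @ x)
    sxx = float(xr @ xr)
    if sxx == 0 or float(yr @ yr) == 0:
        raise ValueError("degenerate regression: zero variance")
    r = float(xr @ yr) / np.sqrt(sxx * float(yr @ yr))
    df = n - X0.shape[1] - 1
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return np.inf, 0.0
    f = df * r2 / (1.0 - r2)
    return f, float(stats.f.sf(f, 1, df))


def _tertile_bins(G: np.ndarray) -> list[np.ndarray]:
    qs = np.quantile(G, [1 / 3, 2 / 3])
    labels = np.digitize(G, qs)
    return [np.flatnonzero(labels == b) for b in range(3) if (labels == b).any()]


def _perm_p4(L, G, T, n_perm: int, rng: np.random.Generator) -> float:
    """Equivalence-test P for condition 4 (small = L independent of T | G).

    Observed statistic: F for L in T ~ G + L.  The dependence-null
    distribution is built by permuting L within G tertiles (preserving
    the L-G association coarsely) and giving the surrogate outcome a
    direct L effect equal to the observed marginal slope of T on L:
    T*_b = b_marg * L*_b + resid(T ~ L).  p4 is the add-one smoothed
    proportion of dependence-null F statistics <= the observed F.
    """
    L = np.asarray(L, float)
    G = np.asarray(G, float)
    T = np.asarray(T, float)
    n = len(L)
    X0 = np.column_stack([np.ones(n), G])
    Q, _ = np.linalg.qr(X0)
    df = n - 3

    def f_stats(y_cols: np.ndarray, l_cols: np.ndarray) -> np.ndarray:
        """Partial F of each L column in y ~ G + L (columns aligned)."""
        lr = l_cols - Q @ (Q.T @ l_cols)
        yr = y_cols - Q @ (Q.T @ y_cols)
        sxx = (lr * lr).sum(axis=0)
        syy = (yr * yr).sum(axis=0)
        num = (yr * lr).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where((sxx > 0) & (syy > 0), num * num / (sxx * syy), 0.0)
        r2 = np.minimum(r2, 1.0 - 1e-15)
        return df * r2 / (1.0 - r2)

    f_obs = float(f_stats(T[:, None], L[:, None])[0])

    # observed marginal slope of T on L and its residuals
    lc = L - L.mean()
    b_marg = float(lc @ (T - T.mean())) / float(lc @ lc)
    resid_marg = T - b_marg * L

    perm_idx = np.tile(np.arange(n), (n_perm, 1))
    for idx in _tertile_bins(G):
        keys = rng.random((n_perm, len(idx)))
        perm_idx[:, idx] = idx[np.argsort(keys, axis=1)]
    l_perm = L[perm_idx].T  # n x B
    t_dep = b_marg * l_perm + resid_marg[:, None]
    f_dep = f_stats(t_dep, l_perm)
    return (1.0 + float((f_dep <= f_obs).sum())) / (n_perm + 1.0)


def cit_components(
    L, G, T, n_perm: int = 1000, rng: np.random.Generator | None = None
) -> tuple[float, float, float, float]:
    """Component P values (p1, p2, p3, p4) for the direction L -> G -> T.

    p1..p3 are the association F-tests; p4 is the permutation equivalence
    P for conditional independence (small p4 supports the causal
    direction, like the other components).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = np.asarray(L, float)
    G = np.asarray(G, float)
    T = np.asarray(T, float)
    if L.std() == 0 or G.std() == 0 or T.std() == 0:
        raise ValueError("degenerate triplet: constant vector")
    _, p1 = _partial_f_p(T, L, None)
    _, p2 = _partial_f_p(G, L, T)
    _, p3 = _partial_f_p(T, G, L)
    p4 = _perm_p4(L, G, T, n_perm, rng)
    return p1, p2, p3, p4


def cit_omnibus(components: tuple[float, float, float, float]) -> float:
    """Intersection-union omnibus: the maximum of the four components."""
    return max(components)


def cit_test(
    triplet: Triplet, n_perm: int = 1000, seed: int = 0
) -> CITResult:
    """Run both directions of the CIT on one triplet.

    Permutation seeds are derived from the pipeline seed and the mediator
    gene id, so swapping G and T (with their ids) swaps p_causal and
    p_reactive exactly.
    """
    rng_c = np.random.default_rng(
        child_seed(seed, "cit_perm", triplet.variant_id, triplet.cis_id)
    )
    rng_r = np.random.default_rng(
        child_seed(seed, "cit_perm", triplet.variant_id, triplet.trans_id)
    )
    causal = cit_components(triplet.L, triplet.G, triplet.T, n_perm, rng_c)
    reactive = cit_components(triplet.L, triplet.T, triplet.G, n_perm, rng_r)
    return CITResult(
        variant_id=triplet.variant_id,
        cis_id=triplet.cis_id,
        trans_id=triplet.trans_id,
        causal_components=causal,
        reactive_components=reactive,
        p_causal=cit_omnibus(causal),
        p_reactive=cit_omnibus(reactive),
    )


def classify_triplet(p_causal: float, p_reactive: float, n_tests: int) -> str:
    """Causal/reactive/independent call at Bonferroni level 0.05/n_tests.

    Causal iff p_causal < alpha and p_reactive >= alpha; reactive for the
    mirror case; otherwise (including both significant) independent.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    alpha = ALPHA / n_tests
    if p_causal < alpha and p_reactive >= alpha:
        return "causal"
    if p_reactive < alpha and p_causal >= alpha:
        return "reactive"
    return "independent"


def build_regulatory_network(results: list[CITResult]):
    """Directed cis/trans regulatory network from classified CIT results.

    Causal triplets contribute variant -> cis -> trans edges; reactive
    ones variant -> trans -> cis.  Gene nodes are labeled 'cis', 'trans'
    or 'cis/trans' according to every role they play.
    """
    import networkx as nx

    g = nx.DiGraph()
    roles: dict[str, set[str]] = {}
    for res in results:
        if res.classification == "causal":
            chain = (res.variant_id, res.cis_id, res.trans_id)
        elif res.classification == "reactive":
            chain = (res.variant_id, res.trans_id, res.cis_id)
        else:
            continue
        roles.setdefault(res.cis_id, set()).add("cis")
        roles.setdefault(res.trans_id, set()).add("trans")
        g.add_node(chain[0], kind="variant")
        g.add_edge(chain[0], chain[1])
        g.add_edge(chain[1], chain[2])
    for gene, rs in roles.items():
        g.nodes[gene]["kind"] = "cis/trans" if len(rs) > 1 else next(iter(rs))
    counts = {"cis": 0, "trans": 0, "cis/trans": 0, "variant": 0}
    for _, data in g.nodes(data=True):
        counts[data["kind"]] += 1
    g.graph["node_class_counts"] = counts
    return g
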