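"""Synthetic cohort generation for every pipeline input.

The generators emulate the statistical structure the downstream analyses
assume: LD-blocked diploid genotypes with a controllable within-block
Pearson correlation, paired quantitative-trait GWAS with configurable
shared/distinct causal variants and cohort-overlap noise correlation,
cis-eQTL expression with explicit covariates, variant -> cis -> trans
mediation triplets, and two-group transcript TPM driven by a
promoter-usage genotype effect.

Genotypes come from a latent multivariate-normal model: each haplotype's
block shares a common Gaussian factor, alleles are thresholded at the
MAF quantile, and the latent correlation is chosen by tetrachoric
inversion so the realized genotype correlation matches the requested LD.
MAF is drawn once per block and shared by its variants — strongly
correlated binary alleles require comparable allele frequencies, so a
per-variant MAF spread would silently cap the attainable LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed

_BASES = np.array(["A", "C", "G", "T"])
# biallelic ref/alt pairs excluding the strand-ambiguous A/T and C/G
_ALLELE_PAIRS = [
    (r, a)
    for r in _BASES
    for a in _BASES
    if r != a and {r, a} not in ({"A", "T"}, {"C", "G"})
]


@dataclass
class ReferencePanel:
    """Diploid reference genotypes with block structure.

    ``dosages`` is samples x variants with values in {0, 1, 2} counting
    alt alleles; ``variants`` has columns chrom, pos, id, ref, alt, block.
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix does not match variant table")
        self._index = {v: i for i, v in enumerate(self.variants["id"])}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    def column(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant id {variant_id!r} not in panel") from None

    def dosage_for(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.column(variant_id)]

    def block_members(self, block: int) -> list[str]:
        mask = self.variants["block"] == block
        return list(self.variants.loc[mask, "id"])

    def block_columns(self, block: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.variants["block"]) == block)


@dataclass
class SimulationSpec:
    """Configuration of a paired-GWAS simulation.

    ``config`` names which trait(s) the causal variant(s) influence;
    ``overlap_corr`` is the cohort-overlap noise correlation C in [-1, 1]
    between the two traits, measured on fully shared samples.
    """

    config: str  # null | trait1_only | trait2_only | shared | distinct
    causal_ids: tuple[str, ...] = ()
    effect1: float = 0.0
    effect2: float = 0.0
    n: int = 1000
    overlap_corr: float = 0.0
    seed: int = 0

    _CONFIGS = ("null", "trait1_only", "trait2_only", "shared", "distinct")

    def __post_init__(self) -> None:
        if self.config not in self._CONFIGS:
            raise ValueError(f"unknown config {self.config!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not -1.0 <= self.overlap_corr <= 1.0:
            raise ValueError("overlap_corr must lie in [-1, 1]")
        if self.config == "shared" and len(self.causal_ids) != 1:
            raise ValueError("shared config needs exactly one causal id")
        if self.config == "distinct":
            if len(self.causal_ids) != 2 or self.causal_ids[0] == self.causal_ids[1]:
                raise ValueError("distinct config needs two different causal ids")
        if self.config in ("trait1_only", "trait2_only") and len(self.causal_ids) != 1:
            raise ValueError(f"{self.config} config needs exactly one causal id")


def _binary_corr(latent_rho: float, thresh: float, maf: float) -> float:
    """Pearson correlation of two Bernoulli alleles thresholded from a
    bivariate normal with correlation ``latent_rho`` at quantile ``thresh``."""
    if latent_rho >= 1.0:
        return 1.0
    p11 = stats.multivariate_normal.cdf(
        [thresh, thresh], mean=[0.0, 0.0],
        cov=[[1.0, latent_rho], [latent_rho, 1.0]],
    )
    return (p11 - maf * maf) / (maf * (1.0 - maf))


def _latent_rho_for(target_r: float, maf: float) -> float:
    """Invert the tetrachoric relation: latent normal correlation giving a
    binary allele correlation of ``target_r`` at the given MAF."""
    if target_r <= 0.0:
        return 0.0
    thresh = stats.norm.ppf(maf)
    lo, hi = 0.0, 0.999999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _binary_corr(mid, thresh, maf) < target_r:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


def simulate_reference_panel(
    n_samples: int,
    blocks: list[int],
    within_block_ld: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
    spacing: int = 1000,
) -> ReferencePanel:
    """Simulate an LD-blocked diploid reference panel.

    Variants within a block have expected pairwise genotype correlation
    close to ``within_block_ld`` and near zero across blocks.  Monomorphic
    columns (possible at small n and low MAF) are repaired by setting one
    random sample heterozygous, so every site is polymorphic.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if any(b < 1 for b in blocks):
        raise ValueError("blocks must all have size >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5]; got {maf_range}")
    if not 0.0 <= within_block_ld < 1.0:
        raise ValueError("within_block_ld must lie in [0, 1)")

    rng = np.random.default_rng(child_seed(seed, "panel"))
    n_hap = 2 * n_samples
    cols: list[np.ndarray] = []
    rows: list[dict] = []
    pos = 0
    vid = 0
    for b, size in enumerate(blocks):
        maf = float(rng.uniform(lo, hi))
        thresh = stats.norm.ppf(maf)
        rho = _latent_rho_for(within_block_ld, maf)
        shared = rng.standard_normal(n_hap)[:, None]
        noise = rng.standard_normal((n_hap, size))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        alleles = (latent < thresh).astype(np.int8)
        dos = alleles[:n_samples] + alleles[n_samples:]
        for j in range(size):
            pos += spacing
            # non-palindromic pairs only, so harmonization never has to
            # drop a synthetic site as strand-ambiguous
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            vid += 1
            rows.append(
                dict(chrom=chrom, pos=pos, id=f"rs{vid}",
                     ref=ref, alt=alt, block=b)
            )
        cols.append(dos)
    dosages = np.concatenate(cols, axis=1)

    # repair monomorphic columns so downstream LD is always defined
    for j in np.flatnonzero(dosages.std(axis=0) == 0):
        i = int(rng.integers(n_samples))
        dosages[i, j] = 1 if dosages[0, j] != 1 else 0

    return ReferencePanel(pd.DataFrame(rows), dosages)


def _marginal_regression(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-variant simple linear regression of y on each dosage column."""
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return pd.DataFrame(dict(beta=beta, se=se, p=np.clip(p, 1e-320, 1.0)))


def simulate_gwas_pair(
    panel: ReferencePanel, spec: SimulationSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two quantitative-trait GWAS over the panel's variants.

    Phenotypes are y_t = sum(effect_t * dosage) + noise, with the two
    traits' noises drawn with correlation ``spec.overlap_corr`` on fully
    shared samples; per-variant marginal regression yields beta, SE and P.
    Returns two standardized summary tables (chrom, pos, rsid, ea, nea,
    beta, se, p, n) oriented to the panel's alt allele.
    """
    for cid in spec.causal_ids:
        if cid not in panel._index:
            raise KeyError(f"causal id {cid!r} not in panel")
    n = spec.n
    if n > panel.n_samples:
        raise ValueError(
            f"requested n={n} exceeds panel samples ({panel.n_samples})"
        )
    rng = np.random.default_rng(child_seed(spec.seed, "gwas"))
    G = panel.dosages[:n].astype(float)

    g1 = np.zeros(n)
    g2 = np.zeros(n)
    if spec.config in ("trait1_only", "shared"):
        g1 = spec.effect1 * panel.dosage_for(spec.causal_ids[0])[:n]
    if spec.config == "trait2_only":
        g2 = spec.effect2 * panel.dosage_for(spec.causal_ids[0])[:n]
    if spec.config == "shared":
        g2 = spec.effect2 * panel.dosage_for(spec.causal_ids[0])[:n]
    if spec.config == "distinct":
        g1 = spec.effect1 * panel.dosage_for(spec.causal_ids[0])[:n]
        g2 = spec.effect2 * panel.dosage_for(spec.causal_ids[1])[:n]

    C = spec.overlap_corr
    cov = np.array([[1.0, C], [C, 1.0]])
    noise = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    y1 = g1 + noise[:, 0]
    y2 = g2 + noise[:, 1]

    base = panel.variants[["chrom", "pos", "id"]].rename(columns={"id": "rsid"})
    out = []
    for y in (y1, y2):
        tbl = _marginal_regression(G, y)
        tbl = pd.concat([base.reset_index(drop=True), tbl], axis=1)
        tbl["ea"] = list(panel.variants["alt"])
        tbl["nea"] = list(panel.variants["ref"])
        tbl["n"] = n
        out.append(tbl[["chrom", "pos", "rsid", "ea", "nea",
                        "beta", "se", "p", "n"]])
    return out[0], out[1]


def simulate_eqtl_study(
    panel: ReferencePanel,
    causal_id: str,
    effect: float,
    n_covariates: int = 3,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a cis-eQTL study on the panel's samples.

    expression = effect * dosage(causal) + covariates @ w + noise, with
    the covariate matrix returned explicitly so colocalization methods can
    adjust for it.
    """
    if causal_id not in panel._index:
        raise KeyError(f"causal id {causal_id!r} not in panel")
    rng = np.random.default_rng(child_seed(seed, "eqtl"))
    n = panel.n_samples
    covariates = rng.standard_normal((n, n_covariates))
    w = rng.normal(0.0, 0.5, size=n_covariates)
    expr = (
        effect * panel.dosage_for(causal_id)
        + covariates @ w
        + rng.normal(0.0, noise_sd, size=n)
    )
    return panel.dosages.copy(), expr, covariates


def simulate_triplet(
    panel: ReferencePanel,
    model: str,
    effects: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    causal_id: str | None = None,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a (variant, cis-gene, trans-gene) mediation triplet.

    * causal:      G = a*L + e1,  T = b*G + e2   (variant -> cis -> trans)
    * reactive:    T = a*L + e1,  G = b*T + e2   (variant -> trans -> cis)
    * independent: G = a*L + e1,  T = b*L + e3   (independent noises)
    """
    if model not in ("causal", "reactive", "independent"):
        raise ValueError(f"unknown triplet model {model!r}")
    a, b = effects
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("effects must be finite")
    rng = np.random.default_rng(child_seed(seed, "triplet"))
    if causal_id is None:
        causal_id = panel.variant_ids[0]
    L = panel.dosage_for(causal_id).astype(float)
    n = len(L)
    e1 = rng.normal(0.0, noise_sd, n)
    e2 = rng.normal(0.0, noise_sd, n)
    if model == "causal":
        G = a * L + e1
        T = b * G + e2
    elif model == "reactive":
        T = a * L + e1
        G = b * T + e2
    else:
        e3 = rng.normal(0.0, noise_sd, n)
        G = a * L + e1
        T = b * L + e3
    return L, G, T


def simulate_transcript_usage(
    dosages: np.ndarray,
    usage_effect: float,
    baseline_tpm: tuple[float, float] = (50.0, 50.0),
    seed: int = 0,
    noise_sd: float = 5.0,
) -> pd.DataFrame:
    """Simulate per-sample long- and short-group transcript TPM.

    Each alt-allele copy shifts ``usage_effect`` TPM from the long group
    to the short group (the reciprocal promoter-switch pattern), plus
    independent Gaussian noise; TPM is floored at zero.
    """
    long_base, short_base = baseline_tpm
    if long_base < 0 or short_base < 0:
        raise ValueError("baseline TPMs must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "usage"))
    d = np.asarray(dosages, float)
    n = len(d)
    long_tpm = long_base - usage_effect * d + rng.normal(0.0, noise_sd, n)
    short_tpm = short_base + usage_effect * d + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        dict(long=np.maximum(long_tpm, 0.0), short=np.maximum(short_tpm, 0.0))
    )
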