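"""RTC scoring: self-extinction, null behavior, discrimination."""

import numpy as np
import pytest

from pleioscan.rtc import (
    RTCInput,
    RTCResult,
    colocalized,
    genotype_pcs,
    rank_inverse_normal,
    residualize,
    rtc_score,
)
from pleioscan.sumstats import GenomicInterval
from pleioscan.synthetic import simulate_eqtl_study, simulate_reference_panel


def make_input(panel, expr, cov, sentinel, lead):
    return RTCInput(
        interval=GenomicInterval("1", 1, 10**6),
        variant_ids=panel.variant_ids,
        positions=[int(p) for p in panel.variants["pos"]],
        dosages=panel.dosages.astype(float),
        expression=expr,
        covariates=cov,
        sentinel_id=sentinel,
        lead_id=lead,
    )


class TestGenotypePCs:
    def test_single_variant_component_proportional_to_dosage(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        pcs = genotype_pcs(g[:, None], k=1)
        gc = g - g.mean()
        r = np.corrcoef(pcs[:, 0], gc)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_samples_get_equal_scores(self, rng):
        X = rng.integers(0, 3, (20, 5)).astype(float)
        X2 = np.vstack([X, X[0]])
        pcs = genotype_pcs(X2, k=2)
        assert pcs[0] == pytest.approx(pcs[-1], abs=1e-10)

    def test_orthogonality(self, rng):
        X = rng.normal(size=(100, 8))
        pcs = genotype_pcs(X, k=3)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_deterministic(self, rng):
        X = rng.normal(size=(60, 6))
        assert np.array_equal(genotype_pcs(X, 3), genotype_pcs(X.copy(), 3))


class TestResidualize:
    def test_y_in_span_gives_zero(self, rng):
        X = rng.normal(size=(40, 2))
        y = 3.0 + X @ np.array([1.5, -2.0])
        assert np.abs(residualize(y, X)).max() < 1e-8

    def test_intercept_only_centers(self, rng):
        y = rng.normal(size=30) + 5
        assert residualize(y, None) == pytest.approx(y - y.mean())

    def test_orthogonal_to_covariates(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        r = residualize(y, X)
        assert np.abs(X.T @ r).max() < 1e-8


class TestRTCScore:
    def test_sentinel_equals_lead_scores_one(self):
        panel = simulate_reference_panel(300, [8], 0.5, seed=1)
        _, expr, cov = simulate_eqtl_study(panel, "rs3", 1.0, seed=2)
        res = rtc_score(make_input(panel, expr, cov, "rs3", "rs3"))
        assert res.rtc == 1.0 and res.rank == 0

    def test_single_variant_interval(self):
        panel = simulate_reference_panel(200, [1], 0.0, seed=3)
        _, expr, cov = simulate_eqtl_study(panel, "rs1", 0.5, seed=4)
        res = rtc_score(make_input(panel, expr, cov, "rs1", "rs1"))
        assert res.n_int == 1 and res.rtc == 1.0

    def test_rtc_bounds(self):
        panel = simulate_reference_panel(200, [10], 0.3, seed=5)
        _, expr, cov = simulate_eqtl_study(panel, "rs2", 0.8, seed=6)
        for sentinel in panel.variant_ids[:4]:
            res = rtc_score(make_input(panel, expr, cov, sentinel, "rs2"))
            assert 0.0 < res.rtc <= 1.0
            assert 0 <= res.rank < res.n_int

    def test_null_sentinel_mean_near_half(self):
        """An uninformative sentinel ranks uniformly: mean RTC ~ 0.5."""
        scores = []
        for s in range(100):
            panel = simulate_reference_panel(300, [10], 0.0, seed=s)
            _, expr, cov = simulate_eqtl_study(panel, "rs5", 1.0, seed=s)
            res = rtc_score(make_input(panel, expr, cov, "rs9", "rs5"))
            scores.append(res.rtc)
        assert abs(np.mean(scores) - 0.5) < 0.12

    def test_missing_variant_named_in_error(self):
        panel = simulate_reference_panel(100, [5], 0.0, seed=7)
        _, expr, cov = simulate_eqtl_study(panel, "rs1", 0.5, seed=8)
        with pytest.raises(KeyError, match="rsZ"):
            make_input(panel, expr, cov, "rsZ", "rs1")

    def test_discrimination_same_vs_independent_causal(self):
        """Sentinels tagging the eQTL's causal variant score high; sentinels
        tagging an independent causal variant in the interval score lower."""
        same, indep = [], []
        for s in range(40):
            panel = simulate_reference_panel(500, [12], 0.9, seed=s)
            _, expr, cov = simulate_eqtl_study(panel, "rs3", 1.0, seed=s)
            # lead: strongest marginal association in the interval
            resid = expr - cov @ np.linalg.lstsq(cov, expr, rcond=None)[0]
            r = [abs(np.corrcoef(panel.dosages[:, j], resid)[0, 1])
                 for j in range(panel.n_variants)]
            lead = panel.variant_ids[int(np.argmax(r))]
            same.append(rtc_score(make_input(panel, expr, cov, "rs3", lead)).rtc)

            panel2 = simulate_reference_panel(500, [6, 6], 0.9, seed=1000 + s)
            _, expr2, cov2 = simulate_eqtl_study(panel2, "rs3", 1.0, seed=s)
            # sentinel tags a causal variant of the *other* block
            indep.append(
                rtc_score(make_input(panel2, expr2, cov2, "rs9", "rs3")).rtc
            )
        assert np.median(same) >= 0.9
        assert np.median(same) - np.median(indep) > 0.1

    def test_label_permutation_consistent(self):
        panel = simulate_reference_panel(300, [6], 0.4, seed=9)
        _, expr, cov = simulate_eqtl_study(panel, "rs2", 1.0, seed=10)
        base = {
            v: rtc_score(make_input(panel, expr, cov, v, "rs2")).rank
            for v in panel.variant_ids
        }
        # reverse the variant order; ranks must be preserved per id
        perm = list(range(panel.n_variants))[::-1]
        inp = RTCInput(
            interval=GenomicInterval("1", 1, 10**6),
            variant_ids=[panel.variant_ids[j] for j in perm],
            positions=[int(panel.variants["pos"].iloc[j]) for j in perm],
            dosages=panel.dosages[:, perm].astype(float),
            expression=expr,
            covariates=cov,
            sentinel_id="rs4",
            lead_id="rs2",
        )
        assert rtc_score(inp).rank == base["rs4"]


class TestColocalizedCall:
    @pytest.mark.parametrize("rtc,expected", [(0.9, True), (0.89, False), (1.0, True)])
    def test_inclusive_threshold(self, rtc, expected):
        res = RTCResult(n_int=10, rank=1, rtc=rtc, sentinel_id="a", lead_id="b")
        assert colocalized(res) is expected


def test_rank_inverse_normal_is_monotone_and_standardized(rng):
    y = rng.exponential(size=500)
    t = rank_inverse_normal(y)
    assert np.all(np.diff(t[np.argsort(y)]) >= 0)
    assert abs(t.mean()) < 0.05 and abs(t.std() - 1.0) < 0.1
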