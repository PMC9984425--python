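"""Generator contracts: determinism, LD targeting, effect recovery."""

import numpy as np
import pytest
from scipy import stats

from pleioscan.synthetic import (
    SimulationSpec,
    simulate_eqtl_study,
    simulate_gwas_pair,
    simulate_reference_panel,
    simulate_transcript_usage,
    simulate_triplet,
)


class TestReferencePanel:
    def test_determinism(self):
        a = simulate_reference_panel(50, [4, 3], 0.5, seed=7)
        b = simulate_reference_panel(50, [4, 3], 0.5, seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_different_seed_differs(self):
        a = simulate_reference_panel(200, [10], 0.5, seed=1)
        b = simulate_reference_panel(200, [10], 0.5, seed=2)
        assert not np.array_equal(a.dosages, b.dosages)

    def test_independent_blocks_uncorrelated(self):
        p = simulate_reference_panel(2000, [5, 5], within_block_ld=0.0, seed=3)
        r = np.corrcoef(p.dosages, rowvar=False)
        off = np.abs(r[np.triu_indices(10, 1)])
        assert off.mean() < 0.1

    def test_within_block_ld_targeted(self):
        p = simulate_reference_panel(5000, [10], within_block_ld=0.8, seed=4)
        r = np.corrcoef(p.dosages, rowvar=False)
        mean_r = r[np.triu_indices(10, 1)].mean()
        assert abs(mean_r - 0.8) < 0.1

    def test_invariants(self, small_panel):
        assert set(np.unique(small_panel.dosages)) <= {0, 1, 2}
        assert small_panel.dosages.std(axis=0).min() > 0  # no monomorphic
        dup = small_panel.variants.duplicated(subset=["chrom", "pos"])
        assert not dup.any()
        assert (small_panel.variants["ref"] != small_panel.variants["alt"]).all()

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_samples=1, blocks=[3]), "n_samples"),
            (dict(n_samples=10, blocks=[0]), "blocks"),
            (dict(n_samples=10, blocks=[3], maf_range=(0.0, 0.5)), "maf_range"),
            (dict(n_samples=10, blocks=[3], maf_range=(0.1, 0.7)), "maf_range"),
        ],
    )
    def test_rejects_bad_inputs(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_reference_panel(**kwargs)


class TestGwasPair:
    def test_determinism(self, small_panel):
        spec = SimulationSpec("shared", ("rs2",), 0.3, 0.3, n=500, seed=9)
        a1, a2 = simulate_gwas_pair(small_panel, spec)
        b1, b2 = simulate_gwas_pair(small_panel, spec)
        assert a1.equals(b1) and a2.equals(b2)

    def test_null_p_uniform(self):
        panel = simulate_reference_panel(1000, [1] * 300, 0.0, seed=11)
        spec = SimulationSpec("null", (), n=1000, seed=12)
        t1, _ = simulate_gwas_pair(panel, spec)
        assert abs((t1["p"] < 0.05).mean() - 0.05) < 0.04
        assert stats.kstest(t1["p"], "uniform").pvalue > 1e-3

    def test_shared_causal_is_top_hit(self):
        hits = 0
        for s in range(20):
            panel = simulate_reference_panel(2000, [8, 8], 0.3, seed=s)
            spec = SimulationSpec("shared", ("rs4",), 0.5, 0.5, n=2000, seed=s)
            t1, t2 = simulate_gwas_pair(panel, spec)
            if (
                t1.loc[t1["p"].idxmin(), "rsid"] == "rs4"
                and t2.loc[t2["p"].idxmin(), "rsid"] == "rs4"
            ):
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_overlap_null_z_correlation(self):
        panel = simulate_reference_panel(2000, [1] * 300, 0.0, seed=21)
        spec = SimulationSpec("null", (), n=2000, overlap_corr=0.4, seed=22)
        t1, t2 = simulate_gwas_pair(panel, spec)
        zcorr = np.corrcoef(t1["beta"] / t1["se"], t2["beta"] / t2["se"])[0, 1]
        assert abs(zcorr - 0.4) < 0.1

    def test_effect_recovery_within_2se(self):
        devs = []
        for s in range(25):
            panel = simulate_reference_panel(1500, [5], 0.2, seed=50 + s)
            spec = SimulationSpec("trait1_only", ("rs3",), 0.4, 0.0, n=1500, seed=s)
            t1, _ = simulate_gwas_pair(panel, spec)
            row = t1[t1["rsid"] == "rs3"].iloc[0]
            devs.append((row["beta"] - 0.4) / row["se"])
        assert abs(np.mean(devs)) < 2.0

    def test_unknown_causal_id_raises(self, small_panel):
        spec = SimulationSpec("shared", ("nope",), 0.5, 0.5, n=100, seed=0)
        with pytest.raises(KeyError, match="nope"):
            simulate_gwas_pair(small_panel, spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(config="weird"),
            dict(config="shared", causal_ids=("a", "b")),
            dict(config="distinct", causal_ids=("a", "a")),
            dict(config="null", n=1),
            dict(config="null", overlap_corr=1.5),
        ],
    )
    def test_spec_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSpec(**{"causal_ids": (), **kwargs})


class TestEqtlAndTriplet:
    def test_eqtl_determinism_and_lead(self):
        hits = 0
        for s in range(20):
            panel = simulate_reference_panel(500, [10], 0.5, seed=s)
            dos, expr, cov = simulate_eqtl_study(panel, "rs5", 1.0, seed=s)
            resid = expr - cov @ np.linalg.lstsq(cov, expr, rcond=None)[0]
            r = [
                abs(np.corrcoef(dos[:, j], resid)[0, 1])
                for j in range(dos.shape[1])
            ]
            lead = int(np.argmax(r))
            ld = np.corrcoef(dos[:, lead], panel.dosage_for("rs5"))[0, 1]
            if ld**2 > 0.8:
                hits += 1
        assert hits >= 19  # >= 95% of seeds
        a = simulate_eqtl_study(panel, "rs5", 1.0, seed=3)
        b = simulate_eqtl_study(panel, "rs5", 1.0, seed=3)
        assert np.array_equal(a[1], b[1])

    def test_triplet_models(self, small_panel):
        L, G, T = simulate_triplet(small_panel, "causal", (0.0, 0.0), seed=5)
        assert abs(np.corrcoef(L, G)[0, 1]) < 0.1
        assert abs(np.corrcoef(G, T)[0, 1]) < 0.1
        with pytest.raises(ValueError, match="model"):
            simulate_triplet(small_panel, "sideways", (1, 1), seed=0)

    def test_independent_model_partial_correlation_nonzero(self, small_panel):
        # L->G and L->T directly: conditioning on G leaves L-T dependence
        L, G, T = simulate_triplet(
            small_panel, "independent", (1.0, 1.0), seed=6
        )
        resG = np.polyfit(G, L, 1)
        rl = L - np.polyval(resG, G)
        rt = T - np.polyval(np.polyfit(G, T, 1), G)
        assert abs(np.corrcoef(rl, rt)[0, 1]) > 0.2


class TestTranscriptUsage:
    def test_reciprocal_slopes(self, small_panel):
        d = small_panel.dosage_for("rs2")
        pos_neg = 0
        for s in range(20):
            tpm = simulate_transcript_usage(d[:200], 5.0, seed=s)
            short_b = np.polyfit(d[:200], tpm["short"], 1)[0]
            long_b = np.polyfit(d[:200], tpm["long"], 1)[0]
            if short_b > 0 and long_b < 0:
                pos_neg += 1
        assert pos_neg >= 18

    def test_determinism_and_validation(self, small_panel):
        d = small_panel.dosage_for("rs1")
        a = simulate_transcript_usage(d, 2.0, seed=1)
        b = simulate_transcript_usage(d, 2.0, seed=1)
        assert a.equals(b)
        with pytest.raises(ValueError, match="baseline"):
            simulate_transcript_usage(d, 2.0, baseline_tpm=(-1.0, 10.0))
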