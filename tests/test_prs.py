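"""PRS engine: allele alignment, LD, clumping, scoring and threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from prsconv import prs
from prsconv.errors import ConfigurationError, DataError
from prsconv.simulate import SimConfig, draw_true_betas, simulate_genotypes

from conftest import make_panel


def _summary(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"])


class TestReader:
    def test_synonyms_and_or_transform(self, tmp_path):
        df = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2"],
                "chrom": ["1", "1"],
                "position": [100, 200],
                "effect_allele": ["a", "g"],
                "other_allele": ["g", "c"],
                "OR": [1.5, 0.8],
                "pval": [0.01, 0.2],
            }
        )
        path = tmp_path / "sumstats.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = prs.read_gwas_summary(path)
        assert list(out["SNP"]) == ["rs1", "rs2"]
        assert out["A1"].tolist() == ["A", "G"]
        np.testing.assert_allclose(out["BETA"], np.log([1.5, 0.8]))

    def test_missing_required_column_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"SNP": ["rs1"], "P": [0.5]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(DataError, match="missing required"):
            prs.read_gwas_summary(path)


class TestAlignAlleles:
    def _panel(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.4, size=(80, 4)).astype(float)
        return make_panel(dosage, a1=["G", "G", "G", "A"], a2=["A", "A", "A", "T"])

    def test_orientation_rules(self):
        panel = self._panel()
        summary = _summary(
            [
                ("v1", "1", 10000, "G", "A", 0.2, 0.05, 0.01),   # identity
                ("v2", "1", 20000, "A", "G", 0.2, 0.05, 0.01),   # swapped
                ("v3", "1", 30000, "A", "C", 0.2, 0.05, 0.01),   # mismatch
                ("v4", "1", 40000, "A", "T", 0.2, 0.05, 0.01),   # ambiguous
            ]
        )
        aligned = prs.align_alleles(summary, panel)
        t = aligned.table.set_index("variant_id")
        assert t.loc["v1", "beta"] == pytest.approx(0.2)
        assert t.loc["v2", "beta"] == pytest.approx(-0.2)
        assert set(aligned.dropped["variant_id"]) == {"v3", "v4"}
        assert dict(zip(aligned.dropped["variant_id"], aligned.dropped["reason"])) == {
            "v3": "allele_mismatch", "v4": "ambiguous",
        }

    def test_zero_matches_is_error(self):
        panel = self._panel()
        summary = _summary([("nope", "1", 1, "G", "A", 0.1, 0.1, 0.5)])
        with pytest.raises(DataError, match="aligned"):
            prs.align_alleles(summary, panel)


class TestLdR2:
    def test_self_and_duplicate_are_one(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, size=200).astype(float)
        panel = make_panel(np.column_stack([col, col, rng.binomial(2, 0.3, 200)]))
        assert prs.ld_r2(panel, 0, 0) == pytest.approx(1.0)
        assert prs.ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.binomial(2, 0.4, size=(2000, 2)).astype(float))
        assert prs.ld_r2(panel, 0, 1) < 0.05

    def test_monomorphic_defined_as_zero(self):
        dosage = np.column_stack([np.ones(100), np.random.default_rng(3).binomial(2, 0.5, 100)])
        panel = make_panel(dosage.astype(float))
        assert prs.ld_r2(panel, 0, 1) == 0.0

    def test_too_few_overlapping_samples_is_error(self):
        panel = make_panel(np.ones((20, 2)))
        with pytest.raises(DataError):
            prs.ld_r2(panel, 0, 1)


class TestClump:
    def test_no_ld_identity(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.binomial(2, 0.4, size=(300, 5)).astype(float))
        weights = prs.AlignedWeights(
            pd.DataFrame(
                {"variant_id": [f"v{j+1}" for j in range(5)],
                 "col_index": range(5),
                 "beta": 0.1,
                 "p": [0.5, 0.1, 0.2, 0.9, 0.3]}
            )
        )
        clumped = prs.clump(weights, panel)
        assert sorted(clumped.table["variant_id"]) == [f"v{j+1}" for j in range(5)]

    def test_index_variant_wins(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.5, size=500).astype(float)
        noise = rng.random(500) < 0.05
        b = np.where(noise, rng.binomial(2, 0.5, size=500), a).astype(float)
        panel = make_panel(np.column_stack([a, b]), positions=[10_000, 20_000])
        assert prs.ld_r2(panel, 0, 1) > 0.8
        weights = prs.AlignedWeights(
            pd.DataFrame(
                {"variant_id": ["v1", "v2"], "col_index": [0, 1],
                 "beta": [0.3, 0.2], "p": [1e-8, 1e-3]}
            )
        )
        clumped = prs.clump(weights, panel)
        assert clumped.table["variant_id"].tolist() == ["v1"]

    def test_distant_pairs_not_clumped(self):
        rng = np.random.default_rng(6)
        a = rng.binomial(2, 0.5, size=500).astype(float)
        panel = make_panel(np.column_stack([a, a]), positions=[10_000, 400_000])
        weights = prs.AlignedWeights(
            pd.DataFrame(
                {"variant_id": ["v1", "v2"], "col_index": [0, 1],
                 "beta": [0.3, 0.2], "p": [1e-8, 1e-3]}
            )
        )
        clumped = prs.clump(weights, panel)  # 390 kb apart > 250 kb window
        assert len(clumped) == 2

    def test_no_retained_pair_in_high_ld(self):
        cfg = SimConfig(n_target=400, n_variants=100, n_blocks=5, n_causal=20,
                        ld_copy_prob=0.9, missing_rate=0.0, seed=55)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(7)
        weights = prs.AlignedWeights(
            pd.DataFrame(
                {"variant_id": panel.variants["variant_id"],
                 "col_index": range(100),
                 "beta": rng.normal(size=100),
                 "p": rng.random(100)}
            )
        )
        clumped = prs.clump(weights, panel, r2_threshold=0.5, window_kb=250)
        cols = clumped.table["col_index"].to_numpy()
        pos = panel.variants["pos"].to_numpy()
        for i, j in [(i, j) for i in cols for j in cols if i < j]:
            if abs(pos[i] - pos[j]) <= 250_000:
                assert prs.ld_r2(panel, int(i), int(j)) <= 0.5


class TestScore:
    def test_hand_example(self):
        panel = make_panel(np.array([[2.0], [0.0]]))
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": ["v1"], "col_index": [0],
                          "beta": [0.5], "p": [0.01]})
        )
        np.testing.assert_allclose(prs.score(panel, weights, 0.05), [1.0, 0.0])

    def test_zero_betas_zero_scores(self, small_panel):
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": small_panel.variants["variant_id"],
                          "col_index": range(small_panel.n_variants),
                          "beta": 0.0, "p": 0.5})
        )
        np.testing.assert_allclose(prs.score(panel=small_panel, weights=weights, p_T=1.0), 0.0)

    def test_nothing_passes_threshold_warns_and_zeroes(self, small_panel, caplog):
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": ["x"], "col_index": [0], "beta": [1.0], "p": [0.9]})
        )
        with caplog.at_level("WARNING"):
            out = prs.score(small_panel, weights, p_T=0.5)
        np.testing.assert_allclose(out, 0.0)
        assert any("no variant" in r.message for r in caplog.records)

    def test_missing_dosage_imputed_with_allele_frequency(self):
        dosage = np.array([[2.0], [0.0], [1.0], [np.nan]])
        panel = make_panel(dosage)
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": ["v1"], "col_index": [0],
                          "beta": [1.0], "p": [0.01]})
        )
        out = prs.score(panel, weights, 1.0)
        assert out[3] == pytest.approx(2.0 * (3 / 6))


class TestSweep:
    def _signal_setup(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 250, 60
        dosage = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        panel = make_panel(dosage)
        betas = np.zeros(m)
        pvals = np.empty(m)
        pvals[:15] = rng.uniform(0.001, 0.05, 15)   # informative set
        pvals[15:] = rng.uniform(0.3, 1.0, m - 15)  # noise set
        betas[:15] = rng.normal(0, 0.3, 15)
        betas[15:] = rng.normal(0, 0.3, m - 15)
        signal = dosage[:, :15] @ betas[:15]
        signal = (signal - signal.mean()) / signal.std()
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 1.2 * signal)))).astype(float)
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": [f"v{j+1}" for j in range(m)],
                          "col_index": range(m), "beta": betas, "p": pvals})
        )
        return panel, weights, y

    def test_monotone_inclusion(self):
        panel, weights, y = self._signal_setup(0)
        profile = prs.sweep_and_select(panel, weights, y, grid=np.linspace(0.05, 1, 20))
        counts = profile.per_threshold["n_variants"].to_numpy()
        assert (np.diff(counts) >= 0).all()
        assert counts[-1] == len(weights)

    def test_selects_informative_threshold_more_often_than_uniform(self):
        hits = 0
        reps = 12
        for seed in range(reps):
            panel, weights, y = self._signal_setup(1000 + seed)
            profile = prs.sweep_and_select(
                panel, weights, y, grid=np.linspace(0.05, 1, 20)
            )
            hits += profile.best_p_t <= 0.25
        # uniform selection over the grid would land there 25% of the time
        assert hits / reps > 0.5

    def test_outlier_trim_mass_near_two_sided_normal_tail(self):
        z = np.random.default_rng(9).normal(size=10_000)
        mask = np.abs(z - z.mean()) > 2 * z.std()
        assert 0.03 < mask.mean() < 0.06

    def test_profile_z_scores_standardized(self):
        panel, weights, y = self._signal_setup(3)
        profile = prs.sweep_and_select(panel, weights, y, grid=np.linspace(0.05, 1, 10))
        assert profile.best_z.mean() == pytest.approx(0.0, abs=1e-10)
        assert profile.best_z.std() == pytest.approx(1.0, abs=1e-10)


class TestPermutation:
    def test_small_n_perm_is_error(self):
        panel = make_panel(np.random.default_rng(0).binomial(2, 0.4, (60, 3)).astype(float))
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": ["v1", "v2", "v3"], "col_index": [0, 1, 2],
                          "beta": [0.1, 0.2, 0.3], "p": [0.1, 0.5, 0.9]})
        )
        with pytest.raises(ConfigurationError, match="n_perm"):
            prs.permutation_correct(panel, weights, np.zeros(60), None, 0.1, n_perm=0)

    def test_null_observed_r2_gives_large_p(self):
        rng = np.random.default_rng(10)
        panel = make_panel(rng.binomial(2, 0.4, (150, 20)).astype(float))
        weights = prs.AlignedWeights(
            pd.DataFrame({"variant_id": [f"v{j+1}" for j in range(20)],
                          "col_index": range(20),
                          "beta": rng.normal(size=20), "p": rng.random(20)})
        )
        y = (rng.random(150) < 0.3).astype(float)
        p = prs.permutation_correct(
            panel, weights, y, None, observed_best_r2=0.0,
            grid=np.linspace(0.1, 1, 10), n_perm=100, seed=1,
        )
        assert p > 0.5
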