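"""LD scores, partitioned-heritability fit, jackknife, and BH-FDR."""

import numpy as np
import pytest

from v2g.genomic_core import Snp
from v2g.heritability_ldsc import (
    BASE_CATEGORY,
    AnnotationMatrix,
    bh_fdr,
    fit_partitioned,
    ld_scores,
)
from v2g.ld_proxies import HaplotypePanel
from v2g.synthetic_data import (
    SimulationConfig,
    enriched_snp_indices,
    simulate_gwas,
    simulate_haplotypes,
)


def _panel_from_matrix(matrix, positions, chrom="chr1"):
    snps = [Snp(f"rs{i}", chrom, p, "A", "G")
            for i, p in enumerate(positions)]
    return HaplotypePanel(snps=snps, matrix=matrix)


def _base_annotation(panel, extra=None):
    M = len(panel.snps)
    cats = [BASE_CATEGORY] + (list(extra) if extra else [])
    ind = np.ones((M, len(cats)))
    if extra:
        for c, (name, idx) in enumerate(extra.items(), start=1):
            ind[:, c] = 0
            ind[idx, c] = 1
    return AnnotationMatrix([s.snp_id for s in panel.snps], cats, ind)


class TestLdScores:
    def test_single_snp_score_is_one(self, rng):
        m = rng.integers(0, 2, size=(20, 1))
        while len(np.unique(m)) < 2:
            m = rng.integers(0, 2, size=(20, 1))
        panel = _panel_from_matrix(m, [100])
        ann = _base_annotation(panel)
        table = ld_scores(panel, ann, window_bp=1000)
        assert table.scores[0, 0] == pytest.approx(1.0)

    def test_two_perfectly_correlated_snps_score_two(self, rng):
        col = rng.integers(0, 2, size=20)
        while len(np.unique(col)) < 2:
            col = rng.integers(0, 2, size=20)
        panel = _panel_from_matrix(np.column_stack([col, col]), [100, 200])
        ann = _base_annotation(panel)
        table = ld_scores(panel, ann, window_bp=1000)
        assert np.allclose(table.scores[:, 0], 2.0)

    def test_agrees_with_brute_force_double_loop(self):
        cfg = SimulationConfig(seed=13, n_snps_per_chrom=100)
        panel, block_of, _ = simulate_haplotypes(
            cfg, np.random.default_rng(13)
        )
        idx = np.arange(0, len(panel.snps), 3)
        ann = _base_annotation(panel, extra={"cat": idx})
        window = 60_000
        table = ld_scores(panel, ann, window_bp=window)
        n = panel.n_haplotypes
        X = panel.matrix.astype(float)
        for j in [0, 17, 55, 140, 199]:
            for c, members in [(0, set(range(len(panel.snps)))),
                               (1, set(idx))]:
                expected = 0.0
                for k in range(len(panel.snps)):
                    if k not in members:
                        continue
                    if panel.snps[k].chrom != panel.snps[j].chrom:
                        continue
                    if abs(panel.snps[k].pos - panel.snps[j].pos) > window:
                        continue
                    r = np.corrcoef(X[:, j], X[:, k])[0, 1] ** 2
                    expected += r - (1 - r) / (n - 2)
                assert table.scores[j, c] == pytest.approx(expected,
                                                           abs=1e-9)


class TestFitPartitioned:
    def test_base_category_enrichment_is_identically_one(self):
        cfg = SimulationConfig(seed=21)
        rng = np.random.default_rng(21)
        panel, block_of, _ = simulate_haplotypes(cfg, rng)
        idx = enriched_snp_indices(40, block_of, rng)
        ann = _base_annotation(panel, extra={"enriched": idx})
        ss = simulate_gwas(panel, block_of, ann, cfg, rng)
        scores = ld_scores(panel, ann, window_bp=100_000)
        fit = fit_partitioned(ss["chi2"].to_numpy(), ss["N"].to_numpy(),
                              scores, ann)
        base = fit.table.set_index("category").loc[BASE_CATEGORY]
        assert base["enrichment"] == pytest.approx(1.0, abs=1e-9)

    def test_null_tau_and_intercept_calibrated(self):
        """tau = 0 simulation: mean intercept within 3 sigma of 1 and
        tau estimates within 3 sigma of 0 over 20 replicates."""
        taus, intercepts = [], []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed)
            rng = np.random.default_rng(seed + 500)
            panel, block_of, _ = simulate_haplotypes(cfg, rng)
            idx = enriched_snp_indices(40, block_of, rng)
            ann = _base_annotation(panel, extra={"enriched": idx})
            ss = simulate_gwas(panel, block_of, ann, cfg, rng,
                               tau_zero=True)
            scores = ld_scores(panel, ann, window_bp=100_000)
            fit = fit_partitioned(ss["chi2"].to_numpy(),
                                  ss["N"].to_numpy(), scores, ann)
            taus.append(
                fit.table.set_index("category").loc["enriched", "tau"]
            )
            intercepts.append(fit.intercept)
        for values, target in [(intercepts, 1.0), (taus, 0.0)]:
            mean = np.mean(values)
            se = np.std(values, ddof=1) / np.sqrt(len(values))
            assert abs(mean - target) < 3 * se + 1e-12

    def test_duplicate_category_is_rank_deficient_error(self):
        cfg = SimulationConfig(seed=2)
        rng = np.random.default_rng(2)
        panel, block_of, _ = simulate_haplotypes(cfg, rng)
        idx = np.arange(40)
        ann = _base_annotation(panel, extra={"a": idx, "b": idx})
        ss = simulate_gwas(panel, block_of, ann, cfg, rng, tau_zero=True)
        scores = ld_scores(panel, ann, window_bp=100_000)
        with pytest.raises(ValueError, match="collinear"):
            fit_partitioned(ss["chi2"].to_numpy(), ss["N"].to_numpy(),
                            scores, ann)


class TestJackknife:
    def _fit(self, seed, n_blocks):
        cfg = SimulationConfig(seed=seed)
        rng = np.random.default_rng(seed + 900)
        panel, block_of, _ = simulate_haplotypes(cfg, rng)
        idx = enriched_snp_indices(40, block_of, rng)
        ann = _base_annotation(panel, extra={"enriched": idx})
        ss = simulate_gwas(panel, block_of, ann, cfg, rng)
        scores = ld_scores(panel, ann, window_bp=100_000)
        return fit_partitioned(ss["chi2"].to_numpy(), ss["N"].to_numpy(),
                               scores, ann, n_jackknife_blocks=n_blocks)

    def test_two_block_closed_form(self):
        """At B = 2 the jackknife se reduces to |theta_1 - theta_2| / 2."""
        from v2g.heritability_ldsc import _enrichment_from_tau, _wls_tau

        cfg = SimulationConfig(seed=4)
        rng = np.random.default_rng(904)
        panel, block_of, _ = simulate_haplotypes(cfg, rng)
        idx = enriched_snp_indices(40, block_of, rng)
        ann = _base_annotation(panel, extra={"enriched": idx})
        ss = simulate_gwas(panel, block_of, ann, cfg, rng)
        scores = ld_scores(panel, ann, window_bp=100_000)
        chi2 = ss["chi2"].to_numpy()
        N = ss["N"].to_numpy()
        fit = fit_partitioned(chi2, N, scores, ann, n_jackknife_blocks=2)
        M = len(chi2)
        thetas = []
        for keep in (slice(M // 2, M), slice(0, M // 2)):
            mask = np.zeros(M, bool)
            mask[keep] = True
            tau, _ = _wls_tau(chi2[mask], N[mask], scores.scores[mask], 0)
            theta, _, _, _ = _enrichment_from_tau(tau,
                                                  ann.indicators[mask])
            thetas.append(theta[1])
        expected_se = abs(thetas[0] - thetas[1]) / 2
        got_se = fit.table.set_index("category").loc["enriched", "se"]
        assert got_se == pytest.approx(expected_se, rel=1e-9)

    def test_identical_pseudovalues_give_zero_se(self):
        # the base category's enrichment is 1 in every delete-one fit
        fit = self._fit(seed=6, n_blocks=10)
        base = fit.table.set_index("category").loc[BASE_CATEGORY]
        assert base["se"] == pytest.approx(0.0, abs=1e-9)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.4], [0.4]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.01, 0.5, 0.04], [0.03, 0.5, 0.06]),
        ],
    )
    def test_step_up_by_hand(self, p, expected):
        assert np.allclose(bh_fdr(p), expected)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
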