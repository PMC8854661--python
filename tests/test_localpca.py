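"""Local PCA, MDS embedding, candidate regions and inversion genotyping."""

import numpy as np
import pandas as pd
import pytest

from popscan.localpca import (
    detect_candidate_regions,
    genotype_inversion,
    local_pca_windows,
    mds_embed,
    scan_genome,
    verify_inversion_ld,
    window_distance,
)
from popscan.simulate import InversionSpec, SimConfig, simulate_dataset
from tests.conftest import make_matrix

INV_KEY = "chr1:2000000-4000000"


def random_matrix(n_var, n_samp, seed, n_chrom=1):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, size=(n_var * n_chrom, n_samp)).astype(np.int8)
    chroms = np.repeat([f"chr{i+1}" for i in range(n_chrom)], n_var)
    pos = np.tile(np.arange(1, n_var + 1) * 100, n_chrom)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "T",
         "missense": False}
    )
    from popscan.core import GenotypeMatrix
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samp)],
        populations=np.array(["P"] * n_samp, dtype=object),
        variants=variants, genotypes=g,
    )


class TestLocalPCAWindows:
    def test_eigenvalues_match_full_decomposition(self):
        """Top-k of the trace-normalized covariance agree with numpy's full eigh."""
        gm = random_matrix(100, 20, seed=0)
        res = local_pca_windows(gm, snps_per_window=100, k=3)
        x = gm.genotypes.astype(float)
        xc = x - x.mean(axis=1, keepdims=True)
        cov = xc.T @ xc
        cov /= np.trace(cov)
        full = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigvals[0], full[:3], atol=1e-10)
        assert res.eigvals[0].sum() <= 1.0 + 1e-9
        assert np.all(np.diff(res.eigvals[0]) <= 1e-12)

    def test_duplicated_window_data_identical_summaries(self):
        gm = random_matrix(100, 15, seed=1)
        g2 = np.vstack([gm.genotypes, gm.genotypes])
        gm2 = make_matrix(g2, ["P"] * 15, positions=np.arange(1, 201) * 50)
        res = local_pca_windows(gm2, snps_per_window=100, k=2)
        np.testing.assert_allclose(res.eigvals[0], res.eigvals[1], atol=1e-10)
        assert window_distance(res)[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_constant_window_flagged_degenerate(self):
        g = np.ones((100, 10), dtype=np.int8)
        gm = make_matrix(g, ["P"] * 10, positions=np.arange(1, 101) * 10)
        res = local_pca_windows(gm, snps_per_window=100)
        assert bool(res.windows["degenerate"].iloc[0])
        assert np.all(res.eigvals[0] == 0)

    def test_remainder_snps_dropped_and_short_chrom_skipped(self):
        gm = random_matrix(150, 10, seed=2, n_chrom=2)
        res = local_pca_windows(gm, snps_per_window=100)
        assert len(res.windows) == 2  # one window per chromosome, 50 SNPs dropped
        with pytest.raises(ValueError):
            local_pca_windows(random_matrix(50, 10, seed=3), snps_per_window=100)


class TestWindowDistance:
    def test_metric_properties_on_random_fixtures(self):
        gm = random_matrix(100, 12, seed=4, n_chrom=1)
        g = np.vstack([random_matrix(100, 12, seed=s).genotypes for s in range(5)])
        gm = make_matrix(g, ["P"] * 12, positions=np.arange(1, 501) * 10)
        res = local_pca_windows(gm, snps_per_window=100)
        d = window_distance(res)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()
        rng = np.random.default_rng(0)
        for _ in range(100):
            i, j, k = rng.integers(0, d.shape[0], size=3)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestMDSEmbed:
    def test_zero_distances_give_zero_coordinates(self):
        coords = mds_embed(np.zeros((4, 4)), n_axes=2)
        np.testing.assert_allclose(coords, 0.0)

    def test_collinear_points_recovered(self):
        # points at 0, 1, 3 on a line
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        coords = mds_embed(d, n_axes=1)[:, 0]
        got = sorted([abs(coords[0] - coords[1]), abs(coords[1] - coords[2]),
                      abs(coords[0] - coords[2])])
        np.testing.assert_allclose(got, [1, 2, 3], atol=1e-8)

    def test_euclidean_input_recovered_exactly(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = mds_embed(d, n_axes=2)
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_non_euclidean_warns(self):
        # symmetric "distances" whose double-centered Gram matrix carries
        # heavy negative spectral mass (many violated triangles)
        d = np.array(
            [[0.0, 1.601, 0.214, 0.382, 0.745],
             [1.601, 0.0, 0.399, 0.239, 0.234],
             [0.214, 0.399, 0.0, 0.286, 0.332],
             [0.382, 0.239, 0.286, 0.0, 1.498],
             [0.745, 0.234, 0.332, 1.498, 0.0]]
        )
        with pytest.warns(UserWarning, match="non-Euclidean"):
            mds_embed(d, n_axes=1)


class TestDetectCandidateRegions:
    @staticmethod
    def _windows(n):
        return pd.DataFrame(
            {"chrom": ["chr1"] * n,
             "start": np.arange(n) * 1000 + 1,
             "end": (np.arange(n) + 1) * 1000}
        )

    def test_contiguous_extreme_block_returned(self):
        scores = np.zeros(40)
        scores[:: 2] = 0.01  # nonzero MAD
        scores[10:15] = 5.0
        regions = detect_candidate_regions(self._windows(40), scores[:, None])
        assert len(regions) == 1
        assert regions[0].window_indices == (10, 11, 12, 13, 14)
        assert regions[0].start == 10_001
        assert regions[0].end == 15_000

    def test_no_outliers_gives_empty(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        assert detect_candidate_regions(self._windows(40), scores[:, None],
                                        threshold_mads=10) == []

    def test_single_gap_tolerated_but_short_runs_rejected(self):
        scores = np.zeros(40)
        scores[:: 2] = 0.01
        scores[[20, 21, 23, 24]] = 5.0  # gap at 22
        regions = detect_candidate_regions(self._windows(40), scores[:, None])
        assert len(regions) == 1
        assert regions[0].window_indices == (20, 21, 23, 24)
        scores2 = np.zeros(40)
        scores2[:: 2] = 0.01
        scores2[[30, 31]] = 5.0  # only 2 outliers < min_windows
        assert detect_candidate_regions(self._windows(40), scores2[:, None]) == []


class TestInversionRecovery:
    def test_planted_inversion_detected_and_genotyped(self, inversion_sim):
        cfg, gm, truth = inversion_sim
        res, mds, regions, calls = scan_genome(gm, seed=0)
        assert len(calls) >= 1
        # the detected region overlaps the planted 2-4 Mb interval
        overlapping = [
            (reg, call, ver) for reg, call, ver in calls
            if reg.chrom == "chr1" and reg.start < 4_000_000 and reg.end > 2_000_000
        ]
        assert len(overlapping) == 1
        reg, call, ver = overlapping[0]
        window_bp = 100 / (cfg.snp_density * 0.9)  # rough window genomic span
        assert abs(reg.start - 2_000_000) <= 2.5 * window_bp
        assert abs(reg.end - 4_000_000) <= 2.5 * window_bp
        assert call.success
        tg = truth.inversion_genotypes[INV_KEY]
        agreement = np.mean([call.genotypes[s] == g for s, g in tg.items()])
        assert agreement >= 0.95
        assert call.cluster_het[1] == max(call.cluster_het)
        assert ver is not None and ver.passes
        assert ver.mean_r2_all > ver.mean_r2_noncarrier

    def test_null_genome_has_no_regions_and_failed_call(self):
        cfg = SimConfig(
            chromosomes={"chr1": 3_000_000}, populations={"A": 20, "B": 20, "C": 20},
            drift={"A": 0.15, "B": 0.15, "C": 0.15}, snp_density=0.0008, seed=31,
        )
        gm, _ = simulate_dataset(cfg)
        _, _, regions, _ = scan_genome(gm, seed=0)
        assert regions == []
        call = genotype_inversion(gm, ("chr1", 1_000_000, 2_000_000))
        # without an inversion the heterozygosity signature is absent
        assert not call.success

    def test_null_region_ld_means_close(self):
        cfg = SimConfig(
            chromosomes={"chr1": 3_000_000}, populations={"A": 30},
            drift={"A": 0.1}, snp_density=0.001, seed=32,
        )
        gm, _ = simulate_dataset(cfg)
        call = genotype_inversion(gm, ("chr1", 1_000_000, 2_000_000))
        if not call.success:  # force a genotype split to exercise verification
            import pandas as pd
            geno = pd.Series(
                np.r_[np.zeros(15, int), np.ones(10, int), np.full(5, 2)],
                index=gm.samples,
            )
            call.genotypes = geno
            call.success = True
        ver = verify_inversion_ld(gm, ("chr1", 1_000_000, 2_000_000), call, seed=0)
        assert ver.performed
        # without an inversion, each sample set's within-region LD matches its
        # own genome background (composite r2 baselines scale with 1/n, so
        # the two sets are compared to matched backgrounds, not to each other)
        assert ver.mean_r2_all == pytest.approx(ver.background_all, rel=0.25)
        assert ver.mean_r2_noncarrier == pytest.approx(ver.background_noncarrier, rel=0.25)
        assert not (ver.mean_r2_all > 2 * ver.background_all)

    def test_sensitivity_and_false_positives_over_seeds(self):
        """>=90% detection of a planted inversion, 0 false regions on nulls."""
        detected = 0
        false_regions = 0
        n_seeds = 10
        for seed in range(200, 200 + n_seeds):
            cfg = SimConfig(
                chromosomes={"chr1": 8_000_000},
                populations={"A": 20, "B": 20, "C": 20},
                drift={"A": 0.15, "B": 0.15, "C": 0.15},
                snp_density=0.0008,
                inversions=[InversionSpec("chr1", 2_500_000, 4_500_000, 0.3,
                                          marker_error=0.01)],
                seed=seed,
            )
            gm, _ = simulate_dataset(cfg)
            _, _, regions, calls = scan_genome(gm, verify=False, seed=0)
            hit = any(
                r.start < 4_500_000 and r.end > 2_500_000 and
                call.success
                for r, call, _ in calls
            )
            detected += hit
            null_cfg = SimConfig(
                chromosomes={"chr1": 8_000_000},
                populations={"A": 20, "B": 20, "C": 20},
                drift={"A": 0.15, "B": 0.15, "C": 0.15},
                snp_density=0.0008, seed=seed + 1000,
            )
            null_gm, _ = simulate_dataset(null_cfg)
            _, _, null_regions, _ = scan_genome(null_gm, verify=False, seed=0)
            false_regions += len(null_regions)
        assert detected >= 0.9 * n_seeds
        assert false_regions == 0
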