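import numpy as np
import pytest

from wmhseg import (
    BinaryMask,
    connected_components,
    icc_absolute_agreement,
    log_wmhr,
    overlap_metrics,
    reproducibility_stats,
    spearman_rho,
    wmh_ratio,
)
from wmhseg.metrics import cohort_log_wmhr


def _mask(data):
    return BinaryMask(data=np.asarray(data, dtype=np.uint8), affine=np.eye(4))


def _random_mask_pair(rng, shape=(12, 12, 12), p=0.1):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return _mask(a), _mask(b)


class TestConnectedComponents:
    def test_isolated_voxels(self):
        data = np.zeros((6, 6, 6))
        data[1, 1, 1] = 1
        data[4, 4, 4] = 1
        cs = connected_components(_mask(data), 26)
        assert cs.n_clusters == 2 and list(cs.sizes) == [1, 1]

    def test_diagonal_connectivity_semantics(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 1
        data[2, 2, 2] = 1
        assert connected_components(_mask(data), 26).n_clusters == 1
        assert connected_components(_mask(data), 6).n_clusters == 2

    def test_empty_mask(self):
        assert connected_components(_mask(np.zeros((3, 3, 3)))).n_clusters == 0


class TestOverlapMetrics:
    def test_perfect_agreement(self, rng):
        a = _mask(rng.random((8, 8, 8)) < 0.2)
        rep = overlap_metrics(a, a)
        assert rep.si == 1.0
        assert rep.voxel_fpr == rep.voxel_fnr == 0
        assert rep.cluster_fpr == rep.cluster_fnr == 0
        assert rep.der == rep.oer == 0

    def test_hand_enumerated_case(self):
        # manual: cluster A (4 vox) + cluster B (2 vox)
        # auto: A' (5 vox, 3 overlapping A) + C (3 vox, disjoint)
        manual = np.zeros((12, 12, 3))
        manual[1, 1:5, 1] = 1          # A
        manual[5, 1:3, 1] = 1          # B
        auto = np.zeros((12, 12, 3))
        auto[1, 2:7, 1] = 1            # A' = y 2..6 (5 vox, overlap y=2,3,4)
        auto[9, 1:4, 1] = 1            # C
        rep = overlap_metrics(_mask(auto), _mask(manual))
        assert rep.si == pytest.approx(6 / 14)
        assert rep.voxel_fpr == pytest.approx(5 / 8)
        assert rep.voxel_fnr == pytest.approx(0.5)
        assert rep.cluster_fpr == pytest.approx(0.5)
        assert rep.cluster_fnr == pytest.approx(0.5)
        assert rep.mean_total_area_voxels == pytest.approx(7)
        assert rep.der == pytest.approx(5 / 7)
        assert rep.oer == pytest.approx(3 / 7)
        assert rep.der + rep.oer == pytest.approx(2 * (1 - rep.si), abs=1e-12)

    def test_empty_auto_boundary_convention(self):
        manual = np.zeros((5, 5, 5))
        manual[2, 2, 2] = 1
        rep = overlap_metrics(_mask(np.zeros((5, 5, 5))), _mask(manual))
        assert rep.si == 0
        assert rep.voxel_fnr == 1 and rep.cluster_fnr == 1
        assert rep.voxel_fpr == 0

    def test_empty_empty_defined_as_perfect(self):
        rep = overlap_metrics(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 4))))
        assert rep.si == 1.0 and rep.der == 0 and rep.oer == 0

    def test_der_oer_identity_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = _random_mask_pair(rng)
            rep = overlap_metrics(a, b)
            assert rep.der + rep.oer == pytest.approx(2 * (1 - rep.si), abs=1e-9)

    def test_si_symmetric_and_rates_swap(self, rng):
        a, b = _random_mask_pair(rng)
        r1 = overlap_metrics(a, b)
        r2 = overlap_metrics(b, a)
        assert r1.si == pytest.approx(r2.si)
        assert r1.fp_voxels == r2.fn_voxels and r1.fn_voxels == r2.fp_voxels
        assert r1.fp_clusters == r2.fn_clusters


def _icc_anova_oracle(v1, v2):
    """Brute-force two-way ANOVA via explicit cell enumeration."""
    data = np.column_stack([v1, v2]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


class TestICC:
    def test_perfect_agreement(self):
        assert icc_absolute_agreement([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_offset_penalised(self):
        assert icc_absolute_agreement([1, 2, 3], [2, 3, 4]) < 1.0

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(20):
            v1 = rng.normal(size=10)
            v2 = v1 + rng.normal(scale=0.5, size=10)
            ours = icc_absolute_agreement(v1, v2)
            assert ours == pytest.approx(_icc_anova_oracle(v1, v2), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        v1 = rng.normal(size=12)
        v2 = v1 + rng.normal(scale=0.3, size=12)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "score": np.column_stack([v1, v2]).ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute_agreement(v1, v2) == pytest.approx(icc2, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            icc_absolute_agreement([1, 2], [1, 2])


class TestVolumeRatios:
    def test_wmhr_percent(self):
        assert wmh_ratio(15_000, 1_500_000) == pytest.approx(1.0)
        assert wmh_ratio(0, 1_500_000) == 0.0
        with pytest.raises(ValueError):
            wmh_ratio(10, 0)

    def test_log_wmhr(self):
        assert log_wmhr(1.0) == 0.0
        assert log_wmhr(0.0, 1e-4) == pytest.approx(np.log(1e-4))
        with pytest.raises(ValueError):
            log_wmhr(-1)
        xs = [0.5, 1.0, 2.0]
        logs = [log_wmhr(x) for x in xs]
        assert logs == sorted(logs)

    def test_cohort_epsilon_rule(self):
        out = cohort_log_wmhr([0.0, 0.4, 1.0])
        assert out[0] == pytest.approx(np.log(0.2))  # eps = 0.4 / 2


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=20)
        assert spearman_rho(x, x**3) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_example_matches_hand_formula(self):
        # x ranks: [1.5, 1.5, 3, 4]; y ranks: [1, 2, 3.5, 3.5]
        x = [10, 10, 20, 30]
        y = [1, 2, 5, 5]
        rx = np.array([1.5, 1.5, 3, 4])
        ry = np.array([1, 2, 3.5, 3.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestReproducibility:
    def test_identical_scans(self):
        out = reproducibility_stats([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert out["percentage_error_mean"] == 0
        assert out["bland_altman_lower"] == out["bland_altman_upper"] == 0
        assert out["icc"] == pytest.approx(1.0)

    def test_single_pair_formula(self):
        # per-pair error of the (10, 12) pair is 100*2/11 ~ 18.18%
        out = reproducibility_stats([10.0, 20.0, 30.0], [12.0, 20.0, 30.0])
        assert out["percentage_error_mean"] == pytest.approx(100 * 2 / 11 / 3)

    def test_constant_offset(self):
        v1 = np.array([10.0, 20.0, 30.0])
        out = reproducibility_stats(v1, v1 + 2.0)
        assert out["bland_altman_mean_diff"] == pytest.approx(-2.0)
        assert out["bland_altman_lower"] == pytest.approx(-2.0)
        assert out["bland_altman_upper"] == pytest.approx(-2.0)

    def test_zero_mean_pair_excluded(self):
        with pytest.warns(UserWarning, match="zero mean"):
            out = reproducibility_stats([0.0, 10.0, 20.0, 5.0], [0.0, 10.0, 20.0, 5.0])
        assert out["percentage_error_mean"] == 0
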