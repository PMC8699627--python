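import numpy as np
import pandas as pd
import pytest

import plasmasig as ps
from plasmasig.matrix import QuantMatrix


def qmat(arr, missing=(), index=None, columns=None, **kw):
    arr = np.asarray(arr, float).copy()
    for r, c in missing:
        arr[r, c] = np.nan
    index = index or [f"S{i}" for i in range(arr.shape[0])]
    columns = columns or [f"P{j}" for j in range(arr.shape[1])]
    return QuantMatrix(pd.DataFrame(arr, index=index, columns=columns), **kw)


class TestPresenceFilter:
    def test_boundary_is_inclusive(self):
        """41/51 observed (80.4%) is kept; 40/51 (78.4%) is dropped."""
        rng = np.random.default_rng(0)
        arr = rng.uniform(1, 2, size=(51, 2))
        arr[:10, 0] = np.nan   # 41/51 observed
        arr[:11, 1] = np.nan   # 40/51 observed
        qm = qmat(arr)
        out = ps.filter_by_presence(qm, 0.80)
        assert out.protein_ids == ["P0"]

    def test_complete_matrix_is_identity(self):
        qm = qmat(np.random.default_rng(1).uniform(1, 2, (5, 4)))
        out = ps.filter_by_presence(qm, 0.80)
        pd.testing.assert_frame_equal(out.values, qm.values)

    @pytest.mark.parametrize("thr", [0.0, 1.5, -0.1])
    def test_bad_threshold(self, thr):
        qm = qmat([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ps.filter_by_presence(qm, thr)


class TestLLSImpute:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(2)
        latent = rng.uniform(1, 5, size=20)
        coef = rng.uniform(0.5, 3, size=15)
        arr = np.outer(latent, coef)
        truth = arr[3, 1]
        qm = qmat(arr, missing=[(3, 1)])
        out, model = ps.lls_impute(qm, k=5)
        assert out.values.iloc[3, 1] == pytest.approx(truth, rel=1e-9)
        assert out.scale_tag == "imputed"
        assert model.imputed_cells == [("S3", "P1")]

    def test_beats_column_mean_on_low_rank_data(self):
        rng = np.random.default_rng(3)
        n, p, r = 40, 30, 3
        arr = np.exp(rng.normal(0, 1, (n, r)) @ rng.normal(0, 1, (r, p)) / 2
                     + rng.normal(0, 0.05, (n, p)) + 3)
        qm = qmat(arr)
        masked, hidden = ps.mask_entries(qm, 0.05, seed=4)
        out, _ = ps.lls_impute(masked, k=8)
        err_lls, err_mean = [], []
        col_means = masked.values.mean(axis=0)
        for _, row in hidden.iterrows():
            truth = row.value
            err_lls.append(out.values.loc[row.sample_id, row.protein_id]
                           - truth)
            err_mean.append(col_means[row.protein_id] - truth)
        assert np.sqrt(np.mean(np.square(err_lls))) < \
            np.sqrt(np.mean(np.square(err_mean)))

    def test_complete_matrix_identity_empty_registry(self):
        qm = qmat(np.random.default_rng(5).uniform(1, 2, (6, 5)))
        out, model = ps.lls_impute(qm, k=3)
        pd.testing.assert_frame_equal(out.values, qm.values)
        assert model.imputed_cells == []

    def test_observed_cells_never_altered(self, study):
        qm, _, _ = study
        filtered = ps.filter_by_presence(qm, 0.80)
        out, _ = ps.lls_impute(filtered, k=10)
        obs = filtered.mask.to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs],
                              filtered.values.to_numpy()[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_too_few_donors_reduces_k_with_warning(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(1, 2, (10, 4))
        qm = qmat(arr, missing=[(0, 0), (1, 1)])  # only 2 complete proteins
        with pytest.warns(UserWarning, match="reducing k"):
            out, _ = ps.lls_impute(qm, k=5)
        assert not np.isnan(out.values.to_numpy()).any()

    def test_imputed_values_stay_positive(self):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0.1, 10, (12, 8))
        qm = qmat(arr, missing=[(0, 0), (5, 0), (3, 1)])
        out, _ = ps.lls_impute(qm, k=4)
        assert (out.values.to_numpy() > 0).all()


class TestStability:
    def _groups(self, n):
        return np.array([0, 1] * (n // 2))

    def test_constant_protein_ranks_first(self):
        rng = np.random.default_rng(8)
        arr = np.exp(rng.normal(3, 0.5, (20, 12)))
        arr[:, 5] = 7.0
        qm = qmat(arr)
        tab = ps.rank_stability(qm, self._groups(20))
        assert tab.iloc[0]["protein_id"] == "P5"
        assert tab.iloc[0]["stability"] < 0.1
        simple = ps.rank_stability(qm, self._groups(20), method="simple")
        srow = simple[simple["protein_id"] == "P5"].iloc[0]
        assert srow["stability"] == pytest.approx(0.0, abs=1e-12)
        assert srow["rank"] == 1

    def test_group_shift_ranks_strictly_worse(self):
        rng = np.random.default_rng(9)
        g = self._groups(30)
        arr = np.exp(rng.normal(3, 0.4, (30, 20)))
        arr[:, 0] = np.exp(np.log(arr[:, 1]))            # identical copy
        arr[g == 1, 0] *= np.exp(2.0)                     # 2 log-unit shift
        qm = qmat(arr)
        for method in ("normfinder", "simple"):
            tab = ps.rank_stability(qm, g, method=method).set_index(
                "protein_id")
            assert tab.loc["P0", "stability"] > tab.loc["P1", "stability"]

    def test_identical_proteins_identical_stability(self):
        rng = np.random.default_rng(10)
        arr = np.exp(rng.normal(3, 0.4, (16, 8)))
        arr[:, 3] = arr[:, 4]
        tab = ps.rank_stability(qmat(arr), self._groups(16)).set_index(
            "protein_id")
        assert tab.loc["P3", "stability"] == tab.loc["P4", "stability"]

    def test_invariant_to_adding_log_constant(self):
        rng = np.random.default_rng(11)
        arr = np.exp(rng.normal(3, 0.4, (16, 8)))
        g = self._groups(16)
        t1 = ps.rank_stability(qmat(arr), g)
        t2 = ps.rank_stability(qmat(arr * np.exp(1.7)), g)
        np.testing.assert_allclose(t1["stability"], t2["stability"],
                                   rtol=1e-9)
        assert list(t1["protein_id"]) == list(t2["protein_id"])

    def test_small_group_errors(self):
        arr = np.exp(np.random.default_rng(12).normal(3, 0.4, (5, 4)))
        with pytest.raises(ValueError, match="fewer than 2"):
            ps.rank_stability(qmat(arr), np.array([0, 0, 0, 0, 1]))

    def test_recovers_planted_housekeeping(self, preprocessed, study):
        _, stab, nm, _ = preprocessed
        _, _, truth = study
        assert set(nm.norm_protein_ids) == set(truth.housekeeping_proteins)


class TestNSF:
    def test_sample_at_medians_has_unit_nsf(self):
        arr = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 8, 12, 16]])
        qm = qmat(arr)
        nm = ps.fit_nsf(qm, ["P0", "P1", "P2", "P3"])
        assert nm.nsf.iloc[1] == pytest.approx(1.0)  # row 1 is the median

    def test_geometric_mean_symmetry(self):
        arr = np.array([[1.0, 1, 1, 1], [2, 0.5, 1, 1], [1, 1, 1, 1]])
        qm = qmat(arr)
        nm = ps.fit_nsf(qm, ["P0", "P1", "P2", "P3"])
        assert nm.nsf.iloc[1] == pytest.approx(1.0)

    def test_sample_scaling_scales_nsf_exactly(self):
        """Scaling one sample by c multiplies its NSF by exactly c (the
        reference medians are held fixed, as when applying a fitted model)."""
        rng = np.random.default_rng(13)
        arr = rng.uniform(1, 5, (7, 6))
        qm = qmat(arr)
        ids = ["P0", "P1", "P2", "P3"]
        nm = ps.fit_nsf(qm, ids)
        c = 3.7
        arr2 = arr.copy()
        arr2[2] *= c
        nm2 = ps.fit_nsf(qmat(arr2), ids, medians=nm.medians)
        assert nm2.nsf.iloc[2] == pytest.approx(nm.nsf.iloc[2] * c, rel=1e-12)
        others = [i for i in range(7) if i != 2]
        np.testing.assert_allclose(nm2.nsf.iloc[others], nm.nsf.iloc[others],
                                   rtol=1e-12)

    def test_zero_abundance_rejected(self):
        arr = np.array([[1.0, 2], [0.0, 3]])
        with pytest.raises(ValueError, match="positive"):
            ps.fit_nsf(qmat(arr), ["P0", "P1"])


class TestApplyNSF:
    def test_unit_nsf_is_identity(self):
        arr = np.ones((4, 5)) * 2.0
        qm = qmat(arr).with_values(pd.DataFrame(
            arr, index=[f"S{i}" for i in range(4)],
            columns=[f"P{j}" for j in range(5)]), scale_tag="imputed")
        nm = ps.fit_nsf(qm, ["P0", "P1"])
        out = ps.apply_nsf(qm, nm)
        np.testing.assert_allclose(out.values.to_numpy(), arr)
        assert out.scale_tag == "normalized"
        assert out.norm_protein_ids == ("P0", "P1")

    def test_renormalization_is_noop(self):
        """After one normalization pass (normalizers scaled too), refitting
        against the model medians finds no residual bias: all NSF = 1."""
        rng = np.random.default_rng(17)
        arr = np.exp(rng.normal(3, 1, (12, 9)))
        qm = qmat(arr).with_values(pd.DataFrame(
            arr, index=[f"S{i}" for i in range(12)],
            columns=[f"P{j}" for j in range(9)]), scale_tag="imputed")
        ids = ["P0", "P1", "P2", "P3"]
        nm = ps.fit_nsf(qm, ids)
        out = ps.apply_nsf(qm, nm, norm_proteins="scale")
        again = ps.fit_nsf(out, ids, medians=nm.medians)
        np.testing.assert_allclose(again.nsf.to_numpy(), 1.0, rtol=1e-12)

    def test_sample_mismatch_error(self):
        qm = qmat(np.ones((4, 3)) * 2.0)
        nm = ps.fit_nsf(qm, ["P0"])
        qm2 = qmat(np.ones((3, 3)) * 2.0)
        with pytest.raises(ValueError, match="mismatch"):
            ps.apply_nsf(qm2, nm)


class TestScaleInvariance:
    def test_per_sample_bias_removed_exactly(self):
        """Multiplying each sample by an arbitrary positive factor leaves
        the normalized non-normalizer values unchanged (rel err < 1e-9)
        when normalizing against the unbiased model's reference medians."""
        rng = np.random.default_rng(14)
        arr = np.exp(rng.normal(3, 1, (10, 20)))
        ids = [f"P{j}" for j in range(4)]
        c = rng.uniform(0.2, 5, size=10)

        def run(a, medians=None):
            qm = qmat(a).with_values(
                pd.DataFrame(a, index=[f"S{i}" for i in range(10)],
                             columns=[f"P{j}" for j in range(20)]),
                scale_tag="imputed")
            nm = ps.fit_nsf(qm, ids, medians=medians)
            return ps.apply_nsf(qm, nm), nm

        out1, nm1 = run(arr)
        out2, _ = run(arr * c[:, None], medians=nm1.medians)
        a1 = out1.values.drop(columns=ids).to_numpy()
        a2 = out2.values.drop(columns=ids).to_numpy()
        np.testing.assert_allclose(a2, a1, rtol=1e-9)

    def test_self_contained_normalization_equal_up_to_global_scale(self):
        """Without a frozen reference, re-deriving medians from the biased
        matrix recovers the unbiased values up to one global constant (the
        absolute scale is unidentifiable from ratios alone)."""
        rng = np.random.default_rng(15)
        arr = np.exp(rng.normal(3, 1, (11, 20)))
        ids = [f"P{j}" for j in range(4)]
        c = rng.uniform(0.2, 5, size=11)

        def run(a):
            qm = qmat(a).with_values(
                pd.DataFrame(a, index=[f"S{i}" for i in range(11)],
                             columns=[f"P{j}" for j in range(20)]),
                scale_tag="imputed")
            return ps.apply_nsf(qm, ps.fit_nsf(qm, ids))

        a1 = run(arr).values.drop(columns=ids).to_numpy()
        a2 = run(arr * c[:, None]).values.drop(columns=ids).to_numpy()
        ratio = a2 / a1
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)


class TestReferenceCorrelation:
    def test_own_medians_give_perfect_correlation(self):
        rng = np.random.default_rng(15)
        arr = np.exp(rng.normal(3, 1, (10, 20)))
        qm = qmat(arr)
        ref = {p: float(qm.values[p].median()) for p in qm.protein_ids}
        rho, p, n = ps.reference_correlation_qc(qm, ref, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)
        assert n == 20

    def test_antisorted_reference(self):
        rng = np.random.default_rng(16)
        arr = np.exp(rng.normal(3, 1, (10, 15)))
        qm = qmat(arr)
        med = qm.values.median()
        order = med.sort_values().index
        rev = med.sort_values(ascending=False).to_numpy()
        ref = {p: float(v) for p, v in zip(order, rev)}
        rho, _, _ = ps.reference_correlation_qc(qm, ref, n_perm=49, seed=0)
        assert rho < -0.9

    def test_too_few_shared_proteins(self):
        qm = qmat(np.ones((3, 4)) * 2)
        with pytest.raises(ValueError, match="at least 3"):
            ps.reference_correlation_qc(qm, {"P0": 1.0, "P1": 2.0})
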