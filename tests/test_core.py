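"""Unit tests for reference/perturbed SCN construction and IDSCN Z-scores."""

import numpy as np
import pandas as pd
import pytest

from idscn.core import (
    CovariateModel,
    ReferenceSCN,
    compute_idscn,
    compute_perturbed_scn,
    compute_reference_scn,
    cohort_networks,
    individual_network,
    pearson_correlation,
    residualize,
    residualize_array,
    upper_triangle,
)
from idscn.io import CovariateTable, RegionalVolumeTable, align_subjects
from idscn.synthetic import CohortSpec, CovariateEffects, generate_cohort

from _oracle import idscn_z_loop, pearson_loop
from conftest import random_tables


def _ref_scn(r_matrix, n_ref=34, labels=None):
    """ReferenceSCN with a dummy covariate model, for formula-level tests."""
    R = r_matrix.shape[0]
    labels = labels or tuple(f"R{k}" for k in range(R))
    return ReferenceSCN(
        r_matrix=np.asarray(r_matrix, float),
        n_ref=n_ref,
        region_labels=tuple(labels),
        covariate_model=CovariateModel(coefficients=np.zeros((5, R))),
    )


class TestResidualize:
    def test_residuals_orthogonal_to_each_covariate(self):
        rng = np.random.default_rng(0)
        volumes, covariates = random_tables(rng, 30, 5)
        resid, model = residualize(volumes, covariates)
        X = np.column_stack([np.ones(30), covariates.values])
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_null_covariate_effects_leave_correlations_unchanged(self):
        # volumes generated without covariate dependence: adjusted and raw
        # correlations agree up to estimation noise that vanishes with n
        spec = CohortSpec(n_reference=3000, n_patients=0, n_regions=5,
                          covariate_effects=CovariateEffects.null(),
                          aberrant_edges=None, seed=3)
        cohort = generate_cohort(spec)
        raw = np.corrcoef(cohort.volumes.values, rowvar=False)
        resid, _ = residualize(cohort.volumes, cohort.covariates)
        adj = pearson_correlation(resid)
        assert np.max(np.abs(raw - adj)) < 0.01

    def test_tiv_driven_regions_decorrelate_after_adjustment(self):
        # two regions that are exact linear functions of TIV plus noise
        # correlate strongly raw but not after covariate adjustment
        rng = np.random.default_rng(1)
        n = 2000
        volumes, covariates = random_tables(rng, n, 2)
        tiv = covariates.values[:, 3]
        V = np.column_stack([
            5 + 0.01 * tiv + rng.normal(0, 0.3, n),
            8 + 0.02 * tiv + rng.normal(0, 0.3, n),
        ])
        volumes = RegionalVolumeTable(
            pd.DataFrame(V, index=volumes.subject_ids, columns=["A", "B"])
        )
        raw = np.corrcoef(V, rowvar=False)[0, 1]
        resid, _ = residualize(volumes, covariates)
        adj = pearson_correlation(resid)[0, 1]
        assert raw > 0.5
        assert abs(adj) < 0.06

    def test_constant_covariate_is_named_in_error(self):
        rng = np.random.default_rng(2)
        volumes, covariates = random_tables(rng, 20, 3)
        df = covariates.data.copy()
        df["sex"] = 1.0
        with pytest.raises(ValueError, match="sex"):
            residualize_array(volumes.values, df.to_numpy())

    def test_misaligned_subjects_rejected(self):
        rng = np.random.default_rng(3)
        volumes, covariates = random_tables(rng, 10, 3)
        shuffled = CovariateTable(covariates.data.iloc[::-1])
        with pytest.raises(ValueError, match="align"):
            residualize(volumes, shuffled)


class TestReferenceSCN:
    def test_pearson_matches_textbook_formula_on_tiny_input(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(4, 3))
        assert np.allclose(pearson_correlation(M), pearson_loop(M), atol=1e-12)

    def test_identical_regions_correlate_at_one(self):
        M = np.column_stack([np.arange(6.0), np.arange(6.0), np.arange(6.0)[::-1]])
        r = pearson_correlation(M)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_116_regions_give_6670_edges(self):
        ref = _ref_scn(np.eye(116))
        assert ref.n_edges == 6670

    def test_zero_variance_region_is_named(self):
        M = np.column_stack([np.arange(8.0), np.full(8, 3.0)])
        with pytest.raises(ValueError, match="flatline"):
            pearson_correlation(M, region_labels=["ok", "flatline"])

    def test_reference_needs_residual_degrees_of_freedom(self):
        with pytest.raises(ValueError, match="at least"):
            _ref_scn(np.eye(3), n_ref=5)


class TestPerturbedSCN:
    def test_uses_n_plus_one_subjects_and_shrinks_with_n(self):
        # a held-out healthy subject perturbs a large reference less than
        # a small one: max |pSCN - rSCN| decreases with n_ref
        deltas = {}
        for n_ref in (15, 200):
            spec = CohortSpec(n_reference=n_ref, n_patients=1, n_regions=6,
                              aberrant_edges=None, seed=11)
            c = generate_cohort(spec)
            ref_vol = c.volumes.subset(c.reference_ids)
            ref_cov = c.covariates.subset(c.reference_ids)
            ref = compute_reference_scn(ref_vol, ref_cov)
            pscn = compute_perturbed_scn(
                ref_vol, ref_cov,
                c.volumes.subset(c.patient_ids), c.covariates.subset(c.patient_ids),
            )
            deltas[n_ref] = np.max(np.abs(pscn - ref.r_matrix))
        assert deltas[200] < deltas[15]

    def test_duplicate_of_reference_subject_rejected(self):
        rng = np.random.default_rng(5)
        volumes, covariates = random_tables(rng, 10, 3)
        with pytest.raises(ValueError, match="already in the reference"):
            compute_perturbed_scn(volumes, covariates,
                                  volumes.subset([volumes.subject_ids[0]]),
                                  covariates.subset([volumes.subject_ids[0]]))

    def test_region_label_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        volumes, covariates = random_tables(rng, 10, 3)
        other = RegionalVolumeTable(
            volumes.data.iloc[[0]].set_axis(["X1"], axis=0)
            .set_axis(["a", "b", "c"], axis=1)
        )
        with pytest.raises(ValueError, match="region labels"):
            compute_perturbed_scn(volumes, covariates, other,
                                  CovariateTable(covariates.data.iloc[[0]]
                                                 .set_axis(["X1"], axis=0)))


class TestIDSCN:
    def test_no_perturbation_gives_zero_z_and_unit_p(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        ref = _ref_scn(r)
        net = compute_idscn(ref, r.copy(), "K")
        assert np.all(net.z_matrix == 0)
        assert np.all(net.p_matrix == 1)
        assert net.significant == ()

    def test_z_formula_hand_example(self):
        # delta = 0.1 on an edge with r = 0.5, n = 34:
        # Z = 0.1 / ((1 - 0.25) / 33) = 4.4
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        pert = np.array([[1.0, 0.6], [0.6, 1.0]])
        net = compute_idscn(_ref_scn(r, n_ref=34), pert, "K")
        assert net.z_matrix[0, 1] == pytest.approx(4.4, abs=1e-12)

    def test_sign_convention_and_antisymmetry(self):
        # stronger covariance in K -> positive Z; negating the edge change
        # negates Z exactly
        # exactly representable values so the +/- deltas are bit-identical
        r = np.array([[1.0, 0.25], [0.25, 1.0]])
        d = np.array([[0, 0.125], [0.125, 0]])
        up = compute_idscn(_ref_scn(r), r + d, "K")
        down = compute_idscn(_ref_scn(r), r - d, "K")
        assert up.z_matrix[0, 1] > 0
        assert up.z_matrix[0, 1] == -down.z_matrix[0, 1]
        assert np.sign(up.z_matrix[0, 1]) == np.sign(up.delta_matrix[0, 1])

    def test_sqrt_variant_rescales_z(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        pert = np.array([[1.0, 0.6], [0.6, 1.0]])
        plain = compute_idscn(_ref_scn(r, n_ref=34), pert, "K")
        rooted = compute_idscn(_ref_scn(r, n_ref=34), pert, "K", sqrt_variant=True)
        scale = (1 - 0.25) / 33
        assert rooted.z_matrix[0, 1] == pytest.approx(
            plain.z_matrix[0, 1] * np.sqrt(scale)
        )

    def test_degenerate_reference_edge_raises(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            compute_idscn(_ref_scn(r), r.copy(), "K")

    def test_significant_edges_ordered_by_p_then_pair(self):
        R = 4
        rng = np.random.default_rng(7)
        r = np.eye(R)
        pert = np.eye(R)
        iu = upper_triangle(R)
        pert[iu] = pert[iu[::-1]] = rng.uniform(0.5, 0.9, iu[0].size)
        net = compute_idscn(_ref_scn(r, n_ref=100), pert, "K")
        ps = [e.p for e in net.significant]
        assert ps == sorted(ps)
        assert all(e.i < e.j for e in net.significant)
        assert len(net.significant) <= R * (R - 1) // 2


class TestOracleEquivalence:
    def test_full_pipeline_matches_straight_line_reimplementation(self):
        # independent loop-based residuals -> Pearson -> Z agree to 1e-10
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            volumes, covariates = random_tables(rng, 9, 4)
            ref_vol = volumes.subset(volumes.subject_ids[:-1])
            ref_cov = covariates.subset(volumes.subject_ids[:-1])
            sub_vol = volumes.subset(volumes.subject_ids[-1:])
            sub_cov = covariates.subset(volumes.subject_ids[-1:])
            net = individual_network(ref_vol, ref_cov, sub_vol, sub_cov)
            Z = idscn_z_loop(ref_vol.values, ref_cov.values,
                             sub_vol.values[0], sub_cov.values[0])
            # relative tolerance: spurious |r| ~ 1 edges at n=8 yield huge Z
            assert np.max(np.abs(net.z_matrix - Z) / (1 + np.abs(Z))) < 1e-10

    def test_region_permutation_permutes_outputs_consistently(self):
        rng = np.random.default_rng(8)
        volumes, covariates = random_tables(rng, 12, 5)
        perm = rng.permutation(5)
        vol_p = RegionalVolumeTable(volumes.data.iloc[:, perm])
        ids = volumes.subject_ids
        net = individual_network(volumes.subset(ids[:-1]), covariates.subset(ids[:-1]),
                                 volumes.subset(ids[-1:]), covariates.subset(ids[-1:]))
        net_p = individual_network(vol_p.subset(ids[:-1]), covariates.subset(ids[:-1]),
                                   vol_p.subset(ids[-1:]), covariates.subset(ids[-1:]))
        assert np.allclose(net_p.z_matrix, net.z_matrix[np.ix_(perm, perm)],
                           atol=1e-10)


class TestCohortNetworks:
    def test_leave_one_out_changes_reference_size(self, tiny_cohort):
        data = align_subjects(tiny_cohort.volumes, tiny_cohort.covariates,
                              tiny_cohort.clinical)
        loo = cohort_networks(data, tiny_cohort.reference_ids,
                              target_ids=tiny_cohort.reference_ids[:1])
        kept = cohort_networks(data, tiny_cohort.reference_ids,
                               target_ids=tiny_cohort.reference_ids[:1],
                               leave_one_out=False)
        sid = tiny_cohort.reference_ids[0]
        assert loo[sid].n_ref == len(tiny_cohort.reference_ids) - 1
        assert kept[sid].n_ref == len(tiny_cohort.reference_ids)
        assert not np.allclose(loo[sid].z_matrix, kept[sid].z_matrix)

    def test_patients_scored_against_full_reference(self, tiny_cohort):
        data = align_subjects(tiny_cohort.volumes, tiny_cohort.covariates,
                              tiny_cohort.clinical)
        nets = cohort_networks(data, tiny_cohort.reference_ids,
                               target_ids=tiny_cohort.patient_ids)
        assert all(nets[p].n_ref == len(tiny_cohort.reference_ids)
                   for p in tiny_cohort.patient_ids)
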