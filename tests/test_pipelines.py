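import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connleak as cl
from connleak.pipelines import PipelineSpec, gold_counterpart, standard_variants
from connleak.splits import family_kfold, plain_kfold

FAST = cl.ModelSpec(alpha_grid=(1.0,), feature_fraction=0.1)


class TestFamilyKFold:
    def test_500_twin_families_split_400_100(self):
        fams = np.repeat([f"f{i}" for i in range(500)], 2)
        folds = family_kfold(fams, 5, seed=0)
        assert sorted(len(f) for f in folds) == [200] * 5
        for fold in folds:
            test_fams = set(fams[fold])
            assert len(test_fams) == 100
            train_fams = set(fams) - test_fams
            assert len(train_fams) == 400

    def test_all_singletons_reduce_to_plain_kfold(self):
        fams = np.array([f"s{i}" for i in range(23)])
        for seed in (0, 5):
            a = family_kfold(fams, 4, seed)
            b = plain_kfold(23, 4, seed)
            assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_trio_never_split(self):
        fams = np.array(["t", "t", "t"] + [f"s{i}" for i in range(12)])
        for seed in range(5):
            folds = family_kfold(fams, 5, seed)
            trio_folds = [i for i, f in enumerate(folds) if set(f) & {0, 1, 2}]
            assert len(trio_folds) == 1
            assert {0, 1, 2} <= set(folds[trio_folds[0]])

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="families"):
            family_kfold(np.array(["a", "a", "b", "b"]), 3, 0)

    def test_plain_fold_sizes(self):
        folds = plain_kfold(10, 5, seed=1)
        assert sorted(len(f) for f in folds) == [2] * 5
        folds = plain_kfold(11, 5, seed=1)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]

    def test_same_seed_same_folds(self):
        a = plain_kfold(30, 5, 42)
        b = plain_kfold(30, 5, 42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    @settings(max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(1, 4), min_size=5, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    def test_partition_and_family_integrity(self, fam_sizes, seed):
        fams = np.concatenate(
            [[f"f{i}"] * s for i, s in enumerate(fam_sizes)]
        )
        k = min(5, len(fam_sizes))
        if k < 2:
            return
        folds = family_kfold(fams, k, seed)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(len(fams)))
        fold_of = np.empty(len(fams), dtype=int)
        for i, f in enumerate(folds):
            fold_of[f] = i
        for fam in np.unique(fams):
            assert len(set(fold_of[fams == fam])) == 1


class TestSubjectLeakageInjection:
    def test_worked_example_1000_to_1200(self):
        ds = cl.null_dataset(1000, 5, seed=0)
        aug = cl.inject_subject_leakage(ds, 20.0, seed=1)
        assert aug.n_subjects == 1200

    def test_zero_pct_is_identity(self, tiny_dataset):
        assert cl.inject_subject_leakage(tiny_dataset, 0.0, 0) is tiny_dataset

    def test_duplicates_bitwise_equal_and_singleton_families(self, tiny_dataset):
        aug = cl.inject_subject_leakage(tiny_dataset, 25.0, seed=3)
        n, m = tiny_dataset.n_subjects, aug.n_subjects - tiny_dataset.n_subjects
        assert m == 10
        for j in range(m):
            row = aug.X[n + j]
            src = np.flatnonzero((tiny_dataset.X == row).all(axis=1))
            assert len(src) == 1
            i = src[0]
            assert aug.y[n + j] == tiny_dataset.y[i]
            assert aug.site[n + j] == tiny_dataset.site[i]
        dup_fams = aug.family_id[n:]
        assert len(np.unique(dup_fams)) == m
        assert not set(dup_fams) & set(tiny_dataset.family_id)


class TestRunPipeline:
    def test_gold_on_degenerate_data_equals_plain_variant_bitwise(self):
        # single site, all-singleton families: the gold standard coincides
        # exactly with (cv covariates, cv selection, plain split)
        ds = cl.generate_dataset(
            cl.SyntheticConfig(n_subjects=60, n_nodes=20, seed=4)
        )
        gold = cl.run_pipeline(ds, PipelineSpec(), FAST, seed=9)
        plain = cl.run_pipeline(
            ds,
            PipelineSpec(site_correction="none", split="plain"),
            FAST,
            seed=9,
        )
        assert gold.predictions.tobytes() == plain.predictions.tobytes()
        assert gold.r == plain.r

    def test_subject_leakage_pipeline_predicts_all_rows(self, moderate_dataset):
        res = cl.run_pipeline(
            moderate_dataset,
            PipelineSpec(site_correction="none", subject_leakage_pct=20.0),
            FAST,
            seed=0,
        )
        assert len(res.predictions) == 144  # 120 originals + 24 duplicates
        assert np.all(np.isfinite(res.predictions))

    def test_result_bookkeeping(self, moderate_dataset):
        spec = PipelineSpec(site_correction="none", outer_k=4)
        res = cl.run_pipeline(moderate_dataset, spec, FAST, seed=1)
        assert len(res.fold_test_indices) == 4
        assert len(res.selected_edges) == 4
        assert all(c.shape == (moderate_dataset.n_edges,) for c in res.coefficients)
        total = sum(len(f) for f in res.fold_test_indices)
        assert total == moderate_dataset.n_subjects

    def test_gold_purity_sentinel(self, moderate_dataset):
        # mutating a test fold's rows must not change that fold's fitted model
        spec = PipelineSpec(site_correction="none")
        res = cl.run_pipeline(moderate_dataset, spec, FAST, seed=2)
        fold = 0
        test_idx = res.fold_test_indices[fold]
        mutated = moderate_dataset.subset(np.arange(moderate_dataset.n_subjects))
        mutated.X[test_idx] += 100.0
        mutated.y[test_idx] = -mutated.y[test_idx]
        res2 = cl.run_pipeline(mutated, spec, FAST, seed=2)
        assert np.array_equal(res2.fold_test_indices[fold], test_idx)
        assert np.array_equal(res.selected_edges[fold], res2.selected_edges[fold])
        assert np.allclose(res.coefficients[fold], res2.coefficients[fold])

    def test_test_only_site_surfaces_combat_error(self):
        rng = np.random.default_rng(0)
        n = 30
        site = np.array(["A"] * 29 + ["B"])  # B will appear only in one fold
        ds = cl.ConnectomeDataset(
            subject_ids=np.array([f"s{i}" for i in range(n)]),
            X=rng.standard_normal((n, 20)),
            y=rng.standard_normal(n),
            covariates={"age": rng.uniform(8, 22, n)},
            site=site,
            family_id=np.array([f"f{i}" for i in range(n)]),
        )
        with pytest.raises(ValueError):
            cl.run_pipeline(ds, PipelineSpec(), FAST, seed=0)

    def test_cpm_pipeline_runs(self, moderate_dataset):
        res = cl.run_pipeline(
            moderate_dataset,
            PipelineSpec(site_correction="none"),
            cl.ModelSpec(kind="cpm", feature_fraction=0.1),
            seed=0,
        )
        assert np.isfinite(res.r)


class TestIterationAndDeltas:
    def test_single_iteration(self, moderate_dataset):
        out = cl.run_iterations(
            moderate_dataset, PipelineSpec(site_correction="none"), FAST, 1, 7
        )
        assert len(out.results) == 1
        assert out.median_r == out.results[0].r

    def test_median_invariant_to_iteration_order(self, moderate_dataset):
        out = cl.run_iterations(
            moderate_dataset, PipelineSpec(site_correction="none"), FAST, 4, 7
        )
        rs = [r.r for r in out.results]
        assert out.median_r == pytest.approx(np.median(rs[::-1]))

    def test_delta_of_gold_vs_itself_is_exactly_zero(self, moderate_dataset):
        spec = PipelineSpec(site_correction="none")
        d = cl.delta_vs_gold(
            moderate_dataset, spec, FAST, seed=3, gold_spec=spec
        )
        assert d.delta_r == 0.0 and d.delta_q2 == 0.0

    def test_delta_antisymmetry(self, moderate_dataset):
        a = PipelineSpec(site_correction="none", feature_selection="leaky")
        b = PipelineSpec(site_correction="none")
        d1 = cl.delta_vs_gold(moderate_dataset, a, FAST, seed=3, gold_spec=b)
        d2 = cl.delta_vs_gold(moderate_dataset, b, FAST, seed=3, gold_spec=a)
        assert d1.delta_r == pytest.approx(-d2.delta_r)
        assert d1.delta_q2 == pytest.approx(-d2.delta_q2)

    def test_gold_counterpart_resets_leaky_stages_only(self):
        spec = PipelineSpec(
            site_correction="none",
            covariate_regression="leaky",
            feature_selection="leaky",
            split="plain",
            subject_leakage_pct=10.0,
        )
        g = gold_counterpart(spec)
        assert g.site_correction == "none"  # omitted stages stay omitted
        assert g.covariate_regression == "cv"
        assert g.feature_selection == "cv"
        assert g.split == "family_aware"
        assert g.subject_leakage_pct == 0.0

    def test_standard_variants_cover_eleven_pipelines(self):
        v = standard_variants()
        assert len(v) == 11
        assert v["gold_standard"] == PipelineSpec(name="gold_standard")


class TestExperiments:
    def test_subsample_bookkeeping_and_family_respect(self):
        ds = cl.generate_dataset(
            cl.SyntheticConfig(
                n_subjects=120, n_nodes=16, family_fraction=0.5, seed=5
            )
        )
        specs = {
            "family_leakage": PipelineSpec(
                site_correction="none", covariate_regression="none", split="plain"
            )
        }
        table = cl.subsample_experiment(
            ds, sizes=[40], n_resamples=2, n_iters=2,
            leaky_specs=specs, model_spec=FAST, base_seed=0,
        )
        assert len(table) == 4
        assert (table["actual_n"] <= 40).all()
        med = cl.summarize_subsample(table)
        assert len(med) == 2

    def test_subsample_exact_n_with_singletons(self):
        ds = cl.null_dataset(80, 10, seed=1)
        specs = {"feature": PipelineSpec(
            site_correction="none", covariate_regression="none",
            feature_selection="leaky",
        )}
        table = cl.subsample_experiment(
            ds, sizes=[30], n_resamples=1, n_iters=1,
            leaky_specs=specs, model_spec=FAST, base_seed=0,
        )
        assert (table["actual_n"] == 30).all()

    def test_subsample_size_below_largest_family_rejected(self):
        fams = np.repeat("bigfam", 10)
        rng = np.random.default_rng(0)
        ds = cl.ConnectomeDataset(
            subject_ids=np.array([f"s{i}" for i in range(10)]),
            X=rng.standard_normal((10, 6)),
            y=rng.standard_normal(10),
            covariates={"age": rng.uniform(8, 22, 10)},
            site=np.repeat("A", 10),
            family_id=fams,
        )
        with pytest.raises(ValueError, match="largest family"):
            cl.subsample_experiment(
                ds, sizes=[5], n_resamples=1, n_iters=1,
                leaky_specs={"x": PipelineSpec(site_correction="none",
                                               covariate_regression="none",
                                               split="plain")},
                model_spec=FAST, base_seed=0,
            )

    def test_family_sweep_zero_fraction_delta_is_zero(self):
        base = cl.SyntheticConfig(n_subjects=60, n_nodes=16, n_signal_edges=20, seed=6)
        table = cl.family_sweep(base, [0.0], FAST, n_iters=2)
        assert np.allclose(table["delta_r"], 0.0)
        assert list(table.columns) == ["family_fraction", "iteration", "delta_r", "delta_q2"]

    def test_family_sweep_rows(self):
        base = cl.SyntheticConfig(n_subjects=40, n_nodes=12, n_signal_edges=20, seed=6)
        table = cl.family_sweep(base, [0.0, 1.0], FAST, n_iters=2)
        assert len(table) == 4
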