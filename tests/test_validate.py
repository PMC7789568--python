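import numpy as np
import pandas as pd
import pytest

from dmrscan.difftest import test_all
from dmrscan.dmr import call_dmrs
from dmrscan.simulate import SimConfig, simulate_dataset
from dmrscan.validate import (
    blinded_workflow,
    classify,
    cross_validate,
    dmr_rpkm,
    pca_fit,
    permutation_test,
    remove_outlier_dmrs,
)
from dmrscan.windows import CountMatrix


def _rpkm_frame(case_mean, control_mean, n_dmrs=5, n_per_group=3, noise=0.0, rng=None):
    cols = {}
    for i in range(n_per_group):
        cols[f"case_{i}"] = np.full(n_dmrs, case_mean, dtype=float)
        cols[f"control_{i}"] = np.full(n_dmrs, control_mean, dtype=float)
    df = pd.DataFrame(cols, index=[f"d{i}" for i in range(n_dmrs)])
    if noise and rng is not None:
        df += rng.normal(0, noise, df.shape)
    return df


def _groups(df):
    return pd.Series({c: ("case" if c.startswith("case") else "control")
                      for c in df.columns})


class TestPcaFit:
    def test_separable_groups(self, rng):
        df = _rpkm_frame(10.0, 2.0, noise=1e-6, rng=rng)
        model = pca_fit(df, _groups(df))
        c1, c0 = model.centroids["case"], model.centroids["control"]
        assert np.linalg.norm(c1 - c0) > 1.0
        # within-group spread is negligible relative to separation
        assert model.explained_variance[0] > 0.99

    def test_centroids_are_projected_training_means(self, rng):
        df = _rpkm_frame(5.0, 3.0, noise=0.5, rng=rng)
        model = pca_fit(df, _groups(df))
        X = df.to_numpy().T
        scores = (X - model.means) @ model.loadings.T
        for g, sel in (("case", [0, 2, 4]), ("control", [1, 3, 5])):
            idx = [i for i, c in enumerate(df.columns) if c.startswith(g)]
            np.testing.assert_allclose(model.centroids[g], scores[idx].mean(axis=0))

    def test_loadings_orthonormal(self, rng):
        df = _rpkm_frame(5.0, 3.0, n_dmrs=10, noise=1.0, rng=rng)
        model = pca_fit(df, _groups(df))
        np.testing.assert_allclose(model.loadings @ model.loadings.T, np.eye(2),
                                   atol=1e-10)

    def test_training_scores_centered(self, rng):
        df = _rpkm_frame(5.0, 3.0, n_dmrs=8, noise=1.0, rng=rng)
        model = pca_fit(df, _groups(df))
        X = df.to_numpy().T
        scores = (X - model.means) @ model.loadings.T
        assert np.abs(scores.mean(axis=0)).max() < 1e-10

    def test_rank_two_subspace_recovery(self, rng):
        # rank-2 matrix: recovered 2-component subspace = generating subspace
        basis, _ = np.linalg.qr(rng.normal(size=(20, 2)))
        scores = rng.normal(size=(8, 2)) * [5.0, 2.0]
        X = scores @ basis.T
        df = pd.DataFrame(
            X.T, index=[f"d{i}" for i in range(20)],
            columns=[f"case_{i}" for i in range(4)] + [f"control_{i}" for i in range(4)],
        )
        model = pca_fit(df, _groups(df))
        # principal angles via singular values of basis overlap
        sv = np.linalg.svd(model.loadings @ basis, compute_uv=False)
        assert np.abs(sv - 1).max() < 1e-8

    def test_too_few_dmrs_raises(self):
        df = _rpkm_frame(5.0, 3.0, n_dmrs=1)
        with pytest.raises(ValueError):
            pca_fit(df, _groups(df))


class TestClassify:
    @pytest.fixture
    def model(self, rng):
        df = _rpkm_frame(10.0, 2.0, noise=0.01, rng=rng)
        return pca_fit(df, _groups(df))

    def test_case_like_vector(self, model):
        res = classify(model, np.full(5, 10.0))
        assert res.predicted == "case"

    def test_centroid_midpoint_unclassified(self, model):
        res = classify(model, np.full(5, 6.0))
        # near the midpoint of the group means the distances nearly tie
        assert abs(res.distances["case"] - res.distances["control"]) < 0.1

    def test_exact_tie_unclassified(self, rng):
        df = _rpkm_frame(10.0, 2.0)  # no noise -> exactly symmetric
        model = pca_fit(df, _groups(df))
        res = classify(model, np.full(5, 6.0))
        assert res.predicted == "unclassified"

    def test_length_mismatch_raises(self, model):
        with pytest.raises(ValueError):
            classify(model, np.zeros(4))


class TestRemoveOutlierDmrs:
    def test_spiked_dmr_removed(self, rng):
        train = _rpkm_frame(5.0, 5.0, n_dmrs=10, noise=0.5, rng=rng)
        blinded = pd.DataFrame({"b1": np.full(10, 5.0)}, index=train.index)
        blinded.loc["d3", "b1"] = 500.0
        keep, removed = remove_outlier_dmrs(train, _groups(train), blinded)
        assert removed == 1
        assert "d3" not in keep

    def test_null_removal_rate_low(self, rng):
        cols = [f"case_{i}" for i in range(30)] + [f"control_{i}" for i in range(30)]
        train = pd.DataFrame(rng.normal(10, 1, (500, 60)),
                             index=[f"d{i}" for i in range(500)], columns=cols)
        blinded = pd.DataFrame(rng.normal(10, 1, (500, 2)), index=train.index)
        keep, removed = remove_outlier_dmrs(train, _groups(train), blinded)
        assert removed <= 5  # <= 1% of 500 at 3 SD

    def test_idempotent(self, rng):
        train = _rpkm_frame(5.0, 5.0, n_dmrs=20, noise=0.5, rng=rng)
        blinded = pd.DataFrame(rng.normal(5, 0.5, (20, 3)), index=train.index)
        keep1, _ = remove_outlier_dmrs(train, _groups(train), blinded)
        keep2, removed2 = remove_outlier_dmrs(
            train.loc[keep1], _groups(train), blinded.loc[keep1]
        )
        assert keep2 == keep1
        assert removed2 == 0

    def test_removing_everything_raises(self):
        train = _rpkm_frame(5.0, 5.0, n_dmrs=2, noise=0.0)
        blinded = pd.DataFrame({"b": [1e6, 1e6]}, index=train.index)
        with pytest.raises(ValueError, match="every DMR"):
            remove_outlier_dmrs(train, _groups(train), blinded, k=0.0)


class TestPermutationTest:
    def test_deterministic_for_seed(self, small_sim):
        kw = dict(n_permutations=3, p_threshold=1e-4, seed=9, dispersion=0.1)
        a = permutation_test(small_sim.counts, small_sim.grid, **kw)
        b = permutation_test(small_sim.counts, small_sim.grid, **kw)
        assert a.null_counts == b.null_counts

    def test_empirical_p_never_zero(self, small_sim):
        null = permutation_test(small_sim.counts, small_sim.grid,
                                n_permutations=5, p_threshold=1e-4,
                                seed=1, dispersion=0.1)
        assert 0 < null.empirical_p <= 1
        assert null.empirical_p >= 1 / 6

    def test_strong_signal_beats_all_permutations(self, small_sim):
        null = permutation_test(small_sim.counts, small_sim.grid,
                                n_permutations=5, p_threshold=1e-4,
                                seed=2, dispersion=0.1)
        assert null.observed > max(null.null_counts)
        assert null.empirical_p == pytest.approx(1 / 6)

    def test_invalid_n_permutations(self, small_sim):
        with pytest.raises(ValueError):
            permutation_test(small_sim.counts, small_sim.grid, n_permutations=0)


class TestCrossValidate:
    def test_strong_signal_perfect_accuracy(self, small_sim):
        cv = cross_validate(small_sim.counts, small_sim.grid,
                            p_threshold=1e-4, dispersion=0.1)
        assert cv.scheme == "leave-one-out"
        assert cv.accuracy == 1.0
        assert (cv.folds["n_dmrs_in_fold"] > 0).all()

    def test_held_out_cannot_influence_dmr_selection(self, small_sim):
        cm = small_sim.counts
        corrupted_counts = cm.counts.copy()
        corrupted_counts["case_01"] *= 100  # held-out corruption
        corrupted = CountMatrix.from_counts(corrupted_counts, cm.groups)
        train_ids = [s for s in cm.samples if s != "case_01"]
        res_clean = test_all(cm.subset_samples(train_ids), dispersion=0.1)
        res_corr = test_all(corrupted.subset_samples(train_ids), dispersion=0.1)
        d1 = call_dmrs(res_clean, small_sim.grid, 1e-4)
        d2 = call_dmrs(res_corr, small_sim.grid, 1e-4)
        assert [d.label for d in d1] == [d.label for d in d2]

    def test_duplicate_sample_classified_with_its_twin(self, small_sim):
        cm = small_sim.counts
        dup = cm.counts.copy()
        dup["case_04"] = dup["case_01"]  # held-out duplicates a training case
        cm2 = CountMatrix.from_counts(dup, cm.groups)
        cv = cross_validate(cm2, small_sim.grid, p_threshold=1e-4, dispersion=0.1)
        row = cv.folds.set_index("held_out").loc["case_04"]
        assert row["predicted"] == "case"

    def test_too_few_samples_raises(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=10_000, n_case=2,
                        n_control=2, seed=1)
        sim = simulate_dataset(cfg)
        with pytest.raises(ValueError):
            cross_validate(sim.counts, sim.grid)


@pytest.fixture(scope="module")
def split_sim():
    cfg = SimConfig(n_chromosomes=1, chrom_length=600_000, n_planted_dmrs=20,
                    effect_fold=3.0, n_case=7, n_control=7,
                    base_mean_depth=50.0, seed=40)
    sim = simulate_dataset(cfg)
    cm = sim.counts
    blind = ["case_06", "case_07", "control_06", "control_07"]
    train = cm.subset_samples([s for s in cm.samples if s not in blind])
    blinded = cm.subset_samples(blind)
    return sim, train, blinded


class TestBlindedWorkflow:
    def test_blinded_predictions_correct(self, split_sim):
        sim, train, blinded = split_sim
        preds, prov = blinded_workflow(train, blinded, sim.grid,
                                       p_threshold=1e-4, dispersion=0.1)
        truth = {s: ("case" if s.startswith("case") else "control")
                 for s in blinded.samples}
        assert all(p.predicted == truth[p.sample] for p in preds)
        assert prov["n_dmrs"] >= prov["n_dmrs_after_outlier_removal"] > 0

    def test_empty_blinded_set(self, split_sim):
        sim, train, blinded = split_sim
        preds, prov = blinded_workflow(train, blinded.subset_samples([]),
                                       sim.grid, p_threshold=1e-4, dispersion=0.1)
        assert preds == []

    def test_deterministic(self, split_sim):
        sim, train, blinded = split_sim
        kw = dict(p_threshold=1e-4, dispersion=0.1)
        p1, _ = blinded_workflow(train, blinded, sim.grid, **kw)
        p2, _ = blinded_workflow(train, blinded, sim.grid, **kw)
        assert [p.predicted for p in p1] == [p.predicted for p in p2]

    def test_grid_mismatch_raises(self, split_sim):
        sim, train, blinded = split_sim
        shifted = CountMatrix.from_counts(
            blinded.counts.iloc[:-1], blinded.groups
        )
        with pytest.raises(ValueError):
            blinded_workflow(train, shifted, sim.grid)


def test_accuracy_monotone_in_effect_fold():
    """Blinded accuracy does not decrease as the planted effect grows."""
    def acc(fold, seed=21):
        n_pl = 0 if fold == 1.0 else 20
        cfg = SimConfig(n_chromosomes=1, chrom_length=600_000,
                        n_planted_dmrs=n_pl, effect_fold=max(fold, 1.001),
                        n_case=17, n_control=17, seed=seed)
        sim = simulate_dataset(cfg)
        cm = sim.counts
        blind = [f"case_{i:02d}" for i in range(14, 18)] + [
            f"control_{i:02d}" for i in range(14, 18)]
        train = cm.subset_samples([s for s in cm.samples if s not in blind])
        blinded = cm.subset_samples(blind)
        try:
            preds, _ = blinded_workflow(train, blinded, sim.grid,
                                        p_threshold=1e-4, dispersion=0.1)
        except ValueError:  # no DMRs at all -> no classifier
            return 0.0
        truth = {s: ("case" if s.startswith("case") else "control") for s in blind}
        return sum(p.predicted == truth[p.sample] for p in preds) / len(preds)

    accs = [acc(f) for f in (1.0, 2.0, 3.0)]
    assert accs == sorted(accs)


def test_dmr_rpkm_values(small_sim):
    res = test_all(small_sim.counts, dispersion=0.1)
    dmrs = call_dmrs(res, small_sim.grid, 1e-4)
    mat = dmr_rpkm(small_sim.counts, dmrs, small_sim.grid)
    d = dmrs[0]
    s = small_sim.counts.samples[0]
    member = small_sim.counts.counts.loc[list(d.window_labels), s].sum()
    expected = member / ((d.stop - d.start) / 1000) / (
        small_sim.counts.library_size[s] / 1e6
    )
    assert mat.loc[d.label, s] == pytest.approx(expected)
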