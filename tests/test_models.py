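"""Curation filters, Gaussian fitting, symmetrization, samplers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duplexmc import models
from duplexmc.fixtures import DNA_DEFAULT_SD, make_synthetic_step_db

SEPARATED = dict(
    n_decoy=300,
    main_sd=np.array([0.57, 0.5, 0.23, 3.56, 5.17, 6.24]),
    decoy_mean=np.array([0.0, -3.0, 2.6, 0.1, 15.0, 22.0]),
    decoy_sd=np.array([0.4, 0.3, 0.2, 2.5, 3.0, 3.0]),
)


class TestCuration:
    def test_hard_thresholds(self):
        df = pd.DataFrame(
            [
                [0, 0.3, 3.3, 0, 1.5, 4.0],  # Z-form-like twist: drop
                [0, 0.3, 5.6, 0, 1.5, 35.0],  # intercalation-like rise: drop
                [0, 0.3, 3.3, 0, 1.5, 35.0],  # keep
            ]
            + [[0, 0.3, 3.3, 0, 1.5, 35.0 + d] for d in np.linspace(-3, 3, 20)],
            columns=models.PARAM_COLS,
        )
        kept = models.curate(df)
        assert len(kept) == 21
        assert (kept["twist"] > 5.0).all() and (kept["rise"] < 5.5).all()

    def test_metadata_filters(self):
        df = make_synthetic_step_db(n_decoy=0, n_outliers=0, seed=0)
        df["resolution"] = np.linspace(1.5, 3.5, len(df))
        df["protein"] = [i % 3 == 0 for i in range(len(df))]
        kept = models.curate(df)
        assert (kept["resolution"] <= 2.8).all()
        assert not kept["protein"].any()

    def test_planted_outliers_removed_and_main_kept(self):
        db = make_synthetic_step_db(seed=4, **SEPARATED)
        cur = models.curate(db, models.CurationConfig(remove_aform=True))
        counts = cur["label"].value_counts()
        assert counts.get("outlier", 0) <= 3
        assert counts.get("decoy", 0) <= 2
        # survivors ~ main count minus the SD-filter clip on the tails
        assert 860 <= counts["main"] <= 900

    def test_kmeans_label_recovery_on_separated_clusters(self):
        # well-separated planted A-form decoy: >= 99% of labels resolved
        db = make_synthetic_step_db(seed=3, **SEPARATED)
        cur = models.curate(db, models.CurationConfig(remove_aform=True))
        counts = cur["label"].value_counts()
        correct = (
            counts.get("main", 0)
            + (300 - counts.get("decoy", 0))
            + (20 - counts.get("outlier", 0))
        )
        assert correct / len(db) >= 0.99

    def test_realistic_overlap_removes_decoy_cluster_entirely(self):
        # at survey-like widths the A cluster is fully removed; a slice of
        # the B tail near the boundary goes with it
        db = make_synthetic_step_db(seed=1, n_decoy=300)
        cur = models.curate(db, models.CurationConfig(remove_aform=True))
        counts = cur["label"].value_counts()
        assert counts.get("decoy", 0) <= 8
        assert counts["main"] >= 0.8 * 900

    def test_sd_filter_idempotent(self):
        db = make_synthetic_step_db(seed=0, n_decoy=0)
        cur = models.curate(db)
        assert models.curate(cur).equals(cur)

    def test_empty_after_filters_errors(self):
        df = pd.DataFrame([[0, 0, 3.3, 0, 0, 2.0]], columns=models.PARAM_COLS)
        with pytest.raises(ValueError):
            models.curate(df)


class TestGaussianFit:
    def test_parameter_recovery(self, rng, dna_model):
        x = dna_model.means[0] + rng.standard_normal((10000, 6)) @ np.diag(
            DNA_DEFAULT_SD
        )
        df = pd.DataFrame(x, columns=models.PARAM_COLS)
        m = models.fit_gaussians(df, per_type=False)
        se = DNA_DEFAULT_SD / np.sqrt(10000)
        assert np.all(np.abs(m.means[0] - dna_model.means[0]) < 4 * se)
        assert np.allclose(
            np.sqrt(np.diag(m.covs[0])), DNA_DEFAULT_SD, rtol=0.05
        )

    def test_degenerate_repeated_row_errors(self):
        df = pd.DataFrame([[0, 0, 3.3, 0, 0, 35.0]] * 10, columns=models.PARAM_COLS)
        with pytest.raises(ValueError, match="rank-deficient"):
            models.fit_gaussians(df, per_type=False)

    def test_too_few_rows_errors(self):
        df = make_synthetic_step_db(n_main=6, n_decoy=0, n_outliers=0, seed=0)
        with pytest.raises(ValueError, match="7 rows"):
            models.fit_gaussians(df, per_type=False)

    def test_json_round_trip(self, tmp_path, dna_model):
        path = tmp_path / "model.json"
        dna_model.to_json(path)
        back = models.GaussianStepModel.from_json(path)
        assert back.step_types == dna_model.step_types
        assert np.allclose(back.means, dna_model.means)
        assert np.allclose(back.covs, dna_model.covs)


class TestSymmetrize:
    @pytest.fixture
    def sixteen_type_model(self, rng):
        db = make_synthetic_step_db(seed=7, n_decoy=0, n_outliers=0, n_main=3200)
        return models.fit_gaussians(db)

    def test_ten_unique_types_and_count_conservation(self, sixteen_type_model):
        sym = models.symmetrize(sixteen_type_model)
        assert sym.n_unique == 10
        assert sym.counts[
            [sym.step_types.index(t) for t in ("AA", "AT", "TA", "CG", "GC",
                                               "AC", "AG", "CA", "GA", "CC")]
        ].sum() == sixteen_type_model.counts.sum()

    def test_palindromic_types_get_zero_shift_and_tilt(self, sixteen_type_model):
        sym = models.symmetrize(sixteen_type_model)
        for t in ("AT", "TA", "CG", "GC"):
            k = sym.step_types.index(t)
            assert sym.means[k][0] == pytest.approx(0.0, abs=1e-12)
            assert sym.means[k][3] == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_complements_merge_identically(self):
        # a type and its strand-reversed complement carrying exactly
        # mirrored statistics collapse onto the same distribution
        mean = np.array([0.2, 0.3, 3.3, 1.0, 2.0, 34.0])
        cov = np.diag([0.1, 0.2, 0.05, 2.0, 3.0, 5.0])
        F = np.diag([-1.0, 1, 1, -1, 1, 1])
        m = models.GaussianStepModel(
            step_types=("AC", "GT"),
            means=np.vstack([mean, F.diagonal() * mean]),
            covs=np.stack([cov, F @ cov @ F]),
            counts=[50, 50],
        )
        sym = models.symmetrize(m)
        assert np.allclose(sym.means[0], mean)
        assert np.allclose(sym.means[1], F.diagonal() * mean)

    def test_pooled_model_rejected(self, dna_model):
        with pytest.raises(ValueError):
            models.symmetrize(dna_model)


class TestDrawStep:
    def test_gaussian_moments(self, rng, dna_model):
        n = 100_000
        draws = dna_model.means[0] + rng.standard_normal((n, 6)) @ dna_model.factors()[
            0
        ].T
        # sanity on the factor algebra itself
        assert np.allclose(np.cov(draws, rowvar=False), dna_model.covs[0], rtol=0.05,
                           atol=0.3)
        one = models.draw_step(dna_model, rng=rng)
        assert one.shape == (6,)

    def test_fragment_singleton_always_returned(self, rng):
        lib = models.FragmentLibrary({"AA": [[0, 0, 3.3, 0, 0, 34.0]]})
        for _ in range(5):
            assert np.allclose(
                models.draw_step(lib, "AA", rng=rng), [0, 0, 3.3, 0, 0, 34.0]
            )

    def test_random_sequence_over_identical_gaussians_is_single_gaussian(self, rng):
        mean = np.array([0, 0, 3.3, 0, 0, 35.0])
        cov = np.diag([0.3, 0.3, 0.05, 9.0, 16.0, 36.0])
        m = models.GaussianStepModel(
            step_types=tuple(models.STEP_TYPES),
            means=np.tile(mean, (16, 1)),
            covs=np.tile(cov, (16, 1, 1)),
            counts=np.full(16, 100),
        )
        draws = np.array([models.draw_step(m, rng=rng) for _ in range(4000)])
        for dim in range(6):
            p = stats.kstest(
                draws[:, dim], "norm", args=(mean[dim], np.sqrt(cov[dim, dim]))
            ).pvalue
            assert p > 0.005

    def test_unknown_type_rejected(self, rng, dna_model):
        with pytest.raises(KeyError):
            models.draw_step(dna_model, "XX", rng=rng)

    def test_requires_rng(self, dna_model):
        with pytest.raises(ValueError):
            models.draw_step(dna_model)


def test_pooled_mixture_moments(rng):
    # uniform 16-type mixture moments match the pooled single Gaussian
    db = make_synthetic_step_db(seed=9, n_decoy=0, n_outliers=0, n_main=4800)
    m16 = models.fit_gaussians(db)
    pooled = m16.pooled()
    mix_mean = m16.means.mean(axis=0)
    assert np.allclose(pooled.means[0], mix_mean)
    second = np.mean(
        [c + np.outer(mu, mu) for c, mu in zip(m16.covs, m16.means)], axis=0
    )
    assert np.allclose(pooled.covs[0], second - np.outer(mix_mean, mix_mean))


def test_step_table_io(tmp_path):
    db = make_synthetic_step_db(seed=0, n_main=50, n_decoy=0, n_outliers=0)
    path = tmp_path / "steps.tsv"
    models.write_step_table(db, path)
    back = models.read_step_table(path)
    assert np.allclose(back[models.PARAM_COLS], db[models.PARAM_COLS])
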