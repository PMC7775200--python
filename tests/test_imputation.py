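"""The six handling methods: contracts, oracles, failure modes."""

import numpy as np
import pytest

import lwibench as lw
from lwibench.failures import MethodFailure
from lwibench.imputation import _conditional_draw, _em_mvn

from conftest import make_panel


def panel_with_nans(block, **kw):
    return make_panel(np.asarray(block, dtype=float), **kw)


NAN = np.nan


@pytest.fixture()
def incomplete_reference(default_reference):
    panel, _ = default_reference
    incomplete, _ = lw.inject_mcar(panel, 10, seed=77)
    return panel, incomplete


# ---------------------------------------------------------------------------
# shared contracts


@pytest.mark.parametrize("method", lw.METHODS)
def test_observed_cells_pass_through_and_output_complete(
    incomplete_reference, method
):
    complete, incomplete = incomplete_reference
    result = lw.handle(method, incomplete, seed=3)
    expected_n = 5 if method in ("em_mi", "pmm_mi") else 1
    assert len(result.completed) == expected_n
    obs = ~np.isnan(incomplete.measured())
    for ds in result.completed:
        block = ds.measured()
        assert not np.isnan(block).any()
        assert block.min() >= 0 and block.max() <= 1
        if method != "listwise":
            np.testing.assert_array_equal(
                block[obs], incomplete.measured()[obs]
            )


@pytest.mark.parametrize("method", ["knn", "lowrank", "em_mi", "pmm_mi"])
def test_seeded_determinism(incomplete_reference, method):
    _, incomplete = incomplete_reference
    a = lw.handle(method, incomplete, seed=5)
    b = lw.handle(method, incomplete, seed=5)
    for da, db in zip(a.completed, b.completed):
        np.testing.assert_array_equal(da.measured(), db.measured())


def test_no_missing_is_identity(default_reference):
    panel, _ = default_reference
    for method in lw.METHODS:
        result = lw.handle(method, panel, seed=1)
        for ds in result.completed:
            np.testing.assert_array_equal(ds.measured(), panel.measured())


# ---------------------------------------------------------------------------
# listwise deletion


def test_listwise_drops_incomplete_rows():
    block = np.random.default_rng(0).uniform(0, 1, (5, 8))
    block[1, 2] = NAN
    block[4, 0] = NAN
    result = lw.listwise_delete(panel_with_nans(block, n_units=5, n_days=1))
    assert len(result.completed[0].frame) == 3


def test_listwise_all_rows_incomplete_fails():
    block = np.random.default_rng(0).uniform(0, 1, (4, 8))
    block[:, 3] = NAN
    with pytest.raises(MethodFailure, match="complete"):
        lw.listwise_delete(panel_with_nans(block, n_units=4, n_days=1))


# ---------------------------------------------------------------------------
# mean imputation


def test_mean_impute_column_mean():
    block = np.full((3, 8), 0.5)
    block[:, 0] = [0.2, NAN, 0.4]
    result = lw.mean_impute(panel_with_nans(block, n_units=3, n_days=1))
    filled = result.completed[0].measured()
    assert filled[1, 0] == pytest.approx(0.3)
    # imputation preserves the observed mean
    assert filled[:, 0].mean() == pytest.approx(0.3)


def test_mean_impute_fully_missing_column_fails():
    block = np.full((3, 8), 0.5)
    block[:, 2] = NAN
    with pytest.raises(MethodFailure, match="dinner"):
        lw.mean_impute(panel_with_nans(block, n_units=3, n_days=1))


# ---------------------------------------------------------------------------
# kNN


@pytest.mark.parametrize(
    "n,expected", [(884, 29), (9, 3), (100, 9), (1, 1), (2, 1), (16, 3), (27, 5)]
)
def test_choose_k_nearest_odd_to_sqrt(n, expected):
    assert lw.choose_k(n) == expected


def test_knn_single_donor_copies_value():
    # one complete row, one row missing a single cell: k = 1 -> copy
    block = np.array(
        [
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, NAN],
        ]
    )
    result = lw.knn_impute(panel_with_nans(block, n_units=2, n_days=1))
    assert result.completed[0].measured()[1, 7] == pytest.approx(0.8)


def test_knn_identical_donors_any_k():
    block = np.vstack([np.full((9, 8), 0.4), np.full((1, 8), 0.4)])
    block[9, 5] = NAN
    result = lw.knn_impute(panel_with_nans(block, n_units=10, n_days=1))
    assert result.completed[0].measured()[9, 5] == pytest.approx(0.4)


def test_knn_weighted_mean_matches_hand_computation():
    """9 complete donors (k = 3): distance-kernel weighted mean over the 3
    nearest donors, recomputed by brute force in the test."""
    rng = np.random.default_rng(6)
    donors = rng.uniform(0, 1, (9, 8))
    target = np.array([[0.05] * 7 + [NAN]])
    block = np.vstack([donors, target])
    result = lw.knn_impute(panel_with_nans(block, n_units=10, n_days=1))
    assert result.diagnostics["k"] == 3
    # brute-force oracle: rescaled Euclidean over the 7 observed coords,
    # Gaussian kernel weights over the 3 nearest donors
    d = np.sqrt(8 / 7 * ((donors[:, :7] - 0.05) ** 2).sum(axis=1))
    nearest = np.argsort(d)[:3]
    w = np.exp(-(d[nearest] ** 2))
    expected = (w * donors[nearest, 7]).sum() / w.sum()
    assert result.completed[0].measured()[9, 7] == pytest.approx(expected)


def test_knn_fails_on_fully_missing_row():
    block = np.random.default_rng(1).uniform(0, 1, (10, 8))
    block[3, :] = NAN
    with pytest.raises(MethodFailure, match="all measured"):
        lw.knn_impute(panel_with_nans(block, n_units=10, n_days=1))


def test_knn_fails_without_donors():
    block = np.random.default_rng(1).uniform(0, 1, (6, 8))
    block[np.arange(6), np.arange(6)] = NAN  # every row incomplete
    with pytest.raises(MethodFailure, match="donors"):
        lw.knn_impute(panel_with_nans(block, n_units=6, n_days=1))


# ---------------------------------------------------------------------------
# low-rank (soft-impute)


def test_soft_impute_recovers_rank1_matrix():
    """Noiseless rank-1 completion: with the rank cap at 2 (the centered
    target is rank 2) and lambda ~ 0, all masked entries are recovered to
    1e-3 -- checked against the exact entries of the generating outer
    product."""
    rng = np.random.default_rng(0)
    a = rng.uniform(0.2, 1.0, 50)
    b = rng.uniform(0.2, 1.0, 8)
    truth = np.outer(a, b)
    truth /= truth.max()
    mask = rng.random((50, 8)) < 0.3
    block = truth.copy()
    block[mask] = NAN
    result = lw.soft_impute(
        panel_with_nans(block, n_units=50, n_days=1),
        lam=1e-9,
        max_rank=2,
        tol=1e-14,
        max_iter=5000,
        use_design=False,
    )
    recovered = result.completed[0].measured()
    assert np.abs(recovered[mask] - truth[mask]).max() < 1e-3


def test_soft_impute_full_shrinkage_gives_column_means():
    rng = np.random.default_rng(2)
    block = rng.uniform(0, 1, (30, 8))
    block[rng.random((30, 8)) < 0.2] = NAN
    obs_means = np.nanmean(block, axis=0)
    result = lw.soft_impute(
        panel_with_nans(block, n_units=30, n_days=1),
        lam=1e6,  # beyond lambda_max: all-zero centered solution
        use_design=False,
    )
    filled = result.completed[0].measured()
    miss = np.isnan(block)
    for j in range(8):
        if miss[:, j].any():
            np.testing.assert_allclose(
                filled[miss[:, j], j], obs_means[j], atol=1e-10
            )


def test_soft_impute_diagnostics_recorded(incomplete_reference):
    _, incomplete = incomplete_reference
    result = lw.soft_impute(incomplete, seed=4)
    diag = result.diagnostics
    assert diag["lambda"] > 0
    assert 1 <= diag["rank"] <= 48
    assert diag["iterations"] >= 1


# ---------------------------------------------------------------------------
# EM-based multiple imputation


def test_em_complete_data_reproduces_sample_moments():
    rng = np.random.default_rng(3)
    x = rng.multivariate_normal(np.zeros(8), np.eye(8), size=200)
    mu, sigma = _em_mvn(x)
    np.testing.assert_allclose(mu, x.mean(axis=0), atol=1e-8)
    np.testing.assert_allclose(
        sigma, np.cov(x.T, ddof=0) + 1e-4 * np.eye(8), atol=1e-6
    )


def test_conditional_draw_matches_closed_form():
    """Bivariate normal with known parameters: the mean of conditional
    draws reproduces mu1 + Sigma12 Sigma22^-1 (x2 - mu2)."""
    mu = np.array([1.0, 2.0])
    sigma = np.array([[2.0, 1.2], [1.2, 1.5]])
    row = np.array([NAN, 3.0])
    expected = 1.0 + 1.2 / 1.5 * (3.0 - 2.0)
    rng = np.random.default_rng(5)
    draws = [_conditional_draw(row, mu, sigma, rng)[0] for _ in range(4000)]
    cond_sd = np.sqrt(2.0 - 1.2**2 / 1.5)
    assert np.mean(draws) == pytest.approx(expected, abs=4 * cond_sd / np.sqrt(4000))


def test_em_mi_produces_five_data_sets(incomplete_reference):
    _, incomplete = incomplete_reference
    result = lw.em_mi(incomplete, seed=1)
    assert len(result.completed) == 5
    # imputations differ between the 5 data sets (parameter + draw noise)
    a = result.completed[0].measured()
    b = result.completed[1].measured()
    assert not np.array_equal(a, b)


def test_em_mi_fails_with_starved_column():
    block = np.random.default_rng(0).uniform(0, 1, (30, 8))
    block[1:, 4] = NAN  # one observed value only
    with pytest.raises(MethodFailure, match="step_ach"):
        lw.em_mi(panel_with_nans(block, n_units=30, n_days=1), seed=0)


# ---------------------------------------------------------------------------
# PMM multiple imputation


def test_pmm_imputed_values_come_from_observed_set(incomplete_reference):
    _, incomplete = incomplete_reference
    block = incomplete.measured()
    result = lw.pmm_mi(incomplete, seed=2)
    assert len(result.completed) == 5
    miss = np.isnan(block)
    for ds in result.completed:
        filled = ds.measured()
        for j in range(8):
            if miss[:, j].any():
                observed = set(np.round(block[~miss[:, j], j], 12))
                imputed = set(np.round(filled[miss[:, j], j], 12))
                assert imputed <= observed


def test_pmm_exact_linear_relation_single_donor():
    """When the target is exactly linear in the predictors and d = 1, the
    imputed value is the observed value of the donor with the closest
    predictor profile (brute-force donor search oracle)."""
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 1, (40, 7))
    w = np.array([0.1, 0.2, 0.05, 0.15, 0.1, 0.2, 0.2])
    y = X @ w  # in [0, 1]
    block = np.column_stack([X, y])
    miss_rows = [3, 17, 29]
    block_nan = block.copy()
    block_nan[miss_rows, 7] = NAN
    result = lw.pmm_mi(
        panel_with_nans(block_nan, n_units=40, n_days=1),
        m=1,
        seed=0,
        donors=1,
    )
    filled = result.completed[0].measured()
    obs_rows = [i for i in range(40) if i not in miss_rows]
    for i in miss_rows:
        donor = min(obs_rows, key=lambda r: abs(y[r] - y[i]))
        assert filled[i, 7] == pytest.approx(y[donor], abs=1e-6)


def test_pmm_fails_when_donor_pool_unconstructible():
    block = np.random.default_rng(0).uniform(0, 1, (30, 8))
    block[:-3, 6] = NAN  # only 3 observed < donors + 1
    with pytest.raises(MethodFailure, match="donor pool"):
        lw.pmm_mi(panel_with_nans(block, n_units=30, n_days=1), seed=0)
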