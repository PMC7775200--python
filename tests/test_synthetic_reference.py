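"""Synthetic reference generator: shape, marginals, latent structure."""

import numpy as np
import pandas as pd
import pytest

import lwibench as lw
from lwibench.synthetic_reference import (
    DEFAULT_BEHAVIOR_SPECS,
    GRADED_SUPPORT,
    MarginalSpec,
    config_from_dict,
    config_to_dict,
)


@pytest.mark.parametrize(
    "x,lo,hi,expected",
    [(50, 0, 100, 0.5), (3, 3, 9, 0.0), (9, 3, 9, 1.0), (6.7, 0, 100, 0.067)],
)
def test_minmax_normalization(x, lo, hi, expected):
    assert lw.normalize_minmax(x, lo, hi) == pytest.approx(expected)


def test_minmax_degenerate_range_rejected():
    with pytest.raises(ValueError, match="constant"):
        lw.normalize_minmax(1.0, 2.0, 2.0)


class TestReferenceShape:
    def test_row_count_is_collected_minus_excluded(self, default_reference):
        panel, _ = default_reference
        assert len(panel.frame) == 1148 - 264 == 884

    def test_design_matrix_is_884_by_49(self, default_reference):
        panel, _ = default_reference
        design = lw.build_design(panel)
        assert design.shape == (884, 49)
        dummy_cols = [c for c in design.columns if c.startswith("unit_")]
        assert len(dummy_cols) == 40

    def test_unit_day_pairs_unique(self, default_reference):
        panel, _ = default_reference
        assert not panel.frame.duplicated(["unit_id", "day_index"]).any()

    def test_measured_values_in_unit_interval(self, default_reference):
        panel, _ = default_reference
        block = panel.measured()
        assert block.min() >= 0 and block.max() <= 1

    def test_graded_variables_on_their_support(self, default_reference):
        panel, _ = default_reference
        for name in ("breakfast", "lunch", "dinner"):
            vals = np.unique(panel.frame[name])
            assert set(vals) <= set(GRADED_SUPPORT)
        assert set(np.unique(panel.frame["exercise"])) <= {0.0, 1.0}

    def test_reference_coefficients_have_8_entries(self, default_reference):
        _, coefs = default_reference
        assert coefs.a.shape == (8,)


def test_generation_is_deterministic():
    a, ca = lw.generate_reference(lw.GeneratorConfig(seed=7))
    b, cb = lw.generate_reference(lw.GeneratorConfig(seed=7))
    pd.testing.assert_frame_equal(a.frame, b.frame)
    np.testing.assert_array_equal(ca.a, cb.a)
    c, _ = lw.generate_reference(lw.GeneratorConfig(seed=8))
    assert not a.frame.equals(c.frame)


def test_marginal_means_match_targets(default_reference):
    """Sample means land within 3 Monte-Carlo SEs of the configured means
    (e.g. breakfast 0.242 on the normalized scale)."""
    panel, _ = default_reference
    n = len(panel.frame)
    for name, spec in DEFAULT_BEHAVIOR_SPECS.items():
        sample_mean = panel.frame[name].mean()
        se = spec.sd / np.sqrt(n)
        assert abs(sample_mean - spec.mean) < 3 * se, (
            f"{name}: mean {sample_mean:.3f} vs target {spec.mean}"
        )


def test_proxy_score_marginal_plausible(default_reference):
    """The generated proxy score reproduces the published mean/SD scale."""
    panel, _ = default_reference
    assert panel.frame["y"].mean() == pytest.approx(0.634, abs=0.03)
    assert panel.frame["y"].std() == pytest.approx(0.159, abs=0.03)


def test_low_rank_spectrum(default_reference):
    """Top latent_rank+1 singular values carry >= 90% of the measured
    block's (centered) variance under default noise."""
    panel, _ = default_reference
    block = panel.measured()
    s = np.linalg.svd(block - block.mean(axis=0), compute_uv=False)
    frac = (s[:6] ** 2).sum() / (s**2).sum()
    assert frac >= 0.90


def test_noiseless_identifiability():
    """With no unit effects, no error noise and continuous marginals, the
    fitted coefficients reproduce the generating coefficients."""
    specs = {
        name: MarginalSpec(0.5, 0.15, "continuous") for name in lw.BEHAVIOR_VARS
    }
    cfg = lw.GeneratorConfig(
        behavior_specs=specs, sigma_mu=0.0, sigma_u=0.0, seed=3
    )
    _, coefs = lw.generate_reference(cfg)
    np.testing.assert_allclose(coefs.a, cfg.true_coefficients, atol=1e-6)


def test_time_variable_linear_map(default_reference):
    panel, _ = default_reference
    design = lw.build_design(panel)
    day = panel.frame["day_index"]
    assert design.loc[day == 1, "time"].eq(0).all()
    assert design.loc[day == 28, "time"].eq(1).all()
    # interior day: linear interpolation oracle
    assert design.loc[day == 15, "time"].unique() == pytest.approx(14 / 27)


def test_infeasible_marginal_names_variable():
    specs = dict(DEFAULT_BEHAVIOR_SPECS)
    specs["step_ach"] = MarginalSpec(0.5, 0.9, "continuous")  # SD too large
    with pytest.raises(ValueError, match="step_ach"):
        lw.generate_reference(lw.GeneratorConfig(behavior_specs=specs))


def test_config_roundtrip_through_dict():
    cfg = lw.GeneratorConfig(seed=11, latent_rank=3)
    back = config_from_dict(config_to_dict(cfg))
    assert back.seed == 11 and back.latent_rank == 3
    np.testing.assert_array_equal(back.true_coefficients, cfg.true_coefficients)
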