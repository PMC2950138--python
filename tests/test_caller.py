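"""Mixture-model copy-number calling: model selection, labeling, assignment."""

import numpy as np
import pandas as pd
import pytest

from mlpacall.caller import (
    ClusterModel,
    Component,
    _label_components,
    assign_integer_cn,
    call_samples,
    fit_ratio_clusters,
    flag_no_cnv,
)


@pytest.fixture(scope="module")
def three_cluster_model():
    rng = np.random.default_rng(17)
    x = np.concatenate(
        [rng.normal(1, 0.07, 60), rng.normal(2, 0.07, 480), rng.normal(3, 0.07, 60)]
    )
    return fit_ratio_clusters(x, probe_id="P", seed=17), x


class TestFit:
    def test_no_variation_single_component_cn2(self):
        rng = np.random.default_rng(0)
        m = fit_ratio_clusters(rng.normal(2.0, 0.02, 300), seed=0)
        assert m.k == 1
        assert m.components[0].cn == 2
        assert flag_no_cnv(m)

    def test_three_cluster_recovery(self, three_cluster_model):
        m, _ = three_cluster_model
        assert m.k == 3
        assert [c.cn for c in m.components] == [1, 2, 3]
        for c in m.components:
            assert abs(c.mean - c.cn) < 0.05

    def test_unimodal_uniform_flags_no_cnv(self):
        rng = np.random.default_rng(5)
        m = fit_ratio_clusters(rng.uniform(1.7, 2.3, 500), seed=5)
        assert flag_no_cnv(m)
        assert m.components[0].cn == 2

    def test_near_duplicate_components_merge_to_no_cnv(self):
        # indistinguishable split clusters collapse to one class; the fitted
        # model then reports it as the diploid no-CNV state
        comps, unit = _label_components(
            np.array([1.98, 2.02]), np.array([1e-4, 1e-4]), np.array([0.5, 0.5])
        )
        assert len(comps) == 1
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(1.98, 0.01, 250), rng.normal(2.02, 0.01, 250)])
        m = fit_ratio_clusters(x, seed=2)
        assert m.no_cnv and m.components[0].cn == 2

    def test_wt_only_probe_lattice_relabeling(self):
        # clusters at 0/2/4/6 (median individual has one countable copy):
        # the unit is the inter-cluster spacing, labels must be 0..3
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [
                np.abs(rng.normal(0, 0.02, 150)),
                rng.normal(2, 0.1, 400),
                rng.normal(4, 0.15, 300),
                rng.normal(6, 0.2, 30),
            ]
        )
        m = fit_ratio_clusters(x, seed=3)
        assert [c.cn for c in m.components] == [0, 1, 2, 3]
        assert m.unit == pytest.approx(2.0, abs=0.15)

    def test_noise_free_atoms_modeled_exactly(self):
        x = np.array([1.0] * 10 + [2.0] * 50 + [3.0] * 10)
        m = fit_ratio_clusters(x, seed=0)
        assert [c.cn for c in m.components] == [1, 2, 3]
        calls = [assign_integer_cn(m, v).cn for v in (1.0, 2.0, 3.0)]
        assert calls == [1, 2, 3]

    def test_determinism(self, three_cluster_model):
        _, x = three_cluster_model
        a = fit_ratio_clusters(x, seed=17).to_dict()
        b = fit_ratio_clusters(x, seed=17).to_dict()
        assert a == b

    def test_small_sample_limits_k(self):
        x = np.array([1.0, 1.1, 2.0, 2.1, 2.05, 1.95, 2.2, 1.9, 2.0, 3.0, 3.1, 2.02])
        m = fit_ratio_clusters(x, seed=1)  # only K <= 6 candidates possible
        assert max(m.bic_table) <= len(x) // 2

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match=">=10"):
            fit_ratio_clusters(np.ones(5) * 2)


class TestAssign:
    def test_modal_ratio_called_two(self, three_cluster_model):
        m, _ = three_cluster_model
        call = assign_integer_cn(m, m.components[1].mean)
        assert call.cn == 2 and call.posterior >= 0.5

    def test_tiny_ratio_called_zero(self, three_cluster_model):
        m, _ = three_cluster_model
        assert assign_integer_cn(m, 0.02).cn == 0

    def test_midway_posterior_half_and_low_confidence(self):
        m = ClusterModel(
            probe_id="P",
            components=(
                Component(1.0, 0.01, 0.5, 1),
                Component(2.0, 0.01, 0.5, 2),
            ),
            unit=1.0,
            no_cnv=False,
            bic_table={},
            n_samples=100,
            seed=0,
        )
        call = assign_integer_cn(m, 1.5)
        assert call.posterior == pytest.approx(0.5, abs=1e-9)
        assert call.low_confidence

    def test_calls_monotone_in_ratio(self, three_cluster_model):
        m, _ = three_cluster_model
        grid = np.linspace(0.0, 6.0, 400)
        calls = np.array([assign_integer_cn(m, r).cn for r in grid])
        assert (np.diff(calls) >= 0).all()

    def test_rare_high_cn_called_on_extrapolated_lattice(self, three_cluster_model):
        m, _ = three_cluster_model
        assert m.extrapolated, "lattice extension expected above fitted range"
        assert assign_integer_cn(m, 5.0).cn == 5

    def test_call_samples_handles_missing_ratios(self, three_cluster_model):
        m, _ = three_cluster_model
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "normalized_ratio": [2.0, np.nan]}
        )
        out = call_samples(m, df)
        assert out.loc[0, "cn"] == 2
        assert np.isnan(out.loc[1, "cn"])

    def test_no_cnv_probe_calls_constant_two(self):
        rng = np.random.default_rng(0)
        m = fit_ratio_clusters(rng.normal(2.0, 0.02, 300), probe_id="P3", seed=0)
        out = call_samples(
            m, pd.DataFrame({"sample_id": ["a", "b"], "normalized_ratio": [1.9, 2.1]})
        )
        assert (out["cn"] == 2).all()
        assert out["no_cnv_probe"].all()
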