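"""Synthetic cohort generator: determinism, distributions, renders, metrics."""

import numpy as np
import pandas as pd
import pytest

from mlpacall import assay, association, genotype as gt, pipeline, simulate as sim
from mlpacall.simulate import SimulationParams, case_cn_probs


class TestCohortSampling:
    def test_seed_determinism(self):
        a = sim.simulate_cohort(SimulationParams(n_cases=50, n_controls=50, seed=4))
        b = sim.simulate_cohort(SimulationParams(n_cases=50, n_controls=50, seed=4))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_two_copy_wild_type_cohort(self):
        p = SimulationParams(
            n_cases=20, n_controls=20, control_cn_probs={2: 1.0}, mt_allele_freq=0.0
        )
        truth = sim.simulate_cohort(p)
        assert (truth["cn_total"] == 2).all()
        assert all(c == ("WT", "WT") for c in truth["copies"])

    def test_class_and_allele_frequencies_recovered_at_large_n(self):
        p = SimulationParams(n_cases=5000, n_controls=5000, seed=12)
        truth = sim.simulate_cohort(p)
        n = len(truth)
        low = (truth["cn_total"] == 1).mean()
        high = (truth["cn_total"] >= 3).mean()
        for obs, expected in ((low, 0.067), (high, 0.094)):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) < 3 * se
        alleles = truth["wt_copies"].sum() + truth["mt_copies"].sum()
        mt_frac = truth["mt_copies"].sum() / alleles
        se = np.sqrt(0.407 * 0.593 / alleles)
        assert abs(mt_frac - 0.407) < 3 * se

    def test_truth_signals_obey_ligation_model(self):
        truth = sim.simulate_cohort(SimulationParams(n_cases=30, n_controls=30, seed=2))
        assert (truth[f"signal_{assay.PROBE_TOTAL}"] == truth["cn_total"]).all()
        assert (truth[f"signal_{assay.PROBE_WT_ONLY}"] == truth["wt_copies"]).all()


class TestCaseDistribution:
    def test_null_odds_ratios_are_identity(self):
        p = SimulationParams()
        assert case_cn_probs(p) == pytest.approx(p.control_cn_probs)

    def test_odds_rescaling_enriches_targeted_class(self):
        p = SimulationParams(cn_class_odds_ratios={1: 2.0})
        probs = case_cn_probs(p)
        assert probs[1] > p.control_cn_probs[1]
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_negative_odds_ratio_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            case_cn_probs(SimulationParams(cn_class_odds_ratios={1: -1.0}))

    def test_low_cn_effect_recovered_over_replicates(self):
        # simulate a true low-CN enrichment (OR 2.0) at the study's group
        # sizes and re-estimate the odds ratio from the sampled classes
        estimates = []
        for rep in range(200):
            p = SimulationParams(cn_class_odds_ratios={1: 2.0}, seed=5000 + rep)
            truth = sim.simulate_cohort(p)
            tab = pd.crosstab(truth["status"], truth["cn_total"] == 1)
            arr = np.array(
                [
                    [tab.loc["RA", True], tab.loc["RA", False]],
                    [tab.loc["control", True], tab.loc["control", False]],
                ]
            )
            estimates.append(association.odds_ratio(arr).odds_ratio)
        assert 1.6 <= float(np.median(estimates)) <= 2.5


class TestRenders:
    def test_noise_free_peaks_reproduce_signals_exactly(self):
        p = SimulationParams(
            n_cases=40, n_controls=40, mlpa_sigma=0.0, sample_scale_sigma=0.0, seed=6
        )
        truth = sim.simulate_cohort(p)
        peaks = sim.render_mlpa(truth, p)
        from mlpacall.normalize import compute_ratios

        ratios = compute_ratios(peaks, assay.CONTROL_GENES)
        merged = ratios[ratios["probe_id"] == assay.PROBE_TOTAL].merge(
            truth, on="sample_id"
        )
        np.testing.assert_allclose(
            merged["raw_ratio"], merged["cn_total"].astype(float), atol=1e-12
        )

    def test_no_cnv_probe_rendered_flat(self):
        p = SimulationParams(n_cases=60, n_controls=60, seed=8)
        truth = sim.simulate_cohort(p)
        peaks = sim.render_mlpa(truth, p)
        ratios, models, calls = pipeline.call_cohort(
            peaks, probe_ids=[assay.PROBE_NO_CNV], seed=8
        )
        assert models[assay.PROBE_NO_CNV].no_cnv
        assert (calls[assay.PROBE_NO_CNV]["cn"] == 2).all()

    def test_noise_free_qpcr_doubles_per_cycle(self):
        p = SimulationParams(
            n_cases=10,
            n_controls=10,
            control_cn_probs={2: 0.5, 4: 0.5},
            ct_sd=0.0,
            seed=3,
        )
        truth = sim.simulate_cohort(p)
        ct = sim.render_qpcr(truth, p)
        target = ct[ct["assay"] == "FCGR3B"].merge(truth, on="sample_id")
        two = target[target["cn_total"] == 2]["ct"].unique()
        four = target[target["cn_total"] == 4]["ct"].unique()
        assert len(two) == 1 and len(four) == 1
        assert two[0] - four[0] == pytest.approx(1.0)


class TestTruthMetrics:
    def _truth(self, n1):
        n = 100
        cn = np.array([1] * n1 + [2] * (n - n1))
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "wt_copies": cn,
                "mt_copies": 0,
                f"signal_{assay.PROBE_TOTAL}": cn,
            }
        )

    def test_perfect_calls(self):
        truth = self._truth(10)
        calls = pd.DataFrame(
            {"sample_id": truth["sample_id"], "cn": truth[f"signal_{assay.PROBE_TOTAL}"]}
        )
        m = sim.truth_metrics(truth, calls, assay.PROBE_TOTAL)
        assert m["accuracy"] == 1.0

    def test_constant_two_calls_miss_the_one_copy_class(self):
        truth = self._truth(10)
        calls = pd.DataFrame({"sample_id": truth["sample_id"], "cn": 2.0})
        m = sim.truth_metrics(truth, calls, assay.PROBE_TOTAL)
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["per_class_accuracy"][1] == 0.0

    def test_id_mismatch_rejected(self):
        truth = self._truth(5)
        calls = pd.DataFrame({"sample_id": ["nope"], "cn": [2.0]})
        with pytest.raises(ValueError, match="sample ids"):
            sim.truth_metrics(truth, calls, assay.PROBE_TOTAL)
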