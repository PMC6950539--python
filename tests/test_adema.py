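"""Network-constrained direction-of-change calls: group enumeration, the
mixed-type MI estimator, and the call logic with its oracle equivalences."""

import numpy as np
import pandas as pd
import pytest

from netmet.adema import (DirectionCall, enumerate_groups, estimate_mi,
                          predict_direction, run_adema)
from netmet.panel import default_network, load_network


def _net(edges):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_network(edges)


class TestGroupEnumeration:
    def test_isolated_node_has_only_its_singleton(self):
        groups = enumerate_groups(_net([]), k=3)
        assert all(len(gs) == 1 and gs[0].members == (a,)
                   for a, gs in groups.items())

    def test_anchor_with_two_neighbors_at_k2(self):
        net = _net([("glucose", "lactate"), ("glucose", "serine")])
        gs = enumerate_groups(net, k=2)["glucose"]
        members = {g.members for g in gs}
        assert members == {("glucose",), ("glucose", "lactate"),
                           ("glucose", "serine")}

    @pytest.mark.parametrize("d", [1, 3, 5])
    def test_star_center_group_count_is_degree_plus_one(self, d):
        leaves = ["lactate", "serine", "myo-inositol", "ascorbate",
                  "alanine"][:d]
        net = _net([("glucose", leaf) for leaf in leaves])
        gs = enumerate_groups(net, k=2)["glucose"]
        assert len(gs) == d + 1

    def test_k3_adds_connected_triples_through_the_anchor(self):
        net = _net([("glucose", "lactate"), ("glucose", "serine")])
        gs = enumerate_groups(net, k=3)["glucose"]
        assert ("glucose", "lactate", "serine") in {g.members for g in gs}

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            enumerate_groups(_net([]), k=0)


class TestMIEstimator:
    def test_fully_separated_classes_reach_one_bit(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(30, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        assert estimate_mi(x, y) == pytest.approx(1.0, abs=0.1)

    def test_never_negative(self):
        rng = np.random.default_rng(1)
        for i in range(20):
            mi = estimate_mi(rng.normal(size=20),
                             np.array([0] * 10 + [1] * 10))
            assert mi >= 0.0

    def test_constant_values_give_zero(self):
        assert estimate_mi(np.ones(20), np.array([0] * 10 + [1] * 10)) == 0.0

    def test_null_distribution_concentrates_near_zero(self):
        # at n = 46 the k-NN estimator's null noise is ~0.05 bits; the null
        # median sits below 0.05 and the upper tail below 0.2 bits
        rng = np.random.default_rng(2)
        nulls = np.array([
            estimate_mi(rng.normal(size=46), np.array([0] * 31 + [1] * 15))
            for _ in range(200)
        ])
        assert np.median(nulls) < 0.05
        assert np.quantile(nulls, 0.95) < 0.2

    def test_one_dimensional_case_agrees_with_reference_estimator(self):
        from sklearn.feature_selection import mutual_info_classif
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(2, 1, 60)])
        y = np.array([0] * 60 + [1] * 60)
        ours = estimate_mi(x, y, k=3)
        ref = mutual_info_classif(x[:, None], y, n_neighbors=3,
                                  random_state=0)[0] / np.log(2)
        assert ours == pytest.approx(ref, abs=0.02)

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi(np.arange(5.0), np.array([0, 0, 0, 1, 1]))


def _frame(case, control, name="m"):
    vals = np.concatenate([case, control])
    df = pd.DataFrame({name: vals})
    labels = pd.Series([True] * len(case) + [False] * len(control))
    return df, labels


class TestPredictDirection:
    def _groups(self, name="m"):
        from netmet.adema import MetaboliteGroup
        return [MetaboliteGroup(name, (name,))]

    def test_identical_distributions_call_same(self):
        vals = np.exp(np.linspace(0, 1, 10))
        df, labels = _frame(vals, vals)
        call = predict_direction("m", self._groups(), df, labels)
        assert call.call == "same"

    def test_planted_positive_shift_called_up_with_high_rate(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            case = np.exp(rng.normal(0.25, 0.25, 31))  # +1 SD on the log scale
            control = np.exp(rng.normal(0.0, 0.25, 15))
            df, labels = _frame(case, control)
            hits += predict_direction("m", self._groups(), df,
                                      labels).call == "up"
        assert hits / n_sim >= 0.90

    def test_sign_symmetry(self):
        rng = np.random.default_rng(5)
        case = np.exp(rng.normal(0.5, 0.2, 20))
        control = np.exp(rng.normal(0.0, 0.2, 20))
        df, labels = _frame(case, control)
        up = predict_direction("m", self._groups(), df, labels)
        df2, labels2 = _frame(control, case)
        down = predict_direction("m", self._groups(), df2, labels2)
        assert (up.call, down.call) == ("up", "down")

    def test_boundary_at_epsilon_stays_same(self):
        case = np.full(5, 1.05)
        control = np.ones(5)
        df, labels = _frame(case, control)
        call = predict_direction("m", self._groups(), df, labels,
                                 epsilon=0.05, min_z=0.0)
        assert call.call == "same"

    def test_no_groups_for_anchor_rejected(self):
        df, labels = _frame(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="no groups"):
            predict_direction("m", [], df, labels)


class TestRunAdema:
    def test_empty_network_reduces_to_threshold_comparison(self, quant_table,
                                                           default_cohort):
        """With singleton groups and no z-gate the calls must equal a direct
        epsilon-thresholded comparison of class geometric means."""
        manifest, _ = default_cohort
        contrast = {"metastases_at_diagnosis": ("metastatic", True, False)}
        dm = run_adema(quant_table, manifest, net=_net([]),
                       contrasts=contrast, min_z=0.0, epsilon=0.05)
        meta = manifest.set_index("sample_id")
        prim = meta[meta.tissue_class == "primary_tumor"]
        case_ids = prim.index[prim.metastatic == True]  # noqa: E712
        ctrl_ids = prim.index[prim.metastatic == False]  # noqa: E712
        for m in quant_table.columns:
            gcase = np.exp(np.mean(np.log(quant_table.loc[case_ids, m])))
            gctrl = np.exp(np.mean(np.log(quant_table.loc[ctrl_ids, m])))
            rel = gcase / gctrl - 1
            expected = "up" if rel > 0.05 else ("down" if rel < -0.05 else "=")
            assert dm.calls.loc[m, "metastases_at_diagnosis"] == expected

    def test_default_cohort_gives_27_by_7_matrix(self, quant_table,
                                                 default_cohort):
        manifest, _ = default_cohort
        dm = run_adema(quant_table, manifest)
        assert dm.calls.shape == (27, 7)
        assert set(np.unique(dm.calls.to_numpy())) <= {"up", "down", "="}

    def test_deterministic_given_fixed_inputs(self, quant_table,
                                              default_cohort):
        manifest, _ = default_cohort
        contrast = {"tumor_grade": ("grade", "G1", "G2")}
        a = run_adema(quant_table, manifest, contrasts=contrast)
        b = run_adema(quant_table, manifest, contrasts=contrast)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_contrast_with_too_small_side_is_skipped(self, quant_table,
                                                     default_cohort):
        manifest, _ = default_cohort
        manifest = manifest.copy()
        manifest.loc[manifest.tissue_class == "primary_tumor",
                     "functional"] = True
        dm = run_adema(quant_table, manifest,
                       contrasts={"tumor_secretion":
                                  ("functional", True, False)})
        assert dm.calls.shape[1] == 0

    def test_monotone_recovery_in_effect_size(self):
        """Stronger planted shifts never recover worse (3-point effect grid)."""
        from netmet.cohort import CohortConfig, generate_cohort
        from netmet.panel import default_effect_table

        eff0 = default_effect_table() * 0.0
        signs = np.sign(default_effect_table()["metastases_at_diagnosis"])
        nonzero = signs[signs != 0]
        rates = []
        for mag in (0.25, 1.0, 2.0):
            eff = eff0.copy()
            eff["metastases_at_diagnosis"] = signs * mag
            hits = total = 0
            for seed in range(8):
                cfg = CohortConfig(seed=seed, effect_table=eff,
                                   n_liver_mets=0, n_normal_si=0,
                                   n_normal_liver=0)
                manifest, truth = generate_cohort(cfg)
                dm = run_adema(truth, manifest,
                               contrasts={"metastases_at_diagnosis":
                                          ("metastatic", True, False)})
                got = dm.calls["metastases_at_diagnosis"].map(
                    {"up": 1, "down": -1, "=": 0})
                hits += sum(got[m] == nonzero[m] for m in nonzero.index)
                total += len(nonzero)
            rates.append(hits / total)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.95
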