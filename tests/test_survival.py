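import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from fi_netkit.io import ClinicalTable, GeneSet, MutationTable
from fi_netkit.modules import ModuleAssignment
from fi_netkit.survival import (
    GroupLabels,
    coxph_group,
    km_curves,
    km_logrank,
    module_survival_scan,
    split_samples,
)

from helpers import logrank_chi2_hand


def _mut(records):
    return MutationTable(
        pd.DataFrame(records, columns=["gene", "sample", "variant_classification"])
    )


def _clin(samples, times, events):
    return ClinicalTable(pd.DataFrame({"sample": samples, "time": times, "event": events}))


class TestSplitSamples:
    def test_carrier_gets_group_one(self):
        mut = _mut([("A", "S1", "M")])
        clin = _clin(["S1", "S2"], [1.0, 2.0], [1, 1])
        groups = split_samples(GeneSet("m", frozenset({"A"})), mut, clin)
        assert groups.labels == {"S1": 1, "S2": 0}

    def test_empty_module_all_group_zero(self):
        mut = _mut([("A", "S1", "M")])
        clin = _clin(["S1"], [1.0], [1])
        groups = split_samples(GeneSet("m", frozenset({"ZZZ"})), mut, clin)
        assert set(groups.labels.values()) == {0}

    def test_clinical_only_samples_default_group_zero_or_dropped(self):
        mut = _mut([("A", "S1", "M")])
        clin = _clin(["S1", "S9"], [1.0, 2.0], [1, 1])
        gs = GeneSet("m", frozenset({"A"}))
        assert "S9" in split_samples(gs, mut, clin).labels
        assert "S9" not in split_samples(gs, mut, clin, drop_unmutated_samples=True).labels

    def test_mutation_only_samples_dropped_and_reported(self):
        mut = _mut([("A", "S1", "M"), ("A", "SX", "M")])
        clin = _clin(["S1"], [1.0], [1])
        groups = split_samples(GeneSet("m", frozenset({"A"})), mut, clin)
        assert "SX" not in groups.labels
        assert groups.dropped_samples == {"SX"}

    def test_no_shared_samples_errors(self):
        mut = _mut([("A", "SX", "M")])
        clin = _clin(["S1"], [1.0], [1])
        with pytest.raises(ValueError, match="shared"):
            split_samples(GeneSet("m", frozenset({"A"})), mut, clin)

    def test_planted_carrier_fixture(self):
        rng = np.random.default_rng(8)
        samples = [f"S{i:02d}" for i in range(40)]
        carriers = set(rng.choice(samples, size=15, replace=False))
        records = [("MOD", s, "M") for s in carriers] + [("OTHER", s, "M") for s in samples]
        groups = split_samples(
            GeneSet("m", frozenset({"MOD"})),
            _mut(records),
            _clin(samples, rng.exponential(1, 40), [1] * 40),
        )
        assert {s for s, v in groups.labels.items() if v == 1} == carriers


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        clin = _clin(["S1", "S2"], [1.0, 2.0], [1, 1])
        groups = GroupLabels({"S1": 0, "S2": 0})
        curve = km_curves(groups, clin)[0]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(0.5)
        assert surv[2.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        n = 60
        times = rng.exponential(1.0, n)
        clin = _clin([f"S{i}" for i in range(n)], times, [1] * n)
        curve = km_curves(GroupLabels({f"S{i}": 0 for i in range(n)}), clin)[0]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_identical_groups_logrank_p_one(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        clin = _clin([f"S{i}" for i in range(6)], times, [1] * 6)
        groups = GroupLabels({f"S{i}": int(i >= 3) for i in range(6)})
        _, p = km_logrank(groups, clin)
        assert p == pytest.approx(1.0)

    def test_six_sample_logrank_matches_hand_statistic(self):
        # small worked example checked against the observed-expected sum
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        grp = [0, 1, 0, 1, 0, 1]
        clin = _clin([f"S{i}" for i in range(6)], times, events)
        groups = GroupLabels({f"S{i}": grp[i] for i in range(6)})
        _, p = km_logrank(groups, clin)
        stat = logrank_chi2_hand(times, events, grp)
        assert p == pytest.approx(chi2.sf(stat, df=1), rel=1e-9)

    def test_missing_group_errors(self):
        clin = _clin(["S1", "S2"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="both groups"):
            km_logrank(GroupLabels({"S1": 0, "S2": 0}), clin)


class TestCoxPH:
    @staticmethod
    def _simulate(n, hr, seed, censor=0.2):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(grp == 1, hr, 1.0))
        cens = rng.random(n) < censor
        times = np.where(cens, t * rng.random(n), t)
        events = (~cens).astype(int)
        clin = _clin([f"S{i}" for i in range(n)], times, events)
        return GroupLabels({f"S{i}": int(grp[i]) for i in range(n)}), clin

    def test_null_log_hr_small(self):
        groups, clin = self._simulate(500, 1.0, seed=21)
        cox = coxph_group(groups, clin)
        assert abs(cox.log_hr) < 0.2

    def test_relabeling_inverts_hazard_ratio(self):
        groups, clin = self._simulate(150, 2.0, seed=5)
        flipped = GroupLabels({s: 1 - v for s, v in groups.labels.items()})
        a, b = coxph_group(groups, clin), coxph_group(flipped, clin)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, rel=1e-6)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_no_events_errors(self):
        clin = _clin(["S1", "S2"], [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="events"):
            coxph_group(GroupLabels({"S1": 0, "S2": 1}), clin)

    def test_complete_separation_flagged(self):
        # all events in group 1, none in group 0, with group-1 deaths
        # preceding every group-0 censoring time: monotone likelihood
        clin = _clin(
            [f"S{i}" for i in range(8)],
            [0.1, 0.2, 0.3, 0.4, 9.0, 9.0, 9.0, 9.0],
            [1, 1, 1, 1, 0, 0, 0, 0],
        )
        groups = GroupLabels({f"S{i}": int(i < 4) for i in range(8)})
        cox = coxph_group(groups, clin)
        assert not cox.converged
        assert cox.hazard_ratio == np.inf


class TestModuleScan:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i:03d}" for i in range(120)]
        genes = {f"M0_{j}": 0 for j in range(4)} | {f"M1_{j}": 1 for j in range(4)}
        records = []
        for s in samples:
            for g in genes:
                if rng.random() < 0.1:
                    records.append((g, s, "M"))
        clin = _clin(samples, rng.exponential(1.0, 120), rng.integers(0, 2, 120))
        return ModuleAssignment(genes), _mut(records), clin

    def test_single_module_fdr_equals_p(self):
        assign, mut, clin = self._inputs()
        one = ModuleAssignment({g: 0 for g in assign.mapping if g.startswith("M0")})
        scan = module_survival_scan(one, mut, clin, min_module_size=2)
        assert len(scan) == 1
        assert scan.iloc[0]["fdr"] == scan.iloc[0]["coxph_p"]

    def test_all_modules_below_min_size_gives_empty_with_warning(self, caplog):
        assign, mut, clin = self._inputs()
        scan = module_survival_scan(assign, mut, clin, min_module_size=50)
        assert len(scan) == 0
        assert "empty scan" in caplog.text

    def test_invariant_to_sample_order(self):
        assign, mut, clin = self._inputs(3)
        scan1 = module_survival_scan(assign, mut, clin, min_module_size=2)
        shuffled = ClinicalTable(clin.df.sample(frac=1.0, random_state=9).reset_index(drop=True))
        mut2 = MutationTable(mut.df.sample(frac=1.0, random_state=10).reset_index(drop=True))
        scan2 = module_survival_scan(assign, mut2, shuffled, min_module_size=2)
        pd.testing.assert_frame_equal(scan1, scan2)

    def test_group_sizes_partition_the_cohort(self):
        assign, mut, clin = self._inputs(4)
        scan = module_survival_scan(assign, mut, clin, min_module_size=2)
        assert ((scan["n0"] + scan["n1"]) == len(clin)).all()


def test_logrank_and_cox_agree_on_large_samples():
    """Wald CoxPH p and log-rank p coincide asymptotically (two-group, n=1000)."""
    close = 0
    for seed in range(10):
        groups, clin = TestCoxPH._simulate(1000, 1.0, seed=2000 + seed)
        _, lr = km_logrank(groups, clin)
        cox = coxph_group(groups, clin)
        close += abs(lr - cox.p_value) < 0.01
    assert close >= 9
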