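import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyldrift import io as mio
from methyldrift import survey
from oracles import bh_stepup, pearson_loop


def _matrix(values, probes=None, samples=None, scale="m"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return mio.MethylationMatrix(
        pd.DataFrame(values, index=probes, columns=samples), scale=scale
    )


class TestSelectHypomethylated:
    def test_strict_threshold(self):
        ns = _matrix([[0.1, 0.2], [0.25, 0.25]], scale="beta")
        selected = survey.select_hypomethylated(ns, beta_max=0.25)
        assert selected == {"cg000"}  # mean 0.15 in, mean 0.25 out (strict <)

    def test_hand_counted_toy(self):
        rng = np.random.default_rng(0)
        means = np.array([0.1, 0.2, 0.24, 0.249, 0.3, 0.5, 0.7, 0.26, 0.4, 0.9])
        ns = _matrix(np.tile(means[:, None], (1, 3)), scale="beta")
        assert survey.select_hypomethylated(ns) == {"cg000", "cg001", "cg002", "cg003"}

    def test_split_returns_hyper_set(self):
        ns = _matrix([[0.1], [0.5], [0.9]], scale="beta")
        hypo, hyper = survey.split_by_ns_level(ns)
        assert hypo == {"cg000"}
        assert hyper == {"cg002"}


class TestClockDrift:
    def test_zero_drift_when_equal_to_reference(self):
        m = _matrix([[1.0, 2.0], [0.5, 0.5]])
        ref = pd.Series([1.0, 0.5], index=["cg000", "cg001"])
        clock = mio.ClockSet(["cg000", "cg001"])
        drift = survey.compute_clock_drift(m, clock, ref)
        assert drift["S0"] == pytest.approx(0.0)

    def test_uniform_elevation(self):
        ref = pd.Series([0.0, 1.0, -1.0], index=["cg000", "cg001", "cg002"])
        m = _matrix((ref.to_numpy() + 1.0)[:, None])
        drift = survey.compute_clock_drift(m, mio.ClockSet(list(ref.index)), ref)
        assert drift["S0"] == pytest.approx(1.0)

    def test_hand_computed_means(self):
        # 3-probe clock, 2 samples, hand arithmetic
        m = _matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]])
        ref = pd.Series([0.5, 1.0, 1.5], index=["cg000", "cg001", "cg002"])
        drift = survey.compute_clock_drift(m, mio.ClockSet(list(ref.index)), ref)
        assert drift["S0"] == pytest.approx((0.5 + 1.0 + 1.5) / 3)
        assert drift["S1"] == pytest.approx((3.5 + 4.0 + 7.5) / 3)

    def test_missing_clock_probe_listed(self):
        m = _matrix([[1.0]])
        ref = pd.Series([0.0], index=["cg000"])
        with pytest.raises(mio.DomainError, match="cg999"):
            survey.compute_clock_drift(m, mio.ClockSet(["cg000", "cg999"]), ref)


class TestBHAdjust:
    def test_single_p(self):
        assert survey.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            survey.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(survey.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(mio.DomainError):
            survey.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_stepup_definition_and_monotone(self, p):
        q = survey.bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup(np.asarray(p)), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(survey.bh_adjust(p), q_sm, atol=1e-12)


class TestScanProbes:
    def test_probe_equal_to_drift_has_r_one(self):
        drift = pd.Series([0.1, 0.4, 0.9, 1.5], index=[f"S{j}" for j in range(4)])
        m = _matrix(np.vstack([drift.to_numpy(), [1, 2, 3, 4]]))
        calls = survey.scan_probes(m, drift, set(m.probe_ids))
        assert calls.loc["cg000", "r"] == pytest.approx(1.0)
        assert calls.loc["cg001", "r"] < 1.0  # monotone but not perfectly linear

    def test_perfect_linearity(self):
        drift = pd.Series([2.0, 4.0, 6.0], index=["S0", "S1", "S2"])
        m = _matrix([[1.0, 2.0, 3.0]])
        calls = survey.scan_probes(m, drift, {"cg000"})
        assert calls.loc["cg000", "r"] == pytest.approx(1.0)
        assert calls.loc["cg000", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_probe_excluded(self):
        drift = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{j}" for j in range(4)])
        m = _matrix([[0.5, 0.5, 0.5, 0.5], [1, 2, 3, 5]])
        calls = survey.scan_probes(m, drift, set(m.probe_ids))
        assert calls.loc["cg000", "call"] == "excluded"
        assert calls.loc["cg001", "call"] != "excluded"

    def test_zero_variance_drift_is_global_error(self):
        drift = pd.Series([1.0, 1.0, 1.0], index=["S0", "S1", "S2"])
        m = _matrix([[1, 2, 3]])
        with pytest.raises(mio.DomainError):
            survey.scan_probes(m, drift, {"cg000"})

    def test_clock_probes_removed_from_test_set(self):
        drift = pd.Series([1.0, 2.0, 3.0], index=["S0", "S1", "S2"])
        m = _matrix([[1, 2, 3], [3, 2, 1]])
        clock = mio.ClockSet(["cg000"])
        calls = survey.scan_probes(m, drift, set(m.probe_ids), clock=clock)
        assert "cg000" not in calls.index

    def test_against_bruteforce_oracle(self):
        """Planted-correlate scan matches per-probe covariance-formula r/p
        and step-up BH to 1e-10, including missing values."""
        rng = np.random.default_rng(42)
        n_probes, n_samples = 100, 20
        drift_vals = rng.normal(size=n_samples)
        x = rng.normal(size=(n_probes, n_samples))
        x[:10] = drift_vals[None, :] * 2 + rng.normal(scale=0.1, size=(10, n_samples))
        x[rng.random(size=x.shape) < 0.05] = np.nan  # scattered missingness
        samples = [f"S{j}" for j in range(n_samples)]
        m = _matrix(x, samples=samples)
        drift = pd.Series(drift_vals, index=samples)
        calls = survey.scan_probes(m, drift, set(m.probe_ids))

        oracle_r, oracle_p, keep = {}, {}, []
        for i, pid in enumerate(m.probe_ids):
            r, p, n = pearson_loop(x[i], drift_vals)
            if np.isfinite(r):
                keep.append(pid)
                oracle_r[pid], oracle_p[pid] = r, p
        oracle_q = dict(zip(keep, bh_stepup(np.array([oracle_p[k] for k in keep]))))
        for pid in keep:
            assert calls.loc[pid, "r"] == pytest.approx(oracle_r[pid], abs=1e-10)
            assert calls.loc[pid, "p"] == pytest.approx(oracle_p[pid], abs=1e-10)
            assert calls.loc[pid, "q"] == pytest.approx(oracle_q[pid], abs=1e-10)
            expected_call = (
                "drift_positive"
                if oracle_r[pid] > 0.5 and oracle_q[pid] < 0.01
                else "drift_negative"
                if oracle_r[pid] < -0.5 and oracle_q[pid] < 0.01
                else "static"
            )
            assert calls.loc[pid, "call"] == expected_call


class TestAggregateIslands:
    def _calls(self, mapping):
        return pd.DataFrame(
            {"call": list(mapping.values())},
            index=pd.Index(list(mapping.keys()), name="probe_id"),
        )

    def _probes(self, assignments):
        return pd.DataFrame(
            [
                {
                    "probe_id": pid,
                    "chrom": "chr1",
                    "pos": 100 + i,
                    "island_id": isl,
                    "relation": "island",
                    "gene_region": "TSS200",
                }
                for i, (pid, isl) in enumerate(assignments.items())
            ]
        )

    def test_boundary_inclusive_at_min_drift(self):
        probes = self._probes({f"cg{i}": "isl_1" for i in range(5)})
        calls = self._calls({f"cg{i}": "drift_positive" for i in range(5)})
        out = survey.aggregate_islands(calls, probes, min_drift=5)
        assert out.loc["isl_1", "is_drift_island"]

    def test_below_threshold(self):
        probes = self._probes({f"cg{i}": "isl_1" for i in range(5)})
        mapping = {f"cg{i}": "drift_positive" for i in range(4)}
        mapping["cg4"] = "static"
        out = survey.aggregate_islands(self._calls(mapping), probes, min_drift=5)
        assert not out.loc["isl_1", "is_drift_island"]

    def test_drift_count_conservation(self, small_cohort, small_manifest, be_matrix, ns_matrix):
        clock = mio.ClockSet(small_manifest.clock_probe_ids)
        hypo = survey.select_hypomethylated(ns_matrix)
        drift = survey.compute_clock_drift(
            be_matrix.to_m(), clock, survey.ns_reference(ns_matrix)
        )
        calls = survey.scan_probes(be_matrix.to_m(), drift, hypo, clock=clock)
        out = survey.aggregate_islands(calls, small_manifest.probes)
        island_probe_ids = set(
            small_manifest.probes.loc[
                small_manifest.probes["relation"] == "island", "probe_id"
            ]
        )
        n_island_drift_calls = sum(
            1
            for pid in calls.index[calls["call"] == "drift_positive"]
            if pid in island_probe_ids
        )
        assert out["n_drift"].sum() == n_island_drift_calls


class TestAnnotationProportions:
    def _probes(self, relations):
        return pd.DataFrame(
            [
                {
                    "probe_id": f"cg{i}",
                    "chrom": "chr1",
                    "pos": i + 1,
                    "island_id": "isl_1" if rel != "open_sea" else None,
                    "relation": rel,
                    "gene_region": "TSS200",
                }
                for i, rel in enumerate(relations)
            ]
        )

    def test_all_island_drift(self):
        probes = self._probes(["island"] * 4)
        calls = pd.DataFrame(
            {"call": ["drift_positive"] * 4},
            index=pd.Index([f"cg{i}" for i in range(4)], name="probe_id"),
        )
        out = survey.annotation_proportions(calls, probes)
        rel = out[out["margin"] == "relation"].set_index("level")
        assert rel.loc["island", "drift_fraction"] == pytest.approx(1.0)

    def test_hand_counted_open_sea_fraction(self):
        probes = self._probes(["island"] * 8 + ["open_sea"] * 2)
        call = ["drift_positive"] * 8 + ["drift_positive"] * 2
        calls = pd.DataFrame(
            {"call": call}, index=pd.Index([f"cg{i}" for i in range(10)], name="probe_id")
        )
        out = survey.annotation_proportions(calls, probes)
        rel = out[out["margin"] == "relation"].set_index("level")
        assert rel.loc["open_sea", "drift_fraction"] == pytest.approx(0.2)
        assert rel["drift_fraction"].sum() == pytest.approx(1.0)

    def test_zero_drift_calls_gives_explicit_empty(self):
        probes = self._probes(["island"] * 3)
        calls = pd.DataFrame(
            {"call": ["static"] * 3},
            index=pd.Index([f"cg{i}" for i in range(3)], name="probe_id"),
        )
        out = survey.annotation_proportions(calls, probes)
        assert len(out) == 0

    def test_empty_call_table_rejected(self):
        probes = self._probes(["island"])
        with pytest.raises(mio.DomainError):
            survey.annotation_proportions(
                pd.DataFrame(columns=["call"]), probes
            )
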