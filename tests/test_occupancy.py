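import numpy as np
import pandas as pd
import pytest

from ionbridge import datasets, occupancy, sites, synth
from ionbridge.io import Trajectory
from ionbridge.occupancy import (
    aggregate_by_positive_site,
    count_above_thresholds,
    cross_condition_mean,
    distance_series,
    effective_sample_size,
    ion_site_occupancy,
    occupancy_percent,
    per_site_average,
    subunit_average,
    windowed_occupancy,
)

from conftest import make_two_atom_trajectory


def _series(distances):
    topology, traj = make_two_atom_trajectory(distances)
    found = sites.identify_charged_sites(topology, include_termini=False)
    pair = sites.enumerate_candidate_pairs(found)[0]
    return distance_series(traj, pair), pair, traj


class TestOccupancyPercent:
    def test_all_frames_bound_gives_100(self):
        series, _, _ = _series([0.45] * 10)
        assert occupancy_percent(series).occupancy_pct == 100.0

    def test_exact_cutoff_frames_never_count(self):
        series, _, _ = _series([0.60] * 10)
        assert occupancy_percent(series).occupancy_pct == 0.0

    def test_distance_stats_use_sample_sd(self):
        series, _, _ = _series([0.4, 0.5, 0.6])
        rec = occupancy_percent(series)
        assert rec.mean_distance == pytest.approx(0.5)
        assert rec.sd_distance == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1))
        assert rec.n_frames == 3

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        series, _, _ = _series(rng.uniform(0.2, 1.4, 500))
        values = [
            occupancy_percent(series, cutoff=c).occupancy_pct
            for c in np.linspace(0.05, 2.0, 25)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[0] == 0.0 and values[-1] == 100.0

    def test_two_state_markov_recovery_within_three_effective_se(self):
        """Stationary bound fraction 0.75 recovered from 40 000 frames."""
        spec = synth.default_spec(p=0.75, n_frames=40_000, seed=7)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        found = sites.identify_charged_sites(topology, include_termini=False)
        pair = next(
            q
            for q in sites.enumerate_candidate_pairs(found)
            if q.positive.residue_name == "LYS" and q.scope == "intra"
            and q.positive.chain_id == "A" and q.negative.residue_name == "GLU"
        )
        series = distance_series(traj, pair)
        rec = occupancy_percent(series)
        bound = (series.distances < 0.6).astype(float)
        ess = effective_sample_size(bound)
        p_hat = rec.occupancy_pct / 100
        se = np.sqrt(p_hat * (1 - p_hat) / ess) * 100
        expected = spec.analytic_occupancy(0.75)
        assert abs(rec.occupancy_pct - expected) < 3 * se
        # oracle: direct count
        assert rec.occupancy_pct == pytest.approx(100 * bound.mean())


class TestSubunitAverage:
    def _records(self, occupancies):
        spec = synth.default_spec(p=1.0, n_frames=3, seed=0)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        found = sites.identify_charged_sites(topology, include_termini=False)
        pairs = [
            q
            for q in sites.enumerate_candidate_pairs(found)
            if q.scope == "intra"
            and q.positive.residue_name == "LYS"
            and q.negative.residue_name == "GLU"
        ]
        assert len(pairs) == 3  # one per subunit
        records = []
        for pair, occ in zip(pairs, occupancies):
            rec = occupancy_percent(distance_series(traj, pair))
            rec.occupancy_pct = occ
            records.append(rec)
        return records

    @pytest.mark.parametrize(
        "occupancies,expected",
        [((100.0, 100.0, 100.0), 100.0), ((0.0, 50.0, 100.0), 50.0)],
    )
    def test_mean_across_subunits(self, occupancies, expected):
        avg = subunit_average(self._records(occupancies))
        assert avg.occupancy_pct == pytest.approx(expected)

    def test_random_triple_equals_hand_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, 3)
        avg = subunit_average(self._records(tuple(vals)))
        assert avg.occupancy_pct == pytest.approx(vals.mean())

    def test_mismatched_pairs_rejected(self):
        spec = synth.default_spec(p=1.0, n_frames=3, seed=0)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        found = sites.identify_charged_sites(topology, include_termini=False)
        pairs = sites.enumerate_candidate_pairs(found)
        r1 = occupancy_percent(distance_series(traj, pairs[0]))
        different = next(
            q for q in pairs if q.negative.residue_seq != pairs[0].negative.residue_seq
        )
        r2 = occupancy_percent(distance_series(traj, different))
        with pytest.raises(ValueError, match="mismatched"):
            subunit_average([r1, r2])


class TestAggregation:
    """Aggregation arithmetic on the bundled per-pair occupancy tables."""

    def test_per_site_sum_reference_value(self):
        table = datasets.load_occupancy_table("intra")
        charmm = table[table["condition"] == "Charmm27_tip3p"]
        sums = aggregate_by_positive_site(charmm)
        arg68 = sums.loc[sums["positive_site"] == "Arg68", "intra_sum"].item()
        assert arg68 == pytest.approx(193.9)

    def test_combined_equals_intra_plus_inter_exactly(self):
        table = datasets.load_occupancy_table("both")
        g43 = table[table["condition"] == "Gromos43a1_spce"]
        sums = aggregate_by_positive_site(g43)
        assert np.allclose(
            sums["combined_sum"], sums["intra_sum"] + sums["inter_sum"], atol=0
        )
        arg33 = sums.loc[sums["positive_site"] == "Arg33"]
        assert arg33["intra_sum"].item() == pytest.approx(54.8)
        assert arg33["inter_sum"].item() == pytest.approx(66.5)
        assert arg33["combined_sum"].item() == pytest.approx(121.3)

    def test_site_with_no_partners_sums_to_zero(self):
        df = pd.DataFrame(
            {
                "positive_site": ["a", "a", "b"],
                "scope": ["intra", "intra", "inter"],
                "occupancy_pct": [10.0, 20.0, 5.0],
            }
        )
        sums = aggregate_by_positive_site(df)
        b = sums.loc[sums["positive_site"] == "b"]
        assert b["intra_sum"].item() == 0.0
        assert b["combined_sum"].item() == pytest.approx(5.0)

    def test_per_site_average_reference_values(self):
        intra = datasets.load_occupancy_table("intra")
        g53 = intra[intra["condition"] == "Gromos53a6_spce"]
        assert round(per_site_average(g53, "intra"), 1) == 74.0
        inter = datasets.load_occupancy_table("inter")
        charmm = inter[inter["condition"] == "Charmm27_tip3p"]
        assert round(per_site_average(charmm, "inter"), 1) == 23.7

    def test_single_site_average_is_its_sum(self):
        df = pd.DataFrame(
            {"positive_site": ["a"], "scope": ["intra"], "occupancy_pct": [50.0]}
        )
        assert per_site_average(df, "intra") == 50.0

    def test_exclusion_changes_denominator(self):
        ion = datasets.load_ion_occupancy_table()
        charmm = ion[ion["condition"] == "Charmm27_tip3p"]
        all17 = charmm["residue_occupancy_pct"].mean()
        no_arg33 = charmm.loc[
            charmm["positive_site"] != "Arg33", "residue_occupancy_pct"
        ].mean()
        assert round(all17, 1) == 99.3
        assert round(no_arg33, 1) == 105.5


class TestCrossConditionMean:
    def test_intra_grand_mean(self):
        mean, _ = cross_condition_mean([82.5, 83.6, 79.7, 77.7, 79.0, 74.0])
        assert round(mean, 1) == 79.4

    def test_combined_grand_mean_and_sample_sd(self):
        mean, sd = cross_condition_mean([105.5, 112.1, 110.6, 103.8, 104.9, 93.5])
        assert round(mean, 1) == 105.1
        assert round(sd, 1) == 6.6  # n−1 convention

    def test_identical_values_have_zero_sd(self):
        mean, sd = cross_condition_mean([50.0, 50.0, 50.0])
        assert (mean, sd) == (50.0, 0.0)

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError):
            cross_condition_mean([1.0])


class TestThresholdCounts:
    def test_all_at_100(self):
        out = count_above_thresholds([100.0] * 10, thresholds=[0.1, 90])
        assert out["count"].tolist() == [10, 10]
        assert out["percent"].tolist() == [100.0, 100.0]

    def test_strict_inequality_at_threshold(self):
        out = count_above_thresholds([0.05, 0.5, 50.0, 0.1], thresholds=[0.1])
        assert out["count"].item() == 2  # the exact-0.1 record does not count

    def test_random_records_match_brute_force(self):
        rng = np.random.default_rng(8)
        occ = rng.uniform(0, 100, 200)
        out = count_above_thresholds(occ)
        for _, row in out.iterrows():
            assert row["count"] == int(np.sum(occ > row["threshold"]))
            assert row["percent"] == pytest.approx(100 * row["count"] / 200)


class TestWindowedOccupancy:
    def _bridge(self, distances):
        topology, traj = make_two_atom_trajectory(distances)
        found = sites.identify_charged_sites(topology, include_termini=False)
        pair = sites.enumerate_candidate_pairs(found)[0]
        return topology, traj, pair

    def test_400_frames_make_four_windows(self):
        _, traj, pair = self._bridge([0.3] * 400)
        out = windowed_occupancy(traj, [pair], window_ns=100)
        assert out["window"].nunique() == 4

    def test_bound_only_in_first_window(self):
        distances = [0.3] * 100 + [1.0] * 300
        _, traj, pair = self._bridge(distances)
        out = windowed_occupancy(traj, [pair], window_ns=100)
        assert out["occupancy_pct"].tolist() == pytest.approx([100.0, 0.0, 0.0, 0.0])

    def test_frame_weighted_average_equals_global(self):
        rng = np.random.default_rng(17)
        distances = rng.uniform(0.2, 1.2, 437)  # deliberately non-multiple length
        _, traj, pair = self._bridge(distances)
        out = windowed_occupancy(traj, [pair], window_ns=100)
        assert out["n_frames"].sum() == 437
        weighted = (out["occupancy_pct"] * out["n_frames"]).sum() / 437
        global_occ = occupancy_percent(distance_series(traj, pair)).occupancy_pct
        assert weighted == pytest.approx(global_occ, abs=1e-12)

    def test_stationary_series_windows_near_global(self):
        spec = synth.default_spec(p=0.5, n_frames=40_000, seed=21)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        found = sites.identify_charged_sites(topology, include_termini=False)
        pair = next(
            q
            for q in sites.enumerate_candidate_pairs(found)
            if q.positive.residue_name == "LYS" and q.scope == "intra"
            and q.positive.chain_id == "A" and q.negative.residue_name == "GLU"
        )
        series = distance_series(traj, pair)
        bound = (series.distances < 0.6).astype(float)
        out = windowed_occupancy(traj, [pair], window_ns=100)  # 4 windows of 10k
        global_occ = 100 * bound.mean()
        for _, row in out.iterrows():
            win_bound = bound[
                int(row["start_ns"] / spec.dt_ns) : int(row["end_ns"] / spec.dt_ns)
            ]
            ess = effective_sample_size(win_bound)
            p = max(min(row["occupancy_pct"] / 100, 1 - 1e-9), 1e-9)
            se = 100 * np.sqrt(p * (1 - p) / ess)
            assert abs(row["occupancy_pct"] - global_occ) < 3 * se + 1e-9


class TestIonOccupancy:
    def _site(self, topology):
        found = sites.identify_charged_sites(topology, include_termini=False)
        return [s for s in found if s.polarity == +1][0]

    def test_single_ion_fixed_near(self):
        spec = synth.default_spec(p=1.0, n_frames=50, seed=0)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        site = self._site(topology)
        topo2, traj2 = synth.place_ions(
            topology, traj, site.reference_atom, "CL", [1.0], seed=4
        )
        res = ion_site_occupancy(traj2, topo2, site, "CL")
        assert res.summed_pct == 100.0
        assert res.max_single_pct == 100.0

    def test_two_alternating_ions_sum_to_100(self):
        spec = synth.default_spec(p=1.0, n_frames=10, seed=0)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        site = self._site(topology)
        topo2, traj2 = synth.place_ions(
            topology, traj, site.reference_atom, "CL", [0.5, 0.5], seed=4
        )
        # force exact alternation for the brute-force check
        ion_a, ion_b = topo2.ion_indices
        ref_xyz = traj2.coords[:, site.reference_atom, :]
        near = ref_xyz + np.array([0.3, 0, 0])
        far = ref_xyz + np.array([1.5, 0, 0])
        even = np.arange(10) % 2 == 0
        traj2.coords[:, ion_a, :] = np.where(even[:, None], near, far)
        traj2.coords[:, ion_b, :] = np.where(even[:, None], far, near)
        res = ion_site_occupancy(traj2, topo2, site, "CL")
        assert sorted(v for _, v in res.per_ion) == [50.0, 50.0]
        assert res.summed_pct == 100.0
        assert res.max_single_pct == 50.0

    def test_absent_species_gives_zero(self):
        spec = synth.default_spec(p=1.0, n_frames=5, seed=0)
        topology, ref = synth.build_toy_trimer(spec)
        traj = synth.simulate_bridge_trajectory(topology, ref, spec)
        site = self._site(topology)
        res = ion_site_occupancy(traj, topology, site, "NA")
        assert res.per_ion == [] and res.summed_pct == 0.0
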