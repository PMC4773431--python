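"""Tracking: nearest-neighbour init, cost function, annealing, repair,
label propagation."""

import itertools
from collections import Counter

import numpy as np
import pytest

from embryotrack.model import Centre, CentreSet, LineageForest
from embryotrack.track import (
    AnnealConfig,
    anneal,
    forest_cost,
    init_nearest_neighbour,
    propagate_labels,
    repair,
    track,
)

from conftest import straight_track_forest


def two_frame_instance(seed, box=30.0, max_n=5):
    rng = np.random.default_rng(seed)
    n0, n1 = rng.integers(1, max_n + 1), rng.integers(1, max_n + 1)
    cs0 = CentreSet(0, [Centre(i, 0, tuple(rng.uniform(0, box, 3)))
                        for i in range(n0)])
    cs1 = CentreSet(1, [Centre(100 + i, 1, tuple(rng.uniform(0, box, 3)))
                        for i in range(n1)])
    return [cs0, cs1]


def brute_force_min_cost(centres_by_t, cfg):
    """Exhaustive enumeration over every valid mother assignment (oracle)."""
    base = init_nearest_neighbour(centres_by_t, cfg.d_max)
    ids0 = sorted(c.id for c in base.centres.values() if c.t == 0)
    ids1 = sorted(c.id for c in base.centres.values() if c.t == 1)
    best = np.inf
    for assign in itertools.product([None] + ids0, repeat=len(ids1)):
        counts = Counter(a for a in assign if a is not None)
        if any(v > 2 for v in counts.values()):
            continue
        f = base.copy()
        for d in ids1:
            f.unlink(d)
        for d, m in zip(ids1, assign):
            if m is not None:
                f.add_link(m, d)
        best = min(best, forest_cost(f, cfg).total)
    return best


class TestNearestNeighbourInit:
    def test_single_link(self):
        cs = [CentreSet(0, [Centre(0, 0, (0.0, 0.0, 0.0))]),
              CentreSet(1, [Centre(0, 1, (1.0, 0.0, 0.0))])]
        f = init_nearest_neighbour(cs, d_max=10.0)
        assert f.n_links == 1
        (m, d), = f.links
        assert f.centres[m].t == 0 and f.centres[d].t == 1

    def test_division_candidate_both_link(self):
        cs = [CentreSet(0, [Centre(0, 0, (0.0, 0.0, 0.0))]),
              CentreSet(1, [Centre(0, 1, (2.0, 0.0, 0.0)),
                            Centre(1, 1, (-2.0, 0.0, 0.0))])]
        f = init_nearest_neighbour(cs, d_max=10.0)
        assert f.out_degree(0) == 2

    def test_beyond_dmax_not_linked(self):
        cs = [CentreSet(0, [Centre(0, 0, (0.0, 0.0, 0.0))]),
              CentreSet(1, [Centre(0, 1, (50.0, 0.0, 0.0))])]
        f = init_nearest_neighbour(cs, d_max=10.0)
        assert f.n_links == 0

    def test_identity_permutation_recovered(self, rng):
        pos = rng.uniform(0, 100, (5, 3))
        sets = []
        for t in range(3):
            sets.append(CentreSet(t, [
                Centre(i, t, tuple(pos[i] + 0.01 * t)) for i in range(5)]))
        f = init_nearest_neighbour(sets, d_max=5.0)
        # each centre links straight down its own track
        for d, m in ((d, m) for (m, d) in f.links):
            assert f.centres[d].id % 5 == f.centres[m].id % 5

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            init_nearest_neighbour([CentreSet(0, [])], d_max=1.0)


class TestForestCost:
    def test_perfect_tracking_costs_zero(self):
        f = straight_track_forest(n_frames=5, step=(0.0, 0.0, 0.0))
        cb = forest_cost(f, AnnealConfig(d_max=10.0))
        assert cb.total == 0.0

    def test_motherless_centre_costs_its_weight(self):
        f = LineageForest([Centre(0, 0, (0, 0, 0)), Centre(1, 1, (1, 0, 0))])
        cb = forest_cost(f, AnnealConfig(d_max=10.0, allow_disappearance=True))
        assert cb.total == pytest.approx(cb.per_term["motherless"])
        assert cb.per_term["motherless"] == pytest.approx(10.0)

    def test_hand_computed_three_daughter_fixture(self):
        cfg = AnnealConfig(d_max=10.0)
        f = LineageForest([Centre(0, 0, (0.0, 0.0, 0.0))])
        for i, x in [(1, 2.0), (2, -2.0), (3, 4.0)]:
            f.add_centre(Centre(i, 1, (x, 0.0, 0.0)))
            f.add_link(0, i)
        cb = forest_cost(f, cfg)
        w = cfg.weights
        # hand computation: one excess daughter; three displacements;
        # daughters are leaves at t_max (no disappearance); out-degree 3 is
        # not a 2-daughter division so no sister/division terms
        expected = (w["excess_daughters"] * 1
                    + w["displacement"] * ((2 / 10) ** 2 + (2 / 10) ** 2 + (4 / 10) ** 2))
        assert cb.total == pytest.approx(expected)
        assert cb.per_term["excess_daughters"] == pytest.approx(w["excess_daughters"])

    def test_total_equals_sum_of_terms(self, rng):
        from conftest import random_forest

        f = random_forest(rng, n_roots=10, n_frames=6)
        cb = forest_cost(f, AnnealConfig(d_max=5.0))
        assert cb.total == pytest.approx(sum(cb.per_term.values()), abs=1e-9)

    def test_invariant_under_rigid_translation_and_relabelling(self, rng):
        from conftest import random_forest

        f = random_forest(rng, n_roots=8, n_frames=5)
        cfg = AnnealConfig(d_max=5.0)
        base = forest_cost(f, cfg).total

        shift = np.array([17.0, -4.0, 9.0])
        g = LineageForest()
        offset = 1000
        for c in f.centres.values():
            g.add_centre(Centre(c.id + offset, c.t, tuple(np.asarray(c.pos) + shift),
                                c.intensity, c.virtual))
        for m, d in f.links:
            g.add_link(m + offset, d + offset)
        assert forest_cost(g, cfg).total == pytest.approx(base, rel=1e-12)

    def test_disappearance_term_and_switch(self):
        f = LineageForest([Centre(0, 0, (0, 0, 0)), Centre(1, 1, (0, 0, 0)),
                           Centre(2, 0, (5, 5, 5))], links=[(0, 1)])
        cfg = AnnealConfig(d_max=10.0)
        cb = forest_cost(f, cfg)
        assert cb.per_term["disappearance"] == pytest.approx(10.0)
        cfg2 = AnnealConfig(d_max=10.0, allow_disappearance=True)
        assert forest_cost(f, cfg2).per_term["disappearance"] == 0.0


class TestAnneal:
    def test_optimal_forest_unchanged_at_zero_temperature(self):
        cs = [CentreSet(0, [Centre(0, 0, (0.0, 0.0, 0.0)),
                            Centre(1, 0, (20.0, 0.0, 0.0))]),
              CentreSet(1, [Centre(0, 1, (0.5, 0.0, 0.0)),
                            Centre(1, 1, (20.5, 0.0, 0.0))])]
        f = init_nearest_neighbour(cs, d_max=10.0)
        cfg = AnnealConfig(d_max=10.0, T0=1e-12, n_sweeps=50, seed=1)
        g = anneal(f, cfg)
        assert g.links == f.links

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimum(self, seed):
        inst = two_frame_instance(seed)
        cfg = AnnealConfig(d_max=10.0, n_sweeps=60)
        oracle = brute_force_min_cost(inst, cfg)
        init = init_nearest_neighbour(inst, cfg.d_max)
        best = min(
            forest_cost(
                anneal(init, AnnealConfig(d_max=10.0, n_sweeps=60, seed=s)), cfg
            ).total
            for s in range(20)
        )
        assert best == pytest.approx(oracle, abs=1e-9)

    def test_mitosis_recovered(self):
        cs = [CentreSet(0, [Centre(0, 0, (10.0, 10.0, 10.0)),
                            Centre(1, 0, (40.0, 40.0, 10.0))]),
              CentreSet(1, [Centre(0, 1, (8.0, 10.0, 10.0)),
                            Centre(1, 1, (12.0, 10.0, 10.0)),
                            Centre(2, 1, (41.0, 40.0, 10.0))])]
        cfg = AnnealConfig(d_max=10.0, n_sweeps=100, seed=3)
        f = anneal(init_nearest_neighbour(cs, cfg.d_max), cfg)
        assert f.divisions() == [0]
        assert f.daughters(0) == {2, 3}  # relabelled sequential ids

    def test_hard_constraints_satisfied(self, rng):
        sets = []
        for t in range(3):
            sets.append(CentreSet(t, [
                Centre(i, t, tuple(rng.uniform(0, 15, 3))) for i in range(8)]))
        cfg = AnnealConfig(d_max=20.0, n_sweeps=30, seed=5)
        f = anneal(init_nearest_neighbour(sets, cfg.d_max), cfg)
        f.validate()  # raises on any violation

    def test_deterministic_given_seed(self):
        inst = two_frame_instance(42)
        cfg = AnnealConfig(d_max=10.0, n_sweeps=40, seed=9)
        init = init_nearest_neighbour(inst, cfg.d_max)
        assert anneal(init, cfg) == anneal(init, cfg)


class TestRepair:
    def test_spurious_short_branch_deleted(self):
        f = straight_track_forest(n_frames=8)
        spurious_id = 100
        f.add_centre(Centre(spurious_id, 3, (80.0, 80.0, 80.0)))
        cfg = AnnealConfig(d_max=5.0, L_min=3, seed=0)
        before = forest_cost(f, cfg).total
        g = repair(f, cfg)
        assert spurious_id not in g.centres
        assert forest_cost(g, cfg).total < before

    def test_one_frame_gap_bridged_at_midpoint(self):
        f = LineageForest()
        for t in range(10):
            if t == 5:
                continue
            f.add_centre(Centre(t, t, (float(t), 0.0, 0.0)))
        for t in range(1, 10):
            if t in (5, 6):
                continue
            f.add_link(t - 1, t)
        cfg = AnnealConfig(d_max=5.0, seed=0)
        g = repair(f, cfg)
        virtuals = [c for c in g.centres.values() if c.virtual]
        assert len(virtuals) == 1
        v = virtuals[0]
        assert v.t == 5
        assert v.pos == pytest.approx((5.0, 0.0, 0.0))
        assert g.mother(v.id) == 4 and g.daughters(v.id) == {6}

    def test_coherent_forest_unchanged(self):
        f = straight_track_forest(n_frames=8)
        cfg = AnnealConfig(d_max=5.0, seed=0)
        g = repair(f, cfg)
        assert g == f


class TestPropagateLabels:
    def _two_generation_forest(self):
        f = LineageForest([Centre(0, 0, (0, 0, 0))])
        nid = 1
        for m in [0]:
            for _ in range(2):
                f.add_centre(Centre(nid, 1, (nid, 0, 0)))
                f.add_link(0, nid)
                nid += 1
        for m in [1, 2]:
            for _ in range(2):
                f.add_centre(Centre(nid, 2, (nid, 0, 0)))
                f.add_link(m, nid)
                nid += 1
        return f

    def test_clone_inherits_root_label(self):
        f = self._two_generation_forest()
        labels = propagate_labels(f, {0: "epiblast"})
        assert labels == {i: "epiblast" for i in range(7)}

    def test_distinct_roots_stay_distinct(self):
        f = LineageForest([Centre(0, 0, (0, 0, 0)), Centre(1, 0, (9, 0, 0)),
                           Centre(2, 1, (0, 0, 1)), Centre(3, 1, (9, 0, 1))],
                          links=[(0, 2), (1, 3)])
        labels = propagate_labels(f, {0: "A", 1: "B"})
        assert labels[2] == "A" and labels[3] == "B"

    def test_unknown_id_is_error(self):
        f = straight_track_forest(3)
        with pytest.raises(KeyError):
            propagate_labels(f, {999: "x"})

    def test_synthetic_clone_partition_recovered(self):
        from embryotrack.synthetic import SyntheticConfig, simulate_ground_truth

        cfg = SyntheticConfig(n_cells_initial=3, n_frames=12,
                              box_size=(60.0, 60.0, 40.0), min_separation=6.0,
                              division_prob_per_frame=0.15,
                              division_refractory=2, seed=4)
        gold = simulate_ground_truth(cfg)
        f = gold.forest
        roots = f.roots()
        labels = propagate_labels(f, {r: f"clone{r}" for r in roots})
        # every centre is labelled with its true ancestral root
        for cid in f.centres:
            anc = cid
            while f.mother(anc) is not None:
                anc = f.mother(anc)
            assert labels[cid] == f"clone{anc}"


class TestFullTrack:
    def test_three_stage_pipeline_on_clean_tracks(self, rng):
        sets = []
        base = rng.uniform(10, 40, (6, 3))
        for t in range(5):
            sets.append(CentreSet(t, [
                Centre(i, t, tuple(base[i] + rng.normal(0, 0.2, 3) + [t, 0, 0]))
                for i in range(6)]))
        cfg = AnnealConfig(d_max=6.0, n_sweeps=30, seed=2)
        f = track(sets, cfg)
        f.validate()
        assert len(f.centres) == 30
        # every non-initial centre has a mother: no track breaks
        for c in f.centres.values():
            if c.t > 0:
                assert f.mother(c.id) is not None
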