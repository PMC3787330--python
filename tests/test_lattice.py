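import math

import numpy as np
import pytest

from thymostate.errors import SimulationError
from thymostate.lattice import (
    REGION_CORTEX,
    REGION_EXIT,
    REGION_MEDULLA,
    REGION_SUBCAPSULAR,
    InteractionLog,
    SelectionThresholds,
    Thymocyte,
    ThymusConfig,
    build_thymus_lattice,
    egress_check,
    lineage_decision,
    move_agent,
    run_thymus_abm,
    selection_decision,
    stage_chemokine,
    update_binding,
)


class TestBuildLattice:
    def test_seed_determinism(self):
        a = build_thymus_lattice(30, 30, 0.2, seed=4)
        b = build_thymus_lattice(30, 30, 0.2, seed=4)
        np.testing.assert_array_equal(a.epithelium, b.epithelium)
        np.testing.assert_array_equal(a.region, b.region)

    def test_exact_epithelial_count(self):
        lat = build_thymus_lattice(50, 50, 0.2, seed=0)
        assert lat.epithelium.sum() == 500

    def test_region_partition_and_exit_on_medulla_boundary(self):
        lat = build_thymus_lattice(24, 24, 0.1, seed=1)
        assert set(np.unique(lat.region)) <= {REGION_SUBCAPSULAR, REGION_CORTEX,
                                              REGION_MEDULLA, REGION_EXIT}
        exit_rows = np.unique(np.nonzero(lat.region == REGION_EXIT)[0])
        assert list(exit_rows) == [lat.height - 1]
        # exit row borders the medulla band
        assert np.all(lat.region[lat.height - 2, :] == REGION_MEDULLA)

    def test_fraction_out_of_range(self):
        with pytest.raises(SimulationError):
            build_thymus_lattice(20, 20, 0.7, seed=0)

    def test_chemokine_fields_peak_in_attractor(self):
        lat = build_thymus_lattice(20, 20, 0.1, seed=0)
        for field in lat.fields.values():
            assert np.all(field.concentrations >= 0)
            inside = field.concentrations[field.attractor]
            outside = field.concentrations[~field.attractor]
            assert inside.min() >= outside.max()


class TestStageChemokine:
    @pytest.mark.parametrize("stage,expected", [
        ("DN", "CXCL12"), ("DP", "CXCL12"),
        ("SP4", "CCL19_21"), ("SP8", "CCL19_21"),
    ])
    def test_mapping(self, stage, expected):
        assert stage_chemokine(stage) == expected

    def test_mature_sp_uses_s1p(self):
        assert stage_chemokine("SP4", mature=True) == "S1P"
        assert stage_chemokine("SP8", mature=True) == "S1P"

    def test_unknown_stage(self):
        with pytest.raises(SimulationError):
            stage_chemokine("XX")


class TestMoveAgent:
    def _world(self):
        lat = build_thymus_lattice(20, 20, 0.1, seed=2)
        lat.epithelium[:] = False
        return lat

    def test_greedy_deterministic_toward_gradient(self):
        lat = self._world()
        agent = Thymocyte(0, stage="DN", position=(0, 10))
        lat.occupant[0, 10] = 0
        rng = np.random.default_rng(0)
        new = move_agent(agent, lat, noise=0.0, rng=rng)
        assert new == (1, 10) or lat.fields["CXCL12"].concentrations[new] > \
            lat.fields["CXCL12"].concentrations[(0, 10)]

    def test_all_neighbors_occupied_stays(self):
        lat = self._world()
        agent = Thymocyte(0, stage="DN", position=(5, 5))
        lat.occupant[4:7, 4:7] = 99
        lat.occupant[5, 5] = 0
        new = move_agent(agent, lat, noise=0.0, rng=np.random.default_rng(0))
        assert new == (5, 5)

    def test_bound_agent_rejected(self):
        lat = self._world()
        agent = Thymocyte(0, stage="DN", position=(5, 5), bound_to=(5, 6))
        with pytest.raises(SimulationError, match="bound"):
            move_agent(agent, lat, 0.0, np.random.default_rng(0))

    def test_noise_one_uniform_over_vacant(self):
        lat = self._world()
        start = (10, 10)
        counts: dict = {}
        rng = np.random.default_rng(8)
        n = 10_000
        for _ in range(n):
            agent = Thymocyte(0, stage="DN", position=start)
            lat.occupant[:] = -1
            lat.occupant[start] = 0
            new = move_agent(agent, lat, noise=1.0, rng=rng)
            counts[new] = counts.get(new, 0) + 1
        assert len(counts) == 8
        p = 1 / 8
        se = math.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3.5 * se

    def test_stays_when_no_strictly_higher_neighbor(self):
        lat = self._world()
        # center of the cortex band: concentration already maximal
        row = int(np.mean(np.nonzero(np.any(lat.region == REGION_CORTEX, axis=1))[0]))
        agent = Thymocyte(0, stage="DN", position=(row, 10))
        lat.occupant[row, 10] = 0
        new = move_agent(agent, lat, noise=0.0, rng=np.random.default_rng(0))
        assert new == (row, 10)

    def test_chemotaxis_converges_within_width_plus_height(self):
        lat = self._world()
        for stage, region_code, mature in (("DN", REGION_CORTEX, False),
                                           ("SP4", REGION_MEDULLA, False),
                                           ("SP4", REGION_EXIT, True)):
            lat.occupant[:] = -1
            agent = Thymocyte(0, stage=stage, position=(0, 0), mature=mature)
            lat.occupant[0, 0] = 0
            rng = np.random.default_rng(1)
            for _ in range(lat.width + lat.height):
                if lat.region[agent.position] == region_code:
                    break
                move_agent(agent, lat, noise=0.0, rng=rng)
            else:
                if region_code == REGION_MEDULLA:
                    ok = lat.region[agent.position] in (REGION_MEDULLA, REGION_EXIT)
                else:
                    ok = lat.region[agent.position] == region_code
                assert ok, f"{stage} did not reach its attractor"


class TestBinding:
    def _lattice_with_epi(self, epi_sites):
        lat = build_thymus_lattice(12, 12, 0.1, seed=0)
        lat.epithelium[:] = False
        for s in epi_sites:
            lat.epithelium[s] = True
        return lat

    def test_no_adjacent_epithelium_stays_unbound(self):
        lat = self._lattice_with_epi([])
        agent = Thymocyte(0, position=(5, 5))
        bound = update_binding(agent, lat, 0.1, np.random.default_rng(0), 5.0, 1.0)
        assert not bound and agent.log.count == 0

    def test_koff_zero_accrues_exactly(self):
        lat = self._lattice_with_epi([(5, 6)])
        agent = Thymocyte(0, position=(5, 5))
        rng = np.random.default_rng(0)
        update_binding(agent, lat, 0.1, rng, k_on=1e9, k_off=0.0)  # binds now
        assert agent.bound
        for _ in range(7):
            update_binding(agent, lat, 0.1, rng, k_on=1e9, k_off=0.0)
        assert agent.log.total_bound_time == pytest.approx(0.7)
        assert agent.log.count == 1

    def test_longest_not_greater_than_total(self):
        lat = self._lattice_with_epi([(5, 6), (6, 5)])
        agent = Thymocyte(0, position=(5, 5))
        rng = np.random.default_rng(3)
        for _ in range(200):
            update_binding(agent, lat, 0.1, rng, k_on=3.0, k_off=2.0)
        assert agent.log.longest <= agent.log.total_bound_time + 1e-12
        assert agent.log.count >= 1

    def test_distinct_partner_count_matches_independent_oracle(self):
        """Mean #distinct partners vs a straightforward re-simulation."""
        k_on, k_off, dt, steps, n_epi = 4.0, 1.5, 0.1, 60, 3
        epi = [(5, 6), (6, 5), (6, 6)]
        reps = 400

        def package_run(seed):
            lat = self._lattice_with_epi(epi)
            agent = Thymocyte(0, position=(5, 5))
            rng = np.random.default_rng(seed)
            for _ in range(steps):
                update_binding(agent, lat, dt, rng, k_on, k_off)
            return len(agent.log.partners)

        def oracle_run(seed):
            # independent two-state bind/unbind chain
            rng = np.random.default_rng(seed)
            bound = None
            partners = set()
            p_on = 1 - math.exp(-k_on * dt)
            p_off = 1 - math.exp(-k_off * dt)
            for _ in range(steps):
                if bound is None:
                    if rng.random() < p_on:
                        bound = int(rng.integers(n_epi))
                        partners.add(bound)
                else:
                    if rng.random() < p_off:
                        bound = None
            return len(partners)

        got = np.array([package_run(1000 + r) for r in range(reps)])
        exp = np.array([oracle_run(5000 + r) for r in range(reps)])
        se = math.sqrt(got.var(ddof=1) / reps + exp.var(ddof=1) / reps)
        assert abs(got.mean() - exp.mean()) < 3 * se


class TestSelectionDecision:
    TH = SelectionThresholds()

    def _log(self, bound=0.0, count=0, clock=0.0, longest=0.0):
        log = InteractionLog(total_bound_time=bound, count=count,
                             stage_clock=clock, longest=longest)
        return log

    def test_positive_when_threshold_crossed(self):
        log = self._log(bound=3.0, count=5, clock=10.0)
        assert selection_decision(log, self.TH, "DP") == "positive"

    def test_neglect_when_clock_expires(self):
        log = self._log(bound=1.0, count=2, clock=31.0)
        assert selection_decision(log, self.TH, "DP") == "death_by_neglect"

    def test_negative_overrides_positive(self):
        log = self._log(bound=12.5, count=9, clock=5.0)
        assert selection_decision(log, self.TH, "DP") == "negative"

    def test_none_while_developing(self):
        log = self._log(bound=1.0, count=2, clock=5.0)
        assert selection_decision(log, self.TH, "DP") == "none"

    def test_sp_uses_own_thresholds(self):
        log = self._log(bound=1.0, count=3, clock=1.0)
        assert selection_decision(log, self.TH, "SP4") == "positive"
        assert selection_decision(log, self.TH, "DP") == "none"

    def test_unknown_stage(self):
        with pytest.raises(SimulationError):
            selection_decision(self._log(), self.TH, "weird")


class TestLineageDecision:
    def test_long_duration_cd4(self):
        log = InteractionLog(count=3, longest=4.0)
        assert lineage_decision(log, 2.0) == "CD4"

    def test_short_duration_cd8(self):
        log = InteractionLog(count=3, longest=1.0)
        assert lineage_decision(log, 2.0) == "CD8"

    def test_boundary_goes_cd4(self):
        log = InteractionLog(count=1, longest=2.0)
        assert lineage_decision(log, 2.0) == "CD4"

    def test_empty_log_rejected(self):
        with pytest.raises(SimulationError):
            lineage_decision(InteractionLog(), 2.0)


class TestEgress:
    def _lattice(self):
        return build_thymus_lattice(12, 12, 0.1, seed=0)

    def test_mature_sp4_on_exit_exports_cd4(self):
        lat = self._lattice()
        site = (lat.height - 1, 4)
        agent = Thymocyte(0, stage="SP4", position=site, mature=True)
        lat.occupant[site] = 0
        log: list = []
        assert egress_check(agent, lat, log, t=1.0)
        assert lat.occupant[site] == -1
        assert log == [(1.0, 0, "export", "CD4")]

    def test_mature_sp_not_on_exit_persists(self):
        lat = self._lattice()
        agent = Thymocyte(0, stage="SP8", position=(3, 3), mature=True)
        assert not egress_check(agent, lat)

    def test_immature_or_dp_never_egress(self):
        lat = self._lattice()
        site = (lat.height - 1, 4)
        assert not egress_check(Thymocyte(0, stage="DP", position=site), lat)
        assert not egress_check(
            Thymocyte(0, stage="SP4", position=site, mature=False), lat)


class TestWholeSimulation:
    def test_seed_determinism(self):
        cfg = ThymusConfig(width=20, height=20)
        a = run_thymus_abm(cfg, t_end=10.0, seed=11)
        b = run_thymus_abm(cfg, t_end=10.0, seed=11)
        assert a.fates == b.fates
        assert a.log == b.log
        for k in a.stage_counts:
            np.testing.assert_array_equal(a.stage_counts[k], b.stage_counts[k])

    def test_occupancy_exclusive_and_consistent(self):
        cfg = ThymusConfig(width=20, height=20, influx_per_step=2)
        from thymostate.lattice import ThymusWorld

        world = ThymusWorld(cfg, seed=13)
        for _ in range(150):
            world.step()
        occ = world.lattice.occupant
        ids = occ[occ >= 0]
        assert len(ids) == len(set(ids.tolist()))  # one thymocyte per site
        assert set(ids.tolist()) == set(world.agents.keys())
        for a in world.agents.values():
            assert occ[a.position] == a.id

    def test_agent_total_balance(self):
        cfg = ThymusConfig(width=20, height=20)
        res = run_thymus_abm(cfg, t_end=40.0, seed=2)
        removed = (res.fates["exported_CD4"] + res.fates["exported_CD8"]
                   + res.fates["death_by_neglect"] + res.fates["negative"])
        alive = sum(int(v[-1]) for v in res.stage_counts.values())
        assert res.fates["influx"] == alive + removed

    def test_dp_fates_mutually_exclusive(self):
        cfg = ThymusConfig(width=24, height=24)
        res = run_thymus_abm(cfg, t_end=60.0, seed=8)
        per_agent: dict = {}
        for (_, aid, event, detail) in res.log:
            if event == "positive" or (event in ("negative", "death_by_neglect")
                                       and detail == "DP"):
                per_agent.setdefault(aid, []).append(event)
        assert per_agent, "no DP resolved a fate in this run"
        for aid, events in per_agent.items():
            assert len(events) == 1, f"agent {aid} has several DP fates: {events}"

    def test_raising_t_neg_weakly_reduces_negative_selection(self):
        neg = {}
        for t_neg in (3.0, 50.0):
            total = 0
            for seed in (1, 2, 3):
                cfg = ThymusConfig(width=20, height=20)
                cfg.thresholds.t_neg = t_neg
                res = run_thymus_abm(cfg, t_end=40.0, seed=seed)
                total += res.fates["negative"]
            neg[t_neg] = total
        assert neg[50.0] <= neg[3.0]

    def test_config_from_document(self, models_dir):
        import yaml

        data = yaml.safe_load((models_dir / "thymus_lattice.yaml").read_text())
        cfg = ThymusConfig.from_document(data)
        assert cfg.width == 40 and cfg.height == 40
        assert cfg.thresholds.theta_pos == {"DP": 5, "SP": 3}
        assert cfg.thresholds.tau_lineage == 2.0
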