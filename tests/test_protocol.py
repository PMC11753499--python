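"""Protocol stages: compression, conformer selection, crosslinking, control."""

import numpy as np
import pytest

from flexgel.params import SimulationParameters
from flexgel.protocol import (
    ProtocolPlan,
    assign_crosslinks,
    compress_to_volume,
    flexible_stage,
    run_full_protocol,
    select_conformations,
    self_assembly_stage,
    stiff_stage,
)
from flexgel.synthetic import generate_initial_chains, preset

from conftest import make_random_config


@pytest.fixture(scope="module")
def ci_setup():
    spec, plan, params = preset("ci", seed=7)
    return spec, plan, params


@pytest.fixture(scope="module")
def compressed(ci_setup):
    spec, plan, params = ci_setup
    cfg = generate_initial_chains(spec, params)
    for edge, steps in plan.compression_targets:
        res = compress_to_volume(cfg, edge, steps, params, seed=11,
                                 record_every=plan.record_every)
        cfg = res.final_config
    return cfg


class TestProtocolPlan:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ProtocolPlan(2, 5, 10.0, [(12.0, 100)], 100, 1, [0.1], 100, 1)
        with pytest.raises(ValueError):
            ProtocolPlan(2, 5, 10.0, [(5.0, 100)], 100, 1, [1.5], 100, 1)
        with pytest.raises(ValueError):
            ProtocolPlan(2, 5, 10.0, [(5.0, 100)], 100, 1, [0.1], 100, 0)

    def test_round_trip(self):
        plan = preset("ci")[1]
        assert ProtocolPlan.from_dict(plan.to_dict()) == plan


class TestCompression:
    def test_reaches_target_exactly(self, ci_setup, compressed):
        _, plan, _ = ci_setup
        assert compressed.box_edge == plan.compression_targets[-1][0]

    def test_volume_monotone_nonincreasing(self, ci_setup):
        spec, plan, params = ci_setup
        cfg = generate_initial_chains(spec, params)
        res = compress_to_volume(cfg, plan.compression_targets[0][0],
                                 plan.compression_targets[0][1], params,
                                 seed=3, record_every=10)
        assert np.all(np.diff(res.trace.volume) <= 1e-9)

    def test_target_above_current_rejected(self, ci_setup):
        spec, plan, params = ci_setup
        cfg = generate_initial_chains(spec, params)
        with pytest.raises(ValueError):
            compress_to_volume(cfg, cfg.box_edge * 2, 100, params)


class TestSelfAssembly:
    def test_trace_bookkeeping(self, compressed, ci_setup):
        _, plan, params = ci_setup
        res = self_assembly_stage(compressed, 500, params, seed=5,
                                  record_every=50, snapshot_every=100)
        assert len(res.trace) == 500 // 50 + 1
        assert len(res.snapshots) == 5

    def test_zero_pressure_target_swells(self, compressed, ci_setup):
        # with p_target = 0 a purely repulsive system can only expand
        _, plan, params = ci_setup
        p0 = params.with_(p_target=0.0)
        res = self_assembly_stage(compressed, 2000, p0, seed=6, record_every=100)
        assert res.trace.volume[-1] > res.trace.volume[0]


class TestSelectConformations:
    def _snapshots(self, volumes):
        snaps = []
        for v in volumes:
            c = make_random_config(n_chains=1, dp=3, box_edge=10.0, seed=1,
                                   min_sep=0.1)
            c.box_edge = float(v) ** (1.0 / 3.0)
            c.positions = c.positions * (c.box_edge / 10.0)
            snaps.append(c)
        return snaps

    def test_k1_returns_final(self):
        snaps = self._snapshots([5.0, 3.0, 4.0])
        picked = select_conformations(snaps, 1)
        assert len(picked) == 1
        assert picked[0][0] == "a"
        assert picked[0][1].box_edge == pytest.approx(4.0 ** (1 / 3))

    def test_monotone_trace_gives_decreasing_volumes(self):
        snaps = self._snapshots(np.linspace(10.0, 2.0, 25))
        picked = select_conformations(snaps, 4)
        labels = [l for l, _ in picked]
        vols = [c.box_edge**3 for _, c in picked]
        assert labels == ["a", "b", "c", "d"]
        assert all(a > b for a, b in zip(vols, vols[1:]))
        # final snapshot occupies the last slot
        assert vols[-1] == pytest.approx(2.0)

    def test_evenly_spaced_quantiles(self):
        volumes = np.linspace(20.0, 4.0, 33)
        snaps = self._snapshots(volumes)
        picked = select_conformations(snaps, 4)
        vols = np.array([c.box_edge**3 for _, c in picked])
        targets = np.array([20.0, 20 - 16 / 3, 20 - 32 / 3, 4.0])
        stride = volumes[0] - volumes[1]
        assert np.all(np.abs(vols - targets) <= stride + 1e-9)

    def test_too_few_snapshots(self):
        with pytest.raises(ValueError):
            select_conformations(self._snapshots([1.0, 2.0]), 4)


class TestAssignCrosslinks:
    def test_zero_probability(self, compressed, ci_setup):
        _, _, params = ci_setup
        out, rep = assign_crosslinks(compressed, 0.0, params=params)
        assert rep.realized_links == 0
        assert out.crosslinks.shape == (0, 2)

    def test_unit_probability_links_all_eligible(self, compressed, ci_setup):
        _, _, params = ci_setup
        out, rep = assign_crosslinks(compressed, 1.0, params=params)
        assert rep.realized_links == rep.eligible_pairs
        # every link joins different chains at distance < 2r
        for i, j in out.crosslinks:
            assert out.chain_of[i] != out.chain_of[j]
            disp = out.positions[i] - out.positions[j]
            disp -= out.box_edge * np.rint(disp / out.box_edge)
            assert np.linalg.norm(disp) < params.bond_length

    def test_eligible_matches_brute_force(self, compressed, ci_setup):
        _, _, params = ci_setup
        _, rep = assign_crosslinks(compressed, 1.0, params=params)
        pos = compressed.positions
        box = compressed.box_edge
        n = compressed.n_beads
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if compressed.chain_of[i] == compressed.chain_of[j]:
                    continue
                disp = pos[i] - pos[j]
                disp -= box * np.rint(disp / box)
                if np.linalg.norm(disp) < params.bond_length:
                    count += 1
        assert rep.eligible_pairs == count

    def test_binomial_counts(self, ci_setup):
        # a dense artificial contact cloud gives a decent eligible count
        _, _, params = ci_setup
        from flexgel.config import PolymerConfiguration, chain_topology

        rng = np.random.default_rng(13)
        side = 6
        box = side * 1.0  # lattice constant ~ the contact distance
        grid = (np.indices((side,) * 3).reshape(3, -1).T + 0.5) * (box / side)
        pos = np.mod(grid + rng.uniform(-0.15, 0.15, grid.shape), box)
        n = len(pos)
        chain_of, bonds, angles = chain_topology([3] * (n // 3))
        cfg = PolymerConfiguration(
            positions=pos, velocities=np.zeros((n, 3)),
            chain_of=chain_of, bonds=bonds, angles=angles, box_edge=box,
        )
        _, rep_all = assign_crosslinks(cfg, 1.0, params=params)
        e = rep_all.eligible_pairs
        assert e > 20
        pcl = 0.25
        counts = []
        for seed in range(30):
            _, rep = assign_crosslinks(
                cfg, pcl, np.random.default_rng(seed), params
            )
            counts.append(rep.realized_links)
        mean = np.mean(counts)
        sd_of_mean = np.sqrt(e * pcl * (1 - pcl) / len(counts))
        assert abs(mean - pcl * e) < 4 * sd_of_mean


class TestStiffFlexibleStages:
    def test_crosslinks_immutable_through_stages(self, compressed, ci_setup):
        _, plan, params = ci_setup
        linked, _ = assign_crosslinks(compressed, 1.0, params=params)
        st = stiff_stage(linked, 300, params, seed=2, record_every=100)
        fl = flexible_stage(st.final_config, 300, params, seed=3, record_every=100)
        assert np.array_equal(st.final_config.crosslinks, linked.crosslinks)
        assert np.array_equal(fl.final_config.crosslinks, linked.crosslinks)
        assert np.array_equal(fl.final_config.bonds, linked.bonds)

    def test_zero_bending_stiff_equals_flexible(self, compressed, ci_setup):
        _, _, params = ci_setup
        p0 = params.with_(K_theta=0.0)
        st = stiff_stage(compressed, 200, p0, seed=9, record_every=100)
        fl = flexible_stage(compressed, 200, p0, seed=9, record_every=100)
        assert np.array_equal(st.final_config.positions,
                              fl.final_config.positions)

    def test_angular_energy_zero_throughout_flexible_stage(
        self, compressed, ci_setup
    ):
        _, _, params = ci_setup
        fl = flexible_stage(compressed, 300, params, seed=4, record_every=50)
        assert np.all(fl.e_angle == 0.0)

    def test_stiff_stage_has_angular_energy(self, compressed, ci_setup):
        _, _, params = ci_setup
        st = stiff_stage(compressed, 300, params, seed=4, record_every=50)
        assert st.e_angle[-1] > 0.0


@pytest.fixture(scope="module")
def ci_result():
    _, plan, params = preset("ci", seed=5)
    return run_full_protocol(plan, params), plan


class TestRunFullProtocol:

    def test_phase_map_entry_count(self, ci_result):
        res, plan = ci_result
        # pcl > 0 cells: n_conformations per pcl; control adds one more
        expected = plan.n_conformations * 1 + 1  # pcl_values = [0, 0.25]
        assert len(res.entries) == expected

    def test_cells_table_complete(self, ci_result):
        res, plan = ci_result
        per_replica = plan.n_conformations * 1 + 1
        assert len(res.cells) == per_replica * plan.n_replicas

    def test_determinism(self):
        _, plan, params = preset("ci", seed=6)
        a = run_full_protocol(plan, params)
        b = run_full_protocol(plan, params)
        for ea, eb in zip(a.entries, b.entries):
            assert ea.sv == eb.sv
            assert ea.v_stiff_norm == eb.v_stiff_norm

    def test_control_uses_assembly_tail(self, ci_result):
        res, plan = ci_result
        label = "ab"[plan.n_conformations - 1] if plan.n_conformations <= 2 else "d"
        stiffs = res.stiff_traces[(label, 0.0)]
        # the control stiff trace spans exactly the trailing stage_steps
        for tr in stiffs:
            assert tr.steps.max() - tr.steps.min() <= plan.stage_steps

    def test_checkpoint_resume(self, tmp_path):
        _, plan, params = preset("ci", seed=8)
        first = run_full_protocol(plan, params, checkpoint_dir=str(tmp_path))
        second = run_full_protocol(plan, params, checkpoint_dir=str(tmp_path))
        for ea, eb in zip(first.entries, second.entries):
            assert eb.sv == pytest.approx(ea.sv, rel=1e-12)
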