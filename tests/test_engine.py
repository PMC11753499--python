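"""Langevin/Berendsen engine: determinism, neighbor lists, physics oracles."""

import numpy as np
import pytest

from flexgel import _kernels
from flexgel.config import PolymerConfiguration
from flexgel.engine import (
    StageOptions,
    berendsen_rescale,
    langevin_step,
    neighbor_pairs,
    run_stage,
)
from flexgel.errors import GeometryError
from flexgel.params import SimulationParameters
from flexgel.potentials import _exclusion_keys, compute_forces, repulsion_shift

from conftest import make_random_config


def free_bead(box=100.0):
    return PolymerConfiguration(
        positions=np.array([[box / 2, box / 2, box / 2]]),
        velocities=np.zeros((1, 3)),
        chain_of=np.array([0]),
        bonds=np.empty((0, 2), dtype=np.int64),
        angles=np.empty((0, 3), dtype=np.int64),
        box_edge=box,
    )


def unwrapped_trajectory(snapshots, box):
    pos = np.array([s.positions[0] for s in snapshots])
    d = np.diff(pos, axis=0)
    d -= box * np.rint(d / box)
    return np.cumsum(d, axis=0)


class TestStageOptions:
    def test_invariants(self):
        with pytest.raises(ValueError):
            StageOptions(n_steps=0)
        with pytest.raises(ValueError):
            StageOptions(n_steps=10, record_every=0)
        with pytest.raises(ValueError):
            StageOptions(n_steps=10, barostat_on=True, box_schedule=(5.0, 10))


class TestRunStageBookkeeping:
    def test_single_step_trace(self, params):
        res = run_stage(free_bead(), StageOptions(n_steps=1, record_every=1), params)
        assert len(res.trace) == 2  # step 0 and step 1
        assert res.trace.steps.tolist() == [0, 1]

    def test_trace_length(self, params):
        res = run_stage(
            free_bead(), StageOptions(n_steps=1000, record_every=100), params
        )
        assert len(res.trace) == 11

    def test_determinism(self, params):
        cfg = make_random_config(seed=8)
        opts = StageOptions(n_steps=500, record_every=100, seed=123)
        a = run_stage(cfg, opts, params)
        b = run_stage(cfg, opts, params)
        assert np.array_equal(a.final_config.positions, b.final_config.positions)
        assert np.array_equal(a.final_config.velocities, b.final_config.velocities)

    def test_different_seeds_differ(self, params):
        cfg = make_random_config(seed=8)
        a = run_stage(cfg, StageOptions(n_steps=200, record_every=100, seed=1), params)
        b = run_stage(cfg, StageOptions(n_steps=200, record_every=100, seed=2), params)
        assert not np.array_equal(
            a.final_config.positions, b.final_config.positions
        )

    def test_nvt_box_constant(self, params):
        cfg = make_random_config(seed=9)
        res = run_stage(cfg, StageOptions(n_steps=300, record_every=50), params)
        assert np.all(res.trace.volume == cfg.box_edge**3)

    def test_input_not_modified(self, params):
        cfg = make_random_config(seed=10)
        before = cfg.positions.copy()
        run_stage(cfg, StageOptions(n_steps=100, record_every=100, seed=5), params)
        assert np.array_equal(cfg.positions, before)

    def test_box_too_small_raises(self, params):
        cfg = make_random_config(seed=11, box_edge=5.0, min_sep=0.7)
        with pytest.raises(GeometryError):
            run_stage(cfg, StageOptions(n_steps=10), params)

    def test_langevin_step_advances(self, params):
        cfg = make_random_config(seed=12)
        out = langevin_step(cfg, params, seed=3)
        assert not np.array_equal(out.positions, cfg.positions)


class TestNeighborPairs:
    def test_distant_beads_empty(self, params):
        cfg = PolymerConfiguration(
            positions=np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 9.0]]),
            velocities=np.zeros((2, 3)),
            chain_of=np.array([0, 1]),
            bonds=np.empty((0, 2), dtype=np.int64),
            angles=np.empty((0, 3), dtype=np.int64),
            box_edge=20.0,
        )
        assert len(neighbor_pairs(cfg, 2.5, 0.4)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed, params):
        rng = np.random.default_rng(seed)
        n = 50
        box = 7.0
        pos = rng.uniform(0, box, (n, 3))
        cfg = PolymerConfiguration(
            positions=pos, velocities=np.zeros((n, 3)),
            chain_of=np.arange(n),
            bonds=np.empty((0, 2), dtype=np.int64),
            angles=np.empty((0, 3), dtype=np.int64),
            box_edge=box,
        )
        cutoff, skin = 2.0, 0.3
        got = {tuple(p) for p in neighbor_pairs(cfg, cutoff, skin).tolist()}
        # brute force within cutoff must be a subset; list within cutoff+skin
        disp = pos[:, None] - pos[None, :]
        disp -= box * np.rint(disp / box)
        d = np.sqrt((disp**2).sum(-1))
        within_cut = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] < cutoff
        }
        within_list = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] < cutoff + skin
        }
        assert within_cut <= got <= within_list

    def test_bonded_pair_excluded(self, params):
        cfg = make_random_config(seed=4)
        pairs = {tuple(p) for p in neighbor_pairs(cfg, 2.5, 0.4).tolist()}
        for i, j in cfg.bonds:
            assert (min(i, j), max(i, j)) not in pairs

    def test_box_too_small_raises(self, params):
        cfg = make_random_config(seed=5, box_edge=8.0)
        with pytest.raises(GeometryError):
            neighbor_pairs(cfg, 3.0, 1.5)


class TestKernelAgainstReference:
    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("flexible", [False, True])
    def test_forces_energy_virial(self, seed, flexible):
        p = SimulationParameters(K_theta=80.0)
        cfg = make_random_config(seed=seed, flexible=flexible)
        cfg.crosslinks = np.array([[2, 11], [5, 16]])
        ref = compute_forces(cfg, p)
        n = cfg.n_beads
        cap = 4096
        pi = np.zeros(cap, np.int32)
        pj = np.zeros(cap, np.int32)
        rlist = p.d_cutoff + p.skin
        cnt = _kernels.build_pairs(
            cfg.positions, cfg.box_edge, rlist**2, _exclusion_keys(cfg), pi, pj
        )
        bonded = np.vstack([cfg.bonds, cfg.crosslinks])
        F = np.zeros((n, 3))
        st, epot, eang, vir = _kernels.compute_forces_kernel(
            cfg.positions, cfg.box_edge, pi, pj, cnt, bonded, cfg.angles,
            p.K_bond, p.bond_length, p.K_theta, -1.0, flexible,
            p.epsilon, p.sigma**2, p.d_cutoff**2, repulsion_shift(p), F,
        )
        assert st == 0
        assert epot == pytest.approx(ref.energy, rel=1e-10)
        assert vir == pytest.approx(ref.virial, rel=1e-10)
        assert np.allclose(F, ref.forces, rtol=1e-9, atol=1e-9)
        assert eang == pytest.approx(ref.e_angle, rel=1e-10, abs=1e-12)


class TestBerendsenRescale:
    def test_at_target_unchanged(self, params):
        cfg = make_random_config(seed=6)
        out, mu = berendsen_rescale(cfg, params.p_target, params)
        assert mu == 1.0
        assert np.array_equal(out.positions, cfg.positions)

    def test_overpressure_expands(self, params):
        cfg = make_random_config(seed=6)
        out, mu = berendsen_rescale(cfg, params.p_target + 1.0, params)
        assert mu > 1.0
        assert out.box_edge > cfg.box_edge

    def test_underpressure_shrinks(self, params):
        cfg = make_random_config(seed=6)
        out, mu = berendsen_rescale(cfg, params.p_target - 1.0, params)
        assert mu < 1.0

    def test_pathological_pressure_clamped(self, params):
        cfg = make_random_config(seed=6)
        out, mu = berendsen_rescale(cfg, -1e6, params)
        assert mu == params.mu_min


class TestPhysicsOracles:
    def test_zero_temperature_velocity_decay(self):
        # dt must be pinned: the default time step is tied to the diffusion
        # time, which diverges as kBT -> 0
        p = SimulationParameters(kBT=1e-30, dt=2e-3)
        cfg = free_bead()
        cfg.velocities[0] = [1.0, 0.0, 0.0]
        res = run_stage(cfg, StageOptions(n_steps=1000, record_every=1000, seed=1), p)
        v = res.final_config.velocities[0, 0]
        expected = np.exp(-p.gamma * p.dt * 1000)
        assert v == pytest.approx(expected, rel=1e-2)

    def test_free_diffusion_einstein_relation(self, params):
        # origin-averaged MSD fitted with the exact Ornstein-Uhlenbeck form,
        # pooled over three independent runs
        box = 100.0
        estimates = []
        for seed in (11, 12, 13):
            res = run_stage(
                free_bead(box),
                StageOptions(n_steps=1_000_000, record_every=1_000_000,
                             snapshot_every=100, seed=seed),
                params,
            )
            traj = unwrapped_trajectory(res.snapshots, box)
            lags = np.array([40, 80, 160])
            msd = np.array(
                [np.mean(((traj[l:] - traj[:-l]) ** 2).sum(1)) for l in lags]
            )
            t = lags * 100 * params.dt
            g = params.gamma
            model = 6.0 / g * (g * t - 1 + np.exp(-g * t))
            w = 1.0 / lags**2
            estimates.append((w * msd * model).sum() / (w * model * model).sum())
        d_est = float(np.mean(estimates))
        assert d_est == pytest.approx(params.D, rel=0.05)

    def test_equipartition_in_dense_system(self):
        p = SimulationParameters(K_theta=50.0)
        from flexgel.synthetic import SystemSpec, generate_initial_chains

        cfg = generate_initial_chains(SystemSpec(10, 10, 40.0, seed=3), p)
        res = run_stage(
            cfg,
            StageOptions(n_steps=40_000, record_every=10_000,
                         snapshot_every=200, seed=12),
            p,
        )
        kes = [
            0.5 * p.m * (s.velocities**2).sum() / (3 * s.n_beads)
            for s in res.snapshots[50:]
        ]
        assert np.mean(kes) == pytest.approx(0.5 * p.kBT, rel=0.05)

    def test_barostat_reaches_target_pressure(self):
        # dilute repulsive gas relaxes until the time-averaged pressure
        # matches the barostat target within 10%
        p = SimulationParameters(p_target=0.05)
        rng = np.random.default_rng(7)
        n = 200
        box = 20.0
        # regular lattice placement avoids near-overlaps in the start state
        grid = (np.indices((6, 6, 6)).reshape(3, -1).T[:n] + 0.5) * (box / 6)
        cfg = PolymerConfiguration(
            positions=grid + rng.uniform(-0.3, 0.3, (n, 3)),
            velocities=rng.normal(size=(n, 3)),
            chain_of=np.arange(n),
            bonds=np.empty((0, 2), dtype=np.int64),
            angles=np.empty((0, 3), dtype=np.int64),
            box_edge=box,
        )
        res = run_stage(
            cfg,
            StageOptions(n_steps=40_000, record_every=20, barostat_on=True,
                         seed=21),
            p,
        )
        tail = res.pressure[len(res.pressure) // 2:]
        assert np.mean(tail) == pytest.approx(p.p_target, rel=0.10)
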