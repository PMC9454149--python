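import numpy as np
import pandas as pd
import pytest

from dockrl.env import EnvConfig
from dockrl.fixtures import FixtureSpec, make_suite
from dockrl.inference import InferConfig, aggregate_results, dock, evaluate, should_stop
from dockrl.networks import PolicyNetwork, TrunkConfig, ValueNetwork
from dockrl.voxel import BoxSpec


CFG = InferConfig(T_MAX=600, T_MIN=300, delta=50, threshold=0.3)


class TestShouldStop:
    def test_before_t_min_never_stops(self):
        history = [0.0] * 200  # perfectly flat
        assert not should_stop(history, 100, CFG)
        assert not should_stop(history, 299, CFG)

    def test_range_below_threshold_stops(self, rng):
        history = list(rng.uniform(0, 0.29, size=350))
        assert should_stop(history, 350, CFG)

    def test_range_at_threshold_boundary(self):
        base = [0.0] * 300
        assert should_stop(base + [0.0] * 49 + [0.29], 350, CFG)
        assert not should_stop(base + [0.0] * 49 + [0.31], 350, CFG)
        # strict inequality: range exactly == threshold does not stop
        assert not should_stop(base + [0.0] * 49 + [0.30], 350, CFG)

    def test_needs_full_window(self):
        cfg = InferConfig(T_MAX=100, T_MIN=10, delta=50, threshold=0.3)
        assert not should_stop([0.0] * 20, 20, cfg)
        assert should_stop([0.0] * 50, 20, cfg)

    def test_only_last_delta_values_considered(self):
        history = [5.0] * 300 + [0.1] * 50  # huge early range, flat tail
        assert should_stop(history, 350, CFG)

    def test_stop_monotonicity(self, rng):
        """Appending a value inside the current window's range keeps the
        rule satisfied at the next step."""
        for _ in range(20):
            history = list(rng.uniform(0.1, 0.35, size=320))
            if not should_stop(history, len(history), CFG):
                continue
            window = history[-CFG.delta :]
            nxt = rng.uniform(min(window), max(window))
            assert should_stop(history + [nxt], len(history) + 1, CFG)


class TestInferConfigValidation:
    def test_t_min_le_t_max(self):
        with pytest.raises(ValueError):
            InferConfig(T_MAX=100, T_MIN=200)

    def test_positive_threshold(self):
        with pytest.raises(ValueError):
            InferConfig(threshold=0.0)


def _setup(tiny_cu_map):
    template = FixtureSpec(
        n_protein_atoms=25, pocket_geometry="shell", ligand_kind="single_atom",
        box_edge=12.0, shell_radius=4.0,
    )
    records, _ = make_suite(2, template, tiny_cu_map, base_seed=60)
    box = BoxSpec(edge_length=12.0, margin=2.0, min_protein_atoms=5)
    env_cfg = EnvConfig(T_MAX=600, step_translation=0.25)
    trunk = TrunkConfig(
        grid_extent=12, n_channels=tiny_cu_map.n_channels, variant="single",
        filter_sizes=(2, 3, 4), filter_counts=(1, 1, 1), hidden=8,
    )
    actor = PolicyNetwork(trunk, seed=1)
    critic = ValueNetwork(trunk, seed=2)
    return records, box, env_cfg, actor, critic


class _ConstantCritic:
    """Critic stub with a fixed output (tests the stopping rule)."""

    def __init__(self, value=0.1):
        self._value = value

    def value(self, grid):
        return self._value


class _OscillatingCritic:
    """Critic stub whose outputs swing wider than any sane threshold."""

    def __init__(self):
        self._n = 0

    def value(self, grid):
        self._n += 1
        return 0.9 if self._n % 2 else -0.9


class TestDock:
    def test_constant_critic_stops_at_exactly_t_min(self, tiny_cu_map):
        records, box, env_cfg, actor, _ = _setup(tiny_cu_map)
        cfg = InferConfig(T_MAX=200, T_MIN=40, delta=10, threshold=0.3)
        res = dock(records[0], actor, _ConstantCritic(), tiny_cu_map,
                   cfg, box, env_cfg, seed=4)
        if res.stop_reason == "critic_converged":
            assert res.steps == cfg.T_MIN
        else:  # the greedy walk may leave the box before T_MIN
            assert res.stop_reason == "out_of_box"
            assert res.steps < cfg.T_MIN

    def test_oscillating_critic_never_converges(self, tiny_cu_map):
        records, box, env_cfg, actor, _ = _setup(tiny_cu_map)
        cfg = InferConfig(T_MAX=30, T_MIN=5, delta=5, threshold=0.3)
        res = dock(records[0], actor, _OscillatingCritic(), tiny_cu_map,
                   cfg, box, env_cfg, seed=4)
        assert res.stop_reason in ("max_steps", "out_of_box")

    def test_greedy_determinism(self, tiny_cu_map):
        records, box, env_cfg, actor, critic = _setup(tiny_cu_map)
        cfg = InferConfig(T_MAX=40, T_MIN=10, delta=5, threshold=0.3)
        r1 = dock(records[0], actor, critic, tiny_cu_map, cfg, box, env_cfg, seed=9)
        r2 = dock(records[0], actor, critic, tiny_cu_map, cfg, box, env_cfg, seed=9)
        assert r1.steps == r2.steps
        assert r1.stop_reason == r2.stop_reason
        np.testing.assert_array_equal(
            r1.trace.end_pose.coords, r2.trace.end_pose.coords
        )
        np.testing.assert_allclose(r1.trace.critic_outputs, r2.trace.critic_outputs)

    def test_trace_is_well_formed(self, tiny_cu_map):
        records, box, env_cfg, actor, critic = _setup(tiny_cu_map)
        cfg = InferConfig(T_MAX=30, T_MIN=5, delta=5, threshold=0.3)
        res = dock(records[0], actor, critic, tiny_cu_map, cfg, box, env_cfg, seed=2)
        tr = res.trace
        assert len(tr.rewards) == len(tr.poses) - 1
        assert len(tr.critic_outputs) == len(tr.poses)
        assert res.steps == tr.n_steps
        # stopping never reads the truth: all critic outputs in tanh range
        assert all(-1 < o < 1 for o in tr.critic_outputs)

    def test_out_of_box_ends_with_last_in_box_pose(self, tiny_cu_map):
        records, box, env_cfg, actor, critic = _setup(tiny_cu_map)
        # huge steps force a quick exit
        env_big = EnvConfig(T_MAX=600, step_translation=3.0)
        cfg = InferConfig(T_MAX=100, T_MIN=90, delta=5, threshold=0.3)
        res = dock(records[0], actor, critic, tiny_cu_map, cfg, box, env_big, seed=2)
        assert res.stop_reason == "out_of_box"
        assert np.isfinite(res.final_rmsd)


class TestEvaluate:
    def test_rows_and_summary(self, tiny_cu_map):
        records, box, env_cfg, actor, critic = _setup(tiny_cu_map)
        cfg = InferConfig(T_MAX=25, T_MIN=5, delta=5, threshold=0.3)
        rows, summary = evaluate(records, actor, critic, tiny_cu_map, cfg,
                                 box, env_cfg, boxes_per_record=2, seed=0)
        assert len(rows) == 4
        for col in ("final_rmsd", "improvement_rate", "stop_reason", "steps"):
            assert col in rows.columns
        for key in ("mean_rmsd", "median_rmsd", "mean_improvement_rate",
                    "median_improvement_rate", "dcc_success_rate"):
            assert key in summary

    def test_sulfate_reports_both_distances(self, so4_map):
        template = FixtureSpec(
            n_protein_atoms=25, pocket_geometry="shell", ligand_kind="sulfate_like",
            box_edge=12.0, shell_radius=4.0,
        )
        records, _ = make_suite(1, template, so4_map, base_seed=70)
        box = BoxSpec(edge_length=12.0, margin=2.0, min_protein_atoms=5)
        env_cfg = EnvConfig(T_MAX=600, step_translation=0.25)
        trunk = TrunkConfig(
            grid_extent=12, n_channels=so4_map.n_channels, variant="multi",
            filter_sizes=(4, 5, 6), filter_counts=(1, 1, 1), hidden=8,
        )
        actor = PolicyNetwork(trunk, seed=1)
        critic = ValueNetwork(trunk, seed=2)
        cfg = InferConfig(T_MAX=15, T_MIN=3, delta=3, threshold=0.3)
        rows, summary = evaluate(records, actor, critic, so4_map, cfg,
                                 box, env_cfg, seed=0)
        assert "permutation_distance" in rows.columns
        assert "center_distance" in rows.columns
        assert "median_permutation_distance" in summary
        assert "median_center_distance" in summary

    def test_mean_improvement_aggregation(self):
        rows = pd.DataFrame(
            {"final_rmsd": [1.0, 2.0], "improvement_rate": [0.6, 0.8]}
        )
        summary = aggregate_results(rows)
        assert summary["mean_improvement_rate"] == pytest.approx(0.7)

    def test_empty_dataset_rejected(self, tiny_cu_map):
        _, box, env_cfg, actor, critic = _setup(tiny_cu_map)
        with pytest.raises(ValueError, match="empty"):
            evaluate([], actor, critic, tiny_cu_map)


def test_perfect_oracle_actor_reaches_truth(tiny_cu_map):
    """An oracle policy that always argmaxes the truth-approaching action
    achieves improvement rate ~1 on an empty-pocket fixture."""
    from dockrl.fixtures import make_fixture
    from dockrl.metrics import rmsd
    from dockrl.env import DockingEnv

    record, _ = make_fixture(
        FixtureSpec(n_protein_atoms=25, pocket_geometry="empty",
                    ligand_kind="single_atom", box_edge=12.0, seed=81),
        tiny_cu_map,
    )
    box = BoxSpec(edge_length=12.0, margin=2.0, min_protein_atoms=5)
    env_cfg = EnvConfig(T_MAX=600, step_translation=0.1)
    env = DockingEnv(record, tiny_cu_map, box, env_cfg, seed=3)
    env.reset()
    d0 = rmsd(env.true_pose, env.pose)
    done = False
    while not done:
        delta = env.true_pose.coords[0] - env.pose.coords[0]
        axis = int(np.argmax(np.abs(delta)))
        action = 2 * axis + (0 if delta[axis] > 0 else 1)
        _, _, done, _ = env.step(action)
        if rmsd(env.true_pose, env.pose) < 0.1:
            break
    d1 = rmsd(env.true_pose, env.pose)
    assert (d0 - d1) / d0 > 0.95
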