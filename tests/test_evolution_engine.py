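import dataclasses

import numpy as np
import pytest

import redqueen as rq
from redqueen.evolution_engine import SimulationConfig, make_offspring, run, step_generation
from redqueen.genome_model import AffinityDistribution, Population, create_allele


def tiny_config(**kw):
    base = dict(N=20, u=1e-3, v=1e-3, h=20, d=6.0, mean_affinity=1.0,
                generations=30, burn_in=5, seed=11, L=50_000,
                record_trajectory=True)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(N=1), dict(u=1.5), dict(v=-0.1), dict(burn_in=40),
        dict(mode="nope"), dict(c_hom=2.5), dict(n_mei=0), dict(d=0.0),
    ])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            tiny_config(**bad)

    def test_rescaled_keeps_4Nu_invariant(self):
        cfg = tiny_config(N=20, u=1e-3, v=2e-3)
        r = cfg.rescaled(2.0)
        assert r.N == 10 and r.u == pytest.approx(2e-3)
        assert 4 * r.N * r.u == pytest.approx(4 * cfg.N * cfg.u)
        assert r.rescale == pytest.approx(2.0)
        with pytest.raises(ValueError):
            tiny_config(N=21).rescaled(2.0)


class TestStepGeneration:
    def test_population_size_constant(self, rng):
        cfg = tiny_config(N=30)
        pop = Population.founder(30, 20, AffinityDistribution(1.0), rng, L=50_000)
        step_generation(pop, cfg, rng)
        assert pop.N == 30
        assert len(pop.hap_allele) == 60
        assert pop.generation == 1

    def test_frequencies_normalized_after_steps(self, rng):
        cfg = tiny_config(N=25, u=5e-3)
        pop = Population.founder(25, 20, AffinityDistribution(1.0), rng, L=50_000)
        for _ in range(5):
            step_generation(pop, cfg, rng)
            f = rq.allele_frequencies(pop)
            assert sum(f.values()) == pytest.approx(1.0)
            assert set(f) == set(pop.registry)  # registry == live alleles


class TestDeterminism:
    def test_bit_identical_trajectories(self):
        cfg = tiny_config(generations=40, seed=7)
        r1 = run(cfg)
        r2 = run(cfg)
        assert r1.scalars.equals(r2.scalars)
        assert r1.population.to_json() == r2.population.to_json()

    def test_seed_changes_trajectory(self):
        r1 = run(tiny_config(generations=40, seed=7))
        r2 = run(tiny_config(generations=40, seed=8))
        assert not r1.scalars.equals(r2.scalars)


class TestMakeOffspring:
    def test_sterile_parent_never_contributes(self, rng):
        # parent 1 fully eroded: zero binding, so every gamete from parent 0
        pop = Population.founder(2, 30, AffinityDistribution(5.0), rng, L=50_000)
        a = next(iter(pop.registry.values()))
        b = create_allele(pop, pop.affinity_dist, rng)
        b.affinities[:] = 5.0
        pop.col_aff[pop.allele_cols[b.row]] = 5.0
        pop.hap_allele[2:] = b.row
        pop.hap_state[2:, pop.allele_cols[b.row]] = 0  # parent 1 dead sites
        pop.version += 1
        cfg = tiny_config(N=2, h=30, mean_affinity=5.0)
        for _ in range(20):
            child = make_offspring(pop, cfg, rng)
            assert child.hap_a.prdm9_allele == a.allele_id
            assert child.hap_b.prdm9_allele == a.allele_id

    def test_gamete_source_tracks_relative_fertility(self, rng):
        # two parents with different success rates: at n_mei=1 the share of
        # gametes from parent i is w_i / (w_1 + w_2) (rejection sampling)
        from redqueen import summary_stats as ss
        pop = Population.founder(2, 120, AffinityDistribution(0.2), rng, L=200_000)
        a = next(iter(pop.registry.values()))
        b = create_allele(pop, pop.affinity_dist, rng)
        pop.hap_allele[2:] = b.row
        # erode 70% of parent 1's sites (highest affinity first)
        cols = pop.allele_cols[b.row]
        order = np.argsort(pop.col_aff[cols])[::-1]
        pop.hap_state[2:, cols[order[:84]]] = 0
        pop.version += 1
        # empirical per-parent meiosis success rates as the oracle
        from redqueen.meiosis_kernel import resolve_meiosis
        reg = dict(pop.registry)
        n_mc = 1500
        w_emp = []
        for i in (0, 1):
            ind = pop.individual_view(i)
            w_emp.append(sum(
                resolve_meiosis(ind, reg, "symmetry_required", 6.0, 1.0, rng).success
                for _ in range(n_mc)) / n_mc)
        w0, w1 = w_emp
        cfg = tiny_config(N=2, h=120, mean_affinity=0.2)
        n = 300
        from_a = 0
        for _ in range(n):
            child = make_offspring(pop, cfg, rng)
            from_a += (child.hap_a.prdm9_allele == a.allele_id)
            from_a += (child.hap_b.prdm9_allele == a.allele_id)
        p = w0 / (w0 + w1)
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(from_a / (2 * n) - p) < 4 * se

    def test_livelock_guard(self, rng):
        pop = Population.founder(4, 20, AffinityDistribution(1.0), rng, L=50_000)
        pop.hap_state[:, : pop.n_cols] = 0  # entire population sterile
        pop.version += 1
        cfg = tiny_config(N=4, max_parent_draws=500)
        with pytest.raises(RuntimeError, match="sterile"):
            make_offspring(pop, cfg, rng)


class TestRun:
    def test_zero_generations(self):
        res = run(tiny_config(generations=0, burn_in=0))
        assert res.scalars.empty
        assert res.summary == {}

    def test_summary_averages_post_burnin(self):
        cfg = tiny_config(generations=30, burn_in=10)
        res = run(cfg)
        assert res.summary["generations_averaged"] == 20
        assert 1.0 <= res.summary["D"]
        assert 0.0 <= res.summary["theta_bar"] <= 1.0

    def test_trajectory_contents(self):
        cfg = tiny_config(generations=30, stats_interval=10)
        res = run(cfg)
        tr = res.trajectory
        assert set(tr.columns) == {"generation", "allele_id", "f", "theta",
                                   "mean_affinity", "q", "w"}
        by_gen = tr.groupby("generation")["f"].sum()
        assert np.allclose(by_gen.values, 1.0)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = tiny_config(generations=20)
        run(cfg, checkpoint_dir=tmp_path, checkpoint_interval=10)
        files = sorted(tmp_path.glob("checkpoint_*.json"))
        assert len(files) == 2
        pop = Population.from_json(files[-1].read_text())
        assert pop.generation == 20
        assert sum(rq.allele_frequencies(pop).values()) == pytest.approx(1.0)


class TestNeutralControl:
    def test_fixation_probability_matches_initial_frequency(self, rng):
        # control mode, no mutation, saturating sites: pure Wright-Fisher
        # drift; an allele at frequency p fixes with probability p
        p0, N, reps = 0.25, 16, 400
        fixed = 0
        from redqueen.evolution_engine import _Engine
        from redqueen import _kernels
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            pop = Population.founder(N, 6, AffinityDistribution(50.0), r, L=20_000)
            b = create_allele(pop, pop.affinity_dist, r)
            pop.hap_allele[: int(p0 * 2 * N)] = b.row
            cfg = SimulationConfig(N=N, u=0.0, v=0.0, h=6, d=6.0,
                                   mean_affinity=50.0, generations=1,
                                   mode="control_no_symmetry", seed=1000 + rep)
            eng = _Engine(pop, cfg, _kernels.new_rng_state(2000 + rep))
            for _ in range(3000):
                eng.step(pop, r)
                rows = set(pop.hap_allele.tolist())
                if len(rows) == 1:
                    break
            fixed += (b.allele_id in pop.registry)
        se = np.sqrt(p0 * (1 - p0) / reps)
        assert abs(fixed / reps - p0) < 3.5 * se
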