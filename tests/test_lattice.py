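"""Lattice engine: initialization, diffusion, stepping, determinism, audit."""
import numpy as np
import pytest
from scipy import stats

from macpol import InjectionEvent, Simulation, SimulationConfig, run, total
from macpol.engine import CELL_COLUMNS, CENSUS_COLUMNS, move_sites
from macpol.errors import ConfigurationError


def tiny_config(**kw):
    base = dict(
        L=6, n_steps=20, seed=5,
        n_macrophages=30, n_bcells=40, n_h1=40, n_h2=40, n_hr=40,
        helper_innate_activation=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestInit:
    def test_zero_cells_empty_lattice(self):
        cfg = tiny_config(n_macrophages=0, n_bcells=0, n_h1=0, n_h2=0, n_hr=0)
        sim = Simulation(cfg)
        assert sim.state.n_agents == 0
        assert sim.state.census().sum() == 0

    def test_initial_census_matches_config(self):
        sim = Simulation(tiny_config())
        row = dict(zip(CENSUS_COLUMNS, sim.state.census()))
        assert row["M0_r"] == 30          # all macrophages resting, M0
        assert row["B_a"] == 40           # B cells start active
        assert row["H1_r"] == row["H2_r"] == row["Hr_r"] == 40
        assert sum(row[c] for c in CELL_COLUMNS) == 190
        assert all(row[c] == 0 for c in ("IFNg", "IL4", "IL10", "Ab"))

    def test_default_lymphocyte_monocyte_ratio(self):
        cfg = SimulationConfig()
        lymph = cfg.n_bcells + cfg.n_h1 + cfg.n_h2 + cfg.n_hr
        assert lymph / cfg.n_macrophages == pytest.approx(5.0)

    def test_every_macrophage_starts_uncommitted(self):
        sim = Simulation(tiny_config())
        assert (sim.state.phen == 0).all()
        assert (sim.state.grn == 0).all()

    def test_site_capacity_violation(self):
        with pytest.raises(ConfigurationError):
            Simulation(tiny_config(L=1, site_capacity=10))


class TestDiffusion:
    def test_periodic_wrap_returns_to_origin(self):
        L = 5
        site = np.array([0])
        for _ in range(L):
            site = move_sites(site, np.array([1]), L)  # +x every time
        assert site[0] == 0

    def test_counts_conserved(self):
        cfg = tiny_config(n_steps=30, injections=[InjectionEvent(step=0, species="Ag", amount=200, has_lps=True)],
                          ag_replication_prob=0.0)
        ts = run(cfg)
        # no reactions can change total cells; macrophage count constant
        assert (total(ts, "M") == 30).all()

    def test_single_walker_occupancy_uniform(self):
        # one agent random-walking on a 4^3 torus visits sites uniformly
        # record every 25th position so samples are effectively independent
        L, n_steps, thin = 4, 50000, 25
        rng = np.random.default_rng(11)
        site = np.array([0])
        visits = np.zeros(L**3, dtype=int)
        for t in range(n_steps):
            site = move_sites(site, rng.integers(0, 7, 1), L)
            if t % thin == 0:
                visits[site[0]] += 1
        assert stats.chisquare(visits).pvalue > 0.001


class TestStepAndRun:
    def test_empty_lattice_census_zero(self):
        cfg = tiny_config(n_macrophages=0, n_bcells=0, n_h1=0, n_h2=0, n_hr=0)
        ts = run(cfg)
        assert (ts[list(CENSUS_COLUMNS)].to_numpy() == 0).all()

    def test_n_steps_zero_initial_census_only(self):
        ts = run(tiny_config(n_steps=0))
        assert len(ts) == 1 and ts["step"].iloc[0] == 0

    def test_seed_determinism_byte_identical_csv(self, tmp_path):
        csvs = []
        for i in range(2):
            p = tmp_path / f"run{i}.csv"
            cfg = tiny_config(output_path=str(p),
                              injections=[InjectionEvent(step=0, species="Ag", amount=100, has_lps=True)])
            run(cfg)
            csvs.append(p.read_bytes())
        assert csvs[0] == csvs[1]

    def test_different_seeds_differ(self):
        inj = [InjectionEvent(step=0, species="Ag", amount=100, has_lps=True)]
        a = run(tiny_config(seed=1, injections=inj, helper_innate_activation=0.05))
        b = run(tiny_config(seed=2, injections=inj, helper_innate_activation=0.05))
        assert not a.equals(b)

    def test_colocated_macrophage_and_ifng_activate_before_diffusion(self, net):
        # deterministic micro-scenario on a 1-site lattice
        from macpol.engine import SimState, apply_rule_phase
        from macpol.rules import build_rule_table
        import numpy as np

        state = SimState(
            L=1,
            kind=np.array([0], dtype=np.int8), act=np.array([0], dtype=np.int8),
            phen=np.zeros(1, dtype=np.int8), site=np.zeros(1, dtype=np.int64),
            grn=np.zeros(1, dtype=np.uint32),
            grids=np.zeros((6, 1), dtype=np.int64),
        )
        state.grids[0, 0] = 1  # one IFNg token
        rules = build_rule_table()
        delta = np.zeros(len(CENSUS_COLUMNS), dtype=np.int64)
        rng = np.random.default_rng(0)
        apply_rule_phase(state, rules, rng.permutation(len(rules)), rng, delta)
        assert state.act[0] == 1  # active before any diffusion happened

    def test_injection_schedule_appears_in_census(self):
        cfg = tiny_config(
            n_steps=10, ag_replication_prob=0.0,
            injections=[InjectionEvent(step=5, species="IL4", amount=50)],
            cytokine_half_life=1e9,
        )
        ts = run(cfg)
        assert ts["IL4"].iloc[4] == 0
        assert ts["IL4"].iloc[5] == 50


class TestAudit:
    def test_census_reconciles_over_200_steps(self):
        cfg = tiny_config(
            n_steps=200, seed=3, helper_innate_activation=0.05,
            injections=[
                InjectionEvent(step=0, species="Ag", amount=300, has_lps=True),
                InjectionEvent(step=40, species="IL10", amount=200),
            ],
        )
        sim = Simulation(cfg)
        sim.run()  # raises AuditError on any discrepancy
        assert len(sim.audit_log) == 200
        assert all(rec.discrepancy == 0 for rec in sim.audit_log)
        assert any(rec.firings for rec in sim.audit_log)
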