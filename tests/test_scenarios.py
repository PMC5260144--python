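"""Ensemble layer: replicate orchestration, outcome labels, aggregation."""
import numpy as np
import pytest

from macpol import (
    OutcomePolicy,
    classify_outcome,
    dampened_fraction,
    make_scenario,
    run_scenario,
)
from macpol.engine import CENSUS_COLUMNS
from macpol.errors import ConfigurationError
from macpol.fixtures import make_fixture
from macpol.scenarios import EnsembleResult, bacterium_il10, gram_negative, vaccine_il4

TINY = dict(L=6, n_steps=30, n_macrophages=20, n_bcells=25, n_h1=25, n_h2=25, n_hr=25)


def test_scenario_injection_schedules():
    gn = gram_negative()
    assert gn.config.injections[0].step == 0 and gn.config.injections[0].has_lps

    vx = vaccine_il4()
    assert not vx.config.injections[0].has_lps
    assert vx.config.ag_replication_prob == 0.0
    il4 = [ev for ev in vx.config.injections if ev.species == "IL4"]
    spd = vx.config.steps_per_day
    assert [ev.step for ev in il4] == [spd * d for d in range(3, 10)]  # day 3, one week

    bi = bacterium_il10()
    assert bi.config.injections[0].has_lps
    il10 = [ev for ev in bi.config.injections if ev.species == "IL10"]
    assert len(il10) == 7


def test_unknown_scenario_rejected():
    with pytest.raises(ConfigurationError):
        make_scenario("nonsense")


def test_single_replicate_mean_equals_series_sd_zero():
    res = run_scenario(gram_negative(ag_dose=50, **TINY), n_replicates=1, base_seed=3)
    ts = res.replicates[0]
    assert np.allclose(res.mean[list(CENSUS_COLUMNS)], ts[list(CENSUS_COLUMNS)])
    assert (res.sd[list(CENSUS_COLUMNS)].to_numpy() == 0).all()


def test_replicates_use_consecutive_seeds():
    res = run_scenario(gram_negative(ag_dose=50, **TINY), n_replicates=3, base_seed=10)
    assert res.seeds == [10, 11, 12]
    assert res.n_replicates == 3


def test_outcome_partition():
    res = run_scenario(gram_negative(ag_dose=50, **TINY), n_replicates=4, base_seed=0)
    assert all(o in ("controlled", "dampened") for o in res.outcomes)
    controlled = res.outcomes.count("controlled") / 4
    assert controlled + dampened_fraction(res) == pytest.approx(1.0)


class TestClassifyOutcome:
    def test_growing_antigen_is_dampened(self, rng):
        ts = make_fixture("timeseries", rng, ag_trend="dampened")
        assert classify_outcome(ts) == "dampened"

    def test_cleared_antigen_is_controlled(self, rng):
        ts = make_fixture("timeseries", rng, ag_trend="controlled")
        assert classify_outcome(ts) == "controlled"

    def test_empty_series_rejected(self, rng):
        import pandas as pd

        with pytest.raises(ValueError):
            classify_outcome(pd.DataFrame())

    def test_threshold_policy(self, rng):
        ts = make_fixture("timeseries", rng, ag_trend="dampened")  # 100 -> 350
        assert classify_outcome(ts, OutcomePolicy(ratio=10.0)) == "controlled"


def test_dampened_fraction_arithmetic():
    res = EnsembleResult("x", [0], [None], None, None, ["dampened", "controlled", "dampened"])
    assert dampened_fraction(res) == pytest.approx(2 / 3)


def test_il10_dose_response_is_monotone():
    """More IL-10 does not make the infection easier to control: the
    dampened fraction is non-decreasing over three widely spaced dose
    levels (small-ensemble tolerance of one replicate)."""
    fracs = []
    for i, dose in enumerate((0, 8000, 48000)):
        sc = bacterium_il10(il10_dose=dose)
        res = run_scenario(sc, n_replicates=8, base_seed=40 + 100 * i)
        fracs.append(res.dampened_fraction)
    assert fracs[1] >= fracs[0] - 1 / 8
    assert fracs[2] >= fracs[1] - 1 / 8
    assert fracs[2] > fracs[0]  # the lever visibly engages


def test_polarization_outcome_survives_upscaling():
    """Doubling L with all counts and doses scaled by volume (constant
    density) preserves the Gram-negative scenario's M1 polarization."""
    from macpol import total as _total

    sc = gram_negative(
        ag_dose=64000, L=18,
        n_macrophages=4000, n_bcells=5000, n_h1=5000, n_h2=5000, n_hr=5000,
        n_steps=800,
    )
    ts = run_scenario(sc, n_replicates=1, base_seed=3).replicates[0]
    assert _total(ts, "M1").iloc[-1] > _total(ts, "M2").iloc[-1]
    assert _total(ts, "Ag").iloc[-1] < 64000
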