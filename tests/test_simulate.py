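"""Tests for the synthetic droplet generator.

Stochastic assertions use 3-standard-error bands around closed-form
expectations; oracles are independent of the code paths they check
(direct numpy sampling, explicit burst-cycle loops).
"""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gaussian_kde

from phagedrop.gating import GatePolicy, classify_and_summarize, size_filter
from phagedrop.poisson import lambda_from_negative_fraction
from phagedrop.simulate import (
    DropletPopulation,
    SimulationConfig,
    render_events,
    simulate_encapsulation,
    simulate_event_table,
    simulate_experiment,
    simulate_propagation,
)


def _config(**overrides) -> SimulationConfig:
    base = dict(seed=11, n_droplets=1000, timepoints_h=(0.0, 5.0))
    base.update(overrides)
    return SimulationConfig(**base)


class TestEncapsulation:
    def test_empty_fraction_matches_poisson_zero_class(self):
        # lambda=0.08: 92.3% of droplets should hold no phage
        cfg = _config(lambda_phage=0.08, n_droplets=1_000_000)
        pop = simulate_encapsulation(cfg)
        p0 = math.exp(-0.08)
        se = math.sqrt(p0 * (1 - p0) / cfg.n_droplets)
        assert abs((pop.n_phage == 0).mean() - p0) < 3 * se

    def test_zero_rate_means_every_droplet_empty(self):
        pop = simulate_encapsulation(_config(lambda_phage=0.0, n_droplets=5000))
        assert (pop.n_phage == 0).all()

    def test_mean_occupancy_matches_independent_poisson_oracle(self):
        cfg = _config(lambda_phage=0.8, n_droplets=100_000)
        pop = simulate_encapsulation(cfg)
        oracle = np.random.default_rng(987654).poisson(0.8, cfg.n_droplets)
        se_diff = math.sqrt(2 * 0.8 / cfg.n_droplets)
        assert abs(pop.n_phage.mean() - 0.8) < 3 * math.sqrt(0.8 / cfg.n_droplets)
        assert abs(pop.n_phage.mean() - oracle.mean()) < 3 * se_diff

    def test_cell_counts_independent_of_phage_counts(self):
        pop = simulate_encapsulation(_config(n_droplets=200_000))
        # sample correlation between independent Poissons ~ N(0, 1/sqrt(n))
        r = np.corrcoef(pop.n_phage, pop.n_cells)[0, 1]
        assert abs(r) < 3 / math.sqrt(len(pop))

    def test_diameter_mean_and_cv(self):
        cfg = _config(n_droplets=200_000, diameter_mean_um=30.0, diameter_cv=0.05)
        pop = simulate_encapsulation(cfg)
        assert pop.diameter_um.mean() == pytest.approx(30.0, rel=0.005)
        cv = pop.diameter_um.std() / pop.diameter_um.mean()
        assert cv == pytest.approx(0.05, rel=0.05)
        assert (pop.diameter_um > 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            _config(lambda_phage=-0.1)
        with pytest.raises(ValueError):
            _config(n_droplets=0)
        with pytest.raises(ValueError):
            _config(burst_size=1.0)
        with pytest.raises(ValueError):
            _config(artifact_intensity=5.0)  # below baseline


class TestPropagation:
    @staticmethod
    def _ladder_oracle(n_phage, n_cells, burst, latent, cap, t):
        """Step-by-step burst-cycle loop, independent of the closed form."""
        if n_phage == 0 or n_cells == 0:
            return float(n_phage)
        g = float(n_phage)
        for _ in range(math.floor(t / latent)):
            g = min(cap, g * burst)
        return g

    def test_pre_latent_identity(self):
        cfg = _config(latent_period_h=1.0)
        pop = simulate_encapsulation(cfg)
        assert np.array_equal(simulate_propagation(pop, cfg, 0.0), pop.n_phage)

    def test_no_phage_or_no_cells_never_grows(self):
        cfg = _config()
        pop = simulate_encapsulation(cfg)
        g = simulate_propagation(pop, cfg, 24.0)
        inert = (pop.n_phage == 0) | (pop.n_cells == 0)
        assert np.array_equal(g[inert], pop.n_phage[inert].astype(float))

    @pytest.mark.parametrize(
        "n_phage,burst,latent,cap,t",
        [
            (1, 100.0, 1.0, 1e5, 24.0),  # saturates at the cap
            (1, 100.0, 1.0, 1e5, 2.0),
            (3, 7.0, 0.5, 1e9, 3.3),
            (2, 120.0, 0.4, 1e5, 1.0),
            (1, 2.0, 2.0, 50.0, 11.0),
        ],
    )
    def test_matches_iterative_ladder_oracle(self, n_phage, burst, latent, cap, t):
        cfg = _config(
            burst_size=burst,
            latent_period_h=latent,
            genome_cap=cap,
            timepoints_h=(0.0, t),
            artifact_intensity=10.1,  # keep within (baseline, cap level) for every cap
        )
        pop = DropletPopulation(
            config=cfg,
            n_phage=np.array([n_phage]),
            n_cells=np.array([1]),
            diameter_um=np.array([30.0]),
            artifact=np.array([False]),
        )
        expected = self._ladder_oracle(n_phage, 1, burst, latent, cap, t)
        assert simulate_propagation(pop, cfg, t)[0] == pytest.approx(expected)

    @given(
        t1=st.floats(0.0, 48.0),
        t2=st.floats(0.0, 48.0),
        n_phage=st.integers(0, 5),
        n_cells=st.integers(0, 40),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_time_and_capped(self, t1, t2, n_phage, n_cells):
        cfg = _config()
        pop = DropletPopulation(
            config=cfg,
            n_phage=np.array([n_phage]),
            n_cells=np.array([n_cells]),
            diameter_um=np.array([30.0]),
            artifact=np.array([False]),
        )
        lo, hi = sorted([t1, t2])
        g_lo = simulate_propagation(pop, cfg, lo)[0]
        g_hi = simulate_propagation(pop, cfg, hi)[0]
        assert g_lo <= g_hi
        assert g_hi <= max(cfg.genome_cap, n_phage)
        assert g_lo >= 0


class TestRenderEvents:
    def test_baseline_only_when_no_genomes(self):
        cfg = _config(lambda_phage=0.0, artifact_prob=0.0, n_droplets=50_000)
        pop = simulate_encapsulation(cfg)
        ev = render_events(pop, cfg, 5.0)
        se = cfg.fl_baseline * cfg.fl_noise_cv / math.sqrt(len(ev))
        assert ev["fluorescence"].mean() == pytest.approx(cfg.fl_baseline, abs=3 * se)
        assert (ev["condition"] == "no_phage").all()

    def test_zero_gain_makes_conditions_indistinguishable(self):
        from scipy.stats import ks_2samp

        kw = dict(fl_per_genome=0.0, artifact_prob=0.0, n_droplets=20_000)
        with_phage = simulate_event_table(_config(seed=3, lambda_phage=0.2, **kw))
        without = simulate_event_table(_config(seed=4, lambda_phage=0.0, **kw))
        stat = ks_2samp(
            with_phage["fluorescence"], without["fluorescence"]
        )
        assert stat.pvalue > 0.001

    def test_unknown_timepoint_rejected(self):
        cfg = _config()
        pop = simulate_encapsulation(cfg)
        with pytest.raises(ValueError, match="timepoint"):
            render_events(pop, cfg, 2.0)

    def test_bimodal_and_threshold_separable_at_five_hours(self):
        # the reference condition should produce two well-separated
        # fluorescence modes at 5 h, split cleanly by a single threshold
        cfg = SimulationConfig(seed=5, lambda_phage=0.2, lambda_cells=19.0)
        pop = simulate_encapsulation(cfg)
        ev = render_events(pop, cfg, 5.0)
        logf = np.log10(ev["fluorescence"].to_numpy())
        grid = np.linspace(logf.min(), logf.max(), 512)
        dens = gaussian_kde(logf)(grid)
        maxima = np.sum(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        )
        assert maxima >= 2
        # essentially nothing falls between the two modes
        mid_band = ((ev["fluorescence"] > 50) & (ev["fluorescence"] < 130)).mean()
        assert mid_band < 0.01

    def test_same_seed_and_config_byte_identical(self, tmp_path):
        cfg = _config(n_droplets=2000)
        a = simulate_event_table(cfg)
        b = simulate_event_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_event_table(_config(seed=1, n_droplets=500))
        b = simulate_event_table(_config(seed=2, n_droplets=500))
        assert not a["fluorescence"].equals(b["fluorescence"])

    def test_fluorescent_fraction_nondecreasing_without_artifacts(self):
        cfg = SimulationConfig(
            seed=13,
            n_droplets=20_000,
            artifact_prob=0.0,
            fl_noise_cv=0.05,
        )
        _, ev = simulate_experiment(cfg)
        # classify without the size filter: its per-timepoint resampling
        # adds jitter unrelated to the renderer property under test
        summary = classify_and_summarize(ev, GatePolicy(apply_size_filter=False))
        fracs = summary.sort_values("timepoint_h")["fluorescent_fraction"].to_numpy()
        assert (np.diff(fracs) >= -1e-12).all()


class TestLatentTruthRoundTrip:
    def test_population_indexing_matches_arrays(self):
        cfg = _config(n_droplets=50)
        pop = simulate_encapsulation(cfg)
        s = pop[7]
        assert s.n_phage == pop.n_phage[7]
        assert s.genomes_at[0.0] == pop.n_phage[7]
        assert list(s.genomes_at) == list(cfg.timepoints_h)

    def test_lambda_recovered_within_own_ci_across_replicates(self):
        # estimator round trip through the full simulate->gate->invert path:
        # the 95% CI should cover the true lambda in >= 90/100 replicates
        for lam in (0.05, 0.2, 0.8):
            hits = 0
            for rep in range(100):
                cfg = SimulationConfig(
                    seed=100_000 + rep,
                    lambda_phage=lam,
                    n_droplets=20_000,
                    timepoints_h=(5.0,),
                    artifact_prob=0.0,
                )
                _, ev = simulate_experiment(cfg)
                summary = classify_and_summarize(ev, GatePolicy())
                row = summary.iloc[0]
                est = lambda_from_negative_fraction(
                    1.0 - row.fluorescent_fraction, int(row.n_after_size_filter)
                )
                hits += est.ci_low <= lam <= est.ci_high
            assert hits >= 90, f"coverage {hits}/100 at lambda={lam}"
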