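"""Receptor activation, Notch binding, delayed gene regulation."""

import numpy as np
import pytest

from msm.config import control_config
from msm.engine import Simulation
from msm.signalling import (
    DelayBuffer,
    GeneRegulationParams,
    activate_vegfr,
    bind_notch,
    gene_regulation_update,
    sample_activation,
)


class TestActivateVegfr:
    @pytest.mark.parametrize(
        "vegfr,lig,expected",
        [
            (10, 0.5, 5.0),
            (10, 0.0, 0.0),  # no ligand, no activation
            (10, 2.0, 10.0),  # capped: a receptor is active or not
            (0, 5.0, 0.0),
        ],
    )
    def test_examples(self, vegfr, lig, expected):
        assert activate_vegfr(vegfr, lig) == pytest.approx(expected)

    def test_vectorised_cap(self):
        out = activate_vegfr([4, 4, 4], [0.25, 1.0, 3.0])
        np.testing.assert_allclose(out, [1.0, 4.0, 4.0])

    def test_sampling_matches_expectation_and_never_exceeds_pool(self, rng):
        veg = np.full(4000, 10)
        lig = np.full(4000, 0.3)
        s = sample_activation(veg, lig, rng)
        assert np.all(s <= veg)
        assert s.mean() == pytest.approx(3.0, abs=0.1)


class TestBindNotch:
    @pytest.mark.parametrize(
        "avail,nmax,expected",
        [
            (3, 5, 3),  # Dll4 < Notch -> Notch* = Dll4
            (9, 5, 5),  # Dll4 > Notch -> Notch* = Notch_max
            (5, 5, 5),  # equality -> full available amount
            (0, 5, 0),
        ],
    )
    def test_examples(self, avail, nmax, expected):
        notch, consumed = bind_notch(avail, nmax)
        assert notch == expected
        assert consumed == expected  # bound ligand is removed

    def test_non_junction_agent_binds_nothing(self):
        assert bind_notch(7, 5, is_junction=False) == (0.0, 0.0)


class TestGeneRegulation:
    def test_uninhibited_cell_at_ceiling(self):
        p = GeneRegulationParams(vegfr_max=1000, sigma=10)
        v, d = gene_regulation_update(500, 0, delayed_notch=0,
                                      delayed_vegfr_active=0, params=p)
        assert v == 1000

    def test_full_inhibition_floors_at_zero(self):
        p = GeneRegulationParams(vegfr_max=1000, sigma=10)
        v, _ = gene_regulation_update(500, 0, delayed_notch=200,
                                      delayed_vegfr_active=0, params=p)
        assert v == 0

    def test_dll4_accumulates_and_caps(self):
        p = GeneRegulationParams(delta=2.0, d_max=100.0)
        _, d = gene_regulation_update(0, 90.0, 0, delayed_vegfr_active=20,
                                      params=p)
        assert d == 100.0  # ceiling

    def test_replace_mode(self):
        p = GeneRegulationParams(delta=2.0, d_max=1e6, dll4_mode="replace")
        _, d = gene_regulation_update(0, 500.0, 0, delayed_vegfr_active=30,
                                      params=p)
        assert d == 60.0


class TestDelayBuffer:
    def test_zero_primed_startup(self):
        buf = DelayBuffer(28)
        buf.append(5.0)
        assert buf.read() == 0.0

    def test_reads_exactly_delay_steps_back(self):
        buf = DelayBuffer(28)
        for t in range(101):
            buf.append(float(t))
        # current step is t=100; the delayed read is the t=72 record
        assert buf.read() == 72.0


class TestMeanFieldReduction:
    def test_two_cell_delay_map_oracle(self):
        """With filopodia disabled and deterministic activation under
        uniform VEGF, the engine's two-cell Dll4/Vegfr dynamics must match
        a two-variable delayed map iterated directly."""
        cfg = control_config(
            **{
                "vessel.n_cells": 2,
                "vegf.mode": "uniform",
                "vegf.V": 0.8,
                "filopodia.F": 0.0,  # no extension at all
                "signalling.stochastic_activation": False,
            }
        )
        sim = Simulation(cfg, seed=0)
        sig = cfg.signalling
        cell = sim.vessel.cells[0]
        n = cell.n_agents
        nj = int(cell.is_junction.sum())
        a = np.minimum(cell.ell, 1.0)

        # independent brute-force delay map: equal real-valued receptor
        # share, expected activation summed over the body agents
        T = 400
        R = np.full(2, sig.vegfr_max)
        D = np.zeros(2)
        vhist, nhist = [], []
        D_expect = np.zeros((T, 2))
        asum = a.sum()
        for t in range(T):
            vstar = (R / n) * asum
            alloc = D / nj
            nstar = np.array(
                [nj * min(alloc[1], sig.notch_max), nj * min(alloc[0], sig.notch_max)]
            )
            consumed = nstar[::-1]
            D = np.maximum(D - consumed, 0.0)
            vhist.append(vstar.copy())
            nhist.append(nstar.copy())
            dv = vhist[t - sig.delay_steps] if t >= sig.delay_steps else np.zeros(2)
            dn = nhist[t - sig.delay_steps] if t >= sig.delay_steps else np.zeros(2)
            R = np.maximum(0.0, sig.vegfr_max - sig.sigma * dn)
            D = np.minimum(sig.d_max, D + sig.delta * dv)
            D_expect[t] = D

        trace = Simulation(cfg, seed=0).run(T)
        np.testing.assert_allclose(trace.dll4, D_expect, rtol=1e-9)

    def test_symmetry_holds_iff_filopodia_disabled(self):
        cfg = control_config(
            **{
                "vessel.n_cells": 2,
                "vegf.mode": "uniform",
                "vegf.V": 0.8,
                "filopodia.F": 0.0,
                "signalling.stochastic_activation": False,
            }
        )
        tr = Simulation(cfg, seed=5).run(300)
        assert np.allclose(tr.dll4[:, 0], tr.dll4[:, 1])

        cfg2 = control_config(
            **{"vessel.n_cells": 2, "vegf.mode": "uniform", "vegf.V": 0.8}
        )
        tr2 = Simulation(cfg2, seed=5).run(300)
        assert not np.allclose(tr2.dll4[:, 0], tr2.dll4[:, 1])
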