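"""Shared fixtures: the frozen default web and small programmatic webs."""

import numpy as np
import pytest
from hypothesis import settings

from ecosens.config import (
    Component,
    DietMatrix,
    FoodWebConfig,
    Forcing,
    ProcessParams,
    RefugeFactors,
    Settings,
)
from ecosens.synthetic import load_default_web

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_web():
    return load_default_web()


def make_pool(cfg, cid, biomass, *, kind="biomass_pool", guild="zooplankton",
              mum=0.0, C=0.0, E=0.5, mL=0.0, mQ=0.0, key=False):
    cfg.components.append(Component(cid, cid, kind, guild, 1, is_key_species=key))
    cfg.params[cid] = ProcessParams(
        mum=np.array([mum]), C=np.array([C]), E=E, mL=mL,
        mQ_juvenile=mQ, mQ_adult=mQ)
    cfg.initial.pools[cid] = float(biomass)


def make_vert(cfg, cid, numbers, w_struct, w_reserve, *, guild="pelagic_fish",
              mum=None, C=None, E=0.6, mL=0.0, mQ_j=0.0, mQ_a=0.0,
              maint=0.0, maturity=2, mode="beverton_holt", sigma=0.0,
              spawn_fraction=0.2, KDENR=None, BHa=None, BHb=None,
              recruit_ws=None, recruit_wr=None, key=False):
    n = len(numbers)
    cfg.components.append(Component(
        cid, cid, "vertebrate", guild, n, is_key_species=key,
        recruitment_mode=mode, recruitment_lognormal_sigma=sigma))
    p = ProcessParams(
        mum=np.asarray(mum if mum is not None else [0.0] * n, dtype=float),
        C=np.asarray(C if C is not None else [0.0] * n, dtype=float),
        E=E, mL=mL, mQ_juvenile=mQ_j, mQ_adult=mQ_a,
        maintenance_rate=maint, maturity_age=maturity,
        spawn_fraction=spawn_fraction,
        recruit_w_struct=recruit_ws if recruit_ws is not None else w_struct[0],
        recruit_w_reserve=recruit_wr if recruit_wr is not None else w_reserve[0],
        KDENR=KDENR, BHa=BHa, BHb=BHb)
    cfg.params[cid] = p
    cfg.initial.vertebrates[cid] = {
        "numbers": np.asarray(numbers, dtype=float),
        "w_struct": np.asarray(w_struct, dtype=float),
        "w_reserve": np.asarray(w_reserve, dtype=float),
    }


def base_config(years=1, spin_up=0, window=1, seed=0, spawn_day=90):
    cfg = FoodWebConfig()
    cfg.settings = Settings(years_total=years, spin_up_years=spin_up,
                            averaging_window_years=window, seed=seed,
                            spawn_day=spawn_day)
    cfg.diet = DietMatrix()
    cfg.refuge = RefugeFactors()
    cfg.forcing = Forcing(producer_id="")
    return cfg


@pytest.fixture
def minimal_web():
    """Smallest valid web: a forced producer plus one grazing pool."""
    cfg = base_config(years=1)
    make_pool(cfg, "PP", 1000.0, kind="producer", guild="phytoplankton")
    make_pool(cfg, "ZP", 100.0, mum=0.1, C=1e-4, E=0.5, mL=0.01, mQ=1e-6)
    cfg.diet = DietMatrix({"ZP": {"PP": 0.5}})
    cfg.forcing = Forcing(producer_id="PP", cycle=np.full(365, 1000.0))
    return cfg


@pytest.fixture
def closed_web():
    """Closed web (no producer, detritus retains everything): detritus-feeding
    pool plus a small age-structured vertebrate, for nitrogen-budget tests."""
    cfg = base_config(years=3, window=1, spawn_day=90)
    make_pool(cfg, "DET", 5.0e5, kind="detritus", guild="detritus", mL=0.0)
    make_pool(cfg, "ZP", 1.0e5, mum=0.05, C=2e-7, E=0.5, mL=0.005, mQ=2e-7)
    make_vert(cfg, "FV", [500.0, 300.0, 150.0], [1.0, 2.0, 3.5], [0.5, 1.0, 1.8],
              mum=[0.004, 0.004, 0.001], C=[5e-6, 5e-6, 5e-6], E=0.6,
              mL=5e-4, mQ_j=1e-6, mQ_a=1e-6, maint=1e-4, maturity=2,
              BHa=2.0, BHb=2.0e3, spawn_fraction=0.2)
    cfg.diet = DietMatrix({"ZP": {"DET": 0.4}, "FV": {"ZP": 0.5}})
    return cfg
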