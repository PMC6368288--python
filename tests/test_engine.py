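"""Dynamics engine: elemental process operations, closed forms, budget and
oracle equivalence against an independently coded naive step."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecosens.engine import (
    SimulationError,
    age_cohorts,
    available_prey,
    grazing,
    grow_and_allocate,
    mortality_step,
    recruit,
    run_simulation,
)

from conftest import base_config, make_pool, make_vert


# ---------------------------------------------------------------------------
# elemental operations

class TestAvailablePrey:
    def test_zero_availability(self):
        assert available_prey(0.0, 1.0, 1.0, 1.0, 500.0) == 0.0

    def test_identity_case(self):
        assert available_prey(1.0, 1.0, 1.0, 1.0, 100.0) == 100.0

    def test_refuge_product(self):
        assert available_prey(0.5, 0.8, 1.0, 1.0, 200.0) == pytest.approx(80.0)

    def test_gape_mask_per_age(self):
        b = np.array([10.0, 20.0, 30.0])
        mask = np.array([1.0, 0.0, 0.0])
        assert available_prey(0.5, 1.0, 1.0, mask, b) == pytest.approx(5.0)


class TestGrazing:
    def test_no_consumption(self):
        assert grazing(10.0, 0.0, 1.0, 1.0, np.array([50.0])).sum() == 0.0

    def test_no_prey(self):
        assert grazing(10.0, 0.1, 1.0, 1.0, np.zeros(3)).sum() == 0.0

    def test_hand_value(self):
        # B=10, C=0.1, B*=50, E=1, mum=1 -> 10*0.1*50 / (1 + 0.1*50/1) = 50/6
        gr = grazing(10.0, 0.1, 1.0, 1.0, np.array([50.0]))
        assert gr[0] == pytest.approx(50.0 / 6.0, rel=1e-12)

    def test_degenerate_mum(self):
        with pytest.raises(SimulationError, match="mum"):
            grazing(10.0, 0.1, 0.0, 1.0, np.array([50.0]))

    @given(C=st.floats(1e-4, 1.0), mum=st.floats(1e-3, 2.0),
           E=st.floats(0.1, 1.0), B=st.floats(0.1, 1e4),
           bstar=st.lists(st.floats(0.0, 1e6), min_size=1, max_size=5),
           scale=st.floats(1.0, 100.0))
    def test_saturation_monotone_and_bounded(self, C, mum, E, B, bstar, scale):
        """Assimilated intake is nondecreasing in prey availability and
        bounded by the maximum growth capacity mum*B."""
        b = np.array(bstar)
        a1 = E * grazing(B, C, mum, E, b).sum()
        a2 = E * grazing(B, C, mum, E, scale * b).sum()
        assert a2 >= a1 - 1e-9 * max(a1, 1.0)
        assert a2 <= mum * B * (1 + 1e-12)


class TestMortality:
    def test_no_mortality(self):
        assert mortality_step(0.0, 0.0, 0.0, 100.0) == 0.0

    def test_linear_pool(self):
        assert mortality_step(0.01, 0.0, 0.0, 100.0, dt=1.0) == pytest.approx(1.0)

    def test_quadratic(self):
        # (mQ * Num) * Num = 1e-4 * 1000 * 1000 = 100 per unit time
        assert mortality_step(0.0, 1e-4, 0.0, 1000.0, dt=1.0) == pytest.approx(100.0)
        assert mortality_step(0.0, 1e-4, 0.0, 1000.0, dt=0.5) == pytest.approx(50.0)

    def test_clipped_to_stock(self):
        assert mortality_step(2.0, 0.0, 0.0, 100.0) == 100.0


class TestRecruit:
    def test_constant_per_adult(self):
        assert recruit("constant_per_adult", mature_count=1000.0,
                       KDENR=0.45) == pytest.approx(450.0)

    def test_beverton_holt_hand_value(self):
        # Sp=100, BHa=2, Biom=150, BHb=50 -> 100*2/200 = 1.0
        assert recruit("beverton_holt", Sp=100.0, Biom=150.0, BHa=2.0,
                       BHb=50.0) == pytest.approx(1.0)

    def test_deterministic_without_noise(self):
        vals = {recruit("beverton_holt", Sp=10.0, Biom=100.0, BHa=3.0, BHb=20.0)
                for _ in range(5)}
        assert len(vals) == 1

    def test_degenerate_denominator(self):
        with pytest.raises(SimulationError, match="denominator"):
            recruit("beverton_holt", Sp=1.0, Biom=0.0, BHa=1.0, BHb=0.0)

    @given(sp=st.floats(0.0, 1e6), k=st.floats(0.1, 10.0),
           biom1=st.floats(1.0, 1e6), biom2=st.floats(1.0, 1e6))
    def test_nonincreasing_in_biomass_linear_in_spawn(self, sp, k, biom1, biom2):
        lo, hi = sorted([biom1, biom2])
        r_lo = recruit("beverton_holt", Sp=sp, Biom=lo, BHa=2.0, BHb=100.0)
        r_hi = recruit("beverton_holt", Sp=sp, Biom=hi, BHa=2.0, BHb=100.0)
        assert r_hi <= r_lo + 1e-12
        r1 = recruit("beverton_holt", Sp=sp, Biom=lo, BHa=2.0, BHb=100.0)
        rk = recruit("beverton_holt", Sp=k * sp, Biom=lo, BHa=2.0, BHb=100.0)
        assert rk == pytest.approx(k * r1, rel=1e-9, abs=1e-12)


class TestGrowAndAllocate:
    def test_starvation_direction(self):
        ws, wr, spent = grow_and_allocate(0.0, 0.01, 0.1, 0.5, 2.0, 1.0)
        assert ws == 2.0
        assert wr < 1.0

    def test_cap_binds(self):
        mum = 0.05
        ws, wr, spent = grow_and_allocate(2 * mum, 0.0, mum, 0.5, 2.0, 1.0)
        assert (ws - 2.0) + (wr - 1.0) == pytest.approx(mum)
        assert spent == pytest.approx(mum)  # surplus above the cap

    def test_split_fraction(self):
        ws, wr, _ = grow_and_allocate(0.04, 0.0, 0.1, 0.75, 2.0, 1.0)
        assert ws - 2.0 == pytest.approx(0.03)
        assert wr - 1.0 == pytest.approx(0.01)


class TestAgeCohorts:
    def test_shift_and_merge(self):
        num, ws, wr = age_cohorts([10.0, 20.0, 30.0], [1.0, 2.0, 3.0],
                                  [0.5, 1.0, 1.5])
        assert num.tolist() == [0.0, 10.0, 50.0]

    def test_all_zero(self):
        num, ws, wr = age_cohorts([0.0, 0.0], [1.0, 2.0], [0.5, 1.0])
        assert num.tolist() == [0.0, 0.0]

    def test_plus_group_weighted_mean(self):
        num, ws, wr = age_cohorts([0.0, 30.0, 10.0], [0.0, 2.0, 4.0],
                                  [0.0, 1.0, 2.0])
        # merged weight = (10*4 + 30*2)/40 = 2.5 ; reserve (10*2 + 30*1)/40
        assert ws[-1] == pytest.approx(2.5)
        assert wr[-1] == pytest.approx(1.25)


# ---------------------------------------------------------------------------
# full simulation properties

def test_zero_years_returns_initial_state(minimal_web):
    minimal_web.settings.years_total = 0
    minimal_web.settings.averaging_window_years = 0
    traj = run_simulation(minimal_web)
    assert traj.biomass.shape[0] == 1
    assert traj.component_biomass("ZP")[0] == pytest.approx(100.0)


def test_determinism_same_seed(closed_web):
    closed_web.component("FV").recruitment_lognormal_sigma = 0.3
    t1 = run_simulation(closed_web, seed=5)
    t2 = run_simulation(closed_web, seed=5)
    assert np.array_equal(t1.biomass, t2.biomass)
    t3 = run_simulation(closed_web, seed=6)
    assert not np.array_equal(t1.biomass, t3.biomass)


def test_linear_pool_decay_closed_form():
    """With mQ = 0 and grazing off, a pool follows B_n = B0 (1 - mL dt)^n."""
    cfg = base_config(years=1)
    make_pool(cfg, "ZP", 100.0, mL=0.01)
    traj = run_simulation(cfg)
    n = np.arange(traj.days.size)
    expected = 100.0 * (1.0 - 0.01) ** n
    np.testing.assert_allclose(traj.component_biomass("ZP"), expected, rtol=1e-12)


def test_no_prey_overdrawn_random_webs():
    """No prey loses more than its standing biomass in one step."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        cfg = base_config(years=1)
        make_pool(cfg, "DET", 1e4, kind="detritus", guild="detritus")
        make_pool(cfg, "A", rng.uniform(10, 1e3), mum=rng.uniform(0.1, 2),
                  C=rng.uniform(1e-4, 1e-1), E=rng.uniform(0.3, 1.0), mL=0.01)
        make_pool(cfg, "B", rng.uniform(10, 1e3), mum=rng.uniform(0.1, 2),
                  C=rng.uniform(1e-4, 1e-1), E=rng.uniform(0.3, 1.0), mL=0.01)
        cfg.diet.p = {"A": {"B": rng.uniform(0.5, 1.0)},
                      "B": {"A": rng.uniform(0.5, 1.0), "DET": 0.5}}
        traj = run_simulation(cfg)
        assert (traj.biomass >= 0).all()


def test_mass_conservation_closed_web(closed_web):
    """Total nitrogen in a closed web is conserved to <= 1e-9 relative per
    step over 1000 daily steps (spanning recruitment and aging events)."""
    traj = run_simulation(closed_web)
    total = traj.biomass.sum(axis=1)[:1001]
    steps = np.abs(np.diff(total)) / total[:-1]
    assert steps.max() <= 1e-9


# ---------------------------------------------------------------------------
# oracle equivalence: independently coded naive recomputation

def _naive_steps(cfg, n_steps):
    """Pure-python re-implementation of the daily forward map."""
    ids = [c.id for c in cfg.components]
    comp = {c.id: c for c in cfg.components}
    P = cfg.params
    split = {cid: P[cid].growth_split_structural for cid in ids}

    B = {}
    Num, Ws, Wr = {}, {}, {}
    for c in cfg.components:
        if c.kind == "vertebrate":
            st_ = cfg.initial.vertebrates[c.id]
            Num[c.id] = [float(x) for x in st_["numbers"]]
            Ws[c.id] = [float(x) for x in st_["w_struct"]]
            Wr[c.id] = [float(x) for x in st_["w_reserve"]]
        else:
            B[c.id] = float(cfg.initial.pools[c.id])
    prod = cfg.forcing.producer_id or None
    det = next((c.id for c in cfg.components if c.kind == "detritus"), None)

    def comp_biomass(cid):
        if comp[cid].kind == "vertebrate":
            return sum(n * (a + b) for n, a, b in zip(Num[cid], Ws[cid], Wr[cid]))
        return B[cid]

    def cohorts(cid):
        c = comp[cid]
        if c.kind == "vertebrate":
            return [(cid, a) for a in range(c.n_age_classes)]
        return [(cid, 0)]

    all_coh = [ch for cid in ids for ch in cohorts(cid)]

    def coh_biomass(ch):
        cid, a = ch
        if comp[cid].kind == "vertebrate":
            return Num[cid][a] * (Ws[cid][a] + Wr[cid][a])
        return B[cid]

    def avail(pred, prey_ch):
        prey, a = prey_ch
        p = cfg.diet.get(pred, prey)
        if p == 0.0:
            return 0.0
        size = cfg.refuge.get_size(pred, prey, comp[prey].n_age_classes)
        return (p * cfg.refuge.get_overlap(pred, prey)
                * cfg.refuge.get_habitat(pred, prey) * float(size[a]))

    out = [[comp_biomass(cid) for cid in ids]]
    for t in range(n_steps):
        doy = t % 365
        if prod:
            B[prod] = float(cfg.forcing.cycle[doy])

        # grazing fluxes per predator cohort
        Gr = {}
        for ch in all_coh:
            cid, a = ch
            p = P[cid]
            C = float(np.asarray(p.C)[a])
            if C == 0.0:
                continue
            bio = coh_biomass(ch)
            if comp[cid].kind == "vertebrate":
                wt = Ws[cid][a] + Wr[cid][a]
                mum_rate = ((float(np.asarray(p.mum)[a]) + p.maintenance_rate * wt)
                            / wt if wt > 0 else 0.0)
            else:
                mum_rate = float(np.asarray(p.mum)[a])
            bstars = {q: avail(cid, q) * coh_biomass(q) for q in all_coh}
            S = sum(bstars.values())
            denom = 1.0 + (C * p.E * S / mum_rate if mum_rate > 0 else 0.0)
            Gr[ch] = {q: bio * C * v / denom for q, v in bstars.items()}

        loss = {q: sum(g.get(q, 0.0) for g in Gr.values()) for q in all_coh}
        for q in all_coh:
            bq = coh_biomass(q)
            if loss[q] > bq:
                f = bq / loss[q]
                for g in Gr.values():
                    if q in g:
                        g[q] *= f
                loss[q] = sum(g.get(q, 0.0) for g in Gr.values())

        det_in = 0.0
        intake = {ch: sum(Gr.get(ch, {}).values()) for ch in all_coh}
        assim = {ch: P[ch[0]].E * intake[ch] for ch in all_coh}
        det_in += sum(intake[ch] - assim[ch] for ch in all_coh)

        # growth allocation
        for ch in all_coh:
            cid, a = ch
            p = P[cid]
            if comp[cid].kind == "vertebrate":
                n = Num[cid][a]
                if n <= 0:
                    det_in += assim[ch]
                    continue
                a_i = assim[ch] / n
                wt = Ws[cid][a] + Wr[cid][a]
                expense = p.maintenance_rate * wt
                mum = float(np.asarray(p.mum)[a])
                if a_i >= expense:
                    surplus = a_i - expense
                    gain = min(surplus, mum)
                    Ws[cid][a] += split[cid] * gain
                    Wr[cid][a] += (1 - split[cid]) * gain
                    det_in += (expense + surplus - gain) * n
                else:
                    deficit = expense - a_i
                    take = min(deficit, max(Wr[cid][a] - 1e-12, 0.0))
                    Wr[cid][a] -= take
                    det_in += (a_i + take) * n
            else:
                mum = float(np.asarray(p.mum)[a])
                gain = min(assim[ch], mum * B[cid])
                B[cid] += gain
                det_in += assim[ch] - gain

        # grazing losses
        for q in all_coh:
            cid, a = q
            if comp[cid].kind == "vertebrate":
                wt = Ws[cid][a] + Wr[cid][a]
                if wt > 0:
                    Num[cid][a] = max(Num[cid][a] - loss[q] / wt, 0.0)
            else:
                B[cid] = max(B[cid] - loss[q], 0.0)

        # mortality
        for ch in all_coh:
            cid, a = ch
            p = P[cid]
            if comp[cid].kind == "vertebrate":
                mq = p.mQ_juvenile if (a + 1) < p.maturity_age else p.mQ_adult
                mst = (p.mSt_rate
                       if Wr[cid][a] < p.mSt_threshold * Ws[cid][a] else 0.0)
                rate = min((p.mL + mq * Num[cid][a] + mst), 1.0)
                dn = Num[cid][a] * rate
                Num[cid][a] -= dn
                det_in += dn * (Ws[cid][a] + Wr[cid][a])
            else:
                rate = min(p.mL + p.mQ_adult * B[cid], 1.0)
                dB = B[cid] * rate
                B[cid] -= dB
                if cid != det and cid != prod:
                    det_in += dB

        if det is not None:
            B[det] += det_in
        out.append([comp_biomass(cid) for cid in ids])
    return np.asarray(out)


def _oracle_web():
    cfg = base_config(years=1, spawn_day=200)
    make_pool(cfg, "PP", 1000.0, kind="producer", guild="phytoplankton")
    make_pool(cfg, "ZP", 200.0, mum=0.2, C=2e-3, E=0.5, mL=0.01, mQ=1e-5)
    make_vert(cfg, "FV", [50.0, 20.0], [1.0, 2.0], [0.6, 1.1],
              mum=[0.004, 0.002], C=[1e-4, 8e-5], E=0.6, mL=1e-4,
              mQ_j=1e-6, mQ_a=2e-6, maint=2e-4, BHa=1.0, BHb=100.0)
    cfg.diet.p = {"ZP": {"PP": 0.6}, "FV": {"ZP": 0.5}}
    from ecosens.config import Forcing
    cycle = 1000.0 * (1.0 + 0.3 * np.sin(np.arange(365) / 58.0))
    cfg.forcing = Forcing(producer_id="PP", cycle=cycle)
    return cfg


def test_engine_matches_naive_recomputation():
    """The vectorized engine equals an independently coded naive per-cohort
    recomputation over 5 daily steps, to 1e-12 relative."""
    cfg = _oracle_web()
    expected = _naive_steps(cfg, 5)
    traj = run_simulation(cfg)
    np.testing.assert_allclose(traj.biomass[:6], expected, rtol=1e-12, atol=1e-9)


def test_engine_matches_naive_two_steps_three_components():
    cfg = _oracle_web()
    expected = _naive_steps(cfg, 2)
    traj = run_simulation(cfg)
    np.testing.assert_allclose(traj.biomass[:3], expected, rtol=1e-12, atol=1e-9)
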