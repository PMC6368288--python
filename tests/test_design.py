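"""Perturbation design: OAT enumeration, extremes, pairing, edit application."""

import numpy as np
import pytest

from ecosens.design import (
    DesignError,
    ParameterRef,
    RunSpec,
    apply_edits,
    build_manifest,
    default_extremes,
    enumerate_extremes,
    enumerate_oat,
    load_manifest,
    pair_combinations,
    save_manifest,
)

from conftest import base_config, make_pool, make_vert


@pytest.fixture
def one_pool_web():
    cfg = base_config()
    make_pool(cfg, "ZP", 100.0, mum=0.1, key=True)
    return cfg


class TestEnumerateOAT:
    def test_reference_count(self, fixture_web):
        """5 vertebrates x 4 families x 2 + 4 pools x 3 families x 2 = 64."""
        runs = enumerate_oat(fixture_web)
        assert len(runs) == 64

    def test_single_pool(self, one_pool_web):
        assert len(enumerate_oat(one_pool_web)) == 6

    def test_no_key_species(self, one_pool_web):
        assert enumerate_oat(one_pool_web, key_species=[]) == []

    def test_unknown_species(self, one_pool_web):
        with pytest.raises(DesignError, match="XX"):
            enumerate_oat(one_pool_web, key_species=["XX"])

    def test_single_edit_property(self, fixture_web):
        for r in enumerate_oat(fixture_web):
            assert len(r.edits) == 1
            assert r.provenance == "oat"

    def test_pools_have_no_recruitment_runs(self, fixture_web):
        for r in enumerate_oat(fixture_web):
            ref = r.edits[0][0]
            if ref.parameter == "recruitment":
                assert fixture_web.component(ref.component).kind == "vertebrate"


class TestExtremes:
    def test_default_set(self):
        runs = enumerate_extremes()
        assert len(runs) == 4
        mults = sorted(m for r in runs for _, m in r.edits)
        assert mults == pytest.approx([0.10, 0.61, 1.70, 3.30])

    def test_herring_recruitment_multiplier(self):
        # a +230% change is the multiplier 3.30 on the recruitment slope
        ref, mult = default_extremes()[0]
        assert ref.parameter == "recruitment"
        assert mult == pytest.approx(3.30)

    def test_empty_spec(self):
        assert enumerate_extremes([]) == []

    def test_nonpositive_multiplier(self):
        with pytest.raises(DesignError):
            enumerate_extremes([(ParameterRef("SSH", "mum"), 0.0)])


class TestApplyEdits:
    def test_mum_vector_elementwise(self):
        cfg = base_config()
        make_vert(cfg, "FV", [10.0, 5.0], [1.0, 2.0], [0.5, 1.0],
                  mum=[1.2, 1.8], BHa=1.0, BHb=10.0)
        rs = RunSpec("r1", "x", [(ParameterRef("FV", "mum"), 1.25)], "oat")
        out = apply_edits(cfg, rs)
        np.testing.assert_allclose(out.params["FV"].mum, [1.5, 2.25])
        np.testing.assert_allclose(cfg.params["FV"].mum, [1.2, 1.8])  # untouched

    def test_identity_multiplier(self, fixture_web):
        rs = RunSpec("r1", "x", [(ParameterRef("ZS", "mum"), 1.0)], "oat")
        assert apply_edits(fixture_web, rs) == fixture_web

    def test_mortality_scales_both_coefficients(self):
        cfg = base_config()
        make_vert(cfg, "FV", [10.0, 5.0], [1.0, 2.0], [0.5, 1.0],
                  mQ_j=2e-6, mQ_a=4e-6, BHa=1.0, BHb=10.0)
        rs = RunSpec("r1", "x", [(ParameterRef("FV", "mQ"), 1.25)], "oat")
        out = apply_edits(cfg, rs)
        assert out.params["FV"].mQ_juvenile == pytest.approx(2.5e-6)
        assert out.params["FV"].mQ_adult == pytest.approx(5e-6)

    def test_recruitment_resolves_by_mode(self, fixture_web):
        rs = RunSpec("r1", "x", [(ParameterRef("MWH", "recruitment"), 0.75)], "oat")
        out = apply_edits(fixture_web, rs)
        assert out.params["MWH"].KDENR == pytest.approx(
            0.75 * fixture_web.params["MWH"].KDENR)
        rs = RunSpec("r2", "x", [(ParameterRef("CAP", "recruitment"), 1.25)], "oat")
        out = apply_edits(fixture_web, rs)
        assert out.params["CAP"].BHa == pytest.approx(
            1.25 * fixture_web.params["CAP"].BHa)

    def test_recruitment_on_pool_rejected(self, fixture_web):
        rs = RunSpec("r1", "x", [(ParameterRef("ZS", "recruitment"), 0.75)],
                     "extreme")
        with pytest.raises(DesignError, match="pool"):
            apply_edits(fixture_web, rs)

    def test_unknown_component(self, fixture_web):
        rs = RunSpec("r1", "x", [(ParameterRef("XX", "mum"), 0.75)], "oat")
        with pytest.raises(DesignError, match="XX"):
            apply_edits(fixture_web, rs)


class TestManifest:
    def test_reference_counts(self, fixture_web):
        m = build_manifest(fixture_web)
        assert len(m) == 105
        assert len(m.by_provenance("control")) == 1
        assert len(m.by_provenance("oat")) == 64
        assert len(m.by_provenance("extreme")) == 4
        assert len(m.by_provenance("combination")) == 36

    def test_combination_edits_are_parent_union(self, fixture_web):
        m = build_manifest(fixture_web)
        for r in m.by_provenance("combination"):
            union = []
            for pid in r.parents:
                union.extend(m.get(pid).edits)
            assert set(r.edits) == set(union)

    def test_key_species_pairing_includes_triple_edit_run(self, fixture_web):
        m = build_manifest(fixture_web)
        combos = m.by_provenance("combination")
        n_edits = sorted(len(r.edits) for r in combos)
        assert n_edits.count(3) == 1  # one run pairs an OAT with a combination
        assert n_edits.count(2) == 35

    def test_determinism(self, fixture_web):
        m1 = build_manifest(fixture_web)
        m2 = build_manifest(fixture_web)
        assert [r.run_id for r in m1] == [r.run_id for r in m2]
        assert [r.edits for r in m1] == [r.edits for r in m2]

    def test_round_trip(self, tmp_path, fixture_web):
        m = build_manifest(fixture_web)
        save_manifest(m, tmp_path / "m.csv")
        back = load_manifest(tmp_path / "m.csv")
        assert [r.run_id for r in back] == [r.run_id for r in m]
        assert [r.edits for r in back] == [r.edits for r in m]
        assert [r.parents for r in back] == [r.parents for r in m]


class TestPairCombinations:
    def _oat(self, i, comp, fam, mult):
        return RunSpec(f"run{i:02d}", "x", [(ParameterRef(comp, fam), mult)], "oat")

    def test_high_low_selection_rule(self):
        runs = [self._oat(1, "A", "mum", 1.25), self._oat(2, "B", "mum", 0.75),
                self._oat(3, "A", "C", 1.25), self._oat(4, "B", "C", 0.75)]
        impacts = {"run01": 2.5, "run02": 1.0, "run03": 1.8, "run04": 1.2}
        combos = pair_combinations(runs, impacts, families=("mum", "C"))
        # 4 selected runs -> C(4,2) = 6 pairs
        assert len(combos) == 6
        assert combos[0].parents == ["run01", "run02"]

    def test_conflicting_parents_dropped(self):
        runs = [self._oat(1, "A", "mum", 1.25), self._oat(2, "A", "mum", 0.75)]
        impacts = {"run01": 2.0, "run02": 1.0}
        combos = pair_combinations(runs, impacts, families=("mum",))
        assert combos == []  # the only pair shares component A's mum

    def test_tie_break_lowest_run_id(self):
        runs = [self._oat(1, "A", "mum", 1.25), self._oat(2, "B", "mum", 0.75),
                self._oat(3, "C", "C", 1.25)]
        impacts = {"run01": 1.5, "run02": 1.5, "run03": 1.0}
        combos = pair_combinations(runs, impacts, families=("mum", "C"))
        parents = {p for r in combos for p in r.parents}
        # tied high/low both resolve to the lowest run id; run02 is not picked
        assert parents == {"run01", "run03"}

    def test_combination_conflict_error(self):
        a = self._oat(1, "A", "mum", 1.25)
        b = self._oat(2, "A", "mum", 0.75)
        from ecosens.design import _union_edits
        with pytest.raises(DesignError, match="conflicting"):
            _union_edits(a, b)
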