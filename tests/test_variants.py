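"""Variant representation, scaling laws, combination and downscaling search."""

import numpy as np
import pytest

from assrnet.cells import StepProtocol, build_l5pc, extract_features
from assrnet.channels import IDENTITY_MODIFIER, KineticModifier
from assrnet.variants import (
    FeatureBands,
    ParamDelta,
    VariantSpec,
    VariantTableError,
    VariantUnusableError,
    apply_variant,
    combine_variants,
    downscale,
    features_within,
    get_variant,
    load_bundled_variants,
    load_variant_table,
    save_variant_table,
    scale_variant,
    synthesize_variant_library,
)


@pytest.fixture(scope="module")
def library():
    return load_bundled_variants()


def _variant(deltas, vid="test", chan="CaHVA", gene="CACNA1C"):
    return VariantSpec(id=vid, gene=gene, target_channel=chan,
                       deltas=tuple(ParamDelta(*d) for d in deltas))


class TestScaling:
    def test_full_effect_at_c_one(self):
        v = _variant([("m", "dv_shift", -6.0), ("-", "g_factor", 1.4)])
        sv = scale_variant(v, 1.0)
        mods = sv.effective_modifiers["CaHVA"]
        assert mods["m"].dv_shift == pytest.approx(-6.0)
        assert mods["-"].g_factor == pytest.approx(1.4)

    def test_linear_for_shifts_log_for_factors(self):
        v = _variant([("m", "dv_shift", -6.0), ("m", "tau_factor", 4.0)])
        sv = scale_variant(v, 0.5)
        mod = sv.effective_modifiers["CaHVA"]["m"]
        assert mod.dv_shift == pytest.approx(-3.0)
        assert mod.tau_factor == pytest.approx(2.0)  # 4^0.5

    def test_c_outside_unit_interval_rejected(self):
        v = _variant([("m", "dv_shift", -6.0)])
        for c in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                scale_variant(v, c)

    def test_continuity_toward_identity(self):
        v = _variant([("m", "dv_shift", -8.0), ("m", "slope_factor", 1.5)])
        mod = scale_variant(v, 1e-6).effective_modifiers["CaHVA"]["m"]
        assert abs(mod.dv_shift) < 1e-5
        assert mod.slope_factor == pytest.approx(1.0, abs=1e-5)


class TestCombination:
    def test_identity_neutral_element(self):
        v = scale_variant(_variant([("m", "dv_shift", -6.0)]), 1.0)
        ident = scale_variant(
            _variant([("m", "dv_shift", 0.0)], vid="id", chan="Ih", gene="HCN1"), 1.0)
        comb = combine_variants([v, ident])
        assert comb.effective_modifiers["CaHVA"]["m"].dv_shift == pytest.approx(-6.0)
        assert comb.effective_modifiers["Ih"]["m"].dv_shift == 0.0

    def test_self_combination_doubles_and_squares(self):
        v = scale_variant(
            _variant([("m", "dv_shift", -5.0), ("m", "tau_factor", 1.5)]), 1.0)
        comb = combine_variants([v, v])
        mod = comb.effective_modifiers["CaHVA"]["m"]
        assert mod.dv_shift == pytest.approx(-10.0)
        assert mod.tau_factor == pytest.approx(2.25)

    def test_commutative_and_associative(self, library):
        a = scale_variant(get_variant(library, "Ca7"), 0.5)
        b = scale_variant(get_variant(library, "HCN1-2"), 0.5)
        c = scale_variant(get_variant(library, "Ca74"), 0.5)
        ab_c = combine_variants([combine_variants([a, b]), c])
        a_bc = combine_variants([a, combine_variants([b, c])])
        ba_c = combine_variants([combine_variants([b, a]), c])
        for comb in (a_bc, ba_c):
            for chan in ab_c.effective_modifiers:
                for gate, mod in ab_c.effective_modifiers[chan].items():
                    other = comb.effective_modifiers[chan][gate]
                    assert mod.dv_shift == pytest.approx(other.dv_shift)
                    assert mod.slope_factor == pytest.approx(other.slope_factor)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_variants([])

    def test_paper_style_cascade_merges_same_gene(self, library):
        # combinations built up one variant at a time: Ih deltas of the two
        # HCN variants superpose (shifts add, slope factors multiply)
        ca7 = scale_variant(get_variant(library, "Ca7"), 1.0)
        hcn2 = scale_variant(get_variant(library, "HCN1-2"), 1.0)
        ca74 = scale_variant(get_variant(library, "Ca74"), 1.0)
        hcn1 = scale_variant(get_variant(library, "HCN1-1"), 1.0)
        comb1 = combine_variants([ca7, hcn2])
        comb2 = combine_variants([comb1, ca74])
        comb3 = combine_variants([comb2, hcn1])
        ih = comb3.effective_modifiers["Ih"]["m"]
        assert ih.dv_shift == pytest.approx(
            hcn2.effective_modifiers["Ih"]["m"].dv_shift
            + hcn1.effective_modifiers["Ih"]["m"].dv_shift)
        assert ih.slope_factor == pytest.approx(
            hcn2.effective_modifiers["Ih"]["m"].slope_factor
            * hcn1.effective_modifiers["Ih"]["m"].slope_factor)
        assert set(comb3.effective_modifiers) == {"CaHVA", "CaLVA", "Ih"}


class TestApply:
    def test_original_cell_untouched(self, l5pc, library):
        sv = scale_variant(get_variant(library, "Ca7"), 1.0)
        modified = apply_variant(l5pc, sv)
        for comp in l5pc.compartments:
            for ch in comp.channels:
                assert ch.modifier == IDENTITY_MODIFIER
                assert ch.gate_modifiers == ()
        assert modified is not l5pc

    def test_absent_channel_rejected(self, basket, library):
        sv = scale_variant(get_variant(library, "Ca7"), 1.0)
        with pytest.raises(ValueError, match="absent"):
            apply_variant(basket, sv)

    def test_inverse_application_restores_kinetics(self, l5pc):
        v = _variant([("m", "dv_shift", -6.0), ("m", "slope_factor", 1.5)])
        inv = _variant([("m", "dv_shift", 6.0), ("m", "slope_factor", 1 / 1.5)])
        cell = apply_variant(apply_variant(l5pc, scale_variant(v, 1.0)),
                             scale_variant(inv, 1.0))
        for comp in cell.compartments:
            for ch in comp.channels:
                if ch.name == "CaHVA":
                    eff = ch.gate_modifier("m")
                    assert eff.dv_shift == pytest.approx(0.0)
                    assert eff.slope_factor == pytest.approx(1.0)

    def test_variant_changes_cell_features(self, l5pc, library):
        proto = StepProtocol(dt_ms=0.05)
        control = extract_features(l5pc, proto)
        sv = scale_variant(get_variant(library, "Ca7"), 1.0)
        fv = extract_features(apply_variant(l5pc, sv), proto)
        assert fv.spike_counts != control.spike_counts


class TestDownscale:
    def test_identity_variant_keeps_c_one(self, l5pc):
        v = _variant([("m", "dv_shift", 0.0)])
        sv = downscale(v, l5pc, evaluate=lambda c: True)
        assert sv.coefficient == 1.0

    def test_bisection_matches_grid_scan_on_known_boundary(self, l5pc):
        # constructed criterion passing iff c <= 0.25; oracle = grid scan
        v = _variant([("m", "dv_shift", -10.0)])
        sv = downscale(v, l5pc, evaluate=lambda c: c <= 0.25)
        grid = np.arange(1e-3, 1.0 + 1e-9, 1e-3)
        oracle = grid[[c <= 0.25 for c in grid]].max()
        assert abs(sv.coefficient - oracle) <= 1e-3

    def test_bisection_matches_grid_for_every_bundled_variant(self, library):
        # deterministic analytic criterion: total scaled effect magnitude
        # below a fixed budget; per-variant boundary recovered to 1e-3
        cell = build_l5pc()
        grid = np.arange(1e-3, 1.0 + 1e-9, 1e-3)
        for v in library:
            def size(c, v=v):
                s = 0.0
                for d in v.deltas:
                    val = d.scaled(c)
                    s += abs(val) if d.param_class == "dv_shift" else abs(np.log(val)) * 10
                return s

            thresh = max(size(1e-3), min(size(1.0), 2.0))
            passes = lambda c, v=v, t=thresh: size(c, v) <= t + 1e-12
            sv = downscale(v, cell, evaluate=passes)
            mask = np.array([passes(c) for c in grid])
            oracle = grid[mask].max() if mask.any() else np.nan
            assert abs(sv.coefficient - oracle) <= 2e-3, v.id

    def test_non_monotone_boundary_found(self, l5pc):
        # passes on [0, 0.3] and on a high island [0.7, 0.8] that covers a
        # coarse scan point; the descending scan must find the island first
        v = _variant([("m", "dv_shift", -10.0)])
        sv = downscale(v, l5pc,
                       evaluate=lambda c: c <= 0.3 or 0.7 <= c <= 0.8)
        assert 0.69 <= sv.coefficient <= 0.81

    def test_hopeless_variant_flagged_unusable(self, l5pc):
        v = _variant([("m", "dv_shift", -10.0)])
        with pytest.raises(VariantUnusableError):
            downscale(v, l5pc, evaluate=lambda c: False)

    def test_simulation_backed_downscale_restores_features(self, l5pc, library):
        bands = FeatureBands(protocol=StepProtocol(dt_ms=0.05))
        ca7 = get_variant(library, "Ca7")
        sv = downscale(ca7, l5pc, criteria=bands)
        assert 0.0 < sv.coefficient < 1.0
        control = extract_features(l5pc, bands.protocol)
        fv = extract_features(apply_variant(l5pc, sv), bands.protocol)
        assert features_within(fv, control, bands)
        # full effect must violate the bands, else downscaling was a no-op
        full = extract_features(apply_variant(l5pc, scale_variant(ca7, 1.0)),
                                bands.protocol)
        assert not features_within(full, control, bands)


class TestVariantTable:
    def test_bundled_library_shape(self, library):
        assert len(library) == 86
        classes = {d.param_class for v in library for d in v.deltas}
        assert classes == {"dv_shift", "slope_factor", "tau_factor", "g_factor"}
        for vid in ("Ca7", "Ca74", "HCN1-1", "HCN1-2"):
            get_variant(library, vid)

    def test_hcn1_2_shape_matches_description(self, library):
        # negative offset shift and increased slope of the Ih activation gate
        hcn2 = get_variant(library, "HCN1-2")
        assert hcn2.target_channel == "Ih"
        mod = scale_variant(hcn2, 1.0).effective_modifiers["Ih"]["m"]
        assert mod.dv_shift < 0
        assert mod.slope_factor > 1

    def test_generator_is_deterministic(self):
        a = synthesize_variant_library(seed=7)
        b = synthesize_variant_library(seed=7)
        assert [v.id for v in a] == [v.id for v in b]
        assert all(va.deltas == vb.deltas for va, vb in zip(a, b))

    def test_roundtrip_through_tsv(self, tmp_path, library):
        path = tmp_path / "v.tsv"
        save_variant_table(library[:10], path)
        back = load_variant_table(path)
        assert [v.id for v in back] == [v.id for v in library[:10]]

    def test_negative_factor_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "id\tgene\tchannel\tgate\tparam_class\tvalue\tprovenance\n"
            "X1\tCACNA1C\tCaHVA\t-\tg_factor\t-0.5\t\n"
        )
        with pytest.raises(VariantTableError, match="bad.tsv:2"):
            load_variant_table(path)

    def test_unknown_gene_rejected(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        path.write_text(
            "id\tgene\tchannel\tgate\tparam_class\tvalue\tprovenance\n"
            "X1\tMYGENE\tCaHVA\tm\tdv_shift\t-5\t\n"
        )
        with pytest.raises(VariantTableError):
            load_variant_table(path)

    def test_duplicate_rows_same_id_must_agree_on_channel(self, tmp_path):
        path = tmp_path / "bad3.tsv"
        path.write_text(
            "id\tgene\tchannel\tgate\tparam_class\tvalue\tprovenance\n"
            "X1\tCACNA1C\tCaHVA\tm\tdv_shift\t-5\t\n"
            "X1\tCACNA1C\tCaLVA\tm\tdv_shift\t-3\t\n"
        )
        with pytest.raises(VariantTableError, match="inconsistent"):
            load_variant_table(path)

    def test_both_hcn1_spellings_accepted(self):
        _variant([("m", "dv_shift", -5.0)], chan="Ih", gene="HCN1A")
        _variant([("m", "dv_shift", -5.0)], chan="Ih", gene="HCN1")
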