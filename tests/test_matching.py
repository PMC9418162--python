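"""Density reduction, filling-ratio solving, residual delta-HU tables, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctphantom.exceptions import (
    InfeasibleTargetError,
    InsufficientMaterialDataError,
    InvalidInputError,
    MissingGridPointError,
)
from ctphantom.fixtures import load_fill_plan_reference, load_material_library
from ctphantom.matching import (
    FillPlan,
    MaterialRecord,
    correct_contrast,
    delta_table,
    filling_ratio_for_target,
    material_hu_at,
    rank_materials,
    read_material_library_csv,
    reduced_density_hu,
)
from ctphantom.models import TissueClass, TissueTarget

KV_GRID = (70.0, 80.0, 100.0, 120.0, 140.0)


class TestReducedDensity:
    def test_dense_bone_surrogate_value(self):
        assert reduced_density_hu(1063.0, 0.969462) == pytest.approx(1000.0, abs=1e-3)

    def test_full_density_is_identity(self):
        for h in (-800.0, 0.0, 1063.0):
            assert reduced_density_hu(h, 1.0) == h

    def test_half_density_of_plus_1000(self):
        assert reduced_density_hu(1000.0, 0.5) == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            reduced_density_hu(500.0, 0.0)
        with pytest.raises(InvalidInputError):
            reduced_density_hu(-1000.0, 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(h=st.floats(-999.0, 3000.0), f=st.floats(1e-3, 1.0))
    def test_ratio_roundtrip_is_exact(self, h, f):
        assert filling_ratio_for_target(h, reduced_density_hu(h, f)) == pytest.approx(
            f, abs=1e-12)

    def test_monotone_in_fill(self):
        fs = np.linspace(0.1, 1.0, 50)
        hus = [reduced_density_hu(537.0, f) for f in fs]
        assert np.all(np.diff(hus) > 0)


class TestFillingRatio:
    @pytest.mark.parametrize("material_hu, target_hu, percent", [
        (1063.0, 350.0, 65.4),
        (1063.0, 500.0, 72.7),
        (1063.0, 1000.0, 96.9),
        (537.0, 350.0, 87.8),
        (537.0, 500.0, 97.6),
        (-42.0, -80.0, 96.0),
    ])
    def test_published_ratios_at_one_decimal(self, material_hu, target_hu, percent):
        f = filling_ratio_for_target(material_hu, target_hu)
        assert round(100 * f, 1) == percent

    def test_self_target_is_unity(self):
        assert filling_ratio_for_target(537.0, 537.0) == 1.0

    def test_infeasible_target_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            filling_ratio_for_target(996.0, 1000.0)


class TestDeltaTable:
    def plan_for(self, bone_model, adipose_model, library, material, target_hu, tissue):
        mat = library[material]
        model = bone_model if tissue is TissueClass.BONE else adipose_model
        target = TissueTarget(tissue, target_hu)
        f = filling_ratio_for_target(mat.hu_ref, target_hu)
        return delta_table(mat, f, model, target, KV_GRID)

    def test_zero_mismatch_at_reference_by_construction(
            self, bone_model, adipose_model, material_library):
        plan = self.plan_for(bone_model, adipose_model, material_library,
                             "PLA/stone", 1000.0, TissueClass.BONE)
        assert plan.delta_hu[120.0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("material, target_hu, tissue", [
        ("PLA/stone", 350.0, TissueClass.BONE),
        ("PLA/stone", 500.0, TissueClass.BONE),
        ("PLA/stone", 1000.0, TissueClass.BONE),
        ("PLA/chalk", 350.0, TissueClass.BONE),
        ("PLA/chalk", 500.0, TissueClass.BONE),
        ("HIPS", -80.0, TissueClass.ADIPOSE),
    ])
    def test_residual_tables_match_published_rows(
            self, bone_model, adipose_model, material_library, material, target_hu, tissue):
        """Every published residual delta-HU entry reproduced within +-5 HU
        (the published ratios and offsets are rounded)."""
        plan = self.plan_for(bone_model, adipose_model, material_library,
                             material, target_hu, tissue)
        ref = load_fill_plan_reference()
        row = ref[(ref.material == material) & (ref.target_hu == target_hu)].iloc[0]
        assert round(100 * plan.filling_ratio, 1) == row.filling_percent
        for kv in (70, 80, 100, 140):
            assert plan.delta_hu[float(kv)] == pytest.approx(row[f"delta_{kv}"], abs=5.0)

    def test_missing_per_kv_data_raises(self, bone_model):
        mat = MaterialRecord("PP", "filament", -140.0, delta_to_tissue=None)
        target = TissueTarget(TissueClass.BONE, 350.0)
        with pytest.raises(InsufficientMaterialDataError):
            delta_table(mat, 0.9, bone_model, target, KV_GRID)

    def test_material_reconstruction_inverts_offset_definition(
            self, bone_model, material_library):
        """Full-density material HU at kV = tissue prediction at its own
        reference HU plus the tabulated offset."""
        mat = material_library["PLA/stone"]
        got = material_hu_at(mat, 70.0, bone_model)
        assert got == pytest.approx(bone_model.k(70.0) * 1063.0 + 12.0, abs=1e-9)
        assert material_hu_at(mat, 120.0, bone_model) == 1063.0


class TestRanking:
    def test_soft_bone_prefers_chalk_filled_filament(
            self, bone_model, material_library):
        mats = [material_library["PLA/stone"], material_library["PLA/chalk"]]
        ranked = rank_materials(mats, bone_model, TissueTarget(TissueClass.BONE, 350.0),
                                KV_GRID)
        assert [m.name for m, _, _ in ranked] == ["PLA/chalk", "PLA/stone"]
        assert ranked[0][2] < 10 < ranked[1][2]

    def test_dense_bone_excludes_less_attenuating_vinyl(
            self, bone_model, material_library):
        mats = [material_library["Vinyl"], material_library["PLA/stone"]]
        ranked = rank_materials(mats, bone_model, TissueTarget(TissueClass.BONE, 1000.0),
                                KV_GRID)
        assert [m.name for m, _, _ in ranked] == ["PLA/stone"]

    def test_single_feasible_material(self, adipose_model, material_library):
        ranked = rank_materials([material_library["HIPS"]], adipose_model,
                                TissueTarget(TissueClass.ADIPOSE, -80.0), KV_GRID)
        assert len(ranked) == 1 and ranked[0][0].name == "HIPS"

    def test_no_feasible_material_warns_and_returns_empty(
            self, bone_model, material_library):
        with pytest.warns(UserWarning, match="no feasible"):
            ranked = rank_materials([material_library["PLA/chalk"]], bone_model,
                                    TissueTarget(TissueClass.BONE, 2500.0), KV_GRID)
        assert ranked == []

    def test_resins_are_evaluated_at_full_density(self, bone_model):
        resin = MaterialRecord("rigid resin", "resin", 400.0,
                               delta_to_tissue={70.0: 0, 80.0: 0, 100.0: 0, 140.0: 0},
                               underfillable=False)
        ranked = rank_materials([resin], bone_model,
                                TissueTarget(TissueClass.BONE, 350.0), KV_GRID)
        (_, plan, score) = ranked[0]
        assert plan.filling_ratio == 1.0
        # the 50 HU reference mismatch stays in the score; it is largest at the
        # soft end where the bone multiplier amplifies the surplus attenuation
        assert score == pytest.approx(bone_model.k(70.0) * 50.0, abs=1e-9)


class TestContrastCorrection:
    def make_plan(self, material, target, deltas):
        return FillPlan(material=material, tissue_target=target, filling_ratio=0.9,
                        predicted_hu={kv: 0.0 for kv in deltas}, delta_hu=deltas)

    def test_zero_deltas_leave_contrast_unchanged(self, material_library):
        t = TissueTarget(TissueClass.BONE, 500.0)
        a = self.make_plan(material_library["PLA/stone"], t, {70.0: 0.0})
        b = self.make_plan(material_library["PLA/chalk"], t, {70.0: 0.0})
        assert correct_contrast(430.0, a, b, 70.0) == 430.0

    def test_offset_subtraction_and_antisymmetry(self, material_library):
        t = TissueTarget(TissueClass.BONE, 500.0)
        a = self.make_plan(material_library["PLA/stone"], t, {70.0: 25.0})
        b = self.make_plan(material_library["PLA/chalk"], t, {70.0: 0.0})
        corrected = correct_contrast(500.0, a, b, 70.0)
        assert corrected == 475.0
        # swapping the plans negates the applied offset, restoring the raw contrast
        assert correct_contrast(corrected, b, a, 70.0) == pytest.approx(500.0)

    def test_missing_grid_point_raises(self, material_library):
        t = TissueTarget(TissueClass.BONE, 500.0)
        a = self.make_plan(material_library["PLA/stone"], t, {70.0: 25.0})
        b = self.make_plan(material_library["PLA/chalk"], t, {80.0: 0.0})
        with pytest.raises(MissingGridPointError):
            correct_contrast(500.0, a, b, 70.0)


class TestLibraryCsv:
    def test_packaged_library_loads_characterised_materials(self):
        mats = {m.name: m for m in load_material_library()}
        assert mats["PLA/stone"].hu_ref == 1063.0
        assert mats["HIPS"].hu_ref == -42.0
        assert mats["HIPS"].delta_to_tissue[70.0] == -15.0
        assert mats["HIPS"].delta_to_tissue[120.0] == 0.0
        # metadata-only rows (no characterised CT number) are not records
        assert "Nylon" not in mats
        assert "Tango" not in mats

    def test_offset_nonzero_at_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            MaterialRecord("bad", "filament", 500.0,
                           delta_to_tissue={120.0: 5.0, 70.0: 0.0})

    def test_custom_library_roundtrip(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            "name,material_class,tissue,hu_ref,delta_70,delta_80,delta_100,delta_140,"
            "underfillable,polymer,product\n"
            "custom,filament,bone,800,10,5,2,-1,True,PLA blend,Custom 800\n")
        mats = read_material_library_csv(path)
        assert len(mats) == 1
        assert mats[0].delta_to_tissue == {70.0: 10.0, 80.0: 5.0, 100.0: 2.0,
                                           140.0: -1.0, 120.0: 0.0}


def test_ranking_respects_characterisation_tissue(adipose_model, material_library):
    """Materials characterised against the bone curve are not candidates for
    adipose targets (their per-kV offsets are bone-relative)."""
    ranked = rank_materials(list(material_library.values()), adipose_model,
                            TissueTarget(TissueClass.ADIPOSE, -80.0), KV_GRID)
    assert [m.name for m, _, _ in ranked] == ["HIPS"]
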