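import numpy as np
import pytest

from enmgap.endemism_richness import (
    CategoryLabel,
    SpeciesProfile,
    UNCERTAINTY_CODES,
    UnresolvedCategoryError,
    classify,
    richness_area,
    stack_richness,
    uncertainty,
)
from enmgap.reference_data import default_category_overrides, habitat_extents


def profile(**kw):
    defaults = dict(
        species="sp", endemic=True, current_area_km2=5000.0, breadth=0.3,
        occ_elevations_m=(100.0, 400.0), zone_overlap={},
    )
    defaults.update(kw)
    return SpeciesProfile(**defaults)


class TestClassify:
    def test_wide_endemic(self):
        # royenii-like published profile
        lab = classify(profile(current_area_km2=15993.0, breadth=0.62))
        assert lab.label == "wide_endemic"
        assert not lab.overridden

    def test_narrow_montane(self):
        # cuneatum-like published profile
        lab = classify(profile(current_area_km2=4812.0, breadth=0.11,
                               occ_elevations_m=(1800.0, 2400.0)))
        assert lab.label == "narrow_endemic_montane"

    def test_narrow_lowland(self):
        lab = classify(profile(current_area_km2=6094.0, breadth=0.11,
                               occ_elevations_m=(50.0, 900.0)))
        assert lab.label == "narrow_endemic_lowland"

    def test_borderline_breadth_is_wide(self):
        # inclusive cutoffs: breadth exactly 0.5 with area 14,152 -> wide
        lab = classify(profile(current_area_km2=14152.0, breadth=0.50))
        assert lab.label == "wide_endemic"

    def test_nonendemic_dry(self):
        # capitellatum-like: dry-zone dominant overlap
        lab = classify(profile(endemic=False,
                               zone_overlap={"dry": 0.6, "arid": 0.1, "wet": 0.3}))
        assert lab.label == "nonendemic_dry"

    def test_nonendemic_wet(self):
        lab = classify(profile(endemic=False, zone_overlap={"wet": 0.7, "dry": 0.3}))
        assert lab.label == "nonendemic_wet"

    def test_unresolved_endemic_errors(self):
        # area large but breadth small: matches neither endemic rule
        with pytest.raises(UnresolvedCategoryError):
            classify(profile(current_area_km2=12000.0, breadth=0.3))

    def test_tied_zones_error(self):
        with pytest.raises(UnresolvedCategoryError):
            classify(profile(endemic=False, zone_overlap={"wet": 0.5, "dry": 0.5}))

    def test_override_applies_and_flags(self):
        lab = classify(profile(current_area_km2=12000.0, breadth=0.3),
                       overrides={"sp": "wide_endemic"})
        assert lab.label == "wide_endemic"
        assert lab.overridden

    def test_rule_trace_nonempty(self):
        assert classify(profile(current_area_km2=15000.0, breadth=0.7)).rule_trace

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            CategoryLabel(label="bogus", rule_trace="x")


class TestPublishedProfiles:
    """The packaged per-species table, plus the shipped override file, must
    classify every species to its published category (elevations proxied
    from the published montane/lowland distinction)."""

    def test_all_species_match_published_categories(self):
        table = habitat_extents()
        overrides = default_category_overrides()
        for _, row in table.iterrows():
            elev = (500.0, 1500.0) if "montane" in row["category"] else (50.0, 250.0)
            zones = (
                {"dry": 0.7, "wet": 0.3} if row["category"] == "nonendemic_dry"
                else {"wet": 0.7, "dry": 0.3}
            )
            prof = SpeciesProfile(
                species=row["species"], endemic=bool(row["endemic"]),
                current_area_km2=float(row["current_km2"]),
                breadth=float(row["breadth"]),
                occ_elevations_m=elev, zone_overlap=zones,
            )
            lab = classify(prof, overrides=overrides)
            assert lab.label == row["category"], row["species"]


class TestStackRichness:
    def test_single_member_identity(self):
        m = np.array([[1.0, 0.0], [np.nan, 1.0]])
        counts = stack_richness([m])
        assert counts[0, 0] == 1 and counts[0, 1] == 0
        assert np.isnan(counts[1, 0])

    def test_overlap_counts(self):
        a = np.zeros((3, 5)); a[:, :3] = 1
        b = np.zeros((3, 5)); b[:, 1:4] = 1
        counts = stack_richness([a, b])
        assert (counts[:, 1:3] == 2).all()
        assert counts.max() == 2

    def test_max_bounded_by_members(self):
        maps = [np.ones((2, 2)) for _ in range(4)]
        assert stack_richness(maps).max() == 4


class TestRichnessArea:
    def test_single_species(self):
        m = np.array([[1.0, 0.0, 1.0]])
        areas = np.full((1, 3), 2.0)
        assert richness_area(m, areas) == 4.0

    def test_triple_overlap_enumeration(self):
        a = np.zeros((4, 4)); a[:3, :3] = 1
        b = np.zeros((4, 4)); b[1:, 1:] = 1
        c = np.zeros((4, 4)); c[1:3, :] = 1
        counts = stack_richness([a, b, c])
        areas = np.ones((4, 4))
        # cells where all 3 overlap: rows 1-2 x cols 1-2 -> 4 cells
        assert counts.max() == 3
        assert richness_area(counts, areas, level="max") == 4.0

    def test_level_one_at_least_max_level(self):
        a = np.zeros((4, 4)); a[:3, :3] = 1
        b = np.zeros((4, 4)); b[1:, 1:] = 1
        counts = stack_richness([a, b])
        areas = np.ones((4, 4))
        assert richness_area(counts, areas, level=1) >= richness_area(counts, areas, level="max")

    def test_empty_map_zero(self):
        assert richness_area(np.zeros((2, 2)), np.ones((2, 2))) == 0.0


class TestUncertainty:
    def test_identical_replicates_no_mixed(self):
        rep = np.array([[1.0, 0.0]])
        out = uncertainty([[rep, rep.copy(), rep.copy()]])
        assert out[0, 0] == UNCERTAINTY_CODES["always"]
        assert out[0, 1] == UNCERTAINTY_CODES["absent"]
        assert (out != UNCERTAINTY_CODES["mixed"]).all()

    def test_one_dissenting_replicate_mixed(self):
        agree = np.array([[1.0]])
        dissent = np.array([[0.0]])
        out = uncertainty([[agree, agree, dissent]])
        assert out[0, 0] == UNCERTAINTY_CODES["mixed"]

    def test_absent_complement_of_union(self):
        a = np.array([[1.0, 0.0, 1.0]])
        b = np.array([[0.0, 0.0, 1.0]])
        out = uncertainty([[a, b]])
        # cell 1: no replicate predicts -> absent; cell 0: mixed; cell 2: always
        assert out[0, 1] == UNCERTAINTY_CODES["absent"]
        assert out[0, 0] == UNCERTAINTY_CODES["mixed"]
        assert out[0, 2] == UNCERTAINTY_CODES["always"]

    def test_multi_member_absent_dominates(self):
        present = np.array([[1.0]])
        absent = np.array([[0.0]])
        out = uncertainty([[present, present], [absent, absent]])
        assert out[0, 0] == UNCERTAINTY_CODES["absent"]

    def test_tri_state_partition(self):
        rng = np.random.default_rng(0)
        members = [
            [(rng.uniform(size=(6, 6)) > 0.5).astype(float) for _ in range(3)]
            for _ in range(2)
        ]
        out = uncertainty(members)
        assert set(np.unique(out)) <= {0.0, 1.0, 2.0}

    def test_always_subset_of_any_richness(self):
        rng = np.random.default_rng(1)
        members = [
            [(rng.uniform(size=(5, 5)) > 0.4).astype(float) for _ in range(4)]
            for _ in range(3)
        ]
        out = uncertainty(members)
        always = out == UNCERTAINTY_CODES["always"]
        not_absent = out != UNCERTAINTY_CODES["absent"]
        union_any = np.zeros((5, 5), dtype=bool)
        for reps in members:
            union_any |= np.any(np.stack(reps) == 1.0, axis=0)
        assert (always <= not_absent).all()
        assert (not_absent <= union_any).all()
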