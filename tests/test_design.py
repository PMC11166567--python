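import numpy as np
import pandas as pd
import pytest

from morphmap import (
    DesignError,
    DesignSpec,
    PerturbationLabel,
    PlateMaps,
    WellAddress,
    estimate_image_count,
    make_plate_maps,
    make_schedule,
    make_splits,
)
from morphmap.design import SECONDARY_CONDITIONS
from morphmap.profiles import parse_targets


def audit_plate_maps(spec: DesignSpec, maps: PlateMaps) -> None:
    """Exhaustive brute-force audit of cardinalities and zone constraints."""
    for pm in maps:
        # every well address valid, unique, and zone label correct
        seen = set()
        for r in pm.entries.itertuples():
            w = WellAddress.parse(str(r.Metadata_Plate), str(r.Metadata_Well))
            assert (w.row, w.column) not in seen
            seen.add((w.row, w.column))
            expected_zone = (
                "outer" if w.row in "ABOP" or w.column in (1, 2, 23, 24) else "inner"
            )
            assert r.Metadata_zone == expected_zone

    cpd, cri, orf = maps.compound.entries, maps.crispr.entries, maps.orf.entries

    # cardinalities
    cpd_counts = cpd.groupby("Metadata_perturbation").size()
    trt = cpd[cpd["Metadata_control_type"] == "trt"]["Metadata_perturbation"]
    assert (cpd_counts[trt.unique()] == 1).all()
    pos = cpd[cpd["Metadata_control_type"] == "poscon_diverse"]["Metadata_perturbation"]
    assert pos.nunique() == spec.n_poscon_diverse
    assert (cpd_counts[pos.unique()] == 2).all() if len(pos) else True
    assert (cpd["Metadata_control_type"] == "negcon").sum() == spec.n_dmso_wells

    gui = cri[cri["Metadata_control_type"] == "trt"]
    assert len(gui) == spec.n_guides
    assert gui["Metadata_perturbation"].is_unique
    cneg = cri[cri["Metadata_control_type"] == "negcon"]
    assert cneg["Metadata_perturbation"].nunique() == spec.n_crispr_negcon
    assert (cneg.groupby("Metadata_perturbation").size() == spec.crispr_negcon_replicates).all()

    otrt = orf[orf["Metadata_control_type"] == "trt"]
    assert (
        otrt.groupby("Metadata_perturbation").size()
        == spec.orf_treatment_replicates_per_plate
    ).all()
    assert otrt["Metadata_perturbation"].nunique() == spec.n_target_genes
    oneg = orf[orf["Metadata_control_type"] == "negcon"]
    assert oneg["Metadata_perturbation"].nunique() == spec.n_orf_negcon
    assert (oneg.groupby("Metadata_perturbation").size() == spec.orf_negcon_replicates).all()

    # zone constraints: build gene -> zone per plate, exhaustively
    def gene_zones(entries: pd.DataFrame) -> dict[str, set[str]]:
        zones: dict[str, set[str]] = {}
        for r in entries.itertuples():
            for g in parse_targets(r.Metadata_target):
                zones.setdefault(g, set()).add(str(r.Metadata_zone))
        return zones

    z_cpd, z_cri, z_orf = gene_zones(cpd), gene_zones(cri), gene_zones(orf)
    for g in z_cpd:
        # (a) all compounds of a target share one zone
        assert len(z_cpd[g]) == 1, f"gene {g} compounds split across zones"
        # (b) the gene's guides and ORFs sit in that same zone
        assert z_cri[g] == z_cpd[g]
        assert z_orf[g] == z_cpd[g]
    # (c) positive-control compounds are inner-only
    assert (
        cpd.loc[cpd["Metadata_control_type"] == "poscon_diverse", "Metadata_zone"]
        == "inner"
    ).all()


class TestPlateMaps:
    def test_default_compound_plate_has_64_dmso_wells(self):
        maps = make_plate_maps(seed=0)
        assert maps.compound.count_wells("negcon") == 64

    def test_default_design_yields_303_distinct_compounds(self):
        maps = make_plate_maps(seed=0)
        cpd = maps.compound.entries
        n_compounds = cpd.loc[
            cpd["Metadata_control_type"] != "negcon", "Metadata_perturbation"
        ].nunique()
        assert n_compounds == 303
        assert maps.compound.n_occupied == 384

    def test_sister_compounds_share_zone_by_construction(self):
        maps = make_plate_maps(seed=1)
        cpd = maps.compound.entries
        zones: dict[str, set] = {}
        for r in cpd.itertuples():
            for g in parse_targets(r.Metadata_target):
                zones.setdefault(g, set()).add(r.Metadata_zone)
        assert all(len(z) == 1 for z in zones.values())

    @pytest.mark.parametrize("seed", [0, 7])
    def test_full_audit_default_spec(self, seed):
        spec = DesignSpec()
        audit_plate_maps(spec, make_plate_maps(spec, seed=seed))

    def test_full_audit_tiny_spec(self):
        spec = DesignSpec(
            n_target_genes=4,
            n_single_guide_genes=1,
            n_dmso_wells=8,
            n_poscon_diverse=2,
            n_crispr_negcon=3,
            n_orf_negcon=2,
        )
        audit_plate_maps(spec, make_plate_maps(spec, seed=3))

    def test_seed_determinism(self):
        a = make_plate_maps(seed=5)
        b = make_plate_maps(seed=5)
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa.entries, pb.entries)

    def test_overfull_plate_raises(self):
        with pytest.raises(DesignError, match="occupancy"):
            DesignSpec(n_target_genes=200, n_poscon_diverse=0)

    def test_infeasible_inner_zone_raises(self):
        # inner-only positive controls exceeding the 256 inner wells
        spec = DesignSpec(
            n_target_genes=5, n_single_guide_genes=0, n_dmso_wells=0,
            n_poscon_diverse=125, n_crispr_negcon=1, n_orf_negcon=1,
        )
        with pytest.raises(DesignError, match="inner"):
            make_plate_maps(spec, seed=0)


class TestSchedule:
    def test_primary_group_has_40_plates(self):
        sched = make_schedule()
        totals = sched.group_totals()
        assert int(totals.loc["primary", "physical_plates"]) == 40
        assert int(totals.loc["primary", "plates_of_images"]) == 40

    def test_overall_totals_51_physical_107_images(self):
        sched = make_schedule()
        assert sched.n_physical_plates == 51
        assert sched.n_plates_of_images == 107

    def test_no_secondary_means_images_equal_physical(self):
        sched = make_schedule(secondary=())
        assert sched.n_plates_of_images == sched.n_physical_plates == 40

    def test_schedule_is_pure_function_of_spec(self):
        pd.testing.assert_frame_equal(
            make_schedule().entries, make_schedule().entries
        )

    def test_secondary_conditions_cover_seven_named_variants(self):
        names = {c["condition"] for c in SECONDARY_CONDITIONS}
        assert len(names) == 7


class TestImageCount:
    def test_single_plate_single_site_single_image(self):
        sched = make_schedule(secondary=())
        sched.entries = sched.entries.iloc[:1]
        assert estimate_image_count(sched, wells=384, sites_per_well=1, images_per_site=1) == 384

    def test_default_schedule_is_nearly_3_million(self):
        count = estimate_image_count(make_schedule())
        assert 2_900_000 < count <= 3_000_000

    def test_matches_brute_force_sum_over_entries(self):
        rng = np.random.default_rng(11)
        sched = make_schedule()
        sched.entries = sched.entries.assign(
            imaging_events=rng.integers(1, 6, size=len(sched.entries))
        )
        expected = sum(
            int(e) * 384 * 9 * 8 for e in sched.entries["imaging_events"]
        )
        assert estimate_image_count(sched) == expected

    def test_rejects_non_positive_arguments(self):
        with pytest.raises(ValueError):
            estimate_image_count(make_schedule(), sites_per_well=0)


class TestSplits:
    @staticmethod
    def _labels():
        labels = []
        for i in range(1, 101):
            g = f"G{i:03d}"
            labels.append(PerturbationLabel(f"GUIDE-{g}-1", "crispr", "trt", frozenset({g})))
            labels.append(PerturbationLabel(f"GUIDE-{g}-2", "crispr", "trt", frozenset({g})))
        for name in ("BVT-948", "dexamethasone", "thiostrepton"):
            labels.append(PerturbationLabel(f"{name}-id1", "compound", "trt", frozenset({"G001"})))
            labels.append(PerturbationLabel(f"{name}-id2", "compound", "trt", frozenset({"G001"})))
        return labels

    def test_both_guides_of_a_gene_share_a_split(self):
        splits = make_splits(self._labels(), seed=2)
        for i in range(1, 101):
            g = f"G{i:03d}"
            assert splits[f"GUIDE-{g}-1"] == splits[f"GUIDE-{g}-2"]

    def test_duplicate_structure_compounds_share_a_split(self):
        splits = make_splits(self._labels(), seed=2)
        for name in ("BVT-948", "dexamethasone", "thiostrepton"):
            assert splits[f"{name}-id1"] == splits[f"{name}-id2"]

    def test_deterministic_given_seed(self):
        a = make_splits(self._labels(), seed=9).assignment
        b = make_splits(self._labels(), seed=9).assignment
        assert a == b

    def test_entity_level_fractions_within_one_entity(self):
        splits = make_splits(self._labels(), fractions=(0.5, 0.25, 0.25), seed=4)
        frame = splits.to_frame()
        # entities: 100 genes + 3 duplicate-name compound groups = 103
        entity = frame["Metadata_perturbation"].str.replace(
            r"(-[12]$)|(-id[12]$)", "", regex=True
        )
        sizes = frame.groupby("split")["Metadata_perturbation"].apply(
            lambda s: entity[s.index].nunique()
        )
        assert abs(sizes["train"] - 0.5 * 103) <= 1
        assert abs(sizes["validate"] - 0.25 * 103) <= 1

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            make_splits(self._labels(), fractions=(0.5, 0.2, 0.2))
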