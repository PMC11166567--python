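"""Constraint-based experiment design: plate maps, schedule, data splits.

The benchmark experiment arrays three perturbation modalities on
separate 384-well plates (one compound plate, one CRISPR plate, one ORF
plate) and images replicate plates under a primary grid of conditions
(cell type x time point) plus a small set of secondary conditions.

Plate-layout constraints guard against edge effects: the plate is split
into *outer* wells (the two rows and columns nearest each edge, 128
wells) and *inner* wells (the remaining 256).  Sister compounds sharing
a target stay in one zone, the genetic reagents for that target sit in
the same zone of their own plates, and positive-control compounds are
restricted to inner wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    ControlType,
    Modality,
    PerturbationLabel,
    WellAddress,
    enumerate_wells,
    format_targets,
    WELLS_PER_PLATE,
)

# outer zone: the two rows (A, B, O, P) and two columns (1, 2, 23, 24)
# closest to each edge -> 4*24 + 12*4 = 144 wells; inner = 12*20 = 240
N_OUTER_WELLS = sum(1 for w in enumerate_wells("_") if w.zone == "outer")
N_INNER_WELLS = WELLS_PER_PLATE - N_OUTER_WELLS

#: Compounds present under two distinct identifiers (small structural
#: differences, same name); their identifier pairs must share a split.
DUPLICATE_STRUCTURE_COMPOUNDS = ("BVT-948", "dexamethasone", "thiostrepton")


class DesignError(ValueError):
    """The design constraints cannot be satisfied."""


@dataclass(frozen=True)
class DesignSpec:
    """Counts defining the three plate layouts and the replicate scheme.

    Defaults reproduce the benchmark design: 160 target genes, two
    compounds per target, two CRISPR guides per gene (one for 15 genes),
    64 DMSO wells, 30 CRISPR negative controls in duplicate, 15 ORF
    negative controls in quadruplicate, duplicated ORF treatments, and
    17 duplicated diverse positive-control compounds.
    """

    n_target_genes: int = 160
    compounds_per_target: int = 2
    guides_per_gene: int = 2
    n_single_guide_genes: int = 15
    n_orf_negcon: int = 15
    n_crispr_negcon: int = 30
    n_dmso_wells: int = 64
    orf_negcon_replicates: int = 4
    crispr_negcon_replicates: int = 2
    orf_treatment_replicates_per_plate: int = 2
    n_poscon_diverse: int = 17
    compound_replicate_plates: int = 4
    crispr_replicate_plates: int = 4
    orf_replicate_plates: int = 2

    def __post_init__(self) -> None:
        counts = {
            "n_target_genes": self.n_target_genes,
            "compounds_per_target": self.compounds_per_target,
            "guides_per_gene": self.guides_per_gene,
        }
        for name, value in counts.items():
            if value <= 0:
                raise DesignError(f"{name} must be positive, got {value}")
        if not 0 <= self.n_single_guide_genes <= self.n_target_genes:
            raise DesignError("n_single_guide_genes must lie in [0, n_target_genes]")
        for plate, occ in self.plate_occupancies().items():
            if occ > WELLS_PER_PLATE:
                raise DesignError(
                    f"{plate} plate occupancy {occ} exceeds {WELLS_PER_PLATE} wells"
                )

    # -- derived counts ----------------------------------------------------
    @property
    def n_guides(self) -> int:
        return (
            self.n_target_genes * self.guides_per_gene
            - self.n_single_guide_genes * (self.guides_per_gene - 1)
        )

    @property
    def n_compound_annotations(self) -> int:
        return self.n_target_genes * self.compounds_per_target

    @property
    def n_distinct_compounds(self) -> int:
        """Distinct treatment compounds after dual-target merging.

        The full grid of gene x compound annotations does not fit on one
        plate next to the DMSO wells and duplicated positive controls;
        pairs of annotations are merged into dual-target
        (polypharmacology-style) compounds until the plate fits.
        """
        capacity = WELLS_PER_PLATE - self.n_dmso_wells - 2 * self.n_poscon_diverse
        return min(self.n_compound_annotations, capacity)

    @property
    def n_merged_compounds(self) -> int:
        return self.n_compound_annotations - self.n_distinct_compounds

    def plate_occupancies(self) -> dict[str, int]:
        capacity = WELLS_PER_PLATE - self.n_dmso_wells - 2 * self.n_poscon_diverse
        n_merge = max(0, self.n_compound_annotations - capacity)
        if n_merge > self.n_target_genes // 2:
            raise DesignError(
                "compound plate infeasible: "
                f"{self.n_compound_annotations} target annotations cannot be "
                f"reduced to {capacity} distinct compounds by pairwise merging"
            )
        return {
            "compound": (
                self.n_compound_annotations
                - n_merge
                + 2 * self.n_poscon_diverse
                + self.n_dmso_wells
            ),
            "crispr": self.n_guides
            + self.n_crispr_negcon * self.crispr_negcon_replicates,
            "orf": self.n_target_genes * self.orf_treatment_replicates_per_plate
            + self.n_orf_negcon * self.orf_negcon_replicates,
        }

    def gene_ids(self) -> list[str]:
        width = max(3, len(str(self.n_target_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_target_genes + 1)]

    def single_guide_genes(self) -> set[str]:
        """Genes with only one guide: the last IDs in sorted order."""
        genes = sorted(self.gene_ids())
        if self.n_single_guide_genes == 0:
            return set()
        return set(genes[-self.n_single_guide_genes:])


@dataclass
class PlateMap:
    """Assignment of perturbations to the wells of one 384-well plate."""

    plate_id: str
    modality: str
    entries: pd.DataFrame  # Metadata_Plate/Well/zone/perturbation/modality/control_type/target

    @property
    def n_occupied(self) -> int:
        return len(self.entries)

    @property
    def n_empty(self) -> int:
        return WELLS_PER_PLATE - self.n_occupied

    def control_counts(self) -> pd.Series:
        return self.entries["Metadata_control_type"].value_counts()

    def count_wells(self, control_type: str) -> int:
        return int((self.entries["Metadata_control_type"] == control_type).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()

    def labels(self) -> list[PerturbationLabel]:
        from .profiles import parse_targets

        return [
            PerturbationLabel(
                str(r.Metadata_perturbation),
                str(r.Metadata_modality),
                str(r.Metadata_control_type),
                parse_targets(r.Metadata_target),
            )
            for r in self.entries.itertuples()
        ]


class PlateMaps(NamedTuple):
    compound: PlateMap
    crispr: PlateMap
    orf: PlateMap


@dataclass(frozen=True)
class _Entity:
    """One reagent to be placed, possibly in several copies."""

    perturbation_id: str
    modality: str
    control_type: str
    targets: frozenset[str]
    copies: int = 1


def _compound_entities(spec: DesignSpec, rng: np.random.Generator) -> list[_Entity]:
    genes = spec.gene_ids()
    n_merge = spec.n_merged_compounds
    merged_genes: list[str] = []
    if n_merge > 0:
        order = list(rng.permutation(genes))
        merged_genes = order[: 2 * n_merge]
    merged_pairs = [
        (merged_genes[2 * i], merged_genes[2 * i + 1]) for i in range(n_merge)
    ]
    in_merge = {g for pair in merged_pairs for g in pair}

    entities: list[_Entity] = []
    for g in genes:
        # the final compound slot of a merged gene is covered by the merge
        n_own = spec.compounds_per_target - (1 if g in in_merge else 0)
        for j in range(1, n_own + 1):
            entities.append(
                _Entity(f"CPD-{g}-{j}", Modality.COMPOUND.value, ControlType.TRT.value, frozenset({g}))
            )
    for i, (ga, gb) in enumerate(merged_pairs, start=1):
        entities.append(
            _Entity(
                f"CPD-DUAL-{i:03d}",
                Modality.COMPOUND.value,
                ControlType.TRT.value,
                frozenset({ga, gb}),
            )
        )
    return entities


def _zone_components(spec: DesignSpec, compounds: Sequence[_Entity]) -> list[set[str]]:
    """Connected components of genes linked by shared (dual-target) compounds."""
    parent: dict[str, str] = {g: g for g in spec.gene_ids()}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for ent in compounds:
        targets = sorted(ent.targets)
        for other in targets[1:]:
            union(targets[0], other)
    groups: dict[str, set[str]] = {}
    for g in parent:
        groups.setdefault(find(g), set()).add(g)
    return sorted(groups.values(), key=lambda s: min(s))


def _plate_loads(
    spec: DesignSpec, genes: Iterable[str], compounds: Sequence[_Entity]
) -> dict[str, int]:
    genes = set(genes)
    single = spec.single_guide_genes()
    return {
        "compound": sum(1 for e in compounds if e.targets & genes),
        "crispr": sum(
            1 if g in single else spec.guides_per_gene for g in genes
        ),
        "orf": len(genes) * spec.orf_treatment_replicates_per_plate,
    }


def _assign_zones(
    spec: DesignSpec, compounds: Sequence[_Entity], rng: np.random.Generator
) -> set[str]:
    """Pick the set of outer-zone genes.

    Components of genes coupled through dual-target compounds move as a
    unit so sister compounds, sister guides and the matching ORF always
    share a zone.  Roughly a third of the treatments go to the outer
    zone (its share of the plate), subject to outer capacity and to
    leaving enough inner wells for the inner-only positive controls.
    """
    components = _zone_components(spec, compounds)
    totals = _plate_loads(spec, spec.gene_ids(), compounds)
    targets = {
        plate: int(np.floor(load * N_OUTER_WELLS / WELLS_PER_PLATE))
        for plate, load in totals.items()
    }
    inner_reserved = {"compound": 2 * spec.n_poscon_diverse, "crispr": 0, "orf": 0}

    order = list(rng.permutation(len(components)))
    outer_genes: set[str] = set()
    outer_load = {plate: 0 for plate in totals}
    for idx in order:
        comp = components[idx]
        loads = _plate_loads(spec, comp, compounds)
        if all(outer_load[p] + loads[p] <= min(N_OUTER_WELLS, targets[p]) for p in loads):
            outer_genes |= comp
            for p in loads:
                outer_load[p] += loads[p]
    # grow further if the inner zone cannot hold what is left
    for idx in order:
        comp = components[idx]
        if comp <= outer_genes:
            continue
        inner_ok = all(
            totals[p] - outer_load[p] + inner_reserved[p] <= N_INNER_WELLS
            for p in totals
        )
        if inner_ok:
            break
        loads = _plate_loads(spec, comp, compounds)
        if all(outer_load[p] + loads[p] <= N_OUTER_WELLS for p in loads):
            outer_genes |= comp
            for p in loads:
                outer_load[p] += loads[p]
    for p in totals:
        if outer_load[p] > N_OUTER_WELLS:
            raise DesignError(
                f"{p} plate: {outer_load[p]} outer-designated wells exceed "
                f"{N_OUTER_WELLS} outer wells (deficit {outer_load[p] - N_OUTER_WELLS})"
            )
        inner_need = totals[p] - outer_load[p] + inner_reserved[p]
        if inner_need > N_INNER_WELLS:
            raise DesignError(
                f"{p} plate: {inner_need} inner-designated wells exceed "
                f"{N_INNER_WELLS} inner wells (deficit {inner_need - N_INNER_WELLS})"
            )
    return outer_genes


def _striped_selection(wells: Sequence[WellAddress], n: int) -> list[WellAddress]:
    """Pick ``n`` wells evenly spaced over a row-major ordering.

    Latin-hypercube-style striping: spreads solvent-control wells across
    rows and columns instead of clustering them.
    """
    ordered = sorted(wells, key=lambda w: (w.column, w.row))
    if n >= len(ordered):
        return list(ordered)
    idx = np.linspace(0, len(ordered) - 1, num=n)
    return [ordered[int(round(i))] for i in idx]


def _place_plate(
    plate_id: str,
    modality: str,
    treatments: Sequence[_Entity],
    inner_only: Sequence[_Entity],
    fillers: Sequence[_Entity],
    striped_filler: _Entity | None,
    outer_genes: set[str],
    rng: np.random.Generator,
) -> PlateMap:
    wells = enumerate_wells(plate_id)
    outer = [w for w in wells if w.zone == "outer"]
    inner = [w for w in wells if w.zone == "inner"]
    rng.shuffle(outer)  # type: ignore[arg-type]
    rng.shuffle(inner)  # type: ignore[arg-type]

    rows: list[tuple[WellAddress, _Entity]] = []

    def take(pool: list[WellAddress], ent: _Entity) -> None:
        if not pool:
            raise DesignError(
                f"{plate_id}: ran out of wells while placing {ent.perturbation_id!r}"
            )
        rows.append((pool.pop(), ent))

    for ent in treatments:
        pool = outer if (ent.targets and ent.targets <= outer_genes) else inner
        for _ in range(ent.copies):
            take(pool, ent)
    for ent in inner_only:
        for _ in range(ent.copies):
            take(inner, ent)

    remaining = outer + inner
    if striped_filler is not None:
        chosen = _striped_selection(remaining, striped_filler.copies)
        chosen_set = set(chosen)
        rows.extend((w, striped_filler) for w in chosen)
        remaining = [w for w in remaining if w not in chosen_set]
    rng.shuffle(remaining)  # type: ignore[arg-type]
    for ent in fillers:
        for _ in range(ent.copies):
            take(remaining, ent)

    data = pd.DataFrame(
        {
            "Metadata_Plate": plate_id,
            "Metadata_Well": [w.name for w, _ in rows],
            "Metadata_zone": [w.zone for w, _ in rows],
            "Metadata_perturbation": [e.perturbation_id for _, e in rows],
            "Metadata_modality": [e.modality for _, e in rows],
            "Metadata_control_type": [e.control_type for _, e in rows],
            "Metadata_target": [format_targets(e.targets) for _, e in rows],
        }
    ).sort_values("Metadata_Well", kind="mergesort", ignore_index=True)
    return PlateMap(plate_id=plate_id, modality=modality, entries=data)


def make_plate_maps(spec: DesignSpec | None = None, seed: int = 0) -> PlateMaps:
    """Generate the compound, CRISPR and ORF plate maps.

    Well placement within a zone is uniform at random given the seed;
    the layout constraints (shared zones for sister reagents, inner-only
    positive controls, striped DMSO wells) are deterministic.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    compounds = _compound_entities(spec, rng)
    outer_genes = _assign_zones(spec, compounds, rng)

    poscon_diverse = [
        _Entity(
            f"POSCON-DIV-{i:02d}",
            Modality.COMPOUND.value,
            ControlType.POSCON_DIVERSE.value,
            frozenset(),
            copies=2,
        )
        for i in range(1, spec.n_poscon_diverse + 1)
    ]
    dmso = _Entity(
        "DMSO",
        Modality.COMPOUND.value,
        ControlType.NEGCON.value,
        frozenset(),
        copies=spec.n_dmso_wells,
    )
    compound_map = _place_plate(
        "compound_plate",
        Modality.COMPOUND.value,
        compounds,
        poscon_diverse,
        [],
        dmso,
        outer_genes,
        rng,
    )

    single = spec.single_guide_genes()
    guides = [
        _Entity(
            f"GUIDE-{g}-{j}", Modality.CRISPR.value, ControlType.TRT.value, frozenset({g})
        )
        for g in spec.gene_ids()
        for j in range(1, (1 if g in single else spec.guides_per_gene) + 1)
    ]
    # 3 cutting (intergenic-site) + the rest non-cutting guide controls
    n_cutting = min(3, spec.n_crispr_negcon)
    crispr_negcon = [
        _Entity(
            f"GUIDE-NC-{'cut' if i <= n_cutting else 'noncut'}-{i:02d}",
            Modality.CRISPR.value,
            ControlType.NEGCON.value,
            frozenset(),
            copies=spec.crispr_negcon_replicates,
        )
        for i in range(1, spec.n_crispr_negcon + 1)
    ]
    crispr_map = _place_plate(
        "crispr_plate",
        Modality.CRISPR.value,
        guides,
        [],
        crispr_negcon,
        None,
        outer_genes,
        rng,
    )

    orfs = [
        _Entity(
            f"ORF-{g}",
            Modality.ORF.value,
            ControlType.TRT.value,
            frozenset({g}),
            copies=spec.orf_treatment_replicates_per_plate,
        )
        for g in spec.gene_ids()
    ]
    orf_negcon = [
        _Entity(
            f"ORF-NC-{i:02d}",
            Modality.ORF.value,
            ControlType.NEGCON.value,
            frozenset(),
            copies=spec.orf_negcon_replicates,
        )
        for i in range(1, spec.n_orf_negcon + 1)
    ]
    orf_map = _place_plate(
        "orf_plate", Modality.ORF.value, orfs, [], orf_negcon, None, outer_genes, rng
    )
    return PlateMaps(compound=compound_map, crispr=crispr_map, orf=orf_map)


# ---------------------------------------------------------------------------
# Experiment schedule


TIME_POINTS = {
    Modality.COMPOUND.value: ("24h", "48h"),
    Modality.ORF.value: ("48h", "96h"),
    Modality.CRISPR.value: ("96h", "144h"),
}
CELL_TYPES = ("U2OS", "A549")

#: The secondary experimental conditions, as data: each entry yields
#: ``n_plates`` schedule rows; ``new_physical`` marks plates beyond the
#: primary set and ``imaging_events`` counts image-plate acquisitions.
SECONDARY_CONDITIONS: tuple[dict, ...] = (
    {"condition": "orf_blasticidin", "modality": "orf", "cell_type": "A549",
     "time_point": "96h", "n_plates": 1, "new_physical": True, "imaging_events": 1},
    {"condition": "crispr_puromycin", "modality": "crispr", "cell_type": "A549",
     "time_point": "144h", "n_plates": 2, "new_physical": True, "imaging_events": 1},
    {"condition": "compound_density_up20", "modality": "compound", "cell_type": "A549",
     "time_point": "48h", "n_plates": 2, "new_physical": True, "imaging_events": 1},
    {"condition": "compound_density_down20", "modality": "compound", "cell_type": "A549",
     "time_point": "48h", "n_plates": 2, "new_physical": True, "imaging_events": 1},
    # photobleaching: the four primary A549 24 h compound plates re-imaged
    # six additional times
    {"condition": "compound_photobleaching", "modality": "compound", "cell_type": "A549",
     "time_point": "24h", "n_plates": 4, "new_physical": False, "imaging_events": 6},
    # sample stability: two ORF replicates x two cell types x 96 h/144 h,
    # re-imaged on days 1, 4, 14 and 28 after first imaging
    {"condition": "orf_stability", "modality": "orf", "cell_type": "U2OS",
     "time_point": "96h", "n_plates": 2, "new_physical": False, "imaging_events": 4},
    {"condition": "orf_stability", "modality": "orf", "cell_type": "U2OS",
     "time_point": "144h", "n_plates": 2, "new_physical": False, "imaging_events": 4},
    {"condition": "orf_stability", "modality": "orf", "cell_type": "A549",
     "time_point": "96h", "n_plates": 2, "new_physical": False, "imaging_events": 4},
    {"condition": "orf_stability", "modality": "orf", "cell_type": "A549",
     "time_point": "144h", "n_plates": 2, "new_physical": False, "imaging_events": 4},
    {"condition": "compound_cas9_line", "modality": "compound", "cell_type": "A549",
     "time_point": "48h", "n_plates": 4, "new_physical": True, "imaging_events": 1},
)


@dataclass
class ExperimentSchedule:
    """Enumeration of plate x condition instances with imaging counts."""

    entries: pd.DataFrame

    @property
    def n_physical_plates(self) -> int:
        return int(self.entries["new_physical"].sum())

    @property
    def n_plates_of_images(self) -> int:
        return int(self.entries["imaging_events"].sum())

    def group_totals(self) -> pd.DataFrame:
        return self.entries.groupby("group").agg(
            physical_plates=("new_physical", "sum"),
            plates_of_images=("imaging_events", "sum"),
        )

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def make_schedule(
    spec: DesignSpec | None = None,
    secondary: Sequence[Mapping] | None = SECONDARY_CONDITIONS,
) -> ExperimentSchedule:
    """Enumerate the primary and secondary plate schedule.

    The primary group crosses each modality's replicate plates with two
    cell types and two (modality-specific) time points, one imaging
    event per plate.  Secondary conditions are supplied as data rows;
    pass an empty sequence for a primary-only schedule.
    """
    spec = spec or DesignSpec()
    replicates = {
        Modality.COMPOUND.value: spec.compound_replicate_plates,
        Modality.CRISPR.value: spec.crispr_replicate_plates,
        Modality.ORF.value: spec.orf_replicate_plates,
    }
    rows: list[dict] = []
    for modality, n_rep in replicates.items():
        for cell in CELL_TYPES:
            for tp in TIME_POINTS[modality]:
                for r in range(1, n_rep + 1):
                    rows.append(
                        {
                            "plate_id": f"{modality}_{cell}_{tp}_r{r}",
                            "modality": modality,
                            "cell_type": cell,
                            "time_point": tp,
                            "replicate": r,
                            "group": "primary",
                            "condition": "baseline",
                            "new_physical": True,
                            "imaging_events": 1,
                        }
                    )
    for cond in secondary or ():
        for r in range(1, int(cond["n_plates"]) + 1):
            rows.append(
                {
                    "plate_id": f"{cond['condition']}_{cond['cell_type']}_{cond['time_point']}_r{r}",
                    "modality": cond["modality"],
                    "cell_type": cond["cell_type"],
                    "time_point": cond["time_point"],
                    "replicate": r,
                    "group": "secondary",
                    "condition": cond["condition"],
                    "new_physical": bool(cond["new_physical"]),
                    "imaging_events": int(cond["imaging_events"]),
                }
            )
    return ExperimentSchedule(entries=pd.DataFrame(rows))


def estimate_image_count(
    schedule: ExperimentSchedule,
    wells: int = WELLS_PER_PLATE,
    sites_per_well: int = 9,
    images_per_site: int = 8,
) -> int:
    """Total images: plates of images x wells x sites x images per site."""
    if min(wells, sites_per_well, images_per_site) <= 0:
        raise ValueError("wells, sites_per_well and images_per_site must be positive")
    return schedule.n_plates_of_images * wells * sites_per_well * images_per_site


# ---------------------------------------------------------------------------
# Recommended dataset splits


@dataclass
class SplitAssignment:
    """Map of perturbation id -> split label (train/validate/test).

    All replicate wells of a perturbation (and all cells of a well)
    inherit the perturbation's split by construction.
    """

    assignment: dict[str, str]

    def __getitem__(self, perturbation_id: str) -> str:
        return self.assignment[perturbation_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Metadata_perturbation": list(self.assignment),
                "split": list(self.assignment.values()),
            }
        )


def make_splits(
    labels: Sequence[PerturbationLabel],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    duplicate_structure_names: Sequence[str] = DUPLICATE_STRUCTURE_COMPOUNDS,
) -> SplitAssignment:
    """Assign perturbations to train/validate/test splits.

    Entities that must travel together are grouped before assignment:
    CRISPR guides of one gene, and compounds whose identifier carries
    one of the known duplicate-structure compound names.  Fractions are
    honoured at the entity (group) level to within one entity; a larger
    forced group triggers a warning, not a failure.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    names = ("train", "validate", "test")

    ids = sorted({lab.perturbation_id for lab in labels})
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    by_gene: dict[str, list[str]] = {}
    for lab in labels:
        if lab.modality == Modality.CRISPR.value and lab.control_type == ControlType.TRT.value:
            (gene,) = lab.target_genes
            by_gene.setdefault(gene, []).append(lab.perturbation_id)
    for members in by_gene.values():
        for other in members[1:]:
            union(members[0], other)
    for name in duplicate_structure_names:
        members = [i for i in ids if name in i]
        for other in members[1:]:
            union(members[0], other)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    entities = sorted(groups.values(), key=lambda g: g[0])

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entities))
    n_entities = len(entities)
    quota = [f * n_entities for f in fractions]
    counts = [0.0, 0.0, 0.0]
    assignment: dict[str, str] = {}
    for idx in order:
        group = entities[idx]
        deficits = [quota[j] - counts[j] for j in range(3)]
        j = int(np.argmax(deficits))
        if counts[j] + 1 > quota[j] + 1:
            warnings.warn(
                f"split {names[j]!r} exceeds its requested share by more than "
                "one entity due to forced grouping",
                stacklevel=2,
            )
        counts[j] += 1
        for pid in group:
            assignment[pid] = names[j]
    return SplitAssignment(assignment=assignment)
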