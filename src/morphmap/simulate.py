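"""Synthetic well-level profile datasets with known ground truth.

The generator emulates the statistical structure the benchmark analysis
relies on, without any real images: replicate wells of perturbations
across plates, three modalities laid out by the plate-map generator,
per-plate negative controls, sister perturbations sharing gene targets
(with optional sign flips for compounds), a signed cross-modality
coupling to each gene's latent phenotype, additive well-position
artifacts, and an inactive fraction of perturbations.

Each gene g carries a unit latent phenotype vector u_g.  A well treated
with an active perturbation of sign s measures

    x = s * effect_size * u + layout(well) + eps,   eps_j ~ N(0, noise_sd),

where u is the (mixed, for multi-target compounds) latent of the
perturbation's targets, and layout(well) is a well-position artifact
shared across plates (a smooth edge gradient plus a per-position
offset).  Inactive perturbations and negative controls have s = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignSpec, PlateMaps, make_plate_maps
from .profiles import (
    ControlType,
    Modality,
    ProfileTable,
    SingleCellTable,
    WellAddress,
    format_targets,
    parse_targets,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic profile generator.

    ``sign_map`` couples each modality to the gene latent; the all
    positive default mirrors the empirical observation that CRISPR,
    ORF and compound profiles of a gene tend to correlate positively.
    ``compound_sign_flip_prob`` is the chance that a sister compound
    opposes its partner's direction.
    """

    n_features: int = 100
    n_genes: int = 20
    compounds_per_gene: int = 2
    guides_per_gene: int = 2
    compound_plates: int = 4
    crispr_plates: int = 4
    orf_plates: int = 2
    orf_replicates_per_plate: int = 2
    effect_size: float = 1.0
    noise_sd: float = 0.1
    layout_effect_sd: float = 0.05
    inactive_fraction: float = 0.2
    sign_map: Mapping[str, int] = field(
        default_factory=lambda: {"compound": 1, "crispr": 1, "orf": 1}
    )
    sign_flip_prob: Mapping[str, float] = field(
        default_factory=lambda: {"compound": 0.0, "crispr": 0.0, "orf": 0.0}
    )
    compound_sign_flip_prob: float = 0.3
    polypharmacology_rate: float = 0.21
    n_dmso_wells: int = 64
    n_crispr_negcon: int = 30
    n_orf_negcon: int = 15
    n_poscon_diverse: int = 0
    cell_type: str = "U2OS"
    timepoint: str = "long"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inactive_fraction", "compound_sign_flip_prob", "polypharmacology_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0 or self.layout_effect_sd < 0:
            raise ValueError("noise_sd and layout_effect_sd must be non-negative")

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            n_target_genes=self.n_genes,
            compounds_per_target=self.compounds_per_gene,
            guides_per_gene=self.guides_per_gene,
            n_single_guide_genes=0,
            n_orf_negcon=self.n_orf_negcon,
            n_crispr_negcon=self.n_crispr_negcon,
            n_dmso_wells=self.n_dmso_wells,
            orf_treatment_replicates_per_plate=self.orf_replicates_per_plate,
            n_poscon_diverse=self.n_poscon_diverse,
            compound_replicate_plates=self.compound_plates,
            crispr_replicate_plates=self.crispr_plates,
            orf_replicate_plates=self.orf_plates,
        )


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    return matrix / np.linalg.norm(matrix, axis=1, keepdims=True)


def _layout_field(
    rng: np.random.Generator, d: int, sd: float
) -> dict[str, np.ndarray]:
    """Well-position artifact vectors shared across all plates.

    A smooth radial edge gradient (strongest in the outer two rows and
    columns, decaying inward) plus an independent per-position offset;
    each component has vector norm ~ ``sd`` so the artifact competes
    with ``effect_size`` on that scale.
    """
    edge_vec = rng.normal(scale=sd / np.sqrt(d), size=d)
    field_map: dict[str, np.ndarray] = {}
    for row_idx, row in enumerate("ABCDEFGHIJKLMNOP"):
        for col in range(1, 25):
            dist = min(row_idx, 15 - row_idx, col - 1, 24 - col)
            weight = float(np.exp(-dist / 2.0))
            offset = rng.normal(scale=sd / np.sqrt(d), size=d)
            field_map[f"{row}{col:02d}"] = weight * edge_vec + offset
    return field_map


def simulate(config: SyntheticConfig) -> tuple[ProfileTable, pd.DataFrame]:
    """Generate a synthetic well-level dataset plus a ground-truth manifest.

    Returns the profile table (all modalities, all replicate plates)
    and a manifest with one row per perturbation: its targets
    (including injected off-targets), activity flag and signed coupling.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    design_seed = int(rng.integers(2**31))
    maps = make_plate_maps(config.design_spec(), seed=design_seed)

    d = config.n_features
    spec = config.design_spec()
    genes = spec.gene_ids()
    latents = {g: u for g, u in zip(genes, _unit_rows(rng.normal(size=(len(genes), d))))}

    # unique perturbations with their designed targets
    pert_rows: dict[str, dict] = {}
    for pm in maps:
        for r in pm.entries.itertuples():
            pid = str(r.Metadata_perturbation)
            if pid not in pert_rows:
                pert_rows[pid] = {
                    "perturbation_id": pid,
                    "modality": str(r.Metadata_modality),
                    "control_type": str(r.Metadata_control_type),
                    "targets": set(parse_targets(r.Metadata_target)),
                    "off_target": "",
                }

    # polypharmacology: a fraction of single-target compounds picks up a
    # second, off-class target mixed 50/50 into its latent
    compounds = sorted(
        p
        for p, rec in pert_rows.items()
        if rec["modality"] == Modality.COMPOUND.value
        and rec["control_type"] == ControlType.TRT.value
    )
    single_target = [p for p in compounds if len(pert_rows[p]["targets"]) == 1]
    n_off = int(round(config.polypharmacology_rate * len(single_target)))
    if n_off and len(genes) > 1:
        for p in rng.choice(single_target, size=n_off, replace=False):
            rec = pert_rows[str(p)]
            candidates = [g for g in genes if g not in rec["targets"]]
            off = str(rng.choice(candidates))
            rec["targets"].add(off)
            rec["off_target"] = off

    # activity, sign and latent direction per perturbation
    sister_rank: dict[str, int] = {}
    per_gene: dict[str, list[str]] = {}
    for p in compounds:
        g = min(pert_rows[p]["targets"])
        per_gene.setdefault(g, []).append(p)
    for g, members in per_gene.items():
        for k, p in enumerate(sorted(members)):
            sister_rank[p] = k

    for pid in sorted(pert_rows):
        rec = pert_rows[pid]
        if rec["control_type"] != ControlType.TRT.value:
            rec.update(active=False, sign=0)
            continue
        rec["active"] = bool(rng.random() >= config.inactive_fraction)
        modality = rec["modality"]
        sign = int(config.sign_map.get(modality, 1))
        if rng.random() < float(config.sign_flip_prob.get(modality, 0.0)):
            sign = -sign
        if (
            modality == Modality.COMPOUND.value
            and sister_rank.get(pid, 0) > 0
            and rng.random() < config.compound_sign_flip_prob
        ):
            sign = -sign
        rec["sign"] = sign if rec["active"] else 0
        if rec["targets"]:
            mix = np.mean([latents[g] for g in sorted(rec["targets"])], axis=0)
            rec["latent"] = mix / np.linalg.norm(mix)
        else:
            rec["latent"] = np.zeros(d)

    layout = _layout_field(rng, d, config.layout_effect_sd)

    plate_counts = {
        Modality.COMPOUND.value: config.compound_plates,
        Modality.CRISPR.value: config.crispr_plates,
        Modality.ORF.value: config.orf_plates,
    }
    frames: list[pd.DataFrame] = []
    feature_names = [f"F{i:03d}" for i in range(1, d + 1)]
    for pm in maps:
        n_rows = len(pm.entries)
        base = np.zeros((n_rows, d))
        for i, r in enumerate(pm.entries.itertuples()):
            rec = pert_rows[str(r.Metadata_perturbation)]
            if rec.get("sign", 0) != 0:
                base[i] = rec["sign"] * config.effect_size * rec["latent"]
        layout_block = np.stack(
            [layout[str(w)] for w in pm.entries["Metadata_Well"]]
        )
        for rep in range(1, plate_counts[pm.modality] + 1):
            plate_id = f"{pm.modality}_r{rep}"
            noise = rng.normal(scale=config.noise_sd, size=(n_rows, d))
            values = base + layout_block + noise
            meta = pd.DataFrame(
                {
                    "Metadata_Plate": plate_id,
                    "Metadata_Well": pm.entries["Metadata_Well"].to_numpy(),
                    "Metadata_perturbation": pm.entries["Metadata_perturbation"].to_numpy(),
                    "Metadata_modality": pm.modality,
                    "Metadata_control_type": pm.entries["Metadata_control_type"].to_numpy(),
                    "Metadata_target": [
                        format_targets(pert_rows[str(p)]["targets"])
                        for p in pm.entries["Metadata_perturbation"]
                    ],
                    "Metadata_cell_type": config.cell_type,
                    "Metadata_timepoint": config.timepoint,
                }
            )
            frames.append(
                pd.concat([meta, pd.DataFrame(values, columns=feature_names)], axis=1)
            )
    table = ProfileTable(pd.concat(frames, ignore_index=True))

    manifest = pd.DataFrame(
        [
            {
                "perturbation_id": rec["perturbation_id"],
                "modality": rec["modality"],
                "control_type": rec["control_type"],
                "targets": format_targets(rec["targets"]),
                "off_target": rec["off_target"],
                "active": bool(rec.get("active", False)),
                "sign": int(rec.get("sign", 0)),
            }
            for rec in (pert_rows[p] for p in sorted(pert_rows))
        ]
    )
    return table, manifest


def simulate_single_cells(
    config: SyntheticConfig,
    cells_per_well: int,
    cell_noise_sd: float | None = None,
) -> SingleCellTable:
    """Expand each synthetic well into per-cell profiles.

    Cell profiles are the well's mean profile plus independent per-cell
    noise, so the per-well median converges to the well profile as
    ``cells_per_well`` grows.
    """
    if cells_per_well < 1:
        raise ValueError("cells_per_well must be at least 1")
    table, _ = simulate(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 7)))
    sd = config.noise_sd if cell_noise_sd is None else cell_noise_sd
    wells = table.data
    feats = table.features
    reps = np.repeat(np.arange(len(wells)), cells_per_well)
    values = feats[reps] + rng.normal(scale=sd, size=(len(reps), feats.shape[1]))
    meta = wells[table.metadata_columns].iloc[reps].reset_index(drop=True)
    meta.insert(
        2, "Metadata_cell_id", [f"c{i % cells_per_well + 1:05d}" for i in range(len(reps))]
    )
    df = pd.concat(
        [meta, pd.DataFrame(values, columns=table.feature_names)], axis=1
    )
    return SingleCellTable(df)
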