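"""Generate the benchmark plate maps, experiment schedule and data splits.

Builds the three 384-well plate layouts (compound, CRISPR, ORF) under
the default design, enumerates the imaging schedule, estimates the
total image count, and assigns guide-aware train/validate/test splits.
"""

from morphmap import (
    DesignSpec,
    estimate_image_count,
    make_plate_maps,
    make_schedule,
    make_splits,
)

spec = DesignSpec()
maps = make_plate_maps(spec, seed=0)

print("Compound plate:", maps.compound.control_counts().to_dict())
# 286 singlicate treatment compounds, 17 diverse positive-control
# compounds in duplicate (34 wells), and 64 DMSO solvent wells: 384 wells.

print("CRISPR plate:", maps.crispr.control_counts().to_dict(),
      f"({maps.crispr.n_empty} empty wells)")
print("ORF plate:", maps.orf.control_counts().to_dict(),
      f"({maps.orf.n_empty} empty wells)")

sched = make_schedule(spec)
print("\nSchedule:", sched.group_totals().to_string())
print("Physical plates:", sched.n_physical_plates,
      "| plates of images:", sched.n_plates_of_images)
# 40 primary plates imaged once; 11 extra physical plates plus
# re-imaging events bring the total to 107 plates of images.

n_images = estimate_image_count(sched)
print(f"Estimated images (9 sites/well, 8 images/site): {n_images:,}")
# just under 3 million individual microscope images.

splits = make_splits(maps.crispr.labels(), fractions=(0.6, 0.2, 0.2), seed=1)
frame = splits.to_frame()
print("\nSplit sizes:", frame["split"].value_counts().to_dict())
# Both guides of a gene always land in the same split, so matching
# tasks never leak a gene across the train/test boundary.
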