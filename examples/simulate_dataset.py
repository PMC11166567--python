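"""Generate a synthetic profiling dataset and write it to disk.

Produces a well-level profile table covering all three modalities and
their replicate plates, plus a ground-truth manifest recording each
perturbation's activity, sign and (possibly injected off-)targets.
"""

from pathlib import Path

from morphmap import SyntheticConfig, simulate, write_profiles

out = Path("scratch/synthetic_dataset")
out.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(n_genes=20, seed=0)
table, manifest = simulate(cfg)

write_profiles(table, out / "profiles.csv")
manifest.to_csv(out / "ground_truth.csv", index=False)

print(table)
print("plates:", sorted(table.data["Metadata_Plate"].unique()))
n_active = int(manifest["active"].sum())
print(f"{len(manifest)} unique perturbations; {n_active} truly active; "
      f"{(manifest['off_target'] != '').sum()} with injected off-targets")
print(f"written to {out}/")
# profiles.csv follows the Metadata_-prefix convention and round-trips
# through read_profiles; ground_truth.csv is the evaluation key.
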