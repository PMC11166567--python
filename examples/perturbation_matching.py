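"""Perturbation matching within and across modalities.

After filtering to phenotypically active perturbations, sister
compounds (same annotated gene target) try to retrieve each other with
absolute cosine similarity, sister CRISPR guides with signed
similarity, and compounds try to retrieve the genetic reagents of
their targets (absolute similarity; gene-compound pairs may mimic or
oppose).
"""

from morphmap import (
    SyntheticConfig,
    activity_filter,
    simulate,
    task_cross_modality,
    task_replicate_detection,
    task_sister_matching,
)

cfg = SyntheticConfig(n_genes=30, inactive_fraction=0.1, seed=8)
table, _ = simulate(cfg)

active = {}
for modality in ("compound", "crispr"):
    sub = table.subset(modality=modality)
    act = task_replicate_detection(sub, n_perm=9_999, seed=9)
    active[modality] = activity_filter(sub, act)
    print(f"{modality}: {act.fraction_retrieved:.2f} of perturbations active")

sis_cpd = task_sister_matching(active["compound"], "compound", n_perm=9_999, seed=9)
sis_cri = task_sister_matching(active["crispr"], "crispr", n_perm=9_999, seed=9)
print(f"sister-compound matching: fraction retrieved = {sis_cpd.fraction_retrieved:.2f}")
print(f"sister-guide matching:    fraction retrieved = {sis_cri.fraction_retrieved:.2f}")
# fraction of target genes whose sister perturbations retrieve each
# other better than chance - the within-modality matching benchmark.

cross = task_cross_modality(active["compound"], active["crispr"], n_perm=9_999, seed=9)
print(f"gene-compound matching:   fraction retrieved = {cross.fraction_retrieved:.2f}")
print("top matched genes:", cross.per_class.nsmallest(3, "combined_q")["class_id"].tolist())
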