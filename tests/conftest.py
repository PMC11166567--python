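import numpy as np
import pandas as pd
import pytest

from morphmap import ProfileTable


def build_table(
    n_plates: int = 2,
    perturbations: dict[str, int] | None = None,
    n_negcon: int = 4,
    n_features: int = 5,
    seed: int = 0,
    modality: str = "compound",
    targets: dict[str, str] | None = None,
) -> ProfileTable:
    """Small deterministic profile table: each perturbation replicated
    once per plate, plus negative-control wells, random features."""
    rng = np.random.default_rng(seed)
    perturbations = perturbations or {"cpdA": 1, "cpdB": 1}
    targets = targets or {}
    rows = []
    for p in range(1, n_plates + 1):
        col = 1
        for pert, copies in perturbations.items():
            for _ in range(copies):
                rows.append(("P%d" % p, f"A{col:02d}", pert, "trt", targets.get(pert, "")))
                col += 1
        for j in range(n_negcon):
            rows.append(("P%d" % p, f"B{j + 1:02d}", "DMSO", "negcon", ""))
    meta = pd.DataFrame(
        rows,
        columns=[
            "Metadata_Plate",
            "Metadata_Well",
            "Metadata_perturbation",
            "Metadata_control_type",
            "Metadata_target",
        ],
    )
    meta["Metadata_modality"] = modality
    meta["Metadata_cell_type"] = "U2OS"
    meta["Metadata_timepoint"] = "long"
    feats = pd.DataFrame(
        rng.normal(size=(len(meta), n_features)),
        columns=[f"F{i:03d}" for i in range(1, n_features + 1)],
    )
    return ProfileTable(pd.concat([meta, feats], axis=1))


@pytest.fixture
def toy_table() -> ProfileTable:
    return build_table()


def ap_by_definition(relevance) -> float:
    """Independent oracle: AP = sum_k (R_k - R_{k-1}) P_k, explicit loop."""
    relevance = list(relevance)
    m = sum(relevance)
    assert m > 0
    ap = 0.0
    tp = 0
    prev_recall = 0.0
    for k, rel in enumerate(relevance, start=1):
        if rel:
            tp += 1
        recall = tp / m
        precision = tp / k
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
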