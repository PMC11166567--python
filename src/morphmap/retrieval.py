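"""Retrieval-based benchmarking: average precision with permutation
significance, FDR control, per-class summaries and the three benchmark
task assemblies.

For a query profile, candidate profiles are ranked by cosine similarity
(signed, or absolute where both correlation directions count as a
match).  The quality of the ranking is the average precision

    AP = sum_k (R_k - R_{k-1}) P_k,

the precision averaged over each rank k at which recall changes.  Its
significance is assessed against the permutation null obtained by
shuffling the rank list: the null depends only on the number of
positives m and the list length n, so one shared, seeded null sample is
drawn per (m, n) configuration.  Per-query p-values are adjusted with
the Benjamini-Hochberg step-up within a task; queries are grouped into
classes (perturbations, or target genes) summarized by the mean AP and
the geometric mean of member q-values.  The headline number of a task
is the *fraction retrieved*: the fraction of classes with combined
q-value below 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .profiles import ControlType, Modality, ProfileTable, parse_targets

logger = logging.getLogger(__name__)

SimilarityMode = Literal["signed", "absolute"]
DEFAULT_N_PERM = 100_000
SIGNIFICANCE_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Similarity


def cosine_similarity(a: np.ndarray, b: np.ndarray, mode: SimilarityMode = "signed") -> float:
    """Cosine similarity of two vectors; absolute value optionally."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    s = float(np.dot(a, b) / (na * nb))
    return abs(s) if mode == "absolute" else s


def cosine_matrix(
    queries: np.ndarray, candidates: np.ndarray, mode: SimilarityMode = "signed"
) -> np.ndarray:
    """Pairwise cosine similarities, rows = queries, columns = candidates."""
    q = np.asarray(queries, dtype=float)
    c = np.asarray(candidates, dtype=float)
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    cn = np.linalg.norm(c, axis=1, keepdims=True)
    if (qn == 0).any() or (cn == 0).any():
        raise ValueError("cosine similarity undefined for a zero vector")
    sims = (q / qn) @ (c / cn).T
    return np.abs(sims) if mode == "absolute" else sims


# ---------------------------------------------------------------------------
# Average precision


@dataclass
class RankList:
    """Candidates for one query: similarities plus binary relevance."""

    query_id: str
    similarities: np.ndarray
    relevant: np.ndarray
    similarity_mode: SimilarityMode = "signed"

    def __post_init__(self) -> None:
        self.similarities = np.asarray(self.similarities, dtype=float)
        self.relevant = np.asarray(self.relevant, dtype=bool)
        if self.similarities.shape != self.relevant.shape:
            raise ValueError("similarities and relevance labels must align")
        if not self.relevant.any():
            raise ValueError(f"rank list for {self.query_id!r} has no relevant candidate")
        if self.relevant.all():
            raise ValueError(f"rank list for {self.query_id!r} has no non-relevant candidate")

    @property
    def n(self) -> int:
        return int(self.similarities.size)

    @property
    def m(self) -> int:
        return int(self.relevant.sum())

    def sorted_relevance(self) -> np.ndarray:
        """Relevance labels ordered by descending similarity (stable)."""
        order = np.argsort(-self.similarities, kind="stable")
        return self.relevant[order]


def average_precision_from_relevance(relevance: np.ndarray) -> float:
    """AP of an already-ordered binary relevance vector."""
    relevance = np.asarray(relevance, dtype=bool)
    m = int(relevance.sum())
    if m == 0:
        raise ValueError("average precision undefined without relevant candidates")
    ranks = np.flatnonzero(relevance) + 1  # 1-based ranks of the positives
    precision_at_hits = np.arange(1, m + 1) / ranks
    # recall increments by 1/m at each hit, so AP is the mean precision there
    return float(precision_at_hits.mean())


def average_precision(ranklist: RankList) -> float:
    """AP = sum_k (R_k - R_{k-1}) P_k over the similarity-ordered list."""
    return average_precision_from_relevance(ranklist.sorted_relevance())


# ---------------------------------------------------------------------------
# Permutation null


class NullDistributionCache:
    """Shared permutation nulls for AP, keyed by (m, n).

    Shuffling a rank list makes the positive positions a uniform random
    m-subset of the n ranks, so the null depends only on (m, n); one
    seeded draw per configuration is shared across queries.
    """

    def __init__(self, n_perm: int = DEFAULT_N_PERM, seed: int = 0):
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        self.n_perm = int(n_perm)
        self.seed = int(seed)
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def null_aps(self, m: int, n: int) -> np.ndarray:
        """Sorted null AP sample for m positives in a list of length n."""
        if not 1 <= m < n:
            raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
        key = (m, n)
        if key not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(m, n))
            )
            # positions of the m positives: first m entries of a random
            # permutation of 0..n-1, drawn for all permutations at once
            u = rng.random((self.n_perm, n))
            positions = np.argpartition(u, m - 1, axis=1)[:, :m]
            ranks = np.sort(positions, axis=1) + 1
            hits = np.arange(1, m + 1)
            aps = (hits / ranks).mean(axis=1)
            self._cache[key] = np.sort(aps)
        return self._cache[key]

    def p_value(self, ap: float, m: int, n: int) -> float:
        """p = (1 + #{null AP >= observed}) / (n_perm + 1)."""
        null = self.null_aps(m, n)
        n_ge = null.size - np.searchsorted(null, ap - 1e-12, side="left")
        return float((1 + n_ge) / (self.n_perm + 1))


def permutation_p(
    ap: float,
    m: int,
    n: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    cache: NullDistributionCache | None = None,
) -> float:
    """Permutation p-value of an AP score against the (m, n) null."""
    cache = cache or NullDistributionCache(n_perm=n_perm, seed=seed)
    return cache.p_value(ap, m, n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Scores and task summaries


@dataclass(frozen=True)
class RetrievalScore:
    query_id: str
    class_id: str
    ap: float
    p_value: float
    q_value: float = math.nan


@dataclass
class TaskSummary:
    """Per-class retrieval results and the fraction-retrieved headline."""

    scores: pd.DataFrame  # query_id, class_id, ap, p_value, q_value
    per_class: pd.DataFrame  # class_id, map, combined_q, n_queries
    threshold: float = SIGNIFICANCE_THRESHOLD

    @property
    def fraction_retrieved(self) -> float:
        if len(self.per_class) == 0:
            return math.nan
        return float((self.per_class["combined_q"] < self.threshold).mean())

    def retrieved_classes(self) -> list[str]:
        sel = self.per_class["combined_q"] < self.threshold
        return self.per_class.loc[sel, "class_id"].tolist()


def summarize_task(
    scores: Sequence[RetrievalScore] | pd.DataFrame,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> TaskSummary:
    """Aggregate per-query scores into per-class mAP and combined q.

    The combined q of a class is the geometric mean of its members'
    q-values; a class is *retrieved* when that falls below ``threshold``.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = pd.DataFrame([s.__dict__ for s in scores])
    if df.empty:
        raise ValueError("cannot summarize an empty score list")
    if df["q_value"].isna().any():
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    per_class = (
        df.groupby("class_id")
        .agg(
            map=("ap", "mean"),
            combined_q=("q_value", lambda q: float(np.exp(np.mean(np.log(q))))),
            n_queries=("ap", "size"),
        )
        .reset_index()
        .sort_values("class_id", ignore_index=True)
    )
    return TaskSummary(scores=df, per_class=per_class, threshold=threshold)


# ---------------------------------------------------------------------------
# Task assemblies


def _require_single_condition(table: ProfileTable) -> None:
    for col in ("Metadata_cell_type", "Metadata_timepoint", "Metadata_modality"):
        values = table.data[col].unique()
        if len(values) > 1:
            raise ValueError(
                f"task requires a single condition; {col} has values {sorted(map(str, values))}"
            )


def task_replicate_detection(
    table: ProfileTable,
    position_match: Literal["same", "different", "any"] = "any",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    cache: NullDistributionCache | None = None,
) -> TaskSummary:
    """Phenotypic activity: retrieve a well's replicates from negcons.

    Each non-control well is a query; positives are its replicate wells
    (optionally restricted to the same, or to different, well
    addresses), negatives are all negative-control wells, similarity is
    signed cosine.  Classes are perturbations.
    """
    _require_single_condition(table)
    df = table.data
    feats = table.features
    is_negcon = (df["Metadata_control_type"] == ControlType.NEGCON.value).to_numpy()
    if not is_negcon.any():
        raise ValueError("no negative-control wells in table")
    neg_idx = np.flatnonzero(is_negcon)
    cache = cache or NullDistributionCache(n_perm=n_perm, seed=seed)

    perts = df["Metadata_perturbation"].to_numpy()
    wells = df["Metadata_Well"].to_numpy()
    rows: list[dict] = []
    for pert in pd.unique(perts[~is_negcon]):
        members = np.flatnonzero((perts == pert) & ~is_negcon)
        if members.size < 2:
            logger.warning("perturbation %r has <2 replicates; skipped", pert)
            continue
        for q in members:
            others = members[members != q]
            if position_match == "same":
                pos = others[wells[others] == wells[q]]
            elif position_match == "different":
                pos = others[wells[others] != wells[q]]
            else:
                pos = others
            if pos.size == 0:
                continue
            cand = np.concatenate([pos, neg_idx])
            sims = cosine_matrix(feats[q][None, :], feats[cand], mode="signed")[0]
            relevant = np.zeros(cand.size, dtype=bool)
            relevant[: pos.size] = True
            rl = RankList(f"{pert}:{df['Metadata_Plate'].iloc[q]}:{wells[q]}", sims, relevant)
            ap = average_precision(rl)
            rows.append(
                {
                    "query_id": rl.query_id,
                    "class_id": str(pert),
                    "ap": ap,
                    "p_value": cache.p_value(ap, rl.m, rl.n),
                    "q_value": math.nan,
                }
            )
    if not rows:
        raise ValueError("no query produced a rank list (no replicated perturbations)")
    scores = pd.DataFrame(rows)
    scores["q_value"] = bh_adjust(scores["p_value"].to_numpy())
    return summarize_task(scores, threshold=threshold)


def activity_filter(
    table: ProfileTable,
    summary: TaskSummary,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    keep_controls: bool = False,
) -> ProfileTable:
    """Keep perturbations whose replicate-detection combined q <= threshold.

    Perturbations indistinguishable from negative controls (q above the
    threshold) are removed before the matching tasks.
    """
    active = set(
        summary.per_class.loc[
            summary.per_class["combined_q"] <= threshold, "class_id"
        ].astype(str)
    )
    df = table.data
    mask = df["Metadata_perturbation"].astype(str).isin(active)
    if keep_controls:
        mask |= df["Metadata_control_type"] != ControlType.TRT.value
    out = df.loc[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError("no perturbation passed the activity filter")
    return ProfileTable(out)


def consensus_profiles(table: ProfileTable) -> ProfileTable:
    """Median profile per perturbation (over its replicate wells)."""
    df = table.data
    feats = table.feature_names
    grouped = df.groupby("Metadata_perturbation", sort=True)
    med = grouped[feats].median()
    meta_cols = [
        c
        for c in table.metadata_columns
        if c not in ("Metadata_perturbation", "Metadata_Plate", "Metadata_Well")
    ]
    meta = grouped[meta_cols].first()
    out = meta.join(med).reset_index()
    out["Metadata_Plate"] = "consensus"
    out["Metadata_Well"] = "A01"
    return ProfileTable(out)


def _targets_per_row(df: pd.DataFrame) -> list[frozenset[str]]:
    return [parse_targets(t) for t in df["Metadata_target"]]


def task_sister_matching(
    table: ProfileTable,
    modality: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    use_consensus: bool = True,
    cache: NullDistributionCache | None = None,
) -> TaskSummary:
    """Within-modality matching of sister perturbations sharing a target.

    Queries are (consensus) profiles of active perturbations of one
    modality; positives share at least one annotated target gene,
    negatives share none.  Compounds use absolute cosine similarity
    (sister compounds may correlate either way); CRISPR guides use
    signed similarity.  Classes are target genes.  ORF is rejected:
    with a single reagent per gene there are no sisters.
    """
    if modality == Modality.ORF.value:
        raise ValueError("sister matching undefined for ORF: one reagent per gene")
    mode: SimilarityMode = "absolute" if modality == Modality.COMPOUND.value else "signed"
    sub = table.subset(modality=modality, control_type=ControlType.TRT.value)
    cons = consensus_profiles(sub) if use_consensus else sub
    df = cons.data
    feats = cons.features
    targets = _targets_per_row(df)
    cache = cache or NullDistributionCache(n_perm=n_perm, seed=seed)

    gene_counts: dict[str, int] = {}
    for t in targets:
        for g in t:
            gene_counts[g] = gene_counts.get(g, 0) + 1

    sims_all = cosine_matrix(feats, feats, mode=mode)
    rows: list[dict] = []
    for i in range(len(df)):
        shares = np.array(
            [bool(targets[i] & targets[j]) if j != i else False for j in range(len(df))]
        )
        others = np.flatnonzero(np.arange(len(df)) != i)
        relevant = shares[others]
        if not relevant.any() or relevant.all():
            continue
        rl = RankList(str(df["Metadata_perturbation"].iloc[i]), sims_all[i, others], relevant, mode)
        ap = average_precision(rl)
        p = cache.p_value(ap, rl.m, rl.n)
        for g in sorted(targets[i]):
            if gene_counts.get(g, 0) >= 2:
                rows.append(
                    {"query_id": rl.query_id, "class_id": g, "ap": ap,
                     "p_value": p, "q_value": math.nan}
                )
    if not rows:
        raise ValueError("no sister pairs available for matching")
    scores = pd.DataFrame(rows)
    scores["q_value"] = bh_adjust(scores["p_value"].to_numpy())
    return summarize_task(scores, threshold=threshold)


def task_cross_modality(
    table_cpd: ProfileTable,
    table_gen: ProfileTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    use_consensus: bool = True,
    cache: NullDistributionCache | None = None,
) -> TaskSummary:
    """Gene-compound matching across modalities.

    Each active compound queries the active genetic perturbations of
    one modality; positives target one of the compound's annotated
    genes.  Absolute cosine similarity throughout (gene-compound pairs
    may mimic or oppose).  Classes are genes.
    """
    cpd = table_cpd.subset(control_type=ControlType.TRT.value)
    gen = table_gen.subset(control_type=ControlType.TRT.value)
    cons_c = consensus_profiles(cpd) if use_consensus else cpd
    cons_g = consensus_profiles(gen) if use_consensus else gen
    if set(cons_c.feature_names) != set(cons_g.feature_names):
        raise ValueError("compound and genetic tables must share a feature space")
    feats_g = cons_g.data[cons_c.feature_names].to_numpy(dtype=float)

    t_c = _targets_per_row(cons_c.data)
    t_g = _targets_per_row(cons_g.data)
    genes_present = {g for t in t_g for g in t}
    sims = cosine_matrix(cons_c.features, feats_g, mode="absolute")
    cache = cache or NullDistributionCache(n_perm=n_perm, seed=seed)

    rows: list[dict] = []
    for i, tc in enumerate(t_c):
        relevant = np.array([bool(tc & tg) for tg in t_g])
        if not relevant.any() or relevant.all():
            continue
        rl = RankList(
            str(cons_c.data["Metadata_perturbation"].iloc[i]), sims[i], relevant, "absolute"
        )
        ap = average_precision(rl)
        p = cache.p_value(ap, rl.m, rl.n)
        for g in sorted(tc & genes_present):
            rows.append(
                {"query_id": rl.query_id, "class_id": g, "ap": ap,
                 "p_value": p, "q_value": math.nan}
            )
    if not rows:
        raise ValueError("no gene-compound pairs available for matching")
    scores = pd.DataFrame(rows)
    scores["q_value"] = bh_adjust(scores["p_value"].to_numpy())
    return summarize_task(scores, threshold=threshold)
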