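"""Directionality of cross-modality matching.

Do reagent pairs that target the same gene (e.g. a CRISPR guide and an
ORF construct, or a compound and a genetic reagent) correlate
positively (mimic) or negatively (oppose)?  Signed cosine similarities
of same-gene pairs are compared with the null of different-gene pairs:
the 5th and 95th percentiles of the null define the tails, and a
Fisher's exact test on the beyond-threshold counts asks whether true
pairs are more likely to be positively than negatively correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .profiles import ProfileTable
from .retrieval import cosine_matrix, _targets_per_row


@dataclass
class DirectionalityResult:
    """Tail counts of true pairs against the different-gene null."""

    true_similarities: np.ndarray
    null_similarities: np.ndarray
    lo_threshold: float  # 5th percentile of the null
    hi_threshold: float  # 95th percentile of the null
    n_above: int  # true pairs above hi_threshold
    n_below: int  # true pairs below lo_threshold
    n_null_above: int
    n_null_below: int
    fisher_odds_ratio: float
    fisher_p: float
    no_signal: bool = False

    @property
    def pct_above(self) -> float:
        return 100.0 * self.n_above / self.true_similarities.size

    @property
    def pct_below(self) -> float:
        return 100.0 * self.n_below / self.true_similarities.size

    @property
    def direction(self) -> str:
        """'positive' when true pairs favour the upper tail, else 'negative'."""
        if self.no_signal or self.n_above == self.n_below:
            return "none"
        return "positive" if self.n_above > self.n_below else "negative"


def pair_similarities(
    table_a: ProfileTable, table_b: ProfileTable
) -> tuple[np.ndarray, np.ndarray]:
    """Signed cosines of all cross-table reagent pairs, split by annotation.

    Tables hold one (consensus) profile per reagent with annotated
    target genes.  Pairs sharing at least one gene are *true* pairs;
    pairs sharing none form the null.
    """
    if set(table_a.feature_names) != set(table_b.feature_names):
        raise ValueError("tables must share a feature space")
    feats_b = table_b.data[table_a.feature_names].to_numpy(dtype=float)
    sims = cosine_matrix(table_a.features, feats_b, mode="signed")
    t_a = _targets_per_row(table_a.data)
    t_b = _targets_per_row(table_b.data)
    shared = np.array(
        [[bool(ta & tb) for tb in t_b] for ta in t_a], dtype=bool
    )
    true = sims[shared]
    null = sims[~shared]
    if true.size == 0:
        raise ValueError("no cross-table pairs share a target gene")
    return true, null


def directionality_test(
    true_similarities: np.ndarray,
    null_similarities: np.ndarray,
    lo_percentile: float = 5.0,
    hi_percentile: float = 95.0,
) -> DirectionalityResult:
    """Tail test of true-pair similarities against the different-gene null.

    Thresholds are the null's percentiles (linear interpolation).  The
    contingency table [[true above, true below], [null above, null
    below]] enters a two-sided Fisher's exact test: an odds ratio above
    one means true pairs beyond the thresholds are preferentially
    positively correlated.
    """
    true = np.asarray(true_similarities, dtype=float)
    null = np.asarray(null_similarities, dtype=float)
    if null.size < 20:
        raise ValueError("need at least 20 null pairs for stable percentiles")
    lo = float(np.percentile(null, lo_percentile))
    hi = float(np.percentile(null, hi_percentile))
    n_above = int((true > hi).sum())
    n_below = int((true < lo).sum())
    n_null_above = int((null > hi).sum())
    n_null_below = int((null < lo).sum())
    if n_above == 0 and n_below == 0:
        return DirectionalityResult(
            true, null, lo, hi, 0, 0, n_null_above, n_null_below,
            fisher_odds_ratio=float("nan"), fisher_p=1.0, no_signal=True,
        )
    table = np.array([[n_above, n_below], [n_null_above, n_null_below]])
    odds, p = fisher_exact(table, alternative="two-sided")
    return DirectionalityResult(
        true, null, lo, hi, n_above, n_below, n_null_above, n_null_below,
        fisher_odds_ratio=float(odds), fisher_p=float(p),
    )
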