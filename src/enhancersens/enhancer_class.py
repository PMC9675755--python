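"""The enhancer taxonomy: activation targets, mutation-sensitivity groups,
accessibility classes, remodeling calls and ROC evaluation of predictors.

A *target enhancer* is a binding site that gains H3K27ac and/or Med1 signal
upon expression of the wild-type receptor (padj below the FDR cut, positive
log2 fold change). Target enhancers are then partitioned by which mutant
(E379K in the ligand-binding domain, R212Q in the hinge) loses binding:
``dual`` (both), ``E379K_only``, ``R212Q_only``, ``gained`` (binding gained
by a mutant, lost by none), or ``insensitive``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("enhancersens")

SENSITIVITY_GROUPS = ("dual", "E379K_only", "R212Q_only", "gained", "insensitive", "other")


@dataclass
class EnhancerRecord:
    peak_id: str
    gain_h3k27ac: bool = False
    gain_med1: bool = False
    sensitivity_group: str = "other"
    accessibility: str = "inaccessible"
    remodeled_by_wt: bool = False
    basal_med1: float = float("nan")
    basal_h3k27ac: float = float("nan")
    motif_score: float = float("nan")
    segment_scores: dict = field(default_factory=dict)

    @property
    def is_target(self) -> bool:
        return self.gain_h3k27ac or self.gain_med1


def define_target_enhancers(
    diff_h3k27ac: pd.DataFrame,
    diff_med1: pd.DataFrame,
    fdr: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag gains per mark and the target union, with Venn counts.

    Returns (flags indexed by feature id with boolean columns gain_h3k27ac,
    gain_med1, is_target) and counts {n_h3k27ac, n_med1, n_both, n_union}.
    """
    a = diff_h3k27ac.set_index("id")
    b = diff_med1.set_index("id")
    if set(a.index) != set(b.index):
        raise ValueError("H3K27ac and Med1 results cover different feature sets")
    b = b.reindex(a.index)
    gain_h3 = (a["padj"] < fdr) & (a["log2FoldChange"] > 0)
    gain_med1 = (b["padj"] < fdr) & (b["log2FoldChange"] > 0)
    flags = pd.DataFrame(
        {
            "gain_h3k27ac": gain_h3,
            "gain_med1": gain_med1,
            "is_target": gain_h3 | gain_med1,
        }
    )
    counts = venn_union(int(gain_h3.sum()), int(gain_med1.sum()), int((gain_h3 & gain_med1).sum()))
    return flags, counts


def venn_union(n_a: int, n_b: int, n_both: int) -> dict[str, int]:
    """Inclusion-exclusion bookkeeping for two overlapping gain sets."""
    if n_both > min(n_a, n_b):
        raise ValueError("overlap exceeds a marginal")
    return {
        "n_h3k27ac": n_a,
        "n_med1": n_b,
        "n_both": n_both,
        "n_union": n_a + n_b - n_both,
    }


def classify_sensitivity(
    diff_e379k: pd.DataFrame,
    diff_r212q: pd.DataFrame,
    target_ids: list[str],
    padj_max: float = 0.05,
    change_frac: float = 0.25,
) -> tuple[pd.Series, dict[str, int]]:
    """Assign each target enhancer its mutation-sensitivity group.

    Lost binding by a mutant: padj < padj_max and the mutant/WT intensity
    ratio down by at least ``change_frac`` (L2FC <= log2(1 - change_frac));
    gained is symmetric (ratio up by at least the same fraction). Groups are
    disjoint and exhaustive over the supplied targets; enhancers missing from
    either result are classified ``other`` and logged.
    """
    lo = np.log2(1 - change_frac)
    hi = np.log2(1 + change_frac)
    e = diff_e379k.set_index("id")
    r = diff_r212q.set_index("id")
    groups: dict[str, str] = {}
    for pid in target_ids:
        if pid not in e.index or pid not in r.index:
            log.warning("target %s missing from a mutant contrast; classified other", pid)
            groups[pid] = "other"
            continue
        lost_e = (e.at[pid, "padj"] < padj_max) and (e.at[pid, "log2FoldChange"] <= lo)
        lost_r = (r.at[pid, "padj"] < padj_max) and (r.at[pid, "log2FoldChange"] <= lo)
        gained_e = (e.at[pid, "padj"] < padj_max) and (e.at[pid, "log2FoldChange"] >= hi)
        gained_r = (r.at[pid, "padj"] < padj_max) and (r.at[pid, "log2FoldChange"] >= hi)
        if lost_e and lost_r:
            groups[pid] = "dual"
        elif lost_e:
            groups[pid] = "E379K_only"
        elif lost_r:
            groups[pid] = "R212Q_only"
        elif gained_e or gained_r:
            groups[pid] = "gained"
        else:
            groups[pid] = "insensitive"
    series = pd.Series(groups, name="sensitivity_group")
    counts = {g: int((series == g).sum()) for g in SENSITIVITY_GROUPS}
    return series, counts


def venn_sensitivity(lost_a: int, lost_b: int, dual: int) -> dict[str, int]:
    """Split two lost-binding totals into dual and mutant-only counts."""
    if dual > min(lost_a, lost_b):
        raise ValueError("dual count exceeds a marginal")
    return {"dual": dual, "a_only": lost_a - dual, "b_only": lost_b - dual}


def classify_accessibility(
    atac_normalized: pd.Series,
    threshold: float = 15.0,
) -> pd.Series:
    """Accessible iff the mean normalized nucleosome-free count exceeds the
    threshold; a count exactly at the threshold is inaccessible (the two
    strict inequalities of the published cut leave the boundary unassigned,
    pinned here to inaccessible)."""
    return pd.Series(
        np.where(atac_normalized > threshold, "accessible", "inaccessible"),
        index=atac_normalized.index,
        name="accessibility",
    )


def define_remodeled(diff_atac: pd.DataFrame, padj_max: float = 0.05) -> pd.Series:
    """Remodeled by WT := padj < padj_max and positive accessibility L2FC."""
    d = diff_atac.set_index("id")
    flags = (d["padj"] < padj_max) & (d["log2FoldChange"] > 0)
    flags.name = "remodeled_by_wt"
    return flags


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    ``labels`` are boolean (True = positive class); ties in scores
    contribute 1/2. Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
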