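"""Gene-level target definitions, mutation-sensitive gene classes, and the
resampling-normalized enhancer-vicinity enrichment.

Differentially expressed genes are those with padj below the cut and a fold
change beyond the minimum in either direction upon wild-type receptor
expression. Induced genes are further classified by which mutant fails to
induce them. Vicinity enrichment compares the number of enhancers near a
gene group's TSSs to the average near repeated random draws of non-regulated
genes, scaled to the group's size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("enhancersens")

GENE_SENSITIVITY = ("dual", "E379K_only", "R212Q_only", "insensitive", "none")


def define_de_genes(
    diff_wt: pd.DataFrame,
    padj_max: float = 0.05,
    fold_min: float = 1.5,
) -> tuple[pd.Series, dict[str, int]]:
    """induced / repressed / unaffected status per gene, plus counts.

    induced: padj < padj_max and L2FC > log2(fold_min); repressed is the
    mirror with L2FC < -log2(fold_min); a fold of exactly ``fold_min`` is
    unaffected (strict inequality).
    """
    d = diff_wt.set_index("id")
    thr = np.log2(fold_min)
    sig = d["padj"] < padj_max
    status = pd.Series("unaffected", index=d.index, name="de_status")
    status[sig & (d["log2FoldChange"] > thr)] = "induced"
    status[sig & (d["log2FoldChange"] < -thr)] = "repressed"
    counts = {
        "induced": int((status == "induced").sum()),
        "repressed": int((status == "repressed").sum()),
        "total": int((status != "unaffected").sum()),
    }
    return status, counts


def classify_gene_sensitivity(
    diff_e379k: pd.DataFrame,
    diff_r212q: pd.DataFrame,
    induced_ids: list[str],
    padj_max: float = 0.05,
    less_fold: float = 1.25,
    insens_frac: float = 0.25,
) -> tuple[pd.Series, dict[str, int]]:
    """Sensitivity class per induced gene.

    less-induced by a mutant: padj < padj_max and L2FC(mut vs WT)
    <= -log2(less_fold); dual / E379K_only / R212Q_only by overlap of the
    two less-induced sets; insensitive: |L2FC| < log2(1 + insens_frac) for
    both mutants; anything else is ``none``.
    """
    thr = np.log2(less_fold)
    ithr = np.log2(1 + insens_frac)
    e = diff_e379k.set_index("id")
    r = diff_r212q.set_index("id")
    out: dict[str, str] = {}
    for gid in induced_ids:
        le = (e.at[gid, "padj"] < padj_max) and (e.at[gid, "log2FoldChange"] <= -thr)
        lr = (r.at[gid, "padj"] < padj_max) and (r.at[gid, "log2FoldChange"] <= -thr)
        if le and lr:
            out[gid] = "dual"
        elif le:
            out[gid] = "E379K_only"
        elif lr:
            out[gid] = "R212Q_only"
        elif abs(e.at[gid, "log2FoldChange"]) < ithr and abs(r.at[gid, "log2FoldChange"]) < ithr:
            out[gid] = "insensitive"
        else:
            out[gid] = "none"
    series = pd.Series(out, name="gene_sensitivity")
    counts = {g: int((series == g).sum()) for g in GENE_SENSITIVITY}
    return series, counts


def _count_near(
    enh_by_chrom: dict[str, np.ndarray],
    tss: pd.DataFrame,
    window: int,
) -> int:
    """Number of enhancers whose center lies within ``window`` of any TSS."""
    total = 0
    for chrom, centers in enh_by_chrom.items():
        pos = tss.loc[tss["chrom"] == chrom, "tss"].to_numpy()
        if pos.size == 0:
            continue
        pos = np.sort(pos)
        lo = np.searchsorted(pos, centers - window, side="left")
        hi = np.searchsorted(pos, centers + window, side="right")
        total += int(np.count_nonzero(hi > lo))
    return total


def vicinity_enrichment(
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    gene_groups: dict[str, list[str]],
    window: int = 100_000,
    n_random: int = 200,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of enhancers near each gene group's TSSs over a resampled
    baseline of non-regulated genes.

    ``enhancers`` needs columns chrom, center (optionally a ``group`` column
    to stratify by enhancer group); ``genes`` needs gene_id, chrom, tss and a
    de_status column whose "unaffected" genes form the resampling pool.
    Baseline = mean over ``reps`` draws of ``n_random`` pool genes, scaled
    linearly to the gene group's size. Draws are without replacement and
    deterministic per seed.
    """
    pool = genes[genes["de_status"] == "unaffected"]
    if len(pool) < n_random:
        raise ValueError(f"non-regulated pool ({len(pool)}) smaller than n_random ({n_random})")
    rng = np.random.default_rng(seed)
    enh_groups = (
        {g: enhancers[enhancers["group"] == g] for g in enhancers["group"].unique()}
        if "group" in enhancers.columns
        else {"all": enhancers}
    )
    genes_idx = genes.set_index("gene_id")
    rows = []
    for eg, edf in sorted(enh_groups.items()):
        by_chrom = {
            c: edf.loc[edf["chrom"] == c, "center"].to_numpy() for c in edf["chrom"].unique()
        }
        baselines = []
        for _ in range(reps):
            draw = pool.sample(n=n_random, replace=False, random_state=rng.integers(2**31))
            baselines.append(_count_near(by_chrom, draw, window))
        base_per_gene = float(np.mean(baselines)) / n_random
        for gg, gids in sorted(gene_groups.items()):
            sub = genes_idx.loc[[g for g in gids if g in genes_idx.index]].reset_index()
            observed = _count_near(by_chrom, sub, window)
            baseline = base_per_gene * len(sub)
            ratio = observed / baseline if baseline > 0 else float("inf")
            if baseline == 0:
                log.warning("zero baseline for enhancer group %s vs gene group %s", eg, gg)
            rows.append(
                {
                    "enhancer_group": eg,
                    "gene_group": gg,
                    "n_genes": len(sub),
                    "observed": observed,
                    "baseline": baseline,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
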