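"""Window quantification and a negative-binomial Wald differential test.

The test is a deliberately simple, fully documented NB Wald test (no fold
shrinkage, no outlier filtering, no independent filtering): per-feature
method-of-moments dispersion with Var = mu + d*mu^2, a pseudo-mean-stabilized
log2 fold change, a delta-method standard error and a two-sided normal
p-value, followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicInterval
from .peakcall import TagTrack

log = logging.getLogger("enhancersens")

#: counting half-window per assay, bp from feature center
HALF_WINDOWS = {"H3K27ac": 1500, "Med1": 250, "ATAC": 250, "PPARg": 250}

LN2 = float(np.log(2.0))


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample size factors."""

    features: list[str]
    samples: list[tuple[str, str, str]]  # (assay, condition, replicate)
    counts: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("counts shape inconsistent with features/samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be positive")

    def normalized(self) -> np.ndarray:
        if self.size_factors is None:
            raise ValueError("size factors not set")
        return self.counts / self.size_factors[None, :]

    def columns_for(self, condition: str) -> np.ndarray:
        idx = np.array([j for j, (_, cond, _) in enumerate(self.samples) if cond == condition])
        if idx.size == 0:
            raise ValueError(f"no samples for condition {condition!r}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        cols = ["_".join(s) for s in self.samples]
        return pd.DataFrame(self.counts, index=self.features, columns=cols)


def quantify(
    features: list[GenomicInterval],
    feature_ids: list[str],
    tracks: list[TagTrack],
    half_window: int,
) -> CountMatrix:
    """Raw tag counts of every track in [center - w, center + w) per feature."""
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    counts = np.zeros((len(features), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        for i, iv in enumerate(features):
            c = iv.center
            counts[i, j] = track.count(iv.chrom, c - half_window, c + half_window)
    return CountMatrix(
        features=list(feature_ids),
        samples=[t.label for t in tracks],
        counts=counts,
    )


def size_factors(matrix: CountMatrix, method: str = "total_count") -> np.ndarray:
    """Per-sample normalization factors, rescaled to geometric mean 1.

    ``total_count``: column total over the geometric mean of totals (the
    library-size normalization). ``median_of_ratios``: the DESeq-style median
    over features of counts / per-feature geometric mean; falls back to
    ``total_count`` with a warning when no feature is positive in all samples.
    """
    counts = matrix.counts.astype(float)
    if method == "total_count":
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("a sample has zero total count")
        factors = totals / stats.gmean(totals)
    elif method == "median_of_ratios":
        allpos = np.all(counts > 0, axis=1)
        if not np.any(allpos):
            log.warning("no all-positive feature; falling back to total_count factors")
            return size_factors(matrix, "total_count")
        sub = counts[allpos]
        geo = stats.gmean(sub, axis=1)
        factors = np.median(sub / geo[:, None], axis=0)
        factors = factors / stats.gmean(factors)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    matrix.size_factors = factors
    return factors


def library_size_factors(matrix: CountMatrix, tracks: list[TagTrack]) -> np.ndarray:
    """Size factors from tag-directory totals (library size), gmean-rescaled.

    Uses the whole track's tag count rather than the column sums of the
    window matrix, so normalization is not distorted when most quantified
    windows carry condition-dependent signal.
    """
    totals = np.array([t.total for t in tracks], dtype=float)
    if np.any(totals <= 0):
        raise ValueError("a track has zero tags")
    factors = totals / stats.gmean(totals)
    matrix.size_factors = factors
    return factors


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    min_mu: float = 0.5,
    dispersion: float | None = None,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test of condition B vs condition A.

    Returns a DataFrame with columns id, baseMean, log2FoldChange, se, p, padj.
    With one replicate per condition a config-wide ``dispersion`` is required;
    otherwise the per-feature dispersion is moderated toward the
    across-feature median with ``prior_df`` prior degrees of freedom.
    """
    cond_a, cond_b = contrast
    if matrix.size_factors is None:
        size_factors(matrix, "total_count")
    q = matrix.normalized()
    ia, ib = matrix.columns_for(cond_a), matrix.columns_for(cond_b)
    na, nb = len(ia), len(ib)
    if (na < 2 or nb < 2) and dispersion is None:
        raise ValueError("with a single replicate per condition, dispersion must be supplied")

    qa, qb = q[:, ia], q[:, ib]
    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)
    base_mean = q[:, np.concatenate([ia, ib])].mean(axis=1)

    df = na + nb - 2
    if dispersion is not None:
        d = np.full(len(matrix.features), float(dispersion))
    else:
        # per-feature method of moments on per-condition-centered normalized
        # counts, moderated toward the across-feature mean (limma/edgeR
        # style): at n=2 the raw estimate has 2 df and is useless alone
        resid = np.concatenate([qa - mean_a[:, None], qb - mean_b[:, None]], axis=1)
        s2 = (resid**2).sum(axis=1) / df
        mu_bar = np.maximum(base_mean, min_mu)
        mom = np.maximum((s2 - mu_bar) / mu_bar**2, 1e-8)
        d = (df * mom + prior_df * np.mean(mom)) / (df + prior_df)

    l2fc = np.log2((mean_b + min_mu) / (mean_a + min_mu))
    mu_a = np.maximum(mean_a, min_mu)
    mu_b = np.maximum(mean_b, min_mu)
    se = np.sqrt((1.0 / LN2) ** 2 * ((1 / na) * (1 / mu_a + d) + (1 / nb) * (1 / mu_b + d)))
    z = np.where(se > 0, l2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (mean_a == 0) & (mean_b == 0)
    l2fc[allzero] = 0.0
    p[allzero] = 1.0
    base_mean[allzero] = 0.0

    res = pd.DataFrame(
        {
            "id": matrix.features,
            "baseMean": base_mean,
            "log2FoldChange": l2fc,
            "se": se,
            "p": p,
            "padj": bh_adjust(p),
        }
    )
    return res
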