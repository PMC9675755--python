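"""Synthetic genome, planted response elements, ChIP/ATAC tag tracks and gene
counts with the causal structure the downstream analysis assumes.

The generator plants four sensitivity groups of target enhancers plus a
class of bound-but-not-activated background sites. Hinge-mutation-sensitive
groups (``dual``, ``R212Q_only``) carry strong 5' extensions and receptor
half-sites and sit in inaccessible chromatin with low basal activation
marks; ``E379K_only`` and ``insensitive`` enhancers carry weaker motifs in
accessible chromatin with high basal marks. Mutant binding rates are the
wild-type rate times a per-group multiplicative penalty. Tag counts per
enhancer window are negative binomial (Var = m + d m^2) and tags spread
triangularly so that window counts match the planted means; accessibility
is encoded as a two-component fragment-length mixture with a sub-nucleosomal
(< 120 bp) and a mono-nucleosomal (~180 bp) mode.

Every planted parameter is recorded in a :class:`TruthTable`, the oracle
against which pipeline recovery is measured.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Genome, PWM
from .diffcount import CountMatrix
from .peakcall import TagTrack

log = logging.getLogger("enhancersens")

TARGET_GROUPS = ("dual", "E379K_only", "R212Q_only", "insensitive")
ASSAYS = ("PPARg", "H3K27ac", "Med1", "ATAC")
CONDITIONS = ("control", "WT", "E379K", "R212Q")

_BASES = "ACGT"


def stage_seed(seed: int, *parts: str) -> int:
    """Stable per-stage seed below 2^31 derived from a global seed."""
    key = ":".join([str(seed), *parts]).encode()
    return zlib.crc32(key) % (2**31)


def _default_penalties() -> dict[str, dict[str, float]]:
    # multiplicative binding reduction of each mutant, by planted group
    return {
        "dual": {"E379K": 0.25, "R212Q": 0.25},
        "E379K_only": {"E379K": 0.25, "R212Q": 1.0},
        "R212Q_only": {"E379K": 1.0, "R212Q": 0.25},
        "insensitive": {"E379K": 1.0, "R212Q": 1.0},
        "nontarget": {"E379K": 1.0, "R212Q": 1.0},
    }


def _default_mismatches() -> dict[str, dict[str, int]]:
    # planted consensus mismatches per motif segment, by group
    return {
        "dual": {"ext5": 0, "ppar_hs": 0, "rxr_hs": 1},
        "R212Q_only": {"ext5": 0, "ppar_hs": 0, "rxr_hs": 1},
        "E379K_only": {"ext5": 2, "ppar_hs": 2, "rxr_hs": 1},
        "insensitive": {"ext5": 2, "ppar_hs": 2, "rxr_hs": 1},
        "nontarget": {"ext5": 3, "ppar_hs": 3, "rxr_hs": 3},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults encode strong planted effects: binding fold >= 4 over
    background, two replicates per condition, dispersion 0.02, and a 0.25
    binding penalty (four-fold loss) for the mutant(s) a group is sensitive
    to. Basal activation marks are low at the closed hinge-sensitive groups,
    intermediate at E379K_only and highest at insensitive enhancers.
    """

    chrom_count: int = 6
    chrom_length: int = 1_250_000
    enhancers_per_group: int = 100
    n_background_sites: int = 200
    replicates: int = 2
    dispersion: float = 0.02
    site_spacing: int = 12_000
    seed: int = 0

    # per-bp per-replicate uniform background tag rates
    chip_background_rate: float = 0.01
    atac_background_rate: float = 0.0005

    # expected tags per counting window per replicate
    pparg_mean: float = 60.0
    bg_site_pparg_mean: float = 40.0
    med1_basal_low: float = 8.0
    med1_basal_mid: float = 30.0
    med1_basal_high: float = 50.0
    h3k27ac_basal_low: float = 15.0
    h3k27ac_basal_mid: float = 55.0
    h3k27ac_basal_high: float = 80.0
    activation_fold_closed: float = 6.0
    activation_fold_open: float = 3.0
    bg_site_med1: float = 30.0
    bg_site_h3k27ac: float = 40.0

    atac_closed_mean: float = 5.0
    atac_open_mean: float = 40.0
    atac_bg_site_mean: float = 25.0
    remodel_fold: float = 6.0
    remodel_penalty: dict[str, float] = field(
        default_factory=lambda: {"E379K": 0.6, "R212Q": 0.2}
    )
    # fraction of sub-nucleosomal fragments at accessible / inaccessible sites
    sub_frac_open: float = 0.85
    sub_frac_closed: float = 0.35
    frag_sub_mean: float = 70.0
    frag_sub_sd: float = 25.0
    frag_mono_mean: float = 180.0
    frag_mono_sd: float = 20.0

    # tag spread half-widths, matched to the counting windows
    spread: dict[str, int] = field(
        default_factory=lambda: {"PPARg": 250, "Med1": 250, "H3K27ac": 1500, "ATAC": 250}
    )

    linked_genes_per_group: int = 25
    n_pool_genes: int = 700
    gene_base_mean: float = 100.0
    induced_fold: float = 4.0
    gene_link_max_dist: int = 2_500

    penalties: dict[str, dict[str, float]] = field(default_factory=_default_penalties)
    mismatches: dict[str, dict[str, int]] = field(default_factory=_default_mismatches)

    def __post_init__(self) -> None:
        if self.chrom_length < 10_000:
            raise ValueError("chromosomes must be at least 10 kb")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.replicates < 1 or self.enhancers_per_group < 1:
            raise ValueError("counts must be >= 1")
        for group, pen in self.penalties.items():
            for mut, v in pen.items():
                if not (0 < v <= 1):
                    raise ValueError(f"penalty {group}/{mut} must lie in (0, 1]")
        if self.site_spacing < 3_000:
            raise ValueError("site spacing must keep >= 3 kb padding")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.chrom_count)}

    @property
    def n_sites(self) -> int:
        return self.enhancers_per_group * len(TARGET_GROUPS) + self.n_background_sites


@dataclass
class TruthTable:
    """Planted parameters per enhancer and per gene (the recovery oracle)."""

    enhancers: pd.DataFrame
    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        rate_cols = [c for c in self.enhancers.columns if c.startswith(ASSAYS)]
        if (self.enhancers[rate_cols] < 0).any().any():
            raise ValueError("expected rates must be non-negative")
        linked = set(self.genes["linked_enhancer"]) - {""}
        if not linked <= set(self.enhancers["enhancer_id"]):
            raise ValueError("a gene links to an unknown enhancer id")


def generate_genome(config: SimulationConfig, seed: int) -> Genome:
    """I.i.d. uniform A/C/G/T chromosomes; deterministic for a fixed seed."""
    rng = np.random.default_rng(stage_seed(seed, "genome"))
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        chrom: lut[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for chrom, length in config.chrom_lengths.items()
    }
    return Genome(sequences=sequences)


def _mutate_segment(rng: np.random.Generator, consensus: list[str], lo: int, hi: int, k: int) -> None:
    """Replace k positions in consensus[lo:hi] (0-based) with a different base."""
    k = min(k, hi - lo)
    for i in rng.choice(np.arange(lo, hi), size=k, replace=False):
        alternatives = [b for b in _BASES if b != consensus[i]]
        consensus[i] = alternatives[rng.integers(0, 3)]


def _sample_motif(rng: np.random.Generator, pwm: PWM, mism: dict[str, int]) -> str:
    seq = list(pwm.consensus)
    L = len(seq)
    ranges = {"ext5": (0, min(4, L)), "ppar_hs": (4, min(10, L)), "rxr_hs": (11, min(17, L))}
    for seg, (lo, hi) in ranges.items():
        if hi > lo:
            _mutate_segment(rng, seq, lo, hi, mism.get(seg, 0))
    return "".join(seq)


def plant_enhancers(
    genome: Genome, pwm: PWM, config: SimulationConfig, seed: int
) -> tuple[Genome, TruthTable]:
    """Write planted response elements into the genome and build the truth.

    Sites are laid out on a regular grid (``site_spacing`` apart, round-robin
    over groups so every chromosome carries every group); each carries a
    motif string sampled from the PWM consensus with per-segment mismatch
    counts from its group, written in at the site center.
    """
    rng = np.random.default_rng(stage_seed(seed, "plant"))
    chroms = list(genome.sequences)
    per_chrom_capacity = (config.chrom_length - 20_000) // config.site_spacing
    if per_chrom_capacity * len(chroms) < config.n_sites:
        raise ValueError(
            f"genome too small for {config.n_sites} sites at spacing {config.site_spacing}"
        )

    groups = [g for g in TARGET_GROUPS for _ in range(config.enhancers_per_group)]
    groups += ["nontarget"] * config.n_background_sites
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    seqs = {c: bytearray(genome.sequences[c], "ascii") for c in chroms}
    rows = []
    for i, group in enumerate(groups):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        center = 10_000 + slot * config.site_spacing
        motif = _sample_motif(rng, pwm, config.mismatches[group])
        start = center - len(motif) // 2
        seqs[chrom][start : start + len(motif)] = motif.encode("ascii")

        accessible = group in ("E379K_only", "insensitive", "nontarget")
        pen = config.penalties[group]
        pparg_wt = config.bg_site_pparg_mean if group == "nontarget" else config.pparg_mean
        if group == "nontarget":
            med1_c, h3_c = config.bg_site_med1, config.bg_site_h3k27ac
            med1_wt, h3_wt = med1_c, h3_c
            atac_c = config.atac_bg_site_mean
            atac_wt = atac_c
        else:
            fold = config.activation_fold_open if accessible else config.activation_fold_closed
            if not accessible:
                med1_c, h3_c = config.med1_basal_low, config.h3k27ac_basal_low
            elif group == "E379K_only":
                med1_c, h3_c = config.med1_basal_mid, config.h3k27ac_basal_mid
            else:
                med1_c, h3_c = config.med1_basal_high, config.h3k27ac_basal_high
            med1_wt, h3_wt = med1_c * fold, h3_c * fold
            atac_c = config.atac_open_mean if accessible else config.atac_closed_mean
            atac_wt = atac_c if accessible else atac_c * config.remodel_fold

        row = {
            "enhancer_id": f"enh_{i:04d}",
            "chrom": chrom,
            "center": center,
            "start": center - 250,
            "end": center + 250,
            "group": group,
            "accessible": accessible,
            "motif": motif,
            "PPARg_control": 0.0,  # receptor-null cells: no specific binding
            "PPARg_WT": pparg_wt,
            "PPARg_E379K": pparg_wt * pen["E379K"],
            "PPARg_R212Q": pparg_wt * pen["R212Q"],
            "Med1_control": med1_c,
            "Med1_WT": med1_wt,
            "Med1_E379K": med1_c + (med1_wt - med1_c) * pen["E379K"],
            "Med1_R212Q": med1_c + (med1_wt - med1_c) * pen["R212Q"],
            "H3K27ac_control": h3_c,
            "H3K27ac_WT": h3_wt,
            "H3K27ac_E379K": h3_c + (h3_wt - h3_c) * pen["E379K"],
            "H3K27ac_R212Q": h3_c + (h3_wt - h3_c) * pen["R212Q"],
            "ATAC_control": atac_c,
            "ATAC_WT": atac_wt,
            "ATAC_E379K": atac_c + (atac_wt - atac_c) * config.remodel_penalty["E379K"],
            "ATAC_R212Q": atac_c + (atac_wt - atac_c) * config.remodel_penalty["R212Q"],
        }
        rows.append(row)
    enhancers = pd.DataFrame(rows)

    genes = _plant_genes(enhancers, config, rng)
    new_genome = Genome(sequences={c: seqs[c].decode("ascii") for c in chroms})
    return new_genome, TruthTable(
        enhancers=enhancers, genes=genes, chrom_lengths=dict(config.chrom_lengths)
    )


def _plant_genes(
    enhancers: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    gid = 0
    base = config.gene_base_mean
    wt = base * config.induced_fold
    for group in TARGET_GROUPS:
        sub = enhancers[enhancers["group"] == group].head(config.linked_genes_per_group)
        pen = config.penalties[group]
        for _, e in sub.iterrows():
            offset = int(rng.integers(500, config.gene_link_max_dist + 1)) * (
                1 if rng.random() < 0.5 else -1
            )
            rows.append(
                {
                    "gene_id": f"gene_{gid:04d}",
                    "chrom": e["chrom"],
                    "tss": int(e["center"] + offset),
                    "linked_enhancer": e["enhancer_id"],
                    "expr_control": base,
                    "expr_WT": wt,
                    "expr_E379K": wt * pen["E379K"],
                    "expr_R212Q": wt * pen["R212Q"],
                }
            )
            gid += 1
    chroms = sorted(set(enhancers["chrom"]))
    chrom_len = int(enhancers["center"].max() + 10_000)
    for _ in range(config.n_pool_genes):
        rows.append(
            {
                "gene_id": f"gene_{gid:04d}",
                "chrom": chroms[int(rng.integers(0, len(chroms)))],
                "tss": int(rng.integers(0, chrom_len)),
                "linked_enhancer": "",
                "expr_control": base,
                "expr_WT": base,
                "expr_E379K": base,
                "expr_R212Q": base,
            }
        )
        gid += 1
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = m + d m^2 (Poisson when d -> 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def _spread_tags(
    rng: np.random.Generator, center: int, n: int, half_width: int, chrom_len: int
) -> np.ndarray:
    """Triangular tag placement around a center, clipped to the chromosome."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    pos = rng.triangular(center - half_width, center, center + half_width, size=n)
    return np.clip(pos.astype(np.int64), 0, chrom_len - 1)


def simulate_chip_tags(
    truth: TruthTable,
    assay: str,
    condition: str,
    replicate: int,
    config: SimulationConfig,
    seed: int,
) -> TagTrack:
    """One ChIP sample: NB window counts at planted sites plus uniform background.

    The control condition of the receptor assay contains background only
    (receptor-null cells express no receptor).
    """
    if assay not in ("PPARg", "H3K27ac", "Med1"):
        raise ValueError(f"unknown ChIP assay {assay!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(stage_seed(seed, "chip", assay, condition, str(replicate)))
    half = config.spread[assay]
    positions: dict[str, list[np.ndarray]] = {c: [] for c in truth.chrom_lengths}
    means = truth.enhancers[f"{assay}_{condition}"].to_numpy()
    counts = _nb_draw(rng, means, config.dispersion)
    for (_, e), n in zip(truth.enhancers.iterrows(), counts):
        chrom = e["chrom"]
        positions[chrom].append(
            _spread_tags(rng, int(e["center"]), int(n), half, truth.chrom_lengths[chrom])
        )
    for chrom, length in truth.chrom_lengths.items():
        n_bg = rng.poisson(config.chip_background_rate * length)
        positions[chrom].append(rng.integers(0, length, size=n_bg))
    merged = {
        c: np.sort(np.concatenate(parts)) if parts else np.zeros(0, dtype=np.int64)
        for c, parts in positions.items()
    }
    return TagTrack(
        positions=merged,
        chrom_lengths=dict(truth.chrom_lengths),
        label=(assay, condition, f"rep{replicate}"),
    )


def simulate_atac(
    truth: TruthTable,
    condition: str,
    replicate: int,
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """One ATAC sample: fragments (chrom, start, end, length).

    Fragment lengths follow a two-component normal mixture; accessible sites
    emit a larger sub-nucleosomal fraction, and planted remodeling raises
    rates at closed target enhancers under WT expression.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(stage_seed(seed, "atac", condition, str(replicate)))
    half = config.spread["ATAC"]
    rows_chrom, rows_mid, rows_len = [], [], []

    sub_means = truth.enhancers[f"ATAC_{condition}"].to_numpy()
    sub_counts = _nb_draw(rng, sub_means, config.dispersion)
    for (_, e), n_sub in zip(truth.enhancers.iterrows(), sub_counts):
        chrom = e["chrom"]
        chrom_len = truth.chrom_lengths[chrom]
        sub_frac = config.sub_frac_open if e["accessible"] else config.sub_frac_closed
        # planted rate counts sub-nucleosomal fragments; monos scale with 1-f over f
        n_mono = rng.poisson(float(n_sub) * (1 - sub_frac) / max(sub_frac, 1e-9))
        mids = _spread_tags(rng, int(e["center"]), int(n_sub) + int(n_mono), half, chrom_len)
        lengths = np.concatenate(
            [
                rng.normal(config.frag_sub_mean, config.frag_sub_sd, int(n_sub)),
                rng.normal(config.frag_mono_mean, config.frag_mono_sd, int(n_mono)),
            ]
        )
        rows_chrom += [chrom] * len(mids)
        rows_mid.append(mids)
        rows_len.append(lengths)

    for chrom, length in truth.chrom_lengths.items():
        n_bg = rng.poisson(config.atac_background_rate * length)
        mids = rng.integers(0, length, size=n_bg)
        is_sub = rng.random(n_bg) < 0.5
        lengths = np.where(
            is_sub,
            rng.normal(config.frag_sub_mean, config.frag_sub_sd, n_bg),
            rng.normal(config.frag_mono_mean, config.frag_mono_sd, n_bg),
        )
        rows_chrom += [chrom] * n_bg
        rows_mid.append(mids)
        rows_len.append(lengths)

    mids = np.concatenate(rows_mid) if rows_mid else np.zeros(0, dtype=np.int64)
    lengths = np.clip(np.concatenate(rows_len) if rows_len else np.zeros(0), 10, 500)
    lengths = lengths.astype(np.int64)
    starts = np.maximum(mids - lengths // 2, 0)
    frags = pd.DataFrame(
        {
            "chrom": rows_chrom,
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
        }
    )
    return frags.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def atac_track(
    frags: pd.DataFrame,
    chrom_lengths: dict[str, int],
    condition: str,
    replicate: int,
    max_length: int = 120,
) -> TagTrack:
    """Nucleosome-free TagTrack: midpoints of fragments <= max_length bp."""
    sub = frags[frags["length"] <= max_length]
    mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
    positions = {
        c: np.sort(mids[(sub["chrom"] == c).to_numpy()]) for c in chrom_lengths
    }
    return TagTrack(
        positions=positions,
        chrom_lengths=dict(chrom_lengths),
        label=("ATAC", condition, f"rep{replicate}"),
    )


def simulate_expression(
    truth: TruthTable, condition: str, config: SimulationConfig, seed: int
) -> CountMatrix:
    """NB gene counts for one condition (one column per replicate)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    means = truth.genes[f"expr_{condition}"].to_numpy()
    cols = []
    for rep in range(1, config.replicates + 1):
        rng = np.random.default_rng(stage_seed(seed, "expr", condition, str(rep)))
        cols.append(_nb_draw(rng, means, config.dispersion))
    return CountMatrix(
        features=list(truth.genes["gene_id"]),
        samples=[("RNA", condition, f"rep{rep}") for rep in range(1, config.replicates + 1)],
        counts=np.column_stack(cols),
    )
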