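"""Core mining computations on the surfaceome-restricted expression matrix.

Expression-class binning (ZERO/LOW/MED/HIGH), 4x4 class-transition tile
matrices per stage, stage-wise fold-change differential calls, the 15-region
Venn partition across the four stages, candidate marker selection, and
threshold expression calls.

Class boundary convention: [0, 0.1) ZERO, [0.1, 1) LOW, [1, 10] MED,
(10, inf) HIGH — "high" is strictly above 10, the interior joints are
half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from surfdbm.expression import STAGES, ExpressionMatrix, group_mean

CLASS_LABELS = ("ZERO", "LOW", "MED", "HIGH")
CLASS_BOUNDS = (0.1, 1.0, 10.0)


def classify_array(values, bounds: Sequence[float] = CLASS_BOUNDS) -> np.ndarray:
    """Class index (0..3) per entry of a non-negative TPM vector."""
    v = np.asarray(values, dtype=float)
    if v.size and (not np.isfinite(v).all() or (v < 0).any()):
        raise ValueError("TPM values must be finite and non-negative")
    b0, b1, b2 = bounds
    if not 0 < b0 < b1 < b2:
        raise ValueError(f"bounds must be increasing and positive, got {bounds}")
    idx = np.zeros(v.shape, dtype=int)
    idx[v >= b0] = 1
    idx[v >= b1] = 2
    idx[v > b2] = 3
    return idx


def classify_expression(tpm: float, bounds: Sequence[float] = CLASS_BOUNDS) -> str:
    """Map one TPM value to its expression-class label."""
    return CLASS_LABELS[int(classify_array([tpm], bounds)[0])]


@dataclass
class TileMatrix:
    """4x4 contingency of per-gene expression class: wild type (rows) vs transgenic (cols)."""

    stage: str
    counts: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError(f"tile counts must be 4x4, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("tile counts must be non-negative")
        if int(self.counts.sum()) != self.n_genes:
            raise ValueError("tile counts must sum to n_genes")

    @property
    def n_cells(self) -> int:
        return self.counts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(CLASS_LABELS, name="wildtype"),
            columns=pd.Index(CLASS_LABELS, name="transgenic"),
        )

    def wildtype_histogram(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def transgenic_histogram(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def tile_matrix(
    matrix: ExpressionMatrix, stage: str, bounds: Sequence[float] = CLASS_BOUNDS
) -> TileMatrix:
    """Tile the genes of one stage by (wild-type class, transgenic class) of replicate means."""
    try:
        mean_wt = group_mean(matrix, "wildtype", stage)
        mean_tg = group_mean(matrix, "transgenic", stage)
    except ValueError as exc:
        raise ValueError(f"stage {stage}: {exc}") from None
    wt_idx = classify_array(mean_wt.to_numpy(), bounds)
    tg_idx = classify_array(mean_tg.to_numpy(), bounds)
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (wt_idx, tg_idx), 1)
    return TileMatrix(stage=stage, counts=counts, n_genes=matrix.n_genes)


def call_differential(
    mean_tg: float, mean_wt: float, min_mean: float = 1.0, fold: float = 10.0
) -> str:
    """Threshold differential call between genotype replicate means.

    "up" iff mean_tg > min_mean and mean_tg > fold * mean_wt; "down" is the
    genotype-mirrored rule; otherwise "none". The fold test is multiplicative
    so a zero comparator needs no division; all inequalities are strict.
    """
    for name, v in (("mean_tg", mean_tg), ("mean_wt", mean_wt)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    if mean_tg > min_mean and mean_tg > fold * mean_wt:
        return "up"
    if mean_wt > min_mean and mean_wt > fold * mean_tg:
        return "down"
    return "none"


@dataclass
class DifferentialResult:
    """Per-stage up/down gene sets with the means behind each call."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    table: pd.DataFrame  # columns: gene_id, stage, direction, mean_tg, mean_wt

    def all_stage_intersection(self, direction: str = "up") -> set[str]:
        sets = self.up if direction == "up" else self.down
        out: set[str] | None = None
        for stage in sets:
            out = set(sets[stage]) if out is None else out & sets[stage]
        return out or set()


def differential_by_stage(
    matrix: ExpressionMatrix, min_mean: float = 1.0, fold: float = 10.0
) -> DifferentialResult:
    """Apply the differential rule per gene at every stage; all four stages required."""
    stages = list(STAGES)
    for stage in stages:
        for genotype in ("transgenic", "wildtype"):
            if not matrix.columns_for(genotype=genotype, stage=stage):
                raise ValueError(f"stage {stage}: no {genotype} samples")
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    rows: list[dict] = []
    for stage in stages:
        mean_tg = group_mean(matrix, "transgenic", stage)
        mean_wt = group_mean(matrix, "wildtype", stage)
        tg = mean_tg.to_numpy()
        wt = mean_wt.to_numpy()
        up_mask = (tg > min_mean) & (tg > fold * wt)
        down_mask = (wt > min_mean) & (wt > fold * tg)
        genes = np.asarray(matrix.gene_ids)
        up[stage] = set(genes[up_mask])
        down[stage] = set(genes[down_mask])
        for g, direction in [(g, "up") for g in genes[up_mask]] + [
            (g, "down") for g in genes[down_mask]
        ]:
            rows.append(
                {
                    "gene_id": g,
                    "stage": stage,
                    "direction": direction,
                    "mean_tg": float(mean_tg[g]),
                    "mean_wt": float(mean_wt[g]),
                }
            )
    table = pd.DataFrame(rows, columns=["gene_id", "stage", "direction", "mean_tg", "mean_wt"])
    table = table.sort_values(["stage", "direction", "gene_id"]).reset_index(drop=True)
    return DifferentialResult(up=up, down=down, table=table)


def region_label(stages: Iterable[str], order: Sequence[str] = STAGES) -> str:
    return "+".join(s for s in order if s in set(stages))


@dataclass
class VennPartition:
    """The 15 disjoint membership regions induced by four stage gene sets."""

    regions: dict[frozenset, set[str]]
    stages: tuple[str, ...]

    def region(self, *stages: str) -> set[str]:
        return self.regions[frozenset(stages)]

    @property
    def all_stage_region(self) -> set[str]:
        return self.regions[frozenset(self.stages)]

    def counts(self) -> dict[str, int]:
        return {
            region_label(k, self.stages): len(v)
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), region_label(kv[0], self.stages)))
        }

    def to_dict(self) -> dict[str, list[str]]:
        return {
            region_label(k, self.stages): sorted(v)
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), region_label(kv[0], self.stages)))
        }


def venn_partition(stage_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition the union of the stage sets into the 2^k - 1 exact-membership regions."""
    stages = tuple(stage_sets)
    sets = {s: set(v) for s, v in stage_sets.items()}
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(stages) + 1):
        for combo in combinations(stages, r):
            regions[frozenset(combo)] = set()
    universe = set().union(*sets.values()) if sets else set()
    for gene in universe:
        signature = frozenset(s for s in stages if gene in sets[s])
        regions[signature].add(gene)
    return VennPartition(regions=regions, stages=stages)


def select_candidates(
    matrix: ExpressionMatrix, min_mean_tpm: float = 20.0, min_fold: float = 5.0
) -> pd.DataFrame:
    """Rank genes as candidate markers: high transgenic expression plus a fold gap.

    A gene is selected iff its maximum over stages of the transgenic
    replicate mean exceeds ``min_mean_tpm`` AND at some stage
    mean_tg > min_fold * mean_wt. Per-stage means are always reported so
    other aggregation policies can be applied downstream.
    """
    if min_mean_tpm <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    stages = [s for s in STAGES if matrix.columns_for(stage=s)]
    if not stages:
        raise ValueError("matrix has no recognizable stage samples")
    tg = pd.DataFrame({s: group_mean(matrix, "transgenic", s) for s in stages})
    wt = pd.DataFrame({s: group_mean(matrix, "wildtype", s) for s in stages})
    max_mean_tg = tg.max(axis=1)
    fold_pass = (tg.to_numpy() > min_fold * wt.to_numpy()).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tg.to_numpy() / wt.to_numpy()
    ratio[(wt.to_numpy() == 0) & (tg.to_numpy() > 0)] = np.inf
    ratio[(wt.to_numpy() == 0) & (tg.to_numpy() == 0)] = 1.0
    best_fold = np.max(ratio, axis=1)
    out = pd.DataFrame({"gene_id": matrix.gene_ids})
    for s in stages:
        out[f"mean_tg_{s}"] = tg[s].to_numpy()
    for s in stages:
        out[f"mean_wt_{s}"] = wt[s].to_numpy()
    out["max_mean_tg"] = max_mean_tg.to_numpy()
    out["best_fold"] = best_fold
    out["selected"] = (max_mean_tg.to_numpy() > min_mean_tpm) & fold_pass
    return out


def expression_call(value: float, threshold: float = 4.0) -> bool:
    """True iff the abundance value is strictly above the threshold (FPKM > 4 by default)."""
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"value must be finite and non-negative, got {value}")
    return value > threshold


@dataclass
class MarkerSummary:
    """Tidy per-sample values and per-group means for a set of marker genes."""

    values: pd.DataFrame  # gene_id, sample_id, genotype, stage, replicate, value
    group_means: pd.DataFrame  # gene_id, genotype, stage, mean
    expressed_fraction: pd.Series  # per gene: fraction of samples strictly above threshold
    missing: list[str] = field(default_factory=list)


def marker_summary(
    matrix: ExpressionMatrix, genes: Sequence[str], threshold: float = 4.0
) -> MarkerSummary:
    """Per-gene per-sample value table plus group means and cohort expressed fraction.

    Genes absent from the matrix are reported in ``missing`` with a warning,
    not an error.
    """
    present = [g for g in genes if g in matrix.values.index]
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        warnings.warn(f"marker_summary: genes not in matrix: {missing}", stacklevel=2)
    rows = []
    for g in present:
        for m in matrix.samples:
            rows.append(
                {
                    "gene_id": g,
                    "sample_id": m.sample_id,
                    "genotype": m.genotype,
                    "stage": m.stage,
                    "replicate": m.replicate,
                    "value": float(matrix.values.at[g, m.sample_id]),
                }
            )
    values = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "genotype", "stage", "replicate", "value"]
    )
    if len(values):
        group_means = (
            values.groupby(["gene_id", "genotype", "stage"], sort=True)["value"]
            .mean()
            .reset_index()
            .rename(columns={"value": "mean"})
        )
        expressed = values.groupby("gene_id")["value"].apply(
            lambda v: float(np.mean([expression_call(x, threshold) for x in v]))
        )
    else:
        group_means = pd.DataFrame(columns=["gene_id", "genotype", "stage", "mean"])
        expressed = pd.Series(dtype=float)
    return MarkerSummary(
        values=values, group_means=group_means, expressed_fraction=expressed, missing=missing
    )
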