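"""Study-shaped synthetic data with planted structure for end-to-end testing.

Generates per-sample abundance TSVs, a transcript-to-gene map, a surfaceome
catalogue, a sample sheet, and a machine-readable truth file for the
2-genotype x 4-stage x replicate design. Expression is log-normal with
additive log2-scale effects: a per-gene baseline, a per-(gene, stage)
program (large, shared between genotypes, so leading principal components
separate stages), a genotype effect confined to a small planted surfaceome
gene set (so a later component separates genotypes), and per-replicate
log-normal noise.

Counts are realized deterministically by largest-remainder rounding of
library_size * share, so per-sample counts sum exactly to library_size and
a zero-noise configuration yields identical replicates. Multinomial
realization is available via ``count_model="multinomial"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from surfdbm.expression import (
    GENOTYPES,
    STAGES,
    AbundanceRecord,
    compute_tpm,
    write_abundance,
)

_CATEGORIES = ("surface", "secreted", "presumptive_surface")


@dataclass(frozen=True)
class PlantedEffect:
    """A genotype effect planted in a gene set at a subset of stages.

    ``direction`` "up" boosts the transgenic group, "down" boosts wild type.
    If ``genes`` is None, ``n_genes`` members are drawn from the surfaceome
    universe at generation time.
    """

    n_genes: int = 12
    stages: tuple[str, ...] = STAGES
    log2_fold: float = 4.3
    direction: str = "up"
    genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not set(self.stages) <= set(STAGES):
            raise ValueError(f"stages must be a subset of {STAGES}, got {self.stages}")
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if self.genes is None and self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not np.isfinite(self.log2_fold):
            raise ValueError("log2_fold must be finite")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; a single seed governs all randomness."""

    n_genes: int = 2000
    n_surfaceome: int = 300
    transcripts_per_gene: int = 2
    n_replicates: int = 3
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    planted_baseline_log2_offset: float = -2.0
    stage_effect_sd: float = 2.0
    noise_sd: float = 0.2
    planted: list[PlantedEffect] = field(default_factory=lambda: [PlantedEffect()])
    library_size: int = 1_000_000
    count_model: str = "rounded"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_surfaceome <= self.n_genes:
            raise ValueError("n_surfaceome must be in [0, n_genes]")
        if self.transcripts_per_gene < 1:
            raise ValueError("transcripts_per_gene must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("baseline_log2_sd", "stage_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.count_model not in ("rounded", "multinomial"):
            raise ValueError(f"count_model must be 'rounded' or 'multinomial', got {self.count_model!r}")
        n_planted = sum(p.n_genes if p.genes is None else len(p.genes) for p in self.planted)
        if n_planted > self.n_surfaceome:
            raise ValueError("planted genes must fit inside the surfaceome universe")


@dataclass
class SyntheticTruth:
    """Planted assignments plus the expected per-group TPM used for recovery scoring."""

    surfaceome_genes: list[str]
    planted: list[dict]
    expected_tpm: pd.DataFrame  # genes x "<genotype>:<stage>" columns

    def universe(self) -> set[str]:
        return set(self.expected_tpm.index)

    def planted_genes(self, stage: str, direction: str = "up") -> set[str]:
        out: set[str] = set()
        for p in self.planted:
            if p["direction"] == direction and stage in p["stages"]:
                out.update(p["genes"])
        return out

    def planted_all_stages(self, direction: str = "up") -> set[str]:
        out: set[str] | None = None
        for stage in STAGES:
            s = self.planted_genes(stage, direction)
            out = s if out is None else out & s
        return out or set()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "surfaceome_genes": self.surfaceome_genes,
            "planted": self.planted,
            "expected_tpm": {
                "genes": self.expected_tpm.index.tolist(),
                "columns": self.expected_tpm.columns.tolist(),
                "values": self.expected_tpm.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        exp = payload["expected_tpm"]
        df = pd.DataFrame(exp["values"], index=exp["genes"], columns=exp["columns"])
        return cls(
            surfaceome_genes=payload["surfaceome_genes"],
            planted=[
                {**p, "genes": list(p["genes"]), "stages": list(p["stages"])}
                for p in payload["planted"]
            ],
            expected_tpm=df,
        )


def _largest_remainder(target: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``target`` proportional to ``shares``; sums exactly."""
    raw = shares / shares.sum() * target
    base = np.floor(raw).astype(np.int64)
    short = target - int(base.sum())
    if short > 0:
        frac = raw - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> SyntheticTruth:
    """Write a complete synthetic dataset into ``out_dir`` and return the truth.

    Files: ``<sample_id>.tsv`` abundance tables, ``t2g.tsv``,
    ``surfaceome.tsv``, ``samples.tsv``, ``truth.json``. Fully reproducible
    from ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    width = max(5, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    gene_index = {g: i for i, g in enumerate(genes)}

    surfaceome = sorted(rng.choice(genes, size=config.n_surfaceome, replace=False).tolist())
    available = list(surfaceome)
    planted_resolved: list[dict] = []
    for p in config.planted:
        if p.genes is not None:
            chosen = list(p.genes)
            bad = [g for g in chosen if g not in set(surfaceome)]
            if bad:
                raise ValueError(f"planted genes not in surfaceome universe: {bad}")
        else:
            if p.n_genes > len(available):
                raise ValueError("not enough unplanted surfaceome genes left to plant")
            chosen = sorted(rng.choice(available, size=p.n_genes, replace=False).tolist())
        available = [g for g in available if g not in set(chosen)]
        planted_resolved.append(
            {
                "genes": chosen,
                "stages": list(p.stages),
                "direction": p.direction,
                "log2_fold": p.log2_fold,
            }
        )

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    # planted markers start from a modest baseline: the fold boost then lands in a
    # realistic range and the planted set does not dominate library mass
    for p in planted_resolved:
        idx = [gene_index[g] for g in p["genes"]]
        baseline[idx] += config.planted_baseline_log2_offset
    stage_effect = rng.normal(0.0, config.stage_effect_sd, (config.n_genes, len(STAGES)))

    # expected log2 expression per (genotype, stage)
    log2exp: dict[tuple[str, str], np.ndarray] = {}
    for genotype in GENOTYPES:
        for si, stage in enumerate(STAGES):
            e = baseline + stage_effect[:, si]
            for p in planted_resolved:
                boosted = (genotype == "transgenic") == (p["direction"] == "up")
                if boosted and stage in p["stages"]:
                    idx = [gene_index[g] for g in p["genes"]]
                    e = e.copy()
                    e[idx] += p["log2_fold"]
            log2exp[(genotype, stage)] = e

    expected_raw = {k: 2.0**v for k, v in log2exp.items()}
    expected_tpm = pd.DataFrame(
        {
            f"{genotype}:{stage}": expected_raw[(genotype, stage)]
            / expected_raw[(genotype, stage)].sum()
            * 1e6
            for genotype in GENOTYPES
            for stage in STAGES
        },
        index=pd.Index(genes, name="gene_id"),
    )

    tx_per_gene = config.transcripts_per_gene
    transcripts = [f"{g}.t{t}" for g in genes for t in range(1, tx_per_gene + 1)]
    lengths = rng.integers(500, 3001, size=len(transcripts))
    eff_length = lengths - 200.0  # min 300, always positive

    with (out_dir / "t2g.tsv").open("w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx in transcripts:
            fh.write(f"{tx}\t{tx.rsplit('.', 1)[0]}\n")

    categories = rng.choice(_CATEGORIES, size=len(surfaceome))
    with (out_dir / "surfaceome.tsv").open("w") as fh:
        fh.write("gene_id\tsymbol\tcategory\n")
        for g, cat in zip(surfaceome, categories):
            fh.write(f"{g}\t{g.replace('G', 'Sym', 1)}\t{cat}\n")

    sheet_rows: list[tuple[str, str, str, int, str]] = []
    for genotype in GENOTYPES:
        tag = "tg" if genotype == "transgenic" else "wt"
        for stage in STAGES:
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{tag}_{stage}_r{rep}"
                gene_tpm = expected_raw[(genotype, stage)] * 2.0 ** rng.normal(
                    0.0, config.noise_sd, config.n_genes
                )
                tx_tpm = np.repeat(gene_tpm / tx_per_gene, tx_per_gene)
                share = tx_tpm * eff_length
                if config.count_model == "multinomial":
                    counts = rng.multinomial(config.library_size, share / share.sum())
                else:
                    counts = _largest_remainder(config.library_size, share)
                tpm = (
                    compute_tpm(counts, eff_length)
                    if counts.sum() > 0
                    else np.zeros(len(counts))
                )
                records = [
                    AbundanceRecord(
                        transcript_id=tx,
                        length=int(lengths[i]),
                        eff_length=float(eff_length[i]),
                        est_counts=float(counts[i]),
                        tpm=float(tpm[i]),
                    )
                    for i, tx in enumerate(transcripts)
                ]
                fname = f"{sample_id}.tsv"
                write_abundance(out_dir / fname, records)
                sheet_rows.append((sample_id, genotype, stage, rep, fname))

    with (out_dir / "samples.tsv").open("w") as fh:
        fh.write("sample_id\tgenotype\tstage\treplicate\tpath\n")
        for row in sheet_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    truth = SyntheticTruth(
        surfaceome_genes=surfaceome, planted=planted_resolved, expected_tpm=expected_tpm
    )
    truth.to_json(out_dir / "truth.json")
    return truth


def _precision_recall(calls: set[str], planted: set[str]) -> dict[str, float]:
    tp = len(calls & planted)
    precision = tp / len(calls) if calls else 1.0
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall}


def evaluate_recovery(
    calls: Mapping[str, set[str]], truth: SyntheticTruth, direction: str = "up"
) -> dict:
    """Precision/recall of differential calls against the planted truth.

    ``calls`` maps stage to called gene set. Returns per-stage scores plus
    scores for the all-stage intersection. Raises if any called gene lies
    outside the truth's gene universe.
    """
    universe = truth.universe()
    for stage, genes in calls.items():
        stray = set(genes) - universe
        if stray:
            raise ValueError(f"calls at {stage} contain genes outside the truth universe: {sorted(stray)[:5]}")
    per_stage = {
        stage: _precision_recall(set(genes), truth.planted_genes(stage, direction))
        for stage, genes in calls.items()
    }
    inter: set[str] | None = None
    for genes in calls.values():
        inter = set(genes) if inter is None else inter & set(genes)
    inter = inter or set()
    all_stage = _precision_recall(inter, truth.planted_all_stages(direction))
    return {"per_stage": per_stage, "all_stages": all_stage}
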