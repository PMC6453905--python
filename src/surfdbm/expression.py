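"""Abundance-table IO, TPM/FPKM conversion, and gene-level matrix assembly.

Consumes the pseudo-alignment abundance-TSV dialect (one file per sample,
columns ``target_id  length  eff_length  est_counts  tpm``), aggregates
transcript abundances to genes, and assembles an annotated gene x sample
expression matrix for the downstream mining steps.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("transgenic", "wildtype")
STAGES = ("DN1", "DN2", "DN3", "DN4")
UNITS = ("TPM", "FPKM")

ABUNDANCE_COLUMNS = ("target_id", "length", "eff_length", "est_counts", "tpm")

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "stage", "replicate", "path")
T2G_COLUMNS = ("transcript_id", "gene_id")


class AbundanceFormatError(ValueError):
    """An abundance table deviates from the expected TSV dialect."""


@dataclass(frozen=True)
class AbundanceRecord:
    """One transcript-level abundance estimate from a single sample."""

    transcript_id: str
    length: int
    eff_length: float
    est_counts: float
    tpm: float

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if self.eff_length <= 0:
            raise ValueError(f"eff_length must be > 0, got {self.eff_length}")
        if self.est_counts < 0:
            raise ValueError(f"est_counts must be >= 0, got {self.est_counts}")
        if self.tpm < 0:
            raise ValueError(f"tpm must be >= 0, got {self.tpm}")


def read_abundance(path: str | Path) -> list[AbundanceRecord]:
    """Parse one abundance TSV into records, validating the dialect strictly.

    Raises :class:`AbundanceFormatError` on a malformed header, a non-numeric
    field (the message cites the offending line number), or an empty file.
    """
    path = Path(path)
    records: list[AbundanceRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AbundanceFormatError(f"{path}: empty file") from None
        if header != list(ABUNDANCE_COLUMNS):
            raise AbundanceFormatError(
                f"{path}: expected header {list(ABUNDANCE_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ABUNDANCE_COLUMNS):
                raise AbundanceFormatError(
                    f"{path}:{lineno}: expected {len(ABUNDANCE_COLUMNS)} fields, got {len(row)}"
                )
            try:
                rec = AbundanceRecord(
                    transcript_id=row[0],
                    length=int(row[1]),
                    eff_length=float(row[2]),
                    est_counts=float(row[3]),
                    tpm=float(row[4]),
                )
            except ValueError as exc:
                raise AbundanceFormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    if not records:
        raise AbundanceFormatError(f"{path}: no data rows")
    return records


def write_abundance(path: str | Path, records: Iterable[AbundanceRecord]) -> None:
    """Write records in the abundance-TSV dialect (floats at 6 significant digits)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(ABUNDANCE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.length}\t{r.eff_length:.6g}\t"
                f"{r.est_counts:.6g}\t{r.tpm:.6g}\n"
            )


def compute_tpm(est_counts: Sequence[float], eff_length: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million from estimated counts and effective lengths.

    tpm_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6; the output sums to 1e6.
    """
    c = np.asarray(est_counts, dtype=float)
    l = np.asarray(eff_length, dtype=float)
    if c.shape != l.shape or c.ndim != 1:
        raise ValueError("est_counts and eff_length must be 1-D vectors of equal length")
    if np.any(l <= 0):
        raise ValueError("effective lengths must all be > 0")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rate = c / l
    total = rate.sum()
    if total <= 0:
        raise ValueError("TPM undefined: all counts are zero")
    return rate / total * 1e6


def compute_fpkm(est_counts: Sequence[float], eff_length: Sequence[float]) -> np.ndarray:
    """Fragments per kilobase per million mapped fragments.

    fpkm_i = c_i / (l_i / 1e3) / (sum_j c_j / 1e6).
    """
    c = np.asarray(est_counts, dtype=float)
    l = np.asarray(eff_length, dtype=float)
    if c.shape != l.shape or c.ndim != 1:
        raise ValueError("est_counts and eff_length must be 1-D vectors of equal length")
    if np.any(l <= 0):
        raise ValueError("effective lengths must all be > 0")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("FPKM undefined: zero total counts")
    return c / (l / 1e3) / (total / 1e6)


def read_t2g(path: str | Path) -> dict[str, str]:
    """Read a 2-column transcript-to-gene map TSV (header: transcript_id, gene_id)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AbundanceFormatError(f"{path}: empty file") from None
        if header != list(T2G_COLUMNS):
            raise AbundanceFormatError(
                f"{path}: expected header {list(T2G_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise AbundanceFormatError(f"{path}:{lineno}: expected 2 fields")
            mapping[row[0]] = row[1]
    return mapping


def aggregate_to_genes(
    records: Sequence[AbundanceRecord], t2g: Mapping[str, str]
) -> pd.Series:
    """Sum member-transcript TPMs to gene level.

    Transcripts absent from ``t2g`` are dropped (a count is logged). Raises
    if the map is empty while records are not.
    """
    if records and not t2g:
        raise ValueError("transcript-to-gene map is empty but records are not")
    sums: dict[str, float] = {}
    dropped = 0
    for rec in records:
        gene = t2g.get(rec.transcript_id)
        if gene is None:
            dropped += 1
            continue
        sums[gene] = sums.get(gene, 0.0) + rec.tpm
    if dropped:
        logger.info("aggregate_to_genes: dropped %d unmapped transcripts", dropped)
    return pd.Series(sums, dtype=float)


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced sample in the 2-genotype x 4-stage design."""

    sample_id: str
    genotype: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


def read_sample_sheet(path: str | Path) -> list[tuple[SampleMeta, Path]]:
    """Read the sample sheet TSV; relative abundance paths resolve against the sheet's directory.

    Enforces unique sample_id and unique (genotype, stage, replicate) triples.
    """
    path = Path(path)
    out: list[tuple[SampleMeta, Path]] = []
    seen_ids: set[str] = set()
    seen_triples: set[tuple[str, str, int]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(SAMPLE_SHEET_COLUMNS):
            raise AbundanceFormatError(
                f"{path}: expected header {list(SAMPLE_SHEET_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SAMPLE_SHEET_COLUMNS):
                raise AbundanceFormatError(f"{path}:{lineno}: expected 5 fields")
            try:
                meta = SampleMeta(row[0], row[1], row[2], int(row[3]))
            except ValueError as exc:
                raise AbundanceFormatError(f"{path}:{lineno}: {exc}") from None
            if meta.sample_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate sample_id {meta.sample_id!r}")
            triple = (meta.genotype, meta.stage, meta.replicate)
            if triple in seen_triples:
                raise ValueError(f"{path}:{lineno}: duplicate (genotype, stage, replicate) {triple}")
            seen_ids.add(meta.sample_id)
            seen_triples.add(triple)
            p = Path(row[4])
            if not p.is_absolute():
                p = path.parent / p
            out.append((meta, p))
    return out


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with per-sample metadata and a unit tag.

    ``values`` is a DataFrame indexed by gene_id with one column per
    sample_id, in the same order as ``samples``. The unit tag records TPM vs
    FPKM (or a log-transformed label); downstream thresholds declare which
    unit they apply to.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    unit: str = "TPM"
    species: str | None = None

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="gene_id")
        ids = [m.sample_id for m in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns must match sample metadata order")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("matrix entries must be finite")
        if self.unit in UNITS and arr.size and (arr < 0).any():
            raise ValueError(f"negative entries not allowed in a {self.unit} matrix")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.samples]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta(self, sample_id: str) -> SampleMeta:
        for m in self.samples:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def columns_for(self, genotype: str | None = None, stage: str | None = None) -> list[str]:
        """Sample ids matching the given genotype and/or stage, in column order."""
        return [
            m.sample_id
            for m in self.samples
            if (genotype is None or m.genotype == genotype)
            and (stage is None or m.stage == stage)
        ]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving this matrix's row order; unknown ids ignored."""
        keep = set(genes)
        idx = [g for g in self.values.index if g in keep]
        return ExpressionMatrix(
            values=self.values.loc[idx],
            samples=list(self.samples),
            unit=self.unit,
            species=self.species,
        )

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            samples=list(self.samples),
            unit=self.unit if unit is None else unit,
            species=self.species,
        )


def assemble_matrix(
    per_sample: Mapping[str, pd.Series],
    metas: Sequence[SampleMeta],
    unit: str = "TPM",
    species: str | None = None,
) -> ExpressionMatrix:
    """Outer-join per-sample gene vectors into one matrix, columns in ``metas`` order.

    Genes absent from some sample are zero-filled with a warning.
    """
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id: {dups}")
    missing = [i for i in ids if i not in per_sample]
    if missing:
        raise ValueError(f"no expression vector for samples: {missing}")

    gene_order: dict[str, None] = {}
    for sid in ids:
        for g in per_sample[sid].index:
            gene_order.setdefault(g, None)
    genes = list(gene_order)

    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    n_filled = 0
    for sid in ids:
        col = per_sample[sid].reindex(genes)
        n_filled += int(col.isna().sum())
        df[sid] = col.fillna(0.0)
    if n_filled:
        warnings.warn(
            f"assemble_matrix: zero-filled {n_filled} gene/sample cells absent from input",
            stacklevel=2,
        )
    return ExpressionMatrix(values=df, samples=list(metas), unit=unit, species=species)


def group_mean(matrix: ExpressionMatrix, genotype: str, stage: str) -> pd.Series:
    """Arithmetic mean per gene over the replicates of one (genotype, stage) group."""
    cols = matrix.columns_for(genotype=genotype, stage=stage)
    if not cols:
        raise ValueError(f"no samples for genotype={genotype!r}, stage={stage!r}")
    return matrix.values[cols].mean(axis=1)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix TSV plus a ``<path>.meta.json`` sidecar with unit and sample metadata."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    sidecar = {
        "unit": matrix.unit,
        "species": matrix.species,
        "samples": [
            {
                "sample_id": m.sample_id,
                "genotype": m.genotype,
                "stage": m.stage,
                "replicate": m.replicate,
            }
            for m in matrix.samples
        ],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".meta.json").read_text())
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    metas = [SampleMeta(**d) for d in sidecar["samples"]]
    return ExpressionMatrix(
        values=df, samples=metas, unit=sidecar["unit"], species=sidecar.get("species")
    )
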