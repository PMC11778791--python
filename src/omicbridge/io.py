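"""Domain containers and on-disk formats.

Cells are rows everywhere.  Matrices travel as Matrix Market triplets with
two one-column ID files, or as delimited text with a header row of feature
IDs and a leading column of cell IDs.  Labels and transfer results are TSV.
Peak coordinates are BED-style 0-based half-open; GTF's 1-based closed
intervals are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

SOURCE = "source"
TARGET = "target"


@dataclass
class FeatureMatrix:
    """Cells-by-features numeric matrix with IDs and a modality tag."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str = SOURCE

    def __post_init__(self):
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows but "
                f"{len(self.cell_ids)} cell IDs"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{len(self.feature_ids)} feature IDs"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in matrix")
        if self.modality not in (SOURCE, TARGET):
            raise ValueError(f"modality must be '{SOURCE}' or '{TARGET}'")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSet:
    """cell_id -> cell-type mapping with the sorted list of classes."""

    mapping: dict[str, str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        expected = sorted(set(self.mapping.values()))
        if not self.classes:
            self.classes = expected
        elif sorted(self.classes) != expected:
            raise ValueError("classes must be exactly the set of mapped values")

    def labels_for(self, cell_ids: list[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.mapping]
        if missing:
            raise KeyError(f"{len(missing)} cell IDs without labels, e.g. {missing[:3]}")
        return np.array([self.mapping[c] for c in cell_ids])


@dataclass
class PeakMatrix:
    """Cells-by-peaks counts with 0-based half-open peak intervals."""

    values: np.ndarray
    peak_intervals: list[tuple[str, int, int]]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.peak_intervals)):
            raise ValueError("matrix shape inconsistent with IDs/intervals")
        for chrom, start, end in self.peak_intervals:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")


@dataclass
class GeneModel:
    """Gene coordinates, 0-based half-open, strand-aware."""

    genes: list[tuple[str, str, str, int, int]]  # (gene_id, chrom, strand, start, end)

    def __post_init__(self):
        for gid, chrom, strand, start, end in self.genes:
            if strand not in ("+", "-"):
                raise ValueError(f"gene {gid}: strand must be + or -")
            if start < 0 or start >= end:
                raise ValueError(f"gene {gid}: bad interval {start}-{end}")


@dataclass
class TransferResult:
    """Per-target-cell label call from the k-NN vote."""

    cell_ids: list[str]
    predicted_labels: list[str]
    confidences: np.ndarray
    neighbor_indices: np.ndarray | None = None
    flag_low_confidence: np.ndarray | None = None
    conf_threshold: float = 0.60

    def __post_init__(self):
        self.confidences = np.asarray(self.confidences, dtype=np.float64)
        if self.confidences.size and (
            self.confidences.min() < 0 or self.confidences.max() > 1
        ):
            raise ValueError("confidences must lie in [0, 1]")
        if self.flag_low_confidence is None:
            self.flag_low_confidence = self.confidences < self.conf_threshold
        self.flag_low_confidence = np.asarray(self.flag_low_confidence, dtype=bool)


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------


def _read_ids(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_feature_matrix(
    matrix_path,
    modality: str = SOURCE,
    cells_path=None,
    features_path=None,
    delimiter: str = "\t",
) -> FeatureMatrix:
    """Read an MTX triplet (matrix + cell/feature ID files) or delimited text.

    MTX matrices are stored cells-by-features; delimited text has feature IDs
    in the header row and cell IDs in the first column.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx" or (cells_path and features_path):
        if cells_path is None or features_path is None:
            raise ValueError("MTX input needs cell and feature ID files")
        mat = scipy.io.mmread(matrix_path)
        cells = _read_ids(cells_path)
        feats = _read_ids(features_path)
        return FeatureMatrix(mat, cells, feats, modality)
    df = pd.read_csv(matrix_path, sep=delimiter, index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric entries in columns {list(bad)[:3]}")
    return FeatureMatrix(
        df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)), modality
    )


def write_feature_matrix(fm: FeatureMatrix, matrix_path, cells_path=None, features_path=None):
    """Write as MTX triplet (if matrix_path ends in .mtx) or TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if cells_path is None or features_path is None:
            raise ValueError("MTX output needs cell and feature ID paths")
        scipy.io.mmwrite(matrix_path, sp.coo_matrix(fm.values))
        Path(cells_path).write_text("\n".join(fm.cell_ids) + "\n")
        Path(features_path).write_text("\n".join(fm.feature_ids) + "\n")
    else:
        pd.DataFrame(fm.values, index=fm.cell_ids, columns=fm.feature_ids).to_csv(
            matrix_path, sep="\t", float_format="%.10g"
        )


def read_labels(path) -> LabelSet:
    """Two-column TSV: cell_id <tab> cell_type (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, cell_type")
    if df.iloc[0, 0] in ("cell_id", "cell"):
        df = df.iloc[1:]
    return LabelSet(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_labels(labels: LabelSet, path):
    with open(path, "w") as fh:
        fh.write("cell_id\tcell_type\n")
        for cid, ct in labels.mapping.items():
            fh.write(f"{cid}\t{ct}\n")


def read_bed_peaks(bed_path, counts: np.ndarray, cell_ids: list[str]) -> PeakMatrix:
    """BED3(+score) file describing the peak columns of `counts`."""
    intervals = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return PeakMatrix(counts, intervals, cell_ids)


def read_gtf_genes(gtf_path) -> GeneModel:
    """Extract gene records from GTF (1-based closed -> 0-based half-open)."""
    genes = []
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            gid = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gid = item.split(" ", 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise ValueError(f"GTF gene record without gene_id: {line[:60]}")
            genes.append((gid, chrom, strand, int(start) - 1, int(end)))
    return GeneModel(genes)


def write_transfer_result(result: TransferResult, path):
    """TSV: cell_id, predicted_label, confidence, flagged. Round-trips."""
    with open(path, "w") as fh:
        fh.write("cell_id\tpredicted_label\tconfidence\tflagged\n")
        for cid, lab, conf, flag in zip(
            result.cell_ids,
            result.predicted_labels,
            result.confidences,
            result.flag_low_confidence,
        ):
            fh.write(f"{cid}\t{lab}\t{conf:.10g}\t{int(flag)}\n")


def read_transfer_result(path, conf_threshold: float = 0.60) -> TransferResult:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "predicted_label": str})
    return TransferResult(
        cell_ids=list(df["cell_id"].astype(str)),
        predicted_labels=list(df["predicted_label"].astype(str)),
        confidences=df["confidence"].to_numpy(dtype=float),
        flag_low_confidence=df["flagged"].to_numpy(dtype=bool)
        if "flagged" in df
        else None,
        conf_threshold=conf_threshold,
    )


# ---------------------------------------------------------------------
# feature harmonization and gene activity
# ---------------------------------------------------------------------


def harmonize_features(
    src: FeatureMatrix, tgt: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict both matrices to their common features, identical order.

    The shared features are taken in the source matrix's column order so the
    operation is deterministic; the selected *set* is symmetric in the inputs.
    """
    if src.n_cells == 0 or tgt.n_cells == 0:
        raise ValueError("empty input matrix")
    tgt_set = set(tgt.feature_ids)
    common = [f for f in src.feature_ids if f in tgt_set]
    if not common:
        raise ValueError("no shared features between the two modalities")
    src_idx = [src.feature_ids.index(f) for f in common]
    tgt_pos = {f: i for i, f in enumerate(tgt.feature_ids)}
    tgt_idx = [tgt_pos[f] for f in common]
    return (
        FeatureMatrix(src.values[:, src_idx], src.cell_ids, common, src.modality),
        FeatureMatrix(tgt.values[:, tgt_idx], tgt.cell_ids, common, tgt.modality),
    )


def gene_activity(
    peaks: PeakMatrix, genes: GeneModel, promoter_bp: int = 2000
) -> FeatureMatrix:
    """Aggregate peak counts into per-gene activity scores.

    A peak contributes its counts to every gene whose body, extended
    upstream of the TSS by `promoter_bp` (strand-aware), it overlaps.
    Peaks on chromosomes absent from the gene model contribute nothing.
    """
    if promoter_bp < 0:
        raise ValueError("promoter_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g_i, (gid, chrom, strand, start, end) in enumerate(genes.genes):
        if strand == "+":
            lo, hi = max(0, start - promoter_bp), end
        else:
            lo, hi = start, end + promoter_bp
        trees.setdefault(chrom, IntervalTree())[lo:hi] = g_i

    n_cells, n_genes = len(peaks.cell_ids), len(genes.genes)
    activity = np.zeros((n_cells, n_genes))
    missing_chroms = set()
    for p_i, (chrom, start, end) in enumerate(peaks.peak_intervals):
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            continue
        for hit in tree[start:end]:
            activity[:, hit.data] += peaks.values[:, p_i]
    if missing_chroms:
        warnings.warn(
            f"peaks on chromosomes absent from gene model ignored: "
            f"{sorted(missing_chroms)}"
        )
    gene_ids = [g[0] for g in genes.genes]
    return FeatureMatrix(activity, peaks.cell_ids, gene_ids, TARGET)


def normalize_counts(
    fm: FeatureMatrix, target_sum: float = 1e4, log1p: bool = True
) -> FeatureMatrix:
    """Per-cell library-size normalization to `target_sum`, then log1p.

    The standard preprocessing applied before CCA and model input; both steps
    can be disabled.
    """
    vals = fm.values
    if target_sum:
        lib = vals.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        vals = vals / lib * target_sum
    if log1p:
        vals = np.log1p(vals)
    return FeatureMatrix(vals, fm.cell_ids, fm.feature_ids, fm.modality)
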