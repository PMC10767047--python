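"""Data model and I/O for spot matrices, positions, images, and gene sets.

The on-disk layout follows the 10x Genomics convention: a MatrixMarket
triplet (``matrix.mtx`` with genes as rows, spots as columns,
``features.tsv``, ``barcodes.tsv``) plus a ``tissue_positions.csv`` with
columns ``barcode, in_tissue, array_row, array_col, y_px, x_px``.  Spot
metadata (sample, genotype, age, optional region/cluster) is carried in a
``spot_meta.csv`` sidecar.  Pixel coordinates are 0-based with x right and
y down, consistent with image array indexing (``image[y, x]``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

POSITION_COLUMNS = ["array_row", "array_col", "x_px", "y_px"]
_POSITIONS_CSV_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                          "y_px", "x_px"]


@dataclass
class SpotDataset:
    """Sparse gene x spot counts with spot coordinates and metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix of shape (n_genes, n_spots).
    gene_ids, spot_ids
        Unique string identifiers for rows / columns of ``counts``.
    positions
        Per-spot table with columns ``array_row, array_col, x_px, y_px``,
        indexed by spot id.
    meta
        Per-spot table with at least ``sample``; typically also
        ``genotype`` in {WT, AD} and ``age`` in {3M, 7M}, optionally
        ``region`` (ground truth) and ``cluster``.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    positions: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"counts has {n_genes} gene rows but {len(self.gene_ids)} gene ids")
        if len(self.spot_ids) != n_spots:
            raise ValueError(
                f"counts has {n_spots} spot columns but {len(self.spot_ids)} spot ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("spot ids are not unique")
        missing = [c for c in POSITION_COLUMNS if c not in self.positions.columns]
        if missing:
            raise ValueError(f"positions is missing columns {missing}")
        if len(self.positions) != n_spots:
            raise ValueError("positions must have one row per spot")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=pd.Index(self.spot_ids, name="barcode"))
        if len(self.meta) != n_spots:
            raise ValueError("meta must have one row per spot")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes``; raises KeyError on absent symbols."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def spot_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_spots(self, mask) -> "SpotDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpotDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            spot_ids=self.spot_ids[idx],
            positions=self.positions.iloc[idx],
            meta=self.meta.iloc[idx],
        )

    def copy(self) -> "SpotDataset":
        return SpotDataset(self.counts.copy(), self.gene_ids.copy(),
                           self.spot_ids.copy(), self.positions.copy(),
                           self.meta.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (set name -> ordered, de-duplicated gene list)."""

    sets: dict

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str):
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self):
        return list(self.sets)


def write_mtx_triplet(dataset: SpotDataset, out_dir) -> None:
    """Write a dataset as a 10x-style MTX triplet plus positions/meta CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(dataset.counts),
                     field="integer")
    feats = pd.DataFrame({0: dataset.gene_ids, 1: dataset.gene_ids,
                          2: "Gene Expression"})
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(dataset.spot_ids).to_csv(out / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    pos = dataset.positions
    table = pd.DataFrame({
        "barcode": dataset.spot_ids,
        "in_tissue": 1,
        "array_row": pos["array_row"].to_numpy(),
        "array_col": pos["array_col"].to_numpy(),
        "y_px": pos["y_px"].to_numpy(),
        "x_px": pos["x_px"].to_numpy(),
    })
    table.to_csv(out / "tissue_positions.csv", index=False)
    if len(dataset.meta.columns):
        meta = dataset.meta.copy()
        meta.insert(0, "barcode", dataset.spot_ids)
        meta.to_csv(out / "spot_meta.csv", index=False)


def read_mtx_triplet(in_dir) -> SpotDataset:
    """Read a dataset written by :func:`write_mtx_triplet`.

    Raises ``ValueError`` when the MTX header disagrees with the
    features/barcodes file lengths, citing both sizes.
    """
    src = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(src / "matrix.mtx")).astype(np.int64)
    feats = pd.read_csv(src / "features.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None,
                           dtype=str)[0].to_numpy()
    gene_ids = feats[0].to_numpy()
    if counts.shape[0] != len(gene_ids):
        raise ValueError(
            f"matrix.mtx declares {counts.shape[0]} genes but features.tsv "
            f"has {len(gene_ids)} rows")
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix.mtx declares {counts.shape[1]} spots but barcodes.tsv "
            f"has {len(barcodes)} rows")
    pos_csv = pd.read_csv(src / "tissue_positions.csv")
    pos_csv = pos_csv.set_index("barcode").loc[barcodes]
    positions = pd.DataFrame({
        "array_row": pos_csv["array_row"].to_numpy(),
        "array_col": pos_csv["array_col"].to_numpy(),
        "x_px": pos_csv["x_px"].to_numpy(),
        "y_px": pos_csv["y_px"].to_numpy(),
    }, index=pd.Index(barcodes, name="barcode"))
    meta_path = src / "spot_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path).set_index("barcode").loc[barcodes]
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return SpotDataset(counts, gene_ids, barcodes, positions, meta)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, tab-sep genes).

    Duplicate genes within a set are dropped with a warning; duplicate set
    names are an error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            genes, seen = [], set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    warnings.warn(f"set {name!r}: duplicate gene {g!r} dropped")
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def merge_samples(datasets, sample_names=None) -> SpotDataset:
    """Merge per-sample datasets into one, prefixing spot ids by sample.

    Gene universes are unioned (genes absent from a sample are zero-filled
    on its spots).  Sample names come from the ``sample`` meta column when
    present, else from ``sample_names``.
    """
    if len(datasets) == 0:
        raise ValueError("no datasets to merge")
    if sample_names is None:
        sample_names = []
        for i, d in enumerate(datasets):
            if "sample" in d.meta.columns and d.meta["sample"].nunique() == 1:
                sample_names.append(str(d.meta["sample"].iloc[0]))
            else:
                sample_names.append(f"sample{i}")
    genes: list = []
    seen: set = set()
    for d in datasets:
        for g in d.gene_ids:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    gene_ids = np.asarray(genes, dtype=object)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    blocks, spot_ids, pos_frames, meta_frames = [], [], [], []
    for name, d in zip(sample_names, datasets):
        row_map = np.array([gene_pos[g] for g in d.gene_ids])
        coo = sp.coo_matrix(d.counts)
        block = sp.coo_matrix((coo.data, (row_map[coo.row], coo.col)),
                              shape=(len(gene_ids), d.n_spots))
        blocks.append(block)
        prefixed = np.array([f"{name}_{s}" for s in d.spot_ids], dtype=object)
        spot_ids.append(prefixed)
        pos = d.positions.copy()
        pos.index = pd.Index(prefixed, name="barcode")
        pos_frames.append(pos)
        meta = d.meta.copy()
        meta.index = pd.Index(prefixed, name="barcode")
        if "sample" not in meta.columns:
            meta["sample"] = name
        meta_frames.append(meta)
    all_ids = np.concatenate(spot_ids)
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("spot ids collide after sample prefixing")
    return SpotDataset(
        counts=sp.hstack(blocks).tocsr(),
        gene_ids=gene_ids,
        spot_ids=all_ids,
        positions=pd.concat(pos_frames),
        meta=pd.concat(meta_frames),
    )


def write_truth_json(truth: dict, path) -> None:
    """Write a ground-truth sidecar (lists/scalars only) as JSON."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, default=_default, indent=1)
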