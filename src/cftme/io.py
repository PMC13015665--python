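"""Reading and writing the pipeline's file formats.

Count matrices are plain gene-by-sample tables (TSV with the gene identifier
in the first column, or MatrixMarket coordinate files with ``genes.txt`` /
``samples.txt`` sidecars).  Sample metadata is a TSV with a mandatory header
set.  Gene sets use the standard GMT dialect (name, description, then
tab-separated members).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Columns every metadata table must carry.
METADATA_COLUMNS = (
    "sample_id",
    "cohort",
    "timepoint",
    "response",
    "pfs_time",
    "pfs_event",
    "intron_exon_ratio",
    "five_three_bias",
    "total_counts",
)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, e.g. one TME archetype marker list."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            dupes = sorted({m for m in self.members if list(self.members).count(m) > 1})
            raise ValueError(f"gene set {self.name!r} has duplicate members: {dupes}")

    def __len__(self) -> int:
        return len(self.members)


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants: unique identifiers, non-negative integers."""
    if counts.index.has_duplicates:
        dupes = sorted(counts.index[counts.index.duplicated()].unique())
        raise ValueError(f"duplicate gene identifiers: {dupes[:10]}")
    if counts.columns.has_duplicates:
        dupes = sorted(counts.columns[counts.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample identifiers: {dupes[:10]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix is not numeric")
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integer entries")
    return counts.astype(np.int64)


def read_count_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene-by-sample count matrix.

    Parameters
    ----------
    path
        For ``tsv``: the table itself. For ``mtx``: the ``.mtx`` file; the
        sidecars ``genes.txt`` and ``samples.txt`` must sit next to it.
    format
        ``"tsv"`` or ``"mtx"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            counts = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"failed to parse {path}: {exc}") from exc
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        genes = (path.parent / "genes.txt").read_text().split()
        samples = (path.parent / "samples.txt").read_text().split()
        counts = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
            index=genes,
            columns=samples,
        )
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    return validate_count_matrix(counts)


def write_count_matrix(counts: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix as TSV or MatrixMarket + sidecar name files."""
    path = Path(path)
    if format == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.to_numpy()))
        (path.parent / "genes.txt").write_text("\n".join(counts.index) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata TSV, enforcing the mandatory header set."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing mandatory columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    if (meta["pfs_time"] < 0).any():
        raise ValueError("pfs_time must be non-negative")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set (name, description, members...)."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name, description, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has an empty member list")
        sets.append(GeneSet(name=name, members=tuple(members), description=description))
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *s.members]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SingleCellMatrix:
    """Cell-by-gene integer counts with per-cell sample and cluster labels."""

    counts: np.ndarray  # (n_cells, n_genes)
    genes: list[str]
    cell_ids: list[str]
    sample_labels: np.ndarray  # (n_cells,) str
    cluster_labels: np.ndarray  # (n_cells,) str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        n_cells, n_genes = self.counts.shape
        if (self.counts < 0).any():
            raise ValueError("single-cell counts must be non-negative")
        if len(self.genes) != n_genes:
            raise ValueError("gene list does not match count matrix width")
        for name, labels in (("cell_ids", self.cell_ids), ("sample", self.sample_labels), ("cluster", self.cluster_labels)):
            if len(labels) != n_cells:
                raise ValueError(f"{name} labels do not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


def read_single_cell(mtx_path: str | Path, labels_path: str | Path) -> SingleCellMatrix:
    """Read cell counts from MatrixMarket (cells x genes) plus a label TSV.

    The label TSV has columns ``cell_id``, ``sample_id``, ``cluster`` in cell
    (row) order; gene names come from a ``genes.txt`` sidecar.
    """
    mtx_path = Path(mtx_path)
    mat = scipy.io.mmread(mtx_path)
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = (mtx_path.parent / "genes.txt").read_text().split()
    labels = pd.read_csv(labels_path, sep="\t")
    return SingleCellMatrix(
        counts=counts,
        genes=genes,
        cell_ids=list(labels["cell_id"]),
        sample_labels=labels["sample_id"].to_numpy(),
        cluster_labels=labels["cluster"].to_numpy(),
    )


def archetype_gene_sets() -> list[GeneSet]:
    """The packaged LN / FMAC / TEX archetype marker sets (20 genes each)."""
    ref = importlib.resources.files("cftme.data").joinpath("archetypes.gmt")
    with importlib.resources.as_file(ref) as p:
        return read_gene_sets(p)
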