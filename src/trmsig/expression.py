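"""Expression-matrix data model, filtering, transforms, PCA and clustering.

The pipeline consumes a genes x samples FPKM matrix.  Every stage tracks the
scale of the values explicitly (``fpkm`` -> ``log2`` -> ``standardised``) so
that operations can refuse inputs on the wrong scale instead of silently
producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, ParseError

SCALES = ("fpkm", "log2", "standardised")

#: condition labels of the four-arm stimulation design
CONDITIONS = ("Untreated", "TGFb", "IL2", "IL2_TGFb")

#: conditions in which the cells saw TGF-beta / IL-2
TGFB_CONDITIONS = ("TGFb", "IL2_TGFb")
IL2_CONDITIONS = ("IL2", "IL2_TGFb")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense genes x samples matrix with an explicit scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene ids with unique sample-id columns.
    scale:
        One of ``fpkm``, ``log2`` or ``standardised``.
    zero_variance:
        Gene ids whose row had zero variance when the matrix was
        standardised (their standardised rows are all zeros).
    """

    data: pd.DataFrame
    scale: str = "fpkm"
    zero_variance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigurationError(
                f"unknown scale {self.scale!r}; expected one of {SCALES}"
            )
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dupes}")
        if self.scale == "fpkm" and (self.data.to_numpy() < 0).any():
            raise ConfigurationError("fpkm matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample id to its (condition, replicate) pair."""

    table: pd.DataFrame  # index sample id; columns condition, replicate
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if not {"condition", "replicate"}.issubset(self.table.columns):
            raise ParseError("design table needs 'condition' and 'replicate' columns")
        if self.table.index.duplicated().any():
            raise ParseError("duplicate sample ids in design")
        unknown = set(self.table["condition"]) - set(self.conditions)
        if unknown:
            raise ConfigurationError(f"conditions not in level order: {sorted(unknown)}")

    def samples_for(self, conditions) -> list[str]:
        if isinstance(conditions, str):
            conditions = [conditions]
        mask = self.table["condition"].isin(list(conditions))
        return self.table.index[mask].tolist()

    def n_replicates(self, condition: str) -> int:
        return int((self.table["condition"] == condition).sum())

    def tgfb_treated(self, sample_id: str) -> bool:
        return self.table.loc[sample_id, "condition"] in TGFB_CONDITIONS

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.samples) - set(self.table.index)
        extra = set(self.table.index) - set(matrix.samples)
        if missing or extra:
            raise ConfigurationError(
                f"design/matrix sample mismatch: missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV (first column gene id).

    Raises :class:`ParseError` naming the offending line for ragged rows,
    non-numeric cells or duplicated ids.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    ncol = len(header)
    samples = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from exc
    data = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(data=data, scale="fpkm")


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    # %.8g keeps round-trips lossless well past 6 significant digits
    out.to_csv(path, sep="\t", float_format="%.8g")


def read_design_tsv(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SampleDesign(table=table)


def write_design_tsv(design: SampleDesign, path) -> None:
    out = design.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def filter_low_expression(
    matrix: ExpressionMatrix, cutoff: float = 0.3, mode: str = "mean"
) -> ExpressionMatrix:
    """Drop lowly expressed genes from an FPKM matrix.

    ``mode="mean"`` keeps genes whose mean FPKM across all samples exceeds
    ``cutoff``; ``mode="all"`` requires every sample to exceed it.
    """
    if matrix.scale != "fpkm":
        raise ConfigurationError("filter_low_expression expects an fpkm matrix")
    if cutoff < 0:
        raise ConfigurationError("cutoff must be >= 0")
    if mode == "mean":
        keep = matrix.data.mean(axis=1) > cutoff
    elif mode == "all":
        keep = (matrix.data > cutoff).all(axis=1)
    else:
        raise ConfigurationError(f"unknown filter mode {mode!r}; use 'mean' or 'all'")
    return replace(matrix, data=matrix.data.loc[keep])


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount).  Keeps zeros at zero for pseudocount 1."""
    if matrix.scale != "fpkm":
        raise ConfigurationError("log2_transform expects an fpkm matrix")
    values = matrix.data.to_numpy()
    if pseudocount <= 0 and (values == 0).any():
        raise ConfigurationError(
            "pseudocount must be > 0 when the matrix contains zero FPKM values"
        )
    if (values + pseudocount <= 0).any():
        raise ConfigurationError("fpkm + pseudocount must be positive everywhere")
    out = pd.DataFrame(
        np.log2(values + pseudocount), index=matrix.genes, columns=matrix.samples
    )
    return ExpressionMatrix(data=out, scale="log2")


def standardise(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (ddof=1).

    Zero-variance rows map to all-zeros and are recorded in
    ``zero_variance`` rather than producing NaNs.
    """
    if matrix.scale not in ("log2", "standardised"):
        raise ConfigurationError("standardise expects a log2 (or standardised) matrix")
    values = matrix.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    flagged = tuple(matrix.genes[flat])
    out = pd.DataFrame(z, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(data=out, scale="standardised", zero_variance=flagged)


@dataclass(frozen=True)
class PcaSummary:
    """Variance fractions and per-sample scores of a sample-space PCA."""

    variance_fraction: np.ndarray  # (n_components,), non-increasing
    scores: pd.DataFrame  # samples x components

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-8:
            raise ValueError("variance fractions sum above 1")


def pca(matrix: ExpressionMatrix, design: SampleDesign | None = None) -> PcaSummary:
    """PCA over samples (observations) in gene space.

    Uses the SVD of the column-centred samples x genes matrix; zero-variance
    genes are excluded since their standardised values carry no signal.
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("PCA needs at least 2 samples")
    if design is not None:
        design.validate_against(matrix)
    data = matrix.data
    if matrix.zero_variance:
        data = data.drop(index=list(matrix.zero_variance))
    x = data.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    var = s**2 / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaSummary(
        variance_fraction=frac,
        scores=pd.DataFrame(scores, index=matrix.samples, columns=cols),
    )


_LINKAGES = ("ward", "complete", "average", "single")
_DISTANCES = {
    "maximum": "chebyshev",
    "chebyshev": "chebyshev",
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "correlation": "correlation",
}


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative clustering of samples.

    ``merges`` is the scipy linkage matrix over ``sample_ids`` leaves.
    """

    merges: np.ndarray
    sample_ids: tuple[str, ...]
    linkage_name: str
    distance_name: str

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.sample_ids[i] for i in leaves_list(self.merges))

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(v) for v in labels)))


def hierarchical_clustering(
    matrix: ExpressionMatrix,
    linkage_name: str = "ward",
    distance_name: str = "maximum",
) -> ClusterTree:
    """Cluster samples with the given linkage on a precomputed dissimilarity.

    The default mirrors Ward linkage applied to the Chebyshev ("maximum")
    distance matrix between sample profiles.  Ward on a non-Euclidean
    dissimilarity is a recognised heuristic: merge heights can in rare cases
    be non-monotone.
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("clustering needs at least 2 samples")
    if linkage_name not in _LINKAGES:
        raise ConfigurationError(
            f"unknown linkage {linkage_name!r}; supported: {_LINKAGES}"
        )
    if distance_name not in _DISTANCES:
        raise ConfigurationError(
            f"unknown distance {distance_name!r}; supported: {tuple(_DISTANCES)}"
        )
    data = matrix.data
    if matrix.zero_variance:
        data = data.drop(index=list(matrix.zero_variance))
    profiles = data.to_numpy(dtype=float).T  # samples x genes
    condensed = pdist(profiles, metric=_DISTANCES[distance_name])
    merges = linkage(condensed, method=linkage_name)
    return ClusterTree(
        merges=merges,
        sample_ids=tuple(matrix.samples),
        linkage_name=linkage_name,
        distance_name=distance_name,
    )


def cluster_purity(tree: ClusterTree, labels: dict[str, str], n_clusters: int = 2) -> float:
    """Fraction of samples in the majority label of their cluster.

    With ``n_clusters=2`` and TGF-beta treatment labels this scores how
    cleanly the dendrogram separates treated from untreated samples.
    """
    assignment = tree.cut(n_clusters)
    correct = 0
    for cluster in set(assignment.values()):
        members = [s for s, c in assignment.items() if c == cluster]
        counts: dict[str, int] = {}
        for s in members:
            counts[labels[s]] = counts.get(labels[s], 0) + 1
        correct += max(counts.values())
    return correct / len(assignment)
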