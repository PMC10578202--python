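"""Expression-derived statistics on a feature x sample TPM matrix.

The matrix carries per-sample metadata (tissue, developmental stage,
replicate). From it we compute expressed-feature calls, the tau
tissue-specificity index, per-transcript expression breadth, and a
sample-similarity matrix with complete-linkage clustering.

tau (Yanai et al.) over per-tissue mean TPMs x_1..x_N:

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

0 for uniform expression, 1 for single-tissue expression. Genes with
tau strictly above 0.9 are called tissue specific and assigned to their
highest-mean tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ValidationError

__all__ = [
    "ExpressionMatrix",
    "is_expressed",
    "tau",
    "tissue_specific_genes",
    "expression_breadth",
    "sample_similarity",
    "cluster_samples",
]


@dataclass
class ExpressionMatrix:
    """TPM values (features x samples) plus sample metadata.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; ``metadata`` is indexed by sample name with columns
    ``tissue``, ``stage``, ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative TPM in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample names")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, metadata_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(values=values, metadata=metadata)

    def tissues(self) -> list[str]:
        return sorted(self.metadata["tissue"].unique())

    def tissue_means(self) -> pd.DataFrame:
        """Feature x tissue matrix of per-tissue mean TPM."""
        groups = self.metadata.loc[list(self.values.columns), "tissue"]
        return self.values.T.groupby(groups.values).mean().T.sort_index(axis=1)

    def tissue_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, tissue in self.metadata["tissue"].items():
            if sample in self.values.columns:
                out.setdefault(tissue, []).append(sample)
        return out


def is_expressed(row, min_tpm: float = 0.1, min_samples: int = 2) -> bool:
    """True iff at least min_samples entries are >= min_tpm (TPM >= 0.1 in >= 2 samples)."""
    row = np.asarray(row, dtype=float)
    return int((row >= min_tpm).sum()) >= min_samples


def tau(tissue_means) -> float:
    """Tissue-specificity index of a vector of per-tissue mean TPMs."""
    x = np.asarray(tissue_means, dtype=float)
    if x.size < 2:
        raise ValidationError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValidationError("tau requires non-negative means")
    top = x.max()
    if top == 0:
        raise ValidationError("tau undefined for an all-zero vector")
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tissue_specific_genes(
    matrix: ExpressionMatrix, tau_threshold: float = 0.9
) -> pd.DataFrame:
    """Genes with tau strictly above the threshold, assigned to their top tissue.

    Ties on the maximal tissue mean go to the lexicographically first
    tissue. Returns a DataFrame indexed by feature with columns
    ``tau`` and ``tissue``.
    """
    means = matrix.tissue_means()
    rows = []
    for feature, x in means.iterrows():
        if x.max() == 0:
            continue
        value = tau(x.to_numpy())
        if value > tau_threshold:
            top = x[x == x.max()].index.min()
            rows.append({"feature": feature, "tau": value, "tissue": top})
    return pd.DataFrame(rows, columns=["feature", "tau", "tissue"]).set_index("feature")


def expression_breadth(
    row: pd.Series,
    tissue_groups: dict[str, list[str]],
    min_tpm: float = 0.1,
    min_samples: int = 4,
) -> int:
    """Number of tissues where TPM is strictly above min_tpm in >= min_samples samples."""
    breadth = 0
    for samples in tissue_groups.values():
        if int((row.loc[samples] > min_tpm).sum()) >= min_samples:
            breadth += 1
    return breadth


def sample_similarity(matrix: ExpressionMatrix, pseudo_count: float = 0.1) -> pd.DataFrame:
    """Pearson correlation of log10(TPM + pseudo_count) between samples."""
    if matrix.values.shape[0] < 2 or matrix.values.shape[1] < 2:
        raise ValidationError("similarity needs >= 2 features and >= 2 samples")
    logged = np.log10(matrix.values + pseudo_count)
    flat = logged.std(axis=0)
    zero_var = flat[flat == 0]
    if len(zero_var):
        raise ValidationError(
            f"zero-variance sample vector(s): {list(zero_var.index)}"
        )
    return logged.corr(method="pearson")


def cluster_samples(similarity: pd.DataFrame) -> list[tuple[frozenset, frozenset, float]]:
    """Complete-linkage agglomeration on distance d = 1 - similarity.

    Returns the ordered merge list as (cluster_a, cluster_b, height)
    with clusters given as frozensets of sample names. Ties are broken
    by the smallest participating sample index, making the merge
    sequence fully deterministic.
    """
    names = list(similarity.columns)
    d = 1.0 - similarity.to_numpy(dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(names))]
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                height = max(d[i, j] for i in clusters[a] for j in clusters[b])
                key = (height, min(clusters[a] + clusters[b]), min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, *_), a, b = best
        merges.append(
            (
                frozenset(names[i] for i in clusters[a]),
                frozenset(names[i] for i in clusters[b]),
                float(height),
            )
        )
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges
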