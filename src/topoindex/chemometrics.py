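"""Similarity (cluster) analysis and PCA of descriptor tables.

Cluster analysis is agglomerative single linkage on Euclidean distances,
either between compounds (rows) or between descriptors (columns).  By default
it runs on the raw index values: that is the configuration that reproduces
the source study's dendrograms (their three compound clusters, and the
Rouvray index R joining the descriptor tree last) -- pass
``standardize=True`` for autoscaled input.

PCA is the eigendecomposition of the correlation matrix (equivalently, the
covariance of autoscaled data, the study's stated preprocessing); components
are retained by the Kaiser criterion (eigenvalue > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "standardize", "cluster", "pca", "ClusterTree", "PCAResult",
]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Autoscale every column to mean 0, unit sd (n-1 denominator)."""
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    return (table - table.mean()) / sd


@dataclass
class ClusterTree:
    """Single-linkage merge history over a labelled axis.

    ``merges`` is the scipy linkage matrix: row k merges clusters ``merges[k,0]``
    and ``merges[k,1]`` (ids < n are leaves) at height ``merges[k,2]``.
    """

    labels: list[str]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _states(self):
        """Yield (height, partition as dict id->set of labels) after each merge."""
        clusters = {i: {lab} for i, lab in enumerate(self.labels)}
        for k, (a, b, h, _) in enumerate(self.merges):
            clusters[self.n_leaves + k] = clusters.pop(int(a)) | clusters.pop(int(b))
            yield float(h), clusters

    def tight_multimember_clusters(self, k: int = 3) -> list[set[str]]:
        """The k tightest multi-member clusters.

        Walks merges in ascending height and returns the multi-member
        clusters of the first partition state containing exactly k of them
        (the smallest cut height with k multi-member groups).
        """
        for _, clusters in self._states():
            multi = [set(c) for c in clusters.values() if len(c) > 1]
            if len(multi) == k:
                return sorted(multi, key=lambda c: sorted(c))
        raise ValueError(f"no partition state with exactly {k} multi-member clusters")

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two clusters joined by the final (highest) merge."""
        clusters = dict(self._states_upto(len(self.merges) - 1))
        a, b = int(self.merges[-1, 0]), int(self.merges[-1, 1])
        return set(clusters[a]), set(clusters[b])

    def last_to_join(self) -> set[str]:
        """Labels of the smaller side of the final merge (the most distant item)."""
        sa, sb = self.top_split()
        return set(min(sa, sb, key=len))

    def _states_upto(self, k: int):
        clusters = {i: {lab} for i, lab in enumerate(self.labels)}
        for j, (a, b, h, _) in enumerate(self.merges[:k]):
            clusters[self.n_leaves + j] = clusters.pop(int(a)) | clusters.pop(int(b))
        return clusters.items()

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes: dict[int, str] = {i: lab.replace(" ", "_") for i, lab in enumerate(self.labels)}
        for k, (a, b, h, _) in enumerate(self.merges):
            nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return f"({nodes[n + len(self.merges) - 1]});" if len(self.merges) else f"({nodes[0]});"

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": [
                {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
                for a, b, h, s in self.merges
            ],
        }


def cluster(table: pd.DataFrame, axis: str = "compounds",
            standardize_first: bool = False) -> ClusterTree:
    """Single-linkage Euclidean clustering of rows (compounds) or columns
    (descriptors) of a descriptor table."""
    if axis not in ("compounds", "descriptors"):
        raise ValueError(f"axis must be 'compounds' or 'descriptors', got {axis!r}")
    data = standardize(table) if standardize_first else table
    if axis == "descriptors":
        data = data.T
    if len(data) < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r}, got {len(data)}")
    merges = linkage(data.values.astype(float), method="single", metric="euclidean")
    return ClusterTree(labels=list(data.index.astype(str)), merges=merges)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending; sums to the number of variables
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations x components
    n_kaiser: int  # eigenvalues strictly > 1

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca(table: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a descriptor table.

    With fewer observations than variables the correlation matrix is rank
    deficient; trailing eigenvalues within -1e-9 of zero are clamped to 0.
    Loading signs follow the convention that each component's
    largest-magnitude loading is positive.
    """
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 observations")
    z = standardize(table)  # raises on constant columns
    corr = np.corrcoef(table.values.astype(float), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals.min() < -1e-9:
        raise ValueError("correlation matrix has a significantly negative eigenvalue")
    evals = np.clip(evals, 0.0, None)
    # orientation-free sign convention
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=table.columns, columns=comp)
    scores = pd.DataFrame(z.values @ evecs, index=table.index, columns=comp)
    return PCAResult(
        eigenvalues=evals,
        loadings=loadings,
        scores=scores,
        n_kaiser=int((evals > 1.0).sum()),
    )
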