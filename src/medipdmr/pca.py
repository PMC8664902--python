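"""Principal component analysis of normalized counts over DMR windows.

The input is log2(CPM + 1) on effective (TMM-scaled) library sizes,
restricted to the windows that make up the called DMRs — a labeled
reconstruction of the usual "PCA of the differential regions" figure.
Scores come from a column-centered SVD with a deterministic sign
convention (each component's largest-magnitude loading is positive) so
results are byte-stable across runs and sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .difftest import NormalizationState
from .windowing import CountMatrix

__all__ = ["PCAResult", "normalize_for_pca", "compute_pca"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_explained: np.ndarray
    component_count: int

    def to_scores_tsv(self, path, groups: Sequence[str] | None = None) -> None:
        out = self.scores.copy()
        if groups is not None:
            out.insert(0, "group", list(groups))
        out.to_csv(path, sep="\t", index_label="sample_id")

    def to_variance_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.component_count)],
                "variance_explained": self.variance_explained,
            }
        ).to_csv(path, sep="\t", index=False)


def normalize_for_pca(
    counts: CountMatrix,
    dmr_window_indices: Sequence[int],
    normalization: NormalizationState,
) -> pd.DataFrame:
    """log2(CPM + 1) matrix (samples x DMR windows) on effective library sizes."""
    idx = np.asarray(list(dmr_window_indices), dtype=int)
    if idx.size == 0:
        raise ValueError(
            "no DMR windows to analyse — call DMRs first (or relax the p threshold)"
        )
    pos = {w: i for i, w in enumerate(counts.window_index)}
    missing = [w for w in idx if w not in pos]
    if missing:
        raise ValueError(f"windows {missing[:5]} are not in the count matrix")
    rows = np.array([pos[w] for w in idx])
    cpm = counts.counts[rows, :] / normalization.effective_lib_sizes[None, :] * 1e6
    mat = np.log2(cpm + 1.0).T  # samples x windows
    labels = [counts.windows[w].label for w in idx]
    return pd.DataFrame(mat, index=list(counts.samples), columns=labels)


def compute_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Column-centered SVD with a deterministic sign convention.

    ``variance_explained`` fractions are non-increasing and sum to 1
    when all rank components are kept; a constant input matrix yields
    all-zero scores and variance fractions.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fix each component's sign by its largest-magnitude loading
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total_var = float((s**2).sum())
    var_frac = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        variance_explained=var_frac[:k],
        component_count=k,
    )
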