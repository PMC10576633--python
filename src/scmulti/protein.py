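"""Antibody-count normalization, 2-D embedding and clone signature testing.

Antibody capture counts are compositional: each cell's total reflects
capture efficiency, not biology.  :func:`clr_normalize` applies the
centered log-ratio transform per cell (natural log, +1 pseudocount).
:func:`reduce_dim` projects cells to 2-D (PCA deterministic, UMAP/t-SNE
seeded), and :func:`find_signature` ranks proteins by a one-vs-rest Welch
t-test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .data_model import AssayMatrix, CloneLabels, SampleError

logger = logging.getLogger(__name__)

EMBED_METHODS = ("pca", "umap", "tsne")
DEFAULT_EMBED_METHOD = "umap"
DEFAULT_EMBED_SEED = 42


class ProteinError(ValueError):
    pass


@dataclass
class Embedding:
    """2-D cell coordinates with the method and seed that produced them."""

    coords: np.ndarray  # (n_cells, 2)
    method: str
    seed: int
    cell_barcodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ProteinError(f"coords must be (n_cells, 2), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ProteinError("coords must be finite")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def clr_normalize(counts: AssayMatrix) -> AssayMatrix:
    """Centered log-ratio transform of antibody counts, per cell.

    For cell i over P proteins: ``y(i,k) = ln(c(i,k)+1) - mean_m ln(c(i,m)+1)``.
    Every output row sums to zero.  Requires at least two proteins -- with a
    single protein the centering removes all information.
    """
    if counts.units != "count":
        raise ProteinError(f"clr_normalize expects units='count', got {counts.units!r}")
    if counts.n_features < 2:
        raise ProteinError("CLR needs >= 2 proteins; a single-protein panel "
                           "centers to all zeros")
    logc = np.log1p(counts.values.astype(float))
    y = logc - logc.mean(axis=1, keepdims=True)
    return AssayMatrix(
        values=y,
        cell_barcodes=counts.cell_barcodes.copy(),
        feature_ids=counts.feature_ids.copy(),
        units="normalized",
    )


def _fix_pca_signs(components: np.ndarray, coords: np.ndarray):
    """Flip each component so its largest-magnitude loading is positive."""
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            coords[:, k] *= -1
    return components, coords


def reduce_dim(
    matrix: AssayMatrix,
    method: str = DEFAULT_EMBED_METHOD,
    seed: int = DEFAULT_EMBED_SEED,
) -> Embedding:
    """Project cells to two dimensions.

    ``pca`` is deterministic (top-2 principal components, signs fixed so
    each component's largest-magnitude loading is positive); ``umap`` and
    ``tsne`` are run with *seed* as the random state, recorded on the
    returned :class:`Embedding`.
    """
    if method not in EMBED_METHODS:
        raise ProteinError(f"unknown method {method!r}; expected one of {EMBED_METHODS}")
    if matrix.units != "normalized":
        logger.warning("reduce_dim: input units are %r, not 'normalized'",
                       matrix.units)
    if matrix.n_cells < 3:
        raise ProteinError(f"need >= 3 cells to embed, got {matrix.n_cells}")
    x = matrix.values.astype(float)

    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(x)
        _fix_pca_signs(pca.components_, coords)
    elif method == "umap":
        import umap  # deferred: slow import (numba compilation)

        reducer = umap.UMAP(n_components=2, random_state=seed)
        coords = reducer.fit_transform(x)
    else:  # tsne
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(1.0, (matrix.n_cells - 1) / 3.0))
        coords = TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(x)

    return Embedding(
        coords=np.asarray(coords, dtype=float),
        method=method,
        seed=seed,
        cell_barcodes=matrix.cell_barcodes.copy(),
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def find_signature(
    matrix: AssayMatrix,
    labels: CloneLabels,
    target_clone: int,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """One-vs-rest differential expression of each protein for one clone.

    Cells of *target_clone* are compared against all other labeled cells
    (noise cells, label 0, are excluded) with a two-sided Welch t-test per
    protein; p-values are BH-adjusted across proteins.  The table is sorted
    by adjusted p-value (ties: raw p-value, then protein id) with columns
    ``protein_id, mean_target, mean_rest, difference, t_statistic, p_value,
    p_adjusted``.
    """
    if matrix.units != "normalized":
        raise ProteinError(
            f"find_signature expects units='normalized', got {matrix.units!r};"
            " run clr_normalize first"
        )
    if len(labels) != matrix.n_cells:
        raise SampleError(
            f"labels length {len(labels)} != matrix rows {matrix.n_cells}"
        )
    lab = labels.labels
    if target_clone <= 0:
        raise ProteinError("target_clone must be a positive clone number")
    target = lab == target_clone
    rest = (lab > 0) & ~target
    if target.sum() < min_group_size or rest.sum() < min_group_size:
        raise ProteinError(
            f"need >= {min_group_size} cells per group; clone {target_clone} "
            f"has {int(target.sum())}, rest has {int(rest.sum())}"
        )
    a = matrix.values[target]
    b = matrix.values[rest]
    t_stat, p_val = stats.ttest_ind(a, b, axis=0, equal_var=False)
    # degenerate proteins (zero variance in both groups) -> no evidence
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    p_adj = benjamini_hochberg(p_val)

    table = pd.DataFrame(
        {
            "protein_id": matrix.feature_ids,
            "mean_target": a.mean(axis=0),
            "mean_rest": b.mean(axis=0),
            "t_statistic": t_stat,
            "p_value": p_val,
            "p_adjusted": p_adj,
        }
    )
    table["difference"] = table["mean_target"] - table["mean_rest"]
    table = table[
        ["protein_id", "mean_target", "mean_rest", "difference",
         "t_statistic", "p_value", "p_adjusted"]
    ]
    table = table.sort_values(
        ["p_adjusted", "p_value", "protein_id"], kind="stable"
    ).reset_index(drop=True)
    return table
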