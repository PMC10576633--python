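"""Variant-call QC filtering, clone identification and variant annotation.

The DNA stage turns raw per-cell genotype calls into a clean VAF matrix and
a per-cell clone assignment:

1. :func:`call_validity_mask` flags each (cell, variant) call as trustworthy
   or not based on depth, genotype quality and allele-frequency support.
2. :func:`filter_variants` removes cells with too many invalid calls, then
   variants that are poorly covered or never mutated.
3. :func:`identify_clones` runs DBSCAN on the scaled VAF matrix; noise cells
   get label 0 and clusters are numbered 1..K by decreasing size.
4. :func:`clone_sorted_matrix` orders rows for clone-blocked heatmaps and
   :func:`annotate_variants` attaches gene-level annotation through a
   pluggable provider (offline lookup table by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .data_model import (
    AssayMatrix,
    CloneLabels,
    DnaVariantAssay,
    MultiomicSample,
    SampleError,
    renumber_by_size,
)

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    """Raised when QC filtering removes every cell or every variant."""


@dataclass
class QCThresholds:
    """Thresholds applied to individual genotype calls and to cells/variants.

    A call is *valid* when it is not missing, has depth >= ``min_depth``,
    genotype quality >= ``min_gq`` and -- for mutated calls -- allele
    frequency >= ``min_af_mutated`` percent.  Cells and variants whose
    fraction of valid calls falls below the completeness thresholds are
    removed, as are variants mutated in less than
    ``variant_min_mutated_fraction`` of their valid calls.
    """

    min_depth: float = 10
    min_gq: float = 30
    min_af_mutated: float = 20.0
    cell_min_valid_fraction: float = 0.5
    variant_min_valid_fraction: float = 0.5
    variant_min_mutated_fraction: float = 0.01

    def __post_init__(self) -> None:
        for name in ("cell_min_valid_fraction", "variant_min_valid_fraction",
                     "variant_min_mutated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("min_depth and min_gq must be >= 0")
        if not 0 <= self.min_af_mutated <= 100:
            raise ValueError("min_af_mutated must lie in [0, 100]")


@dataclass
class FilterReport:
    cells_before: int
    cells_after: int
    variants_before: int
    variants_after: int
    invalid_call_fraction: float
    removed: Dict[str, int] = field(default_factory=dict)

    def render(self) -> str:
        lines = [
            f"cells:    {self.cells_before} -> {self.cells_after}",
            f"variants: {self.variants_before} -> {self.variants_after}",
            f"invalid call fraction: {self.invalid_call_fraction:.4f}",
        ]
        lines += [f"removed[{k}]: {v}" for k, v in self.removed.items()]
        return "\n".join(lines)


@dataclass
class ClusterParams:
    """DBSCAN parameters for clone identification on scaled VAF vectors."""

    min_points: int = 10
    epsilon: Optional[float] = None  # auto-estimated from the k-NN knee when None
    af_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0 when given")


def call_validity_mask(dna: DnaVariantAssay, qc: QCThresholds) -> np.ndarray:
    """Boolean (n_cells x n_variants) mask of trustworthy genotype calls.

    Entry (i, j) is True iff the call is not missing (NGT != 3), depth and
    genotype quality meet their thresholds, and -- when the genotype is
    mutated -- the allele frequency supports it (AF >= min_af_mutated).
    """
    ngt = dna.NGT
    mask = (
        (ngt != 3)
        & (dna.DP >= qc.min_depth)
        & (dna.GQ >= qc.min_gq)
        & ((ngt == 0) | (dna.AF >= qc.min_af_mutated))
    )
    return mask


def filter_variants(
    sample: MultiomicSample, qc: QCThresholds | None = None
) -> tuple[MultiomicSample, FilterReport]:
    """QC-filter variant calls; drop bad cells from all assays, then bad variants.

    Cells whose fraction of valid calls across variants falls below
    ``cell_min_valid_fraction`` are removed from every assay (the cell axis
    is shared).  On the remaining cells a variant is kept iff its fraction
    of valid calls is >= ``variant_min_valid_fraction`` and the fraction of
    mutated genotypes (NGT 1 or 2) among its valid calls is >=
    ``variant_min_mutated_fraction``.  Invalid calls are recorded in
    ``sample.dna.valid_mask`` (masked, not zeroed) for downstream use.
    """
    qc = qc or QCThresholds()
    if sample.status.dna_filtered:
        logger.warning("filter_variants: sample already marked dna_filtered")
    dna = sample.dna
    n_cells, n_variants = dna.n_cells, dna.n_variants
    mask = call_validity_mask(dna, qc)
    invalid_fraction = 1.0 - (mask.mean() if mask.size else 0.0)

    cell_valid_frac = mask.mean(axis=1) if n_variants else np.ones(n_cells)
    keep_cells = cell_valid_frac >= qc.cell_min_valid_fraction
    if not keep_cells.any():
        raise FilterError(
            f"all {n_cells} cells removed at cell_min_valid_fraction="
            f"{qc.cell_min_valid_fraction} (min_depth={qc.min_depth}, "
            f"min_gq={qc.min_gq}, min_af_mutated={qc.min_af_mutated})"
        )

    mask_c = mask[keep_cells]
    ngt_c = dna.NGT[keep_cells]
    n_valid = mask_c.sum(axis=0)
    variant_valid_frac = n_valid / mask_c.shape[0]
    mutated = mask_c & ((ngt_c == 1) | (ngt_c == 2))
    with np.errstate(invalid="ignore"):
        mutated_frac = np.where(n_valid > 0, mutated.sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    pass_completeness = variant_valid_frac >= qc.variant_min_valid_fraction
    pass_mutated = mutated_frac >= qc.variant_min_mutated_fraction
    keep_variants = pass_completeness & pass_mutated
    if not keep_variants.any():
        raise FilterError(
            f"all {n_variants} variants removed at variant_min_valid_fraction="
            f"{qc.variant_min_valid_fraction}, variant_min_mutated_fraction="
            f"{qc.variant_min_mutated_fraction}"
        )

    cell_idx = np.flatnonzero(keep_cells)
    out = sample.subset_cells(cell_idx)
    out.dna = out.dna.subset_variants(np.flatnonzero(keep_variants))
    out.dna.valid_mask = mask[np.ix_(cell_idx, np.flatnonzero(keep_variants))]
    out.status.dna_filtered = True

    report = FilterReport(
        cells_before=n_cells,
        cells_after=int(keep_cells.sum()),
        variants_before=n_variants,
        variants_after=int(keep_variants.sum()),
        invalid_call_fraction=float(invalid_fraction),
        removed={
            "cells_low_valid_fraction": int((~keep_cells).sum()),
            "variants_low_valid_fraction": int((~pass_completeness).sum()),
            "variants_low_mutated_fraction": int(
                (pass_completeness & ~pass_mutated).sum()
            ),
        },
    )
    logger.info("filter_variants: %s", report.render().replace("\n", "; "))
    return out, report


def estimate_epsilon(scaled_af: np.ndarray, min_points: int) -> float:
    """DBSCAN radius from the knee of the sorted k-NN distance curve.

    The distance of each cell to its ``min_points``-th nearest neighbour is
    sorted ascending; the knee is the point of maximum deviation from the
    chord joining the curve's endpoints (a max-curvature proxy).
    """
    n = scaled_af.shape[0]
    k = min(min_points, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scaled_af)
    dists, _ = nn.kneighbors(scaled_af)
    curve = np.sort(dists[:, -1])
    if curve[-1] <= curve[0]:  # flat curve: all cells equally spaced
        eps = float(curve[-1]) if curve[-1] > 0 else 1e-3
        return eps
    x = np.linspace(0.0, 1.0, n)
    y = (curve - curve[0]) / (curve[-1] - curve[0])
    # distance from each point to the chord y = x (normalized endpoints)
    deviation = y - x
    knee = int(np.argmax(np.abs(deviation)))
    eps = float(curve[knee])
    if eps <= 0:
        eps = float(curve[curve > 0][0]) if (curve > 0).any() else 1e-3
    return eps


def identify_clones(
    sample: MultiomicSample, params: ClusterParams | None = None
) -> CloneLabels:
    """Cluster cells into clones with DBSCAN on the scaled VAF matrix.

    AF is divided by ``af_scale`` (values in [0, 1]); invalid calls, when a
    validity mask is present, are imputed with the per-variant mean of valid
    calls so that missing data does not distort Euclidean distances.  Noise
    cells receive label 0; clusters are renumbered 1..K by decreasing size.
    The labels are stored on the sample and returned.
    """
    params = params or ClusterParams()
    if not sample.status.dna_filtered:
        logger.warning("identify_clones: sample has not been QC-filtered")
    n = sample.n_cells
    if n < params.min_points:
        raise SampleError(
            f"cannot cluster {n} cells with min_points={params.min_points}"
        )
    af = sample.dna.AF / params.af_scale
    if sample.dna.valid_mask is not None:
        af = af.copy()
        mask = sample.dna.valid_mask
        with np.errstate(invalid="ignore"):
            col_sum = np.where(mask, af, 0.0).sum(axis=0)
            col_n = mask.sum(axis=0)
            col_mean = np.where(col_n > 0, col_sum / np.maximum(col_n, 1), 0.0)
        af[~mask] = np.broadcast_to(col_mean, af.shape)[~mask]

    eps = params.epsilon
    if eps is None:
        eps = estimate_epsilon(af, params.min_points)
        logger.info("identify_clones: auto-estimated epsilon=%.6g "
                    "(min_points=%d)", eps, params.min_points)
    raw = DBSCAN(eps=eps, min_samples=params.min_points).fit_predict(af)
    labels = CloneLabels(renumber_by_size(raw + 1))  # DBSCAN noise -1 -> 0
    sample.clone_labels = labels
    logger.info("identify_clones: %d clones, %d noise cells",
                labels.n_clones, int((labels.labels == 0).sum()))
    return labels


def clone_sorted_matrix(
    matrix: AssayMatrix, labels: CloneLabels
) -> tuple[AssayMatrix, pd.DataFrame]:
    """Reorder rows by (clone label ascending, barcode ascending).

    Returns the permuted matrix and a per-row annotation frame with columns
    ``barcode`` and ``clone`` in the new order, ready for heatmap rendering.
    """
    if len(labels) != matrix.n_cells:
        raise SampleError(
            f"labels length {len(labels)} != matrix rows {matrix.n_cells}"
        )
    lab = labels.labels
    order = np.lexsort((matrix.cell_barcodes.astype(str), lab))
    reordered = matrix.subset_cells(order)
    annotation = pd.DataFrame(
        {"barcode": reordered.cell_barcodes, "clone": lab[order]}
    )
    return reordered, annotation


def feature_overlay(
    embedding, values: Sequence[float], feature_name: str
) -> pd.DataFrame:
    """Per-cell (x, y, value) tuples for coloring an embedding by a feature.

    *embedding* may be an :class:`~scmulti.protein.Embedding` or a plain
    (n_cells x 2) coordinate array.  Row order is preserved.
    """
    coords = getattr(embedding, "coords", embedding)
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise SampleError(f"embedding must be (n_cells, 2), got {coords.shape}")
    if len(values) != coords.shape[0]:
        raise SampleError(
            f"values length {len(values)} != embedding rows {coords.shape[0]}"
        )
    return pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "value": values,
         "feature": feature_name}
    )


# --- variant annotation -------------------------------------------------

_VARIANT_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[A-Za-z*-]+)/(?P<alt>[A-Za-z*-]+)$")

ANNOTATION_FIELDS = ("gene", "protein_change", "function_class")


def parse_variant_id(variant_id: str) -> Dict[str, str]:
    """Split a ``CHROM:POS:REF/ALT`` id into its components (POS 1-based)."""
    m = _VARIANT_ID_RE.match(variant_id)
    if not m:
        raise ValueError(f"unparseable variant id: {variant_id!r} "
                         "(expected CHROM:POS:REF/ALT)")
    return m.groupdict()


class AnnotationProvider(Protocol):
    """Source of per-variant annotation records.

    Implementations return a mapping with keys ``gene``, ``protein_change``
    and ``function_class`` for a known variant id, or ``None`` on a miss.
    A network-backed provider (e.g. a vendor annotation API client) is a
    supported extension point; the bundled default is a local lookup table.
    """

    def lookup(self, variant_id: str) -> Optional[Dict[str, str]]: ...


class TableAnnotationProvider:
    """Annotation provider backed by a tab-separated lookup table.

    The table needs columns ``variant_id``, ``gene``, ``protein_change`` and
    ``function_class``.  Without a path, the small lookup table bundled with
    the package is used.
    """

    def __init__(self, path: Optional[Path] = None):
        if path is None:
            ref = resources.files("scmulti").joinpath("data/variant_annotations.tsv")
            with resources.as_file(ref) as p:
                table = pd.read_csv(p, sep="\t", dtype=str)
        else:
            table = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"variant_id", *ANNOTATION_FIELDS} - set(table.columns)
        if missing:
            raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
        self._records = {
            row["variant_id"]: {f: row[f] for f in ANNOTATION_FIELDS}
            for _, row in table.iterrows()
        }

    def lookup(self, variant_id: str) -> Optional[Dict[str, str]]:
        return self._records.get(variant_id)


class DictAnnotationProvider:
    """In-memory provider, mainly for tests and ad-hoc tables."""

    def __init__(self, records: Dict[str, Dict[str, str]]):
        self._records = dict(records)

    def lookup(self, variant_id: str) -> Optional[Dict[str, str]]:
        return self._records.get(variant_id)


def annotate_variants(
    variant_ids: Sequence[str], provider: AnnotationProvider | None = None
) -> pd.DataFrame:
    """One annotation row per input variant id, in input order.

    Ids must parse as ``CHROM:POS:REF/ALT``; a provider miss yields a row of
    nulls rather than an error.
    """
    provider = provider or TableAnnotationProvider()
    rows = []
    for vid in variant_ids:
        parts = parse_variant_id(vid)
        hit = provider.lookup(vid)
        row = {"variant_id": vid, "chrom": parts["chrom"],
               "pos": int(parts["pos"]), "ref": parts["ref"], "alt": parts["alt"]}
        for f in ANNOTATION_FIELDS:
            row[f] = hit[f] if hit else None
        rows.append(row)
    columns = ["variant_id", "chrom", "pos", "ref", "alt", *ANNOTATION_FIELDS]
    return pd.DataFrame(rows, columns=columns)
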