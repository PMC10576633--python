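"""In-memory containers for a single-sample multi-assay experiment.

A :class:`MultiomicSample` bundles three cell-by-feature assays measured on
the same cells -- DNA variant calls, CNV amplicon read counts and antibody
(protein) read counts -- together with optional per-cell clone labels and
processing-status flags.  All pipeline stages consume and return these
types; construction enforces a single canonical cell order shared by every
assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Allowed values for :attr:`AssayMatrix.units`.
UNITS = ("count", "percent", "normalized", "ploidy")

#: Genotype call codes used in the NGT layer.
NGT_WILDTYPE = 0
NGT_HET = 1
NGT_HOM_ALT = 2
NGT_MISSING = 3


class SampleError(ValueError):
    """Raised when a container violates its consistency rules."""


def _check_unique(names: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(names, dtype=object)
    if len(set(arr)) != len(arr):
        raise SampleError(f"{what} must be pairwise distinct")
    return arr


@dataclass
class AssayMatrix:
    """Generic cell x feature numeric matrix with identifiers and a units tag.

    Parameters
    ----------
    values
        Numeric matrix of shape ``(n_cells, n_features)``.
    cell_barcodes
        Unique cell barcodes, one per row.
    feature_ids
        Unique feature identifiers, one per column.
    units
        One of ``{"count", "percent", "normalized", "ploidy"}``.  Count
        matrices must hold non-negative integers.
    """

    values: np.ndarray
    cell_barcodes: np.ndarray
    feature_ids: np.ndarray
    units: str = "count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise SampleError("values must be a 2-D matrix")
        self.cell_barcodes = _check_unique(self.cell_barcodes, "cell barcodes")
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        n_cells, n_features = self.values.shape
        if len(self.cell_barcodes) != n_cells:
            raise SampleError(
                f"barcode count {len(self.cell_barcodes)} != row count {n_cells}"
            )
        if len(self.feature_ids) != n_features:
            raise SampleError(
                f"feature-id count {len(self.feature_ids)} != column count {n_features}"
            )
        if self.units not in UNITS:
            raise SampleError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.units == "count":
            vals = self.values
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise SampleError("count matrices must contain non-negative integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "AssayMatrix":
        """Return a copy restricted to the given cell (row) index array."""
        return AssayMatrix(
            values=self.values[index].copy(),
            cell_barcodes=self.cell_barcodes[index].copy(),
            feature_ids=self.feature_ids.copy(),
            units=self.units,
        )


@dataclass
class DnaVariantAssay:
    """Four aligned cell x variant layers from single-cell variant calling.

    ``AF`` holds variant allele frequencies in percent (0-100), ``NGT``
    genotype codes (0 wild-type, 1 het, 2 hom-alt, 3 missing), ``GQ``
    genotype qualities and ``DP`` read depths.  Variant ids use the
    canonical ``CHROM:POS:REF/ALT`` form with 1-based positions.
    """

    AF: np.ndarray
    NGT: np.ndarray
    GQ: np.ndarray
    DP: np.ndarray
    cell_barcodes: np.ndarray
    variant_ids: np.ndarray
    #: optional call-validity mask set by QC filtering (True = trustworthy call)
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.AF = np.asarray(self.AF, dtype=float)
        self.NGT = np.asarray(self.NGT)
        self.GQ = np.asarray(self.GQ)
        self.DP = np.asarray(self.DP)
        shapes = {self.AF.shape, self.NGT.shape, self.GQ.shape, self.DP.shape}
        if len(shapes) != 1 or self.AF.ndim != 2:
            raise SampleError(f"AF/NGT/GQ/DP must share one 2-D shape, got {shapes}")
        self.cell_barcodes = _check_unique(self.cell_barcodes, "cell barcodes")
        self.variant_ids = _check_unique(self.variant_ids, "variant ids")
        n_cells, n_variants = self.AF.shape
        if len(self.cell_barcodes) != n_cells:
            raise SampleError(
                f"barcode count {len(self.cell_barcodes)} != row count {n_cells}"
            )
        if len(self.variant_ids) != n_variants:
            raise SampleError(
                f"variant-id count {len(self.variant_ids)} != column count {n_variants}"
            )
        if self.AF.size:
            if np.nanmin(self.AF) < 0 or np.nanmax(self.AF) > 100:
                raise SampleError("AF entries must lie in [0, 100]")
            if not np.isin(self.NGT, [0, 1, 2, 3]).all():
                raise SampleError("NGT entries must be in {0,1,2,3}")
            if np.any(self.DP < 0) or not np.allclose(self.DP, np.round(self.DP)):
                raise SampleError("DP must be integral and >= 0")
            if np.any(self.GQ < 0):
                raise SampleError("GQ must be >= 0")
        if self.valid_mask is not None and self.valid_mask.shape != self.AF.shape:
            raise SampleError("valid_mask shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.AF.shape[0]

    @property
    def n_variants(self) -> int:
        return self.AF.shape[1]

    def subset_cells(self, index: np.ndarray) -> "DnaVariantAssay":
        return DnaVariantAssay(
            AF=self.AF[index].copy(),
            NGT=self.NGT[index].copy(),
            GQ=self.GQ[index].copy(),
            DP=self.DP[index].copy(),
            cell_barcodes=self.cell_barcodes[index].copy(),
            variant_ids=self.variant_ids.copy(),
            valid_mask=None if self.valid_mask is None else self.valid_mask[index].copy(),
        )

    def subset_variants(self, index: np.ndarray) -> "DnaVariantAssay":
        return DnaVariantAssay(
            AF=self.AF[:, index].copy(),
            NGT=self.NGT[:, index].copy(),
            GQ=self.GQ[:, index].copy(),
            DP=self.DP[:, index].copy(),
            cell_barcodes=self.cell_barcodes.copy(),
            variant_ids=self.variant_ids[index].copy(),
            valid_mask=None if self.valid_mask is None else self.valid_mask[:, index].copy(),
        )

    def af_matrix(self) -> AssayMatrix:
        """Expose the AF layer as an :class:`AssayMatrix` (units=percent)."""
        return AssayMatrix(
            values=self.AF.copy(),
            cell_barcodes=self.cell_barcodes.copy(),
            feature_ids=self.variant_ids.copy(),
            units="percent",
        )


@dataclass
class CloneLabels:
    """Per-cell integer clone assignment.

    Label 0 marks unassigned/noise cells; positive labels are clone numbers
    ``1..K`` assigned by decreasing clone size (ties broken by the smaller
    pre-renumbering label).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise SampleError("labels must be a 1-D vector")
        if np.any(self.labels < 0):
            raise SampleError("labels must be >= 0 (0 = unassigned/noise)")
        positive = np.unique(self.labels[self.labels > 0])
        if positive.size and not np.array_equal(positive, np.arange(1, positive.size + 1)):
            raise SampleError(
                f"positive labels must be exactly 1..K with no gaps, got {positive.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clones(self) -> int:
        return int(self.labels.max(initial=0))

    def clone_sizes(self) -> Dict[int, int]:
        uniq, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


def renumber_by_size(raw: np.ndarray) -> np.ndarray:
    """Renumber positive labels 1..K by decreasing group size.

    Zeros are preserved.  Ties in size are broken by the smaller original
    label coming first (receiving the smaller new label).
    """
    raw = np.asarray(raw, dtype=int)
    out = np.zeros_like(raw)
    uniq, counts = np.unique(raw[raw > 0], return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    for new, i in enumerate(order, start=1):
        out[raw == uniq[i]] = new
    return out


@dataclass
class StatusFlags:
    dna_filtered: bool = False
    cnv_normalized: bool = False
    protein_normalized: bool = False

    def as_dict(self) -> Dict[str, bool]:
        return {
            "dna_filtered": self.dna_filtered,
            "cnv_normalized": self.cnv_normalized,
            "protein_normalized": self.protein_normalized,
        }


@dataclass
class MultiomicSample:
    """All assays for one biological sample, on one canonical cell order."""

    name: str
    dna: DnaVariantAssay
    cnv: AssayMatrix
    protein: AssayMatrix
    clone_labels: Optional[CloneLabels] = None
    status: StatusFlags = field(default_factory=StatusFlags)

    def __post_init__(self) -> None:
        bc = self.dna.cell_barcodes
        for other, label in ((self.cnv, "cnv"), (self.protein, "protein")):
            if not np.array_equal(bc, other.cell_barcodes):
                raise SampleError(
                    f"{label} assay barcodes differ from DNA barcodes; "
                    "use build_sample() to reconcile assays"
                )
        if self.clone_labels is not None and len(self.clone_labels) != len(bc):
            raise SampleError(
                f"clone labels length {len(self.clone_labels)} != n_cells {len(bc)}"
            )

    @property
    def cell_barcodes(self) -> np.ndarray:
        return self.dna.cell_barcodes

    @property
    def n_cells(self) -> int:
        return self.dna.n_cells

    def subset_cells(self, index: np.ndarray) -> "MultiomicSample":
        labels = None
        if self.clone_labels is not None:
            labels = CloneLabels(renumber_by_size(self.clone_labels.labels[index]))
        return MultiomicSample(
            name=self.name,
            dna=self.dna.subset_cells(index),
            cnv=self.cnv.subset_cells(index),
            protein=self.protein.subset_cells(index),
            clone_labels=labels,
            status=replace(self.status),
        )


@dataclass
class SummaryStats:
    """Dimension counts and status flags for one sample."""

    n_cells: int
    n_variants: int
    n_cnv_amplicons: int
    n_proteins: int
    status: Dict[str, bool]

    def render(self) -> str:
        lines = [
            f"cells:         {self.n_cells}",
            f"variants:      {self.n_variants}",
            f"CNV amplicons: {self.n_cnv_amplicons}",
            f"proteins:      {self.n_proteins}",
        ]
        lines += [f"{k}: {v}" for k, v in self.status.items()]
        return "\n".join(lines)


@dataclass
class DropReport:
    """Barcodes discarded per assay when reconciling a sample."""

    dropped: Dict[str, list]

    def counts(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.dropped.items()}


def build_sample(
    dna: DnaVariantAssay,
    cnv: AssayMatrix,
    protein: AssayMatrix,
    name: str = "sample",
) -> tuple[MultiomicSample, DropReport]:
    """Assemble a sample on the intersection of the three barcode sets.

    Assays are restricted to the shared barcodes and reordered to a single
    canonical (lexicographic) cell order.  Row values travel with their
    barcode; nothing else is transformed.

    Returns the sample together with a :class:`DropReport` listing, per
    assay, the barcodes that were not shared by all three assays.

    Raises
    ------
    SampleError
        If the barcode intersection is empty.
    """
    sets = {
        "dna": set(dna.cell_barcodes.tolist()),
        "cnv": set(cnv.cell_barcodes.tolist()),
        "protein": set(protein.cell_barcodes.tolist()),
    }
    common = sets["dna"] & sets["cnv"] & sets["protein"]
    if not common:
        raise SampleError(
            "empty barcode intersection across assays "
            f"(dna={len(sets['dna'])}, cnv={len(sets['cnv'])}, "
            f"protein={len(sets['protein'])} barcodes)"
        )
    order = sorted(common)
    report = DropReport(
        dropped={k: sorted(s - common) for k, s in sets.items()}
    )
    for assay, n_drop in report.counts().items():
        if n_drop:
            logger.info("build_sample: dropping %d %s-only barcodes", n_drop, assay)

    def row_index(barcodes: np.ndarray) -> np.ndarray:
        pos = {b: i for i, b in enumerate(barcodes.tolist())}
        return np.array([pos[b] for b in order], dtype=int)

    sample = MultiomicSample(
        name=name,
        dna=dna.subset_cells(row_index(dna.cell_barcodes)),
        cnv=cnv.subset_cells(row_index(cnv.cell_barcodes)),
        protein=protein.subset_cells(row_index(protein.cell_barcodes)),
    )
    return sample, report


def summarize(sample: MultiomicSample) -> SummaryStats:
    """Dimension counts plus processing-status flags for *sample*."""
    return SummaryStats(
        n_cells=sample.n_cells,
        n_variants=sample.dna.n_variants,
        n_cnv_amplicons=sample.cnv.n_features,
        n_proteins=sample.protein.n_features,
        status=sample.status.as_dict(),
    )


def set_clone_labels(sample: MultiomicSample, labels) -> MultiomicSample:
    """Store per-cell clone labels on *sample*, renumbered by clone size.

    Positive labels are renumbered ``1..K`` by decreasing clone size (ties
    broken by the smaller original label); zeros stay zero.  The sample is
    modified in place and also returned.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or len(labels) != sample.n_cells:
        raise SampleError(
            f"labels length {labels.size} != sample cell count {sample.n_cells}"
        )
    if np.any(labels < 0):
        raise SampleError("labels must be >= 0")
    sample.clone_labels = CloneLabels(renumber_by_size(labels))
    return sample
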