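"""CNV count normalization and per-amplicon ploidy against a diploid reference.

Raw amplicon read counts vary multiplicatively by cell (droplet depth) and
by amplicon (primer efficiency).  :func:`normalize_cnv` removes both
effects; :func:`calculate_ploidy` then rescales normalized counts so that a
user-designated reference clone -- assumed diploid genome-wide -- sits at
ploidy 2 on every amplicon, which makes other clones' values interpretable
as copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import AssayMatrix, CloneLabels, SampleError

logger = logging.getLogger(__name__)

#: minimum reference-clone size for a usable per-amplicon mean
MIN_REFERENCE_CELLS = 10


class CnvError(ValueError):
    pass


@dataclass
class PloidyResult:
    """Per-cell and per-clone ploidy estimates.

    ``cell_ploidy`` is an (n_cells x n_amplicons) matrix (units=ploidy) on
    the cells that entered the calculation; ``clone_ploidy`` averages it
    within each clone 1..K (noise cells excluded).  The row of
    ``clone_ploidy`` belonging to ``reference_clone`` equals 2 at every
    amplicon by construction.
    """

    cell_ploidy: AssayMatrix
    clone_ploidy: np.ndarray  # (K, n_amplicons)
    clone_ids: np.ndarray  # (K,) clone numbers matching clone_ploidy rows
    amplicon_ids: np.ndarray
    reference_clone: int

    def clone_row(self, clone: int) -> np.ndarray:
        idx = np.flatnonzero(self.clone_ids == clone)
        if idx.size != 1:
            raise KeyError(f"clone {clone} not present")
        return self.clone_ploidy[idx[0]]

    def tidy(self):
        """(clone, amplicon, ploidy) triples for scatter plotting."""
        import pandas as pd

        rows = [
            {"clone": int(g), "amplicon": a, "ploidy": float(p)}
            for gi, g in enumerate(self.clone_ids)
            for a, p in zip(self.amplicon_ids, self.clone_ploidy[gi])
        ]
        return pd.DataFrame(rows, columns=["clone", "amplicon", "ploidy"])


def normalize_cnv(counts: AssayMatrix) -> AssayMatrix:
    """Remove cell-wise and amplicon-wise scale from raw CNV counts.

    Two steps: each cell's counts are rescaled so its total matches the
    median cell total (cells with total 0 are dropped with a warning), then
    each amplicon is divided by its median across cells (amplicons with a
    zero median are dropped with a warning).  In the resulting matrix a
    typical diploid cell sits near 1 everywhere.
    """
    if counts.units != "count":
        raise CnvError(f"normalize_cnv expects units='count', got {counts.units!r}")
    if counts.n_cells < 1 or counts.n_features < 1:
        raise CnvError("need at least 1 cell and 1 amplicon")
    c = counts.values.astype(float)

    totals = c.sum(axis=1)
    keep_cells = totals > 0
    if not keep_cells.all():
        logger.warning("normalize_cnv: dropping %d cells with zero total counts",
                       int((~keep_cells).sum()))
    c = c[keep_cells]
    totals = totals[keep_cells]
    if c.shape[0] == 0:
        raise CnvError("all cells have zero total CNV counts")
    r = c / totals[:, None] * np.median(totals)

    m = np.median(r, axis=0)
    keep_amps = m > 0
    if not keep_amps.all():
        logger.warning("normalize_cnv: dropping %d amplicons with zero median",
                       int((~keep_amps).sum()))
    if not keep_amps.any():
        raise CnvError("all amplicons dropped (zero median normalized counts)")
    n = r[:, keep_amps] / m[keep_amps]

    return AssayMatrix(
        values=n,
        cell_barcodes=counts.cell_barcodes[keep_cells],
        feature_ids=counts.feature_ids[keep_amps],
        units="normalized",
    )


def calculate_ploidy(
    normalized: AssayMatrix,
    labels: CloneLabels,
    reference_clone: int,
    min_reference_cells: int = MIN_REFERENCE_CELLS,
) -> PloidyResult:
    """Per-amplicon ploidy of every cell and clone, anchored on a diploid clone.

    For each amplicon j, mu(j) is the mean normalized count over cells of
    the reference clone; cell ploidy is ``2 * n(i, j) / mu(j)`` and clone
    ploidy the within-clone mean (noise cells, label 0, are excluded).  By
    construction the reference clone's ploidy is exactly 2 at every
    amplicon.
    """
    if normalized.units != "normalized":
        raise CnvError(
            f"calculate_ploidy expects units='normalized', got {normalized.units!r};"
            " run normalize_cnv first"
        )
    if len(labels) != normalized.n_cells:
        raise SampleError(
            f"labels length {len(labels)} != matrix rows {normalized.n_cells}"
        )
    if reference_clone <= 0:
        raise CnvError("reference_clone must be a positive clone number")
    lab = labels.labels
    ref_cells = lab == reference_clone
    n_ref = int(ref_cells.sum())
    if n_ref < min_reference_cells:
        raise CnvError(
            f"reference clone {reference_clone} has {n_ref} cells; "
            f"need >= {min_reference_cells}"
        )
    n = normalized.values
    mu = n[ref_cells].mean(axis=0)
    zero = np.flatnonzero(mu == 0)
    if zero.size:
        bad = normalized.feature_ids[zero[0]]
        raise CnvError(
            f"reference clone mean is zero at amplicon {bad!r}; "
            "ploidy is undefined there"
        )
    cell_ploidy = 2.0 * n / mu

    clone_ids = np.unique(lab[lab > 0])
    clone_ploidy = np.vstack(
        [cell_ploidy[lab == g].mean(axis=0) for g in clone_ids]
    )
    return PloidyResult(
        cell_ploidy=AssayMatrix(
            values=cell_ploidy,
            cell_barcodes=normalized.cell_barcodes.copy(),
            feature_ids=normalized.feature_ids.copy(),
            units="ploidy",
        ),
        clone_ploidy=clone_ploidy,
        clone_ids=clone_ids,
        amplicon_ids=normalized.feature_ids.copy(),
        reference_clone=int(reference_clone),
    )
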