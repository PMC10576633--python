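"""Reading and writing the multi-assay HDF5 sample layout.

The on-disk schema follows the Tapestri pipeline v2 convention::

    assays/dna_variants/layers/{AF,NGT,GQ,DP}
    assays/dna_variants/ra/barcode          assays/dna_variants/ca/id
    assays/dna_read_counts/layers/read_counts     (+ ra/barcode, ca/id)
    assays/protein_read_counts/layers/read_counts (+ ra/barcode, ca/id)

Layers are 2-D with cells as rows; files written with cells as columns are
detected by comparing dataset shape against the annotation lengths and
transposed on read.  Group names can be overridden through a layout map for
dialect differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import h5py
import numpy as np

from .data_model import (
    AssayMatrix,
    DnaVariantAssay,
    DropReport,
    MultiomicSample,
    SampleError,
    build_sample,
)

logger = logging.getLogger(__name__)


class H5FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass
class H5Layout:
    """Path map from in-memory assays to HDF5 groups and datasets."""

    assays_group: str = "assays"
    dna_group: str = "dna_variants"
    cnv_group: str = "dna_read_counts"
    protein_group: str = "protein_read_counts"
    dna_layers: tuple = ("AF", "NGT", "GQ", "DP")
    count_layer: str = "read_counts"
    barcode_path: str = "ra/barcode"
    feature_path: str = "ca/id"

    def group_path(self, which: str) -> str:
        name = {"dna": self.dna_group, "cnv": self.cnv_group,
                "protein": self.protein_group}[which]
        return f"{self.assays_group}/{name}"

    def layer_paths(self, which: str) -> Dict[str, str]:
        base = self.group_path(which)
        layers = self.dna_layers if which == "dna" else (self.count_layer,)
        return {layer: f"{base}/layers/{layer}" for layer in layers}

    def annotation_paths(self, which: str) -> Dict[str, str]:
        base = self.group_path(which)
        return {
            "barcodes": f"{base}/{self.barcode_path}",
            "features": f"{base}/{self.feature_path}",
        }

    def required_paths(self) -> List[str]:
        paths: List[str] = []
        for which in ("dna", "cnv", "protein"):
            paths.extend(self.layer_paths(which).values())
            paths.extend(self.annotation_paths(which).values())
        return paths

    @classmethod
    def from_dict(cls, d: Dict) -> "H5Layout":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise H5FormatError(f"unknown layout keys: {sorted(unknown)}")
        d = dict(d)
        if "dna_layers" in d:
            d["dna_layers"] = tuple(d["dna_layers"])
        return cls(**d)


DEFAULT_LAYOUT = H5Layout()


def _decode_strings(ds: h5py.Dataset) -> np.ndarray:
    raw = ds[()]
    out = np.array(
        [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in raw],
        dtype=object,
    )
    return out


def _read_dataset(f: h5py.File, path: str) -> h5py.Dataset:
    if path not in f:
        raise H5FormatError(f"missing required dataset: /{path}")
    node = f[path]
    if not isinstance(node, h5py.Dataset):
        raise H5FormatError(f"/{path} is not a dataset")
    return node


def _read_layers(f: h5py.File, layout: H5Layout, which: str):
    """Return (layers dict, barcodes, feature ids) with cells as rows."""
    ann = layout.annotation_paths(which)
    barcodes = _decode_strings(_read_dataset(f, ann["barcodes"]))
    features = _decode_strings(_read_dataset(f, ann["features"]))
    layers = {}
    for layer, path in layout.layer_paths(which).items():
        mat = np.asarray(_read_dataset(f, path)[()])
        if mat.ndim != 2:
            raise H5FormatError(f"/{path} must be 2-D, got shape {mat.shape}")
        if mat.shape == (len(barcodes), len(features)):
            pass
        elif mat.shape == (len(features), len(barcodes)):
            logger.info("transposing /%s (stored features x cells)", path)
            mat = mat.T
        else:
            raise H5FormatError(
                f"/{path} shape {mat.shape} matches neither "
                f"(cells={len(barcodes)}, features={len(features)}) nor its transpose"
            )
        layers[layer] = mat
    return layers, barcodes, features


def read_h5(
    path, layout: H5Layout = DEFAULT_LAYOUT, name: str | None = None
) -> MultiomicSample:
    """Load a multi-assay HDF5 file into a :class:`MultiomicSample`.

    AF values outside [0, 100] are clamped (the number of clamped entries is
    logged); string datasets are decoded as UTF-8.  Assays with mismatched
    barcode sets are reconciled by :func:`~scmulti.data_model.build_sample`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        dna_layers, dna_bc, variant_ids = _read_layers(f, layout, "dna")
        cnv_layers, cnv_bc, amplicon_ids = _read_layers(f, layout, "cnv")
        prot_layers, prot_bc, protein_ids = _read_layers(f, layout, "protein")

    af = dna_layers["AF"].astype(float)
    n_clamped = int(np.sum((af < 0) | (af > 100)))
    if n_clamped:
        logger.warning("read_h5: clamped %d AF entries into [0, 100]", n_clamped)
        af = np.clip(af, 0.0, 100.0)

    dna = DnaVariantAssay(
        AF=af,
        NGT=dna_layers["NGT"].astype(int),
        GQ=dna_layers["GQ"],
        DP=dna_layers["DP"],
        cell_barcodes=dna_bc,
        variant_ids=variant_ids,
    )
    cnv = AssayMatrix(
        values=np.rint(cnv_layers["read_counts"]).astype(np.int64),
        cell_barcodes=cnv_bc,
        feature_ids=amplicon_ids,
        units="count",
    )
    protein = AssayMatrix(
        values=np.rint(prot_layers["read_counts"]).astype(np.int64),
        cell_barcodes=prot_bc,
        feature_ids=protein_ids,
        units="count",
    )
    sample, _report = build_sample(dna, cnv, protein, name=name or path.stem)
    return sample


def write_h5(sample: MultiomicSample, path, layout: H5Layout = DEFAULT_LAYOUT) -> Path:
    """Serialize *sample* to an HDF5 file conforming to the layout.

    Refuses to write degenerate samples (zero cells or zero features in any
    assay): such files could not be read back meaningfully.
    """
    if sample.n_cells == 0:
        raise SampleError("refusing to serialize a sample with 0 cells")
    for n, what in (
        (sample.dna.n_variants, "variants"),
        (sample.cnv.n_features, "CNV amplicons"),
        (sample.protein.n_features, "proteins"),
    ):
        if n == 0:
            raise SampleError(f"refusing to serialize a sample with 0 {what}")

    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")

    def write_assay(f, which, layers: Dict[str, np.ndarray], barcodes, features):
        for layer, data in layers.items():
            f.create_dataset(layout.layer_paths(which)[layer], data=data)
        ann = layout.annotation_paths(which)
        f.create_dataset(ann["barcodes"], data=np.asarray(barcodes, dtype=str_dt))
        f.create_dataset(ann["features"], data=np.asarray(features, dtype=str_dt))

    with h5py.File(path, "w") as f:
        write_assay(
            f, "dna",
            {"AF": sample.dna.AF, "NGT": sample.dna.NGT,
             "GQ": sample.dna.GQ, "DP": sample.dna.DP},
            sample.dna.cell_barcodes, sample.dna.variant_ids,
        )
        write_assay(
            f, "cnv", {layout.count_layer: sample.cnv.values},
            sample.cnv.cell_barcodes, sample.cnv.feature_ids,
        )
        write_assay(
            f, "protein", {layout.count_layer: sample.protein.values},
            sample.protein.cell_barcodes, sample.protein.feature_ids,
        )
    return path


def validate_layout(path, layout: H5Layout = DEFAULT_LAYOUT) -> List[str]:
    """Walk the layout path map over *path*; return a list of problems.

    An empty list means the file conforms: every required dataset exists,
    layers within a group share one shape, and annotation lengths match the
    layer dimensions.
    """
    problems: List[str] = []
    with h5py.File(path, "r") as f:
        for which in ("dna", "cnv", "protein"):
            shapes = set()
            for layer, p in layout.layer_paths(which).items():
                if p not in f:
                    problems.append(f"missing /{p}")
                else:
                    shapes.add(f[p].shape)
            if len(shapes) > 1:
                problems.append(f"{which}: layer shapes differ: {sorted(shapes)}")
            ann = layout.annotation_paths(which)
            lengths = {}
            for key, p in ann.items():
                if p not in f:
                    problems.append(f"missing /{p}")
                else:
                    lengths[key] = len(f[p])
            if len(shapes) == 1 and len(lengths) == 2:
                shape = next(iter(shapes))
                expected = (lengths["barcodes"], lengths["features"])
                if shape not in (expected, expected[::-1]):
                    problems.append(
                        f"{which}: layer shape {shape} inconsistent with "
                        f"annotations {expected}"
                    )
    return problems
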