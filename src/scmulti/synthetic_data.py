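"""Clone-structured synthetic multiomic samples with known ground truth.

Each configured clone carries a genotype vector (codes 0/1/2 per variant),
an integer copy-number vector per amplicon and a mean-expression vector per
protein.  The generator emits a :class:`~scmulti.data_model.MultiomicSample`
whose assays look like real targeted single-cell data:

* AF centered at 0/50/100 by genotype with Gaussian noise, clipped to
  [0, 100]; DP Poisson around a gamma-distributed per-cell depth; random
  dropout calls get NGT=3, GQ=0, DP=0.
* CNV counts Poisson with multiplicative lognormal per-cell and
  per-amplicon factors scaled by copy number -- exactly the row- and
  column-wise variation the CNV normalization is meant to remove.
* protein counts negative-binomial around clone means.

One master seed drives everything through per-assay child streams, so
adding draws to one assay never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .data_model import (
    AssayMatrix,
    CloneLabels,
    DnaVariantAssay,
    MultiomicSample,
    build_sample,
    renumber_by_size,
)
from .h5_io import write_h5

#: AF centers (percent) indexed by genotype code 0/1/2
GENOTYPE_AF_CENTERS = np.array([0.0, 50.0, 100.0])


@dataclass
class CloneSpec:
    """One clone: size, genotypes, copy numbers and protein means."""

    n_cells: int
    genotypes: Sequence[int]  # per variant, codes {0,1,2}
    copy_numbers: Sequence[int]  # per amplicon, non-negative integers
    protein_means: Sequence[float]  # per protein, mean raw counts

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        self.copy_numbers = np.asarray(self.copy_numbers, dtype=int)
        self.protein_means = np.asarray(self.protein_means, dtype=float)
        if self.n_cells < 1:
            raise ValueError("clone must have >= 1 cell")
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotype codes must be in {0,1,2}")
        if np.any(self.copy_numbers < 0):
            raise ValueError("copy numbers must be >= 0")
        if np.any(self.protein_means < 0):
            raise ValueError("protein means must be >= 0")


@dataclass
class SyntheticConfig:
    clones: List[CloneSpec]
    seed: int
    vaf_noise_sd: float = 2.0  # percent
    mean_depth: float = 80.0
    depth_dispersion: float = 10.0  # gamma shape of per-cell depth factors
    gq_valid: float = 99.0
    protein_dispersion: float = 5.0  # NB size; larger = closer to Poisson
    dropout_rate: float = 0.01
    cnv_cell_log_sd: float = 0.25
    cnv_amplicon_log_sd: float = 0.25
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("need >= 1 clone")
        nv = {len(c.genotypes) for c in self.clones}
        na = {len(c.copy_numbers) for c in self.clones}
        np_ = {len(c.protein_means) for c in self.clones}
        if len(nv) != 1 or len(na) != 1 or len(np_) != 1:
            raise ValueError("all clones must share vector lengths per assay")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.vaf_noise_sd < 0 or self.mean_depth <= 0:
            raise ValueError("vaf_noise_sd >= 0 and mean_depth > 0 required")

    @property
    def n_cells(self) -> int:
        return sum(c.n_cells for c in self.clones)

    @property
    def n_variants(self) -> int:
        return len(self.clones[0].genotypes)

    @property
    def n_amplicons(self) -> int:
        return len(self.clones[0].copy_numbers)

    @property
    def n_proteins(self) -> int:
        return len(self.clones[0].protein_means)

    @classmethod
    def from_dict(cls, d: Dict) -> "SyntheticConfig":
        d = dict(d)
        d["clones"] = [
            c if isinstance(c, CloneSpec) else CloneSpec(**c) for c in d["clones"]
        ]
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did, in emitted (renumbered) clone order."""

    true_labels: CloneLabels
    true_copy_number: np.ndarray  # (K, n_amplicons)
    true_protein_means: np.ndarray  # (K, n_proteins)
    clone_ids: np.ndarray  # (K,) = 1..K
    #: per clone, indices of proteins whose mean differs from the grand mean
    signature_proteins: Dict[int, List[int]] = field(default_factory=dict)


def default_config(seed: int = 0) -> SyntheticConfig:
    """A well-separated 3-clone sample usable as an end-to-end fixture.

    Clone copy-number profiles are total-preserving (gains balanced by
    losses), which keeps total-count normalization unbiased, and dropout is
    disabled so that clone recovery from VAF is exact.
    """
    n_variants, n_amplicons, n_proteins = 24, 12, 8
    g1 = np.zeros(n_variants, int)
    g2 = np.zeros(n_variants, int)
    g2[:8] = 1
    g3 = np.zeros(n_variants, int)
    g3[8:16] = 2
    cn_diploid = np.full(n_amplicons, 2, int)
    cn_gain = cn_diploid.copy()
    cn_gain[:4] = 3  # balanced: four +1 gains, four -1 losses
    cn_gain[4:8] = 1
    cn_loss = cn_diploid.copy()
    cn_loss[8:] = 3
    cn_loss[:4] = 1
    base = np.full(n_proteins, 60.0)
    hi = base.copy()
    hi[0] = 400.0
    lo = base.copy()
    lo[1] = 8.0
    return SyntheticConfig(
        clones=[
            CloneSpec(150, g1, cn_diploid, base),
            CloneSpec(100, g2, cn_gain, hi),
            CloneSpec(60, g3, cn_loss, lo),
        ],
        dropout_rate=0.0,
        seed=seed,
    )


def _clone_cell_index(config: SyntheticConfig) -> np.ndarray:
    """Raw clone index (0-based, config order) per generated cell."""
    return np.repeat(np.arange(len(config.clones)), [c.n_cells for c in config.clones])


def simulate_sample(config: SyntheticConfig) -> tuple[MultiomicSample, GroundTruth]:
    """Generate a sample plus its ground truth from *config* (deterministic)."""
    ss = np.random.SeedSequence(config.seed)
    rng_dna, rng_cnv, rng_prot = (np.random.default_rng(s) for s in ss.spawn(3))

    n_cells = config.n_cells
    n_variants, n_amplicons, n_proteins = (
        config.n_variants, config.n_amplicons, config.n_proteins,
    )
    clone_idx = _clone_cell_index(config)
    barcodes = np.array([f"cell_{i + 1:05d}" for i in range(n_cells)], dtype=object)

    # --- DNA -------------------------------------------------------------
    genotypes = np.vstack([c.genotypes for c in config.clones])[clone_idx]
    af = GENOTYPE_AF_CENTERS[genotypes] + rng_dna.normal(
        0.0, config.vaf_noise_sd, size=(n_cells, n_variants)
    )
    af = np.clip(af, 0.0, 100.0)
    depth_factor = rng_dna.gamma(
        shape=config.depth_dispersion, scale=1.0 / config.depth_dispersion,
        size=n_cells,
    )
    dp = rng_dna.poisson(config.mean_depth * depth_factor[:, None],
                         size=(n_cells, n_variants))
    gq = np.full((n_cells, n_variants), config.gq_valid, dtype=float)
    ngt = genotypes.copy()
    dropout = rng_dna.random((n_cells, n_variants)) < config.dropout_rate
    ngt[dropout] = 3
    gq[dropout] = 0.0
    dp[dropout] = 0
    af[dropout] = 0.0
    dna = DnaVariantAssay(
        AF=af, NGT=ngt, GQ=gq, DP=dp,
        cell_barcodes=barcodes.copy(),
        variant_ids=np.array(
            [f"chr1:{1000 + 10 * j}:A/T" for j in range(n_variants)], dtype=object
        ),
    )

    # --- CNV -------------------------------------------------------------
    cn = np.vstack([c.copy_numbers for c in config.clones])[clone_idx]
    cell_f = rng_cnv.lognormal(0.0, config.cnv_cell_log_sd, size=n_cells)
    amp_f = rng_cnv.lognormal(0.0, config.cnv_amplicon_log_sd, size=n_amplicons)
    lam = config.mean_depth * cell_f[:, None] * (cn / 2.0) * amp_f[None, :]
    cnv_counts = rng_cnv.poisson(lam)
    cnv = AssayMatrix(
        values=cnv_counts,
        cell_barcodes=barcodes.copy(),
        feature_ids=np.array([f"AMP{j + 1:03d}" for j in range(n_amplicons)],
                             dtype=object),
        units="count",
    )

    # --- protein ---------------------------------------------------------
    means = np.vstack([c.protein_means for c in config.clones])[clone_idx]
    size = config.protein_dispersion
    p = size / (size + np.maximum(means, 1e-12))
    prot_counts = np.where(means > 0, rng_prot.negative_binomial(size, p), 0)
    protein = AssayMatrix(
        values=prot_counts.astype(np.int64),
        cell_barcodes=barcodes.copy(),
        feature_ids=np.array([f"P{k + 1}" for k in range(n_proteins)], dtype=object),
        units="count",
    )

    sample, _ = build_sample(dna, cnv, protein, name=config.name)

    # barcodes are zero-padded, so build_sample's lexicographic order equals
    # generation order and clone_idx still lines up with sample rows
    raw_labels = clone_idx + 1
    labels = CloneLabels(renumber_by_size(raw_labels))
    # map raw clone index -> emitted label to reorder truth matrices
    emitted_for_raw = np.array(
        [labels.labels[clone_idx == g][0] for g in range(len(config.clones))]
    )
    order = np.argsort(emitted_for_raw)  # raw indices sorted by emitted label
    true_cn = np.vstack([config.clones[g].copy_numbers for g in order])
    true_pm = np.vstack([config.clones[g].protein_means for g in order])
    grand = true_pm.mean(axis=0)
    signature = {
        int(g + 1): np.flatnonzero(~np.isclose(true_pm[g], grand)).tolist()
        for g in range(true_pm.shape[0])
    }
    truth = GroundTruth(
        true_labels=labels,
        true_copy_number=true_cn,
        true_protein_means=true_pm,
        clone_ids=np.arange(1, len(config.clones) + 1),
        signature_proteins=signature,
    )
    return sample, truth


def write_fixture(config: SyntheticConfig, prefix) -> Dict[str, Path]:
    """Simulate and write ``<prefix>.h5`` plus ground-truth TSV sidecars."""
    import pandas as pd

    prefix = Path(prefix)
    sample, truth = simulate_sample(config)
    paths = {"h5": prefix.with_suffix(".h5")}
    write_h5(sample, paths["h5"])

    labels_path = prefix.parent / f"{prefix.name}.labels.tsv"
    pd.DataFrame(
        {"barcode": sample.cell_barcodes, "clone": truth.true_labels.labels}
    ).to_csv(labels_path, sep="\t", index=False)
    paths["labels"] = labels_path

    cnv_path = prefix.parent / f"{prefix.name}.cnv_truth.tsv"
    pd.DataFrame(
        truth.true_copy_number,
        index=pd.Index(truth.clone_ids, name="clone"),
        columns=sample.cnv.feature_ids,
    ).to_csv(cnv_path, sep="\t")
    paths["cnv_truth"] = cnv_path

    prot_path = prefix.parent / f"{prefix.name}.protein_truth.tsv"
    pd.DataFrame(
        truth.true_protein_means,
        index=pd.Index(truth.clone_ids, name="clone"),
        columns=sample.protein.feature_ids,
    ).to_csv(prot_path, sep="\t")
    paths["protein_truth"] = prot_path
    return paths
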