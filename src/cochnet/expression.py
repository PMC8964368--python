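"""Expression-matrix container, gene filtering, log transform, sample PCA.

The container tracks whether values are linear FPKM or log2(FPKM + 1); the
filter and the transform check the flag so they cannot silently be applied
twice or in the wrong order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import AlignmentError, ScaleError, ValidationError
from .simulate import SHARED, MODELS


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus the sample design table.

    ``scale`` is ``"linear"`` (FPKM) or ``"log2"`` (log2(FPKM + 1)).
    """

    values: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample_id, model, stage, replicate
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if not v.index.is_unique:
            dupes = v.index[v.index.duplicated()].tolist()[:3]
            raise ValidationError(f"duplicated gene ids: {dupes}")
        if not v.columns.is_unique:
            raise ValidationError("duplicated sample ids")
        meta_ids = list(self.samples["sample_id"])
        if sorted(meta_ids) != sorted(v.columns):
            raise AlignmentError(
                "expression columns and metadata sample_ids do not match"
            )
        if self.scale == "linear" and (v.values < 0).any():
            raise ValidationError("negative FPKM values")
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        ctrl = self.samples[self.samples["stage"] == "control"]
        if not (ctrl["model"] == SHARED).all():
            raise ValidationError("control rows must carry the shared model label")
        for m in MODELS:
            sub = self.samples[self.samples["model"] == m]
            if len(sub) and sub["stage"].eq("control").all():
                raise ValidationError(f"model {m} has only control samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples,
                                self.scale)


def read_expression(matrix_path: str | Path,
                    metadata_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (first column gene id) plus its sample metadata."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "model", "stage", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise AlignmentError(f"metadata is missing columns: {sorted(missing)}")
    # align column order to metadata order
    meta_ids = list(samples["sample_id"])
    if sorted(meta_ids) != sorted(values.columns):
        raise AlignmentError(
            "expression columns and metadata sample_ids do not match"
        )
    return ExpressionMatrix(values[meta_ids], samples, scale="linear")


def filter_genes(m: ExpressionMatrix, fpkm_threshold: float = 0.5,
                 min_fraction: float = 0.5) -> ExpressionMatrix:
    """Discard genes expressed above ``fpkm_threshold`` in less than
    ``min_fraction`` of samples.

    A gene is retained iff FPKM > threshold (strict) in at least
    ceil(min_fraction * n_samples) samples; with 27 samples and the 0.5
    defaults, 14 qualifying samples retain a gene and 13 discard it.
    Gene order is preserved; the operation is idempotent.
    """
    if m.scale != "linear":
        raise ScaleError("gene filter must run on linear-scale FPKM values")
    need = math.ceil(min_fraction * m.n_samples)
    counts = (m.values > fpkm_threshold).sum(axis=1)
    keep = counts[counts >= need].index
    return ExpressionMatrix(m.values.loc[keep], m.samples, "linear")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1); inverse is 2**x - 1."""
    if m.scale != "linear":
        raise ScaleError("matrix is already log-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.samples, "log2")


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x PCs
    variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        vr = self.variance_ratio
        if np.any(vr < -1e-12) or np.any(vr > 1 + 1e-12):
            raise ValidationError("variance fractions outside [0, 1]")
        if np.any(np.diff(vr) > 1e-12):
            raise ValidationError("variance fractions must be non-increasing")


def pca_samples(m: ExpressionMatrix, n_components: int = 2) -> PcaResult:
    """PCA with samples as observations and centered genes as features."""
    if m.scale != "log2":
        raise ScaleError("sample PCA expects the log2 matrix")
    x = m.values.to_numpy().T  # samples x genes
    if n_components > min(x.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        pd.DataFrame(coords, index=m.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
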