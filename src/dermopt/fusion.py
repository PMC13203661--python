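"""Serial (column-wise) fusion of per-extractor feature matrices.

Feature blocks from different extractors are concatenated along the feature
axis (``R^p ⊕ R^q → R^{p+q}``) with per-column provenance tags so a fused
matrix can be split back into its original blocks.  No normalization is
applied at fusion time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "reduction_percentage",
    "serial_concat",
    "split_by_provenance",
]


@dataclass
class FeatureMatrix:
    """A samples × features matrix with column provenance and optional labels."""

    values: np.ndarray
    provenance: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if not self.provenance:
            self.provenance = ["F"] * self.values.shape[1]
        if len(self.provenance) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.provenance)} provenance tags for "
                f"{self.values.shape[1]} columns"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("label vector length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        """Write as CSV: ``label`` column first (if present), then features
        named ``<provenance>_<index>``."""
        counts: dict[str, int] = {}
        names = []
        for tag in self.provenance:
            counts[tag] = counts.get(tag, 0) + 1
            names.append(f"{tag}_{counts[tag]:04d}")
        df = pd.DataFrame(self.values, columns=names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        provenance = [c.rsplit("_", 1)[0] for c in df.columns]
        return cls(values=df.to_numpy(float), provenance=provenance, labels=labels)


def serial_concat(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature blocks column-wise, preserving block order.

    All blocks must share the row count; labels are taken from the first
    block that carries them.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    n = blocks[0].n_samples
    for k, blk in enumerate(blocks):
        if blk.n_samples != n:
            raise ValueError(
                f"block {k} has {blk.n_samples} rows, expected {n}"
            )
    labels = next((b.labels for b in blocks if b.labels is not None), None)
    return FeatureMatrix(
        values=np.concatenate([b.values for b in blocks], axis=1),
        provenance=[tag for b in blocks for tag in b.provenance],
        labels=labels,
    )


def split_by_provenance(fused: FeatureMatrix) -> dict[str, FeatureMatrix]:
    """Recover the original blocks of a fused matrix from its tags."""
    order: list[str] = []
    for tag in fused.provenance:
        if tag not in order:
            order.append(tag)
    tags = np.asarray(fused.provenance)
    return {
        tag: FeatureMatrix(
            values=fused.values[:, tags == tag],
            provenance=[tag] * int((tags == tag).sum()),
            labels=fused.labels,
        )
        for tag in order
    }


def reduction_percentage(input_width: int, output_width: int) -> int:
    """Percent of columns removed, rounded to the nearest integer."""
    if not 0 < output_width <= input_width:
        raise ValueError(
            f"output width {output_width} must lie in (0, {input_width}]"
        )
    return int(round(100.0 * (input_width - output_width) / input_width))
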