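"""Symmetric pairwise-distance container used throughout the pipeline.

Stores the condensed upper triangle (scipy ``pdist`` ordering) together with
the site labels, so matrices from different stages can be checked for site
agreement before being correlated or partitioned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .errors import ValidationError


@dataclass
class DistMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    ids: list
    condensed: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.condensed = np.asarray(self.condensed, dtype=float)
        n = len(self.ids)
        if self.condensed.shape != (n * (n - 1) // 2,):
            raise ValidationError(
                f"condensed length {self.condensed.shape} inconsistent with {n} sites"
            )
        finite = self.condensed[np.isfinite(self.condensed)]
        if finite.size and finite.min() < 0:
            raise ValidationError("distances must be non-negative")

    @classmethod
    def from_square(cls, ids: Sequence, square: np.ndarray, metric: str = "") -> "DistMatrix":
        square = np.asarray(square, dtype=float)
        if square.shape[0] != square.shape[1]:
            raise ValidationError("matrix is not square")
        if not np.allclose(square, square.T, equal_nan=True):
            raise ValidationError("matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(square))) > 1e-12 if square.size else False:
            raise ValidationError("diagonal is not zero")
        return cls(ids, squareform(square, checks=False), metric)

    @property
    def n(self) -> int:
        return len(self.ids)

    def square(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)

    def same_sites(self, other: "DistMatrix") -> bool:
        return self.ids == other.ids
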