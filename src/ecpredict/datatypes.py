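"""Core in-memory containers: parcel time series and effective-connectivity matrices.

Conventions
-----------
* A :class:`ParcelTimeSeries` stores one subject's signals as a
  ``n_regions x n_volumes`` array together with the sampling interval (TR).
* An :class:`ECMatrix` stores directed connection weights in units of 1/s
  with the *row = target, column = source* orientation: ``weights[i, j]`` is
  the influence of region ``j`` on region ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["ParcelTimeSeries", "ECMatrix"]


def _default_region_ids(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


@dataclass
class ParcelTimeSeries:
    """Region-by-time signal table for one subject.

    Parameters
    ----------
    data
        Array of shape ``(n_regions, n_volumes)``.
    tr
        Sampling interval in seconds (repetition time).
    region_ids
        Optional region labels; auto-generated when omitted.
    """

    data: np.ndarray
    tr: float
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SchemaError("time-series data must be 2-D (regions x volumes)")
        if self.tr <= 0:
            raise SchemaError("tr must be positive")
        if self.region_ids is None:
            self.region_ids = _default_region_ids(self.data.shape[0])
        elif len(self.region_ids) != self.data.shape[0]:
            raise SchemaError("region_ids length does not match number of rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path) -> None:
        """Write as tab-delimited text, one row per parcel."""
        np.savetxt(path, self.data, delimiter="\t")

    @classmethod
    def from_csv(cls, path, tr: float) -> "ParcelTimeSeries":
        data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        return cls(data=data, tr=tr)


@dataclass
class ECMatrix:
    """Directed effective-connectivity matrix (row = target, column = source)."""

    weights: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise SchemaError("EC matrix must be square")
        if not np.all(np.isfinite(self.weights)):
            raise SchemaError("EC matrix contains non-finite entries")
        if self.region_ids is None:
            self.region_ids = _default_region_ids(self.weights.shape[0])
        elif len(self.region_ids) != self.weights.shape[0]:
            raise SchemaError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def spectral_abscissa(self) -> float:
        """Largest real part among the eigenvalues of the weight matrix."""
        return float(np.max(np.linalg.eigvals(self.weights).real))

    def to_csv(self, path) -> None:
        """Write as delimited numeric matrix with a header row of region ids."""
        pd.DataFrame(self.weights, columns=self.region_ids).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ECMatrix":
        df = pd.read_csv(path)
        return cls(weights=df.to_numpy(dtype=float), region_ids=list(df.columns))


def as_weights(ec) -> np.ndarray:
    """Accept either an :class:`ECMatrix` or a plain array of weights."""
    if isinstance(ec, ECMatrix):
        return ec.weights
    return np.asarray(ec, dtype=float)
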