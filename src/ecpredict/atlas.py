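"""Parcel-to-network atlas handling and EC feature extraction.

The seven canonical resting-state networks (visual, somatomotor, dorsal
attention, ventral attention, limbic, frontoparietal, default mode) partition
the cortical parcels.  An EC matrix is converted into prediction features
either whole-brain (every directed entry) or within-network (entries whose
target and source parcels share a network label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import as_weights
from .errors import ConfigError, SchemaError

__all__ = [
    "NETWORK_LABELS",
    "NetworkAtlas",
    "FeatureVector",
    "load_atlas",
    "extract_within_network",
    "vectorize_wholebrain",
    "build_feature_matrix",
    "reconstruct",
]

#: Canonical label order for the seven resting-state networks.
NETWORK_LABELS: tuple[str, ...] = ("Vis", "SMN", "DAN", "VAN", "Lim", "FPN", "DMN")


@dataclass(frozen=True)
class NetworkAtlas:
    """Assignment of each parcel (by index) to one network label.

    ``labels[i]`` is the network of parcel ``i``.  Small toy atlases with
    fewer than seven networks are permitted for unit-level work; atlases read
    from disk through :func:`load_atlas` are validated against the canonical
    seven labels.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise SchemaError("atlas must label at least one parcel")

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, canonical labels first in canonical order."""
        present = set(self.labels)
        ordered = [lab for lab in NETWORK_LABELS if lab in present]
        extra = [lab for lab in dict.fromkeys(self.labels) if lab not in NETWORK_LABELS]
        return tuple(ordered + extra)

    def parcels_in(self, network: str) -> np.ndarray:
        """Sorted parcel indices belonging to ``network``."""
        idx = np.flatnonzero(np.asarray(self.labels, dtype=object) == network)
        return idx

    def block_sizes(self) -> dict[str, int]:
        return {net: int(self.parcels_in(net).size) for net in self.networks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parcel_id": np.arange(self.n_parcels), "network_label": list(self.labels)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_atlas(path) -> NetworkAtlas:
    """Read a parcel->network lookup table (CSV: parcel_id, network_label).

    Parcel ids must form the contiguous range ``0 .. n-1`` with no duplicates,
    every label must be one of the seven canonical networks, and all seven
    networks must be represented.
    """
    df = pd.read_csv(path)
    required = {"parcel_id", "network_label"}
    if not required.issubset(df.columns):
        raise SchemaError(f"atlas table needs columns {sorted(required)}")
    for row_i, lab in enumerate(df["network_label"]):
        if lab not in NETWORK_LABELS:
            raise SchemaError(f"row {row_i}: unknown network label {lab!r}")
    ids = df["parcel_id"].to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise SchemaError(f"row {int(np.flatnonzero(dup)[0])}: duplicate parcel id")
    n = len(df)
    missing = set(range(n)) - set(int(i) for i in ids)
    if missing:
        raise SchemaError(f"missing parcel ids: {sorted(missing)[:5]}")
    labels = df.sort_values("parcel_id")["network_label"].tolist()
    absent = set(NETWORK_LABELS) - set(labels)
    if absent:
        raise SchemaError(f"networks absent from atlas: {sorted(absent)}")
    return NetworkAtlas(labels=tuple(labels))


@dataclass
class FeatureVector:
    """Ordered EC entries with their (target, source) provenance.

    ``index_map[k] = (i, j)`` means ``values[k]`` came from ``ec[i, j]``.
    ``family`` is ``"WB"`` for whole-brain features or a network label.
    """

    values: np.ndarray
    index_map: np.ndarray  # shape (n_features, 2), columns (target, source)
    family: str = "WB"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.index_map = np.asarray(self.index_map, dtype=int)
        if self.index_map.shape != (self.values.size, 2):
            raise SchemaError("index_map shape must be (n_features, 2)")

    def __len__(self) -> int:
        return self.values.size


def _pairs_for_block(idx: np.ndarray, include_diagonal: bool) -> np.ndarray:
    tgt, src = np.meshgrid(idx, idx, indexing="ij")
    pairs = np.column_stack([tgt.ravel(), src.ravel()])
    if not include_diagonal:
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    return pairs


def extract_within_network(
    ec, atlas: NetworkAtlas, network: str, include_diagonal: bool = True
) -> FeatureVector:
    """Features from entries whose target and source share ``network``.

    With ``m`` parcels in the network the vector has ``m**2`` entries
    (``m**2 - m`` when the self-connection diagonal is excluded), in fixed
    row-major (target-major) order.
    """
    w = as_weights(ec)
    idx = atlas.parcels_in(network)
    if idx.size == 0:
        raise ConfigError(f"network {network!r} has no parcels in this atlas")
    if idx.max() >= w.shape[0]:
        raise SchemaError("atlas indexes parcels beyond the EC matrix size")
    pairs = _pairs_for_block(idx, include_diagonal)
    values = w[pairs[:, 0], pairs[:, 1]]
    return FeatureVector(values=values, index_map=pairs, family=network)


def vectorize_wholebrain(ec, include_diagonal: bool = True) -> FeatureVector:
    """All directed entries of the EC matrix in row-major order."""
    w = as_weights(ec)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise SchemaError("EC matrix must be square")
    pairs = _pairs_for_block(np.arange(w.shape[0]), include_diagonal)
    return FeatureVector(values=w[pairs[:, 0], pairs[:, 1]], index_map=pairs, family="WB")


def features_for_family(
    ec, atlas: NetworkAtlas, family: str, include_diagonal: bool = True
) -> FeatureVector:
    """Dispatch: ``"WB"`` -> whole-brain, otherwise within-network."""
    if family == "WB":
        return vectorize_wholebrain(ec, include_diagonal=include_diagonal)
    return extract_within_network(ec, atlas, family, include_diagonal=include_diagonal)


def build_feature_matrix(
    ecs, atlas: NetworkAtlas, family: str, include_diagonal: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one family's feature vector across subjects.

    Returns ``(X, index_map)`` where ``X`` is ``n_subjects x n_features``.
    """
    rows = []
    index_map = None
    for ec in ecs:
        fv = features_for_family(ec, atlas, family, include_diagonal=include_diagonal)
        rows.append(fv.values)
        index_map = fv.index_map
    return np.vstack(rows), index_map


def reconstruct(fv: FeatureVector, n_regions: int, fill: float = np.nan) -> np.ndarray:
    """Place feature values back into an ``n_regions x n_regions`` matrix."""
    out = np.full((n_regions, n_regions), fill, dtype=float)
    out[fv.index_map[:, 0], fv.index_map[:, 1]] = fv.values
    return out
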