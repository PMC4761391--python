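"""PRIM / frequency-matrix representations and the fixed-layout feature vector.

Each protein sequence yields an 80-dimensional descriptor under defaults:

* 10 raw + 10 central + 10 Hahn moments (orders x + y <= 3) of the square
  row-major embedding of the encoded sequence;
* the same 30 moments of the position-relative incidence matrix (PRIM), a
  k x 20 matrix with entry ``i + 1`` in the column of the residue observed at
  position ``i`` and 0 elsewhere;
* the 20-element amino acid frequency vector (FM).

The layout is fingerprinted so that a trained model refuses vectors extracted
under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .moments import (
    HahnBasis,
    MomentSet,
    OrderScheme,
    build_hahn_basis,
    central_moments,
    hahn_moments,
    moment_orders,
    raw_moments,
)
from .sequence_io import (
    AMINO_ACIDS,
    EncodingMap,
    ProteinSequence,
    embed_square,
    encode_sequence,
    reshape_to_matrix,
)


class FeatureError(ValueError):
    """Feature extraction failed or produced invalid values."""


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings; the fingerprint guards model/feature compatibility."""

    order_max: int = 3
    scheme: OrderScheme = "triangle"
    mu: float = 0.0
    nu: float = 0.0
    encoding: str = "alphabetical"

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "order_max": self.order_max,
                "scheme": self.scheme,
                "mu": self.mu,
                "nu": self.nu,
                "encoding": self.encoding,
                "blocks": _BLOCKS,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def n_moments(self) -> int:
        return len(moment_orders(self.order_max, self.scheme))

    @property
    def n_features(self) -> int:
        return 6 * self.n_moments + 20


_BLOCKS = ("seq_raw", "seq_central", "seq_hahn", "prim_raw", "prim_central", "prim_hahn", "fm")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-layout feature values with provenance metadata."""

    values: np.ndarray
    layout: tuple[tuple[str, int, int], ...]  # (block, start, stop)
    fingerprint: str

    def block(self, name: str) -> np.ndarray:
        for blk, start, stop in self.layout:
            if blk == name:
                return self.values[start:stop]
        raise KeyError(name)


def compute_prim(seq: ProteinSequence) -> np.ndarray:
    """Position-relative incidence matrix: PRIM[i, j] = i + 1 at the residue's
    own alphabetical column, 0 elsewhere.  Non-canonical residues (retained by
    the ``map_x_to_zero`` policy) leave their row all zero."""
    if seq.k == 0:
        raise FeatureError(f"sequence {seq.id!r} is empty")
    prim = np.zeros((seq.k, 20))
    for i, aa in enumerate(seq.residues):
        j = AMINO_ACIDS.find(aa)
        if j >= 0:
            prim[i, j] = i + 1
    return prim


def compute_fm(seq: ProteinSequence) -> np.ndarray:
    """20-element residue occurrence counts, alphabetical order."""
    if seq.k == 0:
        raise FeatureError(f"sequence {seq.id!r} is empty")
    counts = np.zeros(20, dtype=np.int64)
    for aa in seq.residues:
        j = AMINO_ACIDS.find(aa)
        if j >= 0:
            counts[j] += 1
    return counts


@lru_cache(maxsize=512)
def _cached_basis(N: int, order_max: int, mu: float, nu: float) -> HahnBasis:
    # tiny grids (N <= order_max) clamp the basis order; missing entries are
    # reported as 0 by hahn_moments so the feature layout stays fixed
    return build_hahn_basis(N, min(order_max, N - 1), mu, nu)


def prim_moments(
    prim: np.ndarray,
    order_max: int = 3,
    scheme: OrderScheme = "triangle",
    mu: float = 0.0,
    nu: float = 0.0,
) -> tuple[MomentSet, MomentSet, MomentSet]:
    """Raw, central, and Hahn moment sets of a PRIM grid.

    Raw and central moments run on the k x 20 rectangle directly.  The Hahn
    transform needs a square support, so the PRIM is flattened row-major and
    re-embedded as a square matrix first (the same embedding used for the
    sequence itself).
    """
    prim = np.asarray(prim, dtype=float)
    if prim.size == 0:
        raise FeatureError("empty PRIM")
    raw = raw_moments(prim, order_max, scheme)
    central = central_moments(prim, order_max, scheme)
    square = embed_square(prim.ravel())
    basis = _cached_basis(square.shape[0], order_max, mu, nu)
    hahn = hahn_moments(square, basis, order_max, scheme)
    return raw, central, hahn


def extract_features(
    seq: ProteinSequence,
    config: FeatureConfig = FeatureConfig(),
    encoding: EncodingMap | None = None,
) -> FeatureVector:
    """Assemble the full feature vector of one validated sequence.

    Blocks in order: seq_raw, seq_central, seq_hahn, prim_raw, prim_central,
    prim_hahn, fm.  Raises :class:`FeatureError` naming the block if any
    value is non-finite.
    """
    if seq.k < 1:
        raise FeatureError(f"sequence {seq.id!r} is empty")
    encoding = encoding or EncodingMap.alphabetical()
    codes = encode_sequence(seq, encoding, unknown="zero")
    sm = reshape_to_matrix(codes)
    basis = _cached_basis(sm.n, config.order_max, config.mu, config.nu)

    blocks: list[tuple[str, np.ndarray]] = []
    blocks.append(("seq_raw", raw_moments(sm, config.order_max, config.scheme).values))
    blocks.append(("seq_central", central_moments(sm, config.order_max, config.scheme).values))
    blocks.append(
        ("seq_hahn", hahn_moments(sm.values, basis, config.order_max, config.scheme).values)
    )

    prim = compute_prim(seq)
    p_raw, p_central, p_hahn = prim_moments(
        prim, config.order_max, config.scheme, config.mu, config.nu
    )
    blocks.append(("prim_raw", p_raw.values))
    blocks.append(("prim_central", p_central.values))
    blocks.append(("prim_hahn", p_hahn.values))
    blocks.append(("fm", compute_fm(seq).astype(float)))

    layout = []
    pos = 0
    for name, vals in blocks:
        if not np.all(np.isfinite(vals)):
            raise FeatureError(f"non-finite values in feature block {name!r} for {seq.id!r}")
        layout.append((name, pos, pos + len(vals)))
        pos += len(vals)
    values = np.concatenate([vals for _, vals in blocks])
    return FeatureVector(values=values, layout=tuple(layout), fingerprint=config.fingerprint())


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Column names matching the vector layout (block + moment orders / residue)."""
    orders = moment_orders(config.order_max, config.scheme)
    names: list[str] = []
    for block in _BLOCKS[:-1]:
        names.extend(f"{block}_{x}{y}" for x, y in orders)
    names.extend(f"fm_{aa}" for aa in AMINO_ACIDS)
    return names


# --- scaling ----------------------------------------------------------------


@dataclass(frozen=True)
class Scaler:
    """Per-feature standardisation statistics fit on training vectors only."""

    mean: np.ndarray
    scale: np.ndarray  # 1.0 for zero-variance features (pass-through)
    fingerprint: str = ""


def fit_scaler(vectors: Sequence[FeatureVector] | np.ndarray) -> Scaler:
    """Fit mean/sd standardisation; zero-variance features pass through."""
    X, fingerprint = _stack(vectors)
    if X.shape[0] == 0:
        raise FeatureError("cannot fit a scaler on an empty list")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # near-zero variance (up to float cancellation noise) counts as constant
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    scale = np.where(zero, 1.0, sd)
    mean = np.where(zero, 0.0, mean)
    return Scaler(mean=mean, scale=scale, fingerprint=fingerprint)


def apply_scaler(scaler: Scaler, vector: FeatureVector | np.ndarray):
    """Standardise a vector (or matrix of rows) with frozen training statistics."""
    if isinstance(vector, FeatureVector):
        if scaler.fingerprint and vector.fingerprint != scaler.fingerprint:
            raise FeatureError(
                "feature-layout fingerprint mismatch between scaler and vector"
            )
        scaled = (vector.values - scaler.mean) / scaler.scale
        return FeatureVector(values=scaled, layout=vector.layout, fingerprint=vector.fingerprint)
    X = np.asarray(vector, dtype=float)
    return (X - scaler.mean) / scaler.scale


def _stack(vectors) -> tuple[np.ndarray, str]:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(np.asarray(vectors, dtype=float)), ""
    vecs = list(vectors)
    if not vecs:
        return np.empty((0, 0)), ""
    if isinstance(vecs[0], FeatureVector):
        fps = {v.fingerprint for v in vecs}
        if len(fps) > 1:
            raise FeatureError("mixed feature-layout fingerprints")
        return np.vstack([v.values for v in vecs]), vecs[0].fingerprint
    return np.atleast_2d(np.asarray(vecs, dtype=float)), ""


# --- feature tables ---------------------------------------------------------


def extract_feature_table(
    labeled: Iterable[tuple[ProteinSequence, str]],
    config: FeatureConfig = FeatureConfig(),
    encoding: EncodingMap | None = None,
) -> pd.DataFrame:
    """Feature table with columns id, label, then one column per feature."""
    rows = []
    names = feature_names(config)
    for seq, label in labeled:
        fv = extract_features(seq, config, encoding)
        rows.append([seq.id, label, *fv.values])
    return pd.DataFrame(rows, columns=["id", "label", *names])


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
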