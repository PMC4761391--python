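"""Labeled synthetic protein sequences with class-dependent composition.

The generator emulates the compositional contrast between membrane and
soluble proteins: transmembrane segments are enriched in hydrophobic residues
(A, F, I, L, M, V, W), so the membrane profile up-weights those letters while
the nonmembrane profile is near-uniform.  Residues are drawn i.i.d. from the
class profile and lengths uniformly from the profile's range (minimum 50,
mirroring the usual short-fragment exclusion), which gives a compositional —
not positional — class signal: the simplest structure the frequency-vector
and moment features can provably detect.

The module also ships deterministic numeric fixture matrices whose raw and
central moments are computed by a literal brute-force double loop, serving as
an independent oracle for the vectorised implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import AMINO_ACIDS, ProteinSequence

HYDROPHOBIC = "AFILMVW"


class ProfileError(ValueError):
    """Invalid class profile."""


@dataclass(frozen=True)
class ClassProfile:
    """Residue sampling weights and length range for one class."""

    label: str
    residue_weights: tuple[float, ...]  # 20 positive reals summing to 1
    length_range: tuple[int, int] = (50, 400)

    def __post_init__(self) -> None:
        w = np.asarray(self.residue_weights, dtype=float)
        if w.size != 20 or np.any(w <= 0):
            raise ProfileError("residue_weights must be 20 positive reals")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ProfileError("residue_weights must sum to 1")
        lo, hi = self.length_range
        if not (50 <= lo <= hi):
            raise ProfileError("length_range must satisfy 50 <= min <= max")


def default_profiles() -> tuple[ClassProfile, ClassProfile]:
    """Default membrane (hydrophobicity-skewed) and nonmembrane (uniform)
    profiles, total-variation distance >= 0.15 apart."""
    membrane = np.full(20, 0.44 / 13)
    for aa in HYDROPHOBIC:
        membrane[AMINO_ACIDS.index(aa)] = 0.56 / 7
    membrane /= membrane.sum()
    nonmembrane = np.full(20, 0.05)
    return (
        ClassProfile(label="membrane", residue_weights=tuple(membrane)),
        ClassProfile(label="nonmembrane", residue_weights=tuple(nonmembrane)),
    )


def total_variation(p: Sequence[float], q: Sequence[float]) -> float:
    """TV distance 0.5 * sum |p_i - q_i| between two weight vectors."""
    return 0.5 * float(np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


def generate_dataset(
    n_per_class: int,
    profiles: tuple[ClassProfile, ClassProfile] | None = None,
    seed: int = 7,
) -> list[tuple[ProteinSequence, str]]:
    """Draw ``n_per_class`` sequences per profile, fully seeded.

    Lengths are uniform on each profile's range; residues i.i.d. from its
    weights.  Record ids follow ``synth_<label>_<index>`` and the description
    carries the label and seed.
    """
    if n_per_class < 1:
        raise ProfileError("n_per_class must be >= 1")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    dataset: list[tuple[ProteinSequence, str]] = []
    for profile in profiles:
        weights = np.asarray(profile.residue_weights)
        lo, hi = profile.length_range
        for i in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(alphabet, size=length, p=weights))
            rid = f"synth_{profile.label}_{i}"
            desc = f"{rid} label={profile.label} seed={seed}"
            dataset.append(
                (ProteinSequence(id=rid, residues=residues, description=desc), profile.label)
            )
    return dataset


def write_fasta(path: str | Path, dataset: Sequence[tuple[ProteinSequence, str]]) -> None:
    """FASTA with the label encoded in the header description."""
    with open(path, "w") as fh:
        for seq, label in dataset:
            desc = seq.description or f"{seq.id} label={label}"
            fh.write(f">{desc}\n")
            for start in range(0, seq.k, 70):
                fh.write(seq.residues[start : start + 70] + "\n")


def write_labels_tsv(path: str | Path, dataset: Sequence[tuple[ProteinSequence, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for seq, label in dataset:
            fh.write(f"{seq.id}\t{label}\n")


def label_from_description(description: str) -> str | None:
    """Recover ``label=<x>`` from a FASTA description, if present."""
    for token in description.split():
        if token.startswith("label="):
            return token.split("=", 1)[1]
    return None


# --- moment oracles and fixtures -------------------------------------------


def brute_force_raw_moment(M: np.ndarray, x: int, y: int) -> float:
    """Literal double-loop raw moment sum_i sum_j i^x j^y M[i, j] (oracle)."""
    M = np.asarray(M, dtype=float)
    total = 0.0
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            total += (i**x) * (j**y) * M[i, j]
    return total


def brute_force_central_moment(M: np.ndarray, x: int, y: int) -> float:
    """Literal double-loop central moment about the brute-force centroid."""
    M = np.asarray(M, dtype=float)
    m00 = brute_force_raw_moment(M, 0, 0)
    p_bar = brute_force_raw_moment(M, 1, 0) / m00
    q_bar = brute_force_raw_moment(M, 0, 1) / m00
    total = 0.0
    for p in range(M.shape[0]):
        for q in range(M.shape[1]):
            total += ((p - p_bar) ** x) * ((q - q_bar) ** y) * M[p, q]
    return total


def fixture_matrices(seed: int = 0, n_random: int = 6) -> list[dict]:
    """Deterministic small matrices with oracle-computed expected moments.

    Each fixture dict carries the matrix plus expected raw moments (orders
    x + y <= 3) and, when the mass is positive, the centroid — all from the
    brute-force oracle.
    """
    rng = np.random.default_rng(seed)
    mats: list[tuple[str, np.ndarray]] = [
        ("ones_2x2", np.ones((2, 2))),
        ("point_mass_2_3", _point_mass(4, 2, 3)),
        ("identity_3x3", np.eye(3)),
    ]
    for i in range(n_random):
        n = int(rng.integers(2, 13))
        mats.append((f"random_{i}_{n}x{n}", rng.integers(0, 21, size=(n, n)).astype(float)))
    fixtures = []
    for name, M in mats:
        expected_raw = {
            (x, y): brute_force_raw_moment(M, x, y)
            for x in range(4)
            for y in range(4 - x)
        }
        fx = {"name": name, "matrix": M, "expected_raw": expected_raw}
        if expected_raw[(0, 0)] > 0:
            fx["expected_centroid"] = (
                expected_raw[(1, 0)] / expected_raw[(0, 0)],
                expected_raw[(0, 1)] / expected_raw[(0, 0)],
            )
            fx["expected_central"] = {
                (x, y): brute_force_central_moment(M, x, y)
                for x in range(4)
                for y in range(4 - x)
            }
        fixtures.append(fx)
    return fixtures


def _point_mass(n: int, i: int, j: int) -> np.ndarray:
    M = np.zeros((n, n))
    M[i, j] = 1.0
    return M
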