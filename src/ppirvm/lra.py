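"""Low-rank PSSM descriptors and pair feature vectors.

A protein's PSSM has as many rows as the sequence has residues, so PSSMs of
different proteins cannot be compared directly.  Viewing the profile as a
20 x L matrix N (amino acids x positions) and truncating its singular value
decomposition at rank r gives the best Frobenius-norm rank-r approximation
N* = U1 S1 V1^T (Eckart-Young).  The 20 x r matrix U1 S1^(1/2) depends only
on the amino-acid side of the factorization and therefore has a fixed size
for every sequence length; flattened row-wise it is a 20*r descriptor vector
per protein.  A protein pair is represented by concatenating the two
descriptors (40*r values).  The default rank is r = 5, giving 100 values per
protein and 200 per pair.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

from .pssm import PSSM

__all__ = [
    "LRAResult",
    "Descriptor",
    "PairFeature",
    "low_rank_approx",
    "pssm_descriptor",
    "pair_feature",
    "write_feature_table",
    "read_feature_table",
    "pair_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_RANK = 5


@dataclass(frozen=True)
class LRAResult:
    """Truncated-SVD factorization of a score matrix.

    ``approximation`` is the best rank-<=r approximation U1 S1 V1^T under the
    Frobenius norm; ``residual_frobenius`` equals
    sqrt(sigma_{r+1}^2 + ... + sigma_m^2) for the discarded singular values.
    """

    rank: int
    approximation: np.ndarray
    left_factors: np.ndarray       # m x r, orthonormal columns (sign-fixed)
    singular_values: np.ndarray    # r, descending, >= 0
    right_factors: np.ndarray      # n x r, orthonormal columns
    residual_frobenius: float


@dataclass(frozen=True)
class Descriptor:
    """Fixed-length per-protein feature vector, flattened U1 S1^(1/2)."""

    protein_id: str
    rank: int
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (20 * self.rank,):
            raise ValueError(
                f"descriptor for {self.protein_id!r} must have length "
                f"{20 * self.rank}, got {values.shape}"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PairFeature:
    """Concatenated descriptors of a protein pair plus an optional label."""

    id_a: str
    id_b: str
    values: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size % 2 != 0:
            raise ValueError("pair feature vector must be 1-D with even length")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        object.__setattr__(self, "values", values)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign ambiguity deterministically.

    Each column of U is flipped (together with the matching row of Vt) so
    that its largest-magnitude entry is positive; ties break at the earliest
    index (argmax over |.|).  This makes descriptors reproducible across
    linear-algebra backends.
    """
    U = U.copy()
    Vt = Vt.copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, Vt


def low_rank_approx(N: np.ndarray, r: int) -> LRAResult:
    """Best rank-<=r Frobenius-norm approximation of ``N`` via truncated SVD.

    Parameters
    ----------
    N : (m, n) array
        Score matrix, typically a transposed PSSM (20 x L).
    r : int
        Target rank, 1 <= r <= min(m, n).
    """
    N = np.asarray(N, dtype=float)
    if N.ndim != 2:
        raise ValueError(f"N must be a matrix, got ndim={N.ndim}")
    if not np.all(np.isfinite(N)):
        raise ValueError("N contains non-finite entries")
    m, n = N.shape
    if not (1 <= r <= min(m, n)):
        raise ValueError(f"rank r={r} must satisfy 1 <= r <= min{(m, n)}")

    U, s, Vt = np.linalg.svd(N, full_matrices=False)
    if r < s.size and s[r - 1] > 0 and np.isclose(s[r - 1], s[r], rtol=1e-12, atol=0.0):
        # Repeated singular value across the cut: the optimum is non-unique
        # and the backend's subspace choice is kept.
        logger.warning(
            "sigma_r == sigma_{r+1} (%.6g): rank-%d approximation is not unique",
            s[r - 1], r,
        )
    U1, V1t = _fix_signs(U[:, :r], Vt[:r, :])
    s1 = s[:r]
    approx = (U1 * s1) @ V1t
    residual = float(np.sqrt(np.sum(s[r:] ** 2)))
    return LRAResult(
        rank=r,
        approximation=approx,
        left_factors=U1,
        singular_values=s1,
        right_factors=V1t.T,
        residual_frobenius=residual,
    )


def pssm_descriptor(pssm: PSSM, r: int = DEFAULT_RANK) -> Descriptor:
    """Compute the fixed-length low-rank descriptor of one PSSM.

    The L x 20 score matrix is transposed to 20 x L, truncated at rank ``r``,
    and the 20 x r matrix U1 diag(sqrt(sigma_1..sigma_r)) is flattened
    row-wise (amino-acid rows first).  Its squared Euclidean norm equals
    sigma_1 + ... + sigma_r.  An all-zero PSSM yields the all-zero
    descriptor.
    """
    if pssm.length < r:
        raise ValueError(
            f"PSSM {pssm.protein_id!r} has length {pssm.length} < rank {r}"
        )
    N = pssm.scores.T  # 20 x L
    res = low_rank_approx(N, r)
    D = res.left_factors * np.sqrt(res.singular_values)
    return Descriptor(protein_id=pssm.protein_id, rank=r, values=D.ravel(order="C"))


def pair_feature(
    d_a: Descriptor, d_b: Descriptor, label: Optional[int] = None
) -> PairFeature:
    """Concatenate two protein descriptors into one pair vector (a first)."""
    if d_a.rank != d_b.rank:
        raise ValueError(
            f"descriptor rank mismatch: {d_a.protein_id!r} has r={d_a.rank}, "
            f"{d_b.protein_id!r} has r={d_b.rank}"
        )
    values = np.concatenate([d_a.values, d_b.values])
    return PairFeature(id_a=d_a.protein_id, id_b=d_b.protein_id, values=values, label=label)


def pair_matrix(pairs: Sequence[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair features into (X, y); y entries are -1 where unlabeled."""
    if not pairs:
        raise ValueError("no pair features given")
    X = np.vstack([p.values for p in pairs])
    y = np.array([-1 if p.label is None else p.label for p in pairs], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Feature table TSV
# ---------------------------------------------------------------------------

def write_feature_table(pairs: Sequence[PairFeature], path, rank: int) -> None:
    """Write pair features as TSV: a rank comment, a header, one row per pair."""
    n_feat = 40 * rank
    with open(path, "w") as fh:
        fh.write(f"# rank={rank}\n")
        cols = ["id_a", "id_b", "label"] + [f"f{i:04d}" for i in range(n_feat)]
        fh.write("\t".join(cols) + "\n")
        for p in pairs:
            if p.values.size != n_feat:
                raise ValueError(
                    f"pair ({p.id_a}, {p.id_b}) has {p.values.size} features, "
                    f"expected {n_feat} for rank {rank}"
                )
            label = "" if p.label is None else str(p.label)
            fh.write(
                "\t".join([p.id_a, p.id_b, label] + [repr(float(v)) for v in p.values]) + "\n"
            )


def read_feature_table(path) -> tuple[list[PairFeature], int]:
    """Read a feature table TSV; returns (pairs, rank)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# rank="):
            raise ValueError(f"{path}: missing '# rank=' header line")
        rank = int(first.split("=", 1)[1])
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id_a", "id_b", "label"]:
            raise ValueError(f"{path}: bad column header")
        n_feat = 40 * rank
        pairs: list[PairFeature] = []
        for line_no, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + n_feat:
                raise ValueError(
                    f"{path}: line {line_no} has {len(fields)} fields, "
                    f"expected {3 + n_feat}"
                )
            label = None if fields[2] == "" else int(fields[2])
            values = np.array([float(v) for v in fields[3:]])
            pairs.append(PairFeature(fields[0], fields[1], values, label))
    return pairs, rank
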