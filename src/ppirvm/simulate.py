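"""Synthetic PSSMs and labeled pair datasets with planted class structure.

Real benchmark datasets for pair classification need database downloads and
an iterative profile search, so this module emulates their statistical
shape instead: integer score profiles that look like PSI-BLAST output
(L x 20, values roughly in [-10, 13]) and labeled protein-pair lists with a
controllable class signal.

The signal is planted in the left (20-dimensional amino-acid) singular
subspace of the 20 x L score matrix, because that is exactly what the
low-rank descriptor U1 S1^(1/2) reads: interacting (positive) pairs draw
both members' profiles around one shared class basis with a fixed,
strictly decreasing singular spectrum, so their descriptors concentrate;
each protein of a non-interacting pair gets its own independent random
basis.  ``separation`` scales the planted component relative to the integer
noise — 0 gives label-independent pure-noise profiles (a null dataset),
large values give a nearly separable problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .pssm import AMINO_ACIDS, PSSM, ProteinRecord, write_ascii_pssm, write_fasta, write_pssm_tsv

__all__ = ["SyntheticConfig", "synth_pssm", "synth_ppi_dataset", "random_basis",
           "write_fixture_files"]

SCORE_LO, SCORE_HI = -10, 13
#: Per-entry RMS of the integer noise background (chosen so no-signal
#: profiles fill most of the PSI-BLAST score range).
NOISE_RMS = 4.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic pair dataset.

    ``separation`` is the RMS amplitude (in score units) of the planted
    low-rank class component; 0 removes the signal entirely.  Sequence
    lengths default to at least 50 residues, mirroring the usual short-
    sequence filter on real interaction datasets.
    """

    n_positive: int = 200
    n_negative: int = 200
    length_range: tuple[int, int] = (50, 200)
    separation: float = 8.0
    rank_signal: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("pair counts must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.rank_signal < 1:
            raise ValueError("rank_signal must be >= 1")


def random_basis(rng: np.random.Generator, k: int) -> np.ndarray:
    """A uniformly random 20 x k matrix with orthonormal columns."""
    A = rng.standard_normal((20, k))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))  # sign fix makes the distribution Haar


def synth_pssm(
    length: int,
    seed: int,
    planted_basis: Optional[np.ndarray] = None,
    signal: float = 8.0,
    noise: float = NOISE_RMS,
    protein_id: str = "synthetic",
) -> PSSM:
    """Generate one synthetic integer PSSM of the given length.

    Without a basis the profile is integer noise inside [-10, 13].  With a
    20 x k ``planted_basis`` the 20 x L matrix is a low-rank component whose
    left singular subspace is the basis (with a fixed, strictly decreasing
    spectrum so column order and signs are stable) plus Gaussian noise,
    rounded to integers and clipped to the score range.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    M = noise * rng.standard_normal((20, length))
    if planted_basis is not None and signal > 0:
        B = np.asarray(planted_basis, dtype=float)
        if B.ndim != 2 or B.shape[0] != 20:
            raise ValueError(f"planted_basis must be 20 x k, got {B.shape}")
        k = B.shape[1]
        # Row-orthonormal right factors keep the left subspace exactly col(B).
        G = np.linalg.qr(rng.standard_normal((length, k)))[0].T  # k x L
        spectrum = np.linspace(1.0, 0.5, k)                      # distinct sigmas
        S = (B * spectrum) @ G
        S *= signal * np.sqrt(20 * length) / np.linalg.norm(S)   # entry RMS = signal
        M += S
    scores = np.clip(np.rint(M), SCORE_LO, SCORE_HI).T  # L x 20
    return PSSM(protein_id=protein_id, scores=scores)


@dataclass(frozen=True)
class PairLabel:
    id_a: str
    id_b: str
    label: int


def synth_ppi_dataset(config: SyntheticConfig) -> tuple[list[PSSM], list[PairLabel]]:
    """Generate PSSMs and a labeled pair list under ``config``.

    Every pair introduces two fresh proteins.  Both members of a positive
    pair are planted on the single class basis (drawn once per dataset);
    each member of a negative pair is planted on its own independent basis
    of the same strength, so the two classes differ only in the coherence of
    their profile subspaces, not in scale.  Fully determined by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    class_basis = random_basis(rng, config.rank_signal)

    pssms: list[PSSM] = []
    pairs: list[PairLabel] = []
    counter = 0

    def new_protein(basis: Optional[np.ndarray]) -> str:
        nonlocal counter
        pid = f"P{counter:05d}"
        counter += 1
        length = int(rng.integers(lo, hi + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        pssms.append(
            synth_pssm(length, child_seed, planted_basis=basis,
                       signal=config.separation, protein_id=pid)
        )
        return pid

    for _ in range(config.n_positive):
        a = new_protein(class_basis)
        b = new_protein(class_basis)
        pairs.append(PairLabel(a, b, 1))
    for _ in range(config.n_negative):
        a = new_protein(random_basis(rng, config.rank_signal))
        b = new_protein(random_basis(rng, config.rank_signal))
        pairs.append(PairLabel(a, b, 0))
    return pssms, pairs


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def write_fixture_files(
    config: SyntheticConfig,
    out_dir,
    pssm_format: str = "tsv",
) -> tuple[Path, Path]:
    """Materialize a synthetic dataset as standard fixture files.

    Writes ``proteins.fasta`` (random sequences of matching lengths), one
    PSSM file per protein (``<id>.tsv`` or ``<id>.pssm`` ASCII dialect) and
    ``pairs.tsv`` with columns id_a, id_b, label.  Returns
    (pssm directory, pairs file).
    """
    if pssm_format not in ("tsv", "ascii"):
        raise ValueError(f"pssm_format must be 'tsv' or 'ascii', got {pssm_format!r}")
    out = Path(out_dir)
    pssm_dir = out / "pssms"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    pssms, pairs = synth_ppi_dataset(config)

    rng = np.random.default_rng(config.seed + 1)
    records = [
        ProteinRecord(p.protein_id, _random_sequence(rng, p.length)) for p in pssms
    ]
    write_fasta(records, out / "proteins.fasta")
    for p, rec in zip(pssms, records):
        if pssm_format == "tsv":
            write_pssm_tsv(p, pssm_dir / f"{p.protein_id}.tsv")
        else:
            write_ascii_pssm(p, pssm_dir / f"{p.protein_id}.pssm", sequence=rec.sequence)
    pairs_path = out / "pairs.tsv"
    with open(pairs_path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for pl in pairs:
            fh.write(f"{pl.id_a}\t{pl.id_b}\t{pl.label}\n")
    return pssm_dir, pairs_path
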