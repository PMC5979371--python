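"""Shared fixtures: hand-written PSSM text and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import ppirvm as pv

# Hand-written 3-residue PSI-BLAST ASCII PSSM. The log-odds block (first 20
# columns) was transcribed independently into EXPECTED_PSSM_SCORES below.
ASCII_PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -4  -2  -1  -3  -3  -2   1   2  -2   8   0  -3  -2  -1  -2  -2   0    0   0   0   0   0   0   0   0   0   0   6   0  94   0   0   0   0   0   0   0  0.95 0.12
    2 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1   0  -1  -4  -2  -3    0  13   0   0   0   0   6   0   0   0   0  81   0   0   0   0   0   0   0   0  0.72 0.30
    3 V     0  -3  -3  -4  -1  -3  -3  -4  -4   3   1  -3   1  -1  -3  -2   0  -3  -1   4    6   0   0   0   0   0   0   0   0  13   9   0   0   0   0   0   0   0   0  72  0.61 0.25

                      K         Lambda
Standard Ungapped    0.1337     0.3177
"""

# Independent hand transcription of the log-odds block above.
EXPECTED_PSSM_SCORES = np.array(
    [
        [-1, -2, -3, -4, -2, -1, -3, -3, -2, 1, 2, -2, 8, 0, -3, -2, -1, -2, -2, 0],
        [-1, 2, 0, -1, -4, 1, 1, -2, -1, -3, -3, 5, -2, -4, -1, 0, -1, -4, -2, -3],
        [0, -3, -3, -4, -1, -3, -3, -4, -4, 3, 1, -3, 1, -1, -3, -2, 0, -3, -1, 4],
    ],
    dtype=float,
)


@pytest.fixture
def ascii_pssm_text() -> str:
    return ASCII_PSSM_TEXT


@pytest.fixture
def expected_pssm_scores() -> np.ndarray:
    return EXPECTED_PSSM_SCORES


@pytest.fixture
def ascii_pssm_file(tmp_path):
    path = tmp_path / "P00001.pssm"
    path.write_text(ASCII_PSSM_TEXT)
    return path


@pytest.fixture
def random_pssm() -> pv.PSSM:
    return pv.synth_pssm(length=60, seed=42, protein_id="PRAND")


@pytest.fixture(scope="session")
def small_separable_dataset():
    """40 positive + 40 negative pairs with a strong planted class signal."""
    cfg = pv.SyntheticConfig(n_positive=40, n_negative=40, separation=8.0,
                             length_range=(50, 120), seed=7)
    pssms, pairs = pv.synth_ppi_dataset(cfg)
    desc = {p.protein_id: pv.pssm_descriptor(p) for p in pssms}
    feats = [pv.pair_feature(desc[pl.id_a], desc[pl.id_b], pl.label) for pl in pairs]
    return feats


@pytest.fixture(scope="session")
def small_null_dataset():
    """40 + 40 pairs with no class signal at all."""
    cfg = pv.SyntheticConfig(n_positive=40, n_negative=40, separation=0.0,
                             length_range=(50, 120), seed=11)
    pssms, pairs = pv.synth_ppi_dataset(cfg)
    desc = {p.protein_id: pv.pssm_descriptor(p) for p in pssms}
    return [pv.pair_feature(desc[pl.id_a], desc[pl.id_b], pl.label) for pl in pairs]
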