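"""Base <-> integer code helpers shared across the package.

Bases are stored as uint8 codes A=0, C=1, G=2, T=3; anything else (e.g. N in
user FASTQ) is code 4 and is ignored by pileups and treated as a mismatch by
the aligner.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
AMBIG = 4

_ENC = np.full(256, AMBIG, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = np.array([T, G, C, A, AMBIG], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to a DNA string (4 -> N)."""
    return _DEC[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[np.asarray(codes, dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[np.asarray(codes, dtype=np.uint8)][::-1]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]
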