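"""Nucleotide encoding helpers shared by the scanning and simulation code.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity)
becomes 4 and scores -inf in every position-weight lookup table; code 5 is
reserved for padding of ragged batches.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
PAD_CODE = 5

_ENC = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as an int8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_batch(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a padded (n, max_len) int8 array plus true lengths."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    if len(seqs) == 0:
        return np.zeros((0, 0), dtype=np.int8), lengths
    out = np.full((len(seqs), int(lengths.max())), PAD_CODE, dtype=np.int8)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = encode(s)
    return out, lengths


def decode(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGTNN", dtype=np.uint8)
    return lookup[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (case preserving, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]
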