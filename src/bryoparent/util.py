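"""Shared low-level helpers: base encoding, reverse complement, seeding."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGTN"
N_CODE = 4

# byte -> code lookup (anything unexpected maps to N)
_ASCII2CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ASCII2CODE[ord(_b)] = _i
    _ASCII2CODE[ord(_b.lower())] = _i

_CODE2ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement of A,C,G,T is T,G,C,A; N stays N
_RC = np.array([3, 2, 1, 0, N_CODE], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ASCII2CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _CODE2ASCII[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _RC[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def child_seed(seed: int, *path: int) -> int:
    """Derive a stable child seed (< 2**31) from a root seed and a path.

    Used to fan a single run seed out to independently rerunnable stages.
    """
    ss = np.random.SeedSequence([int(seed), *map(int, path)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_from(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *path) if path else int(seed))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
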