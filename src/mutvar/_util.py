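"""Shared low-level helpers: base/k-mer encoding, reverse complement, seeded streams."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
BASE_TO_CODE["N"] = 4
CODE_TO_BASE = np.array(list(BASES) + ["N"])
COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the 12 point-mutation directions, ordered as in mutation-spectrum tables
DIRECTIONS = [
    ("C", "T"), ("G", "A"), ("T", "C"), ("A", "G"),
    ("C", "G"), ("G", "C"), ("T", "G"), ("A", "C"),
    ("T", "A"), ("A", "T"), ("C", "A"), ("G", "T"),
]

#: strand-complementary pairing of mutation directions
STRAND_PAIRS = [
    (("C", "T"), ("G", "A")),
    (("T", "C"), ("A", "G")),
    (("C", "G"), ("G", "C")),
    (("C", "A"), ("G", "T")),
    (("T", "A"), ("A", "T")),
    (("T", "G"), ("A", "C")),
]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def revcomp_direction(direction: tuple[str, str]) -> tuple[str, str]:
    return (COMPLEMENT[direction[0]], COMPLEMENT[direction[1]])


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGTN string (case-insensitive) as uint8 codes 0..4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        codes[arr == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(CODE_TO_BASE[codes])


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window k-mer integer codes over a code array.

    Returns (codes_of_each_window, valid_mask); windows containing N are
    invalid and carry an arbitrary code.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        valid &= window != 4
        out = out * 4 + np.where(window == 4, 0, window).astype(np.int64)
    return out, valid


def kmer_to_string(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def string_to_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * 4 + BASE_TO_CODE[ch]
    return code


def cell_rng(seed: int, cell_key: int) -> np.random.Generator:
    """Counter-based per-cell stream: independent of which other cells exist."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cell_key,)))


def spawn_rng(seed: int, label: int) -> np.random.Generator:
    """Deterministic sub-stream `label` of master seed `seed`."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(label,)))
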