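"""2-bit DNA codec and vectorised canonical k-mer extraction.

Sequences live in uint8 arrays with A,C,G,T -> 0,1,2,3. The sentinel value 4
separates concatenated records so a whole read set can be scanned in one
vectorised pass; windows touching a sentinel are masked out. A k-mer with
odd k <= 31 packs into a uint64 (2 bits/base, most significant = leftmost
base), and its canonical form is the numeric minimum of the forward and
reverse-complement codes, which for this packing coincides with
lexicographic order on the strings. Odd k guarantees no k-mer is its own
reverse complement, so canonicalisation is unambiguous.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 4
MAX_K = 31

_ENC = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# reverse-complement of the four 2-bit fields packed in one byte
_RC_BYTE = [0] * 256
for _x in range(256):
    _y, _t = 0, _x
    for _ in range(4):
        _y = (_y << 2) | (3 - (_t & 3))
        _t >>= 2
    _RC_BYTE[_x] = _y


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (non-ACGT -> sentinel)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string (sentinel -> N)."""
    return _DEC[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return decode(revcomp_arr(encode(seq)))


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a pure-ACGT code array (no sentinels)."""
    return (3 - arr[::-1]).astype(np.uint8)


def check_k(k: int) -> None:
    if not (3 <= k <= MAX_K) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [3, {MAX_K}], got {k}")


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Forward k-mer codes for every window of ``arr`` (caller masks validity)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    a = arr.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : j + n]
    return codes


def canonical_codes(arr: np.ndarray, k: int):
    """Canonical k-mer codes for all windows of a (possibly sentinel-separated) array.

    Returns ``(canon, fwd_is_canon, valid)``; positions where ``valid`` is False
    contain garbage codes and must be ignored.
    """
    check_k(k)
    n = arr.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    fwd = kmer_codes(arr, k)
    comp = np.where(arr >= SENTINEL, arr, 3 - arr).astype(np.uint8)
    rc = kmer_codes(comp[::-1], k)[::-1]
    canon = np.minimum(fwd, rc)
    fwd_is_canon = fwd <= rc
    bad = np.concatenate(([0], np.cumsum(arr >= SENTINEL)))
    valid = (bad[k:] - bad[:-k]) == 0
    return canon, fwd_is_canon, valid


def rc_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer code (scalar, byte-table based)."""
    nbytes = (2 * k + 7) // 8
    r = 0
    for _ in range(nbytes):
        r = (r << 8) | _RC_BYTE[code & 0xFF]
        code >>= 8
    return r >> (8 * nbytes - 2 * k)


def code_to_str(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def str_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_ENC[ord(ch)])
    return code


def concat_with_sentinels(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate encoded sequences with one sentinel between records.

    Returns ``(big, starts)`` where ``starts[i]`` is the offset of sequence
    ``i`` inside ``big``.
    """
    total = sum(len(s) for s in seqs) + max(0, len(seqs) - 1)
    big = np.full(total, SENTINEL, dtype=np.uint8)
    starts = np.empty(len(seqs), dtype=np.int64)
    pos = 0
    for i, s in enumerate(seqs):
        starts[i] = pos
        big[pos : pos + len(s)] = encode(s)
        pos += len(s) + 1
    return big, starts
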