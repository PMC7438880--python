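"""Exact k-mer indexing and seed clustering for the search machinery.

Chromosome-scale sequences are hashed once (base-4 rolling hash, k <= 31)
into a sorted array that answers "where does this k-mer occur" by binary
search; windows containing N never seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4, as a uint8 array."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid) for every window start; invalid windows contain an N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.where(codes == 4, 0, codes).astype(np.int64)
    h = np.zeros(n, dtype=np.int64)
    for j in range(k):
        h = h * 4 + safe[j : j + n]
    bad = np.concatenate(([0], np.cumsum(codes == 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return h, valid


class KmerIndex:
    """Sorted-hash index over one sequence for exact k-mer lookups."""

    def __init__(self, seq: str | np.ndarray, k: int = 12):
        self.k = k
        self.codes = encode(seq) if isinstance(seq, str) else seq
        self.length = len(self.codes)
        h, valid = kmer_hashes(self.codes, k)
        pos = np.nonzero(valid)[0]
        hv = h[pos]
        order = np.argsort(hv, kind="stable")
        self._hashes = hv[order]
        self._positions = pos[order]

    def seed_matches(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All exact k-mer matches as ``(query_positions, target_positions)``."""
        qh, qvalid = kmer_hashes(query_codes, self.k)
        qpos_all = np.nonzero(qvalid)[0]
        if qpos_all.size == 0 or self._hashes.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._hashes, qh[qpos_all], side="left")
        hi = np.searchsorted(self._hashes, qh[qpos_all], side="right")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos_rep = np.repeat(qpos_all[keep], counts[keep])
        tpos = np.concatenate(
            [self._positions[a:b] for a, b in zip(lo[keep], hi[keep])]
        )
        return qpos_rep.astype(np.int64), tpos.astype(np.int64)


@dataclass(frozen=True)
class SeedCluster:
    """A diagonal-consistent group of seeds and its alignment window."""

    window_start: int
    window_end: int
    n_seeds: int


def cluster_windows(
    qpos: np.ndarray,
    tpos: np.ndarray,
    query_len: int,
    target_len: int,
    k: int,
    band: int = 15,
    pad: int = 40,
    max_gap: int | None = None,
    min_seeds: int = 1,
) -> list[SeedCluster]:
    """Group seeds by diagonal (+/- band) into candidate alignment windows.

    Seeds whose diagonals differ by more than ``band``, or that jump more than
    ``max_gap`` (default: query length) along the target within one diagonal
    group, start a new cluster.  Each cluster maps to a target window wide
    enough to hold a full-query alignment; overlapping windows merge.
    """
    if qpos.size == 0:
        return []
    if max_gap is None:
        max_gap = query_len + 2 * band
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag, tpos_s = diag[order], tpos[order]
    windows: list[tuple[int, int, int]] = []
    start_i = 0
    for i in range(1, len(diag) + 1):
        if (
            i == len(diag)
            or diag[i] - diag[i - 1] > band
            or (diag[i] == diag[i - 1] and tpos_s[i] - tpos_s[i - 1] > max_gap)
        ):
            if i - start_i >= min_seeds:
                d_lo = int(diag[start_i])
                d_hi = int(diag[i - 1])
                ws = max(0, d_lo - pad)
                we = min(target_len, d_hi + query_len + k + pad)
                if we > ws:
                    windows.append((ws, we, i - start_i))
            start_i = i
    windows.sort()
    merged: list[list[int]] = []
    for ws, we, n in windows:
        if merged and ws <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], we)
            merged[-1][2] += n
        else:
            merged.append([ws, we, n])
    return [SeedCluster(ws, we, n) for ws, we, n in merged]
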