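"""Bottom-s MinHash sketches and Mash distances between MGE sequences.

Each sequence is reduced to the s smallest 64-bit hash values over its
canonical k-mers (a k-mer and its reverse complement hash identically, so
sketches are strand-independent).  The Mash distance between two sketches
is d = -(1/k) * ln(2j / (1 + j)) with j the Jaccard index estimated from
the bottom-s sketch of the union; j = 0 saturates at d = 1.0.  MGE pairs
at d strictly below 0.01 count as similar elements.

Hashing is a seeded 64-bit MurmurHash3-finalizer-style mix applied to the
2-bit-packed k-mer, vectorized with numpy; the seed is fixed (42) so
sketches are deterministic and comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from taloci.config import (
    DEFAULT_HASH_SEED,
    DEFAULT_K,
    DEFAULT_MASH_THRESHOLD,
    DEFAULT_SKETCH_SIZE,
)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX2 = np.uint64(0xC4CEB9FE1A85EC53)


@dataclass
class MinHashSketch:
    """Bottom-s sketch: the s smallest hash values over canonical k-mers."""

    mge_id: str
    k: int
    s: int
    seed: int
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > 1 and not np.all(self.hashes[1:] > self.hashes[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit finalizer mix (MurmurHash3 fmix64 constants)."""
    with np.errstate(over="ignore"):
        z = x + np.uint64(seed) * _GOLDEN
        z ^= z >> np.uint64(33)
        z *= _MIX1
        z ^= z >> np.uint64(33)
        z *= _MIX2
        z ^= z >> np.uint64(33)
    return z


def _kmer_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _pack_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-pack all k-mers; returns (packed values, validity mask)."""
    n = codes.size - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(windows >= 0, axis=1)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    packed = (windows.astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)
    assert packed.size == n
    return packed, valid


def sketch(
    seq: str,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_HASH_SEED,
    mge_id: str = "",
) -> MinHashSketch:
    """Sketch a nucleotide sequence.

    Canonical k-mer = lexicographic minimum of the k-mer and its reverse
    complement (odd k keeps the two distinct).  K-mers containing N (or
    any non-ACGT letter) are skipped.  Deterministic for fixed
    (seq, k, s, seed).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = _kmer_codes(seq)
    fwd, valid = _pack_kmers(codes, k)
    # reverse complement: complement codes (3 - c), reversed; its i-th k-mer
    # is the canonical partner of the forward k-mer at position n-1-i.
    rc_codes = (np.int8(3) - codes)[::-1].copy()
    rc_codes[codes[::-1] < 0] = -1
    rev, _ = _pack_kmers(rc_codes, k)
    rev = rev[::-1]
    canonical = np.minimum(fwd, rev)[valid]
    if canonical.size == 0:
        return MinHashSketch(mge_id, k, s, seed, np.empty(0, dtype=np.uint64))
    hashes = np.unique(_mix64(canonical, seed))  # unique() also sorts
    return MinHashSketch(mge_id, k, s, seed, hashes[:s])


def jaccard_estimate(a: MinHashSketch, b: MinHashSketch) -> float:
    """Jaccard index estimated from the bottom-s sketch of the union."""
    if a.k != b.k or a.s != b.s:
        raise ValueError("sketch parameter mismatch (k or s)")
    if a.seed != b.seed:
        raise ValueError("sketch seed mismatch")
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(a.s, union.size)]
    if bottom.size == 0:
        return 0.0
    shared = np.intersect1d(bottom, np.intersect1d(a.hashes, b.hashes)).size
    return shared / bottom.size


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance d = -(1/k) * ln(2j/(1+j)); j=0 saturates at 1.0."""
    j = jaccard_estimate(a, b)
    if j <= 0.0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.k
    return float(min(max(d, 0.0), 1.0))


def similar_edges(
    sketches: Sequence[MinHashSketch],
    threshold: float = DEFAULT_MASH_THRESHOLD,
) -> list[tuple[str, str, float]]:
    """All unordered MGE pairs at Mash distance strictly below ``threshold``."""
    edges: list[tuple[str, str, float]] = []
    for i in range(len(sketches)):
        for jdx in range(i + 1, len(sketches)):
            d = mash_distance(sketches[i], sketches[jdx])
            if d < threshold:
                edges.append((sketches[i].mge_id, sketches[jdx].mge_id, d))
    return edges


def sketches_to_json(sketches: Sequence[MinHashSketch], path: str | Path) -> None:
    """Serialize sketches (hashes hex-encoded) to a JSON file."""
    payload = [
        {
            "mge_id": sk.mge_id,
            "k": sk.k,
            "s": sk.s,
            "seed": sk.seed,
            "hashes": [format(int(h), "016x") for h in sk.hashes],
        }
        for sk in sketches
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def sketches_from_json(path: str | Path) -> list[MinHashSketch]:
    payload = json.loads(Path(path).read_text())
    return [
        MinHashSketch(
            item["mge_id"],
            item["k"],
            item["s"],
            item["seed"],
            np.array([int(h, 16) for h in item["hashes"]], dtype=np.uint64),
        )
        for item in payload
    ]


def edges_to_tsv(edges: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mge_a\tmge_b\tmash_distance\n")
        for a, b, d in edges:
            fh.write(f"{a}\t{b}\t{d:.6f}\n")
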