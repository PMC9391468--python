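"""DNA sequence encoding helpers.

Bases are encoded A=0, C=1, G=2, T=3; any ambiguity code becomes 4 (N)
and is excluded from scanning windows.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (N=4 for ambiguity)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def dinucleotide_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erikson Euler-path shuffle: the doublet graph's edge lists
    are permuted and a random last-edge tree into the terminal base is
    drawn by rejection; the returned walk has identical first/last base
    and doublet composition. Positions with N break the sequence into
    independently shuffled segments.
    """
    codes = np.asarray(codes)
    if np.any(codes == N_CODE):
        out = codes.copy()
        # shuffle each N-free segment independently
        is_ok = codes != N_CODE
        boundaries = np.flatnonzero(np.diff(is_ok.astype(int)) != 0) + 1
        segments = np.split(np.arange(len(codes)), boundaries)
        for seg in segments:
            if len(seg) > 1 and is_ok[seg[0]]:
                out[seg] = dinucleotide_shuffle(codes[seg], rng)
        return out
    n = len(codes)
    if n < 3:
        return codes.copy()
    first, last = int(codes[0]), int(codes[-1])
    # successor edge lists per vertex
    succ: list[list[int]] = [[] for _ in range(4)]
    for a, b in zip(codes[:-1], codes[1:]):
        succ[a].append(int(b))
    vertices = [v for v in range(4) if succ[v] or v == last]
    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v != last and succ[v]:
                last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        # check: following last edges from every vertex reaches `last`
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - rejection always terminates for DNA
        raise RuntimeError("dinucleotide shuffle failed to find an Euler path")
    shuffled: list[list[int]] = []
    for v in range(4):
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        edges = [edges[i] for i in perm]
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled.append(edges)
    walk = [first]
    ptr = [0, 0, 0, 0]
    u = first
    for _ in range(n - 1):
        nxt = shuffled[u][ptr[u]]
        ptr[u] += 1
        walk.append(nxt)
        u = nxt
    return np.asarray(walk, dtype=np.int8)
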