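"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import numpy as np

_CODE = {b: i for i, b in enumerate("ACGT")}
_COMP = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def naive_nonunique_windows(
    seq: str, window: int = 300, step: int = 10, max_mismatch: int = 2
) -> set:
    """All-pairs Hamming scan: window starts (on the step grid) that match a
    second genomic locale on either strand at <= max_mismatch mismatches.

    Lag-based but exhaustive: for every relative offset the per-position
    mismatch indicator is cumulative-summed, giving every window-vs-window
    Hamming distance exactly.
    """
    n = len(seq)
    g = _encode(seq)
    h = _encode(seq.translate(_COMP)[::-1])  # reverse complement
    grid = set(range(0, n - window + 1, step))
    bad: set[int] = set()

    # forward strand: compare every pair of starts (i, i + d), d >= 1
    for d in range(1, n - window + 1):
        mism = (g[d:] != g[:-d]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(mism)])
        if len(mism) < window:
            break
        dist = cs[window:] - cs[:-window]
        for i in np.flatnonzero(dist <= max_mismatch):
            i = int(i)
            if i in grid:
                bad.add(i)
            j = i + d
            if j in grid:
                bad.add(j)

    # reverse strand: window i of g vs window i+o of h; the rc-window at
    # index m in h corresponds to genomic locale n - window - m
    for o in range(-(n - window), n - window + 1):
        lo = max(0, -o)
        hi = min(n, n - o)
        if hi - lo < window:
            continue
        mism = (g[lo:hi] != h[lo + o:hi + o]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(mism)])
        dist = cs[window:] - cs[:-window]
        for t in np.flatnonzero(dist <= max_mismatch):
            i = lo + int(t)
            if i not in grid:
                continue
            locale = n - window - (i + o)
            if locale != i:  # a palindrome matching itself is not a 2nd locale
                bad.add(i)
    return bad


def fourfold_count_by_codon_scan(genome) -> int:
    """Count 4-fold third positions by re-translating every codon with
    Biopython, independently of the generator's classification arrays."""
    from Bio.Seq import Seq

    total = 0
    seq = genome.sequence
    for _, row in genome.genes.iterrows():
        gene = seq[row.start:row.end]
        if row.strand == "-":
            gene = str(Seq(gene).reverse_complement())
        for k in range(0, len(gene), 3):
            codon = gene[k:k + 3]
            aa = str(Seq(codon).translate())
            if sum(str(Seq(codon[:2] + b).translate()) == aa for b in "ACGT") == 4:
                total += 1
    return total
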