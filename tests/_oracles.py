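"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by the most transparent route available
(exhaustive recomputation, sliding windows, closed forms), sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_agglomerate(ids, coords, threshold, linkage="average"):
    """O(n^3) agglomeration recomputing every linkage distance from scratch
    at every step.  Returns frozenset of frozensets of sample ids."""
    coords = np.asarray(coords, dtype=float)
    clusters = [[i] for i in range(len(ids))]

    def dist(a, b):
        d = [
            float(np.hypot(*(coords[i] - coords[j])))
            for i in a
            for j in b
        ]
        if linkage == "complete":
            return max(d)
        if linkage == "single":
            return min(d)
        return sum(d) / len(d)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = dist(clusters[x], clusters[y])
                key = (
                    d,
                    ids[min(clusters[x] + clusters[y])],
                    ids[max(min(clusters[x]), min(clusters[y]))],
                )
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, *_), x, y = best
        if d > threshold:
            break
        clusters[x] = sorted(clusters[x] + clusters[y])
        del clusters[y]
    return frozenset(frozenset(ids[i] for i in c) for c in clusters)


def sliding_hits(reference: dict[str, str], query: str, max_mm: int):
    """Every (chrom, start, strand, mismatches) where the query or its
    reverse complement matches a window within max_mm substitutions,
    computed by comparing all windows with numpy."""
    k = len(query)
    out = set()
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        for strand, q in (("+", query), ("-", revcomp(query))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            mm = (windows != qa).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                out.add((chrom, int(pos), strand, int(mm[pos])))
    return out


def chi2_gof(observed, ratio):
    """Pearson chi-square statistic and p computed from first principles."""
    total = sum(observed)
    expected = [r * total / sum(ratio) for r in ratio]
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(chi2_dist.sf(stat, len(observed) - 1))
    return stat, p
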