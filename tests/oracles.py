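"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from definitions with different code
paths than the package (per-diagonal numpy enumeration instead of seeded
scanning, position-by-position walks instead of run-length encoding), so
agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from plastobarcode._seq import complement, revcomp
from plastobarcode.repeats import DEFAULT_SSR_THRESHOLDS, LongRepeatHit

_ENC = np.full(256, 4, np.int16)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i


def oracle_long_repeats(seq, min_len=20, max_mm=3, types=("F", "R", "P", "C")):
    """All maximal disjoint-copy repeat hits, from the definition."""
    n = len(seq)
    A = _ENC[np.frombuffer(seq.encode(), np.uint8)]
    hits = []
    for rtype in types:
        bs = {"F": seq, "C": complement(seq), "R": seq[::-1], "P": revcomp(seq)}[rtype]
        B = _ENC[np.frombuffer(bs.encode(), np.uint8)].copy()
        B[B == 4] = 5  # N never matches, not even N-N
        drange = range(1, n) if rtype in ("F", "C") else range(-(n - 1), n)
        per_diag = {}
        for d in drange:
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            m = A[lo:hi] == B[lo + d : hi + d]
            L = hi - lo
            mm = np.flatnonzero(~m)
            sent = np.concatenate(([-1], mm, [L]))
            wins = []
            if len(mm) <= max_mm:
                wins.append((0, L))
            else:
                for t in range(len(mm) - max_mm + 1):
                    wins.append((int(sent[t]) + 1, int(sent[t + max_mm + 1])))
            for wl, wh in wins:
                while wl < wh and not m[wl]:
                    wl += 1
                while wh > wl and not m[wh - 1]:
                    wh -= 1
                if wh - wl < min_len:
                    continue
                nmm = int(np.count_nonzero(~m[wl:wh]))
                wl2, wh2 = wl + lo, wh + lo
                if rtype in ("R", "P") and wl2 > n - d - wh2:
                    wl2, wh2 = n - d - wh2, n - d - wl2
                length = wh2 - wl2
                if rtype in ("F", "C"):
                    p1, p2 = wl2, wl2 + d
                else:
                    p1, p2 = wl2, n - d - wh2
                if p2 < p1:
                    p1, p2 = p2, p1
                if p2 < p1 + length:  # overlapping copies discarded
                    continue
                per_diag.setdefault(d, set()).add((wl2, wh2, nmm))
        for d, wins in per_diag.items():
            ws = sorted(wins)
            cluster, cl_end = [], -1
            for w in ws + [(n + 2, n + 2, 0)]:
                if cluster and w[0] >= cl_end:
                    wl, wh, nmm = min(cluster, key=lambda x: (-(x[1] - x[0]), x[2], x[0]))
                    length = wh - wl
                    if rtype in ("F", "C"):
                        p1, p2 = wl, wl + d
                    else:
                        p1, p2 = wl, n - d - wh
                    if p2 < p1:
                        p1, p2 = p2, p1
                    hits.append(LongRepeatHit(rtype, length, p1, p2, nmm))
                    cluster, cl_end = [], -1
                if w[0] <= n:
                    cluster.append(w)
                    cl_end = max(cl_end, w[1])
    return sorted(hits, key=lambda h: (h.type, h.pos1, h.pos2))


def oracle_ssrs(seq, thresholds=None):
    """Maximal perfect tandem runs meeting the thresholds, by direct walk."""
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    out = []
    for p, minrep in sorted(thresholds.items()):
        i = 0
        while i + p <= n:
            if 0 < i and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                i += 1
                continue  # not left-maximal
            j = i
            while j + p < n and seq[j] == seq[j + p]:
                j += 1
            if j == i:
                i += 1
                continue
            total = (j + p) - i
            count = total // p
            motif = seq[i : i + p]
            primitive = all(
                motif != motif[:d] * (p // d) for d in range(1, p) if p % d == 0
            )
            if count >= minrep and primitive and "N" not in motif:
                out.append((i, i + total, p, motif, count))
            i += 1
    return sorted(out)


def k2p_closed_form(P: float, Q: float) -> float:
    """Independent numeric evaluation of the K2P closed form."""
    return -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
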