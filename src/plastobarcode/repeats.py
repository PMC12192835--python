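"""Microsatellite (SSR) and long-repeat detection.

SSRs follow MISA-style thresholds: a perfect tandem run of a 1-6 bp motif
is reported when its repeat count reaches the per-period minimum
(10/5/4/3/3/3 by default).  Runs are reported at their smallest period only
(a poly-A run is not also an AA dimer), and circular genomes are scanned on
the doubled sequence with deduplication.

Long repeats come in four flavours named after REPuter's vocabulary:
the second copy equals the first (F, forward), its reverse (R), its
complement (C), or its reverse complement (P, palindromic).  A hit is a
maximal pair of disjoint copies of >= ``min_len`` bp agreeing under the
type's transformation with at most ``max_mismatch`` (Hamming) mismatches.
Overlapping candidate windows on one diagonal are collapsed to the single
best (longest) hit, which keeps one planted repeat from surfacing as a
cluster of shifted windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from ._seq import complement, revcomp, to_uint8

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

SPECTRUM_BINS = ("20-30", "31-40", "41-50", "51-60", ">61")

REPEAT_TYPES = ("F", "R", "P", "C")


@dataclass(frozen=True)
class SSRHit:
    start: int
    end: int  # half-open; may include a partial trailing repeat
    period: int
    motif: str
    canonical_class: str
    repeat_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LongRepeatHit:
    type: str  # F | R | P | C
    length: int
    pos1: int
    pos2: int
    mismatches: int


def canonical_motif(motif: str) -> str:
    """Canonical strand/rotation-invariant motif class, e.g. "AAT/ATT".

    The class is the lexicographically smallest rotation among all rotations
    of the motif and of its reverse complement, displayed together with that
    rotation's reverse complement.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    variants = []
    for m in (motif, revcomp(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    smallest = min(variants)
    return f"{smallest}/{revcomp(smallest)}"


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    thresholds: dict[int, int] | None = None,
    circular: bool = False,
) -> list[SSRHit]:
    """All maximal perfect tandem runs meeting the period thresholds."""
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    scan_seq = sequence + sequence if circular else sequence
    a = to_uint8(scan_seq)
    hits: dict[tuple[int, int], SSRHit] = {}
    for period, min_repeats in sorted(thresholds.items()):
        if len(scan_seq) <= period:
            continue
        eq = a[period:] == a[:-period]
        # maximal True runs of eq
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            run = int(run_end - run_start)
            start = int(run_start)
            total = run + period  # length of the periodic stretch
            if circular:
                if start >= n:
                    continue
                total = min(total, n)
            count = total // period
            if count < min_repeats:
                continue
            motif = scan_seq[start : start + period]
            if "N" in motif or not _is_primitive(motif):
                continue
            key = (start % n if circular else start, period)
            hit = SSRHit(
                start=key[0],
                end=key[0] + total,
                period=period,
                motif=motif,
                canonical_class=canonical_motif(motif),
                repeat_count=count,
            )
            if key not in hits or hits[key].length < hit.length:
                hits[key] = hit
    return sorted(hits.values(), key=lambda h: (h.start, h.period))


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode2(seq: str, off: int = 0) -> np.ndarray:
    """2-bit codes; non-ACGT become 4+off so they never match anything."""
    out = _ENC[to_uint8(seq)].copy()
    if off:
        out[out == 4] = 4 + off
    return out


def _kmer_codes(codes: np.ndarray, k: int, invalid: int) -> np.ndarray:
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for t in range(k):
        win = codes[t : t + n].astype(np.int64)
        c = c * 4 + np.minimum(win, 3)
        valid &= win < 4
    c[~valid] = invalid
    return c


def _seed_pairs(
    a2: np.ndarray, b2: np.ndarray, k: int, d_lo: int, d_hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (d, i) with an exact k-mer match a[i:i+k] == b[i+d : i+d+k],
    sorted by (d, i).  Every window of >= min_len with <= max_mm mismatches
    contains such a seed by pigeonhole when k <= ceil((min_len-mm)/(mm+1))."""
    ca = _kmer_codes(a2, k, invalid=-2)
    cb = _kmer_codes(b2, k, invalid=-3)
    if not len(ca) or not len(cb):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    oa = np.argsort(ca, kind="stable")
    ob = np.argsort(cb, kind="stable")
    sa, sb = ca[oa], cb[ob]
    ua, a_start = np.unique(sa, return_index=True)
    ub, b_start = np.unique(sb, return_index=True)
    a_end = np.append(a_start[1:], len(sa))
    b_end = np.append(b_start[1:], len(sb))
    common, ai, bi = np.intersect1d(ua, ub, return_indices=True)
    ii, jj = [], []
    for t in range(len(common)):
        if common[t] < 0:
            continue
        ga = oa[a_start[ai[t]] : a_end[ai[t]]]
        gb = ob[b_start[bi[t]] : b_end[bi[t]]]
        ii.append(np.repeat(ga, len(gb)))
        jj.append(np.tile(gb, len(ga)))
    if not ii:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    d = j - i
    keep = (d >= d_lo) & (d < d_hi)
    i, d = i[keep], d[keep]
    order = np.lexsort((i, d))
    return d[order], i[order]


@njit(cache=False)
def _refine_kernel(a2, b2, ds, is_, min_len, max_mm, gap_merge):  # pragma: no cover - jit
    """Maximal-window scan restricted to seed neighbourhoods.

    Seeds (sorted by diagonal, then position) are merged into segments per
    diagonal; around each segment the queue scan emits every maximal window
    with <= max_mm interior mismatches that intersects it.  Returns flat
    (d, lo, hi) int64 triples (window bounds in a-coordinates).
    """
    na = a2.shape[0]
    nb = b2.shape[0]
    cap = 4096
    out = np.empty(cap, dtype=np.int64)
    cnt = 0
    q = np.empty(max_mm + 1, dtype=np.int64)
    tmp = np.empty(max_mm + 1, dtype=np.int64)
    npairs = ds.shape[0]
    p = 0
    while p < npairs:
        d = ds[p]
        i0 = is_[p]
        i1 = i0
        p += 1
        while p < npairs and ds[p] == d and is_[p] - i1 <= gap_merge:
            i1 = is_[p]
            p += 1
        lo_b = 0 if d >= 0 else -d
        hi_b = na if nb - d < na else na
        if nb - d < na:
            hi_b = nb - d
        # prefill the queue with the max_mm+1 nearest mismatches left of i0
        t = 0
        pos = i0 - 1
        while pos >= lo_b and t < max_mm + 1:
            if a2[pos] != b2[pos + d]:
                tmp[t] = pos
                t += 1
            pos -= 1
        for x in range(max_mm + 1):
            q[x] = lo_b - 1
        for x in range(t):
            q[max_mm - x] = tmp[x]
        nreal = t
        mm_after = 0
        i = i0
        reached_end = True
        while i < hi_b:
            if a2[i] != b2[i + d]:
                if nreal >= max_mm and i - (q[0] + 1) >= min_len:
                    if cnt + 3 > cap:
                        cap *= 2
                        grown = np.empty(cap, dtype=np.int64)
                        grown[:cnt] = out[:cnt]
                        out = grown
                    out[cnt] = d
                    out[cnt + 1] = q[0] + 1
                    out[cnt + 2] = i
                    cnt += 3
                for x in range(max_mm):
                    q[x] = q[x + 1]
                q[max_mm] = i
                nreal += 1
                if i > i1:
                    mm_after += 1
                    if mm_after > max_mm:
                        reached_end = False
                        break
            i += 1
        if reached_end and hi_b - (q[0] + 1) >= min_len:
            if cnt + 3 > cap:
                cap *= 2
                grown = np.empty(cap, dtype=np.int64)
                grown[:cnt] = out[:cnt]
                out = grown
            out[cnt] = d
            out[cnt + 1] = q[0] + 1
            out[cnt + 2] = hi_b
            cnt += 3
    return out[:cnt].copy()


def _scan_diagonals(a_seq: str, b_seq: str, min_len: int, max_mm: int,
                    d_lo: int, d_hi: int) -> np.ndarray:
    """Exact enumeration of maximal <=max_mm-mismatch windows of >= min_len
    via k-mer seeding plus local refinement."""
    k = min(8, max(1, (min_len - max_mm + max_mm) // (max_mm + 1)))
    gap_merge = (max_mm + 1) * (k - 1) + max_mm + k + 2
    a2 = _encode2(a_seq, off=0)
    b2 = _encode2(b_seq, off=1)
    ds, is_ = _seed_pairs(a2, b2, k, d_lo, d_hi)
    if not len(ds):
        return np.empty(0, dtype=np.int64)
    return _refine_kernel(a2, b2, ds, is_, min_len, max_mm, gap_merge)


def _transformed(seq: str, rtype: str) -> str:
    if rtype == "F":
        return seq
    if rtype == "C":
        return complement(seq)
    if rtype == "R":
        return seq[::-1]
    if rtype == "P":
        return revcomp(seq)
    raise ValueError(f"unknown repeat type {rtype!r}")


def _map_window(rtype: str, n: int, d: int, lo: int, hi: int) -> tuple[int, int, int]:
    """(pos1, pos2, length) of the two copies for an i-window [lo, hi)."""
    length = hi - lo
    if rtype in ("F", "C"):
        return lo, lo + d, length
    # R/P pair i with n-1-d-i; the partner copy occupies [n-d-hi, n-d-lo)
    return lo, n - d - hi, length


def find_long_repeats(
    sequence: str,
    min_len: int = 20,
    max_mismatch: int = 3,
    types: Sequence[str] = REPEAT_TYPES,
    exclude_ir: bool = False,
    ir_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> list[LongRepeatHit]:
    """All maximal disjoint-copy repeat pairs of each requested type.

    With ``exclude_ir`` and the genome's IR intervals supplied, palindromic
    hits that are the quadripartite IR pair itself are dropped.
    """
    n = len(sequence)
    if n < 2 * min_len:
        return []
    a = _encode2(sequence, off=0)
    hits: list[LongRepeatHit] = []
    for rtype in types:
        b_seq = _transformed(sequence, rtype)
        b = _encode2(b_seq, off=1)
        if rtype in ("F", "C"):
            d_lo, d_hi = 1, n
        else:
            d_lo, d_hi = -(n - 1), n
        raw = _scan_diagonals(sequence, b_seq, min_len, max_mismatch, d_lo, d_hi)
        per_diag: dict[int, list[tuple[int, int, int, int]]] = {}
        seen: set[tuple[int, int, int]] = set()
        for t in range(0, len(raw), 3):
            d, lo, hi = int(raw[t]), int(raw[t + 1]), int(raw[t + 2])
            # trim to match-bounded window and recount mismatches
            while lo < hi and a[lo] != b[lo + d]:
                lo += 1
            while hi > lo and a[hi - 1] != b[hi - 1 + d]:
                hi -= 1
            if hi - lo < min_len:
                continue
            if rtype in ("R", "P") and lo > n - d - hi:
                # mirror-pair representation: keep the left copy's window
                lo, hi = n - d - hi, n - d - lo
            mism = int(np.count_nonzero(a[lo:hi] != b[lo + d : hi + d]))
            pos1, pos2, length = _map_window(rtype, n, d, lo, hi)
            if pos2 < pos1:
                pos1, pos2 = pos2, pos1
            if pos2 < pos1 + length:  # overlapping copies: discarded
                continue
            key = (pos1, pos2, length)
            if key in seen:
                continue
            seen.add(key)
            per_diag.setdefault(d, []).append((lo, hi, mism, pos1))
        # collapse overlapping windows on one diagonal to the best hit
        for d, wins in per_diag.items():
            wins.sort()
            cluster: list[tuple[int, int, int, int]] = []
            cl_end = -1
            for w in wins + [(n + 1, n + 1, 0, 0)]:
                if cluster and w[0] >= cl_end:
                    best = min(cluster, key=lambda x: (-(x[1] - x[0]), x[2], x[0]))
                    lo, hi, mism, _ = best
                    pos1, pos2, length = _map_window(rtype, n, d, lo, hi)
                    if pos2 < pos1:
                        pos1, pos2 = pos2, pos1
                    hits.append(LongRepeatHit(rtype, length, pos1, pos2, mism))
                    cluster = []
                    cl_end = -1
                if w[0] <= n:
                    cluster.append(w)
                    cl_end = max(cl_end, w[1])
    if exclude_ir and ir_intervals is not None:
        (b1, e1), (b2, e2) = ir_intervals
        hits = [
            h
            for h in hits
            if not (
                h.type == "P"
                and _within(h.pos1, h.pos1 + h.length, b1, e1, n)
                and _within(h.pos2, h.pos2 + h.length, b2, e2, n)
            )
        ]
    return sorted(hits, key=lambda h: (h.type, h.pos1, h.pos2))


def _within(s: int, e: int, lo: int, hi: int, n: int) -> bool:
    if hi <= lo:
        hi += n
    if s < lo:
        s, e = s + n, e + n
    return lo <= s and e <= hi


def repeat_length_spectrum(hits: Iterable[LongRepeatHit]) -> dict[str, int]:
    """Counts per length bin (20-30, 31-40, 41-50, 51-60, >61 as labelled
    in the plastome literature; lengths above 60 fall in the last bin)."""
    counts = {b: 0 for b in SPECTRUM_BINS}
    for h in hits:
        length = h.length
        if length <= 30:
            counts["20-30"] += 1
        elif length <= 40:
            counts["31-40"] += 1
        elif length <= 50:
            counts["41-50"] += 1
        elif length <= 60:
            counts["51-60"] += 1
        else:
            counts[">61"] += 1
    return counts
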