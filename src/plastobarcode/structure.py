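"""Quadripartite plastome structure: IR detection, region GC, junction genes.

A typical plastome is a circle tiled by four regions, LSC -> IRb -> SSC ->
IRa, where IRa is the reverse complement of IRb.  Detection seeds exact
25-mer matches between the sequence and its reverse complement, groups them
by anti-diagonal, takes the longest exact core and extends it outward
allowing mismatches up to ``max_mismatch_frac``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._seq import complement, gc_percent
from .genome_io import GenomeRecord

log = logging.getLogger(__name__)

REGIONS = ("LSC", "IRb", "SSC", "IRa")


class NoIRFound(ValueError):
    """No inverted-repeat pair of the required size exists."""


def gc_content(sequence: str) -> float:
    """GC percentage of a sequence; Ns excluded from the denominator."""
    return gc_percent(sequence)


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals (0-based half-open on the circle).

    Intervals are stored unwrapped: ``end`` may exceed the genome length, in
    which case the region wraps the origin.  The four regions are disjoint
    and tile the full circle in the order LSC, IRb, SSC, IRa.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    ir_identity: float

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def lengths(self) -> dict[str, int]:
        return {k: e - s for k, (s, e) in self.as_dict().items()}

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name, (s, e) in self.as_dict().items():
            if s <= pos < e or s <= pos + self.genome_length < e:
                return name
        raise ValueError(f"position {pos} not covered")  # pragma: no cover

    def junctions(self) -> dict[str, int]:
        """Junction name -> boundary position (start of the second region)."""
        n = self.genome_length
        return {
            "LSC/IRb": self.irb[0] % n,
            "IRb/SSC": self.ssc[0] % n,
            "SSC/IRa": self.ira[0] % n,
            "IRa/LSC": self.lsc[0] % n,
        }


def _seed_antidiagonals(seq: str, k: int) -> dict[int, list[int]]:
    """Map anti-diagonal (a+b+k-1 mod n) -> sorted starts a of inverted k-mer matches.

    Positions are circular; k-mers are taken from the doubled sequence so
    repeats wrapping the origin are found too.
    """
    n = len(seq)
    doubled = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for a in range(n):
        index.setdefault(doubled[a : a + k], []).append(a)
    rc_map: dict[int, list[int]] = {}
    comp_tr = complement(doubled)
    for a in range(n):
        km_rc = comp_tr[a : a + k][::-1]
        for b in index.get(km_rc, ()):
            c = (a + b + k - 1) % n
            rc_map.setdefault(c, []).append(a)
    for c in rc_map:
        rc_map[c] = sorted(set(rc_map[c]))
    return rc_map


def _longest_circular_run(starts: list[int], n: int) -> tuple[int, int]:
    """Longest run of consecutive integers (mod n); returns (start, run_length)."""
    if not starts:
        return 0, 0
    runs = []
    s0 = prev = starts[0]
    for a in starts[1:]:
        if a == prev + 1:
            prev = a
        else:
            runs.append((s0, prev - s0 + 1))
            s0 = prev = a
    runs.append((s0, prev - s0 + 1))
    # merge a run ending at n-1 with one starting at 0 (circular adjacency)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][0] + runs[-1][1] == n:
        s0, l0 = runs.pop()
        runs[0] = (s0, l0 + runs[0][1])
    return max(runs, key=lambda r: (r[1], -r[0]))


def _pair_at(seq: str, i: int, j: int) -> bool:
    n = len(seq)
    return seq[i % n] == complement(seq[j % n])


def detect_quadripartite(
    genome: GenomeRecord | str,
    min_ir_len: int = 1000,
    max_mismatch_frac: float = 0.01,
    seed_k: int = 25,
) -> QuadripartitePartition:
    """Detect the LSC/IRb/SSC/IRa partition of a circular plastome.

    Returns the maximal pair of disjoint intervals whose sequences are
    reverse complements within ``max_mismatch_frac``; the longer single-copy
    stretch between them is LSC, the shorter SSC.  Raises :class:`NoIRFound`
    when no inverted pair of at least ``min_ir_len`` exists.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    n = len(seq)
    if n < 4 * min_ir_len:
        raise NoIRFound(f"genome of {n} bp is shorter than 4*min_ir_len")

    diag = _seed_antidiagonals(seq, seed_k)
    min_seeds = max(1, (min_ir_len - seed_k + 1) // 8)
    candidates = []
    for c, starts in diag.items():
        if len(starts) < min_seeds:
            continue
        a0, run = _longest_circular_run(starts, n)
        core_len = run + seed_k - 1
        if core_len * 2 > n:  # self-palindromic artifact
            continue
        candidates.append((core_len, c, a0))
    if not candidates:
        raise NoIRFound("no inverted repeat pair found")
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    best = None
    for core_len, c, a0 in candidates[:5]:
        hit = _extend_ir(seq, c, a0, core_len, max_mismatch_frac)
        if hit is None:
            continue
        length, mism, s1, s2 = hit
        if length < min_ir_len:
            continue
        identity = 1.0 - mism / length
        key = (length, identity, -(s1 % n))
        if best is None or key > best[0]:
            best = (key, (length, identity, s1, s2))
    if best is None:
        raise NoIRFound(f"no inverted repeat pair of >= {min_ir_len} bp found")

    length, identity, s1, s2 = best[1]
    s1 %= n
    s2 %= n
    e1 = s1 + length  # copy1 interval (unwrapped)
    e2 = s2 + length
    gap_a = (s2 - e1) % n  # single-copy stretch after copy1
    gap_b = (s1 - e2) % n  # single-copy stretch after copy2
    if gap_a >= gap_b:
        # copy2 follows the longer stretch ... LSC precedes copy2 => copy2 = IRb? no:
        # LSC is the longer gap; IRb is the IR that follows LSC.
        lsc = (e1 % n, e1 % n + gap_a)
        irb = (s2, e2)
        ssc = (e2 % n, e2 % n + gap_b)
        ira = (s1, e1)
    else:
        lsc = (e2 % n, e2 % n + gap_b)
        irb = (s1, e1)
        ssc = (e1 % n, e1 % n + gap_a)
        ira = (s2, e2)
    part = QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n, ir_identity=identity
    )
    assert sum(part.lengths().values()) == n
    return part


def _extend_ir(
    seq: str, c: int, a0: int, core_len: int, max_frac: float
) -> tuple[int, int, int, int] | None:
    """Extend an exact inverted core outward allowing mismatches.

    The core occupies copy1 = [a0, a0+core_len) pairing with
    copy2 = [c - (a0+core_len-1), c - a0 + 1) under base complementarity
    (positions mod n).  Returns (length, mismatches, copy1_start, copy2_start)
    or None for degenerate geometry.
    """
    n = len(seq)
    s1, e1 = a0, a0 + core_len
    s2 = (c - (e1 - 1)) % n
    e2 = s2 + core_len
    if s2 == s1 % n:  # self-pair
        return None
    gap_inner = (s2 - e1) % n
    gap_outer = (s1 - e2) % n
    mism = 0
    length = core_len

    xdrop = 12  # X-drop threshold: match +1, mismatch -3

    def probe(side: str, k: int) -> bool:
        if side == "outer":
            return _pair_at(seq, s1 - 1 - k, e2 + k)
        return _pair_at(seq, e1 + k, s2 - 1 - k)

    def advance(side: str, take: int) -> None:
        nonlocal s1, e1, s2, e2
        if side == "outer":
            s1 -= take
            e2 += take
        else:
            e1 += take
            s2 -= take

    def grow(side: str, budget: int) -> None:
        # X-drop extension: walk outward scoring +1/-3, remember the
        # furthest running-max position whose overall mismatch fraction
        # stays within max_frac, and give up once the score falls xdrop
        # below that max.  Crisp boundaries (a mismatch right outside the
        # repeat) are recovered exactly; interior mismatch clusters are
        # crossed.
        nonlocal mism, length
        score = best_score = 0
        best_k = best_mm = cur_mm = 0
        k = 0
        while k < budget:
            if probe(side, k):
                score += 1
            else:
                score -= 3
                cur_mm += 1
            k += 1
            if score > best_score and (mism + cur_mm) / (length + k) <= max_frac:
                best_score, best_k, best_mm = score, k, cur_mm
            if best_score - score > xdrop:
                break
        advance(side, best_k)
        mism += best_mm
        length += best_k

    # split each gap budget between its two encroaching ends
    grow("inner", gap_inner // 2)
    grow("outer", gap_outer // 2)
    if (s2 - e1) % n == 0 and (s1 - e2) % n == 0:
        return None
    return length, mism, s1 % n, s2 % n


def region_gc_profile(
    genome: GenomeRecord | str, partition: QuadripartitePartition
) -> dict[str, float]:
    """GC percentage per region.  Warns (does not fail) if SSC < LSC < IR
    ordering is violated, which on real plastomes indicates a suspect
    partition."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    doubled = seq + seq
    out = {}
    for name, (s, e) in partition.as_dict().items():
        out[name] = gc_percent(doubled[s % len(seq) : s % len(seq) + (e - s)])
    if not (out["SSC"] < out["LSC"] < max(out["IRa"], out["IRb"]) + 1e-12):
        log.warning("unusual GC ordering: %s", out)
    return out


@dataclass(frozen=True)
class JunctionEntry:
    position: int
    gene: str
    distance: int  # junction - gene end; negative when the gene spans it
    spanning: bool


@dataclass(frozen=True)
class JunctionReport:
    entries: dict[str, JunctionEntry]


def junction_table(genome: GenomeRecord, partition: QuadripartitePartition) -> JunctionReport:
    """For each of the four junctions, the spanning gene or the nearest gene
    with the signed distance from its end to the junction."""
    n = len(genome.sequence)
    genes = genome.genes()
    entries = {}
    for jname, jpos in partition.junctions().items():
        best = None
        for g in genes:
            s, e = g.span
            spans = s <= jpos < e or s <= jpos + n < e
            if spans:
                dist = _signed_circ(jpos, e % n, n)
                best = (0, abs(dist), JunctionEntry(jpos, g.name, dist, True))
                break
            dist = _signed_circ(jpos, e % n, n)
            cand = (1, abs(dist), JunctionEntry(jpos, g.name, dist, False))
            if best is None or cand[:2] < best[:2]:
                best = cand
        entries[jname] = (
            best[2] if best else JunctionEntry(jpos, "", 0, False)
        )
    return JunctionReport(entries=entries)


def _signed_circ(a: int, b: int, n: int) -> int:
    """Signed circular difference a - b in (-n/2, n/2]."""
    d = (a - b) % n
    if d > n // 2:
        d -= n
    return d
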