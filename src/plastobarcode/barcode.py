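"""Per-locus K2P divergence, barcode resolution, and concatenation search.

The Kimura two-parameter distance separates transitions from transversions:
with P and Q the transition and transversion proportions over compared
sites, ``d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` substitutions per site.

"Resolution" of a locus set over a panel of accessions is the percentage of
accessions carrying a unique haplotype there (every printed resolution
value in intraspecific plastome barcoding studies on 34-accession panels is
a multiple of 100/34, which pins this per-accession reading).  Because a
single plastid locus rarely resolves conspecific varieties, locus sets are
searched: exhaustively for small sizes and by beam search above that.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genome_io import Locus

log = logging.getLogger(__name__)


class NoComparableSites(ValueError):
    """All aligned sites carry a gap or N in at least one sequence."""


@dataclass(frozen=True)
class PairwiseDivergence:
    n_sites: int
    s: int  # transitions
    v: int  # transversions
    P: float
    Q: float
    d: float  # nan when the K2P logs are undefined (saturation)
    defined: bool


def k2p_distance(seq1: str, seq2: str) -> PairwiseDivergence:
    """K2P divergence of two aligned sequences.

    Sites with a gap or N in either sequence are excluded; an undefined
    distance (1-2P-Q <= 0 or 1-2Q <= 0) is flagged, not capped.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    n = s = v = 0
    for a, b in zip(seq1, seq2):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a != b:
            if (a in "AG") == (b in "AG"):
                s += 1
            else:
                v += 1
    if n == 0:
        raise NoComparableSites("no ungapped, unambiguous sites to compare")
    P, Q = s / n, v / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return PairwiseDivergence(n, s, v, P, Q, float("nan"), False)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDivergence(n, s, v, P, Q, d, True)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    undefined: np.ndarray  # boolean mask of flagged entries

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.nanmax(np.abs(v - v.T), initial=0) > 1e-12:
            raise ValueError("matrix not symmetric")


_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 255, dtype=np.uint8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def k2p_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    """All pairwise K2P distances over an alignment (vectorised)."""
    labels = list(aligned)
    rows = [_encode(aligned[l]) for l in labels]
    m = len(labels)
    values = np.zeros((m, m))
    undef = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            x, y = rows[i], rows[j]
            valid = (x < 4) & (y < 4)
            n = int(valid.sum())
            if n == 0:
                undef[i, j] = undef[j, i] = True
                continue
            diff = valid & (x != y)
            s = int((diff & ((x >> 1) == (y >> 1))).sum())
            v = int(diff.sum()) - s
            P, Q = s / n, v / n
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                undef[i, j] = undef[j, i] = True
                values[i, j] = values[j, i] = np.nan
            else:
                d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
                values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, undefined=undef)


def align_locus(locus: Locus) -> dict[str, str]:
    """Equal-length alignment of one locus across accessions.

    Equal-length inputs pass through untouched (conspecific loci mostly
    differ by substitutions only); otherwise each sequence is globally
    aligned to the longest one and insertion columns are merged.
    """
    seqs = locus.sequences
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return dict(seqs)
    ref_acc = max(sorted(seqs), key=lambda a: len(seqs[a]))
    ref = seqs[ref_acc]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1

    n = len(ref)
    per_seq: dict[str, tuple[list[str], list[str]]] = {}
    ins_len = [0] * (n + 1)
    for acc, seq in seqs.items():
        if acc == ref_acc:
            base = list(ref)
            ins = [""] * (n + 1)
        else:
            aln = aligner.align(ref, seq)[0]
            base = ["-"] * n
            ins = [""] * (n + 1)
            r_prev = q_prev = 0
            for (rs, re_), (qs, qe) in zip(*aln.aligned):
                ins[rs] += seq[q_prev:qs]
                for t in range(rs - r_prev):
                    pass  # deleted reference bases stay '-'
                for t in range(re_ - rs):
                    base[rs + t] = seq[qs + t]
                r_prev, q_prev = re_, qe
            ins[n] += seq[q_prev:]
        per_seq[acc] = (base, ins)
        for p in range(n + 1):
            ins_len[p] = max(ins_len[p], len(per_seq[acc][1][p]))

    out = {}
    for acc, (base, ins) in per_seq.items():
        parts = []
        for p in range(n):
            parts.append(ins[p].ljust(ins_len[p], "-"))
            parts.append(base[p])
        parts.append(ins[n].ljust(ins_len[n], "-"))
        out[acc] = "".join(parts)
    return out


def locus_distance_matrix(locus: Locus) -> DistanceMatrix:
    """Pairwise K2P matrix on the locus alignment."""
    if len(locus.sequences) < 2:
        raise ValueError("need at least two sequences")
    return k2p_matrix(align_locus(locus))


@dataclass(frozen=True)
class ResolutionResult:
    locus_names: tuple[str, ...]
    n_accessions: int
    resolved_ids: frozenset[str]
    resolution_pct: float
    concatenated_length: int

    @property
    def kinds_key(self) -> str:
        return "_".join(self.locus_names)


def _resolved_from_haplotypes(haps: dict[str, str]) -> frozenset[str]:
    groups: dict[str, list[str]] = {}
    for acc, h in haps.items():
        groups.setdefault(h, []).append(acc)
    return frozenset(accs[0] for accs in groups.values() if len(accs) == 1)


def resolution_score(
    matrix: DistanceMatrix, locus_names: tuple[str, ...] = (), concatenated_length: int = 0
) -> ResolutionResult:
    """Fraction of accessions whose distance to every other accession is
    positive (unique haplotype).  Undefined (saturated) entries count as
    positive divergence."""
    m = len(matrix.labels)
    resolved = set()
    for i, label in enumerate(matrix.labels):
        row = np.delete(matrix.values[i], i)
        mask = np.delete(matrix.undefined[i], i)
        if np.all(mask | (row > 0)):
            resolved.add(label)
    return ResolutionResult(
        locus_names=tuple(locus_names),
        n_accessions=m,
        resolved_ids=frozenset(resolved),
        resolution_pct=100.0 * len(resolved) / m,
        concatenated_length=concatenated_length,
    )


def resolution_from_locus(locus: Locus) -> ResolutionResult:
    """Resolution by exact haplotype equality on the locus alignment (robust
    to K2P saturation masking; indel differences count as divergence)."""
    haps = align_locus(locus)
    resolved = _resolved_from_haplotypes(haps)
    length = len(next(iter(haps.values())))
    return ResolutionResult(
        locus_names=(locus.name,),
        n_accessions=len(haps),
        resolved_ids=resolved,
        resolution_pct=100.0 * len(resolved) / len(haps),
        concatenated_length=length,
    )


def concatenate_loci(loci: list[Locus]) -> Locus:
    """Accession-wise concatenation of per-locus alignments, in order."""
    if not loci:
        raise ValueError("no loci to concatenate")
    accs = set(loci[0].sequences)
    for loc in loci[1:]:
        if set(loc.sequences) != accs:
            missing = accs.symmetric_difference(loc.sequences)
            raise ValueError(f"accession sets differ across loci: {sorted(missing)}")
    aligned = [align_locus(loc) for loc in loci]
    return Locus(
        name="_".join(loc.name for loc in loci),
        kind="concat",
        sequences={acc: "".join(a[acc] for a in aligned) for acc in sorted(accs)},
    )


@dataclass
class SearchReport:
    results: list[ResolutionResult]
    pair_counts: dict[str, int] = field(default_factory=dict)
    evaluated: int = 0

    @property
    def best(self) -> ResolutionResult:
        return self.results[0]


def _rank_key(r: ResolutionResult):
    return (-r.resolution_pct, len(r.locus_names), r.concatenated_length, r.locus_names)


def search_concatenations(
    loci: list[Locus],
    k_max: int = 5,
    strategy: str = "beam",
    beam_width: int = 50,
    budget: int = 20000,
) -> SearchReport:
    """Search locus concatenations maximising barcode resolution.

    Enumeration is exhaustive for every set size k with C(n, k) <= budget
    (always for k <= 2); larger sizes are explored by beam search over
    single-locus additions.  Results are ranked by resolution, then fewer
    loci, then shorter concatenation, then name.
    """
    if len(loci) < 2:
        raise ValueError("need at least two candidate loci")
    if strategy not in ("exhaustive", "beam"):
        raise ValueError(f"unknown strategy {strategy!r}")
    aligned = {loc.name: align_locus(loc) for loc in loci}
    lengths = {name: len(next(iter(a.values()))) for name, a in aligned.items()}
    kinds = {loc.name: loc.kind for loc in loci}
    names = sorted(aligned)
    accs = sorted(next(iter(aligned.values())))

    results: dict[frozenset[str], ResolutionResult] = {}
    pair_counts = {"gene_gene": 0, "gene_intergene": 0, "intergene_intergene": 0}

    def evaluate(combo: tuple[str, ...]) -> ResolutionResult:
        key = frozenset(combo)
        if key in results:
            return results[key]
        combo = tuple(sorted(combo))
        haps = {acc: "".join(aligned[nm][acc] for nm in combo) for acc in accs}
        resolved = _resolved_from_haplotypes(haps)
        res = ResolutionResult(
            locus_names=combo,
            n_accessions=len(accs),
            resolved_ids=resolved,
            resolution_pct=100.0 * len(resolved) / len(accs),
            concatenated_length=sum(lengths[nm] for nm in combo),
        )
        results[key] = res
        if len(combo) == 2:
            ks = sorted(kinds[nm] for nm in combo)
            cat = "_".join(ks)
            if cat in pair_counts:
                pair_counts[cat] += 1
        return res

    for nm in names:
        evaluate((nm,))

    n = len(names)
    for k in range(2, k_max + 1):
        if k <= 2 or math.comb(n, k) <= budget:
            for combo in itertools.combinations(names, k):
                evaluate(combo)
        elif strategy == "exhaustive":
            log.warning("C(%d,%d) exceeds budget %d; stopping exhaustive search", n, k, budget)
            break
        else:  # beam
            prev = sorted(
                (r for r in results.values() if len(r.locus_names) == k - 1),
                key=_rank_key,
            )[:beam_width]
            for r in prev:
                for nm in names:
                    if nm not in r.locus_names:
                        evaluate(tuple(sorted(r.locus_names + (nm,))))

    ranked = sorted(results.values(), key=_rank_key)
    return SearchReport(results=ranked, pair_counts=pair_counts, evaluated=len(results))
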