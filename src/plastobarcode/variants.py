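"""Pairwise plastome comparison: rotation normalisation, anchored alignment,
SNP/indel calling and per-genome summaries.

Conspecific plastomes deposited in public databases frequently differ by the
chosen origin (rotation) and occasionally by strand.  ``normalize_rotation``
fixes both using shared unique k-mers; ``align_to_reference`` then chains
unique 21-mer anchors by longest collinear subsequence and closes the
inter-anchor gaps with global alignment, from which variants are called:
each mismatch column is a SNP (classified transition/transversion), each
maximal gap run is one indel event, left-normalised in homopolymer runs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import is_transition, revcomp, rotate
from .genome_io import FeatureAnnotation, GenomeRecord, replace_features
from .structure import QuadripartitePartition

log = logging.getLogger(__name__)


class UnrelatedSequence(ValueError):
    """Too few shared k-mers for the two genomes to be comparable."""


class ChainFailure(ValueError):
    """Anchor chaining covered too little of the reference."""


@dataclass(frozen=True)
class Variant:
    kind: str  # SNP | insertion | deletion
    ref_pos: int  # 0-based on the reference
    ref_allele: str
    alt_allele: str
    change_class: str  # transition | transversion | indel
    region: str = ""
    locus_context: str = "-"


@dataclass
class AlignmentChain:
    """Anchor blocks plus the stitched full alignment of query to reference."""

    blocks: list[tuple[int, int, int]]  # (ref_start, query_start, length)
    ref_aligned: str
    query_aligned: str
    coverage: float
    ref_id: str = ""
    query_id: str = ""


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _circular_unique_kmers(seq: str, k: int) -> dict[str, int]:
    ext = seq + seq[: k - 1]
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq)):
        km = ext[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _modal_offset(ref_k: dict[str, int], qry_k: dict[str, int], n: int) -> tuple[int, int]:
    """(offset, support): the modal (ref_pos - query_pos) mod n, refined to
    the offset of the shared anchor nearest the reference origin so the
    circular seam aligns exactly even when indels shift downstream anchors."""
    pairs = []
    offsets = Counter()
    for km, qpos in qry_k.items():
        rpos = ref_k.get(km)
        if rpos is not None:
            off = (rpos - qpos) % n
            pairs.append((rpos, off))
            offsets[off] += 1
    if not offsets:
        return 0, 0
    modal, cnt = max(offsets.items(), key=lambda kv: (kv[1], -kv[0]))
    near = [
        (rpos, off)
        for rpos, off in pairs
        if min((off - modal) % n, (modal - off) % n) <= 2000
    ]
    off = min(near)[1] if near else modal
    return off, cnt


def normalize_rotation(
    query: GenomeRecord, reference: GenomeRecord, k: int = 21, min_shared: float = 0.10
) -> GenomeRecord:
    """Rotate (and strand-flip if needed) the query onto the reference frame.

    The rotation offset maximising shared unique k-mer collinearity wins;
    raises :class:`UnrelatedSequence` when fewer than ``min_shared`` of the
    unique k-mers are shared in either orientation.
    """
    n = len(query.sequence)
    ref_k = _circular_unique_kmers(reference.sequence, k)
    qry_k = _circular_unique_kmers(query.sequence, k)
    off_f, cnt_f = _modal_offset(ref_k, qry_k, n)
    flipped_seq = revcomp(query.sequence)
    qry_k_rc = _circular_unique_kmers(flipped_seq, k)
    off_r, cnt_r = _modal_offset(ref_k, qry_k_rc, n)

    denom = max(1, min(len(ref_k), len(qry_k)))
    if max(cnt_f, cnt_r) / denom < min_shared:
        raise UnrelatedSequence(
            f"{query.accession_id}: only {max(cnt_f, cnt_r)} shared unique {k}-mers"
        )
    flip = cnt_r > cnt_f
    delta = off_r if flip else off_f
    # shared k-mers satisfy ref_pos = qry_pos + delta, so position -delta
    # of the (possibly flipped) query must move to position 0
    shift = (-delta) % n
    seq = flipped_seq if flip else query.sequence
    new_seq = rotate(seq, shift)
    feats = [_transform_feature(f, n, flip, shift) for f in query.features]
    out = replace_features(
        GenomeRecord(
            accession_id=query.accession_id,
            label=query.label,
            group=query.group,
            sequence=new_seq,
            circular=query.circular,
        ),
        feats,
    )
    return out


def _transform_feature(f: FeatureAnnotation, n: int, flip: bool, shift: int) -> FeatureAnnotation:
    strand = f.strand
    out = []
    for s0, e0 in f.intervals:
        length = e0 - s0
        if flip:
            s0 = n - e0
        s1 = (s0 - shift) % n
        if s1 + length <= n:
            out.append((s1, s1 + length))
        else:  # wraps the origin: split
            out.append((s1, n))
            out.append((0, s1 + length - n))
    if flip:
        strand = "-" if f.strand == "+" else "+"
    return FeatureAnnotation(
        name=f.name, kind=f.kind, strand=strand, intervals=tuple(sorted(out)), copy_tag=f.copy_tag
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5  # opening base: -4 open plus -1 extend
    aligner.extend_gap_score = -1
    return aligner


def _align_gap(aligner: Align.PairwiseAligner, ref_gap: str, qry_gap: str) -> tuple[str, str]:
    if not ref_gap and not qry_gap:
        return "", ""
    if not ref_gap:
        return "-" * len(qry_gap), qry_gap
    if not qry_gap:
        return ref_gap, "-" * len(ref_gap)
    aln = aligner.align(ref_gap, qry_gap)[0]
    # rebuild the gapped strings from the aligned coordinate pairs
    r_out, q_out = [], []
    r_prev = q_prev = 0
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        r_out.append(ref_gap[r_prev:rs])
        q_out.append("-" * (rs - r_prev))
        r_out.append("-" * (qs - q_prev))
        q_out.append(qry_gap[q_prev:qs])
        r_out.append(ref_gap[rs:re_])
        q_out.append(qry_gap[qs:qe])
        r_prev, q_prev = re_, qe
    r_out.append(ref_gap[r_prev:])
    q_out.append("-" * (len(ref_gap) - r_prev))
    r_out.append("-" * (len(qry_gap) - q_prev))
    q_out.append(qry_gap[q_prev:])
    return "".join(r_out), "".join(q_out)


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing (in query) subsequence of anchors sorted by ref."""
    if not anchors:
        return []
    anchors.sort()
    import bisect

    tails: list[int] = []  # query positions
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, (_, q) in enumerate(anchors):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    return chain[::-1]


def align_to_reference(
    query: GenomeRecord,
    reference: GenomeRecord,
    k: int = 21,
    band: int = 5000,
) -> AlignmentChain:
    """Anchor-chain alignment of a rotation-normalised query to the reference."""
    ref_seq, qry_seq = reference.sequence, query.sequence
    ref_k = _unique_kmers(ref_seq, k)
    qry_k = _unique_kmers(qry_seq, k)
    anchors = [(rpos, qry_k[km]) for km, rpos in ref_k.items() if km in qry_k]
    if not anchors:
        raise ChainFailure("no shared unique k-mer anchors")
    chain = _lis_chain(anchors)

    # merge same-diagonal consecutive anchors into blocks, trimming overlaps
    blocks: list[list[int]] = []  # [ref_start, qry_start, length]
    for r, q in chain:
        if blocks:
            br, bq, bl = blocks[-1]
            if r - q == br - bq and r <= br + bl:
                blocks[-1][2] = max(bl, r + k - br)
                continue
            overlap = max(br + bl - r, bq + bl - q, 0)
            r2, q2 = r + overlap, q + overlap
            if r2 + 1 > r + k:
                continue
            blocks.append([r2, q2, k - overlap])
        else:
            blocks.append([r, q, k])

    aligner = _make_aligner()
    r_parts: list[str] = []
    q_parts: list[str] = []
    unaligned_ref = 0
    prev_r = prev_q = 0
    for br, bq, bl in blocks:
        ref_gap = ref_seq[prev_r:br]
        qry_gap = qry_seq[prev_q:bq]
        if max(len(ref_gap), len(qry_gap)) <= band:
            ra, qa = _align_gap(aligner, ref_gap, qry_gap)
            r_parts.append(ra)
            q_parts.append(qa)
        else:
            unaligned_ref += len(ref_gap)
        r_parts.append(ref_seq[br : br + bl])
        q_parts.append(qry_seq[bq : bq + bl])
        prev_r, prev_q = br + bl, bq + bl
    ref_tail = ref_seq[prev_r:]
    qry_tail = qry_seq[prev_q:]
    if max(len(ref_tail), len(qry_tail)) <= band:
        ra, qa = _align_gap(aligner, ref_tail, qry_tail)
        r_parts.append(ra)
        q_parts.append(qa)
    else:
        unaligned_ref += len(ref_tail)

    coverage = 1.0 - unaligned_ref / max(1, len(ref_seq))
    if coverage < 0.5:
        raise ChainFailure(f"chain coverage {coverage:.2f} < 0.5")
    return AlignmentChain(
        blocks=[tuple(b) for b in blocks],
        ref_aligned="".join(r_parts),
        query_aligned="".join(q_parts),
        coverage=coverage,
        ref_id=reference.accession_id,
        query_id=query.accession_id,
    )


def _left_normalize(pos: int, allele: str, ref_seq: str) -> tuple[int, str]:
    """Shift an indel event to its leftmost equivalent position."""
    while pos > 0 and allele and ref_seq[pos - 1] == allele[-1]:
        allele = ref_seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def call_variants(
    chain: AlignmentChain,
    partition: QuadripartitePartition | None = None,
    reference: GenomeRecord | None = None,
    min_intergene_len: int = 10,
) -> list[Variant]:
    """SNPs and one-event-per-gap-run indels from a stitched alignment."""
    ra, qa = chain.ref_aligned, chain.query_aligned
    assert len(ra) == len(qa)
    ref_seq = ra.replace("-", "")
    variants: list[Variant] = []
    rpos = 0
    i = 0
    L = len(ra)
    while i < L:
        rc, qc = ra[i], qa[i]
        if rc != "-" and qc != "-":
            if rc != qc and rc != "N" and qc != "N":
                variants.append(
                    Variant(
                        kind="SNP",
                        ref_pos=rpos,
                        ref_allele=rc,
                        alt_allele=qc,
                        change_class="transition" if is_transition(rc, qc) else "transversion",
                    )
                )
            rpos += 1
            i += 1
        elif qc == "-":  # deletion run in query
            j = i
            while j < L and qa[j] == "-" and ra[j] != "-":
                j += 1
            allele = ra[i:j]
            pos, allele = _left_normalize(rpos, allele, ref_seq)
            variants.append(
                Variant(kind="deletion", ref_pos=pos, ref_allele=allele, alt_allele="",
                        change_class="indel")
            )
            rpos += j - i
            i = j
        else:  # insertion run relative to the reference
            j = i
            while j < L and ra[j] == "-" and qa[j] != "-":
                j += 1
            allele = qa[i:j]
            pos, allele = _left_normalize(rpos, allele, ref_seq)
            variants.append(
                Variant(kind="insertion", ref_pos=pos, ref_allele="", alt_allele=allele,
                        change_class="indel")
            )
            i = j
    if partition is not None or reference is not None:
        variants = [
            _annotate(v, partition, reference, min_intergene_len) for v in variants
        ]
    return variants


def _annotate(
    v: Variant,
    partition: QuadripartitePartition | None,
    reference: GenomeRecord | None,
    min_intergene_len: int,
) -> Variant:
    region = partition.region_of(v.ref_pos) if partition is not None else ""
    locus = "-"
    if reference is not None:
        genes = sorted(reference.genes(), key=lambda f: f.span)
        n = len(reference.sequence)
        for idx, g in enumerate(genes):
            s, e = g.span
            if s <= v.ref_pos < e or s <= v.ref_pos + n < e:
                locus = g.name
                break
        else:
            for idx, g in enumerate(genes):
                h = genes[(idx + 1) % len(genes)]
                g_end = g.span[1]
                h_start = h.span[0] + (n if idx == len(genes) - 1 else 0)
                if g_end <= v.ref_pos < h_start or g_end <= v.ref_pos + n < h_start:
                    if h_start - g_end >= min_intergene_len:
                        locus = f"{g.name}-{h.name}"
                    break
    return Variant(
        kind=v.kind,
        ref_pos=v.ref_pos,
        ref_allele=v.ref_allele,
        alt_allele=v.alt_allele,
        change_class=v.change_class,
        region=region,
        locus_context=locus,
    )


def variant_summary(variants_by_genome: dict[str, list[Variant]]) -> pd.DataFrame:
    """Per-genome counts and proportions by class and region."""
    rows = []
    for label, variants in variants_by_genome.items():
        n_snp = sum(v.kind == "SNP" for v in variants)
        n_ts = sum(v.change_class == "transition" for v in variants)
        n_tv = sum(v.change_class == "transversion" for v in variants)
        row = {
            "genome": label,
            "n_snp": n_snp,
            "n_transition": n_ts,
            "n_transversion": n_tv,
            "pct_transition": 100.0 * n_ts / n_snp if n_snp else np.nan,
            "pct_transversion": 100.0 * n_tv / n_snp if n_snp else np.nan,
            "n_insertion": sum(v.kind == "insertion" for v in variants),
            "n_deletion": sum(v.kind == "deletion" for v in variants),
            "n_indel": sum(v.change_class == "indel" for v in variants),
        }
        for region in ("LSC", "IRb", "SSC", "IRa"):
            row[f"n_{region}"] = sum(v.region == region for v in variants)
        rows.append(row)
    return pd.DataFrame(rows)
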