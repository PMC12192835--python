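"""Plastome record I/O and locus extraction.

Reads and writes annotated chloroplast genomes (GenBank flat files / FASTA)
and extracts named gene and intergenic loci consistently across accessions.
Internally all coordinates are 0-based half-open on the forward strand; a
feature that wraps the origin of a circular molecule is represented by an
interval pair ``[(start, n), (0, end)]``.  Conversion from GenBank's 1-based
inclusive locations happens only at the I/O boundary (via Biopython).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

log = logging.getLogger(__name__)

GROUPS = ("vini", "syl", "cau", "lab", "outgroup", "synthetic")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")

# The literature writes tRNA symbols both with and without the anticodon
# hyphen ("trnMCAU" vs "trnM-CAU"); one canonical spelling is enforced.
_TRN_RE = re.compile(r"^(trn[A-Za-z]{1,3})-?([ACGTU]{3})$")


class CoordinateError(ValueError):
    """A feature location falls outside the sequence."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature on a plastome.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    pairs in ascending genomic order; minus-strand features are
    reverse-complemented as a whole on extraction.  ``copy_tag`` marks the
    IR copy a duplicated feature lives in (assigned once a quadripartite
    partition is known).
    """

    name: str
    kind: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    copy_tag: str = "single"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"feature {self.name!r}: empty interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        """(start of first interval, unwrapped end of last interval)."""
        s0 = self.intervals[0][0]
        e1 = self.intervals[-1][1]
        if len(self.intervals) > 1 and e1 <= s0:
            # wraps the origin: report the unwrapped end
            e1 += max(e for _, e in self.intervals[:-1])
        return s0, e1

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class GenomeRecord:
    """One circular annotated plastome with a variety/group label."""

    accession_id: str
    label: str
    group: str
    sequence: str
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < n and 0 < e <= n):
                    raise CoordinateError(
                        f"feature {f.name!r} interval ({s}, {e}) outside [0, {n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: FeatureAnnotation) -> str:
        parts = "".join(self.sequence[s:e] for s, e in feat.intervals)
        return revcomp(parts) if feat.strand == "-" else parts

    def slice_circular(self, start: int, end: int) -> str:
        """Sequence of [start, end) where end may exceed the length (wrap)."""
        n = len(self.sequence)
        length = end - start
        if length < 0:
            raise ValueError("end before start")
        if length > n:
            raise ValueError("slice longer than the genome")
        start %= n
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def genes(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "gene"]


@dataclass
class Locus:
    """One named gene or intergene with per-accession sequences."""

    name: str
    kind: str  # "gene" | "intergene"
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for acc, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"locus {self.name!r}: empty sequence for {acc}")


def normalize_gene_name(raw: str) -> str:
    """Normalize a gene symbol: strip qualifiers, unify tRNA hyphenation."""
    name = raw.strip()
    if name.lower().startswith("gene="):
        name = name[5:]
    m = _TRN_RE.match(name)
    if m:
        name = f"{m.group(1)}-{m.group(2)}"
    return name


def infer_group(label: str) -> str:
    for g in ("vini", "syl", "cau", "lab"):
        if label.lower().endswith(g):
            return g
    return "synthetic"


def _location_to_intervals(loc) -> tuple[tuple[tuple[int, int], ...], str]:
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    intervals = sorted((int(p.start), int(p.end)) for p in parts)
    return tuple(intervals), strand


def read_genbank(path: str | Path, group: str | None = None) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    GenBank 1-based inclusive coordinates become 0-based half-open;
    ``join()``/``complement()`` locations map to interval lists plus strand.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: record has no usable ORIGIN sequence")
    features = []
    for f in rec.features:
        if f.type not in FEATURE_KINDS:
            continue
        quals = f.qualifiers
        raw = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
        intervals, strand = _location_to_intervals(f.location)
        for s, e in intervals:
            if e > len(seq):
                raise CoordinateError(
                    f"{path}: feature {raw!r} extends to {e} beyond length {len(seq)}"
                )
        features.append(
            FeatureAnnotation(
                name=normalize_gene_name(raw),
                kind=f.type,
                strand=strand,
                intervals=intervals,
            )
        )
    label = rec.name or rec.id
    circular = rec.annotations.get("topology", "circular") == "circular"
    return GenomeRecord(
        accession_id=rec.id or rec.name,
        label=label,
        group=group or infer_group(label),
        sequence=seq,
        circular=circular,
        features=features,
    )


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a :class:`GenomeRecord` back to a GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession_id,
        name=genome.label[:16] or genome.accession_id[:16],
        description=f"{genome.label} synthetic plastome" if genome.group == "synthetic" else genome.label,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(
            SeqFeature(location, type=f.kind, qualifiers={"gene": [f.name]})
        )
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path, group: str | None = None) -> GenomeRecord:
    rec = SeqIO.read(str(path), "fasta")
    label = rec.id
    return GenomeRecord(
        accession_id=rec.id,
        label=label,
        group=group or infer_group(label),
        sequence=str(rec.seq).upper(),
    )


def extract_gene_loci(genome: GenomeRecord) -> list[tuple[str, str]]:
    """One ``(name, sequence)`` per gene feature.

    Minus-strand genes are reverse-complemented; multi-interval genes are
    concatenated in exon order; IR-duplicated genes are emitted once per
    copy, disambiguated by their copy tag.
    """
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for f in sorted(genome.genes(), key=lambda f: f.span):
        name = f.name
        if f.copy_tag != "single":
            name = f"{name}@{f.copy_tag}"
        if name in seen:  # duplicate without informative copy tag
            seen[name] += 1
            name = f"{name}#{seen[name]}"
        else:
            seen[name] = 1
        out.append((name, genome.feature_sequence(f)))
    return out


def extract_intergenic_loci(
    genome: GenomeRecord, min_intergene_len: int = 10
) -> list[tuple[str, str]]:
    """Gap sequences between consecutive genes, named ``"upstream-downstream"``.

    Genes are ordered by start around the circle; a gap shorter than
    ``min_intergene_len`` (or overlapping/abutting genes) yields no locus.
    On circular genomes the wrap-around gap between the last and first gene
    is emitted once.
    """
    genes = sorted(genome.genes(), key=lambda f: f.span)
    if len(genes) < 2:
        return []
    n = len(genome.sequence)
    out = []
    for i, g in enumerate(genes):
        h = genes[(i + 1) % len(genes)]
        g_end = g.span[1]
        h_start = h.span[0]
        if i == len(genes) - 1:
            if not genome.circular:
                break
            h_start += n
        gap = h_start - g_end
        if gap < min_intergene_len:
            continue
        seq = genome.slice_circular(g_end % n, (g_end % n) + gap)
        out.append((f"{g.name}-{h.name}", seq))
    return out


def build_locus_table(
    genomes: Sequence[GenomeRecord],
    min_intergene_len: int = 10,
    exclude: Iterable[str] = ("rps12",),
) -> list[Locus]:
    """Loci whose name occurs in every genome, with per-accession sequences.

    IR-duplicated genes are counted once (the untagged/IRb copy preferred);
    trans-spliced ``rps12`` is excluded by default to avoid chimeric loci.
    Non-universal locus names are reported via the module logger.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    excluded = set(exclude)
    per_genome: list[dict[str, tuple[str, str]]] = []
    for g in genomes:
        table: dict[str, tuple[str, str]] = {}
        for name, seq in extract_gene_loci(g):
            base = name.split("@")[0].split("#")[0]
            if base in excluded or not seq:
                continue
            # prefer the first (lowest-coordinate / single-copy) occurrence
            if base not in table:
                table[base] = ("gene", seq)
        for name, seq in extract_intergenic_loci(g, min_intergene_len):
            key = name
            if key not in table and seq:
                table[key] = ("intergene", seq)
        per_genome.append(table)

    shared = set(per_genome[0])
    union = set(per_genome[0])
    for t in per_genome[1:]:
        shared &= set(t)
        union |= set(t)
    dropped = sorted(union - shared)
    if dropped:
        log.info("dropped %d non-universal loci: %s", len(dropped), ", ".join(dropped))
    if not shared:
        raise ValueError("no locus is shared by all genomes")

    loci = []
    for name in sorted(shared):
        kind = per_genome[0][name][0]
        loci.append(
            Locus(
                name=name,
                kind=kind,
                sequences={g.accession_id: t[name][1] for g, t in zip(genomes, per_genome)},
            )
        )
    return loci


def assign_copy_tags(genome: GenomeRecord, irb: tuple[int, int], ira: tuple[int, int]) -> GenomeRecord:
    """Tag features fully inside an IR copy with that copy's tag."""

    def inside(f: FeatureAnnotation, iv: tuple[int, int]) -> bool:
        s, e = f.span
        lo, hi = iv
        n = len(genome.sequence)
        if hi <= lo:
            hi += n
        if s < lo:
            s, e = s + n, e + n
        return lo <= s and e <= hi

    feats = []
    for f in genome.features:
        if inside(f, irb):
            feats.append(replace(f, copy_tag="IRb"))
        elif inside(f, ira):
            feats.append(replace(f, copy_tag="IRa"))
        else:
            feats.append(f)
    return replace_features(genome, feats)


def replace_features(genome: GenomeRecord, features: list[FeatureAnnotation]) -> GenomeRecord:
    return GenomeRecord(
        accession_id=genome.accession_id,
        label=genome.label,
        group=genome.group,
        sequence=genome.sequence,
        circular=genome.circular,
        features=features,
    )
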