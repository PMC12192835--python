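"""Ground-truthed synthetic plastome datasets.

The generator emulates the observables of a conspecific grapevine-style
plastome panel: a circular quadripartite genome (LSC/IRb/SSC/IRa with IRa
the exact reverse complement of IRb), annotated genes including
IR-duplicated and junction-spanning ones, planted SSRs and long repeats,
and a population of accessions differing from the reference by
transition-biased SNPs, small indels, shared group-level haplotypes at
diagnostic loci, and start-coordinate rotations (two accessions get large
displaced starts, as real deposits sometimes do).

Every planted event is recorded in a :class:`GroundTruth` and re-verified
against the emitted sequences at generation time, so downstream detectors
can be tested against exact expectations.  Default sizes (40 kb genome,
5 kb IRs) keep test runs fast; ``paper_scale()`` yields a 160,928 bp
configuration matching real *V. vinifera* plastome dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import complement, revcomp, rotate
from .genome_io import FeatureAnnotation, GenomeRecord, write_genbank
from .repeats import canonical_motif
from .structure import QuadripartitePartition
from .variants import Variant, _left_normalize, _transform_feature

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_NAMES = [
    "rbcL", "matK", "ndhD", "rpl16", "rpoC2", "trnM-CAU", "ccsA", "trnN-GUU",
    "rpoB", "rpoC1", "atpA", "atpB", "atpE", "atpF", "psaA", "psaB", "psbB",
    "psbC", "psbD", "petA", "petB", "petD", "rps2", "rps3", "rps4", "rps8",
    "rps11", "rps14", "rpl14", "rpl20", "rpl33", "ndhA", "ndhE", "ndhG",
    "ndhH", "ccsA2", "cemA", "clpP", "accD", "ycf3", "ycf4", "rpl36",
]
IR_GENE_NAMES = ["rpl2", "rpl23"]
JUNCTION_GENES = {"psbA": "IRa/LSC", "rps19": "LSC/IRb", "ndhF": "IRb/SSC", "ycf1": "SSC/IRa"}

GROUP_CYCLE = ("vini", "syl", "cau", "lab")

STOPS = ("TAA", "TGA", "TAG")
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genome_length: int = 40_000
    ir_length: int = 5_000
    ssc_frac: float = 0.12
    n_genes: int = 30
    n_groups: int = 4
    accessions_per_group: int = 3
    snp_rate: float = 0.4  # events/kb vs reference, per accession
    indel_rate: float = 0.2  # events/kb
    ts_tv_ratio: float = 2.0
    planted_ssrs: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", 12), ("AT", 6), ("AAT", 5), ("AAAT", 4), ("AAAAG", 3)]
    )
    planted_long_repeats: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("F", 30, 0), ("P", 26, 2), ("R", 24, 0)]
    )
    rotations: dict[str, int] | None = None  # accession label -> offset; None = defaults
    diagnostic_loci: tuple[str, ...] = ("rpl16", "rpoC2", "trnM-CAU")

    def __post_init__(self) -> None:
        if self.snp_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        ssc_len = int(self.genome_length * self.ssc_frac)
        lsc_len = self.genome_length - 2 * self.ir_length - ssc_len
        if lsc_len <= ssc_len or ssc_len <= 0:
            raise ValueError("infeasible spec: regions do not fit the genome length")


def paper_scale(seed: int = 0, **kw) -> SyntheticSpec:
    """A 160,928 bp configuration with real-plastome region proportions."""
    return SyntheticSpec(
        seed=seed, genome_length=160_928, ir_length=26_353, ssc_frac=0.1186,
        n_genes=80, **kw,
    )


@dataclass
class PlantedSSR:
    start: int
    motif: str
    count: int

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def end(self) -> int:
        return self.start + self.period * self.count

    @property
    def canonical_class(self) -> str:
        return canonical_motif(self.motif)


@dataclass
class PlantedRepeat:
    type: str
    length: int
    pos1: int
    pos2: int
    mismatches: int


@dataclass
class GroundTruth:
    partition: QuadripartitePartition
    ssrs: list[PlantedSSR] = field(default_factory=list)
    long_repeats: list[PlantedRepeat] = field(default_factory=list)
    variants: dict[str, list[Variant]] = field(default_factory=dict)
    rotations: dict[str, int] = field(default_factory=dict)
    locus_haplotypes: dict[str, dict[str, str]] = field(default_factory=dict)
    gene_sequences: dict[str, str] = field(default_factory=dict)
    cds_codons_drawn: int = 0


def _rng(spec_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, stage])


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + ``n_codons`` uniform sense codons + a uniform stop codon."""
    body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))
    return "ATG" + body + str(rng.choice(STOPS))


def generate_reference(spec: SyntheticSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Build the annotated reference plastome and its ground truth."""
    n = spec.genome_length
    ir = spec.ir_length
    ssc_len = int(n * spec.ssc_frac)
    lsc_len = n - 2 * ir - ssc_len
    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + ir)
    ssc = (lsc_len + ir, lsc_len + ir + ssc_len)
    ira = (n - ir, n)

    rng = _rng(spec.seed, 1)
    arr = rng.choice(BASES, size=n)
    features: list[FeatureAnnotation] = []
    truth = GroundTruth(
        partition=QuadripartitePartition(
            lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n, ir_identity=1.0
        )
    )

    def write_seq(pos: int, seq: str) -> None:
        arr[pos : pos + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    def plant_gene(name: str, start: int, length: int, region_tag: str = "single") -> None:
        length -= length % 3
        n_codons = max(1, length // 3 - 2)
        cds = random_cds(rng, n_codons)
        truth.cds_codons_drawn += n_codons
        write_seq(start, cds)
        iv = ((start, start + len(cds)),)
        features.append(FeatureAnnotation(name, "gene", "+", iv, copy_tag=region_tag))
        features.append(FeatureAnnotation(name, "CDS", "+", iv, copy_tag=region_tag))

    gaps: list[tuple[int, int]] = []

    def tile(region: tuple[int, int], names: list[str], margin: int, tag: str = "single") -> None:
        pos = region[0] + margin
        hi = region[1] - margin
        for name in names:
            length = int(rng.integers(100, 500)) * 3
            gap = int(rng.integers(60, 250))
            if pos + length + gap > hi:
                break
            plant_gene(name, pos, length, tag)
            if tag == "single":  # IR gaps are mirrored; never plant there
                gaps.append((pos + length, pos + length + gap))
            pos += length + gap
        if pos < hi and tag == "single":
            gaps.append((pos, hi))

    # junction-flanking genes, as in real plastomes
    plant_gene("psbA", 30, 501)
    plant_gene("rps19", lsc[1] - 120, 210)  # spans LSC/IRb
    plant_gene("ndhF", ssc[0] + 40, 750)  # just inside SSC
    plant_gene("ycf1", ira[0] - 900, 1200)  # spans SSC/IRa

    n_main = max(4, spec.n_genes - 4 - len(IR_GENE_NAMES))
    n_ssc = max(2, n_main // 6)
    pool = list(GENE_NAMES)
    tile((600, lsc[1] - 400), pool[: n_main - n_ssc], margin=0)
    tile((ssc[0] + 900, ira[0] - 1100), pool[n_main - n_ssc : n_main], margin=0)
    tile((irb[0] + 300, irb[1] - 300), IR_GENE_NAMES, margin=0, tag="IRb")

    # planted SSRs and long repeats carve space out of intergenic gaps,
    # widest first; the unused remainder of a gap stays claimable
    def claim(width: int) -> int:
        gaps.sort(key=lambda g: g[0] - g[1])
        for t, (s, e) in enumerate(gaps):
            if e - s >= width + 4:
                gaps[t] = (s + width + 4, e)
                return s + 2
        raise ValueError("not enough intergenic space for planted repeats")

    for motif, count in spec.planted_ssrs:
        start = claim(len(motif) * count)
        run = motif * count
        breaker = next(b for b in "CGTA" if b not in motif)
        write_seq(start - 1, breaker)
        write_seq(start, run)
        write_seq(start + len(run), breaker)
        truth.ssrs.append(PlantedSSR(start=start, motif=motif, count=count))

    for rtype, length, mism in spec.planted_long_repeats:
        p1 = claim(length)
        p2 = claim(length)
        copy1 = "".join(chr(b) for b in rng.choice(BASES, size=length))
        if rtype == "F":
            copy2 = copy1
        elif rtype == "R":
            copy2 = copy1[::-1]
        elif rtype == "C":
            copy2 = complement(copy1)
        else:
            copy2 = revcomp(copy1)
        c2 = list(copy2)
        # mismatches stay interior so the planted pair is match-bounded
        for t in rng.choice(np.arange(2, length - 2), size=mism, replace=False):
            c2[t] = next(b for b in "ACGT" if b != c2[t])
        write_seq(p1, copy1)
        write_seq(p2, "".join(c2))
        truth.long_repeats.append(PlantedRepeat(rtype, length, p1, p2, mism))

    # enforce IRa = revcomp(IRb) after all planting
    irb_seq = arr[irb[0] : irb[1]].tobytes().decode()
    write_seq(ira[0], revcomp(irb_seq))

    # break complementarity just outside the IR pair so the planted
    # boundaries are the maximal ones (outer pairing: IRb start-1 with the
    # first base after IRa, i.e. position 0; inner: IRb end with IRa start-1)
    if chr(arr[irb[0] - 1]) == complement(chr(arr[0])):
        arr[0] = ord(next(b for b in "ACGT" if b != chr(arr[0]) and b != complement(chr(arr[irb[0] - 1])) ))
    if chr(arr[irb[1]]) == complement(chr(arr[ira[0] - 1])):
        arr[irb[1]] = ord(next(b for b in "ACGT" if b != chr(arr[irb[1]]) and complement(b) != chr(arr[ira[0] - 1])))

    # mirror IRb gene annotations into IRa (minus strand)
    mirrored = []
    for f in [f for f in features if f.copy_tag == "IRb"]:
        s, e = f.intervals[0]
        ms = ira[0] + (irb[1] - e)
        me = ira[0] + (irb[1] - s)
        mirrored.append(
            FeatureAnnotation(f.name, f.kind, "-", ((ms, me),), copy_tag="IRa")
        )
    features.extend(mirrored)

    sequence = arr.tobytes().decode()
    genome = GenomeRecord(
        accession_id="SYNREF",
        label="SYN-1_vini",
        group="vini",
        sequence=sequence,
        circular=True,
        features=sorted(features, key=lambda f: f.span),
    )
    for name, seq in _gene_map(genome).items():
        truth.gene_sequences[name] = seq
    _verify_reference(genome, truth)
    return genome, truth


def _gene_map(genome: GenomeRecord) -> dict[str, str]:
    out = {}
    for f in genome.genes():
        if f.copy_tag != "IRa" and f.name not in out:
            out[f.name] = genome.feature_sequence(f)
    return out


def _verify_reference(genome: GenomeRecord, truth: GroundTruth) -> None:
    seq = genome.sequence
    p = truth.partition
    irb = seq[p.irb[0] : p.irb[1]]
    ira = seq[p.ira[0] % len(seq) : p.ira[0] % len(seq) + (p.ira[1] - p.ira[0])]
    if revcomp(irb) != ira:
        raise AssertionError("IR pair broken during composition")
    for ssr in truth.ssrs:
        run = seq[ssr.start : ssr.end]
        if run != ssr.motif * ssr.count:
            raise AssertionError(f"planted SSR at {ssr.start} was overwritten")
    for rep in truth.long_repeats:
        c1 = seq[rep.pos1 : rep.pos1 + rep.length]
        c2 = seq[rep.pos2 : rep.pos2 + rep.length]
        want = {"F": c1, "R": c1[::-1], "C": complement(c1), "P": revcomp(c1)}[rep.type]
        mm = sum(a != b for a, b in zip(want, c2))
        if mm != rep.mismatches:
            raise AssertionError(f"planted {rep.type} repeat at {rep.pos1} has {mm} mismatches")


def _sample_positions(
    rng: np.random.Generator,
    k: int,
    windows: list[tuple[int, int]],
    taken: list[tuple[int, int]],
    spacing: int,
) -> list[int]:
    spans = [e - s for s, e in windows]
    total = sum(spans)
    out: list[int] = []
    tries = 0
    while len(out) < k and tries < 200 * k + 200:
        tries += 1
        r = int(rng.integers(0, total))
        for (s, e), w in zip(windows, spans):
            if r < w:
                pos = s + r
                break
            r -= w
        if all(pos + spacing <= a or pos >= b + spacing for a, b in taken):
            taken.append((pos, pos + 1))
            out.append(pos)
    if len(out) < k:
        raise ValueError("could not place all events with the requested spacing")
    return out


def generate_population(
    reference: GenomeRecord, truth: GroundTruth, spec: SyntheticSpec
) -> list[GenomeRecord]:
    """Derive the accession panel from the reference.

    The reference itself is the first accession of the first group (offset
    0, no variants); every other accession gets group-diagnostic SNPs at
    the configured loci, private SNPs/indels at the configured per-kb
    rates, and its rotation offset.  All events are recorded in ``truth``
    on the reference coordinate frame.
    """
    n = len(reference.sequence)
    rng = _rng(spec.seed, 2)
    p = truth.partition

    # windows where variants may be planted: single-copy, clear of planted
    # repeat tracts and feature boundaries
    protected: list[tuple[int, int]] = []
    for ssr in truth.ssrs:
        protected.append((ssr.start - 20, ssr.end + 20))
    for rep in truth.long_repeats:
        protected.append((rep.pos1 - 20, rep.pos1 + rep.length + 20))
        protected.append((rep.pos2 - 20, rep.pos2 + rep.length + 20))
    boundaries = []
    for f in reference.features:
        s, e = f.span
        boundaries.extend([(s - 25, s + 25), (e - 25, e + 25)])

    def windows_clear() -> list[tuple[int, int]]:
        bad = sorted(protected + boundaries)
        wins = []
        for lo, hi in (p.lsc, p.ssc):
            cur = lo + 30
            for bs, be in bad:
                if be <= cur or bs >= hi - 30:
                    continue
                if bs > cur:
                    wins.append((cur, bs))
                cur = max(cur, be)
            if cur < hi - 30:
                wins.append((cur, hi - 30))
        return wins

    wins = windows_clear()

    groups = [GROUP_CYCLE[i % len(GROUP_CYCLE)] for i in range(spec.n_groups)]
    # group-diagnostic SNPs: one per diagnostic locus per (non-first) group
    gene_by_name = {f.name: f for f in reference.genes() if f.copy_tag != "IRa"}
    diag_snps: dict[str, list[tuple[int, str, str]]] = {g: [] for g in groups}
    for gidx, g in enumerate(groups):
        if gidx == 0:
            continue
        for locus in spec.diagnostic_loci:
            feat = gene_by_name.get(locus)
            if feat is None:
                continue
            s, e = feat.span
            pos = s + 30 + ((gidx * 37) % max(1, (e - s - 60)))
            ref_b = reference.sequence[pos]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_b]
            diag_snps[g].append((pos, ref_b, alt))

    records: list[GenomeRecord] = []
    default_rot: dict[str, int] = {}
    labels: list[str] = []
    for gidx, g in enumerate(groups):
        for a in range(spec.accessions_per_group):
            labels.append(f"SYN{gidx + 1}-{a + 1}_{g}")
    if spec.rotations is None:
        # two displaced starts, emulating accessions deposited off-origin
        default_rot = {labels[min(4, len(labels) - 1)]: int(0.29 * n)}
        if len(labels) > 1:
            default_rot[labels[-1]] = int(0.45 * n)
        rotations = default_rot
    else:
        rotations = spec.rotations

    idx = 0
    for gidx, g in enumerate(groups):
        for a in range(spec.accessions_per_group):
            label = labels[idx]
            idx += 1
            acc_id = label.split("_")[0]
            if gidx == 0 and a == 0:
                rec = GenomeRecord(
                    accession_id=acc_id, label=label, group=g,
                    sequence=reference.sequence, circular=True,
                    features=list(reference.features),
                )
                truth.variants[label] = []
                truth.rotations[label] = 0
                records.append(rec)
                continue

            taken = [(pos, pos + 1) for pos, _, _ in diag_snps[g]]
            sc_len = (p.lsc[1] - p.lsc[0]) + (p.ssc[1] - p.ssc[0])
            n_snp = rng.poisson(spec.snp_rate * sc_len / 1000)
            n_indel = rng.poisson(spec.indel_rate * sc_len / 1000)
            snp_pos = _sample_positions(rng, n_snp, wins, taken, spacing=10)
            indel_pos = _sample_positions(rng, n_indel, wins, taken, spacing=60)

            events: list[Variant] = []
            for pos, ref_b, alt in diag_snps[g]:
                events.append(Variant("SNP", pos, ref_b, alt, "transition"))
            for pos in snp_pos:
                ref_b = reference.sequence[pos]
                if rng.random() < spec.ts_tv_ratio / (spec.ts_tv_ratio + 1):
                    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_b]
                    cls = "transition"
                else:
                    choices = [b for b in "ACGT" if b != ref_b and
                               ((b in "AG") != (ref_b in "AG"))]
                    alt = choices[int(rng.integers(0, len(choices)))]
                    cls = "transversion"
                events.append(Variant("SNP", pos, ref_b, alt, cls))
            for pos in indel_pos:
                length = int(rng.integers(1, 8))
                if rng.random() < 0.5:
                    allele = reference.sequence[pos : pos + length]
                    npos, allele = _left_normalize(pos, allele, reference.sequence)
                    events.append(Variant("deletion", npos, allele, "", "indel"))
                else:
                    allele = "".join(chr(b) for b in rng.choice(BASES, size=length))
                    npos, allele = _left_normalize(pos, allele, reference.sequence)
                    events.append(Variant("insertion", npos, "", allele, "indel"))
            events.sort(key=lambda v: v.ref_pos)

            seq, feats = _apply_events(reference, events)
            off = rotations.get(label, 0)
            if off:
                seq = rotate(seq, off)
                feats = [_transform_feature(f, len(seq), False, off) for f in feats]
            rec = GenomeRecord(
                accession_id=acc_id, label=label, group=g,
                sequence=seq, circular=True, features=feats,
            )
            truth.variants[label] = events
            truth.rotations[label] = rotations.get(label, 0)
            records.append(rec)

    for locus in spec.diagnostic_loci:
        truth.locus_haplotypes[locus] = {}
        for rec in records:
            feat = next((f for f in rec.genes() if f.name == locus and f.copy_tag != "IRa"), None)
            if feat is not None:
                truth.locus_haplotypes[locus][rec.label] = rec.feature_sequence(feat)
    return records


def _apply_events(
    reference: GenomeRecord, events: list[Variant]
) -> tuple[str, list[FeatureAnnotation]]:
    """Apply SNPs and indels (reference coordinates) and shift annotations."""
    seq = list(reference.sequence)
    indels = [v for v in events if v.kind != "SNP"]
    for v in events:
        if v.kind == "SNP":
            assert seq[v.ref_pos] == v.ref_allele
            seq[v.ref_pos] = v.alt_allele
    for v in sorted(indels, key=lambda v: -v.ref_pos):
        if v.kind == "deletion":
            del seq[v.ref_pos : v.ref_pos + len(v.ref_allele)]
        else:
            seq[v.ref_pos:v.ref_pos] = list(v.alt_allele)
    new_seq = "".join(seq)

    def shift(b: int) -> int:
        off = 0
        for v in indels:
            if v.kind == "insertion" and v.ref_pos <= b:
                off += len(v.alt_allele)
            elif v.kind == "deletion" and v.ref_pos + len(v.ref_allele) <= b:
                off -= len(v.ref_allele)
        return b + off

    feats = []
    for f in reference.features:
        ivs = tuple((shift(s), shift(e)) for s, e in f.intervals)
        feats.append(FeatureAnnotation(f.name, f.kind, f.strand, ivs, f.copy_tag))
    return new_seq, feats


def generate_dataset(spec: SyntheticSpec) -> tuple[list[GenomeRecord], GroundTruth]:
    """Reference + derived accessions in one call."""
    reference, truth = generate_reference(spec)
    records = generate_population(reference, truth, spec)
    return records, truth


def export_fixture(records: list[GenomeRecord], truth: GroundTruth, out_dir: str | Path) -> None:
    """Write GenBank + FASTA per accession and ground-truth TSVs."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_genbank(rec, out / "genomes" / f"{rec.label}.gb")
        with open(out / "genomes" / f"{rec.label}.fasta", "w") as fh:
            fh.write(f">{rec.label}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    with open(out / "truth" / "variants.tsv", "w") as fh:
        fh.write("accession\tkind\tref_pos\tref_allele\talt_allele\tchange_class\n")
        for label in sorted(truth.variants):
            for v in truth.variants[label]:
                fh.write(f"{label}\t{v.kind}\t{v.ref_pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.change_class}\n")
    with open(out / "truth" / "ssrs.tsv", "w") as fh:
        fh.write("start\tmotif\tcount\tcanonical_class\n")
        for s in truth.ssrs:
            fh.write(f"{s.start}\t{s.motif}\t{s.count}\t{s.canonical_class}\n")
    with open(out / "truth" / "long_repeats.tsv", "w") as fh:
        fh.write("type\tlength\tpos1\tpos2\tmismatches\n")
        for r in truth.long_repeats:
            fh.write(f"{r.type}\t{r.length}\t{r.pos1}\t{r.pos2}\t{r.mismatches}\n")
    with open(out / "truth" / "partition.tsv", "w") as fh:
        fh.write("region\tstart\tend\n")
        for name, (s, e) in truth.partition.as_dict().items():
            fh.write(f"{name}\t{s}\t{e}\n")
    with open(out / "truth" / "rotations.tsv", "w") as fh:
        fh.write("accession\toffset\n")
        for label in sorted(truth.rotations):
            fh.write(f"{label}\t{truth.rotations[label]}\n")
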