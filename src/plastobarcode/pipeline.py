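"""End-to-end orchestration: extract -> structure -> rscu -> repeats ->
variants -> barcode -> tree, with plain-text stage outputs and a manifest.

Every output file starts with a comment header naming the config hash and
seed, and all stage outputs are TSV/FASTA/Newick so any stage can be
re-run or audited in isolation.  A genome that fails a stage is
quarantined (recorded in the manifest) rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import barcode, codon_usage, phylo, repeats, structure, variants
from .genome_io import GenomeRecord, build_locus_table, read_fasta, read_genbank

log = logging.getLogger(__name__)

STAGES = ("extract", "structure", "rscu", "repeats", "variants", "barcode", "tree")


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    reference_id: str | None = None
    min_intergene_len: int = 10
    min_ir_len: int = 1000
    max_ir_mismatch_frac: float = 0.01
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(repeats.DEFAULT_SSR_THRESHOLDS)
    )
    long_repeat_min_len: int = 20
    long_repeat_max_mismatch: int = 3
    k_max: int = 5
    strategy: str = "beam"
    beam_width: int = 50
    bootstrap_replicates: int = 200
    seed: int = 42

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"# plastobarcode run config={config.digest()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def load_genomes(input_dir: str | Path) -> tuple[list[GenomeRecord], dict[str, str]]:
    """All parseable .gb/.gbk/.fasta/.fa genomes in a directory; failures
    are returned as a name -> error map."""
    genomes: list[GenomeRecord] = []
    failures: dict[str, str] = {}
    seen: set[str] = set()
    paths = sorted(Path(input_dir).iterdir(),
                   key=lambda p: (p.suffix not in (".gb", ".gbk", ".genbank"), p.name))
    for path in paths:
        try:
            if path.suffix in (".gb", ".gbk", ".genbank"):
                rec = read_genbank(path)
            elif path.suffix in (".fa", ".fasta"):
                rec = read_fasta(path)
            else:
                continue
            if rec.label in seen:
                continue
            seen.add(rec.label)
            genomes.append(rec)
        except Exception as exc:
            failures[path.name] = str(exc)
    return genomes, failures


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, failures = load_genomes(config.input_dir)
    if not genomes:
        raise ValueError(f"no parseable genomes in {config.input_dir}: {failures}")
    manifest: dict = {
        "config": config.digest(),
        "seed": config.seed,
        "n_genomes": len(genomes),
        "quarantined": failures,
        "stages": {},
    }
    by_label = {g.label: g for g in genomes}
    reference = by_label.get(config.reference_id or "", genomes[0])

    # --- extract ---------------------------------------------------------
    loci = build_locus_table(genomes, min_intergene_len=config.min_intergene_len)
    inv = pd.DataFrame(
        [
            {"locus": l.name, "kind": l.kind,
             "mean_length": sum(map(len, l.sequences.values())) / len(l.sequences)}
            for l in loci
        ]
    )
    _write_tsv(inv, out / "locus_inventory.tsv", config)
    loci_dir = out / "loci"
    loci_dir.mkdir(exist_ok=True)
    for l in loci:
        with open(loci_dir / f"{l.name.replace('/', '_')}.fasta", "w") as fh:
            for acc in sorted(l.sequences):
                fh.write(f">{acc}\n{l.sequences[acc]}\n")
    manifest["stages"]["extract"] = {"n_loci": len(loci)}

    # --- structure -------------------------------------------------------
    rows, jrows = [], []
    partitions = {}
    for g in genomes:
        try:
            part = structure.detect_quadripartite(
                g, min_ir_len=config.min_ir_len,
                max_mismatch_frac=config.max_ir_mismatch_frac,
            )
        except structure.NoIRFound as exc:
            manifest["quarantined"][g.label] = f"structure: {exc}"
            continue
        partitions[g.label] = part
        gc = structure.region_gc_profile(g, part)
        for region, (s, e) in part.as_dict().items():
            rows.append(
                {"accession": g.label, "region": region, "start": s, "end": e,
                 "length": e - s, "gc_pct": round(gc[region], 4)}
            )
        rows.append(
            {"accession": g.label, "region": "genome", "start": 0,
             "end": len(g.sequence), "length": len(g.sequence),
             "gc_pct": round(structure.gc_content(g.sequence), 4)}
        )
        jt = structure.junction_table(g, part)
        for jname, e in jt.entries.items():
            jrows.append(
                {"accession": g.label, "junction": jname, "position": e.position,
                 "gene": e.gene, "distance": e.distance, "spanning": e.spanning}
            )
    _write_tsv(pd.DataFrame(rows), out / "regions.tsv", config)
    _write_tsv(pd.DataFrame(jrows), out / "junctions.tsv", config)
    manifest["stages"]["structure"] = {"n_partitioned": len(partitions)}

    # --- rscu ------------------------------------------------------------
    rrows = []
    for g in genomes:
        cds = [
            g.feature_sequence(f)
            for f in g.features
            if f.kind == "CDS" and f.copy_tag != "IRa"
        ]
        if not cds:
            continue
        table = codon_usage.compute_rscu(codon_usage.count_codons(cds))
        row = {"accession": g.label, "total_codons": table.total_codons}
        row.update({c: round(table.rscu.get(c, float("nan")), 4) for c in codon_usage.ALL_CODONS})
        rrows.append(row)
    _write_tsv(pd.DataFrame(rrows), out / "rscu.tsv", config)
    manifest["stages"]["rscu"] = {"n_genomes": len(rrows)}

    # --- repeats ---------------------------------------------------------
    srows, lrows, specrows = [], [], []
    for g in genomes:
        for h in repeats.find_ssrs(g.sequence, config.ssr_thresholds, circular=g.circular):
            srows.append(
                {"accession": g.label, "start": h.start, "end": h.end,
                 "period": h.period, "motif": h.motif,
                 "class": h.canonical_class, "count": h.repeat_count}
            )
        hits = repeats.find_long_repeats(
            g.sequence, min_len=config.long_repeat_min_len,
            max_mismatch=config.long_repeat_max_mismatch,
        )
        for h in hits:
            lrows.append(
                {"accession": g.label, "type": h.type, "length": h.length,
                 "pos1": h.pos1, "pos2": h.pos2, "mismatches": h.mismatches}
            )
        spectrum = repeats.repeat_length_spectrum(hits)
        specrows.append({"accession": g.label, **spectrum})
    _write_tsv(pd.DataFrame(srows), out / "ssrs.tsv", config)
    _write_tsv(pd.DataFrame(lrows), out / "long_repeats.tsv", config)
    _write_tsv(pd.DataFrame(specrows), out / "repeat_spectrum.tsv", config)
    manifest["stages"]["repeats"] = {"n_ssrs": len(srows), "n_long": len(lrows)}

    # --- variants --------------------------------------------------------
    vrows = []
    by_genome: dict[str, list[variants.Variant]] = {}
    ref_part = partitions.get(reference.label)
    for g in genomes:
        if g.label == reference.label:
            by_genome[g.label] = []
            continue
        try:
            norm = variants.normalize_rotation(g, reference)
            chain = variants.align_to_reference(norm, reference)
            calls = variants.call_variants(chain, ref_part, reference,
                                           config.min_intergene_len)
        except (variants.UnrelatedSequence, variants.ChainFailure) as exc:
            manifest["quarantined"][g.label] = f"variants: {exc}"
            continue
        by_genome[g.label] = calls
        for v in calls:
            vrows.append(
                {"CHROM": reference.label, "POS": v.ref_pos + 1,
                 "REF": v.ref_allele or "-", "ALT": v.alt_allele or "-",
                 "accession": g.label, "kind": v.kind, "class": v.change_class,
                 "region": v.region, "locus": v.locus_context}
            )
    _write_tsv(pd.DataFrame(vrows), out / "variants.tsv", config)
    _write_tsv(variants.variant_summary(by_genome), out / "variant_summary.tsv", config)
    manifest["stages"]["variants"] = {"n_variants": len(vrows)}

    # --- barcode ---------------------------------------------------------
    perlocus = []
    for l in loci:
        res = barcode.resolution_from_locus(l)
        perlocus.append(
            {"locus": l.name, "kind": l.kind, "n_accessions": res.n_accessions,
             "resolution_pct": round(res.resolution_pct, 2),
             "length": res.concatenated_length}
        )
    _write_tsv(pd.DataFrame(perlocus), out / "locus_resolution.tsv", config)
    report = barcode.search_concatenations(
        loci, k_max=config.k_max, strategy=config.strategy,
        beam_width=config.beam_width,
    )
    comb = pd.DataFrame(
        [
            {"loci": "_".join(r.locus_names), "k": len(r.locus_names),
             "resolution_pct": round(r.resolution_pct, 2),
             "length": r.concatenated_length,
             "resolved": ",".join(sorted(r.resolved_ids))}
            for r in report.results[:200]
        ]
    )
    _write_tsv(comb, out / "combinations.tsv", config)
    manifest["stages"]["barcode"] = {
        "evaluated": report.evaluated,
        "pair_counts": report.pair_counts,
        "best": "_".join(report.best.locus_names),
        "best_resolution_pct": round(report.best.resolution_pct, 2),
    }

    # --- tree ------------------------------------------------------------
    best_loci = [l for l in loci if l.name in report.best.locus_names]
    concat = barcode.concatenate_loci(best_loci)
    aligned = barcode.align_locus(concat)
    tree = phylo.bootstrap_tree(aligned, config.bootstrap_replicates, config.seed)
    tree_path = out / "tree.nwk"
    with open(tree_path, "w") as fh:
        fh.write(_header(config))
    with open(tree_path, "a") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                real_value_format_specifier=".6f"))
    manifest["stages"]["tree"] = {
        "loci": "_".join(report.best.locus_names),
        "replicates": config.bootstrap_replicates,
    }

    manifest["n_analyzed"] = len(genomes)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
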