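"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for codon j of amino acid i with n_i synonymous codons is
``x_ij / ((1/n_i) * sum_j x_ij)``: the observed count divided by the count
expected under uniform synonymous usage.  1 marks unbiased usage; the
conventional Sharp & Li cut-offs (<0.6 very low, >1.6 very high) classify
bias strength.  Stop codons are kept as a three-codon "Ter" degeneracy
group, so termination-codon preferences are reported on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id

log = logging.getLogger(__name__)

ALL_CODONS = tuple("".join(p) for p in product("ACGT", repeat=3))

# plastid genetic code (NCBI translation table 11); degeneracies identical
# to the standard table for RSCU purposes
_TABLE = unambiguous_dna_by_id[11]

CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table.get(c, "Ter") for c in ALL_CODONS}

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}


@dataclass
class CodonUsageTable:
    """Codon counts and (optionally) RSCU values pooled over a CDS set."""

    counts: dict[str, int]
    rscu: dict[str, float] = field(default_factory=dict)
    skipped_triplets: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_sequences: Iterable[str]) -> CodonUsageTable:
    """In-frame triplet counts pooled over all CDS sequences.

    A trailing remainder (length not divisible by 3) is trimmed with a log
    message; triplets containing N or other ambiguity codes are skipped and
    the number of skips recorded.
    """
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for seq in cds_sequences:
        seq = seq.upper()
        rem = len(seq) % 3
        if rem:
            log.debug("CDS length %d not divisible by 3; trimming %d trailing bases", len(seq), rem)
            seq = seq[: len(seq) - rem]
        for i in range(0, len(seq), 3):
            cod = seq[i : i + 3]
            if cod in counts:
                counts[cod] += 1
            else:
                skipped += 1
    if skipped:
        log.debug("skipped %d ambiguous triplets", skipped)
    return CodonUsageTable(counts=counts, skipped_triplets=skipped)


def compute_rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill in RSCU values.  Amino acids with zero total count get no RSCU
    entry (missing, not zero)."""
    rscu: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(table.counts[c] for c in codons)
        if total == 0:
            continue
        expected = total / len(codons)
        for c in codons:
            rscu[c] = table.counts[c] / expected
    table.rscu = rscu
    return table


BIAS_LEVELS = ("very_low", "low", "unbiased", "high", "very_high")


def classify_bias(table: CodonUsageTable) -> dict[str, str]:
    """Sharp & Li bias categories: <0.6 very_low, [0.6,1) low, =1 unbiased,
    (1,1.6] high, >1.6 very_high."""
    if not table.rscu:
        raise ValueError("compute_rscu must be called first")
    out = {}
    for codon, v in table.rscu.items():
        if v < 0.6:
            out[codon] = "very_low"
        elif v < 1.0:
            out[codon] = "low"
        elif v == 1.0:
            out[codon] = "unbiased"
        elif v <= 1.6:
            out[codon] = "high"
        else:
            out[codon] = "very_high"
    return out
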