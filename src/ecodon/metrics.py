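"""Sequence-level scores for characterizing and comparing codon designs.

CAI (codon adaptation index) is the geometric mean of per-codon relative
adaptiveness weights; it equals 1.0 exactly when every codon is its family's
preferred one.  The usage distance measures how far a gene's within-family
codon choices sit from an organism's average usage, as an amino-acid-
composition-weighted total-variation distance in [0, 1].
"""

from __future__ import annotations

import math
from collections import Counter
from typing import List

from .codon_tables import STOP, CodonUsageTable, normalize_dna


def split_codons(dna: str) -> List[str]:
    """Normalize and split an in-frame DNA string into codons."""
    dna = normalize_dna(dna)
    if not dna:
        raise ValueError("empty sequence")
    if len(dna) % 3:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]


def _sense_codons(dna: str, table: CodonUsageTable) -> List[str]:
    """Codons of ``dna`` minus a permitted terminal stop; internal stops error."""
    codons = split_codons(dna)
    code = table.code
    if code.codon_to_aa[codons[-1]] == STOP:
        codons = codons[:-1]
    if not codons:
        raise ValueError("sequence contains only a stop codon")
    for pos, codon in enumerate(codons, start=1):
        if code.codon_to_aa[codon] == STOP:
            raise ValueError(f"internal stop codon {codon} at codon position {pos}")
    return codons


def cai(dna: str, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Single-codon families (Met, Trp) carry weight 1.  A terminal stop codon
    is permitted and excluded from the score; internal stops are errors.
    """
    codons = _sense_codons(dna, table)
    log_sum = sum(math.log(table.weight[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def gc_content(dna: str, positions: str = "all") -> float:
    """Fraction of G/C bases, over all positions or third codon positions."""
    dna = normalize_dna(dna)
    if not dna:
        raise ValueError("empty sequence")
    if positions == "all":
        bases = dna
    elif positions == "third":
        if len(dna) % 3:
            raise ValueError("third-position GC requires in-frame input")
        bases = dna[2::3]
    else:
        raise ValueError(f"positions must be 'all' or 'third', got {positions!r}")
    return sum(b in "GC" for b in bases) / len(bases)


def usage_distance(dna: str, table: CodonUsageTable) -> float:
    """Distance between a gene's codon choices and the table's average usage.

    For each amino acid a used n_a times out of N total, the per-family
    total-variation distance (1/2) * sum_c |observed fraction - table
    frequency| is weighted by n_a / N and summed.  Zero iff every family's
    observed codon fractions match the table exactly.
    """
    codons = _sense_codons(dna, table)
    code = table.code
    by_aa: Counter = Counter(code.codon_to_aa[c] for c in codons)
    codon_counts: Counter = Counter(codons)
    total = len(codons)
    dist = 0.0
    for aa, n_aa in by_aa.items():
        tv = 0.0
        for c in code.families[aa]:
            observed = codon_counts[c] / n_aa
            tv += abs(observed - table.family_frequency[c])
        dist += (n_aa / total) * tv / 2.0
    return dist


def sequence_difference(dna_a: str, dna_b: str) -> float:
    """Per-base Hamming distance between two equal-length sequences."""
    a = normalize_dna(dna_a)
    b = normalize_dna(dna_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x != y for x, y in zip(a, b)) / len(a)
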