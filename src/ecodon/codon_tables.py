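"""Genetic-code handling and codon usage tables.

A codon usage table holds per-codon counts tallied over a set of in-frame
coding sequences from one organism.  From the counts we derive, per
synonymous family (the codons encoding one amino acid):

* ``family_frequency`` f_c = count_c / family total, summing to 1;
* ``weight`` w_c = f_c / max f over the family — the relative adaptiveness
  used by the codon adaptation index (CAI), equal to 1 for the family's
  preferred codon;
* RSCU_c = count_c / (mean count over the family), summing to the family
  degeneracy.

Zero-count codons receive a small positive floor weight so that the
geometric mean underlying CAI stays defined.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

from Bio.Data import CodonTable as _bio_codon_table

STOP = "*"

_BASES = "ACGT"
ALL_CODONS: Tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

DEFAULT_PSEUDO_FLOOR = 0.01


def normalize_dna(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """Mapping of the 64 DNA triplets to amino-acid letters ('*' = stop)."""

    codon_to_aa: Mapping[str, str]
    code_id: int = 1

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 DNA triplets")
        if not self.stop_codons:
            raise ValueError("genetic code must contain at least one stop codon")

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = _bio_codon_table.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = STOP
        return cls(codon_to_aa=mapping, code_id=1)

    @cached_property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    @cached_property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)

    @cached_property
    def amino_acids(self) -> Tuple[str, ...]:
        return tuple(sorted({aa for aa in self.codon_to_aa.values() if aa != STOP}))

    @cached_property
    def families(self) -> Mapping[str, Tuple[str, ...]]:
        """Synonymous family per amino acid, codons in alphabetical order."""
        fams: Dict[str, list] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}

    def family_of(self, codon: str) -> Tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def translate(self, dna: str) -> str:
        """Translate an in-frame DNA string (stops rendered as '*')."""
        dna = normalize_dna(dna)
        if len(dna) % 3:
            raise ValueError("sequence length not divisible by 3")
        return "".join(self.codon_to_aa[dna[i : i + 3]] for i in range(0, len(dna), 3))


STANDARD_CODE = GeneticCode.standard()


@dataclass
class CodonUsageTable:
    """Per-codon counts for one organism with derived frequencies and weights.

    Parameters
    ----------
    counts
        Count per sense codon (missing codons are treated as zero).
    stop_counts
        Count per stop codon, kept separate from the sense statistics; the
        most frequent stop is used as the default appended stop codon.
    pseudo_floor
        Weight assigned to zero-count codons so CAI remains defined.
    """

    organism_label: str = ""
    counts: Dict[str, int] = field(default_factory=dict)
    stop_counts: Dict[str, int] = field(default_factory=dict)
    pseudo_floor: float = DEFAULT_PSEUDO_FLOOR
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def __post_init__(self) -> None:
        if self.pseudo_floor <= 0:
            raise ValueError("pseudo_floor must be positive")
        full = {c: 0 for c in self.code.sense_codons}
        for codon, n in self.counts.items():
            codon = normalize_dna(codon)
            if codon not in full:
                raise ValueError(f"not a sense codon of the genetic code: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for codon {codon}: {n}")
            full[codon] = int(n)
        self.counts = full
        stops = {c: 0 for c in self.code.stop_codons}
        for codon, n in self.stop_counts.items():
            codon = normalize_dna(codon)
            if codon not in stops:
                raise ValueError(f"not a stop codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for stop codon {codon}: {n}")
            stops[codon] = int(n)
        self.stop_counts = stops
        self._derive()

    def _derive(self) -> None:
        freq: Dict[str, float] = {}
        weight: Dict[str, float] = {}
        for aa, family in self.code.families.items():
            total = sum(self.counts[c] for c in family)
            if total == 0:
                for c in family:
                    freq[c] = 0.0
                    weight[c] = self.pseudo_floor
                continue
            fmax = max(self.counts[c] for c in family)
            for c in family:
                freq[c] = self.counts[c] / total
                weight[c] = max(self.counts[c] / fmax, self.pseudo_floor)
        self.family_frequency: Dict[str, float] = freq
        self.weight: Dict[str, float] = weight

    # -- convenience accessors -------------------------------------------

    def family(self, aa: str) -> Tuple[str, ...]:
        return self.code.families[aa]

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in self.family(aa))

    def preferred_stop(self) -> str:
        """Most frequent stop codon; alphabetical tie-break; TAA if no data."""
        best = max(
            sorted(self.stop_counts),
            key=lambda c: (self.stop_counts[c], ),
        )
        if self.stop_counts[best] == 0:
            return "TAA"
        # max() keeps the first of equal keys; sorted input makes that the
        # alphabetically smallest codon.
        return best

    def total_sense_count(self) -> int:
        return sum(self.counts.values())


def _record_name(record: object, index: int) -> str:
    rec_id = getattr(record, "id", None)
    return str(rec_id) if rec_id is not None else f"record {index}"


def _record_seq(record: object) -> str:
    seq = getattr(record, "seq", record)
    return normalize_dna(str(seq))


def build_usage_table(
    cds_records: Iterable[object],
    code: GeneticCode = STANDARD_CODE,
    organism_label: str = "",
    pseudo_floor: float = DEFAULT_PSEUDO_FLOOR,
) -> CodonUsageTable:
    """Tally codon counts over in-frame coding sequences.

    ``cds_records`` may be plain strings or Biopython ``SeqRecord`` objects.
    Codons containing N are skipped; stop codons are counted separately.
    Raises ``ValueError`` for off-frame or non-ACGTN sequences (naming the
    offending record) and for empty input.
    """
    counts = {c: 0 for c in code.sense_codons}
    stop_counts = {c: 0 for c in code.stop_codons}
    n_records = 0
    for i, record in enumerate(cds_records):
        name = _record_name(record, i)
        seq = _record_seq(record)
        if not set(seq) <= set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"invalid characters {bad} in CDS {name}")
        if len(seq) % 3:
            raise ValueError(
                f"CDS {name} has length {len(seq)}, not divisible by 3"
            )
        n_records += 1
        for j in range(0, len(seq), 3):
            codon = seq[j : j + 3]
            if "N" in codon:
                continue
            if codon in counts:
                counts[codon] += 1
            else:
                stop_counts[codon] += 1
    if n_records == 0:
        raise ValueError("no coding sequences supplied")
    return CodonUsageTable(
        organism_label=organism_label,
        counts=counts,
        stop_counts=stop_counts,
        pseudo_floor=pseudo_floor,
        code=code,
    )


def compute_rscu(table: CodonUsageTable) -> Dict[str, float]:
    """Relative synonymous codon usage: count / mean family count.

    Families with zero total count are omitted (RSCU undefined there).
    For families with data, the family sum equals the degeneracy.
    """
    rscu: Dict[str, float] = {}
    for aa, family in table.code.families.items():
        total = sum(table.counts[c] for c in family)
        if total == 0:
            continue
        mean = total / len(family)
        for c in family:
            rscu[c] = table.counts[c] / mean
    return rscu


# -- table I/O -----------------------------------------------------------

_TSV_HEADER = ("codon", "amino_acid", "count")

# kazusa-style entries look like "UUU 17.6( 714298)"
_KAZUSA_ENTRY = re.compile(r"([ACGTU]{3})\s+[0-9.]+\s*\(\s*([0-9]+)\s*\)")


def write_usage_table(table: CodonUsageTable, path: Union[str, Path]) -> None:
    """Write a tab-separated table: codon, amino_acid, count (64 rows)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for codon in ALL_CODONS:
            aa = table.code.codon_to_aa[codon]
            n = table.counts[codon] if aa != STOP else table.stop_counts[codon]
            writer.writerow([codon, aa, n])


def read_usage_table(
    path: Union[str, Path],
    format: str = "tsv",
    code: GeneticCode = STANDARD_CODE,
    organism_label: str = "",
    pseudo_floor: float = DEFAULT_PSEUDO_FLOOR,
) -> CodonUsageTable:
    """Read a usage table from tab-separated or kazusa-style text.

    Missing codons default to count 0.  Duplicate rows, unknown codons and
    negative counts are errors.
    """
    path = Path(path)
    text = path.read_text()
    if format == "tsv":
        raw = _parse_tsv(text)
    elif format in ("kazusa", "kazusa-style-text"):
        raw = _parse_kazusa(text)
    else:
        raise ValueError(f"unknown usage-table format: {format!r}")
    counts: Dict[str, int] = {}
    stop_counts: Dict[str, int] = {}
    for codon, n in raw.items():
        if codon not in code.codon_to_aa:
            raise ValueError(f"unknown codon in table: {codon!r}")
        if n < 0:
            raise ValueError(f"negative count for codon {codon}: {n}")
        if code.codon_to_aa[codon] == STOP:
            stop_counts[codon] = n
        else:
            counts[codon] = n
    return CodonUsageTable(
        organism_label=organism_label or path.stem,
        counts=counts,
        stop_counts=stop_counts,
        pseudo_floor=pseudo_floor,
        code=code,
    )


def _parse_tsv(text: str) -> Dict[str, int]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty usage-table file")
    header = tuple(f.strip().lower() for f in lines[0].split("\t"))
    if header[:3] != _TSV_HEADER:
        raise ValueError(
            "usage table must start with header 'codon\\tamino_acid\\tcount'"
        )
    raw: Dict[str, int] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed usage-table row: {ln!r}")
        codon = normalize_dna(fields[0].strip())
        if codon in raw:
            raise ValueError(f"duplicate codon row: {codon}")
        raw[codon] = int(fields[2])
    return raw


def _parse_kazusa(text: str) -> Dict[str, int]:
    raw: Dict[str, int] = {}
    for match in _KAZUSA_ENTRY.finditer(text):
        codon = normalize_dna(match.group(1))
        if codon in raw:
            raise ValueError(f"duplicate codon entry: {codon}")
        raw[codon] = int(match.group(2))
    if not raw:
        raise ValueError("no codon entries found in kazusa-style text")
    return raw
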