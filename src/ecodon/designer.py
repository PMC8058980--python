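"""Codon-design strategies for heterologous expression.

Two strategies are implemented:

* **HC (high-CAI)** — every amino acid is back-translated to its most-used
  codon in the target organism, giving a design with CAI 1.0.

* **ECO (expression cassette optimization)** — a zoned design.  The second
  codon is chosen to approximate a favourable translational start context
  (Kozak-type consensus); codons 3–10 use rarely-used codons, which tend to
  be AT-rich in high-GC genomes and so weaken mRNA secondary structure
  around the start codon; codons 11–45 and the last 50 codons are high-CAI;
  the remaining middle region is filled so its codon usage matches the
  organism's average usage, either by exact largest-remainder quotas or by
  seeded sampling.

All tie-breaks are alphabetical by codon so designs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import metrics
from .codon_tables import CodonUsageTable


class Zone(str, Enum):
    START = "START"
    CONSENSUS = "CONSENSUS"
    DESTABILIZED = "DESTABILIZED"
    HEAD_HC = "HEAD_HC"
    MIDDLE = "MIDDLE"
    TAIL_HC = "TAIL_HC"


@dataclass(frozen=True)
class ZoneConfig:
    """Zone layout for the ECO strategy; codon positions are 1-based inclusive.

    Attributes
    ----------
    destabilized_span
        Positions given rarely-used codons to weaken 5' mRNA structure.
    head_hc_span
        Early high-CAI stretch following the destabilized window.
    tail_hc_length
        Number of terminal codons forced to high-CAI (stop codon excluded).
    consensus_pattern
        Nucleotide preference for the codon-2 triplet; '*' positions are
        unscored.  The default rewards a G immediately after ATG.
    middle_mode
        "quota" for deterministic largest-remainder apportionment or
        "stochastic" for seeded sampling from the table frequencies.
    """

    destabilized_span: Tuple[int, int] = (3, 10)
    head_hc_span: Tuple[int, int] = (11, 45)
    tail_hc_length: int = 50
    consensus_pattern: str = "G**"
    middle_mode: str = "quota"

    def __post_init__(self) -> None:
        d0, d1 = self.destabilized_span
        h0, h1 = self.head_hc_span
        if not (2 < d0 <= d1):
            raise ValueError("destabilized span must start after codon 2")
        if not (d1 < h0 <= h1):
            raise ValueError("head high-CAI span must start after the destabilized span")
        if self.tail_hc_length < 0:
            raise ValueError("tail_hc_length must be >= 0")
        if len(self.consensus_pattern) != 3 or not set(self.consensus_pattern) <= set("ACGT*"):
            raise ValueError("consensus_pattern must be 3 characters over ACGT*")
        if self.middle_mode not in ("quota", "stochastic"):
            raise ValueError("middle_mode must be 'quota' or 'stochastic'")


DEFAULT_ZONE_CONFIG = ZoneConfig()


def zone_map(protein_length: int, cfg: ZoneConfig = DEFAULT_ZONE_CONFIG) -> List[Zone]:
    """Assign a design zone to every codon position 1..L.

    Overlaps on short proteins are resolved by precedence
    START > CONSENSUS > DESTABILIZED > TAIL_HC > HEAD_HC > MIDDLE:
    the 5' rules are the most mechanistic so they win, and the tail rule is
    unconditional so it beats the head span.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    L = protein_length
    zones = [Zone.MIDDLE] * L
    # paint in increasing precedence so later zones overwrite earlier ones
    h0, h1 = cfg.head_hc_span
    for pos in range(h0, min(h1, L) + 1):
        zones[pos - 1] = Zone.HEAD_HC
    for pos in range(max(1, L - cfg.tail_hc_length + 1), L + 1):
        if cfg.tail_hc_length:
            zones[pos - 1] = Zone.TAIL_HC
    d0, d1 = cfg.destabilized_span
    for pos in range(d0, min(d1, L) + 1):
        zones[pos - 1] = Zone.DESTABILIZED
    if L >= 2:
        zones[1] = Zone.CONSENSUS
    zones[0] = Zone.START
    return zones


# -- per-position codon choices ------------------------------------------


def _family_with_counts(aa: str, table: CodonUsageTable) -> Sequence[str]:
    try:
        family = table.family(aa)
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None
    if all(table.counts[c] == 0 for c in family):
        raise ValueError(
            f"no usage counts for amino acid {aa}; supply a richer codon table"
        )
    return family


def pick_hc_codon(aa: str, table: CodonUsageTable) -> str:
    """Most-used codon for ``aa``; alphabetical tie-break."""
    family = _family_with_counts(aa, table)
    return max(sorted(family), key=lambda c: table.counts[c])


def pick_destabilized_codon(aa: str, table: CodonUsageTable, rule: str = "min_count") -> str:
    """Rarely-used codon for ``aa``.

    ``rule="min_count"`` (default) picks the least-used codon with a nonzero
    count, so the choice is still a codon the organism actually uses.
    ``rule="min_gc"`` instead minimizes the codon's G+C content (closest to
    the structure-weakening rationale), breaking ties by lower count.
    """
    family = _family_with_counts(aa, table)
    nonzero = [c for c in family if table.counts[c] > 0]
    if rule == "min_count":
        return min(sorted(nonzero), key=lambda c: table.counts[c])
    if rule == "min_gc":
        return min(sorted(nonzero), key=lambda c: (sum(b in "GC" for b in c), table.counts[c]))
    raise ValueError(f"unknown destabilized rule: {rule!r}")


def pick_start_context_codon(aa: str, table: CodonUsageTable, consensus_pattern: str = "G**") -> str:
    """Family codon best matching the start-context consensus.

    Each non-'*' pattern position that matches scores one point; ties are
    broken by higher usage count, then alphabetically.
    """
    family = _family_with_counts(aa, table)

    def score(codon: str) -> int:
        return sum(
            1
            for base, want in zip(codon, consensus_pattern)
            if want != "*" and base == want
        )

    return max(sorted(family), key=lambda c: (score(c), table.counts[c]))


def largest_remainder_quota(n: int, family: Sequence[str], table: CodonUsageTable) -> Dict[str, int]:
    """Apportion ``n`` slots among family codons proportionally to frequency.

    Integer parts are assigned first; leftover slots go to the largest
    fractional remainders, ties broken alphabetically.
    """
    freqs = {c: table.family_frequency[c] for c in family}
    shares = {c: n * f for c, f in freqs.items()}
    quota = {c: int(shares[c]) for c in family}
    leftover = n - sum(quota.values())
    by_remainder = sorted(family, key=lambda c: (-(shares[c] - quota[c]), c))
    for c in by_remainder[:leftover]:
        quota[c] += 1
    return quota


def match_average_usage(
    aa_segment: str,
    table: CodonUsageTable,
    mode: str = "quota",
    seed: Optional[int] = None,
) -> List[str]:
    """Back-translate a segment so codon usage matches the table's average.

    In quota mode each amino acid's occurrences receive codons in exact
    largest-remainder proportion, interleaved by cycling the codons in
    descending-quota order.  In stochastic mode each occurrence samples a
    codon with probability equal to the table frequency; a fixed seed gives
    identical output.
    """
    if not aa_segment:
        raise ValueError("empty amino-acid segment")
    if mode == "quota":
        return _match_usage_quota(aa_segment, table)
    if mode == "stochastic":
        return _match_usage_stochastic(aa_segment, table, seed)
    raise ValueError(f"unknown middle mode: {mode!r}")


def _match_usage_quota(aa_segment: str, table: CodonUsageTable) -> List[str]:
    counts: Dict[str, int] = {}
    for aa in aa_segment:
        counts[aa] = counts.get(aa, 0) + 1
    # per-aa cyclic codon streams in descending-quota order
    streams: Dict[str, List[str]] = {}
    for aa, n in counts.items():
        family = _family_with_counts(aa, table)
        quota = largest_remainder_quota(n, family, table)
        order = sorted(family, key=lambda c: (-quota[c], c))
        remaining = dict(quota)
        stream: List[str] = []
        while len(stream) < n:
            for c in order:
                if remaining[c] > 0:
                    stream.append(c)
                    remaining[c] -= 1
        streams[aa] = stream
    cursors = {aa: 0 for aa in counts}
    out: List[str] = []
    for aa in aa_segment:
        out.append(streams[aa][cursors[aa]])
        cursors[aa] += 1
    return out


def _match_usage_stochastic(
    aa_segment: str, table: CodonUsageTable, seed: Optional[int]
) -> List[str]:
    rng = np.random.default_rng(seed)
    out: List[str] = []
    for aa in aa_segment:
        family = _family_with_counts(aa, table)
        probs = np.array([table.family_frequency[c] for c in family])
        probs = probs / probs.sum()
        out.append(family[rng.choice(len(family), p=probs)])
    return out


# -- full designs ---------------------------------------------------------


@dataclass
class DesignResult:
    """A back-translated design with its zone labels and summary metrics."""

    protein: str
    dna: str
    codons: List[str]
    zones: List[Zone]
    strategy: str
    seed: Optional[int] = None
    stop_codon: Optional[str] = None
    metrics: Dict[str, float] = field(default_factory=dict)

    @property
    def coding_dna(self) -> str:
        """The design without the appended stop codon."""
        return "".join(self.codons)

    def report_dict(self) -> dict:
        zone_spans: Dict[str, List[int]] = {}
        for pos, zone in enumerate(self.zones, start=1):
            zone_spans.setdefault(zone.value, []).append(pos)
        spans = {
            z: [positions[0], positions[-1]] for z, positions in zone_spans.items()
        }
        return {
            "strategy": self.strategy,
            "seed": self.seed,
            "length_aa": len(self.protein),
            "stop_codon": self.stop_codon,
            "zone_spans": spans,
            "metrics": self.metrics,
        }

    def codon_rows(self, table: CodonUsageTable) -> List[Tuple[int, str, str, str, float]]:
        """Per-codon report rows: position, amino acid, codon, zone, weight."""
        return [
            (i + 1, self.protein[i], self.codons[i], self.zones[i].value, table.weight[self.codons[i]])
            for i in range(len(self.codons))
        ]


_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _validate_protein(protein: str, require_start_met: bool) -> str:
    protein = protein.strip().upper().rstrip("*")
    if not protein:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein, start=1):
        if aa not in _STANDARD_AA:
            raise ValueError(f"non-standard amino acid {aa!r} at position {i}")
    if require_start_met and protein[0] != "M":
        raise ValueError("protein does not start with Met (pass require_start_met=False to permit)")
    return protein


def _finish(
    protein: str,
    codons: List[str],
    zones: List[Zone],
    strategy: str,
    table: CodonUsageTable,
    seed: Optional[int],
    append_stop: bool,
) -> DesignResult:
    stop = table.preferred_stop() if append_stop else None
    dna = "".join(codons) + (stop or "")
    coding = "".join(codons)
    result = DesignResult(
        protein=protein,
        dna=dna,
        codons=codons,
        zones=zones,
        strategy=strategy,
        seed=seed,
        stop_codon=stop,
        metrics={
            "cai": metrics.cai(coding, table),
            "gc": metrics.gc_content(coding),
            "gc3": metrics.gc_content(coding, positions="third"),
            "usage_distance": metrics.usage_distance(coding, table),
        },
    )
    assert table.code.translate(coding) == protein
    return result


def design_hc(
    protein: str,
    table: CodonUsageTable,
    append_stop: bool = True,
    require_start_met: bool = True,
) -> DesignResult:
    """High-CAI design: the most-used codon at every position."""
    protein = _validate_protein(protein, require_start_met)
    codons = [pick_hc_codon(aa, table) for aa in protein]
    zones = [Zone.MIDDLE] * len(protein)  # HC has no zone structure
    return _finish(protein, codons, zones, "HC", table, None, append_stop)


def design_eco(
    protein: str,
    table: CodonUsageTable,
    cfg: ZoneConfig = DEFAULT_ZONE_CONFIG,
    seed: Optional[int] = None,
    append_stop: bool = True,
    require_start_met: bool = True,
    destabilized_rule: str = "min_count",
) -> DesignResult:
    """Zoned expression-cassette-optimization design."""
    protein = _validate_protein(protein, require_start_met)
    zones = zone_map(len(protein), cfg)
    codons: List[Optional[str]] = [None] * len(protein)
    middle_positions: List[int] = []
    for i, (aa, zone) in enumerate(zip(protein, zones)):
        if zone is Zone.START:
            codons[i] = pick_hc_codon(aa, table)  # ATG for Met
        elif zone is Zone.CONSENSUS:
            codons[i] = pick_start_context_codon(aa, table, cfg.consensus_pattern)
        elif zone is Zone.DESTABILIZED:
            codons[i] = pick_destabilized_codon(aa, table, rule=destabilized_rule)
        elif zone in (Zone.HEAD_HC, Zone.TAIL_HC):
            codons[i] = pick_hc_codon(aa, table)
        else:
            middle_positions.append(i)
    if middle_positions:
        segment = "".join(protein[i] for i in middle_positions)
        middle_codons = match_average_usage(segment, table, mode=cfg.middle_mode, seed=seed)
        for i, codon in zip(middle_positions, middle_codons):
            codons[i] = codon
    return _finish(protein, list(codons), zones, "ECO", table, seed, append_stop)
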