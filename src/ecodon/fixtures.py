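"""Deterministic synthetic fixtures so the toolkit runs without downloads.

The generator emulates the inputs the real workflow consumes: a set of
coding sequences with a biased codon distribution (standing in for a fungal
genome's CDS catalogue, from which the usage table is built), test proteins
of several lengths, read-depth profiles for strains carrying the cassette
at 1, 6, 7 and 10 copies — the copy levels of the characterized strain
panel — and a 20-strain copy-number/titer panel with a linear dose-response
plus measurement noise.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .codon_tables import CodonUsageTable, GeneticCode, STANDARD_CODE, build_usage_table, write_usage_table
from .copynum import DepthProfile, simulate_depth, write_depth_tsv

# study-condition defaults: strain panel copy levels, 500 kb reference with
# a 5 kb cassette, mean per-200bp-bin depth 40
FIXTURE_COPY_LEVELS = (1, 6, 7, 10)
REFERENCE_LENGTH = 500_000
CASSETTE_REGION = (250_000, 255_000)
MEAN_BIN_DEPTH = 40.0
BIN_SIZE = 200
PROTEIN_LENGTHS = (8, 100, 120, 300)
N_CDS = 60
# dose-response for the synthetic titer panel: ~30 mg/L per cassette copy
# with 25 mg/L assay noise over copies 1..10
TITER_SLOPE = 30.0
TITER_NOISE_SD = 25.0
N_PANEL_STRAINS = 20


@dataclass
class FixtureBundle:
    """In-memory bundle of synthetic inputs; ``write`` emits plain-text files."""

    seed: int
    cds_records: List[Tuple[str, str]]
    usage_table: CodonUsageTable
    proteins: Dict[str, str]
    depth_profiles: Dict[int, DepthProfile]
    titer_points: List[Tuple[int, float]]

    def protein_of_length(self, length: int) -> str:
        return self.proteins[f"protein_{length}aa"]

    def write(self, outdir: Path) -> List[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: List[Path] = []

        cds_path = outdir / "cds.fasta"
        with cds_path.open("w") as fh:
            for name, seq in self.cds_records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        written.append(cds_path)

        table_path = outdir / "usage_table.tsv"
        write_usage_table(self.usage_table, table_path)
        written.append(table_path)

        prot_path = outdir / "proteins.fasta"
        with prot_path.open("w") as fh:
            for name in sorted(self.proteins):
                seq = self.proteins[name]
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        written.append(prot_path)

        for copies, profile in sorted(self.depth_profiles.items()):
            depth_path = outdir / f"depth_copy{copies}.tsv"
            write_depth_tsv(profile, depth_path)
            written.append(depth_path)

        panel_path = outdir / "copy_titer.csv"
        with panel_path.open("w") as fh:
            fh.write("copy_number,titer_mg_per_l\n")
            for copies, titer in self.titer_points:
                fh.write(f"{copies},{titer:.3f}\n")
        written.append(panel_path)
        return written


def _codon_bias(rng: np.random.Generator, code: GeneticCode) -> Dict[str, np.ndarray]:
    """Per-family codon probabilities: Dirichlet bias mixed with a uniform
    floor so every codon keeps a usable (nonzero) probability."""
    bias: Dict[str, np.ndarray] = {}
    for aa, family in code.families.items():
        k = len(family)
        p = rng.dirichlet(np.full(k, 0.6))
        p = 0.85 * p + 0.15 / k
        bias[aa] = p / p.sum()
    return bias


def _random_protein(rng: np.random.Generator, length: int, alphabet: str) -> str:
    body = "".join(rng.choice(list(alphabet), size=length - 1))
    return "M" + body


def generate_fixtures(seed: int, outdir: Path | None = None) -> FixtureBundle:
    """Build the full synthetic bundle; identical seeds give identical output."""
    rng = np.random.default_rng(seed)
    code = STANDARD_CODE
    amino_acids = "".join(code.amino_acids)
    bias = _codon_bias(rng, code)
    stop_probs = rng.dirichlet(np.full(len(code.stop_codons), 1.0))

    cds_records: List[Tuple[str, str]] = []
    for g in range(N_CDS):
        length = int(rng.integers(150, 451))
        protein = _random_protein(rng, length, amino_acids)
        if g == 0:
            # guarantee every amino acid (hence family) is represented
            protein = "M" + amino_acids + protein[len(amino_acids) + 1 :]
        codons = []
        for aa in protein:
            family = code.families[aa]
            codons.append(family[rng.choice(len(family), p=bias[aa])])
        stop = code.stop_codons[rng.choice(len(code.stop_codons), p=stop_probs)]
        cds_records.append((f"gene_{g + 1:03d}", "".join(codons) + stop))

    table = build_usage_table(
        [seq for _, seq in cds_records],
        code=code,
        organism_label=f"synthetic-seed{seed}",
    )

    proteins = {
        f"protein_{length}aa": _random_protein(rng, length, amino_acids)
        for length in PROTEIN_LENGTHS
    }

    depth_profiles = {
        copies: simulate_depth(
            REFERENCE_LENGTH,
            CASSETTE_REGION,
            copies,
            mean_bin_depth=MEAN_BIN_DEPTH,
            bin_size=BIN_SIZE,
            seed=int(rng.integers(0, 2**31)),
        )
        for copies in FIXTURE_COPY_LEVELS
    }

    panel_copies = rng.integers(1, 11, size=N_PANEL_STRAINS)
    titers = TITER_SLOPE * panel_copies + rng.normal(0.0, TITER_NOISE_SD, size=N_PANEL_STRAINS)
    titer_points = [(int(c), float(max(t, 0.0))) for c, t in zip(panel_copies, titers)]

    bundle = FixtureBundle(
        seed=seed,
        cds_records=cds_records,
        usage_table=table,
        proteins=proteins,
        depth_profiles=depth_profiles,
        titer_points=titer_points,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
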