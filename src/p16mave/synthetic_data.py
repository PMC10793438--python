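"""Synthetic pooled-competition data for a saturation functional assay of p16INK4a.

This module generates count tables (and optionally raw paired reads) with the
statistical structure that the downstream analysis assumes, so that calibration,
classification and benchmarking are all testable without any external data.

The experimental design being emulated
--------------------------------------
The assay competes, within one lentiviral library per residue, all 20 amino-acid
variants at that residue (19 missense + 1 synonymous) of the 156-residue tumor
suppressor p16INK4a, expressed in a CDKN2A-null pancreatic cancer cell line.
Cells carrying a functionally deleterious (loss-of-function) variant escape
p16-mediated growth suppression and expand relative to cells carrying a
functional protein.  Variant representation is read out by amplicon sequencing
at Day 9 after transduction and again when the culture reaches confluency
(Day 16-40).  An all-neutral control pool of 20 non-functional 9-bp barcodes
("CellTags"), assayed in triplicate, provides the data used to calibrate the
null model.

Generative model
----------------
1. Library composition: per-variant plasmid proportions are drawn from a
   symmetric Dirichlet; any variant whose drawn proportion falls at or below
   ``underrep_threshold`` is spiked to ``spike_to`` and the vector renormalised,
   mirroring the wet-lab rebalancing of underrepresented library members.
2. Transduction: ``n_cells_transduced`` cells are assigned to variants by a
   multinomial draw on the library proportions (MOI ~ 1, single integration).
3. Growth: abundances evolve deterministically as ``a_v(t) = a_v(0) * exp(g_v t)``.
   Between transduction and the Day-9 harvest each variant's abundance also
   receives a one-shot multiplicative lognormal jitter (``bottleneck_sd``,
   log scale) representing the puromycin-selection bottleneck and early
   clonal growth stochasticity; between Day 9 and confluency each variant
   accrues growth-phase heterogeneity as a lognormal multiplier whose
   log-standard deviation grows with the square root of elapsed culture time
   (``growth_noise_sd`` per sqrt(day)), the signature of stochastic clonal
   growth.  These count-independent components dominate sequencing-sampling
   noise at realistic depths, which is what makes a single shared dispersion
   across variants (the gamma shape of the null model) a faithful
   description; and because the all-neutral control pool is the longest
   culture of the design (Day 45), a dispersion calibrated on it is
   conservative for every shorter-duration assay library.
4. Sequencing: read counts at each timepoint are multinomial draws of the
   configured depth on the population proportions at that timepoint.

The confluency day is drawn uniformly from ``confluency_day_range`` per library
and replicate and recorded in the output.
"""

from __future__ import annotations


import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "P16_SEQUENCE",
    "AMINO_ACIDS",
    "COUNT_COLUMNS",
    "TRUTH_COLUMNS",
    "SimulationConfig",
    "LibraryDesign",
    "make_library_design",
    "make_fitness_map",
    "simulate_assay",
    "simulate_library",
    "simulate_screen",
    "simulate_celltag_control",
    "reference_cds",
    "emit_reads",
    "write_fastq",
]

#: Human p16INK4a (CDKN2A, UniProt P42771), 156 residues.
P16_SEQUENCE = (
    "MEPAAGSSMEPSADWLATAAARGRVEEVRALLEAGALPNAPNSYGRRPIQVMMMGSARVA"
    "ELLLLHGAEPNCADPATLTRPVHDAAREGFLDTLVVLHRAGARLDVRDAWGRLPVDLAEE"
    "LGHRDVARYLRAAAGGTRGSNHARIDAAEGPSDIPD"
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical count-table schema shared by every stage of the pipeline.
COUNT_COLUMNS = [
    "library_id",
    "replicate_id",
    "residue_index",
    "ref_aa",
    "alt_aa",
    "count_day9",
    "count_confluent",
    "day_confluent",
]

TRUTH_COLUMNS = ["variant", "growth_rate", "is_deleterious"]

#: One representative codon per amino acid (deterministic choice; the amplicon
#: analysis collapses to amino-acid identity so the specific codon is inert).
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

LN2 = math.log(2.0)


class ParameterError(ValueError):
    """Invalid simulation or design parameter."""


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pooled-competition experiment.

    Rates are per day; proportions lie in (0, 1); depths and cell numbers are
    positive integers.  ``deleterious_advantage`` is an additive growth-rate
    increment over ``neutral_growth_rate``; the default ln(2)/10 per day means
    an advantaged variant doubles its relative representation every 10 days,
    i.e. a 1.6x-8.6x total enrichment across the Day 16-40 confluency window,
    matching the magnitude of log2 normalized fold changes observed for
    loss-of-function variants in this assay class.
    """

    n_residues: int = 156
    variants_per_residue: int = 20
    library_concentration: float = 10.0
    underrep_threshold: float = 0.01
    spike_to: float = 0.05
    n_cells_transduced: int = 100_000
    neutral_growth_rate: float = 0.35
    deleterious_advantage: float = LN2 / 10.0
    deleterious_fraction: float = 0.177
    confluency_cells: int = 5_000_000
    depth_init: int = 100_000
    depth_cf: int = 100_000
    n_replicates: int = 1
    confluency_day_range: tuple[int, int] = (16, 40)
    day_init: int = 9
    bottleneck_sd: float = 0.25
    growth_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_residues > len(P16_SEQUENCE):
            raise ParameterError(f"n_residues must be in 1..{len(P16_SEQUENCE)}")
        if self.variants_per_residue != 20:
            raise ParameterError("variants_per_residue must be 20 (19 missense + 1 synonymous)")
        if self.library_concentration <= 0:
            raise ParameterError("library_concentration must be > 0")
        for name in ("underrep_threshold", "spike_to", "deleterious_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.spike_to <= self.underrep_threshold:
            raise ParameterError("spike_to must exceed underrep_threshold")
        for name in ("n_cells_transduced", "confluency_cells", "depth_init", "depth_cf", "n_replicates"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        lo, hi = self.confluency_day_range
        if not (self.day_init < lo <= hi):
            raise ParameterError("confluency_day_range must be an increasing range after day_init")
        if self.bottleneck_sd < 0 or self.growth_noise_sd < 0:
            raise ParameterError("noise standard deviations must be non-negative")
        if not math.isfinite(self.neutral_growth_rate) or not math.isfinite(self.deleterious_advantage):
            raise ParameterError("growth rates must be finite")


@dataclass(frozen=True)
class LibraryDesign:
    """Plasmid-library composition for one residue: alt amino acid -> proportion."""

    residue_index: int
    ref_aa: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"library proportions sum to {total}, expected 1")
        if self.ref_aa not in self.proportions:
            raise ParameterError("design must contain the synonymous (reference) variant")

    @property
    def variants(self) -> list[str]:
        """Variant names in design order, e.g. ``G101W`` (``G101G`` = synonymous)."""
        return [f"{self.ref_aa}{self.residue_index}{alt}" for alt in self.proportions]

    @property
    def synonymous(self) -> str:
        return f"{self.ref_aa}{self.residue_index}{self.ref_aa}"


def make_library_design(
    residue_index: int,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> LibraryDesign:
    """Draw a per-residue library composition with the spike-in correction.

    Proportions are drawn from a symmetric Dirichlet with concentration
    ``config.library_concentration``.  Any variant drawn at or below
    ``underrep_threshold`` is raised to ``spike_to`` (the wet-protocol rule of
    re-adding underrepresented variants to a calculated 5% of the pool) and the
    vector is then renormalised.  Deterministic given the seed.
    """
    if not 1 <= residue_index <= config.n_residues:
        raise ParameterError(f"residue_index {residue_index} outside 1..{config.n_residues}")
    rng = _as_rng(seed)
    ref = P16_SEQUENCE[residue_index - 1]
    alts = [aa for aa in AMINO_ACIDS if aa != ref] + [ref]  # 19 missense + synonymous
    p = rng.dirichlet(np.full(len(alts), config.library_concentration))
    # Raise-and-renormalise until nothing sits at or below the threshold
    # (one pass suffices unless renormalisation pushes a borderline variant
    # back under, which requires an extremely skewed draw).
    for _ in range(len(alts)):
        low = p <= config.underrep_threshold
        if not low.any():
            break
        p[low] = config.spike_to
        p = p / p.sum()
    return LibraryDesign(residue_index, ref, dict(zip(alts, p.tolist())))


def make_fitness_map(
    design: LibraryDesign,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    deleterious_fraction: float | None = None,
) -> dict[str, float]:
    """Assign a ground-truth growth rate to every variant in a design.

    Each missense variant is deleterious (loss of p16 function, hence a growth
    advantage of ``config.deleterious_advantage``) with probability
    ``deleterious_fraction``; the synonymous variant is always neutral.
    """
    rng = _as_rng(seed)
    frac = config.deleterious_fraction if deleterious_fraction is None else deleterious_fraction
    rates: dict[str, float] = {}
    for variant, alt in zip(design.variants, design.proportions):
        if alt != design.ref_aa and rng.random() < frac:
            rates[variant] = config.neutral_growth_rate + config.deleterious_advantage
        else:
            rates[variant] = config.neutral_growth_rate
    return rates


class AssayTables(NamedTuple):
    counts: pd.DataFrame
    truth: pd.DataFrame


def _evolve(abundance: np.ndarray, rates: np.ndarray, days: float) -> np.ndarray:
    return abundance * np.exp(rates * days)


def simulate_assay(
    design: LibraryDesign,
    fitness_map: Mapping[str, float],
    config: SimulationConfig,
    seed: int | np.random.Generator,
    library_id: str | None = None,
    replicate_id: int = 1,
) -> AssayTables:
    """Simulate one library x replicate competition and its sequencing readout.

    Returns the count table (schema :data:`COUNT_COLUMNS`) together with the
    ground-truth fitness labels.  Raises :class:`ParameterError` on an empty
    design or a fitness map that does not cover the design.
    """
    variants = design.variants
    if not variants:
        raise ParameterError("empty library design")
    missing = [v for v in variants if v not in fitness_map]
    if missing:
        raise ParameterError(f"fitness map missing variants: {missing[:3]}...")
    rng = _as_rng(seed)

    p0 = np.array(list(design.proportions.values()))
    rates = np.array([fitness_map[v] for v in variants])

    cells = rng.multinomial(config.n_cells_transduced, p0).astype(float)
    jitter9 = np.exp(rng.normal(0.0, config.bottleneck_sd, len(variants))) if config.bottleneck_sd else 1.0
    a9 = _evolve(cells * jitter9, rates, config.day_init)
    p9 = a9 / a9.sum()

    day_cf = int(rng.integers(config.confluency_day_range[0], config.confluency_day_range[1] + 1))
    growth_sd = config.growth_noise_sd * math.sqrt(day_cf - config.day_init)
    jcf = np.exp(rng.normal(0.0, growth_sd, len(variants))) if growth_sd else 1.0
    acf = _evolve(a9, rates, day_cf - config.day_init) * jcf
    pcf = acf / acf.sum()

    c9 = rng.multinomial(config.depth_init, p9)
    ccf = rng.multinomial(config.depth_cf, pcf)

    lib = library_id if library_id is not None else f"res{design.residue_index:03d}"
    counts = pd.DataFrame(
        {
            "library_id": lib,
            "replicate_id": replicate_id,
            "residue_index": design.residue_index,
            "ref_aa": design.ref_aa,
            "alt_aa": list(design.proportions),
            "count_day9": c9,
            "count_confluent": ccf,
            "day_confluent": day_cf,
        }
    )
    truth = pd.DataFrame(
        {
            "variant": variants,
            "growth_rate": rates,
            "is_deleterious": rates > config.neutral_growth_rate,
        }
    )
    return AssayTables(counts, truth)


def simulate_library(
    residue_index: int,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    deleterious_fraction: float | None = None,
) -> AssayTables:
    """Design, fitness assignment and ``config.n_replicates`` assay replicates
    for one residue.  Replicates share the design and ground truth but have
    independent transduction, noise and confluency days."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    design_rng, fitness_rng, *rep_rngs = [
        np.random.default_rng(s) for s in ss.spawn(2 + config.n_replicates)
    ]
    design = make_library_design(residue_index, config, design_rng)
    fitness = make_fitness_map(design, config, fitness_rng, deleterious_fraction)
    parts, truth = [], None
    for rep, rng in enumerate(rep_rngs, start=1):
        counts, truth = simulate_assay(design, fitness, config, rng, replicate_id=rep)
        parts.append(counts)
    return AssayTables(pd.concat(parts, ignore_index=True), truth)


def simulate_screen(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
    deleterious_fraction: float | None = None,
) -> AssayTables:
    """Simulate the full screen: one library per residue, all replicates.

    A single master seed (``config.seed`` unless overridden) expands into
    independent per-library substreams, so any library can be regenerated in
    isolation and identical seeds give byte-identical outputs.
    """
    if isinstance(seed, np.random.SeedSequence):
        master = seed
    else:
        master = np.random.SeedSequence(config.seed if seed is None else seed)
    children = master.spawn(config.n_residues)
    counts_parts, truth_parts = [], []
    for residue, child in enumerate(children, start=1):
        counts, truth = simulate_library(residue, config, child, deleterious_fraction)
        counts_parts.append(counts)
        truth_parts.append(truth)
    return AssayTables(
        pd.concat(counts_parts, ignore_index=True),
        pd.concat(truth_parts, ignore_index=True),
    )


def simulate_celltag_control(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
    n_experiments: int = 3,
    n_barcodes: int = 20,
    confluency_day: int = 45,
) -> list[pd.DataFrame]:
    """Simulate the all-neutral CellTag control experiments.

    Twenty non-functional barcodes at exactly equal initial representation,
    sharing a single growth rate, assayed in ``n_experiments`` independent
    experiments (default triplicate).  The control culture runs to a fixed
    Day-45 confluency endpoint.  Returned tables use the count-table schema
    with the barcode name in ``alt_aa`` and ``residue_index`` 0.
    """
    if config.n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        config.seed if seed is None else seed
    )
    barcodes = [f"TAG{i:02d}" for i in range(1, n_barcodes + 1)]
    tables = []
    for exp, child in enumerate(ss.spawn(n_experiments), start=1):
        rng = np.random.default_rng(child)
        p0 = np.full(n_barcodes, 1.0 / n_barcodes)
        rates = np.full(n_barcodes, config.neutral_growth_rate)
        cells = rng.multinomial(config.n_cells_transduced, p0).astype(float)
        j9 = np.exp(rng.normal(0.0, config.bottleneck_sd, n_barcodes)) if config.bottleneck_sd else 1.0
        a9 = _evolve(cells * j9, rates, config.day_init)
        growth_sd = config.growth_noise_sd * math.sqrt(confluency_day - config.day_init)
        jcf = np.exp(rng.normal(0.0, growth_sd, n_barcodes)) if growth_sd else 1.0
        acf = _evolve(a9, rates, confluency_day - config.day_init) * jcf
        c9 = rng.multinomial(config.depth_init, a9 / a9.sum())
        ccf = rng.multinomial(config.depth_cf, acf / acf.sum())
        tables.append(
            pd.DataFrame(
                {
                    "library_id": "celltag",
                    "replicate_id": exp,
                    "residue_index": 0,
                    "ref_aa": "-",
                    "alt_aa": barcodes,
                    "count_day9": c9,
                    "count_confluent": ccf,
                    "day_confluent": confluency_day,
                }
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Read-level fixture generation (round-trips through the counting stage)
# ---------------------------------------------------------------------------

def reference_cds(protein: str = P16_SEQUENCE) -> str:
    """A deterministic in-frame CDS encoding the given protein sequence."""
    return "".join(PREFERRED_CODON[aa] for aa in protein)


def emit_reads(
    counts: Mapping[str, int],
    residue_index: int,
    cds: str,
    read_length: int = 150,
    seed: int | np.random.Generator = 0,
    base_quality: int = 40,
    overlap_target: int = 30,
):
    """Emit paired reads realising a per-amino-acid count table at one residue.

    For each counted amino acid, that many read pairs are produced whose merged
    sequence matches ``cds`` over the amplicon window except at the target
    codon, which encodes the counted amino acid (the reference codon for the
    synonymous entry).  Mate 2 is returned reverse-complemented as sequenced.
    Phred qualities are constant at ``base_quality``.  Returns a list of
    :class:`~p16mave.variant_counting.ReadPair`.
    """
    from .variant_counting import ReadPair, reverse_complement

    if len(cds) % 3:
        raise ParameterError("reference CDS length must be divisible by 3")
    n_res = len(cds) // 3
    if not 1 <= residue_index <= n_res:
        raise ParameterError(f"residue {residue_index} outside the amplicon span")
    bad = [aa for aa in counts if aa not in PREFERRED_CODON]
    if bad:
        raise ParameterError(f"unknown amino acids in count table: {bad}")

    span = min(len(cds), 2 * read_length - overlap_target)
    if span < 2 * read_length - len(cds) or span < 3:
        raise ParameterError("reads too short to form an overlapping pair on this CDS")
    codon_start = 3 * (residue_index - 1)
    start = min(max(0, codon_start + 1 - span // 2), len(cds) - span)
    if not (start <= codon_start and codon_start + 3 <= start + span):
        raise ParameterError(f"codon for residue {residue_index} not covered by the amplicon")

    ref_aa = P16_SEQUENCE[residue_index - 1] if cds == reference_cds() else None
    qual = [base_quality] * read_length
    pairs = []
    for aa, n in counts.items():
        if n < 0:
            raise ParameterError("negative read count")
        codon = cds[codon_start: codon_start + 3] if aa == ref_aa else PREFERRED_CODON[aa]
        amplicon = cds[start:codon_start] + codon + cds[codon_start + 3: start + span]
        mate1 = amplicon[:read_length]
        mate2 = reverse_complement(amplicon[span - read_length:])
        pairs.extend(ReadPair(mate1, list(qual), mate2, list(qual)) for _ in range(int(n)))
    return pairs


def write_fastq(pairs: Sequence, path1, path2) -> None:
    """Write mate-1 / mate-2 FASTQ files (4-line records, Phred+33)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, pair in enumerate(pairs):
            q1 = "".join(chr(q + 33) for q in pair.qual1)
            q2 = "".join(chr(q + 33) for q in pair.qual2)
            f1.write(f"@read{i}/1\n{pair.seq1}\n+\n{q1}\n")
            f2.write(f"@read{i}/2\n{pair.seq2}\n+\n{q2}\n")
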