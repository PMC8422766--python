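"""Synthetic genome evolution with exact ground truth.

Generates the two kinds of inputs the rest of the package analyzes,
without any external downloads:

* **Diverged bacterial strain pairs** — a random ancestor chromosome
  evolves by uniform point substitutions plus non-overlapping segmental
  inversions (the rearrangement process believed to underlie inversion
  symmetry). The exact inversion breakpoints and substituted positions are
  recorded, so ground-truth synteny blocks (direct between breakpoints,
  inverse inside them) can stand in for aligner output.

* **Eukaryote-like masked/unmasked contrasts** — genomes carrying
  soft-masked low-complexity tracts (short tandem repeats, lowercase in
  the emitted FASTA). Divergence concentrated in those tracts makes the
  unmasked k-mer distance exceed the masked one, the direction the KDR
  statistic measures.

Every generator is a pure function of its inputs and a seed: identical
seeds reproduce identical output bit for bit. The substitution model is
deliberately minimal (uniform rate, no transition/transversion bias, no
indels); inversions are sampled without overlap so ground-truth blocks
stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sequence_io import GenomeRecord, reverse_complement
from .synteny import SyntenyBlock

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

Interval = Tuple[int, int]  # 1-based inclusive


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class EvolutionScenario:
    """Parameters of one simulated divergence experiment.

    ``substitution_rate`` is the per-site probability of a point mutation
    on the descendant; ``n_inversions`` segments with lengths drawn
    uniformly from ``inversion_length_range`` (bp, inclusive) are reverse
    complemented in place; ``n_low_complexity_tracts`` tracts with lengths
    from ``tract_length_range`` are overwritten with tandem repeats and
    soft-masked.
    """

    ancestor_length: int = 50_000
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    substitution_rate: float = 0.0
    n_inversions: int = 0
    inversion_length_range: Tuple[int, int] = (500, 5000)
    n_low_complexity_tracts: int = 0
    tract_length_range: Tuple[int, int] = (400, 1600)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be 4 non-negative reals summing to 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.n_inversions < 0 or self.n_low_complexity_tracts < 0:
            raise ValueError("event counts must be >= 0")
        for lo, hi in (self.inversion_length_range, self.tract_length_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """Exact event record on descendant coordinates (1-based inclusive)."""

    inverted_intervals: List[Interval] = field(default_factory=list)
    substituted_positions: List[int] = field(default_factory=list)
    masked_intervals: List[Interval] = field(default_factory=list)


def random_genome(
    length: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    record_id: str = "synthetic",
) -> GenomeRecord:
    """i.i.d. random chromosome with the given base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base_composition must be 4 non-negative reals summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp / comp.sum())
    return GenomeRecord(
        id=record_id,
        sequence=_BASES[codes].tobytes().decode("ascii"),
        masking_mode="unmasked",
    )


def _sample_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    n_intervals: int,
    length_range: Tuple[int, int],
    max_tries: int = 1000,
) -> List[Interval]:
    """Rejection-sample n non-overlapping intervals (1-based inclusive), sorted."""
    chosen: List[Interval] = []
    for _ in range(n_intervals):
        for _try in range(max_tries):
            seg_len = int(rng.integers(length_range[0], length_range[1] + 1))
            if seg_len > length:
                continue
            start = int(rng.integers(1, length - seg_len + 2))
            end = start + seg_len - 1
            if all(end < a or start > b for a, b in chosen):
                chosen.append((start, end))
                break
        else:
            raise RuntimeError(
                f"could not place {n_intervals} non-overlapping intervals of "
                f"{length_range} bp on a {length} bp sequence; "
                "use fewer or shorter segments"
            )
    return sorted(chosen)


def evolve_strain(
    ancestor: GenomeRecord,
    scenario: EvolutionScenario,
    seed: Optional[int] = None,
) -> Tuple[GenomeRecord, GroundTruth]:
    """Derive a strain from ``ancestor`` by inversions then substitutions.

    Inversions replace each sampled segment by its reverse complement in
    place; substitutions are then applied on descendant coordinates (each
    mutated site gets a different base, uniformly), so all GroundTruth
    positions refer to one coordinate system.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    L = ancestor.length
    inversions = _sample_nonoverlapping(
        rng, L, scenario.n_inversions, scenario.inversion_length_range
    )
    seq = bytearray(ancestor.sequence, "ascii")
    for start, end in inversions:
        segment = seq[start - 1 : end].decode("ascii")
        seq[start - 1 : end] = reverse_complement(segment).encode("ascii")

    codes = _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]
    hit = rng.random(L) < scenario.substitution_rate
    hit &= codes != 255  # only substitute unambiguous bases
    positions = np.flatnonzero(hit)
    if positions.size:
        offsets = rng.integers(1, 4, size=positions.size)
        new_codes = (codes[positions].astype(np.int64) + offsets) % 4
        arr = np.frombuffer(bytes(seq), dtype=np.uint8).copy()
        arr[positions] = _BASES[new_codes]
        seq = bytearray(arr.tobytes())

    descendant = GenomeRecord(
        id=f"{ancestor.id}|derived",
        sequence=bytes(seq).decode("ascii"),
        masking_mode=ancestor.masking_mode,
    )
    truth = GroundTruth(
        inverted_intervals=inversions,
        substituted_positions=(positions + 1).tolist(),
        masked_intervals=[],
    )
    return descendant, truth


def true_blocks(
    truth: GroundTruth, length: int, min_block: int = 0
) -> List[SyntenyBlock]:
    """Ground-truth synteny blocks implied by the recorded events.

    Unchanged segments between inversion breakpoints become direct blocks;
    inverted intervals become inverse blocks. Block identity mirrors what
    an aligner would report: 100 * (1 - substitutions inside / length).
    Blocks shorter than ``min_block`` are dropped.
    """
    subs = np.asarray(sorted(truth.substituted_positions), dtype=np.int64)

    def identity(a: int, b: int) -> float:
        n_subs = int(np.searchsorted(subs, b, side="right") - np.searchsorted(subs, a))
        return 100.0 * (1.0 - n_subs / (b - a + 1))

    blocks: List[SyntenyBlock] = []

    def add(a: int, b: int, orientation: str) -> None:
        if b >= a and (b - a + 1) >= min_block:
            blocks.append(SyntenyBlock(a, b, identity(a, b), orientation))

    prev_end = 0
    for start, end in sorted(truth.inverted_intervals):
        add(prev_end + 1, start - 1, "direct")
        add(start, end, "inverse")
        prev_end = end
    add(prev_end + 1, length, "direct")
    return blocks


def plant_low_complexity(
    genome: GenomeRecord,
    scenario: EvolutionScenario,
    seed: Optional[int] = None,
) -> Tuple[GenomeRecord, GroundTruth]:
    """Overwrite sampled tracts with soft-masked short tandem repeats.

    Each tract is filled by repeating a random 1–3 bp motif and written in
    lowercase, so loading the result in ``masked`` mode removes exactly
    these intervals while ``unmasked`` mode keeps them.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    tracts = _sample_nonoverlapping(
        rng, genome.length, scenario.n_low_complexity_tracts, scenario.tract_length_range
    )
    seq = bytearray(genome.sequence, "ascii")
    for start, end in tracts:
        _fill_tract(rng, seq, start, end)
    return (
        GenomeRecord(id=genome.id, sequence=bytes(seq).decode("ascii"), masking_mode="raw"),
        GroundTruth(masked_intervals=tracts),
    )


def _fill_tract(rng: np.random.Generator, seq: bytearray, start: int, end: int) -> None:
    """Write a lowercase tandem repeat of a random 1-3 bp motif into [start, end]."""
    motif_len = int(rng.integers(1, 4))
    motif = _BASES[rng.integers(0, 4, size=motif_len)].tobytes().decode("ascii").lower()
    tract_len = end - start + 1
    repeat = (motif * (tract_len // motif_len + 1))[:tract_len]
    seq[start - 1 : end] = repeat.encode("ascii")


def diverged_masked_pair(
    scenario: EvolutionScenario,
    seed: Optional[int] = None,
    id_prefix: str = "chr",
) -> Tuple[Tuple[GenomeRecord, GroundTruth], Tuple[GenomeRecord, GroundTruth]]:
    """Two strains whose divergence is concentrated in maskable tracts.

    Both strains share an ancestral backbone and the *positions* of the
    low-complexity tracts (they are homologous loci), but each strain gets
    independent background substitutions and an independently drawn repeat
    motif per tract — low-complexity sequence diverging much faster than
    the rest of the genome. Records are soft-masked; use
    ``sequence_io.apply_masking`` to obtain the unmasked/masked views.
    """
    ss = _seed_seq(scenario.seed if seed is None else seed)
    s_anc, s_tracts, s_a, s_b = ss.spawn(4)
    ancestor = random_genome(
        scenario.ancestor_length,
        scenario.base_composition,
        seed=s_anc,
        record_id=id_prefix,
    )
    tracts = _sample_nonoverlapping(
        np.random.default_rng(s_tracts),
        ancestor.length,
        scenario.n_low_complexity_tracts,
        scenario.tract_length_range,
    )

    out = []
    backbone_scenario = replace(
        scenario, n_inversions=0, n_low_complexity_tracts=0
    )
    for label, strain_seed in (("A", s_a), ("B", s_b)):
        rng = np.random.default_rng(strain_seed)
        strain, truth = evolve_strain(
            ancestor, backbone_scenario, seed=rng.integers(2**31)
        )
        seq = bytearray(strain.sequence, "ascii")
        for start, end in tracts:
            _fill_tract(rng, seq, start, end)
        rec = GenomeRecord(
            id=f"{id_prefix}|strain{label}",
            sequence=bytes(seq).decode("ascii"),
            masking_mode="raw",
        )
        truth.masked_intervals = list(tracts)
        out.append((rec, truth))
    return out[0], out[1]


def graded_strain_cohort(
    n_pairs: int = 20,
    ancestor_length: int = 50_000,
    rate_range: Tuple[float, float] = (0.01, 0.18),
    inversion_range: Tuple[int, int] = (1, 6),
    inversion_length_range: Tuple[int, int] = (500, 5000),
    seed: int = 0,
) -> List[Tuple[float, GenomeRecord, GenomeRecord, GroundTruth]]:
    """Strain pairs with a graded substitution/inversion load.

    Pair i carries substitution rate and inversion count interpolated
    across the given ranges, emulating a cohort of strain pairs at
    increasing evolutionary separation. The rate ladder spans past the
    point where block identity crosses the 90% synteny threshold, so both
    k-mer distances and synteny proximities respond. Returns
    (rate, ancestor, descendant, truth) per pair.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rates = np.linspace(rate_range[0], rate_range[1], n_pairs)
    inversions = np.round(np.linspace(inversion_range[0], inversion_range[1], n_pairs))
    seeds = _seed_seq(seed).spawn(n_pairs)
    cohort = []
    for i in range(n_pairs):
        rng = np.random.default_rng(seeds[i])
        ancestor = random_genome(
            ancestor_length, seed=rng.integers(2**31), record_id=f"pair{i:02d}"
        )
        scenario = EvolutionScenario(
            ancestor_length=ancestor_length,
            substitution_rate=float(rates[i]),
            n_inversions=int(inversions[i]),
            inversion_length_range=inversion_length_range,
        )
        descendant, truth = evolve_strain(ancestor, scenario, seed=rng.integers(2**31))
        cohort.append((float(rates[i]), ancestor, descendant, truth))
    return cohort


def kdr_replicate(
    n_chromosomes: int = 3,
    chromosome_length: int = 30_000,
    n_tracts: int = 5,
    tract_length_range: Tuple[int, int] = (400, 1600),
    substitution_rate: float = 0.02,
    seed: int = 0,
) -> Tuple[List[GenomeRecord], List[GenomeRecord]]:
    """One replicate of the masked/unmasked contrast: two multi-chromosome genomes.

    Chromosome i of genome A and chromosome i of genome B descend from the
    same ancestor (independent ancestors across i), with divergence
    concentrated in shared low-complexity tracts as in
    :func:`diverged_masked_pair`. Returns the two soft-masked chromosome
    lists.
    """
    seeds = _seed_seq(seed).spawn(n_chromosomes)
    genome_a, genome_b = [], []
    for i in range(n_chromosomes):
        scenario = EvolutionScenario(
            ancestor_length=chromosome_length,
            substitution_rate=substitution_rate,
            n_low_complexity_tracts=n_tracts,
            tract_length_range=tract_length_range,
        )
        (rec_a, _), (rec_b, _) = diverged_masked_pair(
            scenario, seed=seeds[i], id_prefix=f"chr{i + 1}"
        )
        genome_a.append(rec_a)
        genome_b.append(rec_b)
    return genome_a, genome_b


def ground_truth_to_json(truth: GroundTruth) -> dict:
    return {
        "inverted_intervals": [list(iv) for iv in truth.inverted_intervals],
        "substituted_positions": list(truth.substituted_positions),
        "masked_intervals": [list(iv) for iv in truth.masked_intervals],
    }
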