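"""Design and in-silico assembly of hybrid OL1/UAS operator arrays.

A hybrid FROS array is a tandem repeat of alternating operator sites for two
DNA-binding proteins: OL1 (bound by the lambda cI repressor) and UAS (bound by
the Gal4 DNA-binding domain).  The array is built hierarchically: an initial
building block carries a *split* OL1 site (the tail of one OL1 at its left end
and the head of the next at its right end), a complete UAS in the middle, and
flanking type-IIS restriction sites (BpiI, BsaI).  Cutting two block pools
with the two enzymes yields fragments with compatible 4-nt overhangs; ligating
them doubles the insert and reconstitutes one full OL1 at the junction.
Repeating the cycle doubles the unit count each time, so an N-unit array takes
``1 + log2(N)`` steps counting the initial block construction.

The 4-nt ligation overhang lies *inside* the OL1 motif (the last four bases of
the motif head), so the ligation scar is motif interior and every junction
yields a complete OL1 by plain string concatenation.  A raw n-unit ligation
product therefore contains n-1 internal full OL1 sites plus two terminal
half-sites; finalisation appends the missing tail half-site so the emitted
construct contains exactly n complete OL1 motifs, matching the n complete UAS
motifs.

Coordinates in user-facing output are 1-based inclusive; internally all
positions are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OperatorMotif",
    "BuildingBlock",
    "AssemblyState",
    "HybridArray",
    "ReporterSplitSpec",
    "AssemblyDesignError",
    "OverhangMismatchError",
    "OL1_LAMBDA",
    "UAS_GAL4",
    "BPII_SITE",
    "BSAI_SITE",
    "MVENUS_SPLIT",
    "SYNTHETIC_VENUS_LIKE",
    "make_building_block",
    "initial_state",
    "simulate_assembly_cycle",
    "assemble_to_target",
    "count_motifs",
    "find_motifs",
    "split_reporter",
    "reverse_complement",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: BpiI (BbsI) and BsaI recognition sequences (type IIS: cut outside the site).
BPII_SITE = "GAAGAC"
BSAI_SITE = "GGTCTC"

#: Fixed dinucleotides anchoring each random spacer (the two determined base
#: pairs of the spacer design); remaining spacer bases are randomised.
SPACER_FIXED = ("CT", "AG")


class AssemblyDesignError(ValueError):
    """A building block satisfying the design constraints cannot be produced."""


class OverhangMismatchError(ValueError):
    """Two fragments with incompatible ligation overhangs were combined."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what}: non-ACGT characters {sorted(bad)!r}")


@dataclass(frozen=True)
class OperatorMotif:
    """A protein binding site on DNA.

    ``split_after`` (0-based half-open boundary, i.e. length of the left
    half-site) is only meaningful for the motif that is split across adjacent
    building blocks (OL1).
    """

    name: str
    sequence: str
    split_after: int | None = None

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"motif {self.name!r}")
        if self.split_after is not None and not (
            0 < self.split_after < len(self.sequence)
        ):
            raise ValueError("split_after must fall strictly inside the motif")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def left_half(self) -> str:
        if self.split_after is None:
            raise ValueError(f"motif {self.name!r} has no split point")
        return self.sequence[: self.split_after]

    @property
    def right_half(self) -> str:
        if self.split_after is None:
            raise ValueError(f"motif {self.name!r} has no split point")
        return self.sequence[self.split_after :]


#: 17-bp lambda OL1 operator, split at the midpoint (left half = 9 bases).
OL1_LAMBDA = OperatorMotif("OL1", "TACCTCTGGCGGTGATA", split_after=9)
#: 17-bp Gal4 UAS consensus.
UAS_GAL4 = OperatorMotif("UAS", "CGGAGGACTGTCCTCCG")


@dataclass(frozen=True)
class BuildingBlock:
    """One repeat unit of the array as synthesised for hierarchical assembly.

    The block core reads ``left_half_site + spacer + uas + spacer +
    right_half_site`` where ``left_half_site`` is the *tail* of an OL1 motif
    (completing the junction with the previous block) and ``right_half_site``
    is the *head* of the next OL1 (its last four bases double as the ligation
    overhang).  ``right_half_site`` of one block concatenated with
    ``left_half_site`` of the next reconstitutes the full OL1.
    """

    left_half_site: str
    uas: str
    right_half_site: str
    spacers: tuple[str, ...]
    left_overhang: str
    right_overhang: str
    enzyme_sites: tuple[str, str] = (BPII_SITE, BSAI_SITE)
    ol1: OperatorMotif = OL1_LAMBDA
    uas_motif: OperatorMotif = UAS_GAL4

    @property
    def core(self) -> str:
        return (
            self.left_half_site
            + self.spacers[0]
            + self.uas
            + self.spacers[1]
            + self.right_half_site
        )

    @property
    def unit_length(self) -> int:
        return len(self.core)

    @property
    def oligo(self) -> str:
        """Full synthetic oligo including the flanking type-IIS sites."""
        return self.enzyme_sites[1] + "A" + self.core + "A" + reverse_complement(self.enzyme_sites[0])


def _has_enzyme_site(seq: str, sites: tuple[str, str]) -> bool:
    for s in sites:
        if s in seq or reverse_complement(s) in seq:
            return True
    return False


def make_building_block(
    ol1: OperatorMotif = OL1_LAMBDA,
    uas: OperatorMotif = UAS_GAL4,
    spacer_lengths: tuple[int, int] = (6, 6),
    seed: int = 0,
    enzyme_sites: tuple[str, str] = (BPII_SITE, BSAI_SITE),
    max_tries: int = 500,
) -> BuildingBlock:
    """Design the initial building block with randomised spacers.

    Spacers are random except for a fixed dinucleotide at their first two
    positions.  Randomisation is retried (bounded) until no type-IIS
    recognition site occurs anywhere in the block core, nor across the
    block-block junction (checked on a doubled core), on either strand.
    Deterministic for a given seed.
    """
    if ol1.split_after is None:
        raise ValueError("OL1 motif must declare a split point")
    if any(n <= 0 for n in spacer_lengths):
        raise ValueError("spacer lengths must be positive")
    if len(spacer_lengths) != 2:
        raise ValueError("exactly two spacers flank the UAS")
    for motif in (ol1, uas):
        if _has_enzyme_site(motif.sequence, enzyme_sites):
            raise AssemblyDesignError(
                f"enzyme recognition site occurs inside motif {motif.name!r}"
            )
    if ol1.split_after < 4:
        raise ValueError("OL1 left half must be at least 4 nt to host the overhang")

    overhang = ol1.left_half[-4:]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        spacers = []
        for i, n in enumerate(spacer_lengths):
            fixed = SPACER_FIXED[i % len(SPACER_FIXED)]
            tail = "".join(rng.choice(bases, size=max(0, n - len(fixed))))
            spacers.append((fixed + tail)[:n])
        block = BuildingBlock(
            left_half_site=ol1.right_half,
            uas=uas.sequence,
            right_half_site=ol1.left_half,
            spacers=tuple(spacers),
            left_overhang=overhang,
            right_overhang=overhang,
            enzyme_sites=enzyme_sites,
            ol1=ol1,
            uas_motif=uas,
        )
        if not _has_enzyme_site(block.core + block.core, enzyme_sites):
            return block
    raise AssemblyDesignError(
        "could not avoid enzyme recognition sites within "
        f"{max_tries} spacer randomisations"
    )


@dataclass(frozen=True)
class AssemblyState:
    """An intermediate ligation product of the hierarchical assembly."""

    unit_count: int
    step_index: int
    sequence: str
    left_overhang: str
    right_overhang: str
    block: BuildingBlock

    def __post_init__(self) -> None:
        if self.unit_count < 1:
            raise ValueError("unit_count must be positive")


def initial_state(block: BuildingBlock) -> AssemblyState:
    """The 1-unit state after the initial block construction (step one)."""
    return AssemblyState(
        unit_count=1,
        step_index=1,
        sequence=block.core,
        left_overhang=block.left_overhang,
        right_overhang=block.right_overhang,
        block=block,
    )


def simulate_assembly_cycle(state: AssemblyState, partner: AssemblyState) -> AssemblyState:
    """Ligate two digested inserts; unit counts add, one OL1 forms at the junction."""
    if state.block.core != partner.block.core:
        raise ValueError("both states must derive from the same building-block design")
    if state.right_overhang != partner.left_overhang:
        raise OverhangMismatchError(
            f"right overhang {state.right_overhang!r} does not match "
            f"partner left overhang {partner.left_overhang!r}"
        )
    return AssemblyState(
        unit_count=state.unit_count + partner.unit_count,
        step_index=max(state.step_index, partner.step_index) + 1,
        sequence=state.sequence + partner.sequence,
        left_overhang=state.left_overhang,
        right_overhang=partner.right_overhang,
        block=state.block,
    )


@dataclass(frozen=True)
class HybridArray:
    """A finalised hybrid operator array ready for genomic integration."""

    sequence: str
    n_units: int
    n_ol1: int
    n_uas: int
    assembly_steps: int
    block: BuildingBlock | None = field(default=None, compare=False)


def assemble_to_target(block: BuildingBlock, target_units: int) -> HybridArray:
    """Simulate hierarchical doubling assembly up to ``target_units`` repeats.

    ``target_units`` must be a power of two (the scheme doubles the insert in
    every post-initial cycle).  Finalisation appends the missing OL1 tail
    half-site so the emitted array contains exactly ``target_units`` complete
    OL1 motifs alongside ``target_units`` UAS motifs.
    """
    if target_units < 1 or target_units & (target_units - 1):
        raise ValueError(
            f"target_units={target_units}: the doubling assembly scheme can "
            "only reach powers of two"
        )
    state = initial_state(block)
    for _ in range(int(math.log2(target_units))):
        state = simulate_assembly_cycle(state, state)
    sequence = state.sequence + block.ol1.right_half  # terminal OL1 completion
    array = HybridArray(
        sequence=sequence,
        n_units=state.unit_count,
        n_ol1=count_motifs_seq(sequence, block.ol1),
        n_uas=count_motifs_seq(sequence, block.uas_motif),
        assembly_steps=state.step_index,
        block=block,
    )
    return array


def find_motifs(sequence: str, motif: OperatorMotif) -> list[tuple[int, int, int]]:
    """All non-overlapping motif occurrences on either strand.

    Returns ``(start, end, strand)`` tuples with 0-based half-open coordinates
    on the forward sequence and strand +1/-1.  A site whose reverse complement
    coincides with a forward hit (palindrome) is reported once.
    """
    hits: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for pattern, strand in ((motif.sequence, 1), (reverse_complement(motif.sequence), -1)):
        start = 0
        while True:
            idx = sequence.find(pattern, start)
            if idx < 0:
                break
            iv = (idx, idx + len(pattern))
            if iv not in seen:
                seen.add(iv)
                hits.append((iv[0], iv[1], strand))
            start = idx + len(pattern)
    hits.sort()
    return hits


def count_motifs_seq(sequence: str, motif: OperatorMotif) -> int:
    return len(find_motifs(sequence, motif))


def count_motifs(array: HybridArray | AssemblyState | str, motif: OperatorMotif) -> int:
    """Exact count of non-overlapping motif occurrences, both strands scanned."""
    seq = array if isinstance(array, str) else array.sequence
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"array alphabet {sorted(bad)!r} incompatible with motif scan")
    return count_motifs_seq(seq, motif)


# --------------------------------------------------------------------------
# Split fluorescent reporter


@dataclass(frozen=True)
class ReporterSplitSpec:
    """Partition of a fluorescent protein into BiFC fragments.

    ``split_after`` is the 1-based residue index ending the N-terminal
    fragment; ``mutations`` are ``(position, from, to)`` substitutions (1-based)
    applied before splitting.
    """

    full_length: int = 238
    split_after: int = 154
    mutations: tuple[tuple[int, str, str], ...] = ((152, "I", "L"),)

    def __post_init__(self) -> None:
        if not (1 <= self.split_after < self.full_length):
            raise ValueError("split point must fall strictly inside the protein")


#: Default split of mVenus into its BiFC halves: residues 1-154 form the
#: N-terminal fragment (carrying the I152L substitution that suppresses
#: spontaneous self-assembly of the halves) and residues 155-238 the
#: C-terminal fragment.
MVENUS_SPLIT = ReporterSplitSpec(full_length=238, split_after=154,
                                 mutations=((152, "I", "L"),))


def _venus_like(length: int = 238, ile_at: int = 152, seed: int = 7) -> str:
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHKLMNPQRSTVWY"))  # no I: placed explicitly
    seq = list("M" + "".join(rng.choice(aa, size=length - 1)))
    seq[ile_at - 1] = "I"
    return "".join(seq)


#: Synthetic stand-in for the mVenus protein sequence (the real sequence is
#: not bundled): correct length (238 aa) and an isoleucine at position 152 so
#: the I152L mutation applies; residue content is otherwise arbitrary.  All
#: split arithmetic is independent of residue identity.
SYNTHETIC_VENUS_LIKE = _venus_like()


def split_reporter(spec: ReporterSplitSpec, sequence: str = SYNTHETIC_VENUS_LIKE) -> tuple[str, str]:
    """Apply the substitutions and split the reporter into its two fragments."""
    if len(sequence) != spec.full_length:
        raise ValueError(
            f"sequence length {len(sequence)} != spec.full_length {spec.full_length}"
        )
    residues = list(sequence)
    for pos, old, new in spec.mutations:
        if not (1 <= pos <= spec.full_length):
            raise ValueError(f"mutation position {pos} out of range")
        if residues[pos - 1] != old:
            raise ValueError(
                f"mutation {old}{pos}{new}: sequence has {residues[pos - 1]!r} at {pos}"
            )
        residues[pos - 1] = new
    mutated = "".join(residues)
    return mutated[: spec.split_after], mutated[spec.split_after :]
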