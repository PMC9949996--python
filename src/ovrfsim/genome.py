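"""Genome, ORF and reading-frame bookkeeping.

A genome is a linear or circular nucleotide sequence carrying zero or more
open reading frames (ORFs) on either strand. ORFs may overlap one another
in any of the six pairwise frameshift configurations (+0, +1, +2 on the
same strand; -0, -1, -2 on opposite strands), and on a circular genome an
ORF may wrap across the origin. This module classifies those overlaps,
partitions the sequence into regions of identical ORF membership, and
builds the per-site context records (codon indices per frame, protection
of terminal codons) that the substitution model consumes.

Coordinates are 0-based half-open internally; conversion from the 1-based
inclusive convention used in GenBank/YAML lives in :mod:`ovrfsim.io_formats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
MIN_GENOME_LENGTH = 9

# frame labels in canonical order; sign = strand relation, digit = shift
FRAME_LABELS = ("-2", "-1", "-0", "+0", "+1", "+2")


class GenomeError(ValueError):
    """Invalid genome, ORF geometry or frame query."""


class NoOverlapError(GenomeError):
    """Raised when a frameshift is requested for two non-overlapping ORFs."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class Genome:
    """A root nucleotide sequence with linear or circular topology."""

    sequence: str
    is_circular: bool = False

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_GENOME_LENGTH:
            raise GenomeError(
                f"sequence has {len(seq)} nt; minimum is {MIN_GENOME_LENGTH} nt"
            )
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise GenomeError(
                f"sequence contains non-ACGT characters {sorted(bad)}; "
                "ambiguity codes are rejected because every site needs a "
                "well-defined substitution rate"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """An open reading frame.

    ``segments`` are (start, end) 0-based half-open intervals stored in
    reading order on the forward strand (GenBank ``join`` order). A
    circular-origin wrap is exactly two segments, the first ending at the
    sequence length and the second starting at 0. For a ``-`` strand ORF
    the coding sequence is the reverse complement of the concatenated
    segments, so reading order runs through the segments backwards.
    """

    name: str
    segments: tuple[tuple[int, int], ...]
    strand: str = "+"
    omega_spec: Optional[object] = None  # rate_model.DistributionSpec
    mu_spec: Optional[object] = None

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        if self.strand not in "+-":
            raise GenomeError(f"ORF {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def validate(self, genome: Genome) -> None:
        if not self.segments:
            raise GenomeError(f"ORF {self.name}: no segments")
        if self.length <= 0 or self.length % 3 != 0:
            raise GenomeError(
                f"ORF {self.name}: total length {self.length} is not a "
                "positive multiple of 3"
            )
        L = genome.length
        for s, e in self.segments:
            if not (0 <= s < e <= L):
                raise GenomeError(
                    f"ORF {self.name}: segment ({s}, {e}) outside sequence "
                    f"bounds [0, {L})"
                )
        if len(self.segments) == 1:
            pass
        elif len(self.segments) == 2:
            if not genome.is_circular:
                raise GenomeError(
                    f"ORF {self.name}: multi-segment ORFs are only supported "
                    "as a circular-origin wrap"
                )
            (s1, e1), (s2, e2) = self.segments
            if not (e1 == L and s2 == 0):
                raise GenomeError(
                    f"ORF {self.name}: a wrapping ORF must be two segments "
                    "meeting at the origin (first ends at L, second starts at 0)"
                )
        else:
            raise GenomeError(
                f"ORF {self.name}: at most two segments (one origin wrap) "
                "are supported"
            )
        # self-overlap check
        seen: set[int] = set()
        for s, e in self.segments:
            block = set(range(s, e))
            if seen & block:
                raise GenomeError(f"ORF {self.name}: segments self-overlap")
            seen |= block

    def positions(self) -> list[int]:
        """Genome positions of the ORF in reading (5'→3' coding) order."""
        fwd: list[int] = []
        for s, e in self.segments:
            fwd.extend(range(s, e))
        if self.strand == "+":
            return fwd
        return fwd[::-1]

    def coding_sequence(self, sequence: str) -> str:
        raw = "".join(sequence[s:e] for s, e in self.segments)
        return raw if self.strand == "+" else reverse_complement(raw)


@dataclass(frozen=True)
class FrameLabel:
    """Pairwise frameshift label: sign = strand relation, digit = shift."""

    sign: str  # '+' same strand, '-' opposite
    shift: int  # 0, 1 or 2

    def __post_init__(self):
        if self.sign not in "+-" or self.shift not in (0, 1, 2):
            raise GenomeError(f"invalid frame label {self.sign}{self.shift}")

    @property
    def value(self) -> str:
        return f"{self.sign}{self.shift}"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Region:
    """Maximal set of sites sharing one ORF-membership set."""

    id: str
    sites: frozenset[int]
    orf_membership: frozenset[str]


@dataclass(frozen=True)
class SiteContext:
    """Per-site frame memberships and terminal-codon protection.

    ``frame_memberships`` holds (orf name, codon index, offset-in-codon)
    triples; ``protected`` marks sites in the first or last codon of any
    ORF, which are excluded from substitution sampling so that mutations
    never disrupt a start or stop codon.
    """

    position: int
    frame_memberships: tuple[tuple[str, int, int], ...]
    protected: bool


class Annotation:
    """Genome + validated ORFs with all derived per-site bookkeeping.

    Precomputes, once per run: reading-order position lists per ORF,
    per-site contexts, the region partition and a site→region index.
    """

    def __init__(self, genome: Genome, orfs: Sequence[Orf]):
        names = [o.name for o in orfs]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate ORF names")
        for orf in orfs:
            orf.validate(genome)
        self.genome = genome
        self.orfs: dict[str, Orf] = {o.name: o for o in orfs}
        self._positions: dict[str, list[int]] = {
            o.name: o.positions() for o in orfs
        }
        self._reading_index: dict[str, dict[int, int]] = {
            name: {p: i for i, p in enumerate(pos)}
            for name, pos in self._positions.items()
        }
        for orf in orfs:
            cds = orf.coding_sequence(genome.sequence)
            if not cds.startswith("ATG"):
                logger.warning("ORF %s does not begin with ATG", orf.name)
            if cds[-3:] not in ("TAA", "TAG", "TGA"):
                logger.warning("ORF %s does not end with a stop codon", orf.name)
        self.contexts = self._build_contexts()
        self.regions = self._build_regions()
        self.region_index: dict[int, int] = {}
        for ridx, region in enumerate(self.regions):
            for p in region.sites:
                self.region_index[p] = ridx

    def _build_contexts(self) -> list[SiteContext]:
        L = self.genome.length
        memberships: list[list[tuple[str, int, int]]] = [[] for _ in range(L)]
        protected = [False] * L
        for name, pos in self._positions.items():
            n_codons = len(pos) // 3
            for r, p in enumerate(pos):
                ci, off = divmod(r, 3)
                memberships[p].append((name, ci, off))
                if ci == 0 or ci == n_codons - 1:
                    protected[p] = True
        return [
            SiteContext(p, tuple(memberships[p]), protected[p]) for p in range(L)
        ]

    def _build_regions(self) -> list[Region]:
        by_membership: dict[frozenset[str], set[int]] = {}
        for ctx in self.contexts:
            key = frozenset(m[0] for m in ctx.frame_memberships)
            by_membership.setdefault(key, set()).add(ctx.position)
        regions = []
        # deterministic order: by smallest site
        for key, sites in sorted(by_membership.items(), key=lambda kv: min(kv[1])):
            rid = "|".join(sorted(key)) if key else "noncoding"
            regions.append(Region(rid, frozenset(sites), key))
        return regions

    def codon_positions(self, orf_name: str, codon_index: int) -> list[int]:
        """Genome positions (reading order) of one codon of an ORF."""
        pos = self._positions[orf_name]
        return pos[3 * codon_index : 3 * codon_index + 3]

    def codon_at(self, sequence: Sequence[str], position: int, orf_name: str
                 ) -> tuple[str, int]:
        """Codon of ``orf_name`` containing ``position`` in the current
        sequence, read on the ORF's own strand, plus the site's offset."""
        r = self._reading_index[orf_name].get(position)
        if r is None:
            raise GenomeError(f"position {position} not in ORF {orf_name}")
        ci, off = divmod(r, 3)
        codon = "".join(
            sequence[p] if self.orfs[orf_name].strand == "+" else
            COMPLEMENT[sequence[p]]
            for p in self.codon_positions(orf_name, ci)
        )
        return codon, off

    def codon_phase(self, orf_name: str, position: int) -> int:
        """Offset of ``position`` within its codon, along the ORF's strand."""
        return self._reading_index[orf_name][position] % 3


def classify_frameshift(a: Orf, b: Orf, genome: Genome) -> FrameLabel:
    """Frameshift label of ORF ``b`` relative to ORF ``a``.

    Sign is ``+`` iff the strands match; the digit is the offset of b's
    reading frame relative to a's, measured along a's reading direction
    (constant over the shared interval, including across a circular wrap).
    """
    a.validate(genome)
    b.validate(genome)
    pa = a.positions()
    pb = b.positions()
    shared = set(pa) & set(pb)
    if not shared:
        raise NoOverlapError(f"ORFs {a.name} and {b.name} do not overlap")
    idx_a = {p: i for i, p in enumerate(pa)}
    idx_b = {p: i for i, p in enumerate(pb)}
    p = next(iter(shared))
    ca = idx_a[p] % 3
    cb = idx_b[p] % 3
    same = a.strand == b.strand
    cb_on_a = cb if same else 2 - cb
    shift = (ca - cb_on_a) % 3
    return FrameLabel("+" if same else "-", shift)


def partition_regions(genome: Genome, orfs: Sequence[Orf]) -> list[Region]:
    """Partition sites into equivalence classes of identical ORF membership."""
    return Annotation(genome, orfs).regions


def site_contexts(genome: Genome, orfs: Sequence[Orf]) -> list[SiteContext]:
    """One :class:`SiteContext` per genome position."""
    return Annotation(genome, orfs).contexts


def codon_at(sequence: Sequence[str], annotation: Annotation, position: int,
             orf_name: str) -> tuple[str, int]:
    """Module-level convenience wrapper over :meth:`Annotation.codon_at`."""
    return annotation.codon_at(sequence, position, orf_name)
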