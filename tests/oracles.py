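"""Independent oracles used by the test suite.

These re-derive expected quantities by brute force, deliberately avoiding
the package's own event-tree / rate-model code paths: reading frames are
enumerated directly from ORF coordinates, synonymy is decided with
Biopython's translator, and event rates come from a flat enumeration over
all (site, target) pairs.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def reading_positions(segments, strand):
    """Genome positions of an ORF in coding order (independent arithmetic)."""
    fwd = [p for s, e in segments for p in range(s, e)]
    return fwd if strand == "+" else list(reversed(fwd))


def protected_positions(segments, strand):
    pos = reading_positions(segments, strand)
    return set(pos[:3]) | set(pos[-3:])


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def frameshift_shift(a_segments, a_strand, b_segments, b_strand) -> int:
    """Digit of b's frame relative to a, by enumerating codon boundaries.

    Only single-segment ORFs with ``a`` on the forward strand, which is
    all the randomized pair generator produces.
    """
    assert a_strand == "+" and len(a_segments) == 1 and len(b_segments) == 1
    (sa, _ea), (sb, eb) = a_segments[0], b_segments[0]
    phase_a = sa % 3
    # genome-leftmost codon boundaries of b are congruent to its start
    # (forward strand) or its end (reverse strand) mod 3
    phase_b = sb % 3 if b_strand == "+" else eb % 3
    return (phase_b - phase_a) % 3


def flat_event_rates(sequence, orfs, assignments, params, scale):
    """{(position, to_nt): rate} over every possible substitution event.

    ``orfs`` are (name, segments, strand) triples; omega/mu category
    values are read from the run's fixed assignments (shared input data,
    not implementation).
    """
    seq = list(sequence)
    L = len(seq)
    protected = set()
    per_orf = {}
    for name, segments, strand in orfs:
        protected |= protected_positions(segments, strand)
        per_orf[name] = (reading_positions(segments, strand), strand)
    rates = {}
    for pos in range(L):
        if pos in protected:
            continue
        cur = seq[pos]
        for to in "ACGT":
            if to == cur:
                continue
            omega = 1.0
            for name, (positions, strand) in per_orf.items():
                if pos not in positions:
                    continue
                r = positions.index(pos)
                ci = r // 3
                codon_pos = positions[3 * ci:3 * ci + 3]
                old = "".join(seq[p] for p in codon_pos)
                new = "".join(to if p == pos else seq[p] for p in codon_pos)
                if strand == "-":
                    old = str(Seq(old).complement())
                    new = str(Seq(new).complement())
                if translate_codon(old) != translate_codon(new):
                    omega *= assignments.omega_value(pos, name)
            lam = (scale * float(assignments.mu_value[pos])
                   * params.pi_of(to) * omega)
            if (cur, to) in TRANSITIONS:
                lam *= params.kappa
            rates[(pos, to)] = lam
    return rates


def quantile_bin_means(dist, ncat: int) -> np.ndarray:
    """Conditional means of equal-probability bins by adaptive quadrature."""
    from scipy import integrate

    edges = dist.ppf(np.linspace(0, 1, ncat + 1))
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_ = lo if np.isfinite(lo) else dist.ppf(1e-12)
        hi_ = hi if np.isfinite(hi) else dist.ppf(1 - 1e-12)
        val, _err = integrate.quad(lambda x: x * dist.pdf(x), lo_, hi_,
                                   limit=200)
        out.append(val * ncat)
    return np.array(out)
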