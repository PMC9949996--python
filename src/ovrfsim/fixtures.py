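"""Deterministic synthetic genomes, ORF layouts and random trees.

Everything the pipeline needs can be generated here from a seed, so the
full simulator runs and all property tests require no downloads. The
``hbv-like`` layout reproduces the coordinate *relations* of a small
circular DNA virus — four ORFs, one wrapping the origin, with +1 and +0
overlaps — without using any real accession.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .genome import Genome, Orf
from .rate_model import DistributionSpec
from .simulator import Phylogeny

STYLES = ("fig2", "hbv-like", "dense")

_DEFAULT_OMEGA = DistributionSpec(family="gamma", shape=2.0, scale=0.5, ncat=4)


@dataclass(frozen=True)
class OverlapLayout:
    """A generated ORF arrangement plus the genome topology it assumes."""

    style: str
    orfs: tuple[Orf, ...]
    circular: bool


def make_genome(length: int, gc_content: float = 0.5, seed: int = 0,
                circular: bool = False) -> Genome:
    """Random sequence with the requested expected GC fraction."""
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    seq = "".join(rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at]))
    return Genome(seq, is_circular=circular)


def _with_spec(orf: Orf, spec: DistributionSpec) -> Orf:
    return Orf(orf.name, orf.segments, orf.strand, omega_spec=spec)


def make_overlap_layout(style: str, length: int = 1200,
                        omega_spec: Optional[DistributionSpec] = None
                        ) -> OverlapLayout:
    """Generate one of the canned ORF arrangements.

    fig2:     three ORFs on a linear genome, one isolated and one
              overlapping pair, partitioning the sequence into exactly
              five regions.
    hbv-like: four ORFs on a circular genome; ORF P wraps the origin and
              is overlapped (+1) by ORF S, ORF C is overlapped (+0) by
              ORF X.
    dense:    two full-length ORFs on opposite strands; every site lies
              in at least two reading frames.
    """
    spec = omega_spec or _DEFAULT_OMEGA
    if style == "fig2":
        if length < 120:
            raise ValueError("fig2 layout needs length >= 120")

        def sn(x: int) -> int:  # scale the 120-nt template, snap to codons
            return 3 * round(x * length / 120 / 3)

        orfs = (
            Orf("a", ((sn(6), sn(36)),), "+", omega_spec=spec),
            Orf("b", ((sn(48), sn(90)),), "+", omega_spec=spec),
            Orf("c", ((sn(81), sn(111)),), "+", omega_spec=spec),
        )
        return OverlapLayout(style, orfs, circular=False)
    if style == "hbv-like":
        if length < 600:
            raise ValueError("hbv-like layout needs length >= 600")
        q = length // 4
        seg1 = (length - q, length)  # P wraps the origin
        e2 = q
        while (length - seg1[0] + e2) % 3:
            e2 += 1
        p = Orf("P", (seg1, (0, e2)), "+", omega_spec=spec)
        s_start = seg1[0] + q // 3
        s_start += (1 - (s_start - seg1[0])) % 3  # +1 shift relative to P
        s_len = 3 * max(4, q // 12)
        assert s_start + s_len <= length - 3
        s = Orf("S", ((s_start, s_start + s_len),), "+", omega_spec=spec)
        mid_lo, mid_hi = e2 + q // 6, length - q - q // 6
        c_start = mid_lo
        c_len = 3 * ((mid_hi - mid_lo) * 11 // 60)
        c = Orf("C", ((c_start, c_start + c_len),), "+", omega_spec=spec)
        overlap = 3 * max(5, c_len // 15)
        x_start = c_start + c_len - overlap  # +0 shift relative to C
        x_len = 3 * ((mid_hi - x_start) // 3 * 2 // 3)
        assert x_len > overlap and x_start + x_len <= mid_hi
        x = Orf("X", ((x_start, x_start + x_len),), "+", omega_spec=spec)
        return OverlapLayout(style, (p, s, c, x), circular=True)
    if style == "dense":
        if length % 3:
            raise ValueError("dense layout needs a length divisible by 3")
        orfs = (
            Orf("fwd", ((0, length),), "+", omega_spec=spec),
            Orf("rev", ((0, length),), "-", omega_spec=spec),
        )
        return OverlapLayout(style, orfs, circular=False)
    raise ValueError(f"unknown layout style {style!r}; choose from {STYLES}")


def make_tree(n_tips: int, total_depth: float = 1.0, seed: int = 0
              ) -> Phylogeny:
    """Random rooted binary ultrametric tree of the requested depth,
    built by successive random pair merges at increasing heights."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not total_depth > 0:
        raise ValueError("total_depth must be > 0")
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.exponential(size=n_tips - 1))
    times *= total_depth / times[-1]
    active: list[tuple[str, float]] = [(f"t{i + 1}", 0.0)
                                       for i in range(n_tips)]
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (ni, hi) = active[i]
        (nj, hj) = active[j]
        merged = f"({ni}:{t - hi:.12g},{nj}:{t - hj:.12g})"
        active[i] = (merged, float(t))
        active.pop(j)
    newick = active[0][0] + ";"
    return Phylogeny.from_newick(newick)


def write_fixture_set(outdir, style: str = "hbv-like", length: int = 1200,
                      n_tips: int = 20, total_depth: float = 1.0,
                      seed: int = 0, gc_content: float = 0.5) -> dict:
    """Write a ready-to-run FASTA + YAML + Newick triple; returns paths."""
    from .io_formats import (OrfConfig, RunConfig, to_external, write_config,
                             write_tree)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_overlap_layout(style, length)
    genome = make_genome(length, gc_content, seed, circular=layout.circular)
    fasta = outdir / "root.fasta"
    with open(fasta, "w") as handle:
        handle.write(f">root {style} synthetic\n")
        for i in range(0, genome.length, 70):
            handle.write(genome.sequence[i:i + 70] + "\n")
    orf_configs = tuple(
        OrfConfig(
            name=o.name,
            coords=tuple(to_external(s, e) for s, e in o.segments),
            strand=o.strand,
            omega=o.omega_spec,
        )
        for o in layout.orfs
    )
    config = RunConfig(circular=layout.circular, orfs=orf_configs)
    config_path = outdir / "config.yaml"
    write_config(config, config_path)
    tree_path = outdir / "tree.nwk"
    write_tree(make_tree(n_tips, total_depth, seed), tree_path)
    return {"fasta": str(fasta), "config": str(config_path),
            "tree": str(tree_path)}
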