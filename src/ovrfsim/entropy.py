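"""Shannon-entropy diagnostics of simulated alignments.

Per-column nucleotide entropy H = -sum_i P_i log2 P_i (0 for a conserved
column, 2 bits at equal frequencies of all four nucleotides), sliding-
window mean profiles (default width 20 nt, step 1), and region-stratified
summaries contrasting overlapping with non-overlapping coding sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome import NUCLEOTIDES, Region
from .simulator import TipAlignment

logger = logging.getLogger(__name__)


class EntropyError(ValueError):
    pass


def column_entropy(counts: Union[dict, Sequence[float]]) -> float:
    """Shannon entropy in bits of one alignment column's residue counts;
    0*log(0) is taken as 0."""
    if isinstance(counts, dict):
        values = np.array(list(counts.values()), dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
    total = values.sum()
    if total <= 0:
        raise EntropyError("column has no residues")
    p = values[values > 0] / total
    return float(-(p * np.log2(p)).sum())


def _as_matrix(alignment) -> np.ndarray:
    if isinstance(alignment, TipAlignment):
        seqs = list(alignment.sequences.values())
    elif isinstance(alignment, dict):
        seqs = list(alignment.values())
    else:
        seqs = list(alignment)
    if not seqs:
        raise EntropyError("empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise EntropyError("alignment rows differ in length")
    return np.array([list(s.upper()) for s in seqs])


def alignment_entropy(alignment) -> np.ndarray:
    """Per-column nucleotide entropy of an alignment (rows of equal
    length). Gap or ambiguity characters are excluded from the frequency
    counts with a warning."""
    mat = _as_matrix(alignment)
    known = np.zeros(mat.shape[1])
    h = np.zeros(mat.shape[1])
    plogp = np.zeros(mat.shape[1])
    counts = [(mat == nt).sum(axis=0) for nt in NUCLEOTIDES]
    known = np.sum(counts, axis=0).astype(float)
    if (known < mat.shape[0]).any():
        logger.warning("alignment contains non-ACGT characters; they are "
                       "excluded from entropy frequencies")
    if (known == 0).any():
        raise EntropyError("column with no unambiguous residues")
    for c in counts:
        p = c / known
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        plogp += term
    return np.maximum(-plogp, 0.0)


def sliding_window_mean(h: Sequence[float], width: int = 20, step: int = 1,
                        circular: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean entropy over sliding windows.

    Linear profiles yield only full windows (length - width + 1 starting
    offsets before stepping); circular profiles wrap and yield one window
    per position. Returns (window centers, means); centers are the
    midpoint offset start + (width - 1) / 2.
    """
    h = np.asarray(h, dtype=float)
    if width < 1 or step < 1:
        raise EntropyError("width and step must be >= 1")
    n = len(h)
    if circular:
        ext = np.concatenate([h, h[:width - 1]]) if width > 1 else h
        starts = np.arange(0, n, step)
    else:
        if n < width:
            raise EntropyError(
                f"alignment length {n} is shorter than window width {width}")
        ext = h
        starts = np.arange(0, n - width + 1, step)
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[starts + width] - csum[starts]) / width
    centers = starts + (width - 1) / 2.0
    return centers, means


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropies with windowed means and window geometry."""

    per_column: np.ndarray
    window_centers: np.ndarray
    window_means: np.ndarray
    width: int
    step: int
    circular: bool


def entropy_profile(alignment, width: int = 20, step: int = 1,
                    circular: bool = False) -> EntropyProfile:
    h = alignment_entropy(alignment)
    centers, means = sliding_window_mean(h, width, step, circular)
    return EntropyProfile(h, centers, means, width, step, circular)


def region_summary(h: Sequence[float], regions: Sequence[Region]
                   ) -> dict:
    """Mean and interquartile range of per-column entropy per region,
    plus a two-sided rank-sum comparison of overlapping (>= 2 ORFs)
    versus non-overlapping (exactly 1 ORF) coding sites.

    Quartiles use midpoint interpolation.
    """
    h = np.asarray(h, dtype=float)
    rows = []
    for region in regions:
        sites = sorted(region.sites)
        vals = h[sites]
        rows.append({
            "region": region.id,
            "n_orfs": len(region.orf_membership),
            "n_sites": len(sites),
            "mean": float(vals.mean()),
            "q1": float(np.percentile(vals, 25, method="midpoint")),
            "q3": float(np.percentile(vals, 75, method="midpoint")),
        })
    table = pd.DataFrame(rows)
    overlap = np.concatenate([
        h[sorted(r.sites)] for r in regions if len(r.orf_membership) >= 2
    ]) if any(len(r.orf_membership) >= 2 for r in regions) else np.array([])
    single = np.concatenate([
        h[sorted(r.sites)] for r in regions if len(r.orf_membership) == 1
    ]) if any(len(r.orf_membership) == 1 for r in regions) else np.array([])
    comparison: Optional[dict] = None
    if overlap.size and single.size:
        stat, pvalue = stats.mannwhitneyu(overlap, single,
                                          alternative="two-sided")
        comparison = {
            "mean_overlap": float(overlap.mean()),
            "mean_nonoverlap": float(single.mean()),
            "statistic": float(stat),
            "pvalue": float(pvalue),
        }
    return {"regions": table, "overlap_vs_nonoverlap": comparison}
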