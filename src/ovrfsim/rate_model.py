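"""Per-event substitution rates with multiplicative selection across frames.

The substitution process is HKY-like at the nucleotide level: an event at
site i changing the residue to j has rate

    lambda_ij = mu_i * pi_j                (synonymous/non-coding transversion)
              = mu_i * kappa * pi_j        (synonymous/non-coding transition)
              = mu_i * omega * pi_j        (non-synonymous transversion)
              = mu_i * omega * kappa * pi_j  (non-synonymous transition)

where omega is the product of a six-entry selection vector w over the
reading-frame contexts {-2,-1,-0,+0,+1,+2}: each frame in which the event
is non-synonymous contributes that site's assigned dN/dS category for the
corresponding ORF, every other entry is 1. Site-to-site variation in both
mu and omega comes from gamma or lognormal distributions discretized into
equal-probability categories represented by their bin conditional means.

Note on the gamma parameterization: ``shape`` is the usual alpha and
``scale`` the usual scale (mean = shape * scale). With shape 2 and
scale 0.5 the four equal-probability categories are 0.293, 0.655, 1.070
and 1.982, with mean exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome import COMPLEMENT, NUCLEOTIDES, Annotation, SiteContext

logger = logging.getLogger(__name__)

#: standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop)
GENETIC_CODE: dict[str, str] = {}


def _init_genetic_code() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    GENETIC_CODE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        GENETIC_CODE[stop] = "*"


_init_genetic_code()

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True iff a->b is a transition (A<->G or C<->T)."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


class RateModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionParams:
    """Global substitution-model parameters.

    kappa: transition/transversion rate multiplier (default 0.3).
    pi: stationary target-nucleotide frequencies in A, C, G, T order;
        defaults to the empirical frequencies of the root sequence.
    global_rate: expected substitutions per neutral site per unit branch
        length; branch lengths are interpreted in these units.
    """

    kappa: float = 0.3
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    global_rate: float = 1.0

    def __post_init__(self):
        if not self.kappa > 0:
            raise RateModelError(f"kappa must be > 0, got {self.kappa}")
        pi = tuple(float(p) for p in self.pi)
        object.__setattr__(self, "pi", pi)
        if len(pi) != 4 or any(p <= 0 for p in pi):
            raise RateModelError("pi must be 4 positive frequencies")
        if abs(sum(pi) - 1.0) > 1e-9:
            raise RateModelError(f"pi must sum to 1, got {sum(pi)}")
        if not self.global_rate > 0:
            raise RateModelError("global_rate must be > 0")

    def pi_of(self, nt: str) -> float:
        return self.pi[NUCLEOTIDES.index(nt)]

    @classmethod
    def with_empirical_pi(cls, sequence: str, kappa: float = 0.3,
                          global_rate: float = 1.0) -> "SubstitutionParams":
        counts = np.array([sequence.count(nt) for nt in NUCLEOTIDES], float)
        if (counts == 0).any():
            # keep pi strictly positive on degenerate sequences
            counts += 1.0
        pi = tuple(counts / counts.sum())
        return cls(kappa=kappa, pi=pi, global_rate=global_rate)


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of a rate distribution to be discretized.

    family: 'gamma' (shape alpha, scale beta), 'lognormal' (shape = sigma
    of the underlying normal, scale = exp(mu), i.e. the median), or
    'constant' (``value``).
    """

    family: str
    shape: Optional[float] = None
    scale: float = 1.0
    ncat: int = 1
    value: Optional[float] = None

    def __post_init__(self):
        if self.family not in ("gamma", "lognormal", "constant"):
            raise RateModelError(f"unknown distribution family {self.family!r}")
        if self.ncat < 1:
            raise RateModelError("ncat must be >= 1")
        if self.family == "constant":
            if self.value is None or not self.value > 0:
                raise RateModelError("constant family requires a positive value")
        else:
            if self.shape is None or not self.shape > 0 or not self.scale > 0:
                raise RateModelError(
                    f"{self.family} family requires positive shape and scale"
                )


@dataclass(frozen=True)
class CategorySet:
    """Equal-probability rate categories (bin conditional means)."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise RateModelError(f"non-finite or non-positive category: {vals}")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise RateModelError("categories must be nondecreasing")

    @property
    def ncat(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def discretize(spec: DistributionSpec) -> CategorySet:
    """Discretize into ``ncat`` equal-probability quantile bins, each
    represented by its conditional mean.

    The conditional means are computed in closed form: for a gamma with
    shape a and scale s, E[X | q_k < X <= q_{k+1}] uses the identity
    x*pdf_a(x) = a*s*pdf_{a+1}(x); for a lognormal, the analogous shifted
    normal-CDF identity. The telescoping sum of bin means times 1/ncat
    recovers the continuous mean exactly.
    """
    n = spec.ncat
    if spec.family == "constant":
        return CategorySet((spec.value,) * n)
    probs = np.linspace(0.0, 1.0, n + 1)
    if spec.family == "gamma":
        a, s = spec.shape, spec.scale
        edges = stats.gamma.ppf(probs, a, scale=s)
        upper_cdf = stats.gamma.cdf(edges, a + 1, scale=s)
        means = a * s * np.diff(upper_cdf) * n
    else:  # lognormal
        sigma, scale = spec.shape, spec.scale
        mu = np.log(scale)
        edges = stats.lognorm.ppf(probs, sigma, scale=scale)
        with np.errstate(divide="ignore"):
            z = (np.log(edges) - mu - sigma**2) / sigma
        z[0], z[-1] = -np.inf, np.inf
        mean_total = np.exp(mu + sigma**2 / 2)
        means = mean_total * np.diff(stats.norm.cdf(z)) * n
    if not np.all(np.isfinite(means)):
        raise RateModelError(f"non-finite conditional means: {means}")
    return CategorySet(tuple(means))


@dataclass(frozen=True)
class OmegaVector:
    """Selection vector w over the six frame contexts.

    Entries default to 1; a frame in which the substitution is
    non-synonymous carries the affected site's omega category for the
    ORF occupying that frame. ORF frame labels are taken relative to the
    forward frame anchored at genome position 0; if two ORFs share a
    label their factors multiply into the same slot (the product, which
    is what enters the rate, is unaffected).
    """

    entries: tuple[float, float, float, float, float, float] = (1.0,) * 6

    def __post_init__(self):
        e = tuple(float(x) for x in self.entries)
        object.__setattr__(self, "entries", e)
        if len(e) != 6 or any(x <= 0 for x in e):
            raise RateModelError("OmegaVector needs 6 positive entries")

    @classmethod
    def from_factors(cls, factors: dict[str, float]) -> "OmegaVector":
        """Build from {frame label value: factor}; missing labels are 1."""
        from .genome import FRAME_LABELS

        entries = []
        for lab in FRAME_LABELS:
            entries.append(factors.get(lab, 1.0))
        return cls(tuple(entries))


def omega_product(w: OmegaVector) -> float:
    """Total selective effect omega = product of the six entries; 1 for a
    fully synonymous or non-coding event."""
    return float(np.prod(w.entries))


def event_rate(mu: float, params: SubstitutionParams, to_nt: str,
               transition: bool, omega: float) -> float:
    """lambda_ij for one candidate substitution; synonymous-in-all-frames
    events are exactly omega = 1."""
    rate = mu * params.pi_of(to_nt) * omega
    if transition:
        rate *= params.kappa
    return rate


class SiteRateAssignments:
    """Fixed per-site rate-category draws for one simulation run.

    Each site draws one global mu category; each site of each ORF draws
    one omega category from that ORF's set. ORF-level mu specifications,
    when present, contribute an extra per-site multiplier on mu.
    Assignments are made once, before any branch is simulated, and are
    never resampled along the tree.
    """

    def __init__(self, annotation: Annotation, mu_set: CategorySet,
                 omega_sets: dict[str, CategorySet], rng: np.random.Generator,
                 orf_mu_sets: Optional[dict[str, CategorySet]] = None):
        L = annotation.genome.length
        self.mu_set = mu_set
        self.omega_sets = omega_sets
        self.mu_category = rng.integers(mu_set.ncat, size=L)
        mu_vals = np.asarray(mu_set.values)[self.mu_category]
        self.omega_category: dict[str, dict[int, int]] = {}
        self.mu_mult_category: dict[str, dict[int, int]] = {}
        orf_mu_sets = orf_mu_sets or {}
        for name in annotation.orfs:
            pos = annotation._positions[name]
            draws = rng.integers(omega_sets[name].ncat, size=len(pos))
            self.omega_category[name] = dict(zip(pos, (int(d) for d in draws)))
            if name in orf_mu_sets:
                mset = orf_mu_sets[name]
                mdraws = rng.integers(mset.ncat, size=len(pos))
                self.mu_mult_category[name] = dict(
                    zip(pos, (int(d) for d in mdraws))
                )
                for p, d in zip(pos, mdraws):
                    mu_vals[p] *= mset.values[d]
        self.orf_mu_sets = orf_mu_sets
        #: effective per-site mu (global category times any ORF multipliers)
        self.mu_value = mu_vals

    def omega_value(self, position: int, orf_name: str) -> float:
        idx = self.omega_category[orf_name][position]
        return self.omega_sets[orf_name].values[idx]

    def __getitem__(self, position: int) -> "SiteRateAssignment":
        omega = {
            name: cats[position]
            for name, cats in self.omega_category.items()
            if position in cats
        }
        return SiteRateAssignment(position, int(self.mu_category[position]), omega)


@dataclass(frozen=True)
class SiteRateAssignment:
    """View of one site's fixed category indices."""

    position: int
    mu_category: int
    omega_categories: dict[str, int]


def assign_site_categories(annotation: Annotation, mu_set: CategorySet,
                           omega_sets: dict[str, CategorySet],
                           rng: np.random.Generator,
                           orf_mu_sets: Optional[dict[str, CategorySet]] = None
                           ) -> SiteRateAssignments:
    return SiteRateAssignments(annotation, mu_set, omega_sets, rng, orf_mu_sets)


def orf_frame_labels(annotation: Annotation) -> dict[str, str]:
    """Frame label of each ORF relative to the forward frame at position 0."""
    labels = {}
    for name, orf in annotation.orfs.items():
        pos = annotation._positions[name]
        if orf.strand == "+":
            shift = pos[0] % 3
        else:
            # leftmost genome position of codon 0 anchors the frame
            shift = pos[2] % 3
        labels[name] = f"{orf.strand}{shift}"
    return labels


def nonsynonymous_orfs(annotation: Annotation, sequence: Sequence[str],
                       context: SiteContext, to_nt: str) -> list[str]:
    """Names of ORFs in which substituting ``to_nt`` changes the amino acid."""
    pos = context.position
    hits = []
    for orf_name, _ci, _off in context.frame_memberships:
        codon, off = annotation.codon_at(sequence, pos, orf_name)
        strand = annotation.orfs[orf_name].strand
        new_nt = to_nt if strand == "+" else COMPLEMENT[to_nt]
        new_codon = codon[:off] + new_nt + codon[off + 1:]
        if GENETIC_CODE[codon] != GENETIC_CODE[new_codon]:
            hits.append(orf_name)
    return hits


def event_selection(annotation: Annotation, assignments: SiteRateAssignments,
                    sequence: Sequence[str], context: SiteContext, to_nt: str
                    ) -> tuple[tuple[tuple[str, int], ...], float]:
    """Canonical omega-combination key and its product for one event.

    The key is the sorted multiset of (ORF name, omega category index)
    pairs over the frames where the event is non-synonymous; the product
    of the corresponding category values is the total selective effect.
    """
    pos = context.position
    key = tuple(sorted(
        (name, assignments.omega_category[name][pos])
        for name in nonsynonymous_orfs(annotation, sequence, context, to_nt)
    ))
    omega = 1.0
    for name, idx in key:
        omega *= assignments.omega_sets[name].values[idx]
    return key, omega


def substitution_effect(annotation: Annotation,
                        assignments: SiteRateAssignments,
                        sequence: Sequence[str], context: SiteContext,
                        to_nt: str,
                        frame_labels: Optional[dict[str, str]] = None
                        ) -> OmegaVector:
    """Selection vector w for substituting ``to_nt`` at ``context.position``.

    For each ORF membership the affected codon is translated before and
    after the change on the ORF's own strand; an amino-acid change sets
    that frame's entry to the site's assigned omega category for the ORF.
    A change creating a premature internal stop codon is treated as
    non-synonymous in that frame (only terminal codons are protected).
    """
    if context.protected:
        raise RateModelError("protected sites carry no substitution events")
    pos = context.position
    cur = sequence[pos]
    if to_nt == cur:
        raise RateModelError("to_nt equals the current residue")
    if frame_labels is None:
        frame_labels = orf_frame_labels(annotation)
    factors: dict[str, float] = {}
    for orf_name in nonsynonymous_orfs(annotation, sequence, context, to_nt):
        label = frame_labels[orf_name]
        w = assignments.omega_value(pos, orf_name)
        factors[label] = factors.get(label, 1.0) * w
    return OmegaVector.from_factors(factors)
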