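"""The event probability tree: hierarchical storage of substitution events.

Every possible substitution event at every unprotected site is stored at
exactly one tip of a five-level tree whose levels factor the event rate:

    target nucleotide j -> transition/transversion -> mu signature
        -> region (ORF-membership class) -> omega-combination class

All events at one tip share an identical rate, so sampling proceeds by
walking root to tip choosing each child with probability proportional to
its cached subtree weight, then picking a member uniformly. This makes
the sampled event distribution exactly lambda_e / Lambda, equivalent to a
flat weighted draw over all events, while updates after a substitution
touch only the affected codon neighborhoods.

The "mu signature" is the site's global mutation-rate category together
with any ORF-level mu multiplier categories, so that tip members always
share one mu value.

Rates are scaled at construction so that an average neutral site accrues
``global_rate`` substitutions per unit branch length (see
:class:`ovrfsim.rate_model.SubstitutionParams`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .genome import NUCLEOTIDES, Annotation
from .rate_model import (
    SiteRateAssignments,
    SubstitutionParams,
    event_selection,
    is_transition,
)

# relative tolerance for the shared-rate assertion within a tip subset
_TIP_RATE_RTOL = 1e-9


class EventTreeError(RuntimeError):
    pass


@dataclass(frozen=True)
class EventRecord:
    """One concrete substitution event and its current rate."""

    position: int
    from_nt: str
    to_nt: str
    rate: float


class _TipSet:
    """Indexed set of positions sharing one event rate (swap-pop removal)."""

    __slots__ = ("lam", "items", "index")

    def __init__(self, lam: float):
        self.lam = lam
        self.items: list[int] = []
        self.index: dict[int, int] = {}

    def add(self, pos: int) -> None:
        self.index[pos] = len(self.items)
        self.items.append(pos)

    def extend(self, positions) -> None:
        base = len(self.items)
        self.items.extend(positions)
        self.index.update((p, base + i) for i, p in enumerate(positions))

    def remove(self, pos: int) -> None:
        i = self.index.pop(pos)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.index[last] = i

    def copy(self) -> "_TipSet":
        new = _TipSet.__new__(_TipSet)
        new.lam = self.lam
        new.items = list(self.items)
        new.index = dict(self.index)
        return new

    def __len__(self) -> int:
        return len(self.items)


class EventTree:
    """Event probability tree bound to an evolving sequence.

    The tree owns the mutable ``sequence`` (a list of single characters);
    :class:`~ovrfsim.simulator.SimulationState` mutates it and calls
    :meth:`update_after_substitution`.
    """

    def __init__(self, annotation: Annotation,
                 assignments: SiteRateAssignments,
                 params: SubstitutionParams,
                 sequence: Optional[list[str]] = None,
                 scale: Optional[float] = None):
        self.annotation = annotation
        self.assignments = assignments
        self.params = params
        self.sequence = (list(annotation.genome.sequence)
                         if sequence is None else list(sequence))
        if len(self.sequence) != annotation.genome.length:
            raise EventTreeError("sequence length does not match annotation")
        self.scale = self._compute_scale() if scale is None else float(scale)
        # nodes[prefix] maps next key component -> cached subtree weight,
        # for prefixes of length 0..4; full 5-component keys index `tips`.
        self.nodes: dict[tuple, dict] = {(): {}}
        self.tips: dict[tuple, _TipSet] = {}
        self._build()
        if not self.tips:
            raise EventTreeError("no simulatable events: every site is "
                                 "protected or the genome has no targets")

    # -- construction -----------------------------------------------------

    def _neutral_site_factor(self, nt: str) -> float:
        """Total neutral substitution rate of a site holding ``nt`` before
        scaling: sum over targets of pi_j times kappa for transitions."""
        total = 0.0
        for to in NUCLEOTIDES:
            if to == nt:
                continue
            w = self.params.pi_of(to)
            if is_transition(nt, to):
                w *= self.params.kappa
            total += w
        return total

    def _compute_scale(self) -> float:
        """Normalize so the mean neutral per-site rate is ``global_rate``."""
        factors = np.array([self._neutral_site_factor(nt) for nt in NUCLEOTIDES])
        codes = np.array([NUCLEOTIDES.index(c) for c in self.sequence])
        lam_neutral = float(np.sum(self.assignments.mu_value * factors[codes]))
        L = len(self.sequence)
        return self.params.global_rate * L / lam_neutral

    def _mu_signature(self, pos: int) -> tuple:
        a = self.assignments
        mults = tuple(sorted(
            (name, cats[pos])
            for name, cats in a.mu_mult_category.items() if pos in cats
        ))
        return (int(a.mu_category[pos]), mults)

    def _compute_events(self, pos: int) -> list[tuple[str, tuple, float]]:
        """(to_nt, tip key, rate) for every candidate event at ``pos``."""
        ctx = self.annotation.contexts[pos]
        if ctx.protected:
            return []
        cur = self.sequence[pos]
        mu_sig = self._mu_signature(pos)
        region = self.annotation.region_index[pos]
        mu = float(self.assignments.mu_value[pos])
        out = []
        for to in NUCLEOTIDES:
            if to == cur:
                continue
            if ctx.frame_memberships:
                okey, omega = event_selection(
                    self.annotation, self.assignments, self.sequence, ctx, to)
            else:
                okey, omega = (), 1.0
            ti = is_transition(cur, to)
            lam = self.scale * mu * self.params.pi_of(to) * omega
            if ti:
                lam *= self.params.kappa
            out.append((to, (to, ti, mu_sig, region, okey), lam))
        return out

    def _build(self) -> None:
        ann = self.annotation
        # bulk path: unprotected sites outside every ORF share event keys
        # within (current nt, mu category) groups
        ctxs = ann.contexts
        nc_positions = [p for p in range(len(ctxs))
                        if not ctxs[p].frame_memberships]
        coding = [p for p in range(len(ctxs))
                  if ctxs[p].frame_memberships and not ctxs[p].protected]
        if nc_positions:
            nc = np.asarray(nc_positions)
            region = ann.region_index[nc_positions[0]]
            codes = np.array([NUCLEOTIDES.index(self.sequence[p])
                              for p in nc_positions])
            mu_cat = self.assignments.mu_category[nc]
            mu_values = self.assignments.mu_set.values
            for ci, cur in enumerate(NUCLEOTIDES):
                for cat in range(self.assignments.mu_set.ncat):
                    group = nc[(codes == ci) & (mu_cat == cat)]
                    if group.size == 0:
                        continue
                    positions = [int(p) for p in group]
                    for to in NUCLEOTIDES:
                        if to == cur:
                            continue
                        ti = is_transition(cur, to)
                        lam = (self.scale * mu_values[cat]
                               * self.params.pi_of(to))
                        if ti:
                            lam *= self.params.kappa
                        key = (to, ti, (cat, ()), region, ())
                        self._add_bulk(key, lam, positions)
        for pos in coding:
            for _to, key, lam in self._compute_events(pos):
                self._add_event(key, lam, pos)

    # -- weight bookkeeping -----------------------------------------------

    def _propagate(self, key: tuple, delta: float) -> None:
        for level in range(5):
            node = self.nodes.setdefault(key[:level], {})
            node[key[level]] = node.get(key[level], 0.0) + delta

    def _get_tip(self, key: tuple, lam: float) -> _TipSet:
        tip = self.tips.get(key)
        if tip is None:
            tip = self.tips[key] = _TipSet(lam)
        elif abs(tip.lam - lam) > _TIP_RATE_RTOL * tip.lam:
            raise EventTreeError(
                f"events with unequal rates ({tip.lam} vs {lam}) grouped "
                f"at one tip {key}")
        return tip

    def _add_event(self, key: tuple, lam: float, pos: int) -> None:
        self._get_tip(key, lam).add(pos)
        self._propagate(key, lam)

    def _add_bulk(self, key: tuple, lam: float, positions: list[int]) -> None:
        self._get_tip(key, lam).extend(positions)
        self._propagate(key, lam * len(positions))

    def _remove_event(self, key: tuple, pos: int) -> None:
        tip = self.tips[key]
        tip.remove(pos)
        self._propagate(key, -tip.lam)
        if not tip:
            del self.tips[key]
            for level in range(4, -1, -1):
                prefix = key[:level]
                child = key[:level + 1]
                alive = key in self.tips if level == 4 else child in self.nodes
                if alive:
                    break
                self.nodes[prefix].pop(key[level], None)
                if self.nodes[prefix] or level == 0:
                    break
                del self.nodes[prefix]

    # -- public interface ---------------------------------------------------

    @property
    def total(self) -> float:
        """Lambda: summed rate of all events in the tree."""
        return sum(self.nodes[()].values())

    def sample_event(self, rng: np.random.Generator) -> EventRecord:
        """Draw one event with probability lambda_event / Lambda by
        weight-proportional root-to-tip traversal, then a uniform pick
        within the tip's equal-rate subset."""
        key: tuple = ()
        for _level in range(5):
            node = self.nodes[key]
            r = rng.random() * sum(node.values())
            acc = 0.0
            comp = None
            for c, w in node.items():
                if w <= 0.0:
                    continue
                acc += w
                comp = c
                if r < acc:
                    break
            if comp is None:
                raise EventTreeError("sampled from an empty event tree")
            key = key + (comp,)
        tip = self.tips[key]
        pos = tip.items[int(rng.integers(len(tip.items)))]
        return EventRecord(pos, self.sequence[pos], key[0], tip.lam)

    def affected_positions(self, pos: int) -> list[int]:
        """The mutated site plus every site sharing a codon with it in any
        reading frame; these are the events re-derived after a change."""
        ann = self.annotation
        out = {pos}
        for orf_name, ci, _off in ann.contexts[pos].frame_memberships:
            out.update(ann.codon_positions(orf_name, ci))
        return sorted(out)

    def update_after_substitution(self, event: EventRecord) -> None:
        """Re-derive all events whose rate or classification may have
        changed. Call after the substitution has been applied to
        ``self.sequence``; the incremental result is identical to a fresh
        build on the updated sequence."""
        pos = event.position
        if self.sequence[pos] != event.to_nt:
            raise EventTreeError("sequence does not reflect the event")
        affected = self.affected_positions(pos)
        # old keys are recomputed under the pre-event sequence
        self.sequence[pos] = event.from_nt
        old = {p: self._compute_events(p) for p in affected}
        for p, events in old.items():
            for _to, key, _lam in events:
                self._remove_event(key, p)
        self.sequence[pos] = event.to_nt
        for p in affected:
            for _to, key, lam in self._compute_events(p):
                self._add_event(key, lam, p)

    def deep_copy(self) -> "EventTree":
        """Independent copy sharing only the immutable annotation,
        assignments and parameters."""
        new = EventTree.__new__(EventTree)
        new.annotation = self.annotation
        new.assignments = self.assignments
        new.params = self.params
        new.sequence = list(self.sequence)
        new.scale = self.scale
        new.nodes = {prefix: dict(node) for prefix, node in self.nodes.items()}
        new.tips = {key: tip.copy() for key, tip in self.tips.items()}
        return new

    def all_events(self) -> Iterator[EventRecord]:
        """Flat iteration over every stored event (testing/diagnostics)."""
        for key, tip in self.tips.items():
            for pos in tip.items:
                yield EventRecord(pos, self.sequence[pos], key[0], tip.lam)

    def n_events(self) -> int:
        return sum(len(t) for t in self.tips.values())

    def validate_weights(self, rtol: float = 1e-9) -> None:
        """Check cached weights against child sums at every node."""
        for prefix, node in self.nodes.items():
            for comp, w in node.items():
                child = prefix + (comp,)
                if len(child) == 5:
                    expect = self.tips[child].lam * len(self.tips[child])
                else:
                    expect = sum(self.nodes[child].values())
                if abs(w - expect) > rtol * max(abs(expect), 1e-300):
                    raise EventTreeError(
                        f"weight mismatch at {child}: cached {w}, "
                        f"children sum {expect}")

    def dump(self) -> dict:
        """JSON-able snapshot of weights per level (debug output)."""
        return {
            "total": self.total,
            "n_events": self.n_events(),
            "nodes": {
                repr(prefix): {repr(c): w for c, w in node.items()}
                for prefix, node in self.nodes.items()
            },
        }


def build(annotation: Annotation, assignments: SiteRateAssignments,
          params: SubstitutionParams, sequence: Optional[list[str]] = None,
          scale: Optional[float] = None) -> EventTree:
    """Build an event tree for the current sequence (root by default)."""
    return EventTree(annotation, assignments, params, sequence, scale)
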