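"""Gillespie simulation of substitutions along a rooted phylogeny.

The root sequence seeds a :class:`SimulationState` (sequence + event
tree). Along each branch, exponential waiting times with rate Lambda (the
summed event rate) are drawn; while the accumulated time stays within the
branch length an event is sampled with probability lambda/Lambda, applied,
and the event tree updated. When the waiting time overshoots the branch,
the current sequence is propagated to the child node. Nodes are visited
in level order; the state (sequence plus a deep copy of the event tree)
is duplicated at every internal node, one copy per child branch. Branch
lengths are in units of expected substitutions per neutral site divided
by ``global_rate`` (so global_rate 0.01 over a branch of length 1 yields
0.01 substitutions per site on average, absent selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .event_tree import EventRecord, EventTree
from .genome import Genome, Orf, Annotation
from .rate_model import (
    CategorySet,
    DistributionSpec,
    SubstitutionParams,
    assign_site_categories,
    discretize,
)

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


class TreeError(ValueError):
    """Invalid phylogeny (unrooted, missing branch lengths, ...)."""


class Phylogeny:
    """A rooted tree with branch lengths, backed by dendropy."""

    def __init__(self, tree: dendropy.Tree, allow_polytomy: bool = False):
        self.tree = tree
        self.validate(allow_polytomy)

    @classmethod
    def from_newick(cls, newick: str, allow_polytomy: bool = False
                    ) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise TreeError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree, allow_polytomy)

    def validate(self, allow_polytomy: bool = False) -> None:
        root = self.tree.seed_node
        n_children = len(root.child_nodes())
        if n_children < 2:
            raise TreeError("tree must have a root with at least two children")
        if n_children > 2 and not allow_polytomy:
            raise TreeError(
                f"root has {n_children} children (basal polytomy); the tree "
                "is treated as unrooted — resolve it or allow polytomies")
        labels = []
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError("tree must contain branch lengths on every edge")
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("every tip must be labelled")
                labels.append(node.taxon.label)
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels must be unique")

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def total_branch_length(self) -> float:
        return sum(
            node.edge.length or 0.0
            for node in self.tree.preorder_node_iter()
            if node is not self.tree.seed_node
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class LogEntry:
    """One applied substitution."""

    branch: str
    time: float  # elapsed time within the branch
    position: int
    from_nt: str
    to_nt: str


class SimulationState:
    """Evolving sequence + event tree + substitution log for one lineage."""

    def __init__(self, tree: EventTree, log: Optional[list[LogEntry]] = None):
        self.tree = tree
        self.log: list[LogEntry] = [] if log is None else log

    @property
    def sequence(self) -> str:
        return "".join(self.tree.sequence)

    def copy(self) -> "SimulationState":
        return SimulationState(self.tree.deep_copy(), list(self.log))

    def apply_substitution(self, event: EventRecord, time: float = 0.0,
                           branch: str = "") -> None:
        pos = event.position
        ctx = self.tree.annotation.contexts[pos]
        assert not ctx.protected, "event sampled at a protected site"
        assert self.tree.sequence[pos] == event.from_nt
        self.tree.sequence[pos] = event.to_nt
        self.tree.update_after_substitution(event)
        self.log.append(LogEntry(branch, time, pos, event.from_nt, event.to_nt))


@dataclass(frozen=True)
class TipAlignment:
    """Evolved sequences at the tips, all of genome length."""

    sequences: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise SimulationError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise SimulationError("tip sequences differ in length")

    @property
    def labels(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def __getitem__(self, label: str) -> str:
        return self.sequences[label]

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


def build_root_state(genome: Genome, orfs: Sequence[Orf],
                     params: SubstitutionParams, mu_spec: DistributionSpec,
                     rng: np.random.Generator) -> SimulationState:
    """Initialize the simulation: discretize rate distributions, fix
    per-site category assignments, and build the root event tree."""
    annotation = Annotation(genome, orfs)
    mu_set = discretize(mu_spec)
    omega_sets: dict[str, CategorySet] = {}
    orf_mu_sets: dict[str, CategorySet] = {}
    for orf in orfs:
        if orf.omega_spec is None:
            raise SimulationError(f"ORF {orf.name} has no omega distribution")
        omega_sets[orf.name] = discretize(orf.omega_spec)
        if orf.mu_spec is not None:
            orf_mu_sets[orf.name] = discretize(orf.mu_spec)
    assignments = assign_site_categories(annotation, mu_set, omega_sets, rng,
                                         orf_mu_sets or None)
    tree = EventTree(annotation, assignments, params)
    return SimulationState(tree)


def simulate_branch(state: SimulationState, branch_length: float,
                    rng: np.random.Generator, branch: str = ""
                    ) -> SimulationState:
    """Evolve ``state`` in place along one branch and return it."""
    if branch_length < 0:
        raise SimulationError(f"negative branch length {branch_length}")
    elapsed = 0.0
    while True:
        lam = state.tree.total
        if lam <= 0.0:
            break
        elapsed += rng.exponential(1.0 / lam)
        if elapsed > branch_length:
            break  # waiting time overshoots: propagate current sequence
        event = state.tree.sample_event(rng)
        state.apply_substitution(event, time=elapsed, branch=branch)
    return state


def _branch_rng(seed: int, index: int) -> np.random.Generator:
    # independent stream per branch: adding tips elsewhere in the tree
    # does not perturb this lineage's draws
    return np.random.default_rng([seed, index])


def traverse_phylogeny(root_state: SimulationState, phylogeny: Phylogeny,
                       seed: int) -> TipAlignment:
    """Level-order traversal: simulate every branch, deep-copying the
    state at internal nodes, and collect the sequences at the tips."""
    alignment, _log = traverse_phylogeny_with_log(root_state, phylogeny, seed)
    return alignment


def traverse_phylogeny_with_log(root_state: SimulationState,
                                phylogeny: Phylogeny, seed: int
                                ) -> tuple[TipAlignment, list[LogEntry]]:
    states: dict[int, SimulationState] = {id(phylogeny.tree.seed_node): root_state}
    tips: dict[str, str] = {}
    full_log: list[LogEntry] = []
    nodes = list(phylogeny.tree.levelorder_node_iter())
    for index, node in enumerate(nodes):
        if node is phylogeny.tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        state = parent_state.copy()
        label = (node.taxon.label if node.is_leaf() and node.taxon
                 else f"node{index}")
        before = len(state.log)
        simulate_branch(state, node.edge.length, _branch_rng(seed, index),
                        branch=label)
        full_log.extend(state.log[before:])
        if node.is_leaf():
            tips[label] = state.sequence
        else:
            states[id(node)] = state
    return TipAlignment(tips), full_log


@dataclass
class SimulationResult:
    alignment: TipAlignment
    log: list[LogEntry]
    summary: dict


def run_simulation(genome: Genome, orfs: Sequence[Orf],
                   params: SubstitutionParams, mu_spec: DistributionSpec,
                   phylogeny: Phylogeny, seed: int) -> SimulationResult:
    """End-to-end run: root state, traversal, alignment + log + summary.

    All randomness derives from ``seed``: category assignment consumes
    the stream [seed, 0]; branch ``i`` (level-order index) uses
    [seed, i]. Identical inputs and seed give bit-identical output.
    """
    master = np.random.default_rng([seed, 0])
    root_state = build_root_state(genome, orfs, params, mu_spec, master)
    lam_root = root_state.tree.total
    alignment, log = traverse_phylogeny_with_log(root_state, phylogeny, seed)
    summary = {
        "seed": seed,
        "sequence_length": genome.length,
        "circular": genome.is_circular,
        "kappa": params.kappa,
        "pi": list(params.pi),
        "global_rate": params.global_rate,
        "n_orfs": len(orfs),
        "orfs": {
            o.name: {"segments": [list(s) for s in o.segments],
                     "strand": o.strand}
            for o in orfs
        },
        "lambda_root": lam_root,
        "n_events": len(log),
        "n_tips": len(alignment),
    }
    return SimulationResult(alignment, log, summary)
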