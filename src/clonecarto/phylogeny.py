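"""Maximum-parsimony clone phylogenies and tree statistics.

Trees are built from a binary subclone-by-event matrix and rooted in a cell
with no genetic alterations. Copy-number evolution violates the infinite
sites assumption, so characters can be constrained by class: chromosomal
breakpoints outside centromeres are unique events (one gain, no loss), loss
of heterozygosity is irreversible (no loss, parallel gains allowed), while
whole-chromosome gains/losses may evolve in parallel and back-mutate freely.

Conflict-free matrices take the exact perfect-phylogeny route and yield the
unique zero-homoplasy tree; conflicting matrices trigger a parsimony search
(exhaustive for small taxon sets, stepwise addition with NNI refinement
beyond). Ties between equally parsimonious trees are broken toward the
smallest number of back mutations, then the lexicographically smallest
Newick string.

Statistics: the index of genomic diversity (IGD) of the subclones of one
sample type is the ratio of summed MRCA-to-subclone distances to summed
root-to-subclone distances (0 = all subclones coincide with their common
node, 1 = their common node is the root); irregularity is the sample
variance of root-to-taxon distances; total branch length counts every event
acquisition on the tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleMatrixError, NotClassifiableError, ValidationError
from .trees import CloneNode, CloneTree

INF = float("inf")

#: character classes and their loss (1 -> 0) costs / gain caps
_CLASS_RULES = {
    "free": (1.0, None),
    "whole_chrom": (1.0, None),
    "unique": (INF, 1),
    "breakpoint": (INF, 1),
    "snv": (INF, 1),
    "loh": (INF, None),
}

TIMEPOINT_ORDER = ("pre", "during", "post", "metastatic_relapse", "progression")


# ---------------------------------------------------------------------------
# matrix helpers

def _dedupe(matrix: pd.DataFrame) -> tuple[list[str], list[frozenset[str]]]:
    """Merge taxa with identical genotypes; returns (labels, genotypes)."""
    events = list(matrix.columns)
    seen: dict[frozenset, list[str]] = {}
    for taxon in matrix.index:
        genotype = frozenset(e for e in events if matrix.loc[taxon, e])
        seen.setdefault(genotype, []).append(str(taxon))
    labels = ["+".join(sorted(names)) for names in seen.values()]
    return labels, list(seen.keys())


def _is_conflict_free(carriers: Sequence[frozenset]) -> bool:
    for a, b in itertools.combinations(set(carriers), 2):
        if a & b and not (a <= b or b <= a):
            return False
    return True


# ---------------------------------------------------------------------------
# perfect phylogeny (exact, unique)

def _perfect_tree(labels: list[str], genotypes: list[frozenset]) -> CloneTree:
    taxa_of = dict(zip(labels, genotypes))
    all_events = sorted({e for g in genotypes for e in g})
    carriers: dict[str, frozenset] = {
        e: frozenset(l for l in labels if e in taxa_of[l]) for e in all_events}
    # events never carried cannot place; drop them
    carriers = {e: c for e, c in carriers.items() if c}
    # branch = one distinct carrier set
    by_set: dict[frozenset, list[str]] = {}
    for e, c in carriers.items():
        by_set.setdefault(c, []).append(e)
    # process larger carrier sets first so each set's minimal strict superset
    # (unique in a laminar family) already has a node
    sets = sorted(by_set, key=lambda s: (-len(s), sorted(s)))
    tree = CloneTree()
    node_of: dict[frozenset, CloneNode] = {}
    for s in sets:
        supersets = [t for t in node_of if s < t]
        parent = node_of[min(supersets, key=len)] if supersets else tree.root
        node_of[s] = tree.add_child(parent, events=sorted(by_set[s]))
    # attach taxa at the node of their minimal containing carrier set
    for label in labels:
        containing = [s for s in node_of if label in s]
        node = node_of[min(containing, key=len)] if containing else tree.root
        if node.name is None and node is not tree.root:
            node.name = label
        else:
            # a second taxon at the same node, or a zero-alteration taxon at
            # the root: pendant zero-length child
            child = tree.add_child(node, events=(), name=label)
            child._genotype = node.genotype
    return tree


# ---------------------------------------------------------------------------
# general parsimony search

def _enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies over leaves 0..n-1 (edge lists)."""
    if n_leaves == 1:
        yield []
        return
    if n_leaves == 2:
        yield [(0, 1)]
        return
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    stack = [(base, 3, n_leaves + 1)]
    while stack:
        edges, next_leaf, next_internal = stack.pop()
        if next_leaf == n_leaves:
            yield edges
            continue
        for i, (u, v) in enumerate(edges):
            new = edges[:i] + edges[i + 1:]
            w = next_internal
            new += [(u, w), (v, w), (next_leaf, w)]
            stack.append((new, next_leaf + 1, next_internal + 1))


def _root_at(edges: list[tuple[int, int]], root_leaf: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    children: dict[int, list[int]] = {root_leaf: []}
    stack = [(root_leaf, None)]
    while stack:
        node, parent = stack.pop()
        kids = [x for x in adj.get(node, []) if x != parent]
        children[node] = kids
        for k in kids:
            stack.append((k, node))
    return children


def _score_topology(children: Mapping[int, list[int]], root: int,
                    leaf_states: Mapping[int, np.ndarray],
                    loss_costs: np.ndarray,
                    gain_caps: list[Optional[int]]) -> tuple[float, int]:
    """(total parsimony cost, back mutations) of a rooted topology.

    Per-character DP over states {0, 1}: gains cost 1, losses cost the class
    loss cost; classes with a gain cap turn topologies needing more gains
    infeasible (cost inf). The back-mutation count is taken from a minimal
    reconstruction that secondarily minimizes losses.
    """
    n_chars = loss_costs.shape[0]
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(children[node])
    post = order[::-1]

    # cost[node] shape (n_chars, 2); tuple cost = changes + epsilon * losses
    eps = 1e-6
    cost: dict[int, np.ndarray] = {}
    for node in post:
        kids = children[node]
        if not kids:
            c = np.full((n_chars, 2), INF)
            states = leaf_states[node]
            c[np.arange(n_chars), states] = 0.0
            cost[node] = c
            continue
        total = np.zeros((n_chars, 2))
        for k in kids:
            ck = cost[k]
            # transition costs: stay 0, gain (0->1) = 1; loss (1->0), stay 1
            from0 = np.minimum(ck[:, 0], ck[:, 1] + 1.0)
            from1 = np.minimum(ck[:, 0] + loss_costs + eps * (loss_costs < INF),
                               ck[:, 1])
            total[:, 0] += from0
            total[:, 1] += from1
        cost[node] = total
    root_cost = cost[root][:, 0]  # the root is the zero-alteration cell
    if np.any(np.isinf(root_cost)):
        return INF, 0
    # enforce gain caps by re-deriving the number of gains per capped char:
    # with losses forbidden (cost INF) the total equals the gain count
    for idx, cap in enumerate(gain_caps):
        if cap is not None and root_cost[idx] > cap + 1e-9:
            return INF, 0
    total = float(np.floor(root_cost.sum() + 1e-9))
    losses = int(round((root_cost.sum() - total) / eps)) if eps else 0
    return root_cost.sum(), losses


def _reconstruct(children: Mapping[int, list[int]], root: int,
                 leaf_states: Mapping[int, np.ndarray],
                 loss_costs: np.ndarray) -> dict[int, np.ndarray]:
    """Minimal-change ancestral states (ties: fewer losses, then state 0)."""
    n_chars = loss_costs.shape[0]
    eps = 1e-6
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(children[node])
    post = order[::-1]
    cost: dict[int, np.ndarray] = {}
    for node in post:
        kids = children[node]
        if not kids:
            c = np.full((n_chars, 2), INF)
            c[np.arange(n_chars), leaf_states[node]] = 0.0
            cost[node] = c
        else:
            total = np.zeros((n_chars, 2))
            for k in kids:
                ck = cost[k]
                total[:, 0] += np.minimum(ck[:, 0], ck[:, 1] + 1.0)
                total[:, 1] += np.minimum(ck[:, 0] + loss_costs + eps, ck[:, 1])
            cost[node] = total
    states: dict[int, np.ndarray] = {root: np.zeros(n_chars, dtype=int)}
    for node in order:
        s_parent = states[node]
        for k in children[node]:
            ck = cost[k]
            child_state = np.empty(n_chars, dtype=int)
            for i in range(n_chars):
                sp = s_parent[i]
                stay = ck[i, sp]
                flip_state = 1 - sp
                trans = 1.0 if sp == 0 else loss_costs[i] + eps
                flip = ck[i, flip_state] + trans
                child_state[i] = sp if stay <= flip else flip_state
            states[k] = child_state
    return states


def _clone_tree_from_states(children: Mapping[int, list[int]], root: int,
                            states: Mapping[int, np.ndarray],
                            leaf_labels: Mapping[int, str],
                            event_names: list[str]) -> CloneTree:
    tree = CloneTree()

    def events_between(parent_state, child_state):
        evs = []
        for i, name in enumerate(event_names):
            if parent_state[i] == 0 and child_state[i] == 1:
                evs.append(name)
            elif parent_state[i] == 1 and child_state[i] == 0:
                evs.append(f"loss:{name}")
        return evs

    def attach(node_id: int, parent_node: CloneNode, parent_state: np.ndarray):
        state = states[node_id]
        evs = events_between(parent_state, state)
        kids = children[node_id]
        label = leaf_labels.get(node_id)
        if not evs and parent_node is not tree.root and not kids:
            # zero-length pendant leaf: hoist the taxon onto the parent node
            if label is not None:
                if parent_node.name is None:
                    parent_node.name = label
                else:
                    extra = tree.add_child(parent_node, events=(), name=label)
                    extra._genotype = parent_node.genotype
            return
        node = tree.add_child(parent_node, events=evs, name=label)
        node._genotype = frozenset(
            event_names[i] for i in range(len(event_names)) if state[i])
        for k in kids:
            attach(k, node, state)

    root_state = states[root]
    for k in children[root]:
        attach(k, tree.root, root_state)
    # collapse internal edges with no events and no taxon
    def collapse(node: CloneNode):
        for child in list(node.children):
            collapse(child)
        if (node is not tree.root and not node.events and node.name is None
                and node.parent is not None):
            parent = node.parent
            parent.children.remove(node)
            for child in node.children:
                child.parent = parent
                parent.children.append(child)
    collapse(tree.root)
    return tree


def build_tree(matrix: pd.DataFrame,
               event_classes: Optional[Mapping[str, str]] = None,
               max_exhaustive: int = 7) -> CloneTree:
    """Rooted maximum-parsimony tree from a binary subclone-by-event matrix.

    Rows are subclones, columns events; the tree is rooted in a cell without
    alterations. Conflict-free matrices yield the unique perfect phylogeny.
    Otherwise all topologies are searched exhaustively up to
    ``max_exhaustive`` taxa and by stepwise addition plus
    nearest-neighbor-interchange refinement beyond. ``event_classes`` maps
    event ids to one of free / whole_chrom / unique / breakpoint / snv / loh.
    """
    if matrix.empty or matrix.shape[1] == 0:
        tree = CloneTree()
        for taxon in matrix.index:
            node = tree.add_child(tree.root, events=(), name=str(taxon))
            node._genotype = frozenset()
        return tree
    bad = set(np.unique(matrix.to_numpy())) - {0, 1}
    if bad:
        raise ValidationError(f"event matrix must be binary, found values {sorted(bad)}")

    labels, genotypes = _dedupe(matrix)
    event_names = sorted({e for g in genotypes for e in g})
    carriers = [frozenset(l for l, g in zip(labels, genotypes) if e in g)
                for e in event_names]
    if _is_conflict_free(carriers):
        return _perfect_tree(labels, genotypes)

    classes = dict(event_classes or {})
    loss_costs = np.array([_CLASS_RULES.get(classes.get(e, "free"), _CLASS_RULES["free"])[0]
                           for e in event_names])
    gain_caps = [_CLASS_RULES.get(classes.get(e, "free"), _CLASS_RULES["free"])[1]
                 for e in event_names]

    n = len(labels)
    leaf_states = {i: np.array([1 if event_names[j] in genotypes[i] else 0
                                for j in range(len(event_names))], dtype=int)
                   for i in range(n)}
    leaf_states[n] = np.zeros(len(event_names), dtype=int)  # zero-alteration outgroup
    root_leaf = n
    n_leaves = n + 1

    def evaluate(edges):
        children = _root_at(edges, root_leaf)
        score, losses = _score_topology(children, root_leaf, leaf_states,
                                        loss_costs, gain_caps)
        return children, score, losses

    best = None  # (score, losses, newick, tree)
    if n <= max_exhaustive:
        candidates = _enumerate_topologies(n_leaves)
    else:
        candidates = [_stepwise_topology(n_leaves, root_leaf, leaf_states,
                                         loss_costs, gain_caps)]
    for edges in candidates:
        children, score, losses = evaluate(edges)
        if score == INF:
            continue
        if best is not None and score - 1e-9 > best[0]:
            continue
        states = _reconstruct(children, root_leaf, leaf_states, loss_costs)
        tree = _clone_tree_from_states(children, root_leaf, states,
                                       {i: labels[i] for i in range(n)}, event_names)
        key = (round(score, 6), losses, tree.newick())
        if best is None or key < (round(best[0], 6), best[1], best[2]):
            best = (score, losses, tree.newick(), tree)
    if best is None:
        raise InfeasibleMatrixError(
            "no topology satisfies the chromosomal-evolution constraints")
    return best[3]


def _stepwise_topology(n_leaves, root_leaf, leaf_states, loss_costs, gain_caps):
    """Greedy stepwise addition, then NNI hill climbing (heuristic)."""
    leaves = [l for l in range(n_leaves)]
    edges = [(leaves[0], n_leaves), (leaves[1], n_leaves), (leaves[2], n_leaves)]
    next_internal = n_leaves + 1
    for leaf in leaves[3:]:
        best_edges, best_score = None, INF
        for i, (u, v) in enumerate(edges):
            trial = edges[:i] + edges[i + 1:] + [(u, next_internal),
                                                 (v, next_internal),
                                                 (leaf, next_internal)]
            children = _root_at(trial, root_leaf)
            score, _ = _score_topology(children, root_leaf, leaf_states,
                                       loss_costs, gain_caps)
            if score < best_score:
                best_score, best_edges = score, trial
        edges = best_edges
        next_internal += 1
    # NNI refinement
    improved = True
    while improved:
        improved = False
        children = _root_at(edges, root_leaf)
        current, _ = _score_topology(children, root_leaf, leaf_states,
                                     loss_costs, gain_caps)
        internal_edges = [(u, v) for u, v in edges
                          if u >= n_leaves and v >= n_leaves]
        adj: dict[int, set[int]] = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        for u, v in internal_edges:
            nu = [x for x in adj[u] if x != v]
            nv = [x for x in adj[v] if x != u]
            if len(nu) != 2 or len(nv) != 2:
                continue
            for swap_u, swap_v in ((nu[0], nv[0]), (nu[0], nv[1])):
                trial = []
                for a, b in edges:
                    pair = {a, b}
                    if pair == {u, swap_u}:
                        trial.append((u, swap_v))
                    elif pair == {v, swap_v}:
                        trial.append((v, swap_u))
                    else:
                        trial.append((a, b))
                score, _ = _score_topology(_root_at(trial, root_leaf), root_leaf,
                                           leaf_states, loss_costs, gain_caps)
                if score < current - 1e-9:
                    edges, improved = trial, True
                    break
            if improved:
                break
    return edges


# ---------------------------------------------------------------------------
# statistics

def igd(tree: CloneTree, taxa_subset: Iterable[str]) -> float:
    """Index of genomic diversity of a set of subclones.

    IGD = sum_i d(MRCA, taxon_i) / sum_i d(root, taxon_i) over the subclones
    of one sample type; ranges from 0 (all at their common node) to 1 (their
    common node is the root).
    """
    names = list(taxa_subset)
    if not names:
        raise ValidationError("IGD needs a non-empty subclone subset")
    nodes = [tree.find_taxon(n) for n in names]
    mrca = tree.mrca(nodes)
    d_root = [tree.depth(n) for n in nodes]
    if sum(d_root) == 0:
        raise ValidationError("IGD undefined: subset has zero total root distance")
    d_mrca = [tree.depth(n) - tree.depth(mrca) for n in nodes]
    return sum(d_mrca) / sum(d_root)


def irregularity(tree: CloneTree) -> float:
    """Sample variance (n-1 denominator) of root-to-taxon distances."""
    depths = [tree.depth(n) for n in tree.taxa()]
    if len(depths) < 2:
        raise ValidationError("irregularity needs at least two taxa")
    return float(np.var(depths, ddof=1))


def total_branch_length(tree: CloneTree) -> int:
    """Total number of event acquisitions on the tree."""
    return tree.total_branch_length()


# ---------------------------------------------------------------------------
# collateral clonal replacement vs linear evolution

@dataclass
class ReplacementCall:
    classification: str  # 'CCR' | 'linear' | 'mixed'
    earlier_timepoint: str
    later_timepoint: str
    dominant_later: list[str]
    supported: dict[str, Optional[str]] = field(default_factory=dict)
    #: earlier-dominant taxa still detected later (evidence against full replacement)
    persisting_earlier: list[str] = field(default_factory=list)


def classify_replacement(tree: CloneTree,
                         sample_timepoints: Mapping[str, str],
                         detection: Mapping[str, Iterable[str]],
                         timepoint_order: Sequence[str] = TIMEPOINT_ORDER,
                         fractions: Optional[Mapping[str, Mapping[str, float]]] = None,
                         witness_detection: Optional[Mapping[str, Iterable[str]]] = None,
                         ) -> ReplacementCall:
    """Classify temporal evolution as collateral clonal replacement or linear.

    ``detection`` maps taxon name to the samples where that subclone is
    detected as an extant population; ``sample_timepoints`` maps samples to
    timepoint labels. A subclone dominating a later timepoint is *linearly*
    derived if a subclone detected at an earlier timepoint lies on its root
    path (itself included) strictly below the patient MRCA — the common
    ancestor of all detected populations is trivially ancestral to everything
    and only counts as a linear witness when it itself *dominated* the
    earlier timepoint (an ascertained ancestral population). If no
    later-dominant subclone has such an ancestor — the later populations
    descend from a different most recent ancestor while the earlier dominant
    lineages disappear — the pattern is collateral clonal replacement (CCR).
    A mixture of both is 'mixed'.

    Dominance = largest extant fraction in at least one sample of the
    timepoint (taken from ``fractions``; with no fractions every detected
    taxon of the timepoint counts as dominant). ``witness_detection``
    optionally provides a stricter detection map used for witnesses only
    (ancestral populations claimed at the earlier timepoint should be
    ascertained well above the detection limit); it defaults to
    ``detection``.
    """
    rank = {tp: i for i, tp in enumerate(timepoint_order)}
    detection = {t: set(s) for t, s in detection.items()}
    tps_present = sorted({sample_timepoints[s] for ss in detection.values() for s in ss},
                         key=lambda tp: rank.get(tp, len(rank)))
    if len(tps_present) < 2:
        raise NotClassifiableError("need detections from at least two timepoints")
    later_tp = tps_present[-1]
    earlier_tps = set(tps_present[:-1])

    def samples_at(tp):
        return {s for s, t in sample_timepoints.items() if t == tp}

    later_samples = samples_at(later_tp)
    earlier_taxa = {t for t, ss in detection.items()
                    if any(sample_timepoints[s] in earlier_tps for s in ss)}
    later_taxa = {t for t, ss in detection.items() if ss & later_samples}
    if not earlier_taxa or not later_taxa:
        raise NotClassifiableError("no detected subclones on one side of the comparison")

    if fractions:
        dominant: set[str] = set()
        for s in later_samples:
            best, best_val = None, 0.0
            for t in later_taxa:
                val = fractions.get(t, {}).get(s, 0.0)
                if val > best_val:
                    best, best_val = t, val
            if best is not None:
                dominant.add(best)
        if not dominant:
            dominant = set(later_taxa)
    else:
        dominant = set(later_taxa)

    detected_nodes = [tree.find_taxon(t) for t, ss in detection.items() if ss]
    patient_mrca = tree.mrca(detected_nodes)

    strong = ({t: set(ss) for t, ss in witness_detection.items()}
              if witness_detection is not None else detection)
    earlier_samples = {s for s, tp in sample_timepoints.items() if tp in earlier_tps}
    if fractions:
        earlier_dominant: set[str] = set()
        for s in earlier_samples:
            best, best_val = None, 0.0
            for t in detection:
                val = fractions.get(t, {}).get(s, 0.0)
                if val > best_val:
                    best, best_val = t, val
            if best is not None:
                earlier_dominant.add(best)
    else:
        earlier_dominant = set(earlier_taxa)
    witnesses = set()
    for e in earlier_taxa:
        if not any(sample_timepoints[s] in earlier_tps for s in strong.get(e, ())):
            continue
        e_node = tree.find_taxon(e)
        strictly_below = (tree.is_ancestor(patient_mrca, e_node)
                          and e_node is not patient_mrca)
        if strictly_below or e in earlier_dominant:
            witnesses.add(e)

    supported: dict[str, Optional[str]] = {}
    for t in sorted(dominant):
        node = tree.find_taxon(t)
        witness = None
        for e in sorted(witnesses):
            if tree.is_ancestor(tree.find_taxon(e), node):
                witness = e
                break
        supported[t] = witness

    n_supported = sum(1 for w in supported.values() if w is not None)
    persisting = sorted(t for t in earlier_taxa
                        if detection[t] & later_samples and t not in later_taxa | set())
    if n_supported == len(supported):
        call = "linear"
    elif n_supported == 0:
        call = "CCR"
    else:
        call = "mixed"
    return ReplacementCall(classification=call,
                           earlier_timepoint=tps_present[0],
                           later_timepoint=later_tp,
                           dominant_later=sorted(dominant),
                           supported=supported,
                           persisting_earlier=persisting)
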