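"""Clustering of clone-size patterns into a nested subclone configuration.

Events (CNAs and SNVs) that occur in the same subclone show the same mutated
clone fraction in every sample; clustering the events-by-samples MCF matrix
therefore recovers the subclones. Two constraints of chromosomal evolution
shape the configuration:

* **pigeonhole** — subclones that are parallel (neither nested in the other)
  cannot together exceed 100% of the tumor cells in any biopsy, so two groups
  whose fractions sum above 1.0 somewhere must be nested;
* **containment** — a subclone nested within another can never exceed its
  mother's fraction in any sample.

Same-coordinate aberrations with two different allelic compositions
("mixed") mark event pairs that must never be nested: a cell cannot hold two
copy-number states of one segment at once.

The resolved configuration is a forest over event groups; adding the
zero-alteration root turns it into the clone tree, and expanding each group
into the events on its root path yields the binary subclone-by-event matrix
used for phylogenetic reconstruction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .cna_quantification import SegmentCall, mcf_from_msf, msf_from_mbaf, msf_from_ratio
from .errors import ConfigurationError, ConstraintConflictError, ValidationError
from .trees import CloneTree

#: default tolerance when grouping MCF patterns (covers the ~10% clone-size
#: error margin of array data plus rounding)
DEFAULT_GROUP_TOL = 0.15

#: a child may nominally exceed its mother by this much before nesting is ruled out
NEST_TOL = 0.1
#: parallel subclones may sum to at most 1 + SUM_TOL in any sample
SUM_TOL = 0.1

#: PDX / cell line rule set
PDX_CLONAL_MCF = 0.9
PDX_PARALLEL_CAP = 1.2


def round_to_tenth(x: float) -> float:
    """Round half away from zero to the nearest 0.1 (deterministic)."""
    return math.floor(x * 10.0 + 0.5) / 10.0


@dataclass
class MCFMatrix:
    """Events-by-samples matrix of mutated clone fractions."""

    values: pd.DataFrame  # index: event ids, columns: sample ids
    no_nest_pairs: set[frozenset] = field(default_factory=set)
    event_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr < -1e-9) or np.any(arr > 1.0 + 1e-9):
            raise ValidationError("MCF values must lie in [0, 1]")

    @property
    def events(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EventGroup:
    group_id: str
    events: tuple[str, ...]
    profile: dict[str, float]  # per-sample fraction, multiples of 0.1
    annotation: str = "observed"
    #: unrounded per-sample mean over members (kept for detection decisions)
    raw_profile: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.profile.values())


@dataclass
class SubcloneConfiguration:
    groups: list[EventGroup]
    parents: dict[str, Optional[str]]  # group_id -> parent group_id (None = root)
    samples: list[str]
    no_nest_pairs: set[frozenset] = field(default_factory=set)

    def group(self, gid: str) -> EventGroup:
        return next(g for g in self.groups if g.group_id == gid)

    def children(self, gid: Optional[str]) -> list[EventGroup]:
        return [g for g in self.groups if self.parents[g.group_id] == gid]

    def ancestors(self, gid: str) -> list[str]:
        out = []
        p = self.parents[gid]
        while p is not None:
            out.append(p)
            p = self.parents[p]
        return out

    def relation(self, a: str, b: str) -> str:
        if a == b:
            return "identical"
        if b in self.ancestors(a) or a in self.ancestors(b):
            return "nested"
        return "parallel"

    def extant_fractions(self, raw: bool = False) -> pd.DataFrame:
        """Per-sample fraction of cells whose most derived genotype is each group.

        ``raw=True`` uses the unrounded group profiles, which avoids the
        rounding bias when the result feeds detection decisions.
        """
        def prof(g: EventGroup) -> dict[str, float]:
            return (g.raw_profile or g.profile) if raw else g.profile

        rows = {}
        for g in self.groups:
            child_sum = {s: 0.0 for s in self.samples}
            for c in self.children(g.group_id):
                for s in self.samples:
                    child_sum[s] += prof(c).get(s, 0.0)
            rows[g.group_id] = {
                s: max(prof(g).get(s, 0.0) - child_sum[s], 0.0) for s in self.samples}
        return pd.DataFrame.from_dict(rows, orient="index")[self.samples]

    def to_clone_tree(self) -> CloneTree:
        tree = CloneTree()
        nodes = {}
        remaining = {g.group_id: g for g in self.groups}
        # attach groups root-down
        while remaining:
            progressed = False
            for gid, g in list(remaining.items()):
                parent = self.parents[gid]
                if parent is None or parent in nodes:
                    anchor = tree.root if parent is None else nodes[parent]
                    node = tree.add_child(anchor, events=g.events, name=gid)
                    node.fractions = dict(g.profile)
                    nodes[gid] = node
                    del remaining[gid]
                    progressed = True
            if not progressed:  # pragma: no cover - defensive
                raise ConstraintConflictError("cyclic parent assignment")
        extant = self.extant_fractions()
        for gid, node in nodes.items():
            node.extant = extant.loc[gid].to_dict()
        return tree


# ---------------------------------------------------------------------------
# grouping

def group_events(matrix: MCFMatrix, tol: float = DEFAULT_GROUP_TOL) -> list[EventGroup]:
    """Merge events whose MCFs agree within ``tol`` in every sample.

    Complete-linkage clustering under the per-sample Chebyshev metric, so no
    group spans more than ``tol`` internally and the result is independent of
    input order. The group profile is the per-sample mean over members,
    rounded to the nearest 0.1. Event pairs barred from nesting (mixed
    allelic compositions of one segment) are never grouped together.
    """
    if tol < 0:
        raise ConfigurationError(f"grouping tolerance must be non-negative, got {tol}")
    df = matrix.values
    if df.empty:
        raise ValidationError("cannot group an empty MCF matrix")
    order = sorted(df.index)
    data = df.loc[order].to_numpy(dtype=float)
    if len(order) == 1:
        labels = np.array([1])
    else:
        dist = pdist(data, metric="chebyshev")
        if matrix.no_nest_pairs:
            pos = {e: i for i, e in enumerate(order)}
            n = len(order)
            for pair in matrix.no_nest_pairs:
                pair = sorted(pos[e] for e in pair if e in pos)
                if len(pair) == 2:
                    i, j = pair
                    dist[n * i + j - ((i + 2) * (i + 1)) // 2] = 1e6
        labels = fcluster(linkage(dist, method="complete"), t=tol, criterion="distance")
    groups: list[EventGroup] = []
    for lab in sorted(set(labels), key=lambda l: min(i for i in range(len(order)) if labels[i] == l)):
        idx = [i for i in range(len(order)) if labels[i] == lab]
        members = tuple(order[i] for i in idx)
        mean = data[idx].mean(axis=0)
        profile = {s: round_to_tenth(v) for s, v in zip(df.columns, mean)}
        groups.append(EventGroup(group_id=f"G{len(groups) + 1}", events=members,
                                 profile=profile,
                                 raw_profile={s: float(v) for s, v in zip(df.columns, mean)}))
    return groups


def _barred(a: EventGroup, b: EventGroup, no_nest_pairs: set[frozenset]) -> bool:
    return any(frozenset((ea, eb)) in no_nest_pairs
               for ea in a.events for eb in b.events)


# ---------------------------------------------------------------------------
# configuration search

def resolve_configuration(groups: Sequence[EventGroup],
                          no_nest_pairs: Iterable[frozenset] = (),
                          samples: Optional[Sequence[str]] = None,
                          nest_tol: float = NEST_TOL,
                          sum_tol: float = SUM_TOL,
                          strict: bool = True,
                          max_backtrack: int = 200_000) -> SubcloneConfiguration:
    """Find the subclone configuration satisfying all constraints.

    Groups are inserted in order of decreasing total fraction, each under the
    deepest already-placed group that dominates its profile in every sample
    (ties: smaller total fraction, then lexicographic id). Backtracking
    explores alternative placements when the greedy choice violates the
    pigeonhole (must-nest) constraints or the per-sample antichain cap; the
    search is exact up to the backtracking budget and reports the violated
    sample on infeasibility. With ``strict=False`` the pigeonhole must-nest
    pairs become soft preferences (noisy fraction estimates can make them
    jointly unsatisfiable) while containment and the no-nest bars stay hard.
    """
    groups = list(groups)
    no_nest_pairs = set(no_nest_pairs)
    if samples is None:
        samples = sorted({s for g in groups for s in g.profile})
    samples = list(samples)

    def can_nest(child: EventGroup, parent: EventGroup) -> bool:
        if _barred(child, parent, no_nest_pairs):
            return False
        return all(child.profile.get(s, 0.0) <= parent.profile.get(s, 0.0) + nest_tol
                   for s in samples)

    def must_nest(a: EventGroup, b: EventGroup) -> Optional[str]:
        for s in samples:
            if a.profile.get(s, 0.0) + b.profile.get(s, 0.0) > 1.0 + sum_tol:
                return s
        return None

    forced: list[tuple[EventGroup, EventGroup, str]] = []
    for a, b in itertools.combinations(groups, 2):
        s = must_nest(a, b)
        if s is not None:
            if _barred(a, b, no_nest_pairs):
                raise ConstraintConflictError(
                    f"groups {a.group_id} and {b.group_id} exceed 100% in sample {s} "
                    "but are barred from nesting (mixed allelic compositions)")
            forced.append((a, b, s))

    # insertion order: large clones first; deterministic tie-break
    order = sorted(groups, key=lambda g: (-g.total(), g.events[0]))
    parents: dict[str, Optional[str]] = {}
    by_id = {g.group_id: g for g in order}

    def ancestors_of(gid: str) -> set[str]:
        out = set()
        p = parents.get(gid)
        while p is not None:
            out.add(p)
            p = parents.get(p)
        return out

    def antichain_ok(placed: list[EventGroup]) -> bool:
        # max-weight antichain per sample via tree DP must stay <= 1 + sum_tol
        for s in samples:
            def weight(gid: Optional[str]) -> float:
                kids = [g for g in placed if parents.get(g.group_id, "?") == gid]
                kid_sum = sum(weight(g.group_id) for g in kids)
                if gid is None:
                    return kid_sum
                return max(by_id[gid].profile.get(s, 0.0), kid_sum)
            if weight(None) > 1.0 + sum_tol:
                return False
        return True

    budget = [max_backtrack]

    def search(i: int) -> bool:
        if i == len(order):
            if strict:
                for a, b, s in forced:
                    rel_ok = (a.group_id in ancestors_of(b.group_id)
                              or b.group_id in ancestors_of(a.group_id))
                    if not rel_ok:
                        return False
            return True
        g = order[i]
        placed = order[:i]
        candidates = [p for p in placed if can_nest(g, p)]
        # deepest first: most ancestors, then smallest total fraction, then id
        candidates.sort(key=lambda p: (-len(ancestors_of(p.group_id)), p.total(), p.group_id))
        for parent in candidates + [None]:
            if budget[0] <= 0:
                return False
            budget[0] -= 1
            parents[g.group_id] = parent.group_id if parent is not None else None
            # no-nest must also hold against every ancestor
            if parent is not None and any(
                    _barred(g, by_id[a], no_nest_pairs) for a in ancestors_of(g.group_id)):
                continue
            if not antichain_ok(order[:i + 1]):
                continue
            if search(i + 1):
                return True
        parents.pop(g.group_id, None)
        return False

    if not search(0):
        detail = ""
        if forced:
            a, b, s = forced[0]
            detail = (f" (e.g. {a.group_id} and {b.group_id} must nest because their "
                      f"fractions exceed 100% in sample {s})")
        raise ConstraintConflictError("no feasible subclone configuration" + detail)

    return SubcloneConfiguration(groups=list(order), parents=dict(parents),
                                 samples=samples, no_nest_pairs=no_nest_pairs)


def collapse_chains(config: SubcloneConfiguration,
                    values: pd.DataFrame,
                    tol: float = DEFAULT_GROUP_TOL) -> SubcloneConfiguration:
    """Merge parent-child groups whose fraction profiles are indistinguishable.

    Noise can fragment one clone's events into a nested pair of groups whose
    profiles differ by less than the pattern tolerance in every sample; the
    'extant' mass separating them is then a subtraction artifact, not an
    ascertained population. Such children are folded into their parents
    (profiles recomputed as the mean over the united events) until stable.
    Groups separated by more than ``tol`` in some sample are never touched.
    """
    groups = {g.group_id: g for g in config.groups}
    parents = dict(config.parents)
    samples = config.samples

    def raw(g: EventGroup) -> dict[str, float]:
        return g.raw_profile or g.profile

    changed = True
    while changed:
        changed = False
        for gid in sorted(parents):
            pid = parents.get(gid)
            if pid is None:
                continue
            g, p = groups[gid], groups[pid]
            if max(abs(raw(g).get(s, 0.0) - raw(p).get(s, 0.0)) for s in samples) <= tol:
                events = tuple(sorted(set(p.events) | set(g.events)))
                mean = values.loc[list(events)].mean(axis=0)
                p.events = events
                p.raw_profile = {s: float(mean[s]) for s in samples}
                p.profile = {s: round_to_tenth(float(mean[s])) for s in samples}
                for child, par in list(parents.items()):
                    if par == gid:
                        parents[child] = pid
                del parents[gid], groups[gid]
                changed = True
                break
    return SubcloneConfiguration(groups=[groups[g] for g in sorted(groups)],
                                 parents=parents, samples=samples,
                                 no_nest_pairs=config.no_nest_pairs)


# ---------------------------------------------------------------------------
# inference of missing events

def infer_missing_events(matrix: MCFMatrix) -> MCFMatrix:
    """Patient-wide reconciliation of irreconcilable CNA annotations.

    * Same-breakpoint gains observed with different allele counts in
      different samples: the state with the lowest allele count is inferred
      as stem (clonal in every sample) since the higher states presuppose it.
    * Whole-chromosome events whose cross-sample fractions cannot follow a
      single order (they would have to nest in both directions) are split
      into per-sample parallel events annotated as inferred private.

    Consistent matrices pass through unchanged (idempotent).
    """
    values = matrix.values.copy()
    meta = {e: dict(matrix.event_meta.get(e, {})) for e in values.index}
    no_nest = set(matrix.no_nest_pairs)

    # rule A: same-breakpoint gains, different allele counts -> lowest is stem
    by_locus: dict[tuple, list[str]] = {}
    for e in values.index:
        m = meta.get(e, {})
        if m.get("kind") == "gain" and {"chrom", "start", "end"} <= set(m):
            by_locus.setdefault((m["chrom"], m["start"], m["end"]), []).append(e)
    for locus, events in by_locus.items():
        if len(events) < 2:
            continue
        counts = {e: meta[e].get("n_a", 0) + meta[e].get("n_b", 0) for e in events}
        if len(set(counts.values())) < 2:
            continue
        lowest = min(events, key=lambda e: (counts[e], e))
        values.loc[lowest] = 1.0
        meta[lowest]["annotation"] = "inferred_stem"

    # rule B: whole-chromosome events with contradictory nesting directions
    whole = [e for e in values.index if meta.get(e, {}).get("whole_chrom")]
    split: dict[str, pd.Series] = {}
    for e in whole:
        for other in values.index:
            if other == e:
                continue
            pe, po = values.loc[e], values.loc[other]
            over = (pe + po) > 1.0 + SUM_TOL
            if not over.any():
                continue
            e_in_o = (pe <= po + NEST_TOL).all()
            o_in_e = (po <= pe + NEST_TOL).all()
            if not e_in_o and not o_in_e:
                split[e] = pe
                break
    for e, profile in split.items():
        values = values.drop(index=e)
        for s in profile.index:
            if profile[s] > 0:
                new_id = f"{e}@{s}"
                row = pd.Series(0.0, index=values.columns, name=new_id)
                row[s] = profile[s]
                values = pd.concat([values, row.to_frame().T])
                meta[new_id] = dict(meta[e], annotation="inferred_private")
                for prev in [i for i in values.index if i.startswith(f"{e}@") and i != new_id]:
                    no_nest.add(frozenset((new_id, prev)))
        meta.pop(e, None)

    return MCFMatrix(values=values, no_nest_pairs=no_nest, event_meta=meta)


# ---------------------------------------------------------------------------
# PDX / cell line deconvolution

def pdx_deconvolve(segments: Sequence[SegmentCall],
                   sample_lineage: Optional[dict[str, str]] = None,
                   ploidy: int = 2,
                   tol: float = DEFAULT_GROUP_TOL) -> SubcloneConfiguration:
    """Deconvolution for pure tumor material (xenografts, cell lines).

    Purity is 1 (murine/medium cells removed), so MCF = MSF computed against
    reference ploidy 2. MCF >= 0.9 is clonal; final clone sizes are rounded
    to the nearest 10%; parallel sums may reach 120% (two concomitant 10%
    error margins) and anything above 100% is renormalized to 100%. A 2+0
    (copy-neutral imbalance) segment in a sample whose sibling samples mostly
    show 1+2 at the same locus is ordered as an allele loss from the trisomy,
    i.e. nested below it. Aberrations unique to one lineage (cell line) or
    one tumor (PDX pair, via ``sample_lineage``) are private; the rest are
    shared/stem.
    """
    samples = sorted({s.sample_id for s in segments})
    by_event: dict[str, dict[str, float]] = {}
    event_meta: dict[str, dict] = {}
    no_nest: set[frozenset] = set()
    by_locus: dict[tuple, dict[str, tuple[int, int]]] = {}
    for seg in segments:
        if seg.nt != seg.nb:
            msf = msf_from_ratio(seg.ratio, seg.nt, seg.nb, ploidy)
        else:
            if seg.mbaf is None:
                raise ValidationError(
                    f"copy-neutral segment {seg.chrom}:{seg.start}-{seg.end} needs an mBAF")
            msf = msf_from_mbaf(seg.mbaf, seg.n_a, seg.n_b)
        mcf = mcf_from_msf(msf, 1.0).value  # purity 1
        mcf = 1.0 if mcf >= PDX_CLONAL_MCF else round_to_tenth(mcf)
        eid = f"{seg.chrom}:{seg.start}-{seg.end}({seg.n_a}+{seg.n_b})"
        by_event.setdefault(eid, {s: 0.0 for s in samples})[seg.sample_id] = mcf
        event_meta[eid] = {"chrom": seg.chrom, "start": seg.start, "end": seg.end,
                           "n_a": seg.n_a, "n_b": seg.n_b}
        by_locus.setdefault((seg.chrom, seg.start, seg.end), {})[seg.sample_id] = (seg.n_a, seg.n_b)

    values = pd.DataFrame.from_dict(by_event, orient="index")[samples].fillna(0.0)

    for locus, comps in by_locus.items():
        chrom, start, end = locus
        # CNNI-on-trisomy ordering: a 2+0 against mostly-1+2 siblings derives from
        # the trisomy by allele loss, so the trisomy is inferred present (ancestral)
        # wherever the 2+0 is observed and the 2+0 nests below it.
        states = list(comps.values())
        trisomies = sum(1 for c in states if c == (1, 2))
        if (0, 2) in states and trisomies * 2 > len(states):
            cnni_id = f"{chrom}:{start}-{end}(0+2)"
            tri_id = f"{chrom}:{start}-{end}(1+2)"
            if tri_id in values.index:
                for s, comp in comps.items():
                    if comp == (0, 2):
                        values.loc[tri_id, s] = max(values.loc[tri_id, s],
                                                    values.loc[cnni_id, s])
                event_meta[cnni_id]["derived_from"] = tri_id
        # different compositions at one locus in one sample -> mixed, never nested
        per_sample: dict[str, set] = {}
        for seg in segments:
            if (seg.chrom, seg.start, seg.end) == locus:
                per_sample.setdefault(seg.sample_id, set()).add((seg.n_a, seg.n_b))
        for s, comp_set in per_sample.items():
            if len(comp_set) > 1:
                ids = [f"{chrom}:{start}-{end}({a}+{b})" for a, b in sorted(comp_set)]
                for x, y in itertools.combinations(ids, 2):
                    no_nest.add(frozenset((x, y)))

    # per-sample parallel cap 120%, then renormalize totals above 100%
    # (applied on extant mass after the configuration is known is equivalent
    # here to scaling each sample's column before grouping)
    matrix = MCFMatrix(values=values.clip(0.0, 1.0), no_nest_pairs=no_nest,
                       event_meta=event_meta)
    groups = group_events(matrix, tol=tol)
    config = resolve_configuration(groups, no_nest_pairs=no_nest, samples=samples,
                                   sum_tol=PDX_PARALLEL_CAP - 1.0)
    config = normalize_parallel_sums(config)

    if sample_lineage:
        for g in config.groups:
            carriers = {s for s, v in g.profile.items() if v > 0}
            lineages = {sample_lineage.get(s, s) for s in carriers}
            if len(lineages) == 1 and len(set(sample_lineage.values())) > 1:
                g.annotation = "private"
            else:
                g.annotation = "shared"
    return config


def normalize_parallel_sums(config: SubcloneConfiguration) -> SubcloneConfiguration:
    """Rescale samples where parallel clone sizes exceed 100% (up to the
    tolerated 120%) back to exactly 100%."""
    for s in config.samples:
        def antichain_weight(gid):
            kids = config.children(gid)
            kid_sum = sum(antichain_weight(k.group_id) for k in kids)
            if gid is None:
                return kid_sum
            return max(config.group(gid).profile.get(s, 0.0), kid_sum)
        total = antichain_weight(None)
        if total > PDX_PARALLEL_CAP + 1e-9:
            raise ConstraintConflictError(
                f"parallel subclones sum to {total:.2f} > {PDX_PARALLEL_CAP} in sample {s}")
        if total > 1.0 + 1e-9:
            for g in config.groups:
                if g.profile.get(s, 0.0):
                    g.profile[s] = g.profile[s] / total
    return config


# ---------------------------------------------------------------------------
# event matrix for phylogeny

def event_matrix(config: SubcloneConfiguration) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary subclone-by-event matrix plus per-sample subclone fractions.

    Each subclone row carries every event on its root path, which is the
    input expected by the tree builder; the companion frame holds the
    (cumulative) per-sample fractions of each subclone.
    """
    all_events: list[str] = []
    for g in config.groups:
        all_events.extend(g.events)
    rows = {}
    for g in config.groups:
        carried = set(g.events)
        for anc in config.ancestors(g.group_id):
            carried.update(config.group(anc).events)
        rows[g.group_id] = [1 if e in carried else 0 for e in all_events]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=all_events)
    fractions = pd.DataFrame.from_dict(
        {g.group_id: {s: g.profile.get(s, 0.0) for s in config.samples}
         for g in config.groups}, orient="index")[config.samples]
    return mat, fractions
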