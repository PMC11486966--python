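"""Ground-truth tumor simulator with bulk and single-cell readouts.

The generator draws a rooted clone tree (stem clone below a zero-alteration
root cell), assigns copy-number aberrations with explicit allele
compositions and point mutations to each branch, and distributes extant
clone fractions over multi-region samples. Bulk readouts follow the forward
models used throughout the package: segment copy ratios from the dosage
equation with Gaussian noise (optionally compressed by an array platform
factor), mirrored BAFs from the allele-composition model, and variant allele
frequencies with binomial read sampling at a fixed depth. Single-cell
readouts are integer copy-number profiles over 1 Mb bins with per-bin noise.

Region fractions are drawn on a 0.1 grid (the resolution at which clone
sizes are reported) and rejection-sampled until the configuration is
*identifiable*: every clone's cumulative fraction profile is separated from
every other clone's by at least 0.2 in some sample, and is dominated only by
the profiles of its true ancestors. Multi-region sampling resolving nesting
ambiguity in this way is the study condition the generator emulates; without
it no method could recover the clone structure from fractions alone.

Treatment is modeled as per-clone survival weights: killing an entire
dominant lineage while a collateral branch survives constructs a collateral
clonal replacement (CCR) truth; letting descendants of a detected ancestral
clone expand constructs a linear-evolution truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cna_quantification import mbaf_from_msf, ratio_from_msf
from .errors import ConfigurationError, ExtinctionError, ValidationError
from .trees import CloneTree

N_CHROM = 22
BINS_PER_CHROM = 100
BIN_SIZE = 1_000_000  # 1 Mb

DEFAULT_DEPTH = 200
DEFAULT_NOISE_SD = 0.05

#: minimal cumulative-profile separation between any two clones in >=1 sample
SEPARATION = 0.2

#: allelic compositions by CNA kind: (n_a, n_b) of the aberrant cells
CNA_KINDS = {
    "gain": (1, 2),   # trisomy
    "loss": (0, 1),   # monosomy / deletion
    "cnni": (0, 2),   # copy-neutral imbalance
}


@dataclass(frozen=True)
class CNAEvent:
    event_id: str
    chrom: str
    start_bin: int  # 0-based inclusive
    end_bin: int    # 0-based exclusive
    kind: str
    n_a: int
    n_b: int

    @property
    def nt(self) -> int:
        return self.n_a + self.n_b

    @property
    def start_bp(self) -> int:
        return self.start_bin * BIN_SIZE + 1

    @property
    def end_bp(self) -> int:
        return self.end_bin * BIN_SIZE


@dataclass(frozen=True)
class SNVEvent:
    event_id: str
    chrom: str
    pos: int
    multiplicity: int = 1
    cn: int = 2  # local total copies in the tumor


@dataclass
class Region:
    name: str
    purity: float
    timepoint: str
    extant: dict[str, float]  # clone -> fraction of tumor cells (0.1 grid)

    def __post_init__(self):
        total = sum(self.extant.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"region {self.name}: clone fractions sum to {total}")


@dataclass
class TruthTumor:
    tree: CloneTree
    cna_events: dict[str, CNAEvent]
    snv_events: dict[str, SNVEvent]
    regions: list[Region]
    seed: int
    mode: str = "branched"

    def clones(self) -> list[str]:
        return [n.name for n in self.tree.taxa()]

    def clone_node(self, clone: str):
        return self.tree.find_taxon(clone)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise ValidationError(f"unknown region {name!r}")

    def cumulative(self, clone: str, region: str) -> float:
        """Fraction of tumor cells in ``region`` carrying ``clone``'s genotype."""
        reg = self.region(region)
        node = self.clone_node(clone)
        total = 0.0
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_taxon:
                total += reg.extant.get(n.name, 0.0)
            stack.extend(n.children)
        return round(total, 10)

    def clone_of_event(self, event_id: str) -> str:
        for node in self.tree.taxa():
            if event_id in node.events:
                return node.name
        raise ValidationError(f"event {event_id!r} not on any branch")

    def event_profile(self, event_id: str) -> dict[str, float]:
        clone = self.clone_of_event(event_id)
        return {r.name: self.cumulative(clone, r.name) for r in self.regions}


# ---------------------------------------------------------------------------
# helpers

def _quantize_tenths(fractions: Mapping[str, float]) -> dict[str, float]:
    """Largest-remainder rounding of a composition onto the 0.1 grid."""
    total = sum(fractions.values())
    if total <= 0:
        raise ValidationError("cannot quantize an empty composition")
    scaled = {c: 10.0 * f / total for c, f in fractions.items()}
    base = {c: int(np.floor(v)) for c, v in scaled.items()}
    short = 10 - sum(base.values())
    order = sorted(scaled, key=lambda c: (-(scaled[c] - base[c]), c))
    for c in order[:short]:
        base[c] += 1
    return {c: v / 10.0 for c, v in base.items() if v > 0}


def _identifiable(truth: TruthTumor, separation: float = SEPARATION) -> bool:
    """Check that cumulative profiles pin down the clone tree.

    (a) every clone pair differs by >= ``separation`` in some sample (so no
    two clones merge under pattern grouping); (b) every clone's profile is
    dominated (within the 0.1 nesting tolerance) only by its true ancestors,
    so the deepest-dominator placement recovers the true parent.
    """
    clones = truth.clones()
    regions = [r.name for r in truth.regions]
    q = {c: np.array([truth.cumulative(c, r) for r in regions]) for c in clones}
    for a, b in itertools.combinations(clones, 2):
        if np.max(np.abs(q[a] - q[b])) < separation - 1e-9:
            return False
    nodes = {c: truth.clone_node(c) for c in clones}
    for v in clones:
        for u in clones:
            if u == v:
                continue
            if truth.tree.is_ancestor(nodes[u], nodes[v]):
                continue  # true ancestor: domination expected
            if truth.tree.is_ancestor(nodes[v], nodes[u]):
                continue  # descendant: dominated by v instead
            # u must NOT dominate v within the nesting tolerance
            if not np.any(q[v] >= q[u] + separation - 1e-9):
                return False
    return True


# ---------------------------------------------------------------------------
# truth construction

def simulate_truth(n_clones: int = 6,
                   mode: str = "branched",
                   n_regions: int = 3,
                   cna_rate: float = 1.5,
                   snv_rate: float = 2.0,
                   purity_range: tuple[float, float] = (0.6, 0.95),
                   timepoint: str = "pre",
                   seed: int = 0,
                   max_attempts: int = 60_000) -> TruthTumor:
    """Random ground-truth tumor with an identifiable region composition.

    ``mode``: 'linear' (chain), 'star' (all clones children of the stem) or
    'branched' (random attachment with at least one multifurcation). The stem
    branch always carries two gains, a loss and a copy-neutral imbalance (so
    purity is estimable from both dosage and imbalance); other branches carry
    1 + Poisson(cna_rate - 1) CNAs and Poisson(snv_rate) SNVs. Deterministic
    given the seed.
    """
    if n_clones < 1:
        raise ConfigurationError("need at least one clone")
    if cna_rate < 1 or snv_rate < 0:
        raise ConfigurationError("invalid event rates")
    rng = np.random.default_rng(seed)

    for attempt in range(30):
        tree, names = _draw_topology(n_clones, mode, rng)
        cna_events, snv_events = _draw_events(tree, names, cna_rate, snv_rate, rng)
        truth = _draw_regions(tree, names, cna_events, snv_events, n_regions,
                              purity_range, timepoint, seed, mode, rng,
                              max_attempts // 30)
        if truth is not None:
            return truth
    raise ValidationError(
        f"could not draw an identifiable {n_clones}-clone configuration "
        f"for seed {seed}")


def _draw_topology(n_clones, mode, rng):
    tree = CloneTree()
    names = [f"C{i + 1}" for i in range(n_clones)]
    nodes = {}
    for i, name in enumerate(names):
        if i == 0:
            parent = tree.root
        elif mode == "linear":
            parent = nodes[names[i - 1]]
        elif mode == "star":
            parent = nodes[names[0]]
        elif mode == "branched":
            parent = nodes[names[int(rng.integers(0, i))]]
        else:
            raise ConfigurationError(f"unknown mode {mode!r}")
        nodes[name] = tree.add_child(parent, events=(), name=name)
    if mode == "branched" and n_clones >= 3:
        if not any(len(n.children) >= 2 for n in nodes.values()):
            # force a second lineage off the stem
            last = nodes[names[-1]]
            last.parent.children.remove(last)
            last.parent = nodes[names[0]]
            nodes[names[0]].children.append(last)
    return tree, names


def _draw_events(tree, names, cna_rate, snv_rate, rng):
    # genomic slots: two disjoint halves per chromosome, no overlapping CNAs
    slots = [(str(c + 1), h) for c in range(N_CHROM) for h in (0, 1)]
    rng.shuffle(slots)
    slot_iter = iter(slots)
    cna_events: dict[str, CNAEvent] = {}
    snv_events: dict[str, SNVEvent] = {}

    def new_cna(kind):
        try:
            chrom, half = next(slot_iter)
        except StopIteration:
            return None
        half_len = BINS_PER_CHROM // 2
        length = int(rng.integers(5, min(41, half_len)))
        start = int(rng.integers(0, half_len - length)) + half * half_len
        n_a, n_b = CNA_KINDS[kind]
        ev = CNAEvent(event_id=f"{chrom}:{start * BIN_SIZE + 1}-{(start + length) * BIN_SIZE}"
                               f"({n_a}+{n_b})",
                      chrom=chrom, start_bin=start, end_bin=start + length,
                      kind=kind, n_a=n_a, n_b=n_b)
        cna_events[ev.event_id] = ev
        return ev

    def new_snv():
        try:
            chrom, half = next(slot_iter)
        except StopIteration:
            return None
        pos = int(rng.integers(0, BINS_PER_CHROM // 2) + half * BINS_PER_CHROM // 2)
        pos = pos * BIN_SIZE + int(rng.integers(1, BIN_SIZE))
        ev = SNVEvent(event_id=f"{chrom}:{pos}:A>T", chrom=chrom, pos=pos)
        snv_events[ev.event_id] = ev
        return ev

    for i, name in enumerate(names):
        node = tree.find_taxon(name)
        events = []
        if i == 0:  # stem: fixed repertoire so purity is always estimable
            kinds = ["gain", "gain", "loss", "cnni"]
        else:
            n_cna = 1 + int(rng.poisson(max(cna_rate - 1.0, 0.0)))
            kinds = [str(rng.choice(["gain", "loss", "cnni"], p=[0.5, 0.35, 0.15]))
                     for _ in range(n_cna)]
        for kind in kinds:
            ev = new_cna(kind)
            if ev is not None:
                events.append(ev.event_id)
        for _ in range(int(rng.poisson(snv_rate))):
            ev = new_snv()
            if ev is not None:
                events.append(ev.event_id)
        if not events:  # every branch must be observable
            ev = new_cna("gain") or new_snv()
            if ev is not None:
                events.append(ev.event_id)
        node.events = frozenset(events)
        node._genotype = None
    for node in tree.nodes():
        node._genotype = None
    return cna_events, snv_events


def _draw_regions(tree, names, cna_events, snv_events, n_regions, purity_range,
                  timepoint, seed, mode, rng, attempts):
    n = len(names)
    idx = {c: i for i, c in enumerate(names)}
    # descendant closure: desc[i, j] = clone j in subtree of clone i
    desc = np.zeros((n, n), dtype=bool)
    for c in names:
        stack = [tree.find_taxon(c)]
        while stack:
            node = stack.pop()
            if node.is_taxon:
                desc[idx[c], idx[node.name]] = True
            stack.extend(node.children)
    anc_or_self = desc.T  # anc_or_self[i, j] = clone j ancestor-or-self of clone i
    comparable = desc | desc.T
    np.fill_diagonal(comparable, True)

    k_hi = min(n, 5)
    for attempt in range(max(attempts, 100)):
        extant = np.zeros((n, n_regions))
        if attempt % 2 == 0 or n == 1:
            # free proposal: random clone subsets per region (clones may span
            # several regions, as a third of real subclones do)
            for r in range(n_regions):
                k = int(rng.integers(2, k_hi + 1)) if n > 1 else 1
                chosen = rng.choice(n, size=k, replace=False)
                tenths = rng.multinomial(10 - k, rng.dirichlet(np.ones(k))) + 1
                extant[chosen, r] = tenths / 10.0
        else:
            # partition proposal: each clone extant in one home region only —
            # far more likely to be identifiable when clones are many
            home = rng.integers(0, n_regions, size=n)
            bad = False
            for r in range(n_regions):
                members = np.where(home == r)[0]
                if len(members) == 0 or len(members) > 10:
                    bad = True
                    break
                k = len(members)
                tenths = rng.multinomial(10 - k, rng.dirichlet(np.ones(k))) + 1
                extant[members, r] = tenths / 10.0
            if bad:
                continue
        if not (extant.max(axis=1) >= 0.1 - 1e-9).all():
            continue
        q = desc @ extant  # cumulative fraction per clone x region
        # pairwise L-inf separation >= SEPARATION
        diff = np.abs(q[:, None, :] - q[None, :, :]).max(axis=2)
        np.fill_diagonal(diff, 1.0)
        if (diff < SEPARATION - 1e-9).any():
            continue
        # an incomparable clone must never dominate another within the
        # nesting tolerance: exceed[i, j] = exists region with q_i >= q_j + sep
        exceed = (q[:, None, :] >= q[None, :, :] + SEPARATION - 1e-9).any(axis=2)
        if (~exceed & ~comparable).any():
            continue
        regions = []
        for r in range(n_regions):
            purity = float(np.round(rng.uniform(*purity_range), 2))
            regions.append(Region(
                name=f"R{r + 1}", purity=purity, timepoint=timepoint,
                extant={names[i]: round(extant[i, r], 10)
                        for i in range(n) if extant[i, r] > 0}))
        return TruthTumor(tree=tree, cna_events=dict(cna_events),
                          snv_events=dict(snv_events), regions=regions,
                          seed=seed, mode=mode)
    return None


def recovered_matches_truth(subclones: Sequence[Mapping], truth: TruthTumor) -> bool:
    """Exact structural recovery check for pipeline output against the truth.

    ``subclones`` is the pipeline report's subclone list (id, events,
    parent). Each recovered group must consist of events from exactly one
    truth clone, the mapping must be a bijection onto the clones, and the
    parent relations must agree — i.e. the rooted Robinson–Foulds distance
    between recovered and true clone tree is zero. Events legitimately
    removed upstream (e.g. variants below the VAF cutoff in every sample) may
    be absent, but every clone must be represented by its remaining events.
    """
    owner = {}
    for c in truth.clones():
        for e in truth.clone_node(c).events:
            owner[e] = c
    mapping: dict[str, str] = {}
    for g in subclones:
        owners = {owner.get(e) for e in g["events"]}
        if len(owners) != 1 or None in owners:
            return False
        mapping[g["id"]] = owners.pop()
    if sorted(mapping.values()) != sorted(set(mapping.values())):
        return False  # a clone fragmented into several groups
    if set(mapping.values()) != set(truth.clones()):
        return False  # a clone lost entirely
    for g in subclones:
        clone = mapping[g["id"]]
        true_parent = truth.clone_node(clone).parent.name
        got_parent = mapping.get(g["parent"]) if g["parent"] is not None else None
        if got_parent != true_parent:
            return False
    return True


# ---------------------------------------------------------------------------
# bulk rendering

def render_bulk(truth: TruthTumor,
                region: str,
                depth: int = DEFAULT_DEPTH,
                noise_sd: float = DEFAULT_NOISE_SD,
                platform_factor: Optional[float] = None,
                seed: int = 0,
                sample_id: Optional[str] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and variant tables for one region.

    Every event is reported in every region (a region without the aberration
    shows a normal copy ratio plus noise, and zero variant reads). Ratios are
    linear unless ``platform_factor`` is given, in which case the ``ratio``
    column holds compressed log2 values to be linearized with the platform
    correction.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    reg = truth.region(region)
    rng = np.random.default_rng(seed)
    sample = sample_id or region

    seg_rows = []
    for eid in sorted(truth.cna_events):
        ev = truth.cna_events[eid]
        clone = truth.clone_of_event(eid)
        msf = reg.purity * truth.cumulative(clone, region)
        ratio = ratio_from_msf(msf, ev.nt, 2, 2) + rng.normal(0.0, noise_sd)
        ratio = max(ratio, 0.05)
        mbaf = mbaf_from_msf(msf, ev.n_a, ev.n_b) + rng.normal(0.0, noise_sd)
        mbaf = float(np.clip(mbaf, 0.5, 0.995))
        if platform_factor is not None:
            ratio = np.log2(ratio) * platform_factor
        seg_rows.append({
            "sample": sample, "chrom": ev.chrom, "start": ev.start_bp,
            "end": ev.end_bp, "ratio": float(ratio), "mbaf": mbaf,
            "n_a": ev.n_a, "n_b": ev.n_b,
            "clonal_hint": truth.cumulative(clone, region) >= 1.0 - 1e-9,
            "true_msf": msf,
        })
    segments = pd.DataFrame(seg_rows)

    var_rows = []
    for eid in sorted(truth.snv_events):
        ev = truth.snv_events[eid]
        clone = truth.clone_of_event(eid)
        msf = reg.purity * truth.cumulative(clone, region)
        vaf_true = ev.multiplicity * msf / (ev.cn * reg.purity + 2.0 * (1.0 - reg.purity))
        alt = int(rng.binomial(depth, min(vaf_true, 1.0)))
        var_rows.append({
            "sample": sample, "chrom": ev.chrom, "pos": ev.pos, "ref": "A",
            "alt": "T", "depth": depth, "alt_reads": alt,
            "vaf": alt / depth, "normal_fraction": 0.0, "source": "wes_frozen",
            "true_vaf": vaf_true,
        })
    variants = pd.DataFrame(var_rows)
    return segments, variants


def render_bulk_all(truth: TruthTumor, depth: int = DEFAULT_DEPTH,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    platform_factor: Optional[float] = None,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenated bulk tables over all regions (one sub-seed per region)."""
    segs, vars_ = [], []
    for i, reg in enumerate(truth.regions):
        s, v = render_bulk(truth, reg.name, depth=depth, noise_sd=noise_sd,
                           platform_factor=platform_factor,
                           seed=(seed * 1009 + i) % (2**31 - 1))
        segs.append(s)
        vars_.append(v)
    return pd.concat(segs, ignore_index=True), pd.concat(vars_, ignore_index=True)


# ---------------------------------------------------------------------------
# treatment

def apply_treatment(truth: TruthTumor,
                    weights: Mapping[str, float],
                    timepoint: str = "post",
                    seed: Optional[int] = None) -> TruthTumor:
    """Post-treatment tumor: clone fractions reweighted by survival.

    Post fractions are proportional to pre fractions times the clone's
    survival weight, renormalized per region and re-quantized to the 0.1
    grid. A region whose detected populations are all killed is repopulated
    uniformly by the surviving clones (expansion of sub-detection residues).
    All-zero weights are an extinction error; all-one weights leave the
    fractions unchanged.
    """
    for c, w in weights.items():
        if not 0.0 <= w <= 1.0:
            raise ValidationError(f"survival weight of {c} must lie in [0, 1]")
    survivors = [c for c in truth.clones() if weights.get(c, 1.0) > 0]
    if not survivors:
        raise ExtinctionError("treatment killed every clone")
    post_regions = []
    for reg in truth.regions:
        mass = {c: f * weights.get(c, 1.0) for c, f in reg.extant.items()}
        mass = {c: m for c, m in mass.items() if m > 0}
        if not mass:
            mass = {c: 1.0 for c in survivors}
        post_regions.append(Region(name=f"{reg.name}_{timepoint}", purity=reg.purity,
                                   timepoint=timepoint,
                                   extant=_quantize_tenths(mass)))
    return TruthTumor(tree=truth.tree, cna_events=truth.cna_events,
                      snv_events=truth.snv_events, regions=post_regions,
                      seed=truth.seed, mode=truth.mode)


# ---------------------------------------------------------------------------
# constructed treatment scenarios (CCR vs linear, known by design)

@dataclass
class Scenario:
    truth: TruthTumor  # pre and post regions combined
    expected: str      # 'CCR' | 'linear'
    pre_samples: list[str]
    post_samples: list[str]


def treatment_scenario(kind: str, seed: int = 0,
                       n_regions: int = 3,
                       purity_range: tuple[float, float] = (0.6, 0.95),
                       max_attempts: int = 5000) -> Scenario:
    """A tumor whose temporal evolution pattern is known by construction.

    ``kind='ccr'``: the stem clone has two sub-lineages; all detectable
    pre-treatment mass lies in one (L1 -> L2), which chemotherapy eradicates,
    and the post-treatment samples are repopulated by the collateral lineage
    (R1 -> R2) that was below detection before. The surviving populations
    share no detected ancestor with the pre-treatment ones below the stem —
    collateral clonal replacement.

    ``kind='linear'``: a chain stem -> A -> B with a late clone D branching
    off A. A dominates before treatment and its descendants (B, D) expand
    after it, so later populations descend linearly from a clone already
    detected at diagnosis.
    """
    if kind not in ("ccr", "linear"):
        raise ConfigurationError(f"scenario kind must be 'ccr' or 'linear', got {kind!r}")
    rng = np.random.default_rng(seed)

    for _ in range(max_attempts):
        tree = CloneTree()
        if kind == "ccr":
            stem = tree.add_child(tree.root, name="C1")
            l1 = tree.add_child(stem, name="L1")
            tree.add_child(l1, name="L2")
            r1 = tree.add_child(stem, name="R1")
            tree.add_child(r1, name="R2")
            pre_pool, post_pool = ["L1", "L2"], ["R1", "R2"]
        else:
            stem = tree.add_child(tree.root, name="C1")
            a = tree.add_child(stem, name="A")
            tree.add_child(a, name="B")
            tree.add_child(a, name="D")
            # the stem population is still extant at diagnosis (distinguishing
            # the dominant clone A from the stem), and A's descendants expand
            # after treatment
            pre_pool, post_pool = ["C1", "A", "B"], ["B", "D"]
        names = [n.name for n in tree.taxa()]
        cna_events, snv_events = _draw_events(tree, names, cna_rate=2.0,
                                              snv_rate=2.0, rng=rng)

        regions = []
        ok = True
        for r in range(n_regions):
            purity = float(np.round(rng.uniform(*purity_range), 2))
            extant = _grid_split(pre_pool, rng, dominant="A" if kind == "linear" else None)
            regions.append(Region(name=f"Pre{r + 1}", purity=purity,
                                  timepoint="pre", extant=extant))
        for r in range(n_regions):
            purity = float(np.round(rng.uniform(*purity_range), 2))
            extant = _grid_split(post_pool, rng)
            regions.append(Region(name=f"Post{r + 1}", purity=purity,
                                  timepoint="post", extant=extant))
        truth = TruthTumor(tree=tree, cna_events=cna_events, snv_events=snv_events,
                           regions=regions, seed=seed, mode=kind)
        # scenario-critical clones must be solidly detectable at their timepoint
        for pool, tp in ((pre_pool, "pre"), (post_pool, "post")):
            for clone in pool:
                mean = np.mean([reg.extant.get(clone, 0.0) for reg in regions
                                if reg.timepoint == tp])
                if mean < 0.2:
                    ok = False
        if ok and _identifiable(truth):
            return Scenario(truth=truth, expected="CCR" if kind == "ccr" else "linear",
                            pre_samples=[r.name for r in regions if r.timepoint == "pre"],
                            post_samples=[r.name for r in regions if r.timepoint == "post"])
    raise ValidationError(f"could not construct an identifiable {kind} scenario for seed {seed}")


def _grid_split(clones: Sequence[str], rng, dominant: Optional[str] = None) -> dict[str, float]:
    """Random 0.1-grid composition over ``clones`` with every clone >= 0.2;
    ``dominant`` (if given) receives at least half of the mass."""
    while True:
        weights = rng.dirichlet(np.ones(len(clones)))
        extant = _quantize_tenths(dict(zip(clones, weights)))
        if any(extant.get(c, 0.0) < 0.2 for c in clones):
            continue
        if dominant is not None and extant.get(dominant, 0.0) < 0.5:
            continue
        return extant


# ---------------------------------------------------------------------------
# single-cell rendering

def render_cells(truth: TruthTumor,
                 region: str,
                 n_cells: int,
                 bin_noise_rate: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """Cells-by-bins integer copy-number matrix for one region.

    Cells are drawn multinomially from the region's extant clone fractions;
    each cell's profile applies its clone's CNAs on a diploid baseline.
    Per-bin noise flips single bins by one copy at ``bin_noise_rate`` —
    isolated (<5 bin) deviations that the event-calling filter must remove.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    reg = truth.region(region)
    rng = np.random.default_rng(seed)
    clones = sorted(reg.extant)
    counts = rng.multinomial(n_cells, [reg.extant[c] for c in clones])

    chroms = [str(c + 1) for c in range(N_CHROM)]
    columns = pd.MultiIndex.from_tuples(
        [(chrom, b) for chrom in chroms for b in range(BINS_PER_CHROM)])
    rows = {}
    cell_idx = 0
    for clone, count in zip(clones, counts):
        node = truth.clone_node(clone)
        genotype = node.genotype
        base = {chrom: np.full(BINS_PER_CHROM, 2, dtype=int) for chrom in chroms}
        for eid in genotype:
            ev = truth.cna_events.get(eid)
            if ev is None:
                continue
            base[ev.chrom][ev.start_bin:ev.end_bin] = ev.nt
        flat = np.concatenate([base[chrom] for chrom in chroms])
        for _ in range(count):
            profile = flat.copy()
            if bin_noise_rate > 0:
                flips = rng.random(profile.shape[0]) < bin_noise_rate
                delta = rng.choice([-1, 1], size=profile.shape[0])
                profile[flips] = np.maximum(profile[flips] + delta[flips], 0)
            rows[f"cell_{cell_idx:04d}"] = profile
            cell_idx += 1
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
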