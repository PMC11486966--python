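"""Copy-number event calling and clone trees from single-cell WGS profiles.

Input is a matrix of integer copy numbers over 1 Mb genome bins, one row (or
column) per cell, from shallow single-cell whole-genome sequencing. Event
calling applies the run-length filter optimized for this data type: a
deviant copy-number run must span at least five consecutive 1 Mb bins to be
accepted, except high-grade amplifications (copy number >= 5) overlapping a
designated amplicon region (by default the 2p24 region around *MYCN* and the
4q28.3–q31.1 region around *MAML3*), where two consecutive bins count as a
true gain.

Events of all cells are then harmonized into a shared catalog — overlapping
same-class events are decomposed at their (tolerance-snapped) boundaries so
that every cell's event is a union of catalog entries — producing the binary
cell-by-event matrix used for phylogenetic reconstruction. Cells with
identical profiles collapse into one clone taxon carrying a cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import phylogeny
from .errors import HarmonizationError, ValidationError
from .trees import CloneTree

MIN_EVENT_BINS = 5
AMPLICON_MIN_BINS = 2
AMPLIFICATION_CN = 5  # copies at or above which a gain is an amplification

#: designated high-grade-amplification regions, 1 Mb bin coordinates
#: (0-based, end-exclusive) on the hg19-sized genome: 2p24 (*MYCN*) and
#: 4q28.3-q31.1 (*MAML3*)
DEFAULT_AMPLICON_REGIONS = (
    ("2", 12, 18),
    ("4", 137, 152),
)


@dataclass
class CellEvent:
    chrom: str
    start_bin: int  # 0-based inclusive
    end_bin: int    # 0-based exclusive
    copy_number: int
    klass: str      # 'gain' | 'loss' | 'amplification'

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def overlaps(self, chrom: str, start: int, end: int) -> int:
        if self.chrom != chrom:
            return 0
        return max(0, min(self.end_bin, end) - max(self.start_bin, start))


@dataclass
class CellProfile:
    cell_id: str
    bins: dict[str, np.ndarray]  # chrom -> integer copy number per 1 Mb bin

    def __post_init__(self):
        if not self.bins:
            raise ValidationError(f"cell {self.cell_id} has an empty profile")
        for chrom, arr in self.bins.items():
            arr = np.asarray(arr, dtype=int)
            if (arr < 0).any():
                raise ValidationError(f"negative copy number on {chrom} in {self.cell_id}")
            self.bins[chrom] = arr


def profiles_from_frame(frame: pd.DataFrame) -> list[CellProfile]:
    """Cells-by-bins frame (columns MultiIndex (chrom, bin) or 'chrom:bin') ->
    profiles."""
    cols = frame.columns
    if not isinstance(cols, pd.MultiIndex):
        parsed = [tuple(str(c).split(":", 1)) for c in cols]
        frame = frame.copy()
        frame.columns = pd.MultiIndex.from_tuples(
            [(chrom, int(b)) for chrom, b in parsed])
    profiles = []
    for cell_id, row in frame.iterrows():
        bins = {chrom: row[chrom].to_numpy(dtype=int)
                for chrom in row.index.get_level_values(0).unique()}
        profiles.append(CellProfile(cell_id=str(cell_id), bins=bins))
    return profiles


def call_cell_events(profile: CellProfile,
                     ploidy: int = 2,
                     min_bins: int = MIN_EVENT_BINS,
                     amplicon_regions: Sequence[tuple[str, int, int]] = DEFAULT_AMPLICON_REGIONS,
                     amplicon_min_bins: int = AMPLICON_MIN_BINS,
                     amplification_cn: int = AMPLIFICATION_CN) -> list[CellEvent]:
    """Maximal constant-copy-number runs deviating from the baseline ploidy.

    Runs shorter than ``min_bins`` are excluded, unless they are high-grade
    amplifications (copy number >= ``amplification_cn``) overlapping a
    designated amplicon region with at least ``amplicon_min_bins`` bins.
    """
    events: list[CellEvent] = []
    for chrom in sorted(profile.bins):
        arr = profile.bins[chrom]
        i = 0
        while i < len(arr):
            cn = arr[i]
            j = i
            while j < len(arr) and arr[j] == cn:
                j += 1
            if cn != ploidy:
                if cn >= amplification_cn:
                    klass = "amplification"
                elif cn > ploidy:
                    klass = "gain"
                else:
                    klass = "loss"
                ev = CellEvent(chrom=chrom, start_bin=i, end_bin=j,
                               copy_number=int(cn), klass=klass)
                if ev.n_bins >= min_bins:
                    events.append(ev)
                elif (klass == "amplification"
                      and ev.n_bins >= amplicon_min_bins
                      and any(ev.overlaps(c, s, e) for c, s, e in amplicon_regions)):
                    events.append(ev)
            i = j
    return events


def _snap(values: Iterable[int], tol: int) -> dict[int, int]:
    """Map each boundary to the representative of its tolerance cluster."""
    out: dict[int, int] = {}
    cluster: list[int] = []
    for v in sorted(set(values)):
        if cluster and v - cluster[-1] > tol:
            rep = cluster[0]
            out.update({x: rep for x in cluster})
            cluster = []
        cluster.append(v)
    if cluster:
        rep = cluster[0]
        out.update({x: rep for x in cluster})
    return out


def harmonize_events(events_by_cell: Mapping[str, Sequence[CellEvent]],
                     bin_tol: int = 1) -> tuple[list[CellEvent], pd.DataFrame]:
    """Shared event catalog and binary cell-by-event matrix.

    Boundaries of same-class events on the same chromosome agreeing within
    ``bin_tol`` bins are snapped together; the snapped boundaries decompose
    the chromosome into atomic intervals, each becoming one catalog entry
    carried by every cell whose event covers it. Identical events across
    cells thus merge into a single entry, partially overlapping events split
    into shared and extension entries, and nested distinct intervals stay
    separate.
    """
    if len(events_by_cell) < 2:
        raise ValidationError("harmonization needs events from at least two cells")
    groups: dict[tuple[str, str], list[tuple[str, CellEvent]]] = {}
    for cell in sorted(events_by_cell):
        for ev in events_by_cell[cell]:
            key = (ev.chrom, "amplification" if ev.klass == "amplification" else ev.klass)
            groups.setdefault(key, []).append((cell, ev))

    catalog: list[CellEvent] = []
    carriers: dict[str, set[str]] = {}
    for (chrom, klass), items in sorted(groups.items()):
        snap_start = _snap([ev.start_bin for _, ev in items], bin_tol)
        snap_end = _snap([ev.end_bin for _, ev in items], bin_tol)
        bounds = sorted({snap_start[ev.start_bin] for _, ev in items}
                        | {snap_end[ev.end_bin] for _, ev in items})
        atoms = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        for start, end in atoms:
            carrying: set[str] = set()
            states: list[int] = []
            for cell, ev in items:
                if snap_start[ev.start_bin] <= start and snap_end[ev.end_bin] >= end:
                    carrying.add(cell)
                    states.append(ev.copy_number)
            if not carrying:
                continue
            cn = int(np.median(states))
            eid = f"{chrom}:{start}-{end}:{klass}"
            catalog.append(CellEvent(chrom=chrom, start_bin=start, end_bin=end,
                                     copy_number=cn, klass=klass))
            carriers[eid] = carrying

    cells = sorted(events_by_cell)
    event_ids = [f"{ev.chrom}:{ev.start_bin}-{ev.end_bin}:{ev.klass}" for ev in catalog]
    matrix = pd.DataFrame(0, index=cells, columns=event_ids, dtype=int)
    for eid, carrying in carriers.items():
        matrix.loc[sorted(carrying), eid] = 1
    return catalog, matrix


def collapse_clones(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse cells with identical event profiles into clone taxa.

    Returns the clone-by-event matrix and the cell counts per clone. Clones
    are named clone_1, clone_2, ... in order of decreasing size (ties by
    genotype string, deterministic).
    """
    genotype_cells: dict[tuple, list[str]] = {}
    for cell in matrix.index:
        genotype_cells.setdefault(tuple(matrix.loc[cell]), []).append(str(cell))
    ordered = sorted(genotype_cells.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows, counts = {}, {}
    for i, (genotype, cells) in enumerate(ordered, start=1):
        name = f"clone_{i}"
        rows[name] = list(genotype)
        counts[name] = len(cells)
    clone_matrix = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)
    return clone_matrix, counts


def build_cell_tree(matrix: pd.DataFrame,
                    event_classes: Optional[Mapping[str, str]] = None) -> CloneTree:
    """Maximum-parsimony tree over single cells, collapsed to clones.

    Taxa are clones (cells with identical profiles) annotated with their cell
    counts; the tree is rooted in a cell without alterations.
    """
    clone_matrix, counts = collapse_clones(matrix)
    tree = phylogeny.build_tree(clone_matrix, event_classes=event_classes)
    for node in tree.nodes():
        if node.is_taxon:
            total = 0
            for name in node.name.split("+"):
                total += counts.get(name, 0)
            node.cell_count = total
    return tree


def pop_statistic(trees: CloneTree | Sequence[CloneTree],
                  predicate: Callable[[frozenset], bool]) -> float:
    """Proportion of progeny (PoP): the fraction of sequenced cells
    descending from branches whose event set matches ``predicate``.

    The root (zero-alteration cell, empty event set) counts as a branch, so a
    predicate matching it captures every cell. With several trees (tumors)
    the per-tree fractions are averaged.
    """
    if isinstance(trees, CloneTree):
        trees = [trees]
    fractions = []
    for tree in trees:
        total = 0
        matched = 0
        for taxon in tree.taxa():
            count = taxon.cell_count or 0
            total += count
            if any(predicate(frozenset(node.events)) for node in tree.root_path(taxon)):
                matched += count
        if total == 0:
            raise ValidationError("PoP undefined: tree carries no cells")
        fractions.append(matched / total)
    return float(np.mean(fractions))


def clone_dynamics(matrices: Sequence[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Per-timepoint clone fractions (fishplot-ready).

    ``matrices`` holds (timepoint, cell-by-event matrix) pairs over a common
    event catalog; clones are identical genotypes pooled across timepoints.
    """
    if not matrices:
        raise ValidationError("no timepoints supplied")
    columns = list(matrices[0][1].columns)
    for tp, mat in matrices:
        if list(mat.columns) != columns:
            raise HarmonizationError(
                f"event catalog of timepoint {tp!r} differs from the first timepoint")
    genotypes: dict[tuple, str] = {}
    rows: dict[str, dict[str, float]] = {}
    pooled = pd.concat([m for _, m in matrices])
    for genotype in sorted({tuple(r) for r in pooled.to_numpy().tolist()},
                           key=lambda g: (-sum(g), g)):
        genotypes[genotype] = f"clone_{len(genotypes) + 1}"
    for tp, mat in matrices:
        counts: dict[str, int] = {}
        for _, row in mat.iterrows():
            counts[genotypes[tuple(row)]] = counts.get(genotypes[tuple(row)], 0) + 1
        n = len(mat)
        for clone in genotypes.values():
            rows.setdefault(clone, {})[tp] = counts.get(clone, 0) / n
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[[tp for tp, _ in matrices]]
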