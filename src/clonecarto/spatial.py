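"""Approximate 2D subclone territories from per-biopsy clone fractions.

Paraffin blocks sectioned at a roughly constant depth allow subclone sizes
(clone fractions times biopsy areas) to be projected onto a two-dimensional
map. Placement follows three rules: a subclone detected in several biopsies
sits at the midpoint of their centroids (around the interface); a subclone
private to one biopsy is packed into the remaining space of that biopsy, as
far as possible from already-placed territories; a nested subclone found in
a single sample sits at the geographic center of its mother clone.
Territories are rendered as circles of the fraction-proportional area — only
the count, area and centroid feed the summary statistics (subclones per mm²
and the median pairwise centroid distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class BiopsyLocation:
    sample_id: str
    x_mm: float
    y_mm: float
    area_mm2: float

    def __post_init__(self):
        if self.area_mm2 <= 0:
            raise ValidationError(f"biopsy {self.sample_id} must have positive area")

    @property
    def radius(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi)


@dataclass
class Territory:
    subclone: str
    x_mm: float
    y_mm: float
    area_mm2: float
    samples: tuple[str, ...]
    nested_in: Optional[str] = None

    @property
    def radius(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi)


@dataclass
class TerritoryStats:
    n_territories: int
    density_per_mm2: float
    median_centroid_distance_mm: Optional[float]


def place_territories(fractions: pd.DataFrame,
                      layout: Sequence[BiopsyLocation],
                      parents: Optional[Mapping[str, Optional[str]]] = None,
                      presence_threshold: float = 0.05) -> list[Territory]:
    """Territories (circles) for the subclones of ``fractions``.

    ``fractions`` is subclones x samples; a subclone is present in a biopsy
    where its fraction reaches ``presence_threshold``. Territory area is the
    sum of fraction x biopsy area over the biopsies of presence. ``parents``
    optionally gives the nesting structure for the mother-centroid rule.
    """
    by_id = {b.sample_id: b for b in layout}
    missing = [s for s in fractions.columns if s not in by_id]
    if missing:
        raise ValidationError(f"samples without layout coordinates: {missing}")
    parents = dict(parents or {})

    presence: dict[str, list[str]] = {}
    areas: dict[str, float] = {}
    for sub in fractions.index:
        samples = [s for s in fractions.columns
                   if fractions.loc[sub, s] >= presence_threshold]
        presence[str(sub)] = samples
        areas[str(sub)] = float(sum(fractions.loc[sub, s] * by_id[s].area_mm2
                                    for s in samples))

    placed: dict[str, Territory] = {}

    def order_key(sub: str):
        # multi-biopsy first, then larger areas; deterministic
        return (len(presence[sub]) < 2, -areas[sub], sub)

    # place parents before children
    ordered: list[str] = []
    pending = sorted((str(s) for s in fractions.index), key=order_key)
    while pending:
        progressed = False
        for sub in list(pending):
            par = parents.get(sub)
            if par is None or par in ordered or par not in presence:
                ordered.append(sub)
                pending.remove(sub)
                progressed = True
        if not progressed:
            raise ValidationError("cyclic nesting in parents mapping")

    for sub in ordered:
        samples = presence[sub]
        if not samples:
            continue
        par = parents.get(sub)
        if (par in placed and len(samples) == 1):
            mother = placed[par]
            x, y = mother.x_mm, mother.y_mm  # nested: center of the mother clone
        elif len(samples) >= 2:
            xs = [by_id[s].x_mm for s in samples]
            ys = [by_id[s].y_mm for s in samples]
            x, y = float(np.mean(xs)), float(np.mean(ys))
        else:
            k = sum(1 for t in placed.values()
                    if t.samples == (samples[0],) and t.nested_in is None)
            x, y = _remaining_space(by_id[samples[0]], list(placed.values()), k)
        biopsy_cap = sum(by_id[s].area_mm2 for s in samples)
        if areas[sub] > biopsy_cap * (1 + 0.1):
            # fraction rounding can nominally exceed the biopsy; warn via flag
            areas[sub] = biopsy_cap
        placed[sub] = Territory(subclone=sub, x_mm=x, y_mm=y, area_mm2=areas[sub],
                                samples=tuple(samples),
                                nested_in=par if par in placed else None)
    return [placed[s] for s in ordered if s in placed]


_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def _remaining_space(biopsy: BiopsyLocation, placed: Sequence[Territory],
                     k: int) -> tuple[float, float]:
    """Deterministic packing into the remaining space of a biopsy.

    The first private territory of a biopsy sits at half the biopsy radius,
    pointing away from the centroid mass of already-placed territories;
    subsequent privates fan out by golden-angle steps. All directions are
    defined relative to the placed geometry, so the summary statistics are
    invariant under rigid transformations of the layout.
    """
    if not placed and k == 0:
        return biopsy.x_mm, biopsy.y_mm
    r = biopsy.radius / 2.0
    if placed:
        mx = sum(t.x_mm for t in placed) / len(placed)
        my = sum(t.y_mm for t in placed) / len(placed)
        vx, vy = biopsy.x_mm - mx, biopsy.y_mm - my
    else:
        vx = vy = 0.0
    if math.hypot(vx, vy) < 1e-9:
        vx, vy = 1.0, 0.0  # degenerate geometry: fixed convention
    base = math.atan2(vy, vx) + k * _GOLDEN_ANGLE
    return (biopsy.x_mm + r * math.cos(base), biopsy.y_mm + r * math.sin(base))


def territory_stats(territories: Sequence[Territory],
                    total_viable_area_mm2: float) -> TerritoryStats:
    """Subclone density (count per mm² of viable tumor) and dispersion
    (median pairwise centroid distance; absent for a single territory)."""
    if not territories:
        raise ValidationError("no territories supplied")
    if total_viable_area_mm2 <= 0:
        raise ValidationError("total viable area must be positive")
    n = len(territories)
    density = n / total_viable_area_mm2
    if n < 2:
        return TerritoryStats(n, density, None)
    dists = [math.hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm)
             for i, a in enumerate(territories) for b in territories[i + 1:]]
    return TerritoryStats(n, density, float(np.median(dists)))
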