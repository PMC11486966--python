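"""End-to-end subclone reconstruction: quantify -> integrate -> deconvolve ->
tree -> metrics -> classification.

The pipeline consumes a multi-sample segment table (and optionally a variant
table) from one patient/tumor, estimates per-sample purity from clonal
aberrations, converts every event to mutated clone fractions, clusters the
fraction patterns into subclones under the chromosomal-evolution
constraints, builds the maximum-parsimony phylogeny and reports diversity
statistics plus — when at least two timepoints are sampled — the collateral
clonal replacement vs linear evolution call. Every filtering decision is
logged with its rule tag, and the run is deterministic given config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import deconvolution, phylogeny
from .cna_quantification import (SamplePurity, SegmentCall, combined_msf,
                                 estimate_tcf, mcf_from_msf, quantify_segment)
from .errors import NoSignalError, NotClassifiableError, PurityError, ValidationError
from .io import read_segments, read_variants
from .variant_integration import (CopyNumberContext, FilterPolicy, VariantCall,
                                  _clamp_mcf, default_multiplicity,
                                  filter_variants, mcf_from_vaf)

DETECTION_LIMIT = 0.1  # clone fraction below which a population is undetected


@dataclass
class PipelineConfig:
    segments: Union[str, pd.DataFrame, Sequence[SegmentCall]]
    variants: Union[str, pd.DataFrame, Sequence[VariantCall], None] = None
    sample_timepoints: Mapping[str, str] = field(default_factory=dict)
    mode: str = "clinical"  # 'clinical' | 'pdx'
    ploidy: int = 2
    tol: float = deconvolution.DEFAULT_GROUP_TOL
    detection_limit: float = DETECTION_LIMIT
    log2_input: bool = False
    correction: float = 0.55
    filter_policy: Optional[FilterPolicy] = None
    seed: int = 0


def _load_segments(config: PipelineConfig) -> list[SegmentCall]:
    src = config.segments
    if isinstance(src, str):
        return read_segments(src, config.log2_input, config.correction)
    if isinstance(src, pd.DataFrame):
        from .io import segments_from_frame
        return segments_from_frame(src, config.log2_input, config.correction)
    return list(src)


def _load_variants(config: PipelineConfig) -> list[VariantCall]:
    src = config.variants
    if src is None:
        return []
    if isinstance(src, str):
        return read_variants(src)
    if isinstance(src, pd.DataFrame):
        if src.empty:
            return []
        from .io import variants_from_frame
        return variants_from_frame(src)
    return list(src)


def segment_event_id(seg: SegmentCall) -> str:
    return f"{seg.chrom}:{seg.start}-{seg.end}({seg.n_a}+{seg.n_b})"


def variant_event_id(var: VariantCall) -> str:
    return f"{var.chrom}:{var.pos}:{var.ref}>{var.alt}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full reconstruction and return the report dictionary."""
    log: list[dict] = []
    segments = _load_segments(config)
    if not segments:
        raise ValidationError("no segments supplied")
    samples = sorted({s.sample_id for s in segments})

    # ---- quantify ----------------------------------------------------
    for seg in segments:
        try:
            quantify_segment(seg, config.ploidy)
        except NoSignalError:
            log.append({"stage": "quantify", "rule": "no_signal",
                        "item": segment_event_id(seg), "sample": seg.sample_id})

    purity: dict[str, SamplePurity] = {}
    if config.mode == "pdx":
        for s in samples:
            purity[s] = SamplePurity(sample_id=s, tcf_ratio=1.0, tcf_ai=1.0)
    else:
        for s in samples:
            own = [seg for seg in segments if seg.sample_id == s]
            try:
                purity[s] = estimate_tcf(own)
            except PurityError as exc:
                raise PurityError(f"sample {s}: {exc}") from exc
            if not purity[s].consistent:
                log.append({"stage": "purity", "rule": "tcf_inconsistent",
                            "item": s, "sample": s})

    # ---- event MCF matrix -------------------------------------------
    mcf_rows: dict[str, dict[str, float]] = {}
    event_meta: dict[str, dict] = {}
    for seg in segments:
        eid = segment_event_id(seg)
        # inverse-variance combination of the dosage and imbalance readouts
        # (imbalance-only events such as copy-neutral ones use mBAF alone)
        msf = combined_msf(seg, config.ploidy)
        if msf is None:
            continue
        mcf = mcf_from_msf(msf, purity[seg.sample_id].tcf)
        if mcf.review_multiplicity:
            log.append({"stage": "quantify", "rule": "mcf_above_1.2_clamped",
                        "item": eid, "sample": seg.sample_id})
        mcf_rows.setdefault(eid, {})[seg.sample_id] = mcf.value
        event_meta[eid] = {"kind": "cna", "chrom": seg.chrom, "start": seg.start,
                           "end": seg.end, "n_a": seg.n_a, "n_b": seg.n_b}

    # mixed aberrations: same coordinates, different compositions -> never nested
    no_nest: set[frozenset] = set()
    by_locus: dict[tuple, set[str]] = {}
    for eid, meta in event_meta.items():
        by_locus.setdefault((meta["chrom"], meta["start"], meta["end"]), set()).add(eid)
    for ids in by_locus.values():
        if len(ids) > 1:
            ids = sorted(ids)
            for i, x in enumerate(ids):
                for y in ids[i + 1:]:
                    no_nest.add(frozenset((x, y)))

    variants = _load_variants(config)
    if variants and config.mode == "clinical":
        result = filter_variants(variants, config.filter_policy)
        for var, reason in result.rejected:
            log.append({"stage": "filter", "rule": reason,
                        "item": variant_event_id(var), "sample": var.sample_id})
        by_key: dict[tuple, list[VariantCall]] = {}
        for var in result.kept:
            by_key.setdefault(var.key, []).append(var)
        for key, records in by_key.items():
            # multiplicity starts at the ploidy default; it is raised to 2
            # when the resulting clone fraction exceeds 1.2 in the majority
            # of the samples carrying the variant
            def trial(m: float) -> dict[str, float]:
                out = {}
                for var in records:
                    tcf = purity[var.sample_id].tcf if var.sample_id in purity else 1.0
                    ctx = CopyNumberContext(cn1=2.0, f1=tcf, tcf=tcf)
                    out[var.sample_id] = mcf_from_vaf(var.vaf, m, ctx).raw
                return out

            m = float(default_multiplicity(config.ploidy))
            raws = trial(m)
            over = sum(1 for v in raws.values() if v > 1.2)
            if over * 2 > len(raws) and m < 2:
                m = 2.0
                raws = trial(m)
                eid0 = variant_event_id(records[0])
                log.append({"stage": "integrate", "rule": "multiplicity_raised_to_2",
                            "item": eid0, "sample": None})
            for var in records:
                eid = variant_event_id(var)
                mcf = _clamp_mcf(raws[var.sample_id])
                if mcf.review_multiplicity:
                    log.append({"stage": "integrate", "rule": "mcf_above_1.2_clamped",
                                "item": eid, "sample": var.sample_id})
                mcf_rows.setdefault(eid, {})[var.sample_id] = mcf.value
                event_meta.setdefault(eid, {"kind": "snv", "chrom": var.chrom,
                                            "pos": var.pos})

    values = pd.DataFrame.from_dict(mcf_rows, orient="index").reindex(columns=samples)
    values = values.fillna(0.0)
    matrix = deconvolution.MCFMatrix(values=values, no_nest_pairs=no_nest,
                                     event_meta=event_meta)

    # ---- deconvolve ---------------------------------------------------
    # noisy fraction estimates can fragment clones and make the strict
    # pigeonhole/containment system infeasible; escalate deterministically —
    # wider containment/sum tolerances, soft must-nest, then a coarser
    # grouping tolerance that re-merges the fragments
    groups = None
    configuration = None
    relax_ladder = [
        (0.0, deconvolution.NEST_TOL, deconvolution.SUM_TOL, True),
        (0.0, 0.2, 0.15, True),
        (0.0, 0.2, 0.2, False),
        (0.05, 0.2, 0.2, False),
        (0.10, 0.25, 0.2, False),
        (0.15, 0.3, 0.25, False),
        (0.25, 0.35, 0.3, False),
        (0.35, 0.4, 0.3, False),
        (0.35, 0.4, 0.4, False),
        (0.5, 0.5, 0.5, False),
    ]
    for step, (tol_add, nest_tol, sum_tol, strict) in enumerate(relax_ladder):
        try:
            groups = deconvolution.group_events(matrix, tol=config.tol + tol_add)
            configuration = deconvolution.resolve_configuration(
                groups, no_nest_pairs=no_nest, samples=samples,
                nest_tol=nest_tol, sum_tol=sum_tol, strict=strict)
            if step > 0:
                log.append({"stage": "deconvolve", "rule": "constraints_relaxed",
                            "item": f"tol={config.tol + tol_add},nest_tol={nest_tol},"
                                    f"sum_tol={sum_tol},strict={strict}",
                            "sample": None})
            break
        except deconvolution.ConstraintConflictError:
            if step == len(relax_ladder) - 1:
                raise
    # fold nested groups whose profiles the data cannot distinguish
    configuration = deconvolution.collapse_chains(configuration, values, tol=config.tol)
    ev_matrix, fractions = deconvolution.event_matrix(configuration)

    # ---- tree ---------------------------------------------------------
    tree = phylogeny.build_tree(ev_matrix)
    raw_extant = configuration.extant_fractions(raw=True)
    for node in tree.taxa():
        gid = node.name
        if gid in fractions.index:
            node.fractions = fractions.loc[gid].to_dict()
            node.extant = raw_extant.loc[gid].to_dict()

    # ---- metrics ------------------------------------------------------
    timepoints = dict(config.sample_timepoints)
    tps = sorted(set(timepoints.values()))

    def detect(limit: float) -> dict[str, set[str]]:
        # a population is detected at a timepoint when its mean extant
        # fraction over that timepoint's samples reaches the limit
        out: dict[str, set[str]] = {}
        for node in tree.taxa():
            detected_samples: set[str] = set()
            if timepoints:
                for tp in tps:
                    tp_samples = [s for s in samples if timepoints.get(s) == tp]
                    if tp_samples:
                        mean = float(np.mean([node.extant.get(s, 0.0)
                                              for s in tp_samples]))
                        if mean >= limit:
                            detected_samples |= set(tp_samples)
            else:
                detected_samples = {s for s in samples
                                    if node.extant.get(s, 0.0) >= limit}
            out[node.name] = detected_samples
        return out

    detection = detect(config.detection_limit)
    # ancestral witnesses for the linear-vs-CCR call must be ascertained
    # well above the detection limit (twice the limit)
    witness_detection = detect(2.0 * config.detection_limit)

    igd_by_tp: dict[str, Optional[float]] = {}
    for tp in tps:
        tp_samples = {s for s in samples if timepoints.get(s) == tp}
        taxa = [t for t, ss in detection.items() if ss & tp_samples]
        try:
            igd_by_tp[tp] = phylogeny.igd(tree, taxa) if taxa else None
        except ValidationError:
            igd_by_tp[tp] = None
    try:
        irr = phylogeny.irregularity(tree)
    except ValidationError:
        irr = None

    classification = None
    if len({tp for t, ss in detection.items() for tp in
            {timepoints[s] for s in ss}}) >= 2:
        extant_map = {t: tree.find_taxon(t).extant for t in detection}
        try:
            call = phylogeny.classify_replacement(
                tree, timepoints, detection, fractions=extant_map,
                witness_detection=witness_detection)
            classification = {
                "pattern": call.classification,
                "earlier_timepoint": call.earlier_timepoint,
                "later_timepoint": call.later_timepoint,
                "dominant_later": call.dominant_later,
                "supported": call.supported,
            }
        except NotClassifiableError:
            classification = None

    report = {
        "seed": config.seed,
        "mode": config.mode,
        "samples": samples,
        "purity": {s: {"tcf": round(p.tcf, 4), "tcf_ratio": round(p.tcf_ratio, 4),
                       "tcf_ai": round(p.tcf_ai, 4), "consistent": p.consistent}
                   for s, p in purity.items()},
        "n_events": int(len(values.index)),
        "subclones": [
            {"id": g.group_id, "events": list(g.events),
             "profile": {s: g.profile.get(s, 0.0) for s in samples},
             "parent": configuration.parents[g.group_id]}
            for g in configuration.groups],
        "event_matrix": ev_matrix.to_dict(orient="index"),
        "newick": tree.newick(),
        "stats": {"igd": igd_by_tp, "irregularity": irr,
                  "total_branch_length": phylogeny.total_branch_length(tree)},
        "classification": classification,
        "filter_log": log,
    }
    return report
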