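"""Tabular input/output for the pipeline's TSV/CSV dialects."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .cna_quantification import SegmentCall, apply_platform_correction
from .errors import ValidationError
from .variant_integration import VariantCall

SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "ratio", "n_a", "n_b")
VARIANT_COLUMNS = ("sample", "chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf")

PathLike = Union[str, Path]


def read_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _require(frame: pd.DataFrame, columns, what: str, path=None):
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        where = f" in {path}" if path else ""
        raise ValidationError(f"{what} table{where} lacks columns {missing}")


def segments_from_frame(frame: pd.DataFrame,
                        log2_input: bool = False,
                        correction: float = 0.55,
                        path: Optional[PathLike] = None) -> list[SegmentCall]:
    """Parse a segment table; validation errors name the offending line."""
    _require(frame, SEGMENT_COLUMNS, "segment", path)
    segments = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            ratio = float(row.ratio)
            if log2_input:
                ratio = apply_platform_correction(ratio, correction)
            mbaf = getattr(row, "mbaf", None)
            mbaf = None if mbaf is None or pd.isna(mbaf) else float(mbaf)
            segments.append(SegmentCall(
                sample_id=str(row.sample), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), ratio=ratio,
                n_a=int(row.n_a), n_b=int(row.n_b), mbaf=mbaf,
                clonal_hint=bool(getattr(row, "clonal_hint", False)),
            ))
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"segment table line {i + 2}: {exc}") from exc
    return segments


def variants_from_frame(frame: pd.DataFrame,
                        path: Optional[PathLike] = None) -> list[VariantCall]:
    _require(frame, VARIANT_COLUMNS, "variant", path)
    variants = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            variants.append(VariantCall(
                sample_id=str(row.sample), chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt), depth=int(row.depth),
                alt_reads=int(row.alt_reads), vaf=float(row.vaf),
                normal_fraction=float(getattr(row, "normal_fraction", 0.0)),
                source=str(getattr(row, "source", "wes_frozen")),
            ))
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"variant table line {i + 2}: {exc}") from exc
    return variants


def read_segments(path: PathLike, log2_input: bool = False,
                  correction: float = 0.55) -> list[SegmentCall]:
    return segments_from_frame(read_table(path), log2_input, correction, path)


def read_variants(path: PathLike) -> list[VariantCall]:
    return variants_from_frame(read_table(path), path)


def write_table(frame: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame.to_csv(path, sep=sep, index=index)
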