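"""Ratio preprocessing: log2, winsorization, identifier resolution,
standardization and direction qualification.

The pipeline order is fixed: identifier mapping → log2 transform →
winsorization → multi-identifier resolution (fan-out, then median collapse)
→ direction qualification on the pre-standardization log2 ratios →
standardization by the sample standard deviation.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import RawRatioRecord

log = logging.getLogger(__name__)

__all__ = [
    "ProcessingConfig",
    "ExpressionProfile",
    "log2_transform",
    "winsorize",
    "apply_id_mapping",
    "resolve_identifiers",
    "standardize",
    "qualify_directions",
    "build_profile",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """All tunable thresholds of the pipeline.

    winsor_threshold: cap on |log2 ratio| (default 10, i.e. ~1024-fold).
    fold_threshold: minimum fold change for a protein's direction to be
        trusted (default 1.5); below it the ratio is zeroed in the test
        vector.
    diag_constant: diagonal of the knowledge-based covariance (default 0.4,
        the STRING medium-confidence level).
    alpha: significance level for pathway retention (default 0.05).
    min_score: confidence floor for PPI edges (default 0.4).
    """

    winsor_threshold: float = 10.0
    fold_threshold: float = 1.5
    already_logged: bool = False
    diag_constant: float = 0.4
    alpha: float = 0.05
    min_score: float = 0.4

    def __post_init__(self) -> None:
        if self.winsor_threshold <= 0:
            raise ValueError("winsor_threshold must be positive")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not (0 < self.diag_constant <= 1):
            raise ValueError("diag_constant must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ExpressionProfile:
    """Processed per-protein expression state.

    values: standardized log2 ratios (sample SD 1 over all proteins).
    qualified: whether the protein's fold change clears the qualification
        threshold; unqualified proteins enter the test vector as zero.
    raw_log2: pre-standardization (but winsorized) log2 ratios.
    """

    values: dict[str, float]
    qualified: dict[str, bool]
    raw_log2: dict[str, float]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.values.keys() == self.qualified.keys() == self.raw_log2.keys()):
            raise ValueError("profile maps must share an identical key set")

    def accessions(self) -> list[str]:
        return sorted(self.values)


def log2_transform(
    records: Sequence[RawRatioRecord], already_logged: bool = False
) -> tuple[list[RawRatioRecord], int]:
    """Move fold-scale ratios onto the log2 scale.

    Pre-logged input passes through unchanged.  Non-positive fold ratios
    have no log; those records are dropped and counted.
    """
    if already_logged:
        return list(records), 0
    out: list[RawRatioRecord] = []
    n_dropped = 0
    for rec in records:
        if rec.ratio <= 0:
            n_dropped += 1
            continue
        out.append(RawRatioRecord(rec.identifiers, math.log2(rec.ratio)))
    if n_dropped:
        log.warning("dropped %d record(s) with non-positive fold ratios", n_dropped)
    return out, n_dropped


def winsorize(values: Sequence[float], threshold: float) -> list[float]:
    """Replace out-of-range values by the maximum permitted in-range value.

    The maximum permitted value m is the largest |v| among input values
    with |v| ≤ threshold.  A value above ``threshold`` becomes +m and a
    value below ``-threshold`` becomes −m, so the sign is preserved: with
    input (−7, −1, 3, 4, 6) and threshold 5, the extreme 6 becomes 4 and
    −7 becomes −4.  If every value is out of range the hard bound
    ±threshold is used.  Order is preserved; in-range values pass through.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    in_range = [abs(v) for v in values if -threshold <= v <= threshold]
    if in_range:
        permitted = max(in_range)
    else:
        permitted = None
    out = []
    for v in values:
        if -threshold <= v <= threshold:
            out.append(v)
        elif permitted is None:
            log.warning("no in-range value to substitute for %g; clamping", v)
            out.append(threshold if v > 0 else -threshold)
        else:
            out.append(permitted if v > 0 else -permitted)
    return out


def apply_id_mapping(
    records: Sequence[RawRatioRecord], mapping: Mapping[str, frozenset[str]] | None
) -> list[RawRatioRecord]:
    """Translate record identifiers through a source→canonical multimap.

    An identifier with several targets fans out to all of them; identifiers
    absent from the map are kept unchanged.
    """
    if not mapping:
        return list(records)
    out = []
    for rec in records:
        idents: set[str] = set()
        for ident in rec.identifiers:
            idents.update(mapping.get(ident, frozenset((ident,))))
        out.append(RawRatioRecord(tuple(sorted(idents)), rec.ratio))
    return out


def resolve_identifiers(records: Sequence[RawRatioRecord]) -> dict[str, float]:
    """Collapse records to one log2 ratio per accession.

    A record with several identifiers assigns its ratio to each of them
    (fan-out first); an accession then seen with several ratios receives
    their median (midpoint of the central pair for even counts).
    """
    per_accession: dict[str, list[float]] = {}
    for rec in records:
        for ident in rec.identifiers:
            per_accession.setdefault(ident, []).append(rec.ratio)
    return {acc: statistics.median(rs) for acc, rs in per_accession.items()}


def standardize(values: Mapping[str, float]) -> dict[str, float]:
    """Divide every value by the sample standard deviation (n−1 denominator)."""
    if len(values) < 2:
        raise ValueError("standardization needs at least two accessions")
    sd = statistics.stdev(values.values())
    if sd == 0:
        raise ValueError("standard deviation is zero; all ratios identical")
    return {acc: v / sd for acc, v in values.items()}


def qualify_directions(
    raw_log2: Mapping[str, float], fold_threshold: float
) -> dict[str, bool]:
    """Mark the proteins whose fold change clears the qualification threshold.

    Qualified ⇔ |log2 ratio| ≥ log2(fold_threshold).  Unqualified proteins
    keep their pathway membership but contribute zero to the test vector.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    cut = math.log2(fold_threshold)
    return {acc: abs(v) >= cut for acc, v in raw_log2.items()}


def build_profile(
    records: Sequence[RawRatioRecord],
    mapping: Mapping[str, frozenset[str]] | None = None,
    config: ProcessingConfig | None = None,
) -> ExpressionProfile:
    """Run the full preprocessing pipeline on raw ratio records."""
    config = config or ProcessingConfig()
    records = apply_id_mapping(records, mapping)
    records, n_dropped = log2_transform(records, config.already_logged)
    if not records:
        raise ValueError("no records left after log2 transform")
    capped = winsorize([r.ratio for r in records], config.winsor_threshold)
    records = [RawRatioRecord(r.identifiers, v) for r, v in zip(records, capped)]
    raw_log2 = resolve_identifiers(records)
    qualified = qualify_directions(raw_log2, config.fold_threshold)
    values = standardize(raw_log2)
    return ExpressionProfile(values, qualified, raw_log2, n_dropped)
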