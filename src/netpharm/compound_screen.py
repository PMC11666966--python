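"""ADME screening of phytochemical panels.

Herbal-compound screening in network pharmacology conventionally keeps
compounds with oral bioavailability (OB) of at least 30% and drug-likeness
(DL) of at least 0.18.  This module applies that screen to a deduplicated
compound panel and keeps an auditable record of everything it drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "CompoundRecord",
    "ScreenConfig",
    "DroppedCompound",
    "dedup_compounds",
    "filter_adme",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One phytochemical with its screening parameters.

    ``ob`` is oral bioavailability in percent; ``dl`` is unitless
    drug-likeness in [0, 1].  ``target_count`` carries the number of
    disease-relevant predicted targets when known.
    """

    pubchem_id: Optional[str]
    name: str
    ob: float
    dl: float
    smiles: Optional[str] = None
    target_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValueError(f"OB must be nonnegative, got {self.ob} for {self.name!r}")
        if not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"DL must lie in [0, 1], got {self.dl} for {self.name!r}")
        if self.target_count is not None and self.target_count < 0:
            raise ValueError(f"target_count must be nonnegative for {self.name!r}")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the OB/DL screen (inclusive)."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValueError("screen thresholds must be nonnegative")


@dataclass(frozen=True)
class DroppedCompound:
    """A screened-out compound together with the criteria it failed."""

    record: CompoundRecord
    reasons: tuple[str, ...] = field(default_factory=tuple)


def dedup_compounds(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse duplicate compounds, preserving first occurrence and order.

    Records sharing a ``pubchem_id`` are duplicates; records without an id
    fall back to a case-insensitive name key.
    """
    seen: set[tuple[str, str]] = set()
    out: list[CompoundRecord] = []
    for rec in records:
        key = ("id", rec.pubchem_id) if rec.pubchem_id else ("name", rec.name.strip().lower())
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def filter_adme(
    records: Sequence[CompoundRecord],
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[CompoundRecord], list[DroppedCompound]]:
    """Partition ``records`` into (kept, dropped) under the OB/DL screen.

    Both thresholds are inclusive: a compound sitting exactly on a
    threshold is kept.  Dropped records carry the failed criteria
    ("OB", "DL", or both) so the screen is auditable.
    """
    kept: list[CompoundRecord] = []
    dropped: list[DroppedCompound] = []
    for rec in records:
        reasons = []
        if rec.ob < config.ob_min:
            reasons.append("OB")
        if rec.dl < config.dl_min:
            reasons.append("DL")
        if reasons:
            dropped.append(DroppedCompound(rec, tuple(reasons)))
        else:
            kept.append(rec)
    return kept, dropped
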