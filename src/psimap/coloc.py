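"""Positional colocalization of significant variants with PSI regions.

A variant at 1-based position p maps to region [s, e) iff s <= p-1 < e; the
regions are disjoint, so at most one can match. Mapped variants inherit the
region's full PSI type set. Colocalization here is positional overlap only —
no posterior-probability signal colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gwas import GWASRecord, TraitCategory, TraitSpec
from .regions import PSI_TYPE_NAMES, PSIRegion


@dataclass(frozen=True)
class MappedVariant:
    record: GWASRecord
    region_id: str
    type_set: frozenset[int]

    @property
    def identity(self) -> str:
        return self.record.identity


class RegionIndex:
    """Sorted per-chromosome start/end arrays for binary-search lookup."""

    def __init__(self, regions: list[PSIRegion]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[PSIRegion]]] = {}
        by_chrom: dict[str, list[PSIRegion]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"regions {a.region_id} and {b.region_id} overlap on {chrom}"
                    )
            starts = np.array([r.start for r in rs], dtype=np.int64)
            ends = np.array([r.end for r in rs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, rs)

    def lookup(self, chrom: str, pos: int) -> PSIRegion | None:
        """Region containing 1-based position ``pos``, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, rs = entry
        offset = pos - 1  # to 0-based
        i = int(np.searchsorted(starts, offset, side="right")) - 1
        if i >= 0 and offset < ends[i]:
            return rs[i]
        return None


def map_variants(records: list[GWASRecord], regions: list[PSIRegion]) -> list[MappedVariant]:
    """Map each significant variant into the disjoint region set.

    Unmapped variants are simply absent from the output; input order is kept.
    """
    index = RegionIndex(regions)
    out: list[MappedVariant] = []
    for rec in records:
        region = index.lookup(rec.chrom, rec.pos)
        if region is not None:
            out.append(MappedVariant(rec, region.region_id, region.type_set))
    return out


def count_pleiotropic(mapped: list[MappedVariant]) -> tuple[int, int]:
    """(distinct mapped variants, those significant-and-mapped in >= 2 traits)."""
    traits_by_variant: dict[str, set[str]] = {}
    for mv in mapped:
        traits_by_variant.setdefault(mv.identity, set()).add(mv.record.trait_id)
    n_distinct = len(traits_by_variant)
    n_pleio = sum(1 for ts in traits_by_variant.values() if len(ts) >= 2)
    return n_distinct, n_pleio


def type_level_counts(mapped: list[MappedVariant], traits: list[TraitSpec],
                      multi_type: str = "all") -> pd.DataFrame:
    """Mapping-event counts per PSI type and trait category.

    Each mapped variant-trait record is one event. A variant in a multi-type
    region increments every constituent type when ``multi_type="all"``
    (default); ``multi_type="exclude"`` drops multi-type regions instead.
    """
    if multi_type not in ("all", "exclude"):
        raise ValidationError(f"multi_type must be 'all' or 'exclude', got {multi_type!r}")
    category = {t.trait_id: TraitCategory(t.category).value for t in traits}
    table = pd.DataFrame(0, index=sorted(PSI_TYPE_NAMES), columns=["disease", "quantitative"])
    for mv in mapped:
        try:
            cat = category[mv.record.trait_id]
        except KeyError:
            raise ValidationError(
                f"mapped variant trait {mv.record.trait_id!r} missing from trait specs"
            ) from None
        if multi_type == "exclude" and len(mv.type_set) > 1:
            continue
        for t in mv.type_set:
            table.loc[t, cat] += 1
    table.index.name = "type_code"
    return table
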