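"""LD-block locus clumping and locus-level mapping rates.

Loci are the reported, mutually independent lead variants of each trait,
together with every significant variant in linkage disequilibrium r^2 > 0.8
(strict) with them. However many member variants of a block map to PSI
regions, the block counts as one mapped locus; the locus-level mapping rate
is 100 * mapped loci / input loci. Loci are trait-specific: the same genomic
lead reported by two traits is two loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .gwas import GWASRecord
from .coloc import MappedVariant

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.8


@dataclass(frozen=True)
class LDPair:
    variant_id: str
    lead_id: str
    r2: float

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"r2 must be in [0, 1], got {self.r2}")


@dataclass
class LocusAssignment:
    """One (trait, lead) block. The lead is always a member of its own block
    (r^2 = 1 by convention); ``mapped`` is set by :func:`locus_mapping_rate`."""

    lead_id: str
    trait_id: str
    member_ids: frozenset[str]
    mapped: bool = False
    n_mapped_members: int = field(default=0)


@dataclass(frozen=True)
class LocusRates:
    n_input_loci: int
    n_mapped_loci: int
    rate_pct: float


def read_ld_table(path) -> list[LDPair]:
    """Read an LD TSV (variant_id, lead_id, r2)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "lead_id", "r2"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return [LDPair(str(v), str(l), float(r))
            for v, l, r in zip(df["variant_id"], df["lead_id"], df["r2"])]


def assign_blocks(records: list[GWASRecord], ld: list[LDPair],
                  leads: list[str] | None = None,
                  singleton_mode: bool = False,
                  ) -> tuple[list[LocusAssignment], list[GWASRecord]]:
    """Cluster each trait's significant variants into lead-defined LD blocks.

    A variant joins lead L's block iff r^2(variant, L) > 0.8 (strict); with
    several qualifying leads it joins the highest-r^2 one, ties broken by the
    lead at the smaller genomic position. Variants with no lead above the
    threshold are returned separately as unassigned and excluded from locus
    counts, unless ``singleton_mode`` turns each into its own single-variant
    locus. ``leads`` overrides the per-trait lead sets otherwise taken from
    the records' lead_id column.
    """
    ld_by_variant: dict[str, list[LDPair]] = {}
    ld_leads: set[str] = set()
    for pair in ld:
        ld_by_variant.setdefault(pair.variant_id, []).append(pair)
        ld_leads.add(pair.lead_id)

    pos_by_identity: dict[str, tuple[str, int]] = {}
    for rec in records:
        pos_by_identity.setdefault(rec.identity, (rec.chrom, rec.pos))

    by_trait: dict[str, list[GWASRecord]] = {}
    for rec in records:
        by_trait.setdefault(rec.trait_id, []).append(rec)

    assignments: list[LocusAssignment] = []
    unassigned: list[GWASRecord] = []

    for trait_id in by_trait:
        trait_records = by_trait[trait_id]
        identities = {r.identity for r in trait_records}
        if leads is not None:
            trait_leads = set(leads)
        else:
            trait_leads = {r.lead_id for r in trait_records if r.lead_id}
        if not trait_leads and not singleton_mode:
            logger.warning("trait %s: no leads; all %d variants unassigned",
                           trait_id, len(trait_records))
        members: dict[str, set[str]] = {}
        for lead in sorted(trait_leads):
            if lead not in identities:
                logger.warning("trait %s: lead %s absent from significant records",
                               trait_id, lead)
                if lead not in ld_leads:
                    continue  # no way to populate this block
            members[lead] = {lead}
        for rec in trait_records:
            ident = rec.identity
            if ident in members:
                continue  # a lead, already its own block
            candidates = [p for p in ld_by_variant.get(ident, ())
                          if p.lead_id in members and p.r2 > R2_THRESHOLD]
            if candidates:
                best = max(candidates,
                           key=lambda p: (p.r2, -_lead_pos(p.lead_id, pos_by_identity),
                                          p.lead_id))
                members[best.lead_id].add(ident)
            elif singleton_mode:
                members[ident] = {ident}
            else:
                unassigned.append(rec)
        for lead in sorted(members):
            assignments.append(LocusAssignment(
                lead_id=lead, trait_id=trait_id, member_ids=frozenset(members[lead])))
    return assignments, unassigned


def _lead_pos(lead_id: str, pos_by_identity: dict[str, tuple[str, int]]) -> float:
    """Genomic position for tie-breaking; unknown leads sort last."""
    entry = pos_by_identity.get(lead_id)
    return float(entry[1]) if entry else float("inf")


def locus_mapping_rate(assignments: list[LocusAssignment],
                       mapped: list[MappedVariant]) -> LocusRates:
    """Mark each block mapped iff >= 1 member variant mapped, and compute the
    locus-level mapping rate (percentage, one decimal)."""
    from .report import pct  # shared half-away-from-zero rounding

    if not assignments:
        raise ValidationError("no input loci: cannot compute a mapping rate")
    mapped_keys = {(mv.record.trait_id, mv.identity) for mv in mapped}
    n_mapped = 0
    for a in assignments:
        hits = sum(1 for m in a.member_ids if (a.trait_id, m) in mapped_keys)
        a.n_mapped_members = hits
        a.mapped = hits > 0
        n_mapped += int(a.mapped)
    return LocusRates(
        n_input_loci=len(assignments),
        n_mapped_loci=n_mapped,
        rate_pct=pct(n_mapped, len(assignments)),
    )


def write_locus_report(assignments: list[LocusAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("trait_id\tlead_id\tn_members\tn_mapped_members\tmapped\n")
        for a in sorted(assignments, key=lambda a: (a.trait_id, a.lead_id)):
            fh.write(f"{a.trait_id}\t{a.lead_id}\t{len(a.member_ids)}\t"
                     f"{a.n_mapped_members}\t{int(a.mapped)}\n")
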