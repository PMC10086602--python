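"""Primate-specific (PSI) elements and their merged non-overlapping regions.

Nine classes of primate-/human-specific genomic elements (HARs, human-gained
enhancers, human-biased and primate-specific cis-regulatory elements,
recurrent de-novo-mutation elements, human-specific insertions,
primate-specific transcriptional units, accelerated DHSs and hominin-specific
gene regulatory elements) are read from BED-like files, validated against a
genome table, and merged into the maximal non-overlapping intervals — "PSI
regions" — that all downstream variant mapping uses.

Coordinates are 0-based half-open throughout (BED convention). Two elements
merge iff they share at least one base; abutting intervals (end == start) stay
separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParseError, ValidationError
from .genome import GenomeTable, chrom_sort_key

#: Field names of the nine PSI element classes, keyed by integer type code.
PSI_TYPE_NAMES = {
    1: "HAR",
    2: "HGE",
    3: "hbCRE",
    4: "psCRE",
    5: "DNM",
    6: "hsInsert",
    7: "psTU",
    8: "haDHS",
    9: "hsGRE",
}

#: Types without obvious regulatory evidence: human-specific insertions and
#: primate-specific transcriptional units.
NON_REGULATORY_TYPES = frozenset({6, 7})

#: Display floor for vanishingly small p-values, mirroring R's print convention.
P_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class PSIElement:
    """One source interval from a PSI element catalogue (0-based half-open)."""

    element_id: str
    type_code: int
    chrom: str
    start: int
    end: int
    source_label: str = ""

    def __post_init__(self):
        if self.type_code not in PSI_TYPE_NAMES:
            raise ValidationError(f"type_code {self.type_code} not in 1..9")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"element {self.element_id}: invalid interval "
                f"[{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def type_name(self) -> str:
        return PSI_TYPE_NAMES[self.type_code]


@dataclass(frozen=True)
class PSIRegion:
    """Maximal merged interval of overlapping PSI elements (0-based half-open).

    ``type_set`` holds the type codes of every constituent element;
    ``regulatory`` is true when no constituent type is one of the
    non-regulatory classes (hsInsert, psTU).
    """

    region_id: str
    chrom: str
    start: int
    end: int
    element_ids: frozenset[str]
    type_set: frozenset[int]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def multi_element(self) -> bool:
        return len(self.element_ids) > 1

    @property
    def regulatory(self) -> bool:
        return not (self.type_set & NON_REGULATORY_TYPES)


@dataclass(frozen=True)
class RegionSummary:
    n_regions: int
    n_multi_element: int
    total_bp: int
    mean_bp: float            # one-decimal mean length
    mean_bp_truncated: int    # mean truncated toward zero
    genome_coverage: float    # fraction of the genome covered
    per_chrom: tuple[tuple[str, int, int, float], ...]  # (chrom, n, covered_bp, fraction)


def read_psi_bed(path, type_code: int, genome: GenomeTable,
                 source_label: str | None = None) -> list[PSIElement]:
    """Read one BED3+ file of elements of a single PSI type.

    Every row must lie on a chromosome of ``genome`` and inside its bounds.
    Element ids are assigned sequentially as ``t{type}_{n}``.
    """
    label = source_label if source_label is not None else PSI_TYPE_NAMES.get(type_code, "")
    elements: list[PSIElement] = []
    n = 0
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 tab-separated columns", str(path), i)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", str(path), i
                ) from None
            if start >= end:
                raise ValidationError(
                    f"{path}, line {i}: start {start} >= end {end}"
                )
            if chrom not in genome:
                raise ValidationError(
                    f"{path}, line {i}: chromosome {chrom!r} absent from genome table"
                )
            if end > genome.length(chrom):
                raise ValidationError(
                    f"{path}, line {i}: end {end} exceeds {chrom} length "
                    f"{genome.length(chrom)}"
                )
            n += 1
            elements.append(PSIElement(f"t{type_code}_{n}", type_code, chrom, start, end, label))
    return elements


def merge_into_regions(elements: list[PSIElement]) -> list[PSIRegion]:
    """Merge elements into non-overlapping PSI regions.

    Regions are the connected components of the overlap graph on each
    chromosome: elements sharing at least one base (half-open semantics) fall
    in one region; abutting elements do not. Output is sorted by
    (chromosome, start) with sequential region ids.
    """
    ordered = sorted(elements, key=lambda e: (chrom_sort_key(e.chrom), e.start, e.end))
    regions: list[PSIRegion] = []
    cur: list[PSIElement] = []

    def flush():
        if not cur:
            return
        regions.append(PSIRegion(
            region_id="",  # assigned below once ordering is final
            chrom=cur[0].chrom,
            start=min(e.start for e in cur),
            end=max(e.end for e in cur),
            element_ids=frozenset(e.element_id for e in cur),
            type_set=frozenset(e.type_code for e in cur),
        ))

    cur_end = -1
    cur_chrom = None
    for e in ordered:
        if cur and e.chrom == cur_chrom and e.start < cur_end:
            cur.append(e)
            cur_end = max(cur_end, e.end)
        else:
            flush()
            cur = [e]
            cur_chrom = e.chrom
            cur_end = e.end
    flush()

    width = max(6, len(str(len(regions))))
    return [
        PSIRegion(f"PSIR{i + 1:0{width}d}", r.chrom, r.start, r.end, r.element_ids, r.type_set)
        for i, r in enumerate(regions)
    ]


def summarize_regions(regions: list[PSIRegion], genome: GenomeTable) -> RegionSummary:
    """Counts, length statistics and genome coverage of a merged region set.

    The mean length is reported both to one decimal and truncated toward zero.
    """
    for r in regions:
        if r.chrom not in genome:
            raise ValidationError(
                f"region {r.region_id} on {r.chrom!r}: chromosome absent from genome table"
            )
    n = len(regions)
    total_bp = sum(r.length for r in regions)
    mean = total_bp / n if n else 0.0
    per_chrom = []
    by_chrom: dict[str, list[PSIRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, length in genome.entries:
        rs = by_chrom.get(chrom, [])
        covered = sum(r.length for r in rs)
        per_chrom.append((chrom, len(rs), covered, covered / length))
    return RegionSummary(
        n_regions=n,
        n_multi_element=sum(1 for r in regions if r.multi_element),
        total_bp=total_bp,
        mean_bp=round(mean, 1),
        mean_bp_truncated=math.trunc(mean),
        genome_coverage=total_bp / genome.total_bp,
        per_chrom=tuple(per_chrom),
    )


def chisq_chromosome_distribution(regions: list[PSIRegion], genome: GenomeTable):
    """Goodness-of-fit test of region counts against chromosome lengths.

    Under uniform placement the expected count on chromosome c is
    ``N * L_c / sum(L)``; the statistic is the usual Pearson sum with
    ``df = #chromosomes - 1``. The raw p-value is retained; callers display it
    floored at 2.2e-16.
    """
    from .stats import ContingencyResult  # local import: stats has no regions dependency

    if len(genome) < 2:
        raise ValidationError("need >= 2 chromosomes for a distribution test")
    n = len(regions)
    if n == 0:
        raise ValidationError("no regions to test")
    counts = {c: 0 for c in genome.chroms}
    for r in regions:
        if r.chrom not in counts:
            raise ValidationError(f"region chromosome {r.chrom!r} absent from genome table")
        counts[r.chrom] += 1
    observed = np.array([counts[c] for c in genome.chroms], dtype=float)
    lengths = np.array([l for _, l in genome.entries], dtype=float)
    expected = n * lengths / lengths.sum()
    if np.any(expected <= 0):
        bad = [c for c, e in zip(genome.chroms, expected) if e <= 0]
        raise ValidationError(
            f"zero expected count on {bad}; exclude these chromosomes before testing"
        )
    stat, p = sps.chisquare(observed, expected)
    return ContingencyResult(
        table=np.vstack([observed, expected]),
        row_labels=("observed", "expected"),
        col_labels=genome.chroms,
        statistic=float(stat),
        df=len(genome) - 1,
        p=float(p),
        correction=False,
        kind="goodness_of_fit",
    )


def write_regions_bed(regions: list[PSIRegion], path) -> None:
    """Write regions as BED6-style TSV with type-set, element-count and
    regulatory-flag extra columns."""
    with open(path, "w") as fh:
        for r in regions:
            types = ",".join(str(t) for t in sorted(r.type_set))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{len(r.element_ids)}\t.\t"
                f"{types}\t{int(r.regulatory)}\n"
            )
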