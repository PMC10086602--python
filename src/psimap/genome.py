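"""Genome assembly table: chromosome names and lengths.

The table is read from a two-column ``chrom.sizes`` file (UCSC convention:
chromosome name, length in bp) and anchors every coordinate check in the
package — element validation, coverage fractions and the length-weighted
expected counts of the chromosomal-distribution test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, ValidationError


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Karyotype-aware sort key: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    base = name[3:] if name.lower().startswith("chr") else name
    if base.isdigit():
        return (0, int(base), "")
    return (1, 0, base)


@dataclass(frozen=True)
class GenomeTable:
    """Ordered collection of (chromosome, length-in-bp) entries.

    Chromosome names must be unique and every length positive.
    """

    entries: tuple[tuple[str, int], ...]
    _lengths: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        names = [c for c, _ in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome names: {dup}")
        for chrom, length in self.entries:
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.entries))

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeTable":
        """Read a UCSC-style chrom.sizes file (TSV: name, length)."""
        entries = []
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError("expected 2 tab-separated columns", str(path), i)
                try:
                    length = int(fields[1])
                except ValueError:
                    raise ParseError(f"non-integer length {fields[1]!r}", str(path), i) from None
                entries.append((fields[0], length))
        return cls(tuple(entries))

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.entries:
                fh.write(f"{chrom}\t{length}\n")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.entries)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in genome table") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self.entries)
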