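"""GWAS summary-statistics input and genome-wide significance filtering.

Each trait contributes one TSV of associated variants scored either by
p-value or by log10 Bayes factor; the genome-wide significance rule is
p < 5e-8 or log10BF > 6, both strict. A trait manifest (YAML or TSV) lists
trait id, category (quantitative/disease), significance mode and file path.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Genome-wide significance thresholds (both comparisons strict).
P_THRESHOLD = 5e-8
LOG10BF_THRESHOLD = 6.0


class TraitCategory(str, enum.Enum):
    quantitative = "quantitative"
    disease = "disease"


class SigMode(str, enum.Enum):
    pvalue = "pvalue"
    log10bf = "log10bf"


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    category: TraitCategory
    sig_mode: SigMode

    def __post_init__(self):
        object.__setattr__(self, "category", TraitCategory(self.category))
        object.__setattr__(self, "sig_mode", SigMode(self.sig_mode))


@dataclass(frozen=True)
class GWASRecord:
    """One associated-variant row: 1-based position, trait and score.

    ``score`` is a p-value in (0, 1] or a log10 Bayes factor depending on the
    trait's significance mode. ``identity`` is the cross-trait variant key:
    the variant id when present, else "chrom:pos".
    """

    variant_id: str | None
    chrom: str
    pos: int
    trait_id: str
    score: float
    lead_id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")

    @property
    def identity(self) -> str:
        return self.variant_id if self.variant_id else f"{self.chrom}:{self.pos}"


def _score_column(sig_mode: SigMode) -> str:
    return "pvalue" if sig_mode == SigMode.pvalue else "log10bf"


def read_gwas_table(path, trait: TraitSpec) -> list[GWASRecord]:
    """Read one trait's summary-statistics TSV into records.

    Required columns: chrom, pos, and the trait's score column (pvalue or
    log10bf). variant_id and lead_id are optional. Duplicate rows for the same
    variant keep the most significant score, with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    score_col = _score_column(trait.sig_mode)
    for col in ("chrom", "pos", score_col):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    scores = pd.to_numeric(df[score_col], errors="coerce")
    bad = scores.isna() & df[score_col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"non-numeric {score_col} value {df[score_col][bad.idxmax()]!r}",
                         str(path), line)
    if scores.isna().any():
        line = int(scores.isna().idxmax()) + 2
        raise ParseError(f"missing {score_col} value", str(path), line)
    if trait.sig_mode == SigMode.pvalue and ((scores <= 0) | (scores > 1)).any():
        i = int(((scores <= 0) | (scores > 1)).idxmax())
        raise ValidationError(f"{path}, line {i + 2}: p-value {scores[i]} outside (0, 1]")

    records: list[GWASRecord] = []
    has_vid = "variant_id" in df.columns
    has_lead = "lead_id" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        pos = int(getattr(row, "pos"))
        vid = getattr(row, "variant_id") if has_vid else None
        if vid is not None and (pd.isna(vid) or vid == ""):
            vid = None
        lead = getattr(row, "lead_id") if has_lead else None
        if lead is not None and (pd.isna(lead) or lead == ""):
            lead = None
        records.append(GWASRecord(
            variant_id=None if vid is None else str(vid),
            chrom=str(getattr(row, "chrom")),
            pos=pos,
            trait_id=trait.trait_id,
            score=float(scores.iloc[i]),
            lead_id=None if lead is None else str(lead),
        ))
    return _dedupe(records, trait, str(path))


def _dedupe(records: list[GWASRecord], trait: TraitSpec, where: str) -> list[GWASRecord]:
    """Keep one row per variant identity: smallest p / largest log10BF wins."""
    best: dict[str, GWASRecord] = {}
    order: list[str] = []
    n_dup = 0
    better = ((lambda new, old: new < old) if trait.sig_mode == SigMode.pvalue
              else (lambda new, old: new > old))
    for rec in records:
        key = rec.identity
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            n_dup += 1
            if better(rec.score, best[key].score):
                best[key] = rec
    if n_dup:
        logger.warning("%s: %d duplicate variant row(s) for trait %s collapsed "
                       "to the most significant score", where, n_dup, trait.trait_id)
    return [best[k] for k in order]


def filter_significant(records: list[GWASRecord], trait: TraitSpec) -> list[GWASRecord]:
    """Apply the genome-wide significance rule (strict inequalities)."""
    for rec in records:
        if rec.trait_id != trait.trait_id:
            raise ValidationError(
                f"record for trait {rec.trait_id!r} passed with spec for {trait.trait_id!r}"
            )
    if trait.sig_mode == SigMode.pvalue:
        return [r for r in records if r.score < P_THRESHOLD]
    return [r for r in records if r.score > LOG10BF_THRESHOLD]


def read_trait_manifest(path) -> list[tuple[TraitSpec, Path]]:
    """Read a trait manifest (YAML list or TSV) into (spec, table-path) pairs.

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    rows: list[dict]
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = data["traits"] if isinstance(data, dict) else data
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
    out = []
    for row in rows:
        for col in ("trait_id", "category", "sig_mode", "path"):
            if col not in row:
                raise ValidationError(f"{path}: manifest entry missing {col!r}: {row}")
        spec = TraitSpec(str(row["trait_id"]), row["category"], row["sig_mode"])
        out.append((spec, base / str(row["path"])))
    ids = [s.trait_id for s, _ in out]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate trait ids in manifest")
    return out
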