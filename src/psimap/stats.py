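"""Contingency tables and chi-square tests for the enrichment contrasts.

Three 2x2 contrasts are built from the mapping results: a focal-PSI-type vs
rest contrast of disease/quantitative mapped-variant counts, a disease vs
quantitative contrast of mapped/unmapped locus counts, and a regulatory vs
non-regulatory contrast of hit/no-hit region counts (multi-type regions
excluded). Tests default to Yates continuity correction on 2x2 tables,
matching R's ``chisq.test`` default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

P_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ContingencyResult:
    """A tested contingency table: counts, Pearson statistic, df and p-value."""

    table: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    statistic: float
    df: int
    p: float
    correction: bool
    kind: str = "independence"

    @property
    def p_display(self) -> str:
        """R-style display: values below 2.2e-16 are floored for printing only."""
        if self.p < P_DISPLAY_FLOOR:
            return "< 2.2e-16"
        return f"{self.p:.4g}"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "table": [[float(x) for x in row] for row in self.table],
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_display": self.p_display,
            "correction": self.correction,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=list(self.row_labels),
                            columns=list(self.col_labels))


def _coerce_table(table) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        return arr, tuple(map(str, table.index)), tuple(map(str, table.columns))
    arr = np.asarray(table, dtype=float)
    rows = tuple(f"row{i}" for i in range(arr.shape[0]))
    cols = tuple(f"col{j}" for j in range(arr.shape[1]))
    return arr, rows, cols


def chisq_independence(table, correction: bool = True) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction`` applies the Yates continuity correction (2x2 only, scipy
    semantics: |O-E| reduced by 0.5, floored at 0). Zero expected cells raise;
    expected cells below 5 only warn.
    """
    arr, rows, cols = _coerce_table(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"table must be at least 2x2, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValidationError("table is all zeros")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValidationError(
            "a zero expected cell (empty row or column margin); drop it before testing"
        )
    if np.any(expected < 5):
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) below 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    use_correction = correction and arr.shape == (2, 2)
    stat, p, df, _ = sps.chi2_contingency(arr, correction=use_correction)
    return ContingencyResult(
        table=arr,
        row_labels=rows,
        col_labels=cols,
        statistic=float(stat),
        df=int(df),
        p=float(p),
        correction=use_correction,
        kind="independence",
    )


def build_type_contrast_table(type_counts: pd.DataFrame, focal_type: int) -> pd.DataFrame:
    """Focal-type vs pooled-rest table of disease/quantitative variant counts.

    ``type_counts`` is the per-type x category count table from
    :func:`psimap.coloc.type_level_counts`.
    """
    from .regions import PSI_TYPE_NAMES

    if focal_type not in PSI_TYPE_NAMES:
        raise ValidationError(f"focal_type {focal_type} not in 1..9")
    if type_counts.to_numpy().sum() == 0:
        raise ValidationError("type-level counts are empty")
    focal = type_counts.loc[focal_type]
    other = type_counts.drop(index=focal_type).sum(axis=0)
    return pd.DataFrame(
        [
            [int(focal["disease"]), int(focal["quantitative"])],
            [int(other["disease"]), int(other["quantitative"])],
        ],
        index=[PSI_TYPE_NAMES[focal_type], "other"],
        columns=["disease", "quantitative"],
    )


def build_locus_category_table(assignments, traits) -> pd.DataFrame:
    """Disease vs quantitative x mapped vs unmapped locus counts.

    ``assignments`` must already carry the mapped flag (set by
    :func:`psimap.loci.locus_mapping_rate`).
    """
    category = {t.trait_id: getattr(t.category, "value", str(t.category)) for t in traits}
    counts = {("disease", True): 0, ("disease", False): 0,
              ("quantitative", True): 0, ("quantitative", False): 0}
    for a in assignments:
        try:
            cat = category[a.trait_id]
        except KeyError:
            raise ValidationError(f"trait {a.trait_id!r} missing from trait specs") from None
        counts[(cat, a.mapped)] += 1
    return pd.DataFrame(
        [
            [counts[("disease", True)], counts[("disease", False)]],
            [counts[("quantitative", True)], counts[("quantitative", False)]],
        ],
        index=["disease", "quantitative"],
        columns=["mapped", "unmapped"],
    )


def build_regulatory_table(regions, mapped) -> pd.DataFrame:
    """Regulatory vs non-regulatory x hit vs no-hit region counts.

    Regions carrying more than one PSI type are excluded for simplicity; the
    rest are regulatory unless their single type is hsInsert or psTU.
    """
    hit_ids = {mv.region_id for mv in mapped}
    counts = {("regulatory", True): 0, ("regulatory", False): 0,
              ("non_regulatory", True): 0, ("non_regulatory", False): 0}
    for r in regions:
        if len(r.type_set) > 1:
            continue
        row = "regulatory" if r.regulatory else "non_regulatory"
        counts[(row, r.region_id in hit_ids)] += 1
    return pd.DataFrame(
        [
            [counts[("regulatory", True)], counts[("regulatory", False)]],
            [counts[("non_regulatory", True)], counts[("non_regulatory", False)]],
        ],
        index=["regulatory", "non_regulatory"],
        columns=["mapped", "unmapped"],
    )
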