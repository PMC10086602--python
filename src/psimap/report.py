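"""End-to-end pipeline driver and consolidated report.

``run_pipeline`` executes build-regions -> significance filter -> variant
mapping -> LD clumping -> enrichment tests over an input bundle and writes a
report JSON plus TSV side files. Every percentage in the report is recomputed
from its numerator/denominator at write time (internal consistency check),
and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import coloc, gwas, loci, regions as reg, stats
from .errors import PipelineError, PsimapError, ValidationError
from .genome import GenomeTable


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for report percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half away from zero; 0/0 is reported as 0."""
    if denominator == 0:
        if numerator == 0:
            return 0.0
        raise ValidationError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def mean_length(total_bp: int, n: int) -> tuple[float, int]:
    """Mean region length as (one-decimal value, integer truncated toward zero)."""
    if n == 0:
        return 0.0, 0
    mean = total_bp / n
    return round_half_away(mean, 1), math.trunc(mean)


@dataclass
class RunConfig:
    """Paths and flags for one pipeline run."""

    chrom_sizes: Path
    psi_beds: dict[int, Path]           # type code -> BED path
    trait_manifest: Path
    ld_table: Path
    out_dir: Path
    correction: bool = True             # Yates on 2x2 tables
    singleton_mode: bool = False        # unassigned variants become singleton loci
    multi_type: str = "all"             # multi-type regions in type-level counts
    focal_type: int = 6                 # hsInsert: the disease-biased class contrast
    extra_flags: dict = field(default_factory=dict)

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir, **flags) -> "RunConfig":
        """Build a config from a bundle directory holding manifest.yaml."""
        import yaml

        bundle = Path(bundle_dir)
        with open(bundle / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        return cls(
            chrom_sizes=bundle / manifest["chrom_sizes"],
            psi_beds={int(k): bundle / v for k, v in manifest["psi_elements"].items()},
            trait_manifest=bundle / "manifest.yaml",
            ld_table=bundle / manifest["ld"],
            out_dir=Path(out_dir),
            **flags,
        )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def _test_or_skip(build_fn, test_fn, reason_if_empty: str) -> dict:
    try:
        table = build_fn()
        result = test_fn(table)
        return result.to_dict()
    except (ValidationError, PsimapError) as exc:
        return {"skipped": f"{reason_if_empty}: {exc}"}


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle into out_dir.

    Returns the report dict. On stage failure a PipelineError naming the stage
    is raised and partial outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out: Path, written: list[Path]) -> dict:
    genome = _stage("read_genome", GenomeTable.from_chrom_sizes, config.chrom_sizes)

    elements = []
    for code in sorted(config.psi_beds):
        elements.extend(_stage("read_elements", reg.read_psi_bed,
                               config.psi_beds[code], code, genome))
    regions = _stage("merge_regions", reg.merge_into_regions, elements)
    summary = _stage("summarize_regions", reg.summarize_regions, regions, genome)
    chrom_test = _stage("chromosome_distribution",
                        reg.chisq_chromosome_distribution, regions, genome)

    trait_entries = _stage("read_traits", gwas.read_trait_manifest, config.trait_manifest)
    traits = [spec for spec, _ in trait_entries]
    significant: list[gwas.GWASRecord] = []
    per_trait_sig: dict[str, int] = {}
    for spec, path in trait_entries:
        records = _stage("read_gwas", gwas.read_gwas_table, path, spec)
        sig = _stage("filter_significant", gwas.filter_significant, records, spec)
        per_trait_sig[spec.trait_id] = len(sig)
        significant.extend(sig)

    mapped = _stage("map_variants", coloc.map_variants, significant, regions)
    n_distinct_mapped, n_pleio = coloc.count_pleiotropic(mapped)
    type_counts = _stage("type_level_counts", coloc.type_level_counts,
                         mapped, traits, config.multi_type)

    ld = _stage("read_ld", loci.read_ld_table, config.ld_table)
    assignments, unassigned = _stage("ld_clump", loci.assign_blocks,
                                     significant, ld,
                                     singleton_mode=config.singleton_mode)
    if assignments:
        rates = _stage("locus_mapping_rate", loci.locus_mapping_rate, assignments, mapped)
        n_input_loci, n_mapped_loci = rates.n_input_loci, rates.n_mapped_loci
        locus_rate = rates.rate_pct
    else:
        n_input_loci = n_mapped_loci = 0
        locus_rate = 0.0

    hit_region_ids = {mv.region_id for mv in mapped}
    n_mapped_regions = len(hit_region_ids)
    nonreg_mapped = sum(1 for r in regions
                        if r.region_id in hit_region_ids and not r.regulatory)

    if significant and mapped:
        tests = {
            "type_contrast": _test_or_skip(
                lambda: stats.build_type_contrast_table(type_counts, config.focal_type),
                lambda t: stats.chisq_independence(t, config.correction),
                "type contrast not testable"),
            "locus_category": _test_or_skip(
                lambda: stats.build_locus_category_table(assignments, traits),
                lambda t: stats.chisq_independence(t, config.correction),
                "locus-category contrast not testable"),
            "regulatory": _test_or_skip(
                lambda: stats.build_regulatory_table(regions, mapped),
                lambda t: stats.chisq_independence(t, config.correction),
                "regulatory contrast not testable"),
        }
    else:
        tests = {"skipped": "no significant variants mapped; contrasts not testable"}

    report = {
        "flags": {
            "correction": config.correction,
            "singleton_mode": config.singleton_mode,
            "multi_type": config.multi_type,
            "focal_type": config.focal_type,
            "p_threshold": gwas.P_THRESHOLD,
            "log10bf_threshold": gwas.LOG10BF_THRESHOLD,
            "r2_threshold": loci.R2_THRESHOLD,
        },
        "elements": {
            "n_total": len(elements),
            "per_type": {str(code): sum(1 for e in elements if e.type_code == code)
                         for code in sorted(config.psi_beds)},
        },
        "regions": {
            "n_regions": summary.n_regions,
            "n_multi_element": summary.n_multi_element,
            "multi_element_pct": pct(summary.n_multi_element, summary.n_regions),
            "total_bp": summary.total_bp,
            "mean_bp": summary.mean_bp,
            "mean_bp_truncated": summary.mean_bp_truncated,
            "genome_coverage": summary.genome_coverage,
            "genome_coverage_pct": round_half_away(100 * summary.genome_coverage, 2),
            "per_chrom": [
                {"chrom": c, "n_regions": n, "covered_bp": bp, "coverage": frac}
                for c, n, bp, frac in summary.per_chrom
            ],
        },
        "chromosome_distribution": chrom_test.to_dict(),
        "gwas": {
            "n_significant_records": len(significant),
            "per_trait": per_trait_sig,
        },
        "mapping": {
            "n_mapped_records": len(mapped),
            "n_distinct_mapped_variants": n_distinct_mapped,
            "variant_mapping_rate_pct": pct(len(mapped), len(significant))
                                        if significant else 0.0,
            "n_pleiotropic": n_pleio,
            "pleiotropic_pct": pct(n_pleio, n_distinct_mapped)
                               if n_distinct_mapped else 0.0,
            "n_mapped_regions": n_mapped_regions,
            "mapped_region_pct": pct(n_mapped_regions, summary.n_regions),
            "n_nonregulatory_mapped_regions": nonreg_mapped,
            "nonregulatory_mapped_share_pct": pct(nonreg_mapped, n_mapped_regions)
                                              if n_mapped_regions else 0.0,
        },
        "loci": {
            "n_input_loci": n_input_loci,
            "n_mapped_loci": n_mapped_loci,
            "locus_mapping_rate_pct": locus_rate,
            "n_unassigned_variants": len(unassigned),
        },
        "tests": tests,
    }
    _assert_consistent(report)

    _stage("write_outputs", _write_outputs, report, config, out, written,
           regions, mapped, assignments, traits, type_counts)
    return report


def _assert_consistent(report: dict) -> None:
    """Every display percentage must recompute from its numerator/denominator."""
    r, m, l = report["regions"], report["mapping"], report["loci"]
    checks = [
        (r["multi_element_pct"], r["n_multi_element"], r["n_regions"]),
        (m["variant_mapping_rate_pct"], m["n_mapped_records"],
         report["gwas"]["n_significant_records"]),
        (m["pleiotropic_pct"], m["n_pleiotropic"], m["n_distinct_mapped_variants"]),
        (m["mapped_region_pct"], m["n_mapped_regions"], r["n_regions"]),
        (m["nonregulatory_mapped_share_pct"], m["n_nonregulatory_mapped_regions"],
         m["n_mapped_regions"]),
        (l["locus_mapping_rate_pct"], l["n_mapped_loci"], l["n_input_loci"]),
    ]
    for value, num, den in checks:
        expect = pct(num, den) if den else 0.0
        if value != expect:
            raise PsimapError(
                f"internal inconsistency: reported {value} != recomputed {expect} "
                f"({num}/{den})"
            )


def _write_outputs(report, config: RunConfig, out: Path, written: list[Path],
                   regions, mapped, assignments, traits, type_counts) -> None:
    category = {t.trait_id: t.category.value for t in traits}

    path = out / "regions.bed"
    written.append(path)
    reg.write_regions_bed(regions, path)

    path = out / "mapped_variants.tsv"
    written.append(path)
    with open(path, "w") as fh:
        fh.write("variant_id\tchrom\tpos\ttrait_id\tcategory\tregion_id\ttype_codes\n")
        for mv in mapped:
            types = ",".join(str(t) for t in sorted(mv.type_set))
            fh.write(f"{mv.identity}\t{mv.record.chrom}\t{mv.record.pos}\t"
                     f"{mv.record.trait_id}\t{category[mv.record.trait_id]}\t"
                     f"{mv.region_id}\t{types}\n")

    path = out / "loci.tsv"
    written.append(path)
    loci.write_locus_report(assignments, path)

    path = out / "tables" / "type_level_counts.tsv"
    written.append(path)
    type_counts.to_csv(path, sep="\t")
    for name, entry in report["tests"].items():
        if not isinstance(entry, dict) or "table" not in entry:
            continue
        path = out / "tables" / f"{name}.tsv"
        written.append(path)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(entry["col_labels"]) + "\n")
            for label, row in zip(entry["row_labels"], entry["table"]):
                fh.write(label + "\t" + "\t".join(f"{x:g}" for x in row) + "\n")

    path = out / "run.log"
    written.append(path)
    with open(path, "w") as fh:
        for key, value in sorted(report["flags"].items()):
            fh.write(f"flag {key} = {value}\n")
        fh.write(f"elements {report['elements']['n_total']}\n")
        fh.write(f"regions {report['regions']['n_regions']}\n")
        fh.write(f"significant_records {report['gwas']['n_significant_records']}\n")
        fh.write(f"mapped_records {report['mapping']['n_mapped_records']}\n")
        fh.write(f"input_loci {report['loci']['n_input_loci']}\n")
        fh.write(f"mapped_loci {report['loci']['n_mapped_loci']}\n")

    path = out / "report.json"
    written.append(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
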