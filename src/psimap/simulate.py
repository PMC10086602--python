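"""Synthetic genomes, PSI element sets, GWAS summary statistics and LD tables.

The generator emits exactly the file formats the pipeline reads, with known
ground truth, so every stage and statistical property is testable without any
download. Its shape mirrors the real inputs: nine element classes of very
different counts and length scales placed unevenly across chromosomes, traits
of two categories whose significant variants are lead variants plus LD-block
members, and a controllable enrichment of disease-locus leads inside PSI
regions.

Enrichment model: with genome coverage c by PSI regions, a disease-trait lead
lands inside a region with probability theta*c / (theta*c + 1 - c) — i.e. the
in-region odds are multiplied by theta relative to coverage-proportional
placement — while quantitative-trait leads use probability c. theta = 1 is the
null. Every output is a pure function of the config (seeded determinism).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import PsimapError, ValidationError
from .genome import GenomeTable
from .gwas import SigMode, TraitCategory
from .regions import PSI_TYPE_NAMES, PSIElement, PSIRegion, merge_into_regions

_LOG10_P_LOW = -30.0          # significant p-values drawn log-uniform in (1e-30, 5e-8)
_LOG10_P_HIGH = np.log10(5e-8)
_LOG10BF_LOW = 6.0            # significant log10 Bayes factors drawn uniform in (6, 30)
_LOG10BF_HIGH = 30.0
_MEMBER_R2_LOW = 0.81         # block members: r2 ~ U(0.81, 1.0) to their lead
_DECOY_R2_HIGH = 0.8          # decoys: r2 ~ U(0, 0.8) to the nearest lead


@dataclass(frozen=True)
class SimTypeConfig:
    """One element class: count, log-normal length scale (median, bp), and
    per-chromosome placement weights (must sum to 1)."""

    type_code: int
    n_elements: int
    length_scale: float
    chrom_weights: tuple[float, ...]
    sigma: float = 0.5


@dataclass(frozen=True)
class SimTraitConfig:
    trait_id: str
    category: str            # "quantitative" | "disease"
    n_loci: int
    members_per_locus: float  # Poisson mean of non-lead block members
    sig_mode: str = "pvalue"


@dataclass(frozen=True)
class SimConfig:
    seed: int
    chrom_spec: tuple[tuple[str, int], ...]
    per_type: tuple[SimTypeConfig, ...]
    traits: tuple[SimTraitConfig, ...]
    theta: float = 1.0
    block_halfwidth: int = 25_000
    decoy_rate: float = 0.10

    def __post_init__(self):
        if self.theta < 0:
            raise ValidationError(f"theta must be >= 0, got {self.theta}")
        for t in self.per_type:
            if t.n_elements < 0:
                raise ValidationError(f"type {t.type_code}: negative element count")
            if len(t.chrom_weights) != len(self.chrom_spec):
                raise ValidationError(
                    f"type {t.type_code}: {len(t.chrom_weights)} weights for "
                    f"{len(self.chrom_spec)} chromosomes"
                )
            if abs(sum(t.chrom_weights) - 1.0) > 1e-9:
                raise ValidationError(f"type {t.type_code}: chrom_weights must sum to 1")
        for tr in self.traits:
            if tr.n_loci < 0 or tr.members_per_locus < 0:
                raise ValidationError(f"trait {tr.trait_id}: negative count parameter")
            TraitCategory(tr.category)
            SigMode(tr.sig_mode)

    @property
    def genome(self) -> GenomeTable:
        return GenomeTable(self.chrom_spec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return _config_from_dict(d)


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["chrom_spec"] = [list(x) for x in config.chrom_spec]
    d["per_type"] = [dict(dataclasses.asdict(t),
                          chrom_weights=list(t.chrom_weights)) for t in config.per_type]
    d["traits"] = [dataclasses.asdict(t) for t in config.traits]
    return d


def _config_from_dict(d: dict) -> SimConfig:
    return SimConfig(
        seed=int(d["seed"]),
        chrom_spec=tuple((str(c), int(l)) for c, l in d["chrom_spec"]),
        per_type=tuple(SimTypeConfig(
            type_code=int(t["type_code"]), n_elements=int(t["n_elements"]),
            length_scale=float(t["length_scale"]),
            chrom_weights=tuple(float(w) for w in t["chrom_weights"]),
            sigma=float(t.get("sigma", 0.5)),
        ) for t in d["per_type"]),
        traits=tuple(SimTraitConfig(
            trait_id=str(t["trait_id"]), category=str(t["category"]),
            n_loci=int(t["n_loci"]), members_per_locus=float(t["members_per_locus"]),
            sig_mode=str(t.get("sig_mode", "pvalue")),
        ) for t in d["traits"]),
        theta=float(d.get("theta", 1.0)),
        block_halfwidth=int(d.get("block_halfwidth", 25_000)),
        decoy_rate=float(d.get("decoy_rate", 0.10)),
    )


# Default per-type counts and length scales echo the heterogeneity of the real
# nine catalogues at ~1/33 scale: hsInsert dominates in count, psCRE/psTU/hsGRE
# are few-but-long, HGE/DNM are tiny sets. Length scales (bp) are the real
# catalogues' implied mean element lengths.
_DEFAULT_TYPE_SHAPE = {
    1: (83, 253.0), 2: (2, 392.0), 3: (30, 198.0), 4: (45, 3304.0), 5: (1, 797.0),
    6: (360, 868.0), 7: (4, 3395.0), 8: (16, 330.0), 9: (58, 4197.0),
}


def default_config(seed: int, theta: float = 1.0, n_loci: int = 50,
                   members_per_locus: float = 3.0,
                   element_scale: float = 1.0) -> SimConfig:
    """Small default study: 5 chromosomes x 2 Mb, ~600 elements in nine
    classes, and four traits (two quantitative, two disease).

    ``element_scale`` multiplies every class's element count (denser placement
    for experiments that need higher genome coverage).
    """
    chrom_spec = tuple((f"chr{i}", 2_000_000) for i in range(1, 6))
    # Uneven placement: odd chromosomes slightly over-weighted.
    base = np.array([1.3, 0.8, 1.2, 0.9, 0.8])
    weights = tuple(float(w) for w in base / base.sum())
    per_type = tuple(
        SimTypeConfig(code, max(1, int(round(n * element_scale))), scale, weights)
        for code, (n, scale) in _DEFAULT_TYPE_SHAPE.items()
    )
    traits = (
        SimTraitConfig("qt_height", "quantitative", n_loci, members_per_locus, "pvalue"),
        SimTraitConfig("qt_bmi", "quantitative", n_loci, members_per_locus, "log10bf"),
        SimTraitConfig("dis_scz", "disease", n_loci, members_per_locus, "pvalue"),
        SimTraitConfig("dis_t2d", "disease", n_loci, members_per_locus, "pvalue"),
    )
    return SimConfig(seed=seed, chrom_spec=chrom_spec, per_type=per_type,
                     traits=traits, theta=theta)


@dataclass
class SimTruth:
    """Ground truth of one simulated study: the config, whether each lead was
    placed inside a PSI region, and the realized genome coverage."""

    config: SimConfig
    lead_in_region: dict[str, bool]
    coverage: float

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_dict(self.config),
            "lead_in_region": {k: bool(v) for k, v in sorted(self.lead_in_region.items())},
            "coverage": self.coverage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def draw_elements(config: SimConfig, rng: np.random.Generator) -> list[PSIElement]:
    """Draw every class's elements: log-normal lengths (median = length_scale,
    minimum 10 bp), chromosome per the class weights, start uniform."""
    genome = config.genome
    chroms = genome.chroms
    elements: list[PSIElement] = []
    for t in config.per_type:
        weights = np.asarray(t.chrom_weights)
        chrom_idx = rng.choice(len(chroms), size=t.n_elements, p=weights)
        for j in range(t.n_elements):
            chrom = chroms[int(chrom_idx[j])]
            chrom_len = genome.length(chrom)
            for attempt in range(100):
                length = max(10, int(round(rng.lognormal(np.log(t.length_scale), t.sigma))))
                if length <= chrom_len:
                    break
            else:
                raise PsimapError(
                    f"type {t.type_code}: could not draw an element fitting "
                    f"{chrom} (length {chrom_len}) in 100 attempts"
                )
            start = int(rng.integers(0, chrom_len - length + 1))
            elements.append(PSIElement(
                f"t{t.type_code}_{j + 1}", t.type_code, chrom, start, start + length,
                PSI_TYPE_NAMES[t.type_code],
            ))
    return elements


def simulate_psi_elements(config: SimConfig, out_dir) -> dict:
    """Write chrom.sizes plus one BED per element class; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    elements = draw_elements(config, rng)
    genome = config.genome
    sizes_path = out / "chrom.sizes"
    genome.to_chrom_sizes(sizes_path)
    paths = {}
    for t in config.per_type:
        path = out / f"psi_type{t.type_code}.bed"
        with open(path, "w") as fh:
            for e in elements:
                if e.type_code == t.type_code:
                    fh.write(f"{e.chrom}\t{e.start}\t{e.end}\n")
        paths[t.type_code] = path
    return {"chrom_sizes": sizes_path, "beds": paths, "elements": elements}


@dataclass(frozen=True)
class _SimVariant:
    variant_id: str
    chrom: str
    pos: int
    score: float
    lead_id: str | None   # None for decoys


def _coverage(regions: list[PSIRegion], genome: GenomeTable) -> float:
    return sum(r.length for r in regions) / genome.total_bp


def _draw_in_region_pos(regions, region_lengths, rng) -> tuple[str, int]:
    i = int(rng.choice(len(regions), p=region_lengths / region_lengths.sum()))
    r = regions[i]
    offset = int(rng.integers(0, r.length))
    return r.chrom, r.start + 1 + offset   # 1-based position inside [start, end)


def _draw_out_region_pos(genome, region_index, rng) -> tuple[str, int]:
    lengths = np.array([l for _, l in genome.entries], dtype=float)
    p = lengths / lengths.sum()
    for _ in range(1000):
        ci = int(rng.choice(len(genome.entries), p=p))
        chrom = genome.chroms[ci]
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        if region_index.lookup(chrom, pos) is None:
            return chrom, pos
    raise PsimapError("could not place an out-of-region lead in 1000 attempts")


def draw_gwas(config: SimConfig, regions: list[PSIRegion],
              rng: np.random.Generator):
    """Draw every trait's significant variants and the LD table.

    Returns (variants_by_trait, ld_rows, truth) where ld_rows are
    (variant_id, lead_id, r2) tuples.
    """
    from .coloc import RegionIndex

    genome = config.genome
    c = _coverage(regions, genome)
    if c == 0 and config.theta > 0:
        raise ValidationError("regions cover zero bases: cannot place enriched leads")
    region_lengths = np.array([r.length for r in regions], dtype=float)
    region_index = RegionIndex(regions)

    p_in_disease = config.theta * c / (config.theta * c + 1 - c)
    variants_by_trait: dict[str, list[_SimVariant]] = {}
    ld_rows: list[tuple[str, str, float]] = []
    lead_in_region: dict[str, bool] = {}

    for trait in config.traits:
        p_in = p_in_disease if trait.category == "disease" else c
        draws: list[_SimVariant] = []
        used_pos: set[tuple[str, int]] = set()
        lead_positions: list[tuple[str, int, str]] = []

        def draw_score() -> float:
            if trait.sig_mode == "pvalue":
                return float(10 ** rng.uniform(_LOG10_P_LOW, _LOG10_P_HIGH))
            return float(rng.uniform(_LOG10BF_LOW, _LOG10BF_HIGH))

        for _ in range(trait.n_loci):
            in_region = bool(rng.random() < p_in)
            for _ in range(50):   # avoid duplicate positions within a trait
                if in_region:
                    chrom, pos = _draw_in_region_pos(regions, region_lengths, rng)
                else:
                    chrom, pos = _draw_out_region_pos(genome, region_index, rng)
                if (chrom, pos) not in used_pos:
                    break
            used_pos.add((chrom, pos))
            lead_id = f"v_{chrom}_{pos}"
            lead_in_region[lead_id] = region_index.lookup(chrom, pos) is not None
            draws.append(_SimVariant(lead_id, chrom, pos, draw_score(), lead_id))
            ld_rows.append((lead_id, lead_id, 1.0))
            lead_positions.append((chrom, pos, lead_id))

            n_members = int(rng.poisson(trait.members_per_locus))
            chrom_len = genome.length(chrom)
            for _ in range(n_members):
                for _ in range(20):
                    offset = int(rng.integers(-config.block_halfwidth,
                                              config.block_halfwidth + 1))
                    mpos = min(max(pos + offset, 1), chrom_len)
                    if (chrom, mpos) not in used_pos:
                        break
                else:
                    continue
                used_pos.add((chrom, mpos))
                mid = f"v_{chrom}_{mpos}"
                draws.append(_SimVariant(mid, chrom, mpos, draw_score(), lead_id))
                ld_rows.append((mid, lead_id, float(rng.uniform(_MEMBER_R2_LOW, 1.0))))

        n_decoys = int(round(config.decoy_rate * len(draws)))
        for _ in range(n_decoys):
            for _ in range(50):
                ci = int(rng.integers(0, len(genome.entries)))
                chrom = genome.chroms[ci]
                pos = int(rng.integers(1, genome.length(chrom) + 1))
                if (chrom, pos) not in used_pos:
                    break
            used_pos.add((chrom, pos))
            vid = f"v_{chrom}_{pos}"
            draws.append(_SimVariant(vid, chrom, pos, draw_score(), None))
            if lead_positions:
                same = [(abs(p - pos), lid) for (ch, p, lid) in lead_positions if ch == chrom]
                nearest = min(same)[1] if same else min(
                    (abs(p - pos), lid) for (_, p, lid) in lead_positions)[1]
                ld_rows.append((vid, nearest, float(rng.uniform(0.0, _DECOY_R2_HIGH))))
        variants_by_trait[trait.trait_id] = draws

    truth = SimTruth(config=config, lead_in_region=lead_in_region, coverage=c)
    return variants_by_trait, ld_rows, truth


def trait_specs(config: SimConfig) -> list:
    """The TraitSpec objects matching the config's traits."""
    from .gwas import TraitSpec

    return [TraitSpec(t.trait_id, t.category, t.sig_mode) for t in config.traits]


def to_gwas_records(variants_by_trait: dict, config: SimConfig) -> list:
    """Flatten an in-memory draw into GWASRecord objects (all significant by
    construction)."""
    from .gwas import GWASRecord

    records = []
    for trait in config.traits:
        for v in variants_by_trait[trait.trait_id]:
            records.append(GWASRecord(v.variant_id, v.chrom, v.pos,
                                      trait.trait_id, v.score, v.lead_id))
    return records


def to_ld_pairs(ld_rows: list[tuple[str, str, float]]) -> list:
    from .loci import LDPair

    return [LDPair(v, l, r) for v, l, r in ld_rows]


@dataclass
class SimStudy:
    """One in-memory synthetic study: inputs plus ground truth."""

    elements: list[PSIElement]
    regions: list[PSIRegion]
    records: list          # GWASRecord, all genome-wide significant
    ld: list               # LDPair
    truth: SimTruth


def draw_study(config: SimConfig, rng: np.random.Generator | None = None) -> SimStudy:
    """Draw a full study in memory: elements -> merged regions -> GWAS + LD.

    The same draw sequence as :func:`end_to_end_fixture`, without file IO;
    convenient for repeated-draw experiments (calibration, power, parameter
    recovery).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elements = draw_elements(config, rng)
    regions = merge_into_regions(elements)
    variants_by_trait, ld_rows, truth = draw_gwas(config, regions, rng)
    return SimStudy(elements, regions,
                    to_gwas_records(variants_by_trait, config),
                    to_ld_pairs(ld_rows), truth)


def draw_locus_category_table(config: SimConfig,
                              rng: np.random.Generator | None = None):
    """One draw of the disease/quantitative x mapped/unmapped locus table.

    Returns (table, study). Used by the calibration, power and
    theta-recovery experiments.
    """
    from .coloc import map_variants
    from .loci import assign_blocks, locus_mapping_rate
    from .stats import build_locus_category_table

    study = draw_study(config, rng)
    mapped = map_variants(study.records, study.regions)
    assignments, _ = assign_blocks(study.records, study.ld)
    locus_mapping_rate(assignments, mapped)
    return build_locus_category_table(assignments, trait_specs(config)), study


def simulate_gwas(config: SimConfig, regions: list[PSIRegion], out_dir,
                  rng: np.random.Generator | None = None) -> SimTruth:
    """Write per-trait GWAS TSVs, the LD TSV, the trait manifest and the
    ground-truth JSON. ``rng`` defaults to a fresh generator from the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants_by_trait, ld_rows, truth = draw_gwas(config, regions, rng)

    manifest_traits = []
    for trait in config.traits:
        score_col = "pvalue" if trait.sig_mode == "pvalue" else "log10bf"
        path = out / f"gwas_{trait.trait_id}.tsv"
        with open(path, "w") as fh:
            fh.write(f"variant_id\tchrom\tpos\t{score_col}\tlead_id\n")
            for v in variants_by_trait[trait.trait_id]:
                score = f"{v.score:.6e}" if score_col == "pvalue" else f"{v.score:.4f}"
                fh.write(f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{score}\t"
                         f"{v.lead_id or ''}\n")
        manifest_traits.append({
            "trait_id": trait.trait_id, "category": trait.category,
            "sig_mode": trait.sig_mode, "path": path.name,
        })

    with open(out / "ld.tsv", "w") as fh:
        fh.write("variant_id\tlead_id\tr2\n")
        for vid, lid, r2 in ld_rows:
            fh.write(f"{vid}\t{lid}\t{r2:.6f}\n")

    manifest = {
        "chrom_sizes": "chrom.sizes",
        "psi_elements": {t.type_code: f"psi_type{t.type_code}.bed"
                         for t in config.per_type},
        "ld": "ld.tsv",
        "traits": manifest_traits,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    truth.to_json(out / "sim_truth.json")
    return truth


def end_to_end_fixture(config: SimConfig, out_dir) -> SimTruth:
    """Write a complete input bundle (chrom.sizes, nine BEDs, GWAS TSVs, LD
    table, manifest, ground truth) into one directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    elements = draw_elements(config, rng)
    genome = config.genome
    genome.to_chrom_sizes(out / "chrom.sizes")
    for t in config.per_type:
        with open(out / f"psi_type{t.type_code}.bed", "w") as fh:
            for e in elements:
                if e.type_code == t.type_code:
                    fh.write(f"{e.chrom}\t{e.start}\t{e.end}\n")
    regions = merge_into_regions(elements)
    return simulate_gwas(config, regions, out, rng=rng)
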