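"""Seeded generators for bi-parental F1 populations, storage trajectories
and candidate-filter fixtures.

The genetic model is the (a, d) parameterisation: at a biallelic marker
with sorted alleles (lo, hi), the lo/lo homozygote contributes -a months,
the heterozygote d, and the hi/hi homozygote +a.  Offspring genotypes are
drawn by Mendelian gamete sampling from the parental genotypes (Aa x aa
segregates 1:1, Aa x Aa segregates 1:2:1).  Environmental noise is scaled
so the realised broad-sense heritability matches a target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    GenomicInterval,
    GenotypeTable,
    VariantRecord,
    call_alleles,
    normalize_call,
)
from .marker_effects import classify_ratio
from .phenotype import (
    DEFAULT_RAPID_DROP,
    DEFAULT_THRESHOLDS,
    LAST_MONTH,
    TYPE_I,
    TYPE_II,
    TYPE_III,
    StorageSeries,
)

MAX_MONTH = 6.0


# ---------------------------------------------------------------------------
# marker and population simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSpec:
    """One segregating marker: parental genotypes plus (a, d) effects."""

    marker_id: str
    parent1: str  # genotype-class label, e.g. "A:G"
    parent2: str
    a: float  # half-difference of homozygote contributions, months
    d: float  # heterozygote deviation from the homozygote midpoint, months

    def __post_init__(self) -> None:
        p1 = normalize_call(self.parent1)
        p2 = normalize_call(self.parent2)
        if p1 is None or p2 is None:
            raise ValueError(f"marker {self.marker_id}: missing parental genotype")
        object.__setattr__(self, "parent1", p1)
        object.__setattr__(self, "parent2", p2)
        het1 = len(set(call_alleles(p1))) == 2
        het2 = len(set(call_alleles(p2))) == 2
        if not (het1 or het2):
            raise ValueError(
                f"marker {self.marker_id}: both parents homozygous "
                f"({p1} x {p2}); marker does not segregate"
            )
        if len(self.alleles) > 2:
            raise ValueError(f"marker {self.marker_id}: more than 2 alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(sorted(set(call_alleles(self.parent1))
                            | set(call_alleles(self.parent2))))

    def contribution(self, genotype: str) -> float:
        """Genetic contribution (months) of one offspring genotype class."""
        lo, hi = self.alleles
        table = {
            f"{lo}:{lo}": -self.a,
            ":".join(sorted((lo, hi))): self.d,
            f"{hi}:{hi}": +self.a,
        }
        return table[genotype]

    @property
    def intended_action(self) -> str:
        """Allelic-action label implied by d/a (same bins as the estimator)."""
        if abs(self.a) < 1e-12:
            return "undetermined"
        return classify_ratio(abs(self.d / self.a))

    def offspring_classes(self) -> list[str]:
        """Genotype classes realizable from these parents."""
        p1 = call_alleles(self.parent1)
        p2 = call_alleles(self.parent2)
        return sorted({":".join(sorted((x, y))) for x in p1 for y in p2})

    @property
    def span(self) -> float:
        """Range of the realizable genotype-class contributions."""
        values = [self.contribution(g) for g in self.offspring_classes()]
        return max(values) - min(values)


@dataclass
class SimulationConfig:
    n_hybrids: int
    markers: list[MarkerSpec]
    population_mean: float = 2.0
    target_h2: float = 0.84
    n_years: int = 1
    seed: int = 0
    integer_mode: bool = False
    truncate: bool = True
    max_month: float = MAX_MONTH

    def __post_init__(self) -> None:
        if self.n_hybrids < 2:
            raise ValueError("n_hybrids must be >= 2")
        if not (0 < self.target_h2 <= 1):
            raise ValueError("target_h2 must be in (0, 1]")
        if not self.markers:
            raise ValueError("need at least one segregating marker")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeTable
    true_genetic_values: pd.Series  # per hybrid, pre-truncation scale
    phenotypes: pd.DataFrame
    config: SimulationConfig
    sigma_e: float

    def true_class_effects(self, marker_id: str) -> dict[str, float]:
        """Construction-known class effects for one marker.

        The per-class genetic contribution (-a, d, +a) minus its realised
        population-frequency-weighted mean, i.e. what the class-mean-minus-
        overall-mean estimator converges to on this population.
        """
        spec = next(m for m in self.config.markers if m.marker_id == marker_id)
        column = self.genotypes.calls[marker_id]
        counts = column.value_counts()
        contrib = {g: spec.contribution(g) for g in counts.index}
        weighted_mean = sum(contrib[g] * counts[g] for g in counts.index) / counts.sum()
        return {g: contrib[g] - weighted_mean for g in counts.index}


def _sample_offspring(spec: MarkerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Mendelian gamete sampling: one allele per parent, uniform per parent."""
    p1 = call_alleles(spec.parent1)
    p2 = call_alleles(spec.parent2)
    g1 = rng.integers(0, 2, size=n)
    g2 = rng.integers(0, 2, size=n)
    labels = np.empty(n, dtype=object)
    # precompute the 4 gamete combinations
    combo = {
        (i, j): ":".join(sorted((p1[i], p2[j]))) for i in (0, 1) for j in (0, 1)
    }
    for (i, j), label in combo.items():
        labels[(g1 == i) & (g2 == j)] = label
    return labels


def simulate_f1_population(config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None,
                           ) -> SimulatedPopulation:
    """Generate genotypes, true genetic values and phenotypes for an F1 cross.

    Environmental noise has variance Var(g) * (1 - h2) / h2 so the plug-in
    variance ratio matches ``target_h2`` before truncation.  Phenotypes are
    truncated to [0, max_month] and, in integer mode, rounded to the
    monthly grid; the recorded true genetic values are pre-truncation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geno_stream, noise_stream = rng.spawn(2)
    n = config.n_hybrids
    hybrid_ids = [f"H{i + 1:05d}" for i in range(n)]
    calls = {}
    g = np.zeros(n)
    for spec in config.markers:
        labels = _sample_offspring(spec, n, geno_stream)
        calls[spec.marker_id] = labels
        g += np.vectorize(spec.contribution)(labels).astype(float)
    frame = pd.DataFrame(calls, index=pd.Index(hybrid_ids, name="hybrid_id"))
    frame.columns.name = "marker_id"
    genotypes = GenotypeTable(frame)

    var_g = float(np.var(g))
    if var_g == 0:
        raise ValueError("simulated genetic variance is zero")
    sigma_e = float(np.sqrt(var_g * (1.0 - config.target_h2) / config.target_h2))

    records = []
    for year in range(1, config.n_years + 1):
        noise = noise_stream.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
        pheno = config.population_mean + g + noise
        if config.truncate:
            pheno = np.clip(pheno, 0.0, config.max_month)
        if config.integer_mode:
            pheno = np.rint(pheno)
        records.append(
            pd.DataFrame(
                {
                    "hybrid_id": hybrid_ids,
                    "trait": "retainability",
                    "opv": pheno,
                    "year": year,
                }
            )
        )
    phenotypes = pd.concat(records, ignore_index=True)
    true_g = pd.Series(g, index=hybrid_ids, name="true_genetic_value")
    return SimulatedPopulation(genotypes, true_g, phenotypes, config, sigma_e)


def make_marker_panel(n_markers: int = 28,
                      span_min: float = 0.1,
                      span_max: float = 3.5) -> list[MarkerSpec]:
    """Deterministic marker panel whose class-mean spans cover a target range.

    The head of the panel is intercross (Aa x Aa) markers with large spans
    and one marker per allelic-action class, so action recovery can be
    checked; the tail is backcross (Aa x aa) markers with spans shrinking
    geometrically to ``span_min``.
    """
    if n_markers < 6:
        raise ValueError("panel needs at least 6 markers")
    specs: list[MarkerSpec] = []

    def f2(mid: str, a: float, d: float) -> MarkerSpec:
        return MarkerSpec(mid, "A:G", "A:G", a=a, d=d)

    # span of an additive/partial-dominant intercross marker is 2a
    specs.append(f2("M001", a=span_max / 2.0, d=0.0))               # additive, widest
    specs.append(f2("M002", a=0.7, d=0.0))                          # additive, span 1.4
    specs.append(f2("M003", a=0.6, d=0.3))                          # partial, span 1.2
    specs.append(f2("M004", a=0.8, d=0.8))                          # complete, span 1.6
    specs.append(f2("M005", a=0.6, d=0.9))                          # overdominant, span 1.5
    n_tail = n_markers - 5
    # backcross span is |a + d|; with d = 0 it is simply a
    hi, lo = 0.45, span_min
    ratio = (lo / hi) ** (1.0 / max(1, n_tail - 1))
    for i in range(n_tail):
        span = hi * ratio**i
        specs.append(
            MarkerSpec(f"M{i + 6:03d}", "A:G", "A:A", a=span, d=0.0)
        )
    return specs


# ---------------------------------------------------------------------------
# storage-trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class StorageParams:
    start: float
    fast_drop: float
    slow_rate: float
    noise_sd: float


#: defaults chosen so each type's contract holds with margin at the default
#: noise level (crispness mirrors the 10x smaller measurement scale)
DEFAULT_STORAGE_PARAMS: dict[tuple[str, str], StorageParams] = {
    ("firmness", TYPE_I): StorageParams(6.0, 0.0, 0.20, 0.10),
    ("firmness", TYPE_II): StorageParams(9.0, 1.5, 0.05, 0.10),
    ("firmness", TYPE_III): StorageParams(8.2, 0.0, 0.12, 0.10),
    ("crispness", TYPE_I): StorageParams(0.60, 0.00, 0.020, 0.010),
    ("crispness", TYPE_II): StorageParams(0.90, 0.15, 0.005, 0.010),
    ("crispness", TYPE_III): StorageParams(0.82, 0.00, 0.012, 0.010),
}


def _deterministic_trajectory(ptype: str, params: StorageParams) -> np.ndarray:
    months = np.arange(LAST_MONTH + 1)
    if ptype == TYPE_I:
        return params.start - params.slow_rate * months
    if ptype == TYPE_II:
        values = np.empty(LAST_MONTH + 1)
        values[0] = params.start
        values[1:] = params.start - params.fast_drop - params.slow_rate * np.arange(LAST_MONTH)
        return values
    if ptype == TYPE_III:
        return params.start - params.slow_rate * months
    raise ValueError(f"unknown phenotype type {ptype!r}")


def _check_type_contract(ptype: str, values: np.ndarray, threshold: float,
                         rapid_drop: float) -> None:
    if ptype == TYPE_I:
        if values[0] >= threshold:
            raise ValueError("type I parameters start at/above threshold")
        return
    if np.any(values < threshold):
        raise ValueError(f"type {ptype} parameters cross the threshold")
    drop = values[0] - values[1]
    if ptype == TYPE_II and drop < rapid_drop:
        raise ValueError("type II first-month drop below the rapid-drop cutoff")
    if ptype == TYPE_III and drop >= rapid_drop:
        raise ValueError("type III first-month drop reaches the rapid-drop cutoff")


def simulate_storage_series(ptype: str, trait: str,
                            params: Optional[StorageParams] = None,
                            rng: Optional[np.random.Generator] = None,
                            hybrid_id: str = "SIM",
                            seed: Optional[int] = None) -> StorageSeries:
    """Generate one monthly storage trajectory of the requested type.

    The noiseless trajectory must satisfy the type's contract (checked
    before emission); Gaussian measurement noise is then added, so at high
    noise an emitted series may occasionally score to a different type.
    """
    if params is None:
        try:
            params = DEFAULT_STORAGE_PARAMS[(trait, ptype)]
        except KeyError:
            raise KeyError(f"no default storage parameters for ({trait}, {ptype})") from None
    if rng is None:
        rng = np.random.default_rng(seed)
    threshold = DEFAULT_THRESHOLDS[trait]
    rapid_drop = DEFAULT_RAPID_DROP[trait]
    values = _deterministic_trajectory(ptype, params)
    _check_type_contract(ptype, values, threshold, rapid_drop)
    noisy = np.maximum(0.0, values + rng.normal(0.0, params.noise_sd, size=values.size))
    return StorageSeries(
        hybrid_id=hybrid_id, trait=trait,
        months=np.arange(LAST_MONTH + 1), values=noisy,
    )


# ---------------------------------------------------------------------------
# candidate-filter fixtures
# ---------------------------------------------------------------------------

@dataclass
class CandidateFixture:
    qtls: list[GenomicInterval]
    genes: list[GenomicInterval]
    variants: list[VariantRecord]
    expression: dict[str, float]
    deg_ids: list[str]
    manifest: dict  # construction-known truth

    def write(self, out_dir: str | Path) -> None:
        from . import io_tables

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_tables.write_bed(self.qtls, out / "qtls.bed")
        io_tables.write_bed(self.genes, out / "genes.bed")
        io_tables.write_minimal_vcf(self.variants, out / "variants.vcf")
        expr = pd.DataFrame(
            sorted(self.expression.items()), columns=["gene_id", "expression"]
        )
        expr.to_csv(out / "expression.tsv", sep="\t", index=False)
        (out / "deg_ids.txt").write_text(
            "".join(f"{g}\n" for g in self.deg_ids), encoding="utf-8"
        )
        with (out / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


_SCENARIOS = ("survivor_domain", "survivor_promoter_deg", "fail_R2", "fail_R3", "fail_R4")


def simulate_candidate_tables(n_genes: int = 12, n_variants: int = 20,
                              seed: int = 0) -> CandidateFixture:
    """Build a candidate-filter fixture with construction-known survivors.

    Genes are placed alternately inside and outside two QTL intervals;
    in-QTL genes cycle through scenarios (kept via a domain-disrupting CDS
    variant, kept via a promoter variant plus DEG membership, or removed by
    each exclusion rule).  The manifest records which genes must survive
    and which rule removes each of the others, independent of the filter
    implementation.
    """
    rng = np.random.default_rng(seed)
    gene_len = 3000
    spacing = 10_000
    qtls = [
        GenomicInterval("chr1", 100_000, 100_000 + spacing * n_genes, "QTL1"),
        GenomicInterval("chr2", 500_000, 500_000 + spacing * n_genes, "QTL2"),
    ]
    genes: list[GenomicInterval] = []
    variants: list[VariantRecord] = []
    expression: dict[str, float] = {}
    deg_ids: list[str] = []
    expected_survivors: list[str] = []
    expected_removed: dict[str, str] = {}
    variant_budget = n_variants

    for i in range(n_genes):
        gene_id = f"G{i + 1:03d}"
        outside = i % 4 == 3  # every fourth gene falls outside all QTLs
        if outside:
            chrom, base = "chr3", 900_000 + spacing * i
        else:
            qtl = qtls[i % 2]
            chrom = qtl.chrom
            base = qtl.start + spacing * (i // 2) + 2500
        iv = GenomicInterval(chrom, base, base + gene_len, gene_id)
        genes.append(iv)
        expression[gene_id] = float(rng.uniform(1.0, 50.0))

        if outside:
            expected_removed[gene_id] = "R1"
            continue

        scenario = _SCENARIOS[i % len(_SCENARIOS)]
        if scenario != "fail_R2" and variant_budget == 0:
            scenario = "fail_R2"  # no variants left to place

        if scenario == "survivor_domain":
            variants.append(VariantRecord(
                chrom, iv.start + int(rng.integers(100, gene_len - 100)),
                "A", "T", region="CDS_domain", disrupts_domain=True,
            ))
            variant_budget -= 1
            expected_survivors.append(gene_id)
        elif scenario == "survivor_promoter_deg":
            variants.append(VariantRecord(
                chrom, max(0, iv.start - int(rng.integers(50, 1500))),
                "C", "G", region="promoter", disrupts_cis_element=True,
            ))
            variant_budget -= 1
            deg_ids.append(gene_id)
            expected_survivors.append(gene_id)
        elif scenario == "fail_R2":
            if variant_budget > 0:  # harmless non-impactful variant
                variants.append(VariantRecord(
                    chrom, iv.start + int(rng.integers(100, gene_len - 100)),
                    "G", "A", region="CDS_other",
                ))
                variant_budget -= 1
            expected_removed[gene_id] = "R2"
        elif scenario == "fail_R3":
            variants.append(VariantRecord(
                chrom, iv.start + int(rng.integers(100, gene_len - 100)),
                "T", "C", region="CDS_domain", disrupts_domain=True,
            ))
            variant_budget -= 1
            expression[gene_id] = 0.0
            expected_removed[gene_id] = "R3"
        else:  # fail_R4: promoter-only impactful variant, not a DEG
            variants.append(VariantRecord(
                chrom, max(0, iv.start - int(rng.integers(50, 1500))),
                "C", "A", region="promoter", disrupts_cis_element=True,
            ))
            variant_budget -= 1
            expected_removed[gene_id] = "R4"

    manifest = {
        "seed": seed,
        "n_genes": n_genes,
        "n_variants_placed": len(variants),
        "expected_survivors": sorted(expected_survivors),
        "expected_removed": expected_removed,
    }
    return CandidateFixture(qtls, genes, variants, expression, deg_ids, manifest)
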