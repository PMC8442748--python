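"""Synthetic F2 bulk-sequencing data with the structure a BSA-seq scan assumes.

Emulates the study design end to end: two fully homozygous inbred parents
differing at many biallelic SNPs, an F2 from their selfed F1 segregating a
single fully penetrant recessive sterility locus, phenotype-class bulks of 30
plants each, and pooled short-read sequencing of each bulk at ~34x mean depth
with a small per-read error rate.

Meiosis follows the Haldane model: the crossover count per chromosome per
gamete is Poisson with mean ``recomb_rate`` (the chromosome's map length in
Morgans) and crossover positions are uniform, with no interference. Pool
depth at a site is Poisson with mean ``mean_depth``; conditional on depth,
each read carries the sterile-parent allele with probability equal to the
bulk's true allele frequency, flipped with probability ``base_error``.

A truth sidecar (TSV) records the causal locus and per-site true bulk
frequencies. It exists for tests only; no pipeline stage reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomeLayout",
    "SimConfig",
    "Population",
    "Bulks",
    "SimResult",
    "default_layout",
    "simulate_f2_population",
    "form_bulks",
    "bulk_allele_freq",
    "simulate_pool_depths",
    "simulate_case",
    "write_simulation",
]

STERILE, FERTILE = "sterile", "fertile"

# sample roles used in every emitted VCF, in column order
SAMPLE_ROLES = ("parent_sterile", "parent_fertile", "bulk_sterile", "bulk_fertile")

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid simulation layout or parameters."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, SNP positions and the causal sterility locus.

    ``snp_positions`` maps chromosome name to a sorted 1-based position array.
    ``causal_locus`` is a ``(chrom, pos)`` pair that must coincide with one of
    the SNPs, or ``None`` for a null genome with no sterility locus (then
    phenotypes are assigned at random with the Mendelian 1/4 sterile rate).
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: Mapping[str, np.ndarray]
    causal_locus: tuple[str, int] | None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("layout needs at least one chromosome")
        lengths = dict(self.chromosomes)
        total = 0
        for chrom, length in self.chromosomes:
            pos = np.asarray(self.snp_positions.get(chrom, ()))
            total += pos.size
            if pos.size == 0:
                continue
            if not np.all(np.diff(pos) > 0):
                raise ConfigurationError(f"{chrom}: SNP positions must strictly increase")
            if pos[0] < 1 or pos[-1] > length:
                raise ConfigurationError(f"{chrom}: SNP positions outside [1, {length}]")
        if total == 0:
            raise ConfigurationError("layout contains no SNPs")
        if self.causal_locus is not None:
            chrom, pos = self.causal_locus
            if chrom not in lengths:
                raise ConfigurationError(f"causal chromosome {chrom!r} not in layout")
            if pos not in np.asarray(self.snp_positions[chrom]):
                raise ConfigurationError("causal locus must coincide with a SNP")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def n_snps(self) -> int:
        return sum(np.asarray(p).size for p in self.snp_positions.values())

    def site_table(self) -> pd.DataFrame:
        """Flat (chrom, pos) table over all SNPs in genome order."""
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": np.asarray(self.snp_positions[chrom])})
            for chrom, _ in self.chromosomes
        ]
        return pd.concat(frames, ignore_index=True)

    def causal_index(self) -> int | None:
        """Row index of the causal SNP in :meth:`site_table` order."""
        if self.causal_locus is None:
            return None
        offset = 0
        for chrom, _ in self.chromosomes:
            pos = np.asarray(self.snp_positions[chrom])
            if chrom == self.causal_locus[0]:
                return offset + int(np.searchsorted(pos, self.causal_locus[1]))
            offset += pos.size
        raise AssertionError("unreachable: causal chromosome validated in __post_init__")


@dataclass(frozen=True)
class SimConfig:
    """Tunable parameters of one simulated mapping experiment.

    Defaults mirror the study design: bulks of 30 plants per phenotype class
    sequenced at ~34x mean pool depth. ``recomb_rate`` is the expected
    crossover count per chromosome per gamete (its map length in Morgans);
    the default 0.4 gives the desk-scale 10 Mb chromosomes the ~4 cM/Mb map
    density of the watermelon genome, so physical-window linkage decay
    behaves as it does in the real data.
    """

    n_f2: int = 200
    bulk_size: int = 30
    mean_depth: float = 34.0
    base_error: float = 0.01
    recomb_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ConfigurationError("n_f2 must be >= 1")
        if self.bulk_size < 1:
            raise ConfigurationError("bulk_size must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if not (0.0 <= self.base_error < 0.5):
            raise ConfigurationError("base_error must be in [0, 0.5)")
        if self.recomb_rate < 0:
            raise ConfigurationError("recomb_rate must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def default_layout(
    n_chromosomes: int = 11,
    chrom_length: int = 10_000_000,
    n_snps: int = 2000,
    causal_chrom_index: int = 5,
    causal_target_bp: int = 2_366_479,
    layout_seed: int = 97103,
) -> GenomeLayout:
    """Desk-scale stand-in for the 11-chromosome watermelon genome.

    Eleven 10 Mb chromosomes with ~2000 SNPs genome-wide (uniformly placed,
    fixed layout seed so the layout itself is a constant of the package).
    The causal sterility locus sits on the sixth chromosome at the SNP
    nearest ``causal_target_bp``, echoing the candidate gene's position at
    ~2.37 Mb on chromosome 6 of the real assembly.
    """
    rng = np.random.default_rng(layout_seed)
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    chroms = tuple((f"chr{i + 1:02d}", chrom_length) for i in range(n_chromosomes))
    positions = {}
    for (name, length), k in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        positions[name] = pos.astype(np.int64)
    causal_chrom = chroms[causal_chrom_index][0]
    cpos = positions[causal_chrom]
    causal_pos = int(cpos[np.argmin(np.abs(cpos - causal_target_bp))])
    return GenomeLayout(chroms, positions, (causal_chrom, causal_pos))


@dataclass
class Population:
    """Simulated F2 plants: genotype = copies of the sterile-parent allele."""

    layout: GenomeLayout
    genotypes: np.ndarray  # (n_f2, n_snps) int8, values 0/1/2
    phenotypes: np.ndarray  # (n_f2,) of {"sterile", "fertile"}

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class Bulks:
    sterile_idx: np.ndarray
    fertile_idx: np.ndarray


@dataclass
class SimResult:
    """One complete simulated experiment, ready for the association scan."""

    layout: GenomeLayout
    config: SimConfig
    population: Population
    bulks: Bulks
    true_freq_sterile: np.ndarray
    true_freq_fertile: np.ndarray
    sites: pd.DataFrame  # chrom,pos,ref,alt + parent GTs + pool allele depths


def _gametes(layout: GenomeLayout, recomb_rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n haploid gametes over all SNPs; 1 = sterile-parent haplotype segment.

    Each gamete is a crossover mosaic of the two parental haplotypes: per
    chromosome the crossover count is Poisson(recomb_rate), breakpoints are
    uniform, and the starting parental phase is a fair coin.
    """
    out = np.empty((n, layout.n_snps), dtype=np.int8)
    offset = 0
    for chrom, length in layout.chromosomes:
        pos = np.asarray(layout.snp_positions[chrom])
        k = pos.size
        if k == 0:
            continue
        n_xo = rng.poisson(recomb_rate, size=n)
        starts = rng.integers(0, 2, size=n)
        for i in range(n):
            if n_xo[i] == 0:
                out[i, offset : offset + k] = starts[i]
            else:
                xo = np.sort(rng.uniform(0, length, size=n_xo[i]))
                crossings = np.searchsorted(xo, pos)
                out[i, offset : offset + k] = (starts[i] + crossings) % 2
        offset += k
    return out


def simulate_f2_population(layout: GenomeLayout, config: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Simulate n_f2 plants from a selfed F1: genotype = sum of two gametes.

    The sterility phenotype is fully penetrant recessive: a plant is sterile
    iff it carries two sterile-parent alleles at the causal locus. For a null
    layout (no causal locus) phenotypes are Bernoulli(1/4) sterile,
    independent of genotype.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = _gametes(layout, config.recomb_rate, 2 * config.n_f2, rng)
    genotypes = (g[: config.n_f2] + g[config.n_f2 :]).astype(np.int8)
    ci = layout.causal_index()
    if ci is None:
        sterile = rng.random(config.n_f2) < 0.25
    else:
        sterile = genotypes[:, ci] == 2
    phenotypes = np.where(sterile, STERILE, FERTILE)
    return Population(layout, genotypes, phenotypes)


def form_bulks(population: Population, bulk_size: int, rng: np.random.Generator | int | None = None) -> Bulks:
    """Draw disjoint random bulks of ``bulk_size`` plants per phenotype class."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bulks = {}
    for label in (STERILE, FERTILE):
        idx = np.flatnonzero(population.phenotypes == label)
        if idx.size < bulk_size:
            raise ValueError(
                f"cannot form {label} bulk: {idx.size} {label} plants < bulk size {bulk_size}"
            )
        bulks[label] = rng.choice(idx, size=bulk_size, replace=False)
    return Bulks(bulks[STERILE], bulks[FERTILE])


def bulk_allele_freq(population: Population, member_idx: np.ndarray) -> np.ndarray:
    """Per-site sterile-parent allele frequency in the pooled bulk DNA."""
    return population.genotypes[member_idx].mean(axis=0) / 2.0


def simulate_pool_depths(
    true_freq: np.ndarray,
    mean_depth: float,
    base_error: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence a pool: per-site (ref_depth, alt_depth) counts.

    ``alt`` is the sterile-parent allele. Total depth is Poisson(mean_depth);
    each read carries alt with probability f(1-e) + (1-f)e where f is the
    pool's true frequency and e the per-read flip probability.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    f = np.asarray(true_freq, dtype=float)
    total = rng.poisson(mean_depth, size=f.shape)
    p = f * (1.0 - base_error) + (1.0 - f) * base_error
    alt = rng.binomial(total, p)
    return total - alt, alt


def _site_frame(
    layout: GenomeLayout,
    depth_sterile: tuple[np.ndarray, np.ndarray],
    depth_fertile: tuple[np.ndarray, np.ndarray],
    parent_depth: float,
    base_error: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assemble the four-sample variant table; alleles drawn at random.

    By construction REF is the fertile-parent allele and ALT the
    sterile-parent allele; downstream code never relies on that and instead
    orients each site from the parent genotype calls.
    """
    sites = layout.site_table()
    m = len(sites)
    ref = _BASES[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)  # ensures alt != ref
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    ps_ref, ps_alt = simulate_pool_depths(np.ones(m), parent_depth, base_error, rng)
    pf_ref, pf_alt = simulate_pool_depths(np.zeros(m), parent_depth, base_error, rng)
    sites = sites.assign(
        ref=ref,
        alt=alt,
        n_alt_alleles=1,
        gt_parent_sterile="1/1",
        gt_parent_fertile="0/0",
        ad_ref_parent_sterile=ps_ref,
        ad_alt_parent_sterile=ps_alt,
        ad_ref_parent_fertile=pf_ref,
        ad_alt_parent_fertile=pf_alt,
        ad_ref_bulk_sterile=depth_sterile[0],
        ad_alt_bulk_sterile=depth_sterile[1],
        ad_ref_bulk_fertile=depth_fertile[0],
        ad_alt_bulk_fertile=depth_fertile[1],
    )
    return sites


def simulate_case(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
) -> SimResult:
    """Run one full experiment: cross, bulking, pooled sequencing.

    The single entry point used by the analysis drivers and the acceptance
    checks. All randomness flows from one generator seeded by ``seed``
    (falling back to ``config.seed``), so equal seeds give identical results.

    Resampling rule: if either phenotype class has fewer than ``bulk_size``
    plants (a ~1/4 sterile rate leaves this possible at small n_f2), further
    plants are grown in batches of n_f2/4 until both bulks are attainable —
    what an experimenter does when the field is short of one class.
    """
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    population = simulate_f2_population(layout, config, rng)
    batch = max(config.n_f2 // 4, 8)
    while min(
        int((population.phenotypes == STERILE).sum()),
        int((population.phenotypes == FERTILE).sum()),
    ) < config.bulk_size:
        extra_cfg = SimConfig(
            n_f2=batch, bulk_size=config.bulk_size, mean_depth=config.mean_depth,
            base_error=config.base_error, recomb_rate=config.recomb_rate,
        )
        extra = simulate_f2_population(layout, extra_cfg, rng)
        population = Population(
            layout,
            np.vstack([population.genotypes, extra.genotypes]),
            np.concatenate([population.phenotypes, extra.phenotypes]),
        )
    bulks = form_bulks(population, config.bulk_size, rng)
    f_s = bulk_allele_freq(population, bulks.sterile_idx)
    f_f = bulk_allele_freq(population, bulks.fertile_idx)
    d_s = simulate_pool_depths(f_s, config.mean_depth, config.base_error, rng)
    d_f = simulate_pool_depths(f_f, config.mean_depth, config.base_error, rng)
    sites = _site_frame(layout, d_s, d_f, config.mean_depth, config.base_error, rng)
    return SimResult(layout, config, population, bulks, f_s, f_f, sites)


def write_simulation(result: SimResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.vcf`` (four samples, GT + AD) and ``<prefix>.truth.tsv``.

    The truth sidecar (chrom, pos, true_freq_sterile, true_freq_fertile,
    is_causal) is consumed only by tests, never by the pipeline.
    """
    from . import io_formats  # local import: io layer depends on nothing here

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = prefix.with_suffix(".vcf")
    io_formats.write_vcf(result.sites, result.layout.chromosomes, vcf_path)

    truth_path = Path(str(prefix) + ".truth.tsv")
    causal = result.layout.causal_locus
    truth = result.sites[["chrom", "pos"]].copy()
    truth["true_freq_sterile"] = result.true_freq_sterile
    truth["true_freq_fertile"] = result.true_freq_fertile
    truth["is_causal"] = [
        int(causal is not None and (c, p) == causal)
        for c, p in zip(truth["chrom"], truth["pos"])
    ]
    truth.to_csv(truth_path, sep="\t", index=False)
    return vcf_path, truth_path
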