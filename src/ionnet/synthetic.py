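"""Synthetic stratified genotype-phenotype populations.

Generates country-structured variant-count tables, a gene-pathway map,
multi-task phenotypes with controllable genetic / country / noise
variance fractions, replicate measurements and country-clustered GPS
coordinates — everything the pipeline consumes, with no downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import N_TYPES, VARIANT_TYPES, AnnotatedVariantTable
from .evaluation import PhenotypeTable, default_task_names
from .networks import PathwayMap

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_population",
    "generate_simpson_dataset",
    "make_pretraining_labels",
]


@dataclass
class SyntheticConfig:
    """Knobs for :func:`generate_population`.

    ``heritable_frac`` (h) and ``country_frac`` (c) are the phenotype
    variance fractions of the genetic and country components; the
    remainder ``1 - h - c`` is i.i.d. noise. ``stratification`` scales
    per-(country, gene) Poisson rate shifts, so larger values make the
    genome more country-predictable.
    """

    n_samples: int = 500
    n_countries: int = 5
    country_weights: tuple[float, ...] | None = None
    gps_jitter: float = 1.0  # degrees around each country centroid
    n_genes: int = 200
    type_intensities: tuple[float, ...] | None = None  # 17 Poisson rates
    stratification: float = 0.5
    n_causal: int = 20
    causal_per_task: int = 8
    heritable_frac: float = 0.5
    country_frac: float = 0.3
    n_replicates: int = 6
    replicate_noise_sd: float = 0.3
    n_tasks: int = 36
    unannotated_frac: float = 0.28
    n_real_pathways: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.heritable_frac and 0 <= self.country_frac):
            raise ValueError("variance fractions must be non-negative")
        if self.heritable_frac + self.country_frac > 1 + 1e-12:
            raise ValueError("heritable_frac + country_frac must be <= 1")
        if self.replicate_noise_sd < 0 or self.gps_jitter < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_causal > self.n_genes:
            raise ValueError("causal gene pool larger than gene universe")
        if self.causal_per_task > self.n_causal:
            raise ValueError("causal_per_task exceeds the causal pool")
        if self.country_weights is not None and len(self.country_weights) != self.n_countries:
            raise ValueError("country_weights length must equal n_countries")


@dataclass
class SyntheticDataset:
    """Everything one generated population provides, plus ground truth."""

    config: SyntheticConfig
    variant_table: AnnotatedVariantTable
    counts: np.ndarray  # (N, G, 17) ground-truth raw counts
    phenotypes: PhenotypeTable
    pathway_map: PathwayMap
    components: dict[str, np.ndarray]  # genetic / country / noise, each (N, T)
    causal_genes: dict[int, tuple[str, ...]]  # task index -> gene ids

    def write(self, directory: str | Path) -> None:
        """Emit the plain-text file formats the pipeline consumes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.variant_table.to_tsv(directory / "variants.tsv")
        self.phenotypes.to_csv(directory / "phenotypes.csv")
        if self.phenotypes.replicates is not None:
            self.phenotypes.replicates_to_csv(directory / "replicates.csv")
        self.pathway_map.to_tsv(directory / "pathways.tsv")
        with open(directory / "manifest.json", "w") as fh:
            json.dump({"config": asdict(self.config)}, fh, indent=2)


def _default_intensities() -> np.ndarray:
    # common region types (intronic/intergenic/up/downstream) dominate
    base = np.full(N_TYPES, 0.02)
    for label, rate in {
        "intronic": 0.35,
        "intergenic": 0.30,
        "upstream": 0.20,
        "downstream": 0.20,
        "UTR3": 0.10,
        "UTR5": 0.08,
        "nonsynonymous": 0.15,
    }.items():
        base[VARIANT_TYPES.index(label)] = rate
    return base


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    std = a.std(axis=axis, keepdims=True)
    return (a - mean) / np.where(std > 0, std, 1.0)


def _counts_to_table(
    counts: np.ndarray, sample_ids, gene_ids
) -> AnnotatedVariantTable:
    s_idx, g_idx, t_idx = np.nonzero(counts)
    reps = counts[s_idx, g_idx, t_idx].astype(int)
    samples = np.repeat(np.asarray(sample_ids, dtype=object)[s_idx], reps)
    genes = np.repeat(np.asarray(gene_ids, dtype=object)[g_idx], reps)
    types = np.repeat(np.asarray(VARIANT_TYPES, dtype=object)[t_idx], reps)
    records = pd.DataFrame({"sample": samples, "gene": genes, "variant_type": types})
    return AnnotatedVariantTable(records, tuple(sample_ids), tuple(gene_ids))


def generate_population(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one stratified population.

    Counts come from Poisson laws with per-(country, gene) rate shifts;
    each task's phenotype mixes a standardized causal-gene signal, a
    per-(country, task) offset and i.i.d. noise in the configured
    variance fractions; replicate measurements add observation noise on
    top.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g, c = cfg.n_samples, cfg.n_genes, cfg.n_countries

    sample_ids = tuple(f"s{i:04d}" for i in range(n))
    gene_ids = tuple(f"gene{i:04d}" for i in range(g))
    country_names = np.array([f"country{c_i}" for c_i in range(c)])
    weights = (
        np.full(c, 1.0 / c)
        if cfg.country_weights is None
        else np.asarray(cfg.country_weights, float) / np.sum(cfg.country_weights)
    )
    country_idx = rng.choice(c, size=n, p=weights)

    # GPS: centroids on a coarse grid, jittered per sample
    cent_lat = 35.0 + 6.0 * np.arange(c) % 50
    cent_lon = -10.0 + 11.0 * np.arange(c) % 170
    lat = np.clip(cent_lat[country_idx] + rng.normal(0, cfg.gps_jitter, n), -90, 90)
    lon = np.clip(cent_lon[country_idx] + rng.normal(0, cfg.gps_jitter, n), -180, 180)

    intensities = (
        _default_intensities()
        if cfg.type_intensities is None
        else np.asarray(cfg.type_intensities, float)
    )
    if intensities.shape != (N_TYPES,):
        raise ValueError(f"type_intensities must have length {N_TYPES}")
    gene_scale = rng.uniform(0.5, 1.5, size=g)
    base_rate = gene_scale[:, None] * intensities[None, :]  # (G, 17)
    s = cfg.stratification
    shift = rng.standard_normal((c, g))
    rate = base_rate[None] * np.exp(s * shift - 0.5 * s * s)[:, :, None]  # (C, G, 17)
    counts = rng.poisson(rate[country_idx])  # (N, G, 17)

    # gene mutational loads, standardized across samples
    loads = _zscore(counts.sum(axis=2).astype(float))

    causal_pool = rng.choice(g, size=cfg.n_causal, replace=False)
    task_names = default_task_names(cfg.n_tasks)
    genetic = np.empty((n, cfg.n_tasks))
    causal_genes: dict[int, tuple[str, ...]] = {}
    for t in range(cfg.n_tasks):
        picks = rng.choice(causal_pool, size=cfg.causal_per_task, replace=False)
        effects = rng.standard_normal(cfg.causal_per_task)
        genetic[:, t] = loads[:, picks] @ effects
        causal_genes[t] = tuple(gene_ids[i] for i in picks)
    genetic = _zscore(genetic)

    country_effect = rng.standard_normal((c, cfg.n_tasks))
    country_comp = _zscore(country_effect[country_idx])
    noise = _zscore(rng.standard_normal((n, cfg.n_tasks)))

    h, cf = cfg.heritable_frac, cfg.country_frac
    phen = (
        np.sqrt(h) * genetic
        + np.sqrt(cf) * country_comp
        + np.sqrt(max(1.0 - h - cf, 0.0)) * noise
    )

    replicates = None
    values = phen
    if cfg.n_replicates > 0:
        replicates = phen[:, :, None] + rng.normal(
            0.0, cfg.replicate_noise_sd, size=(n, cfg.n_tasks, cfg.n_replicates)
        )
        values = replicates.mean(axis=2)

    phenotypes = PhenotypeTable(
        sample_ids=sample_ids,
        values=values,
        task_names=task_names,
        countries=country_names[country_idx],
        lat=lat,
        lon=lon,
        replicates=replicates,
    )

    # pathway map: causal genes concentrated in a few pathways
    pathway_ids = tuple(f"bin{p:03d}" for p in range(cfg.n_real_pathways))
    assignments: dict[str, tuple[str, ...]] = {}
    n_causal_bins = max(1, cfg.n_real_pathways // 4)
    for j, gi in enumerate(np.sort(causal_pool)):
        assignments[gene_ids[gi]] = (pathway_ids[j % n_causal_bins],)
    causal_set = set(causal_pool.tolist())
    for gi in range(g):
        if gi in causal_set:
            continue
        if rng.random() < cfg.unannotated_frac:
            continue  # unannotated -> dummy node at mask build time
        assignments[gene_ids[gi]] = (pathway_ids[int(rng.integers(cfg.n_real_pathways))],)
    pmap = PathwayMap(assignments, pathway_ids)

    table = _counts_to_table(counts, sample_ids, gene_ids)
    return SyntheticDataset(
        config=cfg,
        variant_table=table,
        counts=counts,
        phenotypes=phenotypes,
        pathway_map=pmap,
        components={"genetic": genetic, "country": country_comp, "noise": noise},
        causal_genes=causal_genes,
    )


def make_pretraining_labels(
    counts: np.ndarray,
    countries: np.ndarray,
    n_tasks: int = 288,
    heritable_frac: float = 0.5,
    country_frac: float = 0.3,
    n_causal_per_task: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Auxiliary multi-task labels for pretraining, from the same genomes.

    Mirrors the phenotype mixture of :func:`generate_population` but
    with independent causal weights per task, so the pretraining task
    family shares genetic structure with the target tasks without being
    identical.
    """
    rng = np.random.default_rng(seed)
    n, g = counts.shape[0], counts.shape[1]
    loads = _zscore(counts.sum(axis=2).astype(float))
    uniq, inv = np.unique(np.asarray(countries), return_inverse=True)
    labels = np.empty((n, n_tasks))
    country_effect = rng.standard_normal((len(uniq), n_tasks))
    for t in range(n_tasks):
        picks = rng.choice(g, size=min(n_causal_per_task, g), replace=False)
        genetic = _zscore((loads[:, picks] @ rng.standard_normal(len(picks)))[:, None])[:, 0]
        cc = _zscore(country_effect[inv, t][:, None])[:, 0]
        eps = rng.standard_normal(n)
        eps = (eps - eps.mean()) / max(eps.std(), 1e-12)
        labels[:, t] = (
            np.sqrt(heritable_frac) * genetic
            + np.sqrt(country_frac) * cc
            + np.sqrt(max(1 - heritable_frac - country_frac, 0)) * eps
        )
    return labels


def generate_simpson_dataset(
    n_groups: int = 5,
    between_slope: float = 1.0,
    within_signal: float = 0.0,
    n_per_group: int = 200,
    group_spread: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, PhenotypeTable]:
    """Two-level dataset exhibiting Simpson's paradox by construction.

    Group feature means lie on a line; the phenotype follows that line
    with slope ``between_slope`` plus ``within_signal`` times the
    within-group feature deviation plus noise. With ``within_signal=0``
    the within-group phenotype is pure noise while the pooled
    correlation is driven entirely by the group means.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    centers = (
        np.linspace(-1.0, 1.0, n_groups) * group_spread
        if n_groups > 1
        else np.zeros(1)
    )
    n = n_groups * n_per_group
    group_idx = np.repeat(np.arange(n_groups), n_per_group)
    delta = rng.standard_normal(n)
    x = centers[group_idx] + delta
    y = (
        between_slope * centers[group_idx]
        + within_signal * delta
        + noise_sd * rng.standard_normal(n)
    )
    table = PhenotypeTable(
        sample_ids=tuple(f"s{i:05d}" for i in range(n)),
        values=y[:, None],
        task_names=("trait",),
        countries=np.array([f"group{g}" for g in group_idx]),
    )
    return x[:, None], table
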