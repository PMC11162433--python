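"""Gene-centric encoding of annotated variant tables.

Each genome is summarised as a ``samples x genes x 17`` tensor of
variant-type counts per gene ("mutational damage" histograms), with
optional carrier-frequency MAF filtering and three normalisation
dialects: none, global per-feature z-scoring, and per-gene frequency
normalisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_TYPES",
    "VARIANT_TYPE_INDEX",
    "AnnotatedVariantTable",
    "GeneMutationTensor",
    "MafFilterConfig",
    "GlobalZTransform",
    "encode_variants",
    "maf_filter",
    "standardize",
    "read_variant_table",
]

#: The 17 recognised variant-type labels, in canonical index order.
VARIANT_TYPES: tuple[str, ...] = (
    "nonsynonymous",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "stoploss",
    "frameshift_insertion",
    "frameshift_deletion",
    "UTR3",
    "UTR5",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
    "intronic",
    "splicing",
    "ncRNA_splicing",
    "stopgain",
)

VARIANT_TYPE_INDEX: dict[str, int] = {t: i for i, t in enumerate(VARIANT_TYPES)}

N_TYPES = len(VARIANT_TYPES)


@dataclass(frozen=True)
class MafFilterConfig:
    """Carrier-frequency based minor-allele-frequency filter.

    ``threshold`` is a fraction in [0, 0.5]; variants whose folded carrier
    frequency ``min(f, 1 - f)`` is <= threshold are removed.
    """

    threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 0.5:
            raise ValueError(
                f"MAF threshold must be in [0, 0.5], got {self.threshold}"
            )


@dataclass
class AnnotatedVariantTable:
    """Long-format table of (sample, gene, variant_type) records.

    One row per carried variant occurrence; multiplicities are expressed
    by repeated rows. ``sample_ids`` and ``gene_ids`` fix the universes
    (and hence tensor axes) even for samples/genes with no records.
    """

    records: pd.DataFrame
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    REQUIRED_COLUMNS = ("sample", "gene", "variant_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"variant table is missing columns: {missing}")
        if len(self.gene_ids) == 0:
            raise ValueError("gene universe is empty")
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.gene_ids = tuple(str(g) for g in self.gene_ids)

        bad_types = set(self.records["variant_type"]) - set(VARIANT_TYPES)
        if bad_types:
            raise ValueError(f"unknown variant-type label(s): {sorted(bad_types)}")
        bad_genes = set(self.records["gene"].astype(str)) - set(self.gene_ids)
        if bad_genes:
            raise ValueError(f"unknown gene id(s): {sorted(bad_genes)[:10]}")
        bad_samples = set(self.records["sample"].astype(str)) - set(self.sample_ids)
        if bad_samples:
            raise ValueError(f"unknown sample id(s): {sorted(bad_samples)[:10]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_variant_table(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> AnnotatedVariantTable:
    """Read an annotated-variant table from TSV.

    Two dialects are accepted:

    * long format with columns ``sample``, ``gene``, ``variant_type``;
    * wide (multianno-style) format with columns ``gene``,
      ``variant_type`` plus one 0/1 presence column per sample.

    If the universes are not given they default to the ids observed in
    the file (sorted for determinism).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" in df.columns:
        long = df[["sample", "gene", "variant_type"]].copy()
    else:
        if not {"gene", "variant_type"} <= set(df.columns):
            raise ValueError("variant table needs 'gene' and 'variant_type' columns")
        value_cols = [c for c in df.columns if c not in ("gene", "variant_type")]
        melted = df.melt(
            id_vars=["gene", "variant_type"],
            value_vars=value_cols,
            var_name="sample",
            value_name="present",
        )
        melted["present"] = melted["present"].astype(int)
        melted = melted.loc[melted["present"] > 0]
        long = melted.loc[
            melted.index.repeat(melted["present"])
        ][["sample", "gene", "variant_type"]].reset_index(drop=True)
        if sample_ids is None:
            sample_ids = value_cols
    if sample_ids is None:
        sample_ids = sorted(long["sample"].unique())
    if gene_ids is None:
        gene_ids = sorted(long["gene"].unique())
    return AnnotatedVariantTable(long, tuple(sample_ids), tuple(gene_ids))


@dataclass(frozen=True)
class GlobalZTransform:
    """Per-feature affine map fitted on a sample subset.

    Features with zero variance on the fit subset get scale 0, so they
    are mapped to a constant 0 rather than dividing by zero.
    """

    mean: np.ndarray  # (G, 17)
    scale: np.ndarray  # (G, 17); 0 where the fitted std was 0

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) * self.scale


@dataclass
class GeneMutationTensor:
    """``samples x genes x 17`` variant-type count tensor.

    ``state`` tracks normalisation: ``raw`` (non-negative integer
    counts), ``global-z`` or ``per-gene-frequency``. A fitted
    :class:`GlobalZTransform` is kept on ``transform`` so the same affine
    map can be re-applied to held-out samples.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    state: str = "raw"
    transform: GlobalZTransform | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expected = (len(self.sample_ids), len(self.gene_ids), N_TYPES)
        if self.values.shape != expected:
            raise ValueError(
                f"tensor shape {self.values.shape} != expected {expected}"
            )
        if self.state == "raw":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("raw tensor must contain non-negative integers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def export_matrix(self) -> np.ndarray:
        """Per-sample ``17 x G`` presentation transpose of the tensor."""
        return np.transpose(self.values, (0, 2, 1))

    # -- persistence: raw .npy payload + JSON sidecar --------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(str(prefix) + ".npy", self.values)
        sidecar = {
            "sample_ids": list(self.sample_ids),
            "gene_ids": list(self.gene_ids),
            "variant_types": list(VARIANT_TYPES),
            "state": self.state,
        }
        if self.transform is not None:
            sidecar["transform"] = {
                "mean": self.transform.mean.tolist(),
                "scale": self.transform.scale.tolist(),
            }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, prefix: str | Path) -> "GeneMutationTensor":
        values = np.load(str(prefix) + ".npy")
        with open(str(prefix) + ".json") as fh:
            sidecar = json.load(fh)
        transform = None
        if "transform" in sidecar:
            transform = GlobalZTransform(
                mean=np.asarray(sidecar["transform"]["mean"]),
                scale=np.asarray(sidecar["transform"]["scale"]),
            )
        return cls(
            values=values,
            sample_ids=tuple(sidecar["sample_ids"]),
            gene_ids=tuple(sidecar["gene_ids"]),
            state=sidecar["state"],
            transform=transform,
        )


def encode_variants(table: AnnotatedVariantTable) -> GeneMutationTensor:
    """Count variant occurrences into a raw gene-centric tensor.

    ``result[s, g, t]`` is the number of records of type ``t`` on gene
    ``g`` carried by sample ``s``; invariant under record order.
    """
    values = np.zeros((table.n_samples, table.n_genes, N_TYPES), dtype=np.int64)
    if len(table.records):
        s_idx = pd.Categorical(
            table.records["sample"].astype(str), categories=table.sample_ids
        ).codes
        g_idx = pd.Categorical(
            table.records["gene"].astype(str), categories=table.gene_ids
        ).codes
        t_idx = table.records["variant_type"].map(VARIANT_TYPE_INDEX).to_numpy()
        np.add.at(values, (s_idx, g_idx, t_idx), 1)
    return GeneMutationTensor(values, table.sample_ids, table.gene_ids, state="raw")


def maf_filter(
    table: AnnotatedVariantTable, cfg: MafFilterConfig
) -> AnnotatedVariantTable:
    """Remove common-variant records by folded carrier frequency.

    A "variant" is a (gene, variant_type) pair; its carrier frequency is
    the fraction of samples carrying at least one occurrence, folded to
    the minor side ``min(f, 1 - f)``. Pairs with folded frequency <=
    ``cfg.threshold`` are dropped.
    """
    if table.n_samples < 1:
        raise ValueError("MAF filtering needs at least one sample")
    if len(table.records) == 0:
        return replace(table, records=table.records.copy())
    carriers = (
        table.records.drop_duplicates(["sample", "gene", "variant_type"])
        .groupby(["gene", "variant_type"], sort=False)
        .size()
    )
    freq = carriers / table.n_samples
    folded = np.minimum(freq, 1.0 - freq)
    removed = set(folded.index[folded <= cfg.threshold])
    keys = list(zip(table.records["gene"], table.records["variant_type"]))
    keep = np.array([k not in removed for k in keys])
    return replace(table, records=table.records.loc[keep].reset_index(drop=True))


def standardize(
    tensor: GeneMutationTensor,
    mode: str,
    fit_on: Sequence[str] | None = None,
    transform: GlobalZTransform | None = None,
) -> GeneMutationTensor:
    """Normalise a raw tensor.

    Parameters
    ----------
    mode:
        ``"none"`` (identity), ``"global-z"`` (per (gene, type) feature
        z-score) or ``"per-gene-frequency"`` (each (sample, gene)
        17-vector divided by its own sum; all-zero rows stay all-zero).
    fit_on:
        Sample ids used to fit the global-z moments; defaults to all
        samples. Fitting on the training split only avoids leakage; pass
        all samples to reproduce whole-dataset fitting.
    transform:
        A previously fitted :class:`GlobalZTransform` to re-apply
        (mutually exclusive with ``fit_on``).
    """
    if tensor.state != "raw":
        raise ValueError(
            f"tensor already standardized (state={tensor.state!r}); refusing to re-standardize"
        )
    if mode == "none":
        return replace(tensor)
    if mode == "per-gene-frequency":
        totals = tensor.values.sum(axis=2, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(totals > 0, tensor.values / totals, 0.0)
        return GeneMutationTensor(
            values, tensor.sample_ids, tensor.gene_ids, state="per-gene-frequency"
        )
    if mode == "global-z":
        if transform is None:
            idx = (
                np.arange(tensor.n_samples)
                if fit_on is None
                else tensor.sample_index(fit_on)
            )
            fit_values = tensor.values[idx].astype(float)
            mean = fit_values.mean(axis=0)
            std = fit_values.std(axis=0)
            scale = np.where(std > 0, 1.0 / np.where(std > 0, std, 1.0), 0.0)
            transform = GlobalZTransform(mean=mean, scale=scale)
        values = transform.apply(tensor.values.astype(float))
        return GeneMutationTensor(
            values,
            tensor.sample_ids,
            tensor.gene_ids,
            state="global-z",
            transform=transform,
        )
    raise ValueError(f"unknown standardization mode: {mode!r}")
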