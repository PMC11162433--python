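"""Architecture family: gene compressor, dense / knowledge-sparsified
trunks, transfer-learning head and the GPS-only baseline.

Parameter accounting is part of the contract: the sparsified trunk has
exactly ``E + 1 + P_real * H`` trainable weights (one weight per
gene-pathway edge, one shared pathway offset, and an offset-free dense
map from the real pathway nodes to the hidden layer — the dummy node
does not feed the hidden layer). The head has
``d_in*H + H + 2H + H*T + T`` parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import (
    Dense,
    GeneScorer,
    LayerNorm,
    MaskedDense,
    SequentialNet,
    SliceColumns,
    Tanh,
    count_parameters,
)

__all__ = [
    "PathwayMap",
    "SparsityMask",
    "ArchitectureSpec",
    "IModuleSpec",
    "build_mask",
    "build_g_module",
    "build_dense_trunk",
    "build_bmsnn_trunk",
    "build_i_head",
    "build_model",
    "gps_features",
    "count_parameters",
]

DUMMY_PATHWAY = "__dummy__"


@dataclass
class PathwayMap:
    """Bipartite gene -> pathway annotation.

    ``assignments`` maps a gene id to its pathways in listed order;
    genes absent from the map are unannotated and will be wired to the
    dummy node when a mask is built.
    """

    assignments: dict[str, tuple[str, ...]]
    pathways: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.pathways)
        for gene, ps in self.assignments.items():
            bad = set(ps) - known
            if bad:
                raise ValueError(f"gene {gene} references unknown pathway(s) {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        """Two-column TSV (gene, pathway); repeated rows express
        multi-membership, row order fixes the per-gene listing order."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pathway"], dtype=str)
        assignments: dict[str, list[str]] = {}
        pathways: list[str] = []
        seen = set()
        for gene, pathway in zip(df["gene"], df["pathway"]):
            assignments.setdefault(gene, [])
            if pathway not in assignments[gene]:
                assignments[gene].append(pathway)
            if pathway not in seen:
                seen.add(pathway)
                pathways.append(pathway)
        return cls(
            {g: tuple(ps) for g, ps in assignments.items()}, tuple(sorted(pathways))
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, p) for g, ps in self.assignments.items() for p in ps
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SparsityMask:
    """Binary gene x (pathways + dummy) connectivity matrix.

    The last column is the dummy node absorbing unannotated genes; every
    gene row has at least one edge.
    """

    matrix: np.ndarray  # bool, (G, P_real + 1)
    gene_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]  # real pathways only
    rule: str = "primary"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        g, p = self.matrix.shape
        if g != len(self.gene_ids) or p != len(self.pathway_ids) + 1:
            raise ValueError("mask shape inconsistent with gene/pathway universes")
        if not self.matrix.any(axis=1).all():
            orphan = [g for g, row in zip(self.gene_ids, self.matrix) if not row.any()]
            raise ValueError(f"gene(s) with no edge: {orphan[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_real_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    def to_table(self) -> pd.DataFrame:
        """Sparse triplet export (gene, pathway, 1)."""
        rows, cols = np.nonzero(self.matrix)
        names = list(self.pathway_ids) + [DUMMY_PATHWAY]
        return pd.DataFrame(
            {
                "gene": [self.gene_ids[r] for r in rows],
                "pathway": [names[c] for c in cols],
                "edge": 1,
            }
        )


def build_mask(
    pmap: PathwayMap, genes: tuple[str, ...] | list[str], rule: str = "primary"
) -> SparsityMask:
    """Induce the connectivity mask from a pathway map.

    ``primary``: exactly one edge per gene — its first listed pathway
    (unannotated genes go to the dummy node), so the edge count equals
    the gene count. ``all-edges``: one edge per (gene, pathway)
    association, dummy edges only for unannotated genes.
    """
    genes = tuple(genes)
    if not genes:
        raise ValueError("gene universe is empty")
    if rule not in ("primary", "all-edges"):
        raise ValueError(f"unknown mask rule {rule!r}")
    p_index = {p: i for i, p in enumerate(pmap.pathways)}
    n_real = len(pmap.pathways)
    matrix = np.zeros((len(genes), n_real + 1), dtype=bool)
    for gi, gene in enumerate(genes):
        listed = pmap.assignments.get(gene, ())
        if not listed:
            matrix[gi, n_real] = True  # dummy
        elif rule == "primary":
            matrix[gi, p_index[listed[0]]] = True
        else:
            for p in listed:
                matrix[gi, p_index[p]] = True
    return SparsityMask(matrix, genes, pmap.pathways, rule=rule)


@dataclass
class IModuleSpec:
    """Task head: dense -> affine layer-norm -> tanh -> dense output."""

    d_in: int
    hidden: int
    n_tasks: int = 36

    def __post_init__(self) -> None:
        if min(self.d_in, self.hidden, self.n_tasks) <= 0:
            raise ValueError("all head sizes must be positive")

    @property
    def expected_parameters(self) -> int:
        h, t = self.hidden, self.n_tasks
        return self.d_in * h + h + 2 * h + h * t + t


@dataclass
class ArchitectureSpec:
    """Declarative description of one model variant.

    ``variant`` is one of ``dense`` (fully-connected trunk),
    ``masked`` (knowledge-sparsified trunk), ``frozen-head``,
    ``fine-tune`` (both ride on a pretrained dense model) or ``gps``
    (coordinates-only baseline).
    """

    variant: str
    n_genes: int = 0
    n_types: int = 17
    gene_hidden: int = 8
    latent: int = 50  # gene-trunk latent width (reverse-derived default)
    n_real_pathways: int | None = None
    hidden: int | None = None
    n_tasks: int = 36
    l2: float = 1e-6
    head_hidden: int = 500  # for frozen-head / gps variants

    KNOWN = ("dense", "masked", "frozen-head", "fine-tune", "gps")

    def __post_init__(self) -> None:
        if self.variant not in self.KNOWN:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("n_types", "gene_hidden", "latent", "n_tasks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variant in ("dense", "masked", "frozen-head", "fine-tune"):
            if self.n_genes <= 0:
                raise ValueError("n_genes must be positive for gene-based variants")
        if self.variant == "masked":
            if not self.hidden or self.hidden <= 0:
                raise ValueError("masked variant requires a positive hidden size")


def build_g_module(spec: ArchitectureSpec, rng: np.random.Generator) -> GeneScorer:
    """Shared per-gene compressor: 17-vector -> scalar mutational load."""
    return GeneScorer(spec.n_types, spec.gene_hidden, rng)


def build_dense_trunk(spec: ArchitectureSpec, rng: np.random.Generator) -> SequentialNet:
    """Fully-connected trunk: G gene scalars -> latent -> task head."""
    return SequentialNet(
        [
            Dense(spec.n_genes, spec.latent, rng, name="trunk.latent"),
            Tanh(),
            Dense(spec.latent, spec.n_tasks, rng, name="head.out"),
        ],
        latent_index=2,
        latent_dim=spec.latent,
    )


def build_bmsnn_trunk(
    spec: ArchitectureSpec, mask: SparsityMask, rng: np.random.Generator
) -> SequentialNet:
    """Knowledge-sparsified trunk: gene scalars -> pathway nodes -> hidden.

    Trainable weights: one per mask edge, one shared pathway offset, and
    an offset-free dense map from the real pathway nodes (dummy
    excluded) to the hidden layer — ``E + 1 + P_real * H`` in total.
    """
    if mask.n_genes != spec.n_genes:
        raise ValueError(
            f"mask covers {mask.n_genes} genes but spec declares {spec.n_genes}"
        )
    if spec.n_real_pathways is not None and mask.n_real_pathways != spec.n_real_pathways:
        raise ValueError("mask pathway count disagrees with spec")
    return SequentialNet(
        [
            MaskedDense(mask.matrix, rng, shared_bias=True, name="trunk.pathway"),
            Tanh(),
            SliceColumns(mask.n_real_pathways),
            Dense(mask.n_real_pathways, spec.hidden, rng, bias=False, name="trunk.hidden"),
        ],
        latent_dim=spec.hidden,
    )


def build_i_head(spec: IModuleSpec, rng: np.random.Generator | None = None) -> SequentialNet:
    """Trainable task head used for transfer learning and the GPS baseline."""
    rng = np.random.default_rng(0) if rng is None else rng
    return SequentialNet(
        [
            Dense(spec.d_in, spec.hidden, rng, name="head.fc"),
            LayerNorm(spec.hidden, name="head.ln"),
            Tanh(),
            Dense(spec.hidden, spec.n_tasks, rng, name="head.out"),
        ],
        latent_dim=spec.hidden,
    )


def build_model(
    spec: ArchitectureSpec,
    mask: SparsityMask | None = None,
    seed: int = 0,
) -> SequentialNet:
    """Assemble a full trainable model for one architecture variant.

    ``dense``/``fine-tune``: gene compressor -> dense trunk -> 36-task
    head (latent = trunk output). ``masked``: gene compressor ->
    sparsified trunk -> tanh -> head. ``gps``: the task head applied to
    the 3-dim unit-sphere coordinate features. ``frozen-head`` starts
    from a dense model; use :func:`ionnet.training.freeze_and_extend`.
    """
    rng = np.random.default_rng(seed)
    if spec.variant == "gps":
        net = build_i_head(IModuleSpec(3, spec.head_hidden, spec.n_tasks), rng)
        net.latent_index = 0
        net.latent_dim = 3
        net.input_kind = "gps"
        return net
    if spec.variant in ("dense", "frozen-head", "fine-tune"):
        g = build_g_module(spec, rng)
        trunk = build_dense_trunk(spec, rng)
        return SequentialNet(
            [g] + trunk.layers,
            latent_index=1 + trunk.latent_index,
            latent_dim=spec.latent,
            input_kind="tensor",
        )
    if spec.variant == "masked":
        if mask is None:
            raise ValueError("masked variant requires a sparsity mask")
        g = build_g_module(spec, rng)
        trunk = build_bmsnn_trunk(spec, mask, rng)
        head = Dense(spec.hidden, spec.n_tasks, rng, name="head.out")
        return SequentialNet(
            [g] + trunk.layers + [Tanh(), head],
            latent_index=1 + len(trunk.layers) + 1,
            latent_dim=spec.hidden,
            input_kind="tensor",
        )
    raise AssertionError(spec.variant)


def gps_features(lat, lon) -> np.ndarray:
    """Unit-sphere embedding of coordinates in degrees.

    Returns ``(sin lat, sin lon, cos lon)`` per sample, so the last two
    components always lie on the unit circle.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of range [-180, 180]")
    lat_r, lon_r = np.radians(lat), np.radians(lon)
    return np.stack([np.sin(lat_r), np.sin(lon_r), np.cos(lon_r)], axis=-1)
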