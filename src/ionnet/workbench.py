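"""Experiment orchestration: encode -> build -> cross-validate -> evaluate.

One declarative config drives a full run; a single master seed fans out
to deterministic per-component seeds so the whole pipeline is
reproducible from the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import (
    AnnotatedVariantTable,
    MafFilterConfig,
    encode_variants,
    maf_filter,
    read_variant_table,
    standardize,
)
from .evaluation import (
    CVPlan,
    EvaluationReport,
    PhenotypeTable,
    contextualize,
    global_pool_pearson,
    intra_country_pearson,
    make_cv_plan,
    pearson_upper_bound,
    simpson_diagnostic,
)
from .networks import ArchitectureSpec, IModuleSpec, build_mask, build_model, gps_features
from .nn import count_parameters
from .synthetic import SyntheticConfig, generate_population, make_pretraining_labels
from .training import (
    TrainConfig,
    fine_tune,
    freeze_and_extend,
    save_checkpoint,
    standardize_labels,
    train,
)

__all__ = ["ExperimentConfig", "run_experiment", "audit_plan", "component_seed", "AuditError"]

log = logging.getLogger("ionnet")


class AuditError(RuntimeError):
    """A cross-validation plan violates a leakage or stratification rule."""


def component_seed(master: int, name: str) -> int:
    """Deterministic per-component seed derived from one master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class ExperimentConfig:
    """Inputs, architecture and protocol for one experiment.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig`) or the
    file-path triple (``variants_path``, ``phenotypes_path``, optional
    ``pathways_path``/``replicates_path``) must be provided.
    """

    variant: str = "masked"  # dense | masked | frozen-head | fine-tune | gps
    synthetic: SyntheticConfig | None = None
    variants_path: str | None = None
    phenotypes_path: str | None = None
    replicates_path: str | None = None
    pathways_path: str | None = None
    cv_mode: str = "random-kfold"
    k: int = 5
    standardization: str = "global-z"  # none | global-z | per-gene-frequency
    paper_compat_standardization: bool = False  # fit moments on the full dataset
    maf_threshold: float | None = None
    min_n: int = 50
    gene_hidden: int = 8
    latent: int = 50
    hidden: int = 50
    head_hidden: int = 500
    n_pretrain_tasks: int = 288
    train: TrainConfig = field(default_factory=TrainConfig)
    pretrain_epochs: int = 50
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        have_files = self.variants_path is not None or self.phenotypes_path is not None
        if self.variant == "gps":
            if self.synthetic is None and self.phenotypes_path is None:
                raise ValueError("gps variant needs phenotype input")
        elif (self.synthetic is None) == (not have_files):
            raise ValueError(
                "provide exactly one of a synthetic config or input file paths"
            )
        for name in ("variants_path", "phenotypes_path", "replicates_path", "pathways_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")


def _load_inputs(cfg: ExperimentConfig):
    from .networks import PathwayMap

    if cfg.synthetic is not None:
        dataset = generate_population(cfg.synthetic)
        return dataset.variant_table, dataset.phenotypes, dataset.pathway_map
    phen = PhenotypeTable.from_csv(cfg.phenotypes_path, cfg.replicates_path)
    table = None
    pmap = None
    if cfg.variants_path is not None:
        table = read_variant_table(cfg.variants_path, sample_ids=phen.sample_ids)
    if cfg.pathways_path is not None:
        pmap = PathwayMap.from_tsv(cfg.pathways_path)
    return table, phen, pmap


def _build_for_fold(
    cfg: ExperimentConfig, n_genes: int, pmap, gene_ids, n_tasks: int, fold_seed: int
):
    if cfg.variant == "gps":
        spec = ArchitectureSpec(
            variant="gps", head_hidden=cfg.head_hidden, n_tasks=n_tasks, l2=cfg.train.l2
        )
        return build_model(spec, seed=fold_seed), None
    mask = None
    if cfg.variant == "masked":
        if pmap is None:
            raise ValueError("masked variant requires a pathway map")
        mask = build_mask(pmap, gene_ids, rule="primary")
        spec = ArchitectureSpec(
            variant="masked",
            n_genes=n_genes,
            gene_hidden=cfg.gene_hidden,
            hidden=cfg.hidden,
            n_tasks=n_tasks,
            l2=cfg.train.l2,
        )
    else:
        spec = ArchitectureSpec(
            variant="dense",
            n_genes=n_genes,
            gene_hidden=cfg.gene_hidden,
            latent=cfg.latent,
            n_tasks=n_tasks,
            l2=cfg.train.l2,
        )
    return build_model(spec, mask=mask, seed=fold_seed), mask


def audit_plan(plan: CVPlan, countries: dict[str, str] | None = None) -> dict:
    """Machine-readable leakage audit of a fold plan.

    Checks fold disjointness, test/pretraining separation for
    ``tl-leakage-safe`` plans, and country integrity for stratified
    plans. Raises :class:`AuditError` naming offending ids on violation.
    """
    audit: dict = {"mode": plan.mode, "k": plan.k, "seed": plan.seed, "folds": []}
    seen: dict[str, int] = {}
    for i, fold in enumerate(plan.folds):
        for s in fold:
            if s in seen:
                raise AuditError(f"sample {s} appears in folds {seen[s]} and {i}")
            seen[s] = i
    for i in range(len(plan.folds)):
        test = set(plan.test_ids(i))
        train_ids = set(plan.train_ids(i))
        entry = {
            "fold": i,
            "n_test": len(test),
            "n_train": len(train_ids),
            "test_ids": sorted(test),
            "train_ids": sorted(train_ids),
        }
        overlap = test & train_ids
        if overlap:
            raise AuditError(f"fold {i}: test/train overlap {sorted(overlap)[:5]}")
        if plan.mode == "tl-leakage-safe":
            t1 = set(plan.t1_train_ids(i))
            entry["t1_train_ids"] = sorted(t1)
            leak = test & t1
            if leak:
                raise AuditError(
                    f"fold {i}: test sample(s) leak into pretraining: {sorted(leak)[:5]}"
                )
        audit["folds"].append(entry)
    if plan.mode == "country-stratified":
        if countries is None:
            raise AuditError("country labels required to audit a stratified plan")
        country_fold: dict[str, int] = {}
        for i, fold in enumerate(plan.folds):
            for s in fold:
                c = countries[str(s)]
                if c in country_fold and country_fold[c] != i:
                    raise AuditError(
                        f"country {c} spans folds {country_fold[c]} and {i}"
                    )
                country_fold[c] = i
        audit["countries_per_fold"] = {
            str(i): sorted({countries[str(s)] for s in fold})
            for i, fold in enumerate(plan.folds)
        }
    audit["ok"] = True
    return audit


def run_experiment(cfg: ExperimentConfig) -> EvaluationReport:
    """Execute one experiment end to end and write its artifacts.

    Encoding (with fold-wise standardization unless
    ``paper_compat_standardization``), the CV loop (with pretraining
    inside each fold for the transfer-learning variants), out-of-fold
    prediction collection, and the stratification-aware evaluation.
    """
    table, phen, pmap = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.maf_threshold is not None and table is not None:
        table = maf_filter(table, MafFilterConfig(cfg.maf_threshold))
    raw = encode_variants(table) if table is not None else None

    sample_ids = list(phen.sample_ids)
    cv_seed = component_seed(cfg.seed, "cv")
    cv_mode = "tl-leakage-safe" if cfg.variant in ("frozen-head", "fine-tune") else cfg.cv_mode
    plan = make_cv_plan(sample_ids, cv_mode, k=cfg.k, seed=cv_seed, countries=phen.countries)
    countries_by_id = (
        {str(s): str(c) for s, c in zip(sample_ids, phen.countries)}
        if phen.countries is not None
        else None
    )
    audit = audit_plan(plan, countries_by_id)

    y_std, _, _ = standardize_labels(phen.values)
    preds = np.full_like(phen.values, np.nan, dtype=float)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    failures: list[str] = []
    for fold in range(plan.k):
        fold_seed = component_seed(cfg.seed, f"fold{fold}")
        test_idx = np.array([sample_pos[s] for s in plan.test_ids(fold)])
        train_idx = np.array([sample_pos[s] for s in plan.train_ids(fold)])
        try:
            if cfg.variant == "gps":
                x_all = gps_features(phen.lat, phen.lon)
            else:
                fit_on = None if cfg.paper_compat_standardization else [
                    sample_ids[i] for i in train_idx
                ]
                tensor = standardize(raw, cfg.standardization, fit_on=fit_on)
                x_all = np.asarray(tensor.values, dtype=float)
            y_train = y_std[train_idx]
            build_tasks = (
                cfg.n_pretrain_tasks
                if cfg.variant in ("frozen-head", "fine-tune")
                else phen.n_tasks
            )
            model, mask = _build_for_fold(
                cfg,
                raw.n_genes if raw is not None else 0,
                pmap,
                phen_gene_ids(raw),
                build_tasks,
                fold_seed,
            )
            tcfg = TrainConfig(**{**asdict(cfg.train), "seed": fold_seed})
            if cfg.variant in ("frozen-head", "fine-tune"):
                t1_idx = np.array([sample_pos[s] for s in plan.t1_train_ids(fold)])
                t1_labels = make_pretraining_labels(
                    counts_for(raw),
                    phen.countries,
                    n_tasks=cfg.n_pretrain_tasks,
                    seed=component_seed(cfg.seed, "t1-labels"),
                )
                pre_cfg = TrainConfig(
                    **{**asdict(cfg.train), "epochs": cfg.pretrain_epochs, "seed": fold_seed}
                )
                model, _ = train(model, x_all[t1_idx], t1_labels[t1_idx], pre_cfg)
                if cfg.variant == "frozen-head":
                    model = freeze_and_extend(
                        model,
                        IModuleSpec(model.latent_dim, cfg.head_hidden, phen.n_tasks),
                        seed=fold_seed,
                    )
                    model, history = train(model, x_all[train_idx], y_train, tcfg)
                else:
                    model, history = fine_tune(model, x_all[train_idx], y_train, tcfg)
            else:
                model, history = train(model, x_all[train_idx], y_train, tcfg)
            preds[test_idx] = model.forward(x_all[test_idx])
            log.info(
                "fold %d: final train loss %.4f (%d params)",
                fold,
                history.loss[-1] if history.loss else float("nan"),
                count_parameters(model),
            )
            if out_dir:
                save_checkpoint(model, out_dir / f"fold{fold}", cfg=tcfg, seed=fold_seed)
        except Exception as exc:  # pragma: no cover - partial-failure path
            failures.append(f"fold {fold}: {exc}")
            log.error("fold %d failed: %s", fold, exc)

    report = intra_country_pearson(
        preds, phen.values, phen.countries, min_n=cfg.min_n, task_names=phen.task_names
    )
    report.model = cfg.variant
    ok = ~np.isnan(preds).all(axis=1)
    report.global_r = global_pool_pearson(preds[ok], phen.values[ok], phen.task_names)
    if phen.replicates is not None:
        bounds = pd.Series(
            {
                name: pearson_upper_bound(phen.replicates[:, t, :])
                for t, name in enumerate(phen.task_names)
            }
        )
        report = contextualize(report, bounds)
    simpson = simpson_diagnostic(
        preds[ok], phen.values[ok], phen.countries[ok], task_names=phen.task_names
    ) if phen.countries is not None else None

    if out_dir:
        report.to_csv(out_dir)
        report.to_json(out_dir / "report.json")
        with open(out_dir / "audit.json", "w") as fh:
            json.dump(audit, fh, indent=2)
        if simpson is not None:
            simpson.to_csv(out_dir / "simpson.csv")
        pred_df = pd.DataFrame(preds, columns=list(phen.task_names))
        pred_df.insert(0, "sample", sample_ids)
        pred_df.to_csv(out_dir / "predictions.csv", index=False)
        resolved = asdict(cfg)
        resolved["failures"] = failures
        resolved["input_hashes"] = _input_hashes(cfg)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(resolved, fh, indent=2, default=str)
    if failures:
        raise RuntimeError("; ".join(failures))
    return report


def phen_gene_ids(raw):
    return raw.gene_ids if raw is not None else ()


def counts_for(raw):
    if raw is None:
        raise ValueError("transfer-learning variants need genotype input")
    return np.asarray(raw.values)


def _input_hashes(cfg: ExperimentConfig) -> dict[str, str]:
    hashes = {}
    for name in ("variants_path", "phenotypes_path", "replicates_path", "pathways_path"):
        p = getattr(cfg, name)
        if p is not None:
            hashes[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return hashes
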