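"""Stratification-aware evaluation.

Cross-validation planners (random, country-stratified, leakage-safe for
transfer learning), intra-country Pearson aggregation, the
replicate-based Pearson noise ceiling, Simpson's-paradox diagnostics and
confusion-matrix classification metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "CVPlan",
    "EvaluationReport",
    "ELEMENTS",
    "TISSUES",
    "default_task_names",
    "make_cv_plan",
    "intra_country_pearson",
    "global_pool_pearson",
    "pearson_upper_bound",
    "simpson_diagnostic",
    "classification_metrics",
    "contextualize",
    "compare_models",
]

#: Mineral elements measured per tissue (isotope-tagged names).
ELEMENTS = (
    "Se82", "Mo98", "Mn55", "Cd114", "Sr88", "Mg25", "K39", "Rb85", "Cu65",
    "Ca43", "P31", "S34", "Li7", "As75", "Na23", "Fe57", "Zn66", "Co59",
)
TISSUES = ("leaf", "seed")


def default_task_names(n_tasks: int = 36) -> tuple[str, ...]:
    """Element x tissue task names; synthetic task ids beyond 36."""
    names = [f"{el}_{tis}" for tis in TISSUES for el in ELEMENTS]
    if n_tasks <= len(names):
        return tuple(names[:n_tasks])
    return tuple(names) + tuple(f"task{i}" for i in range(len(names), n_tasks))


@dataclass
class PhenotypeTable:
    """Samples x tasks phenotype matrix with metadata.

    ``replicates`` (optional) is ``N x T x R`` with NaN for missing
    replicate slots; ``values`` holds the per-sample labels (replicate
    means when replicates exist).
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray  # (N, T)
    task_names: tuple[str, ...]
    countries: np.ndarray | None = None  # (N,) str
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    replicates: np.ndarray | None = None  # (N, T, R)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if len(self.sample_ids) != n or len(self.task_names) != t:
            raise ValueError("phenotype table axes inconsistent with ids")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, dtype=float)
            if self.replicates.shape[:2] != (n, t):
                raise ValueError("replicate block shape mismatch")
        for name in ("countries", "lat", "lon"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.task_names))
        df.insert(0, "sample", list(self.sample_ids))
        if self.countries is not None:
            df.insert(1, "country", self.countries)
        if self.lat is not None:
            df.insert(2, "lat", self.lat)
            df.insert(3, "lon", self.lon)
        df.to_csv(path, index=False)

    def replicates_to_csv(self, path: str | Path) -> None:
        if self.replicates is None:
            raise ValueError("no replicates to write")
        n, t, r = self.replicates.shape
        rows = []
        for si in range(n):
            for ti in range(t):
                for ri in range(r):
                    v = self.replicates[si, ti, ri]
                    if np.isfinite(v):
                        rows.append((self.sample_ids[si], self.task_names[ti], ri, v))
        pd.DataFrame(
            rows, columns=["sample", "task", "replicate_index", "value"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, replicates_path: str | Path | None = None
    ) -> "PhenotypeTable":
        df = pd.read_csv(path)
        meta = [c for c in ("sample", "country", "lat", "lon") if c in df.columns]
        task_names = tuple(c for c in df.columns if c not in meta)
        table = cls(
            sample_ids=tuple(df["sample"].astype(str)),
            values=df[list(task_names)].to_numpy(dtype=float),
            task_names=task_names,
            countries=df["country"].to_numpy() if "country" in meta else None,
            lat=df["lat"].to_numpy(float) if "lat" in meta else None,
            lon=df["lon"].to_numpy(float) if "lon" in meta else None,
        )
        if replicates_path is not None:
            rep = pd.read_csv(replicates_path)
            r = int(rep["replicate_index"].max()) + 1
            block = np.full((table.n_samples, table.n_tasks, r), np.nan)
            s_idx = {s: i for i, s in enumerate(table.sample_ids)}
            t_idx = {t: i for i, t in enumerate(table.task_names)}
            for row in rep.itertuples(index=False):
                block[s_idx[str(row.sample)], t_idx[row.task], int(row.replicate_index)] = row.value
            table.replicates = block
        return table


# ---------------------------------------------------------------------------
# Cross-validation planning
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold plan over sample ids.

    ``folds`` lists the test-set ids per fold (a partition of the
    samples). For ``tl-leakage-safe`` plans the pretraining set of a
    fold equals its training set, so test samples are unseen by both the
    pretraining and the target task.
    """

    mode: str
    k: int
    seed: int
    folds: list[np.ndarray]

    def test_ids(self, fold: int) -> np.ndarray:
        return self.folds[fold]

    def train_ids(self, fold: int) -> np.ndarray:
        test = set(self.folds[fold])
        return np.array([s for f in self.folds for s in f if s not in test])

    def t1_train_ids(self, fold: int) -> np.ndarray:
        if self.mode != "tl-leakage-safe":
            raise ValueError("pretraining sets are defined only for tl-leakage-safe plans")
        return self.train_ids(fold)

    def validate(self, countries: dict[str, str] | None = None) -> None:
        all_ids = [s for f in self.folds for s in f]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("folds overlap")
        if self.mode == "country-stratified":
            if countries is None:
                raise ValueError("country labels required to validate stratified plan")
            seen: dict[str, int] = {}
            for i, fold in enumerate(self.folds):
                for s in fold:
                    c = countries[s]
                    if c in seen and seen[c] != i:
                        raise ValueError(f"country {c} spans folds {seen[c]} and {i}")
                    seen[c] = i


def make_cv_plan(
    sample_ids,
    mode: str = "random-kfold",
    k: int = 5,
    seed: int = 0,
    countries=None,
) -> CVPlan:
    """Build a fold plan.

    ``random-kfold`` / ``tl-leakage-safe``: seeded shuffle into k nearly
    equal folds. ``country-stratified``: whole countries are assigned to
    folds greedily (largest country first, onto the currently smallest
    fold), so no country ever spans two folds.
    """
    sample_ids = np.asarray([str(s) for s in sample_ids])
    n = len(sample_ids)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    if mode in ("random-kfold", "tl-leakage-safe"):
        order = rng.permutation(n)
        folds = [sample_ids[chunk] for chunk in np.array_split(order, k)]
        return CVPlan(mode, k, seed, folds)
    if mode == "country-stratified":
        if countries is None:
            raise ValueError("country labels required for country-stratified mode")
        countries = np.asarray(countries)
        uniq, counts = np.unique(countries, return_counts=True)
        if len(uniq) < k:
            raise ValueError(
                f"cannot build {k} folds from {len(uniq)} countries"
            )
        # largest first; ties broken by shuffled order for seed variety
        tie = rng.permutation(len(uniq))
        order = np.lexsort((tie, -counts))
        fold_members: list[list[str]] = [[] for _ in range(k)]
        fold_sizes = np.zeros(k, dtype=int)
        for ci in order:
            target = int(np.argmin(fold_sizes))
            fold_members[target].extend(sample_ids[countries == uniq[ci]])
            fold_sizes[target] += counts[ci]
        return CVPlan(mode, k, seed, [np.asarray(f) for f in fold_members])
    raise ValueError(f"unknown CV mode {mode!r}")


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def intra_country_pearson(
    pred: np.ndarray,
    obs: np.ndarray,
    countries,
    min_n: int = 50,
    task_names=None,
) -> "EvaluationReport":
    """Per-country, per-task Pearson r and its unweighted country mean.

    Only countries with strictly more than ``min_n`` samples are
    included. Countries where r is undefined (zero variance) are
    excluded from the mean with a warning.
    """
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    countries = np.asarray(countries)
    if pred.shape != obs.shape:
        raise ValueError("pred/obs shape mismatch")
    n_tasks = pred.shape[1]
    task_names = list(task_names) if task_names else list(default_task_names(n_tasks))
    uniq, counts = np.unique(countries, return_counts=True)
    included = [c for c, n in zip(uniq, counts) if n > min_n]
    if not included:
        warnings.warn(f"no country exceeds min_n={min_n}; empty report")
    rows = []
    for country in included:
        sel = countries == country
        for t in range(n_tasks):
            ok = np.isfinite(pred[sel, t]) & np.isfinite(obs[sel, t])
            r = _pearson(pred[sel, t][ok], obs[sel, t][ok])
            rows.append((task_names[t], country, r, int(sel.sum())))
    per_country = pd.DataFrame(rows, columns=["task", "country", "r", "n"])
    if len(per_country) and per_country["r"].isna().any():
        bad = per_country.loc[per_country["r"].isna(), ["task", "country"]]
        warnings.warn(
            f"{len(bad)} (task, country) cells have undefined r and are excluded"
        )
    intra_mean = (
        per_country.groupby("task", sort=False)["r"].mean()
        if len(per_country)
        else pd.Series(dtype=float)
    )
    intra_mean = intra_mean.reindex(task_names)
    return EvaluationReport(
        per_country=per_country,
        intra_country_mean=intra_mean,
        task_names=tuple(task_names),
        min_n=min_n,
    )


def global_pool_pearson(pred: np.ndarray, obs: np.ndarray, task_names=None) -> pd.Series:
    """Pearson r per task over all samples pooled."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape[0] < 2:
        raise ValueError("need at least two samples")
    n_tasks = pred.shape[1]
    task_names = list(task_names) if task_names else list(default_task_names(n_tasks))
    out = {}
    for t in range(n_tasks):
        ok = np.isfinite(pred[:, t]) & np.isfinite(obs[:, t])
        out[task_names[t]] = _pearson(pred[ok, t], obs[ok, t])
    return pd.Series(out)


def pearson_upper_bound(
    replicates: np.ndarray, labels_are_replicate_means: bool = True
) -> float:
    """Noise ceiling for Pearson r from replicate measurements.

    ``replicates`` is ``N x R`` (NaN = missing slot). The per-sample
    measurement-noise variance is the unbiased replicate variance; when
    the labels are replicate means it is further divided by that
    sample's replicate count. With signal variance s2 (observed spread
    minus noise, floored at 0) the ceiling is ``sqrt(s2 / (s2 + e2))``.
    """
    reps = np.asarray(replicates, dtype=float)
    counts = np.isfinite(reps).sum(axis=1)
    usable = counts >= 2
    if usable.sum() < 2:
        raise ValueError("need >=2 replicates for >=2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample_var = np.nanvar(reps[usable], axis=1, ddof=1)
        means = np.nanmean(reps[usable], axis=1)
    noise = per_sample_var
    if labels_are_replicate_means:
        noise = noise / counts[usable]
    e2 = float(noise.mean())
    m2 = float(np.var(means, ddof=1))
    s2 = max(m2 - e2, 0.0)
    if e2 == 0.0:
        return 1.0
    return float(np.sqrt(s2 / (s2 + e2)))


def simpson_diagnostic(
    pred: np.ndarray,
    obs: np.ndarray,
    groups,
    gap_threshold: float = 0.3,
    min_n: int = 1,
    task_names=None,
) -> pd.DataFrame:
    """Global-pool vs mean intra-group correlation, per task.

    Tasks whose pooled r exceeds the mean intra-group r by more than
    ``gap_threshold`` are flagged as stratification-inflated.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 1:
        raise ValueError("need at least one group")
    n_tasks = np.asarray(pred).shape[1]
    task_names = list(task_names) if task_names else list(default_task_names(n_tasks))
    glob = global_pool_pearson(pred, obs, task_names)
    if len(np.unique(groups)) == 1:
        intra = glob.copy()  # single group: intra == global, gap 0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            intra = intra_country_pearson(
                pred, obs, groups, min_n=min_n, task_names=task_names
            ).intra_country_mean
    gap = glob - intra
    return pd.DataFrame(
        {
            "global_r": glob,
            "intra_group_mean_r": intra,
            "gap": gap,
            "flagged": gap > gap_threshold,
        }
    )


def classification_metrics(confusion: np.ndarray) -> tuple[float, float]:
    """(macro F1, multi-class MCC) from a K x K confusion matrix.

    Rows index the true class, columns the predicted class.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
        raise ValueError("confusion matrix must be K x K with K >= 2")
    if c.sum() == 0:
        raise ValueError("confusion matrix is empty")
    if (c < 0).any():
        raise ValueError("confusion counts must be non-negative")
    tp = np.diag(c)
    pred_tot = c.sum(axis=0)
    true_tot = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(
            pred_tot + true_tot > 0, 2 * tp / (pred_tot + true_tot), 0.0
        )
    macro_f1 = float(f1.mean())
    s = c.sum()
    trace = tp.sum()
    num = trace * s - float(pred_tot @ true_tot)
    den = np.sqrt(s**2 - float(pred_tot @ pred_tot)) * np.sqrt(
        s**2 - float(true_tot @ true_tot)
    )
    mcc = 0.0 if den == 0 else float(num / den)
    return macro_f1, mcc


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-country correlations plus aggregate, ceiling and diagnostics."""

    per_country: pd.DataFrame  # columns task, country, r, n
    intra_country_mean: pd.Series
    task_names: tuple[str, ...]
    min_n: int = 50
    global_r: pd.Series | None = None
    upper_bound: pd.Series | None = None
    pct_of_bound: pd.Series | None = None
    model: str = ""

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"intra_country_mean_r": self.intra_country_mean})
        for name in ("global_r", "upper_bound", "pct_of_bound"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_country.to_csv(directory / "per_country.csv", index=False)
        self.summary().to_csv(directory / "summary.csv")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "min_n": self.min_n,
            "intra_country_mean_r": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.intra_country_mean.items()
            },
        }
        for name in ("global_r", "upper_bound", "pct_of_bound"):
            v = getattr(self, name)
            if v is not None:
                payload[name] = {
                    k: (None if pd.isna(x) else float(x)) for k, x in v.items()
                }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def contextualize(report: EvaluationReport, bounds: pd.Series) -> EvaluationReport:
    """Express each task's score as a percentage of its noise ceiling.

    Scores above the ceiling are reported as >100% (flagged, not
    clipped); zero ceilings give an undefined (NaN) percentage.
    """
    bounds = bounds.reindex(report.intra_country_mean.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * report.intra_country_mean / bounds.replace(0.0, np.nan)
    zero = bounds == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} task(s) have a zero ceiling; percentage undefined"
        )
    over = pct > 100.0
    if over.any():
        warnings.warn(f"{int(over.sum())} task(s) exceed the ceiling")
    report.upper_bound = bounds
    report.pct_of_bound = pct
    return report


def compare_models(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value over paired correlations."""
    r_a, r_b = np.asarray(r_a, float), np.asarray(r_b, float)
    ok = np.isfinite(r_a) & np.isfinite(r_b)
    return float(stats.wilcoxon(r_a[ok], r_b[ok]).pvalue)
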