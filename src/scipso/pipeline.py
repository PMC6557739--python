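"""End-to-end orchestration of the four-stage gene selection method.

A run: split the data (stratified), build the level-1 pool by
class-separability ranking on the training split, screen randomized
subsets with cross-validated ELM accuracy, score genes from surviving
subset ranks into the level-3 pool, then search that pool with the
annealed particle swarm.  The whole procedure is repeated ``n_repeats``
times (fresh stage seeds each repeat, one shared train/test split) and
per-gene selection frequencies are aggregated, mirroring the repeated
-trials protocol used to report frequently selected genes.

Test-set hygiene: stages 1-4 see only the training rows.  The held-out
rows enter exactly once per repeat, to measure the final subset's test
accuracy with an ELM trained on the full training split.

Expression values are z-scored per gene on the training split by
default (statistics frozen and applied to the test rows); raw
microarray intensities can saturate a sigmoid hidden layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from scipso.data_io import ExpressionDataset, SplitSpec, load_dataset, split_dataset
from scipso.elm import kfold_cv_accuracy, predict, stratified_folds, train_elm
from scipso.filters import (
    build_first_level_pool,
    build_third_level_pool,
    generate_candidate_subsets,
    score_genes,
    screen_and_rank_subsets,
)
from scipso.ipso import IPSOConfig, run_ipso

__all__ = [
    "RunConfig",
    "RunReport",
    "run_scipso",
    "select_genes",
    "frequency_table",
    "sweep",
]


@dataclass
class RunConfig:
    """Every knob of the pipeline, serializable to a flat YAML/JSON file.

    Defaults follow the method's published operating point where one
    exists (swarm 60, 20 generations, c1 = c2 = 1.49445, inertia
    0.9 -> 0.4, level-3 pool of 40, mutation after 3 stagnant
    generations); the remaining values are this package's documented
    choices.
    """

    # data handling
    label_column: str = "label"
    orientation: str = "samples-by-genes"
    train_fraction: float = 0.65
    standardize: bool = True
    # filter cascade
    first_pool_size: int = 300
    n_subsets: int | None = None  # default: 20 * first_pool_size
    subset_size_min: int = 5
    subset_size_max: int = 15
    theta_ac: float = 0.80
    third_pool_size: int = 40
    # ELM fitness
    cv_folds: int = 5
    n_hidden: int | None = None  # default: min(n_train_fold, 20)
    activation: str = "sigmoid"
    # swarm search
    n_select: int = 5
    swarm_size: int = 60
    max_iter: int = 20
    c1: float = 1.49445
    c2: float = 1.49445
    w_ini: float = 0.9
    w_end: float = 0.4
    v_max: float | None = None
    t0: float = 0.1
    t_end: float = 0.001
    eps: float = 0.01
    n_mu: int = 3
    gbest_update: str = "metropolis"
    mutation: bool = True
    # protocol
    n_repeats: int = 100
    master_seed: int = 0

    def resolved_n_subsets(self) -> int:
        return self.n_subsets if self.n_subsets is not None else 20 * self.first_pool_size

    def ipso_config(self, seed: int) -> IPSOConfig:
        return IPSOConfig(
            n_select=self.n_select,
            swarm_size=self.swarm_size,
            max_iter=self.max_iter,
            c1=self.c1,
            c2=self.c2,
            w_ini=self.w_ini,
            w_end=self.w_end,
            v_max=self.v_max,
            t0=self.t0,
            t_end=self.t_end,
            eps=self.eps,
            n_mu=self.n_mu,
            gbest_update=self.gbest_update,
            mutation=self.mutation,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class RunReport:
    """All artifacts of a multi-repeat run, reproducible from
    (config, master_seed)."""

    config: dict
    gene_ids: list[str]
    train_indices: list[int]
    test_indices: list[int]
    repeats: list[dict] = field(default_factory=list)
    frequencies: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "gene_ids": self.gene_ids,
            "train_indices": self.train_indices,
            "test_indices": self.test_indices,
            "repeats": self.repeats,
            "frequencies": self.frequencies,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean([r["cv_accuracy"] for r in self.repeats]))

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([r["test_accuracy"] for r in self.repeats]))


def _stage_seed(master_seed: int, *tags: int) -> int:
    """Deterministic per-stage/per-repeat seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31))


def _standardizer(X_train: np.ndarray):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return lambda X: (X - mu) / sd


def select_genes(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RunConfig,
    seed: int,
) -> dict:
    """Run stages 1-4 on a training split; returns pools and the
    selected subset (dataset gene indices, 0-based)."""
    pool1 = build_first_level_pool(X_train, y_train, n_top=config.first_pool_size)
    subsets = generate_candidate_subsets(
        pool1,
        n_subsets=config.resolved_n_subsets(),
        size_range=(config.subset_size_min, config.subset_size_max),
        seed=_stage_seed(seed, 2),
    )
    survivors = screen_and_rank_subsets(
        subsets,
        X_train,
        y_train,
        theta_ac=config.theta_ac,
        k=config.cv_folds,
        n_hidden=config.n_hidden,
        activation=config.activation,
        seed=_stage_seed(seed, 3),
    )
    scores = score_genes(survivors, n_genes=X_train.shape[1])
    iic_full = np.zeros(X_train.shape[1])
    iic_full[pool1.gene_indices] = pool1.scores
    pool3 = build_third_level_pool(
        scores, pool_size=config.third_pool_size, iic=iic_full
    )

    fit_seed = _stage_seed(seed, 4)
    folds = stratified_folds(y_train, config.cv_folds, fit_seed)
    pool_genes = pool3.gene_indices

    def fitness(slots: tuple[int, ...]) -> float:
        genes = pool_genes[list(slots)]
        res = kfold_cv_accuracy(
            X_train[:, genes],
            y_train,
            k=config.cv_folds,
            n_hidden=config.n_hidden,
            activation=config.activation,
            seed=fit_seed,
            folds=folds,
        )
        return res.mean_accuracy

    result = run_ipso(fitness, len(pool3), config.ipso_config(_stage_seed(seed, 5)))
    selected = tuple(int(g) for g in pool_genes[list(result.best_genes)])
    return {
        "pool1": pool1,
        "survivors": survivors,
        "scores": scores,
        "pool3": pool3,
        "selected": selected,
        "cv_accuracy": result.best_fitness,
        "trace": result.trace,
        "evaluations": result.evaluations,
    }


def run_scipso(
    config: RunConfig,
    dataset: ExpressionDataset | str,
    split: SplitSpec | None = None,
) -> RunReport:
    """Execute the full pipeline ``config.n_repeats`` times.

    ``dataset`` may be an in-memory dataset or a path handed to the
    loader with the config's ``label_column``/``orientation``.  The
    train/test split is drawn once from the master seed (or supplied
    explicitly) and shared by all repeats; repeats differ in the
    randomized screening, fold assignment, ELM draws and swarm seeds.
    """
    if isinstance(dataset, (str, bytes)) or hasattr(dataset, "__fspath__"):
        dataset = load_dataset(
            dataset, label_column=config.label_column, orientation=config.orientation
        )
    if split is None:
        split = split_dataset(
            dataset, config.train_fraction, seed=_stage_seed(config.master_seed, 1)
        )
    tr, te = split.train_indices, split.test_indices
    X_tr_raw = dataset.values[tr]
    y_tr = dataset.labels[tr]
    if config.standardize:
        transform = _standardizer(X_tr_raw)
    else:
        transform = lambda X: X
    X_tr = transform(X_tr_raw)
    X_te = transform(dataset.values[te])
    y_te = dataset.labels[te]

    report = RunReport(
        config=config.to_dict(),
        gene_ids=list(dataset.gene_ids),
        train_indices=[int(i) for i in tr],
        test_indices=[int(i) for i in te],
    )
    score_sum = np.zeros(dataset.n_genes)
    for rep in range(config.n_repeats):
        rep_seed = _stage_seed(config.master_seed, 100, rep)
        stages = select_genes(X_tr, y_tr, config, seed=rep_seed)
        selected = stages["selected"]
        # held-out evaluation: ELM trained on the full training split
        model = train_elm(
            X_tr[:, list(selected)],
            y_tr,
            n_hidden=config.n_hidden,
            activation=config.activation,
            seed=_stage_seed(rep_seed, 6),
            n_classes=dataset.n_classes,
        )
        test_acc = float(np.mean(predict(model, X_te[:, list(selected)]) == y_te))
        score_sum += stages["scores"]
        report.repeats.append(
            {
                "repeat": rep,
                "selected_serials": [g + 1 for g in selected],
                "selected_gene_ids": [dataset.gene_ids[g] for g in selected],
                "cv_accuracy": stages["cv_accuracy"],
                "test_accuracy": test_acc,
                "level3_serials": [int(g) + 1 for g in stages["pool3"].gene_indices],
                "pool_sizes": {
                    "level1": len(stages["pool1"]),
                    "level2_subsets": len(stages["survivors"]),
                    "level3": len(stages["pool3"]),
                },
                "fitness_evaluations": stages["evaluations"],
            }
        )
    report.frequencies = frequency_table(
        report.repeats, dataset.gene_ids, score_sum / max(config.n_repeats, 1)
    )
    return report


def frequency_table(
    repeats: list[dict],
    gene_ids: list[str],
    mean_scores: np.ndarray | None = None,
) -> list[dict]:
    """Per-gene selection counts across repeats, most frequent first.

    Count ties break by higher mean level-3 score (when available),
    then by lower gene index.  Only genes selected at least once are
    listed; total counts sum to n_repeats * D.
    """
    if not repeats:
        raise ValueError("at least one repeat is required")
    counts = np.zeros(len(gene_ids), dtype=int)
    for r in repeats:
        for s in r["selected_serials"]:
            counts[s - 1] += 1
    if mean_scores is None:
        mean_scores = np.zeros(len(gene_ids))
    picked = np.flatnonzero(counts)
    order = picked[np.lexsort((picked, -mean_scores[picked], -counts[picked]))]
    return [
        {
            "serial": int(g + 1),
            "gene_id": gene_ids[g],
            "count": int(counts[g]),
            "mean_score": float(mean_scores[g]),
        }
        for g in order
    ]


_SWEEPABLE = {"theta_ac", "n_select"}


def sweep(
    parameter: str,
    values,
    config: RunConfig,
    dataset: ExpressionDataset | str,
) -> list[dict]:
    """Re-run the full pipeline for each value of ``parameter``.

    ``parameter`` is ``theta_ac`` (subset survival threshold) or
    ``n_select`` (number of selected genes / particle dimension).
    Returns one row per value with the mean CV and test accuracies
    over the config's ``n_repeats``.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {sorted(_SWEEPABLE)}")
    values = list(values)
    if not values:
        raise ValueError("no sweep values supplied")
    rows = []
    for v in values:
        cfg = dataclasses.replace(config, **{parameter: v})
        rep = run_scipso(cfg, dataset)
        rows.append(
            {
                "parameter": parameter,
                "value": v,
                "mean_cv_accuracy": rep.mean_cv_accuracy,
                "mean_test_accuracy": rep.mean_test_accuracy,
            }
        )
    return rows
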