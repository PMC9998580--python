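"""Cross-validation benchmark of training-set optimization methods.

Each replicate splits the dataset into a candidate set (85%) and a test set
(15%), selects training sets of several sizes (10-100% of the candidate set)
with each method, fits genomic prediction models and records the accuracy on
the test set. Results are summarized as the area under the accuracy-vs-size
curve (AUC, trapezoid rule over the sizes below 100%), the percentage gain
in AUC over random sampling with its standard error, and the coordinates of
each method in the relationship trade-off plane (training-test relationship
against within-training diversity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    Partition,
    assign_to_clusters,
    cluster_assignments,
    pam_select,
    stratified_sample,
)
from .core import MarkerMatrix, RelationshipMatrix
from .criteria import CriterionSpec, make_evaluator, resolve_target_population
from .models import fit_predict_bayesb, fit_predict_gblup, fit_predict_rkhs, prediction_accuracy
from .search import SearchConfig, SubsetSolution, optimize_clustered, optimize_subset

logger = logging.getLogger(__name__)

SIZE_GRID_DEFAULT = (0.10, 0.20, 0.40, 0.60, 0.80, 1.00)


@dataclass
class CVPlan:
    """Cross-validation layout: 85/15 candidate/test split, the size grid as
    fractions of the candidate set, and the number of replicates."""

    candidate_fraction: float = 0.85
    test_fraction: float = 0.15
    size_grid: tuple = SIZE_GRID_DEFAULT
    replicates: int = 40
    rng_seed: int = 0
    preselect_cap: int = 1000

    def __post_init__(self) -> None:
        if abs(self.candidate_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("candidate and test fractions must sum to 1")
        grid = tuple(float(s) for s in self.size_grid)
        if any(not 0 < s <= 1 for s in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("size grid must be strictly increasing within (0, 1]")
        self.size_grid = grid


@dataclass
class MethodSpec:
    """One training-set selection method in the benchmark.

    ``name`` is "random", "stratified", "pam" or a criterion name; criterion
    methods carry the optimization scenario and, for the clustered CDmean
    orchestrations, a cluster mode ("within" or "overall")."""

    name: str
    scenario: str = "untargeted"
    cluster_mode: str | None = None

    @property
    def label(self) -> str:
        parts = [self.name]
        if self.cluster_mode:
            parts.append(self.cluster_mode)
        parts.append(self.scenario if self.name not in ("random", "stratified", "pam") else "untargeted")
        return "_".join(parts)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cv_split(ids, plan: CVPlan, replicate_index: int) -> tuple[list[str], list[str]]:
    """Random candidate/test split, reproducible from (seed, replicate)."""
    ids = list(ids)
    n = len(ids)
    if n < 20:
        raise ValueError("need at least 20 individuals for a meaningful split")
    n_test = _round_half_up(plan.test_fraction * n)
    if n_test < 1 or n_test >= n:
        raise ValueError("dataset too small for a nonempty test set")
    rng = np.random.default_rng(np.random.SeedSequence([plan.rng_seed, replicate_index]))
    test_pos = set(rng.choice(n, size=n_test, replace=False).tolist())
    test = [ids[i] for i in range(n) if i in test_pos]
    candidate = [ids[i] for i in range(n) if i not in test_pos]
    return candidate, test


def preselect_candidates(
    A: RelationshipMatrix,
    candidate_ids,
    cap: int = 1000,
    n_components: int = 50,
    search_config: SearchConfig | None = None,
) -> list[str]:
    """Reduce an oversized candidate set to ``cap`` genotypes by untargeted
    CDMEAN2 optimization; identity when the candidate set is at or below the
    cap."""
    if cap < 2:
        raise ValueError("cap must be at least 2")
    candidate = list(candidate_ids)
    if len(candidate) <= cap:
        return candidate
    spec = CriterionSpec("cdmean2", "untargeted", n_components=n_components)
    evaluate = make_evaluator(spec, candidate, A=A)
    config = search_config or SearchConfig(
        ga_generations=30, sa_steps_per_generation=5, population_size=30
    )
    solution = optimize_subset(evaluate, candidate, cap, config)
    return solution.selected_ids


def _restrict_partition(partition: Partition, ids) -> Partition:
    """Partition restricted to a subset of samples, clusters renumbered."""
    label_of = partition.label_of()
    labels = [label_of[s] for s in ids]
    relabel: dict[int, int] = {}
    new = [relabel.setdefault(l, len(relabel)) for l in labels]
    return Partition(list(ids), np.array(new), len(relabel))


def _clustered_cdmean_evaluators(
    spec: CriterionSpec,
    markers: MarkerMatrix,
    A: RelationshipMatrix,
    partition: Partition,
    test_ids,
):
    """Per-cluster evaluators for within-cluster CDmean: untargeted clusters
    use their own remaining set as target; targeted clusters receive the test
    individuals assigned to their nearest centroid."""
    test_by_cluster = (
        assign_to_clusters(markers, partition, test_ids)
        if spec.scenario == "targeted"
        else None
    )
    evaluators = {}
    for label in range(partition.k):
        members = partition.members(label)
        if spec.scenario == "targeted":
            cluster_test = test_by_cluster[label]
            if not cluster_test:
                # no test individual maps here; fall back to untargeted
                local = CriterionSpec(spec.name, "untargeted", lambda_=spec.lambda_,
                                      n_components=spec.n_components)
                evaluators[label] = make_evaluator(local, members, A=A)
                continue
            evaluators[label] = make_evaluator(spec, members, cluster_test, A=A)
        else:
            evaluators[label] = make_evaluator(spec, members, A=A)
    return evaluators


def select_training_set(
    method: MethodSpec,
    size: int,
    candidate_ids,
    test_ids,
    markers: MarkerMatrix,
    A: RelationshipMatrix,
    partition: Partition | None = None,
    search_config: SearchConfig | None = None,
    rng_seed: int = 0,
) -> list[str]:
    """Select a training set of the requested size with one method."""
    candidate = list(candidate_ids)
    if size >= len(candidate):  # 100% size: no optimization possible
        return candidate
    if method.name == "random":
        rng = np.random.default_rng(rng_seed)
        picks = rng.choice(len(candidate), size=size, replace=False)
        return [candidate[i] for i in sorted(picks)]
    if method.name == "stratified":
        if partition is None:
            raise ValueError("stratified sampling requires a partition")
        local = _restrict_partition(partition, candidate)
        return stratified_sample(local, size, np.random.default_rng(rng_seed))
    if method.name == "pam":
        return pam_select(markers, candidate, size)

    spec = CriterionSpec(method.name, method.scenario)
    config = search_config or SearchConfig()
    config = SearchConfig(**{**config.__dict__, "rng_seed": rng_seed})
    if method.cluster_mode:
        if partition is None:
            raise ValueError("clustered optimization requires a partition")
        local = _restrict_partition(partition, candidate)
        if method.cluster_mode == "within":
            evaluators = _clustered_cdmean_evaluators(spec, markers, A, local, test_ids)
            solution = optimize_clustered(
                None, candidate, size, local, "within", config,
                within_evaluators=evaluators,
            )
        else:
            evaluate = make_evaluator(spec, candidate, test_ids, A=A, markers=markers)
            solution = optimize_clustered(evaluate, candidate, size, local, "overall", config)
    else:
        evaluate = make_evaluator(spec, candidate, test_ids, A=A, markers=markers)
        solution = optimize_subset(evaluate, candidate, size, config)
    return solution.selected_ids


def _fit_model(model: str, y_train, markers, A, training_ids, predict_ids):
    if model == "gblup":
        return fit_predict_gblup(y_train, A, training_ids, predict_ids)
    if model == "rkhs":
        return fit_predict_rkhs(y_train, markers, training_ids, predict_ids)
    if model == "bayesb":
        return fit_predict_bayesb(y_train, markers, training_ids, predict_ids)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class BenchmarkResult:
    """Tidy accuracy table plus the per-replicate training-set selections."""

    table: pd.DataFrame
    selections: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def run_benchmark(
    markers: MarkerMatrix,
    A: RelationshipMatrix,
    trait,
    methods: list[MethodSpec],
    models: list[str],
    plan: CVPlan,
    partition: Partition | None = None,
    search_config: SearchConfig | None = None,
    trait_name: str = "trait",
) -> BenchmarkResult:
    """Run the full methods x sizes x models x replicates factorial.

    ``trait`` is either a pair of mappings/Series (phenotype y, genotypic
    value g, both indexed by sample id) or a callable
    ``trait(replicate_index) -> (y, g)`` that regenerates a simulated trait
    for every replicate. Accuracies are Pearson correlations between test-set
    GEBVs and the genotypic values g. Any per-cell failure is recorded and
    the run continues.
    """
    ids = list(markers.sample_ids)
    rows: list[dict] = []
    selections: dict[str, list] = {m.label: [] for m in methods}
    failures: list[dict] = []

    for rep in range(plan.replicates):
        candidate, test = cv_split(ids, plan, rep)
        if len(candidate) > plan.preselect_cap:
            candidate = preselect_candidates(A, candidate, plan.preselect_cap)
        y_all, g_all = trait(rep) if callable(trait) else trait
        y_all = pd.Series(y_all, index=ids) if not isinstance(y_all, pd.Series) else y_all
        g_all = pd.Series(g_all, index=ids) if not isinstance(g_all, pd.Series) else g_all

        for mi, method in enumerate(methods):
            for si, frac in enumerate(plan.size_grid):
                size = max(1, _round_half_up(frac * len(candidate)))
                seed = int(
                    np.random.SeedSequence(
                        [plan.rng_seed, rep, mi, si]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                try:
                    training = select_training_set(
                        method, size, candidate, test, markers, A,
                        partition, search_config, seed,
                    )
                except Exception as exc:
                    logger.warning("selection failed: %s rep=%d size=%d: %s",
                                   method.label, rep, size, exc)
                    failures.append({"stage": "selection", "method": method.label,
                                     "replicate": rep, "size_frac": frac, "error": str(exc)})
                    continue
                selections[method.label].append(
                    {"replicate": rep, "size_frac": frac,
                     "training_ids": training, "test_ids": test}
                )
                for model in models:
                    try:
                        fit = _fit_model(
                            model, y_all[training].to_numpy(), markers, A, training, test
                        )
                        acc = prediction_accuracy(fit.gebv_for(test), g_all[test].to_numpy())
                    except Exception as exc:
                        logger.warning("model failed: %s %s rep=%d: %s",
                                       method.label, model, rep, exc)
                        failures.append({"stage": "model", "method": method.label,
                                         "model": model, "replicate": rep,
                                         "size_frac": frac, "error": str(exc)})
                        acc = np.nan
                    rows.append({
                        "trait": trait_name,
                        "model": model,
                        "method": method.label,
                        "scenario": method.scenario,
                        "size_pct": round(frac * 100, 6),
                        "replicate": rep,
                        "accuracy": acc,
                    })
    if failures:
        logger.warning("benchmark finished with %d failed cell(s)", len(failures))
    return BenchmarkResult(pd.DataFrame(rows), selections, failures)


def auc(sizes_pct, accuracies) -> float:
    """Trapezoid area under the accuracy-vs-size curve, excluding the 100%
    size (the full candidate set involves no optimization)."""
    sizes = np.asarray(sizes_pct, dtype=float)
    accs = np.asarray(accuracies, dtype=float)
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    keep = sizes < 100.0
    sizes, accs = sizes[keep], accs[keep]
    if sizes.size < 2:
        raise ValueError("need at least two sizes below 100%")
    return float(np.sum((accs[:-1] + accs[1:]) / 2.0 * np.diff(sizes)))


def replicate_aucs(table: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, model, method, replicate) AUC from the tidy accuracy table."""
    records = []
    for keys, group in table.groupby(["trait", "model", "method", "replicate"]):
        group = group.sort_values("size_pct")
        if group["accuracy"].isna().any():
            continue
        records.append({
            "trait": keys[0], "model": keys[1], "method": keys[2],
            "replicate": keys[3],
            "auc": auc(group["size_pct"].to_numpy(), group["accuracy"].to_numpy()),
        })
    return pd.DataFrame(records)


def gain_and_sem(table: pd.DataFrame, baseline: str = "random_untargeted") -> pd.DataFrame:
    """Percentage gain in AUC over random sampling with the SEM rule.

    The gain is computed on replicate-mean AUCs; the SEM is the standard
    error over replicates of the per-replicate AUC difference, and a method
    is flagged significant when |mean difference| > 2 SEM.
    """
    per_rep = replicate_aucs(table)
    out = []
    for (trait, model), group in per_rep.groupby(["trait", "model"]):
        base = group[group["method"] == baseline].set_index("replicate")["auc"]
        if base.empty:
            raise ValueError(f"baseline {baseline!r} missing for {trait}/{model}")
        if abs(float(base.mean())) < 1e-300:
            raise ValueError("baseline AUC is zero; gain undefined")
        for method, sub in group.groupby("method"):
            m = sub.set_index("replicate")["auc"]
            common = base.index.intersection(m.index)
            diff = (m[common] - base[common]).to_numpy()
            mean_gain = 100.0 * (m[common].mean() - base[common].mean()) / base[common].mean()
            sem = float(np.std(diff, ddof=1) / np.sqrt(diff.size)) if diff.size > 1 else np.nan
            out.append({
                "trait": trait, "model": model, "method": method,
                "auc_mean": float(m[common].mean()),
                "auc_baseline": float(base[common].mean()),
                "gain_pct": float(mean_gain),
                "sem_diff": sem,
                "significant": bool(abs(diff.mean()) > 2 * sem) if np.isfinite(sem) else False,
                "replicates": int(diff.size),
            })
    return pd.DataFrame(out)


def tradeoff_coordinates(
    A: RelationshipMatrix, selections: dict, size_frac: float | None = None
) -> pd.DataFrame:
    """Per-method coordinates in the relationship trade-off plane.

    x is the mean (over replicates) training-test relationship, y the negated
    mean within-training relationship (diagonal included); both axes are
    scaled/centered across methods and min-max rescaled to [0, 1], so larger
    is better on both.
    """
    labels = [l for l, sels in selections.items() if sels]
    if len(labels) < 2:
        raise ValueError("need at least two methods for the trade-off plane")
    raw_x, raw_y = [], []
    for label in labels:
        sels = selections[label]
        if size_frac is not None:
            sels = [s for s in sels if abs(s["size_frac"] - size_frac) < 1e-9]
        xs = [float(A.submatrix(s["training_ids"], s["test_ids"]).mean()) for s in sels]
        ys = [-float(A.submatrix(s["training_ids"]).mean()) for s in sels]
        raw_x.append(np.mean(xs))
        raw_y.append(np.mean(ys))
    raw_x, raw_y = np.array(raw_x), np.array(raw_y)

    def rescale(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        span = z.max() - z.min()
        if span == 0:
            raise ValueError("degenerate min-max: all methods coincide on an axis")
        return (z - z.min()) / span

    return pd.DataFrame({
        "method": labels,
        "relationship_train_test": rescale(raw_x),
        "diversity_within_train": rescale(raw_y),
        "raw_train_test": raw_x,
        "raw_within_train_negated": raw_y,
    })
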