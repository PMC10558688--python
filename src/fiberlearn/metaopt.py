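"""Self-enhancement: NSGA-II search over trial configurations.

Each *trial* evaluates one configuration: a network is trained on the train
set and its per-task dev metrics become a vector of meta-losses (1 − AUC for
classification, 1 − R² for regression) that NSGA-II minimizes jointly. The
fifth prior-integration level (PriorsOnly) routes to a features-only AutoML
path over the handcrafted priors instead of training a network. Per task the
final model is the trial with the lowest task meta-loss; scarce tasks
(fewer than 100 labelled samples) instead use the trial with the lowest
weighted *total* meta-loss, which acts as a regularizing model selector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fiberlearn import multitask as mt
from fiberlearn.io import Labbook

POPULATION_SIZE = 50
CROSSOVER_PROB = 0.9
GENE_SWAP_PROB = 0.5
SCARCE_TASK_N = 100
FAILED_TRIAL_MARGIN = 0.10


@dataclass
class ConfigurationSpace:
    """Genes and their domains; learning rate is log-uniform continuous."""

    genes: dict = field(default_factory=lambda: {
        "contrast_enhancement": [False, True],
        "downsample": [False, True],
        "augment": [False, True],
        "random_erasing": [False, True],
        "representation": list(mt.REPRESENTATIONS),
        "prior_integration": list(mt.INTEGRATIONS),
        "capacity": list(mt.CAPACITIES),
        "optimizer": list(mt.OPTIMIZERS),
        "momentum": [0.8, 0.9, 0.95],
        "batch_size": list(mt.BATCH_SIZES),
        "gradient_clipping": [False, True],
        "imbalance_sampling": [False, True],
    })
    lr_range: tuple[float, float] = (1e-4, 1e-2)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes) + ["learning_rate"]

    def sample(self, rng: np.random.Generator) -> mt.TrialConfiguration:
        values = {k: v[rng.integers(len(v))] for k, v in self.genes.items()}
        lo, hi = self.lr_range
        values["learning_rate"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return mt.TrialConfiguration(**values)


@dataclass
class Trial:
    trial_id: int
    config: mt.TrialConfiguration
    meta_losses: dict[str, float] = field(default_factory=dict)
    total_meta_loss: float = math.nan
    metrics: dict[str, float] = field(default_factory=dict)
    status: str = "pending"  # ok | failed | pending
    model_state: list | None = None
    result: object = None

    def objective_vector(self, task_names: list[str], worst: float = 1.0) -> np.ndarray:
        return np.array([
            self.meta_losses.get(t, worst) if math.isfinite(
                self.meta_losses.get(t, math.nan)) else worst
            for t in task_names
        ])


# ---------------------------------------------------------------------------
# NSGA-II primitives
# ---------------------------------------------------------------------------


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """a dominates b: no objective worse, at least one strictly better (minimize)."""
    return bool(np.all(a <= b) and np.any(a < b))


def fast_non_dominated_sort(objectives: np.ndarray) -> list[list[int]]:
    """Deb's fast non-dominated sorting; returns fronts of indices."""
    n = len(objectives)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objectives[i], objectives[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(objectives[j], objectives[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    fronts: list[list[int]] = [[i for i in range(n) if domination_count[i] == 0]]
    while fronts[-1]:
        nxt: list[int] = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(objectives: np.ndarray, front: list[int]) -> dict[int, float]:
    """Crowding distance within one front; boundary solutions get infinity."""
    dist = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: math.inf for i in front}
    arr = objectives[front]
    for m in range(arr.shape[1]):
        order = np.argsort(arr[:, m], kind="stable")
        lo, hi = arr[order[0], m], arr[order[-1], m]
        dist[front[order[0]]] = math.inf
        dist[front[order[-1]]] = math.inf
        span = hi - lo
        if span <= 0:
            continue
        for pos in range(1, len(order) - 1):
            i = front[order[pos]]
            if not math.isinf(dist[i]):
                dist[i] += (arr[order[pos + 1], m] - arr[order[pos - 1], m]) / span
    return dist


def _config_genes(config: mt.TrialConfiguration, space: ConfigurationSpace) -> dict:
    d = config.as_dict()
    return {k: d[k] for k in space.gene_names}


def nsga2_step(
    population: list[Trial],
    space: ConfigurationSpace,
    task_names: list[str],
    seed: int,
    n_offspring: int | None = None,
) -> list[mt.TrialConfiguration]:
    """Produce the next generation of configurations.

    Parents are chosen by binary tournament on (non-domination rank, crowding
    distance); uniform crossover fires with probability 0.9 and swaps each
    gene with probability 0.5; no mutation by default. With an empty
    population, configurations are sampled uniformly from the space.
    """
    rng = np.random.default_rng(seed)
    n_offspring = n_offspring or (len(population) if population else POPULATION_SIZE)
    if not population:
        return [space.sample(rng) for _ in range(n_offspring)]

    objectives = np.array([t.objective_vector(task_names) for t in population])
    fronts = fast_non_dominated_sort(objectives)
    rank = {}
    crowd = {}
    for r, front in enumerate(fronts):
        cd = crowding_distance(objectives, front)
        for i in front:
            rank[i] = r
            crowd[i] = cd[i]

    def tournament() -> int:
        a, b = rng.integers(len(population)), rng.integers(len(population))
        if rank[a] != rank[b]:
            return a if rank[a] < rank[b] else b
        if crowd[a] != crowd[b]:
            return a if crowd[a] > crowd[b] else b
        return min(a, b)

    offspring: list[mt.TrialConfiguration] = []
    while len(offspring) < n_offspring:
        p1 = _config_genes(population[tournament()].config, space)
        p2 = _config_genes(population[tournament()].config, space)
        c1, c2 = dict(p1), dict(p2)
        if rng.random() < CROSSOVER_PROB:
            for gene in space.gene_names:
                if rng.random() < GENE_SWAP_PROB:
                    c1[gene], c2[gene] = c2[gene], c1[gene]
        for child in (c1, c2):
            if len(offspring) < n_offspring:
                offspring.append(mt.TrialConfiguration(**child))
    return offspring


def hypervolume_2d(points: np.ndarray, reference: tuple[float, float]) -> float:
    """Dominated hypervolume of a 2-objective minimization front."""
    pts = np.asarray([p for p in points if p[0] <= reference[0] and p[1] <= reference[1]])
    if len(pts) == 0:
        return 0.0
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    hv = 0.0
    prev_y = reference[1]
    best_y = math.inf
    for x, y in pts:
        if y < best_y:
            hv += (reference[0] - x) * (min(prev_y, best_y) - y)
            best_y = y
            prev_y = best_y
    return hv


# ---------------------------------------------------------------------------
# trial execution
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    """Arrays for one split set (inputs built lazily per representation)."""

    images: list  # FiberImage per sample
    priors: np.ndarray  # (N, n_priors), NaN = unavailable
    targets: np.ndarray  # (N, n_tasks)
    mask: np.ndarray  # (N, n_tasks)
    groups: np.ndarray  # (N,) group ids


class RepresentationCache:
    """Input tensors per (representation, downsample) combination.

    Trials sharing a data representation reuse the same stacked input matrix;
    augmentation still randomizes per batch at train time.
    """

    def __init__(self):
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, images, config: mt.TrialConfiguration, tag: str) -> np.ndarray:
        key = (tag, config.representation, config.downsample)
        if key not in self._store:
            self._store[key] = np.stack(
                [mt.build_representation(img, config) for img in images])
        return self._store[key]


def _representation_matrix(images, config, cache: RepresentationCache | None = None,
                           tag: str = "") -> np.ndarray:
    if cache is not None:
        return cache.get(images, config, tag)
    return np.stack([mt.build_representation(img, config) for img in images])


def _prior_features(priors: np.ndarray) -> np.ndarray:
    """NaN-safe prior inputs: unavailable entries imputed to 0 (the train mean
    on normalized priors)."""
    return np.nan_to_num(np.asarray(priors, dtype=np.float64))


def assemble_trial_data(
    cohort,
    split,
    task_names: list[str],
    prior_names: tuple[str, ...] = ("cas2d", "cas3d", "vd", "sl", "csa"),
    compute_priors: bool = True,
    orientation_scale: float = 1.0,
) -> dict[str, TrialData]:
    """Build per-set TrialData from a synthetic cohort and a split.

    Priors are computed from each image (with the generator's foreground mask)
    and z-scored with train-only statistics; labels are likewise normalized
    for continuous tasks. Unavailable priors stay NaN (masked downstream).
    """
    import pandas as pd

    from fiberlearn import priors as pr
    from fiberlearn.cohort import fit_apply_normalization

    rows = []
    for s in cohort.samples:
        row = {"sample_id": s.sample_id}
        if compute_priors:
            pv = pr.compute_priors(s.image, mask=s.truth.get("mask"),
                                   orientation_scale=orientation_scale)
            row.update(pv.as_dict())
        row.update({t: s.labels.get(t, math.nan) for t in task_names})
        rows.append(row)
    table = pd.DataFrame(rows)

    kinds = [cohort.link.tasks[t].kind for t in task_names]
    continuous = [t for t, k in zip(task_names, kinds) if k == "continuous"]
    norm_cols = (list(prior_names) if compute_priors else []) + continuous
    table, _ = fit_apply_normalization(table, split, norm_cols)

    out: dict[str, TrialData] = {}
    for set_name in ("train", "dev", "test"):
        ids = [s.sample_id for s in cohort.samples
               if split.assignment[s.sample_id] == set_name]
        sel = table["sample_id"].isin(ids)
        sub = table[sel]
        samples = [s for s in cohort.samples if s.sample_id in set(ids)]
        priors = (sub[list(prior_names)].to_numpy(dtype=float)
                  if compute_priors else np.zeros((len(sub), 0)))
        targets = sub[task_names].to_numpy(dtype=float)
        out[set_name] = TrialData(
            images=[s.image for s in samples],
            priors=priors,
            targets=np.nan_to_num(targets),
            mask=np.isfinite(targets),
            groups=np.array([s.group_id for s in samples]),
        )
    return out


def priors_only_trial(
    train: TrialData,
    dev: TrialData,
    task_names: list[str],
    task_kinds: list[str],
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float], dict]:
    """Features-only AutoML over the priors (no images).

    A small search over top-k feature selection (k = 1..n_priors, capped at 5)
    crossed with three probabilistic estimator families (L2 linear, random
    forest, k-NN), scored by grouped two-fold cross-validation on the combined
    train+dev samples. Returns (metrics, meta_losses, fitted pipelines).
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.feature_selection import SelectKBest, f_classif, f_regression
    from sklearn.linear_model import LogisticRegression, Ridge
    from sklearn.model_selection import GroupKFold
    from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
    from sklearn.pipeline import Pipeline

    X = np.vstack([_prior_features(train.priors), _prior_features(dev.priors)])
    Y = np.vstack([train.targets, dev.targets])
    M = np.vstack([train.mask, dev.mask])
    groups = np.concatenate([train.groups, dev.groups])

    metrics: dict[str, float] = {}
    pipelines: dict = {}
    for j, (name, kind) in enumerate(zip(task_names, task_kinds)):
        sel = M[:, j]
        Xj, yj, gj = X[sel], Y[sel, j], groups[sel]
        if sel.sum() < 8 or len(np.unique(gj)) < 2:
            metrics[name] = math.nan
            continue
        if kind == "binary" and len(np.unique(yj)) < 2:
            metrics[name] = math.nan
            continue
        if kind == "binary":
            estimators = [
                ("linear", LogisticRegression(C=1.0, max_iter=500)),
                ("forest", RandomForestClassifier(n_estimators=60, random_state=seed)),
                ("knn", KNeighborsClassifier(n_neighbors=min(5, int(sel.sum()) // 2))),
            ]
            score_fn = f_classif
        else:
            estimators = [
                ("linear", Ridge(alpha=1.0)),
                ("forest", RandomForestRegressor(n_estimators=60, random_state=seed)),
                ("knn", KNeighborsRegressor(n_neighbors=min(5, int(sel.sum()) // 2))),
            ]
            score_fn = f_regression
        best = -math.inf
        best_pipe = None
        n_splits = 2
        cv = GroupKFold(n_splits=n_splits)
        for k in range(1, min(5, Xj.shape[1]) + 1):
            for est_name, est in estimators:
                fold_scores = []
                try:
                    for tr_idx, te_idx in cv.split(Xj, yj, gj):
                        if kind == "binary" and len(np.unique(yj[tr_idx])) < 2:
                            raise ValueError("single-class fold")
                        pipe = Pipeline([
                            ("select", SelectKBest(score_fn, k=k)),
                            ("est", est.__class__(**est.get_params())),
                        ])
                        pipe.fit(Xj[tr_idx], yj[tr_idx])
                        if kind == "binary":
                            prob = pipe.predict_proba(Xj[te_idx])[:, 1]
                            fold_scores.append(mt.roc_auc(yj[te_idx], prob))
                        else:
                            pred = pipe.predict(Xj[te_idx])
                            fold_scores.append(mt.r_squared(yj[te_idx], pred))
                except ValueError:
                    continue
                if fold_scores and np.all(np.isfinite(fold_scores)):
                    score = float(np.mean(fold_scores))
                    if score > best:
                        best = score
                        best_pipe = (k, est_name)
        metrics[name] = best if math.isfinite(best) else math.nan
        pipelines[name] = best_pipe
    meta = mt.meta_losses_from_metrics(metrics)
    return metrics, meta, pipelines


def run_trial(
    trial_id: int,
    config: mt.TrialConfiguration,
    train: TrialData,
    dev: TrialData,
    task_names: list[str],
    task_kinds: list[str],
    budget: int = 150,
    seed: int = 0,
    task_weights: dict[str, float] | None = None,
    worst_seen: float = 1.0,
    cache: RepresentationCache | None = None,
    priors_only_cache: dict | None = None,
) -> Trial:
    """Evaluate one configuration into a Trial record.

    PriorsOnly dispatches to the AutoML path and never touches image tensors;
    failed network training yields worst-observed + 10% objectives so the
    trial stays in the population but out of the Pareto fronts.
    """
    trial = Trial(trial_id=trial_id, config=config)
    if config.prior_integration == "PriorsOnly":
        # the AutoML result depends only on the data (its DaRe/NN genes are
        # inert), so repeated PriorsOnly genotypes reuse one evaluation
        if priors_only_cache is not None and "result" in priors_only_cache:
            metrics, meta, _ = priors_only_cache["result"]
        else:
            result_po = priors_only_trial(train, dev, task_names, task_kinds, seed)
            if priors_only_cache is not None:
                priors_only_cache["result"] = result_po
            metrics, meta, _ = result_po
        trial.metrics = metrics
        trial.meta_losses = meta
        trial.total_meta_loss = mt.total_meta_loss(meta, task_weights)
        trial.status = "ok" if any(math.isfinite(v) for v in meta.values()) else "failed"
    else:
        n_priors = train.priors.shape[1]
        use_aux = config.prior_integration in ("AuxLosses", "AuxLosses@Branches")
        tr_t, tr_m = train.targets, train.mask
        dv_t, dv_m = dev.targets, dev.mask
        if use_aux:
            tr_t = np.hstack([tr_t, _prior_features(train.priors)])
            tr_m = np.hstack([tr_m, np.isfinite(train.priors)])
            dv_t = np.hstack([dv_t, _prior_features(dev.priors)])
            dv_m = np.hstack([dv_m, np.isfinite(dev.priors)])
        result = mt.train_trial(
            _representation_matrix(train.images, config, cache, "train"), tr_t, tr_m,
            _prior_features(train.priors),
            _representation_matrix(dev.images, config, cache, "dev"), dv_t, dv_m,
            _prior_features(dev.priors),
            task_names, task_kinds, config, budget=budget, seed=seed,
            task_weights=task_weights,
        )
        trial.result = result
        if result.failed or not result.best_meta:
            trial.status = "failed"
        else:
            trial.status = "ok"
            trial.metrics = result.best_metrics
            trial.meta_losses = result.best_meta
            trial.total_meta_loss = result.best_total_meta
            trial.model_state = result.best_snapshots.get("__total__")
    if trial.status == "failed":
        bad = worst_seen * (1 + FAILED_TRIAL_MARGIN) + FAILED_TRIAL_MARGIN
        trial.meta_losses = {t: bad for t in task_names}
        trial.total_meta_loss = mt.total_meta_loss(trial.meta_losses, task_weights)
    return trial


def select_models(
    trials: list[Trial],
    task_sizes: dict[str, int],
    scarce_threshold: int = SCARCE_TASK_N,
) -> dict[str, Trial]:
    """Per-task model selection.

    Tasks with >= ``scarce_threshold`` labelled samples take the trial with
    the lowest task meta-loss; scarcer tasks take the trial with the lowest
    total meta-loss. Ties break toward the earlier trial id.
    """
    ok = [t for t in trials if t.status == "ok"]
    if not ok:
        raise ValueError("no successful trials to select from")
    selected: dict[str, Trial] = {}
    best_total = min(ok, key=lambda t: (t.total_meta_loss if math.isfinite(
        t.total_meta_loss) else math.inf, t.trial_id))
    for task, n in task_sizes.items():
        if n < scarce_threshold:
            selected[task] = best_total
        else:
            with_task = [t for t in ok if math.isfinite(t.meta_losses.get(task, math.nan))]
            selected[task] = (min(with_task, key=lambda t: (t.meta_losses[task], t.trial_id))
                              if with_task else best_total)
    return selected


def top_trials_summary(trials: list[Trial], task_names: list[str], k: int = 50) -> dict[str, float]:
    """Mean dev metric of the k best trials per task (all trials when fewer)."""
    out: dict[str, float] = {}
    ok = [t for t in trials if t.status == "ok"]
    for task in task_names:
        vals = sorted((t.meta_losses[task] for t in ok
                       if math.isfinite(t.meta_losses.get(task, math.nan))))
        vals = vals[:k]
        out[task] = 1.0 - float(np.mean(vals)) if vals else math.nan
    return out


def mechanism_recovery_experiment(
    seed: int,
    n: int = 200,
    shape: tuple[int, int, int] = (16, 32, 24),
    n_trials: int = 60,
    population_size: int = 10,
    budget: int = 6,
    n_baseline: int = 3,
) -> dict:
    """One seeded run of the prior-integration recovery experiment.

    A cohort whose binary task rides on prior-visible structure (myofibril
    dispersion, hence CAS) is generated at low image SNR; a compact NSGA-II
    search runs over the full configuration space, and the selected model for
    the prior-driven task is compared against a control arm of image-only
    (NoPriors) trials with otherwise random configurations.
    """
    from fiberlearn.cohort import stratified_group_split
    from fiberlearn.synthgen import make_cohort, prior_driven_design

    task_names = ["dystrophic", "active_force"]
    task_kinds = ["binary", "continuous"]
    studies, link = prior_driven_design(n, shape=shape)
    cohort = make_cohort(n, studies=studies, link=link, seed=seed, shape=shape)
    split = stratified_group_split(cohort.manifest(),
                                   dict(zip(task_names, task_kinds)), seed=seed)
    data = assemble_trial_data(cohort, split, task_names,
                               orientation_scale=0.75)
    result = run_self_enhancement(
        data["train"], data["dev"], task_names, task_kinds,
        n_trials=n_trials, population_size=population_size,
        budget=budget, seed=seed)

    selected = result.selected["dystrophic"]
    search_nopriors = [
        t.metrics["dystrophic"] for t in result.trials
        if t.status == "ok" and t.config.prior_integration == "NoPriors"
        and math.isfinite(t.metrics.get("dystrophic", math.nan))]
    # control arm: explicit image-only trials with random remaining genes
    space = ConfigurationSpace()
    rng = np.random.default_rng(seed + 10_000)
    cache = RepresentationCache()
    control = list(search_nopriors)
    while len(control) < n_baseline:
        config = space.sample(rng)
        config = mt.TrialConfiguration(**{**config.as_dict(),
                                          "prior_integration": "NoPriors"})
        trial = run_trial(-1, config, data["train"], data["dev"], task_names,
                          task_kinds, budget=budget,
                          seed=int(rng.integers(2**31 - 1)), cache=cache)
        if trial.status == "ok" and math.isfinite(
                trial.metrics.get("dystrophic", math.nan)):
            control.append(trial.metrics["dystrophic"])
    return {
        "selected_integration": selected.config.prior_integration,
        "selected_dev_auc": float(selected.metrics.get("dystrophic", math.nan)),
        "nopriors_arm_mean_auc": float(np.mean(control)),
        "n_trials": len(result.trials),
    }


@dataclass
class SelfEnhancementResult:
    trials: list[Trial]
    selected: dict[str, Trial]
    summary: dict[str, float]
    labbook: Labbook


def run_self_enhancement(
    train: TrialData,
    dev: TrialData,
    task_names: list[str],
    task_kinds: list[str],
    space: ConfigurationSpace | None = None,
    n_trials: int = 100,
    population_size: int = POPULATION_SIZE,
    budget: int = 150,
    seed: int = 42,
    task_weights: dict[str, float] | None = None,
    labbook: Labbook | None = None,
) -> SelfEnhancementResult:
    """Generational NSGA-II loop over trial configurations.

    Every trial is appended to the labbook (configuration, objectives,
    status), so a run is resumable and auditable. Deterministic for a fixed
    seed.
    """
    space = space or ConfigurationSpace()
    if labbook is None:
        labbook = Labbook()
    rng = np.random.default_rng(seed)
    task_sizes = {
        t: int(train.mask[:, j].sum() + dev.mask[:, j].sum())
        for j, t in enumerate(task_names)
    }

    trials: list[Trial] = []
    population: list[Trial] = []
    cache = RepresentationCache()
    po_cache: dict = {}
    worst = 1.0
    trial_id = 0
    while trial_id < n_trials:
        n_new = min(population_size, n_trials - trial_id)
        configs = nsga2_step(population, space, task_names,
                             seed=int(rng.integers(2**31 - 1)), n_offspring=n_new)
        generation: list[Trial] = []
        for config in configs:
            trial = run_trial(trial_id, config, train, dev, task_names, task_kinds,
                              budget=budget, seed=int(rng.integers(2**31 - 1)),
                              task_weights=task_weights, worst_seen=worst, cache=cache,
                              priors_only_cache=po_cache)
            finite = [v for v in trial.meta_losses.values() if math.isfinite(v)]
            if trial.status == "ok" and finite:
                worst = max(worst, max(finite))
            labbook.log("trial", trial_id=trial.trial_id, config=config.as_dict(),
                        meta_losses=trial.meta_losses,
                        total_meta_loss=trial.total_meta_loss,
                        metrics=trial.metrics, status=trial.status)
            generation.append(trial)
            trials.append(trial)
            trial_id += 1
        # (mu + lambda) survival: parents compete with offspring
        pool = population + generation
        objectives = np.array([t.objective_vector(task_names, worst * 1.2)
                               for t in pool])
        fronts = fast_non_dominated_sort(objectives)
        survivors: list[Trial] = []
        for front in fronts:
            if len(survivors) + len(front) <= population_size:
                survivors.extend(pool[i] for i in front)
            else:
                cd = crowding_distance(objectives, front)
                ranked = sorted(front, key=lambda i: (-cd[i], pool[i].trial_id))
                survivors.extend(pool[i] for i in
                                 ranked[: population_size - len(survivors)])
                break
        population = survivors

    selected = select_models(trials, task_sizes)
    summary = top_trials_summary(trials, task_names)
    return SelfEnhancementResult(trials=trials, selected=selected,
                                 summary=summary, labbook=labbook)
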