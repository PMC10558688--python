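"""Two-level explanations of the self-enhancement process and its models.

Model level: a random-forest surrogate maps configurations to dev performance,
and interventional Shapley values attribute that performance to individual
configuration decisions (exact subset enumeration for small spaces,
permutation sampling otherwise; permutation estimates are exactly additive per
sample by the telescoping property).

Sample level: expected-gradients attribution over the image input — and,
for models with a prior branch, jointly over the prior inputs on the same
scale. For piecewise-linear networks the path integral converges to an
attribution satisfying the completeness axiom: attributions sum to the
output difference against the baseline.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from fiberlearn import nn
from fiberlearn.metaopt import Trial

ORDERED_GENES = {"capacity", "batch_size", "momentum", "learning_rate"}


@dataclass
class ConfigEncoder:
    """Trial configurations -> numeric design matrix.

    Ordered genes (capacity, batch size, momentum, learning rate) are encoded
    ordinally; unordered categoricals are one-hot, with all member columns of
    a dimension grouped for attribution.
    """

    dimensions: list[str] = field(default_factory=list)
    columns: list[tuple[str, object]] = field(default_factory=list)  # (dim, level|None)

    @classmethod
    def fit(cls, trials: list[Trial]) -> "ConfigEncoder":
        enc = cls()
        sample = trials[0].config.as_dict()
        enc.dimensions = list(sample)
        for dim in enc.dimensions:
            values = sorted({t.config.as_dict()[dim] for t in trials}, key=str)
            if dim in ORDERED_GENES or isinstance(sample[dim], bool):
                enc.columns.append((dim, None))
            else:
                for v in values:
                    enc.columns.append((dim, v))
        return enc

    def transform(self, trials: list[Trial]) -> np.ndarray:
        X = np.zeros((len(trials), len(self.columns)))
        for i, t in enumerate(trials):
            d = t.config.as_dict()
            for j, (dim, level) in enumerate(self.columns):
                if level is None:
                    X[i, j] = float(d[dim])
                else:
                    X[i, j] = float(d[dim] == level)
        return X

    def column_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for j, (dim, _) in enumerate(self.columns):
            groups.setdefault(dim, []).append(j)
        return groups


def fit_surrogate(trials: list[Trial], task: str, seed: int = 0,
                  n_estimators: int = 500, min_trials: int = 30):
    """Random-forest surrogate (configuration -> dev metric) with held-out R².

    Returns (forest, encoder, X, y, oob_r2). Requires >= 30 completed trials
    with a finite metric on the task.
    """
    from sklearn.ensemble import RandomForestRegressor

    usable = [t for t in trials if t.status == "ok"
              and math.isfinite(t.metrics.get(task, math.nan))]
    if len(usable) < min_trials:
        raise ValueError(f"need >= {min_trials} completed trials, got {len(usable)}")
    enc = ConfigEncoder.fit(usable)
    X = enc.transform(usable)
    y = np.array([t.metrics[task] for t in usable])
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed,
                                   oob_score=True, bootstrap=True)
    forest.fit(X, y)
    oob = float(forest.oob_score_) if np.var(y) > 0 else math.nan
    return forest, enc, X, y, oob


@dataclass
class ConfigAttribution:
    dimensions: list[str]
    shapley: np.ndarray  # (n_trials, n_dimensions), units of the dev metric
    baseline: float

    def mean_abs(self) -> dict[str, float]:
        return dict(zip(self.dimensions, np.abs(self.shapley).mean(axis=0)))

    def ranking(self) -> list[str]:
        ma = self.mean_abs()
        return sorted(ma, key=lambda d: -ma[d])


def _shapley_exact(predict, x: np.ndarray, background: np.ndarray,
                   groups: dict[str, list[int]]) -> np.ndarray:
    """Interventional Shapley by exhaustive coalition enumeration."""
    dims = list(groups)
    n = len(dims)
    values = {}
    for subset in itertools.chain.from_iterable(
            itertools.combinations(range(n), r) for r in range(n + 1)):
        rows = background.copy()
        for d in subset:
            rows[:, groups[dims[d]]] = x[groups[dims[d]]]
        values[frozenset(subset)] = float(predict(rows).mean())
    phi = np.zeros(n)
    for d in range(n):
        for subset in itertools.chain.from_iterable(
                itertools.combinations([i for i in range(n) if i != d], r)
                for r in range(n)):
            s = frozenset(subset)
            weight = (math.factorial(len(s)) * math.factorial(n - len(s) - 1)
                      / math.factorial(n))
            phi[d] += weight * (values[s | {d}] - values[s])
    return phi


def _shapley_permutation(predict, x: np.ndarray, background: np.ndarray,
                         groups: dict[str, list[int]], rng: np.random.Generator,
                         n_permutations: int = 30) -> np.ndarray:
    """Permutation-sampling Shapley; exactly additive per permutation."""
    dims = list(groups)
    n = len(dims)
    n_bg = len(background)
    phi = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        # one batched prediction over all coalition stages of this permutation
        stages = np.empty((n + 1, n_bg, background.shape[1]))
        rows = background.copy()
        stages[0] = rows
        for s, d in enumerate(order, start=1):
            rows = rows.copy()
            rows[:, groups[dims[d]]] = x[groups[dims[d]]]
            stages[s] = rows
        values = predict(stages.reshape(-1, background.shape[1]))
        values = values.reshape(n + 1, n_bg).mean(axis=1)
        for s, d in enumerate(order, start=1):
            phi[d] += values[s] - values[s - 1]
    return phi / n_permutations


def config_shapley(
    surrogate,
    encoder: ConfigEncoder,
    X: np.ndarray,
    background: np.ndarray | None = None,
    method: str = "auto",
    seed: int = 0,
    n_permutations: int = 30,
    max_exact_dims: int = 10,
) -> ConfigAttribution:
    """Shapley attribution of each configuration dimension, per trial.

    Values are in the units of the surrogate's target (the dev metric);
    per-trial values sum to surrogate prediction − mean background prediction.
    """
    groups = encoder.column_groups()
    if background is None:
        background = X
    if len(background) > 20:
        bg_rng = np.random.default_rng(seed)
        background = background[bg_rng.choice(len(background), 20, replace=False)]
    if method == "auto":
        method = "exact" if len(groups) <= max_exact_dims else "permutation"
    rng = np.random.default_rng(seed)
    baseline = float(surrogate.predict(background).mean())
    rows = []
    for x in X:
        if method == "exact":
            rows.append(_shapley_exact(surrogate.predict, x, background, groups))
        else:
            rows.append(_shapley_permutation(surrogate.predict, x, background,
                                             groups, rng, n_permutations))
    return ConfigAttribution(dimensions=list(groups), shapley=np.array(rows),
                             baseline=baseline)


def attribution_stability(trials: list[Trial], task: str, seeds=(0, 1, 2),
                          n_estimators=(200, 500, 800), top_k: int = 3) -> float:
    """Refit surrogates across seeds/ensemble sizes; mean pairwise rank overlap
    of the top-k dimensions (1 = identical rankings)."""
    rankings = []
    for seed, n_est in zip(seeds, n_estimators):
        forest, enc, X, _, _ = fit_surrogate(trials, task, seed=seed,
                                             n_estimators=n_est)
        attr = config_shapley(forest, enc, X, method="permutation", seed=seed,
                              n_permutations=10)
        rankings.append(attr.ranking()[:top_k])
    overlaps = []
    for a, b in itertools.combinations(rankings, 2):
        overlaps.append(len(set(a) & set(b)) / top_k)
    return float(np.mean(overlaps))


# ---------------------------------------------------------------------------
# sample level
# ---------------------------------------------------------------------------


@dataclass
class SampleAttribution:
    image: np.ndarray  # same shape as the model input
    priors: np.ndarray  # (n_priors,) — empty for models without a prior branch
    output_value: float
    baseline_value: float

    @property
    def total(self) -> float:
        return float(self.image.sum() + self.priors.sum())


def _input_gradient(model, x_val: np.ndarray, p_val: np.ndarray | None,
                    output_index: int):
    x = nn.Tensor(x_val[None], requires_grad=True)
    p = nn.Tensor(p_val[None], requires_grad=True) if p_val is not None else None
    out = model(x, p)
    onehot = np.zeros_like(out.data)
    onehot[0, output_index] = 1.0
    out.backward(onehot)
    gx = x.grad[0]
    gp = p.grad[0] if p is not None else None
    return float(out.data[0, output_index]), gx, gp


def sample_attribution(
    model,
    image: np.ndarray,
    priors: np.ndarray | None = None,
    baselines: np.ndarray | None = None,
    baseline_priors: np.ndarray | None = None,
    output_index: int = 0,
    n_steps: int = 32,
) -> SampleAttribution:
    """Expected-gradients attribution jointly over image voxels and priors.

    For each baseline, gradients are integrated along the straight path from
    baseline to sample (midpoint rule, ``n_steps``); attributions are averaged
    over baselines. Exact for linear models at any step count; additivity
    (sum = output − mean baseline output) holds to the path-integration error.
    A model without a prior branch returns an empty prior block.
    """
    use_priors = getattr(model, "use_branch", False)
    if not use_priors:
        priors = None
    if baselines is None:
        baselines = np.zeros((1,) + image.shape)
    if baselines.ndim == image.ndim:
        baselines = baselines[None]
    if use_priors:
        if priors is None:
            raise ValueError("model has a prior branch; sample priors required")
        if baseline_priors is None:
            baseline_priors = np.zeros((len(baselines), len(priors)))

    img_attr = np.zeros_like(image, dtype=np.float64)
    pri_attr = np.zeros(len(priors)) if use_priors else np.zeros(0)
    base_vals = []
    for b_idx, base in enumerate(baselines):
        bp = baseline_priors[b_idx] if use_priors else None
        base_out, _, _ = _input_gradient(model, base, bp, output_index)
        base_vals.append(base_out)
        path_img = np.zeros_like(image, dtype=np.float64)
        path_pri = np.zeros(len(priors)) if use_priors else None
        for step in range(n_steps):
            alpha = (step + 0.5) / n_steps
            x_al = base + alpha * (image - base)
            p_al = bp + alpha * (priors - bp) if use_priors else None
            _, gx, gp = _input_gradient(model, x_al, p_al, output_index)
            path_img += gx
            if use_priors:
                path_pri += gp
        # (x - b) pairs with ITS OWN path integral; averaging the displacement
        # separately from the gradients would break completeness
        img_attr += (image - base) * path_img / n_steps
        if use_priors:
            pri_attr += (priors - bp) * path_pri / n_steps
    img_attr /= len(baselines)
    if use_priors:
        pri_attr /= len(baselines)
    out_val, _, _ = _input_gradient(model, image, priors if use_priors else None,
                                    output_index)
    return SampleAttribution(image=img_attr, priors=pri_attr,
                             output_value=out_val,
                             baseline_value=float(np.mean(base_vals)))
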