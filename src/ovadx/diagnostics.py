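"""Multi-indicator diagnostic pipeline.

The tabular half of the toolkit: z-score standardization of the 25-item
laboratory panel, principal component analysis on the correlation matrix
with the top 3 components retained, a stratified 2/3–1/3 train/test
split, and a single-hidden-layer back-propagation (BP) classifier whose
hidden size, weights and thresholds are chosen by a genetic algorithm
(GA). The classifier emits a continuous score in [0, 1] per subject
(logistic activations at hidden and output layers).

Demographics (age, menopausal, pregnancies) do not enter the PCA; they
are z-scored and appended to the 3 principal-component scores, giving 6
classifier inputs by default (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import DEMOGRAPHIC_NAMES, INDICATOR_NAMES

__all__ = [
    "StandardizedTable",
    "PCAModel",
    "BPNetwork",
    "GAConfig",
    "SplitResult",
    "zscore_standardize",
    "fit_pca",
    "project_scores",
    "stratified_split",
    "ga_optimize_bp",
    "predict_scores",
    "group_mean_profile",
    "DiagnosticModel",
    "fit_diagnostic_model",
]


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizedTable:
    """Z-scored values with the training-column parameters retained."""

    values: np.ndarray
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    index: np.ndarray


def zscore_standardize(table, fit_rows=None, columns=None) -> StandardizedTable:
    """Standardize columns to mean 0, sd 1 (sample sd, n−1 denominator).

    Parameters are estimated on ``fit_rows`` (default: all rows) and
    applied to every row, so held-out subjects are transformed with the
    training statistics. A constant training column maps to zeros with a
    warning.
    """
    cols = tuple(columns) if columns is not None else tuple(
        c for c in INDICATOR_NAMES if c in table.columns
    )
    values = table[list(cols)].to_numpy(dtype=float)
    fit_idx = (
        np.asarray(fit_rows, dtype=int) if fit_rows is not None
        else np.arange(len(values))
    )
    if fit_idx.size == 0:
        raise ValueError("fit_rows is empty")
    fit = values[fit_idx]
    means = fit.mean(axis=0)
    sds = fit.std(axis=0, ddof=1) if len(fit) > 1 else np.ones(len(cols))
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"constant column(s) {[c for c, k in zip(cols, constant) if k]}: "
            "standardized to zeros"
        )
        sds = np.where(constant, 1.0, sds)
    z = (values - means) / sds
    z[:, constant] = 0.0
    return StandardizedTable(
        values=z, columns=cols, means=means, sds=sds,
        index=np.asarray(table.index),
    )


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Eigen-decomposition of the training correlation matrix.

    ``eigenvectors[:, k]`` is the loading vector of component k+1 (the
    P1..P3 linear forms when k < n_selected); eigenvalues are descending.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    columns: tuple[str, ...]
    n_selected: int = 3

    @property
    def loadings(self) -> np.ndarray:
        """(p, n_selected) loading matrix of the retained components."""
        return self.eigenvectors[:, : self.n_selected]


def fit_pca(table: StandardizedTable, n_selected: int = 3,
            fit_rows=None) -> PCAModel:
    """Eigen-decompose the correlation matrix of z-scored indicators.

    Because the input is z-scored with the sample sd, the covariance of
    the fit rows *is* the correlation matrix; its trace equals the number
    of columns.
    """
    z = table.values if fit_rows is None else table.values[np.asarray(fit_rows)]
    n, p = z.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    corr = (z.T @ z) / (n - 1)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign fix: largest-|loading| entry positive, per component
    flip = eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(p)] < 0
    eigvecs = eigvecs * np.where(flip, -1.0, 1.0)
    return PCAModel(
        eigenvectors=eigvecs, eigenvalues=eigvals,
        columns=table.columns, n_selected=n_selected,
    )


def project_scores(model: PCAModel, table: StandardizedTable) -> np.ndarray:
    """Principal-component scores: z-values × selected eigenvectors."""
    if table.columns != model.columns:
        raise ValueError(
            f"column roster mismatch: table has {table.columns}, "
            f"model expects {model.columns}"
        )
    return table.values @ model.loadings


# --------------------------------------------------------------------------
# Stratified split
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitResult:
    train_ids: np.ndarray
    test_ids: np.ndarray
    stratum_counts: dict


def stratified_split(table, fraction: float = 2 / 3, seed: int = 0,
                     stratify_by: str = "subgroup") -> SplitResult:
    """Seeded stratified split: per stratum, floor(fraction × n) rows go
    to training, the remainder to test."""
    rng = np.random.default_rng(seed)
    train, test, counts = [], [], {}
    for stratum in sorted(table[stratify_by].unique()):
        idx = table.index[table[stratify_by] == stratum].to_numpy()
        if idx.size == 0:
            continue
        perm = idx[rng.permutation(idx.size)]
        n_train = int(np.floor(fraction * idx.size))
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
        counts[stratum] = (n_train, idx.size - n_train)
    return SplitResult(
        train_ids=np.sort(np.asarray(train)),
        test_ids=np.sort(np.asarray(test)),
        stratum_counts=counts,
    )


# --------------------------------------------------------------------------
# GA-optimized BP network
# --------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class BPNetwork:
    """One-hidden-layer feed-forward classifier, logistic throughout."""

    W1: np.ndarray  # (hidden, inputs)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"expected {self.W1.shape[1]} features, got {X.shape[1]}"
            )
        h = _logistic(X @ self.W1.T + self.b1)
        return _logistic(h @ self.W2 + self.b2)


def predict_scores(net: BPNetwork, X: np.ndarray) -> np.ndarray:
    """Continuous diagnostic scores in [0, 1], one per row."""
    return net.predict(X)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (real-valued encoding, tournament
    selection, elitism). ``fitness`` is the validation criterion the GA
    minimizes: "cross_entropy" or "error_rate"."""

    population_size: int = 40
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    hidden_size_range: tuple[int, int] = (2, 20)
    elitism_count: int = 2
    fitness: str = "cross_entropy"
    validation_fraction: float = 0.25
    fine_tune: bool = False
    fine_tune_steps: int = 200
    fine_tune_lr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("GA rates must lie in [0, 1]")
        lo, hi = self.hidden_size_range
        if lo < 1 or hi < lo:
            raise ValueError("hidden_size_range must be a nonempty range")
        if self.fitness not in ("cross_entropy", "error_rate"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


def _decode(chrom: np.ndarray, d: int, h_max: int, lo: int, hi: int) -> BPNetwork:
    """Chromosome = [hidden-size gene | W1 block | b1 | W2 | b2] sized for
    ``h_max`` hidden units; only the first h decoded units are active."""
    h = int(np.clip(np.floor(chrom[0]), lo, hi))
    off = 1
    W1 = chrom[off : off + h_max * d].reshape(h_max, d)[:h]
    off += h_max * d
    b1 = chrom[off : off + h_max][:h]
    off += h_max
    W2 = chrom[off : off + h_max][:h]
    off += h_max
    return BPNetwork(W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=float(chrom[off]))


def _fitness_value(net: BPNetwork, X, y, kind: str) -> float:
    p = np.clip(net.predict(X), 1e-12, 1 - 1e-12)
    if kind == "error_rate":
        return float(np.mean((p >= 0.5).astype(int) != y))
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def ga_optimize_bp(X: np.ndarray, y: np.ndarray,
                   ga: GAConfig = GAConfig()) -> BPNetwork:
    """Evolve the BP classifier's hidden size, weights and thresholds.

    Fitness is the validation error on an internal seeded split of the
    training rows. Elitism guarantees the best-so-far fitness sequence is
    non-worsening; the best individual's network is returned, optionally
    fine-tuned by gradient back-propagation on the full training set. The
    per-generation best-fitness trace is attached as ``net.history``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(ga.seed)
    n, d = X.shape
    lo, hi = ga.hidden_size_range
    h_max = hi
    length = 1 + h_max * d + h_max + h_max + 1

    # internal validation split (stratified at random, seeded)
    order = rng.permutation(n)
    n_val = max(1, int(round(ga.validation_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
        val_idx, tr_idx = order[: max(2, n_val)], order
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    def evaluate(chrom):
        return _fitness_value(
            _decode(chrom, d, h_max, lo, hi), Xval, yval, ga.fitness
        )

    pop = rng.standard_normal((ga.population_size, length))
    pop[:, 0] = rng.uniform(lo, hi + 1, size=ga.population_size)
    fit = np.array([evaluate(c) for c in pop])
    history = []
    for _ in range(ga.generations):
        elite_idx = np.argsort(fit)[: ga.elitism_count]
        new_pop = [pop[i].copy() for i in elite_idx]
        while len(new_pop) < ga.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, ga.population_size, size=2)
                parents.append(pop[a] if fit[a] <= fit[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_rate:  # blend (arithmetic) crossover
                alpha = rng.random(length)
                c1, c2 = alpha * c1 + (1 - alpha) * c2, alpha * c2 + (1 - alpha) * c1
            for c in (c1, c2):
                m = rng.random(length) < ga.mutation_rate
                c[m] += rng.standard_normal(m.sum()) * 0.5
                c[0] = np.clip(c[0], lo, hi + 0.999)
                if len(new_pop) < ga.population_size:
                    new_pop.append(c)
        pop = np.array(new_pop)
        fit = np.array([evaluate(c) for c in pop])
        history.append(float(fit.min()))

    best = pop[int(np.argmin(fit))]
    net = _decode(best, d, h_max, lo, hi)
    if ga.fine_tune:
        net = _backprop_fine_tune(net, X, y, ga.fine_tune_steps, ga.fine_tune_lr)
    object.__setattr__(net, "history", history)  # frozen dataclass, attach trace
    return net


def _backprop_fine_tune(net: BPNetwork, X, y, steps: int, lr: float) -> BPNetwork:
    """Full-batch gradient descent on cross-entropy from the GA solution."""
    W1, b1, W2, b2 = (net.W1.copy(), net.b1.copy(), net.W2.copy(), net.b2)
    n = len(X)
    for _ in range(steps):
        h = _logistic(X @ W1.T + b1)
        p = _logistic(h @ W2 + b2)
        delta = (p - y) / n
        gW2 = h.T @ delta
        gb2 = delta.sum()
        dh = np.outer(delta, W2) * h * (1 - h)
        gW1 = dh.T @ X
        gb1 = dh.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
    return BPNetwork(W1=W1, b1=b1, W2=W2, b2=float(b2))


# --------------------------------------------------------------------------
# Group profiles and the end-to-end model
# --------------------------------------------------------------------------

def group_mean_profile(table, indicators=None):
    """Per-indicator case mean, control mean, and direction of difference.

    Direction is sign(case mean − control mean): −1 where the cancer
    group runs lower (E2, P, AGR, PA, TC on default synthetic cohorts).
    """
    import pandas as pd

    indicators = list(indicators) if indicators is not None else [
        c for c in INDICATOR_NAMES if c in table.columns
    ]
    cases = table[table["label"] == "case"]
    controls = table[table["label"] == "control"]
    if cases.empty or controls.empty:
        raise ValueError("both case and control groups must be nonempty")
    case_mean = cases[indicators].mean()
    control_mean = controls[indicators].mean()
    diff = case_mean - control_mean
    return pd.DataFrame({
        "case_mean": case_mean,
        "control_mean": control_mean,
        "direction": np.sign(diff).astype(int),
    })


@dataclass(frozen=True)
class DiagnosticModel:
    """Fitted pipeline bundle: scaler parameters, PCA, classifier, split."""

    scaler: StandardizedTable
    demo_scaler: StandardizedTable | None
    pca: PCAModel
    net: BPNetwork
    split: SplitResult
    use_demographics: bool = True

    def features(self, table) -> np.ndarray:
        z = StandardizedTable(
            values=(table[list(self.scaler.columns)].to_numpy(dtype=float)
                    - self.scaler.means) / self.scaler.sds,
            columns=self.scaler.columns,
            means=self.scaler.means, sds=self.scaler.sds,
            index=np.asarray(table.index),
        )
        pcs = project_scores(self.pca, z)
        if not self.use_demographics:
            return pcs
        demo = (table[list(DEMOGRAPHIC_NAMES)].to_numpy(dtype=float)
                - self.demo_scaler.means) / self.demo_scaler.sds
        return np.hstack([pcs, demo])

    def predict(self, table) -> np.ndarray:
        return predict_scores(self.net, self.features(table))


def fit_diagnostic_model(table, seed: int = 0, ga: GAConfig | None = None,
                         n_components: int = 3,
                         use_demographics: bool = True) -> DiagnosticModel:
    """Full pipeline on a labeled cohort: stratified 2/3 split → z-score
    (training statistics) → correlation PCA top-``n_components`` → GA-BP.
    """
    split = stratified_split(table, seed=seed)
    train_pos = np.searchsorted(np.asarray(table.index), split.train_ids)
    scaler = zscore_standardize(table, fit_rows=train_pos)
    pca = fit_pca(scaler, n_selected=n_components, fit_rows=train_pos)
    pcs = project_scores(pca, scaler)
    demo_scaler = None
    feats = pcs
    if use_demographics:
        demo_scaler = zscore_standardize(
            table, fit_rows=train_pos, columns=DEMOGRAPHIC_NAMES
        )
        feats = np.hstack([pcs, demo_scaler.values])
    y = (table["label"].to_numpy() == "case").astype(int)
    ga = ga or GAConfig(seed=seed)
    net = ga_optimize_bp(feats[train_pos], y[train_pos], ga)
    return DiagnosticModel(
        scaler=scaler, demo_scaler=demo_scaler, pca=pca, net=net,
        split=split, use_demographics=use_demographics,
    )
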