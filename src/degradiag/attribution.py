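"""Shapley-value attribution of degradation scores to environmental drivers.

The target variable is a per-unit *degradation score*: the signed change in
the composite quality grade (for the composite type) or in the diagnostic
property grade (for a single type) between the two epochs.  Higher score =
mitigation, lower = degradation.  Eleven drivers spanning topography (DEM,
ASPECT, SLOPE), climate (MAP, MAT), location (Dist.Rivers, Dist.Roads),
socio-economy (POP, GDP) and management (SRR straw-return rate, FAR
fertilizer-application rate) are screened for multicollinearity (VIF < 5),
a gradient-boosted surrogate is fitted to the score, and each driver's
contribution to each prediction is measured by its Shapley value

    phi_i = (1/|K|!) * sum over orderings R of [ v(S_R^i + {i}) - v(S_R^i) ]

where S_R^i is the set of features preceding i in ordering R and v(S) is the
surrogate's expected prediction with the features outside S marginalised
(interventionally) over a background sample.  ``shapley_exact`` evaluates the
equivalent weighted-subset sum over all 2^|K| subsets; ``shapley_sampled``
is the unbiased permutation-sampling estimator with Monte-Carlo standard
errors.  Both satisfy efficiency: the phis of an instance sum to
v(K) - v(empty set) (exactly, for the sampler, by telescoping within each
permutation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DRIVER_NAMES = (
    "dem",
    "aspect",
    "slope",
    "map",
    "mat",
    "dist_rivers",
    "dist_roads",
    "pop",
    "gdp",
    "srr",
    "far",
)

VIF_CUTOFF = 5.0
_EXACT_MAX_FEATURES = 15


class DegenerateDesignError(ValueError):
    """Constant column or otherwise singular driver matrix."""


# ---------------------------------------------------------------------------
# multicollinearity screen


def vif_screen(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    R^2_k comes from an intercept-including least-squares regression of
    feature k on all other features.  ``passed`` flags VIF < 5; perfectly
    collinear features report ``inf`` and fail.
    """
    mat = np.asarray(X, dtype=float)
    n, k = mat.shape
    if n <= k + 1:
        raise DegenerateDesignError(f"need more than {k + 1} rows for {k} features")
    const = np.ptp(mat, axis=0) == 0
    if const.any():
        names = list(np.asarray(X.columns)[const])
        raise DegenerateDesignError(f"constant driver columns: {names}")
    vifs = []
    for j in range(k):
        y = mat[:, j]
        others = np.column_stack([np.ones(n), np.delete(mat, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame(
        {"feature": list(X.columns), "vif": vifs, "passed": [v < VIF_CUTOFF for v in vifs]}
    )


# ---------------------------------------------------------------------------
# surrogate model


@dataclass
class Surrogate:
    """A fitted prediction contract: the attribution engine only sees ``predict``."""

    predict: Callable[[np.ndarray], np.ndarray]
    feature_names: tuple[str, ...]
    holdout_r2: float
    n_train: int
    seed: int
    low_signal: bool = False


def fit_surrogate(
    X: pd.DataFrame, y: Sequence[float], seed: int = 0, n_estimators: int = 200
) -> Surrogate:
    """Fit a seeded LightGBM regressor of score on drivers.

    A 25% holdout reports the fit R^2; zero-variance or unpredictable scores
    set ``low_signal`` (with a warning) rather than raising, since a county
    with no degradation signal is a legitimate input.
    """
    from lightgbm import LGBMRegressor
    from sklearn.model_selection import train_test_split

    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"f{i}" for i in range(np.asarray(X).shape[1])
    )
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(Xm) != len(yv):
        raise ValueError("X and y must align")
    if len(Xm) < 100:
        raise ValueError("need at least 100 units to fit a surrogate")
    model = LGBMRegressor(
        n_estimators=n_estimators,
        learning_rate=0.05,
        num_leaves=31,
        min_child_samples=20,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )
    Xf = pd.DataFrame(Xm, columns=list(names))
    if np.var(yv) == 0:
        warnings.warn("degradation score has zero variance; surrogate is constant")
        model.fit(Xf, yv)
        r2 = 0.0
        low = True
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(Xf, yv, test_size=0.25, random_state=seed)
        model.fit(X_tr, y_tr)
        from sklearn.metrics import r2_score

        r2 = float(r2_score(y_te, model.predict(X_te)))
        low = r2 < 0.05
        model.fit(Xf, yv)  # refit on all rows for attribution
    booster = model.booster_

    def predict(A: np.ndarray) -> np.ndarray:
        # raw Booster predict: no sklearn column-name validation, less overhead
        return np.asarray(booster.predict(np.asarray(A, dtype=float)))

    return Surrogate(
        predict=predict,
        feature_names=names,
        holdout_r2=r2,
        n_train=len(Xm),
        seed=seed,
        low_signal=low,
    )


# ---------------------------------------------------------------------------
# generic Shapley engine over an abstract set function


def _check_k(n_features: int) -> None:
    if n_features > _EXACT_MAX_FEATURES:
        raise ValueError(
            f"exact Shapley enumerates 2^{n_features} subsets; use shapley_sampled"
        )


def shapley_exact(v: Callable[[frozenset], float], n_features: int) -> np.ndarray:
    """Exact Shapley values of set function ``v`` over features 0..n-1.

    Uses the weighted-subset form
    phi_i = sum_{S not containing i} |S|! (n-|S|-1)! / n! * [v(S+{i}) - v(S)],
    equal to the permutation average at a cost of 2^n evaluations.
    """
    _check_k(n_features)
    n = n_features
    vals = {}
    for mask in range(1 << n):
        vals[mask] = float(v(frozenset(i for i in range(n) if mask >> i & 1)))
    fact = [math.factorial(m) for m in range(n + 1)]
    phi = np.zeros(n)
    for mask in range(1 << n):
        s = bin(mask).count("1")
        w = fact[s] * fact[n - s - 1] / fact[n]
        for i in range(n):
            if not mask >> i & 1:
                phi[i] += w * (vals[mask | 1 << i] - vals[mask])
    return phi


def shapley_permutation_oracle(v: Callable[[frozenset], float], n_features: int) -> np.ndarray:
    """Brute-force enumeration of all n! orderings (independent cross-check)."""
    n = n_features
    phi = np.zeros(n)
    count = 0
    for perm in permutations(range(n)):
        s: frozenset = frozenset()
        for i in perm:
            phi[i] += v(s | {i}) - v(s)
            s = s | {i}
        count += 1
    return phi / count


def shapley_sampled(
    v: Callable[[frozenset], float], n_features: int, n_perm: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling estimate of the Shapley values with standard errors.

    Averages each feature's marginal contribution over ``n_perm`` uniformly
    random orderings; the s.e. is the across-permutation standard deviation
    over sqrt(n_perm).  Within each ordering the contributions telescope to
    v(K) - v(empty), so efficiency holds exactly for the estimate.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_perm, n_features))
    for p in range(n_perm):
        order = rng.permutation(n_features)
        s: frozenset = frozenset()
        prev = v(s)
        for i in order:
            s = s | {int(i)}
            cur = v(s)
            contrib[p, int(i)] = cur - prev
            prev = cur
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(n_perm)
    return phi, se


# ---------------------------------------------------------------------------
# marginalised value function and batched instance attribution


@dataclass
class MarginalValueFunction:
    """Interventional value function for one instance.

    v(S) = mean over background rows b of predict(x with features outside S
    replaced by b's values).  v(empty) is the background mean prediction and
    v(K) the model's prediction for the instance itself (averaged over the
    degenerate replacement, i.e. exactly predict(x)).
    """

    predict: Callable[[np.ndarray], np.ndarray]
    x: np.ndarray
    background: np.ndarray

    def __call__(self, subset: frozenset) -> float:
        comp = self.background.copy()
        idx = sorted(subset)
        comp[:, idx] = self.x[idx]
        return float(self.predict(comp).mean())


@dataclass
class AttributionResult:
    """Per-instance Shapley values for a sample of evaluation units."""

    phi: np.ndarray  # (n_instances, n_features)
    baseline: float  # v(empty) = background mean prediction
    instance_values: np.ndarray  # v(K) per instance
    feature_names: tuple[str, ...]
    method: str  # "exact" | "sampled"
    n_perm: int | None = None
    seed: int | None = None
    se: np.ndarray | None = None  # (n_instances, n_features) for sampled
    X_instances: np.ndarray | None = field(default=None, repr=False)

    def efficiency_gap(self) -> np.ndarray:
        """Per-instance |sum_i phi_i - (v(K) - v(empty))|."""
        return np.abs(self.phi.sum(axis=1) - (self.instance_values - self.baseline))


def _masked_values(
    predict: Callable, X: np.ndarray, background: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """v(S) for each mask row and each instance: (n_masks, n_inst) matrix.

    One predict call per mask over the (n_inst * B) composite matrix.
    """
    n_inst, k = X.shape
    B = len(background)
    tiled_bg = np.tile(background, (n_inst, 1))  # (n_inst*B, k), instance-major
    inst_rep = np.repeat(X, B, axis=0)
    out = np.empty((len(masks), n_inst))
    for m, mask in enumerate(masks):
        comp = np.where(mask, inst_rep, tiled_bg)
        out[m] = predict(comp).reshape(n_inst, B).mean(axis=1)
    return out


def attribute_exact(
    surrogate: Surrogate, X_instances: pd.DataFrame, background: pd.DataFrame
) -> AttributionResult:
    """Exact Shapley attribution of every instance (2^k value evaluations)."""
    X = np.asarray(X_instances, dtype=float)
    bg = np.asarray(background, dtype=float)
    n_inst, k = X.shape
    _check_k(k)
    masks = np.array([[m >> i & 1 for i in range(k)] for m in range(1 << k)], dtype=bool)
    vals = _masked_values(surrogate.predict, X, bg, masks)
    fact = [math.factorial(m) for m in range(k + 1)]
    phi = np.zeros((n_inst, k))
    sizes = masks.sum(axis=1)
    for m in range(1 << k):
        s = int(sizes[m])
        if s == k:
            continue
        w = fact[s] * fact[k - s - 1] / fact[k]
        for i in range(k):
            if not m >> i & 1:
                phi[:, i] += w * (vals[m | 1 << i] - vals[m])
    return AttributionResult(
        phi=phi,
        baseline=float(vals[0].mean()),
        instance_values=vals[(1 << k) - 1],
        feature_names=surrogate.feature_names,
        method="exact",
        X_instances=X,
    )


def attribute_sampled(
    surrogate: Surrogate,
    X_instances: pd.DataFrame,
    background: pd.DataFrame,
    n_perm: int = 64,
    seed: int = 0,
) -> AttributionResult:
    """Permutation-sampling attribution, batched across instances.

    The same ``n_perm`` random orderings are applied to every instance (the
    estimator stays unbiased per instance; orderings are drawn once from
    ``seed``).  Standard errors are per (instance, feature).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    X = np.asarray(X_instances, dtype=float)
    bg = np.asarray(background, dtype=float)
    n_inst, k = X.shape
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_perm, n_inst, k))
    empty = np.zeros(k, dtype=bool)
    full = np.ones(k, dtype=bool)
    v_empty = _masked_values(surrogate.predict, X, bg, np.array([empty]))[0]
    v_full = _masked_values(surrogate.predict, X, bg, np.array([full]))[0]
    for p in range(n_perm):
        order = rng.permutation(k)
        masks = np.zeros((k, k), dtype=bool)  # prefix masks after adding each feature
        cur = empty.copy()
        for step, i in enumerate(order):
            cur = cur.copy()
            cur[i] = True
            masks[step] = cur
        vals = _masked_values(surrogate.predict, X, bg, masks)
        prev = v_empty
        for step, i in enumerate(order):
            contrib[p, :, int(i)] = vals[step] - prev
            prev = vals[step]
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(n_perm)
    return AttributionResult(
        phi=phi,
        baseline=float(v_empty.mean()),
        instance_values=v_full,
        feature_names=surrogate.feature_names,
        method="sampled",
        n_perm=n_perm,
        seed=seed,
        se=se,
        X_instances=X,
    )


def rank_drivers(result: AttributionResult) -> pd.DataFrame:
    """Global driver ranking by mean |phi| with an effect direction.

    Direction is the sign of the Pearson correlation between a feature's
    values and its phis across instances (positive = raises the score =
    mitigates degradation).  Features whose phis are numerically flat get
    direction 0 and ``low_signal`` True.
    """
    if result.X_instances is None:
        raise ValueError("ranking needs the attributed instance matrix")
    mean_abs = np.abs(result.phi).mean(axis=0)
    scale = max(float(np.abs(result.instance_values - result.baseline).mean()), 1e-12)
    rows = []
    for j, name in enumerate(result.feature_names):
        phi_j = result.phi[:, j]
        x_j = result.X_instances[:, j]
        low = mean_abs[j] < 1e-3 * scale or np.std(phi_j) == 0 or np.std(x_j) == 0
        if low:
            r = 0.0
        else:
            r = float(stats.pearsonr(x_j, phi_j)[0])
        rows.append(
            {
                "feature": name,
                "mean_abs_phi": float(mean_abs[j]),
                "direction": int(np.sign(r)),
                "corr_feature_phi": r,
                "low_signal": bool(low),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_abs_phi", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def degradation_scores(grades: pd.DataFrame, epoch_years: tuple[int, int], dtype: str) -> pd.Series:
    """Per-unit degradation score for ``dtype`` (higher = mitigation).

    Composite: change in the composite quality grade (early minus late).
    Single types: change in the type's diagnostic property grade.
    """
    from . import quality

    prop = {
        "acidification": "ph_grade",
        "fertility_decline": "som_grade",
        "erosion": "som_grade",
        "physical_structure": "bd_grade",
    }
    y1, y2 = epoch_years
    g1 = grades[grades["epoch_year"] == y1].set_index("unit_id")
    g2 = grades[grades["epoch_year"] == y2].set_index("unit_id").loc[g1.index]
    if dtype == "composite":
        c1 = quality.composite_grade_array(g1[quality.GRADE_COLUMNS].to_numpy())
        c2 = quality.composite_grade_array(g2[quality.GRADE_COLUMNS].to_numpy())
        return pd.Series(c1 - c2, index=g1.index, name="score")
    col = prop[dtype]
    return pd.Series(
        g1[col].to_numpy(int) - g2[col].to_numpy(int), index=g1.index, name="score"
    )
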