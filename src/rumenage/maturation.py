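"""Microbiota age: random-forest maturation modelling and plateau detection.

The pipeline regresses chronological age (as log10 of days, matching the
geometric sampling design) on taxon relative abundances with
random-forest regression, repeated over independently seeded rebuilds:

1. rank taxa by out-of-bag permutation importance (increase in OOB MSE
   when a taxon's abundances are permuted), averaged over ``n_repeats``
   forests;
2. trace cross-validated error as a function of the number of top-ranked
   taxa retained (halving grid, as in stepwise variable-count selection);
3. pick the smallest taxon set whose CV error is within a tolerance of the
   global minimum, and fit a sparse forest on it;
4. take each sample's "microbiota age" (out-of-bag forest prediction for
   training animals) and fit a cross-validated smoothing spline of
   microbiota age against log10 chronological age; the community is mature
   from the first sampled age at which the fitted curve stays within
   ``rel_plateau_threshold`` of its fitted rise from the plateau level
   (the tail-averaged fitted value).

Forests use regression defaults in the tradition of the randomForest R
package: mtry = p/3 features per split and a minimum node size of 5.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ImportanceProfile",
    "CVErrorCurve",
    "SparseAgeModel",
    "MaturationResult",
    "rank_taxa_by_importance",
    "cv_error_vs_ntaxa",
    "select_min_taxa",
    "fit_sparse_model",
    "predict_microbiota_age",
    "fit_spline_and_detect_maturation",
    "run_maturation_pipeline",
]

MTRY_FRACTION = 1.0 / 3.0   # features tried per split (regression convention)
MIN_LEAF = 5                # minimum node size for regression trees


@dataclass
class ImportanceProfile:
    """Per-taxon mean OOB permutation importance +/- s.e.m. over rebuilds."""

    taxa: list[str]
    mean_importance: pd.Series
    sem: pd.Series
    n_repeats: int

    def ranked_taxa(self) -> list[str]:
        """Taxa sorted by mean importance descending, id-lexicographic ties."""
        df = pd.DataFrame({"imp": self.mean_importance})
        df["taxon"] = df.index
        return df.sort_values(["imp", "taxon"], ascending=[False, True])["taxon"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_importance": self.mean_importance, "sem": self.sem}
        ).rename_axis("taxon")


def _check_xy(relabund: pd.DataFrame, ages) -> tuple[pd.DataFrame, np.ndarray]:
    ages = np.asarray(pd.Series(ages).reindex(relabund.index)
                      if isinstance(ages, (pd.Series, dict)) else ages, dtype=float)
    if len(ages) != relabund.shape[0] or np.isnan(ages).any():
        raise ValueError("every sample needs a finite age")
    return relabund, ages


def _forest_oob_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator,
    variable: np.ndarray,
) -> np.ndarray:
    """Unscaled %IncMSE for one forest: mean over trees of OOB MSE increase."""
    n, p = X.shape
    max_features = max(1, int(round(p * MTRY_FRACTION)))
    inc = np.zeros(p)
    n_used = np.zeros(p)
    var_idx = np.flatnonzero(variable)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_features, min_samples_leaf=MIN_LEAF,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[boot], y[boot])
        base_mse = float(np.mean((tree.predict(X[oob]) - y[oob]) ** 2))
        if var_idx.size == 0:
            continue
        # one batched predict over all permuted-feature copies
        stacked = np.repeat(X[oob][None, :, :], var_idx.size, axis=0)
        for k, j in enumerate(var_idx):
            stacked[k, :, j] = rng.permutation(stacked[k, :, j])
        preds = tree.predict(stacked.reshape(-1, p)).reshape(var_idx.size, oob.size)
        perm_mse = np.mean((preds - y[oob][None, :]) ** 2, axis=1)
        inc[var_idx] += perm_mse - base_mse
        n_used[var_idx] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(n_used > 0, inc / np.maximum(n_used, 1), 0.0)
    return out


def rank_taxa_by_importance(
    relabund: pd.DataFrame,
    ages,
    n_trees: int = 500,
    n_repeats: int = 100,
    seed: int | None = None,
) -> ImportanceProfile:
    """Average OOB permutation importance over ``n_repeats`` forest rebuilds.

    Constant-abundance taxa get importance 0 with a warning (permuting a
    constant column cannot change predictions).
    """
    relabund, ages = _check_xy(relabund, ages)
    if relabund.shape[1] < 2:
        raise ValueError("need at least 2 taxa")
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages")
    X = relabund.to_numpy(dtype=float)
    variable = X.std(axis=0) > 0
    if not variable.all():
        const = [t for t, v in zip(relabund.columns, variable) if not v]
        warnings.warn(f"constant-abundance taxa get importance 0: {const}", stacklevel=2)
    rng = np.random.default_rng(seed)
    per_repeat = np.stack([
        _forest_oob_importance(X, ages, n_trees, np.random.default_rng(rng.integers(2**31 - 1)),
                               variable)
        for _ in range(n_repeats)
    ])
    mean = per_repeat.mean(axis=0)
    sem = per_repeat.std(axis=0, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 \
        else np.zeros_like(mean)
    return ImportanceProfile(
        taxa=list(relabund.columns),
        mean_importance=pd.Series(mean, index=relabund.columns),
        sem=pd.Series(sem, index=relabund.columns),
        n_repeats=n_repeats,
    )


@dataclass
class CVErrorCurve:
    """Mean and s.d. of k-fold CV MSE at each taxon-count grid size."""

    sizes: list[int]
    mean_error: list[float]
    sd_error: list[float]
    n_folds: int
    n_repeats: int
    ranked_taxa: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_taxa": self.sizes, "mean_cv_error": self.mean_error,
             "sd_cv_error": self.sd_error}
        )


def _size_grid(p: int, step: float) -> list[int]:
    """Halving-style grid: p, round(p*step), ... down to 1 (unique, descending)."""
    sizes = []
    k = float(p)
    while k >= 1:
        r = int(round(k))
        if r >= 1 and (not sizes or r < sizes[-1]):
            sizes.append(r)
        k *= step
        if r == 1:
            break
    if sizes[-1] != 1:
        sizes.append(1)
    return sizes


def cv_error_vs_ntaxa(
    relabund: pd.DataFrame,
    ages,
    profile: ImportanceProfile,
    n_folds: int = 10,
    n_repeats: int = 100,
    step: float = 0.5,
    seed: int | None = None,
    n_trees: int = 100,
) -> CVErrorCurve:
    """Cross-validated error as taxa are pruned from the importance ranking."""
    relabund, ages = _check_xy(relabund, ages)
    if n_folds > relabund.shape[0]:
        raise ValueError(f"n_folds={n_folds} exceeds sample count {relabund.shape[0]}")
    missing = [t for t in relabund.columns if t not in profile.mean_importance.index]
    if missing:
        raise ValueError(f"importance profile missing taxa: {missing}")
    ranked = [t for t in profile.ranked_taxa() if t in relabund.columns]
    X_full = relabund[ranked].to_numpy(dtype=float)
    sizes = _size_grid(len(ranked), step)
    rng = np.random.default_rng(seed)
    errors = np.zeros((n_repeats, len(sizes)))
    for r in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        folds = list(kf.split(X_full))
        for si, size in enumerate(sizes):
            X = X_full[:, :size]
            sse = 0.0
            for train, test in folds:
                rf = RandomForestRegressor(
                    n_estimators=n_trees,
                    max_features=max(1, int(round(size * MTRY_FRACTION))),
                    min_samples_leaf=MIN_LEAF,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit(X[train], ages[train])
                sse += float(np.sum((rf.predict(X[test]) - ages[test]) ** 2))
            errors[r, si] = sse / len(ages)
    return CVErrorCurve(
        sizes=sizes,
        mean_error=errors.mean(axis=0).tolist(),
        sd_error=(errors.std(axis=0, ddof=1) if n_repeats > 1
                  else np.zeros(len(sizes))).tolist(),
        n_folds=n_folds,
        n_repeats=n_repeats,
        ranked_taxa=ranked,
    )


def select_min_taxa(curve: CVErrorCurve, tolerance: float = 0.05) -> int:
    """Smallest grid size with mean error within (1+tolerance) of the minimum."""
    if not curve.sizes:
        raise ValueError("empty CV error curve")
    best = min(curve.mean_error)
    admissible = [s for s, e in zip(curve.sizes, curve.mean_error)
                  if e <= (1.0 + tolerance) * best]
    return min(admissible)


@dataclass
class SparseAgeModel:
    """Sparse random forest predicting chronological age from selected taxa.

    ``target_scale`` records what the forest was trained to predict:
    ``"days"`` or ``"log10_days"``; predictions are always reported in
    days.
    """

    selected_taxa: list[str]
    forest: RandomForestRegressor
    seed: int | None
    oob_r2: float
    target_scale: str = "days"


def fit_sparse_model(
    relabund: pd.DataFrame,
    ages,
    seed: int | None = None,
    n_trees: int = 500,
    target_scale: str = "days",
) -> SparseAgeModel:
    """Fit the sparse forest on pre-selected taxa; records out-of-bag R^2."""
    relabund, ages = _check_xy(relabund, ages)
    if relabund.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    p = relabund.shape[1]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*out-of-bag.*")
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max(1, int(round(p * MTRY_FRACTION))),
            min_samples_leaf=MIN_LEAF,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
        ).fit(relabund.to_numpy(dtype=float), ages)
    if target_scale not in ("days", "log10_days"):
        raise ValueError(f"unknown target scale {target_scale!r}")
    return SparseAgeModel(
        selected_taxa=list(relabund.columns),
        forest=forest,
        seed=seed,
        oob_r2=float(forest.oob_score_),
        target_scale=target_scale,
    )


def predict_microbiota_age(model: SparseAgeModel, relabund: pd.DataFrame) -> pd.Series:
    """Microbiota age (days) per sample from the sparse model."""
    missing = [t for t in model.selected_taxa if t not in relabund.columns]
    if missing:
        raise ValueError(f"table missing model taxa: {missing}")
    X = relabund[model.selected_taxa].to_numpy(dtype=float)
    pred = model.forest.predict(X)
    if model.target_scale == "log10_days":
        pred = 10.0 ** pred
    return pd.Series(pred, index=relabund.index, name="microbiota_age_days")


def _effective_df(x: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix (sum of leverages) at penalty ``lam``."""
    tr = 0.0
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = 1.0
        tr += float(make_smoothing_spline(x, e, w=w, lam=lam)(x[i]))
    return tr


def _cv_smoothing_spline(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> BSpline:
    """Cubic smoothing spline with leave-one-out CV penalty selection.

    The penalty is chosen on a log grid restricted to an effective-df band
    (3.5 .. ~0.8 n): unrestricted selection on a dozen noisy points
    degenerates to either a straight line or an interpolant, both of which
    hide curve shape.
    """
    n = len(x)
    df_lo, df_hi = 3.5, max(4.5, min(10.0, 0.8 * n))
    best_lam, best_err = None, np.inf
    for lam in np.logspace(-6, 2, 25):
        if not (df_lo <= _effective_df(x, w, lam) <= df_hi):
            continue
        err = 0.0
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            sp = make_smoothing_spline(x[m], y[m], w=w[m], lam=lam)
            err += w[i] * float(sp(x[i]) - y[i]) ** 2
        if err < best_err:
            best_lam, best_err = lam, err
    if best_lam is None:  # degenerate band (tiny n): fall back to GCV
        return make_smoothing_spline(x, y, w=w)
    return make_smoothing_spline(x, y, w=w, lam=best_lam)


@dataclass
class MaturationResult:
    """Spline fit of microbiota age vs chronological age with plateau call."""

    microbiota_age: pd.Series
    spline: BSpline
    maturation_age_days: float | None
    rel_threshold: float
    fitted: pd.Series = field(default_factory=pd.Series)  # spline value per sampled age

    @property
    def reached(self) -> bool:
        return self.maturation_age_days is not None


def fit_spline_and_detect_maturation(
    microbiota_age: pd.Series,
    chronological_age_days,
    rel_threshold: float = 0.1,
    min_signal_ratio: float = 2.0,
    log_response: bool = False,
) -> MaturationResult:
    """GCV smoothing spline of microbiota age on log10 chronological age.

    The maturation age is the smallest sampled age a* such that the fitted
    curve at a* and at every older sampled age stays within
    ``rel_threshold`` of the fitted rise (its full range) from the plateau
    level, the weighted mean fitted value over the oldest three sampled
    ages.  If no age before the oldest qualifies the plateau is "not
    reached" (``None``): a curve still rising at the end of the range has
    no plateau.  The criterion is
    relative, so positive rescaling of the microbiota ages cannot change
    the call.

    Two degenerate guards: a constant microbiota age matures at the first
    sampled age (with a warning); when the fitted rise is smaller than
    ``min_signal_ratio`` x the residual standard deviation around the
    spline there is no age trend to plateau, and the call is "not
    reached" (with a warning).
    """
    y = pd.Series(microbiota_age, dtype=float)
    ages = np.asarray(pd.Series(chronological_age_days).reindex(y.index)
                      if isinstance(chronological_age_days, (pd.Series, dict))
                      else chronological_age_days, dtype=float)
    if len(ages) != len(y):
        raise ValueError("microbiota and chronological ages must align")
    if (ages <= 0).any():
        raise ValueError("chronological ages must be positive")
    uniq = np.unique(ages)
    if uniq.size < 4:
        raise ValueError("need >=4 distinct chronological ages for the spline")
    # collapse replicate ages to weighted means (smoothing-spline tie handling)
    xu = np.log10(uniq)
    yv = y.to_numpy()
    if log_response:
        # fit on log10(microbiota age): multiplicative prediction noise is
        # homoscedastic there; the plateau band still applies on the
        # back-transformed (days) curve
        if (yv <= 0).any():
            raise ValueError("log_response requires positive microbiota ages")
        yv = np.log10(yv)
    ymean = np.array([yv[ages == a].mean() for a in uniq])
    wts = np.array([(ages == a).sum() for a in uniq], dtype=float)
    spline = _cv_smoothing_spline(xu, ymean, wts)
    fitted_fit = spline(xu)
    fitted = 10.0 ** fitted_fit if log_response else fitted_fit
    fitted_ser = pd.Series(fitted, index=uniq, name="fitted_microbiota_age")
    rise_fit = float(fitted_fit.max() - fitted_fit.min())
    scale = float(np.max(np.abs(ymean))) if np.max(np.abs(ymean)) > 0 else 1.0
    if rise_fit <= 1e-9 * scale:
        warnings.warn("microbiota age is constant; maturation set to the first "
                      "sampled age", stacklevel=2)
        return MaturationResult(y, spline, float(uniq[0]), rel_threshold, fitted_ser)
    resid_sd = float(np.sqrt(np.mean((yv - spline(np.log10(ages))) ** 2)))
    if rise_fit < min_signal_ratio * resid_sd:
        warnings.warn("fitted age trend is smaller than the residual noise; "
                      "no plateau asserted", stacklevel=2)
        return MaturationResult(y, spline, None, rel_threshold, fitted_ser)
    # plateau level: weighted mean of the oldest sampled fitted values,
    # which averages out group-mean noise at the compressed old end; the
    # band lives on the fitting scale, where the noise is homoscedastic
    n_tail = min(3, uniq.size - 1)
    plateau_level = float(np.average(fitted_fit[-n_tail:], weights=wts[-n_tail:]))
    near = np.abs(fitted_fit - plateau_level) <= rel_threshold * rise_fit
    maturation: float | None = None
    # smallest sampled age from which the curve stays at the plateau level
    for i in range(uniq.size - 1):
        if near[i:].all():
            maturation = float(uniq[i])
            break
    return MaturationResult(y, spline, maturation, rel_threshold, fitted_ser)


@dataclass
class MaturationPipelineResult:
    importance: ImportanceProfile
    curve: CVErrorCurve
    n_selected: int
    model: SparseAgeModel
    maturation: MaturationResult


def run_maturation_pipeline(
    relabund: pd.DataFrame,
    ages,
    n_trees: int = 500,
    n_repeats: int = 100,
    cv_n_trees: int = 100,
    sparse_n_trees: int = 500,
    n_folds: int = 10,
    step: float = 0.5,
    tolerance: float = 0.05,
    rel_plateau_threshold: float = 0.1,
    seed: int | None = None,
) -> MaturationPipelineResult:
    """Importance ranking -> CV selection -> sparse model -> plateau call.

    The forests regress log10(age): the sampling design is geometric
    (7 days to 12 years), and a days-scale loss is dominated by the oldest
    groups, hiding early-life discriminatory taxa from the selector.
    Predictions are back-transformed, so the microbiota age is in days.
    """
    ages_ser = ages if isinstance(ages, pd.Series) else pd.Series(
        np.asarray(ages, dtype=float), index=relabund.index)
    if (ages_ser <= 0).any():
        raise ValueError("chronological ages must be positive")
    log_ages = np.log10(ages_ser)
    rng = np.random.default_rng(seed)
    profile = rank_taxa_by_importance(
        relabund, log_ages, n_trees=n_trees, n_repeats=n_repeats,
        seed=int(rng.integers(2**31 - 1)),
    )
    curve = cv_error_vs_ntaxa(
        relabund, log_ages, profile, n_folds=n_folds, n_repeats=n_repeats,
        step=step, seed=int(rng.integers(2**31 - 1)), n_trees=cv_n_trees,
    )
    n_sel = select_min_taxa(curve, tolerance=tolerance)
    selected = curve.ranked_taxa[:n_sel]
    model = fit_sparse_model(relabund[selected], log_ages,
                             seed=int(rng.integers(2**31 - 1)),
                             n_trees=sparse_n_trees, target_scale="log10_days")
    # microbiota age of the training animals uses out-of-bag predictions so
    # the spline is not distorted by memorised chronological ages
    mic_age = pd.Series(10.0 ** model.forest.oob_prediction_,
                        index=relabund.index, name="microbiota_age_days")
    maturation = fit_spline_and_detect_maturation(
        mic_age, ages_ser, rel_threshold=rel_plateau_threshold,
        log_response=True,
    )
    return MaturationPipelineResult(profile, curve, n_sel, model, maturation)
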