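"""Trait retrieval from spectra: univariate regressions, PLS, forward iPLS.

Multivariate calibration follows classical chemometrics practice:
single-response partial least squares (NIPALS with deflation) on
mean-centered data, validated by random cross-validation with 3 deletion
groups; the number of latent variables (LVs) is chosen by minimising
RMSECV.  Interval PLS (iPLS) partitions the 50-band axis into contiguous
intervals of 10 or 5 variables and greedily adds the interval that most
reduces RMSECV, stopping when no addition strictly improves — trading a
little calibration fit for sparser, interpretable wavelength windows.

Mean centering is refit inside every training fold by default (no
leakage); a ``"global"`` centering switch reproduces workflows that
center once on the full dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandGrid
from .spectra import SpectralDataset

__all__ = [
    "CVPlan",
    "PLSModel",
    "PLSPerformance",
    "IPLSResult",
    "fit_pls",
    "cross_validate",
    "ipls_forward",
    "univariate_table",
    "significance_class",
    "build_model_report",
    "assess",
]

log = logging.getLogger(__name__)


def significance_class(p: float) -> str:
    """Four-step ladder: '****' p<0.0001, '**' p<0.001, '*' p<0.01, else 'ns'."""
    if not np.isfinite(p):
        return "na"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


# ---------------------------------------------------------------- univariate


def univariate_table(vi_result: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """OLS line, R², and significance class for every (index, trait) pair.

    Pairs observations by ``vine_id``; traits measured on a subset (the
    water potentials cover 30 of the 60 vines) use only the vines they
    were measured on.  Cells with < 3 pairs or zero variance are NA with
    a warning.  Returns a long-form frame; pivot on (index, trait) for
    the matrix view.
    """
    index_cols = [c for c in vi_result.columns if c != "vine_id"]
    trait_cols = [c for c in traits.columns if c != "vine_id"]
    merged = pd.merge(vi_result, traits, on="vine_id", how="inner")
    rows = []
    for t in trait_cols:
        for ix in index_cols:
            sub = merged[[ix, t]].dropna()
            x, y = sub[ix].to_numpy(float), sub[t].to_numpy(float)
            rec = {"index": ix, "trait": t, "n": len(sub)}
            if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                log.warning("univariate %s vs %s: degenerate cell (n=%d)", ix, t, len(sub))
                rec.update(slope=np.nan, intercept=np.nan, r_squared=np.nan,
                           p_value=np.nan, sig_class="na")
            else:
                fit = stats.linregress(x, y)
                rec.update(slope=fit.slope, intercept=fit.intercept,
                           r_squared=fit.rvalue**2, p_value=fit.pvalue,
                           sig_class=significance_class(fit.pvalue))
            rows.append(rec)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- CV


@dataclass(frozen=True)
class CVPlan:
    """Random deletion-group assignment: a pure function of (n, k, seed).

    Groups are as balanced as possible (sizes differ by at most one) and
    partition the samples.
    """

    n: int
    k: int
    seed: int
    groups: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 2 or self.k > self.n:
            raise ValueError(f"need 2 <= k <= n, got k={self.k}, n={self.n}")
        perm = np.random.default_rng(self.seed).permutation(self.n)
        groups = np.empty(self.n, dtype=int)
        groups[perm] = np.arange(self.n) % self.k
        object.__setattr__(self, "groups", groups)

    def fold_sizes(self) -> list[int]:
        return np.bincount(self.groups, minlength=self.k).tolist()


# ---------------------------------------------------------------------- PLS


@dataclass
class PLSModel:
    """Fitted single-response PLS model (NIPALS, mean-centered).

    ``coef(l)`` gives the regression vector using the first ``l`` latent
    variables; centering vectors are stored and applied at prediction.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # (B, n_lv) X-weights w_a
    loadings: np.ndarray   # (B, n_lv) X-loadings p_a
    y_loadings: np.ndarray  # (n_lv,) q_a
    scores: np.ndarray     # (n, n_lv) t_a
    n_extracted: int = -1  # < n_lv when the residual covariance ran out

    def __post_init__(self) -> None:
        if self.n_extracted < 0:
            self.n_extracted = self.n_lv

    def coef(self, n_lv: int | None = None) -> np.ndarray:
        l = self.n_lv if n_lv is None else int(n_lv)
        if not 1 <= l <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}]")
        l = min(l, self.n_extracted)  # extra LVs past exhaustion contribute nothing
        if l == 0:
            return np.zeros(self.weights.shape[0])
        W, P, q = self.weights[:, :l], self.loadings[:, :l], self.y_loadings[:l]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        b = self.coef(n_lv)
        return (np.asarray(X, dtype=float) - self.x_mean) @ b + self.y_mean


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int, center: bool = True) -> PLSModel:
    """NIPALS extraction of ``n_lv`` latent variables with deflation.

    For a single response the NIPALS weight step is a direct covariance
    projection (no inner iteration).  With full column rank and
    ``n_lv = rank``, predictions on the training data equal the
    least-squares fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts disagree")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if not 1 <= n_lv <= min(n - 1, B):
        raise ValueError(f"n_lv must be in [1, min(n-1, B)] = [1, {min(n - 1, B)}]")
    x_mean = X.mean(axis=0) if center else np.zeros(B)
    y_mean = float(y.mean()) if center else 0.0
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((B, n_lv))
    P = np.zeros((B, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    n_extracted = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            break  # residual covariance exhausted
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-300:
            break
        p = (Xc.T @ t) / tt
        q_a = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, q_a, t
        n_extracted = a + 1
    return PLSModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean,
                    weights=W, loadings=P, y_loadings=q, scores=T,
                    n_extracted=n_extracted)


@dataclass(frozen=True)
class PLSPerformance:
    """Calibration / cross-validation summary at the chosen LV count."""

    n_lv: int
    rmsec: float
    rmsecv: float
    r2_cal: float
    r2_cv: float


@dataclass(frozen=True)
class CVResult:
    rmsecv: np.ndarray          # per LV count 1..lv_max
    chosen_lv: int
    r2_cv: float
    cv_predictions: np.ndarray  # pooled predictions at chosen LV


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int,
    plan: CVPlan,
    centering: str = "fold",
    r2_definition: str = "one_minus_press",
) -> CVResult:
    """Leave-group-out cross-validation over 1..lv_max latent variables.

    Each deletion group is predicted by a model refit (including
    re-centering, under the default ``"fold"`` policy) on the remaining
    samples.  RMSECV(l) pools squared errors over all samples; the chosen
    LV count minimises it (ties → fewer LVs).  ``r2_cv`` is
    1 − PRESS/SS_total by default (can be negative); the alternative
    ``"corr"`` definition squares the correlation of CV predictions with
    the observations.  A constant response leaves r2_cv undefined (NA).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if plan.n != n:
        raise ValueError("plan covers a different number of samples")
    sizes = plan.fold_sizes()
    if min(sizes) < 2:
        raise ValueError(f"every deletion group needs >= 2 samples, got sizes {sizes}")
    min_train = n - max(sizes)
    lv_eff = min(lv_max, min_train - 1, B)
    if lv_eff < lv_max:
        log.debug("cross_validate: lv_max reduced from %d to %d", lv_max, lv_eff)
    if centering == "global":
        x_mean_g, y_mean_g = X.mean(axis=0), float(y.mean())
    elif centering != "fold":
        raise ValueError(f"unknown centering {centering!r}")
    preds = np.zeros((n, lv_eff))
    for g in range(plan.k):
        test = plan.groups == g
        train = ~test
        if centering == "fold":
            model = fit_pls(X[train], y[train], lv_eff, center=True)
        else:
            model = fit_pls(X[train] - x_mean_g, y[train] - y_mean_g, lv_eff, center=False)
        for l in range(1, lv_eff + 1):
            if centering == "fold":
                preds[test, l - 1] = model.predict(X[test], l)
            else:
                preds[test, l - 1] = model.predict(X[test] - x_mean_g, l) + y_mean_g
    rmsecv = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # first minimum → fewer LVs on ties
    press = float(((preds[:, chosen - 1] - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        log.warning("cross_validate: constant response, r2_cv undefined")
        r2 = np.nan
    elif r2_definition == "one_minus_press":
        r2 = 1.0 - press / ss_tot
    elif r2_definition == "corr":
        r2 = float(np.corrcoef(preds[:, chosen - 1], y)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")
    return CVResult(rmsecv=rmsecv, chosen_lv=chosen, r2_cv=r2,
                    cv_predictions=preds[:, chosen - 1])


def assess(
    X: np.ndarray, y: np.ndarray, lv_max: int, plan: CVPlan, centering: str = "fold"
) -> PLSPerformance:
    """Choose LVs by minimum RMSECV, then summarise calibration + CV."""
    cv = cross_validate(X, y, lv_max, plan, centering=centering)
    model = fit_pls(X, y, cv.chosen_lv)
    yhat = model.predict(X)
    y = np.asarray(y, dtype=float).ravel()
    sse = float(((yhat - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2_cal = np.nan if ss_tot == 0 else 1.0 - sse / ss_tot
    return PLSPerformance(
        n_lv=cv.chosen_lv,
        rmsec=float(np.sqrt(sse / y.size)),
        rmsecv=float(cv.rmsecv[cv.chosen_lv - 1]),
        r2_cal=r2_cal,
        r2_cv=cv.r2_cv,
    )


# --------------------------------------------------------------------- iPLS


@dataclass(frozen=True)
class IPLSResult:
    """Forward interval-PLS outcome for one response."""

    interval_width: int
    partition: tuple[tuple[int, ...], ...]   # band indices per interval
    selected: tuple[int, ...]                # interval indices, addition order
    selected_ranges: str                     # merged "start:end" nm ranges
    performance: PLSPerformance
    trajectory: tuple[float, ...]            # RMSECV after each accepted step

    @property
    def selected_bands(self) -> np.ndarray:
        bands = sorted(b for i in self.selected for b in self.partition[i])
        return np.asarray(bands, dtype=int)


def make_partition(n_bands: int, width: int) -> tuple[tuple[int, ...], ...]:
    """Contiguous intervals of ``width`` bands; a remainder short of a full
    interval is absorbed by the last one (with a warning)."""
    if width < 1 or width > n_bands:
        raise ValueError("interval width must be in [1, n_bands]")
    n_full = n_bands // width
    if n_bands % width:
        log.warning("make_partition: %d bands not divisible by %d; last interval absorbs %d extra",
                    n_bands, width, n_bands % width)
    parts = []
    for i in range(n_full):
        lo = i * width
        hi = (i + 1) * width if i < n_full - 1 else n_bands
        parts.append(tuple(range(lo, hi)))
    return tuple(parts)


def format_ranges(bands: np.ndarray, grid: BandGrid) -> str:
    """Merge contiguous band runs and print 'start:end' nm (integer-rounded)."""
    bands = np.sort(np.asarray(bands, dtype=int))
    runs = []
    start = prev = bands[0]
    for b in bands[1:]:
        if b == prev + 1:
            prev = b
            continue
        runs.append((start, prev))
        start = prev = b
    runs.append((start, prev))
    return " ".join(
        f"{round(grid.centers[a]):d}:{round(grid.centers[b]):d}" for a, b in runs
    )


def ipls_forward(
    X: np.ndarray,
    y: np.ndarray,
    interval_width: int,
    lv_max: int,
    plan: CVPlan,
    grid: BandGrid,
    centering: str = "fold",
) -> IPLSResult:
    """Forward interval selection by minimum RMSECV.

    Starts from the single best interval (LV count re-optimised for
    every candidate set), then repeatedly adds the interval whose
    inclusion most reduces RMSECV; stops when no addition strictly
    improves, so the trajectory is strictly decreasing by construction.
    Ties break deterministically: lower RMSECV, then fewer LVs, then
    lower interval index.
    """
    X = np.asarray(X, dtype=float)
    partition = make_partition(X.shape[1], interval_width)

    def evaluate(intervals: list[int]) -> tuple[float, int]:
        bands = sorted(b for i in intervals for b in partition[i])
        cv = cross_validate(X[:, bands], y, lv_max, plan, centering=centering)
        return float(cv.rmsecv[cv.chosen_lv - 1]), cv.chosen_lv

    selected: list[int] = []
    trajectory: list[float] = []
    current = np.inf
    remaining = list(range(len(partition)))
    while remaining:
        best = None
        for j in remaining:
            rmsecv, lv = evaluate(selected + [j])
            key = (rmsecv, lv, j)
            if best is None or key < best:
                best = key
                best_j = j
        if not selected or best[0] < current:
            selected.append(best_j)
            remaining.remove(best_j)
            current = best[0]
            trajectory.append(current)
        else:
            break
    bands = sorted(b for i in selected for b in partition[i])
    perf_cv = cross_validate(X[:, bands], y, lv_max, plan, centering=centering)
    model = fit_pls(X[:, bands], y, perf_cv.chosen_lv)
    y_arr = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(X[:, bands])
    sse = float(((yhat - y_arr) ** 2).sum())
    ss_tot = float(((y_arr - y_arr.mean()) ** 2).sum())
    perf = PLSPerformance(
        n_lv=perf_cv.chosen_lv,
        rmsec=float(np.sqrt(sse / y_arr.size)),
        rmsecv=float(perf_cv.rmsecv[perf_cv.chosen_lv - 1]),
        r2_cal=np.nan if ss_tot == 0 else 1.0 - sse / ss_tot,
        r2_cv=perf_cv.r2_cv,
    )
    return IPLSResult(
        interval_width=interval_width,
        partition=partition,
        selected=tuple(selected),
        selected_ranges=format_ranges(np.asarray(bands), grid),
        performance=perf,
        trajectory=tuple(trajectory),
    )


# ------------------------------------------------------------------- report


def default_lv_max(n: int) -> int:
    """Cap on latent variables: min(10, n // 3) guards tiny CV folds."""
    return max(1, min(10, n // 3))


def build_model_report(
    spectra: SpectralDataset,
    traits: pd.DataFrame,
    lv_max: int | None = None,
    k: int = 3,
    seed: int = 0,
    widths: tuple[int, ...] = (10, 5),
    centering: str = "fold",
) -> pd.DataFrame:
    """Full-spectrum PLS plus one forward-iPLS row per interval width, for
    every trait column.

    Each trait is paired with the spectra on ``vine_id`` and NA rows
    dropped (subset traits keep their subset).  Within a trait, the best
    row has minimum RMSECV (ties → higher R² CV, then fewer variables)
    and is flagged in the ``best`` column.
    """
    trait_cols = [c for c in traits.columns if c != "vine_id"]
    frame = pd.DataFrame(
        {"vine_id": spectra.vine_id} | {
            f"__b{j}": spectra.values[:, j] for j in range(spectra.values.shape[1])
        }
    )
    rows = []
    for t in trait_cols:
        merged = pd.merge(frame, traits[["vine_id", t]].dropna(), on="vine_id", how="inner")
        X = merged[[c for c in merged.columns if c.startswith("__b")]].to_numpy(float)
        y = merged[t].to_numpy(float)
        n = len(y)
        plan = CVPlan(n=n, k=k, seed=seed)
        lmax = default_lv_max(n) if lv_max is None else lv_max
        perf = assess(X, y, lmax, plan, centering=centering)
        trows = [{
            "y": t, "method": "PLS", "interval_size": None, "selected_bands": "-",
            "n_samples": n, "n_variables": X.shape[1], "n_lv": perf.n_lv,
            "rmsec": perf.rmsec, "rmsecv": perf.rmsecv,
            "r2_cal": perf.r2_cal, "r2_cv": perf.r2_cv,
        }]
        for w in widths:
            res = ipls_forward(X, y, w, lmax, plan, spectra.grid, centering=centering)
            trows.append({
                "y": t, "method": "iPLS", "interval_size": w,
                "selected_bands": res.selected_ranges,
                "n_samples": n, "n_variables": res.selected_bands.size,
                "n_lv": res.performance.n_lv,
                "rmsec": res.performance.rmsec, "rmsecv": res.performance.rmsecv,
                "r2_cal": res.performance.r2_cal, "r2_cv": res.performance.r2_cv,
            })
        order = sorted(
            range(len(trows)),
            key=lambda i: (
                trows[i]["rmsecv"],
                -(trows[i]["r2_cv"] if np.isfinite(trows[i]["r2_cv"]) else -np.inf),
                trows[i]["n_variables"],
            ),
        )
        for i, r in enumerate(trows):
            r["best"] = i == order[0]
        rows.extend(trows)
    return pd.DataFrame(rows)
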