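"""PCA exploration and PLS calibration with day-segmented cross-validation.

The calibration task: regress GC-measured fatty-acid parameters (Y) on
preprocessed FTIR spectra (X) with partial least squares (PLS1, one model
per response, NIPALS algorithm, mean-centering only).  Model complexity is
chosen by leave-one-day-out cross-validation — all spectra from samples
collected on the same cultivation day form one held-out segment, so the
model must predict an unseen time point rather than an unseen replicate —
over 1..25 latent variables, picking the most parsimonious model whose RMSE
is statistically indistinguishable from the minimum (one-standard-error
rule on the between-segment spread).

Reported per response: reference range/mean/SD, cross-validated R^2 (squared
Pearson correlation of CV predictions vs reference), RMSECV, and the
residual predictive deviation RPD_CV = SD / RMSECV (>= 2 usable, >= 3 good).

To keep cross-validation leak-free the EMSC reference can be refit on each
fold's training samples and applied to the held-out day; the held-out day
then never influences centering, the scatter-correction reference, or the
fit itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ResponseError, SegmentationError
from .fatty_acids import FattyAcidTable, summed_parameters, autoscale as _autoscale
from .preprocess import PreprocessConfig, emsc_correct, savitzky_golay_derivative
from .spectra import SpectrumSet, average_technical_replicates, select_region

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# PCA

def pca_scores(
    matrix: Union[np.ndarray, pd.DataFrame],
    scaling: str = "center",
    n_components: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component scores/loadings via SVD of the scaled matrix.

    ``scaling`` is ``"center"`` (column mean-centering, the usual choice for
    spectra) or ``"autoscale"`` (unit variance, the usual choice for GC
    composition data).  Returns (scores, loadings, explained_variance_ratio).
    Sign convention: the largest-magnitude loading element of each component
    is positive, making results reproducible across SVD implementations.
    """
    X = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if scaling == "center":
        Xs = X - X.mean(axis=0)
    elif scaling == "autoscale":
        Xs, _, _ = _autoscale(X)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    k = S.size if n_components is None else min(n_components, S.size)
    evr = (S**2 / max((S**2).sum(), _EPS))[:k]
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, evr


# ---------------------------------------------------------------------------
# PLS (NIPALS)

@dataclass
class PLSModel:
    """Fitted latent-variable regression (NIPALS, mean-centered, unscaled X)."""

    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray  # (n_responses,)
    x_weights: np.ndarray  # W, (n_vars, k)
    x_loadings: np.ndarray  # P, (n_vars, k)
    y_loadings: np.ndarray  # Q, (n_responses, k)
    metadata: dict = field(default_factory=dict)

    def coefficients(self, k: Optional[int] = None) -> np.ndarray:
        """Regression coefficients B (n_vars, n_responses) using the first
        ``k`` latent variables: B = W (P'W)^-1 Q'."""
        k = self.n_components if k is None else k
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must be in 1..{self.n_components}")
        W, P, Q = self.x_weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    @property
    def regression_coefficients(self) -> np.ndarray:
        return self.coefficients()


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSModel:
    """NIPALS PLS with successive deflation.

    Univariate y gives the (non-iterative) PLS1 path; a response matrix is
    handled by the iterative PLS2 update.  X and y are mean-centered, X is
    not variance-scaled.  If the residual carries no covariance with y the
    extraction stops early and the model holds fewer components.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    y2d = y[:, None] if y.ndim == 1 else y
    n, p = X.shape
    if y2d.shape[0] != n:
        raise ValueError("X and y are not row-aligned")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in 1..min(n_samples-1, n_vars) = {min(n - 1, p)}"
        )
    if np.any(y2d.std(axis=0) < _EPS):
        raise ResponseError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = y2d.mean(axis=0)
    E = X - x_mean
    F = y2d - y_mean
    m = y2d.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    k_eff = 0
    for k in range(n_components):
        if m == 1:
            w = E.T @ F[:, 0]
            nw = np.linalg.norm(w)
            if nw < _EPS * max(1.0, np.linalg.norm(F)):
                break
            w /= nw
            t = E @ w
        else:
            u = F[:, np.argmax(F.var(axis=0))]
            t_old = None
            for it in range(max_iter):
                w = E.T @ u
                nw = np.linalg.norm(w)
                if nw < _EPS:
                    break
                w /= nw
                t = E @ w
                q = F.T @ t / max(t @ t, _EPS)
                u = F @ q / max(q @ q, _EPS)
                if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                    break
                t_old = t
            else:
                raise np.linalg.LinAlgError(
                    f"NIPALS did not converge in component {k + 1}"
                )
            if nw < _EPS:
                break
        tt = t @ t
        if tt < _EPS:
            break
        p_load = E.T @ t / tt
        q_load = F.T @ t / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q_load)
        W[:, k], P[:, k], Q[:, k] = w, p_load, q_load
        k_eff = k + 1
    if k_eff == 0:
        # no covariance at all: keep one null component so predictions = mean
        k_eff = 1
        W[:, 0] = P[:, 0] = 0.0
        W[0, 0] = P[0, 0] = 1.0
        Q[:, 0] = 0.0
    return PLSModel(
        n_components=k_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W[:, :k_eff],
        x_loadings=P[:, :k_eff],
        y_loadings=Q[:, :k_eff],
    )


def pls_predict(m: PLSModel, X_new: np.ndarray, k: Optional[int] = None) -> np.ndarray:
    """Predict responses: y_hat = (X_new - x_mean) B + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} variables; model was trained on {m.x_mean.size}"
        )
    out = (X_new - m.x_mean) @ m.coefficients(k) + m.y_mean
    return out[:, 0] if m.y_mean.size == 1 else out


# ---------------------------------------------------------------------------
# Day-segmented cross-validation

@dataclass
class CVResult:
    response: str
    rmse_by_ncomp: np.ndarray  # (max_ncomp,)
    se_by_ncomp: np.ndarray  # between-segment standard error, (max_ncomp,)
    chosen_ncomp: int
    predictions: pd.DataFrame  # columns: segment, y_true, y_pred (chosen), per-k preds
    pred_matrix: np.ndarray  # (n_samples, max_ncomp)

    @property
    def cv_predictions(self) -> np.ndarray:
        """Per-sample prediction at the chosen component count."""
        return self.pred_matrix[:, self.chosen_ncomp - 1]


def select_components(
    rmse_by_ncomp: Sequence[float], se_by_ncomp: Sequence[float]
) -> int:
    """Most parsimonious model not significantly worse than the best one.

    With k* the (smallest) RMSE-minimizing component count, returns the
    smallest k <= k* whose RMSE is within one between-segment standard error
    of RMSE(k*) (the one-standard-error rule).
    """
    rmse = np.asarray(rmse_by_ncomp, float)
    se = np.asarray(se_by_ncomp, float)
    if rmse.size == 0 or rmse.size != se.size:
        raise ValueError("rmse and se vectors must be equal length >= 1")
    k_star = int(np.argmin(rmse))
    threshold = rmse[k_star] + se[k_star]
    for k in range(k_star + 1):
        if rmse[k] <= threshold:
            return k + 1
    return k_star + 1


def day_segmented_cv(
    X: np.ndarray,
    y: np.ndarray,
    days: Sequence,
    max_ncomp: int = 25,
    response: str = "y",
    emsc_refit: bool = False,
    wavenumbers: Optional[np.ndarray] = None,
    emsc_cfg: Optional[PreprocessConfig] = None,
) -> CVResult:
    """Leave-one-day-out cross-validation of a PLS1 model.

    All samples sharing a ``days`` value form one segment; each segment is
    held out in turn and predicted by a model fit on the rest, for
    1..max_ncomp components.  With ``emsc_refit`` the EMSC reference is the
    mean of each fold's *training* derivative spectra and the held-out day is
    corrected against it (leak-free); ``X`` must then be the pre-EMSC
    derivative spectra on the combined region, with ``wavenumbers`` given.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    days = np.asarray(days)
    if X.shape[0] != y.size or y.size != days.size:
        raise ValueError("X, y and days are not aligned")
    uniq = np.unique(days)
    if uniq.size < 2:
        raise SegmentationError(
            "day-segmented CV needs >= 2 distinct days; one day holds all samples"
        )
    if emsc_refit:
        if wavenumbers is None:
            raise ValueError("emsc_refit requires the wavenumber grid")
        emsc_cfg = emsc_cfg or PreprocessConfig()

    n = y.size
    preds = np.full((n, max_ncomp), np.nan)
    seg_rmse = np.full((uniq.size, max_ncomp), np.nan)
    for si, d in enumerate(uniq):
        test = days == d
        train = ~test
        X_tr, X_te = X[train], X[test]
        if emsc_refit:
            ref = X_tr.mean(axis=0)
            X_tr = _emsc_rows(wavenumbers, X_tr, ref, emsc_cfg)
            X_te = _emsc_rows(wavenumbers, X_te, ref, emsc_cfg)
        k_max = min(max_ncomp, X_tr.shape[0] - 1, X_tr.shape[1])
        model = pls_fit(X_tr, y[train], k_max)
        Xc = X_te - model.x_mean
        for k in range(1, max_ncomp + 1):
            kk = min(k, model.n_components)
            preds[test, k - 1] = Xc @ model.coefficients(kk)[:, 0] + model.y_mean[0]
        seg_rmse[si] = np.sqrt(
            np.mean((preds[test] - y[test, None]) ** 2, axis=0)
        )

    rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    se = seg_rmse.std(axis=0, ddof=1) / np.sqrt(uniq.size)
    chosen = select_components(rmse, se)
    frame = pd.DataFrame(
        {
            "segment": days,
            "y_true": y,
            "y_pred": preds[:, chosen - 1],
        }
    )
    return CVResult(
        response=response,
        rmse_by_ncomp=rmse,
        se_by_ncomp=se,
        chosen_ncomp=chosen,
        predictions=frame,
        pred_matrix=preds,
    )


def _emsc_rows(
    wavenumbers: np.ndarray,
    rows: np.ndarray,
    reference: np.ndarray,
    cfg: PreprocessConfig,
) -> np.ndarray:
    """EMSC-correct a plain row matrix against a fixed reference."""
    from .spectra import SampleMeta, SpectrumSet

    meta = [
        SampleMeta(sample_id=f"r{i}", species="x", temperature=0.0, day=1, bio_rep=i + 1)
        for i in range(rows.shape[0])
    ]
    corrected, _ = emsc_correct(
        SpectrumSet(wavenumbers, rows, meta), cfg, reference=reference
    )
    return corrected.absorbance


# ---------------------------------------------------------------------------
# Calibration metrics and the full calibration builder

@dataclass
class CalibrationRow:
    response: str
    range_min: float
    range_max: float
    mean: float
    sd: float
    r2_cv: float
    rmsecv: float
    rpd_cv: float  # inf for a perfect (RMSECV = 0) model
    pls_factors: int


@dataclass
class CalibrationReport:
    rows: List[CalibrationRow]
    cv_results: Dict[str, CVResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "response": r.response,
                    "range_min": r.range_min,
                    "range_max": r.range_max,
                    "mean": r.mean,
                    "sd": r.sd,
                    "r2_cv": r.r2_cv,
                    "rmsecv": r.rmsecv,
                    "rpd_cv": r.rpd_cv,
                    "pls_factors": r.pls_factors,
                }
                for r in self.rows
            ]
        )

    def formatted(self) -> str:
        """Text table in the conventional calibration-report layout:
        response, range, mean, SD, R^2, RMSECV, RPD_CV, PLS factors."""
        lines = [
            f"{'Response':<20}{'Range':>14}{'Mean':>8}{'SD':>7}"
            f"{'R2':>6}{'RMSECV':>8}{'RPD_CV':>8}{'Factors':>8}"
        ]
        for r in self.rows:
            d = 2 if abs(r.mean) < 5 else 1  # small-magnitude responses (UI)
            rng = f"{r.range_min:.{d}f}-{r.range_max:.{d}f}"
            rpd = "inf" if np.isinf(r.rpd_cv) else f"{r.rpd_cv:.1f}"
            lines.append(
                f"{r.response:<20}{rng:>14}{r.mean:>8.{d}f}{r.sd:>7.{d}f}"
                f"{r.r2_cv:>6.2f}{r.rmsecv:>8.{d}f}{rpd:>8}{r.pls_factors:>8d}"
            )
        return "\n".join(lines)


def calibration_metrics(cv: CVResult, y_reference: Optional[np.ndarray] = None) -> CalibrationRow:
    """Summary statistics of a cross-validated calibration.

    RMSECV is recomputed from the pooled CV predictions at the chosen
    component count; R^2 is the squared Pearson correlation between CV
    predictions and reference; RPD_CV = SD(y) / RMSECV with the n-1 SD, so
    RPD * RMSECV = SD holds exactly before any rounding.
    """
    y = cv.predictions["y_true"].to_numpy() if y_reference is None else np.asarray(y_reference, float)
    yhat = cv.cv_predictions
    if y.size != yhat.size:
        raise ValueError("reference not aligned with CV predictions")
    sd = float(y.std(ddof=1))
    if sd < _EPS:
        raise ResponseError(f"{cv.response}: constant reference, R^2 undefined")
    rmsecv = float(np.sqrt(np.mean((yhat - y) ** 2)))
    r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2) if rmsecv > 0 else 1.0
    rpd = float("inf") if rmsecv == 0 else sd / rmsecv
    return CalibrationRow(
        response=cv.response,
        range_min=float(y.min()),
        range_max=float(y.max()),
        mean=float(y.mean()),
        sd=sd,
        r2_cv=r2,
        rmsecv=rmsecv,
        rpd_cv=rpd,
        pls_factors=cv.chosen_ncomp,
    )


def build_calibration(
    spectra: SpectrumSet,
    gc: FattyAcidTable,
    responses: Sequence[str],
    exclusions: Sequence[Tuple[str, float, int]] = (),
    max_ncomp: int = 25,
    cfg: PreprocessConfig = PreprocessConfig(),
    emsc_policy: str = "per-fold",
) -> CalibrationReport:
    """End-to-end calibration of spectral data against a GC reference table.

    ``spectra`` may contain technical replicates (they are averaged first).
    The GC table is keyed by (species, temperature, day); its one averaged
    composition maps onto every biological-replicate spectrum of that
    condition.  ``exclusions`` lists (species, temperature, day) condition
    triples removed before regression (e.g. early-growth samples whose
    biomass chemistry is not yet lipid-dominated).  ``responses`` may name
    raw composition columns or derived parameters (SAT, MUFA, PUFA,
    unsaturation_index, total_lipid).  ``emsc_policy`` is "per-fold"
    (leak-free: the EMSC reference is refit on each CV fold's training days)
    or "global" (one correction of the full set up front).
    """
    if not responses:
        raise ResponseError("no responses requested")
    if emsc_policy not in ("per-fold", "global"):
        raise ValueError(f"unknown emsc_policy {emsc_policy!r}")

    averaged = average_technical_replicates(spectra)
    deriv = savitzky_golay_derivative(averaged, cfg)
    restricted = select_region(deriv, cfg.emsc_regions)

    excl = {(sp, float(t), int(d)) for sp, t, d in exclusions}
    keep = [
        i
        for i, m in enumerate(restricted.meta)
        if (m.species, float(m.temperature), int(m.day)) not in excl
    ]
    n_before = restricted.n_samples
    restricted = restricted.subset(keep)
    logger.info(
        "exclusion filter: %d -> %d averaged spectra", n_before, restricted.n_samples
    )

    # response table keyed by condition
    params = summed_parameters(gc)
    ytab = pd.concat([gc.data[list(gc.acid_columns)], params], axis=1)
    ytab = ytab.loc[:, ~ytab.columns.duplicated()]
    keys = list(
        zip(gc.data["species"], gc.data["temperature"].astype(float), gc.data["day"].astype(int))
    )
    if len(set(keys)) != len(keys):
        raise ResponseError("GC table has duplicate (species, temperature, day) keys")
    ytab.index = pd.MultiIndex.from_tuples(keys)

    cond = [(m.species, float(m.temperature), int(m.day)) for m in restricted.meta]
    missing = sorted({c for c in cond if c not in ytab.index})
    if missing:
        raise ResponseError(f"spectra with no GC reference: {missing[:5]}" +
                            (" ..." if len(missing) > 5 else ""))
    Y = ytab.loc[cond]

    bad = [r for r in responses if r not in Y.columns]
    if bad:
        raise ResponseError(f"response(s) not found in GC data: {bad}")

    X = restricted.absorbance
    wn = restricted.wavenumbers
    days = np.array([m.day for m in restricted.meta])
    if emsc_policy == "global":
        corrected, _ = emsc_correct(restricted, cfg)
        X = corrected.absorbance

    rows, cvs = [], {}
    for resp in responses:
        cv = day_segmented_cv(
            X,
            Y[resp].to_numpy(float),
            days,
            max_ncomp=max_ncomp,
            response=resp,
            emsc_refit=(emsc_policy == "per-fold"),
            wavenumbers=wn if emsc_policy == "per-fold" else None,
            emsc_cfg=cfg,
        )
        rows.append(calibration_metrics(cv))
        cvs[resp] = cv
    return CalibrationReport(rows=rows, cv_results=cvs)
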