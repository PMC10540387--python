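"""NIPALS PLS1 calibration, cross-validation, external validation and RPD scoring.

The calibration chain mirrors standard NIRS chemometrics practice:

1. the sample set is split 4:1 into calibration and external-validation sets,
   with the global minimum and maximum reference samples forced into the
   calibration set so the model never extrapolates during validation;
2. for each candidate (pretreatment × wavelength-window) combination a PLS1
   model is built by NIPALS, its rank (number of latent variables) chosen by
   segmented cross-validation with a parsimony rule;
3. models are ranked by RMSECV and the winner is externally validated on the
   held-out set (RMSEP, R²ev, RPD);
4. optionally, calibration and validation sets are merged and the model is
   recalibrated on the union ("global" modeling).

Model quality statistics follow the conventional definitions: RMSE of the
stage being scored, R² = 1 − SS_res/SS_tot against that stage's observed
values, and RPD = SD_ref/RMSE where SD_ref is always the calibration-set
reference standard deviation (reported to two decimals).

All randomness (splits, CV segment shuffles) sits behind integer seeds.
Pretreatment statistics (MSC reference, centering) are refit inside every CV
fold so no information leaks into held-out segments.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ModelingError
from .preprocess import PretreatmentSpec, apply_pretreatment, fit_pretreatment
from .spectra import (
    ABSORBANCE,
    ReferenceTable,
    SpectraSet,
    WindowSet,
    align,
    apply_windows,
)

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Model container and (de)serialization
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Frozen PLS1 calibration artifact.

    Holds everything needed to predict new spectra: the wavelength windows,
    the fitted pretreatment (with frozen MSC reference where applicable),
    centering statistics, the NIPALS weights/loadings and the composed
    regression coefficient vector in pretreated-variable space.
    """

    trait_name: str
    units: str
    rank: int
    x_mean: np.ndarray
    y_mean: float
    y_sd: float  # calibration-set reference SD (ddof=1); RPD numerator
    weights: np.ndarray  # (p, rank)
    x_loadings: np.ndarray  # (p, rank)
    y_loadings: np.ndarray  # (rank,)
    coefficients: np.ndarray  # (p,)
    pretreatment: PretreatmentSpec
    windows: WindowSet | None
    grid: np.ndarray  # selected-variable wavenumber grid
    calibration_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ModelingError("PLS rank must be >= 1")
        if self.coefficients.shape != (self.grid.size,):
            raise ModelingError("coefficient length must equal the selected-variable count")


def save_model(m: PLSModel, path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "trait_name": m.trait_name,
        "units": m.units,
        "rank": m.rank,
        "x_mean": m.x_mean.tolist(),
        "y_mean": m.y_mean,
        "y_sd": m.y_sd,
        "weights": m.weights.tolist(),
        "x_loadings": m.x_loadings.tolist(),
        "y_loadings": m.y_loadings.tolist(),
        "coefficients": m.coefficients.tolist(),
        "pretreatment": {
            "method": m.pretreatment.method,
            "sg_window": m.pretreatment.sg_window,
            "sg_polyorder": m.pretreatment.sg_polyorder,
            "msc_reference": None
            if m.pretreatment.msc_reference is None
            else m.pretreatment.msc_reference.tolist(),
        },
        "windows": None if m.windows is None else m.windows.intervals,
        "grid": m.grid.tolist(),
        "calibration_ids": m.calibration_ids,
        "seed": m.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> PLSModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise DataError(f"unsupported model schema version {doc.get('schema_version')}")
    pre = doc["pretreatment"]
    ref = pre["msc_reference"]
    return PLSModel(
        trait_name=doc["trait_name"],
        units=doc["units"],
        rank=doc["rank"],
        x_mean=np.array(doc["x_mean"], float),
        y_mean=float(doc["y_mean"]),
        y_sd=float(doc["y_sd"]),
        weights=np.array(doc["weights"], float),
        x_loadings=np.array(doc["x_loadings"], float),
        y_loadings=np.array(doc["y_loadings"], float),
        coefficients=np.array(doc["coefficients"], float),
        pretreatment=PretreatmentSpec(
            method=pre["method"],
            sg_window=pre["sg_window"],
            sg_polyorder=pre["sg_polyorder"],
            msc_reference=None if ref is None else np.array(ref, float),
        ),
        windows=None if doc["windows"] is None else WindowSet([tuple(iv) for iv in doc["windows"]]),
        grid=np.array(doc["grid"], float),
        calibration_ids=list(doc["calibration_ids"]),
        seed=doc["seed"],
    )


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

def _nipals(Xc: np.ndarray, yc: np.ndarray, rank: int, allow_partial: bool = False):
    """NIPALS PLS1 on centered data.

    Per component: w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then
    deflate X (and y). Deterministic — PLS1 needs no random initialization.

    Returns (W, P, q, T) with as many columns as fitted; raises naming the
    failing component when the requested rank exceeds the data rank, unless
    ``allow_partial`` is set.
    """
    X = np.array(Xc, dtype=float)
    y = np.array(yc, dtype=float)
    n, p = X.shape
    if rank < 1 or rank > min(n - 1, p):
        raise ModelingError(f"rank={rank} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    scale = float(np.linalg.norm(X) * np.linalg.norm(y))
    tol = 1e-12 * max(scale, 1.0)
    W = np.zeros((p, rank))
    P = np.zeros((p, rank))
    q = np.zeros(rank)
    T = np.zeros((n, rank))
    fitted = 0
    for a in range(rank):
        w = X.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= tol:
            if allow_partial:
                break
            raise ModelingError(
                f"requested rank {rank} exceeds data rank: zero-norm weight at component {a + 1}"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= tol**2 or tt <= 1e-30:
            if allow_partial:
                break
            raise ModelingError(
                f"requested rank {rank} exceeds data rank: degenerate scores at component {a + 1}"
            )
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        fitted = a + 1
    return W[:, :fitted], P[:, :fitted], q[:fitted], T[:, :fitted]


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, rank: int) -> np.ndarray:
    """Compose the regression vector B = W (PᵀW)⁻¹ q at the given rank."""
    Wa, Pa, qa = W[:, :rank], P[:, :rank], q[:rank]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_pls(X: np.ndarray, y: np.ndarray, rank: int) -> PLSModel:
    """Fit a PLS1 model on a pretreated matrix (centering handled internally).

    Returns a matrix-level :class:`PLSModel` (no windows/pretreatment attached;
    use :func:`calibrate` for the full spectra-to-trait chain).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise DataError("X and y must have the same number of samples")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals(X - x_mean, y - y_mean, rank)
    return PLSModel(
        trait_name="",
        units="",
        rank=rank,
        x_mean=x_mean,
        y_mean=y_mean,
        y_sd=float(y.std(ddof=1)) if y.size > 1 else 0.0,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=_coefficients(W, P, q, rank),
        pretreatment=PretreatmentSpec("NONE"),
        windows=None,
        grid=np.arange(X.shape[1], dtype=float),
    )


def calibrate(
    s: SpectraSet,
    ref: ReferenceTable,
    pretreatment: PretreatmentSpec,
    windows: WindowSet | None,
    rank: int,
    seed: int | None = None,
) -> PLSModel:
    """Full calibration chain: windows → fit+apply pretreatment → NIPALS PLS1."""
    s, ref = align(s, ref)
    sw = apply_windows(s, windows) if windows is not None else s
    pre = fit_pretreatment(sw, pretreatment)
    X = apply_pretreatment(sw, pre).values
    y = ref.values
    m = fit_pls(X, y, rank)
    m.trait_name, m.units = ref.trait_name, ref.units
    m.pretreatment, m.windows, m.grid = pre, windows, sw.grid.copy()
    m.calibration_ids, m.seed = list(s.sample_ids), seed
    return m


def predict(m: PLSModel, s: SpectraSet) -> np.ndarray:
    """Predict trait values for new spectra through the frozen model chain."""
    sw = apply_windows(s, m.windows) if m.windows is not None else s
    if sw.grid.size != m.grid.size or not np.allclose(sw.grid, m.grid):
        label = m.windows.label() if m.windows is not None else "full model grid"
        raise DataError(
            f"spectra grid incompatible with the model's selected range ({label}); "
            f"got {sw.grid.size} variables, model expects {m.grid.size}"
        )
    X = apply_pretreatment(sw, m.pretreatment).values
    return m.y_mean + (X - m.x_mean) @ m.coefficients


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

def metrics(y_obs: np.ndarray, y_hat: np.ndarray, sd_ref: float) -> dict:
    """RMSE, R², RPD and bias of predictions against observed values.

    RMSE uses the n denominator; R² = 1 − SS_res/SS_tot against the observed
    values of the stage being scored; RPD = sd_ref/RMSE (∞ if RMSE is 0).
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_obs.size != y_hat.size or y_obs.size < 2:
        raise DataError("metrics need equal-length vectors with at least 2 entries")
    if not sd_ref > 0:
        raise DataError("sd_ref must be positive")
    resid = y_hat - y_obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("observed values are constant; R² undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {
        "rmse": rmse,
        "r2": r2,
        "rpd": float("inf") if rmse == 0 else float(sd_ref) / rmse,
        "bias": float(resid.mean()),
    }


def rpd(sd_ref: float, rmse: float) -> float:
    """Ratio of (reference) deviation to prediction error: sd_ref / RMSE."""
    if not sd_ref > 0:
        raise DataError("sd_ref must be positive")
    return float("inf") if rmse == 0 else float(sd_ref) / float(rmse)


# ---------------------------------------------------------------------------
# Calibration / validation split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """A calibration/external-validation partition of sample ids."""

    calibration_ids: list[str]
    validation_ids: list[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise DataError(f"calibration/validation sets overlap: {sorted(overlap)[:5]}")


def split_calibration_validation(ref: ReferenceTable, ratio: float = 0.8, seed: int = 0) -> SplitSpec:
    """Seeded random split with range containment.

    After a uniform split at the given calibration fraction, the samples
    holding the global minimum and maximum reference values are swapped into
    the calibration set (exchanging with random validation members so counts
    are preserved), ensuring the validation set never requires extrapolation.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigError(f"split ratio must be in (0, 1), got {ratio}")
    n = ref.n_samples
    if n < 10:
        raise DataError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(round(ratio * n))
    n_cal = min(max(n_cal, 1), n - 1)
    cal = list(perm[:n_cal])
    val = list(perm[n_cal:])
    extremes = {int(np.argmin(ref.values)), int(np.argmax(ref.values))}
    for ex in sorted(extremes):
        if ex in val:
            candidates = [i for i in cal if i not in extremes]
            swap = candidates[int(rng.integers(len(candidates)))]
            cal[cal.index(swap)] = ex
            val[val.index(ex)] = swap
    ids = ref.sample_ids
    return SplitSpec([ids[i] for i in cal], [ids[i] for i in val], ratio, seed)


# ---------------------------------------------------------------------------
# Cross-validation and rank selection
# ---------------------------------------------------------------------------

def _segments(n: int, n_segments: int, seed: int) -> list[np.ndarray]:
    if not 2 <= n_segments <= n:
        raise ModelingError(f"n_segments must be in [2, n={n}], got {n_segments}")
    rng = np.random.default_rng(seed)
    parts = np.array_split(rng.permutation(n), n_segments)
    if n_segments != n and min(len(p) for p in parts) < 2:
        raise ModelingError(
            f"segments of size < 2 with n_segments={n_segments}, n={n}; "
            "use leave-one-out (n_segments = n) instead"
        )
    return parts


def _pre_context(values, grid, pretreatment):
    """Build a throwaway SpectraSet so pretreatment fit/apply can run on a fold."""
    ids = [f"_cv{i}" for i in range(values.shape[0])]
    return SpectraSet(ids, grid, values, ABSORBANCE)


def _cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    max_rank: int,
    n_segments: int,
    seed: int,
    pretreatment: PretreatmentSpec | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray], int]:
    """Pooled out-of-segment predictions for every rank 1..max_rank.

    Each fold fits NIPALS once at the highest feasible rank and extracts the
    coefficient vector at every smaller rank, so rank selection costs one fit
    per fold. Pretreatment statistics are refit on each training fold.

    Returns (pred matrix n × R, segment index arrays, R = feasible max rank).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    parts = _segments(n, n_segments, seed)
    if grid is None:
        grid = np.arange(X.shape[1], dtype=float)
    fold_results = []
    feasible = max_rank
    for held in parts:
        train = np.setdiff1d(np.arange(n), held)
        Xtr, Xte = X[train], X[held]
        if pretreatment is not None and pretreatment.method != "NONE":
            spec = fit_pretreatment(_pre_context(Xtr, grid, pretreatment), pretreatment)
            Xtr = apply_pretreatment(_pre_context(Xtr, grid, spec), spec).values
            Xte = apply_pretreatment(_pre_context(Xte, grid, spec), spec).values
        x_mean, y_mean = Xtr.mean(axis=0), y[train].mean()
        cap = min(max_rank, min(len(train) - 1, Xtr.shape[1]))
        W, P, q, _ = _nipals(Xtr - x_mean, y[train] - y_mean, cap, allow_partial=True)
        got = W.shape[1]
        if got < 1:
            raise ModelingError("a CV training fold has zero spectral variance")
        feasible = min(feasible, got)
        fold_results.append((held, Xte - x_mean, y_mean, W, P, q))
    preds = np.empty((n, feasible))
    for held, Xte_c, y_mean, W, P, q in fold_results:
        for r in range(1, feasible + 1):
            preds[held, r - 1] = y_mean + Xte_c @ _coefficients(W, P, q, r)
    return preds, parts, feasible


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    rank: int,
    n_segments: int,
    seed: int,
    pretreatment: PretreatmentSpec | None = None,
    grid: np.ndarray | None = None,
) -> dict:
    """Segmented cross-validation at a fixed rank.

    The calibration set is shuffled (seeded) and cut into near-equal
    contiguous segments; each segment is predicted by a model refitted on the
    others (including pretreatment statistics). Pooled predictions give
    RMSECV and R²cv.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds, parts, feasible = _cv_predictions(X, y, rank, n_segments, seed, pretreatment, grid)
    if feasible < rank:
        raise ModelingError(f"rank {rank} infeasible in at least one CV fold (max {feasible})")
    y_hat = preds[:, rank - 1]
    stats = metrics(y, y_hat, sd_ref=float(y.std(ddof=1)))
    return {
        "rmsecv": stats["rmse"],
        "r2cv": stats["r2"],
        "rpd_cv": stats["rpd"],
        "predictions": y_hat,
        "segments": parts,
    }


def select_rank(
    X: np.ndarray,
    y: np.ndarray,
    max_rank: int,
    n_segments: int,
    seed: int,
    parsimony: bool = True,
    parsimony_tol: float = 1.02,
    pretreatment: PretreatmentSpec | None = None,
    grid: np.ndarray | None = None,
) -> int:
    """Choose the PLS rank by cross-validated RMSECV.

    With the parsimony rule (default) the smallest rank whose RMSECV is
    within ``parsimony_tol`` × the minimum is returned; with
    ``parsimony=False`` the pure argmin.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds, _, feasible = _cv_predictions(X, y, max_rank, n_segments, seed, pretreatment, grid)
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    if not parsimony:
        return int(np.argmin(rmsecv)) + 1
    best = float(rmsecv.min())
    ok = np.nonzero(rmsecv <= parsimony_tol * best)[0]
    return int(ok[0]) + 1


# ---------------------------------------------------------------------------
# Reports, model search, external validation, global modeling
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    """The Table-style statistic set for one calibrated model."""

    trait_name: str
    units: str
    pretreatment: str
    spectrum_range: str
    rank: int
    n: int
    mean: float
    sd: float
    rmsec: float
    r2: float
    rpd_cal: float
    rmsecv: float
    r2cv: float
    rpd_cv: float
    n_val: int | None = None
    rmsep: float | None = None
    r2ev: float | None = None
    rpd_ev: float | None = None
    stage: str = "calibration"
    seed: int | None = None
    model: PLSModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("rmsec", "rmsecv", "rmsep"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ModelingError(f"{name} must be >= 0")
        for name in ("r2", "r2cv", "r2ev"):
            v = getattr(self, name)
            if v is not None and v > 1 + 1e-12:
                raise ModelingError(f"{name} must be <= 1")


_LEADERBOARD_COLUMNS = [
    "trait", "SCM", "spectrum_range", "rank", "N", "mean", "SD",
    "RMSEC", "R2", "RPD_cal", "RMSECV", "R2cv", "RPD_cv",
    "N_val", "RMSEP", "R2ev", "RPD_ev", "stage", "seed",
]


def leaderboard_frame(reports: list[CalibrationReport]) -> pd.DataFrame:
    """Tabulate reports with conventional column names; RPDs at 2 decimals."""
    rows = []
    for r in reports:
        rows.append(
            {
                "trait": r.trait_name,
                "SCM": r.pretreatment,
                "spectrum_range": r.spectrum_range,
                "rank": r.rank,
                "N": r.n,
                "mean": round(r.mean, 4),
                "SD": round(r.sd, 4),
                "RMSEC": round(r.rmsec, 6),
                "R2": round(r.r2, 6),
                "RPD_cal": round(r.rpd_cal, 2) if np.isfinite(r.rpd_cal) else r.rpd_cal,
                "RMSECV": round(r.rmsecv, 6),
                "R2cv": round(r.r2cv, 6),
                "RPD_cv": round(r.rpd_cv, 2) if np.isfinite(r.rpd_cv) else r.rpd_cv,
                "N_val": r.n_val,
                "RMSEP": None if r.rmsep is None else round(r.rmsep, 6),
                "R2ev": None if r.r2ev is None else round(r.r2ev, 6),
                "RPD_ev": None
                if r.rpd_ev is None
                else (round(r.rpd_ev, 2) if np.isfinite(r.rpd_ev) else r.rpd_ev),
                "stage": r.stage,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows, columns=_LEADERBOARD_COLUMNS)


def _evaluate_candidate(
    s: SpectraSet,
    ref: ReferenceTable,
    pretreatment: PretreatmentSpec,
    windows: WindowSet | None,
    max_rank: int,
    n_segments: int,
    seed: int,
    parsimony: bool = True,
    stage: str = "calibration",
) -> CalibrationReport:
    s, ref = align(s, ref)
    sw = apply_windows(s, windows) if windows is not None else s
    y = ref.values
    cap = min(max_rank, min(sw.n_samples - 1, sw.n_wavenumbers))
    rank = select_rank(
        sw.values, y, cap, n_segments, seed, parsimony=parsimony,
        pretreatment=pretreatment, grid=sw.grid,
    )
    cv = cross_validate(
        sw.values, y, rank, n_segments, seed, pretreatment=pretreatment, grid=sw.grid
    )
    model = calibrate(s, ref, pretreatment, windows, rank, seed=seed)
    train = metrics(y, predict(model, s), sd_ref=model.y_sd)
    return CalibrationReport(
        trait_name=ref.trait_name,
        units=ref.units,
        pretreatment=pretreatment.method,
        spectrum_range=windows.label() if windows is not None else
        f"{s.grid[0]:g}–{s.grid[-1]:g}",
        rank=rank,
        n=ref.n_samples,
        mean=float(y.mean()),
        sd=float(y.std(ddof=1)),
        rmsec=train["rmse"],
        r2=train["r2"],
        rpd_cal=train["rpd"],
        rmsecv=cv["rmsecv"],
        r2cv=cv["r2cv"],
        rpd_cv=cv["rpd_cv"],
        stage=stage,
        seed=seed,
        model=model,
    )


def grid_search(
    s: SpectraSet,
    ref: ReferenceTable,
    candidate_pretreatments: list[PretreatmentSpec],
    candidate_windows: list[WindowSet | None],
    max_rank: int,
    n_segments: int,
    seed: int,
    parsimony: bool = True,
) -> list[CalibrationReport]:
    """Evaluate every pretreatment × window combination; rank by RMSECV.

    Ties break on higher R²cv, then lower rank. The full leaderboard is
    returned so model selection remains inspectable.
    """
    if not candidate_pretreatments or not candidate_windows:
        raise ConfigError("grid_search needs non-empty candidate lists")
    reports: list[CalibrationReport] = []
    failures: list[str] = []
    for pre, win in itertools.product(candidate_pretreatments, candidate_windows):
        try:
            reports.append(
                _evaluate_candidate(s, ref, pre, win, max_rank, n_segments, seed, parsimony)
            )
        except (DataError, ModelingError) as exc:
            label = win.label() if win is not None else "full"
            failures.append(f"{pre.method} × [{label}]: {exc}")
    if not reports:
        raise ModelingError("all grid-search candidates failed:\n  " + "\n  ".join(failures))
    reports.sort(key=lambda r: (r.rmsecv, -r.r2cv, r.rank))
    return reports


def default_window_candidates(
    grid: np.ndarray, n_blocks: int = 10, max_runs: int = 2
) -> list[WindowSet]:
    """Candidate windows: the grid split into equal blocks, plus every union
    of at most ``max_runs`` disjoint runs of consecutive blocks (covers
    two-interval selections like the ones typically reported)."""
    grid = np.asarray(grid, dtype=float)
    edges = np.linspace(grid[0], grid[-1], n_blocks + 1)
    eps = 1e-9 * (grid[-1] - grid[0])
    runs = [
        (edges[i] - eps, edges[j] + eps) for i in range(n_blocks) for j in range(i, n_blocks)
    ]
    candidates = [WindowSet([run]) for run in runs]
    if max_runs >= 2:
        for (a_lo, a_hi), (b_lo, b_hi) in itertools.combinations(runs, 2):
            if a_hi < b_lo or b_hi < a_lo:  # disjoint, non-adjacent runs only
                candidates.append(WindowSet([(a_lo, a_hi), (b_lo, b_hi)]))
    return candidates


def external_validate(m: PLSModel, s_val: SpectraSet, ref_val: ReferenceTable) -> dict:
    """Score the frozen model on held-out spectra (RMSEP, R²ev, RPD).

    RPD uses the calibration-set reference SD stored in the model. Any id
    overlap with the calibration set is rejected as leakage.
    """
    if ref_val.n_samples == 0 or s_val.n_samples == 0:
        raise DataError("external validation set is empty")
    overlap = set(ref_val.sample_ids) & set(m.calibration_ids)
    if overlap:
        raise DataError(
            f"validation ids overlap the calibration set (leakage): {sorted(overlap)[:5]}"
        )
    s_val, ref_val = align(s_val, ref_val)
    stats = metrics(ref_val.values, predict(m, s_val), sd_ref=m.y_sd)
    return {
        "rmsep": stats["rmse"],
        "r2ev": stats["r2"],
        "rpd": stats["rpd"],
        "bias": stats["bias"],
        "n_val": ref_val.n_samples,
    }


def global_recalibrate(
    split: SplitSpec,
    s: SpectraSet,
    ref: ReferenceTable,
    pretreatment: PretreatmentSpec,
    windows: WindowSet | None,
    max_rank: int,
    n_segments: int,
    seed: int,
    parsimony: bool = True,
) -> CalibrationReport:
    """Merge calibration + validation sets and recalibrate on the union.

    Rank selection and cross-validation are rerun on the integrated set with
    the chosen pretreatment/windows; the report is flagged stage='global'.
    """
    ids = list(split.calibration_ids) + list(split.validation_ids)
    return _evaluate_candidate(
        s.subset(ids), ref.subset(ids), pretreatment, windows,
        max_rank, n_segments, seed, parsimony=parsimony, stage="global",
    )
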