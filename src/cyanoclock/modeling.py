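"""Kinetic predictive model of a target transcription factor from clock-gene
regulators.

Each target y follows τ·dy/dt = −y + g(β·Z), where Z collects design
features built from the regulators — every single regulator profile and,
optionally, the elementwise minimum of every regulator pair (an AND-like
joint-regulation term) — and g is a truncated linear link.  For training,
the ODE is discretized to the response r_t = τ·(y_{t+1} − y_t)/Δt + y_t,
regressed on Z at time t; τ = 0 recovers the pure equilibrium regression of
y on Z.  Prediction assumes equilibrium (dy/dt = 0): ŷ = g(β·Z).

Coefficients come from the least-angle-regression lasso path; the L1
constraint is chosen by leave-one-out cross-validation with the
one-standard-error rule, the selection is truncated to a budget of single
and pair predictors in path-entry order and refined under the extended BIC
(greedy drop/swap), and (by default) the surviving coefficients are refit
by ordinary least squares ("relaxed" fit, removing shrinkage bias).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path as _sk_lars_path

from .containers import ExpressionMatrix

__all__ = [
    "Predictor",
    "PredictorDesign",
    "FitSettings",
    "TargetModel",
    "build_design",
    "response_transform",
    "fit_target",
    "predict_steady_state",
    "save_models",
    "load_models",
]


class Predictor(NamedTuple):
    """A design feature: a single regulator or the min of two regulators."""

    kind: str  # "single" | "min_pair"
    genes: tuple[str, ...]

    @classmethod
    def single(cls, gene: str) -> "Predictor":
        return cls("single", (gene,))

    @classmethod
    def min_pair(cls, a: str, b: str) -> "Predictor":
        if a == b:
            raise ValueError("min_pair needs two distinct regulators")
        return cls("min_pair", tuple(sorted((a, b))))

    @property
    def label(self) -> str:
        if self.kind == "single":
            return self.genes[0]
        return f"min({self.genes[0]},{self.genes[1]})"

    def evaluate(self, regulators: pd.DataFrame) -> np.ndarray:
        """Raw feature values per sample from a genes x samples frame."""
        if self.kind == "single":
            return regulators.loc[self.genes[0]].to_numpy(float)
        a = regulators.loc[self.genes[0]].to_numpy(float)
        b = regulators.loc[self.genes[1]].to_numpy(float)
        return np.minimum(a, b)

    def to_json(self) -> dict:
        return {"kind": self.kind, "genes": list(self.genes)}

    @classmethod
    def from_json(cls, obj: dict) -> "Predictor":
        return cls(obj["kind"], tuple(obj["genes"]))


@dataclass
class PredictorDesign:
    """Raw (unstandardized) design values for every candidate predictor.

    Standardization statistics are computed at fit time from training
    samples only and stored on the fitted model, so held-out data never
    leak into the feature scaling.
    """

    predictors: list[Predictor]
    values: pd.DataFrame  # predictor labels x sample ids, raw scale
    samples: pd.DataFrame  # per-sample metadata (time_h, experiment, ...)

    def subset(self, sample_ids) -> "PredictorDesign":
        ids = list(sample_ids)
        return PredictorDesign(self.predictors, self.values[ids], self.samples.loc[ids])


def build_design(regulators: ExpressionMatrix, allow_pairs: bool = True) -> PredictorDesign:
    """All single-regulator features plus, optionally, all C(n,2) min-pairs.

    Constant features (zero variance across the provided samples) are
    dropped with a warning — they carry no signal and break standardization.
    """
    if len(regulators.genes) < 1:
        raise ValueError("need at least one regulator")
    preds = [Predictor.single(g) for g in regulators.genes]
    if allow_pairs:
        preds += [
            Predictor.min_pair(a, b)
            for a, b in itertools.combinations(regulators.genes, 2)
        ]
    rows, kept = [], []
    for p in preds:
        z = p.evaluate(regulators.values)
        if np.std(z) == 0.0:
            warnings.warn(f"dropping constant predictor {p.label}")
            continue
        rows.append(z)
        kept.append(p)
    values = pd.DataFrame(
        np.asarray(rows), index=[p.label for p in kept], columns=regulators.values.columns
    )
    return PredictorDesign(kept, values, regulators.samples.copy())


def response_transform(
    y: pd.Series,
    tau_min: float,
    samples: pd.DataFrame,
    pairing: str = "left",
) -> tuple[np.ndarray, list[str]]:
    """Discretized-ODE response over consecutive within-experiment pairs.

    ``pairing="left"`` is the classical explicit form
    r_t = τ·(y_{t+1} − y_t)/Δt + y_t, paired with the design at time t.
    ``pairing="right"`` is the implicit (backward-Euler) form
    r_{t+1} = τ·(y_{t+1} − y_t)/Δt + y_{t+1}, paired with the design at
    time t+1.  When τ is much smaller than Δt the target lags its drive by
    ≈ τ·(d drive/dt); the left form over-corrects that lag by a term of
    order τ·Δt·(drive)'' while the right form cancels it to O(τ²/Δt), so
    the right form is the default during fitting.

    Δt and τ are both in minutes (sample times are hours).  Returns the
    response vector and the ids of the samples whose design values each row
    is regressed on.  With τ = 0 both forms degenerate to r = y at every
    sample (pure equilibrium regression), so all samples are used.
    """
    if tau_min < 0:
        raise ValueError("tau must be >= 0")
    if pairing not in ("left", "right"):
        raise ValueError("pairing must be 'left' or 'right'")
    meta = samples.loc[list(y.index)]
    if tau_min == 0.0:
        return y.to_numpy(float).copy(), list(y.index)
    resp, at = [], []
    for _, grp in meta.groupby("experiment", sort=False):
        ids = list(grp.sort_values("time_h").index)
        if len(ids) < 2:
            continue
        t = grp.loc[ids, "time_h"].to_numpy(float) * 60.0
        vals = y.loc[ids].to_numpy(float)
        dt = np.diff(t)
        if np.any(dt == 0):
            raise ValueError("zero time step between samples")
        slope = tau_min * (vals[1:] - vals[:-1]) / dt
        if pairing == "left":
            resp.extend(slope + vals[:-1])
            at.extend(ids[:-1])
        else:
            resp.extend(slope + vals[1:])
            at.extend(ids[1:])
    if not at:
        raise ValueError("no within-experiment sample pairs for the response")
    return np.asarray(resp), at


@dataclass(frozen=True)
class FitSettings:
    """Fitting knobs: τ (minutes), the predictor-selection budget, the
    response pairing, and whether the relaxed (OLS + BIC-pruned) refit of
    the lasso-selected set is applied."""

    tau_min: float = 15.0
    max_singles: int = 5
    max_pairs: int = 2
    relax: bool = True
    pairing: str = "right"


@dataclass
class TargetModel:
    """One fitted target: selected predictors, coefficients on the
    standardized design, the truncated-linear link bounds, and the
    training-derived standardization statistics."""

    target: str
    predictors: list[Predictor]
    beta: np.ndarray  # on standardized design, aligned with ``predictors``
    intercept: float
    tau_min: float
    bounds: tuple[float, float]  # (lo, hi) of the truncated linear link
    means: np.ndarray  # training means/sds of the selected raw features
    sds: np.ndarray

    def raw_coefficients(self) -> tuple[dict[str, float], float]:
        """Coefficients on the raw (unstandardized) feature scale."""
        coefs = {}
        b0 = self.intercept
        for p, b, m, s in zip(self.predictors, self.beta, self.means, self.sds):
            coefs[p.label] = b / s
            b0 -= b * m / s
        return coefs, b0

    def to_json(self) -> dict:
        return {
            "target": self.target,
            "predictors": [p.to_json() for p in self.predictors],
            "beta": [float(b) for b in self.beta],
            "intercept": float(self.intercept),
            "tau_min": float(self.tau_min),
            "bounds": [float(self.bounds[0]), float(self.bounds[1])],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TargetModel":
        return cls(
            target=obj["target"],
            predictors=[Predictor.from_json(p) for p in obj["predictors"]],
            beta=np.asarray(obj["beta"], float),
            intercept=float(obj["intercept"]),
            tau_min=float(obj["tau_min"]),
            bounds=(float(obj["bounds"][0]), float(obj["bounds"][1])),
            means=np.asarray(obj["means"], float),
            sds=np.asarray(obj["sds"], float),
        )


def save_models(models: dict[str, TargetModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({t: m.to_json() for t, m in sorted(models.items())}, indent=1)
    )


def load_models(path: str | Path) -> dict[str, TargetModel]:
    raw = json.loads(Path(path).read_text())
    return {t: TargetModel.from_json(o) for t, o in raw.items()}


# ---- lasso path + LOO-CV machinery ----------------------------------------


def lars_path(X, y, method="lasso"):
    """Lasso path with degenerate-regressor warnings silenced.

    The min-pair dictionary is strongly collinear by construction, so the
    path solver routinely drops regressors whose Cholesky pivot underflows;
    that is expected behavior here, not a numerical problem worth a warning
    per fold.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return _sk_lars_path(X, y, method=method)


def _coefs_at(alphas_path: np.ndarray, coefs_path: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Lasso-path coefficients at arbitrary alphas.

    Path coefficients are piecewise linear in alpha, so linear interpolation
    between breakpoints is exact; queries beyond the path ends clamp to the
    end coefficients (all-zero at the large end, least constrained at the
    small end).
    """
    ap = alphas_path[::-1]  # increasing
    cp = coefs_path[:, ::-1]
    if len(ap) == 1:
        return np.repeat(cp, len(grid), axis=1)
    g = np.clip(grid, ap[0], ap[-1])
    j = np.clip(np.searchsorted(ap, g, side="right") - 1, 0, len(ap) - 2)
    denom = np.where(ap[j + 1] > ap[j], ap[j + 1] - ap[j], 1.0)
    w = (g - ap[j]) / denom
    return cp[:, j] * (1.0 - w) + cp[:, j + 1] * w


def _loo_cv_alpha_index(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> int:
    """Index into ``grid`` chosen by leave-one-out CV with the 1-SE rule.

    ``grid`` is the decreasing alpha sequence of the full-data path; for
    each fold a fresh path is computed and evaluated on the held-out sample
    across the whole grid.  The 1-SE rule takes the largest alpha whose CV
    error is within one standard error of the minimum — a deliberately
    conservative choice that keeps pure-noise targets at the intercept-only
    model.
    """
    n = len(y)
    err = np.empty((n, len(grid)))
    idx = np.arange(n)
    for k in range(n):
        tr = idx != k
        Xt, yt = X[tr], y[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        a_k, _, c_k = lars_path(Xt - xm, yt - ym, method="lasso")
        C = _coefs_at(a_k, c_k, grid)
        pred = (X[k] - xm) @ C + ym
        err[k] = (pred - y[k]) ** 2
    mse = err.mean(axis=0)
    i_min = int(np.argmin(mse))
    se = float(err[:, i_min].std(ddof=1)) / np.sqrt(n) if n > 1 else 0.0
    ok = np.flatnonzero(mse <= mse[i_min] + se)
    return int(ok[0])  # grid is decreasing: first index = largest alpha


def _entry_order(alphas_path: np.ndarray, coefs_path: np.ndarray) -> list[int]:
    """Predictor indices by order of first activation along the path."""
    first = np.full(coefs_path.shape[0], np.inf)
    nz = np.abs(coefs_path) > 1e-12
    for p in range(coefs_path.shape[0]):
        hits = np.flatnonzero(nz[p])
        if hits.size:
            first[p] = hits[0]
    order = np.argsort(first, kind="stable")
    return [int(p) for p in order if np.isfinite(first[p])]


def _ebic_refine(
    X: np.ndarray, r: np.ndarray, keep: list[int], kinds: list[str],
    gamma: float = 1.0,
) -> list[int]:
    """Greedy refinement of the lasso-selected set under the extended BIC:
    backward elimination plus same-kind swaps.

    The extended BIC, n·ln(RSS/n) + k·ln(n) + 2γ·k·ln(P), adds a ln(P)
    charge per selected feature, the consistency correction for selection
    among P ≫ n candidates (γ = 1 is the most conservative standard
    choice, appropriate for this strongly collinear dictionary).  Highly
    collinear design features let the lasso retain near-duplicates of a
    true predictor, or a near-duplicate instead of the true predictor;
    dropping any feature whose removal lowers the criterion, and replacing
    any kept feature by an out-of-set feature of the same kind when that
    lowers it, removes free riders and repairs coherent swaps, while a
    genuinely contributing predictor always survives.
    """
    n = len(r)
    n_feat = X.shape[1]

    def ebic(idx: list[int]) -> float:
        A = np.column_stack([X[:, idx], np.ones(n)]) if idx else np.ones((n, 1))
        res = r - A @ np.linalg.lstsq(A, r, rcond=None)[0]
        rss = max(float(res @ res), 1e-300)
        return (
            n * np.log(rss / n)
            + (len(idx) + 1) * np.log(n)
            + 2.0 * gamma * len(idx) * np.log(n_feat)
        )

    cur = list(keep)
    improved = True
    while improved and cur:
        improved = False
        base = ebic(cur)
        for j in list(cur):
            cand = [k for k in cur if k != j]
            if ebic(cand) < base:
                cur = cand
                improved = True
                break
        if improved:
            continue
        for j in list(cur):
            rest = [k for k in cur if k != j]
            for q in range(n_feat):
                if q in cur or kinds[q] != kinds[j]:
                    continue
                cand = sorted(rest + [q])
                if ebic(cand) < base - 1e-9:
                    cur = cand
                    improved = True
                    break
            if improved:
                break
    return sorted(cur)


def fit_target(
    y: pd.Series,
    design: PredictorDesign,
    settings: FitSettings | None = None,
) -> TargetModel:
    """Fit one target's kinetic model on the samples indexed by ``y``.

    Steps: ODE response transform → per-fit standardization of the design
    (training statistics only) → lasso path with LOO-CV/1-SE constraint
    selection → truncation to the single/pair budget in path-entry order →
    relaxed refit (extended-BIC elimination/swap refinement followed by
    OLS, removing shrinkage bias and predictors that do not pay for
    themselves).  Link bounds are the min/max of the training responses.
    """
    settings = settings or FitSettings()
    train_ids = list(y.index)
    if len(train_ids) < 6:
        raise ValueError("need at least 6 training samples")
    r, at_ids = response_transform(y, settings.tau_min, design.samples, settings.pairing)

    Z_all = design.values[train_ids].to_numpy(float)  # P x n_train
    mu = Z_all.mean(axis=1)
    sd = Z_all.std(axis=1)
    usable = sd > 0
    if not usable.any() or float(np.std(r)) == 0.0:
        lo, hi = float(np.min(r)), float(np.max(r))
        return TargetModel(
            str(y.name), [], np.zeros(0), float(np.mean(r)),
            settings.tau_min, (lo, hi), np.zeros(0), np.zeros(0),
        )

    Z_at = design.values.loc[:, at_ids].to_numpy(float)
    X = ((Z_at - mu[:, None]) / np.where(usable, sd, 1.0)[:, None])[usable].T
    pred_pool = [p for p, u in zip(design.predictors, usable) if u]

    ym = r.mean()
    alphas, _, coefs = lars_path(X - X.mean(axis=0), r - ym, method="lasso")
    i_alpha = _loo_cv_alpha_index(X, r, alphas)
    active = np.flatnonzero(np.abs(coefs[:, i_alpha]) > 1e-12)

    # budget truncation in path-entry order
    order = _entry_order(alphas, coefs)
    n_single = n_pair = 0
    keep: list[int] = []
    for p in order:
        if p not in active:
            continue
        if pred_pool[p].kind == "single":
            if n_single < settings.max_singles:
                keep.append(p)
                n_single += 1
        else:
            if n_pair < settings.max_pairs:
                keep.append(p)
                n_pair += 1
    keep.sort()

    lo, hi = float(np.min(r)), float(np.max(r))
    if settings.relax and keep:
        keep = _ebic_refine(X, r, keep, [p.kind for p in pred_pool])
    if not keep:
        return TargetModel(
            str(y.name), [], np.zeros(0), float(ym),
            settings.tau_min, (lo, hi), np.zeros(0), np.zeros(0),
        )

    if settings.relax:
        A = np.column_stack([X[:, keep], np.ones(len(r))])
        sol, *_ = np.linalg.lstsq(A, r, rcond=None)
        beta, b0 = sol[:-1], float(sol[-1])
    else:
        beta = coefs[keep, i_alpha]
        b0 = float(ym - X[:, keep].mean(axis=0) @ beta)

    sel_idx = [int(np.flatnonzero(usable)[p]) for p in keep]
    return TargetModel(
        target=str(y.name),
        predictors=[pred_pool[p] for p in keep],
        beta=np.asarray(beta, float),
        intercept=b0,
        tau_min=settings.tau_min,
        bounds=(lo, hi),
        means=mu[sel_idx],
        sds=sd[sel_idx],
    )


def predict_steady_state(model: TargetModel, regulators: pd.DataFrame) -> pd.Series:
    """Equilibrium prediction ŷ = g(β·Z) = clamp(β·Z + intercept, lo, hi).

    ``regulators`` is a genes x samples frame of raw regulator values; the
    model's stored training statistics standardize its features.
    """
    for p in model.predictors:
        for g in p.genes:
            if g not in regulators.index:
                raise KeyError(f"regulator {g!r} missing from input")
    pred = np.full(regulators.shape[1], model.intercept, float)
    for p, b, m, s in zip(model.predictors, model.beta, model.means, model.sds):
        z = (p.evaluate(regulators) - m) / s
        pred = pred + b * z
    lo, hi = model.bounds
    return pd.Series(np.clip(pred, lo, hi), index=regulators.columns, name=model.target)
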