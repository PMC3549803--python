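"""From raw or normalized expression to the two analysis-ready forms.

Two-channel arrays pass through an MA-plot lowess normalization (the
intensity-dependent dye bias is the locally weighted regression of
M = log2(Cy5/Cy3) on A = mean log2 intensity, subtracted per array),
replicate/dye-swap averaging, and an operonic-pair correlation sanity
check.  For network learning, expression is upsampled with a natural cubic
spline and quantile-discretized into equal-frequency states; order-1
transition pairs are built within experiments only (samples from different
cultures are never paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .containers import DiscreteMatrix, ExpressionMatrix, TransitionDataset

__all__ = [
    "lowess_normalize",
    "average_replicates",
    "OperonValidation",
    "validate_operon_correlation",
    "spline_upsample",
    "quantile_discretize",
    "build_transitions",
]


def lowess_normalize(raw: pd.DataFrame, smoothing_fraction: float = 0.2) -> pd.DataFrame:
    """Per-array MA lowess normalization of a tidy two-channel table.

    ``raw`` needs columns array, probe, gene, cy3, cy5 (as produced by
    ``synthetic.gen_two_channel``).  Returns the table with added columns
    A, M and M_norm, where M_norm is M minus the lowess fit of M on A at
    the given smoothing fraction.
    """
    if not 0.0 < smoothing_fraction <= 1.0:
        raise ValueError("smoothing fraction must lie in (0, 1]")
    for col in ("array", "probe", "cy3", "cy5"):
        if col not in raw.columns:
            raise ValueError(f"raw table missing column {col!r}")
    if np.any(raw["cy3"].to_numpy(float) <= 0) or np.any(raw["cy5"].to_numpy(float) <= 0):
        raise ValueError("intensities must be positive")
    out = raw.copy()
    out["M"] = np.log2(out["cy5"].to_numpy(float) / out["cy3"].to_numpy(float))
    out["A"] = 0.5 * np.log2(out["cy5"].to_numpy(float) * out["cy3"].to_numpy(float))
    fitted = np.empty(len(out))
    for _, idx in out.groupby("array", sort=False).indices.items():
        if len(idx) < 3:
            raise ValueError("need at least 3 probes per array for lowess")
        m = out["M"].to_numpy(float)[idx]
        a = out["A"].to_numpy(float)[idx]
        fitted[idx] = sm_lowess(m, a, frac=smoothing_fraction, return_sorted=False)
    out["M_norm"] = out["M"].to_numpy(float) - fitted
    return out


def average_replicates(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    value_col: str = "M_norm",
) -> ExpressionMatrix:
    """Collapse a normalized probe table to one value per gene and sample.

    Dye-swap arrays are sign-flipped (their log-ratios are negated by
    construction), probe replicates are averaged within array, and arrays
    belonging to the same biological sample are averaged.  ``samples`` is
    the per-sample metadata frame for the resulting matrix; every sample
    must be covered by at least one array.
    """
    needed = {"sample", "gene", "dye_swap", value_col}
    missing = needed - set(norm.columns)
    if missing:
        raise ValueError(f"normalized table missing columns {sorted(missing)}")
    work = norm.copy()
    sign = np.where(work["dye_swap"].to_numpy(bool), -1.0, 1.0)
    work["value"] = sign * work[value_col].to_numpy(float)
    per_array = (
        work.groupby(["sample", "array", "gene"], sort=False)["value"].mean().reset_index()
    )
    per_sample = per_array.groupby(["sample", "gene"], sort=False)["value"].mean()
    matrix = per_sample.unstack("sample")
    matrix.index.name = None
    matrix.columns.name = None
    empty = [s for s in samples.index if s not in matrix.columns]
    if empty:
        raise ValueError(f"samples with no arrays: {empty}")
    return ExpressionMatrix(matrix[list(samples.index)], samples.copy())


@dataclass(frozen=True)
class OperonValidation:
    """Median within-pair Pearson correlation per class and the verdict."""

    median_operonic: float
    median_non_operonic: float
    passed: bool  # strict: operonic > non-operonic


def _pair_correlations(
    expr: ExpressionMatrix, pairs: Sequence[tuple[str, str]]
) -> list[float]:
    vals = []
    for a, b in pairs:
        x = expr.values.loc[a].to_numpy(float)
        y = expr.values.loc[b].to_numpy(float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            warnings.warn(f"skipping pair ({a}, {b}): constant gene")
            continue
        vals.append(float(np.corrcoef(x, y)[0, 1]))
    return vals


def validate_operon_correlation(
    expr: ExpressionMatrix,
    operonic_pairs: Sequence[tuple[str, str]],
    non_operonic_pairs: Sequence[tuple[str, str]],
) -> OperonValidation:
    """Normalization sanity check: co-transcribed (operonic) gene pairs
    should be more correlated than non-operonic ones."""
    if not operonic_pairs or not non_operonic_pairs:
        raise ValueError("need at least one pair per class")
    op = _pair_correlations(expr, operonic_pairs)
    non = _pair_correlations(expr, non_operonic_pairs)
    if not op or not non:
        raise ValueError("all pairs in one class were skipped")
    med_op, med_non = float(np.median(op)), float(np.median(non))
    return OperonValidation(med_op, med_non, med_op > med_non)


def spline_upsample(expr: ExpressionMatrix, points_between: int) -> ExpressionMatrix:
    """Insert ``points_between`` equally spaced samples between consecutive
    observations using a natural cubic spline, per gene and per experiment.

    Observed samples are preserved exactly (only the new time points are
    spline-evaluated).  With 4 h spacing and two inserted points the new
    spacing is 4/3 h.  Inserted samples copy the condition/split labels of
    their left neighbour.
    """
    if points_between < 0:
        raise ValueError("points_between must be >= 0")
    if points_between == 0:
        return ExpressionMatrix(expr.values.copy(), expr.samples.copy())
    cols: list[pd.Series] = []
    meta_rows: list[pd.Series] = []
    for exp, grp in expr.samples.groupby("experiment", sort=False):
        ids = list(grp.sort_values("time_h").index)
        if len(ids) < 4:
            raise ValueError(f"experiment {exp!r} has <4 samples; cannot spline")
        t = grp.loc[ids, "time_h"].to_numpy(float)
        if len(np.unique(t)) != len(t):
            raise ValueError("duplicate time stamps")
        y = expr.values[ids].to_numpy(float)
        spline = CubicSpline(t, y, axis=1, bc_type="natural")
        for k, sid in enumerate(ids):
            cols.append(expr.values[sid])
            meta_rows.append(expr.samples.loc[sid])
            if k == len(ids) - 1:
                continue
            gaps = (t[k + 1] - t[k]) * np.arange(1, points_between + 1) / (points_between + 1)
            new_t = t[k] + gaps
            new_vals = spline(new_t)
            for j, tn in enumerate(new_t):
                new_id = f"{sid}.{j + 1}"
                cols.append(pd.Series(new_vals[:, j], index=expr.values.index, name=new_id))
                row = expr.samples.loc[sid].copy()
                row["time_h"] = float(tn)
                row.name = new_id
                meta_rows.append(row)
    values = pd.concat(cols, axis=1)
    samples = pd.DataFrame(meta_rows)
    return ExpressionMatrix(values, samples)


def quantile_discretize(expr: ExpressionMatrix, n_states: int = 3) -> DiscreteMatrix:
    """Per-gene equal-frequency binning into ``n_states`` states.

    Samples are ranked (ties broken by original sample order) and split
    into bins of near-equal size, remainder samples going to the lowest
    bins; state 0 is the lowest-expression bin.  Constant genes collapse to
    a single state (r_i = 1) with a warning.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    n = expr.n_samples
    base, rem = divmod(n, n_states)
    sizes = [base + 1] * rem + [base] * (n_states - rem)
    bin_of_rank = np.repeat(np.arange(n_states), sizes)
    states = np.empty(expr.values.shape, dtype=np.int64)
    r = pd.Series(n_states, index=expr.values.index)
    for gi, gene in enumerate(expr.values.index):
        vals = expr.values.iloc[gi].to_numpy(float)
        if np.all(vals == vals[0]):
            warnings.warn(f"gene {gene!r} is constant; single-state (r=1)")
            states[gi] = 0
            r[gene] = 1
            continue
        order = np.argsort(vals, kind="stable")
        states[gi, order] = bin_of_rank
    frame = pd.DataFrame(states, index=expr.values.index, columns=expr.values.columns)
    return DiscreteMatrix(frame, expr.samples.copy(), r)


def build_transitions(disc: DiscreteMatrix, order: int = 1) -> TransitionDataset:
    """Order-1 (x_t → x_{t+1}) pairs; never across an experiment boundary."""
    if order != 1:
        raise ValueError("only order-1 transitions are supported")
    xs, xn = [], []
    for _, grp in disc.samples.groupby("experiment", sort=False):
        ids = list(grp.sort_values("time_h").index)
        if len(ids) < 2:
            continue
        block = disc.states[ids].to_numpy().T  # samples x genes
        xs.append(block[:-1])
        xn.append(block[1:])
    if not xs:
        raise ValueError("no transitions: every experiment has a single sample")
    return TransitionDataset(
        genes=list(disc.states.index),
        x_t=np.vstack(xs),
        x_next=np.vstack(xn),
        state_counts=disc.n_states.loc[disc.states.index].to_numpy(int),
    )
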