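"""Dynamic-Bayesian-network structure learning with the Mutual Information
Test (MIT) score.

An order-1 DBN explains each gene's state at time t+1 from a parent set of
gene states at time t.  The MIT score of a node is twice the sample size
times the plug-in mutual information between the child and the joint parent
configuration (the G-statistic, in nats), penalized by chi-square quantiles
at significance ``alpha`` whose degrees of freedom grow with the product of
parent state counts.  Because the G-statistic is asymptotically chi-square
under independence, the penalty is the null quantile: a parent set scores
positive only when its association would be rejected as noise at level
``alpha``.

The score decomposes over nodes, so the globally optimal network is found by
an exhaustive per-node search over parent sets.  A provable bound caps the
parent-set size: once the smallest achievable cumulative penalty of an
s-parent set exceeds the largest achievable gain 2N·ln(r_i), all sets of
that size (and larger, by penalty monotonicity) score below the empty set.

Minimum Description Length (MDL) is supported as an alternative metric.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .containers import TransitionDataset

__all__ = [
    "MITConfig",
    "ParentSet",
    "Network",
    "mutual_information",
    "dof_term",
    "chi2_critical",
    "mit_penalty",
    "mit_node_score",
    "mdl_node_score",
    "max_parent_bound",
    "learn_network",
    "null_positive_rate",
]


@dataclass(frozen=True)
class MITConfig:
    """Learner settings.

    alpha: significance level of the chi-square penalty (0 < alpha < 1).
    metric: "mit" or "mdl".
    max_parents_cap: hard cap on parent-set size on top of the provable bound.
    dbn_order: fixed at 1 (parents at t, child at t+1).
    allow_self_loops: whether X_i^t may parent X_i^{t+1}; legal in an
        order-1 DBN and on by default.
    """

    alpha: float = 0.999
    metric: str = "mit"
    max_parents_cap: int = 3
    dbn_order: int = 1
    allow_self_loops: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.metric not in ("mit", "mdl"):
            raise ValueError("metric must be 'mit' or 'mdl'")
        if self.max_parents_cap < 1:
            raise ValueError("max_parents_cap must be >= 1")
        if self.dbn_order != 1:
            raise ValueError("only order-1 DBNs are supported")


@dataclass(frozen=True)
class ParentSet:
    """A target's chosen parents and the node score they achieve."""

    target: str
    parents: tuple[str, ...]
    score: float


@dataclass
class Network:
    """Directed regulator→target network; score decomposes over targets."""

    genes: list[str]
    parent_sets: dict[str, ParentSet]
    metric: str
    config: MITConfig | None = None

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for ps in self.parent_sets.values():
            out.extend((p, ps.target) for p in ps.parents)
        return sorted(out)

    @property
    def total_score(self) -> float:
        return float(sum(ps.score for ps in self.parent_sets.values()))

    # ---- exports ---------------------------------------------------------

    def write_edge_tsv(self, path: str | Path) -> None:
        lines = ["regulator\ttarget\tnode_score"]
        for ps in self.parent_sets.values():
            for p in ps.parents:
                lines.append(f"{p}\t{ps.target}\t{ps.score:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_sif(self, path: str | Path) -> None:
        lines = [f"{p}\tregulates\t{t}" for p, t in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_dot(self, path: str | Path) -> None:
        lines = ["digraph clock {"]
        lines += [f'  "{g}";' for g in self.genes]
        lines += [f'  "{p}" -> "{t}";' for p, t in self.edges]
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---- score components ----------------------------------------------------


def mutual_information(joint_counts: np.ndarray) -> float:
    """Plug-in (maximum-likelihood) mutual information of a contingency
    table, in nats, with the 0·log 0 ≡ 0 convention.

    Natural logarithm is deliberate: 2N·I is then the G-statistic, whose
    null distribution matches the chi-square penalty.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total < 1:
        raise ValueError("contingency table has no observations")
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def dof_term(r_i: int, parent_state_counts: Sequence[int], j: int) -> int:
    """Degrees of freedom l_iσ(j) of the j-th chi-square penalty term.

    ``parent_state_counts`` must already be sorted in descending order (the
    canonical permutation σ puts the parent with the most states first).
    j is 1-based.  j=1 → (r_i−1)(r_σ(1)−1); for j≥2 the term is multiplied
    by the running product of the preceding parents' state counts.
    """
    s = len(parent_state_counts)
    if not 1 <= j <= s:
        raise IndexError(f"j={j} out of range for {s} parents")
    base = (r_i - 1) * (parent_state_counts[j - 1] - 1)
    if j == 1:
        return base
    return base * int(np.prod(parent_state_counts[: j - 1]))


@lru_cache(maxsize=None)
def chi2_critical(alpha: float, dof: int) -> float:
    """Quantile x with P(chi2_dof <= x) = alpha; dof=0 contributes nothing."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if dof < 0:
        raise ValueError("dof must be >= 0")
    if dof == 0:
        # a single-state variable adds no free parameter
        return 0.0
    return float(stats.chi2.ppf(alpha, dof))


def mit_penalty(alpha: float, r_i: int, parent_state_counts: Sequence[int]) -> float:
    """Total chi-square penalty Σ_j χ_{α, l_iσ(j)} for a parent multiset.

    Parents are canonicalized to descending state count internally, so the
    result is invariant to input order.
    """
    counts = sorted((int(r) for r in parent_state_counts), reverse=True)
    return sum(
        chi2_critical(alpha, dof_term(r_i, counts, j))
        for j in range(1, len(counts) + 1)
    )


def _joint_counts(
    data: TransitionDataset, target_idx: int, parent_idx: Sequence[int]
) -> np.ndarray:
    """Child-vs-parent-configuration contingency table from the transitions."""
    r = data.state_counts
    r_i = int(r[target_idx])
    child = data.x_next[:, target_idx]
    if not parent_idx:
        return np.bincount(child, minlength=r_i).reshape(r_i, 1).astype(float)
    code = np.zeros(data.n_transitions, dtype=np.int64)
    n_cfg = 1
    for p in parent_idx:
        code = code * int(r[p]) + data.x_t[:, p]
        n_cfg *= int(r[p])
    flat = np.bincount(child * n_cfg + code, minlength=r_i * n_cfg)
    return flat.reshape(r_i, n_cfg).astype(float)


def _resolve(data: TransitionDataset, gene: str | int) -> int:
    return gene if isinstance(gene, int) else data.gene_index(gene)


def mit_node_score(
    target: str | int,
    parents: Sequence[str | int],
    data: TransitionDataset,
    alpha: float,
) -> float:
    """MIT node score 2N·I(X_i^{t+1}, Pa_i^t) − Σ_j χ_{α, l_iσ(j)}.

    The empty parent set scores exactly 0 (the score's sum runs over
    non-empty parent sets only), which makes 0 the baseline every candidate
    set must beat.
    """
    ti = _resolve(data, target)
    pi = [_resolve(data, p) for p in parents]
    if len(set(pi)) != len(pi):
        raise ValueError("duplicate parents")
    if not pi:
        return 0.0
    counts = _joint_counts(data, ti, pi)
    n = data.n_transitions
    gain = 2.0 * n * mutual_information(counts)
    pen = mit_penalty(alpha, int(data.state_counts[ti]), [int(data.state_counts[p]) for p in pi])
    return gain - pen


def mdl_node_score(
    target: str | int, parents: Sequence[str | int], data: TransitionDataset
) -> float:
    """MDL description length N·Ĥ(X_i^{t+1} | Pa_i^t) + (ln N / 2)·(r_i−1)·∏_j r_ij.

    Smaller is better; the learner negates it so both metrics are maximized.
    """
    ti = _resolve(data, target)
    pi = [_resolve(data, p) for p in parents]
    counts = _joint_counts(data, ti, pi)
    n = data.n_transitions
    cfg_tot = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / cfg_tot)
    cond_entropy = -float(np.nansum(terms)) / n  # Ĥ(X | Pa) in nats
    r_i = int(data.state_counts[ti])
    n_params = (r_i - 1) * int(np.prod([data.state_counts[p] for p in pi])) if pi else (r_i - 1)
    return n * cond_entropy + 0.5 * math.log(n) * n_params


# ---- search --------------------------------------------------------------


def max_parent_bound(
    data: TransitionDataset,
    alpha: float,
    r_target: int,
    candidate_state_counts: Sequence[int] | None = None,
    metric: str = "mit",
) -> int:
    """Largest parent-set size that can possibly beat the empty set.

    For MIT the achievable gain is at most 2N·ln(r_i) (mutual information is
    bounded by the child's entropy), while the cheapest s-parent penalty is
    attained by the s candidates with the fewest states (the penalty is
    monotone in every parent's state count).  Once that minimal penalty
    exceeds the maximal gain, size s — and by monotonicity every larger
    size — scores below the empty set and is pruned.  For MDL the same
    argument bounds the entropy reduction by N·ln(r_i) against the
    (ln N / 2)-weighted parameter-count growth.

    Returns the largest size still worth searching (0 forces the empty
    network).  The bound never decreases with N.
    """
    n = data.n_transitions
    if candidate_state_counts is None:
        candidate_state_counts = [int(r) for r in data.state_counts]
    cand = sorted(int(r) for r in candidate_state_counts)
    if not cand:
        return 0
    bound = 0
    for s in range(1, len(cand) + 1):
        cheapest = cand[:s]
        if metric == "mit":
            max_gain = 2.0 * n * math.log(r_target)
            penalty = mit_penalty(alpha, r_target, cheapest)
        else:
            max_gain = n * math.log(r_target)
            penalty = 0.5 * math.log(n) * (r_target - 1) * (
                int(np.prod(cheapest)) - 1
            )
        if penalty > max_gain:
            break
        bound = s
    return bound


def _node_objective(metric: str, target_idx: int, parent_idx, data, alpha) -> float:
    if metric == "mit":
        return mit_node_score(target_idx, list(parent_idx), data, alpha)
    return -mdl_node_score(target_idx, list(parent_idx), data)


def learn_network(data: TransitionDataset, config: MITConfig | None = None) -> Network:
    """Globally optimal order-1 DBN under the configured metric.

    Decomposability lets each target's parent set be optimized
    independently by exhaustive enumeration up to the provable size bound
    (further capped by ``max_parents_cap``).  Ties are broken toward the
    smaller set, then lexicographically by gene ids — enumeration order is
    size-ascending, lexicographic, and only strict improvements replace the
    incumbent.
    """
    config = config or MITConfig()
    if data.n_transitions < 2:
        raise ValueError("need at least 2 transitions")
    if len(data.genes) < 2:
        raise ValueError("need at least 2 genes")
    order = sorted(range(len(data.genes)), key=lambda i: data.genes[i])
    parent_sets: dict[str, ParentSet] = {}
    for ti, target in enumerate(data.genes):
        r_i = int(data.state_counts[ti])
        if r_i <= 1:
            warnings.warn(
                f"target {target!r} has a single state; forced empty parent set"
            )
            base = _node_objective(config.metric, ti, (), data, config.alpha)
            parent_sets[target] = ParentSet(target, (), base)
            continue
        candidates = [i for i in order if config.allow_self_loops or i != ti]
        cand_counts = [int(data.state_counts[i]) for i in candidates]
        bound = max_parent_bound(data, config.alpha, r_i, cand_counts, config.metric)
        limit = min(bound, config.max_parents_cap, len(candidates))
        best_parents: tuple[int, ...] = ()
        best = _node_objective(config.metric, ti, (), data, config.alpha)
        for size in range(1, limit + 1):
            for combo in itertools.combinations(candidates, size):
                score = _node_objective(config.metric, ti, combo, data, config.alpha)
                if score > best:
                    best, best_parents = score, combo
        parent_sets[target] = ParentSet(
            target, tuple(data.genes[i] for i in best_parents), best
        )
    return Network(list(data.genes), parent_sets, config.metric, config)


# ---- calibration utility -------------------------------------------------


def null_positive_rate(
    alpha: float, n_transitions: int, n_replicates: int, seed: int, n_states: int = 2
) -> float:
    """Fraction of replicates in which an independent parent-child pair
    attains a positive MIT score.

    Under independence 2N·I is asymptotically chi-square with
    (r−1)² degrees of freedom, so the fraction approaches 1 − alpha as N
    grows — the calibration the penalty is built on.
    """
    rng = np.random.default_rng(seed)
    positives = 0
    for _ in range(n_replicates):
        x = rng.integers(0, n_states, size=n_transitions)
        y = rng.integers(0, n_states, size=n_transitions)
        data = TransitionDataset(
            genes=["parent", "child"],
            x_t=np.column_stack([x, np.zeros_like(x)]),
            x_next=np.column_stack([np.zeros_like(y), y]),
            state_counts=np.array([n_states, n_states]),
        )
        if mit_node_score("child", ["parent"], data, alpha) > 0:
            positives += 1
    return positives / n_replicates
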