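"""Synthetic study generator.

Reproduces, from a seed, the shape of the study design: clock regulators
entrained to three 12 h light/dark cycles followed by 24 h of continuous
light, sampled every 4 h (18 training + 6 held-out samples); target
transcription factors driven by the kinetic model τ·dy/dt = −y + g(β·Z)
with known predictors and coefficients; discrete order-1 DBN trajectories
from a known network with explicit conditional probability tables; and raw
two-channel microarray intensities with an intensity-dependent dye bias for
exercising the lowess normalization stage.

Clock waveforms are sinusoids — the analytic stand-in for 24 h rhythmic
regulators, keeping every ground truth closed-form.  All generators are
pure functions of their arguments including the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, DiscreteMatrix
from .modeling import Predictor

__all__ = [
    "ScheduleError",
    "IntegrationError",
    "ConditionSchedule",
    "SyntheticSpec",
    "TrueTargetModel",
    "CPT",
    "GroundTruth",
    "make_schedule",
    "default_clock_spec",
    "gen_clock_profiles",
    "gen_targets",
    "gen_discrete_dbn",
    "gen_two_channel",
    "random_dbn_truth",
    "make_driven_truth",
    "make_recovery_truth",
    "simulate_study",
    "DEFAULT_CLOCK_GENES",
]

DEFAULT_CLOCK_GENES = [
    "kaiA", "kaiB1", "kaiB3", "kaiB4", "kaiC1", "kaiC2",
    "ldpA", "cikA", "cpmA", "labA", "sasA", "rpaA",
]


class ScheduleError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class ConditionSchedule:
    """Ordered sample records: time (hours), condition (L/D/LL), split."""

    records: pd.DataFrame  # index: sample id; columns time_h, condition, experiment, split

    def __post_init__(self) -> None:
        t = self.records["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ScheduleError("sample times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return self.records["time_h"].to_numpy(float)

    def split_ids(self, split: str) -> list[str]:
        return list(self.records.index[self.records["split"] == split])


def make_schedule(
    n_ld_cycles: int, ll_hours: float, spacing_h: float
) -> ConditionSchedule:
    """Sampling schedule: ``n_ld_cycles`` alternating 12 h L / 12 h D cycles
    (split=train, experiment "LD") followed by ``ll_hours`` of continuous
    light (split=test, experiment "LL"), sampled every ``spacing_h`` hours.

    The default study design, (3, 24, 4), yields 18 training and 6 test
    samples.  Spacing must divide the 12 h photoperiod so samples never
    straddle a light transition.
    """
    if n_ld_cycles < 1:
        raise ScheduleError("need at least one L/D cycle")
    if spacing_h <= 0:
        raise ScheduleError("spacing must be positive")
    if abs(12.0 / spacing_h - round(12.0 / spacing_h)) > 1e-9:
        raise ScheduleError(f"spacing {spacing_h} h does not divide the 12 h photoperiod")
    ld_end = n_ld_cycles * 24.0
    times = np.arange(0.0, ld_end + ll_hours, spacing_h)
    rows = []
    for t in times:
        if t < ld_end:
            cond = "L" if (t % 24.0) < 12.0 else "D"
            rows.append((t, cond, "LD", "train"))
        else:
            rows.append((t, "LL", "LL", "test"))
    ids = [f"t{int(round(t * 60)):05d}" for t, *_ in rows]
    frame = pd.DataFrame(
        rows, columns=["time_h", "condition", "experiment", "split"], index=ids
    )
    return ConditionSchedule(frame)


@dataclass
class SyntheticSpec:
    """Clock-regulator generator settings: per-gene amplitude and phase of a
    sinusoid with the given period, plus additive Gaussian noise."""

    genes: list[str]
    amplitudes: np.ndarray
    phases: np.ndarray  # hours, in [0, period)
    period: float
    noise_sd: float
    schedule: ConditionSchedule
    seed: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, float)
        self.phases = np.asarray(self.phases, float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.phases < 0) or np.any(self.phases >= self.period):
            raise ValueError("phases must lie in [0, period)")
        if not (len(self.genes) == len(self.amplitudes) == len(self.phases)):
            raise ValueError("genes/amplitudes/phases length mismatch")

    @property
    def n_clock_genes(self) -> int:
        return len(self.genes)


def default_clock_spec(
    seed: int,
    noise_sd: float = 0.35,
    schedule: ConditionSchedule | None = None,
) -> SyntheticSpec:
    """The 12 clock regulators: unit amplitude, phases spread 2 h apart over
    the 24 h period, the (3, 24, 4) schedule, and measurement noise at the
    level two-channel arrays show on rhythmic transcripts (sd 0.35 on a
    unit-amplitude log-ratio oscillation, i.e. roughly half the signal sd).

    The regulator noise is what makes co-periodic regulators statistically
    distinguishable: noise-free sinusoids of a common period span only a
    two-dimensional space, so each gene's private measurement noise is the
    identifying signature that regression on the observed profiles keys on.
    """
    schedule = schedule or make_schedule(3, 24.0, 4.0)
    n = len(DEFAULT_CLOCK_GENES)
    return SyntheticSpec(
        genes=list(DEFAULT_CLOCK_GENES),
        amplitudes=np.ones(n),
        phases=np.arange(n) * (24.0 / n),
        period=24.0,
        noise_sd=noise_sd,
        schedule=schedule,
        seed=seed,
    )


def gen_clock_profiles(spec: SyntheticSpec) -> ExpressionMatrix:
    """Entrained regulator profiles: amp·sin(2π(t − phase)/period) + noise."""
    t = spec.schedule.times
    clean = spec.amplitudes[:, None] * np.sin(
        2.0 * np.pi * (t[None, :] - spec.phases[:, None]) / spec.period
    )
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else clean
    values = pd.DataFrame(noisy, index=spec.genes, columns=spec.schedule.records.index)
    return ExpressionMatrix(values, spec.schedule.records.copy())


@dataclass
class TrueTargetModel:
    """Ground-truth kinetic model of one target: raw-scale coefficients on
    named predictors plus an intercept (identity link, no truncation)."""

    predictors: list[Predictor]
    beta: np.ndarray
    intercept: float = 0.0


@dataclass
class CPT:
    """Conditional probability table of one gene given its parents at t−1.

    ``table`` has one row per parent configuration (mixed-radix encoding,
    first parent most significant) and one column per child state; rows sum
    to one.  Parentless genes have a single-row table (their marginal)."""

    parents: tuple[str, ...]
    table: np.ndarray

    def validate(self, n_states: int) -> None:
        tab = np.asarray(self.table, float)
        if tab.ndim != 2 or tab.shape[1] != n_states:
            raise ValueError("CPT shape inconsistent with state count")
        if np.any(tab < 0) or np.any(np.abs(tab.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("CPT rows must be distributions summing to 1")


@dataclass
class GroundTruth:
    """Everything the generators know and downstream recovery is judged on."""

    dbn_edges: list[tuple[str, str]] = field(default_factory=list)
    cpts: dict[str, CPT] = field(default_factory=dict)
    initial: dict[str, np.ndarray] = field(default_factory=dict)
    target_models: dict[str, TrueTargetModel] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "dbn_edges": [list(e) for e in self.dbn_edges],
            "cpts": {
                g: {"parents": list(c.parents), "table": np.asarray(c.table).tolist()}
                for g, c in self.cpts.items()
            },
            "initial": {g: np.asarray(p).tolist() for g, p in self.initial.items()},
            "target_models": {
                t: {
                    "predictors": [p.to_json() for p in m.predictors],
                    "beta": np.asarray(m.beta).tolist(),
                    "intercept": m.intercept,
                }
                for t, m in self.target_models.items()
            },
        }


def gen_targets(
    clock: ExpressionMatrix,
    truth: GroundTruth,
    tau_min: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Integrate each true target's kinetic model along the schedule.

    Regulator inputs between samples are linearly interpolated; integration
    is explicit Euler with step ≤ τ/10 (in minutes), started at the
    equilibrium of the first sample.  Observation noise is added after
    integration, at the sample times only.
    """
    if tau_min <= 0:
        raise ValueError("tau must be positive for trajectory generation")
    times_min = clock.samples["time_h"].to_numpy(float) * 60.0
    rng = np.random.default_rng(seed)
    rows = {}
    for name, model in truth.target_models.items():
        for p in model.predictors:
            for g in p.genes:
                if g not in clock.values.index:
                    raise ValueError(f"true predictor gene {g!r} not in clock matrix")
        z = np.asarray([p.evaluate(clock.values) for p in model.predictors], float)
        drive = model.beta @ z + model.intercept  # g(β·Z) at sample times

        step = tau_min / 10.0
        y = float(drive[0])
        out = np.empty(len(times_min))
        out[0] = y
        for k in range(len(times_min) - 1):
            t0, t1 = times_min[k], times_min[k + 1]
            n_sub = max(1, int(np.ceil((t1 - t0) / step)))
            h = (t1 - t0) / n_sub
            for j in range(n_sub):
                tm = t0 + j * h
                w = (tm - t0) / (t1 - t0)
                g_now = (1.0 - w) * drive[k] + w * drive[k + 1]
                y = y + h * (-y + g_now) / tau_min
                if not np.isfinite(y):
                    raise IntegrationError(f"non-finite state for target {name!r}")
            out[k + 1] = y
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        rows[name] = out
    values = pd.DataFrame(rows).T
    values.columns = clock.values.columns
    return ExpressionMatrix(values, clock.samples.copy())


def gen_discrete_dbn(
    truth: GroundTruth, n_steps: int, n_states: int, seed: int
) -> DiscreteMatrix:
    """Order-1 Markov sampling of ``n_steps`` state vectors from the CPTs.

    The first vector is drawn from the stated per-gene initial
    distributions (uniform when unspecified); every later vector is drawn
    gene-wise from the CPT row indexed by the parents' previous states.
    """
    genes = list(truth.cpts)
    for g, cpt in truth.cpts.items():
        cpt.validate(n_states)
        for p in cpt.parents:
            if p not in truth.cpts:
                raise ValueError(f"CPT parent {p!r} is not a generated gene")
    rng = np.random.default_rng(seed)
    states = np.empty((len(genes), n_steps), dtype=np.int64)
    for i, g in enumerate(genes):
        init = truth.initial.get(g, np.full(n_states, 1.0 / n_states))
        states[i, 0] = rng.choice(n_states, p=np.asarray(init, float))
    gi = {g: i for i, g in enumerate(genes)}
    for t in range(1, n_steps):
        prev = states[:, t - 1]
        for i, g in enumerate(genes):
            cpt = truth.cpts[g]
            row = 0
            for p in cpt.parents:
                row = row * n_states + prev[gi[p]]
            states[i, t] = rng.choice(n_states, p=cpt.table[row])
    ids = [f"s{t:04d}" for t in range(n_steps)]
    samples = pd.DataFrame(
        {
            "time_h": np.arange(n_steps, dtype=float),
            "condition": "LL",
            "experiment": "sim",
            "split": "train",
        },
        index=ids,
    )
    frame = pd.DataFrame(states, index=genes, columns=ids)
    return DiscreteMatrix(frame, samples, pd.Series(n_states, index=genes))


def random_dbn_truth(
    n_genes: int = 10,
    n_states: int = 3,
    max_parents: int = 2,
    fidelity: float = 0.85,
    seed: int = 0,
    n_roots: int = 3,
) -> GroundTruth:
    """A random sparse order-1 DBN with strong (high-fidelity) CPTs.

    Root genes are i.i.d. uniform; every other gene copies its single
    parent, or the elementwise minimum of its two parents, with probability
    ``fidelity`` (remaining mass spread over the other states).  i.i.d.
    roots keep lag-1 autocorrelation out of the system so only true edges
    carry signal.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    cpts: dict[str, CPT] = {}
    edges: list[tuple[str, str]] = []
    for i, g in enumerate(genes):
        if i < n_roots:
            cpts[g] = CPT((), np.full((1, n_states), 1.0 / n_states))
            continue
        k = int(rng.integers(1, max_parents + 1))
        parents = tuple(sorted(rng.choice(genes[:i], size=min(k, i), replace=False)))
        n_rows = n_states ** len(parents)
        table = np.full((n_rows, n_states), (1.0 - fidelity) / (n_states - 1))
        for row in range(n_rows):
            cfg = []
            rr = row
            for _ in parents:
                cfg.append(rr % n_states)
                rr //= n_states
            cfg = cfg[::-1]  # first parent most significant
            pick = cfg[0] if len(cfg) == 1 else min(cfg)
            table[row, pick] = fidelity
        cpts[g] = CPT(parents, table)
        edges.extend((p, g) for p in parents)
    return GroundTruth(dbn_edges=sorted(edges), cpts=cpts)


def make_driven_truth(
    regulators: list[str],
    n_targets: int,
    seed: int,
    allow_pairs: bool = True,
    n_predictors: tuple[int, int] = (1, 2),
    clock: ExpressionMatrix | None = None,
    min_drive_sd: float = 0.5,
) -> GroundTruth:
    """Random true target models over the given regulators.

    Each target draws 1–2 predictors (singles, and min-pairs when allowed)
    with raw-scale coefficients of magnitude in [0.8, 1.5] and a small
    intercept — effect sizes comparable to the unit-amplitude regulators.

    When ``clock`` is supplied, draws whose combined drive β·Z has standard
    deviation below ``min_drive_sd`` are rejected and redrawn: a
    clock-driven target is, by definition, one with a non-degenerate
    rhythmic amplitude, and two randomly signed terms of similar shape can
    otherwise cancel each other to an effectively unregulated profile.
    """
    rng = np.random.default_rng(seed)
    pool = [Predictor.single(g) for g in regulators]
    if allow_pairs:
        pool += [
            Predictor.min_pair(a, b) for a, b in itertools.combinations(regulators, 2)
        ]
    models = {}
    for i in range(n_targets):
        for _ in range(100):
            k = int(rng.integers(n_predictors[0], n_predictors[1] + 1))
            idx = rng.choice(len(pool), size=k, replace=False)
            beta = rng.uniform(0.8, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
            if clock is None:
                break
            drive = beta @ np.asarray(
                [pool[j].evaluate(clock.values) for j in idx], float
            )
            if float(np.std(drive)) >= min_drive_sd:
                break
        else:
            raise RuntimeError("could not draw a target with detectable drive")
        models[f"tf{i:03d}"] = TrueTargetModel(
            predictors=[pool[j] for j in idx],
            beta=beta,
            intercept=float(rng.uniform(-0.5, 0.5)),
        )
    return GroundTruth(target_models=models)


def gen_two_channel(
    expr: ExpressionMatrix,
    bias_curve,
    seed: int,
    n_replicates: int = 2,
    dye_swap: bool = True,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Raw Cy3/Cy5 intensities whose log2-ratio is the expression value plus
    an intensity-dependent dye bias plus noise.

    One array per sample (plus a dye-swap copy per array when requested,
    with the channels exchanged so its log-ratios are negated), and
    ``n_replicates`` probe replicates per gene.  Returns a tidy table with
    columns array, sample, probe, gene, replicate, dye_swap, cy3, cy5.
    """
    rng = np.random.default_rng(seed)
    genes = expr.genes
    base_a = rng.uniform(8.0, 12.0, size=(len(genes), n_replicates))
    bias = np.asarray(bias_curve(base_a), float)
    if not np.all(np.isfinite(bias)):
        raise ValueError("bias curve is not finite on the intensity range")
    rows = []
    for sid in expr.values.columns:
        m_true = expr.values[sid].to_numpy(float)
        for rep in range(n_replicates):
            a = base_a[:, rep]
            m = m_true + bias[:, rep]
            if noise_sd > 0:
                m = m + rng.normal(0.0, noise_sd, size=m.shape)
            cy5 = 2.0 ** (a + m / 2.0)
            cy3 = 2.0 ** (a - m / 2.0)
            if np.any(cy5 <= 0) or np.any(cy3 <= 0) or not (
                np.all(np.isfinite(cy5)) and np.all(np.isfinite(cy3))
            ):
                raise ValueError("generated intensities must be positive and finite")
            for gi, g in enumerate(genes):
                rows.append((f"{sid}_fwd", sid, f"{g}_p{rep}", g, rep, False, cy3[gi], cy5[gi]))
                if dye_swap:
                    rows.append((f"{sid}_swap", sid, f"{g}_p{rep}", g, rep, True, cy5[gi], cy3[gi]))
    return pd.DataFrame(
        rows,
        columns=["array", "sample", "probe", "gene", "replicate", "dye_swap", "cy3", "cy5"],
    )


def make_recovery_truth(regulators: list[str], seed: int) -> GroundTruth:
    """One target with one single and one min-pair predictor on disjoint
    regulators — the canonical parameter-recovery ground truth."""
    rng = np.random.default_rng(seed)
    gs = rng.choice(len(regulators), size=3, replace=False)
    preds = [
        Predictor.single(regulators[gs[0]]),
        Predictor.min_pair(regulators[gs[1]], regulators[gs[2]]),
    ]
    beta = rng.uniform(0.8, 1.5, size=2) * rng.choice([-1.0, 1.0], size=2)
    return GroundTruth(
        target_models={
            "tf000": TrueTargetModel(preds, beta, float(rng.uniform(-0.5, 0.5)))
        }
    )


def simulate_study(
    seed: int,
    n_driven: int = 10,
    n_noise: int = 10,
    regulator_noise_sd: float = 0.35,
    target_noise_sd: float = 0.1,
    tau_min: float = 15.0,
    schedule: ConditionSchedule | None = None,
    allow_pairs: bool = True,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth, pd.Series]:
    """The full labelled study fixture.

    Returns (clock regulators, target matrix, ground truth, labels) where
    labels marks each target "driven" (a true kinetic function of the
    clock) or "noise" (unit-variance Gaussian, no clock input).  Target
    observation noise defaults to 10% of the unit signal amplitude.
    """
    schedule = schedule or make_schedule(3, 24.0, 4.0)
    spec = default_clock_spec(seed, noise_sd=regulator_noise_sd, schedule=schedule)
    clock = gen_clock_profiles(spec)
    truth = make_driven_truth(
        spec.genes, n_driven, seed=seed + 1, allow_pairs=allow_pairs, clock=clock
    )
    driven = gen_targets(
        clock, truth, tau_min=tau_min, noise_sd=target_noise_sd, seed=seed + 2
    )
    rng = np.random.default_rng(seed + 3)
    noise_vals = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_noise, schedule.n_samples)),
        index=[f"noise{i:03d}" for i in range(n_noise)],
        columns=clock.values.columns,
    )
    targets = ExpressionMatrix(
        pd.concat([driven.values, noise_vals]), clock.samples.copy()
    )
    labels = pd.Series(
        ["driven"] * n_driven + ["noise"] * n_noise, index=list(targets.values.index)
    )
    return clock, targets, truth, labels
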