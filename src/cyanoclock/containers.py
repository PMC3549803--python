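"""Core data containers shared across the pipeline.

Expression data travel as a genes x samples table with a per-sample metadata
frame (time in hours, light condition, experiment id, train/test split).
Discretized data additionally carry the per-gene state count ``r_i``, and the
order-1 transition dataset holds the (x_t, x_{t+1}) state-vector pairs that
the dynamic-Bayesian-network score is computed on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_FIELDS = ("time_h", "condition", "experiment", "split")
CONDITIONS = ("L", "D", "LL")
SPLITS = ("train", "test")


def _check_samples(samples: pd.DataFrame) -> None:
    missing = [f for f in SAMPLE_FIELDS if f not in samples.columns]
    if missing:
        raise ValueError(f"sample metadata missing fields: {missing}")
    bad_cond = set(samples["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    bad_split = set(samples["split"]) - set(SPLITS)
    if bad_split:
        raise ValueError(f"unknown split labels: {sorted(bad_split)}")
    for exp, grp in samples.groupby("experiment", sort=False):
        t = grp["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times not strictly increasing in experiment {exp!r}")


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples expression with per-sample metadata.

    ``values``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns
    ``time_h, condition, experiment, split``; column order matches ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample index do not match")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("non-finite expression values")
        _check_samples(self.samples)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_split(self, split: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["split"] == split]
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.samples.loc[sample_ids])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)

    # ---- TSV + JSON-sidecar serialization -------------------------------

    def write(self, tsv_path: str | Path) -> None:
        tsv_path = Path(tsv_path)
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "samples": [
                {"id": sid, **{f: _jsonable(row[f]) for f in SAMPLE_FIELDS}}
                for sid, row in self.samples.iterrows()
            ]
        }
        tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read(cls, tsv_path: str | Path) -> "ExpressionMatrix":
        tsv_path = Path(tsv_path)
        table = pd.read_csv(tsv_path, sep="\t")
        table = table.set_index("gene")
        table.index.name = None
        meta = json.loads(tsv_path.with_suffix(tsv_path.suffix + ".json").read_text())
        samples = pd.DataFrame(meta["samples"]).set_index("id")
        samples.index.name = None
        return cls(table, samples.loc[list(table.columns)])


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


@dataclass
class DiscreteMatrix:
    """Integer-state expression; ``n_states[g]`` is the state count r_g."""

    states: pd.DataFrame
    samples: pd.DataFrame
    n_states: pd.Series

    def __post_init__(self) -> None:
        if list(self.states.columns) != list(self.samples.index):
            raise ValueError("states columns and sample index do not match")
        _check_samples(self.samples)
        arr = self.states.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("states must be integers")
        r = self.n_states.loc[self.states.index].to_numpy(int)
        if np.any(r < 1):
            raise ValueError("state counts must be >= 1")
        if np.any(arr < 0) or np.any(arr >= r[:, None]):
            raise ValueError("state out of [0, r_i) range")

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    def write(self, tsv_path: str | Path) -> None:
        """TSV with a ``#states`` header line giving each gene's r_i."""
        tsv_path = Path(tsv_path)
        header = "#states\t" + "\t".join(
            f"{g}={int(self.n_states[g])}" for g in self.genes
        )
        out = self.states.copy()
        out.insert(0, "gene", out.index)
        body = out.to_csv(sep="\t", index=False)
        tsv_path.write_text(header + "\n" + body)
        sidecar = {
            "samples": [
                {"id": sid, **{f: _jsonable(row[f]) for f in SAMPLE_FIELDS}}
                for sid, row in self.samples.iterrows()
            ]
        }
        tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )


@dataclass
class TransitionDataset:
    """Order-1 transition pairs the DBN score is evaluated on.

    ``x_t`` and ``x_next`` are (N, n_genes) integer arrays of consecutive
    state vectors; pairs never straddle an experiment boundary.
    """

    genes: list[str]
    x_t: np.ndarray
    x_next: np.ndarray
    state_counts: np.ndarray  # r_i per gene, aligned with ``genes``

    def __post_init__(self) -> None:
        if self.x_t.shape != self.x_next.shape:
            raise ValueError("x_t / x_next shape mismatch")
        if self.x_t.shape[1] != len(self.genes):
            raise ValueError("gene count mismatch")
        if len(self.state_counts) != len(self.genes):
            raise ValueError("state_counts length mismatch")

    @property
    def n_transitions(self) -> int:
        return self.x_t.shape[0]

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)
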