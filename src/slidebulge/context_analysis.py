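"""Next-nearest-neighbor representativeness, triplet isolation, group tests.

Bulge penalties are measured with some sequence context beyond the nearest
neighbors (the NNNs), and that context perturbs the measurement.  To pick a
standard context, the same set of bulges is measured under many NNN pairs;
a context's deviation at each (bulge, temperature) cell is its distance
from the cell's across-context mean, its RMS over all cells scores overall
representativeness, and its largest absolute deviation guards against
outliers.  This module also isolates the interior triplet-state energy from
matched two-/three-slide measurements (the three-slide ensemble contains
exactly one extra Boltzmann term) and provides the Welch two-sample
comparison used for purine-vs-pyrimidine contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .partition_model import rt


class AnalysisError(ValueError):
    """Raised for incomplete tensors or inconsistent extraction input."""


class InconsistentDataError(AnalysisError):
    """Two-/three-slide pair implies a non-positive triplet weight."""


@dataclass(frozen=True)
class NNNScore:
    """Representativeness summary of one NNN context."""

    context: str
    rms: float  # kcal/mol, over all (bulge, temperature) deviations
    max_abs_deviation: float  # kcal/mol

    def __post_init__(self):
        if self.rms < 0 or self.max_abs_deviation < 0:
            raise AnalysisError("scores must be non-negative")
        if self.rms > self.max_abs_deviation + 1e-12:
            raise AnalysisError("rms cannot exceed the maximum |deviation|")


@dataclass
class DdgTensor:
    """Complete bulge x NNN-context x temperature array of ΔΔG° values."""

    bulges: list
    contexts: list
    temperatures: np.ndarray
    values: np.ndarray  # shape (bulge, context, temperature), kcal/mol

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.bulges), len(self.contexts), self.temperatures.size)
        if self.values.shape != expected:
            raise AnalysisError(
                f"tensor shape {self.values.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise AnalysisError("tensor has missing or non-finite cells")

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    def deviations_per_context(self) -> int:
        return len(self.bulges) * self.temperatures.size

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "DdgTensor":
        """Long form: columns bulge, nnn5, nnn3, temperature_C, ddG_kcal_mol."""
        required = {"bulge", "nnn5", "nnn3", "temperature_C", "ddG_kcal_mol"}
        if not required.issubset(records.columns):
            raise AnalysisError(
                f"missing columns {sorted(required - set(records.columns))}"
            )
        df = records.copy()
        df["context"] = df["nnn5"].astype(str) + "/" + df["nnn3"].astype(str)
        bulges = sorted(df["bulge"].unique())
        contexts = sorted(df["context"].unique())
        temps = np.sort(df["temperature_C"].unique().astype(float))
        values = np.full((len(bulges), len(contexts), temps.size), np.nan)
        b_ix = {b: i for i, b in enumerate(bulges)}
        c_ix = {c: i for i, c in enumerate(contexts)}
        t_ix = {t: i for i, t in enumerate(temps)}
        for _, row in df.iterrows():
            values[
                b_ix[row["bulge"]], c_ix[row["context"]],
                t_ix[float(row["temperature_C"])],
            ] = float(row["ddG_kcal_mol"])
        return cls(bulges, contexts, temps, values)

    def to_records(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.bulges):
            for j, c in enumerate(self.contexts):
                nnn5, nnn3 = c.split("/")
                for k, t in enumerate(self.temperatures):
                    rows.append((b, nnn5, nnn3, float(t), float(self.values[i, j, k])))
        return pd.DataFrame(
            rows, columns=["bulge", "nnn5", "nnn3", "temperature_C", "ddG_kcal_mol"]
        )


def nnn_statistics(tensor: DdgTensor) -> tuple[np.ndarray, list[NNNScore]]:
    """Deviation tensor and per-context representativeness scores.

    deviation[b, c, t] = value[b, c, t] − mean over contexts at (b, t);
    each context is scored by the RMS of its deviations over every
    (bulge, temperature) cell and by its largest |deviation|.
    """
    dev = tensor.values - tensor.values.mean(axis=1, keepdims=True)
    scores = []
    for j, ctx in enumerate(tensor.contexts):
        d = dev[:, j, :]
        scores.append(
            NNNScore(
                context=ctx,
                rms=float(np.sqrt(np.mean(d**2))),
                max_abs_deviation=float(np.max(np.abs(d))),
            )
        )
    return dev, scores


def select_representative(
    scores: Sequence[NNNScore], k_low: int = 3, k_high: int = 3
) -> list[str]:
    """Contexts with the lowest RMS, excluding the worst-outlier contexts.

    Takes the ``k_low`` lowest-RMS contexts and removes any that rank in
    the ``k_high`` highest maximum deviations.  Ties break lexicographically
    on the context label, so the result does not depend on input order.
    An empty result is returned as such for the caller to judge.
    """
    if not scores:
        raise AnalysisError("no scores supplied")
    if k_low >= len(scores) or k_high >= len(scores):
        raise AnalysisError("k_low and k_high must be smaller than the context count")
    by_rms = sorted(scores, key=lambda s: (s.rms, s.context))
    low = [s.context for s in by_rms[:k_low]]
    by_max = sorted(scores, key=lambda s: (-s.max_abs_deviation, s.context))
    high = {s.context for s in by_max[:k_high]}
    return sorted(c for c in low if c not in high)


def representative_ddg(values: Sequence[float]) -> float:
    """Working ΔΔG°: mean of the measurements in the representative contexts."""
    if len(values) == 0:
        raise AnalysisError("no measurements supplied")
    return float(np.mean(values))


def extract_triplet(
    two_slide_ddgs: Sequence[float],
    three_slide_ddgs: Sequence[float],
    temperature_C: float,
    contexts: Optional[Sequence[str]] = None,
) -> float:
    """Isolate the interior triplet-state ΔΔG° from matched measurements.

    For each flank context, the three-slide partition function exceeds the
    two-slide one by exactly the triplet Boltzmann weight:
    w_t = exp(−g3/RT) − exp(−g2/RT).  The weights are averaged across
    contexts (mean of Boltzmann factors, not of energies) and converted
    back: ΔΔG°(triplet) = −RT ln(mean w_t).
    """
    g2 = np.asarray(two_slide_ddgs, dtype=float)
    g3 = np.asarray(three_slide_ddgs, dtype=float)
    if g2.size == 0:
        raise AnalysisError("empty context list")
    if g2.shape != g3.shape:
        raise AnalysisError(
            f"got {g2.size} two-slide but {g3.size} three-slide values"
        )
    labels = list(contexts) if contexts is not None else [
        f"context {i}" for i in range(g2.size)
    ]
    if len(labels) != g2.size:
        raise AnalysisError("context labels not aligned with the measurements")
    RT = rt(temperature_C)
    weights = np.exp(-g3 / RT) - np.exp(-g2 / RT)
    bad = np.flatnonzero(weights <= 0)
    if bad.size:
        raise InconsistentDataError(
            f"non-positive triplet weight for {labels[bad[0]]}: the three-slide "
            "ensemble must be strictly larger than the two-slide one"
        )
    return float(-RT * math.log(float(np.mean(weights))))


@dataclass(frozen=True)
class GroupComparison:
    """Welch's unequal-variance two-sample comparison."""

    t: float
    df: float
    p: float


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Welch's t-test (two-sided) with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least two values")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return GroupComparison(0.0, float(a.size + b.size - 2), 1.0)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        va**2 / (a.size - 1) + vb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(float(t), float(df), float(p))
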