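"""Toehold-exchange energy measurement: equilibrium model and ΔΔG° inference.

Three strands interact: a shared complement C can bind either a protector P
or a probe X, which occupy opposite ends of C and displace each other
through toehold exchange.  At equilibrium, the CP/CX partitioning encodes
the free-energy difference between the two duplexes.  Only CX fluoresces
(C carries a fluorophore, P a quencher), so the normalized signal

    f = (F_sample − F_negative) / (F_positive − F_negative)

estimates [CX]/C0.  Running the same exchange with a reference probe and a
bulge-bearing probe and taking

    ΔΔG° = −RT ln(K_bulge / K_reference),  K = [CX][P] / ([CP][X])

cancels every shared contribution, leaving the bulge penalty alone.  The
inference neglects free C (C is limiting against excess P and X); the
forward simulator solves the full coupled equilibria, so round trips
quantify that approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .partition_model import rt

PHASES = ("cooling", "heating")

#: Working concentrations (molar): C 20 nM, P 30 nM, X(reference) 40 nM.
DEFAULT_TOTALS = {"C0": 20e-9, "P0": 30e-9, "X0": 40e-9}
#: Bulge probes run in excess to populate the weaker CX duplex: 1 uM.
DEFAULT_X0_BULGE = 1e-6

#: Normalized signals within eps of 0 or 1 carry no usable information.
SIGNAL_EPS = 1e-3


class TeemError(ValueError):
    """Raised for inconsistent assay data or unusable signals."""


class SaturatedSignalError(TeemError):
    """Normalized fluorescence outside (eps, 1 - eps)."""


@dataclass
class TEEMAssay:
    """One exchange reaction: totals, temperature series and raw signals.

    Fluorescence is stored per phase ("cooling"/"heating") as arrays
    aligned to ``temperatures``; sample, positive control (no P: maximal
    CX) and negative control (no X: zero CX) share the grid.
    """

    totals: dict  # {"C0", "P0", "X0"} in molar
    temperatures: np.ndarray
    f_sample: dict
    f_pos: dict
    f_neg: dict

    def __post_init__(self):
        for key in ("C0", "P0", "X0"):
            if key not in self.totals or self.totals[key] <= 0:
                raise TeemError(f"total {key} must be present and positive")
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        for phase in self.phases:
            for name, series in (
                ("sample", self.f_sample),
                ("positive", self.f_pos),
                ("negative", self.f_neg),
            ):
                if phase not in series:
                    raise TeemError(f"missing {name} series for phase {phase!r}")
                arr = np.asarray(series[phase], dtype=float)
                if arr.shape != self.temperatures.shape:
                    raise TeemError(
                        f"{name}/{phase} length {arr.size} does not match "
                        f"temperature grid length {self.temperatures.size}"
                    )
                series[phase] = arr
            if np.any(self.f_pos[phase] <= self.f_neg[phase]):
                raise TeemError(
                    f"positive control must exceed negative control at every "
                    f"temperature (phase {phase!r})"
                )

    @property
    def phases(self) -> tuple:
        return tuple(p for p in PHASES if p in self.f_sample)

    def normalized(self, phase: str) -> np.ndarray:
        """Signal fraction f = (F_sample − F_neg)/(F_pos − F_neg)."""
        if phase not in self.f_sample:
            raise TeemError(f"no phase {phase!r} in assay")
        span = self.f_pos[phase] - self.f_neg[phase]
        return (self.f_sample[phase] - self.f_neg[phase]) / span

    def index_of(self, temperature_C: float) -> int:
        idx = np.flatnonzero(np.isclose(self.temperatures, temperature_C))
        if idx.size == 0:
            raise TeemError(
                f"temperature {temperature_C} degC not in assay grid"
            )
        return int(idx[0])

    def to_records(self) -> pd.DataFrame:
        rows = []
        for phase in self.phases:
            for role, series in (
                ("sample", self.f_sample),
                ("positive", self.f_pos),
                ("negative", self.f_neg),
            ):
                for t, f in zip(self.temperatures, series[phase]):
                    rows.append((float(t), phase, role, float(f)))
        return pd.DataFrame(
            rows, columns=["temperature_C", "phase", "well_role", "fluorescence"]
        )

    def write_csv(self, path) -> None:
        self.to_records().to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: pd.DataFrame, totals: Mapping) -> "TEEMAssay":
        required = {"temperature_C", "phase", "well_role", "fluorescence"}
        if not required.issubset(records.columns):
            raise TeemError(
                f"assay CSV missing columns {sorted(required - set(records.columns))}"
            )
        temps = np.sort(records["temperature_C"].unique().astype(float))
        series = {"sample": {}, "positive": {}, "negative": {}}
        for (phase, role), grp in records.groupby(["phase", "well_role"]):
            grp = grp.sort_values("temperature_C")
            if not np.allclose(grp["temperature_C"].to_numpy(dtype=float), temps):
                raise TeemError(
                    f"{role}/{phase} series not aligned to the common grid"
                )
            series[role][phase] = grp["fluorescence"].to_numpy(dtype=float)
        return cls(
            totals=dict(totals),
            temperatures=temps,
            f_sample=series["sample"],
            f_pos=series["positive"],
            f_neg=series["negative"],
        )


@dataclass
class ExchangePair:
    """Matched reference and bulge assays sharing a temperature grid."""

    reference: TEEMAssay
    bulge: TEEMAssay

    def __post_init__(self):
        if not np.array_equal(
            self.reference.temperatures, self.bulge.temperatures
        ):
            raise TeemError("reference and bulge assays must share a grid")

    @property
    def temperatures(self) -> np.ndarray:
        return self.reference.temperatures


def simulate_equilibrium(
    k_cp: float, k_cx: float, totals: Mapping[str, float]
) -> dict:
    """Exact species concentrations for C+P <-> CP, C+X <-> CX.

    Solves the scalar mass balance in free C by monotone bracketing
    (Brent) followed by Newton polishing; all five constraints hold to
    better than 1e-12 relative.
    """
    if k_cp < 0 or k_cx < 0:
        raise TeemError("association constants must be non-negative")
    c0, p0, x0 = (float(totals[k]) for k in ("C0", "P0", "X0"))
    if min(c0, p0, x0) <= 0:
        raise TeemError("totals must be positive")

    def balance(c):
        return (
            c
            + k_cp * c * p0 / (1.0 + k_cp * c)
            + k_cx * c * x0 / (1.0 + k_cx * c)
            - c0
        )

    c = brentq(balance, 0.0, c0, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    for _ in range(3):  # Newton polish toward machine precision
        f = balance(c)
        fp = (
            1.0
            + k_cp * p0 / (1.0 + k_cp * c) ** 2
            + k_cx * x0 / (1.0 + k_cx * c) ** 2
        )
        step = f / fp
        if c - step <= 0:
            break
        c -= step
    p = p0 / (1.0 + k_cp * c)
    x = x0 / (1.0 + k_cx * c)
    out = {"C": c, "P": p, "X": x, "CP": k_cp * c * p, "CX": k_cx * c * x}
    resid = max(
        abs(out["C"] + out["CP"] + out["CX"] - c0) / c0,
        abs(out["P"] + out["CP"] - p0) / p0,
        abs(out["X"] + out["CX"] - x0) / x0,
    )
    if resid > 1e-12:
        raise TeemError(f"equilibrium solve did not converge (residual {resid:.2e})")
    return out


@dataclass(frozen=True)
class TeemInference:
    """Per-temperature ΔΔG° with phase-level diagnostics.

    ``ddg`` is the mean over available phases; cooling- and heating-phase
    values are also reported individually, along with the normalized
    signals and exchange quotients that produced them.
    """

    temperature_C: float
    ddg: float
    ddg_by_phase: dict
    f_reference: dict
    f_bulge: dict
    k_reference: dict
    k_bulge: dict
    free_c_error_bound: Optional[float] = None


def _exchange_quotient(assay: TEEMAssay, phase: str, idx: int, eps: float) -> tuple:
    f = float(assay.normalized(phase)[idx])
    if not (eps < f < 1.0 - eps):
        raise SaturatedSignalError(
            f"normalized signal {f:.4g} outside ({eps}, {1 - eps}) at "
            f"{assay.temperatures[idx]} degC ({phase}); the exchange is "
            "saturated or empty"
        )
    c0, p0, x0 = (assay.totals[k] for k in ("C0", "P0", "X0"))
    cx = f * c0
    cp = c0 - cx
    p = p0 - cp
    x = x0 - cx
    if min(cp, p, x) <= 0:
        raise TeemError(
            f"negative inferred concentration at {assay.temperatures[idx]} degC: "
            f"CP={cp:.3g}, P={p:.3g}, X={x:.3g}"
        )
    return f, cx * p / (cp * x)


def infer_ddg(
    pair: ExchangePair,
    temperature_C: float,
    eps: float = SIGNAL_EPS,
    k_cp: Optional[float] = None,
) -> TeemInference:
    """Infer the bulge ΔΔG° at one temperature from an exchange pair.

    Treats free C as negligible: [CX] = f·C0 then closes the mass balances
    for CP, P and X.  Passing the protector association constant ``k_cp``
    adds an estimate of the ΔΔG° error that the free-C approximation can
    introduce.
    """
    idx = pair.reference.index_of(temperature_C)
    RT = rt(temperature_C)
    phases = tuple(p for p in pair.reference.phases if p in pair.bulge.phases)
    if not phases:
        raise TeemError("no common measurement phase between the assays")
    ddg_by_phase, f_ref, f_bul, k_ref, k_bul = {}, {}, {}, {}, {}
    for phase in phases:
        f1, k1 = _exchange_quotient(pair.reference, phase, idx, eps)
        f2, k2 = _exchange_quotient(pair.bulge, phase, idx, eps)
        f_ref[phase], f_bul[phase] = f1, f2
        k_ref[phase], k_bul[phase] = k1, k2
        ddg_by_phase[phase] = -RT * math.log(k2 / k1)
    bound = None
    if k_cp is not None:
        bound = 0.0
        for assay, f_map, k_map in (
            (pair.reference, f_ref, k_ref),
            (pair.bulge, f_bul, k_bul),
        ):
            c0, p0 = assay.totals["C0"], assay.totals["P0"]
            for phase in phases:
                cx = f_map[phase] * c0
                cp = c0 - cx
                p = p0 - cp
                c_free = cp / (k_cp * p)  # from K_CP = [CP]/([C][P])
                # first-order shift of the exchange quotient if that free C
                # were reassigned to CP, doubled as a safety margin against
                # the neglected control-well free C
                bound = max(bound, 2.0 * RT * (c_free / p + c_free / cp))
    return TeemInference(
        temperature_C=float(temperature_C),
        ddg=float(np.mean(list(ddg_by_phase.values()))),
        ddg_by_phase=ddg_by_phase,
        f_reference=f_ref,
        f_bulge=f_bul,
        k_reference=k_ref,
        k_bulge=k_bul,
        free_c_error_bound=bound,
    )


def infer_ddg_series(pair: ExchangePair, **kw) -> pd.DataFrame:
    """Independent per-temperature inference over the whole grid."""
    rows = []
    for t in pair.temperatures:
        try:
            inf = infer_ddg(pair, float(t), **kw)
        except TeemError as exc:
            rows.append({"temperature_C": float(t), "ddg_kcal_mol": np.nan,
                         "flag": str(exc)})
            continue
        row = {"temperature_C": float(t), "ddg_kcal_mol": inf.ddg, "flag": ""}
        for phase, val in inf.ddg_by_phase.items():
            row[f"ddg_{phase}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_assay(
    true_ddg: float,
    k_reference: Union[float, Callable[[float], float]],
    totals: Optional[Mapping[str, float]] = None,
    temperatures=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    k_cp: Optional[Union[float, Callable[[float], float]]] = None,
    x0_bulge: float = DEFAULT_X0_BULGE,
    f_neg_level: float = 1000.0,
    f_pos_level: float = 50000.0,
) -> ExchangePair:
    """Forward-simulate a reference/bulge exchange pair with known ΔΔG°.

    ``k_reference`` is the CX association constant of the reference probe
    (1/M; a callable of temperature is accepted); the bulge probe gets
    K·exp(−ΔΔG°/RT).  Controls are simulated physically (no P for the
    positive control, no X for the negative), and Gaussian noise of
    standard deviation ``noise_sd`` × dynamic range is added per reading.
    Identical seeds give identical pairs.
    """
    if noise_sd < 0:
        raise TeemError("noise_sd must be >= 0")
    totals = dict(DEFAULT_TOTALS if totals is None else totals)
    if temperatures is None:
        temperatures = np.arange(25.0, 68.0)
    temperatures = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    span = f_pos_level - f_neg_level

    def at(k, t):
        return float(k(t)) if callable(k) else float(k)

    def one_assay(kx_of_t, x0):
        tot = {**totals, "X0": x0}
        f_sample, f_pos, f_neg = {}, {}, {}
        for phase in PHASES:
            sample, pos, neg = [], [], []
            for t in temperatures:
                kcp = at(k_cp, t) if k_cp is not None else at(k_reference, t)
                kcx = kx_of_t(t)
                eq = simulate_equilibrium(kcp, kcx, tot)
                frac = eq["CX"] / tot["C0"]
                # positive control omits P; negative omits X (CX = 0)
                eq_pos = simulate_equilibrium(0.0, kcx, {**tot, "P0": 1e-300})
                frac_pos = eq_pos["CX"] / tot["C0"]
                sample.append(f_neg_level + frac * span)
                pos.append(f_neg_level + frac_pos * span)
                neg.append(f_neg_level)
            for store, vals in ((f_sample, sample), (f_pos, pos), (f_neg, neg)):
                arr = np.asarray(vals)
                if noise_sd > 0:
                    arr = arr + rng.normal(0.0, noise_sd * span, arr.shape)
                store[phase] = arr
        return TEEMAssay(tot, temperatures.copy(), f_sample, f_pos, f_neg)

    reference = one_assay(lambda t: at(k_reference, t), totals["X0"])
    bulge = one_assay(
        lambda t: at(k_reference, t) * math.exp(-true_ddg / rt(t)), x0_bulge
    )
    return ExchangePair(reference, bulge)


def check_equilibration(assay: TEEMAssay, tolerance: float = 0.02) -> pd.DataFrame:
    """Compare cooling- and heating-phase signals temperature by temperature.

    Agreement within ``tolerance`` (normalized signal units) indicates the
    exchange reached equilibrium; larger gaps flag kinetically trapped
    temperatures.  Returns one row per temperature with a boolean verdict.
    """
    for phase in PHASES:
        if phase not in assay.f_sample:
            raise TeemError(f"equilibration check needs both phases; {phase!r} missing")
    f_cool = assay.normalized("cooling")
    f_heat = assay.normalized("heating")
    diff = np.abs(f_cool - f_heat)
    return pd.DataFrame(
        {
            "temperature_C": assay.temperatures,
            "f_cooling": f_cool,
            "f_heating": f_heat,
            "abs_diff": diff,
            "equilibrated": diff <= tolerance,
        }
    )
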