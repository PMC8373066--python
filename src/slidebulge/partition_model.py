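"""Partition-function prediction of sliding-bulge ΔΔG° and duplex yield.

A sliding bulge with N degenerate positions is treated as an equilibrium
ensemble: each conformation contributes a Boltzmann factor exp(−g/RT) and
the ensemble penalty is ΔΔG° = −RT ln Z.  For a tract of N identical bases
flanked by f5 and f3, the ensemble collapses to two building blocks — the
two-slide composite (both terminal conformations) and the interior triplet
state, whose weight enters (N−2)-fold:

    ΔΔG°(f5 B^N f3) = −RT ln( e^(−g2/RT) + (N−2)·e^(−gt/RT) )

with g2 the two-slide table entry and gt the triplet entry for B.  Because
the triplet weight accumulates with length, long enough tracts reach a
"singularity" where degeneracy cancels the bulge penalty entirely (Z >= 1,
ΔΔG° <= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .energy_tables import EnergyTable, ParameterSet, TableError
from .motif_model import BASES, BulgeMotif, BulgeState, MotifError, enumerate_states

#: Gas constant in kcal/(mol K).
R = 1.9872e-3
KELVIN = 273.15


def rt(temperature_C: float) -> float:
    """Thermal energy RT in kcal/mol at a Celsius temperature."""
    return R * (temperature_C + KELVIN)


Tables = Union[ParameterSet, Mapping[str, EnergyTable]]


def _table(tables: Tables, motif_class: str) -> EnergyTable:
    if isinstance(tables, ParameterSet):
        return tables.table(motif_class)
    try:
        return tables[motif_class]
    except KeyError as exc:
        raise TableError(f"no {motif_class!r} table supplied") from exc


@dataclass(frozen=True)
class PredictionResult:
    """Ensemble ΔΔG° with its partition-function decomposition.

    ``state_weights`` pairs each contributing term with its Boltzmann
    weight already multiplied by its multiplicity; for n >= 2 the two
    terminal conformations enter through the measured two-slide composite
    and are reported as one joint term.
    """

    motif: BulgeMotif
    temperature_C: float
    ddg: float
    Z: float
    state_weights: tuple[tuple[str, float], ...]
    occupancies: tuple[float, ...]

    def __post_init__(self):
        total = sum(self.occupancies)
        if self.occupancies and abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {total}, expected 1")


def predict_ddg(
    motif: BulgeMotif,
    tables: Tables,
    temperature_C: float = 37.0,
    extrapolate: bool = True,
) -> PredictionResult:
    """Predict the destabilization ΔΔG° (kcal/mol) of a sliding bulge.

    n=1 and n=2 are direct table lookups (a single conformation and the
    measured two-state composite); n >= 3 assembles the closed-form
    partition function from the two-slide and triplet entries.
    """
    RT = rt(temperature_C)
    kw = {"extrapolate": extrapolate}
    if motif.n == 1:
        g = _table(tables, "non_slide").ddg_at(motif.non_slide_key, temperature_C, **kw)
        _require_finite(g, motif.non_slide_key)
        return PredictionResult(
            motif, temperature_C, g, math.exp(-g / RT),
            ((motif.non_slide_key, math.exp(-g / RT)),), (1.0,),
        )
    g2 = _table(tables, "two_slide").ddg_at(motif.two_slide_key, temperature_C, **kw)
    _require_finite(g2, motif.two_slide_key)
    if motif.n == 2:
        w2 = math.exp(-g2 / RT)
        return PredictionResult(
            motif, temperature_C, g2, w2, ((motif.two_slide_key, w2),), (1.0,)
        )
    gt = _table(tables, "triplet").ddg_at(motif.triplet_key, temperature_C, **kw)
    _require_finite(gt, motif.triplet_key)
    m_t = motif.n - 2
    # log-sum-exp keeps Z finite for extreme per-state energies
    log_z = logsumexp([-g2 / RT, -gt / RT], b=[1.0, float(m_t)])
    ddg = -RT * float(log_z)
    w2 = math.exp(-g2 / RT - log_z)  # occupancy of the composite term
    wt = m_t * math.exp(-gt / RT - log_z)
    z = math.exp(log_z)
    return PredictionResult(
        motif,
        temperature_C,
        ddg,
        z,
        ((motif.two_slide_key, w2 * z), (motif.triplet_key, wt * z)),
        (w2, wt),
    )


def _require_finite(g: float, key: str) -> None:
    if not math.isfinite(g):
        raise TableError(f"non-finite energy for {key!r}")


def predict_ddg_enumerated(
    motif: BulgeMotif,
    state_energies: Mapping[Union[str, BulgeState], float],
    temperature_C: float = 37.0,
) -> float:
    """Brute-force ensemble ΔΔG° from explicit per-state energies.

    Sums multiplicity-weighted Boltzmann factors over every enumerated
    conformation (overflow-safe).  Energies may be keyed by state label
    (``cTt``) or by :class:`~slidebulge.motif_model.BulgeState`.
    """
    RT = rt(temperature_C)
    log_terms, mults = [], []
    for state in enumerate_states(motif):
        if state in state_energies:
            g = state_energies[state]
        elif state.key in state_energies:
            g = state_energies[state.key]
        else:
            raise MotifError(f"missing energy for state {state.key!r}")
        if not math.isfinite(g):
            raise TableError(f"non-finite energy for state {state.key!r}")
        log_terms.append(-g / RT)
        mults.append(float(state.multiplicity))
    return -RT * float(logsumexp(log_terms, b=mults))


def singularity_length(
    base: str,
    flank5: str,
    flank3: str,
    tables: Tables,
    temperature_C: float = 37.0,
    n_max: int = 1000,
    method: str = "formula",
) -> Optional[int]:
    """Smallest repeat count at which the sliding bulge stops destabilizing.

    Returns the least n <= ``n_max`` with ΔΔG° <= 0 (equivalently Z >= 1),
    or None if no such length exists within the bound.  ``method`` selects
    the closed-form ceiling solution or an incremental scan over n; the two
    must agree and the scan serves as the independent check.
    """
    if n_max < 2:
        raise MotifError(f"n_max must be >= 2, got {n_max}")
    probe = BulgeMotif(flank5, base, flank3, 2)
    RT = rt(temperature_C)
    g2 = _table(tables, "two_slide").ddg_at(probe.two_slide_key, temperature_C)
    gt = _table(tables, "triplet").ddg_at(probe.triplet_key, temperature_C)
    if method == "scan":
        for n in range(2, n_max + 1):
            m = BulgeMotif(flank5, base, flank3, n)
            if predict_ddg(m, tables, temperature_C).ddg <= 0.0:
                return n
        return None
    if method != "formula":
        raise ValueError(f"unknown method {method!r}: expected 'formula' or 'scan'")
    w2 = math.exp(-g2 / RT)
    if w2 >= 1.0:
        return 2
    wt = math.exp(-gt / RT)
    if wt == 0.0:
        return None  # Z is bounded below 1 for every length
    n_star = 2 + math.ceil((1.0 - w2) / wt)
    return n_star if n_star <= n_max else None


def mean_ddg_summary(
    base: str,
    n: int,
    tables: Tables,
    temperature_C: float = 37.0,
) -> float:
    """Mean predicted ΔΔG° over all nine flank contexts of a bulged base.

    The flanks each range over the three bases different from the bulged
    base; the arithmetic mean of the nine per-motif predictions summarises
    one (base, length) family.
    """
    if base not in BASES:
        raise MotifError(f"invalid base {base!r}")
    values = [
        predict_ddg(BulgeMotif(f5, base, f3, n), tables, temperature_C).ddg
        for f5 in BASES
        if f5 != base
        for f3 in BASES
        if f3 != base
    ]
    return float(np.mean(values))


def validation_residuals(measured, tables: Tables) -> "pd.DataFrame":
    """Residuals between predicted and measured sliding-bulge ΔΔG°.

    ``measured`` is a long-form table with columns ``motif``,
    ``temperature_C`` and ``ddG_kcal_mol`` (e.g. independently measured
    longer sliding bulges).  Returns the input plus ``predicted`` and
    ``residual`` (predicted − measured) columns; summarise with the median
    and maximum of ``residual.abs()``.
    """
    import pandas as pd

    from .motif_model import parse_motif

    required = {"motif", "temperature_C", "ddG_kcal_mol"}
    if not required.issubset(measured.columns):
        raise TableError(
            f"measured table missing columns {sorted(required - set(measured.columns))}"
        )
    out = measured.copy()
    out["predicted"] = [
        predict_ddg(parse_motif(str(row["motif"])), tables,
                    float(row["temperature_C"])).ddg
        for _, row in measured.iterrows()
    ]
    out["residual"] = out["predicted"] - out["ddG_kcal_mol"]
    return out


@dataclass(frozen=True)
class DuplexResult:
    """Hybridization free energy and equilibrium yield of a probe-target pair."""

    dg_duplex: float  # kcal/mol
    K: float  # association constant, 1/M
    duplex_conc: float  # M at equilibrium
    bound_fraction: float  # of the limiting species


def duplex_dg_and_yield(
    stack_dgs: Sequence[float],
    init_terms: float,
    bulge_ddg: float,
    temperature_C: float,
    conc_probe: float,
    conc_target: float,
) -> DuplexResult:
    """Duplex ΔG° from nearest-neighbor stacks plus a bulge penalty, and the
    resulting equilibrium hybridization yield.

    ΔG°duplex = Σ stack ΔG° + initiation terms + bulge ΔΔG°.  The bound
    fraction solves the exact bimolecular mass balance
    x = K (A0 − x)(B0 − x) via the numerically stable quadratic root and is
    reported for the limiting (lower-concentration) species.
    """
    vals = np.asarray(list(stack_dgs) + [init_terms, bulge_ddg], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite free-energy input")
    if conc_probe <= 0 or conc_target <= 0:
        raise ValueError("concentrations must be positive")
    dg = float(np.sum(vals))
    RT = rt(temperature_C)
    K = math.exp(-dg / RT)
    a0, b0 = float(conc_probe), float(conc_target)
    # K x^2 - (K(a0+b0)+1) x + K a0 b0 = 0; smaller root is physical.
    q = K * (a0 + b0) + 1.0
    disc = math.sqrt(max(q * q - 4.0 * K * K * a0 * b0, 0.0))
    x = 2.0 * K * a0 * b0 / (q + disc)
    limiting = min(a0, b0)
    return DuplexResult(dg, K, x, x / limiting)
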