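"""Two-compartment kinetic model of mRNA metabolism.

Transcripts are produced in the nucleus at rate ``alpha``, exported to the
cytoplasm at rate ``beta`` and degraded in the cytoplasm at rate ``gamma``;
an optional nuclear decay rate ``delta`` removes transcripts from the
nucleus directly.  Two independent species are tracked per gene — an
unmethylated (``A``) and an m6A-methylated (``m6A``) one — each with its own
rate triple.  The dynamics per species are the linear system

    dNuc/dt = alpha - (beta + delta) * Nuc
    dCyt/dt = beta * Nuc - gamma * Cyt

whose steady state is ``Nuc = alpha / (beta + delta)`` and
``Cyt = beta * Nuc / gamma``.  All rates are in arbitrary, mutually
consistent inverse-time units.

This module provides the scalar object API (:class:`RateSet`,
:class:`CompartmentState`, :func:`steady_state`, :func:`simulate_dynamics`)
as well as vectorised array primitives used by the cohort layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "ParameterError",
    "NoSteadyStateError",
    "DegenerateStateError",
    "RateSet",
    "CompartmentState",
    "DerivedIndices",
    "ModelVariant",
    "TimeCourse",
    "VARIANT_NAMES",
    "steady_state",
    "derive_indices",
    "simulate_dynamics",
    "apply_variant",
    "steady_state_pools",
    "index_table",
    "species_course",
]

# Relative |beta - gamma| threshold below which the closed-form cytoplasmic
# solution switches to its t*exp(-gamma t) limit to avoid cancellation.
_DEGENERACY_RTOL = 1e-9


class ParameterError(ValueError):
    """A rate is negative, non-finite, or otherwise inadmissible."""


class NoSteadyStateError(ValueError):
    """The rate set admits no finite steady state (unbounded accumulation)."""


class DegenerateStateError(ValueError):
    """All four transcript pools are zero; no index is defined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

RATE_FIELDS = (
    "alpha_A",
    "alpha_m6A",
    "beta_A",
    "beta_m6A",
    "gamma_A",
    "gamma_m6A",
    "delta",
)


@dataclass(frozen=True)
class RateSet:
    """Kinetic rates for one gene (two species sharing a nucleus/cytoplasm).

    Parameters
    ----------
    alpha_A, alpha_m6A
        Production rates of unmethylated / methylated transcripts.
    beta_A, beta_m6A
        Nuclear export rates.
    gamma_A, gamma_m6A
        Cytoplasmic decay rates.
    delta
        Nuclear decay rate shared by both species (default 0, i.e. the
        baseline model without nuclear degradation).
    S
        Decay multiplier recorded when ``gamma_m6A`` was constructed as
        ``S * gamma_A``; informational only.
    """

    alpha_A: float
    alpha_m6A: float
    beta_A: float
    beta_m6A: float
    gamma_A: float
    gamma_m6A: float
    delta: float = 0.0
    S: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"rate {name}={v!r} must be finite and >= 0")

    @classmethod
    def baseline(
        cls,
        alpha_A: float,
        alpha_m6A: float,
        beta: float,
        gamma_A: float,
        S: float = 10.0,
        delta: float = 0.0,
    ) -> "RateSet":
        """Baseline parameterisation: shared export, ``gamma_m6A = S * gamma_A``."""
        return cls(
            alpha_A=alpha_A,
            alpha_m6A=alpha_m6A,
            beta_A=beta,
            beta_m6A=beta,
            gamma_A=gamma_A,
            gamma_m6A=S * gamma_A,
            delta=delta,
            S=S,
        )

    def to_dict(self) -> dict[str, float]:
        d = {name: float(getattr(self, name)) for name in RATE_FIELDS}
        if self.S is not None:
            d["S"] = float(self.S)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown rate keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CompartmentState:
    """Abundances of the four transcript pools (arbitrary copy units)."""

    nuc_A: float
    nuc_m6A: float
    cyt_A: float
    cyt_m6A: float

    def __post_init__(self) -> None:
        for name in ("nuc_A", "nuc_m6A", "cyt_A", "cyt_m6A"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"pool {name}={v!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.nuc_A, self.nuc_m6A, self.cyt_A, self.cyt_m6A])

    @property
    def total(self) -> float:
        return self.nuc_A + self.nuc_m6A + self.cyt_A + self.cyt_m6A


@dataclass(frozen=True)
class DerivedIndices:
    """The five steady-state read-outs of a compartment state.

    ``gene_level`` is the summed abundance of all four pools;
    ``nuc_m6a_level`` / ``cyt_m6a_level`` / ``m6a_level`` are the methylated
    fractions of the nuclear, cytoplasmic, and whole-cell transcript pools;
    ``nuc_cyt_ratio`` is total nuclear over total cytoplasmic abundance.
    A ratio whose denominator is empty is reported as ``None`` (an explicit
    undefined marker) rather than raising or propagating NaN.
    """

    gene_level: float
    nuc_m6a_level: float | None
    cyt_m6a_level: float | None
    m6a_level: float
    nuc_cyt_ratio: float | None


@dataclass(frozen=True)
class ModelVariant:
    """A named preset transforming a base :class:`RateSet`.

    ``baseline``            shared export, ``gamma_m6A = S * gamma_A``, no nuclear decay
    ``nuclear_decay``       baseline plus nuclear decay ``delta > 0``
    ``export_facilitated``  m6A facilitates export instead of decay:
                            ``beta_m6A = 10 * beta_A``, ``gamma_m6A = gamma_A``
    ``export_inhibited``    m6A inhibits export instead of decay:
                            ``beta_m6A = 0.1 * beta_A``, ``gamma_m6A = gamma_A``
    ``ko``                  writer knockout: no selective decay (``gamma_m6A = gamma_A``)

    The export variants are alternative hypotheses in which m6A acts on
    export rather than on cytoplasmic stability, so they also remove the
    selective decay of the methylated species.

    ``params`` carries explicit overrides composed on top of the preset
    (e.g. ``{"S": 5}`` for baseline or ``{"delta": 0.5}`` for nuclear_decay,
    ``{"factor": 20}`` for the export variants).
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ParameterError(
                f"unknown variant {self.name!r}; expected one of {sorted(VARIANT_NAMES)}"
            )


VARIANT_NAMES = frozenset(
    {"baseline", "nuclear_decay", "export_facilitated", "export_inhibited", "ko"}
)


def apply_variant(rates: RateSet, variant: ModelVariant | str) -> RateSet:
    """Return a transformed copy of ``rates`` under a model variant preset.

    The base rate set is never mutated.  ``baseline`` re-imposes shared
    export and ``gamma_m6A = S * gamma_A`` (S from the variant params, the
    recorded ``rates.S``, or 10); the export variants scale ``beta_m6A``
    relative to ``beta_A`` and leave the decay rates untouched; ``ko``
    removes selective decay.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    p = dict(variant.params)
    if variant.name == "baseline":
        S = float(p.get("S", rates.S if rates.S is not None else 10.0))
        return replace(
            rates, beta_m6A=rates.beta_A, gamma_m6A=S * rates.gamma_A, delta=0.0, S=S
        )
    if variant.name == "nuclear_decay":
        delta = float(p.get("delta", 1.0))
        if delta <= 0:
            raise ParameterError("nuclear_decay variant requires delta > 0")
        return replace(rates, delta=delta)
    if variant.name == "export_facilitated":
        factor = float(p.get("factor", 10.0))
        return replace(rates, beta_m6A=factor * rates.beta_A, gamma_m6A=rates.gamma_A, S=1.0)
    if variant.name == "export_inhibited":
        factor = float(p.get("factor", 0.1))
        return replace(rates, beta_m6A=factor * rates.beta_A, gamma_m6A=rates.gamma_A, S=1.0)
    if variant.name == "ko":
        return replace(rates, gamma_m6A=rates.gamma_A, S=1.0)
    raise ParameterError(f"unknown variant {variant.name!r}")


# ---------------------------------------------------------------------------
# vectorised primitives
# ---------------------------------------------------------------------------


def steady_state_pools(
    alpha_A: ArrayLike,
    alpha_m6A: ArrayLike,
    beta_A: ArrayLike,
    beta_m6A: ArrayLike,
    gamma_A: ArrayLike,
    gamma_m6A: ArrayLike,
    delta: ArrayLike = 0.0,
) -> dict[str, np.ndarray]:
    """Analytic steady state, vectorised over genes.

    Per species: ``nuc = alpha / (beta + delta)``, ``cyt = beta * nuc / gamma``.
    Raises :class:`NoSteadyStateError` if any gene has positive production
    with zero export and zero nuclear decay (the nucleus would accumulate
    without bound), and :class:`ParameterError` on zero cytoplasmic decay
    with a fed cytoplasm.
    """
    aA, aM = np.asarray(alpha_A, float), np.asarray(alpha_m6A, float)
    bA, bM = np.asarray(beta_A, float), np.asarray(beta_m6A, float)
    gA, gM = np.asarray(gamma_A, float), np.asarray(gamma_m6A, float)
    d = np.asarray(delta, float)
    arrs = np.broadcast_arrays(aA, aM, bA, bM, gA, gM, d)
    aA, aM, bA, bM, gA, gM, d = arrs
    for arr in arrs:
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ParameterError("rates must be finite and >= 0")

    out: dict[str, np.ndarray] = {}
    for key, (alpha, beta, gamma) in {
        "A": (aA, bA, gA),
        "m6A": (aM, bM, gM),
    }.items():
        b = beta + d
        if np.any((b == 0) & (alpha > 0)):
            raise NoSteadyStateError(
                "positive production with zero export and zero nuclear decay"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            nuc = np.where(b > 0, alpha / np.where(b > 0, b, 1.0), 0.0)
            influx = beta * nuc
            if np.any((gamma == 0) & (influx > 0)):
                raise NoSteadyStateError(
                    "zero cytoplasmic decay with nonzero export influx"
                )
            cyt = np.where(gamma > 0, influx / np.where(gamma > 0, gamma, 1.0), 0.0)
        out[f"nuc_{key}"] = nuc
        out[f"cyt_{key}"] = cyt
    return out


def index_table(
    nuc_A: ArrayLike,
    nuc_m6A: ArrayLike,
    cyt_A: ArrayLike,
    cyt_m6A: ArrayLike,
) -> dict[str, np.ndarray]:
    """The five derived indices, vectorised; undefined ratios come back NaN."""
    nA, nM = np.asarray(nuc_A, float), np.asarray(nuc_m6A, float)
    cA, cM = np.asarray(cyt_A, float), np.asarray(cyt_m6A, float)
    nuc = nA + nM
    cyt = cA + cM
    total = nuc + cyt
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "gene_level": total,
            "nuc_m6a_level": np.where(nuc > 0, nM / np.where(nuc > 0, nuc, 1.0), np.nan),
            "cyt_m6a_level": np.where(cyt > 0, cM / np.where(cyt > 0, cyt, 1.0), np.nan),
            "m6a_level": np.where(
                total > 0, (nM + cM) / np.where(total > 0, total, 1.0), np.nan
            ),
            "nuc_cyt_ratio": np.where(cyt > 0, nuc / np.where(cyt > 0, cyt, 1.0), np.nan),
        }


def species_course(
    alpha: ArrayLike,
    beta: ArrayLike,
    gamma: ArrayLike,
    delta: ArrayLike,
    nuc0: ArrayLike,
    cyt0: ArrayLike,
    times: ArrayLike,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form trajectory of one species on a time grid.

    Parameters broadcast against each other along a leading gene axis; the
    time grid is appended as the trailing axis of the returned arrays.
    With ``b = beta + delta``:

        Nuc(t) = Nss + (Nuc0 - Nss) e^{-b t}                 (b > 0)
        Cyt(t) = Css + B e^{-b t} + (Cyt0 - Css - B) e^{-g t},
                 B = beta (Nuc0 - Nss) / (gamma - b)

    switching to the ``t e^{-gamma t}`` limit expression when
    ``|gamma - b| < 1e-9 max(gamma, b)`` to avoid catastrophic cancellation.
    ``b == 0`` implies ``beta == delta == 0``: the nucleus then grows
    linearly (``alpha > 0``) or stays put, and the cytoplasm is decoupled.
    """
    t = np.asarray(times, float)
    if t.ndim != 1:
        raise ParameterError("time grid must be one-dimensional")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ParameterError("times must be finite and >= 0")
    a, be, g, d, n0, c0 = (
        np.atleast_1d(np.asarray(x, float))[:, None]
        for x in np.broadcast_arrays(alpha, beta, gamma, delta, nuc0, cyt0)
    )
    if np.any(n0 < 0) or np.any(c0 < 0) or np.any(~np.isfinite(n0)) or np.any(~np.isfinite(c0)):
        raise ParameterError("initial pools must be finite and >= 0")
    b = be + d
    tt = t[None, :]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        nss = np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)
        eb = np.exp(-b * tt)
        nuc = np.where(b > 0, nss + (n0 - nss) * eb, n0 + a * tt)

        if np.any((g == 0) & ((be * n0 > 0) | (be * a > 0))):
            raise ParameterError("gamma must be > 0 for a species with export influx")
        g_safe = np.where(g > 0, g, 1.0)
        css = be * nss / g_safe
        eg = np.exp(-g * tt)

        degen = np.abs(g - b) < _DEGENERACY_RTOL * np.maximum(g, b)
        diff = np.where(degen, 1.0, g - b)
        B = be * (n0 - nss) / diff
        cyt_generic = css + B * eb + (c0 - css - B) * eg
        cyt_degen = css + (c0 - css) * eg + be * (n0 - nss) * tt * eg
        cyt = np.where(degen, cyt_degen, cyt_generic)
        cyt = np.where(g > 0, cyt, c0)  # g==0 admissible only with zero influx

    # linear dynamics with non-negative coefficients cannot go negative;
    # clip the epsilon-scale undershoot of the float evaluation
    nuc, cyt = np.maximum(nuc, 0.0), np.maximum(cyt, 0.0)
    # t = 0 must reproduce the initial condition bit-exactly
    at0 = tt[0] == 0.0
    if np.any(at0):
        nuc[:, at0] = n0
        cyt[:, at0] = c0
    return nuc, cyt


# ---------------------------------------------------------------------------
# scalar object API
# ---------------------------------------------------------------------------


def steady_state(rates: RateSet) -> CompartmentState:
    """Analytic steady state of the two-species system."""
    pools = steady_state_pools(
        rates.alpha_A,
        rates.alpha_m6A,
        rates.beta_A,
        rates.beta_m6A,
        rates.gamma_A,
        rates.gamma_m6A,
        rates.delta,
    )
    return CompartmentState(
        nuc_A=float(pools["nuc_A"]),
        nuc_m6A=float(pools["nuc_m6A"]),
        cyt_A=float(pools["cyt_A"]),
        cyt_m6A=float(pools["cyt_m6A"]),
    )


def derive_indices(state: CompartmentState) -> DerivedIndices:
    """Compute the five read-outs of a state; empty-denominator ratios are None."""
    if state.total == 0:
        raise DegenerateStateError("all four pools are zero")
    t = index_table(state.nuc_A, state.nuc_m6A, state.cyt_A, state.cyt_m6A)

    def _opt(x: np.ndarray) -> float | None:
        v = float(x)
        return None if np.isnan(v) else v

    return DerivedIndices(
        gene_level=float(t["gene_level"]),
        nuc_m6a_level=_opt(t["nuc_m6a_level"]),
        cyt_m6a_level=_opt(t["cyt_m6a_level"]),
        m6a_level=float(t["m6a_level"]),
        nuc_cyt_ratio=_opt(t["nuc_cyt_ratio"]),
    )


@dataclass(frozen=True)
class TimeCourse:
    """Trajectory of the four pools on a time grid.

    ``rates_before`` / ``rates_after`` record the rate sets around a
    perturbation at t=0 where applicable (``rates_before`` is None for a
    plain simulation from an arbitrary initial condition).
    """

    times: np.ndarray
    nuc_A: np.ndarray
    nuc_m6A: np.ndarray
    cyt_A: np.ndarray
    cyt_m6A: np.ndarray
    rates_after: RateSet
    rates_before: RateSet | None = None

    def state(self, i: int) -> CompartmentState:
        return CompartmentState(
            nuc_A=float(self.nuc_A[i]),
            nuc_m6A=float(self.nuc_m6A[i]),
            cyt_A=float(self.cyt_A[i]),
            cyt_m6A=float(self.cyt_m6A[i]),
        )

    def to_frame(self, derived: bool = True):
        """Tidy table: time, the four pools and (optionally) the indices."""
        import pandas as pd

        data = {
            "time": self.times,
            "nuc_A": self.nuc_A,
            "nuc_m6A": self.nuc_m6A,
            "cyt_A": self.cyt_A,
            "cyt_m6A": self.cyt_m6A,
        }
        if derived:
            data.update(index_table(self.nuc_A, self.nuc_m6A, self.cyt_A, self.cyt_m6A))
        return pd.DataFrame(data)

    def to_tsv(self, path, derived: bool = True) -> None:
        self.to_frame(derived=derived).to_csv(path, sep="\t", index=False)


def simulate_dynamics(
    rates: RateSet,
    initial: CompartmentState,
    times: Sequence[float] | np.ndarray,
    method: str = "closed_form",
) -> TimeCourse:
    """Integrate the linear system from ``initial`` over a strictly increasing grid.

    ``method="closed_form"`` evaluates the exact two-exponential solution;
    ``method="numeric"`` uses an adaptive LSODA integrator as an independent
    route (the two agree to tight tolerance and are cross-checked in the
    test suite).
    """
    t = np.asarray(times, float)
    if t.ndim != 1 or len(t) == 0:
        raise ParameterError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time grid must be strictly increasing")
    if np.any(t < 0):
        raise ParameterError("negative time")

    if method == "closed_form":
        nA, cA = species_course(
            rates.alpha_A, rates.beta_A, rates.gamma_A, rates.delta,
            initial.nuc_A, initial.cyt_A, t,
        )
        nM, cM = species_course(
            rates.alpha_m6A, rates.beta_m6A, rates.gamma_m6A, rates.delta,
            initial.nuc_m6A, initial.cyt_m6A, t,
        )
        return TimeCourse(
            times=t, nuc_A=nA[0], nuc_m6A=nM[0], cyt_A=cA[0], cyt_m6A=cM[0],
            rates_after=rates,
        )
    if method == "numeric":
        from scipy.integrate import solve_ivp

        r = rates

        def rhs(_t: float, y: np.ndarray) -> list[float]:
            nA, nM, cA, cM = y
            return [
                r.alpha_A - (r.beta_A + r.delta) * nA,
                r.alpha_m6A - (r.beta_m6A + r.delta) * nM,
                r.beta_A * nA - r.gamma_A * cA,
                r.beta_m6A * nM - r.gamma_m6A * cM,
            ]

        t_eval = t
        t0 = 0.0 if t[0] > 0 else t[0]
        sol = solve_ivp(
            rhs,
            (t0, t[-1] if t[-1] > t0 else t0 + 1e-12),
            initial.as_array(),
            t_eval=t_eval,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = np.maximum(sol.y, 0.0)
        return TimeCourse(
            times=t, nuc_A=y[0], nuc_m6A=y[1], cyt_A=y[2], cyt_m6A=y[3],
            rates_after=rates,
        )
    raise ParameterError(f"unknown method {method!r}")
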