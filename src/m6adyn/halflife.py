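"""Half-life estimation from transcription-shutoff time courses.

After transcription shutoff (production set to zero, the actinomycin-D
design) total transcript abundance decays and the decay rate ``k`` is the
slope of a least-squares fit of log abundance against time.  Only negative
slopes with a two-sided p-value below 0.05 are accepted; the half-life is
then ``HL = ln(2) / (-k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetic import ParameterError, species_course

__all__ = [
    "HalfLifeFit",
    "InsufficientDataError",
    "fit_half_life",
    "cohort_half_lives",
    "default_decay_grid",
]

P_THRESHOLD = 0.05
# relative residual scale below which a fit counts as exact (p := 0)
_EXACT_RTOL = 1e-12


class InsufficientDataError(ValueError):
    """Fewer than three usable timepoints."""


@dataclass(frozen=True)
class HalfLifeFit:
    """Result of one log-linear decay fit.

    ``k`` is the slope on the natural-log scale (per unit time);
    ``half_life`` is reported only when the fit passes the filter
    (negative slope, p < 0.05) and is ``None`` otherwise.
    """

    k: float
    p_value: float
    half_life: float | None
    passed: bool
    n_points: int


def _slope_pvalues(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slope of y on t and its two-sided t-test p-value.

    ``t`` and ``y`` are (G, T); an exact fit (residuals at float noise
    level relative to the signal) is assigned p = 0 so that ideal
    simulated decay passes the significance filter.
    """
    n = t.shape[1]
    tbar = t.mean(axis=1, keepdims=True)
    ybar = y.mean(axis=1, keepdims=True)
    tc = t - tbar
    yc = y - ybar
    sxx = np.sum(tc * tc, axis=1)
    slope = np.sum(tc * yc, axis=1) / sxx
    resid = yc - slope[:, None] * tc
    sse = np.sum(resid * resid, axis=1)
    syy = np.sum(yc * yc, axis=1)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        tstat = np.abs(slope) / se
        p = 2.0 * stats.t.sf(tstat, dof)
    exact = sse <= _EXACT_RTOL * np.maximum(syy, 1.0)
    p = np.where(exact, 0.0, p)
    return slope, p


def fit_half_life(
    abundance: Sequence[float],
    times: Sequence[float],
    log_base: float = np.e,
) -> HalfLifeFit:
    """Fit log abundance against time; apply the slope-sign / p-value filter.

    The user-facing ``log_base`` only changes the scale on which the
    regression is run; the slope is converted back to the natural-log
    scale before computing ``HL = ln(2) / (-k)``.
    """
    a = np.asarray(abundance, float)
    t = np.asarray(times, float)
    if len(a) != len(t):
        raise ParameterError("abundance and times must have equal length")
    if len(a) < 3:
        raise InsufficientDataError(f"need >= 3 timepoints, got {len(a)}")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ParameterError("abundances must be finite and > 0 for log fitting")
    if log_base <= 0 or log_base == 1:
        raise ParameterError("log base must be positive and != 1")
    y = np.log(a) / np.log(log_base)
    slope, p = _slope_pvalues(t[None, :], y[None, :])
    k = float(slope[0]) * np.log(log_base)  # back to natural-log scale
    p_value = float(p[0])
    passed = (k < 0) and (p_value < P_THRESHOLD)
    return HalfLifeFit(
        k=k,
        p_value=p_value,
        half_life=float(np.log(2) / -k) if passed else None,
        passed=passed,
        n_points=len(a),
    )


def default_decay_grid(gamma_A: np.ndarray) -> np.ndarray:
    """Per-gene sampling grid t = {0, 1, 2, 4, 8} * (ln 2 / gamma_A).

    Mimics a transcription-shutoff course with timepoints scaled to each
    gene's unmethylated cytoplasmic half-life, so fast and slow genes are
    equally well resolved.  Shape (G, 5).
    """
    gamma_A = np.asarray(gamma_A, float)
    if np.any(gamma_A <= 0):
        raise ParameterError("gamma_A must be > 0 to scale the decay grid")
    unit = np.log(2) / gamma_A
    return unit[:, None] * np.array([0.0, 1.0, 2.0, 4.0, 8.0])[None, :]


def _total_abundance_course(rates: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Total (nuc+cyt, both species) abundance after shutoff, per gene.

    ``times`` is either a shared 1-D grid or a per-gene (G, T) grid.
    The course starts from the pre-shutoff steady state.
    """
    from .kinetic import steady_state_pools

    arrays = {k: rates[k].to_numpy() for k in rates.columns}
    pools = steady_state_pools(
        arrays["alpha_A"], arrays["alpha_m6A"],
        arrays["beta_A"], arrays["beta_m6A"],
        arrays["gamma_A"], arrays["gamma_m6A"], arrays["delta"],
    )
    times = np.asarray(times, float)
    if times.ndim == 1:
        nA, cA = species_course(
            0.0, arrays["beta_A"], arrays["gamma_A"], arrays["delta"],
            pools["nuc_A"], pools["cyt_A"], times,
        )
        nM, cM = species_course(
            0.0, arrays["beta_m6A"], arrays["gamma_m6A"], arrays["delta"],
            pools["nuc_m6A"], pools["cyt_m6A"], times,
        )
        return nA + cA + nM + cM
    # per-gene grids: evaluate gene-by-gene on its own 1-D grid
    total = np.empty_like(times)
    for i in range(times.shape[0]):
        nA, cA = species_course(
            0.0, arrays["beta_A"][i], arrays["gamma_A"][i], arrays["delta"][i],
            pools["nuc_A"][i], pools["cyt_A"][i], times[i],
        )
        nM, cM = species_course(
            0.0, arrays["beta_m6A"][i], arrays["gamma_m6A"][i], arrays["delta"][i],
            pools["nuc_m6A"][i], pools["cyt_m6A"][i], times[i],
        )
        total[i] = (nA + cA + nM + cM)[0]
    return total


def cohort_half_lives(
    cohort,
    times: np.ndarray | None = None,
    condition: str = "wt",
) -> pd.DataFrame:
    """Half-life fits for every gene of a cohort under shutoff.

    The model-generated course is total abundance (both compartments, both
    species) after setting production to zero, starting from the condition's
    steady state; ``condition="ko"`` first removes selective decay
    (``gamma_m6A = gamma_A``).  Default timepoints follow
    :func:`default_decay_grid`.  Genes whose fit fails the filter get
    ``half_life`` NaN with ``passed`` False.
    """
    from .cohort import _apply_variant_table
    from .kinetic import ModelVariant

    if condition not in {"wt", "ko"}:
        raise ParameterError(f"condition must be 'wt' or 'ko', got {condition!r}")
    rates = cohort.rates
    if condition == "ko":
        rates = _apply_variant_table(rates, ModelVariant("ko"), cohort.S)
    if times is None:
        times = default_decay_grid(rates["gamma_A"].to_numpy())
    times = np.asarray(times, float)
    total = _total_abundance_course(rates, times)
    t2 = times if times.ndim == 2 else np.broadcast_to(times, total.shape)

    ok = np.all(total > 0, axis=1)
    slope = np.full(len(rates), np.nan)
    p = np.full(len(rates), np.nan)
    if ok.any():
        with np.errstate(divide="ignore"):
            y = np.log(total[ok])
        slope[ok], p[ok] = _slope_pvalues(np.asarray(t2[ok], float), y)
    passed = ok & (slope < 0) & (p < P_THRESHOLD)
    hl = np.where(passed, np.log(2) / -slope, np.nan)
    return pd.DataFrame(
        {"k": slope, "p_value": p, "half_life": hl, "passed": passed},
        index=cohort.gene_ids,
    )
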