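"""Named perturbation scenarios and their trajectory read-outs.

A perturbation is an instantaneous rate change applied at t = 0 to a
cohort sitting at its pre-perturbation steady state.  The frozen presets
map one-to-one onto the classic experimental designs:

``actd``          transcription shutoff (actinomycin D): alpha := 0
``cpt``           reduced production (camptothecin): alpha := 0.1 * alpha
``ythdf_ko``      loss of m6A-dependent decay: gamma_m6A := gamma_A
``export_block``  global export reduction: beta := 0.1 * beta
``hs_induction``  transcriptional induction (heat-shock-like): alpha := 10 * alpha

Production and export targets apply to both species jointly unless a
species-specific target (``alpha_A`` / ``alpha_m6A``) is named.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GeneCohort, cohort_steady_state
from .halflife import cohort_half_lives
from .kinetic import ParameterError, index_table, species_course

__all__ = [
    "Perturbation",
    "PRESETS",
    "TrajectoryTable",
    "apply_perturbation",
    "run_perturbation_course",
    "decay_ordering",
    "ko_comparison",
    "default_time_grid",
]

TARGETS = frozenset({"alpha", "alpha_A", "alpha_m6A", "beta", "gamma_m6A"})
MODES = frozenset({"set", "scale", "match_A"})


@dataclass(frozen=True)
class Perturbation:
    """An instantaneous rate change.

    ``mode="set"`` assigns ``value``; ``mode="scale"`` multiplies by it;
    ``mode="match_A"`` copies the A-species rate onto the m6A species
    (only meaningful for ``target="gamma_m6A"``, the writer/reader
    knockout).  ``applied_at`` records when the switch happens (courses
    start at that instant).
    """

    target: str
    mode: str
    value: float | None = None
    applied_at: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ParameterError(f"unknown target {self.target!r}")
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode == "match_A":
            if self.target != "gamma_m6A":
                raise ParameterError("match_A mode only applies to gamma_m6A")
        elif self.value is None or not np.isfinite(self.value) or self.value < 0:
            raise ParameterError("value must be finite and >= 0")


PRESETS: dict[str, Perturbation] = {
    "actd": Perturbation("alpha", "set", 0.0),
    "cpt": Perturbation("alpha", "scale", 0.1),
    "ythdf_ko": Perturbation("gamma_m6A", "match_A"),
    "export_block": Perturbation("beta", "scale", 0.1),
    "hs_induction": Perturbation("alpha", "scale", 10.0),
}

_TARGET_COLUMNS = {
    "alpha": ["alpha_A", "alpha_m6A"],
    "alpha_A": ["alpha_A"],
    "alpha_m6A": ["alpha_m6A"],
    "beta": ["beta_A", "beta_m6A"],
    "gamma_m6A": ["gamma_m6A"],
}


def apply_perturbation(
    rates: pd.DataFrame, perturbation: Perturbation | str
) -> pd.DataFrame:
    """Transformed copy of a cohort rate table; the input is unchanged."""
    if isinstance(perturbation, str):
        perturbation = PRESETS[perturbation]
    out = rates.copy()
    cols = _TARGET_COLUMNS[perturbation.target]
    if perturbation.mode == "set":
        out[cols] = perturbation.value
    elif perturbation.mode == "scale":
        out[cols] = out[cols] * perturbation.value
    else:  # match_A
        out["gamma_m6A"] = out["gamma_A"]
    return out


def default_time_grid(rates: pd.DataFrame, n_points: int = 40) -> np.ndarray:
    """Dense logarithmic grid on [0, 10 / min(positive post-perturbation rates)].

    Log spacing resolves the fast early transient while the upper end
    reaches the slowest gene's new steady state.
    """
    vals = rates.to_numpy(float)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ParameterError("no positive rate to scale the time grid")
    t_max = 10.0 / pos.min()
    grid = np.geomspace(t_max / 1000.0, t_max, n_points - 1)
    return np.concatenate([[0.0], grid])


@dataclass
class TrajectoryTable:
    """Per-gene index trajectories on a shared time grid.

    ``table`` is tidy: gene_id, time, the four pools, gene_level,
    m6a_level, nuc_cyt_ratio.  ``normalized`` flags whether values were
    divided by their t=0 value.
    """

    table: pd.DataFrame
    rates_before: pd.DataFrame
    rates_after: pd.DataFrame
    normalized: bool = False
    steady_state_flag: bool = True  # False if post-perturbation SS does not exist

    def pivot(self, column: str = "m6a_level") -> pd.DataFrame:
        """Wide genes x times matrix of one column."""
        return self.table.pivot(index="gene_id", columns="time", values=column)

    def t0_normalized(self, column: str = "m6a_level") -> pd.DataFrame:
        """Trajectories divided by their value at t = 0 (start at 1)."""
        wide = self.pivot(column)
        return wide.div(wide.iloc[:, 0], axis=0)

    def row_zscored(self, column: str = "m6a_level") -> pd.DataFrame:
        """Per-gene z-score across timepoints (heatmap row scaling)."""
        wide = self.pivot(column)
        mu = wide.mean(axis=1)
        sd = wide.std(axis=1, ddof=0)
        return wide.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_perturbation_course(
    cohort: GeneCohort,
    perturbation: Perturbation | str,
    times: Sequence[float] | np.ndarray | None = None,
) -> TrajectoryTable:
    """Simulate every gene from its steady state under the perturbed rates.

    The t = 0 row equals the pre-perturbation steady state exactly.  If the
    perturbed rates admit no finite steady state (e.g. zero export with
    positive production) the transient is still computed and the result is
    flagged via ``steady_state_flag=False``.
    """
    before = cohort.rates
    after = apply_perturbation(before, perturbation)
    if times is None:
        times = default_time_grid(after)
    t = np.asarray(times, float)
    if t.ndim != 1 or t[0] != 0:
        raise ParameterError("time grid must be 1-D and start at 0")

    ss = cohort_steady_state(cohort)
    a = {k: after[k].to_numpy() for k in after.columns}
    nA, cA = species_course(
        a["alpha_A"], a["beta_A"], a["gamma_A"], a["delta"],
        ss["nuc_A"].to_numpy(), ss["cyt_A"].to_numpy(), t,
    )
    nM, cM = species_course(
        a["alpha_m6A"], a["beta_m6A"], a["gamma_m6A"], a["delta"],
        ss["nuc_m6A"].to_numpy(), ss["cyt_m6A"].to_numpy(), t,
    )
    G, T = nA.shape
    idx = index_table(nA, nM, cA, cM)
    table = pd.DataFrame(
        {
            "gene_id": np.repeat(cohort.gene_ids.to_numpy(), T),
            "time": np.tile(t, G),
            "nuc_A": nA.ravel(),
            "nuc_m6A": nM.ravel(),
            "cyt_A": cA.ravel(),
            "cyt_m6A": cM.ravel(),
            "gene_level": idx["gene_level"].ravel(),
            "m6a_gene_level": (nM + cM).ravel(),
            "m6a_level": idx["m6a_level"].ravel(),
            "nuc_cyt_ratio": idx["nuc_cyt_ratio"].ravel(),
        }
    )
    # flagged (not fatal): no finite steady state after the switch
    beta_plus_delta = a["beta_A"] + a["delta"], a["beta_m6A"] + a["delta"]
    no_ss = bool(
        np.any((beta_plus_delta[0] == 0) & (a["alpha_A"] > 0))
        or np.any((beta_plus_delta[1] == 0) & (a["alpha_m6A"] > 0))
    )
    return TrajectoryTable(
        table=table,
        rates_before=before,
        rates_after=after,
        steady_state_flag=not no_ss,
    )


def decay_ordering(
    cohort: GeneCohort,
    times: Sequence[float] | np.ndarray | None = None,
    column: str = "m6a_gene_level",
) -> pd.DataFrame:
    """Normalized m6A trajectories after transcription shutoff.

    Returns a wide genes x times matrix of ``column(t) / column(0)``.  The
    default column is the methylated-species abundance (``nuc_m6A +
    cyt_m6A``): among genes differing only in their decay rates, that
    quantity declines faster for larger ``gamma_A`` at every timepoint.
    (The whole-cell methylated *fraction*, ``column="m6a_level"``, orders
    the other way in that construction: a fast-turnover gene keeps most of
    its transcripts in the nucleus where the methylated fraction is
    pinned, so its fraction decays the least.)
    """
    course = run_perturbation_course(cohort, "actd", times=times)
    return course.t0_normalized(column)


def ko_comparison(cohort: GeneCohort, times: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene contrast of the baseline cohort with its writer-knockout.

    KO removes selective decay of the methylated species.  Columns:
    steady-state ``m6a_level`` (WT), ``nuc_cyt_wt`` / ``nuc_cyt_ko``,
    ``delta_nuc_cyt = log(nuc_cyt_wt) - log(nuc_cyt_ko)``, both
    fitted half-lives and ``hl_ratio = HL_KO / HL_WT``.  Failed half-life
    fits propagate as NaN.
    """
    from .cohort import _apply_variant_table
    from .kinetic import ModelVariant

    wt = cohort_steady_state(cohort)
    ko_rates = _apply_variant_table(cohort.rates, ModelVariant("ko"), cohort.S)
    ko_cohort = cohort.with_rates(ko_rates, ModelVariant("ko"))
    ko = cohort_steady_state(ko_cohort)

    hl_wt = cohort_half_lives(cohort, times=times, condition="wt")
    hl_ko = cohort_half_lives(cohort, times=times, condition="ko")
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_nc = np.log(wt["nuc_cyt_ratio"]) - np.log(ko["nuc_cyt_ratio"])
        ratio = hl_ko["half_life"] / hl_wt["half_life"]
    return pd.DataFrame(
        {
            "m6a_level": wt["m6a_level"],
            "nuc_cyt_wt": wt["nuc_cyt_ratio"],
            "nuc_cyt_ko": ko["nuc_cyt_ratio"],
            "delta_nuc_cyt": delta_nc,
            "hl_wt": hl_wt["half_life"],
            "hl_ko": hl_ko["half_life"],
            "hl_ratio": ratio,
        },
        index=cohort.gene_ids,
    )
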