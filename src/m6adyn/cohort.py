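"""Gene cohorts with gamma-distributed kinetic rates.

A cohort is a population of simulated genes whose production, export, and
decay rates are drawn independently from a gamma distribution (default
shape 1, rate 1), with the methylated species tied to the unmethylated one
by the active model variant (baseline: shared export, ``gamma_m6A = S *
gamma_A`` with S = 10).  The module also provides the binned / correlation
summaries used to describe population steady states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetic import (
    ModelVariant,
    ParameterError,
    RATE_FIELDS,
    index_table,
    steady_state_pools,
)

__all__ = [
    "GeneCohort",
    "BinnedSummary",
    "sample_rates",
    "cohort_steady_state",
    "bin_and_summarize",
    "grid_heatmap",
    "association",
    "quantile_bins",
]

POOL_FIELDS = ("nuc_A", "nuc_m6A", "cyt_A", "cyt_m6A")
INDEX_FIELDS = ("gene_level", "nuc_m6a_level", "cyt_m6a_level", "m6a_level", "nuc_cyt_ratio")


@dataclass
class GeneCohort:
    """Per-gene rate sets (one row per gene) plus optional cached states."""

    rates: pd.DataFrame  # columns RATE_FIELDS, index = gene ids
    variant: ModelVariant
    seed: int | None = None
    S: float = 10.0
    states: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(RATE_FIELDS) - set(self.rates.columns)
        if missing:
            raise ParameterError(f"rates table missing columns {sorted(missing)}")
        if self.rates.index.has_duplicates:
            raise ParameterError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.rates)

    @property
    def gene_ids(self) -> pd.Index:
        return self.rates.index

    def rate_arrays(self) -> dict[str, np.ndarray]:
        return {k: self.rates[k].to_numpy() for k in RATE_FIELDS}

    def with_rates(self, rates: pd.DataFrame, variant: ModelVariant | None = None) -> "GeneCohort":
        """Copy of the cohort with a transformed rate table (states dropped)."""
        return GeneCohort(
            rates=rates, variant=variant or self.variant, seed=self.seed, S=self.S
        )

    def to_frame(self) -> pd.DataFrame:
        """Rates joined with pools and indices (computing them if needed)."""
        return self.rates.join(cohort_steady_state(self))

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def _apply_variant_table(rates: pd.DataFrame, variant: ModelVariant, S: float) -> pd.DataFrame:
    """Vectorised analogue of :func:`m6adyn.kinetic.apply_variant`."""
    out = rates.copy()
    p = dict(variant.params)
    if variant.name == "baseline":
        s = float(p.get("S", S))
        out["beta_m6A"] = out["beta_A"]
        out["gamma_m6A"] = s * out["gamma_A"]
        out["delta"] = 0.0
    elif variant.name == "nuclear_decay":
        out["delta"] = float(p.get("delta", 1.0))
    elif variant.name == "export_facilitated":
        out["beta_m6A"] = float(p.get("factor", 10.0)) * out["beta_A"]
        out["gamma_m6A"] = out["gamma_A"]
    elif variant.name == "export_inhibited":
        out["beta_m6A"] = float(p.get("factor", 0.1)) * out["beta_A"]
        out["gamma_m6A"] = out["gamma_A"]
    elif variant.name == "ko":
        out["gamma_m6A"] = out["gamma_A"]
    else:  # pragma: no cover - guarded by ModelVariant
        raise ParameterError(f"unknown variant {variant.name!r}")
    return out


def sample_rates(
    n: int,
    shape: float = 1.0,
    rate: float = 1.0,
    S: float = 10.0,
    variant: ModelVariant | str = "baseline",
    seed: int | None = None,
) -> GeneCohort:
    """Draw a cohort of ``n`` genes with gamma-distributed rates.

    ``alpha_A``, ``alpha_m6A``, ``beta`` and ``gamma_A`` are sampled
    independently from Gamma(shape, rate); ``beta_m6A`` and ``gamma_m6A``
    are then fixed by the variant (default: ``beta_m6A = beta_A``,
    ``gamma_m6A = S * gamma_A``).  Fully reproducible under a fixed seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if shape <= 0 or rate <= 0:
        raise ParameterError("gamma shape and rate must be > 0")
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    rng = np.random.default_rng(seed)
    scale = 1.0 / rate
    base = pd.DataFrame(
        {
            "alpha_A": rng.gamma(shape, scale, n),
            "alpha_m6A": rng.gamma(shape, scale, n),
            "beta_A": rng.gamma(shape, scale, n),
            "gamma_A": rng.gamma(shape, scale, n),
        },
        index=pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id"),
    )
    base["beta_m6A"] = base["beta_A"]
    base["gamma_m6A"] = S * base["gamma_A"]
    base["delta"] = 0.0
    rates = _apply_variant_table(base, variant, S)[list(RATE_FIELDS)]
    return GeneCohort(rates=rates, variant=variant, seed=seed, S=S)


def cohort_steady_state(cohort: GeneCohort) -> pd.DataFrame:
    """Steady-state pools and derived indices, one row per gene (cached)."""
    if cohort.states is not None:
        return cohort.states
    pools = steady_state_pools(**cohort.rate_arrays())
    table = {**pools, **index_table(**pools)}
    df = pd.DataFrame(table, index=cohort.gene_ids)
    cohort.states = df
    return df


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedSummary:
    """Per-bin statistic over quantile bins of near-equal count."""

    bin_labels: np.ndarray  # per-observation bin index (0-based)
    statistic: pd.Series  # per-bin statistic, indexed by bin
    counts: pd.Series
    edges: pd.DataFrame  # per-bin min/max of the binning variable
    by_name: str = "by"

    def to_frame(self) -> pd.DataFrame:
        out = self.edges.copy()
        out["count"] = self.counts
        out["statistic"] = self.statistic
        return out


def quantile_bins(by: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count quantile bin index per observation.

    Observations are ranked with a stable sort (ties broken by input
    order) and split so that bin counts differ by at most one; the result
    is deterministic for any input.
    """
    by = np.asarray(by)
    n = len(by)
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if n < n_bins:
        raise ParameterError(f"cannot form {n_bins} bins from {n} observations")
    order = np.argsort(by, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


_STATS: dict[str, Callable[[np.ndarray], float]] = {
    "median": np.median,
    "mean": np.mean,
}


def _stat_fn(statistic: str | Callable) -> Callable[[np.ndarray], float]:
    if callable(statistic):
        return statistic
    try:
        return _STATS[statistic]
    except KeyError:
        raise ParameterError(f"unknown statistic {statistic!r}") from None


def bin_and_summarize(
    values: Sequence[float],
    by: Sequence[float],
    n_bins: int = 4,
    statistic: str | Callable = "median",
) -> BinnedSummary:
    """Quantile-bin ``by`` into near-equal bins, summarise ``values`` per bin."""
    values = np.asarray(values, float)
    by_arr = np.asarray(by, float)
    if len(values) != len(by_arr):
        raise ParameterError("values and by must have equal length")
    labels = quantile_bins(by_arr, n_bins)
    fn = _stat_fn(statistic)
    idx = pd.RangeIndex(n_bins, name="bin")
    stat = pd.Series(
        [fn(values[labels == b]) for b in range(n_bins)], index=idx, name="statistic"
    )
    counts = pd.Series(
        [int(np.sum(labels == b)) for b in range(n_bins)], index=idx, name="count"
    )
    edges = pd.DataFrame(
        {
            "lo": [by_arr[labels == b].min() for b in range(n_bins)],
            "hi": [by_arr[labels == b].max() for b in range(n_bins)],
        },
        index=idx,
    )
    return BinnedSummary(bin_labels=labels, statistic=stat, counts=counts, edges=edges)


def grid_heatmap(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    n_bins_x: int = 5,
    n_bins_y: int = 5,
    statistic: str | Callable = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-axis quantile binning; returns (statistic, count) grids.

    Rows are y-bins, columns x-bins; a cell with no observations is NaN in
    the statistic grid and 0 in the count grid.
    """
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ParameterError("x, y, z must have equal length")
    bx = quantile_bins(x, n_bins_x)
    by = quantile_bins(y, n_bins_y)
    fn = _stat_fn(statistic)
    stat = np.full((n_bins_y, n_bins_x), np.nan)
    cnt = np.zeros((n_bins_y, n_bins_x), dtype=int)
    for j in range(n_bins_y):
        for i in range(n_bins_x):
            mask = (bx == i) & (by == j)
            cnt[j, i] = mask.sum()
            if cnt[j, i]:
                stat[j, i] = fn(z[mask])
    idx = pd.RangeIndex(n_bins_y, name="y_bin")
    cols = pd.RangeIndex(n_bins_x, name="x_bin")
    return pd.DataFrame(stat, index=idx, columns=cols), pd.DataFrame(cnt, index=idx, columns=cols)


def association(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    transform: str | None = None,
) -> dict[str, float]:
    """Correlation coefficient and R^2 between two paired vectors.

    ``transform="log"`` takes natural logs of both vectors first (ratios
    such as localization and half-life ratios are multiplicative, so the
    log scale is the natural one); non-finite pairs are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    if transform == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            x, y = np.log(x), np.log(y)
    elif transform is not None:
        raise ParameterError(f"unknown transform {transform!r}")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ParameterError("need >= 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in x or y")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ParameterError(f"unknown method {method!r}")
    return {"coefficient": float(r), "r_squared": float(r * r), "n": int(len(x))}
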