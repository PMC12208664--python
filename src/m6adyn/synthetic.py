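"""Count-level synthetic data with known ground truth.

Every generator turns a cohort's model-derived abundances into the count
tables the metrics layer consumes, adding negative-binomial counting noise
(shared dispersion across genes, ``size = 1/dispersion``; dispersion 0
collapses to Poisson).  Ground-truth columns are always emitted alongside
the counts so recovery experiments are self-contained, and every generator
is a pure function of (cohort, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GeneCohort, cohort_steady_state
from .kinetic import ParameterError, species_course
from .metrics import CountTable

__all__ = [
    "NoiseModel",
    "generate_fraction_counts",
    "generate_merip_counts",
    "generate_glori_sites",
    "generate_decay_counts",
]


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise parameters for the synthetic sequencing designs.

    ``depth`` — expected reads per library;
    ``dispersion`` — negative-binomial overdispersion (0 = Poisson);
    ``ip_background`` — fraction of unmethylated molecules captured in IP;
    ``seed`` — RNG seed making every generated table reproducible.
    """

    depth: float = 1_000_000.0
    dispersion: float = 0.1
    ip_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ParameterError("depth must be >= 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if not (0 <= self.ip_background < 1):
            raise ParameterError("ip_background must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, size=1/dispersion) counts; Poisson when dispersion is 0."""
    mean = np.asarray(mean, float)
    if np.any(mean < 0) or np.any(~np.isfinite(mean)):
        raise ParameterError("expected counts must be finite and >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _scaled_means(weights: np.ndarray, depth: float) -> np.ndarray:
    total = weights.sum()
    if total == 0 or depth == 0:
        return np.zeros_like(weights)
    return depth * weights / total


def generate_fraction_counts(
    cohort: GeneCohort, noise: NoiseModel
) -> tuple[CountTable, CountTable, pd.DataFrame]:
    """Nuclear and cytoplasmic RNA-seq count tables from steady states.

    The expected count of a gene in each fraction is proportional to its
    summed pool abundance there (both species).  Returns (nuclear,
    cytoplasmic, truth); truth carries the exact pools and indices.
    """
    ss = cohort_steady_state(cohort)
    rng = noise.rng()
    nuc_w = (ss["nuc_A"] + ss["nuc_m6A"]).to_numpy()
    cyt_w = (ss["cyt_A"] + ss["cyt_m6A"]).to_numpy()
    nuc = _nb_draw(rng, _scaled_means(nuc_w, noise.depth), noise.dispersion)
    cyt = _nb_draw(rng, _scaled_means(cyt_w, noise.depth), noise.dispersion)
    idx = cohort.gene_ids
    meta = pd.DataFrame({"fraction": ["nuclear"], "assay": ["rna"]}, index=["nuc_1"])
    meta_c = pd.DataFrame({"fraction": ["cytoplasmic"], "assay": ["rna"]}, index=["cyt_1"])
    return (
        CountTable(pd.DataFrame({"nuc_1": nuc}, index=idx), metadata=meta),
        CountTable(pd.DataFrame({"cyt_1": cyt}, index=idx), metadata=meta_c),
        ss.copy(),
    )


def generate_merip_counts(
    cohort: GeneCohort, noise: NoiseModel
) -> tuple[CountTable, CountTable, pd.DataFrame]:
    """IP and input count tables emulating an m6A-seq2 library pair.

    Capture is modeled per molecule: a methylated molecule is pulled down
    with efficiency 1, an unmethylated one with ``ip_background``, so a
    gene's expected IP count is ``depth * c_g * p_g`` where ``p_g`` is its
    share of total RNA and ``c_g = level_g + ip_background * (1 -
    level_g)``.  The IP library size is therefore the capture *yield* of
    the sample (a globally hypermethylated sample yields more), and both
    tables carry an explicit ``library_sizes`` equal to the nominal depth
    — the anchored normalization a spike-in provides in the real assay.
    Dividing the anchored-normalized IP by input makes the expected GI the
    per-gene capture efficiency ``c_g``, an affine function of the true
    m6A level.
    """
    ss = cohort_steady_state(cohort)
    rng = noise.rng()
    total = (ss["nuc_A"] + ss["nuc_m6A"] + ss["cyt_A"] + ss["cyt_m6A"]).to_numpy()
    meth = (ss["nuc_m6A"] + ss["cyt_m6A"]).to_numpy()
    unmeth = total - meth
    input_mean = _scaled_means(total, noise.depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        capture = np.where(total > 0, (meth + noise.ip_background * unmeth) / np.where(total > 0, total, 1.0), 0.0)
    ip_mean = capture * input_mean
    ip = _nb_draw(rng, ip_mean, noise.dispersion)
    inp = _nb_draw(rng, input_mean, noise.dispersion)
    idx = cohort.gene_ids
    meta_ip = pd.DataFrame({"fraction": ["whole"], "assay": ["ip"]}, index=["ip_1"])
    meta_in = pd.DataFrame({"fraction": ["whole"], "assay": ["input"]}, index=["input_1"])
    lib = pd.Series([noise.depth], dtype=float)
    return (
        CountTable(
            pd.DataFrame({"ip_1": ip}, index=idx),
            library_sizes=lib.set_axis(["ip_1"]),
            metadata=meta_ip,
        ),
        CountTable(
            pd.DataFrame({"input_1": inp}, index=idx),
            library_sizes=lib.set_axis(["input_1"]),
            metadata=meta_in,
        ),
        ss.copy(),
    )


def generate_glori_sites(
    cohort: GeneCohort,
    sites_per_gene: int = 3,
    coverage_law: tuple[str, float] = ("poisson", 50.0),
    noise: NoiseModel | None = None,
    decoys_per_gene: int = 1,
    background_rate: float = 0.01,
    adenosines_per_gene: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-level deamination-score table with planted ground truth.

    Each gene gets ``sites_per_gene`` DRACH sites whose unconverted counts
    are Binomial(coverage, true whole-cell m6A level), plus
    ``decoys_per_gene`` non-DRACH decoy sites scored at the conversion
    background.  ``coverage_law`` is ("poisson", mean) or ("fixed", value).
    Returns (site table, truth); the site table carries gene_id, site_id,
    coverage, score, in_drach and adenosine_count columns.
    """
    if sites_per_gene < 1:
        raise ParameterError("sites_per_gene must be >= 1")
    noise = noise or NoiseModel()
    law, par = coverage_law
    if law not in {"poisson", "fixed"} or par < 0:
        raise ParameterError(f"invalid coverage law {coverage_law!r}")
    rng = noise.rng()
    ss = cohort_steady_state(cohort)
    level = ss["m6a_level"].to_numpy()
    rows = []
    for gi, gene in enumerate(cohort.gene_ids):
        n_sites = sites_per_gene + decoys_per_gene
        if law == "poisson":
            cov = rng.poisson(par, n_sites)
        else:
            cov = np.full(n_sites, int(par))
        for s in range(n_sites):
            drach = s < sites_per_gene
            p = level[gi] if drach else background_rate
            unconv = rng.binomial(cov[s], p) if cov[s] > 0 else 0
            rows.append(
                {
                    "site_id": f"{gene}_s{s}",
                    "gene_id": gene,
                    "coverage": int(cov[s]),
                    "score": unconv / cov[s] if cov[s] > 0 else 0.0,
                    "in_drach": drach,
                    "adenosine_count": adenosines_per_gene,
                }
            )
    return pd.DataFrame(rows), ss.copy()


def generate_decay_counts(
    cohort: GeneCohort,
    times: np.ndarray,
    noise: NoiseModel,
) -> tuple[CountTable, pd.DataFrame]:
    """Transcription-shutoff time-course counts (actinomycin-D design).

    Expected counts follow each gene's total-abundance trajectory after
    setting production to zero, scaled so the t = 0 library has the
    nominal depth; later libraries shrink with global RNA loss (no
    cross-timepoint renormalization, matching how shutoff courses are
    usually fit).  Truth carries the exact abundances per timepoint.
    """
    t = np.asarray(times, float)
    if t.ndim != 1 or len(t) < 3:
        raise ParameterError("need a 1-D grid of >= 3 timepoints")
    ss = cohort_steady_state(cohort)
    r = cohort.rate_arrays()
    nA, cA = species_course(
        0.0, r["beta_A"], r["gamma_A"], r["delta"],
        ss["nuc_A"].to_numpy(), ss["cyt_A"].to_numpy(), t,
    )
    nM, cM = species_course(
        0.0, r["beta_m6A"], r["gamma_m6A"], r["delta"],
        ss["nuc_m6A"].to_numpy(), ss["cyt_m6A"].to_numpy(), t,
    )
    total = nA + cA + nM + cM  # (G, T)
    t0_sum = total[:, 0].sum()
    scale = noise.depth / t0_sum if t0_sum > 0 else 0.0
    rng = noise.rng()
    counts = _nb_draw(rng, scale * total, noise.dispersion)
    cols = [f"t{j}" for j in range(len(t))]
    meta = pd.DataFrame(
        {"fraction": "whole", "assay": "rna", "timepoint": t}, index=cols
    )
    truth = pd.DataFrame(total, index=cohort.gene_ids, columns=cols)
    return (
        CountTable(pd.DataFrame(counts, index=cohort.gene_ids, columns=cols), metadata=meta),
        truth,
    )
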