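"""Measurement-side gene indices computed from count tables.

This layer mirrors what a sequencing analysis would compute downstream of
alignment and quantification:

* **m6A-GI / m6A-SI** — gene-level and sample-level m6A indices from
  IP-vs-input enrichment (the m6A-seq2 read-out).  The GI of a gene is its
  normalized IP abundance divided by its normalized input abundance; the SI
  is the expression-weighted mean GI of a sample.
* **GLORI-GI** — per-gene aggregate of deamination-based site scores: the
  sum of scores of DRACH sites passing coverage/score filters, normalized
  by the gene's adenosine count.
* **Nuc:Cyt LFC** — log2 fold-change of TMM-normalized nuclear versus
  cytoplasmic counts.
* **PC1 loadings** — first principal component of a log2, per-gene scaled
  GI matrix, with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetic import ParameterError

__all__ = [
    "CountTable",
    "GeneIndexTable",
    "PCAResult",
    "m6a_gene_index",
    "m6a_sample_index",
    "glori_gene_index",
    "tmm_factors",
    "nuc_cyt_lfc",
    "pc1_loadings",
]

# default expression floor: a gene needs this many input reads in a sample
# to receive a GI there (mirrors the GLORI coverage floor)
MIN_INPUT_READS = 20


@dataclass
class CountTable:
    """Gene x sample matrix of non-negative integer counts.

    ``library_sizes`` defaults to the column sums.  ``metadata`` is an
    optional per-sample table (index = sample names) carrying e.g.
    fraction ∈ {nuclear, cytoplasmic, whole}, assay ∈ {ip, input, rna},
    timepoint, replicate.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be >= 0")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)
            if self.library_sizes.isna().any() or (self.library_sizes < 0).any():
                raise ParameterError("library sizes must cover all samples and be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None) -> "CountTable":
        """Read a wide gene x sample TSV, or a (gene_id, sample, count) triplet TSV."""
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:3]) == ["gene_id", "sample", "count"]:
            counts = df.pivot(index="gene_id", columns="sample", values="count").fillna(0)
        else:
            counts = df.set_index(df.columns[0])
        return cls(counts=counts, metadata=metadata)


@dataclass
class GeneIndexTable:
    """m6A-GI values per gene and sample, with optional SI and PC1 columns."""

    gi: pd.DataFrame
    si: pd.Series | None = None
    pc1: pd.Series | None = None

    def to_tsv(self, path) -> None:
        self.gi.rename_axis("gene_id").to_csv(path, sep="\t")


def _paired_columns(ip: CountTable, input: CountTable) -> list[tuple[str, str]]:
    if len(ip.samples) != len(input.samples):
        raise ParameterError(
            f"unpaired samples: {len(ip.samples)} IP vs {len(input.samples)} input"
        )
    return list(zip(ip.samples, input.samples))


def _effective_libsizes(table: CountTable, normalization: str) -> pd.Series:
    if normalization == "library_size":
        return table.library_sizes.copy()
    if normalization == "tmm":
        return table.library_sizes * tmm_factors(table.counts)
    raise ParameterError(f"unknown normalization {normalization!r}")


def m6a_gene_index(
    ip: CountTable,
    input: CountTable,
    normalization: str = "library_size",
    min_input: int = MIN_INPUT_READS,
) -> GeneIndexTable:
    """Gene-level m6A index: normalized IP over normalized input, per paired sample.

    IP and input samples are paired positionally (column i with column i);
    output columns take the IP sample names.  A gene with fewer than
    ``min_input`` input reads in a pair — or zero input with nonzero IP —
    is reported missing (NaN) for that pair.  With ``normalization="tmm"``
    the library sizes of each assay are first rescaled by TMM factors
    computed across that assay's samples.
    """
    genes = ip.genes
    if not genes.equals(input.genes):
        raise ParameterError("IP and input tables must share the same gene set/order")
    pairs = _paired_columns(ip, input)
    ip_lib = _effective_libsizes(ip, normalization)
    in_lib = _effective_libsizes(input, normalization)

    out = {}
    for ip_s, in_s in pairs:
        ip_norm = ip.counts[ip_s].to_numpy(float) / ip_lib[ip_s]
        in_norm = input.counts[in_s].to_numpy(float) / in_lib[in_s]
        with np.errstate(divide="ignore", invalid="ignore"):
            gi = np.where(in_norm > 0, ip_norm / np.where(in_norm > 0, in_norm, 1.0), np.nan)
        gi = np.where(input.counts[in_s].to_numpy() >= min_input, gi, np.nan)
        out[ip_s] = gi
    return GeneIndexTable(gi=pd.DataFrame(out, index=genes))


def m6a_sample_index(
    ip: CountTable,
    input: CountTable,
    normalization: str = "library_size",
    min_input: int = MIN_INPUT_READS,
) -> pd.Series:
    """Sample-level m6A index: expression-weighted mean of gene GIs.

    Weights are the normalized input abundances, so SI is linear in the
    GIs and equals 1 when every gene's GI is 1.
    """
    git = m6a_gene_index(ip, input, normalization=normalization, min_input=min_input)
    in_lib = _effective_libsizes(input, normalization)
    si = {}
    for (ip_s, in_s) in _paired_columns(ip, input):
        gi = git.gi[ip_s]
        w = input.counts[in_s].astype(float) / in_lib[in_s]
        ok = gi.notna() & (w > 0)
        if not ok.any():
            si[ip_s] = np.nan
            continue
        si[ip_s] = float(np.average(gi[ok], weights=w[ok]))
    return pd.Series(si, name="m6a_si")


def glori_gene_index(
    sites: pd.DataFrame,
    adenosine_counts: Mapping[str, float] | pd.Series | None = None,
    min_coverage: int = 20,
    min_score: float = 0.1,
) -> pd.Series:
    """Per-gene GLORI index from a site-level deamination-score table.

    ``sites`` needs columns gene_id, coverage, score, in_drach (and
    optionally adenosine_count, otherwise supplied separately).  A site
    contributes when it lies in a DRACH context, has coverage >= 20 and a
    score strictly greater than 0.1; the passing scores of a gene are
    summed and divided by the gene's total adenosine count.  A gene whose
    adenosine count is zero or absent is reported missing.
    """
    required = {"gene_id", "coverage", "score", "in_drach"}
    missing = required - set(sites.columns)
    if missing:
        raise ParameterError(f"site table missing columns {sorted(missing)}")
    if ((sites["score"] < 0) | (sites["score"] > 1)).any():
        raise ParameterError("scores must lie in [0, 1]")
    if adenosine_counts is None:
        if "adenosine_count" not in sites.columns:
            raise ParameterError("adenosine counts required (column or argument)")
        adenosine_counts = sites.groupby("gene_id")["adenosine_count"].first()
    a_counts = pd.Series(adenosine_counts, dtype=float)

    eligible = (
        sites["in_drach"].astype(bool)
        & (sites["coverage"] >= min_coverage)
        & (sites["score"] > min_score)
    )
    sums = sites.loc[eligible].groupby("gene_id")["score"].sum()
    genes = a_counts.index
    sums = sums.reindex(genes, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gi = sums / a_counts
    gi[~(a_counts > 0)] = np.nan
    return gi.rename("glori_gi")


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors across samples.

    For each sample against the reference, gene-wise log2 expression
    ratios (M) and mean log2 abundances (A) are computed over genes
    expressed in both; the upper and lower 30% of M and 5% of A are
    discarded and the factor is two to the precision-weighted mean of the
    remaining M values.  Factors multiply library sizes and are rescaled
    so their geometric mean is 1.  With ``reference=None`` the sample
    whose upper-quartile expression is closest to the mean upper quartile
    is used.
    """
    if counts.shape[1] < 2:
        raise ParameterError("TMM needs at least two samples")
    X = counts.to_numpy(float)
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        raise ParameterError("a sample has zero total counts")

    if reference is None:
        with np.errstate(invalid="ignore"):
            uq = np.array(
                [np.quantile(X[X[:, j] > 0, j] / lib[j], 0.75) for j in range(X.shape[1])]
            )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)

    r = X[:, ref_idx]
    Nr = lib[ref_idx]
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_idx:
            continue
        x = X[:, j]
        Nx = lib[j]
        ok = (x > 0) & (r > 0)
        if not ok.any():
            raise ParameterError(
                f"sample {counts.columns[j]!r} shares no expressed gene with the reference"
            )
        xs, rs = x[ok], r[ok]
        M = np.log2((xs / Nx) / (rs / Nr))
        A = 0.5 * np.log2((xs / Nx) * (rs / Nr))
        w = (Nx - xs) / (Nx * xs) + (Nr - rs) / (Nr * rs)
        n = len(M)
        loM = np.floor(n * logratio_trim) + 1
        loA = np.floor(n * abundance_trim) + 1
        # rank-based double trim, as in the standard implementation
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (rM >= loM) & (rM <= n + 1 - loM) & (rA >= loA) & (rA <= n + 1 - loA)
        if keep.any() and w[keep].sum() > 0:
            f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        else:
            f = 0.0
        factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def nuc_cyt_lfc(
    nuc: CountTable,
    cyt: CountTable,
    normalization: str = "tmm",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 ratio of normalized nuclear over cytoplasmic counts.

    Normalization (TMM by default, plain library size otherwise) is
    applied within each fraction across its samples; fractions are then
    paired positionally.  Counts are put on the counts-per-million scale
    and offset by ``pseudocount`` reads per (scaled) library before the
    log, so dropout genes stay finite.
    """
    if not nuc.genes.equals(cyt.genes):
        raise ParameterError("fraction tables must share the same gene set/order")
    pairs = _paired_columns(nuc, cyt)
    if normalization == "tmm" and (len(nuc.samples) < 2 or len(cyt.samples) < 2):
        normalization = "library_size"  # TMM undefined for a single sample
    n_lib = _effective_libsizes(nuc, normalization)
    c_lib = _effective_libsizes(cyt, normalization)
    out = {}
    for n_s, c_s in pairs:
        n_cpm = nuc.counts[n_s].to_numpy(float) / n_lib[n_s] * 1e6
        c_cpm = cyt.counts[c_s].to_numpy(float) / c_lib[c_s] * 1e6
        cn = pseudocount / n_lib[n_s] * 1e6
        cc = pseudocount / c_lib[c_s] * 1e6
        out[f"{n_s}_vs_{c_s}"] = np.log2(n_cpm + cn) - np.log2(c_cpm + cc)
    return pd.DataFrame(out, index=nuc.genes)


@dataclass(frozen=True)
class PCAResult:
    """PC1 of a gene x sample index matrix.

    ``loadings`` is the per-gene unit-norm vector along PC1;
    ``sample_profile`` is the corresponding per-sample direction;
    ``explained_variance_ratio`` is PC1's share of total variance.
    """

    loadings: pd.Series
    sample_profile: pd.Series
    explained_variance_ratio: float


def pc1_loadings(
    gi_matrix: pd.DataFrame,
    sample_order: Sequence[float] | None = None,
) -> PCAResult:
    """First principal component of the log2, per-gene scaled GI matrix.

    Only complete genes are admissible (the matrix must have no missing
    entries); each gene's log2 values are centred and scaled to unit
    variance, and the decomposition treats genes as observations.  The
    sign is fixed so the per-sample PC1 profile correlates positively
    with ``sample_order`` (defaults to column position), making the
    convention deterministic and stable under resampling that preserves
    the ordering.
    """
    if gi_matrix.isna().to_numpy().any():
        raise ParameterError("GI matrix must be complete (genes with a value everywhere)")
    if gi_matrix.shape[1] < 3:
        raise ParameterError("need at least 3 samples")
    if (gi_matrix.to_numpy() <= 0).any():
        raise ParameterError("GI values must be > 0 for the log2 transform")
    X = np.log2(gi_matrix.to_numpy(float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.all(sd == 0):
        raise ParameterError("matrix has zero variance; no principal component")
    keep = sd[:, 0] > 0
    Xs = (X[keep] - mu[keep]) / sd[keep]
    # SVD of the gene-scaled matrix: U[:,0] = per-gene direction,
    # V[0] = per-sample profile
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    evr = float(s[0] ** 2 / np.sum(s**2))
    load = np.zeros(len(gi_matrix))
    load[keep] = U[:, 0]
    profile = Vt[0]

    order = (
        np.arange(gi_matrix.shape[1], dtype=float)
        if sample_order is None
        else np.asarray(sample_order, float)
    )
    oc = order - order.mean()
    sign = np.sign(np.dot(profile, oc))
    if sign == 0:
        sign = np.sign(profile[np.argmax(np.abs(profile))]) or 1.0
    load *= sign
    profile = profile * sign
    return PCAResult(
        loadings=pd.Series(load, index=gi_matrix.index, name="pc1_loading"),
        sample_profile=pd.Series(profile, index=gi_matrix.columns, name="pc1_profile"),
        explained_variance_ratio=evr,
    )
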