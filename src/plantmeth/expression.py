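"""Expression quantification (FPKM) and a self-contained differential
expression stage.

FPKM = count * 10^9 / (transcript length * mapped-read total); per-tissue
FPKM is the mean over replicates.  Differential expression between two tissue
groups uses median-of-ratios size factors, gene-wise method-of-moments
negative-binomial dispersions shrunk 50/50 (in log space) toward a log-linear
mean-dispersion trend, and a Wald test on the log2 fold change of normalized
group means.  A gene is a DEG when |log2FC| >= log2(4) and BH-FDR q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8
_DISP_CAP = 10.0
_PSEUDOCOUNT = 0.5


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM per gene (rows) per sample (columns).

    ``library_sizes`` are the mapped-read totals per sample; when omitted the
    column sums of the count matrix are used (only appropriate when the matrix
    covers the whole transcriptome).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene length")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes < 1).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be >= 1 for every sample")
    denom = np.outer(lengths.to_numpy(dtype=float), library_sizes.to_numpy(dtype=float))
    return pd.DataFrame(
        counts.to_numpy(dtype=float) * 1e9 / denom,
        index=counts.index,
        columns=counts.columns,
    )


def fpkm_per_tissue(fpkm: pd.DataFrame, sample_tissue: pd.Series) -> pd.DataFrame:
    """Mean FPKM over each tissue's replicate columns."""
    groups = sample_tissue.reindex(fpkm.columns)
    if groups.isna().any():
        raise ValueError("sample sheet missing a sample")
    return fpkm.T.groupby(groups.to_numpy()).mean().T


def classify_expression(fpkm_tissue: pd.Series, threshold: float = 1.0) -> pd.Series:
    """Label genes expressed (FPKM >= threshold) or unexpressed."""
    return pd.Series(
        np.where(fpkm_tissue >= threshold, "expressed", "unexpressed"),
        index=fpkm_tissue.index,
        name="expression_class",
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed over genes with all-positive
    counts, relative to the per-gene geometric mean)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in all samples")
    log_arr = np.log(arr[positive])
    log_geo = log_arr.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_arr - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _dispersion_estimates(norm: np.ndarray, groups: list[np.ndarray],
                          inv_sf_mean: float) -> np.ndarray:
    """Gene-wise MoM dispersions shrunk 50/50 (log scale) toward a log-linear
    mean-dispersion trend.

    The trend is fitted to *signed* MoM bin means so that on Poisson-like data
    (where roughly half the gene-wise estimates are negative) it collapses to
    the floor and the Wald variance reduces to the Poisson term.
    """
    mu = norm.mean(axis=1)
    # pooled within-group variance of normalized counts
    ss = np.zeros(norm.shape[0])
    df = 0
    for idx in groups:
        if idx.size >= 2:
            sub = norm[:, idx]
            ss += sub.var(axis=1, ddof=1) * (idx.size - 1)
            df += idx.size - 1
    if df == 0:  # single replicate per group: fall back to cross-group variance
        ss = norm.var(axis=1, ddof=1) * (norm.shape[1] - 1)
        df = norm.shape[1] - 1
    s2 = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_signed = (s2 - mu * inv_sf_mean) / np.maximum(mu, 1e-300) ** 2
    raw = np.clip(raw_signed, _DISP_FLOOR, _DISP_CAP)

    ok = mu > 0
    n_ok = int(ok.sum())
    if n_ok >= 20:
        order = np.argsort(mu[ok])
        idx_ok = np.flatnonzero(ok)[order]
        n_bins = min(10, max(2, n_ok // 20))
        xs, ys = [], []
        for chunk in np.array_split(idx_ok, n_bins):
            xs.append(np.log(mu[chunk].mean()))
            # E[raw_signed] = dispersion (unbiased); negative bin means clamp
            ys.append(np.log(max(float(raw_signed[chunk].mean()), _DISP_FLOOR)))
        slope, intercept = np.polyfit(xs, ys, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-300)))
        trend = np.clip(trend, _DISP_FLOOR, _DISP_CAP)
    else:
        trend = np.full_like(raw, max(float(np.mean(raw_signed[ok])) if n_ok else
                                      _DISP_FLOOR, _DISP_FLOOR))
    shrunk = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    return np.clip(shrunk, _DISP_FLOOR, _DISP_CAP)


def call_degs(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_fold: float = 4.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential expression of tissue A (left) over tissue B.

    Inputs are replicate count columns per group on a shared gene index.
    Returns one row per gene: base_mean, log2fc (A over B), p, q, direction
    (up = higher in A), is_deg, and an ``all_zero`` skip flag.
    """
    if not counts_a.index.equals(counts_b.index):
        counts_b = counts_b.reindex(counts_a.index)
        if counts_b.isna().any().any():
            raise ValueError("gene index mismatch between groups")
    combined = pd.concat([counts_a, counts_b], axis=1)
    if (combined.to_numpy() < 0).any():
        raise ValueError("negative counts")
    all_zero = (combined.to_numpy() == 0).all(axis=1)

    sf = size_factors(combined)
    norm = combined.to_numpy(dtype=float) / sf.to_numpy()
    na, nb = counts_a.shape[1], counts_b.shape[1]
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    inv_sf = 1.0 / sf.to_numpy()
    disp = _dispersion_estimates(norm, [idx_a, idx_b], float(inv_sf.mean()))

    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_a + _PSEUDOCOUNT) / (mean_b + _PSEUDOCOUNT))

    # Wald SE from the NB variance of each group's normalized-count mean:
    # Var(K_j/s_j) = mu/s_j + disp*mu^2, Var(log2 mean) by the delta method.
    def _var_log_mean(mean, idx):
        mu = np.maximum(mean, _PSEUDOCOUNT)
        var_mean = (mu * inv_sf[idx].sum() + disp * mu**2 * idx.size) / idx.size**2
        return var_mean / mu**2

    se = np.sqrt(_var_log_mean(mean_a, idx_a) + _var_log_mean(mean_b, idx_b)) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[all_zero] = np.nan

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    q[tested] = bh_adjust(p[tested])

    lfc_cut = np.log2(min_fold)
    is_deg = tested & (q < q_threshold) & (np.abs(log2fc) >= lfc_cut)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", "down"),
            "is_deg": is_deg,
            "all_zero": all_zero,
        },
        index=combined.index,
    )


def write_deg_tsv(degs: pd.DataFrame, path) -> None:
    out = degs.reset_index().rename(columns={"index": "gene_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
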