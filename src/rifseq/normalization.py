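"""FPKM expression and TMM between-sample scaling factors.

FPKM (fragments per kilobase of gene per million reads) is computed as

    fpkm[g, s] = counts[g, s] * 1e9 / (lib_size[s] * length_bp[g])

with ``lib_size`` the raw column sum of the count matrix. The log-scale
expression used for co-expression work downstream is log2(FPKM + 1).

TMM (trimmed mean of M-values) computes, for each sample against a
reference sample, the weighted mean of gene-wise log2 expression ratios
(M-values) after trimming the most extreme 30% of M-values and 5% of
average-abundance values (A-values) from each tail; weights are inverse
asymptotic binomial variances. The factors are re-centered to geometric
mean 1 and multiply the raw library sizes to give the effective library
sizes used by the exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from rifseq.errors import ValidationError
from rifseq.io import CountMatrix

__all__ = ["NormalizedMatrix", "compute_fpkm", "tmm_factors", "normalize"]


@dataclass(frozen=True)
class NormalizedMatrix:
    """FPKM and log2(FPKM+1) expression with library sizes and TMM factors."""

    fpkm: pd.DataFrame
    log_expr: pd.DataFrame
    lib_size: pd.Series
    tmm_factor: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def effective_lib_size(self) -> pd.Series:
        """Library size scaled by the TMM factor (used for testing)."""
        return self.lib_size * self.tmm_factor


def compute_fpkm(counts: CountMatrix, meta: pd.DataFrame) -> NormalizedMatrix:
    """FPKM-normalize a count matrix given per-gene exonic lengths in bp.

    TMM factors are initialized to 1; use :func:`normalize` to also fit TMM.
    """
    missing = sorted(set(counts.gene_ids) - set(meta.index))
    if missing:
        raise ValidationError(f"genes without length metadata: {missing[:10]}")
    lib = counts.lib_sizes()
    zero = lib[lib == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample {zero.index[0]!r}")
    lengths = meta.loc[counts.gene_ids, "length_bp"].to_numpy(dtype=float)
    fpkm = counts.counts.to_numpy(dtype=float) * 1e9 / (
        lib.to_numpy(dtype=float)[None, :] * lengths[:, None]
    )
    fpkm_df = pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)
    ones = pd.Series(1.0, index=counts.counts.columns)
    return NormalizedMatrix(
        fpkm=fpkm_df,
        log_expr=np.log2(fpkm_df + 1.0),
        lib_size=lib,
        tmm_factor=ones,
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValidationError("sample shares no nonzero genes with the TMM reference")
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # inverse asymptotic binomial variance weights
    v = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:  # identical composition: factor exactly 1
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 0.0
    w = 1.0 / v[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


def tmm_factors(
    counts: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, re-centered to geometric mean 1.

    The reference defaults to the sample whose 75th percentile of
    library-size-scaled counts is closest to the mean across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    samples = counts.sample_ids
    if len(samples) < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = counts.lib_sizes().to_numpy(dtype=float)
    if (lib == 0).any():
        s = samples[int(np.argmin(lib))]
        raise ValidationError(f"zero library size for sample {s!r}")
    if ref_sample is None:
        uq = np.quantile(mat / lib[None, :], 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in samples:
            raise ValidationError(f"unknown TMM reference sample {ref_sample!r}")
        ref_idx = samples.index(ref_sample)
    log_f = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(len(samples))
        ]
    )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.counts.columns)


def normalize(
    counts: CountMatrix,
    meta: pd.DataFrame,
    use_tmm: bool = True,
    ref_sample: str | None = None,
) -> NormalizedMatrix:
    """FPKM + (optionally) TMM in one step."""
    norm = compute_fpkm(counts, meta)
    if not use_tmm:
        return norm
    factors = tmm_factors(counts, ref_sample=ref_sample)
    return NormalizedMatrix(
        fpkm=norm.fpkm, log_expr=norm.log_expr, lib_size=norm.lib_size, tmm_factor=factors
    )
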