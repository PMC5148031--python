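"""Two-group negative-binomial exact testing with expression/FC/p filters.

The testing chain follows the classical count-based recipe for small
two-group designs:

1. effective library sizes = raw library size x TMM factor;
2. a common (or tagwise-shrunk) NB dispersion estimated by conditional
   maximum likelihood on quantile-adjusted "pseudo-counts", i.e. counts
   mapped to a common library size by matching NB quantiles (qCML);
3. per gene, a two-sided exact test conditioning on the total pseudo-count
   across both groups: the p-value is the probability mass of all splits of
   that total no more probable than the observed split;
4. Benjamini-Hochberg FDR over the tested (expressed) genes.

Gene-level calling applies the study filters: mean group FPKM above
``min_group_fpkm`` in at least one group, fold change >= ``min_fc`` and
p <= ``max_p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from rifseq.errors import ValidationError
from rifseq.io import CountMatrix, SampleDesign
from rifseq.normalization import NormalizedMatrix

__all__ = [
    "DEConfig",
    "estimate_dispersion",
    "exact_nb_test",
    "bh_fdr",
    "call_de",
]


@dataclass(frozen=True)
class DEConfig:
    """Filter thresholds and dispersion mode for DE calling."""

    min_group_fpkm: float = 0.5
    min_fc: float = 1.5
    max_p: float = 0.01
    pseudo: float = 0.01  # pseudo-count on FPKM means for the FC ratio
    dispersion_mode: str = "common"  # or "tagwise"

    def __post_init__(self) -> None:
        if self.min_fc < 1:
            raise ValidationError(f"min_fc must be >= 1, got {self.min_fc}")
        if not (0 < self.max_p <= 1):
            raise ValidationError(f"max_p must be in (0, 1], got {self.max_p}")
        if self.dispersion_mode not in ("common", "tagwise"):
            raise ValidationError(f"unknown dispersion_mode {self.dispersion_mode!r}")


# ---------------------------------------------------------------------------
# quantile-to-quantile NB adjustment (library-size equalization)


def _q2qnbinom(
    x: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, dispersion: float
) -> np.ndarray:
    """Map counts with mean ``mu_in`` to the NB quantile-matched value at
    ``mu_out``, averaging a normal and a gamma continuous approximation."""
    x = np.asarray(x, dtype=float)
    mu_in = np.maximum(np.asarray(mu_in, dtype=float), 0.0)
    mu_out = np.maximum(np.asarray(mu_out, dtype=float), 0.0)
    zero = (mu_in < 1e-14) | (mu_out < 1e-14)
    mu_in = np.where(zero, mu_in + 0.25, mu_in)
    mu_out = np.where(zero, mu_out + 0.25, mu_out)
    ri = 1.0 + dispersion * mu_in
    vi = mu_in * ri
    ro = 1.0 + dispersion * mu_out
    vo = mu_out * ro

    q1 = np.empty_like(x)
    q2 = np.empty_like(x)
    upper = x >= mu_in
    lower = ~upper
    tiny = 1e-300

    if upper.any():
        xi, mi, vii, mo, voi = (a[upper] for a in (x, mu_in, vi, mu_out, vo))
        logp = stats.norm.logsf(xi, loc=mi, scale=np.sqrt(vii))
        q1[upper] = mo - np.sqrt(voi) * special.ndtri_exp(logp)
        pg = stats.gamma.sf(xi, a=mi**2 / vii, scale=vii / mi)
        q2[upper] = special.gammainccinv(mo**2 / voi, np.maximum(pg, tiny)) * (voi / mo)
    if lower.any():
        xi, mi, vii, mo, voi = (a[lower] for a in (x, mu_in, vi, mu_out, vo))
        logp = stats.norm.logcdf(xi, loc=mi, scale=np.sqrt(vii))
        q1[lower] = mo + np.sqrt(voi) * special.ndtri_exp(logp)
        pg = stats.gamma.cdf(xi, a=mi**2 / vii, scale=vii / mi)
        q2[lower] = special.gammaincinv(mo**2 / voi, np.maximum(pg, tiny)) * (voi / mo)
    return np.maximum((q1 + q2) / 2.0, 0.0)


def _fit_group_means(
    counts: np.ndarray, lib: np.ndarray, dispersion: float, n_iter: int = 8
) -> np.ndarray:
    """Per-gene NB rate (counts per unit library size) for one group.

    One-group NB fit with log link and log(lib) offset, Newton iterations
    on the intercept; the quasi-Poisson estimate row_sum/lib_sum is the
    starting value and the exact answer when dispersion is 0.
    """
    lam = counts.sum(axis=1) / lib.sum()
    if dispersion <= 0:
        return lam
    pos = lam > 0
    lam_pos = lam[pos]
    y = counts[pos]
    for _ in range(n_iter):
        mu = lam_pos[:, None] * lib[None, :]
        denom = 1.0 + dispersion * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        lam_pos = lam_pos * np.exp(step)
    lam[pos] = lam_pos
    return lam


def _equalize(
    counts: np.ndarray,
    lib: np.ndarray,
    group_idx: list[np.ndarray],
    dispersion: float,
) -> tuple[np.ndarray, float]:
    """Pseudo-counts at the common (geometric-mean) library size."""
    common_lib = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.empty_like(counts, dtype=float)
    for idx in group_idx:
        lam = _fit_group_means(counts[:, idx], lib[idx], dispersion)
        mu_in = lam[:, None] * lib[idx][None, :]
        mu_out = np.repeat(lam[:, None] * common_lib, len(idx), axis=1)
        pseudo[:, idx] = _q2qnbinom(counts[:, idx], mu_in, mu_out, dispersion)
    return pseudo, common_lib


def _cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], r: float) -> float:
    """Conditional NB log-likelihood summed over genes and groups (equal
    library sizes assumed; terms constant in the dispersion dropped)."""
    total = 0.0
    for idx in group_idx:
        y = pseudo[:, idx]
        m = len(idx)
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * m * special.gammaln(r)
            + y.shape[0] * special.gammaln(m * r)
            - np.sum(special.gammaln(z + m * r))
        )
    return total


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame | np.ndarray,
    eff_lib_sizes: pd.Series | np.ndarray,
    groups: tuple[list[str] | np.ndarray, list[str] | np.ndarray],
    mode: str = "common",
    prior_df: float = 10.0,
) -> float | np.ndarray:
    """qCML dispersion from a two-group count matrix.

    ``common`` returns one scalar maximizing the pooled conditional
    likelihood of the quantile-adjusted pseudo-counts; ``tagwise`` shrinks
    per-gene estimates toward the common value with a weighted-likelihood
    prior equivalent to ``prior_df`` degrees of freedom.
    """
    if isinstance(counts, CountMatrix):
        df = counts.counts
    elif isinstance(counts, pd.DataFrame):
        df = counts
    else:
        df = pd.DataFrame(np.asarray(counts))
    if isinstance(eff_lib_sizes, pd.Series):
        eff_lib_sizes = eff_lib_sizes.loc[df.columns]
        lib = eff_lib_sizes.to_numpy(dtype=float)
    else:
        lib = np.asarray(eff_lib_sizes, dtype=float)
    ga, gb = groups
    cols = list(df.columns)
    if all(isinstance(s, str) for s in ga):
        ia = np.array([cols.index(s) for s in ga])
        ib = np.array([cols.index(s) for s in gb])
    else:
        ia, ib = np.asarray(ga, dtype=int), np.asarray(gb, dtype=int)
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError("dispersion estimation needs >= 2 samples per group")
    mat = df.to_numpy(dtype=float)
    used = mat.sum(axis=1) > 0
    if not used.any():
        raise ValidationError("all-zero count matrix: dispersion undefined")
    mat = mat[used]
    group_idx = [ia, ib]

    disp = 0.01
    pseudo = mat
    for _ in range(2):
        pseudo, _common = _equalize(mat, lib, group_idx, disp)
        res = minimize_scalar(
            lambda delta: -_cond_loglik(pseudo, group_idx, (1.0 - delta) / delta),
            bounds=(1e-4, 100.0 / 101.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        delta = float(res.x)
        disp = delta / (1.0 - delta)
    if disp <= 2e-4 / (1 - 1e-4):  # boundary: no extra-Poisson variation detected
        disp = 0.0
    if mode == "common":
        return disp

    # tagwise: per-gene weighted-likelihood shrinkage toward the pooled curve
    n_used = mat.shape[0]
    prior_n = prior_df / max(len(ia) + len(ib) - 2, 1)
    deltas = np.linspace(1e-4, 0.98, 120)
    per_gene = np.zeros((n_used, deltas.size))
    pooled = np.zeros(deltas.size)
    for k, delta in enumerate(deltas):
        r = (1.0 - delta) / delta
        for idx in group_idx:
            y = pseudo[:, idx]
            m = len(idx)
            z = y.sum(axis=1)
            ll = (
                special.gammaln(y + r).sum(axis=1)
                - m * special.gammaln(r)
                + special.gammaln(m * r)
                - special.gammaln(z + m * r)
            )
            per_gene[:, k] += ll
        pooled[k] = per_gene[:, k].mean()
    best = np.argmax(per_gene + prior_n * pooled[None, :], axis=1)
    tag = deltas[best] / (1.0 - deltas[best])
    out = np.full(len(used), disp)
    out[used] = tag
    return out


# ---------------------------------------------------------------------------
# exact test


def exact_nb_test(
    sum_a: float,
    sum_b: float,
    n_a: int,
    n_b: int,
    dispersion: float,
    tie_rel_tol: float = 1e-12,
) -> float:
    """Two-sided exact NB test of one gene's (equalized) group totals.

    Conditions on ``s = round(sum_a) + round(sum_b)``: under NB with the
    given dispersion and a common per-sample mean, p is the total
    probability of all splits (x, s-x) no more probable than the observed
    one. Splits tied with the observed probability (within ``tie_rel_tol``
    relative tolerance) are included, which is conservative. With
    dispersion 0 this is the two-sided exact binomial (Poisson) test.
    """
    if dispersion < 0:
        raise ValidationError(f"dispersion must be >= 0, got {dispersion}")
    s1 = int(round(sum_a))
    s2 = int(round(sum_b))
    s = s1 + s2
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    if dispersion < 1e-10:
        logp = stats.binom.logpmf(x, s, n_a / (n_a + n_b))
    else:
        mu = (s1 + s2) / (n_a + n_b)  # per-sample mean at the common library size
        r = 1.0 / dispersion
        logp = stats.nbinom.logpmf(x, n_a * r, n_a * r / (n_a * r + n_a * mu)) + \
            stats.nbinom.logpmf(s - x, n_b * r, n_b * r / (n_b * r + n_b * mu))
    log_obs = logp[s1]
    keep = logp <= log_obs + np.log1p(tie_rel_tol)
    p = float(np.exp(special.logsumexp(logp[keep]) - special.logsumexp(logp)))
    return min(max(p, 1e-300), 1.0)  # keep p in (0, 1] despite underflow


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene-level calling


def call_de(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    design: SampleDesign,
    config: DEConfig = DEConfig(),
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Full two-group DE table with the expression / FC / p filters applied.

    Returns a DataFrame with columns gene_id, mean_fpkm_A, mean_fpkm_B, fc,
    direction, p, fdr, expressed, de. p-values (and FDR) are computed only
    for expressed genes; non-expressed genes get NaN.
    """
    design.validate_against(counts)
    samples_a, samples_b = design.samples_a, design.samples_b
    fpkm = norm.fpkm
    mean_a = fpkm[samples_a].mean(axis=1)
    mean_b = fpkm[samples_b].mean(axis=1)
    expressed = (mean_a > config.min_group_fpkm) | (mean_b > config.min_group_fpkm)
    ratio = (mean_a + config.pseudo) / (mean_b + config.pseudo)
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1.0, "up_in_A", "up_in_B")

    eff_lib = norm.effective_lib_size()
    sub = counts.counts[samples_a + samples_b]
    if dispersion is None:
        dispersion = estimate_dispersion(
            sub, eff_lib.loc[samples_a + samples_b], (samples_a, samples_b),
            mode=config.dispersion_mode,
        )
    disp_common = (
        float(np.median(dispersion)) if np.ndim(dispersion) else float(dispersion)
    )
    mat = sub.to_numpy(dtype=float)
    lib = eff_lib.loc[samples_a + samples_b].to_numpy(dtype=float)
    ia = np.arange(len(samples_a))
    ib = np.arange(len(samples_a), len(samples_a) + len(samples_b))
    # equalize under the pooled (null) abundance: the exact test conditions
    # on the total, so the mapping to the common library size must not use
    # group-specific means
    pseudo, _ = _equalize(mat, lib, [np.concatenate([ia, ib])], disp_common)
    sums_a = pseudo[:, ia].sum(axis=1)
    sums_b = pseudo[:, ib].sum(axis=1)

    disp_vec = (
        np.asarray(dispersion, dtype=float)
        if np.ndim(dispersion)
        else np.full(mat.shape[0], float(dispersion))
    )
    p = np.full(mat.shape[0], np.nan)
    for g in np.flatnonzero(expressed.to_numpy()):
        p[g] = exact_nb_test(sums_a[g], sums_b[g], len(ia), len(ib), disp_vec[g])

    fdr = np.full(mat.shape[0], np.nan)
    idx = np.flatnonzero(expressed.to_numpy())
    if idx.size:
        fdr[idx] = bh_fdr(p[idx])

    de = (
        expressed.to_numpy()
        & (fc.to_numpy() >= config.min_fc)
        & np.where(np.isnan(p), False, p <= config.max_p)
    )
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_fpkm_A": mean_a.to_numpy(),
            "mean_fpkm_B": mean_b.to_numpy(),
            "fc": fc.to_numpy(),
            "direction": direction,
            "p": p,
            "fdr": fdr,
            "expressed": expressed.to_numpy(),
            "de": de,
        }
    )
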