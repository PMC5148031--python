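"""Regulatory impact factors (RIF1/RIF2) of regulators against DE genes.

For regulator i and the DE gene set j = 1..n_de, with all expression on
the log2(FPKM + 1) scale:

    a_hat_j = (e1_j + e2_j) / 2        average expression of DE gene j
    d_j     = e1_j - e2_j              differential expression (A minus B)
    r1_ij, r2_ij                       within-condition Pearson correlation
                                       between regulator i and DE gene j

    RIF1_i = (1/n_de) * sum_j a_hat_j * d_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_de) * sum_j (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2

RIF1 rewards regulators whose co-expression with large, strongly DE genes
rewires between conditions; RIF2 contrasts the regulator's condition-
specific "predictive energy" over the DE set. Both are standardized to
z-scores over the expressed-regulator list.

Regulators must pass the same expression filter as DE genes (group-mean
FPKM above ``min_trf_fpkm`` in at least one condition) to enter the
analysis. A gene or regulator with zero within-condition variance has an
undefined correlation; the convention r = 0 keeps it in the sum (with a
warning record) rather than silently shrinking n_de.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from rifseq.errors import ValidationError
from rifseq.io import SampleDesign
from rifseq.normalization import NormalizedMatrix

__all__ = ["RIFInputs", "build_rif_inputs", "rif1", "rif2", "zscore", "compute_rif"]


@dataclass(frozen=True)
class RIFInputs:
    """Per-gene and per-regulator inputs of the RIF sums."""

    de_gene_ids: list[str]
    trf_ids: list[str]  # expressed regulators only
    a_hat: np.ndarray  # (n_de,)
    d: np.ndarray  # (n_de,)
    e1: np.ndarray  # (n_de,)
    e2: np.ndarray  # (n_de,)
    r1: np.ndarray  # (n_trf, n_de)
    r2: np.ndarray  # (n_trf, n_de)
    excluded_trfs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.de_gene_ids) < 1:
            raise ValidationError("no DE genes; RIF undefined")
        for name in ("r1", "r2"):
            r = getattr(self, name)
            if np.any(np.abs(r) > 1 + 1e-9):
                raise ValidationError(f"{name} contains values outside [-1, 1]")


def _unit_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; zero-variance rows become zero
    (so downstream dot products give r = 0). Returns (scaled, flat_mask)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    norms[flat] = 1.0
    return centered / norms[:, None], flat


def _corr_matrix(
    trf_expr: np.ndarray, gene_expr: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson (or Spearman, via ranks) correlation of every regulator row
    with every gene row across the given samples."""
    if method == "spearman":
        trf_expr = rankdata(trf_expr, axis=1)
        gene_expr = rankdata(gene_expr, axis=1)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    zt, flat_t = _unit_rows(trf_expr)
    zg, flat_g = _unit_rows(gene_expr)
    return np.clip(zt @ zg.T, -1.0, 1.0), flat_t, flat_g


def build_rif_inputs(
    norm: NormalizedMatrix,
    design: SampleDesign,
    de_genes: Sequence[str],
    trf_ids: Sequence[str],
    min_trf_fpkm: float = 0.5,
    method: str = "pearson",
) -> RIFInputs:
    """Assemble RIF inputs for a DE gene set and a regulator list.

    Regulators failing the expression filter (group-mean FPKM not above
    ``min_trf_fpkm`` in either condition) are excluded and recorded;
    regulators absent from the matrix are ignored here (they are reported
    as unmeasured by the pipeline).
    """
    de_genes = list(de_genes)
    if not de_genes:
        raise ValidationError("no DE genes; RIF undefined")
    missing = sorted(set(de_genes) - set(norm.gene_ids))
    if missing:
        raise ValidationError(f"DE genes absent from expression matrix: {missing[:10]}")
    sa, sb = design.samples_a, design.samples_b
    if len(sa) < 3 or len(sb) < 3:
        raise ValidationError("correlations need >= 3 samples per condition")

    measured = [t for t in trf_ids if t in set(norm.gene_ids)]
    mean_a = norm.fpkm.loc[measured, sa].mean(axis=1)
    mean_b = norm.fpkm.loc[measured, sb].mean(axis=1)
    keep_mask = (mean_a > min_trf_fpkm) | (mean_b > min_trf_fpkm)
    kept = [t for t, k in zip(measured, keep_mask) if k]
    excluded = [t for t, k in zip(measured, keep_mask) if not k]
    if not kept:
        raise ValidationError("no regulator passes the expression filter")

    log_expr = norm.log_expr
    ga = log_expr.loc[de_genes, sa].to_numpy()
    gb = log_expr.loc[de_genes, sb].to_numpy()
    ta = log_expr.loc[kept, sa].to_numpy()
    tb = log_expr.loc[kept, sb].to_numpy()
    e1 = ga.mean(axis=1)
    e2 = gb.mean(axis=1)

    warnings: list[str] = []
    r1, flat_t1, flat_g1 = _corr_matrix(ta, ga, method)
    r2, flat_t2, flat_g2 = _corr_matrix(tb, gb, method)
    for cond, ft, fg in (("A", flat_t1, flat_g1), ("B", flat_t2, flat_g2)):
        for t in np.asarray(kept)[ft]:
            warnings.append(f"regulator {t} constant within condition {cond}; r set to 0")
        for g in np.asarray(de_genes)[fg]:
            warnings.append(f"DE gene {g} constant within condition {cond}; r set to 0")

    return RIFInputs(
        de_gene_ids=de_genes,
        trf_ids=kept,
        a_hat=(e1 + e2) / 2.0,
        d=e1 - e2,
        e1=e1,
        e2=e2,
        r1=r1,
        r2=r2,
        excluded_trfs=excluded,
        warnings=warnings,
    )


def rif1(inputs: RIFInputs) -> np.ndarray:
    """RIF1 per regulator: mean over DE genes of a_hat * d * (r1 - r2)^2."""
    w = inputs.a_hat * inputs.d
    return ((inputs.r1 - inputs.r2) ** 2 * w[None, :]).mean(axis=1)


def rif2(inputs: RIFInputs) -> np.ndarray:
    """RIF2 per regulator: mean over DE genes of (e1*r1)^2 - (e2*r2)^2."""
    return (
        (inputs.e1[None, :] * inputs.r1) ** 2 - (inputs.e2[None, :] * inputs.r2) ** 2
    ).mean(axis=1)


def zscore(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Standardize with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z-scores need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("z-scores undefined for constant scores")
    return (x - x.mean()) / sd


def compute_rif(inputs: RIFInputs) -> pd.DataFrame:
    """RIF1/RIF2 raw scores and z-scores for every expressed regulator."""
    s1 = rif1(inputs)
    s2 = rif2(inputs)
    return pd.DataFrame(
        {
            "trf_id": inputs.trf_ids,
            "rif1": s1,
            "rif2": s2,
            "z1": zscore(s1),
            "z2": zscore(s2),
        }
    )
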