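"""Bootstrap null distribution and significance thresholds for RIF z-scores.

Each iteration draws a pseudo-DE gene set of the same size as the real one,
without replacement from all expressed genes, rebuilds the RIF inputs for
that set (a_hat, d, e1, e2 and both correlation matrices are recomputed)
and standardizes the resulting RIF1/RIF2 scores over the regulator list.
The z-scores of all iterations are pooled per score type and the
significance thresholds are the empirical ((1-level)/2, 1-(1-level)/2)
percentiles (linear interpolation between order statistics) of that pooled
null sample. A regulator is called significant at a level when its observed
z falls strictly outside the thresholds on RIF1 or RIF2.

Randomness contract: one master seed; per-iteration generators are derived
with ``numpy.random.SeedSequence.spawn`` so results do not depend on
execution order. Iterations with a degenerate (constant) score vector are
recorded as skipped, not re-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rifseq.errors import ValidationError
from rifseq.io import SampleDesign
from rifseq.normalization import NormalizedMatrix
from rifseq.rif import _unit_rows

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_null", "call_significant"]


@dataclass(frozen=True)
class BootstrapConfig:
    n_iter: int = 10_000
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    seed: int = 0
    per_trf: bool = False  # also derive per-regulator percentile thresholds

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError(f"n_iter must be >= 1, got {self.n_iter}")
        for lvl in self.ci_levels:
            if not (0 < lvl < 1):
                raise ValidationError(f"ci level must be in (0, 1), got {lvl}")


@dataclass(frozen=True)
class BootstrapResult:
    """Pooled-null thresholds per (score, level) plus bookkeeping."""

    thresholds: dict[tuple[str, float], tuple[float, float]]
    n_pooled: int  # pooled null sample size per score type
    n_skipped: int  # iterations skipped for degenerate scores
    n_de: int
    config: BootstrapConfig
    # optional per-regulator thresholds: (score, level) -> (lower, upper) arrays
    per_trf_thresholds: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] | None = None

    def threshold(self, score: str, level: float) -> tuple[float, float]:
        key = (score, level)
        if key not in self.thresholds:
            raise ValidationError(f"no bootstrap thresholds for {score} at level {level}")
        return self.thresholds[key]


def bootstrap_null(
    norm: NormalizedMatrix,
    design: SampleDesign,
    expressed_genes: Sequence[str],
    trf_ids: Sequence[str],
    n_de: int,
    config: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Build the pooled bootstrap null of RIF1/RIF2 z-scores.

    ``trf_ids`` should be the expressed regulator list actually scored
    (the same list standardized in the observed analysis).
    """
    expressed_genes = list(expressed_genes)
    trf_ids = list(trf_ids)
    if n_de > len(expressed_genes):
        raise ValidationError(
            f"n_de = {n_de} exceeds the {len(expressed_genes)} expressed genes"
        )
    if n_de < 1:
        raise ValidationError("n_de must be >= 1")
    if len(trf_ids) < 2:
        raise ValidationError("bootstrap needs >= 2 regulators")

    sa, sb = design.samples_a, design.samples_b
    log_expr = norm.log_expr
    ga = log_expr.loc[expressed_genes, sa].to_numpy()
    gb = log_expr.loc[expressed_genes, sb].to_numpy()
    ta = log_expr.loc[trf_ids, sa].to_numpy()
    tb = log_expr.loc[trf_ids, sb].to_numpy()

    e1 = ga.mean(axis=1)
    e2 = gb.mean(axis=1)
    w_rif1 = (e1 + e2) / 2.0 * (e1 - e2)  # a_hat * d per candidate gene
    zg_a, _ = _unit_rows(ga)
    zg_b, _ = _unit_rows(gb)
    zt_a, _ = _unit_rows(ta)
    zt_b, _ = _unit_rows(tb)

    n_trf = len(trf_ids)
    null1 = np.empty(config.n_iter * n_trf)
    null2 = np.empty(config.n_iter * n_trf)  # filled as (iteration, trf) blocks
    n_ok = 0
    n_skipped = 0
    children = np.random.SeedSequence(config.seed).spawn(config.n_iter)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(len(expressed_genes), size=n_de, replace=False)
        r1 = np.clip(zt_a @ zg_a[idx].T, -1.0, 1.0)
        r2 = np.clip(zt_b @ zg_b[idx].T, -1.0, 1.0)
        s1 = ((r1 - r2) ** 2 * w_rif1[idx][None, :]).mean(axis=1)
        s2 = ((e1[idx][None, :] * r1) ** 2 - (e2[idx][None, :] * r2) ** 2).mean(axis=1)
        sd1 = s1.std(ddof=1)
        sd2 = s2.std(ddof=1)
        if sd1 == 0 or sd2 == 0:
            n_skipped += 1
            continue
        null1[n_ok * n_trf : (n_ok + 1) * n_trf] = (s1 - s1.mean()) / sd1
        null2[n_ok * n_trf : (n_ok + 1) * n_trf] = (s2 - s2.mean()) / sd2
        n_ok += 1
    if n_ok == 0:
        raise ValidationError("all bootstrap iterations degenerate; no null available")
    null1 = null1[: n_ok * n_trf]
    null2 = null2[: n_ok * n_trf]

    thresholds: dict[tuple[str, float], tuple[float, float]] = {}
    per_trf: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] | None = (
        {} if config.per_trf else None
    )
    for level in config.ci_levels:
        alpha = (1.0 - level) / 2.0
        for score, pool in (("rif1", null1), ("rif2", null2)):
            lo, hi = np.percentile(pool, [100 * alpha, 100 * (1 - alpha)])
            thresholds[(score, level)] = (float(lo), float(hi))
            if per_trf is not None:
                by_trf = pool.reshape(n_ok, n_trf)
                per_trf[(score, level)] = (
                    np.percentile(by_trf, 100 * alpha, axis=0),
                    np.percentile(by_trf, 100 * (1 - alpha), axis=0),
                )
    return BootstrapResult(
        thresholds=thresholds,
        n_pooled=n_ok * n_trf,
        n_skipped=n_skipped,
        n_de=n_de,
        config=config,
        per_trf_thresholds=per_trf,
    )


def call_significant(
    z: np.ndarray | Sequence[float],
    result: BootstrapResult,
    level: float,
    score: str,
    per_trf: bool = False,
) -> np.ndarray:
    """Flag z-scores strictly outside the (lower, upper) null thresholds.

    With ``per_trf=True`` each regulator is compared to its own null
    percentiles (requires a result built with ``BootstrapConfig.per_trf``).
    """
    z = np.asarray(z, dtype=float)
    if per_trf:
        if result.per_trf_thresholds is None:
            raise ValidationError("result has no per-regulator thresholds")
        key = (score, level)
        if key not in result.per_trf_thresholds:
            raise ValidationError(f"no bootstrap thresholds for {score} at level {level}")
        lo, hi = result.per_trf_thresholds[key]
        if z.shape != lo.shape:
            raise ValidationError("z-score vector does not match the regulator list")
    else:
        lo, hi = result.threshold(score, level)
    return (z < lo) | (z > hi)


def significant_regulators(
    scores: pd.DataFrame, result: BootstrapResult, level: float
) -> pd.DataFrame:
    """Per-regulator flags at one level; ``significant`` = RIF1 or RIF2."""
    f1 = call_significant(scores["z1"].to_numpy(), result, level, "rif1")
    f2 = call_significant(scores["z2"].to_numpy(), result, level, "rif2")
    return pd.DataFrame(
        {
            "trf_id": scores["trf_id"].to_numpy(),
            "rif1_flag": f1,
            "rif2_flag": f2,
            "significant": f1 | f2,
        }
    )
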