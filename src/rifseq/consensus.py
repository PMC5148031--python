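"""Multi-evidence regulator consensus and technical-validation metrics.

Three independent evidence lines support a regulator: being DE itself in
the contrast, being RIF-significant (RIF1 or RIF2 at the chosen level),
and appearing in an external knowledge-base regulator list. The consensus
report counts evidence per regulator and assigns a tier; regulators backed
by all three lines are the prime candidates.

The validation metrics are the ones used to check RNA-seq against an
orthogonal assay: the Pearson correlation of expression values and Lin's
concordance correlation coefficient (CCC) of fold-change estimates,

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with population (1/n) moments; CCC penalizes location/scale disagreement
on top of decorrelation, so |ccc| <= |pearson| always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rifseq.errors import ValidationError

__all__ = ["EvidenceSets", "consensus", "pearson", "ccc"]

_TIERS = {3: "all_three", 2: "two", 1: "one", 0: "none"}


@dataclass(frozen=True)
class EvidenceSets:
    """The three regulator evidence sets, validated against a universe."""

    de_trfs: frozenset[str]
    rif_trfs: frozenset[str]
    kb_trfs: frozenset[str]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name in ("de_trfs", "rif_trfs", "kb_trfs"):
            outside = sorted(getattr(self, name) - uni)
            if outside:
                raise ValidationError(
                    f"{name} contains ids outside the regulator universe: {outside[:10]}"
                )


def evidence_sets(
    de_trfs: Iterable[str],
    rif_trfs: Iterable[str],
    kb_trfs: Iterable[str],
    universe: Sequence[str],
) -> EvidenceSets:
    return EvidenceSets(
        de_trfs=frozenset(de_trfs),
        rif_trfs=frozenset(rif_trfs),
        kb_trfs=frozenset(kb_trfs),
        universe=tuple(universe),
    )


def consensus(evidence: EvidenceSets) -> pd.DataFrame:
    """Evidence count and tier per regulator, ordered by tier then id."""
    rows = []
    for trf in evidence.universe:
        in_de = trf in evidence.de_trfs
        in_rif = trf in evidence.rif_trfs
        in_kb = trf in evidence.kb_trfs
        n = int(in_de) + int(in_rif) + int(in_kb)
        rows.append((trf, in_de, in_rif, in_kb, n, _TIERS[n]))
    out = pd.DataFrame(
        rows, columns=["trf_id", "in_de", "in_rif", "in_kb", "n_evidence", "tier"]
    )
    return out.sort_values(
        ["n_evidence", "trf_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} paired values, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; hard error on constant input."""
    x, y = _pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def ccc(x: Sequence[float], y: Sequence[float], sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    Uses population (1/n) moments by default, matching the original
    estimator; ``sample_moments=True`` switches to n-1 denominators.
    """
    x, y = _pair(x, y, 2)
    ddof = 1 if sample_moments else 0
    sx = x.var(ddof=ddof)
    sy = y.var(ddof=ddof)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sample_moments:
        sxy *= x.size / (x.size - 1)
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValidationError("CCC undefined: both vectors constant and equal")
    return float(2.0 * sxy / denom)
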