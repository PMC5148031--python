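"""Seeded two-condition count simulator with planted DE genes and planted
differentially co-expressed regulators.

The generator emulates the design of a two-group muscle transcriptome
study at desk scale: two conditions with 6 samples each, about half of the
annotated genes expressed, NB-distributed counts, a configurable fraction
of DE genes with fold change >= 1.5, and a small set of regulator genes
whose correlation with their target genes differs between conditions.

Per gene g and sample s, a latent log2 expression is drawn:

    x[g, s] = baseline[g] (+/- log2(fc)/2 DE offset by condition)
              + deviation[g, s]

where the deviation is ``bio_sd``-scaled independent noise for ordinary
genes, ``coupled_sd * u[k, s]`` for planted regulator k (u its per-sample
standard-normal latent factor), and for a target of regulators K in
condition c

    coupled_sd * ( sum_k lambda_k * u[k, s] + sqrt(1 - sum lambda_k^2) * z )

so the latent correlation with each regulator is lambda_k. The loadings
are calibrated upward for NB measurement attenuation so that the OBSERVED
Pearson correlation of log2(FPKM+1) approaches ``coupling_A`` /
``coupling_B``, and jointly capped below 1 where targets are shared.
Counts are then NB with mean 2^x * length * library_size / 1e9 and
dispersion ``nb_dispersion``; non-expressed genes get baselines far below
the 0.5-FPKM expression threshold.

Each planted regulator's targets share one DE direction (drawn per
regulator): a regulator that drives its targets induces a co-directional
DE module, which is what gives the signed RIF1 weights a coherent sum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from rifseq.errors import ValidationError
from rifseq.io import CountMatrix, SampleDesign
from rifseq.normalization import NormalizedMatrix

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate", "empirical_target_correlation"]

_LOG2E2 = np.log2(np.e) ** 2  # (log2 e)^2, log2-scale variance of relative noise


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the emulated study design."""

    n_genes: int = 2_000
    n_trf: int = 100
    samples_per_group: int = 6
    frac_expressed: float = 0.5
    frac_de: float = 0.05
    fc_range: tuple[float, float] = (1.5, 4.0)
    nb_dispersion: float = 0.1
    mean_log2_fpkm: float = 6.5  # expressed genes; desk-scale matrices carry
    sd_log2_fpkm: float = 1.5   # few genes, so per-gene FPKM runs high
    nonexpr_mean_log2_fpkm: float = -6.5
    nonexpr_sd_log2_fpkm: float = 0.5
    n_planted_regulators: int = 3
    targets_per_regulator: int = 40
    coupling_A: float = 0.8
    coupling_B: float = 0.0
    bio_sd: float = 0.25  # log2-scale independent biological noise
    coupled_sd: float = 1.5  # log2-scale swing of regulators and their targets
    length_range: tuple[int, int] = (300, 10_000)
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.2
    condition_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_expressed", "frac_de"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("coupling_A", "coupling_B"):
            if abs(getattr(self, name)) >= 1:
                raise ValidationError(f"|{name}| must be < 1")
        if self.n_planted_regulators > self.n_trf:
            raise ValidationError("more planted regulators than regulator genes")
        n_de = round(self.frac_de * self.n_genes)
        if self.n_planted_regulators > 0 and self.targets_per_regulator > n_de:
            raise ValidationError(
                f"targets_per_regulator = {self.targets_per_regulator} exceeds the "
                f"planted DE pool of {n_de} genes"
            )
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset; round-trips exactly via JSON."""

    seed: int
    config: dict
    de_genes: dict[str, dict]  # gene_id -> {direction, fc}
    regulators: dict[str, dict]  # trf_id -> {coupling_A, coupling_B, targets}
    expressed_genes: list[str]
    baseline_log2_fpkm: dict[str, float]
    gene_length: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)

    @property
    def de_gene_ids(self) -> list[str]:
        return list(self.de_genes)

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.regulators)


def _jsonable(obj):
    """Tuples become lists so the truth record equals its JSON round-trip."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class SimResult(NamedTuple):
    counts: CountMatrix
    meta: pd.DataFrame
    trf_ids: list[str]
    design: SampleDesign
    truth: SimTruth


def _attenuation(mu_count: np.ndarray, dispersion: float, coupled_sd: float) -> np.ndarray:
    """Expected shrinkage of a log-scale correlation due to NB counting
    noise on top of a latent signal of sd ``coupled_sd`` (delta method).

    The Poisson 1/mu term is averaged over the log-normal latent swing
    (E[2^-x] for x ~ N(0, coupled_sd^2)), since low-expression samples
    dominate the counting noise.
    """
    poisson_inflation = np.exp((coupled_sd * np.log(2.0)) ** 2 / 2.0)
    me2 = _LOG2E2 * (poisson_inflation / np.maximum(mu_count, 1e-9) + dispersion)
    return coupled_sd / np.sqrt(coupled_sd**2 + me2)


def simulate(config: SimConfig = SimConfig()) -> SimResult:
    """Generate (CountMatrix, GeneMeta, TRF list, SampleDesign, SimTruth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    m = config.samples_per_group
    cond_a, cond_b = config.condition_labels

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    lengths = np.round(
        np.exp(rng.uniform(np.log(config.length_range[0]), np.log(config.length_range[1]), n))
    ).astype(np.int64)

    trf_idx = np.sort(rng.choice(n, size=config.n_trf, replace=False))
    is_trf = np.zeros(n, dtype=bool)
    is_trf[trf_idx] = True

    expressed = rng.random(n) < config.frac_expressed
    planted_reg_idx = rng.choice(trf_idx, size=config.n_planted_regulators, replace=False)
    expressed[planted_reg_idx] = True

    baseline = np.where(
        expressed,
        rng.normal(config.mean_log2_fpkm, config.sd_log2_fpkm, n),
        rng.normal(config.nonexpr_mean_log2_fpkm, config.nonexpr_sd_log2_fpkm, n),
    )

    # planted DE genes: expressed, not regulators, random direction/FC
    n_de = round(config.frac_de * n)
    pool = np.flatnonzero(expressed & ~is_trf)
    if n_de > pool.size:
        raise ValidationError(
            f"DE pool infeasible: need {n_de} expressed non-regulator genes, have {pool.size}"
        )
    de_idx = rng.choice(pool, size=n_de, replace=False)
    fc = rng.uniform(config.fc_range[0], config.fc_range[1], n_de)
    de_dir = rng.choice([-1.0, 1.0], size=n_de)

    # planted regulator targets: each regulator claims unclaimed DE genes
    # first and only shares targets once the pool is exhausted; a shared
    # target's DE direction follows the first regulator that claimed it
    reg_dir = rng.choice([-1.0, 1.0], size=config.n_planted_regulators)
    targets: list[np.ndarray] = []
    de_pos = {g: k for k, g in enumerate(de_idx)}
    claimed: set[int] = set()
    for k in range(config.n_planted_regulators):
        free = np.array([g for g in de_idx if g not in claimed], dtype=np.int64)
        if free.size >= config.targets_per_regulator:
            t = rng.choice(free, size=config.targets_per_regulator, replace=False)
        else:
            taken = np.array([g for g in de_idx if g in claimed], dtype=np.int64)
            extra = rng.choice(
                taken, size=config.targets_per_regulator - free.size, replace=False
            )
            t = np.concatenate([free, extra])
        targets.append(t)
        for g in t:
            if g not in claimed:
                de_dir[de_pos[g]] = reg_dir[k]
                claimed.add(g)

    offset = np.zeros(n)
    offset[de_idx] = de_dir * np.log2(fc) / 2.0
    mean_a = baseline + offset
    mean_b = baseline - offset

    # library sizes, log-normal around lib_size_mean with the given CV
    sigma_l = np.sqrt(np.log1p(config.lib_size_cv**2))
    lib = rng.lognormal(np.log(config.lib_size_mean) - sigma_l**2 / 2, sigma_l, 2 * m)

    # latent per-sample deviations
    u = rng.standard_normal((config.n_planted_regulators, 2 * m))
    dev = config.bio_sd * rng.standard_normal((n, 2 * m))
    for k, g in enumerate(planted_reg_idx):
        dev[g, :] = config.coupled_sd * u[k, :]

    # per-target latent loadings, calibrated for NB attenuation per condition
    cols = {cond_a: np.arange(m), cond_b: np.arange(m, 2 * m)}
    couplings = {cond_a: config.coupling_A, cond_b: config.coupling_B}
    cond_means = {cond_a: mean_a, cond_b: mean_b}
    gene_regs: dict[int, list[int]] = {}
    for k, t in enumerate(targets):
        for g in t:
            gene_regs.setdefault(int(g), []).append(k)
    for g, regs in gene_regs.items():
        for cond in (cond_a, cond_b):
            c = couplings[cond]
            idx = cols[cond]
            lam = np.zeros(len(regs))
            if c != 0.0:
                mu_g = 2.0 ** cond_means[cond][g] * lengths[g] * config.lib_size_mean / 1e9
                att_g = _attenuation(mu_g, config.nb_dispersion, config.coupled_sd)
                for j, k in enumerate(regs):
                    rg = planted_reg_idx[k]
                    mu_r = (
                        2.0 ** cond_means[cond][rg] * lengths[rg] * config.lib_size_mean / 1e9
                    )
                    att_r = _attenuation(mu_r, config.nb_dispersion, config.coupled_sd)
                    lam[j] = np.clip(c / (att_g * att_r), -0.99, 0.99)
                norm2 = float(np.sum(lam**2))
                if norm2 > 0.995**2:
                    lam *= 0.995 / np.sqrt(norm2)
                    norm2 = 0.995**2
            else:
                norm2 = 0.0
            resid = np.sqrt(max(0.0, 1.0 - norm2))
            z = rng.standard_normal(len(idx))
            dev[g, idx] = config.coupled_sd * (
                sum(l * u[k, idx] for l, k in zip(lam, regs)) + resid * z
            )

    log2_fpkm = np.where(
        np.arange(2 * m)[None, :] < m, mean_a[:, None], mean_b[:, None]
    ) + dev
    mu = 2.0**log2_fpkm * lengths[:, None] * lib[None, :] / 1e9
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    sample_ids = [f"{cond_a}{i + 1}" for i in range(m)] + [
        f"{cond_b}{i + 1}" for i in range(m)
    ]
    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids)
    )
    meta = pd.DataFrame(
        {"length_bp": lengths}, index=pd.Index(gene_ids, name="gene_id")
    )
    design = SampleDesign(
        pd.DataFrame(
            {"sample_id": sample_ids, "condition": [cond_a] * m + [cond_b] * m}
        ),
        (cond_a, cond_b),
    )
    truth = SimTruth(
        seed=config.seed,
        config=_jsonable(asdict(config)),
        de_genes={
            gene_ids[g]: {
                "direction": "up_in_A" if de_dir[k] > 0 else "up_in_B",
                "fc": float(fc[k]),
            }
            for k, g in enumerate(de_idx)
        },
        regulators={
            gene_ids[g]: {
                "coupling_A": config.coupling_A,
                "coupling_B": config.coupling_B,
                "targets": sorted(gene_ids[t] for t in targets[k]),
            }
            for k, g in enumerate(planted_reg_idx)
        },
        expressed_genes=[str(g) for g in gene_ids[expressed]],
        baseline_log2_fpkm={str(g): float(b) for g, b in zip(gene_ids, baseline)},
        gene_length={str(g): int(l) for g, l in zip(gene_ids, lengths)},
    )
    return SimResult(cm, meta, [str(g) for g in gene_ids[trf_idx]], design, truth)


def empirical_target_correlation(
    norm: NormalizedMatrix,
    design: SampleDesign,
    truth: SimTruth,
    condition: str,
) -> pd.Series:
    """Mean within-condition Pearson r between each planted regulator and
    its targets, on the log2(FPKM+1) scale (generator self-check)."""
    if condition == design.condition_a:
        samples = design.samples_a
    elif condition == design.condition_b:
        samples = design.samples_b
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    out = {}
    expr = norm.log_expr[samples]
    for reg, info in truth.regulators.items():
        x = expr.loc[reg].to_numpy()
        xs = x - x.mean()
        nx = np.linalg.norm(xs)
        rs = []
        for tgt in info["targets"]:
            y = expr.loc[tgt].to_numpy()
            ys = y - y.mean()
            ny = np.linalg.norm(ys)
            rs.append(0.0 if nx == 0 or ny == 0 else float(xs @ ys / (nx * ny)))
        out[reg] = float(np.mean(rs)) if rs else np.nan
    return pd.Series(out, dtype=float)
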