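"""End-to-end orchestration: normalize -> DE -> RIF -> bootstrap -> consensus.

A run is a pure function of its inputs and configuration: the manifest it
writes contains every threshold applied, every stage count, the seed, and
a SHA-256 hash per output file plus one over the manifest body, so reruns
with identical config and seed are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import rifseq
from rifseq import io as rio
from rifseq.bootstrap import BootstrapConfig, BootstrapResult, bootstrap_null, significant_regulators
from rifseq.consensus import consensus, evidence_sets
from rifseq.de import DEConfig, call_de
from rifseq.errors import ValidationError
from rifseq.normalization import normalize
from rifseq.rif import build_rif_inputs, compute_rif

logger = logging.getLogger("rifseq")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    counts_path: str
    genes_path: str
    trf_path: str
    design_path: str
    contrast: tuple[str, str]
    out_dir: str
    kb_path: str | None = None  # external knowledge-base regulator list
    de: DEConfig = field(default_factory=DEConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    min_trf_fpkm: float = 0.5
    correlation: str = "pearson"
    use_tmm: bool = True
    call_level: float = 0.95  # level used for the consensus RIF evidence

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        de = DEConfig(**raw.pop("de", {}))
        bs = BootstrapConfig(**{k: tuple(v) if k == "ci_levels" else v
                                for k, v in raw.pop("bootstrap", {}).items()})
        raw["contrast"] = tuple(raw["contrast"])
        return cls(de=de, bootstrap=bs, **raw)

    def validate(self) -> None:
        for name in ("counts_path", "genes_path", "trf_path", "design_path"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ValidationError(f"{name} does not exist: {p}")
        if self.kb_path is not None and not Path(self.kb_path).is_file():
            raise ValidationError(f"kb_path does not exist: {self.kb_path}")
        if self.call_level not in self.bootstrap.ci_levels:
            raise ValidationError(
                f"call_level {self.call_level} not among bootstrap ci_levels"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for one contrast; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    logger.info("reading inputs")
    counts = rio.read_counts(config.counts_path)
    meta = rio.read_gene_meta(config.genes_path, counts)
    trf_ids = rio.read_trf_list(config.trf_path)
    design = rio.read_design(config.design_path, config.contrast)
    design.validate_against(counts)
    trf_table = rio.annotate_trfs(trf_ids, counts)
    n_unmeasured = int((~trf_table["measured"]).sum())
    if n_unmeasured:
        logger.info("%d regulator ids not present in the count matrix", n_unmeasured)

    logger.info("normalizing (FPKM%s)", " + TMM" if config.use_tmm else "")
    norm = normalize(counts, meta, use_tmm=config.use_tmm)
    fpkm_out = norm.fpkm.round(6).reset_index().rename(columns={"index": "gene_id"})
    fpkm_out.columns = ["gene_id"] + list(norm.fpkm.columns)
    _write_tsv(fpkm_out, out / "fpkm.tsv")
    factors = pd.DataFrame(
        {
            "sample_id": norm.sample_ids,
            "lib_size": norm.lib_size.to_numpy(),
            "tmm_factor": norm.tmm_factor.to_numpy(),
        }
    )
    _write_tsv(factors, out / "factors.tsv")

    logger.info(
        "differential expression: FPKM > %g, FC >= %g, p <= %g",
        config.de.min_group_fpkm, config.de.min_fc, config.de.max_p,
    )
    de_table = call_de(counts, norm, design, config.de)
    _write_tsv(de_table, out / "de_results.tsv")
    expressed_genes = list(de_table.loc[de_table["expressed"], "gene_id"])
    de_genes = list(de_table.loc[de_table["de"], "gene_id"])
    logger.info("%d expressed genes, %d DE genes", len(expressed_genes), len(de_genes))
    if not de_genes:
        raise ValidationError("no DE genes; RIF undefined")

    logger.info("RIF scoring (%s correlation)", config.correlation)
    measured_trfs = [t for t in trf_ids if trf_table.loc[t, "measured"]]
    inputs = build_rif_inputs(
        norm, design, de_genes, measured_trfs,
        min_trf_fpkm=config.min_trf_fpkm, method=config.correlation,
    )
    warnings.extend(inputs.warnings)
    logger.info(
        "%d regulators pass the %g-FPKM filter (%d excluded)",
        len(inputs.trf_ids), config.min_trf_fpkm, len(inputs.excluded_trfs),
    )
    scores = compute_rif(inputs)
    scores_out = scores.copy()
    scores_out["expressed"] = True
    _write_tsv(scores_out, out / "rif_scores.tsv")

    logger.info("bootstrap null (%d iterations, seed %d)",
                config.bootstrap.n_iter, config.bootstrap.seed)
    boot = bootstrap_null(
        norm, design, expressed_genes, inputs.trf_ids, len(de_genes), config.bootstrap
    )
    if boot.n_skipped:
        warnings.append(f"{boot.n_skipped} bootstrap iterations skipped as degenerate")
    thr_rows = [
        {"score": score, "level": level, "lower": lo, "upper": hi}
        for (score, level), (lo, hi) in sorted(boot.thresholds.items())
    ]
    _write_tsv(pd.DataFrame(thr_rows), out / "bootstrap_thresholds.tsv")

    calls = {lvl: significant_regulators(scores, boot, lvl)
             for lvl in config.bootstrap.ci_levels}
    call_table = scores[["trf_id"]].copy()
    for lvl, tab in calls.items():
        call_table[f"significant_{int(lvl * 100)}"] = tab["significant"].to_numpy()
        call_table[f"rif1_flag_{int(lvl * 100)}"] = tab["rif1_flag"].to_numpy()
        call_table[f"rif2_flag_{int(lvl * 100)}"] = tab["rif2_flag"].to_numpy()
    _write_tsv(call_table, out / "rif_calls.tsv")

    kb_trfs = rio.read_trf_list(config.kb_path) if config.kb_path else []
    rif_sig = list(calls[config.call_level].loc[
        calls[config.call_level]["significant"], "trf_id"])
    de_trfs = [t for t in trf_ids if t in set(de_genes)]
    evidence = evidence_sets(de_trfs, rif_sig, [t for t in kb_trfs if t in set(trf_ids)],
                             trf_ids)
    cons = consensus(evidence)
    _write_tsv(cons, out / "consensus.tsv")

    manifest = {
        "package": "rifseq",
        "version": rifseq.__version__,
        "config": {
            **{k: v for k, v in asdict(config).items()},
        },
        "inputs": {
            "n_genes": counts.shape[0],
            "n_samples": counts.shape[1],
            "n_trf": len(trf_ids),
            "n_trf_unmeasured": n_unmeasured,
        },
        "counts": {
            "n_expressed": len(expressed_genes),
            "n_de": len(de_genes),
            "n_de_up_in_A": int(
                (de_table["de"] & (de_table["direction"] == "up_in_A")).sum()
            ),
            "n_de_up_in_B": int(
                (de_table["de"] & (de_table["direction"] == "up_in_B")).sum()
            ),
            "n_trf_expressed": len(inputs.trf_ids),
            "n_trf_excluded": len(inputs.excluded_trfs),
            "n_rif_significant": {
                str(lvl): int(tab["significant"].sum()) for lvl, tab in calls.items()
            },
            "n_de_trfs": len(de_trfs),
            "n_kb_trfs": len([t for t in kb_trfs if t in set(trf_ids)]),
            "consensus_tiers": {
                tier: int((cons["tier"] == tier).sum())
                for tier in ("all_three", "two", "one", "none")
            },
        },
        "bootstrap": {
            "n_iter": config.bootstrap.n_iter,
            "seed": config.bootstrap.seed,
            "n_pooled": boot.n_pooled,
            "n_skipped": boot.n_skipped,
        },
        "warnings": warnings,
        "outputs": {
            name: _sha256(out / name)
            for name in (
                "fpkm.tsv", "factors.tsv", "de_results.tsv", "rif_scores.tsv",
                "bootstrap_thresholds.tsv", "rif_calls.tsv", "consensus.tsv",
            )
        },
    }
    body = json.dumps(manifest, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(body.encode()).hexdigest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("run complete: %s", manifest["manifest_hash"][:12])
    return manifest
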