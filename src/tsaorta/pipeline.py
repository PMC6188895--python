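"""End-to-end orchestration of the cohort analysis stages.

Stages run in dependency order: synthetic-cohort generation (or ingestion of
a phenotype table + VCF) -> karyotype copy-number calls -> aortic z-scores ->
variant QC -> gene-based association -> Xp candidate ranking -> risk tables.
Each stage writes its table under the run directory and a manifest records
the configuration hash, seed and per-stage counts, so identical
configuration and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tsio
from .aortic import classify_aortopathy
from .association import exome_wide_threshold, fit_null_model, qq_data, skat_o_test
from .candidates import load_xp_gene_annotations, rank_xp_candidates
from .karyotype import dichotomize_copy_number, locus_copy_number, parse_iscn
from .qc import qc_chain
from .risk import attribute_profile, combinatorial_analysis
from .synthetic import EffectConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All thresholds and switches for a pipeline run.

    Defaults are the analysis' published operating points: 99% variant call
    rate, 5% sample missingness, HWE 1e-6, MAF 0.05 / r^2 0.2 / 50 kb / step
    5 for pruning, EV cuts (-0.3, +0.3), CADD 15, TAD z 1.9 and copy-number
    dichotomization at 1.1.
    """

    seed: int = 0
    n_subjects: int = 188
    min_call_rate: float = 0.99
    max_sample_missing: float = 0.05
    hwe_alpha: float = 1e-6
    maf_min: float = 0.05
    r2_max: float = 0.2
    ld_window_bp: int = 50_000
    ld_step_variants: int = 5
    ev1_cut: float = -0.3
    ev2_cut: float = 0.3
    cadd_threshold: float = 15.0
    tad_z_threshold: float = 1.9
    copy_threshold: float = 1.1
    mse_ar: float = 0.01
    mse_aao: float = 0.01
    n_perm: int = 999
    alpha: float = 0.05
    n_genes_exome: int = 19_392
    stages: tuple[str, ...] = (
        "simulate", "karyotype", "zscore", "qc", "assoc", "rank", "risk"
    )
    effects: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.min_call_rate <= 1, "min_call_rate in (0,1]"),
            (0 <= self.max_sample_missing <= 1, "max_sample_missing in [0,1]"),
            (0 < self.hwe_alpha < 1, "hwe_alpha in (0,1)"),
            (0 <= self.maf_min < 0.5, "maf_min in [0,0.5)"),
            (0 < self.r2_max <= 1, "r2_max in (0,1]"),
            (self.ld_window_bp > 0, "ld_window_bp positive"),
            (self.ld_step_variants > 0, "ld_step_variants positive"),
            (self.cadd_threshold >= 0, "cadd_threshold non-negative"),
            (self.copy_threshold >= 1, "copy_threshold >= 1"),
            (self.mse_ar > 0 and self.mse_aao > 0, "MSE positive"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eff = EffectConfig(**raw.pop("effects", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(effects=eff, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages and return the manifest (also written)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        if name not in cfg.stages:
            return
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - halt with a named stage
            _write_manifest(manifest, out)
            raise StageError(name, exc) from exc

    def stage_simulate():
        cohort = simulate_cohort(cfg.n_subjects, cfg.effects, seed=cfg.seed)
        state["cohort"] = cohort
        tsio.write_phenotype_table(cohort.subjects, out / "phenotypes.tsv")
        tsio.write_vcf(cohort.genotypes, out / "genotypes.vcf")
        cohort.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        return {"n_subjects": len(cohort.subjects)}

    def stage_karyotype():
        cohort = state["cohort"]
        rows = []
        for s, k in zip(cohort.subjects, cohort.karyotypes):
            copies = locus_copy_number(k)
            s.timp1_copies = copies
            rows.append(
                {
                    "id": s.id,
                    "karyotype": k.iscn,
                    "timp1_copies": copies,
                    "timp1_group": dichotomize_copy_number(copies, cfg.copy_threshold),
                    "y_present": int(k.y_present),
                }
            )
        pd.DataFrame(rows).to_csv(out / "karyotype_calls.tsv", sep="\t", index=False)
        one = sum(1 for r in rows if r["timp1_group"] == "1 copy")
        return {"n_one_copy": one, "n_multi_copy": len(rows) - one}

    def stage_zscore():
        cohort = state["cohort"]
        rows = []
        for s in cohort.subjects:
            flags = classify_aortopathy(s, cfg.tad_z_threshold)
            rows.append(
                {
                    "id": s.id,
                    "bsa_m2": s.bsa_m2,
                    "ar_z": s.ar.z if s.ar else np.nan,
                    "aao_z": s.aao.z if s.aao else np.nan,
                    "tad": flags["tad"] if flags["tad"] is not None else "",
                    "bav_with_tad": flags["bav_with_tad"]
                    if flags["bav_with_tad"] is not None
                    else "",
                }
            )
        pd.DataFrame(rows).to_csv(out / "zscores.tsv", sep="\t", index=False)
        measured = sum(1 for r in rows if r["tad"] != "")
        return {"n_with_measurement": measured}

    def stage_qc():
        cohort = state["cohort"]
        filtered, reports = qc_chain(
            cohort.genotypes, cfg.min_call_rate, cfg.max_sample_missing,
            cfg.hwe_alpha,
        )
        state["filtered"] = filtered
        log = pd.DataFrame(
            [
                {"stage": r.stage, "n_input": r.n_input, "n_removed": r.n_removed,
                 "n_retained": r.n_retained}
                for r in reports
            ]
        )
        log.to_csv(out / "qc_log.tsv", sep="\t", index=False)
        return {r.stage: r.n_removed for r in reports} | {
            "n_variants_final": filtered.n_variants
        }

    def stage_assoc():
        cohort = state["cohort"]
        m = state.get("filtered", cohort.genotypes)
        outcome = np.array([int(bool(s.bav)) for s in cohort.subjects])
        null = fit_null_model(outcome)
        genes = {"TIMP3": list(range(m.n_variants))}
        rows = []
        for gene, cols in genes.items():
            res = skat_o_test(
                m.calls[:, cols].astype(float), null, n_perm=cfg.n_perm,
                seed=cfg.seed, gene=gene,
            )
            rows.append(
                {"gene": res.gene, "n_variants": res.n_variants,
                 "p_value": res.p_value, "rho": res.rho_selected,
                 "method": res.method}
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / "association.tsv", sep="\t", index=False)
        qq_data(table["p_value"].tolist()).to_csv(
            out / "qq.tsv", sep="\t", index=False
        )
        return {
            "n_genes": len(rows),
            "threshold": exome_wide_threshold(cfg.n_genes_exome, cfg.alpha),
        }

    def stage_rank():
        ranked = rank_xp_candidates(load_xp_gene_annotations())
        ranked.to_csv(out / "xp_ranking.tsv", sep="\t", index=False)
        return {"n_ranked": len(ranked), "top_gene": ranked.iloc[0]["gene"]}

    def stage_risk():
        cohort = state["cohort"]
        for strat, fname in (("rs11547635", "attributes_by_rs11547635.tsv"),
                             ("timp1", "attributes_by_timp1.tsv")):
            attribute_profile(
                cohort.subjects, strat, cfg.copy_threshold
            ).to_csv(out / fname, sep="\t", index=False)
        combo_rows = []
        for outcome in ("bav", "bav_with_tad"):
            for g in combinatorial_analysis(
                cohort.subjects, outcome, cfg.copy_threshold
            ):
                combo_rows.append(
                    {
                        "outcome": outcome, "group": g.label, "n": g.n,
                        "n_affected": g.n_affected,
                        "percent_affected": g.percent_affected,
                        "odds_ratio": g.odds_ratio.or_point if g.odds_ratio else np.nan,
                        "ci_low": g.odds_ratio.ci_low if g.odds_ratio else np.nan,
                        "ci_high": g.odds_ratio.ci_high if g.odds_ratio else np.nan,
                        "p_value": g.odds_ratio.p_value if g.odds_ratio else np.nan,
                    }
                )
        pd.DataFrame(combo_rows).to_csv(
            out / "combinatorial.tsv", sep="\t", index=False
        )
        return {"n_combo_groups": len(combo_rows)}

    run_stage("simulate", stage_simulate)
    run_stage("karyotype", stage_karyotype)
    run_stage("zscore", stage_zscore)
    run_stage("qc", stage_qc)
    run_stage("assoc", stage_assoc)
    run_stage("rank", stage_rank)
    run_stage("risk", stage_risk)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def validate_inputs(
    phenotype_path: Optional[str | Path] = None,
    vcf_path: Optional[str | Path] = None,
) -> list[str]:
    """Schema dry-run over supplied inputs; returns the list of failures."""
    failures: list[str] = []
    if phenotype_path is not None:
        try:
            subjects = tsio.read_phenotype_table(phenotype_path)
        except Exception as exc:  # noqa: BLE001 - collect, don't crash
            failures.append(f"phenotype table: {exc}")
            subjects = []
        for s in subjects:
            if s.karyotype:
                try:
                    parse_iscn(s.karyotype)
                except Exception as exc:  # noqa: BLE001
                    failures.append(f"subject {s.id}: {exc}")
    if vcf_path is not None:
        try:
            first = Path(vcf_path).read_text().splitlines()[0]
            if not first.startswith("##fileformat=VCF"):
                failures.append(f"{vcf_path}: missing ##fileformat=VCF header")
        except Exception as exc:  # noqa: BLE001
            failures.append(f"vcf: {exc}")
    return failures
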