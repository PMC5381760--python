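"""End-to-end pipeline orchestration with reproducible per-stage seeds.

A single global seed deterministically derives one seed per stage (by hashing
the stage name), so any stage can be re-run in isolation and a full synthetic
run is byte-reproducible.  Every stage writes plain-text artifacts into the
run directory plus a machine-readable manifest echoing the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, csr as csr_mod, env_effects, maxent, overlap, records as rec_mod, synth
from .raster import read_ascii_grid, write_ascii_grid

logger = logging.getLogger("phenoniche")

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]


@dataclass
class PipelineConfig:
    # input paths (ignored in synthetic mode)
    records_path: str | None = None
    env_dir: str | None = None
    biomes_path: str | None = None
    ndvi_change_path: str | None = None
    # filtering
    max_age_years: int = 20
    ndvi_cutoff: float = 0.7
    dedup_km: float = 25.0
    reference_year: int = 2015
    # CSR
    csr_buffer_km: float = 200.0
    csr_n_sim: int = 500
    # SDM
    train_fraction: float = 0.7
    n_background: int = 10_000
    tol: float = 1e-5
    max_iter: int = 500
    sdm_replicates: int = 10
    r_cutoff: float = 0.7
    # comparison
    null_replicates: int = 100
    # synthetic mode
    synthetic: bool = False
    synthetic_config: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_age_years", "ndvi_cutoff", "dedup_km", "csr_buffer_km",
                     "csr_n_sim", "n_background", "tol", "max_iter",
                     "sdm_replicates", "null_replicates", "r_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _log_stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.2fs %s", name, time.perf_counter() - t0, extra)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run records -> association -> CSR -> SDM -> comparison -> drivers.

    Returns the run directory; partial outputs are retained on failure and the
    failing stage is named in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.echo(), "stages": {}}
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "synth" if config.synthetic else "load"
        t0 = time.perf_counter()
        if config.synthetic:
            scfg = synth.SyntheticConfig(
                seed=stage_seed(config.seed, "synth"), **config.synthetic_config
            )
            truth = synth.generate_truth(scfg)
            synth.write_truth(truth, out / "synthetic")
            records = truth.records
            env = truth.env
            biomes = truth.biomes
            ndvi_change = truth.ndvi_change
        else:
            for name, p in (("records", config.records_path),
                            ("environment layers", config.env_dir),
                            ("biome layer", config.biomes_path)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing required input: {name} ({p})")
            records = rec_mod.read_records(config.records_path)
            layer_paths = sorted(Path(config.env_dir).glob("*.asc"))
            if not layer_paths:
                raise FileNotFoundError(f"no .asc layers in {config.env_dir}")
            rasters = {p.stem: read_ascii_grid(p) for p in layer_paths}
            from .raster import EnvStack

            env = EnvStack.from_rasters(rasters)
            biomes = read_ascii_grid(config.biomes_path)
            ndvi_change = (
                read_ascii_grid(config.ndvi_change_path)
                if config.ndvi_change_path
                else None
            )
        manifest["stages"][stage] = {"n_records": len(records)}
        _log_stage(stage, t0, n_records=len(records))

        # ----------------------------------------------------------- records
        stage = "records"
        t0 = time.perf_counter()
        eligible = rec_mod.modelling_eligible(records)
        deduped = rec_mod.dedup_camera_traps(eligible, diameter_km=config.dedup_km)
        filtered, report = rec_mod.filter_records(
            deduped,
            reference_year=config.reference_year,
            ndvi_change=ndvi_change,
            ndvi_cutoff=config.ndvi_cutoff,
            max_age_years=config.max_age_years,
        )
        filtered = rec_mod.assign_biomes(filtered, biomes)
        filtered = rec_mod.attach_env_values(filtered, env)
        rec_mod.write_records(filtered, out / "records_filtered.csv")
        report.to_json(out / "filter_report.json")
        manifest["stages"][stage] = {
            "n_eligible": len(eligible),
            "n_after_dedup": len(deduped),
            "n_filtered": report.n_output,
        }
        _log_stage(stage, t0, n_out=report.n_output)

        # ------------------------------------------------------- association
        stage = "assoc"
        t0 = time.perf_counter()
        table = association.contingency_table(filtered)
        table.to_frame().to_csv(out / "contingency.csv", index=False)
        table.stats_json(out / "association_stats.json")
        freq = association.phenotype_frequency(filtered)
        (out / "frequency.json").write_text(json.dumps(freq, indent=2))
        manifest["stages"][stage] = {
            "chi_square": table.chi_square,
            "frequency_pct": freq["frequency_pct"],
        }
        _log_stage(stage, t0, chi2=round(table.chi_square, 3))

        # --------------------------------------------------------------- csr
        stage = "csr"
        t0 = time.perf_counter()
        polygon = csr_mod.build_study_polygon(filtered, buffer_km=config.csr_buffer_km)
        csr_out = {}
        for phen in ("non_melanistic", "melanistic"):
            subset = [r for r in filtered if r.phenotype == phen]
            if len(subset) < 3:
                logger.warning("csr: phenotype %s has <3 records; skipped", phen)
                continue
            result = csr_mod.csr_test(
                subset, polygon, n_sim=config.csr_n_sim,
                seed=stage_seed(config.seed, f"csr:{phen}"),
            )
            result.curves_frame().to_csv(out / f"csr_{phen}_curves.csv", index=False)
            csr_out[phen] = {"p_value": result.p_value,
                             "deviation": result.deviation_stat}
        (out / "csr.json").write_text(json.dumps(csr_out, indent=2))
        manifest["stages"][stage] = csr_out
        _log_stage(stage, t0)

        # --------------------------------------------------------------- sdm
        stage = "sdm"
        t0 = time.perf_counter()
        selected = maxent.select_predictors(
            env, n_points=min(config.n_background, int(env.mask.sum())),
            r_cutoff=config.r_cutoff, seed=stage_seed(config.seed, "predictors"),
        )
        env_sel = env.subset(selected)
        maps = {}
        sdm_meta = {"selected_predictors": selected, "models": {}}
        for phen in ("non_melanistic", "melanistic"):
            subset = [r for r in filtered if r.phenotype == phen]
            mean_map, evaluation = maxent.run_replicates(
                subset, env_sel,
                train_fraction=config.train_fraction,
                n_replicates=config.sdm_replicates,
                seed=stage_seed(config.seed, f"sdm:{phen}"),
                n_background=config.n_background,
                max_iter=config.max_iter, tol=config.tol,
            )
            maps[phen] = mean_map
            write_ascii_grid(out / f"suitability_{phen}.asc", mean_map)
            sdm_meta["models"][phen] = {
                "auc_test": evaluation.auc_test,
                "auc_test_se": evaluation.auc_test_se,
                "n_presence": evaluation.n_presence,
                "variable_importance": evaluation.variable_importance,
            }
        (out / "sdm.json").write_text(json.dumps(sdm_meta, indent=2))
        manifest["stages"][stage] = sdm_meta
        _log_stage(stage, t0)

        # ----------------------------------------------------------- compare
        stage = "compare"
        t0 = time.perf_counter()
        d, i_stat, rr = overlap.overlap_statistics(maps["melanistic"],
                                                   maps["non_melanistic"])
        paired = overlap.paired_suitability_test(filtered, maps["non_melanistic"],
                                                 maps["melanistic"])
        protocol = overlap.ModelProtocol(
            n_background=min(config.n_background, 2000),
            max_iter=config.max_iter, tol=config.tol,
            train_fraction=config.train_fraction,
        )
        equiv = overlap.equivalency_null(
            filtered, env_sel, n_replicates=config.null_replicates,
            protocol=protocol, seed=stage_seed(config.seed, "equivalency"),
        )
        equiv.to_json(out / "equivalency.json")
        compare_meta = {
            "D": d, "I": i_stat, "RR": rr,
            "p_D": equiv.p_D, "p_I": equiv.p_I, "p_RR": equiv.p_RR,
            "non_equivalent": bool(equiv.p_D <= 0.05),
            "paired_t": paired.t_statistic, "paired_p": paired.p_value,
            "mean_suitability_non_melanistic": paired.mean_a
            if paired.mean_a is not None else None,
        }
        (out / "comparison.json").write_text(json.dumps(compare_meta, indent=2))
        manifest["stages"][stage] = compare_meta
        _log_stage(stage, t0, D=round(d, 3))

        # ----------------------------------------------------------- drivers
        stage = "drivers"
        t0 = time.perf_counter()
        contrast = env_effects.driver_contrast(
            filtered, env_sel,
            {"melanistic": maps["melanistic"], "non_melanistic": maps["non_melanistic"]},
        )
        contrast.frame().to_csv(out / "driver_contrasts.csv", index=False)
        manifest["stages"][stage] = {"n_comparisons": contrast.n_comparisons}
        _log_stage(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
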