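"""Reproducible end-to-end runs: simulate -> trace -> network -> timecourse
-> quantify, with a config, per-stage outputs, and a checksum manifest.

Every source of randomness derives from the single config seed, and no output
embeds timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem
from .calibration import fit_calibration, inverse_predict, normalize_content
from .cspp_network import annotate_adduct_artifacts, build_network, export_network
from .features import SampleDesign, group_by_coelution, mean_by_timepoint, read_feature_table, write_feature_table
from .sil_trace import find_multiplets, multiplet_census, write_multiplets
from .synthetic_data import builtin_flax_spec, emit_feature_table, simulate_kinetics
from .timecourse import ConstantProfileError, hcluster, ratio_profiles, znorm

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger(__name__)

#: Dilution-series layout for the synthetic calibration stage (µM).
CALIBRATION_LEVELS = (20, 10, 5, 2, 1, 0.5, 0.2, 0.1, 0.05, 0.01)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Tolerances and options for one pipeline run.

    The two matching tolerances default to the reference workflow's values:
    +/- 0.005 Da for isotopologue spacing, +/- 0.002 Da for conversion mass
    differences.
    """

    seed: int = 0
    rt_tol: float = 0.1
    multiplet_mz_tol: float = 0.005
    cspp_mass_tol: float = 0.002
    max_k: int = 5
    cv: float = 0.2
    mz_sigma: float = 0.0003
    lod: float = 50.0
    linkage: str = "average"
    n_clusters: int = 5
    ratio_max_time_h: float = 24.0
    ruleset_path: str | None = None
    feature_table: str | None = None  # measured data instead of simulation
    design_table: str | None = None
    calibration_true_slope: float = 5e4
    calibration_noise_sd: float = 1.5e4
    extract_volume_L: float = 1e-3
    dry_weight_g: float = 4e-3

    def __post_init__(self) -> None:
        for name in ("rt_tol", "multiplet_mz_tol", "cspp_mass_tol", "cv", "mz_sigma"):
            if getattr(self, name) < 0 or (name.endswith("tol") and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.ruleset_path is not None and not Path(self.ruleset_path).exists():
            raise ValueError(f"ruleset path does not exist: {self.ruleset_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def ruleset(self) -> chem.Ruleset:
        if self.ruleset_path is None:
            return chem.builtin_ruleset()
        return chem.read_ruleset(self.ruleset_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages into ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ruleset = config.ruleset()
    manifest: dict = {"package_version": __version__, "seed": config.seed, "stages": []}
    manifest_path = outdir / "manifest.json"

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"].append(
            {"name": stage, "files": {f.name: _sha256(f) for f in sorted(files)}}
        )
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    def fail(stage: str, exc: Exception) -> StageError:
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return StageError(stage, exc)

    # -- simulate (or ingest) -------------------------------------------------
    try:
        if config.feature_table is not None:
            if config.design_table is None:
                raise ValueError("feature_table requires design_table")
            features, design = read_feature_table(config.feature_table, config.design_table)
            truth = None
        else:
            spec = builtin_flax_spec()
            kinetics = simulate_kinetics(spec)
            features, design, truth = emit_feature_table(
                spec,
                kinetics,
                cv=config.cv,
                mz_sigma=config.mz_sigma,
                lod=config.lod,
                seed=config.seed,
                mass_tol=config.cspp_mass_tol,
                rt_tol=config.rt_tol,
                ruleset=ruleset,
            )
        feat_path = outdir / "features.csv"
        write_feature_table(features.round(6), feat_path)
        design_path = outdir / "design.csv"
        design.to_csv(design_path)
        files = [feat_path, design_path]
        if truth is not None:
            links_path = outdir / "truth_multiplets.tsv"
            pd.DataFrame(
                sorted(truth.multiplet_links), columns=["light_id", "k", "heavy_id"]
            ).to_csv(links_path, sep="\t", index=False)
            edges_path = outdir / "truth_edges.tsv"
            pd.DataFrame(
                sorted(truth.edges), columns=["substrate", "product", "short"]
            ).to_csv(edges_path, sep="\t", index=False)
            files += [links_path, edges_path]
        record("simulate", files)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("simulate", exc) from exc

    # -- trace ----------------------------------------------------------------
    try:
        groups = group_by_coelution(features, config.rt_tol)
        multiplets = find_multiplets(
            features, groups, mz_tol=config.multiplet_mz_tol, max_k=config.max_k
        )
        mult_path = outdir / "multiplets.tsv"
        write_multiplets(multiplets, mult_path)
        census_path = outdir / "multiplet_census.json"
        census_path.write_text(
            json.dumps({str(k): v for k, v in multiplet_census(multiplets).items()}, indent=2)
            + "\n"
        )
        record("trace", [mult_path, census_path])
    except Exception as exc:  # noqa: BLE001
        raise fail("trace", exc) from exc

    # -- network --------------------------------------------------------------
    try:
        graph = build_network(
            features, ruleset, multiplets=multiplets, mass_tol=config.cspp_mass_tol
        )
        annotate_adduct_artifacts(graph, features, groups, mz_tol=config.multiplet_mz_tol)
        net_files = export_network(graph, outdir, "network")
        record("network", net_files)
    except Exception as exc:  # noqa: BLE001
        raise fail("network", exc) from exc

    # -- timecourse -----------------------------------------------------------
    try:
        means = mean_by_timepoint(features, design)
        heavy_ids = sorted({fid for m in multiplets for _, fid, _ in m.members})
        profiles = means.loc[[i for i in heavy_ids if i in means.index]]
        keep = [i for i in profiles.index if profiles.loc[i].std(ddof=1) > 0]
        profiles = profiles.loc[keep]
        files = []
        if len(profiles) >= 2:
            result = hcluster(profiles, linkage=config.linkage)
            labels = result.labels(k=min(config.n_clusters, len(profiles)))
            lab_path = outdir / "clusters_abundance.tsv"
            pd.Series(labels, name="cluster").rename_axis("id").to_csv(lab_path, sep="\t")
            nwk_path = outdir / "dendrogram_abundance.nwk"
            nwk_path.write_text(result.to_newick() + "\n")
            files += [lab_path, nwk_path]
        ratios = ratio_profiles(
            multiplets, features, design, max_time_h=config.ratio_max_time_h
        )
        ratio_rows = {}
        for rp in ratios:
            series = np.nan_to_num(np.asarray(rp.ratios, float))
            if series.std(ddof=1) > 0:
                ratio_rows[rp.heavy_id] = series
        if len(ratio_rows) >= 2:
            some_times = ratios[0].times
            ratio_df = pd.DataFrame.from_dict(ratio_rows, orient="index", columns=some_times)
            result = hcluster(ratio_df, linkage=config.linkage)
            labels = result.labels(k=min(config.n_clusters, len(ratio_df)))
            lab_path = outdir / "clusters_ratio.tsv"
            pd.Series(labels, name="cluster").rename_axis("id").to_csv(lab_path, sep="\t")
            files.append(lab_path)
        record("timecourse", files)
    except Exception as exc:  # noqa: BLE001
        raise fail("timecourse", exc) from exc

    # -- quantify -------------------------------------------------------------
    try:
        rng = np.random.default_rng(config.seed + 1)
        x = np.repeat(CALIBRATION_LEVELS, 3).astype(float)
        y = config.calibration_true_slope * x + rng.normal(0, config.calibration_noise_sd, x.size)
        model = fit_calibration(x, y)
        unknowns = {}
        for true_conc, m in (("2.0", 5), ("5.0", 5), ("12.0", 5)):
            y0 = config.calibration_true_slope * float(true_conc) + rng.normal(
                0, config.calibration_noise_sd / np.sqrt(m)
            )
            pred = inverse_predict(y0, model, m=m)
            per_seedling, per_gram = normalize_content(
                pred.estimate, config.extract_volume_L, dry_weight_g=config.dry_weight_g
            )
            unknowns[true_conc] = {
                "estimate_uM": pred.estimate,
                "ci_95": [pred.lower, pred.upper],
                "ug_per_seedling": per_seedling,
                "ug_per_g_dw": per_gram,
            }
        quant_path = outdir / "calibration.json"
        quant_path.write_text(
            json.dumps(
                {
                    "model": {
                        "slope": model.b1,
                        "intercept": model.b0,
                        "r_squared": model.r_squared,
                        "residual_sd": model.s,
                        "n": model.n,
                    },
                    "predictions": unknowns,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        record("quantify", [quant_path])
    except Exception as exc:  # noqa: BLE001
        raise fail("quantify", exc) from exc

    return manifest
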