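"""End-to-end orchestration: simulate-or-read, extract states, select the
horizon, compute transition energies, aggregate, exclude outliers, run the
group statistics, and record a run manifest."""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import brainte
from brainte import cohort, energy, io, states as st, stats
from brainte.aggregate import aggregate_cohort, exclude_outliers

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("brainte_out")
    seed: int = 0
    # simulation (used when no manifest is supplied)
    simulate: bool = True
    n_subjects: int = 30
    n_frames: int = 120
    n_regions: int = 86
    k_true: int = 4
    amplitude: float = 1.0
    noise_sd: float = 0.5
    subject_perturbation_sd: float = 0.05
    connectome_modules: int = 4
    connectome_density: float = 0.3
    # inputs (used when simulate is False)
    manifest: Path | None = None
    connectome: Path | None = None
    parcellation: Path | None = None
    # state extraction
    k: int | str = 4
    k_min: int = 2
    k_max: int = 14
    gain_threshold: float = 0.01
    n_replicates: int = 10
    stability_runs: int = 10
    # control energy
    t_horizon: float = energy.DEFAULT_T
    select_horizon: bool = False
    t_grid: list[float] | None = None
    n_steps: int = 1000
    # aggregation / stats
    iqr_factor: float = 1.5
    fdr_q: float = 0.05
    run_stats: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, lo in [("n_steps", 1), ("n_replicates", 1), ("stability_runs", 1)]:
            if getattr(self, name) < lo:
                raise ValueError(f"{name} must be >= {lo}")
        if not self.t_horizon > 0:
            raise ValueError("t_horizon must be > 0")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")

    @classmethod
    def from_file(cls, path: Path, **overrides) -> "PipelineConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _stage(manifest: dict, name: str, start: float, outputs: list[Path]) -> None:
    manifest["stages"].append(
        {
            "name": name,
            "wall_seconds": round(time.perf_counter() - start, 3),
            "outputs": {str(p): io.sha256_of(p) for p in outputs if p.exists()},
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as
    ``run_manifest.json`` in the output directory)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": brainte.__version__,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()},
        "stages": [],
        "warnings": [],
    }
    ss = np.random.SeedSequence(entropy=config.seed)
    sim_seed, extract_seed = [int(s.generate_state(1)[0]) for s in ss.spawn(2)]

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- stage: simulate or read inputs -------------------------------
        t0 = time.perf_counter()
        if config.simulate:
            parcellation = cohort.ParcellationScheme.default(config.n_regions)
            sc = cohort.generate_connectome(
                config.n_regions,
                config.connectome_modules,
                config.connectome_density,
                seed=sim_seed,
            )
            truth = cohort.SyntheticTruth(
                true_centroids=cohort.generate_state_centroids(
                    parcellation, config.k_true, config.amplitude, seed=sim_seed
                ),
                dwell_matrix=cohort.default_dwell_matrix(config.k_true),
                noise_sd=config.noise_sd,
                seed=sim_seed,
            )
            draw = cohort.generate_cohort(
                config.n_subjects,
                truth,
                parcellation,
                seed=sim_seed,
                n_frames=config.n_frames,
                subject_perturbation_sd=config.subject_perturbation_sd,
            )
            series_list, covariates = draw.series, draw.covariates
            series_dir = out / "series"
            series_dir.mkdir(exist_ok=True)
            paths = {}
            for s in series_list:
                p = series_dir / f"{s.subject_id}.tsv"
                io.write_series(p, s, list(parcellation.region_names))
                paths[s.subject_id] = p
            io.write_manifest(out / "manifest.tsv", covariates, paths)
            io.write_parcellation(out / "parcellation.tsv", parcellation)
            io.write_matrix_tsv(out / "connectome.tsv", sc, list(parcellation.region_names))
            pd.DataFrame(
                {
                    "subject_id": np.repeat(
                        list(draw.labels), [len(v) for v in draw.labels.values()]
                    ),
                    "frame": np.concatenate([np.arange(len(v)) for v in draw.labels.values()]),
                    "state": np.concatenate(list(draw.labels.values())),
                }
            ).to_csv(out / "true_labels.tsv", sep="\t", index=False)
            _stage(
                manifest,
                "simulate",
                t0,
                [out / "manifest.tsv", out / "parcellation.tsv", out / "connectome.tsv"],
            )
        else:
            if not (config.manifest and config.connectome and config.parcellation):
                raise ValueError("manifest, connectome and parcellation paths are required")
            parcellation = io.read_parcellation(config.parcellation)
            sc, _ = io.read_matrix_tsv(config.connectome)
            table = io.read_manifest(config.manifest)
            covariates = table.drop(columns=["series_path"])
            series_list = io.load_cohort_series(
                table, parcellation.n_regions, base_dir=Path(config.manifest).parent
            )
            _stage(manifest, "read_inputs", t0, [])

        # --- stage: state extraction --------------------------------------
        t0 = time.perf_counter()
        extraction = st.extract_states(
            series_list,
            parcellation,
            k=config.k,
            k_range=range(config.k_min, config.k_max + 1),
            gain_threshold=config.gain_threshold,
            n_replicates=config.n_replicates,
            stability_runs=config.stability_runs,
            seed=extract_seed,
        )
        manifest["k_selected"] = extraction.k_selected
        io.write_matrix_tsv(
            out / "group_centroids.tsv",
            extraction.states.group_centroids,
            list(parcellation.region_names),
        )
        pd.DataFrame(
            {"state": range(extraction.k_selected), "label": extraction.states.labels}
        ).to_csv(out / "state_labels.tsv", sep="\t", index=False)
        io.write_matrix_tsv(
            out / "ami_matrix.tsv",
            extraction.ami_matrix,
            [f"run_{i}" for i in range(extraction.ami_matrix.shape[0])],
        )
        if extraction.states.explained_variance_by_k:
            pd.DataFrame(
                sorted(extraction.states.explained_variance_by_k.items()),
                columns=["k", "explained_variance"],
            ).to_csv(out / "explained_variance_by_k.tsv", sep="\t", index=False)
        _stage(
            manifest,
            "extract_states",
            t0,
            [out / "group_centroids.tsv", out / "state_labels.tsv", out / "ami_matrix.tsv"],
        )

        # --- stage: horizon -----------------------------------------------
        t0 = time.perf_counter()
        system = energy.stabilize_system(sc, T=config.t_horizon)
        if config.select_horizon:
            t_grid = (
                np.asarray(config.t_grid, dtype=float)
                if config.t_grid is not None
                else energy.DEFAULT_T_GRID
            )
            t_star, grid, rhos = energy.select_time_horizon(
                extraction.states, list(extraction.subject_labels.values()), system, t_grid
            )
            pd.DataFrame({"T": grid, "spearman_rho": rhos}).to_csv(
                out / "horizon_sweep.tsv", sep="\t", index=False
            )
            system = energy.StabilizedSystem(A_norm=system.A_norm, B=system.B, T=t_star)
            manifest["t_horizon"] = t_star
            _stage(manifest, "select_horizon", t0, [out / "horizon_sweep.tsv"])
        else:
            manifest["t_horizon"] = config.t_horizon

        # --- stage: transition energies -----------------------------------
        t0 = time.perf_counter()
        gramian = energy.controllability_gramian(system)
        tensors: dict[str, np.ndarray] = {}
        for s in series_list:
            labels = extraction.subject_labels[s.subject_id]
            cents = st.subject_centroids(s, labels, extraction.states)
            tensors[s.subject_id] = energy.pairwise_te(
                system, gramian, cents.centroids, n_steps=config.n_steps
            )
        io.write_te_h5(out / "te_tensors.h5", tensors)
        io.write_te_long(out / "te_long.tsv", tensors, list(parcellation.region_names))
        _stage(manifest, "compute_te", t0, [out / "te_long.tsv"])

        # --- stage: aggregate + outliers ----------------------------------
        t0 = time.perf_counter()
        _, wide = aggregate_cohort(tensors, parcellation)
        wide.to_csv(out / "te_aggregated.tsv", sep="\t", index=False)
        report = exclude_outliers(
            wide.set_index("subject_id")["mean_global"], factor=config.iqr_factor
        )
        pd.DataFrame(
            {
                "subject_id": list(report.excluded_subject_ids),
                "lower_fence": report.lower_fence,
                "upper_fence": report.upper_fence,
            }
        ).to_csv(out / "outliers.tsv", sep="\t", index=False)
        manifest["n_outliers_excluded"] = report.n_excluded
        kept = wide[~wide["subject_id"].isin(report.excluded_subject_ids)]
        _stage(manifest, "aggregate", t0, [out / "te_aggregated.tsv", out / "outliers.tsv"])

        # --- stage: statistics --------------------------------------------
        if config.run_stats:
            t0 = time.perf_counter()
            families = {
                "global": ["mean_global"],
                "network": [f"mean_{n}" for n in parcellation.present_networks],
            }
            tables = stats.run_group_stats(kept, covariates, families, q=config.fdr_q)
            tables["ancova"].to_csv(out / "ancova_results.tsv", sep="\t", index=False)
            tables["posthoc"].to_csv(out / "posthoc.tsv", sep="\t", index=False)
            tables["spearman"].to_csv(out / "spearman.tsv", sep="\t", index=False)
            _stage(
                manifest,
                "stats",
                t0,
                [out / "ancova_results.tsv", out / "posthoc.tsv", out / "spearman.tsv"],
            )

    manifest["warnings"] = [str(w.message) for w in caught]
    io.write_json_atomic(out / "run_manifest.json", manifest)
    return manifest
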