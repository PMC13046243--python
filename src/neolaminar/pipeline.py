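"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis from a single config:
simulate (or load) inputs -> equivolumetric depth surfaces -> volume
sampling -> central moments -> parcel-wise developmental models ->
geometric eigenmodes -> spin tests -> eigenmode variance decomposition,
writing every intermediate artifact plus a machine-readable manifest.

All randomness derives from one master seed through named substreams,
so a rerun with the same config and seed is numerically byte-identical;
wall-clock timings go to a separate log file and never touch results.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .equivolume import CorticalRibbon, SurfaceMesh, build_depth_surfaces
from .errors import ContractError, NeolaminarError
from .glm import ModelSpec, compare_models, parcelwise_effects, interaction_effects
from .eigenmodes import compute_eigenmodes, upsample_parcel_map
from .moments import Parcellation, parcel_mean_profiles, profile_moments
from .phantom import (
    make_recovery_spec,
    simulate_cohort,
    simulate_phantom_geometry,
    simulate_subject_volume,
)
from .sampling import sample_profiles
from .spin import SphereProjection, eigenmode_variance_explained, spin_correlation_test

__all__ = ["PipelineConfig", "run_pipeline", "subject_parcel_moments",
           "cohort_parcel_moments"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (simulation mode by default).

    Set ``inputs`` to a dict of file paths (pial, white, sphere, labels,
    cohort, volumes: {subject_id: path}) to run on real data instead;
    a config with both an input block and ``simulate=True`` is invalid.
    """

    master_seed: int = 7
    simulate: bool = True
    inputs: dict | None = None
    # simulation block
    n_subjects: int = 40
    subdivision: int = 3
    n_parcels: int = 20
    white_radius: float = 10.0
    thickness: float = 2.0
    voxel_size: float = 0.5
    deep_ga_slope: float = 0.02
    superficial_pna_slope: float = 0.02
    noise_sd: float = 0.1
    # analysis block
    n_depths: int = 12
    boundary_depths: bool = True
    alpha: float = 0.025
    k_modes: int = 10
    n_perm: int = 1000
    clamp_negative: bool = False
    fit_interaction: bool = False
    fit_thickness: bool = False

    def validate(self):
        if self.simulate and self.inputs is not None:
            raise ContractError(
                "config must use exactly one of the simulation block or "
                "real-input paths, not both"
            )
        if not self.simulate and self.inputs is None:
            raise ContractError("neither simulation block nor input paths given")


def subject_parcel_moments(volume, stack, parcellation: Parcellation,
                           clamp_negative: bool = False,
                           vertex_mask=None) -> pd.DataFrame:
    """Sample one subject's volume and reduce to per-parcel moments.

    Returns a DataFrame indexed by parcel id with mu1, mu2 and
    n_vertices.  Negative sampled intensities are rejected by
    ``profile_moments`` unless ``clamp_negative`` clips them at zero.
    ``vertex_mask`` restricts averaging to a vertex subset (e.g. a
    parcel-interior mask) on top of the sampling-validity mask.
    """
    profiles = sample_profiles(volume, stack)
    intens = profiles.intensities
    if clamp_negative:
        intens = np.clip(intens, 0.0, None)
    mask = profiles.mask if vertex_mask is None else profiles.mask & vertex_mask
    table = parcel_mean_profiles(intens, parcellation, mask)
    depth_cols = [c for c in table.columns if c.startswith("depth_")]
    mu1, mu2 = profile_moments(table[depth_cols].to_numpy())
    return pd.DataFrame(
        {"mu1": mu1, "mu2": mu2, "n_vertices": table["n_vertices"].to_numpy()},
        index=table.index,
    )


def cohort_parcel_moments(geom, cohort, spec, stack, noise_seed: int,
                          clamp_negative: bool = False, vertex_mask=None):
    """Per-parcel moments for every cohort subject.

    Returns (mu1, mu2) DataFrames of shape parcels x subjects with
    subject ids as columns.  Subject ``i`` uses noise substream
    ``noise_seed + i``.
    """
    mu1_cols, mu2_cols = {}, {}
    for i, row in enumerate(cohort.itertuples(index=False)):
        vol = simulate_subject_volume(
            geom, row._asdict(), spec, seed=(noise_seed + i) % 2**31
        )
        m = subject_parcel_moments(vol, stack, geom.parcellation,
                                   clamp_negative=clamp_negative,
                                   vertex_mask=vertex_mask)
        mu1_cols[row.subject_id] = m["mu1"]
        mu2_cols[row.subject_id] = m["mu2"]
    return pd.DataFrame(mu1_cols), pd.DataFrame(mu2_cols)


def _substreams(master_seed: int, n: int = 4) -> list:
    """Named child seeds (each < 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis; returns the manifest dict.

    Artifacts are written under ``out_dir``; any stage failure aborts
    with the stage name and the last completed stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": [], "seeds": {}}
    log_lines = []
    last_good = "start"

    def declare(path):
        manifest["outputs"].append(str(Path(path).relative_to(out)))

    cohort_seed, geom_seed, noise_seed, spin_seed = _substreams(config.master_seed)
    manifest["seeds"] = {
        "master": config.master_seed, "cohort": cohort_seed,
        "geometry": geom_seed, "noise": noise_seed, "spin": spin_seed,
    }

    def stage(name, fn):
        nonlocal last_good
        t0 = time.perf_counter()
        try:
            result = fn()
        except NeolaminarError as exc:
            raise NeolaminarError(
                f"stage '{name}' failed (last good stage: '{last_good}'): {exc}"
            ) from exc
        log_lines.append(f"{name}: {time.perf_counter() - t0:.2f}s")
        last_good = name
        return result

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        cohort = stage("simulate-cohort", lambda: simulate_cohort(
            config.n_subjects, seed=cohort_seed))
        geom = stage("simulate-geometry", lambda: simulate_phantom_geometry(
            subdivision=config.subdivision, n_parcels=config.n_parcels,
            white_radius=config.white_radius, thickness=config.thickness,
            voxel_size=config.voxel_size, seed=geom_seed))
        spec = make_recovery_spec(
            deep_ga_slope=config.deep_ga_slope,
            superficial_pna_slope=config.superficial_pna_slope,
            noise_sd=config.noise_sd,
        )
        ribbon, sphere, parcellation = geom.ribbon, geom.sphere, geom.parcellation
        nio.write_cohort(out / "cohort.csv", cohort)
        declare(out / "cohort.csv")
        for name, mesh in (("pial", ribbon.pial), ("white", ribbon.white)):
            nio.write_surface(out / f"{name}.surf.gii", mesh)
            declare(out / f"{name}.surf.gii")
        nio.write_surface(
            out / "sphere.surf.gii",
            SurfaceMesh(sphere.coordinates, ribbon.pial.triangles))
        declare(out / "sphere.surf.gii")
        nio.write_labels(out / "parcels.label.gii", parcellation.labels)
        nio.write_labels(out / "parcels.csv", parcellation.labels)
        declare(out / "parcels.label.gii")
        declare(out / "parcels.csv")
    else:
        paths = config.inputs
        cohort = stage("read-cohort", lambda: nio.read_cohort(paths["cohort"]))
        pial = nio.read_surface(paths["pial"])
        white = nio.read_surface(paths["white"])
        ribbon = CorticalRibbon(pial=pial, white=white)
        sphere_mesh = nio.read_surface(paths["sphere"])
        norms = np.linalg.norm(sphere_mesh.vertices, axis=1)
        sphere = SphereProjection(sphere_mesh.vertices / norms[:, None])
        parcellation = Parcellation(labels=nio.read_labels(paths["labels"]))
        geom = spec = None
        last_good = "read-inputs"

    # --- depth surfaces and moments --------------------------------------
    stack = stage("depth-surfaces", lambda: build_depth_surfaces(
        ribbon, n_depths=config.n_depths, boundary=config.boundary_depths))
    for d, surf in enumerate(stack.surfaces, start=1):
        nio.write_surface(out / f"depth_{d:02d}.surf.gii", surf)
        declare(out / f"depth_{d:02d}.surf.gii")

    if config.simulate:
        mu1, mu2 = stage("sample-moments", lambda: cohort_parcel_moments(
            geom, cohort, spec, stack, noise_seed,
            clamp_negative=config.clamp_negative))
    else:
        def _real_moments():
            cols1, cols2 = {}, {}
            for sid, vpath in paths["volumes"].items():
                vol = nio.read_volume(vpath)
                m = subject_parcel_moments(vol, stack, parcellation,
                                           clamp_negative=config.clamp_negative)
                cols1[sid], cols2[sid] = m["mu1"], m["mu2"]
            return pd.DataFrame(cols1), pd.DataFrame(cols2)
        mu1, mu2 = stage("sample-moments", _real_moments)
    for name, df in (("mu1", mu1), ("mu2", mu2)):
        df.index.name = "parcel_id"
        df.to_csv(out / f"parcel_{name}.csv")
        declare(out / f"parcel_{name}.csv")

    # --- parcel-wise models ----------------------------------------------
    model_terms = [
        ("pma", ("pma", "sex")),
        ("ga", ("ga", "pna", "sex")),
        ("pna", ("ga", "pna", "sex")),
    ]
    effect_maps = {}

    def _fit_all():
        for moment_name, table in (("mu1", mu1), ("mu2", mu2)):
            for term, preds in model_terms:
                preds_used = preds + (("thickness",) if config.fit_thickness else ())
                mspec = ModelSpec(response=moment_name, predictors=preds_used,
                                  term_of_interest=term)
                eff = parcelwise_effects(table, cohort, mspec, alpha=config.alpha)
                effect_maps[(moment_name, term)] = eff
                eff.to_csv(out / f"effects_{term}_{moment_name}.csv")
                declare(out / f"effects_{term}_{moment_name}.csv")
            if config.fit_interaction:
                eff = interaction_effects(table, cohort, alpha=config.alpha,
                                          response=moment_name)
                effect_maps[(moment_name, "ga_x_pna")] = eff
                eff.to_csv(out / f"effects_interaction_{moment_name}.csv")
                declare(out / f"effects_interaction_{moment_name}.csv")
    stage("parcel-models", _fit_all)

    # --- global model comparison -----------------------------------------
    def _compare():
        rows = {}
        for moment_name, table in (("mu1", mu1), ("mu2", mu2)):
            y = table.mean(axis=0).to_numpy()
            fits, ftests = compare_models(
                y, cohort,
                [("sex",), ("ga", "sex"), ("pna", "sex"), ("ga", "pna", "sex")],
            )
            fits.to_csv(out / f"model_comparison_{moment_name}.csv", index=False)
            ftests.to_csv(out / f"model_comparison_{moment_name}_ftests.csv",
                          index=False)
            declare(out / f"model_comparison_{moment_name}.csv")
            declare(out / f"model_comparison_{moment_name}_ftests.csv")
            rows[moment_name] = float(np.corrcoef(
                cohort["pma_weeks"], y)[0, 1])
        return rows
    global_pma_corr = stage("model-comparison", _compare)

    # --- eigenmodes -------------------------------------------------------
    mid = SurfaceMesh(
        0.5 * (ribbon.pial.vertices + ribbon.white.vertices),
        ribbon.pial.triangles,
    )
    basis = stage("eigenmodes", lambda: compute_eigenmodes(mid, k=config.k_modes))
    pd.DataFrame({"mode": np.arange(1, config.k_modes + 1),
                  "eigenvalue": basis.eigenvalues}).to_csv(
        out / "eigenvalues.csv", index=False)
    declare(out / "eigenvalues.csv")
    nio.write_metric(out / "modes.func.gii", basis.modes,
                     names=[f"mode{i + 1}" for i in range(config.k_modes)])
    declare(out / "modes.func.gii")

    # --- spin tests and eigenmode R^2 ------------------------------------
    def _spin_all():
        spin_out = {}
        r2_rows = []
        for (moment_name, term), eff in sorted(effect_maps.items()):
            if term == "ga_x_pna":
                continue
            vmap = upsample_parcel_map(eff, parcellation)
            for mode_num in (2, 3, 4):
                res = spin_correlation_test(
                    vmap, basis.mode(mode_num), sphere,
                    n_perm=config.n_perm, seed=spin_seed)
                spin_out[f"{term}_{moment_name}_mode{mode_num}"] = {
                    "r_obs": res.r_obs, "p_spin": res.p_spin,
                    "n_perm": res.n_perm, "seed": res.seed,
                }
            r2 = eigenmode_variance_explained(vmap, basis)
            for _, row in r2.iterrows():
                r2_rows.append({
                    "moment": moment_name, "term": term,
                    "modes": "+".join(map(str, row["modes"])),
                    "r2": row["r2"],
                })
        with open(out / "spin_results.json", "w") as fh:
            json.dump(spin_out, fh, indent=2, sort_keys=True)
        declare(out / "spin_results.json")
        pd.DataFrame(r2_rows).to_csv(out / "eigenmode_r2.csv", index=False)
        declare(out / "eigenmode_r2.csv")
        return spin_out
    spin_out = stage("spin-tests", _spin_all)

    # --- summary and manifest --------------------------------------------
    summary = {
        "n_subjects": len(cohort),
        "n_parcels_analyzed": int(len(mu1)),
        "ga_pna_corr": float(np.corrcoef(cohort["ga_weeks"],
                                         cohort["pna_weeks"])[0, 1]),
        "global_pma_corr": global_pma_corr,
        "n_significant": {
            f"{term}_{m}": int(eff["significant"].sum())
            for (m, term), eff in sorted(effect_maps.items())
        },
        "spin": spin_out,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    declare(out / "summary.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return manifest
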