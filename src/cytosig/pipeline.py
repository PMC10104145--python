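"""End-to-end study orchestration.

``run_study`` drives the full analysis on one cytokine dataset (simulated
or loaded): plate cleaning, then the four canonical models —

* PLSR regressing timepoint on cytokines within the transgenic group,
* PLSR regressing timepoint within wild-type (healthy aging),
* PLS-DA of genotype at the earliest timepoint,
* PLS-DA of genotype at the latest timepoint,

each with cross-validated latent-variable selection, a permutation test,
orthogonalization, VIP scoring and signature extraction — followed by a
disease-vs-aging signature comparison, and optionally the count-based
differential-expression stage and the extracellular-flux stage on their
own synthetic inputs.  Every artifact lands in the output directory and is
listed in a manifest together with the seeds that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import luminex, model_selection, nanostring, pls, seahorse, signature
from .errors import ConfigError
from .synthetic import (
    CytokineSimConfig,
    gen_cytokine_study,
    gen_nanostring_counts,
    gen_ocr_traces,
)

__all__ = ["RunConfig", "run_pls_recipe", "run_study"]

# fixed per-stage seed offsets so each stage is independently reproducible
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "plsr_ad": 101,
    "plsr_wt": 202,
    "plsda_first": 303,
    "plsda_last": 404,
    "nanostring": 505,
    "seahorse": 606,
}


@dataclass
class RunConfig:
    out_dir: str = "cytosig_run"
    seed: int = 17
    sim: CytokineSimConfig = None  # None -> defaults with derived seed
    plate_csv: str = None  # load a real plate instead of simulating
    lod: float = 3.2
    min_beads: int = 20
    grouping: tuple = ("genotype", "timepoint_days")
    n_iter: int = 100
    n_perm: int = 100
    candidates: tuple = (1, 2, 3, 4, 5)
    vip_threshold: float = 1.0
    run_de: bool = True
    run_mito: bool = True
    force: bool = False


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pls_recipe(
    X: pd.DataFrame,
    response,
    seed: int,
    candidates=(1, 2, 3, 4, 5),
    n_iter: int = 100,
    n_perm: int = 100,
    vip_threshold: float = 1.0,
    positive_class=None,
    name: str = "model",
) -> dict:
    """One full modeling recipe on a cleaned matrix subset.

    Cross-validates the latent-variable count, fits the final model on all
    samples, orthogonalizes, scores VIPs, extracts the signature, and runs
    the permutation test at the chosen component count.
    """
    y = np.asarray(response)
    cv = model_selection.cross_validate(
        X.to_numpy(dtype=float), y, candidates=candidates,
        n_iter=n_iter, seed=seed,
    )
    model = pls.fit_model(X, y, cv.chosen)
    model = pls.orthogonalize(model, positive_class=positive_class)
    vip = pls.vip_scores(model)
    perm = model_selection.permutation_test(
        X.to_numpy(dtype=float), y, cv.chosen,
        n_perm=n_perm, seed=seed + 1, n_iter=n_iter,
    )
    sig = signature.extract_signature(
        model,
        vip,
        threshold=vip_threshold,
        provenance={
            "name": name,
            "n_lv": cv.chosen,
            "mode": cv.mode,
            "cv_score": cv.chosen_score,
            "p_value": perm.p_value,
            "n_samples": len(y),
        },
    )
    return {"cv": cv, "model": model, "vip": vip, "perm": perm,
            "signature": sig, "name": name}


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "files": []}

    def write(path: Path, writer) -> None:
        if path.exists() and not config.force:
            raise ConfigError(
                f"refusing to overwrite {path}; pass force=True"
            )
        writer(path)
        manifest["files"].append(str(path))

    # -- data -----------------------------------------------------------
    truth = None
    if config.plate_csv is not None:
        plate = pd.read_csv(config.plate_csv)
    else:
        sim = config.sim or CytokineSimConfig(
            seed=_stage_seed(config.seed, "simulate")
        )
        plate, truth = gen_cytokine_study(sim)
        write(out / "plate.csv", lambda p: plate.to_csv(p, index=False))
        write(out / "ground_truth.json", truth.to_json)

    matrix = luminex.clean_plate(
        plate, lod=config.lod, min_beads=config.min_beads,
        grouping=config.grouping,
    )
    write(out / "cleaned_matrix.csv", matrix.to_csv)
    manifest["stages"]["clean"] = {
        "n_samples": len(matrix.values),
        "n_cytokines": matrix.values.shape[1],
        "dropped_cytokines": matrix.dropped,
        "n_bead_removals": int(len(matrix.bead_removals)),
        "n_outlier_removals": int(matrix.provenance["outlier_removed"].sum()),
    }

    # -- the four canonical models --------------------------------------
    meta = matrix.metadata
    tps = sorted(meta["timepoint_days"].unique())
    recipes = {
        "plsr_ad": (meta["genotype"] == "AD", "timepoint_days", None),
        "plsr_wt": (meta["genotype"] == "WT", "timepoint_days", None),
        "plsda_first": (meta["timepoint_days"] == tps[0], "genotype", "AD"),
        "plsda_last": (meta["timepoint_days"] == tps[-1], "genotype", "AD"),
    }
    results = {}
    for name, (mask, resp_col, pos) in recipes.items():
        sub = matrix.values.loc[mask.values]
        resp = meta.loc[mask.values, resp_col].to_numpy()
        res = run_pls_recipe(
            sub,
            resp,
            seed=_stage_seed(config.seed, name),
            candidates=config.candidates,
            n_iter=config.n_iter,
            n_perm=config.n_perm,
            vip_threshold=config.vip_threshold,
            positive_class=pos,
            name=name,
        )
        results[name] = res
        write(
            out / f"{name}_signature.json", res["signature"].to_json
        )
        write(
            out / f"{name}_loadings.csv",
            lambda p, r=res: pls.loadings_table(r["model"], r["vip"]).to_csv(
                p, index=False
            ),
        )
        manifest["stages"][name] = {
            "n_lv": res["cv"].chosen,
            "mode": res["cv"].mode,
            "cv_score": res["cv"].chosen_score,
            "p_value": res["perm"].p_value,
            "signature": res["signature"].members["cytokine"].tolist(),
        }

    comparison = signature.compare_signatures(
        results["plsr_ad"]["signature"], results["plsr_wt"]["signature"]
    )
    write(
        out / "ad_vs_aging_comparison.json",
        lambda p: Path(p).write_text(json.dumps(comparison, indent=1)),
    )
    manifest["stages"]["comparison"] = comparison

    if truth is not None:
        found = results["plsr_ad"]["signature"].directions()
        planted = truth.signature
        manifest["stages"]["signature_recovery"] = {
            "planted": planted,
            "recovered": {
                c: int(found.get(c, 0)) for c in planted
            },
            "all_recovered": all(
                found.get(c) == s for c, s in planted.items()
            ),
        }

    # -- downstream stages ----------------------------------------------
    if config.run_de:
        ns_seed = _stage_seed(config.seed, "nanostring")
        rng = np.random.default_rng(ns_seed)
        de_plan = {int(g): float(l) for g, l in zip(
            rng.choice(40, size=6, replace=False),
            [2.0, 1.5, -1.5, -2.0, 1.8, -1.8],
        )}
        counts, de_truth = gen_nanostring_counts(
            de_genes=de_plan, seed=ns_seed
        )
        de, norm, kept_hk = nanostring.run_de(counts, cell_type="neuron")
        write(out / "de_table.csv", de.to_csv)
        hits = de.index[de["significant"]].tolist()
        manifest["stages"]["nanostring"] = {
            "kept_housekeepers": kept_hk,
            "n_significant": len(hits),
            "planted": sorted(de_truth.de_genes),
            "planted_recovered": sorted(
                set(hits) & set(de_truth.de_genes)
            ),
        }

    if config.run_mito:
        ocr, ocr_truth = gen_ocr_traces(
            n_wells_per_arm=48,
            n_replicates_per_arm=6,
            p_dead=0.02,
            p_nonresponder=0.02,
            seed=_stage_seed(config.seed, "seahorse"),
        )
        kept, excl = seahorse.qc_wells(ocr)
        reps = seahorse.aggregate_and_normalize(ocr, kept)
        write(out / "mito_replicates.csv", lambda p: reps.to_csv(p, index=False))
        tests = {}
        for metric in ("basal", "maximal", "atp_production", "proton_leak"):
            t, p = seahorse.compare_groups(reps, metric)
            tests[metric] = {"t": t, "p": p}
        manifest["stages"]["seahorse"] = {
            "n_wells_kept": len(kept),
            "exclusions": excl,
            "tests": tests,
        }

    write(
        out / "manifest.json",
        lambda p: Path(p).write_text(json.dumps(manifest, indent=1, default=str)),
    )
    return manifest
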