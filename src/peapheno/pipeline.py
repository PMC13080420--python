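"""Pipeline runners tying the stages into the full workflow.

``run_simulate`` writes a complete synthetic experiment to disk (images,
manual-measurement table, ground truth, manifest); ``run_extract`` reads
the manifest and produces the long trait table; ``run_stats`` turns a
trait table into the report bundle (sensitivity indices, ANOVA, variance
components and heritability, CV, correlation matrices/networks, PCA).
With fixed seeds every stage is deterministic, so simulate -> extract ->
stats yields identical artifacts across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from peapheno import derived, phantoms, stats
from peapheno.image_traits import (
    SIDE_VIEW_ANGLES,
    FluorescencePair,
    PlantMask,
    ReflectanceStack,
    SegmentationPolicy,
    extract_record,
    SideViewSet,
    segment_plant,
)
from peapheno.manifest import (
    ExperimentManifest,
    PipelineConfig,
    PlantEntry,
    write_trait_table,
)
from peapheno.reference import TRAITS
from peapheno.simulate import CONDITIONS, _accession_ids, _species_assignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# simulate


def _plant_phantom(rng: np.random.Generator, drought: bool, seed: int) -> phantoms.PlantPhantomSpec:
    """Draw a per-plant phantom; drought shrinks stature and branching."""
    shrink = 0.65 if drought else 1.0
    n_branches = int(rng.integers(2, 6))
    return phantoms.PlantPhantomSpec(
        stem_height=int(rng.integers(60, 120) * shrink),
        n_branches=n_branches,
        branch_lengths=tuple(rng.uniform(10, 30, n_branches) * shrink),
        leaf_radii=tuple(rng.uniform(2.5, 5.5, n_branches)),
        azimuths=tuple(rng.uniform(0, 360, n_branches)),
        canopy_spread=40,
        seed=seed,
    )


def run_simulate(config: PipelineConfig, outdir: str | Path) -> ExperimentManifest:
    """Generate a synthetic experiment on disk and return its manifest.

    Per plant: six side-view PNGs, a 3-band reflectance TIFF, an (F0, Fm)
    fluorescence TIFF, plus a ground-truth CSV row; one manual-measurement
    CSV covers all plants, generated consistently with the image ground
    truth (fresh weight tracks digital biomass, height tracks pixel height).
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    accessions = _accession_ids(config.n_accessions)
    species = dict(zip(accessions, _species_assignment(config.n_accessions)))

    entries, gt_rows, manual_rows = [], [], []
    for acc in accessions:
        # accession-level latent vigor and physiology, shared across reps
        vigor = rng.uniform(0.8, 1.2)
        fvfm_base = rng.uniform(0.74, 0.80)
        for cond in CONDITIONS[: config.n_conditions]:
            drought = cond == "drought"
            for rep in range(1, config.n_reps + 1):
                plant_id = f"{acc}_{cond}_r{rep}"
                pseed = int(rng.integers(0, 2**31 - 1))
                spec = _plant_phantom(np.random.default_rng(pseed), drought, pseed)
                views, gt, frames = phantoms.render_side_views(spec)

                side_paths = {}
                for angle, frame in zip(SIDE_VIEW_ANGLES, frames):
                    rel = f"images/{plant_id}_side{angle:03d}.png"
                    Image.fromarray(frame).save(outdir / rel)
                    side_paths[angle] = rel

                ndvi = float(np.clip(rng.normal(0.21 - (0.01 if drought else 0.0), 0.02), 0.02, 0.6))
                npci = float(np.clip(rng.normal(0.18 - (0.04 if drought else 0.0), 0.02), 0.01, 0.6))
                stack, _, gt_stack = phantoms.render_reflectance_stack(
                    {"NDVI": ndvi, "NPCI": npci}, shape=(64, 64),
                    mask_fraction=float(0.25 * (0.9 if drought else 1.0) * rng.uniform(0.85, 1.15)),
                    seed=pseed,
                )
                refl_rel = f"images/{plant_id}_refl.tif"
                tifffile.imwrite(
                    outdir / refl_rel,
                    np.stack([stack.r_red, stack.r_green, stack.r_blue]).astype(np.float32),
                    photometric="minisblack",
                )

                target_fvfm = float(np.clip(
                    fvfm_base + (0.01 if drought else 0.0) + rng.normal(0, 0.005), 0.0, 0.99
                ))
                pair, _ = phantoms.render_fluorescence_pair(
                    target_fvfm, shape=(64, 64), mask_fraction=0.25, seed=pseed
                )
                fluo_rel = f"images/{plant_id}_f0fm.tif"
                tifffile.imwrite(
                    outdir / fluo_rel,
                    np.stack([pair.f0, pair.fm]).astype(np.float32),
                    photometric="minisblack",
                )

                entries.append(PlantEntry(
                    plant_id=plant_id, accession=acc, species_group=species[acc],
                    condition=cond, replicate=rep,
                    side_view_paths=side_paths,
                    reflectance_path=refl_rel, fluorescence_path=fluo_rel,
                ))
                db = float(np.mean(gt.true_area_per_angle))
                gt_rows.append({
                    "plant_id": plant_id, "DB": db,
                    "CH": float(np.mean(gt.true_hull_area)),
                    "height_px": gt.true_height,
                    "TA": gt_stack.true_top_area,
                    **{k: v for k, v in gt_stack.true_index_values.items()},
                    "PhE": target_fvfm,
                })

                # manual measurements track the image ground truth
                fw = vigor * db * 0.08 * (0.7 if drought else 1.0) * rng.uniform(0.95, 1.05)
                dw = fw * rng.uniform(0.15, 0.20)
                sfw = fw * rng.uniform(1.15, 1.30)
                leaf_dw = dw * rng.uniform(0.28, 0.34)
                tla = leaf_dw * rng.uniform(220, 260)
                ph = gt.true_height * rng.uniform(0.9, 1.1)
                water = rng.uniform(400, 600) * (0.45 if drought else 1.0)
                manual_rows.append({
                    "plant_id": plant_id, "accession": acc, "condition": cond,
                    "replicate": rep, "FW": fw, "DW": dw, "SFW": sfw,
                    "leaf_DW": leaf_dw, "TLA": tla, "PH": ph, "water_used": water,
                })

    pd.DataFrame(gt_rows).to_csv(outdir / "ground_truth.csv", index=False)
    pd.DataFrame(manual_rows).to_csv(outdir / "manual_measurements.csv", index=False)
    manifest = ExperimentManifest(
        plants=entries, seed=config.seed,
        note="synthetic phantom experiment", manual_csv="manual_measurements.csv",
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# extract


def _segmentation_policies(config: PipelineConfig) -> tuple[SegmentationPolicy, SegmentationPolicy]:
    side = SegmentationPolicy(
        view="side", blue_margin=config.blue_margin,
        min_component_px=config.min_component_px,
    )
    top = SegmentationPolicy(
        view="top", excess_green_threshold=config.excess_green_threshold,
        min_component_px=config.min_component_px,
    )
    return side, top


def run_extract(manifest: ExperimentManifest, config: PipelineConfig,
                root: str | Path = ".") -> pd.DataFrame:
    """Extract the long trait table from a manifest's images.

    Unreadable images flag the plant and the run continues; missing
    modalities leave their traits absent for that plant. If the manifest
    names a manual-measurement CSV, the manual and derived ratio traits
    (FW, DW, PH, TLA, SLA, LWR, LAR, RWC, WUE) are appended.
    """
    root = Path(root)
    side_policy, _ = _segmentation_policies(config)
    manual = None
    if manifest.manual_csv is not None:
        manual = pd.read_csv(root / manifest.manual_csv).set_index("plant_id")

    rows = []
    for plant in manifest.plants:
        try:
            views = None
            if plant.side_view_paths:
                masks = []
                for angle in SIDE_VIEW_ANGLES:
                    img = np.asarray(Image.open(root / plant.side_view_paths[angle]))
                    masks.append(segment_plant(img, side_policy))
                views = SideViewSet(masks=tuple(masks), plant_id=plant.plant_id)

            stack = None
            if plant.reflectance_path is not None:
                bands = tifffile.imread(root / plant.reflectance_path)
                # top-view mask from excess green on the reflectance bands
                rgb = np.stack([bands[0], bands[1], bands[2]], axis=-1)
                top_policy = SegmentationPolicy(
                    view="top", excess_green_threshold=config.excess_green_threshold,
                    min_component_px=config.min_component_px,
                )
                mask = segment_plant(rgb, top_policy)
                stack = ReflectanceStack(
                    r_red=bands[0], r_green=bands[1], r_blue=bands[2], mask=mask
                )

            pair = None
            if plant.fluorescence_path is not None:
                f0fm = tifffile.imread(root / plant.fluorescence_path)
                pair = FluorescencePair(
                    f0=f0fm[0], fm=f0fm[1], mask=PlantMask(f0fm[1] > 0)
                )

            rec = extract_record(plant.plant_id, views=views, stack=stack, pair=pair)
        except (OSError, ValueError) as exc:
            logger.warning("plant %s failed extraction: %s", plant.plant_id, exc)
            continue

        values = {
            "SA": rec.SA, "DB": rec.DB, "CH": rec.CH, "SOL": rec.SOL,
            "TA": rec.TA, "NDVI": rec.NDVI, "NPCI": rec.NPCI,
            "PSRI": rec.PSRI, "GLI": rec.GLI, "PhE": rec.PhE,
        }
        if manual is not None and plant.plant_id in manual.index:
            m = manual.loc[plant.plant_id]
            values.update({
                "FW": m["FW"], "DW": m["DW"], "PH": m["PH"], "TLA": m["TLA"],
                "SLA": derived.specific_leaf_area(m["TLA"], m["leaf_DW"]),
                "LWR": derived.leaf_weight_ratio(m["leaf_DW"], m["DW"]),
                "LAR": derived.leaf_area_ratio(m["TLA"], m["DW"]),
                "RWC": derived.relative_water_content(m["FW"], m["DW"], m["SFW"]),
                "WUE": derived.water_use_efficiency(rec.DB, m["water_used"]),
            })
        for trait, value in values.items():
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            rows.append({
                "accession": plant.accession, "species_group": plant.species_group,
                "condition": plant.condition, "replicate": plant.replicate,
                "trait": trait, "value": float(value),
            })
    return pd.DataFrame(
        rows, columns=["accession", "species_group", "condition", "replicate", "trait", "value"]
    )


# ---------------------------------------------------------------------------
# stats


def run_stats(table: pd.DataFrame, config: PipelineConfig,
              outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Full report bundle from a trait table; everything written as CSV.

    Emits: sensitivity_indices.csv, anova.csv, variance_components.csv
    (components, relative contributions, h2), cv.csv, correlation matrices
    and network edge lists per condition, and the PCA loadings / scores /
    explained-variance files. Traits failing a stage's preconditions are
    skipped with a logged reason.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = [t for t in TRAITS if t in set(table["trait"])] or sorted(set(table["trait"]))
    out: dict[str, pd.DataFrame] = {}

    si = derived.sensitivity_table(table, traits=traits)
    si.to_csv(outdir / "sensitivity_indices.csv", index=False)
    out["sensitivity_indices"] = si

    anova_rows, vc_rows, cv_rows = [], [], []
    for trait in traits:
        try:
            an = stats.two_way_anova(table, trait)
        except ValueError as exc:
            logger.warning("skipping ANOVA for %s: %s", trait, exc)
            continue
        frame = an.table.reset_index(names="term")
        frame.insert(0, "trait", trait)
        anova_rows.append(frame)

        vc = stats.estimate_variance_components(an)
        contrib = stats.relative_contributions(
            vc, include_residual=config.include_residual_contribution
        )
        h2 = stats.heritability(vc, basis=config.heritability_basis)
        vc_rows.append({
            "trait": trait,
            "sigma2_G": vc.sigma2_g, "sigma2_C": vc.sigma2_c,
            "sigma2_GC": vc.sigma2_gc, "sigma2_E": vc.sigma2_e,
            "se_G": vc.se["genotype"], "se_C": vc.se["condition"],
            "se_GC": vc.se["genotype:condition"], "se_E": vc.se["residual"],
            "truncated": ";".join(vc.truncated),
            **{f"pct_{k}": v for k, v in contrib.items()},
            "h2": h2,
        })
        cv = stats.coefficient_of_variation(table, trait)
        cv_rows.append({"trait": trait, **{f"cv_{c}": v for c, v in cv.items()}})

    if anova_rows:
        out["anova"] = pd.concat(anova_rows, ignore_index=True)
        out["anova"].to_csv(outdir / "anova.csv", index=False)
    if vc_rows:
        out["variance_components"] = pd.DataFrame(vc_rows)
        out["variance_components"].to_csv(outdir / "variance_components.csv", index=False)
    if cv_rows:
        out["cv"] = pd.DataFrame(cv_rows)
        out["cv"].to_csv(outdir / "cv.csv", index=False)

    for cond in sorted(table["condition"].unique()):
        corr = stats.correlation_matrix(table, cond)
        corr.to_csv(outdir / f"correlation_{cond}.csv")
        out[f"correlation_{cond}"] = corr
        net = stats.correlation_network(
            table, cond, draw_threshold=config.draw_threshold,
            strong_threshold=config.strong_threshold,
        )
        edges = pd.DataFrame(
            [{"trait_a": a, "trait_b": b, **d} for a, b, d in net.edges(data=True)]
        )
        edges.to_csv(outdir / f"network_edges_{cond}.csv", index=False)
        out[f"network_edges_{cond}"] = edges

    try:
        pca = stats.pca_biplot(table)
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        pca.scores.to_csv(outdir / "pca_scores.csv")
        pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(pca.explained_variance_ratio))],
            "explained_variance_ratio": pca.explained_variance_ratio,
        }).to_csv(outdir / "pca_explained.csv", index=False)
        out["pca_loadings"] = pca.loadings
    except ValueError as exc:
        logger.warning("skipping PCA: %s", exc)

    write_trait_table(table, outdir / "trait_table.csv")
    return out
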