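"""End-to-end pipeline: simulate -> calibrate -> quantify -> orient -> enrich
-> qrich -> rbh, with deterministic per-stage seeding and a run manifest.

Each stochastic stage consumes a child seed derived from the master seed and
the stage name, so re-running with the same configuration and seed produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import nucfish
from nucfish import io as nio
from nucfish.config import PipelineConfig
from nucfish.enrichment import (
    filter_matrix, impute_mnar, log2_transform, sam_welch_test, volcano_table,
)
from nucfish.profiles import calibrate_border, dapi_centroid, extract_profile
from nucfish.profiles import nucleus_mask as _nucleus_mask
from nucfish.seqstats import qrich_scan_records, rbh_classify
from nucfish.spots import (
    classify_molecule_species, detect_spots, group_spots_to_molecules,
    localize_molecule, orientation_analysis, per_cell_counts,
)
from nucfish.synthetic import (
    LfqGroundTruth, OpticsParams, SceneGeometry, generate_cell_scene,
    generate_hit_tables, generate_lfq_dataset, generate_protein_sequences,
    PROBE_CHANNELS,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "quantify", "orient", "enrich", "qrich", "rbh")

# roughly the per-cell transcript load reported for the long reporter mRNA
# (a few molecules per cell), spread over the observed species/location mix
DEFAULT_SCENE_COUNTS = {
    ("intact", "cytoplasm"): 2,
    ("intact", "nucleus"): 1,
    ("five_prime_part", "periphery"): 2,
    ("three_prime_part", "cytoplasm"): 1,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[str]
    file_digests: dict[str, str] = field(default_factory=dict)

    def add_file(self, path: Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.file_digests[Path(path).name] = h

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                    "file_digests": self.file_digests,
                },
                fh, indent=2, sort_keys=True,
            )


def _scene_stack_paths(outdir: Path, i: int):
    return outdir / f"scene_{i:03d}.tiff", outdir / f"truth_{i:03d}.tsv"


def run_pipeline(
    config: PipelineConfig,
    outdir,
    stages: list[str] | None = None,
    n_scenes: int = 3,
    scene_counts: dict | None = None,
    orientation_fraction: float = 0.81,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    Image-dependent stages (calibrate/quantify/orient) require the simulate
    stage's outputs in ``outdir``; a missing upstream file raises an error
    naming the stage that should have produced it.
    """
    config.validate()
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), seed=config.master_seed,
        version=nucfish.__version__, stages=stages,
    )
    geometry = SceneGeometry(**vars(config.geometry))
    optics = OpticsParams(
        voxel_size=config.optics.voxel_size,
        psf_sigma=config.optics.psf_sigma,
        background_level=config.optics.background_level,
        photon_scale=config.optics.photon_scale,
        noise_model=config.optics.noise_model,
        dapi_falloff=config.optics.dapi_falloff,
    )
    scene_counts = scene_counts or DEFAULT_SCENE_COUNTS

    for stage in stages:
        t0 = time.monotonic()
        if stage == "simulate":
            seed = child_seed(config.master_seed, stage)
            from nucfish.synthetic import render_image

            for i in range(n_scenes):
                scene = generate_cell_scene(
                    scene_counts, orientation_fraction, seed=seed + i,
                    geometry=geometry, compaction_um=config.pairing_radius_um,
                )
                stack = render_image(scene, optics, seed=seed + 1000 + i)
                tiff_path, truth_path = _scene_stack_paths(outdir, i)
                nio.write_stack(tiff_path, stack)
                nio.scene_truth_frame(scene).to_csv(truth_path, sep="\t", index=False)
                manifest.add_file(tiff_path)
                manifest.add_file(truth_path)
            matrix, record = generate_lfq_dataset(
                LfqGroundTruth(), seed=child_seed(config.master_seed, "simulate-lfq")
            )
            nio.write_lfq_tsv(outdir / "lfq_matrix.tsv", matrix)
            (outdir / "lfq_truth.json").write_text(
                json.dumps({k: record[k] for k in ("enriched_ids", "flagged_ids")})
            )
            records, qtruth = generate_protein_sequences(
                40, planted_qrich_per_protein=[1] * 20 + [0] * 20,
                seed=child_seed(config.master_seed, "simulate-seq"),
                residue=config.qrich_residue, window=config.qrich_window,
                min_count=config.qrich_min_count,
            )
            nio.write_fasta(outdir / "proteins.fasta", records)
            (outdir / "qrich_truth.json").write_text(json.dumps(qtruth))
            manifest.add_file(outdir / "lfq_matrix.tsv")
            manifest.add_file(outdir / "proteins.fasta")

        elif stage in ("calibrate", "quantify", "orient"):
            stacks, truths = [], []
            for i in range(n_scenes):
                tiff_path, truth_path = _scene_stack_paths(outdir, i)
                if not tiff_path.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {tiff_path.name}; run 'simulate' first"
                    )
                stacks.append(nio.read_stack(tiff_path))
                truths.append(pd.read_csv(truth_path, sep="\t"))

            if stage == "calibrate":
                profiles = []
                for stack in stacks:
                    centroid = dapi_centroid(stack)
                    # four orthogonal in-plane rays per nucleus
                    for direction in ([0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]):
                        d = np.asarray(direction, float)
                        hi = (np.array(stack.shape_zyx) - 1) * np.array(stack.voxel_size)
                        t_max = np.inf
                        for ax in range(3):
                            if d[ax] > 0:
                                t_max = min(t_max, (hi[ax] - centroid[ax]) / d[ax])
                            elif d[ax] < 0:
                                t_max = min(t_max, -centroid[ax] / d[ax])
                        start = centroid + 0.999 * t_max * d
                        profiles.append(
                            extract_profile(
                                stack, start, centroid, config.sampling_step_um,
                                smooth_sigma_um=float(np.mean(config.optics.psf_sigma[1:])),
                            )
                        )
                rows = []
                for method, marker in (("marker_peak", "nup"), ("intersection", "cyto")):
                    cal = calibrate_border(
                        profiles, method=method, marker_channel=marker,
                        threshold=config.cytoplasm_likelihood_cut,
                    )
                    rows.append(
                        {
                            "method": method, "mean": cal.mean, "sd": cal.sd,
                            "n": cal.n, "fraction_below_33": cal.fraction_below_33,
                        }
                    )
                path = outdir / "border_calibration.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                manifest.add_file(path)

            elif stage == "quantify":
                probe_map = {k: tuple(v) for k, v in config.probe_map.items()}
                per_cell = {}
                for i, stack in enumerate(stacks):
                    spots = []
                    for ch in PROBE_CHANNELS:
                        spots += detect_spots(
                            stack, ch, threshold_k=config.detection_k_mad,
                            psf_sigma=config.optics.psf_sigma,
                        )
                    molecules = group_spots_to_molecules(
                        spots, config.pairing_radius_um
                    )
                    centroid = dapi_centroid(stack)
                    for mol in molecules:
                        classify_molecule_species(mol, probe_map)
                        localize_molecule(
                            mol, stack, centroid, band=config.periphery_band,
                            cyto_cut=config.periphery_band[0],
                            sampling_step=config.sampling_step_um,
                        )
                    per_cell[f"cell_{i:03d}"] = molecules
                    nio.molecules_frame(molecules).to_csv(
                        outdir / f"molecules_{i:03d}.tsv", sep="\t", index=False
                    )
                table, summary = per_cell_counts(per_cell)
                table.to_csv(outdir / "counts.tsv", sep="\t")
                summary.to_csv(outdir / "counts_summary.tsv", sep="\t")
                manifest.add_file(outdir / "counts.tsv")

            else:  # orient
                mol_path = outdir / "molecules_000.tsv"
                if not mol_path.exists():
                    raise FileNotFoundError(
                        "stage 'orient' needs molecules tables; run 'quantify' first"
                    )
                results = []
                probe_map = {k: tuple(v) for k, v in config.probe_map.items()}
                for i, stack in enumerate(stacks):
                    spots = []
                    for ch in PROBE_CHANNELS:
                        spots += detect_spots(
                            stack, ch, threshold_k=config.detection_k_mad,
                            psf_sigma=config.optics.psf_sigma,
                        )
                    molecules = group_spots_to_molecules(spots, config.pairing_radius_um)
                    centroid = dapi_centroid(stack)
                    for mol in molecules:
                        classify_molecule_species(mol, probe_map)
                        localize_molecule(
                            mol, stack, centroid, band=config.periphery_band,
                            sampling_step=config.sampling_step_um,
                        )
                    res = orientation_analysis(
                        molecules, _nucleus_mask(stacks[i]), stacks[i].voxel_size
                    )
                    results.append(res)
                n_el = sum(r.n_eligible for r in results)
                n_first = sum(r.n_five_prime_first for r in results)
                frame = pd.concat([r.records for r in results], ignore_index=True)
                frame.to_csv(outdir / "orientation.tsv", sep="\t", index=False)
                summary = {
                    "n_eligible": n_el,
                    "n_five_prime_first": n_first,
                    "fraction": (n_first / n_el) if n_el else None,
                }
                (outdir / "orientation_summary.json").write_text(json.dumps(summary))
                manifest.add_file(outdir / "orientation.tsv")

        elif stage == "enrich":
            lfq_path = outdir / "lfq_matrix.tsv"
            if not lfq_path.exists():
                raise FileNotFoundError(
                    "stage 'enrich' needs lfq_matrix.tsv; run 'simulate' first"
                )
            matrix = nio.read_lfq_tsv(lfq_path)
            filtered = filter_matrix(matrix)
            logged = log2_transform(filtered)
            imputed = impute_mnar(
                logged, width=config.imputation_width,
                downshift=config.imputation_downshift,
                seed=child_seed(config.master_seed, "enrich-impute"),
            )
            result = sam_welch_test(
                imputed, s0=config.s0, n_randomizations=config.n_randomizations,
                fdr=config.fdr, seed=child_seed(config.master_seed, "enrich-test"),
            )
            result.table.to_csv(outdir / "enrichment.tsv", sep="\t")
            volcano_table(result).to_csv(outdir / "volcano.tsv", sep="\t")
            manifest.add_file(outdir / "enrichment.tsv")

        elif stage == "qrich":
            fasta = outdir / "proteins.fasta"
            if not fasta.exists():
                raise FileNotFoundError(
                    "stage 'qrich' needs proteins.fasta; run 'simulate' first"
                )
            records = nio.read_fasta(fasta)
            scores = qrich_scan_records(
                records, window=config.qrich_window,
                min_count=config.qrich_min_count, residue=config.qrich_residue,
            )
            scores.to_csv(outdir / "qrich.tsv", sep="\t")
            manifest.add_file(outdir / "qrich.tsv")

        elif stage == "rbh":
            fasta = outdir / "proteins.fasta"
            if not fasta.exists():
                raise FileNotFoundError(
                    "stage 'rbh' needs proteins.fasta; run 'simulate' first"
                )
            ids = [pid for pid, _ in nio.read_fasta(fasta)]
            seed = child_seed(config.master_seed, "rbh")
            rng = np.random.default_rng(seed)
            taxa = ["yeast", "worm", "mouse", "plasmodium"]
            homolog_of = {
                t: set(rng.choice(ids, size=len(ids) // 4, replace=False).tolist())
                for t in taxa
            }
            fwd, rev = generate_hit_tables(ids, taxa, homolog_of, seed=seed)
            calls = rbh_classify(fwd, rev, ids, config.rbh_evalue_cutoff)
            calls.to_csv(outdir / "rbh.tsv", sep="\t")
            manifest.add_file(outdir / "rbh.tsv")

        logger.info("stage %s finished in %.2f s", stage, time.monotonic() - t0)

    manifest.write(outdir / "manifest.json")
    return manifest
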