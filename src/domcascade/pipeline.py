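"""End-to-end orchestration: simulate/assign -> dataset -> statistics -> trends.

Every stage reads and writes plain TSV/JSON files in the output directory, so
runs are resumable and deterministic stages are byte-reproducible.  A run
manifest records the configuration hash, the seed, package version, and the
SHA-256 of every written artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assignment import AssignmentConfig, Peak, assign_peaklist
from .cascade_stats import class_profile, universal_fractions, universal_set, weighted_mass
from .dataset_io import DOMDataset
from .gradient_inference import GradientDesign, fit_trend
from .rarefied_similarity import SimilarityConfig, similarity_to_reference
from .synthetic_data import SimulationConfig, simulate_dataset, simulate_peaklist

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, stage settings and output directory for one run."""

    out_dir: str
    seed: int = 0
    # either simulate inputs ...
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # ... or point at existing peak-list / metadata TSVs
    peaklist_path: str | None = None
    metadata_path: str | None = None
    reference_path: str | None = None
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    run_trends: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        asg = AssignmentConfig(**raw.pop("assignment", {}))
        simcfg = SimilarityConfig(**raw.pop("similarity", {}))
        return cls(simulation=sim, assignment=asg, similarity=simcfg, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"].append(
            {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3), **counts}
        )
        logger.info("stage %s done (%s)", stage, counts)

    def write(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=index, float_format="%.12g")
        manifest["artifacts"][name] = _sha256(path)

    # ----- obtain a dataset ------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        sim = config.simulation
        sim = SimulationConfig(**{**asdict_no_table(sim), "seed": config.seed})
        dataset, truth = simulate_dataset(sim)
        dataset.to_tsv(out / "dataset.tsv", out / "metadata.tsv")
        manifest["artifacts"]["dataset.tsv"] = _sha256(out / "dataset.tsv")
        manifest["artifacts"]["metadata.tsv"] = _sha256(out / "metadata.tsv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "universal_core_size": len(truth.universal_core),
                    "expected_universal_share": truth.expected_universal_share.round(6).to_dict(),
                },
                indent=1,
                sort_keys=True,
            )
        )
        manifest["artifacts"]["ground_truth.json"] = _sha256(out / "ground_truth.json")
        record("simulate", t0, n_samples=dataset.n_samples, n_formulas=dataset.n_formulas)
    else:
        for label, p in (("peak list", config.peaklist_path), ("metadata", config.metadata_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {label} input file: {p}")
        peaks = pd.read_csv(config.peaklist_path, sep="\t")
        tables = {}
        for sid, grp in peaks.groupby("sample_id", sort=False):
            plist = [
                Peak(float(r.mz), float(r.intensity), str(r.replicate_id))
                for r in grp.itertuples()
            ]
            intensity, _log = assign_peaklist(plist, config.assignment)
            tables[sid] = intensity
        long = pd.concat(
            {sid: s for sid, s in tables.items()}, names=["sample_id", "formula"]
        ).rename("intensity").reset_index()
        long.to_csv(out / "dataset.tsv", sep="\t", index=False, float_format="%.12g")
        dataset = DOMDataset.from_tsv(out / "dataset.tsv", config.metadata_path)
        manifest["artifacts"]["dataset.tsv"] = _sha256(out / "dataset.tsv")
        record("assign", t0, n_samples=dataset.n_samples, n_formulas=dataset.n_formulas)

    # ----- cascade statistics ---------------------------------------------
    t0 = time.perf_counter()
    pool = universal_set(dataset)
    fractions = universal_fractions(dataset, pool)
    write("universal_fractions.tsv", fractions)
    write("class_profile_universal.tsv", class_profile(dataset, "count", "universal", pool))
    wm_frames = []
    for cls in sorted(dataset.descriptors["compound_class"].unique()):
        wm = weighted_mass(dataset, cls, "non-universal", pool)
        wm.insert(0, "compound_class", cls)
        wm_frames.append(wm)
    write("weighted_mass_nonuniversal.tsv", pd.concat(wm_frames))
    record("universal/classes/wmass", t0, n_universal=len(pool))

    # ----- rarefied similarity --------------------------------------------
    if config.reference_path:
        t0 = time.perf_counter()
        reference = pd.read_csv(config.reference_path, sep="\t")["formula"].tolist()
        units = {
            sid: dataset.intensities.index[dataset.intensities[sid] > 0].tolist()
            for sid in dataset.sample_ids
        }
        simcfg = SimilarityConfig(
            depth_d=config.similarity.depth_d,
            iterations=config.similarity.iterations,
            seed=config.seed,
            reference_rarefied=config.similarity.reference_rarefied,
        )
        write("similarity.tsv", similarity_to_reference(units, reference, simcfg), index=False)
        record("similarity", t0, n_units=len(units))

    # ----- gradient trends -------------------------------------------------
    if config.run_trends:
        t0 = time.perf_counter()
        soil = fractions.join(dataset.metadata).query("sample_type == 'soil'").copy()
        soil["depth_cm"] = soil["depth_cm"].astype(int).astype(str) + "cm"
        soil["share"] = soil["intensity_pct"] / 100.0
        design = GradientDesign(
            data=soil, response="share", focal="depth_cm",
            covariates=("position", "catchment"), family="gaussian-logit",
        )
        trend = fit_trend(design)
        write("trend_universal_intensity_emmeans.tsv", trend.emmeans, index=False)
        write("trend_universal_intensity_contrasts.tsv", trend.contrasts, index=False)
        record("trends", t0, df_resid=trend.df_resid)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def asdict_no_table(sim: SimulationConfig) -> dict:
    d = {k: v for k, v in sim.__dict__.items() if k != "class_table"}
    return d
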