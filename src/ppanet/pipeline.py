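"""End-to-end pipeline: load -> filter -> project -> calibrate -> cluster ->
enrich -> mine -> predict, with a run manifest for exact reproducibility.

A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so any stage
can be rerun in isolation with the same randomness it saw inside the full
run.  The manifest echoes the configuration verbatim and records a SHA-256
checksum for every file written; no timestamps enter any output, so a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import DEFAULT_FRACTIONS, overlap_curve, select_threshold
from .clustering import cluster_network, filter_clusters, mcl
from .enrichment import enrich, mine_chemical_disease, results_frame
from .io import (
    DEFAULT_EVIDENCE_CODES,
    DEFAULT_MIN_DISEASE_SCORE,
    filter_annotations,
    filter_negations,
    read_annotations,
    read_associations,
    read_reference_interactions,
)
from .prediction import predict_targets
from .projection import project
from .synthetic import WorldSpec, generate_world

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

STAGES = (
    "load",
    "filter",
    "project",
    "calibrate",
    "cluster",
    "enrich",
    "mine",
    "predict",
)


def stage_seed(seed: int, stage_index: int) -> int:
    """Derive a per-stage seed from the global one (kept below 2**31)."""
    ss = np.random.SeedSequence(seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    With no input paths the run starts from a generated synthetic world
    (``world`` holds its parameters); otherwise ``associations_path``,
    ``reference_path``, ``go_path`` and ``disease_path`` point at the TSV
    inputs.  All thresholds mirror the method's operating points: top-8%
    edge fraction, minimum cluster size 5, corrected alpha 0.05, disease
    score cutoff 60, pull-down inclusion threshold 0.1.
    """

    out_dir: str = "ppanet_run"
    seed: int = 0
    associations_path: str | None = None
    reference_path: str | None = None
    go_path: str | None = None
    disease_path: str | None = None
    world: WorldSpec = field(default_factory=WorldSpec)
    fraction: float = 0.08
    calibration_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    calibration_permutations: int = 10
    inflation: float = 2.0
    expansion: int = 2
    prune: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 200
    min_cluster_size: int = 5
    alpha: float = 0.05
    evidence_codes: tuple[str, ...] = tuple(sorted(DEFAULT_EVIDENCE_CODES))
    min_disease_score: float = DEFAULT_MIN_DISEASE_SCORE
    pulldown_threshold: float = 0.1
    randomizations: int = 10_000
    predict_chemicals: tuple[str, ...] | int = 2

    def validate(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        if self.inflation <= 1.0:
            raise ValueError("inflation must exceed 1")
        if self.alpha <= 0.0 or self.alpha >= 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.randomizations < 100:
            raise ValueError("randomizations must be at least 100")
        paths = (self.associations_path, self.reference_path)
        if any(paths) and not all(paths):
            raise ValueError(
                "associations_path and reference_path must be given together"
            )
        self.world.validate()

    @property
    def synthetic(self) -> bool:
        return self.associations_path is None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"] = dataclasses.asdict(self.world)
        d["calibration_fractions"] = list(self.calibration_fractions)
        d["evidence_codes"] = list(self.evidence_codes)
        if isinstance(self.predict_chemicals, tuple):
            d["predict_chemicals"] = list(self.predict_chemicals)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        world_raw = raw.pop("world", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if world_raw:
            cfg.world = WorldSpec(**world_raw)
        for name in ("calibration_fractions", "evidence_codes"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        if isinstance(cfg.predict_chemicals, list):
            cfg.predict_chemicals = tuple(cfg.predict_chemicals)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ppanet_version": __version__,
        "config": config.to_dict(),
        "stages": [],
    }

    def _relpath(p: Path) -> str:
        try:
            return str(Path(p).relative_to(out))
        except ValueError:  # inputs outside the run directory stay absolute
            return str(p)

    def record(stage: str, outputs: dict[str, Path], params: dict | None = None) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "seed": stage_seed(config.seed, STAGES.index(stage)),
                "parameters": params or {},
                "outputs": {
                    k: {"path": _relpath(p), "sha256": _sha256(p)}
                    for k, p in outputs.items()
                },
            }
        )

    def fail(stage: str, exc: Exception) -> "RuntimeError":
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # --- load ---
    stage = "load"
    try:
        if config.synthetic:
            world = generate_world(config.world, seed=stage_seed(config.seed, 0))
            world_paths = world.write(out / "world")
            associations = world.associations
            reference = world.reference
            go_ann = world.go_annotations
            disease_ann = world.disease_annotations
            record(stage, world_paths, {"synthetic": True})
        else:
            associations = read_associations(config.associations_path)
            reference = read_reference_interactions(config.reference_path)
            go_ann = (
                read_annotations(config.go_path, "go") if config.go_path else None
            )
            disease_ann = (
                read_annotations(config.disease_path, "disease")
                if config.disease_path
                else None
            )
            inputs = {
                "associations": Path(config.associations_path),
                "reference": Path(config.reference_path),
            }
            if config.go_path:
                inputs["go"] = Path(config.go_path)
            if config.disease_path:
                inputs["disease"] = Path(config.disease_path)
            record(stage, inputs, {"synthetic": False})
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        raise fail(stage, exc) from exc

    # --- filter ---
    stage = "filter"
    try:
        filtered = filter_negations(associations)
        if go_ann is not None:
            go_ann = filter_annotations(
                go_ann, allowed_evidence=frozenset(config.evidence_codes)
            )
        if disease_ann is not None:
            disease_ann = filter_annotations(
                disease_ann, min_score=config.min_disease_score
            )
        record(stage, {}, {"n_associations": len(filtered)})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # --- project ---
    stage = "project"
    try:
        ppan = project(filtered)
        p_edges = out / "ppan_edges.tsv"
        ppan.write_edges(p_edges)
        record(stage, {"edges": p_edges}, {"n_proteins": len(ppan.proteins), "n_edges": ppan.n_edges})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # --- calibrate ---
    stage = "calibrate"
    try:
        curve = overlap_curve(
            ppan,
            reference,
            score_kind="wscore",
            fractions=config.calibration_fractions,
            permutations=config.calibration_permutations,
            seed=stage_seed(config.seed, 3),
        )
        p_curve = out / "calibration_curve.tsv"
        curve.to_frame().to_csv(p_curve, sep="\t", index=False, float_format="%.12g")
        hc = select_threshold(ppan, config.fraction)
        p_hc = out / "hc_edges.tsv"
        hc.network.write_edges(p_hc)
        record(
            stage,
            {"curve": p_curve, "hc_edges": p_hc},
            {"fraction": config.fraction, "cutoff": hc.cutoff, "n_edges": hc.n_edges},
        )
    except Exception as exc:
        raise fail(stage, exc) from exc

    # --- cluster ---
    stage = "cluster"
    try:
        clustering = mcl(
            hc,
            inflation=config.inflation,
            expansion=config.expansion,
            prune=config.prune,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        clustering = filter_clusters(clustering, config.min_cluster_size)
        p_clusters = out / "clusters.tsv"
        clustering.write(p_clusters)
        cn = cluster_network(clustering, hc)
        p_cn = out / "cluster_network.tsv"
        cn.write(p_cn)
        record(
            stage,
            {"clusters": p_clusters, "cluster_network": p_cn},
            {"n_clusters": len(clustering.clusters), "converged": clustering.converged},
        )
    except Exception as exc:
        raise fail(stage, exc) from exc

    background = hc.proteins

    # --- enrich ---
    stage = "enrich"
    try:
        outputs = {}
        if go_ann is not None:
            all_results = []
            for c in clustering.clusters:
                all_results.extend(
                    enrich(c.members, go_ann, background, alpha=config.alpha, cluster_id=c.id)
                )
            p_go = out / "enrichment_go.tsv"
            results_frame(all_results).to_csv(p_go, sep="\t", index=False, float_format="%.6g")
            outputs["go"] = p_go
        record(stage, outputs, {"alpha": config.alpha})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # --- mine ---
    stage = "mine"
    try:
        outputs = {}
        if disease_ann is not None:
            disease_results = []
            chem_results = []
            overlap_frames = []
            for c in clustering.clusters:
                disease_results.extend(
                    enrich(c.members, disease_ann, background, alpha=config.alpha, cluster_id=c.id)
                )
                mining = mine_chemical_disease(
                    c.members, filtered, disease_ann, background,
                    alpha=config.alpha, cluster_id=c.id,
                )
                chem_results.extend(mining.chemical_results)
                overlap_frames.append(mining.overlaps)
            p_dis = out / "enrichment_disease.tsv"
            results_frame(disease_results).to_csv(p_dis, sep="\t", index=False, float_format="%.6g")
            p_chem = out / "mining_chemicals.tsv"
            results_frame(chem_results).to_csv(p_chem, sep="\t", index=False, float_format="%.6g")
            p_ov = out / "mining_overlaps.tsv"
            if overlap_frames:
                overlaps = pd.concat(overlap_frames, ignore_index=True)
            else:
                overlaps = pd.DataFrame(
                    columns=[
                        "cluster_id", "chemical_id", "disease_id", "disease_name",
                        "n_disease_members", "n_targeted_disease_members",
                    ]
                )
            overlaps.to_csv(p_ov, sep="\t", index=False)
            outputs = {"disease": p_dis, "chemicals": p_chem, "overlaps": p_ov}
        record(stage, outputs, {"alpha": config.alpha})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # --- predict ---
    stage = "predict"
    try:
        if isinstance(config.predict_chemicals, int):
            # default: the chemicals with the most targets inside the network
            counts = [
                (len(filtered.chemical_index[c] & background), c)
                for c in filtered.chemical_index
            ]
            counts.sort(key=lambda t: (-t[0], t[1]))
            chems = [c for _, c in counts[: config.predict_chemicals]]
        else:
            chems = list(config.predict_chemicals)
        outputs = {}
        seed_p = stage_seed(config.seed, 7)
        for i, chem in enumerate(chems):
            targets = filtered.chemical_index.get(chem, frozenset())
            result = predict_targets(
                targets,
                hc,
                threshold=config.pulldown_threshold,
                R=config.randomizations,
                seed=seed_p + i,
                chemical_id=chem,
            )
            p_pred = out / f"predictions_{chem}.tsv"
            result.table.to_csv(p_pred, sep="\t", index=False, float_format="%.12g")
            outputs[chem] = p_pred
        record(stage, outputs, {"threshold": config.pulldown_threshold, "R": config.randomizations})
    except Exception as exc:
        raise fail(stage, exc) from exc

    p_manifest = out / "manifest.json"
    with open(p_manifest, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
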