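"""End-to-end pipeline: simulate (optional) -> preprocess -> group-level
microstates -> per-subject backfit and parameters -> per-state source
connectivity -> group statistics.

Group-level templates are obtained by concatenating GFP-peak maps across
all subjects of a group and clustering once per group; the group
templates are then backfitted to each subject. Fitted states are named
A-D by matching against the canonical topographies, and group B's states
are aligned to group A's by optimal template matching so that the
between-group tests compare like with like. Every stage writes its
outputs before the next starts, and a JSON manifest records the config,
software version, output hashes, timings and warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    build_sloreta_inverse,
    extract_state_data,
    apply_inverse,
    parcellate,
    pearson_connectivity,
    summarize_connectivity,
    threshold_edges,
)
from .io import write_json, write_leadfield_bundle, write_recording
from .microstates import (
    ModifiedKMeans,
    backfit,
    compute_gfp,
    compute_parameters,
    match_templates,
    name_states,
    select_k,
    smooth_labels,
)
from .preprocess import PreprocessConfig, preprocess
from .simulate import SimulationConfig, generate_cohort
from .stats import compare_connectivity_tables, compare_parameter_tables

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run (YAML-mappable)."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    # microstate options
    k_range: tuple = (2, 8)
    forced_k: int | None = 4
    n_restarts: int = 50
    smoothing_ms: float = 0.0
    backfit_mode: str = "peaks"
    # connectivity options
    connectivity_mode: str = "peaks"
    # project the state's own template out of its peak maps before
    # inversion: the rank-one microstate mode otherwise saturates every
    # region correlation and masks genuine coupling differences
    remove_template: bool = True
    inverse_alpha: float = 1e-6
    edge_threshold: float = 0.5
    # statistics options
    correction: str | None = None
    write_recordings: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pre = PreprocessConfig(**raw.pop("preprocessing", {}))
        k_range = tuple(raw.pop("k_range", (2, 8)))
        cfg = cls(simulation=sim, preprocessing=pre, k_range=k_range, **raw)
        cfg.simulation.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in vars(self).items()
            if k not in ("simulation", "preprocessing")
        }
        d["k_range"] = list(self.k_range)
        d["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.simulation).items()
        }
        d["preprocessing"] = self.preprocessing.to_dict()
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, err: Exception):
        self.stage = stage
        self.subject = subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {err}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline on a synthetic cohort; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    cfg.simulation.seed = cfg.seed
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    captured: list[str] = []

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.log = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                self.ctx.__exit__(None, None, None)
                for w in self.log:
                    captured.append(f"{name}: {w.message}")
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)
                }
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, None, exc) from exc
                return False

        return _Stage()

    # ---- simulate -------------------------------------------------------
    with stage("simulate"):
        cohort = generate_cohort(cfg.simulation)
        write_json(cohort.manifest(), out / "cohort_manifest.json")
        if cohort.leadfield is not None:
            write_leadfield_bundle(
                cohort.leadfield, cohort.parcellation, out / "forward_model"
            )
        if cfg.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for subs in cohort.groups.values():
                for s in subs:
                    write_recording(
                        s.recording, rec_dir / f"{s.subject_id}.tsv"
                    )

    # ---- preprocess -----------------------------------------------------
    clean: dict = {}
    reports = {}
    with stage("preprocess"):
        for gname, subs in cohort.groups.items():
            for s in subs:
                try:
                    clean[s.subject_id], reports[s.subject_id] = preprocess(
                        s.recording, cfg.preprocessing
                    )
                except Exception as err:
                    raise PipelineError("preprocess", s.subject_id, err)
        write_json(reports, out / "preprocessing_report.json")

    # ---- group-level microstates ---------------------------------------
    models = {}
    selection_meta = {}
    with stage("microstates"):
        for gi, (gname, subs) in enumerate(cohort.groups.items()):
            maps = []
            for s in subs:
                rec = clean[s.subject_id]
                gfp = compute_gfp(rec)
                X = rec.data[:, gfp.peak_indices].T
                maps.append(X - X.mean(axis=1, keepdims=True))
            maps = np.vstack(maps)
            fits = [
                ModifiedKMeans(
                    n_clusters=k,
                    n_init=cfg.n_restarts,
                    random_state=np.random.default_rng((cfg.seed, gi, k)),
                ).fit(maps)
                for k in range(cfg.k_range[0], cfg.k_range[1] + 1)
            ]
            model, meta = select_k(fits, forced_k=cfg.forced_k)
            meta["aggregation"] = "concatenated-group-gfp-peaks"
            models[gname], selection_meta[gname] = model, meta
        # align group B states to group A and name them A-D
        names_a = name_states(models["A"].templates_, cohort.montage)
        perm, _, _ = match_templates(
            models["A"].templates_, models["B"].templates_
        )
        state_names = {"A": names_a, "B": [None] * len(names_a)}
        for i, name in enumerate(names_a):
            state_names["B"][perm[i]] = name
        write_json(
            {
                g: {
                    "templates": models[g].templates_,
                    "state_names": state_names[g],
                    "gev": models[g].gev_,
                    "cv": models[g].cv_,
                    "selection": selection_meta[g],
                }
                for g in models
            },
            out / "microstate_models.json",
        )

    # ---- per-subject backfit + parameters ------------------------------
    tables = {}
    segmentations = {}
    with stage("parameters"):
        for gname, subs in cohort.groups.items():
            model = models[gname]
            rows = []
            for s in subs:
                try:
                    rec = clean[s.subject_id]
                    gfp = compute_gfp(rec)
                    seg = backfit(
                        model.templates_, rec, gfp, mode=cfg.backfit_mode
                    )
                    if cfg.smoothing_ms > 0:
                        seg = smooth_labels(
                            seg, rec, model.templates_, cfg.smoothing_ms
                        )
                    segmentations[s.subject_id] = (rec, gfp, seg)
                    params = compute_parameters(seg, model.n_clusters)
                    for _, row in params.iterrows():
                        sname = state_names[gname][int(row["state"])]
                        for metric in ("duration_ms", "occurrence_hz", "coverage"):
                            rows.append(
                                (s.subject_id, sname, metric, row[metric])
                            )
                except Exception as err:
                    raise PipelineError("parameters", s.subject_id, err)
            tables[gname] = pd.DataFrame(
                rows, columns=["subject", "state", "metric", "value"]
            )
            tables[gname].to_csv(
                out / f"parameters_group{gname}.tsv", sep="\t", index=False
            )

    # ---- connectivity ---------------------------------------------------
    pooled = {"A": {}, "B": {}}
    with stage("connectivity"):
        if cohort.leadfield is not None:
            lf = cohort.leadfield
            lf.alpha = cfg.inverse_alpha
            inverse = build_sloreta_inverse(lf)
            parc = cohort.parcellation
            per_subject_cm = {g: {} for g in cohort.groups}
            for gname, subs in cohort.groups.items():
                for s in subs:
                    rec, gfp, seg = segmentations[s.subject_id]
                    for k in range(models[gname].n_clusters):
                        sname = state_names[gname][k]
                        try:
                            data, n = extract_state_data(
                                rec, seg, k, gfp, mode=cfg.connectivity_mode
                            )
                            if n < 3:
                                continue
                            if cfg.remove_template:
                                t_k = models[gname].templates_[k]
                                data = data - np.outer(t_k, t_k @ data)
                            src = apply_inverse(inverse, data)
                            region_ts = parcellate(src, parc)
                            cm = pearson_connectivity(
                                region_ts, k, parc.region_names
                            )
                        except Exception as err:
                            raise PipelineError(
                                "connectivity", s.subject_id, err
                            )
                        per_subject_cm[gname].setdefault(sname, []).append(cm)
                        edges = threshold_edges(cm, cfg.edge_threshold)
                        edges.to_csv(
                            out
                            / f"edges_{s.subject_id}_state{sname}.tsv",
                            sep="\t",
                            index=False,
                        )
            for gname in cohort.groups:
                for sname, cms in per_subject_cm[gname].items():
                    pooled[gname][sname] = summarize_connectivity(cms)
            write_json(pooled, out / "connectivity_pooled.json")

    # ---- statistics ------------------------------------------------------
    with stage("statistics"):
        param_results = compare_parameter_tables(
            tables["A"], tables["B"], correction=cfg.correction
        )
        param_results.to_csv(
            out / "statistics_parameters.tsv", sep="\t", index=False
        )
        conn_results = None
        if pooled["A"] and pooled["B"]:
            conn_results = compare_connectivity_tables(pooled["A"], pooled["B"])
            conn_results.to_csv(
                out / "statistics_connectivity.tsv", sep="\t", index=False
            )
        _write_report(out / "report.txt", param_results, conn_results)

    manifest["warnings"] = captured
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    write_json(manifest, out / "manifest.json")
    return manifest


def _write_report(path: Path, params: pd.DataFrame, conn) -> None:
    lines = ["Group comparison of microstate parameters (Mann-Whitney)", ""]
    for _, r in params.iterrows():
        lines.append(
            f"MS {r['state']} {r['metric']}: "
            f"A {r['mean_a']:.2f} +- {r['sd_a']:.2f}, "
            f"B {r['mean_b']:.2f} +- {r['sd_b']:.2f} "
            f"(Z = {r['Z']:.3f}, p = {r['p']:.3f})"
        )
    if conn is not None:
        lines += ["", "Connectivity (two-sample Z on pooled edges)", ""]
        for _, r in conn.iterrows():
            lines.append(
                f"MS {r['state']}: A {r['mean_a']:.2f} +- {r['sd_a']:.2f}, "
                f"B {r['mean_b']:.2f} +- {r['sd_b']:.2f} "
                f"(Z = {r['Z']:.2f}, p = {r['p']:.3g})"
            )
    path.write_text("\n".join(lines) + "\n")
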