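"""End-to-end session drivers: social-context and anxiety-context analyses.

Each driver takes an :class:`AnalysisConfig` (load a session from disk or
generate a synthetic one), runs events → ensembles → modulation → decoding →
geometry, and returns a :class:`ResultsBundle` of delimited tables plus a
provenance manifest (config hash, master seed) so a bundle can be
regenerated from its own record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import EventRaster, SessionAnnotation
from .decoding import DecodeTask, surrogate_shuffle, train_eval, transfer_eval
from .ensembles import (
    activity_summary,
    population_vector,
    similarity_matrix,
    within_between_summary,
)
from .events import EventDetectorParams, detect_events
from .geometry import overlap_table, similarity_report_matrix, vector_similarity
from .io import read_session, write_session
from .modulation import (
    arm_modulation,
    behavior_modulation,
    context_modulation,
    maze_modulation,
)
from .synthgen import (
    MAZE_ARMS,
    SessionSpec,
    TruthConfig,
    default_maze_spec,
    default_social_spec,
    generate_maze_session,
    generate_session,
)

__all__ = ["AnalysisConfig", "ResultsBundle", "run_social_pipeline", "run_maze_pipeline"]

SOCIAL_EPOCHS = ("A", "B", "C", "D")


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs, under a single master seed."""

    mode: str = "social-context"  # or "anxiety-context"
    input_path: str | None = None  # session directory; None => synthesize
    synth: dict[str, Any] = field(default_factory=dict)  # SessionSpec overrides
    truth: dict[str, Any] = field(default_factory=dict)  # TruthConfig overrides
    dynamic: bool = True  # social mode: context switch between AB and CD
    from_traces: bool = False  # run event detection instead of using the raster
    detector: dict[str, Any] = field(default_factory=dict)
    n_shuffles: int = 10_000
    n_iterations: int = 500
    transfer_iterations: int = 200
    holdout: float = 0.25
    seed: int = 0
    out: str | None = None

    def __post_init__(self):
        if self.mode not in ("social-context", "anxiety-context"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultsBundle:
    tables: dict[str, pd.DataFrame]
    manifest: dict[str, Any]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def _load_or_generate(config: AnalysisConfig):
    if config.input_path is not None:
        session = read_session(config.input_path)
        return session
    synth = dict(config.synth)
    truth = TruthConfig(**config.truth)
    if config.mode == "social-context":
        spec = default_social_spec(seed=config.seed, dynamic=config.dynamic, **synth)
        return generate_session(spec, truth)
    spec = default_maze_spec(seed=config.seed, **synth)
    return generate_maze_session(spec, truth)


def _raster(config: AnalysisConfig, session) -> EventRaster:
    if config.from_traces:
        params = EventDetectorParams(**config.detector) if config.detector else EventDetectorParams()
        return detect_events(session.traces, params)
    return session.raster


def _manifest(config: AnalysisConfig, session) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "n_neurons": int(session.raster.n_neurons),
        "n_frames": int(session.raster.n_frames),
    }


def run_social_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Social/context analysis over epochs A-D.

    Produces epoch-wise social/nonsocial population-vector similarity, the
    within/between-context summary, hold-out and transfer decoding tables
    (real and surrogate), AB/CD social modulation indices and their
    correlation, context modulation, modulation-vector similarity reports
    and the social x context overlap table.
    """
    session = _load_or_generate(config)
    raster = _raster(config, session)
    annotation = session.annotation
    missing = [e for e in SOCIAL_EPOCHS if e not in annotation.epoch_ids]
    if missing:
        raise ValueError(f"annotation lacks social epochs: {missing}")
    rng = np.random.default_rng(config.seed)
    ctx_of = {e: annotation.context_of(e) for e in SOCIAL_EPOCHS}

    # --- population vectors and similarity (epoch x behavior) -------------
    vectors = []
    for e in SOCIAL_EPOCHS:
        vectors.append(
            population_vector(raster, annotation.social_mask([e]), f"{e}:social")
        )
        vectors.append(
            population_vector(raster, annotation.nonsocial_mask([e]), f"{e}:nonsocial")
        )
    sim = similarity_matrix(vectors)
    sim_df = sim.to_frame().reset_index(names="condition")
    wb = within_between_summary(sim, ctx_of)

    # --- activity summary -------------------------------------------------
    act = activity_summary(
        raster,
        {
            "social": annotation.social_mask(SOCIAL_EPOCHS),
            "nonsocial": annotation.nonsocial_mask(SOCIAL_EPOCHS),
        },
    )

    # --- decoding ---------------------------------------------------------
    soc_all = annotation.social_mask(SOCIAL_EPOCHS)
    non_all = annotation.nonsocial_mask(SOCIAL_EPOCHS)
    dec_rows = []
    task = DecodeTask(
        soc_all, non_all, n_iterations=config.n_iterations,
        holdout=config.holdout, seed=rng.integers(2**31),
    )
    dec_rows.append(train_eval(raster, task, "all-epochs").to_row())
    surr = surrogate_shuffle(raster, rng.integers(2**31))
    task_s = DecodeTask(
        soc_all, non_all, n_iterations=config.n_iterations,
        holdout=config.holdout, seed=rng.integers(2**31),
    )
    row = train_eval(surr, task_s, "all-epochs").to_row()
    row["surrogate"] = True
    dec_rows.append(row)
    # transfer: train on each epoch, test on the remaining three
    for e in SOCIAL_EPOCHS:
        train_task = DecodeTask(
            annotation.social_mask([e]), annotation.nonsocial_mask([e]),
            n_iterations=config.transfer_iterations, holdout=config.holdout,
            seed=rng.integers(2**31),
        )
        tests = [
            (f, annotation.social_mask([f]), annotation.nonsocial_mask([f]))
            for f in SOCIAL_EPOCHS
            if f != e
        ]
        for res in transfer_eval(raster, train_task, tests, train_name=e):
            r = res.to_row()
            r["within_context"] = ctx_of[res.train_scope] == ctx_of[res.test_scope]
            dec_rows.append(r)
    decoding_df = pd.DataFrame(dec_rows)

    # --- modulation -------------------------------------------------------
    mod_kw = dict(n_shuffles=config.n_shuffles)
    soc_ab = behavior_modulation(
        raster, annotation, ("A", "B"), "social", "mean-difference",
        seed=rng.integers(2**31), **mod_kw,
    )
    soc_cd = behavior_modulation(
        raster, annotation, ("C", "D"), "social", "mean-difference",
        seed=rng.integers(2**31), **mod_kw,
    )
    non_ab = behavior_modulation(
        raster, annotation, ("A", "B"), "nonsocial", "mean-difference",
        seed=rng.integers(2**31), **mod_kw,
    )
    non_cd = behavior_modulation(
        raster, annotation, ("C", "D"), "nonsocial", "mean-difference",
        seed=rng.integers(2**31), **mod_kw,
    )
    ctx_mod = context_modulation(
        raster, annotation, (("A", "B"), ("C", "D")),
        seed=rng.integers(2**31), **mod_kw,
    )
    mod_df = pd.concat(
        [v.to_frame() for v in (soc_ab, soc_cd, non_ab, non_cd, ctx_mod)],
        ignore_index=True,
    )
    keep = soc_ab.valid() & soc_cd.valid()
    ab_cd_r = float(np.corrcoef(soc_ab.index[keep], soc_cd.index[keep])[0, 1])

    # --- geometry ---------------------------------------------------------
    mvecs = [soc_ab, soc_cd, non_ab, non_cd, ctx_mod]
    mnames = ["social_AB", "social_CD", "nonsocial_AB", "nonsocial_CD", "context"]
    real, shuf, reports = similarity_report_matrix(
        mvecs, mnames, metric="pearson",
        n_permutations=min(config.n_shuffles, 1000), seed=rng.integers(2**31),
    )
    geom_rows = [
        {
            "pair": "-".join(rep.pair),
            "metric": rep.metric,
            "observed": rep.observed,
            "null_mean": rep.null_mean,
            "null_sd": rep.null_sd,
            "percentile": rep.percentile,
            "outside_null_band": rep.outside_null_band,
        }
        for rep in reports.values()
    ]
    # headline orthogonality check: zero-centered cosine, social vs context
    cos_rep = vector_similarity(
        soc_ab, ctx_mod, "cosine", n_permutations=config.n_shuffles,
        seed=rng.integers(2**31), names=("social_AB", "context"),
    )
    geom_rows.append(
        {
            "pair": "social_AB-context:cosine",
            "metric": "cosine",
            "observed": cos_rep.observed,
            "null_mean": cos_rep.null_mean,
            "null_sd": cos_rep.null_sd,
            "percentile": cos_rep.percentile,
            "outside_null_band": cos_rep.outside_null_band,
        }
    )
    overlap = overlap_table(soc_ab, ctx_mod)
    overlap_df = overlap.to_frame().reset_index(names="social_AB")

    summary = pd.DataFrame(
        [
            {
                "ab_cd_social_index_r": ab_cd_r,
                "social_ab_vs_context_cosine": cos_rep.observed,
                "social_ab_vs_context_percentile": cos_rep.percentile,
                "n_neurons": raster.n_neurons,
                "n_frames": raster.n_frames,
            }
        ]
    )
    tables = {
        "population_similarity": sim_df,
        "within_between": wb,
        "activity_summary": act,
        "decoding": decoding_df,
        "modulation": mod_df,
        "geometry_reports": pd.DataFrame(geom_rows),
        "geometry_similarity_real": real.reset_index(names="vector"),
        "geometry_similarity_shuffled": shuf.reset_index(names="vector"),
        "overlap_social_context": overlap_df,
        "summary": summary,
    }
    bundle = ResultsBundle(tables, _manifest(config, session))
    if config.out:
        bundle.write(config.out)
    return bundle


def _maze_condition_masks(annotation: SessionAnnotation) -> dict[str, np.ndarray]:
    """Condition masks for each home-cage epoch and each maze arm."""
    masks: dict[str, np.ndarray] = {}
    for e in annotation.epoch_ids:
        if e.startswith("HC"):
            masks[e] = annotation.epoch_mask(e)
        elif e in MAZE_ARMS:
            for arm in annotation.arm_labels([e]):
                masks[f"{e}:{arm}"] = annotation.arm_mask(arm, [e])
    return masks


def run_maze_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Anxiety/context analysis over home-cage and maze epochs.

    Produces arm-wise population vectors and their similarity matrix,
    grouped mean similarities (within-maze, maze-vs-home-cage, open-open
    across mazes), maze- and arm-wise modulation vectors with similarity
    reports, arm occupancy, and a decoder transfer grid over disjoint
    context/arm discriminations.
    """
    session = _load_or_generate(config)
    raster = _raster(config, session)
    annotation = session.annotation
    mazes = [e for e in annotation.epoch_ids if e in MAZE_ARMS]
    if not mazes:
        raise ValueError("annotation contains no maze epochs")
    rng = np.random.default_rng(config.seed)

    masks = _maze_condition_masks(annotation)
    vectors, skipped = [], []
    for name, m in masks.items():
        if m.any():
            vectors.append(population_vector(raster, m, name))
        else:
            skipped.append(name)  # arm never visited: vector undefined
    sim = similarity_matrix(vectors)
    sim_df = sim.to_frame().reset_index(names="condition")

    # occupancy per maze arm
    occ_rows = []
    for maze in mazes:
        total = annotation.epoch_mask(maze).sum()
        for arm in annotation.arm_labels([maze]):
            occ_rows.append(
                {
                    "maze": maze,
                    "arm": arm,
                    "n_frames": int(annotation.arm_mask(arm, [maze]).sum()),
                    "fraction": annotation.arm_mask(arm, [maze]).sum() / total,
                }
            )
    occupancy = pd.DataFrame(occ_rows)

    # grouped mean similarities
    def _mean_sim(sel_a, sel_b):
        vals = []
        for i, va in enumerate(sim.conditions):
            for j, vb in enumerate(sim.conditions):
                if j <= i:
                    continue
                if (sel_a(va) and sel_b(vb)) or (sel_a(vb) and sel_b(va)):
                    vals.append(sim.values[i, j])
        return float(np.mean(vals)) if vals else np.nan

    def _in_maze(m):
        return lambda c: c.startswith(f"{m}:")

    def _is_hc(c):
        return c.startswith("HC")

    grouped = []
    for maze in mazes:
        grouped.append(
            {
                "comparison": f"{maze} vs {maze}",
                "mean_r": _mean_sim(_in_maze(maze), _in_maze(maze)),
            }
        )
        grouped.append(
            {"comparison": f"HC vs {maze}", "mean_r": _mean_sim(_is_hc, _in_maze(maze))}
        )
    grouped.append({"comparison": "HC vs HC", "mean_r": _mean_sim(_is_hc, _is_hc)})
    if "EZM" in mazes and "EPM" in mazes:
        ezm_open = lambda c: c.startswith("EZM:open")
        epm_open = lambda c: c == "EPM:open"
        epm_closed = lambda c: c == "EPM:closed"
        grouped.append(
            {"comparison": "EZM open vs EPM open", "mean_r": _mean_sim(ezm_open, epm_open)}
        )
        grouped.append(
            {
                "comparison": "EZM open vs EPM closed",
                "mean_r": _mean_sim(ezm_open, epm_closed),
            }
        )
    grouped_df = pd.DataFrame(grouped)

    # --- modulation vectors ----------------------------------------------
    mod_kw = dict(n_shuffles=config.n_shuffles)
    mvecs, mnames = [], []
    for maze in mazes:
        mvecs.append(
            maze_modulation(raster, annotation, maze, seed=rng.integers(2**31), **mod_kw)
        )
        mnames.append(f"{maze}/HC")
    arm_plans = {
        "EZM": [("EZM_open", ["open_CW", "open_CCW"])],
        "EPM": [("EPM_open", ["open"])],
        "TM": [("TM_long", ["long"]), ("TM_short", ["short"])],
    }
    for maze in mazes:
        for name, arms in arm_plans.get(maze, []):
            available = annotation.arm_labels([maze])
            arms_present = [a for a in arms if a in available]
            if not arms_present:
                skipped.append(name)
                continue
            mvecs.append(
                arm_modulation(
                    raster, annotation, maze, arms_present,
                    seed=rng.integers(2**31), **mod_kw,
                )
            )
            mnames.append(name)
    mod_df = pd.concat([v.to_frame() for v in mvecs], ignore_index=True)
    mod_df["name"] = np.repeat(mnames, [v.n_neurons for v in mvecs])
    real, shuf, reports = similarity_report_matrix(
        mvecs, mnames, metric="pearson",
        n_permutations=min(config.n_shuffles, 1000), seed=rng.integers(2**31),
    )
    geom_rows = [
        {
            "pair": "-".join(rep.pair),
            "observed": rep.observed,
            "null_mean": rep.null_mean,
            "null_sd": rep.null_sd,
            "percentile": rep.percentile,
            "outside_null_band": rep.outside_null_band,
        }
        for rep in reports.values()
    ]

    # --- decoder transfer grid over disjoint discriminations --------------
    tasks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    hc_ids = [e for e in annotation.epoch_ids if e.startswith("HC")]
    for maze in mazes:
        adj = [h for h in hc_ids if abs(annotation.epoch_ids.index(h) - annotation.epoch_ids.index(maze)) == 1]
        if adj:
            tasks[f"{maze}-vs-HC"] = (
                annotation.epoch_mask(maze),
                annotation.epoch_mask(adj),
            )
    if len(hc_ids) >= 2:
        tasks["HC1-vs-HC2"] = (
            annotation.epoch_mask(hc_ids[0]),
            annotation.epoch_mask(hc_ids[1]),
        )
    arm_tasks = {
        "EZM": ("EZM-open-vs-closed", ["open_CW", "open_CCW"], ["closed_CW", "closed_CCW"]),
        "EPM": ("EPM-open-vs-closed", ["open"], ["closed"]),
        "TM": ("TM-long-vs-short", ["long"], ["short"]),
    }
    for maze in mazes:
        if maze in arm_tasks:
            name, pos, neg = arm_tasks[maze]
            available = annotation.arm_labels([maze])
            pos = [a for a in pos if a in available]
            neg = [a for a in neg if a in available]
            if pos and neg:
                tasks[name] = (
                    annotation.arm_mask(pos, [maze]),
                    annotation.arm_mask(neg, [maze]),
                )
    transfer_rows = []
    for tname, (pm, nm) in tasks.items():
        train_task = DecodeTask(
            pm, nm, n_iterations=config.transfer_iterations,
            holdout=config.holdout, seed=rng.integers(2**31),
        )
        train_frames = pm | nm
        tests = [
            (oname, opm, onm)
            for oname, (opm, onm) in tasks.items()
            if oname != tname and not ((opm | onm) & train_frames).any()
        ]
        if not tests:
            continue
        for res in transfer_eval(raster, train_task, tests, train_name=tname):
            transfer_rows.append(res.to_row())
    transfer_df = pd.DataFrame(transfer_rows)

    tables = {
        "population_similarity": sim_df,
        "grouped_similarity": grouped_df,
        "arm_occupancy": occupancy,
        "modulation": mod_df,
        "geometry_reports": pd.DataFrame(geom_rows),
        "geometry_similarity_real": real.reset_index(names="vector"),
        "geometry_similarity_shuffled": shuf.reset_index(names="vector"),
        "transfer_grid": transfer_df,
    }
    manifest = _manifest(config, session)
    manifest["skipped_conditions"] = skipped
    bundle = ResultsBundle(tables, manifest)
    if config.out:
        bundle.write(config.out)
    return bundle
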