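"""End-to-end orchestration: QC -> preprocess -> CAP -> stats -> surrogate.

``run_pipeline`` consumes a cohort directory (see :mod:`capdyn.io`),
applies motion exclusion before any analysis, preprocesses the included
subjects, runs frame selection and clustering at each configured
fraction, compares group state frequencies, optionally repeats the
clustering on phase-randomized surrogates, and writes every artifact
plus a manifest with config echo, seeds and output hashes.
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
from .clustering import (
    kmeans_cluster,
    pool_frames,
    scan_k_and_find_elbow,
    select_top_frames,
    top_components,
)
from .io import read_cohort
from .motion import (
    FDTrace,
    align_fd_to_trim,
    cap_motion_summary,
    compute_fd,
    evaluate_exclusion,
    qc_report,
)
from .preprocess import PreprocessConfig, run_postica_pipeline
from .stats import DEFAULT_COVARIATES, EXTENDED_COVARIATES, compare_groups_regression
from .surrogate import surrogate_cap_analysis

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see YAML keys of the same names)."""

    input_dir: str
    output_dir: str
    fractions: tuple[float, ...] = (0.20, 0.30)
    k_range: tuple[int, ...] = tuple(range(2, 21))
    fixed_k: int | None = None  # skip the elbow scan when set
    metric: str = "correlation"
    n_init: int = 100
    scan_n_init: int = 20
    rng_seed: int = 0
    qc_mean_thresh: float = 0.5
    qc_frame_thresh: float = 0.5
    qc_max_frames: int = 35
    qc_pre_trim: bool = True
    covariate_preset: str = "default"  # or "with_sex"
    ttest_variant: str = "welch"
    fdr: bool = False
    n_surrogates: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "preprocess" in raw:
            pknown = {f.name for f in dataclasses.fields(PreprocessConfig)}
            punknown = set(raw["preprocess"]) - pknown
            if punknown:
                raise PipelineError(f"unknown preprocess keys: {sorted(punknown)}")
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        for key in ("fractions", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class RunManifest:
    config: dict
    version: str
    seeds: dict
    outputs: dict  # path -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest written to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, participants, motion = read_cohort(config.input_dir)
    logger.info("loaded %d subjects from %s", len(subjects), config.input_dir)

    # ---- motion QC (on raw-length traces, before any trimming) ----
    fd_traces: dict[str, FDTrace] = {}
    for ts in subjects:
        m = motion[ts.subject_id]
        if m.ndim == 2:
            fd_traces[ts.subject_id] = compute_fd(m, ts.subject_id)
        else:
            fd_traces[ts.subject_id] = FDTrace(ts.subject_id, m)
    decisions = [
        evaluate_exclusion(
            fd_traces[ts.subject_id],
            config.qc_mean_thresh,
            config.qc_frame_thresh,
            config.qc_max_frames,
        )
        for ts in subjects
    ]
    report = qc_report(decisions)
    report.to_csv(out / "qc_report.csv", index=False)
    included = {d.subject_id for d in decisions if d.included}
    if len(included) < 2:
        raise PipelineError("fewer than 2 subjects pass motion QC")
    subjects = [ts for ts in subjects if ts.subject_id in included]
    participants = participants[
        participants["participant_id"].isin(included)
    ].reset_index(drop=True)
    logger.info("%d subjects pass motion QC", len(subjects))

    # ---- preprocessing ----
    pp = config.preprocess
    processed = [run_postica_pipeline(ts, pp) for ts in subjects]
    fd_aligned = {
        sid: align_fd_to_trim(fd_traces[sid], pp.n_drop_leading, pp.target_frames)
        if pp.do_trim
        else fd_traces[sid]
        for sid in included
    }
    mean_fd = {sid: fd_traces[sid].mean_fd for sid in included}
    participants = participants.assign(
        mean_fd=[mean_fd[s] for s in participants["participant_id"]]
    )

    covariates = (
        EXTENDED_COVARIATES if config.covariate_preset == "with_sex" else DEFAULT_COVARIATES
    )

    outputs: dict[str, str] = {}
    seeds = {"rng_seed": config.rng_seed}
    for fraction in config.fractions:
        tag = f"top{int(round(fraction * 100))}"
        selected = [
            select_top_frames(ts.seed_series, fraction, ts.subject_id)
            for ts in processed
        ]
        pooled = pool_frames(processed, selected)

        if config.fixed_k is None:
            curve = scan_k_and_find_elbow(
                pooled,
                k_range=config.k_range,
                metric=config.metric,
                n_init=config.scan_n_init,
                rng_seed=config.rng_seed,
            )
            curve.to_frame().assign(elbow=lambda d: d["k"] == curve.elbow_k).to_csv(
                out / f"cvi_curve_{tag}.csv", index=False
            )
            k = curve.elbow_k
        else:
            k = config.fixed_k
        solution = kmeans_cluster(
            pooled, k, metric=config.metric, n_init=config.n_init,
            rng_seed=config.rng_seed,
        )

        cent = pd.DataFrame(
            solution.centroids,
            columns=list(pooled.component_ids),
            index=[f"state_{j + 1}" for j in range(k)],
        )
        cent.to_csv(out / f"centroids_{tag}.csv")
        pd.DataFrame(
            {
                "participant_id": pooled.subject_index,
                "frame": pooled.frame_index,
                "state": solution.labels + 1,  # 1-based states in reports
            }
        ).to_csv(out / f"labels_{tag}.csv", index=False)

        tops = []
        for j in range(k):
            tc = top_components(
                solution.centroids[j], pooled.component_ids, pooled.network_labels,
                n=min(10, len(pooled.component_ids)),
            )
            tc.insert(0, "state", j + 1)
            tops.append(tc)
        pd.concat(tops).to_csv(out / f"top_components_{tag}.csv", index=False)

        from .stats import frequency_table  # local import avoids cycle at module load

        freq = frequency_table(solution.labels, pooled.subject_index, k)
        freq.to_csv(out / f"frequencies_{tag}.csv")
        result = compare_groups_regression(
            freq,
            participants,
            covariates=covariates,
            ttest_variant=config.ttest_variant,
            fdr=config.fdr,
        )
        result.table.to_csv(out / f"group_stats_{tag}.csv")

        capfd = cap_motion_summary(
            fd_aligned, pooled.subject_index, pooled.frame_index, solution.labels
        )
        capfd["state"] = capfd["state"] + 1
        capfd.to_csv(out / f"cap_motion_{tag}.csv", index=False)

        if config.n_surrogates > 0:
            surr = surrogate_cap_analysis(
                processed, solution, fraction,
                n_realizations=config.n_surrogates,
                n_init=config.scan_n_init,
                rng_seed=config.rng_seed,
            )
            pd.DataFrame(
                {
                    "realization": range(len(surr.surrogate_scores)),
                    "score": surr.surrogate_scores,
                }
            ).to_csv(out / f"surrogate_scores_{tag}.csv", index=False)
            with open(out / f"surrogate_summary_{tag}.json", "w") as fh:
                json.dump(
                    {
                        "original_score": surr.original_score,
                        "mean_surrogate_score": float(
                            np.mean(surr.surrogate_scores)
                        ),
                        "score_ratio": surr.score_ratio,
                        "fraction_below_original": surr.percentile_of_original(),
                    },
                    fh,
                    indent=1,
                )

        _write_report(out, tag, k, result, capfd)

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            outputs[p.name] = _sha256(p)
    manifest = RunManifest(
        config=_config_dict(config), version=__version__, seeds=seeds, outputs=outputs
    )
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1, sort_keys=True)
    )
    return manifest


def _write_report(out: Path, tag: str, k: int, result, capfd: pd.DataFrame) -> None:
    lines = [
        f"# CAP analysis report ({tag})",
        "",
        f"States discovered: {k}",
        f"Reference group: {result.reference_group}",
        f"Covariates: {', '.join(result.covariates)}",
        "",
        "## Group comparison (frequency of occurrence)",
        "",
        result.table.round(4).to_markdown(),
        "",
        "## Mean FD per CAP (mm)",
        "",
        capfd.round(4).to_markdown(index=False),
        "",
    ]
    (out / f"report_{tag}.md").write_text("\n".join(lines))
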