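"""End-to-end orchestration: simulate → preprocess → segment → backfit →
group statistics, with per-stage outputs on disk, resumability and a
reproducibility manifest.

Every stage reads its inputs from the run directory and writes plain-text
outputs, so deleting a stage's outputs and re-running recreates only that
stage and its dependents. All randomness derives from one top-level seed
via ``numpy.random.SeedSequence(seed, stage_index)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .backfitting import backfit_cohort
from .preprocessing import PreprocessingConfig, preprocess
from .segmentation import (
    compute_gfp,
    find_gfp_peaks,
    group_segmentation,
    individual_segmentation,
    label_by_archetype,
    match_templates,
)
from .stats import pearson_correlations, rm_anova_posthoc, stepwise_regression, tanova
from .synthetic import SyntheticConfig, simulate_cohort

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "segment", "backfit", "stats"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_patients": 8,
        "n_controls": 8,
        "n_channels": 64,
        "duration_s": 60.0,
        "snr": 2.0,
    },
    "preprocess": {
        "band": [1.0, 40.0],
        "target_sfreq": 125.0,
        "bad_channels": [],
        "crop": None,
    },
    "segment": {
        "k_individual": 5,
        "k_population": 6,
        "k_range": [2, 8],
        "restarts": 30,
        "min_peak_separation_ms": 10.0,
    },
    "backfit": {"min_duration_ms": 0.0},
    "stats": {"tanova_permutations": 1000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    """Load a YAML config and fill in every default (logged in the manifest)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, STAGES.index(stage) if stage in STAGES else 97])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(out_dir: Path, stage: str) -> bool:
    return (out_dir / stage / ".done").exists()


def _mark_done(out_dir: Path, stage: str) -> None:
    (out_dir / stage / ".done").write_text("ok\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out_dir: Path) -> None:
    d = out_dir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    c = cfg["cohort"]
    syn = SyntheticConfig(
        n_channels=int(c["n_channels"]),
        duration_s=float(c["duration_s"]),
        snr=float(c["snr"]),
    )
    cohort = simulate_cohort(
        syn,
        int(c["n_patients"]),
        int(c["n_controls"]),
        seed=_stage_seed(cfg["seed"], "simulate"),
    )
    for rec in cohort.recordings:
        msio.write_recording(rec, d / f"{rec.subject_id}.tsv")
    msio.write_covariates(cohort.covariates, d / "covariates.csv")
    msio.write_templates(cohort.ground_truth.templates, d / "true_templates.tsv")
    cohort.ground_truth.realized.to_csv(d / "true_parameters.tsv", sep="\t", index=False)


def _recordings_in(d: Path) -> list[Path]:
    return sorted(p for p in d.glob("*.tsv") if not p.name.startswith(("covariates", "true_")))


def _stage_preprocess(cfg: dict, out_dir: Path) -> None:
    src = out_dir / "simulate"
    d = out_dir / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    p = cfg["preprocess"]
    pconf = PreprocessingConfig(
        band=tuple(p["band"]),
        target_sfreq=float(p["target_sfreq"]),
        bad_channels=list(p["bad_channels"]),
        crop=tuple(p["crop"]) if p["crop"] else None,
    )
    for path in _recordings_in(src):
        rec = msio.read_recording(path)
        t0 = time.time()
        out = preprocess(rec, pconf)
        logger.info("preprocess %s in %.2fs", rec.subject_id, time.time() - t0)
        msio.write_recording(out, d / path.name)


def _stage_segment(cfg: dict, out_dir: Path) -> None:
    src = out_dir / "preprocess"
    d = out_dir / "segment"
    d.mkdir(parents=True, exist_ok=True)
    s = cfg["segment"]
    seed = _stage_seed(cfg["seed"], "segment")
    rng = np.random.default_rng(seed)
    k_ind = s["k_individual"]
    k_range = range(int(s["k_range"][0]), int(s["k_range"][1]) + 1)

    by_group: dict[str, list] = {}
    for path in _recordings_in(src):
        rec = msio.read_recording(path)
        res = individual_segmentation(
            rec,
            k=int(k_ind) if k_ind else None,
            k_range=k_range,
            n_restarts=int(s["restarts"]),
            seed=int(rng.integers(2**31 - 1)),
            min_separation_ms=float(s["min_peak_separation_ms"]),
        )
        msio.write_templates(res.templates, d / f"individual_{rec.subject_id}.tsv")
        by_group.setdefault(rec.group or "all", []).append(res.templates)
        logger.info(
            "segment %s: K=%d GEV=%.3f", rec.subject_id, res.templates.n_classes,
            res.gev_total,
        )

    montage = msio.read_recording(_recordings_in(src)[0]).montage
    all_sets = []
    for group, sets in sorted(by_group.items()):
        res = group_segmentation(
            sets,
            k=None if k_ind is None else len(sets[0].class_labels),
            k_range=k_range,
            n_restarts=int(s["restarts"]),
            seed=int(rng.integers(2**31 - 1)),
            level="group",
        )
        labelled = label_by_archetype(res.templates, montage)
        msio.write_templates(labelled, d / f"group_{group}.tsv")
        all_sets.extend(sets)

    k_pop = s["k_population"]
    res = group_segmentation(
        all_sets,
        k=int(k_pop) if k_pop else None,
        k_range=k_range,
        n_restarts=int(s["restarts"]),
        seed=int(rng.integers(2**31 - 1)),
        level="population",
    )
    labelled = label_by_archetype(res.templates, montage)
    msio.write_templates(labelled, d / "population.tsv")
    summary = {
        "population_k": labelled.n_classes,
        "population_gev": res.gev_total,
        "gev_per_class": {
            c: float(g) for c, g in zip(res.templates.class_labels, res.gev_per_class)
        },
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2))


def _stage_backfit(cfg: dict, out_dir: Path) -> None:
    src = out_dir / "preprocess"
    d = out_dir / "backfit"
    d.mkdir(parents=True, exist_ok=True)
    templates = msio.read_templates(out_dir / "segment" / "population.tsv")
    recs = [msio.read_recording(p) for p in _recordings_in(src)]
    table = backfit_cohort(
        recs, templates, min_duration_ms=float(cfg["backfit"]["min_duration_ms"])
    )
    msio.write_parameters(table, d / "parameters.tsv")


def _subject_dominant_maps(recs: list) -> np.ndarray:
    """One topography per subject: the dominant eigenvector of its GFP-peak
    maps (a polarity-invariant 'mean map'), sign-aligned across subjects."""
    out = []
    for rec in recs:
        gfp = compute_gfp(rec, warn_reference=False)
        peaks = find_gfp_peaks(gfp)
        X = rec.data[:, peaks]
        X = X - X.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(X.T, full_matrices=False)
        out.append(vt[0])
    M = np.vstack(out)
    ref = M[0]
    for i in range(1, M.shape[0]):
        if M[i] @ ref < 0:
            M[i] = -M[i]
    return M


def _stage_stats(cfg: dict, out_dir: Path) -> None:
    src = out_dir / "preprocess"
    d = out_dir / "stats"
    d.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(cfg["seed"], "stats")
    params = msio.read_parameters(out_dir / "backfit" / "parameters.tsv")
    covs = msio.read_covariates(out_dir / "simulate" / "covariates.csv")

    recs = [msio.read_recording(p) for p in _recordings_in(src)]
    groups = sorted({r.group for r in recs})
    maps_by_group = {
        g: _subject_dominant_maps([r for r in recs if r.group == g]) for g in groups
    }
    tn = tanova(
        maps_by_group[groups[0]],
        maps_by_group[groups[1]],
        n_permutations=int(cfg["stats"]["tanova_permutations"]),
        seed=seed,
    )
    (d / "tanova.json").write_text(
        json.dumps(
            {
                "groups": groups,
                "observed_diss": tn.observed_diss,
                "p_value": tn.p_value,
                "n_permutations": tn.n_permutations,
            },
            indent=2,
        )
    )

    for metric in ("gev", "md", "tc", "occ"):
        res = rm_anova_posthoc(params, metric)
        res.effects.to_csv(d / f"anova_{metric}_effects.tsv", sep="\t", index=False)
        res.posthoc.to_csv(d / f"anova_{metric}_posthoc.tsv", sep="\t", index=False)

    pairs = [(m, "A", "SDMT") for m in ("gev", "md", "tc", "occ")] + [
        ("md", "A", "disease_duration")
    ]
    patients = covs[covs["group"] == "patient"]
    try:
        corr = pearson_correlations(
            params[params["subject_id"].isin(patients["subject_id"])], covs, pairs
        )
        corr.to_csv(d / "correlations.tsv", sep="\t", index=False)
    except ValueError as exc:
        logger.warning("correlations skipped: %s", exc)

    # stepwise: SDMT ~ clinical + one class-A metric per model (patients only)
    reg_out = {}
    pat_params = params[params["subject_id"].isin(patients["subject_id"])]
    a_rows = pat_params[pat_params["class"] == "A"].set_index("subject_id")
    clinical = patients.set_index("subject_id")[["disease_duration", "EDSS", "ARR"]]
    for metric, col in (
        ("gev", "gev"),
        ("md", "mean_duration_ms"),
        ("tc", "time_coverage_pct"),
        ("occ", "occurrence_per_min"),
    ):
        cand = clinical.join(a_rows[[col]].rename(columns={col: f"{metric}_A"}))
        cand = cand.dropna(how="any")
        y = patients.set_index("subject_id").loc[cand.index, "SDMT"]
        if len(cand) <= cand.shape[1] + 2:
            continue
        res = stepwise_regression(y.to_numpy(), cand)
        reg_out[metric] = {
            "selected": res.selected,
            "r_squared": res.r_squared,
            "vif": res.vif,
            "coefficients": {k: float(v) for k, v in res.coefficients.items()},
        }
    (d / "regression.json").write_text(json.dumps(reg_out, indent=2))


# ---------------------------------------------------------------------------
# Runner / manifest / report
# ---------------------------------------------------------------------------

_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "backfit": _stage_backfit,
    "stats": _stage_stats,
}


def run_pipeline(
    config, out_dir: str | Path, seed: int | None = None, resume: bool = True
) -> Path:
    """Run all stages in order; previously completed stages are skipped when
    ``resume`` and their outputs exist. Returns the run directory."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config_resolved.yaml").write_text(yaml.safe_dump(cfg))

    manifest = {
        "config": cfg,
        "seed": cfg["seed"],
        "version": _package_version(),
        "stages": {},
    }
    invalidated = False  # once a stage re-runs, everything downstream re-runs
    for stage in STAGES:
        if resume and not invalidated and _stage_done(out_dir, stage):
            logger.info("stage %s: resume (outputs present)", stage)
            manifest["stages"][stage] = {"status": "resumed"}
            continue
        invalidated = True
        t0 = time.time()
        try:
            _STAGE_FN[stage](cfg, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _mark_done(out_dir, stage)
        files = sorted(
            str(p.relative_to(out_dir))
            for p in (out_dir / stage).rglob("*")
            if p.is_file() and p.name != ".done"
        )
        manifest["stages"][stage] = {
            "status": "ran",
            "seconds": round(time.time() - t0, 3),
            "seed": _stage_seed(cfg["seed"], stage),
            "outputs": {f: _sha256(out_dir / f) for f in files},
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report(out_dir)
    return out_dir


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("microstates")
    except Exception:
        return "unknown"


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    seg = run_dir / "segment"
    if not (seg / "population.tsv").exists():
        raise FileNotFoundError(f"{run_dir} does not contain a completed run")
    pop = msio.read_templates(seg / "population.tsv")
    summary = json.loads((seg / "summary.json").read_text())
    lines = ["# Microstate pipeline report", ""]
    lines.append(
        f"Population clustering: {pop.n_classes} classes "
        f"({', '.join(pop.class_labels)}), GEV = {summary['population_gev']:.3f}"
    )
    group_files = sorted(seg.glob("group_*.tsv"))
    if len(group_files) == 2:
        g1 = msio.read_templates(group_files[0])
        g2 = msio.read_templates(group_files[1])
        mapping, corrs = match_templates(g1, g2)
        lines.append("")
        lines.append("## Cross-group template matching")
        for (i, j), r in sorted(corrs.items()):
            lines.append(
                f"- {g1.class_labels[i]} ({group_files[0].stem}) vs "
                f"{g2.class_labels[j]} ({group_files[1].stem}): |r| = {r:.2f}"
            )
    ppath = run_dir / "backfit" / "parameters.tsv"
    if ppath.exists():
        params = msio.read_parameters(ppath)
        lines.append("")
        lines.append("## Temporal parameters (mean ± SD per group)")
        for metric, col in (
            ("GEV", "gev"),
            ("MD (ms)", "mean_duration_ms"),
            ("TC (%)", "time_coverage_pct"),
            ("occ/min", "occurrence_per_min"),
        ):
            lines.append(f"### {metric}")
            agg = params.groupby(["class", "group"])[col].agg(["mean", "std"])
            for (cls, grp), row in agg.iterrows():
                lines.append(f"- {cls} / {grp}: {row['mean']:.3g} ± {row['std']:.3g}")
    tpath = run_dir / "stats" / "tanova.json"
    if tpath.exists():
        tn = json.loads(tpath.read_text())
        lines.append("")
        lines.append(
            f"## TANOVA\nobserved DISS = {tn['observed_diss']:.4f}, "
            f"p = {tn['p_value']:.4f} ({tn['n_permutations']} permutations)"
        )
    rpath = run_dir / "stats" / "regression.json"
    if rpath.exists():
        reg = json.loads(rpath.read_text())
        lines.append("")
        lines.append("## Stepwise regression (SDMT ~ clinical + class-A metric)")
        for metric, res in reg.items():
            lines.append(
                f"- model[{metric}]: selected={res['selected']}, "
                f"R²={res['r_squared']:.3f}, VIF={res['vif']}"
            )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
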