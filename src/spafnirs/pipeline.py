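"""End-to-end orchestration: generate/load -> preprocess -> derive ->
classify -> group statistics -> coupling models -> results bundle.

The bundle on disk is a directory of TSV/JSON files plus a run manifest
(config hash, seed, package version) so a run can be reproduced and every
table row traced back to subject ids.  Subjects whose recordings fail a
stage's preconditions are excluded with machine-readable reasons rather than
aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SubgroupAssignment, assign_subgroups
from .derived import (
    SIGNALS,
    BlockAverageSet,
    attach_ftoe,
    block_average,
    compute_deltas,
    deltas_to_frame,
    interval_medians,
    normalize_to_interval2,
)
from .gam import GamConfig, build_delta_series, compare_subgroups, fit_gam
from .preprocess import PreprocessCfg, preprocess_session
from .session_io import (
    StudyProtocol,
    default_protocol,
    read_metadata_table,
    read_session,
)
from .stats import (
    contingency_suite,
    signed_rank_rb,
    spearman_screen,
    table1_battery,
    welch_t,
)
from .synth import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "make_report"]

log = logging.getLogger("spafnirs")

TABLE1_COVARIATES = [
    "gestational_age",
    "postnatal_age",
    "birth_weight",
    "weight_at_measurement",
    "length_at_birth",
    "length_at_measurement",
    "head_circumference_at_birth",
    "head_circumference_at_measurement",
    "apgar_1min",
    "apgar_5min",
    "haematocrit",
    "behavioural_state_mean",
    "behavioural_state_std",
]


@dataclass
class PipelineConfig:
    """Either ``input_dir`` (session CSVs + metadata.tsv) or ``synth`` must
    be set, not both."""

    input_dir: str | None = None
    synth: CohortConfig | None = None
    preprocess: PreprocessCfg = field(default_factory=PreprocessCfg)
    protocol: StudyProtocol | None = None
    alpha: float = 0.05
    gam: GamConfig = field(default_factory=GamConfig)
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synth is None):
            raise ValueError("set exactly one of input_dir / synth")


@dataclass
class ResultsBundle:
    quality: pd.DataFrame
    assignments: list[SubgroupAssignment]
    counts: dict
    deltas: pd.DataFrame
    subgroup_stats: pd.DataFrame
    table1: pd.DataFrame
    contingency: dict
    spearman: pd.DataFrame
    block_averages: BlockAverageSet
    gam_report: dict
    excluded: dict
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return str(o)

    d = dataclasses.asdict(cfg)
    # output location and verbosity are run metadata, not analysis parameters
    d.pop("output_dir", None)
    d.pop("log_level", None)
    blob = json.dumps(d, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(cfg: PipelineConfig):
    if cfg.synth is not None:
        sessions, metas, _truth = generate_cohort(cfg.synth)
        return sessions, metas
    indir = Path(cfg.input_dir)
    metas = read_metadata_table(indir / "metadata.tsv")
    sessions = []
    for m in metas:
        p = indir / f"{m.subject_id}.csv"
        if not p.exists():
            log.warning("subject %s: session file missing, skipped", m.subject_id)
            continue
        sessions.append(read_session(p, subject_id=m.subject_id))
    return sessions, metas


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute every stage in order and (optionally) write the bundle."""
    logging.basicConfig(level=cfg.log_level)
    protocol = cfg.protocol or default_protocol()
    sessions, metas = _load_cohort(cfg)
    meta_by_id = {m.subject_id: m for m in metas}
    excluded: dict[str, str] = {}

    # --- preprocess -------------------------------------------------------
    pres, quality_rows = [], []
    for rec in sessions:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pre = preprocess_session(rec, cfg.preprocess, protocol)
        except Exception as e:  # malformed/short recording
            excluded[rec.subject_id] = f"preprocess: {e}"
            log.warning("subject %s excluded at preprocess: %s", rec.subject_id, e)
            continue
        attach_ftoe(pre)
        pres.append(pre)
        row = {"subject_id": pre.subject_id,
               "threshold_T": pre.quality["threshold_T"],
               "masked_fraction": pre.quality["masked_fraction"]}
        for k, v in pre.quality["masked_fraction_per_interval"].items():
            row[f"masked_frac_interval_{k}"] = v
        quality_rows.append(row)
        log.info("subject %s preprocessed (masked %.1f%%)",
                 pre.subject_id, 100 * pre.quality["masked_fraction"])
    if not pres:
        raise RuntimeError(
            f"zero usable subjects after preprocessing; exclusions: {excluded}"
        )
    quality = pd.DataFrame(quality_rows)

    # --- derived measures + classification -------------------------------
    summaries = {p.subject_id: interval_medians(p, protocol) for p in pres}
    deltas = [compute_deltas(s) for s in summaries.values()]
    normalized = {
        p.subject_id: normalize_to_interval2(p, summaries[p.subject_id], protocol)
        for p in pres
    }
    assignments, counts = assign_subgroups(pres, protocol, cfg.alpha)
    subgroup_of = {a.subject_id: a.subgroup for a in assignments}
    for a in assignments:
        if a.subgroup is None:
            excluded.setdefault(a.subject_id, f"classification: {a.reason}")

    block = block_average(normalized, {k: v for k, v in subgroup_of.items() if v})

    # --- subgroup statistics ---------------------------------------------
    delta_frame = deltas_to_frame(deltas)
    delta_by = {d.subject_id: d for d in deltas}
    stat_rows = []
    for sig in SIGNALS:
        groups = {}
        for g in (1, 2):
            members = [sid for sid, sg in subgroup_of.items() if sg == g]
            vals = np.array([delta_by[sid][sig] for sid in members], dtype=float)
            groups[g] = vals[~np.isnan(vals)]
            if len(groups[g]) >= 1:
                res = signed_rank_rb(groups[g], name=f"{sig}_sg{g}")
                stat_rows.append({
                    "signal": sig, "subgroup": g, "n": len(groups[g]),
                    "delta_median": float(np.median(groups[g])),
                    "p": res.p_value, "r_rb": res.r_rb,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                })
        if len(groups.get(1, ())) >= 2 and len(groups.get(2, ())) >= 2:
            w = welch_t(groups[1], groups[2])
            stat_rows.append({
                "signal": sig, "subgroup": "1 vs 2", "n": w["n"],
                "delta_median": np.nan, "p": w["p"], "r_rb": np.nan,
                "ci_low": np.nan, "ci_high": np.nan,
            })
    subgroup_stats = pd.DataFrame(stat_rows)

    # --- Table-1 battery + contingency + Spearman screen ------------------
    assigned = [a.subject_id for a in assignments if a.subgroup]
    labels = np.array([subgroup_of[sid] for sid in assigned])
    cov = pd.DataFrame(
        {c: [getattr(meta_by_id[sid], c) for sid in assigned] for c in TABLE1_COVARIATES}
    )
    cov["sex"] = [1.0 if meta_by_id[sid].sex == "male" else 0.0 for sid in assigned]
    cov["mode_of_delivery"] = [
        1.0 if meta_by_id[sid].mode_of_delivery == "caesarean" else 0.0
        for sid in assigned
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table1 = table1_battery(cov, labels)

    a = sum(1 for sid in assigned if subgroup_of[sid] == 1 and meta_by_id[sid].sex == "female")
    b = sum(1 for sid in assigned if subgroup_of[sid] == 1 and meta_by_id[sid].sex == "male")
    c = sum(1 for sid in assigned if subgroup_of[sid] == 2 and meta_by_id[sid].sex == "female")
    d = sum(1 for sid in assigned if subgroup_of[sid] == 2 and meta_by_id[sid].sex == "male")
    contingency = dataclasses.asdict(contingency_suite(a, b, c, d)) if min(a + b, c + d) > 0 else {
        "counts": (a, b, c, d), "note": "one subgroup empty; suite skipped"}

    # Hct/length screen: AC and PFC deltas pooled per the published analysis
    pooled_sto2 = np.concatenate([
        np.array([delta_by[sid]["sto2_ac"] for sid in assigned]),
        np.array([delta_by[sid]["sto2_pfc"] for sid in assigned]),
    ])
    pooled_ftoe = np.concatenate([
        np.array([delta_by[sid]["ftoe_ac"] for sid in assigned]),
        np.array([delta_by[sid]["ftoe_pfc"] for sid in assigned]),
    ])
    hct2 = np.tile([meta_by_id[sid].haematocrit for sid in assigned], 2)
    len2 = np.tile([meta_by_id[sid].length_at_measurement for sid in assigned], 2)
    screen = spearman_screen({
        "dsto2_vs_haematocrit": (hct2, pooled_sto2),
        "dftoe_vs_haematocrit": (hct2, pooled_ftoe),
        "dsto2_vs_length_at_measurement": (len2, pooled_sto2),
    })
    spearman = pd.DataFrame([dataclasses.asdict(r) for r in screen])

    # --- GAM coupling models ----------------------------------------------
    gam_fits: dict[str, dict[int, object]] = {}
    for site in ("ac", "pfc"):
        fits = {}
        for g in (1, 2):
            members = [sid for sid, sg in subgroup_of.items() if sg == g]
            try:
                series = build_delta_series(normalized, members, site, g)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits[g] = fit_gam(series, cfg.gam)
            except ValueError as e:
                log.warning("GAM site=%s subgroup=%s skipped: %s", site, g, e)
        gam_fits[site] = fits
    gam_report = {site: compare_subgroups(fits) for site, fits in gam_fits.items()}

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "n_input": len(sessions),
        "n_retained": len(pres),
    }
    bundle = ResultsBundle(
        quality, assignments, counts, delta_frame, subgroup_stats, table1,
        contingency, spearman, block, gam_report, excluded, manifest,
    )
    if cfg.output_dir:
        write_bundle(bundle, cfg.output_dir, gam_fits)
    return bundle


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    return str(o)


def write_bundle(bundle: ResultsBundle, out_dir: str | Path, gam_fits=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.quality.to_csv(out / "quality.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(a) for a in bundle.assignments]).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    bundle.deltas.to_csv(out / "deltas.tsv", sep="\t", index=False)
    bundle.subgroup_stats.to_csv(out / "subgroup_stats.tsv", sep="\t", index=False)
    bundle.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    bundle.spearman.to_csv(out / "spearman.tsv", sep="\t", index=False)
    for (g, sig), df in bundle.block_averages.curves.items():
        df.to_csv(out / f"block_average_sg{g}_{sig}.tsv", sep="\t", index=False)
    if gam_fits:
        for site, fits in gam_fits.items():
            for g, fit in fits.items():
                gg1, gg2 = np.meshgrid(fit.grid_dspo2, fit.grid_dpr, indexing="ij")
                pd.DataFrame({
                    "dspo2": gg1.ravel(),
                    "dpr": gg2.ravel(),
                    "fitted_dsto2": fit.fitted_surface.ravel(),
                }).to_csv(out / f"gam_surface_{site}_sg{g}.tsv", sep="\t", index=False)
    payload = {
        "counts": bundle.counts,
        "contingency": bundle.contingency,
        "gam": bundle.gam_report,
        "excluded": bundle.excluded,
        "manifest": bundle.manifest,
    }
    (out / "results.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
    )
    (out / "report.md").write_text(make_report(bundle))
    return out


def bundle_hash(out_dir: str | Path) -> str:
    """SHA-256 over the sorted TSV/JSON contents of a written bundle
    (excluding the report, which is derived)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def make_report(bundle: ResultsBundle) -> str:
    """Human-readable markdown summary of a results bundle (idempotent)."""
    c = bundle.counts
    lines = [
        "# SPA-fNIRS pipeline report",
        "",
        f"Run {bundle.manifest['config_hash']} (seed {bundle.manifest['seed']}, "
        f"version {bundle.manifest['version']})",
        "",
        f"Subjects: {bundle.manifest['n_input']} input, "
        f"{bundle.manifest['n_retained']} retained.",
        "",
        "## Protocol",
        "9 intervals over 55 min (baseline, touch, singing 10-20 min, hold, "
        "rest, touch, singing 35-45 min, hold, rest).",
        "",
        "## Subgroups",
        f"- subgroup 1 (StO2 increase): n = {c['n1']}",
        f"- subgroup 2 (StO2 decrease): n = {c['n2']}",
        f"- unassigned: n = {c['n_unassigned']}",
        f"- individually significant changes: {c['n_significant']}",
    ]
    if bundle.excluded:
        lines += ["", "## Exclusions / unassigned"]
        lines += [f"- {sid}: {reason}" for sid, reason in sorted(bundle.excluded.items())]
    if "chi2" in bundle.contingency:
        ct = bundle.contingency
        lines += [
            "",
            "## Sex-by-subgroup contingency",
            f"counts (sg1 F/M, sg2 F/M) = {tuple(ct['counts'])}; "
            f"chi2 = {ct['chi2']:.3f} (df=1, p = {ct['p']:.3f}); "
            f"log OR = {ct['log_or']:.3f} "
            f"[{ct['or_ci_low']:.3f}, {ct['or_ci_high']:.3f}]; "
            f"tau-b = {ct['tau_b']:.3f}",
        ]
    lines += ["", "## Files",
              "quality.tsv, assignments.tsv, deltas.tsv, subgroup_stats.tsv, "
              "table1.tsv, spearman.tsv, block_average_*.tsv, "
              "gam_surface_*.tsv, results.json"]
    return "\n".join(lines) + "\n"
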