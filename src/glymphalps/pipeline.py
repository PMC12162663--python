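"""End-to-end pipeline driver: simulate -> fit -> index -> stats.

Each stage reads the previous stage's products, every intermediate is
written to disk, and a run manifest (inputs, outputs, seed, checksums,
versions) makes the run reproducible byte-for-byte: the same config and
seed give the same checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alps import compute_alps, default_roi_set, extract_roi_means, place_rois
from .cohort import CohortSpec, PSG_FIELDS, QUESTIONNAIRE_FIELDS, simulate_cohort
from .io import read_cohort_csv, roiset_to_json, write_cohort_csv, write_dwi, write_ground_truth, write_maps
from .stats import (
    ADJUST_MODEL_I,
    ADJUST_MODEL_II,
    backward_select,
    compare_groups,
    paired_prepost,
    univariate_screen,
)
from .tensorfit import fit_tensor, tensor_to_maps

__all__ = ["RunConfig", "run_pipeline", "write_reports"]

_STAGES = ("simulate", "fit", "index", "stats")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; loadable from YAML."""

    out_dir: str
    seed: int
    stages: tuple[str, ...] = _STAGES
    n_per_group: dict = field(default_factory=lambda: {"HC": 8, "true_rTMS": 10, "sham_rTMS": 8})
    alps_convention: str = "per_hemisphere_then_average"
    roi_search_radius: int = 4
    p_screen: float = 0.2
    p_removal: float = 0.1
    noise_model: str = "rician"
    snr: float = 30.0
    n_directions: int = 32
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    cohort_csv: str | None = None  # required when running stats without simulate
    write_imaging: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        for name in ("p_screen", "p_removal"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.roi_search_radius < 0:
            raise ValueError("roi_search_radius must be >= 0")
        needs_cohort = "stats" in self.stages and "simulate" not in self.stages
        if needs_cohort and not self.cohort_csv:
            raise ValueError("stats without simulate requires cohort_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in payload:
            payload["grid_shape"] = tuple(payload["grid_shape"])
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |", "| " + " | ".join("---" for _ in header) + " |"]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join(lines) + "\n"


def write_reports(
    table: pd.DataFrame,
    out_dir: str | Path,
    p_screen: float = 0.2,
    p_removal: float = 0.1,
) -> dict:
    """Group-comparison, diffusivity/ALPS, regression, and pre/post reports.

    Emits four CSV tables with markdown companions plus a JSON
    elimination trace. Adjusted models that the sample size cannot
    support are recorded as skipped rather than silently dropped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- demographics & cognition ------------------------------------
    demo_vars = ["age", "gender", "education"] + [f for f in QUESTIONNAIRE_FIELDS if f in table.columns]
    sleep_vars = [f for f in PSG_FIELDS if f in table.columns]

    def comparison_frame(variables: list[str]) -> pd.DataFrame:
        rows = []
        for var in variables:
            res = compare_groups(table, var)
            if res.kind == "anova":
                row = {"variable": var, "test": "ANOVA", "statistic": res.statistic, "p": res.p}
                for g, (m, s, n) in res.group_stats.items():
                    row[f"{g}_mean"] = m
                    row[f"{g}_sd"] = s
                    row[f"{g}_n"] = n
                for (g1, g2), padj in res.pairwise.items():
                    row[f"tukey_{g1}_vs_{g2}"] = padj
            else:
                row = {"variable": var, "test": "chi2", "statistic": res.statistic, "p": res.p}
            rows.append(row)
        return pd.DataFrame(rows)

    demo = comparison_frame(demo_vars)
    sleep = comparison_frame(sleep_vars)
    alps_cmp = comparison_frame(["alps"])

    paths = {}
    for name, frame in (("table1_demographics", demo), ("table2_sleep", sleep), ("table3_alps", alps_cmp)):
        p_csv = out / f"{name}.csv"
        frame.to_csv(p_csv, index=False, float_format="%.6g")
        header = list(frame.columns)
        rows = [[f"{v:.4g}" if isinstance(v, float) else str(v) for v in rec] for rec in frame.itertuples(index=False)]
        (out / f"{name}.md").write_text(_fmt_md_table(header, rows))
        paths[name] = p_csv

    # -- univariate screen + backward-elimination models --------------
    candidates = ["age", "education"] + list(sleep_vars)
    uni = univariate_screen(table, outcome="alps", candidates=candidates, p_screen=p_screen)
    uni_frame = pd.DataFrame(
        [
            {"variable": u.variable, "beta": u.beta, "ci_low": u.ci_low, "ci_high": u.ci_high, "p": u.p, "flagged": u.flagged}
            for u in uni
        ]
    )
    screened = [u.variable for u in uni if u.flagged]

    models = {}
    trace_payload = {"p_screen": p_screen, "p_removal": p_removal, "screened": screened, "models": {}}
    specs = [("crude", ()), ("model_I", ADJUST_MODEL_I), ("model_II", ADJUST_MODEL_II)]
    for tag, adjust in specs:
        cand = [c for c in screened if c not in adjust]
        if not cand:
            trace_payload["models"][tag] = {"skipped": "no screened candidates"}
            continue
        try:
            res = backward_select(table, outcome="alps", screened=cand, adjust=adjust, p_removal=p_removal, model_tag=tag)
        except ValueError as exc:
            trace_payload["models"][tag] = {"skipped": str(exc)}
            continue
        models[tag] = res
        trace_payload["models"][tag] = {
            "retained": res.retained,
            "adjusted_for": res.adjusted_for,
            "trace": [{"removed": var, "p_at_removal": p} for var, p in res.trace],
            "n": res.n,
        }

    reg_rows = []
    for tag, res in models.items():
        for term, (beta, lo, hi, p) in res.params.items():
            reg_rows.append({"model": tag, "term": term, "beta": beta, "ci_low": lo, "ci_high": hi, "p": p, "forced": term in res.adjusted_for})
    reg_frame = pd.DataFrame(reg_rows)
    p4 = out / "table4_regression.csv"
    uni_frame.to_csv(out / "univariate_screen.csv", index=False, float_format="%.6g")
    reg_frame.to_csv(p4, index=False, float_format="%.6g")
    if len(reg_frame):
        rows = [[f"{v:.4g}" if isinstance(v, float) else str(v) for v in rec] for rec in reg_frame.itertuples(index=False)]
        (out / "table4_regression.md").write_text(_fmt_md_table(list(reg_frame.columns), rows))
    else:
        (out / "table4_regression.md").write_text("(no estimable models)\n")
    (out / "elimination_trace.json").write_text(json.dumps(trace_payload, indent=2, sort_keys=True))
    paths["table4_regression"] = p4

    # -- paired pre/post contrasts ------------------------------------
    paired_rows = []
    for group in ("true_rTMS", "sham_rTMS"):
        if not ((table["group"] == group) & (table["timepoint"] == "post")).any():
            continue
        for var in ["alps", "psqi", "isi", "ess", "total_sleep_time", "n2_duration", "arousal_index"]:
            if var not in table.columns:
                continue
            r = paired_prepost(table, var, group)
            paired_rows.append(
                {"group": group, "variable": var, "n_pairs": r.n_pairs, "mean_diff": r.mean_diff,
                 "ci_low": r.ci_low, "ci_high": r.ci_high, "t": r.t, "p": r.p, "degenerate": r.degenerate}
            )
    pd.DataFrame(paired_rows).to_csv(out / "prepost_contrasts.csv", index=False, float_format="%.6g")
    paths["prepost_contrasts"] = out / "prepost_contrasts.csv"
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    table: pd.DataFrame | None = None
    imaging: dict = {}

    try:
        if "simulate" in config.stages:
            cspec = CohortSpec(
                n_per_group=dict(config.n_per_group),
                snr=config.snr,
                noise_model=config.noise_model,
                n_directions=config.n_directions,
                grid_shape=config.grid_shape,
                seed=config.seed,
            )
            needs_imaging = "fit" in config.stages or "index" in config.stages or config.write_imaging
            table, imaging = simulate_cohort(cspec, imaging=needs_imaging)
            cohort_path = out / "cohort.csv"
            write_cohort_csv(table, cohort_path)
            outputs.append(cohort_path)
            if imaging and config.write_imaging:
                img_dir = out / "imaging"
                img_dir.mkdir(exist_ok=True)
                for (sid, tp), (truth, dwi) in imaging.items():
                    stem = img_dir / f"{sid}_{tp}"
                    write_dwi(dwi, f"{stem}_dwi.nii", f"{stem}.bval", f"{stem}.bvec")
                    write_ground_truth(truth, f"{stem}_labels.nii", f"{stem}_truth.json")
                    outputs += [Path(f"{stem}_dwi.nii"), Path(f"{stem}.bval"), Path(f"{stem}.bvec"),
                                Path(f"{stem}_labels.nii"), Path(f"{stem}_truth.json")]
        elif config.cohort_csv:
            table = read_cohort_csv(config.cohort_csv)

        maps_by_visit = {}
        if "fit" in config.stages:
            if not imaging:
                raise ValueError("fit stage requires simulated imaging (or run stage-wise via the library)")
            for key, (truth, dwi) in imaging.items():
                field = fit_tensor(dwi)
                maps_by_visit[key] = (truth, tensor_to_maps(field))

        if "index" in config.stages:
            if not maps_by_visit:
                raise ValueError("index stage requires fitted maps; include the fit stage")
            alps_rows = []
            for (sid, tp), (truth, maps) in maps_by_visit.items():
                initial = default_roi_set(truth.labels)
                placed = place_rois(maps, initial, search_radius=config.roi_search_radius)
                means = extract_roi_means(maps, placed)
                res = compute_alps(means, convention=config.alps_convention)
                alps_rows.append({"subject_id": sid, "timepoint": tp, "alps_left": res.alps_left,
                                  "alps_right": res.alps_right, "alps": res.alps_bilateral,
                                  "alps_true": truth.alps_true})
                if len(alps_rows) == 1:
                    (out / "rois_example.json").write_text(roiset_to_json(placed))
                    outputs.append(out / "rois_example.json")
            alps_frame = pd.DataFrame(alps_rows).sort_values(["subject_id", "timepoint"]).reset_index(drop=True)
            alps_path = out / "alps.csv"
            alps_frame.to_csv(alps_path, index=False, float_format="%.10g")
            outputs.append(alps_path)
            if table is not None:
                merged = table.merge(alps_frame[["subject_id", "timepoint", "alps"]],
                                     on=["subject_id", "timepoint"], how="left", suffixes=("_sim", ""))
                merged["alps"] = merged["alps"].fillna(merged.pop("alps_sim"))
                table = merged
                cohort_path = out / "cohort.csv"
                write_cohort_csv(table, cohort_path)

        if "stats" in config.stages:
            if table is None:
                raise ValueError("stats stage requires a cohort table")
            report_paths = write_reports(table, out / "reports", p_screen=config.p_screen, p_removal=config.p_removal)
            outputs += sorted(Path(out / "reports").glob("*"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": {**asdict(config), "stages": list(config.stages), "grid_shape": list(config.grid_shape)},
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs)) if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
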