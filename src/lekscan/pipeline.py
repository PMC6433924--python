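"""End-to-end orchestration: filter -> scan -> windows -> tests -> F_ST.

``run_all`` drives the whole analysis from a single structured config
(dict or YAML file), writes every stage's output plus a ``report.json``
of headline numbers and a ``manifest.json`` (config snapshot, seed,
checksums, stage timings) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .data import (
    DesignSpec,
    filter_loci,
    orient_global_minor,
    read_count_table,
    read_design,
    write_count_table,
)
from .experiment import ExperimentConfig, evaluate_recovery, simulate_experiment
from .fst import regimen_fst
from .scan import scan_loci
from .windows import (
    arm_distribution_test,
    build_windows,
    p_s_less_f,
    regimen_ttest,
    starting_freq_test,
    window_enrichment,
    window_mean_he,
)

__all__ = ["PipelineError", "run_all", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "input": {"counts": None, "design": None, "dialect": "native_tsv",
              "synthetic": None},
    "filter": {"min_cov": 5, "max_cov": 250, "min_maf": 0.05},
    "scan": {"fdr": 0.05},
    "windows": {"size": 50_000, "step": 10_000},
    "tests": {"n_resamples": 10_000},
    "fst": {"estimator": "wc84"},
}


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and normalize a pipeline config (YAML path or mapping)."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = {k: dict(v) if isinstance(v, dict) else v
              for k, v in DEFAULT_CONFIG.items()}
    for key, val in dict(config).items():
        if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_all(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every stage in order; returns the manifest dict.

    Stage order mirrors the analysis: load, filter, scan, windows,
    tests, fst, report.  A failing stage raises :class:`PipelineError`
    naming the stage.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg["seed"]))

    manifest: dict[str, Any] = {
        "config": _jsonable(cfg),
        "seed": cfg["seed"],
        "stages": {},
        "outputs": {},
    }
    report: dict[str, Any] = {}
    truth = None

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 4)

        return done

    # ---- load -------------------------------------------------------------
    done = stage("load")
    try:
        inp = cfg["input"]
        if inp.get("counts"):
            if not inp.get("design"):
                raise ValueError("a design file is required with a counts file")
            table = read_count_table(inp["counts"], dialect=inp.get(
                "dialect", "native_tsv"))
            design = read_design(inp["design"])
        elif inp.get("synthetic"):
            syn = dict(inp["synthetic"])
            exp_cfg = ExperimentConfig(**syn)
            table, truth = simulate_experiment(exp_cfg, rng)
            write_count_table(table, out / "synthetic_counts.tsv")
            design = DesignSpec(
                {lid: ("success" if lid.startswith("S")
                       else "failure" if lid.startswith("F") else "control")
                 for lid in table.line_ids}
            )
            design.to_tsv(out / "synthetic_design.tsv")
        else:
            raise ValueError("config needs input.counts or input.synthetic")
        table.validate()
        report["n_loci_input"] = table.n_loci
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    done()

    # ---- filter -----------------------------------------------------------
    done = stage("filter")
    try:
        fcfg = cfg["filter"]
        table = orient_global_minor(table)
        table = filter_loci(
            table,
            min_cov=fcfg["min_cov"],
            max_cov=fcfg["max_cov"],
            min_global_maf=fcfg["min_maf"],
        )
        write_count_table(table, out / "filtered_counts.tsv")
        report["n_loci_filtered"] = table.n_loci
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    done()

    # ---- scan -------------------------------------------------------------
    done = stage("scan")
    try:
        scan = scan_loci(table, design, fdr=cfg["scan"]["fdr"])
        scan.to_tsv(out / "locus_stats.tsv")
        st = scan.stats
        report.update(
            n_diffstat=int(st["is_diffstat"].sum()),
            n_sig_diffstat=int(st["is_sig_diffstat"].sum()),
            n_glm_sig=int(st["is_glm_sig"].sum()),
            n_sdv=int(st["is_sdv"].sum()),
            glm_sig_threshold=scan.glm_sig_threshold,
        )
        if truth is not None:
            rec = evaluate_recovery(scan, truth)
            report["recovery"] = _jsonable(rec.__dict__)
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc
    done()

    # ---- windows ----------------------------------------------------------
    done = stage("windows")
    try:
        wcfg = cfg["windows"]
        extents = {
            arm: (int(grp["pos"].min()), int(grp["pos"].max()))
            for arm, grp in table.loci.groupby("chrom")
        }
        win = build_windows(extents, size=wcfg["size"], step=wcfg["step"])
        win = window_mean_he(win, table.loci, scan.he, table.line_ids)
        win = window_enrichment(win, table.loci, scan.sdv_mask,
                                fdr=cfg["scan"]["fdr"])
        win.to_csv(out / "windows.tsv", sep="\t", index=False,
                   lineterminator="\n")
        report["n_windows"] = len(win)
        report["n_windows_with_sdv"] = int((win["s"] >= 1).sum())
        report["n_enriched_windows"] = int(win["is_enriched"].sum())
    except Exception as exc:
        raise PipelineError("windows", str(exc)) from exc
    done()

    # ---- tests ------------------------------------------------------------
    done = stage("tests")
    try:
        tcfg = cfg["tests"]
        nonempty = win[win["n"] >= 1]

        def line_medians(frame, lids):
            return [float(frame[f"he_{lid}"].median()) for lid in lids]

        med_s = line_medians(nonempty, design.success_lines)
        med_f = line_medians(nonempty, design.failure_lines)
        t_genome = regimen_ttest(med_s, med_f)
        tests_out: dict[str, Any] = {
            "t_genome": {"t": t_genome.t, "df": t_genome.df,
                         "p": t_genome.p_value},
            "median_he": {
                reg: float(np.mean(line_medians(nonempty, design.lines(reg))))
                for reg in ("success", "failure", "control")
                if design.lines(reg)
            },
        }
        enriched = nonempty[nonempty["is_enriched"]]
        if len(enriched) >= 2:
            t_enr = regimen_ttest(
                line_medians(enriched, design.success_lines),
                line_medians(enriched, design.failure_lines),
            )
            tests_out["t_enriched"] = {"t": t_enr.t, "df": t_enr.df,
                                       "p": t_enr.p_value}

        st = scan.stats
        if st["is_diffstat"].any():
            tests_out["p_s_less_f"] = p_s_less_f(
                scan.he, st["is_diffstat"].to_numpy(), table.line_ids, design
            )
        if st["is_sdv"].any() and design.control_lines:
            sft = starting_freq_test(
                st["start_freq"].to_numpy(),
                st["is_sdv"].to_numpy(),
                n_resamples=tcfg["n_resamples"],
                rng=rng,
            )
            tests_out["starting_freq"] = _jsonable(sft.__dict__)
        if report["n_enriched_windows"] >= 1:
            armt = arm_distribution_test(
                win.loc[win["is_enriched"], "chrom"].tolist(),
                win["chrom"].tolist(),
                n_resamples=tcfg["n_resamples"],
                rng=rng,
            )
            tests_out["arm_distribution"] = armt.to_dict(orient="records")
        with open(out / "tests.json", "w") as fh:
            json.dump(_jsonable(tests_out), fh, indent=2, sort_keys=True)
        report["tests"] = _jsonable(tests_out)
    except Exception as exc:
        raise PipelineError("tests", str(exc)) from exc
    done()

    # ---- fst --------------------------------------------------------------
    done = stage("fst")
    try:
        fst = regimen_fst(table, design, estimator=cfg["fst"]["estimator"])
        fst.matrix.to_csv(out / "fst.tsv", sep="\t", lineterminator="\n")
        report["fst"] = {
            "success": fst.fst_success,
            "failure": fst.fst_failure,
            "dfst": fst.dfst,
            "estimator": cfg["fst"]["estimator"],
        }
    except Exception as exc:
        raise PipelineError("fst", str(exc)) from exc
    done()

    # ---- report + manifest ------------------------------------------------
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    manifest["report"] = report
    return manifest
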