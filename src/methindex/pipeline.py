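"""End-to-end orchestration: template → reads → calls → cohort → fits → report.

A single JSON config drives the run.  Simulation stages are seeded from one
master seed (sub-streams are spawned per stage, so adding a stage never
perturbs another), every produced file is hashed into a run manifest, and
the same config + seed reproduce the run byte-for-byte (manifests differ
only in their timing section).

Minimal config (the shipped demo)::

    {
      "seed": 7,
      "template": {"simulate": true},
      "reads": {"simulate": true},
      "cohort": {"simulate": true},
      "models": [
        {"endpoint": "os", "coding": "tertile",
         "covariates": ["age", "kps", "idh1"]}
      ],
      "spline": {"basis": "rcs", "n_knots": 5},
      "diagnostics": ["schoenfeld", "martingale"]
    }

When reads are simulated they realize the simulated cohort's per-patient
indices, are re-called with the QC-gated caller, and the called index is
merged back into the cohort table — so the downstream models run on the
assay's output, not on the generator's bookkeeping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .amplicon import (
    DEFAULT_TEMPLATE,
    read_template,
    synthesize_template,
    write_template,
)
from .caller import CallerConfig, call_sample, read_reads, write_calls, write_reads
from .synthetic_data import (
    CohortConfig,
    ReadSimConfig,
    default_cohort_config,
    default_os_endpoint,
    default_pfs_endpoint,
    export_cohort,
    import_cohort,
    pattern_with_index,
    simulate_cohort,
    simulate_reads,
)
from .survival import (
    ModelSpec,
    fit_cox,
    fit_spline_cox,
    martingale_diagnostics,
    render_table_text,
    report_tables,
    schoenfeld_test,
)

__all__ = ["PipelineConfigError", "PipelineError", "RunConfig", "run_pipeline"]

logger = logging.getLogger("methindex.pipeline")


class PipelineConfigError(ValueError):
    """The run configuration is invalid."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; see the module docstring for the JSON."""

    seed: int
    outdir: str = "run_out"
    template: dict = field(default_factory=lambda: {"simulate": True})
    reads: Optional[dict] = field(default_factory=lambda: {"simulate": True})
    cohort: dict = field(default_factory=lambda: {"simulate": True})
    models: tuple[dict, ...] = (
        {"endpoint": "os", "coding": "tertile", "covariates": ["age", "kps", "idh1"]},
    )
    spline: Optional[dict] = None
    diagnostics: tuple[str, ...] = ()
    plots: bool = False
    caller: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise PipelineConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        needs_sim = any(
            (raw.get(k) or {}).get("simulate") for k in ("template", "reads", "cohort")
        ) or "seed" not in raw
        if "seed" not in raw:
            raise PipelineConfigError("config must set an integer 'seed'")
        cohort = raw.get("cohort", {"simulate": True})
        if not cohort.get("simulate") and "csv" not in cohort:
            raise PipelineConfigError(
                "cohort section must either set 'simulate': true or give a 'csv' path"
            )
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=raw.get("outdir", "run_out"),
            template=raw.get("template", {"simulate": True}),
            reads=raw.get("reads", {"simulate": True}),
            cohort=cohort,
            models=tuple(raw.get("models", cls.models)),
            spline=raw.get("spline"),
            diagnostics=tuple(raw.get("diagnostics", ())),
            plots=bool(raw.get("plots", False)),
            caller=raw.get("caller", {}),
        )
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = _time.perf_counter() - self.t0
            manifest["timing"][name] = round(elapsed, 3)
            if exc is not None:
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, elapsed)
            return False

    return _Ctx()


def _record(manifest: dict, stage: str, path: Path) -> None:
    manifest["stages"].setdefault(stage, {})[path.name] = _sha256(path)


def _cohort_config_from(section: dict, seed: int) -> CohortConfig:
    cfg = default_cohort_config(seed=seed)
    if section.get("os_effect_mode"):
        cfg = dataclasses.replace(
            cfg, os=default_os_endpoint(effect_mode=section["os_effect_mode"])
        )
    if section.get("pfs_effect_mode"):
        cfg = dataclasses.replace(
            cfg, pfs=default_pfs_endpoint(effect_mode=section["pfs_effect_mode"])
        )
    scale = int(section.get("scale", 1))
    if scale != 1:
        cfg = cfg.scaled(scale)
    return cfg


def run_pipeline(
    config: RunConfig | dict | str | Path, outdir: Optional[str | Path] = None
) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_json(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(("template", "reads", "cohort"), root_ss.spawn(3))
    }

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": {},
        "timing": {},
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # -- template -----------------------------------------------------------
    with _stage(manifest, "template"):
        if config.template.get("simulate"):
            if config.template.get("default", True) and not config.template.get(
                "randomize"
            ):
                template = DEFAULT_TEMPLATE
            else:
                template = synthesize_template(seed=stage_seeds["template"])
        else:
            template = read_template(
                config.template["fasta"], config.template.get("sidecar")
            )
        fa = out / "template.fa"
        write_template(template, fa)
        _record(manifest, "template", fa)
        _record(manifest, "template", fa.with_suffix(".json"))
        site_map = template.site_map

    # -- cohort (simulated before reads so reads can realize its indices) ---
    with _stage(manifest, "cohort"):
        if config.cohort.get("simulate"):
            cohort_cfg = _cohort_config_from(config.cohort, stage_seeds["cohort"])
            cohort = simulate_cohort(cohort_cfg)
        else:
            cohort = import_cohort(config.cohort["csv"])

    # -- reads + calls ------------------------------------------------------
    caller_cfg = CallerConfig(
        detection_threshold=float(config.caller.get("detection_threshold", 0.10)),
        min_site_coverage=int(config.caller.get("min_site_coverage", 2)),
    )
    call_mismatches = 0
    if config.reads and (config.reads.get("simulate") or config.reads.get("fasta")):
        with _stage(manifest, "reads"):
            if config.reads.get("simulate"):
                rng = np.random.default_rng(stage_seeds["reads"])
                n_samples = int(config.reads.get("n_samples", len(cohort)))
                n_samples = min(n_samples, len(cohort))
                readsets = []
                for i in range(n_samples):
                    truth_index = int(cohort["index"].iloc[i])
                    pattern = pattern_with_index(site_map, truth_index, rng)
                    rs, _ = simulate_reads(
                        template,
                        site_map,
                        ReadSimConfig(
                            allele_fractions=pattern.fractions,
                            conversion_failure_rate=float(
                                config.reads.get("conversion_failure_rate", 0.0)
                            ),
                            seq_error_rate=float(
                                config.reads.get("seq_error_rate", 0.0)
                            ),
                        ),
                        rng=rng,
                        sample_id=str(cohort["id"].iloc[i]),
                    )
                    readsets.append(rs)
                reads_fa = out / "reads.fa"
                write_reads(readsets, reads_fa)
                _record(manifest, "reads", reads_fa)
            else:
                readsets = read_reads(config.reads["fasta"])

        with _stage(manifest, "calls"):
            calls = [call_sample(rs, site_map, caller_cfg) for rs in readsets]
            calls_csv = out / "calls.csv"
            write_calls(calls, calls_csv)
            _record(manifest, "calls", calls_csv)
            by_id = {c.sample_id: c for c in calls}
            merged = 0
            for i, sid in enumerate(cohort["id"]):
                c = by_id.get(str(sid))
                if c is None:
                    continue
                if c.qc_pass:
                    if int(cohort["index"].iloc[i]) != c.index:
                        call_mismatches += 1
                    cohort.iloc[i, cohort.columns.get_loc("index")] = c.index
                    merged += 1
            manifest["stages"]["calls"]["merged_into_cohort"] = merged
            manifest["stages"]["calls"]["truth_mismatches"] = call_mismatches

    cohort_csv = out / "cohort.csv"
    export_cohort(cohort, cohort_csv)
    _record(manifest, "cohort", cohort_csv)

    # -- model fits ---------------------------------------------------------
    fits = []
    with _stage(manifest, "fits"):
        for m in config.models:
            spec = ModelSpec(
                endpoint=m.get("endpoint", "os"),
                coding=m.get("coding", "tertile"),
                covariates=tuple(m.get("covariates", ("age", "kps", "idh1"))),
                ties=m.get("ties", "efron"),
            )
            fits.append(fit_cox(cohort, spec))
        table = report_tables(fits)
        report_csv = out / "report.csv"
        table.to_csv(report_csv, index=False)
        (out / "report.txt").write_text(render_table_text(table))
        _record(manifest, "fits", report_csv)
        _record(manifest, "fits", out / "report.txt")

    # -- spline -------------------------------------------------------------
    spline_result = None
    if config.spline is not None:
        with _stage(manifest, "spline"):
            s = config.spline
            spec = ModelSpec(
                endpoint=s.get("endpoint", "os"),
                coding="continuous",
                covariates=tuple(
                    s.get("covariates", ("age", "kps", "idh1", "resection"))
                ),
            )
            spline_result = fit_spline_cox(
                cohort,
                spec,
                basis=s.get("basis", "rcs"),
                n_knots=int(s.get("n_knots", 5)),
            )
            curve = pd.DataFrame(
                {
                    "index": spline_result.grid,
                    "log_hr": spline_result.log_hr,
                    "ci_lower": spline_result.ci_lower,
                    "ci_upper": spline_result.ci_upper,
                }
            )
            curve_csv = out / "spline_curve.csv"
            curve.to_csv(curve_csv, index=False)
            _record(manifest, "spline", curve_csv)
            manifest["stages"]["spline"]["chi2"] = round(spline_result.chi2, 3)
            manifest["stages"]["spline"]["argmin_index"] = spline_result.curve_argmin()

    # -- diagnostics --------------------------------------------------------
    if config.diagnostics:
        with _stage(manifest, "diagnostics"):
            diag_out = {}
            if "schoenfeld" in config.diagnostics and fits:
                sch = schoenfeld_test(fits[0])
                diag_out["schoenfeld"] = {
                    term: {
                        "chi2": round(float(r["chi2"]), 4),
                        "df": int(r["df"]),
                        "p": round(float(r["p"]), 4),
                    }
                    for term, r in sch.schoenfeld.iterrows()
                }
            if "martingale" in config.diagnostics:
                md = martingale_diagnostics(
                    cohort, endpoint=config.models[0].get("endpoint", "os")
                )
                diag_out["martingale"] = {
                    "residual_sum": float(md.martingale["residual"].sum()),
                    "smooth_min_at_index": float(
                        md.smooth.loc[md.smooth["y"].idxmin(), "x"]
                    ),
                }
            diag_json = out / "diagnostics.json"
            diag_json.write_text(json.dumps(diag_out, indent=2) + "\n")
            _record(manifest, "diagnostics", diag_json)

    # -- plots --------------------------------------------------------------
    if config.plots:
        with _stage(manifest, "plots"):
            from .plots import plot_adjusted_curves, plot_martingale, plot_spline
            from .survival import adjusted_curves

            categorical = [f for f in fits if f.spec.coding != "continuous"]
            if categorical:
                p = plot_adjusted_curves(
                    adjusted_curves(categorical[0]), out / "survival_curves.png"
                )
                _record(manifest, "plots", p)
            if spline_result is not None:
                p = plot_spline(spline_result, out / "spline_curve.png")
                _record(manifest, "plots", p)
            if "martingale" in config.diagnostics:
                md = martingale_diagnostics(cohort)
                p = plot_martingale(md, out / "martingale.png")
                _record(manifest, "plots", p)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
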