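"""Synthetic inputs for the whole pipeline: reads with truth, and cohorts.

Two generators live here.

**Read simulator** — emulates the bisulfite Sanger assay on one sample:
each of the four overlapping reads (forward/reverse primer, duplicate
reactions) is an independent molecule draw.  Per CpG the molecule is
methylated with that site's allele fraction; per control cytosine the
bisulfite reaction fails (C survives) with a configurable rate; every base
may finally be miscalled uniformly at a configurable error rate.  The truth
pattern is returned alongside so callers can be scored exactly.

**Cohort simulator** — emulates a 240-patient newly-diagnosed glioblastoma
cohort with the study's structure: four methylation strata (unmethylated
n=115 and index tertiles n=44/38/43, indices uniform within each stratum),
stratum-specific age and Karnofsky-performance-status distributions,
resection and IDH1 mutation frequencies, and overall/progression-free
survival drawn from a proportional-hazards model by inverse-CDF sampling.
The default effect sizes are the study's adjusted hazard ratios (tertile OS
1.62 / 0.48 / 0.62; PFS 0.85 / 0.27 / 0.46; 4% per-unit hazard reduction in
linear mode), the baseline is calibrated so the unmethylated arm's marginal
median OS is 14 months (PFS 8 months), and per-stratum exponential dropout
plus an administrative cutoff reproduce the observed censoring fractions
(40.9 / 15.9 / 21.1 / 7.0%).

Everything is reproducible: one integer seed fully determines the output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .amplicon import (
    AmpliconTemplate,
    MethylationPattern,
    SiteMap,
    bisulfite_convert,
    reverse_complement,
)
from .caller import Read, ReadSet

__all__ = [
    "ReadSimConfig",
    "EndpointConfig",
    "CohortConfig",
    "SchemaError",
    "simulate_reads",
    "pattern_with_index",
    "default_os_endpoint",
    "default_pfs_endpoint",
    "default_cohort_config",
    "simulate_cohort",
    "export_cohort",
    "import_cohort",
    "COHORT_COLUMNS",
    "RESECTION_LEVELS",
    "tertile_group_of_index",
]

_LOG = math.log

# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimConfig:
    """Noise model for one sample's simulated read set."""

    allele_fractions: Optional[tuple[float, ...]] = None
    n_reads: int = 4
    conversion_failure_rate: float = 0.0
    seq_error_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("conversion_failure_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.n_reads <= 4:
            raise ValueError("n_reads must be 1-4")


_READ_LAYOUT = (  # orientation, replicate for the 4 overlapping reactions
    ("forward", 1),
    ("forward", 2),
    ("reverse", 1),
    ("reverse", 2),
)
_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def pattern_with_index(
    site_map: SiteMap, index: int, rng: np.random.Generator
) -> MethylationPattern:
    """Random binary methylation pattern with exactly ``index`` methylated sites."""
    if not 0 <= index <= site_map.n_cpg:
        raise ValueError(f"index {index} outside [0, {site_map.n_cpg}]")
    chosen = rng.choice(site_map.n_cpg, size=index, replace=False)
    fractions = np.zeros(site_map.n_cpg)
    fractions[chosen] = 1.0
    return MethylationPattern(tuple(fractions))


def simulate_reads(
    template: AmpliconTemplate,
    site_map: SiteMap,
    config: ReadSimConfig,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
) -> tuple[ReadSet, MethylationPattern]:
    """Simulate one sample's bisulfite Sanger read set plus its truth pattern.

    Each read is an independent allele draw; reverse-orientation reads are
    stored reverse-complemented, as they would be base-called.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.allele_fractions is None:
        fractions = rng.random(site_map.n_cpg)
    else:
        fractions = np.asarray(config.allele_fractions, dtype=float)
        if fractions.shape != (site_map.n_cpg,):
            raise ValueError(
                f"allele_fractions has shape {fractions.shape}, "
                f"expected ({site_map.n_cpg},)"
            )
    truth = MethylationPattern(tuple(fractions))

    reads = []
    for i in range(config.n_reads):
        orientation, replicate = _READ_LAYOUT[i]
        allele = rng.random(site_map.n_cpg) < fractions
        mol = list(bisulfite_convert(template, allele, site_map))
        if config.conversion_failure_rate > 0:
            fails = rng.random(site_map.n_controls) < config.conversion_failure_rate
            for pos, failed in zip(site_map.control_positions, fails):
                if failed:
                    mol[pos] = "C"
        if config.seq_error_rate > 0:
            errs = np.flatnonzero(rng.random(len(mol)) < config.seq_error_rate)
            for pos in errs:
                mol[pos] = _OTHER_BASES[mol[pos]][rng.integers(3)]
        seq = "".join(mol)
        if orientation == "reverse":
            seq = reverse_complement(seq)
        reads.append(
            Read(
                read_id=f"{sample_id}|{orientation[0].upper()}|{replicate}",
                orientation=orientation,
                replicate=replicate,
                sequence=seq,
            )
        )
    return ReadSet(sample_id, tuple(reads)), truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

RESECTION_LEVELS = ("biopsy", "subtotal", "gross_total", "unknown")

COHORT_COLUMNS = (
    "id",
    "age",
    "gender",
    "kps",
    "resection",
    "idh1",
    "index",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
)

#: index ranges of the strata, unmethylated first
_TERTILE_RANGES = ((0, 0), (1, 6), (7, 12), (13, 17))
_QUINTILE_RANGES = ((0, 0), (1, 3), (4, 6), (7, 9), (10, 13), (14, 17))

_EFFECT_MODES = ("null", "binary", "tertile", "quintile", "linear", "spline-shape")


class SchemaError(ValueError):
    """Cohort CSV does not match the expected schema."""


def tertile_group_of_index(index: np.ndarray) -> np.ndarray:
    """Stratum 0-3 (unmethylated, 1-6, 7-12, 13-17) for each index value."""
    index = np.asarray(index)
    return np.select(
        [index == 0, index <= 6, index <= 12], [0, 1, 2], default=3
    )


@dataclass(frozen=True)
class EndpointConfig:
    """Hazard model for one survival endpoint (OS or PFS).

    ``covariate_log_hrs`` keys: age (per year, centered at the unmethylated
    stratum's mean), kps (per point, likewise centered), idh1 (mutant vs
    wild-type), res_subtotal / res_gross_total / res_unknown (vs biopsy).
    The Weibull baseline scale is calibrated at simulation time so the
    unmethylated arm's marginal median equals ``baseline_median`` months.
    """

    name: str = "os"
    effect_mode: str = "tertile"
    tertile_log_hrs: tuple[float, float, float] = (
        _LOG(1.62),
        _LOG(0.48),
        _LOG(0.62),
    )
    quintile_log_hrs: tuple[float, ...] = (
        _LOG(1.99),
        _LOG(1.28),
        _LOG(0.46),
        _LOG(0.46),
        _LOG(0.68),
    )
    binary_log_hr: float = _LOG(0.79)
    linear_log_hr: float = _LOG(0.96)
    shape_nodes: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (3.5, _LOG(1.62)),
        (11.0, _LOG(0.40)),
        (15.0, _LOG(0.62)),
        (17.0, _LOG(0.62)),
    )
    covariate_log_hrs: dict[str, float] = field(
        default_factory=lambda: {
            "age": _LOG(1.02),
            "kps": _LOG(0.98),
            "idh1": _LOG(0.56),
            "res_subtotal": 0.0,
            "res_gross_total": 0.0,
            "res_unknown": 0.0,
        }
    )
    baseline_median: float = 14.0
    weibull_shape: float = 1.0
    censoring: bool = True
    dropout_targets: tuple[float, float, float, float] = (0.409, 0.159, 0.211, 0.070)
    admin_cutoff_months: float = 132.0

    def __post_init__(self) -> None:
        if self.effect_mode not in _EFFECT_MODES:
            raise ValueError(f"effect_mode must be one of {_EFFECT_MODES}")
        if self.baseline_median <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline parameters must be positive")

    def methylation_log_hr(self, index: np.ndarray) -> np.ndarray:
        """Log hazard ratio vs index 0 implied by the configured effect mode."""
        index = np.asarray(index, dtype=float)
        if self.effect_mode == "null":
            return np.zeros_like(index)
        if self.effect_mode == "binary":
            return np.where(index > 0, self.binary_log_hr, 0.0)
        if self.effect_mode == "tertile":
            coefs = np.array((0.0,) + tuple(self.tertile_log_hrs))
            return coefs[tertile_group_of_index(index)]
        if self.effect_mode == "quintile":
            edges = np.array([1, 4, 7, 10, 14, 18], dtype=float)
            group = np.searchsorted(edges, index, side="right")
            coefs = np.array((0.0,) + tuple(self.quintile_log_hrs))
            return coefs[group]
        if self.effect_mode == "linear":
            return self.linear_log_hr * index
        nodes = np.array(self.shape_nodes)
        return np.interp(index, nodes[:, 0], nodes[:, 1])


def default_os_endpoint(**overrides) -> EndpointConfig:
    return dataclasses.replace(EndpointConfig(name="os"), **overrides)


def default_pfs_endpoint(**overrides) -> EndpointConfig:
    cfg = EndpointConfig(
        name="pfs",
        tertile_log_hrs=(_LOG(0.85), _LOG(0.27), _LOG(0.46)),
        quintile_log_hrs=(
            _LOG(0.80),
            _LOG(0.92),
            _LOG(0.21),
            _LOG(0.31),
            _LOG(0.48),
        ),
        binary_log_hr=_LOG(0.60),
        linear_log_hr=_LOG(0.94),
        shape_nodes=(
            (0.0, 0.0),
            (3.5, _LOG(0.85)),
            (11.0, _LOG(0.25)),
            (15.0, _LOG(0.46)),
            (17.0, _LOG(0.46)),
        ),
        covariate_log_hrs={
            "age": 0.0,
            "kps": _LOG(0.99),
            "idh1": _LOG(0.52),
            "res_subtotal": _LOG(2.08),
            "res_gross_total": _LOG(1.59),
            "res_unknown": 0.0,
        },
        baseline_median=8.0,
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass(frozen=True)
class CohortConfig:
    """Structure of the simulated cohort (defaults follow the study cohort)."""

    seed: int = 0
    group_sizes: tuple[int, int, int, int] = (115, 44, 38, 43)
    quintile_group_sizes: tuple[int, ...] = (115, 24, 20, 14, 31, 36)
    age_means: tuple[float, ...] = (58.5, 57.4, 61.0, 60.0)
    age_sds: tuple[float, ...] = (11.5, 14.8, 11.8, 12.2)
    age_bounds: tuple[float, float] = (18.0, 90.0)
    male_fraction: float = 0.59 / 0.98  # two-level split renormalized
    kps_means: tuple[float, ...] = (82.0, 82.1, 78.5, 81.3)
    kps_sds: tuple[float, ...] = (10.5, 10.8, 8.57, 11.0)
    resection_counts: tuple[tuple[int, ...], ...] = (
        (19, 37, 48, 11),
        (6, 11, 21, 6),
        (6, 14, 14, 4),
        (3, 13, 23, 4),
    )
    idh1_rates: tuple[float, ...] = (5 / 115, 2 / 44, 4 / 38, 4 / 43)
    index_sampler: Optional[
        Callable[[np.random.Generator, int, tuple[int, int]], np.ndarray]
    ] = None  # hook: (rng, size, (lo, hi)) -> indices; default uniform
    os: EndpointConfig = field(default_factory=default_os_endpoint)
    pfs: EndpointConfig = field(default_factory=default_pfs_endpoint)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.group_sizes) or sum(self.group_sizes) <= 0:
            raise ValueError("group sizes must be non-negative with positive total")

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes)

    def scaled(self, factor: int) -> "CohortConfig":
        """Same structure with every stratum size multiplied by ``factor``."""
        return dataclasses.replace(
            self,
            group_sizes=tuple(s * factor for s in self.group_sizes),
            quintile_group_sizes=tuple(
                s * factor for s in self.quintile_group_sizes
            ),
        )

    def unmethylated_only(self, n: int, censoring: bool = False) -> "CohortConfig":
        """Unmethylated arm only; censoring off by default (pure event times)."""
        return dataclasses.replace(
            self,
            group_sizes=(n, 0, 0, 0),
            os=dataclasses.replace(self.os, censoring=censoring),
            pfs=dataclasses.replace(self.pfs, censoring=censoring),
        )


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    return dataclasses.replace(CohortConfig(seed=seed), **overrides)


# -- calibration ------------------------------------------------------------

_CALIBRATION_SEED = 1_234_567  # internal; independent of the user's seed
_CALIBRATION_N = 40_000


def _draw_group_covariates(
    config: CohortConfig, group: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariate draws given each patient's stratum (0-3)."""
    n = len(group)
    age = rng.normal(
        np.take(config.age_means, group), np.take(config.age_sds, group)
    ).clip(*config.age_bounds)
    gender = np.where(rng.random(n) < config.male_fraction, "male", "female")
    kps = (
        (rng.normal(np.take(config.kps_means, group), np.take(config.kps_sds, group)))
        .clip(40, 100)
    )
    kps = (np.round(kps / 10) * 10).clip(40, 100).astype(int)
    probs = np.array(
        [np.array(c, dtype=float) / sum(c) for c in config.resection_counts]
    )
    u = rng.random(n)
    cum = probs.cumsum(axis=1)[group]
    res_idx = (u[:, None] > cum).sum(axis=1)
    resection = np.array(RESECTION_LEVELS)[res_idx]
    idh1 = (rng.random(n) < np.take(config.idh1_rates, group)).astype(int)
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "gender": gender,
            "kps": kps,
            "resection": resection,
            "idh1": idh1,
        }
    )


def _covariate_lp(
    cov: pd.DataFrame, config: CohortConfig, ep: EndpointConfig
) -> np.ndarray:
    """Covariate part of the linear predictor, centered at the unmethylated
    stratum's mean age/KPS so the calibrated baseline stays interpretable."""
    b = ep.covariate_log_hrs
    lp = b.get("age", 0.0) * (cov["age"].to_numpy() - config.age_means[0])
    lp = lp + b.get("kps", 0.0) * (cov["kps"].to_numpy() - config.kps_means[0])
    lp = lp + b.get("idh1", 0.0) * cov["idh1"].to_numpy()
    res = cov["resection"].to_numpy()
    lp = lp + b.get("res_subtotal", 0.0) * (res == "subtotal")
    lp = lp + b.get("res_gross_total", 0.0) * (res == "gross_total")
    lp = lp + b.get("res_unknown", 0.0) * (res == "unknown")
    return np.asarray(lp, dtype=float)


def _group_ranges(config: CohortConfig, ep: EndpointConfig):
    if ep.effect_mode == "quintile":
        return config.quintile_group_sizes, _QUINTILE_RANGES
    return config.group_sizes, _TERTILE_RANGES


def _draw_index(
    config: CohortConfig,
    lo_hi: tuple[int, int],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = lo_hi
    if config.index_sampler is not None:
        idx = np.asarray(config.index_sampler(rng, size, (lo, hi)), dtype=int)
        if idx.size and (idx.min() < lo or idx.max() > hi):
            raise ValueError("index_sampler produced indices outside the stratum")
        return idx
    return rng.integers(lo, hi + 1, size=size)


def _calibration_clp(
    config: CohortConfig, ep: EndpointConfig, group_range: tuple[int, int], m: int
) -> np.ndarray:
    """Internal large-sample draw of the centered linear predictor for one
    stratum (covariates + methylation effect), used for calibration only."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    idx = _draw_index(config, group_range, m, rng)
    tert = tertile_group_of_index(idx)
    cov = _draw_group_covariates(config, tert, rng)
    return _covariate_lp(cov, config, ep) + ep.methylation_log_hr(idx)


def _calibrate_baseline_scale(config: CohortConfig, ep: EndpointConfig) -> float:
    """Weibull scale such that the unmethylated arm's marginal median equals
    ``ep.baseline_median`` (solved on the survival-mixture identity, so the
    calibration itself is deterministic and noise-free)."""
    clp = _calibration_clp(config, ep, (0, 0), _CALIBRATION_N)
    e = np.exp(clp)
    m, k = ep.baseline_median, ep.weibull_shape

    def f(log_z: float) -> float:
        z = math.exp(log_z)  # z = (m / scale)^k
        return float(np.mean(np.exp(-z * e))) - 0.5

    log_z = brentq(f, -20.0, 20.0, xtol=1e-12)
    return m / math.exp(log_z) ** (1.0 / k)


def _p_censored_exponential(
    mu: float, rates: np.ndarray, cutoff: float
) -> float:
    """P(censor) under exponential events (rates), dropout mu, admin cutoff."""
    tot = rates + mu
    p_event = rates / tot * (1.0 - np.exp(-tot * cutoff))
    return float(1.0 - p_event.mean())


def _p_censored_weibull(
    mu: float, clp: np.ndarray, scale: float, shape: float, cutoff: float
) -> float:
    t = np.linspace(1e-6, cutoff, 400)
    e = np.exp(clp[:, None])
    zk = (t / scale) ** shape
    dens = shape / scale * (t / scale) ** (shape - 1) * e * np.exp(-zk * e)
    p_event = np.trapezoid(dens * np.exp(-mu * t), t, axis=1)
    return float(1.0 - p_event.mean())


def _calibrate_dropout(
    config: CohortConfig, ep: EndpointConfig, scale: float
) -> tuple[float, ...]:
    """Per-stratum exponential dropout rate hitting the target censoring
    fraction (0 if the administrative cutoff alone already censors more)."""
    sizes, ranges = _group_ranges(config, ep)
    # dropout targets are given per tertile stratum; map finer strata onto them
    targets = ep.dropout_targets
    if len(sizes) != len(targets):
        mapped = []
        for lo, hi in ranges:
            mapped.append(targets[int(tertile_group_of_index(np.array([hi]))[0])])
        targets = tuple(mapped)
    rates_out = []
    for (lo, hi), target in zip(ranges, targets):
        clp = _calibration_clp(config, ep, (lo, hi), 8_000)
        if ep.weibull_shape == 1.0:
            rates = np.exp(clp) / scale

            def g(mu: float) -> float:
                return _p_censored_exponential(mu, rates, ep.admin_cutoff_months) - target

        else:

            def g(mu: float) -> float:
                return (
                    _p_censored_weibull(
                        mu, clp[:4000], scale, ep.weibull_shape, ep.admin_cutoff_months
                    )
                    - target
                )

        if g(0.0) >= 0.0:
            rates_out.append(0.0)
        else:
            rates_out.append(brentq(g, 0.0, 10.0, xtol=1e-10))
    return tuple(rates_out)


# -- simulation -------------------------------------------------------------


def _simulate_endpoint(
    config: CohortConfig,
    ep: EndpointConfig,
    index: np.ndarray,
    cov: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time, event) for one endpoint by inverse-CDF sampling."""
    scale = _calibrate_baseline_scale(config, ep)
    clp = _covariate_lp(cov, config, ep) + ep.methylation_log_hr(index)
    n = len(index)
    e_std = rng.exponential(1.0, size=n)
    t_event = scale * (e_std / np.exp(clp)) ** (1.0 / ep.weibull_shape)
    if not ep.censoring:
        return t_event, np.ones(n, dtype=int)
    dropout_rates = _calibrate_dropout(config, ep, scale)
    sizes, ranges = _group_ranges(config, ep)
    group_rate = np.zeros(n)
    for g, (lo, hi) in enumerate(ranges):
        mask = (index >= lo) & (index <= hi)
        group_rate[mask] = dropout_rates[g]
    with np.errstate(divide="ignore"):
        t_drop = np.where(
            group_rate > 0,
            rng.exponential(1.0, size=n) / np.maximum(group_rate, 1e-300),
            np.inf,
        )
    t_cens = np.minimum(t_drop, ep.admin_cutoff_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a full cohort table (one row per patient).

    Indices are drawn per stratum, covariates per stratum model, and both
    endpoints by inverse-CDF sampling under the configured proportional-
    hazards models.  Identical config and seed give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    sizes, ranges = _group_ranges(config, ep := config.os)
    # the index structure is shared by both endpoints; if either endpoint is
    # quintile-coded, draw on the finer quintile strata
    if config.pfs.effect_mode == "quintile" and config.os.effect_mode != "quintile":
        sizes, ranges = _group_ranges(config, config.pfs)
    index = np.concatenate(
        [
            _draw_index(config, lo_hi, size, rng)
            for lo_hi, size in zip(ranges, sizes)
        ]
    ).astype(int)
    n = len(index)
    tert = tertile_group_of_index(index)
    cov = _draw_group_covariates(config, tert, rng)

    os_time, os_event = _simulate_endpoint(config, config.os, index, cov, rng)
    pfs_time, pfs_event = _simulate_endpoint(config, config.pfs, index, cov, rng)

    width = max(4, len(str(n)))
    table = pd.DataFrame(
        {
            "id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "age": cov["age"],
            "gender": cov["gender"],
            "kps": cov["kps"],
            "resection": cov["resection"],
            "idh1": cov["idh1"],
            "index": index,
            "os_months": np.round(os_time, 4),
            "os_event": os_event,
            "pfs_months": np.round(pfs_time, 4),
            "pfs_event": pfs_event,
        }
    )
    return table


# -- CSV round-trip ---------------------------------------------------------


def export_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort as CSV (schema of :data:`COHORT_COLUMNS`)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table lacks required columns: {missing}")
    table.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def import_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`SchemaError` if a
    required column is missing.  Unknown-resection rows are preserved as the
    explicit ``"unknown"`` level."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort CSV lacks required columns: {missing}")
    for col in ("os_months", "pfs_months"):
        if (table[col] <= 0).any():
            raise SchemaError(f"column {col} must be strictly positive")
    for col in ("os_event", "pfs_event", "idh1"):
        if not set(table[col].unique()) <= {0, 1}:
            raise SchemaError(f"column {col} must be 0/1")
    if ((table["index"] < 0) | (table["index"] > 17)).any():
        raise SchemaError("column index must lie in [0, 17]")
    return table
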