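"""Group-comparison layer: permutation dispersion test, bootstrap contrasts,
and a mixed-model adapter.

The in-repo statistic is a permutation test of dispersion homogeneity: a
one-way F computed on centroid distances, with the null built by permuting
group labels over *individuals* so that all records of one animal move
together (tissues are nested within individuals and are not exchangeable on
their own).  The mixed-model stage is a thin adapter over R's ``nlme::lme``
(REML, optional power-of-the-mean variance function); it is validated, not
reimplemented.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .metrics import (
    DistanceRecord,
    GroupKey,
    IndividualContrast,
    _paired_individuals,
)
from .samples import SampleSet

__all__ = [
    "TestResult",
    "BootstrapResult",
    "ModelSpec",
    "EffectTest",
    "ModelSummary",
    "permutation_dispersion_test",
    "bootstrap_contrast",
    "fit_group_effects",
]

FactorName = Literal["habitat", "age", "group"]

DEFAULT_N_PERMUTATIONS = 9999
DEFAULT_N_BOOT = 1999


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic_name: str
    observed: float
    p_value: float
    n_permutations: int
    seed: int
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class BootstrapResult:
    metric: str
    group1: str
    group2: str
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    n_redrawn: int
    seed: int


def _factor_of(record: DistanceRecord, factor: FactorName | Callable[[DistanceRecord], str]) -> str:
    if callable(factor):
        return factor(record)
    if factor == "habitat":
        return record.group.habitat
    if factor == "age":
        return record.group.age
    if factor == "group":
        return record.group.label()
    raise ValueError(f"unknown factor {factor!r}")


def _anova_f(values: np.ndarray, labels: np.ndarray, k: int) -> float:
    """One-way ANOVA F for integer-coded labels in [0, k)."""
    n = values.size
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    ssb = 0.0
    for g in range(k):
        mask = labels == g
        ng = int(mask.sum())
        if ng:
            ssb += ng * (values[mask].mean() - grand) ** 2
    ssw = sst - ssb
    if ssw <= 0.0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def permutation_dispersion_test(
    records: Sequence[DistanceRecord],
    factor: FactorName | Callable[[DistanceRecord], str] = "group",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> TestResult:
    """Permutation test of dispersion homogeneity across factor levels.

    The observed statistic is the one-way F on the distances.  The null
    distribution is built by randomly reassigning factor levels to
    individuals (keeping every individual's records together) and the
    p-value uses the add-one rule ``(1 + #{F* >= F}) / (1 + n_permutations)``
    so it is never exactly zero.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if not records:
        raise ValueError("no distance records supplied")

    values = np.array([r.distance for r in records], dtype=float)
    rec_labels = [_factor_of(r, factor) for r in records]
    rec_inds = [r.individual_id for r in records]

    # individual -> single factor level (all records of an animal share one)
    ind_level: dict[str, str] = {}
    for ind, lab in zip(rec_inds, rec_labels):
        if ind_level.setdefault(ind, lab) != lab:
            raise ValueError(
                f"individual {ind!r} maps to several factor levels; grouping is degenerate"
            )

    levels = sorted(set(rec_labels))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 factor levels")
    level_code = {lab: i for i, lab in enumerate(levels)}

    label_arr = np.array([level_code[lab] for lab in rec_labels], dtype=np.intp)
    sizes = tuple(int((label_arr == g).sum()) for g in range(k))
    if min(sizes) < 2:
        raise ValueError("every factor level needs >= 2 records")
    if float(values.var()) == 0.0:
        raise ValueError("distances have zero variance; dispersion statistic undefined")

    observed = _anova_f(values, label_arr, k)

    individuals = sorted(ind_level)
    n_ind = len(individuals)
    ind_code = {ind: i for i, ind in enumerate(individuals)}
    rec_ind_idx = np.array([ind_code[i] for i in rec_inds], dtype=np.intp)

    # canonical slot vector: groups ordered by descending individual count
    # (then label), so the null is invariant to renaming the levels
    n_ind_per_level = {lab: 0 for lab in levels}
    for lab in ind_level.values():
        n_ind_per_level[lab] += 1
    slot_order = sorted(levels, key=lambda lab: (-n_ind_per_level[lab], lab))
    slots = np.concatenate(
        [np.full(n_ind_per_level[lab], level_code[lab], dtype=np.intp) for lab in slot_order]
    )

    rng = np.random.default_rng(seed)
    # permute individuals into the fixed slots, all permutations at once
    idx = rng.permuted(np.tile(np.arange(n_ind), (n_permutations, 1)), axis=1)
    perms = np.empty((n_permutations, n_ind), dtype=np.intp)
    perms[np.arange(n_permutations)[:, None], idx] = slots[None, :]
    perm_rec_labels = perms[:, rec_ind_idx]  # (n_perm, n_rec)

    n = values.size
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    ssb = np.zeros(n_permutations)
    for g in range(k):
        mask = perm_rec_labels == g
        ng = mask.sum(axis=1)
        sums = mask @ values
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(ng > 0, sums / np.maximum(ng, 1), grand)
        ssb += ng * (means - grand) ** 2
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore"):
        f_perm = np.where(ssw > 0, (ssb / (k - 1)) / (ssw / (n - k)), np.inf)
        f_perm = np.where((ssw == 0) & (ssb == 0), 0.0, f_perm)

    n_ge = int(np.sum(f_perm >= observed - 1e-12))
    p = (1 + n_ge) / (1 + n_permutations)
    return TestResult(
        statistic_name="dispersion_F",
        observed=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_labels=tuple(levels),
        group_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# bootstrap contrasts
# ---------------------------------------------------------------------------

MetricName = Literal["tnw", "wic", "wic_tnw", "mean_breadth"]

_MAX_REDRAWS = 10_000


def _group_individual_data(s: SampleSet, group: GroupKey, metric: MetricName):
    """Per-individual arrays for resampling.  Returns (kind, data)."""
    if metric == "tnw":
        pts: dict[str, list[tuple[float, float]]] = {}
        for x in s:
            if x.habitat == group.habitat and x.age == group.age and (
                group.tissue is None or x.tissue == group.tissue
            ):
                pts.setdefault(x.individual_id, []).append(x.point)
        return [np.array(v, dtype=float) for v in pts.values()]
    paired = _paired_individuals(s, group)
    if metric in ("wic", "mean_breadth"):
        return [
            float(np.hypot(v["muscle"][0] - v["collagen"][0], v["muscle"][1] - v["collagen"][1]))
            for v in paired.values()
        ]
    if metric == "wic_tnw":
        return [
            np.array([v["muscle"], v["collagen"]], dtype=float) for v in paired.values()
        ]
    raise ValueError(f"unknown metric {metric!r}")


def _metric_from_data(metric: MetricName, data) -> float:
    if metric == "tnw":
        pts = np.concatenate(data, axis=0)
        if len(pts) < 2:
            raise ValueError("need >= 2 samples")
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        return float(d.mean())
    if metric == "wic":
        return float(np.mean(data) / 2.0)
    if metric == "mean_breadth":
        return float(np.mean(data))
    if metric == "wic_tnw":
        pts = np.concatenate(data, axis=0)
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        tnw = float(d.mean())
        breadths = [float(np.linalg.norm(pair[0] - pair[1])) for pair in data]
        wic = float(np.mean(breadths) / 2.0)
        if tnw == 0.0:
            raise ValueError("zero TNW in resample")
        return wic / tnw
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_contrast(
    s: SampleSet,
    metric: MetricName,
    group1: GroupKey,
    group2: GroupKey,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile CI for metric(group1) - metric(group2).

    Individuals are resampled with replacement within each group.  A
    replicate on which the metric is undefined (e.g. zero spread) is redrawn
    and the number of redraws reported.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    data1 = _group_individual_data(s, group1, metric)
    data2 = _group_individual_data(s, group2, metric)
    for g, d in ((group1, data1), (group2, data2)):
        if len(d) < 2:
            raise ValueError(f"group {g.label()!r} has < 2 usable individuals")

    point = _metric_from_data(metric, data1) - _metric_from_data(metric, data2)

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    n_redrawn = 0
    i = 0
    attempts = 0
    while i < n_boot:
        attempts += 1
        if attempts > n_boot + _MAX_REDRAWS:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx1 = rng.integers(0, len(data1), size=len(data1))
        idx2 = rng.integers(0, len(data2), size=len(data2))
        try:
            v1 = _metric_from_data(metric, [data1[j] for j in idx1])
            v2 = _metric_from_data(metric, [data2[j] for j in idx2])
        except ValueError:
            n_redrawn += 1
            continue
        draws[i] = v1 - v2
        i += 1

    alpha = 1.0 - level
    lower, upper = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        metric=metric,
        group1=group1.label(),
        group2=group2.label(),
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mixed-model adapter (nlme::lme via Rscript)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed linear model.

    ``fixed`` is an R-style fixed-effects formula right-hand side, e.g.
    ``"habitat * age * tissue"`` or ``"habitat * age"``.  Random intercepts:
    province always allowed; individual (tissues nested within animal) only
    when the response has several rows per individual.
    """

    response: str
    fixed: str
    random_province: bool = True
    random_individual: bool = False
    variance_power: bool = True
    power_exponent: float | None = None  # None: estimated from the data


@dataclass(frozen=True)
class EffectTest:
    name: str
    df_num: int
    df_den: int
    f_value: float
    p_value: float


@dataclass
class ModelSummary:
    spec: ModelSpec
    converged: bool
    effects: list[EffectTest] = field(default_factory=list)
    variance_components: dict[str, float] = field(default_factory=dict)
    power_exponent: float | None = None
    engine: str = "nlme::lme (REML)"
    diagnostics: str = ""


_R_TEMPLATE = r"""
suppressMessages({library(nlme); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1], stringsAsFactors = TRUE)
spec <- fromJSON(args[2])

fixed <- as.formula(paste(spec$response, "~", spec$fixed))
random <- NULL
if (spec$random_province && spec$random_individual) {
  random <- ~ 1 | province / individual_id
} else if (spec$random_province) {
  random <- ~ 1 | province
} else if (spec$random_individual) {
  random <- ~ 1 | individual_id
}
weights <- NULL
if (spec$variance_power) {
  if (!is.null(spec$power_exponent)) {
    weights <- varPower(fixed = spec$power_exponent)
  } else {
    weights <- varPower()
  }
}
ctrl <- lmeControl(maxIter = 200, msMaxIter = 200, niterEM = 50, returnObject = FALSE)

fit <- tryCatch(
  if (is.null(random)) {
    # no random structure requested: generalized least squares, same variance model
    gls(model = fixed, data = d, weights = weights, method = "REML")
  } else {
    lme(fixed = fixed, data = d, random = random, weights = weights,
        method = "REML", control = ctrl)
  },
  error = function(e) e
)
out_path <- args[3]
if (inherits(fit, "error")) {
  write_json(list(converged = FALSE, error = conditionMessage(fit)),
             out_path, auto_unbox = TRUE)
  quit(status = 0)
}
a <- anova(fit)
terms <- rownames(a)
keep <- terms != "(Intercept)"
den <- a$denDF
if (is.null(den)) {  # anova.gls reports no denominator df; use residual df
  den <- rep(fit$dims$N - fit$dims$p, length(terms))
}
eff <- data.frame(
  name = terms[keep],
  df_num = a$numDF[keep],
  df_den = den[keep],
  f_value = a[["F-value"]][keep],
  p_value = a[["p-value"]][keep]
)
vc <- tryCatch({
  m <- VarCorr(fit)
  sd_col <- suppressWarnings(as.numeric(m[, "StdDev"]))
  names(sd_col) <- rownames(m)
  as.list(sd_col[is.finite(sd_col)])
}, error = function(e) list())
vc$residual_sd <- fit$sigma
pw <- NULL
if (spec$variance_power) {
  pw <- tryCatch(unname(coef(fit$modelStruct$varStruct, unconstrained = FALSE)),
                 error = function(e) spec$power_exponent)
  if (length(pw) == 0) pw <- spec$power_exponent
}
write_json(list(converged = TRUE, effects = eff, variance_components = vc,
                power_exponent = pw),
           out_path, auto_unbox = TRUE, digits = 12)
"""


def _rows_per_individual(data) -> bool:
    counts: dict[str, int] = {}
    for v in data["individual_id"]:
        counts[v] = counts.get(v, 0) + 1
    return any(c > 1 for c in counts.values())


def fit_group_effects(spec: ModelSpec, data) -> ModelSummary:
    """Fit one mixed linear model and return per-effect F tests.

    ``data`` is a pandas DataFrame holding the response column and every
    factor named in the spec.  The engine is R's ``nlme::lme`` invoked in a
    subprocess; F statistics, numerator/denominator dfs and p-values come
    from its sequential ``anova`` table, and the denominator-df accounting
    is whatever that machinery provides.  Non-convergence yields a summary
    with ``converged=False`` and diagnostics — no silent fallback.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing from data")
    if spec.random_province and "province" not in data.columns:
        raise ValueError("column 'province' missing from data")
    if spec.random_individual and "individual_id" not in data.columns:
        raise ValueError("column 'individual_id' missing from data")
    if spec.random_individual and not _rows_per_individual(data):
        raise ValueError(
            "random individual term requires replicate rows per individual"
        )
    if data[spec.response].nunique() <= 1:
        return ModelSummary(
            spec=spec,
            converged=False,
            diagnostics="response is constant; model is degenerate",
        )
    rscript = shutil.which("Rscript")
    if rscript is None:
        raise RuntimeError("Rscript not found on PATH; the mixed-model adapter needs R + nlme")

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.csv"
        out_path = tmp / "result.json"
        script_path = tmp / "fit.R"
        data.to_csv(data_path, index=False)
        script_path.write_text(_R_TEMPLATE)
        spec_json = json.dumps(
            {
                "response": spec.response,
                "fixed": spec.fixed,
                "random_province": spec.random_province,
                "random_individual": spec.random_individual,
                "variance_power": spec.variance_power,
                "power_exponent": spec.power_exponent,
            }
        )
        proc = subprocess.run(
            [rscript, "--vanilla", str(script_path), str(data_path), spec_json, str(out_path)],
            capture_output=True,
            text=True,
            timeout=600,
        )
        if proc.returncode != 0 or not out_path.exists():
            return ModelSummary(
                spec=spec,
                converged=False,
                diagnostics=f"Rscript failed (exit {proc.returncode}): {proc.stderr.strip()}",
            )
        payload = json.loads(out_path.read_text())

    if not payload.get("converged", False):
        return ModelSummary(
            spec=spec, converged=False, diagnostics=str(payload.get("error", "non-convergence"))
        )

    effects_raw = payload.get("effects", [])
    if isinstance(effects_raw, dict):  # jsonlite column-major corner case
        effects_raw = [
            {k: effects_raw[k][i] for k in effects_raw}
            for i in range(len(effects_raw["name"]))
        ]
    effects = [
        EffectTest(
            name=str(e["name"]),
            df_num=int(e["df_num"]),
            df_den=int(e["df_den"]),
            f_value=float(e["f_value"]),
            p_value=float(e["p_value"]),
        )
        for e in effects_raw
    ]
    vc = {
        str(k): float(v)
        for k, v in (payload.get("variance_components") or {}).items()
        if isinstance(v, (int, float))
    }
    pw = payload.get("power_exponent")
    if isinstance(pw, list):
        pw = pw[0] if pw else None
    if not isinstance(pw, (int, float)):
        pw = None  # jsonlite serializes R NULL as {}
    return ModelSummary(
        spec=spec,
        converged=True,
        effects=effects,
        variance_components=vc,
        power_exponent=float(pw) if pw is not None else None,
    )


def contrasts_to_records(contrasts: Sequence[IndividualContrast]) -> list[DistanceRecord]:
    """Convenience: dispersion records from contrasts (re-export path)."""
    from .metrics import difference_dispersion

    return difference_dispersion(list(contrasts))
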