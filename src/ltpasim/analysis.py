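"""Replication-consistency and sensitivity analyses.

* Consistency: how many replications are needed before stochastic
  (aleatory) variation stops mattering.  Twenty independent sets of m
  replications are generated per candidate m; the Vargha-Delaney A test
  compares the first set against each of the other nineteen, per output
  per yearly time point.  Folded scores (0.5 + |A - 0.5|) near 0.5 mean
  the sets are interchangeable.
* Robustness (one-at-a-time): each parameter is disturbed individually
  and the disturbed output distributions are A-tested against baseline.
* Global sensitivity: Latin Hypercube Sampling over the selected
  parameter domains, one simulated scenario per sample, and partial
  rank correlation coefficients (PRCC) between each parameter and each
  output, controlling for the other parameters.

Effect-size conventions for the A test: ~0.56 small, ~0.64 medium,
>=0.71 large; for PRCC: ~0.2 small, ~0.5 average, ~0.8 high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import OUTPUT_COLUMNS, run_replications, sample_yearly
from .world import ModelParams, ROBUSTNESS_PARAMS, default_sa_domains, resolve_param_name, PARAM_FIELDS

__all__ = [
    "A_SMALL",
    "A_MEDIUM",
    "A_LARGE",
    "vargha_delaney_a",
    "fold_a",
    "ConsistencyResult",
    "consistency_analysis",
    "robustness_analysis",
    "latin_hypercube",
    "prcc",
    "GlobalSAResult",
    "global_sensitivity",
]

#: folded A-score effect-size thresholds
A_SMALL = 0.56
A_MEDIUM = 0.64
A_LARGE = 0.71


def vargha_delaney_a(x, y) -> float:
    """Vargha-Delaney A: probability of superiority of x over y.

    ``A = (#{x_i > y_j} + 0.5 #{x_i = y_j}) / (|x| |y|)``, computed via
    the rank-sum identity.  0.5 means stochastically equal samples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    n, m = x.size, y.size
    return float((r1 - n * (n + 1) / 2.0) / (n * m))


def fold_a(a) -> np.ndarray | float:
    """Direction-free deviation magnitude ``0.5 + |A - 0.5|`` in [0.5, 1]."""
    a = np.asarray(a, dtype=float)
    out = 0.5 + np.abs(a - 0.5)
    return float(out) if out.ndim == 0 else out


def _yearly_output_cube(
    params: ModelParams, n_reps: int, base_seed
) -> tuple[np.ndarray, np.ndarray]:
    """Run replications; return (cube[m, year, output], year_weeks)."""
    n_points = params.horizon_weeks // 52
    if n_points < 1:
        raise ValueError("horizon shorter than one year")
    df = run_replications(params, n_reps, base_seed)
    yearly = sample_yearly(df, 52, n_points)
    weeks = 52 * np.arange(1, n_points + 1)
    cube = (
        yearly.sort_values(["replicate", "week"])[OUTPUT_COLUMNS]
        .to_numpy()
        .reshape(n_reps, n_points, len(OUTPUT_COLUMNS))
    )
    return cube, weeks


@dataclass
class ConsistencyResult:
    """Summary table, raw A scores, and the replication recommendation.

    ``table`` has one row per (m, output, year) with the folded median
    and maximum of the 19 first-vs-other set comparisons; ``scores``
    keeps each raw comparison; ``recommendation`` is the smallest m
    whose worst folded score stays below the small-effect threshold
    (None if no tested m qualifies).
    """

    table: pd.DataFrame
    scores: pd.DataFrame
    recommendation: int | None
    threshold: float = A_SMALL


def consistency_analysis(
    params: ModelParams,
    m_list: list[int],
    n_sets: int = 20,
    base_seed: int = 0,
) -> ConsistencyResult:
    """A-test consistency protocol over replicate-set sizes.

    For each m in ``m_list``, ``n_sets`` independent sets of m
    replications are generated; per output per yearly point, the first
    set's distribution is A-tested against each of the remaining sets.
    """
    if any(m < 1 for m in m_list):
        raise ValueError("replication counts must be >= 1")
    if n_sets < 2:
        raise ValueError("need at least two sets to compare")
    master = np.random.SeedSequence(base_seed)
    table_rows, score_rows = [], []
    for m, m_seed in zip(m_list, master.spawn(len(m_list))):
        cubes = [
            _yearly_output_cube(params, m, s)[0] for s in m_seed.spawn(n_sets)
        ]
        weeks = 52 * np.arange(1, cubes[0].shape[1] + 1)
        for oi, out in enumerate(OUTPUT_COLUMNS):
            for yi, week in enumerate(weeks):
                ref = cubes[0][:, yi, oi]
                folded = []
                for s in range(1, n_sets):
                    a = vargha_delaney_a(ref, cubes[s][:, yi, oi])
                    folded.append(fold_a(a))
                    score_rows.append(
                        {"m": m, "output": out, "week": int(week), "set": s,
                         "A": a, "folded_A": fold_a(a)}
                    )
                table_rows.append(
                    {"m": m, "output": out, "week": int(week),
                     "median_A": float(np.median(folded)),
                     "max_A": float(np.max(folded))}
                )
    table = pd.DataFrame(table_rows)
    scores = pd.DataFrame(score_rows)
    worst = table.groupby("m")["max_A"].max()
    ok = worst[worst < A_SMALL]
    recommendation = int(ok.index.min()) if len(ok) else None
    return ConsistencyResult(table=table, scores=scores, recommendation=recommendation)


def robustness_analysis(
    baseline_params: ModelParams,
    param_name: str,
    values,
    n_reps: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One-at-a-time robustness sweep of a single parameter.

    Every value is run with all other parameters at baseline and the
    output distributions (per output, per yearly point) are A-tested
    against the baseline distributions.  Folded scores >= 0.71 flag
    significant sensitivity.
    """
    fname = resolve_param_name(param_name)
    if fname not in ROBUSTNESS_PARAMS:
        raise ValueError(f"{param_name!r} is not a swept parameter")
    _, (lo, hi), is_int = ROBUSTNESS_PARAMS[fname]
    values = list(values)
    for v in values:
        if not (lo <= v <= hi):
            raise ValueError(f"value {v!r} outside documented domain [{lo}, {hi}]")
    master = np.random.SeedSequence(base_seed)
    seeds = master.spawn(len(values) + 1)
    base_cube, weeks = _yearly_output_cube(baseline_params, n_reps, seeds[0])
    rows = []
    for vi, v in enumerate(values):
        v_cast = int(round(v)) if is_int else float(v)
        cand = baseline_params.replace(**{fname: v_cast})
        cube, _ = _yearly_output_cube(cand, n_reps, seeds[vi + 1])
        for oi, out in enumerate(OUTPUT_COLUMNS):
            for yi, week in enumerate(weeks):
                a = vargha_delaney_a(cube[:, yi, oi], base_cube[:, yi, oi])
                fa = fold_a(a)
                rows.append(
                    {"parameter": fname, "value": v_cast, "output": out,
                     "week": int(week), "A": a, "folded_A": fa,
                     "significant": fa >= A_LARGE}
                )
    return pd.DataFrame(rows)


def latin_hypercube(
    domains, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Latin Hypercube Sample: n points, one per equal-width stratum.

    ``domains`` is a sequence of (lo, hi) pairs (or a dict of them, in
    insertion order).  Per parameter, the n samples occupy the n strata
    exactly once: one uniform draw inside each stratum, strata randomly
    permuted.
    """
    if isinstance(domains, dict):
        domains = list(domains.values())
    if n < 1:
        raise ValueError("n must be >= 1")
    d = len(domains)
    out = np.empty((n, d))
    for j, (lo, hi) in enumerate(domains):
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
            raise ValueError(f"degenerate domain for parameter {j}: [{lo}, {hi}]")
        strata = (rng.permutation(n) + rng.random(n)) / n
        out[:, j] = lo + (hi - lo) * strata
    return out


def prcc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation coefficient of each column of X with y.

    Columns of X and y are rank-transformed (average ties); for each
    parameter j, rank(x_j) and rank(y) are each regressed (with
    intercept) on all the other rank-transformed columns, and the
    Pearson correlation of the two residual vectors is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if n <= d + 2:
        raise ValueError("need n > d + 2 observations")
    for j in range(d):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"column {j} of X is constant")
    R = np.column_stack([stats.rankdata(X[:, j]) for j in range(d)])
    ry = stats.rankdata(y)
    ones = np.ones((n, 1))
    out = np.empty(d)
    for j in range(d):
        others = np.delete(np.arange(d), j)
        design = np.hstack([ones, R[:, others]])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular design when partialling out for column {j}")
        coef_x, *_ = np.linalg.lstsq(design, R[:, j], rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        res_x = R[:, j] - design @ coef_x
        res_y = ry - design @ coef_y
        denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
        if denom == 0.0:
            raise ValueError(f"degenerate residuals for column {j}")
        out[j] = float((res_x * res_y).sum() / denom)
    return out


def _effect_size_label(value: float) -> str:
    """Qualitative PRCC magnitude: small ~0.2, average ~0.5, high ~0.8."""
    mag = abs(value)
    if mag < 0.35:
        return "small"
    if mag < 0.65:
        return "average"
    return "high"


@dataclass
class GlobalSAResult:
    """PRCC per (parameter, output, year) plus the min/max/mean/sd summary."""

    scenarios: pd.DataFrame  # sampled parameter values, one row per scenario
    prcc_by_year: pd.DataFrame  # parameter, output, week, prcc
    summary: pd.DataFrame  # parameter, output, min, max, mean, sd, effect_size
    outputs: list[str] = field(default_factory=lambda: list(OUTPUT_COLUMNS))


def global_sensitivity(
    baseline_params: ModelParams,
    domains: dict[str, tuple[float, float]] | None = None,
    n_scenarios: int = 100,
    n_reps: int = 5,
    base_seed: int = 0,
) -> GlobalSAResult:
    """LHS + PRCC global sensitivity analysis.

    Defaults to the six most influential parameters (alpha.behavior,
    perception.radius, alpha.network, alpha.comm, prop.ltpa.sites,
    mean.ql) over their documented domains.  Each LHS scenario is run
    ``n_reps`` times; the replicate-mean output at each yearly point is
    the scenario-level observation entering the PRCC.  Coefficients are
    summarized by min/max/mean/sd over the yearly points.
    """
    if domains is None:
        domains = default_sa_domains(baseline_params)
    else:
        domains = {resolve_param_name(k): tuple(v) for k, v in domains.items()}
    for name, (lo, hi) in domains.items():
        if lo >= hi:
            raise ValueError(f"zero-width domain for {name!r}: [{lo}, {hi}]")

    master = np.random.SeedSequence(base_seed)
    lhs_seed, run_seed = master.spawn(2)
    X = latin_hypercube(list(domains.values()), n_scenarios,
                        np.random.default_rng(lhs_seed))
    names = list(domains)
    int_fields = {"k_network", "n_activity_types", "grid_side", "n_persons"}

    n_points = baseline_params.horizon_weeks // 52
    Y = np.empty((n_scenarios, n_points, len(OUTPUT_COLUMNS)))
    run_seeds = run_seed.spawn(n_scenarios)
    for s in range(n_scenarios):
        changes = {
            name: (int(round(X[s, j])) if name in int_fields else float(X[s, j]))
            for j, name in enumerate(names)
        }
        cand = baseline_params.replace(**changes)
        cube, weeks = _yearly_output_cube(cand, n_reps, run_seeds[s])
        Y[s] = cube.mean(axis=0)

    weeks = 52 * np.arange(1, n_points + 1)
    prcc_rows = []
    for oi, out in enumerate(OUTPUT_COLUMNS):
        for yi, week in enumerate(weeks):
            coeffs = prcc(X, Y[:, yi, oi])
            for j, name in enumerate(names):
                prcc_rows.append(
                    {"parameter": PARAM_FIELDS.get(name, name), "output": out,
                     "week": int(week), "prcc": coeffs[j]}
                )
    prcc_by_year = pd.DataFrame(prcc_rows)
    summary = (
        prcc_by_year.groupby(["parameter", "output"], sort=False)["prcc"]
        .agg(["min", "max", "mean", "std"])
        .rename(columns={"std": "sd"})
        .reset_index()
    )
    summary["effect_size"] = summary["mean"].map(_effect_size_label)
    scenarios = pd.DataFrame(X, columns=[PARAM_FIELDS.get(n, n) for n in names])
    scenarios.insert(0, "scenario", np.arange(n_scenarios))
    return GlobalSAResult(
        scenarios=scenarios, prcc_by_year=prcc_by_year, summary=summary
    )
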