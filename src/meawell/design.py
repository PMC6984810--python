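"""Experimental-design computations for multi-well MEA studies.

Covers four design-stage questions:

* how to split a plate of arrays with heterogeneous spontaneous firing
  into treatment groups with comparable baseline activity (minimum-F
  bootstrap assignment over random candidate partitions);
* how correlated a follow-up recording of the same arrays will be with
  baseline, and how to construct simulated follow-ups with an exact
  target correlation (residual orthogonalization,
  B = rho*A + A_perp*sqrt(1 - rho^2));
* the statistical power of a pre/post, control/treatment design
  analysed by ANCOVA with Tukey honest-significant-difference
  comparisons over the four group x time cells;
* how the between-day correlation of array firing rates grows with
  recording duration (rho fitted against ln minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import studentized_range

from .interchange import SpikeTable

__all__ = [
    "AssignmentPlan",
    "PowerGrid",
    "CorrelationCurve",
    "one_way_f",
    "assign_groups",
    "correlated_followup",
    "ancova_treatment_test",
    "power_grid",
    "duration_correlation_curve",
]


@dataclass
class AssignmentPlan:
    """A well -> group assignment selected by the minimum-F bootstrap."""

    groups: dict[str, str]  # well -> group label
    group_sizes: list[int]
    f_statistic: float
    iterations: int
    seed: int

    @property
    def n_assigned(self) -> int:
        return len(self.groups)


@dataclass
class PowerGrid:
    """Monte-Carlo power over a sample-size x effect-size grid."""

    sample_sizes: list[int]
    effect_sizes: list[float]
    iterations_per_cell: int
    alpha: float
    power: np.ndarray  # |sample_sizes| x |effect_sizes|
    rho: float
    seed: int

    @property
    def n_simulated_treatments(self) -> int:
        return len(self.sample_sizes) * len(self.effect_sizes) * self.iterations_per_cell


@dataclass
class CorrelationCurve:
    """Between-day firing-rate correlation as a function of duration."""

    minutes: list[float]
    rho_values: list[float]
    log_fit: tuple[float, float] = field(default=(np.nan, np.nan))  # (slope, intercept)


# ---------------------------------------------------------------------------
# minimum-F group assignment

def one_way_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic of ``values`` grouped by ``labels``.

    Returns 0 when both between- and within-group sums of squares are
    zero (all observations identical).
    """
    values = np.asarray(values, dtype=float)
    groups = [values[labels == g] for g in np.unique(labels)]
    n = len(values)
    k = len(groups)
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw <= 0:
        return 0.0 if ssb <= 0 else np.inf
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def _batched_f(vals: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Vectorized one-way F for many candidate assignments.

    ``vals`` has shape (iterations, sum(sizes)); columns are sliced into
    consecutive groups of the given sizes.
    """
    n = vals.shape[1]
    k = len(sizes)
    grand = vals.mean(axis=1, keepdims=True)
    ssb = np.zeros(vals.shape[0])
    ssw = np.zeros(vals.shape[0])
    start = 0
    for sz in sizes:
        g = vals[:, start : start + sz]
        gm = g.mean(axis=1, keepdims=True)
        ssb += sz * (gm[:, 0] - grand[:, 0]) ** 2
        ssw += ((g - gm) ** 2).sum(axis=1)
        start += sz
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, 0.0))
    return f


def assign_groups(
    pool: list[tuple[str, float]],
    n_groups: int,
    sizes: list[int] | None = None,
    iterations: int = 10_000,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> AssignmentPlan:
    """Assign wells to treatment groups minimizing baseline imbalance.

    Generates ``iterations`` uniformly random candidate assignments
    (wells sampled without replacement), scores each by the one-way
    ANOVA F of log10 MFR on group, and returns the candidate with the
    lowest F.  Unequal group sizes are supported; ties keep the first
    candidate encountered.  Deterministic for a fixed seed.
    """
    if sizes is None:
        if len(pool) % n_groups:
            raise ValueError("sizes required when pool does not divide evenly")
        sizes = [len(pool) // n_groups] * n_groups
    if len(sizes) != n_groups:
        raise ValueError("len(sizes) must equal n_groups")
    n_assigned = int(sum(sizes))
    if n_assigned > len(pool):
        raise ValueError(f"sum(sizes)={n_assigned} exceeds pool size {len(pool)}")
    if group_labels is None:
        group_labels = [f"g{i + 1}" for i in range(n_groups)]

    wells = np.array([w for w, _ in pool])
    vals = np.array([v for _, v in pool], dtype=float)
    rng = np.random.default_rng(seed)

    best_f = np.inf
    best_idx = None
    batch = 2000  # keep the permutation matrix small
    done = 0
    while done < iterations:
        b = min(batch, iterations - done)
        perms = rng.permuted(np.tile(np.arange(len(pool)), (b, 1)), axis=1)[:, :n_assigned]
        f = _batched_f(vals[perms], sizes)
        j = int(np.argmin(f))
        if f[j] < best_f:
            best_f = float(f[j])
            best_idx = perms[j].copy()
        done += b

    groups: dict[str, str] = {}
    start = 0
    for lab, sz in zip(group_labels, sizes):
        for i in best_idx[start : start + sz]:
            groups[str(wells[i])] = lab
        start += sz
    return AssignmentPlan(
        groups=groups,
        group_sizes=list(sizes),
        f_statistic=best_f,
        iterations=iterations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# correlated follow-up construction

def correlated_followup(baseline: np.ndarray, rho: float, seed: int = 0) -> np.ndarray:
    """Simulate a follow-up measurement with exact sample correlation rho.

    Draws a standard-normal vector, regresses it on the baseline A, and
    keeps the residuals A_perp (orthogonal to A in sample), rescaled to
    the SD of A.  The returned vector is

        B = rho * A + A_perp * sqrt(1 - rho^2)

    whose *sample* Pearson correlation with A equals rho exactly (to
    numerical precision), not merely in expectation.
    """
    a = np.asarray(baseline, dtype=float)
    if a.size < 3:
        raise ValueError("baseline must have at least 3 values")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    sd_a = a.std(ddof=1)
    if sd_a == 0:
        raise ValueError("constant baseline: correlation undefined")
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(a.size), a])
    for _ in range(8):  # redraw if the auxiliary sample is collinear with A
        z = rng.standard_normal(a.size)
        coef, *_ = np.linalg.lstsq(x, z, rcond=None)
        resid = z - x @ coef
        if resid.std(ddof=1) > 1e-8 * z.std(ddof=1):
            break
    else:
        raise RuntimeError("could not draw a sample independent of the baseline")
    a_perp = resid * (sd_a / resid.std(ddof=1))
    return rho * a + a_perp * np.sqrt(1.0 - rho**2)


# ---------------------------------------------------------------------------
# ANCOVA with Tukey HSD over group x time cells

def _tukey_cells(cells: list[np.ndarray]) -> tuple[np.ndarray, float, int]:
    """Cell means, pooled error variance, and error df of a cell-means model."""
    means = np.array([c.mean() for c in cells])
    n_total = sum(len(c) for c in cells)
    df = n_total - len(cells)
    sse = sum(((c - c.mean()) ** 2).sum() for c in cells)
    mse = sse / df if df > 0 else np.nan
    return means, mse, df


def ancova_treatment_test(
    control: list[tuple[float, float]],
    treatment: list[tuple[float, float]],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Control-vs-treatment comparison at the post time point.

    Fits the two-factor (group x time) linear model with interaction on
    the long-format data — equivalent, for this saturated design, to
    the four cell means with a pooled error variance — and applies
    Tukey's honest-significant-difference correction over the four
    cells.  Returns ``(adjusted_p, estimate)`` for the
    treatment-minus-control difference at the post time.
    """
    if len(control) < 2 or len(treatment) < 2:
        raise ValueError("need at least 2 (pre, post) pairs per group")
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    cells = [c[:, 0], c[:, 1], t[:, 0], t[:, 1]]  # (ctrl,pre) (ctrl,post) (trt,pre) (trt,post)
    means, mse, df = _tukey_cells(cells)
    estimate = float(means[3] - means[1])
    n_c, n_t = len(c), len(t)
    se = np.sqrt(mse / 2.0 * (1.0 / n_c + 1.0 / n_t))
    if se == 0:
        return (1.0 if estimate == 0 else 0.0), estimate
    q = abs(estimate) / se
    p = float(studentized_range.sf(q, 4, df))
    return p, estimate


def power_grid(
    baseline_pop: np.ndarray,
    rho: float = 0.8,
    sample_sizes: list[int] | None = None,
    effect_sizes: list[float] | None = None,
    iterations: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerGrid:
    """Monte-Carlo power of the pre/post ANCOVA design.

    For each (n, effect) cell: draw n control and n treatment arrays'
    paired (t0, t1) log10 Hz values from the baseline population and
    its correlated follow-up, subtract ``effect`` from the treatment
    t1 values, and test control vs treatment at t1 with Tukey HSD over
    the four group x time cells.  Power is the fraction of iterations
    with adjusted p < alpha.

    The default grid (n = 3..16, effects 0.1..2.0 in steps of 0.1,
    5000 iterations per cell) enumerates 1.4e6 simulated treatments.
    """
    if sample_sizes is None:
        sample_sizes = list(range(3, 17))
    if effect_sizes is None:
        effect_sizes = [round(0.1 * k, 1) for k in range(1, 21)]
    if not sample_sizes or not effect_sizes:
        raise ValueError("sample_sizes and effect_sizes must be non-empty")
    if min(sample_sizes) < 3:
        raise ValueError("sample sizes below 3 are not supported")
    pop_t0 = np.asarray(baseline_pop, dtype=float)
    pop_t1 = correlated_followup(pop_t0, rho, seed=seed)
    n_pop = pop_t0.size
    rng = np.random.default_rng(seed + 1)

    power = np.zeros((len(sample_sizes), len(effect_sizes)))
    for i, n in enumerate(sample_sizes):
        df = 4 * n - 4
        q_crit = studentized_range.isf(alpha, 4, df)
        # one index draw per iteration, reused across effect sizes so
        # effect monotonicity is not masked by sampling noise
        idx = np.argsort(rng.random((iterations, n_pop)), axis=1)[:, : 2 * n]
        ctrl, trt = idx[:, :n], idx[:, n:]
        c0, c1 = pop_t0[ctrl], pop_t1[ctrl]
        t0 = pop_t0[trt]
        t1_base = pop_t1[trt]
        # within-cell SS for the three cells that do not depend on effect
        sse_fixed = (
            ((c0 - c0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((c1 - c1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((t0 - t0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        )
        sse_t1 = ((t1_base - t1_base.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        m_c1 = c1.mean(axis=1)
        m_t1 = t1_base.mean(axis=1)
        for j, eff in enumerate(effect_sizes):
            mse = (sse_fixed + sse_t1) / df  # shifting a cell leaves its SS unchanged
            se = np.sqrt(mse / n)
            diff = np.abs((m_t1 - eff) - m_c1)
            with np.errstate(divide="ignore", invalid="ignore"):
                q = diff / se
            power[i, j] = float(np.mean(q > q_crit))
    return PowerGrid(
        sample_sizes=list(sample_sizes),
        effect_sizes=list(effect_sizes),
        iterations_per_cell=iterations,
        alpha=alpha,
        power=power,
        rho=rho,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# duration-correlation curve

def duration_correlation_curve(
    day1: SpikeTable,
    day2: SpikeTable,
    step_minutes: float = 5.0,
) -> CorrelationCurve:
    """Between-day correlation of array log firing rate vs duration.

    For each accumulating interval [0, k*step] the per-well log10 MFR is
    computed in both recordings and the across-well Pearson correlation
    taken; an OLS fit of rho on ln(minutes) summarizes the growth of
    reliability with recording length.
    """
    wells = sorted(set(day1.layout.well_labels) & set(day2.layout.well_labels))
    if len(wells) < 2:
        raise ValueError("need at least 2 common wells")
    d1 = min(r.duration for r in day1.recordings)
    d2 = min(r.duration for r in day2.recordings)
    max_minutes = min(d1, d2) / 60.0
    n_steps = int(np.floor(max_minutes / step_minutes))
    if n_steps < 2:
        raise ValueError("recordings must span at least 2 accumulation steps")

    def _times(table: SpikeTable) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {w: [] for w in wells}
        for e in table.events:
            if e.well in out:
                out[e.well].append(e.timestamp)
        return {w: np.sort(np.array(v)) for w, v in out.items()}

    t1, t2 = _times(day1), _times(day2)
    minutes, rhos = [], []
    for k in range(1, n_steps + 1):
        horizon = k * step_minutes * 60.0
        v1 = np.array([np.log10((np.searchsorted(t1[w], horizon) + 1) / horizon) for w in wells])
        v2 = np.array([np.log10((np.searchsorted(t2[w], horizon) + 1) / horizon) for w in wells])
        if v1.std() == 0 or v2.std() == 0:
            rho = np.nan
        else:
            rho = float(np.corrcoef(v1, v2)[0, 1])
        minutes.append(k * step_minutes)
        rhos.append(rho)
    ok = np.isfinite(rhos)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(np.log(np.array(minutes)[ok]), np.array(rhos)[ok], 1)
    else:
        slope = intercept = np.nan
    return CorrelationCurve(minutes=minutes, rho_values=rhos, log_fit=(float(slope), float(intercept)))
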