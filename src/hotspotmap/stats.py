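"""Statistics for grid maps: bootstrap map correlation, Student's t-tests
and the paired half-map test.

Map correlation resamples whole branch maps (at the animal level when animal
ids are given), recomputes the cohort-average maps, and summarises Pearson's
r over jointly valid squares by its bootstrap median and percentile 95% CI;
a correlation is significant when the CI excludes zero. Resampling whole
maps, never individual squares, respects the spatial autocorrelation within
a map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .mapping import GRID_N, GridMap


@dataclass
class CorrelationResult:
    metric_pair: tuple[str, str]
    median_r: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    significant: bool
    n_squares: int = 0
    r_observed: float = float("nan")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    tails: str  # "one" | "two"
    df: float
    design: str  # "two_sample" | "paired"


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined (error) for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_r is undefined when either input has zero variance")
    return float(sps.pearsonr(x, y).statistic)


def _stack_maps(maps: list[GridMap]) -> tuple[np.ndarray, np.ndarray]:
    """(n, 100) value matrix with NaN for undefined squares, plus the cohort
    union-ostium column mask."""
    vals = np.stack([np.asarray(m.values, dtype=float).ravel() for m in maps])
    union = np.any(np.stack([np.asarray(m.ostium, dtype=bool).ravel() for m in maps]), axis=0)
    return vals, union


def _as_matrix(maps) -> tuple[np.ndarray, np.ndarray, str]:
    if len(maps) and isinstance(maps[0], GridMap):
        vals, union = _stack_maps(list(maps))
        return vals, union, maps[0].metric
    vals = np.asarray(maps, dtype=float).reshape(len(maps), -1)
    if vals.shape[1] != GRID_N**2:
        raise ValueError("expected 10x10 maps")
    return vals, np.zeros(vals.shape[1], dtype=bool), "map"


def _resampler(rng, n, animal_ids):
    """Returns a function drawing one bootstrap index vector (branch level,
    or animal level preserving the hierarchy when ids are given)."""
    if animal_ids is None:
        return lambda: rng.integers(0, n, n)
    ids = np.asarray(animal_ids)
    if ids.shape[0] != n:
        raise ValueError("animal_ids length must match the number of branch maps")
    groups = [np.flatnonzero(ids == a) for a in np.unique(ids)]
    k = len(groups)

    def draw():
        chosen = rng.integers(0, k, k)
        return np.concatenate([groups[c] for c in chosen])

    return draw


def map_correlation(
    branch_maps_a,
    branch_maps_b,
    n_boot: int = 10_000,
    seed: int | None = None,
    animal_ids_a=None,
    animal_ids_b=None,
    share_resampling: bool | None = None,
    dataset_seeds: tuple[int, int] | None = None,
) -> CorrelationResult:
    """Bootstrap median Pearson r between two cohorts of branch grid maps.

    ``share_resampling`` draws the same branch indices for both datasets and
    should be used when the two metrics come from the same branches (paired
    cohorts); by default it is inferred from object identity. Passing
    ``dataset_seeds`` gives each dataset its own resampling stream, making
    the statistic exactly symmetric when arguments and seeds are swapped
    together.
    """
    A, union_a, metric_a = _as_matrix(branch_maps_a)
    B, union_b, metric_b = _as_matrix(branch_maps_b)
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 branch maps in each dataset")
    if share_resampling is None:
        share_resampling = branch_maps_a is branch_maps_b or (
            na == nb and np.array_equal(A, B, equal_nan=True)
        )
    if share_resampling and na != nb:
        raise ValueError("shared resampling requires equally sized datasets")

    keep = ~(union_a | union_b)
    with np.errstate(invalid="ignore"):
        mean_a = _nanmean0(A)[keep]
        mean_b = _nanmean0(B)[keep]
    finite = np.isfinite(mean_a) & np.isfinite(mean_b)
    if finite.sum() < 3:
        raise ValueError("fewer than 3 jointly valid grid squares")
    r_obs = _safe_r(mean_a[finite], mean_b[finite])

    if dataset_seeds is not None:
        rng_a = np.random.default_rng(dataset_seeds[0])
        rng_b = np.random.default_rng(dataset_seeds[1])
    else:
        root = np.random.default_rng(seed)
        rng_a = np.random.default_rng(root.integers(2**31))
        rng_b = np.random.default_rng(root.integers(2**31))
    draw_a = _resampler(rng_a, na, animal_ids_a)
    draw_b = _resampler(rng_b, nb, animal_ids_b)

    r_boot = np.full(n_boot, np.nan)
    keep_idx = np.flatnonzero(keep)
    Ak = A[:, keep_idx]
    Bk = B[:, keep_idx]
    for t in range(n_boot):
        ia = draw_a()
        ib = ia if share_resampling else draw_b()
        with np.errstate(invalid="ignore"):
            ma = _nanmean0(Ak[ia])
            mb = _nanmean0(Bk[ib])
        ok = np.isfinite(ma) & np.isfinite(mb)
        if ok.sum() >= 3:
            r_boot[t] = _safe_r(ma[ok], mb[ok])

    good = r_boot[np.isfinite(r_boot)]
    if good.size == 0:
        raise ValueError("no bootstrap replicate yielded a defined correlation")
    median_r = float(np.median(good))
    ci_low = float(np.percentile(good, 2.5))
    ci_high = float(np.percentile(good, 97.5))
    return CorrelationResult(
        metric_pair=(metric_a, metric_b),
        median_r=median_r,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        significant=not (ci_low <= 0.0 <= ci_high),
        n_squares=int(finite.sum()),
        r_observed=r_obs,
    )


def _nanmean0(m: np.ndarray) -> np.ndarray:
    cnt = np.isfinite(m).sum(axis=0)
    s = np.nansum(np.where(np.isfinite(m), m, 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / cnt
    out[cnt == 0] = np.nan
    return out


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.array_equal(x, y):
        return 1.0  # self-correlation, exactly (also covers constant maps)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    c = np.corrcoef(x, y)[0, 1]
    return float(np.clip(c, -1.0, 1.0))


def two_sample_t(a, b, tails: str = "two", welch: bool = False) -> TestResult:
    """Student's pooled-variance t-test (Welch by flag).

    One-tailed p is for the alternative mean(a) < mean(b) when t < 0 and
    mean(a) > mean(b) when t > 0 is NOT assumed; ``tails="one"`` halves the
    two-tailed p, i.e. tests in the direction of the observed difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if a.mean() == b.mean():
                return TestResult(0.0, 1.0 if tails == "two" else 0.5, tails, na + nb - 2, "two_sample")
            raise ValueError("zero pooled variance with unequal means")
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    t = (a.mean() - b.mean()) / se
    p_two = 2.0 * sps.t.sf(abs(t), df)
    p = p_two if tails == "two" else p_two / 2.0
    return TestResult(float(t), float(min(p, 1.0)), tails, float(df), "two_sample")


def paired_t(diff, alternative: str = "greater") -> TestResult:
    """One-sample t on paired differences with a one-sided alternative."""
    d = np.asarray(diff, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError("paired test needs >= 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, 0.5, "one", n - 1, "paired")
        p = 0.0 if (d.mean() > 0) == (alternative == "greater") else 1.0
        return TestResult(np.inf * np.sign(d.mean()), p, "one", n - 1, "paired")
    t = d.mean() / (sd / np.sqrt(n))
    p = sps.t.sf(t, n - 1) if alternative == "greater" else sps.t.cdf(t, n - 1)
    return TestResult(float(t), float(p), "one", float(n - 1), "paired")


def half_map_test(branch_maps: list[GridMap], direction: str = "downstream_greater") -> TestResult:
    """Paired 1-tailed t-test of downstream (rows 5-9) vs upstream (rows 0-4)
    per-branch half-map means."""
    if direction not in ("downstream_greater", "upstream_greater"):
        raise ValueError("direction must be downstream_greater or upstream_greater")
    if len(branch_maps) < 3:
        raise ValueError("need >= 3 branch maps")
    diffs = []
    for m in branch_maps:
        v = m.values
        up = v[: GRID_N // 2].ravel()
        down = v[GRID_N // 2 :].ravel()
        up = up[np.isfinite(up)]
        down = down[np.isfinite(down)]
        if up.size == 0 or down.size == 0:
            raise ValueError("a branch map has no valid squares in one half")
        diffs.append(down.mean() - up.mean())
    alt = "greater" if direction == "downstream_greater" else "less"
    return paired_t(np.asarray(diffs), alternative=alt)
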