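"""Inferential statistics: t-tests, circular dispersion tests, TFCE
cluster permutation, power analysis, and group summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .ssvep import circular_mean, wrap_phase


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" | "two"
    pairing: str  # "dependent" | "independent"
    n: tuple[int, ...]
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the minimum-detectable-effect-size computation."""

    n1: int = 200
    n2: int = 200
    alpha: float = 0.05
    power: float = 0.8
    sidedness: str = "two"

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.alpha >= self.power:
            raise ValueError("alpha must be below the target power")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 observations per group")


def t_test(
    x: np.ndarray,
    y: np.ndarray,
    pairing: str = "independent",
    alternative: str = "two-sided",
) -> TestResult:
    """Student t-test for dependent or independent samples.

    ``alternative`` follows scipy ('two-sided', 'less', 'greater') and
    refers to the mean of ``x`` relative to ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if x.var() == 0 and y.var() == 0:
        raise ValueError("zero variance in both samples")
    if pairing == "dependent":
        if x.size != y.size:
            raise ValueError("paired test requires equal sample sizes")
        if np.all(x == y):
            # identical paired samples: no evidence against the null
            return TestResult(0.0, 1.0, "two" if alternative == "two-sided"
                              else "one", pairing, (x.size, y.size), "t-test")
        res = sps.ttest_rel(x, y, alternative=alternative)
    elif pairing == "independent":
        res = sps.ttest_ind(x, y, alternative=alternative)
    else:
        raise ValueError("pairing must be 'dependent' or 'independent'")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two" if alternative == "two-sided" else "one",
        pairing=pairing,
        n=(x.size, y.size),
        method="t-test",
    )


def _angular_distances(phases: np.ndarray, center: str) -> np.ndarray:
    phases = np.asarray(phases, dtype=float)
    if phases.size < 5:
        raise ValueError("need at least 5 angles per sample")
    mean_angle, r = circular_mean(phases)
    if r < 1e-9:
        raise ValueError("degenerate resultant: circular center undefined")
    if center == "mean":
        mu = mean_angle
    elif center == "median":
        # circular median: angle minimizing the mean angular distance
        cand = phases
        dists = np.abs(wrap_phase(cand[None, :] - cand[:, None])).mean(axis=1)
        mu = float(cand[np.argmin(dists)])
    else:
        raise ValueError("center must be 'mean' or 'median'")
    return np.abs(wrap_phase(phases - mu))


def wallraff_test(
    phases_a: np.ndarray,
    phases_b: np.ndarray,
    pairing: str = "independent",
    center: str = "mean",
    alternative: str = "two-sided",
) -> TestResult:
    """Compare angular concentration of two phase samples.

    Each sample's angular distances to its own circular mean (or median)
    are compared with a Wilcoxon signed-rank test (dependent samples) or a
    Mann-Whitney U test (independent samples).
    """
    da = _angular_distances(phases_a, center)
    db = _angular_distances(phases_b, center)
    if pairing == "dependent":
        if da.size != db.size:
            raise ValueError("paired test requires equal sample sizes")
        if np.all(da == db):
            res_stat, res_p = 0.0, 1.0
        else:
            res = sps.wilcoxon(da, db, alternative=alternative)
            res_stat, res_p = float(res.statistic), float(res.pvalue)
        method = "wallraff-wilcoxon"
    elif pairing == "independent":
        res = sps.mannwhitneyu(da, db, alternative=alternative)
        res_stat, res_p = float(res.statistic), float(res.pvalue)
        method = "wallraff-mannwhitney"
    else:
        raise ValueError("pairing must be 'dependent' or 'independent'")
    return TestResult(
        statistic=res_stat,
        p_value=res_p,
        sidedness="two" if alternative == "two-sided" else "one",
        pairing=pairing,
        n=(da.size, db.size),
        method=method,
    )


def tfce_transform(
    t_map: np.ndarray,
    adjacency: np.ndarray,
    e: float = 0.5,
    h: float = 2.0,
    dh_frac: float = 0.1,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed sensor statistic map.

    Integrates ``extent**E * height**H`` over thresholds from ``dh`` to the
    map maximum in steps of ``dh = dh_frac * max|t|``; positive and negative
    parts are enhanced separately and recombined with their signs.
    """
    t_map = np.asarray(t_map, dtype=float)
    out = np.zeros_like(t_map)
    max_abs = np.abs(t_map).max()
    if max_abs == 0:
        return out
    dh = dh_frac * max_abs
    thresholds = np.arange(dh, max_abs + dh / 2, dh)
    neighbors = [np.flatnonzero(adjacency[i]) for i in range(t_map.size)]
    for sign in (1.0, -1.0):
        vals = sign * t_map
        for thr in thresholds:
            supra = vals > thr
            if not supra.any():
                continue
            seen = np.zeros(t_map.size, dtype=bool)
            for start in np.flatnonzero(supra):
                if seen[start]:
                    continue
                stack, members = [start], []
                seen[start] = True
                while stack:
                    node = stack.pop()
                    members.append(node)
                    for nb in neighbors[node]:
                        if supra[nb] and not seen[nb]:
                            seen[nb] = True
                            stack.append(nb)
                inc = sign * (len(members) ** e) * (thr**h) * dh
                out[members] += inc
    return out


def tfce_cluster_test(
    amplitudes_a: np.ndarray,
    amplitudes_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1024,
    e: float = 0.5,
    h: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Spatial cluster permutation test with TFCE and max-statistic FWER.

    ``amplitudes_a``/``b`` are trials x sensors for the two conditions;
    group labels are shuffled across trials. Returns a corrected two-sided
    p-value per sensor.
    """
    a = np.atleast_2d(np.asarray(amplitudes_a, dtype=float))
    b = np.atleast_2d(np.asarray(amplitudes_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("both conditions need the same sensor set")
    if a.shape[1] < 2:
        raise ValueError("need at least 2 sensors")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    adjacency = np.asarray(adjacency, dtype=bool)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    rng = np.random.default_rng() if rng is None else rng

    na = a.shape[0]
    combined = np.vstack([a, b])

    def t_map(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
        ma, mb = ga.mean(axis=0), gb.mean(axis=0)
        va, vb = ga.var(axis=0, ddof=1), gb.var(axis=0, ddof=1)
        n1, n2 = ga.shape[0], gb.shape[0]
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        denom = sp * np.sqrt(1 / n1 + 1 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (ma - mb) / denom, 0.0)
        return t

    observed = tfce_transform(t_map(a, b), adjacency, e=e, h=h)
    max_null = np.empty(n_perm)
    idx = np.arange(combined.shape[0])
    for p in range(n_perm):
        perm = rng.permutation(idx)
        ga, gb = combined[perm[:na]], combined[perm[na:]]
        max_null[p] = np.abs(tfce_transform(t_map(ga, gb), adjacency, e=e, h=h)).max()
    exceed = (max_null[:, None] >= np.abs(observed)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_perm)


def _power_two_sample(d: float, n1: int, n2: int, alpha: float,
                      sidedness: str) -> float:
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    if sidedness == "two":
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))
    tc = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))


def detectable_effect_size(
    spec: PowerSpec, method: str = "noncentral-t", tol: float = 1e-6
) -> float:
    """Smallest Cohen's d detectable at the requested power.

    Solved by bisection on the noncentral-t power function of the
    independent-samples t-test; ``method='normal'`` gives the closed-form
    normal approximation instead.
    """
    spec.validate()
    if method == "normal":
        if spec.sidedness == "two":
            za = sps.norm.ppf(1 - spec.alpha / 2)
        else:
            za = sps.norm.ppf(1 - spec.alpha)
        zb = sps.norm.ppf(spec.power)
        return float((za + zb) * np.sqrt(1 / spec.n1 + 1 / spec.n2))
    if method != "noncentral-t":
        raise ValueError("method must be 'noncentral-t' or 'normal'")
    lo, hi = 0.0, 0.1
    while _power_two_sample(hi, spec.n1, spec.n2, spec.alpha, spec.sidedness) < spec.power:
        hi *= 2
        if hi > 1e3:
            raise ValueError("requested power unreachable")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if _power_two_sample(mid, spec.n1, spec.n2, spec.alpha,
                             spec.sidedness) < spec.power:
            lo = mid
        else:
            hi = mid
    return float((lo + hi) / 2)


def residual_artifact_bound(d: float, sd1: float, sd2: float) -> float:
    """Detectable difference in means: d times the pooled SD (equal n)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(d * np.sqrt((sd1**2 + sd2**2) / 2.0))


def group_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation (divide by N)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    return float(values.mean()), float(values.std(ddof=0))


def rayleigh_uniformity_p(phases: np.ndarray) -> float:
    """Rayleigh test p-value for circular uniformity (Zar's approximation)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    r = np.abs(np.exp(1j * phases).mean())
    z = n * r**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * r) ** 2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0)) if np.isfinite(p) else float(np.exp(-z))
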