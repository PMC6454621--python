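"""Characterization of motoneuron firing against grasp force and movement velocity.

The central object is the saturating rate-force law

    FR(f) = B / (C + exp(-f/D)) - A

with force ``f`` and rate ``FR`` both normalized to their maxima. A, B and C
set the saturation value ``B/C - A`` (the asymptotic normalized rate), D is
the characteristic force of the saturation process. The law is fitted by
bounded nonlinear least squares with Latin-hypercube multi-start, because the
four parameters are strongly correlated on a small force grid and a single
start is unreliable.

Group comparisons follow a distribution-gated scheme: Lilliefors normality
and Bartlett homoscedasticity gates at alpha = 0.05 select one-way ANOVA when
both pass and Kruskal-Wallis otherwise, with Tukey-Kramer post-hoc pairwise
comparisons for more than two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

__all__ = [
    "fr_force_curve",
    "FRForceFit",
    "fit_fr_force",
    "compute_fr_slope",
    "SlopeVelocityFit",
    "fit_slope_velocity",
    "GatedTestResult",
    "gated_group_test",
    "bootstrap_pairs",
]

#: optimizer box bounds: A, B, C in [0, 10], D in (1e-3, 10]
FIT_LOWER = np.array([0.0, 0.0, 0.0, 1e-3])
FIT_UPPER = np.array([10.0, 10.0, 10.0, 10.0])
N_STARTS = 20


def fr_force_curve(f, A, B, C, D):
    """Saturating rate-force law FR(f) = B/(C + e^(-f/D)) - A."""
    f = np.asarray(f, dtype=float)
    return B / (C + np.exp(-f / D)) - A


@dataclass
class FRForceFit:
    A: float
    B: float
    C: float
    D: float
    r_squared: float
    phase: str = "reaching"
    degenerate: bool = False

    @property
    def saturation(self) -> float:
        """Asymptotic normalized firing rate, B/C - A."""
        return self.B / self.C - self.A

    def __call__(self, f):
        return fr_force_curve(f, self.A, self.B, self.C, self.D)

    def to_dict(self) -> dict:
        return {"A": self.A, "B": self.B, "C": self.C, "D": self.D,
                "saturation": self.saturation, "r_squared": self.r_squared,
                "phase": self.phase, "degenerate": self.degenerate}


class FitConvergenceError(RuntimeError):
    """All multi-start fits failed; carries per-start diagnostics."""

    def __init__(self, diagnostics):
        super().__init__(f"rate-force fit failed in all starts: {diagnostics}")
        self.diagnostics = diagnostics


def _r_squared(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_fr_force(force_norm, fr_norm, phase: str = "reaching",
                 n_starts: int = N_STARTS, seed: int = 0) -> FRForceFit:
    """Fit the saturating rate-force law to max-normalized (force, rate) pairs.

    Uses ``n_starts`` Latin-hypercube starting points inside the parameter box
    (deterministic for a given ``seed``) and keeps the best least-squares
    solution. Constant-rate input is flagged degenerate with R^2 = 0.
    """
    f = np.asarray(force_norm, dtype=float)
    y = np.asarray(fr_norm, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("force_norm and fr_norm must be equal-length 1-D")
    if len(f) < 4:
        raise ValueError("need at least 4 points to fit 4 parameters")
    if np.ptp(y) == 0.0:
        return FRForceFit(A=0.0, B=0.0, C=1.0, D=1.0, r_squared=0.0,
                          phase=phase, degenerate=True)

    def residuals(p):
        return fr_force_curve(f, *p) - y

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), FIT_LOWER + 1e-3, FIT_UPPER)
    best, best_cost, failures = None, np.inf, []
    for p0 in starts:
        try:
            sol = optimize.least_squares(residuals, p0, max_nfev=2000,
                                         bounds=(FIT_LOWER, FIT_UPPER))
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        # an exhausted evaluation budget still yields a usable iterate
        if np.isfinite(sol.cost) and sol.cost < best_cost:
            best, best_cost = sol, sol.cost
        elif not sol.success:
            failures.append(sol.message)
        if best_cost < 1e-16:
            break
    if best is None:
        raise FitConvergenceError(failures)
    A, B, C, D = best.x
    return FRForceFit(A=float(A), B=float(B), C=float(C), D=float(D),
                      r_squared=_r_squared(y, fr_force_curve(f, *best.x)),
                      phase=phase)


def compute_fr_slope(fr_series, t_grid, movement_onset: float,
                     normalize: bool = True, flat_is_zero: bool = False) -> float:
    """Firing-rate slope between the FR maximum and the movement onset cue.

    slope = (FR_max - FR(onset)) / (t_max - onset), computed on the
    max-normalized series when ``normalize``; units 1/s when normalized.
    """
    fr = np.asarray(fr_series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if fr.shape != t.shape:
        raise ValueError("fr_series and t_grid must have the same shape")
    if normalize:
        m = fr.max()
        if m > 0:
            fr = fr / m
    mask = t >= movement_onset
    if not mask.any():
        raise ValueError("movement_onset beyond the end of the series")
    i_max = np.argmax(fr[mask])
    t_max = t[mask][i_max]
    if t_max <= movement_onset:
        if flat_is_zero:
            return 0.0
        raise ValueError("FR maximum coincides with movement onset")
    fr_onset = float(np.interp(movement_onset, t, fr))
    return float((fr[mask][i_max] - fr_onset) / (t_max - movement_onset))


@dataclass
class SlopeVelocityFit:
    slope: float
    intercept: float
    r_squared: float
    pairs: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "pairs": self.pairs}


def fit_slope_velocity(velocities, slopes) -> SlopeVelocityFit:
    """Ordinary least squares of normalized FR slope on movement velocity."""
    v = np.asarray(velocities, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if v.shape != s.shape or len(v) < 2:
        raise ValueError("need >= 2 (velocity, slope) pairs")
    if np.ptp(v) == 0.0:
        raise ValueError("all velocities identical; slope undefined")
    res = stats.linregress(v, s)
    return SlopeVelocityFit(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            pairs=list(zip(v.tolist(), s.tolist())))


@dataclass
class GatedTestResult:
    normality_p: float
    homoscedasticity_p: float
    chosen_test: str            # "anova" | "kruskal"
    p_value: float
    posthoc: dict[tuple[int, int], float] | None = None

    def to_dict(self) -> dict:
        d = {"normality_p": self.normality_p,
             "homoscedasticity_p": self.homoscedasticity_p,
             "chosen_test": self.chosen_test, "p_value": self.p_value}
        if self.posthoc is not None:
            d["posthoc"] = {f"{i}-{j}": p for (i, j), p in self.posthoc.items()}
        return d


def gated_group_test(groups, alpha: float = 0.05,
                     posthoc: bool = False) -> GatedTestResult:
    """Distribution-gated group comparison.

    Gates: Lilliefors normality on every group (the reported normality p is
    the minimum across groups) and Bartlett homoscedasticity across groups.
    One-way ANOVA iff both gate p-values exceed ``alpha``, else
    Kruskal-Wallis. Tukey-Kramer pairwise p-values are attached when
    ``posthoc`` and more than two groups.
    """
    from statsmodels.stats.diagnostic import lilliefors

    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 4:
            raise ValueError(f"group {i} has n < 4")
        if np.ptp(g) == 0.0:
            raise ValueError(f"group {i} has zero variance")
    normality_p = min(float(lilliefors(g, dist="norm")[1]) for g in groups)
    homo_p = float(stats.bartlett(*groups).pvalue)
    if normality_p > alpha and homo_p > alpha:
        chosen, p = "anova", float(stats.f_oneway(*groups).pvalue)
    else:
        chosen, p = "kruskal", float(stats.kruskal(*groups).pvalue)
    ph = None
    if posthoc and len(groups) > 2:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate(groups)
        labels = np.concatenate([np.full(len(g), i)
                                 for i, g in enumerate(groups)])
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        pairs = [(int(a), int(b)) for a, b in
                 zip(*np.triu_indices(len(groups), k=1))]
        ph = {pair: float(p_adj)
              for pair, p_adj in zip(pairs, res.pvalues)}
    return GatedTestResult(normality_p=normality_p, homoscedasticity_p=homo_p,
                           chosen_test=chosen, p_value=p, posthoc=ph)


def bootstrap_pairs(x, y, n_boot: int, seed: int | None = None):
    """Case-resample (x, y) pairs with replacement.

    Returns arrays of shape (n_boot, n) for x and y; reproducible by seed.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) == 0:
        raise ValueError("empty input")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    return x[idx], y[idx]
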