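"""Hill-equation analysis of cation-dependent ATPase activity curves.

Activation mode:  v(c) = v0 + (v_max − v0) · cⁿ / (Kⁿ + cⁿ)
Inhibition mode:  v(c) = v0 + (v_max − v0) · Kⁿ / (Kⁿ + cⁿ)

K is the half-maximal concentration K₀.₅ (mM) and n the Hill coefficient;
n ≈ 1 indicates a single non-cooperative binding site. Fitting is nonlinear
least squares with deterministic multi-start initialisation over
n ∈ {0.5, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ActivityCurve",
    "HillFitResult",
    "DegenerateFitError",
    "hill_fit",
    "hill_predict",
    "subtract_background",
]


class DegenerateFitError(RuntimeError):
    """Data carry no usable concentration dependence."""


@dataclass
class ActivityCurve:
    """Concentration–activity data; activities in any consistent rate unit."""

    concentrations: np.ndarray  # mM
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.concentrations.shape != self.activities.shape:
            raise ValueError("concentrations and activities must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(self.concentrations, kind="stable")
        self.concentrations = self.concentrations[order]
        self.activities = self.activities[order]
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations to fit")


@dataclass
class HillFitResult:
    n: float
    K_half: float  # mM
    v_max: float
    v0: float
    mode: str  # "activation" | "inhibition"
    residual_ss: float
    include_basal: bool = True
    bootstrap_ci: dict[str, tuple[float, float]] | None = None


def _hill(c: np.ndarray, n: float, K: float, v_max: float, v0: float, mode: str) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    cn = np.power(np.maximum(c, 0.0), n)
    Kn = K**n
    frac = cn / (Kn + cn)
    if mode == "inhibition":
        frac = Kn / (Kn + cn)
    return v0 + (v_max - v0) * frac


def hill_predict(fit: HillFitResult, concentrations: np.ndarray) -> np.ndarray:
    """Evaluate a fitted Hill model; concentrations must be non-negative."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return _hill(c, fit.n, fit.K_half, fit.v_max, fit.v0, fit.mode)


def hill_fit(
    curve: ActivityCurve,
    mode: str,
    include_basal: bool = True,
    weights: np.ndarray | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> HillFitResult:
    """Fit the Hill equation to an activity curve.

    Initialisation is deterministic: v0/v_max from the data extremes, K₀.₅
    from the concentration nearest half-range, and a multi-start over
    n ∈ {0.5, 1, 2}; the start with the lowest residual sum of squares wins
    (ties break toward the smallest n). With ``include_basal=False`` the
    basal term v0 is pinned at 0. ``bootstrap`` > 0 adds percentile
    confidence intervals from that many case resamples (seeded).
    """
    if mode not in ("activation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    c = curve.concentrations
    v = curve.activities
    span = float(v.max() - v.min())
    if span <= 0 or span < 1e-12 * max(abs(float(v.max())), 1.0):
        raise DegenerateFitError("activities are constant; nothing to fit")

    lo, hi = float(v.min()), float(v.max())
    # in both modes v0 is the low plateau and v_max the high one:
    # activation rises from v0 to v_max; inhibition falls from v_max to v0
    v0_init, vmax_init = lo, hi
    half = 0.5 * (lo + hi)
    pos = c[c > 0]
    if pos.size == 0:
        raise DegenerateFitError("all concentrations are zero")
    K_init = float(pos[np.argmin(np.abs(v[c > 0] - half))])
    if K_init <= 0:
        K_init = float(np.median(pos))

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)

    best: tuple[float, np.ndarray] | None = None
    last_err: Exception | None = None
    for n_start in (0.5, 1.0, 2.0):
        try:
            if include_basal:
                def f(cc, n, K, vmax, v0):
                    return _hill(cc, n, K, vmax, v0, mode)
                p0 = [n_start, K_init, vmax_init, v0_init]
                bounds = ([1e-3, 1e-9, -np.inf, -np.inf], [20.0, np.inf, np.inf, np.inf])
            else:
                def f(cc, n, K, vmax):
                    return _hill(cc, n, K, vmax, 0.0, mode)
                p0 = [n_start, K_init, vmax_init]
                bounds = ([1e-3, 1e-9, -np.inf], [20.0, np.inf, np.inf])
            popt, _ = curve_fit(f, c, v, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = v - f(c, *popt)
        ss = float(resid @ resid)
        if best is None or ss < best[0] - 1e-15:
            best = (ss, popt)
    if best is None:
        raise RuntimeError(f"Hill fit failed for every start: {last_err}")

    ss, popt = best
    if include_basal:
        n_fit, K_fit, vmax_fit, v0_fit = popt
    else:
        n_fit, K_fit, vmax_fit = popt
        v0_fit = 0.0

    ci = None
    if bootstrap > 0:
        # case resampling; each replicate refits from the point estimate
        rng = np.random.default_rng(seed)
        samples = {"n": [], "K_half": [], "v_max": [], "v0": []}
        n_pts = len(c)
        # |n|, |K| reparameterisation keeps LM unconstrained yet positive
        if include_basal:
            def f_boot(cc, n, K, vmax, v0):
                return _hill(cc, abs(n), abs(K), vmax, v0, mode)
        else:
            def f_boot(cc, n, K, vmax):
                return _hill(cc, abs(n), abs(K), vmax, 0.0, mode)
        for _ in range(bootstrap):
            idx = rng.integers(0, n_pts, n_pts)
            cc, vv = c[idx], v[idx]
            if len(np.unique(cc)) < 5:
                continue
            try:
                pb, _ = curve_fit(
                    f_boot, cc, vv, p0=list(popt), method="lm", maxfev=5000
                )
            except (RuntimeError, ValueError):
                continue
            samples["n"].append(abs(pb[0]))
            samples["K_half"].append(abs(pb[1]))
            samples["v_max"].append(pb[2])
            samples["v0"].append(pb[3] if include_basal else 0.0)
        ci = {
            k: (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5)))
            for k, s in samples.items()
            if s
        }

    return HillFitResult(
        n=float(n_fit),
        K_half=float(K_fit),
        v_max=float(vmax_fit),
        v0=float(v0_fit),
        mode=mode,
        residual_ss=ss,
        include_basal=include_basal,
        bootstrap_ci=ci,
    )


def subtract_background(
    activities: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Pairwise blank subtraction (e.g. activity in saturating inhibitor)."""
    a = np.asarray(activities, dtype=float)
    b = np.asarray(background, dtype=float)
    if a.shape != b.shape:
        raise ValueError("activity and background columns must align")
    return a - b
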