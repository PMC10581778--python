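"""Van't Hoff transformation and continuous segmented-line fitting.

A heating response curve is mapped to van't Hoff coordinates — log of the
absolute current against inverse absolute temperature — and fitted with a
continuous piecewise-linear model with 0, 1 or 2 breakpoints.  The first
breakpoint (in °C) is the activation threshold of the heat-activated
conductance; a second breakpoint, where the slope falls again, marks open
probability reaching its maximum, the remaining temperature dependence
reflecting diffusion through the open pore.  Q10 values are computed per
segment from the fitted currents via

    Q10 = (I2 / I1) ** (10 / (T2 - T1))

which is independent of the logarithm base used for the transform.

The breakpoint search is exact on a grid: candidate breakpoints are the
observed inverse-temperature values (pairs of them for two breakpoints),
and for every candidate the continuous piecewise model is an ordinary
least-squares fit on the hinge basis {1, x, (x-b)+, ...}.  Sums entering
the normal equations are taken from prefix sums, so the full grid is
evaluated in closed form and the minimum is the global grid minimum.  A
note on conventions: a pure Q10 process is exactly log-linear in T, not in
1/T; fitting in 1/T (the van't Hoff/Arrhenius convention) therefore leaves
a small, quantifiable curvature — on the spans encountered here the
resulting relative error on endpoint Q10s is of order 1e-4 and is
characterized in the test suite rather than corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gating import CELSIUS_OFFSET
from .traces import ActivationSegment, measure_leak, measure_max_current

__all__ = [
    "VantHoffCurve",
    "SegmentedVantHoffFit",
    "ActivationMetrics",
    "EmptyCurveError",
    "FitError",
    "ExtrapolationError",
    "to_vanthoff",
    "fit_segmented",
    "q10_between",
    "derive_metrics",
    "windowed_q10",
]


class EmptyCurveError(ValueError):
    """All points fell below the current floor."""


class FitError(ValueError):
    """The segmented fit is under-determined for the requested model."""


class ExtrapolationError(ValueError):
    """A temperature outside the fitted range was requested."""


@dataclass
class VantHoffCurve:
    """log|I| versus 1/T(K) for one activation."""

    inv_T: np.ndarray
    log_abs_I: np.ndarray
    log_base: float  # math.e or 10.0
    n_dropped: int = 0
    cell_id: Optional[str] = None
    activation_index: Optional[int] = None

    def __len__(self) -> int:
        return len(self.inv_T)


def to_vanthoff(
    seg: ActivationSegment,
    current_floor: float = 1e-3,
    log_base: float = math.e,
) -> VantHoffCurve:
    """Transform a heating segment to van't Hoff coordinates.

    ``inv_T = 1 / (T + 273.15)`` and ``log|I|`` in the requested base
    (natural log by default).  Samples with ``|I|`` below ``current_floor``
    nA are dropped and counted.  Raises :class:`EmptyCurveError` when no
    points survive.
    """
    T = np.asarray(seg.temperature, float)
    I = np.abs(np.asarray(seg.current, float))
    keep = I >= current_floor
    n_dropped = int((~keep).sum())
    if not np.any(keep):
        raise EmptyCurveError("all samples below the current floor")
    inv_T = 1.0 / (T[keep] + CELSIUS_OFFSET)
    logs = np.log(I[keep])
    if log_base != math.e:
        logs = logs / math.log(log_base)
    return VantHoffCurve(
        inv_T=inv_T,
        log_abs_I=logs,
        log_base=float(log_base),
        n_dropped=n_dropped,
        cell_id=seg.cell_id,
        activation_index=seg.activation_index,
    )


@dataclass
class SegmentedVantHoffFit:
    """A continuous piecewise-linear fit in van't Hoff coordinates.

    ``breakpoints`` are in inverse kelvin, ascending (so descending in °C);
    ``slopes`` are per segment in the same ascending-inv_T order, in units
    of log-current per K⁻¹.  ``model_stats`` holds RSS and BIC per candidate
    breakpoint count.
    """

    n_breakpoints: int
    breakpoints: np.ndarray
    slopes: np.ndarray
    intercept: float
    rss: float
    n_points: int
    log_base: float
    inv_T_min: float
    inv_T_max: float
    model_stats: dict = field(default_factory=dict)
    breakpoint_se: Optional[np.ndarray] = None
    # z-space parameters used for prediction
    _z_mu: float = 0.0
    _z_sd: float = 1.0
    _beta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    _knots_z: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def predict(self, inv_T) -> np.ndarray:
        """Fitted log|I| (in ``log_base``) at the given inverse temperatures."""
        z = (np.asarray(inv_T, float) - self._z_mu) / self._z_sd
        y = self._beta[0] + self._beta[1] * z
        for j, c in enumerate(self._knots_z):
            y = y + self._beta[2 + j] * np.maximum(z - c, 0.0)
        return y


def _prefix_sums(x: np.ndarray, y: np.ndarray):
    z = np.concatenate([[0.0], x])
    return {
        "n": np.arange(len(x) + 1, dtype=float),
        "x": np.concatenate([[0.0], np.cumsum(x)]),
        "xx": np.concatenate([[0.0], np.cumsum(x * x)]),
        "y": np.concatenate([[0.0], np.cumsum(y)]),
        "xy": np.concatenate([[0.0], np.cumsum(x * y)]),
    }


def _suffix(P, pos):
    """Sums over points with index >= pos (x strictly above the candidate)."""
    return {k: v[-1] - v[pos] for k, v in P.items()}


def _solve_batch(G: np.ndarray, c: np.ndarray, yty: float, cands: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve stacked normal equations; returns (rss, beta) arrays."""
    try:
        beta = np.linalg.solve(G, c[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.empty_like(c)
        for i in range(G.shape[0]):
            beta[i] = np.linalg.lstsq(G[i], c[i], rcond=None)[0]
    rss = yty - np.einsum("ij,ij->i", beta, c)
    return np.maximum(rss, 0.0), beta


def _fit_k0(x, y):
    A = np.vstack([np.ones_like(x), x]).T
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid), beta


def _exact_refit(z, y, knots):
    """Clean lstsq refit at fixed knots.

    The prefix-sum grid search accumulates rounding at large n; the knots it
    selects are used here to recompute coefficients and RSS exactly.
    """
    cols = [np.ones_like(z), z] + [np.maximum(z - c, 0.0) for c in knots]
    A = np.vstack(cols).T
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid), beta


def _candidate_indices(cum: np.ndarray, n: int, msp: int, max_candidates: int) -> np.ndarray:
    """Indices into the unique-value array usable as a single breakpoint."""
    valid = np.nonzero((cum >= msp) & (n - cum >= msp))[0]
    if valid.size > max_candidates:
        pick = np.linspace(0, valid.size - 1, max_candidates).round().astype(int)
        valid = valid[np.unique(pick)]
    return valid


def _fit_k1(x, y, P, u, cum, cand, yty):
    n = len(x)
    Ax, Axx, Ay, Axy = P["x"][-1], P["xx"][-1], P["y"][-1], P["xy"][-1]
    pos = cum[cand]
    b = u[cand]
    S1 = n - pos
    Sx = P["x"][-1] - P["x"][pos]
    Sxx = P["xx"][-1] - P["xx"][pos]
    Sy = P["y"][-1] - P["y"][pos]
    Sxy = P["xy"][-1] - P["xy"][pos]
    Sh = Sx - b * S1
    Shh = Sxx - 2 * b * Sx + b * b * S1
    Sxh = Sxx - b * Sx
    Shy = Sxy - b * Sy
    m = len(cand)
    G = np.empty((m, 3, 3))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = Ax
    G[:, 0, 2] = G[:, 2, 0] = Sh
    G[:, 1, 1] = Axx
    G[:, 1, 2] = G[:, 2, 1] = Sxh
    G[:, 2, 2] = Shh
    c = np.stack([np.full(m, Ay), np.full(m, Axy), Shy], axis=1)
    rss, beta = _solve_batch(G, c, yty, m)
    i = int(np.argmin(rss))
    return float(rss[i]), beta[i], np.array([b[i]])


def _fit_k2(x, y, P, u, cum, cand, yty, msp, chunk=200_000):
    n = len(x)
    Ax, Axx, Ay, Axy = P["x"][-1], P["xx"][-1], P["y"][-1], P["xy"][-1]
    j1, j2 = np.meshgrid(cand, cand, indexing="ij")
    keep = (j1 < j2) & (cum[j2] - cum[j1] >= msp)
    j1, j2 = j1[keep], j2[keep]
    if j1.size == 0:
        return None
    best = (np.inf, None, None)
    for lo in range(0, j1.size, chunk):
        a = j1[lo : lo + chunk]
        bidx = j2[lo : lo + chunk]
        b1, b2 = u[a], u[bidx]
        p1, p2 = cum[a], cum[bidx]
        S1_1 = n - p1
        Sx_1 = P["x"][-1] - P["x"][p1]
        Sxx_1 = P["xx"][-1] - P["xx"][p1]
        Sy_1 = P["y"][-1] - P["y"][p1]
        Sxy_1 = P["xy"][-1] - P["xy"][p1]
        S1_2 = n - p2
        Sx_2 = P["x"][-1] - P["x"][p2]
        Sxx_2 = P["xx"][-1] - P["xx"][p2]
        Sy_2 = P["y"][-1] - P["y"][p2]
        Sxy_2 = P["xy"][-1] - P["xy"][p2]
        Sh1 = Sx_1 - b1 * S1_1
        Sh2 = Sx_2 - b2 * S1_2
        Sh1h1 = Sxx_1 - 2 * b1 * Sx_1 + b1 * b1 * S1_1
        Sh2h2 = Sxx_2 - 2 * b2 * Sx_2 + b2 * b2 * S1_2
        Sh1h2 = Sxx_2 - (b1 + b2) * Sx_2 + b1 * b2 * S1_2
        Sxh1 = Sxx_1 - b1 * Sx_1
        Sxh2 = Sxx_2 - b2 * Sx_2
        Sh1y = Sxy_1 - b1 * Sy_1
        Sh2y = Sxy_2 - b2 * Sy_2
        m = a.size
        G = np.empty((m, 4, 4))
        G[:, 0, 0] = n
        G[:, 0, 1] = G[:, 1, 0] = Ax
        G[:, 0, 2] = G[:, 2, 0] = Sh1
        G[:, 0, 3] = G[:, 3, 0] = Sh2
        G[:, 1, 1] = Axx
        G[:, 1, 2] = G[:, 2, 1] = Sxh1
        G[:, 1, 3] = G[:, 3, 1] = Sxh2
        G[:, 2, 2] = Sh1h1
        G[:, 2, 3] = G[:, 3, 2] = Sh1h2
        G[:, 3, 3] = Sh2h2
        c = np.stack([np.full(m, Ay), np.full(m, Axy), Sh1y, Sh2y], axis=1)
        rss, beta = _solve_batch(G, c, yty, m)
        i = int(np.argmin(rss))
        if rss[i] < best[0]:
            best = (float(rss[i]), beta[i], np.array([b1[i], b2[i]]))
    return best


def fit_segmented(
    curve: VantHoffCurve,
    max_breakpoints: int = 2,
    min_seg_points: int = 5,
    *,
    max_candidates: int = 400,
    force_k: Optional[int] = None,
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
) -> SegmentedVantHoffFit:
    """Fit continuous segmented lines with 0..``max_breakpoints`` breakpoints.

    For each candidate breakpoint count the model is optimized by exact
    least squares over a grid of observed inverse-temperature values (all
    ordered pairs for two breakpoints); every segment must contain at least
    ``min_seg_points`` points.  When the number of eligible grid values
    exceeds ``max_candidates`` the grid is thinned evenly (the default, 400,
    resolves breakpoints to well under 0.1 °C on a standard downsampled
    ramp).  The reported model is the count selected by the Bayesian
    information criterion (ties favour fewer breakpoints), unless
    ``force_k`` overrides the selection.  Breakpoint standard errors are
    estimated by a seeded nonparametric bootstrap over points when
    ``bootstrap_reps`` > 0.
    """
    if not 0 <= max_breakpoints <= 2:
        raise ValueError("max_breakpoints must be 0, 1 or 2")
    x_raw = np.asarray(curve.inv_T, float)
    y_raw = np.asarray(curve.log_abs_I, float)
    n = x_raw.size
    if n < max(2, (1 if force_k is None else force_k + 1) * min_seg_points):
        raise FitError(
            f"{n} points cannot support the requested model "
            f"(need >= {min_seg_points} per segment)"
        )
    order = np.argsort(x_raw, kind="stable")
    xs, ys = x_raw[order], y_raw[order]
    mu, sd = float(xs.mean()), float(xs.std())
    if sd == 0:
        raise FitError("all temperatures identical; no slope is defined")
    z = (xs - mu) / sd
    yty = float(ys @ ys)
    P = _prefix_sums(z, ys)
    u, counts = np.unique(z, return_counts=True)
    cum = np.cumsum(counts)

    results: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    rss0, beta0 = _fit_k0(z, ys)
    results[0] = (rss0, beta0, np.zeros(0))
    if max_breakpoints >= 1:
        cand = _candidate_indices(cum, n, min_seg_points, max_candidates)
        if cand.size:
            _, _, knots1 = _fit_k1(z, ys, P, u, cum, cand, yty)
            rss1, beta1 = _exact_refit(z, ys, knots1)
            results[1] = (rss1, beta1, knots1)
        if max_breakpoints >= 2 and cand.size >= 2:
            r2 = _fit_k2(z, ys, P, u, cum, cand, yty, min_seg_points)
            if r2 is not None and r2[1] is not None:
                rss2, beta2 = _exact_refit(z, ys, r2[2])
                results[2] = (rss2, beta2, r2[2])

    if force_k is not None:
        if force_k not in results:
            raise FitError(
                f"{force_k} breakpoints are under-determined for this curve"
            )
        selected = force_k
    else:
        # BIC on gaussian RSS; floor keeps noiseless fits comparable and
        # ties resolve toward fewer breakpoints
        floor = yty * 1e-20 + 1e-300
        bics = {}
        for k, (rss, _, _) in results.items():
            p = 2 + 2 * k
            bics[k] = n * math.log(max(rss, floor) / n) + p * math.log(n)
        selected = 0
        for k in sorted(results):
            if bics[k] < bics[selected] - 1e-9:
                selected = k

    rss, beta, knots_z = results[selected]
    # slopes per segment, ascending inv_T, converted back to 1/K units
    slopes = np.concatenate([[beta[1]], beta[1] + np.cumsum(beta[2:])]) / sd if selected else np.array([beta[1] / sd])
    intercept = float(beta[0] - beta[1] * mu / sd)
    breakpoints = knots_z * sd + mu

    stats = {}
    for k, (r, _, _) in results.items():
        p = 2 + 2 * k
        stats[k] = {
            "rss": r,
            "bic": n * math.log(max(r, yty * 1e-20 + 1e-300) / n) + p * math.log(n),
        }

    fit = SegmentedVantHoffFit(
        n_breakpoints=selected,
        breakpoints=breakpoints,
        slopes=slopes,
        intercept=intercept,
        rss=float(rss),
        n_points=n,
        log_base=curve.log_base,
        inv_T_min=float(xs[0]),
        inv_T_max=float(xs[-1]),
        model_stats=stats,
        _z_mu=mu,
        _z_sd=sd,
        _beta=np.asarray(beta, float),
        _knots_z=np.asarray(knots_z, float),
    )

    if bootstrap_reps > 0 and selected > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n, size=n)
            bcurve = VantHoffCurve(
                inv_T=x_raw[idx], log_abs_I=y_raw[idx], log_base=curve.log_base
            )
            try:
                bfit = fit_segmented(
                    bcurve,
                    max_breakpoints=selected,
                    min_seg_points=min_seg_points,
                    max_candidates=max_candidates,
                    force_k=selected,
                )
            except FitError:
                continue
            draws.append(bfit.breakpoints)
        if draws:
            fit.breakpoint_se = np.std(np.vstack(draws), axis=0, ddof=1)
    return fit


def q10_between(fit: SegmentedVantHoffFit, T1: float, T2: float) -> float:
    """Q10 between two temperatures from the fitted (not raw) currents.

    ``Q10 = (I2/I1) ** (10/(T2-T1))`` evaluated on the fitted model, which
    makes the result independent of the logarithm base of the transform.
    Raises :class:`ExtrapolationError` for temperatures outside the fitted
    range.
    """
    if T1 == T2:
        raise ValueError("T1 and T2 must differ")
    xs = 1.0 / (np.array([T1, T2], float) + CELSIUS_OFFSET)
    tol = 1e-9 * (fit.inv_T_max - fit.inv_T_min)
    if np.any(xs < fit.inv_T_min - tol) or np.any(xs > fit.inv_T_max + tol):
        raise ExtrapolationError(
            f"temperatures ({T1}, {T2}) fall outside the fitted range"
        )
    L1, L2 = fit.predict(xs)
    return float(fit.log_base ** ((L2 - L1) * 10.0 / (T2 - T1)))


CLASS_DISTINCT = "distinct_threshold"
CLASS_NO_DISTINCT = "no_distinct_threshold"
CLASS_BASELINE = "baseline_only"


@dataclass
class ActivationMetrics:
    """Scalar metrics for one activation of one cell."""

    activation_index: int
    classification: str
    threshold_C: Optional[float]
    second_breakpoint_C: Optional[float]
    baseline_q10: Optional[float]
    activation_q10: Optional[float]
    supra_q10: Optional[float]
    leak_nA: float
    max_current_nA: float
    hold_temp_C: float
    n_breakpoints: int
    cell_id: Optional[str] = None


def derive_metrics(
    fit: SegmentedVantHoffFit,
    seg: ActivationSegment,
    q10_floor: float = 3.0,
    *,
    max_current_at: float = 35.0,
) -> ActivationMetrics:
    """Derive threshold, per-band Q10s, leak and maximum current.

    The activation threshold is the lowest fitted breakpoint (in °C) whose
    following segment has Q10 above ``q10_floor`` (the conventional
    criterion for distinct thermosensitivity); the next breakpoint after it,
    if any, is reported as the saturation breakpoint with its supra-Q10.
    Curves with no qualifying breakpoint are classified ``baseline_only``
    when their overall Q10 stays at or below the floor, and
    ``no_distinct_threshold`` when the Q10 is high from the hold temperature
    up (channels already open at the hold).  Ambiguity is carried in the
    classification; no exception is raised.
    """
    T_lo = 1.0 / fit.inv_T_max - CELSIUS_OFFSET
    T_hi = 1.0 / fit.inv_T_min - CELSIUS_OFFSET
    bps_C = sorted(1.0 / bp - CELSIUS_OFFSET for bp in fit.breakpoints)
    bounds = [T_lo, *bps_C, T_hi]
    q10s = [q10_between(fit, bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    leak = measure_leak(seg)
    maxc = measure_max_current(seg, max_current_at, leak.leak_nA)

    threshold = second_bp = None
    baseline = activation = supra = None
    j = next((i for i in range(1, len(bounds) - 1) if q10s[i] > q10_floor), None)
    if q10s[0] > q10_floor:
        # already steep from the hold temperature: channels open before any
        # fitted breakpoint, so no distinct threshold can be assigned
        classification = CLASS_NO_DISTINCT
        activation = q10_between(fit, T_lo, T_hi)
    elif j is not None:
        classification = CLASS_DISTINCT
        threshold = bounds[j]
        activation = q10s[j]
        baseline = q10s[0]
        if j + 1 <= len(bps_C):
            second_bp = bounds[j + 1]
            supra = q10s[j + 1]
    else:
        classification = CLASS_BASELINE
        baseline = q10s[0]

    return ActivationMetrics(
        activation_index=seg.activation_index,
        classification=classification,
        threshold_C=threshold,
        second_breakpoint_C=second_bp,
        baseline_q10=baseline,
        activation_q10=activation,
        supra_q10=supra,
        leak_nA=leak.leak_nA,
        max_current_nA=maxc.value_nA,
        hold_temp_C=leak.hold_temp_C,
        n_breakpoints=fit.n_breakpoints,
        cell_id=seg.cell_id,
    )


def windowed_q10(
    seg: ActivationSegment,
    T_lo: float,
    T_hi: float,
    *,
    min_points: int = 10,
    current_floor: float = 1e-3,
) -> Optional[float]:
    """Q10 over a restricted temperature window (e.g. 0-5 °C).

    Fits an ordinary least-squares line to the van't Hoff curve restricted
    to ``[T_lo, T_hi]`` and converts its endpoint values with the Q10
    formula.  Returns ``None`` (undefined-metric flag) when fewer than
    ``min_points`` in-window samples are available.
    """
    T = np.asarray(seg.temperature, float)
    I = np.abs(np.asarray(seg.current, float))
    mask = (T >= T_lo) & (T <= T_hi) & (I >= current_floor)
    if mask.sum() < min_points:
        return None
    x = 1.0 / (T[mask] + CELSIUS_OFFSET)
    if np.ptp(x) == 0:
        return None
    y = np.log(I[mask])
    A = np.vstack([np.ones_like(x), x]).T
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    x1, x2 = 1.0 / (T_lo + CELSIUS_OFFSET), 1.0 / (T_hi + CELSIUS_OFFSET)
    L1, L2 = beta[0] + beta[1] * x1, beta[0] + beta[1] * x2
    return float(np.exp((L2 - L1) * 10.0 / (T_hi - T_lo)))
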