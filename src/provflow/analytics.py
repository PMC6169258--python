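"""Quantitative microbial physiology from growth-curve data.

The pipeline mirrors how batch and chemostat cultivations are evaluated in
quantitative physiology work:

* the exponential growth phase of a biomass signal (OD660 or dry weight)
  is found *algorithmically* — no visual inspection — as the longest
  contiguous window whose log-linear fit satisfies objective criteria,
  followed by trimming of boundary points that fall off the exponential
  trend (lag or stationary-phase values);
* the maximum specific growth rate mu_max [1/h] is the slope of the
  least-squares line through (t, ln signal) inside that window;
* the biomass yield on glucose Y_X/S [g/g] is the slope of biomass against
  consumed glucose over the same window;
* the biomass-specific glucose uptake rate is
  ``q_glucose = -(mu / Y_X/S) * 1000 / M_glucose`` in mmol per gram biomass
  per hour (negative = consumption), with M_glucose = 180.156 g/mol;
* chemostat cultures at dilution rate ``D = F_out / V_L`` grow at mu = D
  once a nutrient-limited steady state is reached, which is asserted from
  the drift of replicate biomass samples;
* replicate cultures are summarized as mean, mean absolute deviation (MAD,
  about the mean) and a pooled standard error across all culture samples,
  computed on log-transformed data for multiplicative-error quantities
  such as rates and back-transformed for reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (DomainError, NoPhaseError, SteadyStateError,
                     ValidationError)

#: molar mass of glucose [g/mol]
M_GLUCOSE = 180.156


@dataclass
class GrowthCurve:
    """A biomass signal over time (hours)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "od"          # "od" (OD660) or "dryweight" (g/L)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError("times and values must be equal-length 1-D")
        if len(self.times) < 2:
            raise ValidationError("a growth curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseWindow:
    """Inclusive index window of the exponential phase."""

    start: int
    stop: int
    r_squared: float
    slope: float

    @property
    def n_points(self) -> int:
        return self.stop - self.start + 1

    def slice(self) -> slice:
        return slice(self.start, self.stop + 1)


@dataclass
class MuFit:
    mu: float
    stderr: float
    r_squared: float
    window: PhaseWindow | None = None


@dataclass
class PhysiologyResult:
    """Per-condition physiology with replicate statistics."""

    mu_max: "ReplicateSummary"
    yield_xs: "ReplicateSummary | None" = None
    q_glucose: "ReplicateSummary | None" = None
    per_replicate: dict = field(default_factory=dict)


@dataclass
class ReplicateSummary:
    mean: float
    mad: float
    pooled_se: float | None = None
    values: tuple[float, ...] = ()

    def __str__(self) -> str:
        return f"{self.mean:.2f}±{self.mad:.2f}"


@dataclass
class ChemostatSettings:
    """Chemostat operating point; D is derived as F_out / V_L."""

    flow_out: float           # F_out [L/h]
    volume: float             # V_L [L]
    feed_glucose: float       # S_in [g/L]

    def __post_init__(self):
        for name in ("flow_out", "volume", "feed_glucose"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def dilution_rate(self) -> float:
        return self.flow_out / self.volume


@dataclass
class ChemostatSample:
    time: float               # h
    biomass: float            # g/L dry weight
    glucose: float            # residual glucose g/L


@dataclass
class ChemostatResult:
    dilution_rate: float
    mu: float
    biomass: float
    residual_glucose: float
    yield_xs: float
    q_glucose: float


# ---------------------------------------------------------------------------
# exponential-phase detection
# ---------------------------------------------------------------------------

def _window_stats(t: np.ndarray, y: np.ndarray, i: int, j: int,
                  pre) -> tuple[float, float]:
    """Slope and R^2 of the log-linear fit on the inclusive window [i, j]."""
    st, st2, sy, sy2, sty = pre
    n = j - i + 1
    S_t = st[j + 1] - st[i]
    S_t2 = st2[j + 1] - st2[i]
    S_y = sy[j + 1] - sy[i]
    S_y2 = sy2[j + 1] - sy2[i]
    S_ty = sty[j + 1] - sty[i]
    sxx = S_t2 - S_t * S_t / n
    sxy = S_ty - S_t * S_y / n
    syy = S_y2 - S_y * S_y / n
    if sxx <= 0:
        return 0.0, 0.0
    slope = sxy / sxx
    if syy <= 0:
        return slope, 0.0
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, min(r2, 1.0)


def detect_exponential_phase(curve: GrowthCurve, *, min_points: int = 5,
                             r2_threshold: float = 0.995,
                             outlier_z: float = 3.0,
                             trim: bool = True) -> PhaseWindow:
    """Objectively locate the exponential phase of a growth curve.

    Stage 1 selects the longest contiguous window whose log-linear fit has
    ``R^2 >= r2_threshold`` and positive slope (ties: higher R^2, then
    earlier start).  Stage 2 removes boundary points whose standardized
    residual against the refitted line exceeds ``outlier_z`` — these are
    values outside the exponential phase (lag or stationary) that a long
    window can absorb without dropping below the R^2 threshold.

    Raises :class:`NoPhaseError` when no window qualifies.
    """
    if min_points < 3:
        raise ValidationError("min_points must be >= 3")
    t = curve.times
    v = curve.values
    if np.any(v <= 0):
        keep = v > 0
        t, v = t[keep], v[keep]
    if len(t) < min_points:
        raise NoPhaseError(
            f"fewer than {min_points} positive values in the curve")
    y = np.log(v)
    pre = (np.concatenate([[0.0], np.cumsum(t)]),
           np.concatenate([[0.0], np.cumsum(t * t)]),
           np.concatenate([[0.0], np.cumsum(y)]),
           np.concatenate([[0.0], np.cumsum(y * y)]),
           np.concatenate([[0.0], np.cumsum(t * y)]))
    n = len(t)
    best: tuple | None = None   # (length, r2, -start, i, j, slope)
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            slope, r2 = _window_stats(t, y, i, j, pre)
            if slope <= 0 or r2 < r2_threshold:
                continue
            cand = (j - i + 1, r2, -i, i, j, slope)
            if best is None or cand[:3] > best[:3]:
                best = cand
    if best is None:
        raise NoPhaseError(
            f"no window of >= {min_points} points reaches "
            f"R^2 >= {r2_threshold} with positive slope")
    _, r2, _, i, j, slope = best
    if trim:
        i, j = _trim_window(t, y, i, j, min_points, outlier_z)
        slope, r2 = _window_stats(t, y, i, j, pre)
    return PhaseWindow(start=i, stop=j, r_squared=r2, slope=slope)


def _trim_window(t, y, i, j, min_points, outlier_z):
    # Residuals are standardized against a robust (median-based) scale so
    # that a run of lag or stationary points absorbed by the base window
    # cannot inflate the scale and mask themselves; the floor keeps
    # machine-noise residuals of noiseless data from registering as
    # outliers.
    while j - i + 1 > min_points:
        tw, yw = t[i:j + 1], y[i:j + 1]
        res = stats.linregress(tw, yw)
        resid = yw - (res.intercept + res.slope * tw)
        scale = 1.4826 * float(np.median(np.abs(resid)))
        scale = max(scale, 1e-9 * max(1.0, float(np.ptp(yw))))
        z_lo, z_hi = abs(resid[0]) / scale, abs(resid[-1]) / scale
        z = max(z_lo, z_hi)
        if z <= outlier_z:
            break
        if z_hi >= z_lo:
            j -= 1
        else:
            i += 1
    return i, j


# ---------------------------------------------------------------------------
# rate / yield estimators
# ---------------------------------------------------------------------------

def fit_mu_max(curve: GrowthCurve, window: PhaseWindow) -> MuFit:
    """Specific growth rate: slope of ln(signal) vs time in the window."""
    sl = window.slice()
    t, v = curve.times[sl], curve.values[sl]
    if len(t) < 2:
        raise ValidationError("mu fit needs at least 2 points")
    if np.any(v <= 0):
        raise ValidationError("log-domain fit requires positive values")
    res = stats.linregress(t, np.log(v))
    r2 = float(res.rvalue ** 2) if not math.isnan(res.rvalue) else 1.0
    stderr = float(res.stderr) if not math.isnan(res.stderr) else 0.0
    return MuFit(mu=float(res.slope), stderr=stderr, r_squared=r2,
                 window=window)


def compute_yield(biomass: GrowthCurve, glucose: GrowthCurve,
                  window: PhaseWindow, *, strict: bool = True) -> float:
    """Biomass yield on glucose: slope of X against consumed glucose.

    Both series must share the time grid over the window, and glucose must
    be decreasing there (it is being consumed): strictly sample-to-sample
    by default, or only in net (last < first) with ``strict=False``, which
    tolerates observation noise on individual samples.
    """
    sl = window.slice()
    if window.n_points < 2:
        raise ValidationError("yield fit needs at least 2 points")
    tx, x = biomass.times[sl], biomass.values[sl]
    ts, s = glucose.times[sl], glucose.values[sl]
    if len(tx) != len(ts) or not np.allclose(tx, ts):
        raise ValidationError(
            "biomass and glucose series must share the time grid")
    decreasing = (not np.any(np.diff(s) >= 0)) if strict else s[-1] < s[0]
    if not decreasing:
        raise DomainError("glucose must be decreasing over the "
                          "exponential window")
    consumed = s[0] - s
    res = stats.linregress(consumed, x)
    y = float(res.slope)
    if not 0 < y <= 1.0:
        warnings.warn(
            f"yield {y:.3f} g/g outside the (0, 1] sanity range for aerobic "
            "growth on glucose", stacklevel=2)
    return y


def compute_q_glucose(mu: float, yield_xs: float) -> float:
    """Biomass-specific glucose uptake rate [mmol / g biomass / h].

    ``q = -(mu / Y_X/S) * 1000 / M_glucose``; negative sign = consumption.
    """
    if yield_xs <= 0:
        raise DomainError(f"yield must be positive, got {yield_xs}")
    return -(mu / yield_xs) * 1000.0 / M_GLUCOSE + 0.0


def chemostat_physiology(settings: ChemostatSettings,
                         samples: Sequence[ChemostatSample], *,
                         drift_tolerance: float = 0.05) -> ChemostatResult:
    """Steady-state chemostat physiology.

    At nutrient-limited steady state the specific growth rate equals the
    dilution rate ``D = F_out / V_L``.  Steady state is asserted when the
    relative spread of the biomass samples is below *drift_tolerance*;
    yield is ``X_bar / (S_in - S_residual_bar)`` and q_glucose follows from
    :func:`compute_q_glucose` at mu = D.
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 steady-state samples")
    x = np.array([s.biomass for s in samples], dtype=float)
    s_res = np.array([s.glucose for s in samples], dtype=float)
    drift = float((x.max() - x.min()) / x.mean())
    if drift > drift_tolerance:
        raise SteadyStateError(
            f"biomass drift {drift:.1%} exceeds tolerance "
            f"{drift_tolerance:.1%}: not at steady state")
    d = settings.dilution_rate
    x_bar = float(x.mean())
    s_bar = float(s_res.mean())
    if s_bar >= settings.feed_glucose:
        raise DomainError("residual glucose >= feed glucose")
    y = x_bar / (settings.feed_glucose - s_bar)
    return ChemostatResult(dilution_rate=d, mu=d, biomass=x_bar,
                           residual_glucose=s_bar, yield_xs=y,
                           q_glucose=compute_q_glucose(d, y))


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

def summarize_replicates(values: Sequence[float],
                         samples: Sequence[Sequence[float]] | None = None,
                         *, multiplicative: bool = False) -> ReplicateSummary:
    """Mean, MAD and pooled standard error of replicate cultures.

    *values* holds one derived value per replicate culture (e.g. mu_max of
    each of two bioreactors); the mean and the mean absolute deviation
    about the mean are computed from these.  *samples*, when given, holds
    the underlying per-culture sample values; the within-replicate sample
    variances are pooled with ``(n_i - 1)`` weights and the standard error
    is ``sqrt(pooled variance / N_total)``.

    For multiplicative-error quantities (rates), the pooling is done on
    log-transformed samples and the standard error is mapped back to the
    linear scale via the delta method (``SE = mean * SE_log``).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("need at least one replicate value")
    mean = float(vals.mean())
    mad = float(np.mean(np.abs(vals - mean)))
    pooled_se = None
    if samples is not None:
        groups = [np.asarray(list(g), dtype=float) for g in samples]
        if any(g.size == 0 for g in groups):
            raise ValidationError("empty sample group")
        if multiplicative:
            if any(np.any(g <= 0) for g in groups):
                raise ValidationError(
                    "log transform requires positive sample values")
            groups = [np.log(g) for g in groups]
        num = sum((g.size - 1) * g.var(ddof=1) for g in groups if g.size > 1)
        den = sum(g.size - 1 for g in groups if g.size > 1)
        n_total = sum(g.size for g in groups)
        if den == 0:
            raise ValidationError(
                "pooled variance needs a group with >= 2 samples")
        pooled_var = num / den
        pooled_se = float(np.sqrt(pooled_var / n_total))
        if multiplicative:
            pooled_se = abs(mean) * pooled_se
    return ReplicateSummary(mean=mean, mad=mad, pooled_se=pooled_se,
                            values=tuple(float(v) for v in vals))


# ---------------------------------------------------------------------------
# table-driven pipeline
# ---------------------------------------------------------------------------

def analyze_batch_table(df, mapping: dict) -> dict:
    """Run the batch-physiology pipeline on a tidy table.

    *mapping* names the relevant columns: ``time``, ``biomass`` (dry weight
    or OD), optional ``glucose``, and optional ``replicate`` (a column that
    distinguishes replicate cultures).  Detection options may be supplied
    under ``detect`` (``min_points``, ``r2_threshold``).  Returns a dict
    with per-replicate fits and a :class:`PhysiologyResult`.
    """
    detect_kw = dict(mapping.get("detect", {}))
    groups = ([(None, df)] if "replicate" not in mapping else
              [(k, g) for k, g in df.groupby(mapping["replicate"], sort=True)])
    per_rep: dict = {}
    mus, yields, qs = [], [], []
    for key, g in groups:
        g = g.sort_values(mapping["time"])
        curve = GrowthCurve(g[mapping["time"]].to_numpy(dtype=float),
                            g[mapping["biomass"]].to_numpy(dtype=float))
        window = detect_exponential_phase(curve, **detect_kw)
        fit = fit_mu_max(curve, window)
        entry = {"mu_max": fit.mu, "mu_stderr": fit.stderr,
                 "window": (window.start, window.stop),
                 "r_squared": window.r_squared}
        mus.append(fit.mu)
        if "glucose" in mapping:
            glc = GrowthCurve(g[mapping["time"]].to_numpy(dtype=float),
                              g[mapping["glucose"]].to_numpy(dtype=float))
            y = compute_yield(curve, glc, window, strict=False)
            q = compute_q_glucose(fit.mu, y)
            entry["yield_xs"] = y
            entry["q_glucose"] = q
            yields.append(y)
            qs.append(q)
        per_rep[key] = entry
    result = PhysiologyResult(
        mu_max=summarize_replicates(mus),
        yield_xs=summarize_replicates(yields) if yields else None,
        q_glucose=summarize_replicates(qs) if qs else None,
        per_replicate=per_rep)
    return {"per_replicate": per_rep, "summary": result}
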