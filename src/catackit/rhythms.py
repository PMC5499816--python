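"""Bioluminescence rhythm analysis: FFT-NLLS cosinor fitting and statistics.

The pipeline mirrors standard luciferase chronobiology practice: discard the
first 24 h of each recording (fresh-luciferin settling) and any light-phase
samples, detrend with a centred 24-h running mean, then fit a multicomponent
cosine model by iterative, coupled fast-Fourier-transform-seeded nonlinear
least squares (FFT-NLLS).  Each iteration seeds a new component at the
dominant spectral peak of the residuals (computed on a linearly interpolated
uniform grid) and jointly refits all components on the native timestamps; a
component is kept only while its amplitude's 95% confidence interval excludes
zero.

Rhythm strength is summarised by the relative amplitude error (RAE): the
ratio of the amplitude's 95% confidence half-width to the amplitude estimate
of the circadian component (period within 15-35 h).  Flies are classified
rhythmic (RAE < 0.7), weakly rhythmic (0.7 <= RAE <= 1) or arrhythmic
(RAE > 1, or no circadian fit at all).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

CIRCADIAN_RANGE = (15.0, 35.0)
RAE_RHYTHMIC = 0.7
RAE_WEAK = 1.0


@dataclass
class LuminescenceTrace:
    """One fly's time-stamped photon counts with light-regime annotation."""

    fly_id: str
    times: np.ndarray
    counts: np.ndarray
    regime: np.ndarray | None = None  # per-sample "LD"/"DD"
    genotype: str = ""
    fit_eligible: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.size != self.counts.size:
            raise ValueError("times and counts differ in length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.regime is None:
            self.regime = np.full(self.times.size, "DD")
        else:
            self.regime = np.asarray(self.regime)

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


@dataclass
class CosineComponent:
    period: float
    amplitude: float
    phase: float
    amplitude_ci95_half_width: float = math.nan
    period_ci95_half_width: float = math.nan

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        self.phase = self.phase % self.period


@dataclass
class RhythmResult:
    fly_id: str = ""
    components: list[CosineComponent] = field(default_factory=list)
    circadian_component: CosineComponent | None = None
    rae: float | None = None
    classification: str = "arrhythmic"
    offset: float = 0.0
    fit_failed: bool = False

    @property
    def circadian_period(self) -> float | None:
        return self.circadian_component.period if self.circadian_component else None


def traces_from_frame(df: pd.DataFrame, genotype: str = "") -> list[LuminescenceTrace]:
    """Split a tidy trace table (fly_id, time_h, counts[, regime]) into traces."""
    traces = []
    for fly_id, g in df.groupby("fly_id", sort=True):
        g = g.sort_values("time_h")
        traces.append(
            LuminescenceTrace(
                fly_id=str(fly_id),
                times=g["time_h"].to_numpy(),
                counts=g["counts"].to_numpy(),
                regime=g["regime"].to_numpy() if "regime" in g else None,
                genotype=genotype,
            )
        )
    return traces


def preprocess(
    trace: LuminescenceTrace,
    exclude_initial_h: float = 24.0,
    dd_only: bool = True,
    min_span_h: float = 48.0,
) -> LuminescenceTrace:
    """Drop the settling head and (optionally) all light-phase samples.

    The exclusion window is measured from the first sample.  Traces left with
    less than *min_span_h* of data are flagged fit-ineligible.
    """
    if trace.times.size == 0:
        return replace(trace, fit_eligible=False)
    keep = trace.times >= trace.times[0] + exclude_initial_h
    if dd_only:
        keep &= trace.regime == "DD"
    out = LuminescenceTrace(
        fly_id=trace.fly_id,
        times=trace.times[keep],
        counts=trace.counts[keep],
        regime=trace.regime[keep],
        genotype=trace.genotype,
    )
    out.fit_eligible = out.span_h >= min_span_h
    return out


def detrend(trace: LuminescenceTrace, window_h: float = 24.0) -> LuminescenceTrace:
    """Subtract a centred running mean of width *window_h* (edge-truncated)."""
    if trace.span_h < window_h:
        raise ValueError("trace shorter than the detrending window")
    t, y = trace.times, trace.counts
    half = window_h / 2.0
    trend = np.empty_like(y)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        trend[i] = y[sel].mean()
    return replace(trace, counts=y - trend)


def _model(params: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    y = np.full_like(t, params[0])
    for j in range(k):
        period, amp, phase = params[1 + 3 * j : 4 + 3 * j]
        y = y + amp * np.cos(2 * np.pi * (t - phase) / period)
    return y


def _spectral_seed(t, resid, existing_periods, period_floor=4.0):
    """Dominant residual spectral peak on an interpolated uniform grid."""
    dt = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    r = np.interp(grid, t, resid)
    r = r - r.mean()
    spec = np.fft.rfft(r)
    freqs = np.fft.rfftfreq(grid.size, d=dt)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    ok = (periods >= period_floor) & (periods <= 2 * (t[-1] - t[0]))
    ok &= np.isfinite(periods)
    for p in existing_periods:
        ok &= np.abs(periods - p) > 0.1 * p
    if not ok.any():
        return None
    k = np.argmax(np.abs(spec) * ok)
    if np.abs(spec[k]) == 0:
        return None
    period = periods[k]
    amp = 2 * np.abs(spec[k]) / grid.size
    phase = (grid[0] + np.angle(spec[k]) * period / (2 * np.pi)) % period
    return (period, amp, phase), int(ok.sum())


def _fit_components(t, y, seeds):
    """Joint NLLS refit of all components; returns params, covariance, dof."""
    k = len(seeds)
    x0 = np.concatenate([[y.mean()], np.ravel(seeds)])
    lo = np.concatenate([[-np.inf], np.tile([2.0, 0.0, -np.inf], k)])
    hi = np.concatenate([[np.inf], np.tile([4 * (t[-1] - t[0]), np.inf, np.inf], k)])
    x0 = np.clip(x0, lo, hi)
    res = optimize.least_squares(
        lambda p: _model(p, t, k) - y, x0, bounds=(lo, hi), method="trf"
    )
    dof = max(t.size - res.x.size, 1)
    s2 = 2 * res.cost / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((res.x.size, res.x.size), np.nan)
    return res, cov, dof


def fft_nlls(
    trace: LuminescenceTrace,
    max_components: int = 4,
    period_range: tuple[float, float] = CIRCADIAN_RANGE,
) -> RhythmResult:
    """Iterative coupled FFT-NLLS multicomponent cosine fit of one trace.

    Expects a preprocessed (and normally detrended) trace spanning >= 48 h.
    Returns an arrhythmic :class:`RhythmResult` when the fit fails or no
    component falls in *period_range*.
    """
    t, y = trace.times, trace.counts
    if not trace.fit_eligible or trace.span_h < 48.0 or t.size < 12:
        return RhythmResult(fly_id=trace.fly_id, fit_failed=True)
    try:
        params = np.array([y.mean()])
        accepted: list[tuple[float, float, float]] = []
        best = None
        for _ in range(max_components):
            resid = y - _model(params, t, len(accepted))
            seeded = _spectral_seed(t, resid, [c[0] for c in accepted])
            if seeded is None:
                break
            seed, n_bins = seeded
            trial = accepted + [seed]
            res, cov, dof = _fit_components(t, y, trial)
            # Amplitude significance of a free-phase cosine is a 2-df
            # (quadrature-pair) test, and the candidate was picked as the best
            # of n_bins spectral bins, so the acceptance bound is an F(2, dof)
            # quantile at a Bonferroni-corrected level.
            alpha = 0.05 / max(n_bins, 1)
            fcrit = stats.f.ppf(1 - alpha, 2, dof)
            new_amp = res.x[1 + 3 * len(accepted) + 1]
            new_se = math.sqrt(max(cov[2 + 3 * len(accepted), 2 + 3 * len(accepted)], 0.0))
            new_amp_hw = math.sqrt(2 * fcrit) * new_se
            if not math.isfinite(new_amp_hw) or new_amp - new_amp_hw <= 0:
                break  # newest component indistinguishable from zero
            accepted = [tuple(res.x[1 + 3 * j : 4 + 3 * j]) for j in range(len(trial))]
            params = res.x
            best = (res, cov, dof)
        if best is None:
            return RhythmResult(fly_id=trace.fly_id, fit_failed=True)
        res, cov, dof = best
        tcrit = stats.t.ppf(0.975, dof)
        components = []
        for j in range(len(accepted)):
            period, amp, phase = res.x[1 + 3 * j : 4 + 3 * j]
            se = np.sqrt(np.clip(np.diag(cov)[1 + 3 * j : 4 + 3 * j], 0.0, None))
            components.append(
                CosineComponent(
                    period=float(period),
                    amplitude=float(amp),
                    phase=float(phase),
                    amplitude_ci95_half_width=float(tcrit * se[1]),
                    period_ci95_half_width=float(tcrit * se[0]),
                )
            )
        components.sort(key=lambda c: -c.amplitude)
        result = RhythmResult(
            fly_id=trace.fly_id, components=components, offset=float(res.x[0])
        )
        in_range = [
            c for c in components if period_range[0] <= c.period <= period_range[1]
        ]
        if in_range:
            circ = max(in_range, key=lambda c: c.amplitude)
            result.circadian_component = circ
            result.rae = relative_amplitude_error(circ)
            result.classification = classify(result.rae)
        return result
    except (ValueError, np.linalg.LinAlgError):
        return RhythmResult(fly_id=trace.fly_id, fit_failed=True)


def relative_amplitude_error(component: CosineComponent) -> float:
    """RAE: amplitude 95% CI half-width over the amplitude estimate."""
    if component.amplitude <= 0:
        return math.inf
    return component.amplitude_ci95_half_width / component.amplitude


def classify(rae: float | None) -> str:
    """Map an RAE value onto rhythmic / weakly_rhythmic / arrhythmic."""
    if rae is None or not math.isfinite(rae) or rae > RAE_WEAK:
        return "arrhythmic"
    if rae < RAE_RHYTHMIC:
        return "rhythmic"
    return "weakly_rhythmic"


def analyze_trace(
    trace: LuminescenceTrace,
    exclude_initial_h: float = 24.0,
    dd_only: bool = True,
    detrend_window_h: float = 24.0,
    max_components: int = 4,
    trim_edges: bool = True,
) -> RhythmResult:
    """Full single-fly pipeline: preprocess, detrend, FFT-NLLS.

    The running-mean trend estimate is biased within half a window of either
    end of the recording (the window is edge-truncated there), which injects
    spurious low-frequency structure; by default those edge samples are
    trimmed before fitting.
    """
    pre = preprocess(trace, exclude_initial_h=exclude_initial_h, dd_only=dd_only)
    if not pre.fit_eligible:
        return RhythmResult(fly_id=trace.fly_id, fit_failed=True)
    det = detrend(pre, window_h=detrend_window_h)
    if trim_edges:
        half = detrend_window_h / 2.0
        keep = (det.times >= det.times[0] + half) & (det.times <= det.times[-1] - half)
        det = LuminescenceTrace(
            fly_id=det.fly_id,
            times=det.times[keep],
            counts=det.counts[keep],
            regime=det.regime[keep],
            genotype=det.genotype,
        )
        if det.span_h < 48.0:
            return RhythmResult(fly_id=trace.fly_id, fit_failed=True)
    return fft_nlls(det, max_components=max_components)


def average_trace(
    traces: list[LuminescenceTrace], detrended: bool = True
) -> tuple[LuminescenceTrace, np.ndarray, RhythmResult]:
    """Pointwise mean trace on a common grid, with its FFT-NLLS overlay.

    Traces are linearly interpolated onto the overlap of their time ranges.
    Returns ``(mean_trace, overlay_counts, fit)`` where the overlay is the
    fitted multicomponent cosine evaluated on the common grid.
    """
    if not traces:
        raise ValueError("no traces to average")
    t0 = max(tr.times[0] for tr in traces)
    t1 = min(tr.times[-1] for tr in traces)
    if t1 <= t0:
        raise ValueError("traces have disjoint time ranges")
    dt = float(np.median([np.median(np.diff(tr.times)) for tr in traces]))
    grid = np.arange(t0, t1 + dt / 2, dt)
    mean_counts = np.mean(
        [np.interp(grid, tr.times, tr.counts) for tr in traces], axis=0
    )
    mean_trace = LuminescenceTrace(
        fly_id="mean", times=grid, counts=mean_counts, genotype=traces[0].genotype
    )
    fit = fft_nlls(mean_trace) if detrended else fft_nlls(detrend(mean_trace))
    k = len(fit.components)
    params = np.concatenate(
        [[fit.offset]]
        + [[c.period, c.amplitude, c.phase] for c in fit.components]
    ) if k else np.array([mean_counts.mean()])
    overlay = _model(params, grid, k)
    return mean_trace, overlay, fit


@dataclass
class GroupSummary:
    n_flies: int
    pct_rhythmic: float
    pct_weakly_rhythmic: float
    pct_arrhythmic: float
    mean_rae: float | None
    sem_rae: float | None
    mean_period: float | None
    sem_period: float | None


def summarize_group(results: list[RhythmResult]) -> GroupSummary:
    """Class percentages plus mean +/- SEM of RAE and circadian period.

    Means are computed over rhythmic and weakly rhythmic flies only, as is
    conventional when arrhythmic fits return no amplitude estimate.
    """
    if not results:
        raise ValueError("no results to summarise")
    n = len(results)
    classes = [r.classification for r in results]
    scored = [r for r in results if r.classification != "arrhythmic"]
    raes = np.array([r.rae for r in scored], dtype=float)
    periods = np.array([r.circadian_period for r in scored], dtype=float)

    def _mean_sem(x):
        if x.size == 0:
            return None, None
        sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
        return float(x.mean()), sem

    mean_rae, sem_rae = _mean_sem(raes)
    mean_period, sem_period = _mean_sem(periods)
    return GroupSummary(
        n_flies=n,
        pct_rhythmic=100.0 * classes.count("rhythmic") / n,
        pct_weakly_rhythmic=100.0 * classes.count("weakly_rhythmic") / n,
        pct_arrhythmic=100.0 * classes.count("arrhythmic") / n,
        mean_rae=mean_rae,
        sem_rae=sem_rae,
        mean_period=mean_period,
        sem_period=sem_period,
    )


def rhythmicity_table(groups: dict[str, list[RhythmResult]]) -> pd.DataFrame:
    """Counts of R/WR/AR per group (rows), for chi-square comparisons."""
    rows = {}
    for name, results in groups.items():
        classes = [r.classification for r in results]
        rows[name] = {
            "rhythmic": classes.count("rhythmic"),
            "weakly_rhythmic": classes.count("weakly_rhythmic"),
            "arrhythmic": classes.count("arrhythmic"),
        }
    return pd.DataFrame(rows).T


def chi_square_classes(
    a: list[RhythmResult], b: list[RhythmResult]
) -> tuple[float, float]:
    """Pairwise chi-square on the 2 x 3 rhythmicity-class table.

    Classes empty in both groups are dropped (with a warning) to keep the
    expected counts well-defined.
    """
    table = rhythmicity_table({"a": a, "b": b}).to_numpy()
    keep = table.sum(axis=0) > 0
    if not keep.all():
        warnings.warn("rhythmicity class absent from both groups; dropped")
        table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum comparison."""
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA F and p."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 1]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    a = ((w * (m - mw) ** 2).sum()) / (k - 1)
    hc = ((1 - w / W) ** 2 / (n - 1)).sum()
    f = a / (1 + 2 * (k - 2) / (k**2 - 1) * hc)
    df2 = (k**2 - 1) / (3 * hc)
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), p


def tamhane_t2(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tamhane's T2 pairwise post-hoc comparisons.

    Unequal-variance (Welch) t statistics with Welch-Satterthwaite degrees of
    freedom and Sidak-adjusted two-sided p-values across all pairs.
    """
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            se = math.sqrt(va + vb)
            tstat = (a.mean() - b.mean()) / se
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            p_raw = 2 * stats.t.sf(abs(tstat), df)
            p_adj = 1 - (1 - min(p_raw, 1.0)) ** m
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "t": tstat,
                    "df": df,
                    "p_raw": p_raw,
                    "p_adj": min(p_adj, 1.0),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(a, b, test: str):
    """Dispatch one of the supported group comparisons.

    ``chi_square`` takes two RhythmResult lists; ``mann_whitney`` two arrays
    of expression levels; ``welch_anova_tamhane`` a dict of named arrays and
    returns (F, p, posthoc table).
    """
    if test == "chi_square":
        return chi_square_classes(a, b)
    if test == "mann_whitney":
        return mann_whitney(np.asarray(a, float), np.asarray(b, float))
    if test == "welch_anova_tamhane":
        groups = dict(a)
        if b:
            groups.update(dict(b))
        f, p = welch_anova(list(groups.values()))
        return f, p, tamhane_t2(groups)
    raise ValueError(f"unknown test {test!r}")


def expression_level(
    traces: list[LuminescenceTrace], at_h: float = 6.0, tolerance_h: float = 1.0
) -> pd.DataFrame:
    """Per-fly raw counts at the sample nearest *at_h* hours after DD onset.

    Flies without a sample within ``tolerance_h`` of the target are excluded
    with a warning.  Returns a frame with fly_id, genotype and level.
    """
    rows = []
    for tr in traces:
        dd = np.nonzero(tr.regime == "DD")[0]
        if dd.size == 0:
            warnings.warn(f"{tr.fly_id}: no DD samples; excluded")
            continue
        target = tr.times[dd[0]] + at_h
        i = int(np.argmin(np.abs(tr.times - target)))
        if abs(tr.times[i] - target) > tolerance_h:
            warnings.warn(f"{tr.fly_id}: no sample within {tolerance_h} h of target")
            continue
        rows.append(
            {"fly_id": tr.fly_id, "genotype": tr.genotype, "level": tr.counts[i]}
        )
    return pd.DataFrame(rows, columns=["fly_id", "genotype", "level"])
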