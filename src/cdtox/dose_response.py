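"""Concentration-dependent reduced-transcriptome (RHT) dose-response engine.

Per-gene log2 fold change against vehicle controls is fitted with nine
concentration-effect models covering three curve types (sigmoidal, linear,
U-shaped).  The lowest-AIC model wins; a gene is a differentially expressed
gene (DEG) when the winner beats the intercept-only null (F-test, p < alpha)
and an effective concentration (EC_DEG) can be extracted from its curve:

* sigmoidal  - concentration at half the asymptotic maximum effect,
* linear     - concentration where |log2 fold change| reaches log2(1.5),
* U-shaped   - the same 1.5-fold crossing restricted to the first monotonic
  portion of the curve (up to the fitted extremum).

The module also implements the cell-viability arithmetic (relative viability
from optical densities) and two-parameter log-logistic ECx fitting.

A note on the significance rule: AIC alone yields no p-value, so model
selection (AIC) and significance (F-test of the winning model against the
intercept-only null) are deliberately separated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "CountMatrix",
    "GeneFit",
    "DegRecord",
    "Model",
    "default_registry",
    "log2_fold_change",
    "fit_gene_models",
    "call_deg",
    "ec_deg",
    "analyze_counts",
    "relative_viability",
    "fit_viability_ecx",
    "FOLD_CHANGE_THRESHOLD",
]

#: 1.5-fold threshold on the log2 scale.
FOLD_CHANGE_THRESHOLD = math.log2(1.5)


# ---------------------------------------------------------------------------
# Count container and fold change
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample count matrix with per-sample concentration metadata.

    ``counts``: DataFrame indexed by gene id, columns sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``concentration`` (mg carbon/L; 0 only for vehicles) and ``is_vehicle``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks entries for {sorted(missing)[:5]}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.samples["is_vehicle"].any():
            raise ValueError("at least one vehicle-control sample is required")
        pos = self.treated_concentrations()
        if len(np.unique(pos)) < 2:
            raise ValueError("at least two distinct positive concentrations required")

    @classmethod
    def from_files(cls, counts_tsv: str, samples_csv: str) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_csv, index_col=0)
        samples = samples.rename(
            columns={"concentration_mg_per_L": "concentration"})
        samples["is_vehicle"] = samples["is_vehicle"].astype(bool)
        return cls(counts, samples.loc[counts.columns])

    def vehicle_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["is_vehicle"]])

    def treated_ids(self) -> list[str]:
        mask = ~self.samples["is_vehicle"]
        order = self.samples.loc[mask, "concentration"].sort_values().index
        return list(order)

    def treated_concentrations(self) -> np.ndarray:
        return self.samples.loc[self.treated_ids(), "concentration"].to_numpy(float)


def log2_fold_change(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-gene log2 fold change at each positive concentration.

    fc(g, c) = log2((x_gc + q) / (mean vehicle x_g + q)) where x are raw
    counts, or counts-per-million when ``normalize`` is on (the default;
    library sizes in this assay span an order of magnitude, and raw-count
    ratios would confound fold change with sequencing depth).
    """
    mat = cm.counts.astype(float)
    if normalize:
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("zero library size; cannot normalize")
        mat = mat.div(lib, axis=1) * 1e6
    veh = mat[cm.vehicle_ids()].mean(axis=1)
    treated = mat[cm.treated_ids()]
    if pseudocount == 0 and ((treated.eq(0).any(axis=1)) & veh.eq(0)).any():
        raise ValueError("all-zero gene with pseudocount=0")
    fc = np.log2(treated.add(pseudocount, axis=0).div(veh + pseudocount, axis=0))
    fc.columns = cm.treated_concentrations()
    return fc


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Model:
    """A parametric concentration-effect form y = f(x; params), x = log10 conc."""

    id: int
    name: str
    curve_type: str  # sigmoidal | linear | u_shaped
    n_params: int
    func: Callable[..., np.ndarray]
    init: Callable[[np.ndarray, np.ndarray], np.ndarray]
    linear_degree: Optional[int] = None  # polynomial models solved exactly
    saturating: bool = False             # horizontal asymptotes on both sides
    extra_inits: Optional[Callable[[np.ndarray, np.ndarray], list]] = None


def _logistic4(x, bottom, top, mid, slope):
    return bottom + (top - bottom) * expit(slope * (x - mid))


def _logistic3(x, top, mid, slope):
    return top * expit(slope * (x - mid))


def _gompertz(x, top, mid, slope):
    with np.errstate(over="ignore"):
        return top * np.exp(-np.exp(np.clip(-slope * (x - mid), -700.0, 700.0)))


def _power(x, a, b):
    # power law in concentration: a * C^b, monotone from 0
    return a * np.power(10.0, b * x)


def _exponential(x, a, b):
    # exponential growth in log10 concentration, anchored at 0 for x -> -inf
    return a * np.expm1(np.clip(b * x, -50.0, 50.0))


def _bell(x, a, m, w):
    # Gaussian bell in log10 concentration: the canonical non-monotone
    # (hormesis-like) dose-response shape.  The width is floored at half a
    # decade: a bump narrower than the dilution-grid spacing would fit a
    # single point, which is noise, not a concentration response.
    w_eff = np.hypot(w, 0.5)
    return a * np.exp(-(((x - m) / w_eff) ** 2))


def _biphasic(x, a1, m1, a2, m2, slope):
    # opposing logistic phases with a shared slope magnitude; five
    # parameters keep the form identifiable on a seven-point design
    return a1 * expit(slope * (x - m1)) - a2 * expit(slope * (x - m2))


def _realized_curve_type(fit: "GeneFit", lo: float, hi: float) -> str:
    """Curve type of the fitted curve itself on the search window.

    The EC rule follows the shape the fitted curve actually takes: a
    U-shaped-family fit whose extremum lies outside the window is monotone
    there, and is treated as sigmoidal when its family saturates
    (horizontal asymptotes) or as linear otherwise.
    """
    if _first_extremum(fit.predict, lo, hi) is not None:
        return "u_shaped"
    if fit.model.curve_type == "sigmoidal" or fit.model.saturating:
        return "sigmoidal"
    return "linear"


def _step_positions(x, y, k=2):
    """Candidate sigmoid midpoints: between the k largest consecutive jumps."""
    order = np.argsort(x)
    jumps = np.abs(np.diff(y[order]))
    mids = (x[order][1:] + x[order][:-1]) / 2.0
    return [float(m) for m in mids[np.argsort(jumps)[::-1][:k]]]


def _sig_starts(x, y):
    """Deterministic starts for the logistic family: a smooth fit through
    the endpoint levels plus steep step-like fits at the largest jumps
    (the global optimum on noisy profiles is often a sharp step)."""
    lo, hi = y[np.argmin(x)], y[np.argmax(x)]
    starts = [np.array([lo, hi if hi != lo else lo + 0.5, float(np.median(x)), 2.0])]
    for m in _step_positions(x, y):
        starts.append(np.array([lo, hi if hi != lo else lo + 0.5, m, 15.0]))
    return starts


def _sig_init(x, y):
    return _sig_starts(x, y)[0]


def _biphasic_inits(x, y):
    """Step-position pairs for the biphasic phases, both phase orders."""
    amp = max(float(np.abs(y).max()), 0.5)
    pos = _step_positions(x, y, k=2)
    if len(pos) < 2:
        return []
    p, q = sorted(pos)
    return [np.array([amp, p, amp, q, 10.0]),
            np.array([-amp, p, -amp, q, 10.0]),
            np.array([amp, q, amp, p, 10.0])]


def _rate_sign_inits(x, y):
    """Both rate signs for power/exponential forms (rising or falling)."""
    a = np.sign(y[np.argmax(x)]) * 0.1 or 0.1
    return [np.array([-a, 0.5]), np.array([a, -0.5]), np.array([-a, -0.5])]


def default_registry() -> list[Model]:
    """The nine default concentration-effect models, three per curve type."""
    return [
        Model(1, "logistic4", "sigmoidal", 4, _logistic4, _sig_init,
              saturating=True, extra_inits=lambda x, y: _sig_starts(x, y)[1:]),
        Model(2, "logistic3", "sigmoidal", 3, _logistic3,
              lambda x, y: np.array([y[np.argmax(x)] or 0.5, float(np.median(x)), 2.0]),
              saturating=True,
              extra_inits=lambda x, y: [np.array([y[np.argmax(x)] or 0.5, m, 15.0])
                                        for m in _step_positions(x, y)]),
        Model(3, "gompertz", "sigmoidal", 3, _gompertz,
              lambda x, y: np.array([y[np.argmax(x)] or 0.5, float(np.median(x)), 2.0]),
              saturating=True,
              extra_inits=lambda x, y: [np.array([y[np.argmax(x)] or 0.5, m, 15.0])
                                        for m in _step_positions(x, y)]),
        Model(4, "linear", "linear", 2, lambda x, a, b: a + b * x,
              lambda x, y: np.array([0.0, 0.0]), linear_degree=1),
        Model(5, "power", "linear", 2, _power,
              lambda x, y: np.array([np.sign(y[np.argmax(x)]) * 0.1 or 0.1, 0.5]),
              extra_inits=_rate_sign_inits),
        Model(6, "exponential", "linear", 2, _exponential,
              lambda x, y: np.array([np.sign(y[np.argmax(x)]) * 0.1 or 0.1, 0.5]),
              extra_inits=_rate_sign_inits),
        Model(7, "quadratic", "u_shaped", 3, lambda x, a, b, c: a + b * x + c * x**2,
              lambda x, y: np.zeros(3), linear_degree=2),
        Model(8, "bell", "u_shaped", 3, _bell,
              lambda x, y: np.array([y[np.argmax(np.abs(y))],
                                     float(x[np.argmax(np.abs(y))]), 1.0])),
        Model(9, "biphasic", "u_shaped", 5, _biphasic,
              lambda x, y: np.array([max(y.max(), 0.5), float(np.quantile(x, 0.25)),
                                     max(y.max(), 0.5), float(np.quantile(x, 0.75)),
                                     2.0]), saturating=True,
              extra_inits=_biphasic_inits),
    ]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    """One model fitted to one gene's fold-change profile."""

    model: Model
    params: np.ndarray
    rss: float
    aic: float
    p_value: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return self.model.func(np.asarray(x, float), *self.params)

    @property
    def curve_type(self) -> str:
        return self.model.curve_type


def _aic(n: int, rss: float, k: int, small_sample: bool = False) -> float:
    """AIC = n ln(RSS/n) + 2k; optionally with the small-sample (AICc)
    correction 2k(k+1)/(n-k-1)."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if small_sample:
        if n - k - 1 <= 0:
            return math.inf
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def _f_test_p(y: np.ndarray, rss: float, k: int) -> float:
    """F-test of a k-parameter fit against the intercept-only null."""
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = k - 1, n - k
    if df2 <= 0 or df1 <= 0:
        return 1.0
    if rss0 <= 1e-12:
        return 1.0  # constant profile: no variance to explain
    if rss <= 1e-12 * rss0:
        return 0.0
    f = ((rss0 - rss) / df1) / (rss / df2)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, df1, df2))


def _fit_one(model: Model, x: np.ndarray, y: np.ndarray,
             rng: np.random.Generator, n_starts: int) -> GeneFit:
    n = len(x)
    if model.linear_degree is not None:
        coef = np.polynomial.polynomial.polyfit(x, y, model.linear_degree)
        pred = np.polynomial.polynomial.polyval(x, coef)
        rss = float(np.sum((y - pred) ** 2))
        params = np.asarray(coef, float)
        return GeneFit(model, params, rss, _aic(n, rss, model.n_params),
                       _f_test_p(y, rss, model.n_params), True)

    best: Optional[tuple[np.ndarray, float]] = None
    p0_base = model.init(x, y)
    starts: list[np.ndarray] = [p0_base]
    if model.extra_inits is not None:
        starts += list(model.extra_inits(x, y))
    while len(starts) < max(n_starts, len(starts)):
        starts.append(p0_base + rng.normal(0, 1.0, size=len(p0_base)))
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    model.func, x, y, p0=p0, method="lm", maxfev=400)
            rss = float(np.sum((y - model.func(x, *popt)) ** 2))
            if np.isfinite(rss) and (best is None or rss < best[1]):
                best = (popt, rss)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return GeneFit(model, np.full(model.n_params, np.nan), np.inf, np.inf, 1.0, False)
    popt, rss = best
    return GeneFit(model, popt, rss, _aic(n, rss, model.n_params),
                   _f_test_p(y, rss, model.n_params), True)


def fit_gene_models(
    fc: Sequence[float],
    log10_conc: Sequence[float],
    registry: Optional[list[Model]] = None,
    seed: int = 0,
    n_starts: int = 3,
) -> list[GeneFit]:
    """Fit all registry models to one gene's fold-change profile.

    Requires at least 5 concentration points.  Non-convergence of an
    individual model yields an infinite-AIC placeholder, not an error.
    """
    x = np.asarray(log10_conc, float)
    y = np.asarray(fc, float)
    if len(x) != len(y):
        raise ValueError("fc and log10_conc must have equal length")
    if len(x) < 5:
        raise ValueError("at least 5 concentration points are required")
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(seed)
    return [_fit_one(m, x, y, rng, n_starts) for m in registry]


# ---------------------------------------------------------------------------
# EC extraction and DEG calling
# ---------------------------------------------------------------------------

@dataclass
class DegRecord:
    """A called DEG: winning fit, effective concentration and metadata."""

    gene: str
    fit: GeneFit
    ec: float
    direction: str  # up | down
    extrapolated: bool

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "model": self.fit.model.name,
            "curve_type": self.fit.curve_type,
            "p_value": self.fit.p_value,
            "aic": self.fit.aic,
            "ec_deg": self.ec,
            "direction": self.direction,
            "extrapolated": self.extrapolated,
        }


def _first_crossing(g: Callable[[np.ndarray], np.ndarray], lo: float, hi: float,
                    n_grid: int = 512) -> Optional[float]:
    """First upward crossing of g through 0 on [lo, hi] (Brent-refined).

    Only rising crossings count: a curve that starts above the threshold
    and dips below it (e.g. the low-concentration divergence of |a + b x|)
    is traversed until the magnitude rises through the threshold again.
    Returns None when no rising crossing lies inside the window.
    """
    xs = np.linspace(lo, hi, n_grid)
    vals = np.asarray(g(xs), float)
    cross = np.nonzero((vals[1:] >= 0) & (vals[:-1] < 0))[0]
    if cross.size == 0:
        return None
    i = int(cross[0]) + 1
    return float(optimize.brentq(lambda t: float(g(np.array([t]))[0]),
                                 xs[i - 1], xs[i], xtol=1e-12, rtol=1e-12))


def _first_extremum(f: Callable[[np.ndarray], np.ndarray], lo: float, hi: float,
                    n_grid: int = 1024, rel_prominence: float = 0.01) -> Optional[float]:
    """First material turning point of f on [lo, hi].

    Flat asymptotes of fitted curves carry numerical wiggles; a reversal
    only counts when the curve retraces more than ``rel_prominence`` of its
    total range after the candidate extremum.
    """
    xs = np.linspace(lo, hi, n_grid)
    vals = np.asarray(f(xs), float)
    rng_ = float(vals.max() - vals.min())
    if rng_ <= 0:
        return None
    tol = rel_prominence * rng_
    direction = 0  # +1 rising, -1 falling
    best_val, best_idx = vals[0], 0
    for i in range(1, n_grid):
        v = vals[i]
        if direction == 0:
            if v - vals[0] > tol:
                direction, best_val, best_idx = +1, v, i
            elif vals[0] - v > tol:
                direction, best_val, best_idx = -1, v, i
        elif direction > 0:
            if v > best_val:
                best_val, best_idx = v, i
            elif best_val - v > tol:
                return float(xs[best_idx])
        else:
            if v < best_val:
                best_val, best_idx = v, i
            elif v - best_val > tol:
                return float(xs[best_idx])
    return None


def ec_deg(
    fit: GeneFit,
    conc_range: tuple[float, float],
    fold_threshold: float = 1.5,
    extrapolate_decades: float = 1.0,
) -> Optional[tuple[float, str, bool]]:
    """Extract EC_DEG (mg carbon/L) from a fitted curve, or None.

    conc_range is the (lowest, highest) tested concentration; the search may
    extend ``extrapolate_decades`` beyond either end, and an EC outside the
    tested range is flagged as extrapolated.
    """
    if not fit.converged:
        return None
    thr = math.log2(fold_threshold)
    x_min, x_max = math.log10(conc_range[0]), math.log10(conc_range[1])
    lo, hi = x_min - extrapolate_decades, x_max + extrapolate_decades
    f = fit.predict
    realized = _realized_curve_type(fit, lo, hi)

    if realized == "sigmoidal":
        y_lo = float(f(np.array([lo - 20.0]))[0])
        y_hi = float(f(np.array([hi + 20.0]))[0])
        effect = y_hi - y_lo
        if abs(effect) < 1e-9:
            return None
        target = y_lo + effect / 2.0
        s = 1.0 if effect > 0 else -1.0
        x_ec = _first_crossing(lambda t: s * (f(t) - target), lo, hi)
    elif realized == "u_shaped":
        # anchored at the lowest tested concentration: polynomial forms
        # diverge below the tested range and have no meaning there
        x_ext = _first_extremum(f, x_min, hi)
        end = x_ext if x_ext is not None else hi
        x_ec = _first_crossing(lambda t: np.abs(f(t)) - thr, x_min, end)
    else:  # linear curve type: monotone, 1.5-fold rule
        x_ec = _first_crossing(lambda t: np.abs(f(t)) - thr, lo, hi)

    if x_ec is None:
        return None
    direction = "up" if float(f(np.array([x_ec]))[0]) > 0 else "down"
    if realized == "sigmoidal":
        # direction of the effect itself (sign of the asymptotic change)
        direction = "up" if (float(f(np.array([hi + 20.0]))[0])
                             - float(f(np.array([lo - 20.0]))[0])) > 0 else "down"
    ec = 10.0 ** x_ec
    extrapolated = not (conc_range[0] <= ec <= conc_range[1])
    return ec, direction, extrapolated


def call_deg(
    gene: str,
    fits: list[GeneFit],
    conc_range: tuple[float, float],
    alpha: float = 0.05,
    fold_threshold: float = 1.5,
    extrapolate_decades: float = 1.0,
) -> Optional[DegRecord]:
    """AIC-select the winning fit; call the gene a DEG if significant with an EC."""
    converged = [f for f in fits if f.converged]
    if not converged:
        return None
    winner = min(converged, key=lambda f: f.aic)
    if winner.p_value >= alpha:
        return None
    res = ec_deg(winner, conc_range, fold_threshold, extrapolate_decades)
    if res is None:
        return None
    ec, direction, extrapolated = res
    return DegRecord(gene, winner, ec, direction, extrapolated)


def analyze_counts(
    cm: CountMatrix,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    normalize: bool = True,
    registry: Optional[list[Model]] = None,
    seed: int = 0,
    n_starts: int = 3,
) -> tuple[list[DegRecord], pd.DataFrame]:
    """Run the full RHT analysis on a count matrix.

    Returns the called DEG records plus a per-gene summary frame (winning
    model, AIC, p-value, EC where defined).
    """
    fc = log2_fold_change(cm, pseudocount=pseudocount, normalize=normalize)
    conc = cm.treated_concentrations()
    x = np.log10(conc)
    conc_range = (float(conc.min()), float(conc.max()))
    degs: list[DegRecord] = []
    rows = []
    for gene, y in fc.iterrows():
        fits = fit_gene_models(y.to_numpy(float), x, registry=registry,
                               seed=seed, n_starts=n_starts)
        rec = call_deg(str(gene), fits, conc_range, alpha=alpha)
        conv = [f for f in fits if f.converged]
        winner = min(conv, key=lambda f: f.aic) if conv else None
        rows.append({
            "gene": gene,
            "model": winner.model.name if winner else None,
            "curve_type": winner.curve_type if winner else None,
            "p_value": winner.p_value if winner else np.nan,
            "aic": winner.aic if winner else np.nan,
            "is_deg": rec is not None,
            "ec_deg": rec.ec if rec else np.nan,
            "direction": rec.direction if rec else None,
            "extrapolated": rec.extrapolated if rec else False,
        })
        if rec is not None:
            degs.append(rec)
    return degs, pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Cell viability
# ---------------------------------------------------------------------------

def relative_viability(od_treated: float, od_control: float, od_blank: float) -> float:
    """Relative cell viability in percent from optical densities.

    100 x (OD_treated - OD_blank) / (OD_control - OD_blank).  May exceed 100
    under growth stimulation.  Affine-invariant in the three ODs.
    """
    denom = od_control - od_blank
    if denom <= 0:
        raise ValueError("OD_control must exceed OD_blank")
    return 100.0 * (od_treated - od_blank) / denom


def fit_viability_ecx(
    conc: Sequence[float],
    viability: Sequence[float],
    x: float = 20.0,
) -> Optional[dict]:
    """Fit v = 100 / (1 + (C/EC50)^h) and solve for the x% effect level.

    Returns ``{"ecx": ..., "ec50": ..., "hill": ...}`` or None when the data
    never reach the x% inhibition level (flagged by the caller as no-ECx).
    """
    c = np.asarray(conc, float)
    v = np.asarray(viability, float)
    mask = c > 0
    if mask.sum() < 4:
        raise ValueError("at least 4 positive concentration points required")
    if v.min() > 100.0 - x:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                lambda cc, ec50, h: 100.0 / (1.0 + (cc / ec50) ** h),
                c[mask], v[mask],
                p0=[float(np.median(c[mask])), 1.0],
                bounds=([1e-12, 0.05], [np.inf, 20.0]), maxfev=10000)
    except (RuntimeError, ValueError):
        return None
    ec50, h = float(popt[0]), float(popt[1])
    ecx = ec50 * (x / (100.0 - x)) ** (1.0 / h)
    return {"ecx": ecx, "ec50": ec50, "hill": h}
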