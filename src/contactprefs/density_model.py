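"""Piecewise 3D densities for contact-atom clouds.

The density over spherical coordinates (r, theta, phi) is piecewise in the
polar angle: non-overlapping theta intervals cover [0, pi], each carrying a
weight, a von Mises factor in theta, a normal factor in r and a mixture of
normal factors over phi sub-intervals. Every 1D factor is renormalized to its
own interval (truncated, not wrapped), so the interval weights carry all
cross-interval mass and the product integrates to one over
[0, R_max] x [0, pi] x [0, 2*pi).

The model deliberately fits the marginal coordinate samples directly, without
a sin(theta) volume Jacobian: "uniform" here means uniform in the coordinates,
matching the 1D histogram treatment used to choose the component structure.

Component structure is chosen by histogram mode detection (sign changes in the
sequence of adjacent bin-height differences), never by EM over free mixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "AzimuthalComponent",
    "PolarComponent",
    "PiecewiseDensity",
    "PiecewiseDensityEstimator",
    "detect_modes",
    "eval_density",
    "log_likelihood",
    "ml_estimates",
]

TWO_PI = 2.0 * np.pi

#: variance floor for degenerate clusters (rad^2 or A^2)
VAR_FLOOR = 1e-4
#: concentration cap (beyond this the von Mises is numerically a point mass)
KAPPA_CAP = 500.0
#: default clamp on the number of histogram modes
MIN_MODES, MAX_MODES = 1, 4

SCHEMA_VERSION = 1


def _vm_pdf(theta, mu, kappa):
    """von Mises density on the full circle, numerically stable in kappa."""
    theta = np.asarray(theta, dtype=float)
    # exp(kappa cos(x)) / (2 pi I0(kappa)) = exp(kappa (cos(x) - 1)) / (2 pi i0e(kappa))
    return np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))


def _vm_interval_mass(lo, hi, mu, kappa, order=64):
    """Gauss-Legendre integral of the full-circle von Mises pdf over [lo, hi]."""
    nodes, wts = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    return float(0.5 * (hi - lo) * np.sum(wts * _vm_pdf(x, mu, kappa)))


def _trunc_norm_factor(lo, hi, mu, var):
    """Normalizing mass of N(mu, var) restricted to [lo, hi]."""
    sd = np.sqrt(var)
    z = stats.norm.cdf(hi, loc=mu, scale=sd) - stats.norm.cdf(lo, loc=mu, scale=sd)
    return float(z)


def a1(kappa):
    """Mean resultant length of a von Mises: A1 = I1(kappa)/I0(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    return special.i1e(kappa) / special.i0e(kappa)


def a1_inv(rbar, kappa_cap=KAPPA_CAP):
    """Solve A1(kappa) = rbar by bracketed root finding (tolerance 1e-8)."""
    if rbar <= 0.0:
        return 0.0
    if a1(kappa_cap) <= rbar:
        return float(kappa_cap)
    return float(optimize.brentq(lambda k: a1(k) - rbar, 1e-12, kappa_cap, xtol=1e-8))


@dataclass
class AzimuthalComponent:
    """One phi sub-interval: truncated normal with an interval-local weight."""

    phi_lo: float
    phi_hi: float
    weight: float
    mu_phi: float
    var_phi: float

    def validate(self):
        if not (0.0 <= self.phi_lo < self.phi_hi <= TWO_PI + 1e-12):
            raise ValueError(f"phi interval [{self.phi_lo}, {self.phi_hi}) outside [0, 2pi)")
        if self.weight < 0:
            raise ValueError("negative azimuthal weight")
        if self.var_phi <= 0:
            raise ValueError("non-positive azimuthal variance")


@dataclass
class PolarComponent:
    """One theta interval: interval-truncated von Mises in theta, truncated
    normal in r, and a phi sub-interval mixture."""

    theta_lo: float
    theta_hi: float
    weight: float
    mu_theta: float
    kappa: float
    mu_r: float
    var_r: float
    azimuthal: list = field(default_factory=list)
    n_obs: int = 0  # records used to estimate this component

    def validate(self):
        if not (0.0 <= self.theta_lo < self.theta_hi <= np.pi + 1e-12):
            raise ValueError(f"theta interval [{self.theta_lo}, {self.theta_hi}] outside [0, pi]")
        if self.weight < 0:
            raise ValueError("negative component weight")
        if self.kappa < 0:
            raise ValueError("negative concentration")
        if self.var_r <= 0:
            raise ValueError("non-positive distance variance")
        wsum = sum(a.weight for a in self.azimuthal)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"azimuthal weights sum to {wsum}, expected 1")
        for a in self.azimuthal:
            a.validate()


@dataclass
class PiecewiseDensity:
    """Fitted piecewise density for one (fragment class, target class) pair."""

    fragment_class: str
    target_class: str
    r_max: float
    components: list
    n_train: int = 0

    def validate(self):
        if not self.components:
            raise ValueError("density has no components")
        comps = sorted(self.components, key=lambda c: c.theta_lo)
        if abs(comps[0].theta_lo) > 1e-9 or abs(comps[-1].theta_hi - np.pi) > 1e-9:
            raise ValueError("polar intervals do not cover [0, pi]")
        for a, b in zip(comps, comps[1:]):
            if abs(a.theta_hi - b.theta_lo) > 1e-9:
                raise ValueError("polar intervals overlap or leave gaps")
        wsum = sum(c.weight for c in self.components)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {wsum}, expected 1")
        for c in self.components:
            c.validate()

    # -- serialization (versioned JSON schema) --------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseDensity":
        d = dict(d)
        d.pop("schema_version", None)
        comps = []
        for c in d.pop("components"):
            c = dict(c)
            c["azimuthal"] = [AzimuthalComponent(**a) for a in c.pop("azimuthal")]
            comps.append(PolarComponent(**c))
        return cls(components=comps, **d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PiecewiseDensity":
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# -- evaluation ---------------------------------------------------------------


def _component_pdf(comp: PolarComponent, r, theta, phi, r_max: float):
    """Vectorized density of one polar component at points inside its interval."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)

    z_vm = _vm_interval_mass(comp.theta_lo, comp.theta_hi, comp.mu_theta, comp.kappa)
    f_theta = _vm_pdf(theta, comp.mu_theta, comp.kappa) / z_vm

    z_r = _trunc_norm_factor(0.0, r_max, comp.mu_r, comp.var_r)
    f_r = stats.norm.pdf(r, loc=comp.mu_r, scale=np.sqrt(comp.var_r)) / z_r

    f_phi = np.zeros_like(phi)
    for az in comp.azimuthal:
        if az.phi_hi >= TWO_PI - 1e-12:
            inside = (phi >= az.phi_lo) & (phi < TWO_PI)
        else:
            inside = (phi >= az.phi_lo) & (phi < az.phi_hi)
        z_phi = _trunc_norm_factor(az.phi_lo, az.phi_hi, az.mu_phi, az.var_phi)
        f_phi = f_phi + inside * az.weight * stats.norm.pdf(
            phi, loc=az.mu_phi, scale=np.sqrt(az.var_phi)
        ) / z_phi

    return comp.weight * f_theta * f_r * f_phi


def eval_density(d: PiecewiseDensity, point) -> float:
    """Density value at a single spherical point (r, theta, phi).

    Zero outside the support r in [0, R_max]. Units A^-1 rad^-2 (no volume
    Jacobian; see module docstring).
    """
    r, theta, phi = np.asarray(point, dtype=float)
    return float(eval_density_many(d, np.array([[r, theta, phi]]))[0])


def eval_density_many(d: PiecewiseDensity, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`eval_density` over an (n, 3) array of (r, theta, phi)."""
    pts = np.asarray(points, dtype=float)
    r, theta, phi = pts[:, 0], pts[:, 1], pts[:, 2]
    out = np.zeros(len(pts))
    support = (r >= 0.0) & (r <= d.r_max)
    comps = sorted(d.components, key=lambda c: c.theta_lo)
    for i, comp in enumerate(comps):
        last = i == len(comps) - 1
        if last:
            sel = (theta >= comp.theta_lo) & (theta <= comp.theta_hi)
        else:
            sel = (theta >= comp.theta_lo) & (theta < comp.theta_hi)
        sel &= support
        if np.any(sel):
            out[sel] = _component_pdf(comp, r[sel], theta[sel], phi[sel], d.r_max)
    return out


def log_likelihood(d: PiecewiseDensity, cloud) -> float:
    """Sum of log density over the records of a cloud.

    Returns -inf (with a warning) when any record has zero density; raises on
    an empty cloud.
    """
    pts = _as_points(cloud)
    if len(pts) == 0:
        raise ValueError("cannot compute the likelihood of an empty cloud")
    vals = eval_density_many(d, pts)
    if np.any(vals <= 0.0):
        warnings.warn("records with zero density; log-likelihood is -inf")
        return float("-inf")
    return float(np.sum(np.log(vals)))


def _as_points(cloud) -> np.ndarray:
    """Accept a TargetCloud-like object (``.to_array()``) or an (n, 3) array."""
    if hasattr(cloud, "to_array"):
        return np.asarray(cloud.to_array(), dtype=float)
    arr = np.asarray(cloud, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of (r, theta, phi)")
    return arr


# -- histogram mode detection --------------------------------------------------


def _count_modes(heights: np.ndarray):
    """Local maxima / minima of a bar sequence via sign changes of adjacent
    differences (plateaus collapse onto the previous sign)."""
    diffs = np.diff(heights)
    maxima, minima = [], []
    sign = 0
    last_rise_end = 0
    for k, dlt in enumerate(diffs):
        s = 0 if dlt == 0 else (1 if dlt > 0 else -1)
        if s == 0:
            continue
        if sign >= 0 and s < 0:
            # peak at the bin where the rise ended
            maxima.append(k if sign > 0 else last_rise_end)
        if sign < 0 and s > 0:
            minima.append(k)
        if s > 0:
            last_rise_end = k + 1
        sign = s
    if sign > 0:
        maxima.append(len(heights) - 1)
    if sign == 0 and len(heights) > 0:
        maxima.append(int(np.argmax(heights)))
    if not maxima:  # monotone decreasing: single leading maximum
        maxima.append(0)
    return maxima, minima


def detect_modes(samples, min_modes=MIN_MODES, max_modes=MAX_MODES, domain=(0.0, np.pi), bins=None):
    """Histogram-based mode count and interval boundaries for angle samples.

    The bin heights are scanned for sign changes of adjacent differences; each
    +/- change is a local maximum. The count is clamped to
    [min_modes, max_modes] by decreasing or increasing the number of bins one
    at a time; if no bin count satisfies the clamp, the ``max_modes`` highest
    maxima are retained. Interval boundaries are the local minima (bin
    centers) between retained maxima.

    Returns ``(n_modes, boundaries)`` where ``boundaries`` is an increasing
    array of interior cut points (empty for one mode). Fewer than 10 samples
    falls back to a single mode spanning the whole domain.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 10:
        return 1, np.array([])
    if bins is None:
        bins = int(np.ceil(np.log2(len(x)))) + 1  # Sturges
    lo, hi = domain

    tried = {}
    b = bins
    for _ in range(max(bins, 64)):
        heights, edges = np.histogram(x, bins=b, range=(lo, hi))
        maxima, minima = _count_modes(heights)
        tried[b] = (maxima, minima, edges)
        if min_modes <= len(maxima) <= max_modes:
            break
        b = b - 1 if len(maxima) > max_modes else b + 1
        if b < 2 or b > 8 * bins:
            b = bins  # give up; clamp by truncation below
            break

    maxima, minima, edges = tried[b]
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(maxima) > max_modes:
        order = np.argsort(np.histogram(x, bins=b, range=(lo, hi))[0][maxima])[::-1]
        maxima = sorted(np.asarray(maxima)[order[:max_modes]])
    n_modes = max(len(maxima), min_modes)
    if len(maxima) <= 1:
        return n_modes, np.array([])

    heights = np.histogram(x, bins=b, range=(lo, hi))[0]
    boundaries = []
    for a, c in zip(maxima, maxima[1:]):
        between = np.arange(a + 1, c)
        if len(between) == 0:
            boundaries.append(0.5 * (centers[a] + centers[c]))
        else:
            boundaries.append(centers[between[np.argmin(heights[between])]])
    return len(maxima), np.asarray(boundaries)


# -- maximum likelihood fitting -------------------------------------------------


def _refine_trunc_vm(theta, lo, hi, mu0, kappa0, kappa_cap):
    """ML of the interval-truncated von Mises.

    The fitted component renormalizes the von Mises to its interval, so the
    correct ML maximizes sum(kappa*cos(t - mu)) - n*log Z(mu, kappa) with
    Z the interval integral; the circular mean/resultant moment estimates are
    only the full-circle solution and are biased when the interval clips the
    density. They are used as the starting point.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    if n < 5 or kappa0 >= kappa_cap or kappa0 <= 0:
        return mu0, kappa0
    nodes, wts = np.polynomial.legendre.leggauss(64)
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * wts

    def nll(params):
        mu, logk = params
        k = np.exp(logk)
        if k > kappa_cap:
            return np.inf
        # log Z with the exp(k*(cos-1)) scaling; the -k*n terms cancel
        z = np.log(np.sum(w * np.exp(k * (np.cos(x - mu) - 1.0))))
        return -(k * np.sum(np.cos(theta - mu) - 1.0)) + n * z

    res = optimize.minimize(nll, x0=[mu0, np.log(kappa0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 500})
    if not res.success:
        return mu0, kappa0
    mu, kappa = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, min(kappa, kappa_cap)


def _interval_masks(values, boundaries, lo, hi):
    """Partition values into the intervals cut by ``boundaries`` within [lo, hi]."""
    cuts = [lo, *np.asarray(boundaries, dtype=float), hi]
    masks = []
    for i, (a, b) in enumerate(zip(cuts, cuts[1:])):
        last = i == len(cuts) - 2
        m = (values >= a) & ((values <= b) if last else (values < b))
        masks.append(((a, b), m))
    return masks


def _merge_sparse(masks, min_count=2):
    """Merge intervals holding fewer than ``min_count`` points into a neighbor."""
    masks = list(masks)
    changed = True
    while changed and len(masks) > 1:
        changed = False
        for i, ((a, b), m) in enumerate(masks):
            if m.sum() < min_count:
                j = i + 1 if i + 1 < len(masks) else i - 1
                (a2, b2), m2 = masks[j]
                merged = ((min(a, a2), max(b, b2)), m | m2)
                masks[min(i, j)] = merged
                del masks[max(i, j)]
                changed = True
                break
    return masks


def _azimuthal_fit(phi, max_modes, var_floor):
    """Fit the phi sub-interval mixture within one polar component."""
    n = len(phi)
    _, cuts = detect_modes(phi, max_modes=max_modes, domain=(0.0, TWO_PI))
    masks = _merge_sparse(_interval_masks(phi, cuts, 0.0, TWO_PI))
    out = []
    for (a, b), m in masks:
        sub = phi[m]
        out.append(
            AzimuthalComponent(
                phi_lo=a,
                phi_hi=b,
                weight=m.sum() / n,
                mu_phi=float(np.mean(sub)),
                var_phi=max(float(np.var(sub)), var_floor),
            )
        )
    return out


def ml_estimates(
    cloud,
    partition=None,
    r_max=None,
    max_modes=MAX_MODES,
    var_floor=VAR_FLOOR,
    kappa_cap=KAPPA_CAP,
    fragment_class="",
    target_class="",
) -> PiecewiseDensity:
    """Marginal maximum-likelihood fit of the piecewise density to a cloud.

    ``partition`` is an optional increasing sequence of interior theta cut
    points; by default it is chosen by :func:`detect_modes` on the polar
    samples. Per polar interval: the weight is the record fraction, the von
    Mises mean and concentration come from the circular mean and resultant
    (``A1(kappa) = Rbar``), the distance mean and variance are sample moments,
    and the azimuthal structure is fitted by mode detection on phi within the
    interval. Intervals with fewer than two records are merged into a
    neighbor.
    """
    pts = _as_points(cloud)
    if len(pts) < 2:
        raise ValueError("need at least two records to fit a density")
    r, theta, phi = pts[:, 0], pts[:, 1], pts[:, 2]
    if r_max is None:
        r_max = getattr(cloud, "r_max", None) or float(np.max(r))

    if partition is None:
        _, partition = detect_modes(theta, max_modes=max_modes, domain=(0.0, np.pi))
    masks = _merge_sparse(_interval_masks(theta, partition, 0.0, np.pi))

    n = len(pts)
    comps = []
    for (a, b), m in masks:
        th, rr, ph = theta[m], r[m], phi[m]
        c_bar, s_bar = float(np.mean(np.cos(th))), float(np.mean(np.sin(th)))
        mu_theta = float(np.arctan2(s_bar, c_bar))
        rbar = float(np.hypot(c_bar, s_bar))
        kappa = a1_inv(rbar, kappa_cap=kappa_cap)
        mu_theta, kappa = _refine_trunc_vm(th, a, b, mu_theta, kappa, kappa_cap)
        comps.append(
            PolarComponent(
                theta_lo=a,
                theta_hi=b,
                weight=m.sum() / n,
                mu_theta=mu_theta,
                kappa=kappa,
                mu_r=float(np.mean(rr)),
                var_r=max(float(np.var(rr)), var_floor),
                azimuthal=_azimuthal_fit(ph, max_modes, var_floor),
                n_obs=int(m.sum()),
            )
        )

    density = PiecewiseDensity(
        fragment_class=fragment_class,
        target_class=target_class,
        r_max=float(r_max),
        components=comps,
        n_train=n,
    )
    density.validate()
    return density


# -- sklearn-style estimator -----------------------------------------------------


class PiecewiseDensityEstimator(BaseEstimator):
    """Fit the piecewise directional density to an (n, 3) array of
    (r, theta, phi) samples.

    Parameters
    ----------
    max_modes : int
        Clamp on the number of histogram modes per angle (default 4).
    r_max : float or None
        Support cutoff; defaults to the largest observed distance.
    var_floor : float
        Variance floor for degenerate clusters (rad^2 or A^2).
    kappa_cap : float
        Upper cap on the von Mises concentration.
    priors : PriorHyper or None
        When given, the fit is a conjugate MAP update of the ML partition
        (see :mod:`contactprefs.bayes_update`) instead of plain ML.

    Attributes
    ----------
    density_ : PiecewiseDensity
        The fitted model.
    """

    def __init__(self, max_modes=MAX_MODES, r_max=None, var_floor=VAR_FLOOR,
                 kappa_cap=KAPPA_CAP, priors=None, fragment_class="", target_class=""):
        self.max_modes = max_modes
        self.r_max = r_max
        self.var_floor = var_floor
        self.kappa_cap = kappa_cap
        self.priors = priors
        self.fragment_class = fragment_class
        self.target_class = target_class

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array of (r, theta, phi)")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if np.any(X[:, 0] < 0):
            raise ValueError("distances must be non-negative")
        density = ml_estimates(
            X,
            r_max=self.r_max,
            max_modes=self.max_modes,
            var_floor=self.var_floor,
            kappa_cap=self.kappa_cap,
            fragment_class=self.fragment_class,
            target_class=self.target_class,
        )
        if self.priors is not None:
            from .bayes_update import update_density

            density = update_density(density, X, self.priors)
        self.density_ = density
        self.n_features_in_ = 3
        return self

    def score_samples(self, X):
        """Log density at each row of X (-inf where the density is zero)."""
        vals = eval_density_many(self.density_, np.asarray(X, dtype=float))
        with np.errstate(divide="ignore"):
            return np.log(vals)

    def score(self, X, y=None):
        """Total log-likelihood of X under the fitted density."""
        return float(np.sum(self.score_samples(X)))
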