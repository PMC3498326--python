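"""Conjugate-prior MAP updating of the piecewise density parameters.

Mean parameters get standard conjugate updates: normal means (distance,
azimuth) are precision-weighted averages of the prior mean and the sample
mean; the von Mises mean direction is the direction of the summed resultant
vector (prior pseudo-resultant plus data unit vectors). The von Mises
concentration is obtained by variance matching: the posterior mean cosine
about the mean direction pools the prior mean-resultant with the data mean
cosine by pseudo-counts, and kappa solves A1(kappa) = pooled value.

Variances are not updated in the Bayesian sense: they keep the marginal ML
estimates, because the data-generation process (refinement constraints,
thermal motion) makes their uncertainty hard to model credibly.

All pooled quantities are linear in counts, so updating with cloud A then
cloud B (carrying the updated hyperparameters forward) equals a single joint
update with A and B together, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .density_model import (
    KAPPA_CAP,
    VAR_FLOOR,
    PiecewiseDensity,
    _as_points,
    _interval_masks,
    a1,
    a1_inv,
)

__all__ = [
    "PriorHyper",
    "map_normal_mean",
    "map_vm_mean",
    "map_vm_concentration",
    "update_density",
]

#: fixed prior variance constant for the distance-mean prior (A^2);
#: the original constant is not recoverable, this default is non-canonical
SIGMA0_SQ_DEFAULT = 0.04


@dataclass
class PriorHyper:
    """Hyperparameters of the conjugate priors for one polar component.

    Mean slots left as None default to the current component values of the
    density being updated (the prior density carries its own modes).
    Pseudo-counts default to zero, which reduces MAP to ML — by convention the
    pseudo-count for a parameter is the number of observations behind its
    prior estimate.
    """

    m0_r: float | None = None  # prior mean of the distance mean (A)
    tau0_r: float = 0.0  # pseudo-count for the distance mean
    m0_phi: float | None = None  # prior mean of the azimuthal mean (rad)
    tau0_phi: float | list = 0.0  # pseudo-count(s) for the azimuthal mean(s)
    mu0_theta: float | None = None  # prior von Mises mean direction (rad)
    c0_theta: float = 0.0  # pseudo-resultant length for the direction
    R0: float | None = None  # prior mean resultant for the concentration
    c_kappa: float = 0.0  # pseudo-count for the concentration
    sigma0_sq: float = SIGMA0_SQ_DEFAULT  # fixed prior variance constant (A^2)

    def __post_init__(self):
        for name in ("tau0_r", "tau0_phi", "c0_theta", "c_kappa"):
            val = getattr(self, name)
            vals = val if isinstance(val, (list, tuple)) else [val]
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-negative")
        if self.R0 is not None and not (0.0 <= self.R0 <= 1.0):
            raise ValueError("R0 must lie in [0, 1]")


def map_normal_mean(samples, m0: float, tau0: float, var: float) -> float:
    """Conjugate posterior mode of a normal mean with known variance:
    (tau0*m0 + n*mean) / (tau0 + n)."""
    if var <= 0:
        raise ValueError("known variance must be positive")
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if tau0 + n == 0:
        raise ValueError("no data and zero prior pseudo-count")
    if n == 0:
        return float(m0)
    return float((tau0 * m0 + n * np.mean(x)) / (tau0 + n))


def map_vm_mean(angles, mu0: float, c0: float):
    """MAP direction of a von Mises mean: direction of
    c0*(cos mu0, sin mu0) + sum_k (cos a_k, sin a_k).

    Returns ``(direction, resultant_length, degenerate)``; a zero resultant
    returns mu0 with the degeneracy flag set.
    """
    x = np.asarray(angles, dtype=float)
    cx = c0 * np.cos(mu0) + np.sum(np.cos(x))
    sx = c0 * np.sin(mu0) + np.sum(np.sin(x))
    rlen = float(np.hypot(cx, sx))
    if rlen < 1e-12:
        return float(mu0), 0.0, True
    return float(np.arctan2(sx, cx)), rlen, False


def map_vm_concentration(angles, R0: float, c_kappa: float, mu: float,
                         kappa_cap: float = KAPPA_CAP):
    """Concentration by variance matching with a Bessel-form conjugate prior.

    The data enter through the mean cosine about the mean direction ``mu``;
    the prior through the pseudo-resultant ``R0`` with weight ``c_kappa``:

        Rbar_post = (c_kappa*R0 + n*mean(cos(a - mu))) / (c_kappa + n)

    and kappa solves A1(kappa) = Rbar_post (bracketed root finding, 1e-8).
    Rbar_post >= 1 returns the cap with a flag; returns ``(kappa, capped)``.
    """
    x = np.asarray(angles, dtype=float)
    n = len(x)
    if n == 0 and c_kappa == 0:
        raise ValueError("no data and zero prior pseudo-count for kappa")
    data_c = float(np.mean(np.cos(x - mu))) if n else 0.0
    rbar = (c_kappa * R0 + n * data_c) / (c_kappa + n)
    if rbar >= a1(kappa_cap):
        return float(kappa_cap), True
    return a1_inv(max(rbar, 0.0), kappa_cap=kappa_cap), False


def _phi_masks(phis, azimuthal):
    """Assign phi samples to the azimuthal sub-intervals of a component."""
    cuts = [az.phi_lo for az in azimuthal[1:]]
    lo = azimuthal[0].phi_lo
    hi = azimuthal[-1].phi_hi
    return [m for _, m in _interval_masks(phis, cuts, lo, hi)]


def update_density(d: PiecewiseDensity, cloud, priors) -> PiecewiseDensity:
    """Conjugate MAP update of every mean/concentration parameter of ``d``.

    ``priors`` is one :class:`PriorHyper` applied to every polar component, or
    a list with one entry per component (sorted by theta_lo). Prior means left
    as None default to the component's current values, so ``d`` itself acts as
    the prior mode. Variances are replaced by marginal ML estimates on the new
    cloud (kept when the cloud contributes fewer than two points to the
    component); component weights are re-estimated from counts when the cloud
    is non-empty.

    The returned density carries ``posterior_hyper_`` — per-component
    :class:`PriorHyper` with pooled pseudo-counts — so that sequential updates
    exactly reproduce a joint update.
    """
    pts = _as_points(cloud)
    frag = getattr(cloud, "fragment_class", None)
    targ = getattr(cloud, "target_class", None)
    if frag and d.fragment_class and frag != d.fragment_class:
        raise ValueError(f"cloud fragment class {frag} != density {d.fragment_class}")
    if targ and d.target_class and targ != d.target_class:
        raise ValueError(f"cloud target class {targ} != density {d.target_class}")

    comps = sorted(d.components, key=lambda c: c.theta_lo)
    if isinstance(priors, PriorHyper):
        priors = [priors] * len(comps)
    if len(priors) != len(comps):
        raise ValueError("one PriorHyper required per polar component")

    r, theta, phi = (pts[:, 0], pts[:, 1], pts[:, 2]) if len(pts) else (np.array([]),) * 3
    cuts = [c.theta_hi for c in comps[:-1]]
    masks = [m for _, m in _interval_masks(theta, cuts, 0.0, np.pi)] if len(pts) else [
        np.array([], dtype=bool)
    ] * len(comps)

    new_comps, new_hyper = [], []
    n_total = len(pts)
    for comp, hyper, m in zip(comps, priors, masks):
        th, rr, ph = theta[m], r[m], phi[m]
        n = len(th)

        m0_r = comp.mu_r if hyper.m0_r is None else hyper.m0_r
        mu0_theta = comp.mu_theta if hyper.mu0_theta is None else hyper.mu0_theta
        R0 = float(a1(comp.kappa)) if hyper.R0 is None else hyper.R0

        if hyper.tau0_r + n > 0:
            mu_r = map_normal_mean(rr, m0_r, hyper.tau0_r, hyper.sigma0_sq)
        else:
            mu_r = m0_r
        mu_theta, c_post, _ = map_vm_mean(th, mu0_theta, hyper.c0_theta)
        kappa, _ = map_vm_concentration(th, R0, hyper.c_kappa, mu_theta)

        var_r = max(float(np.var(rr)), VAR_FLOOR) if n >= 2 else comp.var_r
        weight = n / n_total if n_total else comp.weight

        new_az = []
        if n:
            ph_masks = _phi_masks(ph, comp.azimuthal)
        else:
            ph_masks = [np.array([], dtype=bool)] * len(comp.azimuthal)
        if isinstance(hyper.tau0_phi, (list, tuple)):
            tau_phi = list(hyper.tau0_phi)
        else:
            tau_phi = [hyper.tau0_phi] * len(comp.azimuthal)
        tau_phi_post = []
        for az, pm, tau0 in zip(comp.azimuthal, ph_masks, tau_phi):
            sub = ph[pm] if n else np.array([])
            k = len(sub)
            m0_phi = az.mu_phi if hyper.m0_phi is None else hyper.m0_phi
            if tau0 + k > 0:
                mu_phi = map_normal_mean(sub, m0_phi, tau0, hyper.sigma0_sq)
            else:
                mu_phi = m0_phi
            var_phi = max(float(np.var(sub)), VAR_FLOOR) if k >= 2 else az.var_phi
            w_phi = k / n if n else az.weight
            tau_phi_post.append(tau0 + k)
            new_az.append(replace(az, weight=w_phi, mu_phi=mu_phi, var_phi=var_phi))
        if n and sum(a.weight for a in new_az) == 0:
            new_az = [replace(a, weight=az0.weight) for a, az0 in zip(new_az, comp.azimuthal)]

        new_comps.append(
            replace(
                comp,
                weight=weight,
                mu_theta=mu_theta,
                kappa=kappa,
                mu_r=mu_r,
                var_r=var_r,
                azimuthal=new_az,
                n_obs=comp.n_obs + n,
            )
        )
        # pooled hyperparameters: sequential updating == joint updating
        data_c = float(np.mean(np.cos(th - mu_theta))) if n else 0.0
        new_hyper.append(
            replace(
                hyper,
                m0_r=mu_r,
                tau0_r=hyper.tau0_r + n,
                m0_phi=None,
                tau0_phi=tau_phi_post,
                mu0_theta=mu_theta,
                c0_theta=c_post,
                R0=(hyper.c_kappa * R0 + n * data_c) / (hyper.c_kappa + n)
                if (hyper.c_kappa + n) > 0
                else R0,
                c_kappa=hyper.c_kappa + n,
            )
        )

    if n_total:
        wsum = sum(c.weight for c in new_comps)
        if wsum == 0:
            raise ValueError("cloud contributes no records to any component")
        new_comps = [replace(c, weight=c.weight / wsum) for c in new_comps]

    out = PiecewiseDensity(
        fragment_class=d.fragment_class,
        target_class=d.target_class,
        r_max=d.r_max,
        components=new_comps,
        n_train=d.n_train + n_total,
    )
    out.validate()
    out.posterior_hyper_ = new_hyper
    return out
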