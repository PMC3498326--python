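"""Seeded generators for clouds, densities and fixture PDB files.

These make every stage of the pipeline testable without touching external
structure archives: target clouds drawn from known density parameters close
the loop on estimation (generate -> fit -> recover), and fixture PDB files
with planted contacts close the loop on extraction (plant -> write -> parse ->
reproduce the manifest).

The generators are deliberately idealized: coordinates are exact, B-factors
constant, occupancies one. They emulate the statistical structure of contact
clouds (directional clustering around preferred approach geometries), not
crystallographic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .density_model import (
    AzimuthalComponent,
    PiecewiseDensity,
    PolarComponent,
    _vm_pdf,
)
from .fragments import ContactRecord, TargetCloud
from .frames import build_frame, from_spherical, to_spherical
from scipy import stats

__all__ = [
    "AzimuthalSpec",
    "ComponentSpec",
    "CloudSpec",
    "gen_cloud",
    "spec_density",
    "gen_random_density",
    "gen_fixture_pdb",
    "FRAGMENT_EXEMPLARS",
]

TWO_PI = 2.0 * np.pi


@dataclass
class AzimuthalSpec:
    weight: float
    mu_phi: float
    var_phi: float
    phi_lo: float = 0.0
    phi_hi: float = TWO_PI


@dataclass
class ComponentSpec:
    weight: float
    mu_theta: float
    kappa: float
    mu_r: float
    var_r: float
    theta_lo: float = 0.0
    theta_hi: float = np.pi
    azimuthal: list = field(default_factory=list)

    def __post_init__(self):
        if not self.azimuthal:
            self.azimuthal = [AzimuthalSpec(1.0, np.pi, 1.0)]


@dataclass
class CloudSpec:
    """Ground-truth parameters for a synthetic target cloud."""

    components: list
    r_max: float
    n: int
    seed: int
    fragment_class: str = "f2"
    target_class: str = "C14"

    def __post_init__(self):
        wsum = sum(c.weight for c in self.components)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {wsum}, expected 1")
        for c in self.components:
            if c.var_r <= 0 or any(a.var_phi <= 0 for a in c.azimuthal):
                raise ValueError("variances must be positive")
            if abs(sum(a.weight for a in c.azimuthal) - 1.0) > 1e-9:
                raise ValueError("azimuthal weights must sum to 1")

    @classmethod
    def from_yaml(cls, source) -> "CloudSpec":
        d = yaml.safe_load(source if isinstance(source, str) else source.read())
        comps = []
        for c in d.pop("components"):
            az = [AzimuthalSpec(**a) for a in c.pop("azimuthal", [])]
            comps.append(ComponentSpec(azimuthal=az, **c))
        return cls(components=comps, **d)


def _sample_trunc_vm(rng, mu, kappa, lo, hi, size):
    """Inverse-CDF sampling of an interval-truncated von Mises on a fine grid."""
    grid = np.linspace(lo, hi, 4097)
    pdf = _vm_pdf(grid, mu, kappa)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    u = rng.uniform(size=size)
    return np.interp(u, cdf, grid)


def _sample_trunc_norm(rng, mu, var, lo, hi, size):
    sd = np.sqrt(var)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                               random_state=np.random.RandomState(rng.integers(2**31)))


def gen_cloud(spec: CloudSpec) -> TargetCloud:
    """Draw a synthetic target cloud from the spec's ground-truth density.

    Each sample picks a polar component by weight, draws theta from the
    interval-truncated von Mises, phi from a weighted truncated-normal
    sub-component and r from the [0, R_max]-truncated normal. Deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    counts = rng.multinomial(spec.n, weights)
    records = []
    for comp, k in zip(spec.components, counts):
        if k == 0:
            continue
        theta = _sample_trunc_vm(rng, comp.mu_theta, comp.kappa, comp.theta_lo,
                                 comp.theta_hi, k)
        r = _sample_trunc_norm(rng, comp.mu_r, comp.var_r, 0.0, spec.r_max, k)
        az_w = np.array([a.weight for a in comp.azimuthal])
        az_idx = rng.choice(len(comp.azimuthal), size=k, p=az_w)
        phi = np.empty(k)
        for j, az in enumerate(comp.azimuthal):
            m = az_idx == j
            if m.any():
                phi[m] = _sample_trunc_norm(rng, az.mu_phi, az.var_phi, az.phi_lo,
                                            az.phi_hi, int(m.sum()))
        for rr, tt, pp in zip(r, theta, phi):
            records.append(
                ContactRecord(
                    fragment_class=spec.fragment_class,
                    target_class=spec.target_class,
                    r=float(rr), theta=float(tt), phi=float(pp),
                    source_id="synthetic",
                )
            )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return TargetCloud(fragment_class=spec.fragment_class,
                       target_class=spec.target_class,
                       records=records, r_max=spec.r_max)


def spec_density(spec: CloudSpec) -> PiecewiseDensity:
    """The exact density a :class:`CloudSpec` samples from (the ground truth
    the fitted estimates are compared against)."""
    comps = []
    for c in spec.components:
        az = [AzimuthalComponent(a.phi_lo, a.phi_hi, a.weight, a.mu_phi, a.var_phi)
              for a in c.azimuthal]
        comps.append(PolarComponent(c.theta_lo, c.theta_hi, c.weight, c.mu_theta,
                                    c.kappa, c.mu_r, c.var_r, azimuthal=az))
    d = PiecewiseDensity(fragment_class=spec.fragment_class,
                         target_class=spec.target_class,
                         r_max=spec.r_max, components=comps, n_train=0)
    d.validate()
    return d


def gen_random_density(rng: np.random.Generator, max_components: int = 3,
                       max_azimuthal: int = 3) -> PiecewiseDensity:
    """A random valid :class:`PiecewiseDensity` with moderate concentrations,
    for normalization and integration property tests."""
    n_comp = int(rng.integers(1, max_components + 1))
    cuts = np.sort(rng.uniform(0.15, np.pi - 0.15, size=n_comp - 1))
    edges = np.concatenate([[0.0], cuts, [np.pi]])
    weights = rng.dirichlet(np.ones(n_comp) * 2.0)
    r_max = float(rng.uniform(3.5, 5.0))
    comps = []
    for i in range(n_comp):
        lo, hi = float(edges[i]), float(edges[i + 1])
        n_az = int(rng.integers(1, max_azimuthal + 1))
        az_cuts = np.sort(rng.uniform(0.3, TWO_PI - 0.3, size=n_az - 1))
        az_edges = np.concatenate([[0.0], az_cuts, [TWO_PI]])
        az_w = rng.dirichlet(np.ones(n_az) * 2.0)
        azs = [
            AzimuthalComponent(
                phi_lo=float(az_edges[j]),
                phi_hi=float(az_edges[j + 1]),
                weight=float(az_w[j]),
                mu_phi=float(rng.uniform(az_edges[j], az_edges[j + 1])),
                var_phi=float(rng.uniform(0.05, 1.0)),
            )
            for j in range(n_az)
        ]
        comps.append(
            PolarComponent(
                theta_lo=lo,
                theta_hi=hi,
                weight=float(weights[i]),
                mu_theta=float(rng.uniform(lo, hi)),
                kappa=float(rng.uniform(0.2, 30.0)),
                mu_r=float(rng.uniform(1.8, r_max - 0.5)),
                var_r=float(rng.uniform(0.02, 0.3)),
                azimuthal=azs,
            )
        )
    d = PiecewiseDensity(fragment_class="fX", target_class="CX", r_max=r_max,
                         components=comps)
    d.validate()
    return d


# -- fixture PDB files -----------------------------------------------------------

# Exemplar ligand geometries in the canonical pose (Main at origin, Atom1 on
# -z, Atom2 in the y=0, x<0 half-plane). Classes with a unique Atom2 choice,
# so the planted manifest maps one-to-one onto extracted records.
FRAGMENT_EXEMPLARS = {
    # hydroxyl O on an sp3 carbon: O-C(-C) chain, ethanol-like heavy atoms
    "f2": {
        "main": ("O", "O1", np.array([0.0, 0.0, 0.0])),
        "atom1": ("C", "C1", np.array([0.0, 0.0, -1.43])),
        "atom2": ("C", "C2", np.array([-1.4424, 0.0, -1.9406])),
    },
    # primary amino N on an sp3 carbon: N-C(-C), ethylamine-like
    "f26": {
        "main": ("N", "N1", np.array([0.0, 0.0, 0.0])),
        "atom1": ("C", "C1", np.array([0.0, 0.0, -1.47])),
        "atom2": ("C", "C2", np.array([-1.4424, 0.0, -1.9806])),
    },
}

# target class -> (residue, planted atom name, trailing stub atom names);
# stub atoms are placed radially outward so only the planted atom is in range
_TARGET_STUBS = {
    "C3": ("ALA", "CB", ["CA", "N", "C", "O"]),
    "C4": ("GLY", "CA", ["N", "C", "O"]),
    "C5": ("PHE", "CD1", ["CG", "CB", "CA", "N", "C", "O"]),
    "C6": ("MET", "SD", ["CG", "CB", "CA", "N", "C", "O"]),
    "C7": ("CYS", "SG", ["CB", "CA", "N", "C", "O"]),
    "C8": ("ASN", "ND2", ["CG", "CB", "CA", "N", "C", "O"]),
    "C9": ("HIS", "NE2", ["CD2", "CG", "CB", "CA", "N", "C", "O"]),
    "C10": ("LYS", "NZ", ["CE", "CD", "CG", "CB", "CA", "N", "C", "O"]),
    "C11": ("ASN", "OD1", ["CG", "CB", "CA", "N", "C", "O"]),
    "C12": ("ASP", "OD1", ["CG", "CB", "CA", "N", "C", "O"]),
    "C13": ("SER", "OG", ["CB", "CA", "N", "C", "O"]),
    "C14": ("GLY", "O", ["C", "CA", "N"]),
    "C15": ("GLY", "N", ["CA", "C", "O"]),
}

_PDB_ATOM = (
    "{kind:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}\n"
)


def _pdb_line(kind, serial, name, resname, chain, resseq, pos, element):
    name_fmt = f" {name:<3}" if len(name) < 4 else name
    return _PDB_ATOM.format(
        kind=kind, serial=serial, name=name_fmt, altloc="", resname=resname,
        chain=chain, resseq=resseq, icode="", x=pos[0], y=pos[1], z=pos[2],
        occ=1.0, b=20.0, element=element,
    )


def _rigid_transform(rng):
    """A uniformly random proper rotation (QR of a Gaussian matrix) and a
    bounded random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def gen_fixture_pdb(fragment_class: str, planted, rng=None, resolution: float = 1.8,
                    r_cutoff_warn: float = 4.0) -> tuple:
    """Write a fixture PDB text with a ligand bearing the fragment and protein
    stub atoms at exactly the planted model-frame positions.

    ``planted`` is a list of ``(target_class, (r, theta, phi))`` tuples. When
    ``rng`` is given, the whole scene is rigidly rotated and translated before
    writing — the extracted spherical coordinates are invariant under this.

    Returns ``(pdb_text, manifest)`` where ``manifest`` is a dict with the
    expected contact records (``fragment_class``, ``target_class``, ``r``,
    ``theta``, ``phi``) and ``warnings`` for plants beyond the collection
    cutoff.
    """
    if fragment_class not in FRAGMENT_EXEMPLARS:
        raise ValueError(
            f"no exemplar geometry for {fragment_class!r}; available: "
            f"{sorted(FRAGMENT_EXEMPLARS)}"
        )
    ex = FRAGMENT_EXEMPLARS[fragment_class]
    if rng is not None:
        rot, trans = _rigid_transform(rng)
    else:
        rot, trans = np.eye(3), np.zeros(3)
    # round to the PDB coordinate precision (0.001 A) at placement time, so
    # the manifest is computed from exactly the coordinates that get written
    place = lambda p: np.round(rot @ p + trans, 3)

    lig = [(el, name, place(pos)) for el, name, pos in
           (ex["main"], ex["atom1"], ex["atom2"])]
    main_w = lig[0][2]
    written_frame = build_frame(lig[0][2], lig[1][2], lig[2][2])

    expected, warnings_list = [], []
    residues = []
    for k, (target_class, sph) in enumerate(planted):
        if target_class not in _TARGET_STUBS:
            raise ValueError(f"no residue stub for target class {target_class!r}")
        resname, atom_name, stub_names = _TARGET_STUBS[target_class]
        r, theta, phi = sph
        if r > r_cutoff_warn:
            warnings_list.append(
                f"planted {target_class} at r={r:.2f} A beyond collection cutoff"
            )
        pos_w = place(from_spherical(sph))
        u = pos_w - main_w
        u /= np.linalg.norm(u)
        atoms = [(atom_name, pos_w)]
        for j, nm in enumerate(stub_names, start=1):
            atoms.append((nm, np.round(pos_w + u * 1.6 * j, 3)))
        residues.append((resname, 10 + k, atoms))
        r_w, theta_w, phi_w = to_spherical(written_frame.apply(pos_w))
        expected.append(
            {"fragment_class": fragment_class, "target_class": target_class,
             "r": float(r_w), "theta": float(theta_w), "phi": float(phi_w)}
        )

    lines = [
        "HEADER    SYNTHETIC FIXTURE\n",
        f"REMARK   2 RESOLUTION. {resolution:5.2f} ANGSTROMS.\n",
    ]
    serial = 1
    for resname, resseq, atoms in residues:
        for nm, pos in atoms:
            lines.append(_pdb_line("ATOM", serial, nm, resname, "A", resseq, pos,
                                   nm.lstrip("0123456789")[0]))
            serial += 1
    for el, nm, pos in lig:
        lines.append(_pdb_line("HETATM", serial, nm, "LIG", "B", 900, pos, el))
        serial += 1
    lines.append("END\n")

    manifest = {"fragment_class": fragment_class, "expected": expected,
                "warnings": warnings_list}
    return "".join(lines), manifest
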