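"""Chemistry-based supervision weights and prior-probability tables.

Raw probability masses would let a rarely observed contact type outrank a
common one inside the small region where its few observations happen to sit.
To keep contact types comparable, masses are multiplied by prior weights that
encode how chemically plausible each (fragment, target) pairing is. The
weight has a Coulomb form: the product of element-level partial-charge
surrogates over the squared mean contact distance.

The partial-charge surrogate combines Pauling electronegativity with element
softness. Softness of an element X in the group
G = {C, N, O, S, F, CL, BR, I} is defined as twice the G-mean of absolute
hardness minus the hardness of X (hardness constants packaged from
Parr & Pearson). The packaged prior table is the default source of prior
probabilities; the computed route exists for experimentation but has no
published ground truth because the surrogate mapping and the training-set
mean distances are free choices.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_G",
    "element_chemistry",
    "softness",
    "partial_charge",
    "coulomb_weight",
    "normalize_priors",
    "load_prior_table",
    "PriorTable",
]

GROUP_G = ("C", "N", "O", "S", "F", "CL", "BR", "I")

TARGET_CLASSES = tuple(f"C{i}" for i in range(3, 16))


def _data_path(name: str):
    return resources.files("contactprefs.data").joinpath(name)


def element_chemistry() -> pd.DataFrame:
    """Packaged hardness (eV) and electronegativity constants, indexed by
    element symbol, with derived softness."""
    with resources.as_file(_data_path("hardness_electronegativity.csv")) as p:
        df = pd.read_csv(p, comment="#")
    df["element"] = df["element"].str.upper()
    df = df.set_index("element")
    mean_hard = df.loc[list(GROUP_G), "hardness_ev"].mean()
    df["softness_ev"] = 2.0 * mean_hard - df["hardness_ev"]
    return df


def softness(element: str) -> float:
    """Softness (eV): twice the G-mean hardness minus the element's hardness."""
    element = element.upper()
    if element not in GROUP_G:
        raise ValueError(f"element {element!r} is not in group G {GROUP_G}")
    return float(element_chemistry().loc[element, "softness_ev"])


def partial_charge(element: str) -> float:
    """Default partial-charge surrogate: centered electronegativity scaled by
    relative softness, (chi - chi_G_mean) * S / S_G_mean.

    This mapping is a package design choice (config-replaceable); it is why
    the packaged table, not the computed route, is the default prior source.
    """
    element = element.upper()
    if element not in GROUP_G:
        raise ValueError(f"element {element!r} is not in group G {GROUP_G}")
    chem = element_chemistry().loc[list(GROUP_G)]
    chi = chem.loc[element, "electronegativity"]
    s = chem.loc[element, "softness_ev"]
    return float((chi - chem["electronegativity"].mean()) * s / chem["softness_ev"].mean())


def coulomb_weight(delta_f: float, delta_t: float, mean_dist: float) -> float:
    """Coulomb-form supervision weight |delta_f * delta_t| / mean_dist**2."""
    if mean_dist <= 0:
        raise ValueError("mean distance must be positive")
    return abs(delta_f * delta_t) / mean_dist**2


def normalize_priors(weights) -> np.ndarray:
    """Normalize one fragment's raw weights over the 13 target classes so the
    row sums to one; order preserved."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight row cannot be normalized")
    return w / total


class PriorTable:
    """Prior probabilities indexed (fragment class, target class)."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in TARGET_CLASSES if c not in table.columns]
        if missing:
            raise ValueError(f"prior table misses target classes {missing}")
        bad = table[(table[list(TARGET_CLASSES)] < 0).any(axis=1)
                    | (table[list(TARGET_CLASSES)] > 1).any(axis=1)]
        if len(bad):
            raise ValueError("prior probabilities must lie in [0, 1]")
        sums = table[list(TARGET_CLASSES)].sum(axis=1)
        off = sums[(sums - 1.0).abs() > 0.005]
        if len(off):
            raise ValueError(f"fragment rows do not sum to 1 within 0.005: {dict(off)}")
        self.table = table[list(TARGET_CLASSES)].copy()

    def __getitem__(self, key):
        frag, targ = key
        if frag not in self.table.index:
            raise KeyError(f"no prior row for fragment class {frag!r}")
        return float(self.table.loc[frag, targ])

    def row(self, fragment_class: str) -> pd.Series:
        if fragment_class not in self.table.index:
            raise KeyError(f"no prior row for fragment class {fragment_class!r}")
        return self.table.loc[fragment_class]

    @property
    def fragment_classes(self):
        return list(self.table.index)


def load_prior_table(source: str = "packaged", charges=None, mean_distances=None) -> PriorTable:
    """Load the prior-probability table.

    ``source='packaged'`` returns the shipped table verbatim (the default).
    ``source='computed'`` (experimental) builds rows from
    :func:`coulomb_weight` + :func:`normalize_priors`, given ``charges`` — a
    mapping from fragment class and from target class to a partial charge —
    and ``mean_distances`` — a mapping (fragment, target) -> mean contact
    distance in angstrom.
    """
    if source == "packaged":
        with resources.as_file(_data_path("prior_table.csv")) as p:
            df = pd.read_csv(p).set_index("fragment_class")
        return PriorTable(df)
    if source != "computed":
        raise ValueError("source must be 'packaged' or 'computed'")
    if charges is None or mean_distances is None:
        raise ValueError("computed mode needs charges and mean_distances")
    rows = {}
    frags = sorted({f for f, _ in mean_distances})
    for frag in frags:
        raw = [
            coulomb_weight(charges[frag], charges[targ], mean_distances[(frag, targ)])
            for targ in TARGET_CLASSES
        ]
        rows[frag] = normalize_priors(raw)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TARGET_CLASSES))
    df.index.name = "fragment_class"
    return PriorTable(df)
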