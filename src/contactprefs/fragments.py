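"""Fragment/target classification, PDB reading and contact extraction.

A *fragment* is an atom triple (Main-atom, Atom1, Atom2) inside a ligand,
typed by the Main-atom's element, covalent bond count, aromaticity and
functional group into one of 24 classes (hydroxyl, carbonyl, carboxyl,
carbamoyl, amide and phosphate oxygens; aromatic/aliphatic carbons; halogens;
ring and amino nitrogens). A *target* is a protein atom near the Main-atom,
classified by element, residue and main/side chain membership into one of the
13 classes C3..C15. Contacts are collected within interaction-dependent
distance cutoffs and expressed as spherical coordinates in the fragment's
canonical frame (see :mod:`contactprefs.frames`), which makes them poolable
across fragment instances and structures.

Covalent bonds in ligands are inferred from distances (sum of covalent radii
plus 0.4 A); aromaticity comes from ring perception (smallest rings of the
bond graph, 5/6-membered, planar within 0.1 A) rather than an external
chemical dictionary. When Atom2 can be chosen from several bonded atoms,
every choice is emitted as its own fragment instance — the densities of the
choices are related by rotation about the Main-Atom1 bond.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import gemmi
import networkx as nx
import numpy as np
import yaml

from .frames import build_frame, to_spherical

__all__ = [
    "Atom",
    "StructureModel",
    "FragmentHit",
    "ContactRecord",
    "TargetCloud",
    "DistanceCutoffs",
    "read_structure",
    "find_fragments",
    "find_contacts",
    "classify_target",
    "flip_carbamoyl",
    "filter_additives",
    "build_clouds",
    "default_cutoffs",
]

#: maximum resolution admitted for training structures (A)
RESOLUTION_CUTOFF = 2.5

#: covalent radii (A) for bond inference
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
BOND_SLACK = 0.4
#: C-X distance below which the bond counts as a double bond (carbonyl etc.)
DOUBLE_BOND_CO = 1.32
#: max deviation from the ring plane for aromatic/planar ring perception (A)
PLANARITY_TOL = 0.1

HALOGENS = {"F", "CL", "BR", "I"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# side-chain atom -> target class, by (residue, atom name); main chain handled
# separately (N -> C15, O/OXT -> C14, CA -> C4)
_SIDECHAIN_CLASS = {
    ("ALA", "CB"): "C3",
    ("VAL", "CG1"): "C3", ("VAL", "CG2"): "C3",
    ("LEU", "CD1"): "C3", ("LEU", "CD2"): "C3",
    ("ILE", "CG2"): "C3", ("ILE", "CD1"): "C3",
    ("THR", "CG2"): "C3",
    ("MET", "CE"): "C3",
    ("PHE", "CG"): "C5", ("PHE", "CD1"): "C5", ("PHE", "CD2"): "C5",
    ("PHE", "CE1"): "C5", ("PHE", "CE2"): "C5", ("PHE", "CZ"): "C5",
    ("TYR", "CG"): "C5", ("TYR", "CD1"): "C5", ("TYR", "CD2"): "C5",
    ("TYR", "CE1"): "C5", ("TYR", "CE2"): "C5", ("TYR", "CZ"): "C5",
    ("TRP", "CG"): "C5", ("TRP", "CD1"): "C5", ("TRP", "CD2"): "C5",
    ("TRP", "CE2"): "C5", ("TRP", "CE3"): "C5", ("TRP", "CZ2"): "C5",
    ("TRP", "CZ3"): "C5", ("TRP", "CH2"): "C5",
    ("HIS", "CG"): "C5", ("HIS", "CD2"): "C5", ("HIS", "CE1"): "C5",
    ("MET", "SD"): "C6",
    ("CYS", "SG"): "C7",
    ("ASN", "ND2"): "C8", ("GLN", "NE2"): "C8",
    ("TRP", "NE1"): "C9",
    ("HIS", "ND1"): "C9", ("HIS", "NE2"): "C9",
    ("ARG", "NE"): "C9", ("ARG", "NH1"): "C9", ("ARG", "NH2"): "C9",
    ("LYS", "NZ"): "C10",
    ("ASN", "OD1"): "C11", ("GLN", "OE1"): "C11",
    ("ASP", "OD1"): "C12", ("ASP", "OD2"): "C12",
    ("GLU", "OE1"): "C12", ("GLU", "OE2"): "C12",
    ("SER", "OG"): "C13", ("THR", "OG1"): "C13", ("TYR", "OH"): "C13",
}

FRAGMENT_CLASSES = (
    "f2", "f3", "f5", "f6", "f7", "f8", "f9", "f10", "f11", "f12", "f13",
    "f17", "f18", "f20", "f21", "f22", "f23", "f26", "f27", "f29", "f34",
    "f35", "f36", "f37",
)


@dataclass
class Atom:
    """One atom of a structure, with the metadata the classifiers need."""

    serial: int
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    pos: np.ndarray  # (3,) in A
    het: bool
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0


@dataclass
class StructureModel:
    """Parsed structure: atom list, resolution and selection flags."""

    atoms: list
    resolution: float | None = None
    source_id: str = ""
    flags: list = field(default_factory=list)

    @property
    def ligand_atoms(self):
        return [a for a in self.atoms if a.het and a.resname not in ("HOH", "WAT")]

    @property
    def protein_atoms(self):
        return [a for a in self.atoms if not a.het and a.resname in STANDARD_AA]

    @property
    def ligand_ids(self):
        return sorted({a.resname for a in self.ligand_atoms})


@dataclass(frozen=True)
class FragmentHit:
    """One fragment instance: a typed (Main, Atom1, Atom2) triple."""

    class_id: str
    main: Atom
    atom1: Atom
    atom2: Atom


@dataclass(frozen=True)
class ContactRecord:
    """One contact-atom position in a fragment's canonical model frame."""

    fragment_class: str
    target_class: str
    r: float
    theta: float
    phi: float
    source_id: str = ""
    ligand_id: str = ""
    resolution: float | None = None
    is_additive: bool = False


@dataclass
class TargetCloud:
    """All contacts of one (fragment class, target class) pair."""

    fragment_class: str
    target_class: str
    records: list
    r_max: float

    def __post_init__(self):
        for rec in self.records:
            if (rec.fragment_class, rec.target_class) != (self.fragment_class, self.target_class):
                raise ValueError("cloud records must share the fragment/target classes")
            if rec.r > self.r_max + 1e-9:
                raise ValueError(f"record at r={rec.r} beyond the collection cutoff {self.r_max}")

    def __len__(self):
        return len(self.records)

    def to_array(self) -> np.ndarray:
        return np.array([[rec.r, rec.theta, rec.phi] for rec in self.records]).reshape(-1, 3)


@dataclass(frozen=True)
class DistanceCutoffs:
    """The three contact-collection distance criteria (A). Deliberately
    without defaults: the canonical values are configuration, not code."""

    hbond: float  # alleged H-bonds and charged groups
    dispersion: float  # probable dispersion contacts
    halogen: float  # halogen bonds

    def for_pair(self, main_element: str, target_element: str) -> float:
        if main_element.upper() in HALOGENS:
            return self.halogen
        if main_element.upper() in ("N", "O") and target_element.upper() in ("N", "O"):
            return self.hbond
        return self.dispersion

    @property
    def r_max(self) -> float:
        return max(self.hbond, self.dispersion, self.halogen)


def default_cutoffs() -> DistanceCutoffs:
    """Packaged default cutoffs (non-canonical; see data/defaults.yaml)."""
    path = resources.files("contactprefs.data").joinpath("defaults.yaml")
    with resources.as_file(path) as p:
        cfg = yaml.safe_load(p.read_text())
    return DistanceCutoffs(**cfg["distance_cutoffs"])


# -- PDB ingestion -------------------------------------------------------------


def read_structure(path, max_resolution: float = RESOLUTION_CUTOFF) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Only the first model is used. Alternate locations keep the
    highest-occupancy conformer (ties prefer altloc 'A'). Structures that
    fail the selection criteria (resolution above the cutoff, no ligand) are
    flagged in ``StructureModel.flags``, never silently dropped.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution else None

    raw = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                raw.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        resname=res.name,
                        resseq=res.seqid.num,
                        chain=chain.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        het=het,
                        occupancy=at.occ,
                        altloc=at.altloc or "",
                        bfactor=at.b_iso,
                    )
                )

    # altloc resolution: keep the highest occupancy, tie -> altloc 'A' (or first)
    best = {}
    for a in raw:
        key = (a.chain, a.resseq, a.resname, a.name)
        cur = best.get(key)
        if cur is None or a.occupancy > cur.occupancy or (
            a.occupancy == cur.occupancy and (a.altloc or "A") < (cur.altloc or "A")
        ):
            best[key] = a
    atoms = sorted(best.values(), key=lambda a: a.serial)

    flags = []
    if resolution is not None and resolution > max_resolution:
        flags.append(f"resolution {resolution:.2f} A above cutoff {max_resolution} A")
    if not any(a.het and a.resname not in ("HOH", "WAT") for a in atoms):
        flags.append("no ligand (HETATM) present")
    return StructureModel(atoms=atoms, resolution=resolution,
                          source_id=st.name or str(path), flags=flags)


# -- ligand chemistry ----------------------------------------------------------


def _bond_graph(atoms) -> nx.Graph:
    """Distance-based covalent bond inference over a list of atoms."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    for i in range(len(atoms)):
        ri = COVALENT_RADII.get(atoms[i].element)
        if ri is None:
            continue
        for j in range(i + 1, len(atoms)):
            rj = COVALENT_RADII.get(atoms[j].element)
            if rj is None:
                continue
            d = float(np.linalg.norm(atoms[i].pos - atoms[j].pos))
            if d < ri + rj + BOND_SLACK and d > 0.4:
                g.add_edge(i, j, length=d)
    return g


def _ring_planarity(atoms, ring) -> float:
    pts = np.array([atoms[i].pos for i in ring])
    pts = pts - pts.mean(axis=0)
    return float(np.linalg.svd(pts, compute_uv=False)[-1] / max(np.sqrt(len(ring)), 1))


def _perceive_rings(atoms, graph):
    """Aromatic and planar-ring membership via the cycle basis of the bond
    graph (SSSR surrogate) plus a planarity test."""
    aromatic, planar_ring = set(), set()
    for ring in nx.cycle_basis(graph):
        if len(ring) not in (5, 6):
            continue
        if _ring_planarity(atoms, ring) > PLANARITY_TOL:
            continue
        planar_ring.update(ring)
        ok = all(
            atoms[i].element in ("C", "N", "O", "S") and graph.degree(i) <= 3
            for i in ring
        )
        if ok:
            aromatic.update(ring)
    return aromatic, planar_ring


def _is_planar_carbon(atoms, graph, idx, aromatic) -> bool:
    """A carbon counts as planar when aromatic or double-bonded (short bond)."""
    if idx in aromatic:
        return True
    for j in graph.neighbors(idx):
        if atoms[j].element in ("O", "N", "C"):
            if graph.edges[idx, j]["length"] < DOUBLE_BOND_CO:
                return True
    return False


def _classify_main(atoms, graph, idx, aromatic, planar_ring):
    """Fragment classes for which atom ``idx`` qualifies as the Main-atom.

    Returns a list of (class_id, atom1_index) pairs; Atom2 choices are
    expanded by the caller.
    """
    a = atoms[idx]
    nbrs = list(graph.neighbors(idx))
    deg = len(nbrs)
    out = []

    if a.element == "O" and deg == 1:
        j = nbrs[0]
        b = atoms[j]
        if b.element == "P":
            out.append(("f8", j))
        elif b.element == "C":
            d = graph.edges[idx, j]["length"]
            if d < DOUBLE_BOND_CO:  # carbonyl-type oxygen
                others = [k for k in graph.neighbors(j) if k != idx]
                term_o = [k for k in others if atoms[k].element == "O"]
                n_nbrs = [k for k in others if atoms[k].element == "N"]
                if term_o and all(graph.degree(k) == 1 for k in term_o):
                    out.append(("f6", j))
                elif n_nbrs:
                    n = n_nbrs[0]
                    if graph.degree(n) == 1:
                        out.append(("f7", j))
                    else:
                        rest = [k for k in others if k not in n_nbrs]
                        if any(k in aromatic for k in rest):
                            out.append(("f10", j))
                        else:
                            out.append(("f9", j))
                else:
                    out.append(("f5", j))
            else:  # hydroxyl-type oxygen
                if j in aromatic:
                    out.append(("f3", j))
                elif not _is_planar_carbon(atoms, graph, j, aromatic):
                    out.append(("f2", j))
    elif a.element == "O" and deg == 2 and any(atoms[j].element == "P" for j in nbrs):
        j = next(j for j in nbrs if atoms[j].element == "P")
        out.append(("f8", j))
    elif a.element == "C":
        if deg == 2:
            cls = "f11" if idx in aromatic else "f12"
            out.extend((cls, j) for j in nbrs)
        elif deg == 1:
            out.append(("f13", nbrs[0]))
    elif a.element in HALOGENS and deg == 1:
        j = nbrs[0]
        arom = j in aromatic
        cls = {
            "F": "f17" if arom else "f18",
            "CL": "f20" if arom else "f21",
            "BR": "f34" if arom else "f35",
            "I": "f36" if arom else "f37",
        }[a.element]
        out.append((cls, j))
    elif a.element == "N":
        if deg == 2 and idx in aromatic:
            out.extend(("f22", j) for j in nbrs)
        elif deg == 2 and idx in planar_ring:
            out.extend(("f23", j) for j in nbrs)
        elif deg == 1:
            j = nbrs[0]
            if j in aromatic:
                out.append(("f27", j))
            elif atoms[j].element == "C" and _is_planar_carbon(atoms, graph, j, aromatic):
                out.append(("f29", j))
            elif atoms[j].element == "C":
                out.append(("f26", j))
    return out


def find_fragments(structure: StructureModel, classes=None) -> list:
    """Locate fragment instances in the structure's ligands.

    ``classes`` optionally restricts the class vocabulary. Every admissible
    Atom2 choice is emitted as its own :class:`FragmentHit` (the degeneracy is
    real: each choice has its own density). Deterministic order: by Main-atom
    serial, class id, Atom1 then Atom2 serials.
    """
    lig = structure.ligand_atoms
    hits = []
    # per-residue graphs: ligand copies in different chains are independent
    by_res = {}
    for a in lig:
        by_res.setdefault((a.chain, a.resseq, a.resname), []).append(a)
    for atoms in by_res.values():
        graph = _bond_graph(atoms)
        aromatic, planar_ring = _perceive_rings(atoms, graph)
        for idx in range(len(atoms)):
            for class_id, a1 in _classify_main(atoms, graph, idx, aromatic, planar_ring):
                if classes is not None and class_id not in classes:
                    continue
                a2_choices = [k for k in graph.neighbors(a1) if k != idx]
                for a2 in a2_choices:
                    hits.append(FragmentHit(class_id, atoms[idx], atoms[a1], atoms[a2]))
    hits.sort(key=lambda h: (h.main.serial, h.class_id, h.atom1.serial, h.atom2.serial))
    return hits


# -- target classification and contact extraction ------------------------------


def classify_target(atom: Atom) -> str | None:
    """Table-driven contact-atom class of a protein atom, or None.

    Classification is by element, residue and main/side chain membership;
    every atom maps to at most one class.
    """
    if atom.het or atom.resname not in STANDARD_AA:
        return None
    if atom.name == "N":
        return "C15"
    if atom.name in ("O", "OXT"):
        return "C14"
    if atom.name == "CA":
        return "C4"
    return _SIDECHAIN_CLASS.get((atom.resname, atom.name))


def find_contacts(hit: FragmentHit, structure: StructureModel,
                  cutoffs: DistanceCutoffs, is_additive=None) -> list:
    """Contact records of one fragment instance.

    Protein atoms within the applicable cutoff of the Main-atom are
    classified and transformed into the canonical frame; atoms without a
    contact class are skipped (their count is available via the returned
    list's ``skipped`` attribute pattern: see :func:`extract_contacts`).
    """
    frame = build_frame(hit.main.pos, hit.atom1.pos, hit.atom2.pos)
    additive_fn = is_additive or (lambda ligand_id: False)
    records = []
    for atom in structure.protein_atoms:
        d = float(np.linalg.norm(atom.pos - hit.main.pos))
        if d > cutoffs.r_max:
            continue
        cls = classify_target(atom)
        if cls is None:
            continue
        if d > cutoffs.for_pair(hit.main.element, atom.element):
            continue
        r, theta, phi = to_spherical(frame.apply(atom.pos))
        records.append(
            ContactRecord(
                fragment_class=hit.class_id,
                target_class=cls,
                r=r,
                theta=theta,
                phi=phi,
                source_id=structure.source_id,
                ligand_id=hit.main.resname,
                resolution=structure.resolution,
                is_additive=additive_fn(hit.main.resname),
            )
        )
    return records


def extract_contacts(structure: StructureModel, cutoffs: DistanceCutoffs,
                     classes=None, is_additive=None) -> list:
    """All contact records of all fragment instances in a structure."""
    out = []
    for hit in find_fragments(structure, classes=classes):
        out.extend(find_contacts(hit, structure, cutoffs, is_additive=is_additive))
    return out


def flip_carbamoyl(structure: StructureModel) -> tuple:
    """Swap the O and N coordinates of every ligand carbamoyl group (-CO-NH2).

    The two atoms cannot be told apart by the diffraction data, so a mislabel
    is corrected by exchanging the coordinates. Returns ``(new_structure,
    flipped)`` where ``flipped`` lists (O serial, N serial) pairs; applying
    the operation twice restores the original coordinates. Structures without
    a carbamoyl group are returned unchanged.
    """
    new = copy.deepcopy(structure)
    lig = new.ligand_atoms
    graph = _bond_graph(lig)
    flipped = []
    for j in range(len(lig)):
        if lig[j].element != "C":
            continue
        nbrs = list(graph.neighbors(j))
        # no bond-length test here: after a mislabel (or a previous flip) the
        # short bond sits on the N position, and the group must still match
        term_o = [k for k in nbrs if lig[k].element == "O" and graph.degree(k) == 1]
        term_n = [k for k in nbrs if lig[k].element == "N" and graph.degree(k) == 1]
        if len(term_o) == 1 and len(term_n) == 1:
            o, n = lig[term_o[0]], lig[term_n[0]]
            o.pos, n.pos = n.pos.copy(), o.pos.copy()
            flipped.append((o.serial, n.serial))
    return new, flipped


def filter_additives(records, additive_ids) -> tuple:
    """Remove records whose source ligand identifier is in the additive list.

    Returns ``(kept, n_removed)``."""
    additive_ids = set(additive_ids)
    kept = [r for r in records if r.ligand_id not in additive_ids]
    return kept, len(records) - len(kept)


def build_clouds(records, r_max: float) -> dict:
    """Group contact records into :class:`TargetCloud` objects keyed by
    (fragment class, target class)."""
    groups = {}
    for rec in records:
        groups.setdefault((rec.fragment_class, rec.target_class), []).append(rec)
    return {
        key: TargetCloud(fragment_class=key[0], target_class=key[1],
                         records=recs, r_max=r_max)
        for key, recs in groups.items()
    }


def records_to_frame(records):
    """Contact records as a pandas DataFrame (the contact-cloud TSV schema)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fragment_class": r.fragment_class,
                "target_class": r.target_class,
                "r": r.r,
                "theta": r.theta,
                "phi": r.phi,
                "source_id": r.source_id,
                "ligand_id": r.ligand_id,
                "resolution": r.resolution,
                "is_additive": r.is_additive,
            }
            for r in records
        ]
    )
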