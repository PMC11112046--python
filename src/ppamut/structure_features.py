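"""Structure-derived features: SASA, interface region, hydrogen bonds,
residue depth, and contact-network centralities of the mutation site.

All geometry runs on heavy atoms of the wild-type structure (predicted
models often lack hydrogens).  Solvent accessibility uses a dot-sphere
(Shrake-Rupley) construction; the residue contact network connects residues
whose representative points (C-beta, C-alpha for glycine) lie strictly
within a distance cutoff, 8 A by default, including inter-chain contacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Heavy-atom van der Waals radii (A), standard protein set.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960
DEFAULT_CONTACT_CUTOFF = 8.0

#: Maximal accessible surface area (A^2) of residue X in an extended
#: Gly-X-Gly tripeptide (theoretical values, Tien et al. 2013).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Hydrogen-bond-capable heavy atoms per residue (hydrogen-free criterion).
#: Backbone N donates (except proline) and backbone O accepts for every
#: residue; entries below list side-chain atoms only.
SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"), "N": ("ND2",), "Q": ("NE2",),
    "H": ("ND1", "NE2"), "K": ("NZ",), "S": ("OG",), "T": ("OG1",),
    "W": ("NE1",), "Y": ("OH",), "C": ("SG",),
}
SIDECHAIN_ACCEPTORS = {
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"), "N": ("OD1",), "Q": ("OE1",),
    "H": ("ND1", "NE2"), "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
    "M": ("SD",),
}
HBOND_DISTANCE_CUTOFF = 3.5

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureParseError(ValueError):
    """Unreadable or contentless structure file."""


class InterfaceRegion(str, Enum):
    """Burial-based position class of a residue in a complex.

    ``core``/``support``/``rim`` are interface residues (they lose
    accessible area upon complex formation); ``interior``/``surface`` are
    non-interface residues, split by burial in the complex.
    """

    CORE = "core"
    SUPPORT = "support"
    RIM = "rim"
    INTERIOR = "interior"
    SURFACE = "surface"


ResidueKey = tuple[str, int]  # (chain id, author residue number)


@dataclass
class StructureModel:
    """Heavy-atom coordinates of a multi-chain complex with residue indexing.

    Arrays are parallel over atoms; ``residues`` holds one row per residue
    with chain, author number and one-letter code.
    """

    atom_coords: np.ndarray            # (n_atoms, 3) in A
    atom_radii: np.ndarray             # (n_atoms,) vdW radii in A
    atom_names: np.ndarray             # (n_atoms,) PDB atom names
    atom_elements: np.ndarray          # (n_atoms,)
    atom_residue: np.ndarray           # (n_atoms,) index into residues
    residues: pd.DataFrame             # columns: chain, number, aa
    chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureParseError("structure has no polymer chains")
        if (self.atom_radii <= 0).any():
            raise StructureParseError("non-positive van der Waals radius")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_coords)

    def residue_keys(self) -> list[ResidueKey]:
        return list(zip(self.residues["chain"], self.residues["number"]))

    def residue_index(self, key: ResidueKey) -> int:
        mask = (self.residues["chain"] == key[0]) & (self.residues["number"] == key[1])
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"residue {key} not in structure")
        return int(idx[0])

    def atoms_of_residue(self, key: ResidueKey) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == self.residue_index(key))

    def select_chains(self, chains: list[str]) -> "StructureModel":
        """A sub-structure with only the given chains (monomer extraction)."""
        res_mask = self.residues["chain"].isin(chains).to_numpy()
        old_to_new = -np.ones(len(self.residues), dtype=int)
        old_to_new[res_mask] = np.arange(res_mask.sum())
        atom_mask = res_mask[self.atom_residue]
        return StructureModel(
            atom_coords=self.atom_coords[atom_mask],
            atom_radii=self.atom_radii[atom_mask],
            atom_names=self.atom_names[atom_mask],
            atom_elements=self.atom_elements[atom_mask],
            atom_residue=old_to_new[self.atom_residue[atom_mask]],
            residues=self.residues[res_mask].reset_index(drop=True),
            chains=[c for c in self.chains if c in chains],
        )

    def translated(self, shift: np.ndarray) -> "StructureModel":
        return StructureModel(
            atom_coords=self.atom_coords + np.asarray(shift, float),
            atom_radii=self.atom_radii, atom_names=self.atom_names,
            atom_elements=self.atom_elements, atom_residue=self.atom_residue,
            residues=self.residues, chains=list(self.chains))

    def rotated(self, rotation: np.ndarray) -> "StructureModel":
        return StructureModel(
            atom_coords=self.atom_coords @ np.asarray(rotation, float).T,
            atom_radii=self.atom_radii, atom_names=self.atom_names,
            atom_elements=self.atom_elements, atom_residue=self.atom_residue,
            residues=self.residues, chains=list(self.chains))


def parse_structure(path: str | Path, keep_hydrogens: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Keeps the first model and first altloc, drops waters and, by default,
    hydrogens.  Non-water HETATM residues without a canonical amino-acid
    code are skipped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_waters()
    if not keep_hydrogens:
        st.remove_hydrogens()

    coords, radii, names, elements, res_of_atom = [], [], [], [], []
    res_rows = []
    chains = []
    model = st[0]
    for chain in model:
        chain_has_residues = False
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                continue
            res_idx = len(res_rows)
            res_rows.append((chain.name, res.seqid.num, one))
            chain_has_residues = True
            for atom in res:
                el = atom.element.name.upper()
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(VDW_RADII.get(el, 1.80))
                names.append(atom.name)
                elements.append(el)
                res_of_atom.append(res_idx)
        if chain_has_residues:
            chains.append(chain.name)
    if not res_rows:
        raise StructureParseError(f"{path}: no polymer amino-acid residues")
    return StructureModel(
        atom_coords=np.asarray(coords, float),
        atom_radii=np.asarray(radii, float),
        atom_names=np.asarray(names, object),
        atom_elements=np.asarray(elements, object),
        atom_residue=np.asarray(res_of_atom, int),
        residues=pd.DataFrame(res_rows, columns=["chain", "number", "aa"]),
        chains=chains,
    )


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _accessible_dots(coords: np.ndarray, radii: np.ndarray,
                     probe_radius: float, n_points: int):
    """Per-atom solvent-accessible dot fractions and the accessible dots.

    Returns (fraction accessible per atom, concatenated accessible dot
    coordinates on the expanded spheres).
    """
    sphere = _unit_sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max()
    fractions = np.empty(len(coords))
    dots_out = []
    for i in range(len(coords)):
        dots = coords[i] + expanded[i] * sphere
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            nb = np.asarray(neighbors, int)
            d2 = ((dots[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
        else:
            buried = np.zeros(n_points, dtype=bool)
        fractions[i] = 1.0 - buried.mean()
        if (~buried).any():
            dots_out.append(dots[~buried])
    all_dots = (np.concatenate(dots_out) if dots_out
                else np.empty((0, 3)))
    return fractions, all_dots


def atom_sasa(structure: StructureModel,
              probe_radius: float = DEFAULT_PROBE_RADIUS,
              n_sphere_points: int = DEFAULT_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), dot-sphere method."""
    fractions, _ = _accessible_dots(structure.atom_coords, structure.atom_radii,
                                    probe_radius, n_sphere_points)
    expanded = structure.atom_radii + probe_radius
    return fractions * 4.0 * math.pi * expanded ** 2


def compute_sasa(structure: StructureModel,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                 ) -> dict[ResidueKey, float]:
    """Per-residue SASA (A^2): per-atom dot accessibility summed per residue."""
    per_atom = atom_sasa(structure, probe_radius, n_sphere_points)
    out: dict[ResidueKey, float] = {}
    keys = structure.residue_keys()
    sums = np.zeros(len(keys))
    np.add.at(sums, structure.atom_residue, per_atom)
    for idx, key in enumerate(keys):
        out[key] = float(sums[idx])
    return out


def relative_sasa(residue_sasa: float, residue_code: str) -> float:
    """SASA normalised by the residue's Gly-X-Gly maximal accessibility.

    May slightly exceed 1 for chain termini.
    """
    try:
        ref = MAX_ASA[residue_code]
    except KeyError as exc:
        raise KeyError(f"no reference accessibility for {residue_code!r}") from exc
    return residue_sasa / ref


def classify_interface_region(rsasa_monomer: float, rsasa_complex: float,
                              burial_threshold: float = 0.25,
                              tolerance: float = 1e-6) -> InterfaceRegion:
    """Assign core/support/rim/interior/surface from relative accessibility.

    A residue is at the interface when it loses accessible area upon
    complex formation (delta = rSASA_monomer - rSASA_complex > tolerance):
    ``support`` if already buried in the monomer, ``core`` if exposed in the
    monomer but buried in the complex, ``rim`` if it stays exposed.
    Otherwise it is ``interior`` (buried) or ``surface`` (exposed).
    """
    if rsasa_monomer < 0 or rsasa_complex < 0:
        raise ValueError("relative SASA values must be nonnegative")
    delta = rsasa_monomer - rsasa_complex
    if delta <= tolerance:
        return (InterfaceRegion.INTERIOR if rsasa_complex < burial_threshold
                else InterfaceRegion.SURFACE)
    if rsasa_monomer < burial_threshold:
        return InterfaceRegion.SUPPORT
    if rsasa_complex < burial_threshold:
        return InterfaceRegion.CORE
    return InterfaceRegion.RIM


def _hbond_atom_sets(structure: StructureModel):
    """Boolean donor/acceptor masks over atoms (hydrogen-free dictionary)."""
    n = structure.n_atoms
    donors = np.zeros(n, dtype=bool)
    acceptors = np.zeros(n, dtype=bool)
    aa_of_res = structure.residues["aa"].to_numpy()
    for i in range(n):
        aa = aa_of_res[structure.atom_residue[i]]
        name = structure.atom_names[i]
        if name == "N" and aa != "P":
            donors[i] = True
        if name == "O":
            acceptors[i] = True
        if name in SIDECHAIN_DONORS.get(aa, ()):
            donors[i] = True
        if name in SIDECHAIN_ACCEPTORS.get(aa, ()):
            acceptors[i] = True
    return donors, acceptors


def count_hbond_donors_acceptors(structure: StructureModel,
                                 residue: ResidueKey,
                                 distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                                 ) -> tuple[int, int]:
    """Count the residue's donor and acceptor heavy atoms engaged in
    hydrogen bonds (eligible partner in another residue within the
    distance cutoff)."""
    res_idx = structure.residue_index(residue)
    donors, acceptors = _hbond_atom_sets(structure)
    own = structure.atom_residue == res_idx
    tree = cKDTree(structure.atom_coords)

    def _engaged(own_mask: np.ndarray, partner_mask: np.ndarray) -> int:
        count = 0
        partner_idx = np.flatnonzero(partner_mask & ~own)
        if len(partner_idx) == 0:
            return 0
        ptree = cKDTree(structure.atom_coords[partner_idx])
        for i in np.flatnonzero(own_mask & own):
            near = ptree.query_ball_point(structure.atom_coords[i],
                                          distance_cutoff)
            if near:
                count += 1
        return count

    del tree
    n_donors = _engaged(donors, acceptors)
    n_acceptors = _engaged(acceptors, donors)
    return n_donors, n_acceptors


def residue_depth(structure: StructureModel, residue: ResidueKey,
                  probe_radius: float = DEFAULT_PROBE_RADIUS,
                  n_sphere_points: int = DEFAULT_SPHERE_POINTS) -> float:
    """Mean distance (A) from the residue's heavy atoms to the nearest
    solvent-accessible surface dot of the whole structure.

    For a single-atom structure every dot lies on its own expanded sphere,
    so the depth degenerates to r + probe.
    """
    _, dots = _accessible_dots(structure.atom_coords, structure.atom_radii,
                               probe_radius, n_sphere_points)
    atom_idx = structure.atoms_of_residue(residue)
    if len(dots) == 0:  # fully occluded structure; no surface to measure from
        return 0.0
    tree = cKDTree(dots)
    dists, _ = tree.query(structure.atom_coords[atom_idx])
    return float(np.mean(dists))


def _representative_points(structure: StructureModel) -> np.ndarray:
    """C-beta per residue (C-alpha for glycine, centroid as fallback)."""
    n_res = len(structure.residues)
    points = np.full((n_res, 3), np.nan)
    have_cb = np.zeros(n_res, dtype=bool)
    have_ca = np.zeros(n_res, dtype=bool)
    ca = np.full((n_res, 3), np.nan)
    sums = np.zeros((n_res, 3))
    counts = np.zeros(n_res)
    for i in range(structure.n_atoms):
        r = structure.atom_residue[i]
        sums[r] += structure.atom_coords[i]
        counts[r] += 1
        if structure.atom_names[i] == "CB":
            points[r] = structure.atom_coords[i]
            have_cb[r] = True
        elif structure.atom_names[i] == "CA":
            ca[r] = structure.atom_coords[i]
            have_ca[r] = True
    aa = structure.residues["aa"].to_numpy()
    for r in range(n_res):
        if aa[r] == "G" or not have_cb[r]:
            if have_ca[r]:
                points[r] = ca[r]
            elif not have_cb[r]:
                logger.warning("residue %s lacks CB/CA; using centroid",
                               structure.residue_keys()[r])
                points[r] = sums[r] / counts[r]
    return points


def build_contact_graph(structure: StructureModel,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        atom_mode: str = "cbeta") -> nx.Graph:
    """Residue contact network: edge iff inter-residue distance < cutoff.

    ``atom_mode='cbeta'`` measures between representative points (C-beta,
    C-alpha for glycine); ``'min_heavy'`` uses the minimum heavy-atom
    distance.  Edges are strict (< cutoff) and include inter-chain pairs.
    Graph nodes are (chain, author number) keys with an ``aa`` attribute.
    """
    keys = structure.residue_keys()
    graph = nx.Graph(cutoff=cutoff, distance_definition=atom_mode)
    for key, aa in zip(keys, structure.residues["aa"]):
        graph.add_node(key, aa=aa)
    if atom_mode == "cbeta":
        points = _representative_points(structure)
        tree = cKDTree(points)
        for i, j in tree.query_pairs(cutoff):
            d = float(np.linalg.norm(points[i] - points[j]))
            if d < cutoff:
                graph.add_edge(keys[i], keys[j], distance=d)
    elif atom_mode == "min_heavy":
        tree = cKDTree(structure.atom_coords)
        seen: set[tuple[int, int]] = set()
        for ai, aj in tree.query_pairs(cutoff):
            ri, rj = structure.atom_residue[ai], structure.atom_residue[aj]
            if ri == rj:
                continue
            pair = (min(ri, rj), max(ri, rj))
            if pair in seen:
                continue
            d = float(np.linalg.norm(structure.atom_coords[ai]
                                     - structure.atom_coords[aj]))
            if d < cutoff:
                seen.add(pair)
                graph.add_edge(keys[pair[0]], keys[pair[1]])
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    return graph


def _eigenvector_centrality(graph: nx.Graph) -> dict:
    """Principal adjacency eigenvector per connected component, unit
    Euclidean norm, nonnegative; isolated nodes get 0."""
    out = {n: 0.0 for n in graph}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        A = nx.to_numpy_array(graph, nodelist=comp)
        w, v = np.linalg.eigh(A)
        vec = v[:, np.argmax(w)]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)
        vec /= np.linalg.norm(vec)
        for node, val in zip(comp, vec):
            out[node] = float(val)
    return out


def site_centralities(graph: nx.Graph, node) -> dict[str, float]:
    """Normalized degree, betweenness, closeness and eigenvector centrality
    of one node of the residue contact network.

    Degree is divided by n-1; betweenness by (n-1)(n-2)/2; closeness is the
    within-component (n_c - 1) / sum-of-distances convention; eigenvector
    comes from the per-component principal adjacency eigenvector.  Isolated
    nodes score 0 on all four.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    n = graph.number_of_nodes()
    if graph.degree(node) == 0:
        return {"degree": 0.0, "betweenness": 0.0,
                "closeness": 0.0, "eigenvector": 0.0}
    degree = graph.degree(node) / (n - 1) if n > 1 else 0.0
    betweenness = nx.betweenness_centrality(graph, normalized=True)[node]
    closeness = nx.closeness_centrality(graph, u=node, wf_improved=False)
    eigen = _eigenvector_centrality(graph)[node]
    return {"degree": float(degree), "betweenness": float(betweenness),
            "closeness": float(closeness), "eigenvector": float(eigen)}


def residue_feature_table(structure: StructureModel,
                          probe_radius: float = DEFAULT_PROBE_RADIUS,
                          n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                          contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                          atom_mode: str = "cbeta") -> pd.DataFrame:
    """All per-residue structure features of a complex in one table.

    Columns: chain, position, aa, sasa, rsasa, rsasa_monomer, region,
    hbond_donors, hbond_acceptors, depth, and the four centralities.
    Monomer accessibility is computed on each chain extracted alone.
    """
    sasa_complex = compute_sasa(structure, probe_radius, n_sphere_points)
    sasa_monomer: dict[ResidueKey, float] = {}
    for chain in structure.chains:
        mono = structure.select_chains([chain])
        sasa_monomer.update(compute_sasa(mono, probe_radius, n_sphere_points))
    graph = build_contact_graph(structure, contact_cutoff, atom_mode)

    donors_all, acceptors_all = _hbond_atom_sets(structure)
    tree = cKDTree(structure.atom_coords)
    pairs = tree.query_pairs(HBOND_DISTANCE_CUTOFF)
    n_res = len(structure.residues)
    donor_atoms_engaged: list[set[int]] = [set() for _ in range(n_res)]
    acceptor_atoms_engaged: list[set[int]] = [set() for _ in range(n_res)]
    for ai, aj in pairs:
        ri, rj = structure.atom_residue[ai], structure.atom_residue[aj]
        if ri == rj:
            continue
        if donors_all[ai] and acceptors_all[aj]:
            donor_atoms_engaged[ri].add(ai)
            acceptor_atoms_engaged[rj].add(aj)
        if donors_all[aj] and acceptors_all[ai]:
            donor_atoms_engaged[rj].add(aj)
            acceptor_atoms_engaged[ri].add(ai)

    _, dots = _accessible_dots(structure.atom_coords, structure.atom_radii,
                               probe_radius, n_sphere_points)
    dot_tree = cKDTree(dots) if len(dots) else None

    rows = []
    for r, key in enumerate(structure.residue_keys()):
        aa = structure.residues["aa"].iloc[r]
        sasa = sasa_complex[key]
        rs_c = relative_sasa(sasa, aa)
        rs_m = relative_sasa(sasa_monomer[key], aa)
        region = classify_interface_region(rs_m, rs_c)
        atom_idx = np.flatnonzero(structure.atom_residue == r)
        if dot_tree is not None:
            depth = float(np.mean(dot_tree.query(
                structure.atom_coords[atom_idx])[0]))
        else:
            depth = 0.0
        cents = site_centralities(graph, key)
        rows.append({
            "chain": key[0], "position": key[1], "aa": aa,
            "sasa": sasa, "rsasa": rs_c, "rsasa_monomer": rs_m,
            "region": region.value,
            "hbond_donors": len(donor_atoms_engaged[r]),
            "hbond_acceptors": len(acceptor_atoms_engaged[r]),
            "depth": depth, **{f"centrality_{k}": v for k, v in cents.items()},
        })
    return pd.DataFrame(rows)


def write_residue_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
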