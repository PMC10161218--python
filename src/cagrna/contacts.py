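"""ATP-RNA interaction analysis of MD trajectories.

The central question is where ATP binds on a CAG-repeat hairpin: at the
Watson-Crick edge of the nucleobases (competing with base pairing) or at
the backbone's ribose/phosphate moieties.  Hydrogen bonds between ATP and
RNA are counted per frame with the geometric criterion

    d(donor, acceptor) < 0.4 nm   AND   angle(donor, H, acceptor) > 120 deg

and bucketed by the RNA-side moiety (base / ribose / phosphate), with base
contacts further split by nucleobase identity.  Mean per-frame counts for
the native and unwound hairpin states are differenced to quantify the shift
of ATP contacts toward the bases in the unwound state.

Also provided: glycosidic chi torsions (base/ribose orientation) and the
RMSD of each frame to the iteratively refined average structure after
Kabsch superposition.

Internal length unit is nm; PDB angstroms are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Topology", "Trajectory", "HBondCriteria", "MoietyMap", "InteractionTable",
    "classify_moieties", "count_hbonds", "trajectory_interactions",
    "interaction_delta", "chi_torsions", "rmsd_to_average", "dihedral",
    "read_trajectory", "write_trajectory",
    "RNA_RESIDUES", "PHOSPHATE_ATOMS", "RIBOSE_ATOMS", "WC_EDGE_ATOMS",
    "RNA_DONORS", "RNA_ACCEPTORS", "ATP_DONORS", "ATP_ACCEPTORS",
]

RNA_RESIDUES = {"A", "C", "G", "U"}

# --- moiety definition tables (PDB atom naming) --------------------------

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O5'", "O3'"}
RIBOSE_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}

BASE_HEAVY_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"},
    "G": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "U": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"},
}

#: Base atoms engaged in canonical Watson-Crick pairing.
WC_EDGE_ATOMS = {
    "A": {"N1", "N6"},
    "C": {"N3", "N4", "O2"},
    "G": {"N1", "N2", "O6"},
    "U": {"N3", "O2", "O4"},
}

# Hydrogen names attached to each heavy atom (donors only need these).
_H_CHILDREN = {
    ("A", "N6"): ("H61", "H62"),
    ("C", "N4"): ("H41", "H42"),
    ("G", "N1"): ("H1",),
    ("G", "N2"): ("H21", "H22"),
    ("U", "N3"): ("H3",),
}

#: RNA hydrogen-bond donors: heavy atom -> names of its polar hydrogens.
RNA_DONORS = dict(_H_CHILDREN) | {
    ("A", "O2'"): ("HO2'",),
    ("C", "O2'"): ("HO2'",),
    ("G", "O2'"): ("HO2'",),
    ("U", "O2'"): ("HO2'",),
}

#: RNA hydrogen-bond acceptors per residue (base lone pairs + backbone O).
_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O5'", "O3'", "O4'", "O2'"}
RNA_ACCEPTORS = {
    "A": {"N1", "N3", "N7"} | _BACKBONE_ACCEPTORS,
    "C": {"O2", "N3"} | _BACKBONE_ACCEPTORS,
    "G": {"O6", "N3", "N7"} | _BACKBONE_ACCEPTORS,
    "U": {"O2", "O4"} | _BACKBONE_ACCEPTORS,
}

#: ATP donors (heavy atom -> hydrogens) and acceptors.
ATP_DONORS = {"N6": ("H61", "H62"), "O2'": ("HO2'",), "O3'": ("HO3'",)}
ATP_ACCEPTORS = {"N1", "N3", "N7", "O4'", "O2'", "O3'",
                 "O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"}
_ATP_PHOSPHORUS = {"PA", "PB", "PG"}


# --- containers ----------------------------------------------------------

@dataclass
class Topology:
    """Constant atom metadata of a trajectory (parallel arrays)."""

    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray

    def __post_init__(self):
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.residue_name = np.asarray(self.residue_name, dtype="U4")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype="U2")
        self.element = np.asarray(self.element, dtype="U2")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def is_hydrogen(self) -> np.ndarray:
        return self.element == "H"


@dataclass
class Trajectory:
    """Frames over a constant topology; coordinates in nm."""

    topology: Topology
    coords: np.ndarray            # (n_frames, n_atoms, 3), nm
    frame_time: float = 1.0       # ns between frames

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion: D-A distance and D-H-A angle."""

    d_max: float = 0.4        # nm, donor-acceptor distance cutoff
    theta_min: float = 120.0  # deg, minimum donor-hydrogen-acceptor angle

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_min < 180:
            raise ValueError("theta_min must be in (0, 180)")


@dataclass
class MoietyMap:
    """Per-atom moiety assignment (base/ribose/phosphate) + WC-edge flag.

    ``moiety`` holds '' for hydrogens and non-RNA atoms; every RNA heavy
    atom is assigned exactly one moiety.
    """

    moiety: np.ndarray     # 'base' | 'ribose' | 'phosphate' | ''
    wc_edge: np.ndarray    # bool


class MoietyClassificationError(ValueError):
    pass


def classify_moieties(top: Topology) -> MoietyMap:
    """Assign every RNA heavy atom to base, ribose, or phosphate.

    Hydrogens inherit no moiety of their own (they follow their heavy
    atom through the donor tables).  Unknown RNA heavy-atom names raise
    :class:`MoietyClassificationError` listing the offenders.
    """
    moiety = np.full(top.n_atoms, "", dtype="U9")
    wc = np.zeros(top.n_atoms, dtype=bool)
    unknown = []
    for i in range(top.n_atoms):
        res, name = top.residue_name[i], top.atom_name[i]
        if res not in RNA_RESIDUES or top.element[i] == "H":
            continue
        if name in PHOSPHATE_ATOMS:
            moiety[i] = "phosphate"
        elif name in RIBOSE_ATOMS:
            moiety[i] = "ribose"
        elif name in BASE_HEAVY_ATOMS[res]:
            moiety[i] = "base"
            wc[i] = name in WC_EDGE_ATOMS[res]
        else:
            unknown.append(f"{res}{top.residue_index[i]}:{name}")
    if unknown:
        raise MoietyClassificationError(
            "unclassified RNA heavy atoms: " + ", ".join(unknown))
    return MoietyMap(moiety=moiety, wc_edge=wc)


# --- hydrogen-bond counting ----------------------------------------------

_BASE_LETTERS = ("A", "C", "G", "U")
_COUNT_KEYS = [("base", b) for b in _BASE_LETTERS] + [("ribose", ""), ("phosphate", "")]


def _zero_counts() -> dict:
    return {k: 0.0 for k in _COUNT_KEYS}


def _index_partners(top: Topology, donors: dict, side: str):
    """List (donor_idx, (h_idx, ...)) for one molecule side.

    ``side`` is 'rna' (keys (residue, atom)) or 'atp' (keys atom name).
    Missing polar hydrogens raise, since the angle criterion needs them.
    """
    out = []
    by_residue: dict = {}
    for i in range(top.n_atoms):
        by_residue.setdefault((top.chain_id[i], top.residue_index[i]), {})[
            top.atom_name[i]] = i
    for (chain, resi), atoms in by_residue.items():
        any_idx = next(iter(atoms.values()))
        res = top.residue_name[any_idx]
        is_rna = res in RNA_RESIDUES
        if (side == "rna") != is_rna:
            continue
        for name, idx in atoms.items():
            key = (res, name) if side == "rna" else name
            if key not in donors:
                continue
            h_idx = tuple(atoms[h] for h in donors[key] if h in atoms)
            if not h_idx:
                raise ValueError(
                    f"donor {res}{resi}:{name} has no polar hydrogen in the "
                    "topology; add explicit hydrogens")
            out.append((idx, h_idx))
    return out


def _acceptor_indices(top: Topology, side: str, acceptors_rna: dict,
                      acceptors_atp: set) -> np.ndarray:
    idx = []
    for i in range(top.n_atoms):
        res, name = top.residue_name[i], top.atom_name[i]
        if side == "rna":
            if res in RNA_RESIDUES and name in acceptors_rna[res]:
                idx.append(i)
        else:
            if res not in RNA_RESIDUES and name in acceptors_atp:
                idx.append(i)
    return np.array(idx, dtype=int)


def _angle_deg(d, h, a):
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def count_hbonds(frame: np.ndarray, top: Topology, criteria: HBondCriteria,
                 moieties: MoietyMap | None = None,
                 rna_donors: dict = RNA_DONORS, rna_acceptors: dict = RNA_ACCEPTORS,
                 atp_donors: dict = ATP_DONORS, atp_acceptors: set = ATP_ACCEPTORS) -> dict:
    """Count ATP-RNA hydrogen bonds in one frame, bucketed by RNA moiety.

    A donor-acceptor pair is counted once when d(D, A) < d_max and at least
    one attached hydrogen satisfies angle(D, H, A) > theta_min.  Both
    directions are scanned (ATP donor -> RNA acceptor and RNA donor -> ATP
    acceptor); each bond is bucketed by its RNA-side atom's moiety and, for
    base contacts, by the nucleobase identity.

    Returns a dict keyed by ('base', letter), ('ribose', ''), ('phosphate', '').
    """
    frame = np.asarray(frame, dtype=float)
    if moieties is None:
        moieties = classify_moieties(top)
    counts = _zero_counts()

    pairs = [
        (_index_partners(top, atp_donors, "atp"),
         _acceptor_indices(top, "rna", rna_acceptors, atp_acceptors), "acceptor"),
        (_index_partners(top, rna_donors, "rna"),
         _acceptor_indices(top, "atp", rna_acceptors, atp_acceptors), "donor"),
    ]
    for donor_list, acceptor_idx, rna_side in pairs:
        if not donor_list or acceptor_idx.size == 0:
            continue
        acc_xyz = frame[acceptor_idx]
        for d_idx, h_indices in donor_list:
            dist = np.linalg.norm(acc_xyz - frame[d_idx], axis=1)
            for j in np.nonzero(dist < criteria.d_max)[0]:
                a_idx = int(acceptor_idx[j])
                ok = any(
                    _angle_deg(frame[d_idx], frame[h], frame[a_idx]) > criteria.theta_min
                    for h in h_indices)
                if not ok:
                    continue
                rna_atom = a_idx if rna_side == "acceptor" else d_idx
                m = moieties.moiety[rna_atom]
                if m == "base":
                    counts[("base", str(top.residue_name[rna_atom]))] += 1
                else:
                    counts[(m, "")] += 1
    return counts


@dataclass
class InteractionTable:
    """Mean per-frame ATP-RNA hydrogen-bond counts for one hairpin state."""

    state: str
    n_frames: int
    counts: dict               # keys as in count_hbonds, values: mean counts

    @property
    def base_total(self) -> float:
        return float(sum(v for (m, _), v in self.counts.items() if m == "base"))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"moiety": m, "nucleobase": b or "-", "mean_hbonds": v,
                 "state": self.state} for (m, b), v in self.counts.items()]
        return pd.DataFrame(rows)


def trajectory_interactions(traj: Trajectory, state: str,
                            criteria: HBondCriteria | None = None,
                            **tables) -> InteractionTable:
    """Average :func:`count_hbonds` over all frames (equal weights)."""
    criteria = criteria or HBondCriteria()
    moieties = classify_moieties(traj.topology)
    total = _zero_counts()
    for f in range(traj.n_frames):
        c = count_hbonds(traj.coords[f], traj.topology, criteria, moieties, **tables)
        for k, v in c.items():
            total[k] += v
    mean = {k: v / traj.n_frames for k, v in total.items()}
    return InteractionTable(state=state, n_frames=traj.n_frames, counts=mean)


def interaction_delta(native: InteractionTable, unwound: InteractionTable) -> dict:
    """Element-wise (unwound - native) mean hydrogen-bond counts."""
    if set(native.counts) != set(unwound.counts):
        raise ValueError("interaction tables have mismatched indices")
    return {k: unwound.counts[k] - native.counts[k] for k in native.counts}


# --- geometry ------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (deg in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def chi_torsions(frame: np.ndarray, top: Topology) -> dict:
    """Glycosidic chi torsion per RNA nucleotide, deg in (-180, 180].

    Purines (A, G): dihedral(O4', C1', N9, C4); pyrimidines (C, U):
    dihedral(O4', C1', N1, C2).  Residues with a missing defining atom get
    a NaN entry.
    """
    frame = np.asarray(frame, dtype=float)
    atoms_by_res: dict = {}
    for i in range(top.n_atoms):
        if top.residue_name[i] in RNA_RESIDUES:
            atoms_by_res.setdefault(
                (str(top.chain_id[i]), int(top.residue_index[i]),
                 str(top.residue_name[i])), {})[top.atom_name[i]] = i
    out = {}
    for (chain, resi, res), atoms in sorted(atoms_by_res.items()):
        quad = (("O4'", "C1'", "N9", "C4") if res in ("A", "G")
                else ("O4'", "C1'", "N1", "C2"))
        if all(a in atoms for a in quad):
            out[(chain, resi)] = dihedral(*(frame[atoms[a]] for a in quad))
        else:
            out[(chain, resi)] = np.nan
    return out


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    mc = mobile - mobile.mean(axis=0)
    tc = target.mean(axis=0)
    Rm = kabsch_rotation(mc, target - tc)
    return mc @ Rm.T + tc


def rmsd_to_average(traj: Trajectory, selection: np.ndarray | None = None,
                    refine_iterations: int = 2) -> np.ndarray:
    """RMSD (nm) of every frame to the iteratively refined average structure.

    Procedure: superpose all frames on frame 0 (Kabsch), average the
    coordinates, then repeat ``refine_iterations`` times: re-superpose every
    frame onto the current average and re-average.  The returned series is
    the RMSD of each superposed frame to the final average.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        sel = np.arange(traj.topology.n_atoms)
    else:
        sel = np.asarray(selection)
        sel = np.nonzero(sel)[0] if sel.dtype == bool else sel.astype(int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    X = traj.coords[:, sel, :].copy()

    # collinearity check: superposition is ill-conditioned for rank < 2
    c0 = X[0] - X[0].mean(axis=0)
    if np.linalg.matrix_rank(c0, tol=1e-10) < 2:
        import warnings
        warnings.warn("selection is (near-)collinear; superposition ill-defined",
                      stacklevel=2)

    aligned = np.stack([_superpose(X[f], X[0]) for f in range(X.shape[0])])
    avg = aligned.mean(axis=0)
    for _ in range(refine_iterations):
        aligned = np.stack([_superpose(aligned[f], avg) for f in range(X.shape[0])])
        avg = aligned.mean(axis=0)
    diff = aligned - avg
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


def backbone_selection(top: Topology) -> np.ndarray:
    """Boolean mask of nucleic-backbone atoms (phosphate + ribose chain)."""
    names = PHOSPHATE_ATOMS | {"C5'", "C4'", "C3'", "O4'", "C1'", "C2'"}
    return np.array([n in names and r in RNA_RESIDUES
                     for n, r in zip(top.atom_name, top.residue_name)])


# --- PDB I/O (via biotite) ----------------------------------------------

def read_trajectory(path, frame_time: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory (angstrom -> nm)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    top = Topology(
        atom_name=stack.atom_name,
        residue_name=np.char.strip(stack.res_name),
        residue_index=stack.res_id,
        chain_id=stack.chain_id,
        element=stack.element,
    )
    return Trajectory(topology=top, coords=np.asarray(stack.coord) / 10.0,
                      frame_time=frame_time)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file (nm -> angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.topology.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coords[f] * 10.0
        arr.atom_name = traj.topology.atom_name
        arr.res_name = traj.topology.residue_name
        arr.res_id = traj.topology.residue_index
        arr.chain_id = traj.topology.chain_id
        arr.element = traj.topology.element
        arr.hetero = np.array([r not in RNA_RESIDUES
                               for r in traj.topology.residue_name])
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
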