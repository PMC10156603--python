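"""Intersubunit bridge contacts and buried surface area on atomic models.

Companion structural analysis to the kinetic pipeline: quantifies which
intersubunit bridges (named SSU--LSU contacts such as B2b, B7a, B8, eB8,
eB13) are formed in an atomic model of the ribosome, how individual
contact points change between two conformations (e.g. SSU rolling in the
GA-to-AC transition), and how much surface a bound small molecule buries
against its receptor.

Rules
-----
* A bridge contact point -- a pair of residues, one per subunit -- is
  *formed* when any two non-hydrogen atoms of the two residues are within
  4.0 A (inclusive).
* Every contact point of a bridge contributes equally; total formation is
  the percentage of points formed.
* The change between two models compares *individual* contact points, not
  the totals: two models can share the same total percentage while every
  individual point changed.
* Buried surface area is SASA(receptor) + SASA(ligand) - SASA(complex),
  with a Shrake--Rupley numeric-sphere SASA (960 Fibonacci points per
  atom, probe 1.4 A, Bondi van der Waals radii, hydrogens excluded).

File I/O goes through gemmi (PDB and mmCIF).  Residue-level bridge
definitions are supplied as a TSV (bridge, chain_a, resid_a, chain_b,
resid_b); the packaged default list is a fixture-scale placeholder -- real
analyses should supply the assignment scheme for their numbering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomicModel",
    "BridgeDefinition",
    "load_model",
    "load_bridge_definitions",
    "contact_formed",
    "bridge_formation",
    "bridge_change",
    "buried_surface_area",
    "shrake_rupley_sasa",
    "write_fixture",
]

# Bondi (1964) van der Waals radii, A
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "K": 2.75, "NA": 2.27, "ZN": 1.39,
}
DEFAULT_RADIUS = 1.70


class StructureError(ValueError):
    pass


class MissingResidueError(KeyError):
    pass


@dataclass
class AtomicModel:
    """Flat atom table of one coordinate model.

    Residues are addressed by (chain id, author residue number); insertion
    codes are appended to the residue number string when present.
    """

    chain: np.ndarray     # str per atom
    resid: np.ndarray     # author residue number (str, incl. insertion code)
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray       # (n, 3) A
    is_hetero: np.ndarray
    partition: dict[str, str] = field(default_factory=dict)  # chain -> SSU|LSU|ligand|factor
    _res_index: dict[tuple[str, str], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.xyz).all():
            raise StructureError("non-finite coordinates in model")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def residue_atoms(self, chain: str, resid: int | str) -> np.ndarray:
        """Indices of the atoms of one residue (empty if absent)."""
        if self._res_index is None:
            idx: dict[tuple[str, str], list[int]] = {}
            for i, (c, r) in enumerate(zip(self.chain, self.resid)):
                idx.setdefault((c, r), []).append(i)
            self._res_index = {k: np.array(v) for k, v in idx.items()}
        return self._res_index.get((chain, str(resid)), np.array([], dtype=int))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Rigid-body transformed copy (used by invariance tests)."""
        out = AtomicModel(
            chain=self.chain, resid=self.resid, resname=self.resname,
            atom_name=self.atom_name, element=self.element,
            xyz=self.xyz @ np.asarray(rotation).T + np.asarray(translation),
            is_hetero=self.is_hetero, partition=dict(self.partition),
        )
        return out


def load_model(
    path: str | Path,
    fmt: str | None = None,
    partition: dict[str, str] | None = None,
) -> AtomicModel:
    """Load an atomic model from PDB or mmCIF (all ATOM/HETATM records).

    ``fmt`` may be "pdb" or "mmcif"; by default the format is inferred
    from the file contents/extension.  Heteroatoms are retained and
    flagged.
    """
    path = Path(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path.name}: no coordinate models")
    model = st[0]
    chains, resids, resnames, names, elements, het = [], [], [], [], [], []
    coords = []
    for chain in model:
        for res in chain:
            rid = str(res.seqid.num) + (res.seqid.icode.strip() or "")
            for atom in res:
                chains.append(chain.name)
                resids.append(rid)
                resnames.append(res.name)
                names.append(atom.name)
                elements.append(atom.element.name.upper())
                het.append(res.het_flag == "H")
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise StructureError(f"{path.name}: no atoms parsed")
    return AtomicModel(
        chain=np.array(chains),
        resid=np.array(resids),
        resname=np.array(resnames),
        atom_name=np.array(names),
        element=np.array(elements),
        xyz=np.array(coords, dtype=float),
        is_hetero=np.array(het, dtype=bool),
        partition=partition or {},
    )


# ---------------------------------------------------------------------------
# Bridge definitions and contact rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BridgeDefinition:
    """A named intersubunit bridge as a list of residue contact points."""

    name: str
    points: tuple[tuple[tuple[str, str], tuple[str, str]], ...]  # ((chain,res),(chain,res))

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise StructureError(f"bridge {self.name!r} has no contact points")


def load_bridge_definitions(path: str | Path | None = None) -> list[BridgeDefinition]:
    """Read bridge definitions from TSV (bridge, chain_a, resid_a, chain_b,
    resid_b).  Without a path, the packaged placeholder list is loaded."""
    if path is None:
        src = resources.files("smdecode") / "presets" / "bridge_definitions.tsv"
        df = pd.read_csv(str(src), sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"bridge", "chain_a", "resid_a", "chain_b", "resid_b"}
    if not required.issubset(df.columns):
        raise StructureError(f"bridge TSV must have columns {sorted(required)}")
    out = []
    for name, grp in df.groupby("bridge", sort=False):
        points = tuple(
            ((row.chain_a, str(row.resid_a)), (row.chain_b, str(row.resid_b)))
            for row in grp.itertuples()
        )
        out.append(BridgeDefinition(name=str(name), points=points))
    return out


def contact_formed(
    model: AtomicModel,
    residue_pair: tuple[tuple[str, str | int], tuple[str, str | int]],
    threshold: float = 4.0,
) -> tuple[bool, float]:
    """Whether two residues form a contact (min heavy-atom distance <= 4 A).

    Returns (formed, minimum inter-atomic distance).  Hydrogens are
    ignored.  Raises :class:`MissingResidueError` if either residue is
    absent from the model.
    """
    (ca, ra), (cb, rb) = residue_pair
    ia = model.residue_atoms(ca, ra)
    ib = model.residue_atoms(cb, rb)
    for idx, key in ((ia, (ca, ra)), (ib, (cb, rb))):
        if idx.size == 0:
            raise MissingResidueError(f"residue {key} not in model")
    ia = ia[model.element[ia] != "H"]
    ib = ib[model.element[ib] != "H"]
    if ia.size == 0 or ib.size == 0:
        raise MissingResidueError(f"no heavy atoms for pair {residue_pair}")
    d = np.linalg.norm(model.xyz[ia][:, None, :] - model.xyz[ib][None, :, :], axis=2)
    dmin = float(d.min())
    return dmin <= threshold, dmin


def _point_status(
    model: AtomicModel, definitions: list[BridgeDefinition], threshold: float
) -> pd.DataFrame:
    rows = []
    for bdef in definitions:
        for pt in bdef.points:
            try:
                formed, dmin = contact_formed(model, pt, threshold)
                rows.append((bdef.name, pt, formed, dmin, True))
            except MissingResidueError:
                rows.append((bdef.name, pt, False, np.nan, False))
    return pd.DataFrame(rows, columns=["bridge", "point", "formed", "min_dist", "resolved"])


def bridge_formation(
    model: AtomicModel,
    definitions: list[BridgeDefinition],
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Percentage of contact points formed for each bridge.

    Unresolved residues (absent from the model) are excluded from the
    denominator with a warning.  Returns one row per bridge with columns
    n_formed, n_points, n_unresolved, percent_formed.
    """
    if not definitions:
        raise StructureError("empty bridge definition set")
    status = _point_status(model, definitions, threshold)
    n_unres = int((~status["resolved"]).sum())
    if n_unres:
        warnings.warn(f"{n_unres} bridge contact points unresolved in model", stacklevel=2)
    rows = []
    for name, grp in status.groupby("bridge", sort=False):
        res = grp[grp["resolved"]]
        n_formed = int(res["formed"].sum())
        n_total = len(res)
        rows.append(
            {
                "bridge": name,
                "n_formed": n_formed,
                "n_points": n_total,
                "n_unresolved": int((~grp["resolved"]).sum()),
                "percent_formed": 100.0 * n_formed / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def bridge_change(
    model_a: AtomicModel,
    model_b: AtomicModel,
    definitions: list[BridgeDefinition],
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Per-bridge change in *individual* contact points between two models.

    For each bridge: the total percentages in A and B, the number of
    points gained (formed in B only) and lost (formed in A only), and the
    signed individual-point change -- the percentage of contact points
    whose status differs, with the sign of the net gain.  Swapping the
    models flips the sign.
    """
    if not definitions:
        raise StructureError("empty bridge definition set")
    sa = _point_status(model_a, definitions, threshold)
    sb = _point_status(model_b, definitions, threshold)
    merged = sa.merge(sb, on=["bridge", "point"], suffixes=("_a", "_b"))
    rows = []
    for name, grp in merged.groupby("bridge", sort=False):
        res = grp[grp["resolved_a"] & grp["resolved_b"]]
        n = len(res)
        gained = int((res["formed_b"] & ~res["formed_a"]).sum())
        lost = int((res["formed_a"] & ~res["formed_b"]).sum())
        changed = gained + lost
        sign = 1.0 if gained >= lost else -1.0
        rows.append(
            {
                "bridge": name,
                "percent_a": 100.0 * res["formed_a"].sum() / n if n else np.nan,
                "percent_b": 100.0 * res["formed_b"].sum() / n if n else np.nan,
                "n_gained": gained,
                "n_lost": lost,
                "individual_change_percent": sign * 100.0 * changed / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shrake--Rupley SASA and buried surface area
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    xyz: np.ndarray,
    elements: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), heavy atoms only.

    Numeric-sphere (Shrake--Rupley) algorithm: each atom's expanded sphere
    (vdW radius + probe) is sampled with ``n_points`` Fibonacci points and
    the accessible fraction is the fraction of points outside every
    neighbour's expanded sphere.
    """
    xyz = np.asarray(xyz, dtype=float)
    heavy = np.asarray(elements) != "H"
    radii = np.array([VDW_RADII.get(e, DEFAULT_RADIUS) for e in elements]) + probe
    sphere = _fibonacci_sphere(n_points)
    sasa = np.zeros(xyz.shape[0])
    hidx = np.flatnonzero(heavy)
    if hidx.size == 0:
        return sasa
    pos = xyz[hidx]
    rad = radii[hidx]
    tree = cKDTree(pos)
    rmax = rad.max()
    for a, (p, r) in enumerate(zip(pos, rad)):
        pts = p + r * sphere
        neigh = tree.query_ball_point(p, r + rmax)
        neigh = [j for j in neigh if j != a]
        acc = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            acc &= d2 > rad[j] ** 2
        sasa[hidx[a]] = acc.mean() * 4.0 * math.pi * r * r
    return sasa


def buried_surface_area(
    model: AtomicModel,
    ligand_mask: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried surface area (A^2) between a ligand selection and the rest.

    BSA = SASA(receptor alone) + SASA(ligand alone) - SASA(complex).
    ``ligand_mask`` is a boolean per-atom selection; it must be non-empty
    and must not cover the whole model.
    """
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if ligand_mask.sum() == 0:
        raise StructureError("empty ligand selection")
    if ligand_mask.all():
        raise StructureError("ligand selection covers the entire model")
    sasa_complex = shrake_rupley_sasa(model.xyz, model.element, probe, n_points).sum()
    lig = ligand_mask
    rec = ~ligand_mask
    sasa_lig = shrake_rupley_sasa(model.xyz[lig], model.element[lig], probe, n_points).sum()
    sasa_rec = shrake_rupley_sasa(model.xyz[rec], model.element[rec], probe, n_points).sum()
    return float(sasa_rec + sasa_lig - sasa_complex)


def ligand_mask_by_resname(model: AtomicModel, resname: str) -> np.ndarray:
    return model.resname == resname


def ligand_mask_by_chain(model: AtomicModel, chain: str) -> np.ndarray:
    return model.chain == chain


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def write_fixture(
    atoms: list[dict],
    path: str | Path,
    fmt: str = "pdb",
) -> Path:
    """Write a toy structure to a standards-conformant PDB or mmCIF file.

    ``atoms`` is a list of dicts with keys chain, resid, resname, name,
    element, x, y, z.  The file round-trips exactly through
    :func:`load_model` (coordinates to PDB precision, 1e-3 A).
    """
    st = gemmi.Structure()
    st.name = "fixture"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for spec in atoms:
        cid = str(spec["chain"])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        chain = chains[cid]
        resid = int(spec["resid"])
        res = None
        for existing in chain:
            if existing.seqid.num == resid:
                res = existing
                break
        if res is None:
            res = gemmi.Residue()
            res.name = str(spec["resname"])
            res.seqid = gemmi.SeqId(resid, " ")
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = str(spec["name"])
        atom.element = gemmi.Element(str(spec["element"]))
        atom.pos = gemmi.Position(float(spec["x"]), float(spec["y"]), float(spec["z"]))
        atom.occ = 1.0
        atom.b_iso = 10.0
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureError(f"unknown format {fmt!r}")
    return path
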