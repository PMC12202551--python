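"""Halo-adaptation profiling from sequence and structure.

Halophilic proteins show a characteristic signature: enrichment of surface
aspartate/glutamate, preference for arginine over lysine on the surface,
and dense salt-bridge networks.  This module computes those metrics from a
coordinate model with explicit, tool-independent criteria:

* solvent-accessible surface area by the Shrake–Rupley rolling-probe
  algorithm on a fixed deterministic sphere-point set (default 960 points,
  probe 1.4 Å),
* relative accessibility against a theoretical maximum-ASA reference scale
  (Tien et al. style values), surface exposure at a >= 10 % cutoff,
* salt bridges as carboxylate-oxygen-to-basic-nitrogen contacts within a
  distance cutoff (default 4.0 Å), histidine counted as basic by default.

Exact agreement with third-party tools (GETAREA, SwissPDB viewer, RING) is
not claimed; the criteria here are fixed and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InputError, ParseError

# van der Waals radii (Å) by element, Bondi-style values.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

# Theoretical maximum accessible surface areas per residue (Å², Tien-style
# theoretical scale) used for relative accessibility.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    xyz: tuple[float, float, float]
    element: str

    def __post_init__(self) -> None:
        if not self.element:
            raise InputError(f"atom {self.serial}: empty element")
        if not all(np.isfinite(self.xyz)):
            raise InputError(f"atom {self.serial}: non-finite coordinates")


ResidueKey = tuple[str, int]  # (chain, residue_number)


@dataclass
class StructureModel:
    """Ordered atom collection for one coordinate model."""

    atoms: list[Atom]
    id: str = "model"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError(f"structure {self.id!r}: no atoms")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.name)
            if key in seen:
                raise InputError(
                    f"structure {self.id!r}: duplicate atom {key}"
                )
            seen.add(key)

    def residues(self) -> dict[ResidueKey, tuple[str, list[Atom]]]:
        """Atoms grouped by residue, preserving atom order."""
        out: dict[ResidueKey, tuple[str, list[Atom]]] = {}
        for a in self.atoms:
            key = (a.chain, a.residue_number)
            if key not in out:
                out[key] = (a.residue_name, [])
            out[key][1].append(a)
        return out

    def sequence(self) -> str:
        """One-letter sequence in residue order; unknown residues -> 'X'."""
        return "".join(
            THREE_TO_ONE.get(name, "X")
            for name, _ in self.residues().values()
        )

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


def read_pdb(path) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file.

    Only the first MODEL is used; alternate locations other than blank or
    'A' are dropped.  Parsing is delegated to gemmi.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=atom.name,
                        residue_name=res.name,
                        chain=chain.name or "A",
                        residue_number=res.seqid.num,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        element=atom.element.name.upper(),
                    )
                )
    return StructureModel(atoms=atoms, id=st.name or str(path))


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal fixed-column PDB file."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   lovkit model {model.id}\n")
        for a in model.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
                f"{a.chain:1s}{a.residue_number:4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Residue composition
# ---------------------------------------------------------------------------


def residue_composition(seq: str) -> dict[str, tuple[int, float]]:
    """Counts and fractions per residue; fractions sum to 1."""
    if not seq:
        raise InputError("empty sequence")
    allowed = set(THREE_TO_ONE.values()) | {"X"}
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise InputError(f"invalid residue {ch!r} at position {i}")
    total = len(seq)
    out: dict[str, tuple[int, float]] = {}
    for ch in sorted(set(seq)):
        n = seq.count(ch)
        out[ch] = (n, n / total)
    return out


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (Å²)."""

    model: StructureModel
    atom_areas: np.ndarray
    probe_radius: float
    n_points: int
    residue_areas: dict[ResidueKey, float] = field(init=False)
    residue_names: dict[ResidueKey, str] = field(init=False)

    def __post_init__(self) -> None:
        self.residue_areas = {}
        self.residue_names = {}
        for atom, area in zip(self.model.atoms, self.atom_areas):
            key = (atom.chain, atom.residue_number)
            self.residue_areas[key] = self.residue_areas.get(key, 0.0) + area
            self.residue_names[key] = atom.residue_name

    def relative_accessibility(
        self, reference_scale: Mapping[str, float] | None = None
    ) -> dict[ResidueKey, float]:
        scale = MAX_ASA if reference_scale is None else reference_scale
        out = {}
        for key, area in self.residue_areas.items():
            name = self.residue_names[key]
            if name not in scale:
                raise InputError(
                    f"residue {name} at {key} missing from reference scale"
                )
            out[key] = area / scale[name]
        return out


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    default_radius: float | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's probe-expanded sphere is sampled at ``n_points`` fixed
    quasi-uniform points; a point is accessible when it lies outside every
    other atom's expanded sphere.  ``default_radius`` substitutes for
    elements missing from the radius table; without it an unknown element
    raises.
    """
    table = dict(VDW_RADII if radii is None else radii)
    rs = np.empty(len(model.atoms))
    for i, atom in enumerate(model.atoms):
        r = table.get(atom.element)
        if r is None:
            if default_radius is None:
                raise InputError(
                    f"unknown element {atom.element!r} (atom {atom.serial}); "
                    "supply default_radius to proceed"
                )
            r = default_radius
        rs[i] = r
    coords = model.coordinates()
    expanded = rs + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(model.atoms))
    for i in range(len(model.atoms)):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], max_reach)
            if j != i
            and np.linalg.norm(coords[j] - coords[i])
            < expanded[i] + expanded[j]
        ]
        pts = coords[i] + expanded[i] * unit
        if neighbors:
            nb = coords[np.array(neighbors)]
            nr = expanded[np.array(neighbors)]
            d2 = ((pts[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return SasaResult(
        model=model,
        atom_areas=areas,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def surface_exposed_residues(
    sasa: SasaResult,
    cutoff_fraction: float = 0.10,
    reference_scale: Mapping[str, float] | None = None,
) -> set[ResidueKey]:
    """Residues whose relative accessibility is >= the cutoff (default 10 %)."""
    rel = sasa.relative_accessibility(reference_scale)
    return {key for key, frac in rel.items() if frac >= cutoff_fraction}


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaltBridge:
    """Ionic contact between an acidic carboxylate and a basic group."""

    acidic: tuple[str, int, str]  # chain, residue number, residue name
    basic: tuple[str, int, str]
    min_distance: float


def detect_salt_bridges(
    model: StructureModel,
    cutoff: float = 4.0,
    include_his: bool = True,
) -> list[SaltBridge]:
    """Salt bridges: Asp/Glu carboxylate O to Arg/Lys(/His) side-chain N.

    A bridge is reported once per residue pair with the minimum
    charged-atom distance; charged residues lacking their side-chain atoms
    are skipped with a warning.
    """
    basic_atoms = dict(BASIC_ATOMS)
    if not include_his:
        basic_atoms.pop("HIS")
    residues = model.residues()
    acidic_groups: list[tuple[tuple[str, int, str], np.ndarray]] = []
    basic_groups: list[tuple[tuple[str, int, str], np.ndarray]] = []
    n_skipped = 0
    for (chain, num), (name, atoms) in residues.items():
        if name in ACIDIC_ATOMS:
            coords = [a.xyz for a in atoms if a.name in ACIDIC_ATOMS[name]]
            if coords:
                acidic_groups.append(((chain, num, name), np.array(coords)))
            else:
                n_skipped += 1
        if name in basic_atoms:
            coords = [a.xyz for a in atoms if a.name in basic_atoms[name]]
            if coords:
                basic_groups.append(((chain, num, name), np.array(coords)))
            else:
                n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} charged residue(s) lacked side-chain atoms and "
            "were skipped",
            stacklevel=2,
        )
    bridges = []
    for (akey, acoords) in acidic_groups:
        for (bkey, bcoords) in basic_groups:
            if akey[:2] == bkey[:2]:
                continue
            dmin = float(
                np.sqrt(
                    ((acoords[:, None, :] - bcoords[None, :, :]) ** 2)
                    .sum(axis=2)
                    .min()
                )
            )
            if dmin <= cutoff:
                bridges.append(
                    SaltBridge(acidic=akey, basic=bkey, min_distance=dmin)
                )
    bridges.sort(key=lambda b: (b.acidic, b.basic))
    return bridges


# ---------------------------------------------------------------------------
# Halo profile
# ---------------------------------------------------------------------------


@dataclass
class HaloProfile:
    """Combined halo-adaptation metrics for one structure."""

    structure_id: str
    counts: dict[str, int]  # whole-sequence counts of D, E, R, K
    fractions: dict[str, float]
    exposed_counts: dict[str, int]  # D, E, R, K among exposed residues
    exposed_de: int
    exposed_arg_pct: float  # % of exposed residues that are Arg
    exposed_lys_pct: float
    n_exposed: int
    salt_bridges: list[SaltBridge]

    @property
    def n_salt_bridges(self) -> int:
        return len(self.salt_bridges)


def halo_profile(
    model: StructureModel,
    seq: str | None = None,
    sasa_cutoff: float = 0.10,
    bridge_cutoff: float = 4.0,
    include_his: bool = True,
    probe_radius: float = 1.4,
    n_points: int = 960,
    reference_scale: Mapping[str, float] | None = None,
) -> HaloProfile:
    """Full halo-adaptation profile: composition, exposure, bridge census."""
    sequence = seq if seq is not None else model.sequence()
    comp = residue_composition(sequence)
    counts = {aa: comp.get(aa, (0, 0.0))[0] for aa in "DERK"}
    fractions = {aa: comp.get(aa, (0, 0.0))[1] for aa in "DERK"}

    sasa = shrake_rupley_sasa(
        model, probe_radius=probe_radius, n_points=n_points
    )
    exposed = surface_exposed_residues(
        sasa, cutoff_fraction=sasa_cutoff, reference_scale=reference_scale
    )
    res_names = sasa.residue_names
    exposed_counts = {aa: 0 for aa in "DERK"}
    for key in exposed:
        one = THREE_TO_ONE.get(res_names[key], "X")
        if one in exposed_counts:
            exposed_counts[one] += 1
    n_exposed = len(exposed)
    arg_pct = 100.0 * exposed_counts["R"] / n_exposed if n_exposed else 0.0
    lys_pct = 100.0 * exposed_counts["K"] / n_exposed if n_exposed else 0.0

    bridges = detect_salt_bridges(
        model, cutoff=bridge_cutoff, include_his=include_his
    )
    return HaloProfile(
        structure_id=model.id,
        counts=counts,
        fractions=fractions,
        exposed_counts=exposed_counts,
        exposed_de=exposed_counts["D"] + exposed_counts["E"],
        exposed_arg_pct=arg_pct,
        exposed_lys_pct=lys_pct,
        n_exposed=n_exposed,
        salt_bridges=bridges,
    )
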