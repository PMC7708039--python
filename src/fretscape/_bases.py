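"""Idealized planar nucleobase templates and Watson-Crick pair assembly.

Bases are built as regular polygons (bond length 1.38 A) with exocyclic
substituents placed radially; the two bases of a pair are then docked by a
rigid 2-D fit that puts the Watson-Crick hydrogen-bond donor/acceptor pairs
2.90 A apart.  Each assembled pair template is expressed in the pair frame
used throughout the package:

* origin at the midpoint of the two C1' atoms,
* +y from the top-strand C1' toward the bottom-strand C1',
* +x toward the major-groove edge of the bases (minor groove at -x),
* +z completing a right-handed frame (the helix is stacked along +z).

The duplex generator and the geometry descriptors share these conventions,
which is what makes generator round-trip tests exact by construction.
"""
from __future__ import annotations

import numpy as np

RING_BOND = 1.38     # aromatic ring bond length, A
B_CO = 1.23          # exocyclic C=O bond, A
B_CN = 1.34          # exocyclic C-N bond, A
B_GLY = 1.47         # glycosidic N-C1' bond, A
HBOND = 2.90         # donor-acceptor heavy atom distance, A
SUGAR_OFFSET = 1.40  # sugar-ring centroid distance beyond C1', A
SUGAR_RADIUS = 1.20  # pseudo sugar-ring radius, A

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

#: aromatic ring atoms per base (used for base-ring centroids)
RING_ATOMS = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: sugar-ring atoms (C1' plus the pseudo-ring)
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

GLYCOSIDIC = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}


def _polar(angle_deg: float, radius: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return radius * np.array([np.cos(a), np.sin(a)])


def _pyrimidine(base: str) -> dict[str, np.ndarray]:
    """Pyrimidine with its WC edge (N3 and substituents) facing +y.

    Ring order N1..C6 runs clockwise so O2 lands on the minor-groove (-x)
    side and N4/O4 on the major-groove (+x) side.
    """
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = {n: _polar(210.0 - 60.0 * j, RING_BOND) for j, n in enumerate(names)}
    angle = {n: 210.0 - 60.0 * j for j, n in enumerate(names)}
    atoms["O2"] = _polar(angle["C2"], RING_BOND + B_CO)
    if base == "C":
        atoms["N4"] = _polar(angle["C4"], RING_BOND + B_CN)
    else:  # T
        atoms["O4"] = _polar(angle["C4"], RING_BOND + B_CO)
        atoms["C7"] = _polar(angle["C5"], RING_BOND + 1.50)
    atoms["C1'"] = _polar(angle["N1"], RING_BOND + B_GLY)
    return atoms


def _fused_pentagon(c4: np.ndarray, c5: np.ndarray) -> dict[str, np.ndarray]:
    """Regular pentagon N7/C8/N9 fused on the C4-C5 edge, away from the origin."""
    side = np.linalg.norm(c5 - c4)
    mid = 0.5 * (c4 + c5)
    out = mid / np.linalg.norm(mid)  # hexagon is centered at the origin
    apothem = side / (2.0 * np.tan(np.deg2rad(36.0)))
    center = mid + apothem * out
    radius = side / (2.0 * np.sin(np.deg2rad(36.0)))

    def ang(p: np.ndarray) -> float:
        v = p - center
        return np.rad2deg(np.arctan2(v[1], v[0]))

    a4, a5 = ang(c4), ang(c5)
    step = ((a5 - a4 + 180.0) % 360.0) - 180.0  # signed +-72
    out_atoms = {}
    for k, name in enumerate(("N7", "C8", "N9"), start=2):
        a = a4 + step * k
        out_atoms[name] = center + radius * np.array(
            [np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))]
        )
    out_atoms["_pent_center"] = center
    return out_atoms


def _purine(base: str) -> dict[str, np.ndarray]:
    """Purine with its WC edge (N1 and substituents) facing -y."""
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = {n: _polar(-90.0 - 60.0 * j, RING_BOND) for j, n in enumerate(names)}
    angle = {n: -90.0 - 60.0 * j for j, n in enumerate(names)}
    pent = _fused_pentagon(atoms["C4"], atoms["C5"])
    center5 = pent.pop("_pent_center")
    atoms.update(pent)
    if base == "G":
        atoms["O6"] = _polar(angle["C6"], RING_BOND + B_CO)
        atoms["N2"] = _polar(angle["C2"], RING_BOND + B_CN)
    else:  # A
        atoms["N6"] = _polar(angle["C6"], RING_BOND + B_CN)
    v = atoms["N9"] - center5
    atoms["C1'"] = atoms["N9"] + B_GLY * v / np.linalg.norm(v)
    return atoms


def _rigid_fit_2d(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper 2-D rotation R and translation t minimizing |R s + t - d|^2."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        Vt = Vt.copy()
        Vt[-1] *= -1
        R = Vt.T @ U.T
    return R, dc - R @ sc


def _dock_purine(pyr: dict, pur: dict, bonds: list[tuple[str, str]]) -> dict:
    """Place the purine above the pyrimidine so each WC bond is HBOND along +y."""
    src = np.array([pur[p] for p, _ in bonds])
    dst = np.array([pyr[q] + np.array([0.0, HBOND]) for _, q in bonds])
    R, t = _rigid_fit_2d(src, dst)
    return {k: R @ v + t for k, v in pur.items()}


#: WC hydrogen bonds as (purine atom, pyrimidine atom)
WC_BONDS = {
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("A", "T"): [("N1", "N3"), ("N6", "O4")],
}


def _sugar(atoms_2d: dict[str, np.ndarray], base: str) -> dict[str, np.ndarray]:
    """Pseudo sugar ring in 3-D, hung radially off C1' away from the base."""
    c1 = np.append(atoms_2d["C1'"], 0.0)
    ngly = np.append(atoms_2d[GLYCOSIDIC[base]], 0.0)
    u = c1 - ngly
    u /= np.linalg.norm(u)
    center = c1 + SUGAR_OFFSET * u
    v = -u  # in-plane direction back toward C1'
    z = np.array([0.0, 0.0, 1.0])
    out = {}
    for k, name in enumerate(("C2'", "C3'", "C4'", "O4'"), start=1):
        a = np.deg2rad(72.0 * k)
        out[name] = center + SUGAR_RADIUS * (np.cos(a) * v + np.sin(a) * z)
    return out


def _assemble_canonical(pur_base: str) -> dict[str, dict[str, np.ndarray]]:
    """Canonical pair, purine at +y / pyrimidine at -y, in the pair frame."""
    pyr_base = COMPLEMENT[pur_base]
    pyr = _pyrimidine(pyr_base)
    pur = _dock_purine(pyr, _purine(pur_base), WC_BONDS[(pur_base, pyr_base)])

    # lift to 3-D and add sugars
    def lift(d: dict, base: str) -> dict[str, np.ndarray]:
        out = {k: np.append(v, 0.0) for k, v in d.items()}
        out.update(_sugar(d, base))
        return out

    pair = {pyr_base: lift(pyr, pyr_base), pur_base: lift(pur, pur_base)}

    # re-express in the pair frame: C1' midpoint at origin, pyrimidine C1'
    # -> purine C1' along +y (rotation about z only, chirality preserved)
    c1_pyr = pair[pyr_base]["C1'"]
    c1_pur = pair[pur_base]["C1'"]
    mid = 0.5 * (c1_pyr + c1_pur)
    yv = c1_pur - c1_pyr
    ang = np.arctan2(yv[0], yv[1])  # rotate so yv maps onto +y
    c, s = np.cos(ang), np.sin(ang)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    for base in pair:
        for k in pair[base]:
            pair[base][k] = R @ (pair[base][k] - mid)
    return pair


_CANONICAL = {b: _assemble_canonical(b) for b in ("G", "A")}


def pair_template(top_base: str) -> dict[str, dict[str, np.ndarray]]:
    """Atoms of the base pair whose top (W) strand base is ``top_base``.

    Returns ``{"W": {atom: xyz}, "Y": {atom: xyz}}`` in the pair frame
    (top-strand C1' at -y, bottom-strand C1' at +y, major groove at +x).
    """
    top_base = top_base.upper()
    if top_base not in COMPLEMENT:
        raise ValueError(f"unknown base {top_base!r}; sequence must use A/C/G/T")
    bot_base = COMPLEMENT[top_base]
    pur = top_base if top_base in ("G", "A") else bot_base
    canon = _CANONICAL[pur]
    if top_base in ("C", "T"):
        # pyrimidine already sits at -y: top strand as-is
        return {
            "W": {k: v.copy() for k, v in canon[top_base].items()},
            "Y": {k: v.copy() for k, v in canon[bot_base].items()},
        }
    # purine on the top strand: rotate the pair 180 deg about x
    # (y -> -y, z -> -z) so the purine moves to the -y (top) side while
    # keeping the frame right-handed and the major groove at +x.
    flip = np.diag([1.0, -1.0, -1.0])
    return {
        "W": {k: flip @ v for k, v in canon[top_base].items()},
        "Y": {k: flip @ v for k, v in canon[bot_base].items()},
    }
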