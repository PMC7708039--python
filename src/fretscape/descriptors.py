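"""DNA geometry descriptors for duplex models and ensembles.

All descriptors are built from simplified base-pair frames (C1'-based, not
full standard-reference-frame fits): origin at the C1'-C1' midpoint, y along
the top->bottom C1' vector, z along the local helical direction
orthogonalized against y, x = y cross z.  The duplex generator shares these
conventions, so generator round trips are exact by construction.

Pair numbers are 1-based positions along the top strand, matching the
W1..Wn numbering of duplex constructs; step k lies between pairs k and k+1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import _bases
from .structure import StructureModel

__all__ = [
    "BasePairFrame",
    "DescriptorSeries",
    "MissingAtomsError",
    "basepair_frames",
    "step_twist",
    "cumulative_twist",
    "twist_series",
    "untwist_angle",
    "bend_angle",
    "bend_direction_dihedral",
    "base_extrusion_dihedral",
    "hydrogen_bonds",
    "block_average",
    "block_scan",
    "dihedral",
]


class MissingAtomsError(ValueError):
    """A descriptor's required atoms are absent; ``missing`` lists them."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing atoms: " + ", ".join(self.missing))


@dataclass(frozen=True)
class BasePairFrame:
    """Right-handed orthonormal frame attached to one base pair."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


@dataclass
class DescriptorSeries:
    """Per-model values of one geometric descriptor with block statistics."""

    name: str
    values: np.ndarray
    unit: str = "degrees"
    mean: float | None = None
    block_sd: float | None = None
    n_blocks: int | None = None
    meta: dict = field(default_factory=dict)

    def with_blocks(self, n_blocks: int) -> "DescriptorSeries":
        mean, sd = block_average(self.values, n_blocks)
        return DescriptorSeries(self.name, self.values, self.unit,
                                mean, sd, n_blocks, dict(self.meta))


# ---------------------------------------------------------------------------
# frames and twist
# ---------------------------------------------------------------------------


def basepair_frames(model: StructureModel, model_index: int = 0
                    ) -> list[BasePairFrame]:
    """One frame per base pair of ``model.pairing`` (5'->3' top-strand order).

    Raises
    ------
    MissingAtomsError
        Naming every absent C1' atom, e.g. for crystal models with
        unresolved residues.
    """
    if len(model.pairing) < 2:
        raise ValueError("need at least 2 base pairs to define frames")
    missing: list[str] = []
    c1w, c1y = [], []
    for (wc, wr), (yc, yr) in model.pairing:
        a = model.single_atom(wc, wr, "C1'", model_index)
        b = model.single_atom(yc, yr, "C1'", model_index)
        if a is None:
            missing.append(f"{wc}:{wr}:C1'")
        if b is None:
            missing.append(f"{yc}:{yr}:C1'")
        c1w.append(a)
        c1y.append(b)
    if missing:
        raise MissingAtomsError(missing)
    origins = np.array([0.5 * (a + b) for a, b in zip(c1w, c1y)])
    frames = []
    n = len(origins)
    for j in range(n):
        y = c1y[j] - c1w[j]
        y = y / np.linalg.norm(y)
        lo, hi = max(j - 1, 0), min(j + 1, n - 1)
        d = origins[hi] - origins[lo]
        z = d - (d @ y) * y
        nz = np.linalg.norm(z)
        if nz < 1e-9:
            raise ValueError(f"degenerate helical direction at pair {j + 1}")
        z = z / nz
        x = np.cross(y, z)
        frames.append(BasePairFrame(origins[j], x, y, z))
    return frames


def step_twist(frames: list[BasePairFrame], step: int) -> float:
    """Signed twist (degrees) of step ``step`` (between pairs step, step+1).

    The angle is measured between successive y axes about the mean local z
    axis, in (-180, 180].
    """
    if not 1 <= step <= len(frames) - 1:
        raise IndexError(f"step {step} outside 1..{len(frames) - 1}")
    f1, f2 = frames[step - 1], frames[step]
    zm = f1.z + f2.z
    zm = zm / np.linalg.norm(zm)
    y1 = f1.y - (f1.y @ zm) * zm
    y2 = f2.y - (f2.y @ zm) * zm
    ang = np.degrees(np.arctan2(zm @ np.cross(y1, y2), y1 @ y2))
    return float(ang)


def cumulative_twist(frames: list[BasePairFrame], from_pair: int,
                     to_pair: int) -> float:
    """Sum of step twists from pair ``from_pair`` to ``to_pair`` (degrees).

    A span W14 -> W19 covers 5 steps.
    """
    if to_pair <= from_pair:
        raise ValueError("to_pair must exceed from_pair")
    return float(sum(step_twist(frames, k) for k in range(from_pair, to_pair)))


def twist_series(model: StructureModel, from_pair: int, to_pair: int
                 ) -> np.ndarray:
    """Per-model cumulative twist (degrees) over a span, for an ensemble."""
    return np.array(
        [
            cumulative_twist(basepair_frames(model, m), from_pair, to_pair)
            for m in range(model.n_models)
        ]
    )


def untwist_angle(cumulative_twists, twist_initial,
                  n_blocks: int | None = None) -> DescriptorSeries:
    """Untwist = Twist_initial - Twist, per model.

    Positive values mean further *untwisting* relative to the reference,
    negative values further twisting.

    Parameters
    ----------
    cumulative_twists : array
        Cumulative twist per model over the span of interest (degrees).
    twist_initial : float or array
        Reference twist: either a number, or the reference sub-ensemble's
        cumulative twists (e.g. the early part of a trajectory), which are
        averaged.
    n_blocks : int, optional
        Attach block-averaged mean and SD when given.
    """
    twists = np.asarray(cumulative_twists, dtype=float)
    ref = np.asarray(twist_initial, dtype=float)
    if ref.ndim > 0:
        if ref.size == 0:
            raise ValueError("empty reference ensemble for twist_initial")
        ref = ref.mean()
    series = DescriptorSeries(
        "untwist", ref - twists, "degrees",
        meta={"twist_initial": float(ref)},
    )
    if n_blocks is not None:
        series = series.with_blocks(n_blocks)
    return series


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------


def _arm_axis(origins: np.ndarray) -> np.ndarray:
    """Principal axis of base-pair origins, oriented 5'->3'."""
    centered = origins - origins.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (origins[-1] - origins[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _check_arms(n_pairs: int, hinge: int, arm_length: int) -> None:
    if arm_length < 2:
        raise ValueError("arm_length must be >= 2")
    if hinge - arm_length < 1 or hinge + arm_length > n_pairs:
        raise ValueError(
            f"insufficient arm pairs: hinge {hinge} with arms of "
            f"{arm_length} needs pairs {hinge - arm_length}.."
            f"{hinge + arm_length} in 1..{n_pairs}"
        )


def bend_angle(model: StructureModel, hinge_pair: int, arm_length: int,
               model_index: int = 0) -> float:
    """Angle (degrees) between the 5' and 3' arm axes around a hinge pair.

    Each arm axis is the principal axis of ``arm_length`` base-pair origins
    on that side of the hinge (hinge pair excluded), oriented 5'->3'; a
    straight helix reads 0.
    """
    frames = basepair_frames(model, model_index)
    _check_arms(len(frames), hinge_pair, arm_length)
    origins = np.array([f.origin for f in frames])
    a5 = _arm_axis(origins[hinge_pair - 1 - arm_length:hinge_pair - 1])
    a3 = _arm_axis(origins[hinge_pair:hinge_pair + arm_length])
    return float(np.degrees(np.arccos(np.clip(a5 @ a3, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    return float(ang)


#: overall sign applied to the bend-direction torsion, calibrated on
#: generator fixtures so minor-groove-directed bending is negative
_BEND_DIRECTION_SIGN = 1.0


def bend_direction_dihedral(model: StructureModel, hinge_pair: int,
                            arm_length: int, model_index: int = 0,
                            min_bend: float = 2.0) -> float | None:
    """Bend-direction pseudo-dihedral (degrees): negative toward the minor groove.

    Torsion over four reference points -- the hinge pair's bottom-strand C1'
    (which fixes the groove frame: the base-pair long axis), the distal
    5'-arm origin, the hinge origin and the distal 3'-arm origin.  The sign
    convention is calibrated on generator fixtures: bending toward the
    minor groove gives negative values, toward the major groove positive.

    Returns None (undefined direction) when the bend angle is below
    ``min_bend`` degrees.
    """
    frames = basepair_frames(model, model_index)
    _check_arms(len(frames), hinge_pair, arm_length)
    if bend_angle(model, hinge_pair, arm_length, model_index) < min_bend:
        return None
    (wc, wr), (yc, yr) = model.pairing[hinge_pair - 1]
    c1y = model.single_atom(yc, yr, "C1'", model_index)
    if c1y is None:
        raise MissingAtomsError([f"{yc}:{yr}:C1'"])
    p1 = c1y
    p2 = frames[hinge_pair - 1 - arm_length].origin
    p3 = frames[hinge_pair - 1].origin
    p4 = frames[hinge_pair - 1 + arm_length].origin
    return _BEND_DIRECTION_SIGN * dihedral(p1, p2, p3, p4)


# ---------------------------------------------------------------------------
# base extrusion
# ---------------------------------------------------------------------------


def _residue_centroid(model: StructureModel, chain: str, resid: int,
                      names, model_index: int, label: str) -> np.ndarray:
    coords = model.residue_coords(chain, resid, names, model_index)
    if coords.shape[0] == 0:
        raise MissingAtomsError([f"{chain}:{resid}:{label}"])
    return coords.mean(axis=0)


def base_extrusion_dihedral(model: StructureModel, pair: int,
                            model_index: int = 0) -> float:
    """Base-extrusion pseudo-dihedral (degrees) for the top-strand base at
    ``pair``.

    Torsion over (centroid of the base pair 3' of the flip site, sugar-ring
    centroid of the 3' neighbor, sugar-ring centroid of the flipping
    nucleotide, base-ring centroid of the flipping base).  Rotating a base
    out of the stack about the backbone shifts this angle by the rotation
    applied; the stacked ideal-duplex value serves as the baseline.
    """
    if pair + 1 > len(model.pairing):
        raise ValueError(f"pair {pair} needs a 3' neighbor pair")
    (wc, wr), _ = model.pairing[pair - 1]
    (wc3, wr3), (yc3, yr3) = model.pairing[pair]
    resname = model.atoms.loc[model.atom_index(wc, wr)[0], "resname"]
    base = resname.lstrip("D")
    ring = _bases.RING_ATOMS.get(base)
    if ring is None:
        raise ValueError(f"unsupported residue {resname} at {wc}:{wr}")
    p1 = np.concatenate(
        [
            model.residue_coords(wc3, wr3, None, model_index),
            model.residue_coords(yc3, yr3, None, model_index),
        ]
    ).mean(axis=0)
    p2 = _residue_centroid(model, wc3, wr3, _bases.SUGAR_ATOMS, model_index,
                           "sugar ring")
    p3 = _residue_centroid(model, wc, wr, _bases.SUGAR_ATOMS, model_index,
                           "sugar ring")
    p4 = _residue_centroid(model, wc, wr, ring, model_index, "base ring")
    return dihedral(p1, p2, p3, p4)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

#: default heavy-atom donor/acceptor table for nucleobases
DEFAULT_DONORS = {
    ("DA", "N6"), ("DC", "N4"), ("DG", "N1"), ("DG", "N2"), ("DT", "N3"),
}
DEFAULT_ACCEPTORS = {
    ("DA", "N1"), ("DA", "N3"), ("DA", "N7"),
    ("DC", "N3"), ("DC", "O2"),
    ("DG", "O6"), ("DG", "N3"), ("DG", "N7"),
    ("DT", "O2"), ("DT", "O4"),
}


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float
    angle: float | None = None


def hydrogen_bonds(model: StructureModel, model_index: int = 0,
                   donors=None, acceptors=None, d_max: float = 3.5,
                   angle_min: float = 120.0) -> list[HydrogenBond]:
    """Detect hydrogen bonds between heavy-atom donors and acceptors.

    A bond requires donor-acceptor distance <= ``d_max`` (A) between atoms
    of different residues and, when an explicit hydrogen is bonded to the
    donor (within 1.2 A), a D-H...A angle >= ``angle_min`` degrees.
    Covalently linked neighbors (same chain, adjacent residue numbers) are
    excluded, as in standard contact analyses.  An empty list is a valid
    result.
    """
    donors = DEFAULT_DONORS if donors is None else donors
    acceptors = DEFAULT_ACCEPTORS if acceptors is None else acceptors
    atoms = model.atoms
    xyz = model.coords[model_index]
    keys = list(zip(atoms["resname"], atoms["name"]))
    d_idx = [i for i, k in enumerate(keys) if k in donors]
    a_idx = [i for i, k in enumerate(keys) if k in acceptors]
    if not d_idx or not a_idx:
        return []
    dist = cdist(xyz[d_idx], xyz[a_idx])
    h_idx = [i for i, el in enumerate(atoms["element"]) if el == "H"]
    bonds = []
    for ii, i in enumerate(d_idx):
        for jj, j in enumerate(a_idx):
            if dist[ii, jj] > d_max:
                continue
            if atoms.at[i, "chain"] == atoms.at[j, "chain"] and abs(
                int(atoms.at[i, "resid"]) - int(atoms.at[j, "resid"])
            ) <= 1:
                continue
            angle = None
            if h_idx:
                hd = np.linalg.norm(xyz[h_idx] - xyz[i], axis=1)
                local_h = [h for h, dd in zip(h_idx, hd) if dd < 1.2]
                if local_h:
                    best = None
                    for h in local_h:
                        v1 = xyz[i] - xyz[h]
                        v2 = xyz[j] - xyz[h]
                        cosang = v1 @ v2 / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        a = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        best = a if best is None else max(best, a)
                    angle = best
                    if angle < angle_min:
                        continue
            bonds.append(
                HydrogenBond(
                    donor=(atoms.at[i, "chain"], int(atoms.at[i, "resid"]),
                           atoms.at[i, "name"]),
                    acceptor=(atoms.at[j, "chain"], int(atoms.at[j, "resid"]),
                              atoms.at[j, "name"]),
                    distance=float(dist[ii, jj]),
                    angle=angle,
                )
            )
    return bonds


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------


def block_average(series, n_blocks: int) -> tuple[float, float]:
    """Overall mean and standard deviation of contiguous block means.

    The series is split into ``n_blocks`` equal contiguous blocks (any
    trailing remainder is discarded); the SD of the block means estimates
    the uncertainty of the mean for correlated series.
    """
    values = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if values.size < n_blocks:
        raise ValueError(
            f"series of length {values.size} shorter than {n_blocks} blocks"
        )
    block_len = values.size // n_blocks
    used = values[: block_len * n_blocks]
    means = used.reshape(n_blocks, block_len).mean(axis=1)
    return float(used.mean()), float(means.std(ddof=1))


def block_scan(series, n_blocks_list=(2, 4, 5, 8, 10)) -> dict[int, float]:
    """Block-mean SD for several block counts (plateau indicates the
    decorrelated error estimate)."""
    values = np.asarray(series, dtype=float)
    return {
        nb: block_average(values, nb)[1]
        for nb in n_blocks_list
        if values.size >= nb
    }
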