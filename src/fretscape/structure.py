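"""Coordinate models of DNA duplexes (optionally with protein) and PDB I/O.

A :class:`StructureModel` holds one atom table shared by one or more
coordinate sets (MODEL records = ensemble frames), plus a base-pairing map
listing top-strand/bottom-strand partners in 5'->3' order of the top strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder

__all__ = [
    "StructureModel",
    "StructureError",
    "read_structure",
    "write_structure",
]

_DNA_RESNAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
}

ResidueKey = tuple[str, int]  # (chain id, residue number)


class StructureError(ValueError):
    """Malformed or unusable structure input."""


@dataclass
class StructureModel:
    """Ordered atoms plus one or more coordinate sets and a base-pairing map.

    Attributes
    ----------
    atoms : pandas.DataFrame
        Columns ``name``, ``element``, ``resname``, ``chain``, ``resid``.
    coords : numpy.ndarray
        Shape ``(n_models, n_atoms, 3)`` in Angstrom.
    pairing : tuple
        ``((top_key, bottom_key), ...)`` residue-key pairs, ordered 5'->3'
        along the top strand.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    pairing: tuple[tuple[ResidueKey, ResidueKey], ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coords have {self.coords.shape[1]} atoms but the atom "
                f"table has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        keys = {(c, r) for c, r in zip(self.atoms["chain"], self.atoms["resid"])}
        for top, bottom in self.pairing:
            for key in (top, bottom):
                if (key[0], key[1]) not in keys:
                    raise StructureError(f"paired residue {key} not in model")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(
        self,
        chain: str,
        resid: int,
        names: list[str] | tuple[str, ...] | None = None,
    ) -> np.ndarray:
        """Row indices of a residue's atoms, optionally restricted by name."""
        mask = (self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
        if names is not None:
            mask &= self.atoms["name"].isin(names)
        return np.flatnonzero(mask.to_numpy())

    def residue_coords(
        self,
        chain: str,
        resid: int,
        names=None,
        model: int = 0,
    ) -> np.ndarray:
        idx = self.atom_index(chain, resid, names)
        return self.coords[model, idx]

    def single_atom(self, chain: str, resid: int, name: str, model: int = 0):
        """Coordinates of one named atom, or None if absent."""
        idx = self.atom_index(chain, resid, [name])
        if idx.size == 0:
            return None
        return self.coords[model, idx[0]]

    def pair_number(self, top_resid: int) -> int:
        """1-based position of a top-strand residue in the pairing list."""
        for i, (top, _) in enumerate(self.pairing, start=1):
            if top[1] == top_resid:
                return i
        raise KeyError(f"top-strand residue {top_resid} is not paired")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Copy with every model rigidly rotated then translated."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(self.atoms.copy(), new, self.pairing,
                              dict(self.meta))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write all coordinate sets as a (multi-MODEL) PDB file."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("fs")
    names = model.atoms["name"].to_numpy()
    elements = model.atoms["element"].to_numpy()
    resnames = model.atoms["resname"].to_numpy()
    chains = model.atoms["chain"].to_numpy()
    resids = model.atoms["resid"].to_numpy()
    for m in range(model.n_models):
        builder.init_model(m)
        seen_chain = None
        seen_res = None
        serial = 1
        for i in range(model.n_atoms):
            if chains[i] != seen_chain:
                builder.init_chain(str(chains[i]))
                builder.init_seg("    ")
                seen_chain = chains[i]
                seen_res = None
            if resids[i] != seen_res:
                builder.init_residue(str(resnames[i]), " ", int(resids[i]), " ")
                seen_res = resids[i]
            builder.init_atom(
                str(names[i]), model.coords[m, i], 0.0, 1.0, " ",
                str(names[i]).rjust(3).ljust(4)[:4], serial,
                element=str(elements[i]),
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def _infer_pairing(
    atoms: pd.DataFrame, coords0: np.ndarray
) -> tuple[tuple[ResidueKey, ResidueKey], ...]:
    """Distance heuristic: mutually nearest complementary C1' pairs (< 12 A)."""
    is_c1 = atoms["name"] == "C1'"
    sub = atoms[is_c1]
    keys = list(zip(sub["chain"], sub["resid"]))
    bases = [_DNA_RESNAMES.get(rn) for rn in sub["resname"]]
    pos = coords0[np.flatnonzero(is_c1.to_numpy())]
    complement = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(keys)
    if n < 2:
        return ()
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # disallow same-chain partners and non-complementary bases
    for i in range(n):
        for j in range(n):
            if keys[i][0] == keys[j][0] or complement.get(bases[i]) != bases[j]:
                d[i, j] = np.inf
    nearest = d.argmin(axis=1)
    pairs = []
    for i in range(n):
        j = nearest[i]
        if d[i, j] < 12.0 and nearest[j] == i and i < j:
            pairs.append((i, j))
    # order 5'->3' by residue number of the lexicographically first chain
    def top_of(p):
        i, j = p
        return (i, j) if keys[i][0] < keys[j][0] else (j, i)

    ordered = sorted((top_of(p) for p in pairs), key=lambda p: keys[p[0]][1])
    return tuple((keys[i], keys[j]) for i, j in ordered)


def read_structure(
    path: str | Path,
    pairing: tuple[tuple[ResidueKey, ResidueKey], ...] | None = None,
) -> StructureModel:
    """Read a (multi-MODEL) PDB file into a :class:`StructureModel`.

    The base-pairing map is taken from ``pairing`` when given, otherwise
    inferred from mutually nearest complementary C1' atoms.

    Raises
    ------
    StructureError
        If the file contains no DNA residues, or the MODELs disagree in
        atom count.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("fs", str(path))
    models = list(struct)
    if not models:
        raise StructureError(f"{path.name}: no models")

    rows = []
    per_model_coords = []
    n_dna = 0
    for mi, mdl in enumerate(models):
        coords = []
        count = 0
        for chain in mdl:
            for res in chain:
                resname = res.get_resname().strip()
                for atom in res:
                    if mi == 0:
                        rows.append(
                            {
                                "name": atom.get_name(),
                                "element": (atom.element or "").strip() or
                                atom.get_name()[0],
                                "resname": resname,
                                "chain": chain.id,
                                "resid": res.id[1],
                            }
                        )
                        if resname in _DNA_RESNAMES and atom.get_name() == "C1'":
                            n_dna += 1
                    coords.append(atom.get_coord())
                    count += 1
        per_model_coords.append(np.array(coords, dtype=float))
    lengths = {c.shape[0] for c in per_model_coords}
    if len(lengths) != 1:
        bad = [i for i, c in enumerate(per_model_coords)
               if c.shape[0] != per_model_coords[0].shape[0]]
        raise StructureError(
            f"{path.name}: inconsistent atom counts across models {bad}"
        )
    if n_dna == 0:
        raise StructureError(f"{path.name}: no DNA residues found")
    atoms = pd.DataFrame(rows)
    coords = np.stack(per_model_coords)
    if pairing is None:
        pairing = _infer_pairing(atoms, coords[0])
    return StructureModel(atoms, coords, tuple(pairing), {"source": str(path)})
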