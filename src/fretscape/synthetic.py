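"""Synthetic inputs with known ground truth: TCSPC decays and DNA duplexes.

``simulate_decay`` produces multi-exponential photon-count histograms under
the acquisition model of a time-resolved FRET experiment (Poisson counting
noise, optional Gaussian instrument response).  ``build_duplex`` constructs
an idealized double helix whose twist, bend and base-flip perturbations are
injected as rigid rotations, so that the geometry descriptors can recover
them exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import erfc

from . import _bases
from .structure import StructureModel
from .trace import AcquisitionConfig, DecayTrace

__all__ = [
    "LifetimeComponent",
    "DuplexSpec",
    "simulate_decay",
    "decay_profile",
    "build_duplex",
    "build_ensemble",
    "MINOR_GROOVE",
    "MAJOR_GROOVE",
]

#: bend-direction azimuths in the hinge base-pair frame, degrees
MINOR_GROOVE = 180.0
MAJOR_GROOVE = 0.0


@dataclass(frozen=True)
class LifetimeComponent:
    """One exponential decay component: lifetime tau (ns), fractional amplitude."""

    tau: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


def _as_components(components) -> list[LifetimeComponent]:
    out = []
    for c in components:
        if isinstance(c, LifetimeComponent):
            out.append(c)
        else:
            tau, amp = c
            out.append(LifetimeComponent(float(tau), float(amp)))
    return out


def decay_profile(times: np.ndarray, tau: float, irf_fwhm: float = 0.0
                  ) -> np.ndarray:
    """Unit-peak-free exponential decay, optionally blurred by a Gaussian IRF.

    With a delta response this is ``exp(-t/tau)`` for t >= 0; with
    ``irf_fwhm > 0`` it is the analytic convolution of that decay with a
    unit-area Gaussian centered at t = 0 (sigma = fwhm / 2.3548).
    """
    t = np.asarray(times, dtype=float)
    if irf_fwhm == 0.0:
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    arg = sigma / (np.sqrt(2.0) * tau) - t / (np.sqrt(2.0) * sigma)
    # log-space evaluation avoids overflow of exp() against erfc() underflow
    with np.errstate(over="ignore"):
        val = 0.5 * np.exp(sigma**2 / (2 * tau**2) - t / tau) * erfc(arg)
    return np.where(np.isfinite(val), val, 0.0)


def simulate_decay(
    components,
    acq: AcquisitionConfig | None = None,
    noiseless: bool = False,
    rng: np.random.Generator | None = None,
) -> DecayTrace:
    """Simulate a TCSPC decay trace from exponential lifetime components.

    The expected counts in channel k are

    ``mu_k = background_rate + S * sum_i a_i * f(t_k; tau_i)``

    where ``f`` is the (IRF-convolved) exponential profile and the scale S
    is chosen so that ``max_k mu_k`` equals ``acq.peak_counts``.  Noisy
    traces are per-channel Poisson draws of mu_k.

    Parameters
    ----------
    components : iterable
        ``LifetimeComponent`` objects or ``(tau_ns, amplitude)`` pairs;
        amplitudes must sum to 1 within 1e-9.
    acq : AcquisitionConfig, optional
        Acquisition settings (default: 100 ns window, 4096 channels,
        10,000 peak counts, delta IRF).
    noiseless : bool
        Return the expected curve mu_k itself instead of Poisson draws.
    rng : numpy.random.Generator, optional
        Noise source; defaults to ``default_rng(acq.seed)``.
    """
    acq = acq or AcquisitionConfig()
    comps = _as_components(components)
    if not comps:
        raise ValueError("at least one lifetime component is required")
    total = sum(c.amplitude for c in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"component amplitudes must sum to 1 (got {total!r}); "
            "normalize them before simulating"
        )
    for c in comps:
        if c.tau >= 10.0 * acq.window:
            warnings.warn(
                f"lifetime {c.tau} ns is >= 10x the {acq.window} ns window "
                "and cannot be resolved",
                stacklevel=2,
            )
    times = acq.times()
    shape = np.zeros_like(times)
    for c in comps:
        shape += c.amplitude * decay_profile(times, c.tau, acq.irf_fwhm)
    peak = shape.max()
    if acq.background_rate >= acq.peak_counts:
        raise ValueError("background_rate must be below peak_counts")
    scale = (acq.peak_counts - acq.background_rate) / peak
    mu = acq.background_rate + scale * shape
    if noiseless:
        counts = mu
    else:
        rng = rng if rng is not None else np.random.default_rng(acq.seed)
        counts = rng.poisson(mu).astype(float)
    meta = {
        "components": [(c.tau, c.amplitude) for c in comps],
        "scale": scale,
    }
    return DecayTrace(times=times, counts=counts, acq=acq,
                      noiseless=noiseless, meta=meta)


# ---------------------------------------------------------------------------
# duplex generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexSpec:
    """Recipe for an idealized duplex with optional site perturbations.

    Residue/pair numbering is 1-based along the top strand (5'->3'), the
    convention used for the W strand of a protein-DNA construct; step k
    lies between pairs k and k+1.

    Parameters
    ----------
    sequence : str
        Top-strand bases (A/C/G/T).
    rise : float
        Helical rise per step in Angstrom.
    twist : float
        Helical twist per step in degrees.
    untwist_steps : tuple of (step, degrees)
        Extra *untwisting* (twist reduction) applied at individual steps.
    bends : tuple of (hinge_pair, bend_deg, direction_deg)
        Rigid bend of the 3' arm about the hinge pair; direction is the
        azimuth in the hinge-pair frame (0 = toward the major groove,
        180 = toward the minor groove; see MINOR_GROOVE / MAJOR_GROOVE).
    base_rotations : tuple of (pair, degrees)
        Rigid rotation of the top-strand base at ``pair`` about the
        backbone pivot (axis through its sugar-ring centroid, along the
        backbone direction from the 3'-neighbor sugar), emulating base
        extrusion.
    """

    sequence: str
    rise: float = 3.4
    twist: float = 36.0
    untwist_steps: tuple[tuple[int, float], ...] = ()
    bends: tuple[tuple[int, float, float], ...] = ()
    base_rotations: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("sequence must be non-empty")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"sequence uses non-ACGT characters: {sorted(bad)}")
        n = len(seq)
        for step, _ in self.untwist_steps:
            if not 1 <= step <= n - 1:
                raise ValueError(f"untwist step {step} outside duplex (1..{n-1})")
        for hinge, _, _ in self.bends:
            if not 2 <= hinge <= n - 1:
                raise ValueError(f"bend hinge {hinge} outside duplex (2..{n-1})")
        for pair, _ in self.base_rotations:
            if not 1 <= pair <= n - 1:
                raise ValueError(
                    f"base rotation at pair {pair} needs a 3' neighbor "
                    f"(1..{n-1})"
                )


def _rotation_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def build_duplex(spec: DuplexSpec) -> StructureModel:
    """Build an idealized B-form-like duplex from a :class:`DuplexSpec`.

    The top strand is chain ``W`` numbered 1..N in sequence order; the
    complementary bottom strand is chain ``Y`` numbered so that W_i pairs
    with Y_{N-i+1}.  Perturbations are applied as rigid rotations after the
    unperturbed helix is assembled.
    """
    seq = spec.sequence
    n = len(seq)
    twist_steps = np.full(max(n - 1, 0), float(spec.twist))
    for step, extra in spec.untwist_steps:
        twist_steps[step - 1] -= extra
    phi = np.concatenate([[0.0], np.cumsum(twist_steps)]) if n > 1 else np.array([0.0])

    rows = []
    coords = []
    pair_of_atom = []
    for j, base in enumerate(seq):
        tmpl = _bases.pair_template(base)
        R = _rotation_z(phi[j])
        shift = np.array([0.0, 0.0, j * spec.rise])
        for strand, resid in (("W", j + 1), ("Y", n - j)):
            b = base if strand == "W" else _bases.COMPLEMENT[base]
            for name, xyz in tmpl[strand].items():
                rows.append(
                    {
                        "name": name,
                        "element": name[0],
                        "resname": _bases.RESNAME[b],
                        "chain": strand,
                        "resid": resid,
                    }
                )
                coords.append(R @ xyz + shift)
                pair_of_atom.append(j + 1)
    atoms = pd.DataFrame(rows)
    xyz = np.array(coords)
    pair_idx = np.array(pair_of_atom)
    # group atoms by chain and residue (stable within-residue order) so the
    # table matches PDB chain/residue ordering and round-trips cleanly
    order = np.lexsort((atoms["resid"].to_numpy(),
                        atoms["chain"].to_numpy()))
    atoms = atoms.iloc[order].reset_index(drop=True)
    xyz = xyz[order]
    pair_idx = pair_idx[order]

    # --- base rotations about the backbone pivot -------------------------
    for pair, angle in spec.base_rotations:
        s_here = _sugar_centroid(atoms, xyz, "W", pair)
        s_next = _sugar_centroid(atoms, xyz, "W", pair + 1)
        axis = s_here - s_next
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        base_names = _bases.RING_ATOMS[seq[pair - 1]] + tuple(
            nm for nm in ("O2", "N2", "N4", "N6", "O4", "O6", "C7")
        )
        mask = (
            (atoms["chain"] == "W")
            & (atoms["resid"] == pair)
            & atoms["name"].isin(base_names)
        ).to_numpy()
        xyz[mask] = rot.apply(xyz[mask] - s_here) + s_here

    # --- hinge bends ------------------------------------------------------
    for hinge, bend, direction in spec.bends:
        o_prev = _c1_midpoint(atoms, xyz, hinge - 1, n)
        o_h = _c1_midpoint(atoms, xyz, hinge, n)
        o_next = _c1_midpoint(atoms, xyz, hinge + 1, n)
        y_h = _c1_axis(atoms, xyz, hinge, n)
        z_h = o_next - o_prev
        z_h -= (z_h @ y_h) * y_h
        z_h /= np.linalg.norm(z_h)
        x_h = np.cross(y_h, z_h)
        d = np.deg2rad(direction)
        u = np.cos(d) * x_h + np.sin(d) * y_h
        axis = np.cross(z_h, u)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(bend) * axis)
        mask = pair_idx > hinge
        xyz[mask] = rot.apply(xyz[mask] - o_h) + o_h

    pairing = tuple(
        (("W", j + 1), ("Y", n - j)) for j in range(n)
    )
    meta = {"spec": spec, "generator": "fretscape.build_duplex"}
    return StructureModel(atoms, xyz[None], pairing, meta)


def _sugar_centroid(atoms, xyz, chain, resid) -> np.ndarray:
    mask = (
        (atoms["chain"] == chain)
        & (atoms["resid"] == resid)
        & atoms["name"].isin(_bases.SUGAR_ATOMS)
    ).to_numpy()
    return xyz[mask].mean(axis=0)


def _c1_midpoint(atoms, xyz, pair, n) -> np.ndarray:
    w = _c1(atoms, xyz, "W", pair)
    y = _c1(atoms, xyz, "Y", n - pair + 1)
    return 0.5 * (w + y)


def _c1_axis(atoms, xyz, pair, n) -> np.ndarray:
    w = _c1(atoms, xyz, "W", pair)
    y = _c1(atoms, xyz, "Y", n - pair + 1)
    v = y - w
    return v / np.linalg.norm(v)


def _c1(atoms, xyz, chain, resid) -> np.ndarray:
    mask = (
        (atoms["chain"] == chain)
        & (atoms["resid"] == resid)
        & (atoms["name"] == "C1'")
    ).to_numpy()
    return xyz[mask][0]


def build_ensemble(specs) -> StructureModel:
    """Stack duplexes built from several specs (same sequence) into one
    multi-model ensemble, e.g. to emulate a trajectory with drifting twist."""
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one spec")
    models = [build_duplex(s) for s in specs]
    first = models[0]
    for m in models[1:]:
        if not m.atoms[["name", "chain", "resid"]].equals(
            first.atoms[["name", "chain", "resid"]]
        ):
            raise ValueError("all specs must produce identical atom tables")
    coords = np.concatenate([m.coords for m in models], axis=0)
    return StructureModel(first.atoms, coords, first.pairing,
                          {"generator": "fretscape.build_ensemble"})
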