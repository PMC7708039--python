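# fretscape

Fluorescence-lifetime FRET conformational landscapes and DNA geometry
descriptors for protein–DNA complexes.

## The problem

DNA-repair proteins such as the damage sensor Rad4/XPC "open" a DNA
duplex — untwisting it, bending it, and flipping nucleotides out of the
stack.  A crystal structure shows one frozen conformation; in solution
the protein-bound DNA samples several.  A fluorescence-lifetime (FLT)
approach resolves that heterogeneity: a rigid cytosine-analog FRET pair
(donor tC°, acceptor tC_nitro) is built into the duplex around the
probed site, and the donor decay is recorded by time-correlated
single-photon counting (TCSPC).  Each coexisting DNA conformation has
its own donor lifetime `tau_DA,i` and hence its own FRET efficiency

    E_i = 1 − tau_DA,i / tau_D

(`tau_D` ≈ 4.9 ns is the donor lifetime without acceptor).  Inverting
the decay into a lifetime *distribution* by the maximum-entropy method
(MEM), then decomposing that distribution into Gaussian components in
log-lifetime, yields the populations of the coexisting conformations:
each component's area is its fractional population `A_i`, and the sample
average FRET is

    <E> = 1 − (Σ_i A_i · tau_DA,i) / tau_D.

`fretscape` implements this pipeline end to end — decay simulation with
known ground truth, entropy-regularized inversion, Gaussian/BIC peak
decomposition, FRET and population bookkeeping — together with the
geometry descriptors used to characterize duplex "opening" in coordinate
models: base-pair-step twist and the untwist angle over a window of
steps, bend angle and a bend-direction pseudo-dihedral (negative toward
the minor groove), a base-extrusion pseudo-dihedral, Watson–Crick
hydrogen-bond detection, and block-averaged uncertainties for
trajectory-style ensembles.  A duplex generator produces idealized
helices with injected untwist/bend/flip perturbations so every
descriptor is testable against exact ground truth, without downloading
any structure.

It is intended for spectroscopists analyzing TCSPC lifetime data and for
structural/computational biologists quantifying duplex distortion in
models and ensembles.

## Worked example

Simulate a decay from a three-state landscape (lifetimes 0.40, 1.7 and
5.2 ns with amplitudes 39/33/28% — the kind of heterogeneous profile a
mismatched duplex shows), invert it, and read off the landscape:

```sh
$ fretscape simulate-decay --components 0.40:0.39,1.7:0.33,5.2:0.28 \
      --seed 2 -o trace.tsv
$ fretscape mem --trace trace.tsv -o dist.tsv
chi2_red=0.953 converged=True
$ fretscape fret --dist dist.tsv --tau-d 4.9
tau 0.391 ns  E 0.92 (raw +0.920)  population 38.7%
tau 1.561 ns  E 0.68 (raw +0.681)  population 32.0%
tau 5.083 ns  E 0.00 (raw -0.037)  population 29.3%
<E> = 0.557 (grid: 0.563)
```

The inversion recovers the three input states: lifetimes within a few
percent, populations within ~2 points of the 39/33/28 ground truth, a
high-FRET state (E ≈ 0.92, compact/B-form probe geometry), a mid-FRET
state, and a no-FRET state whose lifetime sits at the unquenched donor
value (its slightly negative raw E is reported but clamps to 0).  The
same stages are callable as a library:

```python
from fretscape import (AcquisitionConfig, simulate_decay, mem_fit,
                       build_landscape)

trace = simulate_decay([(0.40, 0.39), (1.7, 0.33), (5.2, 0.28)],
                       AcquisitionConfig(seed=2))
landscape = build_landscape(mem_fit(trace), tau_d=4.9)
for p in landscape.peaks:
    print(f"{p.center:.2f} ns  E={p.e_peak:.2f}  {100 * p.fraction:.0f}%")
```

Geometry descriptors run on any (multi-MODEL) PDB; here on a generated
duplex bent 20° toward the minor groove at pair 12:

```sh
$ fretscape make-duplex --seq ACGTACGTACGTACGTACGTACGT --bend 12:20:180 \
      -o bent.pdb
$ fretscape geometry --pdb bent.pdb --span 8:13 --hinge 12 --arms 5
1 model(s), 24 base pairs
untwist over 8..13: 0.00 deg
model 0: bend 20.0 deg, direction -90.0 deg
hydrogen bonds (model 0): 60
```

The injected bend is recovered exactly and the direction dihedral is
negative, the convention for minor-groove-directed bending.  A full
multi-stage run (`fretscape run --config run.yaml`) writes the lifetime
distribution, the landscape table, descriptor series and a JSON summary,
all stamped with the tool version and a config hash; rerunning the same
config reproduces the outputs byte for byte.

## Layout

| module | contents |
| --- | --- |
| `fretscape.trace` | acquisition settings, decay container, two-column text I/O |
| `fretscape.synthetic` | decay simulator, duplex/ensemble generator |
| `fretscape.mem` | lifetime grids, maximum-entropy inversion |
| `fretscape.landscape` | peak counting, Gaussian/BIC decomposition, FRET |
| `fretscape.structure` | atom-table structure model, PDB I/O, pairing |
| `fretscape.descriptors` | twist/untwist, bend angle/direction, extrusion, H-bonds, block averaging |
| `fretscape.pipeline` | YAML config, end-to-end run, reports |
| `fretscape.cli` | `fretscape` subcommands over all of the above |

Model details, numerical choices and limitations are documented in
[docs/methods.md](docs/methods.md).
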