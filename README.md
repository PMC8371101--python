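# alveonet

A random fiber-network model of the pulmonary alveolar wall: 2D spring
networks of collagen and elastin, stretched uniaxially to 100% strain, with
readouts of stress, collagen recruitment, and percolation.

## The scientific problem

The mechanics of the alveolar wall arise from two interwoven protein
networks with wildly different properties: elastin fibers are soft and
continuously strained, while collagen fibers are roughly a thousand times
stiffer but wavy and slack at low strain.  As the tissue stretches, collagen
fibers straighten one by one and are *recruited* to bear load, producing the
characteristic exponential stress–strain curve of lung tissue.  In pulmonary
fibrosis, collagen both stiffens (intra-fiber cross-linking) and loses
waviness, shifting the curve.  This package implements a minimal mechanistic
model of that process and of the connectivity transition — *percolation* —
that accompanies it, for computational biomechanics work on healthy and
fibrotic lung tissue.

## The model

A network is built on the unit square:

* **Geometry** — `n` random chords (anchor uniform on the square, angle
  uniform on [0, 2π)) are each collagen with probability `α` or elastin
  otherwise.  Two crossing fibers are permanently bonded into a shared node
  with probability `ρ` (inter-fiber cross-linking); unbonded crossings do
  not interact.  Fibers attach to the square boundary, and the perimeter is
  covered by elastin-like "edge" springs.  Baseline: `n = 48`, `ρ = 0.85`
  (mean connectivity degree per crossing site 4ρ = 3.4).
* **Springs** — every segment is Hookean, `U = ½ k (d − r₀)²`, except that
  collagen with `d ≤ r₀` is slack and carries nothing (recruitment
  condition).
* **Constitutive initialisation** — a first pass randomises `r₀` (geometric
  length × U(0,1), `k = 1/r₀`) and relaxes the network to a disordered,
  isotropic reference state with all four edges held co-linear.  Rest
  lengths are then re-derived from that equilibrium: elastin at rest, edge
  springs at 95% (pre-tension), and collagen slack by a waviness factor
  `w ~ Beta(a=1.89, b=3.6)` on `[w₁, w₁+0.65]`.  Collagen stiffness scales
  with waviness through a flipped Burr shape (c = 1, κ = 10) whose maximum
  is the amplification `γ`: 10³ for healthy tissue, 10⁴ for fibrotic.
  Conditions: healthy (γ=10³, w₁~U[1.3,1.4]), mild (γ=10⁴, same w₁),
  severe (γ=10⁴, w₁~U[1.1,1.3]).
* **Stretch protocol** — the right boundary moves outward in 5% strain
  increments to 100% strain; left/right edges stay co-linear, top/bottom
  may neck inward.  Each step is an energy minimisation (preconditioned
  L-BFGS, per-node residual force ≤ 10⁻²) warm-started from the previous
  step.  Readouts per step: boundary force, nominal stress, recruited
  collagen fraction, and whether a contiguous path of recruited collagen
  spans left to right (*mechanical percolation*).
* **Bond percolation** — independently of mechanics, segments of the
  collagen subnetwork are occupied at random with probability `p`; the
  ensemble-mean giant-component fraction versus `p` yields the
  bond-percolation threshold at its inflection.

`α` is not well constrained for alveolar tissue; the default `α = 0.5` is a
documented placeholder (it also reproduces the bond-percolation behavior of
the collagen subnetwork, see `docs/methods.md`).

## Worked example

```python
import numpy as np
from alveonet import simulate_stretch, bond_percolation_experiment
from alveonet.percolation import percolation_strain

res = simulate_stretch(seed=7, preset="healthy")   # n=48 fibers, rho=0.85
print(res.to_frame().iloc[::5].to_string(index=False))
print("mechanical percolation strain:", percolation_strain(res))

curve = bond_percolation_experiment(n=480, rho=0.85, n_networks=50, seed=7)
print(f"bond-percolation threshold: {curve.threshold:.3f}")
```

prints

```
 strain     force    stress  recruitment_fraction  percolated  converged    energy
   0.00  0.121338  0.121338              0.000000           0          1  0.002929
   0.25  2.562992  2.562992              0.097928           0          1  0.293393
   0.50  6.603325  6.603325              0.301318           0          1  1.388480
   0.75 19.364545 19.364545              0.557439           1          1  4.334248
   1.00 43.767201 43.767201              0.664783           1          1 12.086417
mechanical percolation strain: 0.6
bond-percolation threshold: 0.719
```

Reading this: at zero strain all collagen is slack (recruitment 0) and the
only stress is the small edge-spring pre-tension.  Stress then grows
nonlinearly as collagen is progressively recruited; in this realisation a
spanning path of taut collagen first appears at 60% strain, when about a
third of the collagen is recruited.  The random-occupation (bond)
threshold of the collagen subnetwork is far higher, ≈0.72 — mechanical
percolation exploits force chains that random occupation does not.

The same experiments are available from a shell:

```
alveonet generate --n 48 --rho 0.85 --seed 1 --out net.json
alveonet stretch --net net.json --condition healthy --out result.csv
alveonet ensemble --conditions healthy,mild,severe --reps 50 --outdir out/
alveonet bondperc --n 480 --rho 0.85 --networks 200 --seed 1 --out curve.csv
alveonet sweep-elastin --reps 40 --seed 1 --out elastin.csv
alveonet render --net net.json --out net.png
```

## Layout

```
src/alveonet/netgen.py        geometry, cross-linking, network format
src/alveonet/constitutive.py  rest lengths, waviness, stiffness presets
src/alveonet/mechanics.py     energies, forces, equilibration, stretch
src/alveonet/percolation.py   mechanical + bond percolation, thresholds
src/alveonet/experiments.py   ensembles, sweeps, CIs, manifests, export
src/alveonet/cli.py           command-line interface
docs/methods.md               modelling notes, assumptions, limitations
```
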