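"""Rest-length and spring-constant initialisation.

Two-phase scheme:

1. *Isotropising pass* — every segment's rest length is its as-built
   geometric length scaled by an i.i.d. uniform(0, 1) factor, with
   ``k = 1/r0`` so every spring has unit stiffness (``k * r0 = 1``).  The
   network is then relaxed to an equilibrium configuration (mechanics
   module), which erases the memory of the straight-chord construction and
   gives the network an isotropic, disordered rest geometry.

2. *Final pass* — rest lengths are re-defined from the equilibrium segment
   lengths: elastin springs rest exactly at their equilibrium length,
   perimeter (edge) springs at 95% of it so the frame is under tension, and
   collagen springs at ``w`` times it, where the waviness factor ``w > 1``
   is drawn from a beta law.  Collagen is thereby flaccid (zero energy) at
   rest and only *recruited* once stretched past its slack.  Collagen spring
   constants are additionally scaled by a flipped Burr function of the
   waviness, making wavier fibers rarer but much stiffer, with amplitude
   gamma (10^3 healthy, 10^4 fibrotic) carrying the collagen/elastin
   stiffness contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgen import COLLAGEN, EDGE, ELASTIN, FiberNetwork

#: edge (perimeter) springs rest at this fraction of their equilibrium length
EDGE_REST_FRACTION = 0.95

#: fixed width of the waviness distribution support
WAVINESS_WIDTH = 0.65


@dataclass(frozen=True)
class WavinessDistribution:
    """Beta law for the collagen waviness factor w on [w1, w2].

    Density p(w) = (w - w1)^(a-1) (w2 - w)^(b-1) / (B(a, b) (w2 - w1)^(a+b-1))
    with shapes a = 1.89, b = 3.6 (measured on alveolar collagen) so the
    density vanishes at both endpoints.  The support width w2 - w1 is fixed
    at 0.65; shifting w1 moves the whole distribution.
    """

    w1: float = 1.3
    w2: float | None = None
    a: float = 1.89
    b: float = 3.6

    def __post_init__(self):
        if self.w2 is None:
            object.__setattr__(self, "w2", self.w1 + WAVINESS_WIDTH)
        if self.w2 <= self.w1:
            raise ValueError("w2 must exceed w1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")

    @property
    def width(self) -> float:
        return self.w2 - self.w1

    def mean(self) -> float:
        return self.w1 + self.width * self.a / (self.a + self.b)

    def var(self) -> float:
        ab = self.a + self.b
        return self.width**2 * self.a * self.b / (ab**2 * (ab + 1.0))


@dataclass(frozen=True)
class BurrParams:
    """Flipped Burr stiffness-vs-waviness factor.

    f(w | c, kappa, gamma) = gamma c kappa (w2-w)^(c-1) / (1 + (w2-w)^c)^(kappa+1)

    With c = 1, kappa = 10 the factor increases monotonically with w: wavier
    collagen is stiffer.  gamma is the overall collagen stiffness
    amplification relative to unit-stiffness elastin: 10^3 for healthy
    tissue, 10^4 for fibrotic tissue.
    """

    c: float = 1.0
    kappa: float = 10.0
    gamma: float = 1e3

    def __post_init__(self):
        if self.c <= 0 or self.kappa <= 0 or self.gamma <= 0:
            raise ValueError("Burr parameters must be positive")


@dataclass(frozen=True)
class ConditionPreset:
    """A tissue condition: Burr amplitude + per-network minimum-waviness range.

    healthy : gamma = 1e3, w1 ~ U[1.3, 1.4]
    mild    : gamma = 1e4, w1 ~ U[1.3, 1.4]  (stiffer collagen only)
    severe  : gamma = 1e4, w1 ~ U[1.1, 1.3]  (stiffer + less wavy collagen)

    w1 is drawn once per network realisation, uniformly from ``w1_range``,
    to emulate between-patient heterogeneity; w2 = w1 + 0.65 always.
    """

    name: str
    gamma: float
    w1_range: tuple[float, float]

    def burr(self) -> BurrParams:
        return BurrParams(gamma=self.gamma)

    def draw_w1(self, rng: np.random.Generator) -> float:
        lo, hi = self.w1_range
        return float(rng.uniform(lo, hi))


PRESETS: dict[str, ConditionPreset] = {
    "healthy": ConditionPreset("healthy", 1e3, (1.3, 1.4)),
    "mild": ConditionPreset("mild", 1e4, (1.3, 1.4)),
    "severe": ConditionPreset("severe", 1e4, (1.1, 1.3)),
}


def initialize_isotropy(network: FiberNetwork, rng: np.random.Generator) -> FiberNetwork:
    """Isotropising pass: r0 <- geometric length x U(0,1), k <- 1/r0.

    Every spring ends up with unit stiffness (k * r0 = 1) and a rest length
    no longer than its as-built length, so the whole network is under
    tension (or at rest) and relaxes into a disordered equilibrium.
    Modifies the network in place and returns it.
    """
    lengths = network.segment_lengths()
    factors = rng.uniform(0.0, 1.0, size=network.n_segments)
    # a draw of exactly 0 would give an infinite spring constant
    while np.any(factors == 0.0):
        zero = factors == 0.0
        factors[zero] = rng.uniform(0.0, 1.0, size=int(zero.sum()))
    network.seg_r0 = lengths * factors
    network.seg_k = 1.0 / network.seg_r0
    network.stage = "pre-equilibration"
    return network


def sample_waviness(
    dist: WavinessDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw waviness factors w in [w1, w2] from the beta law."""
    return dist.w1 + dist.width * rng.beta(dist.a, dist.b, size=size)


def burr_factor(w, params: BurrParams, w2: float):
    """Evaluate the flipped Burr factor f(w) on the support w <= w2.

    At w = w2 (and c = 1) the numerator power is 0^0 := 1, giving
    f(w2) = gamma * c * kappa.
    """
    w = np.asarray(w, float)
    if np.any(w > w2 + 1e-12):
        raise ValueError("waviness above w2 is outside the flipped Burr support")
    x = np.clip(w2 - w, 0.0, None)
    c, kap, gam = params.c, params.kappa, params.gamma
    with np.errstate(divide="ignore"):
        num = np.where(x == 0.0, 1.0 if c == 1.0 else (np.inf if c < 1.0 else 0.0), x ** (c - 1.0))
    f = gam * c * kap * num / (1.0 + x**c) ** (kap + 1.0)
    return float(f) if f.ndim == 0 else f


def collagen_stiffness_factor(w, params: BurrParams, w2: float, raw: bool = False):
    """Waviness-dependent collagen stiffness multiplier, maximal value gamma.

    The flipped-Burr shape of :func:`burr_factor` normalised by its
    amplitude c*kappa, so the multiplier at w = w2 equals gamma exactly:
    the stiffest collagen is gamma-fold (10^3 healthy, 10^4 fibrotic)
    stiffer than unit-stiffness elastin, and the least wavy collagen about
    250-fold softer than that.  ``raw=True`` uses the un-normalised density
    value instead (maximum gamma*c*kappa).
    """
    f = burr_factor(w, params, w2)
    return f if raw else f / (params.c * params.kappa)


def finalize_rest_lengths(
    network: FiberNetwork,
    equilibrium_lengths: np.ndarray,
    preset: ConditionPreset,
    rng: np.random.Generator,
    dist: WavinessDistribution | None = None,
    burr: BurrParams | None = None,
    k_mode: str = "multiply",
    burr_raw: bool = False,
) -> FiberNetwork:
    """Final constitutive pass from the pre-equilibration geometry.

    elastin : r0 = L_eq,        k = 1/r0   (at rest in equilibrium)
    edge    : r0 = 0.95 L_eq,   k = 1/r0   (perimeter under tension)
    collagen: r0 = w L_eq,      k = m(w)/r0   [k_mode="multiply", default]
                                k = m(w)      [k_mode="replace"]
              with w ~ beta waviness law per segment (w stored on the
              segment) and m the waviness-dependent stiffness multiplier of
              :func:`collagen_stiffness_factor` (maximum gamma, so the
              stiffest collagen is 10^3-fold stiffer than elastin in the
              healthy condition; ``burr_raw=True`` keeps the un-normalised
              flipped-Burr density as the multiplier instead).

    If ``dist`` is None a per-network w1 is drawn uniformly from the
    preset's range (RNG order: w1 draw, then the per-segment waviness
    array).  Modifies the network in place and returns it.
    """
    if network.stage != "pre-equilibration":
        raise ValueError(
            "finalize_rest_lengths needs a pre-equilibrated network "
            f"(stage={network.stage!r}); run initialize_isotropy + equilibrate first"
        )
    if k_mode not in ("multiply", "replace"):
        raise ValueError(f"unknown k_mode {k_mode!r}")
    L = np.asarray(equilibrium_lengths, float)
    if L.shape != (network.n_segments,):
        raise ValueError("equilibrium_lengths must have one entry per segment")

    if dist is None:
        dist = WavinessDistribution(w1=preset.draw_w1(rng))
    if burr is None:
        burr = preset.burr()

    el = network.seg_type == ELASTIN
    ed = network.seg_type == EDGE
    co = network.seg_type == COLLAGEN

    r0 = np.empty(network.n_segments)
    k = np.empty(network.n_segments)
    r0[el] = L[el]
    r0[ed] = EDGE_REST_FRACTION * L[ed]
    w = sample_waviness(dist, rng, size=int(co.sum()))
    r0[co] = w * L[co]
    k[el | ed] = 1.0 / r0[el | ed]
    m = collagen_stiffness_factor(w, burr, dist.w2, raw=burr_raw)
    if k_mode == "multiply":
        k[co] = m / r0[co]
    else:
        k[co] = m

    network.seg_r0 = r0
    network.seg_k = k
    network.seg_w = np.full(network.n_segments, np.nan)
    network.seg_w[co] = w
    network.stage = "final"
    return network


def scale_elastin_stiffness(network: FiberNetwork, scale: float) -> FiberNetwork:
    """Multiply elastin spring constants by ``scale`` (edge springs too).

    Used by the elastin-stiffness sweep; baseline scale is 1.  Applied after
    the final constitutive pass.  Modifies in place and returns the network.
    """
    if scale <= 0:
        raise ValueError("elastin scale must be positive")
    mask = network.seg_type != COLLAGEN
    network.seg_k = network.seg_k.copy()
    network.seg_k[mask] *= scale
    return network
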