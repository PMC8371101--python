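"""Ensemble experiments: condition runs, parameter sweeps, aggregation, I/O.

Ties the generation, constitutive, mechanics and percolation modules into
reproducible experiments.  Replicates derive child seeds deterministically
from a master seed (splittable counter scheme), run identical code paths at
desk scale (defaults: 50 replicates per condition, 200 networks for bond
percolation) or paper scale (3000 / 4000 / 40) by configuration only, and
are fully described by a JSON run manifest from which a run can be replayed
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import __version__
from .constitutive import (
    PRESETS,
    ConditionPreset,
    finalize_rest_lengths,
    initialize_isotropy,
    scale_elastin_stiffness,
)
from .mechanics import (
    FORCE_TOL,
    Constraints,
    StretchResult,
    equilibrate,
    run_stretch_protocol,
)
from .netgen import FiberNetwork, NetworkConfig, generate_network
from .percolation import percolation_strain

log = logging.getLogger("alveonet")

#: desk-scale default ensemble size per condition
DEFAULT_REPS = 50
#: retries for degenerate network realisations before giving up
RETRY_CAP = 5


def child_seed(master: int, index: int, attempt: int = 0) -> int:
    """Deterministic child seed for replicate ``index`` of a master seed."""
    ss = np.random.SeedSequence([int(master), int(index), int(attempt)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_specimen(
    config: NetworkConfig,
    preset: ConditionPreset,
    k_mode: str = "multiply",
    force_tol: float = FORCE_TOL,
    elastin_scale: float = 1.0,
    method: str = "lbfgs",
) -> tuple[FiberNetwork, np.ndarray]:
    """Generate one mechanics-ready network and its reference positions.

    Pipeline: seed fibers -> cross-link -> isotropising r0/k pass ->
    relax to the initial equilibrium (all four edges held co-linear, so
    the reference configuration stays spread over the unit square) ->
    final constitutive pass (elastin at rest, edge at 95%, collagen slack
    by its waviness factor).  Returns the finalised network and the
    equilibrium node positions from which the stretch protocol starts.
    """
    rng = config.rng()
    net = generate_network(config, rng)
    if not net.collagen_mask.any():
        raise ValueError("degenerate realisation: no collagen segments")
    if net.n_crossings == 0:
        raise ValueError("degenerate realisation: no fiber crossings")
    initialize_isotropy(net, rng)
    cons = Constraints.frame(net)
    state = equilibrate(net, cons, net.node_xy, force_tol=force_tol,
                        max_evals=200_000, method=method)
    eq_lengths = net.segment_lengths(state.positions)
    finalize_rest_lengths(net, eq_lengths, preset, rng, k_mode=k_mode)
    if elastin_scale != 1.0:
        scale_elastin_stiffness(net, elastin_scale)
    return net, state.positions


def simulate_stretch(
    seed: int,
    preset: ConditionPreset | str = "healthy",
    n: int = 48,
    alpha: float = 0.5,
    rho: float = 0.85,
    elastin_scale: float = 1.0,
    k_mode: str = "multiply",
    strain_step: float = 0.05,
    strain_max: float = 1.0,
    keep_positions: bool = False,
    force_tol: float = FORCE_TOL,
    method: str = "lbfgs",
) -> StretchResult:
    """One full realisation: build a specimen and run the stretch protocol."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    cfg = NetworkConfig(n=n, alpha=alpha, rho=rho, seed=seed)
    net, pos = build_specimen(cfg, preset, k_mode=k_mode, elastin_scale=elastin_scale,
                              force_tol=force_tol, method=method)
    return run_stretch_protocol(
        net, pos, strain_step=strain_step, strain_max=strain_max,
        force_tol=force_tol, keep_positions=keep_positions, method=method,
    )


def _run_replicate(master: int, index: int, **kwargs) -> tuple[StretchResult, int]:
    """Run one replicate, retrying degenerate realisations with fresh seeds."""
    last: Exception | None = None
    for attempt in range(RETRY_CAP):
        seed = child_seed(master, index, attempt)
        try:
            return simulate_stretch(seed, **kwargs), seed
        except ValueError as exc:
            last = exc
            log.warning("replicate %d seed %d degenerate (%s); retrying", index, seed, exc)
    raise RuntimeError(f"replicate {index} failed after {RETRY_CAP} attempts") from last


@dataclass
class EnsembleResult:
    """Stretch-protocol ensemble for one tissue condition.

    ``norm`` divides all stress samples; setting it to the healthy-condition
    mean stress at strain 1 implements the force normalisation used for
    cross-condition comparison (idempotent: the raw samples are kept).
    """

    condition: str
    strain: np.ndarray
    stress_samples: np.ndarray  # (n_reps, n_steps), raw
    recruitment_samples: np.ndarray  # (n_reps, n_steps)
    percolated_samples: np.ndarray  # (n_reps, n_steps) bool
    seeds: list[int]
    norm: float = 1.0
    results: list[StretchResult] = field(default_factory=list, repr=False)

    @property
    def n_reps(self) -> int:
        return len(self.seeds)

    @property
    def mean_stress(self) -> np.ndarray:
        return self.stress_samples.mean(axis=0) / self.norm

    @property
    def mean_recruitment(self) -> np.ndarray:
        return self.recruitment_samples.mean(axis=0)

    def stress_ci(self, level: float = 0.99):
        mean, lo, hi = aggregate_ci(self.stress_samples / self.norm, level)
        return mean, lo, hi

    def percolation_strains(self) -> list[float | None]:
        out = []
        for row in self.percolated_samples:
            idx = np.flatnonzero(row)
            out.append(float(self.strain[idx[0]]) if len(idx) else None)
        return out

    def recruitment_at_percolation(self) -> np.ndarray:
        """Per replicate: collagen recruitment at the first percolating strain.

        Replicates that never percolate are omitted.
        """
        vals = []
        for perc_row, rec_row in zip(self.percolated_samples, self.recruitment_samples):
            idx = np.flatnonzero(perc_row)
            if len(idx):
                vals.append(rec_row[idx[0]])
        return np.array(vals)

    def stress_at(self, strain: float) -> np.ndarray:
        step = int(np.argmin(np.abs(self.strain - strain)))
        return self.stress_samples[:, step] / self.norm


def run_condition_ensemble(
    preset: ConditionPreset | str,
    n_reps: int = DEFAULT_REPS,
    seed: int = 0,
    **kwargs,
) -> EnsembleResult:
    """Run ``n_reps`` independent stretch simulations of one condition.

    Child seeds are derived deterministically from the master seed; a
    degenerate realisation (no collagen, no crossings) is replaced by a
    fresh seed up to a retry cap, with a log record.  Returns raw
    (un-normalised) stresses; see :func:`normalize_to_healthy`.
    """
    if n_reps < 2:
        raise ValueError("an ensemble needs at least 2 replicates")
    if isinstance(preset, str):
        preset = PRESETS[preset]
    results, seeds = [], []
    for i in range(n_reps):
        res, s = _run_replicate(seed, i, preset=preset, **kwargs)
        results.append(res)
        seeds.append(s)
    strain = results[0].strain
    return EnsembleResult(
        condition=preset.name,
        strain=strain,
        stress_samples=np.array([r.stress for r in results]),
        recruitment_samples=np.array([r.recruitment for r in results]),
        percolated_samples=np.array([r.percolated for r in results]),
        seeds=seeds,
        results=results,
    )


def normalize_to_healthy(ensembles: dict[str, EnsembleResult]) -> dict[str, EnsembleResult]:
    """Normalise all stresses to the healthy-condition mean at strain 1.

    After this the healthy mean stress at strain 1 equals 1 exactly.
    Idempotent: the normalisation factor is recomputed from raw samples.
    """
    healthy = ensembles.get("healthy")
    if healthy is None:
        raise ValueError("normalisation requires a 'healthy' ensemble")
    ref = float(healthy.stress_samples[:, -1].mean())
    if ref <= 0:
        raise ValueError("healthy reference stress at strain 1 is not positive")
    for ens in ensembles.values():
        ens.norm = ref
    return ensembles


def aggregate_ci(samples: np.ndarray, level: float = 0.99, method: str = "normal",
                 n_boot: int = 2000, seed: int = 0):
    """Mean and confidence interval of the mean, per column.

    Default: symmetric normal approximation, mean +/- z * s / sqrt(n).
    ``method="bootstrap"`` resamples replicates instead.
    """
    x = np.atleast_2d(np.asarray(samples, float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a confidence interval")
    mean = x.mean(axis=0)
    if method == "normal":
        z = norm.ppf(0.5 + level / 2.0)
        half = z * x.std(axis=0, ddof=1) / np.sqrt(n)
        return mean, mean - half, mean + half
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = x[idx].mean(axis=1)
        lo = np.quantile(boots, 0.5 - level / 2.0, axis=0)
        hi = np.quantile(boots, 0.5 + level / 2.0, axis=0)
        return mean, lo, hi
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class SweepResult:
    """Per-(parameter, strain) ensemble statistics of a 1-D sweep."""

    parameter: str
    grid: np.ndarray
    strain: np.ndarray
    mean_recruitment: np.ndarray  # (n_grid, n_steps)
    percolation_counts: np.ndarray  # (n_grid, n_steps): replicates percolated by strain
    n_reps: int

    def peak_recruitment_strain(self) -> np.ndarray:
        """Strain at which mean recruitment first reaches its maximum, per cell.

        With curves that keep rising to the end of the strain grid this
        saturates at the last strain for every cell; use
        :meth:`half_rise_strain` to rank how early recruitment develops.
        """
        out = np.empty(len(self.grid))
        for i, row in enumerate(self.mean_recruitment):
            idx = int(np.flatnonzero(row >= row.max() - 1e-12)[0])
            out[i] = self.strain[idx]
        return out

    def half_rise_strain(self, level: float = 0.5) -> np.ndarray:
        """Strain at which mean recruitment crosses ``level`` x the sweep maximum.

        The reference is the largest mean recruitment over every
        (parameter, strain) cell, so all parameter values are ranked against
        one common recruitment level; the crossing is linearly interpolated
        between grid points.  Cells that never reach the level get +inf.
        A left-shifted (earlier-developing) recruitment curve gives a
        smaller value.
        """
        target = level * self.mean_recruitment.max()
        out = np.full(len(self.grid), np.inf)
        for i, row in enumerate(self.mean_recruitment):
            above = np.flatnonzero(row >= target)
            if len(above) == 0:
                continue
            j = int(above[0])
            if j == 0:
                out[i] = self.strain[0]
            else:
                x0, x1 = self.strain[j - 1], self.strain[j]
                y0, y1 = row[j - 1], row[j]
                out[i] = x0 + (target - y0) / (y1 - y0) * (x1 - x0)
        return out

    def optimum_scale(self, level: float = 0.5) -> float:
        """Parameter value minimising the half-rise strain, by quadratic fit.

        The half-rise profile over a log-spaced grid is a shallow basin;
        a pointwise argmin is dominated by Monte-Carlo noise, so the
        profile is fitted with a parabola in log10(parameter) and the
        vertex (clamped to the grid range) is returned.  Falls back to the
        discrete argmin when the fit has no interior minimum.
        """
        rise = self.half_rise_strain(level)
        ok = np.isfinite(rise)
        x = np.log10(self.grid[ok])
        y = rise[ok]
        if ok.sum() >= 3:
            a, b, _ = np.polyfit(x, y, 2)
            if a > 0:
                vertex = float(np.clip(-b / (2 * a), x.min(), x.max()))
                return float(10.0**vertex)
        return float(self.grid[int(np.argmin(rise))])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.grid):
            for j, eps in enumerate(self.strain):
                rows.append(
                    {
                        self.parameter: g,
                        "strain": eps,
                        "mean_recruitment": self.mean_recruitment[i, j],
                        "n_percolated": int(self.percolation_counts[i, j]),
                        "n_reps": self.n_reps,
                    }
                )
        return pd.DataFrame(rows)


def _sweep(parameter: str, grid, n_reps: int, seed: int, run_kwargs_of) -> SweepResult:
    grid = np.asarray(grid, float)
    mean_rec = []
    perc_counts = []
    strain = None
    for gi, g in enumerate(grid):
        rec_rows, perc_rows = [], []
        for i in range(n_reps):
            res, _ = _run_replicate(seed, gi * 100_000 + i, **run_kwargs_of(g))
            rec_rows.append(res.recruitment)
            perc_rows.append(np.cumsum(res.percolated) > 0)
            strain = res.strain
        mean_rec.append(np.mean(rec_rows, axis=0))
        perc_counts.append(np.sum(perc_rows, axis=0))
    return SweepResult(
        parameter=parameter,
        grid=grid,
        strain=strain,
        mean_recruitment=np.array(mean_rec),
        percolation_counts=np.array(perc_counts),
        n_reps=n_reps,
    )


def crosslink_sweep(
    preset: ConditionPreset | str,
    rho_grid=np.linspace(0.0, 1.0, 11),
    n_reps: int = 40,
    seed: int = 0,
    **kwargs,
) -> SweepResult:
    """Recruitment and mechanical percolation vs. cross-linking probability."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if np.any((np.asarray(rho_grid) < 0) | (np.asarray(rho_grid) > 1)):
        raise ValueError("rho grid must lie in [0, 1]")
    return _sweep(
        "rho",
        rho_grid,
        n_reps,
        seed,
        lambda rho: dict(preset=preset, rho=float(rho), **kwargs),
    )


def elastin_sweep(
    preset: ConditionPreset | str = "healthy",
    scale_grid=np.logspace(-3.0, 3.0, 7),
    n_reps: int = 40,
    seed: int = 0,
    **kwargs,
) -> SweepResult:
    """Recruitment vs. elastin spring-constant multiplier (baseline 1)."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if np.any(np.asarray(scale_grid) <= 0):
        raise ValueError("elastin scales must be positive")
    return _sweep(
        "elastin_scale",
        scale_grid,
        n_reps,
        seed,
        lambda s: dict(preset=preset, elastin_scale=float(s), **kwargs),
    )


# --------------------------------------------------------------------- export


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def make_manifest(config: dict, seeds: dict[str, list[int]] | None = None) -> dict:
    return {
        "package": "alveonet",
        "version": __version__,
        "config": config,
        "seeds": seeds or {},
        "solver": {"force_tol": FORCE_TOL, "method": "L-BFGS"},
    }


def export_results(
    outdir: str,
    manifest: dict,
    ensembles: dict[str, EnsembleResult] | None = None,
    sweeps: dict[str, SweepResult] | None = None,
) -> list[str]:
    """Write CSV result tables plus a JSON run manifest.

    All payloads are rendered in memory first and written atomically, so an
    unwritable path leaves no partial files behind.  Returns written paths.
    """
    payloads: list[tuple[str, str]] = []
    payloads.append((os.path.join(outdir, "manifest.json"),
                     json.dumps(manifest, indent=2, sort_keys=True)))
    for name, ens in (ensembles or {}).items():
        mean, lo, hi = ens.stress_ci()
        df = pd.DataFrame(
            {
                "strain": ens.strain,
                "mean_stress": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "mean_recruitment": ens.mean_recruitment,
                "n_percolated": ens.percolated_samples.cumsum(axis=1).astype(bool).sum(axis=0),
            }
        )
        payloads.append((os.path.join(outdir, f"ensemble_{name}.csv"),
                         df.to_csv(index=False)))
    for name, sweep in (sweeps or {}).items():
        payloads.append((os.path.join(outdir, f"sweep_{name}.csv"),
                         sweep.to_frame().to_csv(index=False)))
    os.makedirs(outdir, exist_ok=True)
    for path, text in payloads:
        _atomic_write(path, text)
    return [p for p, _ in payloads]
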