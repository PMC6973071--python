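"""Karplus forward-modelling of vicinal couplings and grid inversion of
coupling sets to compatible pseudorotamer regions.

A coupling path (e.g. "F2'-H1'") is governed by one endocyclic torsion
nu_k through a linear map theta = a*nu_k + b; J(theta) follows the
three-coefficient Karplus form.  Inversion scans a (P, tau_m) lattice:
the compatible region is the set of nodes whose predictions fall within
k*sigma of every observed coupling (a box criterion, since published
results quote hard P intervals); the chi-square surface is kept for
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sugar_pucker import torsions_from_pucker

__all__ = [
    "CouplingSet",
    "KarplusParams",
    "PseudorotationFit",
    "load_karplus_params",
    "read_coupling_table",
    "karplus_j",
    "predict_couplings",
    "fit_pseudorotation",
    "simulate_couplings",
]

KNOWN_PATHS = ("H1'-H2'", "H2'-H3'", "H3'-H4'", "F2'-H1'", "F2'-H3'")


@dataclass(frozen=True)
class CouplingSet:
    """Map path label -> (J in Hz, sigma in Hz)."""

    values: dict

    def __post_init__(self):
        for path, (j, sigma) in self.values.items():
            if j < 0:
                raise ValueError(f"{path}: J must be >= 0")
            if sigma < 0:
                raise ValueError(f"{path}: sigma must be >= 0")

    def paths(self):
        return tuple(self.values.keys())


@dataclass(frozen=True)
class KarplusParams:
    """Per-path Karplus coefficients and theta(nu) maps."""

    name: str
    coeffs: dict  # path -> (A, B, C) Hz
    theta_maps: dict  # path -> (nu_index, a, b)

    def __post_init__(self):
        for path, (_, a, _) in self.theta_maps.items():
            if a == 0:
                raise ValueError(f"{path}: slope a must be non-zero")


@dataclass
class PseudorotationFit:
    p_grid: np.ndarray
    tau_grid: np.ndarray
    chisq: np.ndarray  # shape (len(p_grid), len(tau_grid))
    best: tuple[float, float]
    compatible: list[tuple[float, float]]
    p_intervals: list[tuple[float, float]]
    k: float
    no_solution_at_k: bool = False
    meta: dict = field(default_factory=dict)


def load_karplus_params(name_or_path: str = "default") -> KarplusParams:
    """Load a named parameter set shipped as data, or a file path."""
    p = Path(name_or_path)
    if not p.exists():
        p = Path(__file__).parent / "data" / f"karplus_{name_or_path}.txt"
        if not p.exists():
            raise FileNotFoundError(f"no Karplus parameter set {name_or_path!r}")
    coeffs, maps = {}, {}
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        path, A, B, C, k, a, b = line.split("\t")
        coeffs[path] = (float(A), float(B), float(C))
        maps[path] = (int(k), float(a), float(b))
    return KarplusParams(name=str(name_or_path), coeffs=coeffs, theta_maps=maps)


def read_coupling_table(path) -> CouplingSet:
    """Read a TSV with columns path / J_Hz / sigma_Hz."""
    values = {}
    lines = [
        l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty coupling table: {path}")
    start = 1 if lines[0].lower().startswith("path") else 0
    for line in lines[start:]:
        pth, j, sigma = line.split("\t")
        values[pth.strip()] = (float(j), float(sigma))
    if not values:
        raise ValueError(f"no couplings found in {path}")
    return CouplingSet(values=values)


def karplus_j(theta: float, coeffs) -> float:
    """J(theta) = A cos^2(theta) + B cos(theta) + C."""
    A, B, C = coeffs
    c = math.cos(math.radians(theta))
    return A * c * c + B * c + C


def predict_couplings(P: float, tau_m: float, params: KarplusParams, paths=None) -> CouplingSet:
    """Model couplings at (P, tau_m); sigma is 0 (exact prediction)."""
    if paths is None:
        paths = tuple(params.coeffs.keys())
    missing = [p for p in paths if p not in params.coeffs or p not in params.theta_maps]
    if missing:
        raise ValueError(f"parameter set {params.name!r} lacks paths: {missing}")
    nu = torsions_from_pucker(P, tau_m).nu
    values = {}
    for path in paths:
        k, a, b = params.theta_maps[path]
        theta = a * nu[k] + b
        values[path] = (max(0.0, karplus_j(theta, params.coeffs[path])), 0.0)
    return CouplingSet(values=values)


def simulate_couplings(
    P: float, tau_m: float, params: KarplusParams, noise_sd: float, seed: int, paths=None
) -> CouplingSet:
    """Noisy synthetic observation: J + N(0, noise_sd), truncated at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    pred = predict_couplings(P, tau_m, params, paths)
    rng = np.random.default_rng(seed)
    values = {}
    for path, (j, _) in pred.values.items():
        values[path] = (max(0.0, j + float(rng.normal(0.0, noise_sd))), noise_sd)
    return CouplingSet(values=values)


def fit_pseudorotation(
    obs: CouplingSet,
    params: KarplusParams,
    p_step: float = 1.0,
    tau_range: tuple[float, float] = (25.0, 45.0),
    tau_step: float = 1.0,
    k: float = 1.0,
) -> PseudorotationFit:
    """Grid inversion of observed couplings to (P, tau_m) regions.

    ``compatible`` nodes satisfy |J_pred - J_obs| <= k*sigma for every
    observed path; ``p_intervals`` are the minimal circular intervals of
    compatible P (multimodal sets give multiple intervals, never
    merged).  With an empty compatible set the best chi-square node is
    still reported, flagged ``no_solution_at_k``.
    """
    if not obs.values:
        raise ValueError("need at least one observed coupling")
    p_grid = np.arange(0.0, 360.0, p_step)
    tau_grid = np.arange(tau_range[0], tau_range[1] + 1e-9, tau_step)
    paths = obs.paths()
    chisq = np.zeros((len(p_grid), len(tau_grid)))
    compat = np.ones((len(p_grid), len(tau_grid)), dtype=bool)
    for i, P in enumerate(p_grid):
        for j, tm in enumerate(tau_grid):
            pred = predict_couplings(P, tm, params, paths)
            c2 = 0.0
            ok = True
            for path in paths:
                j_obs, sigma = obs.values[path]
                j_pred = pred.values[path][0]
                diff = j_pred - j_obs
                sig = sigma if sigma > 0 else 1e-6
                c2 += (diff / sig) ** 2
                if abs(diff) > k * sigma:
                    ok = False
            chisq[i, j] = c2
            compat[i, j] = ok
    bi, bj = np.unravel_index(np.argmin(chisq), chisq.shape)
    best = (float(p_grid[bi]), float(tau_grid[bj]))
    compatible = [
        (float(p_grid[i]), float(tau_grid[j]))
        for i in range(len(p_grid))
        for j in range(len(tau_grid))
        if compat[i, j]
    ]
    p_intervals = _circular_intervals(
        sorted({p for p, _ in compatible}), step=p_step
    )
    return PseudorotationFit(
        p_grid=p_grid,
        tau_grid=tau_grid,
        chisq=chisq,
        best=best,
        compatible=compatible,
        p_intervals=p_intervals,
        k=k,
        no_solution_at_k=not compatible,
        meta={"paths": list(paths), "params": params.name},
    )


def _circular_intervals(p_values, step: float) -> list[tuple[float, float]]:
    """Cluster sorted P values into intervals on the 360-degree circle."""
    if not p_values:
        return []
    gaps = []
    n = len(p_values)
    for i in range(n):
        nxt = p_values[(i + 1) % n]
        gap = (nxt - p_values[i]) % 360.0
        gaps.append(gap)
    if n == 1:
        return [(p_values[0], p_values[0])]
    intervals = []
    # break the circle at every gap larger than one grid step
    breaks = [i for i, g in enumerate(gaps) if g > step * 1.5]
    if not breaks:
        return [(0.0, 360.0 - step)]
    for bi, brk in enumerate(breaks):
        start = p_values[(brk + 1) % n]
        end_idx = breaks[(bi + 1) % len(breaks)]
        end = p_values[end_idx]
        intervals.append((start, end))
    intervals.sort()
    return intervals
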