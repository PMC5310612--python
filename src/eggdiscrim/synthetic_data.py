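"""Synthetic spectra, visual-system presets and simulated experiments.

Generates eggshell-like reflectance along a natural (blue-green to brown)
and an artificial (green to purple) colour gradient, a default
ultraviolet-sensitive passerine visual system, and binary rejection
responses under a single-threshold or multiple-threshold decision rule,
so the whole pipeline is exercisable without field data.

Template shapes are package constants chosen so the natural gradient
spans roughly 0-8 JND under the default visual system; they are synthetic
stand-ins, not measurements, and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral_core import CANONICAL_GRID, Spectrum, SpectrumSet
from .visual_model import (
    ChromaticityPoint,
    GradientAxes,
    NoiseVector,
    ReceptorCatches,
    StimulusPredictors,
    VisualSystem,
    achromatic_contrast,
    chromatic_basis,
    gradient_projection,
    jnd_coordinates,
    quantum_catches,
    receptor_noise,
)
from .psychometrics import TrialTable, _link_funcs

__all__ = [
    "GradientSpec",
    "SimulationParams",
    "eggshell_spectrum",
    "make_visual_system",
    "simulate_experiment",
]

GRADIENTS = ("natural_bluegreen_brown", "artificial_green_purple")

# Synthetic endpoint templates (peak nm, width nm, amplitude, baseline).
_TEMPLATES = {
    "bluegreen": dict(kind="gauss", peak=500.0, width=55.0, amp=0.55, base=0.06),
    "brown": dict(kind="sigmoid", mid=600.0, width=45.0, amp=0.55, base=0.05),
    "green": dict(kind="gauss", peak=530.0, width=40.0, amp=0.50, base=0.06),
    "purple": dict(
        kind="bimodal",
        peaks=(405.0, 665.0),
        widths=(40.0, 45.0),
        amps=(0.45, 0.50),
        base=0.05,
    ),
}


@dataclass
class GradientSpec:
    """Position ``m`` in [0, 1] along one of the two colour gradients."""

    gradient: str
    m: float
    templates: dict = field(default_factory=lambda: _TEMPLATES)

    def __post_init__(self) -> None:
        if self.gradient not in GRADIENTS:
            raise ValueError(f"unknown gradient {self.gradient!r}; choose from {GRADIENTS}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("mix m must lie in [0, 1]")


@dataclass
class SimulationParams:
    """Parameters of a simulated egg-rejection experiment."""

    rule: str = "single_threshold"
    link: str = "logit"
    beta0: float = -2.8
    beta1: float = 2.43
    beta_achro: float = 0.0
    n: int = 52
    gradient: str = "both"
    #: sd of the smooth multiplicative spectral perturbation per egg;
    #: keeps the design away from a degenerate 1-D manifold.
    spectral_jitter_sd: float = 0.05
    flushed_p: float = 0.5
    clutch_sizes: tuple[int, ...] = (3, 4, 5)
    date_window: tuple[int, int] = (120, 180)
    nest_age_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("single_threshold", "multiple_threshold"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.gradient not in (*GRADIENTS, "both"):
            raise ValueError(f"unknown gradient {self.gradient!r}")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not np.isfinite(self.beta1):
            raise ValueError("beta1 must be finite")


def _template_curve(name: str, templates: dict, wl: np.ndarray) -> np.ndarray:
    t = templates[name]
    if t["kind"] == "gauss":
        v = t["base"] + t["amp"] * np.exp(-0.5 * ((wl - t["peak"]) / t["width"]) ** 2)
    elif t["kind"] == "sigmoid":
        v = t["base"] + t["amp"] / (1.0 + np.exp(-(wl - t["mid"]) / t["width"]))
    elif t["kind"] == "bimodal":
        v = t["base"] + sum(
            a * np.exp(-0.5 * ((wl - p) / w) ** 2)
            for p, w, a in zip(t["peaks"], t["widths"], t["amps"])
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown template kind {t['kind']!r}")
    return np.clip(v, 0.0, 1.0)


def eggshell_spectrum(g: GradientSpec, grid: np.ndarray = CANONICAL_GRID) -> Spectrum:
    """Reflectance at position ``m`` along the requested gradient.

    Linear mixture of the two endpoint templates, clipped to [0, 1].
    """
    if g.gradient == "natural_bluegreen_brown":
        lo = _template_curve("bluegreen", g.templates, grid)
        hi = _template_curve("brown", g.templates, grid)
    else:
        lo = _template_curve("green", g.templates, grid)
        hi = _template_curve("purple", g.templates, grid)
    v = np.clip((1.0 - g.m) * lo + g.m * hi, 0.0, 1.0)
    return Spectrum(grid, v, label=f"{g.gradient}_m{g.m:.3f}")


_PRESETS = ("uvs_default",)


def make_visual_system(preset: str = "uvs_default") -> VisualSystem:
    """Default ultraviolet-sensitive passerine visual system.

    Gaussian-template sensitivities peaking at 370/445/505/565 nm
    (U/S/M/L), broad double cone peaking at 565 nm, flat illuminant,
    densities 1:2:2:4, reference Weber fraction 0.1 on the most abundant
    (L) cone, achromatic Weber fraction 0.1.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {_PRESETS}")
    wl = CANONICAL_GRID
    peaks = {"U": 370.0, "S": 445.0, "M": 505.0, "L": 565.0}
    widths = {"U": 35.0, "S": 38.0, "M": 40.0, "L": 45.0}
    sens = {
        name: Spectrum(
            wl,
            np.exp(-0.5 * ((wl - peaks[name]) / widths[name]) ** 2),
            label=name,
            kind="sensitivity",
        )
        for name in ("U", "S", "M", "L")
    }
    double = Spectrum(
        wl,
        np.exp(-0.5 * ((wl - 565.0) / 80.0) ** 2),
        label="D",
        kind="sensitivity",
    )
    illum = Spectrum(wl, np.ones_like(wl), label="illum", kind="irradiance")
    return VisualSystem(
        receptor_names=("U", "S", "M", "L"),
        sensitivities=sens,
        double_cone=double,
        illuminant=illum,
        densities=np.array([1.0, 2.0, 2.0, 4.0]),
        weber_ref=0.1,
        weber_double=0.1,
    )


#: Host own-egg position on the natural gradient (slightly blue-green).
HOST_M = 0.25


def _uv_direction(
    origin_catches: ReceptorCatches, noise: NoiseVector, basis: np.ndarray
) -> np.ndarray:
    """Embedding displacement caused by a small +U catch perturbation."""
    Q2 = origin_catches.Q.copy()
    Q2[0] *= 1.01
    a = jnd_coordinates(origin_catches, noise, basis)
    b = jnd_coordinates(
        ReceptorCatches(Q=Q2, Q_D=origin_catches.Q_D), noise, basis
    )
    return b.coords - a.coords


def reference_geometry(
    vs: VisualSystem, host_m: float = HOST_M
) -> tuple[ReceptorCatches, GradientAxes, NoiseVector, np.ndarray]:
    """Host reference catches plus gradient axes under ``vs``."""
    noise = receptor_noise(vs)
    basis = chromatic_basis(noise)
    grid = vs.grid

    def _point(gradient: str, m: float) -> tuple[ReceptorCatches, ChromaticityPoint]:
        c = quantum_catches(eggshell_spectrum(GradientSpec(gradient, m), grid), vs)
        return c, jnd_coordinates(c, noise, basis)

    host_catches, host_pt = _point("natural_bluegreen_brown", host_m)
    _, bg = _point("natural_bluegreen_brown", 0.0)
    _, br = _point("natural_bluegreen_brown", 1.0)
    _, gr = _point("artificial_green_purple", 0.0)
    _, pu = _point("artificial_green_purple", 1.0)
    uv = _uv_direction(host_catches, noise, basis)
    _, axes = gradient_projection(
        [], bg, br, gr, pu, origin=host_pt, uv_direction=uv
    )
    return host_catches, axes, noise, basis


def simulate_experiment(
    p: SimulationParams, vs: VisualSystem | None = None
) -> tuple[TrialTable, SpectrumSet]:
    """Simulate one experiment: model-egg spectra and nest responses.

    Per nest, a gradient position m ~ U(0, 1) produces a model-egg
    spectrum; predictors are computed relative to the host reference
    colour; the response is Bernoulli with success probability
    inv_link(beta0 + beta1 * x [+ beta_achro * achromatic]) where x is
    the signed blue-green-to-brown coordinate (single_threshold) or the
    absolute chromatic contrast (multiple_threshold).  Fully seeded.
    """
    if vs is None:
        vs = make_visual_system()
    rng = np.random.default_rng(p.seed)
    host_catches, axes, noise, basis = reference_geometry(vs)
    host_pt = axes.origin
    inv_link = _link_funcs(p.link)[0]

    grid = vs.grid
    rows = []
    spectra = []
    ms = rng.uniform(0.0, 1.0, p.n)
    if p.gradient == "both":
        gradients = np.where(
            rng.uniform(size=p.n) < 0.5, GRADIENTS[0], GRADIENTS[1]
        )
    else:
        gradients = np.full(p.n, p.gradient)
    jitter = rng.normal(0.0, p.spectral_jitter_sd, size=(p.n, 3))
    flushed = (rng.uniform(size=p.n) < p.flushed_p).astype(int)
    clutch = rng.choice(np.asarray(p.clutch_sizes), size=p.n)
    dates = rng.integers(p.date_window[0], p.date_window[1] + 1, p.n)
    ages = rng.integers(p.nest_age_range[0], p.nest_age_range[1] + 1, p.n)
    u = rng.uniform(size=p.n)
    s = (grid - 500.0) / 200.0  # smooth low-order spectral perturbation
    for i in range(p.n):
        spec = eggshell_spectrum(GradientSpec(str(gradients[i]), ms[i]), grid)
        e0, e1, e2 = jitter[i]
        vals = np.clip(spec.values * np.exp(e0 + e1 * s + e2 * s * s), 0.0, 1.0)
        spec = Spectrum(grid, vals, label=f"egg_{i:04d}")
        spectra.append(spec)
        catches = quantum_catches(spec, vs)
        pt = jnd_coordinates(catches, noise, basis)
        d = pt.coords - host_pt.coords
        x_bgbr = float(d @ axes.bluegreen_brown)
        x_gp = float(d @ axes.green_purple)
        x_uv = float(d @ axes.uv_axis)
        chrom = float(np.linalg.norm(d))
        achro = achromatic_contrast(catches, host_catches, noise.omega_D)
        x = x_bgbr if p.rule == "single_threshold" else chrom
        prob = float(inv_link(p.beta0 + p.beta1 * x + p.beta_achro * achro))
        rows.append(
            {
                "nest_id": f"nest_{i:04d}",
                "response": int(u[i] < prob),
                "x_bgbr": x_bgbr,
                "x_gp": x_gp,
                "x_uv": x_uv,
                "chromatic_contrast": chrom,
                "achromatic_contrast": achro,
                "flushed": int(flushed[i]),
                "clutch_size": int(clutch[i]),
                "laying_date": int(dates[i]),
                "nest_age": int(ages[i]),
                "m": float(ms[i]),
                "gradient": str(gradients[i]),
            }
        )
    table = TrialTable(pd.DataFrame(rows))
    sset = SpectrumSet(
        grid=grid, spectra=spectra, metadata={"source": "simulated", "units": "proportion"}
    )
    return table, sset
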