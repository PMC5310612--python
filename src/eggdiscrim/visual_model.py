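"""Receptor-noise-limited (RNL) colour modelling.

Quantum catches, Weber-fraction noise, chromatic/achromatic contrast in
just-noticeable-difference (JND) units, a JND-metric chromaticity
embedding, and signed projections onto experimental colour-gradient axes.

The chromaticity embedding places each stimulus at Cartesian coordinates
such that Euclidean distance between two points equals their RNL
chromatic contrast; the achromatic direction (uniform scaling of all
catches) is projected out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .spectral_core import CANONICAL_GRID, Spectrum

__all__ = [
    "VisualSystem",
    "ReceptorCatches",
    "NoiseVector",
    "ChromaticityPoint",
    "GradientAxes",
    "StimulusPredictors",
    "quantum_catches",
    "receptor_noise",
    "chromatic_contrast",
    "achromatic_contrast",
    "jnd_coordinates",
    "chromatic_basis",
    "mean_catches",
    "gradient_projection",
]


@dataclass
class VisualSystem:
    """Tetrachromatic visual system: sensitivities, illuminant, noise.

    ``receptor_names`` orders the four chromatic channels (conventionally
    U, S, M, L); ``double_cone`` is the achromatic channel.  ``densities``
    are relative receptor abundances; ``weber_ref`` is the Weber fraction
    of the most abundant receptor and ``weber_double`` that of the
    achromatic channel.
    """

    receptor_names: tuple[str, ...]
    sensitivities: dict[str, Spectrum]
    double_cone: Spectrum
    illuminant: Spectrum
    densities: np.ndarray
    weber_ref: float
    weber_double: float

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.receptor_names) != 4:
            raise ValueError("exactly 4 chromatic receptors required")
        if set(self.receptor_names) != set(self.sensitivities):
            raise ValueError("sensitivities must match receptor_names")
        if self.densities.shape != (4,) or np.any(self.densities <= 0):
            raise ValueError("densities must be 4 positive values")
        if not 0 < self.weber_ref < 1:
            raise ValueError("weber_ref must be in (0, 1)")
        if not 0 < self.weber_double < 1:
            raise ValueError("weber_double must be in (0, 1)")
        grid = self.illuminant.wavelengths_nm
        for s in [*self.sensitivities.values(), self.double_cone]:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise ValueError("all visual-system spectra must share a grid")

    @property
    def grid(self) -> np.ndarray:
        return self.illuminant.wavelengths_nm


@dataclass
class ReceptorCatches:
    """Per-receptor quantum catches (arbitrary linear units, > 0)."""

    Q: np.ndarray
    Q_D: float
    label: str = ""

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q <= 0) or self.Q_D <= 0 or not np.all(np.isfinite(self.Q)):
            raise ValueError(f"non-positive quantum catch ({self.label!r})")


@dataclass
class NoiseVector:
    """Weber fractions per chromatic receptor plus the achromatic channel."""

    omega: np.ndarray
    omega_D: float

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega <= 0) or np.any(self.omega >= 1):
            raise ValueError("receptor Weber fractions must be in (0, 1)")
        if not 0 < self.omega_D < 1:
            raise ValueError("omega_D must be in (0, 1)")


@dataclass
class ChromaticityPoint:
    """A stimulus located in the 3-D JND-metric chromaticity space."""

    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("chromaticity coordinates must be 3-D")

    def distance(self, other: "ChromaticityPoint") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class GradientAxes:
    """Orthonormal gradient basis anchored at the host mean colour."""

    origin: ChromaticityPoint
    bluegreen_brown: np.ndarray
    green_purple: np.ndarray
    uv_axis: np.ndarray

    def __post_init__(self) -> None:
        basis = np.stack(
            [self.bluegreen_brown, self.green_purple, self.uv_axis]
        ).astype(float)
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-9):
            raise ValueError("gradient basis is not orthonormal")
        self.bluegreen_brown, self.green_purple, self.uv_axis = basis


@dataclass
class StimulusPredictors:
    """Signed per-axis JND coordinates plus absolute contrasts."""

    x_bgbr: float
    x_gp: float
    x_uv: float
    chromatic_contrast: float
    achromatic_contrast: float = np.nan
    label: str = ""


def quantum_catches(reflectance: Spectrum, vs: VisualSystem) -> ReceptorCatches:
    """Integrate reflectance x sensitivity x illuminant per receptor.

    Trapezoidal quadrature on the shared wavelength grid.
    """
    grid = vs.grid
    if not np.array_equal(reflectance.wavelengths_nm, grid):
        raise ValueError("reflectance is not on the visual-system grid")
    R = reflectance.values
    I = vs.illuminant.values
    Q = np.array(
        [
            np.trapezoid(R * vs.sensitivities[name].values * I, grid)
            for name in vs.receptor_names
        ]
    )
    Q_D = float(np.trapezoid(R * vs.double_cone.values * I, grid))
    return ReceptorCatches(Q=Q, Q_D=Q_D, label=reflectance.label)


def receptor_noise(vs: VisualSystem) -> NoiseVector:
    """Weber fractions from relative receptor densities.

    omega_i = weber_ref * sqrt(eta_ref / eta_i), with eta_ref the largest
    density (the reference receptor); the achromatic Weber fraction is
    passed through unchanged.
    """
    eta_ref = vs.densities.max()
    omega = vs.weber_ref * np.sqrt(eta_ref / vs.densities)
    return NoiseVector(omega=omega, omega_D=vs.weber_double)


def chromatic_contrast(
    a: ReceptorCatches, b: ReceptorCatches, noise: NoiseVector
) -> float:
    """RNL chromatic contrast (JND) between two stimuli.

    Uses the noise-weighted line element with log catch differences
    f_i = ln(Q_i^a / Q_i^b): for n receptors,

        dS^2 = sum_{i<j} (prod_{k not in {i,j}} w_k)^2 (f_i - f_j)^2
               / sum_{m} (prod_{k != m} w_k)^2

    which reduces to the familiar di-/tri-/tetrachromat forms.
    """
    w = noise.omega
    df = np.log(a.Q) - np.log(b.Q)
    n = len(w)
    num = 0.0
    for i, j in itertools.combinations(range(n), 2):
        others = [k for k in range(n) if k != i and k != j]
        num += np.prod(w[others]) ** 2 * (df[i] - df[j]) ** 2
    den = sum(np.prod(np.delete(w, m)) ** 2 for m in range(n))
    return float(np.sqrt(num / den))


def achromatic_contrast(
    a: ReceptorCatches, b: ReceptorCatches, omega_D: float
) -> float:
    """Achromatic contrast |ln(Q_D^a / Q_D^b)| / omega_D (JND)."""
    if a.Q_D <= 0 or b.Q_D <= 0:
        raise ValueError("non-positive double-cone catch")
    return float(abs(np.log(a.Q_D / b.Q_D)) / omega_D)


def chromatic_basis(noise: NoiseVector) -> np.ndarray:
    """Orthonormal 4x3 basis of the chromatic subspace.

    In the space of noise-scaled log catches x_i = ln(Q_i)/omega_i the
    achromatic direction (equal multiplicative change of all catches) is
    u_i = 1/omega_i; the chromatic subspace is its orthogonal complement.
    Deterministic for a given noise vector.
    """
    u = (1.0 / noise.omega).reshape(1, -1)
    B = null_space(u)  # 4 x 3, orthonormal columns
    # Fix column signs for determinism across platforms.
    for j in range(B.shape[1]):
        k = np.argmax(np.abs(B[:, j]))
        if B[k, j] < 0:
            B[:, j] = -B[:, j]
    return B


def jnd_coordinates(
    c: ReceptorCatches, noise: NoiseVector, basis: np.ndarray | None = None
) -> ChromaticityPoint:
    """Embed catches in the 3-D chromaticity space (JND metric).

    Euclidean distance between embedded points equals
    :func:`chromatic_contrast`; uniform scaling of all catches (a pure
    achromatic shift) leaves the coordinates unchanged.
    """
    if basis is None:
        basis = chromatic_basis(noise)
    x = np.log(c.Q) / noise.omega
    return ChromaticityPoint(coords=basis.T @ x, label=c.label)


def mean_catches(catches: list[ReceptorCatches], label: str = "mean") -> ReceptorCatches:
    """Geometric-mean catches across stimuli (mean of log catches).

    Log-space averaging keeps the population mean inside the geometry of
    the log-catch embedding; used for the host-population reference colour.
    """
    if not catches:
        raise ValueError("empty catch list")
    logQ = np.mean([np.log(c.Q) for c in catches], axis=0)
    logQD = np.mean([np.log(c.Q_D) for c in catches])
    return ReceptorCatches(Q=np.exp(logQ), Q_D=float(np.exp(logQD)), label=label)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate gradient geometry")
    return v / n


def gradient_projection(
    points: list[ChromaticityPoint],
    bluegreen_end: ChromaticityPoint,
    brown_end: ChromaticityPoint,
    green_end: ChromaticityPoint,
    purple_end: ChromaticityPoint,
    origin: ChromaticityPoint,
    uv_direction: np.ndarray | None = None,
) -> tuple[list[StimulusPredictors], GradientAxes]:
    """Project chromaticity points onto the experimental gradient axes.

    Axis 1 runs from the blue-green endpoint toward the brown endpoint
    (browner = positive).  Axis 2 is the component of the purple-to-green
    direction orthogonal to axis 1 (greener = positive).  Axis 3 is the
    remaining orthonormal direction, signed so that increasing
    ultraviolet-receptor catch increases the coordinate when
    ``uv_direction`` (the embedding image of a +U perturbation) is given.

    Returns per-point signed predictors (whose Euclidean norm equals the
    chromatic contrast to the origin) and the axes.
    """
    a1 = _unit(brown_end.coords - bluegreen_end.coords)
    g = green_end.coords - purple_end.coords
    g_orth = g - (g @ a1) * a1
    if np.linalg.norm(g_orth) < 1e-9:
        raise ValueError("degenerate gradient geometry: axes colinear")
    a2 = _unit(g_orth)
    a3 = np.cross(a1, a2)
    if uv_direction is not None:
        uv = np.asarray(uv_direction, dtype=float)
        if uv @ a3 < 0:
            a3 = -a3
    axes = GradientAxes(
        origin=origin, bluegreen_brown=a1, green_purple=a2, uv_axis=a3
    )
    preds = []
    for p in points:
        d = p.coords - origin.coords
        preds.append(
            StimulusPredictors(
                x_bgbr=float(d @ a1),
                x_gp=float(d @ a2),
                x_uv=float(d @ a3),
                chromatic_contrast=float(np.linalg.norm(d)),
                label=p.label,
            )
        )
    return preds, axes
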