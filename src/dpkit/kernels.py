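"""Scaled dose point kernel containers and their on-disk CSV form.

A scaled DPK (sDPK) expresses the radial absorbed-energy distribution
around an isotropic point electron source in dimensionless form,

    F(x) = 4*pi*rho*r^2*r0*Phi(r),   x = r/r0,

so that F(x)*dx is the fraction of emitted energy absorbed in the shell
[x, x+dx].  Three abscissa scales occur in practice: ``r0`` (the CSDA
range of a monoenergetic source), ``rN`` (the range at the maximum beta
energy of a radionuclide spectrum) and ``X90`` (the radius containing
90% of the absorbed energy, used for cross-study comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ShellGrid", "BetaGrid", "CustomGrid", "ScaledDPK", "write_kernel_csv", "read_kernel_csv"]


@dataclass(frozen=True)
class ShellGrid:
    """Monoenergetic scoring grid: 60 shells of thickness R_CSDA/40 out to 1.5*R_CSDA."""

    n_shells: int = 60
    thickness: float = 1.0 / 40.0  # d(r/r0)

    def __post_init__(self) -> None:
        if self.n_shells < 1 or self.thickness <= 0:
            raise ValueError("grid needs n_shells >= 1 and positive thickness")

    @property
    def outer_radius(self) -> float:
        return self.n_shells * self.thickness

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_shells) + 0.5) * self.thickness


@dataclass(frozen=True)
class BetaGrid:
    """Beta-kernel grid: 120 shells of thickness r_N/100 out to 1.2*r_N."""

    r_n_cm: float
    n_shells: int = 120
    thickness: float = 1.0 / 100.0

    def __post_init__(self) -> None:
        if not self.r_n_cm > 0:
            raise ValueError("r_N must be positive")
        if self.n_shells < 1 or self.thickness <= 0:
            raise ValueError("grid needs n_shells >= 1 and positive thickness")

    @property
    def outer_radius(self) -> float:
        return self.n_shells * self.thickness

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_shells) + 0.5) * self.thickness


@dataclass(frozen=True)
class CustomGrid:
    """Explicit-midpoint grid (e.g. after X90 rescaling)."""

    midpoints: np.ndarray
    thickness: float
    r_n_cm: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.midpoints, float)
        if m.ndim != 1 or m.size < 1 or self.thickness <= 0:
            raise ValueError("invalid custom grid")
        object.__setattr__(self, "midpoints", m)

    @property
    def n_shells(self) -> int:
        return self.midpoints.size

    @property
    def outer_radius(self) -> float:
        return float(self.midpoints[-1] + 0.5 * self.thickness)


@dataclass(frozen=True)
class ScaledDPK:
    """A scaled DPK: shell grid plus F values and provenance.

    ``scale`` records the abscissa convention: "r0" (monoenergetic CSDA
    range), "rN" (beta maximum-energy range) or "X90".
    """

    grid: ShellGrid | BetaGrid | CustomGrid
    values: np.ndarray
    material_label: str = ""
    energy0_kev: float | None = None
    scale: str = "r0"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (self.grid.n_shells,):
            raise ValueError(
                f"values shape {v.shape} does not match grid ({self.grid.n_shells} shells)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("kernel values must be finite")
        if np.any(v < 0):
            raise ValueError("kernel values must be non-negative")
        if self.integral > 1.02:
            raise ValueError(
                f"kernel integral {self.integral:.4f} exceeds 1.02 (energy conservation)"
            )
        object.__setattr__(self, "values", v)

    @property
    def x(self) -> np.ndarray:
        return self.grid.midpoints

    @property
    def integral(self) -> float:
        """Sum F*dx — absorbed fraction of emitted energy inside the grid."""
        return float(np.sum(np.asarray(self.values, float)) * self.grid.thickness)

    def interpolate(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation of F at scaled distances ``x``; 0 beyond the grid."""
        return np.interp(np.asarray(x, float), self.x, self.values, right=0.0)


def write_kernel_csv(path, kernel: ScaledDPK) -> None:
    """Kernel CSV: metadata header lines (#) then ``x,F`` rows."""
    with open(path, "w") as fh:
        fh.write(f"# material={kernel.material_label}\n")
        fh.write(f"# scale={kernel.scale}\n")
        if kernel.energy0_kev is not None:
            fh.write(f"# energy0_keV={float(kernel.energy0_kev)!r}\n")
        r_n = getattr(kernel.grid, "r_n_cm", None)
        if r_n is not None:
            fh.write(f"# r_N_cm={float(r_n)!r}\n")
        fh.write(f"# thickness={float(kernel.grid.thickness)!r}\n")
        fh.write("x,F\n")
        for xi, fi in zip(kernel.x, kernel.values):
            fh.write(f"{float(xi)!r},{float(fi)!r}\n")


def read_kernel_csv(path) -> ScaledDPK:
    meta: dict[str, str] = {}
    xs: list[float] = []
    fs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.lower().startswith("x,"):
                continue
            else:
                a, b = line.split(",")
                xs.append(float(a))
                fs.append(float(b))
    thickness = float(meta["thickness"])
    r_n = float(meta["r_N_cm"]) if "r_N_cm" in meta else None
    grid = CustomGrid(np.asarray(xs), thickness, r_n_cm=r_n)
    e0 = float(meta["energy0_keV"]) if "energy0_keV" in meta else None
    return ScaledDPK(
        grid=grid,
        values=np.asarray(fs),
        material_label=meta.get("material", ""),
        energy0_kev=e0,
        scale=meta.get("scale", "r0"),
    )
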