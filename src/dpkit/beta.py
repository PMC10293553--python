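"""Beta-emitter scaled DPKs synthesized from monoenergetic kernels.

A beta spectrum is a set of (energy, intensity) lines.  With per-line
monoenergetic kernels F_j on the r/r0_j scale, the radionuclide kernel
on the r/r_N scale (r_N the CSDA range at the spectrum endpoint E_max)
is the intensity- and energy-weighted combination

    F_beta(r/r_N) = r_N * sum_j I_j * E_0j * F_j(r/r_0j) / r_0j / E_eff,

with line intensities normalized to unit sum and E_eff = sum_j I_j E_0j
the mean (effective) emission energy.  For a single line this collapses
to the monoenergetic kernel re-gridded onto the beta grid.

Monoenergetic kernels may come from a trained regressor chain or from
an imported Monte Carlo kernel table; each F_j is evaluated by linear
interpolation on its own 60-point grid, with F = 0 beyond the scoring
sphere (x > 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline

from .chain import ChainModel, predict_chain
from .emulator import FEATURE_COLUMNS, feature_row
from .kernels import BetaGrid, CustomGrid, ScaledDPK
from .materials import MaterialSpec
from .ranges import RangeTable, csda_range

__all__ = [
    "BetaSpectrum",
    "RadionuclideData",
    "resample_spectrum",
    "builtin_nuclides",
    "synthetic_beta_spectrum",
    "beta_sdpk",
    "x90_rescale",
    "mape_vs_reference",
    "read_spectrum_csv",
]

_VALID_LO, _VALID_HI = 10.0, 3000.0


@dataclass(frozen=True)
class BetaSpectrum:
    """Discretized beta emission spectrum, intensities normalized to unit sum."""

    energies_kev: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, float)
        i = np.asarray(self.intensities, float)
        if e.ndim != 1 or e.shape != i.shape or e.size < 1:
            raise ValueError("spectrum needs matching 1-D energy/intensity arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("spectrum energies must be strictly ascending")
        if np.any(i < 0) or i.sum() <= 0:
            raise ValueError("intensities must be non-negative with positive sum")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "intensities", i / i.sum())

    @property
    def e_max(self) -> float:
        return float(self.energies_kev[-1])

    @property
    def e_eff(self) -> float:
        """Mean emission energy sum_j I_j E_0j (unit-sum intensities), keV."""
        return float(self.intensities @ self.energies_kev)


@dataclass(frozen=True)
class RadionuclideData:
    name: str
    half_life_hours: float
    spectrum: BetaSpectrum

    def __post_init__(self) -> None:
        if not self.half_life_hours > 0:
            raise ValueError("half-life must be positive")


def resample_spectrum(energies_kev, intensities, n_points: int = 1000) -> BetaSpectrum:
    """Cubic-spline resampling onto ``n_points`` equally spaced energies.

    The raw (energy, intensity) pairs are fit with a degree-3 spline and
    evaluated from 10 keV up to E_max (the last raw energy); negative
    spline values are clipped to zero and the result renormalized.
    """
    e = np.asarray(energies_kev, float)
    i = np.asarray(intensities, float)
    if e.size < 4:
        raise ValueError("need at least 4 raw points for cubic-spline resampling")
    if np.any(np.diff(e) <= 0):
        raise ValueError("raw energies must be strictly ascending")
    e_max = float(e[-1])
    if e_max <= _VALID_LO:
        raise ValueError(f"spectrum endpoint {e_max} keV must exceed {_VALID_LO} keV")
    spl = InterpolatedUnivariateSpline(e, i, k=3, ext="zeros")
    grid = np.linspace(_VALID_LO, e_max, n_points)
    vals = np.clip(spl(grid), 0.0, None)
    if vals.sum() <= 0:
        raise ValueError("resampled spectrum vanished (check raw intensities)")
    return BetaSpectrum(grid, vals)


def synthetic_beta_spectrum(q_kev: float, n_raw: int = 400) -> BetaSpectrum:
    """Allowed-shape parametric test spectrum N(E) ∝ sqrt(E²+2E·mc²)·(Q−E)².

    A stand-in with the qualitative shape of a real allowed beta
    spectrum; real decay data (e.g. ICRP 107) is user-supplied via CSV.
    """
    mec2 = 510.99895
    e = np.linspace(_VALID_LO, q_kev, n_raw)
    n = np.sqrt(e**2 + 2.0 * e * mec2) * (q_kev - e) ** 2
    return resample_spectrum(e, n)


def builtin_nuclides() -> dict[str, RadionuclideData]:
    """Three fictitious beta emitters spanning low/mid/high endpoint energies."""
    specs = {
        "demo-lo": (500.0, 40.0),
        "demo-mid": (800.0, 150.0),
        "demo-hi": (2280.0, 64.2),
    }
    return {
        name: RadionuclideData(name, t_half, synthetic_beta_spectrum(q))
        for name, (q, t_half) in specs.items()
    }


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Spectrum CSV with header ``energy_keV,intensity``."""
    df = pd.read_csv(path)
    if not {"energy_keV", "intensity"} <= set(df.columns):
        raise ValueError("spectrum CSV needs columns energy_keV,intensity")
    return df["energy_keV"].to_numpy(float), df["intensity"].to_numpy(float)


def _mono_kernels_from_table(table, energies, material_label):
    """Per-line kernels from an imported table, linear in energy between entries."""
    avail = sorted(e for (lab, e) in table if lab == material_label)
    if not avail:
        raise ValueError(f"kernel table has no entries for material {material_label!r}")
    avail = np.asarray(avail)
    any_k = table[(material_label, float(avail[0]))]
    x = any_k.x
    stack = np.stack(
        [table[(material_label, float(e))].values for e in avail]
    )  # (n_avail, n_shells)
    out = np.empty((len(energies), x.size))
    for j, e in enumerate(energies):
        if e <= avail[0]:
            out[j] = stack[0]
        elif e >= avail[-1]:
            out[j] = stack[-1]
        else:
            hi = int(np.searchsorted(avail, e))
            lo = hi - 1
            t = (e - avail[lo]) / (avail[hi] - avail[lo])
            out[j] = (1 - t) * stack[lo] + t * stack[hi]
    return x, out


def beta_sdpk(
    source,
    spectrum: BetaSpectrum,
    material: MaterialSpec,
    *,
    range_override: RangeTable | None = None,
) -> ScaledDPK:
    """Synthesize the beta-emitter sDPK on the 120-shell r_N grid.

    ``source`` is either a trained :class:`~dpkit.chain.ChainModel` or a
    kernel table from :func:`dpkit.emulator.import_kernel_table`.
    """
    e = spectrum.energies_kev
    bad = e[(e < _VALID_LO) | (e > _VALID_HI)]
    if bad.size:
        raise ValueError(
            f"spectrum lines outside model validity [{_VALID_LO}, {_VALID_HI}] keV: "
            f"{np.array2string(bad[:8], precision=1)}"
        )
    r_n = csda_range(spectrum.e_max, material, override=range_override).r0_linear
    r0 = np.array(
        [csda_range(ek, material, override=range_override).r0_linear for ek in e]
    )
    grid = BetaGrid(r_n_cm=r_n)
    r = grid.midpoints * r_n  # cm

    if isinstance(source, ChainModel):
        feats = pd.DataFrame([feature_row(material, ek) for ek in e],
                             columns=list(FEATURE_COLUMNS))
        mono = np.clip(predict_chain(source, feats), 0.0, None)  # (n_lines, 60)
        from .kernels import ShellGrid

        x_mono = ShellGrid(n_shells=mono.shape[1]).midpoints
    elif isinstance(source, dict):
        x_mono, mono = _mono_kernels_from_table(source, e, material.label)
    else:
        raise TypeError("source must be a ChainModel or an imported kernel table dict")

    weights = spectrum.intensities * e / spectrum.e_eff  # sum_j w_j * E-normalization
    f_beta = np.zeros(grid.n_shells)
    for j in range(e.size):
        u = r / r0[j]
        f_beta += weights[j] * (r_n / r0[j]) * np.interp(u, x_mono, mono[j], right=0.0)
    f_beta = np.clip(f_beta, 0.0, None)
    return ScaledDPK(
        grid=grid,
        values=f_beta,
        material_label=material.label,
        energy0_kev=None,
        scale="rN",
    )


def x90_rescale(kernel: ScaledDPK) -> ScaledDPK:
    """Re-express a kernel on the X90 scale (90%-absorption radius = 1).

    X90 is found by linear interpolation of the cumulative F·dx curve at
    0.9 of the kernel's own integral; abscissae are divided by X90 and F
    multiplied by it, so the integral is preserved exactly.
    """
    dx = kernel.grid.thickness
    cum = np.cumsum(kernel.values) * dx
    total = cum[-1]
    if total <= 0:
        raise ValueError("kernel integral is zero; X90 undefined")
    target = 0.9 * total
    edges = (np.arange(kernel.grid.n_shells) + 1) * dx  # outer shell edges
    idx = int(np.searchsorted(cum, target))
    if idx >= cum.size:
        raise ValueError("cumulative absorbed energy never reaches the 90% level")
    c_lo = cum[idx - 1] if idx > 0 else 0.0
    e_lo = edges[idx - 1] if idx > 0 else 0.0
    x90 = e_lo + (target - c_lo) / (cum[idx] - c_lo) * (edges[idx] - e_lo)
    r_n = getattr(kernel.grid, "r_n_cm", None)
    grid = CustomGrid(
        kernel.x / x90,
        dx / x90,
        r_n_cm=None if r_n is None else r_n * x90,  # physical length of one X90 unit
    )
    return ScaledDPK(
        grid=grid,
        values=kernel.values * x90,
        material_label=kernel.material_label,
        energy0_kev=kernel.energy0_kev,
        scale="X90",
    )


def mape_vs_reference(kernel: ScaledDPK, reference: ScaledDPK) -> float:
    """Mean absolute percentage error of ``kernel`` against ``reference``.

    The reference is linearly interpolated onto the kernel's abscissae;
    only shells inside the reference support with nonzero reference
    values are compared.
    """
    x = kernel.x
    inside = (x >= reference.x[0]) & (x <= reference.x[-1])
    ref = np.interp(x, reference.x, reference.values)
    ok = inside & (ref != 0)
    if not ok.any():
        raise ValueError("kernels have no overlapping nonzero support")
    return float(100.0 * np.mean(np.abs(ref[ok] - kernel.values[ok]) / np.abs(ref[ok])))
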