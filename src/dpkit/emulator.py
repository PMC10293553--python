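"""Synthetic shell-scored energy deposition for monoenergetic electrons.

This module is a documented *parametric emulator* of the output of a
condensed-history Monte Carlo shell-scoring run: a point isotropic
monoenergetic electron source at the centre of a homogeneous sphere
scored on 60 concentric shells of thickness R_CSDA/40 (outer radius
1.5*R_CSDA).  It is not transport physics; it produces kernels with the
qualitative features of real ones — a single interior peak that moves
outward with energy, a soft-tissue-like dependence on the effective
atomic number, a radiative-loss deficit in the energy balance, and
multiplicative counting noise of ~1% at the peak shell (for 1e7
primaries) growing toward the tail — so that every downstream stage can
be built and tested without a transport engine.  Real Monte Carlo
kernels can be substituted anywhere via :func:`import_kernel_table`.

The noiseless shape family is

    g(x) = x^a * exp(-b * x^c),          x = r/R_CSDA, c = 2.2,
    a = clip(0.6 + 0.25*ln(E/100 keV), 0.2, 1.8),
    m = clip(0.35 + 0.05*ln(E/100 keV) + 0.01*(z_eff - 7), 0.2, 0.7),
    b = a / (c * m^c)                     (so the mode of g sits at x = m),

normalised so that the 60-shell sum of deposited fractions equals
eta = 1 - Y with the radiative-loss proxy
Y = 6e-4*z_eff*T_MeV / (1 + 6e-4*z_eff*T_MeV) (the radiated part is the
only energy unaccounted for; the shape family puts negligible mass
beyond the 1.5*R_CSDA scoring sphere).  Per-shell multiplicative
Gaussian noise has relative sigma

    sigma_i = 0.01 * sqrt(f_peak / max(f_i, 1e-4)) * sqrt(1e7 / n_primaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from .kernels import ScaledDPK, ShellGrid
from .materials import MaterialSpec, effective_za, material_lookup
from .ranges import csda_range

__all__ = [
    "ShellEdep",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "emulate_shell_edep",
    "noiseless_edep_fractions",
    "edep_to_sdpk",
    "generate_dataset",
    "feature_row",
    "import_kernel_table",
    "export_kernel_table",
]

#: Feature order used by the regressor chain (N and O deliberately absent).
FEATURE_COLUMNS = (
    "E0_keV",
    "R_CSDA_g_cm2",
    "density",
    "w_H",
    "w_C",
    "w_Na",
    "w_Mg",
    "w_P",
    "w_S",
    "w_Cl",
    "w_Ar",
    "w_K",
    "w_Ca",
)

TARGET_COLUMNS = tuple(f"F{i:02d}" for i in range(1, 61))

_ENERGY_LO, _ENERGY_HI = 10.0, 3000.0


@dataclass(frozen=True)
class ShellEdep:
    """Per-shell deposited energy fractions delta_E/E0 for one source."""

    energy0_kev: float
    material: MaterialSpec
    grid: ShellGrid
    edep_fraction: np.ndarray
    n_primaries: int
    seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.edep_fraction, float)
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("edep fractions must be finite and non-negative")
        if f.sum() > 1.0 + 1e-12:
            raise ValueError("edep fractions sum beyond unity (energy conservation)")
        object.__setattr__(self, "edep_fraction", f)


def _shape_params(energy0_kev: float, z_eff: float) -> tuple[float, float, float]:
    c = 2.2
    le = np.log(energy0_kev / 100.0)
    a = float(np.clip(0.6 + 0.25 * le, 0.2, 1.8))
    m = float(np.clip(0.35 + 0.05 * le + 0.01 * (z_eff - 7.0), 0.2, 0.7))
    b = a / (c * m**c)
    return a, b, c


def _absorbed_fraction(energy0_kev: float, z_eff: float) -> float:
    t_mev = energy0_kev / 1000.0
    y = 6e-4 * z_eff * t_mev
    y = y / (1.0 + y)
    return 1.0 - y


def noiseless_edep_fractions(
    energy0_kev: float, material: MaterialSpec, grid: ShellGrid | None = None
) -> np.ndarray:
    """The closed-form (infinite-statistics) per-shell fractions."""
    grid = grid or ShellGrid()
    z_eff = effective_za(material).z_eff
    a, b, c = _shape_params(energy0_kev, z_eff)
    x = grid.midpoints
    g = x**a * np.exp(-b * x**c)
    eta = _absorbed_fraction(energy0_kev, z_eff)
    return eta * g / g.sum()


def emulate_shell_edep(
    energy0_kev: float,
    material: MaterialSpec,
    n_primaries: int = 10_000_000,
    seed: int = 0,
    *,
    noise: bool = True,
    grid: ShellGrid | None = None,
) -> ShellEdep:
    """Draw one emulated shell-scoring result (deterministic given seed)."""
    tol = 1e-9 * _ENERGY_HI  # tolerate float round-off at the bounds
    if not (_ENERGY_LO - tol <= energy0_kev <= _ENERGY_HI + tol):
        raise ValueError(
            f"source energy {energy0_kev} keV outside emulator validity "
            f"[{_ENERGY_LO}, {_ENERGY_HI}] keV"
        )
    energy0_kev = float(np.clip(energy0_kev, _ENERGY_LO, _ENERGY_HI))
    if n_primaries < 1:
        raise ValueError("n_primaries must be >= 1")
    grid = grid or ShellGrid()
    f = noiseless_edep_fractions(energy0_kev, material, grid)
    if noise:
        rng = np.random.default_rng(seed)
        sigma = 0.01 * np.sqrt(f.max() / np.maximum(f, 1e-4)) * np.sqrt(1e7 / n_primaries)
        f = np.clip(f * (1.0 + sigma * rng.standard_normal(f.shape)), 0.0, None)
        total = f.sum()
        if total > 1.0:  # extreme draws only; keep conservation strict
            f = f / (total * (1.0 + 1e-12))  # margin so round-off stays below 1
    return ShellEdep(
        energy0_kev=energy0_kev,
        material=material,
        grid=grid,
        edep_fraction=f,
        n_primaries=int(n_primaries),
        seed=int(seed),
    )


def edep_to_sdpk(edep: ShellEdep) -> ScaledDPK:
    """F_i = (dE_i/E0) / (dr/R_CSDA) — the defining identity of the sDPK."""
    values = edep.edep_fraction / edep.grid.thickness
    return ScaledDPK(
        grid=edep.grid,
        values=values,
        material_label=edep.material.label,
        energy0_kev=edep.energy0_kev,
        scale="r0",
    )


def feature_row(material: MaterialSpec, energy0_kev: float) -> dict[str, float]:
    """The 13 chain features for one (material, energy) pair."""
    row = {
        "E0_keV": float(energy0_kev),
        "R_CSDA_g_cm2": csda_range(energy0_kev, material).r0_areal,
        "density": material.density,
    }
    for col in FEATURE_COLUMNS[3:]:
        row[col] = material.fraction(col[2:])
    return row


def generate_dataset(
    materials: list[MaterialSpec],
    energies_kev: list[float],
    n_primaries: int = 10_000_000,
    seed: int = 0,
    *,
    noise: bool = True,
) -> pd.DataFrame:
    """Emulated training table: one row per (material, energy).

    Columns: ``material`` (label), the 13 :data:`FEATURE_COLUMNS`, then
    the 60 :data:`TARGET_COLUMNS`.  Row-level seeds are spawned
    deterministically from the master seed, so the table is bitwise
    reproducible.
    """
    if not materials or not len(energies_kev):
        raise ValueError("materials and energies must be non-empty")
    pairs = [(m, float(e)) for m in materials for e in energies_kev]
    keys = [(m.label, e) for m, e in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (material, energy) pairs in dataset request")
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (mat, energy), child in zip(pairs, children):
        row_seed = int(child.generate_state(1, np.uint32)[0])
        edep = emulate_shell_edep(
            energy, mat, n_primaries=n_primaries, seed=row_seed, noise=noise
        )
        sdpk = edep_to_sdpk(edep)
        row: dict[str, object] = {"material": mat.label}
        row.update(feature_row(mat, energy))
        row.update(dict(zip(TARGET_COLUMNS, sdpk.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["material", *FEATURE_COLUMNS, *TARGET_COLUMNS])


def export_kernel_table(path, kernels: list[ScaledDPK]) -> None:
    """Write kernels in the interchange CSV schema
    ``material_label,energy_keV,shell_index,x_mid,F``."""
    with open(path, "w") as fh:
        fh.write("material_label,energy_keV,shell_index,x_mid,F\n")
        for k in kernels:
            for i, (x, f) in enumerate(zip(k.x, k.values), start=1):
                fh.write(
                    f"{k.material_label},{float(k.energy0_kev)!r},{i},"
                    f"{float(x)!r},{float(f)!r}\n"
                )


def import_kernel_table(path) -> dict[tuple[str, float], ScaledDPK]:
    """Read externally produced monoenergetic kernels (e.g. real MC output).

    Returns a mapping (material_label, energy_keV) -> ScaledDPK on the
    shared 60-shell grid; usable everywhere a trained model is.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"material_label", "energy_keV", "shell_index", "x_mid", "F"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kernel table missing columns {sorted(missing)}")
    out: dict[tuple[str, float], ScaledDPK] = {}
    for (label, energy), grp in df.groupby(["material_label", "energy_keV"], sort=False):
        grp = grp.sort_values("shell_index")
        x = grp["x_mid"].to_numpy(float)
        dx = np.diff(x)
        if x.size < 2 or not np.allclose(dx, dx[0], rtol=1e-6):
            raise ValueError(f"non-uniform shell grid for ({label}, {energy})")
        from .kernels import CustomGrid

        grid = CustomGrid(x, float(dx[0]))
        out[(str(label), float(energy))] = ScaledDPK(
            grid=grid,
            values=grp["F"].to_numpy(float),
            material_label=str(label),
            energy0_kev=float(energy),
            scale="r0",
        )
    return out
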