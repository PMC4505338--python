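"""Molecules-per-cluster stoichiometry for a membrane protein.

The chain combines four independent measurements into one number:

  quantitative immunoblot (standard curve of recombinant protein)
      → total molecules per cell
  flow cytometry with/without permeabilization, isotype-corrected
      → fraction of the protein on the plasma membrane
  equatorial radius of swollen spherical cells
      → mean cell surface area (4πr²)
  cluster density from super-resolution images
      → clusters per cell

  molecules/cluster = molecules/cell × surface fraction / clusters/cell

For CD53 on human B cells this lands at ≈3.5 molecules per ~100 nm
cluster — an order of magnitude below what a densely packed protein
domain could hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PG_PER_KDA",
    "StandardCurve",
    "StoichiometryInputs",
    "StoichiometryResult",
    "fit_standard_curve",
    "molecules_per_cell",
    "surface_fraction",
    "cell_surface_area",
    "molecules_per_cluster",
    "stoichiometry_chain",
]

# mass of a 1 kDa molecule in picograms: 1000 Da x 1.6605e-24 g x 1e12 pg/g
PG_PER_KDA = 1.66053906892e-9


@dataclass
class StandardCurve:
    """OLS line through (recombinant mass, densitometric signal) points."""

    slope: float  # signal units per pg
    intercept: float
    r_squared: float
    slope_se: float
    n: int

    def mass_from_signal(self, signal: float) -> float:
        """Invert the curve: protein mass (pg) for a measured signal."""
        mass = (signal - self.intercept) / self.slope
        if mass < 0:
            raise ValueError(
                f"signal {signal:g} implies negative mass ({mass:.3g} pg); "
                "outside the calibrated range"
            )
        return mass


def fit_standard_curve(points) -> StandardCurve:
    """Fit the densitometry standard curve signal = a·mass + b by OLS.

    ``points`` is a sequence of (mass_pg, signal) pairs; at least three
    points with distinct masses are required, and the slope must be
    positive for a usable curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (mass_pg, signal) points")
    mass, signal = pts[:, 0], pts[:, 1]
    if np.ptp(mass) == 0:
        raise ValueError("degenerate design: all masses identical")
    res = stats.linregress(mass, signal)
    if res.slope <= 0:
        raise ValueError(f"non-positive slope {res.slope:g}: curve unusable")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        n=len(pts),
    )


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v!r}")


def molecules_per_cell(
    total_mass_pg: float, n_cells: float, molecular_mass_kda: float
) -> float:
    """Total protein copies per cell from lysate mass and molecular mass.

    Per-molecule mass is derived from the molecular mass via Avogadro's
    number (kDa × 1.6605×10⁻⁹ pg).  A sanity window on the molecular mass
    catches Da/kDa unit slips.
    """
    if total_mass_pg == 0:
        return 0.0
    _require_positive(
        total_mass_pg=total_mass_pg,
        n_cells=n_cells,
        molecular_mass_kda=molecular_mass_kda,
    )
    if not (1.0 <= molecular_mass_kda <= 1000.0):
        raise ValueError(
            f"molecular mass {molecular_mass_kda} kDa outside 1-1000 kDa; "
            "check units (Da vs kDa?)"
        )
    per_molecule_pg = molecular_mass_kda * PG_PER_KDA
    return (total_mass_pg / n_cells) / per_molecule_pg


def surface_fraction(
    surface_mfi: float,
    total_mfi: float,
    surface_isotype_mfi: float = 0.0,
    total_isotype_mfi: float = 0.0,
) -> float:
    """% of the protein on the plasma membrane, isotype-corrected:
    100 × (surface − surface isotype) / (total − total isotype)."""
    denom = total_mfi - total_isotype_mfi
    if denom <= 0:
        raise ValueError("total MFI must exceed the total isotype control")
    num = surface_mfi - surface_isotype_mfi
    if num < 0:
        raise ValueError("surface MFI below its isotype control")
    return 100.0 * num / denom


def cell_surface_area(radii_um) -> float:
    """Mean plasma-membrane area (μm²) over cells, sphere model: mean(4πr²).

    Averaging 4πr² (rather than 4π·mean(r)²) is deliberate: for a
    dispersed radius sample the mean of squares exceeds the square of the
    mean, and the membrane area scales with r² cell by cell.  Radii are in
    μm; values above 100 μm are rejected as probable nm/μm slips.
    """
    r = np.asarray(radii_um, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one radius")
    if (r <= 0).any():
        raise ValueError("radii must be > 0")
    if (r > 100.0).any():
        raise ValueError("radius > 100 μm; check units (nm vs μm?)")
    return float(np.mean(4.0 * np.pi * r**2))


@dataclass
class StoichiometryInputs:
    """Everything the chain needs, in fixed units (pg, kDa, μm, μm⁻²)."""

    total_mass_pg: float
    n_cells: float
    molecular_mass_kda: float
    surface_mfi: float
    total_mfi: float
    surface_isotype_mfi: float
    total_isotype_mfi: float
    cell_radii_um: list[float]
    cluster_density_per_um2: float


@dataclass
class StoichiometryResult:
    """The full chain with every intermediate, for audit."""

    molecules_per_cell: float
    surface_fraction_pct: float
    surface_molecules_per_cell: float
    cell_surface_area_um2: float
    cluster_density_per_um2: float
    clusters_per_cell: float
    molecules_per_cluster: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "molecules_per_cell": self.molecules_per_cell,
            "surface_fraction_pct": self.surface_fraction_pct,
            "surface_molecules_per_cell": self.surface_molecules_per_cell,
            "cell_surface_area_um2": self.cell_surface_area_um2,
            "cluster_density_per_um2": self.cluster_density_per_um2,
            "clusters_per_cell": self.clusters_per_cell,
            "molecules_per_cluster": self.molecules_per_cluster,
            "notes": list(self.notes),
        }


def molecules_per_cluster(
    molecules_cell: float,
    surface_fraction_pct: float,
    surface_area_um2: float,
    cluster_density_per_um2: float,
) -> StoichiometryResult:
    """Combine the four chain quantities into molecules per cluster.

    surface molecules = molecules/cell × fraction;
    clusters/cell = area × density;
    molecules/cluster = surface molecules / clusters per cell.
    """
    _require_positive(
        surface_area_um2=surface_area_um2,
        cluster_density_per_um2=cluster_density_per_um2,
    )
    if molecules_cell < 0 or not (0.0 <= surface_fraction_pct <= 100.0):
        raise ValueError("molecules/cell must be >= 0 and fraction in [0, 100] %")
    surface_molecules = molecules_cell * surface_fraction_pct / 100.0
    clusters_cell = surface_area_um2 * cluster_density_per_um2
    return StoichiometryResult(
        molecules_per_cell=molecules_cell,
        surface_fraction_pct=surface_fraction_pct,
        surface_molecules_per_cell=surface_molecules,
        cell_surface_area_um2=surface_area_um2,
        cluster_density_per_um2=cluster_density_per_um2,
        clusters_per_cell=clusters_cell,
        molecules_per_cluster=surface_molecules / clusters_cell,
    )


def stoichiometry_chain(inputs: StoichiometryInputs) -> StoichiometryResult:
    """Run the whole estimation chain from raw inputs."""
    n_cell = molecules_per_cell(
        inputs.total_mass_pg, inputs.n_cells, inputs.molecular_mass_kda
    )
    frac = surface_fraction(
        inputs.surface_mfi,
        inputs.total_mfi,
        inputs.surface_isotype_mfi,
        inputs.total_isotype_mfi,
    )
    area = cell_surface_area(inputs.cell_radii_um)
    result = molecules_per_cluster(
        n_cell, frac, area, inputs.cluster_density_per_um2
    )
    result.notes.append(
        "per-molecule mass computed from the molecular mass via Avogadro's "
        f"number ({inputs.molecular_mass_kda} kDa -> "
        f"{inputs.molecular_mass_kda * PG_PER_KDA:.4g} pg)"
    )
    return result
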