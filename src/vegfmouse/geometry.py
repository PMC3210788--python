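"""Tissue and blood geometry of the two-compartment mouse model.

The tissue compartment is mouse gastrocnemius skeletal muscle, idealised as
parallel cylindrical muscle fibers (myocytes) interspersed with cylindrical
capillaries; the space between them is interstitium composed of the
endothelial basement membrane (EBM), the parenchymal basement membrane (PBM)
and the extracellular matrix (ECM).  Everything the reaction network needs —
surface areas, volume fractions, the pore-theory available-volume fraction
K_AV, and the unit-conversion factors that put receptor densities and molar
rate constants on a per-compartment-volume basis — is derived here from a
small set of base measurements.

Concentration convention used throughout the package: pmol per cm^3 of the
owning compartment (tissue species per cm^3 tissue, blood species per cm^3
blood).  Free diffusible species are referenced back to fluid volume
(interstitial fluid via K_AV, plasma via the plasma fraction) wherever a
molar driving force is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict

import pandas as pd

AVOGADRO = 6.02214076e23  # 1/mol
PMOL_PER_MOL = 1e12
#: pmol per cm^3 of fluid for a 1 M solution (1 mol/L = 1e12 pmol / 1e3 cm^3)
PMOL_PER_CM3_PER_M = 1e9


class GeometryError(ValueError):
    """Raised when base measurements are inconsistent or non-physical."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise GeometryError(msg)


@dataclass(frozen=True)
class WholeBodyParams:
    """Whole-animal measurements.

    Defaults describe a 25 g mouse.  Plasma volume follows the literature
    basis of 3.42 mL per 100 g body weight (0.855 mL for 25 g).
    """

    body_mass: float = 25.0          # g
    blood_volume: float = 1.75       # mL
    plasma_volume: float = 0.855     # mL
    blood_density: float = 1.002     # g/cm^3
    muscle_density: float = 1.06     # g/cm^3

    def __post_init__(self) -> None:
        for name in ("body_mass", "blood_volume", "plasma_volume",
                     "blood_density", "muscle_density"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.plasma_volume <= self.blood_volume,
                 "plasma_volume cannot exceed blood_volume")

    @property
    def plasma_fraction(self) -> float:
        """Plasma volume as a fraction of whole-blood volume."""
        return self.plasma_volume / self.blood_volume


@dataclass(frozen=True)
class MuscleGeometryInputs:
    """Base geometric measurements of the gastrocnemius muscle."""

    capillary_density: float = 650.0          # #/mm^2
    capillary_fiber_ratio: float = 1.95       # dimensionless
    fiber_cross_section: float = 2500.0       # um^2
    luminal_capillary_diameter: float = 5.25  # um
    capillary_wall_thickness: float = 0.5     # um
    perimeter_correction_capillary: float = 1.23
    surface_correction_capillary: float = 1.1
    perimeter_correction_fiber: float = 1.21
    myonuclear_domain_volume: float = 21400.0  # um^3 per myonucleus
    ec_surface_per_side: float = 1000.0        # um^2 per endothelial cell side
    interstitial_fraction: float = 0.1526      # cm^3/cm^3 tissue
    #: canonical fiber perimeter (um).  The published value; the circular
    #: reconstruction 2*sqrt(pi*FCSA)*correction gives 214.47 um and is kept
    #: available as the derived alternative (see derive_fiber_geometry).
    fiber_perimeter_printed: float | None = 214.10

    def __post_init__(self) -> None:
        for name in ("capillary_density", "capillary_fiber_ratio",
                     "fiber_cross_section", "luminal_capillary_diameter",
                     "myonuclear_domain_volume", "ec_surface_per_side",
                     "interstitial_fraction"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.capillary_wall_thickness >= 0,
                 "capillary_wall_thickness must be >= 0")
        for name in ("perimeter_correction_capillary",
                     "surface_correction_capillary",
                     "perimeter_correction_fiber"):
            _require(getattr(self, name) >= 1.0, f"{name} must be >= 1")


@dataclass(frozen=True)
class MatrixPartitionInputs:
    """Pore-theory inputs for the interstitial sub-regions.

    The EBM/PBM volume fractions are stored as overridable constants
    defaulting to the published values: the thickness-times-surface
    reconstruction (``bm_volume_fraction_from_thickness``) does not reproduce
    them and the original pore equations are not available.  Partition
    coefficients are likewise the stated constants.
    """

    ebm_thickness: float = 154.0     # nm
    pbm_thickness: float = 154.0     # nm
    bm_pore_size: float = 7.0        # nm
    ecm_pore_size: float = 66.0      # nm
    collagen_body_fraction: float = 0.025      # g collagen / g body
    collagen_density: float = 1.41             # g/cm^3
    bm_collagen_to_total_ratio: float = 0.0083
    partition_coefficient_bm: float = 0.35
    partition_coefficient_ecm: float = 0.90
    ebm_volume_fraction: float = 0.002014      # cm^3/cm^3 tissue (published)
    pbm_volume_fraction: float = 0.009123      # cm^3/cm^3 tissue (published)

    def __post_init__(self) -> None:
        for name in ("ebm_thickness", "pbm_thickness", "bm_pore_size",
                     "ecm_pore_size", "collagen_density"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("partition_coefficient_bm", "partition_coefficient_ecm"):
            v = getattr(self, name)
            _require(0 < v <= 1, f"{name} must lie in (0, 1]")
        _require(0 <= self.collagen_body_fraction < 1,
                 "collagen_body_fraction must lie in [0, 1)")


@dataclass
class DerivedGeometry:
    """Every derived geometric quantity and unit-conversion factor.

    Areas are cm^2, volumes cm^3, lengths um unless noted.  ``conversions``
    maps conversion names to factors used by the reaction network; ``source``
    marks values carried from the publication ("printed") versus computed
    from the base measurements ("derived").
    """

    tissue_mass: float = 0.0                 # g
    tissue_volume: float = 0.0               # cm^3 (U_N)
    blood_volume: float = 0.0                # cm^3 (U_B)
    plasma_volume: float = 0.0               # cm^3 (U_p)
    plasma_fraction: float = 0.0
    fiber_density: float = 0.0               # #/cm^2
    capillary_density: float = 0.0           # #/cm^2
    external_capillary_diameter: float = 0.0  # um
    capillary_volume_fraction: float = 0.0
    blood_volume_fraction: float = 0.0       # luminal (plasma-accessible) part
    capillary_perimeter: float = 0.0         # um
    capillary_surface_per_tissue: float = 0.0  # cm^2/cm^3 tissue
    total_capillary_surface: float = 0.0     # cm^2 (S_NB)
    fiber_volume_fraction: float = 0.0
    fiber_perimeter: float = 0.0             # um (canonical)
    fiber_perimeter_derived: float = 0.0     # um (circular reconstruction)
    fiber_surface_per_tissue: float = 0.0    # cm^2/cm^3 tissue
    fiber_length: float = 0.0                # um (one myonuclear domain)
    smnd_surface: float = 0.0                # cm^2 (single myonuclear domain)
    ec_per_cm3_tissue: float = 0.0           # endothelial cells / cm^3 tissue
    myocytes_per_cm3: float = 0.0            # myonuclear domains / cm^3 tissue
    ebm_volume_fraction: float = 0.0
    pbm_volume_fraction: float = 0.0
    ecm_volume_fraction: float = 0.0
    ebm_available: float = 0.0               # fluid cm^3 / cm^3 tissue
    pbm_available: float = 0.0
    ecm_available: float = 0.0
    k_av: float = 0.0                        # cm^3 available / cm^3 tissue
    interstitial_fraction: float = 0.0
    conversions: Dict[str, float] = field(default_factory=dict)
    source: Dict[str, str] = field(default_factory=dict)


def derive_whole_body(wb: WholeBodyParams) -> tuple[float, float]:
    """Tissue mass (g) and tissue volume (cm^3) of the mouse.

    The tissue is everything that is not blood: mass = body mass minus blood
    mass, volume via the skeletal-muscle density.
    """
    tissue_mass = wb.body_mass - wb.blood_volume * wb.blood_density
    _require(tissue_mass > 0, "blood mass exceeds body mass")
    tissue_volume = tissue_mass / wb.muscle_density
    return tissue_mass, tissue_volume


def derive_capillary_geometry(g: MuscleGeometryInputs,
                              wb: WholeBodyParams) -> DerivedGeometry:
    """Capillary-related geometry: perimeter, surface densities, fractions.

    The capillary perimeter correction factor (1.23) is the ratio of the
    squared perimeter to 4*pi*area, so the corrected perimeter is
    2*sqrt(pi * A_ext * c); this reproduces the published 21.77 um.
    """
    geo = DerivedGeometry()
    geo.tissue_mass, geo.tissue_volume = derive_whole_body(wb)
    geo.blood_volume = wb.blood_volume
    geo.plasma_volume = wb.plasma_volume
    geo.plasma_fraction = wb.plasma_fraction
    geo.interstitial_fraction = g.interstitial_fraction

    geo.capillary_density = g.capillary_density * 100.0  # #/mm^2 -> #/cm^2
    geo.fiber_density = geo.capillary_density / g.capillary_fiber_ratio

    d_ext = g.luminal_capillary_diameter + 2.0 * g.capillary_wall_thickness
    geo.external_capillary_diameter = d_ext
    a_ext_um2 = math.pi / 4.0 * d_ext ** 2
    a_lum_um2 = math.pi / 4.0 * g.luminal_capillary_diameter ** 2
    # um^2 * #/cm^2 -> dimensionless fraction (1 um^2 = 1e-8 cm^2)
    geo.capillary_volume_fraction = a_ext_um2 * 1e-8 * geo.capillary_density
    geo.blood_volume_fraction = a_lum_um2 * 1e-8 * geo.capillary_density

    geo.capillary_perimeter = 2.0 * math.sqrt(
        math.pi * a_ext_um2 * g.perimeter_correction_capillary)
    geo.capillary_surface_per_tissue = (
        geo.capillary_perimeter * 1e-4            # um -> cm
        * geo.capillary_density
        * g.surface_correction_capillary)
    geo.total_capillary_surface = (
        geo.capillary_surface_per_tissue * geo.tissue_volume)
    geo.source["capillary_perimeter"] = "derived"
    return geo


def fiber_perimeter_from_cross_section(g: MuscleGeometryInputs) -> float:
    """Circular-equivalent fiber perimeter with the linear correction factor."""
    return (2.0 * math.sqrt(math.pi * g.fiber_cross_section)
            * g.perimeter_correction_fiber)


def derive_fiber_geometry(g: MuscleGeometryInputs,
                          geo: DerivedGeometry) -> DerivedGeometry:
    """Muscle-fiber geometry: perimeter, surface density, domain size.

    The fiber volume fraction is FCSA x fiber density corrected down by the
    capillary wall cross-section (the wall is counted with the capillary).
    One "myocyte" is a single myonuclear domain: a fiber segment of length
    domain volume / FCSA.
    """
    geo.fiber_perimeter_derived = fiber_perimeter_from_cross_section(g)
    if g.fiber_perimeter_printed is not None:
        geo.fiber_perimeter = g.fiber_perimeter_printed
        geo.source["fiber_perimeter"] = "printed"
    else:
        geo.fiber_perimeter = geo.fiber_perimeter_derived
        geo.source["fiber_perimeter"] = "derived"

    geo.fiber_surface_per_tissue = (
        geo.fiber_perimeter * 1e-4 * geo.fiber_density)

    d_ext = g.luminal_capillary_diameter + 2.0 * g.capillary_wall_thickness
    wall_um2 = math.pi / 4.0 * (
        d_ext ** 2 - g.luminal_capillary_diameter ** 2)
    geo.fiber_volume_fraction = (
        g.fiber_cross_section * 1e-8 * geo.fiber_density
        - wall_um2 * 1e-8 * geo.capillary_density)
    _require(geo.fiber_volume_fraction > 0, "non-physical fiber volume")

    geo.fiber_length = g.myonuclear_domain_volume / g.fiber_cross_section
    geo.smnd_surface = geo.fiber_perimeter * geo.fiber_length * 1e-8  # cm^2
    geo.ec_per_cm3_tissue = (
        geo.capillary_surface_per_tissue / (g.ec_surface_per_side * 1e-8))
    geo.myocytes_per_cm3 = geo.fiber_density / (geo.fiber_length * 1e-4)
    return geo


def bm_volume_fraction_from_thickness(thickness_nm: float,
                                      surface_per_tissue: float) -> float:
    """Alternative basement-membrane volume fraction: thickness x surface.

    Provided for transparency; it does not reproduce the published EBM/PBM
    volume fractions (0.002014 / 0.009123), which are therefore carried as
    canonical constants in :class:`MatrixPartitionInputs`.
    """
    return thickness_nm * 1e-7 * surface_per_tissue  # nm -> cm


def derive_interstitial_partition(m: MatrixPartitionInputs,
                                  geo: DerivedGeometry,
                                  wb: WholeBodyParams) -> DerivedGeometry:
    """Pore-theory partitioning of the interstitium.

    The interstitial fraction is constrained first; EBM and PBM volume
    fractions are the canonical constants, the ECM takes the remainder.  The
    body's interstitial collagen (2.5% of body mass at 1.41 g/cm^3) is split
    between basement membranes and ECM by the 0.0083 collagen ratio, BM
    collagen proportionally to EBM/PBM volume.  Fluid (non-collagen) volumes
    times partition coefficients compose K_AV.
    """
    geo.ebm_volume_fraction = m.ebm_volume_fraction
    geo.pbm_volume_fraction = m.pbm_volume_fraction
    geo.ecm_volume_fraction = (geo.interstitial_fraction
                               - m.ebm_volume_fraction
                               - m.pbm_volume_fraction)
    _require(geo.ecm_volume_fraction > 0,
             "EBM+PBM volume exceeds the interstitial fraction")
    geo.source["ebm_volume_fraction"] = "printed"
    geo.source["pbm_volume_fraction"] = "printed"

    u_n = geo.tissue_volume
    collagen_total = wb.body_mass * m.collagen_body_fraction / m.collagen_density
    collagen_bm = collagen_total * m.bm_collagen_to_total_ratio
    collagen_ecm = collagen_total - collagen_bm
    bm_total = m.ebm_volume_fraction + m.pbm_volume_fraction
    collagen_ebm = collagen_bm * m.ebm_volume_fraction / bm_total
    collagen_pbm = collagen_bm * m.pbm_volume_fraction / bm_total

    geo.ebm_available = m.ebm_volume_fraction - collagen_ebm / u_n
    geo.pbm_available = m.pbm_volume_fraction - collagen_pbm / u_n
    geo.ecm_available = geo.ecm_volume_fraction - collagen_ecm / u_n
    for name in ("ebm_available", "pbm_available", "ecm_available"):
        _require(getattr(geo, name) > 0, f"{name} came out non-positive")

    geo.k_av = (m.partition_coefficient_bm * (geo.ebm_available
                                              + geo.pbm_available)
                + m.partition_coefficient_ecm * geo.ecm_available)
    _require(0 < geo.k_av <= geo.interstitial_fraction * (1 + 1e-12),
             "K_AV must lie in (0, interstitial fraction]")
    return geo


def derive_unit_conversions(geo: DerivedGeometry,
                            wb: WholeBodyParams,
                            m: MatrixPartitionInputs) -> DerivedGeometry:
    """Unit-conversion factors tying molecular units to compartment volumes.

    * receptor conversions: (pmol/cm^3 compartment) per (dimers/cell) —
      cells per cm^3 over Avogadro; luminal receptors are referenced to
      blood volume (all endothelial cells in the body face U_B of blood).
    * molar conversions: (pmol/cm^3 compartment) per M of the fluid the
      species actually occupies (K_AV for interstitium, plasma fraction for
      blood, available volume x partition coefficient for matrix regions).
    * surface-coupling conversions: (pmol/cm^3) per (mol/cm^2 of endothelial
      surface), for receptor-receptor coupling rate constants.
    """
    ec_per_cm3_blood = (geo.ec_per_cm3_tissue * geo.tissue_volume
                        / geo.blood_volume)
    conv = {
        "abluminal_receptor": geo.ec_per_cm3_tissue / AVOGADRO * PMOL_PER_MOL,
        "luminal_receptor": ec_per_cm3_blood / AVOGADRO * PMOL_PER_MOL,
        "myocyte_receptor": geo.myocytes_per_cm3 / AVOGADRO * PMOL_PER_MOL,
        "tissue_molar": geo.k_av * PMOL_PER_CM3_PER_M,
        "blood_molar": geo.plasma_fraction * PMOL_PER_CM3_PER_M,
        "ecm_molar": (geo.ecm_available * m.partition_coefficient_ecm
                      * PMOL_PER_CM3_PER_M),
        "ebm_molar": (geo.ebm_available * m.partition_coefficient_bm
                      * PMOL_PER_CM3_PER_M),
        "pbm_molar": (geo.pbm_available * m.partition_coefficient_bm
                      * PMOL_PER_CM3_PER_M),
        "tissue_surface_coupling": (geo.capillary_surface_per_tissue
                                    * PMOL_PER_MOL),
        "blood_surface_coupling": (geo.capillary_surface_per_tissue
                                   * geo.tissue_volume / geo.blood_volume
                                   * PMOL_PER_MOL),
    }
    for k, v in conv.items():
        _require(v > 0, f"conversion {k} non-positive")
    geo.conversions = conv
    return geo


def derive_geometry(wb: WholeBodyParams | None = None,
                    g: MuscleGeometryInputs | None = None,
                    m: MatrixPartitionInputs | None = None) -> DerivedGeometry:
    """Run the full geometry derivation from base measurements."""
    wb = wb or WholeBodyParams()
    g = g or MuscleGeometryInputs()
    m = m or MatrixPartitionInputs()
    geo = derive_capillary_geometry(g, wb)
    geo = derive_fiber_geometry(g, geo)
    geo = derive_interstitial_partition(m, geo, wb)
    geo = derive_unit_conversions(geo, wb, m)
    total = (geo.capillary_volume_fraction + geo.fiber_volume_fraction
             + geo.interstitial_fraction)
    _require(0.99 <= total <= 1.01,
             f"volume bookkeeping violated: fractions sum to {total:.4f}")
    return geo


def myonuclear_variant_inputs(g: MuscleGeometryInputs | None = None,
                              domain_length_um: float = 20.0
                              ) -> MuscleGeometryInputs:
    """Geometry inputs for the long-myonuclear-domain variant.

    Changing the domain length changes the number of myocytes per unit
    tissue (the fiber volume fraction is fixed), hence the total myocyte
    NRP-1 per cm^3 tissue.
    """
    g = g or MuscleGeometryInputs()
    return replace(g, myonuclear_domain_volume=(
        domain_length_um * g.fiber_cross_section))


_REPORT_UNITS = {
    "tissue_mass": "g", "tissue_volume": "cm^3", "blood_volume": "cm^3",
    "plasma_volume": "cm^3", "plasma_fraction": "-",
    "fiber_density": "#/cm^2", "capillary_density": "#/cm^2",
    "external_capillary_diameter": "um",
    "capillary_volume_fraction": "cm^3/cm^3 tissue",
    "blood_volume_fraction": "cm^3/cm^3 tissue",
    "capillary_perimeter": "um",
    "capillary_surface_per_tissue": "cm^2/cm^3 tissue",
    "total_capillary_surface": "cm^2",
    "fiber_volume_fraction": "cm^3/cm^3 tissue",
    "fiber_perimeter": "um", "fiber_perimeter_derived": "um",
    "fiber_surface_per_tissue": "cm^2/cm^3 tissue",
    "fiber_length": "um", "smnd_surface": "cm^2",
    "ec_per_cm3_tissue": "#/cm^3", "myocytes_per_cm3": "#/cm^3",
    "ebm_volume_fraction": "cm^3/cm^3 tissue",
    "pbm_volume_fraction": "cm^3/cm^3 tissue",
    "ecm_volume_fraction": "cm^3/cm^3 tissue",
    "ebm_available": "cm^3/cm^3 tissue",
    "pbm_available": "cm^3/cm^3 tissue",
    "ecm_available": "cm^3/cm^3 tissue",
    "k_av": "cm^3/cm^3 tissue", "interstitial_fraction": "cm^3/cm^3 tissue",
}

_CONV_UNITS = {
    "abluminal_receptor": "(pmol/cm^3 tissue)/(dimers/EC)",
    "luminal_receptor": "(pmol/cm^3 blood)/(dimers/EC)",
    "myocyte_receptor": "(pmol/cm^3 tissue)/(dimers/myocyte)",
    "tissue_molar": "(pmol/cm^3 tissue)/M",
    "blood_molar": "(pmol/cm^3 blood)/M",
    "ecm_molar": "(pmol/cm^3 tissue)/M",
    "ebm_molar": "(pmol/cm^3 tissue)/M",
    "pbm_molar": "(pmol/cm^3 tissue)/M",
    "tissue_surface_coupling": "(pmol/cm^3 tissue)/(mol/cm^2 EC)",
    "blood_surface_coupling": "(pmol/cm^3 blood)/(mol/cm^2 EC)",
}


def geometry_report(geo: DerivedGeometry) -> pd.DataFrame:
    """Tabular report: name, value, unit, source(printed|derived)."""
    rows = []
    for name, unit in _REPORT_UNITS.items():
        rows.append({"name": name, "value": getattr(geo, name), "unit": unit,
                     "source": geo.source.get(name, "derived")})
    for name, unit in _CONV_UNITS.items():
        rows.append({"name": f"conversion.{name}",
                     "value": geo.conversions[name], "unit": unit,
                     "source": "derived"})
    return pd.DataFrame(rows, columns=["name", "value", "unit", "source"])
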