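"""Model parameters: receptor densities, kinetics, transport, dosing.

Values are stored in their measured units (M^-1 s^-1, min^-1, molecules per
cell per second, ...) and converted to per-compartment-volume units by the
reaction-network builder using the derived geometry.  The defaults are the
literature/optimised parameter set of the healthy 25 g mouse.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

from .geometry import (MatrixPartitionInputs, MuscleGeometryInputs,
                       WholeBodyParams)


class ParameterError(ValueError):
    """Raised on malformed or inconsistent parameter input."""


@dataclass(frozen=True)
class ReceptorDensities:
    """Cell-surface receptor and matrix binding-site densities.

    Endothelial receptors are dimers per endothelial cell, split evenly
    between the luminal and abluminal membrane; NRP-1 is additionally
    expressed on myocytes.  Matrix glycosaminoglycan (GAG) site densities
    are molar concentrations within each interstitial sub-region.
    """

    vegfr1_per_ec: float = 1050.0      # dimers/EC
    vegfr2_per_ec: float = 700.0       # dimers/EC
    nrp1_per_ec: float = 35000.0       # dimers/EC
    nrp1_per_myocyte: float = 35000.0  # dimers/myonuclear domain
    luminal_fraction: float = 0.5      # share of EC receptors facing blood
    ecm_sites_molar: float = 0.75e-6   # M
    ebm_sites_molar: float = 13e-6     # M
    pbm_sites_molar: float = 13e-6     # M

    def __post_init__(self) -> None:
        if not 0.0 <= self.luminal_fraction <= 1.0:
            raise ParameterError("luminal_fraction must be within [0, 1]")
        for name in ("vegfr1_per_ec", "vegfr2_per_ec", "nrp1_per_ec",
                     "nrp1_per_myocyte", "ecm_sites_molar",
                     "ebm_sites_molar", "pbm_sites_molar"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class KineticParams:
    """Binding/unbinding, coupling, internalization and trap kinetics.

    Rates are in measured units (M^-1 s^-1 for solution binding,
    (mol/cm^2)^-1 s^-1 for surface receptor-receptor coupling, s^-1 for
    unbinding/internalisation) and are converted to per-compartment-volume
    units by the network builder.
    """

    kon_r1: float = 3.00e7        # M^-1 s^-1, either VEGF isoform to VEGFR-1
    koff_r1: float = 1.00e-3      # s^-1
    kon_r2: float = 1.00e7        # M^-1 s^-1
    koff_r2: float = 1.00e-3      # s^-1
    kon_n1: float = 3.13e6        # M^-1 s^-1, VEGF164 only
    koff_n1: float = 1.00e-3      # s^-1
    kon_gag: float = 4.20e5       # M^-1 s^-1, VEGF164 to matrix GAG chains
    koff_gag: float = 1.00e-2     # s^-1
    kc_v164r2_n1: float = 3.10e13   # (mol/cm^2)^-1 s^-1
    koff_v164r2_n1: float = 1.00e-3
    kc_v164n1_r2: float = 1.00e14
    koff_v164n1_r2: float = 1.00e-3
    kc_r1_n1: float = 1.00e14
    kdissoc_r1n1: float = 1.00e-2   # s^-1
    kint: float = 2.80e-4           # s^-1, receptors and complexes alike
    kon_trap: float = 1.13e8        # M^-1 s^-1
    koff_trap: float = 4.23e-5      # s^-1

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def kd_r1(self) -> float:
        return self.koff_r1 / self.kon_r1

    @property
    def kd_r2(self) -> float:
        return self.koff_r2 / self.kon_r2

    @property
    def kd_n1(self) -> float:
        return self.koff_n1 / self.kon_n1

    @property
    def kd_gag(self) -> float:
        return self.koff_gag / self.kon_gag

    @property
    def kd_trap(self) -> float:
        return self.koff_trap / self.kon_trap

    def with_trap_kd(self, kd_molar: float) -> "KineticParams":
        """New params with the trap dissociation constant set via kon.

        The trap unbinding rate is the literature constant; the equilibrium
        constant is what estimation adjusts, so kon = koff / Kd.
        """
        if kd_molar <= 0:
            raise ParameterError("trap Kd must be > 0")
        return replace(self, kon_trap=self.koff_trap / kd_molar)


@dataclass(frozen=True)
class TransportParams:
    """Secretion, intercompartmental transport, clearance, degradation.

    Secretion rates are molecules per myonuclear domain per second; the two
    VEGF isoforms are co-secreted at the fixed tissue expression ratio
    (VEGF164:VEGF120 = 92:8 by default).  Clearance and degradation rate
    constants are per minute, as customarily reported.
    """

    q_v164: float = 0.0626          # molecules/cell/s (optimised)
    v164_secretion_share: float = 0.92
    k_lymph: float = 7.00e-6        # cm^3/s (optimised)
    kp_vegf: float = 4.00e-8        # cm/s
    kp_trap: float = 3.00e-8        # cm/s, also the VEGF/trap complex
    c_vegf: float = 0.23            # min^-1
    c_trap: float = 8.86e-4         # min^-1 (optimised)
    c_complex: float = 2.79e-4      # min^-1 (optimised)
    k_deg: float = 0.0              # min^-1, tissue VEGF degradation

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name == "v164_secretion_share":
                if not 0 < v <= 1:
                    raise ParameterError(
                        "v164_secretion_share must be in (0, 1]")
            elif v < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def q_v120(self) -> float:
        """VEGF120 secretion rate implied by the fixed isoform ratio."""
        share = self.v164_secretion_share
        return self.q_v164 * (1.0 - share) / share


#: rate constant for VEGF degradation variant, min^-1 (60 min half-life)
K_DEG_VARIANT = 1.16e-2

#: optimised free parameters of the degradation-enabled refit
DEGRADATION_REFIT = dict(q_v164=0.0627, k_lymph=7.00e-6,
                         c_trap=8.85e-4, c_complex=2.79e-4)


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated parameter bundle of the mouse model."""

    whole_body: WholeBodyParams = field(default_factory=WholeBodyParams)
    muscle: MuscleGeometryInputs = field(default_factory=MuscleGeometryInputs)
    matrix: MatrixPartitionInputs = field(
        default_factory=MatrixPartitionInputs)
    receptors: ReceptorDensities = field(default_factory=ReceptorDensities)
    kinetics: KineticParams = field(default_factory=KineticParams)
    transport: TransportParams = field(default_factory=TransportParams)

    def replace_section(self, section: str, **kwargs: Any) -> "ParameterSet":
        return replace(self, **{section: replace(getattr(self, section),
                                                 **kwargs)})

    def with_overrides(self, overrides: dict[str, Any]) -> "ParameterSet":
        """Apply dotted ``section.key = value`` overrides."""
        ps = self
        for dotted, value in overrides.items():
            try:
                section, key = dotted.split(".")
            except ValueError as exc:
                raise ParameterError(
                    f"override key {dotted!r} must be 'section.key'") from exc
            if section not in _SECTIONS:
                raise ParameterError(f"unknown parameter section {section!r}")
            if key not in asdict(getattr(ps, section)):
                raise ParameterError(
                    f"unknown key {key!r} in section {section!r}")
            ps = ps.replace_section(section, **{key: float(value)})
        return ps


_SECTIONS = {
    "whole_body": WholeBodyParams,
    "muscle": MuscleGeometryInputs,
    "matrix": MatrixPartitionInputs,
    "receptors": ReceptorDensities,
    "kinetics": KineticParams,
    "transport": TransportParams,
}


def default_parameters() -> ParameterSet:
    return ParameterSet()


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter bundle from YAML; ``None`` loads packaged defaults.

    Every key must belong to a known section/field; missing keys fall back
    to defaults only if the section omits them entirely is not allowed —
    sections must be complete to avoid silent drift.
    """
    if path is None:
        ref = importlib.resources.files("vegfmouse").joinpath(
            "data/mouse_params.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must map sections to tables")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        entries = raw.get(section, {}) or {}
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(entries) - valid
        if bad:
            raise ParameterError(
                f"unknown keys in section {section!r}: {sorted(bad)}")
        coerced = {}
        for key, value in entries.items():
            if value is None:
                coerced[key] = None
            else:
                try:
                    # tolerate YAML-1.1 scientific notation read as strings
                    coerced[key] = float(value)
                except (TypeError, ValueError) as exc:
                    raise ParameterError(
                        f"section {section!r} key {key!r}: "
                        f"non-numeric value {value!r}") from exc
        try:
            kwargs[section] = cls(**coerced)
        except TypeError as exc:
            raise ParameterError(f"section {section!r}: {exc}") from exc
    return ParameterSet(**kwargs)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write the bundle as YAML with canonical section/key ordering."""
    doc = {section: asdict(getattr(ps, section)) for section in _SECTIONS}
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=False))
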