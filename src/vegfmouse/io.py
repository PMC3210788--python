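"""Serialisation: network export (SBML / TSV), trajectory output, and the
reproducible end-to-end pipeline.

All numeric output files carry units in their headers; a run writes a
resolved-configuration snapshot and a checksum manifest so that re-running
with the same configuration reproduces every deterministic artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Sequence
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .analysis import (receptor_occupancy, steady_state_flows,
                       vegf_distribution)
from .estimation import FitDataset, fit_multistart
from .geometry import geometry_report
from .network import ReactionNetwork
from .parameters import load_parameters, save_parameters
from .simulation import (DoseProtocol, WEEK_S, simulate_injection,
                         solve_steady_state, to_picomolar)

logger = logging.getLogger("vegfmouse")

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def _mathml_rate(parent: ET.Element, constant_id: str,
                 species: Sequence[str]) -> None:
    math = ET.SubElement(parent, f"{{{MATHML_NS}}}math")
    if species:
        node = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(node, f"{{{MATHML_NS}}}times")
        ci = ET.SubElement(node, f"{{{MATHML_NS}}}ci")
        ci.text = f" {constant_id} "
        for name in species:
            ci = ET.SubElement(node, f"{{{MATHML_NS}}}ci")
            ci.text = f" {name} "
    else:
        ci = ET.SubElement(math, f"{{{MATHML_NS}}}ci")
        ci.text = f" {constant_id} "


def export_sbml(net: ReactionNetwork, path: str | Path) -> None:
    """Write the chemical reaction system as an SBML Level 3 document.

    Species are in pmol/cm^3 of their compartment; transport terms are part
    of the ODE right-hand side rather than the reaction list and are not
    exported (they are documented in the reaction table alongside).
    """
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml",
                      attrib={"level": "3", "version": "1"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model", attrib={
        "id": "vegf_mouse_two_compartment",
        "substanceUnits": "picomole", "timeUnits": "second",
        "volumeUnits": "cm3", "extentUnits": "picomole"})

    units = ET.SubElement(model, f"{{{SBML_NS}}}listOfUnitDefinitions")
    for uid, kind, scale, mult in (("picomole", "mole", "-12", "1"),
                                   ("cm3", "litre", "-3", "1")):
        ud = ET.SubElement(units, f"{{{SBML_NS}}}unitDefinition",
                           attrib={"id": uid})
        lu = ET.SubElement(ud, f"{{{SBML_NS}}}listOfUnits")
        ET.SubElement(lu, f"{{{SBML_NS}}}unit", attrib={
            "kind": kind, "exponent": "1", "scale": scale,
            "multiplier": mult})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid, size in (("tissue", net.geo.tissue_volume),
                      ("blood", net.geo.blood_volume)):
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment", attrib={
            "id": cid, "size": f"{float(size):.17g}", "constant": "true",
            "spatialDimensions": "3"})

    y0 = net.initial_state()
    sps = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for i, sp in enumerate(net.species):
        ET.SubElement(sps, f"{{{SBML_NS}}}species", attrib={
            "id": sp.name, "compartment": sp.compartment,
            "initialConcentration": f"{float(y0[i]):.17g}",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false"})

    pars = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for k, r in enumerate(net.reactions):
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", attrib={
            "id": f"k_r{k + 1:02d}", "value": f"{float(r.rate_constant):.17g}",
            "constant": "true"})

    rxns = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    names = net.species_names()
    for k, r in enumerate(net.reactions):
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", attrib={
            "id": f"r{k + 1:02d}", "reversible": "false", "fast": "false",
            "name": f"{r.kind}:{r.name}"})
        if r.reactants:
            lof = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for i in r.reactants:
                ET.SubElement(lof, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": names[i], "stoichiometry": "1",
                    "constant": "true"})
        if r.products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for i in r.products:
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": names[i], "stoichiometry": "1",
                    "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        _mathml_rate(kl, f"k_r{k + 1:02d}", [names[i] for i in r.reactants])

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def export_reaction_table(net: ReactionNetwork, path: str | Path) -> None:
    """Human-readable reaction table as TSV."""
    net.reaction_table().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trajectory output
# ---------------------------------------------------------------------------

def trajectory_frame(net: ReactionNetwork, result) -> pd.DataFrame:
    """Tidy trajectory: time_s, species, compartment, value_pmol_per_cm3,
    value_pM (fluid-referenced molar equivalent)."""
    rows = []
    for j, sp in enumerate(net.species):
        conc = result.trajectory[:, j]
        rows.append(pd.DataFrame({
            "time_s": result.times, "species": sp.name,
            "compartment": sp.compartment,
            "value_pmol_per_cm3": conc,
            "value_pM": to_picomolar(net, conc, sp.compartment)}))
    return pd.concat(rows, ignore_index=True)


def write_trajectory_csv(net: ReactionNetwork, result,
                         path: str | Path) -> None:
    trajectory_frame(net, result).to_csv(path, index=False)


def write_trajectory_hdf5(net: ReactionNetwork, result,
                          path: str | Path) -> None:
    """Full grid as HDF5 (times, species names, concentration matrix)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_s", data=result.times)
        h5.create_dataset("concentration_pmol_per_cm3",
                          data=result.trajectory)
        h5.create_dataset(
            "species", data=np.array(net.species_names(), dtype="S"))
        h5.attrs["units"] = "pmol per cm^3 of owning compartment"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full reproducible run."""

    parameter_file: str | None = None
    overrides: Dict[str, float] = field(default_factory=dict)
    output_dir: str = "vegfmouse_run"
    seed: int = 0
    dose_mg_per_kg: float = 25.0
    horizon_weeks: float = 14.0
    degradation: bool = False
    fit_data: str | None = None
    fit_trials: int = 20
    solver_rtol: float = 1e-5
    solver_atol: float = 1e-20

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run geometry -> network -> steady state -> injection -> analyses.

    Each stage writes its artifact into the output directory; a failure
    aborts with the stage name.  A manifest with checksums and the resolved
    configuration snapshot make the run self-describing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "load-parameters"
    try:
        ps = load_parameters(config.parameter_file)
        if config.overrides:
            ps = ps.with_overrides(config.overrides)
        if config.degradation:
            from .parameters import K_DEG_VARIANT
            ps = ps.replace_section("transport", k_deg=K_DEG_VARIANT)
        save_parameters(ps, out / "resolved_parameters.yaml")
        (out / "resolved_config.json").write_text(
            json.dumps(asdict(config), indent=2))

        stage = "geometry"
        net = ReactionNetwork(ps)
        geometry_report(net.geo).to_csv(out / "geometry.csv", index=False)
        logger.info("geometry written")

        stage = "network-export"
        export_sbml(net, out / "network.sbml.xml")
        export_reaction_table(net, out / "reactions.tsv")

        stage = "steady-state"
        ss = solve_steady_state(net)
        pd.DataFrame({
            "species": net.species_names(),
            "compartment": [sp.compartment for sp in net.species],
            "value_pmol_per_cm3": ss,
            "value_pM": [to_picomolar(net, ss[i], sp.compartment)
                         for i, sp in enumerate(net.species)],
        }).to_csv(out / "steady_state.csv", index=False)

        stage = "analysis"
        steady_state_flows(net, ss).to_frame().to_csv(out / "flows.csv")
        vegf_distribution(net, ss).table.to_csv(out / "distribution.csv")
        occ = receptor_occupancy(net, ss)
        occ.per_receptor.rename("fraction").to_csv(out / "occupancy.csv")

        stage = "injection"
        if config.dose_mg_per_kg > 0:
            res = simulate_injection(
                net, ss, DoseProtocol(config.dose_mg_per_kg),
                horizon_s=config.horizon_weeks * WEEK_S,
                rtol=config.solver_rtol, atol=config.solver_atol)
            write_trajectory_csv(net, res, out / "trajectory.csv")

        stage = "fit"
        if config.fit_data:
            data = FitDataset.from_csv(config.fit_data)
            fit = fit_multistart(data, n_trials=config.fit_trials,
                                 seed=config.seed, base=ps,
                                 degradation=config.degradation)
            fit.to_json(out / "fit.json")
            fit.summary().to_csv(out / "fit_summary.csv", index=False)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name not in ("manifest.json", "run.log")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
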