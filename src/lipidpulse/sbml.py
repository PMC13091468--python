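"""SBML Level 3 export and re-import of expanded models.

One SBML species per label variant (ids like ``TAG__1_1_2``; ``u`` marks an
unlabeled chain), one reaction per reaction instance with a mass-action
kinetic law ``k · multiplicity · [reactants]``, and one global parameter per
reaction rule.  FA-influx instances carry the label they produce in a small
annotation (the phase gating is protocol information that SBML core cannot
express); everything else is plain SBML L3 core, so the documents load in
standard tooling.

The importer reads back exactly the subset this exporter writes and returns
a lightweight model that simulates with the same kinetics engine — used for
round-trip validation and by external pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from lxml import etree

from .expansion import ExpandedModel, ReactionInstance
from .simulate import Kinetics, LabelSchedule, _budgeted, solve_ivp

__all__ = ["export_sbml", "import_sbml", "ImportedModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://lipidpulse.readthedocs.io/schema"


def _e(parent, tag, **attrs):
    el = etree.SubElement(parent, f"{{{SBML_NS}}}{tag}")
    for k, v in attrs.items():
        el.set(k, str(v))
    return el


def export_sbml(model: ExpandedModel, path: str | Path) -> None:
    """Write the expanded model as an SBML Level 3 Version 2 core document."""
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    mdl = _e(root, "model", id=f"lipidpulse_{model.n_labels}_labels")

    comps = _e(mdl, "listOfCompartments")
    _e(comps, "compartment", id="cell", spatialDimensions="3", size="1", constant="true")

    sps = _e(mdl, "listOfSpecies")
    for s in model.species:
        _e(
            sps, "species", id=s.id, compartment="cell", initialConcentration="0",
            hasOnlySubstanceUnits="false", boundaryCondition="false", constant="false",
        )

    pars = _e(mdl, "listOfParameters")
    for name in model.parameter_names:
        _e(pars, "parameter", id=name, value="1", constant="true")

    rxns = _e(mdl, "listOfReactions")
    counters: dict[str, int] = {}
    for inst in model.instances:
        n = counters.get(inst.rule_id, 0)
        counters[inst.rule_id] = n + 1
        rxn = _e(rxns, "reaction", id=f"{inst.rule_id}__i{n}", reversible="false")
        if inst.influx_label is not None:
            annot = etree.SubElement(rxn, f"{{{SBML_NS}}}annotation")
            gate = etree.SubElement(
                annot, f"{{{ANNOT_NS}}}influxLabel", nsmap={"lp": ANNOT_NS}
            )
            gate.text = str(inst.influx_label)
        if inst.reactants:
            lor = _e(rxn, "listOfReactants")
            for i in inst.reactants:
                _e(lor, "speciesReference", species=model.species[i].id,
                   stoichiometry="1", constant="true")
        if inst.products:
            lop = _e(rxn, "listOfProducts")
            for i in inst.products:
                _e(lop, "speciesReference", species=model.species[i].id,
                   stoichiometry="1", constant="true")
        kl = _e(rxn, "kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        cn = etree.SubElement(apply_, f"{{{MATHML_NS}}}cn")
        cn.text = repr(float(inst.multiplicity))
        ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        ci.text = model.parameter_names[inst.param_index]
        for i in inst.reactants:
            ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci.text = model.species[i].id

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


@dataclass
class ImportedModel:
    """Expanded model reconstructed from an SBML document.

    Duck-types the pieces of :class:`~lipidpulse.expansion.ExpandedModel`
    that the kinetics engine needs, plus the chain bookkeeping derived from
    the variant ids.
    """

    species_ids: tuple[str, ...]
    instances: tuple[ReactionInstance, ...]
    parameter_names: tuple[str, ...]

    @property
    def n_x(self) -> int:
        return len(self.species_ids)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def base_name(self, species_id: str) -> str:
        return species_id.split("__")[0]

    def unlabeled_index(self, base_name: str) -> int:
        for i, sid in enumerate(self.species_ids):
            name, _, suffix = sid.partition("__")
            if name == base_name and set(suffix.split("_")) <= {"u", ""}:
                return i
        raise KeyError(base_name)

    def simulate_measurement(
        self,
        theta: np.ndarray,
        schedule: LabelSchedule,
        x0_base: dict[str, float],
        rtol: float = 1e-8,
        atol: float = 1e-12,
    ) -> np.ndarray:
        """State at the measurement time from base steady-state levels."""
        kin = Kinetics(self)
        x = np.zeros(self.n_x)
        for name, value in x0_base.items():
            x[self.unlabeled_index(name)] = value
        for lo, hi, lbl in schedule.phases():
            coeff = kin.rate_coeff(np.asarray(theta, dtype=float), active_label=lbl)
            sol = solve_ivp(
                _budgeted(lambda t, y: kin.rhs(y, coeff), 10**6),
                (lo, hi), x, method="LSODA",
                jac=lambda t, y: kin.jac(y, coeff), rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"imported-model integration failed: {sol.message}")
            x = sol.y[:, -1]
        return x


def import_sbml(path: str | Path) -> ImportedModel:
    """Read back a document written by :func:`export_sbml`."""
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS, "m": MATHML_NS, "lp": ANNOT_NS}
    species_ids = tuple(
        el.get("id") for el in tree.findall(".//s:listOfSpecies/s:species", ns)
    )
    sp_index = {sid: i for i, sid in enumerate(species_ids)}
    parameter_names = tuple(
        el.get("id") for el in tree.findall(".//s:listOfParameters/s:parameter", ns)
    )
    p_index = {pid: i for i, pid in enumerate(parameter_names)}

    instances = []
    for rxn in tree.findall(".//s:listOfReactions/s:reaction", ns):
        reactants = tuple(
            sp_index[el.get("species")]
            for el in rxn.findall("s:listOfReactants/s:speciesReference", ns)
        )
        products = tuple(
            sp_index[el.get("species")]
            for el in rxn.findall("s:listOfProducts/s:speciesReference", ns)
        )
        math = rxn.find("s:kineticLaw/m:math/m:apply", ns)
        if math is None:
            raise ValueError(f"reaction {rxn.get('id')!r}: missing kinetic law")
        mult = Fraction(float(math.find("m:cn", ns).text)).limit_denominator(12)
        cis = [el.text for el in math.findall("m:ci", ns)]
        param = next(c for c in cis if c in p_index)
        gate = rxn.find("s:annotation/lp:influxLabel", ns)
        influx_label = int(gate.text) if gate is not None else None
        rule_id = rxn.get("id").split("__")[0]
        instances.append(
            ReactionInstance(
                rule_id, p_index[param], reactants, products, mult, influx_label
            )
        )
    return ImportedModel(species_ids, tuple(instances), parameter_names)
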