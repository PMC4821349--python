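"""Reading and writing metabolic models.

Two formats are supported:

* **SBML** — Level 2 and Level 3 core, read through python-libsbml. GPRs
  are taken from the fbc ``geneProductAssociation`` when present, else from
  the legacy ``GENE_ASSOCIATION:`` notes field used by COBRA-era models.
  Models are written as Level 3 Version 1 with the fbc v2 extension.
* **TSV** — a flat dialect: a directory holding ``reactions.tsv``
  (id, name, equation, lb, ub, subsystem, gpr, objective) and
  ``metabolites.tsv`` (id, name, compartment, boundary), with reaction
  equations as ``"a A + b B -> c C"`` (``<=>`` for reversible).

Bounds absent from a file default to (−1000, 1000) for reversible and
(0, 1000) for irreversible reactions, the COBRA convention. Species marked
``boundaryCondition=true`` (or with the ``_b`` id suffix) are flagged as
boundary metabolites and excluded from mass-balance rows.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml

from .gpr import Gpr, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    validate_model,
)

__all__ = ["read_model", "write_model", "ModelParseError"]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


# ---------------------------------------------------------------------------
# id escaping: SBML SIds cannot hold characters like "(" used in BiGG-era
# ids ("EX_glc(e)"); escape to "__<ord>__" as COBRA tooling does.

_UNESCAPE = re.compile(r"__(\d+)__")


def _sid_escape(raw: str) -> str:
    return "".join(
        c if c.isalnum() or c == "_" else f"__{ord(c)}__" for c in raw
    )


def _sid_unescape(sid: str) -> str:
    return _UNESCAPE.sub(lambda m: chr(int(m.group(1))), sid)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# ---------------------------------------------------------------------------
# dispatch


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model, validate it, and return it.

    ``format`` is ``"sbml"`` or ``"tsv"``; when omitted it is inferred
    (directories are TSV, ``.xml``/``.sbml`` files are SBML).
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.is_dir() else "sbml"
    if format == "sbml":
        model = _read_sbml(path)
    elif format == "tsv":
        model = _read_tsv(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    issues = validate_model(model)
    if issues:
        raise ModelValidationError(
            f"{path}: invalid model: " + "; ".join(issues[:10])
        )
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if format == "sbml":
        _write_sbml(model, path)
    elif format == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# SBML


def _notes_field(sbase, key: str) -> str | None:
    if not sbase.isSetNotes():
        return None
    text = sbase.getNotesString()
    m = re.search(rf"{key}\s*:\s*([^<\n]*)", text)
    return m.group(1).strip() if m else None


def _association_to_gpr(assoc) -> Gpr | None:
    """Convert an fbc association tree to a GPR tree."""
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else None
        raw = label or _sid_unescape(_strip_prefix(assoc.getGeneProduct(), "G_"))
        return Gpr(gene=raw)
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    return Gpr(op=op, children=children)


def _read_sbml(path: Path) -> MetabolicModel:
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: file contains no SBML model")

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = _sid_unescape(_strip_prefix(sp.getId(), "M_"))
        metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                boundary=bool(sp.getBoundaryCondition()) or mid.endswith("_b"),
            )
        )

    fbc_model = sm.getPlugin("fbc")
    objective_coefs: dict[str, float] = {}
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(j)
                objective_coefs[fo.getReaction()] = fo.getCoefficient()

    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid_raw = rx.getId()
        rid = _sid_unescape(_strip_prefix(rid_raw, "R_"))
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = _sid_unescape(_strip_prefix(sr.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = _sid_unescape(_strip_prefix(sr.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()

        reversible = rx.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND
        obj_coef = objective_coefs.get(rid_raw, 0.0)

        fbc_rxn = rx.getPlugin("fbc")
        if fbc_rxn is not None and fbc_rxn.isSetLowerFluxBound():
            p = sm.getParameter(fbc_rxn.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
        if fbc_rxn is not None and fbc_rxn.isSetUpperFluxBound():
            p = sm.getParameter(fbc_rxn.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()

        kl = rx.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                pid = p.getId().upper()
                if pid == "LOWER_BOUND":
                    lb = p.getValue()
                elif pid == "UPPER_BOUND":
                    ub = p.getValue()
                elif pid == "OBJECTIVE_COEFFICIENT" and p.getValue() != 0:
                    obj_coef = p.getValue()

        gpr: Gpr | None = None
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            gpr = _association_to_gpr(
                fbc_rxn.getGeneProductAssociation().getAssociation()
            )
        if gpr is None:
            rule = _notes_field(rx, "GENE_ASSOCIATION") or _notes_field(
                rx, "GENE ASSOCIATION"
            )
            gpr = parse_gpr(rule)

        subsystem = _notes_field(rx, "SUBSYSTEM") or ""

        reactions.append(
            Reaction(
                id=rid,
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=subsystem,
                gpr=gpr,
                objective_coefficient=obj_coef,
            )
        )

    return MetabolicModel(
        id=sm.getId() or path.stem, metabolites=metabolites, reactions=reactions
    )


def _gpr_to_association(gpr: Gpr, fbc_rxn, parent=None):
    if parent is None:
        gpa = fbc_rxn.createGeneProductAssociation()
        parent = gpa
    if gpr.is_leaf:
        ref = parent.createGeneProductRef()
        ref.setGeneProduct("G_" + _sid_escape(gpr.gene))
        return
    node = parent.createAnd() if gpr.op == "and" else parent.createOr()
    for child in gpr.children:
        _gpr_to_association(child, fbc_rxn, node)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid_escape(model.id) or "model")
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(_sid_escape(cid))
        c.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + _sid_escape(m.id))
        sp.setName(m.name)
        sp.setCompartment(_sid_escape(m.compartment))
        sp.setBoundaryCondition(m.boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    for g in sorted(model.genes):
        gp = fbc_model.createGeneProduct()
        gp.setId("G_" + _sid_escape(g))
        gp.setLabel(g)

    objective = fbc_model.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc_model.setActiveObjectiveId("obj")

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rid = "R_" + _sid_escape(r.id)
        rx.setId(rid)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coef in r.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies("M_" + _sid_escape(mid))
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        fbc_rxn = rx.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(r.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr is not None:
            _gpr_to_association(r.gpr, fbc_rxn)
        if r.subsystem:
            rx.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        if r.objective_coefficient != 0:
            fo = objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(r.objective_coefficient)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# TSV dialect

_ARROW = re.compile(r"\s*(<=>|<->|-->|->|=>)\s*")


def _parse_equation(eq: str) -> dict[str, float]:
    """Parse ``"a A + b B -> c C"`` into signed stoichiometry."""
    parts = _ARROW.split(eq, maxsplit=1)
    if len(parts) != 3:
        raise ModelParseError(f"equation without arrow: {eq!r}")
    lhs, _, rhs = parts
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            tokens = term.split()
            if len(tokens) == 2:
                coef, mid = float(tokens[0]), tokens[1]
            elif len(tokens) == 1:
                coef, mid = 1.0, tokens[0]
            else:
                raise ModelParseError(f"cannot parse equation term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}


def _format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        return " + ".join(
            mid if coef == 1 else f"{coef:g} {mid}" for mid, coef in items
        )

    lhs = sorted((m, -c) for m, c in stoich.items() if c < 0)
    rhs = sorted((m, c) for m, c in stoich.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def _read_tsv(path: Path) -> MetabolicModel:
    import pandas as pd

    rpath, mpath = path / "reactions.tsv", path / "metabolites.tsv"
    for p in (rpath, mpath):
        if not p.exists():
            raise FileNotFoundError(p)
    mdf = pd.read_csv(mpath, sep="\t", dtype=str).fillna("")
    rdf = pd.read_csv(rpath, sep="\t", dtype=str).fillna("")

    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            compartment=row.get("compartment", "c") or "c",
            boundary=(str(row.get("boundary", "")).lower() in ("1", "true", "yes"))
            or row["id"].endswith("_b"),
        )
        for _, row in mdf.iterrows()
    ]

    reactions = []
    for _, row in rdf.iterrows():
        try:
            stoich = _parse_equation(row["equation"])
        except ModelParseError as exc:
            raise ModelParseError(f"{rpath}: reaction {row['id']!r}: {exc}") from exc
        lb = float(row["lb"]) if row.get("lb", "") != "" else None
        ub = float(row["ub"]) if row.get("ub", "") != "" else None
        if lb is None or ub is None:
            reversible = "<=>" in row["equation"] or "<->" in row["equation"]
            lb = -DEFAULT_BOUND if (lb is None and reversible) else (lb or 0.0)
            ub = DEFAULT_BOUND if ub is None else ub
        reactions.append(
            Reaction(
                id=row["id"],
                name=row.get("name", ""),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=row.get("subsystem", ""),
                gpr=parse_gpr(row.get("gpr", "")),
                objective_coefficient=float(row.get("objective") or 0.0),
            )
        )
    return MetabolicModel(id=path.name, metabolites=metabolites, reactions=reactions)


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    import pandas as pd

    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "boundary": [int(m.boundary) for m in model.metabolites],
        }
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [
                _format_equation(r.stoichiometry, r.reversible)
                for r in model.reactions
            ],
            "lb": [r.lower_bound for r in model.reactions],
            "ub": [r.upper_bound for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
            "gpr": [
                r.gpr.to_string() if r.gpr is not None else ""
                for r in model.reactions
            ],
            "objective": [r.objective_coefficient for r in model.reactions],
        }
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
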