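"""Metabolic model container and I/O: SBML, a JSON dialect, TSV results.

The in-memory container is :class:`MetabolicModel`, holding the m x n
stoichiometric matrix S, flux bounds v_l/v_u, and the linear objective w of
the flux-balance LP

    max  w' v   s.t.  S v = 0,  v_l <= v <= v_u.

SBML reading supports Level 3 with the FBC package (flux-bound parameters
and the first active objective) and falls back, for Level 2 files, to the
COBRA-era kinetic-law parameters (LOWER_BOUND / UPPER_BOUND /
OBJECTIVE_COEFFICIENT) or a notes-field convention.  Species flagged as
boundary conditions are excluded from the balance rows, as is standard FBA
practice.  Missing bounds default to [-1000, 1000] for reversible and
[0, 1000] for irreversible reactions (the de-facto COBRA convention),
overridable via ``default_bound``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicModel",
    "ModelValidationError",
    "ModelFormatError",
    "read_sbml",
    "write_sbml",
    "read_json_model",
    "write_json_model",
    "validate_model",
    "write_fva_tsv",
    "read_fva_tsv",
    "read_reaction_subset",
]


class ModelFormatError(ValueError):
    """File could not be parsed as a model."""


class ModelValidationError(ValueError):
    """Model content violates an invariant (duplicate IDs, bad bounds, ...)."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: S (m x n), bounds, objective.

    Column order of ``S`` follows ``reaction_ids``; row order follows
    ``metabolite_ids``.  Fluxes are in the model's own units (conventionally
    mmol·gDW⁻¹·h⁻¹); stoichiometric coefficients and objective weights are
    dimensionless.
    """

    model_id: str
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.spmatrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective: np.ndarray
    objective_sense: str = "maximize"

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        m, n = self.S.shape
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float).reshape(n)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float).reshape(n)
        self.objective = np.asarray(self.objective, dtype=float).reshape(n)
        if len(self.reaction_ids) != n or len(self.metabolite_ids) != m:
            raise ModelValidationError("ID list lengths do not match S dimensions")
        for kind, ids in (("reaction", self.reaction_ids),
                          ("metabolite", self.metabolite_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({x for x in ids if ids.count(x) > 1})
                raise ModelValidationError(f"duplicate {kind} IDs: {dups}")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds + 1e-12)[0]
        if bad.size:
            names = [self.reaction_ids[i] for i in bad]
            raise ModelValidationError(f"lower bound exceeds upper bound: {names}")
        if self.objective_sense not in ("maximize", "minimize"):
            raise ModelValidationError(f"bad objective_sense {self.objective_sense!r}")

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"reaction {rid!r} not in model") from None

    def with_objective(self, reaction_id: str, sense: str = "maximize") -> "MetabolicModel":
        """Copy of the model with the objective moved to a single reaction."""
        w = np.zeros(self.n_reactions)
        w[self.reaction_index(reaction_id)] = 1.0
        return MetabolicModel(self.model_id, list(self.metabolite_ids),
                              list(self.reaction_ids), self.S.copy(),
                              self.lower_bounds.copy(), self.upper_bounds.copy(),
                              w, sense)


# ---------------------------------------------------------------------
# validation (findings, never exceptions)
# ---------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of human-readable findings; empty means valid.

    Checks: bound inversions, empty objective, all-zero stoichiometric
    columns, duplicate IDs.  Never mutates the model.  (Construction already
    hard-fails on inversions/duplicates, so those findings mostly surface
    for models built by mutation.)
    """
    findings: list[str] = []
    bad = np.nonzero(model.lower_bounds > model.upper_bounds + 1e-12)[0]
    for i in bad:
        findings.append(
            f"bound inversion on reaction {model.reaction_ids[i]!r}: "
            f"lower {model.lower_bounds[i]} > upper {model.upper_bounds[i]}")
    if not np.any(model.objective):
        findings.append("objective vector is all zero")
    col_nnz = np.diff(sp.csc_matrix(model.S).indptr)
    for i in np.nonzero(col_nnz == 0)[0]:
        findings.append(
            f"reaction {model.reaction_ids[i]!r} has all-zero stoichiometry")
    for kind, ids in (("reaction", model.reaction_ids),
                      ("metabolite", model.metabolite_ids)):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                findings.append(f"duplicate {kind} ID {x!r}")
            seen.add(x)
    return findings


# ---------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------

def read_json_model(path: str) -> MetabolicModel:
    """Read the portable JSON dialect.

    Schema: ``{"id": ..., "metabolites": [ids...], "reactions": [{"id": ...,
    "metabolites": {met_id: coeff}, "lower_bound": ..., "upper_bound": ...,
    "objective_coefficient": ...}, ...]}``.  Optional top-level
    ``objective_sense``.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON: {exc}") from exc
    try:
        met_ids = list(doc["metabolites"])
        reactions = doc["reactions"]
        model_id = doc.get("id", "model")
    except KeyError as exc:
        raise ModelFormatError(f"missing required key {exc}") from exc
    met_pos = {m: i for i, m in enumerate(met_ids)}
    if len(met_pos) != len(met_ids):
        raise ModelValidationError("duplicate metabolite IDs in JSON model")
    n = len(reactions)
    rxn_ids, lows, ups, obj = [], [], [], []
    rows, cols, data = [], [], []
    for j, rxn in enumerate(reactions):
        rid = rxn["id"]
        rxn_ids.append(rid)
        for met, coeff in rxn.get("metabolites", {}).items():
            if met not in met_pos:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown metabolite {met!r}")
            rows.append(met_pos[met])
            cols.append(j)
            data.append(float(coeff))
        lows.append(float(rxn.get("lower_bound", 0.0)))
        ups.append(float(rxn.get("upper_bound", 1000.0)))
        obj.append(float(rxn.get("objective_coefficient", 0.0)))
    S = sp.coo_matrix((data, (rows, cols)), shape=(len(met_ids), n))
    return MetabolicModel(model_id, met_ids, rxn_ids, S,
                          np.array(lows), np.array(ups), np.array(obj),
                          doc.get("objective_sense", "maximize"))


def write_json_model(model: MetabolicModel, path: str) -> None:
    S = sp.csc_matrix(model.S)
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v)
                for i, v in zip(col.row, col.data)}
        reactions.append({
            "id": rid,
            "metabolites": mets,
            "lower_bound": float(model.lower_bounds[j]),
            "upper_bound": float(model.upper_bounds[j]),
            "objective_coefficient": float(model.objective[j]),
        })
    doc = {
        "id": model.model_id,
        "metabolites": list(model.metabolite_ids),
        "reactions": reactions,
        "objective_sense": model.objective_sense,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------

_NOTE_RE = re.compile(
    r"(LOWER_BOUND|UPPER_BOUND|OBJECTIVE_COEFFICIENT)\s*[:=]\s*([-+0-9.eE]+)")


def _bounds_from_notes(rxn) -> dict[str, float]:
    notes = rxn.getNotesString() if rxn.isSetNotes() else ""
    return {k: float(v) for k, v in _NOTE_RE.findall(notes)}


def read_sbml(path: str, default_bound: float = 1000.0,
              objective: Optional[str] = None) -> MetabolicModel:
    """Read an SBML model (Level 3 + FBC preferred, Level 2 fallback).

    Row order follows species document order (boundary species excluded),
    column order follows reaction document order.  ``objective`` overrides
    the file's objective with a single named reaction — useful for models
    whose files do not encode one.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelFormatError(
                    f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"no model element in {path}")

    met_ids: list[str] = []
    met_pos: dict[str, int] = {}
    for si in range(sbml_model.getNumSpecies()):
        spc = sbml_model.getSpecies(si)
        if spc.isSetBoundaryCondition() and spc.getBoundaryCondition():
            continue
        sid = spc.getId()
        if sid in met_pos:
            raise ModelValidationError(f"duplicate species ID {sid!r}")
        met_pos[sid] = len(met_ids)
        met_ids.append(sid)

    fbc = sbml_model.getPlugin("fbc")

    def _param_value(pid: Optional[str]) -> Optional[float]:
        if not pid:
            return None
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    n = sbml_model.getNumReactions()
    rxn_ids, lows, ups = [], np.empty(n), np.empty(n)
    obj = np.zeros(n)
    rows, cols, data = [], [], []
    for j in range(n):
        rxn = sbml_model.getReaction(j)
        rid = rxn.getId()
        if rid in rxn_ids:
            raise ModelValidationError(f"duplicate reaction ID {rid!r}")
        rxn_ids.append(rid)
        for k in range(rxn.getNumReactants()):
            sr = rxn.getReactant(k)
            if sr.getSpecies() in met_pos:
                rows.append(met_pos[sr.getSpecies()])
                cols.append(j)
                data.append(-(sr.getStoichiometry() or 0.0))
        for k in range(rxn.getNumProducts()):
            sr = rxn.getProduct(k)
            if sr.getSpecies() in met_pos:
                rows.append(met_pos[sr.getSpecies()])
                cols.append(j)
                data.append(sr.getStoichiometry() or 0.0)
        lo = up = None
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None:
            lo = _param_value(rfbc.getLowerFluxBound())
            up = _param_value(rfbc.getUpperFluxBound())
        if lo is None or up is None:
            kl = rxn.getKineticLaw()
            params = {}
            if kl is not None:
                for pi in range(kl.getNumParameters()):
                    par = kl.getParameter(pi)
                    params[par.getId()] = par.getValue()
            params.update(_bounds_from_notes(rxn))
            lo = params.get("LOWER_BOUND", lo) if lo is None else lo
            up = params.get("UPPER_BOUND", up) if up is None else up
            if params.get("OBJECTIVE_COEFFICIENT"):
                obj[j] = params["OBJECTIVE_COEFFICIENT"]
        reversible = rxn.getReversible()
        if lo is None:
            lo = -default_bound if reversible else 0.0
        if up is None:
            up = default_bound
        lows[j], ups[j] = lo, up

    sense = "maximize"
    if fbc is not None and fbc.getNumObjectives() > 0:
        if fbc.getNumObjectives() > 1:
            import warnings

            warnings.warn("multiple FBC objectives; using the first active one")
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None:
            sense = ("maximize" if active.getType() == "maximize" else "minimize")
            obj = np.zeros(n)
            for k in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(k)
                try:
                    obj[rxn_ids.index(fo.getReaction())] = fo.getCoefficient()
                except ValueError:
                    raise ModelValidationError(
                        f"objective references unknown reaction {fo.getReaction()!r}")

    S = sp.coo_matrix((data, (rows, cols)), shape=(len(met_ids), n))
    model = MetabolicModel(sbml_model.getId() or "model", met_ids, rxn_ids, S,
                           lows, ups, obj, sense)
    if objective is not None:
        model = model.with_objective(objective, model.objective_sense)
    return model


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 with the FBC v2 package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.model_id or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for mid in model.metabolite_ids:
        spc = sm.createSpecies()
        spc.setId(mid)
        spc.setCompartment("c")
        spc.setHasOnlySubstanceUnits(False)
        spc.setBoundaryCondition(False)
        spc.setConstant(False)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    S = sp.csc_matrix(model.S)
    for j, rid in enumerate(model.reaction_ids):
        rxn = sm.createReaction()
        rxn.setId(rid)
        rxn.setReversible(bool(model.lower_bounds[j] < 0))
        rxn.setFast(False)
        col = S.getcol(j).tocoo()
        for i, v in zip(col.row, col.data):
            sr = rxn.createReactant() if v < 0 else rxn.createProduct()
            sr.setSpecies(model.metabolite_ids[i])
            sr.setStoichiometry(abs(float(v)))
            sr.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(float(model.lower_bounds[j])))
        rplug.setUpperFluxBound(_bound_param(float(model.upper_bounds[j])))

    objp = mplug.createObjective()
    objp.setId("obj")
    objp.setType(model.objective_sense)
    for j in np.nonzero(model.objective)[0]:
        fo = objp.createFluxObjective()
        fo.setReaction(model.reaction_ids[int(j)])
        fo.setCoefficient(float(model.objective[int(j)]))
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------
# result tables and subset lists
# ---------------------------------------------------------------------

def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return repr(float(x))


def write_fva_tsv(result, path: str) -> None:
    """Write per-reaction flux ranges as TSV.

    Header ``reaction_id  minimum  maximum  status_min  status_max``; one
    row per analyzed reaction in model column order; full double precision;
    unbounded values as ``-inf``/``inf``.
    """
    with open(path, "w") as fh:
        fh.write("reaction_id\tminimum\tmaximum\tstatus_min\tstatus_max\n")
        for rid, mn, mx, smn, smx in zip(result.reaction_ids, result.min_flux,
                                         result.max_flux, result.status_min,
                                         result.status_max):
            fh.write(f"{rid}\t{_fmt(mn)}\t{_fmt(mx)}\t{smn}\t{smx}\n")


def read_fva_tsv(path: str):
    """Parse a :func:`write_fva_tsv` file back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"reaction_id": str})


def read_reaction_subset(path: str) -> list[str]:
    """Plain-text reaction subset: one ID per line, ``#`` comments allowed."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
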