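"""ME-type model definition: stoichiometry plus bilinear dilution rows.

A metabolism-and-expression (ME) model couples an ordinary stoichiometric
network ``S v = 0`` with *dilution* constraints of the form

    b_i' v  -  mu c_i' v   {=, >=}  0,

bilinear in the growth rate ``mu`` (1/h) and the flux vector ``v``
(mmol/gDW/h).  Each such row says that synthesis of a macromolecule
(ribosome, RNA polymerase, charged tRNA, enzyme) must at least cover its
dilution by growth.  At fixed ``mu`` the model reduces to an LP; the
feasible growth rates form an interval because each row is quasilinear
in ``mu`` (its level sets are hyperplane slices).

All coefficients are held as exact rationals (``gmpy2.mpq``); they are
rounded only when a solver context takes over.

JSON schema (version 1)
-----------------------
``{"schema_version": 1, "metabolites": [...],``
``  "reactions": [{"id", "lb", "ub", "annotation": {...}}, ...],``
``  "S": [[met_index, rxn_index, coeff], ...],``
``  "growth_reaction": id-or-null,``
``  "dilution_rows": [{"label", "family", "sense",``
``                     "b": [[rxn_id, coeff], ...], "c": [...]}, ...],``
``  "metadata": {...}}``

Coefficients are strings: plain decimal where the value has a finite
decimal expansion, exact ``"p/q"`` fractions otherwise, so round-trips
are lossless at any working precision.  Bounds additionally allow
``"inf"``/``"-inf"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from gmpy2 import mpq

from .arith import INF, bound_from_str, bound_to_str, isfin, rat, rat_to_str
from .xlp import LPProblem

SCHEMA_VERSION = 1

CATEGORIES = ("metabolic", "transcription", "translation", "complex_formation",
              "enzyme_usage", "charging", "dilution", "exchange")
FAMILIES = ("ribosome", "rnap", "trna", "enzyme", "generic")


class ModelValidationError(ValueError):
    pass


@dataclass
class Annotation:
    """Per-reaction category tag plus optional expression metadata.

    ``species`` names the macromolecule a dilution/charging/usage reaction
    refers to (e.g. ``"ribosome"``, a tRNA id, an enzyme id); ``gene`` is
    the gene association used by knockout screens; ``peptide_length`` is
    in amino acids, ``tu_length`` in nucleotides, ``mw`` in g/mol.
    """

    category: str = "metabolic"
    gene: str | None = None
    species: str | None = None
    peptide_length: object | None = None
    tu_length: object | None = None
    mw: object | None = None

    def validate(self, rid):
        if self.category not in CATEGORIES:
            raise ModelValidationError(
                f"reaction {rid!r}: unknown category {self.category!r}")


@dataclass
class DilutionRow:
    """One bilinear row  b'v - mu c'v {sense} 0.

    ``b`` is dimensionless, ``c`` carries hours so that ``mu c'v`` has
    flux units.  ``sense`` is ``"eq"`` or ``"ge"``.
    """

    b: dict
    c: dict
    sense: str = "ge"
    family: str = "generic"
    label: str = ""

    def validate(self, reaction_ids, idx=None):
        tag = self.label or (f"dilution_rows[{idx}]" if idx is not None else "row")
        if self.sense not in ("eq", "ge"):
            raise ModelValidationError(f"{tag}: sense must be 'eq' or 'ge'")
        if self.family not in FAMILIES:
            raise ModelValidationError(f"{tag}: unknown family {self.family!r}")
        if not self.b and not self.c:
            raise ModelValidationError(f"{tag}: b and c are both empty")
        known = set(reaction_ids)
        for vec_name, vec in (("b", self.b), ("c", self.c)):
            for rid in vec:
                if rid not in known:
                    raise ModelValidationError(
                        f"{tag}: {vec_name} references unknown reaction {rid!r}")


@dataclass
class DilutionConstants:
    """Rate/capacity constants of the expression machinery.

    c_ribo: ribosome catalytic constant; kappa_tau and r0 parameterize the
    growth-rate dependence (mu + r0*kappa_tau) of machinery dilution;
    k_eff maps (enzyme id, usage reaction id) -> effective catalytic rate
    (1/h); c_trna and c_mrna are per-species capacity constants.  c_mrna
    is carried for the generic mu-proportional mRNA-dilution hook.
    """

    c_ribo: object = mpq(12)
    kappa_tau: object = mpq(4)
    r0: object = mpq(1, 5)
    k_eff: dict = field(default_factory=dict)
    c_trna: dict = field(default_factory=dict)
    c_mrna: dict = field(default_factory=dict)

    def validate(self):
        def pos(name, v):
            if not (rat(v) > 0):
                raise ModelValidationError(f"constant {name} must be positive")
        pos("c_ribo", self.c_ribo)
        pos("kappa_tau", self.kappa_tau)
        pos("r0", self.r0)
        for k, v in self.k_eff.items():
            pos(f"k_eff[{k}]", v)
        for k, v in self.c_trna.items():
            pos(f"c_trna[{k}]", v)
        for k, v in self.c_mrna.items():
            pos(f"c_mrna[{k}]", v)


@dataclass
class GeneralForm:
    """Stacked matrix view  B v - mu C v {senses} 0,  S v = 0, bounds."""

    S: dict           # {(met_index, rxn_index): mpq}
    Bmat: dict        # {(dil_row, rxn_index): mpq}
    Cmat: dict
    senses: list
    v_lower: list
    v_upper: list
    n_dilution: int
    n_reactions: int


class MEModelSpec:
    """A desk-scale ME model: stoichiometry, bounds, dilution rows, tags."""

    def __init__(self, reaction_ids, metabolite_ids, S, v_lower, v_upper,
                 growth_reaction=None, dilution_rows=None, annotations=None,
                 metadata=None):
        self.reaction_ids = list(reaction_ids)
        self.metabolite_ids = list(metabolite_ids)
        self.S = {k: rat(v) for k, v in dict(S).items() if v != 0}
        self.v_lower = [b if (isinstance(b, float) and not isfin(b)) else rat(b)
                        for b in v_lower]
        self.v_upper = [b if (isinstance(b, float) and not isfin(b)) else rat(b)
                        for b in v_upper]
        self.growth_reaction = growth_reaction
        self.dilution_rows = list(dilution_rows or [])
        self.annotations = dict(annotations or {})
        self.metadata = dict(metadata or {})
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.validate()

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_reactions(self):
        return len(self.reaction_ids)

    @property
    def n_metabolites(self):
        return len(self.metabolite_ids)

    def rxn_index(self, rid) -> int:
        try:
            return self._index[rid]
        except KeyError:
            raise ModelValidationError(f"unknown reaction id {rid!r}") from None

    def annotation(self, rid) -> Annotation:
        return self.annotations.get(rid, Annotation())

    def reactions_by_category(self, category):
        return [rid for rid in self.reaction_ids
                if self.annotation(rid).category == category]

    def validate(self):
        n = self.n_reactions
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != self.n_metabolites:
            raise ModelValidationError("duplicate metabolite ids")
        if len(self.v_lower) != n or len(self.v_upper) != n:
            raise ModelValidationError(
                "bounds arrays must match the number of reactions")
        for j in range(n):
            lo, hi = self.v_lower[j], self.v_upper[j]
            lo_v = lo if isinstance(lo, float) else lo
            if (isfin(lo) and isfin(hi) and lo > hi):
                raise ModelValidationError(
                    f"reaction {self.reaction_ids[j]!r}: v_lower > v_upper")
        for (i, j) in self.S:
            if not (0 <= i < self.n_metabolites and 0 <= j < n):
                raise ModelValidationError(f"S entry ({i},{j}) out of range")
        if self.growth_reaction is not None:
            g = self.rxn_index(self.growth_reaction)
            if isfin(self.v_lower[g]) and self.v_lower[g] < 0:
                raise ModelValidationError(
                    "growth reaction must have a nonnegative lower bound")
        for idx, row in enumerate(self.dilution_rows):
            row.validate(self.reaction_ids, idx)
        for rid, ann in self.annotations.items():
            if rid not in self._index:
                raise ModelValidationError(
                    f"annotation references unknown reaction {rid!r}")
            ann.validate(rid)

    def copy(self):
        return MEModelSpec(
            self.reaction_ids, self.metabolite_ids, dict(self.S),
            list(self.v_lower), list(self.v_upper), self.growth_reaction,
            [DilutionRow(dict(r.b), dict(r.c), r.sense, r.family, r.label)
             for r in self.dilution_rows],
            {rid: Annotation(a.category, a.gene, a.species, a.peptide_length,
                             a.tu_length, a.mw)
             for rid, a in self.annotations.items()},
            dict(self.metadata))


# ----------------------------------------------------------------------
# operations


def build_dilution_rows(model: MEModelSpec,
                        constants: DilutionConstants) -> list:
    """Instantiate the four dilution-constraint families from annotations.

    Machinery rows carry a growth-rate dependence ``(mu + r0*kappa_tau)``
    which expands to a constant part (entering ``b``) and a
    mu-proportional part (entering ``c``):

    * ribosome:  b[translation_i] = -l_p,i r0 / c_ribo,
                 c[translation_i] =  l_p,i / (c_ribo kappa_tau)
    * RNA polymerase: as above with l_TU,i / 3 replacing l_p,i
    * tRNA j:    b[charging_j] = -r0 / c_tRNA,j,
                 c[charging_j] = 1 / (kappa_tau c_tRNA,j)
    * enzyme j:  b has +1 on the dilution flux only,
                 c[usage_i] = 1 / k_eff_ij

    Every row also has +1 on its dilution reaction in ``b`` and defaults
    to sense ``ge``.  Dilution reactions are located by their annotation:
    category ``dilution`` with ``species`` equal to ``"ribosome"``,
    ``"rnap"``, the tRNA id, or the enzyme id.
    """
    constants.validate()
    c_ribo = rat(constants.c_ribo)
    kt = rat(constants.kappa_tau)
    r0 = rat(constants.r0)

    dil_by_species = {}
    for rid in model.reaction_ids:
        ann = model.annotation(rid)
        if ann.category == "dilution" and ann.species:
            dil_by_species[ann.species] = rid

    rows = []

    translations = [rid for rid in model.reactions_by_category("translation")
                    if model.annotation(rid).peptide_length is not None]
    if translations and "ribosome" in dil_by_species:
        b = {dil_by_species["ribosome"]: mpq(1)}
        c = {}
        for rid in translations:
            lp = rat(model.annotation(rid).peptide_length)
            b[rid] = -lp * r0 / c_ribo
            c[rid] = lp / (c_ribo * kt)
        rows.append(DilutionRow(b, c, "ge", "ribosome", "ribosome_dilution"))

    transcriptions = [rid for rid in model.reactions_by_category("transcription")
                      if model.annotation(rid).tu_length is not None]
    if transcriptions and "rnap" in dil_by_species:
        b = {dil_by_species["rnap"]: mpq(1)}
        c = {}
        for rid in transcriptions:
            ltu = rat(model.annotation(rid).tu_length)
            b[rid] = -ltu * r0 / (3 * c_ribo)
            c[rid] = ltu / (3 * c_ribo * kt)
        rows.append(DilutionRow(b, c, "ge", "rnap", "rnap_dilution"))

    for trna_id in sorted(constants.c_trna):
        charge = None
        for rid in model.reactions_by_category("charging"):
            if model.annotation(rid).species == trna_id:
                charge = rid
                break
        if charge is None or trna_id not in dil_by_species:
            continue
        ct = rat(constants.c_trna[trna_id])
        b = {dil_by_species[trna_id]: mpq(1), charge: -r0 / ct}
        c = {charge: mpq(1) / (kt * ct)}
        rows.append(DilutionRow(b, c, "ge", "trna", f"trna_dilution_{trna_id}"))

    enzymes = sorted({enz for (enz, _u) in constants.k_eff})
    for enz in enzymes:
        if enz not in dil_by_species:
            raise ModelValidationError(
                f"enzyme row {enz!r}: no dilution reaction annotated for it")
        b = {dil_by_species[enz]: mpq(1)}
        c = {}
        for (e, usage), k in constants.k_eff.items():
            if e != enz:
                continue
            if usage not in model._index:
                raise ModelValidationError(
                    f"enzyme row {enz!r}: unknown usage reaction {usage!r}")
            c[usage] = c.get(usage, mpq(0)) + mpq(1) / rat(k)
        rows.append(DilutionRow(b, c, "ge", "enzyme", f"enzyme_dilution_{enz}"))

    for row in rows:
        row.validate(model.reaction_ids)
    return rows


def assemble_general_form(model: MEModelSpec) -> GeneralForm:
    """Stack the dilution rows into matrices B and C (row i: b_i'v - mu c_i'v)."""
    Bmat, Cmat = {}, {}
    senses = []
    for i, row in enumerate(model.dilution_rows):
        for rid, coef in row.b.items():
            Bmat[(i, model.rxn_index(rid))] = rat(coef)
        for rid, coef in row.c.items():
            Cmat[(i, model.rxn_index(rid))] = rat(coef)
        senses.append(row.sense)
    return GeneralForm(S=dict(model.S), Bmat=Bmat, Cmat=Cmat, senses=senses,
                       v_lower=list(model.v_lower), v_upper=list(model.v_upper),
                       n_dilution=len(model.dilution_rows),
                       n_reactions=model.n_reactions)


def fix_mu(model: MEModelSpec, mu) -> LPProblem:
    """Reduce the model to the LP obtained by fixing the growth rate.

    Rows: every metabolite balance (eq, rhs 0) followed by every dilution
    row with coefficients ``b_i - mu c_i`` and its own sense.  The growth
    reaction's flux is pinned to ``mu`` by intersecting its bounds with
    ``[mu, mu]`` (an empty intersection yields an infeasible LP), so that
    growth demand scales with the candidate growth rate.  The objective
    maximizes the growth flux when one exists, else zero (pure
    feasibility).  Passing ``mu`` as an exact rational keeps every
    coefficient exact.
    """
    mu_r = rat(mu)
    if mu_r < 0:
        raise ValueError("mu must be nonnegative")
    n = model.n_reactions
    m_met = model.n_metabolites
    cols = [dict() for _ in range(n)]
    for (i, j), a in model.S.items():
        cols[j][i] = a
    row_senses = ["eq"] * m_met
    row_names = list(model.metabolite_ids)
    for k, row in enumerate(model.dilution_rows):
        ridx = m_met + k
        for rid, bcoef in row.b.items():
            j = model.rxn_index(rid)
            cols[j][ridx] = cols[j].get(ridx, mpq(0)) + rat(bcoef)
        if mu_r != 0:
            for rid, ccoef in row.c.items():
                j = model.rxn_index(rid)
                cols[j][ridx] = cols[j].get(ridx, mpq(0)) - mu_r * rat(ccoef)
        for j in range(n):
            if ridx in cols[j] and cols[j][ridx] == 0:
                del cols[j][ridx]
        row_senses.append(row.sense)
        row_names.append(row.label or f"dilution_{k}")
    m = m_met + len(model.dilution_rows)
    rhs = [mpq(0)] * m
    lower = list(model.v_lower)
    upper = list(model.v_upper)
    objective = [mpq(0)] * n
    if model.growth_reaction is not None:
        g = model.rxn_index(model.growth_reaction)
        objective[g] = mpq(1)
        lo = lower[g] if isfin(lower[g]) else mpq(0)
        lower[g] = max(lo, mu_r)
        if isfin(upper[g]):
            upper[g] = min(rat(upper[g]), mu_r)
        else:
            upper[g] = mu_r
    return LPProblem(objective, "max", cols, row_senses, rhs, lower, upper,
                     col_names=list(model.reaction_ids), row_names=row_names)


def mu_level_set_residual(model: MEModelSpec, mu, v):
    """Per-dilution-row residual  b_i'v - mu c_i'v  at the given point.

    For ``ge`` rows a nonnegative residual means the row is satisfied.
    """
    if len(v) != model.n_reactions:
        raise ValueError("flux vector length does not match reaction count")
    res = []
    for row in model.dilution_rows:
        acc = 0
        for rid, coef in row.b.items():
            acc = acc + coef * v[model.rxn_index(rid)]
        if mu != 0:
            for rid, coef in row.c.items():
                acc = acc - mu * coef * v[model.rxn_index(rid)]
        res.append(acc)
    return res


# ----------------------------------------------------------------------
# JSON serialization


def _ann_to_json(ann: Annotation):
    out = {"category": ann.category}
    if ann.gene is not None:
        out["gene"] = ann.gene
    if ann.species is not None:
        out["species"] = ann.species
    if ann.peptide_length is not None:
        out["peptide_length"] = rat_to_str(ann.peptide_length)
    if ann.tu_length is not None:
        out["tu_length"] = rat_to_str(ann.tu_length)
    if ann.mw is not None:
        out["mw"] = rat_to_str(ann.mw)
    return out


def _ann_from_json(d):
    return Annotation(
        category=d.get("category", "metabolic"),
        gene=d.get("gene"),
        species=d.get("species"),
        peptide_length=rat(d["peptide_length"]) if "peptide_length" in d else None,
        tu_length=rat(d["tu_length"]) if "tu_length" in d else None,
        mw=rat(d["mw"]) if "mw" in d else None,
    )


def model_to_json_dict(model: MEModelSpec) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        entry = {"id": rid,
                 "lb": bound_to_str(model.v_lower[j]),
                 "ub": bound_to_str(model.v_upper[j])}
        if rid in model.annotations:
            entry["annotation"] = _ann_to_json(model.annotations[rid])
        reactions.append(entry)
    S = [[i, j, rat_to_str(a)] for (i, j), a in sorted(model.S.items())]
    rows = []
    for row in model.dilution_rows:
        rows.append({
            "label": row.label, "family": row.family, "sense": row.sense,
            "b": [[rid, rat_to_str(c)] for rid, c in sorted(row.b.items())],
            "c": [[rid, rat_to_str(c)] for rid, c in sorted(row.c.items())],
        })
    return {"schema_version": SCHEMA_VERSION,
            "metabolites": list(model.metabolite_ids),
            "reactions": reactions,
            "S": S,
            "growth_reaction": model.growth_reaction,
            "dilution_rows": rows,
            "metadata": model.metadata}


def model_from_json_dict(doc: dict) -> MEModelSpec:
    if not isinstance(doc, dict):
        raise ModelValidationError("model document must be a JSON object")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ModelValidationError(
            f"unsupported schema_version {doc.get('schema_version')!r}")
    for key in ("metabolites", "reactions", "S"):
        if key not in doc:
            raise ModelValidationError(f"missing required key {key!r}")
    rids, lowers, uppers, anns = [], [], [], {}
    for entry in doc["reactions"]:
        for key in ("id", "lb", "ub"):
            if key not in entry:
                raise ModelValidationError(
                    f"reaction entry missing key {key!r}: {entry!r}")
        rids.append(entry["id"])
        lowers.append(bound_from_str(entry["lb"]))
        uppers.append(bound_from_str(entry["ub"]))
        if "annotation" in entry:
            anns[entry["id"]] = _ann_from_json(entry["annotation"])
    S = {}
    for triplet in doc["S"]:
        if len(triplet) != 3:
            raise ModelValidationError(f"bad S triplet: {triplet!r}")
        i, j, a = triplet
        S[(int(i), int(j))] = rat(a)
    rows = []
    for rd in doc.get("dilution_rows", []):
        rows.append(DilutionRow(
            b={rid: rat(c) for rid, c in rd.get("b", [])},
            c={rid: rat(c) for rid, c in rd.get("c", [])},
            sense=rd.get("sense", "ge"),
            family=rd.get("family", "generic"),
            label=rd.get("label", "")))
    return MEModelSpec(rids, doc["metabolites"], S, lowers, uppers,
                       growth_reaction=doc.get("growth_reaction"),
                       dilution_rows=rows, annotations=anns,
                       metadata=doc.get("metadata", {}))


def write_model_json(model: MEModelSpec, path):
    with open(path, "w") as fh:
        json.dump(model_to_json_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_model_json(path) -> MEModelSpec:
    with open(path) as fh:
        doc = json.load(fh)
    return model_from_json_dict(doc)


def models_equal(a: MEModelSpec, b: MEModelSpec) -> bool:
    return model_to_json_dict(a) == model_to_json_dict(b)
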