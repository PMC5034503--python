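"""Desk-scale synthetic ME-like models with known structure.

Three deterministic fixtures and one seeded random family:

* :func:`make_analytic_model` -- a four-reaction model whose maximal
  growth rate has the closed form ``mu* = U / (a_bio + m U / k_eff)``,
  used as the analytic oracle throughout the test suite.
* :func:`make_coupled_complex_model` -- two translation products whose
  only sink is a 1:1 complex; flux variability must return identical
  ranges for the two translation fluxes.
* :func:`make_two_pathway_model` -- two redundant enzyme-catalyzed
  production pathways plus an essential uptake enzyme; exercises
  knockout screening and the expression grid scan.
* :func:`make_multiscale_model` -- a seeded random model instantiating
  all four machinery dilution families (ribosome, RNA polymerase, tRNA
  charging, enzyme usage) plus generic mRNA-dilution rows, with
  coefficients and fluxes spanning many orders of magnitude.  Models are
  feasible by construction: a flux template at a reference growth rate
  is computed exactly from the (square) balance system before bounds are
  finalized.
"""
from __future__ import annotations

import math
from decimal import Decimal

import numpy as np
from gmpy2 import mpq

from .arith import INF, rat, rat_to_str
from .model_core import (Annotation, DilutionConstants, DilutionRow,
                         MEModelSpec, build_dilution_rows, fix_mu)
from .xlp import LPProblem, _solve_exact


def _round_sig(x: float, digits: int = 4):
    """Round to significant decimal digits; returns an exact rational."""
    if x == 0:
        return mpq(0)
    d = Decimal(repr(float(x)))
    shift = digits - 1 - math.floor(math.log10(abs(x)))
    q = d.scaleb(shift).to_integral_value()
    return rat(str(q.scaleb(-shift)))


def analytic_mu_star(U, a_bio, m, k_eff):
    """Closed-form optimum of the analytic fixture (exact rational).

    At the optimum the uptake bound and the enzyme dilution row are both
    tight, so the substrate balance reads U = a_bio mu + m mu U / k_eff.
    """
    U, a_bio, m, k_eff = rat(U), rat(a_bio), rat(m), rat(k_eff)
    return U / (a_bio + m * U / k_eff)


def make_analytic_model(U=10, a_bio=10, m=1, k_eff=100) -> MEModelSpec:
    """Four reactions, one enzyme dilution row, closed-form mu*.

    Reactions: substrate uptake (bounded by ``U``, enzyme-coupled),
    growth (consumes ``a_bio`` substrate per unit growth), enzyme
    synthesis (consumes ``m`` substrate), enzyme dilution.  The dilution
    row ``v_dil - mu (1/k_eff) v_uptake >= 0`` couples enzyme abundance
    to the uptake flux it catalyzes.
    """
    for name, v in (("U", U), ("a_bio", a_bio), ("m", m), ("k_eff", k_eff)):
        if not (rat(v) > 0):
            raise ValueError(f"parameter {name} must be positive")
    U, a_bio, m, k_eff = rat(U), rat(a_bio), rat(m), rat(k_eff)
    rids = ["uptake", "growth", "enzyme_synthesis", "enzyme_dilution"]
    mets = ["substrate", "enzyme"]
    S = {(0, 0): mpq(1), (0, 1): -a_bio, (0, 2): -m,
         (1, 2): mpq(1), (1, 3): mpq(-1)}
    lower = [mpq(0)] * 4
    upper = [U, INF, INF, INF]
    row = DilutionRow(b={"enzyme_dilution": mpq(1)},
                      c={"uptake": mpq(1) / k_eff},
                      sense="ge", family="enzyme", label="enzyme_dilution_row")
    anns = {
        "uptake": Annotation("exchange"),
        "growth": Annotation("metabolic"),
        "enzyme_synthesis": Annotation("translation", gene="enz",
                                       peptide_length=mpq(300), mw=mpq(30000)),
        "enzyme_dilution": Annotation("dilution", species="enzyme"),
    }
    meta = {"generator": "analytic",
            "U": rat_to_str(U), "a_bio": rat_to_str(a_bio),
            "m": rat_to_str(m), "k_eff": rat_to_str(k_eff),
            "mu_star_closed_form": rat_to_str(analytic_mu_star(U, a_bio, m, k_eff))}
    return MEModelSpec(rids, mets, S, lower, upper, growth_reaction="growth",
                       dilution_rows=[row], annotations=anns, metadata=meta)


def make_coupled_complex_model(U=10, a_bio=8, m=1, k_eff=50) -> MEModelSpec:
    """Two subunits, one 1:1 complex, one enzyme dilution row.

    The complex formation flux is the only sink for both translation
    products, so any feasible flux vector has identical values on the two
    translation reactions; their FVA ranges must coincide.  The complex
    catalyzes uptake, so at the maximal growth rate the whole expression
    chain is uniquely determined (zero flux variability).
    mu* = U / (a_bio + 2 m U / k_eff).
    """
    U, a_bio, m, k_eff = rat(U), rat(a_bio), rat(m), rat(k_eff)
    rids = ["uptake", "growth", "translation_su1", "translation_su2",
            "complex_formation", "complex_dilution"]
    mets = ["substrate", "subunit1", "subunit2", "complex"]
    S = {
        (0, 0): mpq(1), (0, 1): -a_bio, (0, 2): -m, (0, 3): -m,
        (1, 2): mpq(1), (1, 4): mpq(-1),
        (2, 3): mpq(1), (2, 4): mpq(-1),
        (3, 4): mpq(1), (3, 5): mpq(-1),
    }
    lower = [mpq(0)] * 6
    upper = [U, INF, INF, INF, INF, INF]
    row = DilutionRow(b={"complex_dilution": mpq(1)},
                      c={"uptake": mpq(1) / k_eff},
                      sense="ge", family="enzyme", label="complex_dilution_row")
    anns = {
        "uptake": Annotation("exchange"),
        "growth": Annotation("metabolic"),
        "translation_su1": Annotation("translation", gene="su1",
                                      peptide_length=mpq(450), mw=mpq(50000)),
        "translation_su2": Annotation("translation", gene="su2",
                                      peptide_length=mpq(200), mw=mpq(22000)),
        "complex_formation": Annotation("complex_formation"),
        "complex_dilution": Annotation("dilution", species="complex"),
    }
    mu_star = U / (a_bio + 2 * m * U / k_eff)
    meta = {"generator": "coupled_complex", "mu_star_closed_form": rat_to_str(mu_star)}
    return MEModelSpec(rids, mets, S, lower, upper, growth_reaction="growth",
                       dilution_rows=[row], annotations=anns, metadata=meta)


def make_two_pathway_model(U=10, a_bio=6, e_atp=1, m_expr="0.1",
                           k_up=100, k_p1=50, k_p2=30) -> MEModelSpec:
    """Growth-coupled production through two redundant pathways.

    Substrate uptake requires enzyme E0 (gene g0: essential).  Energy for
    growth comes from either of two byproduct-forming conversions
    catalyzed by E1 (gene g1) and E2 (gene g2); each alone suffices, so
    g1 and g2 are individually non-essential.  Both conversions secrete
    one product per substrate consumed, coupling product formation to
    growth.  The complex-formation fluxes ``cf_p1``/``cf_p2`` are the
    handles used by the expression grid scan.
    """
    U, a_bio, e_atp = rat(U), rat(a_bio), rat(e_atp)
    m_expr = rat(m_expr)
    k = {"up": rat(k_up), "p1": rat(k_p1), "p2": rat(k_p2)}
    rids = ["uptake", "growth", "conv_p1", "conv_p2", "product_exchange",
            "translation_e0", "translation_e1", "translation_e2",
            "cf_e0", "cf_p1", "cf_p2",
            "dil_e0", "dil_p1", "dil_p2"]
    mets = ["substrate", "atp", "product", "pep0", "pep1", "pep2",
            "enz0", "enz1", "enz2"]
    ix = {r: j for j, r in enumerate(rids)}
    mx = {m: i for i, m in enumerate(mets)}
    S = {}

    def add(met, rxn, coef):
        S[(mx[met], ix[rxn])] = rat(coef)

    add("substrate", "uptake", 1)
    add("substrate", "growth", -a_bio)
    add("substrate", "conv_p1", -1)
    add("substrate", "conv_p2", -1)
    add("substrate", "translation_e0", -m_expr)
    add("substrate", "translation_e1", -m_expr)
    add("substrate", "translation_e2", -m_expr)
    add("atp", "conv_p1", 1)
    add("atp", "conv_p2", 1)
    add("atp", "growth", -e_atp)
    add("product", "conv_p1", 1)
    add("product", "conv_p2", 1)
    add("product", "product_exchange", -1)
    for tag in ("0", "1", "2"):
        dst = {"0": "e0", "1": "p1", "2": "p2"}[tag]
        add(f"pep{tag}", f"translation_e{tag}", 1)
        add(f"pep{tag}", f"cf_{dst}", -1)
        add(f"enz{tag}", f"cf_{dst}", 1)
        add(f"enz{tag}", f"dil_{dst}", -1)
    lower = [mpq(0)] * len(rids)
    upper = [U] + [INF] * (len(rids) - 1)
    # expression machinery caps the two pathway complex-formation fluxes,
    # so forcing both to a high fraction of their maxima stays feasible
    upper[ix["cf_p1"]] = mpq(2)
    upper[ix["cf_p2"]] = mpq(2)
    rows = [
        DilutionRow({"dil_e0": mpq(1)}, {"uptake": 1 / k["up"]},
                    "ge", "enzyme", "dilution_e0"),
        DilutionRow({"dil_p1": mpq(1)}, {"conv_p1": 1 / k["p1"]},
                    "ge", "enzyme", "dilution_p1"),
        DilutionRow({"dil_p2": mpq(1)}, {"conv_p2": 1 / k["p2"]},
                    "ge", "enzyme", "dilution_p2"),
    ]
    anns = {
        "uptake": Annotation("exchange"),
        "growth": Annotation("metabolic"),
        "conv_p1": Annotation("enzyme_usage"),
        "conv_p2": Annotation("enzyme_usage"),
        "product_exchange": Annotation("exchange"),
        "translation_e0": Annotation("translation", gene="g0",
                                     peptide_length=mpq(500), mw=mpq(55000)),
        "translation_e1": Annotation("translation", gene="g1",
                                     peptide_length=mpq(400), mw=mpq(44000)),
        "translation_e2": Annotation("translation", gene="g2",
                                     peptide_length=mpq(350), mw=mpq(38000)),
        "cf_e0": Annotation("complex_formation"),
        "cf_p1": Annotation("complex_formation"),
        "cf_p2": Annotation("complex_formation"),
        "dil_e0": Annotation("dilution", species="enz0"),
        "dil_p1": Annotation("dilution", species="enz1"),
        "dil_p2": Annotation("dilution", species="enz2"),
    }
    meta = {"generator": "two_pathway",
            "substrate_uptake": "uptake",
            "product_exchange": "product_exchange",
            "pathway_1": "cf_p1", "pathway_2": "cf_p2",
            "sectors": {"translation_e0": "core",
                        "translation_e1": "pathway_1",
                        "translation_e2": "pathway_2"}}
    return MEModelSpec(rids, mets, S, lower, upper, growth_reaction="growth",
                       dilution_rows=rows, annotations=anns, metadata=meta)


# ----------------------------------------------------------------------
# seeded multiscale family


def _template_fluxes(model: MEModelSpec, mu0):
    """Exact flux template at growth rate ``mu0``.

    Treats every dilution row as an equality, pins growth to ``mu0`` and
    solves the resulting square rational system.  Raises if the system is
    singular or the solution is negative anywhere -- the generator is
    expected to produce demand-driven tree-like networks where neither
    happens.
    """
    mu0 = rat(mu0)
    lp = fix_mu(model, mu0)
    g = model.rxn_index(model.growth_reaction)
    n, m = lp.n_vars, lp.n_rows
    unknowns = [j for j in range(n) if j != g]
    if len(unknowns) != m:
        raise ValueError(
            f"template system is not square ({len(unknowns)} unknowns, {m} rows)")
    rows = [[mpq(0)] * m for _ in range(m)]
    rhs = [mpq(0)] * m
    for pos, j in enumerate(unknowns):
        for i, a in lp.cols[j].items():
            rows[i][pos] = rat(a)
    for i, a in lp.cols[g].items():
        rhs[i] -= rat(a) * mu0
    sol = _solve_exact([rows[i] for i in range(m)], rhs)
    if sol is None:
        raise RuntimeError("template balance system is singular")
    v = [mpq(0)] * n
    for pos, j in enumerate(unknowns):
        v[j] = sol[pos]
    v[g] = mu0
    return v


def make_multiscale_model(n_peptides=8, n_tus=4, n_trnas=3, n_enzymes=4,
                          magnitude_span_orders=14, seed=0) -> MEModelSpec:
    """Seeded random model instantiating all four dilution families.

    Structure: substrate uptake (bound 1000 mmol/gDW/h, the standard
    free-uptake convention) feeds amino-acid and nucleotide pools;
    peptides are translated from charged tRNA pools, assembled into
    enzyme complexes that catalyze the metabolic reactions; transcription
    units, charged tRNAs, ribosome and RNA polymerase each carry a
    dilution flux constrained by the corresponding machinery row.
    Effective catalytic rates are drawn log-uniformly (with the top of
    the range pinned) so that fluxes span roughly
    ``magnitude_span_orders`` orders of magnitude; peptide lengths are
    uniform on 50..1500 amino acids.

    The model is feasible by construction: an exact flux template at a
    reference growth rate below the growth capacity is solved from the
    balance system and checked for nonnegativity before the model is
    returned.  The seed is stored in the model metadata.
    """
    if min(n_peptides, n_tus, n_trnas, n_enzymes) < 1:
        raise ValueError("all component counts must be >= 1")
    if magnitude_span_orders > 15:
        raise ValueError("magnitude_span_orders must be <= 15")
    rng = np.random.default_rng(seed)
    s = magnitude_span_orders

    U = mpq(1000)
    mu_cap = _round_sig(rng.uniform(0.5, 1.2), 3)
    a_bio = _round_sig(float(U / mu_cap), 4)

    pep_len = [mpq(int(rng.integers(50, 1501))) for _ in range(n_peptides)]
    mean_len = float(sum(pep_len)) / n_peptides
    tu_len = [_round_sig(3.0 * mean_len * rng.uniform(0.5, 1.5), 4)
              for _ in range(n_tus)]
    pep_mw = [_round_sig(110.0 * float(l), 4) for l in pep_len]

    # catalytic rates: log-uniform, top of the range pinned so the flux
    # span is reached deterministically
    k_lo_exp, k_hi_exp = 4.0, max(5.0, s - 5.0)
    k_eff_vals = [_round_sig(10.0 ** rng.uniform(k_lo_exp, k_hi_exp), 4)
                  for _ in range(n_enzymes)]
    k_eff_vals[0] = rat(str(10 ** int(round(k_hi_exp))))
    c_trna = {f"trna{j}": _round_sig(10.0 ** rng.uniform(1.3, 2.3), 4)
              for j in range(n_trnas)}
    c_mrna = {f"TU{t}": _round_sig(10.0 ** rng.uniform(4.0, 5.0), 4)
              for t in range(n_tus)}
    constants = DilutionConstants(c_ribo=mpq(15000), kappa_tau=mpq(4),
                                  r0=mpq(1, 5), c_trna=c_trna, c_mrna=c_mrna)

    usage_pool = ["aa_syn", "nt_syn", "uptake"]
    usage_of = {f"enz{e}": usage_pool[e % len(usage_pool)]
                for e in range(n_enzymes)}
    constants.k_eff = {(f"enz{e}", usage_of[f"enz{e}"]): k_eff_vals[e]
                       for e in range(n_enzymes)}

    enz_of_pep = [i % n_enzymes for i in range(n_peptides)]
    tu_of_pep = [i % n_tus for i in range(n_peptides)]
    trna_of_pep = [i % n_trnas for i in range(n_peptides)]
    L_ribo, L_rnap = mpq(7500), mpq(4000)

    rids, mets = [], []
    anns = {}

    def rxn(rid, ann=None):
        rids.append(rid)
        if ann is not None:
            anns[rid] = ann
        return rid

    rxn("uptake", Annotation("exchange"))
    rxn("growth", Annotation("metabolic"))
    rxn("aa_syn", Annotation("enzyme_usage"))
    rxn("nt_syn", Annotation("enzyme_usage"))
    for i in range(n_peptides):
        rxn(f"translation_{i}",
            Annotation("translation", gene=f"g{i}", peptide_length=pep_len[i],
                       mw=pep_mw[i]))
    for t in range(n_tus):
        rxn(f"transcription_{t}", Annotation("transcription", tu_length=tu_len[t]))
        rxn(f"mrna_dil_{t}", Annotation("dilution", species=f"TU{t}"))
    for j in range(n_trnas):
        rxn(f"charging_{j}", Annotation("charging", species=f"trna{j}"))
        rxn(f"trna_dil_{j}", Annotation("dilution", species=f"trna{j}"))
    for e in range(n_enzymes):
        rxn(f"cf_{e}", Annotation("complex_formation"))
        rxn(f"enz_dil_{e}", Annotation("dilution", species=f"enz{e}"))
    rxn("ribo_syn", Annotation("metabolic"))
    rxn("ribo_dil", Annotation("dilution", species="ribosome"))
    rxn("rnap_syn", Annotation("metabolic"))
    rxn("rnap_dil", Annotation("dilution", species="rnap"))

    mets = (["S", "AA", "NT"]
            + [f"Pep{i}" for i in range(n_peptides)]
            + [f"TU{t}" for t in range(n_tus)]
            + [f"CAA{j}" for j in range(n_trnas)]
            + [f"E{e}" for e in range(n_enzymes)]
            + ["RIBO", "RNAP"])
    ix = {r: j for j, r in enumerate(rids)}
    mx = {m: i for i, m in enumerate(mets)}
    S = {}

    def add(met, rid, coef):
        key = (mx[met], ix[rid])
        S[key] = S.get(key, mpq(0)) + rat(coef)

    add("S", "uptake", 1)
    add("S", "growth", -a_bio)
    add("S", "aa_syn", -1)
    add("S", "nt_syn", -1)
    add("AA", "aa_syn", 1)
    add("NT", "nt_syn", 1)
    for j in range(n_trnas):
        add("AA", f"charging_{j}", -1)
        add(f"CAA{j}", f"charging_{j}", 1)
        add(f"CAA{j}", f"trna_dil_{j}", -1)
    add("AA", "ribo_syn", -L_ribo)
    add("RIBO", "ribo_syn", 1)
    add("RIBO", "ribo_dil", -1)
    add("AA", "rnap_syn", -L_rnap)
    add("RNAP", "rnap_syn", 1)
    add("RNAP", "rnap_dil", -1)
    for i in range(n_peptides):
        add(f"CAA{trna_of_pep[i]}", f"translation_{i}", -pep_len[i])
        add(f"Pep{i}", f"translation_{i}", 1)
        add(f"Pep{i}", f"cf_{enz_of_pep[i]}", -1)
    for t in range(n_tus):
        add("NT", f"transcription_{t}", -tu_len[t])
        add(f"TU{t}", f"transcription_{t}", 1)
        add(f"TU{t}", f"mrna_dil_{t}", -1)
    for e in range(n_enzymes):
        add(f"E{e}", f"cf_{e}", 1)
        add(f"E{e}", f"enz_dil_{e}", -1)

    lower = [mpq(0)] * len(rids)
    upper = [INF] * len(rids)
    upper[ix["uptake"]] = U

    model = MEModelSpec(rids, mets, S, lower, upper, growth_reaction="growth",
                        annotations=anns)
    rows = build_dilution_rows(model, constants)
    for t in range(n_tus):
        peps = [i for i in range(n_peptides) if tu_of_pep[i] == t]
        c = {f"translation_{i}": mpq(1) / rat(c_mrna[f"TU{t}"]) for i in peps}
        rows.append(DilutionRow({f"mrna_dil_{t}": mpq(1)}, c,
                                "ge", "generic", f"mrna_dilution_TU{t}"))
    meta = {"generator": "multiscale", "seed": int(seed),
            "magnitude_span_orders": int(s),
            "mu_cap": rat_to_str(mu_cap), "a_bio": rat_to_str(a_bio)}
    model = MEModelSpec(rids, mets, S, lower, upper, growth_reaction="growth",
                        dilution_rows=rows, annotations=anns, metadata=meta)

    mu0 = rat(mu_cap) / 4
    try:
        v = _template_fluxes(model, mu0)
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(
            f"multiscale generator produced an invalid template (seed={seed}): {exc}"
        ) from exc
    if any(x < 0 for x in v):
        raise RuntimeError(
            f"multiscale generator template has negative flux (seed={seed})")
    if v[ix["uptake"]] > U:
        raise RuntimeError(
            f"multiscale generator template exceeds the uptake bound (seed={seed})")
    nonzero = [abs(float(x)) for x in v if x != 0 and abs(float(x)) > 0.0]
    span = math.log10(max(nonzero) / min(nonzero)) if nonzero else 0.0
    model.metadata["template_mu"] = rat_to_str(mu0)
    model.metadata["template_span_orders"] = round(span, 2)
    return model


# ----------------------------------------------------------------------
# random small rational LPs (solver cross-check instances)


def random_rational_lp(rng) -> LPProblem:
    """A tiny random LP with exact rational data.

    Sized for the exact vertex-enumeration oracle: 2-5 variables, 1-4
    rows, small integer/rational coefficients, mostly finite bounds.
    Instances may be optimal, infeasible or unbounded.
    """
    n = int(rng.integers(2, 6))
    m = int(rng.integers(1, 5))
    def coef():
        return mpq(int(rng.integers(-5, 6)), int(rng.integers(1, 4)))
    cols = [dict() for _ in range(n)]
    for i in range(m):
        for j in range(n):
            if rng.random() < 0.7:
                c = coef()
                if c != 0:
                    cols[j][i] = c
    senses = [("eq" if rng.random() < 0.2 else ("ge" if rng.random() < 0.5 else "le"))
              for _ in range(m)]
    rhs = [mpq(int(rng.integers(-6, 7))) for _ in range(m)]
    lower, upper = [], []
    for j in range(n):
        lo = mpq(int(rng.integers(-4, 1)))
        if rng.random() < 0.85:
            hi = lo + mpq(int(rng.integers(1, 9)))
        else:
            hi = INF
        lower.append(lo)
        upper.append(hi)
    obj = [coef() for _ in range(n)]
    sense = "max" if rng.random() < 0.5 else "min"
    return LPProblem(obj, sense, cols, senses, rhs, lower, upper)
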