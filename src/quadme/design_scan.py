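"""Strain-design case-study pipeline: knockout + expression grid scan.

The growth-coupled overproduction protocol has three steps:

1. delete the knockout genes (zero translation bounds) and find the
   mutant's maximal growth rate mu_KO;
2. run flux variability restricted to the two pathway complex-formation
   reactions with growth fixed to a small fraction (default 0.05) of
   mu_KO, giving each pathway's maximal expression flux;
3. for every pair of expression fractions on the grid, force the
   complex-formation fluxes to at least that fraction of their maxima
   and re-maximize growth, recording product flux, molar yield, the
   pathway translation ratio and proteome sector mass fractions.

Sector mass is the sum of translation flux (mmol/gDW/h) times protein
molecular weight (g/mol) over the proteins of the sector; fractions are
normalized to the total.  Yield is molar: product exchange flux divided
by the absolute substrate uptake flux.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from gmpy2 import mpq

from .arith import ArithmeticContext, rat
from .bisect_search import SearchError
from .model_core import MEModelSpec
from .nlp_solve import NLPError, solve_me
from .variability import gene_map, vary_me

SECTOR_LABELS = ("core", "niche", "pathway_1", "pathway_2", "other")


class ScanConfigError(ValueError):
    pass


@dataclass
class SectorMap:
    """translation reaction id -> sector label, plus molecular weights."""

    sectors: dict
    mw: dict

    def validate(self, model: MEModelSpec):
        for rid in model.reaction_ids:
            ann = model.annotation(rid)
            if ann.category != "translation":
                continue
            if rid not in self.sectors:
                raise ScanConfigError(
                    f"translation reaction {rid!r} is not mapped to a sector")
            if rid not in self.mw or not (rat(self.mw[rid]) > 0):
                raise ScanConfigError(
                    f"translation reaction {rid!r} lacks a molecular weight")

    @classmethod
    def from_model(cls, model: MEModelSpec, overrides=None):
        """Build a map from annotations; unlabelled proteins go to 'other'."""
        labels = dict(model.metadata.get("sectors", {}))
        labels.update(overrides or {})
        sectors, mw = {}, {}
        for rid in model.reaction_ids:
            ann = model.annotation(rid)
            if ann.category != "translation":
                continue
            sectors[rid] = labels.get(rid, "other")
            if ann.mw is None:
                raise ScanConfigError(
                    f"translation reaction {rid!r} lacks a molecular weight")
            mw[rid] = rat(ann.mw)
        return cls(sectors, mw)


@dataclass
class GridPoint:
    fraction_1: float
    fraction_2: float
    feasible: bool
    mu_max: object = None
    product_flux: object = None
    product_yield: object = None
    pathway_ratio: object = None
    sector_fractions: dict = field(default_factory=dict)


@dataclass
class ScanResult:
    points: list
    levels: tuple
    mu_wildtype_ko: object
    pathway_vmax: dict
    n_infeasible: int
    lp_evaluations: int


def proteome_sector_fractions(v, sectors: SectorMap, model: MEModelSpec):
    """Mass fraction of each proteome sector at the flux vector ``v``.

    Sector mass = sum of translation rate x molecular weight over the
    sector's proteins.  Returns (fractions, flagged_zero): when the total
    mass is zero all fractions are reported as 0 with the flag set.
    """
    sectors.validate(model)
    mass = {}
    total = 0.0
    for rid, label in sectors.sectors.items():
        j = model.rxn_index(rid)
        contrib = float(v[j]) * float(sectors.mw[rid])
        mass[label] = mass.get(label, 0.0) + contrib
        total += contrib
    if total <= 0.0:
        return {label: 0.0 for label in mass}, True
    return {label: m / total for label, m in mass.items()}, False


def expression_grid_scan(model: MEModelSpec, knockout_genes,
                         pathway_1: str, pathway_2: str,
                         fractions=None, baseline_fraction=0.05,
                         sectors: SectorMap | None = None,
                         product_exchange: str | None = None,
                         substrate_uptake: str | None = None,
                         ctx: ArithmeticContext | None = None) -> ScanResult:
    """Grid scan of forced pathway expression versus maximal growth.

    ``pathway_1``/``pathway_2`` are complex-formation reaction ids;
    ``fractions`` defaults to 11 linearly spaced levels from 0.05 to
    0.95 applied to each pathway independently (121 grid points).
    Infeasible grid points are recorded and skipped, not fatal.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    if fractions is None:
        fractions = np.linspace(0.05, 0.95, 11)
    fractions = [float(f) for f in fractions]
    for f in fractions:
        if not (0 < f <= 1):
            raise ScanConfigError("fractions must lie in (0, 1]")
    meta = model.metadata
    product_exchange = product_exchange or meta.get("product_exchange")
    substrate_uptake = substrate_uptake or meta.get("substrate_uptake")
    if product_exchange is None or substrate_uptake is None:
        raise ScanConfigError(
            "product_exchange and substrate_uptake reactions must be given "
            "(or present in the model metadata)")
    for rid in (pathway_1, pathway_2, product_exchange, substrate_uptake):
        model.rxn_index(rid)
    if sectors is None:
        sectors = SectorMap.from_model(model)
    sectors.validate(model)

    # step 0: apply the knockouts permanently for the whole scan
    work = model.copy()
    gmap = gene_map(work)
    for gene in knockout_genes:
        if gene not in gmap:
            raise ScanConfigError(f"unknown knockout gene {gene!r}")
        for rid in gmap[gene]:
            j = work.rxn_index(rid)
            work.v_lower[j] = mpq(0)
            work.v_upper[j] = mpq(0)

    # step 1: mutant maximum growth
    base = solve_me(work, ctx=ctx)
    mu_ko = base.mu_star
    lp_evals = base.lp_evaluations

    # step 2: pathway expression capacity at a small growth fraction
    fva = vary_me(work, mu_fraction=baseline_fraction,
                  reactions=[pathway_1, pathway_2], ctx=ctx,
                  nlp_result=base)
    lp_evals += fva.lp_count
    vmax = {p: rat(fva.ranges[p][1]) for p in (pathway_1, pathway_2)}

    # step 3: the grid
    j1 = work.rxn_index(pathway_1)
    j2 = work.rxn_index(pathway_2)
    jp = work.rxn_index(product_exchange)
    ju = work.rxn_index(substrate_uptake)
    ratio_rids = {1: [rid for rid, lab in sectors.sectors.items()
                      if lab == "pathway_1"],
                  2: [rid for rid, lab in sectors.sectors.items()
                      if lab == "pathway_2"]}
    points = []
    n_infeasible = 0
    for f1 in fractions:
        for f2 in fractions:
            work.v_lower[j1] = rat(str(f1)) * vmax[pathway_1]
            work.v_lower[j2] = rat(str(f2)) * vmax[pathway_2]
            try:
                res = solve_me(work, ctx=ctx)
                lp_evals += res.lp_evaluations
            except (SearchError, NLPError):
                points.append(GridPoint(f1, f2, feasible=False))
                n_infeasible += 1
                continue
            v = res.v_star
            prod = v[jp]
            upt = abs(float(v[ju]))
            yield_molar = float(prod) / upt if upt > 0 else 0.0
            t1 = sum(float(v[work.rxn_index(r)]) for r in ratio_rids[1])
            t2 = sum(float(v[work.rxn_index(r)]) for r in ratio_rids[2])
            ratio = t1 / (t1 + t2) if (t1 + t2) > 0 else None
            fracs, _zero = proteome_sector_fractions(v, sectors, work)
            points.append(GridPoint(f1, f2, feasible=True, mu_max=res.mu_star,
                                    product_flux=prod,
                                    product_yield=yield_molar,
                                    pathway_ratio=ratio,
                                    sector_fractions=fracs))
    work.v_lower[j1] = model.v_lower[j1]
    work.v_lower[j2] = model.v_lower[j2]
    return ScanResult(points=points, levels=(len(fractions), len(fractions)),
                      mu_wildtype_ko=mu_ko, pathway_vmax=vmax,
                      n_infeasible=n_infeasible, lp_evaluations=lp_evals)
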