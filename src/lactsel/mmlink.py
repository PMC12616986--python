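"""Three-step pipeline linking the bioenergetic herd model to the
breeding-scheme simulator.

1. **Baseline**: simulate a pedigreed founder population under both
   nutritional environments and estimate the genetic parameters between
   the AA input traits and the complex output traits (the 10-trait panel
   used by the scheme).
2. **Scheme**: run the stochastic breeding scheme under a breeding goal in
   the non-limiting environment; the correlated annual responses on the
   four AA input traits and their genetic-variance retention factors are
   the conventional prediction of how selection moves the biology.
3. **Re-simulation**: shift the AA trait means by the accumulated
   correlated response over a time horizon, reduce their heritabilities
   for the Bulmer effect (residual variances unchanged), re-simulate a
   cow population under each environment, and report the change in
   complex-trait performance per year, standardized by the baseline
   genetic SD.  Before/after populations share their random numbers
   (paired seeds), which removes most Monte-Carlo noise from the response.

The mechanistic (MM) responses can then be compared trait by trait with
the conventional correlated-response predictions of the scheme itself;
differences are pure consequences of the nonlinearity and feedbacks of the
mechanistic model (intake capping, conception feedback, culling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import envgen, founders, herd_model, quantgen, trait_derive
from .breedsim import SchemeResult
from .founders import AA_MEANS, AA_TRAITS, DEFAULT_CV, DEFAULT_H2
from .herd_model import HerdConfig
from .quantgen import GeneticParameters, bulmer_update

RESPONSE_TRAITS = ("BWcalv1", "Milk", "DMI", "Lact_Eff", "IFC")

#: map response trait -> derived-phenotype column
_PHENO_COL = {"BWcalv1": "bw_calv1", "Milk": "milk_280", "DMI": "dmi_mean",
              "Lact_Eff": "lact_eff", "IFC": "ifc"}

#: map AA panel names to founder trait keys
_AA_KEY = {"BasAcq": "bas_acq", "LactAcq": "lact_acq",
           "f_prio_GS": "f_prio_gs", "LactAll": "lact_all"}

HORIZONS = (10, 20, 30)


class LinkError(ValueError):
    pass


@dataclass
class SelectionUpdate:
    """Accumulated effect of selection on the AA input traits."""

    goal: str
    horizon_years: int
    delta_mean: dict          # trait units, total over the horizon
    h2_updated: dict          # Bulmer-reduced heritabilities
    alpha: dict               # genetic-variance retention factors

    @property
    def updated_means(self) -> dict:
        return {t: AA_MEANS[t] + self.delta_mean[t] for t in AA_TRAITS}


@dataclass
class BaselineContext:
    """Baseline simulation and its estimated genetic parameters.

    ``panel_params`` is the bent 10-trait panel used by the breeding
    scheme; ``sigma_g`` maps (trait, scenario) to the baseline genetic SD
    of the complex traits used to standardize responses.
    """

    panel_params: GeneticParameters
    sigma_g: pd.DataFrame          # index RESPONSE_TRAITS, columns HS/MS
    herd_config: HerdConfig
    n_sires: int
    daughters_per_sire: int
    rng_seed: int
    baseline_summary: pd.DataFrame  # lifetime summaries per scenario


def _simulate_phenotypes(pop, scenario, herd_config, rng_seed,
                         calendar_years=13):
    cal = envgen.make_feed_calendar(scenario, calendar_years)
    res = herd_model.simulate_herd(
        pop, cal, herd_config, rng_seed,
        channels=("milk_ecm", "dmi_achieved", "me_intake", "body_weight",
                  "body_reserves"))
    ph = trait_derive.derive_phenotypes(res)
    return res, ph


def estimate_baseline(n_sires: int = 200, daughters_per_sire: int = 100,
                      herd_config: HerdConfig | None = None,
                      rng_seed: int = 0) -> BaselineContext:
    """Step 1: baseline simulation in both environments and parameter
    estimation with the half-sib estimator."""
    cfg = herd_config or HerdConfig()
    pop, ped = founders.sample_founders(n_sires, daughters_per_sire,
                                        rng_seed=rng_seed)
    frames = {}
    summaries = {}
    for sc in ("HS", "MS"):
        res, ph = _simulate_phenotypes(pop, sc, cfg, rng_seed + 1)
        frames[sc] = ph
        summaries[sc] = {
            "lactations_completed": float(res.lactations_completed.mean()),
            "life_eff": float(np.nanmean(res.lifetime_efficiency())),
        }
        del res

    panel = pop.phenotype.rename(columns={
        "bas_acq": "BasAcq", "lact_acq": "LactAcq",
        "f_prio_gs": "f_prio_GS", "lact_all": "LactAll"})
    for sc in ("HS", "MS"):
        panel = panel.join(frames[sc][["milk_280", "dmi_mean", "ifc"]]
                           .rename(columns={"milk_280": f"Milk_{sc}",
                                            "dmi_mean": f"DMI_{sc}",
                                            "ifc": f"IFC_{sc}"}))
    params = quantgen.estimate_variance_components(panel, ped)
    params.genetic_corr = quantgen.bend_correlation_matrix(params.genetic_corr)

    # genetic SDs of all response traits, per scenario, for standardization;
    # a clamped-to-zero sire variance is floored at h2 = 0.01 of the
    # phenotypic variance (the low-fertility-heritability regime)
    sg = {}
    for sc in ("HS", "MS"):
        ext = pop.phenotype.join(
            frames[sc][["bw_calv1", "milk_280", "dmi_mean", "lact_eff", "ifc"]])
        est = quantgen.estimate_variance_components(ext, ped)
        sg[sc] = [max(est.sigma_g[_PHENO_COL[t]],
                      0.1 * est.sigma_p[_PHENO_COL[t]])
                  for t in RESPONSE_TRAITS]
    sigma_g = pd.DataFrame(sg, index=list(RESPONSE_TRAITS))

    return BaselineContext(
        panel_params=params, sigma_g=sigma_g, herd_config=cfg,
        n_sires=n_sires, daughters_per_sire=daughters_per_sire,
        rng_seed=rng_seed,
        baseline_summary=pd.DataFrame(summaries).T,
    )


def build_update(result: SchemeResult, horizon: int,
                 h2=DEFAULT_H2, cv=DEFAULT_CV) -> SelectionUpdate:
    """Step 3a: turn scheme responses into updated AA-trait parameters.

    The mean of AA trait i moves by ``annual response_i (SD units) x
    sigma_g_i x horizon``; the heritability is Bulmer-updated with the
    retention factor alpha_i, keeping residual variances unchanged;
    genetic correlations among AA traits stay at their initial values.
    """
    if horizon <= 0:
        raise LinkError("horizon must be positive")
    delta, h2u, alpha = {}, {}, {}
    for panel_name, key in _AA_KEY.items():
        if panel_name not in result.aa_response.index:
            raise LinkError(f"scheme result lacks AA trait {panel_name}")
        resp = float(result.aa_response[panel_name])
        a = float(np.clip(result.alpha[panel_name], 1e-6, 1.0))
        sg = cv * AA_MEANS[key] * np.sqrt(h2)
        delta[key] = resp * sg * horizon
        h2u[key] = bulmer_update(h2, a)
        alpha[key] = a
    return SelectionUpdate(goal=result.goal, horizon_years=horizon,
                           delta_mean=delta, h2_updated=h2u, alpha=alpha)


def _resim_population(update: SelectionUpdate | None, n_cows: int,
                      rng_seed: int):
    """Founder draw for a re-simulation; shares random numbers across
    updates for a common seed (paired populations)."""
    n_sires = max(10, n_cows // 100)
    dps = n_cows // n_sires
    if update is None:
        pop, _ = founders.sample_founders(n_sires, dps, rng_seed=rng_seed)
    else:
        pop, _ = founders.sample_founders(
            n_sires, dps, means=update.updated_means,
            h2=update.h2_updated, cv=DEFAULT_CV, rng_seed=rng_seed,
            alpha=update.alpha, ref_means=AA_MEANS)
    return pop


def predict_mm_response(context: BaselineContext, update: SelectionUpdate,
                        scenario: str, n_cows: int = 2000,
                        rng_seed: int = 0) -> pd.Series:
    """Step 3b: mechanistic selection response in a nutritional scenario.

    Simulates paired baseline and updated populations of ``n_cows`` under
    the scenario's feed calendar and returns the annualized change in the
    complex-trait phenotype means, standardized by the baseline genetic SD
    of each trait in that scenario (positive IFC = worse fertility).
    """
    rows = {}
    means = {}
    for tag, upd in (("before", None), ("after", update)):
        pop = _resim_population(upd, n_cows, rng_seed + 7)
        res, ph = _simulate_phenotypes(pop, scenario, context.herd_config,
                                       rng_seed + 11)
        means[tag] = ph.mean()
        if tag == "after":
            rows["lactations_completed"] = float(
                res.lactations_completed.mean())
            rows["life_eff"] = float(np.nanmean(res.lifetime_efficiency()))
        del res
    for t in RESPONSE_TRAITS:
        col = _PHENO_COL[t]
        sg = float(context.sigma_g.loc[t, scenario])
        rows[t] = (float(means["after"][col]) - float(means["before"][col])) \
            / update.horizon_years / sg
    out = pd.Series(rows, name=f"{update.goal}/{scenario}/{update.horizon_years}y")
    return out


def conventional_response(result: SchemeResult, scenario: str) -> pd.Series:
    """Conventional (infinitesimal-model) prediction for the response
    traits in a scenario, from the scheme's annual genetic trends.

    BWcalv1 and Lact_Eff are the genetic aliases of BasAcq and LactAll, so
    their trends are environment-independent.
    """
    g = result.annual_gain
    return pd.Series({
        "BWcalv1": g["BasAcq"],
        "Milk": g[f"Milk_{scenario}"],
        "DMI": g[f"DMI_{scenario}"],
        "Lact_Eff": g["LactAll"],
        "IFC": g[f"IFC_{scenario}"],
    }, name=f"{result.goal}/{scenario}/conventional")


def compare_methods(mm: pd.DataFrame, conventional: pd.DataFrame):
    """Differences (MM - conventional) and per-trait goal rankings.

    Both inputs are indexed by goal with the response traits as columns.
    Returns (difference table, rankings dict, list of rank inversions);
    an inversion is a goal pair ordered differently by the two methods on
    some trait.
    """
    if set(mm.index) != set(conventional.index):
        raise LinkError("goal sets differ between methods")
    conventional = conventional.loc[mm.index]
    common = [c for c in mm.columns if c in conventional.columns]
    diff = mm[common] - conventional[common]
    rankings = {}
    inversions = []
    for t in common:
        r_mm = list(mm[t].sort_values(ascending=False).index)
        r_cv = list(conventional[t].sort_values(ascending=False).index)
        rankings[t] = {"mm": r_mm, "conventional": r_cv}
        for i, a in enumerate(mm.index):
            for b in list(mm.index)[i + 1:]:
                s_mm = np.sign(mm.loc[a, t] - mm.loc[b, t])
                s_cv = np.sign(conventional.loc[a, t] - conventional.loc[b, t])
                if s_mm != 0 and s_cv != 0 and s_mm != s_cv:
                    inversions.append((t, a, b))
    return diff, rankings, inversions


def lifetime_summary(result: herd_model.HerdResult) -> tuple[float, float]:
    """(mean completed lactations, mean lifetime efficiency %) over ALL
    simulated cows, including those culled early."""
    if result.n_cows == 0:
        raise LinkError("empty result")
    return (float(result.lactations_completed.mean()),
            float(np.nanmean(result.lifetime_efficiency())))


def link_goal(context: BaselineContext, scheme_result: SchemeResult,
              horizons=HORIZONS, scenarios=("HS", "MS"),
              n_cows: int = 2000, rng_seed: int = 0) -> pd.DataFrame:
    """Full MM response table for one goal: rows (scenario, horizon)."""
    rows = []
    for h in horizons:
        upd = build_update(scheme_result, h)
        for sc in scenarios:
            row = predict_mm_response(context, upd, sc, n_cows, rng_seed)
            row["goal"] = scheme_result.goal
            row["scenario"] = sc
            row["horizon"] = h
            rows.append(row)
    return pd.DataFrame(rows).set_index(["goal", "scenario", "horizon"])
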