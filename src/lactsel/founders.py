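"""Founder population of acquisition/allocation (AA) input traits.

The four genetically driven input traits of the bioenergetic cow model are

* ``bas_acq``   -- basal acquisition: maximal intake of a non-lactating
  mature cow (kg DM/d), mean 7.00;
* ``lact_acq``  -- lactation acquisition: intake increase during lactation
  at its peak (kg DM/d), mean 10.25;
* ``f_prio_gs`` -- rate of transfer of energy-allocation priority from
  growth to survival (1/d), mean 0.0035;
* ``lact_all``  -- energy-allocation coefficient to lactation at the start
  of lactation (dimensionless in (0, 1)), mean 0.56.

The founder population is structured in paternal half-sib families:
``n_sires`` unrelated sires, each with ``daughters_per_sire`` daughters out
of unrelated, non-phenotyped dams.  True breeding values (TBVs) follow the
infinitesimal model (multivariate normal, traits mutually independent);
a daughter's TBV is the parent average plus a Mendelian-sampling deviation
of variance half the additive variance.  Phenotypes are TBV plus an
independent normal residual.  Heritability and the phenotypic coefficient
of variation are shared by all four traits (defaults 0.35 and 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AA_TRAITS = ("bas_acq", "lact_acq", "f_prio_gs", "lact_all")

#: Calibrated population means of the AA input traits.
AA_MEANS = {"bas_acq": 7.00, "lact_acq": 10.25, "f_prio_gs": 0.0035,
            "lact_all": 0.56}

DEFAULT_H2 = 0.35
DEFAULT_CV = 0.10


class ConfigurationError(ValueError):
    pass


@dataclass
class AAPopulation:
    """TBVs and phenotypes of the AA input traits for a cow population.

    ``tbv`` and ``phenotype`` are DataFrames indexed by ``cow_id`` with one
    column per AA trait.  ``means``, ``h2`` and ``cv`` record the sampling
    parameters (per-trait, aligned with ``AA_TRAITS``); ``sigma_g`` and
    ``sigma_e`` the genetic and residual standard deviations actually used.
    """

    tbv: pd.DataFrame
    phenotype: pd.DataFrame
    means: dict
    h2: dict
    sigma_g: dict
    sigma_e: dict

    @property
    def n_cows(self) -> int:
        return len(self.tbv)

    def to_csv(self, path) -> None:
        df = self.tbv.add_suffix("_tbv").join(self.phenotype.add_suffix("_phen"))
        df.to_csv(path, index_label="cow_id")


@dataclass
class Pedigree:
    """Three-column pedigree (0 = unknown parent) with birth year and sex."""

    frame: pd.DataFrame  # columns: animal_id, sire_id, dam_id, birth_year, sex

    def to_file(self, path) -> None:
        self.frame.to_csv(path, sep=" ", index=False, header=True)

    @classmethod
    def from_file(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep=r"\s+"))


def _per_trait(value, traits: Sequence[str]) -> dict:
    if isinstance(value, Mapping):
        return {t: float(value[t]) for t in traits}
    return {t: float(value) for t in traits}


def sample_founders(n_sires: int, daughters_per_sire: int,
                    means: Mapping[str, float] | None = None,
                    h2=DEFAULT_H2, cv=DEFAULT_CV,
                    rng_seed: int = 0,
                    alpha: Mapping[str, float] | None = None,
                    ref_means: Mapping[str, float] | None = None,
                    ) -> tuple[AAPopulation, Pedigree]:
    """Sample the founder cow population and its half-sib pedigree.

    Parameters
    ----------
    n_sires, daughters_per_sire : int
        Family structure (the reference design is 200 x 100 = 20,000 cows).
    means : mapping, optional
        Population mean per AA trait (defaults to the calibrated means).
    h2, cv : float or mapping
        Heritability in (0, 1) and phenotypic coefficient of variation
        (> 0), scalar or per trait.  The phenotypic variance of trait ``t``
        is ``(cv * mean_t)**2``; ``cv`` always refers to the *base*
        population so residual variances are unaffected by ``alpha``.
    rng_seed : int
        Seed; a fixed seed reproduces the population bit-for-bit, and the
        standardized draws depend only on (seed, structure) so populations
        sampled with different means/variances but the same seed are
        coupled (common random numbers).
    alpha : mapping, optional
        Per-trait genetic-variance retention factor in (0, 1], used when
        re-simulating a population after selection: the genetic variance
        becomes ``alpha * sigma_g**2`` while residual variances stay at
        their base values.
    ref_means : mapping, optional
        Means used to set the variance scale (``sigma_p = cv * ref_mean``).
        Defaults to ``means``; pass the base-population means when sampling
        a selection-shifted population so that variances refer to the base.

    Returns
    -------
    (AAPopulation, Pedigree)
    """
    if n_sires < 1 or daughters_per_sire < 1:
        raise ConfigurationError("counts must be positive")
    means = dict(AA_MEANS if means is None else means)
    h2 = _per_trait(h2, AA_TRAITS)
    cv = _per_trait(cv, AA_TRAITS)
    for t in AA_TRAITS:
        if not 0.0 < h2[t] < 1.0:
            raise ConfigurationError("h2 must be in (0, 1)")
        if cv[t] <= 0:
            raise ConfigurationError("cv must be > 0")
    alpha = {t: 1.0 for t in AA_TRAITS} if alpha is None else _per_trait(alpha, AA_TRAITS)
    ref_means = dict(means if ref_means is None else ref_means)

    n_daughters = n_sires * daughters_per_sire
    rng = np.random.default_rng(rng_seed)
    # standardized draws, fixed shape -> common random numbers across
    # parameter sets sharing the seed
    z_sire = rng.standard_normal((n_sires, len(AA_TRAITS)))
    z_dam = rng.standard_normal((n_daughters, len(AA_TRAITS)))
    z_ms = rng.standard_normal((n_daughters, len(AA_TRAITS)))
    z_res = rng.standard_normal((n_daughters, len(AA_TRAITS)))

    sigma_g, sigma_e = {}, {}
    tbv = np.empty((n_daughters, len(AA_TRAITS)))
    phen = np.empty_like(tbv)
    sire_of = np.repeat(np.arange(n_sires), daughters_per_sire)
    for j, t in enumerate(AA_TRAITS):
        sp = cv[t] * ref_means[t]
        sg = np.sqrt(alpha[t] * h2[t]) * sp
        se = np.sqrt(1.0 - h2[t]) * sp
        sigma_g[t], sigma_e[t] = sg, se
        tbv_sire = sg * z_sire[:, j]
        tbv_dam = sg * z_dam[:, j]
        tbv[:, j] = means[t] + 0.5 * (tbv_sire[sire_of] + tbv_dam) \
            + np.sqrt(0.5) * sg * z_ms[:, j]
        phen[:, j] = tbv[:, j] + se * z_res[:, j]

    # guards: strictly positive phenotypes, lact_all in (0, 1).  With the
    # reference CV these bind essentially never but protect the herd model.
    j_f = AA_TRAITS.index("f_prio_gs")
    for arr in (tbv, phen):
        arr[:, :] = np.maximum(arr, 1e-12)
        arr[:, j_f] = np.maximum(arr[:, j_f], 0.0)
    j_l = AA_TRAITS.index("lact_all")
    tbv[:, j_l] = np.clip(tbv[:, j_l], 1e-6, 1 - 1e-6)
    phen[:, j_l] = np.clip(phen[:, j_l], 1e-6, 1 - 1e-6)

    cow_ids = np.arange(1, n_daughters + 1) + n_sires + n_daughters
    pop = AAPopulation(
        tbv=pd.DataFrame(tbv, columns=list(AA_TRAITS), index=cow_ids),
        phenotype=pd.DataFrame(phen, columns=list(AA_TRAITS), index=cow_ids),
        means=means, h2=h2, sigma_g=sigma_g, sigma_e=sigma_e,
    )

    sire_ids = np.arange(1, n_sires + 1)
    dam_ids = np.arange(1, n_daughters + 1) + n_sires
    ped = pd.DataFrame({
        "animal_id": np.concatenate([sire_ids, dam_ids, cow_ids]),
        "sire_id": np.concatenate([np.zeros(n_sires + n_daughters, dtype=int),
                                   sire_ids[sire_of]]),
        "dam_id": np.concatenate([np.zeros(n_sires + n_daughters, dtype=int),
                                  dam_ids]),
        "birth_year": np.concatenate([np.zeros(n_sires + n_daughters, dtype=int),
                                      np.ones(n_daughters, dtype=int)]),
        "sex": np.concatenate([np.full(n_sires, "M"),
                               np.full(n_daughters, "F"),
                               np.full(n_daughters, "F")]),
    })
    return pop, Pedigree(ped)
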