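"""Reduced-form daily bioenergetic lifetime simulation of dairy cows.

Each cow is driven by her four acquisition/allocation (AA) input traits:

* ``bas_acq`` scales the basal (maintenance-related) intake capacity, which
  rises with age along a maturity curve towards ``bas_acq`` kg DM/d;
* ``lact_acq`` scales the extra intake during lactation; the lactation
  intake curve is normalized so that its peak increment equals
  ``lact_acq`` exactly;
* ``lact_all`` is the energy-allocation coefficient to lactation at
  calving; the coefficient decays with a fixed, non-genetic persistency;
* ``f_prio_gs`` is the rate at which the energy-allocation coefficient to
  growth decays with age (priority transfer from growth to survival).

Daily step: expected intake -> achieved intake (capped by the feed offer)
-> metabolizable energy -> maintenance first, then partition of the
surplus by the time-varying allocation coefficients (lactation, gestation,
growth), with the residual stored as labile body reserves.  When achieved
energy falls short of the maintenance plus lactation demand (the demand is
set by the cow's unconstrained intake potential), labile mass is mobilized
up to a daily cap, so under feed restriction milk is buffered at the
expense of body reserves.  Energy is conserved exactly on every day.

Reproduction: a 10-week seasonal mating window with a 21-day oestrus
cycle; the daily conception probability is the product of three
components driven by milk yield (decreasing), body-reserve level
(increasing) and body-reserve mobilization (decreasing).  Pregnancy adds a
fixed gestation-allocation trajectory, so reproductive failure frees
allocation towards lactation and reserves.  Cows not pregnant at the end
of the mating season are culled (heifers immediately, lactating cows at
the end of the running lactation), as are cows whose body reserves fall
below a floor, or that complete the maximum parity.

All free constants are exposed in :class:`HerdConfig`; the defaults are
calibrated once so that the non-limiting baseline population approaches
about 5.9 completed lactations and about 37-38% lifetime efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .envgen import FeedCalendar, SEASON_DAYS
from .founders import AA_TRAITS, AAPopulation

FULL_CHANNELS = ("dmi_expected", "dmi_achieved", "me_intake",
                 "alloc_maintenance", "alloc_growth", "alloc_lactation",
                 "alloc_gestation", "alloc_reserves",
                 "milk_ecm", "body_weight", "body_reserves")
CORE_CHANNELS = ("dmi_achieved", "milk_ecm", "body_weight", "body_reserves")

CULL_NONE, CULL_OPEN, CULL_RESERVES, CULL_MAX_PARITY = 0, 1, 2, 3
CULL_REASONS = {CULL_NONE: "none", CULL_OPEN: "open_at_season_end",
                CULL_RESERVES: "reserves_depleted",
                CULL_MAX_PARITY: "max_parity"}


class ContractViolation(ValueError):
    pass


@dataclass
class HerdConfig:
    """All constants of the reduced-form cow model (units in comments)."""

    # energy bookkeeping (metabolizable-energy basis)
    k_net: float = 1.0            # fraction of ME entering the partition
    maint_coef: float = 0.30      # MJ ME / kg^0.75 / d
    e_milk: float = 5.06          # MJ ME per kg energy-corrected milk
    e_struct: float = 17.0        # MJ ME per kg structural-mass gain
    e_labile: float = 32.0        # MJ ME-equivalent per kg labile mass
    me_reference: float = 11.70   # MJ/kg DM used for the intake potential

    # intake curves
    maturity_rate: float = 0.002  # 1/d, basal-intake maturity curve
    birth_intake_frac: float = 0.10  # basal intake at birth / mature
    lact_intake_rise: float = 18.0   # d, rise time of lactation intake
    lact_intake_decay: float = 240.0  # d, decay time of lactation intake

    # allocation coefficients
    lact_persistency: float = 0.0005   # 1/d decay of lactation coefficient
    growth_coef0: float = 0.85        # growth coefficient at birth
    gest_coef_max: float = 0.30       # gestation coefficient at term
    gest_exponent: float = 3.0
    reserves_soft: float = 0.17       # reserve ratio where storage tapers
    reserves_max: float = 0.24        # reserve ratio where storage stops
    mob_cap: float = 12.0             # MJ/d mobilization cap
    labile_yield: float = 0.60        # MJ delivered per MJ of labile store
    # mobilized (cycling energy through body reserves dissipates the rest)
    milk_drive_rise: float = 8.0      # d; the lactation energy demand rises
    # towards the surplus at peak intake faster than intake itself rises,
    # creating the classic early-lactation energy deficit

    # body
    birth_structural: float = 36.0  # kg
    birth_labile: float = 4.0       # kg

    # reproduction and herd calendar
    gestation_days: int = 282
    mating_season_weeks: int = 10
    oestrus_cycle: int = 21
    heifer_first_mating_age: int = 424  # d
    dry_before_calving: int = 90        # d
    dry_before_season: int = 56         # d
    lactation_max_days: int = 280       # open cows finish lactation here
    max_parity: int = 8
    reserves_cull_floor: float = 0.01

    # conception-probability components (calibration knobs)
    conc_milk_mid: float = 27.0    # kg ECM/d at which p_milk = 0.5
    conc_milk_scale: float = 4.5
    conc_res_mid: float = 0.16    # body-reserve ratio at which p_level = 0.5
    conc_res_scale: float = 0.02
    conc_mob_rate: float = 0.05   # 1/MJ, p_mob = exp(-rate * mobilized MJ)
    conc_max: float = 1.0         # overall scaling of the product

    # feedback switches (diagnostics: disabling them removes the
    # mechanistic nonlinearity so responses become those of a linear map)
    conception_feedback: bool = True
    constant_conception: float = 0.5  # used when conception_feedback=False

    # calendar geometry: day-of-year (0-based) anchors; day 0 = first day
    # of the calving season.
    @property
    def mating_season_start(self) -> int:
        return SEASON_DAYS - self.gestation_days  # 83

    @property
    def birth_doy(self) -> int:
        return (self.mating_season_start - self.heifer_first_mating_age) % SEASON_DAYS


@dataclass
class CowState:
    """Snapshot of one cow's physiological state."""

    age_days: int
    parity: int = 0
    days_in_milk: int = -1          # -1 = not lactating
    pregnant: bool = False
    day_of_gestation: int = 0
    structural_mass: float = 450.0
    labile_mass: float = 80.0
    alive: bool = True
    cull_reason: str = "none"

    @property
    def lactating(self) -> bool:
        return self.days_in_milk >= 0

    @property
    def body_weight(self) -> float:
        return self.structural_mass + self.labile_mass

    @property
    def body_reserves(self) -> float:
        return self.labile_mass / self.body_weight


# ---------------------------------------------------------------------------
# vectorized kernels (shared by the public per-cow operations and the
# cohort simulator)


def _basal_dmi(bas_acq, age_days, cfg: HerdConfig):
    return bas_acq * (1.0 - (1.0 - cfg.birth_intake_frac)
                      * np.exp(-cfg.maturity_rate * np.asarray(age_days, float)))


def _lact_curve_norm(cfg: HerdConfig) -> float:
    """Peak value of the raw lactation-intake curve (for normalization)."""
    tr, td = cfg.lact_intake_rise, cfg.lact_intake_decay
    t_peak = tr * np.log1p(td / tr)
    return float((1.0 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td))


def _lact_dmi(lact_acq, dim, cfg: HerdConfig):
    dim = np.asarray(dim, float)
    raw = (1.0 - np.exp(-dim / cfg.lact_intake_rise)) \
        * np.exp(-dim / cfg.lact_intake_decay)
    return lact_acq * raw / _lact_curve_norm(cfg)


def expected_dmi(aa, state: CowState, cfg: HerdConfig | None = None) -> float:
    """Genetically expected (unconstrained) dry-matter intake, kg/d.

    Sum of a basal component rising with age towards ``bas_acq`` and, when
    lactating, a lactation component whose peak increment equals
    ``lact_acq``.
    """
    cfg = cfg or HerdConfig()
    if not state.alive:
        raise ContractViolation("cow not alive")
    out = float(_basal_dmi(aa["bas_acq"], state.age_days, cfg))
    if state.lactating:
        out += float(_lact_dmi(aa["lact_acq"], state.days_in_milk, cfg))
    return out


def achieved_dmi(expected: float, offer: float) -> float:
    """Achieved intake: the expected intake capped by the daily offer."""
    if expected < 0 or offer < 0:
        raise ContractViolation("intake and offer must be >= 0")
    return min(expected, offer)


def _alloc_coefs(lact_all, f_prio_gs, age_days, dim, dog, lactating,
                 pregnant, cfg: HerdConfig):
    c_l = np.where(lactating,
                   lact_all * np.exp(-cfg.lact_persistency * np.maximum(dim, 0)),
                   0.0)
    c_gest = np.where(pregnant,
                      cfg.gest_coef_max
                      * (np.maximum(dog, 0) / cfg.gestation_days) ** cfg.gest_exponent,
                      0.0)
    c_g = cfg.growth_coef0 * np.exp(-f_prio_gs * np.asarray(age_days, float))
    total = c_l + c_gest + c_g
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    return c_l * scale, c_gest * scale, c_g * scale


def _milk_drive_target(r_pot, r_peak, dim, lactating, cfg: HerdConfig):
    """Surplus level the lactation demand is computed against.

    Equals the unconstrained surplus at calving and relaxes towards the
    surplus at peak intake with time constant ``milk_drive_rise``; since
    intake itself rises more slowly, an energy deficit opens in early
    lactation and is covered by mobilizing reserves.
    """
    drive = 1.0 - np.exp(-np.maximum(dim, 0) / cfg.milk_drive_rise)
    target = r_pot + np.maximum(r_peak - r_pot, 0.0) * drive
    return np.where(lactating, target, r_pot)


def _partition(energy_net, r_target, maint,
               c_l, c_gest, c_g, labile_mass, reserves_ratio,
               cfg: HerdConfig):
    """Vectorized energy partition; returns the five allocations and the
    amount mobilized.  Conservation (sum of allocations == energy_net)
    holds exactly by construction."""
    r = energy_net - maint
    rp = np.maximum(r, 0.0)

    demand_l = c_l * r_target
    deficit_maint = np.maximum(-r, 0.0)
    lact_gap = np.maximum(demand_l - c_l * rp, 0.0)
    labile_energy = labile_mass * cfg.e_labile * cfg.labile_yield
    mob = np.minimum(deficit_maint + lact_gap, cfg.mob_cap)
    # maintenance beyond the cap is still drawn from reserves (starvation)
    mob = np.minimum(np.maximum(mob, deficit_maint), labile_energy)
    m_maint = np.minimum(mob, deficit_maint)
    m_lact = np.minimum(mob - m_maint, lact_gap)

    alloc_l = c_l * rp + m_lact
    alloc_gest = c_gest * rp
    alloc_g = c_g * rp
    # lipogenesis and lipolysis co-occur; alloc_reserves is the NET flow
    # into the labile pool (storage of the unclaimed share, minus the
    # energy mobilized to buffer milk and maintenance)
    leftover = rp * np.maximum(1.0 - c_l - c_gest - c_g, 0.0)
    sat = np.clip((cfg.reserves_max - reserves_ratio)
                  / (cfg.reserves_max - cfg.reserves_soft), 0.0, 1.0)
    alloc_r = leftover * sat - mob
    # maintenance takes the exact remainder (includes unstored surplus
    # dissipated as heat; falls below requirement only under starvation)
    alloc_m = energy_net - alloc_l - alloc_gest - alloc_g - alloc_r
    return alloc_m, alloc_g, alloc_l, alloc_gest, alloc_r, mob


def allocate_energy(state: CowState, net_energy: float, aa,
                    cfg: HerdConfig | None = None) -> dict:
    """Partition one day's net energy for a single cow.

    Returns a dict with keys ``maintenance, growth, lactation, gestation,
    reserves`` (MJ/d; ``reserves`` may be negative = mobilization).  The
    lactation demand is set by the cow's unconstrained intake potential at
    the reference dietary energy content, so that restricted intake
    triggers mobilization of labile mass.
    """
    cfg = cfg or HerdConfig()
    if net_energy < 0:
        raise ContractViolation("net_energy must be >= 0")
    maint = cfg.maint_coef * state.body_weight ** 0.75
    e_pot = expected_dmi(aa, state, cfg) * cfg.me_reference * cfg.k_net
    e_peak = (float(_basal_dmi(aa["bas_acq"], state.age_days, cfg))
              + aa["lact_acq"]) * cfg.me_reference * cfg.k_net
    r_pot = max(e_pot - maint, 0.0)
    r_peak = max(e_peak - maint, 0.0)
    r_target = _milk_drive_target(np.float64(r_pot), np.float64(r_peak),
                                  np.float64(state.days_in_milk),
                                  state.lactating, cfg)
    c_l, c_gest, c_g = _alloc_coefs(
        aa["lact_all"], aa["f_prio_gs"], state.age_days,
        state.days_in_milk, state.day_of_gestation,
        state.lactating, state.pregnant, cfg)
    parts = _partition(np.float64(net_energy), r_target,
                       np.float64(maint), c_l, c_gest, c_g,
                       np.float64(state.labile_mass),
                       np.float64(state.body_reserves), cfg)
    keys = ("maintenance", "growth", "lactation", "gestation", "reserves",
            "mobilized")
    return {k: float(v) for k, v in zip(keys, parts)}


def conception_probability(state_or_reserves, milk_ecm: float,
                           mobilized: float,
                           cfg: HerdConfig | None = None) -> float:
    """Daily conception probability at an insemination.

    Product of three components in [0, 1]: ``p_milk`` (logistic,
    decreasing in milk yield), ``p_level`` (logistic, increasing in the
    body-reserve ratio) and ``p_mob`` (exponential, decreasing in the
    energy mobilized from reserves), scaled by ``conc_max``.
    """
    cfg = cfg or HerdConfig()
    if not cfg.conception_feedback:
        return cfg.constant_conception
    reserves = (state_or_reserves.body_reserves
                if isinstance(state_or_reserves, CowState)
                else float(state_or_reserves))
    p_milk = 1.0 / (1.0 + np.exp((milk_ecm - cfg.conc_milk_mid)
                                 / cfg.conc_milk_scale))
    p_level = 1.0 / (1.0 + np.exp(-(reserves - cfg.conc_res_mid)
                                  / cfg.conc_res_scale))
    p_mob = np.exp(-cfg.conc_mob_rate * max(mobilized, 0.0))
    return float(cfg.conc_max * p_milk * p_level * p_mob)


# ---------------------------------------------------------------------------
# cohort simulator


@dataclass
class HerdResult:
    """Lifetime simulation output for a cohort of cows.

    Daily trajectories are stored as ``(n_days, n_cows)`` arrays in
    ``traj`` for the requested channels; days are global calendar days
    (0-based; day 0 = first day of the calving season of the birth year).
    Event arrays are indexed ``[cow, parity]``; missing events are -1.
    """

    cow_ids: np.ndarray
    aa_phenotype: pd.DataFrame
    config: HerdConfig
    scenario: str
    birth_day: int
    traj: dict
    calving_day: np.ndarray        # (n, max_parity + 1); col p = p-th calving
    first_insem_day: np.ndarray    # (n, max_parity + 1); by parity at mating
    conception_day: np.ndarray
    cull_day: np.ndarray
    cull_reason: np.ndarray
    lactations_completed: np.ndarray
    bw_calv1: np.ndarray
    lifetime_lact_energy: np.ndarray   # MJ allocated to lactation, birth->cull
    lifetime_me_intake: np.ndarray     # MJ ME ingested, birth->cull
    lifetime_dmi: np.ndarray           # kg DM ingested, birth->cull

    @property
    def n_cows(self) -> int:
        return self.cow_ids.size

    def lifetime_efficiency(self) -> np.ndarray:
        """Per-cow lifetime efficiency, % (energy to milk / energy intake)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.lifetime_lact_energy / self.lifetime_me_intake

    def lactation_window(self, cow: int, parity: int):
        """(start_day, end_day) of a lactation, end exclusive; None if the
        cow never reached that parity."""
        if parity >= self.calving_day.shape[1]:
            return None
        c0 = self.calving_day[cow, parity]
        if c0 < 0:
            return None
        nxt = self.calving_day[cow, parity + 1] if parity + 1 <= self.config.max_parity else -1
        end_candidates = [c0 + self.config.lactation_max_days]
        if nxt >= 0:
            end_candidates.append(nxt - 1)  # never overlaps next lactation
            conc = self.conception_day[cow, parity]
            if conc >= 0:
                dry = min(nxt - self.config.dry_before_calving,
                          (nxt - nxt % SEASON_DAYS) - self.config.dry_before_season)
                end_candidates.append(dry)
        if self.cull_day[cow] >= 0:
            end_candidates.append(self.cull_day[cow] + 1)
        return c0, max(c0, min(end_candidates))

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.cow_ids):
            rows.append({
                "cow_id": cid,
                "lactations_completed": self.lactations_completed[i],
                "cull_day": self.cull_day[i],
                "cull_reason": CULL_REASONS[int(self.cull_reason[i])],
                "bw_calv1": self.bw_calv1[i],
            })
        return pd.DataFrame(rows)


def simulate_herd(pop: AAPopulation, calendar: FeedCalendar,
                  config: HerdConfig | None = None, rng_seed: int = 0,
                  channels: Sequence[str] = FULL_CHANNELS,
                  dtype=np.float64) -> HerdResult:
    """Simulate the lifetime of a cohort of cows day by day.

    All cows are born on the same calendar day (single seasonal cohort):
    the birth day is placed so that heifers reach the first-mating age of
    424 d exactly on the first day of a mating season and first calvings
    fall on the first day of a calving season.

    Conception draws are generated for every cow on every insemination
    day from the seeded stream, so two scenarios simulated with the same
    seed share their random numbers cow by cow.
    """
    cfg = config or HerdConfig()
    aa = pop.phenotype
    n = len(aa)
    bas_acq = aa["bas_acq"].to_numpy()
    lact_acq = aa["lact_acq"].to_numpy()
    f_prio = aa["f_prio_gs"].to_numpy()
    lact_all = aa["lact_all"].to_numpy()

    n_days = calendar.n_days
    birth = cfg.birth_doy
    horizon_needed = (cfg.max_parity + 2) * SEASON_DAYS
    if n_days < min(horizon_needed, birth + 2 * SEASON_DAYS):
        raise ContractViolation("calendar shorter than the cows' potential life")

    rng = np.random.default_rng(rng_seed)

    # state
    alive = np.ones(n, bool)
    parity = np.zeros(n, np.int64)
    dim = np.full(n, -1, np.int64)           # -1 = dry / not yet calved
    pregnant = np.zeros(n, bool)
    dog = np.zeros(n, np.int64)
    struct = np.full(n, cfg.birth_structural, np.float64)
    labile = np.full(n, cfg.birth_labile, np.float64)
    pending_cull = np.zeros(n, np.int8)      # reason to apply at lactation end
    next_calving = np.full(n, -1, np.int64)
    dry_day = np.full(n, -1, np.int64)

    P = cfg.max_parity
    calving_day = np.full((n, P + 1), -1, np.int64)
    first_insem = np.full((n, P + 1), -1, np.int64)
    conception = np.full((n, P + 1), -1, np.int64)
    cull_day = np.full(n, -1, np.int64)
    cull_reason = np.zeros(n, np.int8)
    bw_calv1 = np.full(n, np.nan)
    life_lact = np.zeros(n)
    life_me = np.zeros(n)
    life_dmi = np.zeros(n)

    traj = {c: np.full((n_days, n), np.nan, dtype=dtype) for c in channels}

    season_len = 7 * cfg.mating_season_weeks
    mate_start = cfg.mating_season_start
    insem_offsets = set(range(0, season_len - cfg.oestrus_cycle + 1,
                              cfg.oestrus_cycle))

    offer_arr = calendar.dm_offer
    me_arr = calendar.me_content

    for d in range(birth, n_days):
        if not alive.any():
            break
        doy = d % SEASON_DAYS
        age = d - birth
        a = alive

        bw = struct + labile
        res = labile / bw
        maint = cfg.maint_coef * bw ** 0.75
        basal = _basal_dmi(bas_acq, age, cfg)
        lactating = dim >= 0
        dmi_exp = basal + np.where(lactating, _lact_dmi(lact_acq, dim, cfg), 0.0)
        dmi_ach = np.minimum(dmi_exp, offer_arr[d])
        me = me_arr[d]
        e_net = dmi_ach * me * cfg.k_net
        e_pot = dmi_exp * me * cfg.k_net
        r_pot = np.maximum(e_pot - maint, 0.0)
        r_peak = np.maximum((basal + lact_acq) * me * cfg.k_net - maint, 0.0)
        r_target = _milk_drive_target(r_pot, r_peak, dim, lactating, cfg)

        c_l, c_gest, c_g = _alloc_coefs(lact_all, f_prio, age, dim, dog,
                                        lactating, pregnant, cfg)
        al_m, al_g, al_l, al_gest, al_r, mob = _partition(
            e_net, r_target, maint, c_l, c_gest, c_g, labile, res, cfg)
        milk = al_l / cfg.e_milk

        # state update (dead cows frozen); mobilized energy drains the
        # labile store at 1/labile_yield MJ stored per MJ delivered
        struct = np.where(a, struct + al_g / cfg.e_struct, struct)
        d_labile = (al_r + mob) / cfg.e_labile \
            - mob / (cfg.e_labile * cfg.labile_yield)
        labile = np.where(a, np.maximum(labile + d_labile, 0.0), labile)
        life_lact += np.where(a, al_l, 0.0)
        life_me += np.where(a, dmi_ach * me, 0.0)
        life_dmi += np.where(a, dmi_ach, 0.0)

        bw_now = struct + labile
        res_now = labile / bw_now
        if traj:
            vals = {"dmi_expected": dmi_exp, "dmi_achieved": dmi_ach,
                    "me_intake": dmi_ach * me, "alloc_maintenance": al_m,
                    "alloc_growth": al_g, "alloc_lactation": al_l,
                    "alloc_gestation": al_gest, "alloc_reserves": al_r,
                    "milk_ecm": milk, "body_weight": bw_now,
                    "body_reserves": res_now}
            for c in traj:
                traj[c][d, a] = vals[c][a]

        # --- reproduction -------------------------------------------------
        in_season = mate_start <= doy < mate_start + season_len
        if in_season and (doy - mate_start) in insem_offsets:
            u = rng.random(n)  # drawn for all cows: common random numbers
            eligible = (a & ~pregnant & (parity < cfg.max_parity)
                        & (age >= cfg.heifer_first_mating_age)
                        & (pending_cull == 0))
            if eligible.any():
                if cfg.conception_feedback:
                    p_milk = 1.0 / (1.0 + np.exp((milk - cfg.conc_milk_mid)
                                                 / cfg.conc_milk_scale))
                    p_level = 1.0 / (1.0 + np.exp(-(res_now - cfg.conc_res_mid)
                                                  / cfg.conc_res_scale))
                    p_mob = np.exp(-cfg.conc_mob_rate * np.maximum(mob, 0.0))
                    p = cfg.conc_max * p_milk * p_level * p_mob
                else:
                    p = np.full(n, cfg.constant_conception)
                fresh = eligible & (first_insem[np.arange(n), parity] < 0)
                first_insem[fresh, parity[fresh]] = d
                conceive = eligible & (u < p)
                pregnant |= conceive
                dog[conceive] = 0
                conception[conceive, parity[conceive]] = d
                nc = d + cfg.gestation_days
                season_start_of_nc = nc - (nc % SEASON_DAYS)
                next_calving[conceive] = nc
                dry_day[conceive] = min(nc - cfg.dry_before_calving,
                                        season_start_of_nc - cfg.dry_before_season)

        # end of mating season: flag open cows
        if doy == mate_start + season_len - 1:
            open_now = a & ~pregnant & (pending_cull == 0)
            open_mature = open_now & (age >= cfg.heifer_first_mating_age)
            heifer_open = open_mature & (parity == 0)
            alive[heifer_open] = False
            cull_day[heifer_open] = d
            cull_reason[heifer_open] = CULL_OPEN
            cow_open = open_mature & (parity > 0)
            pending_cull[cow_open & (parity < cfg.max_parity)] = CULL_OPEN
            pending_cull[cow_open & (parity >= cfg.max_parity)] = CULL_MAX_PARITY
            a = alive

        # --- transitions --------------------------------------------------
        dog[pregnant & a] += 1

        # dry-off
        to_dry = a & pregnant & (d == dry_day) & (dim >= 0)
        dim[to_dry] = -1

        # end of lactation for cows awaiting culling
        lact_end = a & (pending_cull > 0) & (dim >= cfg.lactation_max_days)
        if lact_end.any():
            alive[lact_end] = False
            cull_day[lact_end] = d
            cull_reason[lact_end] = pending_cull[lact_end]
            a = alive

        # calving
        calv = a & pregnant & (d == next_calving)
        if calv.any():
            parity[calv] += 1
            calving_day[calv, parity[calv]] = d
            dim[calv] = 0
            pregnant[calv] = False
            dog[calv] = 0
            firsts = calv & (parity == 1)
            bw_calv1[firsts] = bw_now[firsts]

        dim[a & (dim >= 0) & ~calv] += 1

        # reserves depletion
        depleted = a & (res_now < cfg.reserves_cull_floor)
        if depleted.any():
            alive[depleted] = False
            cull_day[depleted] = d
            cull_reason[depleted] = CULL_RESERVES

    # cows still alive at calendar end (should not happen with an ample
    # calendar): close them out at the last day
    leftover = alive
    if leftover.any():
        cull_day[leftover] = n_days - 1
        cull_reason[leftover] = CULL_NONE

    return HerdResult(
        cow_ids=np.asarray(pop.phenotype.index),
        aa_phenotype=pop.phenotype,
        config=cfg,
        scenario=calendar.scenario,
        birth_day=birth,
        traj=traj,
        calving_day=calving_day,
        first_insem_day=first_insem,
        conception_day=conception,
        cull_day=cull_day,
        cull_reason=cull_reason,
        lactations_completed=parity,
        bw_calv1=bw_calv1,
        lifetime_lact_energy=life_lact,
        lifetime_me_intake=life_me,
        lifetime_dmi=life_dmi,
    )


# ---------------------------------------------------------------------------
# single-cow interface


@dataclass
class LifeHistory:
    """Daily records and life events of a single cow."""

    cow_id: int
    records: pd.DataFrame
    calving_days: list
    conception_days: list
    cull_day: int
    cull_reason: str
    lactations_completed: int

    @property
    def lifetime_efficiency(self) -> float:
        return 100.0 * self.records["alloc_lactation"].sum() \
            / self.records["me_intake"].sum()


def simulate_lifetime(aa, calendar: FeedCalendar,
                      config: HerdConfig | None = None,
                      rng_seed: int = 0) -> LifeHistory:
    """Simulate a single cow and return her full daily life history."""
    cfg = config or HerdConfig()
    if not isinstance(aa, pd.DataFrame):
        aa = pd.DataFrame([{t: aa[t] for t in AA_TRAITS}], index=[1])
    pop = AAPopulation(tbv=aa.copy(), phenotype=aa, means={}, h2={},
                       sigma_g={}, sigma_e={})
    res = simulate_herd(pop, calendar, cfg, rng_seed,
                        channels=FULL_CHANNELS)
    last = int(res.cull_day[0])
    recs = pd.DataFrame({c: res.traj[c][res.birth_day:last + 1, 0]
                         for c in FULL_CHANNELS})
    recs.insert(0, "day", np.arange(res.birth_day, last + 1))
    return LifeHistory(
        cow_id=int(res.cow_ids[0]),
        records=recs,
        calving_days=[int(x) for x in res.calving_day[0] if x >= 0],
        conception_days=[int(x) for x in res.conception_day[0] if x >= 0],
        cull_day=last,
        cull_reason=CULL_REASONS[int(res.cull_reason[0])],
        lactations_completed=int(res.lactations_completed[0]),
    )
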