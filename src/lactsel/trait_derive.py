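"""Complex-trait phenotypes derived from simulated lifetime trajectories.

The phenotype panel is body weight at first calving (``bw_calv1``, kg) and
four third-lactation traits: cumulative energy-corrected milk over 280 days
(``milk_280``, kg), mean daily dry-matter intake (``dmi_mean``, kg/d),
lactation efficiency (``lact_eff``, %, energy to milk over energy intake
within the lactation) and the interval from first insemination to
conception (``ifc``, days).  Lifetime efficiency (``life_eff``, %) and the
number of completed lactations are carried along.

Lactations shorter than 220 days yield no third-lactation phenotypes;
lactations of 220-279 days are completed to 280 days with a least-squares
cubic spline with 8 equispaced interior knots fitted to the observed daily
yields.

Third-lactation summaries are subject to survivor bias by construction
(only cows reaching a third lactation contribute), so population tables
are exposed both over survivors and over all simulated cows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .herd_model import HerdResult

MIN_LACTATION_DAYS = 220
STD_LACTATION_DAYS = 280
SPLINE_KNOTS = 8

PHENOTYPE_COLUMNS = ("bw_calv1", "milk_280", "dmi_mean", "lact_eff", "ifc",
                     "life_eff", "lactations_completed")


class ContractViolation(ValueError):
    pass


class EmptyResult(ValueError):
    """No cow qualifies for the requested summary."""


def cumulative_milk_280(daily_milk: np.ndarray,
                        lactation_length: int | None = None) -> float:
    """Cumulative 280-d milk yield (kg), spline-completed when needed.

    * length >= 280 d: plain sum of days 1-280;
    * 220 <= length < 280: a least-squares cubic spline with 8 equispaced
      interior knots is fitted to the observed days and evaluated on the
      missing days;
    * length < 220 d: ``nan`` (no phenotype).
    """
    y = np.asarray(daily_milk, dtype=float)
    if lactation_length is None:
        lactation_length = y.size
    y = y[:lactation_length]
    if np.any(y < -1e-9):
        raise ContractViolation("negative daily milk yield")
    n = y.size
    if n < MIN_LACTATION_DAYS:
        return float("nan")
    if n >= STD_LACTATION_DAYS:
        return float(y[:STD_LACTATION_DAYS].sum())
    x = np.arange(1.0, n + 1.0)
    knots = np.linspace(x[0], x[-1], SPLINE_KNOTS + 2)[1:-1]
    spl = LSQUnivariateSpline(x, y, knots, k=3)
    pred = spl(np.arange(n + 1.0, STD_LACTATION_DAYS + 1.0))
    return float(y.sum() + np.clip(pred, 0.0, None).sum())


def _third_lactation_slices(result: HerdResult, cow: int):
    w = result.lactation_window(cow, 3)
    if w is None:
        return None
    start, end = w
    return start, end


def derive_phenotypes(result: HerdResult) -> pd.DataFrame:
    """Per-cow derived phenotypes from a cohort simulation.

    Returns a DataFrame indexed by cow id with the phenotype panel; traits
    the cow never expressed are NaN (e.g. all third-lactation traits for a
    cow culled after two lactations).  Requires the ``milk_ecm``,
    ``dmi_achieved`` and ``me_intake`` channels for third-lactation traits.
    """
    n = result.n_cows
    milk = result.traj.get("milk_ecm")
    dmi = result.traj.get("dmi_achieved")
    me = result.traj.get("me_intake")
    cfg = result.config

    out = {c: np.full(n, np.nan) for c in PHENOTYPE_COLUMNS}
    out["bw_calv1"] = result.bw_calv1.copy()
    out["life_eff"] = result.lifetime_efficiency()
    out["lactations_completed"] = result.lactations_completed.astype(float)

    for i in range(n):
        sl = _third_lactation_slices(result, i)
        if sl is None:
            continue
        start, end = sl
        length = end - start
        if milk is not None:
            out["milk_280"][i] = cumulative_milk_280(milk[start:end, i], length)
        if length >= MIN_LACTATION_DAYS:
            if dmi is not None:
                out["dmi_mean"][i] = np.nanmean(dmi[start:end, i])
            if milk is not None and me is not None:
                intake = np.nansum(me[start:end, i])
                if intake > 0:
                    lact_energy = np.nansum(milk[start:end, i]) * cfg.e_milk
                    out["lact_eff"][i] = 100.0 * lact_energy / intake
        if result.first_insem_day.shape[1] <= 3:
            continue
        fi = result.first_insem_day[i, 3]
        co = result.conception_day[i, 3]
        if fi >= 0 and co >= 0:
            out["ifc"][i] = float(co - fi)

    return pd.DataFrame(out, index=result.cow_ids)


def population_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean and count per trait, over survivors (non-missing) and with the
    all-cow columns (``life_eff``, ``lactations_completed``) over everyone."""
    rows = []
    for c in phenotypes.columns:
        v = phenotypes[c]
        rows.append({"trait": c, "mean": v.mean(), "n": int(v.notna().sum()),
                     "n_total": len(v)})
    return pd.DataFrame(rows).set_index("trait")


def mean_trajectories(result: HerdResult, parity: int = 3,
                      channels=("dmi_achieved", "milk_ecm", "body_weight",
                                "body_reserves"),
                      max_dim: int = STD_LACTATION_DAYS) -> pd.DataFrame:
    """Day-in-milk-aligned mean trajectories of cows reaching ``parity``.

    Returns a DataFrame indexed by day in milk (0-based) with one column
    per requested channel, averaged over qualifying cows still in that
    lactation on the given day.
    """
    if parity >= result.calving_day.shape[1]:
        raise EmptyResult(f"no cow reached parity {parity}")
    cows = np.where(result.calving_day[:, parity] >= 0)[0]
    if cows.size == 0:
        raise EmptyResult(f"no cow reached parity {parity}")
    acc = {c: np.full((max_dim, cows.size), np.nan) for c in channels}
    for j, i in enumerate(cows):
        start, end = result.lactation_window(i, parity)
        m = min(end - start, max_dim)
        for c in channels:
            acc[c][:m, j] = result.traj[c][start:start + m, i]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN late days
        data = {c: np.nanmean(acc[c], axis=1) for c in channels}
    df = pd.DataFrame(data)
    df.index.name = "day_in_milk"
    return df
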