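"""Stochastic overlapping-generation dairy breeding scheme.

A closed breeding nucleus of ``n_cows`` females in ``n_herds`` herds is
selected each year by truncation on a total merit index (TMI) of estimated
breeding values, with pseudo-genomic selection:

* true breeding values (TBVs) for the 10-trait panel follow the
  infinitesimal model (mid-parent plus multivariate Mendelian sampling of
  covariance half the additive covariance);
* direct genomic values (DGVs) are modelled as four additional polygenic
  pseudo-traits of heritability 0.99 whose genetic correlation with the
  underlying trait equals the accuracy of genomic prediction, and are
  recorded on genotyped calves only;
* breeding values are estimated by multi-trait animal-model BLUP
  (Henderson's mixed-model equations with the pedigree-based A-inverse),
  evaluating a sliding window of recent birth cohorts plus their parents;
* each year the best young males are kept as sires for one year, each herd
  retains its best females aged 1-5 as dams, and the best young heifers
  are multiplied by MOET; matings are at random.

Everything is expressed on the genetic-standard-deviation scale (TBVs have
unit variance in the base population), so annual genetic trends are
directly comparable across traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .quantgen import (GOAL_TRAITS, GOAL_TRAIT_ALIASES, TRAIT_PANEL,
                       BreedingGoal, GeneticParameters,
                       bend_correlation_matrix)

#: traits with a direct genomic value, and the default GEBV accuracies
DGV_TRAITS = ("BasAcq", "Milk_HS", "DMI_HS", "IFC_HS", "LactAll")
# BWcalv1 == BasAcq and Lact_Eff == LactAll.  The efficiency DGV accuracy
# follows from the same cow reference that carries the feed-intake
# phenotypes (efficiency is their ratio), at the same accuracy as DMI.
DEFAULT_ACCURACIES = {"BasAcq": 0.68, "Milk_HS": 0.68,
                      "DMI_HS": 0.60, "IFC_HS": 0.58, "LactAll": 0.60}

#: traits recorded on breeding cows (no own feed-intake/efficiency records)
RECORDED_TRAITS = ("BasAcq", "Milk_HS", "IFC_HS")  # BWcalv1, Milk, IFC

AA_IDX = (0, 1, 2, 3)


class SchemeError(RuntimeError):
    pass


@dataclass
class SchemeConfig:
    """Structure of the breeding nucleus (reference values in brackets)."""

    n_cows: int = 20_000
    n_herds: int = 200
    n_sires_per_year: int = 100
    n_genotyped_per_sex: int = 4_000
    n_moet_heifers: int = 400
    flushes: int = 2
    offspring_per_mating: int = 3
    female_max_age: int = 5          # dams selected at ages 1-5
    horizon_years: int = 30
    burn_in_years: int = 20
    replicates: int = 30
    dgv_h2: float = 0.99
    accuracies: dict = field(default_factory=lambda: dict(DEFAULT_ACCURACIES))
    eval_window_cohorts: int = 6     # birth cohorts evaluated by BLUP
    selection: str = "ebv"           # "ebv" or "random" (null scheme)

    def __post_init__(self):
        if self.burn_in_years >= self.horizon_years:
            raise SchemeError("burn_in must be < horizon")
        for name in ("n_cows", "n_herds", "n_sires_per_year",
                     "n_genotyped_per_sex", "n_moet_heifers"):
            if getattr(self, name) <= 0:
                raise SchemeError(f"{name} must be positive")
        if self.n_cows % self.n_herds:
            raise SchemeError("n_cows must be divisible by n_herds")

    @property
    def herd_size(self) -> int:
        return self.n_cows // self.n_herds

    def scaled(self, n_cows: int, n_herds: int | None = None) -> "SchemeConfig":
        """Proportionally scaled-down copy (desk preset helper)."""
        f = n_cows / self.n_cows
        return replace(
            self, n_cows=n_cows,
            n_herds=n_herds or max(2, round(self.n_herds * f)),
            n_sires_per_year=max(2, round(self.n_sires_per_year * f)),
            n_genotyped_per_sex=max(4, round(self.n_genotyped_per_sex * f)),
            n_moet_heifers=max(1, round(self.n_moet_heifers * f)),
        )


DESK_CONFIG = SchemeConfig(
    n_cows=2_000, n_herds=20, n_sires_per_year=10, n_genotyped_per_sex=400,
    n_moet_heifers=40, horizon_years=20, burn_in_years=10, replicates=5)


@dataclass
class SchemeResult:
    """Replicate-mean outcome of the breeding scheme.

    ``annual_gain`` has one row per panel trait (genetic-SD units per
    year); ``aa_response`` restricts to the four AA input traits;
    ``alpha`` is the post-burn-in within-cohort genetic-variance retention
    of the AA traits; rates and intervals are replicate means with their
    per-replicate values kept in ``replicates``.
    """

    goal: str
    annual_gain: pd.Series
    aa_response: pd.Series
    alpha: pd.Series
    inbreeding_rate_pct: float
    generation_interval: float
    replicates: pd.DataFrame

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index_label="replicate")


# ---------------------------------------------------------------------------
# genetic covariance construction


def build_scheme_correlations(params: GeneticParameters,
                              accuracies: dict | None = None,
                              dgv_h2: float = 0.99):
    """Extend the bent panel correlation matrix with the DGV pseudo-traits.

    Returns (trait names incl. DGVs, genetic correlation matrix, h2 vector).
    The DGV of trait t is a*u_t plus an independent polygenic remainder, so
    cor(DGV_t, u_s) = a_t * cor(t, s) and cor(DGV_t, DGV_s) = a_t a_s
    cor(t, s).
    """
    acc = dict(DEFAULT_ACCURACIES if accuracies is None else accuracies)
    base = bend_correlation_matrix(params.genetic_corr).to_numpy()
    names = list(params.trait_names)
    t_idx = [names.index(t) for t in DGV_TRAITS]
    a = np.array([acc[t] for t in DGV_TRAITS])
    n0, nd = len(names), len(DGV_TRAITS)
    g = np.eye(n0 + nd)
    g[:n0, :n0] = base
    for i, (ti, ai) in enumerate(zip(t_idx, a)):
        g[n0 + i, :n0] = ai * base[ti, :]
        g[:n0, n0 + i] = g[n0 + i, :n0]
        for j, (tj, aj) in enumerate(zip(t_idx, a)):
            if i != j:
                g[n0 + i, n0 + j] = ai * aj * base[ti, tj]
    dgv_names = [f"DGV_{t}" for t in DGV_TRAITS]
    # floor away degenerate heritabilities (a clamped-to-zero sire variance
    # would make the residual variance of the record infinite)
    h2 = np.concatenate([np.clip(params.h2.reindex(names).to_numpy(),
                                 0.005, 0.995),
                         np.full(nd, dgv_h2)])
    return names + dgv_names, g, h2


# ---------------------------------------------------------------------------
# public sampling operations


def sample_offspring_tbv(sire_tbv: np.ndarray, dam_tbv: np.ndarray,
                         G: np.ndarray, rng) -> np.ndarray:
    """Offspring TBVs: mid-parent plus Mendelian sampling ~ N(0, G/2)."""
    sire_tbv = np.atleast_2d(sire_tbv)
    dam_tbv = np.atleast_2d(dam_tbv)
    G = np.asarray(G, float)
    if np.allclose(G, 0.0):
        chol = np.zeros_like(G)
    else:
        chol = np.linalg.cholesky(G)
    z = rng.standard_normal(sire_tbv.shape)
    ms = z @ (chol.T * np.sqrt(0.5))
    return 0.5 * (sire_tbv + dam_tbv) + ms


def sample_dgv(tbv: np.ndarray, accuracy: float, rng) -> np.ndarray:
    """Direct genomic values correlated ``accuracy`` with the TBVs."""
    if not 0.0 <= accuracy <= 1.0:
        raise SchemeError("accuracy must be in [0, 1]")
    tbv = np.asarray(tbv, float)
    z = rng.standard_normal(tbv.shape)
    return accuracy * tbv + np.sqrt(1.0 - accuracy ** 2) * z


# ---------------------------------------------------------------------------
# pedigree utilities


def a_inverse(sire: np.ndarray, dam: np.ndarray) -> sp.csr_matrix:
    """Henderson's A-inverse (ignoring inbreeding) for 0-based parent
    indices, -1 = unknown."""
    n = sire.size
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    anim = np.arange(n)
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & ~both
    one_d = (dam >= 0) & ~both
    none = (sire < 0) & (dam < 0)

    add(anim[none], anim[none], np.ones(none.sum()))
    for par, mask in ((sire, one_s), (dam, one_d)):
        a, p = anim[mask], par[mask]
        add(a, a, np.full(a.size, 4.0 / 3.0))
        add(a, p, np.full(a.size, -2.0 / 3.0))
        add(p, a, np.full(a.size, -2.0 / 3.0))
        add(p, p, np.full(a.size, 1.0 / 3.0))
    a, s, d = anim[both], sire[both], dam[both]
    add(a, a, np.full(a.size, 2.0))
    for p in (s, d):
        add(a, p, np.full(a.size, -1.0))
        add(p, a, np.full(a.size, -1.0))
        add(p, p, np.full(a.size, 0.5))
    add(s, d, np.full(a.size, 0.5))
    add(d, s, np.full(a.size, 0.5))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def kinship_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Exact additive-relationship matrix A by the tabular method.

    O(n^2) memory -- intended for small pedigrees (test oracles, desk
    diagnostics).  Parents must precede offspring.
    """
    n = sire.size
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        ks = a[s, :i] if s >= 0 else 0.0
        kd = a[d, :i] if d >= 0 else 0.0
        a[i, :i] = 0.5 * (np.asarray(ks) + np.asarray(kd))
        a[:i, i] = a[i, :i]
        f = 0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + f
    return a


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray,
                            rng=None, n_drops: int = 128) -> np.ndarray:
    """Pedigree inbreeding coefficients by gene-dropping Monte Carlo.

    Two alleles per founder are dropped through the pedigree ``n_drops``
    times; F_i is the proportion of drops in which animal i receives two
    copies identical by descent.  Per-animal values carry Monte-Carlo
    noise of SD <= 0.5/sqrt(n_drops), which averages out in the cohort
    means used for the annual inbreeding rate.  Parents must precede
    offspring.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = sire.size
    pat = np.empty((n, n_drops), dtype=np.int64)
    mat = np.empty((n, n_drops), dtype=np.int64)
    next_allele = 0
    coin = rng.integers(0, 2, size=(n, 2, n_drops), dtype=np.int64)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0:
            pat[i] = np.where(coin[i, 0] == 0, pat[s], mat[s])
        else:
            pat[i] = next_allele
            next_allele += 1
        if d >= 0:
            mat[i] = np.where(coin[i, 1] == 0, pat[d], mat[d])
        else:
            mat[i] = next_allele
            next_allele += 1
    return (pat == mat).mean(axis=1)


# ---------------------------------------------------------------------------
# multi-trait BLUP (Henderson's mixed-model equations)


def _pattern_blocks(records):
    """Group record events by their observed-trait pattern.

    ``records``: list of (trait_tuple, animal_idx array, group_idx array,
    values (m, k) array).  Returned unchanged; helper kept for clarity.
    """
    return records


def _assemble_mme(n_animals: int, sire: np.ndarray, dam: np.ndarray,
                  events, G: np.ndarray, R: np.ndarray,
                  n_groups: int = 0):
    """Build the sparse MME for a multi-trait animal model.

    Unknown ordering: [fixed effects (group x trait, if n_groups > 0),
    animal breeding values (animal-major, trait-minor)].  ``events`` is a
    list of (traits tuple, animal indices, group indices, values array)
    blocks; residuals are correlated within an event per the corresponding
    submatrix of ``R`` and independent across events.
    """
    t = G.shape[0]
    ginv = np.linalg.inv(G)
    n_fix = n_groups * t
    dim = n_fix + n_animals * t

    rows, cols, vals = [], [], []
    rhs = np.zeros(dim)

    def u_idx(an, tr):
        return n_fix + an * t + tr

    def f_idx(gr, tr):
        return gr * t + tr

    for traits, anim, grp, y in events:
        k = len(traits)
        rinv = np.linalg.inv(R[np.ix_(traits, traits)])
        m = anim.size
        for a_i, ta in enumerate(traits):
            rhs_rows_u = u_idx(anim, ta)
            for b_i, tb in enumerate(traits):
                w = rinv[a_i, b_i]
                # Z'R-1Z
                rows.append(u_idx(anim, ta))
                cols.append(u_idx(anim, tb))
                vals.append(np.full(m, w))
                np.add.at(rhs, rhs_rows_u, w * y[:, b_i])
                if n_groups:
                    # X'R-1X, X'R-1Z, Z'R-1X
                    rows.append(f_idx(grp, ta))
                    cols.append(f_idx(grp, tb))
                    vals.append(np.full(m, w))
                    rows.append(f_idx(grp, ta))
                    cols.append(u_idx(anim, tb))
                    vals.append(np.full(m, w))
                    rows.append(u_idx(anim, ta))
                    cols.append(f_idx(grp, tb))
                    vals.append(np.full(m, w))
            if n_groups:
                np.add.at(rhs, f_idx(grp, ta), rinv[a_i].dot(y.T))

    # A-inverse (x) G-inverse
    ainv = a_inverse(sire, dam).tocoo()
    ti, tj = np.meshgrid(np.arange(t), np.arange(t), indexing="ij")
    ti, tj = ti.ravel(), tj.ravel()
    gv = ginv[ti, tj]
    keep = gv != 0.0
    ti, tj, gv = ti[keep], tj[keep], gv[keep]
    rows.append((n_fix + ainv.row[:, None] * t + ti[None, :]).ravel())
    cols.append((n_fix + ainv.col[:, None] * t + tj[None, :]).ravel())
    vals.append((ainv.data[:, None] * gv[None, :]).ravel())

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    mme = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    return mme, rhs


def _solve_mme(mme, rhs, x0=None, tol=1e-8, n_fix=0, block=1):
    """Solve the (symmetric positive semi-definite) MME.

    Conjugate gradients with a block-Jacobi preconditioner (one block per
    animal across its trait equations, which tames the multi-trait
    coupling) and an optional warm start; falls back to a direct sparse
    solve if CG stalls.
    """
    diag = mme.diagonal()
    diag[diag <= 0] = 1.0
    if block > 1 and (mme.shape[0] - n_fix) % block == 0:
        n_anim = (mme.shape[0] - n_fix) // block
        coo = mme.tocoo()
        r, c, v = coo.row, coo.col, coo.data
        m = (r >= n_fix) & (c >= n_fix) \
            & ((r - n_fix) // block == (c - n_fix) // block)
        blocks = np.zeros((n_anim, block, block))
        np.add.at(blocks, ((r[m] - n_fix) // block,
                           (r[m] - n_fix) % block,
                           (c[m] - n_fix) % block), v[m])
        inv_blocks = np.linalg.inv(blocks)
        inv_fix = 1.0 / diag[:n_fix]

        def apply_m(v):
            out = np.empty_like(v)
            out[:n_fix] = inv_fix * v[:n_fix]
            out[n_fix:] = np.einsum(
                "nij,nj->ni", inv_blocks,
                v[n_fix:].reshape(n_anim, block)).ravel()
            return out

        pre = spla.LinearOperator(mme.shape, matvec=apply_m)
    else:
        pre = sp.diags(1.0 / diag)
    x, info = spla.cg(mme, rhs, x0=x0, rtol=tol, maxiter=2000, M=pre)
    if info != 0:
        try:
            x = spla.spsolve(mme.tocsc(), rhs)
        except RuntimeError as exc:  # singular block
            raise SchemeError(f"MME solve failed: {exc}") from exc
    return x


def blup_evaluate(pedigree: pd.DataFrame, phenotypes: pd.DataFrame,
                  G: pd.DataFrame, R: pd.DataFrame,
                  known_means: pd.Series | None = None) -> pd.DataFrame:
    """Multi-trait pedigree BLUP of breeding values.

    Parameters
    ----------
    pedigree : DataFrame
        Columns ``animal_id, sire_id, dam_id`` (0 = unknown), parents
        listed before offspring.
    phenotypes : DataFrame
        One row per animal (indexed by animal id), one column per trait;
        NaN = not recorded.  Animals without records are evaluated too.
    G, R : DataFrame
        Genetic and residual covariance matrices over the trait columns.
    known_means : Series, optional
        If given, phenotypes are deviated from these known trait means and
        no fixed effects are fitted; otherwise one overall mean per trait
        is estimated.

    Returns
    -------
    DataFrame of EBVs indexed by animal id.
    """
    ids = pedigree["animal_id"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    sire = np.array([pos.get(s, -1) for s in pedigree["sire_id"]])
    dam = np.array([pos.get(d, -1) for d in pedigree["dam_id"]])
    traits = list(phenotypes.columns)
    gm = G.loc[traits, traits].to_numpy(float)
    rm = R.loc[traits, traits].to_numpy(float)

    y = phenotypes.copy()
    if known_means is not None:
        y = y - known_means.reindex(traits)
        n_groups = 0
    else:
        n_groups = 1

    events = []
    obs = y.notna().to_numpy()
    anim_idx = np.array([pos[a] for a in y.index])
    patterns = {}
    for r in range(len(y)):
        key = tuple(np.where(obs[r])[0])
        if key:
            patterns.setdefault(key, []).append(r)
    for key, rows_ in patterns.items():
        rows_ = np.asarray(rows_)
        events.append((key, anim_idx[rows_], np.zeros(rows_.size, dtype=int),
                       y.to_numpy()[np.ix_(rows_, list(key))]))

    mme, rhs = _assemble_mme(len(ids), sire, dam, events, gm, rm,
                             n_groups=n_groups)
    sol = _solve_mme(mme, rhs)
    nf = n_groups * len(traits)
    ebv = sol[nf:].reshape(len(ids), len(traits))
    return pd.DataFrame(ebv, index=ids, columns=traits)


# ---------------------------------------------------------------------------
# the breeding scheme


#: evaluation panel: traits carrying records or needed for the TMI
EVAL_TRAITS = ("BasAcq", "LactAll", "Milk_HS", "DMI_HS", "IFC_HS",
               "DGV_BasAcq", "DGV_Milk_HS", "DGV_DMI_HS", "DGV_IFC_HS",
               "DGV_LactAll")
#: goal trait -> position in EVAL_TRAITS
_GOAL_TO_EVAL = {"BWcalv1": 0, "Lact_Eff": 1, "Milk": 2, "DMI": 3, "IFC": 4}


def _eval_matrices(params: GeneticParameters, config: SchemeConfig):
    """G (14x14, sigma_g = 1), its eval-subset, residual covariance of the
    eval panel, and the Cholesky factor for TBV sampling."""
    names14, g14, h2 = build_scheme_correlations(params, config.accuracies,
                                                 config.dgv_h2)
    idx = [names14.index(t) for t in EVAL_TRAITS]
    g_eval = g14[np.ix_(idx, idx)]
    sd_e = np.sqrt((1.0 - h2) / h2)
    r_eval = np.diag(sd_e[idx] ** 2)
    # residual correlation between the jointly recorded Milk and IFC
    base_names = list(params.trait_names)
    re_mi = params.residual_corr.loc["Milk_HS", "IFC_HS"]
    i_m, i_i = EVAL_TRAITS.index("Milk_HS"), EVAL_TRAITS.index("IFC_HS")
    r_eval[i_m, i_i] = r_eval[i_i, i_m] = re_mi * sd_e[idx][i_m] * sd_e[idx][i_i]
    chol14 = np.linalg.cholesky(g14)
    return names14, g14, chol14, np.array(idx), g_eval, r_eval, sd_e


def _goal_eval_weights(goal: BreedingGoal) -> np.ndarray:
    w = np.zeros(len(EVAL_TRAITS))
    for t, wt in goal.weights.items():
        w[_GOAL_TO_EVAL[t]] = wt
    return w


def _replicate(config: SchemeConfig, params: GeneticParameters,
               goal: BreedingGoal, rng: np.random.Generator) -> dict:
    names14, g14, chol14, eval_idx, g_eval, r_eval, sd_e = \
        _eval_matrices(params, config)
    n_panel = len(TRAIT_PANEL)
    n_ev = len(EVAL_TRAITS)
    w_eval = _goal_eval_weights(goal)
    dgv_cols = np.array([names14.index(f"DGV_{t}") for t in DGV_TRAITS])
    sd_dgv = sd_e[dgv_cols]
    i_bw_ev, i_milk_ev, i_ifc_ev = 0, 2, 4
    sd_bw = sd_e[names14.index("BasAcq")]
    sd_milk = sd_e[names14.index("Milk_HS")]
    sd_ifc = sd_e[names14.index("IFC_HS")]
    re_mi = float(params.residual_corr.loc["Milk_HS", "IFC_HS"])
    chol_mi = np.linalg.cholesky(
        np.array([[sd_milk ** 2, re_mi * sd_milk * sd_ifc],
                  [re_mi * sd_milk * sd_ifc, sd_ifc ** 2]]))

    nc, nh = config.n_cows, config.n_herds
    herd_size = config.herd_size
    horizon = config.horizon_years

    # --- founders ---------------------------------------------------------
    n_f0 = config.n_sires_per_year + nc
    tbv = [rng.standard_normal((n_f0, len(names14))) @ chol14.T]
    sire = [np.full(n_f0, -1, np.int64)]
    dam = [np.full(n_f0, -1, np.int64)]
    sex = [np.concatenate([np.zeros(config.n_sires_per_year, np.int8),
                           np.ones(nc, np.int8)])]  # 0 = male
    by = [np.concatenate([np.full(config.n_sires_per_year, -2, np.int64),
                          -1 - rng.integers(0, config.female_max_age, nc)])]
    herd = [np.concatenate([np.full(config.n_sires_per_year, -1, np.int64),
                            np.repeat(np.arange(nh), herd_size)])]
    par_age = [np.full(n_f0, np.nan)]   # mean parental age at own birth
    became_parent = [np.zeros(n_f0, bool)]

    current_sires = np.arange(config.n_sires_per_year)
    in_herd = np.zeros(n_f0, bool)
    in_herd[config.n_sires_per_year:] = True
    moet_set = np.empty(0, np.int64)

    ebv = np.zeros((n_f0, n_ev))
    tmi = np.zeros(n_f0)
    genotyped = np.zeros(n_f0, bool)

    rec_bw = []      # (anim, year, value)
    rec_mi = []      # (anim, year, milk, ifc)
    rec_dgv = []     # (anim, year, 4 values)

    cohort_mean = np.zeros((horizon, n_panel))
    cohort_var = np.zeros((horizon, len(AA_IDX)))

    def cat(parts):
        return np.concatenate(parts)

    n_total = n_f0
    for y in range(horizon):
        tbv_all = cat(tbv)
        by_all = cat(by)
        sex_all = cat(sex)
        herd_all = cat(herd)

        # --- matings and births ------------------------------------------
        dams_pool = np.where(in_herd)[0]
        if dams_pool.size == 0 or current_sires.size == 0:
            raise SchemeError("no parents available")
        n_moet_births = min(moet_set.size * config.flushes
                            * config.offspring_per_mating, nc)
        regular_pool = np.setdiff1d(dams_pool, moet_set)
        n_regular = nc - n_moet_births
        if regular_pool.size < n_regular:
            raise SchemeError("not enough dams")
        reg_dams = rng.choice(regular_pool, n_regular, replace=False)
        if moet_set.size:
            flush_dams = np.repeat(moet_set, config.flushes)
            flush_sires = rng.choice(current_sires, flush_dams.size)
            moet_dams = np.repeat(flush_dams, config.offspring_per_mating)[:n_moet_births]
            moet_sires = np.repeat(flush_sires, config.offspring_per_mating)[:n_moet_births]
        else:
            moet_dams = moet_sires = np.empty(0, np.int64)
        dam_y = np.concatenate([reg_dams, moet_dams])
        sire_y = np.concatenate([rng.choice(current_sires, n_regular), moet_sires])

        z = rng.standard_normal((nc, len(names14)))
        tbv_y = 0.5 * (tbv_all[sire_y] + tbv_all[dam_y]) \
            + z @ (chol14.T * np.sqrt(0.5))
        sex_y = rng.integers(0, 2, nc).astype(np.int8)  # 1 = female
        herd_y = np.where(sex_y == 1, rng.integers(0, nh, nc), -1)
        ages = 0.5 * ((y - by_all[sire_y]) + (y - by_all[dam_y]))

        idx_y = np.arange(n_total, n_total + nc)
        n_total += nc
        tbv.append(tbv_y)
        sire.append(sire_y)
        dam.append(dam_y)
        sex.append(sex_y)
        by.append(np.full(nc, y, np.int64))
        herd.append(herd_y)
        par_age.append(ages)
        became_parent.append(np.zeros(nc, bool))
        bp_all = cat(became_parent)
        bp_all[sire_y] = True
        bp_all[dam_y] = True
        became_parent = [bp_all]

        ebv = np.vstack([ebv, np.zeros((nc, n_ev))])
        tmi = np.concatenate([tmi, np.zeros(nc)])
        in_herd = np.concatenate([in_herd, np.zeros(nc, bool)])
        genotyped = np.concatenate([genotyped, np.zeros(nc, bool)])

        cohort_mean[y] = tbv_y[:, :n_panel].mean(axis=0)
        cohort_var[y] = tbv_y[:, AA_IDX].var(axis=0, ddof=1)

        # --- genotyping preselection on parent-average index --------------
        pa = 0.5 * (tmi[sire_y] + tmi[dam_y])
        geno = []
        for s_val in (0, 1):
            cand = idx_y[sex_y == s_val]
            k = min(config.n_genotyped_per_sex, cand.size)
            if config.selection == "random" or np.allclose(pa, pa[0]):
                pick = rng.choice(cand, k, replace=False)
            else:
                order = np.argsort(-pa[cand - idx_y[0]])
                pick = cand[order[:k]]
            geno.append(pick)
        geno = np.concatenate(geno)
        genotyped[geno] = True
        tbv_all = cat(tbv)
        dgv_vals = tbv_all[np.ix_(geno, dgv_cols)] \
            + rng.standard_normal((geno.size, dgv_cols.size)) * sd_dgv
        rec_dgv.append((geno, np.full(geno.size, y), dgv_vals))

        # --- phenotype recording on breeding cows -------------------------
        by_all = cat(by)
        cows = np.where(in_herd)[0]
        cows = cows[cows < idx_y[0]]          # this year's calves excluded
        if cows.size:
            age = y - by_all[cows]
            first = cows[age == 2]
            if first.size:
                vals = tbv_all[first, 0] + rng.standard_normal(first.size) * sd_bw
                rec_bw.append((first, np.full(first.size, y), vals))
            e = rng.standard_normal((cows.size, 2)) @ chol_mi.T
            milk_v = tbv_all[cows, names14.index("Milk_HS")] + e[:, 0]
            ifc_v = tbv_all[cows, names14.index("IFC_HS")] + e[:, 1]
            rec_mi.append((cows, np.full(cows.size, y), milk_v, ifc_v))

        # --- evaluation ----------------------------------------------------
        if config.selection == "ebv":
            ebv, tmi = _evaluate(config, y, cat(sire), cat(dam), by_all,
                                 rec_bw, rec_mi, rec_dgv, g_eval, r_eval,
                                 ebv, w_eval)

        # --- selection for next year ---------------------------------------
        # sires: the best genotyped 1-year-old males, used for one year
        # (their calves are born when they are 2)
        sex_all = cat(sex)
        herd_all = cat(herd)
        by_all = cat(by)
        all_idx = np.arange(n_total)
        sire_by = y - 1 if y >= 1 else 0
        geno_males = all_idx[(sex_all == 0) & (by_all == sire_by) & genotyped]
        if geno_males.size < config.n_sires_per_year:
            raise SchemeError("not enough genotyped young males")
        if config.selection == "random":
            current_sires = rng.choice(geno_males, config.n_sires_per_year,
                                       replace=False)
        else:
            order = np.argsort(-tmi[geno_males])
            current_sires = geno_males[order[:config.n_sires_per_year]]

        # dams: each herd keeps its best females aged 1-5 (new heifers are
        # last year's calves); unselected females leave the herd for good
        new_in_herd = np.zeros_like(in_herd)
        female = sex_all == 1
        age_sel = y - by_all
        cand_mask = female & (age_sel >= 1) & (age_sel <= config.female_max_age) \
            & (in_herd | (by_all == y - 1))
        for h in range(nh):
            cand = all_idx[cand_mask & (herd_all == h)]
            if cand.size < herd_size:
                raise SchemeError(f"herd {h} short of candidates")
            if config.selection == "random":
                keep = rng.choice(cand, herd_size, replace=False)
            else:
                keep = cand[np.argsort(-tmi[cand])[:herd_size]]
            new_in_herd[keep] = True
        in_herd = new_in_herd

        # MOET: the best heifers in the population, flushed next year
        heifers = all_idx[in_herd & (by_all == y - 1)]
        k = min(config.n_moet_heifers, heifers.size)
        if config.selection == "random":
            moet_set = rng.choice(heifers, k, replace=False) if k else heifers
        else:
            moet_set = heifers[np.argsort(-tmi[heifers])[:k]]

    # --- summaries -------------------------------------------------------
    years = np.arange(horizon)
    post = years >= config.burn_in_years
    x = years[post]
    gains = {}
    for j, t in enumerate(TRAIT_PANEL):
        gains[t] = float(np.polyfit(x, cohort_mean[post, j], 1)[0])
    alpha = {TRAIT_PANEL[j]: float(cohort_var[post, i].mean())
             for i, j in enumerate(AA_IDX)}

    sire_all, dam_all, by_all = cat(sire), cat(dam), cat(by)
    f = inbreeding_coefficients(sire_all, dam_all, rng)
    fbar = np.array([f[by_all == yy].mean() for yy in years])
    dfr = (fbar[1:] - fbar[:-1]) / (1.0 - fbar[:-1])
    dF = float(dfr[post[1:]].mean() * 100.0)

    bp = cat(became_parent)
    pa_all = cat(par_age)
    sel_off = bp & np.isin(by_all, x)
    gen_int = float(np.nanmean(pa_all[sel_off]))

    out = {f"gain_{t}": g for t, g in gains.items()}
    out.update({f"alpha_{t}": a for t, a in alpha.items()})
    out["inbreeding_rate_pct"] = dF
    out["generation_interval"] = gen_int
    return out


def _evaluate(config, y, sire_all, dam_all, by_all, rec_bw, rec_mi, rec_dgv,
              g_eval, r_eval, ebv, w_eval):
    """Sliding-window multi-trait BLUP; returns updated (ebv, tmi)."""
    lo = y - config.eval_window_cohorts + 1
    member = by_all >= lo
    # include parents of members (with unknown grandparents)
    memb_idx = np.where(member)[0]
    parents = np.unique(np.concatenate([sire_all[memb_idx], dam_all[memb_idx]]))
    parents = parents[parents >= 0]
    member[parents] = True
    g_idx = np.where(member)[0]
    local = -np.ones(by_all.size, np.int64)
    local[g_idx] = np.arange(g_idx.size)

    s_loc = np.where(member[np.clip(sire_all[g_idx], 0, None)] & (sire_all[g_idx] >= 0),
                     local[np.clip(sire_all[g_idx], 0, None)], -1)
    d_loc = np.where(member[np.clip(dam_all[g_idx], 0, None)] & (dam_all[g_idx] >= 0),
                     local[np.clip(dam_all[g_idx], 0, None)], -1)

    events = []
    y_min = max(0, lo)
    n_groups = y - y_min + 1

    def grp(yr):
        return np.clip(yr - y_min, 0, n_groups - 1)

    for anim, yr, vals in rec_bw:
        keep = local[anim] >= 0
        if keep.any():
            events.append(((0,), local[anim[keep]], grp(yr[keep]),
                           vals[keep, None]))
    for anim, yr, milk_v, ifc_v in rec_mi:
        keep = local[anim] >= 0
        if keep.any():
            events.append(((2, 4), local[anim[keep]], grp(yr[keep]),
                           np.column_stack([milk_v[keep], ifc_v[keep]])))
    dgv_pattern = tuple(range(5, 5 + len(DGV_TRAITS)))
    for anim, yr, vals in rec_dgv:
        keep = local[anim] >= 0
        if keep.any():
            events.append((dgv_pattern, local[anim[keep]], grp(yr[keep]),
                           vals[keep]))

    mme, rhs = _assemble_mme(g_idx.size, s_loc, d_loc, events, g_eval,
                             r_eval, n_groups=n_groups)
    nf = n_groups * g_eval.shape[0]
    x0 = np.concatenate([np.zeros(nf), ebv[g_idx].ravel()])
    # ranking-grade tolerance: selection decisions are insensitive to
    # EBV errors of ~1e-4 genetic SD
    sol = _solve_mme(mme, rhs, x0=x0, tol=2e-5, n_fix=nf,
                     block=g_eval.shape[0])
    ebv_loc = sol[nf:].reshape(g_idx.size, g_eval.shape[0])
    ebv[g_idx] = ebv_loc
    tmi = ebv @ w_eval
    return ebv, tmi


def run_scheme(config: SchemeConfig, params: GeneticParameters,
               goal: BreedingGoal, rng_seed: int = 0) -> SchemeResult:
    """Run the breeding scheme for one goal and average over replicates.

    Annual genetic gains are the regression of cohort-mean TBVs on birth
    year over the post-burn-in years, in genetic-SD units.
    """
    rows = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, rep]))
        rows.append(_replicate(config, params, goal, rng))
    reps = pd.DataFrame(rows)
    mean = reps.mean()
    gains = pd.Series({t: mean[f"gain_{t}"] for t in TRAIT_PANEL})
    aa = gains.iloc[list(AA_IDX)]
    alpha = pd.Series({t: mean[f"alpha_{t}"]
                       for t in np.array(TRAIT_PANEL)[list(AA_IDX)]})
    return SchemeResult(
        goal=goal.name,
        annual_gain=gains,
        aa_response=aa,
        alpha=alpha,
        inbreeding_rate_pct=float(mean["inbreeding_rate_pct"]),
        generation_interval=float(mean["generation_interval"]),
        replicates=reps,
    )
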