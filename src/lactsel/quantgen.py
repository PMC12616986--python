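"""Deterministic quantitative-genetics toolkit.

Variance-component estimation from the paternal half-sib design, matrix
bending, total-merit-index (TMI) correlations, deterministic genomic
accuracy, and the Bulmer heritability update.

The trait panel couples the four acquisition/allocation (AA) input traits
of the bioenergetic cow model with the complex traits they generate in the
non-limiting (HS) and limiting (MS) environments.  Body weight at first
calving is genetically the same trait as basal acquisition, and
third-lactation efficiency the same trait as lactation allocation, so the
panel carries them once (``BWcalv1 -> BasAcq``, ``Lact_Eff -> LactAll``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAIT_PANEL = ("BasAcq", "LactAcq", "f_prio_GS", "LactAll",
               "Milk_HS", "DMI_HS", "IFC_HS", "Milk_MS", "DMI_MS", "IFC_MS")

#: goal traits are expressed in the HS (breeding) environment
GOAL_TRAIT_ALIASES = {"BWcalv1": "BasAcq", "Milk": "Milk_HS", "DMI": "DMI_HS",
                      "IFC": "IFC_HS", "Lact_Eff": "LactAll"}
GOAL_TRAITS = ("BWcalv1", "Milk", "DMI", "IFC", "Lact_Eff")

AA_PANEL_TRAITS = ("BasAcq", "LactAcq", "f_prio_GS", "LactAll")


class ContractViolation(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class GeneticParameters:
    """Heritabilities and genetic/residual correlation matrices of a panel.

    ``genetic_corr`` / ``residual_corr`` are square DataFrames over
    ``trait_names``; ``h2`` a Series.  ``sigma_g`` (genetic SDs in trait
    units) is optional: it is needed to convert standardized responses back
    to trait units but not for index math.
    """

    trait_names: tuple
    h2: pd.Series
    genetic_corr: pd.DataFrame
    residual_corr: pd.DataFrame
    sigma_g: pd.Series | None = None
    sigma_p: pd.Series | None = None

    def __post_init__(self):
        for m in (self.genetic_corr, self.residual_corr):
            _check_correlation(m.to_numpy())

    def goal_genetic_corr(self) -> pd.DataFrame:
        """Genetic correlations over the five breeding-goal traits."""
        idx = [GOAL_TRAIT_ALIASES[t] for t in GOAL_TRAITS]
        sub = self.genetic_corr.loc[idx, idx].to_numpy()
        return pd.DataFrame(sub, index=GOAL_TRAITS, columns=GOAL_TRAITS)

    # -- Table-1 style round trip: h2 on the diagonal, genetic correlations
    #    in the upper triangle, residual correlations in the lower triangle.
    def to_matrix_frame(self) -> pd.DataFrame:
        n = len(self.trait_names)
        m = np.zeros((n, n))
        g = self.genetic_corr.to_numpy()
        r = self.residual_corr.to_numpy()
        iu = np.triu_indices(n, 1)
        il = np.tril_indices(n, -1)
        m[iu] = g[iu]
        m[il] = r[il]
        m[np.diag_indices(n)] = self.h2.to_numpy()
        return pd.DataFrame(m, index=list(self.trait_names),
                            columns=list(self.trait_names))

    def to_csv(self, path) -> None:
        self.to_matrix_frame().to_csv(path, index_label="trait")

    @classmethod
    def from_matrix_frame(cls, frame: pd.DataFrame,
                          sigma_g: pd.Series | None = None) -> "GeneticParameters":
        names = tuple(frame.index)
        m = frame.to_numpy(dtype=float)
        n = len(names)
        h2 = pd.Series(np.diag(m), index=list(names))
        g = np.eye(n)
        r = np.eye(n)
        iu = np.triu_indices(n, 1)
        g[iu] = m[iu]
        g.T[iu] = m[iu]
        il = np.tril_indices(n, -1)
        r[il] = m[il]
        r.T[il] = m[il]
        gdf = pd.DataFrame(g, index=list(names), columns=list(names))
        rdf = pd.DataFrame(r, index=list(names), columns=list(names))
        return cls(names, h2, gdf, rdf, sigma_g)

    @classmethod
    def from_csv(cls, path) -> "GeneticParameters":
        return cls.from_matrix_frame(pd.read_csv(path, index_col="trait"))


@dataclass
class BreedingGoal:
    """Index weights per goal trait, on the genetic-SD scale."""

    name: str
    weights: pd.Series  # indexed by GOAL_TRAITS

    def __post_init__(self):
        self.weights = self.weights.reindex(list(GOAL_TRAITS)).fillna(0.0)
        if not np.any(self.weights.to_numpy() != 0):
            raise ContractViolation("breeding goal needs a nonzero weight")


@dataclass
class GenomicAccuracyInputs:
    """Inputs of the deterministic genomic-accuracy formula."""

    ne: float = 350.0            # effective population size
    genome_length: float = 30.0  # Morgans
    n_markers: int = 38_000
    n_bulls: int = 10_000
    daughters_per_bull: int = 100
    n_cows: int = 50_000         # cows with own performance for the trait
    h2: float = 0.33

    def __post_init__(self):
        for v in (self.ne, self.genome_length, self.n_markers):
            if v <= 0:
                raise ContractViolation("Ne, L and marker count must be > 0")


def load_default_parameters() -> GeneticParameters:
    """The packaged genetic-parameter panel (reference estimates for the
    HS/MS trait set, genetic upper / residual lower / h2 diagonal)."""
    ref = importlib.resources.files("lactsel.data") / "default_genetic_parameters.csv"
    with importlib.resources.as_file(ref) as p:
        return GeneticParameters.from_csv(p)


def load_default_goals() -> dict[str, BreedingGoal]:
    ref = importlib.resources.files("lactsel.data") / "default_breeding_goals.csv"
    with importlib.resources.as_file(ref) as p:
        tbl = pd.read_csv(p, index_col="trait")
    return {g: BreedingGoal(g, tbl[g]) for g in tbl.columns}


# ---------------------------------------------------------------------------
# half-sib variance components


def _check_correlation(m: np.ndarray, tol: float = 1e-8) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ContractViolation("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=tol):
        raise ContractViolation("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-6):
        raise ContractViolation("correlation matrix must have unit diagonal")


def _sire_components(x: np.ndarray, y: np.ndarray, sire: np.ndarray):
    """Method-of-moments sire (co)variance components for one trait pair.

    Returns (sire covariance, within-sire covariance) from the one-way
    ANOVA/ANCOVA decomposition, using only rows where both traits are
    observed.  ``n0`` is the usual unbalanced-design effective family size.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, sire = x[ok], y[ok], sire[ok]
    df = pd.DataFrame({"x": x, "y": y, "s": sire})
    grp = df.groupby("s")
    n_i = grp.size().to_numpy(dtype=float)
    s = n_i.size
    n = float(n_i.sum())
    if s < 2 or n <= s:
        return np.nan, np.nan
    mx = grp["x"].mean().to_numpy()
    my = grp["y"].mean().to_numpy()
    gx, gy = x.mean(), y.mean()
    mcp_between = float(np.sum(n_i * (mx - gx) * (my - gy))) / (s - 1)
    sx = df["s"].map(grp["x"].mean()).to_numpy()
    sy = df["s"].map(grp["y"].mean()).to_numpy()
    mcp_within = float(np.sum((x - sx) * (y - sy))) / (n - s)
    n0 = (n - float(np.sum(n_i ** 2)) / n) / (s - 1)
    cov_sire = (mcp_between - mcp_within) / n0
    return cov_sire, mcp_within


def estimate_variance_components(phenotypes: pd.DataFrame,
                                 pedigree) -> GeneticParameters:
    """Estimate h2 and genetic/residual correlations from half-sib data.

    Parameters
    ----------
    phenotypes : DataFrame
        One row per cow (index = animal id), one column per trait; NaN for
        missing phenotypes (handled pairwise).
    pedigree : Pedigree or DataFrame
        Must map each phenotyped animal to its sire (``animal_id`` /
        ``sire_id`` columns).

    Notes
    -----
    The estimator is the sire-model method of moments (exact ANOVA for the
    balanced paternal half-sib design): ``h2 = 4 s2_sire / (s2_sire +
    s2_within)``, genetic correlations from between-sire cross-covariances
    and residual covariances as within-sire covariance minus three times
    the sire covariance.  Negative sire variances are clamped to zero.
    """
    frame = pedigree.frame if hasattr(pedigree, "frame") else pedigree
    sire_map = frame.set_index("animal_id")["sire_id"]
    sires = phenotypes.index.map(sire_map).to_numpy()
    if np.unique(sires[~pd.isna(sires)]).size < 2:
        raise ContractViolation("need >= 2 sires")

    traits = list(phenotypes.columns)
    k = len(traits)
    vals = phenotypes.to_numpy(dtype=float)
    cov_s = np.full((k, k), np.nan)
    cov_w = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            cs, cw = _sire_components(vals[:, i], vals[:, j], sires)
            cov_s[i, j] = cov_s[j, i] = cs
            cov_w[i, j] = cov_w[j, i] = cw

    var_s = np.diag(cov_s).copy()
    neg = var_s < 0
    if np.any(neg):
        import warnings
        warnings.warn("negative sire variance clamped to 0 for: "
                      + ", ".join(np.array(traits)[neg]))
        var_s[neg] = 0.0
    var_w = np.diag(cov_w)
    h2 = 4.0 * var_s / np.maximum(var_s + var_w, 1e-300)
    h2 = np.clip(h2, 0.0, 1.0)

    def corr_from(cov, var):
        d = np.sqrt(np.maximum(var, 1e-300))
        c = cov / np.outer(d, d)
        c = np.clip(c, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        return c

    g_corr = corr_from(cov_s, var_s)
    cov_e = cov_w - 3.0 * cov_s
    var_e = np.maximum(np.diag(cov_e), 1e-300)
    r_corr = corr_from(cov_e, var_e)

    sigma_g = pd.Series(2.0 * np.sqrt(var_s), index=traits)
    sigma_p = pd.Series(np.sqrt(var_s + var_w), index=traits)
    return GeneticParameters(
        tuple(traits), pd.Series(h2, index=traits),
        pd.DataFrame(g_corr, index=traits, columns=traits),
        pd.DataFrame(r_corr, index=traits, columns=traits),
        sigma_g, sigma_p,
    )


# ---------------------------------------------------------------------------
# bending


def bend_correlation_matrix(R: np.ndarray | pd.DataFrame,
                            eig_floor: float = 1e-4,
                            max_iter: int = 200) -> np.ndarray | pd.DataFrame:
    """Bend a correlation matrix to positive definiteness.

    Eigenvalue bending in its standard form: negative/small eigenvalues are
    floored, the matrix reconstructed and the unit diagonal restored,
    iterating to convergence.  Already-PD input is returned unchanged;
    off-diagonal magnitudes never exceed 1 in the result.
    """
    as_frame = isinstance(R, pd.DataFrame)
    m = R.to_numpy(dtype=float) if as_frame else np.asarray(R, dtype=float)
    _check_correlation(m)
    out = m.copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        if w.min() >= eig_floor * 0.999:
            break
        w = np.maximum(w, eig_floor)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(out, 1.0)
    if as_frame:
        return pd.DataFrame(out, index=R.index, columns=R.columns)
    return out


# ---------------------------------------------------------------------------
# index math


def tmi_trait_correlations(goal: BreedingGoal,
                           G: pd.DataFrame | np.ndarray) -> pd.Series:
    """Correlation between the total merit index and each goal trait.

    With index weights ``w`` on the genetic-SD scale and genetic
    correlation matrix ``G`` over the goal traits,

        cor(TMI, trait_i) = (G w)_i / sqrt(w' G w).
    """
    if isinstance(G, pd.DataFrame):
        names = list(G.index)
        g = G.loc[names, names].to_numpy(dtype=float)
    else:
        names = list(GOAL_TRAITS)
        g = np.asarray(G, dtype=float)
    w = goal.weights.reindex(names).fillna(0.0).to_numpy(dtype=float)
    denom = float(w @ g @ w)
    if denom <= 0:
        raise ContractViolation("undefined TMI variance (check weights / G)")
    return pd.Series(g @ w / np.sqrt(denom), index=names)


def me_segments(ne: float, genome_length: float) -> float:
    """Effective number of independent chromosome segments,
    ``Me = 2 Ne L / ln(4 Ne L)``."""
    if ne <= 0 or genome_length <= 0:
        raise ContractViolation("Ne and L must be > 0")
    nel = ne * genome_length
    return 2.0 * nel / np.log(4.0 * nel)


def _daughter_group_reliability(n: int, h2: float) -> float:
    """Reliability of a daughter-group mean for the sire's breeding value."""
    if n <= 0:
        return 0.0
    t = h2 / 4.0
    return n * t / (1.0 + (n - 1) * t)


def genomic_accuracy(inputs: GenomicAccuracyInputs, *,
                     variant: str = "daetwyler") -> float:
    """Deterministic accuracy of direct genomic values for a candidate
    without own performance.

    Bulls contribute daughter-group-mean reliability, cows own-performance
    reliability (h2); the two sources are combined on the effective-record
    scale (selection-index combination of independent reference sources).
    ``variant`` selects the accuracy formula applied to the aggregate:

    * ``"daetwyler"``: r2 = T / (T + Me) with T the effective records;
    * ``"goddard2009"``: the same T fed through the formula that accounts
      for the distribution of segment effects (stronger shrinkage).

    Both are multiplied by sqrt(q), q = M / (M + Me), the share of genetic
    variance captured by the marker panel.
    """
    me = me_segments(inputs.ne, inputs.genome_length)
    rel_bull = _daughter_group_reliability(inputs.daughters_per_bull, inputs.h2)
    t_eff = inputs.n_bulls * rel_bull + inputs.n_cows * inputs.h2
    if t_eff <= 0:
        return 0.0
    q = inputs.n_markers / (inputs.n_markers + me)
    if variant == "daetwyler":
        r2 = t_eff / (t_eff + me)
    elif variant == "goddard2009":
        lam = me / max(t_eff, 1e-12) * me  # per-segment noise/signal * Me
        n = t_eff
        a = 1.0 + 2.0 * lam / n
        sa = np.sqrt(a)
        r2 = 1.0 - lam / (2.0 * n * sa) * np.log(
            (1.0 + a + 2.0 * sa) / (1.0 + a - 2.0 * sa))
        r2 = float(np.clip(r2, 0.0, 1.0))
    else:
        raise ContractViolation(f"unknown accuracy variant {variant!r}")
    return float(np.sqrt(q * r2))


def bulmer_update(h2: float, alpha: float) -> float:
    """Heritability after directional selection has eroded genetic variance.

    With retention factor ``alpha`` (new genetic variance = alpha * old) and
    unchanged residual variance,

        h2' = alpha / (alpha + (1 - h2) / h2).
    """
    if not 0.0 < h2 < 1.0:
        raise ContractViolation("h2 must be in (0, 1)")
    if not 0.0 < alpha <= 1.0:
        raise ContractViolation("alpha must be in (0, 1]")
    return alpha / (alpha + (1.0 - h2) / h2)
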