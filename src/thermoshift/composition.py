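"""Community-composition change: distances, ANOSIM, PERMANOVA, LR screen.

The resampling machinery here is written directly against its textbook
definitions: Bray-Curtis dissimilarity on count vectors, Clarke's ANOSIM
on the ranks of those dissimilarities, distance-based (Anderson-style)
PERMANOVA partitioning of squared dissimilarities for a year x transect
crossed design, a posteriori one-factor year tests within each transect,
and a per-species univariate Poisson likelihood-ratio screen with the
signed proportional-change summary used to rank winners and losers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with sample labels."""

    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("Bray-Curtis entries must lie in [0, 1]")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        labels = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i)
                  for i in self.ids]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


def bray_curtis(abundance: pd.DataFrame | np.ndarray, ids: list | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d_ij = sum|x-y| / sum(x+y).

    Rows are samples, columns species.  An all-zero sample has no defined
    dissimilarity and raises an error naming it.
    """
    if isinstance(abundance, pd.DataFrame):
        X = abundance.to_numpy(dtype=float)
        if ids is None:
            ids = list(abundance.index)
    else:
        X = np.asarray(abundance, dtype=float)
        if ids is None:
            ids = list(range(X.shape[0]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if (X < 0).any():
        raise ValueError("negative abundance")
    zero = np.where(X.sum(axis=1) == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {[ids[i] for i in zero]}")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = diff / tot
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    """Clarke's R with its one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None = None


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities on the ranks of the dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs and mid-ranks for ties; R near +1 means all
    between-group dissimilarities exceed all within-group ones.  p is the
    one-sided (k+1)/(n_perm+1) proportion of label permutations with
    R >= observed.
    """
    groups = np.asarray(groups)
    n = len(d)
    if len(groups) != n:
        raise ValueError("groups length mismatch")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    iu0, iu1 = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d.values[iu0, iu1])  # mid-ranks
    m = len(ranks)
    within = groups[iu0] == groups[iu1]
    r_obs = _anosim_r(ranks, within, m)

    rng = rng_for(seed, "anosim")
    perms = np.array([rng.permutation(groups) for _ in range(n_perm)])
    w = perms[:, iu0] == perms[:, iu1]
    s_w = w @ ranks
    n_w = w.sum(axis=1)
    r_w = s_w / n_w
    r_b = (ranks.sum() - s_w) / (m - n_w)
    r_null = (r_b - r_w) / (m / 2.0)
    k = int((r_null >= r_obs - 1e-12).sum())
    return AnosimResult(r=float(r_obs), p=float((k + 1) / (n_perm + 1)),
                        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_f: float | None
    p: float | None


@dataclass
class PermanovaResult:
    """Distance-based multivariate ANOVA partition with permutation p."""

    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    seed: int | None = None
    degenerate: bool = False

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t.name, t.df, t.ss, t.pseudo_f, t.p) for t in self.terms]
        rows.append(("residual", self.residual_df, self.residual_ss, None, None))
        rows.append(("total", sum(t.df for t in self.terms) + self.residual_df,
                     self.total_ss, None, None))
        return pd.DataFrame(rows, columns=["term", "df", "ss", "pseudo_f", "p"])


def _ss_within(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """sum over groups of (sum of squared within-group distances)/n_g."""
    return sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in group_idx)


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.where(labels == v)[0] for v in np.unique(labels)]


def permanova(
    d: DistanceMatrix,
    year,
    transect=None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on squared dissimilarities.

    One factor (``year``) or a balanced crossed two-factor design
    (``year`` x ``transect``), both treated as fixed effects with
    unrestricted permutation of sample labels.  The year x transect
    interaction is partitioned only when every cell holds >= 2 replicate
    samples (visits); with one sample per cell it is inestimable and
    omitted.  SS follow the distance-based identity
    SS_total = sum_{i<j} d_ij^2 / n, with within-group terms computed the
    same way per group.
    """
    year = np.asarray(year)
    n = len(d)
    if len(year) != n:
        raise ValueError("year labels length mismatch")
    d2 = d.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    rng = rng_for(seed, "permanova")

    if ss_total <= 1e-12:
        terms = [PermanovaTerm("year", len(np.unique(year)) - 1, 0.0, None, None)]
        if transect is not None:
            terms.append(PermanovaTerm("transect", len(np.unique(transect)) - 1,
                                       0.0, None, None))
        return PermanovaResult(terms=terms, residual_df=0, residual_ss=0.0,
                               total_ss=0.0, n_perm=n_perm, seed=seed, degenerate=True)

    def fit(perm: np.ndarray) -> dict[str, float]:
        """F statistics of each term for a given sample ordering."""
        dp = d2[np.ix_(perm, perm)]
        out = {}
        if transect is None:
            a = len(year_groups)
            ss_w = _ss_within(dp, year_groups)
            ss_a = ss_total - ss_w
            out["year"] = (ss_a / (a - 1)) / (ss_w / (n - a))
            out["_ss"] = {"year": ss_a, "res": ss_w}
            return out
        ss_w_year = _ss_within(dp, year_groups)
        ss_w_tr = _ss_within(dp, tr_groups)
        ss_year = ss_total - ss_w_year
        ss_tr = ss_total - ss_w_tr
        ss_w_cell = _ss_within(dp, cell_groups)
        ss_cell = ss_total - ss_w_cell
        if with_interaction:
            ss_int = ss_cell - ss_year - ss_tr
            ss_res = ss_total - ss_cell
            df_res = n - len(cell_groups)
        else:
            ss_res = ss_total - ss_year - ss_tr
            df_res = n - df_year - df_tr - 1
        ms_res = ss_res / df_res
        out["year"] = (ss_year / df_year) / ms_res
        out["transect"] = (ss_tr / df_tr) / ms_res
        ss = {"year": ss_year, "transect": ss_tr, "res": ss_res}
        if with_interaction:
            out["year:transect"] = (ss_int / df_int) / ms_res
            ss["year:transect"] = ss_int
        out["_ss"] = ss
        return out

    year_groups = _group_indices(year)
    if transect is None:
        identity = np.arange(n)
        obs = fit(identity)
        f_obs = {"year": obs["year"]}
        df_map = {"year": len(year_groups) - 1}
        df_res = n - len(year_groups)
    else:
        transect = np.asarray(transect)
        if len(transect) != n:
            raise ValueError("transect labels length mismatch")
        tr_groups = _group_indices(transect)
        cells = pd.Series(zip(year, transect))
        cell_counts = cells.value_counts()
        expected = {(y, t) for y in np.unique(year) for t in np.unique(transect)}
        missing = sorted(expected - set(cell_counts.index))
        if missing:
            raise ValueError(f"missing design cells: {missing}")
        if cell_counts.nunique() != 1:
            raise ValueError("unbalanced design: unequal samples per year x transect cell")
        cell_labels = cells.astype(str).to_numpy()
        cell_groups = _group_indices(cell_labels)
        df_year = len(year_groups) - 1
        df_tr = len(tr_groups) - 1
        df_int = df_year * df_tr
        with_interaction = int(cell_counts.iloc[0]) >= 2
        identity = np.arange(n)
        obs = fit(identity)
        f_obs = {k: v for k, v in obs.items() if k != "_ss"}
        df_map = {"year": df_year, "transect": df_tr}
        if with_interaction:
            df_map["year:transect"] = df_int
            df_res = n - len(cell_groups)
        else:
            df_res = n - df_year - df_tr - 1

    exceed = {k: 0 for k in f_obs}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fp = fit(perm)
        for k in exceed:
            if fp[k] >= f_obs[k] - 1e-12:
                exceed[k] += 1
    terms = [
        PermanovaTerm(k, df_map[k], obs["_ss"][k], float(f_obs[k]),
                      float((exceed[k] + 1) / (n_perm + 1)))
        for k in f_obs
    ]
    return PermanovaResult(terms=terms, residual_df=df_res,
                           residual_ss=float(obs["_ss"]["res"]),
                           total_ss=float(ss_total), n_perm=n_perm, seed=seed)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_year_within_transect(
    d: DistanceMatrix,
    year,
    transect,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """A posteriori year contrasts within each transect.

    For every transect with >= 2 samples (visits) per year, a one-factor
    permutation test of the year effect is run on that transect's
    sub-matrix; the label permutation is enumerated exhaustively when
    there are at most 500 distinct assignments, and Monte-Carlo sampled
    otherwise.  Unadjusted p-values are reported next to their Holm
    step-down adjustment; transects with a lone sample in some year are
    skipped with a warning.
    """
    year = np.asarray(year)
    transect = np.asarray(transect)
    rows = []
    for t in np.unique(transect):
        sel = np.where(transect == t)[0]
        ylab = year[sel]
        _, counts = np.unique(ylab, return_counts=True)
        if len(counts) < 2 or (counts < 2).any():
            logger.warning("transect %s skipped: fewer than 2 samples in some year", t)
            continue
        sub = DistanceMatrix(d.values[np.ix_(sel, sel)], [d.ids[i] for i in sel])
        n_s = len(sel)
        groups = _group_indices(ylab)
        d2 = sub.values ** 2
        ss_total = d2.sum() / (2.0 * n_s)
        a = len(groups)

        def f_of(idx_groups) -> float:
            ss_w = _ss_within(d2, idx_groups)
            if ss_w <= 1e-12:
                return np.inf if ss_total > 1e-12 else 0.0
            return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n_s - a))

        f_obs = f_of(groups)
        n1 = len(groups[0])
        n_distinct = math.comb(n_s, n1)
        if n_distinct <= 500:
            hits = total = 0
            for combo in itertools.combinations(range(n_s), n1):
                g0 = np.array(combo)
                g1 = np.setdiff1d(np.arange(n_s), g0)
                total += 1
                if f_of([g0, g1]) >= f_obs - 1e-12:
                    hits += 1
            p = hits / total
            method = "exact"
        else:
            rng = rng_for(seed, f"pairwise:{t}")
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(n_s)
                if f_of([perm[g] for g in groups]) >= f_obs - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
            method = "montecarlo"
        rows.append((t, float(f_obs) if np.isfinite(f_obs) else np.inf, p, method))
    out = pd.DataFrame(rows, columns=["transect_id", "pseudo_f", "p", "method"])
    if len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    else:
        out["p_holm"] = []
    return out


# ---------------------------------------------------------------------------
# Per-species Poisson likelihood-ratio screen
# ---------------------------------------------------------------------------

@dataclass
class SpeciesChangeResult:
    """Year effect on one species: Poisson LR, direction and % change."""

    species_id: str | None
    lr: float
    p: float
    direction: int
    pc: float  # proportional change %, NaN when year-1 count is zero
    status: str = "ok"  # "ok" | "colonization"


def poisson_lr_by_species(
    n1: int,
    n2: int,
    exposure1: float = 1.0,
    exposure2: float = 1.0,
    species_id: str | None = None,
) -> SpeciesChangeResult:
    """Likelihood-ratio test of a year effect on one species' counts.

    Two-group Poisson regression with a log link and log-exposure offset
    has the closed-form deviance
    LR = 2 [ n1 ln(r1/r) + n2 ln(r2/r) ] with r_i = n_i/e_i the year rates
    and r the pooled rate (0 ln 0 = 0); p from chi-square with 1 df.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if exposure1 <= 0 or exposure2 <= 0:
        raise ValueError("exposures must be positive")
    if n1 + n2 == 0:
        raise ValueError("both totals are zero; no information")
    r1, r2 = n1 / exposure1, n2 / exposure2
    r = (n1 + n2) / (exposure1 + exposure2)
    lr = 0.0
    if n1 > 0:
        lr += n1 * math.log(r1 / r)
    if n2 > 0:
        lr += n2 * math.log(r2 / r)
    lr *= 2.0
    p = float(stats.chi2.sf(lr, df=1))
    direction = int(np.sign(r2 - r1))
    if n1 > 0:
        pc = proportional_change(n1, n2)
        status = "ok"
    else:
        pc = float("nan")
        status = "colonization"
    return SpeciesChangeResult(species_id=species_id, lr=float(lr), p=p,
                               direction=direction, pc=pc, status=status)


def proportional_change(n1: int, n2: int) -> float:
    """Signed percent change (n2/n1 - 1) x 100 between the survey years."""
    if n1 <= 0:
        raise ValueError("proportional change undefined for n1 = 0 (colonization)")
    return (n2 / n1 - 1.0) * 100.0


def species_change_table(
    survey,
    classification=None,
    year_a: int | None = None,
    year_b: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species LR screen between two years, ranked by percent change.

    Exposure per year is its number of samples (transect-visits), so a
    resurvey with fewer visits is compared on rates, not raw totals.
    Raw p-values (the published convention keeps species with P < 0.05)
    are reported next to their Holm adjustment.
    """
    years = survey.years
    if year_a is None or year_b is None:
        if len(years) != 2:
            raise ValueError("pass year_a/year_b explicitly for multi-year surveys")
        year_a, year_b = years
    data = survey.subset_years([year_a, year_b])
    samples = data.data.groupby("year").apply(
        lambda g: len(g[["transect_id", "visit"]].drop_duplicates()),
        include_groups=False,
    )
    totals = data.totals_by_species_year()
    cls = classification.class_of() if classification is not None else None

    rows = []
    for sp, per_year in totals.iterrows():
        n1 = int(per_year.get(year_a, 0))
        n2 = int(per_year.get(year_b, 0))
        if n1 + n2 == 0:
            continue
        res = poisson_lr_by_species(n1, n2, float(samples[year_a]),
                                    float(samples[year_b]), species_id=sp)
        rows.append((sp, res.lr, None if cls is None else cls.get(sp, None),
                     res.pc, res.p, n1, n2, res.status))
    out = pd.DataFrame(rows, columns=["species_id", "lr", "cls", "pc_percent",
                                      "p", "n_year_a", "n_year_b", "status"])
    out["p_holm"] = holm_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p"] < alpha
    return out.sort_values("pc_percent", na_position="last").reset_index(drop=True)
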