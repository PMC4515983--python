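"""Vertex-wise maximum-likelihood linear mixed-effects models for log-Jacobian
shape markers, and the longitudinal changepoint model.

Three model families are fit per template vertex v with marker response
J_vj(s) (subject s, scan j):

* cross-sectional  : J_v(s)  = alpha_v + beta_v g(s) + gamma_v d(s) + delta_v i(s) + eps
  (first scan per subject; age optionally included as a nuisance covariate)
* longitudinal     : J_vj(s) = (alpha_v + alpha'_v a_j) + (beta_v + beta'_v a_j) g(s)
                               + gamma_v d(s) + delta_v i(s) + eps_vj(s)
* changepoint      : J_vj(s) = alpha_v + alpha'_v a_j
                               + beta'_v (a_j - (t_sym - Delta)) H(a_j - (t_sym - Delta))
                               + gamma_v d(s) + delta_v i(s) + eps_vj(s)

with g(s) the disease-group indicator, d(s) sex, i(s) log intracranial
volume, and H the Heaviside step.  In the longitudinal models the noise
decomposes as eps = eta(s) + zeta_j(s): a between-subject random effect of
variance rho_v sigma_v^2 plus within-subject noise of variance sigma_v^2,
giving a compound-symmetry per-subject covariance sigma^2 (I + rho 11').

Fitting is ML (not REML): for fixed rho, generalized least squares gives the
fixed effects and sigma^2 in closed form; rho is profiled on [0, 50] by a
grid plus bounded scalar refinement of the one-dimensional profile
likelihood.  The changepoint Delta is shared across vertices of a structure
and estimated by maximizing the vertex-summed profile log-likelihood over a
grid of candidate years-before-onset, ties broken toward smaller Delta.
Ages and log-ICV are centered at the cohort mean before fitting; reported
intercepts and group offsets are back-transformed to the raw age scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic import Cohort, MarkerMatrix

_SIGMA2_FLOOR = 1e-15
_RHO_MAX = 50.0
_LOG2PI = float(np.log(2.0 * np.pi))

DEFAULT_DELTA_GRID = np.arange(0.0, 15.0 + 1e-9, 0.25)
DEFAULT_RHO_GRID = np.concatenate([[0.0], np.geomspace(0.01, _RHO_MAX, 24)])


class ModelUsageError(ValueError):
    pass


@dataclasses.dataclass
class Design:
    """Alternative/null design pair plus the subject block structure."""

    X1: np.ndarray
    X0: np.ndarray
    columns1: list[str]
    columns0: list[str]
    subj_idx: np.ndarray          # row -> subject position (0..n_subj-1)
    scan_ids: list[str]
    model: str                    # 'cs' | 'long' | 'changepoint'
    rho_free: bool                # profile rho (False -> fixed at 0)
    age_mean: float
    licv_mean: float
    tested: list[str]             # columns constrained to 0 under H0

    @property
    def n_obs(self) -> int:
        return self.X1.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subj_idx.max()) + 1 if len(self.subj_idx) else 0


@dataclasses.dataclass
class LMEFit:
    """Per-vertex ML fit: coefficients, variance components, log-likelihood."""

    coef: np.ndarray              # (p, V)
    se: np.ndarray | None         # (p, V) or None when not computed
    sigma2: np.ndarray            # (V,)
    rho: np.ndarray               # (V,)
    loglik: np.ndarray            # (V,)
    columns: list[str]
    model: str
    n_obs: int
    dropped: list[str]            # rank-deficient columns flagged, not crashed on
    degenerate: np.ndarray        # (V,) True where sigma2 hit the floor (noiseless)
    rho_fixed_zero: bool = False

    def coef_named(self, name: str) -> np.ndarray:
        return self.coef[self.columns.index(name)]

    def se_named(self, name: str) -> np.ndarray:
        if self.se is None:
            raise ValueError("standard errors were not computed for this fit")
        return self.se[self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        d = {c: self.coef[i] for i, c in enumerate(self.columns)}
        d["sigma2"] = self.sigma2
        d["rho"] = self.rho
        d["loglik"] = self.loglik
        return pd.DataFrame(d)


@dataclasses.dataclass
class ChangepointFit:
    """Shared-Delta changepoint fit: grid profile and per-vertex fit at Delta-hat."""

    delta: float
    delta_grid: np.ndarray
    profile: np.ndarray           # vertex-summed log-likelihood per grid Delta
    fit: LMEFit                   # alternative fit at Delta-hat
    null_fit: LMEFit              # no-switch null fit
    delta_sd: float | None = None
    structure: str | None = None


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _subset(markers: MarkerMatrix, cohort: Cohort, groups: tuple[str, ...] | None):
    """Align marker columns with the cohort scan table, optionally restricted
    to a subset of diagnostic groups."""
    design = cohort.scan_design()
    col_of = {sid: j for j, sid in enumerate(markers.scan_ids)}
    missing = [s for s in design["scan_id"] if s not in col_of]
    if missing:
        raise ModelUsageError(f"markers missing scans: {missing[:5]}")
    if groups is not None:
        design = design[design["group"].isin(groups)].reset_index(drop=True)
    cols = [col_of[s] for s in design["scan_id"]]
    return design, markers.values[:, cols].T  # Y is (n_obs, V)


def _subject_index(design: pd.DataFrame) -> np.ndarray:
    ids = design["subject_id"].to_numpy()
    uniq = {s: i for i, s in enumerate(pd.unique(ids))}
    return np.array([uniq[s] for s in ids])


def build_design(
    markers: MarkerMatrix,
    cohort: Cohort,
    model: str,
    contrast: tuple[str, str] = ("control", "symptomatic"),
    include_age: bool = True,
    delta: float | None = None,
) -> tuple[Design, np.ndarray]:
    """Assemble the (alternative, null) design pair for one model family.

    ``contrast`` names the reference and disease group for cs/long models; the
    changepoint model instead pools controls with all onset-carrying subjects
    and has no group-offset column (the switch regressor is identically zero
    for controls).
    """
    if model == "changepoint":
        design, Y = _subset(markers, cohort, None)
    else:
        design, Y = _subset(markers, cohort, tuple(contrast))
    a = design["scan_age"].to_numpy(dtype=float)
    d = design["sex"].to_numpy(dtype=float)
    i = design["log_icv"].to_numpy(dtype=float)
    age_mean, licv_mean = float(a.mean()), float(i.mean())
    ac, ic = a - age_mean, i - licv_mean
    one = np.ones_like(a)

    if model == "cs":
        g = (design["group"] == contrast[1]).to_numpy(dtype=float)
        cols = [("intercept", one)]
        if include_age:
            cols.append(("age", ac))
        cols += [("group", g), ("sex", d), ("log_icv", ic)]
        tested = ["group"]
        rho_free = False
    elif model == "long":
        g = (design["group"] == contrast[1]).to_numpy(dtype=float)
        cols = [
            ("intercept", one), ("age", ac), ("group", g), ("group_age", ac * g),
            ("sex", d), ("log_icv", ic),
        ]
        tested = ["group", "group_age"]
        rho_free = True
    elif model == "changepoint":
        if delta is None:
            raise ModelUsageError("changepoint design requires a delta value")
        onset = design["onset_age"].to_numpy(dtype=float)
        cp = onset - delta
        w = np.where(np.isnan(cp), 0.0, np.clip(a - cp, 0.0, None))
        cols = [
            ("intercept", one), ("age", ac), ("post_cp_age", w),
            ("sex", d), ("log_icv", ic),
        ]
        tested = ["post_cp_age"]
        rho_free = True
    else:
        raise ModelUsageError(f"unknown model {model!r}")

    names1 = [c for c, _ in cols]
    X1 = np.column_stack([v for _, v in cols])
    keep0 = [k for k, c in enumerate(names1) if c not in tested]
    X0 = X1[:, keep0]
    names0 = [names1[k] for k in keep0]
    subj_idx = _subject_index(design)
    counts = np.bincount(subj_idx)
    if rho_free and counts.max() == 1:
        rho_free = False  # all single-scan: between/within split unidentifiable
    dz = Design(
        X1, X0, names1, names0, subj_idx, design["scan_id"].tolist(), model,
        rho_free, age_mean, licv_mean, tested,
    )
    return dz, Y


# ---------------------------------------------------------------------------
# Core ML machinery (compound-symmetry GLS with profiled rho)
# ---------------------------------------------------------------------------

def _v_inv_apply(M: np.ndarray, subj_idx: np.ndarray, counts: np.ndarray, rho: float) -> np.ndarray:
    """V^{-1} M for V = blockdiag(I + rho 11') over subject blocks."""
    if rho == 0.0:
        return M
    # scan tables are subject-contiguous, so per-subject sums reduce at block starts
    if len(subj_idx) and subj_idx[0] == 0 and np.all(np.diff(subj_idx) >= 0):
        starts = np.concatenate([[0], np.cumsum(counts[:-1])])
        S = np.add.reduceat(M, starts, axis=0)
    else:
        S = np.zeros((len(counts),) + M.shape[1:])
        np.add.at(S, subj_idx, M)
    shrink = rho / (1.0 + counts * rho)
    return M - shrink[subj_idx, None] * S[subj_idx]


def _gls_loglik(
    X: np.ndarray, Y: np.ndarray, subj_idx: np.ndarray, counts: np.ndarray, rho: float,
    keep: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile log-likelihood at fixed rho for every vertex.

    Returns (loglik (V,), theta (p_keep, V), sigma2 (V,)).
    """
    n = X.shape[0]
    Xk = X[:, keep]
    WX = _v_inv_apply(Xk, subj_idx, counts, rho)
    WY = _v_inv_apply(Y, subj_idx, counts, rho)
    A = Xk.T @ WX
    B = Xk.T @ WY
    theta = np.linalg.solve(A, B)
    resid = Y - Xk @ theta
    rss = np.einsum("nv,nv->v", resid, _v_inv_apply(resid, subj_idx, counts, rho))
    sigma2 = np.maximum(rss / n, _SIGMA2_FLOOR)
    logdet = float(np.log1p(counts * rho).sum())
    loglik = -0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet + n)
    return loglik, theta, sigma2


def _rank_keep(X: np.ndarray) -> np.ndarray:
    """Boolean mask of a maximal linearly independent column subset (greedy QR)."""
    p = X.shape[1]
    keep = np.zeros(p, dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(p):
        v = X[:, j].astype(float).copy()
        nrm0 = np.linalg.norm(v)
        for b in basis:
            v -= (b @ X[:, j]) * b
        if np.linalg.norm(v) > 1e-10 * max(nrm0, 1.0):
            basis.append(v / np.linalg.norm(v))
            keep[j] = True
    return keep


def _ml_fit(
    X: np.ndarray,
    Y: np.ndarray,
    subj_idx: np.ndarray,
    columns: list[str],
    model: str,
    rho_free: bool,
    rho_grid: np.ndarray | None = None,
    refine: bool = True,
    compute_se: bool = False,
) -> LMEFit:
    """ML fit per vertex with rho profiled on a grid (+ optional scalar
    refinement). Rank-deficient columns are dropped and flagged."""
    counts = np.bincount(subj_idx)
    keep = _rank_keep(X)
    dropped = [c for c, k in zip(columns, keep) if not k]
    n, V = Y.shape
    if not rho_free:
        loglik, theta_k, sigma2 = _gls_loglik(X, Y, subj_idx, counts, 0.0, keep)
        rho_hat = np.zeros(V)
    else:
        grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, dtype=float)
        lls = np.empty((len(grid), V))
        for gi, r in enumerate(grid):
            lls[gi] = _gls_loglik(X, Y, subj_idx, counts, float(r), keep)[0]
        best = lls.argmax(axis=0)
        rho_hat = grid[best]
        if refine:
            for v in range(V):
                lo = grid[max(best[v] - 1, 0)]
                hi = grid[min(best[v] + 1, len(grid) - 1)]
                if hi <= lo:
                    continue
                yv = Y[:, v : v + 1]

                def neg(r: float) -> float:
                    return -float(_gls_loglik(X, yv, subj_idx, counts, r, keep)[0][0])

                res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-8})
                if -res.fun > lls[best[v], v]:
                    rho_hat[v] = float(res.x)
        # final pass at the per-vertex rho
        loglik = np.empty(V)
        theta_k = np.empty((int(keep.sum()), V))
        sigma2 = np.empty(V)
        for r in np.unique(rho_hat):
            sel = rho_hat == r
            ll, th, s2 = _gls_loglik(X, Y[:, sel], subj_idx, counts, float(r), keep)
            loglik[sel], theta_k[:, sel], sigma2[sel] = ll, th, s2

    coef = np.full((X.shape[1], V), np.nan)
    coef[keep] = theta_k
    se = None
    if compute_se:
        se = np.full((X.shape[1], V), np.nan)
        Xk = X[:, keep]
        for r in np.unique(rho_hat):
            sel = rho_hat == r
            WX = _v_inv_apply(Xk, subj_idx, counts, float(r))
            Ainv = np.linalg.inv(Xk.T @ WX)
            se[np.ix_(keep, sel)] = np.sqrt(np.outer(np.diag(Ainv), sigma2[sel]))
    return LMEFit(
        coef=coef, se=se, sigma2=sigma2, rho=rho_hat, loglik=loglik,
        columns=list(columns), model=model, n_obs=n, dropped=dropped,
        degenerate=sigma2 <= _SIGMA2_FLOOR, rho_fixed_zero=not rho_free,
    )


# ---------------------------------------------------------------------------
# Public fitting operations
# ---------------------------------------------------------------------------

def fit_cross_sectional(
    markers: MarkerMatrix,
    cohort: Cohort,
    contrast: tuple[str, str] = ("control", "symptomatic"),
    include_age: bool = True,
    null: bool = False,
    compute_se: bool = False,
) -> LMEFit:
    """Per-vertex ML regression of first-scan markers on group + covariates.

    ``include_age=False`` reproduces the literal no-age cross-sectional
    design; by default age enters as a nuisance covariate.
    """
    cs = cohort.first_scans()
    dz, Y = build_design(markers, cs, "cs", contrast, include_age)
    X, cols = (dz.X0, dz.columns0) if null else (dz.X1, dz.columns1)
    return _ml_fit(X, Y, dz.subj_idx, cols, "cs" + ("-null" if null else ""),
                   rho_free=False, compute_se=compute_se)


def fit_longitudinal(
    markers: MarkerMatrix,
    cohort: Cohort,
    contrast: tuple[str, str] = ("control", "symptomatic"),
    null: bool = False,
    rho_grid: np.ndarray | None = None,
    refine: bool = True,
    compute_se: bool = False,
) -> LMEFit:
    """Per-vertex ML fit of the longitudinal group model with compound-symmetry
    subject covariance; rho profiled per vertex."""
    dz, Y = build_design(markers, cohort, "long", contrast)
    X, cols = (dz.X0, dz.columns0) if null else (dz.X1, dz.columns1)
    return _ml_fit(X, Y, dz.subj_idx, cols, "long" + ("-null" if null else ""),
                   rho_free=dz.rho_free, rho_grid=rho_grid, refine=refine,
                   compute_se=compute_se)


def fit_changepoint(
    markers: MarkerMatrix,
    cohort: Cohort,
    delta_grid: np.ndarray | None = None,
    rho_grid: np.ndarray | None = None,
    refine: bool = True,
    compute_se: bool = False,
    structure: str | None = None,
) -> ChangepointFit:
    """Estimate the shared changepoint Delta (years before symptom onset) by
    maximizing the vertex-summed profile log-likelihood over a grid.

    For candidate Deltas placing no scan past the changepoint the switch
    regressor is identically zero; the rank-deficiency handling then scores
    that Delta under beta' = 0, as required.  Ties break toward smaller
    Delta. The per-vertex alternative fit at Delta-hat and the no-switch null
    fit are returned together with the profile.
    """
    non_ctrl = cohort.subjects["onset_age"].notna()
    if not non_ctrl.any():
        raise ModelUsageError("changepoint model needs subjects with an onset age")
    grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, dtype=float)
    if grid.size == 0:
        raise ModelUsageError("delta grid is empty")
    # the design differs across candidate Deltas only in the switch column
    dz, Y = build_design(markers, cohort, "changepoint", delta=float(grid[0]))
    design = cohort.scan_design()
    a = design["scan_age"].to_numpy(dtype=float)
    onset = design["onset_age"].to_numpy(dtype=float)
    w_col = dz.columns1.index("post_cp_age")
    profile = np.empty(len(grid))
    for k, delta in enumerate(grid):
        cp = onset - float(delta)
        dz.X1[:, w_col] = np.where(np.isnan(cp), 0.0, np.clip(a - cp, 0.0, None))
        fit = _ml_fit(dz.X1, Y, dz.subj_idx, dz.columns1, "changepoint-alt",
                      rho_free=dz.rho_free, rho_grid=rho_grid, refine=False)
        profile[k] = float(fit.loglik.sum())
    best = int(np.argmax(profile))  # first max -> smaller Delta on ties
    delta_hat = float(grid[best])
    dz, Y = build_design(markers, cohort, "changepoint", delta=delta_hat)
    alt = _ml_fit(dz.X1, Y, dz.subj_idx, dz.columns1, "changepoint-alt",
                  rho_free=dz.rho_free, rho_grid=rho_grid, refine=refine,
                  compute_se=compute_se)
    nullf = _ml_fit(dz.X0, Y, dz.subj_idx, dz.columns0, "changepoint-null",
                    rho_free=dz.rho_free, rho_grid=rho_grid, refine=refine)
    return ChangepointFit(delta_hat, grid, profile, alt, nullf, structure=structure)


_NESTED = {
    "cs": "cs-null",
    "long": "long-null",
    "changepoint-alt": "changepoint-null",
}


def lr_statistic(alt: LMEFit, null: LMEFit) -> np.ndarray:
    """Per-vertex log-likelihood-ratio statistic S_v = L_v(H1) - L_v(H0)."""
    if _NESTED.get(alt.model) != null.model:
        raise ModelUsageError(f"models not nested: {alt.model!r} vs {null.model!r}")
    if alt.n_obs != null.n_obs or len(alt.loglik) != len(null.loglik):
        raise ModelUsageError("fits come from different data")
    return alt.loglik - null.loglik


# ---------------------------------------------------------------------------
# Bootstrap SD of Delta
# ---------------------------------------------------------------------------

def draw_resample_indices(
    cohort: Cohort, rng: np.random.Generator, stratify: bool = True
) -> np.ndarray:
    """Subject index choice for one bootstrap replicate; stratified within
    diagnostic groups by default so group sizes (and the presence of
    onset-carrying subjects) are preserved in every replicate."""
    subj = cohort.subjects
    if stratify:
        chosen: list[int] = []
        for _, grp in subj.groupby("group", sort=False):
            idx = grp.index.to_numpy()
            chosen.extend(rng.choice(idx, size=len(idx), replace=True))
        return np.asarray(chosen)
    return rng.choice(subj.index.to_numpy(), size=len(subj), replace=True)


def resample_cohort(
    cohort: Cohort, markers: MarkerMatrix, rng: np.random.Generator | None = None,
    stratify: bool = True, chosen: np.ndarray | None = None,
) -> tuple[Cohort, MarkerMatrix]:
    """Subject-level nonparametric bootstrap resample.

    Either pass ``rng`` (indices drawn here) or ``chosen`` (precomputed subject
    indices — used to apply the *same* resample across several structures).
    Duplicated subjects get fresh ids so their scans remain distinct blocks.
    """
    subj = cohort.subjects
    if chosen is None:
        if rng is None:
            raise ValueError("either rng or chosen must be given")
        chosen = draw_resample_indices(cohort, rng, stratify)
    col_of = {sid: j for j, sid in enumerate(markers.scan_ids)}
    scans_by_subj = dict(tuple(cohort.scans.groupby("subject_id", sort=False)))
    subj_rows, scan_rows, cols = [], [], []
    for r, si in enumerate(chosen):
        row = subj.loc[si]
        new_id = f"{row['subject_id']}_b{r}"
        subj_rows.append((new_id, row["group"], row["sex"], row["log_icv"], row["onset_age"]))
        for _, srow in scans_by_subj[row["subject_id"]].iterrows():
            scan_rows.append((new_id, f"{new_id}_{srow['scan_id']}", srow["scan_age"]))
            cols.append(col_of[srow["scan_id"]])
    new_subj = pd.DataFrame(subj_rows, columns=["subject_id", "group", "sex", "log_icv", "onset_age"])
    new_scans = pd.DataFrame(scan_rows, columns=["subject_id", "scan_id", "scan_age"])
    new_markers = MarkerMatrix(markers.values[:, cols], new_scans["scan_id"].tolist())
    return Cohort(new_subj, new_scans), new_markers


def estimate_delta_sd(
    markers: MarkerMatrix,
    cohort: Cohort,
    delta_grid: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int = 0,
    rho_grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Bootstrap SD of the changepoint estimate (stratified subject resampling).

    Returns (SD, replicate Delta-hats)."""
    if n_boot < 50:
        raise ModelUsageError("n_boot must be >= 50 for a stable SD")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        c_b, m_b = resample_cohort(cohort, markers, rng)
        reps[b] = fit_changepoint(m_b, c_b, delta_grid, rho_grid=rho_grid, refine=False).delta
    return float(reps.std(ddof=1)), reps


# ---------------------------------------------------------------------------
# Atrophy rates from structure volumes
# ---------------------------------------------------------------------------

def fit_atrophy_rates(
    volumes: pd.DataFrame, cohort: Cohort, min_scans: int = 3
) -> pd.DataFrame:
    """Annualized per-group atrophy rates (% of baseline volume per year).

    ``volumes`` has columns subject_id, scan_age, volume.  Per subject a
    least-squares line of volume against scan age is fit; the slope, as a
    percentage of that subject's baseline (first-scan) volume, is averaged
    within groups.  Subjects with fewer than ``min_scans`` scans are excluded.
    """
    if (volumes["volume"] <= 0).any():
        raise ValueError("volumes must be positive")
    grp_of = dict(zip(cohort.subjects["subject_id"], cohort.subjects["group"]))
    rows = []
    for sid, sub in volumes.groupby("subject_id", sort=False):
        if len(sub) < min_scans:
            continue
        sub = sub.sort_values("scan_age")
        slope = np.polyfit(sub["scan_age"], sub["volume"], 1)[0]
        baseline = float(sub["volume"].iloc[0])
        rows.append((sid, grp_of[sid], 100.0 * slope / baseline))
    if not rows:
        raise ValueError(f"no subjects with >= {min_scans} scans")
    df = pd.DataFrame(rows, columns=["subject_id", "group", "rate_pct_per_year"])
    out = df.groupby("group")["rate_pct_per_year"].agg(["mean", "count"]).reset_index()
    out.columns = ["group", "atrophy_rate_pct_per_year", "n_subjects"]
    # atrophy is volume loss: report the (positive) loss rate
    out["atrophy_rate_pct_per_year"] = -out["atrophy_rate_pct_per_year"]
    return out
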