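"""Repeatability animal model: Henderson's MME and REML variance components.

The single-trait model is y = X b + Z a + W p + e with a ~ N(0, K s2a)
for K the pedigree (A) or combined pedigree-genomic (H) relationship
matrix, p ~ N(0, I s2p) a permanent-environment effect shared by an
animal's repeated records, and e ~ N(0, I s2e).  Fixed effects are a
contemporary group factor plus two record-level covariates.

Variance components are estimated by EM-REML with average-information
(AI) acceleration once the trajectory stabilizes: AI Newton steps are
attempted and fall back to an EM step whenever they leave the parameter
space or decrease the restricted likelihood.  EM steps can never
produce a negative variance, which keeps the maximizer robust near
boundaries on small data sets.  Everything is dense; the package
targets desk-scale problems (mixed-model equations of a few thousand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .pedigree import RelationshipMatrix


class ModelError(ValueError):
    pass


class REMLConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class TraitModel:
    """Assembled design for one trait: y = X b + Z a + W p + e."""

    y: np.ndarray
    X: np.ndarray
    animal_idx: np.ndarray  # record -> index into ids
    rec_animals: np.ndarray  # animal indices owning >= 1 record (W columns)
    K_inv: np.ndarray
    ids: list[str]
    fixed_names: list[str]
    trait: str = "trait"
    _logdet_K_inv: float | None = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def logdet_K_inv(self) -> float:
        if self._logdet_K_inv is None:
            sign, ld = np.linalg.slogdet(self.K_inv)
            if sign <= 0:
                raise ModelError("relationship inverse is not positive definite")
            self._logdet_K_inv = float(ld)
        return self._logdet_K_inv


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_p: float
    sigma2_e: float
    se: dict[str, float] = field(default_factory=dict)
    loglik: float | None = None
    n_iter: int = 0
    converged: bool = True
    at_boundary: bool = False
    trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_p", "sigma2_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_p + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma2_a + self.sigma2_p) / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("additive_genetic", self.sigma2_a, self.se.get("sigma2_a")),
            ("permanent_environment", self.sigma2_p, self.se.get("sigma2_p")),
            ("residual", self.sigma2_e, self.se.get("sigma2_e")),
            ("heritability", self.h2, self.se.get("h2")),
            ("repeatability", self.repeatability, None),
        ]
        return pd.DataFrame(rows, columns=["component", "estimate", "se"])


@dataclass
class Solutions:
    beta: pd.Series
    gebv: pd.Series  # â for every animal in the relationship structure
    pe: pd.Series
    mme_residual: float
    tolerance: float = 1e-8

    @property
    def converged(self) -> bool:
        return self.mme_residual < self.tolerance


def build_model(
    records: pd.DataFrame,
    relationship: RelationshipMatrix,
    trait: str = "trait",
    drop_level: str = "first",
) -> TraitModel:
    """Design matrices for one trait against a relationship inverse.

    The contemporary-group factor gets one-hot columns with one level
    dropped (intercept retained); covariates are centered.  Traits such
    as cell counts must arrive already log-transformed.
    """
    if relationship.role not in ("A_inverse", "H_inverse"):
        raise ModelError("relationship must be an A_inverse or H_inverse matrix")
    df = records[records["trait"] == trait].reset_index(drop=True)
    if df.empty:
        raise ModelError(f"no records for trait {trait!r}")
    index = {a: i for i, a in enumerate(relationship.ids)}
    unknown = sorted(set(df["animal"]) - set(index))
    if unknown:
        raise ModelError(f"records reference animals absent from the pedigree: {unknown[:5]}")
    animal_idx = df["animal"].map(index).to_numpy(dtype=np.int64)

    levels = sorted(df["fixed_group"].astype(str).unique())
    counts = df["fixed_group"].value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise ModelError(f"empty fixed-effect levels: {empty}")
    dropped = levels[0] if drop_level == "first" else levels[-1]
    kept = [lv for lv in levels if lv != dropped]
    n = len(df)
    X_cols = [np.ones(n)]
    names = ["intercept"]
    for lv in kept:
        X_cols.append((df["fixed_group"].astype(str) == lv).to_numpy(float))
        names.append(f"group[{lv}]")
    for cov in ("interval_days", "age_months"):
        x = df[cov].to_numpy(float)
        X_cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient after the constraint")

    rec_animals = np.unique(animal_idx)
    return TraitModel(
        y=df["value"].to_numpy(float),
        X=X,
        animal_idx=animal_idx,
        rec_animals=rec_animals,
        K_inv=relationship.values,
        ids=list(relationship.ids),
        fixed_names=names,
        trait=trait,
    )


def _assemble(model: TraitModel, vc: VarianceComponents):
    """Coefficient matrix C (lambda form) and right-hand side of the MME."""
    y, X = model.y, model.X
    n, p = X.shape
    q_a = model.n_animals
    q_p = len(model.rec_animals)
    lam_a = vc.sigma2_e / vc.sigma2_a
    lam_p = vc.sigma2_e / vc.sigma2_p

    ZtX = np.zeros((q_a, p))
    np.add.at(ZtX, model.animal_idx, X)
    Zty = np.zeros(q_a)
    np.add.at(Zty, model.animal_idx, y)
    cnt = np.bincount(model.animal_idx, minlength=q_a).astype(float)

    w_pos = {a: j for j, a in enumerate(model.rec_animals)}
    w_idx = np.array([w_pos[a] for a in model.animal_idx], dtype=np.int64)
    WtX = np.zeros((q_p, p))
    np.add.at(WtX, w_idx, X)
    Wty = np.zeros(q_p)
    np.add.at(Wty, w_idx, y)
    cnt_w = np.bincount(w_idx, minlength=q_p).astype(float)

    dim = p + q_a + q_p
    C = np.zeros((dim, dim))
    sl_b = slice(0, p)
    sl_a = slice(p, p + q_a)
    sl_p = slice(p + q_a, dim)
    C[sl_b, sl_b] = X.T @ X
    C[sl_a, sl_b] = ZtX
    C[sl_b, sl_a] = ZtX.T
    C[sl_p, sl_b] = WtX
    C[sl_b, sl_p] = WtX.T
    C[sl_a, sl_a] = np.diag(cnt) + lam_a * model.K_inv
    C[sl_p, sl_p] = np.diag(cnt_w + lam_p)
    # Z'W: animal i vs its own PE column only
    C[sl_a, sl_p][model.rec_animals, np.arange(q_p)] = cnt_w
    C[sl_p, sl_a] = C[sl_a, sl_p].T
    rhs = np.concatenate([X.T @ y, Zty, Wty])
    return C, rhs, (sl_b, sl_a, sl_p), w_idx


def solve_mme(model: TraitModel, vc: VarianceComponents) -> Solutions:
    """Solve Henderson's mixed-model equations at fixed variance ratios."""
    C, rhs, (sl_b, sl_a, sl_p), _ = _assemble(model, vc)
    try:
        cf = scipy.linalg.cho_factor(C)
    except scipy.linalg.LinAlgError as exc:
        raise ModelError(
            "singular mixed-model equations: the fixed-effect block is "
            "confounded with the random effects (e.g. single records with "
            "a saturated group factor)"
        ) from exc
    s = scipy.linalg.cho_solve(cf, rhs)
    resid = float(np.max(np.abs(C @ s - rhs))) / max(float(np.max(np.abs(rhs))), 1e-300)
    rec_ids = [model.ids[a] for a in model.rec_animals]
    return Solutions(
        beta=pd.Series(s[sl_b], index=model.fixed_names),
        gebv=pd.Series(s[sl_a], index=model.ids),
        pe=pd.Series(s[sl_p], index=rec_ids),
        mme_residual=resid,
    )


def reml_loglik(model: TraitModel, vc: VarianceComponents) -> float:
    """Restricted log-likelihood (up to a constant) at the given components."""
    C, rhs, _, _ = _assemble(model, vc)
    n, p = model.X.shape
    q_a, q_p = model.n_animals, len(model.rec_animals)
    dim = C.shape[0]
    cf = scipy.linalg.cho_factor(C)
    s = scipy.linalg.cho_solve(cf, rhs)
    logdet_Clam = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    yPy = (float(model.y @ model.y) - float(s @ rhs)) / vc.sigma2_e
    log_R = n * np.log(vc.sigma2_e)
    log_Gu = (
        q_a * np.log(vc.sigma2_a)
        - model.logdet_K_inv
        + q_p * np.log(vc.sigma2_p)
    )
    log_C = logdet_Clam - dim * np.log(vc.sigma2_e)
    return -0.5 * (log_R + log_Gu + log_C + yPy)


def _reml_inner(model: TraitModel, vc: VarianceComponents):
    """One pass of the REML machinery: solutions, traces, scores, AI matrix."""
    C, rhs, (sl_b, sl_a, sl_p), w_idx = _assemble(model, vc)
    n, p = model.X.shape
    q_a, q_p = model.n_animals, len(model.rec_animals)
    dim = C.shape[0]
    s2a, s2p, s2e = vc.sigma2_a, vc.sigma2_p, vc.sigma2_e
    cf = scipy.linalg.cho_factor(C)
    s = scipy.linalg.cho_solve(cf, rhs)
    Cinv = scipy.linalg.cho_solve(cf, np.eye(dim))
    beta, a_hat, p_hat = s[sl_b], s[sl_a], s[sl_p]

    e_hat = (
        model.y - model.X @ beta - a_hat[model.animal_idx] - p_hat[w_idx]
    )
    yy_sy = float(model.y @ model.y) - float(s @ rhs)

    tr_aa = float(np.sum(model.K_inv * Cinv[sl_a, sl_a]))  # tr(K_inv C_aa)
    tr_pp = float(np.trace(Cinv[sl_p, sl_p]))
    aKa = float(a_hat @ model.K_inv @ a_hat)
    pp = float(p_hat @ p_hat)

    # EM updates
    em = np.array(
        [
            (aKa + s2e * tr_aa) / q_a,
            (pp + s2e * tr_pp) / q_p,
            yy_sy / (n - p),
        ]
    )

    # scores
    tr_PZKZ = (q_a - s2e * tr_aa / s2a) / s2a
    tr_PWW = (q_p - s2e * tr_pp / s2p) / s2p
    lam_a, lam_p = s2e / s2a, s2e / s2p
    tr_ClamTT = dim - (lam_a * tr_aa + lam_p * tr_pp)
    tr_P = (n - tr_ClamTT) / s2e
    score = -0.5 * np.array(
        [
            tr_PZKZ - aKa / s2a**2,
            tr_PWW - pp / s2p**2,
            tr_P - float(e_hat @ e_hat) / s2e**2,
        ]
    )

    # average-information matrix via P-weighted working vectors
    Wmat = np.column_stack(
        [
            a_hat[model.animal_idx] / s2a,
            p_hat[w_idx] / s2p,
            e_hat / s2e,
        ]
    )
    TtW = np.zeros((dim, 3))
    TtW[sl_b] = model.X.T @ Wmat
    np.add.at(TtW[sl_a], model.animal_idx, Wmat)
    np.add.at(TtW[sl_p], w_idx, Wmat)
    PW = (Wmat - _design_apply(model, w_idx, scipy.linalg.cho_solve(cf, TtW))) / s2e
    AI = 0.5 * (Wmat.T @ PW)
    AI = 0.5 * (AI + AI.T)

    logdet_Clam = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    log_R = n * np.log(s2e)
    log_Gu = q_a * np.log(s2a) - model.logdet_K_inv + q_p * np.log(s2p)
    log_C = logdet_Clam - dim * np.log(s2e)
    loglik = -0.5 * (log_R + log_Gu + log_C + yy_sy / s2e)
    return em, score, AI, loglik


def _design_apply(model: TraitModel, w_idx: np.ndarray, s_mat: np.ndarray) -> np.ndarray:
    """Compute T s for T = [X Z W] and stacked solution columns s."""
    p = model.X.shape[1]
    q_a = model.n_animals
    out = model.X @ s_mat[:p]
    out += s_mat[p : p + q_a][model.animal_idx]
    out += s_mat[p + q_a :][w_idx]
    return out


def estimate_reml(
    model: TraitModel,
    start: VarianceComponents | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_em_warmup: int = 3,
    bound: float = 1e-10,
) -> VarianceComponents:
    """EM-REML with AI acceleration for (sigma2_a, sigma2_p, sigma2_e).

    Convergence when the largest relative parameter change drops below
    ``tol``.  Standard errors come from the inverse AI matrix at the
    optimum.  Raises ``REMLConvergenceError`` (carrying the trajectory)
    after ``max_iter`` iterations without convergence; a variance pinned
    at the lower bound is flagged, not fatal.
    """
    n, p = model.X.shape
    if n <= p:
        raise ModelError("need more records than fixed-effect parameters")
    if start is None:
        beta_ols, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
        vy = float(np.var(model.y - model.X @ beta_ols))
        vy = max(vy, 1e-8)
        theta = np.array([0.3 * vy, 0.2 * vy, 0.5 * vy])
    else:
        theta = np.array([start.sigma2_a, start.sigma2_p, start.sigma2_e])
    scale = float(np.var(model.y))
    floor = max(bound, 1e-12 * scale)

    trajectory: list[tuple[float, float, float, float]] = []
    loglik_prev = -np.inf
    hit_boundary = False
    AI = None
    for it in range(1, max_iter + 1):
        vc = VarianceComponents(*theta)
        em, score, AI, loglik = _reml_inner(model, vc)
        trajectory.append((*theta, loglik))

        candidate = None
        if it > n_em_warmup:
            try:
                step = np.linalg.solve(AI, score)
                cand = theta + step
                if np.all(cand > floor):
                    vc_c = VarianceComponents(*cand)
                    ll_c = reml_loglik(model, vc_c)
                    if ll_c >= loglik - 1e-10:
                        candidate = (cand, ll_c)
            except np.linalg.LinAlgError:
                candidate = None
        if candidate is None:
            cand = np.maximum(em, floor)
            candidate = (cand, None)
        new_theta = candidate[0]
        # a component collapsing toward zero converges geometrically and
        # would stall the relative-change test: pin it and move on
        pin = new_theta <= max(1e-8 * scale, floor)
        if pin.any():
            hit_boundary = True
            new_theta = np.where(pin, np.maximum(new_theta, floor), new_theta)
        free = ~pin
        delta = 0.0
        if free.any():
            delta = float(
                np.max(np.abs(new_theta[free] - theta[free]) / np.abs(theta[free]))
            )
        theta = new_theta
        if delta < tol:
            break
        loglik_prev = loglik
    else:
        raise REMLConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory
        )

    vc = VarianceComponents(*theta)
    em, score, AI, loglik = _reml_inner(model, vc)
    se: dict[str, float] = {}
    try:
        cov = np.linalg.inv(AI)
        se = {
            "sigma2_a": float(np.sqrt(max(cov[0, 0], 0.0))),
            "sigma2_p": float(np.sqrt(max(cov[1, 1], 0.0))),
            "sigma2_e": float(np.sqrt(max(cov[2, 2], 0.0))),
        }
        # delta-method SE for h2 = s2a / total
        total = theta.sum()
        grad = np.array(
            [
                (total - theta[0]) / total**2,
                -theta[0] / total**2,
                -theta[0] / total**2,
            ]
        )
        se["h2"] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        *theta,
        se=se,
        loglik=float(loglik),
        n_iter=len(trajectory),
        converged=True,
        at_boundary=hit_boundary,
        trajectory=trajectory,
    )


def em_step(model: TraitModel, vc: VarianceComponents) -> VarianceComponents:
    """A single EM-REML update, exposed for fixed-point diagnostics."""
    em, *_ = _reml_inner(model, vc)
    return VarianceComponents(*np.maximum(em, 1e-12))
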