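"""Stay/switch regression estimation of model-based and model-free indices.

The unit of analysis is the lagged stay row: for every pair of consecutive
non-missed trials within a block, ``stay`` records whether the later
choice repeats the earlier one, and the earlier trial's reward and
transition are carried as ±1-coded regressors.  Per-subject logistic
coefficients of stay on {1, reward, transition, reward x transition} give
the stay tendency (intercept), model-free index (reward), transition
effect, and model-based index (the interaction).

Two estimators are provided:

* :func:`fit_pointwise` — independent ridge-penalized logistic fits per
  subject (Newton-Raphson).
* :func:`fit_hierarchical` — a binomial-logit mixed model with a random
  intercept and all three slopes per subject (unstructured covariance),
  marginal likelihood by the Laplace approximation, per-subject
  coefficients as fixed effects plus conditional modes.  Wald standard
  errors for the fixed effects condition on the estimated random-effect
  covariance, matching standard mixed-model practice.

Extended fixed-effect structures cover group-comparison models (a ±1
subject-level code interacted with all base terms) and the lagged-hit
model (the identifiable reward-conditional hit contrast and its
transition interaction; see :func:`fit_hit_model`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .taskmodel import InvalidArgument, TrialRecord, trials_to_frame

BASE_TERMS = ["intercept", "reward", "transition", "reward_x_transition"]

STAY_COLUMNS = ["subject", "session", "block", "trial", "stay",
                "prev_reward", "prev_transition", "prev_hit"]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_stay_design(
    trials: Union[pd.DataFrame, Sequence[TrialRecord]],
    include_hit: bool = False,
) -> pd.DataFrame:
    """Lagged stay rows from a trial log.

    One row per consecutive pair of non-missed trials within the same
    (subject, session, block); a missed trial breaks the chain, so neither
    it nor its successor yields a row.  ``trial`` is the index of the stay
    (later) trial.  ``prev_hit`` (when requested) is +1 after a hit and −1
    otherwise, including unrewarded previous trials.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if df.empty:
        cols = STAY_COLUMNS if include_hit else STAY_COLUMNS[:-1]
        return pd.DataFrame(columns=cols)
    keys = ["subject", "session", "block", "trial"]
    sorted_idx = df.sort_values(keys, kind="stable").index
    if not np.array_equal(sorted_idx.to_numpy(), df.index.to_numpy()):
        raise InvalidArgument("trials must be sorted by (subject, session, block, trial)")

    grp = df.groupby(["subject", "session", "block"], sort=False)
    prev = grp[["choice", "reward", "transition", "hit", "missed", "trial"]].shift(1)
    missed = df["missed"].astype(bool)
    # NaN (block-leading) rows count as missing predecessors
    prev_missed = ~(prev["missed"] == False).to_numpy()  # noqa: E712
    adjacent = df["trial"].to_numpy() == (prev["trial"].to_numpy() + 1)
    valid = (~missed) & (~prev_missed) & adjacent

    out = pd.DataFrame({
        "subject": df.loc[valid, "subject"].to_numpy(),
        "session": df.loc[valid, "session"].to_numpy(),
        "block": df.loc[valid, "block"].to_numpy(),
        "trial": df.loc[valid, "trial"].to_numpy(),
        "stay": (df.loc[valid, "choice"].to_numpy()
                 == prev.loc[valid, "choice"].to_numpy()).astype(int),
        "prev_reward": (2 * prev.loc[valid, "reward"].to_numpy(dtype=float) - 1
                        ).astype(int),
        "prev_transition": np.where(
            prev.loc[valid, "transition"].to_numpy() == "common", 1, -1),
    })
    if include_hit:
        hit_prev = prev.loc[valid, "hit"].to_numpy(dtype=object)
        out["prev_hit"] = np.where(
            pd.array(hit_prev, dtype="Int64").fillna(0).to_numpy() == 1, 1, -1)
    return out.reset_index(drop=True)


def _design_matrix(rows: pd.DataFrame, model: str,
                   group: Optional[pd.Series] = None
                   ) -> tuple[np.ndarray, list[str]]:
    r = rows["prev_reward"].to_numpy(dtype=float)
    t = rows["prev_transition"].to_numpy(dtype=float)
    base = np.column_stack([np.ones_like(r), r, t, r * t])
    if model == "base":
        return base, list(BASE_TERMS)
    if model == "comparison":
        if group is None:
            raise InvalidArgument("comparison model requires a group code")
        g = rows["subject"].map(group).to_numpy(dtype=float)
        if np.isnan(g).any():
            raise InvalidArgument("every subject needs a group code")
        if np.unique(g).size < 2:
            raise InvalidArgument("comparison model needs at least two groups")
        X = np.column_stack([base, base * g[:, None]])
        terms = BASE_TERMS + ["group", "reward_x_group", "transition_x_group",
                              "reward_x_transition_x_group"]
        return X, terms
    if model == "hit":
        if "prev_hit" not in rows.columns:
            raise InvalidArgument("hit model requires rows built with include_hit")
        h = rows["prev_hit"].to_numpy(dtype=float)
        # hits only occur on rewarded trials, which aliases the hit main
        # effect with reward x hit (and transition x hit with the three-way):
        # 1 - r + h - rh = 0 identically in the ±1 coding.  The identifiable
        # parameterization uses the hit contrast within rewarded trials
        # (+1 hit, -1 no hit, 0 unrewarded) and its transition interaction.
        hc = np.where(r == 1, h, 0.0)
        if np.unique(hc[r == 1]).size < 2:
            raise InvalidArgument("prev_hit is constant; hit model is degenerate")
        X = np.column_stack([base, hc, t * hc])
        terms = BASE_TERMS + ["reward_x_hit", "reward_x_transition_x_hit"]
        return X, terms
    raise InvalidArgument(f"unknown model {model!r}")


def _collapse_by_subject(rows: pd.DataFrame, X: np.ndarray, terms: list[str]):
    """Collapse repeated design rows per subject into binomial cells.

    Returns padded arrays ``Xf (S, C, p)``, ``n (S, C)``, ``k (S, C)`` and
    the subject index.  Padding cells have n = 0 and contribute nothing.
    """
    df = pd.DataFrame(X, columns=terms)
    df["subject"] = rows["subject"].to_numpy()
    df["stay"] = rows["stay"].to_numpy()
    agg = (df.groupby(["subject"] + terms, sort=True)["stay"]
             .agg(n="count", k="sum").reset_index())
    subjects = agg["subject"].unique()
    sidx = {s: i for i, s in enumerate(subjects)}
    counts = agg.groupby("subject", sort=True).size()
    C = int(counts.max())
    S, p = len(subjects), len(terms)
    Xf = np.zeros((S, C, p))
    n = np.zeros((S, C))
    k = np.zeros((S, C))
    pos = np.zeros(S, dtype=int)
    si = agg["subject"].map(sidx).to_numpy()
    xs = agg[terms].to_numpy(dtype=float)
    for j in range(len(agg)):
        i = si[j]
        c = pos[i]
        Xf[i, c] = xs[j]
        n[i, c] = agg["n"].iat[j]
        k[i, c] = agg["k"].iat[j]
        pos[i] += 1
    return Xf, n, k, pd.Index(subjects, name="subject")


# ---------------------------------------------------------------------------
# pointwise (per-subject) logistic fits
# ---------------------------------------------------------------------------

@dataclass
class SubjectCoefficients:
    subject: object
    stay_tendency: float
    mfi: float
    transition_effect: float
    mbi: float
    source: str = "pointwise"
    separation_flag: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.stay_tendency, self.mfi,
                         self.transition_effect, self.mbi])


def _newton_logit(X: np.ndarray, n: np.ndarray, k: np.ndarray, ridge: float,
                  max_iter: int = 100, tol: float = 1e-8
                  ) -> tuple[np.ndarray, bool]:
    """Ridge-penalized binomial-logit Newton-Raphson on collapsed cells."""
    p = X.shape[1]
    theta = np.zeros(p)

    def negobj(th):
        eta = X @ th
        return -(k @ eta - n @ np.logaddexp(0.0, eta)) + 0.5 * ridge * th @ th

    f = negobj(theta)
    converged = False
    for _ in range(max_iter):
        eta = X @ theta
        mu = expit(eta)
        g = X.T @ (k - n * mu) - ridge * theta
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        W = n * mu * (1 - mu)
        H = (X.T * W) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        frac = 1.0
        for _ in range(30):
            f_new = negobj(theta + frac * step)
            if f_new <= f + 1e-12:
                break
            frac *= 0.5
        theta = theta + frac * step
        f = negobj(theta)
    return theta, converged


def fit_pointwise(rows: pd.DataFrame, ridge: float = 1e-3
                  ) -> SubjectCoefficients:
    """Independent logistic fit of one subject's stay rows.

    A small ridge (default 1e-3, on intercept and slopes) keeps the
    estimate finite under separation, which is common in short windows.
    ``separation_flag`` reports whether the unpenalized likelihood
    diverges; with ``ridge=0`` a separated fit raises instead.
    """
    if rows is None or len(rows) == 0:
        raise InvalidArgument("fit_pointwise needs at least one stay row")
    if rows["subject"].nunique() != 1:
        raise InvalidArgument("fit_pointwise expects rows for a single subject")
    if ridge < 0:
        raise InvalidArgument("ridge must be non-negative")
    X, terms = _design_matrix(rows, "base")
    Xc, n, k, _ = _collapse_by_subject(rows, X, terms)
    Xc, n, k = Xc[0], n[0], k[0]
    live = n > 0
    Xc, n, k = Xc[live], n[live], k[live]

    probe, probe_conv = _newton_logit(Xc, n, k, ridge=0.0, max_iter=30)
    separated = (not probe_conv) or np.max(np.abs(probe)) > 12.0
    if ridge == 0.0:
        if separated:
            raise ConvergenceError(
                "perfect separation: unpenalized fit diverges; use ridge > 0")
        theta = probe
    else:
        theta, conv = _newton_logit(Xc, n, k, ridge=ridge)
        if not conv:
            raise ConvergenceError("pointwise Newton failed to converge")
    return SubjectCoefficients(
        subject=rows["subject"].iloc[0],
        stay_tendency=float(theta[0]), mfi=float(theta[1]),
        transition_effect=float(theta[2]), mbi=float(theta[3]),
        source="pointwise", separation_flag=bool(separated))


def pointwise_table(rows: pd.DataFrame, ridge: float = 1e-3) -> pd.DataFrame:
    """Per-subject pointwise coefficient table for a whole cohort."""
    recs = []
    for subject, sub in rows.groupby("subject", sort=True):
        c = fit_pointwise(sub, ridge=ridge)
        recs.append({"subject": subject, "stay_tendency": c.stay_tendency,
                     "mfi": c.mfi, "transition_effect": c.transition_effect,
                     "mbi": c.mbi, "separation_flag": c.separation_flag})
    return pd.DataFrame(recs).set_index("subject")


# ---------------------------------------------------------------------------
# hierarchical (mixed-effects) logistic fit
# ---------------------------------------------------------------------------

_TRIL_IDX = np.tril_indices(4, k=-1)


def _chol_from_theta(theta_cov: np.ndarray, diag_only: bool) -> np.ndarray:
    L = np.zeros((4, 4))
    np.fill_diagonal(L, np.exp(theta_cov[:4]))
    if not diag_only:
        L[_TRIL_IDX] = theta_cov[4:10]
    return L


@dataclass
class HierFit:
    """Fitted hierarchical stay model."""

    fixed: pd.DataFrame                # index term; estimate, se, z, p
    ranef_cov: np.ndarray              # 4x4 covariance of the random effects
    subject_effects: pd.DataFrame      # per-subject conditional modes
    n_subjects: int
    n_rows: int
    loglik: float
    converged: bool
    model: str = "base"
    group: Optional[pd.Series] = None  # per-subject ±1 code (comparison model)
    label: str = ""

    def subject_coefficients(self) -> pd.DataFrame:
        """Fixed effects plus conditional modes, one quadruple per subject.

        For the comparison model each subject's fixed part includes the
        group terms evaluated at that subject's ±1 code.  For the hit
        model the hit terms vary within subject and are not folded in.
        """
        beta = self.fixed["estimate"]
        dev = self.subject_effects[[f"d_{t}" for t in BASE_TERMS]].to_numpy()
        fixed_part = np.tile(beta[BASE_TERMS].to_numpy(), (self.n_subjects, 1))
        if self.model == "comparison":
            g = self.group.reindex(self.subject_effects.index).to_numpy(dtype=float)
            gterms = ["group", "reward_x_group", "transition_x_group",
                      "reward_x_transition_x_group"]
            fixed_part = fixed_part + g[:, None] * beta[gterms].to_numpy()
        coefs = fixed_part + dev
        return pd.DataFrame(
            coefs, index=self.subject_effects.index,
            columns=["stay_tendency", "mfi", "transition_effect", "mbi"])

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "label": self.label,
            "fixed": {
                term: {c: float(row[c]) for c in ("estimate", "se", "z", "p")}
                for term, row in self.fixed.iterrows()
            },
            "ranef_cov": self.ranef_cov.tolist(),
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class _LaplaceObjective:
    """Negative Laplace-approximate marginal log-likelihood.

    Conditional modes are found by damped Newton iterations vectorized
    over subjects (the design collapses to at most eight binomial cells
    per subject, so every inner step is a batch of 4x4 solves).  Modes are
    warm-started between calls.
    """

    def __init__(self, Xf, n, k, diag_only=False):
        self.Xf = Xf          # (S, C, p) fixed design per cell
        self.Zr = Xf[:, :, :4]  # random design: intercept + 3 base slopes
        self.n = n
        self.k = k
        self.S, self.C, self.p = Xf.shape
        self.diag_only = diag_only
        self.b = np.zeros((self.S, 4))
        self.inner_ok = True

    def n_theta(self) -> int:
        return self.p + (4 if self.diag_only else 10)

    def _penalized_ll(self, eta, b, Lam):
        data = (self.k * eta - self.n * np.logaddexp(0.0, eta)).sum(axis=1)
        pen = 0.5 * np.einsum("sd,de,se->s", b, Lam, b)
        return data - pen

    def _find_modes(self, beta, Lam, tol=1e-10, max_iter=60):
        Zr, n, k = self.Zr, self.n, self.k
        eta0 = self.Xf @ beta
        b = self.b.copy()
        eta = eta0 + np.einsum("scd,sd->sc", Zr, b)
        f = self._penalized_ll(eta, b, Lam)
        for _ in range(max_iter):
            mu = expit(eta)
            g = np.einsum("scd,sc->sd", Zr, k - n * mu) - b @ Lam
            if np.max(np.abs(g)) < tol:
                break
            W = n * mu * (1 - mu)
            H = np.einsum("scd,sc,sce->sde", Zr, W, Zr) + Lam[None, :, :]
            step = np.linalg.solve(H, g[..., None])[..., 0]
            frac = np.ones(self.S)
            for _ in range(25):
                b_new = b + frac[:, None] * step
                eta_new = eta0 + np.einsum("scd,sd->sc", Zr, b_new)
                f_new = self._penalized_ll(eta_new, b_new, Lam)
                bad = ~(f_new >= f - 1e-10)
                if not bad.any():
                    break
                frac[bad] *= 0.5
            b, eta, f = b_new, eta_new, f_new
        else:
            self.inner_ok = False
        self.b = b
        return b, eta, f

    def __call__(self, theta: np.ndarray) -> float:
        beta = theta[:self.p]
        L = _chol_from_theta(theta[self.p:], self.diag_only)
        Sigma = L @ L.T
        try:
            Linv = np.linalg.inv(L)
        except np.linalg.LinAlgError:
            return 1e12
        Lam = Linv.T @ Linv
        b, eta, f = self._find_modes(beta, Lam)
        mu = expit(eta)
        W = self.n * mu * (1 - mu)
        Hd = np.einsum("scd,sc,sce->sde", self.Zr, W, self.Zr)
        M = np.eye(4)[None, :, :] + Sigma[None, :, :] @ Hd
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            return 1e12
        val = -(f.sum() - 0.5 * logdet.sum())
        if not np.isfinite(val):
            return 1e12
        return float(val)


def _pooled_start(Xf, n, k, p) -> np.ndarray:
    X = Xf.reshape(-1, p)
    nn = n.reshape(-1)
    kk = k.reshape(-1)
    theta, _ = _newton_logit(X, nn, kk, ridge=1e-6, max_iter=60)
    return theta


def _fit_mixed(rows: pd.DataFrame, model: str,
               group: Optional[pd.Series] = None,
               label: str = "",
               diag_only: bool = False,
               _retry: bool = True) -> HierFit:
    X, terms = _design_matrix(rows, model, group)
    Xf, n, k, subjects = _collapse_by_subject(rows, X, terms)
    S, _, p = Xf.shape
    if S < 2:
        raise InvalidArgument("hierarchical fit needs at least 2 subjects")

    obj = _LaplaceObjective(Xf, n, k, diag_only=diag_only)
    x0 = np.zeros(obj.n_theta())
    x0[:p] = _pooled_start(Xf, n, k, p)
    x0[p:p + 4] = np.log(0.5)
    bounds = ([(None, None)] * p + [(-6.0, 2.5)] * 4
              + ([] if diag_only else [(-4.0, 4.0)] * 6))
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6})

    converged = bool(res.success) and obj.inner_ok
    if not converged and _retry and not diag_only:
        # fall back to a diagonal random-effect covariance; converged stays
        # False only if the retry fails as well
        return _fit_mixed(rows, model, group, label, diag_only=True,
                          _retry=False)

    theta = res.x
    beta = theta[:p]
    L = _chol_from_theta(theta[p:], diag_only)
    Sigma = L @ L.T

    # Wald covariance of beta, conditioning on the estimated ranef covariance
    se = _beta_se(obj, theta, p)
    z = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * norm.sf(np.abs(z))
    fixed = pd.DataFrame({"estimate": beta, "se": se, "z": z, "p": pvals},
                         index=pd.Index(terms, name="term"))

    # conditional modes at the optimum
    Linv = np.linalg.inv(L)
    Lam = Linv.T @ Linv
    b, _, _ = obj._find_modes(beta, Lam)
    subject_effects = pd.DataFrame(
        b, index=subjects, columns=[f"d_{t}" for t in BASE_TERMS])

    gser = None
    if model == "comparison":
        gser = pd.Series(group).reindex(subjects)
    return HierFit(fixed=fixed, ranef_cov=Sigma,
                   subject_effects=subject_effects, n_subjects=S,
                   n_rows=len(rows), loglik=-float(res.fun),
                   converged=converged, model=model, group=gser, label=label)


def _beta_se(obj: _LaplaceObjective, theta: np.ndarray, p: int) -> np.ndarray:
    """Standard errors from the fixed-effect block of the numeric Hessian."""
    h = 1e-4 * (1.0 + np.abs(theta[:p]))
    H = np.zeros((p, p))
    f0 = obj(theta)
    for i in range(p):
        ei = np.zeros_like(theta)
        ei[i] = h[i]
        H[i, i] = (obj(theta + ei) - 2 * f0 + obj(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros_like(theta)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                obj(theta + ei + ej) - obj(theta + ei - ej)
                - obj(theta - ei + ej) + obj(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def fit_hierarchical(rows: pd.DataFrame, diag_only: bool = False,
                     label: str = "") -> HierFit:
    """Mixed-effects logistic stay model for a multi-subject cohort."""
    return _fit_mixed(rows, "base", label=label, diag_only=diag_only)


def fit_comparison(rows: pd.DataFrame,
                   group: Union[Mapping, pd.Series],
                   label: str = "") -> HierFit:
    """Base model plus a ±1 group code interacted with every base term."""
    gser = pd.Series(group)
    vals = set(gser.unique())
    if not vals <= {-1, 1}:
        raise InvalidArgument("group codes must be ±1")
    if len(vals) < 2:
        raise InvalidArgument("comparison model needs both groups present")
    return _fit_mixed(rows, "comparison", group=gser, label=label)


def fit_hit_model(rows: pd.DataFrame, label: str = "") -> HierFit:
    """Base model plus the previous-trial hit contrast.

    Because a hit is only possible on a rewarded trial, the hit main
    effect is perfectly aliased with reward x hit, and transition x hit
    with the three-way interaction; the full factorial is rank-deficient
    by two.  The model therefore carries the two identifiable terms: the
    hit contrast within rewarded trials (``reward_x_hit``) and its
    transition interaction (``reward_x_transition_x_hit``).
    """
    return _fit_mixed(rows, "hit", label=label)


def extract_mbi(fit: Union[HierFit, Sequence[SubjectCoefficients], pd.DataFrame]
                ) -> pd.Series:
    """Per-subject model-based index, ordered by subject identifier."""
    if isinstance(fit, HierFit):
        coefs = fit.subject_coefficients()
        return coefs["mbi"].sort_index()
    if isinstance(fit, pd.DataFrame):
        return fit["mbi"].sort_index()
    ser = pd.Series({c.subject: c.mbi for c in fit})
    ser.index.name = "subject"
    return ser.sort_index()


def write_stay_csv(rows: pd.DataFrame, path) -> None:
    cols = [c for c in STAY_COLUMNS if c in rows.columns]
    rows[cols].to_csv(path, index=False)


def read_stay_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject", "stay", "prev_reward", "prev_transition"} - set(df.columns)
    if missing:
        raise InvalidArgument(f"stay-row CSV missing columns: {sorted(missing)}")
    return df
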