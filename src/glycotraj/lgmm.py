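"""Latent growth mixture model for 24-h glucose trajectories.

Fits a K-class finite mixture of quadratic growth curves to short
longitudinal glucose profiles by EM. Within class k, patient i's readings
follow

    y_it = b0_k + b1_k * t + b2_k * t^2 + b_i + eps_it,

with a shared random intercept ``b_i ~ N(0, sigma_b^2)`` and residual
``eps ~ N(0, sigma^2)``; the patient-level marginal is multivariate normal
with covariance ``sigma_b^2 J + sigma^2 I`` on the patient's time grid.

The EM treats both the class label and the random intercept as latent:
the E-step computes class responsibilities from the marginal likelihood
plus the conditional mean/variance of ``b_i``; the M-step updates mixing
proportions, class curves (responsibility-weighted least squares on the
intercept-corrected readings), and both variance components in closed form.
The observed-data log-likelihood is therefore non-decreasing across
iterations, which the fitter asserts.

Class enumeration follows the conventional four-condition protocol:
information criteria (smallest BIC/AIC, largest log-likelihood) among the
candidate K that keep relative entropy > 0.7, every class at >= 1% of the
cohort, and every class's average posterior probability > 70%.

Numerical choices: time is centered at 12 h and scaled by 12 for
conditioning (coefficients are reported back on the hour scale);
initialization clusters per-patient OLS quadratic coefficients with
k-means, with random-responsibility restarts; convergence is a relative
log-likelihood change below 1e-6 (at most 1000 iterations; variance
components near the sigma_b^2 = 0 boundary converge slowly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

TIME_CENTER_H = 12.0
TIME_SCALE_H = 12.0

#: scaled basis -> hour basis for quadratic coefficients:
#: g = a + b u + c u^2 with u = (t - 12) / 12
_SCALED_TO_HOURS = np.array([
    [1.0, -1.0, 1.0],
    [0.0, 1.0 / 12.0, -1.0 / 6.0],
    [0.0, 0.0, 1.0 / 144.0],
])


class ConvergenceError(RuntimeError):
    """EM failed to converge in every restart; carries the best partial fit."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class TrajectoryModel:
    """A fitted K-class quadratic growth mixture."""

    n_classes: int
    coefficients: np.ndarray        # (K, 3) on the hour scale: b0, b1, b2
    coefficient_se: np.ndarray      # (K, 3) Wald SEs on the hour scale
    mixing_proportions: np.ndarray  # (K,)
    random_intercept_var: float
    residual_var: float
    log_likelihood: float
    aic: float
    bic: float
    entropy: float
    posteriors: np.ndarray          # (N, K)
    map_class: np.ndarray           # (N,) 1-based
    class_shares: np.ndarray        # (K,) MAP shares
    mean_posterior: np.ndarray      # (K,) mean MAP-member posterior
    patient_ids: list
    n_patients: int
    n_parameters: int
    converged: bool
    n_iter: int
    ll_trace: np.ndarray = field(repr=False, default=None)
    degenerate_restarts: int = 0


def _prepare_patterns(glucose_long: pd.DataFrame):
    """Group patients by identical time grids for vectorized E/M steps."""
    patterns = {}
    patient_ids = []
    for pid, grp in glucose_long.groupby("patient_id", sort=True):
        t = grp["time_h"].to_numpy(dtype=float)
        y = grp["glucose_mgdl"].to_numpy(dtype=float)
        order = np.argsort(t)
        t, y = t[order], y[order]
        if t.size < 3:
            raise ValueError(f"patient {pid!r} has {t.size} readings; "
                             "trajectory fitting needs >= 3")
        key = tuple(np.round(t, 6))
        patterns.setdefault(key, {"ys": [], "rows": []})
        patterns[key]["ys"].append(y)
        patterns[key]["rows"].append(len(patient_ids))
        patient_ids.append(pid)
    out = []
    for key, d in patterns.items():
        t = np.asarray(key)
        u = (t - TIME_CENTER_H) / TIME_SCALE_H
        X = np.column_stack([np.ones_like(u), u, u * u])
        out.append({
            "X": X, "t": t,
            "Y": np.vstack(d["ys"]),
            "rows": np.asarray(d["rows"], dtype=int),
        })
    return out, patient_ids


def _e_step(patterns, beta, pi, s2b, s2, n_total, k_classes):
    """Log joint densities, responsibilities and intercept posteriors."""
    logf = np.empty((n_total, k_classes))
    mu_b = np.empty((n_total, k_classes))
    v_b = np.empty(n_total)
    for pat in patterns:
        X, Y, rows = pat["X"], pat["Y"], pat["rows"]
        n = X.shape[0]
        denom = s2 + n * s2b
        c = s2b / denom if denom > 0 else 0.0
        logdet = n * np.log(s2) + np.log(denom / s2)
        v = s2b * s2 / denom if denom > 0 else 0.0
        v_b[rows] = v
        for k in range(k_classes):
            R = Y - (X @ beta[k])[None, :]           # (m, n)
            rs = R.sum(axis=1)
            q = (np.einsum("ij,ij->i", R, R) - c * rs * rs) / s2
            logf[rows, k] = (np.log(pi[k] + 1e-300)
                             - 0.5 * (n * np.log(2 * np.pi) + logdet + q))
            mu_b[rows, k] = s2b * rs / denom
    ll_i = logsumexp(logf, axis=1)
    w = np.exp(logf - ll_i[:, None])
    return float(ll_i.sum()), w, mu_b, v_b


def _m_step(patterns, w, mu_b, v_b, k_classes, estimate_s2b):
    n_total = w.shape[0]
    pi = w.mean(axis=0)
    beta = np.empty((k_classes, 3))
    # weighted OLS per class on intercept-corrected readings
    for k in range(k_classes):
        A = np.zeros((3, 3))
        rhs = np.zeros(3)
        for pat in patterns:
            X, Y, rows = pat["X"], pat["Y"], pat["rows"]
            wk = w[rows, k]
            A += (X.T @ X) * wk.sum()
            Z = Y - mu_b[rows, k][:, None]
            rhs += X.T @ (wk @ Z)
        beta[k] = np.linalg.solve(A, rhs)
    # variance components
    num_b = float((w * (mu_b**2 + v_b[:, None])).sum())
    s2b = num_b / n_total if estimate_s2b else 0.0
    num_e, den_e = 0.0, 0.0
    for pat in patterns:
        X, Y, rows = pat["X"], pat["Y"], pat["rows"]
        n = X.shape[0]
        for k in range(k_classes):
            R = Y - (X @ beta[k])[None, :] - mu_b[rows, k][:, None]
            num_e += float(w[rows, k] @ (np.einsum("ij,ij->i", R, R)
                                         + n * v_b[rows]))
        den_e += n * len(rows)
    s2 = num_e / den_e
    return pi, beta, max(s2b, 0.0), max(s2, 1e-8)


def _initial_responsibilities(patterns, n_total, k_classes, rng, mode):
    if mode == "kmeans":
        from sklearn.cluster import KMeans
        coefs = np.empty((n_total, 3))
        for pat in patterns:
            X, Y, rows = pat["X"], pat["Y"], pat["rows"]
            B = np.linalg.lstsq(X, Y.T, rcond=None)[0]   # (3, m)
            coefs[rows] = B.T
        std = coefs.std(axis=0)
        std[std == 0] = 1.0
        labels = KMeans(n_clusters=k_classes, n_init=5,
                        random_state=int(rng.integers(2**31))
                        ).fit_predict(coefs / std)
        w = np.full((n_total, k_classes), 0.05 / max(k_classes - 1, 1))
        w[np.arange(n_total), labels] = 0.95
        if k_classes == 1:
            w[:] = 1.0
        return w
    w = rng.dirichlet(np.ones(k_classes), size=n_total)
    return w


def _run_em(patterns, n_total, k_classes, w0, estimate_s2b, max_iter, tol):
    mu_b = np.zeros((n_total, k_classes))
    v_b = np.zeros(n_total)
    pi, beta, s2b, s2 = _m_step(patterns, w0, mu_b, v_b, k_classes, estimate_s2b)
    if estimate_s2b and s2b < 1e-8:
        s2b = s2 / 2  # initial split of total variance
    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        ll, w, mu_b, v_b = _e_step(patterns, beta, pi, s2b, s2, n_total, k_classes)
        if ll + 1e-6 * (1 + abs(ll)) < prev:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev:.8f} -> {ll:.8f}")
        trace.append(ll)
        if np.any(pi < 1e-6):
            return None, np.asarray(trace)  # degenerate class, caller restarts
        if prev > -np.inf and abs(ll - prev) < tol * abs(prev):
            converged = True
            prev = ll
            break
        prev = ll
        pi, beta, s2b_new, s2 = _m_step(patterns, w, mu_b, v_b, k_classes,
                                        estimate_s2b)
        s2b = s2b_new
    state = {"pi": pi, "beta": beta, "s2b": s2b, "s2": s2, "ll": prev,
             "w": w, "converged": converged, "n_iter": len(trace)}
    return state, np.asarray(trace)


def compute_entropy(posteriors: np.ndarray) -> float:
    """Relative entropy 1 - sum(-p log p) / (N log K), in [0, 1].

    1 means perfectly crisp assignment, 0 uniform posteriors. With K = 1
    the measure is defined as 1 by convention.
    """
    p = np.asarray(posteriors, dtype=float)
    n, k = p.shape
    if k == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(k)))


def _finalize(state, patterns, patient_ids, k_classes, trace, degenerate):
    pi, beta_u = state["pi"], state["beta"]
    s2b, s2, ll, w = state["s2b"], state["s2"], state["ll"], state["w"]
    n_total = len(patient_ids)
    # stable reporting order: descending mixing proportion
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    beta_u = beta_u[order]
    w = w[:, order]

    # Wald SEs from the weighted GLS information, per class
    se_u = np.empty_like(beta_u)
    for k in range(k_classes):
        info = np.zeros((3, 3))
        for pat in patterns:
            X, rows = pat["X"], pat["rows"]
            n = X.shape[0]
            denom = s2 + n * s2b
            Vinv = (np.eye(n) - (s2b / denom) * np.ones((n, n))) / s2
            info += w[rows, k].sum() * (X.T @ Vinv @ X)
        cov_u = np.linalg.inv(info)
        se_u[k] = np.sqrt(np.diag(_SCALED_TO_HOURS @ cov_u @ _SCALED_TO_HOURS.T))
    beta_h = (_SCALED_TO_HOURS @ beta_u.T).T

    map_class = np.argmin(-w, axis=1)  # argmax with ties to the lower index
    shares = np.array([(map_class == k).mean() for k in range(k_classes)])
    mean_post = np.array([w[map_class == k, k].mean() if (map_class == k).any()
                          else np.nan for k in range(k_classes)])
    p = 3 * k_classes + (k_classes - 1) + 2
    return TrajectoryModel(
        n_classes=k_classes,
        coefficients=beta_h,
        coefficient_se=se_u,
        mixing_proportions=pi,
        random_intercept_var=s2b,
        residual_var=s2,
        log_likelihood=ll,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n_total),
        entropy=compute_entropy(w),
        posteriors=w,
        map_class=map_class + 1,
        class_shares=shares,
        mean_posterior=mean_post,
        patient_ids=list(patient_ids),
        n_patients=n_total,
        n_parameters=p,
        converged=state["converged"],
        n_iter=state["n_iter"],
        ll_trace=trace,
        degenerate_restarts=degenerate,
    )


def fit_lgmm(glucose_long: pd.DataFrame, n_classes: int, seed: int = 0,
             n_restarts: int = 3, random_intercept: bool = True,
             max_iter: int = 1000, tol: float = 1e-6) -> TrajectoryModel:
    """Fit the K-class growth mixture; best of ``n_restarts`` by final
    log-likelihood, deterministic given ``seed``.

    Restart 0 initializes from k-means on per-patient OLS quadratic
    coefficients; later restarts use random responsibilities. A restart
    that collapses a class (mixing proportion < 1e-6) is discarded and
    redrawn (counted in ``degenerate_restarts``).
    """
    if not 1 <= n_classes <= 5:
        raise ValueError("n_classes must be in 1..5")
    patterns, patient_ids = _prepare_patterns(glucose_long)
    n_total = len(patient_ids)
    rng = np.random.default_rng(seed)

    best = None
    best_trace = None
    degenerate = 0
    attempts = 0
    restarts_done = 0
    max_attempts = n_restarts + 10
    while restarts_done < max(n_restarts, 1) and attempts < max_attempts:
        mode = "kmeans" if restarts_done == 0 else "random"
        w0 = _initial_responsibilities(patterns, n_total, n_classes, rng, mode)
        state, trace = _run_em(patterns, n_total, n_classes, w0,
                               random_intercept, max_iter, tol)
        attempts += 1
        if state is None:
            degenerate += 1
            continue
        restarts_done += 1
        if best is None or state["ll"] > best["ll"]:
            best, best_trace = state, trace
    if best is None:
        raise ConvergenceError(
            f"all restarts collapsed a class for K={n_classes}")
    if not best["converged"]:
        fit = _finalize(best, patterns, patient_ids, n_classes, best_trace,
                        degenerate)
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations for K={n_classes}",
            best_fit=fit)
    return _finalize(best, patterns, patient_ids, n_classes, best_trace,
                     degenerate)


def assign_classes(model: TrajectoryModel) -> pd.DataFrame:
    """Per-patient MAP class (1-based; posterior ties break toward the
    lower class index) with its posterior probability."""
    return pd.DataFrame({
        "patient_id": model.patient_ids,
        "map_class": model.map_class,
        "posterior": model.posteriors[np.arange(model.n_patients),
                                      model.map_class - 1],
    })


@dataclass
class ClassSelectionReport:
    """Per-K fit statistics plus the four-condition gate outcomes."""

    table: pd.DataFrame
    selected_k: int | None

    @property
    def no_k_passes(self) -> bool:
        return self.selected_k is None


def select_classes(models: dict[int, TrajectoryModel], min_share: float = 0.01,
                   min_posterior: float = 0.70,
                   entropy_min: float = 0.70) -> ClassSelectionReport:
    """Apply the four-condition class-enumeration protocol.

    Candidates must have relative entropy > ``entropy_min``, every class
    share >= ``min_share`` of the cohort, and every class's average
    posterior > ``min_posterior``; among survivors the smallest BIC wins
    (ties: smaller AIC, then larger K; the largest-log-likelihood condition
    is monotone-equivalent to these information criteria across K).
    """
    rows = []
    for k in sorted(models):
        m = models[k]
        pass_entropy = m.entropy > entropy_min
        pass_share = bool(np.all(m.class_shares >= min_share))
        pass_post = bool(np.all(m.mean_posterior > min_posterior))
        rows.append({
            "n_classes": k, "log_likelihood": m.log_likelihood,
            "aic": m.aic, "bic": m.bic, "entropy": m.entropy,
            "min_class_share": float(m.class_shares.min()),
            "min_mean_posterior": float(np.nanmin(m.mean_posterior)),
            "pass_entropy": pass_entropy, "pass_share": pass_share,
            "pass_posterior": pass_post,
            "pass_all": pass_entropy and pass_share and pass_post,
        })
    table = pd.DataFrame(rows)
    survivors = table[table["pass_all"]]
    if survivors.empty:
        return ClassSelectionReport(table=table, selected_k=None)
    ranked = survivors.sort_values(["bic", "aic", "n_classes"],
                                   ascending=[True, True, False],
                                   kind="stable")
    return ClassSelectionReport(table=table,
                                selected_k=int(ranked["n_classes"].iloc[0]))
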