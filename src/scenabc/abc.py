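"""ABC engine: rejection with robust standardization, logistic-regression
model choice with delta-method confidence intervals, local-linear-regression
parameter adjustment, POD error rates, and posterior-predictive model
checking.

The rejection step scales every statistic by its reference median absolute
deviation (falling back to the standard deviation when the MAD is zero) and
keeps the ``ceil(delta * n)`` rows closest to the observed vector in
Euclidean distance, weighted by an Epanechnikov kernel on distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coalsim.dataset import simulate_dataset
from .coalsim.reftable import PARAM_COLUMNS, ReferenceTable
from .coalsim.priors import PriorSpec, sample_priors

logger = logging.getLogger(__name__)

__all__ = [
    "Rejection",
    "standardize_and_reject",
    "ModelChoiceResult",
    "model_choice",
    "ParameterPosterior",
    "estimate_parameters",
    "ConfusionErrors",
    "pods_error_rates",
    "ModelCheckReport",
    "model_check",
]


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


@dataclass
class Rejection:
    indices: np.ndarray  # accepted row indices, sorted by distance
    distances: np.ndarray
    weights: np.ndarray  # Epanechnikov, max-normalized
    scale: np.ndarray  # per-statistic scale used
    kept_stats: np.ndarray  # boolean mask of statistics retained
    delta: float


def _robust_scale(stats: np.ndarray) -> np.ndarray:
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = stats.std(axis=0)
    return np.where(mad > 0, mad, sd)


def standardize_and_reject(
    stats: np.ndarray, observed: np.ndarray, delta: float
) -> Rejection:
    """Select the fraction ``delta`` of reference rows closest to
    ``observed``.

    Statistics constant across the table are dropped (with a log note when
    the observed value falls outside the constant); remaining ones are
    scaled by MAD (SD fallback).
    """
    stats = np.asarray(stats, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if stats.ndim != 2 or observed.shape != (stats.shape[1],):
        raise ValueError("observed length must equal the table's stat width")
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    scale = _robust_scale(stats)
    keep = scale > 0
    if not keep.all():
        off = np.flatnonzero(~keep)
        mismatched = [int(i) for i in off if observed[i] != stats[0, i]]
        if mismatched:
            logger.warning(
                "constant statistics %s differ from the observed value; dropped",
                mismatched,
            )
        else:
            logger.info("constant statistics %s dropped", off.tolist())
    z = (stats[:, keep] - observed[keep]) / scale[keep]
    dist = np.sqrt((z**2).sum(axis=1))
    n_keep = int(np.ceil(delta * stats.shape[0]))
    order = np.argsort(dist, kind="stable")[:n_keep]
    d = dist[order]
    d_max = d[-1] if d[-1] > 0 else 1.0
    weights = 1.0 - (d / d_max) ** 2
    if weights.max() <= 0:  # all accepted rows at identical distance
        weights = np.ones_like(weights)
    return Rejection(indices=order, distances=d, weights=weights, scale=scale,
                     kept_stats=keep, delta=delta)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    scenarios: list[str]
    direct: dict[str, float]  # vote shares among accepted rows
    logistic: dict[str, float]
    logistic_ci: dict[str, tuple[float, float]]
    delta: float
    n_accepted: int
    distances: dict[str, float] = field(default_factory=dict)
    fallback: bool = False  # True when logistic fit failed -> direct copied

    @property
    def best(self) -> str:
        return max(self.logistic, key=self.logistic.get)


def _multinomial_logit_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                           n_classes: int, ridge: float = 1e-6):
    """Weighted multinomial logistic regression (class 0 as baseline).

    Returns (B, cov) with B of shape (n_classes-1, p+1) including the
    intercept column first, and cov the inverse Hessian at the optimum
    (ridge-regularized NLL).
    """
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    k1 = n_classes - 1
    y_onehot = np.zeros((n, n_classes))
    y_onehot[np.arange(n), y] = 1.0

    def unpack(beta):
        return beta.reshape(k1, p + 1)

    def nll_grad(beta):
        B = unpack(beta)
        eta = Xd @ B.T  # (n, k1)
        eta_full = np.hstack([np.zeros((n, 1)), eta])
        m = eta_full.max(axis=1, keepdims=True)
        logz = m[:, 0] + np.log(np.exp(eta_full - m).sum(axis=1))
        probs = np.exp(eta_full - logz[:, None])
        ll = (w * (np.take_along_axis(eta_full, y[:, None], axis=1)[:, 0] - logz)).sum()
        resid = probs[:, 1:] - y_onehot[:, 1:]  # (n, k1)
        grad = (resid * w[:, None]).T @ Xd  # (k1, p+1)
        pen = ridge * beta
        return (-ll + 0.5 * ridge * (beta**2).sum(),
                grad.ravel() + pen)

    beta0 = np.zeros(k1 * (p + 1))
    res = minimize(nll_grad, beta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "maxfun": 10000, "gtol": 1e-7})
    B = unpack(res.x)

    # Hessian of the weighted NLL at the optimum
    eta = Xd @ B.T
    eta_full = np.hstack([np.zeros((n, 1)), eta])
    m = eta_full.max(axis=1, keepdims=True)
    probs = np.exp(eta_full - m)
    probs /= probs.sum(axis=1, keepdims=True)
    dim = k1 * (p + 1)
    H = np.zeros((dim, dim))
    for a in range(k1):
        for b in range(k1):
            pa = probs[:, a + 1]
            pb = probs[:, b + 1]
            wab = w * (pa * ((a == b) - pb))
            block = Xd.T @ (Xd * wab[:, None])
            H[a * (p + 1):(a + 1) * (p + 1), b * (p + 1):(b + 1) * (p + 1)] = block
    H += ridge * np.eye(dim)
    cov = np.linalg.pinv(H)
    return B, cov, bool(res.success)


def model_choice(
    table: ReferenceTable,
    observed: np.ndarray,
    delta: float = 0.01,
    rng_seed: int = 0,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by rejection vote share and by
    multinomial logistic regression of the scenario indicator on the
    (accepted) centered summary statistics, evaluated at zero offset.

    95% CIs come from the delta method on the softmax of the regression
    intercepts.  On a failed or separated fit the direct estimate is
    returned for both (flagged ``fallback``).
    """
    del rng_seed  # deterministic; kept for interface stability
    scen_names = table.scenarios
    if len(scen_names) < 2:
        raise ValueError("model choice needs at least 2 scenarios in the table")
    stats = table.stats_matrix()
    rej = standardize_and_reject(stats, observed, delta)
    labels = table.data["scenario"].to_numpy()
    acc_labels = labels[rej.indices]
    wsum = rej.weights.sum()
    direct = {
        s: float(rej.weights[acc_labels == s].sum() / wsum) for s in scen_names
    }

    y = np.array([scen_names.index(s) for s in acc_labels])
    X = (stats[rej.indices][:, rej.kept_stats] - observed[rej.kept_stats])
    X = X / np.where(rej.scale[rej.kept_stats] > 0, rej.scale[rej.kept_stats], 1.0)
    # with few accepted rows the full predictor set separates; project onto
    # leading principal components (keeps the regression well-posed while
    # preserving the local geometry around the observed point)
    n_acc, p = X.shape
    if n_acc < 5 * p:
        n_comp = int(np.clip(n_acc // 5, 2, p))
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        proj = vt[:n_comp].T
        X = X @ proj
    k = len(scen_names)
    fallback = False
    try:
        present = np.unique(y)
        if present.size < 2:
            raise RuntimeError("only one scenario among accepted rows")
        # mild ridge scaled with the accepted mass keeps the fit finite under
        # (near-)separation without visibly biasing well-supported posteriors
        ridge = max(1e-6, 1e-3 * float(rej.weights.sum()))
        B, cov, ok = _multinomial_logit_fit(X, y, rej.weights, k, ridge=ridge)
        if not ok:
            raise RuntimeError("logistic fit did not converge")
        intercepts = np.concatenate([[0.0], B[:, 0]])
        expb = np.exp(intercepts - intercepts.max())
        probs = expb / expb.sum()
        # delta method on softmax wrt the k-1 free intercepts
        p1 = probs[1:]
        J = np.zeros((k, k - 1))
        for i in range(k):
            for j in range(k - 1):
                J[i, j] = probs[i] * ((1.0 if i == j + 1 else 0.0) - p1[j])
        p_plus_1 = X.shape[1] + 1
        idx = [j * p_plus_1 for j in range(k - 1)]
        cov_b = cov[np.ix_(idx, idx)]
        var_p = np.clip(np.diag(J @ cov_b @ J.T), 0.0, None)
        se = np.sqrt(var_p)
        logistic = {s: float(probs[i]) for i, s in enumerate(scen_names)}
        ci = {
            s: (float(np.clip(probs[i] - 1.96 * se[i], 0.0, 1.0)),
                float(np.clip(probs[i] + 1.96 * se[i], 0.0, 1.0)))
            for i, s in enumerate(scen_names)
        }
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        logger.warning("logistic model choice failed (%s); using direct estimate",
                       exc)
        fallback = True
        logistic = dict(direct)
        ci = {s: (max(0.0, v - 0.0), min(1.0, v + 0.0)) for s, v in direct.items()}

    return ModelChoiceResult(
        scenarios=scen_names,
        direct=direct,
        logistic=logistic,
        logistic_ci=ci,
        delta=delta,
        n_accepted=len(rej.indices),
        distances={"min": float(rej.distances.min()),
                   "max": float(rej.distances.max())},
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


@dataclass
class ParameterPosterior:
    parameters: list[str]
    prior_ranges: dict[str, tuple[float, float]]
    samples: dict[str, np.ndarray]
    weights: np.ndarray
    summaries: dict[str, dict[str, float]]  # mean, median, q025, q050, q950, q975


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    x = x[order]
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return np.interp(qs, cw, x)


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    delta: float = 0.01,
    scenario: str | None = None,
    parameters: list[str] | None = None,
    min_accepted: int = 200,
) -> ParameterPosterior:
    """Local-linear-regression adjusted posterior for the (winning)
    scenario's parameters.

    Each parameter is logit-transformed to its prior range, adjusted by a
    weighted linear regression on the centered statistics (keeping the
    fitted value at the observed point plus residuals), then
    back-transformed — guaranteeing adjusted draws stay inside the prior.
    A singular regression falls back to ridge (penalty 1e-6) with a log
    note.
    """
    df = table.data
    if scenario is not None:
        df = df[df["scenario"] == scenario].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"scenario {scenario!r} absent from table")
    stats = df[table.stat_names].to_numpy(dtype=float)
    rej = standardize_and_reject(stats, observed, delta)
    if len(rej.indices) < min_accepted:
        raise ValueError(
            f"only {len(rej.indices)} accepted rows; need >= {min_accepted}"
        )
    if parameters is None:
        prior_meta = table.meta.get("prior", {})
        parameters = [p for p in table.param_names
                      if p in prior_meta and df[p].nunique() > 1]
    X = (stats[rej.indices][:, rej.kept_stats] - observed[rej.kept_stats])
    X = X / np.where(rej.scale[rej.kept_stats] > 0, rej.scale[rej.kept_stats], 1.0)
    w = rej.weights
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])

    prior_meta = table.meta.get("prior", {})
    samples: dict[str, np.ndarray] = {}
    summaries: dict[str, dict[str, float]] = {}
    ranges: dict[str, tuple[float, float]] = {}
    eps = 1e-9
    for p in parameters:
        lo, hi = prior_meta.get(p, (float(df[p].min()), float(df[p].max())))
        lo, hi = float(lo), float(hi)
        ranges[p] = (lo, hi)
        theta = df[p].to_numpy(dtype=float)[rej.indices]
        u = np.clip((theta - lo) / (hi - lo), eps, 1.0 - eps)
        z = np.log(u / (1.0 - u))
        WX = Xd * w[:, None]
        A = Xd.T @ WX
        b = WX.T @ z
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            logger.warning("singular local-linear system for %s; ridge fallback", p)
            coef = np.linalg.solve(A + 1e-6 * np.eye(A.shape[0]), b)
        fitted = Xd @ coef
        z_adj = coef[0] + (z - fitted)  # prediction at observed + residuals
        u_adj = 1.0 / (1.0 + np.exp(-z_adj))
        theta_adj = lo + (hi - lo) * u_adj
        samples[p] = theta_adj
        qs = _weighted_quantile(theta_adj, w, [0.025, 0.05, 0.5, 0.95, 0.975])
        summaries[p] = {
            "mean": float(np.average(theta_adj, weights=w)),
            "median": float(qs[2]),
            "q025": float(qs[0]),
            "q050": float(qs[1]),
            "q950": float(qs[3]),
            "q975": float(qs[4]),
        }
    return ParameterPosterior(parameters=list(parameters), prior_ranges=ranges,
                              samples=samples, weights=w, summaries=summaries)


# ---------------------------------------------------------------------------
# POD error rates
# ---------------------------------------------------------------------------


@dataclass
class ConfusionErrors:
    focal: str
    n_pods: dict[str, int]
    type_i: float  # P(focal not selected | focal true)
    type_ii: float  # P(focal selected | other true)
    confusion: dict[str, dict[str, int]]  # true -> selected -> count
    n_failed: int = 0


def pods_error_rates(
    scenarios,
    prior: PriorSpec,
    config,
    loci,
    n_pods: int,
    table: ReferenceTable,
    delta: float = 0.01,
    rng_seed: int = 0,
    focal: str | None = None,
) -> ConfusionErrors:
    """Scenario-choice error rates from pseudo-observed datasets.

    ``n_pods`` datasets are simulated per scenario from the prior; each is
    pushed through :func:`model_choice` against ``table`` and the scenario
    with the highest logistic posterior (direct estimate on ties) is
    selected.  Type I = fraction of focal-scenario PODs where the focal
    scenario is not selected; Type II = fraction of other-scenario PODs
    where it is.
    """
    names = [s.name for s in scenarios]
    focal = focal or names[0]
    confusion: dict[str, dict[str, int]] = {t: {s: 0 for s in names} for t in names}
    counts = {s: 0 for s in names}
    failed = 0
    for si, scen in enumerate(scenarios):
        for ri in range(n_pods):
            ss = np.random.SeedSequence(entropy=rng_seed,
                                        spawn_key=(1000 + si, ri))
            rng = np.random.default_rng(ss)
            try:
                params = sample_priors(prior, scen, rng)
                n_ms = sum(1 for l in loci if l.kind == "microsat")
                rates = rng.gamma(2.0, params["mu_ms"] / 2.0, size=n_ms)
                sim = simulate_dataset(scen, params, config, loci, rng,
                                       msat_rates=rates)
                obs = sim.summary_vector()
                mc = model_choice(table, obs, delta)
                order = sorted(
                    names,
                    key=lambda s: (mc.logistic[s], mc.direct[s], -names.index(s)),
                    reverse=True,
                )
                selected = order[0]
            except Exception as exc:
                logger.warning("POD (%s, %d) failed: %s", scen.name, ri, exc)
                failed += 1
                continue
            confusion[scen.name][selected] += 1
            counts[scen.name] += 1

    n_focal = counts[focal]
    type_i = (1.0 - confusion[focal][focal] / n_focal) if n_focal else float("nan")
    n_other = sum(counts[s] for s in names if s != focal)
    wrong = sum(confusion[s][focal] for s in names if s != focal)
    type_ii = wrong / n_other if n_other else float("nan")
    return ConfusionErrors(focal=focal, n_pods=counts, type_i=float(type_i),
                           type_ii=float(type_ii), confusion=confusion,
                           n_failed=failed)


# ---------------------------------------------------------------------------
# model checking
# ---------------------------------------------------------------------------


@dataclass
class ModelCheckReport:
    stat_names: list[str]
    pca_explained: np.ndarray
    prior_coords: np.ndarray  # (n_table, 2)
    posterior_coords: np.ndarray  # (n_pp, 2)
    observed_coords: np.ndarray  # (2,)
    tail_probabilities: dict[str, float]
    n_pp: int


def model_check(
    table: ReferenceTable,
    posterior: ParameterPosterior,
    observed: np.ndarray,
    scenario,
    config,
    loci,
    n_pp: int = 200,
    rng_seed: int = 0,
) -> ModelCheckReport:
    """Posterior-predictive check: simulate ``n_pp`` datasets from posterior
    draws, project prior / posterior-predictive / observed summary vectors
    on a PCA fitted to the prior simulations, and report per-statistic
    two-sided tail probabilities of the observed values."""
    from sklearn.decomposition import PCA

    if n_pp < 100:
        logger.warning("n_pp=%d < 100: tail probabilities will be unstable", n_pp)
    rng = np.random.default_rng(rng_seed)
    stats = table.stats_matrix()
    scale = _robust_scale(stats)
    keep = scale > 0
    z = (stats[:, keep] - stats[:, keep].mean(axis=0)) / scale[keep]
    pca = PCA(n_components=2)
    prior_coords = pca.fit_transform(z)

    w = posterior.weights / posterior.weights.sum()
    n_acc = len(w)
    pp_stats = np.empty((n_pp, stats.shape[1]))
    for i in range(n_pp):
        j = rng.choice(n_acc, p=w)
        params = {p: float(posterior.samples[p][j]) for p in posterior.parameters}
        # parameters are adjusted marginally, so a joint draw may violate the
        # t1 < t2 < t3 ordering; restore it by sorting the split times
        tkeys = [t for t in ("t1", "t2", "t3") if t in params]
        for key, val in zip(tkeys, sorted(params[t] for t in tkeys)):
            params[key] = val
        for p in PARAM_COLUMNS:
            params.setdefault(p, 0.0)
        if params.get("r", 0.0) <= 0.0 or params.get("r", 0.0) >= 1.0:
            params["r"] = 0.5  # unused by merge-only scenarios
        n_ms = sum(1 for l in loci if l.kind == "microsat")
        rates = rng.gamma(2.0, max(params["mu_ms"], 1e-12) / 2.0, size=n_ms)
        sim = simulate_dataset(scenario, params, config, loci, rng,
                               msat_rates=rates)
        pp_stats[i] = sim.summary_vector()

    def project(mat):
        zz = (mat[:, keep] - stats[:, keep].mean(axis=0)) / scale[keep]
        return pca.transform(zz)

    posterior_coords = project(pp_stats)
    observed_coords = project(observed[None, :])[0]

    tails: dict[str, float] = {}
    for k, name in enumerate(table.stat_names):
        col = pp_stats[:, k]
        lo = ((col <= observed[k]).sum() + 1) / (n_pp + 1)
        hi = ((col >= observed[k]).sum() + 1) / (n_pp + 1)
        tails[name] = float(min(1.0, 2.0 * min(lo, hi)))

    return ModelCheckReport(
        stat_names=list(table.stat_names),
        pca_explained=pca.explained_variance_ratio_,
        prior_coords=prior_coords,
        posterior_coords=posterior_coords,
        observed_coords=observed_coords,
        tail_probabilities=tails,
        n_pp=n_pp,
    )
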