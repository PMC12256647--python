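"""Univariate Gaussian mixture modeling of soma sizes with BIC selection.

The soma-size workflow: (1) derive a glia-exclusion cutoff from the GABA+
size distribution (the lower percentile above which almost all genuine
interneurons lie — small profiles below it are glial); (2) drop cells below
the cutoff; (3) fit univariate normal mixtures by EM for a range of
component counts K; (4) select K by the highest BIC under the convention

    BIC = 2·logL − p·ln(n),   p = 3K − 1 (unequal variances) or 2K (equal),

so that *larger* BIC means a better model (this matches model-based
clustering packages that "maximize BIC"); (5) classify every cell to its
maximum-posterior component.

EM details: components are initialized at evenly spaced quantiles of the
data with the pooled SD and uniform weights; five additional seeded random
restarts are run per K and the best log-likelihood kept. Convergence is a
relative log-likelihood change below ``tol``. A component whose SD collapses
below 1e-6 of the data SD triggers a restart; persistent collapse is an
error. Components are always reported sorted by ascending mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureFit",
    "derive_glia_cutoff",
    "exclude_small_cells",
    "fit_gmm",
    "select_by_bic",
    "classify_cells",
]

logger = logging.getLogger(__name__)

_COLLAPSE_FRACTION = 1e-6
_N_RESTARTS = 5


class DegenerateDataError(ValueError):
    """Raised when the data cannot support a mixture fit."""


@dataclass
class MixtureFit:
    """A converged (or best-effort) univariate normal mixture.

    Components are sorted by ascending mean. ``responsibilities`` has shape
    (n_obs, K) with rows summing to 1, in ascending order of the *sorted*
    training data (use :func:`classify_cells` for arbitrary-order inputs);
    ``loglik_trace`` records the log-likelihood after every EM iteration of
    the winning run.
    """

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    variance_model: str
    responsibilities: np.ndarray = field(repr=False, default=None)
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        k = self.n_components
        return 3 * k - 1 if self.variance_model == "unequal" else 2 * k

    def component_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(self.n_components),
                "weight": self.weights,
                "mean_um2": self.means,
                "sd_um2": self.sds,
            }
        )


def derive_glia_cutoff(gaba_positive_areas, percentile: float = 1.0) -> float:
    """Lower percentile of GABA+ soma areas: the size above which
    (100 − percentile)% of genuine GABAergic cells lie. Linear-interpolation
    percentile convention."""
    areas = np.asarray(gaba_positive_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("no GABA+ areas supplied")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly in (0, 100)")
    return float(np.percentile(areas, percentile))


def exclude_small_cells(dataset: pd.DataFrame, cutoff: float = 40.0) -> pd.DataFrame:
    """Retain cells with ``area_um2 >= cutoff``; smaller profiles are treated
    as glial and excluded (the count is logged)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keep = dataset["area_um2"] >= cutoff
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d cells below %.3g μm² as presumed glia", n_excluded, cutoff)
    if keep.sum() == 0:
        logger.warning("all %d cells fall below the %.3g μm² cutoff", len(dataset), cutoff)
    return dataset.loc[keep].copy()


_LOG_2PI = np.log(2.0 * np.pi)


def _log_density(x: np.ndarray, weights, means, sds) -> np.ndarray:
    """(n, K) matrix of log(w_k) + log N(x | μ_k, σ_k)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - 0.5 * (z * z + _LOG_2PI) - np.log(sds)[None, :]


def _em_run(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    variance_model: str,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    n = x.size
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        log_joint = _log_density(x, weights, means, sds)
        log_norm = np.logaddexp.reduce(log_joint, axis=1)
        loglik = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        trace.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * abs(prev):
            converged = True
            break
        prev = loglik
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if variance_model == "equal":
            sds = np.full_like(means, np.sqrt(sq.sum() / n))
        else:
            sds = np.sqrt(sq / nk)
        if np.any(sds < sd_floor) or np.any(~np.isfinite(sds)):
            raise _ComponentCollapse()
    return weights, means, sds, resp, trace, converged


class _ComponentCollapse(RuntimeError):
    pass


def fit_gmm(
    areas,
    n_components: int,
    *,
    variance_model: str = "unequal",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a K-component univariate normal mixture by EM.

    Deterministic for a fixed seed. Requires n >= 5·K observations and
    non-degenerate data (overall SD > 0). Returns the best of the quantile
    initialization plus five seeded random restarts.
    """
    x = np.sort(np.asarray(areas, dtype=float))
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 5 * k:
        raise ValueError(f"need at least {5 * k} observations for K={k}, got {x.size}")
    if variance_model not in ("equal", "unequal"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    data_sd = x.std(ddof=0)
    if data_sd == 0:
        raise DegenerateDataError("all observations identical: mixture fit undefined")
    sd_floor = _COLLAPSE_FRACTION * data_sd
    rng = np.random.default_rng(seed)

    inits = []
    # deterministic quantile-based start
    q = (np.arange(k) + 0.5) / k
    inits.append((np.full(k, 1.0 / k), np.quantile(x, q), np.full(k, data_sd)))
    for _ in range(_N_RESTARTS):
        centers = rng.choice(x, size=k, replace=False) if x.size >= k else np.quantile(x, q)
        inits.append(
            (
                np.full(k, 1.0 / k),
                np.sort(centers),
                np.full(k, data_sd * rng.uniform(0.5, 1.5)),
            )
        )

    best = None
    failures = 0
    for w0, m0, s0 in inits:
        try:
            w, m, s, resp, trace, conv = _em_run(
                x, w0.copy(), m0.astype(float).copy(), s0.copy(),
                variance_model, tol, max_iter, sd_floor,
            )
        except _ComponentCollapse:
            failures += 1
            continue
        if best is None or trace[-1] > best[4][-1]:
            best = (w, m, s, resp, trace, conv)
    if best is None:
        raise DegenerateDataError(
            f"all {len(inits)} EM starts collapsed for K={k}; data cannot support the model"
        )
    w, m, s, resp, trace, conv = best
    order = np.argsort(m)
    loglik = trace[-1]
    n_params = 3 * k - 1 if variance_model == "unequal" else 2 * k
    bic = 2.0 * loglik - n_params * np.log(x.size)
    return MixtureFit(
        n_components=k,
        weights=w[order],
        means=m[order],
        sds=s[order],
        log_likelihood=loglik,
        bic=float(bic),
        converged=conv,
        n_iter=len(trace),
        variance_model=variance_model,
        responsibilities=resp[:, order],
        loglik_trace=np.asarray(trace),
    )


def select_by_bic(
    areas,
    *,
    k_range=range(1, 10),
    variance_model: str = "unequal",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit every K in ``k_range`` and return the converged fit with the
    highest BIC, plus the full BIC table (columns: n_components, bic,
    log_likelihood, converged)."""
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    fits: dict[int, MixtureFit] = {}
    rows = []
    for k in ks:
        try:
            fit = fit_gmm(
                areas, k, variance_model=variance_model, seed=seed, tol=tol, max_iter=max_iter
            )
        except (ValueError, DegenerateDataError) as exc:
            logger.info("K=%d not fit: %s", k, exc)
            rows.append({"n_components": k, "bic": np.nan, "log_likelihood": np.nan, "converged": False})
            continue
        fits[k] = fit
        rows.append(
            {
                "n_components": k,
                "bic": fit.bic,
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows, columns=["n_components", "bic", "log_likelihood", "converged"])
    converged = {k: f for k, f in fits.items() if f.converged}
    if not converged:
        raise DegenerateDataError("no candidate K produced a converged fit")
    best_k = max(converged, key=lambda k: converged[k].bic)
    return converged[best_k], table


def classify_cells(fit: MixtureFit, areas) -> pd.DataFrame:
    """Maximum-posterior component for each observation; ties go to the
    lower-mean component. Returns a DataFrame with ``area_um2``, ``label``
    and one posterior column per component."""
    x = np.asarray(areas, dtype=float)
    log_joint = _log_density(x, fit.weights, fit.means, fit.sds)
    log_norm = np.logaddexp.reduce(log_joint, axis=1)
    post = np.exp(log_joint - log_norm[:, None])
    labels = post.argmax(axis=1)  # argmax takes the first max: lower-mean wins ties
    out = pd.DataFrame({"area_um2": x, "label": labels})
    for k in range(fit.n_components):
        out[f"posterior_{k}"] = post[:, k]
    return out
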