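"""Segments-of-homozygosity (SoH) estimation.

SoH is a window-based proxy for runs of homozygosity designed for
fragmented assemblies whose scaffolds are shorter than the runs
themselves. Scaffolds are cut into 20-50 kb windows, each window gets a
per-bp heterozygosity rate h_w, and a two-component Gaussian mixture is
fitted to the h_w distribution. The first component is anchored at the
low-heterozygosity tail and, because h_w cannot be negative, its normal
density is renormalized on [0, inf) by the CDF mass lost below zero —
a truncated normal. SoH is the fraction of windowed genome assigned to
that low component under posterior maximum-likelihood classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from sohscan.errors import DegenerateDataError, UndefinedValueError
from sohscan.vcfio import CallableMask, VariantRecord

logger = logging.getLogger(__name__)

MAX_WINDOW = 50_000
MIN_SCAFFOLD = 20_000
SIGMA_FLOOR = 1e-8  # guards collapse on the zero-spike of h
MIN_WINDOWS = 50


def make_windows(
    scaffolds: pd.DataFrame,
    max_len: int = MAX_WINDOW,
    min_scaffold: int = MIN_SCAFFOLD,
) -> pd.DataFrame:
    """Cut scaffolds into windows of at most `max_len` bp.

    A scaffold of length L >= max_len is split into ceil(L / max_len)
    near-equal windows (integer boundaries; the last window absorbs the
    remainder), so every window length stays within [min_scaffold,
    max_len]. A scaffold with min_scaffold <= L < max_len becomes a
    single whole-scaffold window; shorter scaffolds produce none.

    Returns a DataFrame with columns scaffold, start, end (0-based
    half-open).
    """
    rows = []
    for scaf, length in zip(scaffolds["scaffold"], scaffolds["length"]):
        length = int(length)
        if length < min_scaffold:
            continue
        if length < max_len:
            rows.append((scaf, 0, length))
            continue
        k = -(-length // max_len)  # ceil
        base = length // k
        start = 0
        for i in range(k):
            end = length if i == k - 1 else start + base
            rows.append((scaf, start, end))
            start = end
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def window_het_rates(
    windows: pd.DataFrame,
    het_records: list[VariantRecord],
    mask: CallableMask | None = None,
    min_callable_frac: float = 0.5,
) -> pd.DataFrame:
    """Attach per-window heterozygosity rates h_w.

    h_w = n_het / callable_bp when a callable mask is supplied, else
    n_het / window length. Windows with callable_bp below
    `min_callable_frac` of their length are dropped (count logged).
    """
    pos_by_scaf: dict[str, np.ndarray] = {}
    by_scaf: dict[str, list[int]] = {}
    for r in het_records:
        by_scaf.setdefault(r.scaffold, []).append(r.pos - 1)
    for scaf, positions in by_scaf.items():
        pos_by_scaf[scaf] = np.sort(np.asarray(positions, dtype=np.int64))

    out = windows.copy()
    n_het = np.zeros(len(out), dtype=np.int64)
    callable_bp = np.zeros(len(out), dtype=np.int64)
    for i, (scaf, start, end) in enumerate(
        zip(out["scaffold"], out["start"], out["end"])
    ):
        pos = pos_by_scaf.get(scaf)
        if pos is not None:
            n_het[i] = np.searchsorted(pos, end) - np.searchsorted(pos, start)
        callable_bp[i] = (
            mask.overlap_bp(scaf, int(start), int(end)) if mask is not None
            else int(end) - int(start)
        )
    out["n_het"] = n_het
    out["callable_bp"] = callable_bp
    length = (out["end"] - out["start"]).to_numpy()
    keep = callable_bp >= min_callable_frac * length
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d windows with < %.0f%% callable bp",
                    n_drop, 100 * min_callable_frac)
    out = out.loc[keep].reset_index(drop=True)
    out["h"] = np.where(out["callable_bp"] > 0,
                        out["n_het"] / out["callable_bp"], 0.0)
    return out


@dataclass
class TruncGaussMixture:
    """Fitted two-component mixture: truncated-normal low component plus
    free normal high component."""

    w1: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    overlap_coefficient: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def log_component_densities(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) log densities [log f1, log f2]; f1 renormalized on [0, inf)."""
        x = np.asarray(x, dtype=float)
        # CDF "negative excess" correction: divide by P(N(mu1, s1) >= 0)
        log_norm1 = stats.norm.logsf(0.0, loc=self.mu1, scale=self.sigma1)
        lf1 = np.where(
            x >= 0,
            stats.norm.logpdf(x, self.mu1, self.sigma1) - log_norm1,
            -np.inf,
        )
        lf2 = stats.norm.logpdf(x, self.mu2, self.sigma2)
        return np.column_stack([lf1, lf2])

    def log_density(self, x: np.ndarray) -> np.ndarray:
        lc = self.log_component_densities(x)
        lw = np.log([self.w1, 1.0 - self.w1])
        return logsumexp(lc + lw, axis=1)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) posterior component probabilities; rows sum to 1."""
        lc = self.log_component_densities(x)
        lw = np.log([self.w1, 1.0 - self.w1])
        lj = lc + lw
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))


def _overlap_coefficient(mix: TruncGaussMixture, n_grid: int = 20_001) -> float:
    """Overlap of the two normalized component densities, in [0, 1].

    OVL = integral of min(f1, f2); 1 means the components coincide. f1 is
    zero below 0, so the grid covers [0, hi].
    """
    hi = max(mix.mu1 + 8 * mix.sigma1, mix.mu2 + 8 * mix.sigma2, 10 * SIGMA_FLOOR)
    x = np.linspace(0.0, hi, n_grid)
    lc = mix.log_component_densities(x)
    ovl = np.trapezoid(np.exp(np.minimum(lc[:, 0], lc[:, 1])), x)
    return float(min(max(ovl, 0.0), 1.0))


def fit_truncated_mixture(
    h: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    n_restarts: int = 1,
    min_windows: int = MIN_WINDOWS,
) -> TruncGaussMixture:
    """EM fit of w1*f1 + (1-w1)*f2 to window heterozygosity values.

    f1 is a normal renormalized on [0, inf) by 1/(1 - Phi(-mu1/sigma1));
    f2 is an untruncated normal. E-step responsibilities use the
    truncated density of f1. The M-step takes the exact
    responsibility-weighted maximizer for w1 and component 2, and for
    the truncated component numerically maximizes the weighted
    truncated-normal likelihood (moment estimates as warm start and
    fallback), so the log-likelihood never decreases.
    Initialization: mu1 = mean of the lowest decile of h,
    mu2 = median, both sigmas = pooled s.d., w1 = 0.25; mu1 <= mu2 is
    enforced each iteration by component swap. Iteration stops when the
    relative log-likelihood change drops below `tol`.

    With `n_restarts` > 1, subsequent starts jitter the initial means
    (seeded by `seed`) and the best log-likelihood fit is returned.
    """
    h = np.asarray(h, dtype=float)
    if len(h) < min_windows:
        raise DegenerateDataError(
            f"need >= {min_windows} windows to fit the mixture, got {len(h)}"
        )
    if np.any(h < 0):
        raise ValueError("window heterozygosity must be non-negative")
    if np.ptp(h) == 0.0:
        raise DegenerateDataError("all window heterozygosity values identical")
    sd = float(np.std(h))

    rng = np.random.default_rng(seed)
    lowest_decile = np.sort(h)[: max(1, len(h) // 10)]
    base_mu1 = float(np.mean(lowest_decile))
    base_mu2 = float(np.median(h))

    best: TruncGaussMixture | None = None
    for restart in range(n_restarts):
        if restart == 0:
            mu1, mu2 = base_mu1, base_mu2
        else:
            mu1 = abs(base_mu1 + rng.normal(0, sd / 2))
            mu2 = abs(base_mu2 + rng.normal(0, sd / 2))
        fit = _em_once(h, mu1, mu2, sd, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _q_trunc(h: np.ndarray, r: np.ndarray, n_eff: float,
             mu: float, sigma: float) -> float:
    """Responsibility-weighted truncated-normal log-likelihood term."""
    sigma = max(sigma, SIGMA_FLOOR)
    return float(
        r @ stats.norm.logpdf(h, mu, sigma)
        - n_eff * stats.norm.logsf(0.0, loc=mu, scale=sigma)
    )


def _mstep_trunc(
    h: np.ndarray, r: np.ndarray, mu_prev: float, s_prev: float
) -> tuple[float, float]:
    """M-step for the truncated component.

    Maximizes the weighted truncated-normal likelihood numerically,
    keeping the previous parameters or the plain moment update when they
    score better — the update never decreases the EM objective.
    """
    from scipy.optimize import minimize

    n_eff = float(r.sum())
    if n_eff <= 0:
        return mu_prev, s_prev
    mu_m = float(r @ h / n_eff)
    s_m = max(float(np.sqrt(r @ (h - mu_m) ** 2 / n_eff)), SIGMA_FLOOR)
    candidates = [(mu_prev, s_prev), (mu_m, s_m)]

    def neg_q(theta: np.ndarray) -> float:
        return -_q_trunc(h, r, n_eff, theta[0], float(np.exp(theta[1])))

    opt = minimize(neg_q, np.array([mu_m, np.log(s_m)]), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 300})
    if np.isfinite(opt.fun):
        candidates.append((float(opt.x[0]), max(float(np.exp(opt.x[1])), SIGMA_FLOOR)))
    return max(candidates, key=lambda c: _q_trunc(h, r, n_eff, c[0], c[1]))


def _em_once(
    h: np.ndarray, mu1: float, mu2: float, sd: float, tol: float, max_iter: int
) -> TruncGaussMixture:
    w1 = 0.25
    s1 = s2 = max(sd, SIGMA_FLOOR)
    if mu1 > mu2:
        mu1, mu2 = mu2, mu1
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = TruncGaussMixture(w1, mu1, s1, mu2, s2, np.nan, n_iter, False, np.nan)
        lc = mix.log_component_densities(h)
        lj = lc + np.log([w1, 1.0 - w1])
        lse = logsumexp(lj, axis=1)
        new_loglik = float(lse.sum())
        resp = np.exp(lj - lse[:, None])
        trace.append(new_loglik)

        n1 = resp[:, 0].sum()
        n2 = resp[:, 1].sum()
        w1 = float(n1 / len(h))
        mu1, s1 = _mstep_trunc(h, resp[:, 0], mu1, s1)
        if n2 > 0:
            mu2_m = float(resp[:, 1] @ h / n2)
            s2_m = max(float(np.sqrt(resp[:, 1] @ (h - mu2_m) ** 2 / n2)), SIGMA_FLOOR)
            # keep the previous parameters if the floored update scores worse
            prev_q = float(resp[:, 1] @ stats.norm.logpdf(h, mu2, s2))
            new_q = float(resp[:, 1] @ stats.norm.logpdf(h, mu2_m, s2_m))
            if new_q >= prev_q:
                mu2, s2 = mu2_m, s2_m
        if mu1 > mu2:
            mu1, mu2, s1, s2, w1 = mu2, mu1, s2, s1, 1.0 - w1

        if np.isfinite(loglik):
            rel = abs(new_loglik - loglik) / max(abs(new_loglik), 1.0)
            if rel < tol:
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik

    fit = TruncGaussMixture(
        w1=w1, mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2,
        loglik=loglik, n_iter=n_iter, converged=converged,
        overlap_coefficient=np.nan, loglik_trace=np.asarray(trace),
    )
    fit.overlap_coefficient = _overlap_coefficient(fit)
    return fit


@dataclass
class SoHResult:
    """SoH estimate with per-window assignments.

    `defined` is False when the mixture components overlap (no meaningful
    low-het component can be separated), the low component has vanishing
    weight, or classification puts every window in one component.
    """

    soh: float | None
    defined: bool
    assignments: pd.DataFrame
    reason: str | None = None


def classify_windows(
    mixture: TruncGaussMixture,
    windows: pd.DataFrame,
    overlap_threshold: float = 0.9,
    min_w1: float = 1e-3,
) -> SoHResult:
    """Posterior maximum-likelihood classification and SoH.

    Each window goes to the component with the larger posterior; SoH is
    the summed length of low-component windows over the summed length of
    all windows.
    """
    if not np.isfinite(mixture.loglik):
        raise ValueError("mixture is not fitted")
    h = windows["h"].to_numpy(dtype=float)
    resp = mixture.responsibilities(h)
    comp = np.argmax(resp, axis=1) + 1
    assignments = windows.copy()
    assignments["component"] = comp
    assignments["posterior_low"] = resp[:, 0]

    lengths = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    reason = None
    if mixture.overlap_coefficient > overlap_threshold:
        reason = "components overlap completely"
    elif mixture.w1 < min_w1:
        reason = "low-het component weight vanishes"
    elif len(set(comp)) == 1:
        reason = "all windows classified to one component"
    if reason is not None:
        return SoHResult(None, False, assignments, reason)
    soh = float(lengths[comp == 1].sum() / lengths.sum())
    return SoHResult(soh, True, assignments)


def estimate_soh(
    scaffolds: pd.DataFrame,
    het_records: list[VariantRecord],
    mask: CallableMask | None = None,
    max_window: int = MAX_WINDOW,
    min_scaffold: int = MIN_SCAFFOLD,
    seed: int | None = None,
    n_restarts: int = 1,
) -> tuple[SoHResult, TruncGaussMixture, pd.DataFrame]:
    """Full SoH pipeline: window, rate, fit, classify.

    `scaffolds` should already be depth-filtered; `het_records`
    high-confidence heterozygous calls.
    """
    windows = make_windows(scaffolds, max_len=max_window, min_scaffold=min_scaffold)
    if len(windows) == 0:
        raise UndefinedValueError("no scaffolds long enough to window")
    windows = window_het_rates(windows, het_records, mask=mask)
    mix = fit_truncated_mixture(
        windows["h"].to_numpy(), seed=seed, n_restarts=n_restarts
    )
    return classify_windows(mix, windows), mix, windows
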