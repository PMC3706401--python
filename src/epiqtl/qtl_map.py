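"""Interval mapping and empirical-Bayes multi-QTL estimation on
(corrected) QTL-genotype probabilities.

Two estimation devices are kept deliberately distinct:

* :func:`interval_map_single` — the single-QTL three-component normal
  mixture.  Component means are mu+a (QQ), mu+d (Qq), mu-a (qq) with a
  common residual variance; each individual's mixing proportions are its
  (corrected) conditional genotype probabilities.  EM alternates the
  posterior-genotype E-step with weighted least-squares updates.

* :func:`multi_qtl_eb` — the multi-QTL model y = mu + sum_l (z_l a_l +
  w_l d_l) + e regressed on *expected* dummies, with a normal prior
  N(0, sigma2_k) on every effect and a scaled inverse-chi-square prior
  (tau, omega) on each sigma2_k.  The EM follows the empirical-Bayes
  lineage: the E-step is the BLUP-type posterior mean/variance of each
  effect under the current variance components, the M-step updates each
  prior variance from the posterior second moment and the residual
  variance from the corrected residual sum of squares.  With the default
  (tau, omega) = (-2, 0) the variance update is exactly the posterior
  second moment.  Effects whose prior variance falls below a floor are
  shrunk to zero and stay there.

The per-locus LOD is a conditional likelihood-ratio: locus l's additive
and dominance effects are zeroed with everything else held fixed, and the
log10 likelihood drop is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core_map import GenotypeMatrix, LinkageMap
from .qtl_prob import (ConditionalProbMatrix, correct_conditional_probs,
                       expected_dummies, grid_probs, insert_virtual_markers,
                       position_fitness)

__all__ = [
    "EbConfig",
    "SingleQtlFit",
    "QtlModelFit",
    "QtlCall",
    "RunResult",
    "interval_map_single",
    "multi_qtl_eb",
    "lod_profile",
    "call_qtl",
    "run_method",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)

# rows of the fixed-effect design per genotype class (mu, a, d)
_CLASS_DESIGN = np.array([[1.0, 1.0, 0.0],
                          [1.0, 0.0, 1.0],
                          [1.0, -1.0, 0.0]])


@dataclass
class EbConfig:
    """Settings for the empirical-Bayes multi-QTL scan.

    tau, omega
        Hyperparameters of the scaled inverse-chi-square prior on each
        effect variance; the default (-2, 0) makes the variance update the
        posterior second moment.
    grid_step
        Maximum spacing of scan positions in cM (virtual markers are
        inserted into wider gaps).
    lod_threshold
        Minimum LOD for a reported QTL (3.0 by convention), applied to
        the drop-one LOD of the joint least-squares refit.
    screen_lod
        Permissive threshold on the EB conditional-LOD profile used to
        collect candidate peaks before the refit stage.
    merge_window
        Peaks closer than this (cM) are merged onto the higher one.
    var_floor_frac
        An effect variance below ``var_floor_frac * var(y)`` declares the
        locus null.
    """

    tau: float = -2.0
    omega: float = 0.0
    tol: float = 1e-5
    max_iter: int = 500
    grid_step: float = 1.0
    lod_threshold: float = 3.0
    screen_lod: float = 1.0
    merge_window: float = 10.0
    sdl_adjust: str = "bonferroni"
    sdl_alpha: float = 0.05
    var_floor_frac: float = 1e-8
    map_function: str = "kosambi"


@dataclass
class SingleQtlFit:
    """Single-position mixture-model fit."""

    position: float
    mu: float
    a: float
    d: float
    sigma2: float
    loglik: float
    loglik_null: float
    lod: float
    n_iter: int
    converged: bool
    identifiable: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class QtlModelFit:
    """Converged multi-QTL empirical-Bayes fit over a scan grid."""

    chrom: np.ndarray        # per-locus chromosome label
    positions: np.ndarray    # per-locus position (cM)
    mu: float
    a: np.ndarray
    d: np.ndarray
    sigma2_a: np.ndarray
    sigma2_d: np.ndarray
    sigma2: float
    lod: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_loci(self) -> int:
        return len(self.positions)


@dataclass
class QtlCall:
    """A reported QTL."""

    chrom: str
    position: float
    a: float
    d: float
    lod: float
    method: str


@dataclass
class RunResult:
    """Everything produced by one end-to-end mapping run.

    ``design`` holds the regression inputs of the multi-QTL stage
    (expected-dummy matrix, per-locus chromosome labels and positions) so
    that downstream consumers (e.g. the power harness) can evaluate
    single-locus refits without recomputing the probability pipeline.
    """

    method: str
    calls: list[QtlCall]
    fit: QtlModelFit
    corrected_map: LinkageMap
    map_report: object
    sdl_scan: object
    design: tuple | None = None


# ---------------------------------------------------------------------------
# single-interval mixture EM


def interval_map_single(y, probs, position: float = 0.0,
                        tol: float = 1e-8, max_iter: int = 1000) -> SingleQtlFit:
    """EM fit of the three-component normal mixture at one scan position.

    Parameters
    ----------
    y : array_like, shape (n,)
        Phenotypes.
    probs : array_like, shape (n, 3), or ConditionalProbMatrix
        Prior (possibly SDL-corrected) probabilities of QQ, Qq, qq.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(probs, ConditionalProbMatrix):
        probs = probs.probs3[:, 0, :]
    p = np.asarray(probs, dtype=float)
    if p.shape != (y.size, 3):
        raise ValueError(f"probs shape {p.shape} does not match n={y.size}")
    n = y.size
    vary = float(np.var(y))
    if vary == 0:
        vary = 1.0
    floor = 1e-8 * vary
    warnings: list[str] = []

    mu, a, d = float(np.mean(y)), 0.0, 0.0
    sigma2 = vary
    identifiable = True
    converged = False
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        means = np.array([mu + a, mu + d, mu - a])
        dens = np.exp(-0.5 * (y[:, None] - means) ** 2 / sigma2) / math.sqrt(
            2 * math.pi * sigma2)
        mix = p * dens
        tot = mix.sum(1)
        tot = np.where(tot <= 0, 1e-300, tot)
        w = mix / tot[:, None]
        new_loglik = float(np.log(tot).sum())

        # weighted least squares over the 3 pseudo-observations per individual
        A = np.einsum("ng,gi,gj->ij", w, _CLASS_DESIGN, _CLASS_DESIGN)
        b = np.einsum("ng,gi,n->i", w, _CLASS_DESIGN, y)
        if np.linalg.cond(A) > 1e10:
            identifiable = False
            warnings.append("design is singular: effects confounded with "
                            "the mean (degenerate genotype probabilities)")
            theta = np.linalg.lstsq(A, b, rcond=None)[0]
        else:
            theta = np.linalg.solve(A, b)
        mu_new, a_new, d_new = theta
        fitted = _CLASS_DESIGN @ theta
        s2_new = float(np.einsum("ng,ng->", w, (y[:, None] - fitted) ** 2) / n)
        if s2_new < floor:
            s2_new = floor
            warnings.append("residual variance hit the ridge floor")
        delta = max(abs(mu_new - mu), abs(a_new - a), abs(d_new - d),
                    abs(s2_new - sigma2))
        mu, a, d, sigma2 = float(mu_new), float(a_new), float(d_new), s2_new
        loglik = new_loglik
        if delta < tol:
            converged = True
            break
    # final likelihood at the converged parameters
    means = np.array([mu + a, mu + d, mu - a])
    dens = np.exp(-0.5 * (y[:, None] - means) ** 2 / sigma2) / math.sqrt(
        2 * math.pi * sigma2)
    loglik = float(np.log(np.maximum((p * dens).sum(1), 1e-300)).sum())

    s2_null = float(np.var(y))
    loglik_null = float(-0.5 * n * (math.log(2 * math.pi * max(s2_null, 1e-300))
                                    + 1.0))
    lod = (loglik - loglik_null) / _LN10
    return SingleQtlFit(position=position, mu=mu, a=a, d=d, sigma2=sigma2,
                        loglik=loglik, loglik_null=loglik_null, lod=lod,
                        n_iter=it, converged=converged,
                        identifiable=identifiable, warnings=warnings)


# ---------------------------------------------------------------------------
# empirical-Bayes multi-QTL


def _assemble_design(dummies_by_chrom) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-chromosome expected dummies into (X, chrom, positions).

    Columns alternate additive/dominance per locus: X[:, 2l] = z_l,
    X[:, 2l+1] = w_l.
    """
    cols, chroms, pos = [], [], []
    for dm in dummies_by_chrom:
        for k in range(dm.positions.size):
            cols.append(dm.z[:, k])
            cols.append(dm.w[:, k])
            chroms.append(dm.chrom)
            pos.append(dm.positions[k])
    X = np.column_stack(cols)
    return X, np.asarray(chroms), np.asarray(pos, dtype=float)


def multi_qtl_eb(y, X: np.ndarray, chrom: np.ndarray, positions: np.ndarray,
                 config: EbConfig | None = None) -> QtlModelFit:
    """Empirical-Bayes EM for the multi-QTL regression on expected dummies.

    Parameters
    ----------
    y : (n,) phenotypes
    X : (n, 2p) design of expected additive/dominance dummies
        (column 2l = z_l, column 2l+1 = w_l).
    chrom, positions : per-locus labels (length p)
    """
    config = config or EbConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("empty phenotype vector")
    K = X.shape[1]
    p = K // 2
    vary = float(np.var(y)) or 1.0
    var_floor = config.var_floor_frac * vary

    # sufficient statistics: per-iteration cost depends on the number of
    # active effects, not on n or the grid size
    XtX = X.T @ X
    Xty = X.T @ y
    Xt1 = X.sum(0)
    sum_y = float(y.sum())
    yty = float(y @ y)
    diag_XtX = np.diag(XtX).copy()

    sig2k = np.full(K, 0.1 * vary)
    sigma2 = 0.5 * vary
    mu = float(np.mean(y))
    gamma = np.zeros(K)
    trace = []
    converged = False
    it = 0
    denom = config.tau + 3.0
    for it in range(1, config.max_iter + 1):
        A = np.where(sig2k > 0)[0]
        # Woodbury: V^-1 = (I - Xa M^-1 Xa^T / s2) / s2,
        # M = D_A^-1 + Xa^T Xa / s2
        if len(A):
            M = XtX[np.ix_(A, A)] / sigma2 + np.diag(1.0 / sig2k[A])
            cf = cho_factor(M, lower=True)
            T = cho_solve(cf, XtX[A, :])            # (k, K)
            t1 = cho_solve(cf, Xt1[A])
            ty = cho_solve(cf, Xty[A])
            one_Vinv_one = (n - Xt1[A] @ t1 / sigma2) / sigma2
            one_Vinv_y = (sum_y - Xt1[A] @ ty / sigma2) / sigma2
        else:
            one_Vinv_one = n / sigma2
            one_Vinv_y = sum_y / sigma2
        mu_new = float(one_Vinv_y / one_Vinv_one)

        Xtr = Xty - mu_new * Xt1                     # X^T (y - mu)
        if len(A):
            tr = cho_solve(cf, Xtr[A])
            b = (Xtr - XtX[:, A] @ tr / sigma2) / sigma2
            xVx = (diag_XtX
                   - np.einsum("kj,kj->j", XtX[A, :], T) / sigma2) / sigma2
        else:
            b = Xtr / sigma2
            xVx = diag_XtX / sigma2
        gamma_new = sig2k * b
        Vk = np.maximum(sig2k - sig2k ** 2 * xVx, 0.0)

        sig2k_new = (gamma_new ** 2 + Vk + config.omega) / denom
        sig2k_new[sig2k_new < var_floor] = 0.0
        gamma_new[sig2k_new == 0.0] = 0.0

        g = gamma_new
        rss = (yty - 2 * mu_new * sum_y + n * mu_new ** 2
               - 2 * g @ Xtr + g @ (XtX @ g))
        rss = max(rss, 0.0)
        sigma2_new = float((rss + Vk @ diag_XtX) / n)
        sigma2_new = max(sigma2_new, 1e-12 * vary)

        if not np.all(np.isfinite(gamma_new)) or not np.isfinite(sigma2_new):
            raise FloatingPointError(
                f"non-finite EB update at iteration {it}: "
                f"mu={mu_new}, sigma2={sigma2_new}"
            )
        ll = float(-0.5 * n * math.log(2 * math.pi * sigma2_new)
                   - 0.5 * rss / sigma2_new)
        trace.append(ll)
        delta = max(abs(mu_new - mu), float(np.max(np.abs(gamma_new - gamma))))
        mu, gamma, sig2k, sigma2 = mu_new, gamma_new, sig2k_new, sigma2_new
        if delta < config.tol:
            converged = True
            break

    fit = QtlModelFit(chrom=chrom, positions=positions, mu=mu,
                      a=gamma[0::2].copy(), d=gamma[1::2].copy(),
                      sigma2_a=sig2k[0::2].copy(), sigma2_d=sig2k[1::2].copy(),
                      sigma2=sigma2, lod=np.zeros(p),
                      loglik_trace=np.asarray(trace), n_iter=it,
                      converged=converged)
    fit.lod = lod_profile(fit, y, X)
    return fit


def lod_profile(fit: QtlModelFit, y, X: np.ndarray) -> np.ndarray:
    """Conditional per-locus LOD: drop locus l's (a, d) with everything
    else fixed and report the log10 likelihood decrease."""
    y = np.asarray(y, dtype=float)
    gamma = np.empty(2 * fit.n_loci)
    gamma[0::2] = fit.a
    gamma[1::2] = fit.d
    resid_full = y - fit.mu - X @ gamma
    rss_full = float(resid_full @ resid_full)
    lod = np.zeros(fit.n_loci)
    for l in range(fit.n_loci):
        if fit.a[l] == 0.0 and fit.d[l] == 0.0:
            continue
        contrib = X[:, 2 * l] * fit.a[l] + X[:, 2 * l + 1] * fit.d[l]
        resid_l = resid_full + contrib
        rss_l = float(resid_l @ resid_l)
        lod[l] = (rss_l - rss_full) / (2.0 * fit.sigma2 * _LN10)
    return lod


def call_qtl(fit: QtlModelFit, threshold: float = 3.0,
             merge_window: float = 10.0, method: str = "new") -> list[QtlCall]:
    """Local LOD maxima at or above the threshold, merged within a window.

    Peaks on the same chromosome closer than ``merge_window`` cM collapse
    onto the higher peak.
    """
    calls: list[QtlCall] = []
    for cname in pd_unique(fit.chrom):
        idx = np.where(fit.chrom == cname)[0]
        order = idx[np.argsort(fit.positions[idx])]
        lod = fit.lod[order]
        peaks = []
        for k in range(len(order)):
            left = lod[k - 1] if k > 0 else -np.inf
            right = lod[k + 1] if k + 1 < len(order) else -np.inf
            if lod[k] >= threshold and lod[k] >= left and lod[k] >= right:
                peaks.append(k)
        peaks.sort(key=lambda k: -lod[k])
        kept: list[int] = []
        for k in peaks:
            if all(abs(fit.positions[order[k]] - fit.positions[order[j]])
                   > merge_window for j in kept):
                kept.append(k)
        for k in sorted(kept, key=lambda k: fit.positions[order[k]]):
            g = order[k]
            calls.append(QtlCall(chrom=str(cname),
                                 position=float(fit.positions[g]),
                                 a=float(fit.a[g]), d=float(fit.d[g]),
                                 lod=float(lod[k]), method=method))
    return calls


def pd_unique(arr):
    """Order-preserving unique labels."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_method(y, genotypes: GenotypeMatrix, lmap: LinkageMap,
               method: str = "new", config: EbConfig | None = None,
               corrected_map: LinkageMap | None = None, map_report=None,
               sdl_scan_result=None, refit_effects: bool = True) -> RunResult:
    """Run one full mapping pass with the old or the new method.

    Both methods use the selection-corrected linkage map; the new method
    additionally corrects the QTL-genotype conditional probabilities with
    the fitnesses implied by significant SDL pairs (the nearest pair, by
    midpoint distance, supplies the fitness at each scan position).  With
    no significant SDL anywhere the two methods coincide exactly.

    Precomputed pipeline stages (corrected map, SDL scan) may be passed in
    so that paired old/new comparisons share them.
    """
    from .sdl_scan import correct_map, scan_pairs

    if method not in ("old", "new"):
        raise ValueError(f"method must be 'old' or 'new', got {method!r}")
    config = config or EbConfig()
    y = np.asarray(y, dtype=float)

    if corrected_map is None:
        logger.info("stage 1/3: correct linkage map and detect epistatic SDL")
        corrected_map, map_report = correct_map(genotypes, lmap,
                                                config.map_function)
    if sdl_scan_result is None:
        sdl_scan_result = scan_pairs(genotypes, corrected_map,
                                     adjust=config.sdl_adjust,
                                     alpha=config.sdl_alpha,
                                     map_function=config.map_function)

    logger.info("stage 2/3: conditional QTL genotype probabilities (%s)",
                "corrected" if method == "new" else "uncorrected")
    grid = insert_virtual_markers(corrected_map, config.grid_step)
    probs = grid_probs(genotypes, corrected_map, grid, config.map_function)

    sig_by_chrom: dict[str, list] = {}
    for cname, pA, pB, f in sdl_scan_result.significant_pairs():
        sig_by_chrom.setdefault(cname, []).append((pA, pB, f))

    dummies = []
    for cname in grid.chromosomes:
        cpm = probs[cname]
        if method == "new" and cname in sig_by_chrom:
            pairs = sig_by_chrom[cname]
            p4 = cpm.probs4.copy()
            for k, pos in enumerate(cpm.positions):
                pA, pB, f = min(
                    pairs, key=lambda t: abs(0.5 * (t[0] + t[1]) - pos))
                ft = position_fitness(f, (pA, pB), pos,
                                      map_function=config.map_function)
                w4 = np.array([1.0, ft.f2, ft.f3, ft.f4])
                row = p4[:, k, :] * w4
                p4[:, k, :] = row / row.sum(-1, keepdims=True)
            cpm = ConditionalProbMatrix(chrom=cpm.chrom,
                                        positions=cpm.positions, probs4=p4)
        dummies.append(expected_dummies(cpm))

    logger.info("stage 3/3: multi-QTL mapping (%s method)", method)
    X, chroms, positions = _assemble_design(dummies)
    fit = multi_qtl_eb(y, X, chroms, positions, config)
    if refit_effects:
        # two-stage calling: the EB conditional LOD is a screening
        # device (it is not calibrated as a test on a dense, highly
        # correlated grid); candidates are re-tested jointly by OLS
        calls = call_qtl(fit, threshold=config.screen_lod,
                         merge_window=config.merge_window, method=method)
        if calls:
            calls = _backward_refine(y, X, chroms, positions, calls,
                                     config.lod_threshold)
    else:
        calls = call_qtl(fit, threshold=config.lod_threshold,
                         merge_window=config.merge_window, method=method)
    return RunResult(method=method, calls=calls, fit=fit,
                     corrected_map=corrected_map, map_report=map_report,
                     sdl_scan=sdl_scan_result,
                     design=(X, chroms, positions))


def _drop_one_lods(y, D, k):
    """Joint OLS fit of k loci (2 columns each after the intercept) and
    drop-one LOD per locus: (n/2) log10(RSS_without / RSS_with)."""
    n = y.size
    theta, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss_full = float(np.sum((y - D @ theta) ** 2))
    rss_full = max(rss_full, 1e-12 * n)
    lods = np.empty(k)
    for i in range(k):
        keep = [0] + [c for c in range(1, D.shape[1])
                      if c not in (1 + 2 * i, 2 + 2 * i)]
        th_r, *_ = np.linalg.lstsq(D[:, keep], y, rcond=None)
        rss_r = float(np.sum((y - D[:, keep] @ th_r) ** 2))
        lods[i] = 0.5 * n * math.log10(max(rss_r / rss_full, 1.0))
    return theta, lods


def _backward_refine(y, X, chroms, positions, calls, threshold):
    """Joint OLS refit of the screened loci with backward elimination.

    The EB scan shrinks effects and can park large canceling effects on
    highly correlated neighbouring grid columns, which inflates the
    conditional LOD used for screening.  Candidates are therefore
    re-tested jointly: the locus with the smallest drop-one LOD is
    removed until every remaining locus clears the threshold, and the
    reported effects and LODs come from the final unpenalized fit.
    """
    idx = [int(np.argmin(np.where(chroms == c.chrom, 0, np.inf)
                         + np.abs(positions - c.position)))
           for c in calls]
    active = list(range(len(calls)))
    while active:
        D = np.column_stack(
            [np.ones_like(y)]
            + [X[:, 2 * idx[i] + o] for i in active for o in (0, 1)])
        theta, lods = _drop_one_lods(y, D, len(active))
        if np.min(lods) >= threshold:
            break
        active.pop(int(np.argmin(lods)))
    if not active:
        return []
    out = []
    for j, i in enumerate(active):
        out.append(QtlCall(chrom=calls[i].chrom, position=calls[i].position,
                           a=float(theta[1 + 2 * j]),
                           d=float(theta[2 + 2 * j]),
                           lod=float(lods[j]), method=calls[i].method))
    return out
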