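"""EM estimation of epistatic-SDL viability parameters, likelihood-ratio
tests, pairwise recombination-fraction correction, and the 2-D SDL scan.

Estimation is by EM over the 16 ordered two-locus states (female gamete x
male gamete).  The E-step distributes each observed 9-class count (or, at
off-marker positions, each individual's multipoint conditional
probability mass) across the compatible ordered states in proportion to
their current model frequencies — the double heterozygote splits four
ways, the single-heterozygote classes two ways.  The M-step is closed
form: because every ordered state determines its male gamete, the
complete-data likelihood factorizes into a female part (free of the
viabilities) and a male multinomial whose maximizer gives

    v = (c_Ab / c_AB) * (1-r)/r,   u = (c_aB / c_AB) * (1-r)/r,
    x =  c_ab / c_AB,

with c_g the expected male-gamete counts.  When r is estimated jointly,
its update comes from the expected female-strand recombinants (with free
viabilities the male part of the likelihood places no constraint on r);
with the viabilities pinned at 1 both strands pool and the update reduces
to the textbook two-point F2 EM.

Two tests are provided: segregation distortion (H0: u = v = x = 1,
3 df) and epistasis (H0: x = u*v, i.e. multiplicative viabilities, 1 df).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

from .core_map import (CODOMINANT_CODES, GenotypeMatrix, LinkageMap,
                       kosambi_d_from_r, r_from_d)
from .qtl_prob import MultipointEngine
from .sdl_model import (ORDERED_TO_CLASS, ViabilityParams,
                        mendelian_gamete_freqs)

__all__ = [
    "SdlCountTable",
    "SdlFit",
    "SdlScanResult",
    "tabulate_counts",
    "em_fit_sdl_at_markers",
    "em_fit_sdl_interval",
    "test_distortion",
    "test_epistasis",
    "correct_pairwise_r",
    "correct_map",
    "scan_pairs",
]

logger = logging.getLogger(__name__)

_VCAP = 1e4          # viability cap at non-identifiable boundaries
_DEFAULT_TOL = 1e-8
_DEFAULT_MAX_ITER = 2000

# ---------------------------------------------------------------------------
# fast inner kernels (no dataclass overhead; hot path of the 2-D scan)


# ordered state (female gamete i, male gamete j) -> collapsed class
_CLS16 = np.array([(i, j, int(ORDERED_TO_CLASS[i, j])) for i in range(4)
                   for j in range(4)], dtype=np.int64)


@njit(cache=True)
def _pi9_scalar(u, v, x, r):
    """Collapsed 9-class probabilities plus female/male gamete freqs."""
    f0, f1 = (1.0 - r) / 2.0, r / 2.0
    lam = f0 * (1.0 + x) + f1 * (u + v)
    q0, q1, q2, q3 = f0 / lam, v * f1 / lam, u * f1 / lam, x * f0 / lam
    pi = np.empty(9)
    pi[0] = f0 * q0
    pi[1] = f0 * q1 + f1 * q0
    pi[2] = f1 * q1
    pi[3] = f0 * q2 + f1 * q0
    pi[4] = f0 * q3 + f0 * q0 + f1 * q2 + f1 * q1
    pi[5] = f1 * q3 + f0 * q1
    pi[6] = f1 * q2
    pi[7] = f1 * q3 + f0 * q2
    pi[8] = f0 * q3
    f = np.empty(4)
    f[0] = f0; f[1] = f1; f[2] = f1; f[3] = f0
    q = np.empty(4)
    q[0] = q0; q[1] = q1; q[2] = q2; q[3] = q3
    return pi, f, q


@njit(cache=True)
def _loglik_fast(nl, nzi, u, v, x, r):
    """Multinomial log-likelihood; ``nl`` counts, ``nzi`` the indices of
    the non-zero classes."""
    pi, f, q = _pi9_scalar(u, v, x, r)
    s = 0.0
    for i in nzi:
        p = pi[i] if pi[i] > 1e-300 else 1e-300
        s += nl[i] * math.log(p)
    return s


@njit(cache=True)
def _estep_fast(nl, u, v, x, r, cls16):
    """E-step: expected female and male gamete counts (length-4 arrays)."""
    pi, f, q = _pi9_scalar(u, v, x, r)
    cf = np.zeros(4)
    cm = np.zeros(4)
    for t in range(16):
        i, j, k = cls16[t, 0], cls16[t, 1], cls16[t, 2]
        if pi[k] > 1e-300:
            val = f[i] * q[j] * nl[k] / pi[k]
            cf[i] += val
            cm[j] += val
    return cf, cm


@dataclass
class SdlCountTable:
    """Observed counts of the 9 two-locus genotype classes
    (AABB, AABb, AAbb, AaBB, AaBb, Aabb, aaBB, aaBb, aabb)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (9,):
            raise ValueError("SdlCountTable needs exactly 9 class counts")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("total count must be positive")
        self.counts = c

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    def swapped_loci(self) -> "SdlCountTable":
        """Counts after relabelling locus A <-> B (transpose the 3x3 table)."""
        return SdlCountTable(self.counts.reshape(3, 3).T.ravel())


@dataclass
class SdlFit:
    """Result of fitting the gametic-selection model to one locus pair."""

    u: float
    v: float
    x: float
    r: float
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    r_estimated: bool = False
    loglik_null: float = np.nan       # u = v = x = 1 at the same r policy
    loglik_noepi: float = np.nan      # constrained x = u * v
    lrt_distortion: float = np.nan
    p_distortion: float = np.nan
    lrt_epistasis: float = np.nan
    p_epistasis: float = np.nan
    warnings: list[str] = field(default_factory=list)

    @property
    def params(self) -> ViabilityParams:
        return ViabilityParams(u=self.u, v=self.v, x=self.x, r=self.r)


@dataclass
class SdlScanResult:
    """Two-dimensional SDL scan over position pairs of a map."""

    table: pd.DataFrame
    fits: dict
    adjust: str
    alpha: float

    def significant_pairs(self) -> list[tuple[str, float, float, SdlFit]]:
        out = []
        for _, row in self.table[self.table["significant"]].iterrows():
            key = (row["chrom"], row["posA"], row["posB"])
            out.append((*key, self.fits[key]))
        return out


# ---------------------------------------------------------------------------
# tabulation


def tabulate_counts(genotypes: GenotypeMatrix, markerA: str,
                    markerB: str) -> tuple[SdlCountTable, int]:
    """9-class counts at a marker pair from codominant complete records.

    Returns the count table and the number of individuals excluded for
    dominant or missing observations at either marker.
    """
    a = genotypes.column(markerA)
    b = genotypes.column(markerB)
    ok = np.isin(a, CODOMINANT_CODES) & np.isin(b, CODOMINANT_CODES)
    cls = 3 * a[ok].astype(int) + b[ok].astype(int)
    counts = np.bincount(cls, minlength=9).astype(float)
    return SdlCountTable(counts), int((~ok).sum())


# ---------------------------------------------------------------------------
# likelihood helpers


def _nm_minimize(f, x0, xatol=1e-6, fatol=1e-8, maxiter=500):
    """Tiny Nelder-Mead for the 2-4 parameter profile fits.

    scipy's implementation spends ~100 microseconds per iteration on
    array bookkeeping, which dominates these scalar objectives; this
    plain-Python simplex with standard coefficients is ~10x faster at
    identical tolerances.  Returns (x_best, f_best).
    """
    n = len(x0)
    simplex = [list(x0)]
    for i in range(n):
        p = list(x0)
        p[i] += 0.05 if p[i] == 0 else 0.05 * abs(p[i]) + 0.01
        simplex.append(p)
    fvals = [f(p) for p in simplex]
    for _ in range(maxiter):
        order = sorted(range(n + 1), key=lambda i: fvals[i])
        simplex = [simplex[i] for i in order]
        fvals = [fvals[i] for i in order]
        if (fvals[-1] - fvals[0] < fatol
                and max(max(abs(simplex[j][i] - simplex[0][i])
                            for i in range(n))
                        for j in range(1, n + 1)) < xatol):
            break
        centroid = [sum(p[i] for p in simplex[:-1]) / n for i in range(n)]
        worst = simplex[-1]
        refl = [2 * centroid[i] - worst[i] for i in range(n)]
        fr = f(refl)
        if fr < fvals[0]:
            exp = [3 * centroid[i] - 2 * worst[i] for i in range(n)]
            fe = f(exp)
            simplex[-1], fvals[-1] = (exp, fe) if fe < fr else (refl, fr)
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = refl, fr
        else:
            contr = [0.5 * (centroid[i] + worst[i]) for i in range(n)]
            fc = f(contr)
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = contr, fc
            else:
                best = simplex[0]
                for j in range(1, n + 1):
                    simplex[j] = [0.5 * (simplex[j][i] + best[i])
                                  for i in range(n)]
                    fvals[j] = f(simplex[j])
    k = min(range(n + 1), key=lambda i: fvals[i])
    return simplex[k], fvals[k]


def _nl_nzi(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nl = np.asarray(counts, dtype=float)
    return nl, np.flatnonzero(nl > 0)


def _count_loglik(counts: np.ndarray, params: ViabilityParams) -> float:
    """Multinomial log-likelihood (without the combinatorial constant)."""
    nl, nzi = _nl_nzi(counts)
    return _loglik_fast(nl, nzi, params.u, params.v, params.x, params.r)


def _mstep_from_male_counts(c: np.ndarray, r: float,
                            warnings: list[str]) -> tuple[float, float, float]:
    """Closed-form viability update from expected male gamete counts."""
    c0 = c[0]
    if c0 <= 1e-300:
        warnings.append("reference gamete AB has zero expected count; "
                        "viabilities at boundary")
        c0 = 1e-300
    if r <= 0.0:
        # classes Ab and aB are impossible at r = 0: u, v unidentifiable
        if "u, v not identifiable at r = 0" not in warnings:
            warnings.append("u, v not identifiable at r = 0")
        u = v = 1.0
    else:
        ratio = (1.0 - r) / r
        v = min((c[1] / c0) * ratio, _VCAP)
        u = min((c[2] / c0) * ratio, _VCAP)
    x = min(c[3] / c0, _VCAP)
    return u, v, x


def _expected_ordered_counts(counts: np.ndarray,
                             params: ViabilityParams) -> np.ndarray:
    """E-step: distribute class counts across ordered states (4x4)."""
    ordered = genotype_frequencies(params).ordered
    class_tot = np.zeros(9)
    np.add.at(class_tot, ORDERED_TO_CLASS.ravel(), ordered.ravel())
    with np.errstate(divide="ignore", invalid="ignore"):
        share = ordered / class_tot[ORDERED_TO_CLASS]
    share = np.nan_to_num(share)
    return share * counts[ORDERED_TO_CLASS]


# ---------------------------------------------------------------------------
# EM fits on count tables


def em_fit_sdl_at_markers(counts: SdlCountTable, r: float,
                          tol: float = _DEFAULT_TOL,
                          max_iter: int = _DEFAULT_MAX_ITER,
                          init: tuple[float, float, float] = (1.0, 1.0, 1.0),
                          fit_noepi: bool = True) -> SdlFit:
    """Multinomial MLE of the viabilities (u, v, x) with r fixed.

    EM iterates between distributing the 9 observed class counts over the
    16 ordered states and the closed-form male-gamete viability update;
    the observed-data log-likelihood is recorded every iteration and is
    non-decreasing.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"r must be in [0, 0.5], got {r}")
    n = counts.counts
    warnings: list[str] = []
    _margin_checks(n, warnings)
    u, v, x = init
    nl, nzi = _nl_nzi(n)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        trace.append(_loglik_fast(nl, nzi, u, v, x, r))
        _, c_male = _estep_fast(nl, u, v, x, r, _CLS16)
        u_new, v_new, x_new = _mstep_from_male_counts(c_male, r, warnings)
        delta = max(abs(u_new - u), abs(v_new - v), abs(x_new - x))
        u, v, x = u_new, v_new, x_new
        if delta < tol:
            converged = True
            break
    trace.append(_loglik_fast(nl, nzi, u, v, x, r))
    if not converged:
        warnings.append(f"EM did not converge in {max_iter} iterations")
    fit = SdlFit(u=u, v=v, x=x, r=r, loglik=trace[-1],
                 loglik_trace=np.asarray(trace), n_iter=it,
                 converged=converged, warnings=warnings)
    fit.loglik_null = _count_loglik(n, ViabilityParams(1.0, 1.0, 1.0, r))
    if fit_noepi:
        fit.loglik_noepi = _fit_noepi_counts(n, r, (u, v))
    return fit


def _margin_checks(n: np.ndarray, warnings: list[str]):
    tab = n.reshape(3, 3)
    for axis, locus in ((1, "A"), (0, "B")):
        margins = tab.sum(axis=axis)
        if np.any(margins == 0):
            warnings.append(
                f"zero margin at locus {locus}; estimates may sit on a "
                f"boundary (non-identifiable direction)"
            )


def _fit_noepi_counts(n: np.ndarray, r: float,
                      start: tuple[float, float]) -> float:
    """Profile log-likelihood under the no-epistasis constraint x = u*v."""
    nl, nzi = _nl_nzi(n)

    def negll(theta):
        u, v = math.exp(theta[0]), math.exp(theta[1])
        return -_loglik_fast(nl, nzi, u, v, u * v, r)

    best = np.inf
    for s in (start, (1.0, 1.0)):
        x0 = list(np.log(np.clip(s, 1e-8, _VCAP)))
        _, f_best = _nm_minimize(negll, x0, xatol=1e-10, fatol=1e-12,
                                 maxiter=4000)
        best = min(best, f_best)
    return -best


# ---------------------------------------------------------------------------
# tests


def test_distortion(fit: SdlFit) -> tuple[float, float]:
    """LRT of H0: u = v = x = 1 (no segregation distortion), 3 df."""
    lrt = 2.0 * (fit.loglik - fit.loglik_null)
    if lrt < -1e-6:
        raise RuntimeError(
            f"distortion LRT negative ({lrt:.3g}): EM failed to reach the "
            f"null likelihood"
        )
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=3))
    fit.lrt_distortion, fit.p_distortion = lrt, p
    return lrt, p


def test_epistasis(fit: SdlFit) -> tuple[float, float]:
    """LRT of H0: x = u*v (multiplicative male-gamete viabilities), 1 df."""
    lrt = 2.0 * (fit.loglik - fit.loglik_noepi)
    if lrt < -1e-6:
        raise RuntimeError(
            f"epistasis LRT negative ({lrt:.3g}): constrained optimum "
            f"exceeds the full-model likelihood"
        )
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    fit.lrt_epistasis, fit.p_epistasis = lrt, p
    return lrt, p


# ---------------------------------------------------------------------------
# joint (r, u, v, x) EM — pairwise map correction


def correct_pairwise_r(counts: SdlCountTable, r_init: float = 0.25,
                       fix_viabilities: bool = False,
                       pseudo_count: float = 0.5,
                       tol: float = _DEFAULT_TOL,
                       max_iter: int = _DEFAULT_MAX_ITER) -> SdlFit:
    """Jointly estimate the recombination fraction and the viabilities.

    With ``fix_viabilities`` the model is Mendelian and the update pools
    recombinant gametes from both strands (the standard two-point F2 EM);
    otherwise r is driven by the female strand alone and the viabilities
    absorb the distortion of the male strand.

    The joint model is weakly identified when double-recombinant classes
    are empty (a likelihood ridge lets r -> 0 while u, v explode to mimic
    recombination through selection).  ``pseudo_count`` adds a small
    constant to every class count (Haldane-Anscombe style) to keep the
    estimate off that ridge; it is ignored when all nine classes are
    occupied, and can be set to 0 for the exact MLE (as on expected-count
    input, where every class is positive anyway).

    An estimate at the 0.5 boundary is flagged unlinked in ``warnings``.
    """
    n = counts.counts
    if pseudo_count > 0 and np.any(n == 0):
        n = n + pseudo_count
    N = float(n.sum())
    warnings: list[str] = []
    _margin_checks(n, warnings)
    r = min(max(r_init, 1e-6), 0.5)
    u = v = x = 1.0
    nl, nzi = _nl_nzi(n)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        trace.append(_loglik_fast(nl, nzi, u, v, x, r))
        c_female, c_male = _estep_fast(nl, u, v, x, r, _CLS16)
        if fix_viabilities:
            r_new = (c_female[1] + c_female[2] + c_male[1] + c_male[2]) / (2 * N)
            r_new = min(r_new, 0.5)
            u_new = v_new = x_new = 1.0
        else:
            # clamp before the viability update: the male M-step must use
            # the same r the next likelihood evaluation will see
            r_new = min((c_female[1] + c_female[2]) / N, 0.5)
            u_new, v_new, x_new = _mstep_from_male_counts(c_male, r_new, warnings)
        delta = max(abs(r_new - r), abs(u_new - u), abs(v_new - v),
                    abs(x_new - x))
        r, u, v, x = r_new, u_new, v_new, x_new
        if delta < tol:
            converged = True
            break
    trace.append(_loglik_fast(nl, nzi, u, v, x, r))
    if not converged:
        warnings.append(f"EM did not converge in {max_iter} iterations")
    if r >= 0.5 - 1e-6:
        warnings.append("r at the 0.5 boundary: loci effectively unlinked")
    fit = SdlFit(u=u, v=v, x=x, r=r, loglik=trace[-1],
                 loglik_trace=np.asarray(trace), n_iter=it,
                 converged=converged, r_estimated=True, warnings=warnings)
    fit.loglik_null = _count_loglik(n, ViabilityParams(1.0, 1.0, 1.0, r))
    return fit


def _pair_tests_profiled(counts: SdlCountTable, r_init: float = 0.25,
                         pseudo_count: float = 0.5):
    """Distortion (3 df) and epistasis (1 df) LRTs with r profiled out of
    every hypothesis.

    Fixing r at a map estimate makes both tests sensitive to map noise
    (the null pins the whole two-locus table, and the x = u*v constraint
    pins the male-gamete odds ratio to ((1-r)/r)^2, so an error in r
    masquerades as distortion/epistasis; map errors also accumulate over
    distant pairs).  Profiling r within each hypothesis calibrates the
    tests under the Mendelian null.  The pseudo-count policy of
    :func:`correct_pairwise_r` is applied consistently to all three
    likelihoods.

    Returns ``(lrt_dist, p_dist, lrt_epi, p_epi, full_fit)``.
    """
    n = counts.counts
    if pseudo_count > 0 and np.any(n == 0):
        n = n + pseudo_count
    nl, nzi = _nl_nzi(n)

    # full model: short EM for a good start, Nelder-Mead polish
    full = correct_pairwise_r(SdlCountTable(n), r_init=r_init,
                              pseudo_count=0.0, tol=1e-6, max_iter=150)

    def _theta(r, *vs):
        r = min(max(r, 1e-4), 0.5 - 1e-4)
        return [math.log(r / (0.5 - r))] + [
            math.log(min(max(t, 1e-6), _VCAP)) for t in vs]

    def negll_full(theta):
        r = 0.5 / (1.0 + math.exp(-theta[0]))
        u, v, x = (math.exp(t) for t in theta[1:])
        if max(u, v, x) > _VCAP:
            return np.inf
        return -_loglik_fast(nl, nzi, u, v, x, r)

    _, f_best = _nm_minimize(negll_full,
                             _theta(full.r, full.u, full.v, full.x),
                             xatol=1e-6, fatol=1e-8, maxiter=500)
    ll_full = max(full.loglik, -f_best)

    # Mendelian null with free r: standard two-point EM, Brent polish
    null = correct_pairwise_r(SdlCountTable(n), r_init=r_init,
                              pseudo_count=0.0, fix_viabilities=True,
                              tol=1e-9, max_iter=300)
    res_0 = optimize.minimize_scalar(
        lambda r: -_loglik_fast(nl, nzi, 1.0, 1.0, 1.0, r),
        bounds=(1e-6, 0.5), method="bounded",
        options={"xatol": 1e-10})
    ll_null = max(null.loglik, -res_0.fun)

    def negll_con(theta):
        r = 0.5 / (1.0 + math.exp(-theta[0]))
        u, v = math.exp(theta[1]), math.exp(theta[2])
        if max(u, v) > _VCAP:
            return np.inf
        return -_loglik_fast(nl, nzi, u, v, u * v, r)

    ll_con = -np.inf
    for start in (_theta(full.r, full.u, full.v), _theta(r_init, 1.0, 1.0)):
        _, f_best = _nm_minimize(negll_con, start, xatol=1e-6, fatol=1e-8,
                                 maxiter=400)
        ll_con = max(ll_con, -f_best)
    ll_con = max(ll_con, ll_null)  # null is nested in the constrained model

    lrt_d = max(2.0 * (ll_full - ll_null), 0.0)
    lrt_e = max(2.0 * (ll_full - ll_con), 0.0)
    return (lrt_d, float(stats.chi2.sf(lrt_d, df=3)),
            lrt_e, float(stats.chi2.sf(lrt_e, df=1)), full)


def epistasis_test_profiled(counts: SdlCountTable, r_init: float = 0.25,
                            pseudo_count: float = 0.5) -> tuple[float, float]:
    """Epistasis LRT (H0: x = u*v) with r profiled out of both hypotheses."""
    out = _pair_tests_profiled(counts, r_init, pseudo_count)
    return out[2], out[3]


def distortion_test_profiled(counts: SdlCountTable, r_init: float = 0.25,
                             pseudo_count: float = 0.5) -> tuple[float, float]:
    """Distortion LRT (H0: u = v = x = 1) with r profiled out."""
    out = _pair_tests_profiled(counts, r_init, pseudo_count)
    return out[0], out[1]


def correct_map(genotypes: GenotypeMatrix, lmap: LinkageMap,
                map_function: str = "kosambi") -> tuple[LinkageMap, pd.DataFrame]:
    """Re-estimate adjacent-marker distances allowing for gametic selection.

    For every adjacent marker pair the joint (r, u, v, x) EM is run on the
    tabulated 9-class counts; corrected cM distances come from the inverse
    Kosambi function, accumulated from the first marker.

    Returns the corrected map and a per-interval report.
    """
    from .core_map import ChromosomeMap

    new_chroms = []
    rows = []
    for cm in lmap.chromosomes:
        pos = [0.0]
        for i in range(len(cm) - 1):
            mA, mB = cm.markers[i], cm.markers[i + 1]
            d0 = cm.positions[i + 1] - cm.positions[i]
            counts, n_dropped = tabulate_counts(genotypes, mA, mB)
            fit = correct_pairwise_r(counts, r_init=max(r_from_d(d0), 1e-3))
            r_hat = min(fit.r, 0.5 - 1e-9)
            d_hat = kosambi_d_from_r(r_hat)
            pos.append(pos[-1] + d_hat)
            rows.append({"chrom": cm.name, "markerA": mA, "markerB": mB,
                         "d_input": float(d0), "r_hat": fit.r, "d_hat": d_hat,
                         "u": fit.u, "v": fit.v, "x": fit.x,
                         "n_dropped": n_dropped,
                         "unlinked": any("unlinked" in w for w in fit.warnings)})
        new_chroms.append(ChromosomeMap(name=cm.name, markers=list(cm.markers),
                                        positions=np.asarray(pos)))
    return LinkageMap(chromosomes=new_chroms), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# off-marker (interval) EM via multipoint conditional probabilities


def _joint16_gamete_view(joint: np.ndarray) -> np.ndarray:
    """(n, 4, 4) joint over ordered states at two positions -> (n, 4, 4)
    over (female gamete, male gamete)."""
    n = joint.shape[0]
    out = np.empty((n, 4, 4))
    for sA in range(4):
        fa, ma = sA >> 1, sA & 1
        for sB in range(4):
            fb, mb = sB >> 1, sB & 1
            out[:, 2 * fa + fb, 2 * ma + mb] = joint[:, sA, sB]
    return out


def em_fit_sdl_interval(genotypes: GenotypeMatrix, lmap: LinkageMap,
                        chrom: str, posA: float, posB: float,
                        tol: float = _DEFAULT_TOL,
                        max_iter: int = _DEFAULT_MAX_ITER,
                        map_function: str = "kosambi") -> SdlFit:
    """Fit the viabilities at two arbitrary positions of one chromosome.

    The 9-class counts are replaced by each individual's multipoint joint
    probability of the 16 ordered two-locus states given all markers
    (computed without selection); the E-step reweights these by the
    current post-selection/Mendelian frequency ratio, which for male
    gamete g is its viability weight.  Log-likelihoods are reported
    relative to the Mendelian model (the null model has log-likelihood 0),
    so likelihood-ratio tests are unchanged.
    """
    if not posA < posB:
        raise ValueError("posA must be strictly less than posB")
    cm = lmap.chromosome(chrom)
    lo, hi = cm.span
    if posA < lo - 1e-9 or posB > hi + 1e-9:
        raise ValueError(
            f"positions ({posA}, {posB}) outside chromosome {chrom!r} span "
            f"[{lo}, {hi}]"
        )
    eng = MultipointEngine(cm, genotypes, extra_positions=[posA, posB],
                           map_function=map_function)
    J0 = _joint16_gamete_view(eng.pair_joint(posA, posB))  # (n, fem, male)
    r = r_from_d(posB - posA, map_function)

    warnings: list[str] = []
    u = v = x = 1.0
    trace = []
    converged = False
    it = 0
    base = mendelian_gamete_freqs(r)

    def relative_loglik(w):
        lam = float((base * w).sum())
        per = (J0 * w[None, None, :]).sum((1, 2))
        return float(np.log(per).sum() - len(per) * math.log(lam))

    for it in range(1, max_iter + 1):
        w = np.array([1.0, v, u, x])
        trace.append(relative_loglik(w))
        post = J0 * w[None, None, :]
        post /= post.sum((1, 2), keepdims=True)
        c_male = post.sum((0, 1))
        u_new, v_new, x_new = _mstep_from_male_counts(c_male, r, warnings)
        delta = max(abs(u_new - u), abs(v_new - v), abs(x_new - x))
        u, v, x = u_new, v_new, x_new
        if delta < tol:
            converged = True
            break
    trace.append(relative_loglik(np.array([1.0, v, u, x])))
    if not converged:
        warnings.append(f"EM did not converge in {max_iter} iterations")
    fit = SdlFit(u=u, v=v, x=x, r=r, loglik=trace[-1],
                 loglik_trace=np.asarray(trace), n_iter=it,
                 converged=converged, warnings=warnings)
    fit.loglik_null = 0.0

    def negll(theta):
        uu, vv = np.exp(theta)
        return -relative_loglik(np.array([1.0, vv, uu, uu * vv]))

    best = np.inf
    for x0 in (np.log(np.clip([u, v], 1e-8, _VCAP)), np.zeros(2)):
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        best = min(best, res.fun)
    fit.loglik_noepi = -best
    return fit


# ---------------------------------------------------------------------------
# 2-D scan


def scan_pairs(genotypes: GenotypeMatrix, lmap: LinkageMap,
               adjust: str = "bonferroni", alpha: float = 0.05,
               grid_step: float | None = None,
               criterion: str = "distortion",
               map_function: str = "kosambi") -> SdlScanResult:
    """Fit the gametic-selection model at every position pair.

    By default all marker pairs within each chromosome are tested; with
    ``grid_step`` the scan also covers an evenly spaced off-marker grid
    (interval EM).  Pairs where every individual is codominant-complete
    use the fast count-table EM with r profiled out of every test
    hypothesis (see :func:`_pair_tests_profiled`); pairs involving
    dominant/missing observations fall back to the interval EM with r
    fixed from the map.

    Significance is decided by the 3-df distortion test (``criterion =
    "distortion"``, the default: any gametic selection at the pair calls
    for probability correction downstream) or the 1-df epistasis test
    (``"epistasis"``), after the configured multiple-testing adjustment
    (``"bonferroni"`` or ``"none"``).  Note that selection on one true
    SDL pair induces associations in the surviving gamete pool over the
    whole linked region, so many pairs around the true one are expected
    to reach significance; the ranking orders pairs by the criterion's
    likelihood-ratio statistic.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if criterion not in ("epistasis", "distortion"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    fits = {}
    for cm in lmap.chromosomes:
        if len(cm) < 2:
            logger.info("chromosome %s has a single marker; skipped", cm.name)
            continue
        positions = list(np.asarray(cm.positions, dtype=float))
        if grid_step is not None:
            lo, hi = cm.span
            g = np.arange(lo, hi + 1e-9, grid_step)
            positions = sorted(set(np.round(positions + list(g), 9)))
        for pA, pB in itertools.combinations(positions, 2):
            fit, counts = _fit_pair(genotypes, lmap, cm, pA, pB, map_function)
            if counts is not None:
                lrt, p, lrt_e, p_e, _ = _pair_tests_profiled(counts,
                                                             r_init=fit.r)
                fit.lrt_distortion, fit.p_distortion = lrt, p
                fit.lrt_epistasis, fit.p_epistasis = lrt_e, p_e
            else:
                lrt, p = test_distortion(fit)
                lrt_e, p_e = test_epistasis(fit)
            fits[(cm.name, pA, pB)] = fit
            rows.append({"chrom": cm.name, "posA": pA, "posB": pB,
                         "u": fit.u, "v": fit.v, "x": fit.x, "r": fit.r,
                         "loglik": fit.loglik,
                         "lrt_distortion": lrt, "p_distortion": p,
                         "lrt_epistasis": lrt_e, "p_epistasis": p_e})
    table = pd.DataFrame(rows)
    if len(table):
        m = len(table)
        pcol = f"p_{criterion}"
        if adjust == "bonferroni":
            table["p_adjusted"] = np.minimum(table[pcol] * m, 1.0)
        else:
            table["p_adjusted"] = table[pcol]
        table["significant"] = table["p_adjusted"] < alpha
        table = table.sort_values(f"lrt_{criterion}", ascending=False,
                                  kind="stable").reset_index(drop=True)
    else:
        table["p_adjusted"] = []
        table["significant"] = []
    return SdlScanResult(table=table, fits=fits, adjust=adjust, alpha=alpha)


def _fit_pair(genotypes, lmap, cm, pA, pB, map_function):
    """Dispatch to the count EM at codominant-complete marker pairs,
    otherwise the interval EM.  Returns (fit, counts-or-None)."""
    mp = np.asarray(cm.positions, dtype=float)
    iA = np.argmin(np.abs(mp - pA))
    iB = np.argmin(np.abs(mp - pB))
    at_markers = abs(mp[iA] - pA) < 1e-9 and abs(mp[iB] - pB) < 1e-9
    if at_markers:
        counts, n_dropped = tabulate_counts(genotypes, cm.markers[iA],
                                            cm.markers[iB])
        if n_dropped == 0:
            r = r_from_d(pB - pA, map_function)
            return em_fit_sdl_at_markers(counts, r=r, fit_noepi=False), counts
    fit = em_fit_sdl_interval(genotypes, lmap, cm.name, pA, pB,
                              map_function=map_function)
    return fit, None
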