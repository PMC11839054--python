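"""Per-clade divergence and abundance inference from informative-site counts.

Two-step model. Step one fits an ordinary negative binomial to the read
depth over *all* alleles at a clade's informative positions, yielding the
expected depth ``lam_all`` and a moment-matched Gamma prior over the
dispersion shape. Step two fits a zero-inflated negative binomial to the
reads carrying the *clade-specific* allele, where the zero-inflation
probability ``pi`` estimates the fraction of markers systematically absent
from the sample — the divergence proxy. Inference is by slice-within-Gibbs
sampling (default) or penalized maximum likelihood (fast path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .counts import AlleleCountsMatrix
from .phylo import ReferenceDatabase

_LOG_ALPHA_BOUNDS = (-7.0, 12.0)
_LOG_LAM_BOUNDS = (-12.0, 12.0)


# ---------------------------------------------------------------------------
# Likelihood primitives

def nb_logpmf(x, lam, alpha):
    """Negative binomial log-pmf in (mean, shape) parameterization.

    mean ``lam``, variance ``lam + lam**2 / alpha``; equals the
    Gamma(shape=alpha, rate=alpha/lam)-Poisson mixture marginal.
    """
    x = np.asarray(x, dtype=float)
    if lam <= 0:
        return np.where(x == 0, 0.0, -np.inf)
    la = math.log(alpha)
    lal = math.log(alpha + lam)
    return (
        gammaln(x + alpha)
        - gammaln(alpha)
        - gammaln(x + 1)
        + alpha * (la - lal)
        + x * (math.log(lam) - lal)
    )


def zinb_loglik(x, pi, lam, alpha):
    """Zero-inflated NB log-likelihood of count vector ``x``."""
    x = np.asarray(x, dtype=float)
    nb = nb_logpmf(x, lam, alpha)
    with np.errstate(divide="ignore"):
        out = np.logaddexp(
            np.where(x == 0, math.log(pi) if pi > 0 else -np.inf, -np.inf),
            (math.log1p(-pi) if pi < 1 else -np.inf) + nb,
        )
    return float(out.sum())


def slice_sample(x0, logf, rng, width=1.0, max_steps=50):
    """One stepping-out + shrinkage slice-sampling update (univariate)."""
    y = logf(x0) + math.log(rng.uniform(1e-300, 1.0))
    lo = x0 - width * rng.uniform()
    hi = lo + width
    j = int(max_steps * rng.uniform())
    k = max_steps - 1 - j
    while j > 0 and y < logf(lo):
        lo -= width
        j -= 1
    while k > 0 and y < logf(hi):
        hi += width
        k -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if y < logf(x1):
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class InformativeCounts:
    """Counts at one clade's barcode positions within one sample."""

    clade_id: str
    positions: np.ndarray    # barcode positions (1-based)
    x: np.ndarray            # reads carrying the clade-specific allele
    y: np.ndarray            # reads carrying any allele at the same position
    n_missing: int = 0       # barcode positions absent from the sample matrix

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if (self.x < 0).any() or (self.x > self.y).any():
            raise ValueError("need 0 <= x_i <= y_i")

    @property
    def n_supported(self) -> int:
        """Positions with at least one clade-specific read."""
        return int((self.x >= 1).sum())


@dataclass
class DispersionPrior:
    """Gamma(shape=a, rate=b) prior over the NB dispersion shape."""

    a: float
    b: float = 1.0
    wide_fallback: bool = False

    @classmethod
    def from_depths(cls, y, classical: bool = False) -> "DispersionPrior":
        """Moment-matched prior from all-allele depths.

        ``a = mean / (var - mean)`` with ``b = 1`` (as printed; the
        classical method-of-moments shape ``mean**2 / (var - mean)`` is
        available via ``classical=True``).  Under-dispersed depths get a
        wide weakly-informative fallback, flagged.
        """
        y = np.asarray(y, dtype=float)
        m = y.mean()
        v = y.var(ddof=1) if len(y) > 1 else 0.0
        if v > m > 0:
            a = (m * m if classical else m) / (v - m)
            return cls(float(a), 1.0, False)
        return cls(2.0, 0.1, True)

    def logpdf(self, alpha: float) -> float:
        return (self.a - 1.0) * math.log(alpha) - self.b * alpha


class NoCoverageError(RuntimeError):
    """All-allele depth is zero everywhere; nothing can be fit."""


def fit_all_alleles(y, classical: bool = False) -> tuple[float, float, DispersionPrior]:
    """Step one: Bayesian NB fit of all-allele depths.

    Returns ``(lam_all, alpha_all, prior)`` where ``alpha_all`` is the
    posterior mode of the dispersion shape under the moment-matched
    Gamma(a, 1) prior, and ``prior`` is a Gamma approximation (Laplace,
    moment-matched) of the step-one *posterior* over alpha — this is what
    informs the clade-specific fit, so the second step inherits the full
    precision of the depth data rather than the diffuse moment prior.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 informative positions")
    if not (y > 0).any():
        raise NoCoverageError("no reads at any informative position")
    lam = float(y.mean())
    step_one_prior = DispersionPrior.from_depths(y, classical=classical)

    def neg_logpost(log_alpha):
        a = math.exp(log_alpha)
        return -(float(nb_logpmf(y, lam, a).sum()) + step_one_prior.logpdf(a))

    res = minimize_scalar(neg_logpost, bounds=_LOG_ALPHA_BOUNDS, method="bounded")
    alpha = float(math.exp(res.x))

    # Laplace curvature in alpha space -> Gamma moment match
    eps = max(1e-4, 1e-3 * alpha)

    def f(a):
        return -(float(nb_logpmf(y, lam, a).sum()) + step_one_prior.logpdf(a))

    h = (f(alpha + eps) - 2.0 * f(alpha) + f(alpha - eps)) / (eps * eps) \
        if alpha > eps else 0.0
    if h > 0 and np.isfinite(h):
        var = 1.0 / h
        prior = DispersionPrior(alpha * alpha / var, alpha / var,
                                step_one_prior.wide_fallback)
    else:
        prior = step_one_prior
    return lam, alpha, prior


# ---------------------------------------------------------------------------
# Clade fit container

@dataclass
class CladeFit:
    """Posterior (or penalized-MLE) summary for one clade in one sample."""

    clade_id: str
    status: str = "ok"                 # ok | no-call | no-coverage
    method: str = "gibbs"
    pi_map: float | None = None
    lam_cs: float | None = None
    alpha_cs: float | None = None
    lam_all: float | None = None
    alpha_all: float | None = None
    prior: DispersionPrior | None = None
    pi_draws: np.ndarray | None = None
    lam_draws: np.ndarray | None = None
    alpha_draws: np.ndarray | None = None
    pi_grid: np.ndarray | None = None
    pi_density: np.ndarray | None = None   # normalized profile pseudo-density
    rhat: float | None = None
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    steps: int = 0
    burnin_frac: float = 0.0
    n_positions: int = 0
    n_supported: int = 0

    def pi_mass_below(self, threshold: float) -> float:
        """Fraction of the pi posterior (or pseudo-posterior) below a value."""
        if self.pi_draws is not None:
            return float(np.mean(self.pi_draws < threshold))
        if self.pi_grid is not None:
            mask = self.pi_grid < threshold
            return float(
                np.trapezoid(np.where(mask, self.pi_density, 0.0), self.pi_grid)
            )
        raise ValueError("fit carries no posterior representation")

    def pi_hpd(self, mass: float = 0.95) -> tuple[float, float]:
        if self.pi_draws is not None:
            return hpd_interval(self.pi_draws, mass)
        if self.pi_grid is not None:
            return _grid_hdr(self.pi_grid, self.pi_density, mass)
        raise ValueError("fit carries no posterior representation")


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (sorted-window)."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(draws[0]), float(draws[-1])
    widths = draws[m - 1 + np.arange(n - m + 1)] - draws[: n - m + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m - 1])


def _grid_hdr(grid, density, mass):
    """Highest-density region on a grid, reported as its bounding interval."""
    cell = np.gradient(grid)
    probs = density * cell
    probs = probs / probs.sum()
    order = np.argsort(density)[::-1]
    cum = np.cumsum(probs[order])
    k = int(np.searchsorted(cum, mass)) + 1
    chosen = np.sort(order[:k])
    return float(grid[chosen[0]]), float(grid[chosen[-1]])


def map_estimate(draws) -> float:
    """Mode of a sample via the half-sample (shortest-window) estimator."""
    d = np.sort(np.asarray(draws, dtype=float))
    while len(d) > 3:
        m = max(2, int(math.ceil(len(d) / 2)))
        widths = d[m - 1:] - d[: len(d) - m + 1]
        i = int(np.argmin(widths))
        d = d[i: i + m]
    return float(np.mean(d))


def split_rhat(draws) -> float:
    """Split-chain potential scale reduction factor on one chain."""
    d = np.asarray(draws, dtype=float)
    n = len(d) // 2
    halves = np.stack([d[:n], d[n: 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# Extraction

def extract_informative_counts(
    sample: AlleleCountsMatrix,
    db: ReferenceDatabase,
    clade_id: str,
    sample_index: int = 0,
) -> InformativeCounts:
    """(x, y) count vectors at a clade's barcode positions for one sample.

    Strand counts are summed. Barcode positions absent from the sample
    matrix are recorded as x = y = 0 and tallied in ``n_missing``.
    """
    bc = db.barcodes[clade_id]
    allele_depth = sample.allele_depth()[sample_index]    # (P, 4)
    total = allele_depth.sum(axis=1)
    pos_index = {int(p): i for i, p in enumerate(sample.positions)}
    x = np.zeros(bc.size, dtype=np.int64)
    y = np.zeros(bc.size, dtype=np.int64)
    missing = 0
    for k, (pos, allele) in enumerate(bc.snvs):
        i = pos_index.get(pos)
        if i is None:
            missing += 1
            continue
        x[k] = allele_depth[i, allele]
        y[k] = total[i]
    return InformativeCounts(clade_id, bc.positions, x, y, n_missing=missing)


# ---------------------------------------------------------------------------
# Gibbs sampler

def _log_lam_prior(u: float, lam_prior: tuple[float, float] | None) -> float:
    """Log prior density of lam in u = log(lam) space (Jacobian included).

    ``lam_prior`` is an optional Gamma (shape, rate); None means flat in
    log-lam within the working bounds. Anchoring the rate at the
    all-allele depth breaks the lam->0 / pi->1 confound when markers are
    absent everywhere.
    """
    if not (_LOG_LAM_BOUNDS[0] <= u <= _LOG_LAM_BOUNDS[1]):
        return -math.inf
    if lam_prior is None:
        return 0.0
    s, r = lam_prior
    return s * u - r * math.exp(u)


def fit_zinb_gibbs(
    ic: InformativeCounts,
    prior: DispersionPrior,
    steps: int = 10000,
    burnin_frac: float = 0.10,
    seed: int | None = None,
    min_supported: int = 10,
    lam_prior: tuple[float, float] | None = None,
) -> CladeFit:
    """Slice-within-Gibbs posterior for (pi, lam, alpha) of the ZINB.

    Latent indicators ``z_i`` get exact Bernoulli updates against the
    marginal NB likelihood; ``pi`` is conjugate under a Beta(1, 1) prior;
    ``lam`` (log-flat or Gamma ``lam_prior``) and ``alpha`` (Gamma prior
    from step one) are updated by stepping-out slice sampling on the log
    scale. Deterministic given ``seed``. Requires more than
    ``min_supported`` positions carrying at least one clade-specific
    read, else returns a ``no-call`` fit.
    """
    fit = CladeFit(
        ic.clade_id, method="gibbs", prior=prior, seed=seed, steps=steps,
        burnin_frac=burnin_frac, n_positions=len(ic.x), n_supported=ic.n_supported,
    )
    if ic.n_supported <= min_supported:
        fit.status = "no-call"
        return fit

    rng = np.random.default_rng(seed)
    x = ic.x
    ux, inv = np.unique(x, return_inverse=True)
    zero_mask = x == 0
    n = len(x)

    pi = min(max(float(zero_mask.mean()) * 0.5, 0.02), 0.90)
    if (x > 0).any():
        lam = max(float(x[x > 0].mean()), 0.1)
    elif lam_prior is not None:
        lam = lam_prior[0] / lam_prior[1]
    else:
        lam = 1.0
    alpha = prior.a / prior.b if not prior.wide_fallback else 1.0
    z = (~zero_mask).astype(float)

    def weighted_loglik(lam_, alpha_, w):
        return float(np.dot(w, nb_logpmf(ux, lam_, alpha_)))

    n_draws = steps
    pi_d = np.empty(n_draws)
    lam_d = np.empty(n_draws)
    alpha_d = np.empty(n_draws)

    for t in range(steps):
        # z | rest  (only zero-count positions are uncertain)
        p_nb0 = math.exp(alpha * (math.log(alpha) - math.log(alpha + lam)))
        p1 = (1.0 - pi) * p_nb0
        r = p1 / (pi + p1) if (pi + p1) > 0 else 0.0
        z[zero_mask] = (rng.uniform(size=int(zero_mask.sum())) < r).astype(float)

        # pi | z   (Beta(1,1) prior)
        n1 = float(z.sum())
        pi = rng.beta(1.0 + (n - n1), 1.0 + n1)

        w = np.bincount(inv, weights=z, minlength=len(ux))

        # lam | rest
        u = slice_sample(
            math.log(lam),
            lambda u_: (
                weighted_loglik(math.exp(u_), alpha, w) + _log_lam_prior(u_, lam_prior)
                if _LOG_LAM_BOUNDS[0] <= u_ <= _LOG_LAM_BOUNDS[1]
                else -math.inf
            ),
            rng,
        )
        lam = math.exp(u)

        # alpha | rest  (Gamma prior from step one, Jacobian included)
        v = slice_sample(
            math.log(alpha),
            lambda v_: (
                weighted_loglik(lam, math.exp(v_), w)
                + prior.a * v_
                - prior.b * math.exp(v_)
                if _LOG_ALPHA_BOUNDS[0] <= v_ <= _LOG_ALPHA_BOUNDS[1]
                else -math.inf
            ),
            rng,
        )
        alpha = math.exp(v)

        pi_d[t], lam_d[t], alpha_d[t] = pi, lam, alpha

    keep = slice(int(steps * burnin_frac), None)
    fit.pi_draws = pi_d[keep]
    fit.lam_draws = lam_d[keep]
    fit.alpha_draws = alpha_d[keep]
    fit.pi_map = map_estimate(fit.pi_draws)
    fit.lam_cs = map_estimate(fit.lam_draws)
    fit.alpha_cs = map_estimate(fit.alpha_draws)
    fit.rhat = split_rhat(fit.pi_draws)
    if fit.rhat > 1.1:
        fit.warnings.append(f"split-Rhat on pi = {fit.rhat:.3f} > 1.1")
    return fit


# ---------------------------------------------------------------------------
# Penalized MLE

def _profile_nll(x, pi, prior, start, lam_prior=None):
    """Minimize penalized ZINB NLL over (log lam, log alpha) at fixed pi."""

    def nll(theta):
        if not (_LOG_LAM_BOUNDS[0] <= theta[0] <= _LOG_LAM_BOUNDS[1]):
            return 1e12
        if not (_LOG_ALPHA_BOUNDS[0] <= theta[1] <= _LOG_ALPHA_BOUNDS[1]):
            return 1e12
        lam, alpha = math.exp(theta[0]), math.exp(theta[1])
        return -(
            zinb_loglik(x, pi, lam, alpha)
            + prior.logpdf(alpha)
            + _log_lam_prior(theta[0], lam_prior)
        )

    res = minimize(
        nll, start, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    return res.x, float(res.fun)


def fit_zinb_mle(
    ic: InformativeCounts,
    prior: DispersionPrior,
    min_supported: int = 10,
    grid_size: int = 41,
    lam_prior: tuple[float, float] | None = None,
) -> CladeFit:
    """Penalized-MLE ZINB fit with a profile likelihood curve over pi.

    The Gamma prior over alpha enters as a log-penalty (preserving the
    two-step information flow). The normalized profile likelihood over a
    pi grid stands in for the posterior when computing detection masses
    and HPD-like intervals.
    """
    fit = CladeFit(
        ic.clade_id, method="mle", prior=prior,
        n_positions=len(ic.x), n_supported=ic.n_supported,
    )
    if ic.n_supported <= min_supported:
        fit.status = "no-call"
        return fit

    x = ic.x.astype(float)
    grid = np.linspace(0.0, 0.999, grid_size)
    if (x > 0).any():
        lam0 = max(float(x[x > 0].mean()), 0.1)
    else:
        lam0 = lam_prior[0] / lam_prior[1] if lam_prior else 1.0
    alpha0 = prior.a / prior.b if prior.b > 0 and not prior.wide_fallback else 1.0
    start = np.array([math.log(lam0), math.log(alpha0)])

    nlls = np.empty(grid_size)
    thetas = np.empty((grid_size, 2))
    th = start
    failed = False
    for i, pi in enumerate(grid):
        try:
            th, f = _profile_nll(x, pi, prior, th, lam_prior)
        except Exception:
            failed = True
            break
        thetas[i] = th
        nlls[i] = f

    if failed or not np.isfinite(nlls).all():
        # coarse grid fallback over all three parameters
        fit.warnings.append("optimizer failure; coarse-grid fallback")
        lams = np.geomspace(0.05, max(x.max(), 1.0) * 2, 40)
        alphas = np.geomspace(0.05, 100, 25)
        nlls = np.empty(grid_size)
        thetas = np.empty((grid_size, 2))
        for i, pi in enumerate(grid):
            best = (np.inf, 0.0, 0.0)
            for lam in lams:
                for alpha in alphas:
                    v = -(zinb_loglik(x, pi, lam, alpha) + prior.logpdf(alpha))
                    if v < best[0]:
                        best = (v, lam, alpha)
            nlls[i] = best[0]
            thetas[i] = (math.log(best[1]), math.log(best[2]))

    prof = -(nlls - nlls.min())             # profile log-likelihood, max 0
    dens = np.exp(prof)
    dens /= np.trapezoid(dens, grid)
    i_best = int(np.argmin(nlls))

    fit.pi_grid = grid
    fit.pi_density = dens
    fit.pi_map = float(grid[i_best])
    fit.lam_cs = float(math.exp(thetas[i_best, 0]))
    fit.alpha_cs = float(math.exp(thetas[i_best, 1]))
    return fit


# ---------------------------------------------------------------------------
# Detection, abundance, profiles

def relative_abundance(fit: CladeFit) -> float | None:
    """Ratio of clade-specific to all-allele MAP depth (may exceed 1)."""
    if fit.lam_all is None or fit.lam_all == 0:
        return None
    if fit.lam_cs is None:
        return 0.0
    return float(fit.lam_cs / fit.lam_all)


def decide_detection(
    fit: CladeFit,
    abundance: float | None,
    d_thresh: float = 0.35,
    p_frac: float = 0.50,
    hpd_low_max: float = 0.10,
    min_abundance: float = 0.01,
) -> bool:
    """Presence call from the pi posterior and the abundance floor.

    Detected iff at least ``p_frac`` of the pi posterior lies below
    ``d_thresh``, the 95% HPD lower bound on pi is below ``hpd_low_max``,
    and relative abundance is at least ``min_abundance``.
    """
    if fit.status != "ok" or abundance is None:
        return False
    if fit.pi_mass_below(d_thresh) < p_frac:
        return False
    if fit.pi_hpd(0.95)[0] >= hpd_low_max:
        return False
    return abundance >= min_abundance


@dataclass
class ProfileRow:
    clade_id: str
    level: int
    detected: bool
    relative_abundance: float | None
    pi_map: float | None
    pi_hpd_low: float | None
    pi_hpd_high: float | None
    n_positions: int
    n_supported: int
    status: str
    flags: str = ""


@dataclass
class SampleProfile:
    sample_id: str
    rows: list[ProfileRow]

    def level_sum(self, level: int) -> float:
        return sum(
            r.relative_abundance or 0.0
            for r in self.rows
            if r.level == level and r.detected
        )

    def classified_fraction(self, level: int) -> float:
        return min(self.level_sum(level), 1.0)

    def unclassified_fraction(self, level: int) -> float:
        return max(1.0 - self.level_sum(level), 0.0)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "clade": r.clade_id,
                    "level": r.level,
                    "detected": int(r.detected),
                    "relative_abundance": (
                        "" if r.relative_abundance is None
                        else f"{r.relative_abundance:.6g}"
                    ),
                    "pi_MAP": "" if r.pi_map is None else f"{r.pi_map:.6g}",
                    "pi_HPD_low": "" if r.pi_hpd_low is None else f"{r.pi_hpd_low:.6g}",
                    "pi_HPD_high": "" if r.pi_hpd_high is None else f"{r.pi_hpd_high:.6g}",
                    "n_informative_positions": r.n_positions,
                    "n_supported_positions": r.n_supported,
                    "status": r.status,
                    "flags": r.flags,
                }
                for r in self.rows
            ]
        )


def normalize_profile(profile: SampleProfile) -> SampleProfile:
    """Scale each level's detected abundances down when they sum above 1.

    Level sums at or below 1 are untouched; the shortfall is the
    novel/unclassified fraction.
    """
    rows = [ProfileRow(**vars(r)) for r in profile.rows]
    for level in sorted({r.level for r in rows}):
        s = sum(
            r.relative_abundance or 0.0
            for r in rows
            if r.level == level and r.detected
        )
        if s > 1.0:
            for r in rows:
                if r.level == level and r.detected and r.relative_abundance:
                    r.relative_abundance = r.relative_abundance / s
                    r.flags = (r.flags + ";" if r.flags else "") + "normalized"
    return SampleProfile(profile.sample_id, rows)


def classify_sample(
    sample: AlleleCountsMatrix,
    db: ReferenceDatabase,
    sample_index: int = 0,
    method: str = "gibbs",
    steps: int = 10000,
    burnin_frac: float = 0.10,
    seed: int | None = None,
    d_thresh: float = 0.35,
    p_frac: float = 0.50,
    hpd_low_max: float = 0.10,
    min_abundance: float = 0.01,
    normalize: bool = True,
) -> SampleProfile:
    """Run per-clade inference over a whole database for one sample."""
    seeds = (
        np.random.SeedSequence(seed).spawn(len(db.clades))
        if seed is not None
        else [None] * len(db.clades)
    )
    rows: list[ProfileRow] = []
    for k, clade in enumerate(db.clades):
        level = db.levels[clade.clade_id]
        ic = extract_informative_counts(sample, db, clade.clade_id, sample_index)
        try:
            lam_all, alpha_all, prior = fit_all_alleles(ic.y)
        except NoCoverageError:
            rows.append(
                ProfileRow(clade.clade_id, level, False, None, None, None, None,
                           len(ic.x), ic.n_supported, "no-coverage")
            )
            continue
        lam_prior = (0.5, 0.5 / lam_all) if lam_all > 0 else None
        if method == "gibbs":
            child_seed = (
                int(seeds[k].generate_state(1)[0]) if seeds[k] is not None else None
            )
            fit = fit_zinb_gibbs(
                ic, prior, steps, burnin_frac, child_seed, lam_prior=lam_prior
            )
        elif method == "mle":
            fit = fit_zinb_mle(ic, prior, lam_prior=lam_prior)
        else:
            raise ValueError(f"unknown inference method: {method!r}")
        fit.lam_all, fit.alpha_all = lam_all, alpha_all
        if fit.status != "ok":
            rows.append(
                ProfileRow(clade.clade_id, level, False, None, None, None, None,
                           len(ic.x), ic.n_supported, fit.status)
            )
            continue
        abundance = relative_abundance(fit)
        detected = decide_detection(
            fit, abundance, d_thresh, p_frac, hpd_low_max, min_abundance
        )
        lo, hi = fit.pi_hpd(0.95)
        rows.append(
            ProfileRow(
                clade.clade_id, level, detected, abundance, fit.pi_map, lo, hi,
                len(ic.x), ic.n_supported, "ok", ";".join(fit.warnings),
            )
        )
    profile = SampleProfile(sample.sample_ids[sample_index], rows)
    return normalize_profile(profile) if normalize else profile
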