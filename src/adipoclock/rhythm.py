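"""Mixed-model cosinor rhythm detection on DLMO-aligned time series.

Each probe's log2 profile across subjects is fitted with a linearised
single-component cosinor of fixed 24-h period plus a linear trend,

    y_ij = mesor + slope * t_ij + bc * cos(w t_ij) + bs * sin(w t_ij)
           + u_i + e_ij,        u_i ~ N(0, tau^2), e_ij ~ N(0, sigma^2),

with a random intercept u_i per subject. Amplitude A = sqrt(bc^2 + bs^2)
and peak time phi = atan2(bs, bc) / w are derived quantities. A probe is
classified circadian when the conditional R^2 exceeds a threshold (default
0.8) and the 95% CI of the amplitude excludes zero. The false discovery
rate is estimated by re-running the identical fit-and-classify pipeline
after shuffling values across time points within each subject.

The fit profiles the REML criterion over the variance ratio
lambda = tau^2 / sigma^2; because the random-effect design is a single
grouping factor, every quantity reduces to per-subject sums, which lets the
whole search run vectorised across thousands of probes (needed for the
permutation FDR, which refits every probe under every permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignedSeries",
    "CosinorFit",
    "FdrEstimate",
    "fit_cosinor_mixed",
    "fit_cosinor_batch",
    "classify_circadian",
    "permutation_fdr",
    "peak_time_histogram",
]

_TINY = 1e-300


@dataclass(frozen=True)
class AlignedSeries:
    """One probe's observations across subjects on the DLMO-relative axis."""

    probe_id: str
    subject_ids: np.ndarray
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.subject_ids)
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if not (s.shape == t.shape == v.shape) or t.ndim != 1:
            raise ValueError("subject_ids, times_h, values must be matched 1-d")
        counts = pd.Series(s).value_counts()
        if (counts < 3).any():
            warnings.warn(
                f"{self.probe_id}: some subjects contribute < 3 observations; "
                "trend + cosinor may be poorly identified",
                stacklevel=2,
            )
        object.__setattr__(self, "subject_ids", s)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)


@dataclass
class CosinorFit:
    probe_id: str
    mesor: float
    trend_slope: float
    beta_cos: float
    beta_sin: float
    amplitude: float
    amplitude_se: float
    amplitude_ci_low: float
    amplitude_ci_high: float
    peak_time_h: float
    r_squared: float
    is_circadian: bool
    subject_intercepts: dict[str, float] = field(default_factory=dict)
    sigma2: float = np.nan
    variance_ratio: float = np.nan


@dataclass
class FdrEstimate:
    n_observed_circadian: int
    mean_permuted_circadian: float
    fdr: float  # nan when no observed discoveries
    n_permutations: int
    seed: int | None
    permuted_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def fdr_capped(self) -> float:
        """FDR for summaries: capped at 1, nan when undefined."""
        return min(self.fdr, 1.0) if np.isfinite(self.fdr) else np.nan


def wrap_to_half_period(x, period: float = 24.0):
    return (np.asarray(x) + period / 2) % period - period / 2


# ---------------------------------------------------------------------------
# vectorised profiled-REML engine

class _Design:
    """Shared fixed-effect design and per-subject sufficient statistics."""

    def __init__(self, times_h: np.ndarray, subjects: np.ndarray,
                 period_h: float = 24.0):
        t = np.asarray(times_h, dtype=float)
        codes, uniques = pd.factorize(np.asarray(subjects))
        w = 2 * np.pi / period_h
        X = np.column_stack([np.ones_like(t), t, np.cos(w * t), np.sin(w * t)])
        m = len(uniques)
        G = np.zeros((m, len(t)))
        G[codes, np.arange(len(t))] = 1.0
        self.period_h = period_h
        self.t = t
        self.codes = codes
        self.subject_labels = [str(u) for u in uniques]
        self.X = X
        self.n, self.p = X.shape
        self.m = m
        self.G = G
        self.n_i = G.sum(axis=1)
        self.XtX = X.T @ X
        self.XS = G @ X  # (m, p) per-subject column sums of X

    def reml_stats(self, Y: np.ndarray):
        return {
            "XtY": self.X.T @ Y,          # (p, N)
            "S": self.G @ Y,              # (m, N)
            "yy": np.einsum("ij,ij->j", Y, Y),
        }

    def neg2_reml(self, lam: np.ndarray, stats, want_fit: bool = False):
        """-2 REML log-likelihood (up to a constant) for per-probe lambda."""
        n_i = self.n_i[:, None]
        c = lam[None, :] / (1.0 + lam[None, :] * n_i)        # (m, N)
        A = self.XtX[None] - np.einsum("mn,mp,mq->npq", c, self.XS, self.XS)
        b = stats["XtY"].T - np.einsum("mn,mp->np", c * stats["S"], self.XS)
        beta = np.linalg.solve(A, b[..., None])[..., 0]      # (N, p)
        q = stats["yy"] - (c * stats["S"] ** 2).sum(axis=0)
        rss = np.maximum(q - np.einsum("np,np->n", beta, b), 0.0)
        dof = self.n - self.p
        logdetV = np.log1p(lam[None, :] * n_i).sum(axis=0)
        _, logdetA = np.linalg.slogdet(A)
        nll = dof * np.log(np.maximum(rss, _TINY) / dof) + logdetV + logdetA
        if not want_fit:
            return nll
        sigma2 = rss / dof
        cov = np.linalg.inv(A) * sigma2[:, None, None]
        sres = stats["S"] - self.XS @ beta.T                 # (m, N)
        blup = c * sres                                      # (m, N)
        return nll, beta, sigma2, cov, blup

    def profile_lambda(self, Y: np.ndarray, allow_random: bool = True):
        """Per-probe REML-optimal variance ratio via grid + golden section."""
        stats = self.reml_stats(Y)
        N = Y.shape[1]
        if not allow_random or self.m < 2:
            return np.zeros(N), stats
        grid = np.concatenate([[0.0], np.logspace(-8, 6, 29)])
        nlls = np.stack([
            self.neg2_reml(np.full(N, g), stats) for g in grid
        ])  # (G, N)
        best = np.argmin(nlls, axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, len(grid) - 1)]
        # golden section on u = log10(lambda + delta)
        delta = 1e-9
        ulo = np.log10(lo + delta)
        uhi = np.log10(hi + delta)
        invphi = (np.sqrt(5.0) - 1.0) / 2.0

        def f(u):
            return self.neg2_reml(np.maximum(10.0**u - delta, 0.0), stats)

        u1 = uhi - invphi * (uhi - ulo)
        u2 = ulo + invphi * (uhi - ulo)
        f1, f2 = f(u1), f(u2)
        for _ in range(35):
            take_left = f1 < f2
            uhi = np.where(take_left, u2, uhi)
            ulo = np.where(take_left, ulo, u1)
            u2n = ulo + invphi * (uhi - ulo)
            u1n = uhi - invphi * (uhi - ulo)
            f2n = np.where(take_left, f1, np.nan)
            # evaluate only the fresh point (one batched call per iteration)
            fresh = np.where(take_left, u1n, u2n)
            ffresh = f(fresh)
            f1 = np.where(take_left, ffresh, f2)
            f2 = np.where(take_left, f2n, ffresh)
            u1, u2 = u1n, u2n
        lam = np.maximum(10.0 ** ((ulo + uhi) / 2.0) - delta, 0.0)
        # keep the boundary (pure fixed effects) when it is no worse
        nll_lam = self.neg2_reml(lam, stats)
        nll_zero = nlls[0]
        lam = np.where(nll_zero <= nll_lam, 0.0, lam)
        return lam, stats


def _amplitude_ci_delta(bc, bs, cov_cs, z: float = 1.959963984540054):
    amp = np.hypot(bc, bs)
    safe = np.maximum(amp, 1e-12)
    g = np.stack([bc / safe, bs / safe], axis=-1)  # (N, 2)
    var = np.einsum("ni,nij,nj->n", g, cov_cs, g)
    # near-zero amplitude: fall back to the mean component variance
    fallback = 0.5 * (cov_cs[:, 0, 0] + cov_cs[:, 1, 1])
    var = np.where(amp < 1e-12, fallback, var)
    se = np.sqrt(np.maximum(var, 0.0))
    return amp, se, amp - z * se, amp + z * se


def _amplitude_ci_bootstrap(bc, bs, cov_cs, n_boot: int, seed):
    rng = np.random.default_rng(seed)
    amp = np.hypot(bc, bs)
    jitter = 1e-15 * np.eye(2)
    L = np.linalg.cholesky(cov_cs + jitter)
    z = rng.standard_normal((n_boot, len(bc), 2))
    draws = np.stack([bc, bs], axis=-1)[None] + np.einsum("nij,bnj->bni", L, z)
    amps = np.hypot(draws[..., 0], draws[..., 1])
    lo = np.percentile(amps, 2.5, axis=0)
    hi = np.percentile(amps, 97.5, axis=0)
    se = amps.std(axis=0, ddof=1)
    return amp, se, lo, hi


def fit_cosinor_batch(
    times_h: np.ndarray,
    subjects: np.ndarray,
    Y: np.ndarray,
    probe_ids=None,
    period_h: float = 24.0,
    r2_threshold: float = 0.8,
    ci_method: str = "delta",
    n_boot: int = 500,
    seed: int | None = None,
    r2_kind: str = "conditional",
) -> pd.DataFrame:
    """Fit the mixed cosinor to every column of ``Y`` (observations x probes).

    Returns a DataFrame with one row per probe: mesor, trend_slope,
    beta_cos, beta_sin, amplitude (+ SE and 95% CI), peak_time_h in
    [-12, 12), r_squared and the circadian classification. ``r2_kind``
    selects conditional (fixed + predicted random effects, default) or
    marginal (fixed effects only) fitted values for R^2.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    design = _Design(times_h, subjects, period_h)
    if design.m < 2:
        warnings.warn(
            "fewer than 2 subjects: falling back to fixed effects only",
            stacklevel=2,
        )

    degenerate = Y.std(axis=0) < 1e-10
    lam, stats = design.profile_lambda(Y, allow_random=design.m >= 2)
    _, beta, sigma2, cov, blup = design.neg2_reml(lam, stats, want_fit=True)

    fitted_kind = design.X @ beta.T
    if r2_kind == "conditional":
        fitted_kind = fitted_kind + blup[design.codes, :]
    elif r2_kind != "marginal":
        raise ValueError("r2_kind must be 'conditional' or 'marginal'")
    fc = fitted_kind - fitted_kind.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    denom = np.sqrt((fc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, ((fc * yc).sum(axis=0) / denom) ** 2, 0.0)
    r2 = np.clip(np.nan_to_num(r2), 0.0, 1.0)

    bc, bs = beta[:, 2], beta[:, 3]
    cov_cs = cov[:, 2:, 2:]
    if ci_method == "delta":
        amp, se, ci_lo, ci_hi = _amplitude_ci_delta(bc, bs, cov_cs)
    elif ci_method == "bootstrap":
        amp, se, ci_lo, ci_hi = _amplitude_ci_bootstrap(bc, bs, cov_cs, n_boot, seed)
    else:
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    w = 2 * np.pi / period_h
    peak = wrap_to_half_period(np.arctan2(bs, bc) / w, period_h)

    # degenerate (constant) probes: amplitude 0, CI [0, 0], never circadian
    amp = np.where(degenerate, 0.0, amp)
    se = np.where(degenerate, 0.0, se)
    ci_lo = np.where(degenerate, 0.0, ci_lo)
    ci_hi = np.where(degenerate, 0.0, ci_hi)
    r2 = np.where(degenerate, 0.0, r2)
    peak = np.where(degenerate, np.nan, peak)

    is_circ = (r2 > r2_threshold) & (ci_lo > 0) & ~degenerate

    if probe_ids is None:
        probe_ids = [f"col{i}" for i in range(Y.shape[1])]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "mesor": beta[:, 0],
            "trend_slope": beta[:, 1],
            "beta_cos": bc,
            "beta_sin": bs,
            "amplitude": amp,
            "amplitude_se": se,
            "amplitude_ci_low": ci_lo,
            "amplitude_ci_high": ci_hi,
            "peak_time_h": peak,
            "r_squared": r2,
            "is_circadian": is_circ,
            "sigma2": sigma2,
            "variance_ratio": lam,
        }
    )


def fit_cosinor_mixed(
    series: AlignedSeries,
    period_h: float = 24.0,
    r2_threshold: float = 0.8,
    ci_method: str = "delta",
    n_boot: int = 500,
    seed: int | None = None,
    r2_kind: str = "conditional",
) -> CosinorFit:
    """Fit one probe; see :func:`fit_cosinor_batch` for the model."""
    design = _Design(series.times_h, series.subject_ids, period_h)
    df = fit_cosinor_batch(
        series.times_h,
        series.subject_ids,
        series.values[:, None],
        probe_ids=[series.probe_id],
        period_h=period_h,
        r2_threshold=r2_threshold,
        ci_method=ci_method,
        n_boot=n_boot,
        seed=seed,
        r2_kind=r2_kind,
    )
    row = df.iloc[0]
    # recompute BLUPs for the subject-intercept report
    lam = np.array([row["variance_ratio"]])
    stats = design.reml_stats(series.values[:, None])
    _, beta, _, _, blup = design.neg2_reml(lam, stats, want_fit=True)
    intercepts = {
        label: float(blup[i, 0]) for i, label in enumerate(design.subject_labels)
    }
    return CosinorFit(
        probe_id=series.probe_id,
        mesor=float(row["mesor"]),
        trend_slope=float(row["trend_slope"]),
        beta_cos=float(row["beta_cos"]),
        beta_sin=float(row["beta_sin"]),
        amplitude=float(row["amplitude"]),
        amplitude_se=float(row["amplitude_se"]),
        amplitude_ci_low=float(row["amplitude_ci_low"]),
        amplitude_ci_high=float(row["amplitude_ci_high"]),
        peak_time_h=float(row["peak_time_h"]),
        r_squared=float(row["r_squared"]),
        is_circadian=bool(row["is_circadian"]),
        subject_intercepts=intercepts,
        sigma2=float(row["sigma2"]),
        variance_ratio=float(row["variance_ratio"]),
    )


def classify_circadian(
    fit: CosinorFit | pd.Series, r2_threshold: float = 0.8
) -> bool:
    """Circadian iff R^2 strictly exceeds the threshold and the 95%
    amplitude CI excludes zero (lower bound > 0)."""
    if isinstance(fit, CosinorFit):
        r2, lo = fit.r_squared, fit.amplitude_ci_low
    else:
        r2, lo = fit["r_squared"], fit["amplitude_ci_low"]
    return bool(r2 > r2_threshold and lo > 0)


def _permute_within_subjects(
    Y: np.ndarray, codes: np.ndarray, n_permutations: int, rng
) -> np.ndarray:
    """Stack of permuted copies: values shuffled across time labels within
    each subject, independently per probe and permutation."""
    n, N = Y.shape
    out = np.empty((n, n_permutations * N))
    for p in range(n_permutations):
        block = np.empty_like(Y)
        for code in np.unique(codes):
            idx = np.flatnonzero(codes == code)
            order = np.argsort(rng.random((len(idx), N)), axis=0)
            block[idx] = np.take_along_axis(Y[idx], order, axis=0)
        out[:, p * N:(p + 1) * N] = block
    return out


def permutation_fdr(
    times_h: np.ndarray,
    subjects: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 100,
    seed: int | None = None,
    period_h: float = 24.0,
    r2_threshold: float = 0.8,
    ci_method: str = "delta",
    max_block_cols: int = 200_000,
) -> FdrEstimate:
    """Permutation false discovery rate for the circadian classification.

    For every permutation, each probe's values are shuffled across the time
    labels within each subject (preserving subject means) and the full
    fit-and-classify pipeline is re-run; FDR = mean permuted circadian count
    divided by the observed circadian count (nan when nothing is observed).
    Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    N = Y.shape[1]
    observed = fit_cosinor_batch(
        times_h, subjects, Y, period_h=period_h,
        r2_threshold=r2_threshold, ci_method=ci_method, seed=seed,
    )
    n_obs = int(observed["is_circadian"].sum())

    codes, _ = pd.factorize(np.asarray(subjects))
    rng = np.random.default_rng(seed)
    counts = np.empty(n_permutations)
    perms_per_block = max(1, max_block_cols // max(N, 1))
    done = 0
    while done < n_permutations:
        k = min(perms_per_block, n_permutations - done)
        Yp = _permute_within_subjects(Y, codes, k, rng)
        fits = fit_cosinor_batch(
            times_h, subjects, Yp, period_h=period_h,
            r2_threshold=r2_threshold, ci_method=ci_method, seed=seed,
        )
        circ = fits["is_circadian"].to_numpy().reshape(k, N)
        counts[done:done + k] = circ.sum(axis=1)
        done += k

    mean_perm = float(counts.mean())
    fdr = mean_perm / n_obs if n_obs > 0 else np.nan
    return FdrEstimate(
        n_observed_circadian=n_obs,
        mean_permuted_circadian=mean_perm,
        fdr=fdr,
        n_permutations=n_permutations,
        seed=seed,
        permuted_counts=counts,
    )


def peak_time_histogram(
    peak_times_h: np.ndarray, bin_width_h: float = 1.0, period_h: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of circadian peak times in bins over [-period/2, period/2)."""
    half = period_h / 2
    edges = np.arange(-half, half + bin_width_h / 2, bin_width_h)
    pt = wrap_to_half_period(np.asarray(peak_times_h, dtype=float), period_h)
    pt = pt[np.isfinite(pt)]
    counts, _ = np.histogram(pt, bins=edges)
    return counts, edges


def fits_to_tsv(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)
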