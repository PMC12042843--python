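"""Transcriptomic diversity as Hill numbers of order 0 (gene richness).

A cell population's transcriptomic diversity is summarized by the number of
distinct genes detected as a function of the number of UMIs considered: the
rarefaction (interpolation) part is the exact hypergeometric expectation of
richness at a subsample of size m, the extrapolation part rides on the Chao1
asymptotic richness estimator, and standard errors come from a multinomial
bootstrap over the estimated complete abundance distribution. Populations are
compared with a Wald-type Z test at a common evaluation point, recovering the
SE from the 95% CI half-width.

Only order q = 0 is supported (richness); the API carries ``q`` for future
orders but rejects anything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import gammaln

from .containers import CountMatrix
from .multitest import adjust_holm

log = logging.getLogger(__name__)


def pooled_abundance(counts: CountMatrix, population: str) -> np.ndarray:
    """Per-gene UMI totals over a population's cells; zero-total genes removed."""
    mask = (counts.cell_meta["cell_type"] == population).to_numpy()
    if not mask.any():
        raise ValueError(f"population {population!r} has no cells")
    totals = counts.counts[mask].sum(axis=0)
    return totals[totals > 0].astype(np.int64)


def _log_choose(n, k):
    n, k = np.asarray(n, dtype=float), np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_richness(abundance: np.ndarray, m_grid) -> np.ndarray:
    """Expected richness E[S_m] at subsample sizes m <= N (exact hypergeometric).

    E[S_m] = sum_g [1 - C(N - n_g, m) / C(N, m)], evaluated in log space so
    large N stays finite. Exact at m = N (returns S_obs).
    """
    abundance = np.asarray(abundance, dtype=np.int64)
    abundance = abundance[abundance > 0]
    N = int(abundance.sum())
    m_grid = np.atleast_1d(np.asarray(m_grid, dtype=np.int64))
    if (m_grid < 1).any() or (m_grid > N).any():
        raise ValueError(f"interpolation points must lie in [1, N={N}]")
    out = np.empty(len(m_grid), dtype=float)
    for i, m in enumerate(m_grid):
        rest = N - abundance  # UMIs not belonging to gene g
        with np.errstate(invalid="ignore"):
            log_miss = np.where(rest >= m,
                                _log_choose(rest, m) - _log_choose(N, m),
                                -np.inf)
        out[i] = float(np.sum(1.0 - np.exp(log_miss)))
    return out


def chao1(abundance: np.ndarray) -> tuple[float, int, int]:
    """Chao1 asymptotic richness with its singleton/doubleton counts (f1, f2)."""
    abundance = np.asarray(abundance, dtype=np.int64)
    abundance = abundance[abundance > 0]
    s_obs = len(abundance)
    f1 = int((abundance == 1).sum())
    f2 = int((abundance == 2).sum())
    if f2 > 0:
        s_est = s_obs + f1 * f1 / (2.0 * f2)
    else:
        s_est = s_obs + f1 * (f1 - 1) / 2.0
    return float(s_est), f1, f2


def extrapolate_richness(abundance: np.ndarray, m_star) -> np.ndarray:
    """Expected richness at sample sizes beyond N, anchored on the Chao1 asymptote.

    S(N + m*) = S_obs + f0_hat * [1 - (1 - f1/(N*f0_hat + f1))^m*] where
    f0_hat = Chao1 - S_obs. With no singletons (f1 = 0) the curve is flat at
    S_obs (flagged upstream, not an error).
    """
    abundance = np.asarray(abundance, dtype=np.int64)
    abundance = abundance[abundance > 0]
    N = int(abundance.sum())
    s_obs = len(abundance)
    m_star = np.atleast_1d(np.asarray(m_star, dtype=np.int64))
    if (m_star <= N).any():
        raise ValueError("extrapolation points must exceed N")
    s_est, f1, _ = chao1(abundance)
    f0 = s_est - s_obs
    extra = m_star - N
    if f1 == 0 or f0 <= 0:
        return np.full(len(m_star), float(s_obs))
    ratio = f1 / (N * f0 + f1)
    return s_obs + f0 * (1.0 - (1.0 - ratio) ** extra)


def richness_curve(abundance: np.ndarray, m_grid) -> pd.DataFrame:
    """Interpolated + extrapolated richness over an integer grid of UMI depths."""
    abundance = np.asarray(abundance, dtype=np.int64)
    N = int(abundance.sum())
    m_grid = np.atleast_1d(np.asarray(m_grid, dtype=np.int64))
    qd = np.empty(len(m_grid))
    interp = m_grid <= N
    if interp.any():
        qd[interp] = rarefy_richness(abundance, m_grid[interp])
    if (~interp).any():
        qd[~interp] = extrapolate_richness(abundance, m_grid[~interp])
    return pd.DataFrame({"m": m_grid, "qD": qd,
                         "regime": np.where(interp, "interp", "extrap")})


def diversity_se(abundance: np.ndarray, m_grid, n_boot: int = 200,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Bootstrap SE and 95% CI of the richness curve.

    The bootstrap resamples N UMIs from the estimated *complete* abundance
    distribution: observed relative abundances shrunk to leave room for
    f0_hat equally-abundant unseen genes (so unseen-gene uncertainty is
    represented). se = bootstrap SD, ci = estimate +/- 1.96 se.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    if rng is None:
        rng = np.random.default_rng(0)
    abundance = np.asarray(abundance, dtype=np.int64)
    abundance = abundance[abundance > 0]
    N = int(abundance.sum())
    s_est, f1, _ = chao1(abundance)
    f0 = max(int(round(s_est - len(abundance))), 0)

    # estimated complete relative-abundance vector
    p_obs = abundance / N
    if f0 > 0:
        # mass reserved for unseen genes: the standard (1 - f1/N)-style shrinkage
        unseen_mass = min(f1 / N, 0.5)
        probs = np.concatenate([p_obs * (1 - unseen_mass),
                                np.full(f0, unseen_mass / f0)])
    else:
        probs = p_obs

    m_grid = np.atleast_1d(np.asarray(m_grid, dtype=np.int64))
    boot = np.empty((n_boot, len(m_grid)))
    for b in range(n_boot):
        counts = rng.multinomial(N, probs)
        boot[b] = richness_curve(counts[counts > 0], m_grid)["qD"].to_numpy()
    est = richness_curve(abundance, m_grid)
    se = boot.std(axis=0, ddof=1)
    est["se"] = se
    est["lo"] = est["qD"] - 1.96 * se
    est["hi"] = est["qD"] + 1.96 * se
    return est


@dataclass
class RarefactionResult:
    population: str
    curve: pd.DataFrame  # m, qD, regime, se, lo, hi
    s_obs: int
    n_total: int
    chao1: float
    f1: int
    f2: int


def population_curve(counts: CountMatrix, population: str, m_grid,
                     n_boot: int = 200, rng: np.random.Generator | None = None,
                     q: int = 0) -> RarefactionResult:
    """Full rarefaction/extrapolation result for one cell population."""
    if q != 0:
        raise NotImplementedError("only Hill order q=0 (richness) is supported")
    ab = pooled_abundance(counts, population)
    s_est, f1, f2 = chao1(ab)
    curve = diversity_se(ab, m_grid, n_boot=n_boot, rng=rng)
    log.info("diversity %s: S_obs=%d N=%d Chao1=%.1f", population, len(ab), ab.sum(), s_est)
    return RarefactionResult(population, curve, int(len(ab)), int(ab.sum()), s_est, f1, f2)


def compare_to_reference(results: list[RarefactionResult], reference: str,
                         m_star: int) -> pd.DataFrame:
    """Wald-type Z test of each population's richness against a reference.

    SEs are recovered from the CI half-width / 1.96 at the shared evaluation
    point m*, Z = (qD_a - qD_ref) / sqrt(se_a^2 + se_ref^2), two-sided normal
    p, Holm-adjusted across populations.
    """
    by_name = {r.population: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference population {reference!r} not among results")

    def at(r: RarefactionResult):
        row = r.curve[r.curve["m"] == m_star]
        if row.empty:
            raise ValueError(f"m*={m_star} not on the grid of population {r.population!r}")
        row = row.iloc[0]
        se = (row["hi"] - row["lo"]) / (2 * 1.96)
        return float(row["qD"]), float(se)

    qd_ref, se_ref = at(by_name[reference])
    rows = []
    for r in results:
        if r.population == reference:
            continue
        qd, se = at(r)
        denom = np.sqrt(se**2 + se_ref**2)
        if denom > 0:
            z = (qd - qd_ref) / denom
        elif qd == qd_ref:
            z = 0.0
        else:  # zero sampling uncertainty but distinct estimates
            z = np.inf if qd > qd_ref else -np.inf
        p = 2 * st.norm.sf(abs(z))
        rows.append({"population": r.population, "reference": reference,
                     "m_star": m_star, "qD": qd, "qD_ref": qd_ref, "Z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["holm_p"] = adjust_holm(out["p"].to_numpy())
    return out.set_index("population")
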