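"""MCMC convergence diagnostics: Gelman-Rubin, Geweke, Heidelberger-Welch
and Raftery-Lewis.

Each diagnostic is implemented in its classic form:

* Gelman-Rubin potential scale reduction factor R-hat from between/within
  chain variances (needs >= 2 chains);
* Geweke z-score comparing the mean of the first 10% of a chain with the
  last 50%, with variances from spectral density estimates at frequency
  zero (Bartlett-windowed autocovariances);
* Heidelberger-Welch stationarity via a Cramér-von Mises test on the
  Brownian-bridge transform of cumulative sums, with iterative front
  truncation in 10% steps up to 50%, plus the relative half-width check;
* Raftery-Lewis run-length control for estimating the 2.5% posterior
  quantile to within +/-0.005 with 95% confidence, via the dichotomized
  two-state Markov chain.

Degenerate inputs (constant chains, windows too short) mark the affected
test "not run" — a test that cannot run never counts as passed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

RHAT_THRESHOLD = 1.1
GEWEKE_THRESHOLD = 2.576  # two-sided 1% normal critical value
# 5% critical value of the Cramér-von Mises limiting distribution
_CVM_CRIT_05 = 0.461


def spectral_variance(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero (Bartlett window).

    Equals the long-run variance; dividing by n gives the squared standard
    error of the chain mean under autocorrelation.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return float("nan")
    xc = x - x.mean()
    gamma0 = float(np.dot(xc, xc) / n)
    if gamma0 == 0.0:
        return 0.0
    lag_max = min(n - 1, max(5, int(round(2.0 * math.sqrt(n)))))
    s = gamma0
    for k in range(1, lag_max + 1):
        gk = float(np.dot(xc[:-k], xc[k:]) / n)
        s += 2.0 * (1.0 - k / (lag_max + 1.0)) * gk
    return max(s, 0.0)


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor from >= 2 same-length chains."""
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    n = min(len(c) for c in chains)
    if n < 2:
        raise ValueError("chains too short")
    arr = np.vstack([np.asarray(c[:n], dtype=float) for c in chains])
    within = float(arr.var(axis=1, ddof=1).mean())
    between_over_n = float(arr.mean(axis=1).var(ddof=1))
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else float("inf")
    var_hat = (n - 1) / n * within + between_over_n
    return math.sqrt(var_hat / within)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float | None:
    """Geweke convergence z-score; None when the variance estimate degenerates."""
    x = np.asarray(x, dtype=float)
    n = x.size
    n1, n2 = int(first * n), int(last * n)
    if n1 < 10 or n2 < 10:
        return None
    if x.max() == x.min():  # degenerate chain: no variance information
        return None
    a, b = x[:n1], x[n - n2:]
    s1, s2 = spectral_variance(a), spectral_variance(b)
    denom = s1 / n1 + s2 / n2
    if not denom > 0 or not math.isfinite(denom):
        return None
    return float((a.mean() - b.mean()) / math.sqrt(denom))


@dataclass(frozen=True)
class HeidelbergerResult:
    stationary: bool | None     # None = not run
    start_fraction: float | None
    cvm_statistic: float | None
    halfwidth_passed: bool | None
    relative_halfwidth: float | None


def heidelberger_welch(
    x: np.ndarray, eps: float = 0.1, alpha: float = 0.05
) -> HeidelbergerResult:
    """Stationarity (Cramér-von Mises on the bridge of cumulative sums, with
    iterative front truncation) and the relative half-width check."""
    if alpha != 0.05:
        raise NotImplementedError("critical values tabulated for alpha=0.05 only")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        return HeidelbergerResult(None, None, None, None, None)
    s_full = spectral_variance(x[n // 2:])
    if not s_full > 0:
        return HeidelbergerResult(None, None, None, None, None)
    for start_frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(start_frac * n):]
        m = y.size
        cum = np.cumsum(y)
        total = cum[-1]
        k = np.arange(1, m + 1)
        bridge = (cum - k * total / m) / math.sqrt(m * s_full)
        cvm = float(np.sum(bridge**2) / m)
        if cvm < _CVM_CRIT_05:
            mean = y.mean()
            hw = 1.96 * math.sqrt(spectral_variance(y) / m)
            rel = abs(hw / mean) if mean != 0 else float("inf")
            return HeidelbergerResult(
                stationary=True, start_fraction=start_frac, cvm_statistic=cvm,
                halfwidth_passed=bool(rel <= eps), relative_halfwidth=rel,
            )
    return HeidelbergerResult(False, None, cvm, None, None)


@dataclass(frozen=True)
class RafteryLewisResult:
    nmin: int                   # iterations needed were the chain i.i.d.
    thinning: int | None
    burn_in: int | None
    n_required: int | None
    dependence_factor: float | None


def raftery_lewis(
    x: np.ndarray, q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for the q-quantile.

    Dichotomizes the chain at its empirical q-quantile, thins until the
    binary chain behaves as first-order Markov (BIC comparison against a
    second-order chain), then converts the fitted two-state transition
    probabilities into the burn-in and run length needed to estimate the
    quantile to within +/- r with probability s.
    """
    x = np.asarray(x, dtype=float)
    phi = stats.norm.ppf(0.5 * (1.0 + s))
    nmin = int(math.ceil(q * (1.0 - q) * (phi / r) ** 2))
    n = x.size
    if n < nmin // 2 or n < 100:
        return RafteryLewisResult(nmin, None, None, None, None)
    u = (x <= np.quantile(x, q)).astype(int)

    def bic_markov2(z: np.ndarray) -> float:
        # G2 of 2nd- vs 1st-order Markov minus df*log(n): negative => 1st order ok
        trips = np.stack([z[:-2], z[1:-1], z[2:]], axis=1)
        counts = np.zeros((2, 2, 2))
        for a, b, c in trips:
            counts[a, b, c] += 1
        g2 = 0.0
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    o = counts[a, b, c]
                    if o == 0:
                        continue
                    e = counts[a, b, :].sum() * counts[:, b, c].sum() / max(
                        counts[:, b, :].sum(), 1.0
                    )
                    if e > 0:
                        g2 += 2.0 * o * math.log(o / e)
        return g2 - 2.0 * math.log(len(z) - 2)

    k = 1
    z = u
    while bic_markov2(z) > 0 and k < n // 100:
        k += 1
        z = u[::k]
    t01 = np.sum((z[:-1] == 0) & (z[1:] == 1))
    t0 = np.sum(z[:-1] == 0)
    t10 = np.sum((z[:-1] == 1) & (z[1:] == 0))
    t1 = np.sum(z[:-1] == 1)
    if t0 == 0 or t1 == 0:
        return RafteryLewisResult(nmin, k, None, None, None)
    alpha = t01 / t0
    beta = t10 / t1
    if alpha <= 0 or beta <= 0 or alpha + beta >= 2:
        return RafteryLewisResult(nmin, k, None, None, None)
    lam = abs(1.0 - alpha - beta)
    eps0 = 0.001
    if lam == 0:
        m_star = 0
    else:
        m_star = math.log(eps0 * (alpha + beta) / max(alpha, beta)) / math.log(lam)
    burn = int(math.ceil(max(m_star, 0.0))) * k
    n_star = ((2.0 - alpha - beta) * alpha * beta * phi**2) / ((alpha + beta) ** 3 * r**2)
    n_req = int(math.ceil(n_star)) * k
    return RafteryLewisResult(
        nmin=nmin, thinning=k, burn_in=burn, n_required=n_req,
        dependence_factor=(burn + n_req) / nmin,
    )


@dataclass(frozen=True)
class ParameterDiagnostics:
    name: str
    rhat: float | None
    geweke_z: float | None          # worst (largest |z|) across chains
    heidelberger: HeidelbergerResult | None
    raftery_lewis: RafteryLewisResult | None
    not_run: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        if self.not_run:
            return False
        return (
            self.rhat < RHAT_THRESHOLD
            and abs(self.geweke_z) < GEWEKE_THRESHOLD
            and bool(self.heidelberger.stationary)
        )


@dataclass
class DiagnosticsReport:
    parameters: dict[str, ParameterDiagnostics]
    overall_pass: bool

    def to_dict(self) -> dict:
        out: dict = {"overall_pass": self.overall_pass, "parameters": {}}
        for name, p in self.parameters.items():
            out["parameters"][name] = {
                "rhat": p.rhat,
                "geweke_z": p.geweke_z,
                "heidelberger_stationary": None if p.heidelberger is None
                else p.heidelberger.stationary,
                "raftery_lewis_nmin": None if p.raftery_lewis is None
                else p.raftery_lewis.nmin,
                "not_run": list(p.not_run),
                "passed": p.passed,
            }
        return out


def diagnose_parameter(name: str, chains: list[np.ndarray]) -> ParameterDiagnostics:
    """Run all four diagnostics on one scalar parameter's chains."""
    not_run: list[str] = []
    rhat = None
    if len(chains) >= 2:
        rhat = gelman_rubin(chains)
    else:
        not_run.append("gelman_rubin")
    zs = [geweke_z(c) for c in chains]
    zs = [z for z in zs if z is not None]
    worst_z = max(zs, key=abs) if zs else None
    if worst_z is None:
        not_run.append("geweke")
    hw_results = [heidelberger_welch(c) for c in chains]
    hw_run = [h for h in hw_results if h.stationary is not None]
    if hw_run:
        # report the least favourable chain
        hw = next((h for h in hw_run if not h.stationary), hw_run[0])
    else:
        hw = HeidelbergerResult(None, None, None, None, None)
        not_run.append("heidelberger_welch")
    rl = raftery_lewis(np.concatenate(chains))
    return ParameterDiagnostics(
        name=name, rhat=rhat, geweke_z=worst_z, heidelberger=hw,
        raftery_lewis=rl, not_run=tuple(not_run),
    )


def diagnostics(draws) -> DiagnosticsReport:
    """Convergence report over every model parameter of a posterior run.

    ``overall_pass`` requires, for every parameter, R-hat < 1.1,
    |Geweke z| < 2.576 and Heidelberger-Welch stationarity — and that all
    three of those tests actually ran.
    """
    params: dict[str, ParameterDiagnostics] = {}
    for k, drug in enumerate(draws.drugs):
        params[f"d[{drug}]"] = diagnose_parameter(
            f"d[{drug}]", draws.chains_of("d", k)
        )
    for i, sid in enumerate(draws.study_ids):
        params[f"mu[{sid}]"] = diagnose_parameter(
            f"mu[{sid}]", draws.chains_of("mu", i)
        )
    return DiagnosticsReport(
        parameters=params,
        overall_pass=all(p.passed for p in params.values()),
    )
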