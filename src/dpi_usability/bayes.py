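"""Bayesian indirect comparison of device usability scores.

Within-patient GUS observations from an incomplete-block design are merged
into a single coherent model even though no respondent tested all seven
devices.  For respondent i testing device k,

    y_ik = mu_i + delta_ik + eps_ik,      eps_ik ~ N(0, tau^2)

with a respondent-level usability intercept mu_i and delta_i,b(i) = 0 at the
respondent's baseline device b(i) (first of their tested set in canonical
order; Breezhaler under the published design).  The two variants are

* fixed effect (FE):  delta_ik = d_k - d_{b(i)} — every respondent informs
  the same device effects d (d_reference = 0);
* random effect (RE): the vector of a respondent's contrasts is multivariate
  normal with means d_k - d_{b(i)}, variances sigma^2 and covariances
  sigma^2/2 between contrasts sharing the baseline (the standard consistency
  construction for multi-arm units), sigma^2 capturing between-respondent
  heterogeneity of device preference.

Default priors are vague on the bounded 0-50 scale: d_k ~ N(0, 100^2),
mu_i ~ N(25, 100^2), tau ~ U(0, 50), sigma ~ U(0, 25).

Posterior sampling uses component-wise conjugate Gibbs updates for mu, d,
delta and the residual precision, and an adaptive random-walk Metropolis
step (burn-in adaptation only) for sigma.  Model choice follows the
deviance information criterion with the usual >= 3-point rule: the simpler
FE model wins unless RE improves DIC by at least 3.  Device effects are
reported on the absolute GUS scale by anchoring each iteration at the
cohort mean intercept, and rank probabilities are the fraction of
iterations in which a device attains each rank (rank 1 = highest GUS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .devices import DEVICE_INDEX, REFERENCE_DEVICE, sort_devices
from .errors import DisconnectedNetworkError
from .scoring import GUSRecord

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))
RHAT_THRESHOLD = 1.05
DIC_RULE_POINTS = 3.0


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    model_type: str = "FE"  # FE | RE
    reference: str = REFERENCE_DEVICE
    prior_d: tuple[float, float] = (0.0, 100.0)     # normal(mean, sd)
    prior_mu: tuple[float, float] = (25.0, 100.0)   # normal(mean, sd)
    prior_tau_upper: float = 50.0                   # uniform(0, upper) on sd
    prior_sigma_upper: float = 25.0                 # uniform(0, upper), RE only

    def __post_init__(self):
        if self.model_type not in ("FE", "RE"):
            raise ValueError(f"model_type must be FE or RE, got {self.model_type!r}")
        if self.prior_d[1] <= 0 or self.prior_mu[1] <= 0:
            raise ValueError("prior sds must be positive")
        if self.prior_tau_upper <= 0 or self.prior_sigma_upper <= 0:
            raise ValueError("uniform prior upper bounds must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    seed: int
    chains: int = 2
    iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 1

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC samples for one stratum fit.

    ``d`` is aligned with ``devices`` (reference column identically zero);
    ``delta_obs`` (RE only) holds the per-iteration respondent-by-device
    contrasts scattered to observation positions (zero at baseline
    observations).
    """

    model_type: str
    devices: tuple[str, ...]
    reference: str
    respondent_ids: tuple[str, ...]
    d: np.ndarray                    # (n_kept, n_devices)
    mu: np.ndarray                   # (n_kept, n_respondents)
    tau: np.ndarray                  # (n_kept,)
    chain: np.ndarray                # (n_kept,) chain labels
    sigma: np.ndarray | None = None  # (n_kept,) RE only
    delta_obs: np.ndarray | None = None  # (n_kept, n_obs) RE only
    n_obs: int = 0
    prior_mu: tuple[float, float] = (25.0, 100.0)  # intercept prior (mean, sd)
    converged: bool = True
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.d.shape[0]

    def anchored_gus(self) -> np.ndarray:
        """Per-iteration absolute GUS per device: G_k = mean_i(mu_i) + d_k."""
        return self.mu.mean(axis=1)[:, None] + self.d

    def to_frame(self) -> pd.DataFrame:
        """Long draw export: (chain, iteration, parameter, value)."""
        cols: dict[str, np.ndarray] = {f"d[{dev}]": self.d[:, j] for j, dev in enumerate(self.devices)}
        cols["tau"] = self.tau
        if self.sigma is not None:
            cols["sigma"] = self.sigma
        rows = []
        for name, vals in cols.items():
            rows.append(
                pd.DataFrame(
                    {
                        "chain": self.chain,
                        "iteration": _within_chain_index(self.chain),
                        "parameter": name,
                        "value": vals,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _within_chain_index(chain: np.ndarray) -> np.ndarray:
    idx = np.zeros(len(chain), dtype=int)
    for c in np.unique(chain):
        m = chain == c
        idx[m] = np.arange(m.sum())
    return idx


@dataclass(frozen=True)
class DICResult:
    model_type: str
    Dbar: float
    pD: float
    DIC: float


@dataclass(frozen=True)
class DeviceSummary:
    device: str
    mean: float
    cri_low: float
    cri_high: float


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    """Respondents sharing one tested-device set (same baseline/contrasts)."""

    resp_rows: np.ndarray       # respondent indices
    contrast_devs: np.ndarray   # device positions of the non-baseline arms
    obs_full: np.ndarray        # (n_g, p+1) obs indices; column 0 = baseline
    baseline: int
    S: np.ndarray               # (p, n_free): contrast means = S @ d_free

    @property
    def p(self) -> int:
        return len(self.contrast_devs)


@dataclass
class _Data:
    y: np.ndarray          # (n_obs,)
    resp_idx: np.ndarray   # (n_obs,) -> respondent
    dev_idx: np.ndarray    # (n_obs,) -> position in devices
    base_idx: np.ndarray   # (n_obs,) baseline device position of the respondent
    devices: tuple[str, ...]
    respondent_ids: tuple[str, ...]
    patterns: list[_Pattern]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_resp(self) -> int:
        return len(self.respondent_ids)


def _prepare(records: list[GUSRecord], reference: str) -> _Data:
    if not records:
        raise ValueError("no records to fit")
    strata = {r.stratum for r in records}
    if len(strata) != 1:
        raise ValueError(f"records span multiple strata {sorted(strata)}; fit one at a time")
    by_resp: dict[str, list[GUSRecord]] = {}
    for r in records:
        by_resp.setdefault(r.respondent_id, []).append(r)
    dropped = [rid for rid, recs in by_resp.items() if len(recs) < 2]
    if dropped:
        logger.warning(
            "fit: dropping %d single-device respondent(s) (no within-respondent "
            "contrast): %s", len(dropped), ", ".join(sorted(dropped)[:5]),
        )
        for rid in dropped:
            del by_resp[rid]
    if not by_resp:
        raise ValueError("no respondent with >= 2 devices")

    devices = sort_devices({r.device for recs in by_resp.values() for r in recs})
    if reference not in devices:
        raise ValueError(f"reference {reference!r} not observed in these records")
    dpos = {d: j for j, d in enumerate(devices)}

    # connectivity through shared respondents (union-find over devices)
    parent = list(range(len(devices)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for recs in by_resp.values():
        js = [dpos[r.device] for r in recs]
        for j in js[1:]:
            parent[find(j)] = find(js[0])
    roots = {find(j) for j in range(len(devices))}
    if len(roots) > 1:
        comps: dict[int, list[str]] = {}
        for j, d in enumerate(devices):
            comps.setdefault(find(j), []).append(d)
        raise DisconnectedNetworkError(
            f"evidence network disconnected: components {sorted(comps.values())}"
        )

    respondent_ids = tuple(sorted(by_resp))
    y, resp_idx, dev_idx, base_idx = [], [], [], []
    pattern_map: dict[tuple[int, ...], list[int]] = {}
    obs_of: dict[tuple[int, int], int] = {}
    for i, rid in enumerate(respondent_ids):
        recs = sorted(by_resp[rid], key=lambda r: DEVICE_INDEX[r.device])
        b = dpos[recs[0].device]
        for r in recs:
            obs_of[(i, dpos[r.device])] = len(y)
            y.append(float(r.gus_total))
            resp_idx.append(i)
            dev_idx.append(dpos[r.device])
            base_idx.append(b)
        key = tuple(dpos[r.device] for r in recs[1:])  # non-baseline contrasts
        pattern_map.setdefault((b,) + key, []).append(i)

    free = [j for j, d in enumerate(devices) if d != reference]
    free_pos = {j: k for k, j in enumerate(free)}
    patterns = []
    for key, resp_rows in sorted(pattern_map.items()):
        b, contr = key[0], key[1:]
        if not contr:
            continue
        # column 0 = baseline observation, columns 1.. = the contrasts
        obs_full = np.array(
            [[obs_of[(i, j)] for j in (b,) + contr] for i in resp_rows], dtype=int
        )
        p = len(contr)
        # maps free-device effects to the pattern's contrast means d_k - d_b
        S = np.zeros((p, len(free)))
        for row, j in enumerate(contr):
            if j in free_pos:
                S[row, free_pos[j]] = 1.0
            if b in free_pos:
                S[row, free_pos[b]] -= 1.0
        patterns.append(
            _Pattern(
                resp_rows=np.asarray(resp_rows, dtype=int),
                contrast_devs=np.asarray(contr, dtype=int),
                obs_full=obs_full,
                baseline=b,
                S=S,
            )
        )
    return _Data(
        y=np.asarray(y),
        resp_idx=np.asarray(resp_idx, dtype=int),
        dev_idx=np.asarray(dev_idx, dtype=int),
        base_idx=np.asarray(base_idx, dtype=int),
        devices=tuple(devices),
        respondent_ids=respondent_ids,
        patterns=patterns,
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _sample_tau2_inv(rng, n: int, ss: float, upper: float) -> float:
    """Draw the residual precision under a uniform(0, upper) prior on tau.

    p(lambda | .) ~ Gamma((n-1)/2, rate=SS/2) truncated to lambda > 1/upper^2.
    """
    shape = max(0.5 * (n - 1), 0.5)
    rate = max(0.5 * ss, 1e-12)
    lam_min = 1.0 / upper**2
    for _ in range(100):
        lam = rng.gamma(shape, 1.0 / rate)
        if lam > lam_min:
            return lam
    return lam_min * (1.0 + rng.random())


def _mn_contrast_cov_inv(p: int) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of C = (I + J)/2 (unit-sigma contrast cov)."""
    eye = np.eye(p)
    c_inv = 2.0 * (eye - np.ones((p, p)) / (p + 1.0))
    logdet = p * np.log(0.5) + np.log(p + 1.0)
    return c_inv, logdet


def _run_chain_fe(data: _Data, spec: ModelSpec, n_iter, burn_in, thin, rng):
    y, resp, dev, base = data.y, data.resp_idx, data.dev_idx, data.base_idx
    n_obs, n_resp, n_dev = data.n_obs, data.n_resp, len(data.devices)
    m_mu, s_mu = spec.prior_mu
    m_d, s_d = spec.prior_d
    free = [j for j, d_name in enumerate(data.devices) if d_name != spec.reference]
    plus_idx = {k: np.flatnonzero((dev == k) & (base != k)) for k in free}
    minus_idx = {k: np.flatnonzero((base == k) & (dev != k)) for k in free}
    n_per_resp = np.bincount(resp, minlength=n_resp).astype(float)

    # data-based initials with chain-specific jitter for overdispersion
    mu = np.bincount(resp, weights=y, minlength=n_resp) / n_per_resp
    mu = mu + rng.normal(0.0, 1.0, n_resp)
    d = np.zeros(n_dev)
    ref_mean = y[dev == data.devices.index(spec.reference)].mean()
    for k in free:
        d[k] = y[dev == k].mean() - ref_mean + rng.normal(0.0, 1.0)
    resid = y - mu[resp] - (d[dev] - d[base])
    tau2 = max(float(np.var(resid)), 0.25)

    n_kept = (n_iter - burn_in + thin - 1) // thin
    out_mu = np.empty((n_kept, n_resp))
    out_d = np.empty((n_kept, n_dev))
    out_tau = np.empty(n_kept)
    kept = 0
    for it in range(n_iter):
        # mu | .
        contrib = d[dev] - d[base]
        r = y - contrib
        prec = n_per_resp / tau2 + 1.0 / s_mu**2
        mean = (np.bincount(resp, weights=r, minlength=n_resp) / tau2 + m_mu / s_mu**2) / prec
        mu = mean + rng.standard_normal(n_resp) / np.sqrt(prec)
        # d | . (sequential conjugate scan with incremental residual updates)
        s = y - mu[resp] - contrib
        for k in free:
            ip, im = plus_idx[k], minus_idx[k]
            n_k = len(ip) + len(im)
            prec_k = n_k / tau2 + 1.0 / s_d**2
            total = (s[ip] + d[k]).sum() + (d[k] - s[im]).sum()
            mean_k = (total / tau2 + m_d / s_d**2) / prec_k
            new = mean_k + rng.standard_normal() / np.sqrt(prec_k)
            delta_change = new - d[k]
            if delta_change != 0.0:
                s[ip] -= delta_change
                s[im] += delta_change
                d[k] = new
        # tau | .
        ss = float(s @ s)
        tau2 = 1.0 / _sample_tau2_inv(rng, n_obs, ss, spec.prior_tau_upper)
        if it >= burn_in and (it - burn_in) % thin == 0:
            out_mu[kept] = mu
            out_d[kept] = d
            out_tau[kept] = np.sqrt(tau2)
            kept += 1
    return out_mu, out_d[:, :], out_tau, None, None


class _MarginalAlgebra:
    """Closed-form covariance algebra for one pattern.

    With the contrasts integrated out, a respondent's m = p+1 observations
    (baseline first) have covariance A = tau^2 I (+ sigma^2 (I+J)/2 on the
    contrast block); integrating the intercept mu_i adds s_mu^2 J via a
    rank-one (Sherman-Morrison) update.  Everything needed by the sampler
    and the deviance reduces to scalar functions of (tau, sigma) and four
    per-pattern sufficient statistics.
    """

    __slots__ = ("p", "tau2", "a", "b", "apb", "uc", "u0", "uu", "logdet_a")

    def __init__(self, p: int, tau: float, sigma: float):
        self.p = p
        self.tau2 = tau * tau
        sigma2 = sigma * sigma
        self.a = self.tau2 + 0.5 * sigma2       # contrast-block diagonal
        self.b = 0.5 * sigma2                   # contrast-block off-diagonal
        self.apb = self.a + p * self.b
        self.u0 = 1.0 / self.tau2               # (A^-1 1) baseline component
        self.uc = 1.0 / self.apb                # (A^-1 1) contrast components
        self.uu = self.u0 + p * self.uc         # 1' A^-1 1
        self.logdet_a = (
            np.log(self.tau2) + (p - 1) * np.log(self.a) + np.log(self.apb)
        )

    def loglik_stats(
        self, n_g: int, sum_r0sq, sum_c2, sum_c1sq, sum_r0c1, s_mu2: float
    ) -> float:
        """Marginal log-likelihood (mu and delta integrated) from sufficient
        statistics of the mean-centred residuals."""
        p, a, b, apb, tau2 = self.p, self.a, self.b, self.apb, self.tau2
        m = p + 1
        logdet = self.logdet_a + np.log1p(s_mu2 * self.uu)
        quad_a = sum_r0sq / tau2 + sum_c2 / a - (b / (a * apb)) * sum_c1sq
        # sum over respondents of (u'r)^2
        sum_t2 = (
            sum_r0sq / tau2**2
            + 2.0 * sum_r0c1 / (tau2 * apb)
            + sum_c1sq / apb**2
        )
        quad = quad_a - (s_mu2 / (1.0 + s_mu2 * self.uu)) * sum_t2
        return -0.5 * (n_g * (m * LOG_2PI + logdet) + quad)


def _run_chain_re(data: _Data, spec: ModelSpec, n_iter, burn_in, thin, rng):
    """Collapsed Gibbs/Metropolis sampler for the RE model.

    The respondent-level contrasts delta_i are never part of the sampler
    state: mu and d use their exact conditionals under the delta-marginal
    likelihood, and (tau, sigma) are updated by random-walk Metropolis on
    the log scale against the likelihood with BOTH delta and mu integrated
    out (a partially collapsed step; mu is redrawn from its exact
    conditional immediately after, which keeps the joint target invariant).
    Collapsing matters because a single score per respondent-device cell
    identifies sigma and tau only through sigma^2 + 2 tau^2: conditioning on
    mu or delta pins the pair and freezes the chain on that ridge.
    delta draws are reconstructed from their exact conditional at each kept
    iteration for export and downstream use.
    """
    y, resp, dev, base = data.y, data.resp_idx, data.dev_idx, data.base_idx
    n_obs, n_resp, n_dev = data.n_obs, data.n_resp, len(data.devices)
    m_mu, s_mu = spec.prior_mu
    s_mu2 = s_mu * s_mu
    m_d, s_d = spec.prior_d
    free = [j for j, nm in enumerate(data.devices) if nm != spec.reference]
    n_free = len(free)
    pats = data.patterns

    # per-pattern fixed pieces
    Y0 = [y[pat.obs_full[:, 0]] for pat in pats]          # baseline scores
    Yc = [y[pat.obs_full[:, 1:]] for pat in pats]         # contrast scores
    StS = [pat.S.T @ pat.S for pat in pats]
    s1 = [pat.S.T @ np.ones(pat.p) for pat in pats]

    mu = np.array([y[resp == i].mean() for i in range(n_resp)])
    mu = mu + rng.normal(0.0, 1.0, n_resp)
    d = np.zeros(n_dev)
    ref_mean = y[dev == data.devices.index(spec.reference)].mean()
    for k in free:
        d[k] = y[dev == k].mean() - ref_mean + rng.normal(0.0, 1.0)
    d_free = d[free].copy()
    tau = max(float(np.std(y - mu[resp] - (d[dev] - d[base]))), 0.5)
    sigma = 1.0 + rng.random()

    n_substeps = 3
    step = 0.4  # RW scale on (log tau, log sigma), adapted during burn-in
    acc = tries = 0

    n_kept = (n_iter - burn_in + thin - 1) // thin
    out_mu = np.empty((n_kept, n_resp))
    out_d = np.empty((n_kept, n_dev))
    out_tau = np.empty(n_kept)
    out_sigma = np.empty(n_kept)
    out_delta = np.empty((n_kept, n_obs))
    kept = 0

    for it in range(n_iter):
        # ---- (tau, sigma) | y, d with mu, delta integrated out -----------
        stats = []
        for pat, y0, yc in zip(pats, Y0, Yc):
            r0 = y0 - m_mu
            rc = yc - m_mu - (pat.S @ d_free)[None, :]
            c1 = rc.sum(axis=1)
            stats.append(
                (
                    len(pat.resp_rows),
                    float(r0 @ r0),
                    float((rc * rc).sum()),
                    float(c1 @ c1),
                    float(r0 @ c1),
                )
            )

        def loglik(tau_v: float, sigma_v: float) -> float:
            if not (1e-3 < tau_v < spec.prior_tau_upper):
                return -np.inf
            if not (1e-4 < sigma_v < spec.prior_sigma_upper):
                return -np.inf
            lp = 0.0
            for pat, st in zip(pats, stats):
                alg = _MarginalAlgebra(pat.p, tau_v, sigma_v)
                lp += alg.loglik_stats(*st, s_mu2)
            return lp

        cur = loglik(tau, sigma)
        for _ in range(n_substeps):
            prop_tau = float(np.exp(np.log(tau) + step * rng.standard_normal()))
            prop_sigma = float(np.exp(np.log(sigma) + step * rng.standard_normal()))
            prop = loglik(prop_tau, prop_sigma)
            log_ratio = (
                prop - cur
                + np.log(prop_tau) - np.log(tau)      # Jacobians of the
                + np.log(prop_sigma) - np.log(sigma)  # log transforms
            )
            tries += 1
            if np.log(rng.random() + 1e-300) < log_ratio:
                tau, sigma, cur = prop_tau, prop_sigma, prop
                acc += 1
        if it < burn_in and tries >= 150:
            step = float(np.clip(step * np.exp(acc / tries - 0.3), 0.02, 2.0))
            acc = tries = 0

        # ---- mu | y, d, tau, sigma (delta marginal, conjugate) ------------
        algs = [_MarginalAlgebra(pat.p, tau, sigma) for pat in pats]
        for pat, y0, yc, alg in zip(pats, Y0, Yc, algs):
            mean_c = pat.S @ d_free
            score = y0 * alg.u0 + (yc - mean_c[None, :]).sum(axis=1) * alg.uc
            prec = alg.uu + 1.0 / s_mu2
            mean = (score + m_mu / s_mu2) / prec
            mu[pat.resp_rows] = mean + rng.standard_normal(
                len(pat.resp_rows)
            ) / np.sqrt(prec)

        # ---- d | y, mu, tau, sigma (delta marginal, conjugate MVN) --------
        P = np.eye(n_free) / s_d**2
        bvec = np.full(n_free, m_d / s_d**2)
        for pat, y0, yc, sts, sv, alg in zip(pats, Y0, Yc, StS, s1, algs):
            coef_j = alg.b / (alg.a * alg.apb)
            n_g = len(pat.resp_rows)
            P += n_g * (sts / alg.a - coef_j * np.outer(sv, sv))
            W = yc - mu[pat.resp_rows][:, None]
            wsum = W.sum(axis=0)
            bvec += (pat.S.T @ wsum) / alg.a - coef_j * sv * wsum.sum()
        L = np.linalg.cholesky(P)
        w = np.linalg.solve(L, bvec)
        mean_d = np.linalg.solve(L.T, w)
        z = rng.standard_normal(n_free)
        d_free = mean_d + np.linalg.solve(L.T, z)
        d[free] = d_free

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_mu[kept] = mu
            out_d[kept] = d
            out_tau[kept] = tau
            out_sigma[kept] = sigma
            # delta | y, mu, d, tau, sigma : exact conditional MVN; the
            # posterior precision is alpha I - beta J, so its inverse and a
            # matching Gaussian draw have closed forms (no factorizations)
            tau2c, sigma2c = tau * tau, sigma * sigma
            out_delta[kept] = 0.0
            for pat, yc in zip(pats, Yc):
                p = pat.p
                alpha = 2.0 / sigma2c + 1.0 / tau2c
                beta = 2.0 / (sigma2c * (p + 1.0))
                va = 1.0 / alpha
                vb = beta / (alpha * (alpha - p * beta))
                m_contr = pat.S @ d_free
                cm = (2.0 / sigma2c) * (m_contr - m_contr.sum() / (p + 1.0))
                T = (yc - mu[pat.resp_rows][:, None]) / tau2c + cm[None, :]
                M = va * T + vb * T.sum(axis=1)[:, None]
                z = rng.standard_normal((len(pat.resp_rows), p))
                scale1 = (np.sqrt(va + p * vb) - np.sqrt(va)) / p
                draws = M + np.sqrt(va) * z + scale1 * z.sum(axis=1)[:, None]
                out_delta[kept][pat.obs_full[:, 1:]] = draws
            kept += 1
    return out_mu, out_d, out_tau, out_sigma, out_delta


def fit_model(
    records: list[GUSRecord], spec: ModelSpec, config: MCMCConfig
) -> PosteriorDraws:
    """Fit the FE or RE indirect-comparison model by MCMC.

    Deterministic for a fixed ``config.seed``.  Convergence is assessed with
    split-R-hat across chains; non-convergence sets ``converged=False`` and
    emits a warning, never fails silently.
    """
    data = _prepare(records, spec.reference)
    runner = _run_chain_fe if spec.model_type == "FE" else _run_chain_re
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    mus, ds, taus, sigmas, deltas, chains = [], [], [], [], [], []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        mu, d, tau, sigma, delta = runner(
            data, spec, config.iterations, config.burn_in, config.thin, rng
        )
        mus.append(mu)
        ds.append(d)
        taus.append(tau)
        sigmas.append(sigma)
        deltas.append(delta)
        chains.append(np.full(len(tau), c, dtype=int))
    draws = PosteriorDraws(
        model_type=spec.model_type,
        devices=data.devices,
        reference=spec.reference,
        respondent_ids=data.respondent_ids,
        d=np.vstack(ds),
        mu=np.vstack(mus),
        tau=np.concatenate(taus),
        chain=np.concatenate(chains),
        sigma=np.concatenate(sigmas) if spec.model_type == "RE" else None,
        delta_obs=np.vstack(deltas) if spec.model_type == "RE" else None,
        n_obs=data.n_obs,
        prior_mu=spec.prior_mu,
    )
    report = diagnose(draws)
    draws.rhat = report["rhat"]
    draws.converged = report["converged"]
    if not draws.converged:
        worst = max(report["rhat"], key=report["rhat"].get)
        warnings.warn(
            f"{spec.model_type} fit: split R-hat {report['rhat'][worst]:.3f} for "
            f"{worst} exceeds {RHAT_THRESHOLD}; treat results with caution",
            stacklevel=2,
        )
    return draws


# ---------------------------------------------------------------------------
# DIC and model selection
# ---------------------------------------------------------------------------

def marginal_deviance(
    data: _Data,
    free_idx: np.ndarray,
    d_free: np.ndarray,
    tau: np.ndarray,
    sigma: np.ndarray,
    prior_mu: tuple[float, float],
) -> np.ndarray:
    """Population-level deviance per draw: -2 log p(y | d, tau, sigma).

    Both the respondent intercepts mu_i and (for RE) the respondent-level
    contrasts delta_i are integrated out analytically, so the deviance is a
    function of the population parameters alone and the FE model is exactly
    the sigma = 0 special case.  ``d_free`` is (n_draws, n_free); ``tau`` and
    ``sigma`` are (n_draws,).
    """
    m_mu, s_mu = prior_mu
    s_mu2 = s_mu * s_mu
    n_draws = len(tau)
    tau2 = tau**2
    sigma2 = sigma**2
    out = np.zeros(n_draws)
    for pat in data.patterns:
        p = pat.p
        m = p + 1
        n_g = len(pat.resp_rows)
        y0 = data.y[pat.obs_full[:, 0]] - m_mu          # (n_g,)
        B = data.y[pat.obs_full[:, 1:]] - m_mu          # (n_g, p)
        # residual sufficient statistics as functions of the draw's d
        E = d_free @ pat.S.T                            # (n_draws, p)
        tot = E.sum(axis=1)                             # (n_draws,)
        col = B.sum(axis=0)                             # (p,)
        rowsum = B.sum(axis=1)                          # (n_g,)
        sum_r0sq = float(y0 @ y0)
        sum_c2 = float((B * B).sum()) - 2.0 * (E @ col) + n_g * (E * E).sum(axis=1)
        sum_c1sq = float(rowsum @ rowsum) - 2.0 * tot * rowsum.sum() + n_g * tot**2
        sum_r0c1 = float(y0 @ rowsum) - tot * y0.sum()
        # covariance scalars (block + rank-one Sherman-Morrison)
        a = tau2 + 0.5 * sigma2
        b = 0.5 * sigma2
        apb = a + p * b
        u0 = 1.0 / tau2
        uc = 1.0 / apb
        uu = u0 + p * uc
        logdet = (
            np.log(tau2) + (p - 1) * np.log(a) + np.log(apb)
            + np.log1p(s_mu2 * uu)
        )
        quad_a = sum_r0sq / tau2 + sum_c2 / a - (b / (a * apb)) * sum_c1sq
        sum_t2 = (
            sum_r0sq / tau2**2
            + 2.0 * sum_r0c1 / (tau2 * apb)
            + sum_c1sq / apb**2
        )
        quad = quad_a - (s_mu2 / (1.0 + s_mu2 * uu)) * sum_t2
        out += n_g * (m * LOG_2PI + logdet) + quad
    return out


def compute_dic(draws: PosteriorDraws, records: list[GUSRecord]) -> DICResult:
    """DIC = Dbar + pD with pD = Dbar - D(posterior means of parameters).

    The deviance focus is the population level for both models: the
    respondent intercepts and the RE respondent-level contrasts are
    integrated out, so FE and RE deviances condition on comparable
    parameter sets ((d, tau) and (d, tau, sigma)) and the FE model is the
    exact sigma = 0 special case of the RE one.
    """
    data = _prepare(records, draws.reference)
    if data.n_obs != draws.n_obs or data.respondent_ids != draws.respondent_ids:
        raise ValueError("records do not match the fitted draws (dimension mismatch)")
    free_idx = np.array(
        [j for j, nm in enumerate(draws.devices) if nm != draws.reference]
    )
    d_free = draws.d[:, free_idx]
    sigma = (
        draws.sigma if draws.sigma is not None else np.zeros_like(draws.tau)
    )
    dev_all = marginal_deviance(
        data, free_idx, d_free, draws.tau, sigma, draws.prior_mu
    )
    dbar = float(dev_all.mean())
    # plug-in at posterior means on the variance scale (tau^2, sigma^2): the
    # likelihood is parameterized by variances, and with sigma, tau jointly
    # identified only through sigma^2 + 2 tau^2 this keeps the plug-in point
    # on the posterior's high-density set
    dhat = float(
        marginal_deviance(
            data,
            free_idx,
            d_free.mean(axis=0, keepdims=True),
            np.sqrt([float((draws.tau**2).mean())]),
            np.sqrt([float((sigma**2).mean())]),
            draws.prior_mu,
        )[0]
    )
    pd_eff = dbar - dhat
    return DICResult(
        model_type=draws.model_type, Dbar=dbar, pD=pd_eff, DIC=dbar + pd_eff
    )


def select_model(dic_fe: DICResult, dic_re: DICResult) -> str:
    """The published rule: prefer RE only at a >= 3-point DIC advantage.

    Ties and small differences go to the simpler fixed-effect model.
    """
    if dic_re.DIC <= dic_fe.DIC - DIC_RULE_POINTS:
        return "RE"
    return "FE"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_effects(draws: PosteriorDraws) -> list[DeviceSummary]:
    """Posterior mean and central 95% CrI of each device's absolute GUS level.

    Anchoring: G_k = A + d_k per iteration with A the iteration's mean
    respondent intercept; results are sorted by descending posterior mean.
    """
    g = draws.anchored_gus()
    means = g.mean(axis=0)
    lo = np.quantile(g, 0.025, axis=0)
    hi = np.quantile(g, 0.975, axis=0)
    out = [
        DeviceSummary(device=dev, mean=float(m), cri_low=float(l), cri_high=float(h))
        for dev, m, l, h in zip(draws.devices, means, lo, hi)
    ]
    return sorted(out, key=lambda s: -s.mean)


def summaries_frame(summaries: list[DeviceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "device": s.device,
                "mean_gus": s.mean,
                "cri_low": s.cri_low,
                "cri_high": s.cri_high,
            }
            for s in summaries
        ]
    )


def rank_probabilities(draws: PosteriorDraws) -> pd.DataFrame:
    """Device-by-rank probability matrix (rank 1 = highest GUS).

    At each iteration devices are ranked by their anchored GUS, ties broken
    by canonical device order; entry (k, r) is the fraction of iterations in
    which device k holds rank r.  Rows and columns each sum to 1 up to
    Monte-Carlo tolerance.
    """
    g = draws.anchored_gus()
    n_draws, n_dev = g.shape
    # stable argsort on -G: equal values resolve to the lower (canonical) index
    order = np.argsort(-g, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_dev)[None, :].repeat(n_draws, axis=0)
    np.put_along_axis(ranks, order, rows, axis=1)
    counts = np.zeros((n_dev, n_dev))
    for r in range(n_dev):
        counts[:, r] = (ranks == r).sum(axis=0)
    probs = counts / n_draws
    return pd.DataFrame(
        probs, index=list(draws.devices), columns=[r + 1 for r in range(n_dev)]
    )


def rank_long(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy (device, rank, probability) export of the rank matrix."""
    long = rank_matrix.reset_index(names="device").melt(
        id_vars="device", var_name="rank", value_name="probability"
    )
    return long.sort_values(["device", "rank"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """Stack each chain's first/second half as rows (m_chains*2, n//2)."""
    halves = []
    for c in np.unique(chain):
        v = x[chain == c]
        h = len(v) // 2
        halves.append(v[:h])
        halves.append(v[h : 2 * h])
    n = min(len(h) for h in halves)
    return np.vstack([h[:n] for h in halves])


def split_rhat(x: np.ndarray, chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (textbook form)."""
    s = _split_chains(x, chain)
    m, n = s.shape
    if n < 2:
        return float("nan")
    chain_means = s.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = s.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(x: np.ndarray, chain: np.ndarray) -> float:
    """Multi-chain ESS using Geyer's initial-positive-sequence truncation."""
    s = _split_chains(x, chain)
    m, n = s.shape
    if n < 4:
        return float(m * n)
    chain_means = s.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = s.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * w + b / n
    if var_plus == 0:
        return float(m * n)
    # mean autocovariance across chains via FFT
    acov = np.zeros(n)
    for row in s:
        centered = row - row.mean()
        f = np.fft.rfft(centered, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    rho = 1.0 - (w - acov) / var_plus
    # sum consecutive pairs while positive
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        total += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * total)
    return float(min(ess, m * n))


def diagnose(draws: PosteriorDraws) -> dict:
    """Split-R-hat and effective sample size for the scalar parameters.

    Requires >= 2 chains; the convergence flag is all R-hat < 1.05.
    """
    if len(np.unique(draws.chain)) < 2:
        raise ValueError("diagnostics require at least 2 chains")
    params: dict[str, np.ndarray] = {}
    for j, devname in enumerate(draws.devices):
        if devname != draws.reference:
            params[f"d[{devname}]"] = draws.d[:, j]
    params["tau"] = draws.tau
    if draws.sigma is not None:
        params["sigma"] = draws.sigma
    rhat = {k: split_rhat(v, draws.chain) for k, v in params.items()}
    ess = {k: effective_sample_size(v, draws.chain) for k, v in params.items()}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v < RHAT_THRESHOLD for v in finite) if finite else False
    return {"rhat": rhat, "ess": ess, "converged": converged}
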