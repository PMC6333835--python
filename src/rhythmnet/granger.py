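"""MVAR fitting and spectral Granger causality (pairwise, conditional, and
theta-phase-binned), statsmodels-style: an :class:`MVAR` model object whose
``fit()`` returns an :class:`MVARResults` carrying coefficients, noise
covariance, diagnostics, and the Geweke spectral measures.

Signals are downsampled to 250 Hz and z-scored per trial/channel before
modeling; the default model order is 8.  Multi-trial fits pool the
least-squares normal equations across trials, which is what makes order-8
fits of 25-sample half-theta-cycle epochs possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sp_linalg
from scipy import signal as sp_signal

from .phasebin import ThetaBinDefinition
from .session import EpochedSignal
from .spectral import morlet_transform
from .stats import holm_correct, permutation_result

GC_CLAMP = 1e-10
DEFAULT_FREQS = np.arange(3.0, 60.01, 0.5)


def preprocess_gc(signals: list, target_rate_hz: float = 250.0) -> tuple:
    """Anti-alias filter, decimate to 250 Hz, and z-score per trial/channel.

    Returns ``(epochs, rate_hz, trial_ids)`` with epochs shaped
    (n_trials, n_channels, n_samples).
    """
    if not signals:
        raise ValueError("no signals given")
    rate = signals[0].rate_hz
    n = signals[0].n_samples
    ids = signals[0].trial_ids
    for s in signals[1:]:
        if s.rate_hz != rate or s.n_samples != n or not np.array_equal(
                s.trial_ids, ids):
            raise ValueError("signals must share epoch, rate, and trials")
    chans = []
    for s in signals:
        x = s.samples
        if rate != target_rate_hz:
            ratio = rate / target_rate_hz
            if abs(ratio - round(ratio)) < 1e-9:
                x = sp_signal.decimate(x, int(round(ratio)), axis=1,
                                       ftype="fir", zero_phase=True)
            else:
                from fractions import Fraction
                fr = Fraction(target_rate_hz / rate).limit_denominator(1000)
                x = sp_signal.resample_poly(x, fr.numerator, fr.denominator,
                                            axis=1)
        sd = x.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance trial; cannot normalize")
        chans.append((x - x.mean(axis=1, keepdims=True)) / sd)
    return np.stack(chans, axis=1), target_rate_hz, ids.copy()


def _lagged(epochs: np.ndarray, order: int) -> tuple:
    """Design/response blocks per trial: X (n_tr, rows, n*p), Y (n_tr, rows, n)."""
    n_tr, n_ch, n_s = epochs.shape
    rows = n_s - order
    if rows < 1:
        raise ValueError("epoch shorter than the model order")
    X = np.empty((n_tr, rows, n_ch * order))
    for k in range(order):
        X[:, :, k * n_ch:(k + 1) * n_ch] = np.swapaxes(
            epochs[:, :, order - 1 - k:n_s - 1 - k], 1, 2)
    Y = np.swapaxes(epochs[:, :, order:], 1, 2)
    return X, Y


@dataclass
class MVARResults:
    """Fitted vector autoregression and its spectral causal measures."""

    coefficients: np.ndarray      # (order, n, n); x_t = sum A_k x_{t-k} + e
    noise_cov: np.ndarray
    rate_hz: float
    n_obs: int
    channel_names: tuple
    aic_table: dict | None = None
    stable_flag: bool = True

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    def companion(self) -> np.ndarray:
        p, n, _ = self.coefficients.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coefficients), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def transfer(self, freqs_hz: np.ndarray) -> np.ndarray:
        """H(f) = (I - sum A_k e^{-2 pi i f k / fs})^{-1}, (n_f, n, n)."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        p, n, _ = self.coefficients.shape
        z = np.exp(-2j * np.pi * np.outer(freqs_hz, np.arange(1, p + 1))
                   / self.rate_hz)
        a_f = np.eye(n)[None, :, :] - np.einsum(
            "fk,kij->fij", z, self.coefficients)
        return np.linalg.inv(a_f)

    def spectral_matrix(self, freqs_hz: np.ndarray) -> np.ndarray:
        h = self.transfer(freqs_hz)
        return h @ self.noise_cov @ np.conj(np.swapaxes(h, 1, 2))

    def autocovariance(self, n_lags: int) -> np.ndarray:
        """Analytic autocovariance sequence Gamma_0..Gamma_{n_lags}."""
        p, n, _ = self.coefficients.shape
        comp = self.companion()
        q = np.zeros_like(comp)
        q[:n, :n] = self.noise_cov
        big = sp_linalg.solve_discrete_lyapunov(comp, q)
        gammas = [big[:n, k * n:(k + 1) * n] for k in range(p)]
        while len(gammas) <= n_lags:
            k = len(gammas)
            g = np.zeros((n, n))
            for j in range(1, p + 1):
                prev = gammas[k - j] if k - j >= 0 else gammas[j - k].T
                g += self.coefficients[j - 1] @ prev
            gammas.append(g)
        return np.array(gammas[: n_lags + 1])

    def submodel(self, channels: list, order: int | None = None
                 ) -> "MVARResults":
        """Population VAR of a channel subset, from the analytic
        autocovariance (block Yule-Walker).  The subset's exact process is
        VARMA; a longer AR order absorbs the MA part."""
        q = order or max(self.order, 20)
        gam = self.autocovariance(q)
        idx = np.asarray(channels)
        g = gam[:, idx[:, None], idx[None, :]]
        m = idx.size

        def block(j):  # Gamma_j with Gamma_{-j} = Gamma_j^T
            return g[j] if j >= 0 else g[-j].T

        big = np.empty((m * q, m * q))
        for k in range(1, q + 1):
            for j in range(1, q + 1):
                big[(k - 1) * m:k * m, (j - 1) * m:j * m] = block(j - k)
        rhs = np.concatenate([block(j) for j in range(1, q + 1)], axis=1)
        a_stack = rhs @ np.linalg.inv(big)
        coefs = np.array([a_stack[:, (k - 1) * m:k * m]
                          for k in range(1, q + 1)])
        sigma = g[0].copy()
        for k in range(1, q + 1):
            sigma -= coefs[k - 1] @ g[k].T
        sigma = 0.5 * (sigma + sigma.T)
        return MVARResults(coefficients=coefs, noise_cov=sigma,
                           rate_hz=self.rate_hz, n_obs=self.n_obs,
                           channel_names=tuple(self.channel_names[i]
                                               for i in idx))

    # ---- Geweke measures -------------------------------------------------

    def granger(self, freqs_hz: np.ndarray = DEFAULT_FREQS
                ) -> "GrangerSpectrum":
        """Pairwise spectral Granger causality for every ordered pair.

        Pairs are evaluated on the exact bivariate submodel (for a
        two-channel fit this is the fit itself)."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        values = {}
        n = self.n_channels
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                sub = (self if n == 2 else self.submodel([a, b]))
                values[(self.channel_names[a], self.channel_names[b])] = \
                    _pairwise_gc(sub, source=(a if n == 2 else 0),
                                 sink=(b if n == 2 else 1), freqs=freqs_hz)
        return GrangerSpectrum(freqs_hz=freqs_hz, values=values)

    def conditional_granger(self, source, sink, conditioning,
                            freqs_hz: np.ndarray = DEFAULT_FREQS
                            ) -> "GrangerSpectrum":
        """Geweke conditional GC source -> sink given the conditioning
        channel(s): the part of the sink's reduced-model innovation
        spectrum attributable to the source's (orthogonalized) innovation."""
        names = list(self.channel_names)

        def _idx(c):
            return names.index(c) if isinstance(c, str) else int(c)

        si = _idx(source)
        ki = _idx(sink)
        ci = [_idx(c) for c in (conditioning if isinstance(
            conditioning, (list, tuple)) else [conditioning])]
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        reduced = self.submodel([ki] + ci)
        h_full = self.transfer(freqs_hz)            # (nf, n, n)
        g_red = reduced.transfer(freqs_hz)          # (nf, m, m)
        rows = h_full[:, [ki] + ci, :]
        q = np.linalg.solve(g_red, rows)            # (nf, m, n)
        q_sink = q[:, 0, :]                         # (nf, n)
        order = [ki] + ci + [si]
        sig = self.noise_cov[np.ix_(order, order)]
        chol = np.linalg.cholesky(sig)
        r = q_sink[:, order] @ chol                 # (nf, m+1)
        src_part = np.abs(r[:, -1]) ** 2
        s2 = reduced.noise_cov[0, 0]
        denom = np.maximum(s2 - src_part, 1e-300)
        gc = np.log(s2 / denom)
        gc = _clamp_gc(gc)
        key = (self.channel_names[si], self.channel_names[ki])
        return GrangerSpectrum(freqs_hz=freqs_hz, values={key: gc},
                               conditional_on=tuple(self.channel_names[c]
                                                    for c in ci))

    def summary(self) -> str:
        lines = [
            "MVAR results",
            f"  channels: {', '.join(map(str, self.channel_names))}",
            f"  order: {self.order}   rate: {self.rate_hz:g} Hz   "
            f"n_obs: {self.n_obs}",
            f"  spectral radius: {self.spectral_radius:.4f} "
            f"({'stable' if self.stable_flag else 'UNSTABLE'})",
            "  noise covariance:",
        ]
        for row in self.noise_cov:
            lines.append("    " + "  ".join(f"{v: .4f}" for v in row))
        if self.aic_table:
            best = min(self.aic_table, key=self.aic_table.get)
            lines.append(f"  AIC minimum at order {best}")
        return "\n".join(lines)


def _clamp_gc(gc: np.ndarray) -> np.ndarray:
    if np.any(gc < -GC_CLAMP):
        raise ValueError(f"negative Granger values below -{GC_CLAMP}")
    return np.maximum(gc, 0.0)


def _pairwise_gc(model: MVARResults, source: int, sink: int,
                 freqs: np.ndarray) -> np.ndarray:
    """Two-channel Geweke measure source -> sink from the model's transfer
    function and noise covariance."""
    s = model.spectral_matrix(freqs)
    h = model.transfer(freqs)
    sig = model.noise_cov
    s_yy = np.real(s[:, sink, sink])
    partial = sig[source, source] - sig[sink, source] ** 2 / sig[sink, sink]
    intrinsic = s_yy - partial * np.abs(h[:, sink, source]) ** 2
    gc = np.log(s_yy / np.maximum(intrinsic, 1e-300))
    return _clamp_gc(gc)


@dataclass
class GrangerSpectrum:
    freqs_hz: np.ndarray
    values: dict                     # (source, sink) -> per-frequency GC
    conditional_on: tuple | None = None
    theta_bin: str = "all"

    def __getitem__(self, key):
        return self.values[key]


class MVAR:
    """Multi-trial vector autoregression, least squares pooled over trials."""

    def __init__(self, epochs: np.ndarray, rate_hz: float, order: int = 8,
                 channel_names: tuple | None = None):
        epochs = np.asarray(epochs, dtype=float)
        if epochs.ndim != 3:
            raise ValueError("epochs must be (n_trials, n_channels, n_samples)")
        self.epochs = epochs
        self.rate_hz = float(rate_hz)
        self.order = int(order)
        n_ch = epochs.shape[1]
        self.channel_names = tuple(channel_names) if channel_names \
            else tuple(range(n_ch))
        n_obs = epochs.shape[0] * (epochs.shape[2] - order)
        if n_obs < 10 * order * n_ch ** 2:
            warnings.warn(
                f"only {n_obs} observations for {order * n_ch ** 2} "
                "parameters; fit may be unreliable", stacklevel=2)

    def fit(self, compute_aic: bool = False,
            aic_orders=range(1, 13)) -> MVARResults:
        X, Y = _lagged(self.epochs, self.order)
        n_tr, rows, _ = X.shape
        Xf = X.reshape(n_tr * rows, -1)
        Yf = Y.reshape(n_tr * rows, -1)
        beta, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)
        resid = Yf - Xf @ beta
        sigma = resid.T @ resid / (Xf.shape[0] - Xf.shape[1])
        n_ch = self.epochs.shape[1]
        coefs = np.array([beta[k * n_ch:(k + 1) * n_ch].T
                          for k in range(self.order)])
        aic_table = None
        if compute_aic:
            aic_table = {p: self._aic(p) for p in aic_orders}
        res = MVARResults(coefficients=coefs, noise_cov=sigma,
                          rate_hz=self.rate_hz, n_obs=Xf.shape[0],
                          channel_names=self.channel_names,
                          aic_table=aic_table)
        res.stable_flag = res.spectral_radius < 1.0
        if not res.stable_flag:
            warnings.warn("fitted MVAR model is unstable", stacklevel=2)
        return res

    def _aic(self, order: int) -> float:
        X, Y = _lagged(self.epochs, order)
        Xf = X.reshape(-1, X.shape[-1])
        Yf = Y.reshape(-1, Y.shape[-1])
        beta, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)
        resid = Yf - Xf @ beta
        sigma = resid.T @ resid / Xf.shape[0]
        n_ch = Yf.shape[1]
        n = Xf.shape[0]
        _, logdet = np.linalg.slogdet(sigma)
        return float(n * logdet + 2.0 * order * n_ch ** 2)


def fit_mvar(epochs: np.ndarray, rate_hz: float = 250.0, order: int = 8,
             channel_names: tuple | None = None,
             compute_aic: bool = False) -> MVARResults:
    return MVAR(epochs, rate_hz, order, channel_names).fit(
        compute_aic=compute_aic)


def spectral_granger(model: MVARResults,
                     freqs_hz: np.ndarray = DEFAULT_FREQS) -> GrangerSpectrum:
    return model.granger(freqs_hz)


def conditional_granger(model: MVARResults, source, sink, conditioning,
                        freqs_hz: np.ndarray = DEFAULT_FREQS
                        ) -> GrangerSpectrum:
    return model.conditional_granger(source, sink, conditioning, freqs_hz)


def theta_binned_granger(signals: list, theta_source: EpochedSignal,
                         bins: ThetaBinDefinition, order: int = 8,
                         freqs_hz: np.ndarray = DEFAULT_FREQS,
                         min_trials: int = 30,
                         window_ms: float = 100.0) -> dict:
    """Granger spectra fitted separately to good- and poor-theta trials.

    Theta phase per trial comes from a 2-cycle 5 Hz wavelet on
    ``theta_source`` at the bin definition's estimation time; the modeled
    epoch is half a theta cycle (100 ms) centered on that same time,
    pooled across the bin's trials.
    """
    spect = morlet_transform(theta_source, [bins.freq_hz],
                             n_cycles=bins.wavelet_cycles,
                             times_ms=[bins.estimation_time_ms])
    if not spect.valid[0, 0]:
        raise ValueError("theta estimation time is edge-contaminated")
    theta_phase = np.angle(spect.coefficients[:, 0, 0])
    assign = bins.assign(theta_phase)
    epochs, rate, ids = preprocess_gc(signals)
    t0 = signals[0].t0_ms
    center = bins.estimation_time_ms
    i0 = int(round((center - window_ms / 2.0 - t0) * rate / 1000.0))
    n_s = int(round(window_ms * rate / 1000.0))
    if i0 < 0 or i0 + n_s > epochs.shape[2]:
        raise ValueError("half-cycle window outside the epoch")
    names = tuple(s.roi for s in signals)
    out = {}
    for label, flag in (("good", 1), ("poor", -1)):
        sel = assign == flag
        if sel.sum() < min_trials:
            raise ValueError(
                f"{label} theta bin has {int(sel.sum())} trials "
                f"(< {min_trials})")
        model = fit_mvar(epochs[sel][:, :, i0:i0 + n_s], rate, order, names)
        spec = model.granger(freqs_hz)
        spec.theta_bin = label
        out[label] = spec
    return out


def gc_permutation_test(epochs: np.ndarray, rate_hz: float,
                        pair: tuple = (0, 1), order: int = 8,
                        freqs_hz: np.ndarray = DEFAULT_FREQS,
                        n_perm: int = 1500, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Permutation test of directional asymmetry GC(a->b) - GC(b->a).

    The null re-pairs channel b's trials with channel a's (breaking
    cross-channel dependence while preserving each channel's
    autostructure) and refits the bivariate model each time.
    """
    a, b = pair
    sub = epochs[:, [a, b], :]
    n_tr = sub.shape[0]
    if n_tr < 10:
        raise ValueError("need at least 10 trials")
    X, Y = _lagged(sub, order)
    # split the design into per-channel lag blocks for fast re-pairing
    idx_a = np.arange(order) * 2
    idx_b = idx_a + 1
    A_l, B_l = X[:, :, idx_a], X[:, :, idx_b]
    ya, yb = Y[:, :, 0], Y[:, :, 1]
    freqs_hz = np.asarray(freqs_hz, dtype=float)

    def fit_from_parts(perm):
        Bp = B_l[perm]
        ybp = yb[perm]
        xtx = np.empty((2 * order, 2 * order))
        xtx[np.ix_(range(order), range(order))] = np.einsum(
            "irk,irl->kl", A_l, A_l)
        cross = np.einsum("irk,irl->kl", A_l, Bp)
        xtx[np.ix_(range(order), range(order, 2 * order))] = cross
        xtx[np.ix_(range(order, 2 * order), range(order))] = cross.T
        xtx[np.ix_(range(order, 2 * order), range(order, 2 * order))] = \
            np.einsum("irk,irl->kl", Bp, Bp)
        xty = np.empty((2 * order, 2))
        xty[:order, 0] = np.einsum("irk,ir->k", A_l, ya)
        xty[:order, 1] = np.einsum("irk,ir->k", A_l, ybp)
        xty[order:, 0] = np.einsum("irk,ir->k", Bp, ya)
        xty[order:, 1] = np.einsum("irk,ir->k", Bp, ybp)
        beta = np.linalg.solve(xtx, xty)
        n_obs = A_l.shape[0] * A_l.shape[1]
        yty = np.array([[np.sum(ya * ya), np.sum(ya * ybp)],
                        [np.sum(ya * ybp), np.sum(ybp * ybp)]])
        sigma = (yty - beta.T @ xty) / (n_obs - 2 * order)
        coefs = np.empty((order, 2, 2))
        for k in range(order):
            coefs[k, 0, 0] = beta[k, 0]
            coefs[k, 0, 1] = beta[order + k, 0]
            coefs[k, 1, 0] = beta[k, 1]
            coefs[k, 1, 1] = beta[order + k, 1]
        return MVARResults(coefficients=coefs, noise_cov=sigma,
                           rate_hz=rate_hz, n_obs=n_obs,
                           channel_names=("a", "b"))

    def asym(model):
        ab = _pairwise_gc(model, source=0, sink=1, freqs=freqs_hz)
        ba = _pairwise_gc(model, source=1, sink=0, freqs=freqs_hz)
        return ab - ba

    identity = np.arange(n_tr)
    observed = asym(fit_from_parts(identity))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, freqs_hz.size))
    for k in range(n_perm):
        null[k] = asym(fit_from_parts(rng.permutation(n_tr)))
    perms = [permutation_result(observed[i], null[:, i], "two_sided")
             for i in range(freqs_hz.size)]
    holm = holm_correct([p.p for p in perms], alpha=alpha)
    for p, h in zip(perms, holm):
        p.holm_significant = bool(h)
    return {"freqs_hz": freqs_hz, "observed": observed,
            "permutations": perms, "holm_significant": holm}
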