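"""Pairwise temporal and spectral Granger causality with surrogate testing.

The target series Y is modelled by its own past (reduced model) and by its
own past plus the past of the putative source X (full model), both fitted by
ordinary least squares per sliding window.  The Granger statistic is

    F_{X->Y} = ln( var(eps_Y_reduced) / var(eps_Y_full) )

averaged across windows (defaults: 250 Hz, 5 s windows, 80% overlap, order
p = 12).  The spectral statistic is Geweke's frequency-domain decomposition
computed from the fitted full-model VAR transfer function.  Significance
uses block-resampling surrogates: the source is cut at a single random point
and the two blocks swapped, the statistic recomputed, a normal fitted to the
surrogate values, and the threshold set at its 95th percentile.

Window fits are batched (shared lag embedding, per-window Gram matrices via
one matmul) so that surrogate loops stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as spstats

__all__ = [
    "VARModel",
    "GrangerResult",
    "fit_var",
    "granger_temporal",
    "granger_spectral",
    "block_resample",
    "granger_significance",
]


@dataclass
class VARModel:
    """Bivariate VAR(p) fitted by OLS: z(t) = c + sum_k A_k z(t-k) + eps."""

    order: int
    coefs: np.ndarray         # (p, 2, 2); coefs[k-1][i, j]: z_j(t-k) -> z_i(t)
    intercept: np.ndarray     # (2,)
    resid_cov: np.ndarray     # (2, 2)
    loglik: float
    spectral_radius: float

    @property
    def stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class GrangerResult:
    F_xy: float               # X -> Y, window-averaged
    F_yx: float               # Y -> X
    per_window: np.ndarray | None = None   # (n_windows, 2): columns (xy, yx)
    freqs: np.ndarray | None = None
    spectral_xy: np.ndarray | None = None
    spectral_yx: np.ndarray | None = None
    threshold_xy: float | None = None
    threshold_yx: float | None = None
    significant_xy: bool | None = None
    significant_yx: bool | None = None
    n_windows_used: int = 0
    n_windows_total: int = 0
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# lag embeddings and batched window OLS

def _lag_matrix(z: np.ndarray, p: int) -> np.ndarray:
    """Rows t = p..T-1, columns [z(t-1), ..., z(t-p)]."""
    return sliding_window_view(z, p)[: z.size - p, ::-1]


def _window_starts(T: int, n_w: int, step: int) -> np.ndarray:
    return np.arange(0, T - n_w + 1, step)


def _solve_batched(G: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Batched normal-equation solve with a pinv fallback for singular
    windows (e.g. a surrogate whose lag columns duplicate the originals)."""
    try:
        return np.linalg.solve(G, r[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(r)
        for w in range(G.shape[0]):
            try:
                out[w] = np.linalg.solve(G[w], r[w])
            except np.linalg.LinAlgError:
                out[w] = np.linalg.pinv(G[w]) @ r[w]
        return out


class _PairEngine:
    """Precomputed per-window OLS pieces for one (x, y) pair.

    Builds the shared design [1 | y-lags | x-lags], window Gram matrices and
    cross products once; directional statistics then reduce to batched
    25 x 25 solves, which makes the surrogate loop fast.
    """

    def __init__(self, x, y, fs, window_s, overlap, p):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D series")
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero-variance input: VAR fit undefined")
        T = x.size
        n_w = int(round(window_s * fs))
        if n_w <= p + 2 * p + 2:
            raise ValueError("window too short for the model order")
        step = max(1, int(round(n_w * (1 - overlap))))
        starts = _window_starts(T, n_w, step)
        if starts.size < 1:
            raise ValueError("series shorter than one window")
        self.x, self.y, self.p = x, y, p
        self.n_eff = n_w - p
        self.starts = starts
        self.n_windows = starts.size
        # column layout: 0 const, 1..p y-lags, p+1..2p x-lags
        self.idx_y = np.r_[0, 1 + np.arange(p)]
        self.idx_x = np.r_[0, 1 + p + np.arange(p)]
        D = np.empty((T - p, 1 + 2 * p))
        D[:, 0] = 1.0
        D[:, 1 : 1 + p] = _lag_matrix(y, p)
        D[:, 1 + p :] = _lag_matrix(x, p)
        self._set_design(D)

    def _set_design(self, D: np.ndarray) -> None:
        D3 = sliding_window_view(D, self.n_eff, axis=0)  # (T-n_w+1, ncol, n_eff)
        D3 = D3[self.starts].transpose(0, 2, 1)          # (n_win, n_eff, ncol)
        self.D3 = np.ascontiguousarray(D3)
        self.G = self.D3.transpose(0, 2, 1) @ self.D3     # (n_win, ncol, ncol)

    def replace_source(self, side: str, z: np.ndarray) -> None:
        """Swap in a surrogate series for the x or y columns."""
        p = self.p
        D = np.empty((z.size - p, 1 + 2 * p))
        D[:, 0] = 1.0
        D[:, 1 : 1 + p] = _lag_matrix(self.y if side == "x" else z, p)
        D[:, 1 + p :] = _lag_matrix(z if side == "x" else self.x, p)
        self._set_design(D)

    def _targets(self, z: np.ndarray) -> np.ndarray:
        zt = z[self.p :]
        Z = sliding_window_view(zt, self.n_eff)[self.starts]
        return Z

    def direction_stats(self, target: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-window (F, resid_var_full, coefs_full) for source -> target."""
        z = self.y if target == "y" else self.x
        idx_red = self.idx_y if target == "y" else self.idx_x
        Z = self._targets(z)
        r = np.einsum("wti,wt->wi", self.D3, Z)
        zz = np.einsum("wt,wt->w", Z, Z)
        b_full = _solve_batched(self.G, r)
        rss_full = zz - np.einsum("wi,wi->w", b_full, r)
        G_red = self.G[:, idx_red[:, None], idx_red[None, :]]
        r_red = r[:, idx_red]
        b_red = _solve_batched(G_red, r_red)
        rss_red = zz - np.einsum("wi,wi->w", b_red, r_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.log(rss_red / rss_full)
        return F, rss_full / self.n_eff, b_full

    def companion_radius(self, b_y: np.ndarray, b_x: np.ndarray) -> np.ndarray:
        """Spectral radius of the companion matrix, per window."""
        p = self.p
        n_win = b_y.shape[0]
        radius = np.empty(n_win)
        for w in range(n_win):
            A = np.zeros((2 * p, 2 * p))
            for k in range(p):
                A[0, 2 * k] = b_y[w, 1 + k]          # y(t-k-1) -> y
                A[0, 2 * k + 1] = b_y[w, 1 + p + k]  # x(t-k-1) -> y
                A[1, 2 * k] = b_x[w, 1 + k]
                A[1, 2 * k + 1] = b_x[w, 1 + p + k]
            if p > 1:
                A[2:, :-2] = np.eye(2 * p - 2)
            radius[w] = np.max(np.abs(np.linalg.eigvals(A)))
        return radius


def fit_var(x: np.ndarray, y: np.ndarray, p: int) -> VARModel:
    """OLS fit of a bivariate VAR(p) to the full series (variables (x, y))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    T = x.size
    D = np.empty((T - p, 1 + 2 * p))
    D[:, 0] = 1.0
    D[:, 1 : 1 + p] = _lag_matrix(x, p)
    D[:, 1 + p :] = _lag_matrix(y, p)
    Z = np.column_stack([x[p:], y[p:]])
    B, *_ = np.linalg.lstsq(D, Z, rcond=None)
    resid = Z - D @ B
    n = resid.shape[0]
    cov = resid.T @ resid / n
    coefs = np.empty((p, 2, 2))
    for k in range(p):
        # variable order (x, y): column blocks are x-lags then y-lags
        coefs[k, 0, 0] = B[1 + k, 0]
        coefs[k, 0, 1] = B[1 + p + k, 0]
        coefs[k, 1, 0] = B[1 + k, 1]
        coefs[k, 1, 1] = B[1 + p + k, 1]
    comp = np.zeros((2 * p, 2 * p))
    for k in range(p):
        comp[:2, 2 * k : 2 * k + 2] = coefs[k]
    if p > 1:
        comp[2:, :-2] = np.eye(2 * p - 2)
    radius = float(np.max(np.abs(np.linalg.eigvals(comp))))
    sign, logdet = np.linalg.slogdet(cov)
    loglik = -0.5 * n * (2 * np.log(2 * np.pi) + logdet + 2)
    model = VARModel(
        order=p, coefs=coefs, intercept=B[0], resid_cov=cov,
        loglik=float(loglik), spectral_radius=radius,
    )
    if not model.stable:
        warnings.warn(f"fitted VAR is unstable (spectral radius {radius:.3f})")
    return model


def granger_temporal(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 250.0,
    window_s: float = 5.0,
    overlap: float = 0.8,
    p: int = 12,
    drop_unstable: bool = True,
) -> GrangerResult:
    """Window-averaged pairwise temporal Granger causality, both directions.

    Windows whose full bivariate VAR is unstable (companion spectral radius
    >= 1) are excluded from the average; their count is reported.
    """
    eng = _PairEngine(x, y, fs, window_s, overlap, p)
    F_xy, _, b_y = eng.direction_stats("y")   # X -> Y
    F_yx, _, b_x = eng.direction_stats("x")   # Y -> X
    keep = np.ones(eng.n_windows, bool)
    if drop_unstable:
        radius = eng.companion_radius(b_y, b_x)
        keep = radius < 1.0
        if not keep.any():
            raise ValueError("all windows have unstable VAR fits")
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropped {n_drop} unstable window(s) from the average")
    per_window = np.column_stack([F_xy, F_yx])
    return GrangerResult(
        F_xy=float(F_xy[keep].mean()),
        F_yx=float(F_yx[keep].mean()),
        per_window=per_window,
        n_windows_used=int(keep.sum()),
        n_windows_total=eng.n_windows,
        params=dict(fs=fs, window_s=window_s, overlap=overlap, p=p),
    )


def granger_spectral(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 250.0,
    p: int = 12,
    n_freqs: int = 129,
    jitter: float = 1e-12,
) -> GrangerResult:
    """Geweke spectral Granger causality from a full-series VAR fit.

    The spectral density matrix S(f) = H(f) Sigma H*(f) is computed from the
    fitted transfer function H = (I - sum A_k e^{-i 2 pi f k / fs})^{-1};
    the directional statistic at each frequency is

        f_{X->Y}(f) = ln( S_yy / (S_yy - |H_yx|^2 (Sxx - Sxy^2/Syy)) ).
    """
    model = fit_var(x, y, p)
    cov = model.resid_cov.copy()
    if np.linalg.cond(cov) > 1e12:
        warnings.warn(f"near-singular residual covariance; jitter {jitter} added")
        cov += jitter * np.eye(2)
    freqs = np.linspace(0, fs / 2, n_freqs)
    I = np.eye(2)
    gc_xy = np.empty(n_freqs)
    gc_yx = np.empty(n_freqs)
    for i, f in enumerate(freqs):
        A = I.astype(complex).copy()
        for k in range(p):
            A -= model.coefs[k] * np.exp(-2j * np.pi * f * (k + 1) / fs)
        H = np.linalg.inv(A)
        S = H @ cov @ H.conj().T
        # variable order (x, y): index 0 = x, 1 = y
        sxx_c = cov[0, 0] - cov[0, 1] ** 2 / cov[1, 1]   # x residual | y
        syy_c = cov[1, 1] - cov[0, 1] ** 2 / cov[0, 0]
        Syy = S[1, 1].real
        Sxx = S[0, 0].real
        gc_xy[i] = np.log(Syy / max(Syy - (np.abs(H[1, 0]) ** 2) * sxx_c, 1e-300))
        gc_yx[i] = np.log(Sxx / max(Sxx - (np.abs(H[0, 1]) ** 2) * syy_c, 1e-300))
    return GrangerResult(
        F_xy=float(gc_xy.mean()),
        F_yx=float(gc_yx.mean()),
        freqs=freqs,
        spectral_xy=gc_xy,
        spectral_yx=gc_yx,
        params=dict(fs=fs, p=p),
    )


def block_resample(
    x: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cut: int | None = None,
) -> np.ndarray:
    """Block-resampling surrogate: cut at one random point, swap the blocks.

    Preserves the sample multiset and all autocorrelation except at the
    single seam; destroys the temporal relation to any other series.
    """
    x = np.asarray(x)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    if cut is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        cut = int(rng.integers(1, x.size))
    return np.concatenate([x[cut:], x[:cut]])


def granger_significance(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 250.0,
    window_s: float = 5.0,
    overlap: float = 0.8,
    p: int = 12,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    resample: str = "source",
    seed: int | None = None,
) -> GrangerResult:
    """Surrogate significance for window-averaged temporal Granger causality.

    For each direction the putative source is block-resampled (``resample =
    "both"`` also resamples the target), the window-averaged statistic
    recomputed, a normal distribution fitted to the surrogate values, and
    the threshold set at its ``(1 - alpha)`` quantile.
    """
    if resample not in ("source", "both"):
        raise ValueError("resample must be 'source' or 'both'")
    rng = np.random.default_rng(seed)
    obs = granger_temporal(x, y, fs, window_s, overlap, p, drop_unstable=True)

    eng = _PairEngine(x, y, fs, window_s, overlap, p)
    thresholds = {}
    flags = {}
    for direction, target_key, source, side in (
        ("xy", "y", x, "x"),
        ("yx", "x", y, "y"),
    ):
        surr_F = np.empty(n_surrogates)
        for i in range(n_surrogates):
            s_src = block_resample(source, rng=rng)
            if resample == "both":
                tgt = y if target_key == "y" else x
                s_tgt = block_resample(tgt, rng=rng)
                pair = (s_src, s_tgt) if side == "x" else (s_tgt, s_src)
                eng_i = _PairEngine(pair[0], pair[1], fs, window_s, overlap, p)
            else:
                eng.replace_source(side, s_src)
                eng_i = eng
            F, _, _ = eng_i.direction_stats(target_key)
            surr_F[i] = F.mean()
        finite = surr_F[np.isfinite(surr_F)]
        if finite.size < max(2, n_surrogates // 2):
            raise ValueError("degenerate surrogate distribution")
        mu, sd = float(finite.mean()), float(finite.std(ddof=1))
        if sd == 0:
            raise ValueError("degenerate surrogate distribution (zero variance)")
        thr = mu + spstats.norm.ppf(1 - alpha) * sd
        thresholds[direction] = thr
        flags[direction] = bool(
            (obs.F_xy if direction == "xy" else obs.F_yx) > thr
        )
    obs.threshold_xy = thresholds["xy"]
    obs.threshold_yx = thresholds["yx"]
    obs.significant_xy = flags["xy"]
    obs.significant_yx = flags["yx"]
    obs.params.update(n_surrogates=n_surrogates, alpha=alpha, resample=resample)
    return obs
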