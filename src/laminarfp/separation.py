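"""Blind separation of laminar field potentials into FP generators.

The model is linear and instantaneous: the potential at electrode m is a
weighted sum of N generator time courses,

    u_m(t) = sum_n V_mn s_n(t),

where the columns of the mixing matrix V are depth "voltage profiles" that
identify synaptic pathways, and s_n(t) are the generator activations.  PCA
pre-reduction removes noisy weak dimensions and stabilizes the subsequent
ICA; generators contributing less than 1% relative variance are rejected;
left and right profiles are matched by hierarchical clustering of the
correlation distance (pairs accepted below 0.2); and a minimum epoch length
is chosen so the bilateral cross-correlation stays within 3% of its running
mean.

:class:`LaminarICA` is a scikit-learn style estimator (``fit`` /
``transform`` on time x channels arrays) wrapping FastICA with a fixed-seed
multi-restart (best-of-5 by summed non-Gaussianity) and a canonical output
convention: unit-norm profiles with the largest-magnitude loading positive,
amplitude carried by the time course, components ordered by variance
fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .io import BilateralRecording, Recording

__all__ = [
    "save_generator_set",
    "load_generator_set",
    "GeneratorSet",
    "ProfileMatch",
    "PCAReduction",
    "EpochStability",
    "LaminarICA",
    "pca_reduce",
    "run_ica",
    "relative_variance_filter",
    "match_profiles",
    "epoch_stability_length",
]


@dataclass
class GeneratorSet:
    """Separated FP generators: mixing profiles plus time courses.

    ``mixing[:, n]`` is generator n's depth profile (unit Euclidean norm,
    largest-|loading| channel positive); ``timecourses[n]`` carries the
    amplitude (mV at the peak-loading site per unit loading).
    """

    mixing: np.ndarray            # channels x generators
    timecourses: np.ndarray       # generators x time
    fs: float
    variance_fraction: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_generators(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.timecourses

    def subset(self, idx) -> "GeneratorSet":
        idx = np.asarray(idx)
        return GeneratorSet(
            mixing=self.mixing[:, idx],
            timecourses=self.timecourses[idx],
            fs=self.fs,
            variance_fraction=self.variance_fraction[idx],
            labels=[self.labels[i] for i in idx] if self.labels else [],
        )


@dataclass
class ProfileMatch:
    pairs: list[tuple[int, int, float]]   # (index in A, index in B, distance)
    unmatched_a: list[int]
    unmatched_b: list[int]
    linkage_tree: np.ndarray | None = None
    threshold: float = 0.2


@dataclass
class PCAReduction:
    scores: np.ndarray            # components x time
    components: np.ndarray        # components x channels (back-projection rows)
    mean: np.ndarray              # per-channel mean
    explained_variance_ratio: np.ndarray

    def back_project(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else scores
        return self.components.T @ s + self.mean[:, None]


@dataclass
class EpochStability:
    length_s: float               # minimal stable epoch length (NaN if none)
    converged: bool
    lengths_s: np.ndarray
    cc: np.ndarray


# ---------------------------------------------------------------------------
# PCA pre-reduction

def pca_reduce(data: np.ndarray, retain: int | float) -> PCAReduction:
    """PCA dimension reduction of a channels x time matrix.

    ``retain`` is a component count (int) or a variance share in (0, 1).
    """
    data = np.asarray(data, float)
    n_ch = data.shape[0]
    if isinstance(retain, (int, np.integer)):
        if retain > n_ch:
            raise ValueError(f"retain={retain} exceeds channel count {n_ch}")
        rank = np.linalg.matrix_rank(data - data.mean(axis=1, keepdims=True))
        if retain > rank:
            raise ValueError(f"retain={retain} exceeds data rank {rank}")
        n_comp = int(retain)
    else:
        if not 0 < retain < 1:
            raise ValueError("variance share must be in (0, 1)")
        n_comp = retain
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(data.T)        # time x components
    return PCAReduction(
        scores=scores.T,
        components=pca.components_,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# ICA estimator

def _nongaussianity(S: np.ndarray) -> float:
    """Summed logcosh negentropy proxy over components (columns of S)."""
    gauss = 0.3745672075  # E[log cosh(Z)], Z standard normal
    Sn = (S - S.mean(axis=0)) / S.std(axis=0)
    return float(np.sum((np.mean(np.log(np.cosh(Sn)), axis=0) - gauss) ** 2))


class LaminarICA(BaseEstimator, TransformerMixin):
    """ICA decomposition of laminar field potentials into FP generators.

    Parameters
    ----------
    n_components : int or None
        Number of generators to extract (None: all channels/PCA dims).
    n_restarts : int
        FastICA restarts with distinct seeds; the run with the largest
        summed non-Gaussianity wins.
    fun : str
        FastICA contrast ("logcosh" approximates negentropy).
    random_state : int or None
        Seed for the restart sequence (fixed seed => deterministic output).

    Attributes
    ----------
    mixing_ : ndarray, (n_channels, n_components)
        Canonical depth profiles (unit norm, peak loading positive).
    sources_ : ndarray, (n_samples, n_components)
        Generator time courses of the training data, amplitude-bearing.
    variance_fraction_ : ndarray
        Share of total data variance reconstructed by each generator.
    restart_log_ : list of dict
        Per-restart convergence flag, iteration count and contrast value.
    """

    def __init__(self, n_components=None, n_restarts=5, fun="logcosh",
                 max_iter=1000, tol=1e-4, random_state=None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.fun = fun
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (time x channels)")
        n_samples, n_ch = X.shape
        k = self.n_components or n_ch
        if n_samples < 50 * k:
            raise ValueError(
                f"{n_samples} samples < 50x {k} components: too short for ICA"
            )
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(self.n_restarts)
        best = None
        log = []
        for seed in seeds:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                ica = FastICA(
                    n_components=k, fun=self.fun, max_iter=self.max_iter,
                    tol=self.tol, whiten="unit-variance",
                    random_state=int(seed % (2**31)),
                )
                S = ica.fit_transform(X)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            score = _nongaussianity(S)
            log.append(dict(seed=int(seed), converged=converged,
                            n_iter=int(ica.n_iter_), score=score))
            if converged and (best is None or score > best[0]):
                best = (score, ica, S)
        self.restart_log_ = log
        if best is None:
            raise RuntimeError(
                f"FastICA failed to converge in {self.n_restarts} restarts: {log}"
            )
        _, ica, S = best
        mixing = ica.mixing_.copy()            # channels x components
        sources = S.T.copy()                   # components x time

        # warn when >= 2 near-Gaussian components make the rotation arbitrary
        kurt = spstats.kurtosis(sources, axis=1)
        if int(np.sum(np.abs(kurt) < 0.1)) >= 2:
            warnings.warn(
                "two or more near-Gaussian sources: ICA rotation is not "
                "identifiable for them"
            )

        # canonicalize: unit-norm profile, peak loading positive
        norms = np.linalg.norm(mixing, axis=0)
        norms[norms == 0] = 1.0
        mixing /= norms
        sources *= norms[:, None]
        signs = np.sign(mixing[np.argmax(np.abs(mixing), axis=0),
                               np.arange(mixing.shape[1])])
        signs[signs == 0] = 1.0
        mixing *= signs
        sources *= signs[:, None]

        # order by variance fraction (reconstruction variance / data variance)
        total_var = np.var(X, axis=0).sum()
        frac = np.array([
            np.var(np.outer(mixing[:, n], sources[n]), axis=1).sum() / total_var
            for n in range(mixing.shape[1])
        ])
        order = np.argsort(frac)[::-1]
        self.mixing_ = mixing[:, order]
        self.sources_ = sources[order].T
        self.variance_fraction_ = frac[order]
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = n_ch
        return self

    def transform(self, X):
        """Project new data onto the fitted generators (least squares)."""
        check_is_fitted(self, "mixing_")
        X = np.asarray(X, float)
        coef, *_ = np.linalg.lstsq(self.mixing_, (X - self.mean_).T, rcond=None)
        return coef.T

    def to_generator_set(self, fs: float, labels=None) -> GeneratorSet:
        check_is_fitted(self, "mixing_")
        return GeneratorSet(
            mixing=self.mixing_.copy(),
            timecourses=self.sources_.T.copy(),
            fs=fs,
            variance_fraction=self.variance_fraction_.copy(),
            labels=list(labels) if labels else [],
        )


def run_ica(
    data: Recording | BilateralRecording | np.ndarray,
    n_components: int,
    mode: str = "per-shank",
    seed: int | None = None,
    fs: float | None = None,
    **kwargs,
) -> GeneratorSet:
    """Decompose a recording into FP generators (wrapper over LaminarICA).

    ``mode="joint-bilateral"`` stacks left and right channels into one data
    matrix so homologous generators come out with a single time course.
    """
    if isinstance(data, BilateralRecording):
        if mode != "joint-bilateral":
            raise ValueError("pass one Recording for per-shank mode")
        samples = np.vstack([data.left.samples, data.right.samples])
        fs = data.fs
    elif isinstance(data, Recording):
        samples = data.samples
        fs = data.fs
    else:
        samples = np.asarray(data, float)
        if fs is None:
            raise ValueError("fs is required for array input")
    est = LaminarICA(n_components=n_components, random_state=seed, **kwargs)
    est.fit(samples.T)
    return est.to_generator_set(fs=fs)


# ---------------------------------------------------------------------------
# relative-variance filtering

def relative_variance_filter(
    gs: GeneratorSet,
    data: np.ndarray | Recording,
    min_fraction: float = 0.01,
) -> GeneratorSet:
    """Drop generators whose reconstruction carries < ``min_fraction`` of the
    total data variance (default 1%).  Fractions are recomputed against the
    supplied data."""
    samples = data.samples if isinstance(data, Recording) else np.asarray(data)
    total_var = np.var(samples, axis=1).sum()
    frac = np.array([
        np.var(np.outer(gs.mixing[:, n], gs.timecourses[n]), axis=1).sum()
        / total_var
        for n in range(gs.n_generators)
    ])
    gs = GeneratorSet(
        mixing=gs.mixing, timecourses=gs.timecourses, fs=gs.fs,
        variance_fraction=frac, labels=gs.labels,
    )
    keep = np.flatnonzero(frac >= min_fraction)
    return gs.subset(keep)


# ---------------------------------------------------------------------------
# profile matching

def profile_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two depth profiles; cosine similarity when one profile
    is channel-constant (a volume-conducted source), where centred
    correlation is undefined."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def _near_constant(v: np.ndarray) -> bool:
        # centred correlation of an almost-flat profile is dominated by its
        # residual ripple; fall back to cosine when the spread is small
        # relative to the mean loading
        return np.std(v) < 0.2 * abs(np.mean(v))

    if _near_constant(a) or _near_constant(b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b / (na * nb))
    return float(np.corrcoef(a, b)[0, 1])


def profile_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation distance 1 - r between two depth profiles (in [0, 2])."""
    return 1.0 - profile_similarity(a, b)


def match_profiles(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    threshold: float = 0.2,
) -> ProfileMatch:
    """Match two sets of depth profiles by correlation distance.

    One-to-one assignment minimizing total distance; pairs accepted when
    distance < ``threshold`` (population clustering groups homologous
    profiles below 0.2).  An average-linkage tree over the pooled profiles
    is returned for inspection.
    """
    A = np.asarray(profiles_a, float)
    B = np.asarray(profiles_b, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("profile sets must share the channel count")
    na, nb = A.shape[1], B.shape[1]
    D = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            D[i, j] = profile_distance(A[:, i], B[:, j])
    row, col = linear_sum_assignment(D)
    pairs = [(int(i), int(j), float(D[i, j]))
             for i, j in zip(row, col) if D[i, j] < threshold]
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    tree = None
    if na + nb > 1:
        pooled = np.hstack([A, B])
        ntot = na + nb
        condensed = [
            profile_distance(pooled[:, i], pooled[:, j])
            for i in range(ntot) for j in range(i + 1, ntot)
        ]
        tree = linkage(np.asarray(condensed), method="average")
    return ProfileMatch(
        pairs=sorted(pairs, key=lambda p: p[2]),
        unmatched_a=[i for i in range(na) if i not in matched_a],
        unmatched_b=[j for j in range(nb) if j not in matched_b],
        linkage_tree=tree,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# epoch-length stability

def epoch_stability_length(
    left_tc: np.ndarray,
    right_tc: np.ndarray,
    fs: float,
    step: float = 5.0,
    tol: float = 0.03,
    max_len: float | None = None,
) -> EpochStability:
    """Minimal epoch length at which the bilateral CC stabilizes.

    Epochs grow from the start of the record in ``step`` increments; the
    returned length T is the smallest one from which every longer epoch's CC
    stays within ``tol`` of the running mean of the CCs of shorter epochs.
    """
    x = np.asarray(left_tc, float)
    y = np.asarray(right_tc, float)
    if x.shape != y.shape:
        raise ValueError("time courses must have equal length")
    total_s = x.size / fs
    if max_len is None:
        max_len = total_s
    if max_len > total_s:
        raise ValueError("max_len exceeds the record duration")
    lengths = np.arange(step, max_len + 1e-9, step)
    cc = np.array([
        np.corrcoef(x[: int(L * fs)], y[: int(L * fs)])[0, 1] for L in lengths
    ])
    # deviation of each CC from the running mean of the shorter epochs
    ok = np.zeros(len(lengths), bool)
    for j in range(1, len(lengths)):
        m = cc[:j].mean()
        ok[j] = abs(cc[j] - m) <= tol * abs(m)
    stable_from = None
    for i in range(1, len(lengths)):
        if ok[i:].all():
            stable_from = i
            break
    if stable_from is None:
        return EpochStability(float("nan"), False, lengths, cc)
    # stability holding from the second epoch on means the first was
    # already stable
    T = lengths[0] if stable_from == 1 else lengths[stable_from]
    return EpochStability(float(T), True, lengths, cc)


# ---------------------------------------------------------------------------
# serialization

def save_generator_set(gs: GeneratorSet, path) -> None:
    """Write a GeneratorSet to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("mixing", data=gs.mixing)
        f.create_dataset("timecourses", data=gs.timecourses)
        f.create_dataset("variance_fraction", data=gs.variance_fraction)
        f.attrs["fs"] = gs.fs
        if gs.labels:
            f.attrs["labels"] = [str(x) for x in gs.labels]


def load_generator_set(path) -> GeneratorSet:
    import h5py

    with h5py.File(path, "r") as f:
        labels = [
            x.decode() if isinstance(x, bytes) else str(x)
            for x in f.attrs.get("labels", [])
        ]
        return GeneratorSet(
            mixing=f["mixing"][()],
            timecourses=f["timecourses"][()],
            fs=float(f.attrs["fs"]),
            variance_fraction=f["variance_fraction"][()],
            labels=labels,
        )
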