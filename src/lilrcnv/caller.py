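"""Joint integer copy-number genotyping on the LILRB3/LILRA6 lattice.

The geometry of the problem fixes the cluster centers analytically: a
genotype with ``b3`` copies of LILRB3 and ``a6`` of LILRA6 has expected
normalized CNs (b3, a6, b3 + a6). Joint calling therefore fits only the
dispersion around those centers and the mixture weights -- a Gaussian
mixture with *fixed* means on the candidate lattice, per-dimension variance

    sigma^2(mu) = sigma0^2 + k * mu

(read-depth noise grows with copy number), estimated by iterative
responsibility-weighted fitting over the query plus a background cohort.
Calling uses the three-vector (cn_b3core, cn_a6core, cn_sum), never the
unstable core ratio.

Haplotype copy-number types (h_b3, h_a6) and their population frequencies
are estimated by an expectation-maximization over diplotypes under
Hardy-Weinberg, and a diploid genotype is decomposed into ranked haplotype
pairs with probability proportional to f(h1) f(h2) (x2 when h1 != h2).

Both fitted objects follow the scikit-learn estimator contract
(``fit`` / ``predict`` / ``get_params``; fitted attributes end in ``_``),
so they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .depth import ClusterPoint, NormalizedCN, cluster_coordinates
from .errors import LilrError

__all__ = [
    "HaplotypeCNType",
    "CNGenotype",
    "Diplotype",
    "lattice_expected",
    "LatticeMixtureCaller",
    "HaplotypeFrequencyEM",
    "default_hap_freqs",
    "hap_space",
    "decompose_diplotype",
    "fit_joint_model",
    "call_genotype",
    "estimate_hap_freqs",
]

#: candidate diploid lattice; LILRA6 reaches 0-6 copies in most cohorts with
#: a known 7-copy individual, LILRB3 rarely exceeds 4.
B3_MAX, A6_MAX = 5, 7
#: default haploid CN-type space.
HAP_B3_MAX, HAP_A6_MAX = 2, 4
FREQ_FLOOR = 1e-4


@dataclass(frozen=True, order=True)
class HaplotypeCNType:
    """Copies of LILRB3 and LILRA6 carried on one haplotype.

    (0, 0) is the hybrid haplotype: the large deletion removes both genes
    from the chromosome, leaving the LILRB5-3 fusion.
    """

    h_b3: int
    h_a6: int

    def __post_init__(self) -> None:
        if self.h_b3 < 0 or self.h_a6 < 0:
            raise ValueError(f"negative haplotype CN: {self}")

    @property
    def label(self) -> str:
        return f"B3:{self.h_b3}-A6:{self.h_a6}"


@dataclass(frozen=True)
class CNGenotype:
    cn_b3: int
    cn_a6: int
    posterior: float = 1.0

    def __post_init__(self) -> None:
        if self.cn_b3 < 0 or self.cn_a6 < 0:
            raise ValueError(f"negative CN genotype: {self}")


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotype CN types summing to a diploid genotype."""

    h1: HaplotypeCNType
    h2: HaplotypeCNType
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.h2 < self.h1:
            lo, hi = self.h2, self.h1
            object.__setattr__(self, "h1", lo)
            object.__setattr__(self, "h2", hi)

    @property
    def label(self) -> str:
        return f"{self.h1.label}/{self.h2.label}"

    def genotype(self) -> Tuple[int, int]:
        return (self.h1.h_b3 + self.h2.h_b3, self.h1.h_a6 + self.h2.h_a6)


def lattice_expected(b3: int, a6: int) -> NormalizedCN:
    """Expected normalized CN triple for an integer (b3, a6) genotype."""
    if b3 < 0 or a6 < 0:
        raise LilrError(f"negative copy number: ({b3}, {a6})")
    if b3 > B3_MAX or a6 > A6_MAX:
        raise LilrError(
            f"genotype ({b3}, {a6}) outside candidate lattice "
            f"b3<= {B3_MAX}, a6 <= {A6_MAX}"
        )
    return NormalizedCN(cn_b3core=float(b3), cn_a6core=float(a6), cn_sum=float(b3 + a6))


def lattice_point(b3: int, a6: int, zero_threshold: float = 0.3) -> ClusterPoint:
    """Cluster-plot coordinates of a lattice genotype."""
    return cluster_coordinates(lattice_expected(b3, a6), zero_threshold=zero_threshold)


def hap_space(b3_max: int = HAP_B3_MAX, a6_max: int = HAP_A6_MAX) -> List[HaplotypeCNType]:
    return [
        HaplotypeCNType(b, a) for b in range(b3_max + 1) for a in range(a6_max + 1)
    ]


def default_hap_freqs(
    space: Optional[Sequence[HaplotypeCNType]] = None,
    floor: float = FREQ_FLOOR,
) -> Dict[HaplotypeCNType, float]:
    """Default haplotype prior: (1,1) modal, the hybrid haplotype rare.

    Used for worked examples and as a fallback when no cohort is available
    to estimate frequencies from.
    """
    space = list(space) if space is not None else hap_space()
    named = {
        HaplotypeCNType(1, 1): 0.55,
        HaplotypeCNType(1, 2): 0.20,
        HaplotypeCNType(1, 0): 0.15,
        HaplotypeCNType(1, 3): 0.05,
        HaplotypeCNType(0, 0): 0.01,
    }
    freqs = {h: named.get(h, floor) for h in space}
    total = sum(freqs.values())
    return {h: f / total for h, f in freqs.items()}


def _as_matrix(observations) -> np.ndarray:
    if isinstance(observations, np.ndarray):
        return check_array(observations, ensure_min_features=3)
    rows = []
    for obs in observations:
        rows.append(obs.as_array() if isinstance(obs, NormalizedCN) else np.asarray(obs))
    return check_array(np.vstack(rows), ensure_min_features=3)


class LatticeMixtureCaller(BaseEstimator):
    """Gaussian mixture with means fixed on the (b3, a6) genotype lattice.

    Parameters
    ----------
    b3_max, a6_max : int
        Lattice bounds for the candidate genotypes.
    var_floor : float
        Floor on the baseline variance sigma0^2; on noise-free data the
        fitted sigma0^2 collapses to this floor.
    max_iter, tol : EM iteration control (tol on the mean log-likelihood).
    zero_threshold : passed through when plotting coordinates are requested.

    Fitted attributes
    -----------------
    genotypes_ : (C, 2) int array of lattice genotypes, ordered by
        (b3 + a6, b3, a6) so that exact posterior ties resolve toward the
        smaller total CN, then the smaller b3.
    means_ : (C, 3) expected normalized-CN triples.
    weights_ : (C,) mixture weights (first pass uniform, then empirical).
    sigma0_sq_, k_ : (3,) per-dimension variance model
        sigma_d^2(mu) = sigma0_sq_[d] + k_[d] mu.
    loglik_path_ : per-iteration mean log-likelihood (non-decreasing up to
        the variance-model projection).
    """

    def __init__(
        self,
        b3_max: int = B3_MAX,
        a6_max: int = A6_MAX,
        var_floor: float = 1e-6,
        max_iter: int = 100,
        tol: float = 1e-10,
        zero_threshold: float = 0.3,
    ):
        self.b3_max = b3_max
        self.a6_max = a6_max
        self.var_floor = var_floor
        self.max_iter = max_iter
        self.tol = tol
        self.zero_threshold = zero_threshold

    # -- model internals -------------------------------------------------
    def _log_pdf(self, X: np.ndarray, sigma0_sq: float, k: float) -> np.ndarray:
        """(n, C) per-component log density under the diagonal model."""
        var = np.maximum(sigma0_sq + k * self.means_, self.var_floor)  # (C, 3)
        diff = X[:, None, :] - self.means_[None, :, :]
        return -0.5 * np.sum(diff**2 / var + np.log(2 * np.pi * var), axis=2)

    def fit(self, X, y=None) -> "LatticeMixtureCaller":
        X = _as_matrix(X)
        n = X.shape[0]
        if n < 20:
            raise LilrError(
                f"joint fitting needs >= 20 observations, got {n}; "
                "include a background cohort (e.g. a simulated or reference panel)"
            )
        gts = [
            (b, a)
            for b in range(self.b3_max + 1)
            for a in range(self.a6_max + 1)
        ]
        gts.sort(key=lambda g: (g[0] + g[1], g[0], g[1]))
        self.genotypes_ = np.array(gts)
        self.means_ = np.column_stack(
            [self.genotypes_[:, 0], self.genotypes_[:, 1], self.genotypes_[:, 0] + self.genotypes_[:, 1]]
        ).astype(float)
        C = len(gts)

        sigma0_sq = np.full(3, max(0.01, self.var_floor))
        k = np.zeros(3)
        # two-pass prior over the lattice: uniform first, then empirical
        weights = np.full(C, 1.0 / C)
        self.loglik_path_ = []
        prev_ll = -np.inf
        for it in range(self.max_iter):
            log_prob = self._log_pdf(X, sigma0_sq, k) + np.log(np.maximum(weights, 1e-300))
            norm = logsumexp(log_prob, axis=1)
            resp = np.exp(log_prob - norm[:, None])  # (n, C)
            ll = float(np.mean(norm))
            self.loglik_path_.append(ll)

            weights = resp.sum(axis=0) / n
            # per-dimension responsibility-weighted regression of squared
            # residuals on the component mean: E[(x_d - mu_cd)^2] =
            # sigma0_d^2 + k_d mu_cd
            sigma0_new = np.empty(3)
            k_new = np.empty(3)
            sw = resp.sum()
            for d in range(3):
                w = resp  # (n, C)
                mu = self.means_[None, :, d]
                e2 = (X[:, d][:, None] - self.means_[None, :, d]) ** 2
                m_mu = (w * mu).sum() / sw
                m_e2 = (w * e2).sum() / sw
                cov = (w * (mu - m_mu) * (e2 - m_e2)).sum()
                var_mu = (w * (mu - m_mu) ** 2).sum()
                k_new[d] = max(0.0, cov / var_mu) if var_mu > 0 else 0.0
                raw_sigma0 = m_e2 - k_new[d] * m_mu
                if raw_sigma0 >= self.var_floor:
                    sigma0_new[d] = raw_sigma0
                else:
                    # intercept pinned at the floor: refit the slope by
                    # constrained least squares through (0, floor)
                    sigma0_new[d] = self.var_floor
                    num = (w * mu * (e2 - self.var_floor)).sum()
                    den = (w * mu**2).sum()
                    k_new[d] = max(0.0, num / den) if den > 0 else 0.0
            sigma0_sq, k = sigma0_new, k_new

            if it > 0 and abs(ll - prev_ll) < self.tol:
                break
            prev_ll = ll
        self.sigma0_sq_ = sigma0_sq
        self.k_ = k
        self.weights_ = weights
        self.n_iter_ = len(self.loglik_path_)
        return self

    def component_variances(self) -> np.ndarray:
        check_is_fitted(self, "means_")
        return np.maximum(self.sigma0_sq_ + self.k_ * self.means_, self.var_floor)

    def predict_log_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = _as_matrix(X)
        log_prob = self._log_pdf(X, self.sigma0_sq_, self.k_) + np.log(
            np.maximum(self.weights_, 1e-300)
        )
        return log_prob - logsumexp(log_prob, axis=1)[:, None]

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        """(n, 2) integer MAP genotypes; ties resolve via component order."""
        post = self.predict_log_proba(X)
        return self.genotypes_[np.argmax(post, axis=1)]

    def predict_genotypes(self, X) -> List[CNGenotype]:
        post = self.predict_proba(X)
        idx = np.argmax(post, axis=1)
        return [
            CNGenotype(int(self.genotypes_[i, 0]), int(self.genotypes_[i, 1]), float(post[j, i]))
            for j, i in enumerate(idx)
        ]

    def observation_loglik(self, x: np.ndarray, genotype: Tuple[int, int]) -> float:
        """log P(observation | integer genotype) under the fitted noise model."""
        check_is_fitted(self, "weights_")
        mask = (self.genotypes_[:, 0] == genotype[0]) & (self.genotypes_[:, 1] == genotype[1])
        if not mask.any():
            return -np.inf
        i = int(np.flatnonzero(mask)[0])
        return float(self._log_pdf(np.asarray(x, float)[None, :], self.sigma0_sq_, self.k_)[0, i])


class HaplotypeFrequencyEM(BaseEstimator):
    """Hardy-Weinberg EM for haplotype CN-type frequencies.

    Fit on integer diploid genotypes; each genotype's likelihood sums over
    the diplotypes consistent with it. The log-likelihood is non-decreasing
    every iteration (recorded in ``loglik_path_``); convergence at
    delta-loglik < `tol`. Frequencies are floored at `floor` and
    renormalized after convergence.
    """

    def __init__(
        self,
        b3_max: int = HAP_B3_MAX,
        a6_max: int = HAP_A6_MAX,
        floor: float = FREQ_FLOOR,
        tol: float = 1e-8,
        max_iter: int = 2000,
    ):
        self.b3_max = b3_max
        self.a6_max = a6_max
        self.floor = floor
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, genotypes, y=None) -> "HaplotypeFrequencyEM":
        gts = [
            (g.cn_b3, g.cn_a6) if isinstance(g, CNGenotype) else (int(g[0]), int(g[1]))
            for g in genotypes
        ]
        if not gts:
            raise LilrError("empty cohort")
        space = hap_space(self.b3_max, self.a6_max)
        index = {h: i for i, h in enumerate(space)}
        H = len(space)
        # precompute consistent ordered pairs per distinct genotype
        pair_cache: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
        for g in set(gts):
            pairs = []
            for h1 in space:
                b2, a2 = g[0] - h1.h_b3, g[1] - h1.h_a6
                if 0 <= b2 <= self.b3_max and 0 <= a2 <= self.a6_max:
                    pairs.append((index[h1], index[HaplotypeCNType(b2, a2)]))
            if not pairs:
                raise LilrError(
                    f"genotype {g} has no diplotype in the haplotype space "
                    f"(b3 <= {self.b3_max}, a6 <= {self.a6_max})"
                )
            pair_cache[g] = pairs

        def run_em(f0: np.ndarray) -> Tuple[np.ndarray, List[float]]:
            f = f0 / f0.sum()
            path: List[float] = []
            prev_ll = -np.inf
            for _ in range(self.max_iter):
                counts = np.zeros(H)
                ll = 0.0
                for g in gts:
                    pairs = pair_cache[g]
                    probs = np.array([f[i] * f[j] for i, j in pairs])
                    tot = probs.sum()
                    if tot <= 0:
                        tot = 1e-300
                    ll += float(np.log(tot))
                    probs /= tot
                    for (i, j), p in zip(pairs, probs):
                        counts[i] += p
                        counts[j] += p
                path.append(ll)
                f = counts / (2 * len(gts))
                if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                    break
                prev_ll = ll
            return f, path

        # the EM surface has symmetric local optima (several diplotype
        # splittings can explain the same genotype spectrum), so run a small
        # deterministic multi-start and keep the best likelihood
        inits = []
        halved = np.full(H, 0.5)
        skewed = np.full(H, 0.5)
        for g in gts:
            h1 = HaplotypeCNType((g[0] + 1) // 2, (g[1] + 1) // 2)
            h2 = HaplotypeCNType(g[0] - h1.h_b3, g[1] - h1.h_a6)
            if h1 in index and h2 in index:
                halved[index[h1]] += 1
                halved[index[h2]] += 1
            s1 = HaplotypeCNType((g[0] + 1) // 2, min(g[1], self.a6_max))
            s2 = HaplotypeCNType(g[0] - s1.h_b3, g[1] - s1.h_a6)
            if s2.h_a6 >= 0 and s1 in index and s2 in index:
                skewed[index[s1]] += 1
                skewed[index[s2]] += 1
        inits = [halved, skewed, np.linspace(1.0, 2.0, H)]
        best_f, best_path = None, None
        for f0 in inits:
            f, path = run_em(f0)
            if best_path is None or path[-1] > best_path[-1]:
                best_f, best_path = f, path
        f = np.maximum(best_f, self.floor)
        f /= f.sum()
        self.freqs_ = {h: float(f[index[h]]) for h in space}
        self.loglik_path_ = best_path
        self.loglik_ = best_path[-1]
        self.n_iter_ = len(best_path)
        return self

    def predict_proba(self, genotypes) -> List[List[Diplotype]]:
        check_is_fitted(self, "freqs_")
        return [decompose_diplotype(g, self.freqs_) for g in genotypes]


def decompose_diplotype(
    g, freqs: Dict[HaplotypeCNType, float]
) -> List[Diplotype]:
    """All haplotype pairs consistent with genotype `g`, ranked.

    Probability is proportional to f(h1) f(h2) (x2 for heterozygous pairs,
    the Hardy-Weinberg weight), normalized over the returned list. An empty
    list (plus a warning) means the genotype lies outside the span of the
    haplotype space.
    """
    if isinstance(g, CNGenotype):
        target = (g.cn_b3, g.cn_a6)
    else:
        target = (int(g[0]), int(g[1]))
    seen = set()
    raw: List[Tuple[HaplotypeCNType, HaplotypeCNType, float]] = []
    for h1, f1 in freqs.items():
        h2 = HaplotypeCNType(target[0] - h1.h_b3, target[1] - h1.h_a6) if (
            target[0] - h1.h_b3 >= 0 and target[1] - h1.h_a6 >= 0
        ) else None
        if h2 is None or h2 not in freqs:
            continue
        key = tuple(sorted([h1, h2]))
        if key in seen:
            continue
        seen.add(key)
        f2 = freqs[h2]
        w = f1 * f2 * (2.0 if h1 != h2 else 1.0)
        raw.append((key[0], key[1], w))
    if not raw:
        warnings.warn(f"genotype {target} outside the haplotype-space span")
        return []
    total = sum(w for *_, w in raw)
    out = [Diplotype(h1, h2, w / total) for h1, h2, w in raw]
    out.sort(key=lambda d: (-d.probability, d.label))
    return out


# -- thin functional wrappers over the estimators ------------------------

def fit_joint_model(observations, **params) -> LatticeMixtureCaller:
    """Fit the lattice mixture on query + background observations."""
    return LatticeMixtureCaller(**params).fit(_as_matrix(observations))


def call_genotype(obs, model: LatticeMixtureCaller) -> CNGenotype:
    """MAP integer (b3, a6) genotype with posterior for one observation."""
    X = _as_matrix([obs])
    return model.predict_genotypes(X)[0]


def estimate_hap_freqs(genotypes, **params) -> Dict[HaplotypeCNType, float]:
    """Hardy-Weinberg EM haplotype frequencies for a cohort of >= 50 calls."""
    gts = list(genotypes)
    if len(gts) < 50:
        raise LilrError(f"frequency estimation needs >= 50 genotypes, got {len(gts)}")
    return HaplotypeFrequencyEM(**params).fit(gts).freqs_
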