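"""PCA of a genome-wide marker panel and selection of the number of PCs.

Dosages are standardized marker-by-marker (center at 2*p_hat, scale by
sqrt(2*p_hat*(1-p_hat)), the usual eigenanalysis normalization for genotype
data) and the spectrum of the individual-by-individual covariance is
computed through the smaller Gram matrix. Three selectors for the number of
informative PCs are provided:

* ``select_elbow`` — profile-likelihood change-point on the scree
  (two Gaussian groups with common variance);
* ``select_lowrank`` — singular-value hard threshold at the
  Marchenko-Pastur bulk edge, noise calibrated from the median singular
  value (optimal hard threshold for a low-rank-plus-noise matrix);
* ``select_tracywidom`` — sequential Tracy-Widom tests of the leading
  eigenvalue with effective-dimension moment matching.

For a population with K+1 well-separated strata, K PCs separate the strata
and the remaining spectrum behaves like an unstructured noise bulk.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, linalg, optimize


@dataclass
class MarkerPanel:
    """Genotype dosages (individuals x markers, values 0/1/2) for PCA."""

    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if d.size and not np.all(np.isin(np.unique(d), (0, 1, 2))):
            raise ValueError("dosages must be in {0, 1, 2}")
        self.dosages = d.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def m_markers(self) -> int:
        return int(self.dosages.shape[1])

    @property
    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per marker."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class PCResult:
    """Eigenvalues (descending) and the leading PC scores of a marker panel.

    ``eigenvalues`` are those of the individual-by-individual covariance
    X X'/m of the standardized dosage matrix X; under pure noise their bulk
    follows Marchenko-Pastur with upper edge (1 + sqrt(n/m))^2.
    """

    eigenvalues: np.ndarray
    scores: np.ndarray
    n: int
    m: int
    selected_k: int | None = None

    @property
    def singular_values(self) -> np.ndarray:
        """Singular values of the standardized matrix itself."""
        return np.sqrt(np.maximum(self.eigenvalues, 0.0) * self.m)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame(cols)


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Center each marker at 2*p_hat and scale by sqrt(2*p_hat*(1-p_hat));
    monomorphic markers (empirical MAF 0) are dropped."""
    d = np.asarray(dosages, float)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    if not np.any(keep):
        raise ValueError("marker panel is degenerate: all markers monomorphic")
    d = d[:, keep]
    p = p[keep]
    return (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def compute_pcs(panel: MarkerPanel, n_scores: int = 10) -> PCResult:
    """Eigen-decomposition of the standardized-dosage covariance.

    The full spectrum (min(n, m) eigenvalues of X X'/m) is returned together
    with the leading ``n_scores`` score columns (projections of individuals,
    mutually orthogonal).
    """
    if panel.n_individuals < 2 or panel.m_markers < 2:
        raise ValueError("need at least 2 individuals and 2 markers")
    X = standardize_dosages(panel.dosages)
    n, m = X.shape
    n_scores = min(n_scores, n - 1, m)
    if m <= n:
        G = X.T @ X                      # m x m
        evals, evecs = linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        V = evecs[:, order[:n_scores]]
        scores = X @ V                   # columns have norm sqrt(eval)
    else:
        G = X @ X.T                      # n x n
        evals, evecs = linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        scores = evecs[:, order[:n_scores]] * np.sqrt(evals[:n_scores])
    if not np.any(evals > 0.0):
        raise ValueError("marker panel has rank 0 after standardization")
    return PCResult(eigenvalues=evals / m, scores=scores, n=n, m=m)


# ---------------------------------------------------------------------------
# selector 1: profile-likelihood elbow
# ---------------------------------------------------------------------------


def select_elbow(eigenvalues: np.ndarray) -> int:
    """Automated scree-plot elbow via the profile-likelihood change point.

    For each candidate split q, the eigenvalues are modelled as two Gaussian
    groups with separate means and a common variance; the q maximizing the
    profile log-likelihood is returned (at least 1).
    """
    ev = _spectrum(eigenvalues)
    p = ev.shape[0]
    if p < 3:
        raise ValueError("elbow selection needs at least 3 eigenvalues")
    best_q, best_ll = 1, -np.inf
    for q in range(1, p):
        g1, g2 = ev[:q], ev[q:]
        ss = float(np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2))
        sigma2 = max(ss / p, 1e-300)
        ll = -0.5 * p * (np.log(2.0 * np.pi * sigma2) + 1.0)
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q


# ---------------------------------------------------------------------------
# selector 2: low-rank (optimal singular-value hard threshold)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _mp_median(beta: float) -> float:
    """Median of the Marchenko-Pastur distribution with aspect ratio beta."""
    lo, hi = (1.0 - np.sqrt(beta)) ** 2, (1.0 + np.sqrt(beta)) ** 2

    def density(x):
        return np.sqrt(np.maximum((hi - x) * (x - lo), 0.0)) / (2.0 * np.pi * beta * x)

    def cdf_minus_half(x):
        val, _ = integrate.quad(density, lo, x, limit=200)
        return val - 0.5

    return float(optimize.brentq(cdf_minus_half, lo + 1e-12, hi - 1e-12, xtol=1e-10))


def _omega(beta: float) -> float:
    lam = np.sqrt(
        2.0 * (beta + 1.0)
        + 8.0 * beta / (beta + 1.0 + np.sqrt(beta**2 + 14.0 * beta + 1.0))
    )
    return float(lam / np.sqrt(_mp_median(round(float(beta), 6))))


def select_lowrank(spectrum, n: int | None = None, m: int | None = None) -> int:
    """Rank of the signal under a low-rank-plus-noise model of the
    standardized dosage matrix.

    Singular values are compared to a hard threshold at the noise bulk edge,
    omega(beta) * median singular value, where beta = min(n,m)/max(n,m) and
    omega is the optimal-threshold coefficient for Marchenko-Pastur noise of
    unknown level. Returns 0 for a pure-noise panel.
    """
    if isinstance(spectrum, PCResult):
        n, m = spectrum.n, spectrum.m
        sv = spectrum.singular_values
    else:
        if n is None or m is None:
            raise ValueError("n and m are required when passing raw singular values")
        sv = np.asarray(spectrum, float)
    sv = np.sort(sv)[::-1]
    beta = min(n, m) / max(n, m)
    tau = _omega(beta) * float(np.median(sv))
    return int(np.sum(sv > tau))


# ---------------------------------------------------------------------------
# selector 3: sequential Tracy-Widom tests
# ---------------------------------------------------------------------------

# Percentage points of the Tracy-Widom(1) distribution: (CDF, quantile).
_TW1_TABLE = np.array(
    [
        (0.01, -3.8954),
        (0.05, -3.1804),
        (0.10, -2.7824),
        (0.30, -1.9104),
        (0.50, -1.2686),
        (0.70, -0.5923),
        (0.90, 0.4501),
        (0.95, 0.9793),
        (0.975, 1.4538),
        (0.99, 2.0234),
        (0.995, 2.4224),
        (0.999, 3.2724),
    ]
)


def tw1_quantile(prob: float) -> float:
    """Interpolated quantile of the Tracy-Widom(1) distribution."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    return float(np.interp(prob, _TW1_TABLE[:, 0], _TW1_TABLE[:, 1]))


def _tw_statistic(tail: np.ndarray) -> float:
    """Moment-matched Tracy-Widom statistic for the leading eigenvalue of the
    remaining spectrum.

    The tail is treated as the spectrum of a p-variate Wishart (p = number
    of remaining eigenvalues, i.e. the smaller of the two matrix dimensions
    after removing earlier components) whose effective sample count and
    noise level are estimated from the spectrum itself by moment matching;
    the leading eigenvalue is then centered and scaled by the
    Johnstone/Tracy-Widom constants for those effective dimensions.
    """
    p = tail.shape[0]
    s1 = float(tail.sum())
    s2 = float((tail**2).sum())
    denom = p * s2 - s1**2
    if denom <= 0.0:
        return -np.inf
    n_eff = p * s1**2 / denom       # effective sample count
    if n_eff <= 1.0:
        return -np.inf
    ell = p * float(tail[0]) / s1   # leading eigenvalue on mean-one scale
    a, b = np.sqrt(n_eff - 1.0), np.sqrt(float(p))
    mu = (a + b) ** 2 / n_eff
    sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
    return (ell - mu) / sigma


def select_tracywidom(
    spectrum, n: int | None = None, m: int | None = None, alpha: float = 0.05
) -> int:
    """Count of leading eigenvalues significant under sequential Tracy-Widom
    tests at level alpha.

    For j = 1, 2, ... the j-th eigenvalue is normalized against the bulk of
    the remaining spectrum (effective dimensions by moment matching) and
    compared to the upper-alpha TW(1) quantile; the count of consecutive
    rejections from the top is returned. Non-increasing as alpha decreases.
    """
    if isinstance(spectrum, PCResult):
        n, m = spectrum.n, spectrum.m
        ev = spectrum.eigenvalues
    else:
        if n is None or m is None:
            raise ValueError("n and m are required when passing raw eigenvalues")
        ev = np.asarray(spectrum, float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ev = np.sort(ev)[::-1]
    ev = ev[ev > 1e-12]
    if min(n, m) < 10:
        import warnings

        warnings.warn(
            "Tracy-Widom normalization is asymptotic; n or m below 10 is unreliable",
            stacklevel=2,
        )
    crit = tw1_quantile(1.0 - alpha)
    k = 0
    for j in range(ev.shape[0] - 2):
        stat = _tw_statistic(ev[j:])
        if stat > crit:
            k += 1
        else:
            break
    return k


_SELECTORS = {
    "lowrank": lambda pcs: select_lowrank(pcs),
    "elbow": lambda pcs: select_elbow(pcs.eigenvalues),
    "tracywidom": lambda pcs: select_tracywidom(pcs),
}


def select_k(pcs: PCResult, method: str = "lowrank", **kwargs) -> int:
    """Dispatch to one of the three PC-number selectors by name."""
    if method not in _SELECTORS:
        raise ValueError(f"unknown selector {method!r}; choose from {sorted(_SELECTORS)}")
    if method == "tracywidom" and "alpha" in kwargs:
        return select_tracywidom(pcs, alpha=kwargs["alpha"])
    return _SELECTORS[method](pcs)


def _spectrum(eigenvalues) -> np.ndarray:
    ev = np.asarray(eigenvalues, float)
    if np.any(np.diff(ev) > 1e-9):
        ev = np.sort(ev)[::-1]
    return ev


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_markers(path) -> MarkerPanel:
    """Read a delimited dosage matrix (individuals x markers, header row of
    marker ids; '#' lines are comments)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return MarkerPanel(df.to_numpy())


def write_markers(path, panel: MarkerPanel, sep: str = "\t",
                  header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        panel.dosages, columns=[f"m{j + 1}" for j in range(panel.m_markers)]
    )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_pcs(path_prefix, pcs: PCResult, sep: str = "\t") -> None:
    """Write eigenvalues and scores as two TSV files with a common prefix."""
    pd.DataFrame({"eigenvalue": pcs.eigenvalues}).to_csv(
        f"{path_prefix}.eigenvalues.tsv", sep=sep, index=False
    )
    pcs.to_frame().to_csv(f"{path_prefix}.scores.tsv", sep=sep, index=False)
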