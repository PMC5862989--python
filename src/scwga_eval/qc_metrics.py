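"""Reproducibility, uniformity and cross-platform consistency metrics.

* Reproducibility: Pearson correlation of NDR profiles over shared
  autosomal windows, for every pair of samples.
* Uniformity: the coefficient of variation (CV) of NDR — population
  sd/mean across windows; compared against the CV of a normalised Poisson
  reference (draws from Poisson(λ) divided by λ), whose CV is 1/√λ.
* Cross-platform consistency: R² of an ordinary least-squares regression
  of one platform's NDR on the other's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .count_profile import NDRProfile

__all__ = [
    "ReproducibilityMatrix", "UniformityResult", "PoissonReference",
    "pearson_matrix", "cv_uniformity", "poisson_reference", "cross_platform_r2",
]


@dataclass
class ReproducibilityMatrix:
    sample_ids: list[str]
    matrix: np.ndarray          # symmetric, unit diagonal; NaN = undefined
    undefined: np.ndarray       # bool mask of flagged (zero-variance) pairs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.sample_ids):
            for j, b in enumerate(self.sample_ids):
                if j > i:
                    rows.append((a, b, self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])

    def mean_offdiagonal(self) -> float:
        n = len(self.sample_ids)
        iu = np.triu_indices(n, k=1)
        vals = self.matrix[iu]
        return float(np.nanmean(vals)) if len(vals) else float("nan")


@dataclass
class UniformityResult:
    cv: float
    n_windows: int
    corrected: bool = False
    sample_id: str = ""


@dataclass
class PoissonReference:
    """Normalised Poisson(λ)/λ depth reference."""

    sample: np.ndarray
    lam: float
    n_dots: int
    seed: int

    @property
    def cv(self) -> float:
        return float(self.sample.std() / self.sample.mean())


def _shared_autosomal(profiles: Sequence[NDRProfile]) -> np.ndarray:
    w0 = profiles[0].windows
    for p in profiles[1:]:
        w = p.windows
        if w is not w0:
            same = (w.n_windows == w0.n_windows
                    and np.array_equal(w.start, w0.start)
                    and np.array_equal(w.chrom, w0.chrom))
            if not same:
                raise ValueError("profiles are on mismatched window sets")
    return profiles[0].autosomal_usable


def pearson_matrix(profiles: Sequence[NDRProfile]) -> ReproducibilityMatrix:
    """Pairwise Pearson r of NDR over shared usable autosomal windows.

    A pair where either profile has zero variance gets a NaN entry and is
    flagged.  The matrix is symmetric with unit diagonal and is invariant
    (equivariant) under sample reordering.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    mask = _shared_autosomal(profiles)
    data = np.vstack([p.ndr[mask] for p in profiles])
    n = len(profiles)
    mat = np.eye(n)
    undef = np.zeros((n, n), dtype=bool)
    sd = data.std(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                mat[i, j] = mat[j, i] = np.nan
                undef[i, j] = undef[j, i] = True
                continue
            r = float(np.corrcoef(data[i], data[j])[0, 1])
            mat[i, j] = mat[j, i] = r
    ids = [p.sample_id or f"sample{k}" for k, p in enumerate(profiles)]
    return ReproducibilityMatrix(sample_ids=ids, matrix=mat, undefined=undef)


def cv_uniformity(profile: NDRProfile, corrected: bool = False) -> UniformityResult:
    """CV = population sd / mean of NDR over usable autosomal windows."""
    vals = profile.ndr[profile.autosomal_usable]
    if len(vals) < 2:
        raise ValueError("need at least 2 windows")
    cv = float(vals.std(ddof=0) / vals.mean())
    return UniformityResult(cv=cv, n_windows=len(vals), corrected=corrected,
                            sample_id=profile.sample_id)


def poisson_reference(lam: float = 30.0, n: int = 124_011,
                      seed: int = 0) -> PoissonReference:
    """Theoretical depth reference: n draws from Poisson(λ), divided by λ."""
    if lam <= 0 or n <= 0:
        raise ValueError("lam and n must be positive")
    rng = np.random.default_rng(seed)
    sample = rng.poisson(lam, size=n) / lam
    return PoissonReference(sample=sample, lam=float(lam), n_dots=int(n), seed=seed)


def cross_platform_r2(profile_a: NDRProfile, profile_b: NDRProfile) -> float:
    """R² of OLS of profile_b on profile_a over shared autosomal windows.

    For simple linear regression this equals the squared Pearson r.
    Returns NaN when profile_a has zero variance.
    """
    mask = _shared_autosomal([profile_a, profile_b])
    a = profile_a.ndr[mask]
    b = profile_b.ndr[mask]
    if a.std() == 0:
        return float("nan")
    res = sps.linregress(a, b)
    return float(res.rvalue ** 2)
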