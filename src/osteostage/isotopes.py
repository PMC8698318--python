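"""Natural-abundance correction and mean enrichment for isotope tracing.

In a uniformly labeled 13C-glucose tracing experiment the measured
intensity of each mass shift M+i mixes true tracer incorporation with
naturally occurring 13C (about 1.07% of carbon). For a metabolite with
``n`` carbons the measured vector is the true isotopologue distribution
convolved with a binomial natural-labeling kernel; the correction inverts
that convolution by non-negative least squares and reports corrected
fractions, per-isotopologue fractions (e.g. M+6 vs M+11 of UDP-glucose as
glycolysis vs pentose-phosphate proxies) and the mean label enrichment
``sum_i i * x_i / n``.

The same machinery applies to 15N tracing with ``n`` the nitrogen count
and ``natural_abundance=0.00364``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NATURAL_ABUNDANCE_13C",
    "NATURAL_ABUNDANCE_15N",
    "IsotopologueVector",
    "ProteinNormalizedValue",
    "NaturalAbundanceCorrector",
    "build_correction_matrix",
    "correct_distribution",
    "mean_enrichment",
    "isotopologue_fraction",
    "normalize_by_protein",
]

NATURAL_ABUNDANCE_13C = 0.0107
NATURAL_ABUNDANCE_15N = 0.00364


def build_correction_matrix(n_atoms: int, natural_abundance: float = NATURAL_ABUNDANCE_13C,
                            tracer_purity: float = 1.0) -> np.ndarray:
    """Binomial natural-labeling convolution matrix.

    Entry ``[i, j]`` is the probability that a molecule with ``j`` tracer
    atoms is measured at mass shift ``i``: the ``n - j`` unlabeled
    positions each carry a heavy isotope with probability ``p``, so
    ``M[i, j] = C(n-j, i-j) p^(i-j) (1-p)^(n-i)`` for ``j <= i``. Columns
    are probability distributions; ``p = 0`` yields the identity.

    ``tracer_purity`` (fraction of tracer atoms that are actually heavy)
    additionally redistributes each column by a binomial thinning of the
    ``j`` labeled positions; the default 1.0 applies no purity correction.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not 0.0 <= natural_abundance < 1.0:
        raise ValueError("natural_abundance must lie in [0, 1)")
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError("tracer_purity must lie in (0, 1]")
    n, p = n_atoms, natural_abundance
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        i = np.arange(j, n + 1)
        M[i, j] = binom.pmf(i - j, n - j, p)
    if tracer_purity < 1.0:
        # column j: j nominal tracer atoms, each heavy with prob purity
        P = np.zeros((n + 1, n + 1))
        for j in range(n + 1):
            k = np.arange(0, j + 1)
            P[k, j] = binom.pmf(k, j, tracer_purity)
        M = M @ P
    return M


def correct_distribution(raw, correction_matrix: np.ndarray):
    """Invert the natural-abundance convolution by non-negative least squares.

    Returns the corrected fractions (non-negative, summing to 1). Raises on
    an all-zero raw vector.
    """
    raw = np.asarray(raw, dtype=float)
    n_plus_1 = correction_matrix.shape[0]
    if raw.shape != (n_plus_1,):
        raise ValueError(
            f"raw vector length {raw.size} != matrix size {n_plus_1}"
        )
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("raw intensity vector is all zero")
    x, _ = nnls(correction_matrix, raw / total)
    s = x.sum()
    if s == 0:
        raise ValueError("degenerate NNLS solution (all zero)")
    return x / s


def mean_enrichment(corrected, n_atoms: int | None = None) -> float:
    """Mean label enrichment ``sum_i i * x_i / n`` of a corrected distribution."""
    x = np.asarray(corrected, dtype=float)
    if np.any(x < 0):
        raise ValueError("fractions must be non-negative")
    if not np.isclose(x.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must sum to 1")
    n = len(x) - 1 if n_atoms is None else n_atoms
    if n < 1:
        raise ValueError("n_atoms must be >= 1")
    return float(np.dot(np.arange(len(x)), x) / n)


def isotopologue_fraction(corrected, index: int) -> float:
    """Fraction of the M+``index`` isotopologue in a corrected distribution."""
    x = np.asarray(corrected, dtype=float)
    if not 0 <= index < len(x):
        raise IndexError(f"mass shift {index} out of range 0..{len(x) - 1}")
    return float(x[index])


@dataclass
class ProteinNormalizedValue:
    """An intensity normalized by BCA-assayed protein content (per µg)."""

    value: float
    protein_ug: float


def normalize_by_protein(intensity: float, protein_ug: float) -> ProteinNormalizedValue:
    """Normalize an intensity by protein amount (µg) to account for cell number."""
    if protein_ug <= 0:
        raise ValueError("protein_ug must be positive")
    return ProteinNormalizedValue(value=intensity / protein_ug,
                                  protein_ug=protein_ug)


@dataclass
class IsotopologueVector:
    """Raw and corrected isotopologue data for one metabolite measurement."""

    metabolite: str
    n_atoms: int
    raw: np.ndarray
    corrected: np.ndarray = field(default=None)
    mean_enrichment: float = field(default=None)

    def correct(self, natural_abundance: float = NATURAL_ABUNDANCE_13C,
                tracer_purity: float = 1.0) -> "IsotopologueVector":
        M = build_correction_matrix(self.n_atoms, natural_abundance,
                                    tracer_purity)
        self.corrected = correct_distribution(self.raw, M)
        self.mean_enrichment = mean_enrichment(self.corrected, self.n_atoms)
        return self


class NaturalAbundanceCorrector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying natural-abundance correction.

    ``fit`` infers the carbon (or nitrogen) count from the number of input
    columns (``n_atoms = n_columns - 1``) and builds the convolution
    matrix; ``transform`` maps rows of raw mass-shift intensities to
    corrected isotopologue fractions.

    Parameters
    ----------
    natural_abundance : float, default 0.0107 (13C)
    tracer_purity : float, default 1.0

    Attributes
    ----------
    n_atoms_ : inferred number of labelable atoms.
    correction_matrix_ : the (n+1) x (n+1) convolution matrix.
    """

    def __init__(self, natural_abundance: float = NATURAL_ABUNDANCE_13C,
                 tracer_purity: float = 1.0):
        self.natural_abundance = natural_abundance
        self.tracer_purity = tracer_purity

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with >= 2 mass-shift columns")
        self.n_atoms_ = X.shape[1] - 1
        self.correction_matrix_ = build_correction_matrix(
            self.n_atoms_, self.natural_abundance, self.tracer_purity
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "correction_matrix_")
        X = np.asarray(X, dtype=float)
        return np.vstack([
            correct_distribution(row, self.correction_matrix_) for row in X
        ])

    def mean_enrichments(self, X) -> np.ndarray:
        """Mean enrichment of each corrected row of ``X``."""
        corrected = self.transform(X)
        return corrected @ np.arange(self.n_atoms_ + 1) / self.n_atoms_
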