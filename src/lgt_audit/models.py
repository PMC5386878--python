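"""Reversible nucleotide substitution models (JC69, HKY85).

The rate matrix is scaled so the expected substitution rate at equilibrium is
1, i.e. branch lengths are in expected substitutions per site. Transition
probability matrices are obtained from the symmetrised eigendecomposition
(pi^1/2 Q pi^-1/2 is symmetric for reversible models), computed once per model.

Base order everywhere: A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["BASES", "SubstitutionModel", "jc69", "hky85"]

BASES = "ACGT"
_PURINES = {"A": "G", "G": "A"}
_PYRIMIDINES = {"C": "T", "T": "C"}


def _is_transition(i: int, j: int) -> bool:
    a, b = BASES[i], BASES[j]
    return _PURINES.get(a) == b or _PYRIMIDINES.get(a) == b


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible nucleotide model with optional gamma rate variation.

    Parameters
    ----------
    name : "JC69" or "HKY85"
    kappa : transition/transversion rate ratio (HKY85 only)
    base_freqs : equilibrium frequencies (A, C, G, T), summing to 1
    gamma_shape : optional shape of a discrete-gamma rate distribution
    n_categories : number of discrete gamma categories
    """

    name: str
    kappa: float = 1.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_categories: int = 4
    _decomp: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.name not in ("JC69", "HKY85"):
            raise InvalidArgumentError(f"unknown model {self.name!r}")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs <= 0).any():
            raise InvalidArgumentError("base_freqs must be 4 positive values")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise InvalidArgumentError("base_freqs must sum to 1 (tolerance 1e-12)")
        if self.name == "JC69" and not np.allclose(freqs, 0.25):
            raise InvalidArgumentError("JC69 requires uniform base frequencies")
        if self.kappa <= 0:
            raise InvalidArgumentError("kappa must be > 0")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise InvalidArgumentError("gamma_shape must be > 0")
        object.__setattr__(self, "_decomp", self._decompose())

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    @property
    def n_free_parameters(self) -> int:
        """Model parameters optimised/fitted: kappa for HKY85, none for JC69."""
        return 0 if self.name == "JC69" else 1

    def rate_matrix(self) -> np.ndarray:
        """The normalised generator Q (rows sum to 0, mean rate 1)."""
        pi = self.pi
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = self.kappa if (self.name == "HKY85" and _is_transition(i, j)) else 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def _decompose(self):
        pi = self.pi
        q = self.rate_matrix()
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[None, :]) / sqrt_pi[:, None]
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        left = eigvec.T * sqrt_pi[None, :]          # rows: v^T diag(sqrt pi)
        right = eigvec / sqrt_pi[:, None]           # diag(1/sqrt pi) v
        return eigval, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows index the ancestral state."""
        if t < 0:
            raise InvalidArgumentError("branch length must be >= 0")
        eigval, right, left = self._decomp
        p = (right * np.exp(eigval * t)[None, :]) @ left
        return np.clip(p, 0.0, None)

    def gamma_rates(self) -> np.ndarray:
        """Mean rates of the equal-probability discrete gamma categories (mean 1)."""
        if self.gamma_shape is None:
            return np.ones(1)
        from scipy.stats import gamma as gamma_dist

        a = self.gamma_shape
        k = self.n_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean within each slice via the (a+1) trick
        upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
        lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
        rates = (upper - lower) * k
        return rates / rates.mean()


def jc69() -> SubstitutionModel:
    return SubstitutionModel(name="JC69")


def hky85(kappa: float = 2.0,
          base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
          ) -> SubstitutionModel:
    return SubstitutionModel(name="HKY85", kappa=kappa, base_freqs=base_freqs)
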