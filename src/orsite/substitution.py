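"""Empirical amino-acid substitution models and transition probabilities.

A general time-reversible model is assembled from a symmetric exchangeability
table ``s`` and equilibrium frequencies ``pi``:

    Q_ij = s_ij * pi_j   (i != j),      Q_ii = -sum_{j != i} Q_ij,

rescaled so the expected substitution rate at stationarity is one,
``-sum_i pi_i Q_ii = 1``, which puts all evolutionary times and distances in
units of expected substitutions per site. Transition matrices
``P(t) = expm(Q t)`` are computed through the eigendecomposition of the
reversible symmetrization ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is
exact, fast for many values of ``t``, and numerically symmetric.

The packaged JTT (Jones-Taylor-Thornton) table is loaded from a versioned
data file with its provenance recorded in the file header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino-acid rate matrix with its stationary frequencies."""

    name: str
    alphabet: str  # amino-acid letter for each matrix index
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) positive, sums to 1

    # derived, filled in __post_init__
    rate_matrix: np.ndarray = field(init=False, repr=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValidationError("exchangeabilities must be symmetric 20x20")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValidationError("frequencies must be 20 positive reals")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValidationError("frequencies must sum to 1")
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # unit expected rate: one substitution per site per unit time
        scale = -(pi * np.diag(q)).sum()
        q = q / scale
        sqrt_pi = np.sqrt(pi)
        sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        eigvals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "_eigvals", eigvals)
        object.__setattr__(self, "_right", vecs / sqrt_pi[:, None])
        object.__setattr__(self, "_left", vecs * sqrt_pi[:, None])

    def index(self, residue: str) -> int:
        """Matrix index of an amino-acid letter."""
        i = self.alphabet.find(residue.upper())
        if i < 0:
            raise ValidationError(f"{residue!r} is not a modeled amino acid")
        return i

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to one for every t >= 0."""
        if t < 0:
            raise ValidationError(f"time must be nonnegative, got {t}")
        p = (self._right * np.exp(self._eigvals * t)) @ self._left.T
        return np.clip(p, 0.0, None)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of times, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        ew = np.exp(ts[:, None] * self._eigvals[None, :])
        return np.clip(
            np.einsum("ik,tk,jk->tij", self._right, ew, self._left), 0.0, None
        )


@lru_cache(maxsize=None)
def jtt() -> SubstitutionModel:
    """The packaged JTT model (see ``data/jtt.dat`` for provenance)."""
    text = resources.files("orsite.data").joinpath("jtt.dat").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    alphabet = "".join(lines[0].split())
    rows = [list(map(float, ln.split())) for ln in lines[1:21]]
    freqs = np.array(list(map(float, lines[21].split())))
    return SubstitutionModel(
        name="JTT",
        alphabet=alphabet,
        exchangeabilities=np.array(rows),
        frequencies=freqs,
    )
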