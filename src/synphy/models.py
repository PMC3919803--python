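"""Empirical amino-acid substitution models with +I +G +F options.

A :class:`RateModel` bundles a symmetric exchangeability matrix ``S``,
equilibrium frequencies ``pi``, a proportion of invariant sites ``p_inv``
and a discrete-gamma shape ``alpha``. The instantaneous rate matrix is
``Q = S @ diag(pi)`` with the diagonal filled so rows sum to zero, then
normalized so the mean rate ``-sum(pi_i * Q_ii)`` equals one substitution
per site before the invariant-sites/gamma mixture is applied. Branch
lengths are therefore in expected substitutions per site for a variable
site at relative rate 1.

The eight matrices used for partitioned analyses (Blosum62, cpREV,
Dayhoff, JTT, LG, rtREV, VT, WAG) ship as PAML-format data files: 19 rows
of lower-triangular exchangeabilities followed by the 20 equilibrium
frequencies, in the canonical residue order ``ARNDCQEGHILKMFPSTWYV``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

#: Canonical residue order (PAML convention) used for all 20-vectors/matrices.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Integer code for a fully ambiguous state (gap, "X", unknown residue).
AMBIG = 20

#: The eight empirical models available for partitioned analyses, in the
#: fixed tie-break order used throughout.
MODEL_NAMES = ("Blosum62", "cpREV", "Dayhoff", "JTT", "LG", "rtREV", "VT", "WAG")

_MODEL_FILES = {
    "Blosum62": "blosum62.dat",
    "cpREV": "cprev.dat",
    "Dayhoff": "dayhoff.dat",
    "JTT": "jtt.dat",
    "LG": "lg.dat",
    "rtREV": "rtrev.dat",
    "VT": "vt.dat",
    "WAG": "wag.dat",
}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned amino-acid string to int8 codes (0-19, 20=ambiguous).

    Gaps ("-", "."), "X" and any non-standard letter map to the ambiguous
    code, which contributes a flat likelihood over all residues.
    """
    return np.array([AA_INDEX.get(c, AMBIG) for c in seq.upper()], dtype=np.int8)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; ambiguous codes render as "-"."""
    lut = np.array(list(AA_ORDER + "-"), dtype="U1")
    return "".join(lut[np.asarray(codes, dtype=int)])


@functools.lru_cache(maxsize=None)
def load_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load (S, pi) for a named empirical model from the packaged data files."""
    if name not in _MODEL_FILES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    text = resources.files("synphy.data").joinpath(_MODEL_FILES[name]).read_text()
    rows = [ln.split() for ln in text.splitlines() if ln.strip()]
    S = np.zeros((20, 20))
    for i, row in enumerate(rows[:19], start=1):
        S[i, : len(row)] = [float(x) for x in row]
    S = S + S.T
    pi = np.array([float(x) for x in rows[19]])
    pi = pi / pi.sum()
    return S, pi


def discrete_gamma(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Equal-weight discrete-gamma category rates (mean-of-quantile-bin).

    The gamma density with shape ``alpha`` and mean 1 is cut at its
    ``k/n_cat`` quantiles and each category rate is the conditional mean
    of its bin, computed via the incomplete-gamma identity
    ``E[X; X in (a, b)] = P(alpha+1, alpha*b) - P(alpha+1, alpha*a)``.
    Rates are renormalized to mean exactly 1 and are non-decreasing.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if n_cat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, n_cat + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    upper[-1] = 1.0  # edge at +inf
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = n_cat * (upper - lower)
    rates = rates / rates.mean()
    return rates


@dataclass
class RateModel:
    """Substitution model ``S`` + ``pi`` with +I (p_inv) and +G (alpha) options.

    ``alpha=None`` disables gamma rate variation (a single category at rate
    1). The +I +G mixture is the standard two-component form: a site is
    invariant with probability ``p_inv``, otherwise its rate is drawn from
    the discrete gamma. Rates are not rescaled by ``1/(1 - p_inv)``; the
    mixture's overall mean rate is absorbed by the branch lengths.
    """

    name: str
    S: np.ndarray
    pi: np.ndarray
    p_inv: float = 0.0
    alpha: float | None = None
    n_cat: int = 4

    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.S.shape != (20, 20) or self.pi.shape != (20,):
            raise ValueError("S must be 20x20 and pi length 20")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi <= 0).any():
            raise ValueError("pi must be positive and sum to 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    # -- spectral machinery -------------------------------------------------

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of the normalized Q via its symmetric similar form.

        Returns (lam, R, L) with ``P(t) = R @ diag(exp(lam*t)) @ L``.
        """
        if self._eig is None:
            Q = self.S * self.pi[None, :]
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            mean_rate = -(self.pi * np.diag(Q)).sum()
            Q = Q / mean_rate
            sqrt_pi = np.sqrt(self.pi)
            B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            lam, U = np.linalg.eigh((B + B.T) / 2.0)
            R = U / sqrt_pi[:, None]
            L = U.T * sqrt_pi[None, :]
            self._eig = (lam, R, L)
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one rate category; rows sum to 1, P(0) = identity."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        lam, R, L = self._eigen()
        P = (R * np.exp(lam * t * rate)[None, :]) @ L
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma relative rates (all 1.0 when alpha is None)."""
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_cat)

    def with_options(self, **kw) -> "RateModel":
        """Copy with updated pi / p_inv / alpha / n_cat (spectral cache shared
        when pi is unchanged is not attempted; the decomposition is cheap)."""
        args = dict(
            name=self.name, S=self.S, pi=self.pi, p_inv=self.p_inv,
            alpha=self.alpha, n_cat=self.n_cat,
        )
        args.update(kw)
        return RateModel(**args)


def empirical_frequencies(codes: np.ndarray) -> np.ndarray:
    """+F frequencies from observed residue counts with add-one smoothing."""
    counts = np.bincount(
        np.asarray(codes, dtype=int).ravel(), minlength=21
    )[:20].astype(float)
    counts += 1.0
    return counts / counts.sum()


def load_empirical_model(
    name: str,
    pi: np.ndarray | None = None,
    p_inv: float = 0.0,
    alpha: float | None = None,
    n_cat: int = 4,
) -> RateModel:
    """Build a :class:`RateModel` from a packaged empirical matrix.

    ``pi`` overrides the published frequencies (the +F option); pass the
    output of :func:`empirical_frequencies` for dataset-specific values.
    """
    S, pi_model = load_exchangeabilities(name)
    return RateModel(
        name=name,
        S=S,
        pi=pi_model if pi is None else pi,
        p_inv=p_inv,
        alpha=alpha,
        n_cat=n_cat,
    )
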