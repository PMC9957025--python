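"""Empirical amino-acid substitution models with rate heterogeneity.

A model couples a published 20x20 exchangeability table with stationary
frequencies (the model's own, or ``+F`` empirical frequencies from the data)
and an optional among-site rate mixture: ``+I`` (a proportion of invariant
sites), ``+G4`` (discrete gamma, 4 equal-probability categories represented
by their category means, Yang 1994), or ``+I+G4``.  The rate matrix Q is
normalised so the expected rate at equilibrium is one substitution per site
per unit branch length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._matrices import AA_ORDER, EXCHANGEABILITIES, FREQUENCIES

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
SUPPORTED_MODELS = tuple(sorted(EXCHANGEABILITIES))

# characters treated as missing data in likelihood computations
MISSING_CHARS = set("-X?.")

_FREQ_PSEUDOCOUNT = 1.0  # Laplace smoothing for +F empirical frequencies


class UnknownModelError(ValueError):
    pass


def _exchangeability_matrix(name: str) -> np.ndarray:
    key = name.upper()
    if key not in EXCHANGEABILITIES:
        raise UnknownModelError(
            f"unknown substitution model {name!r}; supported: {', '.join(SUPPORTED_MODELS)}"
        )
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(EXCHANGEABILITIES[key], start=1):
        S[i, : len(row)] = row
    return S + S.T


def gamma_category_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability bins of Gamma(alpha, alpha)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    probs = np.arange(1, n_cat) / n_cat
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # mean of Gamma(a, rate a) over [lo, hi] with mass 1/n_cat:
    # n_cat * (I(a+1, a*hi) - I(a+1, a*lo)) using the regularised lower gamma
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = n_cat * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstModel:
    """A reversible empirical amino-acid model with an optional rate mixture."""

    name: str
    frequencies: np.ndarray
    exchangeabilities: np.ndarray
    gamma_alpha: float | None = None
    p_inv: float | None = None
    n_gamma_cat: int = 4
    plus_F: bool = False

    def __post_init__(self) -> None:
        pi = np.asarray(self.frequencies, dtype=float)
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-9 or (pi <= 0).any():
            raise ValueError("frequencies must be 20 positive values summing to 1")
        if self.p_inv is not None and not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")

    # ------------------------------------------------------------------ rates
    @property
    def category_rates(self) -> np.ndarray:
        """Per-category relative rates (overall mean exactly 1)."""
        cached = self.__dict__.get("_category_rates")
        if cached is not None:
            return cached
        if self.gamma_alpha is not None:
            g = gamma_category_rates(self.gamma_alpha, self.n_gamma_cat)
        else:
            g = np.array([1.0])
        if self.p_inv is not None and self.p_inv > 0:
            g = np.concatenate([[0.0], g / (1.0 - self.p_inv)])
        self.__dict__["_category_rates"] = g
        return g

    @property
    def category_weights(self) -> np.ndarray:
        if self.gamma_alpha is not None:
            w = np.full(self.n_gamma_cat, 1.0 / self.n_gamma_cat)
        else:
            w = np.array([1.0])
        if self.p_inv is not None and self.p_inv > 0:
            w = np.concatenate([[self.p_inv], w * (1.0 - self.p_inv)])
        return w

    @property
    def n_free_rate_params(self) -> int:
        k = 0
        if self.gamma_alpha is not None:
            k += 1
        if self.p_inv is not None:
            k += 1
        if self.plus_F:
            k += N_STATES - 1
        return k

    @property
    def spec_string(self) -> str:
        parts = [self.name]
        if self.plus_F:
            parts.append("F")
        if self.p_inv is not None:
            parts.append("I")
        if self.gamma_alpha is not None:
            parts.append(f"G{self.n_gamma_cat}")
        return "+".join(parts)

    # ----------------------------------------------------------------- matrix
    @property
    def rate_matrix(self) -> np.ndarray:
        """Q normalised to mean rate 1 at equilibrium."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        return Q / mean_rate

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigen-decomposition of Q exploiting reversibility (cached).

        Returns ``(lam, A, B)`` with ``expm(Q t) = A @ diag(exp(lam t)) @ B``.
        """
        cached = self.__dict__.get("_eigen")
        if cached is not None:
            return cached
        pi = self.frequencies
        sq = np.sqrt(pi)
        sym = self.rate_matrix * (sq[:, None] / sq[None, :])
        sym = 0.5 * (sym + sym.T)
        lam, U = np.linalg.eigh(sym)
        A = U / sq[:, None]
        B = U.T * sq[None, :]
        self.__dict__["_eigen"] = (lam, A, B)
        return lam, A, B

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t * r_c) for each rate category; shape (n_cat, 20, 20)."""
        lam, A, B = self.eigen()
        rates = self.category_rates
        P = np.einsum("ik,ck,kj->cij", A, np.exp(np.outer(rates, lam) * t), B)
        return np.clip(P, 0.0, None)

    def with_rates(self, gamma_alpha: float | None = None,
                   p_inv: float | None = None) -> "SubstModel":
        kwargs = {}
        if gamma_alpha is not None:
            kwargs["gamma_alpha"] = gamma_alpha
        if p_inv is not None:
            kwargs["p_inv"] = p_inv
        return replace(self, **kwargs)


def empirical_frequencies(alignment, pseudocount: float = _FREQ_PSEUDOCOUNT) -> np.ndarray:
    """Observed residue frequencies of an alignment with Laplace smoothing."""
    counts = np.full(N_STATES, pseudocount)
    for sid in alignment.ids:
        for ch in alignment.rows[sid]:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def build_model(name: str, plus_F: bool = False, heterogeneity: str | None = None,
                alignment=None, gamma_alpha: float = 1.0, p_inv: float = 0.1) -> SubstModel:
    """Assemble a :class:`SubstModel` from a model name and options.

    ``heterogeneity`` is ``None``, ``"I"``, ``"G4"`` or ``"I+G4"``;
    ``gamma_alpha`` / ``p_inv`` give initial values for the rate parameters
    (they are free parameters, optimised during model fitting).
    """
    key = name.upper()
    S = _exchangeability_matrix(key)
    if plus_F:
        if alignment is None:
            raise ValueError("+F frequencies require an alignment")
        pi = empirical_frequencies(alignment)
    else:
        pi = np.asarray(FREQUENCIES[key], dtype=float)
        pi = pi / pi.sum()
    alpha: float | None = None
    pinv: float | None = None
    if heterogeneity:
        spec = heterogeneity.upper().replace(" ", "")
        if spec not in {"I", "G4", "I+G4", "G4+I"}:
            raise ValueError(f"unknown heterogeneity spec {heterogeneity!r}")
        if "G4" in spec:
            alpha = gamma_alpha
        if "I" in spec.split("+"):
            pinv = p_inv
    return SubstModel(name=key, frequencies=pi, exchangeabilities=S,
                      gamma_alpha=alpha, p_inv=pinv, plus_F=plus_F)


_SPEC_RE = re.compile(r"^(?P<base>[A-Za-z0-9.]+)(?P<mods>(\+[A-Za-z0-9]+)*)$")


def parse_model_spec(spec: str, alignment=None) -> SubstModel:
    """Parse an IQ-TREE-style model string like ``"WAG+F+G4"`` or ``"HIVb+F+I"``."""
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise UnknownModelError(f"cannot parse model spec {spec!r}")
    mods = [s for s in m.group("mods").split("+") if s]
    plus_F = any(s.upper() == "F" for s in mods)
    het_parts = [s.upper() for s in mods if s.upper() in {"I", "G4"}]
    heterogeneity = "+".join(het_parts) if het_parts else None
    return build_model(m.group("base"), plus_F=plus_F, heterogeneity=heterogeneity,
                       alignment=alignment)


def encode_sequence(seq: str) -> np.ndarray:
    """Residues to state indices; gaps/X/ambiguity encode as -1 (missing)."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        idx = AA_INDEX.get(ch)
        out[i] = -1 if idx is None else idx
    return out
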