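"""Subunit stoichiometry from photobleaching step distributions.

A complex carrying n copies of a labeled subunit shows j <= n bleaching
steps because each fluorescent-protein tag matures into an active
chromophore only with probability m; complexes with zero matured copies are
invisible. Conditioned on visibility, the observed step count is a
zero-truncated binomial:

    P(j | n, m) = C(n, j) m^j (1-m)^(n-j) / (1 - (1-m)^n),   j = 1..n.

The population step histogram is modeled as a mixture over candidate copy
numbers and the mixture weights are fitted by maximum likelihood (EM). The
same dark-fraction logic corrects two-color co-complex fractions: a
monomeric partner is seen in only a fraction m of the complexes that truly
carry it, so the observed colocalization percentage underestimates the true
degree of cohabitation by the factor m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import binom

from .photobleaching import StepDistribution

__all__ = [
    "StoichiometryEstimate",
    "CorrectedFraction",
    "visible_step_pmf",
    "infer_stoichiometry",
    "co_complex_fraction_correction",
    "species_name",
]

_SPECIES = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
            5: "pentamer", 6: "hexamer"}


def species_name(n: int) -> str:
    return _SPECIES.get(int(n), f"{int(n)}-mer")


def visible_step_pmf(n: int, m: float) -> np.ndarray:
    """P(observe j bleaching steps | n copies, maturation m), j = 1..n.

    Zero-truncated binomial: conditioned on at least one matured copy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < m <= 1.0:
        raise ValueError("maturation probability must be in (0, 1]; "
                         "m = 0 means nothing is ever visible")
    j = np.arange(1, n + 1)
    pmf = binom.pmf(j, n, m) / (1.0 - (1.0 - m) ** n)
    return pmf


@dataclass(frozen=True)
class StoichiometryEstimate:
    """ML mixture over copy numbers fitted to a step histogram."""

    weights: dict[int, float]          # n -> mixture weight, sums to 1
    maturation_prob: float
    n_max: int
    log_likelihood: float
    predicted: dict[int, float]        # j -> P(j steps) under the fit
    observed: dict[int, int]           # j -> trace count used in the fit
    call: str                          # dominant species, e.g. "monomer + dimer"
    dominant_threshold: float

    @property
    def dominant(self) -> list[int]:
        return [n for n, w in sorted(self.weights.items())
                if w >= self.dominant_threshold]


def _em_fit(counts: np.ndarray, pmf_matrix: np.ndarray, w0: np.ndarray,
            max_iter: int = 1000, tol: float = 1e-12) -> tuple[np.ndarray, float]:
    """EM for multinomial mixture weights. counts: (J,), pmf_matrix: (N, J)."""
    w = w0.copy()
    total = counts.sum()
    prev = -np.inf
    for _ in range(max_iter):
        mix = w @ pmf_matrix                      # (J,)
        mix = np.clip(mix, 1e-300, None)
        ll = float(counts @ np.log(mix))
        # responsibilities weighted by observed counts
        resp = (w[:, None] * pmf_matrix) / mix[None, :]   # (N, J)
        w = (resp * counts[None, :]).sum(axis=1) / total
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        if ll - prev < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    mix = np.clip(w @ pmf_matrix, 1e-300, None)
    return w, float(counts @ np.log(mix))


def infer_stoichiometry(dist: StepDistribution | Mapping[int, int],
                        m: float = 0.75,
                        n_max: int = 4,
                        n_restarts: int = 10,
                        seed: int = 0,
                        dominant_threshold: float = 0.1) -> StoichiometryEstimate:
    """Maximum-likelihood copy-number mixture for an observed step histogram.

    ``m = 1`` reproduces the raw reading of the histogram (no dark-fraction
    correction), matching how step distributions are conventionally reported.
    If the histogram contains more steps than ``n_max``, the support is
    widened to cover them.
    """
    observed = dict(dist.counts) if isinstance(dist, StepDistribution) else dict(dist)
    observed = {int(j): int(c) for j, c in observed.items() if c > 0}
    if not observed or sum(observed.values()) == 0:
        raise ValueError("degenerate step histogram: no accepted traces")
    if min(observed) < 1:
        raise ValueError("step counts must be >= 1")
    if not 0.0 < m <= 1.0:
        raise ValueError("maturation probability must be in (0, 1]")

    n_max = max(int(n_max), max(observed))
    j_max = n_max
    js = np.arange(1, j_max + 1)
    counts = np.array([observed.get(int(j), 0) for j in js], dtype=float)

    # component pmfs, zero-padded to the common support
    pmf_matrix = np.zeros((n_max, j_max))
    for n in range(1, n_max + 1):
        pmf_matrix[n - 1, :n] = visible_step_pmf(n, m)

    rng = np.random.default_rng(seed)
    best_w, best_ll = None, -np.inf
    inits = [np.full(n_max, 1.0 / n_max)]
    inits += [rng.dirichlet(np.ones(n_max)) for _ in range(max(n_restarts - 1, 0))]
    for w0 in inits:
        w, ll = _em_fit(counts, pmf_matrix, np.asarray(w0))
        if ll > best_ll:
            best_w, best_ll = w, ll

    predicted = best_w @ pmf_matrix
    weights = {n: float(best_w[n - 1]) for n in range(1, n_max + 1)}
    call = " + ".join(species_name(n) for n, w in sorted(weights.items())
                      if w >= dominant_threshold) or "indeterminate"
    return StoichiometryEstimate(
        weights=weights, maturation_prob=m, n_max=n_max,
        log_likelihood=best_ll,
        predicted={int(j): float(p) for j, p in zip(js, predicted)},
        observed={int(j): int(c) for j, c in zip(js, counts)},
        call=call, dominant_threshold=dominant_threshold,
    )


@dataclass(frozen=True)
class CorrectedFraction:
    """Dark-fraction-corrected co-complex proportion."""

    observed: float
    corrected: float
    maturation_prob: float
    capped: bool


def co_complex_fraction_correction(observed_fraction: float,
                                   m_partner: float) -> CorrectedFraction:
    """Correct an observed co-complex proportion for partner dark molecules.

    A monomeric partner is visible in only a fraction ``m_partner`` of the
    complexes that carry it, so the true fraction is observed / m, capped
    at 1 (the cap is reported, since hitting it means the observation is
    inconsistent with the assumed maturation).
    """
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError("observed fraction must be in [0, 1]")
    if not 0.0 < m_partner <= 1.0:
        raise ValueError("maturation probability must be in (0, 1]")
    raw = observed_fraction / m_partner
    return CorrectedFraction(observed=observed_fraction,
                             corrected=min(raw, 1.0),
                             maturation_prob=m_partner,
                             capped=raw > 1.0)
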