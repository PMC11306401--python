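"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: exact integer/Fraction arithmetic and grid search, no shared code
with the implementations under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p by full enumeration in exact arithmetic.

    P(het = h | n, n_minor) ∝ 2^h * n! / (n_major_hom! h! n_minor_hom!);
    two-sided p sums probabilities <= the observed configuration's.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        minor_hom = (n_minor - h) // 2
        major_hom = n - h - minor_hom
        # multinomial count of genotype configurations times 2^h
        weights[h] = Fraction(2**h) * Fraction(
            comb(n, h) * comb(n - h, minor_hom)
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def firth_grid_maximizer(
    X: np.ndarray, y: np.ndarray, span: float = 8.0, steps: int = 81, zooms: int = 6
) -> np.ndarray:
    """2-parameter grid maximization of the Jeffreys-penalized likelihood
    with iterative zooming; resolves the maximizer to well below 1e-4."""
    assert X.shape[1] == 2
    c0 = np.zeros(2)
    half = span
    best = c0
    for _ in range(zooms):
        g0 = np.linspace(best[0] - half, best[0] + half, steps)
        g1 = np.linspace(best[1] - half, best[1] + half, steps)
        vals = np.array(
            [[penalized_loglik(X, y, np.array([u, v])) for v in g1] for u in g0]
        )
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = np.array([g0[i], g1[j]])
        half = half * 2.0 / (steps - 1) * 2.0  # a few grid cells around the argmax
    return best
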