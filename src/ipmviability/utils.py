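"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: design terms a size polynomial may contain, in canonical order
TERM_ORDER = ("size", "size2")


def linpred(beta, terms, z, delta: float = 0.0):
    """Linear predictor ``beta0 + beta_size*z + beta_size2*z**2 + delta``.

    ``beta`` holds the intercept first, then one coefficient per entry of
    ``terms`` (a subset of :data:`TERM_ORDER`).
    """
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, float(beta[0]) + delta)
    for b, t in zip(beta[1:], terms):
        if t == "size":
            out += b * z
        elif t == "size2":
            out += b * z * z
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown term {t!r}")
    return out


def poly_terms(coeffs):
    """Positional coefficient tuple -> (beta, terms) in canonical order."""
    coeffs = tuple(float(c) for c in coeffs)
    return coeffs, TERM_ORDER[: len(coeffs) - 1]
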