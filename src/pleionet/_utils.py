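"""Shared helpers: seeded substreams, hashing, correlation-matrix repair."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG for a stage or operation.

    All randomness in a run flows from one integer seed; each consumer asks
    for a substream by name so adding a stage never perturbs another stage's
    draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def nearest_correlation(R: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping followed by diagonal renormalisation; adequate for the
    mild indefiniteness produced by pairwise estimation.
    """
    R = np.asarray(R, dtype=float)
    S = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= -eps:
        out = S.copy()
    else:
        vals = np.clip(vals, eps, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


from functools import lru_cache

from scipy import stats as _stats


@lru_cache(maxsize=8)
def bvn_truncated_grids(cutoff: float):
    """Moments of a doubly truncated standard bivariate normal.

    For correlation rho and truncation |z1|<c, |z2|<c, returns grids of
    g(rho) = E[z1 z2 | trunc] and v(rho) = E[z1^2 | trunc] over rho in [-1, 1].
    Gauss-Legendre in z1 with the z2 integral done analytically through the
    conditional normal, so the maps stay accurate up to |rho| -> 1.
    """
    c = float(cutoff)
    nodes, wts = np.polynomial.legendre.leggauss(200)
    z1 = nodes * c
    w = wts * c
    phi1 = _stats.norm.pdf(z1)
    kappa1 = 1.0 - 2 * c * _stats.norm.pdf(c) / (2 * _stats.norm.cdf(c) - 1)

    rhos = np.concatenate([[-1.0], np.linspace(-0.999, 0.999, 201), [1.0]])
    gvals = np.empty_like(rhos)
    vvals = np.empty_like(rhos)
    for i, rho in enumerate(rhos):
        if abs(rho) == 1.0:
            gvals[i] = np.sign(rho) * kappa1
            vvals[i] = kappa1
            continue
        s = np.sqrt(1.0 - rho * rho)
        a = (-c - rho * z1) / s
        b = (c - rho * z1) / s
        pz = _stats.norm.cdf(b) - _stats.norm.cdf(a)
        ez2 = rho * z1 * pz + s * (_stats.norm.pdf(a) - _stats.norm.pdf(b))
        den = (w * phi1 * pz).sum()
        gvals[i] = (w * phi1 * z1 * ez2).sum() / den
        vvals[i] = (w * phi1 * z1 * z1 * pz).sum() / den
    return rhos, gvals, vvals


def bvn_corr_from_truncated_product(m: float, cutoff: float) -> float:
    """Invert g(rho) = E[z1 z2 | |z|<c both] at an observed truncated mean."""
    rhos, gvals, _ = bvn_truncated_grids(float(cutoff))
    return float(np.interp(m, gvals, rhos))


def bvn_corr_from_truncated_pearson(r: float, cutoff: float) -> float:
    """Invert the Pearson correlation of the doubly truncated sample.

    The truncation shrinks a correlation of 0.6 to roughly 0.48 at a 1.96
    cutoff; this maps the observed truncated-sample correlation back to rho.
    """
    rhos, gvals, vvals = bvn_truncated_grids(float(cutoff))
    return float(np.interp(r, gvals / vvals, rhos))


def matrix_fingerprint(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(np.round(np.asarray(a, dtype=float), 12))
        h.update(a.tobytes())
        h.update(str(a.shape).encode())
    return h.hexdigest()
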