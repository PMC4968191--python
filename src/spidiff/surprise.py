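"""Poisson "surprise" model validation.

Given a model of the expected photon count ``n_i`` at every pixel (for some
fluence Phi and particle orientation Omega) and an observed photon frame
``k_i``, the surprise is the negative Poisson log-likelihood

    S = - sum_i log P(n_i, k_i),      P(n, k) = n^k e^-n / k!,

in nats.  Because S is a sum of independent per-pixel terms, its mean and
variance under the model itself are analytic:

    <S>      = sum_i H(n_i)                    (H = Poisson entropy)
    sigma_S^2 = sum_i Var[-log P(n_i, k)].

The z-score z = (S - <S>) / sigma_S then measures model-data agreement on
an absolute scale: |z| of order unity means the frame is as probable as a
typical draw from the model; z >> 1 means the data are "surprising" given
the model.  Minimising S over a grid of fluences and orientations assigns
each frame its most likely (Phi, Omega) and scores the agreement there.

Pixels where the model predicts exactly zero photons contribute nothing to
<S> and sigma_S, but force S = +inf if a photon was nonetheless observed;
an optional uniform background floor can be added to the model to keep S
finite in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import poisson

from .errors import (
    DegenerateModelError,
    IncompatibleInputsError,
    InvalidCountError,
    InvalidSearchError,
)

__all__ = [
    "SurpriseResult",
    "poisson_logpmf",
    "surprise_score",
    "expected_surprise",
    "surprise_std",
    "zscore",
    "minimize_surprise",
]


@dataclass
class SurpriseResult:
    """Surprise statistics for one frame against one (best-fit) model."""

    S: float                 #: surprise, nats
    expected_S: float        #: model mean <S>
    sigma_S: float           #: model standard deviation of S
    z: float                 #: (S - <S>) / sigma_S
    best_fluence: float | None = None
    best_orientation: np.ndarray | None = None
    n_pixels: int = 0
    infinite: bool = False   #: True if an observed photon hit a zero-rate pixel


def _check_counts(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k)
    if np.issubdtype(k.dtype, np.floating):
        if not np.all(np.equal(np.mod(k[np.isfinite(k)], 1), 0)):
            raise InvalidCountError("photon counts must be integers")
        k = k.astype(np.int64)
    if np.any(k < 0):
        raise InvalidCountError("photon counts must be non-negative")
    return k


def poisson_logpmf(n, k):
    """log P(n, k) = k ln n - n - ln k! in nats, elementwise.

    Zero-rate conventions: P(0, 0) = 1 (log 0 = 0) and P(0, k>0) = 0
    (log = -inf).  Stable for large counts via the log-gamma function.
    """
    k = _check_counts(k)
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("expected counts must be non-negative")
    return poisson.logpmf(k, n)


def surprise_score(k, model_n, mask: np.ndarray | None = None) -> float:
    """Surprise S = - sum of log P(n_i, k_i) over unmasked pixels.

    Returns +inf if any unmasked pixel has model rate 0 but an observed
    photon.
    """
    k = np.asarray(k)
    model_n = np.asarray(model_n, dtype=float)
    if k.shape != model_n.shape:
        raise IncompatibleInputsError(
            f"frame shape {k.shape} != model shape {model_n.shape}")
    use = np.ones(k.shape, bool) if mask is None else ~np.asarray(mask, bool)
    if mask is not None and mask.shape != k.shape:
        raise IncompatibleInputsError("mask shape does not match frame")
    logp = poisson_logpmf(model_n[use], k[use])
    return float(-np.sum(logp))


def _logp_moments(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second moments of log P(n, K), K ~ Poisson(n), per pixel.

    Truncated summation over k = 0..K with K = ceil(n + 12 sqrt(n) + 30);
    the neglected upper-tail mass is far below 1e-12 for any n.
    """
    n = np.asarray(n, dtype=float).ravel()
    m1 = np.zeros(n.shape)
    m2 = np.zeros(n.shape)
    pos = n > 0
    if pos.any():
        npos = n[pos]
        kmax = int(np.ceil(np.max(npos + 12.0 * np.sqrt(npos) + 30.0)))
        kk = np.arange(kmax + 1)
        logp = poisson.logpmf(kk[None, :], npos[:, None])
        p = np.exp(logp)
        plogp = np.where(p > 0, p * logp, 0.0)
        m1[pos] = plogp.sum(axis=1)
        m2[pos] = np.where(p > 0, plogp * logp, 0.0).sum(axis=1)
    return m1, m2


def expected_surprise(model_n, mask: np.ndarray | None = None) -> float:
    """Model mean <S>: the summed Poisson entropy of the unmasked pixels."""
    model_n = np.asarray(model_n, dtype=float)
    use = np.ones(model_n.shape, bool) if mask is None else ~np.asarray(mask, bool)
    m1, _ = _logp_moments(model_n[use])
    return float(-m1.sum())


def surprise_std(model_n, mask: np.ndarray | None = None) -> float:
    """Model standard deviation sigma_S of the surprise."""
    model_n = np.asarray(model_n, dtype=float)
    use = np.ones(model_n.shape, bool) if mask is None else ~np.asarray(mask, bool)
    m1, m2 = _logp_moments(model_n[use])
    var = np.sum(m2 - m1 ** 2)
    return float(np.sqrt(max(var, 0.0)))


def zscore(k, model_n, mask: np.ndarray | None = None,
           background: float = 0.0) -> SurpriseResult:
    """Surprise z-score of one frame against one model.

    Parameters
    ----------
    background
        Optional uniform rate (photons/pixel) added to the model before
        scoring, to avoid infinite surprise on zero-rate pixels.

    Raises
    ------
    DegenerateModelError
        If sigma_S = 0 (e.g. an all-zero model).
    """
    model_n = np.asarray(model_n, dtype=float) + float(background)
    S = surprise_score(k, model_n, mask)
    use = np.ones(model_n.shape, bool) if mask is None else ~np.asarray(mask, bool)
    m1, m2 = _logp_moments(model_n[use])
    eS = float(-m1.sum())
    sS = float(np.sqrt(max(np.sum(m2 - m1 ** 2), 0.0)))
    if sS == 0.0:
        raise DegenerateModelError("sigma_S = 0: z-score undefined")
    inf = bool(np.isinf(S))
    z = np.inf if inf else (S - eS) / sS
    return SurpriseResult(S=S, expected_S=eS, sigma_S=sS, z=float(z),
                          n_pixels=int(use.sum()), infinite=inf)


def minimize_surprise(k, base_patterns: Callable | Sequence,
                      fluence_grid, orientations=None,
                      mask: np.ndarray | None = None,
                      background: float = 0.0) -> SurpriseResult:
    """Minimise S over a Cartesian (fluence, orientation) grid.

    Parameters
    ----------
    k
        Observed photon frame.
    base_patterns
        Either a callable ``f(orientation) -> unit-fluence expected grid``
        or a sequence of precomputed unit-fluence grids, one per
        orientation.  The model scored at (Phi, Omega) is
        ``Phi * base(Omega) + background``.
    fluence_grid
        Fluence values to scan (same units the base patterns were built
        for — the product ``Phi * base`` must be photons/pixel).
    orientations
        Orientation parameters passed to the callable (ignored for
        sequence input); ``None`` means a single orientation-free model.
    mask
        True = exclude pixel.

    Returns
    -------
    SurpriseResult
        z computed at the minimising (Phi, Omega), with <S> and sigma_S of
        that selected model.  Ties break to the first grid point in
        (orientation-major, fluence-minor) order.
    """
    fluence_grid = np.asarray(fluence_grid, dtype=float)
    if fluence_grid.size == 0:
        raise InvalidSearchError("empty fluence grid")
    if callable(base_patterns):
        if orientations is None:
            orientations = [None]
        if len(orientations) == 0:
            raise InvalidSearchError("empty orientation grid")
        bases = (base_patterns(om) for om in orientations)
        n_orient = len(orientations)
    else:
        bases = iter(base_patterns)
        n_orient = len(base_patterns)
        orientations = list(range(n_orient)) if orientations is None else orientations
        if n_orient == 0:
            raise InvalidSearchError("empty orientation grid")

    k = np.asarray(k)
    use = np.ones(k.shape, bool) if mask is None else ~np.asarray(mask, bool)
    ku = _check_counts(k[use]).astype(float)
    k_tot = ku.sum()
    # The ln k! term is constant across the grid, so the scan below drops
    # it; the final zscore() call on the winner restores the full S.

    best = (np.inf, 0, 0)  # (S_partial, orient_idx, fluence_idx)
    with np.errstate(divide="ignore"):
        ln_phi = np.log(fluence_grid)
    if k_tot == 0:
        ln_phi = np.zeros_like(fluence_grid)  # k_tot * ln_phi term vanishes
    for oi, base in enumerate(bases):
        b = np.asarray(base, dtype=float)[use] + background
        B = b.sum()
        zero = b == 0
        if np.any(zero & (ku > 0)):
            s_phi = np.full(fluence_grid.shape, np.inf)
        else:
            lnb = np.where(zero, 0.0, np.log(np.where(zero, 1.0, b)))
            klnb = float(np.sum(ku * lnb))
            # S(Phi) up to the Phi-independent ln k! term
            s_phi = fluence_grid * B - k_tot * ln_phi - klnb
            if background > 0:
                # background breaks the pure-scaling shortcut; fall back to
                # exact evaluation per fluence
                s_phi = np.array([
                    -np.sum(poisson.logpmf(ku, phi * (b - background) + background))
                    for phi in fluence_grid])
        fi = int(np.argmin(s_phi))
        if s_phi[fi] < best[0]:
            best = (float(s_phi[fi]), oi, fi)

    oi, fi = best[1], best[2]
    phi = float(fluence_grid[fi])
    if callable(base_patterns):
        full_base = np.asarray(base_patterns(orientations[oi]), dtype=float)
    else:
        full_base = np.asarray(base_patterns[oi], dtype=float)
    model = phi * full_base
    res = zscore(k, model, mask=mask, background=background)
    res.best_fluence = phi
    res.best_orientation = orientations[oi]
    return res
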