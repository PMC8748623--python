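"""Demixed principal component analysis (dPCA).

Trial-averaged population activity, organized as a tensor of
units x stimulus (8 peripheral locations) x decision (match/nonmatch)
x time, is decomposed additively into marginalizations — a
condition-independent time component, stimulus x time, decision x time,
and the stimulus x decision interaction — which sum exactly to the
per-unit-centered tensor. For each marginalization a decoder/encoder
pair is found by ridge-regularized reduced-rank regression of that
marginalization onto the full centered data, so the resulting
components are demixed: each captures variance attributable to one
task factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "MARGINALIZATIONS",
    "DpcaFit",
    "marginalize",
    "fit_dpca",
    "project",
]

MARGINALIZATIONS = ("time", "stimulus", "decision", "interaction")


def _check_tensor(x: np.ndarray) -> None:
    if x.ndim != 4:
        raise ValueError(
            "expected a 4-d tensor units x stimulus x decision x time, "
            f"got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor contains missing condition cells "
                         "(non-finite values); balance the design first")


def marginalize(x: np.ndarray) -> Dict[str, np.ndarray]:
    """Additive decomposition of a centered activity tensor.

    Input: (units, S, D, T) trial-averaged rates. Each unit is first
    centered by its grand mean over all conditions and times. The
    returned marginalizations (each broadcast back to full shape) are

    * ``time``: condition-independent time course,
    * ``stimulus``: stimulus x time variance beyond ``time``,
    * ``decision``: decision x time variance beyond ``time``,
    * ``interaction``: the remainder,

    and they sum exactly to the centered tensor.
    """
    _check_tensor(x)
    xc = x - x.mean(axis=(1, 2, 3), keepdims=True)
    m_time = xc.mean(axis=(1, 2), keepdims=True) * np.ones_like(xc)
    m_stim = xc.mean(axis=2, keepdims=True) - xc.mean(axis=(1, 2), keepdims=True)
    m_stim = m_stim * np.ones_like(xc)
    m_dec = xc.mean(axis=1, keepdims=True) - xc.mean(axis=(1, 2), keepdims=True)
    m_dec = m_dec * np.ones_like(xc)
    m_int = xc - m_time - m_stim - m_dec
    return {"time": m_time, "stimulus": m_stim, "decision": m_dec,
            "interaction": m_int}


@dataclass
class DpcaFit:
    """Per-marginalization decoder/encoder pairs and variance accounting."""

    decoders: Dict[str, np.ndarray]  # (q, units)
    encoders: Dict[str, np.ndarray]  # (units, q)
    explained_variance: Dict[str, np.ndarray]  # (q,) share of total variance
    unit_means: np.ndarray  # grand mean per unit used for centering
    total_variance: float
    regularization: float
    shape: Tuple[int, int, int, int]

    def variance_table(self):
        import pandas as pd
        rows = []
        for marg in MARGINALIZATIONS:
            for i, ev in enumerate(self.explained_variance[marg]):
                rows.append({"marginalization": marg, "component": i + 1,
                             "explained_variance_share": float(ev)})
        return pd.DataFrame(rows)


def _flatten(x: np.ndarray) -> np.ndarray:
    return x.reshape(x.shape[0], -1)


def fit_dpca(x: np.ndarray, n_components: int = 5,
             reg: Optional[float] = None) -> DpcaFit:
    """Fit dPCA to a (units, S, D, T) trial-averaged tensor.

    For marginalization ``phi`` the decoder ``D`` and encoder ``F``
    (rank ``q``) minimize ``||X_phi - F D X||^2 + reg ||D_ols||^2``
    where ``X`` is the full centered data: the ridge solution
    ``W = X_phi X' (X X' + reg I)^-1`` is rank-reduced through the SVD
    of ``W X``, giving an orthonormal encoder. ``reg`` defaults to
    ``1e-6 x total variance``. Explained-variance shares are reported
    against the total centered variance.
    """
    _check_tensor(x)
    n_units, S, D, T = x.shape
    q = min(n_components, n_units, S * D * T)
    unit_means = x.mean(axis=(1, 2, 3))
    margs = marginalize(x)
    xc = _flatten(x - unit_means[:, None, None, None])
    total_var = float(np.sum(xc ** 2))
    if total_var == 0:
        raise ValueError("centered tensor has zero variance")
    if reg is None:
        reg = 1e-6 * total_var
    if reg < 0:
        raise ValueError("regularization must be >= 0")
    gram = xc @ xc.T + reg * np.eye(n_units)
    decoders, encoders, evs = {}, {}, {}
    for name in MARGINALIZATIONS:
        xphi = _flatten(margs[name])
        w = np.linalg.solve(gram, xc @ xphi.T).T  # (units, units) ridge OLS
        m = w @ xc
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        q_eff = min(q, max(rank, 0))
        if q_eff < q and rank > 0:
            import warnings
            warnings.warn(
                f"marginalization {name!r}: rank {rank} < requested "
                f"{q} components", stacklevel=2)
        f = u[:, :q_eff]  # orthonormal encoder
        d = f.T @ w  # decoder
        decoders[name] = d
        encoders[name] = f
        comp = d @ xc  # (q_eff, cond*time)
        evs[name] = np.sum((f[:, :, None] * comp[None, :, :]) ** 2,
                           axis=(0, 2)) / total_var if q_eff else np.empty(0)
    return DpcaFit(decoders=decoders, encoders=encoders,
                   explained_variance=evs, unit_means=unit_means,
                   total_variance=total_var, regularization=float(reg),
                   shape=(n_units, S, D, T))


def project(fit: DpcaFit, x: np.ndarray,
             marginalization: Optional[str] = None) -> Dict[str, np.ndarray]:
    """Component time courses per condition: decoder applied to centered data.

    Returns, per marginalization, an array (q, S, D, T).
    """
    _check_tensor(x)
    if x.shape[0] != fit.shape[0]:
        raise ValueError(
            f"unit dimension {x.shape[0]} does not match fit ({fit.shape[0]})"
        )
    xc = _flatten(x - fit.unit_means[:, None, None, None])
    names = [marginalization] if marginalization else list(MARGINALIZATIONS)
    out = {}
    for name in names:
        d = fit.decoders[name]
        traces = d @ xc
        out[name] = traces.reshape(d.shape[0], *x.shape[1:])
    return out
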