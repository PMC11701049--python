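"""Temporal-interference envelope modulation amplitudes.

Two sinusoidal fields E1, E2 at slightly different kHz frequencies superpose
into an amplitude-modulated field.  The envelope amplitude of the component
along a unit direction n is

    e(n) = | |(E1 + E2) . n| - |(E1 - E2) . n| |

and the maximal modulated envelope amplitude (MMEA) at a point is the maximum
of e(n) over all directions.  For two channels this maximum has a closed
form; for four-channel (3D) montages the standard upper-bound approximation
2 * min_i |E_i| is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np


def envelope_along(E1: np.ndarray, E2: np.ndarray, n: np.ndarray) -> float:
    """Directional envelope amplitude e(n); requires |n| = 1.

    The printed difference-of-moduli form can be negative for some n; the
    physical amplitude is its absolute value, and e(n) = e(-n), so the
    direction hemisphere suffices for maximization.
    """
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction n must be a unit vector")
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    return float(abs(abs((E1 + E2) @ n) - abs((E1 - E2) @ n)))


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci lattice), (n, 3)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _mmea_closed_form(E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
    """Vectorized exact two-channel MMEA for stacked fields (N, 3)."""
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    # flip one field if the angle between them is obtuse (envelope is
    # invariant to the sign of either carrier)
    dot = np.einsum("ij,ij->i", E1, E2)
    E2 = np.where(dot[:, None] < 0.0, -E2, E2)
    n1 = np.linalg.norm(E1, axis=1)
    n2 = np.linalg.norm(E2, axis=1)
    # order so that |A| >= |B|
    swap = n2 > n1
    A = np.where(swap[:, None], E2, E1)
    B = np.where(swap[:, None], E1, E2)
    na = np.where(swap, n2, n1)
    nb = np.where(swap, n1, n2)
    out = np.zeros(len(A))
    nz = nb > 0.0
    dotAB = np.einsum("ij,ij->i", A, B)
    # case 1: |B| <= |A| cos(angle)  ->  2|B|
    case1 = nz & (nb * nb <= dotAB)
    out[case1] = 2.0 * nb[case1]
    # case 2: 2 |B x (A - B)| / |A - B|
    case2 = nz & ~case1
    if np.any(case2):
        D = A[case2] - B[case2]
        nd = np.linalg.norm(D, axis=1)
        cr = np.linalg.norm(np.cross(B[case2], D), axis=1)
        val = np.where(nd > 1e-300, 2.0 * cr / np.maximum(nd, 1e-300),
                       2.0 * nb[case2])
        out[case2] = val
    return out


def _mmea_sampled(E1: np.ndarray, E2: np.ndarray, n_dirs: int,
                  refine_rounds: int = 3) -> np.ndarray:
    dirs = fibonacci_directions(n_dirs)                     # (D, 3)
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    out = np.empty(len(E1))
    topk = 8
    best = np.empty((len(E1), topk, 3))
    # chunk over field pairs to bound the (chunk, D) temporaries
    step = max(1, int(4e7 // n_dirs))
    for s in range(0, len(E1), step):
        sl = slice(s, s + step)
        a = (E1[sl] + E2[sl]) @ dirs.T
        b = (E1[sl] - E2[sl]) @ dirs.T
        e = np.abs(np.abs(a) - np.abs(b))
        out[sl] = e.max(axis=1)
        idx = np.argpartition(e, -topk, axis=1)[:, -topk:]
        best[sl] = dirs[idx]
    # deterministic local polish: shrinking tangent-plane grids around the
    # top lattice directions (several, since e(n) can have near-tied local
    # maxima); still pure sampling, independent of the closed form
    delta = 2.0 * np.sqrt(4.0 * np.pi / n_dirs)
    g = np.linspace(-1.0, 1.0, 7)
    GU, GV = np.meshgrid(g, g)
    offs = np.column_stack([GU.ravel(), GV.ravel()])        # (49, 2)
    n = len(E1)
    for _ in range(refine_rounds):
        b0 = best.reshape(n * topk, 3)
        ref = np.where((np.abs(b0[:, :1]) < 0.9),
                       np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        u = np.cross(b0, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(b0, u)
        cand = (b0[:, None, :]
                + delta * (offs[None, :, 0, None] * u[:, None, :]
                           + offs[None, :, 1, None] * v[:, None, :]))
        cand /= np.linalg.norm(cand, axis=2, keepdims=True)
        cand = cand.reshape(n, topk * len(offs), 3)
        a = np.einsum("nj,nkj->nk", E1 + E2, cand)
        b = np.einsum("nj,nkj->nk", E1 - E2, cand)
        e = np.abs(np.abs(a) - np.abs(b))
        out = np.maximum(out, e.max(axis=1))
        idx = np.argpartition(e, -topk, axis=1)[:, -topk:]
        best = np.take_along_axis(cand, idx[:, :, None], axis=1)
        delta /= 3.0
    return out


def mmea_two_channel(E1: np.ndarray, E2: np.ndarray,
                     method: str = "closed_form",
                     n_dirs: int = 10_000) -> np.ndarray | float:
    """Exact two-channel MMEA: max over unit directions of e(n).

    ``closed_form`` evaluates the analytic maximum; ``sampled`` maximizes
    over a deterministic Fibonacci-lattice direction set (the brute-force
    oracle).  Accepts single 3-vectors or stacked (N, 3) arrays.
    """
    scalar = np.asarray(E1).ndim == 1
    if method == "closed_form":
        out = _mmea_closed_form(E1, E2)
    elif method == "sampled":
        out = _mmea_sampled(E1, E2, n_dirs)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out[0]) if scalar else out


def mmea_min_approx(fields: Sequence[np.ndarray]) -> np.ndarray | float:
    """Multi-channel approximation 2 * min_i |E_i| (>= 2 channels).

    For two channels this is an upper bound on the exact MMEA.
    """
    if len(fields) < 2:
        raise ValueError("need at least two channel fields")
    mags = [np.linalg.norm(np.atleast_2d(np.asarray(f, float)), axis=1)
            for f in fields]
    out = 2.0 * np.min(np.stack(mags), axis=0)
    return float(out[0]) if np.asarray(fields[0]).ndim == 1 else out


@dataclass
class EnvelopeField:
    """MMEA sampled at retinal points, raw and min-max normalized."""

    points: np.ndarray          # (N, 3) mm
    mmea_raw: np.ndarray        # (N,) V/m at the configured drive
    mmea_norm: np.ndarray       # (N,) in [0, 1]
    method: str                 # "exact_2ch" | "min_approx_Nch"
    degenerate: bool = False    # constant raw field (normalization guarded)


def _normalize(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi - lo <= 1e-15 * max(1.0, abs(hi)):
        return np.zeros_like(raw), True
    return (raw - lo) / (hi - lo), False


def envelope_field(channel_fields: Dict[int, np.ndarray],
                   montage_kind: str,
                   points: Optional[np.ndarray] = None) -> EnvelopeField:
    """Per-point MMEA from superposed channel E-fields.

    ``channel_fields`` maps channel id -> (N, 3) field at the sample points
    (already scaled by the channel currents).  2D montages (exactly two
    channels) use the exact closed form; 3D montages (four channels) use the
    2 * min approximation.
    """
    chans = sorted(channel_fields)
    if montage_kind == "2D":
        if len(chans) != 2:
            raise ValueError("2D montage requires exactly 2 channels")
        raw = _mmea_closed_form(channel_fields[chans[0]],
                                channel_fields[chans[1]])
        method = "exact_2ch"
    elif montage_kind == "3D":
        if len(chans) != 4:
            raise ValueError("3D montage requires exactly 4 channels")
        raw = mmea_min_approx([channel_fields[c] for c in chans])
        method = "min_approx_4ch"
    else:
        raise ValueError(f"unknown montage kind {montage_kind!r}")
    raw = np.atleast_1d(raw)
    norm, degen = _normalize(raw)
    if points is None:
        points = np.zeros((len(raw), 3))
    return EnvelopeField(points=points, mmea_raw=raw, mmea_norm=norm,
                         method=method, degenerate=degen)
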