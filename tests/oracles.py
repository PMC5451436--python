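"""Independent brute-force oracles used to validate the vectorized paths.

Each function here is deliberately written as the most literal possible
implementation (explicit loops, closed forms), sharing no code with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np

COULOMB_KE = 138.935458  # kJ mol^-1 nm e^-2


def quaternion_superpose(ref: np.ndarray, mob: np.ndarray) -> np.ndarray:
    """Horn's quaternion-based rigid superposition of mob onto ref.

    Returns the fitted copy of mob. Independent of the Kabsch/SVD route.
    """
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    sxx = mc.T @ rc  # 3x3 cross-covariance
    k = np.array(
        [
            [
                sxx[0, 0] + sxx[1, 1] + sxx[2, 2],
                sxx[1, 2] - sxx[2, 1],
                sxx[2, 0] - sxx[0, 2],
                sxx[0, 1] - sxx[1, 0],
            ],
            [
                sxx[1, 2] - sxx[2, 1],
                sxx[0, 0] - sxx[1, 1] - sxx[2, 2],
                sxx[0, 1] + sxx[1, 0],
                sxx[2, 0] + sxx[0, 2],
            ],
            [
                sxx[2, 0] - sxx[0, 2],
                sxx[0, 1] + sxx[1, 0],
                -sxx[0, 0] + sxx[1, 1] - sxx[2, 2],
                sxx[1, 2] + sxx[2, 1],
            ],
            [
                sxx[0, 1] - sxx[1, 0],
                sxx[2, 0] + sxx[0, 2],
                sxx[1, 2] + sxx[2, 1],
                -sxx[0, 0] - sxx[1, 1] + sxx[2, 2],
            ],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    q0, q1, q2, q3 = vecs[:, np.argmax(vals)]
    rot = np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )
    return mc @ rot.T + ref.mean(axis=0)


def brute_msd(r: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged MSD by the explicit double loop."""
    n = r.shape[0]
    out = np.zeros(max_lag + 1)
    for m in range(1, max_lag + 1):
        acc = 0.0
        for k in range(n - m):
            d = r[k + m] - r[k]
            acc += float(d @ d)
        out[m] = acc / (n - m)
    return out


def brute_cos_correlation(phi: np.ndarray, max_lag: int) -> np.ndarray:
    """<cos(phi(t0+t) - phi(t0))> by the explicit double loop (radians)."""
    n = phi.size
    out = np.empty(max_lag + 1)
    for m in range(max_lag + 1):
        acc = 0.0
        for k in range(n - m):
            acc += np.cos(phi[k + m] - phi[k])
        out[m] = acc / (n - m)
    return out


def brute_qres(
    xa: np.ndarray,
    xb: np.ndarray,
    resid: np.ndarray,
    min_sep: int = 2,
    pref_nm: float = 0.1,
    expo: float = 0.15,
) -> np.ndarray:
    """Per-residue environment similarity by explicit pair enumeration."""
    n = xa.shape[0]
    q = np.ones(n)
    for i in range(n):
        terms = []
        for j in range(n):
            if abs(int(resid[i]) - int(resid[j])) < min_sep:
                continue
            rij = np.linalg.norm(xa[i] - xa[j])
            rpij = np.linalg.norm(xb[i] - xb[j])
            sigma = pref_nm * (1.0 + abs(int(resid[i]) - int(resid[j]))) ** expo
            terms.append(np.exp(-((rij - rpij) ** 2) / (2.0 * sigma**2)))
        if terms:
            q[i] = float(np.mean(terms))
    return q


def brute_pair_energy(
    xa: np.ndarray,
    xb: np.ndarray,
    qa: np.ndarray,
    qb: np.ndarray,
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
) -> tuple[float, float]:
    """(E_coul, E_lj) of one frame by the explicit double loop."""
    e_c = 0.0
    e_l = 0.0
    for i in range(xa.shape[0]):
        for j in range(xb.shape[0]):
            r = float(np.linalg.norm(xa[i] - xb[j]))
            e_c += COULOMB_KE * qa[i] * qb[j] / r
            sig = 0.5 * (sig_a[i] + sig_b[j])
            eps = np.sqrt(eps_a[i] * eps_b[j])
            sr6 = (sig / r) ** 6
            e_l += 4.0 * eps * (sr6 * sr6 - sr6)
    return e_c, e_l


def brute_bias_potential(centers, widths, heights, s: np.ndarray) -> np.ndarray:
    """Metadynamics bias by explicit summation over hills."""
    s = np.asarray(s, dtype=float)
    v = np.zeros_like(s)
    for c, w, h in zip(centers, widths, heights):
        v = v + h * np.exp(-((s - c) ** 2) / (2.0 * w * w))
    return v
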