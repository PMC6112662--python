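"""Independent brute-force reference implementations.

Everything here is written straight from the mathematical definitions with
plain Python/NumPy loops and shares no code with the package internals, so
the production implementations can be validated against it on small
problems.
"""

from __future__ import annotations

import numpy as np


def pulse_value(t, f0, n_cycles):
    """Continuous transmit pulse p(t): n_cycles of cos(2 pi f0 t) under a
    Hann window of duration n_cycles/f0 centred on t = 0."""
    T = n_cycles / f0
    t = np.asarray(t, float)
    env = np.where(np.abs(t) <= T / 2.0, 0.5 * (1.0 + np.cos(2.0 * np.pi * t / T)), 0.0)
    return np.cos(2.0 * np.pi * f0 * t) * env


def simulate_direct(scene, config, t0, n_samples):
    """Direct echo synthesis: for each (angle, element, sample) evaluate
    sum_s a_s * p(t - tau_tx - tau_rx) analytically (no shadow, no
    interpolation).  Only valid for shadow-free scenes."""
    xs = np.vstack([scene.diffuse_scatterers, scene.stone_scatterers])
    t = t0 + np.arange(n_samples) / config.fs
    ex = config.geometry.element_x
    out = np.zeros((config.n_angles, ex.size, n_samples))
    for a, th in enumerate(config.angles_rad):
        for x, z, amp in xs:
            tau_tx = (z * np.cos(th) + x * np.sin(th)) / config.c
            for e, xe in enumerate(ex):
                tau = tau_tx + np.hypot(x - xe, z) / config.c
                out[a, e] += amp * pulse_value(t - tau, config.f0, config.n_cycles)
    return out


def _linear_sample(trace, pos):
    if pos < 0.0 or pos >= trace.size - 1:
        return 0.0
    i0 = int(np.floor(pos))
    f = pos - i0
    return (1.0 - f) * trace[i0] + f * trace[i0 + 1]


def das_rf_loop(data, t0, fs, c, elem_x, angles_rad, grid_x, grid_z,
                focus_depth=None):
    """Delay-and-sum RF by quadruple loop with linear trace interpolation.

    focus_depth=None uses the exact plane-wave transmit delay
    (z cos + x sin)/c; otherwise the fixed-focus straight-ray model
    (z - zf + zf cos + x sin)/c.
    """
    out = np.zeros((len(grid_z), len(grid_x)))
    for a, th in enumerate(angles_rad):
        for iz, z in enumerate(grid_z):
            for ix, x in enumerate(grid_x):
                if focus_depth is None:
                    tau_tx = (z * np.cos(th) + x * np.sin(th)) / c
                else:
                    tau_tx = (z - focus_depth + focus_depth * np.cos(th)
                              + x * np.sin(th)) / c
                acc = 0.0
                for e, xe in enumerate(elem_x):
                    tau = tau_tx + np.hypot(x - xe, z) / c
                    acc += _linear_sample(data[a, e], (tau - t0) * fs)
                out[iz, ix] += acc
    return out


def aligned_patch_loop(data, t0, fs, c, elem_x, angles_rad, x, z, half_k,
                       angle_index):
    """One pixel's delay-aligned (n_el, 2*half_k+1) patch by plain loops.

    angle_index=None sums all angles coherently; an int picks one.
    """
    n_el = len(elem_x)
    n_k = 2 * half_k + 1
    patch = np.zeros((n_el, n_k))
    for a, th in enumerate(angles_rad):
        if angle_index is not None and a != angle_index:
            continue
        tau_tx = (z * np.cos(th) + x * np.sin(th)) / c
        for e, xe in enumerate(elem_x):
            centre = (tau_tx + np.hypot(x - xe, z) / c - t0) * fs
            for k in range(n_k):
                patch[e, k] += _linear_sample(data[a, e], centre - half_k + k)
    return patch


def coherence_curve_loop(patch):
    """R(m), m = 1..n_el-1: mean over pairs (i, i+m) of the zero-delay
    normalized correlation; zero-energy pairs are skipped."""
    n_el = patch.shape[0]
    energy = np.array([float(np.dot(p, p)) for p in patch])
    r = np.zeros(n_el - 1)
    for m in range(1, n_el):
        vals = []
        for i in range(n_el - m):
            if energy[i] > 0.0 and energy[i + m] > 0.0:
                vals.append(float(np.dot(patch[i], patch[i + m]))
                            / np.sqrt(energy[i] * energy[i + m]))
        r[m - 1] = np.mean(vals) if vals else 0.0
    return np.clip(r, -1.0, 1.0)


def slsc_pixel_loop(data, t0, fs, c, elem_x, angles_rad, x, z, half_k, q):
    """SLSC pixel: clip(sum_{m=1..q} R(m), 0) on the coherently compounded
    aligned patch."""
    patch = aligned_patch_loop(data, t0, fs, c, elem_x, angles_rad, x, z,
                               half_k, None)
    r = coherence_curve_loop(patch)
    return max(float(np.sum(r[:q])), 0.0)


def mlsc_pixel_loop(data, t0, fs, c, elem_x, angles_rad, x, z, half_k,
                    m_lo, m_hi):
    """MLSC pixel: per-angle mid-lag sums, clipped at zero, then summed."""
    total = 0.0
    for a in range(len(angles_rad)):
        patch = aligned_patch_loop(data, t0, fs, c, elem_x, angles_rad, x, z,
                                   half_k, a)
        r = coherence_curve_loop(patch)
        total += max(float(np.sum(r[m_lo - 1:m_hi])), 0.0)
    return total


def nearest_mean_quantize(img, means):
    """k-means assignment step: each pixel to the nearest class mean."""
    d = np.abs(img[..., None] - np.asarray(means)[None, None, :])
    return np.argmin(d, axis=-1)


def icm_energy(img, labels, means, beta):
    """Segmentation objective: sum (I - mu_label)^2 + beta * (# disagreeing
    8-neighbour pairs, counted once per ordered pixel as the sweep does)."""
    nz, nx = img.shape
    e = float(np.sum((img - np.asarray(means)[labels]) ** 2))
    for i in range(nz):
        for j in range(nx):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nz and 0 <= jj < nx and labels[ii, jj] != labels[i, j]:
                        e += beta
    return e


def paired_t_closed_form(deltas):
    """t = mean / (sd / sqrt(n)) with the n-1 sd denominator."""
    d = np.asarray(deltas, float)
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))


def vcz_triangle(m, n_elements):
    """van Cittert-Zernike prediction for a uniform aperture: 1 - m/N."""
    return 1.0 - np.asarray(m, float) / n_elements
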