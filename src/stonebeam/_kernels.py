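"""Numba inner loops for simulation, beamforming, coherence and segmentation.

These are implementation details; the public API lives in synthetic_scene,
beamform, coherence and shadow_seg.  Everything here is deterministic and
single-threaded so that repeated runs are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# simulation: fractional-delay spike deposit (Keys cubic, a = -0.5)
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def rx_sample_table(xs, zs, elem_x, inv_c, fs, out):
    """Receive delay sqrt((x - x_i)^2 + z^2)/c in sample units, per
    (scatterer, element); computed once and reused for every steering angle."""
    for s in range(xs.shape[0]):
        x = xs[s]
        z2 = zs[s] * zs[s]
        for e in range(elem_x.shape[0]):
            dx = x - elem_x[e]
            out[s, e] = np.sqrt(dx * dx + z2) * inv_c * fs


@njit(cache=True, fastmath=True)
def deposit_spikes(xs, zs, amps, rx_samples, shadow_ok, elem_x, sin_t, cos_t,
                   inv_c, fs, t0, has_stone, stone_x, stone_z_bottom,
                   stone_half_w, transmission, occlude_rx, spikes):
    """Deposit per-element fractional-delay impulses for one plane wave.

    ``spikes`` is (n_elements, n_spk) and is accumulated in place.  The pulse
    waveform is convolved in afterwards (linear superposition), so the echo of
    a scatterer with round-trip delay tau is amp * p(t - tau) up to the cubic
    fractional-positioning kernel (Keys, a = -0.5).
    """
    n_scat = xs.shape[0]
    n_el = elem_x.shape[0]
    n_spk = spikes.shape[1]
    tan_t = sin_t / cos_t
    for s in range(n_scat):
        x = xs[s]
        z = zs[s]
        a0 = amps[s]
        base = ((z * cos_t + x * sin_t) * inv_c - t0) * fs
        rx_lo = 1.0
        rx_hi = -1.0
        if has_stone and shadow_ok[s]:
            # transmit-side geometric shadow, tilted along the steering angle
            if abs((x - stone_x) - (z - stone_z_bottom) * tan_t) < stone_half_w:
                a0 *= transmission
            if occlude_rx:
                # elements whose straight ray to the scatterer crosses the stone
                r = (z - stone_z_bottom) / z
                lo = (stone_x - stone_half_w - x) / r + x
                hi = (stone_x + stone_half_w - x) / r + x
                if lo < hi:
                    rx_lo = lo
                    rx_hi = hi
                else:
                    rx_lo = hi
                    rx_hi = lo
        for e in range(n_el):
            a = a0
            if rx_lo <= elem_x[e] <= rx_hi:
                a *= transmission
            pos = base + rx_samples[s, e]
            i0 = int(pos)
            f = pos - i0
            if 1 <= i0 < n_spk - 2:
                d = 1.0 + f
                spikes[e, i0 - 1] += a * (-0.5 * (d * d * d - 5.0 * d * d + 8.0 * d - 4.0))
                spikes[e, i0] += a * (1.5 * f * f * f - 2.5 * f * f + 1.0)
                d = 1.0 - f
                spikes[e, i0 + 1] += a * (1.5 * d * d * d - 2.5 * d * d + 1.0)
                d = 2.0 - f
                spikes[e, i0 + 2] += a * (-0.5 * (d * d * d - 5.0 * d * d + 8.0 * d - 4.0))


# --------------------------------------------------------------------------
# delay-and-sum beamforming
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def das_rf(data, t0, fs, inv_c, elem_x, sin_t, cos_t, grid_x, grid_z,
           fixed_focus, zf, hann_apod, f_number, out):
    """Delay-and-sum RF image over all angles in ``data``.

    fixed_focus=False: exact per-pixel plane-wave transmit delays (PWSF).
    fixed_focus=True : transmit synthesized as one beam focused at depth zf,
    with straight-ray arrival z/c away from the focal depth (exact at z=zf).

    f_number > 0 gates the receive aperture per pixel to |x - x_i| <=
    z / (2 * f_number) (expanding aperture); hann_apod weights the accepted
    elements with a Hann window (over the gated window when gating is on,
    over the whole array otherwise).  Defaults off: uniform, full aperture.
    """
    n_ang = data.shape[0]
    n_el = data.shape[1]
    n_s = data.shape[2]
    nx = grid_x.shape[0]
    nz = grid_z.shape[0]
    rxs = np.empty((n_el, nz), dtype=np.float64)
    wts = np.empty((n_el, nz), dtype=np.float64)
    txs = np.empty(nz, dtype=np.float64)
    half_span = 0.5 * (elem_x[n_el - 1] - elem_x[0])
    x_mid = 0.5 * (elem_x[n_el - 1] + elem_x[0])
    for ix in range(nx):
        x = grid_x[ix]
        for e in range(n_el):
            dx = x - elem_x[e]
            dx2 = dx * dx
            for iz in range(nz):
                z = grid_z[iz]
                rxs[e, iz] = np.sqrt(dx2 + z * z) * inv_c * fs
                if f_number > 0.0:
                    half_ap = z / (2.0 * f_number)
                    if abs(dx) <= half_ap:
                        if hann_apod:
                            wts[e, iz] = 0.5 + 0.5 * np.cos(np.pi * dx / half_ap)
                        else:
                            wts[e, iz] = 1.0
                    else:
                        wts[e, iz] = 0.0
                elif hann_apod:
                    wts[e, iz] = 0.5 + 0.5 * np.cos(np.pi * (elem_x[e] - x_mid) / half_span)
                else:
                    wts[e, iz] = 1.0
        for a in range(n_ang):
            st = sin_t[a]
            ct = cos_t[a]
            for iz in range(nz):
                z = grid_z[iz]
                if fixed_focus:
                    tau_tx = (z - zf + zf * ct + x * st) * inv_c
                else:
                    tau_tx = (z * ct + x * st) * inv_c
                txs[iz] = (tau_tx - t0) * fs
            for e in range(n_el):
                trace = data[a, e]
                for iz in range(nz):
                    w = wts[e, iz]
                    if w == 0.0:
                        continue
                    pos = txs[iz] + rxs[e, iz]
                    if 0.0 <= pos < n_s - 1:
                        i0 = int(pos)
                        f = pos - i0
                        out[iz, ix] += w * ((1.0 - f) * trace[i0] + f * trace[i0 + 1])


@njit(cache=True, fastmath=True)
def align_patches(data, t0, fs, inv_c, elem_x, sin_t, cos_t, grid_x, grid_z,
                  half_k, angle_index, patches, truncated):
    """Materialize delay-aligned per-element axial kernels for every pixel.

    angle_index >= 0 selects one plane wave; -1 coherently sums all of them
    (synthetic transmit focusing of the channel data).  ``truncated`` is set
    where any required sample falls outside the recorded trace.
    """
    n_ang = data.shape[0]
    n_el = data.shape[1]
    n_s = data.shape[2]
    n_k = 2 * half_k + 1
    for iz in range(grid_z.shape[0]):
        z = grid_z[iz]
        for ix in range(grid_x.shape[0]):
            x = grid_x[ix]
            for a in range(n_ang):
                if angle_index >= 0 and a != angle_index:
                    continue
                tau_tx = (z * cos_t[a] + x * sin_t[a]) * inv_c
                for e in range(n_el):
                    dx = x - elem_x[e]
                    centre = ((tau_tx + np.sqrt(dx * dx + z * z) * inv_c) - t0) * fs
                    base = centre - half_k
                    i0 = int(np.floor(base))
                    f = base - i0
                    trace = data[a, e]
                    for k in range(n_k):
                        idx = i0 + k
                        if idx < 0 or idx + 1 > n_s - 1:
                            truncated[iz, ix] = True
                        else:
                            patches[iz, ix, e, k] += (1.0 - f) * trace[idx] + f * trace[idx + 1]


@njit(cache=True, fastmath=True, inline="always")
def _patch_pixel(data, t0, fs, inv_c, elem_x, sin_t, cos_t, x, z, half_k,
                 angle, sum_all, patch):
    """Fill one pixel's aligned patch (one angle, or coherent sum of all).

    Kernel positions within a trace are exactly one sample apart, so the
    interpolation fraction is constant along the kernel."""
    n_ang = data.shape[0]
    n_el = data.shape[1]
    n_s = data.shape[2]
    n_k = 2 * half_k + 1
    z2 = z * z
    for e in range(n_el):
        for k in range(n_k):
            patch[e, k] = 0.0
    for a in range(n_ang):
        if not sum_all and a != angle:
            continue
        tau_tx = (z * cos_t[a] + x * sin_t[a]) * inv_c
        base_t = (tau_tx - t0) * fs - half_k
        for e in range(n_el):
            dx = x - elem_x[e]
            base = base_t + np.sqrt(dx * dx + z2) * inv_c * fs
            i0 = int(np.floor(base))
            f = base - i0
            if i0 >= 0 and i0 + n_k < n_s:
                trace = data[a, e]
                g = 1.0 - f
                for k in range(n_k):
                    patch[e, k] += g * trace[i0 + k] + f * trace[i0 + k + 1]


@njit(cache=True, fastmath=True, inline="always")
def _lag_sum(patch, energy, m_lo, m_hi):
    """Sum of normalized lag correlations R(m) over m in [m_lo, m_hi]."""
    n_el = patch.shape[0]
    n_k = patch.shape[1]
    total = 0.0
    for m in range(m_lo, m_hi + 1):
        num_pairs = 0
        rsum = 0.0
        for i in range(n_el - m):
            ei = energy[i]
            ej = energy[i + m]
            if ei > 0.0 and ej > 0.0:
                num = 0.0
                for k in range(n_k):
                    num += patch[i, k] * patch[i + m, k]
                rsum += num / np.sqrt(ei * ej)
                num_pairs += 1
        if num_pairs > 0:
            total += rsum / num_pairs
    return total


@njit(cache=True, fastmath=True)
def slsc_kernel(data, t0, fs, inv_c, elem_x, sin_t, cos_t, grid_x, grid_z,
                half_k, q, out):
    """Short-lag spatial coherence on synthetically focused channel data."""
    n_el = data.shape[1]
    n_k = 2 * half_k + 1
    patch = np.empty((n_el, n_k), dtype=np.float64)
    energy = np.empty(n_el, dtype=np.float64)
    for iz in range(grid_z.shape[0]):
        z = grid_z[iz]
        for ix in range(grid_x.shape[0]):
            _patch_pixel(data, t0, fs, inv_c, elem_x, sin_t, cos_t,
                         grid_x[ix], z, half_k, 0, True, patch)
            for e in range(n_el):
                s = 0.0
                for k in range(n_k):
                    s += patch[e, k] * patch[e, k]
                energy[e] = s
            v = _lag_sum(patch, energy, 1, q)
            out[iz, ix] = v if v > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def mlsc_kernel(data, t0, fs, inv_c, elem_x, sin_t, cos_t, grid_x, grid_z,
                half_k, m_lo, m_hi, out):
    """Mid-lag spatial coherence per angle, incoherently compounded.

    Negative per-angle lag sums are clipped to zero before summation, so the
    pixel value lies in [0, n_angles * (m_hi - m_lo + 1)].
    """
    n_ang = data.shape[0]
    n_el = data.shape[1]
    n_k = 2 * half_k + 1
    patch = np.empty((n_el, n_k), dtype=np.float64)
    energy = np.empty(n_el, dtype=np.float64)
    for iz in range(grid_z.shape[0]):
        z = grid_z[iz]
        for ix in range(grid_x.shape[0]):
            total = 0.0
            for a in range(n_ang):
                _patch_pixel(data, t0, fs, inv_c, elem_x, sin_t, cos_t,
                             grid_x[ix], z, half_k, a, False, patch)
                for e in range(n_el):
                    s = 0.0
                    for k in range(n_k):
                        s += patch[e, k] * patch[e, k]
                    energy[e] = s
                v = _lag_sum(patch, energy, m_lo, m_hi)
                if v > 0.0:
                    total += v
            out[iz, ix] = total


# --------------------------------------------------------------------------
# iterated conditional modes segmentation
# --------------------------------------------------------------------------


@njit(cache=True)
def icm_sweeps(img, labels, means, beta, max_iter):
    """Raster-order ICM: data term (I - mu_c)^2 plus beta per disagreeing
    8-neighbour; class means recomputed after each sweep.  Returns
    (n_iterations, converged)."""
    nz, nx = img.shape
    k = means.shape[0]
    it = 0
    for it in range(1, max_iter + 1):
        changed = 0
        for i in range(nz):
            for j in range(nx):
                best_c = labels[i, j]
                best_cost = 1e300
                for c in range(k):
                    d = img[i, j] - means[c]
                    cost = d * d
                    for di in range(-1, 2):
                        for dj in range(-1, 2):
                            if di == 0 and dj == 0:
                                continue
                            ii = i + di
                            jj = j + dj
                            if 0 <= ii < nz and 0 <= jj < nx and labels[ii, jj] != c:
                                cost += beta
                    if cost < best_cost:
                        best_cost = cost
                        best_c = c
                if best_c != labels[i, j]:
                    labels[i, j] = best_c
                    changed += 1
        # recompute class means (empty classes keep their previous mean)
        sums = np.zeros(k, dtype=np.float64)
        cnts = np.zeros(k, dtype=np.int64)
        for i in range(nz):
            for j in range(nx):
                sums[labels[i, j]] += img[i, j]
                cnts[labels[i, j]] += 1
        for c in range(k):
            if cnts[c] > 0:
                means[c] = sums[c] / cnts[c]
        if changed == 0:
            return it, True
    return it, False
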