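"""Numba-compiled photon-transport kernel for the layered sample.

Same physics as :func:`goniotwin.sample.propagate_reference` (cross-checked in
the test suite), restructured as a per-photon scalar loop with detection and
perturbation-weight accumulation done in place, so that memory stays O(number
of detectors) regardless of the photon budget.

Detection here is the azimuth-integrated variance-reduction scheme: a photon
leaving the stack at polar angle theta_S credits every detector whose
half-opening window contains theta_S with the analytic azimuth weight, and
simultaneously accumulates the three perturbation-weighted sums (mu_a, mu_s,
g) needed for single-run derivatives.

An optional importance-sampling mixture flattens the *first* scattering angle
in the perturbable medium (fraction ``is_frac`` drawn isotropically, with the
exact density ratio carried as a path weight).  This fills the sparsely
populated backward detector angles at thin optical depths without biasing any
expectation; subsequent scattering events always sample the true phase
function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# source modes
SRC_PENCIL = 0
SRC_CACHE = 1


@njit(cache=True, inline="always", fastmath=True)
def _hg_pdf(g, u):
    return (1.0 - g * g) / (2.0 * (1.0 + g * g - 2.0 * g * u) ** 1.5)


@njit(cache=True, inline="always", fastmath=True)
def _hg_sample(g, r):
    # closed form loses ~all precision for |g| -> 0 (0/0 structure); the
    # isotropic branch is exact to O(g) there
    if -1e-7 < g < 1e-7:
        return 2.0 * r - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * r)
    u = (1.0 + g * g - frac * frac) / (2.0 * g)
    if u > 1.0:
        u = 1.0
    elif u < -1.0:
        u = -1.0
    return u


@njit(cache=True, inline="always", fastmath=True)
def _table_sample(table, r):
    # table holds u at equispaced CDF levels
    pos = r * (table.shape[0] - 1)
    i = int(pos)
    if i >= table.shape[0] - 1:
        i = table.shape[0] - 2
    frac = pos - i
    return table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=True, inline="always", fastmath=True)
def _detection_theta(x, y, z, ux, uy, uz, det_r):
    """Polar angle (deg) at which the exit ray crosses the detector sphere.

    The goniometer's detectors sit on a sphere of radius ``det_r`` around the
    sample rotation center; a photon exiting away from the origin is seen at
    the angle of its trajectory's crossing with that sphere, not at its
    direction angle (parallax of a few tenths of a degree per mm of offset).
    ``det_r <= 0`` selects the far-field (direction-only) convention.
    """
    if det_r <= 0.0:
        cz = uz
    else:
        b = x * ux + y * uy + z * uz
        c = x * x + y * y + z * z - det_r * det_r
        t = -b + np.sqrt(b * b - c)
        cz = (z + t * uz) / det_r
    if cz > 1.0:
        cz = 1.0
    elif cz < -1.0:
        cz = -1.0
    return np.arccos(cz) * 180.0 / np.pi


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_scalar(n1, n2, cos_i):
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always", fastmath=True)
def _detect(theta_deg, base_w, w_a, w_s, w_g,
            det_theta, det_sin, det_cos, cos_tr, theta_r_deg,
            s0, sa, ss, sg, s0sq, hits):
    nd = det_theta.shape[0]
    # binary search for the first detector angle >= theta - theta_r
    lo, hi = 0, nd
    tlo = theta_deg - theta_r_deg
    while lo < hi:
        mid = (lo + hi) // 2
        if det_theta[mid] < tlo:
            lo = mid + 1
        else:
            hi = mid
    j = lo
    thi = theta_deg + theta_r_deg
    theta_rad = theta_deg * np.pi / 180.0
    sin_s = np.sin(theta_rad)
    cos_s = np.cos(theta_rad)
    while j < nd and det_theta[j] <= thi:
        sd = det_sin[j]
        w = 0.0
        if sd < 1e-12 or sin_s < 1e-12:
            # degenerate on-axis detector or exactly axial photon: cone test
            sep = theta_deg - det_theta[j]
            if sep < 0.0:
                sep = -sep
            if sep <= theta_r_deg:
                w = 1.0
        else:
            phi = (cos_tr - det_cos[j] * cos_s) / (sd * sin_s)
            if phi <= -1.0:
                w = 1.0
            elif phi < 1.0:
                w = np.arccos(phi) / np.pi
        if w > 0.0:
            bw = base_w * w
            s0[j] += bw
            sa[j] += bw * w_a
            ss[j] += bw * w_s
            sg[j] += bw * w_g
            s0sq[j] += bw * bw
            hits[j] += 1
        j += 1


@njit(cache=True, fastmath=True)
def transport_kernel(
    rng,
    n_photons,
    # source: mode, cache arrays (radial pos, u_r, u_t, u_z)
    src_mode, cache_r, cache_ur, cache_ut, cache_uz,
    # geometry / materials
    z_edges, mua, mus, n_idx, g_arr, use_table, tables, n_out, cutout_r,
    # perturbation setup
    pert_layer, d_mua, d_mus, d_g,
    # importance sampling of the first scattering angle
    is_frac,
    # detectors (angles sorted ascending, degrees; det_dist <= 0 -> far field)
    det_dist, det_theta, det_sin, det_cos, cos_tr, theta_r_deg,
    # accumulators (modified in place)
    s0, sa, ss, sg, s0sq, hits, counters,
):
    """Run ``n_photons`` through the layer stack; accumulate detector sums.

    ``counters``: [absorbed, side_wall, exited, runaway, entered].
    """
    n_layers = z_edges.shape[0] - 1
    cutout2 = cutout_r * cutout_r
    mua_p = mua[pert_layer]
    mus_p = mus[pert_layer]
    g_p = g_arr[pert_layer]
    g_pert = g_p * (1.0 + d_g)
    log1p_ds = np.log(1.0 + d_mus)
    n_cache = cache_r.shape[0]

    for i_ph in range(n_photons):
        # ---- launch ----
        if src_mode == SRC_PENCIL:
            x = 0.0
            y = 0.0
            ux = 0.0
            uy = 0.0
            uz = 1.0
        else:
            # walk the cache sequentially (cache-friendly; every stored ray is
            # used equally often) and randomize only the azimuth
            idx = i_ph % n_cache
            phi0 = 2.0 * np.pi * rng.random()
            cph = np.cos(phi0)
            sph = np.sin(phi0)
            rr = cache_r[idx]
            x = rr * cph
            y = rr * sph
            ux = cache_ur[idx] * cph - cache_ut[idx] * sph
            uy = cache_ur[idx] * sph + cache_ut[idx] * cph
            uz = cache_uz[idx]
        z = 0.0
        # entry interaction outside -> layer 0
        r_ref, cos_t = _fresnel_scalar(n_out, n_idx[0], uz)
        if rng.random() < r_ref:
            uz = -uz
            theta = _detection_theta(x, y, z, ux, uy, uz, det_dist)
            _detect(theta, 1.0, 1.0, 1.0, 1.0, det_theta, det_sin, det_cos,
                    cos_tr, theta_r_deg, s0, sa, ss, sg, s0sq, hits)
            counters[2] += 1
            continue
        eta = n_out / n_idx[0]
        ux *= eta
        uy *= eta
        uz = cos_t
        counters[4] += 1
        layer = 0

        l_med = 0.0
        n_scat = 0
        log_wg = 0.0
        w_is = 1.0
        first_scatter = True
        alive = True
        events = 0

        while alive:
            events += 1
            if events > 10_000_000:
                counters[3] += 1
                break
            mus_k = mus[layer]
            mua_k = mua[layer]
            if mus_k > 0.0:
                s_free = -np.log1p(-rng.random()) / mus_k
            else:
                s_free = 1e30
            if uz > 0.0:
                db = (z_edges[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_edges[layer] - z) / uz
            else:
                db = 1e30
            at_boundary = db <= s_free
            step = db if at_boundary else s_free
            xn = x + step * ux
            yn = y + step * uy
            if xn * xn + yn * yn > cutout2:
                counters[1] += 1
                break
            x = xn
            y = yn
            z += step * uz
            if mua_k > 0.0:
                if rng.random() >= np.exp(-mua_k * step):
                    counters[0] += 1
                    break
            if layer == pert_layer:
                l_med += step
            if at_boundary:
                going_up = uz > 0.0
                if going_up:
                    z = z_edges[layer + 1]
                    nxt = layer + 1
                else:
                    z = z_edges[layer]
                    nxt = layer - 1
                n1 = n_idx[layer]
                if 0 <= nxt < n_layers:
                    n2 = n_idx[nxt]
                else:
                    n2 = n_out
                cos_i = uz if going_up else -uz
                r_ref, cos_t = _fresnel_scalar(n1, n2, cos_i)
                if rng.random() < r_ref:
                    uz = -uz
                else:
                    eta = n1 / n2
                    ux *= eta
                    uy *= eta
                    uz = cos_t if going_up else -cos_t
                    if nxt < 0 or nxt >= n_layers:
                        # exited into the null volume: detect and terminate
                        theta = _detection_theta(x, y, z, ux, uy, uz, det_dist)
                        w_a = np.exp(-l_med * d_mua * mua_p)
                        w_s = np.exp(n_scat * log1p_ds - l_med * d_mus * mus_p)
                        w_g = np.exp(log_wg)
                        _detect(theta, w_is, w_a, w_s, w_g,
                                det_theta, det_sin, det_cos, cos_tr, theta_r_deg,
                                s0, sa, ss, sg, s0sq, hits)
                        counters[2] += 1
                        break
                    layer = nxt
            else:
                # scattering event
                if use_table[layer] == 1:
                    u_sc = _table_sample(tables[layer], rng.random())
                else:
                    g_k = g_arr[layer]
                    if (layer == pert_layer and first_scatter and is_frac > 0.0):
                        if rng.random() < is_frac:
                            u_sc = 2.0 * rng.random() - 1.0
                        else:
                            u_sc = _hg_sample(g_k, rng.random())
                        p_true = _hg_pdf(g_k, u_sc)
                        q = is_frac * 0.5 + (1.0 - is_frac) * p_true
                        w_is *= p_true / q
                    else:
                        u_sc = _hg_sample(g_k, rng.random())
                if layer == pert_layer:
                    n_scat += 1
                    first_scatter = False
                    if d_g != 0.0 and use_table[layer] == 0:
                        log_wg += np.log(_hg_pdf(g_pert, u_sc)) - np.log(_hg_pdf(g_arr[layer], u_sc))
                phi = 2.0 * np.pi * rng.random()
                # rotate (ux, uy, uz) by polar cos u_sc, azimuth phi
                ct = u_sc
                st = np.sqrt(max(1.0 - ct * ct, 0.0))
                cp = np.cos(phi)
                sp = np.sin(phi)
                if uz > 1.0 - 1e-6 or uz < -1.0 + 1e-6:
                    sign = 1.0 if uz >= 0.0 else -1.0
                    ux = st * cp
                    uy = st * sp
                    uz = ct * sign
                else:
                    denom = np.sqrt(1.0 - uz * uz)
                    nx = st * (ux * uz * cp - uy * sp) / denom + ux * ct
                    ny = st * (uy * uz * cp + ux * sp) / denom + uy * ct
                    nz = -st * cp * denom + uz * ct
                    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
                    ux = nx / norm
                    uy = ny / norm
                    uz = nz / norm
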