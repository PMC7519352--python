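"""Numba-compiled Monte Carlo photon-transport kernels.

All kernels share the same physics:

* exponential step sampling with mu_t = mu_a + mu_s,
* continuous absorption weighting (the photon deposits the fraction
  mu_a / mu_t of its weight at each interaction and survives with the
  single-scattering albedo),
* Henyey-Greenstein angular sampling with anisotropy g,
* unpolarized Fresnel reflection/refraction at the z = 0 surface
  (tissue index vs ambient index),
* Russian roulette below ``RR_THRESHOLD`` with survival probability
  ``RR_SURVIVE``,
* path-length fluence estimator: each voxel accumulates weight x path
  length; callers divide by (photons x voxel volume).

An exact bookkeeping audit is accumulated during transport: the launched
weight equals specular loss + absorbed + escaped (top) + terminated
(lateral/bottom) + roulette-killed - roulette-gained, to floating-point
rounding.

Kernels are deterministic for a fixed seed (single-threaded, seeded
``np.random``).
"""

import math

import numpy as np
from numba import njit

RR_THRESHOLD = 1.0e-4
RR_SURVIVE = 0.1

# tally indices
T_LAUNCHED = 0
T_SPECULAR = 1
T_ABSORBED = 2
T_ESCAPED = 3
T_TERMINATED = 4
T_RR_KILLED = 5
T_RR_GAIN = 6
N_TALLY = 7


@njit(cache=True)
def _fresnel_r(cos_i, n1, n2):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i (>= 0)."""
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n1 / n2
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _hg_cos(g):
    if abs(g) < 1.0e-6:
        return 2.0 * np.random.random() - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _spin(ux, uy, uz, g):
    """New direction after a Henyey-Greenstein scatter."""
    ct = _hg_cos(g)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * np.random.random()
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


# ---------------------------------------------------------------------------
# General heterogeneous voxel kernel
# ---------------------------------------------------------------------------

# launch modes
MODE_PENCIL = 0
MODE_LINE = 1
MODE_COSINE = 2
MODE_ISOTROPIC = 3  # interior isotropic emission at (x0, y0, z0)


@njit(cache=True)
def mc_voxel(
    mua,
    mus,
    g,
    n,
    h,
    n_amb,
    mode,
    x0,
    y0,
    sigma_x,
    ax_air,
    ay_air,
    az_air,
    line_y0,
    line_y1,
    z0,
    n_photons,
    seed,
):
    """Voxel Monte Carlo on a bounded grid.

    Launch modes: MODE_PENCIL — beam entering at (x0 + N(0, sigma_x), y0)
    with air-side direction (ax, ay, az), az > 0, refracted at the surface;
    MODE_LINE — same but y uniform over [line_y0, line_y1); MODE_COSINE —
    adjoint detector launch at (x0, y0): directions cosine-weighted inside
    the escape cone, weighted by the Fresnel transmission of the reversed
    (escaping) ray; MODE_ISOTROPIC — interior isotropic emission at
    (x0, y0, z0), modeling fluorophore emission.

    Returns (fluence_sum, escape_map, tallies): fluence_sum holds
    sum(weight x path) per voxel (divide by n_photons * h**3 for fluence
    per launched photon); escape_map (nx, ny) holds the cosine-weighted
    transmitted weight of photons escaping through the surface, the
    radiance a surface-normal camera would collect per surface bin.
    """
    np.random.seed(seed)
    nx, ny, nz = mua.shape
    fl = np.zeros((nx, ny, nz))
    esc = np.zeros((nx, ny))
    tal = np.zeros(N_TALLY)
    eps = 1.0e-12

    for _ in range(n_photons):
        # --- launch -------------------------------------------------------
        if mode == MODE_LINE:
            px = x0 + sigma_x * np.random.standard_normal()
            py = line_y0 + (line_y1 - line_y0) * np.random.random()
        else:
            px = x0 + (sigma_x * np.random.standard_normal() if mode == MODE_PENCIL else 0.0)
            py = y0
        pz = z0 if mode == MODE_ISOTROPIC else 0.0
        ix = int(px / h)
        iy = int(py / h)
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            tal[T_LAUNCHED] += 1.0
            tal[T_TERMINATED] += 1.0  # launched outside the footprint
            continue
        iz = int(pz / h)
        n_surf = n[ix, iy, 0]
        if mode == MODE_ISOTROPIC:
            ct = 2.0 * np.random.random() - 1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            ux = st * math.cos(phi)
            uy = st * math.sin(phi)
            uz = ct
            w = 1.0
            tal[T_LAUNCHED] += 1.0
        elif mode == MODE_COSINE:
            # truncated-cosine sampling within the escape cone, weight by
            # the Fresnel transmission of the reversed escaping ray
            cos_c2 = max(0.0, 1.0 - (n_amb / n_surf) ** 2) if n_surf > n_amb else 0.0
            ct = math.sqrt(cos_c2 + np.random.random() * (1.0 - cos_c2))
            w = 1.0 - _fresnel_r(ct, n_surf, n_amb)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            ux = st * math.cos(phi)
            uy = st * math.sin(phi)
            uz = ct
            tal[T_LAUNCHED] += 1.0
            tal[T_SPECULAR] += 1.0 - w
        else:
            cos_i = az_air
            r_spec = _fresnel_r(cos_i, n_amb, n_surf)
            w = 1.0 - r_spec
            tal[T_LAUNCHED] += 1.0
            tal[T_SPECULAR] += r_spec
            sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
            if sin_i < eps:
                ux, uy, uz = 0.0, 0.0, 1.0
            else:
                sin_t = sin_i * n_amb / n_surf
                cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                # tangential unit vector of the air-side direction
                tx = ax_air / sin_i
                ty = ay_air / sin_i
                ux = sin_t * tx
                uy = sin_t * ty
                uz = cos_t

        tau = -math.log(1.0 - np.random.random())
        alive = True
        while alive:
            mt = mua[ix, iy, iz] + mus[ix, iy, iz]
            # distance to voxel exit
            if ux > eps:
                tx_ = ((ix + 1) * h - px) / ux
            elif ux < -eps:
                tx_ = (ix * h - px) / ux
            else:
                tx_ = 1.0e30
            if uy > eps:
                ty_ = ((iy + 1) * h - py) / uy
            elif uy < -eps:
                ty_ = (iy * h - py) / uy
            else:
                ty_ = 1.0e30
            if uz > eps:
                tz_ = ((iz + 1) * h - pz) / uz
            elif uz < -eps:
                tz_ = (iz * h - pz) / uz
            else:
                tz_ = 1.0e30
            t_exit = min(tx_, min(ty_, tz_))
            if t_exit < 0.0:
                t_exit = 0.0

            if mt > 0.0 and mt * t_exit >= tau:
                # interaction inside this voxel
                t_int = tau / mt
                fl[ix, iy, iz] += w * t_int
                px += ux * t_int
                py += uy * t_int
                pz += uz * t_int
                la = mua[ix, iy, iz] / mt
                tal[T_ABSORBED] += w * la
                w *= 1.0 - la
                if w <= 0.0:
                    alive = False
                    continue
                if w < RR_THRESHOLD:
                    if np.random.random() < RR_SURVIVE:
                        tal[T_RR_GAIN] += w * (1.0 / RR_SURVIVE - 1.0)
                        w /= RR_SURVIVE
                    else:
                        tal[T_RR_KILLED] += w
                        alive = False
                        continue
                gv = g[ix, iy, iz]
                ux, uy, uz = _spin(ux, uy, uz, gv)
                tau = -math.log(1.0 - np.random.random())
            else:
                # traverse to the voxel face
                fl[ix, iy, iz] += w * t_exit
                tau -= mt * t_exit
                px += ux * t_exit
                py += uy * t_exit
                pz += uz * t_exit
                if t_exit == tz_ and uz < 0.0 and iz == 0:
                    # surface: Fresnel reflect or escape
                    pz = 0.0
                    r = _fresnel_r(-uz, n[ix, iy, 0], n_amb)
                    if np.random.random() < r:
                        uz = -uz
                    else:
                        tal[T_ESCAPED] += w
                        esc[ix, iy] += w * (-uz)  # cosine-weighted collection
                        alive = False
                    continue
                if t_exit == tx_:
                    ix += 1 if ux > 0.0 else -1
                    px = (ix if ux > 0.0 else ix + 1) * h
                if t_exit == ty_:
                    iy += 1 if uy > 0.0 else -1
                    py = (iy if uy > 0.0 else iy + 1) * h
                if t_exit == tz_:
                    iz += 1 if uz > 0.0 else -1
                    pz = (iz if uz > 0.0 else iz + 1) * h
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz >= nz:
                    tal[T_TERMINATED] += w
                    alive = False
    return fl, esc, tal


# ---------------------------------------------------------------------------
# Homogeneous-slab response kernels (translation-invariant pipeline fields)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _deposit_2d(phi, w, px, pz, ux, uz, s, h, nu_half, nz):
    """Add w x path to (x, z) bins along a segment.

    x bins are centered at i*h (boundaries at (i +/- 0.5)*h), i in
    [-nu_half, nu_half]; z bins span [k*h, (k+1)*h).
    """
    # clip segment to the scoring box
    x_lo = -(nu_half + 0.5) * h
    x_hi = (nu_half + 0.5) * h
    z_hi = nz * h
    t0 = 0.0
    t1 = s
    if ux > 0.0:
        t0 = max(t0, (x_lo - px) / ux)
        t1 = min(t1, (x_hi - px) / ux)
    elif ux < 0.0:
        t0 = max(t0, (x_hi - px) / ux)
        t1 = min(t1, (x_lo - px) / ux)
    elif px <= x_lo or px >= x_hi:
        return
    if uz > 0.0:
        t0 = max(t0, (0.0 - pz) / uz)
        t1 = min(t1, (z_hi - pz) / uz)
    elif uz < 0.0:
        t0 = max(t0, (z_hi - pz) / uz)
        t1 = min(t1, (0.0 - pz) / uz)
    elif pz < 0.0 or pz >= z_hi:
        return
    if t1 <= t0:
        return
    x = px + ux * t0
    z = pz + uz * t0
    remaining = t1 - t0
    ix = int(math.floor(x / h + 0.5))
    iz = int(math.floor(z / h))
    eps = 1.0e-12
    while remaining > eps:
        if ux > eps:
            dx_ = ((ix + 0.5) * h - x) / ux
        elif ux < -eps:
            dx_ = ((ix - 0.5) * h - x) / ux
        else:
            dx_ = 1.0e30
        if uz > eps:
            dz_ = ((iz + 1) * h - z) / uz
        elif uz < -eps:
            dz_ = (iz * h - z) / uz
        else:
            dz_ = 1.0e30
        dt = min(dx_, min(dz_, remaining))
        if dt < 0.0:
            dt = 0.0
        if -nu_half <= ix <= nu_half and 0 <= iz < nz:
            phi[ix + nu_half, iz] += w * dt
        if dt >= remaining:
            break
        x += ux * dt
        z += uz * dt
        remaining -= dt
        if dt == dx_:
            ix += 1 if ux > 0.0 else -1
            x = (ix - 0.5 if ux > 0.0 else ix + 0.5) * h
        if dt == dz_:
            iz += 1 if uz > 0.0 else -1
            z = (iz if uz > 0.0 else iz + 1) * h


@njit(cache=True, inline="always")
def _deposit_3d_folded(gf, w, px, py, pz, ux, uy, uz, s, h, nfx, nfy, nz):
    """Add w x path to folded (|x|, |y|, z) bins along a segment.

    x and y bins are centered at i*h; z bins span [k*h, (k+1)*h).  The
    caller unfolds with the mirror multiplicity (x2 per nonzero |index|).
    """
    x_hi = (nfx - 0.5) * h
    y_hi = (nfy - 0.5) * h
    z_hi = nz * h
    t0 = 0.0
    t1 = s
    if ux > 0.0:
        t0 = max(t0, (-x_hi - px) / ux)
        t1 = min(t1, (x_hi - px) / ux)
    elif ux < 0.0:
        t0 = max(t0, (x_hi - px) / ux)
        t1 = min(t1, (-x_hi - px) / ux)
    elif px <= -x_hi or px >= x_hi:
        return
    if uy > 0.0:
        t0 = max(t0, (-y_hi - py) / uy)
        t1 = min(t1, (y_hi - py) / uy)
    elif uy < 0.0:
        t0 = max(t0, (y_hi - py) / uy)
        t1 = min(t1, (-y_hi - py) / uy)
    elif py <= -y_hi or py >= y_hi:
        return
    if uz > 0.0:
        t0 = max(t0, (0.0 - pz) / uz)
        t1 = min(t1, (z_hi - pz) / uz)
    elif uz < 0.0:
        t0 = max(t0, (z_hi - pz) / uz)
        t1 = min(t1, (0.0 - pz) / uz)
    elif pz < 0.0 or pz >= z_hi:
        return
    if t1 <= t0:
        return
    x = px + ux * t0
    y = py + uy * t0
    z = pz + uz * t0
    remaining = t1 - t0
    ix = int(math.floor(x / h + 0.5))
    iy = int(math.floor(y / h + 0.5))
    iz = int(math.floor(z / h))
    eps = 1.0e-12
    while remaining > eps:
        if ux > eps:
            dx_ = ((ix + 0.5) * h - x) / ux
        elif ux < -eps:
            dx_ = ((ix - 0.5) * h - x) / ux
        else:
            dx_ = 1.0e30
        if uy > eps:
            dy_ = ((iy + 0.5) * h - y) / uy
        elif uy < -eps:
            dy_ = ((iy - 0.5) * h - y) / uy
        else:
            dy_ = 1.0e30
        if uz > eps:
            dz_ = ((iz + 1) * h - z) / uz
        elif uz < -eps:
            dz_ = (iz * h - z) / uz
        else:
            dz_ = 1.0e30
        dt = min(min(dx_, dy_), min(dz_, remaining))
        if dt < 0.0:
            dt = 0.0
        ax = ix if ix >= 0 else -ix
        ay = iy if iy >= 0 else -iy
        if ax < nfx and ay < nfy and 0 <= iz < nz:
            gf[ax, ay, iz] += w * dt
        if dt >= remaining:
            break
        x += ux * dt
        y += uy * dt
        z += uz * dt
        remaining -= dt
        if dt == dx_:
            ix += 1 if ux > 0.0 else -1
            x = (ix - 0.5 if ux > 0.0 else ix + 0.5) * h
        if dt == dy_:
            iy += 1 if uy > 0.0 else -1
            y = (iy - 0.5 if uy > 0.0 else iy + 0.5) * h
        if dt == dz_:
            iz += 1 if uz > 0.0 else -1
            z = (iz if uz > 0.0 else iz + 1) * h


@njit(cache=True, inline="always")
def _collide_2d(phi, w, px, pz, h, nu_half, nz):
    ix = int(math.floor(px / h + 0.5))
    iz = int(math.floor(pz / h))
    if -nu_half <= ix <= nu_half and 0 <= iz < nz:
        phi[ix + nu_half, iz] += w


@njit(cache=True, inline="always")
def _collide_3d_folded(gf, w, px, py, pz, h, nfx, nfy, nz):
    ix = int(math.floor(px / h + 0.5))
    iy = int(math.floor(py / h + 0.5))
    iz = int(math.floor(pz / h))
    ax = ix if ix >= 0 else -ix
    ay = iy if iy >= 0 else -iy
    if ax < nfx and ay < nfy and 0 <= iz < nz:
        gf[ax, ay, iz] += w


@njit(cache=True)
def mc_slab_response(
    mua,
    mus,
    g,
    n_med,
    n_amb,
    h,
    mode,
    sigma_x,
    ax_air,
    az_air,
    score3d,
    nu_half,
    nfx,
    nfy,
    nz,
    kill_x,
    kill_y,
    kill_z,
    n_photons,
    seed,
):
    """Translation-invariant response fields in a homogeneous slab.

    The slab is laterally unbounded; photons are killed beyond the (kill_x,
    kill_y, kill_z) box around the launch point (matched-boundary
    truncation).  With ``score3d`` False the kernel scores the y-marginal
    field phi2d(x, z) of a beam launched at x ~ N(0, sigma_x) — by
    superposition this equals the fluence of an infinite illumination line
    along y.  With ``score3d`` True it scores the folded 3-D visitation
    field (|x|, |y|, z) of an adjoint detector launch (MODE_COSINE) at the
    origin.

    Fluence is tallied with the collision estimator (weight / mu_t at each
    interaction site): unbiased, and far cheaper than path-length voxel
    walking at the phantom's collision density.  Callers divide by
    (photons x bin volume x mu_t).

    Returns (phi2d, g3d, tallies); the unused field has size 1.
    """
    np.random.seed(seed)
    phi2d = np.zeros((2 * nu_half + 1, nz)) if not score3d else np.zeros((1, 1))
    g3d = np.zeros((nfx, nfy, nz)) if score3d else np.zeros((1, 1, 1))
    tal = np.zeros(N_TALLY)
    mt = mua + mus
    albedo = mus / mt
    eps = 1.0e-12

    for _ in range(n_photons):
        tal[T_LAUNCHED] += 1.0
        px = 0.0
        py = 0.0
        pz = 0.0
        if mode == MODE_COSINE:
            cos_c2 = max(0.0, 1.0 - (n_amb / n_med) ** 2) if n_med > n_amb else 0.0
            ct = math.sqrt(cos_c2 + np.random.random() * (1.0 - cos_c2))
            w = 1.0 - _fresnel_r(ct, n_med, n_amb)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            ux = st * math.cos(phi)
            uy = st * math.sin(phi)
            uz = ct
            tal[T_SPECULAR] += 1.0 - w
        else:
            px = sigma_x * np.random.standard_normal()
            cos_i = az_air
            r_spec = _fresnel_r(cos_i, n_amb, n_med)
            w = 1.0 - r_spec
            tal[T_SPECULAR] += r_spec
            sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
            if sin_i < eps:
                ux, uy, uz = 0.0, 0.0, 1.0
            else:
                sin_t = sin_i * n_amb / n_med
                cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                ux = sin_t * (ax_air / sin_i)
                uy = 0.0
                uz = cos_t

        tau = -math.log(1.0 - np.random.random())
        alive = True
        while alive:
            s = tau / mt
            # surface crossing?
            if uz < 0.0 and pz + uz * s < 0.0:
                t_s = pz / (-uz)
                px += ux * t_s
                py += uy * t_s
                pz = 0.0
                tau -= mt * t_s
                r = _fresnel_r(-uz, n_med, n_amb)
                if np.random.random() < r:
                    uz = -uz
                else:
                    tal[T_ESCAPED] += w
                    alive = False
                continue
            px += ux * s
            py += uy * s
            pz += uz * s
            if abs(px) > kill_x or abs(py) > kill_y or pz > kill_z:
                tal[T_TERMINATED] += w
                alive = False
                continue
            # interaction: collision-estimator tally at the interaction site
            if score3d:
                _collide_3d_folded(g3d, w, px, py, pz, h, nfx, nfy, nz)
            else:
                _collide_2d(phi2d, w, px, pz, h, nu_half, nz)
            la = mua / mt
            tal[T_ABSORBED] += w * la
            w *= albedo
            if w <= 0.0:
                alive = False
                continue
            if w < RR_THRESHOLD:
                if np.random.random() < RR_SURVIVE:
                    tal[T_RR_GAIN] += w * (1.0 / RR_SURVIVE - 1.0)
                    w /= RR_SURVIVE
                else:
                    tal[T_RR_KILLED] += w
                    alive = False
                    continue
            ux, uy, uz = _spin(ux, uy, uz, g)
            tau = -math.log(1.0 - np.random.random())
    return phi2d, g3d, tal


def energy_balance_error(tal: np.ndarray) -> float:
    """Relative bookkeeping error of a kernel tally (should be ~1e-15)."""
    launched = tal[T_LAUNCHED]
    if launched == 0:
        return 0.0
    total = (
        tal[T_SPECULAR]
        + tal[T_ABSORBED]
        + tal[T_ESCAPED]
        + tal[T_TERMINATED]
        + tal[T_RR_KILLED]
        - tal[T_RR_GAIN]
    )
    return abs(total - launched) / launched
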