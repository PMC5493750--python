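"""Numba kernels: torque summation, sweep-and-prune neighbours, Euler loop.

The pair interaction implemented here must stay in sync with the scalar
torque seam in :mod:`lanesim.dynamics` (``pair_torque`` / ``drive_torque``),
which is the single authoritative definition of the model; the unit tests
cross-check the two on random configurations.
"""

import numpy as np
from numba import njit

A_MAX = 1.4  # largest interaction radius of the bidisperse mixture

STATUS_OK = 0
STATUS_DEGENERATE = 1

_R2_DEGENERATE = 1e-24


@njit(cache=True)
def _insertion_sort(order, x):
    """Keep ``order`` sorted by x[order]; fast for nearly sorted input."""
    n = order.shape[0]
    for k in range(1, n):
        j = order[k]
        key = x[j]
        i = k - 1
        while i >= 0 and x[order[i]] > key:
            order[i + 1] = order[i]
            i -= 1
        order[i + 1] = j


@njit(cache=True)
def _min_image(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def _accumulate_torques_sap(x, y, theta, radii, order, B, Lx, Ly, torque):
    """Sweep-and-prune pair scan; accumulates pair torques on both partners.

    Assumes ``order`` sorts x ascending.  Requires Lx >= 4 * A_MAX so the
    x-window never wraps onto itself.  Returns a status code.
    """
    n = x.shape[0]
    torque[:] = 0.0
    for idx in range(n):
        i = order[idx]
        xi = x[i]
        ai = radii[i]
        cutoff = ai + A_MAX
        for k in range(idx + 1, idx + n):
            wrapped = k >= n
            j = order[k - n] if wrapped else order[k]
            dxj = x[j] - xi
            if wrapped:
                dxj += Lx
            if dxj >= cutoff:
                break
            rng = ai + radii[j]
            if dxj >= rng:
                continue
            dy = _min_image(y[i] - y[j], Ly)
            if dy >= rng or dy <= -rng:
                continue
            dx = -dxj  # signed x-component of r_i - r_j
            r2 = dx * dx + dy * dy
            if r2 >= rng * rng:
                continue
            if r2 < _R2_DEGENERATE:
                return STATUS_DEGENERATE
            r = np.sqrt(r2)
            kern = B * (1.0 - r / rng)
            phi = np.arctan2(dy, dx)  # angle of r_i - r_j
            torque[i] += -kern * np.sin(theta[i] - phi)
            # seen from j the centre-to-centre angle is phi + pi
            torque[j] += kern * np.sin(theta[j] - phi)
    return STATUS_OK


@njit(cache=True)
def _accumulate_torques_brute(x, y, theta, radii, B, Lx, Ly, torque):
    """All-pairs torque accumulation (small or narrow boxes)."""
    n = x.shape[0]
    torque[:] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(x[i] - x[j], Lx)
            dy = _min_image(y[i] - y[j], Ly)
            rng = radii[i] + radii[j]
            r2 = dx * dx + dy * dy
            if r2 >= rng * rng:
                continue
            if r2 < _R2_DEGENERATE:
                return STATUS_DEGENERATE
            r = np.sqrt(r2)
            kern = B * (1.0 - r / rng)
            phi = np.arctan2(dy, dx)
            torque[i] += -kern * np.sin(theta[i] - phi)
            torque[j] += kern * np.sin(theta[j] - phi)
    return STATUS_OK


@njit(cache=True)
def advance(
    x, y, theta, ux, uy, radii, theta0, order,
    B, H, v0, dt, Lx, Ly, nsteps, track_unwrapped, use_sap,
):
    """Advance the state by ``nsteps`` forward-Euler steps in place.

    Positions advance along the *current* orientation, then orientations
    take the drive and pair torques evaluated on the same configuration
    (standard forward Euler on the joint system).  ``ux``/``uy`` hold
    unwrapped displacement accumulators when requested.
    """
    n = x.shape[0]
    torque = np.empty(n)
    for _ in range(nsteps):
        if use_sap:
            _insertion_sort(order, x)
            status = _accumulate_torques_sap(
                x, y, theta, radii, order, B, Lx, Ly, torque
            )
        else:
            status = _accumulate_torques_brute(
                x, y, theta, radii, B, Lx, Ly, torque
            )
        if status != STATUS_OK:
            return status
        for i in range(n):
            c = np.cos(theta[i])
            s = np.sin(theta[i])
            ddx = v0 * c * dt
            ddy = v0 * s * dt
            x[i] += ddx
            y[i] += ddy
            if x[i] >= Lx:
                x[i] -= Lx
            elif x[i] < 0.0:
                x[i] += Lx
            if y[i] >= Ly:
                y[i] -= Ly
            elif y[i] < 0.0:
                y[i] += Ly
            if track_unwrapped:
                ux[i] += ddx
                uy[i] += ddy
            theta[i] += dt * (-H * np.sin(theta[i] - theta0[i]) + torque[i])
    return STATUS_OK


@njit(cache=True)
def pairs_sap(x, y, radii, Lx, Ly):
    """Interacting pairs via sweep-and-prune; each unordered pair once."""
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort").astype(np.int64)
    out_i = np.empty(n * 64, dtype=np.int64)
    out_j = np.empty(n * 64, dtype=np.int64)
    m = 0
    for idx in range(n):
        i = order[idx]
        xi = x[i]
        ai = radii[i]
        cutoff = ai + A_MAX
        for k in range(idx + 1, idx + n):
            wrapped = k >= n
            j = order[k - n] if wrapped else order[k]
            dxj = x[j] - xi
            if wrapped:
                dxj += Lx
            if dxj >= cutoff:
                break
            rng = ai + radii[j]
            dy = _min_image(y[i] - y[j], Ly)
            if dxj >= rng or dy >= rng or dy <= -rng:
                continue
            if dxj * dxj + dy * dy < rng * rng:
                if m >= out_i.shape[0]:
                    new_i = np.empty(out_i.shape[0] * 2, dtype=np.int64)
                    new_j = np.empty(out_i.shape[0] * 2, dtype=np.int64)
                    new_i[:m] = out_i[:m]
                    new_j[:m] = out_j[:m]
                    out_i = new_i
                    out_j = new_j
                out_i[m] = i
                out_j[m] = j
                m += 1
    return out_i[:m], out_j[:m]


@njit(cache=True)
def pairs_brute(x, y, radii, Lx, Ly):
    """O(N^2) all-pairs interaction scan (oracle and small-box fallback)."""
    n = x.shape[0]
    out_i = np.empty(n * (n - 1) // 2, dtype=np.int64)
    out_j = np.empty(n * (n - 1) // 2, dtype=np.int64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(x[i] - x[j], Lx)
            dy = _min_image(y[i] - y[j], Ly)
            rng = radii[i] + radii[j]
            if dx * dx + dy * dy < rng * rng:
                out_i[m] = i
                out_j[m] = j
                m += 1
    return out_i[:m], out_j[:m]


@njit(cache=True)
def displacement_histogram(
    x, y, species, Lx, Ly, xmax, ymax, bin_size, hist
):
    """Accumulate pair displacements into per-species-pair 2D histograms.

    ``hist`` has shape (2, 2, nx, ny) indexed by (species_i, species_j)
    with 0 = right, 1 = left; the displacement binned is r_j - r_i
    (minimum image), and each unordered pair contributes to both ordered
    entries at opposite displacements.
    """
    n = x.shape[0]
    nx = hist.shape[2]
    ny = hist.shape[3]
    order = np.argsort(x, kind="mergesort").astype(np.int64)
    for idx in range(n):
        i = order[idx]
        xi = x[i]
        si = 0 if species[i] == 1 else 1
        for k in range(idx + 1, idx + n):
            wrapped = k >= n
            j = order[k - n] if wrapped else order[k]
            dxj = x[j] - xi  # x_j - x_i, >= 0 in sweep order
            if wrapped:
                dxj += Lx
            if dxj >= xmax:
                break
            dy = _min_image(y[j] - y[i], Ly)
            if dy >= ymax or dy < -ymax:
                continue
            sj = 0 if species[j] == 1 else 1
            # r_j - r_i
            ix = int((dxj + xmax) / bin_size)
            iy = int((dy + ymax) / bin_size)
            if 0 <= ix < nx and 0 <= iy < ny:
                hist[si, sj, ix, iy] += 1.0
            # r_i - r_j
            ix = int((-dxj + xmax) / bin_size)
            iy = int((-dy + ymax) / bin_size)
            if 0 <= ix < nx and 0 <= iy < ny:
                hist[sj, si, ix, iy] += 1.0


@njit(cache=True)
def scatter_integrate(
    xr, yr, thr, xl, yl, thl, ar, al,
    B, H, v0, dt, t_max,
    stop_sep_factor, realign_tol, bound_travel,
    rec_every, rec,
):
    """Two-body collision in the unbounded plane, Euler integration.

    Starts with interactions on (the caller places the pair at contact).
    Returns (y_out, t_end, outcome, max_sep) with outcome codes:
    0 = scattered (pair separated and the right mover realigned),
    1 = bound pair (separation never exceeded the interaction range while
    the pair centre travelled ``bound_travel`` transversely),
    2 = time limit reached.

    When ``rec_every`` > 0, rows (t, xr, yr, thr, xl, yl, thl) are
    written into ``rec`` every that many steps; the number of rows used
    is returned alongside.
    """
    rng = ar + al
    yc0 = 0.5 * (yr + yl)
    max_sep = 0.0
    nsteps = int(t_max / dt)
    ever_separated = False
    nrec = 0
    for step in range(nsteps):
        if rec_every > 0 and step % rec_every == 0 and nrec < rec.shape[0]:
            rec[nrec, 0] = step * dt
            rec[nrec, 1] = xr
            rec[nrec, 2] = yr
            rec[nrec, 3] = thr
            rec[nrec, 4] = xl
            rec[nrec, 5] = yl
            rec[nrec, 6] = thl
            nrec += 1
        dx = xr - xl
        dy = yr - yl
        r2 = dx * dx + dy * dy
        r = np.sqrt(r2)
        if r > max_sep:
            max_sep = r
        if r > rng:
            ever_separated = True
        tr = -H * np.sin(thr)          # drive toward Theta = 0
        tl = -H * np.sin(thl - np.pi)  # drive toward Theta = pi
        if r < rng and r2 >= _R2_DEGENERATE:
            kern = B * (1.0 - r / rng)
            phi = np.arctan2(dy, dx)  # angle of r_r - r_l
            tr += -kern * np.sin(thr - phi)
            tl += kern * np.sin(thl - phi)
        xr += v0 * np.cos(thr) * dt
        yr += v0 * np.sin(thr) * dt
        xl += v0 * np.cos(thl) * dt
        yl += v0 * np.sin(thl) * dt
        thr += tr * dt
        thl += tl * dt
        # stopping rules
        if r > stop_sep_factor * rng:
            wr = np.mod(thr + np.pi, 2.0 * np.pi) - np.pi
            if np.abs(wr) < realign_tol:
                return yr, (step + 1) * dt, 0, max_sep, nrec
        if not ever_separated:
            yc = 0.5 * (yr + yl)
            if np.abs(yc - yc0) >= bound_travel:
                return yr, (step + 1) * dt, 1, max_sep, nrec
    return yr, t_max, 2, max_sep, nrec
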