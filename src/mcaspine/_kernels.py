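"""Numba kernels for the bonded-automata solver.

All state lives in flat numpy arrays owned by :class:`mcaspine.core.Ensemble`;
the kernels mutate them in place.  Conventions:

* pair normal force ``fn`` is tension-positive (``fn > 0`` pulls the pair
  together); per-element mean stress ``sigm`` is tension-positive; the
  reported "hydrostatic pressure" (compression-positive) is ``-sigm``.
* the incremental pair law is
  ``dF_n/S = 2 G_i dxi_ij + D_i dsig_i + A_i dsig_j - mean_pair(a dP)``
  with ``D = 1 - 2G/K`` (own effective-mean-stress term), ``A = 4G/(3K)``
  (the volume-dependent many-body term folded into the bond so Newton's
  third law holds exactly), and the Biot pore-pressure push symmetrized
  over the pair.  ``dsig`` is the mean stress of the skeleton (elastic
  pass) only: Hooke feedback acts on the effective stress, and a uniform
  bond stress homogenizes 1:1 into the element mean stress, so the pore
  weight is exactly ``a``.  Both sides are equalized by the 2x2 pair
  partition, which also splits the strain increment between dissimilar
  materials.
* the pore term is evaluated within the current step (elastic pass ->
  fluid state update from the current bond strains -> pore-force pass):
  the pore stiffness K_fl/phi dwarfs the soft-tissue elastic moduli, so a
  one-step lag on it is explosively unstable.
* boundary codes: 0 interior, 1 fixed (v = 0), 2 driven (v_z prescribed).

Run-status codes returned by :func:`run_until`: 0 target force reached,
1 max_steps exhausted, 2 non-finite state, 3 pore collapse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_TARGET = 0
STATUS_MAXSTEPS = 1
STATUS_NAN = 2
STATUS_PORE_COLLAPSE = 3


@njit(cache=True, fastmath=True, inline="always")
def _pair_normal_increment(Gi, Gj, hi, hj, dr, d, S):
    """Solve the pair partition for the normal direction.

    Returns (dxi_i, dxi_j, dF) with equal-and-opposite force by construction:
    2 G_i dxi_i + h_i == 2 G_j dxi_j + h_j and dxi_i + dxi_j == 2 dr / d.
    """
    dxi_i = (4.0 * Gj * dr / d + hj - hi) / (2.0 * (Gi + Gj))
    dxi_j = 2.0 * dr / d - dxi_i
    dF = S * (2.0 * Gi * dxi_i + hi)
    return dxi_i, dxi_j, dF


@njit(cache=True, fastmath=True, error_model="numpy")
def compute_forces(
    pos, vel, omg, frc, trq, nvec,
    pi, pj, rprev, fn, ft, ktq, xi_i, xi_j, xg_i, xg_j, sxi,
    Gp, Dp, Ap, dsigm,
    sig, d, S, q, dt,
):
    """Elastic force pass: pair increments, scatter, raw stress moments.

    Updates the accumulated pair strains (``xi_i``, ``xi_j``, per-element
    sums ``sxi``), normal/tangential forces and rotational-resistance
    torques, and accumulates per-element stress moments into ``sig``
    (volume division and mean-stress bookkeeping happen in
    :func:`finalize_stress`).  Stores the current pair normals in ``nvec``
    for the pore-force pass.
    """
    M = pi.shape[0]
    frc[:, :] = 0.0
    trq[:, :] = 0.0
    sig[:, :] = 0.0
    sxi[:] = 0.0

    for p in range(M):
        i = pi[p]
        j = pj[p]
        rx = pos[j, 0] - pos[i, 0]
        ry = pos[j, 1] - pos[i, 1]
        rz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        nx = rx / r
        ny = ry / r
        nz = rz / r
        nvec[p, 0] = nx
        nvec[p, 1] = ny
        nvec[p, 2] = nz
        dr = r - rprev[p]
        rprev[p] = r

        # relative velocity at the contact point (equal sizes, arm q each)
        wx = omg[i, 0] + omg[j, 0]
        wy = omg[i, 1] + omg[j, 1]
        wz = omg[i, 2] + omg[j, 2]
        cx = wy * nz - wz * ny
        cy = wz * nx - wx * nz
        cz = wx * ny - wy * nx
        vx = vel[j, 0] - vel[i, 0] - q * cx
        vy = vel[j, 1] - vel[i, 1] - q * cy
        vz = vel[j, 2] - vel[i, 2] - q * cz
        vn = vx * nx + vy * ny + vz * nz
        dlx = (vx - vn * nx) * dt
        dly = (vy - vn * ny) * dt
        dlz = (vz - vn * nz) * dt

        Gi = Gp[i]
        Gj = Gp[j]
        # volumetric (mean-stress) coupling acts within a material region;
        # across dissimilar-material bonds the lagged feedback iteration has
        # spectral radius > 1 at high stiffness contrast, so those bonds use
        # the pure pair stiffness (the pore push still applies)
        if Gi == Gj and Dp[i] == Dp[j]:
            hi = Dp[i] * dsigm[i] + Ap[i] * dsigm[j]
            hj = Dp[j] * dsigm[j] + Ap[j] * dsigm[i]
        else:
            hi = 0.0
            hj = 0.0
        dxi_a, dxi_b, dF = _pair_normal_increment(Gi, Gj, hi, hj, dr, d, S)
        xi_i[p] += dxi_a
        xi_j[p] += dxi_b
        fn[p] += dF
        # geometric strain split (by shear moduli only): feeds the fluid's
        # volumetric strain; the constitutive repartition (h-terms) must not,
        # or mean-stress noise is amplified by the pore stiffness K_fl/phi
        gshare = 2.0 * dr / (d * (Gi + Gj))
        xg_i[p] += Gj * gshare
        xg_j[p] += Gi * gshare
        sxi[i] += xg_i[p]
        sxi[j] += xg_j[p]

        # keep the stored tangential force in the plane normal to n
        ftn = ft[p, 0] * nx + ft[p, 1] * ny + ft[p, 2] * nz
        ftx = ft[p, 0] - ftn * nx
        fty = ft[p, 1] - ftn * ny
        ftz = ft[p, 2] - ftn * nz
        kshear = (4.0 * S / d) * (Gi * Gj / (Gi + Gj))
        ftx += kshear * dlx
        fty += kshear * dly
        ftz += kshear * dlz
        ft[p, 0] = ftx
        ft[p, 1] = fty
        ft[p, 2] = ftz

        # rotational resistance of the bond (relative-rotation spring)
        Gpair = 2.0 * Gi * Gj / (Gi + Gj)
        krot = Gpair * S * q * dt
        ktq[p, 0] += krot * (omg[j, 0] - omg[i, 0])
        ktq[p, 1] += krot * (omg[j, 1] - omg[i, 1])
        ktq[p, 2] += krot * (omg[j, 2] - omg[i, 2])

        fx = fn[p] * nx + ftx
        fy = fn[p] * ny + fty
        fz = fn[p] * nz + ftz
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz

        # torque: force couple at arm q plus the rotational-resistance term
        tqx = q * (ny * fz - nz * fy)
        tqy = q * (nz * fx - nx * fz)
        tqz = q * (nx * fy - ny * fx)
        trq[i, 0] += tqx + ktq[p, 0]
        trq[i, 1] += tqy + ktq[p, 1]
        trq[i, 2] += tqz + ktq[p, 2]
        trq[j, 0] += tqx - ktq[p, 0]
        trq[j, 1] += tqy - ktq[p, 1]
        trq[j, 2] += tqz - ktq[p, 2]

        # homogenized stress moments: q * sym(n_a F_b), same for both sides
        sig[i, 0] += q * nx * fx
        sig[i, 1] += q * ny * fy
        sig[i, 2] += q * nz * fz
        sig[i, 3] += q * 0.5 * (nx * fy + ny * fx)
        sig[i, 4] += q * 0.5 * (nx * fz + nz * fx)
        sig[i, 5] += q * 0.5 * (ny * fz + nz * fy)
        sig[j, 0] += q * nx * fx
        sig[j, 1] += q * ny * fy
        sig[j, 2] += q * nz * fz
        sig[j, 3] += q * 0.5 * (nx * fy + ny * fx)
        sig[j, 4] += q * 0.5 * (nx * fz + nz * fx)
        sig[j, 5] += q * 0.5 * (ny * fz + nz * fy)


@njit(cache=True, fastmath=True, error_model="numpy")
def fluid_update(
    pi, pj, rprev, drained, nb,
    mfl, rho_f, Pp, dPp, evol, phi, kperm,
    phi0, dch2, sxi,
    Vsite, S, Kfl, rho0, P0, eta, dt, n_sub,
):
    """Porosity/permeability update, Darcy filtration and the fluid EOS.

    Volumetric strain of each element is geometric: three times the mean of
    the accumulated normal strains of its bonds (exact for affine
    deformation on an isotropic bond set).  The fluid mass ``mfl`` is the
    conserved state and changes only by pairwise antisymmetric transfer,
    with the donor-side cutoff at ``rho <= rho0``.  Returns a status code.
    """
    N = mfl.shape[0]
    M = pi.shape[0]

    for i in range(N):
        ev = 3.0 * sxi[i] / nb[i]
        if phi0[i] + ev <= 0.02 * phi0[i]:
            return STATUS_PORE_COLLAPSE
        evol[i] = ev
        rho_f[i] = mfl[i] / (Vsite * (phi0[i] + ev))
        phi[i] = 1.0 - (1.0 - phi0[i]) / (1.0 + ev)
        kperm[i] = phi[i] * dch2[i]

    dtf = dt / n_sub
    for _ in range(n_sub):
        for p in range(M):
            i = pi[p]
            j = pj[p]
            ri = rho_f[i]
            rj = rho_f[j]
            if ri > rj:
                if ri <= rho0:
                    continue
            else:
                if rj <= rho0:
                    continue
            ksum = kperm[i] + kperm[j]
            if ksum <= 0.0:
                continue
            kh = 2.0 * kperm[i] * kperm[j] / ksum
            dm = Kfl * (kh / eta) * S / rprev[p] * (rj - ri) * dtf
            # do not let the donor drop below the equilibrium density
            if dm > 0.0:
                cap = (rj - rho0) * Vsite * (phi0[j] + evol[j])
                if dm > cap:
                    dm = cap
            else:
                cap = (ri - rho0) * Vsite * (phi0[i] + evol[i])
                if -dm > cap:
                    dm = -cap
            mfl[i] += dm
            mfl[j] -= dm
            rho_f[i] = mfl[i] / (Vsite * (phi0[i] + evol[i]))
            rho_f[j] = mfl[j] / (Vsite * (phi0[j] + evol[j]))
        for i in range(N):
            if drained[i]:
                mfl[i] = rho0 * Vsite * (phi0[i] + evol[i])
                rho_f[i] = rho0

    for i in range(N):
        Pnew = P0 + Kfl * (rho_f[i] / rho0 - 1.0)
        dPp[i] = Pnew - Pp[i]
        Pp[i] = Pnew
    return 0


@njit(cache=True, fastmath=True, error_model="numpy")
def apply_pore_forces(pi, pj, nvec, fn, frc, sig, biot, dPp, Gp, nb, Vsite, d, q):
    """Pore-pressure push on every bond, within-step and conservative.

    The force is the derivative of the per-element fluid compression energy
    V * integral(a P dev) with respect to the bond elongation, using the
    same geometric strain shares w = G_other/(G_i + G_j) that feed ``evol``:
    dF = -(a_i dP_i c_i + a_j dP_j c_j), c_side = 6 V w_side / (nb_side d).
    In a full-coordination bulk c reduces to S/2, which homogenizes to the
    Biot effective-stress reduction -a dP on the diagonal of the total
    stress; at free surfaces and material interfaces the energy-consistent
    weights prevent the spurious pumping of a non-symmetric force law.
    """
    M = pi.shape[0]
    for p in range(M):
        i = pi[p]
        j = pj[p]
        Gi = Gp[i]
        Gj = Gp[j]
        wi = Gj / (Gi + Gj)
        wj = Gi / (Gi + Gj)
        ci = 6.0 * Vsite * wi / (nb[i] * d)
        cj = 6.0 * Vsite * wj / (nb[j] * d)
        dF = -(biot[i] * dPp[i] * ci + biot[j] * dPp[j] * cj)
        if dF == 0.0:
            continue
        fn[p] += dF
        nx = nvec[p, 0]
        ny = nvec[p, 1]
        nz = nvec[p, 2]
        fx = dF * nx
        fy = dF * ny
        fz = dF * nz
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
        sig[i, 0] += q * nx * fx
        sig[i, 1] += q * ny * fy
        sig[i, 2] += q * nz * fz
        sig[i, 3] += q * nx * fy
        sig[i, 4] += q * nx * fz
        sig[i, 5] += q * ny * fz
        sig[j, 0] += q * nx * fx
        sig[j, 1] += q * ny * fy
        sig[j, 2] += q * nz * fz
        sig[j, 3] += q * nx * fy
        sig[j, 4] += q * nx * fz
        sig[j, 5] += q * ny * fz


@njit(cache=True, fastmath=True, error_model="numpy")
def effective_mean_stress(sig, sigm, dsigm, Vsite, beta):
    """Mean stress of the elastic (skeleton/effective) pass, before the pore
    push is added; this is what the constitutive volumetric terms feed on.

    The increments are under-relaxed (factor ``beta``): the per-step sums
    telescope, so the accumulated volumetric force still converges to the
    same value, while the loop gain of the lagged mean-stress iteration --
    which exceeds unity at high-contrast material interfaces -- is scaled
    down by ``beta``.  ``sigm`` tracks the relaxed state; ``sig`` still
    holds raw moments here (divided by volume at the end of the step).
    """
    N = sig.shape[0]
    for i in range(N):
        sm = (sig[i, 0] + sig[i, 1] + sig[i, 2]) / (3.0 * Vsite)
        dsigm[i] = beta * (sm - sigm[i])
        sigm[i] += dsigm[i]


@njit(cache=True, fastmath=True, error_model="numpy")
def finalize_stress(sig, frc, trq, vel, omg, bc, Vsite, alpha):
    """Divide stress moments by the element volume (total stress, pore push
    included) and apply non-viscous local damping to interior particles."""
    N = sig.shape[0]
    for i in range(N):
        for c in range(6):
            sig[i, c] /= Vsite
        # damping never applies to boundary particles: their motion is
        # prescribed and their force sum is the measured reaction
        if alpha > 0.0 and bc[i] == 0:
            for c in range(3):
                f = frc[i, c]
                v = vel[i, c]
                if v > 0.0:
                    frc[i, c] = f - alpha * abs(f)
                elif v < 0.0:
                    frc[i, c] = f + alpha * abs(f)
                t = trq[i, c]
                w = omg[i, c]
                if w > 0.0:
                    trq[i, c] = t - alpha * abs(t)
                elif w < 0.0:
                    trq[i, c] = t + alpha * abs(t)


@njit(cache=True, error_model="numpy")
def run_until(
    # particle state
    pos, vel, omg, frc, trq, fext, mass, inert, bc,
    # pair state
    pi, pj, rprev, fn, ft, ktq, xi_i, xi_j, xg_i, xg_j, sxi, nvec,
    # material arrays
    Gp, Dp, Ap, biot,
    # stress state
    sig, sigm, dsigm,
    # fluid state
    fluid_on, drained, nb, mfl, rho_f, Pp, dPp, evol, phi, kperm, phi0, dch2,
    Kfl, rho0, P0, eta, n_sub,
    # geometry / numerics
    d, S, q, Vsite, dt, alpha, beta, clamp_lateral,
    # protocol
    v_target, ramp_time, target_force, max_steps,
    # time state [t, u] mutated in place
    clock,
    # sampling
    sample_every, smooth_window, stop_on_bottom,
    out_t, out_u, out_ftop, out_fbot,
):
    """Advance velocity-Verlet steps until the smoothed reaction force on the
    driven layer reaches ``target_force`` (checked after the ramp).

    Returns (status, n_steps_done, n_samples).
    """
    N = pos.shape[0]
    max_samples = out_t.shape[0]
    nsamp = 0
    status = STATUS_MAXSTEPS

    for step in range(max_steps):
        t = clock[0]
        if ramp_time > 0.0 and t < ramp_time:
            v_drive = v_target * t / ramp_time
        else:
            v_drive = v_target

        # --- first half-kick + drift
        for i in range(N):
            if bc[i] == 0:
                hm = 0.5 * dt / mass[i]
                vel[i, 0] += hm * (frc[i, 0] + fext[i, 0])
                vel[i, 1] += hm * (frc[i, 1] + fext[i, 1])
                vel[i, 2] += hm * (frc[i, 2] + fext[i, 2])
                hj_ = 0.5 * dt / inert[i]
                omg[i, 0] += hj_ * trq[i, 0]
                omg[i, 1] += hj_ * trq[i, 1]
                omg[i, 2] += hj_ * trq[i, 2]
            else:
                omg[i, 0] = 0.0
                omg[i, 1] = 0.0
                omg[i, 2] = 0.0
                if clamp_lateral:
                    vel[i, 0] = 0.0
                    vel[i, 1] = 0.0
                else:
                    hm = 0.5 * dt / mass[i]
                    vel[i, 0] += hm * frc[i, 0]
                    vel[i, 1] += hm * frc[i, 1]
                vel[i, 2] = -v_drive if bc[i] == 2 else 0.0
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt

        # --- elastic pass at the new positions
        compute_forces(
            pos, vel, omg, frc, trq, nvec,
            pi, pj, rprev, fn, ft, ktq, xi_i, xi_j, xg_i, xg_j, sxi,
            Gp, Dp, Ap, dsigm,
            sig, d, S, q, dt,
        )

        # mean stress of the skeleton (effective) response feeds the
        # volumetric constitutive terms of the next step
        effective_mean_stress(sig, sigm, dsigm, Vsite, beta)

        # --- fluid state from the current strains, then the pore push
        if fluid_on:
            st = fluid_update(
                pi, pj, rprev, drained, nb,
                mfl, rho_f, Pp, dPp, evol, phi, kperm,
                phi0, dch2, sxi,
                Vsite, S, Kfl, rho0, P0, eta, dt, n_sub,
            )
            if st != 0:
                return st, step + 1, nsamp
            apply_pore_forces(pi, pj, nvec, fn, frc, sig, biot, dPp, Gp, nb, Vsite, d, q)

        finalize_stress(sig, frc, trq, vel, omg, bc, Vsite, alpha)

        # --- second half-kick
        for i in range(N):
            if bc[i] == 0:
                hm = 0.5 * dt / mass[i]
                vel[i, 0] += hm * (frc[i, 0] + fext[i, 0])
                vel[i, 1] += hm * (frc[i, 1] + fext[i, 1])
                vel[i, 2] += hm * (frc[i, 2] + fext[i, 2])
                hj_ = 0.5 * dt / inert[i]
                omg[i, 0] += hj_ * trq[i, 0]
                omg[i, 1] += hj_ * trq[i, 1]
                omg[i, 2] += hj_ * trq[i, 2]
            elif not clamp_lateral:
                hm = 0.5 * dt / mass[i]
                vel[i, 0] += hm * frc[i, 0]
                vel[i, 1] += hm * frc[i, 1]

        clock[0] = t + dt
        clock[1] += v_drive * dt

        # --- sampling, stop detection, health check
        if (step + 1) % sample_every == 0 and nsamp < max_samples:
            ftop = 0.0
            fbot = 0.0
            check = 0.0
            for i in range(N):
                if bc[i] == 2:
                    ftop += frc[i, 2]
                elif bc[i] == 1:
                    fbot -= frc[i, 2]
                check += vel[i, 0] + vel[i, 1] + vel[i, 2]
            if not np.isfinite(check + ftop):
                return STATUS_NAN, step + 1, nsamp
            out_t[nsamp] = clock[0]
            out_u[nsamp] = clock[1]
            out_ftop[nsamp] = ftop
            out_fbot[nsamp] = fbot
            nsamp += 1
            if nsamp >= max_samples:
                return STATUS_MAXSTEPS, step + 1, nsamp
            if clock[0] >= ramp_time and nsamp >= smooth_window:
                acc = 0.0
                for s in range(nsamp - smooth_window, nsamp):
                    acc += out_fbot[s] if stop_on_bottom else out_ftop[s]
                if acc / smooth_window >= target_force:
                    return STATUS_TARGET, step + 1, nsamp

    return status, max_steps, nsamp
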