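"""Numba kernels for the Monte-Carlo flight loop.

The navigator state machine here follows :mod:`mothnav.navigator` step for
step (same transition rules, same timing conventions); it is compiled so that
thousands of flights against precomputed plume fields run in seconds.  The
per-flight random stream (wind fluctuations at the flier, cast angles and
sides) is numba's internal Mersenne-Twister, seeded per flight.

Flight status codes: 0 = still running (internal), 1 = crossed x = 0,
2 = escaped downstream, 3 = timed out after starting, 4 = never started.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI_32 = (2.0 * math.pi) ** 1.5

STATUS_CROSSED = 1
STATUS_ESCAPED = 2
STATUS_TIMEOUT = 3
STATUS_NEVER_STARTED = 4

MODE_WAITING = 0
MODE_IN_PUFF = 1
MODE_SURGE = 2
MODE_CAST = 3


@njit(cache=True)
def _gust_at(t, gust_starts, gust_amps, hold):
    g = 0.0
    for i in range(gust_starts.shape[0]):
        if gust_starts[i] <= t < gust_starts[i] + hold:
            g += gust_amps[i]
    return g


@njit(cache=True)
def _concentration(
    x,
    y,
    k,
    pulse_steps,
    n_puffs,
    lengths,
    traj_x,
    traj_y,
    dt,
    a_h,
    a_z,
    b_h,
    b_z,
    sigma_floor,
    mass,
    z0,
    printed_vertical,
):
    """Summed puff concentration at (x, y) on the flight plane at step k."""
    total = 0.0
    max_len = traj_x.shape[1]
    i_lo = (k - max_len) // pulse_steps
    if i_lo < 0:
        i_lo = 0
    i_hi = k // pulse_steps
    if i_hi > n_puffs - 1:
        i_hi = n_puffs - 1
    for i in range(i_lo, i_hi + 1):
        a = k - i * pulse_steps
        if a < 0 or a >= lengths[i]:
            continue
        age = a * dt
        sh = a_h * age**b_h
        if sh < sigma_floor:
            sh = sigma_floor
        sz = a_z * age**b_z
        if sz < sigma_floor:
            sz = sigma_floor
        dx = x - traj_x[i, a]
        dy = y - traj_y[i, a]
        e = (dx * dx + dy * dy) / (2.0 * sh * sh)
        if e > 60.0:
            continue
        vert = 1.0
        if printed_vertical:
            vert = math.exp(-(z0 * z0) / (sz * sz))
        total += mass * vert / (TWO_PI_32 * sh * sh * sz) * math.exp(-e)
    return total


@njit(cache=True)
def run_flight_kernel(
    # start and time grid
    x0,
    y0,
    k0,
    n_steps_max,
    dt,
    # plume field
    pulse_steps,
    lengths,
    traj_x,
    traj_y,
    # plume constants
    a_h,
    a_z,
    b_h,
    b_z,
    sigma_floor,
    mass,
    threshold,
    z0,
    printed_vertical,
    # wind
    u_mean,
    ti,
    gust_starts,
    gust_amps,
    gust_hold,
    meander_amp,
    meander_period,
    # navigator
    ground_speed,
    alpha_min_deg,
    alpha_max_deg,
    use_measured_tc,
    tau,
    surge_from_entry,
    # termination
    x_escape,
    seed,
    # output buffers (length >= n_steps_max + 1)
    out_x,
    out_y,
    out_mode,
):
    """Run one flight; returns scalar outcomes, trajectory in the buffers.

    Returns
    -------
    (status, t_start, t_cross, y_cross, flight_time, search_time,
     n_detections, n_search_cycles, n_counter_turns, path_length,
     first_tc, n_recorded)
    """
    np.random.seed(seed)

    n_puffs = lengths.shape[0]
    sigma_w = ti * u_mean
    alpha_span = alpha_max_deg - alpha_min_deg

    x = x0
    y = y0
    mode = MODE_WAITING
    time_in_mode = 0.0
    t_c = 0.0
    cast_cos = 1.0
    cast_sin = 0.0
    side = 1.0

    started = False
    t_start = -1.0
    t_cross = -1.0
    y_cross = 0.0
    status = 0
    n_det = 0
    n_cycles = 0
    n_turns = 0
    search_time = 0.0
    path_length = 0.0
    first_tc = -1.0

    out_x[0] = x
    out_y[0] = y
    out_mode[0] = mode
    rec = 0

    for step_i in range(n_steps_max):
        k = k0 + step_i
        t = k * dt

        c = _concentration(
            x, y, k, pulse_steps, n_puffs, lengths, traj_x, traj_y, dt,
            a_h, a_z, b_h, b_z, sigma_floor, mass, z0, printed_vertical,
        )
        detected = c >= threshold

        # --- state machine (mirrors navigator.step) -----------------------
        moving = True
        if mode == MODE_WAITING:
            if detected:
                mode = MODE_IN_PUFF
                time_in_mode = dt
                started = True
                t_start = t
                n_det += 1
            else:
                moving = False
        elif mode == MODE_IN_PUFF:
            if detected:
                time_in_mode += dt
            else:
                t_c = time_in_mode
                if first_tc < 0.0:
                    first_tc = t_c
                surge_budget = 0.0 if surge_from_entry else (t_c if use_measured_tc else tau)
                if surge_budget <= 1e-12:
                    mode = MODE_CAST
                    angle = math.radians(alpha_min_deg + alpha_span * np.random.random())
                    cast_cos = math.cos(angle)
                    cast_sin = math.sin(angle)
                    side = 1.0 if np.random.random() < 0.5 else -1.0
                    n_cycles += 1
                    time_in_mode = dt
                else:
                    mode = MODE_SURGE
                    time_in_mode = dt
        elif mode == MODE_SURGE:
            if detected:
                mode = MODE_IN_PUFF
                time_in_mode = dt
                n_det += 1
            else:
                dur = t_c if use_measured_tc else tau
                if time_in_mode >= dur - 1e-12:
                    mode = MODE_CAST
                    angle = math.radians(alpha_min_deg + alpha_span * np.random.random())
                    cast_cos = math.cos(angle)
                    cast_sin = math.sin(angle)
                    side = 1.0 if np.random.random() < 0.5 else -1.0
                    n_cycles += 1
                    time_in_mode = dt
                else:
                    time_in_mode += dt
        else:  # CAST
            if detected:
                mode = MODE_IN_PUFF
                time_in_mode = dt
                n_det += 1
            else:
                dur = t_c if use_measured_tc else tau
                if time_in_mode >= dur - 1e-12:
                    side = -side
                    n_turns += 1
                    time_in_mode = dt
                else:
                    time_in_mode += dt

        # --- move ----------------------------------------------------------
        if moving:
            u = u_mean + _gust_at(t, gust_starts, gust_amps, gust_hold)
            u += sigma_w * np.random.standard_normal()
            v = sigma_w * np.random.standard_normal()
            if meander_amp > 0.0:
                v += meander_amp * u_mean * math.sin(2.0 * math.pi * t / meander_period)
            wmag = math.sqrt(u * u + v * v)
            if wmag < 1e-12:
                ux = -1.0
                uy = 0.0
            else:
                ux = -u / wmag
                uy = -v / wmag
            if mode == MODE_CAST:
                s = cast_sin * side
                hx = cast_cos * ux - s * uy
                hy = s * ux + cast_cos * uy
                search_time += dt
            else:
                hx = ux
                hy = uy
            xn = x + ground_speed * dt * hx
            yn = y + ground_speed * dt * hy

            if x > 0.0 and xn <= 0.0:
                frac = x / (x - xn)
                y_cross = y + frac * (yn - y)
                t_cross = t + frac * dt
                path_length += ground_speed * dt * frac
                if mode == MODE_CAST:
                    search_time += dt * (frac - 1.0)
                status = STATUS_CROSSED
                rec = step_i + 1
                out_x[rec] = 0.0
                out_y[rec] = y_cross
                out_mode[rec] = mode
                break

            path_length += ground_speed * dt
            x = xn
            y = yn

        rec = step_i + 1
        out_x[rec] = x
        out_y[rec] = y
        out_mode[rec] = mode

        if moving and x > x_escape:
            status = STATUS_ESCAPED
            break

    if status == 0:
        status = STATUS_TIMEOUT if started else STATUS_NEVER_STARTED

    flight_time = t_cross - t_start if status == STATUS_CROSSED else -1.0
    return (
        status,
        t_start,
        t_cross,
        y_cross,
        flight_time,
        search_time,
        n_det,
        n_cycles,
        n_turns,
        path_length,
        first_tc,
        rec,
    )
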