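"""Compiled event loop of the simulator.

This module holds the numba-jitted core that executes the event-driven
schedule (activate the individual with the smallest clock, resolve its
action, reschedule it) for the full stabilization + recording protocol.
The behavioural rules mirror :mod:`emobook.agents` and the bookkeeping
formulas mirror :mod:`emobook.dynamics`; equivalence between the two layers
is asserted by the test suite (exactly for the curves, statistically for
partner choice).

LIKE values are stored with per-dyad last-update timestamps and decayed
lazily: a read applies the closed-form idle decay over the elapsed gap,
which the decay semigroup law makes equivalent to eager per-minute decay.
Grooming bouts are chains of 1-minute grooming actions (continuation
probability per minute), so every write carries the timestamp of its own
minute and recording triggers never observe a future-stamped value.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# counter slots (order is part of the kernel's output contract)
COUNTER_NAMES = (
    "activations", "rest", "groom_minutes", "groom_bouts", "attacks",
    "aggressive_signals", "submissive_signals", "affiliative_signals",
    "approaches", "random_walks", "avoids", "leaves", "like_writes",
    "flees", "prox_samples",
)
(C_ACT, C_REST, C_GROOM_MIN, C_BOUTS, C_ATTACK, C_AGSIG, C_SUBSIG, C_AFFSIG,
 C_APPROACH, C_WALK, C_AVOID, C_LEAVE, C_LIKE_WRITES, C_FLEE,
 C_PROX) = range(15)

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def decay_value(v, dt, dec_exp, k_dec, lhw, lb, lin_rate):
    """Idle decay of a LIKE value over a gap of ``dt`` minutes."""
    if dt <= 0.0:
        return v
    if dec_exp:
        if lhw > 0.0:
            v = v * 0.5 ** (dt / lhw)
        else:
            v = v - lin_rate * dt
    else:
        if v <= lb:
            return lb
        x0 = math.log(1.0 / v - 1.0) / k_dec
        ex = k_dec * (x0 + dt)
        v = 0.0 if ex > 700.0 else 1.0 / (1.0 + math.exp(ex))
    return v if v > lb else lb


@njit(cache=True)
def increase_value(v, m, inc_linear, a, k_inc, lb, ub):
    """Increase of a LIKE value over ``m`` minutes of received grooming."""
    if m <= 0.0:
        return v
    if inc_linear:
        v = v + a * m
    else:
        if v >= ub:
            return ub
        if v < lb:
            v = lb
        x0 = math.log(v / (1.0 - v)) / k_inc
        ex = -k_inc * (x0 + m)
        v = 1.0 if ex < -700.0 else 1.0 / (1.0 + math.exp(ex))
    return v if v < ub else ub


@njit(cache=True)
def _relax(v, dt, base, hl):
    """Exponential relaxation of an emotional state toward its baseline."""
    if dt <= 0.0:
        return v
    return base + (v - base) * 0.5 ** (dt / hl)


@njit(cache=True)
def _min_image(d, extent):
    return (d + 0.5 * extent) % extent - 0.5 * extent


@njit(cache=True)
def run_kernel(seed, n,
               # dynamics
               inc_linear, dec_exp, a, k_inc, k_dec, lhw, lb, ub, lin_rate,
               # behaviour
               lps, cont, sat_gain, sat_hl, anx_atk, anx_sig, anx_hl,
               ar_base, ar_hl, ar_bump, agon_p, flee_p, affil_sig_p, leave_p,
               avoid_fear_thr, avoid_dist, avoid_anx_thr, cohesion_dist,
               fear_damp, pursuit_minutes, satiation_strength, anx_prox,
               anx_relief, pscan, half_view,
               # world
               width, height, percep_r, reach, step,
               # schedule (absolute minutes; integers as floats)
               t_stab, t_end, snap_times, like_times, prox_interval,
               prox_radius,
               # outputs (preallocated)
               snapshots, like_samples, groom_minutes, prox_counts, counters,
               spread_sum):
    np.random.seed(seed)

    # --- initial state: dominance ladder, FEAR, positions, clocks ---------
    dom = np.empty(n)
    for i in range(n):
        dom[i] = (n - i) / n  # rank i+1
    max_gap = dom[0] - dom[n - 1]
    fear = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            g = dom[j] - dom[i]
            fear[i, j] = g / max_gap if g > 0.0 else 0.0

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    for i in range(n):
        x[i] = np.random.random() * width
        y[i] = np.random.random() * height
        heading[i] = np.random.random() * TWO_PI

    my_time = np.zeros(n)
    like = np.full((n, n), lb)
    like_t = np.zeros((n, n))

    ar_v = np.full(n, ar_base)
    ar_t = np.zeros(n)
    anx_v = np.zeros(n)
    anx_t = np.zeros(n)
    sat_v = np.zeros(n)
    sat_t = np.zeros(n)

    grooming_with = np.full(n, -1, dtype=np.int64)
    pursue = np.full(n, -1, dtype=np.int64)
    pursue_until = np.zeros(n)
    groomed_by = np.full(n, -1, dtype=np.int64)
    flee_from = np.full(n, -1, dtype=np.int64)

    perc = np.empty(n, dtype=np.int64)
    pdist = np.empty(n)
    wts = np.empty(n)
    low = np.empty(n, dtype=np.int64)

    n_snap = snap_times.shape[0]
    n_like = like_times.shape[0]
    snap_idx = 0
    like_idx = 0
    next_prox = t_stab
    percep_r2 = percep_r * percep_r
    prox_r2 = prox_radius * prox_radius

    while True:
        # next activation: smallest clock, ties broken by id (first index)
        i = 0
        t = my_time[0]
        for j in range(1, n):
            if my_time[j] < t:
                t = my_time[j]
                i = j
        tt = t if t < t_end else t_end

        # recording triggers at or before the activation instant
        while snap_idx < n_snap and snap_times[snap_idx] <= tt:
            s = snap_times[snap_idx]
            for p in range(n):
                for q in range(n):
                    if p == q:
                        snapshots[snap_idx, p, q] = np.nan
                    else:
                        snapshots[snap_idx, p, q] = decay_value(
                            like[p, q], s - like_t[p, q],
                            dec_exp, k_dec, lhw, lb, lin_rate)
            snap_idx += 1
        while like_idx < n_like and like_times[like_idx] <= tt:
            s = like_times[like_idx]
            for p in range(n):
                for q in range(n):
                    if p == q:
                        like_samples[like_idx, p, q] = np.nan
                    else:
                        like_samples[like_idx, p, q] = decay_value(
                            like[p, q], s - like_t[p, q],
                            dec_exp, k_dec, lhw, lb, lin_rate)
            like_idx += 1
        while next_prox <= tt:
            dsum = 0.0
            for p in range(n):
                for q in range(p + 1, n):
                    dx = _min_image(x[q] - x[p], width)
                    dy = _min_image(y[q] - y[p], height)
                    d2 = dx * dx + dy * dy
                    dsum += math.sqrt(d2)
                    if d2 <= prox_r2:
                        prox_counts[p, q] += 1
                        prox_counts[q, p] += 1
            spread_sum[0] += dsum / (n * (n - 1) / 2.0)
            counters[C_PROX] += 1
            next_prox += prox_interval

        if t >= t_end:
            break

        counters[C_ACT] += 1

        # passively being groomed: occupied for this minute
        if groomed_by[i] >= 0:
            my_time[i] = t + 1.0
            continue

        # ongoing bout: continue grooming with fixed per-minute probability
        acted = False
        if grooming_with[i] >= 0:
            j = grooming_with[i]
            if np.random.random() < cont:
                dt = t - like_t[j, i]
                v = decay_value(like[j, i], dt, dec_exp, k_dec, lhw, lb, lin_rate)
                v = increase_value(v, 1.0, inc_linear, a, k_inc, lb, ub)
                like[j, i] = v
                like_t[j, i] = t + 1.0
                counters[C_LIKE_WRITES] += 1
                sv = _relax(sat_v[j], t - sat_t[j], 0.0, sat_hl) + sat_gain
                sat_v[j] = sv if sv < 1.0 else 1.0
                sat_t[j] = t
                si = _relax(sat_v[i], t - sat_t[i], 0.0, sat_hl) + sat_gain
                sat_v[i] = si if si < 1.0 else 1.0
                sat_t[i] = t
                axj = _relax(anx_v[j], t - anx_t[j], 0.0, anx_hl) - anx_relief
                anx_v[j] = axj if axj > 0.0 else 0.0
                anx_t[j] = t
                axi = _relax(anx_v[i], t - anx_t[i], 0.0, anx_hl) - anx_relief
                anx_v[i] = axi if axi > 0.0 else 0.0
                anx_t[i] = t
                if t >= t_stab and t < t_end:
                    groom_minutes[i, j] += 1.0
                counters[C_GROOM_MIN] += 1
                my_time[i] = t + 1.0
                my_time[j] = t + 1.0
                acted = True
            else:
                grooming_with[i] = -1
                groomed_by[j] = -1
                if np.random.random() < leave_p:
                    dx = _min_image(x[j] - x[i], width)
                    dy = _min_image(y[j] - y[i], height)
                    d = math.hypot(dx, dy)
                    if d > 1e-12:
                        x[i] = (x[i] - dx / d * step) % width
                        y[i] = (y[i] - dy / d * step) % height
                        heading[i] = math.atan2(-dy, -dx)
                    counters[C_LEAVE] += 1
                    my_time[i] = t + 1.0
                    acted = True
        if acted:
            continue

        # recently attacked: avoid the attacker with elevated probability
        if flee_from[i] >= 0:
            k = flee_from[i]
            flee_from[i] = -1
            if np.random.random() < flee_p:
                dx = _min_image(x[k] - x[i], width)
                dy = _min_image(y[k] - y[i], height)
                d = math.hypot(dx, dy)
                if d > 1e-12:
                    x[i] = (x[i] - dx / d * step) % width
                    y[i] = (y[i] - dy / d * step) % height
                    heading[i] = math.atan2(-dy, -dx)
                counters[C_FLEE] += 1
                my_time[i] = t + 1.0
                continue

        # arousal gates activity
        ar = _relax(ar_v[i], t - ar_t[i], ar_base, ar_hl)
        ar_v[i] = ar
        ar_t[i] = t
        if np.random.random() >= ar:
            counters[C_REST] += 1
            my_time[i] = t + 1.0
            continue

        # perception (scan event widens the view to 360 degrees)
        full = np.random.random() < pscan
        cnt = 0
        for j in range(n):
            if j == i:
                continue
            dx = _min_image(x[j] - x[i], width)
            dy = _min_image(y[j] - y[i], height)
            d2 = dx * dx + dy * dy
            if d2 > percep_r2:
                continue
            if not full:
                bearing = math.atan2(dy, dx)
                diff = (bearing - heading[i] + math.pi) % TWO_PI - math.pi
                if abs(diff) > half_view:
                    continue
            perc[cnt] = j
            pdist[cnt] = math.sqrt(d2)
            cnt += 1
        if cnt == 0:
            # solitary: keep searching in roughly the same direction
            heading[i] += (np.random.random() - 0.5) * (math.pi / 3.0)
            x[i] = (x[i] + math.cos(heading[i]) * step) % width
            y[i] = (y[i] + math.sin(heading[i]) * step) % height
            counters[C_WALK] += 1
            my_time[i] = t + 1.0
            continue

        # proximity of much-feared dominants raises anxiety
        anx = _relax(anx_v[i], t - anx_t[i], 0.0, anx_hl)
        for c in range(cnt):
            if fear[i, perc[c]] > avoid_fear_thr and pdist[c] < avoid_dist:
                anx += anx_prox
        anx_v[i] = anx if anx < 1.0 else 1.0
        anx_t[i] = t

        # anxious avoidance of a nearby much-feared dominant
        if anx > avoid_anx_thr:
            avoided = False
            for c in range(cnt):
                j = perc[c]
                if fear[i, j] > avoid_fear_thr and pdist[c] < avoid_dist:
                    dx = _min_image(x[j] - x[i], width)
                    dy = _min_image(y[j] - y[i], height)
                    d = math.hypot(dx, dy)
                    if d > 1e-12:
                        x[i] = (x[i] - dx / d * step) % width
                        y[i] = (y[i] - dy / d * step) % height
                        heading[i] = math.atan2(-dy, -dx)
                    counters[C_AVOID] += 1
                    my_time[i] = t + 1.0
                    avoided = True
                    break
            if avoided:
                continue

        # ongoing pursuit: stay committed to a previously chosen partner
        j = -1
        dj = 0.0
        if pursue[i] >= 0:
            jj = pursue[i]
            dx = _min_image(x[jj] - x[i], width)
            dy = _min_image(y[jj] - y[i], height)
            d = math.hypot(dx, dy)
            if t >= pursue_until[i] or d > percep_r:
                pursue[i] = -1  # lost sight of, or lost interest in, the target
            else:
                j = jj
                dj = d

        if j < 0 and np.random.random() < anx_v[i]:
            # anxious: seek out the preferred partner (the strongest
            # established bond, LIKE >= 0.5) to groom; grooming is
            # anxiolytic and overrides satiation
            best = -1
            bw = -1.0
            for c in range(cnt):
                k = perc[c]
                lv = decay_value(like[i, k], t - like_t[i, k],
                                 dec_exp, k_dec, lhw, lb, lin_rate)
                w = lv * (1.0 - fear_damp * fear[i, k])
                if w > bw and lv >= 0.5:
                    bw = w
                    best = c
            if best >= 0:
                j = perc[best]
                dj = pdist[best]
                pursue[i] = j
                pursue_until[i] = t + pursuit_minutes

        if j < 0:
            # agonism, directed down-hierarchy; never touches LIKE
            if np.random.random() < agon_p:
                nlow = 0
                for c in range(cnt):
                    if dom[perc[c]] < dom[i]:
                        low[nlow] = perc[c]
                        nlow += 1
                if nlow > 0:
                    k = low[np.random.randint(0, nlow)]
                    if np.random.random() < 0.5:
                        gain = anx_atk
                        counters[C_ATTACK] += 1
                    else:
                        gain = anx_sig
                        counters[C_AGSIG] += 1
                    ak = _relax(anx_v[k], t - anx_t[k], 0.0, anx_hl) + gain
                    anx_v[k] = ak if ak < 1.0 else 1.0
                    anx_t[k] = t
                    flee_from[k] = i
                else:
                    counters[C_SUBSIG] += 1
                my_time[i] = t + 1.0
                continue

            # satisfaction satiates the drive to seek affiliation
            sat = _relax(sat_v[i], t - sat_t[i], 0.0, sat_hl)
            sat_v[i] = sat
            sat_t[i] = t
            if np.random.random() < satiation_strength * sat:
                # group cohesion: drift back toward the visible group centroid
                cx = 0.0
                cy = 0.0
                for c in range(cnt):
                    k = perc[c]
                    cx += _min_image(x[k] - x[i], width)
                    cy += _min_image(y[k] - y[i], height)
                cx /= cnt
                cy /= cnt
                dcen = math.hypot(cx, cy)
                if dcen > cohesion_dist:
                    x[i] = (x[i] + cx / dcen * step) % width
                    y[i] = (y[i] + cy / dcen * step) % height
                    heading[i] = math.atan2(cy, cx)
                else:
                    heading[i] = np.random.random() * TWO_PI
                    x[i] = (x[i] + math.cos(heading[i]) * step) % width
                    y[i] = (y[i] + math.sin(heading[i]) * step) % height
                counters[C_WALK] += 1
                my_time[i] = t + 1.0
                continue

            # affiliative partner choice: propose a perceived partner with
            # probability falling off with distance (interaction opportunity
            # is local), accept with the LPS-LIKE mixing damped by FEAR, so
            # overall grooming propensity itself tracks the LIKE landscape
            tot = 0.0
            for c in range(cnt):
                wts[c] = 1.0 / (1.0 + pdist[c])
                tot += wts[c]
            u = np.random.random() * tot
            acc = 0.0
            sel = cnt - 1
            for c in range(cnt):
                acc += wts[c]
                if u < acc:
                    sel = c
                    break
            k = perc[sel]
            lv = decay_value(like[i, k], t - like_t[i, k],
                             dec_exp, k_dec, lhw, lb, lin_rate)
            w = ((1.0 - lps) + lps * lv) * (1.0 - fear_damp * fear[i, k])
            if np.random.random() >= w:
                # unappealing candidate: stay with the group instead
                cx = 0.0
                cy = 0.0
                for c in range(cnt):
                    k2 = perc[c]
                    cx += _min_image(x[k2] - x[i], width)
                    cy += _min_image(y[k2] - y[i], height)
                cx /= cnt
                cy /= cnt
                dcen = math.hypot(cx, cy)
                if dcen > cohesion_dist:
                    x[i] = (x[i] + cx / dcen * step) % width
                    y[i] = (y[i] + cy / dcen * step) % height
                    heading[i] = math.atan2(cy, cx)
                else:
                    heading[i] = np.random.random() * TWO_PI
                    x[i] = (x[i] + math.cos(heading[i]) * step) % width
                    y[i] = (y[i] + math.sin(heading[i]) * step) % height
                counters[C_WALK] += 1
                my_time[i] = t + 1.0
                continue
            j = k
            dj = pdist[sel]
            pursue[i] = j
            pursue_until[i] = t + pursuit_minutes

        # act toward the chosen (or pursued) partner
        if dj <= reach:
            if grooming_with[j] < 0 and groomed_by[j] < 0:
                # start a grooming bout (first minute now)
                pursue[i] = -1
                grooming_with[i] = j
                groomed_by[j] = i
                counters[C_BOUTS] += 1
                ai = _relax(ar_v[i], 0.0, ar_base, ar_hl) + ar_bump
                ar_v[i] = ai if ai < 1.0 else 1.0
                aj = _relax(ar_v[j], t - ar_t[j], ar_base, ar_hl) + ar_bump
                ar_v[j] = aj if aj < 1.0 else 1.0
                ar_t[j] = t
                dt = t - like_t[j, i]
                v = decay_value(like[j, i], dt, dec_exp, k_dec, lhw, lb, lin_rate)
                v = increase_value(v, 1.0, inc_linear, a, k_inc, lb, ub)
                like[j, i] = v
                like_t[j, i] = t + 1.0
                counters[C_LIKE_WRITES] += 1
                sv = _relax(sat_v[j], t - sat_t[j], 0.0, sat_hl) + sat_gain
                sat_v[j] = sv if sv < 1.0 else 1.0
                sat_t[j] = t
                si = _relax(sat_v[i], t - sat_t[i], 0.0, sat_hl) + sat_gain
                sat_v[i] = si if si < 1.0 else 1.0
                sat_t[i] = t
                axj = _relax(anx_v[j], t - anx_t[j], 0.0, anx_hl) - anx_relief
                anx_v[j] = axj if axj > 0.0 else 0.0
                anx_t[j] = t
                axi = _relax(anx_v[i], t - anx_t[i], 0.0, anx_hl) - anx_relief
                anx_v[i] = axi if axi > 0.0 else 0.0
                anx_t[i] = t
                if t >= t_stab and t < t_end:
                    groom_minutes[i, j] += 1.0
                counters[C_GROOM_MIN] += 1
                my_time[i] = t + 1.0
                my_time[j] = t + 1.0
            else:
                # partner busy grooming someone: wait within reach
                counters[C_APPROACH] += 1
                my_time[i] = t + 1.0
        elif np.random.random() < affil_sig_p:
            aj = _relax(ar_v[j], t - ar_t[j], ar_base, ar_hl) + ar_bump
            ar_v[j] = aj if aj < 1.0 else 1.0
            ar_t[j] = t
            counters[C_AFFSIG] += 1
            my_time[i] = t + 1.0
        else:
            dx = _min_image(x[j] - x[i], width)
            dy = _min_image(y[j] - y[i], height)
            d = math.hypot(dx, dy)
            if d > 1e-12:
                ss = step if step < d else d
                x[i] = (x[i] + dx / d * ss) % width
                y[i] = (y[i] + dy / d * ss) % height
                heading[i] = math.atan2(dy, dx)
            counters[C_APPROACH] += 1
            my_time[i] = t + 1.0
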